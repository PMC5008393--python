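import numpy as np
import pytest

from mirser import (
    CtMatrix,
    GeneratorConfig,
    consensus_call,
    detection_filter,
    differential_table,
    generate_serum_dataset,
    invariant_normalize,
    is_kras,
    is_wild_type,
    vsn_normalize,
)

CONTRAST = (is_kras, is_wild_type)


@pytest.fixture(scope="session")
def serum_dataset():
    """Default synthetic serum profiling dataset (768 assays, 3 WT vs 6 mutant)."""
    return generate_serum_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def filtered_serum(serum_dataset):
    filtered, dropped = detection_filter(serum_dataset.ct)
    return filtered, dropped


@pytest.fixture(scope="session")
def serum_quantities(filtered_serum):
    filtered, _ = filtered_serum
    return vsn_normalize(filtered), invariant_normalize(filtered)


@pytest.fixture(scope="session")
def serum_consensus(serum_dataset, serum_quantities):
    q_vsn, q_inv = serum_quantities
    res_vsn = differential_table(q_vsn, serum_dataset.samples, CONTRAST,
                                 assays=serum_dataset.assays)
    res_inv = differential_table(q_inv, serum_dataset.samples, CONTRAST,
                                 assays=serum_dataset.assays)
    return consensus_call(res_vsn, res_inv)


@pytest.fixture
def small_ct():
    """3 assays x 2 samples with one undetected well."""
    return CtMatrix(
        ["miR-a", "miR-b", "miR-c"],
        ["s1", "s2"],
        np.array([[25.0, 26.0], [30.0, np.nan], [33.5, 34.25]]),
    )
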