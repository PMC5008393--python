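import math

import numpy as np
import pytest
from scipy import stats

from mirser import (
    DifferentialResult,
    GeneratorConfig,
    agreement_table_from_margins,
    cohens_kappa,
    consensus_call,
    detection_filter,
    differential_table,
    generate_serum_dataset,
    invariant_normalize,
    is_kras,
    is_wild_type,
    welch_test,
)
from mirser.io_model import (
    AssayUniverseMismatchError,
    DegenerateVarianceError,
    EmptyGroupError,
    InsufficientReplicatesError,
    MirserError,
)

CONTRAST = (is_kras, is_wild_type)


# ---------------------------------------------------------------------------
# Welch test
# ---------------------------------------------------------------------------

def _welch_by_hand(a, b):
    """Independent evaluation of the Welch formulas (oracle for welch_test)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def test_welch_identical_groups_give_null_result():
    t, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0


@pytest.mark.parametrize(
    "a,b",
    [
        ([1.0, 2.0, 3.0], [1.5, 2.5]),
        ([0.1, 0.2, 0.35, 0.4], [0.5, 0.9, 1.4]),
        (list(np.random.default_rng(1).normal(0, 1, 8)),
         list(np.random.default_rng(2).normal(0.4, 2, 5))),
    ],
)
def test_welch_matches_independent_formula_evaluation(a, b):
    t, p = welch_test(a, b)
    t_ref, p_ref = _welch_by_hand(a, b)
    assert abs(t - t_ref) < 1e-10 and abs(p - p_ref) < 1e-10


def test_welch_antisymmetric_in_group_order():
    a, b = [1.0, 2.0, 3.0], [1.5, 2.5]
    t_ab, p_ab = welch_test(a, b)
    t_ba, p_ba = welch_test(b, a)
    assert t_ab == pytest.approx(-t_ba) and p_ab == pytest.approx(p_ba)


def test_welch_degenerate_inputs():
    with pytest.raises(InsufficientReplicatesError):
        welch_test([1.0], [2.0, 3.0])
    assert welch_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
    with pytest.raises(DegenerateVarianceError):
        welch_test([2.0, 2.0], [3.0, 3.0])


# ---------------------------------------------------------------------------
# differential table
# ---------------------------------------------------------------------------

def test_null_significant_fraction_within_binomial_band():
    cfg = GeneratorConfig(seed=21, n_assays=1006, fraction_expressed=1.0,
                          n_effect_assays=0)
    ds = generate_serum_dataset(cfg)
    filtered, _ = detection_filter(ds.ct)
    q = invariant_normalize(filtered)
    results = differential_table(q, ds.samples, CONTRAST, alpha=0.05,
                                 assays=ds.assays)
    assert len(results) >= 990
    frac = np.mean([r.significant for r in results])
    half_width = 2.576 * math.sqrt(0.05 * 0.95 / len(results))
    assert abs(frac - 0.05) <= half_width


def test_injected_ct_increase_detected_as_decreased_quantity():
    """A +4 Ct case shift means ~16x less template: log2 fold change near -4."""
    # keep shifted case wells clear of the detection limit so censoring does
    # not truncate the injected effect
    cfg = GeneratorConfig(seed=22, n_assays=106, fraction_expressed=1.0,
                          n_effect_assays=10, effect_ct_shift=+4.0,
                          baseline_ct_range=(22.0, 33.0))
    ds = generate_serum_dataset(cfg)
    filtered, _ = detection_filter(ds.ct)
    q = invariant_normalize(filtered)
    results = {r.assay_id: r for r in
               differential_table(q, ds.samples, CONTRAST, assays=ds.assays)}
    shifted = [a for a in ds.truth.effect_shifts if a in results]
    assert shifted
    for assay in shifted:
        r = results[assay]
        assert r.significant and r.log2_fold_change < 0
    estimates = [results[a].log2_fold_change for a in shifted]
    assert np.mean(estimates) == pytest.approx(-4.0, abs=0.5)


def test_alpha_zero_yields_no_calls(serum_dataset, serum_quantities):
    _, q_inv = serum_quantities
    results = differential_table(q_inv, serum_dataset.samples, CONTRAST,
                                 alpha=0.0, assays=serum_dataset.assays)
    assert not any(r.significant for r in results)


def test_empty_group_predicate_raises(serum_quantities, serum_dataset):
    _, q_inv = serum_quantities
    with pytest.raises(EmptyGroupError):
        differential_table(q_inv, serum_dataset.samples,
                           (lambda s: False, is_wild_type))


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def test_kappa_from_printed_profiling_margins():
    table = agreement_table_from_margins(366, 85, 108, 76)
    np.testing.assert_array_equal(table, [[76, 9], [32, 249]])
    assert round(cohens_kappa(table), 2) == 0.71


def test_kappa_perfect_and_chance_agreement():
    assert cohens_kappa([[10, 0], [0, 10]]) == 1.0
    # counts exactly proportional to marginal products -> chance level
    assert cohens_kappa([[9, 21], [21, 49]]) == pytest.approx(0.0, abs=1e-12)


def test_kappa_symmetric_under_transpose():
    rng = np.random.default_rng(7)
    for _ in range(50):
        table = rng.integers(0, 40, size=(2, 2))
        if table.sum() == 0:
            continue
        assert cohens_kappa(table) == pytest.approx(cohens_kappa(table.T))


def test_kappa_rejects_negative_counts():
    with pytest.raises(MirserError):
        cohens_kappa([[5, -1], [0, 3]])
    with pytest.raises(MirserError):
        agreement_table_from_margins(100, 5, 3, 6)


def test_kappa_closed_form_equals_label_vector_brute_force():
    """The table formula must agree with kappa computed directly from two
    binary rater vectors, across 1,000 random pairs."""
    rng = np.random.default_rng(8)
    for _ in range(1000):
        n = rng.integers(2, 60)
        x = rng.integers(0, 2, size=n)
        y = rng.integers(0, 2, size=n)
        p_o = np.mean(x == y)
        p_e = float(np.mean(x) * np.mean(y) + (1 - np.mean(x)) * (1 - np.mean(y)))
        table = [[np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
                 [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))]]
        if p_e == 1.0:
            assert cohens_kappa(table) == 1.0
        else:
            assert cohens_kappa(table) == pytest.approx((p_o - p_e) / (1 - p_e),
                                                        rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _result(assay, p, lfc):
    return DifferentialResult(assay, lfc, 0.0, lfc, 0.0, p, p < 0.05)


def test_consensus_identical_concordant_sets_have_unit_kappa():
    res_a = [_result("x", 0.01, 1.0), _result("y", 0.01, -2.0), _result("z", 0.5, 0.1)]
    res_b = [_result("x", 0.02, 0.5), _result("y", 0.03, -1.0), _result("z", 0.6, 0.2)]
    c = consensus_call(res_a, res_b)
    assert c.consensus == ["x", "y"]
    assert c.consensus_increased == ["x"] and c.consensus_decreased == ["y"]
    assert c.kappa == 1.0
    assert c.agreement_table.sum() == c.tested_n == 3


def test_consensus_disjoint_sets_are_empty():
    res_a = [_result("x", 0.01, 1.0), _result("y", 0.5, 1.0)]
    res_b = [_result("x", 0.5, 1.0), _result("y", 0.01, 1.0)]
    c = consensus_call(res_a, res_b)
    assert c.consensus == [] and c.discordant == []
    assert c.agreement_table[0, 1] == 1 and c.agreement_table[1, 0] == 1


def test_consensus_excludes_direction_discordant_assays():
    res_a = [_result("x", 0.01, 1.0)]
    res_b = [_result("x", 0.01, -1.0)]
    c = consensus_call(res_a, res_b)
    assert c.consensus == [] and c.discordant == ["x"]


def test_consensus_requires_matching_assay_universe():
    with pytest.raises(AssayUniverseMismatchError, match="y"):
        consensus_call([_result("x", 0.5, 0.0)],
                       [_result("x", 0.5, 0.0), _result("y", 0.5, 0.0)])


def test_consensus_recovers_large_injected_effects(serum_quantities, serum_dataset):
    """60 strong effects at the study's noise level: >= 90% recovered, none
    direction-discordant."""
    from mirser import consensus_call, vsn_normalize

    cfg = GeneratorConfig(seed=23, n_effect_assays=60, effect_ct_shift=-4.0)
    ds = generate_serum_dataset(cfg)
    filtered, _ = detection_filter(ds.ct)
    res_a = differential_table(vsn_normalize(filtered), ds.samples, CONTRAST,
                               assays=ds.assays)
    res_b = differential_table(invariant_normalize(filtered), ds.samples, CONTRAST,
                               assays=ds.assays)
    c = consensus_call(res_a, res_b)
    injected = set(ds.truth.effect_shifts) & {r.assay_id for r in res_a}
    recovered = injected & set(c.consensus_increased)
    assert len(recovered) >= 0.9 * len(injected)
    assert c.discordant == []
    assert c.kappa > 0
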