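import numpy as np
import pytest
from scipy import stats

from mirser import (
    CtMatrix,
    GeneratorConfig,
    ct_to_amount,
    detection_filter,
    generate_serum_dataset,
    invariant_normalize,
    vsn_normalize,
)
from mirser.io_model import EmptyPanelError, MirserError, MissingReferenceError


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------

def test_detection_filter_drops_assay_with_undetected_well(small_ct):
    filtered, dropped = detection_filter(small_ct, max_ct=40)
    assert filtered.assay_ids == ["miR-a", "miR-c"]
    assert dropped == 1
    assert filtered.sample_ids == small_ct.sample_ids


def test_detection_filter_identity_and_idempotence():
    ct = CtMatrix(["a", "b"], ["s1", "s2"], np.full((2, 2), 30.0))
    filtered, dropped = detection_filter(ct, max_ct=40)
    assert dropped == 0 and filtered.assay_ids == ct.assay_ids
    again, dropped2 = detection_filter(filtered, max_ct=40)
    assert dropped2 == 0
    np.testing.assert_array_equal(again.ct, filtered.ct)


def test_detection_filter_empty_panel_error(small_ct):
    with pytest.raises(EmptyPanelError):
        detection_filter(small_ct, max_ct=10)


def test_detection_filter_count_matches_closed_form_expectation():
    """Retained-assay count sits inside the 99% band of the generator's own
    closed-form detection probabilities (Poisson-binomial, normal approx)."""
    ds = generate_serum_dataset(GeneratorConfig(seed=11))
    _, dropped = detection_filter(ds.ct, max_ct=ds.truth.lod_ct)
    retained = len(ds.ct.assay_ids) - dropped
    p = ds.truth.detect_all_probabilities().to_numpy()
    mean, sd = p.sum(), np.sqrt((p * (1 - p)).sum())
    assert abs(retained - mean) <= 2.576 * sd + 1e-9
    # and the panel behaves like the real card: about half detected everywhere
    assert 0.45 <= retained / len(ds.ct.assay_ids) <= 0.55


# ---------------------------------------------------------------------------
# amount transform
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ct,expected", [(50.0, 1.0), (49.0, 2.0), (40.0, 1024.0)])
def test_ct_to_amount_unit_convention(ct, expected):
    assert ct_to_amount(ct) == expected


def test_ct_to_amount_propagates_sentinel_and_is_decreasing():
    assert np.isnan(ct_to_amount(np.nan))
    grid = np.linspace(10, 45, 50)
    amounts = ct_to_amount(grid)
    assert np.all(np.diff(amounts) < 0)


# ---------------------------------------------------------------------------
# VSN-style normalization
# ---------------------------------------------------------------------------

def test_vsn_identical_columns_stay_identical():
    col = np.array([24.0, 28.0, 31.0, 35.0])
    ct = CtMatrix(["a", "b", "c", "d"], ["s1", "s2", "s3"],
                  np.column_stack([col, col, col]))
    q = vsn_normalize(ct)
    np.testing.assert_allclose(q.quantity[:, 0], q.quantity[:, 1])
    np.testing.assert_allclose(q.quantity[:, 0], q.quantity[:, 2])


def test_vsn_cancels_injected_per_sample_offset():
    rng = np.random.default_rng(3)
    base = rng.uniform(22, 36, size=(40, 4))
    ct = CtMatrix([f"a{i}" for i in range(40)], ["s1", "s2", "s3", "s4"], base)
    shifted_vals = base.copy()
    shifted_vals[:, 1] += 2.0  # one sample runs 2 cycles late
    shifted = CtMatrix(ct.assay_ids, ct.sample_ids, shifted_vals)
    q0, q1 = vsn_normalize(ct), vsn_normalize(shifted)
    medians = np.median(q1.quantity, axis=0)
    np.testing.assert_allclose(medians, medians[0], atol=1e-9)
    # per-sample rescaling removes the offset entirely, not just the median
    np.testing.assert_allclose(q0.quantity, q1.quantity, atol=1e-9)


def test_vsn_monotone_within_sample():
    rng = np.random.default_rng(4)
    vals = rng.uniform(20, 38, size=(30, 3))
    ct = CtMatrix([f"a{i}" for i in range(30)], ["s1", "s2", "s3"], vals)
    q = vsn_normalize(ct)
    for j in range(3):
        order = np.argsort(vals[:, j])  # ascending Ct
        assert np.all(np.diff(q.quantity[order, j]) < 0)  # descending quantity


def test_vsn_requires_two_samples():
    ct = CtMatrix(["a", "b"], ["s1"], np.array([[25.0], [30.0]]))
    with pytest.raises(MirserError):
        vsn_normalize(ct)


# ---------------------------------------------------------------------------
# invariant normalization
# ---------------------------------------------------------------------------

def _invariant_fixture():
    # two invariant assays with per-sample means 25 and 27
    vals = np.array([
        [24.0, 26.0],   # inv-1
        [26.0, 28.0],   # inv-2
        [25.0, 27.0],   # target at the invariant mean
        [24.0, 26.0],   # target one cycle below the mean
    ])
    return CtMatrix(["inv-1", "inv-2", "t-mean", "t-minus1"], ["s1", "s2"], vals)


def test_invariant_quantity_one_at_reference_mean():
    q = invariant_normalize(_invariant_fixture(), ["inv-1", "inv-2"])
    i = q.assay_index("t-mean")
    np.testing.assert_allclose(q.quantity[i], [1.0, 1.0])
    np.testing.assert_allclose(q.quantity[q.assay_index("t-minus1")], [2.0, 2.0])


def test_invariant_exactly_cancels_global_sample_shift():
    ct = _invariant_fixture()
    rng = np.random.default_rng(5)
    offsets = rng.normal(0, 1.5, size=len(ct.sample_ids))
    shifted = CtMatrix(ct.assay_ids, ct.sample_ids, ct.ct + offsets[None, :])
    q0 = invariant_normalize(ct, ["inv-1", "inv-2"])
    q1 = invariant_normalize(shifted, ["inv-1", "inv-2"])
    np.testing.assert_allclose(q0.quantity, q1.quantity, rtol=1e-12)


def test_single_invariant_assay_is_its_own_unit():
    ct = _invariant_fixture()
    q = invariant_normalize(ct, ["inv-1"])
    np.testing.assert_allclose(q.quantity[q.assay_index("inv-1")], [1.0, 1.0])


def test_invariant_errors_name_assay_and_sample():
    ct = _invariant_fixture()
    vals = ct.ct.copy()
    vals[0, 1] = np.nan
    broken = CtMatrix(ct.assay_ids, ct.sample_ids, vals)
    with pytest.raises(MissingReferenceError, match="inv-1.*s2"):
        invariant_normalize(broken, ["inv-1", "inv-2"])
    with pytest.raises(MissingReferenceError, match="absent"):
        invariant_normalize(ct, ["not-there"])


# ---------------------------------------------------------------------------
# cross-method properties
# ---------------------------------------------------------------------------

def test_both_methods_preserve_within_sample_rank_order():
    rng = np.random.default_rng(6)
    vals = np.vstack([rng.uniform(22, 36, size=(50, 5)),
                      rng.uniform(26, 30, size=(2, 5))])
    ids = [f"a{i}" for i in range(50)] + ["inv-1", "inv-2"]
    ct = CtMatrix(ids, [f"s{j}" for j in range(5)], vals)
    q_vsn = vsn_normalize(ct)
    q_inv = invariant_normalize(ct, ["inv-1", "inv-2"])
    for j in range(5):
        abundance_rank = len(ids) + 1 - stats.rankdata(vals[:, j])  # low Ct = high rank
        np.testing.assert_array_equal(stats.rankdata(q_vsn.quantity[:, j]), abundance_rank)
        np.testing.assert_array_equal(stats.rankdata(q_inv.quantity[:, j]), abundance_rank)
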