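"""Two-group differential testing per normalization method and consensus
calling with Cohen's kappa agreement.

Each miRNA is tested with Welch's unequal-variance two-tailed t test on log2
quantities, significance at p < alpha with no multiple-testing correction.
A miRNA is a *consensus* call only if significant under both normalization
schemes with concordant direction; agreement between the two schemes'
binary calls is summarized by Cohen's chance-corrected kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .io_model import (
    AssayAnnotation,
    AssayRole,
    AssayUniverseMismatchError,
    DegenerateVarianceError,
    EmptyGroupError,
    InsufficientReplicatesError,
    MirserError,
    QuantityMatrix,
    SampleAnnotation,
)

__all__ = [
    "DEFAULT_ALPHA",
    "DifferentialResult",
    "ConsensusResult",
    "welch_test",
    "differential_table",
    "cohens_kappa",
    "agreement_table_from_margins",
    "consensus_call",
]

#: Significance level used throughout; no multiple-testing correction.
DEFAULT_ALPHA = 0.05

SamplePredicate = Callable[[SampleAnnotation], bool]


def welch_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-tailed t test with Welch-Satterthwaite degrees of freedom.

    Returns ``(t_statistic, p_value)``, with t oriented as mean(a) - mean(b).
    Each group needs >= 2 finite values.  If both sample variances are zero
    the test statistic is undefined: equal means return ``(0.0, 1.0)`` by
    convention, unequal means raise :class:`DegenerateVarianceError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"welch_test needs >= 2 values per group (got {a.size}, {b.size})"
        )
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise MirserError("welch_test requires finite values")
    # a constant group has zero variance even when floating-point summation
    # makes the computed moment a non-zero ulp; test the range instead
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise DegenerateVarianceError(
            "both groups have zero variance with unequal means"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class DifferentialResult:
    """Per-assay two-group test outcome on the log2 quantity scale."""

    assay_id: str
    mean_case: float
    mean_control: float
    log2_fold_change: float
    t_statistic: float
    p_value: float
    significant: bool


def _select(samples: Sequence[SampleAnnotation], predicate: SamplePredicate) -> list[str]:
    return [s.sample_id for s in samples if predicate(s)]


def differential_table(
    q: QuantityMatrix,
    samples: Sequence[SampleAnnotation],
    contrast: tuple[SamplePredicate, SamplePredicate],
    alpha: float = DEFAULT_ALPHA,
    assays: Sequence[AssayAnnotation] | None = None,
) -> list[DifferentialResult]:
    """Welch-test every target assay between case and control sample groups.

    ``contrast`` is a (case predicate, control predicate) pair over sample
    annotations.  Quantities are log2-transformed before testing; the fold
    change is mean(case) - mean(control) on that scale, so a positive value
    means more abundant in cases.  When ``assays`` is given, only assays with
    role TARGET are tested (spike-ins and references are excluded from
    target statistics).  Assays with any undetected value in the selected
    samples are excluded (run the detection filter upstream).
    """
    case_pred, control_pred = contrast
    case_ids = _select(samples, case_pred)
    control_ids = _select(samples, control_pred)
    if not case_ids or not control_ids:
        raise EmptyGroupError(
            f"contrast selected {len(case_ids)} case / {len(control_ids)} control samples"
        )
    sample_pos = {sid: j for j, sid in enumerate(q.sample_ids)}
    case_idx = [sample_pos[s] for s in case_ids if s in sample_pos]
    control_idx = [sample_pos[s] for s in control_ids if s in sample_pos]
    if not case_idx or not control_idx:
        raise EmptyGroupError("contrast selected no samples present in the matrix")

    target_ids: set[str] | None = None
    if assays is not None:
        target_ids = {a.assay_id for a in assays if a.role is AssayRole.TARGET}

    out: list[DifferentialResult] = []
    log_q = np.log2(q.quantity)
    for i, assay in enumerate(q.assay_ids):
        if target_ids is not None and assay not in target_ids:
            continue
        va = log_q[i, case_idx]
        vb = log_q[i, control_idx]
        if np.any(np.isnan(va)) or np.any(np.isnan(vb)):
            continue
        t, p = welch_test(va, vb)
        mean_case = float(va.mean())
        mean_control = float(vb.mean())
        out.append(
            DifferentialResult(
                assay_id=assay,
                mean_case=mean_case,
                mean_control=mean_control,
                log2_fold_change=mean_case - mean_control,
                t_statistic=t,
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return out


def cohens_kappa(agreement_table) -> float:
    """Cohen's kappa for a 2x2 agreement table ``[[both, a_only], [b_only, neither]]``.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (both + neither) / n and chance agreement p_e from the marginal
    products.  The degenerate all-agree table (p_e = 1, p_o = 1) returns 1.0
    exactly.
    """
    table = np.asarray(agreement_table, dtype=float)
    if table.shape != (2, 2):
        raise MirserError(f"agreement table must be 2x2, got shape {table.shape}")
    if np.any(table < 0):
        raise MirserError("agreement table counts must be non-negative")
    n = table.sum()
    if n <= 0:
        raise MirserError("agreement table must have positive total")
    p_o = (table[0, 0] + table[1, 1]) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e == 1.0:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def agreement_table_from_margins(
    tested_n: int, sig_a: int, sig_b: int, both: int
) -> np.ndarray:
    """Reconstruct the 2x2 agreement table from its printed margins.

    From the number of assays tested, the per-method significant counts and
    the size of their intersection: a-only = sig_a - both,
    b-only = sig_b - both, neither = tested - sig_a - sig_b + both.
    """
    a_only = sig_a - both
    b_only = sig_b - both
    neither = tested_n - sig_a - sig_b + both
    table = np.array([[both, a_only], [b_only, neither]], dtype=float)
    if np.any(table < 0):
        raise MirserError("inconsistent margins: negative cell count implied")
    return table


@dataclass
class ConsensusResult:
    """Cross-method agreement summary for one contrast.

    ``agreement_table`` rows index method A's call (significant / not), columns
    method B's; it sums to ``tested_n``.  Direction-discordant dual-significant
    assays are excluded from the increased/decreased partition and listed in
    ``discordant``.
    """

    tested_n: int
    sig_method_a: set[str]
    sig_method_b: set[str]
    consensus_increased: list[str]
    consensus_decreased: list[str]
    discordant: list[str]
    agreement_table: np.ndarray
    kappa: float

    @property
    def consensus(self) -> list[str]:
        return sorted(self.consensus_increased + self.consensus_decreased)

    @property
    def kappa_2dp(self) -> float:
        """Kappa rounded to 2 decimals, matching customary reporting."""
        return round(self.kappa, 2)


def consensus_call(
    results_a: Sequence[DifferentialResult],
    results_b: Sequence[DifferentialResult],
) -> ConsensusResult:
    """Intersect the two methods' significant sets and score their agreement.

    Both result lists must cover the same assay universe.  An assay is in the
    consensus when significant under both methods; its direction (increased /
    decreased in cases) comes from the shared sign of the log2 fold change.
    Dual-significant assays whose fold-change signs disagree are excluded
    from the partition and reported separately.
    """
    universe_a = {r.assay_id for r in results_a}
    universe_b = {r.assay_id for r in results_b}
    if universe_a != universe_b:
        diff = sorted(universe_a.symmetric_difference(universe_b))
        raise AssayUniverseMismatchError(
            f"assay universes differ; symmetric difference: {diff}"
        )
    by_a = {r.assay_id: r for r in results_a}
    by_b = {r.assay_id: r for r in results_b}
    sig_a = {a for a, r in by_a.items() if r.significant}
    sig_b = {a for a, r in by_b.items() if r.significant}
    both = sig_a & sig_b

    increased, decreased, discordant = [], [], []
    for assay in sorted(both):
        sa = np.sign(by_a[assay].log2_fold_change)
        sb = np.sign(by_b[assay].log2_fold_change)
        if sa > 0 and sb > 0:
            increased.append(assay)
        elif sa < 0 and sb < 0:
            decreased.append(assay)
        else:
            discordant.append(assay)

    n = len(universe_a)
    table = np.array(
        [
            [len(both), len(sig_a - sig_b)],
            [len(sig_b - sig_a), n - len(sig_a | sig_b)],
        ],
        dtype=float,
    )
    return ConsensusResult(
        tested_n=n,
        sig_method_a=sig_a,
        sig_method_b=sig_b,
        consensus_increased=increased,
        consensus_decreased=decreased,
        discordant=discordant,
        agreement_table=table,
        kappa=cohens_kappa(table),
    )
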