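"""Serum normalization: detection filtering, amount transform, VSN-style and
invariant delta-Ct normalization.

Two complementary schemes are implemented.  The variance-stabilizing scheme
first converts each Ct to a linear amount ``2^(50 - Ct)`` (an assay with
Ct = 50 defines one arbitrary unit), then applies an arcsinh transform with
per-sample scale factors chosen so every sample has the same median on the
stabilized scale.  The invariant scheme references each Ct against the
per-sample mean Ct of a fixed set of empirically stable serum miRNAs
(delta-Ct against their mean), yielding linear quantities ``2^(r_j - Ct)``.
Both are monotone in -Ct within a sample and cancel per-sample global Ct
offsets — exactly for the invariant scheme, by per-sample rescaling for the
variance-stabilizing one.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .io_model import (
    DEFAULT_INVARIANT_IDS,
    ConfigError,
    CtMatrix,
    EmptyPanelError,
    MirserError,
    MissingReferenceError,
    NormMethod,
    QuantityMatrix,
)

__all__ = [
    "DEFAULT_MAX_CT",
    "CT_UNIT_REFERENCE",
    "detection_filter",
    "ct_to_amount",
    "vsn_normalize",
    "invariant_normalize",
]

#: TaqMan arrays report Ct <= 40 or "Undetermined": any amplified well counts
#: as detected by default.
DEFAULT_MAX_CT = 40.0

#: Ct value arbitrarily defined as one unit of amount.
CT_UNIT_REFERENCE = 50.0


def detection_filter(
    ct: CtMatrix, max_ct: float = DEFAULT_MAX_CT
) -> tuple[CtMatrix, int]:
    """Keep only assays detected (non-sentinel Ct < max_ct) in every sample.

    Returns the restricted matrix and the number of assays dropped.  The
    sample set is unchanged and retained + dropped equals the input assay
    count.  Raises :class:`EmptyPanelError` if nothing survives.
    """
    if not max_ct > 0:
        raise ConfigError("max_ct must be > 0")
    ok = np.all(~np.isnan(ct.ct) & (ct.ct < max_ct), axis=1)
    kept = [a for a, keep in zip(ct.assay_ids, ok) if keep]
    if not kept:
        raise EmptyPanelError("no assay is detected in all samples")
    return ct.subset_assays(kept), int(len(ct.assay_ids) - len(kept))


def ct_to_amount(ct_value):
    """Linear amount ``2^(50 - Ct)``; Ct = 50 is one unit.

    Accepts scalars or arrays; the undetected sentinel (nan) propagates, since
    an amount is undefined for a well that never amplified.  Strictly
    decreasing in Ct: one cycle earlier doubles the amount.
    """
    return np.exp2(CT_UNIT_REFERENCE - np.asarray(ct_value, dtype=float))[()]


def vsn_normalize(ct: CtMatrix) -> QuantityMatrix:
    """Variance-stabilized amounts with per-sample median matching.

    Amounts ``a = 2^(50 - Ct)`` are computed per well; each sample j is scaled
    by its median amount ``s_j`` and passed through
    ``h(a) = arcsinh(c * a / s_j)`` with the fixed scale constant
    ``c = 2^20`` (the amount of a mid-panel well at Ct 30), chosen so the
    stabilized values land in a convenient positive range while keeping the
    output an exact function of the within-sample amount ratios.
    A final per-sample additive adjustment on the stabilized scale (a
    multiplicative one on amounts) makes the median transformed value exactly
    equal across samples.  A global Ct offset on a sample multiplies all its
    amounts by a constant and is cancelled entirely by ``s_j``.  The output
    is tagged ``VSN_AMOUNT`` and carried on the stabilized (glog-like) scale.

    Intended to run after :func:`detection_filter`; wells still undetected
    propagate nan and are ignored by the per-sample medians.
    """
    if len(ct.sample_ids) < 2:
        raise MirserError("vsn_normalize needs at least 2 samples")
    amounts = np.exp2(CT_UNIT_REFERENCE - ct.ct)
    s = np.nanmedian(amounts, axis=0)  # per-sample scale
    if np.any(np.isnan(s)) or np.any(s <= 0):
        raise EmptyPanelError("a sample has no detected assays to scale by")
    c = float(np.exp2(CT_UNIT_REFERENCE - 30.0))  # fixed scale constant
    stabilized = np.arcsinh(c * amounts / s)
    # exact median matching: with an even assay count the interpolated median
    # does not commute with arcsinh, so equalize residual median differences
    med = np.nanmedian(stabilized, axis=0)
    stabilized = stabilized - med + med.mean()
    if np.nanmin(stabilized) <= 0:
        raise MirserError(
            "variance-stabilized values are not positive; Ct values this close "
            "to the unit reference are outside the transform's working range"
        )
    return QuantityMatrix(
        list(ct.assay_ids), list(ct.sample_ids), stabilized, NormMethod.VSN_AMOUNT
    )


def invariant_normalize(
    ct: CtMatrix, invariant_ids: Iterable[str] = DEFAULT_INVARIANT_IDS
) -> QuantityMatrix:
    """Delta-Ct quantities against the mean Ct of the invariant reference set.

    Per sample j the reference ``r_j`` is the arithmetic mean of the invariant
    assays' Ct values (equivalently, the geometric mean of their amounts);
    the normalized quantity of assay x is ``2^(r_j - Ct(x, j))``.  Invariant
    assays themselves are retained in the output.  Each invariant assay must
    be present and detected in every sample.
    """
    invariant_ids = sorted(invariant_ids)
    if not invariant_ids:
        raise ConfigError("invariant_ids must be non-empty")
    assay_set = set(ct.assay_ids)
    for inv in invariant_ids:
        if inv not in assay_set:
            raise MissingReferenceError(f"invariant assay {inv!r} absent from matrix")
    idx = [ct.assay_index(a) for a in invariant_ids]
    ref_block = ct.ct[idx]
    for k, inv in enumerate(invariant_ids):
        for j, sid in enumerate(ct.sample_ids):
            if np.isnan(ref_block[k, j]):
                raise MissingReferenceError(
                    f"invariant assay {inv!r} undetected in sample {sid!r}"
                )
    r = ref_block.mean(axis=0)  # per-sample reference Ct
    quantity = np.exp2(r - ct.ct)
    return QuantityMatrix(
        list(ct.assay_ids), list(ct.sample_ids), quantity, NormMethod.INVARIANT
    )
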