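"""Spike-in-referenced relative quantification for individual-miRNA qPCR.

Serum lacks stable endogenous controls, so two synthetic C. elegans miRNAs
(cel-miR-39-3p and cel-miR-54-3p, spiked before RNA extraction at a known
1,000-fold input-quantity difference) serve as external references.  The
relative expression of a target is ``2^(mean(Ct_39, Ct_54) - Ct(x))`` per
sample; averaging the two spike-in Cts despite their input difference only
offsets all relative expressions by a constant, which cancels in any group
contrast.  The known input ratio also provides an internal accuracy check:
the per-sample delta Ct between the spike-ins should equal log2(ratio) and
should not differ between biological groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    ConfigError,
    CtMatrix,
    EmptyGroupError,
    MissingControlError,
    SampleAnnotation,
)
from .differential_consensus import welch_test

__all__ = [
    "SpikeInConfig",
    "SpikeInControlCheck",
    "spike_in_relative_expression",
    "spike_in_control_check",
    "group_fold_change",
]


@dataclass(frozen=True)
class SpikeInConfig:
    """The two external spike-in assays and their input-quantity ratio."""

    low_input_assay: str = "cel-miR-39-3p"
    high_input_assay: str = "cel-miR-54-3p"
    input_ratio: float = 1000.0  # high-input / low-input spiked quantity

    def __post_init__(self) -> None:
        if not self.input_ratio > 0:
            raise ConfigError("input_ratio must be > 0")

    @property
    def expected_delta_ct(self) -> float:
        """Ct(low-input) - Ct(high-input) under equal amplification efficiency."""
        return math.log2(self.input_ratio)


def _spike_rows(ct: CtMatrix, spike: SpikeInConfig) -> tuple[np.ndarray, np.ndarray]:
    for assay in (spike.low_input_assay, spike.high_input_assay):
        if assay not in set(ct.assay_ids):
            raise MissingControlError(f"spike-in assay {assay!r} absent from matrix")
    low = ct.row(spike.low_input_assay)
    high = ct.row(spike.high_input_assay)
    for j, sid in enumerate(ct.sample_ids):
        for assay, row in (
            (spike.low_input_assay, low),
            (spike.high_input_assay, high),
        ):
            if np.isnan(row[j]):
                raise MissingControlError(
                    f"spike-in assay {assay!r} undetected in sample {sid!r}"
                )
    return low, high


def spike_in_relative_expression(
    ct: CtMatrix, spike: SpikeInConfig, target: str
) -> pd.Series:
    """Per-sample relative expression ``2^(mean(Ct_low, Ct_high) - Ct(target))``.

    Both spike-ins must be detected in every sample.  A per-sample Ct shift
    common to targets and spike-ins cancels.  Samples where the target is
    undetected yield nan.
    """
    low, high = _spike_rows(ct, spike)
    if target not in set(ct.assay_ids):
        raise MissingControlError(f"target assay {target!r} absent from matrix")
    ref = (low + high) / 2.0
    r = np.exp2(ref - ct.row(target))
    return pd.Series(r, index=list(ct.sample_ids), name=target)


@dataclass
class SpikeInControlCheck:
    """Per-sample spike-in delta Ct and its between-group comparison."""

    delta_ct: pd.Series  # Ct(low-input) - Ct(high-input), per sample
    expected_delta_ct: float  # log2(input_ratio)
    t_statistic: float | None = None
    p_value: float | None = None


def spike_in_control_check(
    ct: CtMatrix,
    spike: SpikeInConfig,
    samples: Sequence[SampleAnnotation] | None = None,
    contrast: tuple[Callable[[SampleAnnotation], bool], Callable[[SampleAnnotation], bool]] | None = None,
) -> SpikeInControlCheck:
    """Check the known spike-in input ratio and its stability across groups.

    The per-sample delta Ct (low-input minus high-input spike-in) should sit
    at log2(input_ratio) — 9.9658 cycles for a 1,000-fold difference — and,
    being independent of any biology, should not differ between groups; when
    ``samples`` and ``contrast`` are given the two groups are compared with
    Welch's test.
    """
    low, high = _spike_rows(ct, spike)
    delta = pd.Series(low - high, index=list(ct.sample_ids), name="delta_ct")
    check = SpikeInControlCheck(delta_ct=delta, expected_delta_ct=spike.expected_delta_ct)
    if samples is not None and contrast is not None:
        case_pred, control_pred = contrast
        case = [s.sample_id for s in samples if case_pred(s) and s.sample_id in delta.index]
        control = [
            s.sample_id for s in samples if control_pred(s) and s.sample_id in delta.index
        ]
        if not case or not control:
            raise EmptyGroupError("spike-in group comparison selected an empty group")
        t, p = welch_test(delta[case].to_numpy(), delta[control].to_numpy())
        check.t_statistic, check.p_value = t, p
    return check


def group_fold_change(
    r: pd.Series,
    samples: Sequence[SampleAnnotation],
    contrast: tuple[Callable[[SampleAnnotation], bool], Callable[[SampleAnnotation], bool]],
    geometric: bool = False,
) -> tuple[float, float]:
    """Fold change of group means and Welch p-value for one target.

    ``r`` holds per-sample relative expressions.  The fold change is
    mean(case)/mean(control) on the linear scale (matching how relative
    quantities are usually presented); set ``geometric=True`` for the
    geometric-mean variant.  The p-value always comes from Welch's test on
    log2 values.
    """
    case_pred, control_pred = contrast
    case = [s.sample_id for s in samples if case_pred(s) and s.sample_id in r.index]
    control = [
        s.sample_id for s in samples if control_pred(s) and s.sample_id in r.index
    ]
    if not case or not control:
        raise EmptyGroupError("group_fold_change selected an empty group")
    rc = r[case].to_numpy(dtype=float)
    rk = r[control].to_numpy(dtype=float)
    if np.any(np.isnan(rc)) or np.any(np.isnan(rk)):
        raise MissingControlError("target undetected in a selected sample")
    if geometric:
        fc = float(np.exp2(np.mean(np.log2(rc)) - np.mean(np.log2(rk))))
    else:
        fc = float(rc.mean() / rk.mean())
    _, p = welch_test(np.log2(rc), np.log2(rk))
    return fc, p
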