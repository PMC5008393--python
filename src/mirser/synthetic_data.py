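"""Synthetic Ct-array generator with known ground truth.

Emulates the three study designs end-to-end so every pipeline stage is
testable without external data:

* a serum profiling panel (default 768 assays: targets plus 4 invariant
  references and 2 spike-ins) across genotype/treatment groups, with
  group-dependent Ct shifts on a chosen assay subset, per-sample global Ct
  offsets, per-well Gaussian noise and censoring above a limit of detection
  calibrated so roughly half the panel is detected in every sample;
* duplicate pancreas-tissue lysates carrying a U6 endogenous control, with
  a configurable coupling between serum-increased assays and the abundant
  tissue stratum;
* an individual-miRNA qPCR validation set (16 targets, two genotype groups
  of 9 vs 10 mice) with the two spike-ins at a 1,000-fold input ratio.

The noise model is additive Gaussian on the Ct scale (log-normal on the
quantity scale); dropout is deterministic censoring at the limit of
detection.  Generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    AssayAnnotation,
    AssayRole,
    Compartment,
    ConfigError,
    CtMatrix,
    DEFAULT_INVARIANT_IDS,
    Genotype,
    SampleAnnotation,
)
from .qpcr_quant import SpikeInConfig
from .tissue_origin import DEFAULT_U6_ASSAY

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_serum_dataset",
    "generate_tissue_dataset",
    "generate_qpcr_dataset",
    "is_kras",
    "is_wild_type",
]

GroupSpec = tuple[Genotype, int, int]  # (genotype, caerulein weeks, n samples)

#: Serum profiling design: 3 untreated wild-type mice vs 6 mutants with 2- or
#: 4-week pancreatitis.
DEFAULT_SERUM_GROUPS: tuple[GroupSpec, ...] = (
    (Genotype.WILD_TYPE, 0, 3),
    (Genotype.KRAS_G12D, 2, 3),
    (Genotype.KRAS_G12D, 4, 3),
)

#: qPCR validation design: 9 mutant vs 10 age-matched wild-type mice.
DEFAULT_QPCR_GROUPS: tuple[GroupSpec, ...] = (
    (Genotype.KRAS_G12D, 0, 9),
    (Genotype.WILD_TYPE, 0, 10),
)


def is_kras(s: SampleAnnotation) -> bool:
    return s.genotype is Genotype.KRAS_G12D


def is_wild_type(s: SampleAnnotation) -> bool:
    return s.genotype is Genotype.WILD_TYPE


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic designs; defaults mirror the study designs.

    ``fraction_expressed`` controls what share of target assays carry a serum
    baseline inside ``baseline_ct_range``; the rest sit above the limit of
    detection (``absent_ct_range``) and drop out, so that with the defaults
    about half the panel is detected in all samples.  ``effect_ct_shift`` is
    signed on the Ct scale: negative means earlier amplification, i.e. more
    abundant, in the case group.
    """

    # panel
    n_assays: int = 768
    invariant_ids: tuple[str, ...] = tuple(sorted(DEFAULT_INVARIANT_IDS))
    spike: SpikeInConfig = field(default_factory=SpikeInConfig)
    # serum design
    groups: tuple[GroupSpec, ...] = DEFAULT_SERUM_GROUPS
    baseline_ct_range: tuple[float, float] = (22.0, 36.0)
    fraction_expressed: float = 0.5
    absent_ct_range: tuple[float, float] = (41.0, 46.0)
    n_effect_assays: int = 30
    effect_ct_shift: float = -3.0
    sample_offset_sd: float = 1.0
    noise_sd: float = 0.5
    lod_ct: float = 40.0
    # controls
    reference_ct_range: tuple[float, float] = (26.0, 30.0)
    reference_noise_sd: float = 0.1
    spike_baseline_ct: float = 30.0  # low-input spike-in; high-input is lower
    spike_noise_sd: float = 0.15
    # tissue design
    n_tissue_replicates: int = 2
    u6_assay: str = DEFAULT_U6_ASSAY
    u6_ct: float = 22.0
    u6_noise_sd: float = 0.1
    tissue_baseline_ct_range: tuple[float, float] = (24.0, 42.0)
    tissue_fraction_expressed: float = 0.625
    tissue_top_stratum_ct: tuple[float, float] = (24.0, 27.0)
    tissue_coupling_fraction: float = 0.5
    # qPCR design
    qpcr_groups: tuple[GroupSpec, ...] = DEFAULT_QPCR_GROUPS
    n_qpcr_targets: int = 16
    n_qpcr_effect_targets: int = 3
    qpcr_effect_ct_shift: float = -1.5
    qpcr_baseline_ct_range: tuple[float, float] = (26.0, 34.0)
    qpcr_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sample_offset_sd",
            "noise_sd",
            "reference_noise_sd",
            "spike_noise_sd",
            "u6_noise_sd",
            "qpcr_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.baseline_ct_range
        if not (0 < lo <= hi <= self.lod_ct):
            raise ConfigError("baseline_ct_range must lie within (0, lod_ct]")
        if not 0 <= self.fraction_expressed <= 1:
            raise ConfigError("fraction_expressed must be in [0, 1]")
        if not 0 <= self.tissue_coupling_fraction <= 1:
            raise ConfigError("tissue_coupling_fraction must be in [0, 1]")
        n_controls = len(self.invariant_ids) + 2
        if self.n_assays <= n_controls:
            raise ConfigError("n_assays must exceed the number of control assays")
        if self.n_effect_assays < 0 or self.n_qpcr_effect_targets < 0:
            raise ConfigError("effect-assay counts must be >= 0")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Everything needed to recompute expectations for one generated dataset.

    ``mean_ct`` holds the noise-free expected Ct per well (baseline + group
    effect + per-sample offset); ``assay_noise_sd`` the per-well noise SD per
    assay.  Together with ``lod_ct`` they give the closed-form detection
    probabilities.  ``effect_shifts`` maps each perturbed assay to its signed
    Ct shift in the case group.
    """

    baselines: dict[str, float]
    effect_shifts: dict[str, float]
    sample_offsets: dict[str, float]
    assay_noise_sd: dict[str, float]
    mean_ct: pd.DataFrame  # assays x samples, noise-free
    lod_ct: float
    expressed: set[str] = field(default_factory=set)
    abundant_stratum: set[str] = field(default_factory=set)
    coupled: set[str] = field(default_factory=set)

    @property
    def increased(self) -> set[str]:
        """Assays more abundant in cases (negative Ct shift)."""
        return {a for a, s in self.effect_shifts.items() if s < 0}

    @property
    def decreased(self) -> set[str]:
        return {a for a, s in self.effect_shifts.items() if s > 0}

    def detect_probabilities(self) -> pd.DataFrame:
        """Closed-form P(well detected) per assay x sample.

        Detection means Ct below the limit: with Gaussian per-well noise,
        P = Phi((lod - mean_ct) / sigma_assay).
        """
        sd = np.array(
            [self.assay_noise_sd[a] for a in self.mean_ct.index]
        )[:, None]
        z = (self.lod_ct - self.mean_ct.to_numpy()) / np.where(sd > 0, sd, np.inf)
        probs = stats.norm.cdf(z)
        # zero-noise wells detect deterministically
        det = (self.mean_ct.to_numpy() < self.lod_ct).astype(float)
        probs = np.where(np.broadcast_to(sd, probs.shape) > 0, probs, det)
        return pd.DataFrame(probs, index=self.mean_ct.index, columns=self.mean_ct.columns)

    def detect_all_probabilities(self) -> pd.Series:
        """Closed-form P(assay detected in every sample)."""
        return self.detect_probabilities().prod(axis=1)


@dataclass
class SyntheticDataset:
    ct: CtMatrix
    samples: list[SampleAnnotation]
    assays: list[AssayAnnotation]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Panel and sample construction
# ---------------------------------------------------------------------------

def _target_ids(n: int, stem: str = "mmu-miR-sim") -> list[str]:
    width = len(str(n))
    return [f"{stem}-{i + 1:0{width}d}" for i in range(n)]


def _serum_panel(cfg: GeneratorConfig) -> list[AssayAnnotation]:
    n_targets = cfg.n_assays - len(cfg.invariant_ids) - 2
    panel = [AssayAnnotation(a, AssayRole.TARGET, "mmu") for a in _target_ids(n_targets)]
    panel += [
        AssayAnnotation(a, AssayRole.INVARIANT_REF, "mmu") for a in cfg.invariant_ids
    ]
    panel += [
        AssayAnnotation(cfg.spike.low_input_assay, AssayRole.SPIKE_IN, "cel"),
        AssayAnnotation(cfg.spike.high_input_assay, AssayRole.SPIKE_IN, "cel"),
    ]
    return panel


def _make_samples(
    groups: Sequence[GroupSpec], compartment: Compartment
) -> list[SampleAnnotation]:
    out: list[SampleAnnotation] = []
    for genotype, weeks, n in groups:
        short = "KRAS" if genotype is Genotype.KRAS_G12D else "WT"
        for i in range(n):
            out.append(
                SampleAnnotation(
                    sample_id=f"{short}-{weeks}w-{i + 1}",
                    genotype=genotype,
                    caerulein_weeks=weeks,
                    compartment=compartment,
                )
            )
    ids = [s.sample_id for s in out]
    if len(set(ids)) != len(ids):
        raise ConfigError("group specification yields duplicate sample ids")
    return out


def _assemble(
    cfg: GeneratorConfig,
    panel: list[AssayAnnotation],
    samples: list[SampleAnnotation],
    baselines: dict[str, float],
    noise_sds: dict[str, float],
    effect_shifts: dict[str, float],
    offsets: np.ndarray,
    rng: np.random.Generator,
    case_mask: np.ndarray,
) -> tuple[CtMatrix, GroundTruth]:
    assay_ids = [a.assay_id for a in panel]
    sample_ids = [s.sample_id for s in samples]
    b = np.array([baselines[a] for a in assay_ids])[:, None]
    sd = np.array([noise_sds[a] for a in assay_ids])[:, None]
    shift = np.array([effect_shifts.get(a, 0.0) for a in assay_ids])[:, None]
    mean_ct = b + shift * case_mask[None, :] + offsets[None, :]
    ct_vals = mean_ct + rng.normal(0.0, 1.0, size=mean_ct.shape) * sd
    ct_vals = np.where(ct_vals > cfg.lod_ct, np.nan, ct_vals)
    truth = GroundTruth(
        baselines=dict(baselines),
        effect_shifts={a: s for a, s in effect_shifts.items() if s != 0.0},
        sample_offsets={sid: float(o) for sid, o in zip(sample_ids, offsets)},
        assay_noise_sd=dict(noise_sds),
        mean_ct=pd.DataFrame(mean_ct, index=assay_ids, columns=sample_ids),
        lod_ct=cfg.lod_ct,
    )
    return CtMatrix(assay_ids, sample_ids, ct_vals), truth


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_serum_dataset(cfg: GeneratorConfig | None = None) -> SyntheticDataset:
    """Serum profiling panel across the genotype/treatment groups.

    Target baselines split into an expressed stratum (inside
    ``baseline_ct_range``) and an absent stratum above the limit of
    detection.  ``n_effect_assays`` expressed targets receive
    ``effect_ct_shift`` in every case (mutant-genotype) sample.  Invariant
    references are generated with zero effect and reduced noise; the two
    spike-ins sit at a fixed Ct distance of log2(input_ratio).  Deterministic
    given ``cfg.seed``.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    panel = _serum_panel(cfg)
    samples = _make_samples(cfg.groups, Compartment.SERUM)
    targets = [a.assay_id for a in panel if a.role is AssayRole.TARGET]

    n_expressed = int(round(cfg.fraction_expressed * len(targets)))
    expressed = list(rng.choice(targets, size=n_expressed, replace=False))
    absent = [a for a in targets if a not in set(expressed)]

    baselines: dict[str, float] = {}
    noise_sds: dict[str, float] = {}
    lo, hi = cfg.baseline_ct_range
    for a in expressed:
        baselines[a] = float(rng.uniform(lo, hi))
        noise_sds[a] = cfg.noise_sd
    alo, ahi = cfg.absent_ct_range
    for a in absent:
        baselines[a] = float(rng.uniform(alo, ahi))
        noise_sds[a] = cfg.noise_sd
    for a in cfg.invariant_ids:
        baselines[a] = float(rng.uniform(*cfg.reference_ct_range))
        noise_sds[a] = cfg.reference_noise_sd
    baselines[cfg.spike.low_input_assay] = cfg.spike_baseline_ct
    baselines[cfg.spike.high_input_assay] = (
        cfg.spike_baseline_ct - math.log2(cfg.spike.input_ratio)
    )
    noise_sds[cfg.spike.low_input_assay] = cfg.spike_noise_sd
    noise_sds[cfg.spike.high_input_assay] = cfg.spike_noise_sd

    if cfg.n_effect_assays > len(expressed):
        raise ConfigError("n_effect_assays exceeds the expressed target count")
    effect_assays = list(
        rng.choice(expressed, size=cfg.n_effect_assays, replace=False)
    )
    effect_shifts = {a: cfg.effect_ct_shift for a in effect_assays}

    offsets = rng.normal(0.0, cfg.sample_offset_sd, size=len(samples))
    case_mask = np.array([1.0 if is_kras(s) else 0.0 for s in samples])
    ct, truth = _assemble(
        cfg, panel, samples, baselines, noise_sds, effect_shifts, offsets, rng, case_mask
    )
    truth.expressed = set(expressed) | set(cfg.invariant_ids) | {
        cfg.spike.low_input_assay,
        cfg.spike.high_input_assay,
    }
    return SyntheticDataset(ct=ct, samples=samples, assays=panel, truth=truth)


def generate_tissue_dataset(
    cfg: GeneratorConfig | None = None, serum_truth: GroundTruth | None = None
) -> SyntheticDataset:
    """Duplicate pancreas-tissue lysates over the serum panel plus U6.

    Tissue abundance is independent of the serum design except for the
    configurable coupling: each serum-increased assay (from ``serum_truth``)
    is redrawn, with probability ``tissue_coupling_fraction``, from the
    abundant (low-Ct) stratum, so that serum-increased miRNAs land in the
    top tissue ranks.  Replicates share baselines and differ by per-sample
    offsets and independent per-well noise; U6 sits at a stable low Ct.
    With coupling requested (fraction > 0), ``serum_truth`` is required.
    """
    cfg = cfg or GeneratorConfig()
    if cfg.tissue_coupling_fraction > 0 and serum_truth is None:
        raise ConfigError("tissue coupling requested but no serum ground truth given")
    rng = np.random.default_rng(cfg.seed + 1)
    panel = _serum_panel(cfg) + [
        AssayAnnotation(cfg.u6_assay, AssayRole.ENDOGENOUS_CONTROL, "mmu")
    ]
    samples = [
        SampleAnnotation(
            sample_id=f"TISSUE-{i + 1}",
            genotype=Genotype.KRAS_G12D,
            caerulein_weeks=4,
            compartment=Compartment.TISSUE,
        )
        for i in range(cfg.n_tissue_replicates)
    ]
    targets = [a.assay_id for a in panel if a.role is AssayRole.TARGET]

    n_expressed = int(round(cfg.tissue_fraction_expressed * len(targets)))
    expressed = set(rng.choice(targets, size=n_expressed, replace=False))
    baselines: dict[str, float] = {}
    noise_sds: dict[str, float] = {}
    tlo, thi = cfg.tissue_baseline_ct_range
    alo, ahi = cfg.absent_ct_range
    for a in targets:
        baselines[a] = float(
            rng.uniform(tlo, thi) if a in expressed else rng.uniform(alo, ahi)
        )
        noise_sds[a] = cfg.noise_sd

    coupled: set[str] = set()
    if serum_truth is not None:
        slo, shi = cfg.tissue_top_stratum_ct
        for a in sorted(serum_truth.increased):
            if a in baselines and rng.uniform() < cfg.tissue_coupling_fraction:
                baselines[a] = float(rng.uniform(slo, shi))
                expressed.add(a)
                coupled.add(a)

    # references behave like moderately abundant tissue species; spike-ins are
    # not spiked into lysates and stay below the limit of detection
    for a in cfg.invariant_ids:
        baselines[a] = float(rng.uniform(*cfg.reference_ct_range))
        noise_sds[a] = cfg.reference_noise_sd
    for a in (cfg.spike.low_input_assay, cfg.spike.high_input_assay):
        baselines[a] = float(rng.uniform(alo, ahi))
        noise_sds[a] = cfg.spike_noise_sd
    baselines[cfg.u6_assay] = cfg.u6_ct
    noise_sds[cfg.u6_assay] = cfg.u6_noise_sd

    offsets = rng.normal(0.0, cfg.sample_offset_sd, size=len(samples))
    case_mask = np.zeros(len(samples))
    ct, truth = _assemble(
        cfg, panel, samples, baselines, noise_sds, {}, offsets, rng, case_mask
    )
    slo, shi = cfg.tissue_top_stratum_ct
    truth.expressed = expressed
    truth.abundant_stratum = {
        a for a in targets if baselines[a] <= shi and a in expressed
    }
    truth.coupled = coupled
    return SyntheticDataset(ct=ct, samples=samples, assays=panel, truth=truth)


def generate_qpcr_dataset(cfg: GeneratorConfig | None = None) -> SyntheticDataset:
    """Individual-miRNA qPCR validation set: 16 targets, two genotype groups.

    The first ``n_qpcr_effect_targets`` targets (chosen at random) receive
    ``qpcr_effect_ct_shift`` in mutant samples; both spike-ins are present in
    every sample at the configured 1,000-fold input-quantity distance.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed + 2)
    target_ids = _target_ids(cfg.n_qpcr_targets, stem="mmu-miR-val")
    panel = [AssayAnnotation(a, AssayRole.TARGET, "mmu") for a in target_ids] + [
        AssayAnnotation(cfg.spike.low_input_assay, AssayRole.SPIKE_IN, "cel"),
        AssayAnnotation(cfg.spike.high_input_assay, AssayRole.SPIKE_IN, "cel"),
    ]
    samples = _make_samples(cfg.qpcr_groups, Compartment.SERUM)

    baselines: dict[str, float] = {}
    noise_sds: dict[str, float] = {}
    for a in target_ids:
        baselines[a] = float(rng.uniform(*cfg.qpcr_baseline_ct_range))
        noise_sds[a] = cfg.qpcr_noise_sd
    baselines[cfg.spike.low_input_assay] = cfg.spike_baseline_ct
    baselines[cfg.spike.high_input_assay] = (
        cfg.spike_baseline_ct - math.log2(cfg.spike.input_ratio)
    )
    noise_sds[cfg.spike.low_input_assay] = cfg.spike_noise_sd
    noise_sds[cfg.spike.high_input_assay] = cfg.spike_noise_sd

    if cfg.n_qpcr_effect_targets > cfg.n_qpcr_targets:
        raise ConfigError("n_qpcr_effect_targets exceeds n_qpcr_targets")
    effect_targets = list(
        rng.choice(target_ids, size=cfg.n_qpcr_effect_targets, replace=False)
    )
    effect_shifts = {a: cfg.qpcr_effect_ct_shift for a in effect_targets}

    offsets = rng.normal(0.0, cfg.sample_offset_sd, size=len(samples))
    case_mask = np.array([1.0 if is_kras(s) else 0.0 for s in samples])
    ct, truth = _assemble(
        cfg, panel, samples, baselines, noise_sds, effect_shifts, offsets, rng, case_mask
    )
    truth.expressed = set(ct.assay_ids)
    return SyntheticDataset(ct=ct, samples=samples, assays=panel, truth=truth)
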