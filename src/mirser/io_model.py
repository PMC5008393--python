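"""Domain types, delimited-text I/O and design validation for qPCR Ct arrays.

The pipeline's universal input is a Ct matrix: rows are miRNA assays, columns
are samples, cells are PCR cycle-threshold values.  A well that never crossed
threshold within the run's cycle limit is *undetected*; it is missing data,
not a zero Ct.  Internally the sentinel is ``numpy.nan`` so that arithmetic
propagates it; on disk it is a configurable token (``"Undetermined"`` by
default, the TaqMan export convention) or an empty cell.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNDETECTED",
    "DEFAULT_UNDETECTED_TOKEN",
    "DEFAULT_INVARIANT_IDS",
    "CT_WRITE_DECIMALS",
    "Genotype",
    "Compartment",
    "AssayRole",
    "NormMethod",
    "CtMatrix",
    "QuantityMatrix",
    "SampleAnnotation",
    "AssayAnnotation",
    "ValidationReport",
    "MirserError",
    "FormatError",
    "ParseError",
    "ConfigError",
    "EmptyPanelError",
    "EmptyGroupError",
    "MissingReferenceError",
    "MissingControlError",
    "InsufficientReplicatesError",
    "DegenerateVarianceError",
    "AssayUniverseMismatchError",
    "read_ct_matrix",
    "write_ct_matrix",
    "read_sample_annotations",
    "write_sample_annotations",
    "read_assay_annotations",
    "write_assay_annotations",
    "validate_design",
]

# In-memory sentinel for an undetected (never-amplified) well.
UNDETECTED = float("nan")

DEFAULT_UNDETECTED_TOKEN = "Undetermined"

#: Empirically stable serum miRNAs used as the default delta-Ct reference set.
DEFAULT_INVARIANT_IDS = frozenset(
    {"mmu-miR-146a-5p", "mmu-miR-16-5p", "mmu-miR-30e-5p", "mmu-miR-744-5p"}
)

#: Ct exports carry ~2-4 decimals; 4 preserves read/write round-trips.
CT_WRITE_DECIMALS = 4


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MirserError(Exception):
    """Base class for all package errors."""


class FormatError(MirserError):
    """Structurally invalid input (duplicate ids, bad header...)."""


class ParseError(MirserError):
    """A cell could not be parsed; message carries row/column coordinates."""


class ConfigError(MirserError):
    """Invalid configuration value."""


class EmptyPanelError(MirserError):
    """An operation left no assays to work with."""


class EmptyGroupError(MirserError):
    """A sample-group predicate selected no samples."""


class MissingReferenceError(MirserError):
    """An invariant-reference assay is absent or undetected where required."""


class MissingControlError(MirserError):
    """A control assay (U6, spike-in) is absent or undetected where required."""


class InsufficientReplicatesError(MirserError):
    """A statistical test was asked to run on fewer than 2 values per group."""


class DegenerateVarianceError(MirserError):
    """Both groups have zero variance but unequal means; t is undefined."""


class AssayUniverseMismatchError(MirserError):
    """Two differential tables cover different assay sets."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Genotype(str, enum.Enum):
    KRAS_G12D = "KRAS_G12D"
    WILD_TYPE = "WILD_TYPE"


class Compartment(str, enum.Enum):
    SERUM = "SERUM"
    TISSUE = "TISSUE"


class AssayRole(str, enum.Enum):
    TARGET = "TARGET"
    SPIKE_IN = "SPIKE_IN"
    INVARIANT_REF = "INVARIANT_REF"
    ENDOGENOUS_CONTROL = "ENDOGENOUS_CONTROL"


class NormMethod(str, enum.Enum):
    """Which normalization produced a QuantityMatrix."""

    VSN_AMOUNT = "VSN_AMOUNT"
    INVARIANT = "INVARIANT"
    U6 = "U6"
    SPIKE_IN = "SPIKE_IN"


# ---------------------------------------------------------------------------
# Matrix types
# ---------------------------------------------------------------------------

def _check_axis_labels(assay_ids: Sequence[str], sample_ids: Sequence[str]) -> None:
    if len(set(assay_ids)) != len(assay_ids):
        dupes = sorted({a for a in assay_ids if list(assay_ids).count(a) > 1})
        raise FormatError(f"duplicate assay ids: {dupes}")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if list(sample_ids).count(s) > 1})
        raise FormatError(f"duplicate sample ids: {dupes}")


@dataclass
class CtMatrix:
    """Raw Ct values, assays x samples, with nan marking undetected wells.

    Every non-sentinel Ct must be finite and strictly positive (a cycle
    number).  ``ct`` is always stored as a float ndarray of shape
    ``(len(assay_ids), len(sample_ids))``.
    """

    assay_ids: list[str]
    sample_ids: list[str]
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.assay_ids = [str(a) for a in self.assay_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.assay_ids), len(self.sample_ids)):
            raise FormatError(
                f"ct shape {self.ct.shape} does not match "
                f"({len(self.assay_ids)}, {len(self.sample_ids)})"
            )
        _check_axis_labels(self.assay_ids, self.sample_ids)
        vals = self.ct[~np.isnan(self.ct)]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals <= 0)):
            raise FormatError("non-sentinel Ct values must be finite and > 0")

    # -- convenience -------------------------------------------------------
    @property
    def detected(self) -> np.ndarray:
        """Boolean mask of detected wells."""
        return ~np.isnan(self.ct)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=self.assay_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CtMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def assay_index(self, assay_id: str) -> int:
        try:
            return self.assay_ids.index(assay_id)
        except ValueError:
            raise KeyError(f"assay {assay_id!r} not in matrix") from None

    def row(self, assay_id: str) -> np.ndarray:
        return self.ct[self.assay_index(assay_id)]

    def subset_assays(self, keep: Iterable[str]) -> "CtMatrix":
        keep = list(keep)
        idx = [self.assay_index(a) for a in keep]
        return CtMatrix(keep, list(self.sample_ids), self.ct[idx].copy())


@dataclass
class QuantityMatrix:
    """Linear-scale relative amounts produced by one normalization method.

    All defined quantities are strictly positive (the Ct transforms are
    exponentials); nan marks wells undetected in the source Ct matrix.
    """

    assay_ids: list[str]
    sample_ids: list[str]
    quantity: np.ndarray
    method: NormMethod

    def __post_init__(self) -> None:
        self.assay_ids = [str(a) for a in self.assay_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.quantity = np.asarray(self.quantity, dtype=float)
        self.method = NormMethod(self.method)
        if self.quantity.shape != (len(self.assay_ids), len(self.sample_ids)):
            raise FormatError(
                f"quantity shape {self.quantity.shape} does not match "
                f"({len(self.assay_ids)}, {len(self.sample_ids)})"
            )
        _check_axis_labels(self.assay_ids, self.sample_ids)
        vals = self.quantity[~np.isnan(self.quantity)]
        if vals.size and np.any(vals <= 0):
            raise FormatError("defined quantities must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.quantity, index=self.assay_ids, columns=self.sample_ids
        )

    def assay_index(self, assay_id: str) -> int:
        try:
            return self.assay_ids.index(assay_id)
        except ValueError:
            raise KeyError(f"assay {assay_id!r} not in matrix") from None

    def subset_assays(self, keep: Iterable[str]) -> "QuantityMatrix":
        keep = list(keep)
        idx = [self.assay_index(a) for a in keep]
        return QuantityMatrix(
            keep, list(self.sample_ids), self.quantity[idx].copy(), self.method
        )


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleAnnotation:
    """Design factors for one sample (mouse serum or pancreas lysate)."""

    sample_id: str
    genotype: Genotype
    caerulein_weeks: int
    compartment: Compartment
    age_months: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        object.__setattr__(self, "compartment", Compartment(self.compartment))
        if self.caerulein_weeks < 0:
            raise ConfigError("caerulein_weeks must be >= 0")
        if self.age_months is not None and self.age_months < 0:
            raise ConfigError("age_months must be >= 0")


@dataclass(frozen=True)
class AssayAnnotation:
    """Role of one assay on the card (target, spike-in, reference, U6)."""

    assay_id: str
    role: AssayRole = AssayRole.TARGET
    species_prefix: str = "mmu"

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", AssayRole(self.role))


# ---------------------------------------------------------------------------
# Delimited-text readers/writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    """Choose between tab and comma; both occur in instrument exports."""
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    # single-column file; delimiter irrelevant
    return "\t"


def read_ct_matrix(
    path: str | Path,
    undetected_token: str = DEFAULT_UNDETECTED_TOKEN,
) -> CtMatrix:
    """Read a delimited Ct matrix (first column assay id, header sample ids).

    Cells equal to ``undetected_token`` (case-sensitive) or empty map to the
    undetected sentinel.  Any other non-numeric cell raises :class:`ParseError`
    with its row/column coordinates.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    # check the raw header: pandas would silently mangle duplicate names
    _check_axis_labels([], header[1:])
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    assay_ids = [str(a) for a in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    _check_axis_labels(assay_ids, sample_ids)

    ct = np.empty(raw.shape, dtype=float)
    for i, assay in enumerate(assay_ids):
        for j, sample in enumerate(sample_ids):
            cell = raw.iat[i, j].strip()
            if cell == "" or cell == undetected_token:
                ct[i, j] = UNDETECTED
                continue
            try:
                ct[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"cannot parse Ct cell {cell!r} at assay {assay!r} "
                    f"(row {i + 2}), sample {sample!r} (column {j + 2})"
                ) from None
    return CtMatrix(assay_ids, sample_ids, ct)


def write_ct_matrix(
    ct: CtMatrix,
    path: str | Path,
    undetected_token: str = DEFAULT_UNDETECTED_TOKEN,
    sep: str = "\t",
    decimals: int = CT_WRITE_DECIMALS,
) -> None:
    """Write a Ct matrix as delimited text, sentinel as ``undetected_token``."""
    frame = ct.to_frame().map(
        lambda v: undetected_token if math.isnan(v) else f"{v:.{decimals}f}"
    )
    frame.to_csv(path, sep=sep, index_label="assay_id")


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    path = Path(path)
    sep = _sniff_delimiter(path)
    out: list[SampleAnnotation] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=sep):
            age = row.get("age_months", "")
            out.append(
                SampleAnnotation(
                    sample_id=row["sample_id"],
                    genotype=Genotype(row["genotype"]),
                    caerulein_weeks=int(row["caerulein_weeks"]),
                    compartment=Compartment(row["compartment"]),
                    age_months=int(age) if age not in ("", None) else None,
                )
            )
    ids = [s.sample_id for s in out]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample_id in annotation table")
    return out


def write_sample_annotations(samples: Sequence[SampleAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["sample_id", "genotype", "caerulein_weeks", "compartment", "age_months"]
        )
        for s in samples:
            writer.writerow(
                [
                    s.sample_id,
                    s.genotype.value,
                    s.caerulein_weeks,
                    s.compartment.value,
                    "" if s.age_months is None else s.age_months,
                ]
            )


def read_assay_annotations(path: str | Path) -> list[AssayAnnotation]:
    path = Path(path)
    sep = _sniff_delimiter(path)
    out: list[AssayAnnotation] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=sep):
            out.append(
                AssayAnnotation(
                    assay_id=row["assay_id"],
                    role=AssayRole(row.get("role", "TARGET")),
                    species_prefix=row.get("species_prefix", "mmu"),
                )
            )
    ids = [a.assay_id for a in out]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate assay_id in annotation table")
    return out


def write_assay_annotations(assays: Sequence[AssayAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["assay_id", "role", "species_prefix"])
        for a in assays:
            writer.writerow([a.assay_id, a.role.value, a.species_prefix])


# ---------------------------------------------------------------------------
# Design validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only account of design problems; downstream operations raise."""

    issues: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        return "OK" if self.clean else "\n".join(self.issues)


def validate_design(
    ct: CtMatrix,
    samples: Sequence[SampleAnnotation],
    assays: Sequence[AssayAnnotation],
    invariant_ids: Iterable[str] = DEFAULT_INVARIANT_IDS,
) -> ValidationReport:
    """Cross-check a Ct matrix against its annotations; never raises, never mutates.

    Flags samples without annotation (and vice versa), empty design groups,
    missing invariant-reference assays, and absent spike-in / U6 controls
    where a downstream method would need them.
    """
    report = ValidationReport()
    annotated = {s.sample_id for s in samples}
    for sid in ct.sample_ids:
        if sid not in annotated:
            report.issues.append(f"sample {sid!r} in Ct matrix has no annotation")
    for sid in sorted(annotated - set(ct.sample_ids)):
        report.issues.append(f"annotated sample {sid!r} absent from Ct matrix")

    in_matrix = [s for s in samples if s.sample_id in set(ct.sample_ids)]
    for genotype in Genotype:
        if not any(s.genotype is genotype for s in in_matrix):
            report.issues.append(f"no samples with genotype {genotype.value}")

    assay_set = set(ct.assay_ids)
    for inv in sorted(invariant_ids):
        if inv not in assay_set:
            report.issues.append(f"invariant-reference assay {inv!r} absent")

    by_role: dict[AssayRole, list[str]] = {role: [] for role in AssayRole}
    for a in assays:
        if a.assay_id in assay_set:
            by_role[a.role].append(a.assay_id)
    if len(by_role[AssayRole.SPIKE_IN]) < 2:
        report.issues.append(
            "fewer than 2 spike-in assays present; spike-in normalization unavailable"
        )
    if not by_role[AssayRole.ENDOGENOUS_CONTROL]:
        report.issues.append(
            "no endogenous-control (U6) assay present; tissue normalization unavailable"
        )
    annotated_assays = {a.assay_id for a in assays}
    n_unannotated = sum(1 for a in ct.assay_ids if a not in annotated_assays)
    if assays and n_unannotated:
        report.issues.append(f"{n_unannotated} assays in Ct matrix lack annotation")
    return report
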