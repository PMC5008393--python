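"""Tissue-side analysis: U6-normalized quantification, abundance ranking over
replicate pancreas lysates, and top-N membership of serum-changed miRNAs.

Serum has no universally stable endogenous miRNA control, but tissue does:
U6 snRNA.  Tissue quantities are ``2^(Ct(U6) - Ct(x))`` per sample, assays
are ranked by their mean quantity across replicate lysates, and a set of
serum-changed miRNAs can be asked how many of its members sit in the top N
tissue ranks — evidence that the serum signal originates from the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_model import (
    CtMatrix,
    EmptyPanelError,
    MirserError,
    MissingControlError,
    NormMethod,
    QuantityMatrix,
)

__all__ = [
    "DEFAULT_U6_ASSAY",
    "RankedAssay",
    "TopNMembership",
    "u6_normalize",
    "rank_tissue_expression",
    "top_n_membership",
]

DEFAULT_U6_ASSAY = "U6 snRNA"


def u6_normalize(ct: CtMatrix, u6_assay: str = DEFAULT_U6_ASSAY) -> QuantityMatrix:
    """Quantities relative to the U6 endogenous control: ``2^(Ct(U6,j) - Ct(x,j))``.

    U6 must be detected in every sample; a per-sample global Ct shift moves
    Ct(U6) and Ct(x) equally and cancels.
    """
    if u6_assay not in set(ct.assay_ids):
        raise MissingControlError(f"U6 assay {u6_assay!r} absent from matrix")
    u6_ct = ct.row(u6_assay)
    for j, sid in enumerate(ct.sample_ids):
        if np.isnan(u6_ct[j]):
            raise MissingControlError(f"U6 assay undetected in sample {sid!r}")
    quantity = np.exp2(u6_ct - ct.ct)
    return QuantityMatrix(
        list(ct.assay_ids), list(ct.sample_ids), quantity, NormMethod.U6
    )


@dataclass(frozen=True)
class RankedAssay:
    assay_id: str
    mean_quantity: float
    rank: int  # 1 = most abundant


def rank_tissue_expression(
    q: QuantityMatrix, replicate_ids: Sequence[str]
) -> list[RankedAssay]:
    """Rank assays by mean normalized quantity over replicate tissue samples.

    Assays undetected in every replicate are excluded; assays detected in at
    least one replicate use the mean over their detected replicates.  Rank 1
    is the highest mean quantity; ties break lexicographically by assay name,
    so output is deterministic.
    """
    if not replicate_ids:
        raise MirserError("rank_tissue_expression needs >= 1 replicate")
    pos = {sid: j for j, sid in enumerate(q.sample_ids)}
    missing = [s for s in replicate_ids if s not in pos]
    if missing:
        raise MirserError(f"replicate samples absent from matrix: {missing}")
    cols = [pos[s] for s in replicate_ids]
    block = q.quantity[:, cols]
    n_det = np.sum(~np.isnan(block), axis=1)
    # mean over detected replicates; rows undetected everywhere become nan
    means = np.where(n_det > 0, np.nansum(block, axis=1) / np.maximum(n_det, 1), np.nan)
    entries = [
        (assay, float(m))
        for assay, m in zip(q.assay_ids, means)
        if not np.isnan(m)
    ]
    if not entries:
        raise EmptyPanelError("no assay detected in any replicate")
    entries.sort(key=lambda e: (-e[1], e[0]))
    return [
        RankedAssay(assay_id=a, mean_quantity=m, rank=i + 1)
        for i, (a, m) in enumerate(entries)
    ]


@dataclass
class TopNMembership:
    """How many of a serum assay set fall in the top-n tissue ranks."""

    n: int
    count_in_top_n: int
    fraction: float  # of the full serum set, absent members counted as misses
    ranks: dict[str, int]  # tissue rank per serum assay present in the ranking
    absent: list[str]  # serum assays not in the tissue ranking at all


def top_n_membership(
    serum_set: Sequence[str], tissue_ranking: Sequence[RankedAssay], n: int
) -> TopNMembership:
    """Count serum-set members with tissue rank <= n.

    Assays absent from the tissue ranking count as not-in-top-n and are
    listed.  The fraction is over the full serum set, so it is monotone
    non-decreasing in n and bounded by (members present)/(set size).
    """
    serum = list(dict.fromkeys(serum_set))  # preserve order, drop dupes
    if not serum:
        raise MirserError("serum_set is empty")
    if n < 1:
        raise MirserError("n must be >= 1")
    rank_of = {r.assay_id: r.rank for r in tissue_ranking}
    ranks = {a: rank_of[a] for a in serum if a in rank_of}
    absent = [a for a in serum if a not in rank_of]
    count = sum(1 for r in ranks.values() if r <= n)
    return TopNMembership(
        n=n,
        count_in_top_n=count,
        fraction=count / len(serum),
        ranks=ranks,
        absent=absent,
    )
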