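"""Hierarchical clustering, cluster-separation diagnostics and pipeline
orchestration.

Samples are clustered on log2 normalized quantities (all assays, or the
significantly changed subset), by default with 1 - Pearson correlation
distance and average linkage.  The contract-tested artifacts are text: a
Newick dendrogram and the row/column-ordered matrix; heatmap rendering is
left to downstream plotting.  ``run_pipeline`` wires the whole analysis —
simulate or load, detection-filter, normalize both ways, test, call the
consensus, cluster — and writes every stage's output plus run metadata.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_model import (
    CtMatrix,
    MirserError,
    QuantityMatrix,
    SampleAnnotation,
    read_assay_annotations,
    read_ct_matrix,
    read_sample_annotations,
    write_ct_matrix,
)
from .differential_consensus import (
    ConsensusResult,
    DifferentialResult,
    DEFAULT_ALPHA,
    consensus_call,
    differential_table,
)
from .normalization import DEFAULT_MAX_CT, detection_filter, invariant_normalize, vsn_normalize
from .synthetic_data import GeneratorConfig, generate_serum_dataset

__all__ = [
    "ClusterResult",
    "cluster_profiles",
    "group_separation_score",
    "PipelineStageError",
    "predicate_from_spec",
    "run_pipeline",
]

logger = logging.getLogger("mirser")


class PipelineStageError(MirserError):
    """A pipeline stage failed; message names the stage and offending entity."""


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    sample_order: list[str]
    newick: str
    linkage_matrix: np.ndarray
    sample_ids: list[str]  # leaf order as passed to linkage
    ordered_matrix: pd.DataFrame  # log2 quantities, columns in dendrogram order


def _to_newick(linkage_matrix: np.ndarray, leaf_names: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage_matrix)

    def render(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def cluster_profiles(
    q: QuantityMatrix,
    assay_subset: Sequence[str] | None = None,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterResult:
    """Cluster samples hierarchically on log2 quantities.

    ``distance`` is ``"correlation"`` (1 - Pearson across assays) or
    ``"euclidean"``; ``linkage`` is ``"average"`` or ``"complete"``.  The
    assay subset (if given) is sorted by name before use and the leaf order
    is the deterministic scipy dendrogram order, so the output is fully
    reproducible.  Wells undetected in any sample are excluded from the
    distance computation.
    """
    if distance not in ("correlation", "euclidean"):
        raise MirserError(f"unsupported distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise MirserError(f"unsupported linkage {linkage!r}")
    if len(q.sample_ids) < 2:
        raise MirserError("clustering needs at least 2 samples")
    if assay_subset is not None:
        subset = sorted(set(assay_subset) & set(q.assay_ids))
        if not subset:
            raise MirserError("assay subset is disjoint from the matrix panel")
        q = q.subset_assays(subset)
    log_q = np.log2(q.quantity)
    complete = ~np.any(np.isnan(log_q), axis=1)
    log_q = log_q[complete]
    if log_q.shape[0] < 2:
        raise MirserError("fewer than 2 assays with complete values to cluster on")
    dist = pdist(log_q.T, metric=distance)
    dist = np.clip(dist, 0.0, None)  # correlation metric can go -eps numerically
    link = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(link)
    sample_order = [q.sample_ids[i] for i in order]
    frame = pd.DataFrame(log_q, index=np.array(q.assay_ids)[complete], columns=q.sample_ids)
    return ClusterResult(
        sample_order=sample_order,
        newick=_to_newick(link, q.sample_ids),
        linkage_matrix=link,
        sample_ids=list(q.sample_ids),
        ordered_matrix=frame[sample_order],
    )


def group_separation_score(result: ClusterResult, labels: Mapping[str, str]) -> float:
    """Fraction of samples whose cophenetically nearest neighbour shares
    their group label.

    1.0 means every sample's closest companion in the dendrogram belongs to
    its own group; ties in cophenetic distance break by sample name for
    determinism.  Invariant under renaming the group labels.  Raises if the
    labelling has fewer than 2 distinct groups.
    """
    ids = result.sample_ids
    missing = [s for s in ids if s not in labels]
    if missing:
        raise MirserError(f"samples without group label: {missing}")
    if len({labels[s] for s in ids}) < 2:
        raise MirserError("group separation is undefined with a single group")
    coph = hierarchy.cophenet(result.linkage_matrix)
    from scipy.spatial.distance import squareform

    dmat = squareform(coph)
    hits = 0
    for i, sid in enumerate(ids):
        candidates = [
            (dmat[i, j], ids[j]) for j in range(len(ids)) if j != i
        ]
        _, nearest = min(candidates, key=lambda c: (c[0], c[1]))
        hits += labels[nearest] == labels[sid]
    return hits / len(ids)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def predicate_from_spec(spec: Mapping[str, object]):
    """Build a sample predicate from a field->value mapping.

    Example: ``{"genotype": "KRAS_G12D"}`` or
    ``{"genotype": "WILD_TYPE", "caerulein_weeks": 0}``.  Values may be a
    single value or a list of allowed values.
    """
    items = []
    for key, value in spec.items():
        allowed = value if isinstance(value, (list, tuple, set)) else [value]
        items.append((key, {str(v) for v in allowed}))

    def predicate(s: SampleAnnotation) -> bool:
        for key, allowed in items:
            attr = getattr(s, key)
            attr = attr.value if hasattr(attr, "value") else str(attr)
            if str(attr) not in allowed:
                return False
        return True

    return predicate


def _results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "assay_id": [r.assay_id for r in results],
            "mean_case_log2": [r.mean_case for r in results],
            "mean_control_log2": [r.mean_control for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def _write_consensus(res: ConsensusResult, path: Path) -> None:
    rows = (
        [(a, "increased") for a in res.consensus_increased]
        + [(a, "decreased") for a in res.consensus_decreased]
        + [(a, "discordant") for a in res.discordant]
    )
    pd.DataFrame(rows, columns=["assay_id", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def _write_metadata(path: Path, entries: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}={value}\n")


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: Mapping[str, object] | str | Path, out_dir: str | Path) -> dict:
    """Run the full serum analysis and write all artifacts to ``out_dir``.

    ``config`` is a mapping (or path to a YAML file) with keys:

    - ``seed``: RNG seed (used when simulating; recorded always)
    - ``simulate``: generator overrides for :class:`GeneratorConfig`
      (omit to load real data via ``inputs``)
    - ``inputs``: ``{ct, samples, assays}`` file paths
    - ``max_ct``: detection threshold (default 40)
    - ``alpha``: significance level (default 0.05)
    - ``case`` / ``control``: field->value mappings defining the contrast
      (default mutant vs wild-type genotype)
    - ``distance`` / ``linkage``: clustering options

    Returns a summary dict (kappa, consensus sizes, artifact paths).  The
    run is deterministic: same config and seed reproduce byte-identical
    numeric outputs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    alpha = float(cfg.get("alpha", DEFAULT_ALPHA))
    max_ct = float(cfg.get("max_ct", DEFAULT_MAX_CT))
    case_spec = cfg.get("case", {"genotype": "KRAS_G12D"})
    control_spec = cfg.get("control", {"genotype": "WILD_TYPE"})
    contrast = (predicate_from_spec(case_spec), predicate_from_spec(control_spec))

    with _stage("inputs"):
        if "inputs" in cfg:
            paths = cfg["inputs"]
            ct = read_ct_matrix(paths["ct"])
            samples = read_sample_annotations(paths["samples"])
            assays = read_assay_annotations(paths["assays"])
        else:
            gen_cfg = GeneratorConfig(**{**cfg.get("simulate", {}), "seed": seed})
            dataset = generate_serum_dataset(gen_cfg)
            ct, samples, assays = dataset.ct, dataset.samples, dataset.assays
            write_ct_matrix(ct, out / "simulated_ct.tsv")
    logger.info("input: %d assays x %d samples", len(ct.assay_ids), len(ct.sample_ids))

    with _stage("detection_filter"):
        filtered, dropped = detection_filter(ct, max_ct=max_ct)
    logger.info("detection filter: %d retained, %d dropped", len(filtered.assay_ids), dropped)

    with _stage("normalization"):
        q_vsn = vsn_normalize(filtered)
        q_inv = invariant_normalize(filtered)
        q_vsn.to_frame().to_csv(out / "quantities_vsn.tsv", sep="\t")
        q_inv.to_frame().to_csv(out / "quantities_invariant.tsv", sep="\t")

    with _stage("differential"):
        res_vsn = differential_table(q_vsn, samples, contrast, alpha=alpha, assays=assays)
        res_inv = differential_table(q_inv, samples, contrast, alpha=alpha, assays=assays)
        _results_frame(res_vsn).to_csv(out / "differential_vsn.tsv", sep="\t", index=False)
        _results_frame(res_inv).to_csv(out / "differential_invariant.tsv", sep="\t", index=False)

    with _stage("consensus"):
        consensus = consensus_call(res_vsn, res_inv)
        _write_consensus(consensus, out / "consensus.tsv")
    logger.info(
        "consensus: %d assays (%d up, %d down), kappa=%.4f",
        len(consensus.consensus),
        len(consensus.consensus_increased),
        len(consensus.consensus_decreased),
        consensus.kappa,
    )

    with _stage("clustering"):
        distance = str(cfg.get("distance", "correlation"))
        linkage = str(cfg.get("linkage", "average"))
        cluster_all = cluster_profiles(q_inv, distance=distance, linkage=linkage)
        (out / "dendrogram_all.nwk").write_text(cluster_all.newick + "\n")
        cluster_all.ordered_matrix.to_csv(out / "clustered_matrix_all.tsv", sep="\t")
        if consensus.consensus:
            cluster_sig = cluster_profiles(
                q_inv, assay_subset=consensus.consensus, distance=distance, linkage=linkage
            )
            (out / "dendrogram_significant.nwk").write_text(cluster_sig.newick + "\n")
            cluster_sig.ordered_matrix.to_csv(
                out / "clustered_matrix_significant.tsv", sep="\t"
            )

    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.tsv"))
    }
    _write_metadata(
        out / "run_metadata.txt",
        {
            "seed": seed,
            "alpha": alpha,
            "max_ct": max_ct,
            "case": case_spec,
            "control": control_spec,
            "normalization_methods": "VSN_AMOUNT,INVARIANT",
            "vsn_input_scale": "amounts 2^(50-Ct), arcsinh-stabilized, median-matched",
            "assays_tested": consensus.tested_n,
            "assays_dropped_by_detection_filter": dropped,
            "kappa": f"{consensus.kappa:.6f}",
            "consensus_increased": len(consensus.consensus_increased),
            "consensus_decreased": len(consensus.consensus_decreased),
            "distance": cfg.get("distance", "correlation"),
            "linkage": cfg.get("linkage", "average"),
        },
    )
    return {
        "out_dir": str(out),
        "tested_n": consensus.tested_n,
        "dropped": dropped,
        "kappa": consensus.kappa,
        "consensus_increased": len(consensus.consensus_increased),
        "consensus_decreased": len(consensus.consensus_decreased),
        "checksums": checksums,
    }
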