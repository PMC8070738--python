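"""End-to-end synthetic pipeline runner with a validated configuration.

``run_pipeline`` chains every stage on generated inputs: count simulation →
overlap subtraction → RPKM → Levene-gated DEG calling → GO enrichment of the
called up/down sets → PPI score-matrix clustering → histone-modification
enrichment — and reports planted-truth recovery metrics plus a manifest
(package and library versions, seed, parameters, output checksums) that
makes the run reproducible.
"""

from __future__ import annotations

import hashlib
import importlib.metadata
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .enrichment import AnnotationTable, enrich
from .expression import (
    DEGResult, LEVENE_ALPHA, RPKM_PSEUDOCOUNT, deg_test, rpkm_normalize,
    subtract_overlap,
)
from .histone import histone_enrich
from .ppi import (
    DEFAULT_CUT_HEIGHT, MIN_CLUSTER_SCORE, MIN_CLUSTER_SIZE, PPIClusterSet,
    ScoreMatrix, cluster_scores,
)
from .simulate import (
    CountSimSpec, GOSimSpec, HistoneSimSpec, PPISimSpec,
    simulate_counts, simulate_go_annotation, simulate_histone, simulate_ppi,
)

logger = logging.getLogger(__name__)


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")


@dataclass
class PipelineConfig:
    """Validated parameters of a full synthetic run.

    Unknown keys in the source mapping are rejected; every threshold is
    range-checked at construction.
    """

    seed: int = 0
    counts: dict = field(default_factory=dict)       # CountSimSpec overrides
    go: dict = field(default_factory=dict)           # GOSimSpec overrides
    ppi: dict = field(default_factory=dict)          # PPISimSpec overrides
    histone: dict = field(default_factory=dict)      # HistoneSimSpec overrides
    deg_alpha: float = 0.05
    fc_threshold: float = 2.0
    correction: str = "bh"
    log_values: bool = False
    go_alpha: float = 0.05
    cut_height: float = DEFAULT_CUT_HEIGHT
    min_cluster_size: int = MIN_CLUSTER_SIZE
    min_cluster_score: float = MIN_CLUSTER_SCORE
    histone_alpha: float = 0.05

    def __post_init__(self) -> None:
        _check_range("deg_alpha", self.deg_alpha, 0.0, 1.0)
        _check_range("go_alpha", self.go_alpha, 0.0, 1.0)
        _check_range("histone_alpha", self.histone_alpha, 0.0, 1.0)
        _check_range("min_cluster_score", self.min_cluster_score, 0.0, 1.0)
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.cut_height <= 0:
            raise ValueError("cut_height must be positive")
        if self.correction not in ("bh", "holm"):
            raise ValueError("correction must be 'bh' or 'holm'")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class PipelineResult:
    """All stage outputs of one run plus the reproducibility manifest."""

    counts_naive: object
    counts_corrected: object
    truth: pd.DataFrame
    deg_naive: DEGResult
    deg: DEGResult
    go_tables: dict[str, pd.DataFrame]
    ppi_clusters: PPIClusterSet
    ppi_truth: pd.DataFrame
    histone_results: pd.DataFrame
    histone_summary: dict
    recovery: dict
    manifest: dict


def _recovery_metrics(truth: pd.DataFrame, deg_table: pd.DataFrame) -> dict:
    """Recall / direction accuracy of planted DE genes, FDR-style precision."""
    planted = truth["planted_class"]
    called = deg_table["deg_class"].reindex(truth.index)
    de_mask = planted.isin(["up", "down"])
    called_de = called.isin(["up", "down"])
    n_planted = int(de_mask.sum())
    recall = float((de_mask & called_de).sum() / n_planted) if n_planted else float("nan")
    hits = de_mask & called_de
    direction_acc = (
        float((planted[hits] == called[hits]).mean()) if hits.any() else float("nan")
    )
    eligible_fp = (planted == "ns") & called_de
    precision_denom = int(called_de.sum())
    return {
        "n_planted_de": n_planted,
        "recall": recall,
        "direction_accuracy": direction_acc,
        "n_called_de": precision_denom,
        "n_false_calls": int(eligible_fp.sum()),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute all stages on synthetic inputs in dependency order.

    When ``outdir`` is given, every stage's tables plus a JSON manifest are
    written there; the manifest records versions, the seed, all parameters
    and a sha256 checksum per output file.
    """
    # --- stage 1: counts -------------------------------------------------
    count_spec = CountSimSpec(seed=config.seed, **config.counts)
    sim = simulate_counts(count_spec)
    logger.info("simulated %d genes x %d samples", *sim.counts.counts.shape)

    # --- stage 2: overlap correction ------------------------------------
    if sim.region_counts is not None:
        corrected = subtract_overlap(sim.counts, sim.region_counts)
    else:
        corrected = sim.counts

    # --- stage 3: RPKM + DEG (naive and corrected routes) ---------------
    logger.info("defaults: pseudo-count %.2f RPKM, Levene gate alpha %.2f, "
                "distance 1 - score, cut height %.2f",
                RPKM_PSEUDOCOUNT, LEVENE_ALPHA, config.cut_height)
    deg_kwargs = dict(
        alpha=config.deg_alpha, fc_threshold=config.fc_threshold,
        correction=config.correction, log_values=config.log_values,
    )
    deg_naive = deg_test(rpkm_normalize(sim.counts), sim.counts.design, **deg_kwargs)
    deg = deg_test(rpkm_normalize(corrected), corrected.design, **deg_kwargs)

    # --- stage 4: GO enrichment of the called DEG sets ------------------
    universe = set(deg.table.index[deg.table["deg_class"] != "untested"])
    truth_de = set(sim.truth.index[sim.truth["planted_class"].isin(["up", "down"])])
    go_spec = GOSimSpec(seed=config.seed, **config.go)
    annot_frame = simulate_go_annotation(go_spec, sorted(universe), truth_de)
    annot = AnnotationTable.from_frame(annot_frame, universe)
    go_tables = {}
    for label in ("up", "down", "combined"):
        if label == "combined":
            query = set(deg.table.index[deg.table["deg_class"].isin(["up", "down"])])
        else:
            query = set(deg.table.index[deg.table["deg_class"] == label])
        if query:
            go_tables[label] = enrich(query, annot, correction=config.correction,
                                      alpha=config.go_alpha)

    # --- stage 5: PPI clustering ----------------------------------------
    ppi_spec = PPISimSpec(seed=config.seed, **config.ppi)
    score_matrix, ppi_truth = simulate_ppi(ppi_spec)
    clusters = cluster_scores(
        ScoreMatrix(scores=score_matrix), cut_height=config.cut_height,
        min_size=config.min_cluster_size, min_score=config.min_cluster_score,
    )

    # --- stage 6: histone enrichment on the called classes --------------
    gene_classes = deg.table["deg_class"].replace({"untested": "ns"})
    hist_spec = HistoneSimSpec(seed=config.seed, **config.histone)
    hist_table = simulate_histone(hist_spec, gene_classes)
    hist_res, hist_summary = histone_enrich(
        hist_table, gene_classes, alpha=config.histone_alpha
    )

    recovery = _recovery_metrics(sim.truth, deg.table)
    recovery["n_retained_clusters"] = int(clusters.table["retained"].sum())
    recovery["histone_enriched_up"] = hist_summary.get("up", {}).get("enriched", 0)

    manifest = {
        "seed": config.seed,
        "parameters": {
            "deg_alpha": config.deg_alpha,
            "fc_threshold": config.fc_threshold,
            "correction": config.correction,
            "log_values": config.log_values,
            "rpkm_pseudocount": RPKM_PSEUDOCOUNT,
            "levene_alpha": LEVENE_ALPHA,
            "go_alpha": config.go_alpha,
            "distance_transform": "1 - score",
            "cut_height": config.cut_height,
            "min_cluster_size": config.min_cluster_size,
            "min_cluster_score": config.min_cluster_score,
            "histone_alpha": config.histone_alpha,
        },
        "versions": {
            "esterodeg": _pkg_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "summary": {
            "deg": deg.summary,
            "deg_naive": deg_naive.summary,
            "recovery": recovery,
            "histone": hist_summary,
        },
        "checksums": {},
    }

    result = PipelineResult(
        counts_naive=sim.counts, counts_corrected=corrected, truth=sim.truth,
        deg_naive=deg_naive, deg=deg, go_tables=go_tables,
        ppi_clusters=clusters, ppi_truth=ppi_truth,
        histone_results=hist_res, histone_summary=hist_summary,
        recovery=recovery, manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _pkg_version() -> str:
    try:
        return importlib.metadata.version("esterodeg")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cm = result.counts_corrected
    eio.write_counts(cm, outdir / "counts.tsv", outdir / "annotation.tsv",
                     outdir / "design.tsv")
    result.deg.table.rename_axis("gene_id").to_csv(outdir / "deg.tsv", sep="\t")
    for label, table in result.go_tables.items():
        table.to_csv(outdir / f"go_{label}.tsv", sep="\t")
    result.ppi_clusters.table.drop(columns="members").to_csv(
        outdir / "ppi_clusters.tsv", sep="\t"
    )
    result.ppi_clusters.membership.rename_axis("protein_id").to_csv(
        outdir / "ppi_membership.tsv", sep="\t"
    )
    result.histone_results.to_csv(outdir / "histone.tsv", sep="\t", index=False)
    for p in sorted(outdir.glob("*.tsv")):
        result.manifest["checksums"][p.name] = _sha256(p)
    eio.write_json(result.manifest, outdir / "manifest.json")
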