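"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure of a two-strain wine-yeast
RNA-seq deletion experiment: negative-binomial gene counts with a strongly
up-biased planted differentially-expressed set, a handful of knocked-out
genes with near-zero residual counts in the mutant, one pair of overlapping
ORFs whose naive per-gene counts double-count the shared region, block-
structured protein-protein-interaction score matrices, and histone-
modification ratio tables whose shifts are concentrated in upregulated
genes.  Each generator takes a single integer seed and is byte-reproducible.

All child random streams are spawned from one ``numpy.random.SeedSequence``
so that a single global seed deterministically seeds every generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix

DEFAULT_KNOCKOUTS = ("ATF1", "ATF2", "EEB1", "EHT1")
DEFAULT_OVERLAP_PAIR = ("ATF2", "YGR176W", 0.75)

#: 3 acetylations + 5 methylations of the nucleosome ChIP ratio dataset.
HISTONE_MODIFICATIONS = (
    "H3K9ac", "H3K14ac", "H4ac",
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K36me3", "H3K79me3",
)


class SimSpecError(ValueError):
    """Raised when a simulation spec is internally inconsistent."""


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-generator child stream from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

@dataclass
class CountSimSpec:
    """Parameters of the negative-binomial count generator.

    Defaults describe the emulated experiment: ~6000 detected genes, two
    strains (wildtype and quadruple-deletion mutant) with 3 biological
    replicates each, a planted differential set strongly biased toward
    upregulation in the mutant, four knocked-out genes with near-zero
    residual mutant counts, and one overlapping ORF pair in which the
    knocked-out gene shares reads with a normally expressed neighbour.
    """

    n_genes: int = 6000
    n_replicates_per_strain: int = 3
    #: natural-log range of per-gene NB mean counts (loguniform draw)
    baseline_mean_log_range: tuple[float, float] = (np.log(10.0), np.log(2000.0))
    #: NB size parameter; variance = mu + mu^2 / dispersion
    dispersion: float = 10.0
    n_up: int = 1100
    n_down: int = 22
    effect_log2fc: float = 2.0
    knockout_genes: tuple[str, ...] = DEFAULT_KNOCKOUTS
    overlap_pair: tuple[str, str, float] | None = DEFAULT_OVERLAP_PAIR
    #: mean residual mutant count at a knocked-out locus (Poisson)
    knockout_residual_mean: float = 0.5
    gene_length_range: tuple[int, int] = (300, 4000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates_per_strain <= 0:
            raise SimSpecError("n_genes and n_replicates_per_strain must be positive")
        if self.dispersion <= 0:
            raise SimSpecError("dispersion must be positive")
        if self.effect_log2fc < 1:
            raise SimSpecError("effect_log2fc must be >= 1 (at least a twofold effect)")
        n_special = self.n_up + self.n_down + len(self.knockout_genes)
        if self.overlap_pair is not None:
            a, b, frac = self.overlap_pair
            if not 0.0 <= frac <= 1.0:
                raise SimSpecError("overlap shared_fraction must lie in [0, 1]")
            if a == b:
                raise SimSpecError("overlap pair must name two distinct genes")
            n_special += sum(g not in self.knockout_genes for g in (a, b))
        if n_special > self.n_genes:
            raise SimSpecError(
                "n_up + n_down + knockouts (+ overlap genes) exceed n_genes"
            )


@dataclass
class CountSimResult:
    """Output bundle of :func:`simulate_counts`."""

    counts: CountMatrix                 # naive per-gene totals (shared region double-counted)
    truth: pd.DataFrame                 # gene_id, planted_class, planted_log2fc
    region_counts: pd.DataFrame | None  # per-sample A-unique / B-unique / shared counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """NB(mu, size) with variance mu + mu^2/size, safe at mu == 0."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size_param, p[pos])
    return out


def simulate_counts(spec: CountSimSpec) -> CountSimResult:
    """Generate a two-strain count matrix with planted truth labels.

    Returns naive per-gene totals (the overlap pair's shared region is
    double-counted into both partners, as a position-based read counter
    would), the planted truth table, and — when an overlap pair is declared —
    region-level counts (A-unique, B-unique, shared) that make the overlap
    subtraction well defined.
    """
    rng = _child_rng(spec.seed, 0)
    n_rep = spec.n_replicates_per_strain
    knockouts = list(spec.knockout_genes)

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    special = list(knockouts)
    overlap = spec.overlap_pair
    if overlap is not None:
        for g in overlap[:2]:
            if g not in special:
                special.append(g)
    gene_ids[: len(special)] = special

    lo, hi = spec.baseline_mean_log_range
    base_mean = np.exp(rng.uniform(lo, hi, size=spec.n_genes))
    lengths = rng.integers(spec.gene_length_range[0], spec.gene_length_range[1],
                           size=spec.n_genes, endpoint=True)

    # planted DE assignment on non-special genes only
    idx = np.arange(spec.n_genes)
    free = idx[len(special):]
    chosen = rng.choice(free, size=spec.n_up + spec.n_down, replace=False)
    up_idx, down_idx = chosen[: spec.n_up], chosen[spec.n_up:]

    log2fc = np.zeros(spec.n_genes)
    log2fc[up_idx] = spec.effect_log2fc
    log2fc[down_idx] = -spec.effect_log2fc

    mean_wt = base_mean.copy()
    mean_mut = base_mean * 2.0 ** log2fc

    planted = np.array(["ns"] * spec.n_genes, dtype=object)
    planted[up_idx] = "up"
    planted[down_idx] = "down"
    ko_idx = [gene_ids.index(g) for g in knockouts]
    planted[ko_idx] = "knockout"

    # overlap pair: the first partner shares a fraction of the second
    # partner's reads.  The overlapped gene is kept weakly expressed relative
    # to its neighbour so that shared reads dominate its naive total.
    region_counts = None
    if overlap is not None:
        a, b, frac = overlap
        ia, ib = gene_ids.index(a), gene_ids.index(b)
        # the neighbour is strongly expressed and the overlapped gene's own
        # transcription is a small fraction of the shared-region signal, so
        # shared reads dominate the overlapped gene's naive total and mask
        # its true expression change until the subtraction
        mean_b = max(mean_wt[ib], 0.3 * np.exp(hi))
        shared_mean = frac * mean_b
        mean_wt[ib] = mean_mut[ib] = mean_b
        mean_wt[ia] = shared_mean / 6.0
        if a not in knockouts:
            mean_mut[ia] = mean_wt[ia]

    sample_ids = [f"wt_{r + 1}" for r in range(n_rep)] + [f"mut_{r + 1}" for r in range(n_rep)]
    design = {s: ("wt" if s.startswith("wt") else "mut") for s in sample_ids}

    unique_counts = np.zeros((spec.n_genes, 2 * n_rep), dtype=np.int64)
    for j in range(n_rep):
        unique_counts[:, j] = _nb_draw(rng, mean_wt, spec.dispersion)
    for j in range(n_rep):
        unique_counts[:, n_rep + j] = _nb_draw(rng, mean_mut, spec.dispersion)
    # knocked-out loci: very few residual reads in the mutant, not hard zeros
    for i in ko_idx:
        unique_counts[i, n_rep:] = rng.poisson(spec.knockout_residual_mean, size=n_rep)

    naive = unique_counts.copy()
    if overlap is not None:
        a, b, frac = overlap
        ia, ib = gene_ids.index(a), gene_ids.index(b)
        shared = _nb_draw(rng, np.full(2 * n_rep, frac * mean_wt[ib]), spec.dispersion)
        naive[ia] += shared
        naive[ib] += shared
        region_counts = pd.DataFrame(
            [
                [a, b, "a_unique", *unique_counts[ia]],
                [a, b, "b_unique", *unique_counts[ib]],
                [a, b, "shared", *shared],
            ],
            columns=["gene_a", "gene_b", "region", *sample_ids],
        )

    index = pd.Index(gene_ids, name="gene_id")
    counts = CountMatrix(
        counts=pd.DataFrame(naive, index=index, columns=sample_ids),
        gene_lengths=pd.Series(np.asarray(lengths), index=index, name="length_bp"),
        design=design,
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "planted_class": planted, "planted_log2fc": log2fc}
    ).set_index("gene_id")
    return CountSimResult(counts=counts, truth=truth, region_counts=region_counts)


# ---------------------------------------------------------------------------
# GO annotation simulation
# ---------------------------------------------------------------------------

@dataclass
class GOSimSpec:
    """Flat gene→term annotation generator with optionally planted terms.

    ``planted_enriched_terms`` maps term names to the number of query-set
    genes deliberately packed into the term beyond chance, so that the
    downstream hypergeometric test finds them by construction.
    """

    n_terms: int = 40
    term_size_range: tuple[int, int] = (10, 200)
    planted_enriched_terms: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < len(self.planted_enriched_terms):
            raise SimSpecError("more planted terms than n_terms")
        if self.term_size_range[0] < 1:
            raise SimSpecError("term sizes must be >= 1")


def simulate_go_annotation(
    spec: GOSimSpec, universe: list[str], de_set: set[str]
) -> pd.DataFrame:
    """Two-column (gene_id, term_id) table over ``universe``.

    Planted terms are filled with ``excess`` genes from ``de_set`` plus
    random background genes; remaining terms are uniform random subsets.
    """
    if not universe:
        raise SimSpecError("universe must be nonempty")
    if spec.term_size_range[1] > len(universe):
        raise SimSpecError("term size exceeds universe size")
    rng = _child_rng(spec.seed, 1)
    universe = list(universe)
    de = [g for g in universe if g in de_set]
    non_de = [g for g in universe if g not in de_set]

    planted = list(spec.planted_enriched_terms.items())
    rows: list[tuple[str, str]] = []
    for t, (term, excess) in enumerate(planted):
        if excess > len(de):
            raise SimSpecError(f"planted excess for {term} exceeds DE-set size")
        size = int(rng.integers(spec.term_size_range[0], spec.term_size_range[1],
                                endpoint=True))
        n_bg = max(size - excess, 0)
        members = list(rng.choice(de, size=excess, replace=False))
        if n_bg:
            members += list(rng.choice(non_de, size=min(n_bg, len(non_de)),
                                       replace=False))
        rows += [(g, term) for g in members]
    for t in range(spec.n_terms - len(planted)):
        term = f"TERM:{t:04d}"
        size = int(rng.integers(spec.term_size_range[0], spec.term_size_range[1],
                                endpoint=True))
        members = rng.choice(universe, size=size, replace=False)
        rows += [(g, term) for g in members]
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


# ---------------------------------------------------------------------------
# PPI score-matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class PPISimSpec:
    """Block-structured symmetric confidence-score matrix generator."""

    n_proteins: int = 120
    block_sizes: tuple[int, ...] = (15, 15)
    within_block_score_range: tuple[float, float] = (0.6, 0.95)
    background_score_range: tuple[float, float] = (0.0, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) > self.n_proteins:
            raise SimSpecError("sum of block sizes exceeds n_proteins")
        for lo, hi in (self.within_block_score_range, self.background_score_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise SimSpecError("score ranges must be ordered subsets of [0, 1]")
        if self.within_block_score_range[0] <= self.background_score_range[1]:
            raise SimSpecError(
                "within-block scores must lie strictly above background scores"
            )


def simulate_ppi(spec: PPISimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (score matrix, truth table of planted block labels).

    The matrix is symmetric with zero diagonal; within-block entries are
    drawn from the high range, everything else from the background range.
    """
    rng = _child_rng(spec.seed, 2)
    n = spec.n_proteins
    ids = [f"p{i:04d}" for i in range(n)]
    lo_b, hi_b = spec.background_score_range
    upper = rng.uniform(lo_b, hi_b, size=(n, n))
    scores = np.triu(upper, 1)
    scores = scores + scores.T

    block_of = np.full(n, -1)
    start = 0
    for b, size in enumerate(spec.block_sizes):
        sl = slice(start, start + size)
        lo_w, hi_w = spec.within_block_score_range
        blk = rng.uniform(lo_w, hi_w, size=(size, size))
        blk = np.triu(blk, 1)
        blk = blk + blk.T
        scores[sl, sl] = blk
        block_of[sl] = b
        start += size
    np.fill_diagonal(scores, 0.0)
    mat = pd.DataFrame(scores, index=ids, columns=ids)
    truth = pd.DataFrame({"protein_id": ids, "block": block_of}).set_index("protein_id")
    return mat, truth


# ---------------------------------------------------------------------------
# Histone-modification ratio simulation
# ---------------------------------------------------------------------------

@dataclass
class HistoneSimSpec:
    """Per-gene histone-modification ratio generator.

    Baseline ratios are Normal(1, ``noise_sd``) per modification; genes in
    the upregulated class are shifted by ``shift_up`` on the first
    ``n_shifted_up`` modifications (default 7 of 8), downregulated genes by
    ``shift_down`` on the first ``n_shifted_down`` (default 5 of 8),
    emulating the concentration of chromatin-mark changes in overexpressed
    genes.
    """

    modifications: tuple[str, ...] = HISTONE_MODIFICATIONS
    shift_up: float = 1.0
    shift_down: float = -0.75
    n_shifted_up: int = 7
    n_shifted_down: int = 5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise SimSpecError("noise_sd must be positive")
        if len(self.modifications) != len(set(self.modifications)):
            raise SimSpecError("duplicate modification names")
        if not (0 <= self.n_shifted_up <= len(self.modifications)):
            raise SimSpecError("n_shifted_up out of range")
        if not (0 <= self.n_shifted_down <= len(self.modifications)):
            raise SimSpecError("n_shifted_down out of range")


def simulate_histone(spec: HistoneSimSpec, gene_classes: pd.Series) -> pd.DataFrame:
    """Ratio table (genes × modifications) for a given up/down/ns labelling.

    ``gene_classes`` maps gene_id to one of {"up", "down", "ns"}.
    """
    bad = set(gene_classes.unique()) - {"up", "down", "ns"}
    if bad:
        raise SimSpecError(f"unknown gene class(es): {sorted(bad)}")
    rng = _child_rng(spec.seed, 3)
    genes = list(gene_classes.index)
    mods = list(spec.modifications)
    ratios = rng.normal(1.0, spec.noise_sd, size=(len(genes), len(mods)))
    cls = gene_classes.to_numpy()
    up_mask = cls == "up"
    down_mask = cls == "down"
    ratios[np.ix_(up_mask, range(spec.n_shifted_up))] += spec.shift_up
    ratios[np.ix_(down_mask, range(spec.n_shifted_down))] += spec.shift_down
    return pd.DataFrame(ratios, index=pd.Index(genes, name="gene_id"), columns=mods)
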