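"""Multi-locus meiotic segregation: expectations, simulation, deficit tests.

A deletion-heterozygous diploid yeast segregates each unlinked locus 2:2
within a tetrad.  For a diploid described per locus as wt/wt, wt/del or
del/del, the probability that a random viable-by-default spore carries the
deletion at a locus is 0, 1/2 or 1, and probabilities multiply across
unlinked loci.  A quintuple heterozygote therefore yields all-deleted
spores at frequency (1/2)^5 = 1/32; fixing two loci homozygous-deleted
raises this to 1/8.

Spore simulation supports two modes: ``tetrad`` (exact 2:2 segregation of
heterozygous loci within each four-spore tetrad, independent across loci)
and ``random_spore`` (each spore drawn independently).  A viability model —
an ordered list of haplotype-predicate rules with survival probabilities —
is applied per spore after the genotype draw, giving germination rates and
double-deletion carrier counts among viable spores.  Observed carrier
deficits are tested against expectation with a 1-df chi-square
goodness-of-fit per locus pair.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

ALLELE_STATES = ("wt/wt", "wt/del", "del/del")

#: P(spore carries the deletion) per diploid allele state
CARRIER_P = {"wt/wt": 0.0, "wt/del": 0.5, "del/del": 1.0}


@dataclass
class DiploidGenotype:
    """Per-locus allele state of a diploid, loci assumed unlinked."""

    loci: dict[str, str]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("genotype needs at least one locus")
        bad = {s for s in self.loci.values() if s not in ALLELE_STATES}
        if bad:
            raise ValueError(f"unknown allele state(s) {sorted(bad)}; "
                             f"use one of {ALLELE_STATES}")

    def carrier_probability(self, locus: str) -> float:
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        return CARRIER_P[self.loci[locus]]

    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)


#: The quintuple-heterozygous F1 hybrid (het at ATF1, ATF2, EEB1, EHT1, MGL2).
F1_QUINTUPLE_HET = DiploidGenotype(
    {l: "wt/del" for l in ("ATF1", "ATF2", "EEB1", "EHT1", "MGL2")}
)

#: F2 hybrid fixed homozygous-deleted at ATF2 and EEB1, het elsewhere.
F2_H1XH5 = DiploidGenotype(
    {"ATF1": "wt/del", "ATF2": "del/del", "EEB1": "del/del",
     "EHT1": "wt/del", "MGL2": "wt/del"}
)


@dataclass
class ViabilityRule:
    """First-match-wins survival rule over a spore haplotype.

    Matches when the spore carries the deletion at every locus in
    ``deleted`` and the wildtype allele at every locus in ``wildtype``.
    """

    deleted: frozenset[str] = frozenset()
    wildtype: frozenset[str] = frozenset()
    survival: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.survival <= 1.0:
            raise ValueError("survival probability must lie in [0, 1]")

    def matches(self, haplotype: Mapping[str, bool]) -> bool:
        return all(haplotype.get(l, False) for l in self.deleted) and all(
            not haplotype.get(l, True) for l in self.wildtype
        )


@dataclass
class ViabilityModel:
    """Ordered survival rules; the first matching rule wins, default 1.0."""

    rules: list[ViabilityRule] = field(default_factory=list)
    default_survival: float = 1.0

    def survival(self, haplotype: Mapping[str, bool]) -> float:
        for rule in self.rules:
            if rule.matches(haplotype):
                return rule.survival
        return self.default_survival


NEUTRAL_MODEL = ViabilityModel()


def quintuple_lethal_model(loci: list[str] | None = None) -> ViabilityModel:
    """Spores deleted at all five loci never germinate; others unaffected."""
    loci = loci or ["ATF1", "ATF2", "EEB1", "EHT1", "MGL2"]
    return ViabilityModel(rules=[ViabilityRule(deleted=frozenset(loci), survival=0.0)])


@dataclass
class SporeSample:
    """Dissected-spore outcome of one simulated cross."""

    n_dissected: int
    n_viable: int
    haplotype_counts: Counter          # tuple of deleted loci (sorted) -> viable count
    pair_carrier_counts: dict[tuple[str, str], int]
    loci: list[str]

    @property
    def germination_rate(self) -> float:
        return self.n_viable / self.n_dissected if self.n_dissected else float("nan")

    def carrier_frequency(self, loci: tuple[str, ...]) -> float:
        """Frequency of viable spores deleted at every locus in ``loci``."""
        if self.n_viable == 0:
            return float("nan")
        need = set(loci)
        n = sum(c for hap, c in self.haplotype_counts.items() if need <= set(hap))
        return n / self.n_viable


def expected_spore_frequency(
    g: DiploidGenotype, required_deleted: set[str] | list[str]
) -> float:
    """Probability a spore carries the deletion at every required locus.

    Product over the required loci of the per-locus carrier probability
    (1 for del/del, 1/2 for wt/del, 0 for wt/wt); loci independent.
    """
    p = 1.0
    for locus in required_deleted:
        p *= g.carrier_probability(locus)
    return p


def pair_frequencies(g: DiploidGenotype) -> pd.DataFrame:
    """Expected double-deletion carrier frequency for every unordered pair."""
    loci = g.locus_names
    if len(loci) < 2:
        raise ValueError("need at least 2 loci for pair frequencies")
    rows = [
        (a, b, expected_spore_frequency(g, {a, b}))
        for a, b in itertools.combinations(loci, 2)
    ]
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "expected_frequency"])


def simulate_spores(
    g: DiploidGenotype,
    n_tetrads: int,
    model: ViabilityModel = NEUTRAL_MODEL,
    mode: str = "tetrad",
    seed: int = 0,
    zygote_survival: float = 1.0,
) -> SporeSample:
    """Draw 4 * ``n_tetrads`` spore haplotypes and apply viability.

    ``tetrad`` mode segregates every heterozygous locus exactly 2:2 within
    each tetrad, independently across loci; ``random_spore`` draws each
    spore's haplotype independently.  Both modes have identical marginal
    haplotype distributions for unlinked loci.  ``zygote_survival`` is an
    optional zygote-level hook (default off): each tetrad's founding zygote
    fails outright with probability 1 - zygote_survival, removing all four
    spores from the dissection.
    """
    if n_tetrads < 1:
        raise ValueError("n_tetrads must be >= 1")
    if mode not in ("tetrad", "random_spore"):
        raise ValueError(f"invalid mode {mode!r}; use 'tetrad' or 'random_spore'")
    if not 0.0 <= zygote_survival <= 1.0:
        raise ValueError("zygote_survival must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    loci = g.locus_names
    n_loci = len(loci)

    if zygote_survival < 1.0:
        kept = rng.random(n_tetrads) < zygote_survival
        n_tetrads_kept = int(kept.sum())
    else:
        n_tetrads_kept = n_tetrads
    n_spores = 4 * n_tetrads_kept
    if n_spores == 0:
        return SporeSample(0, 0, Counter(), {}, loci)

    # spores x loci boolean matrix: True = spore carries the deletion
    hap = np.zeros((n_spores, n_loci), dtype=bool)
    for j, locus in enumerate(loci):
        state = g.loci[locus]
        if state == "del/del":
            hap[:, j] = True
        elif state == "wt/wt":
            hap[:, j] = False
        elif mode == "random_spore":
            hap[:, j] = rng.random(n_spores) < 0.5
        else:  # tetrad: exactly two deleted spores per tetrad
            block = np.tile(np.array([True, True, False, False]), (n_tetrads_kept, 1))
            perm = rng.permuted(block, axis=1)
            hap[:, j] = perm.reshape(-1)

    survival = np.array(
        [model.survival(dict(zip(loci, row))) for row in hap]
    )
    viable = rng.random(n_spores) < survival

    hap_counts: Counter = Counter()
    for row in hap[viable]:
        hap_counts[tuple(l for l, d in zip(loci, row) if d)] += 1

    pair_counts: dict[tuple[str, str], int] = {}
    vh = hap[viable]
    for (ia, a), (ib, b) in itertools.combinations(enumerate(loci), 2):
        pair_counts[(a, b)] = int((vh[:, ia] & vh[:, ib]).sum())

    return SporeSample(
        n_dissected=n_spores,
        n_viable=int(viable.sum()),
        haplotype_counts=hap_counts,
        pair_carrier_counts=pair_counts,
        loci=loci,
    )


def chi_square_pair_deficit(
    observed: Mapping[tuple[str, str], int],
    n_viable: int,
    expected_freqs: Mapping[tuple[str, str], float],
) -> pd.DataFrame:
    """1-df carrier/non-carrier goodness-of-fit per locus pair.

    For each pair, the viable spores split into double-deletion carriers
    (observed count c, expected n*f) and non-carriers; the statistic is
    sum (O - E)^2 / E over the two cells.  Pairs whose expected frequency
    is 0 or 1 while the opposite cell is occupied cannot use the chi-square
    approximation; they are flagged and given an exact binomial p instead.
    """
    if n_viable <= 0:
        raise ValueError("n_viable must be positive")
    rows = []
    for pair, f in expected_freqs.items():
        c = observed.get(pair, 0)
        if c > n_viable:
            raise ValueError(f"carrier count exceeds n_viable for pair {pair}")
        if f in (0.0, 1.0):
            mismatch = c > 0 if f == 0.0 else c < n_viable
            if mismatch:
                # degenerate expectation: exact binomial evidence instead
                p = float(stats.binomtest(c, n_viable, f if f else 1e-12).pvalue) \
                    if f else 0.0
                rows.append((*pair, c, n_viable * f, np.nan, p, True))
            else:
                rows.append((*pair, c, n_viable * f, 0.0, 1.0, False))
            continue
        e_carrier = n_viable * f
        e_non = n_viable * (1.0 - f)
        chi2 = (c - e_carrier) ** 2 / e_carrier + ((n_viable - c) - e_non) ** 2 / e_non
        p = float(stats.chi2.sf(chi2, df=1))
        rows.append((*pair, c, e_carrier, chi2, p, False))
    return pd.DataFrame(
        rows,
        columns=["locus_a", "locus_b", "observed_carriers", "expected_carriers",
                 "chi_square", "p_value", "exact_fallback"],
    )
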