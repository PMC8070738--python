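"""Hierarchical clustering of protein-protein-interaction score matrices.

The pairwise confidence scores of differentially expressed genes form a
symmetric similarity matrix in [0, 1] (missing pairs score 0).  It is
converted to a distance d = 1 - score, clustered agglomeratively with
complete linkage, and the dendrogram is cut at a fixed height.  Flat
clusters are retained when they contain more than ``min_size`` members and
the mean of all within-cluster pairwise scores exceeds ``min_score``
(defaults: 10 members, 0.4).

Scores supplied on the 0-1000 integer evidence scale are rescaled to
[0, 1] automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_CUT_HEIGHT = 0.95
MIN_CLUSTER_SIZE = 10     # retained when size strictly exceeds this
MIN_CLUSTER_SCORE = 0.4   # retained when mean within-cluster score exceeds this


@dataclass
class ScoreMatrix:
    """Symmetric [0, 1] similarity matrix over protein ids."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if vals.shape[0] != vals.shape[1]:
            raise ValueError("score matrix must be square")
        if not np.allclose(vals, vals.T):
            raise ValueError("score matrix must be symmetric")
        if np.nanmax(vals, initial=0.0) > 1.0:
            # STRING-style 0-1000 integer scale
            vals = vals / 1000.0
            self.scores = pd.DataFrame(
                vals, index=self.scores.index, columns=self.scores.columns
            )
        off = vals[~np.eye(len(vals), dtype=bool)]
        if ((off < 0) | (off > 1)).any():
            raise ValueError("scores must lie in [0, 1]")

    @classmethod
    def from_edges(
        cls, edges: pd.DataFrame, proteins: list[str] | None = None
    ) -> "ScoreMatrix":
        """Build from a (protein_a, protein_b, score) edge list.

        Missing pairs are imputed as score 0.  ``proteins`` fixes the node
        set (isolated proteins allowed); by default the union of endpoint
        ids is used, in order of first appearance.
        """
        if proteins is None:
            seen: list[str] = []
            for p in pd.concat([edges["protein_a"], edges["protein_b"]]):
                if p not in seen:
                    seen.append(p)
            proteins = seen
        mat = pd.DataFrame(0.0, index=proteins, columns=proteins)
        for a, b, s in edges[["protein_a", "protein_b", "score"]].itertuples(index=False):
            mat.loc[a, b] = s
            mat.loc[b, a] = s
        np.fill_diagonal(mat.values, 0.0)
        return cls(scores=mat)


@dataclass
class PPIClusterSet:
    """Flat clusters from a complete-linkage cut, with retention flags."""

    table: pd.DataFrame      # cluster_id, size, mean_score, retained, members
    membership: pd.Series    # protein_id -> cluster_id
    cut_height: float
    linkage_matrix: np.ndarray

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]


def mean_within_score(scores: pd.DataFrame, members: list[str]) -> float:
    """Mean of all within-cluster pairwise scores; NaN for singletons."""
    if len(members) < 2:
        return float("nan")
    sub = scores.loc[members, members].to_numpy(dtype=float)
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def cluster_scores(
    sm: ScoreMatrix,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    min_size: int = MIN_CLUSTER_SIZE,
    min_score: float = MIN_CLUSTER_SCORE,
) -> PPIClusterSet:
    """Complete-linkage clustering of a similarity matrix at a fixed cut.

    Distances are d = 1 - score; the agglomeration uses complete linkage
    (cluster distance = max pairwise distance), the tree is cut at
    ``cut_height`` and each flat cluster is scored by the mean of its
    within-cluster pairwise similarities.  Clusters are flagged retained
    when size > ``min_size`` and mean score > ``min_score``.
    """
    scores = sm.scores
    if len(scores) < 2:
        raise ValueError("need at least 2 proteins to cluster")
    dist = 1.0 - scores.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=cut_height, criterion="distance")
    membership = pd.Series(labels, index=scores.index, name="cluster_id")

    rows = []
    for cid in sorted(set(labels)):
        members = list(scores.index[labels == cid])
        mean_s = mean_within_score(scores, members)
        retained = (len(members) > min_size) and (
            not np.isnan(mean_s) and mean_s > min_score
        )
        rows.append((cid, len(members), mean_s, retained, members))
    table = pd.DataFrame(
        rows, columns=["cluster_id", "size", "mean_score", "retained", "members"]
    ).set_index("cluster_id")
    return PPIClusterSet(
        table=table, membership=membership, cut_height=cut_height, linkage_matrix=z
    )
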