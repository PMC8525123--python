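"""Dissimilarity and diversity primitives shared by all null models.

Taxonomic metrics (Jaccard, Ružička, Bray–Curtis), Hill numbers and the
Hill-based pairwise dissimilarity qd, plus the phylogenetic metrics
(Faith PD, βMNTD, generalized UniFrac).  Faith PD uses the root-inclusive
convention throughout: the PD of a taxon set is the total branch length of
the union of its root-to-tip paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import CommunityTable, Phylogeny

__all__ = [
    "PairwiseMatrix",
    "dissimilarity",
    "pairwise_dissimilarity",
    "hill_diversity",
    "hill_beta_qd",
    "faith_pd",
    "beta_mntd",
    "beta_mntd_from_distances",
    "generalized_unifrac",
    "branch_proportions",
]

METRICS = ("jaccard", "ruzicka", "bray_curtis")


@dataclass
class PairwiseMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with zero diagonal."""

    values: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        np.fill_diagonal(v, 0.0)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def pair(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def condensed(self) -> np.ndarray:
        v = self.values.to_numpy()
        iu = np.triu_indices(len(v), k=1)
        return v[iu]

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")


def pairwise_dissimilarity(x: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise dissimilarities among the rows of a counts matrix."""
    x = np.asarray(x, dtype=float)
    if np.any(x.sum(axis=1) <= 0):
        raise ValueError("sample with zero total count")
    if metric == "jaccard":
        b = (x > 0).astype(float)
        shared = b @ b.T
        rich = b.sum(axis=1)
        union = rich[:, None] + rich[None, :] - shared
        with np.errstate(invalid="ignore"):
            d = 1.0 - shared / union
        return np.nan_to_num(d, nan=0.0)
    # sum|x-y| gives both Σmin = (sx+sy-M)/2 and Σmax = (sx+sy+M)/2
    m = cdist(x, x, metric="cityblock")
    s = x.sum(axis=1)
    tot = s[:, None] + s[None, :]
    if metric == "ruzicka":
        return np.where(tot + m > 0, 2.0 * m / (tot + m), 0.0)
    if metric == "bray_curtis":
        return np.where(tot > 0, m / tot, 0.0)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def dissimilarity(table: CommunityTable, metric: str) -> PairwiseMatrix:
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = pairwise_dissimilarity(table.counts.to_numpy(), metric)
    return PairwiseMatrix(pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids), metric)


# ---------------------------------------------------------------------------
# Hill numbers
# ---------------------------------------------------------------------------

def hill_diversity(abundances, q: float) -> float:
    """Hill number of order q: ``(Σ p_i^q)^(1/(1-q))``, q=1 by its limit.

    q=0 is richness, q=1 the exponential of Shannon entropy, q=2 the inverse
    Simpson concentration.
    """
    p = np.asarray(abundances, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative abundance")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    p = p[p > 0] / total
    if q < 0:
        raise ValueError("q must be >= 0")
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_beta_qd(x, y, q: float) -> float:
    """Hill-based pairwise dissimilarity qd in [0, 1] for two samples.

    With N=2 equally weighted samples: gamma is the Hill diversity of the
    pooled mean relative-abundance vector; alpha is the Hill alpha of order
    q over the 2S matrix of halved within-sample proportions; beta =
    gamma/alpha lies in [1, 2] and qd = beta - 1 is the effective proportion
    of ASVs not shared between the two communities.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if q < 0:
        raise ValueError("q must be >= 0")
    sx, sy = x.sum(), y.sum()
    if sx <= 0 or sy <= 0:
        raise ValueError("sample with zero total")
    px, py = x / sx, y / sy
    n = 2
    gamma = hill_diversity((px + py) / n, q)
    pij = np.concatenate([px, py]) / n
    pij = pij[pij > 0]
    if abs(q - 1.0) < 1e-12:
        alpha = np.exp(-np.sum(pij * np.log(pij))) / n
    else:
        alpha = np.sum(pij**q) ** (1.0 / (1.0 - q)) / n
    beta = gamma / alpha
    return float(np.clip((beta - 1.0) / (n - 1.0), 0.0, 1.0))


# ---------------------------------------------------------------------------
# phylogenetic metrics
# ---------------------------------------------------------------------------

def faith_pd(taxon_set, tree: Phylogeny) -> float:
    """Faith phylogenetic diversity of a tip set (root-inclusive)."""
    taxa = list(taxon_set)
    if not taxa:
        raise ValueError("empty taxon set")
    seen = np.zeros(len(tree._length), dtype=bool)
    total = 0.0
    for name in taxa:
        for e in tree.tip_path_edges(name):
            if seen[e]:
                break
            seen[e] = True
            total += tree._length[e]
    return float(total)


def beta_mntd_from_distances(f1: np.ndarray, f2: np.ndarray, dmat: np.ndarray) -> float:
    """Abundance-weighted β mean-nearest-taxon distance from a patristic matrix.

    ``f1``/``f2`` are relative-abundance vectors aligned with ``dmat``'s taxa.
    A taxon present in both samples has nearest-taxon distance 0 (its own
    zero self-distance in the other sample counts).
    """
    i1 = np.flatnonzero(f1 > 0)
    i2 = np.flatnonzero(f2 > 0)
    if len(i1) == 0 or len(i2) == 0:
        raise ValueError("empty sample")
    nn12 = dmat[np.ix_(i1, i2)].min(axis=1)
    nn21 = dmat[np.ix_(i2, i1)].min(axis=1)
    return float(0.5 * (f1[i1] @ nn12) + 0.5 * (f2[i2] @ nn21))


def beta_mntd(x, y, tree: Phylogeny, asv_ids=None) -> float:
    """βMNTD between two count vectors on the tips of ``tree``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = list(asv_ids) if asv_ids is not None else tree.tip_names
    labels, dmat = tree.patristic()
    pos = {name: i for i, name in enumerate(labels)}
    try:
        idx = np.array([pos[a] for a in ids])
    except KeyError as exc:
        raise KeyError(f"unknown tip {exc.args[0]!r}") from None
    d = dmat[np.ix_(idx, idx)]
    return beta_mntd_from_distances(x / x.sum(), y / y.sum(), d)


def branch_proportions(rel_abund: np.ndarray, tree: Phylogeny, asv_ids) -> np.ndarray:
    """Per-edge descendant abundance proportions for each sample row.

    Returns an (n_samples, n_edges) matrix where entry (s, b) is the share of
    sample s's abundance held by tips descending through edge b.
    """
    order = {name: p for p, name in enumerate(tree.tip_names)}
    cols = np.array([order[a] for a in asv_ids])
    mask = tree._tip_mask[:, cols]  # (edges_incl_root, aligned tips)
    return np.asarray(rel_abund, dtype=float) @ mask.T.astype(float)


def generalized_unifrac(x, y, tree: Phylogeny, alpha: float = 0.5, asv_ids=None) -> float:
    """Generalized UniFrac distance between two samples.

    ``Σ_b L_b (p_bA+p_bB)^α |p_bA-p_bB|/(p_bA+p_bB)`` normalized by
    ``Σ_b L_b (p_bA+p_bB)^α`` over edges with descendant mass; alpha in
    [0, 1] controls abundance weighting (alpha=1 recovers weighted-normalized
    UniFrac).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("sample with zero total")
    ids = list(asv_ids) if asv_ids is not None else tree.tip_names
    p = branch_proportions(np.vstack([x / x.sum(), y / y.sum()]), tree, ids)
    pa, pb = p[0], p[1]
    tot = pa + pb
    keep = tot > 0
    w = tree._length[keep] * tot[keep] ** alpha
    denom = w.sum()
    if denom == 0:
        return 0.0
    num = float(np.sum(w * np.abs(pa[keep] - pb[keep]) / tot[keep]))
    return num / denom
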