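"""Beta-null deviation: observed minus null-expected beta diversity.

For every sample pair the deviation between the observed dissimilarity
(Bray–Curtis or generalized UniFrac) and the mean dissimilarity of randomly
assembled communities separates niche assembly (deviation away from 0) from
neutral assembly (deviation near 0).  The null keeps each sample's richness
and read total, draws taxa by occurrence frequency and fills reads by
regional relative abundance.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .io import Dataset
from .metrics import PairwiseMatrix, branch_proportions, pairwise_dissimilarity
from .nst import null_communities

logger = logging.getLogger("assemblage")

__all__ = ["null_deviation", "deviation_trajectory"]


def _gunifrac_matrix(counts: np.ndarray, tree, asv_ids, alpha: float) -> np.ndarray:
    rel = counts / counts.sum(axis=1, keepdims=True)
    p = branch_proportions(rel, tree, asv_ids)  # samples x edges
    lengths = tree._length
    n = len(p)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot = p[i] + p[j]
            keep = tot > 0
            w = lengths[keep] * tot[keep] ** alpha
            denom = w.sum()
            d = float(np.sum(w * np.abs(p[i, keep] - p[j, keep]) / tot[keep]) / denom) if denom else 0.0
            out[i, j] = out[j, i] = d
    return out


def _beta_matrix(counts, dataset: Dataset, metric: str, alpha: float) -> np.ndarray:
    if metric == "bray_curtis":
        return pairwise_dissimilarity(counts, "bray_curtis")
    if metric == "generalized_unifrac":
        return _gunifrac_matrix(counts, dataset.tree, dataset.table.asv_ids, alpha)
    raise ValueError(f"metric must be bray_curtis or generalized_unifrac, got {metric!r}")


def null_deviation(
    dataset: Dataset,
    metric: str = "generalized_unifrac",
    n_rand: int = 999,
    seed: int = 0,
    alpha: float = 0.5,
) -> PairwiseMatrix:
    """Pairwise deviation matrix: observed beta minus mean null beta.

    Positive deviations mean the pair is more dissimilar than random
    assembly predicts (niche divergence); near zero, neutral.
    """
    table = dataset.table
    counts = table.counts.to_numpy()
    obs = _beta_matrix(counts, dataset, metric, alpha)
    null_sum = np.zeros_like(obs)
    for null in null_communities(table, "PF", n_rand, seed):
        null_sum += _beta_matrix(null, dataset, metric, alpha)
    dev = obs - null_sum / n_rand
    np.fill_diagonal(dev, 0.0)
    return PairwiseMatrix(
        pd.DataFrame(dev, index=table.sample_ids, columns=table.sample_ids),
        metric=f"{metric}_null_deviation",
    )


def deviation_trajectory(deviations: PairwiseMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, day) mean ± sd of within-cell pair deviations.

    Cells with fewer than 2 samples are skipped with a warning; with 3
    replicates a cell contributes 3 pairs.
    """
    rows = []
    for (group, day), ids in metadata.groupby(["group", "day"], sort=True).groups.items():
        ids = [s for s in ids if s in deviations.sample_ids]
        if len(ids) < 2:
            logger.warning("cell (%s, day %s) has < 2 samples; skipped", group, day)
            continue
        vals = [deviations.pair(a, b) for a, b in combinations(ids, 2)]
        rows.append(
            {
                "group": group,
                "day": day,
                "mean_deviation": float(np.mean(vals)),
                "sd_deviation": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "n_pairs": len(vals),
            }
        )
    return pd.DataFrame(rows)
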