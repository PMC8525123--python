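"""Hill-number dissimilarity null model across paired samples.

The observed Hill-based dissimilarity qd between paired communities (default
pairing: consecutive time points) is compared, over a grid of diversity
orders q, with a null distribution obtained by replacing both members of
each pair with randomized samples that keep the real sample's richness and
read total but draw ASV identities by occurrence frequency and fill reads by
dataset-wide relative abundance.  Observed within the null spread indicates
stochastic turnover; above or below it, deterministic divergence or
convergence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CommunityTable
from .nst import draw_null_sample

__all__ = ["hill_null_sample", "qd_null_comparison", "consecutive_day_pairs", "qd_grid"]


def _pools(counts: np.ndarray):
    occ = (counts > 0).mean(axis=0)
    pool_idx = np.flatnonzero(occ > 0)
    occ_w = occ[pool_idx] / occ[pool_idx].sum()
    abund = counts.sum(axis=0).astype(float)
    return pool_idx, occ_w, abund / abund.sum()


def hill_null_sample(
    table: CommunityTable, sample_id: str, seed: int, uniform_fill: bool = False
) -> np.ndarray:
    """Null version of one sample: same richness and total, identities random.

    ASVs are drawn without replacement with probability proportional to the
    fraction of samples they occur in; the real sample's read total is
    distributed multinomially over the drawn ASVs proportionally to their
    dataset-wide relative abundances (or uniformly with ``uniform_fill``).
    """
    counts = table.counts.to_numpy()
    row = table.counts.loc[sample_id].to_numpy()
    pool_idx, occ_w, abund_w = _pools(counts)
    if uniform_fill:
        abund_w = np.full_like(abund_w, 1.0 / len(abund_w))
    rng = np.random.default_rng(seed)
    return draw_null_sample(
        rng, pool_idx, occ_w, abund_w, int((row > 0).sum()), int(row.sum()), counts.shape[1]
    )


def _qd_curve(x: np.ndarray, y: np.ndarray, q_grid: np.ndarray) -> np.ndarray:
    """hill_beta_qd for one pair, vectorized over the q grid."""
    px = x / x.sum()
    py = y / y.sum()
    pg = (px + py) / 2.0
    pg = pg[pg > 0]
    pij = np.concatenate([px, py]) / 2.0
    pij = pij[pij > 0]
    out = np.empty(len(q_grid))
    for k, q in enumerate(q_grid):
        if abs(q - 1.0) < 1e-12:
            gamma = np.exp(-np.sum(pg * np.log(pg)))
            alpha = np.exp(-np.sum(pij * np.log(pij))) / 2.0
        else:
            gamma = np.sum(pg**q) ** (1.0 / (1.0 - q))
            alpha = np.sum(pij**q) ** (1.0 / (1.0 - q)) / 2.0
        out[k] = gamma / alpha - 1.0
    return np.clip(out, 0.0, 1.0)


def consecutive_day_pairs(table: CommunityTable, group: str | None = None) -> list[tuple[str, str]]:
    """All (earlier, later) sample pairs spanning consecutive day values.

    Within one group (or the whole table), replicate samples at consecutive
    day values are paired all-against-all, e.g. day 0 vs 3, 3 vs 7, ...
    """
    meta = table.metadata if group is None else table.metadata[table.metadata["group"] == group]
    days = sorted(meta["day"].unique())
    pairs = []
    for d0, d1 in zip(days[:-1], days[1:]):
        a_ids = meta.index[meta["day"] == d0]
        b_ids = meta.index[meta["day"] == d1]
        pairs += [(a, b) for a in a_ids for b in b_ids]
    return pairs


def qd_null_comparison(
    table: CommunityTable,
    pairing: list[tuple[str, str]],
    q_grid=None,
    n_rand: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed mean qd vs. its randomization null over a q grid.

    Returns a tidy frame with one row per q: observed mean over pairs, null
    mean and null standard deviation pooled over all pairs and
    randomizations, and the z-score of the observed mean.
    """
    if not pairing:
        raise ValueError("empty pairing")
    q_grid = np.arange(0.0, 2.0 + 1e-9, 0.1) if q_grid is None else np.asarray(q_grid, float)
    if np.any(q_grid < 0):
        raise ValueError("q must be >= 0")
    counts = table.counts.to_numpy()
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    pool_idx, occ_w, abund_w = _pools(counts)
    n_taxa = counts.shape[1]
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)

    obs = np.vstack([_qd_curve(counts[idx[a]], counts[idx[b]], q_grid) for a, b in pairing])
    rng = np.random.default_rng(seed)
    null = np.empty((n_rand, len(pairing), len(q_grid)))
    for r in range(n_rand):
        for p, (a, b) in enumerate(pairing):
            xa = draw_null_sample(rng, pool_idx, occ_w, abund_w, richness[idx[a]], totals[idx[a]], n_taxa)
            xb = draw_null_sample(rng, pool_idx, occ_w, abund_w, richness[idx[b]], totals[idx[b]], n_taxa)
            null[r, p] = _qd_curve(xa, xb, q_grid)
    null_flat = null.reshape(-1, len(q_grid))
    null_mean = null_flat.mean(axis=0)
    null_sd = null_flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs.mean(axis=0) - null_mean) / null_sd
    return pd.DataFrame(
        {
            "q": q_grid,
            "observed_mean": obs.mean(axis=0),
            "observed_sd": obs.std(axis=0, ddof=1) if len(pairing) > 1 else np.nan,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "n_pairs": len(pairing),
            "n_rand": n_rand,
        }
    )


def qd_grid(table: CommunityTable, pairing, q_grid=None) -> pd.DataFrame:
    """Observed qd per pair per q (no null), long format."""
    q_grid = np.arange(0.0, 2.0 + 1e-9, 0.1) if q_grid is None else np.asarray(q_grid, float)
    counts = table.counts.to_numpy()
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    rows = []
    for a, b in pairing:
        qd = _qd_curve(counts[idx[a]], counts[idx[b]], q_grid)
        for q, v in zip(q_grid, qd):
            rows.append({"sample_a": a, "sample_b": b, "q": q, "qd": v})
    return pd.DataFrame(rows)
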