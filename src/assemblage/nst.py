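"""Normalized stochasticity ratio (NST) per sample group.

Observed pairwise similarity is compared with the similarity expected under
null communities that preserve per-sample read totals while drawing taxon
identities with probability proportional to their occurrence frequency in the
group and filling reads proportionally to regional relative abundances.
NST is 0 when assembly is completely deterministic and 1 (100%) when
completely stochastic.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CommunityTable
from .metrics import pairwise_dissimilarity

logger = logging.getLogger("assemblage")

__all__ = [
    "NullEnsemble",
    "NstResult",
    "null_communities",
    "nst_score",
    "nst_from_similarities",
    "nst_by_group",
]

ALGORITHMS = ("PF", "PP")


@dataclass
class NullEnsemble:
    """An observed statistic with the vector of its null-replicate values."""

    observed: float
    null_values: np.ndarray
    seed: int
    generator: str

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))


@dataclass
class NstResult:
    group: str
    metric: str
    algorithm: str
    pair_stochasticity: pd.Series  # indexed by (sample_a, sample_b)
    nst: float
    n_skipped_pairs: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.nst <= 1.0 + 1e-12:
            raise ValueError(f"NST out of [0, 1]: {self.nst}")


def draw_null_sample(rng, pool_idx, occ_w, abund_w, richness, total, n_taxa):
    """One null sample: taxa ∝ occurrence frequency, reads ∝ regional abundance."""
    if richness > len(pool_idx):
        raise ValueError(
            f"sample richness {richness} exceeds taxon pool size {len(pool_idx)}"
        )
    if richness > total:
        richness = int(total)
    if richness == len(pool_idx):
        chosen = pool_idx
    else:
        chosen = rng.choice(pool_idx, size=richness, replace=False, p=occ_w)
    aw = abund_w[chosen]
    aw = aw / aw.sum()
    out = np.zeros(n_taxa, dtype=np.int64)
    # one read per drawn taxon keeps null richness exactly at the constraint
    out[chosen] = 1 + rng.multinomial(total - richness, aw)
    return out


def null_communities(table: CommunityTable, algorithm: str, n_rand: int, seed: int):
    """Yield ``n_rand`` null count matrices under the PF or PP constraint.

    PF fixes each sample's richness at the observed value; PP draws a
    binomial richness with mean equal to observed (both keep the observed
    read total, occurrence-frequency taxon draws and abundance-proportional
    fills).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"algorithm must be one of {ALGORITHMS}")
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    counts = table.counts.to_numpy()
    n_samples, n_taxa = counts.shape
    occ = (counts > 0).mean(axis=0)
    pool_idx = np.flatnonzero(occ > 0)
    occ_w = occ[pool_idx] / occ[pool_idx].sum()
    abund = counts.sum(axis=0).astype(float)
    abund_w = abund / abund.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    if np.any(richness > len(pool_idx)):
        raise ValueError("sample richness exceeds pool size")
    pool_n = len(pool_idx)
    # per-sample streams keyed by sample id so results are invariant to
    # the order samples appear in the table
    sample_keys = [zlib.crc32(str(s).encode()) for s in table.sample_ids]
    for r in range(n_rand):
        null = np.empty_like(counts)
        for s in range(n_samples):
            rng = np.random.default_rng(np.random.SeedSequence([seed, r, sample_keys[s]]))
            if algorithm == "PF":
                k = richness[s]
            else:  # PP: binomial with mean = observed richness
                k = int(np.clip(rng.binomial(pool_n, richness[s] / pool_n), 1, pool_n))
            null[s] = draw_null_sample(rng, pool_idx, occ_w, abund_w, k, totals[s], n_taxa)
        yield null


def nst_score(
    table: CommunityTable,
    metric: str = "ruzicka",
    algorithm: str = "PF",
    n_rand: int = 1000,
    seed: int = 0,
    group: str = "all",
) -> NstResult:
    """NST of one sample group from pairwise similarity vs. its null expectation.

    For each pair, with observed similarity C = 1 - d and null-expected
    similarity E: the normalized selection strength is (C-E)/(1-E) when the
    pair is more similar than expected and (E-C)/E when less similar; the
    pair's stochasticity ratio is its complement, and NST is the mean over
    pairs.
    """
    if table.n_samples < 3:
        raise ValueError("NST needs >= 3 samples in a group")
    if table.n_samples < 6:
        logger.warning(
            "group %s has %d replicates; NST becomes less precise below 6", group, table.n_samples
        )
    obs_d = pairwise_dissimilarity(table.counts.to_numpy(), metric)
    null_sum = np.zeros_like(obs_d)
    for null in null_communities(table, algorithm, n_rand, seed):
        null_sum += pairwise_dissimilarity(null, metric)
    exp_sim = 1.0 - null_sum / n_rand
    return nst_from_similarities(
        table.sample_ids, 1.0 - obs_d, exp_sim,
        group=group, metric=metric, algorithm=algorithm, seed=seed,
    )


def nst_from_similarities(
    ids, obs_sim: np.ndarray, exp_sim: np.ndarray,
    group: str = "all", metric: str = "ruzicka", algorithm: str = "PF", seed: int | None = None,
) -> NstResult:
    """NST from observed and null-expected pairwise similarity matrices.

    The per-pair normalized selection strength divides the deviation from
    the null expectation E by its maximum attainable magnitude (1-E toward
    similarity, E toward dissimilarity); pairs with degenerate E (0 or 1)
    are skipped with a warning.
    """
    ids = list(ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    ratios, index, skipped = [], [], 0
    for i, j in zip(iu, ju):
        c = obs_sim[i, j]
        e = exp_sim[i, j]
        if e >= 1.0 - 1e-12 or e <= 1e-12:
            logger.warning("pair (%s, %s): null expectation %.3f degenerate; skipped", ids[i], ids[j], e)
            skipped += 1
            continue
        nss = (c - e) / (1.0 - e) if c >= e else (e - c) / e
        ratios.append(1.0 - nss)
        index.append((ids[i], ids[j]))
    if not ratios:
        raise ValueError("all pairs skipped; NST undefined")
    pair_st = pd.Series(ratios, index=pd.MultiIndex.from_tuples(index))
    return NstResult(
        group=group,
        metric=metric,
        algorithm=algorithm,
        pair_stochasticity=pair_st,
        nst=float(np.clip(pair_st.mean(), 0.0, 1.0)),
        n_skipped_pairs=skipped,
        seed=seed,
    )


def nst_by_group(
    table: CommunityTable,
    metric: str = "ruzicka",
    algorithm: str = "PF",
    n_rand: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """NST per metadata group; null pools are built within each group."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for g, child in zip(table.groups(), ss.spawn(len(table.groups()))):
        sub = table.group_table(g)
        res = nst_score(
            sub, metric=metric, algorithm=algorithm, n_rand=n_rand,
            seed=int(child.generate_state(1)[0] % 2**31), group=g,
        )
        rows.append(
            {"group": g, "metric": metric, "algorithm": algorithm,
             "nst": res.nst, "nst_percent": 100.0 * res.nst,
             "n_samples": sub.n_samples, "n_pairs": len(res.pair_stochasticity)}
        )
    return pd.DataFrame(rows)
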