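"""Quantitative process estimates: βNTI, Raup–Crick (Bray–Curtis), and the
five-way classification of community assembly processes.

βNTI standardizes the observed abundance-weighted β-mean-nearest-taxon
distance against a taxa-shuffle null (tip labels permuted across the whole
tree).  Pairs with βNTI > +2 are assigned to variable selection, < -2 to
homogeneous selection; the remainder are split by the Raup–Crick index on
Bray–Curtis nulls into dispersal limitation (> +0.95), homogenizing
dispersal (< -0.95), and undominated assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import CommunityTable, Dataset
from .metrics import pairwise_dissimilarity
from .nst import draw_null_sample

logger = logging.getLogger("assemblage")

__all__ = [
    "ProcessProfile",
    "PROCESSES",
    "beta_nti",
    "beta_nti_matrix",
    "rc_bray",
    "classify_processes",
    "BNTI_THRESHOLD",
    "RC_THRESHOLD",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

#: |βNTI| beyond which selection dominates (sign distinguishes variable
#: from homogeneous selection) and |RC| beyond which dispersal dominates
BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


@dataclass
class ProcessProfile:
    """Per-group fractions of pairs assigned to each assembly process."""

    group: str
    fractions: dict[str, float]
    n_pairs: int

    def __post_init__(self) -> None:
        vals = np.array([self.fractions.get(p, 0.0) for p in PROCESSES])
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"process fractions must be >= 0 and sum to 1, got {self.fractions}")

    @property
    def modal(self) -> str:
        return max(PROCESSES, key=lambda p: self.fractions.get(p, 0.0))


def _patristic_for(dataset: Dataset) -> np.ndarray:
    labels, dmat = dataset.tree.patristic()
    pos = {name: i for i, name in enumerate(labels)}
    idx = np.array([pos[a] for a in dataset.table.asv_ids])
    return dmat[np.ix_(idx, idx)]


def _bmntd_for_pairs(rel: np.ndarray, taxa_idx: list[np.ndarray], dmat: np.ndarray, pairs) -> np.ndarray:
    """βMNTD for the listed sample pairs given one (possibly permuted) matrix."""
    samples = sorted({s for p in pairs for s in p})
    nn = {j: dmat[:, taxa_idx[j]].min(axis=1) for j in samples}
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        out[k] = 0.5 * (rel[i] @ nn[j]) + 0.5 * (rel[j] @ nn[i])
    return out


def beta_nti_matrix(
    dataset: Dataset, pairs=None, n_rand: int = 999, seed: int = 0,
    on_degenerate: str = "raise",
) -> pd.DataFrame:
    """βNTI for a set of sample pairs sharing one taxa-shuffle null ensemble.

    One tip-label permutation per null replicate is applied to all pairs, the
    standard practice for group-level βNTI.  Returns a frame with observed
    βMNTD, null mean/sd, and βNTI per pair.  A degenerate pair (null sd = 0,
    e.g. identical taxon supports) raises by default; with
    ``on_degenerate='nan'`` its βNTI is NaN and a warning is logged.
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99 for a usable null")
    table = dataset.table
    counts = table.counts.to_numpy().astype(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    taxa_idx = [np.flatnonzero(counts[s] > 0) for s in range(len(counts))]
    dmat = _patristic_for(dataset)
    ids = table.sample_ids
    if pairs is None:
        pairs = list(combinations(range(len(ids)), 2))
    else:
        pos = {s: i for i, s in enumerate(ids)}
        pairs = [(pos[a], pos[b]) for a, b in pairs]

    obs = _bmntd_for_pairs(rel, taxa_idx, dmat, pairs)
    rng = np.random.default_rng(seed)
    null = np.empty((n_rand, len(pairs)))
    n_taxa = dmat.shape[0]
    for r in range(n_rand):
        perm = rng.permutation(n_taxa)
        null[r] = _bmntd_for_pairs(rel, taxa_idx, dmat[np.ix_(perm, perm)], pairs)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [(ids[pairs[k][0]], ids[pairs[k][1]]) for k in np.flatnonzero(sd == 0)]
        if on_degenerate == "raise":
            raise ValueError(f"degenerate null (sd = 0) for pairs {bad}")
        logger.warning("degenerate βNTI null for %d pair(s): %s", len(bad), bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    return pd.DataFrame(
        {
            "sample_a": [ids[i] for i, _ in pairs],
            "sample_b": [ids[j] for _, j in pairs],
            "bmntd_obs": obs,
            "null_mean": mean,
            "null_sd": sd,
            "beta_nti": bnti,
        }
    )


def beta_nti(dataset: Dataset, pair: tuple[str, str], n_rand: int = 999, seed: int = 0) -> float:
    """βNTI for one sample pair: (observed βMNTD - null mean) / null sd."""
    df = beta_nti_matrix(dataset, pairs=[pair], n_rand=n_rand, seed=seed)
    return float(df["beta_nti"].iloc[0])


def _rc_from_counts(counts, i, j, n_rand, rng) -> float:
    occ = (counts > 0).mean(axis=0)
    pool_idx = np.flatnonzero(occ > 0)
    occ_w = occ[pool_idx] / occ[pool_idx].sum()
    abund = counts.sum(axis=0).astype(float)
    abund_w = abund / abund.sum()
    n_taxa = counts.shape[1]
    obs = pairwise_dissimilarity(counts[[i, j]], "bray_curtis")[0, 1]
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    below = ties = 0
    for _ in range(n_rand):
        xa = draw_null_sample(rng, pool_idx, occ_w, abund_w, richness[i], totals[i], n_taxa)
        xb = draw_null_sample(rng, pool_idx, occ_w, abund_w, richness[j], totals[j], n_taxa)
        d = pairwise_dissimilarity(np.vstack([xa, xb]), "bray_curtis")[0, 1]
        if abs(d - obs) <= 1e-12:
            ties += 1
        elif d < obs:
            below += 1
    rc = (below + 0.5 * ties) / n_rand
    return 2.0 * rc - 1.0


def rc_bray(table: CommunityTable, pair: tuple[str, str], n_rand: int = 999, seed: int = 0) -> float:
    """Raup–Crick index on Bray–Curtis nulls, scaled to [-1, 1].

    Null samples preserve each member's richness and read total; the index
    is the (tie-corrected) fraction of null dissimilarities below the
    observed one, rescaled so 0 is the null expectation.
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99")
    counts = table.counts.to_numpy()
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    rng = np.random.default_rng(seed)
    return _rc_from_counts(counts, pos[pair[0]], pos[pair[1]], n_rand, rng)


def classify_processes(
    dataset: Dataset,
    group: str | None = None,
    n_rand: int = 999,
    seed: int = 0,
    bnti_threshold: float = BNTI_THRESHOLD,
    rc_threshold: float = RC_THRESHOLD,
) -> tuple[ProcessProfile, pd.DataFrame]:
    """Five-way process profile over all within-group sample pairs.

    Returns the profile (fractions over variable selection, homogeneous
    selection, dispersal limitation, homogenizing dispersal, undominated)
    and the per-pair table of βNTI, RC and assigned category.
    """
    from .io import harmonize

    if group is not None:
        sub = dataset.table.group_table(group)
        dataset = harmonize(sub, dataset.tree)
    table = dataset.table
    if table.n_samples < 2:
        raise ValueError("group needs >= 2 samples")
    ss = np.random.SeedSequence(seed)
    s_bnti, s_rc = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    df = beta_nti_matrix(dataset, n_rand=n_rand, seed=s_bnti, on_degenerate="nan")

    counts = table.counts.to_numpy()
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    rng = np.random.default_rng(s_rc)
    rcs, cats = [], []
    for _, row in df.iterrows():
        bnti = row["beta_nti"]
        # a degenerate (NaN) score shows no phylogenetic deviation; the
        # Raup-Crick step below decides the pair
        if np.isfinite(bnti) and bnti > bnti_threshold:
            rcs.append(np.nan)
            cats.append("variable_selection")
            continue
        if np.isfinite(bnti) and bnti < -bnti_threshold:
            rcs.append(np.nan)
            cats.append("homogeneous_selection")
            continue
        rc = _rc_from_counts(counts, pos[row["sample_a"]], pos[row["sample_b"]], n_rand, rng)
        rcs.append(rc)
        if rc > rc_threshold:
            cats.append("dispersal_limitation")
        elif rc < -rc_threshold:
            cats.append("homogenizing_dispersal")
        else:
            cats.append("undominated")
    df["rc_bray"] = rcs
    df["process"] = cats
    fractions = {p: cats.count(p) / len(cats) for p in PROCESSES}
    return ProcessProfile(group=group or "all", fractions=fractions, n_pairs=len(cats)), df
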