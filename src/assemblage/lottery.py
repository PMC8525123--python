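"""Competitive lottery analysis of genus-level ASV groups.

A genus group follows the competitive lottery schema when, sample by sample,
a single member ASV (the "winner") captures more than 90% of the group's
reads while the winner's identity varies between samples.  Winner prevalence
is compared against a stick-breaking (broken-stick) null on within-group
abundances; winner diversity summarizes how variable the winning identity is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CommunityTable

logger = logging.getLogger("assemblage")

__all__ = [
    "LotteryResult",
    "filter_groups",
    "winner_stats",
    "stickbreak_null",
    "stickbreak_win_probability",
    "lottery_analysis",
]


@dataclass
class LotteryResult:
    group_id: str
    n_member_asvs: int
    n_qualifying_samples: int
    winner_prevalence: float
    winner_diversity_normalized: float
    winner_effective_number: float
    winners: pd.Series = field(repr=False)  # sample -> winning ASV (or None)
    null_expected_prevalence: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.winner_prevalence <= 1.0:
            raise ValueError("prevalence out of [0, 1]")
        if not 0.0 <= self.winner_diversity_normalized <= 1.0 + 1e-12:
            raise ValueError("normalized diversity out of [0, 1]")
        if self.winner_effective_number > self.n_member_asvs + 1e-9:
            raise ValueError("effective number exceeds group size")


def filter_groups(
    table: CommunityTable,
    min_reads: int = 5000,
    min_abundance: float = 5e-4,
    min_asvs: int = 3,
) -> dict[str, list[str]]:
    """Genus groups passing the three exclusion rules.

    A genus is removed when its total reads fall below ``min_reads``, its
    overall relative abundance below ``min_abundance`` (0.05%), or its member
    ASV count below ``min_asvs``; each rule is independently configurable.
    """
    genera = table.genera()
    totals = table.counts.sum(axis=0)
    grand = totals.sum()
    groups: dict[str, list[str]] = {}
    for genus, members in genera.groupby(genera).groups.items():
        members = list(members)
        reads = totals[members].sum()
        if len(members) < min_asvs or reads < min_reads or reads / grand < min_abundance:
            continue
        groups[genus] = members
    if not groups:
        logger.warning("no genus group passed the lottery filters")
    return groups


def winner_stats(
    table: CommunityTable,
    members: list[str],
    group_id: str = "",
    winner_threshold: float = 0.9,
    min_group_reads: int = 1,
) -> LotteryResult:
    """Winner prevalence and winner diversity for one genus group.

    A qualifying sample has the group present at >= ``min_group_reads``; a
    winner is the member ASV holding more than ``winner_threshold`` of the
    group's reads there (at most one can exist for thresholds > 0.5).
    Winner diversity is the Shannon entropy of the winner-identity
    distribution over winner-bearing samples, reported both normalized by
    ln(group size) and as an effective number of winners exp(H).
    """
    if not 0.5 < winner_threshold <= 1.0:
        raise ValueError("winner_threshold must be in (0.5, 1]")
    sub = table.counts[members]
    group_total = sub.sum(axis=1)
    qualifying = group_total[group_total >= max(1, min_group_reads)].index
    winners = {}
    for s in qualifying:
        shares = sub.loc[s] / group_total[s]
        top = shares.idxmax()
        winners[s] = top if shares[top] > winner_threshold else None
    winners = pd.Series(winners, dtype=object)
    won = winners.dropna()
    prevalence = len(won) / len(qualifying) if len(qualifying) else 0.0
    if len(won):
        freq = won.value_counts(normalize=True).to_numpy()
        entropy = float(-np.sum(freq * np.log(freq)))
    else:
        entropy = 0.0
    return LotteryResult(
        group_id=group_id,
        n_member_asvs=len(members),
        n_qualifying_samples=len(qualifying),
        winner_prevalence=prevalence,
        winner_diversity_normalized=entropy / np.log(len(members)) if len(members) > 1 else 0.0,
        winner_effective_number=float(np.exp(entropy)),
        winners=winners,
    )


def stickbreak_win_probability(n_members: int, winner_threshold: float) -> float:
    """Closed-form per-sample win probability under the broken stick.

    For a uniform random partition of the unit interval into n fragments,
    P(max fragment > x) = n(1-x)^(n-1) for x >= 1/2.
    """
    if winner_threshold < 0.5:
        raise ValueError("closed form requires threshold >= 0.5")
    return n_members * (1.0 - winner_threshold) ** (n_members - 1)


def stickbreak_null(
    n_members: int,
    n_samples: int,
    winner_threshold: float = 0.9,
    n_sim: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null winner-prevalence distribution under stick-breaking abundances.

    Each simulated sample's within-group relative abundances are the fragment
    lengths from breaking the unit stick at n-1 uniform points; returns the
    ``n_sim`` simulated prevalences (fraction of samples whose largest
    fragment exceeds the threshold).
    """
    if n_members < 2:
        raise ValueError("n_members must be >= 2")
    rng = np.random.default_rng(seed)
    cuts = np.sort(rng.random((n_sim, n_samples, n_members - 1)), axis=-1)
    bounds = np.concatenate(
        [np.zeros((n_sim, n_samples, 1)), cuts, np.ones((n_sim, n_samples, 1))], axis=-1
    )
    fragments = np.diff(bounds, axis=-1)
    wins = fragments.max(axis=-1) > winner_threshold
    return wins.mean(axis=-1)


def lottery_analysis(
    table: CommunityTable,
    winner_threshold: float = 0.9,
    min_reads: int = 5000,
    min_abundance: float = 5e-4,
    min_asvs: int = 3,
    min_group_reads: int = 1,
    n_sim: int = 1000,
    seed: int = 0,
    per_group_label: str | None = None,
) -> pd.DataFrame:
    """Scatter-ready lottery table: one row per genus (per treatment).

    With ``per_group_label`` set to a metadata column (e.g. ``group``), the
    analysis is repeated within each treatment, as in the prevalence/
    diversity scatter; otherwise over all samples.
    """
    ss = np.random.SeedSequence(seed)
    tables = (
        [(g, table.group_table(g)) for g in table.groups()]
        if per_group_label == "group"
        else [("all", table)]
    )
    rows = []
    for (label, sub), child in zip(tables, ss.spawn(len(tables))):
        groups = filter_groups(sub, min_reads=min_reads, min_abundance=min_abundance, min_asvs=min_asvs)
        kids = child.spawn(len(groups))
        for (genus, members), k in zip(sorted(groups.items()), kids):
            res = winner_stats(
                sub, members, group_id=genus,
                winner_threshold=winner_threshold, min_group_reads=min_group_reads,
            )
            null = stickbreak_null(
                len(members), res.n_qualifying_samples or 1, winner_threshold,
                n_sim=n_sim, seed=int(k.generate_state(1)[0] % 2**31),
            )
            rows.append(
                {
                    "treatment": label,
                    "genus": genus,
                    "n_member_asvs": res.n_member_asvs,
                    "n_qualifying_samples": res.n_qualifying_samples,
                    "winner_prevalence": res.winner_prevalence,
                    "winner_diversity_normalized": res.winner_diversity_normalized,
                    "winner_effective_number": res.winner_effective_number,
                    "null_prevalence_mean": float(null.mean()),
                    "null_prevalence_q975": float(np.quantile(null, 0.975)),
                    "null_prevalence_q025": float(np.quantile(null, 0.025)),
                    "exceeds_null": res.winner_prevalence > float(np.quantile(null, 0.975)),
                }
            )
    return pd.DataFrame(rows)
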