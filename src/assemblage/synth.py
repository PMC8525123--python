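"""Synthetic community generator: ASV tables and trees under known regimes.

Datasets are generated under one of six assembly regimes — neutral,
homogeneous selection, variable selection, dispersal limitation, competitive
lottery, and dispersed (logistic-weighted) recruitment through time — so that
every downstream null model can be validated by recovering the regime it was
generated under.  The regional species-abundance distribution is log-normal;
selection acts on a Brownian-motion trait evolved along the tree, which gives
niche differences the phylogenetic signal that βNTI-style inference assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CommunityTable, Dataset, Phylogeny, harmonize, parse_newick

__all__ = [
    "REGIMES",
    "SyntheticTruth",
    "generate_tree",
    "assign_taxonomy",
    "brownian_trait",
    "clade_partition",
    "generate_regime_dataset",
    "generate_time_series",
    "study_design",
    "DEFAULT_GROUPS",
    "DEFAULT_DAYS",
]

REGIMES = (
    "neutral",
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limited",
    "lottery",
    "dispersed_recruitment",
)

#: the seven treatment groups and five sampling days of the microcosm design
DEFAULT_GROUPS = ("FSC", "WAF", "CEWAF", "BEWAF", "SWD", "SWBS", "SW")
DEFAULT_DAYS = (0, 3, 7, 14, 28)

#: default regime assignment used by :func:`study_design`, chosen so every
#: cross-sectional regime is exercised across the seven-group layout
DEFAULT_REGIME_MAP = {
    "FSC": "homogeneous_selection",
    "WAF": "neutral",
    "CEWAF": "variable_selection",
    "BEWAF": "lottery",
    "SWD": "homogeneous_selection",
    "SWBS": "dispersal_limited",
    "SW": "neutral",
}


@dataclass
class SyntheticTruth:
    """Generative regime and parameters attached to a simulated dataset."""

    regime: str
    seed: int
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def generate_tree(n_taxa: int, seed: int) -> Phylogeny:
    """Random rooted ultrametric tree from successive random pair merges.

    Lineages merge backward in time with exponential waiting times at rate k
    for k active lineages (a Yule-like, constant-speciation-through-time
    shape whose node depths are spread evenly, as in typical 16S
    phylogenies); all tips are equidistant from the root.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    lineages: list[tuple[str, float]] = [(f"ASV{i + 1:04d}", 0.0) for i in range(n_taxa)]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nwk_j, h_j) = lineages.pop(j)
        (nwk_i, h_i) = lineages.pop(i)
        merged = f"({nwk_i}:{t - h_i:.10f},{nwk_j}:{t - h_j:.10f})"
        lineages.append((merged, t))
    return parse_newick(lineages[0][0] + ";")


def clade_partition(tree: Phylogeny, max_size: int) -> list[list[str]]:
    """Partition tips into monophyletic clades of at most ``max_size`` tips."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")

    clades: list[list[str]] = []

    def visit(node):
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        if len(tips) <= max_size:
            clades.append(tips)
        else:
            for child in node.children:
                visit(child)

    visit(tree.tree)
    return clades


def assign_taxonomy(tree: Phylogeny, seed: int, genus_size: int = 5) -> pd.Series:
    """Clade-consistent taxonomy strings: one genus per small monophyletic clade."""
    clades = clade_partition(tree, genus_size)
    rows = {}
    for g, tips in enumerate(clades, start=1):
        genus = f"g__Genus{g:03d}"
        for tip in tips:
            rows[tip] = f"d__Bacteria;p__Synthetica;c__Simulata;o__Nullales;f__Modelaceae;{genus};s__"
    return pd.Series(rows, name="taxonomy").loc[tree.tip_names]


def brownian_trait(tree: Phylogeny, seed: int, rate: float = 1.0, delta: float = 1.0) -> pd.Series:
    """Brownian-motion trait on the tree (root value 0, variance ∝ length).

    ``delta`` applies Pagel's depth transform to the variance accumulated
    along each branch: node depths t (scaled to [0, 1]) become t^delta, so
    delta < 1 concentrates trait divergence near the root (niche
    conservatism: clades keep distinct trait values) and delta > 1 pushes it
    toward the tips.
    """
    rng = np.random.default_rng(seed)
    n = len(tree._length)
    depth = np.zeros(n)
    for i in range(n - 1, -1, -1):  # reversed postorder: parent before child
        p = tree._parent[i]
        if p >= 0:
            depth[i] = depth[p] + tree._length[i]
    height = depth.max() or 1.0
    t = depth / height
    val = np.zeros(n)
    for i in range(n - 1, -1, -1):
        p = tree._parent[i]
        if p >= 0:
            var = rate * height * max(t[i] ** delta - t[p] ** delta, 0.0)
            val[i] = val[p] + rng.normal(0.0, np.sqrt(var))
    traits = val[tree._tip_nodes]
    return pd.Series(traits, index=tree.tip_names, name="trait")


# ---------------------------------------------------------------------------
# regime datasets
# ---------------------------------------------------------------------------

def _lognormal_sad(n_taxa: int, rng, sigma: float) -> np.ndarray:
    sad = rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa)
    return sad / sad.sum()


def _sample_weights(regime, tree, sad, rng, params, n_samples, genera):
    """Per-sample taxon sampling weight matrix (n_samples x n_taxa) + truth extras."""
    n_taxa = tree.n_tips
    extras: dict = {}
    w = np.tile(sad, (n_samples, 1))
    if regime == "neutral":
        return w, extras

    if regime in ("homogeneous_selection", "variable_selection"):
        rate = params.get("trait_rate", 1.0)
        delta = params.get("trait_delta", 1.0)
        trait = brownian_trait(tree, seed=int(rng.integers(2**31)), rate=rate, delta=delta).to_numpy()
        niche_width = params.get("niche_width", 0.5)
        if regime == "homogeneous_selection":
            optimum = params.get("optimum")
            if optimum is None:
                # an occupied niche: the regionally dominant taxon's trait
                optimum = float(trait[int(np.argmax(sad))])
            env = np.full(n_samples, float(optimum))
        else:
            env = params.get("env")
            if env is None:
                gradient = params.get("gradient", 4.0) * np.std(trait)
                env = rng.uniform(-gradient, gradient, size=n_samples) + np.mean(trait)
            env = np.asarray(env, dtype=float)
            if len(env) != n_samples:
                raise ValueError("env must have one optimum per sample")
        fitness = np.exp(-((trait[None, :] - env[:, None]) ** 2) / (2.0 * niche_width**2))
        w = w * fitness
        # guard against a sample where every taxon is unfit (numerical zeros)
        dead = w.sum(axis=1) == 0
        if dead.any():
            best = np.argmin(np.abs(trait[None, :] - env[dead, None]), axis=1)
            w[np.flatnonzero(dead), best] = 1.0
        extras.update(env=env.tolist(), niche_width=niche_width)
        extras["trait"] = trait.tolist()
        return w, extras

    if regime == "dispersal_limited":
        # singleton clades by default: monophyletic pools read as variable
        # selection in nearest-taxon metrics (missing-sister effect)
        n_clades = params.get("n_clades", n_taxa)
        clade_fraction = params.get("clade_fraction", 0.5)
        clades = clade_partition(tree, max(1, int(np.ceil(n_taxa / n_clades))))
        order = {name: i for i, name in enumerate(tree.tip_names)}
        pool_map = []
        for s in range(n_samples):
            chosen = [c for c in range(len(clades)) if rng.random() < clade_fraction]
            if not chosen:
                chosen = [int(rng.integers(len(clades)))]
            mask = np.zeros(n_taxa, dtype=bool)
            for c in chosen:
                mask[[order[t] for t in clades[c]]] = True
            w[s, ~mask] = 0.0
            pool_map.append(chosen)
        extras.update(n_clades=len(clades), pool_map=pool_map)
        return w, extras

    if regime == "lottery":
        winner_fraction = params.get("winner_fraction", 0.95)
        genus_labels = genera.to_numpy()
        groups = params.get("lottery_genera")
        if groups is None:
            counts = pd.Series(genus_labels).value_counts()
            groups = list(counts.index[counts >= 3])
        if params.get("equalize_groups", True) and groups:
            # give lottery groups equal, dominant shares so group-level
            # counts are informative at finite depth
            grouped = np.isin(genus_labels, groups)
            share = 0.9 / len(groups)
            w2 = np.array(sad, dtype=float)
            for g in groups:
                m = genus_labels == g
                w2[m] = share * sad[m] / sad[m].sum()
            if (~grouped).any():
                w2[~grouped] = 0.1 * sad[~grouped] / sad[~grouped].sum()
            w = np.tile(w2, (n_samples, 1))
        winners = []
        for s in range(n_samples):
            row_winners = {}
            for g in groups:
                m = np.flatnonzero(genus_labels == g)
                win = int(rng.choice(m))
                gw = w[s, m].sum()
                others = m[m != win]
                rest = w[s, others].sum()
                w[s, win] = winner_fraction * gw
                if rest > 0:
                    w[s, others] *= (1.0 - winner_fraction) * gw / rest
                row_winners[g] = tree.tip_names[win]
            winners.append(row_winners)
        extras.update(winner_fraction=winner_fraction, lottery_genera=list(groups), winners=winners)
        return w, extras

    raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")


def generate_regime_dataset(
    tree: Phylogeny,
    regime: str,
    n_samples: int,
    depth: int,
    seed: int,
    group: str = "SYN",
    days=None,
    replicates=None,
    sad_sigma: float = 1.5,
    drift_sigma: float = 0.0,
    occupancy: float = 1.0,
    **params,
) -> tuple[Dataset, SyntheticTruth]:
    """Simulate an ASV table under an assembly regime on a given tree.

    Regional abundances are log-normal with shape ``sad_sigma`` (1.5 is
    uneven enough for a realistic rare tail while keeping the effective
    richness of desk-scale pools meaningful);
    per-sample taxon sampling weights are shaped by the regime (see module
    docstring), then modulated by two forms of ecological drift — log-normal
    abundance noise (``drift_sigma``, off by default) and independent
    per-sample presence thinning (``occupancy`` < 1 keeps each pool member
    with that probability, emulating stochastic colonization) — and counts
    are drawn multinomially at ``depth`` reads per sample.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    n_taxa = tree.n_tips
    sad = _lognormal_sad(n_taxa, rng, sad_sigma)
    taxonomy = assign_taxonomy(tree, seed=seed)
    genera = taxonomy.map(lambda t: t.split(";")[5])
    w, extras = _sample_weights(regime, tree, sad, rng, params, n_samples, genera)
    if drift_sigma > 0:
        w = w * rng.lognormal(0.0, drift_sigma, size=w.shape)
    if not 0.0 < occupancy <= 1.0:
        raise ValueError("occupancy must be in (0, 1]")
    if occupancy < 1.0:
        keep = rng.random(w.shape) < occupancy
        # never thin a sample to an empty community
        dead = (w * keep).sum(axis=1) == 0
        keep[dead] = True
        w = w * keep
    w = w / w.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, w[s]) for s in range(n_samples)])

    if days is None:
        days = [0] * n_samples
    if replicates is None:
        replicates = list(range(1, n_samples + 1))
    sample_ids = [f"{group}_d{d}_r{r}" for d, r in zip(days, replicates)]
    meta = pd.DataFrame(
        {"group": group, "day": list(days), "replicate": list(replicates)}, index=sample_ids
    )
    table = CommunityTable(
        pd.DataFrame(counts, index=sample_ids, columns=tree.tip_names), meta, taxonomy
    )
    truth = SyntheticTruth(
        regime=regime,
        seed=seed,
        parameters={"depth": depth, "sad_sigma": sad_sigma, "sad": sad.tolist(), **params, **extras},
    )
    return harmonize(table, tree), truth


# ---------------------------------------------------------------------------
# recruitment time series
# ---------------------------------------------------------------------------

def _day_grid(n_timepoints: int) -> list[int]:
    days = list(DEFAULT_DAYS)
    while len(days) < n_timepoints:
        days.append(days[-1] * 2)
    return days[:n_timepoints]


def recruitment_order(tree: Phylogeny, d_true: float, n_recruits: int, initial, rng):
    """Sequential recruitment with probability ∝ logistic(D * z_s).

    z_s is the standardized Faith-PD gain of adding candidate s to the
    current detected set.  Returns the ordered list of recruited tip names.
    """
    n_edges = len(tree._length)
    covered = np.zeros(n_edges, dtype=bool)
    for name in initial:
        covered[tree.tip_path_edges(name)] = True
    paths = {name: tree.tip_path_edges(name) for name in tree.tip_names}
    detected = set(initial)
    pool = [t for t in tree.tip_names if t not in detected]
    order = []
    for _ in range(n_recruits):
        gains = np.array(
            [tree._length[paths[t][~covered[paths[t]]]].sum() for t in pool]
        )
        sd = gains.std()
        z = (gains - gains.mean()) / sd if sd > 0 else np.zeros_like(gains)
        p = 1.0 / (1.0 + np.exp(-d_true * z))
        p = p / p.sum()
        pick = int(rng.choice(len(pool), p=p))
        name = pool.pop(pick)
        covered[paths[name]] = True
        order.append(name)
    return order


def generate_time_series(
    tree: Phylogeny,
    d_true: float,
    n_timepoints: int,
    recruits_per_step: int,
    seed: int,
    depth: int = 10_000,
    group: str = "SYN",
    initial_size: int | None = None,
    sad_sigma: float = 1.0,
) -> tuple[Dataset, SyntheticTruth]:
    """Longitudinal dataset with dispersion-controlled species recruitment.

    Starting from a random detected set, each later time point recruits
    ``recruits_per_step`` new taxa with probability ∝ logistic(D_true·z);
    D_true > 0 favours phylogenetically novel recruits (overdispersion),
    D_true < 0 close relatives (underdispersion), D_true = 0 is neutral.
    Each time point yields one sample over all detected taxa with log-normal
    regional abundances, multinomially sampled at ``depth``.
    """
    if n_timepoints < 3:
        raise ValueError("n_timepoints must be >= 3")
    n_taxa = tree.n_tips
    if initial_size is None:
        initial_size = max(2, n_taxa // 10)
    n_recruits = recruits_per_step * (n_timepoints - 1)
    if initial_size + n_recruits > n_taxa:
        raise ValueError("recruits_per_step x n_timepoints exceeds available taxa")
    rng = np.random.default_rng(seed)
    sad = _lognormal_sad(n_taxa, rng, sad_sigma)
    initial = list(rng.choice(tree.tip_names, size=initial_size, replace=False))
    order = recruitment_order(tree, d_true, n_recruits, initial, rng)

    days = _day_grid(n_timepoints)
    pos = {name: i for i, name in enumerate(tree.tip_names)}
    detected = list(initial)
    rows, meta_rows, ids = [], [], []
    for k, day in enumerate(days):
        if k > 0:
            detected += order[(k - 1) * recruits_per_step : k * recruits_per_step]
        wt = np.zeros(n_taxa)
        wt[[pos[t] for t in detected]] = sad[[pos[t] for t in detected]]
        wt = wt / wt.sum()
        rows.append(rng.multinomial(depth, wt))
        ids.append(f"{group}_d{day}_r1")
        meta_rows.append({"group": group, "day": day, "replicate": 1})
    table = CommunityTable(
        pd.DataFrame(np.vstack(rows), index=ids, columns=tree.tip_names),
        pd.DataFrame(meta_rows, index=ids),
        assign_taxonomy(tree, seed=seed),
    )
    truth = SyntheticTruth(
        regime="dispersed_recruitment",
        seed=seed,
        parameters={
            "d_true": d_true,
            "depth": depth,
            "initial": initial,
            "recruitment_order": order,
            "recruits_per_step": recruits_per_step,
        },
    )
    return harmonize(table, tree), truth


# ---------------------------------------------------------------------------
# full study design
# ---------------------------------------------------------------------------

def study_design(
    seed: int,
    n_taxa: int = 120,
    depth: int = 10_000,
    groups=DEFAULT_GROUPS,
    days=DEFAULT_DAYS,
    n_replicates: int = 3,
    regime_map: dict | None = None,
    **params,
) -> tuple[Dataset, dict[str, SyntheticTruth]]:
    """Simulate the full microcosm layout: 7 groups x 5 days x 3 replicates.

    All groups share one tree and taxonomy; each group's samples are drawn
    under its assigned regime (``regime_map``, defaulting to
    ``DEFAULT_REGIME_MAP``).  Returns the combined harmonized dataset and the
    per-group generative truth.
    """
    regime_map = dict(DEFAULT_REGIME_MAP if regime_map is None else regime_map)
    ss = np.random.SeedSequence(seed)
    tree_seed, *group_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(groups) + 1)]
    tree = generate_tree(n_taxa, seed=tree_seed)
    day_list = [d for d in days for _ in range(n_replicates)]
    rep_list = [r for _ in days for r in range(1, n_replicates + 1)]
    tables, truths = [], {}
    for g, gseed in zip(groups, group_seeds):
        regime = regime_map.get(g, "neutral")
        ds, truth = generate_regime_dataset(
            tree, regime, n_samples=len(day_list), depth=depth, seed=gseed,
            group=g, days=day_list, replicates=rep_list, **params,
        )
        tables.append(ds.table)
        truths[g] = truth
    counts = pd.concat([t.counts for t in tables])
    meta = pd.concat([t.metadata for t in tables])
    table = CommunityTable(counts, meta, tables[0].taxonomy)
    return harmonize(table, tree), truths
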