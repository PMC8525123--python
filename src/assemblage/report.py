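"""Run all six null models over one dataset and build the consensus table.

Each treatment group gets one qualitative verdict per model, using the
model's own thresholds (NST 0.5, two null standard deviations for the
Hill and beta-null comparisons, βNTI ±2 with RC ±0.95, the stick-breaking
97.5th percentile, the bootstrap interval for D), and every verdict cell
carries its underlying number.  All randomness flows from one master seed;
a model failure is recorded in the bundle without aborting the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import betanull, hillnull, lottery, nst, phylodisp, qpe
from .io import Dataset, harmonize

logger = logging.getLogger("assemblage")

__all__ = ["RunConfig", "RunBundle", "run_all", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "group_by": "group",
    "seed": 0,
    "nst": {"metric": "ruzicka", "algorithm": "PF", "n_rand": 1000},
    "hill": {"n_rand": 999, "q_max": 2.0, "q_step": 0.1},
    "betanull": {"metric": "generalized_unifrac", "n_rand": 999, "alpha": 0.5},
    "qpe": {"n_rand": 999},
    "lottery": {
        "winner_threshold": 0.9,
        "min_reads": 5000,
        "min_abundance": 5e-4,
        "min_asvs": 3,
        "n_sim": 1000,
    },
    "phylodisp": {"n_surrogates": 500, "n_bootstrap": 200},
}


def _merged(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


@dataclass
class RunBundle:
    config: dict
    results: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    consensus: pd.DataFrame | None = None


def _seeds(master: int, names):
    ss = np.random.SeedSequence(master)
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, ss.spawn(len(names)))}


def run_all(dataset: Dataset, config: dict | None = None) -> RunBundle:
    """Run every model on the dataset and assemble the consensus table."""
    cfg = _merged(config)
    seeds = _seeds(int(cfg["seed"]), ["nst", "hill", "betanull", "qpe", "lottery", "phylodisp"])
    bundle = RunBundle(config=cfg)
    table = dataset.table
    groups = table.groups()
    verdict: dict[str, dict[str, str]] = {g: {} for g in groups}

    # --- NST -------------------------------------------------------------
    try:
        c = cfg["nst"]
        res = nst.nst_by_group(table, metric=c["metric"], algorithm=c["algorithm"],
                               n_rand=c["n_rand"], seed=seeds["nst"])
        bundle.results["nst"] = res
        for _, row in res.iterrows():
            lean = "stochastic-leaning" if row["nst"] > 0.5 else "deterministic-leaning"
            verdict[row["group"]]["nst"] = f"{lean} ({row['nst_percent']:.0f}%)"
    except Exception as exc:  # model isolation: record and continue
        logger.exception("nst failed")
        bundle.errors["nst"] = str(exc)

    # --- Hill-number null -------------------------------------------------
    try:
        c = cfg["hill"]
        q_grid = np.arange(0.0, c["q_max"] + 1e-9, c["q_step"])
        frames = {}
        for g in groups:
            pairs = hillnull.consecutive_day_pairs(table, group=g)
            if not pairs:
                continue
            frames[g] = hillnull.qd_null_comparison(
                table.group_table(g), pairs, q_grid=q_grid, n_rand=c["n_rand"], seed=seeds["hill"]
            )
            within = np.abs(frames[g]["z"]) <= 2.0
            frac = float(within.mean())
            if frac >= 0.8:
                verdict[g]["hill"] = f"stochastic ({frac:.0%} of q within null)"
            else:
                above = (frames[g]["observed_mean"] > frames[g]["null_mean"]).mean() > 0.5
                verdict[g]["hill"] = (
                    f"deterministic {'divergence' if above else 'convergence'} "
                    f"({frac:.0%} of q within null)"
                )
        bundle.results["hill"] = frames
    except Exception as exc:
        logger.exception("hill failed")
        bundle.errors["hill"] = str(exc)

    # --- beta-null deviation ---------------------------------------------
    try:
        c = cfg["betanull"]
        rows = []
        for g in groups:
            sub = harmonize(table.group_table(g), dataset.tree)
            dev = betanull.null_deviation(sub, metric=c["metric"], n_rand=c["n_rand"],
                                          seed=seeds["betanull"], alpha=c["alpha"])
            traj = betanull.deviation_trajectory(dev, sub.table.metadata)
            traj.insert(0, "treatment", g)
            rows.append(traj)
            m = float(dev.condensed().mean())
            # effect-size cutoff: multinomial sampling alone produces small
            # negative deviations, so +/-0.05 is treated as neutral
            lean = "neutral" if abs(m) <= 0.05 else "niche"
            verdict[g]["betanull"] = f"{lean} (mean dev {m:+.3f})"
        bundle.results["betanull"] = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    except Exception as exc:
        logger.exception("betanull failed")
        bundle.errors["betanull"] = str(exc)

    # --- QPE --------------------------------------------------------------
    try:
        c = cfg["qpe"]
        profiles, pair_frames = [], []
        for g in groups:
            profile, pairs_df = qpe.classify_processes(dataset, group=g, n_rand=c["n_rand"],
                                                       seed=seeds["qpe"])
            pairs_df.insert(0, "treatment", g)
            pair_frames.append(pairs_df)
            profiles.append({"group": g, "n_pairs": profile.n_pairs, **profile.fractions})
            verdict[g]["qpe"] = f"{profile.modal} ({profile.fractions[profile.modal]:.0%})"
        bundle.results["qpe"] = pd.DataFrame(profiles)
        bundle.results["qpe_pairs"] = pd.concat(pair_frames, ignore_index=True)
    except Exception as exc:
        logger.exception("qpe failed")
        bundle.errors["qpe"] = str(exc)

    # --- lottery ----------------------------------------------------------
    try:
        c = cfg["lottery"]
        res = lottery.lottery_analysis(table, per_group_label="group", seed=seeds["lottery"], **c)
        bundle.results["lottery"] = res
        for g in groups:
            sub = res[res["treatment"] == g]
            # the lottery schema needs winners beyond the null AND varied
            # winner identity; a constant winner is dominance, not lottery
            lotto = sub["exceeds_null"] & (sub["winner_diversity_normalized"] > 0.25)
            n_win = int(lotto.sum()) if len(sub) else 0
            best = sub["winner_prevalence"].max() if len(sub) else float("nan")
            state = "lottery winners present" if n_win else "no lottery winners"
            verdict[g]["lottery"] = f"{state} ({n_win} genera, max prevalence {best:.2f})"
    except Exception as exc:
        logger.exception("lottery failed")
        bundle.errors["lottery"] = str(exc)

    # --- phylogenetic dispersion -----------------------------------------
    try:
        c = cfg["phylodisp"]
        fits = {}
        for g in groups:
            try:
                fit = phylodisp.fit_dispersion(dataset, group=g, n_surrogates=c["n_surrogates"],
                                               n_bootstrap=c["n_bootstrap"], seed=seeds["phylodisp"])
            except ValueError as exc:
                verdict[g]["phylodisp"] = f"not fitted ({exc})"
                continue
            fits[g] = fit
            lo, hi = fit.bootstrap_ci()
            if lo <= 0.0 <= hi:
                verdict[g]["phylodisp"] = f"neutral (D={fit.d_hat:+.2f})"
            else:
                kind = "over-dispersed" if fit.d_hat > 0 else "under-dispersed"
                verdict[g]["phylodisp"] = f"{kind} (D={fit.d_hat:+.2f})"
        bundle.results["phylodisp"] = fits
    except Exception as exc:
        logger.exception("phylodisp failed")
        bundle.errors["phylodisp"] = str(exc)

    bundle.consensus = pd.DataFrame(verdict).T.rename_axis("group")
    return bundle
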