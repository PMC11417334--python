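"""Scenario runner, group comparison, and power analysis.

:func:`run_scenario` executes one configured in-silico chimera experiment
end to end — chimera pool, tamoxifen labeling, follicle founding, daily
clone dynamics with optional DTX ablation, and per-follicle observation at
the configured days — and emits per-follicle clonality statistics plus
per-day summaries. :func:`compare_groups` is the rank-sum comparison used
for the per-panel group contrasts (exact enumeration at small n, normal
approximation with tie correction otherwise), and :func:`power_analysis`
maps the detectability of oligoclonal expansion across effect size and
cells-per-follicle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cassette import state_distribution
from .config import ScenarioConfig
from .cohort import (
    TZONE_FOLLICLE_ID,
    apply_labeling,
    found_follicles,
    sample_observation,
    simulate_chimera,
)
from .cohort import _ablate_once, _evolve_one_day, _recover  # shared primitives
from . import stats as cstats

__all__ = [
    "GroupComparison",
    "PowerCell",
    "ScenarioBundle",
    "run_scenario",
    "compare_groups",
    "power_analysis",
    "report",
]

EXACT_MAX_N = 12  # exact rank-sum enumeration when both groups are this small


@dataclass(frozen=True)
class GroupComparison:
    """Wilcoxon–Mann–Whitney comparison of two groups."""

    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    u_statistic: float
    p_value: float
    method: str  # exact | normal_approximation


@dataclass(frozen=True)
class PowerCell:
    """Detection power of the oligoclonality test at one grid point."""

    effect: float  # expansion concentration (small = strong skew)
    n_cells: int
    n_follicles: int
    power: float
    alpha: float


@dataclass
class ScenarioBundle:
    """Outputs of one scenario run: cells, per-follicle stats, day summaries."""

    config: ScenarioConfig
    cells: pd.DataFrame
    follicle_stats: pd.DataFrame
    day_summary: pd.DataFrame
    baseline: np.ndarray
    baseline_source: str


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Wilcoxon–Mann–Whitney U test.

    Small samples (both groups <= 12) use exact full enumeration over all
    C(n1+n2, n1) group assignments of the midranks; larger samples use the
    normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks under ties
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        # Exact two-sided p over all C(n1+n2, n1) midrank assignments,
        # counted by subset-sum dynamic programming (midranks doubled to ints).
        mean_u = n1 * n2 / 2
        d_obs = abs(u1 - mean_u)
        r2 = np.rint(ranks * 2).astype(int)
        max_s = int(r2.sum())
        ways = np.zeros((n1 + 1, max_s + 1))
        ways[0, 0] = 1.0
        for v in r2:
            prev = ways.copy()
            ways[1:, v:] = prev[1:, v:] + prev[:-1, : max_s + 1 - v]
        counts = ways[n1]
        sums = np.arange(max_s + 1) / 2.0
        u_vals = sums - n1 * (n1 + 1) / 2
        hits = counts[np.abs(u_vals - mean_u) >= d_obs - 1e-9].sum()
        p = float(hits / counts.sum())
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal_approximation"
    return GroupComparison(labels, (n1, n2), u1, min(p, 1.0), method)


def _scenario_baseline(config: ScenarioConfig, cells: pd.DataFrame):
    """Empirical pooled T-zone labeled frequencies, else the theoretical null."""
    copies = config.recombination.cassette_copies
    if len(cells):
        tz = cells[cells["compartment"] == "t_zone"]
        counts = cstats.table_to_counts(tz, copies)
        if counts.sum() >= config.min_cells:
            return counts / counts.sum(), "empirical_tzone"
    return state_distribution(config.recombination).labeled_baseline(), "theoretical"


def run_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Run one scenario: simulate, observe, and compute clonality statistics.

    Deterministic given the config (including its seed). Per observation day
    and follicle the bundle reports the labeled-cell (Confetti+) count,
    clonal dominance and clonal divergence; per day it reports the pooled
    labeling density and compartment means.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dose_days = set(config.dtx.dose_days(config.max_day)) if config.dtx else set()

    all_cells = []
    for mi in range(config.n_mice):
        mouse_id = f"m{mi + 1}"
        pop = simulate_chimera(
            config.marrow, config.pool_size, rng, mouse_id=mouse_id,
            tissue=config.tissue,
        )
        pop = apply_labeling(pop, config.recombination, rng)
        clones = found_follicles(pop, config, rng)
        dark_counter = [0]
        for day in range(0, config.max_day + 1):
            if day > 0:
                clones = _evolve_one_day(clones, config, rng, dark_counter)
            if day in dose_days:
                clones = _ablate_once(clones, config, rng)
                clones = _recover(clones, config, rng, config.homeostatic_target)
            if day in config.observation_days:
                all_cells.append(sample_observation(clones, config, day, rng))

    cells = (
        pd.concat(all_cells, ignore_index=True)
        if all_cells
        else pd.DataFrame(columns=_cell_columns())
    )
    baseline, baseline_source = _scenario_baseline(config, cells)
    follicle_stats = _follicle_stats(config, cells, baseline)
    day_summary = _day_summary(config, cells, follicle_stats)
    return ScenarioBundle(config, cells, follicle_stats, day_summary,
                          baseline, baseline_source)


def _cell_columns():
    from .cohort import CELL_COLUMNS

    return CELL_COLUMNS


def _follicle_stats(
    config: ScenarioConfig, cells: pd.DataFrame, baseline: np.ndarray
) -> pd.DataFrame:
    rows = []
    if not len(cells):
        return pd.DataFrame(
            columns=["day", "mouse_id", "compartment", "follicle_id", "n_cells",
                     "n_labeled", "labeling_density", "dominance", "divergence",
                     "below_threshold"]
        )
    copies = config.recombination.cassette_copies
    for (day, mouse, comp, fid), grp in cells.groupby(
        ["day", "mouse_id", "compartment", "follicle_id"], sort=True
    ):
        dens = cstats.labeling_density(grp)
        dom = cstats.clonal_dominance(grp, min_cells=config.min_cells,
                                      cassette_copies=copies)
        div = cstats.divergence_index(grp, baseline, min_cells=config.min_cells,
                                      cassette_copies=copies)
        rows.append(
            {
                "day": int(day),
                "mouse_id": mouse,
                "compartment": comp,
                "follicle_id": fid,
                "n_cells": len(grp),
                "n_labeled": dom.n_labeled,
                "labeling_density": dens.value,
                "dominance": dom.value,
                "divergence": div.value,
                "below_threshold": dom.below_threshold,
            }
        )
    return pd.DataFrame(rows)


def _day_summary(
    config: ScenarioConfig, cells: pd.DataFrame, follicle_stats: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    if not len(cells):
        return pd.DataFrame(
            columns=["day", "compartment", "n_follicles", "pooled_labeling_density",
                     "mean_labeled_count", "mean_labeled_count_labeled_follicles",
                     "mean_dominance", "mean_divergence"]
        )
    for (day, comp), grp in cells.groupby(["day", "compartment"], sort=True):
        fs = follicle_stats[
            (follicle_stats["day"] == day) & (follicle_stats["compartment"] == comp)
        ]
        labeled_counts = fs["n_labeled"]
        rows.append(
            {
                "day": int(day),
                "compartment": comp,
                "n_follicles": len(fs),
                "pooled_labeling_density": cstats.labeling_density(grp).value,
                "mean_labeled_count": float(labeled_counts.mean()),
                "mean_labeled_count_labeled_follicles": (
                    float(labeled_counts[labeled_counts > 0].mean())
                    if (labeled_counts > 0).any()
                    else 0.0
                ),
                "mean_dominance": float(fs["dominance"].dropna().mean())
                if fs["dominance"].notna().any() else float("nan"),
                "mean_divergence": float(fs["divergence"].dropna().mean())
                if fs["divergence"].notna().any() else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def power_analysis(
    base_config: ScenarioConfig,
    effect_grid: Sequence[float],
    n_grid: Sequence[int],
    reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    null_reps: int = 999,
) -> pd.DataFrame:
    """Power of :func:`~tfrtrace.stats.classify_expansion` across a grid.

    Each replicate simulates one follicle's labeled color counts under the
    clone-growth model collapsed to the color level: color proportions are
    Dirichlet-perturbed around the baseline with concentration
    ``effect * k`` (the polyclonal limit ``effect = inf`` reduces to the
    multinomial null), then ``n_cells`` cells are drawn and tested. Power is
    the fraction of replicates called oligoclonal at level ``alpha``.
    """
    if not len(effect_grid) or not len(n_grid):
        raise ValueError("effect_grid and n_grid must be non-empty")
    rng = np.random.default_rng(seed)
    baseline = state_distribution(base_config.recombination).labeled_baseline()
    k = baseline.size
    rows = []
    for effect in effect_grid:
        if not effect > 0:
            raise ValueError("effect (concentration) must be > 0")
        for n_cells in n_grid:
            hits = 0
            for _ in range(reps):
                if math.isinf(effect):
                    w = baseline
                else:
                    w = rng.dirichlet(effect * k * baseline)
                counts = rng.multinomial(int(n_cells), w)
                call = cstats.classify_expansion(
                    counts, baseline, reps=null_reps, alpha=alpha,
                    seed=int(rng.integers(2**31)), min_cells=1,
                    cassette_copies=base_config.recombination.cassette_copies,
                )
                hits += call.call == "oligoclonal"
            rows.append(
                {
                    "effect": float(effect),
                    "n_cells": int(n_cells),
                    "n_follicles": reps,
                    "power": hits / reps,
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)


def report(bundle: ScenarioBundle) -> tuple[str, dict]:
    """Human-readable summary and a machine-readable dict of a scenario run.

    Panels: per-day/compartment group means ± SD of counts, dominance and
    divergence, plus the pre/post rank-sum comparisons when more than one
    observation day exists. The dict serializes to stable JSON (sorted keys).
    """
    fs = bundle.follicle_stats
    panels: dict = {}
    lines = [
        f"scenario seed={bundle.config.seed} "
        f"baseline={bundle.baseline_source}",
    ]
    if len(fs):
        for (day, comp), grp in fs.groupby(["day", "compartment"], sort=True):
            key = f"day{day}_{comp}"
            vals = {
                "n_follicles": int(len(grp)),
                "labeled_count_mean": float(grp["n_labeled"].mean()),
                "labeled_count_sd": float(grp["n_labeled"].std(ddof=0)),
            }
            for col in ("dominance", "divergence", "labeling_density"):
                v = grp[col].dropna()
                vals[f"{col}_mean"] = float(v.mean()) if len(v) else None
                vals[f"{col}_sd"] = float(v.std(ddof=0)) if len(v) else None
            panels[key] = vals
            lines.append(
                f"  {key}: n={vals['n_follicles']} "
                f"labeled {vals['labeled_count_mean']:.2f}"
                f"±{vals['labeled_count_sd']:.2f}"
            )
        days = sorted(fs["day"].unique())
        comparisons: dict = {}
        if len(days) >= 2:
            first, last = days[0], days[-1]
            for comp in sorted(fs["compartment"].unique()):
                sel = fs[fs["compartment"] == comp]
                a = sel[sel["day"] == first]
                b = sel[sel["day"] == last]
                for col in ("n_labeled", "dominance", "divergence"):
                    va = a[col].dropna().to_numpy()
                    vb = b[col].dropna().to_numpy()
                    if len(va) and len(vb):
                        gc = compare_groups(va, vb, (f"day{first}", f"day{last}"))
                        comparisons[f"{comp}_{col}"] = {
                            "u": gc.u_statistic,
                            "p_value": gc.p_value,
                            "method": gc.method,
                            "n": list(gc.n_per_group),
                        }
            panels["comparisons"] = comparisons
    obj = {
        "seed": int(bundle.config.seed),
        "baseline_source": bundle.baseline_source,
        "baseline": [float(x) for x in bundle.baseline],
        "n_panels": len([k for k in panels if k != "comparisons"]),
        "panels": panels,
    }
    return "\n".join(lines), obj


def report_json(bundle: ScenarioBundle) -> str:
    """Stable JSON serialization of :func:`report`'s machine-readable output."""
    _, obj = report(bundle)
    return json.dumps(obj, sort_keys=True, indent=2)
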