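"""Seeded simulator of Confetti chimera experiments on the Treg/Tfr compartment.

The simulator follows the experimental chain: mixed bone-marrow chimerism
fixes the genotype composition of the FoxP3+ pool; a tamoxifen pulse labels
labelable cells by drawing an observable color state from the cassette
model; clones found follicles (and a per-mouse T-cell zone); clones grow by
Dirichlet-multinomial redistribution day by day up to a homeostatic carrying
capacity; labeled clones may "go dark" (be replaced by unlabeled cells) at a
per-day rate; a DTX schedule thins ablatable-origin cells with surviving
clones expanding back to the homeostatic target; and finally a per-follicle
observation samples a fixed number of cells without replacement, optionally
through a color misclassification matrix.

Cell populations and observation tables are pandas DataFrames with the
canonical column schema (see :mod:`tfrtrace.io`); clones are lightweight
dataclasses keyed by (mouse, compartment, follicle).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cassette import (
    UNLABELED,
    ObservableState,
    RecombinationModel,
    enumerate_observable_states,
    state_distribution,
)
from .config import MarrowMix, ScenarioConfig

__all__ = [
    "Clone",
    "UnderSeededWarning",
    "EmptyCompartmentWarning",
    "simulate_chimera",
    "apply_labeling",
    "found_follicles",
    "evolve_clones",
    "apply_ablation",
    "sample_observation",
]

CELL_COLUMNS = [
    "mouse_id", "tissue", "compartment", "follicle_id", "day",
    "origin_genotype", "foxp3", "state", "clone_id",
]

TZONE_FOLLICLE_ID = "TZ"


class UnderSeededWarning(UserWarning):
    """Fewer eligible cells than requested follicle founders."""


class EmptyCompartmentWarning(UserWarning):
    """Ablation removed every clone of a compartment with a positive target."""


@dataclass
class Clone:
    """A clonal unit: all cells share founder color state and origin genotype."""

    clone_id: str
    mouse_id: str
    compartment: str  # "follicle" | "t_zone"
    follicle_id: str
    founder_state: ObservableState
    origin_genotype: str
    size: int

    @property
    def labeled(self) -> bool:
        return self.founder_state.labeled


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_chimera(
    mix: MarrowMix,
    n_cells: int,
    seed: int | np.random.Generator,
    mouse_id: str = "m1",
    tissue: str = "spleen",
) -> pd.DataFrame:
    """Draw the pre-labeling FoxP3+ pool of one mouse from the marrow mix.

    Origin genotypes are multinomial in the donor/host fractions; every
    record is FoxP3+ (the simulator models the regulatory compartment only).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _rng(seed)
    fracs = mix.fractions()
    genotypes = list(fracs)
    counts = rng.multinomial(n_cells, [fracs[g] for g in genotypes])
    origin = np.repeat(genotypes, counts)
    rng.shuffle(origin)
    labelable = set(mix.labelable_genotypes())
    df = pd.DataFrame(
        {
            "mouse_id": mouse_id,
            "tissue": tissue,
            "compartment": "pool",
            "follicle_id": "",
            "day": 0,
            "origin_genotype": origin,
            "foxp3": True,
            "state": str(UNLABELED),
            "clone_id": "",
            "labelable": [g in labelable for g in origin],
        }
    )
    return df


def apply_labeling(
    population: pd.DataFrame,
    recombination: RecombinationModel,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Tamoxifen pulse: labelable FoxP3+ cells draw a state from the cassette model."""
    rng = _rng(seed)
    dist = state_distribution(recombination)
    states = np.array([str(s) for s in dist.states])
    probs = np.asarray(dist.probs)
    df = population.copy()
    mask = df["foxp3"].to_numpy() & df.get(
        "labelable", pd.Series(True, index=df.index)
    ).to_numpy()
    draws = rng.choice(len(states), size=int(mask.sum()), p=probs)
    col = df["state"].to_numpy(dtype=object)
    col[mask] = states[draws]
    df["state"] = col
    return df


def found_follicles(
    population: pd.DataFrame,
    config: ScenarioConfig,
    seed: int | np.random.Generator,
) -> list[Clone]:
    """Found follicle and T-zone clones by sampling cells without replacement.

    Per mouse, ``n_follicles * founders_per_follicle`` follicular founders and
    ``tzone_founders`` T-zone founders are drawn from that mouse's FoxP3+
    pool; founder color state and origin genotype are inherited and the
    initial clone size is 1. If the pool is smaller than requested, an
    :class:`UnderSeededWarning` is issued and founding uses what is available.
    """
    rng = _rng(seed)
    clones: list[Clone] = []
    for mouse_id, pool in population[population["foxp3"]].groupby("mouse_id", sort=True):
        need = config.n_follicles * config.founders_per_follicle + config.tzone_founders
        if need == 0:
            continue
        avail = len(pool)
        if avail < need:
            warnings.warn(
                f"mouse {mouse_id}: pool of {avail} FoxP3+ cells for {need} "
                "requested founders; founding with available pool",
                UnderSeededWarning,
                stacklevel=2,
            )
        take = min(need, avail)
        chosen = pool.iloc[rng.choice(avail, size=take, replace=False)]
        rows = list(chosen.itertuples(index=False))
        k = 0
        for fi in range(config.n_follicles):
            fid = f"F{fi + 1:03d}"
            for ci in range(config.founders_per_follicle):
                if k >= take:
                    break
                row = rows[k]
                k += 1
                clones.append(
                    Clone(
                        clone_id=f"{mouse_id}:{fid}:c{ci + 1:03d}",
                        mouse_id=str(mouse_id),
                        compartment="follicle",
                        follicle_id=fid,
                        founder_state=ObservableState.parse(row.state),
                        origin_genotype=row.origin_genotype,
                        size=1,
                    )
                )
        for ci in range(config.tzone_founders):
            if k >= take:
                break
            row = rows[k]
            k += 1
            clones.append(
                Clone(
                    clone_id=f"{mouse_id}:{TZONE_FOLLICLE_ID}:c{ci + 1:03d}",
                    mouse_id=str(mouse_id),
                    compartment="t_zone",
                    follicle_id=TZONE_FOLLICLE_ID,
                    founder_state=ObservableState.parse(row.state),
                    origin_genotype=row.origin_genotype,
                    size=1,
                )
            )
    return clones


def _redistribute(
    sizes: np.ndarray,
    new_total: int,
    concentration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Dirichlet-multinomial growth/redistribution step.

    Expected proportions equal the current proportions; finite concentration
    adds clone-level growth skew (small alpha => oligoclonal takeover),
    infinite concentration is plain proportional (multinomial) resampling.
    Clones of size 0 stay extinct.
    """
    total = int(sizes.sum())
    if total == 0 or new_total == 0:
        return np.zeros_like(sizes)
    props = sizes / total
    alive = props > 0
    if math.isinf(concentration):
        w = props
    else:
        w = np.zeros_like(props)
        w[alive] = rng.dirichlet(concentration * alive.sum() * props[alive])
    return rng.multinomial(new_total, w)


def _group_key(c: Clone) -> tuple[str, str, str]:
    return (c.mouse_id, c.compartment, c.follicle_id)


def _grouped(clones: Sequence[Clone]) -> dict[tuple, list[Clone]]:
    groups: dict[tuple, list[Clone]] = {}
    for c in clones:
        groups.setdefault(_group_key(c), []).append(c)
    return groups


def _copy(clones: Iterable[Clone]) -> list[Clone]:
    return [replace(c) for c in clones]


def _evolve_one_day(
    clones: list[Clone],
    config: ScenarioConfig,
    rng: np.random.Generator,
    dark_counter: list[int],
) -> list[Clone]:
    """Growth/redistribution toward the carrying capacity, then go-dark events."""
    out: list[Clone] = []
    for _, group in sorted(_grouped(clones).items()):
        sizes = np.array([c.size for c in group], dtype=int)
        total = int(sizes.sum())
        new_total = min(
            int(math.ceil(total * config.growth_rate)), config.homeostatic_target
        )
        new_total = max(new_total, min(total, config.homeostatic_target))
        new_sizes = _redistribute(
            sizes, new_total, config.expansion_concentration, rng
        )
        for c, s in zip(group, new_sizes):
            nc = replace(c, size=int(s))
            if (
                nc.labeled
                and nc.size > 0
                and config.go_dark_rate > 0
                and rng.random() < config.go_dark_rate
            ):
                dark_counter[0] += 1
                nc = replace(
                    nc,
                    founder_state=UNLABELED,
                    clone_id=f"{nc.clone_id}/dark{dark_counter[0]}",
                )
            out.append(nc)
    return out


def evolve_clones(
    clones: Sequence[Clone],
    config: ScenarioConfig,
    until_day: int,
    seed: int | np.random.Generator,
) -> dict[int, list[Clone]]:
    """Per-day clone-size snapshots from day 0 to ``until_day`` (inclusive).

    Each day, per compartment, clone sizes are redrawn multinomially around
    Dirichlet-perturbed previous proportions while the compartment grows
    toward ``homeostatic_target``; labeled clones are then independently
    replaced by unlabeled clones of equal size with probability
    ``go_dark_rate``. No DTX is applied here (see :func:`apply_ablation`).
    """
    if until_day < 0:
        raise ValueError("until_day must be >= 0")
    rng = _rng(seed)
    dark_counter = [0]
    current = _copy(clones)
    snapshots = {0: _copy(current)}
    for day in range(1, until_day + 1):
        current = _evolve_one_day(current, config, rng, dark_counter)
        snapshots[day] = _copy(current)
    return snapshots


def _ablate_once(
    clones: list[Clone], config: ScenarioConfig, rng: np.random.Generator
) -> list[Clone]:
    ablatable = config.marrow.ablatable_genotypes()
    eff = config.dtx.ablation_efficiency
    out = []
    for c in clones:
        if c.origin_genotype in ablatable and c.size > 0 and eff > 0:
            survivors = int(rng.binomial(c.size, 1.0 - eff))
            out.append(replace(c, size=survivors))
        else:
            out.append(replace(c))
    return out


def _recover(
    clones: list[Clone],
    config: ScenarioConfig,
    rng: np.random.Generator,
    target: int,
) -> list[Clone]:
    """Homeostatic expansion of survivors back to the compartment target."""
    out: list[Clone] = []
    for key, group in sorted(_grouped(clones).items()):
        sizes = np.array([c.size for c in group], dtype=int)
        if sizes.sum() == 0:
            if target > 0:
                warnings.warn(
                    f"compartment {key}: all clones ablated, left empty",
                    EmptyCompartmentWarning,
                    stacklevel=2,
                )
            out.extend(replace(c) for c in group)
            continue
        conc = (
            math.inf
            if config.expansion_mode == "proportional"
            else config.expansion_concentration
        )
        new_sizes = _redistribute(sizes, target, conc, rng)
        out.extend(replace(c, size=int(s)) for c, s in zip(group, new_sizes))
    return out


def apply_ablation(
    clones: Sequence[Clone],
    config: ScenarioConfig,
    seed: int | np.random.Generator,
    n_administrations: Optional[int] = None,
) -> list[Clone]:
    """Apply the configured DTX schedule, then restore compartment sizes.

    Each cell of DTX-ablatable origin is removed independently with
    probability ``ablation_efficiency`` per administration; surviving clones
    then expand back to ``homeostatic_target`` — proportionally to size
    (polyclonal mode) or Dirichlet-reweighted (oligoclonal mode).
    """
    if config.dtx is None:
        raise ValueError("no dtx schedule configured")
    rng = _rng(seed)
    if n_administrations is None:
        n_administrations = len(config.dtx.dose_days(config.max_day))
    current = _copy(clones)
    for _ in range(n_administrations):
        current = _ablate_once(current, config, rng)
    return _recover(current, config, rng, config.homeostatic_target)


def _misclassify(
    states: np.ndarray, matrix: np.ndarray, copies: int, rng: np.random.Generator
) -> np.ndarray:
    order = np.array([str(s) for s in enumerate_observable_states(copies)])
    index = {s: i for i, s in enumerate(order)}
    out = states.copy()
    for s, row_idx in index.items():
        mask = states == s
        n = int(mask.sum())
        if n:
            out[mask] = order[rng.choice(len(order), size=n, p=matrix[row_idx])]
    return out


def sample_observation(
    clones: Sequence[Clone],
    config: ScenarioConfig,
    day: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Sample cells per follicle without replacement into an observation table.

    Each follicle contributes ``min(cells_sampled_per_follicle, size)`` cells
    (the T-zone compartment is censused, serving as the empirical color
    baseline). Labeled states optionally pass through the misclassification
    matrix. Output rows are sorted by (mouse, tissue, follicle, clone).
    """
    rng = _rng(seed)
    records: list[dict] = []
    for key, group in sorted(_grouped(clones).items()):
        mouse_id, compartment, follicle_id = key
        sizes = np.array([c.size for c in group], dtype=int)
        total = int(sizes.sum())
        if total == 0:
            continue
        if compartment == "t_zone":
            k = total
        else:
            k = min(config.cells_sampled_per_follicle, total)
        # hypergeometric draw across clones = sample cells without replacement
        cell_owner = np.repeat(np.arange(len(group)), sizes)
        picked = rng.choice(total, size=k, replace=False)
        for idx in np.sort(cell_owner[picked]):
            c = group[idx]
            records.append(
                {
                    "mouse_id": c.mouse_id,
                    "tissue": config.tissue,
                    "compartment": c.compartment,
                    "follicle_id": c.follicle_id,
                    "day": day,
                    "origin_genotype": c.origin_genotype,
                    "foxp3": True,
                    "state": str(c.founder_state),
                    "clone_id": c.clone_id,
                }
            )
    df = pd.DataFrame.from_records(records, columns=CELL_COLUMNS)
    if len(df) and config.misclassification is not None:
        df["state"] = _misclassify(
            df["state"].to_numpy(dtype=object),
            config.misclassification,
            config.recombination.cassette_copies,
            rng,
        )
    df = df.sort_values(
        ["mouse_id", "tissue", "follicle_id", "clone_id"], kind="mergesort"
    ).reset_index(drop=True)
    return df
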