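"""Scenario configuration: marrow mixes, ablation schedules, sampling plans.

A :class:`ScenarioConfig` fully specifies one in-silico chimera experiment —
bone-marrow donor proportions, cassette recombination parameters, follicle
founding and growth, diphtheria-toxin (DTX) ablation with homeostatic
recovery, labeled-clone "go dark" replacement, and the per-follicle
observation plan. Seeds are mandatory: the whole pipeline is stochastic and
reproducibility is part of the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Any, Mapping, Optional, Sequence

import numpy as np

from .cassette import RecombinationModel, enumerate_observable_states

__all__ = [
    "Donor",
    "MarrowMix",
    "DtxSchedule",
    "ScenarioConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid or incomplete scenario configuration."""


@dataclass(frozen=True)
class Donor:
    """One bone-marrow donor compartment and its functional flags."""

    genotype_id: str
    parts: float
    confetti_labelable: bool = False
    dtx_ablatable: bool = False
    tfr_blocked: bool = False
    autoreactive_driver: bool = False

    def __post_init__(self) -> None:
        if self.parts <= 0:
            raise ConfigError(f"donor {self.genotype_id!r}: parts must be > 0")


@dataclass(frozen=True)
class MarrowMix:
    """Mixed bone-marrow chimera composition.

    Donor fractions are parts/Σparts scaled by (1 - host_fraction); the
    remainder is radio-resistant recipient-derived ("host") cells.
    """

    donors: tuple[Donor, ...]
    host_fraction: float = 0.0
    host_genotype: str = "host"
    host_labelable: bool = False

    def __post_init__(self) -> None:
        if not self.donors:
            raise ConfigError("marrow mix requires at least one donor")
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ConfigError("host_fraction must be in [0,1]")
        object.__setattr__(self, "donors", tuple(self.donors))

    def fractions(self) -> dict[str, float]:
        """Genotype → population fraction, including the host compartment."""
        total = sum(d.parts for d in self.donors)
        out = {
            d.genotype_id: d.parts / total * (1.0 - self.host_fraction)
            for d in self.donors
        }
        if self.host_fraction > 0:
            out[self.host_genotype] = self.host_fraction
        return out

    def labelable_genotypes(self) -> set[str]:
        out = {d.genotype_id for d in self.donors if d.confetti_labelable}
        if self.host_labelable and self.host_fraction > 0:
            out.add(self.host_genotype)
        return out

    def ablatable_genotypes(self) -> set[str]:
        return {d.genotype_id for d in self.donors if d.dtx_ablatable}


@dataclass(frozen=True)
class DtxSchedule:
    """Diphtheria-toxin administrations: start day, cadence, per-dose kill rate."""

    start_day: int
    every_k_days: int
    ablation_efficiency: float

    def __post_init__(self) -> None:
        if self.start_day < 0:
            raise ConfigError("dtx start_day must be >= 0")
        if self.every_k_days < 1:
            raise ConfigError("dtx every_k_days must be >= 1")
        if not 0.0 <= self.ablation_efficiency <= 1.0:
            raise ConfigError("ablation_efficiency must be in [0,1]")

    def dose_days(self, until_day: int) -> list[int]:
        return list(range(self.start_day, until_day + 1, self.every_k_days))


@dataclass
class ScenarioConfig:
    """Full in-silico experiment specification. See module docstring."""

    marrow: MarrowMix
    recombination: RecombinationModel
    seed: int
    n_mice: int = 1
    pool_size: int = 5000
    n_follicles: int = 20
    founders_per_follicle: int = 20
    tzone_founders: int = 60
    expansion_concentration: float = math.inf
    expansion_mode: str = "proportional"  # post-ablation recovery mode
    go_dark_rate: float = 0.0
    dtx: Optional[DtxSchedule] = None
    homeostatic_target: int = 100
    growth_rate: float = 2.0
    observation_days: tuple[int, ...] = (14,)
    cells_sampled_per_follicle: int = 30
    misclassification: Optional[np.ndarray] = None
    tissue: str = "spleen"
    min_cells: int = 5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        if not isinstance(self.seed, (int, np.integer)):
            problems.append("seed: required integer")
        for name in ("n_mice", "pool_size", "n_follicles", "founders_per_follicle",
                     "tzone_founders", "homeostatic_target",
                     "cells_sampled_per_follicle", "min_cells"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                problems.append(f"{name}: non-negative integer required, got {v!r}")
        if self.n_mice < 1:
            problems.append("n_mice: must be >= 1")
        if self.pool_size < 1:
            problems.append("pool_size: must be >= 1")
        if not (self.expansion_concentration > 0):
            problems.append("expansion_concentration: must be > 0")
        if self.expansion_mode not in ("proportional", "dirichlet"):
            problems.append("expansion_mode: must be 'proportional' or 'dirichlet'")
        if not 0.0 <= self.go_dark_rate <= 1.0:
            problems.append("go_dark_rate: must be in [0,1]")
        if self.growth_rate < 1.0:
            problems.append("growth_rate: must be >= 1")
        self.observation_days = tuple(int(d) for d in self.observation_days)
        if any(d < 0 for d in self.observation_days):
            problems.append("observation_days: days must be >= 0")
        if not self.observation_days:
            problems.append("observation_days: at least one day required")
        if self.misclassification is not None:
            m = np.asarray(self.misclassification, dtype=float)
            k = len(enumerate_observable_states(self.recombination.cassette_copies))
            if m.shape != (k, k):
                problems.append(f"misclassification: expected {k}x{k} matrix")
            elif (m < 0).any() or np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
                problems.append("misclassification: rows must be stochastic")
            else:
                self.misclassification = m
        if problems:
            raise ConfigError(
                "invalid scenario configuration: " + "; ".join(problems)
            )

    @property
    def max_day(self) -> int:
        return max(self.observation_days)

    # ---- dict round-trip (used by YAML/JSON I/O) --------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "marrow": {
                "donors": [
                    {
                        "genotype_id": don.genotype_id,
                        "parts": don.parts,
                        "confetti_labelable": don.confetti_labelable,
                        "dtx_ablatable": don.dtx_ablatable,
                        "tfr_blocked": don.tfr_blocked,
                        "autoreactive_driver": don.autoreactive_driver,
                    }
                    for don in self.marrow.donors
                ],
                "host_fraction": self.marrow.host_fraction,
                "host_genotype": self.marrow.host_genotype,
                "host_labelable": self.marrow.host_labelable,
            },
            "recombination": {
                "allele_recombination_prob": self.recombination.allele_recombination_prob,
                "outcome_probs": list(self.recombination.outcome_probs),
                "cassette_copies": self.recombination.cassette_copies,
            },
            "seed": int(self.seed),
            "n_mice": self.n_mice,
            "pool_size": self.pool_size,
            "n_follicles": self.n_follicles,
            "founders_per_follicle": self.founders_per_follicle,
            "tzone_founders": self.tzone_founders,
            "expansion_concentration": (
                "inf" if math.isinf(self.expansion_concentration)
                else self.expansion_concentration
            ),
            "expansion_mode": self.expansion_mode,
            "go_dark_rate": self.go_dark_rate,
            "homeostatic_target": self.homeostatic_target,
            "growth_rate": self.growth_rate,
            "observation_days": list(self.observation_days),
            "cells_sampled_per_follicle": self.cells_sampled_per_follicle,
            "tissue": self.tissue,
            "min_cells": self.min_cells,
        }
        if self.dtx is not None:
            d["dtx"] = {
                "start_day": self.dtx.start_day,
                "every_k_days": self.dtx.every_k_days,
                "ablation_efficiency": self.dtx.ablation_efficiency,
            }
        if self.misclassification is not None:
            d["misclassification"] = np.asarray(self.misclassification).tolist()
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ScenarioConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ConfigError("seed is mandatory in scenario configurations")
        for key in ("marrow", "recombination"):
            if key not in data:
                raise ConfigError(f"missing required section: {key!r}")

        m = dict(data["marrow"])
        donors = tuple(Donor(**dict(don)) for don in m.pop("donors", ()))
        try:
            marrow = MarrowMix(donors=donors, **m)
        except TypeError as exc:
            raise ConfigError(f"marrow: {exc}") from exc

        r = dict(data["recombination"])
        if "outcome_probs" in r:
            r["outcome_probs"] = tuple(r["outcome_probs"])
        try:
            recomb = RecombinationModel(**r)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"recombination: {exc}") from exc

        kwargs: dict[str, Any] = {"marrow": marrow, "recombination": recomb}
        if "dtx" in data and data["dtx"] is not None:
            try:
                kwargs["dtx"] = DtxSchedule(**dict(data["dtx"]))
            except TypeError as exc:
                raise ConfigError(f"dtx: {exc}") from exc
        if "misclassification" in data and data["misclassification"] is not None:
            kwargs["misclassification"] = np.asarray(
                data["misclassification"], dtype=float
            )
        ec = data.get("expansion_concentration")
        if ec is not None:
            kwargs["expansion_concentration"] = (
                math.inf if ec in ("inf", "Infinity") else float(ec)
            )
        if "observation_days" in data:
            kwargs["observation_days"] = tuple(data["observation_days"])
        passthrough = (
            "seed", "n_mice", "pool_size", "n_follicles", "founders_per_follicle",
            "tzone_founders", "expansion_mode", "go_dark_rate",
            "homeostatic_target", "growth_rate", "cells_sampled_per_follicle",
            "tissue", "min_cells",
        )
        for key in passthrough:
            if key in data:
                kwargs[key] = data[key]
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
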