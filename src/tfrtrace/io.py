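"""Cell-table and configuration I/O, plus packaged fixture generation.

Cell observation tables are plain CSV (gzip-transparent by file extension)
with a fixed header; color states are serialized canonically ("unlabeled",
"nGFP", "YFP+RFP" with fluorophores in canonical order) and normalized on
read. Scenario configurations are YAML or JSON, validated strictly: unknown
keys are errors (they are almost always typos) and a seed is mandatory.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .cassette import ObservableState, RecombinationModel
from .config import ConfigError, Donor, DtxSchedule, MarrowMix, ScenarioConfig
from .cohort import CELL_COLUMNS

__all__ = [
    "SchemaError",
    "read_cells",
    "write_cells",
    "load_config",
    "save_config",
    "make_fixtures",
    "fixture_config",
    "FIXTURE_NAMES",
]


class SchemaError(ValueError):
    """Cell-table header or value domain violation."""


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a cell observation table, validating schema and state strings.

    Missing schema columns raise :class:`SchemaError` naming them; invalid
    state strings raise with the offending value and line number. Unknown
    extra columns are preserved. State strings are normalized to canonical
    fluorophore order (e.g. "RFP+YFP" becomes "YFP+RFP").
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"mouse_id": str, "follicle_id": str,
                                  "clone_id": str, "state": str})
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    states = []
    for i, raw in enumerate(df["state"].astype(str)):
        try:
            states.append(str(ObservableState.parse(raw)))
        except ValueError as exc:
            # +2: header line plus 1-based indexing
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from exc
    df["state"] = states
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    if (df["day"] < 0).any():
        bad = df.index[df["day"] < 0][0]
        raise SchemaError(f"{path}: line {bad + 2}: negative day")
    df["foxp3"] = df["foxp3"].astype(bool)
    return df


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as CSV (schema columns first, extras preserved)."""
    path = Path(path)
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cannot write table missing columns: {missing}")
    extras = [c for c in cells.columns if c not in CELL_COLUMNS]
    out = cells[CELL_COLUMNS + extras]
    out.to_csv(path, index=False, lineterminator="\n")


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return ScenarioConfig.from_dict(data)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a configuration as YAML (or JSON by extension), sorted keys."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, sort_keys=True, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# Packaged fixtures: small, fast scenario configurations mirroring the three
# in-silico experiments (labeling waning via go-dark, stable polyclonal
# follicles, partial ablation with polyclonal vs oligoclonal recovery).
# ---------------------------------------------------------------------------

def _confetti_mix_one_third() -> dict:
    # 1 part autoreactive driver + 1 part ablatable + 1 part Confetti:
    # one-third of the Treg pool is labelable, up to two-thirds ablatable.
    return {
        "donors": [
            {"genotype_id": "driver_dtr", "parts": 1.0,
             "autoreactive_driver": True, "dtx_ablatable": True},
            {"genotype_id": "foxp3_dtr", "parts": 1.0, "dtx_ablatable": True},
            {"genotype_id": "foxp3_confetti", "parts": 1.0,
             "confetti_labelable": True},
        ],
        "host_fraction": 0.0,
    }


def _confetti_mix_two_thirds() -> dict:
    # 1 part driver + 2 parts Confetti: two-thirds labelable.
    return {
        "donors": [
            {"genotype_id": "driver", "parts": 1.0, "autoreactive_driver": True},
            {"genotype_id": "foxp3_confetti", "parts": 2.0,
             "confetti_labelable": True},
        ],
        "host_fraction": 0.0,
    }


_RECOMBINATION = {
    "allele_recombination_prob": 0.6,
    "outcome_probs": [0.25, 0.25, 0.25, 0.25],
    "cassette_copies": 2,
}

FIXTURE_NAMES = (
    "waning_godark",
    "baseline_polyclonal",
    "ablation_polyclonal",
    "ablation_oligoclonal",
)


def fixture_config(name: str, seed: int = 20240904) -> ScenarioConfig:
    """One of the packaged scenario configurations, by name.

    * ``waning_godark`` — monoclonally founded follicles with a per-day
      go-dark rate; pooled labeling density wanes across days 4/18/32 while
      still-labeled follicles keep their counts.
    * ``baseline_polyclonal`` — stable polyclonal follicles, no ablation.
    * ``ablation_polyclonal`` — DTX every 3 days on the two-thirds ablatable
      compartments with proportional homeostatic recovery.
    * ``ablation_oligoclonal`` — same schedule, but recovery skewed by a
      small Dirichlet concentration (few clones take over).
    """
    base: dict[str, Any] = {
        "recombination": dict(_RECOMBINATION),
        "seed": seed,
        "n_mice": 3,
        "pool_size": 4000,
        "homeostatic_target": 150,
        "growth_rate": 2.0,
        "cells_sampled_per_follicle": 40,
        "min_cells": 5,
    }
    if name == "waning_godark":
        data = {
            **base,
            "marrow": _confetti_mix_two_thirds(),
            # fast growth so monoclonal follicles are at carrying capacity
            # before the first observation; counts then depend on go-dark only
            "growth_rate": 4.0,
            "n_follicles": 40,
            "founders_per_follicle": 1,
            "tzone_founders": 80,
            "go_dark_rate": 0.05,
            "observation_days": [4, 18, 32],
        }
    elif name == "baseline_polyclonal":
        data = {
            **base,
            "marrow": _confetti_mix_two_thirds(),
            "n_follicles": 12,
            "founders_per_follicle": 25,
            "tzone_founders": 80,
            "observation_days": [4, 18, 32],
        }
    elif name == "ablation_polyclonal":
        data = {
            **base,
            "marrow": _confetti_mix_one_third(),
            "n_follicles": 12,
            "founders_per_follicle": 25,
            "tzone_founders": 80,
            "dtx": {"start_day": 4, "every_k_days": 3,
                    "ablation_efficiency": 0.6},
            "expansion_mode": "proportional",
            "observation_days": [3, 15],
        }
    elif name == "ablation_oligoclonal":
        data = {
            **base,
            "marrow": _confetti_mix_one_third(),
            "n_follicles": 12,
            "founders_per_follicle": 25,
            "tzone_founders": 80,
            "dtx": {"start_day": 4, "every_k_days": 3,
                    "ablation_efficiency": 0.6},
            "expansion_mode": "dirichlet",
            "expansion_concentration": 0.04,
            "observation_days": [3, 15],
        }
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return ScenarioConfig.from_dict(data)


def make_fixtures(out_dir: str | Path, seed: int = 20240904) -> dict[str, Path]:
    """Write the packaged scenario configs and small pre-simulated cell tables.

    Deterministic given ``seed``: repeated calls regenerate byte-identical
    files. Returns a name → config-path mapping.
    """
    from .pipeline import run_scenario  # deferred: avoid import cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in FIXTURE_NAMES:
        cfg = fixture_config(name, seed=seed)
        cfg_path = out_dir / f"{name}.yaml"
        save_config(cfg, cfg_path)
        bundle = run_scenario(cfg)
        # keep the cell tables small: first observation day only
        first_day = min(cfg.observation_days)
        cells = bundle.cells[bundle.cells["day"] == first_day]
        write_cells(cells, out_dir / f"{name}_cells_day{first_day}.csv")
        written[name] = cfg_path
    return written
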