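"""Generative model of Brainbow2.1 ("Confetti") cassette recombination.

A tamoxifen pulse gives each cassette copy one Bernoulli chance (probability
``r``) to recombine; a recombined copy commits to one of four fluorophores
(nGFP, YFP, RFP, mCFP) with probabilities ``p``. A cell carrying two copies
("Confetti homozygous") can therefore display an unlabeled state, one of 4
single colors, or one of 6 two-color combinations — ten distinguishable
labeled states in total. Two copies recombined to the *same* fluorophore are
indistinguishable from a single recombined copy, so they collapse onto the
same singleton state.

This module enumerates the observable states, computes their exact
probabilities in closed form, and builds baseline ("random") color
distributions used as the null for the clonal divergence index.
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Fluorophore",
    "ObservableState",
    "UNLABELED",
    "RecombinationModel",
    "StateDistribution",
    "enumerate_observable_states",
    "state_distribution",
    "baseline_from_counts",
    "labeled_fraction",
]


class Fluorophore(enum.IntEnum):
    """The four Brainbow2.1 fluorophores, in canonical order."""

    nGFP = 0
    YFP = 1
    RFP = 2
    mCFP = 3


FLUOROPHORES: tuple[Fluorophore, ...] = tuple(Fluorophore)


@dataclass(frozen=True)
class ObservableState:
    """An observable color state: unlabeled, or a set of 1-2 fluorophores.

    ``fluorophores`` is a tuple sorted in canonical fluorophore order; the
    empty tuple is the unlabeled state.
    """

    fluorophores: tuple[Fluorophore, ...]

    def __post_init__(self) -> None:
        fps = tuple(Fluorophore(f) for f in self.fluorophores)
        if len(set(fps)) != len(fps):
            raise ValueError(f"duplicate fluorophores in state: {fps}")
        if len(fps) > 2:
            raise ValueError("at most two fluorophores are distinguishable")
        object.__setattr__(self, "fluorophores", tuple(sorted(fps)))

    @property
    def labeled(self) -> bool:
        return bool(self.fluorophores)

    @classmethod
    def single(cls, f: Fluorophore) -> "ObservableState":
        return cls((f,))

    @classmethod
    def pair(cls, a: Fluorophore, b: Fluorophore) -> "ObservableState":
        return cls((a, b))

    def sort_key(self) -> tuple:
        # singletons before pairs, then lexicographic in fluorophore order
        return (len(self.fluorophores), self.fluorophores)

    def __str__(self) -> str:
        if not self.fluorophores:
            return "unlabeled"
        return "+".join(f.name for f in self.fluorophores)

    @classmethod
    def parse(cls, text: str) -> "ObservableState":
        """Parse a serialized state; fluorophore order is normalized."""
        s = text.strip()
        if s.lower() == "unlabeled":
            return UNLABELED
        parts = s.split("+")
        try:
            fps = tuple(Fluorophore[p.strip()] for p in parts)
        except KeyError as exc:
            raise ValueError(f"unknown state string: {text!r}") from exc
        return cls(fps)


UNLABELED = ObservableState(())


def enumerate_observable_states(cassette_copies: int) -> list[ObservableState]:
    """Ordered labeled states for a given cassette copy number.

    Two copies yield 4 singletons + 6 distinct pairs = 10 states; one copy
    yields the 4 singletons; zero copies yield nothing. Order is canonical:
    singletons in fluorophore order, then pairs lexicographically.
    """
    if cassette_copies not in (0, 1, 2):
        raise ValueError(
            f"cassette_copies must be 0, 1 or 2, got {cassette_copies!r}"
        )
    if cassette_copies == 0:
        return []
    singles = [ObservableState.single(f) for f in FLUOROPHORES]
    if cassette_copies == 1:
        return singles
    pairs = [
        ObservableState.pair(a, b)
        for a, b in itertools.combinations(FLUOROPHORES, 2)
    ]
    return singles + pairs


@dataclass(frozen=True)
class RecombinationModel:
    """Per-copy recombination probability and fluorophore outcome probabilities.

    Parameters
    ----------
    allele_recombination_prob : float
        Probability ``r`` that one cassette copy recombines during the pulse.
    outcome_probs : sequence of 4 floats
        Probability ``p`` of each fluorophore conditional on recombination,
        ordered (nGFP, YFP, RFP, mCFP). Default uniform.
    cassette_copies : int
        1 (hemizygous) or 2 (homozygous).
    """

    allele_recombination_prob: float
    outcome_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cassette_copies: int = 2

    def __post_init__(self) -> None:
        r = self.allele_recombination_prob
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"allele_recombination_prob must be in [0,1], got {r}")
        p = tuple(float(x) for x in self.outcome_probs)
        if len(p) != 4:
            raise ValueError("outcome_probs must have length 4")
        if any(x < 0 for x in p):
            raise ValueError("outcome_probs must be non-negative")
        if abs(sum(p) - 1.0) > 1e-12:
            raise ValueError(f"outcome_probs must sum to 1, got {sum(p)}")
        if self.cassette_copies not in (1, 2):
            raise ValueError("cassette_copies must be 1 or 2")
        object.__setattr__(self, "outcome_probs", p)


@dataclass(frozen=True)
class StateDistribution:
    """Probability over {unlabeled} ∪ labeled states, in canonical order."""

    states: tuple[ObservableState, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.probs):
            raise ValueError("states and probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {sum(self.probs)}")

    def probability(self, state: ObservableState) -> float:
        try:
            return self.probs[self.states.index(state)]
        except ValueError:
            return 0.0

    @property
    def p_labeled(self) -> float:
        return sum(p for s, p in zip(self.states, self.probs) if s.labeled)

    def labeled_states(self) -> list[ObservableState]:
        return [s for s in self.states if s.labeled]

    def labeled_baseline(self) -> np.ndarray:
        """Renormalized probabilities over labeled states (the divergence null)."""
        labeled = np.array(
            [p for s, p in zip(self.states, self.probs) if s.labeled], dtype=float
        )
        total = labeled.sum()
        if total <= 0:
            raise ValueError("no labeled probability mass to condition on")
        return labeled / total

    def to_json(self) -> str:
        return json.dumps(
            {str(s): p for s, p in zip(self.states, self.probs)}, sort_keys=True
        )

    @classmethod
    def from_mapping(
        cls, probs: Mapping[ObservableState, float]
    ) -> "StateDistribution":
        states = sorted(probs, key=lambda s: s.sort_key())
        return cls(tuple(states), tuple(float(probs[s]) for s in states))


def state_distribution(model: RecombinationModel) -> StateDistribution:
    """Closed-form observable-state distribution for independent cassette copies.

    For two copies with per-copy recombination probability ``r`` and outcome
    probabilities ``p``::

        P(unlabeled)   = (1 - r)^2
        P(single a)    = 2 r (1-r) p_a + r^2 p_a^2
        P(pair {a,b})  = 2 r^2 p_a p_b          (a != b)

    For one copy: ``P(unlabeled) = 1 - r``, ``P(single a) = r p_a``.
    """
    r = model.allele_recombination_prob
    p = np.asarray(model.outcome_probs, dtype=float)
    out: dict[ObservableState, float] = {}
    if model.cassette_copies == 1:
        out[UNLABELED] = 1.0 - r
        for i, f in enumerate(FLUOROPHORES):
            out[ObservableState.single(f)] = r * p[i]
    else:
        out[UNLABELED] = (1.0 - r) ** 2
        for i, f in enumerate(FLUOROPHORES):
            out[ObservableState.single(f)] = 2 * r * (1 - r) * p[i] + r**2 * p[i] ** 2
        for (i, a), (j, b) in itertools.combinations(enumerate(FLUOROPHORES), 2):
            out[ObservableState.pair(a, b)] = 2 * r**2 * p[i] * p[j]
    # guard against tiny negative round-off
    total = sum(out.values())
    return StateDistribution.from_mapping({s: v / total for s, v in out.items()})


def labeled_fraction(model: RecombinationModel) -> float:
    """P(labeled) = 1 - (1-r)^copies."""
    return 1.0 - (1.0 - model.allele_recombination_prob) ** model.cassette_copies


def baseline_from_counts(
    labeled_state_counts: Mapping[ObservableState | str, float],
    cassette_copies: int = 2,
) -> np.ndarray:
    """Empirical baseline: renormalized labeled-state frequencies.

    Returns a probability vector over the canonical labeled-state order for
    ``cassette_copies``; states absent from the mapping get 0.
    """
    order = enumerate_observable_states(cassette_copies)
    index = {s: i for i, s in enumerate(order)}
    vec = np.zeros(len(order))
    for key, count in labeled_state_counts.items():
        state = ObservableState.parse(key) if isinstance(key, str) else key
        if not state.labeled:
            raise ValueError("baseline counts must be over labeled states")
        if state not in index:
            raise ValueError(f"state {state} invalid for {cassette_copies} copies")
        if count < 0:
            raise ValueError(f"negative count for state {state}: {count}")
        vec[index[state]] += count
    total = vec.sum()
    if total <= 0:
        raise ValueError("empty input: total labeled count must be >= 1")
    return vec / total
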