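"""Input-conditioned chemical reaction networks and truncated CME generators.

A reaction network is a set of ``m`` molecular species coupled through ``K``
mass-action reactions.  Reaction ``k`` fires in state ``x`` with propensity

    a_k(x) = theta_k * prod_i C(x_i, nu'_ik),

where ``theta_k`` may depend on a discrete input label and (piecewise
constantly) on time, and ``C`` is the binomial coefficient counting the ways
of picking the required reactant molecules.  The probability vector over
integer states evolves under the chemical master equation ``p' = M p``; on a
finite truncation of the state space ``M`` is an ordinary sparse matrix whose
column ``x`` holds the outflow rates of state ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from scipy.special import comb

__all__ = [
    "RateSchedule",
    "Reaction",
    "ReactionNetwork",
    "InputEnsemble",
    "StateSpace",
    "propensity",
    "build_generator",
]


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant-in-time rate constant for one reaction and input.

    ``values[i]`` applies on ``[breakpoints[i-1], breakpoints[i])`` with the
    convention ``breakpoints[-1] = +inf``; a constant rate has no breakpoints.
    The schedule is right-continuous: at a breakpoint the new rate applies.
    """

    values: tuple[float, ...]
    breakpoints: tuple[float, ...] = ()

    def __post_init__(self):
        if len(self.values) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one rate value per time segment")
        if any(v < 0 for v in self.values):
            raise ValueError("rates must be non-negative")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def constant(cls, value: float) -> "RateSchedule":
        return cls(values=(float(value),))

    def at(self, t: float) -> float:
        i = int(np.searchsorted(self.breakpoints, t, side="right"))
        return self.values[i]


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction with per-input piecewise-constant rates."""

    reactant_coeffs: tuple[int, ...]
    product_coeffs: tuple[int, ...]
    rates: dict  # input label -> RateSchedule

    def __post_init__(self):
        if len(self.reactant_coeffs) != len(self.product_coeffs):
            raise ValueError("reactant and product coefficient lengths differ")
        if any(c < 0 or int(c) != c for c in self.reactant_coeffs + self.product_coeffs):
            raise ValueError("stoichiometric coefficients must be non-negative integers")

    @property
    def change_vector(self) -> tuple[int, ...]:
        return tuple(p - r for r, p in zip(self.reactant_coeffs, self.product_coeffs))

    def rate_at(self, label, t: float) -> float:
        return self.rates[label].at(t)


class ReactionNetwork:
    """Chemical reaction network whose rate constants depend on a discrete input.

    Parameters
    ----------
    species_names
        Identifiers for the ``m`` species.
    reactions
        The ``K`` :class:`Reaction` entries.  Every reaction must define a
        rate schedule for every input label it is ever evaluated at.
    """

    def __init__(self, species_names: Sequence[str], reactions: Sequence[Reaction]):
        self.species_names = list(species_names)
        self.reactions = list(reactions)
        m = len(self.species_names)
        for rx in self.reactions:
            if len(rx.reactant_coeffs) != m:
                raise ValueError("reaction arity does not match species count")
        self.change_vectors = np.array(
            [rx.change_vector for rx in self.reactions], dtype=np.int64
        )

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def labels(self) -> list:
        out = []
        for rx in self.reactions:
            for lab in rx.rates:
                if lab not in out:
                    out.append(lab)
        return out

    def breakpoints(self, label) -> np.ndarray:
        """Union of rate-schedule breakpoints for one input label."""
        bps: set[float] = set()
        for rx in self.reactions:
            bps.update(rx.rates[label].breakpoints)
        return np.array(sorted(bps))

    def propensities(self, state: np.ndarray, label, t: float) -> np.ndarray:
        state = np.asarray(state)
        if np.any(state < 0):
            raise ValueError(f"invalid state with negative component: {state}")
        out = np.empty(self.n_reactions)
        for k, rx in enumerate(self.reactions):
            g = 1.0
            for xi, nu in zip(state, rx.reactant_coeffs):
                if nu:
                    if xi < nu:
                        g = 0.0
                        break
                    g *= comb(xi, nu, exact=True)
            out[k] = rx.rate_at(label, t) * g
        return out


def propensity(network: ReactionNetwork, k: int, state, label, t: float) -> float:
    """Mass-action propensity of reaction ``k`` in ``state`` at time ``t``."""
    return float(network.propensities(np.asarray(state), label, t)[k])


@dataclass
class InputEnsemble:
    """Discrete input alphabet ``u^(1)..u^(q)`` with prior ``p_U`` (default uniform)."""

    labels: list
    prior: np.ndarray | None = None

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("need at least two input labels")
        if self.prior is None:
            self.prior = np.full(len(self.labels), 1.0 / len(self.labels))
        self.prior = np.asarray(self.prior, dtype=float)
        if self.prior.shape != (len(self.labels),):
            raise ValueError("prior length must match number of labels")
        if np.any(self.prior < 0) or abs(self.prior.sum() - 1.0) > 1e-12:
            raise ValueError("prior must be a probability vector")

    @property
    def q(self) -> int:
        return len(self.labels)

    def index(self, label) -> int:
        return self.labels.index(label)


class StateSpace:
    """Finite rectangular truncation of the integer state lattice.

    For a single species this is ``{0, ..., X_max}``.  The truncation is an
    implementation necessity: the CME generator is in principle infinite
    dimensional and is cut off where the stationary occupancy is negligible.
    """

    def __init__(self, caps: Sequence[int]):
        self.caps = tuple(int(c) for c in caps)
        if any(c < 0 for c in self.caps):
            raise ValueError("state caps must be non-negative")
        self._states = np.array(
            list(product(*[range(c + 1) for c in self.caps])), dtype=np.int64
        )
        self._index = {tuple(s): i for i, s in enumerate(self._states)}

    @property
    def n_states(self) -> int:
        return len(self._states)

    @property
    def states(self) -> np.ndarray:
        return self._states

    def index_of(self, state) -> int:
        return self._index[tuple(int(v) for v in np.atleast_1d(state))]

    def contains(self, state) -> bool:
        return tuple(int(v) for v in np.atleast_1d(state)) in self._index

    @classmethod
    def single_species(cls, x_max: int) -> "StateSpace":
        return cls([x_max])


def default_state_space(
    network: ReactionNetwork,
    ensemble: InputEnsemble,
    x0: int,
    floor_margin: int = 20,
    tail_sds: float = 10.0,
) -> StateSpace:
    """Heuristic truncation for single-species networks.

    The cap is ``ceil(mu) + tail_sds * sqrt(mu)`` where ``mu`` is the largest
    drift-balance point ``sum_k a_k(x) nu_k = 0`` over inputs and rate
    segments (for a birth-death process this is the steady-state mean
    ``alpha/beta``, whose stationary law is Poisson so the tail mass beyond
    ten standard deviations is negligible), with a floor of ``x0 + 20``.
    """
    if network.n_species != 1:
        raise ValueError("default truncation heuristic only supports one species")
    mu_max = 0.0
    probe = np.arange(0, 100000)
    for label in ensemble.labels:
        times = np.concatenate([[0.0], network.breakpoints(label) + 1e-9])
        for t in times:
            # drift at state x for a 1-species mass-action network
            drift = np.zeros_like(probe, dtype=float)
            for rx in network.reactions:
                nu = rx.change_vector[0]
                nup = rx.reactant_coeffs[0]
                g = comb(probe, nup, exact=False)
                drift += rx.rate_at(label, t) * g * nu
            above = np.nonzero(drift < 0)[0]
            mu = float(above[0]) if len(above) else float(probe[-1])
            mu_max = max(mu_max, mu)
    cap = int(np.ceil(mu_max) + np.ceil(tail_sds * np.sqrt(max(mu_max, 1.0))))
    cap = max(cap, int(x0) + floor_margin)
    return StateSpace.single_species(cap)


def build_generator(
    network: ReactionNetwork,
    label,
    t: float,
    space: StateSpace,
) -> tuple[np.ndarray, np.ndarray]:
    """Truncated CME generator ``M`` at time ``t`` for one input label.

    Columns follow the master-equation convention ``p' = M p``:
    ``M[x', x]`` is the rate from state ``x`` into ``x'`` and the diagonal
    carries the negative total outflow.  Transitions that leave the truncated
    space are dropped; their total rate per boundary state is returned as the
    leak diagnostic vector (indexed like the states).
    """
    n = space.n_states
    if n == 0:
        raise ValueError("empty state space")
    M = np.zeros((n, n))
    leak = np.zeros(n)
    for j, state in enumerate(space.states):
        a = network.propensities(state, label, t)
        if np.any(a < 0):
            raise ValueError("negative propensity encountered")
        M[j, j] = -a.sum()
        for k in range(network.n_reactions):
            if a[k] == 0.0:
                continue
            target = state + network.change_vectors[k]
            if np.any(target < 0) or not space.contains(target):
                leak[j] += a[k]
                # outflow stays on the diagonal so dwell times remain exact;
                # the escaping probability mass is simply lost (sub-stochastic)
                continue
            M[space.index_of(target), j] += a[k]
    return M, leak
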