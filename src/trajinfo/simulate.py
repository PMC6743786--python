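"""Exact stochastic simulation (Gillespie / SSA) and trajectory containers.

Continuous trajectories are event lists: the visited states and the dwell
time spent in each, covering ``[0, T]``.  Discrete trajectories are the same
paths read out on a uniform grid of ``d`` time points, mimicking sampled
experimental time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork

__all__ = [
    "ContinuousTrajectory",
    "DiscreteTrajectory",
    "ssa_simulate",
    "simulate_dataset",
    "resample_discrete",
]


@dataclass
class ContinuousTrajectory:
    """Event-list representation of one sample path on ``[0, T]``.

    ``states[i]`` (shape ``(r, m)``) is occupied for ``dwell_times[i]``;
    dwell times sum to the horizon ``T``.
    """

    input_label: object
    states: np.ndarray
    dwell_times: np.ndarray
    horizon: float

    def __post_init__(self):
        self.states = np.atleast_2d(np.asarray(self.states, dtype=np.int64))
        self.dwell_times = np.asarray(self.dwell_times, dtype=float)
        if len(self.states) != len(self.dwell_times):
            raise ValueError("states and dwell_times length mismatch")
        if np.any(self.dwell_times <= 0):
            raise ValueError("dwell times must be positive")
        if abs(self.dwell_times.sum() - self.horizon) > 1e-9 * max(1.0, self.horizon):
            raise ValueError("dwell times do not sum to the horizon")

    @property
    def initial_state(self) -> np.ndarray:
        return self.states[0]

    @property
    def n_events(self) -> int:
        return len(self.states) - 1

    def jump_times(self) -> np.ndarray:
        """Times of the ``r - 1`` state changes."""
        return np.cumsum(self.dwell_times)[:-1]

    def truncated(self, horizon: float) -> "ContinuousTrajectory":
        """The same path restricted to ``[0, horizon]``."""
        if not 0 < horizon <= self.horizon:
            raise ValueError("horizon must lie in (0, T]")
        ends = np.cumsum(self.dwell_times)
        r = int(np.searchsorted(ends, horizon, side="left")) + 1
        dwell = self.dwell_times[:r].copy()
        dwell[-1] -= ends[r - 1] - horizon
        return ContinuousTrajectory(self.input_label, self.states[:r], dwell, horizon)


@dataclass
class DiscreteTrajectory:
    """A path sampled at ``i * dt`` for ``i = 1..d`` plus the known ``x0``."""

    input_label: object
    x0: np.ndarray
    values: np.ndarray  # shape (d, m) or (d,) for one species
    dt: float

    def __post_init__(self):
        self.x0 = np.atleast_1d(np.asarray(self.x0))
        self.values = np.asarray(self.values)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if len(self.values) < 1:
            raise ValueError("need d >= 1 sampled values")

    @property
    def d(self) -> int:
        return len(self.values)

    @property
    def horizon(self) -> float:
        return self.d * self.dt


def ssa_simulate(
    network: ReactionNetwork,
    label,
    x0,
    T: float,
    rng,
) -> ContinuousTrajectory:
    """Draw one exact sample path of the network under input ``label``.

    Piecewise-constant rate schedules are handled exactly: when a proposed
    exponential dwell overshoots the next rate breakpoint, the clock advances
    to the breakpoint and the dwell is re-drawn under the new rates, which is
    valid by the memoryless property of the exponential distribution.
    ``rng`` is a :class:`numpy.random.Generator`; identical generator state
    yields identical paths.
    """
    if T <= 0:
        raise ValueError("horizon T must be positive")
    x = np.atleast_1d(np.asarray(x0, dtype=np.int64)).copy()
    if np.any(x < 0):
        raise ValueError("initial state must be non-negative")
    rng = np.random.default_rng(rng)

    bps = network.breakpoints(label)
    bps = bps[(bps > 0) & (bps < T)]
    seg_ends = np.concatenate([bps, [T]])

    states = [x.copy()]
    dwells = []
    t = 0.0
    seg = 0
    t_entered = 0.0  # time the current state was entered
    while t < T:
        a = network.propensities(x, label, t)
        a0 = a.sum()
        if not np.isfinite(a0):
            raise OverflowError("infinite total propensity in SSA")
        seg_end = seg_ends[seg]
        if a0 == 0.0:
            proposed = np.inf
        else:
            proposed = t + rng.exponential(1.0 / a0)
        if proposed >= seg_end:
            # no event in the remainder of this rate segment
            t = seg_end
            seg += 1
            if t >= T:
                break
            continue
        # jump at `proposed`; categorical draw by inverse CDF
        k = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
        k = min(k, len(a) - 1)
        dwells.append(proposed - t_entered)
        x = x + network.change_vectors[k]
        if np.any(x < 0):
            raise RuntimeError("reaction drove a species count negative")
        states.append(x.copy())
        t = proposed
        t_entered = proposed
    dwells.append(T - t_entered)
    return ContinuousTrajectory(label, np.array(states), np.array(dwells), T)


def simulate_dataset(
    network: ReactionNetwork,
    labels,
    x0,
    T: float,
    n_per_label: int,
    seed,
    network_sampler=None,
) -> list[ContinuousTrajectory]:
    """Simulate ``n_per_label`` paths for every label, reproducibly.

    Each trajectory draws its randomness from a deterministically derived
    substream of ``seed`` so datasets are reproducible regardless of
    generation order.  ``network_sampler(rng)``, if given, returns a
    per-trajectory perturbed network (extrinsic noise / cell-to-cell
    variability).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(labels) * n_per_label)
    out = []
    i = 0
    for label in labels:
        for _ in range(n_per_label):
            rng = np.random.default_rng(children[i])
            net = network if network_sampler is None else network_sampler(rng)
            out.append(ssa_simulate(net, label, x0, T, rng))
            i += 1
    return out


def resample_discrete(traj: ContinuousTrajectory, d: int) -> DiscreteTrajectory:
    """Read the path out on the uniform grid ``dt, 2*dt, ..., d*dt = T``.

    The step function is taken right-continuous: the value at a jump instant
    is the post-jump state, matching the "state at time t" semantics of a
    counting process.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    dt = traj.horizon / d
    grid = dt * np.arange(1, d + 1)
    ends = np.cumsum(traj.dwell_times)
    # state index occupied at time t: first interval whose end is > t
    idx = np.searchsorted(ends, grid, side="right")
    idx = np.minimum(idx, len(traj.states) - 1)  # t == T lands in last state
    values = traj.states[idx]
    return DiscreteTrajectory(traj.input_label, traj.initial_state, values, dt)


def discrete_matrix(
    trajectories: list[ContinuousTrajectory], d: int
) -> tuple[np.ndarray, np.ndarray, list]:
    """Resample a dataset to an ``(N, d)`` integer matrix (single species).

    Returns ``(X, x0, labels)``; ``x0`` holds each path's initial count.
    """
    X = np.empty((len(trajectories), d), dtype=np.int64)
    x0 = np.empty(len(trajectories), dtype=np.int64)
    labels = []
    for i, traj in enumerate(trajectories):
        dt_traj = resample_discrete(traj, d)
        X[i] = dt_traj.values[:, 0]
        x0[i] = dt_traj.x0[0]
        labels.append(traj.input_label)
    return X, x0, labels
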