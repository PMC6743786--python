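"""Model-based path likelihoods and exact Monte-Carlo mutual information.

For a fully observed network the likelihood of a continuous-time path is a
product of exponential survival factors and jump rates read off the CME
generator ``M``; for a discretely sampled path it is a product of transition
probabilities from the propagator ``W = expm(M * dt)``.  Averaging exact
log-likelihoods over SSA-sampled paths gives Monte-Carlo approximations of
the response entropy H(X), the noise entropy H(X|U), and hence the mutual
information I(X;U) = H(X) - H(X|U) — the "gold truth" every model-free
estimator in this package is benchmarked against.

All information bookkeeping is in bits (log base 2); natural-log internals
are converted once at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.special import logsumexp

from .network import InputEnsemble, ReactionNetwork, StateSpace, build_generator, default_state_space
from .simulate import ContinuousTrajectory, simulate_dataset, discrete_matrix

__all__ = [
    "PathLikelihoodModel",
    "InfoResult",
    "discrete_propagator",
    "exact_info",
    "exact_info_replicated",
]

LOG2E = float(np.log2(np.e))


def discrete_propagator(M: np.ndarray, dt: float) -> np.ndarray:
    """Transition matrix over one grid step, ``W = expm(M * dt)``.

    Columns sum to one minus the truncation leak; ``dt = 0`` gives the
    identity.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    W = expm(M * dt)
    if not np.all(np.isfinite(W)):
        raise FloatingPointError("non-finite entries in matrix exponential")
    return W


@dataclass
class InfoResult:
    """A mutual-information estimate in bits with its replicate spread."""

    value: float
    std: float
    n_per_label: int
    mode: str  # "continuous" | "discrete"
    d: int | None = None
    T: float | None = None

    def __post_init__(self):
        if self.std < 0:
            raise ValueError("std must be non-negative")


class PathLikelihoodModel:
    """Exact likelihoods of continuous and discrete paths under each input.

    Holds, per input label, the truncated generator for every
    rate-schedule segment, and caches the per-segment propagators used for
    discretely sampled paths.  The initial state is deterministic
    (``p(s_1)`` a point mass), matching the packaged examples.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        ensemble: InputEnsemble,
        x0,
        T: float,
        space: StateSpace | None = None,
    ):
        self.network = network
        self.ensemble = ensemble
        self.x0 = np.atleast_1d(np.asarray(x0, dtype=np.int64))
        self.T = float(T)
        if space is None:
            space = default_state_space(network, ensemble, int(self.x0[0]))
        self.space = space
        # per label: segment boundaries [0, b1, ..., T] and one generator per segment
        self._segments: dict = {}
        self._generators: dict = {}
        self.leak_: dict = {}
        for label in ensemble.labels:
            bps = network.breakpoints(label)
            bps = bps[(bps > 0) & (bps < self.T)]
            bounds = np.concatenate([[0.0], bps, [self.T]])
            gens = []
            leaks = []
            for left in bounds[:-1]:
                M, leak = build_generator(network, label, left, space)
                gens.append(M)
                leaks.append(leak)
            self._segments[label] = bounds
            self._generators[label] = gens
            self.leak_[label] = leaks
        self._prop_cache: dict = {}

    # -- continuous time ---------------------------------------------------

    def _segment_index(self, label, t: float) -> int:
        bounds = self._segments[label]
        i = int(np.searchsorted(bounds[1:-1], t, side="right"))
        return i

    def loglik_continuous(self, traj: ContinuousTrajectory, label) -> float:
        """log2 p(x | u) of an event-list path (point-mass initial state).

        The path contributes one survival term per dwell interval (split
        exactly across rate segments) and one jump-rate factor per reaction
        event; the final interval contributes survival only.  A transition
        that is impossible under this input returns ``-inf``.
        """
        states = traj.states
        idx = np.array([self.space.index_of(s) for s in states])
        if not self.space.contains(states.max(axis=0)):
            raise ValueError("trajectory leaves the truncated state space")
        if not np.array_equal(states[0], self.x0):
            return -np.inf  # point-mass initial condition
        bounds = self._segments[label]
        gens = self._generators[label]
        ends = np.cumsum(traj.dwell_times)
        starts = ends - traj.dwell_times
        ll_nat = 0.0
        # survival: for each dwell interval, time spent in each rate segment
        for g, (lo, hi) in zip(gens, zip(bounds[:-1], bounds[1:])):
            overlap = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0.0, None)
            ll_nat += float(np.dot(g[idx, idx], overlap))
        # jumps: rate of the observed transition at the jump instant
        jump_times = ends[:-1]
        if len(jump_times):
            seg_of_jump = np.searchsorted(bounds[1:-1], jump_times, side="right")
            rates = np.array(
                [gens[s][idx[i + 1], idx[i]] for i, s in enumerate(seg_of_jump)]
            )
            if np.any(rates <= 0.0):
                return -np.inf
            ll_nat += float(np.log(rates).sum())
        return ll_nat * LOG2E

    # -- discrete time -----------------------------------------------------

    def step_log_propagators(self, label, d: int) -> np.ndarray:
        """``(d, n, n)`` array of log2 transition matrices, one per grid step.

        A grid step spanning a rate breakpoint uses the time-ordered product
        of the segment propagators.  Results are cached per ``(label, d)``.
        """
        key = (label, d)
        if key in self._prop_cache:
            return self._prop_cache[key]
        dt = self.T / d
        bounds = self._segments[label]
        gens = self._generators[label]
        # cache expm per (segment, duration) to exploit repeated step lengths
        expm_cache: dict = {}

        def seg_prop(seg: int, duration: float) -> np.ndarray:
            k = (seg, round(duration, 12))
            if k not in expm_cache:
                expm_cache[k] = discrete_propagator(gens[seg], duration)
            return expm_cache[k]

        n = self.space.n_states
        logW = np.empty((d, n, n))
        with np.errstate(divide="ignore"):
            for i in range(d):
                lo, hi = i * dt, (i + 1) * dt
                cuts = bounds[(bounds > lo) & (bounds < hi)]
                pieces = np.concatenate([[lo], cuts, [hi]])
                W = None
                for a, b in zip(pieces[:-1], pieces[1:]):
                    seg = self._segment_index(label, a)
                    Wseg = seg_prop(seg, b - a)
                    W = Wseg if W is None else Wseg @ W
                logW[i] = np.log2(np.clip(W, 0.0, None))
        self._prop_cache[key] = logW
        return logW

    def loglik_discrete_matrix(self, X: np.ndarray, label) -> np.ndarray:
        """log2 p(x | u) for every row of an ``(N, d)`` sample matrix.

        Every grid step from the known initial state onward contributes one
        propagator factor, so a ``d``-point sample yields ``d`` factors.
        """
        X = np.asarray(X, dtype=np.int64)
        d = X.shape[1]
        logW = self.step_log_propagators(label, d)
        prev = np.full(len(X), self.space.index_of(self.x0), dtype=np.int64)
        ll = np.zeros(len(X))
        for i in range(d):
            cur = X[:, i]
            ll += logW[i][cur, prev]
            prev = cur
        return ll

    def loglik_discrete(self, values, label) -> float:
        return float(self.loglik_discrete_matrix(np.atleast_2d(values), label)[0])

    # -- marginals ---------------------------------------------------------

    def conditional_logliks(self, traj_or_values, mode: str) -> np.ndarray:
        """log2 p(x | u) for every input label, as a vector."""
        if mode == "continuous":
            return np.array(
                [self.loglik_continuous(traj_or_values, lab) for lab in self.ensemble.labels]
            )
        return np.array(
            [self.loglik_discrete(traj_or_values, lab) for lab in self.ensemble.labels]
        )

    def marginal_loglik(self, traj_or_values, mode: str = "continuous") -> float:
        """log2 p_X(x) = log2 sum_u p(x|u) p_U(u) via log-sum-exp."""
        ll = self.conditional_logliks(traj_or_values, mode)
        return _prior_logsumexp(ll, self.ensemble.prior)


def _prior_logsumexp(ll_bits: np.ndarray, prior: np.ndarray) -> float:
    """log2 of the prior-weighted mixture of conditionals given in log2."""
    mask = prior > 0
    if not np.any(np.isfinite(ll_bits[mask])):
        return -np.inf
    nat = ll_bits[mask] / LOG2E + np.log(prior[mask])
    return float(logsumexp(nat)) * LOG2E


def exact_info(
    model: PathLikelihoodModel,
    trajectories: list[ContinuousTrajectory],
    mode: str = "continuous",
    d: int | None = None,
) -> float:
    """Exact Monte-Carlo mutual information of a labeled dataset, in bits.

    ``H(X)`` is minus the mean marginal log-likelihood over all paths;
    ``H(X|U)`` is the prior-weighted mean of per-input conditional
    log-likelihoods, each averaged over the paths generated under that
    input.  The dataset must come from the same model for the approximation
    semantics to hold.
    """
    if not trajectories:
        raise ValueError("empty dataset")
    labels = model.ensemble.labels
    prior = model.ensemble.prior
    if mode == "continuous":
        cond = np.array(
            [[model.loglik_continuous(tr, lab) for lab in labels] for tr in trajectories]
        )
        traj_labels = [tr.input_label for tr in trajectories]
    elif mode == "discrete":
        if d is None:
            raise ValueError("discrete mode requires d")
        X, _, traj_labels = discrete_matrix(trajectories, d)
        cond = np.column_stack([model.loglik_discrete_matrix(X, lab) for lab in labels])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for lab in traj_labels:
        if lab not in labels:
            raise ValueError(f"trajectory label {lab!r} not in input ensemble")
    if not np.all(np.isfinite(np.max(cond, axis=1))):
        raise ValueError(
            "some paths are impossible under every input: dataset/model mismatch"
        )
    marg = np.array([_prior_logsumexp(row, prior) for row in cond])
    h_x = -float(marg.mean())
    h_x_given_u = 0.0
    lab_arr = np.array([labels.index(l) for l in traj_labels])
    for j, lab in enumerate(labels):
        own = cond[lab_arr == j, j]
        if len(own) == 0:
            raise ValueError(f"no paths for label {lab!r}")
        h_x_given_u += prior[j] * (-own.mean())
    return h_x - h_x_given_u


def exact_info_replicated(
    network: ReactionNetwork,
    ensemble: InputEnsemble,
    x0,
    T: float,
    n_per_label: int,
    mode: str = "continuous",
    d: int | None = None,
    replicates: int = 20,
    seed=None,
    space: StateSpace | None = None,
) -> InfoResult:
    """Replicated exact Monte-Carlo information with fresh paths per replicate."""
    model = PathLikelihoodModel(network, ensemble, x0, T, space=space)
    ss = np.random.SeedSequence(seed)
    vals = []
    for child in ss.spawn(replicates):
        data = simulate_dataset(network, ensemble.labels, x0, T, n_per_label, child)
        vals.append(exact_info(model, data, mode=mode, d=d))
    vals = np.asarray(vals)
    return InfoResult(
        value=float(vals.mean()),
        std=float(vals.std(ddof=1)) if replicates > 1 else 0.0,
        n_per_label=n_per_label,
        mode=mode,
        d=d,
        T=T,
    )
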