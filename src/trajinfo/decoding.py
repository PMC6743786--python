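"""MAP decoding and confusion-matrix information bounds.

Decoding a response trajectory back into the input that generated it turns
information estimation into a classification problem: the plug-in mutual
information of the q x q confusion matrix between true and decoded inputs is
a lower bound on I(X;U) by the data-processing inequality.  When the decoder
is the Bayes-optimal (MAP) one, the same confusion matrix also yields an
upper bound on I(X;U) of the Feder-Merhav type, built from the per-decode
error probabilities through the floor/ceiling construction phi/alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exact import PathLikelihoodModel
from .simulate import ContinuousTrajectory, simulate_dataset, discrete_matrix

__all__ = [
    "ConfusionMatrix",
    "DecodeRecord",
    "map_decode",
    "confusion_from_decodes",
    "info_from_confusion",
    "info_upper_bound",
    "map_info_bound",
]


@dataclass
class ConfusionMatrix:
    """Joint decode-frequency table: ``eps[i, j] = Pr(U = u_i, Uhat = u_j)``.

    Stored as a joint table (counts over total test size) so the plug-in
    mutual-information formula applies literally with its row/column
    marginals.
    """

    table: np.ndarray
    labels: list
    n_test: int

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        q = len(self.labels)
        if self.table.shape != (q, q):
            raise ValueError("confusion table must be q x q")
        if np.any(self.table < 0):
            raise ValueError("confusion table entries must be non-negative")
        if abs(self.table.sum() - 1.0) > 1e-9:
            raise ValueError("confusion table must sum to one")

    @property
    def q(self) -> int:
        return len(self.labels)


@dataclass
class DecodeRecord:
    """One decoded trajectory: truth, decode, and the per-input scores."""

    true_label: object
    decoded_label: object
    scores: np.ndarray  # log-posterior (up to a constant) per input


def map_decode(traj_or_values, model: PathLikelihoodModel, mode: str = "continuous") -> DecodeRecord:
    """Bayes-optimal decode: ``argmax_u [log p(x|u) + log p_U(u)]``.

    Ties break to the smallest label index so results are reproducible.
    """
    ll = model.conditional_logliks(traj_or_values, mode)
    with np.errstate(divide="ignore"):
        scores = ll + np.log2(model.ensemble.prior)
    if not np.any(np.isfinite(scores)):
        raise ValueError("decode failure: path impossible under every input")
    best = int(np.argmax(scores))  # argmax returns the first (lowest) index on ties
    true_label = getattr(traj_or_values, "input_label", None)
    return DecodeRecord(true_label, model.ensemble.labels[best], scores)


def confusion_from_decodes(true_labels, decoded_labels, labels) -> ConfusionMatrix:
    """Build the joint q x q frequency table from decode results."""
    q = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((q, q))
    for u, uh in zip(true_labels, decoded_labels):
        counts[index[u], index[uh]] += 1
    n = len(true_labels)
    return ConfusionMatrix(counts / n, list(labels), n)


def info_from_confusion(eps: ConfusionMatrix | np.ndarray) -> float:
    """Plug-in mutual information (bits) of a joint confusion table.

    ``0 * log 0 := 0``; the result lies in ``[0, log2 q]`` and equals
    ``log2 q`` only for a permutation-diagonal table.
    """
    table = eps.table if isinstance(eps, ConfusionMatrix) else np.asarray(eps, dtype=float)
    if np.any(table < 0):
        raise ValueError("confusion table entries must be non-negative")
    if abs(table.sum() - 1.0) > 1e-9:
        raise ValueError("confusion table must sum to one")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    mask = table > 0
    outer = np.outer(row, col)
    return float(np.sum(table[mask] * np.log2(table[mask] / outer[mask])))


def _phi(pi: float, q: int) -> float:
    """phi(pi): floor/ceiling interpolation of the error-probability entropy."""
    if pi >= 1.0:
        return float(np.log2(q))  # degenerate column, capped at H(U) scale
    inv = 1.0 / (1.0 - pi)
    fl, ce = np.floor(inv), np.ceil(inv)
    alpha = fl * ((1.0 - pi) * ce - 1.0)
    return float(alpha * np.log2(fl) + (1.0 - alpha) * np.log2(ce))


def info_upper_bound(eps: ConfusionMatrix) -> float:
    """Upper bound on I(U;X) from the MAP confusion matrix (bits).

    ``I_UB = H(U) - sum_uhat p(uhat) * phi(pi_uhat)`` with
    ``pi_uhat = 1 - Pr(U = uhat | Uhat = uhat)``.  Valid only when the
    decodes come from the MAP decoder.
    """
    table = eps.table
    row = table.sum(axis=1)  # p_U
    col = table.sum(axis=0)  # p_Uhat
    h_u = -float(np.sum(row[row > 0] * np.log2(row[row > 0])))
    total = 0.0
    for j in range(eps.q):
        if col[j] == 0:
            continue
        pi = 1.0 - table[j, j] / col[j]
        total += col[j] * _phi(pi, eps.q)
    return h_u - total


def map_info_bound(
    model: PathLikelihoodModel,
    trajectories: list[ContinuousTrajectory],
    mode: str = "continuous",
    d: int | None = None,
) -> tuple[float, float, ConfusionMatrix]:
    """Decode a labeled dataset with the MAP decoder; return (I_MAP, I_UB, eps)."""
    labels = model.ensemble.labels
    true_labels = [tr.input_label for tr in trajectories]
    if mode == "continuous":
        decoded = [map_decode(tr, model, "continuous").decoded_label for tr in trajectories]
    else:
        if d is None:
            raise ValueError("discrete mode requires d")
        X, _, true_labels = discrete_matrix(trajectories, d)
        cond = np.column_stack(
            [model.loglik_discrete_matrix(X, lab) for lab in labels]
        )
        with np.errstate(divide="ignore"):
            scores = cond + np.log2(model.ensemble.prior)
        decoded = [labels[int(i)] for i in np.argmax(scores, axis=1)]
    eps = confusion_from_decodes(true_labels, decoded, labels)
    return info_from_confusion(eps), info_upper_bound(eps), eps


def map_info_bound_replicated(
    network,
    ensemble,
    x0,
    T: float,
    n_per_label: int,
    mode: str = "continuous",
    d: int | None = None,
    replicates: int = 20,
    seed=None,
    space=None,
):
    """Replicated MAP bound with fresh SSA datasets; returns dict of summaries."""
    model = PathLikelihoodModel(network, ensemble, x0, T, space=space)
    ss = np.random.SeedSequence(seed)
    lows, ups = [], []
    eps_last = None
    for child in ss.spawn(replicates):
        data = simulate_dataset(network, ensemble.labels, x0, T, n_per_label, child)
        lo, up, eps_last = map_info_bound(model, data, mode=mode, d=d)
        lows.append(lo)
        ups.append(up)
    lows, ups = np.asarray(lows), np.asarray(ups)
    sd = (lambda v: float(v.std(ddof=1)) if replicates > 1 else 0.0)
    return {
        "I_MAP": float(lows.mean()),
        "I_MAP_std": sd(lows),
        "I_UB": float(ups.mean()),
        "I_UB_std": sd(ups),
        "confusion": eps_last,
    }
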