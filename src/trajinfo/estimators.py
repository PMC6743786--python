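"""Model-free information estimators learned from labeled trajectory data.

All decoders are scikit-learn estimators (``fit`` / ``predict``), so they
compose with pipelines and model selection.  The decoding information
estimator wraps any such classifier: it repeatedly splits the data into
stratified train/test parts, fits on the training part, decodes the test
part, and converts the resulting confusion matrix into a plug-in
mutual-information lower bound.  Two non-decoding baselines are included:
the Kraskov-style k-nearest-neighbor estimator for a continuous response
and a discrete label, and the Gaussian approximation that fits per-class
multivariate normals and Monte-Carlo integrates the mixture entropy.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import cdist, pdist
from scipy.special import digamma, logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .decoding import confusion_from_decodes, info_from_confusion

__all__ = [
    "GaussianDecoder",
    "DendrogramSVC",
    "make_decoder",
    "DecodingInfoEstimator",
    "estimate_info",
    "knn_mutual_information",
    "gaussian_approximation_info",
    "ExponentialFilter",
    "exponential_filter",
]

LN2 = float(np.log(2.0))

# cross-validation grids; the regularization constant grid and the kernel
# width grid (relative to the median pairwise distance) are package defaults
C_GRID = (0.1, 1.0, 10.0, 100.0)
SIGMA_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0)
LAMBDA_GRID = tuple(np.logspace(-4, 1, 11))


# --------------------------------------------------------------------------
# Gaussian decoder
# --------------------------------------------------------------------------


class GaussianDecoder(ClassifierMixin, BaseEstimator):
    """MAP classifier under per-class multivariate-normal response models.

    Fits a mean vector and covariance matrix per class and decodes by
    ``argmax_u [log N(x; mu(u), Sigma(u)) + log p_U(u)]``.  The covariance
    is diagonally regularized as ``Sigma + lambda * I``; with
    ``reg_lambda="auto"`` the strength is chosen to maximize held-out
    log-likelihood on a validation split of the training data, with the
    grid log-spaced relative to the mean diagonal variance.

    Parameters
    ----------
    reg_lambda : float or "auto", default="auto"
        Diagonal regularization strength (absolute if a float).
    val_fraction : float, default=0.2
        Fraction of the training data held out to select ``reg_lambda``.
    random_state : int or None
        Seed for the validation split.
    """

    def __init__(self, reg_lambda="auto", val_fraction=0.2, random_state=None):
        self.reg_lambda = reg_lambda
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _moments(self, X, y):
        means, covs, priors = {}, {}, {}
        for lab in self.classes_:
            rows = X[y == lab]
            means[lab] = rows.mean(axis=0)
            covs[lab] = np.cov(rows, rowvar=False, ddof=1)
            if covs[lab].ndim == 0:
                covs[lab] = covs[lab].reshape(1, 1)
            priors[lab] = len(rows) / len(X)
        return means, covs, priors

    @staticmethod
    def _gaussian_scores(X, means, covs, priors, lam, classes):
        scores = np.empty((len(X), len(classes)))
        for j, lab in enumerate(classes):
            cov = covs[lab] + lam * np.eye(covs[lab].shape[0])
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    "covariance not positive definite after regularization; "
                    f"lambda grid exhausted at lambda={lam:g}"
                )
            diff = X - means[lab]
            sol = np.linalg.solve(cov, diff.T).T
            maha = np.einsum("ij,ij->i", diff, sol)
            d = cov.shape[0]
            scores[:, j] = (
                -0.5 * (d * np.log(2 * np.pi) + logdet + maha) + np.log(priors[lab])
            )
        return scores

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        if self.reg_lambda == "auto":
            X_fit, X_val, y_fit, y_val = train_test_split(
                X,
                y,
                test_size=self.val_fraction,
                stratify=y,
                random_state=self.random_state,
            )
            means, covs, priors = self._moments(X_fit, y_fit)
            scale = np.mean([np.mean(np.diag(covs[l])) for l in self.classes_])
            scale = max(scale, 1e-12)
            best_lam, best_ll = None, -np.inf
            for lam in np.asarray(LAMBDA_GRID) * scale:
                try:
                    scores = self._gaussian_scores(
                        X_val, means, covs, priors, lam, self.classes_
                    )
                except np.linalg.LinAlgError:
                    continue
                idx = np.searchsorted(self.classes_, y_val)
                ll = float(scores[np.arange(len(y_val)), idx].sum())
                if ll > best_ll:
                    best_lam, best_ll = lam, ll
            if best_lam is None:
                raise np.linalg.LinAlgError(
                    "no positive-definite covariance on the lambda grid"
                )
            self.reg_lambda_ = float(best_lam)
        else:
            self.reg_lambda_ = float(self.reg_lambda)
        self.means_, self.covs_, self.priors_ = self._moments(X, y)
        return self

    def decision_scores(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self._gaussian_scores(
            X, self.means_, self.covs_, self.priors_, self.reg_lambda_, self.classes_
        )

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


# --------------------------------------------------------------------------
# SVM decoders (binary and dendrogram multiclass)
# --------------------------------------------------------------------------


# libsvm can take arbitrarily long to converge on inseparable data at large
# C; the iteration cap bounds the fit time at negligible accuracy cost
SVC_MAX_ITER = 20_000


def _tuned_svc(X, y, kernel, cv, random_state):
    """Binary SVC with C (and RBF width) chosen by internal cross-validation."""
    if kernel == "linear":
        grid = {"C": list(C_GRID)}
        base = SVC(kernel="linear", max_iter=SVC_MAX_ITER)
    elif kernel == "rbf":
        sub = X if len(X) <= 500 else X[
            np.random.default_rng(random_state).choice(len(X), 500, replace=False)
        ]
        med = np.median(pdist(sub))
        med = med if med > 0 else 1.0
        sigmas = med * np.asarray(SIGMA_SCALES)
        grid = {"C": list(C_GRID), "gamma": list(1.0 / (2.0 * sigmas**2))}
        base = SVC(kernel="rbf", max_iter=SVC_MAX_ITER)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    n_min = np.min(np.unique(y, return_counts=True)[1])
    folds = int(min(cv, n_min))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if folds >= 2:
            search = GridSearchCV(base, grid, cv=folds, n_jobs=None)
            search.fit(X, y)
            return search.best_estimator_
        base.fit(X, y)
    return base


class DendrogramSVC(ClassifierMixin, BaseEstimator):
    """Soft-margin SVM decoder; multiclass via a dendrogram of binary SVMs.

    For two classes this is a single SVC with the regularization constant
    (and RBF kernel width) set by cross-validation on the training data.
    For ``q > 2`` the classes are clustered bottom-up by average linkage on
    their mean trajectories; each internal node of the resulting tree holds
    a binary SVM separating its two branches, and prediction descends the
    tree from the root.
    """

    def __init__(self, kernel="rbf", cv=5, random_state=None):
        self.kernel = kernel
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        if len(self.classes_) == 2:
            self.tree_ = None
            self.svc_ = _tuned_svc(X, y, self.kernel, self.cv, self.random_state)
            return self
        means = np.array([X[y == lab].mean(axis=0) for lab in self.classes_])
        Z = linkage(means, method="average")
        root, _ = to_tree(Z, rd=True)
        self._nodes = {}

        def build(node):
            if node.is_leaf():
                return
            left = set(node.left.pre_order())
            right = set(node.right.pre_order())
            members = np.array([c in left for c in np.searchsorted(self.classes_, y)])
            in_node = np.isin(np.searchsorted(self.classes_, y), list(left | right))
            side = np.where(members[in_node], 0, 1)
            svc = _tuned_svc(X[in_node], side, self.kernel, self.cv, self.random_state)
            self._nodes[node.id] = (svc, node.left, node.right)
            build(node.left)
            build(node.right)

        build(root)
        self.tree_ = root
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if self.tree_ is None:
            return self.svc_.predict(X)
        out = np.empty(len(X), dtype=self.classes_.dtype)
        for i, x in enumerate(X):
            node = self.tree_
            while not node.is_leaf():
                svc, left, right = self._nodes[node.id]
                side = int(svc.predict(x[None, :])[0])
                node = left if side == 0 else right
            out[i] = self.classes_[node.id]
        return out


def make_decoder(method: str, random_state=None, **kwargs):
    """Decoder factory for the method names used throughout the package.

    ``svm-linear`` / ``svm-rbf``: (dendrogram) SVM with internal CV.
    ``gaussian-decoder``: regularized per-class Gaussian MAP classifier.
    ``mlp``: fully connected 300-200 multi-layer perceptron with Adam,
    early stopping on a 15% validation split.
    """
    if method in ("svm-linear", "svm-lin"):
        return DendrogramSVC(kernel="linear", random_state=random_state, **kwargs)
    if method == "svm-rbf":
        return DendrogramSVC(kernel="rbf", random_state=random_state, **kwargs)
    if method in ("gaussian-decoder", "gd"):
        return GaussianDecoder(random_state=random_state, **kwargs)
    if method == "mlp":
        defaults = dict(
            hidden_layer_sizes=(300, 200),
            activation="relu",
            solver="adam",
            batch_size=128,
            max_iter=200,
            early_stopping=True,
            validation_fraction=0.15,
        )
        defaults.update(kwargs)
        return MLPClassifier(random_state=random_state, **defaults)
    raise ValueError(f"unknown decoder method {method!r}")


# --------------------------------------------------------------------------
# Decoding information estimator
# --------------------------------------------------------------------------


class DecodingInfoEstimator(BaseEstimator):
    """Mutual-information lower bound from a learned decoder.

    For each of ``replicates`` stratified 70/30 splits the decoder is fitted
    on the training part, the held-out part is decoded, and the joint
    confusion matrix is converted to plug-in mutual information.  Fitted
    attributes: ``info_`` (mean bits over replicates), ``info_std_``,
    ``infos_`` (per replicate), ``confusion_`` (last replicate).

    Parameters
    ----------
    decoder : classifier or method name
        Any sklearn classifier, or a string accepted by :func:`make_decoder`.
    train_fraction : float, default=0.7
    replicates : int, default=20
        Number of independent split/fit/decode repetitions.
    shuffle_labels : bool, default=False
        If true, labels are permuted before every replicate (negative
        control: the information of shuffled data should be zero).
    random_state : int or None
    """

    def __init__(
        self,
        decoder="svm-rbf",
        train_fraction=0.7,
        replicates=20,
        shuffle_labels=False,
        random_state=None,
    ):
        self.decoder = decoder
        self.train_fraction = train_fraction
        self.replicates = replicates
        self.shuffle_labels = shuffle_labels
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        labels = list(unique_labels(y))
        rng = np.random.default_rng(self.random_state)
        infos = []
        eps = None
        for rep in range(self.replicates):
            y_rep = rng.permutation(y) if self.shuffle_labels else y
            seed = int(rng.integers(2**31 - 1))
            splitter = StratifiedShuffleSplit(
                n_splits=1, train_size=self.train_fraction, random_state=seed
            )
            (tr, te), = splitter.split(X, y_rep)
            dec = (
                make_decoder(self.decoder, random_state=seed)
                if isinstance(self.decoder, str)
                else clone(self.decoder)
            )
            if "random_state" in dec.get_params():
                dec.set_params(random_state=seed)
            dec.fit(X[tr], y_rep[tr])
            yhat = dec.predict(X[te])
            eps = confusion_from_decodes(y_rep[te], yhat, labels)
            infos.append(info_from_confusion(eps))
        self.infos_ = np.asarray(infos)
        self.info_ = float(self.infos_.mean())
        self.info_std_ = (
            float(self.infos_.std(ddof=1)) if self.replicates > 1 else 0.0
        )
        self.confusion_ = eps
        return self


def estimate_info(
    X,
    y,
    method="svm-rbf",
    train_fraction=0.7,
    replicates=20,
    shuffle_labels=False,
    random_state=None,
):
    """Functional wrapper over :class:`DecodingInfoEstimator`.

    Returns ``(mean_bits, std_bits, per_replicate_values)``.
    """
    est = DecodingInfoEstimator(
        decoder=method,
        train_fraction=train_fraction,
        replicates=replicates,
        shuffle_labels=shuffle_labels,
        random_state=random_state,
    ).fit(X, y)
    return est.info_, est.info_std_, est.infos_


# --------------------------------------------------------------------------
# knn mutual information (continuous response, discrete label)
# --------------------------------------------------------------------------


def knn_mutual_information(X, y, k=1, jitter_sd=0.0, random_state=None):
    """Nearest-neighbor mutual information between trajectories and labels.

    Kraskov-style estimator specialized to a discrete label: for every
    point, take the Chebyshev distance to its k-th nearest neighbor within
    its own class, count how many points of the full sample fall within
    that distance (ties included), and combine the counts through digamma
    terms.  Optionally adds iid Gaussian jitter of scale ``jitter_sd`` to
    every component first — recommended for integer-valued data, whose
    massive distance ties otherwise bias the estimate, potentially to
    large negative values.  The raw estimate is returned faithfully even
    when negative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if k >= counts.min():
        raise ValueError("k must be smaller than the smallest class count")
    if jitter_sd > 0:
        rng = np.random.default_rng(random_state)
        X = X + rng.normal(0.0, jitter_sd, size=X.shape)

    radius = np.empty(n)
    for lab in classes:
        idx = np.nonzero(y == lab)[0]
        sub = X[idx]
        # k-th neighbor distance within the class, excluding the point itself
        for start in range(0, len(idx), 512):
            chunk = slice(start, min(start + 512, len(idx)))
            dist = cdist(sub[chunk], sub, metric="chebyshev")
            part = np.partition(dist, k, axis=1)
            radius[idx[chunk]] = part[:, k]
    if jitter_sd == 0 and np.any(radius == 0):
        warnings.warn(
            "zero k-th neighbor distances (duplicate points); counts include "
            "all tied duplicates — consider jitter_sd > 0 for integer data",
            stacklevel=2,
        )
    m = np.empty(n, dtype=np.int64)
    for start in range(0, n, 512):
        chunk = slice(start, min(start + 512, n))
        dist = cdist(X[chunk], X, metric="chebyshev")
        m[chunk] = (dist <= radius[chunk, None]).sum(axis=1) - 1  # exclude self
    n_class = counts[np.searchsorted(classes, y)]
    mi_nats = (
        digamma(n) - np.mean(digamma(n_class)) + digamma(k) - np.mean(digamma(m))
    )
    return float(mi_nats / LN2)


# --------------------------------------------------------------------------
# Gaussian approximation to the mutual information
# --------------------------------------------------------------------------


def gaussian_approximation_info(X, y, n_mc=10000, reg=0.0, random_state=None):
    """Mutual information under per-class multivariate-normal approximations.

    The conditional entropy is analytic,
    ``H(X|u) = 0.5 * log2 det(2 pi e Sigma(u))``; the mixture entropy
    ``H(X)`` has no closed form and is Monte-Carlo integrated with ``n_mc``
    draws from the fitted mixture.  This approximation carries no bound
    guarantee: on strongly non-Gaussian (discrete, positive) data it can
    overshoot the true information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    d = X.shape[1]
    rng = np.random.default_rng(random_state)
    means, covs, priors = [], [], []
    for lab in classes:
        rows = X[y == lab]
        means.append(rows.mean(axis=0))
        cov = np.cov(rows, rowvar=False, ddof=1).reshape(d, d) + reg * np.eye(d)
        sign, _ = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "class covariance is not positive definite; pass reg > 0 or "
                "collect more samples per class"
            )
        covs.append(cov)
        priors.append(len(rows) / len(X))
    priors = np.asarray(priors)

    h_cond = 0.0
    for p, cov in zip(priors, covs):
        _, logdet = np.linalg.slogdet(2 * np.pi * np.e * cov)
        h_cond += p * 0.5 * logdet / LN2

    # Monte-Carlo mixture entropy: sample a class, then its Gaussian
    comp = rng.choice(len(classes), size=n_mc, p=priors)
    chols = [np.linalg.cholesky(c) for c in covs]
    draws = np.empty((n_mc, d))
    for j in range(len(classes)):
        rows = comp == j
        z = rng.standard_normal((rows.sum(), d))
        draws[rows] = means[j] + z @ chols[j].T
    log_pdfs = np.empty((n_mc, len(classes)))
    for j in range(len(classes)):
        diff = draws - means[j]
        sol = np.linalg.solve(covs[j], diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        _, logdet = np.linalg.slogdet(covs[j])
        log_pdfs[:, j] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha) + np.log(
            priors[j]
        )
    h_mix = -float(np.mean(logsumexp(log_pdfs, axis=1))) / LN2
    return h_mix - h_cond


# --------------------------------------------------------------------------
# Exponential low-pass filter
# --------------------------------------------------------------------------


class ExponentialFilter(TransformerMixin, BaseEstimator):
    """Causal exponential moving average along the time axis of each row.

    ``y[0] = x[0]`` and ``y[i] = a x[i] + (1 - a) y[i-1]`` with
    ``a = 1 - exp(-dt / tau)``; ``tau -> 0`` recovers the identity.  Turns
    integer molecule-count samples into smoothed real-valued traces.
    """

    def __init__(self, tau=50.0, dt=1.0):
        self.tau = tau
        self.dt = dt

    def fit(self, X, y=None):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        return self

    def transform(self, X):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        X = check_array(X).astype(float)
        a = 1.0 - np.exp(-self.dt / self.tau)
        out = np.empty_like(X)
        out[:, 0] = X[:, 0]
        for i in range(1, X.shape[1]):
            out[:, i] = a * X[:, i] + (1.0 - a) * out[:, i - 1]
        return out


def exponential_filter(X, tau, dt=1.0):
    """Functional wrapper over :class:`ExponentialFilter`."""
    return ExponentialFilter(tau=tau, dt=dt).fit(None).transform(X)
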