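"""Generalized partial credit model: probabilities, MML-EM estimation,
EAP scoring, and item/test information.

The GPCM is the standard polytomous IRT model for ordered Likert responses.
An item with discrimination ``a`` and step difficulties ``b_1 < ... < b_{m-1}``
assigns category ``c`` (0-based) the probability

    P(c | theta) = exp(sum_{v<=c} a (theta - b_v)) / sum_k exp(...)

with the category-0 cumulative term defined as 0. The latent trait is fixed
to a standard normal in the reference population for identification, and all
integrals use a fixed normal-weighted rectangular quadrature so that results
are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import simpson
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ResponseMatrix, as_response_matrix

__all__ = [
    "GPCMItem",
    "GPCMModel",
    "InformationProfile",
    "GPCM",
    "category_probabilities",
    "expected_score",
    "marginal_log_likelihood",
    "fit_gpcm",
    "eap_scores",
    "item_information",
    "integrated_information",
    "test_information",
    "gpcm_standard_errors",
    "default_quadrature",
]

#: default for the "entire ability range" of integrated information
FULL_RANGE = (-10.0, 10.0)


# ---------------------------------------------------------------------------
# model containers


@dataclasses.dataclass
class GPCMItem:
    """One GPCM item: discrimination ``a`` and ``m - 1`` step difficulties."""

    a: float
    b: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.a = float(self.a)
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.b.ndim != 1 or self.b.size < 1:
            raise ValueError("b must be a vector of at least one step difficulty")

    @property
    def m(self) -> int:
        """Number of response categories."""
        return self.b.size + 1

    def copy(self) -> "GPCMItem":
        return GPCMItem(self.a, self.b.copy(), self.name)


def default_quadrature(
    n_points: int = 61,
    quad_range: tuple[float, float] = (-6.0, 6.0),
    mean: float = 0.0,
    sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Equally spaced nodes with normalized normal-density weights."""
    nodes = np.linspace(quad_range[0], quad_range[1], n_points)
    w = norm.pdf(nodes, loc=mean, scale=sd)
    return nodes, w / w.sum()


@dataclasses.dataclass
class GPCMModel:
    """A fitted (or true) GPCM: items plus latent-trait prior and quadrature."""

    items: list[GPCMItem]
    quad_points: np.ndarray | None = None
    quad_weights: np.ndarray | None = None
    prior_mean: float = 0.0
    prior_var: float = 1.0
    fit_info: dict | None = None

    def __post_init__(self) -> None:
        if self.prior_var <= 0:
            raise ValueError("prior variance must be positive")
        if self.quad_points is None:
            self.quad_points, self.quad_weights = default_quadrature(
                mean=self.prior_mean, sd=float(np.sqrt(self.prior_var))
            )
        self.quad_points = np.asarray(self.quad_points, dtype=float)
        self.quad_weights = np.asarray(self.quad_weights, dtype=float)
        self.quad_weights = self.quad_weights / self.quad_weights.sum()

    @property
    def n_items(self) -> int:
        return len(self.items)

    def discriminations(self) -> np.ndarray:
        return np.array([it.a for it in self.items])

    def copy(self) -> "GPCMModel":
        return GPCMModel(
            items=[it.copy() for it in self.items],
            quad_points=self.quad_points.copy(),
            quad_weights=self.quad_weights.copy(),
            prior_mean=self.prior_mean,
            prior_var=self.prior_var,
            fit_info=None if self.fit_info is None else dict(self.fit_info),
        )

    def subset(self, items: Sequence[int]) -> "GPCMModel":
        """Model restricted to the given item positions (no refit)."""
        return GPCMModel(
            items=[self.items[j].copy() for j in items],
            quad_points=self.quad_points.copy(),
            quad_weights=self.quad_weights.copy(),
            prior_mean=self.prior_mean,
            prior_var=self.prior_var,
        )

    def to_json(self) -> list[dict]:
        return [
            {
                "name": it.name or f"item{j + 1:02d}",
                "a": it.a,
                "b": [float(v) for v in it.b],
                "m": it.m,
            }
            for j, it in enumerate(self.items)
        ]


@dataclasses.dataclass
class InformationProfile:
    """Per-item and total Fisher information over a theta grid."""

    theta_grid: np.ndarray
    per_item: np.ndarray  # (n_items, n_grid)
    total: np.ndarray  # (n_grid,)

    def to_frame(self, item_names: Sequence[str] | None = None):
        import pandas as pd

        names = item_names or [f"item{j + 1:02d}" for j in range(self.per_item.shape[0])]
        df = pd.DataFrame(self.per_item.T, columns=list(names))
        df.insert(0, "theta", self.theta_grid)
        df["total"] = self.total
        return df


# ---------------------------------------------------------------------------
# probabilities and information


def _cum_thresholds(b: np.ndarray) -> np.ndarray:
    """B_c = sum_{v<=c} b_v with B_0 = 0; length m."""
    return np.concatenate([[0.0], np.cumsum(b)])


def _log_prob_table(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """log P(c | theta) for all categories; shape (m, len(theta))."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    m = len(b) + 1
    c = np.arange(m, dtype=float)
    s = a * (np.outer(c, theta) - _cum_thresholds(np.asarray(b, float))[:, None])
    s -= s.max(axis=0, keepdims=True)
    return s - np.log(np.exp(s).sum(axis=0, keepdims=True))


def category_probabilities(item: GPCMItem, theta) -> np.ndarray:
    """GPCM category probabilities at ``theta``.

    Returns a length-``m`` vector for scalar ``theta``, else an
    ``(m, len(theta))`` array. Columns sum to 1.
    """
    scalar = np.isscalar(theta)
    p = np.exp(_log_prob_table(item.a, item.b, theta))
    return p[:, 0] if scalar else p


def expected_score(item: GPCMItem, theta) -> np.ndarray | float:
    """E[C | theta] with C the 0-based category score."""
    p = np.exp(_log_prob_table(item.a, item.b, theta))
    c = np.arange(item.m, dtype=float)
    out = c @ p
    return float(out[0]) if np.isscalar(theta) else out


def item_information(item: GPCMItem, theta) -> np.ndarray | float:
    """Fisher information ``a^2 Var(C | theta)`` of one item."""
    p = np.exp(_log_prob_table(item.a, item.b, theta))
    c = np.arange(item.m, dtype=float)
    mean = c @ p
    var = (c**2) @ p - mean**2
    out = item.a**2 * var
    return float(out[0]) if np.isscalar(theta) else out


def integrated_information(
    item: GPCMItem, theta_range: tuple[float, float] | None = None, n_points: int = 2001
) -> float:
    """Numerical integral of item information over ``theta_range``.

    ``None`` means the entire ability range, taken as (-10, 10); with that
    convention per-item integrals are additive against full-range test
    information totals.
    """
    lo, hi = theta_range if theta_range is not None else FULL_RANGE
    if not lo < hi:
        raise ValueError("integration range must satisfy lo < hi")
    grid = np.linspace(lo, hi, n_points)
    return float(simpson(item_information(item, grid), x=grid))


def test_information(
    model: GPCMModel,
    subset: Sequence[int] | None = None,
    grid: np.ndarray | None = None,
) -> InformationProfile:
    """Per-item and summed information profiles over a theta grid.

    Total test information is the sum of the item informations; the
    additivity is exact at every grid point.
    """
    if grid is None:
        grid = np.linspace(-6.0, 6.0, 121)
    grid = np.asarray(grid, dtype=float)
    idx = list(range(model.n_items)) if subset is None else list(subset)
    if len(idx) == 0:
        per = np.zeros((0, grid.size))
        return InformationProfile(grid, per, np.zeros(grid.size))
    per = np.vstack([item_information(model.items[j], grid) for j in idx])
    return InformationProfile(grid, per, per.sum(axis=0))


def test_integrated_information(
    model: GPCMModel,
    subset: Sequence[int] | None = None,
    theta_range: tuple[float, float] | None = None,
) -> float:
    """Summed integrated information of a subset (full model by default)."""
    idx = list(range(model.n_items)) if subset is None else list(subset)
    return float(sum(integrated_information(model.items[j], theta_range) for j in idx))


# ---------------------------------------------------------------------------
# likelihood machinery


def _padded_tables(model: GPCMModel) -> list[np.ndarray]:
    """Per-item log-probability tables with an extra all-zero row so that a
    missing response (coded -1) indexes the last row and contributes 0."""
    Q = model.quad_points.size
    out = []
    for it in model.items:
        t = _log_prob_table(it.a, it.b, model.quad_points)
        out.append(np.vstack([t, np.zeros((1, Q))]))
    return out


def _person_loglik_matrix(model: GPCMModel, X: np.ndarray) -> np.ndarray:
    """(N, Q) matrix of log Pi_j P(x_ij | theta_q); missing skipped."""
    tables = _padded_tables(model)
    L = np.zeros((X.shape[0], model.quad_points.size))
    for j, t in enumerate(tables):
        L += t[X[:, j], :]
    return L


def _posterior_weights(model: GPCMModel, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior node weights per person and the total marginal loglik."""
    lw = _person_loglik_matrix(model, X) + np.log(model.quad_weights)[None, :]
    ll_person = logsumexp(lw, axis=1)
    W = np.exp(lw - ll_person[:, None])
    return W, float(ll_person.sum())


def marginal_log_likelihood(model: GPCMModel, data) -> float:
    """Marginal log-likelihood of the data under the model.

    Persons with all responses missing are excluded with a warning.
    """
    data = as_response_matrix(data)
    X = data.zero_based()
    all_missing = (X < 0).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"excluding {int(all_missing.sum())} person(s) with all responses missing"
        )
        X = X[~all_missing]
    _, ll = _posterior_weights(model, X)
    return ll


def eap_scores(model: GPCMModel, data) -> np.ndarray:
    """Expected a posteriori trait score per person (posterior mean).

    Persons with all responses missing get NaN.
    """
    data = as_response_matrix(data)
    X = data.zero_based()
    W, _ = _posterior_weights(model, X)
    scores = W @ model.quad_points
    scores[(X < 0).all(axis=1)] = np.nan
    return scores


# ---------------------------------------------------------------------------
# M-step: per-item maximization of expected complete-data log-likelihood


def _item_objective_grad(x: np.ndarray, R: np.ndarray, theta: np.ndarray):
    """Negative expected complete-data loglik of one item and its gradient.

    ``R[c, q]`` are expected counts of category c at node q.
    """
    a, b = x[0], x[1:]
    m = R.shape[0]
    c = np.arange(m, dtype=float)
    U = np.outer(c, theta) - _cum_thresholds(b)[:, None]  # d s_c / d a
    S = a * U
    S = S - S.max(axis=0, keepdims=True)
    logZ = np.log(np.exp(S).sum(axis=0, keepdims=True))
    logP = S - logZ
    P = np.exp(logP)
    n_q = R.sum(axis=0)
    f = float((R * logP).sum())
    D = R - n_q[None, :] * P
    grad_a = float((D * U).sum())
    # d s_c / d b_v = -a for c >= v
    tail = np.cumsum(D[::-1], axis=0)[::-1]  # tail[v] = sum_{c>=v} D[c]
    grad_b = -a * tail[1:].sum(axis=1)
    return -f, -np.concatenate([[grad_a], grad_b])


def _optimize_item(
    R: np.ndarray,
    theta: np.ndarray,
    x0: np.ndarray,
    a_min: float = 1e-3,
    maxiter: int = 50,
) -> np.ndarray:
    m = R.shape[0]
    res = optimize.minimize(
        _item_objective_grad,
        x0,
        args=(R, theta),
        jac=True,
        method="L-BFGS-B",
        bounds=[(a_min, None)] + [(None, None)] * (m - 1),
        options={"maxiter": maxiter},
    )
    return res.x


def _starting_values(X: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """a = 1, step difficulties from normal quantiles of the cumulative
    category proportions (equally spaced fallback)."""
    J = X.shape[1]
    a0 = np.ones(J)
    b0 = np.empty((J, m - 1))
    for j in range(J):
        x = X[:, j]
        x = x[x >= 0]
        props = np.bincount(x, minlength=m) / max(len(x), 1)
        cum = np.clip(np.cumsum(props)[:-1], 0.02, 0.98)
        q = norm.ppf(cum)
        q = np.sort(q) + 1e-6 * np.arange(m - 1)
        if not np.all(np.isfinite(q)):
            q = np.linspace(-2, 2, m - 1)
        b0[j] = q
    return a0, b0


def fit_gpcm(
    data,
    n_categories: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_quadrature: int = 61,
    quad_range: tuple[float, float] = (-6.0, 6.0),
) -> GPCMModel:
    """Fit a GPCM by marginal maximum likelihood EM.

    E-step: posterior weights on fixed quadrature nodes under the N(0, 1)
    reference prior. M-step: per-item quasi-Newton updates of the expected
    complete-data log-likelihood (a generalized EM step, so the marginal
    log-likelihood never decreases). Convergence is declared when the
    largest absolute parameter change falls below ``tol``; non-convergence
    within ``max_iter`` is flagged in ``fit_info``, not raised.
    """
    data = as_response_matrix(data, n_categories)
    m = n_categories or data.n_categories
    X = data.zero_based()
    all_missing = (X < 0).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"excluding {int(all_missing.sum())} person(s) with all responses missing"
        )
        X = X[~all_missing]
    for j in range(X.shape[1]):
        observed = np.unique(X[X[:, j] >= 0, j])
        if observed.size < 2:
            raise ValueError(
                f"item {data.item_names[j]!r} has fewer than 2 observed categories"
            )

    nodes, weights = default_quadrature(n_quadrature, quad_range)
    a, b = _starting_values(X, m)
    J = X.shape[1]
    onehots = [
        (X[:, j][None, :] == np.arange(m)[:, None]).astype(float) for j in range(J)
    ]

    model = GPCMModel(
        items=[GPCMItem(a[j], b[j], data.item_names[j]) for j in range(J)],
        quad_points=nodes,
        quad_weights=weights,
    )
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        W, ll = _posterior_weights(model, X)
        history.append(ll)
        delta = 0.0
        for j in range(J):
            R = onehots[j] @ W  # (m, Q) expected counts
            x0 = np.concatenate([[model.items[j].a], model.items[j].b])
            x1 = _optimize_item(R, nodes, x0)
            delta = max(delta, float(np.max(np.abs(x1 - x0))))
            model.items[j].a = x1[0]
            model.items[j].b = x1[1:]
        if delta < tol:
            converged = True
            break

    _, final_ll = _posterior_weights(model, X)
    history.append(final_ll)
    small = [data.item_names[j] for j in range(J) if model.items[j].a < 0.01]
    if small:
        warnings.warn(f"discrimination collapsing toward 0 for item(s): {small}")
    model.fit_info = {
        "converged": converged,
        "n_iter": n_iter,
        "log_likelihood": final_ll,
        "loglik_history": history,
    }
    return model


# ---------------------------------------------------------------------------
# standard errors (single group)


def _flatten_params(model: GPCMModel) -> np.ndarray:
    return np.concatenate([np.concatenate([[it.a], it.b]) for it in model.items])


def _unflatten_params(model: GPCMModel, x: np.ndarray) -> GPCMModel:
    out = model.copy()
    pos = 0
    for it in out.items:
        k = 1 + it.b.size
        it.a = x[pos]
        it.b = x[pos + 1 : pos + k].copy()
        pos += k
    return out


def _single_group_score(model: GPCMModel, X: np.ndarray, onehots) -> np.ndarray:
    """Analytic gradient of the marginal log-likelihood in all item params."""
    W, _ = _posterior_weights(model, X)
    grads = []
    for j, it in enumerate(model.items):
        R = onehots[j] @ W
        negf, neggrad = _item_objective_grad(
            np.concatenate([[it.a], it.b]), R, model.quad_points
        )
        grads.append(-neggrad)
    return np.concatenate(grads)


def gpcm_standard_errors(model: GPCMModel, data, step: float = 1e-4):
    """Observed-information standard errors of all item parameters.

    The Hessian is obtained by central finite differences of the analytic
    marginal-likelihood gradient; returns (se_vector, covariance).
    """
    data = as_response_matrix(data)
    X = data.zero_based()
    X = X[~(X < 0).all(axis=1)]
    m = data.n_categories
    onehots = [
        (X[:, j][None, :] == np.arange(m)[:, None]).astype(float)
        for j in range(X.shape[1])
    ]
    x0 = _flatten_params(model)
    P = x0.size
    H = np.empty((P, P))
    for k in range(P):
        for sign, store in ((1.0, "plus"), (-1.0, "minus")):
            xk = x0.copy()
            xk[k] += sign * step
            g = _single_group_score(_unflatten_params(model, xk), X, onehots)
            if store == "plus":
                gp = g
            else:
                gm = g
        H[:, k] = (gp - gm) / (2 * step)
    H = 0.5 * (H + H.T)
    cov = np.linalg.inv(-H)
    return np.sqrt(np.clip(np.diag(cov), 0, None)), cov


# ---------------------------------------------------------------------------
# estimator


class GPCM(BaseEstimator, TransformerMixin):
    """Generalized partial credit model estimator.

    ``fit`` runs MML-EM on an (n_persons, n_items) integer response matrix
    (categories 1..m, NaN missing); ``transform`` returns EAP trait scores.

    Attributes
    ----------
    model_ : GPCMModel
        The fitted measurement model.
    discrimination_ : ndarray of shape (n_items,)
    difficulties_ : ndarray of shape (n_items, m - 1)
    log_likelihood_ : float
    converged_ : bool
    n_iter_ : int
    loglik_history_ : list of float
        Marginal log-likelihood at each EM iteration (non-decreasing).
    """

    def __init__(
        self,
        n_categories: int | None = None,
        max_iter: int = 500,
        tol: float = 1e-4,
        n_quadrature: int = 61,
        quad_range: tuple[float, float] = (-6.0, 6.0),
    ):
        self.n_categories = n_categories
        self.max_iter = max_iter
        self.tol = tol
        self.n_quadrature = n_quadrature
        self.quad_range = quad_range

    def fit(self, X, y=None):
        data = as_response_matrix(X, self.n_categories)
        self.model_ = fit_gpcm(
            data,
            n_categories=self.n_categories,
            max_iter=self.max_iter,
            tol=self.tol,
            n_quadrature=self.n_quadrature,
            quad_range=self.quad_range,
        )
        self.n_features_in_ = data.n_items
        self.discrimination_ = self.model_.discriminations()
        self.difficulties_ = np.vstack([it.b for it in self.model_.items])
        info = self.model_.fit_info
        self.log_likelihood_ = info["log_likelihood"]
        self.converged_ = info["converged"]
        self.n_iter_ = info["n_iter"]
        self.loglik_history_ = info["loglik_history"]
        return self

    def transform(self, X) -> np.ndarray:
        """EAP trait scores, shape (n_persons, 1)."""
        return eap_scores(self.model_, as_response_matrix(X, self.n_categories)).reshape(-1, 1)

    def score(self, X, y=None) -> float:
        """Mean marginal log-likelihood per person."""
        data = as_response_matrix(X, self.n_categories)
        return marginal_log_likelihood(self.model_, data) / data.n_persons

    def information_profile(self, grid=None, subset=None) -> InformationProfile:
        return test_information(self.model_, subset=subset, grid=grid)
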