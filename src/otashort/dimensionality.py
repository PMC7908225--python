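"""Essential-unidimensionality screening for ordinal scales.

Minimum-residual (ULS) factoring of the polychoric correlation matrix, with
Kaiser-Meyer-Olkin sampling adequacy, Bartlett's sphericity test, the
first-to-second eigenvalue ratio, first-factor variance explained, and
screening of items with negative first-factor loadings.

A scale is treated as essentially unidimensional when the eigenvalue ratio
exceeds 3 and the first factor explains at least 20% of the total variance;
items loading negatively on the first factor run against the intended scale
orientation and are flagged for removal before IRT calibration.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import owens_t
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from .containers import as_response_matrix

__all__ = [
    "EFAResult",
    "UnidimensionalityDecision",
    "PolychoricEFA",
    "bivariate_normal_cdf",
    "polychoric_pair",
    "polychoric_matrix",
    "kmo_statistic",
    "bartlett_sphericity",
    "minres_efa",
    "unidimensionality_check",
]


# ---------------------------------------------------------------------------
# bivariate normal CDF via Owen's T


def bivariate_normal_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen's-T formulation; ``h`` and ``k`` broadcast. Exact zeros in the
    thresholds are perturbed by 1e-13 to keep the sign bookkeeping of the
    formula single-branch.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if abs(rho) >= 1 - 1e-12:
        if rho > 0:
            return norm.cdf(np.minimum(h, k))
        return np.clip(norm.cdf(h) + norm.cdf(k) - 1.0, 0.0, None)
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)
    denom = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    beta = np.where(h * k < 0, 0.5, np.where((h * k == 0) & (h + k < 0), 0.5, 0.0))
    out = 0.5 * (norm.cdf(h) + norm.cdf(k)) - owens_t(h, ah) - owens_t(k, ak) - beta
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# polychoric correlations (two-step ML)

_CLIP = 8.0  # effectively +/- infinity for standard-normal thresholds


def _thresholds(counts: np.ndarray) -> np.ndarray:
    """Interior normal-quantile thresholds from marginal counts, with the
    outer sentinels at +/- 8; length len(counts) + 1."""
    cum = np.cumsum(counts) / counts.sum()
    inner = norm.ppf(np.clip(cum[:-1], 1e-12, 1 - 1e-12))
    return np.concatenate([[-_CLIP], np.clip(inner, -_CLIP, _CLIP), [_CLIP]])


def polychoric_pair(x, y) -> float:
    """Two-step polychoric correlation of two ordinal variables.

    Thresholds come from the marginal normal quantiles; the correlation is
    the 1-D maximizer of the bivariate-normal cell likelihood. Empty
    categories collapse automatically (only observed categories enter the
    table); a variable left with fewer than two observed categories is
    degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    xcats, xi = np.unique(x, return_inverse=True)
    ycats, yi = np.unique(y, return_inverse=True)
    if xcats.size < 2 or ycats.size < 2:
        raise ValueError("degenerate pair: a variable has < 2 observed categories")
    table = np.zeros((xcats.size, ycats.size))
    np.add.at(table, (xi, yi), 1.0)
    tx = _thresholds(table.sum(axis=1))
    ty = _thresholds(table.sum(axis=0))

    def negll(rho: float) -> float:
        F = bivariate_normal_cdf(tx[:, None], ty[None, :], rho)
        cell = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
        return -float(np.sum(table * np.log(np.clip(cell, 1e-300, None))))

    res = optimize.minimize_scalar(
        negll, bounds=(-0.9999, 0.9999), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def polychoric_matrix(data) -> np.ndarray:
    """Pairwise polychoric correlation matrix (symmetric, unit diagonal)."""
    data = as_response_matrix(data)
    vals = data.responses.to_numpy()
    p = data.n_items
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            try:
                r = polychoric_pair(vals[:, i], vals[:, j])
            except ValueError as err:
                raise ValueError(
                    f"polychoric failed for pair "
                    f"({data.item_names[i]}, {data.item_names[j]}): {err}"
                ) from err
            R[i, j] = R[j, i] = r
    return R


# ---------------------------------------------------------------------------
# adequacy statistics


def kmo_statistic(corr: np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin sampling adequacy.

    KMO = sum r^2_off / (sum r^2_off + sum q^2_off) with q the anti-image
    partial correlations.
    """
    R = np.asarray(corr, dtype=float)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise ValueError("correlation matrix is singular") from err
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = float(np.sum(R[off] ** 2))
    q2 = float(np.sum(Q[off] ** 2))
    return r2 / (r2 + q2)


def bartlett_sphericity(corr: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: (chi2 statistic, df, p-value)."""
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need more observations than variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(stat), int(df), float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# minres factoring


@dataclasses.dataclass
class EFAResult:
    """Output of minimum-residual factoring of a polychoric matrix."""

    polychoric: np.ndarray
    loadings: np.ndarray  # (p, n_factors)
    eigenvalues: np.ndarray  # of the polychoric matrix, descending
    variance_explained: np.ndarray  # per factor, fraction of p
    communalities: np.ndarray
    kmo: float | None = None
    bartlett: tuple[float, int, float] | None = None
    flagged_items: tuple[int, ...] = ()
    objective: float = np.nan

    def to_json(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "communalities": self.communalities.tolist(),
            "kmo": self.kmo,
            "bartlett": None if self.bartlett is None else list(self.bartlett),
            "flagged_items": list(self.flagged_items),
            "objective": self.objective,
        }


def _minres_loadings(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    """Loadings from the reduced matrix R - diag(psi), top-k eigenpairs."""
    Rr = R - np.diag(psi)
    evals, evecs = np.linalg.eigh(Rr)
    order = np.argsort(evals)[::-1][:k]
    lam = evecs[:, order] * np.sqrt(np.clip(evals[order], 0.0, None))
    return lam


def _minres_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    lam = _minres_loadings(R, psi, k)
    resid = R - lam @ lam.T
    off = ~np.eye(R.shape[0], dtype=bool)
    return float(np.sum(resid[off] ** 2)) / 2.0


def minres_efa(
    corr: np.ndarray,
    n_factors: int = 1,
    n: int | None = None,
    psi0: np.ndarray | None = None,
) -> EFAResult:
    """Minimum-residual (ULS) exploratory factor analysis.

    Minimizes the sum of squared off-diagonal residuals of ``R - LL'`` over
    the uniquenesses. Heywood cases (communality reaching 1) are clamped
    with a warning. The sign of each factor is fixed so the loading sum is
    non-negative. Eigenvalues reported for the ratio criterion are those of
    the raw polychoric matrix.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    ledermann = (2 * p + 1 - np.sqrt(8 * p + 1)) / 2
    if not 1 <= n_factors <= ledermann:
        raise ValueError(f"n_factors must be in [1, {int(ledermann)}]")
    if psi0 is None:
        try:
            smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
        except np.linalg.LinAlgError:
            smc = np.full(p, 0.5)
        psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(
        _minres_objective,
        psi0,
        args=(R, n_factors),
        method="L-BFGS-B",
        bounds=[(1e-4, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
    )
    psi = res.x
    if np.any(psi <= 2e-4):
        warnings.warn("Heywood case: communality clamped at 1 for some item(s)")
    lam = _minres_loadings(R, psi, n_factors)
    for f in range(n_factors):
        if lam[:, f].sum() < 0:
            lam[:, f] = -lam[:, f]
    evals = np.sort(np.linalg.eigvalsh(R))[::-1]
    communal = np.sum(lam**2, axis=1)
    var_expl = np.sum(lam**2, axis=0) / p
    flagged = tuple(int(i) for i in np.where(lam[:, 0] < 0)[0])
    kmo = kmo_statistic(R)
    bart = bartlett_sphericity(R, n) if n is not None else None
    return EFAResult(
        polychoric=R,
        loadings=lam,
        eigenvalues=evals,
        variance_explained=var_expl,
        communalities=communal,
        kmo=kmo,
        bartlett=bart,
        flagged_items=flagged,
        objective=float(res.fun),
    )


@dataclasses.dataclass
class UnidimensionalityDecision:
    """Pure function of an EFAResult: the unidimensionality gate."""

    passed: bool
    eigenvalue_ratio: float
    ratio_ok: bool
    variance_first: float
    variance_ok: bool
    remove_items: tuple[int, ...]

    def to_json(self) -> dict:
        return dataclasses.asdict(self) | {"remove_items": list(self.remove_items)}


def unidimensionality_check(
    efa: EFAResult,
    ratio_threshold: float = 3.0,
    variance_threshold: float = 0.20,
) -> UnidimensionalityDecision:
    """Essential unidimensionality: first/second eigenvalue ratio above the
    threshold AND first-factor variance explained at or above the minimum.
    Also returns the negative-first-factor-loading items to remove."""
    if efa.eigenvalues.size < 2:
        raise ValueError("need at least two eigenvalues")
    ratio = float(efa.eigenvalues[0] / efa.eigenvalues[1])
    var1 = float(efa.variance_explained[0])
    ratio_ok = ratio > ratio_threshold
    var_ok = var1 >= variance_threshold
    return UnidimensionalityDecision(
        passed=bool(ratio_ok and var_ok),
        eigenvalue_ratio=ratio,
        ratio_ok=bool(ratio_ok),
        variance_first=var1,
        variance_ok=bool(var_ok),
        remove_items=efa.flagged_items,
    )


# ---------------------------------------------------------------------------
# estimator


class PolychoricEFA(BaseEstimator):
    """Unidimensionality screen as a feature-selecting estimator.

    ``fit`` computes the polychoric matrix, KMO, Bartlett's test and the
    minres solution; ``transform`` drops items with negative first-factor
    loadings.

    Attributes
    ----------
    polychoric_ : (p, p) ndarray
    loadings_ : (p, n_factors) ndarray
    eigenvalues_ : ndarray
    variance_explained_ : ndarray
    kmo_ : float
    bartlett_ : (statistic, df, p_value)
    result_ : EFAResult
    decision_ : UnidimensionalityDecision
    support_ : boolean mask of retained items
    """

    def __init__(
        self,
        n_factors: int = 1,
        ratio_threshold: float = 3.0,
        variance_threshold: float = 0.20,
    ):
        self.n_factors = n_factors
        self.ratio_threshold = ratio_threshold
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        data = as_response_matrix(X)
        R = polychoric_matrix(data)
        self.result_ = minres_efa(R, self.n_factors, n=data.n_persons)
        self.polychoric_ = self.result_.polychoric
        self.loadings_ = self.result_.loadings
        self.eigenvalues_ = self.result_.eigenvalues
        self.variance_explained_ = self.result_.variance_explained
        self.kmo_ = self.result_.kmo
        self.bartlett_ = self.result_.bartlett
        self.decision_ = unidimensionality_check(
            self.result_, self.ratio_threshold, self.variance_threshold
        )
        self.n_features_in_ = data.n_items
        self.support_ = np.ones(data.n_items, dtype=bool)
        self.support_[list(self.decision_.remove_items)] = False
        return self

    def transform(self, X):
        keep = np.where(self.support_)[0]
        data = as_response_matrix(X)
        return data.subset(keep)
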