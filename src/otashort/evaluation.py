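"""Short-form evaluation: reliability, score correlations, convergent
validity, one-factor CFA fit, and test-information retention.

Cronbach's alpha comes with a Feldt F-based 95% interval; Pearson
correlations with Fisher-z intervals. The confirmatory factor model treats
the Likert items as continuous and fits a single factor by maximum
likelihood to the Pearson covariance matrix, reporting chi-square, RMSEA
(with 90% noncentral-chi-square interval), SRMR (standardized residuals
including the diagonal) and CFI against the independence baseline. Test
information retention is the subset's integrated information as a
percentage of the full scale's, over the entire ability range and over
(-3, 3).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, ncx2, pearsonr
from sklearn.base import BaseEstimator

from .containers import as_response_matrix
from .gpcm import GPCMModel, fit_gpcm, test_integrated_information

__all__ = [
    "CFAResult",
    "OneFactorCFA",
    "ShortFormEvaluation",
    "cronbach_alpha",
    "cronbach_alpha_from_cov",
    "correlation_with_ci",
    "cfa_one_factor",
    "information_retention",
    "evaluate_short_form",
    "information_curve_table",
]


# ---------------------------------------------------------------------------
# reliability and correlations


def cronbach_alpha(
    data, subset: Sequence[int] | None = None, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Cronbach's alpha on complete cases with a Feldt F-based interval."""
    data = as_response_matrix(data)
    cols = data.responses if subset is None else data.responses.iloc[:, list(subset)]
    cols = cols.dropna()
    if cols.shape[1] < 2:
        raise ValueError("alpha needs at least 2 items")
    if cols.shape[0] < 3:
        raise ValueError("alpha needs at least 3 complete cases")
    if float(cols.sum(axis=1).var(ddof=1)) == 0:
        raise ValueError("zero total-score variance")
    import pingouin as pg

    alpha, bounds = pg.cronbach_alpha(data=cols, ci=ci)
    return float(alpha), (float(bounds[0]), float(bounds[1]))


def cronbach_alpha_from_cov(cov: np.ndarray) -> float:
    """Population alpha from an item covariance (or correlation) matrix."""
    C = np.asarray(cov, dtype=float)
    k = C.shape[0]
    total = float(C.sum())
    if total <= 0:
        raise ValueError("non-positive total variance")
    return k / (k - 1) * (1.0 - float(np.trace(C)) / total)


def correlation_with_ci(
    x, y, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = pearsonr(x, y)
    interval = res.confidence_interval(confidence_level=ci)
    return float(res.statistic), (float(interval.low), float(interval.high))


# ---------------------------------------------------------------------------
# one-factor CFA


@dataclasses.dataclass
class CFAResult:
    chi2: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    cfi: float
    loadings: np.ndarray
    uniquenesses: np.ndarray
    n_obs: int
    fmin: float
    converged: bool

    @property
    def adequate(self) -> bool:
        """Standard adequacy cutoffs: RMSEA and SRMR at or below 0.08, CFI
        at or above 0.90."""
        return self.rmsea <= 0.08 and self.srmr <= 0.08 and self.cfi >= 0.90

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["loadings"] = self.loadings.tolist()
        d["uniquenesses"] = self.uniquenesses.tolist()
        d["rmsea_ci90"] = list(self.rmsea_ci90)
        d["adequate"] = self.adequate
        return d


def _fml_and_grad(x: np.ndarray, S: np.ndarray, logdet_S: float):
    p = S.shape[0]
    lam, psi = x[:p], x[p:]
    Sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return 1e10, np.zeros_like(x)
    Sinv = np.linalg.inv(Sigma)
    F = logdet + float(np.trace(Sinv @ S)) - logdet_S - p
    G = Sinv @ (Sigma - S) @ Sinv
    return F, np.concatenate([2.0 * (G @ lam), np.diag(G)])


def _fit_one_factor_ml(S: np.ndarray, x0: np.ndarray | None = None):
    """Minimize the ML discrepancy F(S, lambda lambda' + diag(psi))."""
    p = S.shape[0]
    _, logdet_S = np.linalg.slogdet(S)
    if x0 is None:
        evals, evecs = np.linalg.eigh(S)
        lam0 = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-6)) * 0.9
        if lam0.sum() < 0:
            lam0 = -lam0
        psi0 = np.clip(np.diag(S) - lam0**2, 0.05 * np.diag(S), None)
        x0 = np.concatenate([lam0, psi0])
    res = optimize.minimize(
        _fml_and_grad,
        x0,
        args=(S, logdet_S),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(1e-8, None)] * p,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res


def cfa_one_factor(data, subset: Sequence[int] | None = None) -> CFAResult:
    """One-factor CFA of (a subset of) the items, treated as continuous.

    Maximum likelihood on the Pearson covariance matrix of complete cases;
    chi-square is ``(n - 1) F_ML`` at the minimum. Non-convergence is
    flagged in the result, not raised.
    """
    data = as_response_matrix(data)
    cols = data.responses if subset is None else data.responses.iloc[:, list(subset)]
    cols = cols.dropna()
    n, p = cols.shape
    if p < 4:
        raise ValueError("CFA needs at least 4 items for positive df")
    if n <= p:
        raise ValueError("CFA needs more observations than items")
    S = np.cov(cols.to_numpy(), rowvar=False, ddof=1)
    res = _fit_one_factor_ml(S)
    lam, psi = res.x[:p], res.x[p:]
    if lam.sum() < 0:
        lam = -lam
    fmin = max(float(res.fun), 0.0)
    chisq = (n - 1) * fmin
    df = p * (p + 1) // 2 - 2 * p
    p_value = float(chi2.sf(chisq, df))

    rmsea = float(np.sqrt(max(chisq - df, 0.0) / (df * (n - 1))))
    rmsea_ci = _rmsea_interval(chisq, df, n)

    Sigma = np.outer(lam, lam) + np.diag(psi)
    d = np.sqrt(np.diag(S))
    std_resid = (S - Sigma) / np.outer(d, d)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(std_resid[iu] ** 2)))

    # independence baseline
    _, logdet_S = np.linalg.slogdet(S)
    F_base = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chisq_b = (n - 1) * F_base
    df_b = p * (p - 1) // 2
    denom = max(chisq_b - df_b, chisq - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chisq - df, 0.0) / denom

    return CFAResult(
        chi2=float(chisq),
        df=int(df),
        p_value=p_value,
        rmsea=rmsea,
        rmsea_ci90=rmsea_ci,
        srmr=srmr,
        cfi=float(cfi),
        loadings=lam,
        uniquenesses=psi,
        n_obs=int(n),
        fmin=fmin,
        converged=bool(res.success),
    )


def _rmsea_interval(chisq: float, df: int, n: int, level: float = 0.90):
    """90% RMSEA interval by inverting the noncentral chi-square."""
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2

    def solve(target: float) -> float:
        if ncx2.cdf(chisq, df, 1e-10) < target:
            return 0.0
        hi = max(chisq * 2, 10.0)
        while ncx2.cdf(chisq, df, hi) > target:
            hi *= 2
            if hi > 1e8:
                break
        return float(optimize.brentq(lambda nc: ncx2.cdf(chisq, df, nc) - target, 1e-10, hi))

    nc_lo = solve(lo_q)
    nc_hi = solve(hi_q)
    scale = df * (n - 1)
    return (float(np.sqrt(nc_lo / scale)), float(np.sqrt(nc_hi / scale)))


class OneFactorCFA(BaseEstimator):
    """One-factor confirmatory factor model as an estimator.

    Attributes after ``fit``: ``result_`` (CFAResult) plus the usual
    ``loadings_``, ``chi2_``, ``rmsea_``, ``srmr_``, ``cfi_`` shortcuts.
    """

    def fit(self, X, y=None):
        self.result_ = cfa_one_factor(as_response_matrix(X))
        self.loadings_ = self.result_.loadings
        self.chi2_ = self.result_.chi2
        self.rmsea_ = self.result_.rmsea
        self.srmr_ = self.result_.srmr
        self.cfi_ = self.result_.cfi
        return self

    def score(self, X, y=None) -> float:
        """Negative ML discrepancy (higher is better)."""
        return -self.result_.fmin


# ---------------------------------------------------------------------------
# information retention and the full evaluation


def information_retention(subset_total: float, full_total: float) -> float:
    """Percentage of test information retained, to one decimal."""
    if full_total <= 0:
        raise ValueError("full-scale information must be positive")
    return round(100.0 * subset_total / full_total, 1)


@dataclasses.dataclass
class ShortFormEvaluation:
    """Evaluation of one candidate subset on one sample."""

    alpha: tuple[float, tuple[float, float]]
    r_summed: tuple[float, tuple[float, float]] | None
    r_factor: tuple[float, tuple[float, float]] | None
    r_convergent: dict[str, tuple[float, tuple[float, float]]]
    cfa: CFAResult
    info_retention: dict[str, float]
    subset_information: dict[str, float]
    full_information: dict[str, float]

    def to_json(self) -> dict:
        def tup(t):
            return None if t is None else {"estimate": t[0], "ci": list(t[1])}

        return {
            "alpha": tup(self.alpha),
            "r_summed": tup(self.r_summed),
            "r_factor": tup(self.r_factor),
            "r_convergent": {k: tup(v) for k, v in self.r_convergent.items()},
            "cfa": self.cfa.to_json(),
            "info_retention": self.info_retention,
            "subset_information": self.subset_information,
            "full_information": self.full_information,
        }


def _information_totals(model: GPCMModel) -> dict[str, float]:
    return {
        "full_range": test_integrated_information(model, theta_range=None),
        "theta_-3_3": test_integrated_information(model, theta_range=(-3.0, 3.0)),
    }


def evaluate_short_form(
    train,
    test,
    subset: Sequence[int],
    *,
    full_model: GPCMModel | None = None,
    info_reference_train: GPCMModel | None = None,
    info_reference_test: GPCMModel | None = None,
) -> tuple[ShortFormEvaluation, ShortFormEvaluation]:
    """Full evaluation of a subset on the training and test samples.

    Training sample: alpha with CI, summed- and factor-score correlations
    with the full (comparison) scale, convergent correlations with every
    covariate, one-factor CFA, and information retention. Test sample:
    alpha, CFA and information retention. Subset information uses a GPCM
    refit on the subset (final-report convention); the retention
    denominator comes from ``info_reference_*`` (defaulting to a model of
    all items in the given sample), so the full original scale can serve
    as the reference even after DIF screening.
    """
    train = as_response_matrix(train)
    test = as_response_matrix(test)
    subset = sorted(int(j) for j in subset)
    if full_model is None:
        full_model = fit_gpcm(train)
    if info_reference_train is None:
        info_reference_train = full_model
    if info_reference_test is None:
        info_reference_test = fit_gpcm(test)

    out = []
    for sample, is_train, reference in (
        (train, True, info_reference_train),
        (test, False, info_reference_test),
    ):
        alpha = cronbach_alpha(sample, subset)
        sub_model = fit_gpcm(sample.subset(subset))
        sub_info = _information_totals(sub_model)
        full_info = _information_totals(reference)
        retention = {
            k: information_retention(sub_info[k], full_info[k]) for k in sub_info
        }
        cfa = cfa_one_factor(sample, subset)

        r_sum = r_fac = None
        convergent: dict = {}
        if is_train:
            from .gpcm import eap_scores

            cc = sample.complete_cases()
            vals = sample.responses.to_numpy()[cc]
            r_sum = correlation_with_ci(
                vals[:, subset].sum(axis=1), vals.sum(axis=1)
            )
            theta_full = eap_scores(full_model, sample)
            theta_sub = eap_scores(
                fit_gpcm(sample.subset(subset)), sample.subset(subset)
            )
            r_fac = correlation_with_ci(theta_sub, theta_full)
            if sample.covariates is not None:
                sums = sample.responses.iloc[:, subset].sum(axis=1, skipna=False)
                for name in sample.covariates.columns:
                    convergent[name] = correlation_with_ci(
                        sums.to_numpy(), sample.covariates[name].to_numpy()
                    )
        out.append(
            ShortFormEvaluation(
                alpha=alpha,
                r_summed=r_sum,
                r_factor=r_fac,
                r_convergent=convergent,
                cfa=cfa,
                info_retention=retention,
                subset_information=sub_info,
                full_information=full_info,
            )
        )
    return out[0], out[1]


def information_curve_table(
    models: dict[str, GPCMModel], grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Test-information curves (one column per labelled model) over theta,
    for side-by-side short-form comparisons."""
    from .gpcm import test_information

    if grid is None:
        grid = np.linspace(-3.0, 3.0, 121)
    df = pd.DataFrame({"theta": grid})
    for label, model in models.items():
        df[label] = test_information(model, grid=grid).total
    return df


def plot_information_curves(models: dict[str, GPCMModel], path=None, grid=None):
    """Plot test-information curves; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = information_curve_table(models, grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    for label in [c for c in table.columns if c != "theta"]:
        ax.plot(table["theta"], table[label], label=label)
    ax.set_xlabel(r"latent trait $\theta$")
    ax.set_ylabel("test information")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
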