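"""Gender differential item functioning by the iterative Wald approach.

Stage 1 (Wald-2, all-others-as-anchors): for each studied item, a joint
two-group GPCM is fitted with every other item constrained equal across
groups and the studied item free; the focal-vs-reference parameter
difference is tested with a chi-square Wald statistic. Stage 2 (Wald-1):
the five invariance-screened items with the largest discriminations
(MaxA5) are fixed as anchors, every other item is freed and tested, and
items with p below the significance level are removed.

The reference group's latent trait is fixed to N(0, 1); the focal group's
mean and variance are estimated so that true group impact is not mistaken
for item DIF. Parameter covariances come from the observed information,
computed by central finite differences of the analytic marginal-likelihood
gradient.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2, false_discovery_control, norm
from sklearn.base import BaseEstimator

from .containers import ResponseMatrix, as_response_matrix
from .gpcm import (
    GPCMItem,
    GPCMModel,
    _item_objective_grad,
    _log_prob_table,
    _optimize_item,
    _starting_values,
    default_quadrature,
)

__all__ = [
    "MultigroupGPCMFit",
    "DIFReport",
    "WaldDIFDetector",
    "multigroup_fit",
    "wald_item_test",
    "select_anchors_maxA5",
    "iterative_wald",
]


# ---------------------------------------------------------------------------
# joint two-group fit


@dataclasses.dataclass
class MultigroupGPCMFit:
    """Joint reference/focal GPCM fit with shared and free item blocks."""

    items_ref: list[GPCMItem]
    items_focal: list[GPCMItem]
    free_items: tuple[int, ...]
    shared_items: tuple[int, ...]
    focal_mean: float
    focal_sd: float
    estimate_focal_prior: bool
    quad_points: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    n_categories: int
    # data retained for covariance computation
    _X: np.ndarray = dataclasses.field(repr=False, default=None)
    _group: np.ndarray = dataclasses.field(repr=False, default=None)
    _cov: np.ndarray | None = dataclasses.field(repr=False, default=None)

    # -- parameter bookkeeping --------------------------------------------

    def _layout(self) -> tuple[dict, int]:
        """Map item -> (ref_slice, focal_slice); shared items share one."""
        layout: dict[int, tuple[slice, slice]] = {}
        pos = 0
        k = self.n_categories  # params per item block: 1 + (m - 1) = m
        for j in range(len(self.items_ref)):
            if j in self.free_items:
                sr = slice(pos, pos + k)
                sf = slice(pos + k, pos + 2 * k)
                pos += 2 * k
            else:
                sr = sf = slice(pos, pos + k)
                pos += k
            layout[j] = (sr, sf)
        if self.estimate_focal_prior:
            pos += 2
        return layout, pos

    def parameter_vector(self) -> np.ndarray:
        layout, size = self._layout()
        x = np.empty(size)
        for j, (sr, sf) in layout.items():
            x[sr] = np.concatenate([[self.items_ref[j].a], self.items_ref[j].b])
            if j in self.free_items:
                x[sf] = np.concatenate([[self.items_focal[j].a], self.items_focal[j].b])
        if self.estimate_focal_prior:
            x[-2], x[-1] = self.focal_mean, self.focal_sd
        return x

    def _unpack(self, x: np.ndarray):
        layout, _ = self._layout()
        ref, focal = [], []
        for j in range(len(self.items_ref)):
            sr, sf = layout[j]
            ref.append(GPCMItem(x[sr][0], x[sr][1:]))
            focal.append(GPCMItem(x[sf][0], x[sf][1:]))
        if self.estimate_focal_prior:
            mu, sd = float(x[-2]), float(x[-1])
        else:
            mu, sd = self.focal_mean, self.focal_sd
        return ref, focal, mu, sd

    def ref_model(self) -> GPCMModel:
        return GPCMModel(items=[it.copy() for it in self.items_ref])

    def focal_model(self) -> GPCMModel:
        m = GPCMModel(
            items=[it.copy() for it in self.items_focal],
            prior_mean=self.focal_mean,
            prior_var=self.focal_sd**2,
        )
        return m

    # -- covariance --------------------------------------------------------

    def _score(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient of the total marginal log-likelihood at x."""
        ref, focal, mu, sd = self._unpack(x)
        t = self.quad_points
        m = self.n_categories
        layout, size = self._layout()
        grad = np.zeros(size)
        counts: dict[int, list[np.ndarray | None]] = {}
        mq_focal = None
        nf = 0
        for g, items, (pm, psd) in (
            (0, ref, (0.0, 1.0)),
            (1, focal, (mu, sd)),
        ):
            rows = self._group == g
            Xg = self._X[rows]
            if Xg.shape[0] == 0:
                continue
            w = norm.pdf(t, loc=pm, scale=psd)
            w = w / w.sum()
            L = np.zeros((Xg.shape[0], t.size))
            for j, it in enumerate(items):
                tab = np.vstack([_log_prob_table(it.a, it.b, t), np.zeros((1, t.size))])
                L += tab[Xg[:, j], :]
            lw = L + np.log(w)[None, :]
            W = np.exp(lw - logsumexp(lw, axis=1)[:, None])
            for j in range(len(items)):
                onehot = (Xg[:, j][None, :] == np.arange(m)[:, None]).astype(float)
                counts.setdefault(j, [None, None])[g] = onehot @ W
            if g == 1:
                mq_focal = W.sum(axis=0)
                nf = Xg.shape[0]
        for j in range(len(ref)):
            sr, sf = layout[j]
            Rr, Rf = counts[j]
            if j in self.free_items:
                for sl, items, R in ((sr, ref, Rr), (sf, focal, Rf)):
                    if R is None:
                        continue
                    xblk = np.concatenate([[items[j].a], items[j].b])
                    _, ng = _item_objective_grad(xblk, R, t)
                    grad[sl] += -ng
            else:
                R = (Rr if Rr is not None else 0) + (Rf if Rf is not None else 0)
                xblk = np.concatenate([[ref[j].a], ref[j].b])
                _, ng = _item_objective_grad(xblk, R, t)
                grad[sr] += -ng
        if self.estimate_focal_prior and mq_focal is not None:
            z = (t - mu) / sd
            w = norm.pdf(z)
            w = w / w.sum()
            dmu = z / sd
            dsd = (z**2 - 1.0) / sd
            grad[-2] = float(mq_focal @ dmu - nf * (w @ dmu))
            grad[-1] = float(mq_focal @ dsd - nf * (w @ dsd))
        return grad

    def covariance(self, step: float = 1e-4) -> np.ndarray:
        """Inverse observed information of the full parameter vector."""
        if self._cov is not None:
            return self._cov
        x0 = self.parameter_vector()
        P = x0.size
        H = np.empty((P, P))
        for k in range(P):
            xp = x0.copy()
            xp[k] += step
            xm = x0.copy()
            xm[k] -= step
            H[:, k] = (self._score(xp) - self._score(xm)) / (2 * step)
        H = 0.5 * (H + H.T)
        try:
            self._cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular information matrix in the joint two-group fit"
            ) from err
        return self._cov


def multigroup_fit(
    data,
    constrained_items: Sequence[int],
    free_items: Sequence[int],
    *,
    reference: str | None = None,
    estimate_focal_prior: bool = True,
    n_categories: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_quadrature: int = 61,
    quad_range: tuple[float, float] = (-6.0, 6.0),
    start: GPCMModel | MultigroupGPCMFit | None = None,
) -> MultigroupGPCMFit:
    """Joint MML fit of reference and focal groups.

    Constrained items share parameters across groups; free items get
    group-specific parameters. The reference prior is fixed N(0, 1); the
    focal mean and variance are estimated unless ``estimate_focal_prior``
    is False.
    """
    data = as_response_matrix(data, n_categories)
    if data.group is None:
        raise ValueError("DIF analysis requires group labels")
    constrained = tuple(sorted(int(j) for j in constrained_items))
    free = tuple(sorted(int(j) for j in free_items))
    if set(constrained) | set(free) != set(range(data.n_items)) or set(
        constrained
    ) & set(free):
        raise ValueError("constrained and free items must partition all items")

    m = n_categories or data.n_categories
    X = data.zero_based()
    g = data.group_indicator(reference)
    keep = ~(X < 0).all(axis=1)
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} person(s) with all responses missing"
        )
        X, g = X[keep], g[keep]
    nodes, _ = default_quadrature(n_quadrature, quad_range)
    J = data.n_items

    # starting values
    if isinstance(start, MultigroupGPCMFit):
        items_ref = [it.copy() for it in start.items_ref]
        items_focal = [it.copy() for it in start.items_focal]
        mu, sd = start.focal_mean, start.focal_sd
    elif isinstance(start, GPCMModel):
        items_ref = [it.copy() for it in start.items]
        items_focal = [it.copy() for it in start.items]
        mu, sd = 0.0, 1.0
    else:
        a0, b0 = _starting_values(X, m)
        items_ref = [GPCMItem(a0[j], b0[j], data.item_names[j]) for j in range(J)]
        items_focal = [it.copy() for it in items_ref]
        mu, sd = 0.0, 1.0
    for j in constrained:  # shared blocks start identical
        items_focal[j] = items_ref[j].copy()

    onehots = {
        grp: [
            (X[g == grp][:, j][None, :] == np.arange(m)[:, None]).astype(float)
            for j in range(J)
        ]
        for grp in (0, 1)
    }
    Xg = {grp: X[g == grp] for grp in (0, 1)}
    if Xg[0].shape[0] == 0 or Xg[1].shape[0] == 0:
        raise ValueError("both groups must be non-empty")

    converged = False
    ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step per group
        W = {}
        ll = 0.0
        for grp, items, (pm, psd) in (
            (0, items_ref, (0.0, 1.0)),
            (1, items_focal, (mu, sd)),
        ):
            w = norm.pdf(nodes, loc=pm, scale=psd)
            w = w / w.sum()
            L = np.zeros((Xg[grp].shape[0], nodes.size))
            for j, it in enumerate(items):
                tab = np.vstack(
                    [_log_prob_table(it.a, it.b, nodes), np.zeros((1, nodes.size))]
                )
                L += tab[Xg[grp][:, j], :]
            lw = L + np.log(w)[None, :]
            lp = logsumexp(lw, axis=1)
            ll += float(lp.sum())
            W[grp] = np.exp(lw - lp[:, None])

        # M-step
        delta = 0.0
        for j in range(J):
            Rr = onehots[0][j] @ W[0]
            Rf = onehots[1][j] @ W[1]
            if j in free:
                for items, R in ((items_ref, Rr), (items_focal, Rf)):
                    x0 = np.concatenate([[items[j].a], items[j].b])
                    x1 = _optimize_item(R, nodes, x0)
                    delta = max(delta, float(np.max(np.abs(x1 - x0))))
                    items[j].a, items[j].b = x1[0], x1[1:]
            else:
                x0 = np.concatenate([[items_ref[j].a], items_ref[j].b])
                x1 = _optimize_item(Rr + Rf, nodes, x0)
                delta = max(delta, float(np.max(np.abs(x1 - x0))))
                items_ref[j].a, items_ref[j].b = x1[0], x1[1:]
                items_focal[j] = items_ref[j].copy()
        if estimate_focal_prior:
            mq = W[1].sum(axis=0)
            nf = Xg[1].shape[0]
            mu_new = float(mq @ nodes / nf)
            var_new = float(mq @ (nodes - mu_new) ** 2 / nf)
            delta = max(delta, abs(mu_new - mu), abs(np.sqrt(var_new) - sd))
            mu, sd = mu_new, float(np.sqrt(max(var_new, 1e-6)))
        if delta < tol:
            converged = True
            break

    return MultigroupGPCMFit(
        items_ref=items_ref,
        items_focal=items_focal,
        free_items=free,
        shared_items=constrained,
        focal_mean=mu,
        focal_sd=sd,
        estimate_focal_prior=estimate_focal_prior,
        quad_points=nodes,
        log_likelihood=ll,
        converged=converged,
        n_iter=n_iter,
        n_categories=m,
        _X=X,
        _group=g,
    )


# ---------------------------------------------------------------------------
# Wald test


def wald_item_test(fit: MultigroupGPCMFit, item: int) -> tuple[float, int, float]:
    """Wald chi-square test of focal-vs-reference parameter equality.

    The statistic is ``d' V^-1 d`` with ``d`` the focal-minus-reference
    parameter difference of the studied item and ``V`` the corresponding
    covariance block; df equals the number of item parameters.
    """
    if item not in fit.free_items:
        raise ValueError(f"item {item} is not freely estimated in this fit")
    d = np.concatenate(
        [
            [fit.items_focal[item].a - fit.items_ref[item].a],
            fit.items_focal[item].b - fit.items_ref[item].b,
        ]
    )
    cov = fit.covariance()
    layout, _ = fit._layout()
    sr, sf = layout[item]
    ir = np.arange(sr.start, sr.stop)
    if_ = np.arange(sf.start, sf.stop)
    V = (
        cov[np.ix_(if_, if_)]
        + cov[np.ix_(ir, ir)]
        - cov[np.ix_(if_, ir)]
        - cov[np.ix_(ir, if_)]
    )
    try:
        stat = float(d @ np.linalg.solve(V, d))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"non-invertible covariance block for item {item}"
        ) from err
    stat = max(stat, 0.0)
    df = d.size
    return stat, df, float(chi2.sf(stat, df))


def select_anchors_maxA5(
    source, flagged: Sequence[int] = (), n_anchors: int = 5
) -> tuple[int, ...]:
    """MaxA5 anchor selection: the ``n_anchors`` non-flagged items with the
    largest discriminations, ties broken by lower item index.

    ``source`` may be a GPCMModel, a MultigroupGPCMFit (reference/shared
    parameters are used) or a plain discrimination array.
    """
    if isinstance(source, MultigroupGPCMFit):
        a = np.array([it.a for it in source.items_ref])
    elif isinstance(source, GPCMModel):
        a = source.discriminations()
    else:
        a = np.asarray(source, dtype=float)
    flagged = set(int(j) for j in flagged)
    eligible = [j for j in range(a.size) if j not in flagged]
    if len(eligible) < n_anchors:
        raise ValueError(
            f"only {len(eligible)} eligible items for {n_anchors} anchors; "
            "relax the flagging rule or reduce the anchor count"
        )
    ranked = sorted(eligible, key=lambda j: (-a[j], j))
    return tuple(ranked[:n_anchors])


# ---------------------------------------------------------------------------
# iterative procedure


@dataclasses.dataclass
class DIFReport:
    """Decision trail of the two-stage iterative Wald procedure."""

    wald2: pd.DataFrame  # item, statistic, df, p_value, flagged
    wald1: pd.DataFrame  # item, statistic, df, p_value, removed
    anchors: tuple[int, ...]
    removed: tuple[int, ...]
    focal_mean: float
    focal_sd: float
    alpha: float
    item_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.anchors) & set(self.removed):
            raise ValueError("anchors and removed items must be disjoint")

    def table(self) -> pd.DataFrame:
        """Human-readable long table: item, stage, statistic, df, p, decision."""
        w2 = self.wald2.assign(stage="wald2", decision=np.where(
            self.wald2["flagged"], "flagged", "invariant"))
        w1 = self.wald1.assign(stage="wald1", decision=np.where(
            self.wald1["removed"], "removed", "retained"))
        cols = ["item", "stage", "statistic", "df", "p_value", "decision"]
        return pd.concat([w2[cols], w1[cols]], ignore_index=True)

    def to_json(self) -> dict:
        return {
            "wald2": self.wald2.to_dict(orient="records"),
            "wald1": self.wald1.to_dict(orient="records"),
            "anchors": list(self.anchors),
            "removed": list(self.removed),
            "focal_mean": self.focal_mean,
            "focal_sd": self.focal_sd,
            "alpha": self.alpha,
            "item_names": list(self.item_names),
        }


def iterative_wald(
    data,
    *,
    alpha: float = 0.05,
    n_anchors: int = 5,
    reference: str | None = None,
    estimate_focal_prior: bool = True,
    bh_correction: bool = False,
    loop_until_stable: bool = False,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> tuple[DIFReport, ResponseMatrix]:
    """Two-stage iterative Wald DIF detection.

    Stage 1 tests every item with all others as anchors (Wald-2) and
    provisionally flags items at ``p < alpha``; the MaxA5 anchors are the
    top-discrimination non-flagged items. Stage 2 fixes the anchors, frees
    every other item and tests them (Wald-1); items at ``p < alpha`` are
    removed. Returns the report and the DIF-free response matrix.
    """
    data = as_response_matrix(data)
    if data.n_items < n_anchors + 2:
        raise ValueError("need at least n_anchors + 2 items")
    all_items = tuple(range(data.n_items))
    names = tuple(data.item_names)

    def adjust(p: np.ndarray) -> np.ndarray:
        return false_discovery_control(p) if bh_correction else p

    removed_total: list[int] = []
    current = data
    index_map = list(all_items)  # positions in the original data
    while True:
        J = current.n_items
        base = multigroup_fit(
            current,
            constrained_items=range(J),
            free_items=(),
            reference=reference,
            estimate_focal_prior=estimate_focal_prior,
            max_iter=max_iter,
            tol=tol,
        )
        # stage 1: all-others-as-anchors
        rows = []
        for j in range(J):
            fit_j = multigroup_fit(
                current,
                constrained_items=[k for k in range(J) if k != j],
                free_items=[j],
                reference=reference,
                estimate_focal_prior=estimate_focal_prior,
                max_iter=max_iter,
                tol=tol,
                start=base,
            )
            stat, df, p = wald_item_test(fit_j, j)
            rows.append((index_map[j], stat, df, p))
        wald2 = pd.DataFrame(rows, columns=["item", "statistic", "df", "p_value"])
        wald2["p_adjusted"] = adjust(wald2["p_value"].to_numpy())
        wald2["flagged"] = wald2["p_adjusted"] < alpha
        flagged_pos = list(np.where(wald2["flagged"])[0])

        # anchors among non-flagged, by discrimination of the pooled fit
        anchors_pos = select_anchors_maxA5(base, flagged_pos, n_anchors)

        # stage 2: fixed anchors, all non-anchors free
        studied_pos = [j for j in range(J) if j not in anchors_pos]
        fit1 = multigroup_fit(
            current,
            constrained_items=anchors_pos,
            free_items=studied_pos,
            reference=reference,
            estimate_focal_prior=estimate_focal_prior,
            max_iter=max_iter,
            tol=tol,
            start=base,
        )
        rows = []
        for j in studied_pos:
            stat, df, p = wald_item_test(fit1, j)
            rows.append((index_map[j], stat, df, p))
        wald1 = pd.DataFrame(rows, columns=["item", "statistic", "df", "p_value"])
        wald1["p_adjusted"] = adjust(wald1["p_value"].to_numpy())
        wald1["removed"] = wald1["p_adjusted"] < alpha
        removed_pos = [j for j, r in zip(studied_pos, wald1["removed"]) if r]

        removed_total.extend(index_map[j] for j in removed_pos)
        if not (loop_until_stable and removed_pos):
            report = DIFReport(
                wald2=wald2,
                wald1=wald1,
                anchors=tuple(index_map[j] for j in anchors_pos),
                removed=tuple(sorted(removed_total)),
                focal_mean=fit1.focal_mean,
                focal_sd=fit1.focal_sd,
                alpha=alpha,
                item_names=names,
            )
            keep = [j for j in range(J) if j not in removed_pos]
            return report, current.subset(keep)
        keep = [j for j in range(J) if j not in removed_pos]
        index_map = [index_map[j] for j in keep]
        current = current.subset(keep)


# ---------------------------------------------------------------------------
# estimator


class WaldDIFDetector(BaseEstimator):
    """DIF screen as a feature-selecting estimator.

    ``fit(X, y)`` takes the response matrix and the binary group labels
    (``y`` may be omitted when ``X`` is a ResponseMatrix carrying groups);
    ``transform`` drops the items flagged at the Wald-1 stage.

    Attributes
    ----------
    report_ : DIFReport
    anchors_ : tuple of int
    removed_ : tuple of int
    support_ : boolean mask of retained items
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_anchors: int = 5,
        reference: str | None = None,
        estimate_focal_prior: bool = True,
        bh_correction: bool = False,
        loop_until_stable: bool = False,
    ):
        self.alpha = alpha
        self.n_anchors = n_anchors
        self.reference = reference
        self.estimate_focal_prior = estimate_focal_prior
        self.bh_correction = bh_correction
        self.loop_until_stable = loop_until_stable

    def fit(self, X, y=None):
        data = as_response_matrix(X)
        if y is not None:
            data = dataclasses.replace(data, group=pd.Series(np.asarray(y)))
        self.report_, _ = iterative_wald(
            data,
            alpha=self.alpha,
            n_anchors=self.n_anchors,
            reference=self.reference,
            estimate_focal_prior=self.estimate_focal_prior,
            bh_correction=self.bh_correction,
            loop_until_stable=self.loop_until_stable,
        )
        self.anchors_ = self.report_.anchors
        self.removed_ = self.report_.removed
        self.n_features_in_ = data.n_items
        self.support_ = np.ones(data.n_items, dtype=bool)
        self.support_[list(self.removed_)] = False
        return self

    def transform(self, X):
        keep = np.where(self.support_)[0]
        return as_response_matrix(X).subset(keep)
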