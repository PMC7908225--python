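"""Containers for person x item ordinal response data.

A :class:`ResponseMatrix` bundles the integer response matrix (categories
``1..m``, NaN for missing) with the per-person group label used for DIF
analysis, optional convergent-validity covariates (e.g. personality scale
scores), per-item reverse-coding flags, and -- for simulated data -- the
true latent trait used to generate the responses.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix", "as_response_matrix"]


@dataclasses.dataclass
class ResponseMatrix:
    """Persons x items ordinal responses plus grouping and covariates.

    Parameters
    ----------
    responses
        DataFrame (or array-like) of integer categories in ``1..n_categories``;
        NaN marks a missing response. Columns are item names.
    group
        Optional per-person label with exactly two levels when DIF analysis
        is requested (e.g. gender).
    covariates
        Optional per-person real-valued scores used for convergent validity.
    reverse_flags
        Per-item booleans marking negatively worded items that must be
        recoded ``x -> m + 1 - x`` before scoring.
    n_categories
        Number of response categories ``m``; inferred from the data maximum
        when omitted.
    true_theta
        Simulation truth only: the latent trait values that generated the
        responses. Never produced for ingested data.
    """

    responses: pd.DataFrame
    group: pd.Series | None = None
    covariates: pd.DataFrame | None = None
    reverse_flags: np.ndarray | None = None
    n_categories: int | None = None
    true_theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        resp = pd.DataFrame(self.responses).reset_index(drop=True)
        if resp.shape[1] and not all(isinstance(c, str) for c in resp.columns):
            resp.columns = [f"item{j + 1:02d}" for j in range(resp.shape[1])]
        self.responses = resp.astype(float)
        vals = self.responses.to_numpy()
        obs = vals[~np.isnan(vals)]
        if self.n_categories is None:
            if obs.size == 0:
                raise ValueError("cannot infer n_categories from empty data")
            self.n_categories = int(np.max(obs))
        if obs.size and (
            (obs < 1).any()
            or (obs > self.n_categories).any()
            or np.any(obs != np.round(obs))
        ):
            raise ValueError(
                f"responses must be integers in 1..{self.n_categories}"
            )
        if self.reverse_flags is None:
            self.reverse_flags = np.zeros(self.n_items, dtype=bool)
        self.reverse_flags = np.asarray(self.reverse_flags, dtype=bool)
        if self.reverse_flags.shape != (self.n_items,):
            raise ValueError("reverse_flags length must equal item count")
        if self.group is not None:
            self.group = pd.Series(np.asarray(self.group)).reset_index(drop=True)
            if len(self.group) != self.n_persons:
                raise ValueError("group length must equal person count")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
            if len(self.covariates) != self.n_persons:
                raise ValueError("covariates length must equal person count")
        if self.true_theta is not None:
            self.true_theta = np.asarray(self.true_theta, dtype=float)
            if self.true_theta.shape != (self.n_persons,):
                raise ValueError("true_theta length must equal person count")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def item_names(self) -> list[str]:
        return list(self.responses.columns)

    def zero_based(self) -> np.ndarray:
        """Integer array with categories ``0..m-1``; missing coded ``-1``."""
        vals = self.responses.to_numpy()
        out = np.where(np.isnan(vals), 0.0, vals - 1.0).astype(np.int64)
        out[np.isnan(vals)] = -1
        return out

    def complete_cases(self, items: Sequence[int] | None = None) -> np.ndarray:
        """Boolean mask of persons with no missing response on ``items``."""
        cols = self.responses if items is None else self.responses.iloc[:, list(items)]
        return ~cols.isna().any(axis=1).to_numpy()

    def group_levels(self, reference: str | None = None) -> tuple[object, object]:
        """(reference, focal) group levels; reference defaults to the
        more frequent level (ties broken by sort order)."""
        if self.group is None:
            raise ValueError("no group labels present")
        counts = self.group.value_counts()
        levels = sorted(counts.index, key=lambda lv: (-counts[lv], str(lv)))
        if len(levels) != 2:
            raise ValueError(f"group must have exactly 2 levels, got {len(levels)}")
        if reference is not None:
            if reference not in levels:
                raise ValueError(f"reference level {reference!r} not found")
            focal = levels[0] if levels[1] == reference else levels[1]
            return reference, focal
        return levels[0], levels[1]

    def group_indicator(self, reference: str | None = None) -> np.ndarray:
        """0 for reference-group persons, 1 for focal-group persons."""
        ref, focal = self.group_levels(reference)
        return (self.group.to_numpy() == focal).astype(np.int64)

    # -- transformations ---------------------------------------------------

    def reverse_coded(self) -> "ResponseMatrix":
        """Recode flagged items ``x -> m + 1 - x`` and clear the flags."""
        resp = self.responses.copy()
        m = self.n_categories
        for j, flag in enumerate(self.reverse_flags):
            if flag:
                resp.iloc[:, j] = m + 1 - resp.iloc[:, j]
        return ResponseMatrix(
            responses=resp,
            group=None if self.group is None else self.group.copy(),
            covariates=None if self.covariates is None else self.covariates.copy(),
            reverse_flags=np.zeros(self.n_items, dtype=bool),
            n_categories=m,
            true_theta=None if self.true_theta is None else self.true_theta.copy(),
        )

    def subset(self, items: Sequence[int] | Sequence[str]) -> "ResponseMatrix":
        """New ResponseMatrix restricted to ``items`` (positions or names)."""
        items = list(items)
        if items and isinstance(items[0], str):
            positions = [self.item_names.index(name) for name in items]
        else:
            positions = [int(i) for i in items]
        return ResponseMatrix(
            responses=self.responses.iloc[:, positions].copy(),
            group=None if self.group is None else self.group.copy(),
            covariates=None if self.covariates is None else self.covariates.copy(),
            reverse_flags=self.reverse_flags[positions],
            n_categories=self.n_categories,
            true_theta=None if self.true_theta is None else self.true_theta.copy(),
        )

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write one row per person: id, group, items, covariates."""
        out = pd.DataFrame({"person_id": np.arange(1, self.n_persons + 1)})
        if self.group is not None:
            out["group"] = self.group.to_numpy()
        out = pd.concat([out, self.responses], axis=1)
        if self.covariates is not None:
            out = pd.concat([out, self.covariates], axis=1)
        out.to_csv(path, index=False)

    def write_truth(self, path: str | Path) -> None:
        """Simulation-truth sidecar (true theta); JSON."""
        if self.true_theta is None:
            raise ValueError("no simulation truth attached")
        payload = {
            "note": "simulation truth - latent trait values used to generate responses",
            "theta": [float(t) for t in self.true_theta],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        item_columns: Sequence[str] | None = None,
        group_column: str | None = "group",
        covariate_columns: Sequence[str] | None = None,
        reverse_items: Sequence[str] | None = None,
        n_categories: int | None = None,
    ) -> "ResponseMatrix":
        """Read a delimited response file written by :meth:`to_csv`.

        When ``item_columns`` is omitted, every column whose name starts
        with ``item`` is treated as an item.
        """
        df = pd.read_csv(path)
        if item_columns is None:
            item_columns = [c for c in df.columns if str(c).startswith("item")]
        if not item_columns:
            raise ValueError("no item columns found")
        group = None
        if group_column is not None and group_column in df.columns:
            group = df[group_column]
        covs = None
        if covariate_columns:
            covs = df[list(covariate_columns)]
        flags = np.zeros(len(item_columns), dtype=bool)
        if reverse_items:
            for name in reverse_items:
                flags[list(item_columns).index(name)] = True
        return cls(
            responses=df[list(item_columns)],
            group=group,
            covariates=covs,
            reverse_flags=flags,
            n_categories=n_categories,
        )


def as_response_matrix(X, n_categories: int | None = None) -> ResponseMatrix:
    """Coerce an array-like or ResponseMatrix into a ResponseMatrix."""
    if isinstance(X, ResponseMatrix):
        return X
    return ResponseMatrix(responses=pd.DataFrame(X), n_categories=n_categories)
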