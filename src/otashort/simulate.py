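"""GPCM response-data generator with known simulation truth.

Emulates community questionnaire samples: a 21-item, 6-category Likert
scale answered by several hundred respondents with a standard-normal latent
trait, item discriminations spanning roughly 0.12-1.7, optional group DIF
on selected items, reversed (negatively worded) items, and covariates
correlated about +0.27 / -0.11 with the trait, mimicking neuroticism and
extraversion scores. Every draw is reproducible from a single seed; the
true trait values and item parameters are retained for recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ResponseMatrix
from .gpcm import GPCMItem, GPCMModel, _log_prob_table

__all__ = [
    "SyntheticConfig",
    "generate_true_model",
    "inject_dif",
    "simulate_responses",
    "write_dataset",
]

_COVARIATE_NAMES = ("neuroticism", "extraversion")
# NEO-style 12-item, 5-point scale sums: range 12..60
_COVARIATE_MEAN, _COVARIATE_SD = 36.0, 7.0
_COVARIATE_RANGE = (12, 60)


@dataclasses.dataclass
class SyntheticConfig:
    """Settings of the response generator.

    Parameters
    ----------
    n_persons, n_items, n_categories
        Sample and instrument size; defaults emulate a 569-person telephone
        sample answering a 21-item, 6-category scale.
    discrimination_range
        (low, high) for uniform draws of item discriminations; ignored when
        explicit ``discriminations`` are supplied.
    discriminations
        Optional per-item discriminations overriding the uniform draw.
    threshold_spread
        Scale of the spread of step difficulties around each item's
        location; locations are standard-normal draws.
    dif_spec
        List of (item_index, parameter, focal_shift) tuples applied to the
        focal group only. ``parameter`` is ``"a"``, ``"b"`` (all thresholds)
        or ``"b<k>"`` for the k-th threshold (1-based).
    reversed_items
        0-based indices of negatively worded items; responses are recorded
        reversed and the reverse flag is set (recoded at ingest).
    miskeyed_items
        0-based indices recorded reversed but NOT flagged - items that run
        against the scale orientation and should be caught by the
        negative-loading screen.
    covariate_correlations
        Target correlations of each covariate with the latent trait.
    focal_fraction
        Probability of a person belonging to the focal group.
    focal_trait
        (mean, sd) of the focal group's latent trait (impact); equal to the
        reference (0, 1) by default.
    seed
        Single global seed; all stage substreams derive from it.
    """

    n_persons: int = 569
    n_items: int = 21
    n_categories: int = 6
    discrimination_range: tuple[float, float] = (0.12, 1.7)
    discriminations: Sequence[float] | None = None
    threshold_spread: float = 0.7
    dif_spec: list[tuple[int, str, float]] = dataclasses.field(default_factory=list)
    reversed_items: list[int] = dataclasses.field(default_factory=list)
    miskeyed_items: list[int] = dataclasses.field(default_factory=list)
    covariate_correlations: Sequence[float] = (0.27, -0.11)
    covariate_names: Sequence[str] | None = None
    focal_fraction: float = 0.37
    focal_trait: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("n_categories must be at least 2")
        lo, hi = self.discrimination_range
        if lo <= 0 or lo >= hi:
            raise ValueError("discrimination_range must satisfy 0 < low < high")
        if self.threshold_spread <= 0:
            raise ValueError("threshold_spread must be positive")
        for r in self.covariate_correlations:
            if not -1 < r < 1:
                raise ValueError("covariate correlations must lie in (-1, 1)")
        for idx, param, _ in self.dif_spec:
            if not 0 <= idx < self.n_items:
                raise ValueError(f"dif_spec references invalid item index {idx}")
            if param != "a" and not (
                param == "b" or (param.startswith("b") and param[1:].isdigit())
            ):
                raise ValueError(f"unknown DIF parameter {param!r}")
        for idx in list(self.reversed_items) + list(self.miskeyed_items):
            if not 0 <= idx < self.n_items:
                raise ValueError(f"invalid reversed/miskeyed item index {idx}")
        if not 0 <= self.focal_fraction <= 1:
            raise ValueError("focal_fraction must lie in [0, 1]")
        if self.discriminations is not None and len(self.discriminations) != self.n_items:
            raise ValueError("explicit discriminations must have length n_items")
        if self.covariate_names is None:
            names = list(_COVARIATE_NAMES)
            while len(names) < len(self.covariate_correlations):
                names.append(f"covariate{len(names) + 1}")
            self.covariate_names = tuple(names[: len(self.covariate_correlations)])


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_true_model(config: SyntheticConfig) -> GPCMModel:
    """Draw a GPCM with discriminations in the configured range and strictly
    increasing step difficulties centered near zero; deterministic per seed."""
    rng = _substreams(config.seed, 3)[0]
    J, m = config.n_items, config.n_categories
    if config.discriminations is not None:
        a = np.asarray(config.discriminations, dtype=float)
    else:
        a = rng.uniform(*config.discrimination_range, size=J)
    loc = rng.normal(0.0, 1.0, size=J)
    steps = np.sort(rng.normal(0.0, config.threshold_spread, size=(J, m - 1)), axis=1)
    steps += 1e-6 * np.arange(m - 1)[None, :]  # strictness under ties
    b = loc[:, None] + steps
    items = [GPCMItem(a[j], b[j], f"item{j + 1:02d}") for j in range(J)]
    return GPCMModel(items=items)


def inject_dif(model: GPCMModel, dif_spec: Sequence[tuple[int, str, float]]) -> GPCMModel:
    """Focal-group copy of ``model`` with additive parameter shifts.

    The reference model is left untouched. A shift that produces
    non-increasing thresholds or a non-positive discrimination is rejected.
    """
    focal = model.copy()
    for idx, param, shift in dif_spec:
        item = focal.items[idx]
        if param == "a":
            item.a = item.a + shift
            if item.a <= 0:
                raise ValueError(
                    f"DIF shift on item {idx} produces non-positive discrimination"
                )
        elif param == "b":
            item.b = item.b + shift
        else:
            k = int(param[1:]) - 1
            if not 0 <= k < item.b.size:
                raise ValueError(f"item {idx} has no threshold {param!r}")
            b = item.b.copy()
            b[k] += shift
            if np.any(np.diff(b) <= 0):
                raise ValueError(
                    f"DIF shift on item {idx} threshold {param} breaks ordering"
                )
            item.b = b
    return focal


def _sample_item(
    item: GPCMItem, theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw 0-based categories from the GPCM at each person's theta."""
    p = np.exp(_log_prob_table(item.a, item.b, theta))  # (m, N)
    u = rng.uniform(size=theta.size)
    return (p.cumsum(axis=0) < u[None, :]).sum(axis=0)


def simulate_responses(
    model: GPCMModel, config: SyntheticConfig, n_persons: int | None = None
) -> ResponseMatrix:
    """Simulate a sample from the generating model.

    Latent traits are standard normal in the reference group; the focal
    group (membership Bernoulli(``focal_fraction``)) responds under the
    DIF-shifted model when ``config.dif_spec`` is non-empty. Reversed and
    miskeyed items are recorded as ``m + 1 - x``. Covariates are jointly
    normal with the trait at the configured correlations and rescaled to
    NEO-like integer score sums. The true trait is retained in
    ``ResponseMatrix.true_theta``.
    """
    if model.n_items != config.n_items:
        raise ValueError("model and config item counts disagree")
    _, rng_resp, rng_cov = _substreams(config.seed, 3)
    N = config.n_persons if n_persons is None else int(n_persons)
    m = config.n_categories

    focal = rng_resp.uniform(size=N) < config.focal_fraction
    theta = rng_resp.normal(0.0, 1.0, size=N)
    mu_f, sd_f = config.focal_trait
    theta[focal] = mu_f + sd_f * rng_resp.normal(0.0, 1.0, size=int(focal.sum()))

    focal_model = inject_dif(model, config.dif_spec) if config.dif_spec else model

    X = np.empty((N, config.n_items), dtype=float)
    for j in range(config.n_items):
        x = np.empty(N, dtype=np.int64)
        ref_idx = ~focal
        x[ref_idx] = _sample_item(model.items[j], theta[ref_idx], rng_resp)
        x[focal] = _sample_item(focal_model.items[j], theta[focal], rng_resp)
        X[:, j] = x + 1  # categories 1..m

    flipped = set(config.reversed_items) | set(config.miskeyed_items)
    for j in flipped:
        X[:, j] = m + 1 - X[:, j]
    flags = np.zeros(config.n_items, dtype=bool)
    flags[list(config.reversed_items)] = True

    covs = {}
    for name, r in zip(config.covariate_names, config.covariate_correlations):
        latent = r * theta + np.sqrt(1 - r**2) * rng_cov.normal(size=N)
        score = np.clip(
            np.round(_COVARIATE_MEAN + _COVARIATE_SD * latent), *_COVARIATE_RANGE
        )
        covs[name] = score

    return ResponseMatrix(
        responses=pd.DataFrame(
            X, columns=[it.name or f"item{j + 1:02d}" for j, it in enumerate(model.items)]
        ),
        group=pd.Series(np.where(focal, "focal", "reference")),
        covariates=pd.DataFrame(covs) if covs else None,
        reverse_flags=flags,
        n_categories=m,
        true_theta=theta,
    )


def demo_scenario(seed: int = 0) -> SyntheticConfig:
    """A 21-item scenario with known planted structure.

    Eight high-discrimination items (a in 1.2-1.7) form the short-form
    core; the rest discriminate weakly (a in 0.4-0.6). Item 12 (0-based
    index 11) is miskeyed - generated against the scale orientation and
    not flagged - so the negative-loading screen must remove it. Item 5
    (index 4) carries gender DIF (focal threshold shift +1.0) and must be
    removed by the iterative Wald screen.
    """
    a = np.full(21, 0.5)
    core = [5, 6, 9, 10, 12, 17, 18, 20]
    a[core] = [1.45, 1.30, 1.70, 1.25, 1.35, 1.55, 1.60, 1.20]
    a[[4, 11]] = [0.80, 0.90]
    weak = [j for j in range(21) if j not in core + [4, 11]]
    a[weak] = np.linspace(0.40, 0.60, len(weak))
    return SyntheticConfig(
        discriminations=a,
        dif_spec=[(4, "b", 1.0)],
        miskeyed_items=[11],
        seed=seed,
    )


def write_dataset(config: SyntheticConfig, outdir: str | Path) -> ResponseMatrix:
    """Simulate one sample and write responses.csv plus a truth sidecar
    (true item parameters and trait values, clearly marked as simulation
    truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = generate_true_model(config)
    data = simulate_responses(model, config)
    data.to_csv(outdir / "responses.csv")
    truth = {
        "note": "simulation truth - generating parameters, not estimates",
        "seed": config.seed,
        "items": model.to_json(),
        "reverse_flags": [bool(f) for f in data.reverse_flags],
        "theta": [float(t) for t in data.true_theta],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return data
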