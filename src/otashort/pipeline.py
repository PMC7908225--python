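"""End-to-end short-form construction workflow.

Stage order (fixed): reverse-code flagged items -> polychoric-EFA
unidimensionality screen (drop negative-loading items) -> GPCM calibration
-> iterative Wald gender-DIF screen (drop flagged items) -> minimal-length
optimal test assembly on the training sample -> evaluation on the training
and test samples. A two-sample design (training = selection, test =
confirmation) is the intended mode; a single-sample run is possible but
warned about. Every stage's decisions are logged in the run report so the
final item set is reproducible from the report alone.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import ResponseMatrix
from .dif import iterative_wald
from .dimensionality import minres_efa, polychoric_matrix, unidimensionality_check
from .evaluation import evaluate_short_form
from .gpcm import fit_gpcm
from .ota import DEFAULT_ANCHOR_POINTS, select_minimal_length
from .simulate import SyntheticConfig, generate_true_model, simulate_responses

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Settings of the full workflow; thresholds are configuration, never
    hard-coded in the stages."""

    synthetic: SyntheticConfig | None = None
    n_test_persons: int = 500
    train_path: str | None = None
    test_path: str | None = None
    reverse_items: Sequence[str] = ()
    anchor_points: Sequence[float] = DEFAULT_ANCHOR_POINTS
    alpha_ratio: float = 0.95
    r_summed: float = 0.9
    r_factor: float = 0.9
    dif_alpha: float = 0.05
    n_anchors: int = 5
    ratio_threshold: float = 3.0
    variance_threshold: float = 0.20
    lengths: Sequence[int] | None = None
    run_efa: bool = True
    run_dif: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("alpha_ratio", "r_summed", "r_factor", "dif_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        pts = np.asarray(self.anchor_points, dtype=float)
        if not np.all(np.isfinite(pts)) or np.any(np.diff(pts) <= 0):
            raise ValueError("anchor points must be finite and sorted")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "dif_spec" in syn:
                syn["dif_spec"] = [tuple(entry) for entry in syn["dif_spec"]]
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # environment detail, not analysis configuration
        return d


def _load_samples(config: PipelineConfig) -> tuple[ResponseMatrix, ResponseMatrix]:
    if config.synthetic is not None:
        seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
        train_cfg = dataclasses.replace(config.synthetic, seed=int(seeds[0]))
        test_cfg = dataclasses.replace(
            config.synthetic, seed=int(seeds[1]), n_persons=config.n_test_persons
        )
        # both samples come from the same generating item parameters
        true_model = generate_true_model(train_cfg)
        train = simulate_responses(true_model, train_cfg)
        test = simulate_responses(true_model, test_cfg, n_persons=config.n_test_persons)
        return train, test
    if config.train_path is None:
        raise ValueError("either synthetic settings or a train_path is required")
    train = ResponseMatrix.from_csv(
        config.train_path, reverse_items=config.reverse_items
    )
    if config.test_path is None:
        warnings.warn(
            "no test sample supplied: running in single-sample mode; the "
            "evaluation is not an out-of-sample confirmation"
        )
        test = train
    else:
        test = ResponseMatrix.from_csv(
            config.test_path, reverse_items=config.reverse_items
        )
    return train, test


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study workflow and return the run report.

    Deterministic given the configuration and seed; reruns produce a
    byte-identical report file. A stage failure raises a stage-labelled
    error; artifacts of completed stages are preserved in ``outdir``.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    report: dict = {"seed": config.seed, "config": config.to_json(), "log": log}

    def save(name: str, payload) -> None:
        if outdir:
            (outdir / name).write_text(json.dumps(payload, indent=2, sort_keys=True))

    # ---- load + reverse-code --------------------------------------------
    try:
        log.append("stage:load")
        train, test = _load_samples(config)
        report["n_train"], report["n_test"] = train.n_persons, test.n_persons
        report["items"] = train.item_names
        if outdir and config.synthetic is not None:
            train.to_csv(outdir / "train_responses.csv")
            test.to_csv(outdir / "test_responses.csv")

        log.append("stage:reverse_code")
        reversed_names = [n for n, f in zip(train.item_names, train.reverse_flags) if f]
        train, test = train.reverse_coded(), test.reverse_coded()
        report["reverse_coded_items"] = reversed_names
    except Exception as err:
        raise RuntimeError(f"[load/reverse_code] {err}") from err

    # ---- full-scale calibration (information reference) -----------------
    try:
        log.append("stage:gpcm_original_scale")
        model_original_train = fit_gpcm(train)
        model_original_test = fit_gpcm(test)
    except Exception as err:
        raise RuntimeError(f"[gpcm_original_scale] {err}") from err

    # ---- EFA screen ------------------------------------------------------
    removed_efa: list[str] = []
    if config.run_efa:
        try:
            log.append("stage:efa_screen")
            R = polychoric_matrix(train)
            efa = minres_efa(R, 1, n=train.n_persons)
            decision = unidimensionality_check(
                efa, config.ratio_threshold, config.variance_threshold
            )
            removed_efa = [train.item_names[j] for j in decision.remove_items]
            report["efa"] = {
                "kmo": efa.kmo,
                "bartlett": list(efa.bartlett),
                "eigenvalue_ratio": decision.eigenvalue_ratio,
                "variance_first": decision.variance_first,
                "unidimensional": decision.passed,
                "removed_items": removed_efa,
            }
            save("efa.json", report["efa"])
            if outdir:
                pd.DataFrame(
                    R, index=train.item_names, columns=train.item_names
                ).to_csv(outdir / "polychoric.csv")
            if removed_efa:
                keep = [
                    j
                    for j in range(train.n_items)
                    if train.item_names[j] not in removed_efa
                ]
                train, test = train.subset(keep), test.subset(keep)
            if not decision.passed:
                warnings.warn(
                    "essential unidimensionality not met; the unidimensional "
                    "GPCM may be inappropriate for these data"
                )
        except Exception as err:
            raise RuntimeError(f"[efa_screen] {err}") from err
    report["removed_efa"] = removed_efa

    # ---- DIF screen ------------------------------------------------------
    removed_dif: list[str] = []
    if config.run_dif:
        try:
            log.append("stage:dif_screen")
            dif_report, train_nondif = iterative_wald(
                train, alpha=config.dif_alpha, n_anchors=config.n_anchors
            )
            removed_dif = [train.item_names[j] for j in dif_report.removed]
            keep = [j for j in range(train.n_items) if j not in dif_report.removed]
            test_nondif = test.subset(keep)
            report["dif"] = dif_report.to_json()
            save("dif_report.json", report["dif"])
            if outdir:
                dif_report.table().to_csv(outdir / "dif_table.csv", index=False)
        except Exception as err:
            raise RuntimeError(f"[dif_screen] {err}") from err
    else:
        log.append("stage:dif_skipped")
        train_nondif, test_nondif = train, test
    report["removed_dif"] = removed_dif
    report["removed_items"] = removed_efa + removed_dif

    # ---- non-DIF calibration + OTA --------------------------------------
    try:
        log.append("stage:gpcm_nondif")
        model_nondif = fit_gpcm(train_nondif)
        save("gpcm_nondif.json", model_nondif.to_json())

        log.append("stage:ota")
        search = select_minimal_length(
            train_nondif,
            model_nondif,
            config.lengths,
            anchor_points=config.anchor_points,
            alpha_ratio=config.alpha_ratio,
            r_summed=config.r_summed,
            r_factor=config.r_factor,
        )
        report["ota"] = search.to_json()
        save("ota_search.json", report["ota"])
        if outdir:
            search.audit.to_csv(outdir / "ota_audit.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"[ota] {err}") from err

    # ---- evaluation ------------------------------------------------------
    if search.feasible:
        try:
            log.append("stage:evaluate")
            subset = list(search.selected)
            report["short_form"] = {
                "length": search.length,
                "items": [train_nondif.item_names[j] for j in subset],
            }
            eval_train, eval_test = evaluate_short_form(
                train_nondif,
                test_nondif,
                subset,
                full_model=model_nondif,
                info_reference_train=model_original_train,
                info_reference_test=model_original_test,
            )
            report["evaluation"] = {
                "train": eval_train.to_json(),
                "test": eval_test.to_json(),
            }
            save("evaluation.json", report["evaluation"])
        except Exception as err:
            raise RuntimeError(f"[evaluate] {err}") from err
    else:
        report["short_form"] = None
        report["evaluation"] = None
        log.append("stage:evaluate_skipped_infeasible")

    log.append("done")
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=list)
        )
    return report
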