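"""Whole-study orchestration: load -> classify -> project siblings ->
subset search -> final classifier -> regression, with serialized artifacts."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import Dataset, load_dataset, validate_panel, write_dataset
from .density import fit_distribution
from .fda import fit_fda, loo_scores, project_external, save_model
from .kpls import loo_q2, regression_search
from .roc_classify import confusion_at, decision_threshold, error_curves, roc_c_statistic
from .subset_search import ComboScore, combo_c_statistic, exhaustive_search, greedy_extend
from .synthetic import SyntheticConfig, VinelandLink, generate_dataset

log = logging.getLogger("focm_screen")

ALL_STAGES = ("validate", "classify", "siblings", "search", "final", "regress")


@dataclass
class RunConfig:
    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    k_max: int = 3
    k_extra: int = 2
    regression_k_max: int = 3
    hyper_policy: str = "fixed"
    search_variables: tuple[str, ...] | None = None  # None = full panel
    out_dir: str = "focm_screen_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stage list must be nonempty")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.input_path is None and self.synthetic is None:
            raise ValueError("either input_path or synthetic config required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            link = syn.pop("vineland_link", None)
            if link is not None:
                link["variables"] = tuple(link["variables"])
                link["coefficients"] = tuple(link["coefficients"])
                syn["vineland_link"] = VinelandLink(**link)
            if "variables" in syn:
                syn["variables"] = tuple(syn["variables"])
            syn = SyntheticConfig(**syn)
        for key in ("stages", "search_variables"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(synthetic=syn, **raw)


@dataclass
class Report:
    tables: dict[str, object] = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    version: str = __version__

    def summary_json(self) -> str:
        summary = {}
        for k, v in self.tables.items():
            summary[k] = v if isinstance(v, (int, float, str, dict, list)) else str(v)
        return json.dumps(
            {"version": self.version, "config": self.config_echo, "tables": summary},
            indent=2,
            default=str,
        )


def _load(cfg: RunConfig) -> Dataset:
    if cfg.input_path is not None:
        return load_dataset(cfg.input_path)
    ds, truth = generate_dataset(cfg.synthetic)
    return ds


def _classify_stage(ds: Dataset, variables, out: Path, tag: str) -> dict:
    cv = loo_scores(ds, variables)
    pdf_asd = fit_distribution(cv.by_cohort("ASD"))
    pdf_neu = fit_distribution(cv.by_cohort("NEU"))
    roc = roc_c_statistic(pdf_asd, pdf_neu)
    thr = decision_threshold(pdf_asd, pdf_neu)
    conf = confusion_at(cv, "ASD", thr.threshold)
    pd.DataFrame(
        {"id": cv.ids, "cohort": cv.cohorts, "score": cv.scores}
    ).to_csv(out / f"{tag}_scores.csv", index=False)
    (out / f"{tag}_confusion.json").write_text(conf.to_json())
    grid = np.linspace(cv.scores.min(), cv.scores.max(), 201)
    err = error_curves(cv, "ASD", grid)
    pd.DataFrame(
        {"threshold": err.thresholds, "type_i": err.type_i, "type_ii": err.type_ii}
    ).to_csv(out / f"{tag}_error_curves.csv", index=False)
    return {
        "c_statistic": roc.c_statistic,
        "threshold": thr.threshold,
        "threshold_fallback": thr.fallback_midpoint,
        "confusion": json.loads(conf.to_json()),
    }


def run_analysis(cfg: RunConfig) -> Report:
    """Execute the configured stages in study order, serializing artifacts."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = Report(config_echo={"seed": cfg.seed, "stages": list(cfg.stages)})

    ds = _load(cfg)
    write_dataset(ds, out / "dataset.csv")
    report.tables["cohort_counts"] = ds.cohort_counts()
    search_vars = cfg.search_variables or ds.panel.names

    for stage in cfg.stages:
        t0 = time.perf_counter()
        try:
            if stage == "validate":
                rep = validate_panel(ds)
                (out / "validation.json").write_text(rep.to_json())
                (out / "validation.txt").write_text(rep.to_text())
                report.tables["validation_flags"] = len(rep)
            elif stage == "classify":
                report.tables["full_panel"] = _classify_stage(
                    ds, ds.panel.names, out, "full_panel"
                )
            elif stage == "siblings":
                model = fit_fda(ds, ds.panel.names)
                save_model(model, out / "full_panel_model.json")
                sib = project_external(model, ds, "SIB")
                pd.DataFrame(sib, columns=["id", "score"]).to_csv(
                    out / "sib_scores.csv", index=False
                )
                sib_scores = np.array([s for _, s in sib])
                report.tables["sib_projection"] = {
                    "n": len(sib),
                    "median_score": float(np.median(sib_scores)),
                    "median_asd": model.class_score_means["ASD"],
                    "median_neu": model.class_score_means["NEU"],
                }
            elif stage == "search":
                res = exhaustive_search(
                    ds, k_max=cfg.k_max, variables=search_vars
                )
                rows = [
                    {
                        "size": k,
                        "variables": "|".join(cs.variables),
                        "c_statistic": cs.c_statistic,
                    }
                    for k, cs in sorted(res.best_by_size.items())
                ]
                pd.DataFrame(rows).to_csv(out / "search_best_by_size.csv", index=False)
                report.tables["search"] = {
                    "evaluated": res.evaluated_count,
                    "best_by_size": rows,
                }
            elif stage == "final":
                base_row = report.tables.get("search", {}).get("best_by_size")
                if base_row:
                    best = max(base_row, key=lambda r: r["c_statistic"])
                    base_vars = tuple(best["variables"].split("|"))
                else:
                    base_vars = tuple(search_vars[: cfg.k_max])
                base = combo_c_statistic(ds, base_vars)
                criterion = (
                    "sib_separability" if "SIB" in ds.cohort_counts() else "classification"
                )
                k_extra = min(cfg.k_extra, len(search_vars) - len(base_vars))
                traj = greedy_extend(
                    ds, base, k_extra, criterion=criterion, variables=search_vars
                )
                final_vars = traj[-1].variables
                report.tables["final_panel"] = {
                    "variables": list(final_vars),
                    **_classify_stage(ds, final_vars, out, "final_panel"),
                }
            elif stage == "regress":
                if len(ds.vineland_subset()) >= 10:
                    res = regression_search(
                        ds,
                        k_max=cfg.regression_k_max,
                        hyper_policy=cfg.hyper_policy,
                        variables=search_vars,
                    )
                    rows = [
                        {"size": k, "variables": "|".join(v), "q2": q2}
                        for k, (v, q2) in sorted(res.items())
                    ]
                    pd.DataFrame(rows).to_csv(
                        out / "regression_best_by_size.csv", index=False
                    )
                    k_best, (v_best, q2_best) = max(
                        res.items(), key=lambda kv: kv[1][1]
                    )
                    best_fit = loo_q2(ds, v_best, cfg.hyper_policy)
                    pd.DataFrame(
                        {
                            "id": best_fit.ids,
                            "y_true": best_fit.y_true,
                            "y_pred": best_fit.y_pred,
                        }
                    ).to_csv(out / "regression_predictions.csv", index=False)
                    report.tables["regression"] = {
                        "best_by_size": rows,
                        "best": {"variables": list(v_best), "q2": q2_best},
                    }
                else:
                    report.tables["regression"] = {"skipped": "too few responses"}
        except Exception as e:
            (out / "partial_state.json").write_text(report.summary_json())
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    (out / "report.json").write_text(report.summary_json())
    return report
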