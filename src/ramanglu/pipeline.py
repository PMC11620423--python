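"""Experiment orchestration: three preprocessing scenarios x three models.

The comparison protocol duplicates one dataset into three scenarios —

* ``root``     — raw intensity matrix, no preprocessing;
* ``hotspot``  — reduced to the union of top-variance windows;
* ``vra``      — fluorescence baseline removed per spectrum;

runs every classifier on each by repeated stratified CV, and reports the
grid of mean metrics plus each preprocessed scenario's paired accuracy
improvement over root (same CV seeds across scenarios, so the deltas are
within-run). Optionally the best-scoring scenario is re-run with grid
search. Preprocessing is applied to the full dataset before CV by
default, mirroring the global-mask protocol; ``leakage_safe`` computes
the hotspot mask inside training folds instead.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold

from .baseline import VraParams, VancouverBaselineCorrector
from .errors import EmptyDataset, InvalidParams
from .evaluate import (
    CvConfig,
    DEFAULT_GRIDS,
    EvalReport,
    ModelSpec,
    _class_scores,
    build_classifier,
    evaluate_repeated_cv,
    grid_search,
    ovr_metrics,
)
from .hotspot import HotspotSelector
from .io import SpectraDataset

SCENARIOS = ("root", "hotspot", "vra")
MODEL_ORDER = ("extra_trees", "random_forest", "svm")
MODEL_LABELS = {
    "extra_trees": "Extra Trees",
    "random_forest": "Random Forest",
    "svm": "Support Vector Machine",
}


@dataclass
class ScenarioConfig:
    """One preprocessing scenario and the evaluation settings applied to it."""

    scenario: str = "root"
    hotspot_l: int = 10
    hotspot_k: int = 500
    vra: VraParams = field(default_factory=VraParams)
    cv: CvConfig = field(default_factory=CvConfig)
    models: Sequence[ModelSpec] = field(
        default_factory=lambda: tuple(ModelSpec(m) for m in MODEL_ORDER)
    )
    tuning: str = "off"  # off | grid

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise InvalidParams(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}"
            )
        if self.tuning not in ("off", "grid"):
            raise InvalidParams("tuning must be 'off' or 'grid'")


def preprocess_scenario(
    dataset: SpectraDataset, config: ScenarioConfig
) -> np.ndarray:
    """Feature matrix of one scenario; root returns the raw intensities."""
    X = dataset.intensity_matrix()
    if config.scenario == "root":
        return X
    if config.scenario == "hotspot":
        return HotspotSelector(l=config.hotspot_l, k=config.hotspot_k).fit_transform(X)
    corrector = VancouverBaselineCorrector(
        poly_order=config.vra.poly_order,
        smooth_window=config.vra.smooth_window,
        tol=config.vra.tol,
        max_iter=config.vra.max_iter,
    )
    return corrector.fit_transform(X)


@dataclass
class ComparisonReport:
    """Scenario x model grid of mean metrics plus paired improvements."""

    cells: dict[str, dict[str, EvalReport]] = field(default_factory=dict)
    improvements: dict[str, dict[str, float]] = field(default_factory=dict)
    tuned: dict | None = None
    provenance: dict = field(default_factory=dict)

    def mean_accuracy(self, scenario: str, model: str) -> float:
        return self.cells[scenario][model].means["accuracy"]

    def best_scenario(self) -> str:
        """Scenario with the highest mean accuracy over its models."""
        return max(
            self.cells,
            key=lambda s: np.mean(
                [r.means["accuracy"] for r in self.cells[s].values()]
            ),
        )

    def to_dict(self) -> dict:
        return {
            "cells": {
                s: {m: r.to_dict() for m, r in models.items()}
                for s, models in self.cells.items()
            },
            "improvements": self.improvements,
            "tuned": self.tuned,
            "provenance": self.provenance,
        }


def _dataset_hash(dataset: SpectraDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.shifts).tobytes())
    h.update(np.ascontiguousarray(dataset.intensity_matrix()).tobytes())
    h.update(np.asarray(dataset.labels(), dtype=float).tobytes())
    return h.hexdigest()[:16]


def _evaluate_leakage_safe(
    dataset: SpectraDataset, config: ScenarioConfig, spec: ModelSpec
) -> EvalReport:
    """Fold-wise preprocessing: fit the transformer on train folds only."""
    X = dataset.intensity_matrix()
    y = dataset.labels()
    splitter = RepeatedStratifiedKFold(
        n_splits=config.cv.k,
        n_repeats=config.cv.n_repeats,
        random_state=config.cv.seed,
    )
    classes = np.unique(y)
    iterations = []
    for train, test in splitter.split(X, y):
        if config.scenario == "hotspot":
            sel = HotspotSelector(l=config.hotspot_l, k=config.hotspot_k)
            Xtr = sel.fit_transform(X[train])
            Xte = sel.transform(X[test])
        elif config.scenario == "vra":
            corr = VancouverBaselineCorrector(
                poly_order=config.vra.poly_order,
                smooth_window=config.vra.smooth_window,
                tol=config.vra.tol,
                max_iter=config.vra.max_iter,
            )
            Xtr = corr.fit_transform(X[train])
            Xte = corr.transform(X[test])
        else:
            Xtr, Xte = X[train], X[test]
        clf = build_classifier(spec)
        clf.fit(Xtr, y[train])
        iterations.append(
            ovr_metrics(
                y[test],
                clf.predict(Xte),
                class_scores=_class_scores(clf, Xte, classes),
                classes=classes,
            )
        )
    return EvalReport.from_iterations(
        spec.name,
        iterations,
        scenario=config.scenario,
        hyperparams=dict(spec.hyperparams),
    )


def run_comparison(
    dataset: SpectraDataset,
    configs: Sequence[ScenarioConfig] | None = None,
    *,
    leakage_safe: bool = False,
    tune_best: bool = False,
    tuning_grids: Mapping[str, Mapping] | None = None,
    tuning_cv: CvConfig | None = None,
) -> ComparisonReport:
    """Run every (scenario, model) cell and assemble the comparison report.

    Each scenario's preprocessing is applied once to its own copy of the
    data (scenarios never mutate each other's inputs); all scenarios share
    the same CV seeds so per-model improvements over root are paired
    differences. With ``tune_best``, the scenario with the highest mean
    accuracy is re-run under grid search for each model.
    """
    if len(dataset) == 0:
        raise EmptyDataset("cannot compare on an empty dataset")
    if configs is None:
        configs = [ScenarioConfig(scenario=s) for s in SCENARIOS]
    if not configs:
        raise InvalidParams("at least one scenario required")
    y = dataset.labels()
    report = ComparisonReport()
    for config in configs:
        cell: dict[str, EvalReport] = {}
        features = None if leakage_safe else preprocess_scenario(dataset, config)
        for spec in config.models:
            try:
                if leakage_safe:
                    cell[spec.name] = _evaluate_leakage_safe(
                        dataset, config, spec
                    )
                else:
                    cell[spec.name] = evaluate_repeated_cv(
                        features, y, spec, config.cv, scenario=config.scenario
                    )
            except Exception as exc:
                raise type(exc)(
                    f"scenario {config.scenario!r}, model {spec.name!r}: {exc}"
                ) from exc
        report.cells[config.scenario] = cell
    if "root" in report.cells:
        for scenario, cell in report.cells.items():
            if scenario == "root":
                continue
            report.improvements[scenario] = {
                m: r.means["accuracy"]
                - report.cells["root"][m].means["accuracy"]
                for m, r in cell.items()
            }
    if tune_best:
        best = report.best_scenario()
        best_config = next(c for c in configs if c.scenario == best)
        features = preprocess_scenario(dataset, best_config)
        tuned: dict = {"scenario": best, "models": {}}
        for spec in best_config.models:
            grid = (
                dict(tuning_grids[spec.name])
                if tuning_grids and spec.name in tuning_grids
                else DEFAULT_GRIDS[spec.name]
            )
            params, rep = grid_search(
                features,
                y,
                spec.name,
                grid,
                tuning_cv or best_config.cv,
                model_seed=spec.seed,
            )
            tuned["models"][spec.name] = {
                "best_hyperparams": params,
                "report": rep.to_dict(),
            }
        report.tuned = tuned
    report.provenance = {
        "n_samples": len(dataset),
        "n_points": dataset.n_points,
        "dataset_hash": _dataset_hash(dataset),
        "cv": {
            "k": configs[0].cv.k,
            "n_repeats": configs[0].cv.n_repeats,
            "seed": configs[0].cv.seed,
        },
        "leakage_safe": leakage_safe,
        "scenarios": [c.scenario for c in configs],
    }
    return report


def render_report(report: ComparisonReport, format: str = "json") -> str:
    """Serialize a comparison report as JSON or an aligned text table.

    Ordering is deterministic: scenarios in root/hotspot/vra order, models
    in Extra Trees / Random Forest / SVM order.
    """
    if format == "json":
        return json.dumps(_ordered_dict(report), indent=2)
    if format != "text":
        raise ValueError("format must be 'json' or 'text'")
    scenarios = [s for s in SCENARIOS if s in report.cells]
    scenarios += [s for s in report.cells if s not in SCENARIOS]
    models = [m for m in MODEL_ORDER if any(m in report.cells[s] for s in scenarios)]
    lines = []
    for metric in ("accuracy", "specificity", "sensitivity", "auc"):
        header = f"{'Mean ' + metric + ' (%)':<28}" + "".join(
            f"{s:>12}" for s in scenarios
        )
        rows = []
        for m in models:
            vals = []
            for s in scenarios:
                r = report.cells[s].get(m)
                v = r.means.get(metric) if r else None
                vals.append(f"{100 * v:>12.2f}" if v is not None else f"{'-':>12}")
            rows.append(f"{MODEL_LABELS[m]:<28}" + "".join(vals))
        lines += [header, *rows, ""]
    if report.improvements:
        lines.append(f"{'Improvement in accuracy (%)':<28}" + "".join(
            f"{s:>12}" for s in scenarios if s != "root"
        ))
        for m in models:
            vals = [
                f"{100 * report.improvements[s][m]:>+12.2f}"
                for s in scenarios
                if s != "root" and s in report.improvements
            ]
            lines.append(f"{MODEL_LABELS[m]:<28}" + "".join(vals))
        lines.append("")
    if report.tuned:
        lines.append(f"Grid search on best scenario: {report.tuned['scenario']}")
        for m in models:
            if m in report.tuned["models"]:
                entry = report.tuned["models"][m]
                acc = entry["report"]["means"]["accuracy"]
                lines.append(
                    f"{MODEL_LABELS[m]:<28}{100 * acc:>12.2f}  "
                    f"{entry['best_hyperparams']}"
                )
    return "\n".join(lines)


def _ordered_dict(report: ComparisonReport) -> dict:
    d = report.to_dict()
    scenario_order = [s for s in SCENARIOS if s in d["cells"]] + [
        s for s in d["cells"] if s not in SCENARIOS
    ]
    d["cells"] = {
        s: {
            m: d["cells"][s][m]
            for m in MODEL_ORDER
            if m in d["cells"][s]
        }
        for s in scenario_order
    }
    return d
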