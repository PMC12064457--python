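"""End-to-end pipeline orchestration and report rendering.

Wiring (the study protocol): read -> average replicates -> subtract water
-> Savitzky-Golay x10 + first derivative -> SNV -> stratified 70/30 split
-> OPLS (20 orthogonal components, fitted on training data only) -> PLS
evaluation with and without the OPLS filter -> random forest on the
OPLS-filtered spectra -> exact tree-Shapley attribution -> merged top-k
biomarker selection -> Kruskal-Wallis confirmation on the raw
water-subtracted absorbances -> optional stability / model-comparison /
learning-curve extras.

``paper_mode`` fits the OPLS filter on the whole dataset before the split,
reproducing the published description verbatim; the default fits it on the
training fold only to avoid test-set leakage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribute import (
    DEFAULT_BAND_TABLE,
    AttributionReport,
    annotate_bands,
    attribution_stability,
    confirm_frequencies,
    normality_gate,
    pca_selected,
    rank_and_select,
    shapley_attributions,
)
from .classify import (
    ForestConfig,
    MetricsReport,
    SplitSpec,
    class_weights,
    compare_models,
    evaluate,
    fit_forest,
    learning_curve,
    predict_proba,
    stratified_split,
)
from .errors import UroftirError
from .latent import fit_opls, fit_pls, opls_transform, pls_predict, r2_score, roc_auc
from .preprocess import PreprocConfig, preprocess_chain
from .spectra import SpectraSet

log = logging.getLogger("uroftir")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "report_render"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run, mirroring the study protocol."""

    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    n_ortho: int = 20
    n_pls_components: int = 2
    forest: ForestConfig = field(default_factory=ForestConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    attribution_k: int = 3
    merge_window: float = 10.0
    relevance_floor: float | None = None
    alpha: float = 0.05
    pls_threshold: float = 0.5
    stability_seeds: tuple[int, ...] = (333, 41, 97, 512, 2024)
    paper_mode: bool = False
    run_stability: bool = True
    run_comparison: bool = True
    run_learning_curve: bool = True
    learning_fractions: tuple[float, ...] = (0.3, 0.5, 0.7, 0.85, 1.0)
    comparison_folds: int = 5

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def _pls_eval(X_train, y_train, X_test, y_test, n_components, threshold) -> dict:
    """Fit PLS and score R^2 / thresholded accuracy / AUC on the test fold."""
    model = fit_pls(X_train, y_train, n_components=n_components)
    scores = pls_predict(model, X_test)
    roc = roc_auc(y_test, scores)
    preds = (scores >= threshold).astype(int)
    return {
        "r2": r2_score(y_test, scores),
        "accuracy": float(np.mean(preds == y_test)),
        "auc": roc["auc"],
        "roc": {"fpr": roc["fpr"].tolist(), "tpr": roc["tpr"].tolist()},
        "scores_first2": model.scores[:, : min(2, model.scores.shape[1])],
        "test_scores": scores,
    }


@dataclass
class RunReport:
    """Machine-readable run output covering the full evaluation surface."""

    config: dict
    seed: int
    n_train: int
    n_test: int
    pls_without_opls: dict
    pls_with_opls: dict
    forest_metrics: MetricsReport
    forest_roc: dict
    normality: dict
    attribution: AttributionReport
    stability: dict | None = None
    model_comparison: pd.DataFrame | None = None
    learning_curve: pd.DataFrame | None = None
    pca: dict | None = None


def run_pipeline(raw_set: SpectraSet, config: PipelineConfig | None = None) -> RunReport:
    """Execute the full analysis on a water-subtracted SpectraSet.

    ``raw_set`` must be the replicate-averaged, background-subtracted
    matrix (pre-derivative): the confirmation stage reuses it directly.
    All randomness derives from the seeds declared in ``config``.
    """
    config = config or PipelineConfig()
    y = raw_set.labels

    stage = "preprocess"
    try:
        proc = preprocess_chain(raw_set, config.preproc)
        X = proc.matrix

        stage = "split"
        train, test = stratified_split(y, config.split)
        log.info("split: %d train / %d test", train.size, test.size)

        stage = "pls"
        pls_plain = _pls_eval(X[train], y[train], X[test], y[test],
                              config.n_pls_components, config.pls_threshold)

        stage = "opls"
        if config.paper_mode:
            opls = fit_opls(X, y, n_ortho=config.n_ortho)
        else:
            opls = fit_opls(X[train], y[train], n_ortho=config.n_ortho)
        Xf = opls_transform(opls, X)
        pls_opls = _pls_eval(Xf[train], y[train], Xf[test], y[test],
                             config.n_pls_components, config.pls_threshold)

        # the forest (and the attribution downstream) works on the
        # preprocessed matrix; the OPLS filter serves the PLS branch, where
        # removing label-orthogonal variation sharpens the latent scores —
        # filtering before a tree ensemble would spread the class signal
        # over every column and erase per-wavenumber feature identity
        stage = "forest"
        weights = class_weights(y[train])
        clf = fit_forest(X[train], y[train], config.forest, weights)
        test_scores = predict_proba(clf, X[test])
        metrics = evaluate(y[test], clf.predict(X[test]), test_scores)
        forest_roc = roc_auc(y[test], test_scores)

        stage = "normality"
        # distribution check at the top biomarker column feeds the
        # parametric-vs-nonparametric gate
        normality = {}

        stage = "attribution"
        phi, base = shapley_attributions(clf, X)
        report = rank_and_select(phi, raw_set.grid.values, k=config.attribution_k,
                                 merge_window=config.merge_window,
                                 relevance_floor=config.relevance_floor)

        stage = "confirmation"
        report.kw_results = confirm_frequencies(raw_set, report.selected_top,
                                                alpha=config.alpha)
        report.annotations = annotate_bands(report.selected_top, DEFAULT_BAND_TABLE)
        if report.selected_top:
            col = raw_set.grid.index_of(report.selected_top[0])
            normality = normality_gate(raw_set.matrix[:, col], alpha=config.alpha)

        stage = "pca"
        pca = None
        if len(report.selected_top) >= 2:
            pca = pca_selected(raw_set, report.selected_top,
                               n_pc=min(2, len(report.selected_top)))

        stage = "stability"
        stability = None
        if config.run_stability:
            stability = attribution_stability(
                X, y, raw_set.grid.values, seeds=list(config.stability_seeds),
                k=config.attribution_k, merge_window=config.merge_window,
                forest_config=config.forest,
                test_fraction=config.split.test_fraction)

        stage = "comparison"
        comparison = None
        if config.run_comparison:
            comparison = compare_models(X, y, folds=config.comparison_folds,
                                        seed=config.forest.seed,
                                        forest_config=config.forest)

        stage = "learning_curve"
        curve = None
        if config.run_learning_curve:
            curve = learning_curve(X, y, config.learning_fractions,
                                   folds=config.comparison_folds,
                                   seed=config.forest.seed, config=config.forest)
    except UroftirError as exc:
        raise UroftirError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return RunReport(
        config=config.to_dict(),
        seed=config.forest.seed,
        n_train=int(train.size),
        n_test=int(test.size),
        pls_without_opls=pls_plain,
        pls_with_opls=pls_opls,
        forest_metrics=metrics,
        forest_roc=forest_roc,
        normality=normality,
        attribution=report,
        stability=stability,
        model_comparison=comparison,
        learning_curve=curve,
        pca=pca,
    )


def report_render(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write the report as JSON summary + TSV tables + a plain-text log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _tsv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    summary = {
        "config": report.config,
        "seed": report.seed,
        "n_train": report.n_train,
        "n_test": report.n_test,
        "pls_without_opls": {k: report.pls_without_opls[k] for k in ("r2", "accuracy", "auc")},
        "pls_with_opls": {k: report.pls_with_opls[k] for k in ("r2", "accuracy", "auc")},
        "forest_metrics": report.forest_metrics.to_dict(),
        "normality": report.normality,
        "selected_top": report.attribution.selected_top,
        "n_relevant": report.attribution.n_relevant,
        "kw_results": {str(k): v for k, v in report.attribution.kw_results.items()},
        "annotations": {str(k): v for k, v in report.attribution.annotations.items()},
        "stability": report.stability,
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2))
    written.append(path)

    _tsv("confusion.tsv", pd.DataFrame([{
        "tp": report.forest_metrics.tp, "tn": report.forest_metrics.tn,
        "fp": report.forest_metrics.fp, "fn": report.forest_metrics.fn}]))
    _tsv("roc_forest.tsv", pd.DataFrame({
        "fpr": report.forest_roc["fpr"], "tpr": report.forest_roc["tpr"]}))
    for tag in ("with_opls", "without_opls"):
        block = report.pls_with_opls if tag == "with_opls" else report.pls_without_opls
        _tsv(f"roc_pls_{tag}.tsv", pd.DataFrame(block["roc"]))
        _tsv(f"pls_scores_{tag}.tsv", pd.DataFrame(
            block["scores_first2"], columns=[f"pls{i+1}" for i in
                                             range(block["scores_first2"].shape[1])]))
    _tsv("attribution.tsv", pd.DataFrame(report.attribution.to_records()))
    if report.stability is not None:
        _tsv("stability.tsv", pd.DataFrame({
            "seed": report.stability["seeds"],
            "top_k": [";".join(f"{w:g}" for w in t) for t in report.stability["top_k"]]}))
    if report.model_comparison is not None:
        _tsv("model_comparison.tsv", report.model_comparison)
    if report.learning_curve is not None:
        _tsv("learning_curve.tsv", report.learning_curve)
    if report.pca is not None:
        _tsv("pca_selected.tsv", pd.DataFrame(
            report.pca["scores"], columns=[f"pc{i+1}" for i in
                                           range(report.pca["scores"].shape[1])]))

    logpath = out / "run.log"
    lines = [
        f"uroftir {__version__} seed={report.seed}",
        f"train/test: {report.n_train}/{report.n_test}",
        f"forest accuracy={report.forest_metrics.accuracy:.4f} "
        f"weighted_f1={report.forest_metrics.weighted_f1:.4f} "
        f"auc={report.forest_metrics.auc:.4f}",
        f"selected_top={report.attribution.selected_top}",
    ]
    logpath.write_text("\n".join(lines) + "\n")
    written.append(logpath)
    return written
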