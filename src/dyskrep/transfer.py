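"""Cross-dataset generalization: refit top models on a source cohort, score on a target.

A representation that looks strong in cross-validation can still collapse on
a cohort recorded elsewhere (different device wearing, noise, sampling).
This module takes the top-k leaderboard configurations per representation,
refits each on the full source feature matrix (imputation, sampler,
selector and scaler all fit on source only), predicts the target cohort
once, and compares representations by Welch's t-test over the k transfer
scores.  No target information influences fitting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autofeat import FeatureMatrix
from .metrics import accuracy, confusion_matrix, macro_f1, welch_t_test
from .selection import CVResult, ModelConfig, RankedGrid, _fit_predict_fold

#: Paper-style significance threshold for representation comparisons.
SIGNIFICANCE_LEVEL = 0.001


@dataclass
class TransferResult:
    """One refit configuration scored once on the target cohort."""

    config: ModelConfig
    cv_macro_f1_mean: float              # source cross-validation score, for drop analysis
    target_macro_f1: float
    target_accuracy: float
    confusion: np.ndarray                # 2x2 on the target


@dataclass
class GeneralizationReport:
    """Top-k transfer outcomes for one representation."""

    representation: str
    results: list[TransferResult]

    @property
    def target_scores(self) -> np.ndarray:
        return np.array([r.target_macro_f1 for r in self.results])

    @property
    def mean(self) -> float:
        return float(self.target_scores.mean())

    @property
    def sd(self) -> float:
        s = self.target_scores
        return float(s.std(ddof=1)) if len(s) > 1 else 0.0

    @property
    def mean_cv_drop(self) -> float:
        """Mean (source CV score - target score) over the top-k models."""
        return float(np.mean([r.cv_macro_f1_mean - r.target_macro_f1 for r in self.results]))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rank, r in enumerate(self.results, start=1):
            rows.append({
                "rank": rank,
                "classifier": r.config.classifier_kind,
                "hyperparams": ",".join(f"{k}={v}" for k, v in r.config.hyperparams),
                "selector": "none" if r.config.selector_k is None else r.config.selector_k,
                "sampler": r.config.sampler,
                "cv_macro_f1": r.cv_macro_f1_mean,
                "target_macro_f1": r.target_macro_f1,
                "target_accuracy": r.target_accuracy,
            })
        return pd.DataFrame(rows)


def _as_df(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.df if isinstance(matrix, FeatureMatrix) else matrix


def transfer_evaluate(
    source: FeatureMatrix | pd.DataFrame,
    source_labels,
    target: FeatureMatrix | pd.DataFrame,
    target_labels,
    ranked: RankedGrid,
    top_k: int = 10,
    seed: int = 0,
    representation: str = "",
) -> GeneralizationReport:
    """Refit the top-k ranked configurations on the source and score the target.

    Source and target must share the representation's column schema; the
    target must contain both classes.
    """
    src = _as_df(source)
    tgt = _as_df(target)
    missing = [c for c in src.columns if c not in tgt.columns]
    if missing:
        raise ValueError(f"target is missing column(s): {missing}")
    tgt = tgt[src.columns]
    y_src = np.asarray(source_labels)
    y_tgt = np.asarray(target_labels)
    if len(np.unique(y_tgt)) < 2:
        raise ValueError("target cohort must contain both classes")
    if not representation and isinstance(source, FeatureMatrix):
        representation = source.tag

    results = []
    for config, cv_result in ranked.top(top_k):
        y_pred = _fit_predict_fold(src, y_src, tgt, config, seed)
        results.append(
            TransferResult(
                config=config,
                cv_macro_f1_mean=cv_result.macro_f1_mean,
                target_macro_f1=macro_f1(y_tgt, y_pred),
                target_accuracy=accuracy(y_tgt, y_pred),
                confusion=confusion_matrix(y_tgt, y_pred),
            )
        )
    return GeneralizationReport(representation=representation, results=results)


def compare_representations(
    reports: list[GeneralizationReport] | dict[str, np.ndarray],
    significance: float = SIGNIFICANCE_LEVEL,
) -> pd.DataFrame:
    """Pairwise Welch t-tests between representations' transfer score sets.

    Accepts either reports or a mapping of representation -> score array.
    Pairs with fewer than 2 scores on either side are skipped with a reason.
    """
    if isinstance(reports, dict):
        score_sets = {k: np.asarray(v, dtype=float) for k, v in reports.items()}
    else:
        score_sets = {r.representation: r.target_scores for r in reports}
    if len(score_sets) < 2:
        raise ValueError("need at least 2 representations to compare")
    rows = []
    for (name_a, a), (name_b, b) in itertools.combinations(score_sets.items(), 2):
        row = {
            "representation_a": name_a,
            "representation_b": name_b,
            "mean_a": float(np.mean(a)),
            "sd_a": float(np.std(a, ddof=1)) if len(a) > 1 else 0.0,
            "mean_b": float(np.mean(b)),
            "sd_b": float(np.std(b, ddof=1)) if len(b) > 1 else 0.0,
        }
        if len(a) < 2 or len(b) < 2:
            row.update(t=np.nan, p=np.nan, significant=False,
                       skipped="fewer than 2 scores in a set")
        else:
            t, p = welch_t_test(a, b)
            row.update(t=t, p=p, significant=bool(p < significance), skipped="")
        rows.append(row)
    return pd.DataFrame(rows)


def plot_confusion(conf: np.ndarray, title: str = "", path: str | None = None):
    """Optional confusion-matrix heatmap (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(conf, cmap="Blues")
    for (i, j), val in np.ndenumerate(conf):
        ax.text(j, i, str(int(val)), ha="center", va="center")
    ax.set_xticks([0, 1], ["pred 0", "pred 1"])
    ax.set_yticks([0, 1], ["true 0", "true 1"])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
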