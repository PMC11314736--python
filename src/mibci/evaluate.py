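"""Stratified cross-validation of the filter-bank CSP pipeline.

Every fold refits the whole chain on its training trials only — CSP
filters, the feature scaler, the selector, and the classifier — so the
held-out metrics are leakage-free.  Metrics: accuracy (percent), F1 with
class 2 as positive, and AUROC from the rank (Mann-Whitney) statistic.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierSpec, decision_scores, train
from .csp import fit_csp, transform_csp, default_pairs
from .feature_selection import rank_features, select_top
from .filterbank import FilterBank, apply_filterbank
from .io import EpochedEEG, FeatureTable


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """Classification accuracy in percent from confusion counts."""
    total = tp + tn + fp + fn
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if total == 0:
        raise ValueError("confusion counts sum to zero")
    return 100.0 * (tp + tn) / total


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = 2 TP / (2 TP + FN + FP)."""
    denom = 2 * tp + fn + fp
    if denom == 0:
        raise ValueError("F1 undefined: 2*tp + fn + fp = 0")
    return 2.0 * tp / denom


def auroc(scores: np.ndarray, labels: np.ndarray, positive: int = 2) -> float:
    """Probability a random positive outscores a random negative (ties count 1/2).

    Computed from the Mann-Whitney U statistic via midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics plus the config used."""

    per_fold: pd.DataFrame  # columns: fold, accuracy, f1, auroc, train_time
    config: dict = field(default_factory=dict)

    @property
    def mean(self) -> pd.Series:
        return self.per_fold[["accuracy", "f1", "auroc"]].mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_fold[["accuracy", "f1", "auroc"]].std(ddof=1)

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold.to_dict(orient="records"),
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "config": self.config,
        }

    def summary(self) -> str:
        lines = [
            "Cross-validation report",
            "=" * 55,
            self.per_fold.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "-" * 55,
        ]
        m, s = self.mean, self.sd
        for name in ("accuracy", "f1", "auroc"):
            lines.append(f"{name:>9}: {m[name]:8.4f} +/- {s[name]:.4f}")
        cfg = self.config
        if cfg:
            lines.append("-" * 55)
            lines.append(
                "config: "
                + ", ".join(f"{k}={cfg[k]}" for k in sorted(cfg) if not isinstance(cfg[k], (dict, list)))
            )
        return "\n".join(lines)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive: int = 2) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    return tp, tn, fp, fn


def _fold_features(
    epochs: EpochedEEG,
    bands_epochs: list[EpochedEEG],
    bank: FilterBank,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    k: int | None,
    shrinkage: float,
) -> tuple[FeatureTable, FeatureTable]:
    """Fit per-band CSP on the training trials; transform both splits."""
    tr_blocks, te_blocks = [], []
    for band, band_ep in zip(bank.bands, bands_epochs):
        train_ep = band_ep.subset(train_idx)
        model = fit_csp(train_ep, k=k, shrinkage=shrinkage, band=band)
        tr_blocks.append(transform_csp(model, train_ep))
        te_blocks.append(transform_csp(model, band_ep.subset(test_idx)))
    tr = FeatureTable(
        np.hstack([b.values for b in tr_blocks]),
        epochs.labels[train_idx],
        [m for b in tr_blocks for m in b.feature_meta],
    )
    te = FeatureTable(
        np.hstack([b.values for b in te_blocks]),
        epochs.labels[test_idx],
        [m for b in te_blocks for m in b.feature_meta],
    )
    return tr, te


def crossvalidate(
    epochs: EpochedEEG,
    selector: str | None = "relieff",
    n_features: int | None = None,
    classifier: ClassifierSpec | str = "lda",
    bank: FilterBank | None = None,
    csp_pairs: int | None = None,
    shrinkage: float = 0.0,
    n_folds: int = 5,
    seed: int = 42,
    selector_kwargs: dict | None = None,
    selection_scope: str = "per_fold",
) -> CVReport:
    """Stratified k-fold evaluation of filterbank → CSP → selector → classifier.

    Parameters
    ----------
    selector : str or None
        One of ``relieff, inf_fs, ilfs, fsv, sd``; ``None`` skips selection.
    n_features : int, optional
        Features kept after ranking; default keeps all (selection is then a
        pure reordering).
    selection_scope : {"per_fold", "global"}
        ``per_fold`` (default) fits the selector inside each training fold;
        ``global`` fits it once on all trials before splitting — a
        compatibility mode that deliberately reproduces protocols which rank
        features outside the CV loop, at the cost of selection leakage.
    """
    epochs.require_two_classes()
    if isinstance(classifier, str):
        classifier = ClassifierSpec(kind=classifier)
    if bank is None:
        bank = FilterBank()
    counts = np.bincount(epochs.labels)[1:]
    if counts.min() < n_folds:
        raise ValueError(f"need >= {n_folds} trials per class for {n_folds}-fold CV")
    selector_kwargs = selector_kwargs or {}

    bands_epochs = apply_filterbank(epochs, bank)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    global_keep: list[int] | None = None
    if selector is not None and selection_scope == "global":
        from .csp import multiband_csp_features

        full_feats, _ = multiband_csp_features(epochs, bank, k=csp_pairs, shrinkage=shrinkage)
        ranking = rank_features(_zscored(full_feats), selector, **selector_kwargs)
        n_keep = full_feats.n_features if n_features is None else n_features
        global_keep = select_top(ranking, n_keep)
    elif selection_scope not in ("per_fold", "global"):
        raise ValueError("selection_scope must be 'per_fold' or 'global'")

    rows = []
    preds_all = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(epochs.n_trials), epochs.labels)):
        t0 = time.perf_counter()
        tr, te = _fold_features(epochs, bands_epochs, bank, tr_idx, te_idx, csp_pairs, shrinkage)
        if selector is not None:
            if global_keep is not None:
                keep = global_keep
            else:
                ranking = rank_features(_zscored(tr), selector, **selector_kwargs)
                n_keep = tr.n_features if n_features is None else n_features
                keep = select_top(ranking, n_keep)
            tr, te = tr.select_columns(keep), te.select_columns(keep)
        model = train(classifier, tr)
        y_pred = model.predict(te.values)
        scores = decision_scores(model, te.values)
        elapsed = time.perf_counter() - t0
        tp, tn, fp, fn = _confusion(te.labels, y_pred)
        rows.append(
            {
                "fold": fold,
                "accuracy": accuracy(tp, tn, fp, fn),
                "f1": f1_score(tp, fp, fn),
                "auroc": auroc(scores, te.labels),
                "train_time": elapsed,
            }
        )
        preds_all.append(
            pd.DataFrame(
                {"fold": fold, "trial": te_idx, "label": te.labels, "pred": y_pred, "score": scores}
            )
        )
    config = {
        "bands": [(b.name, b.lo, b.hi) for b in bank.bands],
        "csp_pairs": csp_pairs if csp_pairs is not None else default_pairs(epochs.n_channels),
        "selector": selector,
        "n_features": n_features,
        "classifier": classifier.kind,
        "classifier_hyper": dict(classifier.hyper),
        "n_folds": n_folds,
        "seed": seed,
        "selection_scope": selection_scope,
    }
    report = CVReport(per_fold=pd.DataFrame(rows), config=config)
    report.predictions = pd.concat(preds_all, ignore_index=True)
    return report


def _zscored(table: FeatureTable) -> FeatureTable:
    """Training-fold z-scoring applied before feature ranking."""
    sd = table.values.std(axis=0, ddof=0)
    vals = (table.values - table.values.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return FeatureTable(vals, table.labels.copy(), [dict(m) for m in table.feature_meta])


def sweep_feature_counts(
    epochs: EpochedEEG,
    selectors: list[str] | None = None,
    classifiers: list[str] | None = None,
    fractions: list[float] | None = None,
    bank: FilterBank | None = None,
    csp_pairs: int | None = None,
    n_folds: int = 5,
    seed: int = 42,
) -> pd.DataFrame:
    """Accuracy of every (selector, classifier, feature fraction) cell.

    All cells share one fold assignment (the same seed), giving paired
    comparisons across selectors and feature counts.
    """
    selectors = selectors or ["relieff"]
    classifiers = classifiers or ["lda"]
    fractions = fractions if fractions is not None else [0.5, 0.75, 1.0]
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError("fractions must be in (0, 1]")
    if bank is None:
        bank = FilterBank()
    k = csp_pairs if csp_pairs is not None else default_pairs(epochs.n_channels)
    total = len(bank.bands) * 2 * k
    rows = []
    for sel in selectors:
        for clf in classifiers:
            for frac in fractions:
                n_feat = max(1, int(round(frac * total)))
                rep = crossvalidate(
                    epochs,
                    selector=sel,
                    n_features=n_feat,
                    classifier=clf,
                    bank=bank,
                    csp_pairs=csp_pairs,
                    n_folds=n_folds,
                    seed=seed,
                )
                rows.append(
                    {
                        "selector": sel,
                        "classifier": clf,
                        "fraction": frac,
                        "n_features": n_feat,
                        "mean_accuracy": rep.mean["accuracy"],
                        "sd_accuracy": rep.sd["accuracy"],
                        "mean_f1": rep.mean["f1"],
                        "mean_auroc": rep.mean["auroc"],
                    }
                )
    return pd.DataFrame(rows)
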