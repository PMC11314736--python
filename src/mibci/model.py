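"""Model/results facade over the filter-bank CSP pipeline.

``MotorImageryCSP`` is constructed from epoched data plus pipeline choices;
``fit()`` runs the stratified cross-validation and also fits a final
full-data model, returning a ``MotorImageryResults`` that carries per-fold
metrics, their mean ± SD, the fitted spatial filters and feature ranking,
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierSpec, decision_scores, train
from .csp import CSPModel, multiband_csp_features, transform_csp, default_pairs
from .evaluate import CVReport, crossvalidate, _zscored
from .feature_selection import RankingResult, rank_features, select_top
from .filterbank import FilterBank, apply_filterbank
from .io import EpochedEEG, FeatureTable


class MotorImageryCSP:
    """Filter-bank CSP classification model for two-class motor-imagery EEG.

    Parameters
    ----------
    epochs : EpochedEEG
        Labeled trials.
    bank : FilterBank, optional
        Sub-band decomposition (default: mu / low-beta / high-beta / 8-30 Hz).
    csp_pairs : int, optional
        CSP filter pairs per band; default ``min(4, ch // 2)``.
    selector : str or None
        Feature-ranking method (``relieff``, ``inf_fs``, ``ilfs``, ``fsv``,
        ``sd``) or None for no selection.
    n_features : int, optional
        Features kept after ranking (default: all, i.e. ranking only).
    classifier : str or ClassifierSpec
        ``lda`` (default), ``svm_rbf`` or ``mlp``.
    """

    def __init__(
        self,
        epochs: EpochedEEG,
        bank: FilterBank | None = None,
        csp_pairs: int | None = None,
        selector: str | None = "relieff",
        n_features: int | None = None,
        classifier: str | ClassifierSpec = "lda",
        shrinkage: float = 0.0,
        selector_kwargs: dict | None = None,
    ) -> None:
        epochs.require_two_classes()
        self.epochs = epochs
        self.bank = bank if bank is not None else FilterBank()
        self.csp_pairs = csp_pairs if csp_pairs is not None else default_pairs(epochs.n_channels)
        self.selector = selector
        self.n_features = n_features
        self.classifier = classifier if isinstance(classifier, ClassifierSpec) else ClassifierSpec(kind=classifier)
        self.shrinkage = shrinkage
        self.selector_kwargs = selector_kwargs or {}

    @classmethod
    def from_arrays(
        cls,
        data: np.ndarray,
        labels: np.ndarray,
        fs: float,
        channel_names: list[str] | None = None,
        **kwargs,
    ) -> "MotorImageryCSP":
        """Build from a raw (trials, channels, samples) tensor."""
        return cls(EpochedEEG(data, labels, fs, channel_names or []), **kwargs)

    def fit(self, n_folds: int = 5, seed: int = 42) -> "MotorImageryResults":
        """Cross-validate and fit the final full-data pipeline."""
        report = crossvalidate(
            self.epochs,
            selector=self.selector,
            n_features=self.n_features,
            classifier=self.classifier,
            bank=self.bank,
            csp_pairs=self.csp_pairs,
            shrinkage=self.shrinkage,
            n_folds=n_folds,
            seed=seed,
            selector_kwargs=self.selector_kwargs,
        )
        features, csp_models = multiband_csp_features(
            self.epochs, self.bank, k=self.csp_pairs, shrinkage=self.shrinkage
        )
        ranking = None
        keep = list(range(features.n_features))
        if self.selector is not None:
            ranking = rank_features(_zscored(features), self.selector, **self.selector_kwargs)
            keep = select_top(ranking, self.n_features or features.n_features)
        final = train(self.classifier, features.select_columns(keep))
        return MotorImageryResults(
            model=self,
            report=report,
            features=features,
            csp_models=csp_models,
            ranking=ranking,
            selected=keep,
            final_classifier=final,
        )


@dataclass
class MotorImageryResults:
    """Cross-validation estimates and the fitted full-data pipeline."""

    model: MotorImageryCSP
    report: CVReport
    features: FeatureTable
    csp_models: list[CSPModel]
    ranking: RankingResult | None
    selected: list[int]
    final_classifier: object = field(repr=False, default=None)

    @property
    def mean_accuracy(self) -> float:
        return float(self.report.mean["accuracy"])

    @property
    def per_fold_(self):
        return self.report.per_fold

    def predict(self, epochs: EpochedEEG) -> np.ndarray:
        """Classify new epochs with the full-data pipeline."""
        feats = self._transform(epochs)
        return self.final_classifier.predict(feats.values)

    def scores(self, epochs: EpochedEEG) -> np.ndarray:
        """Decision scores for new epochs (higher = class 2)."""
        feats = self._transform(epochs)
        return decision_scores(self.final_classifier, feats.values)

    def _transform(self, epochs: EpochedEEG) -> FeatureTable:
        bands = apply_filterbank(epochs, self.model.bank)
        blocks = [transform_csp(m, b) for m, b in zip(self.csp_models, bands)]
        table = FeatureTable(
            np.hstack([b.values for b in blocks]),
            epochs.labels.copy(),
            [mm for b in blocks for mm in b.feature_meta],
        )
        return table.select_columns(self.selected)

    def summary(self) -> str:
        """Human-readable fit summary: metrics, bands, selected features."""
        m = self.model
        lines = [
            "Motor-imagery filter-bank CSP results",
            "=" * 55,
            f"trials: {m.epochs.n_trials} ({np.sum(m.epochs.labels == 1)} class 1, "
            f"{np.sum(m.epochs.labels == 2)} class 2), "
            f"{m.epochs.n_channels} channels @ {m.epochs.fs:g} Hz",
            f"bands: {', '.join(f'{b.name} ({b.lo:g}-{b.hi:g} Hz)' for b in m.bank.bands)}",
            f"CSP pairs per band: {m.csp_pairs}  ->  {self.features.n_features} features",
            f"selector: {m.selector or 'none'}; kept {len(self.selected)} features",
            f"classifier: {m.classifier.kind}",
            "",
            self.report.summary(),
        ]
        if self.ranking is not None:
            top = self.ranking.order[: min(8, len(self.selected))]
            parts = []
            for j in top:
                meta = self.features.feature_meta[j]
                parts.append(f"{j}({meta.get('band', '')}#{meta.get('filter', '')})")
            lines += ["", "top-ranked features: " + ", ".join(parts)]
        return "\n".join(lines)

    def plot_per_fold(self, ax=None):
        """Bar plot of per-fold accuracy (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.report.per_fold
        ax.bar(df["fold"], df["accuracy"])
        ax.axhline(self.mean_accuracy, ls="--", color="k", label="mean")
        ax.set_xlabel("fold")
        ax.set_ylabel("accuracy (%)")
        ax.set_ylim(0, 100)
        ax.legend()
        return ax
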