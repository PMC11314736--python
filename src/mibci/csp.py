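"""Common Spatial Pattern (CSP) filters and log-variance features.

CSP finds spatial filters w that maximize the variance of one class while
minimizing it for the other.  With trace-normalized class covariances C1 and
C2 and composite Cc = C1 + C2, a whitening transform P (P Cc P' = I) followed
by the rotation B that diagonalizes the whitened class-1 covariance gives
filters W = P' B satisfying

    W' C1 W = D1,    W' C2 W = D2,    D1 + D2 = I,

so filters at the extremes of the D1 spectrum are maximally discriminative.
Per trial E, the feature for filter w_j is log var(w_j' E); the first k and
last k filters are retained (2k features per band).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .filterbank import BandSpec, FilterBank, apply_filterbank
from .io import EpochedEEG, FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class CSPModel:
    """Fitted spatial filters for one band.

    Attributes
    ----------
    W : ndarray (ch, ch)
        Spatial filters in columns, ordered by descending class-1 eigenvalue.
    eigvals : ndarray (ch,)
        Class-1 eigenvalues (class-2 eigenvalues are their complement to 1).
    k : int
        Filter pairs retained.
    selected : list of int
        Column indices kept for features: first k and last k.
    band : BandSpec or None
        Band the model was fitted on.
    """

    W: np.ndarray
    eigvals: np.ndarray
    k: int
    selected: list[int]
    band: BandSpec | None = None

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def default_pairs(n_channels: int) -> int:
    """Default number of CSP pairs: min(4, ch // 2).

    Yields 8 features per band on high-density montages (e.g. 118 channels)
    and 2 per band on 2-channel bipolar recordings.
    """
    return min(4, n_channels // 2)


def class_covariance(trials: np.ndarray) -> np.ndarray:
    """Average trace-normalized spatial covariance over trials of one class.

    Each trial's covariance E E' is divided by its trace before averaging, so
    the result has trace exactly 1.

    Parameters
    ----------
    trials : ndarray (n_trials, ch, n_samples)
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim == 2:
        trials = trials[None]
    if trials.shape[0] < 1:
        raise ValueError("need at least one trial")
    if trials.shape[1] < 2:
        raise ValueError("need at least two channels")
    covs = []
    for i, E in enumerate(trials):
        C = E @ E.T
        tr = np.trace(C)
        if tr <= 0 or not np.isfinite(tr):
            raise ValueError(f"degenerate trial covariance (trace {tr}) at trial {i}")
        covs.append(C / tr)
    C = np.mean(covs, axis=0)
    C /= np.trace(C)  # guard rounding so the trace-1 postcondition is exact
    return 0.5 * (C + C.T)


def whitening_transform(Cc: np.ndarray, shrinkage: float = 0.0) -> np.ndarray:
    """Whitening matrix P with P Cc P' = I.

    Eigendecomposes Cc = Uc diag(lam) Uc' (eigenvalues descending) and returns
    P = diag(lam)^(-1/2) Uc'.  Optional shrinkage adds ``shrinkage * trace``
    times the identity before decomposition to guard rank deficiency.
    """
    Cc = np.asarray(Cc, dtype=float)
    if shrinkage > 0:
        Cc = Cc + shrinkage * np.trace(Cc) * np.eye(Cc.shape[0])
    lam, U = eigh(Cc)
    lam, U = lam[::-1], U[:, ::-1]  # descending
    if lam[-1] <= 0 or lam[-1] < 1e-12 * lam[0]:
        raise ValueError("rank-deficient composite covariance; enable shrinkage > 0")
    return (U / np.sqrt(lam)).T


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Force each column's largest-magnitude element positive (determinism)."""
    j = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[j, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def fit_csp(
    band_epochs: EpochedEEG,
    k: int | None = None,
    shrinkage: float = 0.0,
    band: BandSpec | None = None,
) -> CSPModel:
    """Fit CSP filters on one band's epochs.

    Parameters
    ----------
    band_epochs : EpochedEEG
        Band-limited trials with both classes present.
    k : int, optional
        Filter pairs to keep; default ``min(4, ch // 2)``.
    shrinkage : float
        Relative ridge added to the composite covariance (0 = off).
    """
    band_epochs.require_two_classes()
    ch = band_epochs.n_channels
    if k is None:
        k = default_pairs(ch)
    if 2 * k > ch:
        raise ValueError(f"2k exceeds channel count ({2 * k} > {ch})")
    if k < 1:
        raise ValueError("k must be >= 1")
    C1 = class_covariance(band_epochs.data[band_epochs.labels == 1])
    C2 = class_covariance(band_epochs.data[band_epochs.labels == 2])
    P = whitening_transform(C1 + C2, shrinkage=shrinkage)
    S1 = P @ C1 @ P.T
    S1 = 0.5 * (S1 + S1.T)
    lam, B = eigh(S1)
    lam, B = lam[::-1], B[:, ::-1]  # descending class-1 eigenvalue
    W = _fix_signs(P.T @ B)
    selected = list(range(k)) + list(range(ch - k, ch))
    return CSPModel(W=W, eigvals=lam, k=k, selected=selected, band=band)


def transform_csp(model: CSPModel, epochs: EpochedEEG, log_floor: float = 1e-300) -> FeatureTable:
    """Project epochs through the selected filters and take log variances.

    Returns a 2k-column feature block; variance uses the n-1 denominator and
    log is natural.  Zero-variance projections are floored at ``log_floor``
    (logged) so features stay finite.
    """
    if epochs.n_channels != model.n_channels:
        raise ValueError(
            f"channel mismatch: model has {model.n_channels}, epochs have {epochs.n_channels}"
        )
    Wsel = model.W[:, model.selected]  # ch x 2k
    proj = np.einsum("cj,tcs->tjs", Wsel, epochs.data)
    var = proj.var(axis=2, ddof=1)
    n_floored = int((var <= 0).sum())
    if n_floored:
        logger.warning("floored %d zero-variance projections", n_floored)
        var = np.maximum(var, log_floor)
    feats = np.log(var)
    band_name = model.band.name if model.band is not None else ""
    meta = [{"band": band_name, "filter": int(j)} for j in model.selected]
    return FeatureTable(feats, epochs.labels.copy(), meta)


def multiband_csp_features(
    epochs: EpochedEEG,
    bank: FilterBank | None = None,
    k: int | None = None,
    shrinkage: float = 0.0,
    fit_on: EpochedEEG | None = None,
) -> tuple[FeatureTable, list[CSPModel]]:
    """Filter-bank CSP: fit per-band filters and concatenate feature blocks.

    Column count is ``n_bands * 2k``; ``feature_meta`` records the band and
    filter index of every column.  When ``fit_on`` is given, filters are
    fitted on those trials and ``epochs`` are only transformed (the
    cross-validation harness uses this to keep test folds out of the fit).
    """
    if bank is None:
        bank = FilterBank()
    fit_epochs = epochs if fit_on is None else fit_on
    blocks, models = [], []
    fit_bands = apply_filterbank(fit_epochs, bank)
    tr_bands = fit_bands if fit_on is None else apply_filterbank(epochs, bank)
    for band, fit_band, tr_band in zip(bank.bands, fit_bands, tr_bands):
        model = fit_csp(fit_band, k=k, shrinkage=shrinkage, band=band)
        blocks.append(transform_csp(model, tr_band))
        models.append(model)
    values = np.hstack([b.values for b in blocks])
    meta = [m for b in blocks for m in b.feature_meta]
    return FeatureTable(values, epochs.labels.copy(), meta), models
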