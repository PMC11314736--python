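"""Containers and storage for epoched EEG and extracted feature tables.

Two on-disk layouts are supported for epochs:

``generic_table``
    The package's own columnar container: ``<stem>.npy`` holding the
    ``(n_trials, n_channels, n_samples)`` tensor plus a ``<stem>.json``
    sidecar with labels, sampling rate and channel names.

``bci3_mat``
    The BCI Competition III distribution layout (MATLAB ``.mat`` with
    ``cnt`` / ``mrk`` / ``nfo`` variables, e.g. Dataset IVA: 100 Hz,
    118 channels), read-only.  Trials are cut cue-locked from the
    continuous recording over a configurable ``[t_start, t_end]`` window
    (default 0.5-2.5 s post-cue); cues without a label (competition test
    trials) are dropped with a logged count.

Feature tables are stored as CSV with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_LABELS = (1, 2)


@dataclass
class EpochedEEG:
    """Labeled trial tensor with sampling rate and channel names.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial signals in volts or arbitrary units.
    labels : ndarray of int, shape (n_trials,)
        Class labels in {1, 2}.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per channel.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (n_trials, n_channels, n_samples)")
        if self.data.shape[2] < 2:
            raise ValueError("n_samples must be >= 2")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal n_trials")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal n_channels")
        bad = ~np.isfinite(self.data)
        if bad.any():
            trial = int(np.argwhere(bad)[0, 0])
            raise ValueError(f"non-finite sample in trial {trial}")
        extra = set(self.labels.tolist()) - set(VALID_LABELS)
        if extra:
            raise ValueError(f"binary labels required: labels must be in {{1,2}}, got extra {sorted(extra)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def require_two_classes(self) -> None:
        """Raise unless both classes are present (needed by any fitting op)."""
        present = set(self.labels.tolist())
        if present != set(VALID_LABELS):
            raise ValueError(f"both classes required for fitting, got labels {sorted(present)}")

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EpochedEEG":
        idx = np.asarray(idx)
        return EpochedEEG(self.data[idx], self.labels[idx], self.fs, list(self.channel_names))


@dataclass
class FeatureTable:
    """Trials-by-features matrix with per-column provenance.

    ``feature_meta`` carries one ``(band, filter_index)``-style dict per
    column, e.g. ``{"band": "mu", "filter": 0}``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_trials, n_features)")
        if self.values.shape[1] == 0:
            raise ValueError("feature table must have at least one column")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal n_trials")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if not self.feature_meta:
            self.feature_meta = [{"band": "", "filter": j} for j in range(self.values.shape[1])]
        if len(self.feature_meta) != self.values.shape[1]:
            raise ValueError("feature_meta length must equal n_features")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, idx: Sequence[int] | np.ndarray) -> "FeatureTable":
        idx = list(idx)
        return FeatureTable(self.values[:, idx], self.labels.copy(), [dict(self.feature_meta[j]) for j in idx])


def save_epochs(epochs: EpochedEEG, path: str | Path) -> None:
    """Write the columnar epoch container (``<stem>.npy`` + ``<stem>.json``)."""
    stem = Path(path).with_suffix("")
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(str(stem) + ".npy", epochs.data)
    meta = {
        "labels": epochs.labels.tolist(),
        "fs": float(epochs.fs),
        "channel_names": list(epochs.channel_names),
    }
    with open(str(stem) + ".json", "w") as fh:
        json.dump(meta, fh)


def _load_generic(path: Path) -> EpochedEEG:
    stem = path.with_suffix("")
    npy, js = Path(str(stem) + ".npy"), Path(str(stem) + ".json")
    if not npy.exists() or not js.exists():
        raise FileNotFoundError(f"epoch container incomplete: need {npy} and {js}")
    data = np.load(npy)
    with open(js) as fh:
        meta = json.load(fh)
    return EpochedEEG(data, np.asarray(meta["labels"]), meta["fs"], meta["channel_names"])


def _load_bci3_mat(path: Path, t_start: float, t_end: float) -> EpochedEEG:
    from scipy.io import loadmat

    m = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    for key in ("cnt", "mrk", "nfo"):
        if key not in m:
            raise ValueError(f"not a BCI Competition III file: missing variable '{key}'")
    cnt = np.asarray(m["cnt"], dtype=float)  # samples x channels, 0.1 uV units
    mrk, nfo = m["mrk"], m["nfo"]
    fs = float(np.ravel(nfo.fs)[0])
    clab = [str(c) for c in np.ravel(nfo.clab)]
    pos = np.atleast_1d(np.ravel(mrk.pos)).astype(int)
    raw_y = np.atleast_1d(np.ravel(mrk.y)).astype(float)
    labeled = np.isfinite(raw_y)
    dropped = int((~labeled).sum())
    if dropped:
        logger.info("dropping %d unlabeled cue(s) from %s", dropped, path.name)
    pos, y = pos[labeled], raw_y[labeled].astype(int)
    if len(pos) == 0:
        raise ValueError("no labeled trials in file")
    i0, i1 = int(round(t_start * fs)), int(round(t_end * fs))
    if i1 - i0 < 2:
        raise ValueError("epoch window too short")
    trials = []
    for p in pos:
        seg = cnt[p + i0 : p + i1, :]
        if seg.shape[0] != i1 - i0:
            raise ValueError("cue too close to end of recording for requested window")
        trials.append(seg.T)  # channels x samples
    data = np.stack(trials) * 0.1e-6  # stored int16 in units of 0.1 uV -> volts
    return EpochedEEG(data, y, fs, clab)


def load_epochs(
    path: str | Path,
    layout: str = "generic_table",
    t_start: float = 0.5,
    t_end: float = 2.5,
) -> EpochedEEG:
    """Read epoched EEG from disk.

    Parameters
    ----------
    path : path
        File location (for ``generic_table`` either the ``.npy`` or ``.json``
        half of the pair, or the common stem).
    layout : {"generic_table", "bci3_mat"}
        On-disk layout (see module docstring).
    t_start, t_end : float
        Cue-locked epoch window in seconds, ``bci3_mat`` only.  The default
        0.5-2.5 s keeps 2 s of post-cue imagery data.
    """
    path = Path(path)
    if layout == "generic_table":
        return _load_generic(path)
    if layout == "bci3_mat":
        if not path.exists():
            raise FileNotFoundError(path)
        return _load_bci3_mat(path, t_start, t_end)
    raise ValueError(f"unsupported layout '{layout}' (expected generic_table or bci3_mat)")


def save_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"f{j}" for j in range(table.n_features)]
    df = pd.DataFrame(table.values, columns=cols)
    df.insert(0, "label", table.labels)
    df.to_csv(path, index=False)  # pandas default repr is shortest round-trip
    with open(str(path.with_suffix("")) + ".meta.json", "w") as fh:
        json.dump({"feature_meta": table.feature_meta}, fh)


def load_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table written by :func:`save_feature_table`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise ValueError("schema mismatch: no 'label' column")
    meta_path = Path(str(path.with_suffix("")) + ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)["feature_meta"]
    values = df.drop(columns="label").to_numpy(dtype=float)
    return FeatureTable(values, df["label"].to_numpy(dtype=int), meta)
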