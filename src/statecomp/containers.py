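"""In-memory containers and on-disk formats for multichannel recordings.

A recording is a samples x channels matrix with a sampling rate and channel
metadata. On disk, a recording is stored as a numeric matrix file (delimited
text or raw float64, selectable) plus a JSON sidecar holding the sampling
rate, channel names, modality, units and subject id, so that a dataset is
fully self-describing without binary container dependencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Recording",
    "EnvelopeSet",
    "ReductionBasis",
    "StateActivation",
    "write_recording",
    "read_recording",
    "read_edf",
]

#: Recognized recording modalities.
MODALITIES = ("electrode", "gradiometer_pair", "combined_gradiometer", "source")


@dataclass
class Recording:
    """One subject's samples x channels time series.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Sensor (or source) time series in acquisition units.
    fs : float
        Sampling rate in Hz.
    channels : sequence of str
        Unique channel identifiers, one per column.
    modality : str
        One of ``electrode``, ``gradiometer_pair``, ``combined_gradiometer``
        or ``source``. Gradiometer pairs are stored as consecutive columns
        (two orthogonal planar gradiometers per location).
    subject_id : str
        Identifier used when concatenating across subjects.
    reference : str
        ``"none"`` or ``"average"`` (common average reference; electrodes
        only).
    """

    data: np.ndarray
    fs: float
    channels: Sequence[str]
    modality: str = "electrode"
    subject_id: str = "S0"
    reference: str = "none"
    band: Optional[tuple[float, float]] = None  # set after band-pass filtering

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channels = list(self.channels)
        if len(self.channels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel ids for {self.data.shape[1]} columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel ids must be unique")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.reference not in ("none", "average"):
            raise ValueError(f"unknown reference {self.reference!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        """Return a copy with some fields replaced (data is copied)."""
        if "data" not in kwargs:
            kwargs["data"] = self.data.copy()
        return replace(self, **kwargs)


@dataclass
class EnvelopeSet:
    """Non-negative power envelopes, possibly demeaned/normalized/concatenated.

    ``normalization`` records, per subject, the channel mean offsets that were
    removed and the single global scale each subject was divided by, so the
    transform is invertible. ``boundaries`` gives the half-open sample ranges
    of each subject segment in a concatenated set.
    """

    data: np.ndarray
    fs: float
    channels: Sequence[str]
    subject_ids: Sequence[str] = field(default_factory=lambda: ["S0"])
    boundaries: Sequence[tuple[int, int]] = field(default_factory=list)
    normalization: dict = field(default_factory=dict)
    demeaned: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if not self.boundaries:
            self.boundaries = [(0, self.data.shape[0])]
        self.channels = list(self.channels)
        self.subject_ids = list(self.subject_ids)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def segment(self, i: int) -> np.ndarray:
        a, b = self.boundaries[i]
        return self.data[a:b]


@dataclass
class ReductionBasis:
    """Principal-component loadings used for dimensionality reduction.

    ``loadings`` is channels x N with orthonormal columns;
    ``explained_variance_ratio`` holds the per-component variance fractions
    (non-increasing).
    """

    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=np.float64
        )
        g = self.loadings.T @ self.loadings
        if not np.allclose(g, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loadings must be orthonormal")
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class StateActivation:
    """Exclusive, complete per-sample state labels at a stated sampling rate.

    ``labels`` holds one integer state index (0-based) per sample. The value
    -1 marks samples awaiting nearest-peak interpolation when a backfit was
    restricted to GFP peaks; such partially-labelled activations are not
    exclusive-complete until smoothed.
    """

    labels: np.ndarray
    n_states: int
    fs: float
    smoothed: bool = False
    peak_indices: Optional[np.ndarray] = None
    state_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        valid = (self.labels >= -1) & (self.labels < self.n_states)
        if not valid.all():
            raise ValueError("labels outside [-1, n_states)")
        if self.peak_indices is not None:
            self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if self.state_names is None:
            self.state_names = [f"state{k + 1}" for k in range(self.n_states)]

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def is_complete(self) -> bool:
        return bool((self.labels >= 0).all())

    def to_binary(self) -> np.ndarray:
        """Return the K x T one-hot activation matrix (requires completeness)."""
        if not self.is_complete:
            raise ValueError("activation has unassigned samples; smooth it first")
        out = np.zeros((self.n_states, self.n_samples), dtype=np.int8)
        out[self.labels, np.arange(self.n_samples)] = 1
        return out


# ---------------------------------------------------------------------------
# On-disk container


def write_recording(rec: Recording, out_dir: str | Path, fmt: str = "text") -> Path:
    """Write a recording as matrix file + JSON sidecar; return the sidecar path.

    fmt="text" writes a tab-delimited matrix (portable, diff-able);
    fmt="binary" writes raw little-endian float64, row-major.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.subject_id}_{rec.modality}"
    if fmt == "text":
        mat_name = stem + ".tsv"
        np.savetxt(out_dir / mat_name, rec.data, delimiter="\t", fmt="%.17g")
    elif fmt == "binary":
        mat_name = stem + ".f64"
        rec.data.astype("<f8").tofile(out_dir / mat_name)
    else:
        raise ValueError("fmt must be 'text' or 'binary'")
    meta = {
        "matrix_file": mat_name,
        "format": fmt,
        "n_samples": rec.n_samples,
        "n_channels": rec.n_channels,
        "fs": rec.fs,
        "channels": list(rec.channels),
        "modality": rec.modality,
        "subject_id": rec.subject_id,
        "reference": rec.reference,
        "band": list(rec.band) if rec.band else None,
        "units": "arbitrary",
    }
    sidecar = out_dir / (stem + ".json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return sidecar


def read_recording(sidecar: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    mat_path = sidecar.parent / meta["matrix_file"]
    if meta["format"] == "text":
        data = np.loadtxt(mat_path, delimiter="\t", ndmin=2)
    else:
        data = np.fromfile(mat_path, dtype="<f8").reshape(
            meta["n_samples"], meta["n_channels"]
        )
    band = meta.get("band")
    return Recording(
        data=data,
        fs=meta["fs"],
        channels=meta["channels"],
        modality=meta["modality"],
        subject_id=meta["subject_id"],
        reference=meta.get("reference", "none"),
        band=tuple(band) if band else None,
    )


def read_edf(path: str | Path, subject_id: Optional[str] = None) -> Recording:
    """Read an electrode recording from an EDF file (requires ``mne``).

    Channels are mapped by label and the sampling rate is taken from the
    header. All channels are loaded as electrodes with no re-referencing
    applied.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T  # mne returns channels x samples
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        modality="electrode",
        subject_id=subject_id or Path(path).stem,
    )
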