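"""Deterministic preprocessing shared by the microstate and envelope-HMM arms.

All operations are pure functions of their inputs: band-pass filtering
(zero-phase), non-overlapping moving-window downsampling, common-average
re-referencing, Euclidean combination of planar-gradiometer pairs, Hilbert
power envelopes, per-subject demeaning/global-scale normalization with
temporal concatenation, principal-component reduction, and a scalar-
regularized minimum-norm inverse onto a known leadfield.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len

from .containers import EnvelopeSet, Recording, ReductionBasis

__all__ = [
    "bandpass",
    "moving_window_downsample",
    "rereference_average",
    "combine_gradiometer_pairs",
    "hilbert_envelope",
    "normalize_and_concatenate",
    "pca_reduce",
    "minimum_norm_inverse",
]

logger = logging.getLogger(__name__)

#: Default duration (s) of envelope edges flagged as filter/Hilbert transients.
EDGE_SECONDS = 1.0


def bandpass(rec: Recording, low_hz: float, high_hz: float) -> Recording:
    """Zero-phase band-pass filter (4th-order Butterworth, forward-backward).

    Butterworth is maximally flat, so the effective (squared) passband ripple
    stays below 1%; forward-backward application cancels group delay so GFP
    peak timing is untouched.
    """
    if not (0 < low_hz < high_hz < rec.fs / 2):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, fs/2)"
        )
    sos = signal.butter(4, (low_hz, high_hz), btype="bandpass", fs=rec.fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=0)
    return rec.copy_with(data=np.ascontiguousarray(out), band=(low_hz, high_hz))


def _window_means(data: np.ndarray, window: int) -> np.ndarray:
    """Means of non-overlapping windows; trailing partial window discarded."""
    n = (data.shape[0] // window) * window
    return data[:n].reshape(-1, window, data.shape[1]).mean(axis=1)


def moving_window_downsample(
    obj: Union[Recording, EnvelopeSet], target_fs: float
) -> Union[Recording, EnvelopeSet]:
    """Downsample by averaging non-overlapping windows of length fs/target_fs.

    The boxcar mean acts as the implicit (soft) low-pass; no extra filter is
    applied. The ratio fs/target_fs must be an integer and trailing samples
    that do not fill a window are discarded, so the output has floor(n/w)
    samples.
    """
    ratio = obj.fs / target_fs
    window = int(round(ratio))
    if abs(ratio - window) > 1e-9 or window < 1:
        raise ValueError(
            f"fs={obj.fs} not an integer multiple of target_fs={target_fs}"
        )
    if window == 1:
        return obj
    out = _window_means(obj.data, window)
    if isinstance(obj, Recording):
        return obj.copy_with(data=out, fs=target_fs)
    scale = window  # boundaries shrink by the window factor
    bounds = [(a // scale, b // scale) for a, b in obj.boundaries]
    return EnvelopeSet(
        data=out, fs=target_fs, channels=obj.channels,
        subject_ids=obj.subject_ids, boundaries=bounds,
        normalization=obj.normalization, demeaned=obj.demeaned,
    )


def rereference_average(rec: Recording) -> Recording:
    """Common average reference: remove each sample's spatial mean.

    Only meaningful for electrode potentials; gradiometer amplitudes have no
    free reference and are rejected.
    """
    if rec.modality != "electrode":
        raise ValueError("average re-referencing applies to electrode data only")
    out = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.copy_with(data=out, reference="average")


def combine_gradiometer_pairs(
    rec: Recording, pairs: Optional[Sequence[Tuple[int, int]]] = None
) -> Recording:
    """Combine orthogonal planar-gradiometer pairs by their Euclidean norm.

    By default consecutive channels (0,1), (2,3), ... form a pair, matching
    the layout written by the synthetic generator. The result is one
    non-negative amplitude channel per sensor location.
    """
    if rec.modality != "gradiometer_pair":
        raise ValueError("input must be gradiometer_pair data")
    if rec.n_channels % 2:
        raise ValueError("gradiometer recordings need an even channel count")
    if pairs is None:
        pairs = [(i, i + 1) for i in range(0, rec.n_channels, 2)]
    idx_a = [a for a, _ in pairs]
    idx_b = [b for _, b in pairs]
    out = np.hypot(rec.data[:, idx_a], rec.data[:, idx_b])
    names = [f"{rec.channels[a]}+{rec.channels[b]}" for a, b in pairs]
    return Recording(
        data=out, fs=rec.fs, channels=names, modality="combined_gradiometer",
        subject_id=rec.subject_id, band=rec.band,
    )


def hilbert_envelope(rec: Recording) -> EnvelopeSet:
    """Per-channel analytic-signal magnitude (power envelope).

    The input should be band-limited; a raw (unfiltered) recording triggers a
    warning since broadband envelopes are dominated by low-frequency drift.
    The FFT length is padded to a fast composite size and truncated back.
    """
    if rec.band is None:
        logger.warning(
            "hilbert_envelope called on an unfiltered recording (%s)",
            rec.subject_id,
        )
    n = rec.n_samples
    analytic = signal.hilbert(rec.data, N=next_fast_len(n), axis=0)[:n]
    return EnvelopeSet(
        data=np.abs(analytic), fs=rec.fs, channels=list(rec.channels),
        subject_ids=[rec.subject_id],
    )


def normalize_and_concatenate(envelopes: List[EnvelopeSet]) -> EnvelopeSet:
    """Demean per channel, scale by each subject's pooled SD, concatenate.

    "Global variance across sensors" is implemented as division by the pooled
    standard deviation over all sensors and samples of the subject (computed
    after demeaning), which makes each subject's pooled variance exactly 1.
    Subject boundaries are recorded for later per-subject restriction.
    """
    if not envelopes:
        raise ValueError("need at least one envelope set")
    ref = envelopes[0]
    for env in envelopes[1:]:
        if list(env.channels) != list(ref.channels) or env.fs != ref.fs:
            raise ValueError("envelope sets differ in channels or sampling rate")
    chunks, bounds, norm = [], [], {}
    offset = 0
    subject_ids: List[str] = []
    for env in envelopes:
        means = env.data.mean(axis=0)
        centered = env.data - means
        scale = centered.std(ddof=0)  # pooled over all sensors and samples
        if scale == 0:
            raise ValueError("constant envelope set cannot be normalized")
        chunks.append(centered / scale)
        sid = env.subject_ids[0]
        subject_ids.append(sid)
        norm[sid] = {"channel_means": means.tolist(), "global_scale": float(scale)}
        bounds.append((offset, offset + env.n_samples))
        offset += env.n_samples
    return EnvelopeSet(
        data=np.concatenate(chunks, axis=0), fs=ref.fs,
        channels=list(ref.channels), subject_ids=subject_ids,
        boundaries=bounds, normalization=norm, demeaned=True,
    )


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|.| element made positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def pca_reduce(env: EnvelopeSet, n_components: int) -> Tuple[np.ndarray, ReductionBasis]:
    """Project onto the top-N principal components of the channel covariance.

    Returns the reduced (samples x N) series and the basis (loadings are the
    leading eigenvectors of the channel covariance of the concatenated set,
    with a deterministic sign convention).
    """
    C = env.n_channels
    if not (1 <= n_components <= C):
        raise ValueError(f"n_components must be in [1, {C}]")
    X = env.data - env.data.mean(axis=0)
    cov = (X.T @ X) / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    loadings = np.column_stack(
        [_fix_sign(evecs[:, i]) for i in range(n_components)]
    )
    evr = evals[:n_components] / evals.sum()
    reduced = X @ loadings
    return reduced, ReductionBasis(loadings=loadings, explained_variance_ratio=evr)


def minimum_norm_inverse(
    rec: Recording, leadfield: np.ndarray, lam: float = 1e-2
) -> Recording:
    """Tikhonov-regularized minimum-norm source estimate.

    Source series = L^T (L L^T + lam * I)^-1 @ sensor series, with the
    regularizer scaled by the mean diagonal of L L^T so ``lam`` is unitless.
    This is a deliberately simplified scalar-lambda inverse; no noise
    covariance whitening is performed.
    """
    L = np.asarray(leadfield, dtype=np.float64)
    if L.shape[0] != rec.n_channels:
        raise ValueError("leadfield rows must match recording channels")
    gram = L @ L.T
    reg = lam * np.trace(gram) / gram.shape[0]
    kernel = L.T @ np.linalg.solve(gram + reg * np.eye(gram.shape[0]), np.eye(gram.shape[0]))
    src = rec.data @ kernel.T
    return Recording(
        data=src, fs=rec.fs,
        channels=[f"src{i + 1:02d}" for i in range(L.shape[1])],
        modality="source", subject_id=rec.subject_id, band=rec.band,
    )
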