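"""Microstate analysis: GFP, AAHC clustering, group alignment, backfitting.

Microstates are recurring quasi-stable sensor topographies. They are
classified here by atomize-agglomerate hierarchical clustering (AAHC):
starting from singleton clusters of instantaneous maps (usually restricted
to local maxima of global field power), the algorithm repeatedly dissolves
the cluster contributing least explained GFP and reassigns its maps to the
cluster whose principal-component topography correlates best (in absolute
value for polarity-invariant electrode data; signed for non-negative
combined-gradiometer amplitude maps). Per-sample state labels are then
obtained by backfitting: each topography is assigned to the template of
maximal (absolute) spatial correlation, optionally at GFP peaks only with
nearest-peak interpolation in between.

Conventions (all deterministic):

* Spatial correlation is computed after removing each map's spatial mean.
* Cluster "GFP" for the atomization choice is the cluster's contribution to
  explained GFP, sum over members of (gfp * |corr to cluster topography|)^2,
  which equals the top eigenvalue of the member scatter matrix / n_channels.
* Principal-component topographies get a fixed sign (largest-|.| channel
  positive); argmax ties break to the lowest index; GFP plateaus peak at
  their first sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import itertools

import numpy as np
from scipy import signal as _signal

from .containers import Recording, StateActivation

__all__ = [
    "MicrostateModel",
    "compute_gfp",
    "gfp_series",
    "find_gfp_peaks",
    "spatial_correlation",
    "aahc_cluster",
    "align_group_templates",
    "backfit",
    "smooth_by_peak_interpolation",
    "global_explained_variance",
]


@dataclass
class MicrostateModel:
    """K microstate template topographies (unit GFP) with fit metadata."""

    templates: np.ndarray  # K x n_channels, unit GFP, spatially demeaned
    labels: Sequence[str]
    polarity_invariant: bool = True
    gev: Optional[float] = None
    channels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=np.float64)
        if self.templates.ndim != 2 or self.templates.shape[0] < 1:
            raise ValueError("templates must be K x n_channels with K >= 1")
        gfps = self.templates.std(axis=1, ddof=0)
        if np.abs(gfps - 1.0).max() > 1e-9:
            raise ValueError("templates must have unit GFP")
        if self.gev is not None and not (0.0 <= self.gev <= 1.0 + 1e-12):
            raise ValueError("gev must lie in [0, 1]")
        self.labels = list(self.labels)
        if len(self.labels) != self.K:
            raise ValueError("one label per template required")

    @property
    def K(self) -> int:
        return self.templates.shape[0]


def compute_gfp(values: np.ndarray) -> float:
    """Global field power of one map: spatial SD about the spatial mean."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("GFP needs a 1-D map with at least 2 channels")
    return float(v.std(ddof=0))


def gfp_series(rec: Recording) -> np.ndarray:
    """GFP at every sample of a recording."""
    return rec.data.std(axis=1, ddof=0)


def find_gfp_peaks(series: np.ndarray) -> np.ndarray:
    """Indices of local maxima of a GFP series.

    Interior samples strictly greater than both neighbours; a flat plateau
    that is a local maximum contributes its first sample. Endpoints never
    count. May be empty (e.g. monotone series).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 3:
        raise ValueError("series too short for peak finding")
    _, props = _signal.find_peaks(x, plateau_size=1)
    return props["left_edges"].astype(np.int64)


def _demean_maps(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=1, keepdims=True)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spatial (map-wise) Pearson correlation after removing spatial means.

    Broadcasting: a is (..., C), b is (..., C); returns the correlation over
    the channel axis. Zero-variance maps give correlation 0.
    """
    a = _demean_maps(np.atleast_2d(np.asarray(a, dtype=np.float64)))
    b = _demean_maps(np.atleast_2d(np.asarray(b, dtype=np.float64)))
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    num = a @ b.T
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return r


def _fix_sign(v: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _unit_gfp(v: np.ndarray) -> np.ndarray:
    g = v.std(ddof=0)
    if g == 0:
        raise ValueError("cannot normalize a flat topography to unit GFP")
    return v / g


def _top_component(scatter: np.ndarray) -> Tuple[np.ndarray, float]:
    """Leading eigenvector (sign-fixed) and eigenvalue of a scatter matrix."""
    evals, evecs = np.linalg.eigh(scatter)
    return _fix_sign(evecs[:, -1]), float(evals[-1])


def aahc_cluster(
    maps: np.ndarray, K: int, polarity_invariant: bool = True,
    channels: Optional[Sequence[str]] = None,
) -> MicrostateModel:
    """Atomize-agglomerate hierarchical clustering of topographies.

    Starts from one singleton cluster per map; at each step the cluster with
    least explained GFP is dissolved (atomized) and each freed map is
    reassigned to the surviving cluster whose principal-component topography
    best matches it by absolute (or signed, if not polarity invariant)
    spatial correlation. Topographies of clusters that gained members are
    recomputed after each reassignment pass. Stops at K clusters; templates
    are returned with unit GFP, ordered by decreasing explained GFP.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=np.float64))
    n_maps, C = maps.shape
    if not (1 <= K <= n_maps):
        raise ValueError(f"K must be in [1, {n_maps}]")
    dm = _demean_maps(maps)
    norms = np.linalg.norm(dm, axis=1)
    # unit-norm versions for correlations; flat maps stay zero
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms[:, None] > 0, dm / np.where(norms > 0, norms, 1.0)[:, None], 0.0)

    # cluster state held in parallel containers so the atomization scan and
    # reassignment correlations stay vectorized
    members: List[List[int]] = [[i] for i in range(n_maps)]
    scatters: List[np.ndarray] = [np.outer(dm[i], dm[i]) for i in range(n_maps)]
    topos = unit.copy()  # row c = current PC topography of cluster c
    # quality (explained GFP) of a cluster = top scatter eigenvalue / C
    qual = (norms**2) / C
    total_gfp_sq = float(np.sum((norms / np.sqrt(C)) ** 2))

    while len(members) > K:
        worst = int(np.argmin(qual))  # ties: lowest index
        freed = members.pop(worst)
        scatters.pop(worst)
        topos = np.delete(topos, worst, axis=0)
        qual = np.delete(qual, worst)
        touched = set()
        scores_all = unit[freed] @ topos.T  # topographies frozen during pass
        if polarity_invariant:
            scores_all = np.abs(scores_all)
        for row, i in enumerate(freed):
            j = int(np.argmax(scores_all[row]))
            members[j].append(i)
            scatters[j] = scatters[j] + np.outer(dm[i], dm[i])
            touched.add(j)
        for j in touched:
            topos[j], lam = _top_component(scatters[j])
            qual[j] = lam / C

    order = np.argsort(-qual, kind="stable")
    templates = np.stack([_unit_gfp(topos[c]) for c in order])
    if not polarity_invariant:
        # orient each topography along the member mean (non-negative maps)
        for k, c in enumerate(order):
            mean_map = dm[members[c]].mean(axis=0)
            if templates[k] @ mean_map < 0:
                templates[k] = -templates[k]
    gev = float(qual.sum() / total_gfp_sq)
    labels = [f"M{k + 1}" for k in range(K)]
    return MicrostateModel(
        templates=templates, labels=labels,
        polarity_invariant=polarity_invariant, gev=gev, channels=channels,
    )


def align_group_templates(models: Sequence[MicrostateModel]) -> MicrostateModel:
    """Permutation-align per-subject models and extract group templates.

    Iteratively: (i) for each subject, find the template permutation (with
    sign flips when polarity invariant) maximizing the mean |spatial
    correlation| to the current group templates (exhaustive over K!); (ii)
    recompute each group template as the first principal component of the
    aligned subject templates. Repeats until the objective stops improving.
    """
    if not models:
        raise ValueError("need at least one model")
    K = models[0].K
    pol = models[0].polarity_invariant
    for m in models:
        if m.K != K:
            raise ValueError("all models must share K")
        if m.templates.shape[1] != models[0].templates.shape[1]:
            raise ValueError("all models must share the channel set")
    group = models[0].templates.copy()
    perms = list(itertools.permutations(range(K)))
    best_obj = -np.inf
    aligned = [m.templates.copy() for m in models]
    for _ in range(100):
        obj_total = 0.0
        new_aligned = []
        for m in models:
            r = spatial_correlation(m.templates, group)  # K x K
            score_mat = np.abs(r) if pol else r
            best_perm, best_score = None, -np.inf
            for p in perms:
                s = float(score_mat[list(p), range(K)].sum())
                if s > best_score + 1e-15:
                    best_score, best_perm = s, p
            t = m.templates[list(best_perm)].copy()
            if pol:  # flip aligned templates toward the group template
                flips = np.sign(np.diag(spatial_correlation(t, group)))
                flips[flips == 0] = 1.0
                t *= flips[:, None]
            new_aligned.append(t)
            obj_total += best_score
        stacked = np.stack(new_aligned)  # subjects x K x C
        group = np.stack([
            _unit_gfp(_fix_sign(np.linalg.eigh(
                stacked[:, k].T @ stacked[:, k]
            )[1][:, -1]))
            for k in range(K)
        ])
        obj = obj_total / (len(models) * K)
        if obj <= best_obj + 1e-12:
            break
        best_obj, aligned = obj, new_aligned
    return MicrostateModel(
        templates=group, labels=[f"M{k + 1}" for k in range(K)],
        polarity_invariant=pol, gev=None, channels=models[0].channels,
    )


def backfit(
    model: MicrostateModel, rec: Recording, restrict_to_peaks: bool = False
) -> StateActivation:
    """Assign each sample (or each GFP-peak sample) to its best template.

    The winning template maximizes the absolute spatial correlation with the
    instantaneous topography (signed correlation when the model is not
    polarity invariant); exact ties go to the lowest template index. With
    ``restrict_to_peaks`` only GFP-peak samples receive labels; the rest are
    marked -1 for later nearest-peak interpolation.
    """
    if model.channels is not None and list(model.channels) != list(rec.channels):
        raise ValueError("model and recording channel sets differ")
    r = spatial_correlation(rec.data, model.templates)  # T x K
    score = np.abs(r) if model.polarity_invariant else r
    labels = np.argmax(score, axis=1).astype(np.int64)
    peaks = None
    if restrict_to_peaks:
        peaks = find_gfp_peaks(gfp_series(rec))
        full = np.full(rec.n_samples, -1, dtype=np.int64)
        full[peaks] = labels[peaks]
        labels = full
    return StateActivation(
        labels=labels, n_states=model.K, fs=rec.fs, smoothed=False,
        peak_indices=peaks, state_names=list(model.labels),
    )


def smooth_by_peak_interpolation(
    activation: StateActivation,
    peak_indices: Optional[np.ndarray] = None,
) -> StateActivation:
    """Extend peak labels to all samples by nearest-neighbour interpolation.

    Every sample takes the label of its nearest peak (in samples); exact
    mid-point ties go to the earlier peak. Labels at the peaks themselves are
    unchanged.
    """
    peaks = peak_indices if peak_indices is not None else activation.peak_indices
    if peaks is None or len(peaks) == 0:
        raise ValueError("no peak indices available for interpolation")
    peaks = np.asarray(peaks, dtype=np.int64)
    t = np.arange(activation.n_samples)
    # searchsorted gives the insertion point among peaks; compare neighbours
    pos = np.searchsorted(peaks, t)
    left = np.clip(pos - 1, 0, len(peaks) - 1)
    right = np.clip(pos, 0, len(peaks) - 1)
    d_left = np.abs(t - peaks[left])
    d_right = np.abs(peaks[right] - t)
    nearest = np.where(d_left <= d_right, peaks[left], peaks[right])
    labels = activation.labels[nearest]
    return StateActivation(
        labels=labels, n_states=activation.n_states, fs=activation.fs,
        smoothed=True, peak_indices=peaks, state_names=activation.state_names,
    )


def global_explained_variance(
    model: MicrostateModel, rec: Recording,
    activation: Optional[StateActivation] = None,
) -> float:
    """Fraction of global variance explained by the microstate labelling.

    GEV = sum_t (gfp_t * corr(map_t, template of assigned state))^2
          / sum_t gfp_t^2,
    evaluated over labelled samples only.
    """
    if activation is None:
        activation = backfit(model, rec)
    gfp = gfp_series(rec)
    mask = activation.labels >= 0
    r = spatial_correlation(rec.data[mask], model.templates)
    rk = r[np.arange(mask.sum()), activation.labels[mask]]
    denom = float(np.sum(gfp[mask] ** 2))
    if denom == 0:
        return 0.0
    return float(np.sum((gfp[mask] * rk) ** 2) / denom)
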