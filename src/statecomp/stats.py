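"""State summary statistics and cross-state comparison analyses.

Given exclusive-complete binary state activations this module computes:

* mean lifetimes (mean duration of contiguous activation runs) and
  fractional occupancies per state;
* partial-correlation power maps: for each state, the correlation between
  its activation series and the power envelope at each location, after
  regressing out the other states' activations from both sides;
* parametric thresholds for those maps via the Fisher z null
  (z ~ N(0, 1/sqrt(nu-3)) with nu = N_tdof - (K-1) temporal degrees of
  freedom, N_tdof = floor(T/4) for 40 Hz envelopes low-passed at 10 Hz),
  Bonferroni-corrected over (K-1) independent states times the spatial
  degrees of freedom;
* within-subject spatial (Pearson, on power maps) and temporal (Spearman,
  on binary activations) correlations between two sets of states, with
  one-sided one-sample group t-tests and Bonferroni correction over state
  pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import EnvelopeSet, StateActivation

__all__ = [
    "StateSummary",
    "PowerMap",
    "ComparisonResult",
    "state_summary",
    "run_length_encode",
    "partial_correlation_map",
    "threshold_map",
    "spatial_state_correlation",
    "temporal_state_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class StateSummary:
    """Per-state lifetime/occupancy table for one activation series."""

    table: pd.DataFrame  # columns: state, mean_lifetime_ms, fractional_occupancy,
    #          n_visits, n_completed_visits, edge_flag
    fs: float
    duration_s: float

    def mean_lifetime_ms(self) -> float:
        """Across-state average of the per-state mean lifetimes."""
        return float(self.table["mean_lifetime_ms"].mean())


@dataclass
class PowerMap:
    """Per-state partial-correlation power maps over locations."""

    values: np.ndarray  # K x V partial correlations
    locations: Sequence[str]
    state_names: Sequence[str]
    n_samples_total: int
    r_crit: Optional[float] = None
    significance_mask: Optional[np.ndarray] = None
    nu: Optional[int] = None
    n_tdof: Optional[int] = None
    spatial_df: Optional[int] = None
    per_subject: Optional[np.ndarray] = None  # n_subjects x K x V

    @property
    def K(self) -> int:
        return self.values.shape[0]


@dataclass
class ComparisonResult:
    """Cross-state correlation matrix with group-level inference."""

    r_mean: np.ndarray  # K_A x K_B mean per-subject correlation
    t: np.ndarray
    p: np.ndarray  # one-sided (greater) p-values
    significant: np.ndarray  # after Bonferroni over state pairs
    n_subjects: int
    alpha: float
    kind: str = "spatial"
    excluded: Optional[np.ndarray] = None  # pairs flagged for zero variance


# ---------------------------------------------------------------------------
# lifetimes and occupancies


def run_length_encode(labels: np.ndarray) -> List[Tuple[int, int, int]]:
    """Maximal constant-label runs as (label, start, length) triples."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def state_summary(
    activation: StateActivation,
    fs: Optional[float] = None,
    exclude_edges: bool = True,
) -> StateSummary:
    """Mean lifetime, fractional occupancy and visit count per state.

    Runs are maximal constant-label segments (half-open sample intervals);
    a run of L samples lasts L/fs seconds. With ``exclude_edges`` (default),
    runs truncated by the series boundaries are excluded from the lifetime
    mean (they bias it downward) but still counted in ``n_visits`` and in
    occupancy; a state whose only visits touch an edge falls back to the
    edge-included mean and is flagged. With ``exclude_edges=False`` the
    accounting identity sum_k n_visits_k * mean_lifetime_k = duration holds
    exactly.
    """
    if not activation.is_complete:
        raise ValueError("state_summary requires an exclusive-complete activation")
    fs = fs or activation.fs
    labels = activation.labels
    T = labels.size
    runs = run_length_encode(labels)
    rows = []
    for k in range(activation.n_states):
        k_runs = [r for r in runs if r[0] == k]
        n_visits = len(k_runs)
        occupancy = float(np.sum(labels == k) / T)
        edge_flag = False
        if n_visits == 0:
            rows.append((k, np.nan, occupancy, 0, 0, False))
            continue
        interior = [
            r for r in k_runs if r[1] > 0 and r[1] + r[2] < T
        ]
        if exclude_edges and interior:
            lengths = [r[2] for r in interior]
        else:
            lengths = [r[2] for r in k_runs]
            edge_flag = exclude_edges  # fell back to edge-included runs
        rows.append(
            (
                k,
                1e3 * float(np.mean(lengths)) / fs,
                occupancy,
                n_visits,
                len(interior),
                edge_flag,
            )
        )
    names = list(activation.state_names or [])
    table = pd.DataFrame(
        rows,
        columns=[
            "state", "mean_lifetime_ms", "fractional_occupancy",
            "n_visits", "n_completed_visits", "edge_flag",
        ],
    )
    table.insert(1, "state_name", [names[k] if k < len(names) else str(k)
                                   for k in table["state"]])
    return StateSummary(table=table, fs=fs, duration_s=T / fs)


# ---------------------------------------------------------------------------
# partial-correlation power maps


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of y (T or T x V) on design (T x p)."""
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def partial_correlation_map(
    activation: StateActivation,
    envelopes: EnvelopeSet,
    per_subject: bool = False,
) -> PowerMap:
    """Partial correlation between each state series and each envelope signal.

    For state k the other states' binary series (plus an intercept) are
    regressed out of both the state series and every envelope channel; the
    map value is the Pearson correlation of the residuals. Because
    exclusive-complete activations sum to one, the K series plus intercept
    are rank deficient; the last-indexed control series is then dropped
    (logged), consistent with losing K-1 degrees of freedom overall.

    With ``per_subject`` the same regression is restricted to each subject's
    segment and stored in ``per_subject`` (n_subjects x K x V).
    """
    if activation.n_states < 2:
        raise ValueError("partial correlation needs K >= 2 states")
    if activation.n_samples != envelopes.n_samples:
        raise ValueError("activation and envelopes differ in length")
    if abs(activation.fs - envelopes.fs) > 1e-9:
        raise ValueError("activation and envelopes differ in sampling rate")
    binary = activation.to_binary().T.astype(np.float64)  # T x K
    E = envelopes.data
    K = activation.n_states

    def _maps(sl: slice) -> np.ndarray:
        B, Y = binary[sl], E[sl]
        T = B.shape[0]
        out = np.empty((K, Y.shape[1]))
        for k in range(K):
            others = [j for j in range(K) if j != k]
            design = np.column_stack([np.ones(T), B[:, others]])
            x = B[:, k]
            rx = _residualize(x, design)
            if np.linalg.norm(rx) <= 1e-8 * max(1.0, np.linalg.norm(x)):
                # complete activations: drop the last control regressor
                # expected whenever activations are exclusive-complete
                logger.info(
                    "rank-deficient control set for state %d; dropping state %d",
                    k, others[-1],
                )
                design = np.column_stack([np.ones(T), B[:, others[:-1]]])
                rx = _residualize(x, design)
            ry = _residualize(Y, design)
            sx = np.linalg.norm(rx)
            sy = np.linalg.norm(ry, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (ry.T @ rx) / np.where(sy * sx > 0, sy * sx, np.inf)
            out[k] = r
        return out

    values = _maps(slice(None))
    per_subj = None
    if per_subject:
        per_subj = np.stack([_maps(slice(a, b)) for a, b in envelopes.boundaries])
    return PowerMap(
        values=values,
        locations=list(envelopes.channels),
        state_names=list(activation.state_names or []),
        n_samples_total=activation.n_samples,
        per_subject=per_subj,
    )


def fisher_r_crit(n_samples_total: int, K: int, spatial_df: int,
                  alpha: float = 0.05) -> Tuple[float, int, int]:
    """Critical partial correlation under the Fisher z null.

    N_tdof = floor(T/4); nu = N_tdof - (K-1); the Fisher-transformed
    correlation is N(0, 1/sqrt(nu-3)) under the null, tested two-tailed at
    alpha / ((K-1) * spatial_df). Returns (r_crit, nu, N_tdof).
    """
    n_tdof = n_samples_total // 4
    nu = n_tdof - (K - 1)
    if nu <= 3:
        raise ValueError(f"nu = {nu} <= 3: not enough temporal degrees of freedom")
    alpha_corr = alpha / ((K - 1) * spatial_df)
    z_crit = sps.norm.ppf(1.0 - alpha_corr / 2.0)
    return float(np.tanh(z_crit / np.sqrt(nu - 3))), int(nu), int(n_tdof)


def threshold_map(
    pmap: PowerMap, alpha: float = 0.05, spatial_df: int = 1
) -> PowerMap:
    """Attach the Fisher-null critical value and significance mask to a map."""
    r_crit, nu, n_tdof = fisher_r_crit(
        pmap.n_samples_total, pmap.K, spatial_df, alpha
    )
    return PowerMap(
        values=pmap.values,
        locations=pmap.locations,
        state_names=pmap.state_names,
        n_samples_total=pmap.n_samples_total,
        r_crit=r_crit,
        significance_mask=np.abs(pmap.values) >= r_crit,
        nu=nu,
        n_tdof=n_tdof,
        spatial_df=spatial_df,
        per_subject=pmap.per_subject,
    )


# ---------------------------------------------------------------------------
# cross-state comparisons


def _group_test(per_subject_r: np.ndarray, alpha: float, n_pairs: int):
    """One-sided one-sample t-test per state pair over subjects."""
    n_subjects = per_subject_r.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_1samp(
            per_subject_r, popmean=0.0, axis=0, alternative="greater",
            nan_policy="omit",
        )
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    p = np.where(np.isnan(p), 1.0, p)
    sig = p < alpha / n_pairs
    return t, p, sig, n_subjects


def _nanmean_pairs(r: np.ndarray) -> np.ndarray:
    """Mean over subjects ignoring NaN, quiet when a pair has no data."""
    counts = np.sum(~np.isnan(r), axis=0)
    sums = np.nansum(r, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def spatial_state_correlation(
    maps_a: np.ndarray, maps_b: np.ndarray, alpha: float = 0.05
) -> ComparisonResult:
    """Within-subject Pearson correlation of unthresholded power maps.

    ``maps_a``/``maps_b`` are (n_subjects, K, V) per-subject map stacks over
    a common location set. Zero-variance maps are flagged and excluded from
    the affected pair's group test.
    """
    maps_a, maps_b = np.asarray(maps_a), np.asarray(maps_b)
    if maps_a.shape[0] != maps_b.shape[0] or maps_a.shape[2] != maps_b.shape[2]:
        raise ValueError("map stacks must share subjects and locations")
    S, Ka, _ = maps_a.shape
    Kb = maps_b.shape[1]
    r = np.full((S, Ka, Kb), np.nan)
    excluded = np.zeros((Ka, Kb), dtype=bool)
    for s in range(S):
        A = maps_a[s] - maps_a[s].mean(axis=1, keepdims=True)
        B = maps_b[s] - maps_b[s].mean(axis=1, keepdims=True)
        na = np.linalg.norm(A, axis=1)
        nb = np.linalg.norm(B, axis=1)
        bad_a, bad_b = na == 0, nb == 0
        na[bad_a], nb[bad_b] = 1.0, 1.0
        rs = (A @ B.T) / np.outer(na, nb)
        rs[bad_a, :] = np.nan
        rs[:, bad_b] = np.nan
        excluded |= np.outer(bad_a, np.ones(Kb, bool)) | np.outer(
            np.ones(Ka, bool), bad_b
        )
        r[s] = rs
    t, p, sig, n = _group_test(r, alpha, Ka * Kb)
    return ComparisonResult(
        r_mean=_nanmean_pairs(r), t=t, p=p, significant=sig,
        n_subjects=n, alpha=alpha, kind="spatial", excluded=excluded,
    )


def temporal_state_correlation(
    acts_a: Sequence[StateActivation],
    acts_b: Sequence[StateActivation],
    alpha: float = 0.05,
) -> ComparisonResult:
    """Within-subject Spearman correlation of binary activation series.

    Both activation lists must be per subject, at equal sampling rates and
    lengths (upsample the slower one first). On binary series the Spearman
    coefficient equals the phi coefficient of the 2x2 contingency table.
    Constant series are flagged and excluded pairwise.
    """
    if len(acts_a) != len(acts_b):
        raise ValueError("need one activation per subject in both sets")
    S = len(acts_a)
    Ka = acts_a[0].n_states
    Kb = acts_b[0].n_states
    r = np.full((S, Ka, Kb), np.nan)
    excluded = np.zeros((Ka, Kb), dtype=bool)
    for s, (a, b) in enumerate(zip(acts_a, acts_b)):
        if abs(a.fs - b.fs) > 1e-9 or a.n_samples != b.n_samples:
            raise ValueError(
                f"subject {s}: activations differ in rate or length"
            )
        A = a.to_binary().astype(np.float64)
        B = b.to_binary().astype(np.float64)
        # Spearman on binary series == Pearson on the series themselves
        # (ranks are an affine function of a binary variable)
        A -= A.mean(axis=1, keepdims=True)
        B -= B.mean(axis=1, keepdims=True)
        na = np.linalg.norm(A, axis=1)
        nb = np.linalg.norm(B, axis=1)
        bad_a, bad_b = na == 0, nb == 0
        na[bad_a], nb[bad_b] = 1.0, 1.0
        rs = (A @ B.T) / np.outer(na, nb)
        rs[bad_a, :] = np.nan
        rs[:, bad_b] = np.nan
        excluded |= np.outer(bad_a, np.ones(Kb, bool)) | np.outer(
            np.ones(Ka, bool), bad_b
        )
        r[s] = rs
    t, p, sig, n = _group_test(r, alpha, Ka * Kb)
    return ComparisonResult(
        r_mean=_nanmean_pairs(r), t=t, p=p, significant=sig,
        n_subjects=n, alpha=alpha, kind="temporal", excluded=excluded,
    )
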