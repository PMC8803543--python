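"""Microstate operations against definitional and re-implementation oracles."""

import itertools

import numpy as np
import pytest

import statecomp as sc
from statecomp.containers import Recording


def _rec(data, fs=40.0):
    data = np.atleast_2d(data)
    return Recording(data=data, fs=fs,
                     channels=[f"c{i}" for i in range(data.shape[1])])


class TestGfp:
    def test_constant_map_zero(self):
        assert sc.compute_gfp(np.full(10, 2.0)) == 0.0

    def test_two_channel_antisymmetric(self):
        assert sc.compute_gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)

    def test_matches_spatial_sd_oracle(self, rng):
        v = rng.standard_normal(10)
        oracle = np.sqrt(np.mean((v - v.mean()) ** 2))
        assert sc.compute_gfp(v) == pytest.approx(oracle, abs=0)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            sc.compute_gfp(np.array([1.0]))


class TestGfpPeaks:
    def test_monotone_series_empty(self):
        assert sc.find_gfp_peaks(np.arange(10.0)).size == 0

    def test_simple_series(self):
        peaks = sc.find_gfp_peaks(np.array([0.0, 1.0, 0.0, 2.0, 0.0]))
        assert peaks.tolist() == [1, 3]

    def test_plateau_first_sample(self):
        peaks = sc.find_gfp_peaks(np.array([0.0, 2.0, 2.0, 2.0, 1.0, 3.0, 0.0]))
        assert peaks.tolist() == [1, 5]

    def test_rectified_sinusoid_matches_analytic_extrema(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        x = np.abs(np.sin(2 * np.pi * 5.0 * t))
        peaks = sc.find_gfp_peaks(x)
        analytic = np.array([0.05 + 0.1 * k for k in range(20)]) * fs
        assert len(peaks) == len(analytic)
        assert np.abs(peaks - analytic).max() <= 1.0


def _aahc_oracle(maps, K):
    """Step-by-step AAHC re-implementation (polarity invariant), kept naive.

    Same declared rules: clusters start as singletons; the cluster with the
    least explained GFP (sum over members of (gfp*|corr to PC topography|)^2)
    is dissolved; freed maps join the cluster of max |spatial corr| with
    topographies frozen during the pass; PC topographies recomputed after.
    Returns the final partition as a set of frozensets of map indices.
    """
    dm = maps - maps.mean(axis=1, keepdims=True)
    C = maps.shape[1]

    def pc(idx):
        M = dm[list(idx)]
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        i = int(np.argmax(np.abs(v)))
        return -v if v[i] < 0 else v

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        return 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))

    def quality(idx):
        topo = pc(idx)
        q = 0.0
        for i in idx:
            g = dm[i].std(ddof=0)
            q += (g * abs(corr(dm[i], topo))) ** 2
        return q

    clusters = [[i] for i in range(maps.shape[0])]
    while len(clusters) > K:
        quals = [quality(c) for c in clusters]
        worst = int(np.argmin(quals))
        freed = clusters.pop(worst)
        topos = [pc(c) for c in clusters]
        gained = set()
        for i in freed:
            scores = [abs(corr(dm[i], t)) for t in topos]
            j = int(np.argmax(scores))
            clusters[j].append(i)
            gained.add(j)
    return {frozenset(c) for c in clusters}


class TestAahc:
    def test_noiseless_recovery_with_sign_flips(self, rng):
        K, C = 4, 12
        planted = np.linalg.qr(rng.standard_normal((C, K)))[0].T
        planted -= planted.mean(axis=1, keepdims=True)
        signs = rng.choice([-1.0, 1.0], size=20 * K)
        scales = rng.uniform(0.5, 2.0, size=20 * K)
        maps = np.repeat(planted, 20, axis=0) * (signs * scales)[:, None]
        order = rng.permutation(len(maps))
        model = sc.aahc_cluster(maps[order], K)
        r = np.abs(sc.spatial_correlation(model.templates, planted))
        # every planted map matched by exactly one template
        assert (r.max(axis=0) > 1 - 1e-6).all()
        assert model.gev == pytest.approx(1.0, abs=1e-9)

    def test_k_equals_n_maps(self, rng):
        maps = rng.standard_normal((5, 8))
        model = sc.aahc_cluster(maps, 5)
        r = np.abs(sc.spatial_correlation(model.templates, maps))
        assert (r.max(axis=1) > 1 - 1e-9).all()

    def test_matches_independent_oracle_templates(self, rng):
        """8 maps, K=2: same clusters as the naive re-implementation."""
        for trial in range(5):
            maps = np.random.default_rng(100 + trial).standard_normal((8, 6))
            model = sc.aahc_cluster(maps, 2)
            oracle_partition = _aahc_oracle(maps, 2)
            # PC topography of each oracle cluster must coincide with one
            # implementation template (|corr| == 1 up to numerics)
            dm = maps - maps.mean(axis=1, keepdims=True)
            for cluster in oracle_partition:
                M = dm[sorted(cluster)]
                v = np.linalg.svd(M, full_matrices=False)[2][0]
                r = np.abs(sc.spatial_correlation(v, model.templates))
                assert r.max() > 1 - 1e-9

    def test_deterministic(self, rng):
        maps = rng.standard_normal((40, 10))
        a = sc.aahc_cluster(maps, 3)
        b = sc.aahc_cluster(maps, 3)
        assert np.array_equal(a.templates, b.templates)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            sc.aahc_cluster(rng.standard_normal((3, 5)), 4)


class TestGroupAlignment:
    def test_pure_permutation_objective_one(self, rng):
        base = sc.aahc_cluster(rng.standard_normal((30, 8)), 3)
        models = []
        for p in ([2, 0, 1], [1, 2, 0], [0, 1, 2]):
            models.append(sc.MicrostateModel(
                templates=base.templates[p], labels=["a", "b", "c"],
            ))
        group = sc.align_group_templates(models)
        r = np.abs(sc.spatial_correlation(group.templates, base.templates))
        # each group template coincides with one base template
        assert (r.max(axis=1) > 1 - 1e-9).all()
        assert (r.max(axis=0) > 1 - 1e-9).all()

    def test_matches_bruteforce_permutation_search(self, rng):
        """Two subjects, K=2: exhaustive search over both permutations."""
        m1 = sc.aahc_cluster(rng.standard_normal((10, 6)), 2)
        m2 = sc.aahc_cluster(rng.standard_normal((10, 6)), 2)
        group = sc.align_group_templates([m1, m2])

        best = -np.inf
        for p1 in itertools.permutations(range(2)):
            for p2 in itertools.permutations(range(2)):
                t1, t2 = m1.templates[list(p1)], m2.templates[list(p2)]
                # group template per slot = PC of the two aligned templates
                obj = 0.0
                for k in range(2):
                    M = np.stack([t1[k], t2[k]])
                    M = M - M.mean(axis=1, keepdims=True)
                    v = np.linalg.svd(M, full_matrices=False)[2][0]
                    obj += sum(
                        abs(sc.spatial_correlation(M[i], v)[0, 0])
                        for i in range(2)
                    )
                best = max(best, obj / 4)
        achieved = np.mean([
            max(
                np.abs(np.diag(sc.spatial_correlation(
                    m.templates[list(p)], group.templates
                ))).mean()
                for p in itertools.permutations(range(2))
            )
            for m in (m1, m2)
        ])
        # iterated alignment reaches the exhaustive-search objective
        assert achieved >= best - 1e-6

    def test_single_subject_identity(self, rng):
        m = sc.aahc_cluster(rng.standard_normal((20, 7)), 3)
        group = sc.align_group_templates([m])
        r = np.abs(np.diag(sc.spatial_correlation(group.templates, m.templates)))
        assert (r > 1 - 1e-9).all()

    def test_mismatched_k_rejected(self, rng):
        m1 = sc.aahc_cluster(rng.standard_normal((10, 6)), 2)
        m2 = sc.aahc_cluster(rng.standard_normal((10, 6)), 3)
        with pytest.raises(ValueError):
            sc.align_group_templates([m1, m2])


class TestBackfit:
    @pytest.fixture()
    def model(self, rng):
        templates = np.linalg.qr(rng.standard_normal((9, 3)))[0].T
        templates -= templates.mean(axis=1, keepdims=True)
        templates /= templates.std(axis=1, ddof=0, keepdims=True)
        return sc.MicrostateModel(templates=templates, labels=list("ABC"))

    def test_scaled_negated_template_recovered(self, model):
        rec = _rec(np.stack([-3.0 * model.templates[1],
                             0.5 * model.templates[2]]))
        act = sc.backfit(model, rec)
        assert act.labels.tolist() == [1, 2]

    def test_matches_argmax_correlation_oracle(self, model, rng):
        data = rng.standard_normal((50, 9))
        act = sc.backfit(model, _rec(data))
        for t in range(50):
            r = [abs(sc.spatial_correlation(data[t], tpl)[0, 0])
                 for tpl in model.templates]
            assert act.labels[t] == int(np.argmax(r))

    def test_tie_breaks_to_lowest_index(self):
        tpl = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        tpl = tpl - tpl.mean(axis=1, keepdims=True)
        tpl /= tpl.std(axis=1, ddof=0, keepdims=True)
        model = sc.MicrostateModel(templates=tpl, labels=["A", "B"])
        # a map equidistant in |corr| from both templates
        mid = tpl[0] + tpl[1]
        act = sc.backfit(model, _rec(mid))
        r0 = abs(sc.spatial_correlation(mid, tpl[0])[0, 0])
        r1 = abs(sc.spatial_correlation(mid, tpl[1])[0, 0])
        assert r0 == pytest.approx(r1, abs=1e-12)
        assert act.labels[0] == 0

    def test_peak_restriction_marks_gaps(self, model, rng):
        data = rng.standard_normal((40, 9))
        act = sc.backfit(model, _rec(data), restrict_to_peaks=True)
        assert act.peak_indices is not None
        mask = np.zeros(40, dtype=bool)
        mask[act.peak_indices] = True
        assert (act.labels[~mask] == -1).all()
        assert (act.labels[mask] >= 0).all()


class TestSmoothing:
    def _act(self, labels, peaks):
        return sc.StateActivation(labels=np.array(labels), n_states=3,
                                  fs=40.0, peak_indices=np.array(peaks))

    def test_single_peak_fills_series(self):
        labels = np.full(30, -1)
        labels[7] = 2
        out = sc.smooth_by_peak_interpolation(self._act(labels, [7]))
        assert (out.labels == 2).all() and out.smoothed

    def test_midpoint_tie_goes_to_earlier_peak(self):
        labels = np.full(31, -1)
        labels[10], labels[20] = 0, 1
        out = sc.smooth_by_peak_interpolation(self._act(labels, [10, 20]))
        assert (out.labels[:15] == 0).all()  # includes the tie at sample 15
        assert (out.labels[16:] == 1).all()
        assert out.labels[15] == 0

    def test_peaks_are_fixed_points(self, rng):
        labels = np.full(100, -1)
        peaks = np.sort(rng.choice(100, size=12, replace=False))
        labels[peaks] = rng.integers(0, 3, size=12)
        out = sc.smooth_by_peak_interpolation(self._act(labels, peaks))
        assert np.array_equal(out.labels[peaks], labels[peaks])

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            sc.smooth_by_peak_interpolation(self._act(np.full(10, -1), []))


class TestGev:
    def test_perfect_fit_gives_one(self, rng):
        tpl = np.linalg.qr(rng.standard_normal((8, 2)))[0].T
        tpl -= tpl.mean(axis=1, keepdims=True)
        tpl /= tpl.std(axis=1, ddof=0, keepdims=True)
        model = sc.MicrostateModel(templates=tpl, labels=["A", "B"])
        scales = rng.uniform(0.5, 3.0, 20)
        idx = rng.integers(0, 2, 20)
        data = tpl[idx] * scales[:, None] * rng.choice([-1, 1], 20)[:, None]
        assert sc.global_explained_variance(model, _rec(data)) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_orthogonal_maps_give_zero(self, rng):
        basis = np.linalg.qr(rng.standard_normal((8, 4)))[0]
        basis = basis - basis.mean(axis=0, keepdims=True)
        # re-orthogonalize in the zero-mean subspace
        basis = np.linalg.qr(basis)[0]
        tpl = basis[:, :2].T.copy()
        tpl /= tpl.std(axis=1, ddof=0, keepdims=True)
        model = sc.MicrostateModel(templates=tpl, labels=["A", "B"])
        data = np.stack([basis[:, 2], basis[:, 3]] * 5)
        gev = sc.global_explained_variance(model, _rec(data))
        assert gev == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_summation_oracle(self, rng):
        tpl = rng.standard_normal((3, 7))
        tpl -= tpl.mean(axis=1, keepdims=True)
        tpl /= tpl.std(axis=1, ddof=0, keepdims=True)
        model = sc.MicrostateModel(templates=tpl, labels=list("ABC"))
        data = rng.standard_normal((30, 7))
        rec = _rec(data)
        act = sc.backfit(model, rec)
        num = den = 0.0
        for t in range(30):
            g = sc.compute_gfp(data[t])
            r = sc.spatial_correlation(data[t], tpl[act.labels[t]])[0, 0]
            num += (g * r) ** 2
            den += g**2
        assert sc.global_explained_variance(model, rec, act) == pytest.approx(
            num / den, abs=1e-12
        )


def test_smoothed_lifetimes_not_shorter_than_raw(micro_recs):
    """Nearest-peak interpolation merges inter-peak fragments."""
    maps = np.concatenate(
        [m.data[sc.find_gfp_peaks(sc.gfp_series(m))] for m in micro_recs]
    )
    model = sc.aahc_cluster(maps, 4)
    for mr in micro_recs:
        raw = sc.backfit(model, mr)
        peaked = sc.backfit(model, mr, restrict_to_peaks=True)
        smooth = sc.smooth_by_peak_interpolation(peaked)
        lt_raw = sc.state_summary(raw).mean_lifetime_ms()
        lt_smooth = sc.state_summary(smooth).mean_lifetime_ms()
        assert lt_smooth >= lt_raw
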