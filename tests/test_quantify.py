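"""Uptake measurement, box summaries, Mann-Whitney, punctae, decay, 3-D."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import cgtension as cg
from cgtension.errors import NormalizationError, ParameterError
from cgtension.quantify import decay_rate_bootstrap_ci
from cgtension.synthetic import DecayTrace


class TestMeasureUptake:
    def test_noiseless_field_recovered_exactly(self):
        ft = cg.gen_cell_field(
            n_cells=5, mean_uptake=2e4, cv=0.0, noise_sd=0.0,
            shape=(256, 256), seed=0, background=80.0,
        )
        recs = cg.measure_uptake(ft.image, ft.labels)
        assert len(recs) == 5
        for r in recs:
            assert r.integrated_intensity == pytest.approx(2e4, rel=1e-9)
            assert r.integrated_intensity == pytest.approx(
                r.mean_intensity * r.area_px, rel=1e-12
            )

    def test_noisy_field_recovered_within_5pct(self):
        ft = cg.gen_cell_field(
            n_cells=10, mean_uptake=5e4, cv=0.3, noise_sd=2.0,
            shape=(384, 384), seed=4,
        )
        recs = cg.measure_uptake(ft.image, ft.labels)
        truth = dict(zip(ft.true_intensity["cell_id"],
                         ft.true_intensity["true_total"]))
        rel = [abs(r.integrated_intensity - truth[r.cell_id]) / truth[r.cell_id]
               for r in recs]
        assert max(rel) < 0.05

    def test_splitting_a_label_preserves_total(self):
        ft = cg.gen_cell_field(
            n_cells=1, mean_uptake=1e4, cv=0.0, noise_sd=0.0,
            shape=(128, 128), seed=1, background=0.0,
        )
        whole = cg.measure_uptake(ft.image, ft.labels)[0].integrated_intensity
        split = ft.labels.copy()
        ys, xs = np.nonzero(split == 1)
        split[ys[: ys.size // 2], xs[: ys.size // 2]] = 2
        parts = cg.measure_uptake(ft.image, split)
        assert sum(p.integrated_intensity for p in parts) == pytest.approx(
            whole, rel=1e-9
        )

    def test_empty_mask_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning):
            out = cg.measure_uptake(np.zeros((8, 8)), np.zeros((8, 8), int))
        assert out == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            cg.measure_uptake(np.zeros((8, 8)), np.zeros((9, 9), int))


class TestNormalization:
    def test_fold_change_arithmetic(self):
        out = cg.normalize_to_control([6.0], [2.0, 4.0])
        assert out[0] == pytest.approx(2.0)

    def test_control_normalized_to_itself_has_unit_mean(self, rng):
        ctrl = rng.lognormal(0, 0.5, 50)
        assert cg.normalize_to_control(ctrl, ctrl).mean() == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        vals = rng.uniform(1, 5, 20)
        ctrl = rng.uniform(1, 5, 20)
        a = cg.normalize_to_control(vals, ctrl)
        b = cg.normalize_to_control(7.3 * vals, 7.3 * ctrl)
        assert np.allclose(a, b)

    def test_bad_control_rejected(self):
        with pytest.raises(NormalizationError):
            cg.normalize_to_control([1.0], [])
        with pytest.raises(NormalizationError):
            cg.normalize_to_control([1.0], [-2.0, 1.0])


class TestBoxSummary:
    def test_reference_five_values(self):
        s = cg.summarize_box([1, 2, 3, 4, 5])
        assert (s.median, s.q25, s.q75) == (3.0, 2.0, 4.0)
        assert s.sd == pytest.approx(1.5811, abs=1e-4)
        assert s.n == 5

    def test_single_value_degenerate(self):
        s = cg.summarize_box([7.0])
        assert s.median == s.q25 == s.q75 == 7.0
        assert s.sd == 0.0 and not s.sd_defined

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_permutation_invariance_and_quartile_order(self, values):
        rng = np.random.default_rng(0)
        a = cg.summarize_box(values)
        b = cg.summarize_box(rng.permutation(values))
        assert (a.median, a.q25, a.q75) == (b.median, b.q25, b.q75)
        assert a.sd == pytest.approx(b.sd, rel=1e-12, abs=1e-12)
        assert a.q25 <= a.median <= a.q75


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = cg.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)

    def test_identical_multisets_are_symmetric(self):
        res = cg.mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.U == pytest.approx(3 * 3 / 2.0)
        assert res.p_two_sided == 1.0

    def test_all_values_tied_flags_degenerate(self):
        res = cg.mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.all_tied and res.p_two_sided == 1.0

    @given(
        st.lists(st.integers(0, 9), min_size=2, max_size=5),
        st.lists(st.integers(0, 9), min_size=2, max_size=5),
    )
    def test_u_statistics_of_both_orientations_sum_to_n1n2(self, a, b):
        ra = cg.mann_whitney(a, b)
        rb = cg.mann_whitney(b, a)
        assert ra.U + rb.U == pytest.approx(len(a) * len(b))

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 7, 2)
            pooled = rng.permutation(np.arange(n1 + n2, dtype=float) * 1.7)
            a, b = pooled[:n1], pooled[n1:]
            mine = cg.mann_whitney(a, b, method="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert mine.U == pytest.approx(ref.statistic)
            assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_matches_enumeration_oracle_with_ties(self, rng):
        from cgtension.panel import _mw_enumeration_oracle

        for _ in range(25):
            n1, n2 = rng.integers(2, 6, 2)
            vals = rng.integers(0, 5, n1 + n2).astype(float)
            a, b = vals[:n1], vals[n1:]
            res = cg.mann_whitney(a, b, method="exact")
            if res.all_tied:
                assert res.p_two_sided == 1.0
                continue
            assert res.p_two_sided == pytest.approx(
                _mw_enumeration_oracle(a, b), abs=1e-12
            )

    def test_normal_approx_close_to_exact_at_n12(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.3, 1, 12)
        exact = cg.mann_whitney(a, b, method="exact")
        approx = cg.mann_whitney(a, b, method="approx")
        assert approx.p_two_sided == pytest.approx(exact.p_two_sided, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            cg.mann_whitney([], [1.0])


class TestPunctae:
    def test_high_snr_spots_found_exactly_and_localized(self):
        stk = cg.gen_punctae_stack([5], psf_sigma_px=1.5, snr=20.0, seed=3)
        det = cg.detect_punctae(stk.frames[0], sigma_px=1.5)
        assert len(det) == 5
        for truth in stk.true_coords[0]:
            d = np.hypot(det[:, 0] - truth[0], det[:, 1] - truth[1])
            assert d.min() <= 1.0

    def test_pure_noise_yields_no_detections(self, rng):
        frame = rng.normal(0, 5.0, (128, 128))
        assert len(cg.detect_punctae(frame, sigma_px=1.5)) == 0

    def test_count_invariant_under_intensity_scaling(self):
        stk = cg.gen_punctae_stack([7], psf_sigma_px=1.5, snr=10.0, seed=5)
        n1 = len(cg.detect_punctae(stk.frames[0]))
        n2 = len(cg.detect_punctae(37.5 * stk.frames[0]))
        assert n1 == n2

    def test_series_normalizes_to_first_frame(self):
        stk = cg.gen_punctae_stack([10, 6, 12], psf_sigma_px=1.5, snr=15.0, seed=6)
        series = cg.punctae_series(stk.frames, sigma_px=1.5)
        norm = [r.normalized_count for r in series]
        assert norm[0] == 1.0
        assert norm[1] == pytest.approx(0.6, abs=0.15)
        assert norm[2] == pytest.approx(1.2, abs=0.15)

    def test_empty_first_frame_flags_unnormalized(self, rng):
        stack = rng.normal(0, 1.0, (2, 64, 64))
        with pytest.warns(UserWarning):
            series = cg.punctae_series(stack)
        assert all(r.normalized_count is None for r in series)


class TestDecayFit:
    def test_noiseless_trace_recovered_to_machine_precision(self):
        (tr,) = cg.gen_decay_traces(100.0, 0.02, 0.0, 1, 150.0, seed=0)
        fit = cg.fit_decay(tr)
        assert fit.rate == pytest.approx(0.02, abs=1e-6)
        assert fit.half_time == pytest.approx(np.log(2) / 0.02, rel=1e-4)

    def test_flat_trace_gives_infinite_half_time(self):
        t = np.linspace(0, 100, 40)
        fit = cg.fit_decay(DecayTrace(t, np.full(40, 50.0)))
        assert abs(fit.rate) < 1e-6 or np.isinf(fit.half_time)

    def test_noisy_recovery_median_under_10pct(self):
        traces = cg.gen_decay_traces(100.0, 0.02, 5.0, 20, 150.0, seed=2)
        errs = [abs(cg.fit_decay(tr).rate - 0.02) / 0.02 for tr in traces]
        assert np.median(errs) < 0.10

    def test_bootstrap_interval_covers_truth(self):
        traces = cg.gen_decay_traces(100.0, 0.02, 5.0, 10, 150.0, seed=3)
        covered = sum(
            1
            for i, tr in enumerate(traces)
            if (lambda ci: ci[0] <= 0.02 <= ci[1])(
                decay_rate_bootstrap_ci(tr, n_boot=100, seed=i)
            )
        )
        assert covered >= 9

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            cg.fit_decay(DecayTrace([0, 1, 2], [3.0, 2.0, 1.0]))


class TestObjects3D:
    def test_two_disjoint_cubes(self):
        stack = np.zeros((20, 20, 20))
        stack[2:5, 2:5, 2:5] = 10.0
        stack[10:14, 10:14, 10:14] = 10.0
        count, sizes = cg.count_objects_3d(stack, threshold=5.0)
        assert count == 2
        assert sizes == [64, 27]

    def test_corner_touching_cubes_merge_under_26_connectivity(self):
        stack = np.zeros((10, 10, 10))
        stack[2:4, 2:4, 2:4] = 10.0
        stack[4:6, 4:6, 4:6] = 10.0  # touches only at the (4,4,4) corner
        count, _ = cg.count_objects_3d(stack, threshold=5.0)
        assert count == 1

    def test_min_voxel_filter(self):
        stack = np.zeros((10, 10, 10))
        stack[1, 1, 1] = 10.0  # single voxel
        stack[5:8, 5:8, 5:8] = 10.0
        count, sizes = cg.count_objects_3d(stack, threshold=5.0, min_voxels=2)
        assert count == 1 and sizes == [27]

    def test_random_nontouching_blob_count(self, rng):
        stack = np.zeros((40, 40, 40))
        k = 6
        centers = rng.integers(4, 36, (k, 3))
        while True:  # enforce separation > 3 voxels
            d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
            if np.all(d[~np.eye(k, dtype=bool)] > 6):
                break
            centers = rng.integers(4, 36, (k, 3))
        for c in centers:
            stack[c[0] - 1 : c[0] + 2, c[1] - 1 : c[1] + 2, c[2] - 1 : c[2] + 2] = 9.0
        count, _ = cg.count_objects_3d(stack, threshold=5.0)
        assert count == k
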