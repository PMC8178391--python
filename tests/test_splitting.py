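"""Section construction and the two self-supervision conditions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from n2itomo.geometry import ImageSlice, Sinogram, fbp_reconstruct, forward_project, make_geometry
from n2itomo.noise import NoiseConfig, simulate_noisy_sinogram
from n2itomo.phantoms import interlaced_schedule
from n2itomo.splitting import (
    SplitScheme,
    angular_split,
    combine_time_steps,
    dynamic_split,
    extract_section,
    multichannel_split,
    verify_conditions,
)


class TestAngularSplit:
    def test_stride_three_of_six(self):
        s = angular_split(6, 3)
        assert s.target_sets == ((0, 3), (1, 4), (2, 5))
        assert s.input_sets == ((1, 2, 4, 5), (0, 2, 3, 5), (0, 1, 3, 4))

    def test_singleton_targets_when_J_equals_n(self):
        s = angular_split(5, 5)
        assert all(len(t) == 1 for t in s.target_sets)
        assert all(len(i) == 4 for i in s.input_sets)

    def test_input_sections_cover_two_thirds(self):
        s = angular_split(360, 3)
        for inp in s.input_sets:
            assert len(inp) / 360 == pytest.approx(2 / 3)

    @pytest.mark.parametrize("J", [0, 1, 7])
    def test_invalid_J(self, J):
        with pytest.raises(ValueError):
            angular_split(6, J)

    @given(n=st.integers(4, 200), J=st.integers(2, 8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_property(self, n, J):
        if J > n:
            return
        s = angular_split(n, J)
        all_targets = [k for t in s.target_sets for k in t]
        assert sorted(all_targets) == list(range(n))
        sizes = [len(t) for t in s.target_sets]
        assert max(sizes) - min(sizes) <= 1
        # remainder goes to the lowest-index target sets
        assert sizes == sorted(sizes, reverse=True)
        for t, i in zip(s.target_sets, s.input_sets):
            assert not (set(t) & set(i))
            assert sorted(set(t) | set(i)) == list(range(n))


class TestExtractSection:
    def _sino(self, n=6, N=16):
        geom = make_geometry(n, np.pi, 0.0, N, N)
        rng = np.random.default_rng(0)
        return Sinogram(rng.random((n, N)), geom)

    def test_full_index_set_is_identity(self):
        s = self._sino()
        out = extract_section(s, range(6))
        np.testing.assert_array_equal(out.values, s.values)
        np.testing.assert_array_equal(out.geometry.angles, s.geometry.angles)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            extract_section(self._sino(), [])

    def test_subset_keeps_original_angles(self):
        s = self._sino()
        out = extract_section(s, [0, 3])
        assert out.values.shape == (2, 16)
        np.testing.assert_array_equal(out.geometry.angles, s.geometry.angles[[0, 3]])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            extract_section(self._sino(), [0, 6])


class TestDynamicSplit:
    def test_round_robin_three(self):
        s = dynamic_split(3)
        assert s.input_sets[0] == (0,)
        assert s.target_sets[0] == (1, 2)
        assert s.unit_kind == "time_step"

    def test_one_to_five_ratio_with_six_steps(self):
        s = dynamic_split(6)
        for inp, tgt in zip(s.input_sets, s.target_sets):
            assert len(tgt) / len(inp) == 5

    def test_pairwise_symmetric_with_two_steps(self):
        s = dynamic_split(2)
        assert s.input_sets == ((0,), (1,))
        assert s.target_sets == ((1,), (0,))

    def test_single_step_rejected(self):
        with pytest.raises(ValueError):
            dynamic_split(1)


class TestCombineTimeSteps:
    def _steps(self, N=32, n_steps=2, per_step=4):
        scheds = interlaced_schedule(n_steps, per_step, 0.0, seed=0)
        geom = make_geometry(1, 2 * np.pi, 0.0, N, N)
        rng = np.random.default_rng(0)
        return [
            Sinogram(rng.random((per_step, N)), geom.with_angles(s))
            for s in scheds
        ]

    def test_single_input_is_identity(self):
        s = self._steps(n_steps=1)[0]
        out = combine_time_steps([s])
        np.testing.assert_array_equal(out.values, s.values)

    def test_two_interlaced_steps_merge_sorted(self):
        out = combine_time_steps(self._steps())
        assert out.num_angles == 8
        assert np.all(np.diff(out.geometry.angles) > 0)
        assert sorted(np.unique(out.angle_sources)) == [0, 1]

    def test_duplicate_angles_rejected(self):
        steps = self._steps()
        clash = Sinogram(steps[0].values, steps[0].geometry)
        with pytest.raises(ValueError):
            combine_time_steps([steps[0], clash])

    def test_combined_reconstruction_beats_single_step(self):
        """Denser angular sampling from combining interlaced steps reduces
        sparse-angle artifacts."""
        N = 64
        c = (N - 1) / 2
        ii, jj = np.ogrid[:N, :N]
        img = ((ii - c) ** 2 + (jj - c) ** 2 <= 20**2) * 0.01
        img = img + ((ii - c - 8) ** 2 + (jj - c + 5) ** 2 <= 6**2) * 0.01
        scheds = interlaced_schedule(6, 50, 0.0, seed=0)
        geom = make_geometry(1, 2 * np.pi, 0.0, N, N)
        steps = []
        for k, s in enumerate(scheds):
            clean = forward_project(ImageSlice(img), geom.with_angles(s))
            steps.append(
                simulate_noisy_sinogram(
                    clean, NoiseConfig(incident_photon_count=1000, seed=k)
                )
            )
        mse_single = np.mean((fbp_reconstruct(steps[0]).values - img) ** 2)
        combined = combine_time_steps(steps)
        mse_combined = np.mean((fbp_reconstruct(combined).values - img) ** 2)
        assert mse_combined < mse_single


class TestMultichannelSplit:
    def _channels(self, C=11, n=30, N=16, angles=None):
        geom = make_geometry(n, np.pi, 0.0, N, N)
        rng = np.random.default_rng(0)
        return [Sinogram(rng.random((n, N)), geom) for _ in range(C)]

    def test_one_scheme_for_all_channels(self):
        s = multichannel_split(self._channels(), 3)
        assert s == angular_split(30, 3)

    def test_single_channel_reduces_to_angular_split(self):
        s = multichannel_split(self._channels(C=1), 2)
        assert s == angular_split(30, 2)

    def test_mismatched_channel_geometries_rejected(self):
        chans = self._channels(C=2)
        geom2 = make_geometry(31, np.pi, 0.0, 16, 16)
        rng = np.random.default_rng(0)
        bad = Sinogram(rng.random((31, 16)), geom2)
        with pytest.raises(ValueError):
            multichannel_split([chans[0], bad], 3)


class TestVerifyConditions:
    def test_generated_scheme_passes(self):
        report = verify_conditions(angular_split(360, 4), 360)
        assert report.condition1_pass and report.condition2_pass

    def test_overlap_fails_condition_one(self):
        s = SplitScheme(
            J=2,
            target_sets=((0, 1), (2, 3)),
            input_sets=((1, 2, 3), (0, 1)),
            unit_kind="angle",
        )
        report = verify_conditions(s, 4)
        assert not report.condition1_pass
        assert report.violations

    def test_missing_unit_fails_condition_two(self):
        s = SplitScheme(
            J=2,
            target_sets=((0, 2), (1, 3)),
            input_sets=((1, 3), (0, 2)),
            unit_kind="angle",
        )
        report = verify_conditions(s, 6)  # units 4, 5 never targets
        assert report.condition1_pass
        assert not report.condition2_pass

    def test_dynamic_scheme_passes_equal_use(self):
        report = verify_conditions(dynamic_split(6), 6)
        assert report.condition1_pass and report.condition2_pass

    def test_json_round_trip(self):
        s = angular_split(10, 3)
        assert SplitScheme.from_json(s.to_json()) == s


class TestNoiseIndependence:
    def test_split_reconstruction_noise_uncorrelated(self):
        """Over independent noise realizations, per-pixel covariance between
        input-section and target-section reconstruction noise is zero within
        Monte-Carlo error."""
        N, n_angles, R = 32, 48, 60
        c = (N - 1) / 2
        ii, jj = np.ogrid[:N, :N]
        img = ((ii - c) ** 2 + (jj - c) ** 2 <= 12**2) * 0.02
        geom = make_geometry(n_angles, np.pi, 0.0, N, N)
        clean = forward_project(ImageSlice(img), geom)
        scheme = angular_split(n_angles, 2)
        clean_in = fbp_reconstruct(extract_section(clean, scheme.input_sets[0])).values
        clean_tg = fbp_reconstruct(extract_section(clean, scheme.target_sets[0])).values
        eps_in = np.empty((R, N, N))
        eps_tg = np.empty((R, N, N))
        for r in range(R):
            noisy = simulate_noisy_sinogram(
                clean, NoiseConfig(incident_photon_count=500, seed=r)
            )
            eps_in[r] = (
                fbp_reconstruct(extract_section(noisy, scheme.input_sets[0])).values
                - clean_in
            )
            eps_tg[r] = (
                fbp_reconstruct(extract_section(noisy, scheme.target_sets[0])).values
                - clean_tg
            )
        cov = np.mean(
            (eps_in - eps_in.mean(0)) * (eps_tg - eps_tg.mean(0)), axis=0
        )
        # Monte-Carlo SE of each pixel covariance, then of the mean over pixels
        se = np.std((eps_in - eps_in.mean(0)) * (eps_tg - eps_tg.mean(0)), axis=0) / np.sqrt(R)
        mean_cov = cov.mean()
        mean_se = np.sqrt(np.mean(se**2) / cov.size)
        assert abs(mean_cov) <= 3 * mean_se
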