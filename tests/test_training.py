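"""Pair construction, the optimization loop, and the two inference modes."""

import numpy as np
import pytest

from n2itomo.geometry import ImageSlice, Sinogram, forward_project, make_geometry
from n2itomo.network import ModelConfig, build_msd
from n2itomo.noise import NoiseConfig, simulate_noisy_sinogram
from n2itomo.phantoms import interlaced_schedule, static_phantom
from n2itomo.splitting import SplitScheme, angular_split, dynamic_split
from n2itomo.training import (
    TrainingConfig,
    denoise_full,
    dynamic_inference,
    make_training_pairs,
    reconstruct_stack,
    train,
)


def _static_stack(N=32, num_slices=8, num_angles=32, seed=0, photons=500.0):
    vol = static_phantom(N, depth=num_slices, num_features=4, seed=seed)
    truth = vol.attenuation
    geom = make_geometry(num_angles, np.pi, 0.0, N, N)
    sinos = []
    for z in range(num_slices):
        clean = forward_project(ImageSlice(truth[z]), geom)
        clean.slice_index = z
        sinos.append(
            simulate_noisy_sinogram(
                clean, NoiseConfig(incident_photon_count=photons, seed=seed + z)
            )
        )
    return truth, sinos


class TestMakeTrainingPairs:
    def test_static_pair_count_and_shapes(self):
        _, sinos = _static_stack(num_slices=8)
        pairs = make_training_pairs(sinos, angular_split(32, 2), "static_25d", context=1)
        assert len(pairs) == 16  # 2 sections x 8 slices
        assert pairs[0].input.shape == (3, 32, 32)
        assert pairs[0].target.shape == (1, 32, 32)
        # every (section, slice) combination appears exactly once
        seen = {(p.j, p.provenance["slice"]) for p in pairs}
        assert len(seen) == 16

    def test_dynamic_pairs_target_from_other_steps(self):
        N = 32
        scheds = interlaced_schedule(3, 20, 0.0, seed=0)
        geom = make_geometry(1, 2 * np.pi, 0.0, N, N)
        rng = np.random.default_rng(0)
        sinos = [
            Sinogram(rng.random((20, N)), geom.with_angles(s), time_index=t)
            for t, s in enumerate(scheds)
        ]
        pairs = make_training_pairs(sinos, dynamic_split(3), "dynamic")
        assert len(pairs) == 3
        for p in pairs:
            assert len(p.provenance["target_steps"]) == 2
            assert p.provenance["input_steps"][0] not in p.provenance["target_steps"]

    def test_multichannel_pairs_keep_all_channels(self):
        N, C, n = 24, 11, 30
        geom = make_geometry(n, np.pi, 0.0, N, N)
        rng = np.random.default_rng(0)
        sinos = [
            Sinogram(rng.random((n, N)), geom, channel_index=c) for c in range(C)
        ]
        pairs = make_training_pairs(sinos, angular_split(n, 3), "multichannel")
        assert len(pairs) == 3
        for p in pairs:
            assert p.input.shape == (11, N, N)
            assert p.target.shape == (11, N, N)

    def test_invalid_scheme_refused(self):
        _, sinos = _static_stack(num_slices=2)
        bad = SplitScheme(
            J=2,
            target_sets=((0, 1), (2, 3)),
            input_sets=((1, 4, 5), (0, 6, 7)),  # overlaps its target
            unit_kind="angle",
        )
        with pytest.raises(ValueError, match="condition|overlap|scheme"):
            make_training_pairs(sinos, bad, "static_25d")


class TestTrain:
    def test_loss_decreases_on_identity_task(self):
        """Noise-free pairs with input == target: training reaches <= 10% of
        the initial loss."""
        rng = np.random.default_rng(0)
        from n2itomo.training import ReconstructionPair

        imgs = rng.random((6, 1, 32, 32))
        pairs = [ReconstructionPair(input=i, target=i, j=0) for i in imgs]
        model = build_msd(ModelConfig(depth=4, in_channels=1, weight_init_seed=0))
        cfg = TrainingConfig(iterations=1200, batch_size=2, shuffle_seed=1)
        trained, losses = train(pairs, model, cfg)
        assert losses[-1] <= 0.10 * losses[0]

    def test_reproducible_loss_history(self):
        _, sinos = _static_stack(num_slices=2)
        pairs = make_training_pairs(sinos, angular_split(32, 2), "static_25d", context=0)
        model = build_msd(ModelConfig(depth=3, in_channels=1, weight_init_seed=5))
        cfg = TrainingConfig(iterations=40, batch_size=2, shuffle_seed=9)
        _, la = train(pairs, model, cfg)
        _, lb = train(pairs, model, cfg)
        assert la == lb

    def test_supervised_loss_decreases_during_training(self):
        """The self-supervised objective is a surrogate: the loss against the
        noise-free reconstruction (available only in simulation) should fall
        too."""
        truth, sinos = _static_stack(num_slices=4, photons=300.0)
        scheme = angular_split(32, 2)
        pairs = make_training_pairs(sinos, scheme, "static_25d", context=0)
        model = build_msd(ModelConfig(depth=6, in_channels=1, weight_init_seed=2))
        history = []

        def monitor(m, epoch):
            if epoch % 10 == 0:
                den = denoise_full(m, sinos, "full", scheme, 0)
                history.append(float(np.mean((den - truth) ** 2)))

        cfg = TrainingConfig(iterations=400, batch_size=2, shuffle_seed=3)
        train(pairs, model, cfg, monitor=monitor)
        assert len(history) >= 3
        assert history[-1] < history[0]

    def test_channel_mismatch_rejected(self):
        _, sinos = _static_stack(num_slices=2)
        pairs = make_training_pairs(sinos, angular_split(32, 2), "static_25d", context=1)
        model = build_msd(ModelConfig(depth=2, in_channels=1))
        with pytest.raises(ValueError):
            train(pairs, model, TrainingConfig(iterations=2))


class TestInference:
    def _trained(self):
        truth, sinos = _static_stack(num_slices=4)
        scheme = angular_split(32, 2)
        pairs = make_training_pairs(sinos, scheme, "static_25d", context=1)
        model = build_msd(ModelConfig(depth=3, in_channels=3, weight_init_seed=0))
        model, _ = train(pairs, model, TrainingConfig(iterations=30, batch_size=2))
        return truth, sinos, scheme, model

    def test_split_average_is_mean_of_section_outputs(self):
        truth, sinos, scheme, model = self._trained()
        from n2itomo.splitting import extract_section
        from n2itomo.training import _apply_volume

        avg = denoise_full(model, sinos, "split_average", scheme, context=1)
        manual = np.mean(
            [
                _apply_volume(
                    model,
                    reconstruct_stack(
                        [extract_section(s, scheme.input_sets[j]) for s in sinos]
                    ),
                    1,
                )
                for j in range(scheme.J)
            ],
            axis=0,
        )
        np.testing.assert_array_equal(avg, manual)

    def test_full_mode_output_shape(self):
        truth, sinos, scheme, model = self._trained()
        out = denoise_full(model, sinos, "full", scheme, context=1)
        assert out.shape == truth.shape

    def test_unknown_mode_rejected(self):
        truth, sinos, scheme, model = self._trained()
        with pytest.raises(ValueError):
            denoise_full(model, sinos, "both", scheme, context=1)

    def test_split_average_requires_scheme(self):
        truth, sinos, scheme, model = self._trained()
        with pytest.raises(ValueError):
            denoise_full(model, sinos, "split_average", None, context=1)

    def test_dynamic_inference_one_output_per_step(self):
        N = 32
        scheds = interlaced_schedule(3, 24, 0.0, seed=1)
        geom = make_geometry(1, 2 * np.pi, 0.0, N, N)
        rng = np.random.default_rng(0)
        sinos = [
            Sinogram(rng.random((24, N)), geom.with_angles(s)) for s in scheds
        ]
        pairs = make_training_pairs(sinos, dynamic_split(3), "dynamic")
        model = build_msd(ModelConfig(depth=2, in_channels=1, weight_init_seed=1))
        model, _ = train(pairs, model, TrainingConfig(iterations=10))
        outs = dynamic_inference(model, sinos)
        assert len(outs) == 3
        assert all(o.shape == (N, N) for o in outs)

    def test_single_step_inference(self):
        N = 32
        geom = make_geometry(24, 2 * np.pi, 0.0, N, N)
        rng = np.random.default_rng(0)
        sino = Sinogram(rng.random((24, N)), geom)
        model = build_msd(ModelConfig(depth=2, in_channels=1, weight_init_seed=1))
        outs = dynamic_inference(model, [sino])
        assert len(outs) == 1
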