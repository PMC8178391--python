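"""Static 3D denoising: angular split, 2.5D network, both inference modes.

Simulates a noisy micro-tomography acquisition of a small porous volume,
trains a denoiser purely on complementary angular sections of the measured
sinograms (no ground truth enters training), and compares the denoised
volume against the known phantom.
"""

import numpy as np

from n2itomo import (
    ImageSlice,
    ModelConfig,
    NoiseConfig,
    TrainingConfig,
    angular_split,
    build_msd,
    denoise_full,
    forward_project,
    make_geometry,
    make_training_pairs,
    simulate_noisy_sinogram,
    static_phantom,
    train,
)
from n2itomo.training import reconstruct_stack

N, num_slices, num_angles = 64, 4, 128

volume = static_phantom(N, depth=num_slices, num_features=8, seed=0)
truth = volume.attenuation
geom = make_geometry(num_angles, np.pi, 0.0, N, N)
noisy = []
for z in range(num_slices):
    clean = forward_project(ImageSlice(truth[z]), geom)
    clean.slice_index = z
    noisy.append(
        simulate_noisy_sinogram(
            clean, NoiseConfig(incident_photon_count=200, seed=100 + z)
        )
    )

scheme = angular_split(num_angles, 2)  # two half-sets of alternating angles
pairs = make_training_pairs(noisy, scheme, "static_25d", context=1)
model = build_msd(ModelConfig(depth=12, in_channels=3, weight_init_seed=1))
model, losses = train(
    pairs, model, TrainingConfig(iterations=600, batch_size=2, shuffle_seed=2)
)

noisy_fbp = reconstruct_stack(noisy)
den_full = denoise_full(model, noisy, "full", scheme, context=1)
den_split = denoise_full(model, noisy, "split_average", scheme, context=1)

mse = lambda a: float(np.mean((a - truth) ** 2))
print(f"training loss: {losses[0]:.3e} (first epoch) -> {losses[-1]:.3e} (last)")
print(f"MSE vs ground truth, noisy FBP:       {mse(noisy_fbp):.3e}")
print(f"MSE vs ground truth, denoised (full): {mse(den_full):.3e}")
print(f"MSE vs ground truth, split-average:   {mse(den_split):.3e}")
print(
    "The denoised volumes should beat the noisy FBP by a wide margin even "
    "though training never saw the phantom; 'full' applies the network to "
    "the all-angles reconstruction, 'split-average' averages the per-section "
    "outputs."
)
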