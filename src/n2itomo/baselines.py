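"""Total-variation baseline, image metrics, and the loss-decomposition check.

The TV baseline solves ``min_x 0.5 * ||A x - y||^2 + lambda * TV(x)`` with
isotropic total variation (forward differences, Neumann boundary) using the
Chambolle-Pock primal-dual algorithm; step sizes come from a power-iteration
estimate of the combined operator norm ``||[A; grad]||``.

``verify_loss_decomposition`` checks, by Monte Carlo, the identity that
justifies self-supervised training: with a *fixed* measurement-independent
denoiser f, over the noise distribution,

    E sum_j ||f(x_{input,j}) - x_{target,j}||^2
      = E sum_j ||f(x_{input,j}) - x_{clean,j}||^2 + ||x_{clean,j} - x_{target,j}||^2

because the cross term pairs the target-section noise (zero-mean) with a
quantity independent of it.  The check reports the Monte-Carlo residual of
the identity together with its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .geometry import (
    ImageSlice,
    ProjectionGeometry,
    Sinogram,
    _divergence,
    _gradient,
    fbp_reconstruct,
    forward_project,
    operator_norm,
    system_matrix,
)
from .noise import NoiseConfig, simulate_noisy_sinogram
from .splitting import angular_split, extract_section

__all__ = [
    "TvConfig",
    "LossDecomposition",
    "tvmin_reconstruct",
    "tv_objective",
    "image_metrics",
    "verify_loss_decomposition",
]


@dataclass(frozen=True)
class TvConfig:
    lam: float
    iterations: int = 500
    step_safety: float = 0.95

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 < self.step_safety < 1):
            raise ValueError("step_safety must be in (0, 1)")


def tv_objective(
    x: np.ndarray, sinogram: Sinogram, lam: float
) -> float:
    """Primal objective 0.5*||Ax - y||^2 + lam * TV_iso(x)."""
    A = system_matrix(sinogram.geometry)
    resid = A @ x.ravel() - sinogram.values.ravel()
    g = _gradient(x)
    tv = np.sum(np.sqrt(g[0] ** 2 + g[1] ** 2))
    return 0.5 * float(resid @ resid) + lam * tv


def tvmin_reconstruct(
    sinogram: Sinogram,
    config: TvConfig,
    norm_seed: int = 0,
    objective_every: int = 0,
) -> ImageSlice | tuple[ImageSlice, list[float]]:
    """Chambolle-Pock primal-dual iteration for the TV-regularized problem.

    Deterministic.  With ``objective_every > 0`` also returns the primal
    objective sampled every that many iterations.
    """
    geom = sinogram.geometry
    N = geom.image_size
    A = system_matrix(geom)
    y = sinogram.values.ravel()
    lam = config.lam
    # stack K = [A; lam*grad] so the step sizes adapt to the regularization
    # weight; the TV dual then lives on the unit ball
    L = operator_norm(
        geom, iterations=30, seed=norm_seed, include_gradient=True,
        gradient_weight=lam,
    )
    sigma = tau = config.step_safety / max(L, 1e-12)

    x = np.zeros(N * N)
    xbar = x.copy()
    p = np.zeros(A.shape[0])  # dual of the data term
    q = np.zeros((2, N, N))  # dual of the TV term (unit ball)
    history: list[float] = []
    for it in range(config.iterations):
        p = (p + sigma * (A @ xbar - y)) / (1.0 + sigma)
        q += sigma * lam * _gradient(xbar.reshape(N, N))
        mag = np.sqrt(q[0] ** 2 + q[1] ** 2)
        scale = np.maximum(1.0, mag)
        q /= scale[None]
        x_new = x - tau * (A.T @ p + lam * (-_divergence(q)).ravel())
        xbar = 2 * x_new - x
        x = x_new
        if objective_every and (it + 1) % objective_every == 0:
            history.append(tv_objective(x.reshape(N, N), sinogram, config.lam))
    img = ImageSlice(values=x.reshape(N, N))
    if objective_every:
        return img, history
    return img


def image_metrics(candidate: np.ndarray, reference: np.ndarray) -> dict:
    """MSE, PSNR (vs reference dynamic range) and SSIM of two equal-shape volumes."""
    candidate = np.asarray(candidate, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if candidate.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: {candidate.shape} vs {reference.shape}"
        )
    mse = float(np.mean((candidate - reference) ** 2))
    rng_ = float(reference.max() - reference.min())
    if mse == 0:
        psnr = float("inf")
    else:
        psnr = float(10 * np.log10(max(rng_, 1e-300) ** 2 / mse))
    data_range = rng_ if rng_ > 0 else 1.0
    if candidate.ndim == 3 and candidate.shape[0] < 7:
        # thin stacks: SSIM per slice (the 3D window would not fit)
        ssim = float(
            np.mean(
                [
                    structural_similarity(
                        reference[z], candidate[z], data_range=data_range
                    )
                    for z in range(candidate.shape[0])
                ]
            )
        )
    else:
        ssim = float(
            structural_similarity(reference, candidate, data_range=data_range)
        )
    return {"mse": mse, "psnr": psnr, "ssim": ssim}


@dataclass
class LossDecomposition:
    """Monte-Carlo estimates of the three terms of the training-loss identity."""

    n2i_loss: float  # self-supervised loss (sum over sections, mean over pixels)
    supervised_loss: float  # loss against noise-free reconstructions
    noise_variance: float  # variance of the target-reconstruction noise
    mc_standard_error: float  # standard error of the per-realization residual
    realizations: int

    @property
    def residual(self) -> float:
        return self.n2i_loss - self.supervised_loss - self.noise_variance


def verify_loss_decomposition(
    phantom: ImageSlice,
    geometry: ProjectionGeometry,
    noise_config: NoiseConfig | None,
    J: int,
    fixed_denoiser,
    realizations: int = 200,
    seed: int = 0,
    filter_name: str = "ram-lak",
) -> LossDecomposition:
    """Empirically verify the training-loss decomposition.

    ``fixed_denoiser`` maps an image array to an image array and must be
    independent of the simulated measurements (a denoiser trained on these
    very realizations would invalidate the identity; that cannot be detected
    here).  ``noise_config=None`` disables noise: then the variance term is
    exactly zero and the self-supervised and supervised losses coincide.
    """
    if realizations < 2:
        raise ValueError("need at least 2 realizations")
    phantom_img = phantom if isinstance(phantom, ImageSlice) else ImageSlice(phantom)
    clean = forward_project(phantom_img, geometry)
    scheme = angular_split(geometry.num_angles, J)
    clean_targets = [
        fbp_reconstruct(extract_section(clean, scheme.target_sets[j]), filter_name).values
        for j in range(J)
    ]
    n2i_vals = np.empty(realizations)
    sup_vals = np.empty(realizations)
    var_vals = np.empty(realizations)
    rng = np.random.default_rng(seed)
    for r in range(realizations):
        if noise_config is None:
            noisy = clean
        else:
            cfg_r = NoiseConfig(
                incident_photon_count=noise_config.incident_photon_count,
                virtual_time_fraction=noise_config.virtual_time_fraction,
                dark_level=noise_config.dark_level,
                seed=int(rng.integers(0, 2**31 - 1)),
                gaussian_sigma=noise_config.gaussian_sigma,
            )
            noisy = simulate_noisy_sinogram(clean, cfg_r)
        n2i = sup = var = 0.0
        for j in range(J):
            x_tgt = fbp_reconstruct(
                extract_section(noisy, scheme.target_sets[j]), filter_name
            ).values
            x_inp = fbp_reconstruct(
                extract_section(noisy, scheme.input_sets[j]), filter_name
            ).values
            f = fixed_denoiser(x_inp)
            n2i += float(np.mean((f - x_tgt) ** 2))
            sup += float(np.mean((f - clean_targets[j]) ** 2))
            var += float(np.mean((clean_targets[j] - x_tgt) ** 2))
        n2i_vals[r], sup_vals[r], var_vals[r] = n2i, sup, var
    resid = n2i_vals - sup_vals - var_vals
    se = float(resid.std(ddof=1) / np.sqrt(realizations))
    return LossDecomposition(
        n2i_loss=float(n2i_vals.mean()),
        supervised_loss=float(sup_vals.mean()),
        noise_variance=float(var_vals.mean()),
        mc_standard_error=se,
        realizations=realizations,
    )
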