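"""Self-supervised training-pair construction, optimization loop, inference.

Training never sees the ground-truth object: pairs are built purely from
measured (or simulated) sinograms and a split scheme, and the loss compares
the network output on the input-section reconstruction against the
target-section reconstruction.  Because the noise in the two reconstructions
is independent and zero-mean, minimizing this loss minimizes — in
expectation — the loss against the unavailable noise-free reconstruction.

Three pairing strategies cover the three acquisition regimes:

``static_25d``
    Per slice and section j: input = multi-slice stack of input-section
    reconstructions (2.5D context), target = single-slice target-section
    reconstruction.
``dynamic``
    Per time-step group: input = reconstruction of one (sparsely sampled)
    time step, target = reconstruction of the combined sinogram of the other
    steps in the group — the target is built from *more* data than the
    input, so the network also learns to remove sparse-angle streaks.
``multichannel``
    Per angular section: input and target are full C-channel reconstructions
    from complementary angular sections; channels are never split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import Sinogram, fbp_reconstruct
from .network import (
    DenoisingModel,
    NormalizationStats,
    apply_model,
    assemble_25d_input,
)
from .splitting import (
    SplitScheme,
    combine_time_steps,
    extract_section,
    verify_conditions,
)

__all__ = [
    "ReconstructionPair",
    "TrainingConfig",
    "make_training_pairs",
    "train",
    "denoise_full",
    "dynamic_inference",
    "reconstruct_stack",
]

STRATEGIES = ("static_25d", "dynamic", "multichannel")


@dataclass
class ReconstructionPair:
    """One training example: input reconstruction(s) and target reconstruction."""

    input: np.ndarray  # (C_in, N, N)
    target: np.ndarray  # (C_out, N, N)
    j: int  # section index within the split scheme
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrainingConfig:
    iterations: int = 2000
    batch_size: int = 4
    learning_rate: float = 1e-3
    shuffle_seed: int = 0
    strategy: str = "static_25d"

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")


def reconstruct_stack(
    sinograms: Sequence[Sinogram], filter_name: str = "ram-lak"
) -> np.ndarray:
    """FBP every sinogram in a stack; returns (len, N, N)."""
    return np.stack([fbp_reconstruct(s, filter_name).values for s in sinograms])


def _check_scheme(scheme: SplitScheme, num_units: int) -> None:
    report = verify_conditions(scheme, num_units)
    if not report.all_pass:
        raise ValueError(
            "split scheme violates the self-supervision conditions: "
            + "; ".join(report.violations)
        )


def make_training_pairs(
    noisy_data: Sequence[Sinogram],
    scheme: SplitScheme,
    strategy: str = "static_25d",
    context: int = 0,
    filter_name: str = "ram-lak",
) -> list[ReconstructionPair]:
    """Build every (section, slice/time) training pair for one epoch.

    ``noisy_data`` is a sequence of per-slice (static), per-time-step
    (dynamic) or per-channel (multichannel) sinograms.  The scheme must pass
    :func:`~n2itomo.splitting.verify_conditions`, otherwise pair construction
    refuses to proceed — training on an invalid scheme would teach the
    network to reproduce noise.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    pairs: list[ReconstructionPair] = []

    if strategy == "static_25d":
        num_angles = noisy_data[0].num_angles
        _check_scheme(scheme, num_angles)
        if scheme.unit_kind != "angle":
            raise ValueError("static strategy needs an angular split")
        # per section: reconstruction volume of the input-section sinograms
        input_vols = []
        target_vols = []
        for j in range(scheme.J):
            inp = [extract_section(s, scheme.input_sets[j]) for s in noisy_data]
            tgt = [extract_section(s, scheme.target_sets[j]) for s in noisy_data]
            input_vols.append(reconstruct_stack(inp, filter_name))
            target_vols.append(reconstruct_stack(tgt, filter_name))
        for j in range(scheme.J):
            for z in range(len(noisy_data)):
                pairs.append(
                    ReconstructionPair(
                        input=assemble_25d_input(input_vols[j], z, context),
                        target=target_vols[j][z][None],
                        j=j,
                        provenance={"slice": z, "section": j},
                    )
                )
        return pairs

    if strategy == "dynamic":
        K = len(noisy_data)
        if scheme.J != K or scheme.unit_kind != "time_step":
            raise ValueError("dynamic strategy needs a time-step split over the group")
        _check_scheme(scheme, K)
        for j in range(scheme.J):
            inp_sino = combine_time_steps(
                [noisy_data[t] for t in scheme.input_sets[j]]
            )
            tgt_sino = combine_time_steps(
                [noisy_data[t] for t in scheme.target_sets[j]]
            )
            pairs.append(
                ReconstructionPair(
                    input=fbp_reconstruct(inp_sino, filter_name).values[None],
                    target=fbp_reconstruct(tgt_sino, filter_name).values[None],
                    j=j,
                    provenance={
                        "input_steps": list(scheme.input_sets[j]),
                        "target_steps": list(scheme.target_sets[j]),
                    },
                )
            )
        return pairs

    # multichannel
    num_angles = noisy_data[0].num_angles
    _check_scheme(scheme, num_angles)
    if scheme.unit_kind != "angle":
        raise ValueError("multichannel strategy needs an angular split")
    for j in range(scheme.J):
        inp = np.stack(
            [
                fbp_reconstruct(
                    extract_section(s, scheme.input_sets[j]), filter_name
                ).values
                for s in noisy_data
            ]
        )
        tgt = np.stack(
            [
                fbp_reconstruct(
                    extract_section(s, scheme.target_sets[j]), filter_name
                ).values
                for s in noisy_data
            ]
        )
        pairs.append(
            ReconstructionPair(
                input=inp, target=tgt, j=j, provenance={"section": j}
            )
        )
    return pairs


class _Adam:
    """Adaptive-moment SGD on a list of float32 arrays."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def train(
    pairs: Sequence[ReconstructionPair],
    model: DenoisingModel,
    config: TrainingConfig,
    monitor: Callable[[DenoisingModel, int], None] | None = None,
) -> tuple[DenoisingModel, list[float]]:
    """Minimize the self-supervised MSE over shuffled pairs.

    Returns the trained model (a copy; the argument is untouched) and the
    per-epoch mean training loss.  Fully reproducible from the model's
    weight seed and ``config.shuffle_seed``.  No early stopping: the small
    parameter count of the MS-D architecture makes overfitting to noise
    unlikely, so the iteration budget is simply exhausted.
    """
    if len(pairs) == 0:
        raise ValueError("no training pairs")
    cfg = model.config
    inputs = np.stack([p.input for p in pairs]).astype(np.float32)
    targets = np.stack([p.target for p in pairs]).astype(np.float32)
    if inputs.shape[1] != cfg.in_channels or targets.shape[1] != cfg.out_channels:
        raise ValueError(
            f"pair shapes {inputs.shape[1]}->{targets.shape[1]} do not match model "
            f"channels {cfg.in_channels}->{cfg.out_channels}"
        )
    model = model.copy()
    model.stats = NormalizationStats.from_data(inputs, targets)
    s = model.stats
    inputs = (inputs - s.input_offset) / s.input_scale
    targets = (targets - s.output_offset) / s.output_scale

    rng = np.random.default_rng(config.shuffle_seed)
    opt = _Adam(model.parameters(), config.learning_rate)
    n = len(pairs)
    order = rng.permutation(n)
    pos = 0
    epoch_losses: list[float] = []
    epoch_acc: list[float] = []
    for it in range(config.iterations):
        if pos >= n:
            epoch_losses.append(float(np.mean(epoch_acc)))
            epoch_acc = []
            if monitor is not None:
                monitor(model, len(epoch_losses))
            order = rng.permutation(n)
            pos = 0
        batch = order[pos : pos + config.batch_size]
        pos += config.batch_size
        x = inputs[batch]
        t = targets[batch]
        y, cache = model.forward(x, keep_cache=True)
        resid = y - t
        loss = float(np.mean(resid.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at iteration {it}; try a lower "
                "learning rate"
            )
        epoch_acc.append(loss)
        grad = (2.0 / resid.size) * resid
        dWh, dbh, dWo, dbo = model.backward(cache, grad)
        opt.step(model.parameters(), [*dWh, dbh, dWo, dbo])
    if epoch_acc:
        epoch_losses.append(float(np.mean(epoch_acc)))
        if monitor is not None:
            monitor(model, len(epoch_losses))
    model.provenance.update(
        {
            "iterations": config.iterations,
            "strategy": config.strategy,
            "shuffle_seed": config.shuffle_seed,
        }
    )
    return model, epoch_losses


def _apply_volume(
    model: DenoisingModel, volume: np.ndarray, context: int
) -> np.ndarray:
    """Apply the model slice-by-slice with 2.5D assembly where applicable."""
    cfg = model.config
    if cfg.in_channels == 2 * context + 1 and cfg.out_channels == 1:
        out = np.empty_like(volume)
        for z in range(volume.shape[0]):
            out[z] = apply_model(model, assemble_25d_input(volume, z, context))[0]
        return out
    if cfg.in_channels == volume.shape[0]:
        # multichannel: the whole stack is one input
        return apply_model(model, volume)
    raise ValueError(
        f"volume of {volume.shape[0]} slices does not match model channels "
        f"({cfg.in_channels} in / {cfg.out_channels} out) with context={context}"
    )


def denoise_full(
    model: DenoisingModel,
    noisy_data: Sequence[Sinogram],
    mode: str = "full",
    scheme: SplitScheme | None = None,
    context: int = 0,
    filter_name: str = "ram-lak",
) -> np.ndarray:
    """Denoise a measured stack in one of the two inference modes.

    ``full``: the model is applied to the reconstruction of *all*
    measurements (empirically the better mode).  ``split_average``: the
    model is applied to each input-section reconstruction separately and the
    J outputs are averaged (the original scheme).
    """
    if mode == "full":
        volume = reconstruct_stack(noisy_data, filter_name)
        return _apply_volume(model, volume, context)
    if mode == "split_average":
        if scheme is None:
            raise ValueError("split_average mode needs the training split scheme")
        num_angles = noisy_data[0].num_angles
        _check_scheme(scheme, num_angles)
        acc = None
        for j in range(scheme.J):
            vol = reconstruct_stack(
                [extract_section(s, scheme.input_sets[j]) for s in noisy_data],
                filter_name,
            )
            out = _apply_volume(model, vol, context)
            acc = out if acc is None else acc + out
        return acc / scheme.J
    raise ValueError("mode must be 'full' or 'split_average'")


def dynamic_inference(
    model: DenoisingModel,
    per_time_step_sinograms: Sequence[Sinogram],
    filter_name: str = "ram-lak",
) -> list[np.ndarray]:
    """Reconstruct each time step alone (sparse angles) and denoise it."""
    outputs = []
    for s in per_time_step_sinograms:
        rec = fbp_reconstruct(s, filter_name).values
        outputs.append(apply_model(model, rec[None])[0])
    return outputs
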