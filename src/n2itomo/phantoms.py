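"""Synthetic ground-truth generators for the three acquisition regimes.

All generators are pure functions of their parameters and a seed.  Phantoms
are piecewise-constant (a few material classes on a background disk), which
makes total-variation regularization a fair baseline and makes its
characteristic stair-casing versus fine-detail trade-off observable.

* ``static_phantom`` — a porous 3D volume: background disk plus randomly
  placed non-overlapping ellipsoids of 2-3 materials spanning several slices,
  so out-of-slice context is informative for a 2.5D network.
* ``dynamic_phantom`` — the same volume evolving in time: nothing changes for
  the first ``start_step`` steps (the training window), then spherical
  inclusions of a new material grow monotonically.
* ``spectral_phantom`` — a labeled 2D slice where every material carries a
  sparse positive per-channel signature; identical labels share identical
  signatures everywhere (the cross-channel correspondence that multi-channel
  training exploits).
* ``interlaced_schedule`` — per-time-step angle lists mutually offset so one
  group of steps tiles a full turn evenly; optional per-step angular jitter
  emulates small rotation-speed deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledVolume",
    "SpectralSlice",
    "DynamicVolumeSequence",
    "static_phantom",
    "dynamic_phantom",
    "spectral_phantom",
    "interlaced_schedule",
]

# attenuation per pixel chosen so a ~100 px object gives line integrals of
# order 1-2, i.e. realistic transmission between ~10% and ~40%
DEFAULT_ATTENUATION = {0: 0.0, 1: 0.010, 2: 0.020, 3: 0.016, 4: 0.024}
INCLUSION_MATERIAL = 9
INCLUSION_ATTENUATION = 0.004  # water-like: lighter than the solid background


@dataclass
class LabeledVolume:
    """Material labels per voxel plus a material -> attenuation table."""

    labels: np.ndarray  # (depth, N, N) integer, 0 = background/air
    attenuation_table: dict[int, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.attenuation_table)
        if missing:
            raise ValueError(f"labels without attenuation entry: {sorted(missing)}")
        if any(v < 0 for v in self.attenuation_table.values()):
            raise ValueError("attenuation must be non-negative")

    @property
    def attenuation(self) -> np.ndarray:
        """Derived attenuation volume, float64 (depth, N, N)."""
        out = np.zeros(self.labels.shape, dtype=np.float64)
        for mat, mu in self.attenuation_table.items():
            out[self.labels == mat] = mu
        return out

    @property
    def depth(self) -> int:
        return self.labels.shape[0]

    @property
    def size(self) -> int:
        return self.labels.shape[1]


@dataclass
class SpectralSlice:
    """Labeled 2D slice with a per-material channel signature (diffractogram)."""

    labels: np.ndarray  # (N, N) integer
    signature_table: dict[int, np.ndarray]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.signature_table = {
            int(k): np.asarray(v, dtype=np.float64)
            for k, v in self.signature_table.items()
        }
        lengths = {v.size for v in self.signature_table.values()}
        if len(lengths) != 1:
            raise ValueError("all signatures must have the same channel count")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.signature_table)
        if missing:
            raise ValueError(f"labels without signature entry: {sorted(missing)}")

    @property
    def num_channels(self) -> int:
        return next(iter(self.signature_table.values())).size

    def channel_volume(self) -> np.ndarray:
        """Per-channel ground truth, shape (C, N, N)."""
        C = self.num_channels
        out = np.zeros((C,) + self.labels.shape, dtype=np.float64)
        for mat, sig in self.signature_table.items():
            mask = self.labels == mat
            for c in range(C):
                out[c][mask] = sig[c]
        return out


@dataclass
class DynamicVolumeSequence:
    """Volumes over T time steps; nothing changes before ``start_step``."""

    volumes: list[LabeledVolume]
    start_step: int

    @property
    def num_steps(self) -> int:
        return len(self.volumes)


def _place_ellipsoids(rng, labels, num_features, materials, radius_range):
    depth, N, _ = labels.shape
    c = (N - 1) / 2.0
    limit = N / 2.0 - 2.0
    placed = []  # (zc, ic, jc, rz, r)
    attempts = 0
    n_done = 0
    while n_done < num_features:
        attempts += 1
        if attempts > 200 * max(num_features, 1):
            raise RuntimeError(
                f"could not pack {num_features} features after {attempts} attempts"
            )
        r = rng.uniform(*radius_range)
        rz = rng.uniform(max(1.5, r * 0.75), max(2.0, r * 1.5))
        ic = rng.uniform(-(limit - r), limit - r)
        jc = rng.uniform(-(limit - r), limit - r)
        if np.hypot(ic, jc) + r > limit:
            continue
        zc = rng.uniform(0, depth - 1)
        ok = True
        for (pz, pi, pj, prz, pr) in placed:
            d_xy = np.hypot(ic - pi, jc - pj)
            d_z = abs(zc - pz)
            if d_xy < (r + pr) and d_z < (rz + prz):
                ok = False
                break
        if not ok:
            continue
        mat = materials[n_done % len(materials)]
        zz, ii, jj = np.ogrid[:depth, :N, :N]
        mask = (
            ((zz - zc) / rz) ** 2
            + ((ii - c - ic) / r) ** 2
            + ((jj - c - jc) / r) ** 2
        ) <= 1.0
        labels[mask] = mat
        placed.append((zc, ic, jc, rz, r))
        n_done += 1


def static_phantom(
    N: int,
    depth: int = 8,
    num_features: int = 12,
    seed: int = 0,
    attenuation_table: dict[int, float] | None = None,
) -> LabeledVolume:
    """Porous static volume: background disk + non-overlapping ellipsoids."""
    if N < 16:
        raise ValueError("N must be >= 16")
    rng = np.random.default_rng(seed)
    table = dict(DEFAULT_ATTENUATION if attenuation_table is None else attenuation_table)
    c = (N - 1) / 2.0
    ii, jj = np.ogrid[:N, :N]
    disk = (ii - c) ** 2 + (jj - c) ** 2 <= (N / 2.0 - 2.0) ** 2
    labels = np.zeros((depth, N, N), dtype=np.int32)
    labels[:, disk] = 1
    if num_features > 0:
        _place_ellipsoids(
            rng,
            labels,
            num_features,
            materials=[2, 3, 4],
            radius_range=(max(2.0, N / 32), N / 8),
        )
        labels[:, ~disk] = 0  # features never spill outside the support disk
    return LabeledVolume(labels=labels, attenuation_table=table)


def dynamic_phantom(
    N: int,
    depth: int = 1,
    T: int = 12,
    start_step: int = 6,
    growth_rate: float = 1.0,
    seed: int = 0,
    num_inclusions: int = 2,
    r0: float = 2.0,
) -> DynamicVolumeSequence:
    """Static base volume, then spherical inclusions growing at ``growth_rate``.

    Inclusion radius at step t is ``r0 + growth_rate * (t - start_step)`` for
    t >= start_step (no inclusion before), so the inclusion voxel count is
    nondecreasing in time.
    """
    if not (0 <= start_step < T):
        raise ValueError("need 0 <= start_step < T")
    if growth_rate <= 0:
        raise ValueError("growth_rate must be positive")
    rng = np.random.default_rng(seed)
    base = static_phantom(N, depth=depth, num_features=6, seed=seed + 1)
    table = dict(base.attenuation_table)
    table[INCLUSION_MATERIAL] = INCLUSION_ATTENUATION
    c = (N - 1) / 2.0
    centers = []
    for _ in range(num_inclusions):
        while True:
            zc = rng.uniform(0, depth - 1)
            ic = rng.uniform(-N / 4, N / 4)
            jc = rng.uniform(-N / 4, N / 4)
            if np.hypot(ic, jc) < N / 2.0 - 2.0 - r0:
                centers.append((zc, ic, jc))
                break
    volumes = []
    zz, ii, jj = np.ogrid[:depth, :N, :N]
    for t in range(T):
        if t < start_step:
            volumes.append(LabeledVolume(labels=base.labels, attenuation_table=table))
            continue
        labels = base.labels.copy()
        r = r0 + growth_rate * (t - start_step)
        rz = max(0.75 * r, 0.5)
        for (zc, ic, jc) in centers:
            mask = (
                ((zz - zc) / rz) ** 2
                + ((ii - c - ic) / r) ** 2
                + ((jj - c - jc) / r) ** 2
            ) <= 1.0
            # inclusions only displace object material, never the air outside
            mask &= base.labels > 0
            labels[mask] = INCLUSION_MATERIAL
        volumes.append(LabeledVolume(labels=labels, attenuation_table=table))
    return DynamicVolumeSequence(volumes=volumes, start_step=start_step)


def spectral_phantom(
    N: int,
    num_materials: int = 4,
    C: int = 11,
    seed: int = 0,
    num_regions: int = 10,
) -> SpectralSlice:
    """Labeled slice whose materials carry sparse positive channel signatures.

    Every material's signature has a few random "peaks"; two regions with the
    same label have identical per-voxel channel vectors by construction.
    """
    if C < 1 or num_materials < 1:
        raise ValueError("C and num_materials must be >= 1")
    rng = np.random.default_rng(seed)
    vol = static_phantom(
        N,
        depth=1,
        num_features=0,
        seed=seed,
    )
    labels = vol.labels[0].copy()
    c = (N - 1) / 2.0
    limit = N / 2.0 - 2.0
    ii, jj = np.ogrid[:N, :N]
    for k in range(num_regions):
        mat = 2 + (k % max(num_materials - 1, 1))
        for _ in range(100):
            r = rng.uniform(max(2.0, N / 24), N / 7)
            ic = rng.uniform(-limit + r, limit - r)
            jc = rng.uniform(-limit + r, limit - r)
            if np.hypot(ic, jc) + r <= limit:
                break
        mask = (ii - c - ic) ** 2 + (jj - c - jc) ** 2 <= r**2
        labels[mask & (labels > 0)] = mat
    signatures: dict[int, np.ndarray] = {0: np.zeros(C)}
    for mat in range(1, num_materials + 1):
        sig = np.zeros(C)
        n_peaks = min(C, int(rng.integers(1, 4)))
        peaks = rng.choice(C, size=n_peaks, replace=False)
        sig[peaks] = rng.uniform(0.008, 0.03, size=n_peaks)
        if mat == 1:  # weak broad background response
            sig = np.full(C, 0.004) + sig * 0.25
        signatures[mat] = sig
    # keep only signatures for labels that are actually present
    present = set(np.unique(labels).tolist())
    signatures = {m: s for m, s in signatures.items() if m in present or m == 0}
    return SpectralSlice(labels=labels, signature_table=signatures)


def interlaced_schedule(
    num_steps: int,
    angles_per_step: int,
    jitter_sd: float = 0.0,
    seed: int = 0,
    offset: float = 0.0,
) -> list[np.ndarray]:
    """Per-step angle lists whose union tiles a full turn evenly.

    Step ``s`` gets ``offset + s*delta/num_steps + k*delta`` for
    ``k = 0..angles_per_step-1`` with ``delta = 2*pi/angles_per_step``, plus an
    optional per-step Gaussian angular jitter (one rigid draw per step,
    modelling a rotation-speed deviation rather than per-angle encoder noise).
    With zero jitter the union over one group of ``num_steps`` steps is a
    uniform grid of ``num_steps * angles_per_step`` distinct angles.
    """
    if num_steps < 1 or angles_per_step < 1:
        raise ValueError("num_steps and angles_per_step must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    delta = 2 * np.pi / angles_per_step
    schedules = []
    for s in range(num_steps):
        jitter = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
        angles = (
            offset + s * delta / num_steps + np.arange(angles_per_step) * delta + jitter
        ) % (2 * np.pi)
        schedules.append(angles)
    return schedules
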