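"""2D parallel-beam geometry, Joseph projector, and filtered backprojection.

Conventions
-----------
Images are ``N x N`` arrays; pixel ``(i, j)`` is centered at coordinates
``(i - (N-1)/2, j - (N-1)/2)`` in pixel units, with the first coordinate
along array axis 0 and the second along array axis 1.

A projection angle ``theta`` describes rays with direction
``d = (cos theta, sin theta)`` in these coordinates — i.e. angle 0 sends
rays along the image +x axis (array axis 0), so the angle-0 projection is
(up to interpolation) the column-sum of the image.  The object rotates
counterclockwise as ``theta`` increases.  The detector lies along the
perpendicular direction ``e = (-sin theta, cos theta)``; detector bin ``s``
samples the line at signed offset ``t = (s - rotation_center) * pixel_size``.

The forward projector is ray-driven Joseph-style: unit steps along the
image axis most parallel to the ray, linear interpolation between the two
nearest pixels in the transverse axis, with path-length weight
``1 / max(|cos theta|, |sin theta|)``.  The backprojector is the exact
matrix transpose, so the adjoint identity holds to machine precision.
Rays that leave the ``N x N`` square are truncated to it (values outside
the grid contribute nothing); detectors narrower than the image diagonal
therefore measure truncated line integrals.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ProjectionGeometry",
    "Sinogram",
    "ImageSlice",
    "make_geometry",
    "forward_project",
    "backproject",
    "fbp_reconstruct",
    "operator_norm",
    "system_matrix",
    "FILTERS",
]

FILTERS = ("ram-lak", "shepp-logan", "cosine")


@dataclass(frozen=True)
class ProjectionGeometry:
    """Angle list plus detector/image layout defining the linear operator A."""

    angles: np.ndarray
    num_detector_pixels: int
    image_size: int
    detector_pixel_size: float = 1.0
    rotation_center: float | None = None

    def __post_init__(self):
        angles = np.atleast_1d(np.asarray(self.angles, dtype=np.float64))
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("angles must be a non-empty 1D sequence")
        if not np.all(np.isfinite(angles)):
            raise ValueError("angles must be finite")
        if np.unique(angles).size != angles.size:
            raise ValueError("angles must be pairwise distinct")
        object.__setattr__(self, "angles", angles)
        if self.num_detector_pixels <= 0:
            raise ValueError("num_detector_pixels must be positive")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.detector_pixel_size <= 0:
            raise ValueError("detector_pixel_size must be positive")
        if self.rotation_center is None:
            object.__setattr__(
                self, "rotation_center", (self.num_detector_pixels - 1) / 2.0
            )

    @property
    def num_angles(self) -> int:
        return int(self.angles.size)

    def with_angles(self, angles: np.ndarray) -> "ProjectionGeometry":
        return replace(self, angles=np.asarray(angles, dtype=np.float64))

    def cache_key(self) -> tuple:
        return (
            self.angles.tobytes(),
            self.num_detector_pixels,
            self.image_size,
            float(self.detector_pixel_size),
            float(self.rotation_center),
        )


@dataclass
class Sinogram:
    """Measured/simulated line integrals with attached geometry.

    ``values`` has shape ``(num_angles, num_detector_pixels)``.  Optional
    indices record which slice / time step / channel the sinogram belongs to.
    """

    values: np.ndarray
    geometry: ProjectionGeometry
    slice_index: int | None = None
    time_index: int | None = None
    channel_index: int | None = None
    angle_sources: np.ndarray | None = None  # provenance: origin time step per row

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("sinogram values must be 2D (angles x detector)")
        if values.shape[0] != self.geometry.num_angles:
            raise ValueError(
                f"sinogram has {values.shape[0]} rows but geometry lists "
                f"{self.geometry.num_angles} angles"
            )
        if values.shape[1] != self.geometry.num_detector_pixels:
            raise ValueError("sinogram width does not match detector size")
        if not np.all(np.isfinite(values)):
            raise ValueError("sinogram values must be finite")
        self.values = values

    @property
    def num_angles(self) -> int:
        return self.values.shape[0]


@dataclass
class ImageSlice:
    """A reconstructed or ground-truth 2D slice (attenuation per pixel)."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("image must be a square 2D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("image values must be finite")
        self.values = values

    @property
    def size(self) -> int:
        return self.values.shape[0]


def make_geometry(
    num_angles: int,
    angular_range: float,
    offset: float = 0.0,
    num_detector_pixels: int | None = None,
    image_size: int = 128,
) -> ProjectionGeometry:
    """Equally spaced geometry: ``angles[k] = offset + k * angular_range / num_angles``.

    ``angular_range`` is typically ``pi`` (half turn) or ``2*pi`` (full turn).
    Angles are reduced modulo ``2*pi``.
    """
    if num_angles < 1:
        raise ValueError("num_angles must be >= 1")
    if angular_range <= 0:
        raise ValueError("angular_range must be positive")
    if num_detector_pixels is None:
        num_detector_pixels = image_size
    angles = (offset + np.arange(num_angles) * angular_range / num_angles) % (
        2 * np.pi
    )
    return ProjectionGeometry(
        angles=angles,
        num_detector_pixels=num_detector_pixels,
        image_size=image_size,
    )


# ---------------------------------------------------------------------------
# System matrix (Joseph) with an nnz-capped LRU cache
# ---------------------------------------------------------------------------

_MATRIX_CACHE: "OrderedDict[tuple, sp.csr_matrix]" = OrderedDict()
_CACHE_NNZ_CAP = 120_000_000


def _build_system_matrix(geom: ProjectionGeometry) -> sp.csr_matrix:
    N = geom.image_size
    S = geom.num_detector_pixels
    c = (N - 1) / 2.0
    t = (np.arange(S) - geom.rotation_center) * geom.detector_pixel_size

    rows_all, cols_all, vals_all = [], [], []
    idx = np.arange(N)
    for a, theta in enumerate(geom.angles):
        d0, d1 = math.cos(theta), math.sin(theta)
        e0, e1 = -d1, d0
        if abs(d0) >= abs(d1):
            # drive along axis 0 (rows i), interpolate along axis 1
            # point on ray with axis-0 coordinate x: tau = (x - t*e0)/d0
            x = idx - c  # (N,)
            tau = (x[None, :] - t[:, None] * e0) / d0  # (S, N)
            y = t[:, None] * e1 + tau * d1
            jf = y + c
            w = 1.0 / abs(d0)
            drive_is_axis0 = True
        else:
            y = idx - c
            tau = (y[None, :] - t[:, None] * e1) / d1
            x = t[:, None] * e0 + tau * d0
            jf = x + c
            w = 1.0 / abs(d1)
            drive_is_axis0 = False

        j0 = np.floor(jf).astype(np.int64)
        frac = jf - j0
        det_idx = np.broadcast_to(np.arange(S)[:, None], jf.shape)
        drive_idx = np.broadcast_to(idx[None, :], jf.shape)

        for jj, wt in ((j0, (1.0 - frac) * w), (j0 + 1, frac * w)):
            mask = (jj >= 0) & (jj < N) & (wt > 0)
            if not mask.any():
                continue
            di = drive_idx[mask]
            tj = jj[mask]
            if drive_is_axis0:
                cols = di * N + tj
            else:
                cols = tj * N + di
            rows_all.append(a * S + det_idx[mask])
            cols_all.append(cols)
            vals_all.append(wt[mask])

    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    vals = np.concatenate(vals_all)
    A = sp.coo_matrix(
        (vals, (rows, cols)), shape=(geom.num_angles * S, N * N)
    ).tocsr()
    return A


def system_matrix(geom: ProjectionGeometry) -> sp.csr_matrix:
    """Sparse CSR matrix of the Joseph forward projector (cached)."""
    key = geom.cache_key()
    if key in _MATRIX_CACHE:
        _MATRIX_CACHE.move_to_end(key)
        return _MATRIX_CACHE[key]
    A = _build_system_matrix(geom)
    _MATRIX_CACHE[key] = A
    total = sum(m.nnz for m in _MATRIX_CACHE.values())
    while total > _CACHE_NNZ_CAP and len(_MATRIX_CACHE) > 1:
        _, old = _MATRIX_CACHE.popitem(last=False)
        total -= old.nnz
    return A


def forward_project(image: ImageSlice, geometry: ProjectionGeometry) -> Sinogram:
    """Line integrals of ``image`` along every (angle, detector bin) ray."""
    img = image.values if isinstance(image, ImageSlice) else np.asarray(image)
    if img.shape != (geometry.image_size, geometry.image_size):
        raise ValueError(
            f"image shape {img.shape} does not match geometry image_size "
            f"{geometry.image_size}"
        )
    A = system_matrix(geometry)
    sino = (A @ img.ravel()).reshape(
        geometry.num_angles, geometry.num_detector_pixels
    )
    return Sinogram(values=sino, geometry=geometry)


def backproject(sinogram: Sinogram) -> ImageSlice:
    """Unfiltered backprojection: the exact transpose of :func:`forward_project`."""
    geom = sinogram.geometry
    A = system_matrix(geom)
    img = (A.T @ sinogram.values.ravel()).reshape(geom.image_size, geom.image_size)
    return ImageSlice(values=img)


def _ramp_kernel(n: int) -> np.ndarray:
    """Discrete ramp filter response (Kak & Slaney) in the frequency domain."""
    # real-space kernel: h[0] = 1/4, h[k] = -1/(pi k)^2 for odd k, 0 for even k
    k = np.concatenate(
        (np.arange(1, n // 2 + 1, 2), np.arange(n // 2 - 1, 0, -2))
    )
    h = np.zeros(n)
    h[0] = 0.25
    h[1::2] = -1.0 / (np.pi * k) ** 2
    return 2 * np.real(np.fft.fft(h))


def _fourier_filter(n: int, filter_name: str) -> np.ndarray:
    ramp = _ramp_kernel(n)
    if filter_name == "ram-lak":
        return ramp
    omega = 2 * np.pi * np.fft.fftfreq(n)
    if filter_name == "shepp-logan":
        out = ramp.copy()
        nz = omega != 0
        out[nz] *= np.sin(omega[nz] / 2) / (omega[nz] / 2)
        return out
    if filter_name == "cosine":
        return ramp * np.cos(omega / 2)
    raise ValueError(
        f"unknown filter {filter_name!r}; expected one of {FILTERS}"
    )


def filter_sinogram(sinogram: Sinogram, filter_name: str = "ram-lak") -> Sinogram:
    """Ramp-filter each projection (zero-padded FFT convolution)."""
    vals = sinogram.values
    S = vals.shape[1]
    n = max(64, 2 ** int(np.ceil(np.log2(2 * S))))
    filt = _fourier_filter(n, filter_name)
    padded = np.zeros((vals.shape[0], n))
    padded[:, :S] = vals
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * filt, axis=1))
    filtered = filtered[:, :S] / sinogram.geometry.detector_pixel_size**2
    return Sinogram(
        values=filtered,
        geometry=sinogram.geometry,
        slice_index=sinogram.slice_index,
        time_index=sinogram.time_index,
        channel_index=sinogram.channel_index,
    )


def fbp_reconstruct(
    sinogram: Sinogram, filter_name: str = "ram-lak"
) -> ImageSlice:
    """Filtered backprojection.

    Scaled by ``pi / num_angles`` so that angle sets uniformly covering a half
    turn (or, with implicit opposite-ray averaging, a full turn) reconstruct
    the attenuation values of the object quantitatively.  Linear in the
    sinogram by construction.
    """
    filtered = filter_sinogram(sinogram, filter_name)
    bp = backproject(filtered)
    px = sinogram.geometry.detector_pixel_size
    scale = np.pi / (2.0 * sinogram.num_angles) * px
    return ImageSlice(values=bp.values * scale)


def _gradient(x: np.ndarray) -> np.ndarray:
    """Forward-difference gradient with Neumann boundary, shape (2, N, N)."""
    g = np.zeros((2,) + x.shape)
    g[0, :-1, :] = x[1:, :] - x[:-1, :]
    g[1, :, :-1] = x[:, 1:] - x[:, :-1]
    return g


def _divergence(g: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`_gradient`."""
    d = np.zeros(g.shape[1:])
    d[:-1, :] += g[0, :-1, :]
    d[1:, :] -= g[0, :-1, :]
    d[:, :-1] += g[1, :, :-1]
    d[:, 1:] -= g[1, :, :-1]
    return d


def operator_norm(
    geometry: ProjectionGeometry,
    iterations: int = 20,
    seed: int = 0,
    include_gradient: bool = False,
    gradient_weight: float = 1.0,
) -> float:
    """Power-iteration estimate of the spectral norm of A (or ``[A; w*grad]``).

    Deterministic given ``seed``; the estimate is nondecreasing in the
    iteration count for a fixed starting vector.  ``gradient_weight`` scales
    the stacked gradient block (used by the TV baseline, which folds the
    regularization weight into the operator).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    N = geometry.image_size
    A = system_matrix(geometry)
    x = rng.standard_normal(N * N)
    x /= np.linalg.norm(x)
    est = 0.0
    w2 = gradient_weight**2
    for _ in range(iterations):
        y = A.T @ (A @ x)
        if include_gradient:
            y = y + w2 * (-_divergence(_gradient(x.reshape(N, N)))).ravel()
        nrm = np.linalg.norm(y)
        if nrm == 0:
            return 0.0
        est = math.sqrt(nrm)
        x = y / nrm
    return est
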