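"""HDF5 containers, TIFF interchange, TOML configs, model checkpoints.

Container schema (single HDF5 file, 32-bit float data):

* ``/sinogram`` + ``/angles`` — a single sinogram and its angle list
* ``/time/<t>/sinogram`` + ``/time/<t>/angles`` — per-time-step sinograms
* ``/channels/<c>/sinogram`` — per-channel sinograms sharing ``/angles``
* ``/volume`` — a reconstructed or ground-truth volume
* geometry stored as attributes under ``geometry/`` on the file root;
  the generating configuration echoed as the ``config`` string attribute.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import ProjectionGeometry, Sinogram
from .network import DenoisingModel, ModelConfig, NormalizationStats

__all__ = [
    "write_container",
    "read_container",
    "write_tiff",
    "read_tiff",
    "load_config",
    "save_model",
    "load_model",
]


def _geom_attrs(grp, geom: ProjectionGeometry) -> None:
    grp.attrs["geometry/num_detector_pixels"] = geom.num_detector_pixels
    grp.attrs["geometry/image_size"] = geom.image_size
    grp.attrs["geometry/detector_pixel_size"] = geom.detector_pixel_size
    grp.attrs["geometry/rotation_center"] = geom.rotation_center


def _geom_from_attrs(grp, angles: np.ndarray) -> ProjectionGeometry:
    return ProjectionGeometry(
        angles=angles,
        num_detector_pixels=int(grp.attrs["geometry/num_detector_pixels"]),
        image_size=int(grp.attrs["geometry/image_size"]),
        detector_pixel_size=float(grp.attrs["geometry/detector_pixel_size"]),
        rotation_center=float(grp.attrs["geometry/rotation_center"]),
    )


def _store_sino(grp, sino: Sinogram) -> None:
    grp.create_dataset("sinogram", data=sino.values.astype(np.float32))
    grp.create_dataset("angles", data=sino.geometry.angles)
    _geom_attrs(grp, sino.geometry)


def _load_sino(grp, **ids) -> Sinogram:
    if "angles" not in grp:
        raise KeyError(f"container group {grp.name!r} is missing '/angles'")
    if "sinogram" not in grp:
        raise KeyError(f"container group {grp.name!r} is missing '/sinogram'")
    angles = np.asarray(grp["angles"])
    return Sinogram(
        values=np.asarray(grp["sinogram"], dtype=np.float64),
        geometry=_geom_from_attrs(grp, angles),
        **ids,
    )


def write_container(
    path,
    sinogram: Sinogram | None = None,
    time_sinograms: list[Sinogram] | None = None,
    channel_sinograms: list[Sinogram] | None = None,
    volume: np.ndarray | None = None,
    config: dict | None = None,
) -> None:
    """Write sinograms/volumes/metadata to a single HDF5 container."""
    with h5py.File(path, "w") as f:
        if sinogram is not None:
            _store_sino(f, sinogram)
        if time_sinograms is not None:
            for t, s in enumerate(time_sinograms):
                _store_sino(f.create_group(f"time/{t}"), s)
        if channel_sinograms is not None:
            for c, s in enumerate(channel_sinograms):
                _store_sino(f.create_group(f"channels/{c}"), s)
        if volume is not None:
            f.create_dataset("volume", data=np.asarray(volume, dtype=np.float32))
        if config is not None:
            f.attrs["config"] = json.dumps(config)


def read_container(path) -> dict:
    """Read a container back; inverse of :func:`write_container`."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "sinogram" in f:
            out["sinogram"] = _load_sino(f)
        if "time" in f:
            steps = sorted(f["time"], key=int)
            out["time_sinograms"] = [
                _load_sino(f[f"time/{t}"], time_index=int(t)) for t in steps
            ]
        if "channels" in f:
            chans = sorted(f["channels"], key=int)
            out["channel_sinograms"] = [
                _load_sino(f[f"channels/{c}"], channel_index=int(c)) for c in chans
            ]
        if "volume" in f:
            out["volume"] = np.asarray(f["volume"], dtype=np.float64)
        if "config" in f.attrs:
            out["config"] = json.loads(f.attrs["config"])
    return out


def write_tiff(path, volume: np.ndarray) -> None:
    """Multi-page 32-bit float TIFF (one page per slice)."""
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim == 2:
        vol = vol[None]
    tifffile.imwrite(path, vol, photometric="minisblack")


def read_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


# ---------------------------------------------------------------------------
# TOML experiment configs
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "geometry": {"num_angles", "angular_range_turns", "offset",
                 "num_detector_pixels", "image_size"},
    "phantom": {"kind", "size", "depth", "num_features", "seed", "time_steps",
                "start_step", "growth_rate", "num_materials", "channels",
                "angles_per_step", "jitter_sd"},
    "noise": {"incident_photon_count", "virtual_time_fraction", "dark_level",
              "seed", "gaussian_sigma"},
    "split": {"strategy", "J", "group_size", "context"},
    "model": {"depth", "dilation_cycle", "weight_init_seed"},
    "training": {"iterations", "batch_size", "learning_rate", "shuffle_seed"},
    "evaluation": {"reference", "candidate"},
    "tv": {"lam", "iterations"},
    "paths": {"container", "model", "output", "report"},
}

_SEED_REQUIRED = {"phantom": "seed", "noise": "seed",
                  "model": "weight_init_seed", "training": "shuffle_seed"}


def load_config(path) -> dict:
    """Load and validate a TOML experiment config.

    Unknown sections or keys are rejected outright; every section that
    involves randomness must carry its seed explicitly, so a config fully
    determines a run.
    """
    with open(path, "rb") as f:
        cfg = tomllib.load(f)
    for section, keys in cfg.items():
        if section not in _KNOWN_KEYS:
            raise ValueError(f"unknown config section [{section}]")
        if not isinstance(keys, dict):
            raise ValueError(f"config section [{section}] must be a table")
        unknown = set(keys) - _KNOWN_KEYS[section]
        if unknown:
            raise ValueError(
                f"unknown keys in [{section}]: {sorted(unknown)}"
            )
    for section, seed_key in _SEED_REQUIRED.items():
        if section in cfg and seed_key not in cfg[section]:
            raise ValueError(
                f"config section [{section}] must state its '{seed_key}'"
            )
    return cfg


# ---------------------------------------------------------------------------
# Model checkpoints
# ---------------------------------------------------------------------------


def save_model(path, model: DenoisingModel, scheme_json: str | None = None) -> None:
    """Single-file HDF5 checkpoint: config, weights, stats, split scheme."""
    cfg = model.config
    with h5py.File(path, "w") as f:
        f.attrs["depth"] = cfg.depth
        f.attrs["in_channels"] = cfg.in_channels
        f.attrs["out_channels"] = cfg.out_channels
        f.attrs["dilation_cycle"] = cfg.dilation_cycle
        f.attrs["weight_init_seed"] = cfg.weight_init_seed
        f.attrs["padding"] = model.padding
        for i, w in enumerate(model.hidden_weights):
            f.create_dataset(f"weights/hidden_{i}", data=w)
        f.create_dataset("weights/hidden_biases", data=model.hidden_biases)
        f.create_dataset("weights/out", data=model.out_weights)
        f.create_dataset("weights/out_bias", data=model.out_bias)
        s = model.stats
        f.attrs["stats"] = json.dumps(
            [s.input_offset, s.input_scale, s.output_offset, s.output_scale]
        )
        f.attrs["provenance"] = json.dumps(model.provenance)
        if scheme_json is not None:
            f.attrs["split_scheme"] = scheme_json


def load_model(path) -> tuple[DenoisingModel, str | None]:
    with h5py.File(path, "r") as f:
        cfg = ModelConfig(
            depth=int(f.attrs["depth"]),
            in_channels=int(f.attrs["in_channels"]),
            out_channels=int(f.attrs["out_channels"]),
            dilation_cycle=int(f.attrs["dilation_cycle"]),
            weight_init_seed=int(f.attrs["weight_init_seed"]),
        )
        hidden = [
            np.asarray(f[f"weights/hidden_{i}"], dtype=np.float32)
            for i in range(cfg.depth)
        ]
        io_, is_, oo_, os_ = json.loads(f.attrs["stats"])
        model = DenoisingModel(
            config=cfg,
            hidden_weights=hidden,
            hidden_biases=np.asarray(f["weights/hidden_biases"], dtype=np.float32),
            out_weights=np.asarray(f["weights/out"], dtype=np.float32),
            out_bias=np.asarray(f["weights/out_bias"], dtype=np.float32),
            stats=NormalizationStats(io_, is_, oo_, os_),
            padding=str(f.attrs["padding"]),
            provenance=json.loads(f.attrs["provenance"]),
        )
        scheme = f.attrs.get("split_scheme")
    return model, (str(scheme) if scheme is not None else None)
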