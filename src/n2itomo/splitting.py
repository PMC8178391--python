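"""Input/target section construction and the two self-supervision conditions.

Noise2Inverse training requires that (1) the noise in the reconstructed input
image is statistically independent of the noise in the reconstructed target
image — guaranteed here by building input and target from disjoint measurement
units — and (2) every measurement unit is used in the target reconstructions
equally often — guaranteed by making the target sets a partition of the units.
Units are either projection angles (static and multi-channel strategies) or
whole time steps (dynamic strategy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import ProjectionGeometry, Sinogram

__all__ = [
    "SplitScheme",
    "ConditionReport",
    "angular_split",
    "extract_section",
    "dynamic_split",
    "combine_time_steps",
    "multichannel_split",
    "verify_conditions",
]


@dataclass(frozen=True)
class SplitScheme:
    """J complementary (input, target) index-set pairs over measurement units."""

    J: int
    target_sets: tuple[tuple[int, ...], ...]
    input_sets: tuple[tuple[int, ...], ...]
    unit_kind: str  # "angle" | "time_step"

    def __post_init__(self):
        if self.J != len(self.target_sets) or self.J != len(self.input_sets):
            raise ValueError("J must equal the number of target/input sets")
        if self.unit_kind not in ("angle", "time_step"):
            raise ValueError("unit_kind must be 'angle' or 'time_step'")
        for s in self.target_sets + self.input_sets:
            if len(s) == 0:
                raise ValueError("every index set must be nonempty")

    def to_json(self) -> str:
        return json.dumps(
            {
                "unit_kind": self.unit_kind,
                "J": self.J,
                "target_sets": [list(s) for s in self.target_sets],
                "input_sets": [list(s) for s in self.input_sets],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitScheme":
        d = json.loads(text)
        return cls(
            J=d["J"],
            target_sets=tuple(tuple(s) for s in d["target_sets"]),
            input_sets=tuple(tuple(s) for s in d["input_sets"]),
            unit_kind=d["unit_kind"],
        )


@dataclass
class ConditionReport:
    condition1_pass: bool
    condition2_pass: bool
    violations: list[str] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return self.condition1_pass and self.condition2_pass


def angular_split(num_angles: int, J: int) -> SplitScheme:
    """Strided angular split: target set j collects angles ``k`` with ``k % J == j``.

    The stride puts adjacent angles in different target sections, keeping each
    section's angular sampling near-uniform.  With J = 3 each input section
    covers 2/3 of the angles and each target 1/3; when ``num_angles`` is not
    divisible by J, the remainder angles land in the lowest-index target sets.
    """
    if J < 2:
        raise ValueError("J must be >= 2 (J=1 leaves the input section empty)")
    if J > num_angles:
        raise ValueError("J cannot exceed the number of angles")
    all_idx = np.arange(num_angles)
    targets = tuple(tuple(int(k) for k in all_idx[j::J]) for j in range(J))
    inputs = tuple(
        tuple(int(k) for k in all_idx if k % J != j) for j in range(J)
    )
    return SplitScheme(J=J, target_sets=targets, input_sets=inputs, unit_kind="angle")


def extract_section(sinogram: Sinogram, index_set: Iterable[int]) -> Sinogram:
    """Row-subset of a sinogram; derived geometry keeps the selected angle values."""
    idx = np.asarray(sorted(index_set), dtype=int)
    if idx.size == 0:
        raise ValueError("index set must be nonempty")
    if idx.min() < 0 or idx.max() >= sinogram.num_angles:
        raise ValueError(
            f"index set out of range for a {sinogram.num_angles}-angle sinogram"
        )
    geom = sinogram.geometry.with_angles(sinogram.geometry.angles[idx])
    return Sinogram(
        values=sinogram.values[idx],
        geometry=geom,
        slice_index=sinogram.slice_index,
        time_index=sinogram.time_index,
        channel_index=sinogram.channel_index,
        angle_sources=None
        if sinogram.angle_sources is None
        else sinogram.angle_sources[idx],
    )


def dynamic_split(num_time_steps_in_group: int) -> SplitScheme:
    """Round-robin time-step split: input = one step, target = all the others.

    Deliberately inverts the size relation of the angular split — the target
    is reconstructed from more measurements (denser combined sampling) than
    the input, so the trained network also learns to suppress sparse-angle
    streaks.  A group of K steps gives an input:target section ratio 1:(K-1).
    """
    K = num_time_steps_in_group
    if K < 2:
        raise ValueError("need at least 2 time steps per group")
    targets = tuple(
        tuple(t for t in range(K) if t != j) for j in range(K)
    )
    inputs = tuple((j,) for j in range(K))
    # note: targets here are the *input-complement*; target sets as defined by
    # the conditions are the singleton step each pair centres on.
    return SplitScheme(
        J=K,
        target_sets=targets,
        input_sets=inputs,
        unit_kind="time_step",
    )


def combine_time_steps(sinograms: Sequence[Sinogram]) -> Sinogram:
    """Merge interlaced per-time-step sinograms into one densely sampled sinogram.

    Angle lists must be pairwise disjoint; rows are sorted by angle and the
    provenance of each row (its source position in ``sinograms``) is retained.
    """
    if len(sinograms) == 0:
        raise ValueError("need at least one sinogram")
    if len(sinograms) == 1:
        s = sinograms[0]
        if s.angle_sources is None:
            s = Sinogram(
                values=s.values,
                geometry=s.geometry,
                slice_index=s.slice_index,
                time_index=s.time_index,
                angle_sources=np.zeros(s.num_angles, dtype=int),
            )
        return s
    det = sinograms[0].geometry.num_detector_pixels
    N = sinograms[0].geometry.image_size
    for s in sinograms[1:]:
        if s.geometry.num_detector_pixels != det or s.geometry.image_size != N:
            raise ValueError("all sinograms must share detector and image size")
        if s.slice_index != sinograms[0].slice_index:
            raise ValueError("all sinograms must belong to the same slice")
    angles = np.concatenate([s.geometry.angles for s in sinograms])
    if np.unique(angles).size != angles.size:
        raise ValueError(
            "duplicate angles across time steps would make the later split "
            "violate noise independence"
        )
    values = np.concatenate([s.values for s in sinograms], axis=0)
    sources = np.concatenate(
        [np.full(s.num_angles, k, dtype=int) for k, s in enumerate(sinograms)]
    )
    order = np.argsort(angles)
    geom = sinograms[0].geometry.with_angles(angles[order])
    return Sinogram(
        values=values[order],
        geometry=geom,
        slice_index=sinograms[0].slice_index,
        angle_sources=sources[order],
    )


def multichannel_split(sinograms: Sequence[Sinogram], J: int) -> SplitScheme:
    """One angular split applied identically to every channel.

    Channels are never separated between input and target: each training
    input and target carries the full channel stack, so the network can
    exploit the cross-channel structure (the diffractogram) of the object.
    """
    if len(sinograms) == 0:
        raise ValueError("need at least one channel")
    ref = sinograms[0].geometry
    for s in sinograms[1:]:
        g = s.geometry
        if (
            g.num_angles != ref.num_angles
            or not np.allclose(g.angles, ref.angles)
            or g.num_detector_pixels != ref.num_detector_pixels
            or g.image_size != ref.image_size
        ):
            raise ValueError("all channels must share an identical geometry")
    return angular_split(ref.num_angles, J)


def verify_conditions(scheme: SplitScheme, num_units: int) -> ConditionReport:
    """Check the two self-supervision conditions on a split scheme.

    Condition 1: every input set is disjoint from its own target set.
    Condition 2: every measurement unit appears in exactly one target set.
    """
    violations: list[str] = []
    cond1 = True
    for j, (tgt, inp) in enumerate(zip(scheme.target_sets, scheme.input_sets)):
        overlap = set(tgt) & set(inp)
        if overlap:
            cond1 = False
            violations.append(
                f"section {j}: input and target overlap on units {sorted(overlap)}"
            )
    counts = np.zeros(num_units, dtype=int)
    cond2 = True
    for tgt in scheme.target_sets:
        for k in tgt:
            if 0 <= k < num_units:
                counts[k] += 1
            else:
                cond2 = False
                violations.append(f"target unit {k} outside range 0..{num_units - 1}")
    if scheme.unit_kind == "time_step":
        # dynamic round-robin: the "target" of pair j is the complement of step
        # j, so each unit appears in K-1 target sets — equally often.
        if np.unique(counts).size > 1:
            cond2 = False
            for k in np.nonzero(counts != counts.max())[0]:
                violations.append(
                    f"unit {k} appears {counts[k]}x in targets (others {counts.max()}x)"
                )
    else:
        missing = np.nonzero(counts == 0)[0]
        multiple = np.nonzero(counts > 1)[0]
        if missing.size:
            cond2 = False
            violations.append(f"units never used as target: {missing.tolist()}")
        if multiple.size:
            cond2 = False
            violations.append(
                f"units used in more than one target set: {multiple.tolist()}"
            )
    return ConditionReport(
        condition1_pass=cond1, condition2_pass=cond2, violations=violations
    )
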