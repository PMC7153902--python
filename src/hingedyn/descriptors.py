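"""Virtual-atom hinge descriptors.

The hinge dimer's slow motions are captured by a handful of geometric
observables built from *virtual atoms* (unweighted geometric centers of
atom groups):

* the opening angle at the disulfide-cluster center between the per-chain
  C5a/C8a midpoints (degrees, 0-180);
* the W-W' twist distance between the two tryptophan side-chain centers
  (nm), a proxy for beta-hairpin twisting;
* the G7-G7' loop distance across the two turn regions (nm);
* a donor-acceptor hydrogen-bond count used to monitor secondary-structure
  integrity.

All descriptors are evaluated per frame and are invariant under rigid-body
motion of the frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_io import CVSeries, HingedynError, Trajectory

__all__ = [
    "VirtualAtomSpec",
    "DescriptorSpec",
    "DegenerateGeometryError",
    "geometric_center",
    "opening_angle",
    "twist_distance",
    "loop_distance",
    "hbond_count",
    "descriptor_series",
    "standard_hinge_descriptors",
]

#: default hydrogen-bond criterion: donor-acceptor distance cutoff (nm) and
#: maximum deviation of the D-H...A angle from linearity (degrees).
HBOND_D_CUT = 0.35
HBOND_ANGLE_CUT = 30.0

_MIN_SEPARATION = 1e-9  # nm; below this two virtual atoms are "coincident"


class DegenerateGeometryError(HingedynError):
    """Virtual-atom construction is geometrically degenerate."""


@dataclass(frozen=True)
class VirtualAtomSpec:
    """A named pseudo-particle at the geometric center of an atom group."""

    name: str
    members: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"virtual atom {self.name!r} has no members")

    def position(self, frame: np.ndarray) -> np.ndarray:
        return geometric_center(frame, self.members)


def geometric_center(frame: np.ndarray, indices: Sequence[int]) -> np.ndarray:
    """Unweighted mean position (nm) of ``indices`` in a (n_atoms, 3) frame."""
    indices = list(indices)
    if not indices:
        raise ValueError("geometric_center needs at least one atom index")
    frame = np.asarray(frame, dtype=float)
    if min(indices) < 0 or max(indices) >= frame.shape[0]:
        raise IndexError(
            f"atom index out of range for frame with {frame.shape[0]} atoms"
        )
    return frame[indices].mean(axis=0)


def opening_angle(
    frame: np.ndarray,
    arm_a: VirtualAtomSpec,
    vertex: VirtualAtomSpec,
    arm_b: VirtualAtomSpec,
) -> float:
    """Hinge opening angle in degrees, in [0, 180].

    The angle at the ``vertex`` center (the disulfide cluster) between the
    vectors pointing to the two arm centers (the per-chain C5a/C8a
    midpoints).  The normalized dot product is clamped to [-1, 1] before
    arccos so exactly collinear arms report 180 (or 0) rather than NaN.
    """
    v = vertex.position(frame)
    u1 = arm_a.position(frame) - v
    u2 = arm_b.position(frame) - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 < _MIN_SEPARATION or n2 < _MIN_SEPARATION:
        raise DegenerateGeometryError(
            "an arm center coincides with the vertex center"
        )
    cosang = float(np.dot(u1, u2) / (n1 * n2))
    cosang = max(-1.0, min(1.0, cosang))
    return math.degrees(math.acos(cosang))


def twist_distance(
    frame: np.ndarray, group_a: Sequence[int], group_b: Sequence[int]
) -> float:
    """Distance (nm) between the geometric centers of two groups."""
    ca = geometric_center(frame, group_a)
    cb = geometric_center(frame, group_b)
    return float(np.linalg.norm(ca - cb))


def loop_distance(frame: np.ndarray, g7a_index: int, g7b_index: int) -> float:
    """G7-G7' alpha-carbon distance (nm)."""
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    for idx in (g7a_index, g7b_index):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range (n_atoms={n})")
    return float(np.linalg.norm(frame[g7a_index] - frame[g7b_index]))


def hbond_count(
    frame: np.ndarray,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    d_cut: float = HBOND_D_CUT,
    angle_cut: float = HBOND_ANGLE_CUT,
) -> int:
    """Count donor/acceptor pairs forming a hydrogen bond.

    A (D-heavy, H) donor and acceptor A count when the D...A distance is
    <= ``d_cut`` (nm) and the D-H...A angle is within ``angle_cut`` degrees
    of linear (i.e. >= 180 - angle_cut).  Each (donor, acceptor) pair is
    counted at most once; geometric criteria only, no chemistry.
    """
    if d_cut <= 0:
        raise ValueError("d_cut must be > 0")
    frame = np.asarray(frame, dtype=float)
    count = 0
    min_angle = 180.0 - angle_cut
    for d_idx, h_idx in donors:
        d = frame[d_idx]
        h = frame[h_idx]
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx):
                continue
            a = frame[a_idx]
            if np.linalg.norm(d - a) > d_cut:
                continue
            u = d - h
            v = a - h
            nu = np.linalg.norm(u)
            nv = np.linalg.norm(v)
            if nu < _MIN_SEPARATION or nv < _MIN_SEPARATION:
                continue
            cosang = max(-1.0, min(1.0, float(np.dot(u, v) / (nu * nv))))
            if math.degrees(math.acos(cosang)) >= min_angle:
                count += 1
    return count


# ---------------------------------------------------------------------------
# descriptor plumbing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorSpec:
    """One named descriptor evaluated per frame.

    kind is one of "opening_angle" (groups = arm_a, vertex, arm_b),
    "twist_distance" (groups = group_a, group_b), "loop_distance"
    (groups = two single-atom groups).
    """

    name: str
    kind: str
    groups: tuple[tuple[int, ...], ...]

    def unit(self) -> str:
        return "deg" if self.kind == "opening_angle" else "nm"

    def evaluate(self, frame: np.ndarray) -> float:
        if self.kind == "opening_angle":
            ga, gv, gb = self.groups
            return opening_angle(
                frame,
                VirtualAtomSpec("arm_a", ga),
                VirtualAtomSpec("vertex", gv),
                VirtualAtomSpec("arm_b", gb),
            )
        if self.kind == "twist_distance":
            ga, gb = self.groups
            return twist_distance(frame, ga, gb)
        if self.kind == "loop_distance":
            ga, gb = self.groups
            if len(ga) != 1 or len(gb) != 1:
                raise ValueError("loop_distance needs two single-atom groups")
            return loop_distance(frame, ga[0], gb[0])
        raise ValueError(f"unknown descriptor kind {self.kind!r}")


def descriptor_series(
    trajectory: Trajectory, specs: Sequence[DescriptorSpec]
) -> CVSeries:
    """Evaluate descriptors frame by frame into a CVSeries."""
    if not specs:
        raise ValueError("no descriptors given")
    values = np.empty((trajectory.n_frames, len(specs)))
    for f, frame in enumerate(trajectory.coords):
        for j, spec in enumerate(specs):
            try:
                values[f, j] = spec.evaluate(frame)
            except HingedynError as exc:
                raise type(exc)(
                    f"descriptor {spec.name!r} failed at frame {f}: {exc}"
                ) from exc
    return CVSeries(
        names=[s.name for s in specs],
        units=[s.unit() for s in specs],
        times=trajectory.times.copy(),
        values=values,
    )


def standard_hinge_descriptors(trajectory: Trajectory) -> list[DescriptorSpec]:
    """The standard hinge descriptor set resolved against the named groups.

    Requires the standard groups built by :func:`~hingedyn.model_io.read_pdb`
    (or the synthetic generator): opening angle from c5c8 midpoints and the
    sulfur cluster, W-W' twist distance, and the G7-G7' loop distance.
    """
    groups = trajectory.topology.groups
    needed = ("c5c8_A", "c5c8_B", "sulfur_cluster", "trpA", "trpB",
              "g7_A", "g7_B")
    missing = [g for g in needed if g not in groups]
    if missing:
        raise HingedynError(
            f"topology lacks standard hinge groups: {missing}"
        )
    g = {k: tuple(groups[k]) for k in needed}
    return [
        DescriptorSpec(
            "opening_angle",
            "opening_angle",
            (g["c5c8_A"], g["sulfur_cluster"], g["c5c8_B"]),
        ),
        DescriptorSpec("ww_distance", "twist_distance", (g["trpA"], g["trpB"])),
        DescriptorSpec(
            "loop_distance", "loop_distance", (g["g7_A"], g["g7_B"])
        ),
    ]
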