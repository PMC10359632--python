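"""Dihedral kinematics: transform chains mapping chi vectors to coordinates.

Every side-chain atom position is expressed as a product of homogeneous
4x4 matrices: constant frame changes that align each rotatable chi bond
with a local Z axis, interleaved with Z rotations by the change of the
corresponding chi angle, and a closing transform back to the world frame,

    p' = C0 . Rz(d1) . C1 . Rz(d2) ... C_{j-1} . Rz(dj) . Cj . p

where ``di`` is the offset of chi_i from its value measured in the input
coordinates and the constant segments ``Ci`` are pre-multiplied once per
residue.  Rotations are rigid, so bond lengths and angles inside the side
chain are exact invariants of any chi change.

Angles are degrees at every interface (radians internally); the frame
convention is proximal-to-distal, +Z along the rotated bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .topology import SideChainTopology

__all__ = [
    "KinematicsError",
    "measure_dihedral",
    "TransformChain",
    "build_transform_chain",
    "evaluate_coordinates",
]

_EPS = 1e-10


class KinematicsError(ValueError):
    """Raised for degenerate geometry or dimension mismatches."""


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from p2 towards p3, a positive angle is
    a clockwise rotation of the p3->p4 bond relative to the p2->p1 bond.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < _EPS:
            raise KinematicsError("consecutive dihedral points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise KinematicsError("three consecutive dihedral points are collinear")
    angle = math.degrees(math.atan2(
        float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))),
        float(np.dot(n1, n2))))
    if angle <= -180.0:
        angle += 360.0
    return angle


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def _rz(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    m = np.eye(4)
    m[0, 0], m[0, 1] = c, -s
    m[1, 0], m[1, 1] = s, c
    return m


def _frame_matrix(origin, z_target, x_ref) -> np.ndarray:
    """World-from-local transform with +Z towards z_target, X towards x_ref."""
    origin = np.asarray(origin, dtype=float)
    z = np.asarray(z_target, dtype=float) - origin
    nz = np.linalg.norm(z)
    if nz < _EPS:
        raise KinematicsError("degenerate rotation axis (zero-length bond)")
    z = z / nz
    x = np.asarray(x_ref, dtype=float) - origin
    x = x - np.dot(x, z) * z
    nx = np.linalg.norm(x)
    if nx < _EPS:
        raise KinematicsError("frame reference atom is collinear with the axis")
    x = x / nx
    y = np.cross(z, x)
    m = np.eye(4)
    m[:3, 0], m[:3, 1], m[:3, 2], m[:3, 3] = x, y, z, origin
    return m


def _inverse_rigid(m: np.ndarray) -> np.ndarray:
    inv = np.eye(4)
    rot = m[:3, :3].T
    inv[:3, :3] = rot
    inv[:3, 3] = -rot @ m[:3, 3]
    return inv


@dataclass
class TransformChain:
    """Cached matrix pipeline from a chi vector to side-chain coordinates."""

    topo: SideChainTopology
    initial_chi: tuple[float, ...]
    frames: list[np.ndarray]             # world-from-local, one per chi
    segments: list[np.ndarray]           # pre-multiplied constant products
    closings: list[np.ndarray]           # per level: inverse of that frame
    fixed_coords: dict[str, np.ndarray]  # level-0 side-chain atoms
    initial_moving: dict[str, np.ndarray]
    levels: dict[str, int]

    @property
    def n_chi(self) -> int:
        return len(self.frames)

    def evaluate(self, chi_deg, up_to: int | None = None,
                 cached: bool = True) -> dict[str, np.ndarray]:
        """Side-chain coordinates for a chi vector (degrees).

        With ``up_to=j`` only atoms governed by chi_1..chi_j (and the fixed
        level-0 atoms) are returned; the chi vector may then be a length-j
        prefix.  ``cached=False`` recomposes the constant segments from the
        stored frames instead of using the pre-multiplied products (the two
        paths agree to rounding).
        """
        k = self.n_chi
        limit = k if up_to is None else up_to
        if not 0 <= limit <= k:
            raise KinematicsError(f"level {up_to} out of range for {k} chi angles")
        chi = [float(c) for c in chi_deg]
        if len(chi) < limit or (up_to is None and len(chi) != k):
            raise KinematicsError(
                f"expected {k if up_to is None else up_to} chi values, "
                f"got {len(chi)}")

        out = {name: pos.copy() for name, pos in self.fixed_coords.items()}
        if limit == 0:
            return out

        deltas = [math.radians(chi[i] - self.initial_chi[i])
                  for i in range(limit)]
        if cached:
            segments = self.segments
        else:
            segments = [self.frames[0]]
            for i in range(1, k):
                segments.append(_inverse_rigid(self.frames[i - 1]) @ self.frames[i])

        # running product through level j, closed per level on demand
        prefix = segments[0] @ _rz(deltas[0])
        transforms = {1: prefix @ self.closings[0]}
        for j in range(2, limit + 1):
            prefix = prefix @ segments[j - 1] @ _rz(deltas[j - 1])
            transforms[j] = prefix @ self.closings[j - 1]

        for name, level in self.levels.items():
            if level > limit:
                continue
            p0 = self.initial_moving[name]
            p = transforms[level] @ np.append(p0, 1.0)
            out[name] = p[:3]
        return out


def build_transform_chain(coords: dict[str, np.ndarray],
                          topo: SideChainTopology) -> TransformChain:
    """Build the cached matrix chain from measured input coordinates."""
    frames = []
    initial_chi = []
    for quad in topo.chi_defs:
        pts = []
        for name in quad:
            if name not in coords:
                raise KinematicsError(
                    f"missing atom {name!r} required by a chi definition of "
                    f"{topo.comp_id}")
            pts.append(np.asarray(coords[name], dtype=float))
        initial_chi.append(measure_dihedral(*pts))
        # rotation axis = the chi bond, proximal (quad[1]) -> distal (quad[2])
        frames.append(_frame_matrix(pts[1], pts[2], pts[0]))

    segments = [frames[0]]
    for i in range(1, len(frames)):
        segments.append(_inverse_rigid(frames[i - 1]) @ frames[i])
    closings = [_inverse_rigid(f) for f in frames]

    fixed, moving, levels = {}, {}, {}
    for name, level in topo.build_order:
        if name not in coords:
            raise KinematicsError(
                f"missing side-chain atom {name!r} of {topo.comp_id}")
        pos = np.asarray(coords[name], dtype=float)
        if level == 0:
            fixed[name] = pos.copy()
        else:
            moving[name] = pos.copy()
            levels[name] = level

    return TransformChain(
        topo=topo, initial_chi=tuple(initial_chi), frames=frames,
        segments=segments, closings=closings, fixed_coords=fixed,
        initial_moving=moving, levels=levels)


def evaluate_coordinates(chain: TransformChain, chi_deg) -> dict[str, np.ndarray]:
    """Coordinates of every side-chain atom at the given chi vector."""
    return chain.evaluate(chi_deg)
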