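"""Deterministic, evenly distributed rotation sampling.

The orientation set is the product of a spherical lattice of rotation-axis
directions with a uniform sweep of in-plane spin angles: for an angular
interval ``delta`` the number of axis directions is ``floor(4*pi/delta_rad**2)``
(placed by a generalized spiral starting at the +z pole) and each direction is
combined with ``round(360/delta)`` spin angles in uniform steps from 0.  The
first element is always the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nucdock.errors import ContractViolation


@dataclass(frozen=True)
class RotationSet:
    """Ordered set of proper rotation matrices at angular interval ``delta``."""

    delta: float
    rotations: np.ndarray  # (n, 3, 3)

    def __len__(self) -> int:
        return len(self.rotations)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.rotations[i]

    def to_text(self) -> str:
        """One rotation per line: 9 row-major matrix entries."""
        lines = [
            " ".join(f"{v:.17g}" for v in R.ravel()) for R in self.rotations
        ]
        return "\n".join(lines) + "\n"


def _sphere_lattice(n: int) -> np.ndarray:
    """n unit vectors by the generalized spiral, first point = +z pole."""
    points = np.zeros((n, 3))
    if n == 1:
        points[0] = (0.0, 0.0, 1.0)
        return points
    phi = 0.0
    for k in range(n):
        h = 1.0 - 2.0 * k / (n - 1)
        theta = np.arccos(np.clip(h, -1.0, 1.0))
        if k == 0 or k == n - 1:
            phi = 0.0
        else:
            phi = phi + 3.6 / np.sqrt(n * (1.0 - h * h))
        points[k] = (
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        )
    return points


def _rotation_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _align_z_to(u: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking +z onto unit vector u."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, u))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, u)
    axis /= np.linalg.norm(axis)
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def generate_rotations(delta_deg: float) -> RotationSet:
    """Evenly distributed rotations at angular interval ``delta_deg`` degrees.

    Count law: ``floor(4*pi/delta_rad**2) * round(360/delta_deg)``; at 15
    degrees this yields 183 * 24 = 4392 rotations.  Fully deterministic.
    """
    if not (0.0 < delta_deg <= 120.0):
        raise ContractViolation(
            f"angle interval must be in (0, 120] degrees, got {delta_deg}"
        )
    delta_rad = np.deg2rad(delta_deg)
    n_sphere = int(np.floor(4.0 * np.pi / delta_rad**2))
    n_spin = int(round(360.0 / delta_deg))
    axes = _sphere_lattice(n_sphere)
    spin_step = 2.0 * np.pi / n_spin
    rotations = np.empty((n_sphere * n_spin, 3, 3))
    i = 0
    for u in axes:
        A = _align_z_to(u)
        for s in range(n_spin):
            rotations[i] = A @ _rotation_z(s * spin_step)
            i += 1
    # lattice point 0 is the pole with spin 0 -> exact identity
    rotations[0] = np.eye(3)
    return RotationSet(delta=delta_deg, rotations=rotations)


def rotation_angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Geodesic angle (degrees) between two proper rotations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for M in (a, b):
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8) or np.linalg.det(M) < 0:
            raise ContractViolation("input is not a proper rotation matrix")
    t = np.trace(a.T @ b)
    return float(np.degrees(np.arccos(np.clip((t - 1.0) / 2.0, -1.0, 1.0))))
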