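"""Shared containers and geometry primitives.

Conventions used throughout the package:

* Volumes are cubic ``(N, N, N)`` float arrays indexed ``(z, y, x)`` with the
  helix axis along ``z``.  ``N`` is even and voxel centers sit at integer
  indices; the rotation/geometry center is ``N / 2`` (the voxel just above the
  geometric middle), which coincides with the DC sample of a centered FFT.
* Euler angles ``(rot, tilt, psi)`` are intrinsic ZYZ in degrees with matrix
  ``R = Rz(psi) @ Ry(tilt) @ Rz(rot)``.  A projection image of a volume ``V``
  at this pose is the z-sum of ``V`` actively rotated by ``R``; ``psi`` is the
  in-plane angle, ``rot`` the angle about the reference (helix) axis, and
  helical side views have ``tilt`` near 90 degrees.
* Right-handed axes; a positive helical twist advances counterclockwise
  (viewed from +z) while climbing +z.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


@dataclass
class VolumeGrid:
    """Cubic 3D density with a physical voxel size.

    Parameters
    ----------
    data:
        ``(N, N, N)`` array, indexed ``(z, y, x)``; stored as float32.
    voxel_size:
        Edge length of one voxel in Angstrom.
    """

    data: np.ndarray
    voxel_size: float
    origin: str = "center"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.data.shape}")
        if self.data.shape[0] % 2 != 0:
            raise ValueError(f"grid side must be even, got {self.data.shape[0]}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def box_angstrom(self) -> float:
        return self.n * self.voxel_size

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.voxel_size, self.origin)

    def like(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(np.asarray(data, dtype=np.float32), self.voxel_size, self.origin)


def euler_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Rotation matrix Rz(psi) @ Ry(tilt) @ Rz(rot) acting on xyz vectors.

    ``rot`` is applied first (about the reference/helix z axis), then the
    out-of-plane ``tilt``, then the in-plane ``psi`` about the beam axis, so
    composing a pose with an extra reference-frame z rotation phi yields the
    pose (rot + phi, tilt, psi).
    """
    return Rotation.from_euler("ZYZ", [psi, tilt, rot], degrees=True).as_matrix()


def rot_z(angle_deg: float) -> np.ndarray:
    return Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()


# index axes are (z, y, x); J converts xyz-convention matrices to index space
_J = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


def affine_volume(
    data: np.ndarray,
    rotation: np.ndarray,
    translation_xyz: tuple[float, float, float] = (0.0, 0.0, 0.0),
    order: int = 1,
    with_weight: bool = False,
):
    """Apply the active rigid transform ``p -> R p + t`` about the grid center.

    Trilinear interpolation by default; out-of-bounds samples are zero.  With
    ``with_weight=True`` also returns the transformed all-ones volume, i.e. the
    in-bounds coverage weight, which callers use for edge-aware averaging.
    """
    data = np.asarray(data, dtype=np.float64)
    n = data.shape[0]
    c = np.array([n / 2.0] * 3)
    t = np.asarray(translation_xyz, dtype=float)[::-1]  # to (z, y, x)
    m = _J @ rotation.T @ _J  # inverse rotation in index space
    offset = c - m @ (c + t)
    out = ndimage.affine_transform(data, m, offset=offset, order=order, mode="constant", cval=0.0)
    if not with_weight:
        return out
    w = ndimage.affine_transform(np.ones_like(data), m, offset=offset, order=order,
                                 mode="constant", cval=0.0)
    return out, w


def rotate_volume(data: np.ndarray, rotation: np.ndarray, order: int = 1) -> np.ndarray:
    """Actively rotate a volume about its center."""
    return affine_volume(data, rotation, (0.0, 0.0, 0.0), order=order)


def helical_operator(twist_deg: float, rise_voxels: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and xyz translation for one application of (twist, rise)."""
    return rot_z(twist_deg), np.array([0.0, 0.0, rise_voxels])


def correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two arrays of identical shape."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("correlation undefined for a constant array")
    return float(np.dot(a, b) / denom)


def nrmse(result: np.ndarray, reference: np.ndarray) -> float:
    """Normalized RMS error of ``result`` against ``reference``."""
    result = np.asarray(result, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    scale = np.sqrt(np.mean(reference**2))
    if scale == 0:
        return float(np.sqrt(np.mean(result**2)))
    return float(np.sqrt(np.mean((result - reference) ** 2)) / scale)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream fanned out from one top-level seed.

    The stream identity depends only on ``(seed, name)``, so modules seeded
    from the same top-level seed are independently reproducible.
    """
    key = zlib.crc32(name.encode("utf-8")) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


@dataclass
class HelicalLattice:
    """Helical symmetry parameters: twist (deg/unit), rise (Å/unit), point group."""

    twist: float
    rise: float
    point_group: str = "C1"
    n_units: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.twist < 360:
            raise ValueError(f"twist must be in (0, 360), got {self.twist}")
        if not self.rise > 0:
            raise ValueError(f"rise must be positive, got {self.rise}")
        if self.point_group not in ("C1", "D1"):
            raise ValueError(f"point_group must be C1 or D1, got {self.point_group}")
        if self.n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {self.n_units}")

    @property
    def pitch(self) -> float:
        """Axial length of one full turn, rise * 360 / twist, in Å."""
        return self.rise * 360.0 / self.twist
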