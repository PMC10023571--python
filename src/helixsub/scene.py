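"""Synthetic protomers, variable-pitch filaments and ground-truth datasets.

The generator emulates the statistical structure of a helical polymer of
D1-symmetric protomers stacked with a twist near 47 degrees and a rise near
26.75 Å, where the pitch may vary within or between filaments ("slinky"
flexibility).  Protomers are sums of isotropic 3D Gaussians, so volumes and
projections have closed forms: rendering evaluates the Gaussians on the
grid and a projection of a Gaussian blob is again a Gaussian.  This keeps
the simulator analytically exact and independent of the Fourier-slice
machinery it is later used to test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import VolumeGrid, euler_matrix, rot_z, substream
from .optics import CTFParams, add_noise, ctf_image


@dataclass
class ProtomerModel:
    """Repeating unit modeled as isotropic Gaussian blobs.

    ``blobs`` is a list of ``(center_xyz_angstrom, sigma_angstrom, weight)``.
    With ``point_group="D1"`` the blob set must be exactly invariant under a
    180-degree rotation about the x axis (the designated in-plane two-fold).
    """

    blobs: list[tuple[np.ndarray, float, float]]
    point_group: str = "D1"

    def __post_init__(self) -> None:
        self.blobs = [(np.asarray(c, dtype=float), float(s), float(w)) for c, s, w in self.blobs]
        for i, (_, sigma, _) in enumerate(self.blobs):
            if not sigma > 0:
                raise ValueError(f"blob {i} has non-positive sigma {sigma}")
        if self.point_group not in ("C1", "D1"):
            raise ValueError(f"point_group must be C1 or D1, got {self.point_group}")
        if self.point_group == "D1" and not self._is_d1():
            raise ValueError("blob set is not invariant under the D1 two-fold (x axis)")

    def _is_d1(self, tol: float = 1e-6) -> bool:
        flip = np.diag([1.0, -1.0, -1.0])
        targets = [(flip @ c, s, w) for c, s, w in self.blobs]
        used = set()
        for c, s, w in targets:
            hit = None
            for j, (c2, s2, w2) in enumerate(self.blobs):
                if j in used:
                    continue
                if np.allclose(c, c2, atol=tol) and abs(s - s2) < tol and abs(w - w2) < tol:
                    hit = j
                    break
            if hit is None:
                return False
            used.add(hit)
        return True

    @property
    def support_radius(self) -> float:
        """Radius (Å) containing every blob out to 3 sigma."""
        return max(float(np.linalg.norm(c)) + 3.0 * s for c, s, _ in self.blobs)

    def mirrored(self) -> "ProtomerModel":
        """Mirror image (x -> -x): opposite chirality, same point group."""
        flip = np.diag([-1.0, 1.0, 1.0])
        return ProtomerModel([(flip @ c, s, w) for c, s, w in self.blobs], self.point_group)


def default_protomer(point_group: str = "D1") -> ProtomerModel:
    """Reference toy protomer: five blobs, D1 about x, chiral otherwise.

    One blob sits on the two-fold axis and two asymmetric pairs straddle it,
    so the only self-mapping rotation is the declared two-fold.  Blob centers
    are spread and sigmas kept moderate so the density is distinguishable
    from its mirror image (chiral) and from rotated copies of itself.
    """
    axis_blob = (np.array([10.0, 0.0, 0.0]), 6.0, 1.2)
    pair_a = (np.array([-12.0, 9.0, 5.0]), 6.0, 1.0)
    pair_b = (np.array([4.0, -14.0, 11.0]), 5.0, 0.8)
    flip = np.diag([1.0, -1.0, -1.0])
    blobs = [axis_blob, pair_a, (flip @ pair_a[0], *pair_a[1:]),
             pair_b, (flip @ pair_b[0], *pair_b[1:])]
    if point_group == "C1":
        # break the two-fold by perturbing one partner
        c, s, w = blobs[2]
        blobs[2] = (c + np.array([0.0, 3.0, 2.0]), s, w)
    return ProtomerModel(blobs, point_group)


def build_protomer(protomer: ProtomerModel, n: int, voxel_size: float) -> VolumeGrid:
    """Render a protomer onto a cubic grid by evaluating its Gaussians.

    Raises if any blob (at 3 sigma) falls outside the grid, naming the blob.
    """
    half = n * voxel_size / 2.0
    for i, (c, s, _) in enumerate(protomer.blobs):
        if np.any(np.abs(c) + 3.0 * s > half):
            raise ValueError(
                f"blob {i} at {c} with sigma {s} exceeds the grid half-width {half:.1f} A"
            )
    data = _eval_blobs([(c, s, w) for c, s, w in protomer.blobs], n, voxel_size)
    return VolumeGrid(data, voxel_size)


def _eval_blobs(blobs, n: int, voxel_size: float) -> np.ndarray:
    """Sum of isotropic Gaussians on an (n, n, n) grid, centers in Å."""
    coords = (np.arange(n) - n / 2.0) * voxel_size
    out = np.zeros((n, n, n), dtype=np.float64)
    for c, sigma, w in blobs:
        cx, cy, cz = c
        gz = np.exp(-((coords - cz) ** 2) / (2 * sigma**2))
        gy = np.exp(-((coords - cy) ** 2) / (2 * sigma**2))
        gx = np.exp(-((coords - cx) ** 2) / (2 * sigma**2))
        out += w * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return out


@dataclass
class PitchProfile:
    """Per-step helical parameters along one filament.

    ``per_unit`` has shape ``(n_units - 1, 2)`` with columns (twist_deg,
    rise_angstrom): entry i is the step from unit i to unit i+1.
    """

    per_unit: np.ndarray
    mode: str
    twist_range: tuple[float, float]
    rise_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.per_unit = np.atleast_2d(np.asarray(self.per_unit, dtype=float))
        if self.per_unit.shape[1] != 2:
            raise ValueError("per_unit must have two columns (twist, rise)")
        t, r = self.per_unit[:, 0], self.per_unit[:, 1]
        eps = 1e-9
        if np.any(t < self.twist_range[0] - eps) or np.any(t > self.twist_range[1] + eps):
            raise ValueError("twist values outside configured range")
        if np.any(r < self.rise_range[0] - eps) or np.any(r > self.rise_range[1] + eps):
            raise ValueError("rise values outside configured range")

    @property
    def n_units(self) -> int:
        return self.per_unit.shape[0] + 1


def sample_pitch_profile(
    twist_range: tuple[float, float],
    rise_range: tuple[float, float],
    mode: str,
    n_units: int,
    rng: np.random.Generator,
    walk_step_fraction: float = 0.3,
) -> PitchProfile:
    """Draw a per-filament pitch profile.

    Modes: ``constant`` (range midpoints, no randomness), ``per_filament``
    (one uniform draw per filament applied to every step) and ``random_walk``
    (reflected uniform-step walk within the ranges, modeling the
    intra-filament spring-like flexibility; adjacent units may differ by up
    to ``walk_step_fraction`` of the full observed range).
    """
    if n_units < 2:
        raise ValueError("a pitch profile needs at least 2 units")
    for lo, hi, name in [(*twist_range, "twist"), (*rise_range, "rise")]:
        if lo > hi:
            raise ValueError(f"{name} range has min > max")
    n_steps = n_units - 1
    if mode == "constant":
        t = np.full(n_steps, np.mean(twist_range))
        r = np.full(n_steps, np.mean(rise_range))
    elif mode == "per_filament":
        t = np.full(n_steps, rng.uniform(*twist_range))
        r = np.full(n_steps, rng.uniform(*rise_range))
    elif mode == "random_walk":
        t = _reflected_walk(twist_range, n_steps, rng, walk_step_fraction)
        r = _reflected_walk(rise_range, n_steps, rng, walk_step_fraction)
    else:
        raise ValueError(f"unknown pitch mode {mode!r}")
    return PitchProfile(np.column_stack([t, r]), mode, tuple(twist_range), tuple(rise_range))


def _reflected_walk(bounds, n, rng, step_fraction):
    lo, hi = bounds
    if hi == lo:
        return np.full(n, lo)
    step = step_fraction * (hi - lo)
    x = rng.uniform(lo, hi)
    out = np.empty(n)
    for i in range(n):
        out[i] = x
        x = x + rng.uniform(-step, step)
        # reflect at the boundaries
        while x < lo or x > hi:
            if x < lo:
                x = 2 * lo - x
            if x > hi:
                x = 2 * hi - x
    return out


@dataclass
class PlacedUnits:
    """A filament as a list of rigid placements of one protomer.

    Unit k sits at azimuth ``phi_k`` (cumulative twist) and height ``z_k``
    (cumulative rise) on a cylinder of the given radius, rotated by
    ``Rz(phi_k)`` so its D1 two-fold stays radial.  The middle unit is
    centered at (phi, z) = (0, 0).
    """

    protomer: ProtomerModel
    radius: float
    phi: np.ndarray  # degrees, per unit
    z: np.ndarray  # Å, per unit
    center_unit: int

    @property
    def n_units(self) -> int:
        return len(self.phi)

    def unit_center(self, k: int) -> np.ndarray:
        """3D center (Å) of unit k's protomer origin."""
        return rot_z(self.phi[k]) @ np.array([self.radius, 0.0, 0.0]) + np.array(
            [0.0, 0.0, self.z[k]]
        )

    def blob_list(self, units: list[int] | None = None):
        """All blobs of the selected units, transformed to the filament frame."""
        out = []
        for k in units if units is not None else range(self.n_units):
            rk = rot_z(self.phi[k])
            ck = self.unit_center(k)
            for c, s, w in self.protomer.blobs:
                out.append((rk @ c + ck, s, w))
        return out


def assemble_filament(
    protomer: ProtomerModel, profile: PitchProfile, radius: float = 45.0
) -> PlacedUnits:
    """Stack protomer placements along a helix following a pitch profile."""
    n_units = profile.n_units
    phi = np.concatenate([[0.0], np.cumsum(profile.per_unit[:, 0])])
    z = np.concatenate([[0.0], np.cumsum(profile.per_unit[:, 1])])
    center = n_units // 2
    phi = phi - phi[center]
    z = z - z[center]
    return PlacedUnits(protomer, radius, phi, z, center)


def render_volume(
    placed: PlacedUnits, n: int, voxel_size: float, units: list[int] | None = None,
    clip_tolerance: float = 0.05,
) -> VolumeGrid:
    """Render (a subset of) a placed-unit model onto a cubic grid.

    Density is the analytic sum of all transformed blobs.  Units whose blobs
    extend beyond the grid trigger a warning reporting the clipped fraction
    of blobs when it exceeds ``clip_tolerance``.
    """
    blobs = placed.blob_list(units)
    half = n * voxel_size / 2.0
    clipped = sum(1 for c, s, _ in blobs if np.any(np.abs(c) + 3.0 * s > half))
    if clipped / max(len(blobs), 1) > clip_tolerance:
        warnings.warn(
            f"{clipped}/{len(blobs)} blobs clip the grid "
            f"({clipped / len(blobs):.0%} > {clip_tolerance:.0%} tolerance)",
            stacklevel=2,
        )
    return VolumeGrid(_eval_blobs(blobs, n, voxel_size), voxel_size)


def project_analytic(
    blobs,
    pose: tuple[float, float, float],
    n: int | tuple[int, int],
    voxel_size: float,
    shift_px: tuple[float, float] = (0.0, 0.0),
    extra_offset: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form projection image of a blob list at a pose.

    The projection along z of ``w exp(-|r - c|^2 / 2 sigma^2)`` is
    ``w sigma sqrt(2 pi) exp(-rho^2 / 2 sigma^2) / voxel_size`` (the division
    converts the analytic integral to the z-voxel-sum normalization of
    discrete projection operators).  ``extra_offset`` (Å, filament frame) is
    added to every blob center before rotation.  ``n`` may be a single box
    edge or a rectangular (ny, nx) canvas shape.
    """
    rot, tilt, psi = pose
    r = euler_matrix(rot, tilt, psi)
    ny, nx = (n, n) if isinstance(n, int) else n
    coords_y = (np.arange(ny) - ny / 2.0) * voxel_size
    coords_x = (np.arange(nx) - nx / 2.0) * voxel_size
    img = np.zeros((ny, nx), dtype=np.float64)
    sx, sy = shift_px[0] * voxel_size, shift_px[1] * voxel_size
    for c, sigma, w in blobs:
        c = np.asarray(c, dtype=float)
        if extra_offset is not None:
            c = c + extra_offset
        p = r @ c
        amp = w * sigma * np.sqrt(2.0 * np.pi) / voxel_size
        gy = np.exp(-((coords_y - (p[1] + sy)) ** 2) / (2 * sigma**2))
        gx = np.exp(-((coords_x - (p[0] + sx)) ** 2) / (2 * sigma**2))
        img += amp * gy[:, None] * gx[None, :]
    return img


# --- dataset simulation ---------------------------------------------------

DEFAULT_CONFIG: dict = {
    "n_filaments": 24,
    # long filaments: the emulated dataset averaged ~25 segments per picked
    # filament, so filament ends contribute little to either route
    "units_per_filament": 24,
    "edge_margin_units": 4,
    "box_px": 72,
    "pixel_size_angstrom": 3.0,
    "radius_angstrom": 45.0,
    "twist_range_deg": (46.9, 47.7),
    "rise_range_angstrom": (25.2, 28.2),
    "pitch_mode": "random_walk",
    "snr": 0.1,
    "ctf": True,
    "defocus_range_um": (1.0, 2.5),
    "voltage_kv": 300.0,
    "cs_mm": 2.7,
    "amplitude_contrast": 0.1,
    "shift_jitter_px": 2,  # integer boxing jitter along/across the trace
    "y_jitter_px": 1.5,  # sub-pixel offset of the filament from the trace
    "point_group": "D1",
}


@dataclass
class SimulatedDataset:
    """Segment stack plus ground truth from one simulator run."""

    stack: np.ndarray  # (n_segments, box, box) float32
    table: pd.DataFrame  # one row per segment, every ground-truth field
    protomer: ProtomerModel
    config: dict
    filaments: list[PlacedUnits] = field(default_factory=list)

    @property
    def pixel_size(self) -> float:
        return self.config["pixel_size_angstrom"]


def simulate_dataset(config: dict | None = None, seed: int = 0) -> SimulatedDataset:
    """Simulate extracted filament segments with full ground truth.

    Each filament is imaged once onto a noisy canvas strip (its in-plane
    direction defines the canvas x axis) and overlapping boxes are cropped at
    every interior unit's helix-axis position, the way ``--helix`` extraction
    walks a trace at one-rise steps.  Because the boxes come from one canvas,
    overlapping segments share micrograph noise — the statistical structure
    that makes filament-aware half-set splitting necessary.  CTF (one defocus
    per filament) acts on the canvas; noise is white Gaussian at the
    requested SNR relative to in-mask signal variance.  Regenerating with the
    same seed is bit-identical.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)

    protomer = default_protomer(cfg["point_group"])
    rng_pitch = substream(seed, "pitch")
    rng_pose = substream(seed, "pose")
    rng_defocus = substream(seed, "defocus")
    rng_noise = substream(seed, "noise")

    n = int(cfg["box_px"])
    vox = float(cfg["pixel_size_angstrom"])
    n_units = int(cfg["units_per_filament"])
    margin = int(cfg["edge_margin_units"])
    if n_units - 2 * margin < 1:
        raise ValueError("edge margin leaves no interior units to extract")
    jmax = int(cfg["shift_jitter_px"])

    images, rows, filaments = [], [], []
    for fid in range(int(cfg["n_filaments"])):
        profile = sample_pitch_profile(
            cfg["twist_range_deg"], cfg["rise_range_angstrom"], cfg["pitch_mode"],
            n_units, rng_pitch,
        )
        placed = assemble_filament(protomer, profile, cfg["radius_angstrom"])
        filaments.append(placed)
        blobs = placed.blob_list()
        rot0 = rng_pose.uniform(0.0, 360.0)
        tilt = 90.0
        y0 = rng_pose.uniform(-cfg["y_jitter_px"], cfg["y_jitter_px"])
        defocus = rng_defocus.uniform(*cfg["defocus_range_um"]) * 1e4  # um -> Å
        ctfp = CTFParams(cfg["voltage_kv"], cfg["cs_mm"], cfg["amplitude_contrast"], defocus)
        steps = profile.per_unit

        # canvas strip: filament axis along x at mid-height, one per filament
        span_px = (placed.z.max() - placed.z.min()) / vox
        width = n + int(np.ceil(span_px)) + 4 * jmax + 16
        height = n + 2 * jmax
        canvas = project_analytic(
            blobs, (rot0, tilt, 0.0), (height, width), vox, shift_px=(0.0, y0)
        )
        if cfg["ctf"]:
            c2d = np.fft.ifftshift(ctf_image(ctfp, (height, width), vox))
            canvas = np.fft.ifft2(np.fft.fft2(canvas) * c2d).real
        if np.isfinite(cfg["snr"]):
            canvas = add_noise(canvas, cfg["snr"], _filament_mask(canvas), rng_noise)

        for k in range(margin, n_units - margin):
            col_k = width / 2.0 + placed.z[k] / vox  # axis position of unit k
            jx = int(rng_pose.integers(-jmax, jmax + 1)) if jmax else 0
            jy = int(rng_pose.integers(-jmax, jmax + 1)) if jmax else 0
            c_int = int(round(col_k)) + jx
            r_int = jmax + jy
            img = canvas[r_int:r_int + n, c_int - n // 2:c_int - n // 2 + n]
            images.append(np.ascontiguousarray(img, dtype=np.float32))
            rows.append({
                "filament_id": fid,
                "unit_index": k,
                # rot at unit k folds in the accumulated twist
                "rot": (rot0 + placed.phi[k]) % 360.0,
                "tilt": tilt,
                "psi": 0.0,
                "psi_prior": 0.0,
                "x": col_k - c_int,  # true axis offset from box center, px
                "y": y0 - jy,
                "defocus": defocus,
                "twist_true": float(np.mean(steps[:, 0])),
                "rise_true": float(np.mean(steps[:, 1])),
            })
    table = pd.DataFrame(rows)
    return SimulatedDataset(np.stack(images), table, protomer, cfg, filaments)


def _filament_mask(noiseless_image: np.ndarray, frac: float = 0.02) -> np.ndarray:
    """Support mask of the noiseless signal (above a small fraction of max)."""
    m = np.abs(noiseless_image)
    return m > frac * m.max()
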