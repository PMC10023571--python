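"""Neighbor signal subtraction and subparticle extraction.

Given an aligned filament-segment stack and a reference map, a mask is built
from the helical geometry covering every protomer except one kept unit (plus
a configurable interface buffer so inter-unit interface density stays with
the kept unit).  The masked reference is projected at each segment's pose,
CTF-modulated, intensity-matched by least squares, and subtracted, leaving
one isolated protomer per segment.  Subparticles are then recentered on the
kept unit, cropped to a smaller box, and given a geometry-corrected defocus
for their beam-axis offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import VolumeGrid, euler_matrix
from .optics import CTFParams, ctf_image, subparticle_defocus
from .scene import PlacedUnits
from .helix import FourierSliceCache, _shift_phase

logger = logging.getLogger(__name__)


@dataclass
class SubtractionMask:
    """Soft [0, 1] mask over the reference grid selecting neighbor density."""

    volume: VolumeGrid
    keep_unit: int
    buffer_angstrom: float
    soft_edge_angstrom: float


def _blob_field(blobs, n: int, voxel_size: float, inner_offset: float, soft: float) -> np.ndarray:
    """Soft union of blob supports: 1 inside 3 sigma + offset, cosine to 0."""
    coords = (np.arange(n) - n / 2.0) * voxel_size
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    out = np.zeros((n, n, n), dtype=np.float64)
    for c, sigma, _ in blobs:
        d = np.sqrt((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
        edge = 3.0 * sigma + inner_offset
        if soft > 0:
            ramp = np.clip((edge + soft - d) / soft, 0.0, 1.0)
            m = 0.5 - 0.5 * np.cos(np.pi * ramp)
        else:
            m = (d <= edge).astype(np.float64)
        np.maximum(out, m, out=out)
    return out


def unit_support_mask(
    protomer, n: int, voxel_size: float,
    buffer_angstrom: float | None = None, soft_edge_angstrom: float = 6.0,
) -> np.ndarray:
    """Soft mask over one protomer's density support (protomer frame, centered).

    This is the kept-unit region of :func:`make_mask`: blob support at 3
    sigma, dilated by the interface buffer (default one mean blob sigma),
    with a raised-cosine edge.  Also used to focus map-vs-truth FSC
    comparisons on the protomer.
    """
    if buffer_angstrom is None:
        buffer_angstrom = float(np.mean([s for _, s, _ in protomer.blobs]))
    return _blob_field(
        [(c, s, w) for c, s, w in protomer.blobs], n, voxel_size,
        buffer_angstrom, soft_edge_angstrom,
    )


def make_mask(
    placed: PlacedUnits,
    n: int,
    voxel_size: float,
    keep_unit: int | None = None,
    buffer_angstrom: float | None = None,
    soft_edge_angstrom: float = 6.0,
) -> SubtractionMask:
    """Build the all-but-one-protomer mask from the filament geometry.

    The mask is ~1 over the density support of every unit except the kept
    one; the kept unit, dilated by the interface buffer (default: one blob
    sigma, keeping interface density intact), is excluded with a raised-
    cosine soft edge.  Raises if the resulting mask is empty.
    """
    if keep_unit is None:
        keep_unit = placed.center_unit
    if not 0 <= keep_unit < placed.n_units:
        raise ValueError(f"keep_unit {keep_unit} outside unit range 0..{placed.n_units - 1}")
    if buffer_angstrom is None:
        buffer_angstrom = float(np.mean([s for _, s, _ in placed.protomer.blobs]))
    others = [k for k in range(placed.n_units) if k != keep_unit]
    neighbor_field = (
        _blob_field(placed.blob_list(others), n, voxel_size, 0.0, soft_edge_angstrom)
        if others else np.zeros((n, n, n))
    )
    kept_field = _blob_field(
        placed.blob_list([keep_unit]), n, voxel_size, buffer_angstrom, soft_edge_angstrom
    )
    mask = neighbor_field * (1.0 - kept_field)
    if others and mask.max() < 1e-3:
        raise ValueError("buffer so large the subtraction mask vanishes")
    return SubtractionMask(
        VolumeGrid(mask, voxel_size), keep_unit, buffer_angstrom, soft_edge_angstrom
    )


def subtract_neighbors(
    segment_image: np.ndarray,
    record: pd.Series,
    reference_map: VolumeGrid,
    mask: SubtractionMask | VolumeGrid,
    ctf: CTFParams | None = None,
    fit_scale: bool = True,
    _cache: FourierSliceCache | None = None,
) -> np.ndarray:
    """Subtract the projected masked reference from one segment image.

    The neighbor model is ``CTF * project(reference * mask)`` at the record's
    pose and shifts, scaled by a least-squares intensity factor fitted inside
    the projected mask support.  With exact poses, reference and mask == 1
    everywhere, the output is ~0; with the all-but-one mask it is the CTF-
    modulated projection of the kept unit alone.
    """
    for key in ("rot", "tilt", "psi"):
        if key not in record or pd.isna(record[key]):
            raise ValueError(f"record lacks an assigned pose ({key})")
    mvol = mask.volume if isinstance(mask, SubtractionMask) else mask
    if _cache is None:
        _cache = FourierSliceCache(reference_map.like(reference_map.data * mvol.data))
    n = segment_image.shape[0]
    s_hat = _cache.slice_hat(euler_matrix(record["rot"], record["tilt"], record["psi"]))
    sx, sy = float(record.get("x", 0.0)), float(record.get("y", 0.0))
    if sx or sy:
        s_hat = s_hat * _shift_phase(n, sx, sy)
    if ctf is not None:
        s_hat = s_hat * ctf_image(ctf, n, reference_map.voxel_size)
    model = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(s_hat))).real
    power = float(np.sum(model**2))
    if power < 1e-12:
        return np.asarray(segment_image, dtype=np.float64).copy()
    scale = 1.0
    if fit_scale:
        scale = float(np.sum(segment_image * model) / power)
    return np.asarray(segment_image, dtype=np.float64) - scale * model


def subtract_stack(
    stack: np.ndarray,
    records: pd.DataFrame,
    reference_map: VolumeGrid,
    mask: SubtractionMask,
    ctf_params: list[CTFParams] | None = None,
    fit_scale: bool = True,
) -> np.ndarray:
    """Vectorized convenience: subtract neighbors from every segment."""
    cache = FourierSliceCache(
        reference_map.like(reference_map.data * mask.volume.data)
    )
    out = np.empty_like(stack, dtype=np.float64)
    for i in range(len(stack)):
        ctf = ctf_params[i] if ctf_params is not None else None
        out[i] = subtract_neighbors(
            stack[i], records.iloc[i], reference_map, mask, ctf, fit_scale, _cache=cache
        )
    return out.astype(np.float32)


def extract_subparticles(
    subtracted_stack: np.ndarray,
    records: pd.DataFrame,
    placed: PlacedUnits,
    crop_box: int,
    pixel_size: float,
    keep_unit: int | None = None,
    defocus_sign_flip: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Recenter each subtracted segment on the kept unit and crop.

    The kept unit's 3D center follows from the lattice geometry and the
    segment pose; its in-plane projection is moved to the box center by a
    sub-pixel Fourier shift, the box is cropped, and the beam-axis component
    corrects the defocus.  One subparticle per segment; segments whose unit
    center projects outside the parent box are dropped (counted in the log).
    """
    n = subtracted_stack.shape[-1]
    if crop_box > n:
        raise ValueError("crop_box must not exceed the parent box")
    if keep_unit is None:
        keep_unit = placed.center_unit
    center_3d = placed.unit_center(keep_unit)  # Å, filament frame
    images, rows, dropped = [], [], 0
    lo = (n - crop_box) // 2
    for i in range(len(subtracted_stack)):
        rec = records.iloc[i]
        r = euler_matrix(rec["rot"], rec["tilt"], rec["psi"])
        p = r @ center_3d  # Å in the image frame; z along the beam
        cx_px = p[0] / pixel_size + float(rec.get("x", 0.0))
        cy_px = p[1] / pixel_size + float(rec.get("y", 0.0))
        if abs(cx_px) > n / 2 - 1 or abs(cy_px) > n / 2 - 1:
            dropped += 1
            continue
        img = subtracted_stack[i].astype(np.float64)
        f = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
        f = f * _shift_phase(n, -cx_px, -cy_px)
        recentered = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(f))).real
        images.append(recentered[lo:lo + crop_box, lo:lo + crop_box].astype(np.float32))
        rows.append({
            "parent_index": int(i),
            "filament_id": int(rec["filament_id"]) if "filament_id" in rec else 0,
            "unit_index": int(keep_unit),
            "rot": float(rec["rot"]) % 360.0,
            "tilt": float(rec["tilt"]),
            "psi": float(rec["psi"]),
            "x": 0.0,
            "y": 0.0,
            "defocus": subparticle_defocus(
                float(rec.get("defocus", 0.0)), float(p[2]), defocus_sign_flip
            ),
        })
    if dropped:
        logger.info("extract_subparticles dropped %d/%d segments (center outside box)",
                    dropped, len(subtracted_stack))
    if not images:
        return np.zeros((0, crop_box, crop_box), dtype=np.float32), pd.DataFrame(rows)
    return np.stack(images), pd.DataFrame(rows)
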