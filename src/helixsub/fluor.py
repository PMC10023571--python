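"""Fluorescence puncta quantification and plate-assay statistics.

Covers the light-microscopy analysis chain for vacuole-associated kinase
condensates: maximum projections over a few z slices, 3D puncta
segmentation into size classes around a 500 nm equivalent-diameter gate,
size-gated Pearson and Manders colocalization, vacuolar-membrane
enrichment, focus-formation kinetics with a model-free half-time, and the
spot-assay relative growth coefficient / EC50 from four ten-fold dilution
series.  A two-channel synthetic stack generator with controlled puncta
overlap provides ground truth for all of it.

Size measure: the "size" of a punctum is its equivalent diameter, i.e. the
diameter of the sphere with the same volume (configurable); gate ties go to
the large class.  Thresholding defaults to Otsu per channel; connectivity
is 26-neighborhood in 3D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core import substream


@dataclass
class ChannelStack:
    """One-channel 3D (z, y, x) intensity stack with physical voxel size."""

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float]  # (z, y, x)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3D (z, y, x)")
        if np.any(self.data < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_size_nm
        return z * y * x / 1e9


@dataclass
class PunctaSet:
    """Labeled 3D objects with physical sizes and intensities."""

    table: pd.DataFrame  # label, n_voxels, volume_um3, equiv_diameter_nm, ...
    labels: np.ndarray  # labeled volume, 0 = background
    voxel_size_nm: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.table)


def max_project(stack: ChannelStack, z_range: tuple[int, int]) -> np.ndarray:
    """Per-pixel maximum over slices [z0, z1) — typically 3-5 slices."""
    z0, z1 = z_range
    if not 0 <= z0 < z1 <= stack.data.shape[0]:
        raise ValueError(f"z range {z_range} empty or outside stack")
    return stack.data[z0:z1].max(axis=0)


def segment_puncta(
    stack: ChannelStack,
    threshold_policy: str | float = "otsu",
    min_voxels: int = 2,
) -> PunctaSet:
    """Connected-component puncta above threshold, with physical measures.

    ``threshold_policy`` is either ``"otsu"`` or an absolute intensity.  A
    threshold above the maximum intensity yields an empty (not erroneous)
    set.  Components smaller than ``min_voxels`` are discarded.
    """
    data = stack.data
    if data.size == 0:
        raise ValueError("empty stack")
    if threshold_policy == "otsu":
        thr = float(threshold_otsu(data)) if data.max() > data.min() else np.inf
    else:
        thr = float(threshold_policy)
    binary = data > thr
    lab = label(binary, connectivity=3)  # 26-connectivity in 3D
    rows = []
    vox_um3 = stack.voxel_volume_um3
    keep = np.zeros(lab.max() + 1, dtype=np.int64)
    next_id = 1
    for prop in regionprops(lab, intensity_image=data):
        if prop.num_pixels < min_voxels:
            continue
        keep[prop.label] = next_id
        volume = prop.num_pixels * vox_um3
        equiv_d_um = (6.0 * volume / np.pi) ** (1.0 / 3.0)
        rows.append({
            "label": next_id,
            "n_voxels": int(prop.num_pixels),
            "volume_um3": volume,
            "equiv_diameter_nm": equiv_d_um * 1e3,
            "total_intensity": float(prop.image_intensity.sum()),
            "centroid_z": prop.centroid[0],
            "centroid_y": prop.centroid[1],
            "centroid_x": prop.centroid[2],
        })
        next_id += 1
    relabeled = keep[lab]
    return PunctaSet(pd.DataFrame(rows), relabeled, stack.voxel_size_nm)


def size_gate(puncta: PunctaSet, cutoff_nm: float = 500.0) -> tuple[PunctaSet, PunctaSet]:
    """Split puncta by equivalent diameter; boundary ties go to 'large'."""
    t = puncta.table
    if len(t) == 0:
        empty = t.copy()
        return (PunctaSet(empty, np.zeros_like(puncta.labels), puncta.voxel_size_nm),
                PunctaSet(empty.copy(), np.zeros_like(puncta.labels), puncta.voxel_size_nm))
    small_sel = t["equiv_diameter_nm"] < cutoff_nm
    small_t, large_t = t[small_sel], t[~small_sel]

    def _subset(sub):
        m = np.isin(puncta.labels, sub["label"].to_numpy())
        return PunctaSet(sub.reset_index(drop=True), np.where(m, puncta.labels, 0),
                         puncta.voxel_size_nm)

    return _subset(small_t), _subset(large_t)


def pearson(ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two channels over masked voxels."""
    ch1, ch2 = np.asarray(ch1, float), np.asarray(ch2, float)
    if mask is None:
        mask = np.ones(ch1.shape, dtype=bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    a, b = ch1[mask], ch2[mask]
    for name, arr in (("channel 1", a), ("channel 2", b)):
        if arr.std() == 0:
            raise ValueError(f"{name} has zero variance inside the mask")
    return float(np.corrcoef(a, b)[0, 1])


def manders(
    ch1: np.ndarray, ch2: np.ndarray, threshold1: float, threshold2: float
) -> tuple[float, float]:
    """Manders overlap coefficients (M1, M2), each in [0, 1].

    M1 is the fraction of channel-1 intensity found where channel 2 exceeds
    its threshold, and symmetrically for M2; the pair is asymmetric by
    construction.
    """
    ch1, ch2 = np.asarray(ch1, float), np.asarray(ch2, float)
    s1, s2 = ch1[ch1 > threshold1].sum(), ch2[ch2 > threshold2].sum()
    if s1 == 0 or s2 == 0:
        raise ValueError("zero denominator: a channel has no suprathreshold signal")
    m1 = ch1[(ch1 > threshold1) & (ch2 > threshold2)].sum() / s1
    m2 = ch2[(ch2 > threshold2) & (ch1 > threshold1)].sum() / s2
    return float(m1), float(m2)


def vacuolar_enrichment(
    image: np.ndarray, membrane_mask: np.ndarray, cytosol_mask: np.ndarray
) -> float:
    """Mean vacuolar-membrane intensity minus mean cytosolic intensity."""
    membrane_mask = np.asarray(membrane_mask, bool)
    cytosol_mask = np.asarray(cytosol_mask, bool)
    if (membrane_mask & cytosol_mask).any():
        raise ValueError("membrane and cytosol masks overlap")
    if not membrane_mask.any() or not cytosol_mask.any():
        raise ValueError("masks must be nonempty")
    image = np.asarray(image, float)
    return float(image[membrane_mask].mean() - image[cytosol_mask].mean())


def halftime(minutes: np.ndarray, intensity: np.ndarray) -> float:
    """Model-free half-time: first crossing of (min + max)/2, interpolated.

    The direction (rising or falling trace) is auto-detected; a flat trace
    is an error.
    """
    minutes = np.asarray(minutes, float)
    intensity = np.asarray(intensity, float)
    lo, hi = intensity.min(), intensity.max()
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):
        raise ValueError("flat intensity trace has no half-time")
    half = 0.5 * (lo + hi)
    rising = intensity[-1] >= intensity[0]
    above = intensity >= half if rising else intensity <= half
    j = int(np.argmax(above))
    if j == 0:
        return float(minutes[0])
    t0, t1 = minutes[j - 1], minutes[j]
    v0, v1 = intensity[j - 1], intensity[j]
    return float(t0 + (half - v0) * (t1 - t0) / (v1 - v0))


def growth_slope(spot_intensities: np.ndarray) -> float:
    """Relative growth coefficient: OLS slope of intensity vs dilution index.

    Exactly four spots (four serial ten-fold dilutions) are required.
    """
    y = np.asarray(spot_intensities, float)
    if y.shape != (4,):
        raise ValueError("exactly 4 dilution spot intensities are required")
    x = np.arange(4.0)
    return float(np.polyfit(x, y, 1)[0])


def _four_pl(x, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (x / ec50) ** hill)


def ec50(concentrations: np.ndarray, growth_coefficients: np.ndarray) -> tuple[float, bool]:
    """Half-maximal effective concentration from a dose-response series.

    Fits a four-parameter logistic to growth coefficient vs concentration
    and returns ``(ec50, fitted)``.  When the fit fails to converge, falls
    back to monotone interpolation at half-maximum with ``fitted=False``.
    Requires >= 4 concentrations whose responses span the transition.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(growth_coefficients, float)
    if x.size < 4:
        raise ValueError("need at least 4 concentrations")
    order = np.argsort(x)
    x, y = x[order], y[order]
    ymax, ymin = y.max(), y.min()
    half = 0.5 * (ymax + ymin)
    spans_half = (y[:2].mean() > half > y[-2:].mean()
                  or y[:2].mean() < half < y[-2:].mean())
    substantial = (ymax - ymin) > 0.2 * max(abs(ymax), abs(ymin))
    if not (spans_half and substantial):
        raise ValueError(
            "responses do not span the transition; extend the concentration range"
        )
    pos = x[x > 0]
    guess_mid = float(np.sqrt(pos.min() * pos.max())) if pos.size else 1.0
    try:
        popt, _ = curve_fit(
            _four_pl, x, y, p0=[ymin, ymax, guess_mid, 1.0],
            maxfev=10000,
        )
        mid = float(popt[2])
        if not np.isfinite(mid) or mid <= 0:
            raise RuntimeError("degenerate fit")
        return mid, True
    except RuntimeError:
        yn = y if y[0] > y[-1] else y[::-1]
        xn = x if y[0] > y[-1] else x[::-1]
        j = int(np.argmax(yn <= half))
        x0, x1 = xn[j - 1], xn[j]
        v0, v1 = yn[j - 1], yn[j]
        return float(x0 + (half - v0) * (x1 - x0) / (v1 - v0)), False


# --- synthetic two-channel generator --------------------------------------

SYNTH_DEFAULTS: dict = {
    "shape": (12, 96, 96),  # z, y, x voxels
    "voxel_size_nm": (500.0, 100.0, 100.0),
    "n_puncta": 12,
    # straddles the 500-nm size gate so both puncta classes are represented
    "diameter_nm": (300.0, 900.0),  # min, max drawn uniformly
    "overlap_fraction": 0.5,
    "intensity": 100.0,
    "psf_sigma_nm": 130.0,  # isotropic Gaussian blur emulating the confocal PSF
    "noise_sigma": 2.0,
    "background": 5.0,
}


def synth_cell_images(config: dict | None = None, seed: int = 0):
    """Two-channel 3D stacks with puncta at a controlled overlap fraction.

    A fraction ``overlap_fraction`` of the puncta are placed at identical
    positions in both channels; the rest are channel-specific with disjoint
    positions.  Puncta are solid spheres of the configured diameter on a
    constant background plus Gaussian noise.  Returns (channel1, channel2,
    ground_truth table).
    """
    cfg = dict(SYNTH_DEFAULTS)
    if config:
        unknown = set(config) - set(SYNTH_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    frac = cfg["overlap_fraction"]
    if not 0.0 <= frac <= 1.0:
        raise ValueError("overlap fraction must lie in [0, 1]")
    rng = substream(seed, "fluor")
    shape = tuple(cfg["shape"])
    vz, vy, vx = cfg["voxel_size_nm"]
    n_shared = int(round(frac * cfg["n_puncta"]))
    n_unique = cfg["n_puncta"] - n_shared

    def _place(n_objects, occupied):
        out = []
        tries = 0
        while len(out) < n_objects and tries < 2000:
            tries += 1
            d = rng.uniform(*cfg["diameter_nm"])
            r_vox = np.array([d / 2 / vz, d / 2 / vy, d / 2 / vx])
            c = np.array([rng.uniform(r_vox[a] + 1, shape[a] - r_vox[a] - 1)
                          for a in range(3)])
            min_sep = 2.2 * max(r_vox)
            if all(np.linalg.norm((c - o) * 1.0) > min_sep for o in occupied):
                occupied.append(c)
                out.append((c, d))
        return out

    occupied: list[np.ndarray] = []
    shared = _place(n_shared, occupied)
    only1 = _place(n_unique, occupied)
    only2 = _place(n_unique, occupied)

    zz, yy, xx = np.indices(shape)

    def _render(objects):
        from scipy.ndimage import gaussian_filter

        img = np.zeros(shape, dtype=np.float64)
        for c, d in objects:
            ell = (((zz - c[0]) * vz) ** 2 + ((yy - c[1]) * vy) ** 2
                   + ((xx - c[2]) * vx) ** 2) <= (d / 2.0) ** 2
            img[ell] += cfg["intensity"]
        psf = cfg["psf_sigma_nm"]
        if psf > 0:
            # blur solid spheres with the PSF: keeps the half-maximum diameter
            # while giving objects the intensity gradients real puncta have
            img = gaussian_filter(img, sigma=(psf / vz, psf / vy, psf / vx))
        return img + cfg["background"]

    img1 = _render(shared + only1)
    img2 = _render(shared + only2)
    if cfg["noise_sigma"] > 0:
        img1 = np.clip(img1 + rng.normal(0, cfg["noise_sigma"], shape), 0, None)
        img2 = np.clip(img2 + rng.normal(0, cfg["noise_sigma"], shape), 0, None)
    rows = []
    for kind, objs in (("shared", shared), ("ch1", only1), ("ch2", only2)):
        for c, d in objs:
            rows.append({"kind": kind, "z": c[0], "y": c[1], "x": c[2],
                         "diameter_nm": d})
    truth = pd.DataFrame(rows)
    return (
        ChannelStack(img1, cfg["voxel_size_nm"], "ch1"),
        ChannelStack(img2, cfg["voxel_size_nm"], "ch2"),
        truth,
    )
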