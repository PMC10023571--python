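"""Single-particle refinement of subparticles and FSC resolution estimation.

The two half-sets are refined independently from a shared, heavily low-pass
filtered starting map (a desk-scale stand-in for fully independent ab
initio models that still keeps the halves independent at high frequency),
with D1 point-group symmetrization each iteration.  Resolution is quoted
where the Fourier shell correlation between half-maps first drops through
the 0.143 gold-standard threshold.  Half-sets can be split per filament so
overlapping segments from one helix never straddle the halves, which would
otherwise share signal and inflate the FSC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import VolumeGrid, substream
from .helix import (
    FourierSliceCache,
    RefineOptions,
    _align_stack,
    _local_pose_grid,
    d1_flip,
    lowpass,
    reconstruct,
)
from .optics import CTFParams, ctf_image


@dataclass
class HalfSetAssignment:
    """Disjoint, exhaustive particle -> {A, B} mapping."""

    labels: pd.Series  # index-aligned with the record table, values "A"/"B"
    policy: str

    def indices(self, half: str) -> np.ndarray:
        return np.flatnonzero((self.labels == half).to_numpy())


def split_halves(records: pd.DataFrame, policy: str = "filament",
                 seed: int = 0) -> HalfSetAssignment:
    """Partition particles into half-sets.

    ``filament`` policy assigns whole filaments greedily (largest first) to
    the smaller half so no helix straddles the split; ``random`` splits
    particles uniformly with |A| - |B| <= 1.  Deterministic given the seed.
    """
    if policy == "filament":
        if "filament_id" not in records:
            raise ValueError("filament policy requires a filament_id column")
        groups = records.groupby("filament_id").size().sort_values(
            ascending=False, kind="stable"
        )
        if len(groups) < 2:
            raise ValueError(
                "gold-standard splitting impossible: only one filament present"
            )
        labels = pd.Series(index=records.index, dtype=object)
        sizes = {"A": 0, "B": 0}
        rng = substream(seed, "split")
        for fid, count in groups.items():
            if sizes["A"] < sizes["B"]:
                half = "A"
            elif sizes["B"] < sizes["A"]:
                half = "B"
            else:
                half = "A" if rng.random() < 0.5 else "B"
            labels[records["filament_id"] == fid] = half
            sizes[half] += count
    elif policy == "random":
        rng = substream(seed, "split")
        order = rng.permutation(len(records))
        labels = pd.Series(index=records.index, dtype=object)
        labels.iloc[order[: len(order) // 2 + len(order) % 2]] = "A"
        labels.iloc[order[len(order) // 2 + len(order) % 2:]] = "B"
    else:
        raise ValueError(f"unknown split policy {policy!r}")
    return HalfSetAssignment(labels, policy)


def d1_symmetrize(volume: VolumeGrid) -> VolumeGrid:
    """Impose the D1 two-fold (180 degrees about x through the center)."""
    return volume.like(0.5 * (volume.data + d1_flip(volume.data)))


def spa_refine(
    stack: np.ndarray,
    records: pd.DataFrame,
    assignment: HalfSetAssignment,
    pixel_size: float,
    initial_map: VolumeGrid | None = None,
    point_group: str = "D1",
    options: RefineOptions | None = None,
    ctf_params: list[CTFParams] | None = None,
    initial_lowpass_angstrom: float = 30.0,
):
    """Refine the two half-sets independently and average the aligned maps.

    Starting poses are taken from the records (as delivered by subtraction).
    Each iteration aligns every particle locally to its own half-map,
    reconstructs with Wiener CTF weighting and symmetrizes; before the next
    alignment round both half-maps are low-pass filtered at the resolution
    their mutual FSC currently supports (gold-standard filtering: the halves
    share only the cutoff, never each other's amplitudes), which prevents
    alignment from chasing half-set noise.  Without an initial map each half
    starts from the reconstruction of its own particles at the input poses,
    filtered at the stated initial cutoff.
    """
    opt = options or RefineOptions()
    halves: dict = {}
    data: dict = {}
    for half in ("A", "B"):
        idx = assignment.indices(half)
        if idx.size == 0:
            raise ValueError(f"half-set {half} is empty")
        sub = stack[idx]
        subrec = records.iloc[idx].reset_index(drop=True)
        if "cc" not in subrec:
            subrec["cc"] = np.nan
        subctf = [ctf_params[i] for i in idx] if ctf_params is not None else None
        stack_hat = [np.fft.fft2(np.fft.ifftshift(im.astype(np.float64))) for im in sub]
        ctf_arrays = None
        if subctf is not None:
            ctf_arrays = [np.fft.ifftshift(ctf_image(p, sub.shape[-1], pixel_size))
                          for p in subctf]
        if initial_map is None:
            start = reconstruct(sub, subrec, pixel_size, ctf_params=subctf)
            if point_group == "D1":
                start = d1_symmetrize(start)
        else:
            start = initial_map
        halves[half] = start
        data[half] = (sub, subrec, subctf, stack_hat, ctf_arrays)

    cutoff = initial_lowpass_angstrom
    nyquist = 2.0 * pixel_size
    history: dict = {"A": [], "B": [], "filter_angstrom": []}
    for _ in range(opt.n_iter):
        for half in ("A", "B"):
            sub, subrec, subctf, stack_hat, ctf_arrays = data[half]
            current = lowpass(halves[half], max(cutoff, nyquist))
            cache = FourierSliceCache(current, order=1)
            pose_lists = [_local_pose_grid(subrec.iloc[i], opt.local_step)
                          for i in range(len(sub))]
            subrec = _align_stack(stack_hat, subrec, cache, pose_lists, ctf_arrays,
                                  opt.max_shift_px)
            vol = reconstruct(sub, subrec, pixel_size, ctf_params=subctf)
            if point_group == "D1":
                vol = d1_symmetrize(vol)
            halves[half] = vol
            data[half] = (sub, subrec, subctf, stack_hat, ctf_arrays)
            history[half].append(float(subrec["cc"].mean()))
        res = resolution_at(fsc(halves["A"], halves["B"]), 0.143)
        cutoff = res.angstrom
        history["filter_angstrom"].append(cutoff)

    combined = halves["A"].like(0.5 * (halves["A"].data + halves["B"].data))
    recs_out = {h: data[h][1] for h in ("A", "B")}
    return halves["A"], halves["B"], combined, recs_out, {"history": history}


class FSCCurve(NamedTuple):
    """Shell-wise correlation between two maps.

    frequencies are shell centers in 1/Å (strictly increasing to Nyquist);
    values lie in [-1, 1].
    """

    frequencies: np.ndarray
    values: np.ndarray
    shell_width: float  # in 1/Å


def fsc(map_a: VolumeGrid, map_b: VolumeGrid, shell_width_voxels: float = 1.0) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid."""
    if map_a.shape != map_b.shape:
        raise ValueError(f"shape mismatch: {map_a.shape} vs {map_b.shape}")
    if abs(map_a.voxel_size - map_b.voxel_size) > 1e-6:
        raise ValueError("voxel size mismatch")
    n = map_a.n
    fa = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(map_a.data.astype(np.float64))))
    fb = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(map_b.data.astype(np.float64))))
    idx = np.arange(n) - n // 2
    zz, yy, xx = np.meshgrid(idx, idx, idx, indexing="ij")
    radius = np.sqrt(zz**2 + yy**2 + xx**2)
    shells = np.floor(radius / shell_width_voxels).astype(int)
    n_shell = int(n // 2 / shell_width_voxels)
    freqs, values = [], []
    for k in range(1, n_shell + 1):
        sel = shells == k
        if not sel.any():
            continue
        a, b = fa[sel], fb[sel]
        num = np.real(np.sum(a * np.conj(b)))
        den = np.sqrt(np.sum(np.abs(a) ** 2) * np.sum(np.abs(b) ** 2))
        values.append(num / den if den > 0 else 0.0)
        freqs.append((k + 0.5) * shell_width_voxels / (n * map_a.voxel_size))
    return FSCCurve(np.asarray(freqs), np.asarray(values),
                    shell_width_voxels / (n * map_a.voxel_size))


class Resolution(NamedTuple):
    angstrom: float
    at_nyquist: bool  # curve never crossed the threshold


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> Resolution:
    """Resolution at the first downward threshold crossing of an FSC curve.

    Linearly interpolates the crossing frequency between shells and returns
    1/frequency in Å; a curve that never drops through the threshold returns
    the Nyquist limit flagged ``at_nyquist=True``.
    """
    f, v = curve.frequencies, curve.values
    if f.size == 0:
        raise ValueError("empty FSC curve")
    below = np.flatnonzero(v < threshold)
    if below.size == 0:
        return Resolution(float(1.0 / f[-1]), True)
    j = below[0]
    if j == 0:
        return Resolution(float(1.0 / f[0]), False)
    f0, f1 = f[j - 1], f[j]
    v0, v1 = v[j - 1], v[j]
    fc = f0 + (v0 - threshold) * (f1 - f0) / (v0 - v1)
    return Resolution(float(1.0 / fc), False)
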