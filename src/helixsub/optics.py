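"""Contrast transfer function model, dose bookkeeping, noise, defocus geometry.

The CTF follows the standard weak-phase form used across cryo-EM packages,

    CTF(s) = -[ sqrt(1 - A^2) sin(gamma(s)) + A cos(gamma(s)) ],
    gamma(s) = pi * lambda * dz * s^2 - (pi / 2) * Cs * lambda^3 * s^4,

with defocus ``dz`` positive for underfocus, amplitude contrast fraction
``A`` and relativistic electron wavelength ``lambda`` at the set voltage.
The sign convention makes CTF(0) = -A (protein appears dark).  No
astigmatism and no envelope by default; an optional Gaussian envelope flag
is provided for experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# physical constants (CODATA): h [J s], m0 [kg], e [C], c [m/s]
_H = 6.62607015e-34
_M0 = 9.1093837015e-31
_E = 1.602176634e-19
_C = 299792458.0


@dataclass
class CTFParams:
    """Microscope/imaging parameters for one particle or micrograph.

    voltage in kV, spherical aberration in mm, amplitude contrast as a
    fraction in [0, 1], defocus in Angstrom (positive = underfocus).
    """

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.1
    defocus_angstrom: float = 15000.0
    phase_flip: bool = False
    b_factor: float = 0.0  # optional Gaussian envelope exp(-B s^2 / 4)

    def __post_init__(self) -> None:
        if not self.voltage_kv > 0:
            raise ValueError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must lie in [0, 1]")


@dataclass
class DoseModel:
    """Exposure bookkeeping: dose rate (e-/Å²/s), exposure (s), frame count."""

    dose_rate: float
    exposure: float
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.dose_rate < 0 or self.exposure < 0 or self.n_frames < 0:
            raise ValueError("dose model fields must be nonnegative")


def total_dose(model: DoseModel) -> float:
    """Total accumulated dose in e-/Å²: rate times exposure."""
    return model.dose_rate * model.exposure


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom at the given voltage."""
    v = voltage_kv * 1e3
    lam = _H / np.sqrt(2.0 * _M0 * _E * v * (1.0 + _E * v / (2.0 * _M0 * _C**2)))
    return lam * 1e10


def ctf_eval(params: CTFParams, s: np.ndarray) -> np.ndarray:
    """Evaluate the CTF at spatial frequencies ``s`` (1/Å); bounded in [-1, 1]."""
    s = np.asarray(s, dtype=np.float64)
    lam = electron_wavelength(params.voltage_kv)
    cs = params.cs_mm * 1e7  # mm -> Å
    gamma = np.pi * lam * params.defocus_angstrom * s**2 - 0.5 * np.pi * cs * lam**3 * s**4
    a = params.amplitude_contrast
    ctf = -(np.sqrt(1.0 - a**2) * np.sin(gamma) + a * np.cos(gamma))
    if params.phase_flip:
        ctf = np.abs(ctf)
    if params.b_factor:
        ctf = ctf * np.exp(-params.b_factor * s**2 / 4.0)
    return ctf


def frequency_grid_2d(shape: int | tuple[int, int], pixel_size: float) -> np.ndarray:
    """Centered radial spatial-frequency magnitudes (1/Å) for an image."""
    ny, nx = (shape, shape) if isinstance(shape, int) else shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=pixel_size))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=pixel_size))
    gy, gx = np.meshgrid(fy, fx, indexing="ij")
    return np.hypot(gy, gx)


def ctf_image(params: CTFParams, shape: int | tuple[int, int],
              pixel_size: float) -> np.ndarray:
    """Centered 2D CTF array for an image at the given pixel size."""
    return ctf_eval(params, frequency_grid_2d(shape, pixel_size))


def apply_ctf(image: np.ndarray, params: CTFParams, pixel_size: float) -> np.ndarray:
    """Multiply a square real image by the CTF in Fourier space."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"apply_ctf requires a square image, got {image.shape}")
    c = np.fft.ifftshift(ctf_image(params, image.shape[0], pixel_size))
    out = np.fft.ifft2(np.fft.fft2(image) * c)
    return out.real


def add_noise(
    image: np.ndarray,
    target_snr: float,
    mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive white Gaussian noise scaled to a target in-mask SNR.

    Noise variance is ``var(signal within mask) / target_snr``.  An infinite
    ``target_snr`` returns the image unchanged.
    """
    image = np.asarray(image, dtype=np.float64)
    if not target_snr > 0:
        raise ValueError("target_snr must be positive")
    if np.isinf(target_snr):
        return image.copy()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("mask is empty; cannot measure signal variance")
    sigma = np.sqrt(image[mask].var() / target_snr)
    return image + rng.normal(0.0, sigma, size=image.shape)


def subparticle_defocus(segment_defocus: float, z_offset: float, flip_sign: bool = False) -> float:
    """Geometry-corrected defocus of a subunit displaced along the beam axis.

    ``z_offset`` (Å) is the beam-axis displacement of the subunit center
    relative to the segment center, as implied by the helical lattice and the
    segment pose.  Convention (fixable with ``flip_sign``): a subunit higher
    in the column, i.e. farther from the detector, is more underfocused, so
    the corrected defocus is ``segment_defocus + z_offset``.
    """
    return segment_defocus + (-z_offset if flip_sign else z_offset)
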