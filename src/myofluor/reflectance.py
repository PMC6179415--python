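"""Diffuse-reflectance absorbance and chromophore ratio metrics.

In the blood-free perfused heart the visible absorbance spectrum is
dominated by myoglobin (oxy form: double peak at ~544/~578 nm; deoxy
form: broad band near 560 nm) and, under oxygen deprivation, by reduced
cytochrome c (peak at 550 nm). Two ratio metrics summarise the tissue
state: A(578)/A(600) tracks myoglobin oxygenation and A(502)/A(550)
tracks the cytochrome c oxidation state (502 nm is insensitive to
oxygenation and serves as the reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ReflectanceSpectrum",
    "AbsorbanceSpectrum",
    "absorbance",
    "absorbance_at",
    "oxygenation_ratio",
    "cytochrome_ratio",
    "difference_spectrum",
    "OXYGENATION_WAVELENGTHS",
    "CYTOCHROME_WAVELENGTHS",
]

OXYGENATION_WAVELENGTHS = (578.0, 600.0)
CYTOCHROME_WAVELENGTHS = (502.0, 550.0)


@dataclass
class ReflectanceSpectrum:
    """Raw spectrometer output: intensity vs wavelength.

    ``role`` distinguishes tissue spectra from the white-reference target
    used for calibration.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    role: str = "sample"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths[0] < 350 or self.wavelengths[-1] > 800:
            raise ValueError("wavelengths must lie within [350, 800] nm")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.role not in ("sample", "white_reference"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class AbsorbanceSpectrum:
    """Tissue absorbance vs wavelength (dimensionless)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must have equal length")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")


def absorbance(
    sample: ReflectanceSpectrum,
    reference: ReflectanceSpectrum,
    sign_convention: str = "standard",
) -> AbsorbanceSpectrum:
    """Tissue absorbance from a sample spectrum and a white reference.

    The reference is interpolated onto the sample grid. The default
    ``"standard"`` convention returns -log10(I/I0), which yields positive
    peaks at absorber bands; ``"as_printed"`` returns log10(I/I0)
    (the sign-flipped variant). Wavelengths where either intensity is
    zero are masked (dropped) with a warning.
    """
    if sign_convention not in ("standard", "as_printed"):
        raise ValueError(f"unknown sign_convention {sign_convention!r}")
    wl = sample.wavelengths
    i = sample.intensities
    i0 = np.interp(wl, reference.wavelengths, reference.intensities)
    valid = (i > 0) & (i0 > 0)
    if not np.all(valid):
        warnings.warn(
            f"masking {int((~valid).sum())} wavelength bins with zero intensity",
            stacklevel=2,
        )
    ratio = i[valid] / i0[valid]
    a = np.log10(ratio) if sign_convention == "as_printed" else -np.log10(ratio)
    return AbsorbanceSpectrum(wl[valid], a)


def absorbance_at(spec: AbsorbanceSpectrum, wavelength: float) -> float:
    """Absorbance at an exact wavelength by linear interpolation."""
    if not (spec.wavelengths[0] <= wavelength <= spec.wavelengths[-1]):
        raise ValueError(
            f"wavelength {wavelength} nm outside spectrum range "
            f"[{spec.wavelengths[0]}, {spec.wavelengths[-1]}] nm"
        )
    return float(np.interp(wavelength, spec.wavelengths, spec.absorbance))


def _ratio(spec: AbsorbanceSpectrum, num_nm: float, den_nm: float) -> float:
    num = absorbance_at(spec, num_nm)
    den = absorbance_at(spec, den_nm)
    if den == 0:
        raise ZeroDivisionError(f"absorbance at {den_nm} nm is zero")
    return num / den


def oxygenation_ratio(spec: AbsorbanceSpectrum) -> float:
    """Myoglobin oxygenation proxy A(578)/A(600).

    578 and 600 nm are the wavelengths where the oxy-minus-deoxy
    absorbance difference is largest in the visible band.
    """
    return _ratio(spec, *OXYGENATION_WAVELENGTHS)


def cytochrome_ratio(spec: AbsorbanceSpectrum) -> float:
    """Cytochrome c oxidation proxy A(502)/A(550).

    The reduced form absorbs at 550 nm; 502 nm is oxygenation-neutral, so
    the ratio falls as cytochrome c becomes reduced.
    """
    return _ratio(spec, *CYTOCHROME_WAVELENGTHS)


def difference_spectrum(
    a: AbsorbanceSpectrum,
    b: AbsorbanceSpectrum,
    band: tuple[float, float] = (400.0, 700.0),
    prominence: float = 0.01,
) -> tuple[AbsorbanceSpectrum, np.ndarray]:
    """a - b restricted to ``band``, plus the wavelengths of its maxima.

    Maxima are local peaks of the difference exceeding the given
    prominence. Used to locate the wavelengths most sensitive to
    oxygenation (578/600 nm for myoglobin).
    """
    if a.wavelengths.shape != b.wavelengths.shape or not np.allclose(
        a.wavelengths, b.wavelengths
    ):
        raise ValueError("spectra must share a common wavelength grid")
    mask = (a.wavelengths >= band[0]) & (a.wavelengths <= band[1])
    if not np.any(mask):
        raise ValueError("no wavelengths within the requested band")
    wl = a.wavelengths[mask]
    diff = a.absorbance[mask] - b.absorbance[mask]
    idx, _ = find_peaks(diff, prominence=prominence)
    return AbsorbanceSpectrum(wl, diff), wl[idx]
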