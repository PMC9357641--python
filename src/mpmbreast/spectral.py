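"""Emission-spectrum model and band-pass channel formation.

The acquisition geometry this package emulates excites tissue with a
near-infrared femtosecond laser (780 nm by default) and records emission
between 380 and 630 nm, either on a 25-bin spectral detector (10 nm bins)
or through three band-pass filters (390/18, 480/40, 629/56 nm) onto a
12-bit detector.  Breast-tissue fluorophores are modelled as single
Gaussian emission lines: broad autofluorescence peaks at 480 nm
(epithelium, adipose, stroma), 510 nm (normal-duct edge puncta) and
570 nm (immune cells), and a sharp second-harmonic-generation (SHG) line
from fibrillar collagen at exactly half the excitation wavelength.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidConfigError

__all__ = [
    "SpectralConfig",
    "EmissionSpectrum",
    "Fluorophore",
    "ChannelFilterSet",
    "DEFAULT_FLUOROPHORES",
    "shg_wavelength",
    "emission_spectrum",
    "channel_response",
    "quantize",
    "fluorophore_channel_weights",
    "read_fluorophore_table",
    "write_fluorophore_table",
    "write_spectrum_csv",
]

#: Names of the six modelled fluorophore classes.
FLUOROPHORE_NAMES = (
    "epithelial_autofluorescence",
    "duct_edge_puncta",
    "immune_cell",
    "shg_collagen",
    "adipose",
    "stromal_fiber",
)


@dataclass(frozen=True)
class SpectralConfig:
    """Acquisition constants of the spectral detector.

    Parameters
    ----------
    excitation_wavelength : float
        Laser wavelength in nm; must lie above the detector range so the
        second harmonic (half the excitation) can fall inside it.
    detector_range_low, detector_range_high : float
        Detection window in nm.
    n_bins : int
        Number of equal-width spectral bins across the window.
    quantization_levels : int
        Gray levels of the detector (4096 = 12 bits).
    """

    excitation_wavelength: float = 780.0
    detector_range_low: float = 380.0
    detector_range_high: float = 630.0
    n_bins: int = 25
    quantization_levels: int = 4096

    def __post_init__(self) -> None:
        if self.excitation_wavelength <= 0:
            raise InvalidConfigError("excitation wavelength must be positive")
        if self.detector_range_high <= self.detector_range_low:
            raise InvalidConfigError("detector range must be increasing")
        if self.n_bins < 1:
            raise InvalidConfigError("need at least one spectral bin")
        if self.quantization_levels < 2:
            raise InvalidConfigError("need at least two gray levels")
        if self.excitation_wavelength <= self.detector_range_high:
            raise InvalidConfigError(
                "excitation must lie above the detector range"
            )

    @property
    def bin_width(self) -> float:
        """Width of one spectral bin in nm (10 nm in the reference setup)."""
        return (self.detector_range_high - self.detector_range_low) / self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(
            self.detector_range_low, self.detector_range_high, self.n_bins + 1
        )

    @property
    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class EmissionSpectrum:
    """A binned emission spectrum on the detector's wavelength axis."""

    bin_centers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        if centers.shape != intens.shape or centers.ndim != 1:
            raise InvalidConfigError("bin_centers and intensities must match")
        if np.any(intens < 0):
            raise InvalidConfigError("spectral intensities must be >= 0")
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "intensities", intens)

    @property
    def bin_width(self) -> float:
        return float(np.diff(self.bin_centers).mean())

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.intensities))


@dataclass(frozen=True)
class Fluorophore:
    """A single-line emitter with Gaussian spectral shape."""

    name: str
    peak_wavelength: float
    bandwidth_fwhm: float
    relative_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.bandwidth_fwhm <= 0:
            raise InvalidConfigError("FWHM must be positive")
        if self.relative_amplitude < 0:
            raise InvalidConfigError("amplitude must be >= 0")

    @property
    def sigma(self) -> float:
        return self.bandwidth_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# Broad autofluorescence (80 nm FWHM) vs sharp SHG (12 nm FWHM); the SHG
# line must be strictly narrower than every autofluorescence line.
_AUTOFLUOR_FWHM = 80.0
_SHG_FWHM = 12.0

DEFAULT_FLUOROPHORES: dict[str, Fluorophore] = {
    "epithelial_autofluorescence": Fluorophore(
        "epithelial_autofluorescence", 480.0, _AUTOFLUOR_FWHM, 1.0
    ),
    "duct_edge_puncta": Fluorophore("duct_edge_puncta", 510.0, _AUTOFLUOR_FWHM, 1.6),
    "immune_cell": Fluorophore("immune_cell", 570.0, _AUTOFLUOR_FWHM, 1.2),
    "shg_collagen": Fluorophore("shg_collagen", 390.0, _SHG_FWHM, 1.0),
    "adipose": Fluorophore("adipose", 480.0, _AUTOFLUOR_FWHM, 0.8),
    "stromal_fiber": Fluorophore("stromal_fiber", 480.0, _AUTOFLUOR_FWHM, 0.6),
}


@dataclass(frozen=True)
class ChannelFilterSet:
    """The three acquisition band-pass filters as (center, full width) nm."""

    filters: tuple[tuple[float, float], ...] = (
        (390.0, 18.0),
        (480.0, 40.0),
        (629.0, 56.0),
    )

    def __post_init__(self) -> None:
        if len(self.filters) != 3:
            raise InvalidConfigError("exactly three acquisition filters")
        for center, width in self.filters:
            if width <= 0 or center <= 0:
                raise InvalidConfigError("filter center and width must be positive")

    @property
    def pass_bands(self) -> list[tuple[float, float]]:
        return [(c - w / 2.0, c + w / 2.0) for c, w in self.filters]


def shg_wavelength(config: SpectralConfig) -> float:
    """Second-harmonic emission wavelength: half the excitation wavelength."""
    if config.excitation_wavelength <= 0:
        raise InvalidConfigError("excitation wavelength must be positive")
    return config.excitation_wavelength / 2.0


def _gaussian_mass(lo: np.ndarray, hi: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Integral of a unit-mass Gaussian between lo and hi."""
    from scipy.special import erf

    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((hi - mu) / s) - erf((lo - mu) / s))


def emission_spectrum(
    fluor: Fluorophore, config: SpectralConfig | None = None
) -> EmissionSpectrum:
    """Bin a fluorophore's Gaussian emission line onto the spectral detector.

    The intensity of each bin is the Gaussian line integrated over the bin,
    scaled by the fluorophore's relative amplitude; peaks outside the
    detector range yield truncated spectra.
    """
    config = config or SpectralConfig()
    edges = config.bin_edges
    mass = _gaussian_mass(edges[:-1], edges[1:], fluor.peak_wavelength, fluor.sigma)
    return EmissionSpectrum(config.bin_centers, fluor.relative_amplitude * mass)


def channel_response(
    spectrum: EmissionSpectrum, filters: ChannelFilterSet | None = None
) -> np.ndarray:
    """Map a binned spectrum through the three band-pass filters.

    Each channel collects the spectrum intensity inside its pass-band;
    a bin partially covered by the band contributes in proportion to the
    overlapping fraction of its width.
    """
    filters = filters or ChannelFilterSet()
    width = spectrum.bin_width
    lo = spectrum.bin_centers - width / 2.0
    hi = spectrum.bin_centers + width / 2.0
    out = np.zeros(3, dtype=float)
    for k, (band_lo, band_hi) in enumerate(filters.pass_bands):
        overlap = np.clip(np.minimum(hi, band_hi) - np.maximum(lo, band_lo), 0.0, None)
        out[k] = float(np.sum(spectrum.intensities * overlap / width))
    return out


def quantize(
    intensity: float | np.ndarray,
    config: SpectralConfig | None = None,
    full_scale: float = 1.0,
) -> int | np.ndarray:
    """Quantize non-negative intensity to detector gray levels.

    ``round(clip(intensity / full_scale, 0, 1) * (levels - 1))``; scalar in,
    scalar out; arrays are quantized elementwise to uint16.
    """
    config = config or SpectralConfig()
    if full_scale <= 0:
        raise InvalidConfigError("full-scale reference must be positive")
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr < 0):
        raise InvalidConfigError("intensity must be non-negative")
    levels = config.quantization_levels
    q = np.rint(np.clip(arr / full_scale, 0.0, 1.0) * (levels - 1))
    if np.isscalar(intensity) or arr.ndim == 0:
        return int(q)
    return q.astype(np.uint16)


def fluorophore_channel_weights(
    fluorophores: dict[str, Fluorophore] | None = None,
    config: SpectralConfig | None = None,
    filters: ChannelFilterSet | None = None,
) -> dict[str, np.ndarray]:
    """Per-fluorophore 3-channel response vectors (amplitude included)."""
    fluorophores = fluorophores or DEFAULT_FLUOROPHORES
    config = config or SpectralConfig()
    filters = filters or ChannelFilterSet()
    return {
        name: channel_response(emission_spectrum(f, config), filters)
        for name, f in fluorophores.items()
    }


def write_fluorophore_table(fluorophores: dict[str, Fluorophore], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "peak_nm", "fwhm_nm", "amplitude"])
        for f in fluorophores.values():
            writer.writerow([f.name, f.peak_wavelength, f.bandwidth_fwhm, f.relative_amplitude])


def read_fluorophore_table(path: str | Path) -> dict[str, Fluorophore]:
    out: dict[str, Fluorophore] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["name"]] = Fluorophore(
                row["name"], float(row["peak_nm"]), float(row["fwhm_nm"]), float(row["amplitude"])
            )
    return out


def write_spectrum_csv(spectrum: EmissionSpectrum, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_center_nm", "intensity"])
        for c, i in zip(spectrum.bin_centers, spectrum.intensities):
            writer.writerow([c, i])
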