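"""Wavelength-sampled spectra: representation, I/O, resampling, generation.

Everything downstream of the spectrometer is a sampled function of wavelength
(reflectance, irradiance, or receptor sensitivity) on a uniform nanometre grid.
This module owns that representation plus the standard curves the colour model
needs: the CIE D65 daylight illuminant and visual-pigment sensitivity templates
generated from the Govardovskii et al. (2000) A1 nomogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "CalibrationPair",
    "DEFAULT_GRID",
    "REFLECTANCE_CEILING",
    "SpectrumError",
    "GridMismatchError",
    "RangeNotCoveredError",
    "resample",
    "raw_to_reflectance",
    "standard_illuminant_d65",
    "receptor_template",
    "read_spectra_csv",
    "write_spectra_csv",
    "flat_illuminant",
]

#: Reflectance values above 1.0 occur routinely when a sample out-reflects the
#: white calibration standard at some wavelengths; tolerate up to this ceiling.
REFLECTANCE_CEILING = 1.2

#: Column name used for the wavelength axis in all spectra CSV files.
WAVELENGTH_COLUMN = "wavelength_nm"


class SpectrumError(ValueError):
    """Base class for spectrum domain errors."""


class GridMismatchError(SpectrumError):
    """Spectra that must share a wavelength grid do not."""


class RangeNotCoveredError(SpectrumError):
    """A resampling target extends beyond the source spectrum's range."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres, inclusive of both endpoints."""

    start_nm: float = 300.0
    stop_nm: float = 700.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise SpectrumError(
                f"grid start ({self.start_nm}) must be below stop ({self.stop_nm})"
            )
        if self.step_nm <= 0:
            raise SpectrumError(f"grid step must be positive, got {self.step_nm}")

    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1


DEFAULT_GRID = WavelengthGrid(300.0, 700.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A sampled nonnegative curve over a :class:`WavelengthGrid`.

    ``kind`` distinguishes reflectance (bounded by ``REFLECTANCE_CEILING``),
    irradiance, and sensitivity curves; ``name`` is a free label used in CSV
    round-trips and report tables.
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "reflectance"
    name: str = ""
    reflectance_ceiling: float = field(default=REFLECTANCE_CEILING, repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.kind not in ("reflectance", "irradiance", "sensitivity"):
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if values.ndim != 1 or len(values) != len(self.grid):
            raise SpectrumError(
                f"values length {values.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(values)):
            raise SpectrumError("spectrum contains non-finite values")
        if np.any(values < 0):
            raise SpectrumError("spectrum contains negative values")
        if self.kind == "reflectance" and np.any(values > self.reflectance_ceiling):
            raise SpectrumError(
                f"reflectance exceeds ceiling {self.reflectance_ceiling}"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths()

    def with_name(self, name: str) -> "Spectrum":
        return replace(self, name=name)


@dataclass(frozen=True)
class CalibrationPair:
    """White/black reference spectra for dark- and white-standard correction."""

    white_standard: Spectrum
    black_standard: Spectrum

    def __post_init__(self) -> None:
        if self.white_standard.grid != self.black_standard.grid:
            raise GridMismatchError("calibration standards must share a grid")
        if np.any(self.white_standard.values < self.black_standard.values):
            raise SpectrumError("white standard below black standard at some wavelength")


# ---------------------------------------------------------------------------
# Resampling and calibration
# ---------------------------------------------------------------------------

def resample(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate ``spectrum`` onto ``target``.

    Extrapolation is refused: the target must lie within the source range.
    Values at wavelengths shared by both grids are preserved exactly.
    """
    src = spectrum.grid
    if target.start_nm < src.start_nm - 1e-9 or target.stop_nm > src.stop_nm + 1e-9:
        raise RangeNotCoveredError(
            f"target grid {target.start_nm}-{target.stop_nm} nm extends beyond "
            f"source {src.start_nm}-{src.stop_nm} nm"
        )
    if target == src:
        return spectrum
    values = np.interp(target.wavelengths(), spectrum.wavelengths, spectrum.values)
    return replace(spectrum, grid=target, values=values)


def raw_to_reflectance(raw: Spectrum, cal: CalibrationPair) -> Spectrum:
    """Dark/white-standard normalisation: (raw − black) / (white − black).

    Negative results (sample darker than the black standard, from noise) are
    clipped at zero. Wavelengths where white equals black are rejected.
    """
    white, black = cal.white_standard, cal.black_standard
    if raw.grid != white.grid:
        raise GridMismatchError("raw spectrum and calibration pair must share a grid")
    denom = white.values - black.values
    if np.any(denom <= 0):
        raise SpectrumError(
            "white and black standards coincide at some wavelength; "
            "reflectance is undefined there"
        )
    values = np.clip((raw.values - black.values) / denom, 0.0, None)
    return Spectrum(raw.grid, values, kind="reflectance", name=raw.name)


# ---------------------------------------------------------------------------
# CIE D65 daylight illuminant
# ---------------------------------------------------------------------------

# CIE standard illuminant D65 relative spectral power distribution,
# 300-780 nm at 5 nm, normalised to 100 at 560 nm (CIE 15 tabulation).
_D65_START, _D65_STOP, _D65_STEP = 300.0, 780.0, 5.0
_D65_VALUES = np.array([
    0.0341, 1.6643, 3.2945, 11.7652, 20.2360, 28.6447, 37.0535, 38.5011,
    39.9488, 42.4302, 44.9117, 45.7750, 46.6383, 49.3637, 52.0891, 51.0323,
    49.9755, 52.3118, 54.6482, 68.7015, 82.7549, 87.1204, 91.4860, 92.4589,
    93.4318, 90.0570, 86.6823, 95.7736, 104.8650, 110.9360, 117.0080, 117.4100,
    117.8120, 116.3360, 114.8610, 115.3920, 115.9230, 112.3670, 108.8110,
    109.0820, 109.3540, 108.5780, 107.8020, 106.2960, 104.7900, 106.2390,
    107.6890, 106.0470, 104.4050, 104.2250, 104.0460, 102.0230, 100.0000,
    98.1671, 96.3342, 96.0611, 95.7880, 92.2368, 88.6856, 89.3459, 90.0062,
    89.8026, 89.5991, 88.6489, 87.6987, 85.4936, 83.2886, 83.4939, 83.6992,
    81.8630, 80.0268, 80.1207, 80.2146, 81.2462, 82.2778, 80.2810, 78.2842,
    74.0027, 69.7213, 70.6652, 71.6091, 72.9790, 74.3490, 67.9765, 61.6040,
    65.7448, 69.8856, 72.4863, 75.0870, 69.3398, 63.5927, 55.0054, 46.4182,
    56.6118, 66.8054, 65.0941, 63.3828,
])


def standard_illuminant_d65(grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """CIE D65 daylight spectral power interpolated onto ``grid``.

    The output is rescaled so its mean over the grid equals 1; the von Kries
    adaptation step downstream cancels any global illuminant scale, so this
    normalisation is a convention, not a physical claim.
    """
    if grid.start_nm < _D65_START or grid.stop_nm > _D65_STOP:
        raise RangeNotCoveredError(
            f"D65 tabulation covers {_D65_START:.0f}-{_D65_STOP:.0f} nm; "
            f"requested {grid.start_nm}-{grid.stop_nm} nm"
        )
    table_wl = _D65_START + _D65_STEP * np.arange(len(_D65_VALUES))
    values = np.interp(grid.wavelengths(), table_wl, _D65_VALUES)
    values = values / values.mean()
    return Spectrum(grid, values, kind="irradiance", name="d65")


def d65_tabulated(wavelength_nm: float) -> float:
    """Raw tabulated D65 power at a 5 nm node (no normalisation)."""
    idx = (wavelength_nm - _D65_START) / _D65_STEP
    if abs(idx - round(idx)) > 1e-9 or not 0 <= round(idx) < len(_D65_VALUES):
        raise SpectrumError(f"{wavelength_nm} nm is not a tabulated D65 node")
    return float(_D65_VALUES[int(round(idx))])


def flat_illuminant(grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Equal-energy illuminant (value 1 everywhere); useful as a neutral stand-in."""
    return Spectrum(grid, np.ones(len(grid)), kind="irradiance", name="flat")


# ---------------------------------------------------------------------------
# Visual-pigment sensitivity templates
# ---------------------------------------------------------------------------

def _govardovskii_a1(lambda_max: float, wavelengths: np.ndarray) -> np.ndarray:
    # Alpha band of the A1 visual-pigment template (Govardovskii et al. 2000)
    # with the published constants. The beta band is deliberately omitted: it
    # adds a secondary short-wavelength bump, and the template contract here
    # is a unimodal sensitivity curve.
    x = lambda_max / wavelengths
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )


def receptor_template(lambda_max: float, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Photoreceptor spectral sensitivity from the A1 visual-pigment nomogram.

    Returns a unimodal curve peaking at ``lambda_max`` with peak value 1.
    Valid for 300 <= lambda_max <= 650 nm, the range over which the nomogram
    constants were fitted.
    """
    if not 300.0 <= lambda_max <= 650.0:
        raise SpectrumError(
            f"lambda_max {lambda_max} nm outside supported range 300-650 nm"
        )
    values = _govardovskii_a1(lambda_max, grid.wavelengths())
    values = values / values.max()
    return Spectrum(grid, values, kind="sensitivity", name=f"lmax{lambda_max:g}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_spectra_csv(path) -> list[Spectrum]:
    """Read named spectra from a CSV with a ``wavelength_nm`` column.

    Every non-wavelength column becomes one Spectrum (kind ``reflectance``).
    Wavelengths must be strictly increasing and uniformly spaced; missing
    values are rejected.
    """
    df = pd.read_csv(path)
    if WAVELENGTH_COLUMN not in df.columns:
        raise SpectrumError(f"missing {WAVELENGTH_COLUMN!r} column in {path}")
    wl = df[WAVELENGTH_COLUMN].to_numpy(dtype=float)
    if len(wl) < 2 or np.any(np.diff(wl) <= 0):
        raise SpectrumError(f"wavelengths in {path} are not strictly increasing")
    steps = np.diff(wl)
    if np.ptp(steps) > 1e-6:
        raise SpectrumError(f"wavelength grid in {path} is not uniform")
    if df.isna().any().any():
        raise SpectrumError(f"missing values in {path}")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))
    spectra = []
    for col in df.columns:
        if col == WAVELENGTH_COLUMN:
            continue
        spectra.append(
            Spectrum(grid, df[col].to_numpy(dtype=float), kind="reflectance", name=col)
        )
    if not spectra:
        raise SpectrumError(f"no spectrum columns in {path}")
    return spectra


def write_spectra_csv(path, spectra: list[Spectrum]) -> None:
    """Write named spectra sharing one grid to CSV (inverse of read_spectra_csv)."""
    if not spectra:
        raise SpectrumError("nothing to write")
    grid = spectra[0].grid
    for s in spectra:
        if s.grid != grid:
            raise GridMismatchError("all spectra in one CSV must share a grid")
    data = {WAVELENGTH_COLUMN: grid.wavelengths()}
    for i, s in enumerate(spectra):
        name = s.name or f"spectrum_{i}"
        if name in data:
            raise SpectrumError(f"duplicate spectrum name {name!r}")
        data[name] = s.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def spectra_by_name(spectra: list[Spectrum]) -> dict[str, Spectrum]:
    return {s.name: s for s in spectra}
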