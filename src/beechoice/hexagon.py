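"""Colour-hexagon model of bee trichromatic vision (Chittka 1992).

A stimulus reflectance R(lambda) viewed against an adapting background under an
illuminant I(lambda) produces, in each of the bee's three photoreceptor classes
(UV, blue, green), a von Kries-adapted quantum catch

    P_i = R_i * integral( I(l) R(l) S_i(l) dl ),
    R_i = 1 / integral( I(l) R_B(l) S_i(l) dl ),

so the background itself always yields P = 1. Receptor excitation saturates as
E = P / (P + 1), mapping the background to 0.5, and the three excitations place
the stimulus at a 2-D locus

    x = (sqrt(3)/2) (E_g - E_u),    y = E_b - (E_u + E_g) / 2,

inside a unit-circumradius hexagon whose centre is the adapted background.
Perceptual distance between stimuli is the Euclidean distance between loci;
the distance from a locus to the centre is the stimulus's contrast against the
background, and its direction is the hue angle (0 deg = straight up,
increasing clockwise by default so the green vertex sits at 120 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import (
    DEFAULT_GRID,
    GridMismatchError,
    Spectrum,
    SpectrumError,
    WavelengthGrid,
    receptor_template,
    resample,
)

__all__ = [
    "ReceptorSet",
    "QuantumCatchTriplet",
    "ExcitationTriplet",
    "HexagonLocus",
    "ContrastReport",
    "HONEYBEE_LAMBDA_MAX",
    "quantum_catch",
    "excitation",
    "hexagon_locus",
    "color_angle",
    "contrast_report",
]

#: Honeybee (Apis mellifera) receptor peak wavelengths in nm: UV, blue, green.
HONEYBEE_LAMBDA_MAX = {"uv": 344.0, "blue": 436.0, "green": 544.0}

#: Below this centre distance the hue angle is treated as undefined.
ANGLE_TOLERANCE = 1e-6


@dataclass(frozen=True)
class ReceptorSet:
    """The three bee photoreceptor sensitivity curves on one shared grid."""

    uv: Spectrum
    blue: Spectrum
    green: Spectrum

    def __post_init__(self) -> None:
        if not (self.uv.grid == self.blue.grid == self.green.grid):
            raise GridMismatchError("receptor sensitivities must share a grid")
        for s in (self.uv, self.blue, self.green):
            if abs(s.values.max() - 1.0) > 1e-9:
                raise SpectrumError("receptor sensitivities must be peak-normalised to 1")

    @classmethod
    def honeybee(cls, grid: WavelengthGrid = DEFAULT_GRID) -> "ReceptorSet":
        """Template sensitivities at the honeybee peak wavelengths."""
        return cls(
            uv=receptor_template(HONEYBEE_LAMBDA_MAX["uv"], grid).with_name("uv"),
            blue=receptor_template(HONEYBEE_LAMBDA_MAX["blue"], grid).with_name("blue"),
            green=receptor_template(HONEYBEE_LAMBDA_MAX["green"], grid).with_name("green"),
        )

    @classmethod
    def from_spectra(cls, uv: Spectrum, blue: Spectrum, green: Spectrum) -> "ReceptorSet":
        """Measured sensitivity curves, re-normalised to unit peak."""
        def norm(s: Spectrum, name: str) -> Spectrum:
            peak = s.values.max()
            if peak <= 0:
                raise SpectrumError(f"{name} sensitivity is identically zero")
            return Spectrum(s.grid, s.values / peak, kind="sensitivity", name=name)

        return cls(norm(uv, "uv"), norm(blue, "blue"), norm(green, "green"))

    def resampled(self, grid: WavelengthGrid) -> "ReceptorSet":
        return ReceptorSet(
            resample(self.uv, grid), resample(self.blue, grid), resample(self.green, grid)
        )


@dataclass(frozen=True)
class QuantumCatchTriplet:
    """Background-adapted quantum catches; (1,1,1) when stimulus = background."""

    P_u: float
    P_b: float
    P_g: float

    def __post_init__(self) -> None:
        if not all(p > 0 for p in (self.P_u, self.P_b, self.P_g)):
            raise ValueError("quantum catches must be strictly positive")


@dataclass(frozen=True)
class ExcitationTriplet:
    """Receptor excitations E = P/(P+1), each in (0,1); background -> 0.5."""

    E_u: float
    E_b: float
    E_g: float


@dataclass(frozen=True)
class HexagonLocus:
    """A point in the colour hexagon with its polar description."""

    x: float
    y: float
    center_distance: float
    angle_deg: float | None  # None when the locus sits at the centre

    @property
    def angle_defined(self) -> bool:
        return self.angle_deg is not None


# ---------------------------------------------------------------------------
# Model stages
# ---------------------------------------------------------------------------

def _catch_one(stimulus, background, illuminant, sensitivity, wavelengths) -> float:
    numer = np.trapezoid(illuminant * stimulus * sensitivity, wavelengths)
    denom = np.trapezoid(illuminant * background * sensitivity, wavelengths)
    if denom <= 0:
        raise SpectrumError(
            "background quantum-catch integral is zero; adaptation undefined"
        )
    return float(numer / denom)


def quantum_catch(
    stimulus: Spectrum,
    background: Spectrum,
    illuminant: Spectrum,
    receptors: ReceptorSet,
) -> QuantumCatchTriplet:
    """Von Kries-adapted quantum catches of a stimulus against a background.

    All spectra must share one grid; integration is trapezoidal on that grid.
    """
    grid = stimulus.grid
    if not (background.grid == grid and illuminant.grid == grid and receptors.uv.grid == grid):
        raise GridMismatchError(
            "stimulus, background, illuminant, and receptors must share a grid"
        )
    wl = grid.wavelengths()
    return QuantumCatchTriplet(
        P_u=_catch_one(stimulus.values, background.values, illuminant.values, receptors.uv.values, wl),
        P_b=_catch_one(stimulus.values, background.values, illuminant.values, receptors.blue.values, wl),
        P_g=_catch_one(stimulus.values, background.values, illuminant.values, receptors.green.values, wl),
    )


def excitation(catch: QuantumCatchTriplet) -> ExcitationTriplet:
    """Saturating receptor excitation E = P/(P+1)."""
    return ExcitationTriplet(
        E_u=catch.P_u / (catch.P_u + 1.0),
        E_b=catch.P_b / (catch.P_b + 1.0),
        E_g=catch.P_g / (catch.P_g + 1.0),
    )


def hexagon_locus(E: ExcitationTriplet, orientation: str = "clockwise") -> HexagonLocus:
    """Place an excitation triplet in the hexagon and derive distance and angle."""
    for e in (E.E_u, E.E_b, E.E_g):
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"excitation {e} outside [0, 1]")
    x = (math.sqrt(3.0) / 2.0) * (E.E_g - E.E_u)
    y = E.E_b - 0.5 * (E.E_u + E.E_g)
    dist = math.hypot(x, y)
    angle = _angle_from_xy(x, y, dist, orientation)
    return HexagonLocus(x=x, y=y, center_distance=dist, angle_deg=angle)


def _angle_from_xy(x: float, y: float, dist: float, orientation: str) -> float | None:
    if dist < ANGLE_TOLERANCE:
        return None
    if orientation == "clockwise":
        ang = math.degrees(math.atan2(x, y))
    elif orientation == "counterclockwise":
        ang = math.degrees(math.atan2(-x, y))
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return ang % 360.0


def color_angle(locus: HexagonLocus) -> float:
    """Hue angle in degrees, 0 at vertical-up; undefined at the centre."""
    if locus.angle_deg is None:
        raise ValueError("hue angle undefined at the hexagon centre")
    return locus.angle_deg


def angular_difference(a_deg: float, b_deg: float) -> float:
    """Smallest absolute difference between two angles, in [0, 180]."""
    d = abs(a_deg - b_deg) % 360.0
    return min(d, 360.0 - d)


# ---------------------------------------------------------------------------
# Report over a set of stimuli
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastReport:
    """Per-stimulus hexagon loci plus the pairwise locus-distance matrix.

    ``loci`` columns: name, x, y, center_distance (the stimulus's contrast
    against the background, i.e. distance of its locus from the hexagon
    centre), angle_deg, green_contrast (|E_g - 0.5|, the conventional
    green-receptor achromatic signal, kept under its own name so the two
    contrast notions are never conflated).
    """

    loci: pd.DataFrame
    pairwise: pd.DataFrame


def contrast_report(
    stimuli: list[Spectrum],
    background: Spectrum,
    illuminant: Spectrum,
    receptors: ReceptorSet,
    orientation: str = "clockwise",
) -> ContrastReport:
    """Run the full hexagon pipeline over named stimuli.

    Inputs are resampled onto the background's grid, which every stimulus,
    the illuminant, and the receptors must cover.
    """
    if not stimuli:
        raise ValueError("contrast_report needs at least one stimulus")
    grid = background.grid
    illum = resample(illuminant, grid)
    recs = receptors.resampled(grid)
    rows = []
    loci: list[HexagonLocus] = []
    names: list[str] = []
    for i, stim in enumerate(stimuli):
        name = stim.name or f"stimulus_{i}"
        e = excitation(quantum_catch(resample(stim, grid), background, illum, recs))
        locus = hexagon_locus(e, orientation=orientation)
        rows.append(
            {
                "name": name,
                "x": locus.x,
                "y": locus.y,
                "center_distance": locus.center_distance,
                "angle_deg": locus.angle_deg,
                "green_contrast": abs(e.E_g - 0.5),
            }
        )
        loci.append(locus)
        names.append(name)
    loci_df = pd.DataFrame(rows)
    xy = np.array([[l.x, l.y] for l in loci])
    diff = xy[:, None, :] - xy[None, :, :]
    pair = pd.DataFrame(np.hypot(diff[..., 0], diff[..., 1]), index=names, columns=names)
    if len(names) < 2:
        pair = pair.iloc[0:0, 0:0]
    return ContrastReport(loci=loci_df, pairwise=pair)
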