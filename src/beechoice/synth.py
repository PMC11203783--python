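"""Synthetic inputs with the statistical structure the analyses assume.

No reflectance spectra, raw choice counts, EAG traces, or weighing sheets are
published for the study system this package models, so every pipeline stage is
exercised on generated data instead:

* cardboard-like reflectance spectra — smooth parametric curves (a long-pass
  step for yellow, a blue-centred Gaussian for blue, a mid-band bump for the
  green background). "Light" variants are convex mixtures of the parent
  reflectance with the background, which guarantees by construction the
  qualitative structure reported for the real cardboards: same hue direction,
  strictly smaller distance from the hexagon centre;
* two-choice records — independent Bernoulli first choices at a specified
  preference probability per trait and species;
* EAG tables — Bernoulli antennal responses per compound, or exact forced
  responder counts for reconstructing printed response grids;
* consumption weights — lognormal per-flower mg/h rates with depth-specific
  means, turned into nonincreasing weighings at 0, 40 min, and 2 h.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eag import CompoundPanel, EAGTable, reference_panel
from .preference import ChoiceDataset, ChoiceRecord, ConsumptionRecord
from .spectral import DEFAULT_GRID, Spectrum, WavelengthGrid

__all__ = [
    "SpectraParams",
    "ChoiceArm",
    "EAGArm",
    "ConsumptionParams",
    "SyntheticScenario",
    "default_scenario",
    "gen_cardboard_spectra",
    "gen_choices",
    "gen_eag_table",
    "gen_consumption",
]

SPECIES = ("O. bicornis", "L. villosulum", "B. terrestris")


@dataclass(frozen=True)
class SpectraParams:
    """Shape parameters of the synthetic cardboard set.

    Reflectance amplitudes are dimensionless in [0, 1.2]; wavelengths in nm.
    ``light_mix_weight`` is the convex weight of the parent colour when mixing
    it with the green background to make the "light" variant (0 = background,
    1 = parent).
    """

    yellow_edge_nm: float = 500.0
    yellow_edge_width_nm: float = 10.0
    yellow_high: float = 0.80
    blue_center_nm: float = 450.0
    blue_sigma_nm: float = 30.0
    blue_amplitude: float = 0.25
    green_center_nm: float = 550.0
    green_sigma_nm: float = 65.0
    green_amplitude: float = 0.30
    baseline: float = 0.12
    light_mix_weight: float = 0.50

    def __post_init__(self) -> None:
        for amp in (self.yellow_high, self.blue_amplitude, self.green_amplitude, self.baseline):
            if not 0.0 <= amp <= 1.2:
                raise ValueError(f"amplitude {amp} outside [0, 1.2]")
        if not 0.0 <= self.light_mix_weight <= 1.0:
            raise ValueError("light_mix_weight must be in [0, 1]")


@dataclass(frozen=True)
class ChoiceArm:
    """One two-choice experiment: trait x species with a true preference."""

    trait: str
    species: str
    preferred_variant: str
    other_variant: str
    p_preferred: float
    n_approaches: int
    block: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_preferred <= 1.0:
            raise ValueError("preference probability must be in [0, 1]")
        if self.n_approaches < 1:
            raise ValueError("need at least one approach")


@dataclass(frozen=True)
class EAGArm:
    """Antennal response probabilities for one species over a panel."""

    species: str
    n_antennae: int
    response_probability: dict[str, float]  # per compound name

    def __post_init__(self) -> None:
        if self.n_antennae < 1:
            raise ValueError("need at least one antenna")
        for p in self.response_probability.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("response probabilities must be in [0, 1]")


@dataclass(frozen=True)
class ConsumptionParams:
    """Lognormal per-flower consumption rates, mg/h, by flower depth."""

    mean_rate_flat_mg_h: float = 90.0
    mean_rate_deep_mg_h: float = 30.0
    log_sd: float = 0.4
    n_flat: int = 9
    n_deep: int = 9
    initial_weight_mg: float = 2000.0

    def __post_init__(self) -> None:
        if min(self.mean_rate_flat_mg_h, self.mean_rate_deep_mg_h) < 0:
            raise ValueError("mean rates must be nonnegative")
        if self.log_sd < 0:
            raise ValueError("dispersion must be nonnegative")
        if min(self.n_flat, self.n_deep) < 1:
            raise ValueError("need at least one flower per arm")


@dataclass(frozen=True)
class SyntheticScenario:
    """Everything needed to generate one full synthetic study."""

    seed: int = 0
    spectra: SpectraParams = field(default_factory=SpectraParams)
    choices: tuple[ChoiceArm, ...] = ()
    eag: tuple[EAGArm, ...] = ()
    consumption: ConsumptionParams = field(default_factory=ConsumptionParams)
    panel: CompoundPanel = field(default_factory=reference_panel)


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """The default study conditions.

    Approach counts per trait and species are the integer counts recovered by
    inverting the published coefficient table (no raw counts were released);
    they are reconstructions, not data. True preference probabilities are the
    corresponding empirical fractions. Antennae: 10 per bumblebee/mason-bee
    species, 6 for the sweat bee. Consumption: 9 flowers per depth arm, flat
    mean rate three times the deep mean.
    """
    # (trait, species, preferred, other, successes, failures) from inversion
    # of the per-species coefficient rows; preferred = modal variant.
    counts = [
        ("hue", "L. villosulum", "yellow", "blue", 39, 13),
        ("hue", "B. terrestris", "yellow", "blue", 148, 58),
        ("hue", "O. bicornis", "yellow", "blue", 11, 16),
        ("size", "B. terrestris", "large", "small", 59, 18),
        ("size", "O. bicornis", "large", "small", 23, 10),
        ("size", "L. villosulum", "large", "small", 32, 12),
        ("achromatic_contrast", "O. bicornis", "intense", "light", 30, 6),
        ("achromatic_contrast", "B. terrestris", "intense", "light", 121, 12),
        ("achromatic_contrast", "L. villosulum", "intense", "light", 39, 29),
        ("scent", "O. bicornis", "complex", "simple", 102, 91),
        ("scent", "B. terrestris", "simple", "complex", 216, 190),
        ("scent", "L. villosulum", "simple", "complex", 30, 22),
    ]
    arms = tuple(
        ChoiceArm(
            trait=trait,
            species=sp,
            preferred_variant=pref,
            other_variant=other,
            p_preferred=a / (a + b),
            n_approaches=a + b,
        )
        for trait, sp, pref, other, a, b in counts
    )
    panel = reference_panel()
    eag_arms = tuple(
        EAGArm(
            species=sp,
            n_antennae=n,
            response_probability={c.name: 0.9 for c in panel.compounds},
        )
        for sp, n in (("O. bicornis", 10), ("B. terrestris", 10), ("L. villosulum", 6))
    )
    return SyntheticScenario(seed=seed, choices=arms, eag=eag_arms, panel=panel)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _smooth_step(wl: np.ndarray, edge: float, width: float) -> np.ndarray:
    # logistic long-pass edge; smooth so coarse-grid quadrature stays accurate
    return 1.0 / (1.0 + np.exp(-(wl - edge) / width))


def gen_cardboard_spectra(
    params: SpectraParams = SpectraParams(),
    grid: WavelengthGrid = DEFAULT_GRID,
) -> dict[str, Spectrum]:
    """Synthetic cardboard reflectances: yellow, blue, light variants, background.

    Light variants are convex mixtures toward the background, so they share
    the parent's hue direction but sit closer to the hexagon centre.
    """
    wl = grid.wavelengths()
    base = params.baseline
    yellow = base + (params.yellow_high - base) * _smooth_step(
        wl, params.yellow_edge_nm, params.yellow_edge_width_nm
    )
    blue = base + params.blue_amplitude * np.exp(
        -0.5 * ((wl - params.blue_center_nm) / params.blue_sigma_nm) ** 2
    )
    green = base + params.green_amplitude * np.exp(
        -0.5 * ((wl - params.green_center_nm) / params.green_sigma_nm) ** 2
    )
    w = params.light_mix_weight
    spectra = {
        "yellow": yellow,
        "blue": blue,
        "light_yellow": w * yellow + (1.0 - w) * green,
        "light_blue": w * blue + (1.0 - w) * green,
        "green_background": green,
    }
    return {
        name: Spectrum(grid, vals, kind="reflectance", name=name)
        for name, vals in spectra.items()
    }


def gen_choices(scenario: SyntheticScenario) -> ChoiceDataset:
    """Independent Bernoulli first choices per arm, bit-reproducible by seed."""
    rng = np.random.default_rng(scenario.seed)
    records: list[ChoiceRecord] = []
    pairs: dict[str, tuple[str, str]] = {}
    for arm in scenario.choices:
        pair = tuple(sorted((arm.preferred_variant, arm.other_variant)))
        existing = pairs.setdefault(arm.trait, pair)
        if existing != pair:
            raise ValueError(
                f"trait {arm.trait!r} has conflicting variant pairs {existing} vs {pair}"
            )
        draws = rng.random(arm.n_approaches) < arm.p_preferred
        for i, hit in enumerate(draws):
            records.append(
                ChoiceRecord(
                    species=arm.species,
                    trait=arm.trait,
                    variant_chosen=arm.preferred_variant if hit else arm.other_variant,
                    block=arm.block,
                    replicate=i,
                )
            )
    return ChoiceDataset(records=records, variant_pairs=pairs)


def gen_eag_table(
    scenario: SyntheticScenario,
    species: str,
    forced_counts: dict[str, int] | None = None,
) -> EAGTable:
    """Binary antennal responses for one species.

    With ``forced_counts`` (compound name -> responder count) the table
    contains exactly that many responders per compound (the first antennae
    respond), which reconstructs a printed response grid deterministically;
    otherwise responses are Bernoulli draws at the arm's probabilities.
    """
    arm = next((a for a in scenario.eag if a.species == species), None)
    if arm is None:
        raise ValueError(f"no EAG arm for species {species!r}")
    rng = np.random.default_rng((scenario.seed, zlib.crc32(species.encode())))
    compounds = [c.name for c in scenario.panel.compounds]
    data = {}
    for name in compounds:
        if forced_counts is not None:
            k = forced_counts.get(name, 0)
            if not 0 <= k <= arm.n_antennae:
                raise ValueError(
                    f"forced count {k} for {name!r} outside 0..{arm.n_antennae}"
                )
            col = np.zeros(arm.n_antennae, dtype=int)
            col[:k] = 1
        else:
            p = arm.response_probability.get(name, 0.0)
            col = (rng.random(arm.n_antennae) < p).astype(int)
        data[name] = col
    responses = pd.DataFrame(
        data, index=[f"{species}_{i + 1}" for i in range(arm.n_antennae)]
    )
    responses.index.name = "antenna_id"
    return EAGTable(species=species, responses=responses)


def gen_consumption(scenario: SyntheticScenario) -> list[ConsumptionRecord]:
    """Per-flower weighings at t0/40 min/2 h from lognormal mg/h rates."""
    p = scenario.consumption
    rng = np.random.default_rng((scenario.seed, 7))
    records: list[ConsumptionRecord] = []
    for depth, n, mean in (
        ("flat", p.n_flat, p.mean_rate_flat_mg_h),
        ("deep", p.n_deep, p.mean_rate_deep_mg_h),
    ):
        if p.log_sd == 0 or mean == 0:
            rates = np.full(n, mean)
        else:
            mu = np.log(mean) - p.log_sd**2 / 2.0
            rates = rng.lognormal(mean=mu, sigma=p.log_sd, size=n)
        for i, rate in enumerate(rates):
            w0 = p.initial_weight_mg
            records.append(
                ConsumptionRecord(
                    flower_id=f"{depth}_{i + 1}",
                    depth=depth,
                    weight_mg_at={
                        "t0": w0,
                        "t40min": max(w0 - rate * (40.0 / 60.0), 0.0),
                        "t2h": max(w0 - rate * 2.0, 0.0),
                    },
                )
            )
    return records
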