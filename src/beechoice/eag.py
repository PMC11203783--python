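"""GC-EAD antennal-activity scoring and scent-mixture composition math.

In gas chromatography with electroantennographic detection an excised bee
antenna acts as the second detector: each eluting volatile either does or does
not elicit a depolarisation. Per species, responses are counted over antennae
(one antenna per female) and a compound is classified as electrophysiologically
active when at least half of the tested antennae responded. Response calling
from raw traces is upstream of this module; it ingests already-called binary
tables.

The mixture math converts a total substance concentration shared equally among
n volatiles into per-substance concentrations and applied masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Compound",
    "CompoundPanel",
    "EAGTable",
    "MixtureSpec",
    "reference_panel",
    "activity_summary",
    "classify_active",
    "per_substance_concentration",
    "applied_mass",
    "panel_balance_report",
]

SUBSTANCE_CLASSES = ("monoterpene", "benzenoid", "sesquiterpene")

#: A compound is active when >= this fraction of tested antennae responded.
ACTIVITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class Compound:
    """One floral volatile: chromatographic and panel metadata."""

    name: str
    retention_index: float
    substance_class: str
    mixture_id: int

    def __post_init__(self) -> None:
        if self.retention_index <= 0:
            raise ValueError("retention index must be positive")
        if self.substance_class not in SUBSTANCE_CLASSES:
            raise ValueError(f"unknown substance class {self.substance_class!r}")


@dataclass(frozen=True)
class CompoundPanel:
    """The tested volatile panel; simple mixtures partition the complex one."""

    compounds: tuple[Compound, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compound names in panel")

    def mixture(self, mixture_id: int) -> list[Compound]:
        return [c for c in self.compounds if c.mixture_id == mixture_id]

    @property
    def mixture_ids(self) -> list[int]:
        return sorted({c.mixture_id for c in self.compounds})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": c.name,
                    "retention_index": c.retention_index,
                    "substance_class": c.substance_class,
                    "mixture_id": c.mixture_id,
                }
                for c in self.compounds
            ]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CompoundPanel":
        return cls(
            tuple(
                Compound(
                    name=str(r.name),
                    retention_index=float(r.retention_index),
                    substance_class=str(r.substance_class),
                    mixture_id=int(r.mixture_id),
                )
                for r in df.itertuples(index=False)
            )
        )

    @classmethod
    def from_csv(cls, path) -> "CompoundPanel":
        return cls.from_dataframe(pd.read_csv(path))


# The 12-volatile panel used in the behavioural and GC-EAD experiments:
# (name, retention index, substance class, simple-mixture id).
_REFERENCE_PANEL = (
    ("beta-myrcene", 986, "monoterpene", 3),
    ("eucalyptol", 1032, "monoterpene", 2),
    ("(E)-beta-ocimene", 1045, "monoterpene", 1),
    ("gamma-terpinene", 1058, "monoterpene", 2),
    ("beta-linalool", 1099, "monoterpene", 1),
    ("2-phenylethanol", 1112, "benzenoid", 2),
    ("methyl salicylate", 1194, "benzenoid", 3),
    ("2-phenethyl acetate", 1255, "benzenoid", 1),
    ("eugenol", 1353, "benzenoid", 3),
    ("benzyl isovalerate", 1396, "benzenoid", 1),
    ("beta-caryophyllene", 1426, "sesquiterpene", 3),
    ("hexahydro farnesyl acetone", 1840, "sesquiterpene", 2),
)


def reference_panel() -> CompoundPanel:
    """The 12-compound floral-volatile panel (3 simple mixtures of 4)."""
    return CompoundPanel(
        tuple(Compound(n, ri, cls_, mix) for n, ri, cls_, mix in _REFERENCE_PANEL)
    )


@dataclass(frozen=True)
class EAGTable:
    """Binary antenna x compound response matrix for one species."""

    species: str
    responses: pd.DataFrame  # index: antenna ids; columns: compound names; 0/1

    def __post_init__(self) -> None:
        vals = self.responses.to_numpy()
        if vals.size == 0:
            raise ValueError("empty EAG table")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("EAG responses must be 0/1")
        if self.responses.index.duplicated().any():
            raise ValueError("duplicate antenna ids (one antenna per female)")

    @classmethod
    def from_csv(cls, path) -> "EAGTable":
        df = pd.read_csv(path)
        for col in ("species", "antenna_id"):
            if col not in df.columns:
                raise ValueError(f"EAG CSV missing column {col!r}")
        species = df["species"].unique()
        if len(species) != 1:
            raise ValueError("one EAG table holds exactly one species")
        responses = df.drop(columns=["species"]).set_index("antenna_id")
        return cls(species=str(species[0]), responses=responses)

    def to_csv(self, path) -> None:
        out = self.responses.reset_index(names="antenna_id")
        out.insert(0, "species", self.species)
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _format_percent(fraction: float, convention: str) -> float:
    pct = 100.0 * fraction
    if convention == "round":
        return round(pct, 1)
    if convention == "truncate":
        return math.floor(pct * 10.0) / 10.0
    raise ValueError(f"unknown display convention {convention!r}")


def activity_summary(table: EAGTable, display: str = "round") -> pd.DataFrame:
    """Per-compound responder counts and percentages.

    Columns: compound, responders, n, fraction (exact), percent (display value
    under the chosen convention — some published tables truncate, e.g. 4/6
    printed as 66%, so the exact fraction is always carried alongside).
    """
    counts = table.responses.sum(axis=0)
    n = len(table.responses)
    rows = [
        {
            "compound": compound,
            "responders": int(c),
            "n": n,
            "fraction": c / n,
            "percent": _format_percent(c / n, display),
        }
        for compound, c in counts.items()
    ]
    return pd.DataFrame(rows)


def classify_active(summary: pd.DataFrame, threshold: float = ACTIVITY_THRESHOLD) -> pd.Series:
    """Active iff the exact response fraction is at least the threshold (inclusive)."""
    return pd.Series(
        (summary["fraction"] >= threshold - 1e-12).to_numpy(),
        index=summary["compound"],
        name="active",
    )


# ---------------------------------------------------------------------------
# Mixture composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    """A scent mixture: total concentration split equally over n substances."""

    total_concentration_ug_ml: float
    n_substances: int
    applied_volume_ul: float = 30.0

    def __post_init__(self) -> None:
        if self.total_concentration_ug_ml < 0:
            raise ValueError("total concentration must be nonnegative")
        if self.n_substances < 1:
            raise ValueError("a mixture needs at least one substance")
        if self.applied_volume_ul <= 0:
            raise ValueError("applied volume must be positive")


def per_substance_concentration(spec: MixtureSpec) -> float:
    """Concentration of each substance in ug/mL (equal-volume split)."""
    return spec.total_concentration_ug_ml / spec.n_substances


def applied_mass(spec: MixtureSpec) -> float:
    """Total substance mass delivered per application, in ng.

    volume [uL] x concentration [ug/mL] = mass [ng], since
    1 uL x 1 ug/mL = 1e-6 L x 1e-3 g/L x ... = 1e-9 g = 1 ng.
    """
    return spec.applied_volume_ul * spec.total_concentration_ug_ml


# ---------------------------------------------------------------------------
# Panel structure
# ---------------------------------------------------------------------------

def panel_balance_report(panel: CompoundPanel) -> pd.DataFrame:
    """Substance-class counts per simple mixture and for the complex mixture.

    The ``balanced`` flag marks mixtures whose class counts deviate from a
    perfectly equal split of that mixture's size across the classes present
    in the panel (an exactly equal split is impossible when the mixture size
    is not a multiple of the class count; such rows are flagged).
    """
    if not panel.compounds:
        return pd.DataFrame(
            columns=["mixture", *SUBSTANCE_CLASSES, "n", "balanced"]
        )
    rows = []
    groups = [(str(mid), panel.mixture(mid)) for mid in panel.mixture_ids]
    groups.append(("complex", list(panel.compounds)))
    classes_present = sorted(
        {c.substance_class for c in panel.compounds},
        key=SUBSTANCE_CLASSES.index,
    )
    for label, compounds in groups:
        counts = {cls_: 0 for cls_ in SUBSTANCE_CLASSES}
        for c in compounds:
            counts[c.substance_class] += 1
        present = [counts[cls_] for cls_ in classes_present]
        balanced = max(present) - min(present) <= (
            0 if len(compounds) % len(classes_present) == 0 else 1
        )
        rows.append({"mixture": label, **counts, "n": len(compounds), "balanced": balanced})
    return pd.DataFrame(rows)
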