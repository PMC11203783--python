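"""Two-choice preference inference and consumption-rate comparison.

Each two-choice assay records which of two artificial-flower variants a bee
approached first. Preference for a trait (hue, size, achromatic contrast,
scent complexity, depth) is inferred with a binomial logistic GLM: the
intercept of a per-species, intercept-only fit is the log-odds of choosing the
"success" variant, tested against zero with a Wald z. Global fits pool species
as a fixed factor; base colour or scent-mixture identity can enter as a
further factor.

Because published reports usually print only the coefficient table, not the
raw counts, the module also provides the inverse operation: recover the
integer (successes, failures) pair behind a printed (estimate, SE) using the
closed forms estimate = ln(a/b), SE = sqrt(1/a + 1/b).

Consumption analysis converts flower weighings into mg/h rates and compares
flat against deep flowers with a Mann-Whitney U test (exact enumeration for
small samples, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ChoiceRecord",
    "ChoiceDataset",
    "CoefEstimate",
    "GlmFit",
    "RecoveredCounts",
    "ConsumptionRecord",
    "fit_two_choice",
    "intercept_closed_form",
    "recover_counts",
    "consumption_rate",
    "mann_whitney",
    "depth_comparison",
    "preference_table",
]

TRAITS = ("hue", "size", "achromatic_contrast", "scent", "depth")


class SeparationError(ValueError):
    """Raised internally when one variant has zero choices (flagged, not thrown)."""


@dataclass(frozen=True)
class ChoiceRecord:
    """One first choice of one female bee in a two-choice assay."""

    species: str
    trait: str
    variant_chosen: str
    block: str = ""
    replicate: int = 0


@dataclass
class ChoiceDataset:
    """Choice records plus, per trait, the ordered pair of variant labels."""

    records: list[ChoiceRecord]
    variant_pairs: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.trait not in self.variant_pairs:
                raise ValueError(f"record trait {r.trait!r} has no variant pair")
            if r.variant_chosen not in self.variant_pairs[r.trait]:
                raise ValueError(
                    f"choice {r.variant_chosen!r} is not a variant of trait {r.trait!r}"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": r.species,
                    "trait": r.trait,
                    "block": r.block,
                    "replicate": r.replicate,
                    "variant_chosen": r.variant_chosen,
                }
                for r in self.records
            ]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ChoiceDataset":
        required = {"species", "trait", "variant_chosen"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"choices table missing columns: {sorted(missing)}")
        pairs: dict[str, tuple[str, str]] = {}
        for trait, sub in df.groupby("trait"):
            labels = sorted(sub["variant_chosen"].unique())
            if len(labels) > 2:
                raise ValueError(f"trait {trait!r} has more than two variants: {labels}")
            if len(labels) == 1:
                labels = [labels[0], labels[0] + "_other"]
            pairs[str(trait)] = (labels[0], labels[1])
        records = [
            ChoiceRecord(
                species=str(row.species),
                trait=str(row.trait),
                variant_chosen=str(row.variant_chosen),
                block=str(getattr(row, "block", "") or ""),
                replicate=int(getattr(row, "replicate", 0) or 0),
            )
            for row in df.itertuples()
        ]
        return cls(records=records, variant_pairs=pairs)

    @classmethod
    def from_csv(cls, path) -> "ChoiceDataset":
        return cls.from_dataframe(pd.read_csv(path))

    @classmethod
    def from_counts(
        cls,
        successes: int,
        failures: int,
        trait: str = "hue",
        species: str = "species",
        pair: tuple[str, str] = ("blue", "yellow"),
        block: str = "",
    ) -> "ChoiceDataset":
        """Expand an aggregated (successes, failures) pair into records.

        The success label is the alphabetically second element of ``pair``,
        matching the default outcome coding of :func:`fit_two_choice`.
        """
        first, second = sorted(pair)
        records = [
            ChoiceRecord(species, trait, second, block, i) for i in range(successes)
        ] + [
            ChoiceRecord(species, trait, first, block, successes + i)
            for i in range(failures)
        ]
        return cls(records=records, variant_pairs={trait: (first, second)})


class CoefEstimate(NamedTuple):
    estimate: float
    std_error: float
    z_value: float
    p_value: float


@dataclass(frozen=True)
class GlmFit:
    """Binomial-logit fit summary: per-coefficient Wald statistics."""

    coefficients: dict[str, CoefEstimate]
    model_spec: str
    n_obs: int
    success_level: str
    separation: bool = False

    @property
    def intercept(self) -> CoefEstimate:
        return self.coefficients["Intercept"]


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_two_choice(
    dataset: ChoiceDataset,
    trait: str,
    species: str | None = None,
    covariate: str | None = None,
    success_level: str | None = None,
) -> GlmFit:
    """Binomial logistic fit of a two-choice experiment.

    With ``species`` given, fits that species' subset; intercept-only unless a
    ``covariate`` ("block") is added. Without ``species``, all species enter
    as a fixed factor. The success level defaults to the alphabetically second
    variant label, which makes the intercept the log-odds of e.g. "yellow"
    over "blue".

    Complete separation (one variant never chosen) is reported as a flagged
    infinite estimate rather than raising.
    """
    if trait not in dataset.variant_pairs:
        raise ValueError(f"unknown trait {trait!r}")
    pair = dataset.variant_pairs[trait]
    success = success_level if success_level is not None else sorted(pair)[1]
    if success not in pair:
        raise ValueError(f"success level {success!r} not among variants {pair}")

    rows = [
        r
        for r in dataset.records
        if r.trait == trait and (species is None or r.species == species)
    ]
    if not rows:
        raise ValueError(f"no records for trait {trait!r}" + (f", species {species!r}" if species else ""))
    df = pd.DataFrame(
        {
            "chose": [1.0 if r.variant_chosen == success else 0.0 for r in rows],
            "species": [r.species for r in rows],
            "block": [r.block for r in rows],
        }
    )

    terms = ["1"]
    if species is None and df["species"].nunique() > 1:
        terms.append("C(species)")
    if covariate is not None:
        if covariate not in ("block",):
            raise ValueError(f"unsupported covariate {covariate!r}")
        if df[covariate].nunique() > 1:
            terms.append(f"C({covariate})")
    formula = "chose ~ " + " + ".join(terms)

    n_succ = int(df["chose"].sum())
    n_fail = len(df) - n_succ
    if n_succ == 0 or n_fail == 0:
        sign = 1.0 if n_fail == 0 else -1.0
        coef = CoefEstimate(sign * math.inf, math.inf, math.nan, math.nan)
        return GlmFit(
            coefficients={"Intercept": coef},
            model_spec=formula + " [separated]",
            n_obs=len(df),
            success_level=success,
            separation=True,
        )

    # tight IRLS tolerance so intercept-only fits match the closed form to 1e-6
    fit = smf.glm(formula, data=df, family=sm.families.Binomial()).fit(
        maxiter=200, tol=1e-12
    )
    coefs = {
        name: CoefEstimate(
            estimate=float(fit.params[name]),
            std_error=float(fit.bse[name]),
            z_value=float(fit.tvalues[name]),
            p_value=float(fit.pvalues[name]),
        )
        for name in fit.params.index
    }
    return GlmFit(
        coefficients=coefs,
        model_spec=formula,
        n_obs=len(df),
        success_level=success,
    )


def intercept_closed_form(a: int, b: int) -> tuple[float, float]:
    """Closed-form intercept of the saturated two-count logit fit.

    For a successes and b failures the MLE intercept is ln(a/b) with
    standard error sqrt(1/a + 1/b).
    """
    if a < 1 or b < 1:
        raise ValueError("both counts must be >= 1 for a finite estimate")
    return math.log(a / b), math.sqrt(1.0 / a + 1.0 / b)


class RecoveredCounts(NamedTuple):
    successes: int
    failures: int
    unique: bool


def recover_counts(
    estimate: float,
    std_error: float,
    z: float | None = None,
    max_total: int = 500,
) -> RecoveredCounts:
    """Invert a printed (estimate, SE) pair back to integer choice counts.

    Searches every (a, b) with a + b <= max_total whose closed-form
    ln(a/b) and sqrt(1/a + 1/b) both round to the inputs at 3 decimals and
    returns the pair minimising the squared discrepancy to the unrounded
    inputs. ``unique`` is False when several pairs match the printed
    rounding. A printed Wald ``z``, when supplied, is added as a third
    rounding constraint and discrepancy term — printed tables occasionally
    admit two count pairs on (estimate, SE) alone that differ in the third
    decimal of z.
    """
    if std_error <= 0:
        raise ValueError("standard error must be positive")
    a = np.arange(1, max_total)
    aa, bb = np.meshgrid(a, a, indexing="ij")
    mask = aa + bb <= max_total
    aa, bb = aa[mask], bb[mask]
    est = np.log(aa / bb)
    se = np.sqrt(1.0 / aa + 1.0 / bb)
    match = (np.round(est, 3) == round(estimate, 3)) & (np.round(se, 3) == round(std_error, 3))
    disc = (est - estimate) ** 2 + (se - std_error) ** 2
    if z is not None:
        zz = est / se
        match &= np.round(zz, 3) == round(z, 3)
        disc = disc + (zz - z) ** 2
    if not match.any():
        raise ValueError(
            f"no integer counts with total <= {max_total} reproduce "
            f"({estimate}, {std_error}) at 3-decimal rounding"
        )
    idx = np.flatnonzero(match)
    best = idx[np.argmin(disc[idx])]
    return RecoveredCounts(int(aa[best]), int(bb[best]), unique=len(idx) == 1)


# ---------------------------------------------------------------------------
# Consumption
# ---------------------------------------------------------------------------

#: Weighing windows: label -> (start field, end field, duration in hours).
_WINDOWS = {
    "40min": ("t0", "t40min", 40.0 / 60.0),
    "2h": ("t0", "t2h", 2.0),
}


@dataclass(frozen=True)
class ConsumptionRecord:
    """Sugar-water weights of one artificial flower at three timepoints (mg)."""

    flower_id: str
    depth: str  # "flat" or "deep"
    weight_mg_at: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth not in ("flat", "deep"):
            raise ValueError(f"depth must be 'flat' or 'deep', got {self.depth!r}")
        order = [self.weight_mg_at.get(k) for k in ("t0", "t40min", "t2h")]
        known = [w for w in order if w is not None and not math.isnan(w)]
        if any(later > earlier + 1e-9 for earlier, later in zip(known, known[1:])):
            warnings.warn(
                f"flower {self.flower_id}: weight increased over time "
                "(evaporation/condensation artefact?)",
                stacklevel=2,
            )


def consumption_rate(rec: ConsumptionRecord, window: str = "40min") -> float:
    """Mass loss per hour (mg/h) over a weighing window.

    Negative losses (weight gain) are clipped to 0 with a warning.
    """
    if window not in _WINDOWS:
        raise ValueError(f"window must be one of {sorted(_WINDOWS)}, got {window!r}")
    start_key, end_key, hours = _WINDOWS[window]
    for key in (start_key, end_key):
        w = rec.weight_mg_at.get(key)
        if w is None or math.isnan(w):
            raise ValueError(f"flower {rec.flower_id}: missing weight at {key}")
    loss = rec.weight_mg_at[start_key] - rec.weight_mg_at[end_key]
    if loss < 0:
        warnings.warn(
            f"flower {rec.flower_id}: negative consumption clipped to 0", stacklevel=2
        )
        loss = 0.0
    return loss / hours


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    ``mode='exact'`` enumerates every assignment of the pooled observations
    to the two groups (feasible for combined n <= 12 and correct under
    ties); ``mode='normal'`` uses the tie-corrected normal approximation;
    ``mode='auto'`` picks exact when combined n <= 12. Returns the U of the
    first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(combined)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    mu = nx * ny / 2.0

    if mode == "auto":
        mode = "exact" if nx + ny <= 12 else "normal"
    if mode == "exact":
        n = nx + ny
        stat_obs = abs(u_x - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n), nx):
            u = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if abs(u - mu) >= stat_obs - 1e-9:
                hits += 1
        return u_x, hits / total
    if mode == "normal":
        if np.ptp(combined) == 0:
            return u_x, 1.0
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


CONSUMPTION_COLUMNS = ("flower_id", "depth", "weight_mg_t0", "weight_mg_t40", "weight_mg_t2h")


def consumption_to_dataframe(records: list[ConsumptionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "flower_id": r.flower_id,
                "depth": r.depth,
                "weight_mg_t0": r.weight_mg_at.get("t0"),
                "weight_mg_t40": r.weight_mg_at.get("t40min"),
                "weight_mg_t2h": r.weight_mg_at.get("t2h"),
            }
            for r in records
        ]
    )


def consumption_from_dataframe(df: pd.DataFrame) -> list[ConsumptionRecord]:
    missing = set(CONSUMPTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"consumption table missing columns: {sorted(missing)}")
    return [
        ConsumptionRecord(
            flower_id=str(row.flower_id),
            depth=str(row.depth),
            weight_mg_at={
                "t0": float(row.weight_mg_t0),
                "t40min": float(row.weight_mg_t40),
                "t2h": float(row.weight_mg_t2h),
            },
        )
        for row in df.itertuples(index=False)
    ]


def consumption_from_csv(path) -> list[ConsumptionRecord]:
    return consumption_from_dataframe(pd.read_csv(path))


def depth_comparison(
    records: list[ConsumptionRecord], window: str = "40min", mode: str = "auto"
) -> dict:
    """Compare flat vs deep consumption rates with a Mann-Whitney U test."""
    flat = [consumption_rate(r, window) for r in records if r.depth == "flat"]
    deep = [consumption_rate(r, window) for r in records if r.depth == "deep"]
    if not flat or not deep:
        raise ValueError("need at least one flat and one deep flower")
    u, p = mann_whitney(flat, deep, mode=mode)
    return {
        "window": window,
        "n_flat": len(flat),
        "n_deep": len(deep),
        "mean_rate_flat_mg_h": float(np.mean(flat)),
        "mean_rate_deep_mg_h": float(np.mean(deep)),
        "U": u,
        "p_value": p,
    }


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def preference_table(dataset: ChoiceDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Per-trait, per-species preference summary in the coefficient-table style.

    The preferred column names the variant on the favourable side of a
    significant intercept (two-sided Wald, strict p < alpha), "no preference"
    otherwise. Unanimous samples (complete separation) report the unanimous
    variant with NaN test statistics and the separation flag set.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    traits = sorted({r.trait for r in dataset.records})
    for trait in traits:
        pair = dataset.variant_pairs[trait]
        first, second = sorted(pair)
        species_list = sorted({r.species for r in dataset.records if r.trait == trait})
        for species in species_list:
            fit = fit_two_choice(dataset, trait, species=species)
            est = fit.intercept.estimate
            if fit.separation:
                preferred = second if est > 0 else first
            elif fit.intercept.p_value < alpha:
                preferred = second if est > 0 else first
            else:
                preferred = "no preference"
            rows.append(
                {
                    "trait": trait,
                    "species": species,
                    "n": fit.n_obs,
                    "preferred": preferred,
                    "estimate": est,
                    "std_error": fit.intercept.std_error,
                    "z_value": fit.intercept.z_value,
                    "p_value": fit.intercept.p_value,
                    "separation": fit.separation,
                }
            )
    return pd.DataFrame(rows)
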