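"""Statistical comparisons linking fibroin architecture to silk mechanics.

Covers the three analyses of the study design: Pearson correlation of
amino-acid frequency vectors between species, Welch two-sample tests of
tensile properties between species groups, and the species-level trend of
a mechanical property against the predicted crystalline fraction (one
point per species, negative slope expected for tensile strength).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, UndefinedCorrelationError
from .simulate import MechRecord

MECH_PROPERTIES = (
    "tensile_strength",
    "youngs_modulus",
    "extensibility",
    "toughness",
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    group_means: tuple[float, float]
    # Welch's unequal-variance form; the study reports raw two-sided p-values.
    method: str = "welch_two_sided"


@dataclass(frozen=True)
class TrendResult:
    property: str
    r: float
    p: float
    slope: float
    monotone_decreasing: bool
    n_species: int


def _as_mech_frame(mech) -> pd.DataFrame:
    if isinstance(mech, pd.DataFrame):
        return mech
    return pd.DataFrame([vars(r) if not isinstance(r, MechRecord) else r.__dict__ for r in mech])


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length vectors")
    if x.size < 3:
        raise InputError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=x.size, p=float(res.pvalue))


def welch_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Welch (unequal-variance) two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
    )


def crystallinity_trend(
    mech,
    cryst,
    property: str = "tensile_strength",
) -> TrendResult:
    """Species-level trend of a mechanical property vs crystalline fraction.

    Joins the two tables on species, averages the property per species,
    and computes Pearson r plus the least-squares slope against the
    crystalline fraction.  ``monotone_decreasing`` is true iff species
    ranked by fraction have strictly decreasing property means.
    """
    mech = _as_mech_frame(mech)
    cryst = cryst if isinstance(cryst, pd.DataFrame) else pd.DataFrame(
        [r.__dict__ for r in cryst]
    )
    if property not in MECH_PROPERTIES:
        raise InputError(f"unknown property {property!r}")
    means = (
        mech.groupby("species", sort=True)[property].mean().reset_index()
    )
    joined = means.merge(cryst, on="species", how="inner")
    if len(joined) < 3:
        raise InputError("need at least 3 species present in both tables")
    frac = joined["crystalline_fraction"].to_numpy(dtype=float)
    prop = joined[property].to_numpy(dtype=float)
    corr = pearson_r(frac, prop)
    slope = float(np.polyfit(frac, prop, 1)[0])
    order = np.argsort(frac)
    ranked = prop[order]
    monotone = bool(np.all(np.diff(ranked) < 0))
    return TrendResult(
        property=property,
        r=corr.r,
        p=corr.p,
        slope=slope,
        monotone_decreasing=monotone,
        n_species=len(joined),
    )


def tensile_summary(mech) -> pd.DataFrame:
    """Per-species n, mean, SD, min, max of the four tensile properties.

    SD is reported as 0 for singleton species, flagged by ``n == 1``.
    Rows are ordered by species name.
    """
    mech = _as_mech_frame(mech)
    if mech.empty:
        raise InputError("mechanics table is empty")
    rows = []
    for species, grp in mech.groupby("species", sort=True):
        row: dict[str, float | str | int] = {"species": species, "n": len(grp)}
        for prop in MECH_PROPERTIES:
            vals = grp[prop].to_numpy(dtype=float)
            row[f"{prop}_mean"] = float(vals.mean())
            row[f"{prop}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            row[f"{prop}_min"] = float(vals.min())
            row[f"{prop}_max"] = float(vals.max())
        rows.append(row)
    return pd.DataFrame(rows)
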