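"""Composite fitness scores and selection regressions on OR contributions.

Pre-dispersive fitness is the per-plant product fruit_set × seed_set,
normalized by the largest product within the plant's ploidy (so each ploidy's
best plant scores 1). Post-dispersive fitness is the three-way product
survival × germination × leaf_number, normalized the same way. Per trait and
ploidy, ordinary least squares regresses fitness on the normalized OR
contribution of maximum- or reduced-class plants; a positive slope means
plants whose trait responded more positively to outcrossing also realized
higher fitness — the signature of selection on the outbreeding response
itself rather than on the trait value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .orstats import individual_contributions
from .traits import COMPARISONS, PLOIDIES, trait_columns

logger = logging.getLogger(__name__)

PRE_COMPONENTS = ("fruit_set", "seed_set")
POST_COMPONENTS = ("survival", "germination", "leaf_number")


@dataclass(frozen=True)
class RegressionResult:
    """OLS of composite fitness on the normalized OR contribution of one trait."""

    trait: str
    ploidy: int
    comparison: str
    fitness_type: str  # "pre" or "post"
    slope: float
    intercept: float
    se: float
    p_value: float
    n: int
    r_squared: float
    degenerate: bool = False  # zero-variance predictor or response

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Star coding: **** p<0.0001, *** p<0.001, ** p<0.01, * p<0.05."""
    if not np.isfinite(p):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""


def _normalized_product(table: pd.DataFrame, components: tuple[str, ...]) -> pd.Series:
    for c in components:
        if c not in table.columns:
            raise ValidationError(f"fitness component column {c!r} missing from table")
    prod = table[components[0]].copy()
    for c in components[1:]:
        prod = prod * table[c]
    out = pd.Series(np.nan, index=table.index, name="fitness")
    for ploidy, sub in prod.groupby(table["ploidy"]):
        mx = sub.max(skipna=True)
        if pd.isna(mx):
            continue
        if mx == 0:
            warnings.warn(f"all fitness products zero for ploidy {ploidy}; scores left at 0")
            out.loc[sub.index] = sub
        else:
            out.loc[sub.index] = sub / mx
    return out


def pre_dispersive_fitness(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plant fruit_set × seed_set, normalized by the within-ploidy maximum."""
    fit = _normalized_product(table, PRE_COMPONENTS)
    return pd.DataFrame({
        "plant_id": table["plant_id"], "ploidy": table["ploidy"],
        "het_class": table["het_class"], "fitness": fit, "fitness_type": "pre",
    })


def post_dispersive_fitness(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plant survival × germination × leaf_number, normalized within ploidy."""
    fit = _normalized_product(table, POST_COMPONENTS)
    return pd.DataFrame({
        "plant_id": table["plant_id"], "ploidy": table["ploidy"],
        "het_class": table["het_class"], "fitness": fit, "fitness_type": "post",
    })


def regress_fitness_on_or(
    fitness: pd.DataFrame,
    contributions: pd.DataFrame,
    trait: str,
    ploidy: int,
    comparison: str,
    fitness_type: str = "pre",
) -> RegressionResult:
    """OLS slope of composite fitness on or_norm for one trait × ploidy × comparison.

    Null-class plants never enter (contributions are defined only for the
    maximum/reduced classes). A zero-variance predictor yields a degenerate
    result flagged rather than raised.
    """
    sub = contributions[
        (contributions["trait"] == trait)
        & (contributions["ploidy"] == ploidy)
        & (contributions["het_class"] == comparison)
    ][["plant_id", "or_norm"]]
    merged = sub.merge(fitness[["plant_id", "fitness"]], on="plant_id").dropna()
    n = len(merged)
    base = dict(trait=trait, ploidy=ploidy, comparison=comparison, fitness_type=fitness_type)
    if n < 3:
        return RegressionResult(**base, slope=np.nan, intercept=np.nan, se=np.nan,
                                p_value=np.nan, n=n, r_squared=np.nan, degenerate=True)
    x = merged["or_norm"].to_numpy()
    y = merged["fitness"].to_numpy()
    if np.ptp(x) == 0:
        return RegressionResult(**base, slope=np.nan, intercept=float(y.mean()), se=np.nan,
                                p_value=np.nan, n=n, r_squared=np.nan, degenerate=True)
    if np.ptp(y) == 0:
        return RegressionResult(**base, slope=0.0, intercept=float(y[0]), se=0.0,
                                p_value=1.0, n=n, r_squared=0.0, degenerate=True)
    res = stats.linregress(x, y)
    return RegressionResult(
        **base, slope=float(res.slope), intercept=float(res.intercept),
        se=float(res.stderr), p_value=float(res.pvalue), n=n,
        r_squared=float(res.rvalue**2),
    )


def selection_table(
    table: pd.DataFrame,
    fitness_types: tuple[str, ...] = ("pre", "post"),
) -> pd.DataFrame:
    """Full selection grid: trait × ploidy × comparison × fitness type.

    Ploidies without both het classes, or cells with < 3 usable plants, are
    emitted with ``degenerate = True`` rather than dropped.
    """
    contributions = individual_contributions(table)
    fits = {"pre": pre_dispersive_fitness, "post": post_dispersive_fitness}
    rows = []
    for ftype in fitness_types:
        if ftype not in fits:
            raise ValidationError(f"fitness_type must be 'pre' or 'post', got {ftype!r}")
        fitness = fits[ftype](table)
        for ploidy in PLOIDIES:
            for comparison in COMPARISONS:
                for trait in trait_columns(table):
                    r = regress_fitness_on_or(
                        fitness, contributions, trait, ploidy, comparison, ftype)
                    rows.append({
                        "trait": r.trait, "ploidy": r.ploidy, "comparison": r.comparison,
                        "fitness_type": r.fitness_type, "slope": r.slope,
                        "intercept": r.intercept, "se": r.se, "p": r.p_value,
                        "stars": r.stars, "n": r.n, "r_squared": r.r_squared,
                        "degenerate": r.degenerate,
                    })
    return pd.DataFrame(rows)
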