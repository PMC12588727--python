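"""The outbreeding-response (OR) index, bootstrap CIs and per-plant contributions.

OR compares a trait mean in a heterozygous group (μi; the first-generation
outcross "maximum" class or its selfed "reduced" offspring) against the selfed
null-heterozygosity baseline (μ0) of the same ploidy, on a scale symmetric
around 0::

    OR = 1 - μ0/μi   if μi > μ0     (heterosis, up to +1)
    OR = μi/μ0 - 1   if μi < μ0     (outbreeding depression, down to -1)
    OR = 0           if μi = μ0

Significance comes from a percentile bootstrap that resamples plants with
replacement independently within each of the two groups. Per-plant
contributions apply the same index to a single plant's value against the null
group mean and are rescaled to (0, 1) via (OR + 1)/2 for the selection
regressions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedInputError, ValidationError
from .traits import COMPARISONS, trait_columns

logger = logging.getLogger(__name__)

_BOOT_CHUNK = 20_000  # bootstrap replicates per vectorized block


@dataclass(frozen=True)
class ORResult:
    """One trait × ploidy × comparison cell of the OR grid."""

    trait: str
    ploidy: int
    comparison: str  # "maximum" or "reduced" (always vs the null class)
    mu0: float
    mui: float
    or_value: float
    n0: int
    ni: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0

    @property
    def significant(self) -> bool:
        """True when the bootstrap CI excludes 0."""
        return bool(self.ci_low > 0 or self.ci_high < 0)


@dataclass(frozen=True)
class IndividualOR:
    """A single plant's contribution to the OR of one trait."""

    plant_id: str
    trait: str
    or_raw: float  # in [-1, 1], against the null-group mean
    or_norm: float = field(init=False)  # (or_raw + 1)/2, in [0, 1]

    def __post_init__(self):
        object.__setattr__(self, "or_norm", (self.or_raw + 1.0) / 2.0)


def compute_or(mu0: float, mui: float) -> float:
    """OR index of a heterozygous-group mean ``mui`` against baseline ``mu0``.

    Both means must be non-negative (all catalogue traits are); the index is
    undefined when both are zero.
    """
    if mu0 < 0 or mui < 0:
        raise ValidationError(f"negative mean ({mu0}, {mui}): trait means must be >= 0")
    if mu0 == 0 and mui == 0:
        raise UndefinedInputError("OR undefined when both group means are zero")
    if mui > mu0:
        return 1.0 - mu0 / mui
    if mui < mu0:
        return mui / mu0 - 1.0
    return 0.0


def _compute_or_vec(mu0: np.ndarray, mui: np.ndarray) -> np.ndarray:
    """Vectorized OR for bootstrap replicates (inputs assumed >= 0)."""
    out = np.zeros(np.broadcast(mu0, mui).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        up = mui > mu0
        down = mui < mu0
        out = np.where(up, 1.0 - mu0 / np.where(up, mui, 1.0), out)
        out = np.where(down, np.where(down, mui, 0.0) / np.where(mu0 > 0, mu0, 1.0) - 1.0, out)
    return out


def _group_values(table: pd.DataFrame, trait: str, ploidy: int, het_class: str) -> np.ndarray:
    sel = (table["ploidy"] == ploidy) & (table["het_class"] == het_class)
    vals = table.loc[sel, trait].dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise InsufficientDataError(
            f"no non-missing {trait!r} values for ploidy {ploidy} het_class {het_class!r}"
        )
    return vals


def group_or(table: pd.DataFrame, trait: str, ploidy: int, comparison: str) -> ORResult:
    """Point OR of ``comparison`` (maximum/reduced) vs null for one trait × ploidy."""
    if comparison not in COMPARISONS:
        raise ValidationError(f"comparison must be one of {COMPARISONS}, got {comparison!r}")
    v0 = _group_values(table, trait, ploidy, "null")
    vi = _group_values(table, trait, ploidy, comparison)
    mu0, mui = float(v0.mean()), float(vi.mean())
    return ORResult(
        trait=trait, ploidy=ploidy, comparison=comparison,
        mu0=mu0, mui=mui, or_value=compute_or(mu0, mui), n0=v0.size, ni=vi.size,
    )


def bootstrap_or_ci(
    table: pd.DataFrame,
    trait: str,
    ploidy: int,
    comparison: str,
    n_boot: int = 100_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ORResult:
    """Percentile-bootstrap CI for one OR cell.

    Each replicate resamples plants with replacement independently within the
    null and the heterozygous group, recomputes the two means and the index.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if n_boot < 100:
        logger.warning("n_boot=%d is very small; CI will be unstable", n_boot)
    point = group_or(table, trait, ploidy, comparison)
    v0 = _group_values(table, trait, ploidy, "null")
    vi = _group_values(table, trait, ploidy, comparison)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for start in range(0, n_boot, _BOOT_CHUNK):
        b = min(_BOOT_CHUNK, n_boot - start)
        m0 = v0[rng.integers(0, v0.size, size=(b, v0.size))].mean(axis=1)
        mi = vi[rng.integers(0, vi.size, size=(b, vi.size))].mean(axis=1)
        reps[start:start + b] = _compute_or_vec(m0, mi)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return ORResult(
        trait=point.trait, ploidy=point.ploidy, comparison=point.comparison,
        mu0=point.mu0, mui=point.mui, or_value=point.or_value,
        n0=point.n0, ni=point.ni,
        ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
    )


def individual_contribution(x: float, mu0: float) -> IndividualOR:
    """Per-plant OR contribution of trait value ``x`` against null-group mean ``mu0``."""
    if mu0 <= 0:
        raise UndefinedInputError(f"null-group mean must be positive, got {mu0}")
    if x < 0:
        raise ValidationError(f"trait value must be >= 0, got {x}")
    return IndividualOR(plant_id="", trait="", or_raw=compute_or(mu0, x))


def individual_contributions(table: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-plant OR contributions for all maximum/reduced plants.

    Columns: plant_id, trait, ploidy, het_class, or_raw, or_norm. The baseline
    μ0 is the null-class mean of the same ploidy; traits whose null mean is 0
    (or has no data) are skipped for that ploidy. Contributions are defined
    only for the maximum and reduced classes.
    """
    rows: list[dict] = []
    for ploidy, sub in table.groupby("ploidy", sort=True):
        null = sub[sub["het_class"] == "null"]
        for trait in trait_columns(table):
            base = null[trait].dropna()
            if base.empty or base.mean() <= 0:
                continue
            mu0 = float(base.mean())
            het = sub[sub["het_class"].isin(COMPARISONS)]
            vals = het[trait]
            ok = vals.notna() & (vals >= 0)
            raw = _compute_or_vec(np.full(int(ok.sum()), mu0), vals[ok].to_numpy(dtype=float))
            for (pid, hc), r in zip(het.loc[ok, ["plant_id", "het_class"]].itertuples(index=False), raw):
                rows.append({
                    "plant_id": pid, "trait": trait, "ploidy": ploidy,
                    "het_class": hc, "or_raw": float(r), "or_norm": (float(r) + 1) / 2,
                })
    return pd.DataFrame(rows, columns=["plant_id", "trait", "ploidy", "het_class", "or_raw", "or_norm"])


def or_table(
    table: pd.DataFrame,
    n_boot: int = 100_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full OR grid: every trait × ploidy present × comparison, with bootstrap CIs.

    Ploidies lacking a het class yield rows flagged ``available = False``
    rather than being dropped. Deterministic given ``seed``.
    """
    if table.empty:
        warnings.warn("empty cohort table: OR grid is empty")
        return pd.DataFrame(columns=[
            "trait", "ploidy", "comparison", "mu0", "mui", "or_value",
            "ci_low", "ci_high", "n_boot", "n0", "ni", "significant", "available",
        ])
    rng = np.random.default_rng(seed)
    rows = []
    for ploidy in sorted(table["ploidy"].unique()):
        for comparison in COMPARISONS:
            for trait in trait_columns(table):
                try:
                    res = bootstrap_or_ci(
                        table, trait, ploidy, comparison,
                        n_boot=n_boot, alpha=alpha, seed=rng.spawn(1)[0],
                    )
                    rows.append({
                        "trait": trait, "ploidy": ploidy, "comparison": comparison,
                        "mu0": res.mu0, "mui": res.mui, "or_value": res.or_value,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "n_boot": res.n_boot, "n0": res.n0, "ni": res.ni,
                        "significant": res.significant, "available": True,
                    })
                except (InsufficientDataError, UndefinedInputError) as exc:
                    logger.warning("OR unavailable for %s/%s/%s: %s", trait, ploidy, comparison, exc)
                    rows.append({
                        "trait": trait, "ploidy": ploidy, "comparison": comparison,
                        "mu0": np.nan, "mui": np.nan, "or_value": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan,
                        "n_boot": 0, "n0": 0, "ni": 0,
                        "significant": False, "available": False,
                    })
    return pd.DataFrame(rows)
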