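"""Phenotypic integration per ploidy × heterozygosity group.

Two complementary views of trait covariation:

* **Correlation counts** — the number of significant pairwise Pearson
  correlations involving each trait (pairwise-complete observations,
  two-sided test at α), summarized as a per-trait profile, the total number
  of significant pairs, and the mean count per trait.
* **Eigenvalue-variance index (PINT)** — the variance of the eigenvalues of
  the trait correlation matrix computed on complete cases. With p traits the
  eigenvalues sum to p and average 1; PINT = (1/p)·Σ(λ−1)² is 0 for
  independent traits and p−1 when all pairs correlate perfectly. Reported
  with a corrected form PINTc = PINT − (p−1)/N (the expected eigenvalue
  variance of a sample correlation matrix under independence with N complete
  cases) and a relative form RelPINT = 100·PINT/(p−1), the percentage of the
  maximum attainable integration. Bootstrap percentile CIs resample complete
  cases with replacement.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .traits import HET_CLASSES, trait_columns

logger = logging.getLogger(__name__)

_BOOT_CHUNK = 2000


@dataclass
class CorrelationProfile:
    """Significant-correlation counts for one (ploidy, het_class) group."""

    group: tuple[int, str]
    counts: pd.Series          # per-trait number of significant pairs
    total_significant: int     # significant unordered pairs
    mean_per_trait: float      # = 2 * total / p
    alpha: float
    n_traits: int


@dataclass
class IntegrationResult:
    """Eigenvalue-variance integration indices for one group."""

    group: tuple[int, str]
    n_traits: int              # p
    n_complete: int            # complete-case individuals N
    pint: float                # (1/p) Σ (λ_i − 1)^2, in [0, p−1]
    pint_c: float              # pint − (p−1)/N
    rel_pint: float            # 100 · pint / (p−1)
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0


def _group_frame(table: pd.DataFrame, group: tuple[int, str]) -> pd.DataFrame:
    ploidy, het = group
    if het not in HET_CLASSES:
        raise ValidationError(f"unknown het_class {het!r}")
    sub = table[(table["ploidy"] == ploidy) & (table["het_class"] == het)]
    if sub.empty:
        raise InsufficientDataError(f"group (ploidy={ploidy}, het_class={het!r}) absent from table")
    return sub[trait_columns(table)]


def count_significant_correlations(
    table: pd.DataFrame, group: tuple[int, str], alpha: float = 0.05
) -> CorrelationProfile:
    """Count significant pairwise Pearson correlations per trait in one group.

    Each unordered pair uses its pairwise-complete observations (>= 4
    required to test); undefined correlations (constant trait) count as
    non-significant.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    data = _group_frame(table, group)
    names = list(data.columns)
    p = len(names)
    counts = pd.Series(0, index=names, dtype=int)
    total = 0
    x = data.to_numpy(dtype=float)
    for i, j in itertools.combinations(range(p), 2):
        ok = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
        n = int(ok.sum())
        if n < 4:
            continue
        xi, xj = x[ok, i], x[ok, j]
        if np.ptp(xi) == 0 or np.ptp(xj) == 0:
            continue
        r, pval = stats.pearsonr(xi, xj)
        if pval < alpha:
            counts.iloc[i] += 1
            counts.iloc[j] += 1
            total += 1
    return CorrelationProfile(
        group=group, counts=counts, total_significant=total,
        mean_per_trait=float(counts.mean()), alpha=alpha, n_traits=p,
    )


def compare_counts(profile_a: CorrelationProfile, profile_b: CorrelationProfile):
    """Two-sample t-test on the per-trait count vectors of two profiles."""
    if list(profile_a.counts.index) != list(profile_b.counts.index):
        raise ValidationError("profiles cover different trait sets")
    a = profile_a.counts.to_numpy(dtype=float)
    b = profile_b.counts.to_numpy(dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def letter_display(profiles: dict[str, CorrelationProfile], alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display over groups: groups sharing no letter differ.

    All-pairs t-tests on per-trait counts; letters are assigned to the
    maximal cliques of the 'not significantly different' graph.
    """
    keys = list(profiles)
    k = len(keys)
    similar = np.ones((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        _, p = compare_counts(profiles[keys[i]], profiles[keys[j]])
        similar[i, j] = similar[j, i] = p >= alpha
    # maximal cliques by subset enumeration (few groups: 3 per ploidy)
    cliques = []
    for size in range(k, 0, -1):
        for combo in itertools.combinations(range(k), size):
            if all(similar[i, j] for i, j in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    letters = {key: "" for key in keys}
    for letter, clique in zip("abcdefghij", sorted(cliques)):
        for i in clique:
            letters[keys[i]] += letter
    return letters


def eigenvalue_variance(corr: np.ndarray) -> float:
    """Population variance of the eigenvalues of a correlation matrix."""
    lam = np.linalg.eigvalsh(corr)
    return float(np.mean((lam - 1.0) ** 2))


def relative_pint(pint_value: float, n_traits: int) -> float:
    """Integration as a percentage of its maximum: 100 · PINT / (p − 1)."""
    if n_traits < 2:
        raise ValidationError(f"need >= 2 traits, got {n_traits}")
    return 100.0 * pint_value / (n_traits - 1)


def _pint_from_cases(x: np.ndarray) -> float:
    if np.any(np.ptp(x, axis=0) == 0):
        raise InsufficientDataError("constant trait among complete cases: correlation undefined")
    return eigenvalue_variance(np.corrcoef(x, rowvar=False))


def pint(table: pd.DataFrame, group: tuple[int, str]) -> IntegrationResult:
    """Point integration indices for one group (complete-case individuals)."""
    data = _group_frame(table, group)
    x = data.dropna().to_numpy(dtype=float)
    p = data.shape[1]
    n = x.shape[0]
    if n < p + 1:
        raise InsufficientDataError(
            f"group {group}: {n} complete cases < p+1 = {p + 1}; "
            "correlation matrix would be rank-deficient")
    v = _pint_from_cases(x)
    return IntegrationResult(
        group=group, n_traits=p, n_complete=n,
        pint=v, pint_c=v - (p - 1) / n, rel_pint=relative_pint(v, p),
    )


def bootstrap_pint(
    table: pd.DataFrame,
    group: tuple[int, str],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> IntegrationResult:
    """Percentile-bootstrap CI for PINT by resampling complete cases."""
    point = pint(table, group)
    data = _group_frame(table, group).dropna().to_numpy(dtype=float)
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for start in range(0, n_boot, _BOOT_CHUNK):
        b = min(_BOOT_CHUNK, n_boot - start)
        for k in range(b):
            idx = rng.integers(0, n, size=n)
            sample = data[idx]
            # a degenerate resample (constant trait) is redrawn
            while np.any(np.ptp(sample, axis=0) == 0):
                idx = rng.integers(0, n, size=n)
                sample = data[idx]
            reps[start + k] = _pint_from_cases(sample)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return IntegrationResult(
        group=point.group, n_traits=point.n_traits, n_complete=point.n_complete,
        pint=point.pint, pint_c=point.pint_c, rel_pint=point.rel_pint,
        ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
    )


def integration_table(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integration indices + correlation counts over every ploidy × het group.

    Returns ``(indices, counts)``: one row per group in the first frame
    (failed groups flagged ``available = False``), one row per group × trait
    in the second.
    """
    rng = np.random.default_rng(seed)
    idx_rows, count_rows = [], []
    for ploidy in sorted(table["ploidy"].unique()):
        for het in HET_CLASSES:
            group = (int(ploidy), het)
            try:
                res = bootstrap_pint(table, group, n_boot=n_boot, alpha=alpha,
                                     seed=rng.spawn(1)[0])
                prof = count_significant_correlations(table, group, alpha=alpha)
                idx_rows.append({
                    "ploidy": group[0], "het_class": het, "p": res.n_traits,
                    "n_complete": res.n_complete, "pint": res.pint,
                    "pint_c": res.pint_c, "rel_pint": res.rel_pint,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "n_boot": res.n_boot,
                    "total_significant": prof.total_significant,
                    "mean_per_trait": prof.mean_per_trait, "available": True,
                })
                for trait, c in prof.counts.items():
                    count_rows.append({
                        "ploidy": group[0], "het_class": het,
                        "trait": trait, "n_significant": int(c),
                    })
            except (InsufficientDataError, ValidationError) as exc:
                logger.warning("integration unavailable for %s: %s", group, exc)
                idx_rows.append({
                    "ploidy": group[0], "het_class": het, "p": np.nan,
                    "n_complete": 0, "pint": np.nan, "pint_c": np.nan,
                    "rel_pint": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "n_boot": 0, "total_significant": np.nan,
                    "mean_per_trait": np.nan, "available": False,
                })
    return pd.DataFrame(idx_rows), pd.DataFrame(count_rows)
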