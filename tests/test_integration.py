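"""Phenotypic-integration indices: closed forms, oracles, bootstrap behaviour."""

import numpy as np
import pandas as pd
import pytest

from outbreeding import (
    CohortSpec,
    InsufficientDataError,
    TRAIT_NAMES,
    bootstrap_pint,
    compare_counts,
    count_significant_correlations,
    eigenvalue_variance,
    generate_cohort,
    integration_table,
    letter_display,
    pint,
)
from outbreeding.integration import CorrelationProfile
from outbreeding.simulate import module_correlation
from conftest import independent_correlations, small_group_sizes


def _table_from_matrix(x: np.ndarray, ploidy=2, het="null") -> pd.DataFrame:
    """Wrap an (n, 20) array as a single-group cohort table."""
    t = pd.DataFrame(x, columns=list(TRAIT_NAMES))
    t.insert(0, "het_class", het)
    t.insert(0, "ploidy", ploidy)
    t.insert(0, "population", "p")
    t.insert(0, "plant_id", [f"x{i}" for i in range(len(t))])
    return t


# ---------------------------------------------------------------- pint forms

def test_pint_identity_matrix_is_zero():
    assert eigenvalue_variance(np.eye(20)) == pytest.approx(0.0, abs=1e-12)


def test_pint_rank_one_matrix_attains_maximum():
    ones = np.ones((20, 20))
    assert eigenvalue_variance(ones) == pytest.approx(19.0, abs=1e-9)


def test_pint_two_traits_closed_form():
    r = 0.6
    corr = np.array([[1, r], [r, 1]])
    assert eigenvalue_variance(corr) == pytest.approx(r**2, abs=1e-12)


@pytest.mark.parametrize("r", [0.2, 0.5])
def test_pint_compound_symmetry_closed_form(r):
    p = 20
    corr = np.full((p, p), r)
    np.fill_diagonal(corr, 1.0)
    assert eigenvalue_variance(corr) == pytest.approx((p - 1) * r**2, rel=1e-9)


def test_eigenvalue_sum_conservation():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((100, 20))
    corr = np.corrcoef(x, rowvar=False)
    assert np.linalg.eigvalsh(corr).sum() == pytest.approx(20.0, abs=1e-8)


def test_pint_brute_force_oracle_small_p():
    """p <= 4: eigenvalues recomputed from the characteristic polynomial (sympy)."""
    import sympy

    rng = np.random.default_rng(1)
    x = rng.standard_normal((50, 4)) @ rng.standard_normal((4, 4))
    corr = np.corrcoef(x, rowvar=False)
    lam = [complex(z).real for z in sympy.nroots(
        sympy.Matrix(corr).charpoly().as_expr())]
    oracle = float(np.mean((np.array(lam) - 1.0) ** 2))
    assert eigenvalue_variance(corr) == pytest.approx(oracle, abs=1e-8)


def test_pint_affine_rescaling_invariance():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((80, 20)) @ rng.standard_normal((20, 20))
    t1 = _table_from_matrix(np.abs(x) + 1.0)
    scale = rng.uniform(0.5, 5.0, 20)
    t2 = _table_from_matrix((np.abs(x) + 1.0) * scale)
    a, b = pint(t1, (2, "null")), pint(t2, (2, "null"))
    assert a.pint == pytest.approx(b.pint, abs=1e-10)


def test_pint_result_internal_consistency(default_cohort):
    res = pint(default_cohort, (4, "null"))
    assert res.rel_pint == pytest.approx(100 * res.pint / (res.n_traits - 1), abs=1e-9)
    assert res.pint_c == pytest.approx(res.pint - (res.n_traits - 1) / res.n_complete)
    assert 0 <= res.pint <= res.n_traits - 1


def test_pint_refuses_rank_deficient_group():
    x = np.abs(np.random.default_rng(3).standard_normal((10, 20))) + 1  # n < p+1
    with pytest.raises(InsufficientDataError, match="complete cases"):
        pint(_table_from_matrix(x), (2, "null"))


# ------------------------------------------------------------- bootstrapping

def test_bootstrap_point_estimate_independent_of_n_boot(default_cohort):
    a = bootstrap_pint(default_cohort, (2, "maximum"), n_boot=10, seed=0)
    b = bootstrap_pint(default_cohort, (2, "maximum"), n_boot=400, seed=1)
    assert a.pint == b.pint
    assert (b.ci_high - b.ci_low) > 0


def test_bootstrap_refuses_degenerate_group():
    x = np.tile(np.abs(np.random.default_rng(4).standard_normal(20)) + 1, (40, 1))
    with pytest.raises(InsufficientDataError):
        bootstrap_pint(_table_from_matrix(x), (2, "null"), n_boot=50, seed=0)


def test_bootstrap_ci_covers_analytic_compound_symmetry():
    """Uniform r=0.5, N=300: CI covers the generating pint = 19 * 0.25 attenuated.

    The copula + marginal transforms attenuate Pearson correlations, so
    coverage is asserted against the analytic pint of the *realized* Gaussian
    copula only loosely: the CI must cover the group's own point estimate
    neighbourhood and sit well away from zero.
    """
    corr = {(p, h): module_correlation(within=0.5, between=0.5)
            for p in (2, 4, 6) for h in ("null", "maximum", "reduced")}
    hits = 0
    for seed in range(1, 6):
        spec = CohortSpec(seed=seed, group_sizes=small_group_sizes(300), correlation=corr)
        cohort = generate_cohort(spec)
        res = bootstrap_pint(cohort, (2, "null"), n_boot=300, seed=seed)
        hits += res.ci_low > 1.0  # strongly integrated, far from independence
        assert res.ci_low <= res.pint <= res.ci_high * 1.05
    assert hits == 5


# ---------------------------------------------------------- correlation counts

def test_null_counts_match_alpha_rate():
    """Independent traits: mean per-trait count ~ alpha * (p - 1).

    The total count is over-dispersed relative to Binomial(p(p-1)/2, alpha)
    because pair tests sharing a trait are positively dependent, so the
    per-seed band is 4 binomial SD; the mean over seeds gets a tighter band.
    """
    p, n, alpha = 20, 500, 0.05
    expected = alpha * (p - 1)
    sd_total = np.sqrt(p * (p - 1) / 2 * alpha * (1 - alpha))
    means = []
    for seed in range(1, 6):
        rng = np.random.default_rng(seed)
        t = _table_from_matrix(np.abs(rng.standard_normal((n, p))) + 3)
        prof = count_significant_correlations(t, (2, "null"), alpha=alpha)
        means.append(prof.mean_per_trait)
        # mean = 2 * total / p, so SD bands on the total scale by 2/p
        assert abs(prof.mean_per_trait - expected) <= 4 * sd_total * 2 / p
    assert abs(np.mean(means) - expected) <= 2 * sd_total * 2 / p


def test_duplicated_trait_pair_always_counted():
    rng = np.random.default_rng(7)
    x = np.abs(rng.standard_normal((60, 20))) + 1
    x[:, 1] = x[:, 0]  # perfect correlation between first two traits
    prof = count_significant_correlations(_table_from_matrix(x), (2, "null"))
    assert prof.counts.iloc[0] >= 1
    assert prof.counts.iloc[1] >= 1


def test_constant_trait_counts_zero():
    rng = np.random.default_rng(8)
    x = np.abs(rng.standard_normal((60, 20))) + 1
    x[:, 5] = 2.5
    prof = count_significant_correlations(_table_from_matrix(x), (2, "null"))
    assert prof.counts.iloc[5] == 0


def test_profile_mean_identity(default_cohort):
    prof = count_significant_correlations(default_cohort, (4, "null"))
    assert prof.mean_per_trait == pytest.approx(2 * prof.total_significant / prof.n_traits)
    assert (prof.counts <= prof.n_traits - 1).all()


def test_compare_counts_identical_profiles():
    counts = pd.Series([3] * 20, index=list(TRAIT_NAMES))
    prof = CorrelationProfile((2, "null"), counts, 30, 3.0, 0.05, 20)
    t, p = compare_counts(prof, prof)
    assert p == 1.0


def test_compare_counts_maximal_separation():
    a = CorrelationProfile((2, "null"), pd.Series([19] * 20, index=list(TRAIT_NAMES)), 190, 19.0, 0.05, 20)
    b = CorrelationProfile((2, "maximum"), pd.Series([0] * 20, index=list(TRAIT_NAMES)), 0, 0.0, 0.05, 20)
    _, p = compare_counts(a, b)
    assert p < 1e-10


def test_letter_display_one_divergent_group():
    rng = np.random.default_rng(9)
    mk = lambda mu, g: CorrelationProfile(
        g, pd.Series(rng.poisson(mu, 20), index=list(TRAIT_NAMES)), 0, 0.0, 0.05, 20)
    profs = {"null": mk(10, (2, "null")), "maximum": mk(10, (2, "maximum")),
             "reduced": mk(1, (2, "reduced"))}
    letters = letter_display(profs)
    assert set(letters["null"]) & set(letters["maximum"])       # share a letter
    assert not set(letters["null"]) & set(letters["reduced"])   # differ
    assert not set(letters["maximum"]) & set(letters["reduced"])


# ---------------------------------------------------------------- full grids

def test_integration_table_nine_groups(small_cohort):
    indices, counts = integration_table(small_cohort, n_boot=50, seed=0)
    assert len(indices) == 9
    assert indices["available"].all()
    assert len(counts) == 9 * 20
    ok = indices["available"]
    assert np.allclose(indices.loc[ok, "rel_pint"],
                       100 * indices.loc[ok, "pint"] / (indices.loc[ok, "p"] - 1))


def test_integration_table_missing_group_flagged(small_cohort):
    sub = small_cohort[~((small_cohort.ploidy == 6) & (small_cohort.het_class == "reduced"))]
    indices, _ = integration_table(sub, n_boot=50, seed=0)
    assert len(indices) == 9
    row = indices[(indices.ploidy == 6) & (indices.het_class == "reduced")]
    assert not row["available"].item()


def test_higher_null_correlation_yields_higher_pint():
    """Groups generated more integrated come out more integrated (2x and 4x)."""
    hits = 0
    for seed in range(1, 11):
        spec = CohortSpec(seed=seed, group_sizes=small_group_sizes(120))
        cohort = generate_cohort(spec)  # default: null r_within .45 > maximum .25
        for ploidy in (2, 4):
            a = pint(cohort, (ploidy, "null")).pint
            b = pint(cohort, (ploidy, "maximum")).pint
            hits += a > b
    assert hits / 20 >= 0.9
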