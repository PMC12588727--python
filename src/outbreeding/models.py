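"""Ploidy and trait-module effects on the OR grid.

The unit of analysis is a trait × ploidy OR value (20 traits × 3 ploidies =
60 observations per heterozygosity comparison). Two complementary tests:

* a Gaussian linear mixed model (REML) with ploidy and module as fixed
  effects and a random intercept per trait, capturing that the same 20
  traits are measured at every ploidy;
* the Scheirer–Ray–Hare extension of the Kruskal–Wallis test: a two-way
  ANOVA on mid-ranks where each term's sum of squares is divided by the
  total rank variance and referred to a chi-square distribution.

The response is bounded in [−1, 1] but continuous; normal-theory output
(β ± SE, t) is reported for the mixed model, with p-values from the t
distribution on the residual degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .traits import MODULE_OF

logger = logging.getLogger(__name__)

PLOIDY_REFERENCE = 2
MODULE_REFERENCE = "fitness"  # alphabetically first of the four modules


@dataclass
class MixedModelResult:
    """REML fit of or_value ~ ploidy + module + (1 | trait)."""

    fixed: pd.DataFrame  # index: term; columns: estimate, se, t, p
    trait_variance: float
    trait_sd: float
    residual_variance: float
    n_obs: int
    boundary: bool        # random-effect variance estimated at (or near) zero
    converged: bool
    reference: dict = field(default_factory=lambda: {
        "ploidy": PLOIDY_REFERENCE, "module": MODULE_REFERENCE})


@dataclass
class SRHResult:
    """Scheirer–Ray–Hare table: one row per term (ploidy, module, interaction)."""

    table: pd.DataFrame  # index: term; columns: df, ss, H, p
    n_obs: int
    ms_total: float


def build_model_frame(or_results: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """Extract the trait/module/ploidy/or_value frame for one comparison.

    Rows with unavailable or non-finite OR are dropped with a warning; more
    than 20% missing cells aborts with a diagnostic (the grid is then too
    sparse for a 60-observation model).
    """
    sub = or_results[or_results["comparison"] == comparison]
    if sub.empty:
        raise ValidationError(f"no rows for comparison {comparison!r} in OR results")
    expected = len(sub)
    ok = sub["or_value"].notna()
    if "available" in sub.columns:
        ok &= sub["available"].astype(bool)
    dropped = expected - int(ok.sum())
    if dropped > 0.2 * expected:
        raise ValidationError(
            f"{dropped}/{expected} OR cells missing for comparison {comparison!r}; "
            "refusing to fit on a grid with >20% missing cells")
    if dropped:
        warnings.warn(f"dropping {dropped} unavailable OR cells for {comparison!r}")
    frame = sub.loc[ok, ["trait", "ploidy", "or_value"]].copy()
    frame.insert(1, "module", frame["trait"].map(MODULE_OF))
    if frame["module"].isna().any():
        unknown = frame.loc[frame["module"].isna(), "trait"].unique()
        raise ValidationError(f"traits outside the catalogue: {list(unknown)}")
    return frame.reset_index(drop=True)


def _fixed_design(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design: intercept + ploidy (ref 2x) + module (ref fitness)."""
    cols: list[np.ndarray] = [np.ones(len(frame))]
    names = ["intercept"]
    for lv in sorted(frame["ploidy"].unique()):
        if lv == PLOIDY_REFERENCE:
            continue
        cols.append((frame["ploidy"] == lv).to_numpy(dtype=float))
        names.append(f"ploidy[{lv}]")
    for lv in sorted(frame["module"].unique()):
        if lv == MODULE_REFERENCE:
            continue
        cols.append((frame["module"] == lv).to_numpy(dtype=float))
        names.append(f"module[{lv}]")
    return np.column_stack(cols), names


def fit_or_mixed_model(frame: pd.DataFrame) -> MixedModelResult:
    """REML linear mixed model of OR on ploidy + module with trait intercepts.

    A fit on the variance boundary (trait variance ~ 0) is returned with
    ``boundary=True``, never raised; fixed effects then coincide with OLS.
    """
    for col, minlev in (("ploidy", 2), ("module", 2)):
        if frame[col].nunique() < minlev:
            raise ValidationError(f"need >= 2 levels of {col!r}, got {frame[col].nunique()}")
    counts = frame.groupby("module")["trait"].nunique()
    if (counts < 2).any():
        raise ValidationError(f"each module needs >= 2 traits; got {counts.to_dict()}")
    from statsmodels.regression.mixed_linear_model import MixedLM

    y = frame["or_value"].to_numpy(dtype=float)
    exog, names = _fixed_design(frame)
    groups = frame["trait"].to_numpy()
    converged = True
    if np.ptp(y) == 0:
        # degenerate constant response: REML is ill-posed; report the flat fit
        est = np.zeros(len(names))
        est[0] = y[0] if len(y) else np.nan
        fixed = pd.DataFrame(
            {"estimate": est, "se": 0.0, "t": np.nan, "p": np.nan}, index=names)
        return MixedModelResult(fixed=fixed, trait_variance=0.0, trait_sd=0.0,
                                residual_variance=0.0, n_obs=len(y),
                                boundary=True, converged=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, exog, groups=groups)
        try:
            res = model.fit(reml=True)
            converged = bool(getattr(res, "converged", True))
        except Exception as exc:  # numerical failure -> OLS fallback, flagged
            logger.warning("MixedLM failed (%s); reporting OLS with zero trait variance", exc)
            res = None
            converged = False
    if res is not None:
        est = np.asarray(res.fe_params, dtype=float)
        se = np.asarray(res.bse_fe, dtype=float)
        var_trait = float(np.asarray(res.cov_re)[0, 0])
        var_resid = float(res.scale)
    else:
        beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
        resid = y - exog @ beta
        dof = max(len(y) - exog.shape[1], 1)
        var_resid = float(resid @ resid / dof)
        cov = var_resid * np.linalg.pinv(exog.T @ exog)
        est, se = beta, np.sqrt(np.diag(cov))
        var_trait = 0.0
    df_resid = max(len(y) - exog.shape[1], 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = est / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    fixed = pd.DataFrame({"estimate": est, "se": se, "t": tvals, "p": pvals}, index=names)
    return MixedModelResult(
        fixed=fixed, trait_variance=var_trait, trait_sd=float(np.sqrt(max(var_trait, 0.0))),
        residual_variance=var_resid, n_obs=len(y),
        boundary=bool(var_trait < 1e-8), converged=converged,
    )


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, 1:]).astype(float)


def scheirer_ray_hare(
    frame: pd.DataFrame,
    factor_a: str = "ploidy",
    factor_b: str = "module",
    response: str = "or_value",
    include_interaction: bool = True,
) -> SRHResult:
    """Scheirer–Ray–Hare rank test for two crossed factors.

    Responses are mid-ranked; Type-II sums of squares are computed on the
    ranks by least squares; each H = SS / MS_total with
    MS_total = SS_total / (N − 1) (the variance of the ranks, which carries
    the tie correction); p from chi-square with the term's df. Works on
    unbalanced designs; invariant to strictly monotone response transforms.
    """
    for f in (factor_a, factor_b):
        if frame[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has a single level")
    a = frame[factor_a].to_numpy()
    b = frame[factor_b].to_numpy()
    r = stats.rankdata(frame[response].to_numpy(dtype=float))
    n = len(r)
    ms_total = float(np.var(r, ddof=1)) if n > 1 else 0.0
    one = np.ones((n, 1))
    da, db = _dummies(a), _dummies(b)
    dab = np.column_stack([da[:, i] * db[:, j]
                           for i in range(da.shape[1]) for j in range(db.shape[1])]) \
        if (include_interaction and da.size and db.size) else np.empty((n, 0))
    X_a = np.hstack([one, da])
    X_b = np.hstack([one, db])
    X_ab = np.hstack([one, da, db])
    X_full = np.hstack([one, da, db, dab])
    rss_a, rss_b, rss_add = _rss(X_a, r), _rss(X_b, r), _rss(X_ab, r)
    terms = {
        factor_a: (rss_b - rss_add, np.linalg.matrix_rank(X_ab) - np.linalg.matrix_rank(X_b)),
        factor_b: (rss_a - rss_add, np.linalg.matrix_rank(X_ab) - np.linalg.matrix_rank(X_a)),
    }
    if include_interaction:
        rss_full = _rss(X_full, r)
        terms["interaction"] = (
            rss_add - rss_full,
            np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_ab),
        )
    rows = {}
    for term, (ss, df) in terms.items():
        ss = max(float(ss), 0.0)
        h = ss / ms_total if ms_total > 0 else 0.0
        p = float(stats.chi2.sf(h, df)) if df > 0 and ms_total > 0 else 1.0
        rows[term] = {"df": int(df), "ss": ss, "H": h, "p": p}
    return SRHResult(table=pd.DataFrame(rows).T, n_obs=n, ms_total=ms_total)
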