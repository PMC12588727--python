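"""Seeded synthetic cohorts with the study's factorial design and known truth.

The generator emulates a greenhouse crossing design on a selfing plant
complex: three ploidy levels (2x, 4x, 6x), each with three heterozygosity
classes — ``null`` (selfed inbred lines), ``maximum`` (first-generation
crosses between inbred lines) and ``reduced`` (selfed offspring of the
maximum class). Default group sizes follow the published study design:
405 diploids (257/53/95 null/maximum/reduced), 764 tetraploids (457/69/238)
and 453 hexaploids (252/112/89).

Ground truth is injected three ways so every downstream stage has a recovery
test:

* **OR effects** — each (trait, ploidy, comparison) may carry a true
  outbreeding-response value v ∈ (−1, 1); the heterozygous generating mean is
  the closed-form inversion of the index (μi = μ0/(1−v) for v > 0,
  μi = μ0(1+v) for v < 0), so the analytic OR of the generating means equals
  v exactly.
* **Integration** — within-group cross-trait dependence follows a
  user-specified correlation matrix via a Gaussian copula (draw multivariate
  normal, push through Φ, then through each trait's marginal quantile
  function).
* **Selection** — optional slopes linking the normalized per-plant OR
  contribution to expected pre-dispersive fitness; when any slope is nonzero
  the fruit_set/seed_set pair is built from a latent fitness that is linear
  in those contributions (their own OR targets are then not honoured).

Marginals respect each trait's support: lognormal for positive-continuous
traits (parameterized by mean and coefficient of variation), negative
binomial for counts (mean and dispersion k), beta for proportions (mean and
concentration ν), Bernoulli for survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ValidationError
from .orstats import _compute_or_vec
from .traits import (
    COMPARISONS,
    DEFAULT_TRAITS,
    HET_CLASSES,
    PLOIDIES,
    TRAIT_BY_NAME,
    TRAIT_NAMES,
    TraitDef,
)

#: Published study design: plants per (ploidy, het_class).
DEFAULT_GROUP_SIZES: dict[tuple[int, str], int] = {
    (2, "null"): 257, (2, "maximum"): 53, (2, "reduced"): 95,
    (4, "null"): 457, (4, "maximum"): 69, (4, "reduced"): 238,
    (6, "null"): 252, (6, "maximum"): 112, (6, "reduced"): 89,
}

#: Null-class generating means, in field-plausible units for a small selfing
#: crucifer (lengths in mm; gamete totals per plant/flower; proportions; 0/1).
DEFAULT_BASE_MEANS: dict[str, float] = {
    "ovules_per_plant": 600.0,
    "pollen_per_plant": 150_000.0,
    "fruit_set": 0.60,
    "seed_set": 0.55,
    "survival": 0.80,
    "germination": 0.60,
    "leaf_number": 15.0,
    "ovules_per_flower": 22.0,
    "pollen_per_flower": 9000.0,
    "plant_height": 250.0,
    "stalk_number": 3.0,
    "stalk_diameter": 2.5,
    "flower_number": 30.0,
    "petal_length": 8.0,
    "flower_diameter": 9.0,
    "corolla_tube_length": 9.0,
    "long_filament_length": 7.0,
    "short_filament_length": 5.0,
    "style_length": 3.5,
    "herkogamy": 1.2,
}

#: Dispersion by kind: CV (positive-continuous), negative-binomial k (count),
#: beta concentration ν (proportion); ignored for binary.
_DEFAULT_NOISE_BY_KIND = {"positive-continuous": 0.30, "count": 8.0, "proportion": 20.0}
DEFAULT_NOISE_SCALES: dict[str, float] = {
    t.name: _DEFAULT_NOISE_BY_KIND.get(t.kind, 0.0) for t in DEFAULT_TRAITS
}

#: Default within/between-module correlations per het class. Selfed (null)
#: groups are the most integrated, first-generation outcrosses the least,
#: mirroring the expected loosening of trait covariation with heterozygosity.
DEFAULT_INTEGRATION_LEVELS: dict[str, tuple[float, float]] = {
    "null": (0.45, 0.15),
    "maximum": (0.25, 0.05),
    "reduced": (0.35, 0.10),
}


def invert_or(mu0: float, true_or: float) -> float:
    """Heterozygous-group mean whose OR against ``mu0`` equals ``true_or``.

    Closed-form inversion of the piecewise index: μi = μ0/(1−v) for v > 0,
    μ0(1+v) for v < 0, μ0 at v = 0.
    """
    if not -1 < true_or < 1:
        raise ValidationError(f"true OR must lie in (-1, 1), got {true_or}")
    if mu0 <= 0:
        raise ValidationError(f"base mean must be positive, got {mu0}")
    if true_or > 0:
        return mu0 / (1.0 - true_or)
    if true_or < 0:
        return mu0 * (1.0 + true_or)
    return mu0


def module_correlation(
    traits: tuple[TraitDef, ...] = DEFAULT_TRAITS,
    within: float = 0.3,
    between: float = 0.1,
) -> np.ndarray:
    """Block correlation matrix: ``within`` inside a module, ``between`` across."""
    modules = np.array([t.module for t in traits])
    same = modules[:, None] == modules[None, :]
    corr = np.where(same, within, between)
    np.fill_diagonal(corr, 1.0)
    return corr


def default_correlations() -> dict[tuple[int, str], np.ndarray]:
    """Per-group correlation matrices at the default integration levels."""
    return {
        (p, h): module_correlation(within=w, between=b)
        for p in PLOIDIES
        for h, (w, b) in DEFAULT_INTEGRATION_LEVELS.items()
    }


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    ``true_or`` maps (trait, ploidy, comparison) → OR in (−1, 1); missing
    entries default to 0 (no effect). ``selection_slope`` maps trait → slope
    of expected pre-dispersive fitness on the normalized OR contribution.
    """

    group_sizes: dict[tuple[int, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    true_or: dict[tuple[str, int, str], float] = field(default_factory=dict)
    base_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_MEANS))
    correlation: dict[tuple[int, str], np.ndarray] = field(default_factory=default_correlations)
    noise_scales: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SCALES))
    selection_slope: dict[str, float] = field(default_factory=dict)
    # Latent-fitness parameters (selection mode). The baseline is high enough
    # that the within-ploidy maximum sits near 1, so the max-normalization of
    # composite fitness leaves injected selection slopes on their own scale.
    fitness_baseline: float = 0.60
    fitness_noise_sd: float = 0.12
    seed: int = 0

    def validate(self) -> "CohortSpec":
        for (p, h), n in self.group_sizes.items():
            if p not in PLOIDIES or h not in HET_CLASSES:
                raise ValidationError(f"unknown group ({p}, {h!r})")
            if n < 2:
                raise ValidationError(f"group ({p}, {h!r}) size must be >= 2, got {n}")
        for t, m in self.base_means.items():
            if t not in TRAIT_BY_NAME:
                raise ValidationError(f"unknown trait {t!r} in base_means")
            if m <= 0:
                raise ValidationError(f"base mean for {t!r} must be positive, got {m}")
            if TRAIT_BY_NAME[t].kind in ("proportion", "binary") and not m < 1:
                raise ValidationError(f"{t!r} base mean must be < 1, got {m}")
        for (t, p, c), v in self.true_or.items():
            if t not in TRAIT_BY_NAME:
                raise ValidationError(f"unknown trait {t!r} in true_or")
            if c not in COMPARISONS:
                raise ValidationError(f"true_or comparison must be in {COMPARISONS}, got {c!r}")
            mi = invert_or(self.base_means[t], v)  # validates v in (-1, 1)
            if TRAIT_BY_NAME[t].kind in ("proportion", "binary") and not mi < 1:
                raise ValidationError(
                    f"true_or {v} pushes {t!r} mean to {mi:.3f} >= 1 (outside support)")
        for (p, h), corr in self.correlation.items():
            corr = np.asarray(corr)
            k = len(TRAIT_NAMES)
            if corr.shape != (k, k):
                raise ValidationError(f"correlation for group ({p}, {h!r}) is not {k}x{k}")
            if not np.allclose(corr, corr.T, atol=1e-10):
                raise ValidationError(f"correlation for group ({p}, {h!r}) is not symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
                raise ValidationError(f"correlation for group ({p}, {h!r}) has non-unit diagonal")
            if np.linalg.eigvalsh(corr)[0] < -1e-8:
                raise ValidationError(
                    f"correlation matrix for group ({p}, {h!r}) is not positive semi-definite")
        return self

    # -- config-file round trip -------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortSpec":
        """Build a spec from a plain-dict config (YAML/JSON friendly).

        Recognized keys: ``seed``; ``group_sizes`` as {"<ploidy>": {het: n}};
        ``base_means``, ``noise_scales``, ``selection_slope`` as flat maps;
        ``true_or`` as a list of {trait, ploidy, comparison, value};
        ``integration_levels`` as {het: {within, between}} (expanded to block
        matrices for every ploidy); ``fitness_baseline``, ``fitness_noise_sd``.
        """
        spec = cls()
        if "seed" in cfg:
            spec.seed = int(cfg["seed"])
        if "group_sizes" in cfg:
            # YAML parses a bare `null:` mapping key as None
            spec.group_sizes = {
                (int(p), h if h is not None else "null"): int(n)
                for p, hs in cfg["group_sizes"].items()
                for h, n in hs.items()
            }
        for key in ("base_means", "noise_scales", "selection_slope"):
            if key in cfg:
                getattr(spec, key).update({k: float(v) for k, v in cfg[key].items()})
        if "true_or" in cfg:
            spec.true_or = {
                (e["trait"], int(e["ploidy"]), e["comparison"]): float(e["value"])
                for e in cfg["true_or"]
            }
        if "integration_levels" in cfg:
            levels = {
                (h if h is not None else "null"): (float(d["within"]), float(d["between"]))
                for h, d in cfg["integration_levels"].items()
            }
            spec.correlation = {
                (p, h): module_correlation(within=w, between=b)
                for p in PLOIDIES for h, (w, b) in levels.items()
            }
        for key in ("fitness_baseline", "fitness_noise_sd"):
            if key in cfg:
                setattr(spec, key, float(cfg[key]))
        return spec.validate()

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def _marginal_ppf(u: np.ndarray, trait: TraitDef, mean: float, scale: float) -> np.ndarray:
    """Quantile transform of uniforms ``u`` to the trait's marginal with given mean."""
    if trait.kind == "positive-continuous":
        sigma = np.sqrt(np.log1p(scale**2))
        mu_log = np.log(mean) - sigma**2 / 2
        return np.exp(mu_log + sigma * stats.norm.ppf(u))
    if trait.kind == "count":
        k = scale
        return stats.nbinom.ppf(u, k, k / (k + mean))
    if trait.kind == "proportion":
        a, b = mean * scale, (1 - mean) * scale
        return stats.beta.ppf(u, a, b)
    if trait.kind == "binary":
        return (u > 1 - mean).astype(float)
    raise ValidationError(f"unknown trait kind {trait.kind!r}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a tidy cohort table from ``spec``; byte-identical given a seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = list(TRAIT_NAMES)
    idx = {t: j for j, t in enumerate(names)}
    selection = {t: s for t, s in spec.selection_slope.items() if s != 0.0}
    frames = []
    for ploidy in PLOIDIES:
        for het in HET_CLASSES:
            n = spec.group_sizes.get((ploidy, het), 0)
            if n == 0:
                continue
            corr = np.asarray(spec.correlation[(ploidy, het)], dtype=float)
            # Gaussian copula: correlated normals -> uniforms -> marginals
            z = rng.multivariate_normal(np.zeros(len(names)), corr, size=n,
                                        method="eigh")
            u = stats.norm.cdf(z)
            data = np.empty_like(u)
            means = {}
            for t in names:
                v = 0.0 if het == "null" else spec.true_or.get((t, ploidy, het), 0.0)
                means[t] = invert_or(spec.base_means[t], v)
                data[:, idx[t]] = _marginal_ppf(
                    u[:, idx[t]], TRAIT_BY_NAME[t], means[t], spec.noise_scales[t])
            if selection:
                _apply_selection(data, u, idx, spec, het, selection, rng)
            frame = pd.DataFrame(data, columns=names)
            frame.insert(0, "het_class", het)
            frame.insert(0, "ploidy", ploidy)
            frame.insert(0, "population", [
                f"pop{ploidy}{'ab'[i % 2]}" for i in range(n)])
            frame.insert(0, "plant_id", [
                f"p{ploidy}-{het}-{i:04d}" for i in range(n)])
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _apply_selection(data, u, idx, spec: CohortSpec, het: str,
                     selection: dict[str, float], rng: np.random.Generator):
    """Overwrite fruit_set/seed_set with a latent fitness linear in OR contributions.

    Latent F = clip(baseline + Σ_t slope_t·(or_norm_t − ½) + noise, 0.02, 0.98);
    the pair is split as fruit_set = F^a, seed_set = F^(1−a) with a jittered
    around ½, so fruit_set × seed_set = F exactly and both stay in (0, 1).
    The noise is drawn outside the copula: it must be independent of the
    predictor traits or the recovered selection slope would be biased.
    """
    n = data.shape[0]
    shift = np.zeros(n)
    if het != "null":
        for t, slope in selection.items():
            mu0 = spec.base_means[t]
            or_norm = (_compute_or_vec(np.full(n, mu0), data[:, idx[t]]) + 1) / 2
            shift += slope * (or_norm - 0.5)
    noise = spec.fitness_noise_sd * rng.standard_normal(n)
    latent = np.clip(spec.fitness_baseline + shift + noise, 0.02, 1.0)
    a = 0.5 + 0.15 * (u[:, idx["seed_set"]] - 0.5)  # in (0.425, 0.575)
    data[:, idx["fruit_set"]] = latent**a
    data[:, idx["seed_set"]] = latent ** (1 - a)
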