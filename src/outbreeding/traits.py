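"""Trait catalogue and tidy cohort table schema.

The study design measures 20 phenotypic traits per plant, grouped a priori
into four modules:

* ``fitness`` (7): per-plant gamete output, fruit/seed set, survival,
  germination, leaf number — the pre- and post-dispersive fitness components.
* ``reproductive`` (2): per-flower gamete production.
* ``individual`` (4): whole-plant size and architecture.
* ``flower`` (7): floral morphometrics, including herkogamy (anther–stigma
  separation).

Each trait carries a statistical *kind* that fixes its support: positive
continuous (lengths in mm, or large counts treated as continuous), count,
proportion in [0, 1], or binary. The kind drives both simulation marginals
and input validation.

A cohort lives in a tidy :class:`pandas.DataFrame`: one row per plant with
``plant_id``, ``population``, ``ploidy`` (2/4/6), ``het_class``
(null/maximum/reduced) and one column per trait. Empty CSV cells are missing
values, never zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

PLOIDIES = (2, 4, 6)
HET_CLASSES = ("null", "maximum", "reduced")
COMPARISONS = ("maximum", "reduced")  # each het class vs the null baseline
MODULES = ("fitness", "reproductive", "individual", "flower")
KINDS = ("positive-continuous", "count", "proportion", "binary")

ID_COLUMNS = ("plant_id", "population", "ploidy", "het_class")


@dataclass(frozen=True)
class TraitDef:
    """One measured trait: its name, a priori module and statistical kind."""

    name: str
    module: str
    kind: str

    def __post_init__(self):
        if self.module not in MODULES:
            raise ValidationError(f"unknown module {self.module!r} for trait {self.name!r}")
        if self.kind not in KINDS:
            raise ValidationError(f"unknown kind {self.kind!r} for trait {self.name!r}")


#: The 20-trait default catalogue (module sizes 7/2/4/7).
DEFAULT_TRAITS: tuple[TraitDef, ...] = (
    # fitness components
    TraitDef("ovules_per_plant", "fitness", "positive-continuous"),
    TraitDef("pollen_per_plant", "fitness", "positive-continuous"),
    TraitDef("fruit_set", "fitness", "proportion"),
    TraitDef("seed_set", "fitness", "proportion"),
    TraitDef("survival", "fitness", "binary"),
    TraitDef("germination", "fitness", "proportion"),
    TraitDef("leaf_number", "fitness", "count"),
    # reproductive (gamete production per flower)
    TraitDef("ovules_per_flower", "reproductive", "count"),
    TraitDef("pollen_per_flower", "reproductive", "positive-continuous"),
    # individual (plant size / architecture)
    TraitDef("plant_height", "individual", "positive-continuous"),
    TraitDef("stalk_number", "individual", "count"),
    TraitDef("stalk_diameter", "individual", "positive-continuous"),
    TraitDef("flower_number", "individual", "count"),
    # flower morphology
    TraitDef("petal_length", "flower", "positive-continuous"),
    TraitDef("flower_diameter", "flower", "positive-continuous"),
    TraitDef("corolla_tube_length", "flower", "positive-continuous"),
    TraitDef("long_filament_length", "flower", "positive-continuous"),
    TraitDef("short_filament_length", "flower", "positive-continuous"),
    TraitDef("style_length", "flower", "positive-continuous"),
    TraitDef("herkogamy", "flower", "positive-continuous"),
)

TRAIT_NAMES: tuple[str, ...] = tuple(t.name for t in DEFAULT_TRAITS)
TRAIT_BY_NAME: dict[str, TraitDef] = {t.name: t for t in DEFAULT_TRAITS}
MODULE_OF: dict[str, str] = {t.name: t.module for t in DEFAULT_TRAITS}


def trait_columns(table: pd.DataFrame) -> list[str]:
    """Trait columns present in ``table``, in catalogue order."""
    return [t for t in TRAIT_NAMES if t in table.columns]


def validate_table(table: pd.DataFrame, *, check_support: bool = False) -> pd.DataFrame:
    """Validate a tidy cohort table against the schema; return it unchanged.

    ``check_support`` additionally enforces per-kind value ranges (used by the
    pipeline's input validator; the basic schema check only enforces factor
    vocabularies, id uniqueness and numeric trait cells).
    """
    for col in ID_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"missing required column {col!r}")
    if table["plant_id"].duplicated().any():
        dup = table.loc[table["plant_id"].duplicated(), "plant_id"].iloc[0]
        raise SchemaError(f"duplicate plant_id {dup!r}")
    bad_ploidy = ~table["ploidy"].isin(PLOIDIES)
    if bad_ploidy.any():
        row = int(np.flatnonzero(bad_ploidy)[0])
        raise SchemaError(f"ploidy {table['ploidy'].iloc[row]!r} not in {PLOIDIES}", row=row + 1)
    bad_het = ~table["het_class"].isin(HET_CLASSES)
    if bad_het.any():
        row = int(np.flatnonzero(bad_het)[0])
        raise SchemaError(
            f"het_class {table['het_class'].iloc[row]!r} not in {HET_CLASSES}", row=row + 1
        )
    for name in trait_columns(table):
        col = table[name]
        if not pd.api.types.is_numeric_dtype(col):
            coerced = pd.to_numeric(col, errors="coerce")
            bad = coerced.isna() & col.notna()
            row = int(np.flatnonzero(bad)[0]) if bad.any() else 0
            raise SchemaError(f"non-numeric value in trait column {name!r}", row=row + 1)
        if check_support:
            _check_support(name, col)
    return table


def _check_support(name: str, col: pd.Series) -> None:
    kind = TRAIT_BY_NAME[name].kind
    x = col.dropna()
    if kind == "proportion" and ((x < 0) | (x > 1)).any():
        raise SchemaError(f"proportion trait {name!r} outside [0, 1]")
    if kind == "binary" and (~x.isin([0, 1])).any():
        raise SchemaError(f"binary trait {name!r} not in {{0, 1}}")
    if kind == "count" and ((x < 0) | (x != np.floor(x))).any():
        raise SchemaError(f"count trait {name!r} not a non-negative integer")
    if kind == "positive-continuous" and (x <= 0).any():
        raise SchemaError(f"positive-continuous trait {name!r} has non-positive values")


def write_table(table: pd.DataFrame, path) -> None:
    """Write a cohort table as tidy CSV (UTF-8, empty cell = missing)."""
    validate_table(table)
    cols = list(ID_COLUMNS) + trait_columns(table)
    table[cols].to_csv(path, index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Read and validate a tidy cohort CSV written by :func:`write_table`."""
    # keep_default_na: the het_class level "null" must survive as a string;
    # only the empty cell means missing
    table = pd.read_csv(path, encoding="utf-8", keep_default_na=False, na_values=[""])
    for name in trait_columns(table):
        if not pd.api.types.is_numeric_dtype(table[name]):
            coerced = pd.to_numeric(table[name], errors="coerce")
            bad = coerced.isna() & table[name].notna()
            if bad.any():
                raise SchemaError(
                    f"non-numeric value {table[name][bad].iloc[0]!r} in trait column {name!r}",
                    row=int(np.flatnonzero(bad)[0]) + 1,
                )
            table[name] = coerced
    return validate_table(table)
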