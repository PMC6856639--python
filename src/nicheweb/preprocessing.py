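"""Field-table preprocessing: cover conversion, pollen filtering, family
pooling, and [0,1] standardization.

The rules implemented here are the conventions of vegetation and
flower-visitor survey data: Braun-Blanquet trace symbols "+" and "r" stand
for 0.5 % and 0.1 % cover; percent cover is turned into integer
pseudo-counts by multiplying with 100 (so that trace covers below 1 %
survive as whole individuals); insect taxa qualify as pollinators only if
the mean pollen-load category over all four body regions and all sampled
individuals exceeds 1; and rarely-caught insect species are pooled into
families, which are the unit of analysis.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CoverParseError",
    "convert_cover",
    "integerize_abundance",
    "cover_to_counts",
    "filter_pollinators",
    "pool_interactions_to_family",
    "pool_traits_to_family",
    "pool_to_family",
    "standardize_environment",
    "standardize_columns",
    "seasonal_mean_temperature",
    "POLLEN_REGIONS",
]

POLLEN_REGIONS = ("head", "thorax", "abdomen", "legs")

_SYMBOLIC_COVER = {"+": 0.5, "r": 0.1}


class CoverParseError(ValueError):
    """A cover record that is neither a percent nor a known symbol."""


def convert_cover(cover) -> float:
    """Percent cover from one record; "+" → 0.5, "r" → 0.1.

    Numeric percents in (0, 100] pass through unchanged.
    """
    if isinstance(cover, str):
        stripped = cover.strip()
        if stripped in _SYMBOLIC_COVER:
            return _SYMBOLIC_COVER[stripped]
        try:
            value = float(stripped)
        except ValueError:
            raise CoverParseError(f"unknown cover code {cover!r}") from None
    else:
        value = float(cover)
    if not 0.0 < value <= 100.0:
        raise CoverParseError(f"percent cover {value} outside (0, 100]")
    return value


def integerize_abundance(percent: float) -> int:
    """Integer pseudo-abundance: round(percent × 100), halves away from zero.

    A result of 0 marks the taxon absent at that site.
    """
    if percent < 0:
        raise ValueError(f"negative percent cover: {percent}")
    return int(math.floor(percent * 100.0 + 0.5))


def cover_to_counts(values: Iterable) -> np.ndarray:
    """Vectorized convert_cover → integerize_abundance."""
    return np.array([integerize_abundance(convert_cover(v)) for v in values], dtype=int)


def filter_pollinators(
    pollen_records: pd.DataFrame,
    taxonomy: Mapping[str, str] | pd.DataFrame,
    families: Iterable[str] | None = None,
) -> set[str]:
    """Families whose pooled mean pollen-load category is strictly > 1.

    ``pollen_records`` holds one row per individual with integer categories
    0–4 for the four body regions; individuals of all member species are
    pooled before averaging, i.e. the filter is evaluated at the taxon
    (family) level at which the analysis runs.
    """
    tax = _taxonomy_mapping(taxonomy)
    missing = [c for c in ("species", "individual", *POLLEN_REGIONS) if c not in pollen_records.columns]
    if missing:
        raise ValueError(f"pollen table missing columns: {missing}")
    cats = pollen_records[list(POLLEN_REGIONS)].to_numpy()
    if not np.array_equal(cats, cats.astype(int)) or cats.min() < 0 or cats.max() > 4:
        raise ValueError("pollen categories must be integers in [0, 4]")
    fam_col = pollen_records["species"].map(tax)
    if fam_col.isna().any():
        offenders = sorted(pollen_records.loc[fam_col.isna(), "species"].unique())
        raise ValueError(f"species without taxonomy entry: {offenders}")
    per_family_mean = pd.Series(cats.mean(axis=1), index=fam_col.values).groupby(level=0).mean()
    wanted = set(families) if families is not None else set(tax.values())
    unevaluable = wanted - set(per_family_mean.index)
    if unevaluable:
        raise ValueError(f"taxa with zero pollen records, cannot evaluate filter: {sorted(unevaluable)}")
    return {fam for fam in wanted if per_family_mean[fam] > 1.0}


def _taxonomy_mapping(taxonomy) -> dict[str, str]:
    if isinstance(taxonomy, pd.DataFrame):
        if not {"species", "family"} <= set(taxonomy.columns):
            raise ValueError("taxonomy table needs 'species' and 'family' columns")
        return dict(zip(taxonomy["species"], taxonomy["family"]))
    return dict(taxonomy)


def pool_interactions_to_family(interactions: pd.DataFrame, taxonomy) -> pd.DataFrame:
    """Sum species-level interaction rows into family rows.

    ``interactions`` is the long table (animal, plant, site, count);
    plants stay at species level.  Unmapped animal species are an error.
    """
    tax = _taxonomy_mapping(taxonomy)
    unmapped = sorted(set(interactions["animal"]) - set(tax))
    if unmapped:
        raise ValueError(f"animal species missing from taxonomy: {unmapped}")
    pooled = interactions.assign(animal=interactions["animal"].map(tax))
    keys = [c for c in ("animal", "plant", "site") if c in pooled.columns]
    return pooled.groupby(keys, as_index=False)["count"].sum()


def pool_traits_to_family(traits: pd.DataFrame, taxonomy) -> pd.DataFrame:
    """Relabel phenotyped individuals to their family, keeping every row."""
    tax = _taxonomy_mapping(taxonomy)
    is_animal = traits["taxon"].isin(tax)
    out = traits.copy()
    out.loc[is_animal, "taxon"] = out.loc[is_animal, "taxon"].map(tax)
    return out


def pool_to_family(
    interactions: pd.DataFrame,
    traits: pd.DataFrame,
    taxonomy,
    kept_families: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool animal species to families, optionally dropping filtered taxa.

    Families absent from ``kept_families`` (e.g. removed by the pollen
    filter) are dropped entirely from both tables.
    """
    pooled_int = pool_interactions_to_family(interactions, taxonomy)
    pooled_traits = pool_traits_to_family(traits, taxonomy)
    if kept_families is not None:
        kept = set(kept_families)
        fams = set(_taxonomy_mapping(taxonomy).values())
        pooled_int = pooled_int[pooled_int["animal"].isin(kept)].reset_index(drop=True)
        drop = fams - kept
        pooled_traits = pooled_traits[~pooled_traits["taxon"].isin(drop)].reset_index(drop=True)
    return pooled_int, pooled_traits


def standardize_environment(values) -> np.ndarray:
    """Min–max standardization x' = (x − min)/(max − min) to [0, 1].

    Computed per dimension within one pool (one scale).  A degenerate
    dimension (max = min) maps every value to 0.5 with a warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("standardization needs at least 2 values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        warnings.warn("degenerate dimension (max = min); mapping all values to 0.5")
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def standardize_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Column-wise min–max standardization of a numeric table."""
    out = frame.copy()
    for col in out.columns:
        out[col] = standardize_environment(out[col].to_numpy())
    return out


def seasonal_mean_temperature(recordings) -> float:
    """Season mean of a logger series: a plain arithmetic mean."""
    arr = np.asarray(recordings, dtype=float)
    if arr.size == 0:
        raise ValueError("empty temperature series")
    return float(arr.mean())
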