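"""Niche position, marginality, and dynamic range-box volume.

One machinery serves two niche types.  The realized Grinnellian niche of a
taxon is the cloud of standardized (temperature', aspect') site values,
each site replicated as many times as the taxon's abundance there (V = Σ_p
a_pj rows).  The fundamental Eltonian niche is the cloud of phenotyped
individuals in standardized trait space (one row per individual).  From a
cloud we derive the position J (column mean — replication encodes the
abundance weighting), the marginality M_j (Euclidean distance of J to the
centroid c of all same-trophic-level taxon positions), and the niche
volume vol(j) via dynamic range boxes: per dimension the (Q_{1−α} − Q_α)
quantile range relative to the pooled global range, aggregated over
dimensions and averaged over a grid of quantile levels α ∈ [0, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RangeBoxConfig",
    "DEFAULT_ALPHA_GRID",
    "build_weighted_cloud",
    "trait_cloud",
    "trait_clouds",
    "niche_position",
    "marginality",
    "range_box_volume",
    "global_ranges",
    "niche_summaries",
]

#: 11 evenly spaced quantile levels, 0 … 0.5.
DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 0.5, 11), 10))


@dataclass
class RangeBoxConfig:
    """Settings of the dynamic range-box volume.

    ``global_ranges`` holds per-dimension (lo, hi) bounds from the pooled
    data of all taxa of the trophic level; a degenerate dimension
    (lo == hi) contributes length 0.
    """

    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    dimension_aggregation: str = "mean"
    global_ranges: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        grid = tuple(float(a) for a in self.alpha_grid)
        if len(grid) == 0:
            raise ValueError("alpha_grid must be non-empty")
        if any(not 0.0 <= a <= 0.5 for a in grid):
            raise ValueError("alpha levels must lie in [0, 0.5]")
        if list(grid) != sorted(grid):
            raise ValueError("alpha_grid must be increasing")
        self.alpha_grid = grid
        if self.dimension_aggregation not in ("mean", "product"):
            raise ValueError("dimension_aggregation must be 'mean' or 'product'")


def build_weighted_cloud(taxon: str, env_table: pd.DataFrame, abundance: pd.Series) -> np.ndarray:
    """Replicate each site's environment row a_pj times (V × d matrix).

    ``env_table`` is indexed by site (values already standardized);
    ``abundance`` maps site → integer a_pj for the taxon.
    """
    common = env_table.index.intersection(abundance.index)
    weights = abundance.reindex(common).fillna(0).to_numpy()
    if (weights < 0).any():
        raise ValueError(f"taxon {taxon}: negative abundance")
    weights = weights.astype(int)
    if weights.sum() == 0:
        raise ValueError(f"taxon {taxon} absent from pool (total abundance 0)")
    rows = env_table.loc[common].to_numpy(dtype=float)
    return np.repeat(rows, weights, axis=0)


def trait_cloud(taxon: str, trait_table: pd.DataFrame) -> np.ndarray:
    """One row per phenotyped individual of ``taxon`` (individuals × traits).

    ``trait_table`` is wide — indexed by (taxon, individual), one column
    per trait.  For animal taxa the individuals of all member species have
    already been pooled under the family label.
    """
    try:
        block = trait_table.xs(taxon, level="taxon")
    except KeyError:
        raise ValueError(f"taxon {taxon}: no phenotyped individuals") from None
    if len(block) == 0:
        raise ValueError(f"taxon {taxon}: no phenotyped individuals")
    return block.to_numpy(dtype=float)


def trait_clouds(trait_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long traits schema to a wide (taxon, individual) × trait table."""
    wide = trait_long.pivot_table(
        index=["taxon", "individual"], columns="trait", values="value", aggfunc="first"
    )
    wide.columns.name = None
    return wide


def niche_position(cloud: np.ndarray) -> np.ndarray:
    """Position J: column mean of the cloud matrix."""
    cloud = np.asarray(cloud, dtype=float)
    if cloud.size == 0:
        raise ValueError("empty cloud")
    return cloud.mean(axis=0)


def marginality(positions: pd.DataFrame) -> pd.Series:
    """M_j = ||J_j − c|| with c the unweighted mean of the taxon positions.

    ``positions`` is taxa × dimensions; computed separately per trophic
    level, niche type, and scale by the caller.  A single taxon gets M = 0.
    """
    if len(positions) == 0:
        raise ValueError("no taxon positions")
    centroid = positions.mean(axis=0)
    deviations = positions - centroid
    return pd.Series(np.linalg.norm(deviations.to_numpy(dtype=float), axis=1), index=positions.index)


def global_ranges(clouds: dict[str, np.ndarray]) -> tuple[tuple[float, float], ...]:
    """Per-dimension (lo, hi) over the pooled rows of all taxa of a level."""
    stacked = np.vstack(list(clouds.values()))
    return tuple((float(lo), float(hi)) for lo, hi in zip(stacked.min(axis=0), stacked.max(axis=0)))


def range_box_volume(cloud: np.ndarray, config: RangeBoxConfig) -> float:
    """Dynamic range-box volume vol(j) ∈ [0, 1].

    Per dimension k and quantile level α the box length is
    ``(Q_{1−α} − Q_α)/(hi_k − lo_k)`` (linear-interpolation quantiles),
    clipped to [0, 1]; per-α size aggregates lengths over dimensions
    (default: mean); vol(j) is the mean over the α grid.
    """
    cloud = np.atleast_2d(np.asarray(cloud, dtype=float))
    if cloud.size == 0:
        raise ValueError("empty cloud")
    if config.global_ranges is None:
        raise ValueError("RangeBoxConfig.global_ranges must be set")
    ranges = np.asarray(config.global_ranges, dtype=float)
    if ranges.shape != (cloud.shape[1], 2):
        raise ValueError(
            f"global_ranges has {ranges.shape[0]} dimensions, cloud has {cloud.shape[1]}"
        )
    widths = ranges[:, 1] - ranges[:, 0]
    if (widths < 0).any():
        raise ValueError("global ranges must have lo <= hi")
    alphas = np.asarray(config.alpha_grid)
    lower = np.quantile(cloud, alphas, axis=0)  # levels × dims
    upper = np.quantile(cloud, 1.0 - alphas, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lengths = np.where(widths > 0, (upper - lower) / widths, 0.0)
    lengths = np.clip(lengths, 0.0, 1.0)
    if config.dimension_aggregation == "mean":
        per_alpha = lengths.mean(axis=1)
    else:
        per_alpha = lengths.prod(axis=1)
    return float(per_alpha.mean())


def niche_summaries(
    clouds: dict[str, np.ndarray],
    niche_type: str,
    trophic_level: str,
    scale: str,
    config: RangeBoxConfig | None = None,
    dimension_names: list[str] | None = None,
) -> pd.DataFrame:
    """Position, marginality, and volume for every taxon of one pool.

    The global ranges default to the pooled data of the supplied clouds.
    Returns one row per taxon: J components, marginality, volume, V.
    """
    if not clouds:
        raise ValueError("no clouds supplied")
    config = config or RangeBoxConfig()
    if config.global_ranges is None:
        config = RangeBoxConfig(
            alpha_grid=config.alpha_grid,
            dimension_aggregation=config.dimension_aggregation,
            global_ranges=global_ranges(clouds),
        )
    taxa = list(clouds)
    positions = pd.DataFrame(
        [niche_position(clouds[t]) for t in taxa],
        index=taxa,
        columns=dimension_names,
    )
    margins = marginality(positions)
    volumes = pd.Series({t: range_box_volume(clouds[t], config) for t in taxa})
    out = positions.copy()
    out.columns = [f"J_{c}" for c in (dimension_names or range(positions.shape[1]))]
    out.insert(0, "taxon", taxa)
    out["marginality"] = margins.values
    out["volume"] = volumes.reindex(taxa).values
    out["V"] = [clouds[t].shape[0] for t in taxa]
    out["niche_type"] = niche_type
    out["trophic_level"] = trophic_level
    out["scale"] = scale
    return out.reset_index(drop=True)
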