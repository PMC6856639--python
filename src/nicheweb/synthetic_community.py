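"""Generator of field-study-shaped community data with known ground truth.

Emulates the tables produced by a plant–flower-visitor field campaign along
a temperature/aspect gradient: site records, Braun-Blanquet-style plant
cover, per-site animal observations, individual-level morphology, pollen
load categories, a species→family taxonomy, and per-site interaction
counts.  Abundances follow Gaussian responses along the environmental
gradient; interaction rates couple to the environment (``coupling_theta``)
and to trait matching between proboscis length and nectar depth
(``matching_gamma``).  Every quantity is reproducible from a single seed
via a fixed stream-splitting rule (one child stream per named stage, in
:data:`STREAMS` order).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteRecord",
    "TrueTaxonParams",
    "SimulationConfig",
    "generate_sites",
    "generate_taxa",
    "generate_abundances",
    "interaction_rates",
    "generate_interactions",
    "generate_traits",
    "generate_pollen",
    "generate_community",
    "generate_study",
    "write_community",
]

#: Named random streams split from the master seed, in spawn order.
STREAMS = (
    "sites",
    "taxa",
    "plant_abundance",
    "animal_abundance",
    "interactions",
    "traits",
    "pollen",
)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Child generator for one named stage of the simulation.

    Uses ``SeedSequence(seed).spawn`` with a fixed stage ordering so that
    adding draws inside one stage never perturbs another.
    """
    try:
        index = STREAMS.index(stream)
    except ValueError as exc:
        raise ValueError(f"unknown random stream {stream!r}") from exc
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return np.random.default_rng(children[index])


@dataclass(frozen=True)
class SiteRecord:
    """One transect or plot along the gradient.

    Aspect is folded to a 0–180° southness axis (north 0°, south 180°,
    east and west 90°).
    """

    site_id: str
    scale: str  # "local" | "regional"
    mean_temperature: float
    aspect: float
    elevation: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("local", "regional"):
            raise ValueError(f"scale must be 'local' or 'regional', got {self.scale!r}")
        if not np.isfinite(self.mean_temperature):
            raise ValueError(f"site {self.site_id}: temperature must be finite")
        if not 0.0 <= self.aspect <= 180.0:
            raise ValueError(f"site {self.site_id}: aspect {self.aspect} outside [0, 180]")


@dataclass(frozen=True)
class TrueTaxonParams:
    """Ground-truth niche and trait architecture of one simulated taxon."""

    taxon_id: str
    trophic_level: str  # "plant" | "animal"
    env_optimum: tuple[float, float]  # (temperature °C, aspect °)
    env_breadth: tuple[float, float]  # per-dimension Gaussian sd, same units
    trait_means: tuple[float, float, float]
    trait_sd: tuple[float, float, float]
    baseline_abundance: float

    def __post_init__(self) -> None:
        if self.trophic_level not in ("plant", "animal"):
            raise ValueError(f"trophic_level must be plant/animal, got {self.trophic_level!r}")
        if any(b <= 0 for b in self.env_breadth):
            raise ValueError(f"taxon {self.taxon_id}: env breadths must be > 0")
        if any(s <= 0 for s in self.trait_sd):
            raise ValueError(f"taxon {self.taxon_id}: trait sds must be > 0")
        if self.baseline_abundance <= 0:
            raise ValueError(f"taxon {self.taxon_id}: baseline abundance must be > 0")


# Default study conditions.  The gradient spans 10 °C (≈ the soil-temperature
# span of a 1,400 m elevational gradient) and the folded aspect axis 180°.
# Default environmental breadths are deliberately broad relative to the
# gradient (1.5 × span): the sampled community consists of environmental
# generalists, so that with coupling_theta = 0 the interaction structure is
# (to good approximation) independent of the environment — narrow breadths
# are passed explicitly in scenarios that need strong environmental
# filtering.
@dataclass
class SimulationConfig:
    """Knobs of the community simulation; ``theta``/``gamma`` ≥ 0."""

    n_sites: int = 24
    n_plants: int = 12
    n_animals: int = 8
    coupling_theta: float = 0.0
    matching_gamma: float = 0.0
    total_interactions: int = 800
    seed: int = 0
    scale: str = "regional"
    temperature_range: tuple[float, float] = (5.0, 15.0)
    temperature_noise_sd: float = 0.3
    aspect_range: tuple[float, float] = (0.0, 180.0)
    env_breadth: tuple[float, float] = (15.0, 270.0)
    plant_baseline: float = 30.0
    animal_baseline: float = 20.0
    strict_matching: bool = False
    n_species_per_family: int = 1
    n_individuals: int = 8
    nonpollinator_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_plants", "n_animals", "total_interactions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2 to span a gradient")
        if self.coupling_theta < 0 or self.matching_gamma < 0:
            raise ValueError("coupling_theta and matching_gamma must be >= 0")
        if self.temperature_range[0] >= self.temperature_range[1]:
            raise ValueError("temperature_range must be increasing")
        if not (0 <= self.aspect_range[0] < self.aspect_range[1] <= 180):
            raise ValueError("aspect_range must be an increasing subrange of [0, 180]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def generate_sites(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[SiteRecord]:
    """Sites evenly covering the temperature gradient, aspects uniform.

    Temperatures are equally spaced over ``temperature_range`` with additive
    Gaussian noise (sd ``temperature_noise_sd``); aspects are uniform on the
    folded axis.
    """
    if config.n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = rng if rng is not None else stream_rng(config.seed, "sites")
    lo, hi = config.temperature_range
    temps = np.linspace(lo, hi, config.n_sites)
    temps = temps + rng.normal(0.0, config.temperature_noise_sd, size=config.n_sites)
    aspects = rng.uniform(config.aspect_range[0], config.aspect_range[1], size=config.n_sites)
    prefix = "P" if config.scale == "local" else "T"
    return [
        SiteRecord(
            site_id=f"{prefix}{k + 1:02d}",
            scale=config.scale,
            mean_temperature=float(temps[k]),
            aspect=float(aspects[k]),
        )
        for k in range(config.n_sites)
    ]


def sites_frame(sites: Sequence[SiteRecord]) -> pd.DataFrame:
    """Site table in the sites.csv schema."""
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "scale": [s.scale for s in sites],
            "temperature": [s.mean_temperature for s in sites],
            "aspect": [s.aspect for s in sites],
        }
    )


def generate_taxa(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[TrueTaxonParams]:
    """Sample a default community of plant and animal taxa.

    Environmental optima are uniform over the gradient; trait architecture
    follows field-plausible ranges in mm (about a quarter of plants are
    open/bowl flowers with nectar depth 0).
    """
    rng = rng if rng is not None else stream_rng(config.seed, "taxa")
    t_lo, t_hi = config.temperature_range
    a_lo, a_hi = config.aspect_range
    taxa: list[TrueTaxonParams] = []
    for j in range(config.n_plants):
        depth = 0.0 if rng.random() < 0.25 else float(rng.uniform(1.0, 9.0))
        taxa.append(
            TrueTaxonParams(
                taxon_id=f"plant_{j + 1:02d}",
                trophic_level="plant",
                env_optimum=(float(rng.uniform(t_lo, t_hi)), float(rng.uniform(a_lo, a_hi))),
                env_breadth=config.env_breadth,
                trait_means=(depth, float(rng.uniform(1.0, 6.0)), float(rng.normal(1.0, 1.5))),
                trait_sd=(max(0.2, 0.1 * depth), 0.3, 0.4),
                baseline_abundance=float(config.plant_baseline * rng.lognormal(0.0, 0.4)),
            )
        )
    for i in range(config.n_animals):
        proboscis = float(rng.uniform(1.0, 10.0))
        taxa.append(
            TrueTaxonParams(
                taxon_id=f"animal_{i + 1:02d}",
                trophic_level="animal",
                env_optimum=(float(rng.uniform(t_lo, t_hi)), float(rng.uniform(a_lo, a_hi))),
                env_breadth=config.env_breadth,
                trait_means=(proboscis, float(rng.uniform(1.0, 3.5)), float(rng.uniform(4.0, 14.0))),
                trait_sd=(max(0.2, 0.08 * proboscis), 0.2, 0.8),
                baseline_abundance=float(config.animal_baseline * rng.lognormal(0.0, 0.4)),
            )
        )
    return taxa


def _gaussian_response(taxon: TrueTaxonParams, sites: Sequence[SiteRecord]) -> np.ndarray:
    x = np.array([[s.mean_temperature, s.aspect] for s in sites])
    opt = np.asarray(taxon.env_optimum, dtype=float)
    breadth = np.asarray(taxon.env_breadth, dtype=float)
    z = (x - opt) / breadth
    return np.exp(-0.5 * np.sum(z**2, axis=1))


def generate_abundances(
    taxa: Sequence[TrueTaxonParams],
    sites: Sequence[SiteRecord],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson counts around a Gaussian response surface (taxa × sites).

    Expected abundance of taxon *j* at site *p* is
    ``baseline × exp(−Σ_k ((x_pk − optimum_k)/breadth_k)² / 2)``.
    """
    if len(sites) == 0:
        raise ValueError("empty site list")
    if len(taxa) == 0:
        raise ValueError("empty taxon list")
    means = np.vstack([t.baseline_abundance * _gaussian_response(t, sites) for t in taxa])
    counts = rng.poisson(means)
    return pd.DataFrame(counts, index=[t.taxon_id for t in taxa], columns=[s.site_id for s in sites])


def expected_abundances(taxa: Sequence[TrueTaxonParams], sites: Sequence[SiteRecord]) -> pd.DataFrame:
    """Noise-free Poisson means of :func:`generate_abundances`."""
    means = np.vstack([t.baseline_abundance * _gaussian_response(t, sites) for t in taxa])
    return pd.DataFrame(means, index=[t.taxon_id for t in taxa], columns=[s.site_id for s in sites])


def _env_distance(animals: Sequence[TrueTaxonParams], plants: Sequence[TrueTaxonParams], config: SimulationConfig) -> np.ndarray:
    """Unitless optimum distance: each dimension scaled by its gradient span."""
    spans = np.array(
        [
            config.temperature_range[1] - config.temperature_range[0],
            config.aspect_range[1] - config.aspect_range[0],
        ]
    )
    a = np.array([t.env_optimum for t in animals]) / spans
    p = np.array([t.env_optimum for t in plants]) / spans
    diff = a[:, None, :] - p[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=2))


def _trait_mismatch(animals: Sequence[TrueTaxonParams], plants: Sequence[TrueTaxonParams]) -> np.ndarray:
    """|proboscis length − nectar depth| in mm (animal × plant)."""
    proboscis = np.array([t.trait_means[0] for t in animals])
    depth = np.array([t.trait_means[0] for t in plants])
    return np.abs(proboscis[:, None] - depth[None, :])


def interaction_rates(
    plant_abundance: pd.DataFrame,
    animal_abundance: pd.DataFrame,
    animals: Sequence[TrueTaxonParams],
    plants: Sequence[TrueTaxonParams],
    config: SimulationConfig,
) -> np.ndarray:
    """Unnormalized rate tensor (site × animal × plant).

    Rate ∝ a_pi · a_pj · exp(−θ·D_env(i,j)) · exp(−γ·mismatch(i,j)); under
    ``strict_matching`` a proboscis shorter than the nectar tube forbids the
    link outright.
    """
    sites = list(plant_abundance.columns)
    if list(animal_abundance.columns) != sites:
        raise ValueError("plant and animal abundance tables must share the site axis")
    a = animal_abundance.to_numpy(dtype=float)  # animals × sites
    p = plant_abundance.to_numpy(dtype=float)  # plants × sites
    kernel = np.exp(-config.coupling_theta * _env_distance(animals, plants, config))
    kernel = kernel * np.exp(-config.matching_gamma * _trait_mismatch(animals, plants))
    if config.strict_matching:
        proboscis = np.array([t.trait_means[0] for t in animals])
        depth = np.array([t.trait_means[0] for t in plants])
        kernel = kernel * (proboscis[:, None] >= depth[None, :])
    # site-major tensor: rates[s, i, j]
    rates = a.T[:, :, None] * p.T[:, None, :] * kernel[None, :, :]
    return rates


def generate_interactions(
    plant_abundance: pd.DataFrame,
    animal_abundance: pd.DataFrame,
    animals: Sequence[TrueTaxonParams],
    plants: Sequence[TrueTaxonParams],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial allocation of ``total_interactions`` over (site, i, j).

    Returns the aggregate animal × plant count matrix and the long per-site
    table (animal, plant, site, count).
    """
    rates = interaction_rates(plant_abundance, animal_abundance, animals, plants, config)
    total_rate = rates.sum()
    if total_rate <= 0:
        raise ValueError("all interaction rates are zero: no co-occurring taxa")
    flat = rates.ravel() / total_rate
    counts = rng.multinomial(config.total_interactions, flat).reshape(rates.shape)
    animal_ids = list(animal_abundance.index)
    plant_ids = list(plant_abundance.index)
    site_ids = list(plant_abundance.columns)
    aggregate = pd.DataFrame(counts.sum(axis=0), index=animal_ids, columns=plant_ids)
    s_idx, i_idx, j_idx = np.nonzero(counts)
    per_site = pd.DataFrame(
        {
            "animal": [animal_ids[i] for i in i_idx],
            "plant": [plant_ids[j] for j in j_idx],
            "site": [site_ids[s] for s in s_idx],
            "count": counts[s_idx, i_idx, j_idx],
        }
    )
    return aggregate, per_site


def generate_traits(
    taxa: Sequence[TrueTaxonParams],
    config: SimulationConfig,
    rng: np.random.Generator,
    species_of: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Individual-level morphology in the long traits.csv schema.

    Plants: nectar_depth (≥ 0; exactly 0 for open/bowl flowers),
    nectar_width (> 0), anther_position (may be negative).  Animals:
    proboscis_length, head_width, body_length (> 0).  ``species_of`` maps a
    taxon to its member species; individuals are drawn per species.
    """
    plant_traits = ("nectar_depth", "nectar_width", "anther_position")
    animal_traits = ("proboscis_length", "head_width", "body_length")
    rows: list[dict] = []
    for t in taxa:
        names = plant_traits if t.trophic_level == "plant" else animal_traits
        members = list(species_of.get(t.taxon_id, [t.taxon_id])) if species_of else [t.taxon_id]
        for sp in members:
            for ind in range(1, config.n_individuals + 1):
                values = rng.normal(t.trait_means, t.trait_sd)
                if t.trophic_level == "plant":
                    values[0] = 0.0 if t.trait_means[0] == 0.0 else max(values[0], 0.05)
                    values[1] = max(values[1], 0.05)
                else:
                    values = np.maximum(values, 0.05)
                for name, value in zip(names, values):
                    rows.append(
                        {"taxon": sp, "individual": f"{sp}_i{ind}", "trait": name, "value": float(value)}
                    )
    return pd.DataFrame(rows)


def generate_pollen(
    animal_species: Sequence[str],
    nonpollinators: Sequence[str],
    rng: np.random.Generator,
    n_individuals: int = 5,
) -> pd.DataFrame:
    """Pollen-load categories (0–4) for four body regions per individual.

    Species listed in ``nonpollinators`` receive loads with mean category
    ≤ 1 and are expected to be removed by the downstream filter.
    """
    rows = []
    poor = set(nonpollinators)
    for sp in animal_species:
        if sp in poor:
            probs = [0.65, 0.3, 0.05, 0.0, 0.0]  # mean 0.4
        else:
            probs = [0.05, 0.15, 0.35, 0.3, 0.15]  # mean 2.35
        for ind in range(1, n_individuals + 1):
            cats = rng.choice(5, size=4, p=probs)
            rows.append(
                {
                    "species": sp,
                    "individual": f"{sp}_i{ind}",
                    "head": int(cats[0]),
                    "thorax": int(cats[1]),
                    "abdomen": int(cats[2]),
                    "legs": int(cats[3]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Community:
    """One simulated scale: sites plus all field-style tables."""

    config: SimulationConfig
    taxa: list[TrueTaxonParams]
    sites: list[SiteRecord]
    plant_abundance: pd.DataFrame  # plants × sites, integer counts
    animal_abundance: pd.DataFrame  # animals × sites, integer counts
    interactions: pd.DataFrame  # aggregate animals × plants
    interactions_per_site: pd.DataFrame  # long (animal, plant, site, count)

    @property
    def plants(self) -> list[TrueTaxonParams]:
        return [t for t in self.taxa if t.trophic_level == "plant"]

    @property
    def animals(self) -> list[TrueTaxonParams]:
        return [t for t in self.taxa if t.trophic_level == "animal"]


def generate_community(
    config: SimulationConfig,
    taxa: Sequence[TrueTaxonParams] | None = None,
    sites: Sequence[SiteRecord] | None = None,
) -> Community:
    """Simulate one scale: sites, abundances, and interaction counts."""
    taxa = list(taxa) if taxa is not None else generate_taxa(config)
    sites = list(sites) if sites is not None else generate_sites(config)
    plants = [t for t in taxa if t.trophic_level == "plant"]
    animals = [t for t in taxa if t.trophic_level == "animal"]
    if not plants or not animals:
        raise ValueError("need at least one plant and one animal taxon")
    plant_ab = generate_abundances(plants, sites, stream_rng(config.seed, "plant_abundance"))
    animal_ab = generate_abundances(animals, sites, stream_rng(config.seed, "animal_abundance"))
    aggregate, per_site = generate_interactions(
        plant_ab, animal_ab, animals, plants, config, stream_rng(config.seed, "interactions")
    )
    return Community(
        config=config,
        taxa=taxa,
        sites=sites,
        plant_abundance=plant_ab,
        animal_abundance=animal_ab,
        interactions=aggregate,
        interactions_per_site=per_site,
    )


@dataclass
class Study:
    """A two-scale study sharing one taxon pool, plus taxonomy/traits/pollen."""

    regional: Community
    local: Community
    taxonomy: pd.DataFrame  # species, family
    traits: pd.DataFrame  # long schema
    pollen: pd.DataFrame
    species_of: dict[str, list[str]] = field(default_factory=dict)


def generate_study(config: SimulationConfig) -> Study:
    """Simulate both scales of the field design from one master seed.

    The regional scale spans the full temperature gradient; the local scale
    emulates microclimatic variation within one meadow (central fifth of
    the gradient, full folded-aspect variation, a quarter of the regional
    interaction total — mirroring the relative sampling effort of transect
    versus plot campaigns).
    """
    taxa = generate_taxa(config)
    t_lo, t_hi = config.temperature_range
    span = t_hi - t_lo
    mid = 0.5 * (t_lo + t_hi)
    local_config = config.replace(
        scale="local",
        seed=config.seed + 1,
        temperature_range=(mid - 0.1 * span, mid + 0.1 * span),
        total_interactions=max(1, config.total_interactions // 4),
    )
    regional_config = config.replace(scale="regional")
    regional = generate_community(regional_config, taxa=taxa)
    local = generate_community(local_config, taxa=taxa)

    rng_taxa = stream_rng(config.seed, "taxa")
    animal_ids = [t.taxon_id for t in taxa if t.trophic_level == "animal"]
    species_of: dict[str, list[str]] = {}
    tax_rows = []
    for fam in animal_ids:
        members = [f"{fam}_sp{k + 1}" for k in range(max(1, config.n_species_per_family))]
        species_of[fam] = members
        for sp in members:
            tax_rows.append({"species": sp, "family": fam})
    taxonomy = pd.DataFrame(tax_rows)

    n_poor = int(round(config.nonpollinator_fraction * len(animal_ids)))
    poor_families = list(rng_taxa.choice(animal_ids, size=n_poor, replace=False)) if n_poor else []
    poor_species = [sp for fam in poor_families for sp in species_of[fam]]
    all_species = [sp for fam in animal_ids for sp in species_of[fam]]

    traits = generate_traits(taxa, config, stream_rng(config.seed, "traits"), species_of=species_of)
    pollen = generate_pollen(all_species, poor_species, stream_rng(config.seed, "pollen"))
    return Study(
        regional=regional,
        local=local,
        taxonomy=taxonomy,
        traits=traits,
        pollen=pollen,
        species_of=species_of,
    )


def edge_length_inputs(
    config: SimulationConfig,
    taxa: Sequence[TrueTaxonParams] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interaction matrix and Grinnellian positions for the edge-length test.

    Positions of both trophic levels come from the generator's independent
    abundance tables (not from the interaction counts themselves, which
    would make the tested matrix and the positions circular), placed in
    the per-scale standardized [0, 1]² environment space.
    """
    from .niche_spaces import build_weighted_cloud, niche_position
    from .preprocessing import standardize_columns

    community = generate_community(config, taxa=taxa)
    env = sites_frame(community.sites).set_index("site_id")[["temperature", "aspect"]]
    env_std = standardize_columns(env)
    positions = {}
    for abundance in (community.plant_abundance, community.animal_abundance):
        for taxon in abundance.index:
            if abundance.loc[taxon].sum() == 0:
                continue
            cloud = build_weighted_cloud(taxon, env_std, abundance.loc[taxon])
            positions[taxon] = niche_position(cloud)
    positions_df = pd.DataFrame(positions).T
    positions_df.columns = ["temperature", "aspect"]
    matrix = community.interactions
    keep_rows = [t for t in matrix.index if t in positions_df.index]
    keep_cols = [t for t in matrix.columns if t in positions_df.index]
    matrix = matrix.loc[keep_rows, keep_cols]
    matrix = matrix.loc[matrix.sum(axis=1) > 0, matrix.sum(axis=0) > 0]
    return matrix, positions_df


def _interactions_to_species(per_site: pd.DataFrame, species_of: Mapping[str, Sequence[str]], rng: np.random.Generator) -> pd.DataFrame:
    """Split family-level interaction rows uniformly over member species."""
    rows = []
    for rec in per_site.itertuples(index=False):
        members = list(species_of.get(rec.animal, [rec.animal]))
        if len(members) == 1:
            rows.append({"animal": members[0], "plant": rec.plant, "site": rec.site, "count": rec.count})
            continue
        split = rng.multinomial(rec.count, np.full(len(members), 1.0 / len(members)))
        for sp, c in zip(members, split):
            if c:
                rows.append({"animal": sp, "plant": rec.plant, "site": rec.site, "count": int(c)})
    return pd.DataFrame(rows, columns=["animal", "plant", "site", "count"])


def _plant_cover_records(abundance: pd.DataFrame, rng: np.random.Generator, code_fraction: float = 0.1) -> pd.DataFrame:
    """Integer cover counts back-transformed to percent cover records.

    A fraction of trace presences (counts 50 and 10, i.e. 0.5 % and 0.1 %)
    is recorded with the Braun-Blanquet symbols "+" and "r" to exercise the
    downstream substitution rule.
    """
    rows = []
    for taxon, series in abundance.iterrows():
        for site, count in series.items():
            if count <= 0:
                continue
            percent = count / 100.0
            value: str | float = percent
            if count == 50 and rng.random() < code_fraction:
                value = "+"
            elif count == 10 and rng.random() < code_fraction:
                value = "r"
            rows.append({"taxon": taxon, "site": site, "value": value})
    return pd.DataFrame(rows, columns=["taxon", "site", "value"])


def write_community(study: Study, outdir) -> dict[str, str]:
    """Write the study as the CSV bundle consumed by the pipeline.

    Schemas: sites.csv (site_id, scale, temperature, aspect), abundance.csv
    (taxon, site, value — percent cover or "+"/"r" for plants, observed
    counts for animals), traits.csv (taxon, individual, trait, value),
    interactions.csv (animal, plant, site, count; animals at species
    level), pollen.csv (species, individual, head, thorax, abdomen, legs),
    taxonomy.csv (species, family).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = study.regional.config.seed
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(99,)))

    sites = pd.concat([sites_frame(study.regional.sites), sites_frame(study.local.sites)], ignore_index=True)

    abundance_parts = []
    for comm in (study.regional, study.local):
        abundance_parts.append(_plant_cover_records(comm.plant_abundance, rng))
        animal_long = (
            comm.animal_abundance.rename_axis(index="taxon", columns="site")
            .stack()
            .rename("value")
            .reset_index()
        )
        abundance_parts.append(animal_long[animal_long["value"] > 0])
    abundance = pd.concat(abundance_parts, ignore_index=True)

    interactions = pd.concat(
        [
            _interactions_to_species(study.regional.interactions_per_site, study.species_of, rng),
            _interactions_to_species(study.local.interactions_per_site, study.species_of, rng),
        ],
        ignore_index=True,
    )

    paths = {}
    for name, frame in (
        ("sites", sites),
        ("abundance", abundance),
        ("traits", study.traits),
        ("interactions", interactions),
        ("pollen", study.pollen),
        ("taxonomy", study.taxonomy),
    ):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = str(path)
    return paths
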