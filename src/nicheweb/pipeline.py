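"""End-to-end orchestration: raw CSV tables → niches, roles, integration
networks, and the edge-length null test, per spatial scale.

Input bundle (UTF-8 CSV with header row):

* ``sites.csv``: site_id, scale, temperature, aspect
* ``abundance.csv``: taxon, site, value (percent cover or "+"/"r" for
  plants; observed counts for animals)
* ``traits.csv``: taxon, individual, trait, value
* ``interactions.csv``: animal, plant, site, count (animals at species level)
* ``pollen.csv``: species, individual, head, thorax, abdomen, legs
* ``taxonomy.csv``: species, family

Outputs: niches.csv, roles.csv, correlations.csv, network.json,
table1.csv (cross-scale correlations), table2.csv (interaction-frequency
correlations), edgetest.json, manifest.json.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bipartite_roles, niche_integration, niche_spaces, preprocessing
from .edge_length_null import edge_length_test
from .synthetic_community import SimulationConfig, generate_study, write_community

logger = logging.getLogger("nicheweb")

INPUT_FILES = ("sites", "abundance", "traits", "interactions", "pollen", "taxonomy")

_SCHEMAS = {
    "sites": ["site_id", "scale", "temperature", "aspect"],
    "abundance": ["taxon", "site", "value"],
    "traits": ["taxon", "individual", "trait", "value"],
    "interactions": ["animal", "plant", "site", "count"],
    "pollen": ["species", "individual", "head", "thorax", "abdomen", "legs"],
    "taxonomy": ["species", "family"],
}

PLANT_TRAITS = ("nectar_depth", "nectar_width", "anther_position")
ANIMAL_TRAITS = ("proboscis_length", "head_width", "body_length")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    output_dir: str
    seed: int | None = None
    input_dir: str | None = None
    simulate: dict | None = None
    scales: tuple[str, ...] = ("local", "regional")
    alpha: float = 0.05
    alpha_grid: tuple[float, ...] = niche_spaces.DEFAULT_ALPHA_GRID
    n_sims: int = 10_000
    animal_positions_from: str = "interactions"  # or "abundance"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir or simulate must be given")
        if self.animal_positions_from not in ("interactions", "abundance"):
            raise ValueError("animal_positions_from must be 'interactions' or 'abundance'")
        stochastic = self.simulate is not None or self.n_sims > 0
        if stochastic and self.seed is None:
            raise ValueError("a seed is required for stochastic runs")

    def to_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "input_dir": None if self.input_dir is None else str(self.input_dir),
            "simulate": self.simulate,
            "scales": list(self.scales),
            "alpha": self.alpha,
            "alpha_grid": list(self.alpha_grid),
            "n_sims": self.n_sims,
            "animal_positions_from": self.animal_positions_from,
        }


def load_config(path) -> RunConfig:
    """RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    if "scales" in data:
        data["scales"] = tuple(data["scales"])
    if "alpha_grid" in data:
        data["alpha_grid"] = tuple(data["alpha_grid"])
    return RunConfig(**data)


def load_tables(input_dir) -> dict[str, pd.DataFrame]:
    """Read the six input CSVs, checking schemas."""
    input_dir = Path(input_dir)
    tables = {}
    for name in INPUT_FILES:
        path = input_dir / f"{name}.csv"
        if not path.exists():
            raise PipelineError("io", f"missing input file {path}")
        frame = pd.read_csv(path, dtype={"value": object} if name == "abundance" else None)
        missing = [c for c in _SCHEMAS[name] if c not in frame.columns]
        if missing:
            raise PipelineError("io", f"{path} missing columns {missing}")
        tables[name] = frame
    return tables


def validate_inputs(tables: dict[str, pd.DataFrame]) -> list[dict]:
    """Schema, type, and referential checks; returns a machine-readable report."""
    report: list[dict] = []

    def entry(file, row, problem):
        report.append({"file": file, "row": None if row is None else int(row), "problem": problem})

    sites = tables["sites"]
    for i, rec in sites.iterrows():
        if rec["scale"] not in ("local", "regional"):
            entry("sites.csv", i, f"unknown scale {rec['scale']!r}")
        if not 0 <= rec["aspect"] <= 180:
            entry("sites.csv", i, f"aspect {rec['aspect']} outside [0, 180]")
        if not np.isfinite(rec["temperature"]):
            entry("sites.csv", i, "non-finite temperature")
    for scale, group in sites.groupby("scale"):
        dupes = group.loc[group["site_id"].duplicated(), "site_id"]
        for i, sid in dupes.items():
            entry("sites.csv", i, f"duplicate site_id {sid!r} within scale {scale}")

    known_sites = set(sites["site_id"])
    taxonomy = tables["taxonomy"]
    species = set(taxonomy["species"])

    inter = tables["interactions"]
    plants = set(inter["plant"])
    for i, rec in inter.iterrows():
        if rec["site"] not in known_sites:
            entry("interactions.csv", i, f"unknown site {rec['site']!r}")
        if rec["count"] < 0:
            entry("interactions.csv", i, f"negative count {rec['count']}")
        if rec["animal"] not in species:
            entry("interactions.csv", i, f"animal {rec['animal']!r} not in taxonomy")

    abundance = tables["abundance"]
    for i, rec in abundance.iterrows():
        if rec["site"] not in known_sites:
            entry("abundance.csv", i, f"unknown site {rec['site']!r}")
        try:
            preprocessing.convert_cover(rec["value"]) if _is_plant_value(rec, species, plants) else float(rec["value"])
        except Exception as exc:
            entry("abundance.csv", i, str(exc))

    trait_taxa = set(tables["traits"]["taxon"])
    families = set(taxonomy["family"])
    for taxon in sorted(plants - trait_taxa):
        entry("interactions.csv", None, f"plant {taxon!r} has no trait records")
    for sp in sorted(set(inter["animal"]) - trait_taxa - families):
        entry("interactions.csv", None, f"animal {sp!r} has no trait records")

    pollen = tables["pollen"]
    for i, rec in pollen.iterrows():
        cats = [rec[c] for c in preprocessing.POLLEN_REGIONS]
        if any((c != int(c)) or not 0 <= c <= 4 for c in cats):
            entry("pollen.csv", i, f"categories {cats} not integers in [0, 4]")
    return report


def _is_plant_value(rec, animal_species, plants) -> bool:
    return rec["taxon"] in plants or (rec["taxon"] not in animal_species)


@dataclass
class ScaleData:
    """Analysis-ready tables for one spatial scale."""

    scale: str
    env_standardized: pd.DataFrame  # site × (temperature, aspect) in [0, 1]
    plant_abundance: pd.DataFrame  # plant × site integer counts
    animal_abundance: pd.DataFrame  # family × site integer counts
    matrix: pd.DataFrame  # aggregated animal family × plant species counts
    traits_wide: pd.DataFrame  # (taxon, individual) × trait, family-pooled


@dataclass
class ScaleResult:
    scale: str
    matrix: pd.DataFrame
    niches: pd.DataFrame
    roles: pd.DataFrame
    index_matrices: dict[str, pd.DataFrame]
    correlations: pd.DataFrame
    networks: dict[str, dict]
    edge_test: dict


def preprocess_tables(tables: dict[str, pd.DataFrame]) -> tuple[dict[str, pd.DataFrame], dict]:
    """Pollen filter then family pooling; returns tables and bookkeeping."""
    taxonomy = tables["taxonomy"]
    kept = preprocessing.filter_pollinators(tables["pollen"], taxonomy)
    total_before = int(tables["interactions"]["count"].sum())
    pooled_int, pooled_traits = preprocessing.pool_to_family(
        tables["interactions"], tables["traits"], taxonomy, kept_families=kept
    )
    stats = {
        "families_total": int(taxonomy["family"].nunique()),
        "families_kept": len(kept),
        "interactions_before_filter": total_before,
        "interactions_after_filter": int(pooled_int["count"].sum()),
    }
    logger.info(
        "pollen filter kept %d/%d families; interactions %d -> %d",
        stats["families_kept"],
        stats["families_total"],
        stats["interactions_before_filter"],
        stats["interactions_after_filter"],
    )
    out = dict(tables)
    out["interactions"] = pooled_int
    out["traits"] = pooled_traits
    return out, stats


def build_scale_data(tables: dict[str, pd.DataFrame], scale: str, animal_positions_from: str = "interactions") -> ScaleData:
    """Restrict to one scale: standardized environment, abundances, matrix."""
    sites = tables["sites"]
    scale_sites = sites[sites["scale"] == scale]
    if len(scale_sites) < 2:
        raise PipelineError("scale", f"scale {scale!r} has fewer than 2 sites")
    env = scale_sites.set_index("site_id")[["temperature", "aspect"]]
    env_std = preprocessing.standardize_columns(env)

    site_ids = set(env.index)
    inter = tables["interactions"]
    inter_s = inter[inter["site"].isin(site_ids)]
    if inter_s["count"].sum() == 0:
        raise PipelineError("scale", f"no interactions recorded at scale {scale!r}")

    taxonomy = tables["taxonomy"]
    animal_names = set(taxonomy["species"]) | set(taxonomy["family"])
    abundance = tables["abundance"]
    ab_s = abundance[abundance["site"].isin(site_ids)]
    plant_rows = ab_s[~ab_s["taxon"].isin(animal_names)]
    counts = preprocessing.cover_to_counts(plant_rows["value"])
    plant_ab = (
        plant_rows.assign(count=counts)
        .pivot_table(index="taxon", columns="site", values="count", aggfunc="sum", fill_value=0)
        .astype(int)
    )
    plant_ab = plant_ab[plant_ab.sum(axis=1) > 0]

    matrix = (
        inter_s.groupby(["animal", "plant"])["count"].sum().unstack(fill_value=0).astype(int)
    )
    matrix = matrix.loc[matrix.sum(axis=1) > 0, matrix.sum(axis=0) > 0]

    if animal_positions_from == "interactions":
        animal_ab = (
            inter_s.groupby(["animal", "site"])["count"].sum().unstack(fill_value=0).astype(int)
        )
    else:
        species_to_family = dict(zip(taxonomy["species"], taxonomy["family"]))
        animal_rows = ab_s[ab_s["taxon"].isin(animal_names)].copy()
        animal_rows["taxon"] = animal_rows["taxon"].map(lambda t: species_to_family.get(t, t))
        animal_rows = animal_rows[animal_rows["taxon"].isin(set(matrix.index))]
        animal_ab = (
            animal_rows.assign(count=animal_rows["value"].astype(float).round().astype(int))
            .pivot_table(index="taxon", columns="site", values="count", aggfunc="sum", fill_value=0)
            .astype(int)
        )
    animal_ab = animal_ab[animal_ab.sum(axis=1) > 0]

    traits_wide = niche_spaces.trait_clouds(tables["traits"])
    return ScaleData(
        scale=scale,
        env_standardized=env_std,
        plant_abundance=plant_ab,
        animal_abundance=animal_ab,
        matrix=matrix,
        traits_wide=traits_wide,
    )


def compute_niches(data: ScaleData, alpha_grid=niche_spaces.DEFAULT_ALPHA_GRID) -> pd.DataFrame:
    """Grinnellian and trait niche summaries for both trophic levels."""
    frames = []
    env = data.env_standardized
    for level, abundance in (("plant", data.plant_abundance), ("animal", data.animal_abundance)):
        clouds = {
            taxon: niche_spaces.build_weighted_cloud(taxon, env, abundance.loc[taxon])
            for taxon in abundance.index
        }
        frames.append(
            niche_spaces.niche_summaries(
                clouds,
                niche_type="grinnellian",
                trophic_level=level,
                scale=data.scale,
                config=niche_spaces.RangeBoxConfig(alpha_grid=alpha_grid),
                dimension_names=list(env.columns),
            )
        )
    # trait niches: pool membership is the set of taxa present at this scale
    for level, trait_names, present in (
        ("plant", PLANT_TRAITS, set(data.plant_abundance.index)),
        ("animal", ANIMAL_TRAITS, set(data.animal_abundance.index) | set(data.matrix.index)),
    ):
        wide = data.traits_wide
        cols = [c for c in trait_names if c in wide.columns]
        level_taxa = [t for t in wide.index.get_level_values("taxon").unique() if t in present]
        block = wide.loc[wide.index.get_level_values("taxon").isin(level_taxa), cols].dropna()
        if len(block) == 0:
            continue
        block_std = preprocessing.standardize_columns(block)
        clouds = {}
        for taxon in level_taxa:
            if taxon in block_std.index.get_level_values("taxon"):
                clouds[taxon] = niche_spaces.trait_cloud(taxon, block_std)
        frames.append(
            niche_spaces.niche_summaries(
                clouds,
                niche_type="trait",
                trophic_level=level,
                scale=data.scale,
                config=niche_spaces.RangeBoxConfig(alpha_grid=alpha_grid),
                dimension_names=cols,
            )
        )
    niches = pd.concat(frames, ignore_index=True)
    position_cols = [c for c in niches.columns if c.startswith("J_")]
    ordered = ["taxon", "trophic_level", "niche_type", "scale", *position_cols, "marginality", "volume", "V"]
    return niches[[c for c in ordered if c in niches.columns]]


def compute_roles(data: ScaleData) -> pd.DataFrame:
    roles = bipartite_roles.species_level(data.matrix)
    roles.insert(2, "scale", data.scale)
    return roles


def grinnellian_positions(niches: pd.DataFrame) -> pd.DataFrame:
    """taxon → J in [0,1]² for both trophic levels of one scale."""
    block = niches[niches["niche_type"] == "grinnellian"]
    # the concatenated niche table carries trait J columns as NaN here
    cols = [c for c in block.columns if c.startswith("J_") and block[c].notna().all()]
    return block.set_index("taxon")[cols]


def integrate_scale(niches: pd.DataFrame, roles: pd.DataFrame, alpha: float = 0.05):
    """Index matrices, pairwise correlations, and networks per trophic level."""
    index_matrices = {}
    corr_frames = []
    networks = {}
    for level in ("plant", "animal"):
        im = niche_integration.assemble_index_matrix(
            niches[niches["trophic_level"] == level],
            roles[roles["trophic_level"] == level],
        )
        index_matrices[level] = im
        corr = niche_integration.pairwise_correlations(im)
        if len(corr):
            corr = corr.assign(trophic_level=level)
            corr_frames.append(corr)
        network = niche_integration.build_correlation_network(corr, alpha=alpha)
        partition, q = niche_integration.modularity_partition(network)
        if len(corr):
            R = niche_integration.correlation_matrix_from_pairs(corr)
            n_eff = int(np.median(corr["n"]))
            integration = niche_integration.integration_index(R, n_eff)
        else:
            integration = (0.0, 0.0)
        networks[level] = niche_integration.network_to_dict(network, partition, q, integration)
    correlations = (
        pd.concat(corr_frames, ignore_index=True)
        if corr_frames
        else pd.DataFrame(columns=["index_a", "index_b", "r", "p", "n", "trophic_level"])
    )
    return index_matrices, correlations, networks


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise PipelineError(name, str(exc)) from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage per scale and write the artifact bundle.

    Identical configuration (including seed) produces byte-identical
    numeric outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim_config = SimulationConfig(seed=config.seed, **config.simulate)
        study = _stage("simulate")(generate_study, sim_config)
        input_dir = outdir / "inputs"
        _stage("simulate")(write_community, study, input_dir)
    else:
        input_dir = Path(config.input_dir)

    tables = _stage("io")(load_tables, input_dir)
    report = _stage("validate")(validate_inputs, tables)
    (outdir / "validation.json").write_text(json.dumps(report, indent=2))
    if report:
        logger.warning("validation found %d problems (see validation.json)", len(report))

    processed, preprocess_stats = _stage("preprocess")(preprocess_tables, tables)

    scale_results: list[ScaleResult] = []
    edge_tests = {}
    for k, scale in enumerate(config.scales):
        data = _stage(f"scale:{scale}")(
            build_scale_data, processed, scale, config.animal_positions_from
        )
        niches = _stage(f"niches:{scale}")(compute_niches, data, config.alpha_grid)
        roles = _stage(f"roles:{scale}")(compute_roles, data)
        index_matrices, correlations, networks = _stage(f"integrate:{scale}")(
            integrate_scale, niches, roles, config.alpha
        )
        positions = grinnellian_positions(niches)
        derived_seed = None if config.seed is None else (config.seed * 1_000_003 + k) % (2**31)
        test = _stage(f"edgetest:{scale}")(
            edge_length_test, data.matrix, positions, config.n_sims, derived_seed
        )
        edge_tests[scale] = test.summary()
        scale_results.append(
            ScaleResult(
                scale=scale,
                matrix=data.matrix,
                niches=niches,
                roles=roles,
                index_matrices=index_matrices,
                correlations=correlations.assign(scale=scale),
                networks=networks,
                edge_test=edge_tests[scale],
            )
        )

    niches_all = pd.concat([r.niches for r in scale_results], ignore_index=True)
    roles_all = pd.concat([r.roles for r in scale_results], ignore_index=True)
    correlations_all = pd.concat([r.correlations for r in scale_results], ignore_index=True)

    table1 = _cross_scale_table(scale_results)
    table2 = _abundance_table(scale_results)

    network_bundle = {
        r.scale: {level: net for level, net in r.networks.items()} for r in scale_results
    }

    niches_all.to_csv(outdir / "niches.csv", index=False)
    roles_all.to_csv(outdir / "roles.csv", index=False)
    correlations_all.to_csv(outdir / "correlations.csv", index=False)
    (outdir / "network.json").write_text(json.dumps(network_bundle, indent=2))
    table1.to_csv(outdir / "table1.csv", index=False)
    table2.to_csv(outdir / "table2.csv", index=False)
    (outdir / "edgetest.json").write_text(json.dumps(edge_tests, indent=2))

    manifest = {
        "package": "nicheweb",
        "version": __version__,
        "libraries": _library_versions(),
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "preprocess": preprocess_stats,
        "validation_problems": len(report),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "niches": niches_all,
        "roles": roles_all,
        "correlations": correlations_all,
        "networks": network_bundle,
        "table1": table1,
        "table2": table2,
        "edge_tests": edge_tests,
        "manifest": manifest,
        "scale_results": scale_results,
        "validation": report,
    }


def _library_versions() -> dict:
    import networkx
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
    }


def _cross_scale_table(scale_results: list[ScaleResult]) -> pd.DataFrame:
    by_scale = {r.scale: r for r in scale_results}
    if not {"local", "regional"} <= set(by_scale):
        return pd.DataFrame(columns=["trophic_level", "index", "t", "df", "p", "r2", "n", "computable"])
    frames = []
    for level in ("animal", "plant"):
        rows = niche_integration.cross_scale_correlation(
            by_scale["local"].index_matrices[level],
            by_scale["regional"].index_matrices[level],
        )
        rows.insert(0, "trophic_level", level)
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)


def _abundance_table(scale_results: list[ScaleResult]) -> pd.DataFrame:
    frames = []
    for r in scale_results:
        margins = {
            "animal": r.matrix.sum(axis=1),
            "plant": r.matrix.sum(axis=0),
        }
        for level in ("animal", "plant"):
            im = r.index_matrices[level]
            if im["degree"].dropna().empty:
                continue
            rows = niche_integration.abundance_correlation(margins[level], im)
            rows.insert(0, "trophic_level", level)
            rows.insert(1, "scale", r.scale)
            frames.append(rows)
    if not frames:
        return pd.DataFrame(columns=["trophic_level", "scale", "index", "r", "p", "n", "significant"])
    return pd.concat(frames, ignore_index=True)
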