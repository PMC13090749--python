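"""Synthetic multi-dataset collections with known generating parameters.

The generator emulates the statistical structure of a global compilation of
riverine fish eDNA metabarcoding datasets:

* six continents with unequal study counts and regionally varying barcode
  reference-database coverage (weak in Africa and South America, strong in
  North America and Europe);
* nested local species pools (basin ⊆ country ⊆ continent) per dataset;
* per-site fish read totals drawn log-normally;
* congruence between the original and reanalyzed assignments governed by a
  beta-logit model: each covered detected species is shared with the
  original assignment with probability ``p* ~ Beta(mean = invlogit(β0 +
  β_reads·log median reads + β_year·(year − year_min) +
  β_richness·richness), precision = φ)``.  Coverage gaps additionally drop
  uncovered latent species from the reanalysis (optionally misassigning
  their reads to other covered local taxa, which are never shared), so
  realized p_sp degrades with reference-database coverage; in the
  complete-coverage, no-misassignment limit E[p_sp] follows the logit model
  exactly;
* species unique to the reanalysis carry a log-scale abundance penalty δ < 0;
* optional synonym noise on species labels, reversible through the complete
  synonym table.

Every random draw flows from a single seed through hierarchically spawned
streams (one per dataset), so a fixed configuration reproduces a collection
byte-for-byte and appending datasets does not perturb earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .collection import Collection, Dataset, DatasetMetadata
from .congruence import OriginalAssignment, ReadTable
from .coverage import ReferenceDB, SpeciesPoolHierarchy
from .taxonomy import SynonymTable

CONTINENTS = ("Africa", "Asia", "Europe", "North America", "Oceania",
              "South America")

# study counts per continent in a 58-study global compilation: 1/15/17/12/4/9
_DEFAULT_WEIGHTS = {
    "Africa": 1 / 58, "Asia": 15 / 58, "Europe": 17 / 58,
    "North America": 12 / 58, "Oceania": 4 / 58, "South America": 9 / 58,
}

# barcode coverage of local pools: weakest in Africa / South America
_DEFAULT_COVERAGE = {
    "Africa": 0.35, "Asia": 0.80, "Europe": 0.85,
    "North America": 0.90, "Oceania": 0.60, "South America": 0.45,
}


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic collection.

    Defaults emulate the study conditions of a ~50-dataset global
    compilation, with read depths and site counts scaled to desk size.
    """

    n_datasets: int = 50
    continent_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    year_range: tuple[int, int] = (2014, 2023)
    sites_range: tuple[int, int] = (3, 40)
    pool_sizes: tuple[int, int, int] = (60, 200, 800)   # basin < country < continent
    nesting: tuple[float, float] = (1.0, 1.0)           # basin|country, country|continent
    refdb_coverage_by_continent: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COVERAGE))
    depth_lognormal: tuple[float, float] = (9.0, 0.8)   # log-mean, log-sd of site totals
    congruence_coefs: tuple[float, float, float, float] = (0.2, 0.30, 0.15, -0.02)
    beta_precision: float = 30.0
    unique_abundance_shift: float = -1.0                # delta, log scale
    synonym_noise_rate: float = 0.0
    seed: int = 0
    # secondary structure
    richness_range: tuple[int, int] = (10, 55)
    original_coverage: float = 0.9       # original study's effective refdb coverage
    false_positive_rate: float = 1.5     # Poisson mean of off-basin originals
    misassignment_rate: float = 0.5      # uncovered latent -> spurious detection
    detection_prob: float = 0.92         # covered latent species detected at all
    nonlocal_detection_rate: float = 4.0  # Poisson mean of non-basin detections
    occupancy: float = 0.6               # per-site presence prob in original tables
    abundance_log_sd: float = 0.8
    n_offpool_refdb: int = 20            # refdb taxa outside any pool
    custom_refdb_prob: float = 21 / 58
    species_table_prob: float = 0.9      # originals providing a species table

    def validate(self) -> None:
        b, c, k = self.pool_sizes
        if not b < c < k:
            raise InvalidConfigError(
                f"pool sizes must be strictly increasing basin < country < "
                f"continent, got {self.pool_sizes}")
        if self.sites_range[0] < 3:
            raise InvalidConfigError("sites_range minimum must be >= 3")
        if not all(0 < f <= 1 for f in self.nesting):
            raise InvalidConfigError("nesting fractions must lie in (0, 1]")
        for cont, p in self.refdb_coverage_by_continent.items():
            if not 0 <= p <= 1:
                raise InvalidConfigError(f"coverage for {cont} outside [0,1]")
        if not 0 <= self.synonym_noise_rate < 1:
            raise InvalidConfigError("synonym_noise_rate must be in [0, 1)")
        if self.beta_precision <= 0:
            raise InvalidConfigError("beta_precision must be positive")
        w = sum(self.continent_weights.values())
        if abs(w - 1) > 1e-6:
            raise InvalidConfigError("continent weights must sum to 1")

    @property
    def year_ref(self) -> int:
        return self.year_range[0]

    @property
    def richness_center(self) -> float:
        return 0.5 * (self.richness_range[0] + self.richness_range[1])


@dataclass
class SyntheticTruth:
    """Ground-truth record for parameter-recovery tests."""

    congruence_coefs: tuple[float, float, float, float]
    beta_precision: float
    unique_abundance_shift: float
    shared_species: dict[str, list[str]] = field(default_factory=dict)
    unique_species: dict[str, list[str]] = field(default_factory=dict)
    realized_coverage: dict[str, float] = field(default_factory=dict)
    p_star: dict[str, float] = field(default_factory=dict)
    canonical_map: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# namespace and pools


def _species_namespace(continent: str, size: int) -> list[str]:
    """Deterministic canonical binomials for one continent's species pool."""
    prefix = continent.replace(" ", "")[:4].capitalize()
    n_gen = max(1, size // 8)
    return [f"{prefix}genus{g % n_gen} epithet{i}" for i, g in
            zip(range(size), range(size))]


def make_continent_pools(config: SimulationConfig) -> dict[str, frozenset[str]]:
    return {c: frozenset(_species_namespace(c, config.pool_sizes[2]))
            for c in CONTINENTS}


def make_synonym_table(pools: Mapping[str, frozenset[str]]) -> tuple[SynonymTable, dict[str, str]]:
    """Complete synonym table: one variant spelling per canonical name."""
    mapping: dict[str, str] = {}
    for pool in pools.values():
        for name in pool:
            genus, epithet = name.split(" ")
            mapping[f"{genus} {epithet}var"] = name
    return SynonymTable(mapping), mapping


def generate_pool_hierarchy(config: SimulationConfig,
                            continent_pool: frozenset[str],
                            rng: np.random.Generator) -> SpeciesPoolHierarchy:
    """Draw nested basin ⊆ country ⊆ continent pools of configured sizes.

    The nesting fraction f restricts the parent region a child pool may be
    drawn from (f = 1: anywhere in the parent); nesting itself always holds.
    """
    config.validate()
    n_basin, n_country, n_continent = config.pool_sizes
    cont = sorted(continent_pool)
    if len(cont) < n_continent:
        raise InvalidConfigError("continent pool smaller than configured size")
    cont = [cont[i] for i in rng.choice(len(cont), n_continent, replace=False)] \
        if len(cont) > n_continent else cont

    def draw(parent: list[str], size: int, frac: float) -> list[str]:
        eligible_n = max(size, int(round(frac * len(parent))))
        idx = rng.choice(len(parent), eligible_n, replace=False) \
            if eligible_n < len(parent) else np.arange(len(parent))
        eligible = [parent[i] for i in idx]
        pick = rng.choice(len(eligible), size, replace=False) \
            if size < len(eligible) else np.arange(len(eligible))
        return [eligible[i] for i in pick]

    country = draw(cont, n_country, config.nesting[1])
    basin = draw(country, n_basin, config.nesting[0])
    return SpeciesPoolHierarchy(frozenset(basin), frozenset(country),
                                frozenset(cont))


def generate_reference_db(pool: frozenset[str], coverage_prob: float,
                          rng: np.random.Generator, primer: str = "12S",
                          offpool: Sequence[str] = ()) -> ReferenceDB:
    """Include each pool species independently with probability coverage_prob."""
    if not 0 <= coverage_prob <= 1:
        raise InvalidConfigError("coverage_prob must be in [0, 1]")
    pool_list = sorted(pool)
    keep = rng.random(len(pool_list)) < coverage_prob
    species = {s for s, k in zip(pool_list, keep) if k}
    species.update(offpool)
    return ReferenceDB(primer, frozenset(species))


# ---------------------------------------------------------------------------
# dataset generation


def _draw_metadata(config: SimulationConfig, dataset_id: str,
                   rng: np.random.Generator) -> DatasetMetadata:
    conts = sorted(config.continent_weights)
    w = np.array([config.continent_weights[c] for c in conts])
    continent = conts[rng.choice(len(conts), p=w / w.sum())]
    year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
    refdb_type = "custom" if rng.random() < config.custom_refdb_prob else "global"
    n_sites = int(rng.integers(config.sites_range[0], config.sites_range[1] + 1))
    return DatasetMetadata(dataset_id, continent, year, "12S", refdb_type,
                           float("nan"), n_sites)


def recovery_probability(config: SimulationConfig, log_median_reads: float,
                         year: int, richness: int) -> float:
    """Mean of the beta-logit recovery model for one dataset's predictors."""
    b0, b_reads, b_year, b_rich = config.congruence_coefs
    eta = (b0 + b_reads * (log_median_reads - config.depth_lognormal[0])
           + b_year * (year - config.year_ref)
           + b_rich * (richness - config.richness_center))
    return float(special.expit(eta))


def generate_dataset(config: SimulationConfig, pools: SpeciesPoolHierarchy,
                     refdb: ReferenceDB, metadata: DatasetMetadata,
                     rng: np.random.Generator
                     ) -> tuple[ReadTable, OriginalAssignment, DatasetMetadata, dict]:
    """One dataset: reanalyzed read table, original assignment, metadata, truth.

    Construction: a latent basin community is drawn; the reanalysis detects
    its covered part (plus possible misassignments of uncovered species to
    other covered local taxa); each covered detected species belongs to the
    original assignment with the beta-logit probability p*, and the original
    additionally reports uncovered latent species ("extra local" species)
    and occasional off-basin false positives.  Reads are multinomial per
    site over log-normal species effects, with unique-to-reanalysis species
    shifted by δ.
    """
    if not pools.basin:
        raise InvalidConfigError("empty basin pool")
    basin = sorted(pools.basin)
    lo, hi = config.richness_range
    m = int(rng.integers(lo, min(hi, len(basin)) + 1))
    latent = [basin[i] for i in rng.choice(len(basin), m, replace=False)]

    # the reanalysis detects (most of) the covered part of the latent
    # community; reads from uncovered species can be misassigned to other
    # covered taxa at any scale, and the uncorrected ("global") assignment
    # additionally picks up non-basin taxa that pool correction removes
    covered = [s for s in latent if s in refdb.species]
    uncovered = [s for s in latent if s not in refdb.species]
    realized_cov = len(covered) / m if m else float("nan")
    detected_covered = [s for s in covered
                        if rng.random() < config.detection_prob]
    missed_covered = sorted(set(covered) - set(detected_covered))

    target_pools = {
        "basin": sorted((pools.basin & refdb.species) - set(latent)),
        "country": sorted((pools.country & refdb.species) - pools.basin),
        "continent": sorted((pools.continent & refdb.species) - pools.country),
        "offpool": sorted(refdb.species - pools.continent),
    }

    def draw_target(weights=((0.5, "basin"), (0.3, "country"),
                             (0.15, "continent"), (0.05, "offpool"))):
        r = rng.random()
        acc, chosen = 0.0, None
        for w, name in weights:
            acc += w
            if r < acc:
                chosen = name
                break
        fallback = [name for _, name in weights if name != chosen]
        for name in ([chosen] if chosen else []) + fallback:
            pool_t = target_pools[name]
            if pool_t:
                return pool_t.pop(int(rng.integers(len(pool_t))))
        return None

    misassigned: list[str] = []
    for _ in uncovered:
        if rng.random() < config.misassignment_rate:
            t = draw_target()
            if t is not None:
                misassigned.append(t)
    for _ in range(int(rng.poisson(config.nonlocal_detection_rate))):
        t = draw_target(((0.0, "basin"), (0.45, "country"),
                         (0.40, "continent"), (0.15, "offpool")))
        if t is not None:
            misassigned.append(t)
    detected = sorted(set(detected_covered) | set(misassigned))

    # per-site totals and the dataset's depth predictor
    mu_log, sd_log = config.depth_lognormal
    site_totals = np.maximum(
        1, np.round(rng.lognormal(mu_log, sd_log, metadata.n_sites))).astype(int)
    median_reads = float(np.median(site_totals))
    metadata.median_fish_reads = median_reads

    # beta-logit congruence stage: each covered detected species appears in
    # the original assignment with probability p*
    p_mean = recovery_probability(config, np.log(median_reads), metadata.year, m)
    phi = config.beta_precision
    p_star = float(rng.beta(p_mean * phi, (1 - p_mean) * phi))
    p_star = min(max(p_star, 1e-6), 1 - 1e-6)
    shared = [s for s in detected_covered if rng.random() < p_star]

    # original assignment = shared species + extra local species the
    # reanalysis could not recover (mostly barcode-less) + off-basin extras
    extra_local = [s for s in uncovered + missed_covered
                   if rng.random() < config.original_coverage]
    off_basin = sorted(pools.continent - pools.basin)
    n_fp = int(rng.poisson(config.false_positive_rate))
    fp = [off_basin[i] for i in rng.choice(len(off_basin),
                                           min(n_fp, len(off_basin)),
                                           replace=False)] if off_basin else []
    original_species = frozenset(shared) | frozenset(extra_local) | frozenset(fp)

    # read counts: multinomial per site over log-normal abundance effects,
    # with the delta penalty on species unique to the reanalysis
    if detected:
        lam = np.exp(rng.normal(0.0, config.abundance_log_sd, len(detected)))
        shared_set = frozenset(shared)
        unique_mask = np.array([s not in shared_set for s in detected])
        lam = lam * np.exp(np.where(unique_mask, config.unique_abundance_shift, 0.0))
        # species occupy a random subset of sites, so per-site richness varies
        occ_sites = rng.random((len(detected), metadata.n_sites)) < config.occupancy
        for i in np.flatnonzero(~occ_sites.any(axis=1)):
            occ_sites[i, int(rng.integers(metadata.n_sites))] = True
        for j in np.flatnonzero(~occ_sites.any(axis=0)):
            occ_sites[int(rng.integers(len(detected))), j] = True
        counts = np.zeros((len(detected), metadata.n_sites), dtype=int)
        for j, t in enumerate(site_totals):
            w = lam * occ_sites[:, j]
            counts[:, j] = rng.multinomial(t, w / w.sum())
    else:
        counts = np.zeros((0, metadata.n_sites), dtype=int)
    table = ReadTable(metadata.dataset_id, pd.DataFrame(
        counts, index=pd.Index(detected, name="species"),
        columns=[f"site{j:03d}" for j in range(metadata.n_sites)]))

    # original per-site presence (for richness comparisons)
    richness_only = rng.random() >= config.species_table_prob
    orig_sorted = sorted(original_species)
    if orig_sorted:
        # shared species tend to be reported at the sites where the
        # reanalysis finds their reads; other originals are spread uniformly
        occ = np.full((len(orig_sorted), metadata.n_sites), config.occupancy)
        det_pos = {s: i for i, s in enumerate(detected)}
        for i, s in enumerate(orig_sorted):
            if s in det_pos:
                has_reads = counts[det_pos[s]] > 0
                occ[i] = np.where(has_reads, 0.8, 0.15)
        pres = (rng.random(occ.shape) < occ).astype(int)
        empty = pres.sum(axis=1) == 0
        for i in np.flatnonzero(empty):
            pres[i, int(rng.integers(metadata.n_sites))] = 1
        presence = pd.DataFrame(pres, index=pd.Index(orig_sorted, name="species"),
                                columns=table.counts.columns)
    else:
        presence = None
    original = OriginalAssignment(metadata.dataset_id, original_species,
                                  presence, richness_only=richness_only)

    truth = {
        "latent": latent,
        "shared": sorted(set(detected) & original_species),
        "unique": sorted(set(detected) - original_species),
        "realized_coverage": realized_cov,
        "p_star": p_star,
        "p_mean": p_mean,
    }
    return table, original, metadata, truth


def inject_name_noise(table: ReadTable, synonyms: SynonymTable, rate: float,
                      rng: np.random.Generator) -> ReadTable:
    """Replace species labels by synonym variants with the given probability.

    Read counts are untouched row-wise; every species must have at least one
    variant in the synonym table.
    """
    if not 0 <= rate < 1:
        raise ValueError("noise rate must be in [0, 1)")
    new_index = []
    for name in table.counts.index:
        variants = synonyms.variants_of(name)
        if not variants:
            raise ValueError(f"no synonym variant available for {name!r}")
        if rng.random() < rate:
            new_index.append(variants[int(rng.integers(len(variants)))])
        else:
            new_index.append(name)
    out = table.counts.copy()
    out.index = pd.Index(new_index, name=table.counts.index.name)
    return ReadTable(table.dataset_id, out)


def generate_collection(config: SimulationConfig
                        ) -> tuple[Collection, SyntheticTruth]:
    """Generate a full collection plus its ground-truth record."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_datasets + 1)
    setup_rng = np.random.default_rng(streams[0])

    continent_pools = make_continent_pools(config)
    synonyms, canonical_map = make_synonym_table(continent_pools)
    truth = SyntheticTruth(config.congruence_coefs, config.beta_precision,
                           config.unique_abundance_shift,
                           canonical_map=canonical_map)

    datasets: list[Dataset] = []
    for d in range(config.n_datasets):
        rng = np.random.default_rng(streams[d + 1])
        dsid = f"D{d + 1:03d}"
        meta = _draw_metadata(config, dsid, rng)
        pools = generate_pool_hierarchy(config, continent_pools[meta.continent],
                                        rng)
        offpool_src = sorted(set().union(
            *(p for c, p in continent_pools.items() if c != meta.continent))
            - continent_pools[meta.continent])
        off_idx = rng.choice(len(offpool_src),
                             min(config.n_offpool_refdb, len(offpool_src)),
                             replace=False)
        refdb = generate_reference_db(
            pools.continent,
            config.refdb_coverage_by_continent[meta.continent], rng,
            primer=meta.barcode,
            offpool=[offpool_src[i] for i in off_idx])
        table, original, meta, ds_truth = generate_dataset(
            config, pools, refdb, meta, rng)
        if config.synonym_noise_rate > 0:
            table = inject_name_noise(table, synonyms,
                                      config.synonym_noise_rate, rng)
        datasets.append(Dataset(dsid, table, original, pools, refdb, meta))
        truth.shared_species[dsid] = ds_truth["shared"]
        truth.unique_species[dsid] = ds_truth["unique"]
        truth.realized_coverage[dsid] = ds_truth["realized_coverage"]
        truth.p_star[dsid] = ds_truth["p_star"]
    _complete_synonyms(synonyms, datasets)
    return Collection(datasets, synonyms), truth


def _complete_synonyms(synonyms: SynonymTable, datasets: list[Dataset]) -> None:
    """Ensure every generated name is a fixed point of the synonym table."""
    for ds in datasets:
        for name in ds.read_table.counts.index:
            if name not in synonyms:
                synonyms.add(name, name, "generated")


# ---------------------------------------------------------------------------
# direct simulators for model-calibration tests


def simulate_congruence_proportions(config: SimulationConfig, n: int,
                                    rng: np.random.Generator) -> pd.DataFrame:
    """Dataset-level regression table drawn straight from the beta-logit stage.

    Skips read-table construction: per dataset it draws the predictors from
    the configured distributions and the response from the beta distribution
    around the logit-linear mean.  Used for calibration checks of the beta
    GLM stage under an exactly-specified model.
    """
    mu_log, sd_log = config.depth_lognormal
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, n)
    richness = rng.integers(config.richness_range[0],
                            config.richness_range[1] + 1, n)
    n_sites = rng.integers(config.sites_range[0], config.sites_range[1] + 1, n)
    med_reads = np.array([
        np.median(np.maximum(1, np.round(rng.lognormal(mu_log, sd_log, k))))
        for k in n_sites])
    p_mean = np.array([
        recovery_probability(config, np.log(r), int(y), int(m))
        for r, y, m in zip(med_reads, years, richness)])
    phi = config.beta_precision
    p = rng.beta(p_mean * phi, (1 - p_mean) * phi)
    return pd.DataFrame({
        "p_sp": p,
        "log_median_fish_reads": np.log(med_reads),
        "year": years.astype(float),
        "reanalyzed_richness": richness.astype(float),
        "refdb_custom": (rng.random(n) < config.custom_refdb_prob).astype(float),
    })


def simulate_nb_glmm(n_groups: int, n_per_group: int, beta0: float,
                     beta1: float, sigma2_u: float, theta: float,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Negative-binomial random-intercept data for parameter-recovery tests."""
    rows = []
    for g in range(n_groups):
        u = rng.normal(0.0, np.sqrt(sigma2_u)) if sigma2_u > 0 else 0.0
        x = rng.normal(0.0, 1.0, n_per_group)
        mu = np.exp(beta0 + beta1 * x + u)
        y = rng.negative_binomial(theta, theta / (theta + mu))
        for xi, yi in zip(x, y):
            rows.append({"group": f"g{g}", "x": xi, "y": int(yi)})
    return pd.DataFrame(rows)
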