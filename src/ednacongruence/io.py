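"""Readers/writers for collection directories and the staged pipeline.

A collection directory holds one TSV read table and one CSV original
assignment per dataset, plus ``pools.csv``, ``refdb.tsv``, ``metadata.csv``,
``synonyms.csv``, an optional ``truth.json`` and a ``manifest.json`` tying
them together.  Reading applies synonym harmonization before validation, so
every downstream comparison sees canonical names.

``run_pipeline`` chains coverage -> congruence -> community -> models ->
report over an in-memory collection, writing every stage output under one
directory with a provenance block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .collection import Collection, Dataset, DatasetMetadata
from .congruence import (OriginalAssignment, ReadTable, abundance_table,
                         congruence_table, correct_to_pool, richness_per_site)
from .coverage import ReferenceDB, SpeciesPoolHierarchy, coverage_report
from .community import (build_occurrence_matrix, jaccard_matrix, permanova,
                        anosim, dispersion_test, dbrda, nmds)
from .models import (fit_abundance_mixed, fit_beta_glm, fit_nb_glmm_richness,
                     group_tests, rank_sum_test, sensitivity_filter)
from .simulate import SyntheticTruth
from .taxonomy import SynonymTable, harmonize_read_table, harmonize_species_set, drop_unresolved

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"


@dataclass
class RunConfig:
    """Knobs of one analysis run."""

    scale: str = "basin"
    resolution: str = "species"
    n_perm: int = 999
    seed: int = 0
    min_fish_reads: float = 0.0
    unresolved: str = "exclude"          # include | exclude in read totals
    out_dir: str = "results"

    def validate(self) -> None:
        if self.scale not in ("basin", "country", "continent", "global"):
            raise ValueError(f"invalid scale {self.scale!r}")
        if self.resolution not in ("species", "genus"):
            raise ValueError(f"invalid resolution {self.resolution!r}")
        if self.unresolved not in ("include", "exclude"):
            raise ValueError(f"invalid unresolved policy {self.unresolved!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _provenance(config: RunConfig | None = None) -> dict:
    prov = {"package": "ednacongruence", "version": __version__,
            "format_version": FORMAT_VERSION}
    if config is not None:
        prov["run_config"] = asdict(config)
    return prov


# ---------------------------------------------------------------------------
# collection directory I/O


def write_collection(collection: Collection, out_dir,
                     truth: SyntheticTruth | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"format_version": FORMAT_VERSION, "datasets": []}
    pools_rows, refdb_rows, meta_rows = [], [], []
    for ds in collection.datasets:
        reads_path = f"{ds.dataset_id}_reads.tsv"
        ds.read_table.counts.to_csv(out / reads_path, sep="\t")
        orig_path = None
        if ds.original is not None:
            orig_path = f"{ds.dataset_id}_original.csv"
            if ds.original.presence is not None:
                ds.original.presence.to_csv(out / orig_path)
            else:
                pd.DataFrame({"species": sorted(ds.original.species)}
                             ).to_csv(out / orig_path, index=False)
        manifest["datasets"].append({
            "dataset_id": ds.dataset_id, "reads": reads_path,
            "original": orig_path,
            "richness_only": bool(ds.original.richness_only)
            if ds.original else False})
        for scale in ("basin", "country", "continent"):
            label = getattr(ds.pools, f"{scale}_label") or ds.metadata.continent
            for sp in sorted(ds.pools.pool(scale)):
                pools_rows.append({"dataset_id": ds.dataset_id, "scale": scale,
                                   "region": label, "species": sp})
        for sp in sorted(ds.refdb.species):
            refdb_rows.append({"dataset_id": ds.dataset_id,
                               "primer": ds.refdb.primer, "species": sp})
        meta_rows.append(ds.metadata.as_dict())
    pd.DataFrame(pools_rows).to_csv(out / "pools.csv", index=False)
    pd.DataFrame(refdb_rows).to_csv(out / "refdb.tsv", sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    collection.synonyms.to_csv(out / "synonyms.csv")
    manifest.update({"pools": "pools.csv", "refdb": "refdb.tsv",
                     "metadata": "metadata.csv", "synonyms": "synonyms.csv"})
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth.as_dict(), indent=1))
        manifest["truth"] = "truth.json"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"


def read_collection(manifest_path) -> Collection:
    """Load, harmonize and validate a collection directory.

    Errors are descriptive: a missing file, a duplicate dataset id or a
    negative count all name the offending dataset.
    """
    mpath = Path(manifest_path)
    if mpath.is_dir():
        mpath = mpath / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"manifest not found: {mpath}")
    base = mpath.parent
    manifest = json.loads(mpath.read_text())
    for key in ("pools", "refdb", "metadata", "synonyms"):
        if not (base / manifest[key]).exists():
            raise FileNotFoundError(
                f"manifest references missing {key} file: {manifest[key]}")
    synonyms = SynonymTable.from_csv(base / manifest["synonyms"])
    pools_df = pd.read_csv(base / manifest["pools"])
    refdb_df = pd.read_csv(base / manifest["refdb"], sep="\t")
    meta_df = pd.read_csv(base / manifest["metadata"]).set_index("dataset_id")

    datasets = []
    seen = set()
    for entry in manifest["datasets"]:
        dsid = entry["dataset_id"]
        if dsid in seen:
            raise ValueError(f"duplicate dataset id {dsid!r}")
        seen.add(dsid)
        reads_file = base / entry["reads"]
        if not reads_file.exists():
            raise FileNotFoundError(f"dataset {dsid}: missing reads table "
                                    f"{entry['reads']}")
        counts = pd.read_csv(reads_file, sep="\t", index_col=0)
        if (counts.values < 0).any():
            i, j = np.argwhere(counts.values < 0)[0]
            raise ValueError(
                f"negative read count in dataset {dsid}, species "
                f"{counts.index[i]!r}, site {counts.columns[j]!r}")
        counts = harmonize_read_table(counts.astype(int), synonyms)
        table = ReadTable(dsid, drop_unresolved(counts))

        original = None
        if entry.get("original"):
            odf = pd.read_csv(base / entry["original"])
            if "species" in odf.columns and odf.shape[1] == 1:
                species = harmonize_species_set(odf["species"], synonyms)
                presence = None
            else:
                odf = odf.set_index(odf.columns[0])
                species = harmonize_species_set(odf.index, synonyms)
                presence = odf
            original = OriginalAssignment(dsid, species, presence,
                                          richness_only=bool(entry.get("richness_only")))

        dpools = pools_df[pools_df.dataset_id == dsid]
        pools = SpeciesPoolHierarchy(
            *(frozenset(harmonize_species_set(
                dpools.loc[dpools.scale == s, "species"], synonyms))
              for s in ("basin", "country", "continent")))
        drefdb = refdb_df[refdb_df.dataset_id == dsid]
        refdb = ReferenceDB(str(drefdb["primer"].iloc[0]) if len(drefdb) else "12S",
                            harmonize_species_set(drefdb["species"], synonyms))
        meta = DatasetMetadata(dataset_id=dsid, **{
            k: meta_df.loc[dsid, k] for k in
            ("continent", "year", "barcode", "refdb_type",
             "median_fish_reads", "n_sites")})
        meta.year = int(meta.year)
        meta.n_sites = int(meta.n_sites)
        datasets.append(Dataset(dsid, table, original, pools, refdb, meta))
    return Collection(datasets, synonyms)


def read_refdb_fasta(path) -> dict[str, ReferenceDB]:
    """Reference-database taxon lists from FASTA headers "primer|Genus species".

    Sequences themselves are ignored; only the taxon inventory matters for
    coverage auditing.  Returns one ReferenceDB per primer found.
    """
    from Bio import SeqIO

    taxa: dict[str, set[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if "|" not in header:
            raise ValueError(f"header {header!r} is not 'primer|Genus species'")
        primer, name = header.split("|", 1)
        taxa.setdefault(primer.strip(), set()).add(name.strip())
    return {p: ReferenceDB(p, frozenset(sp)) for p, sp in taxa.items()}


# ---------------------------------------------------------------------------
# pipeline stages


def richness_pairs(collection: Collection, scale: str = "global") -> pd.DataFrame:
    """Per-site (original, reanalyzed) richness pairs for the NB GLMM."""
    rows = []
    for ds in collection.datasets:
        if ds.original is None or ds.original.presence is None:
            continue
        table = ds.read_table if scale == "global" else \
            correct_to_pool(ds.read_table, ds.pools.pool(scale))
        rean = richness_per_site(table)
        orig = (ds.original.presence > 0).sum(axis=0)
        common = rean.index.intersection(orig.index)
        for site in common:
            rows.append({"dataset_id": ds.dataset_id, "site": site,
                         "original_richness": int(orig[site]),
                         "reanalyzed_richness": int(rean[site])})
    return pd.DataFrame(rows)


def run_pipeline(collection: Collection, config: RunConfig) -> dict:
    """Execute every analysis stage and write the outputs.

    Returns a dict of in-memory stage results; files land in
    ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"provenance": _provenance(config)}

    if config.min_fish_reads > 0:
        collection, removed = sensitivity_filter(collection, config.min_fish_reads)
        removed.to_csv(out / "sensitivity_removed.csv", index=False)
        results["sensitivity_removed"] = removed

    # coverage audit
    cov = coverage_report(collection)
    cov.to_csv(out / "coverage.csv", index=False)
    results["coverage"] = cov

    # congruence
    scale = "basin" if config.scale == "global" else config.scale
    cong = congruence_table(collection, scale=scale)
    cong.to_csv(out / "congruence.csv", index=False)
    abund = abundance_table(collection, scale=scale)
    abund.to_csv(out / "abundance.csv", index=False)
    results["congruence"] = cong
    results["abundance"] = abund

    # community structure
    occ = build_occurrence_matrix(collection)
    community: dict = {}
    if len(occ.data) >= 4 and occ.meta["continent"].nunique() >= 2:
        dist = jaccard_matrix(occ)
        for factor in ("continent", "assignment_type"):
            groups = occ.meta[factor]
            ok = groups.map(groups.value_counts()) >= 2
            if groups[ok].nunique() < 2:
                continue
            d_ok = dist.loc[ok.values, ok.values]
            g_ok = groups[ok.values]
            community[f"permanova_{factor}"] = permanova(
                d_ok, g_ok, config.n_perm, config.seed).as_dict()
            community[f"anosim_{factor}"] = anosim(
                d_ok, g_ok, config.n_perm, config.seed).as_dict()
        gcont = occ.meta["continent"]
        ok = gcont.map(gcont.value_counts()) >= 2
        if gcont[ok.values].nunique() >= 2:
            d_ok = dist.loc[ok.values, ok.values]
            community["dispersion_continent"] = dispersion_test(
                d_ok, gcont[ok.values], config.n_perm, config.seed).as_dict()
            community["dbrda_continent"] = dbrda(
                d_ok, gcont[ok.values], config.n_perm, config.seed).as_dict()
        ord_res = nmds(dist, k=2, seed=config.seed, n_restarts=2)
        nmds_df = pd.DataFrame(ord_res.coordinates,
                               index=dist.index, columns=["axis1", "axis2"])
        nmds_df["stress"] = ord_res.stress
        nmds_df.to_csv(out / "nmds.csv")
        community["nmds_stress"] = ord_res.stress
    (out / "community_tests.json").write_text(
        json.dumps({**community, "provenance": _provenance(config)}, indent=1))
    results["community"] = community

    # regression models
    model_fits: dict = {}
    pairs = richness_pairs(collection, scale="global")
    if not pairs.empty and pairs["dataset_id"].nunique() >= 2:
        model_fits["nb_glmm_richness_global"] = fit_nb_glmm_richness(
            pairs["original_richness"], pairs["reanalyzed_richness"],
            pairs["dataset_id"]).as_dict()
    if len(cong) >= 10:
        df = cong.assign(
            log_median_fish_reads=np.log(cong["median_fish_reads"]),
            refdb_custom=(cong["refdb_type"] == "custom").astype(float),
            reanalyzed_richness=cong["n_reanalyzed"].astype(float))
        for resp in ("p_sp", "p_read"):
            try:
                model_fits[f"beta_glm_{resp}"] = fit_beta_glm(df, resp).as_dict()
            except ValueError as exc:
                logger.warning("beta GLM for %s skipped: %s", resp, exc)
    if not abund.empty and abund["dataset_id"].nunique() >= 2:
        for index in ("a", "b"):
            model_fits[f"abundance_mixed_{index}"] = fit_abundance_mixed(
                abund, index=index).as_dict()
    results["models"] = model_fits
    with open(out / "models.json", "w") as fh:
        json.dump({**model_fits, "provenance": _provenance(config)}, fh,
                  indent=1, default=float)

    # grouped nonparametric tests on the congruence summaries
    gt_rows = []
    if not cong.empty and cong["continent"].nunique() >= 2:
        counts = cong["continent"].value_counts()
        sub = cong[cong["continent"].map(counts) >= 2]
        if sub["continent"].nunique() >= 2:
            gt = group_tests(sub["p_sp"].to_numpy(), sub["continent"].to_numpy())
            gt_rows.append({"comparison": "p_sp_by_continent", "test": gt.test,
                            "statistic": gt.statistic, "p": gt.p_value,
                            "letters": json.dumps(gt.letters)})
            results["group_tests_p_sp_by_continent"] = gt
    if not cong.empty and cong["refdb_type"].nunique() == 2:
        a = cong.loc[cong.refdb_type == "global", "p_sp"]
        b = cong.loc[cong.refdb_type == "custom", "p_sp"]
        if len(a) and len(b):
            rs = rank_sum_test(a, b)
            gt_rows.append({"comparison": "p_sp_by_refdb_type", "test": rs.test,
                            "statistic": rs.statistic, "p": rs.p_value,
                            "letters": None})
            results["rank_sum_p_sp_refdb"] = rs
    pd.DataFrame(gt_rows).to_csv(out / "group_tests.csv", index=False)

    write_report(results, out / "report")
    return results


def write_report(results: dict, out_prefix) -> Path:
    """Single structured report: JSON plus a readable text digest."""
    out_prefix = Path(out_prefix)
    payload = {"provenance": results.get("provenance", _provenance())}
    for key in ("coverage", "congruence", "abundance", "sensitivity_removed"):
        obj = results.get(key)
        payload[key] = obj.to_dict(orient="records") if isinstance(obj, pd.DataFrame) else None
    payload["community"] = results.get("community")
    payload["models"] = results.get("models")
    out_prefix.with_suffix(".json").write_text(
        json.dumps(payload, indent=1, default=float))

    lines = ["# Congruence analysis report", ""]
    cong = results.get("congruence")
    if isinstance(cong, pd.DataFrame) and not cong.empty:
        lines += [f"Datasets with identity comparison: {len(cong)}",
                  f"Mean p_sp: {cong['p_sp'].mean():.4f}",
                  f"Median p_sp: {cong['p_sp'].median():.4f}",
                  f"Mean p_read: {cong['p_read'].mean():.4f}", ""]
    else:
        lines += ["Congruence stage: absent", ""]
    cov = results.get("coverage")
    if isinstance(cov, pd.DataFrame) and not cov.empty:
        sp = cov[(cov.scale == "basin") & (cov.resolution == "species")]
        lines += ["Mean basin-scale species coverage by continent:"]
        lines += [f"  {c}: {v:.3f}" for c, v in
                  sp.groupby("continent")["coverage"].mean().items()]
        lines += [""]
    else:
        lines += ["Coverage stage: absent", ""]
    if results.get("community"):
        for name, res in results["community"].items():
            if isinstance(res, dict):
                lines.append(f"{name}: stat={res['statistic']:.4f} p={res['p']:.4f}")
        lines.append("")
    if results.get("models"):
        for name, fit in results["models"].items():
            lines.append(f"model {name}: converged={fit['converged']}")
    out_prefix.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return out_prefix.with_suffix(".json")
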