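# ednacongruence

Tools for asking a simple question with many moving parts: **when the same
riverine fish eDNA metabarcoding datasets are reanalyzed under one common
bioinformatic workflow, how well do the resulting taxonomic assignments
agree with what the original studies reported — and what explains the
disagreement?**

The package is aimed at eDNA practitioners and meta-analysts who have
per-dataset species × site read tables from a reanalysis, the original
species lists, hierarchical local species checklists (basin / country /
continent) and per-primer barcode reference-database taxon lists.  It
provides:

* **taxonomy** — synonym-table name standardization so all comparisons share
  one namespace of canonical binomials;
* **coverage** — audit of how completely each barcode reference database
  represents the local species pools (coverage = |pool ∩ refdb| / |pool|),
  and how local the taxa in an uncorrected assignment are, at both species
  and genus resolution;
* **congruence** — correction of assignments to local pools and the
  four-category species-identity classification (shared / unique to
  reanalysis / extra local / non-local), with the overlap proportions

      p_sp   = N_shared / N_species in reanalysis
      p_read = N_reads of shared species / N_total reads in reanalysis

  and per-species relative-abundance indices
  a_i = Σ_s R_is / Σ_s Σ_j R_js and b_i = (1/n) Σ_s R_is / Σ_j R_js;
* **community** — Jaccard distances over species occurrence profiles with
  PERMANOVA, ANOSIM, multivariate dispersion, db-RDA (permutation inference
  implemented from scratch, with exact enumeration for small designs) and a
  Kruskal stress-1 NMDS;
* **models** — a negative-binomial random-intercept GLMM for richness
  comparison (Laplace-fitted, with marginal/conditional R²), beta GLMs with
  logit link for the overlap proportions, beta mixed models for the
  abundance indices, Kruskal–Wallis/Dunn group tests with compact letter
  displays, and a median-fish-reads sensitivity filter;
* **simulate** — a synthetic-data generator producing whole collections
  with known ground truth: regionally varying reference-database coverage,
  nested species pools, a year-dependent congruence process and a read-
  abundance penalty for non-shared species.

Real deposited data are not required: every analysis runs end-to-end on the
synthetic collections, and the test suite uses them to verify parameter
recovery and calibration.

## Worked example

```bash
python analysis/01_simulate_collection.py --seed 0
python analysis/03_identity_congruence.py
python analysis/05_regression_models.py
```

which prints (abridged):

```
Simulated 50 datasets covering 1094 sites.
39 datasets with species-identity comparison (of 50 total).
Shared species: mean 64.6%, median 62.5%
Shared reads:   mean 78.6%, median 79.3%
Extra local species: mean 10.6 (0 to 32), of which 0 to 7 have barcode records
Richness GLMM (1094 site pairs): slope = 0.0244 (z = 9.21), R2m = 0.132, R2c = 0.634
Beta GLM p_sp: year z = 2.85 (p = 0.0043), phi = 9.9
Abundance index a: unique-species effect = -0.601 (z = -11.39)
```

Reading this: about two-thirds of the species found by the reanalysis were
also in the original assignments, and shared species carry a larger share
of reads than of species — non-shared species are rare.  Most explanatory
power for richness sits in the dataset random effect (conditional R² 0.63
vs marginal 0.13).  More recently sampled datasets agree better (positive
year effect on the logit of p_sp), and species unique to the reanalysis
have significantly lower relative read abundance (negative effect on the
logit of a_i).  The remaining drivers live in `results/models.json`;
`analysis/02_coverage_audit.py`, `04_community_structure.py` and
`06_sensitivity.py` cover the reference-database audit, the community-level
permutation tests and the low-read-count sensitivity check.

A `ednacongruence` CLI wraps the same stages
(`simulate`, `coverage`, `congruence`, `community`, `models`, `run`):

```bash
ednacongruence run --seed 0 --out results/full_run
```

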