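"""Fit the explanatory regression models.

(1) NB random-intercept GLMM of per-site reanalyzed on original richness;
(2) beta GLMs of p_sp and p_read on log median fish reads, sampling year,
reanalyzed richness and reference-database type; (3) beta mixed models of
the per-species abundance indices on the shared/unique flag.  Writes
results/models.json.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ednacongruence.io import read_collection, richness_pairs
from ednacongruence.models import (fit_abundance_mixed, fit_beta_glm,
                                   fit_nb_glmm_richness)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--collection", type=Path, default=Path("results/collection"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    coll = read_collection(args.collection)
    cong = pd.read_csv(args.results / "congruence.csv")
    abund = pd.read_csv(args.results / "abundance.csv")
    fits = {}

    pairs = richness_pairs(coll, scale="global")
    glmm = fit_nb_glmm_richness(pairs["original_richness"],
                                pairs["reanalyzed_richness"],
                                pairs["dataset_id"])
    fits["nb_glmm_richness"] = glmm.as_dict()
    print(f"Richness GLMM ({len(pairs)} site pairs): slope = "
          f"{glmm.coef('original_richness'):.4f} "
          f"(z = {glmm.params.loc['original_richness', 'z']:.2f}), "
          f"R2m = {glmm.r2_marginal:.3f}, R2c = {glmm.r2_conditional:.3f}")

    cong = cong[np.isfinite(cong["p_sp"])]
    df = cong.assign(
        log_median_fish_reads=np.log(cong["median_fish_reads"]),
        refdb_custom=(cong["refdb_type"] == "custom").astype(float),
        reanalyzed_richness=cong["n_reanalyzed"].astype(float))
    for resp in ("p_sp", "p_read"):
        fit = fit_beta_glm(df, resp)
        fits[f"beta_glm_{resp}"] = fit.as_dict()
        year_z = fit.params.loc["year", "z"]
        year_p = fit.params.loc["year", "p"]
        print(f"Beta GLM {resp}: year z = {year_z:.2f} (p = {year_p:.4f}), "
              f"phi = {fit.dispersion:.1f}")

    for index in ("a", "b"):
        mixed = fit_abundance_mixed(abund, index=index)
        fits[f"abundance_mixed_{index}"] = mixed.as_dict()
        print(f"Abundance index {index}: unique-species effect = "
              f"{mixed.coef('unique'):.3f} "
              f"(z = {mixed.params.loc['unique', 'z']:.2f})")

    (args.results / "models.json").write_text(
        json.dumps(fits, indent=1, default=float))


if __name__ == "__main__":
    main()
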