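"""Test robustness of community structure across assignment types.

Builds the species occurrence matrix over the three assignment types
(original, global reanalysis, basin reanalysis), computes Jaccard distances,
and runs PERMANOVA, ANOSIM, the multivariate dispersion test, db-RDA and a
2-D NMDS.  Writes results/community_tests.json and results/nmds.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ednacongruence.community import (anosim, build_occurrence_matrix, dbrda,
                                      dispersion_test, jaccard_matrix, nmds,
                                      permanova)
from ednacongruence.io import read_collection


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--collection", type=Path, default=Path("results/collection"))
    ap.add_argument("--n-perm", type=int, default=999)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    coll = read_collection(args.collection)
    occ = build_occurrence_matrix(coll)
    dist = jaccard_matrix(occ)
    print(f"Occurrence matrix: {occ.data.shape[0]} profiles x "
          f"{occ.data.shape[1]} species")

    results = {}
    for factor in ("continent", "assignment_type"):
        groups = occ.meta[factor]
        keep = groups.map(groups.value_counts()) >= 2
        d = dist.loc[keep.values, keep.values]
        g = groups[keep.values]
        res_p = permanova(d, g, args.n_perm, args.seed)
        res_a = anosim(d, g, args.n_perm, args.seed)
        results[f"permanova_{factor}"] = res_p.as_dict()
        results[f"anosim_{factor}"] = res_a.as_dict()
        print(f"{factor}: PERMANOVA R2 = {res_p.r_squared:.3f} "
              f"(p = {res_p.p_value:.3f}); ANOSIM R = {res_a.statistic:.3f} "
              f"(p = {res_a.p_value:.3f})")

    groups = occ.meta["continent"]
    keep = groups.map(groups.value_counts()) >= 2
    d = dist.loc[keep.values, keep.values]
    g = groups[keep.values]
    res_d = dispersion_test(d, g, args.n_perm, args.seed)
    res_r = dbrda(d, g, args.n_perm, args.seed)
    results["dispersion_continent"] = res_d.as_dict()
    results["dbrda_continent"] = res_r.as_dict()
    print(f"dispersion: F = {res_d.statistic:.2f} (p = {res_d.p_value:.3f}); "
          f"db-RDA: F = {res_r.statistic:.2f} (p = {res_r.p_value:.3f})")

    ord_res = nmds(dist, k=2, seed=args.seed, n_restarts=4)
    coords = pd.DataFrame(ord_res.coordinates, index=dist.index,
                          columns=["axis1", "axis2"])
    coords = coords.join(occ.meta)
    coords["stress"] = ord_res.stress
    args.out.mkdir(parents=True, exist_ok=True)
    coords.to_csv(args.out / "nmds.csv")
    (args.out / "community_tests.json").write_text(json.dumps(results, indent=1))
    print(f"NMDS stress = {ord_res.stress:.4f}")


if __name__ == "__main__":
    main()
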