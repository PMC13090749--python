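"""Compare species identities between original and reanalyzed assignments.

Classifies every species into the four agreement categories after basin
correction, computes the overlap proportions p_sp and p_read and the
per-species abundance indices, and tests continent / reference-database-type
differences.  Writes results/congruence.csv and results/abundance.csv.
"""

import argparse
from pathlib import Path

from ednacongruence.congruence import abundance_table, congruence_table
from ednacongruence.io import read_collection
from ednacongruence.models import group_tests, rank_sum_test


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--collection", type=Path, default=Path("results/collection"))
    ap.add_argument("--scale", default="basin",
                    choices=["basin", "country", "continent"])
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    coll = read_collection(args.collection)
    cong = congruence_table(coll, scale=args.scale)
    abund = abundance_table(coll, scale=args.scale)
    args.out.mkdir(parents=True, exist_ok=True)
    cong.to_csv(args.out / "congruence.csv", index=False)
    abund.to_csv(args.out / "abundance.csv", index=False)

    ok = cong["p_sp"].notna()
    print(f"{ok.sum()} datasets with species-identity comparison "
          f"(of {len(coll)} total).")
    print(f"Shared species: mean {100 * cong.loc[ok, 'p_sp'].mean():.1f}%, "
          f"median {100 * cong.loc[ok, 'p_sp'].median():.1f}%")
    print(f"Shared reads:   mean {100 * cong.loc[ok, 'p_read'].mean():.1f}%, "
          f"median {100 * cong.loc[ok, 'p_read'].median():.1f}%")
    print(f"Extra local species: mean {cong['n_unique_orig_local'].mean():.1f} "
          f"(0 to {cong['n_unique_orig_local'].max()}), of which "
          f"0 to {cong['extra_local_with_barcode'].max()} have barcode records")

    counts = cong.loc[ok, "continent"].value_counts()
    sub = cong[ok & cong["continent"].map(counts).ge(2)]
    if sub["continent"].nunique() >= 2:
        gt = group_tests(sub["p_sp"].to_numpy(), sub["continent"].to_numpy())
        print(f"p_sp by continent: H = {gt.statistic:.2f}, p = {gt.p_value:.4f}")
    g = cong.loc[ok & (cong.refdb_type == "global"), "p_sp"]
    c = cong.loc[ok & (cong.refdb_type == "custom"), "p_sp"]
    if len(g) >= 2 and len(c) >= 2:
        rs = rank_sum_test(g, c)
        print(f"p_sp global vs custom refdb: rank-sum p = {rs.p_value:.4f}")


if __name__ == "__main__":
    main()
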