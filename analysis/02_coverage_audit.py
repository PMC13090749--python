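"""Audit barcode reference-database coverage of the local species pools.

For every dataset, scale (basin/country/continent) and resolution
(species/genus) this computes (i) the proportion of the local pool with
barcode records and (ii) the proportion of globally assigned taxa that are
local, then tests continent differences with Kruskal-Wallis + Dunn letters.
Writes results/coverage.csv and results/coverage_group_tests.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ednacongruence.coverage import coverage_report
from ednacongruence.io import read_collection
from ednacongruence.models import group_tests


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--collection", type=Path, default=Path("results/collection"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    coll = read_collection(args.collection)
    rep = coverage_report(coll)
    args.out.mkdir(parents=True, exist_ok=True)
    rep.to_csv(args.out / "coverage.csv", index=False)

    sp = rep[(rep.scale == "basin") & (rep.resolution == "species")].dropna(
        subset=["coverage"])
    print("Mean basin-scale species coverage by continent:")
    print(sp.groupby("continent")["coverage"].mean().round(3).to_string())

    rows = []
    for scale in ("basin", "country", "continent"):
        sub = rep[(rep.scale == scale) & (rep.resolution == "species")].dropna(
            subset=["coverage"])
        counts = sub["continent"].value_counts()
        sub = sub[sub["continent"].map(counts) >= 2]
        if sub["continent"].nunique() < 2:
            continue
        gt = group_tests(sub["coverage"].to_numpy(), sub["continent"].to_numpy())
        rows.append({"scale": scale, "H": gt.statistic, "p": gt.p_value,
                     "letters": json.dumps(gt.letters)})
        print(f"{scale}: Kruskal-Wallis H = {gt.statistic:.2f}, "
              f"p = {gt.p_value:.4f}, letters = {gt.letters}")
    pd.DataFrame(rows).to_csv(args.out / "coverage_group_tests.csv", index=False)


if __name__ == "__main__":
    main()
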