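#!/usr/bin/env python
"""Agreement analysis of the measured cohort.

Reads the per-eye cohort produced by 02_measure_cohort.py and reports the
coefficient-of-variation comparison (CVI vs SFCT), the 2D-subfoveal vs 3D
regional agreement table (ICC, Bland-Altman, variance F-test), and the
11/21/31-scan scanning-volume comparison.
"""

import argparse
from pathlib import Path

import pandas as pd

from cvi3d.stats import build_report, cov_percent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", type=Path,
                        default=Path("results/analysis/run/cohort.csv"))
    parser.add_argument("--outdir", type=Path,
                        default=Path("results/analysis/agreement"))
    args = parser.parse_args()

    cohort = pd.read_csv(args.cohort)
    print("coefficient of variation (measured cohort):")
    for col in ("cvi3d_whole", "cvi2d_subfoveal", "sfct_um"):
        print(f"  {col}: {cov_percent(cohort[col].to_numpy()):.2f}%")

    tables = build_report(cohort)
    args.outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(args.outdir / f"{name}.csv", index=False)
    print("\n2D subfoveal vs 3D regional agreement:")
    print(tables["agreement"].to_string(index=False))
    print("\nscanning-volume (11/21/31 scans) agreement:")
    print(tables["scanning_volume"].to_string(index=False))


if __name__ == "__main__":
    main()
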