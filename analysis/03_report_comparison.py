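#!/usr/bin/env python
"""Summarize the habitat comparison and check it against generator truth.

Reads the pipeline outputs and the simulation ground truth, prints the
SMA lines (freshwater on saltwater) for SSD means, SDs and HC5 in both
species-count strata, the fractions of chemicals inside the 0.1–10 and
0.25–4 fold ranges, the species-number correlations, and the per-mode-
of-action t-tests — and states whether the SMA slope interval covers
the generator's true slope of 1.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"

sma = pd.read_csv(ROOT / "pipeline" / "sma_results.csv")
ranges = pd.read_csv(ROOT / "pipeline" / "range_summaries.csv")
tests = pd.read_csv(ROOT / "pipeline" / "tests.csv")
truth_sma = pd.read_csv(ROOT / "sim" / "truth.csv")

primary = sma[sma["orientation"] == "sw_x_fw_y"]
print("SMA regression, freshwater (y) on saltwater (x):")
for _, row in primary.iterrows():
    print(f"  [{row['stratum']:>4}] {row['parameter']:>4}: "
          f"slope {row['slope']:.2f} "
          f"({row['slope_lo']:.2f}-{row['slope_hi']:.2f}), "
          f"intercept {row['intercept']:.2f} "
          f"({row['intercept_lo']:.2f}-{row['intercept_hi']:.2f}), "
          f"r2 {row['r_squared']:.2f}, n {row['n']:.0f}")
    if row["parameter"] in ("mean", "sd"):
        covers = row["slope_lo"] <= 1.0 <= row["slope_hi"]
        print(f"         true slope 1 (generator): "
              f"{'covered' if covers else 'NOT covered'} by the 95% CI")

print("\nfold-ratio ranges:")
for _, row in ranges.iterrows():
    print(f"  [{row['stratum']:>4}] {row['parameter']:>4} within "
          f"{row['range_low']}-{row['range_high']}: "
          f"{100 * row['fraction_within']:.0f}% "
          f"({row['n_outside']:.0f} of {row['n']:.0f} outside)")

print("\nspecies-number correlations (n_min vs |log10 ratio|):")
corr = tests[(tests["test"] == "pearson_n_species") & (tests["error"].isna())]
for _, row in corr.iterrows():
    print(f"  [{row['stratum']:>4}] {row['parameter']:>4}: "
          f"r = {row['estimate']:.2f}, p = {row['p_value']:.3f}")

print("\nper-mode-of-action one-sample t-tests (log10 sw/fw ratio vs 0):")
tt = tests[(tests["test"] == "moa_ttest") & (tests["error"].isna())]
for _, row in tt.iterrows():
    flag = "*" if row["p_value"] < 0.05 else " "
    print(f"  [{row['stratum']:>4}] {row['parameter']:>4} "
          f"{row['group']:>12}: mean {row['estimate']:+.2f}, "
          f"t = {row['statistic']:.2f}, p = {row['p_value']:.3f}{flag}")
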