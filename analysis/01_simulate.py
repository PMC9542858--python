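#!/usr/bin/env python
"""Generate the synthetic study corpus.

Draws a 104-chemical acute-toxicity record table under the default
simulation conditions (bivariate log-normal SSD truth, ρ = 0.95 for
means and 0.5 for SDs, species pools of 854 freshwater / 296 saltwater
species) with a handful of planted violations of every selection
criterion, and writes the records plus the generator's ground truth
under results/sim/.
"""

from pathlib import Path

from ssdcompare import (
    PlantedViolations,
    SimulationConfig,
    ground_truth_report,
    simulate_records,
    simulate_truth,
    write_table,
)

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"

config = SimulationConfig(
    planted=PlantedViolations(
        n_wrong_effect=20, n_chronic=15, n_over_solubility=25,
        n_amphibian=10, n_under_species=3, n_single_taxon=3, n_nonnormal=3,
    )
)

truth = simulate_truth(config, SEED)
records = simulate_records(truth, config, SEED)

OUT.mkdir(parents=True, exist_ok=True)
write_table(records, OUT / "records.csv")
write_table(ground_truth_report(truth), OUT / "truth.csv")

n_regular = (truth.chemicals["kind"] == "regular").sum()
print(f"wrote {len(records)} test records for "
      f"{truth.chemicals['chemical_id'].nunique()} chemicals "
      f"({n_regular} regular + {len(truth.chemicals) - n_regular} planted-violation) "
      f"to {OUT}")
print(f"planted record-level violations: "
      f"{ {k: len(v) for k, v in truth.planted_rows.items()} }")
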