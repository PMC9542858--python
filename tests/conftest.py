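import numpy as np
import pandas as pd
import pytest

from ssdcompare import (
    PlantedViolations,
    SimulationConfig,
    simulate_records,
    simulate_truth,
)


@pytest.fixture(scope="session")
def planted_config() -> SimulationConfig:
    """Small corpus with violations of every selection criterion planted."""
    return SimulationConfig(
        n_chemicals=25,
        planted=PlantedViolations(
            n_wrong_effect=4,
            n_chronic=3,
            n_over_solubility=5,
            n_amphibian=3,
            n_under_species=2,
            n_single_taxon=2,
            n_nonnormal=2,
        ),
    )


@pytest.fixture(scope="session")
def planted_corpus(planted_config):
    truth = simulate_truth(planted_config, seed=2026)
    records = simulate_records(truth, planted_config, seed=2026)
    return truth, records


@pytest.fixture
def fits_frame():
    """Build a fit table (as from fit_all) from per-chemical parameters."""

    def make(params: dict[str, dict[str, tuple[float, float, int]]],
             moa: dict[str, str] | None = None) -> pd.DataFrame:
        # params: chemical -> habitat -> (mean_log10, sd_log10, n_species)
        rows = []
        for chem, habs in params.items():
            for habitat, (mean, sd, n) in habs.items():
                rows.append({
                    "chemical_id": chem, "habitat": habitat,
                    "n_species": n, "n_taxa_groups": 2,
                    "mean_log10": mean, "sd_log10": sd,
                    "hc5_log10": mean - 1.645 * sd,
                    "shapiro_p": 1.0, "shapiro_p_holm": 1.0,
                    "mode_of_action": (moa or {}).get(chem, "unclassified"),
                })
        return pd.DataFrame(rows)

    return make


@pytest.fixture
def tiny_records() -> pd.DataFrame:
    """Six hand-written records for two chemicals."""
    rows = [
        # chem, species, taxon, habitat, measure, exposure, conc, sol
        ("C1", "sp1", "fish", "freshwater", "LC50", "acute", 10.0, 1e4),
        ("C1", "sp1", "fish", "freshwater", "LC50", "acute", 1000.0, 1e4),
        ("C1", "sp2", "invertebrate", "saltwater", "EC50", "acute", 50.0, 1e4),
        ("C2", "sp3", "algae", "freshwater", "NOEC", "acute", 5.0, 1e4),
        ("C2", "sp4", "amphibian", "freshwater", "LC50", "acute", 7.0, 1e4),
        ("C2", "sp5", "fish", "saltwater", "LC50", "chronic", 9.0, 1e4),
    ]
    df = pd.DataFrame(rows, columns=[
        "chemical_id", "species_id", "taxonomic_group", "habitat",
        "effect_measure", "exposure_type", "concentration", "water_solubility",
    ])
    df.insert(0, "row_id", np.arange(1, len(df) + 1))
    df["chemical_name"] = df["chemical_id"]
    df["mode_of_action"] = "narcotic"
    return df
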