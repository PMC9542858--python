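"""Synthetic EnviroTox-shaped corpora with known ground truth.

The generator draws a corpus of chemicals whose "true" freshwater and
saltwater SSDs are known, renders species-level test records from them,
and optionally plants violations of each curation criterion so that the
whole pipeline — filtering, aggregation, eligibility, fitting,
screening, comparison, SMA — can be verified end to end against truth.

Model
-----
Per chemical, the pair of true SSD means (freshwater, saltwater) is
bivariate normal on the log10 µg/L scale with correlation ``mean_rho``;
the pair of true SSD SDs is lognormal (a Gaussian copula on log10 SD)
with correlation ``sd_rho``. With equal marginal scales in the two
habitats the corpus-level true SMA line for each parameter is the 1:1
line. Species sensitivities are normal draws around the true SSD;
each species contributes one or more test records whose log10
concentrations add independent within-species noise, so the geometric
mean of a species' records estimates its sensitivity.

Each chemical's draws come from a dedicated counter-based substream,
so enlarging the corpus never perturbs chemicals already drawn.

Defaults mirror the corpus the pipeline targets: 104 chemicals with
mode-of-action weights 20/39/45, species pools of 854 freshwater and
296 saltwater species, per-chemical species counts of 5–60 (freshwater)
and 5–25 (saltwater).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .records import CANONICAL_COLUMNS
from .ssd import Z_HC5


@dataclass
class PlantedViolations:
    """How many records/chemicals violate each selection criterion."""

    n_wrong_effect: int = 0      # extra NOEC records (criterion: effect measure)
    n_chronic: int = 0           # extra chronic LC50 records
    n_over_solubility: int = 0   # extra records above 5× solubility
    n_amphibian: int = 0         # extra amphibian species records
    n_under_species: int = 0     # chemicals with < min species in saltwater
    n_single_taxon: int = 0      # chemicals with a single taxon in freshwater
    n_nonnormal: int = 0         # chemicals with heavy-tailed sensitivities
    nonnormal_n_species: int = 50  # species per habitat for planted non-normal SSDs


@dataclass
class SimulationConfig:
    n_chemicals: int = 104
    fw_species_pool: int = 854
    sw_species_pool: int = 296
    fw_species_range: tuple[int, int] = (5, 60)
    sw_species_range: tuple[int, int] = (5, 25)
    # true SSD mean law, log10 µg/L
    mean_loc: float = 2.5
    mean_scale: float = 1.2
    mean_rho: float = 0.95
    sw_mean_shift: float = 0.0
    # true SSD SD law: log10(SD) ~ Normal(log10(sd_median), sd_log_spread)
    sd_median: float = 0.6
    sd_log_spread: float = 0.15
    sd_rho: float = 0.5
    # test-record rendering
    replicate_rate: float = 0.5      # extra tests per species ~ Poisson(rate)
    test_noise_sd: float = 0.2       # within-species log10 noise
    solubility_margin: float = 8.0   # log10 headroom of solubility over the mean
    taxa_probs: Mapping[str, float] = field(
        default_factory=lambda: {"algae": 0.2, "invertebrate": 0.4, "fish": 0.4}
    )
    moa_probs: Mapping[str, float] = field(
        default_factory=lambda: {"narcotic": 20 / 104, "specific": 39 / 104,
                                 "unclassified": 45 / 104}
    )
    planted: PlantedViolations = field(default_factory=PlantedViolations)

    def validate(self) -> None:
        if self.n_chemicals < 0:
            raise ValueError("n_chemicals must be >= 0")
        for name in ("mean_scale", "sd_median", "sd_log_spread", "test_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("mean_rho", "sd_rho"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")
        for probs, label in ((self.taxa_probs, "taxa_probs"),
                             (self.moa_probs, "moa_probs")):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} must sum to 1")
        for rng_ in (self.fw_species_range, self.sw_species_range):
            if not 2 <= rng_[0] <= rng_[1]:
                raise ValueError(f"bad species-count range {rng_}")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    chemicals: pd.DataFrame        # one row per chemical: true params, flags
    sma: pd.DataFrame              # per parameter: true slope/intercept (x=sw, y=fw)
    planted_rows: dict[str, list[int]] = field(default_factory=dict)
    planted_chemicals: dict[str, list[str]] = field(default_factory=dict)


HABITAT_CODES = {"freshwater": "fw", "saltwater": "sw"}


def _chem_rng(seed: int, index: int) -> np.random.Generator:
    # one substream per chemical: adding chemicals never reshuffles earlier ones
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _species_pool(config: SimulationConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Fixed per-habitat species pools with one taxon per species."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10**6,)))
    pools = {}
    taxa = list(config.taxa_probs)
    probs = np.array([config.taxa_probs[t] for t in taxa])
    for habitat, size in (("freshwater", config.fw_species_pool),
                          ("saltwater", config.sw_species_pool)):
        code = HABITAT_CODES[habitat]
        pools[habitat] = pd.DataFrame({
            "species_id": [f"SP-{code}-{i:04d}" for i in range(size)],
            "taxonomic_group": rng.choice(taxa, size=size, p=probs),
        })
    return pools


def simulate_truth(config: SimulationConfig, seed: int) -> GroundTruth:
    """Draw the true per-chemical SSD parameters and eligibility flags.

    Regular chemicals come first (``CHEM-0000`` …); chemicals planted to
    violate the species-count, taxon, or normality criteria are appended
    with self-describing ids and recorded in ``planted_chemicals``.
    """
    config.validate()
    p = config.planted
    rows = []
    planted_chemicals: dict[str, list[str]] = {
        "under_species": [], "single_taxon": [], "nonnormal": [],
    }
    moa_labels = list(config.moa_probs)
    moa_p = np.array([config.moa_probs[m] for m in moa_labels])

    def draw_params(rng: np.random.Generator) -> dict:
        cov_m = config.mean_rho * config.mean_scale**2
        mean_fw, mean_sw = rng.multivariate_normal(
            [config.mean_loc, config.mean_loc + config.sw_mean_shift],
            [[config.mean_scale**2, cov_m], [cov_m, config.mean_scale**2]],
        )
        cov_s = config.sd_rho * config.sd_log_spread**2
        log_sd_fw, log_sd_sw = rng.multivariate_normal(
            [np.log10(config.sd_median)] * 2,
            [[config.sd_log_spread**2, cov_s], [cov_s, config.sd_log_spread**2]],
        )
        sd_fw, sd_sw = 10.0**log_sd_fw, 10.0**log_sd_sw
        return {
            "mean_fw": mean_fw, "mean_sw": mean_sw,
            "sd_fw": sd_fw, "sd_sw": sd_sw,
            "hc5_fw": mean_fw - Z_HC5 * sd_fw,
            "hc5_sw": mean_sw - Z_HC5 * sd_sw,
            "mode_of_action": moa_labels[rng.choice(len(moa_labels), p=moa_p)],
        }

    def count_species(rng: np.random.Generator) -> tuple[int, int]:
        n_fw = int(rng.integers(config.fw_species_range[0], config.fw_species_range[1] + 1))
        n_sw = int(rng.integers(config.sw_species_range[0], config.sw_species_range[1] + 1))
        return n_fw, n_sw

    index = 0
    for _ in range(config.n_chemicals):
        rng = _chem_rng(seed, index)
        n_fw, n_sw = count_species(rng)
        rows.append({
            "chemical_id": f"CHEM-{index:04d}", **draw_params(rng),
            "n_species_fw": n_fw, "n_species_sw": n_sw,
            "eligible": True, "eligible_reason": "",
            "normal": True, "kind": "regular",
        })
        index += 1

    for _ in range(p.n_under_species):
        rng = _chem_rng(seed, index)
        n_fw, _ = count_species(rng)
        chem = f"CHEM-US-{index:04d}"
        rows.append({
            "chemical_id": chem, **draw_params(rng),
            "n_species_fw": max(n_fw, 5), "n_species_sw": 4,
            "eligible": False, "eligible_reason": "saltwater n=4 < 5",
            "normal": True, "kind": "under_species",
        })
        planted_chemicals["under_species"].append(chem)
        index += 1

    for _ in range(p.n_single_taxon):
        rng = _chem_rng(seed, index)
        n_fw, n_sw = count_species(rng)
        chem = f"CHEM-ST-{index:04d}"
        rows.append({
            "chemical_id": chem, **draw_params(rng),
            "n_species_fw": max(n_fw, 6), "n_species_sw": n_sw,
            "eligible": False, "eligible_reason": "freshwater taxa=1 < 2",
            "normal": True, "kind": "single_taxon",
        })
        planted_chemicals["single_taxon"].append(chem)
        index += 1

    for _ in range(p.n_nonnormal):
        rng = _chem_rng(seed, index)
        chem = f"CHEM-NN-{index:04d}"
        rows.append({
            "chemical_id": chem, **draw_params(rng),
            "n_species_fw": p.nonnormal_n_species,
            "n_species_sw": p.nonnormal_n_species,
            "eligible": True, "eligible_reason": "",
            "normal": False, "kind": "nonnormal",
        })
        planted_chemicals["nonnormal"].append(chem)
        index += 1

    chemicals = pd.DataFrame(
        rows,
        columns=["chemical_id", "mode_of_action", "mean_fw", "mean_sw",
                 "sd_fw", "sd_sw", "hc5_fw", "hc5_sw",
                 "n_species_fw", "n_species_sw",
                 "eligible", "eligible_reason", "normal", "kind"],
    )
    sigma_fw = config.mean_scale
    sigma_sw = config.mean_scale
    slope_mean = np.sign(config.mean_rho) * sigma_fw / sigma_sw if config.mean_rho else np.nan
    sma = pd.DataFrame([
        {"parameter": "mean", "true_slope": slope_mean,
         "true_intercept": config.mean_loc
         - slope_mean * (config.mean_loc + config.sw_mean_shift)},
        {"parameter": "sd", "true_slope": np.sign(config.sd_rho) or np.nan,
         "true_intercept": 0.0},
        {"parameter": "hc5", "true_slope": slope_mean, "true_intercept": np.nan},
    ])
    return GroundTruth(chemicals=chemicals, sma=sma,
                       planted_chemicals=planted_chemicals)


def _standardized_exponential(rng: np.random.Generator, size: int) -> np.ndarray:
    # mean 0, SD 1, strong right skew: defeats the normality screen at n >= 50
    return rng.exponential(1.0, size=size) - 1.0


def simulate_records(
    truth: GroundTruth, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Render test records from the truth and plant record-level violations.

    Planted violations are appended as *extra* rows (they never replace a
    clean record, so removing them restores the clean corpus exactly);
    their ``row_id`` values are written into ``truth.planted_rows``.
    """
    config.validate()
    pools = _species_pool(config, seed)
    p = config.planted
    frames: list[pd.DataFrame] = []

    for idx, chem in truth.chemicals.iterrows():
        rng = _chem_rng(seed, 2 * 10**6 + int(idx))
        for habitat in ("freshwater", "saltwater"):
            code = HABITAT_CODES[habitat]
            n_species = int(chem[f"n_species_{code}"])
            mu, sd = float(chem[f"mean_{code}"]), float(chem[f"sd_{code}"])
            pool = pools[habitat]
            if chem["kind"] == "single_taxon" and habitat == "freshwater":
                pool = pool[pool["taxonomic_group"] == "fish"]
            picked = pool.iloc[
                rng.choice(len(pool), size=n_species, replace=False)
            ].reset_index(drop=True)
            if chem["kind"] != "single_taxon" or habitat != "freshwater":
                # guarantee >= 2 counted taxa so eligibility truth is exact
                if picked["taxonomic_group"].nunique() < 2:
                    other = pool[~pool["species_id"].isin(picked["species_id"])]
                    other = other[other["taxonomic_group"]
                                  != picked["taxonomic_group"].iloc[0]]
                    replacement = other.iloc[[int(rng.integers(len(other)))]]
                    picked = pd.concat(
                        [picked.iloc[:-1], replacement], ignore_index=True
                    )
            if chem["kind"] == "nonnormal":
                sens = mu + sd * _standardized_exponential(rng, n_species)
            else:
                sens = rng.normal(mu, sd, size=n_species)
            n_tests = 1 + rng.poisson(config.replicate_rate, size=n_species)
            sp_idx = np.repeat(np.arange(n_species), n_tests)
            noise = (rng.normal(0.0, config.test_noise_sd, size=sp_idx.size)
                     if config.test_noise_sd > 0 else 0.0)
            log_conc = sens[sp_idx] + noise
            frames.append(pd.DataFrame({
                "chemical_id": chem["chemical_id"],
                "chemical_name": chem["chemical_id"].lower(),
                "species_id": picked["species_id"].to_numpy()[sp_idx],
                "taxonomic_group": picked["taxonomic_group"].to_numpy()[sp_idx],
                "habitat": habitat,
                "effect_measure": "LC50",
                "exposure_type": "acute",
                "concentration": 10.0 ** log_conc,
                "water_solubility": 10.0 ** (mu + config.solubility_margin),
                "mode_of_action": chem["mode_of_action"],
            }))

    records = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=list(CANONICAL_COLUMNS)))

    # --- planted record-level violations -------------------------------
    planted_rows: dict[str, list[int]] = {
        "wrong_effect": [], "chronic": [], "over_solubility": [], "amphibian": [],
    }
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(3 * 10**6,)))
    extra: list[pd.DataFrame] = []
    next_row = len(records)

    def plant(n: int, key: str, mutate) -> None:
        nonlocal next_row
        if n == 0 or records.empty:
            return
        base = records.iloc[rng.choice(len(records), size=n)].copy()
        base = mutate(base).reset_index(drop=True)
        planted_rows[key] = list(range(next_row, next_row + n))
        next_row += n
        extra.append(base)

    plant(p.n_wrong_effect, "wrong_effect",
          lambda df: df.assign(effect_measure="NOEC"))
    plant(p.n_chronic, "chronic",
          lambda df: df.assign(exposure_type="chronic"))
    plant(p.n_over_solubility, "over_solubility",
          lambda df: df.assign(concentration=df["water_solubility"] * 10.0))

    if p.n_amphibian and not records.empty:
        base = records.iloc[rng.choice(len(records), size=p.n_amphibian)].copy()
        base["species_id"] = [f"SP-amph-{i:03d}" for i in range(p.n_amphibian)]
        base["taxonomic_group"] = "amphibian"
        planted_rows["amphibian"] = list(range(next_row, next_row + p.n_amphibian))
        next_row += p.n_amphibian
        extra.append(base.reset_index(drop=True))

    if extra:
        records = pd.concat([records, *extra], ignore_index=True)
    records.insert(0, "row_id", np.arange(len(records)))
    truth.planted_rows = planted_rows
    return records


def ground_truth_report(truth: GroundTruth) -> pd.DataFrame:
    """Flat per-chemical truth table for joining against pipeline outputs."""
    return truth.chemicals.copy()
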