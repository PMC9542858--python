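"""End-to-end orchestration: curate → fit → screen → compare → SMA.

`run_pipeline` executes the fixed stage order

    effect_measure → solubility → amphibian → aggregate → eligibility
    → fit → normality screen → comparison → SMA/ratio summaries

and writes every result table, the audit trail and a run manifest into
the output directory. Given the same input table and configuration the
run is bit-reproducible.

Every numeric constant of the selection and analysis procedure lives in
:class:`RunConfig` (minimum species, taxa, solubility factor, alpha,
ratio ranges, strata); nothing is hard-coded in the stages.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import compare as cmp_mod
from . import curation, sma, ssd
from .records import AuditTrail, read_records, write_table


@dataclass
class RunConfig:
    input_path: str | None = None
    outdir: str = "out"
    column_map: Mapping[str, str] = field(default_factory=dict)
    unit_multiplier: float = 1.0
    allowed_effect_measures: tuple[str, ...] = ("EC50", "LC50")
    min_species: int = 5
    min_taxa: int = 2
    solubility_factor: float = 5.0
    alpha: float = 0.05
    holm_family: str = "joint"           # joint | per-habitat
    sma_orientation: str = "sw_x_fw_y"   # x = saltwater, y = freshwater
    strata: tuple[tuple[str, int], ...] = (("all", 0), ("ge10", 10))
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"mean": (0.1, 10.0), "sd": (0.25, 4.0),
                                 "hc5": (0.1, 10.0)}
    )
    seed: int = 0   # bootstrap reproducibility

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        cfg = cls(**data)
        cfg.strata = tuple((str(n), int(k)) for n, k in cfg.strata)
        cfg.ranges = {k: (float(lo), float(hi)) for k, (lo, hi) in cfg.ranges.items()}
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strata"] = [list(s) for s in self.strata]
        d["ranges"] = {k: list(v) for k, v in self.ranges.items()}
        d["column_map"] = dict(self.column_map)
        return d


@dataclass
class ReportBundle:
    fits: pd.DataFrame
    comparison: pd.DataFrame
    sma_results: pd.DataFrame
    range_summaries: pd.DataFrame
    tests: pd.DataFrame
    audit: AuditTrail
    screen: ssd.ScreenResult
    outdir: Path | None = None


_SMA_COLUMNS = {"mean": "mean_log10", "sd": "sd_log10", "hc5": "hc5_log10"}


def _sma_table(fits: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """SMA of freshwater vs. saltwater for each parameter and stratum.

    The SD comparison is run on log10(SD) so that its slope, like the
    others, relates the two habitats on a log-log scale. Both
    orientations are reported; ``orientation`` names which axis is x.
    """
    rows = []
    wide_n = fits.pivot(index="chemical_id", columns="habitat", values="n_species")
    n_min = wide_n.min(axis=1)
    for stratum, k in config.strata:
        chems = n_min[n_min >= k].index
        for param, col in _SMA_COLUMNS.items():
            wide = fits[fits["chemical_id"].isin(chems)].pivot(
                index="chemical_id", columns="habitat", values=col
            )
            fw = wide["freshwater"].to_numpy(float)
            sw = wide["saltwater"].to_numpy(float)
            if param == "sd":
                fw, sw = np.log10(fw), np.log10(sw)
            for orientation, x, y in (("sw_x_fw_y", sw, fw), ("fw_x_sw_y", fw, sw)):
                try:
                    res = sma.sma_fit(x, y, alpha=config.alpha)
                except (ValueError, sma.DegenerateInputError) as exc:
                    rows.append({"stratum": stratum, "parameter": param,
                                 "orientation": orientation, "error": str(exc)})
                    continue
                rows.append({
                    "stratum": stratum, "parameter": param,
                    "orientation": orientation, "n": res.n,
                    "slope": res.slope, "slope_lo": res.slope_ci[0],
                    "slope_hi": res.slope_ci[1],
                    "intercept": res.intercept,
                    "intercept_lo": res.intercept_ci[0],
                    "intercept_hi": res.intercept_ci[1],
                    "r_squared": res.r_squared, "error": "",
                })
    return pd.DataFrame(rows)


def _summary_tables(comparison: pd.DataFrame, config: RunConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    ranges_rows, tests_rows = [], []
    for stratum, k in config.strata:
        sub = cmp_mod.subset_min_species(comparison, k)
        for param, rng in config.ranges.items():
            if len(sub):
                summary = cmp_mod.fraction_within(sub, param, rng)
                ranges_rows.append({
                    "stratum": stratum, "parameter": param,
                    "range_low": rng[0], "range_high": rng[1],
                    "fraction_within": summary.fraction_within,
                    "n_outside": summary.n_outside,
                    "outside_ids": ";".join(summary.outside_ids),
                    "n": len(sub),
                })
        for param in ("mean", "sd"):
            try:
                r, p, n = cmp_mod.species_number_correlation(sub, param)
                tests_rows.append({"stratum": stratum, "test": "pearson_n_species",
                                   "parameter": param, "group": "",
                                   "estimate": r, "statistic": r, "df": n - 2,
                                   "p_value": p, "n": n, "error": ""})
            except ValueError as exc:
                tests_rows.append({"stratum": stratum, "test": "pearson_n_species",
                                   "parameter": param, "group": "", "error": str(exc)})
            for moa in sorted(comparison["mode_of_action"].unique()):
                try:
                    m, t, df_, p = cmp_mod.moa_ratio_ttest(sub, param, moa)
                    tests_rows.append({"stratum": stratum, "test": "moa_ttest",
                                       "parameter": param, "group": moa,
                                       "estimate": m, "statistic": t, "df": df_,
                                       "p_value": p, "n": df_ + 1, "error": ""})
                except ValueError as exc:
                    tests_rows.append({"stratum": stratum, "test": "moa_ttest",
                                       "parameter": param, "group": moa,
                                       "error": str(exc)})
    return pd.DataFrame(ranges_rows), pd.DataFrame(tests_rows)


def run_pipeline(config: RunConfig,
                 records: pd.DataFrame | None = None) -> ReportBundle:
    """Run every stage and (if ``config.outdir``) write the report bundle.

    ``records`` may be passed directly (already validated, canonical
    columns); otherwise ``config.input_path`` is read via
    :func:`ssdcompare.records.read_records`.
    """
    if records is None:
        if config.input_path is None:
            raise ValueError("either records or config.input_path is required")
        records = read_records(config.input_path, config.column_map,
                               config.unit_multiplier)

    audit = AuditTrail()
    step = curation.filter_effect_measure(records, config.allowed_effect_measures, audit)
    step = curation.filter_solubility(step, config.solubility_factor, audit)
    step = curation.exclude_amphibians(step, audit)
    sens = curation.aggregate_species_geomean(step, audit)
    eligible = curation.select_chemicals(sens, config.min_species,
                                         config.min_taxa, audit)
    sens = sens[sens["chemical_id"].isin(eligible)]

    if sens.empty:
        empty = pd.DataFrame()
        fits = pd.DataFrame(columns=["chemical_id", "habitat", "n_species",
                                     "n_taxa_groups", "mean_log10", "sd_log10",
                                     "hc5_log10", "shapiro_p", "shapiro_p_holm",
                                     "mode_of_action"])
        screen = ssd.ScreenResult(retained=[], excluded=[], alpha=config.alpha)
        comparison = pd.DataFrame(columns=["chemical_id", "mode_of_action", "n_min",
                                           "mean_fold_fw_sw", "sd_ratio_fw_sw",
                                           "hc5_fold_fw_sw", "mean_fold_sw_fw",
                                           "sd_ratio_sw_fw", "hc5_fold_sw_fw"])
        bundle = ReportBundle(fits, comparison, empty, empty, empty, audit, screen)
    else:
        fits = ssd.fit_all(sens)
        fits, screen = ssd.normality_screen(fits, config.alpha, config.holm_family)
        audit.add_stage(
            "normality_screen", len(eligible), len(screen.retained),
            [(chem, f"shapiro_holm<{config.alpha} in {','.join(habitats)}")
             for chem, habitats, _, _ in screen.excluded],
            unit="chemicals",
        )
        kept_fits = fits[fits["chemical_id"].isin(screen.retained)]
        comparison = cmp_mod.build_comparison(kept_fits)
        sma_results = _sma_table(kept_fits, config)
        range_summaries, tests = _summary_tables(comparison, config)
        bundle = ReportBundle(fits, comparison, sma_results, range_summaries,
                              tests, audit, screen)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(bundle.fits, outdir / "ssd_fits.csv")
        write_table(bundle.comparison, outdir / "comparison.csv")
        write_table(bundle.sma_results, outdir / "sma_results.csv")
        write_table(bundle.range_summaries, outdir / "range_summaries.csv")
        write_table(bundle.tests, outdir / "tests.csv")
        audit.write(outdir / "audit_trail.txt")
        cfg = config.to_dict()
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "versions": {"ssdcompare": __version__,
                         "python": sys.version.split()[0],
                         "numpy": np.__version__, "pandas": pd.__version__},
            "n_records_in": int(len(records)),
            "n_chemicals_retained": len(bundle.screen.retained),
        }
        with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        with open(outdir / "run_config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        bundle.outdir = outdir
    return bundle
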