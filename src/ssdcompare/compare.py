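"""Habitat-paired ratio analyses of SSD parameters.

For each chemical with a screened freshwater and saltwater SSD, the
comparison expresses the differences as fold ratios in concentration
units: means and HC5 values as 10 to the power of the log10-scale
difference, SDs as the direct quotient of the two log10-scale SDs.
A difference of d on the log10 scale is therefore a 10^d-fold ratio,
so "within 0.1–10" for means/HC5 corresponds to |Δlog10| ≤ 1 and
"within 0.25–4" for SDs to |Δlog10 SD ratio| ≤ log10(4) ≈ 0.6.

Two downstream analyses probe structure in the ratios: a Pearson
correlation of the minimum species count against the absolute log10
ratio (do data-poor chemicals disagree more?), and per-mode-of-action
one-sample t-tests of the log10 ratios against 0 (does a mechanistic
class shift systematically between habitats?).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .ssd import Z_HC5, InsufficientDataError

Parameter = Literal["mean", "sd", "hc5"]

_FOLD_COLUMNS = {
    "mean": "mean_fold_fw_sw",
    "sd": "sd_ratio_fw_sw",
    "hc5": "hc5_fold_fw_sw",
}


class PairingError(ValueError):
    """A chemical is missing one habitat's SSD fit."""


@dataclass
class RangeSummary:
    parameter: str
    range: tuple[float, float]
    fraction_within: float
    n_outside: int
    outside_ids: list[str]


def build_comparison(fits: pd.DataFrame) -> pd.DataFrame:
    """Pair each chemical's two fits into one row of fold ratios.

    Expects the fit table of :func:`ssdcompare.ssd.fit_all` (after
    screening). Output columns: freshwater-to-saltwater fold ratios of
    mean, SD and HC5, their saltwater-to-freshwater reciprocals, the
    minimum species count ``n_min``, and the mode of action.
    """
    rows = []
    for chem, grp in fits.groupby("chemical_id", sort=True):
        by_hab = {h: g for h, g in grp.groupby("habitat")}
        if set(by_hab) != {"freshwater", "saltwater"}:
            raise PairingError(
                f"chemical {chem!r} lacks a fit for "
                f"{sorted({'freshwater', 'saltwater'} - set(by_hab))}"
            )
        fw = by_hab["freshwater"].iloc[0]
        sw = by_hab["saltwater"].iloc[0]
        mean_fold = 10.0 ** (fw["mean_log10"] - sw["mean_log10"])
        sd_ratio = fw["sd_log10"] / sw["sd_log10"]
        hc5_fold = 10.0 ** (fw["hc5_log10"] - sw["hc5_log10"])
        rows.append({
            "chemical_id": chem,
            "mode_of_action": fw.get("mode_of_action", "unclassified"),
            "n_min": int(min(fw["n_species"], sw["n_species"])),
            "mean_fold_fw_sw": mean_fold,
            "sd_ratio_fw_sw": sd_ratio,
            "hc5_fold_fw_sw": hc5_fold,
            "mean_fold_sw_fw": 1.0 / mean_fold,
            "sd_ratio_sw_fw": 1.0 / sd_ratio,
            "hc5_fold_sw_fw": 1.0 / hc5_fold,
        })
    return pd.DataFrame(rows)


def fraction_within(
    rows: pd.DataFrame,
    parameter: Parameter,
    range: tuple[float, float],
) -> RangeSummary:
    """Fraction of chemicals whose fold ratio lies in the closed interval."""
    low, high = range
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got {range}")
    folds = rows[_FOLD_COLUMNS[parameter]]
    inside = (folds >= low) & (folds <= high)
    outside = rows.loc[~inside, "chemical_id"].tolist()
    return RangeSummary(
        parameter=parameter,
        range=(low, high),
        fraction_within=float(inside.mean()) if len(rows) else float("nan"),
        n_outside=len(outside),
        outside_ids=outside,
    )


def species_number_correlation(
    rows: pd.DataFrame, parameter: Parameter
) -> tuple[float, float, int]:
    """Pearson correlation of n_min with |log10 fold ratio|.

    Returns (r, two-sided p, n). A negative r means chemicals with more
    tested species have habitat ratios closer to 1.
    """
    if len(rows) < 3:
        raise InsufficientDataError(f"correlation needs >= 3 rows, got {len(rows)}")
    abs_log = np.abs(np.log10(rows[_FOLD_COLUMNS[parameter]].to_numpy(float)))
    n_min = rows["n_min"].to_numpy(float)
    if np.std(abs_log) == 0 or np.std(n_min) == 0:
        raise DegenerateRatioError("zero variance in ratios or species counts")
    res = stats.pearsonr(n_min, abs_log)
    return float(res.statistic), float(res.pvalue), len(rows)


class DegenerateRatioError(ValueError):
    """No variance to correlate or test."""


def moa_ratio_ttest(
    rows: pd.DataFrame,
    parameter: Parameter,
    moa_group: str,
) -> tuple[float, float, int, float]:
    """One-sample t-test: do the group's log10 ratios deviate from 0?

    Ratios are taken saltwater-to-freshwater (a mean below 0 means
    saltwater SSDs sit lower, i.e. saltwater species look more
    sensitive). Returns (mean log10 ratio, t, df, two-sided p).
    """
    grp = rows[rows["mode_of_action"] == moa_group]
    log_ratios = -np.log10(grp[_FOLD_COLUMNS[parameter]].to_numpy(float))
    if log_ratios.size < 2:
        raise InsufficientDataError(
            f"t-test needs >= 2 rows in group {moa_group!r}, got {log_ratios.size}"
        )
    if np.std(log_ratios) == 0:
        raise InsufficientDataError(f"zero variance of ratios in group {moa_group!r}")
    t, p = stats.ttest_1samp(log_ratios, 0.0)
    return float(np.mean(log_ratios)), float(t), log_ratios.size - 1, float(p)


def subset_min_species(rows: pd.DataFrame, k: int) -> pd.DataFrame:
    """Rows whose minimum species count is at least ``k``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return rows[rows["n_min"] >= k].copy()


def check_hc5_consistency(
    rows: pd.DataFrame, fits: pd.DataFrame, rtol: float = 1e-9
) -> bool:
    """Verify hc5_fold = mean_fold · 10^(−1.645·(sd_fw − sd_sw)) row-wise.

    An arithmetic identity of the HC5 definition; a violation indicates
    corrupted inputs rather than an interesting result.
    """
    sd = fits.pivot(index="chemical_id", columns="habitat", values="sd_log10")
    delta_sd = (sd["freshwater"] - sd["saltwater"]).reindex(rows["chemical_id"])
    implied = rows["mean_fold_fw_sw"].to_numpy() * 10.0 ** (-Z_HC5 * delta_sd.to_numpy())
    return bool(np.allclose(implied, rows["hc5_fold_fw_sw"].to_numpy(), rtol=rtol))
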