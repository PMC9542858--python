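"""Log-normal SSD fitting, HC5/HCx, and the normality screen.

An SSD here is a normal distribution fitted to the log10-transformed
species sensitivities of one chemical in one habitat. Its mean is the
arithmetic mean, its SD the sample SD (n−1 denominator). The hazardous
concentration for 5% of species is the plug-in 5th percentile

    HC5 = mean − 1.645 × SD          (log10 µg/L)

with the conventional rounded constant 1.645, kept literal so HC5
values match the standard formula digit-for-digit; other fractions use
the exact standard-normal quantile.

The normality screen runs a Shapiro–Wilk test on every fitted SSD and
applies Holm's step-down adjustment across the whole family of tests
(all candidate chemicals × both habitats by default); a chemical is
dropped whenever either of its habitats rejects normality at the
adjusted level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z_HC5 = 1.645  # rounded 5th-percentile standard-normal deviate


class InsufficientDataError(ValueError):
    """Too few observations for the requested estimate."""


class DegenerateFitError(ValueError):
    """All observations identical: the SSD SD is zero."""


@dataclass
class SSDFit:
    """A fitted log-normal SSD for one chemical × habitat."""

    chemical_id: str
    habitat: str
    n_species: int
    n_taxa_groups: int
    mean_log10: float
    sd_log10: float
    hc5_log10: float
    shapiro_p: float
    shapiro_p_holm: float | None = None


@dataclass
class ScreenResult:
    """Outcome of the family-wise normality screen."""

    retained: list[str]
    excluded: list[tuple[str, list[str], float, float]]  # (chem, habitats, min raw p, min adj p)
    alpha: float


def hcx(mean_log10: float, sd_log10: float, fraction: float = 0.05) -> float:
    """Hazardous concentration for a fraction of species, log10 µg/L.

    ``fraction`` = 0.05 gives HC5 using the literal 1.645; any other
    fraction in (0, 1) uses the exact normal quantile.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if sd_log10 < 0:
        raise ValueError("sd_log10 must be non-negative")
    z = -Z_HC5 if fraction == 0.05 else stats.norm.ppf(fraction)
    return mean_log10 + z * sd_log10


def shapiro_wilk(values: Sequence[float]) -> float:
    """Shapiro–Wilk normality p-value for 3 ≤ n ≤ 5000."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError(f"Shapiro–Wilk needs n >= 3, got {values.size}")
    if values.size > 5000:
        raise ValueError("Shapiro–Wilk is unreliable above n = 5000")
    return float(stats.shapiro(values).pvalue)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    p(i) (ascending) is multiplied by (m − i), a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def fit_ssd(
    values: Sequence[float],
    taxa: Sequence[str],
    chemical_id: str,
    habitat: str,
) -> SSDFit:
    """Fit the log-normal SSD to log10 sensitivities with taxa labels.

    ``shapiro_p`` is NaN outside the Shapiro–Wilk validity range
    3 ≤ n ≤ 5000; the eligibility criteria upstream normally guarantee
    n ≥ 5, and SSDs never approach the upper limit in practice.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"{chemical_id}/{habitat}: SSD needs >= 2 species, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{chemical_id}/{habitat}: non-finite sensitivity values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise DegenerateFitError(
            f"{chemical_id}/{habitat}: all sensitivities identical (SD = 0)"
        )
    shapiro_p = (shapiro_wilk(values) if 3 <= values.size <= 5000
                 else float("nan"))
    return SSDFit(
        chemical_id=chemical_id,
        habitat=habitat,
        n_species=int(values.size),
        n_taxa_groups=int(pd.unique(pd.Series(list(taxa))).size),
        mean_log10=mean,
        sd_log10=sd,
        hc5_log10=hcx(mean, sd, 0.05),
        shapiro_p=shapiro_p,
    )


def fit_all(sensitivities: pd.DataFrame) -> pd.DataFrame:
    """Fit one SSD per chemical × habitat from aggregated sensitivities.

    Returns a table with the SSDFit fields plus ``mode_of_action``
    carried through from the input (one row per chemical × habitat).
    """
    rows = []
    for (chem, habitat), grp in sensitivities.groupby(
        ["chemical_id", "habitat"], sort=True
    ):
        fit = fit_ssd(grp["log10_value"].to_numpy(),
                      grp["taxonomic_group"].tolist(), chem, habitat)
        row = vars(fit).copy()
        row["mode_of_action"] = grp["mode_of_action"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def normality_screen(
    fits: pd.DataFrame,
    alpha: float = 0.05,
    family: Literal["joint", "per-habitat"] = "joint",
) -> tuple[pd.DataFrame, ScreenResult]:
    """Apply the Shapiro–Wilk screen with Holm adjustment over the family.

    Parameters
    ----------
    fits : output of :func:`fit_all`; every chemical must appear with
        exactly one freshwater and one saltwater row.
    alpha : family-wise significance level.
    family : ``"joint"`` adjusts all 2 × n_chemicals p-values together;
        ``"per-habitat"`` adjusts each habitat's n_chemicals separately.

    Returns the fits with ``shapiro_p_holm`` filled in, and a
    :class:`ScreenResult` listing retained and excluded chemicals.
    """
    fits = fits.copy()
    per_chem = fits.groupby("chemical_id")["habitat"].agg(["size", "nunique"])
    bad = per_chem[(per_chem["size"] != 2) | (per_chem["nunique"] != 2)]
    if not bad.empty:
        raise ValueError(
            f"each chemical needs exactly one fit per habitat; offenders: "
            f"{bad.index.tolist()[:5]}"
        )
    if family == "joint":
        fits["shapiro_p_holm"] = holm_adjust(fits["shapiro_p"].to_numpy())
    elif family == "per-habitat":
        fits["shapiro_p_holm"] = np.nan
        for habitat, grp in fits.groupby("habitat"):
            fits.loc[grp.index, "shapiro_p_holm"] = holm_adjust(
                grp["shapiro_p"].to_numpy()
            )
    else:
        raise ValueError(f"unknown family mode {family!r}")

    retained: list[str] = []
    excluded: list[tuple[str, list[str], float, float]] = []
    for chem, grp in fits.groupby("chemical_id", sort=True):
        failing = grp[grp["shapiro_p_holm"] < alpha]
        if failing.empty:
            retained.append(chem)
        else:
            excluded.append((
                chem,
                sorted(failing["habitat"].tolist()),
                float(failing["shapiro_p"].min()),
                float(failing["shapiro_p_holm"].min()),
            ))
    return fits, ScreenResult(retained=retained, excluded=excluded, alpha=alpha)
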