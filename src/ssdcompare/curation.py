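"""Record selection and aggregation for SSD estimation.

The selection criteria applied here, in the order the pipeline runs them:

1. effect measure is EC50 or LC50 and the exposure is acute;
2. the effect concentration does not exceed ``factor`` (default 5)
   times the chemical's water solubility — records above that cap are
   implausible as truly dissolved exposures;
3. amphibian tests are dropped (saltwater amphibian data are absent, so
   they could never contribute to a habitat-paired comparison);
4. replicate tests of one (chemical, habitat, species) combination are
   collapsed to their geometric mean;
5. a chemical is a candidate only if, in *each* habitat separately, its
   aggregated data cover at least ``min_species`` species spanning at
   least ``min_taxa`` of the groups {algae, invertebrate, fish}.

All filters are row-local predicates, hence idempotent and
order-independent among themselves; each one appends an itemized stage
to the audit trail when one is supplied.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .records import AuditTrail

#: taxonomic groups that count toward the minimum-taxa requirement
COUNTED_TAXA = ("algae", "invertebrate", "fish")

DEFAULT_EFFECT_MEASURES = frozenset({"EC50", "LC50"})


class DataConsistencyError(ValueError):
    """A species carries conflicting taxonomic-group labels."""


def _row_ids(df: pd.DataFrame, mask: pd.Series, reason: str) -> list[tuple[str, str]]:
    return [(str(r), reason) for r in df.loc[mask, "row_id"]]


def filter_effect_measure(
    records: pd.DataFrame,
    allowed: Iterable[str] = DEFAULT_EFFECT_MEASURES,
    audit: AuditTrail | None = None,
) -> pd.DataFrame:
    """Keep acute records whose effect measure is in ``allowed``."""
    allowed = {m.upper() for m in allowed}
    bad_measure = ~records["effect_measure"].isin(allowed)
    chronic = records["exposure_type"] != "acute"
    keep = ~(bad_measure | chronic)
    if audit is not None:
        removed = (_row_ids(records, bad_measure, "effect_measure_not_allowed")
                   + _row_ids(records, chronic & ~bad_measure, "chronic_exposure"))
        audit.add_stage("effect_measure", len(records), int(keep.sum()), removed)
    return records[keep].copy()


def filter_solubility(
    records: pd.DataFrame,
    factor: float = 5.0,
    audit: AuditTrail | None = None,
) -> pd.DataFrame:
    """Drop records whose concentration exceeds ``factor`` × solubility.

    The boundary is inclusive on the keep side: a concentration exactly
    at the cap is retained. Records with unknown solubility are kept and
    tallied under ``solubility_unknown`` in the audit notes.
    """
    if not factor > 0:
        raise ValueError(f"factor must be > 0, got {factor}")
    sol = records["water_solubility"]
    over = sol.notna() & (records["concentration"] > factor * sol)
    keep = ~over
    if audit is not None:
        audit.add_stage(
            "solubility", len(records), int(keep.sum()),
            _row_ids(records, over, "exceeds_solubility_cap"),
            solubility_unknown=int(sol.isna().sum()), factor=factor,
        )
    return records[keep].copy()


def exclude_amphibians(
    records: pd.DataFrame, audit: AuditTrail | None = None
) -> pd.DataFrame:
    """Remove every amphibian test record."""
    amph = records["taxonomic_group"] == "amphibian"
    if audit is not None:
        audit.add_stage("amphibian", len(records), int((~amph).sum()),
                        _row_ids(records, amph, "amphibian"))
    return records[~amph].copy()


def aggregate_species_geomean(
    records: pd.DataFrame, audit: AuditTrail | None = None
) -> pd.DataFrame:
    """Collapse replicate tests to one sensitivity per (chemical, habitat, species).

    The species sensitivity is the geometric mean of its effect
    concentrations, stored as ``log10_value`` (log10 µg/L): the
    arithmetic mean of the log10 concentrations. ``n_tests`` counts the
    records aggregated. The taxonomic group and the chemical-level mode
    of action are carried through.

    Raises
    ------
    DataConsistencyError
        if one (chemical, habitat, species) key carries more than one
        taxonomic-group label.
    """
    if records.empty:
        out = pd.DataFrame(columns=["chemical_id", "habitat", "species_id",
                                    "taxonomic_group", "mode_of_action",
                                    "log10_value", "n_tests"])
        return out.astype({"log10_value": float, "n_tests": int})

    key = ["chemical_id", "habitat", "species_id"]
    taxa_per_key = records.groupby(key)["taxonomic_group"].nunique()
    if (taxa_per_key > 1).any():
        bad = taxa_per_key[taxa_per_key > 1].index.tolist()
        raise DataConsistencyError(
            f"conflicting taxonomic_group labels for: {bad[:5]}"
        )

    work = records.assign(_log10=np.log10(records["concentration"].to_numpy(float)))
    agg = (
        work.groupby(key, sort=True)
        .agg(taxonomic_group=("taxonomic_group", "first"),
             mode_of_action=("mode_of_action", "first"),
             log10_value=("_log10", "mean"),
             n_tests=("_log10", "size"))
        .reset_index()
    )
    if audit is not None:
        audit.add_stage("aggregate", len(records), len(records), [],
                        unit="records", species_out=len(agg))
    return agg


def select_chemicals(
    sensitivities: pd.DataFrame,
    min_species: int = 5,
    min_taxa: int = 2,
    audit: AuditTrail | None = None,
) -> list[str]:
    """Return the chemicals eligible for a habitat-paired SSD comparison.

    A chemical qualifies only if each of the two habitats independently
    has ≥ ``min_species`` aggregated species spanning ≥ ``min_taxa`` of
    the counted taxonomic groups. Amphibian rows, if any survived
    upstream, never count toward either requirement.
    """
    if min_species < 2:
        raise ValueError("min_species must be >= 2")
    if min_taxa not in (1, 2, 3):
        raise ValueError("min_taxa must be in {1, 2, 3}")

    counted = sensitivities[sensitivities["taxonomic_group"].isin(COUNTED_TAXA)]
    stats = (
        counted.groupby(["chemical_id", "habitat"])
        .agg(n_species=("species_id", "nunique"),
             n_taxa=("taxonomic_group", "nunique"))
    )
    eligible: list[str] = []
    removed: list[tuple[str, str]] = []
    for chem in sorted(sensitivities["chemical_id"].unique()):
        reasons = []
        for habitat in ("freshwater", "saltwater"):
            try:
                row = stats.loc[(chem, habitat)]
                n_sp, n_tx = int(row["n_species"]), int(row["n_taxa"])
            except KeyError:
                n_sp, n_tx = 0, 0
            if n_sp < min_species:
                reasons.append(f"{habitat} n={n_sp} < {min_species}")
            elif n_tx < min_taxa:
                reasons.append(f"{habitat} taxa={n_tx} < {min_taxa}")
        if reasons:
            removed.append((chem, "; ".join(reasons)))
        else:
            eligible.append(chem)
    if audit is not None:
        n_chem = sensitivities["chemical_id"].nunique()
        audit.add_stage("eligibility", n_chem, len(eligible), removed, unit="chemicals")
    return eligible
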