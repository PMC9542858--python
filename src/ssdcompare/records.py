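"""Data model and flat-table I/O for acute ecotoxicity test records.

A record table has one row per test result. The canonical in-memory
container is a :class:`pandas.DataFrame` with the columns listed in
:data:`CANONICAL_COLUMNS` plus a ``row_id`` column that preserves the
position of each row in the source file, so validation errors and audit
entries can point back at the offending line.

Concentrations are harmonized to µg/L on read (``unit_multiplier``),
because every downstream quantity — geometric means, SSD parameters,
HC5 folds — is only comparable across records in a single unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HABITATS = frozenset({"freshwater", "saltwater"})
TAXA = frozenset({"algae", "invertebrate", "fish", "amphibian"})
EXPOSURE_TYPES = frozenset({"acute", "chronic"})
MODES_OF_ACTION = frozenset({"narcotic", "specific", "unclassified"})

#: canonical record columns, in output order (``row_id`` is prepended on read)
CANONICAL_COLUMNS = (
    "chemical_id",
    "chemical_name",
    "species_id",
    "taxonomic_group",
    "habitat",
    "effect_measure",
    "exposure_type",
    "concentration",
    "water_solubility",
    "mode_of_action",
)

_HABITAT_ALIASES = {
    "freshwater": "freshwater", "fresh": "freshwater", "fw": "freshwater", "f": "freshwater",
    "saltwater": "saltwater", "salt": "saltwater", "sw": "saltwater", "s": "saltwater",
    "marine": "saltwater", "estuarine/marine": "saltwater",
}
_TAXON_ALIASES = {
    "algae": "algae", "alga": "algae", "algal": "algae",
    "invertebrate": "invertebrate", "invertebrates": "invertebrate", "invert": "invertebrate",
    "fish": "fish", "fishes": "fish",
    "amphibian": "amphibian", "amphibians": "amphibian", "amphibia": "amphibian",
}
_EXPOSURE_ALIASES = {"acute": "acute", "chronic": "chronic"}
_MOA_ALIASES = {
    "narcotic": "narcotic", "narcosis": "narcotic",
    "specific": "specific", "specifically acting": "specific",
    "specifically_acting": "specific", "specifically-acting": "specific",
    "unclassified": "unclassified", "unknown": "unclassified",
}


class SchemaError(ValueError):
    """A mapped column is missing from the input file."""


class ValidationError(ValueError):
    """One or more rows violate the record invariants.

    Attributes
    ----------
    problems : list of (row_id, field, message)
        Every offending row is itemized; parsing is total.
    """

    def __init__(self, problems: Sequence[tuple[int, str, str]]):
        self.problems = list(problems)
        lines = [f"row {r}: {f}: {m}" for r, f, m in self.problems]
        super().__init__(
            f"{len(self.problems)} invalid row(s):\n" + "\n".join(lines[:20])
            + ("" if len(lines) <= 20 else f"\n... and {len(lines) - 20} more")
        )


@dataclass(frozen=True)
class ToxicityRecord:
    """One raw acute test result.

    ``concentration`` and ``water_solubility`` are in µg/L;
    ``water_solubility`` may be ``None`` (unknown).
    """

    chemical_id: str
    species_id: str
    taxonomic_group: str
    habitat: str
    effect_measure: str
    exposure_type: str
    concentration: float
    chemical_name: str = ""
    water_solubility: float | None = None
    mode_of_action: str = "unclassified"

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.taxonomic_group not in TAXA:
            raise ValueError(f"unknown taxonomic group {self.taxonomic_group!r}")
        if self.exposure_type not in EXPOSURE_TYPES:
            raise ValueError(f"unknown exposure type {self.exposure_type!r}")
        if self.mode_of_action not in MODES_OF_ACTION:
            raise ValueError(f"unknown mode of action {self.mode_of_action!r}")
        if not (self.concentration > 0):
            raise ValueError(f"concentration must be > 0, got {self.concentration!r}")
        if self.water_solubility is not None and not (self.water_solubility > 0):
            raise ValueError(
                f"water_solubility must be > 0 when present, got {self.water_solubility!r}"
            )


def records_to_frame(records: Iterable[ToxicityRecord]) -> pd.DataFrame:
    """Assemble validated records into the canonical DataFrame layout."""
    rows = []
    for i, r in enumerate(records):
        d = {c: getattr(r, c) for c in CANONICAL_COLUMNS}
        d["row_id"] = i
        rows.append(d)
    df = pd.DataFrame(rows, columns=("row_id",) + CANONICAL_COLUMNS)
    if df.empty:
        df = df.astype({"concentration": float, "water_solubility": float, "row_id": int})
    return df


def _normalize_token(value, aliases: Mapping[str, str]) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return aliases.get(str(value).strip().lower())


def read_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    unit_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Read a record table from CSV, validate, and normalize enum tokens.

    Parameters
    ----------
    path : path to a UTF-8, header-row CSV (RFC-4180 quoting).
    column_map : maps *file* column names to canonical field names, e.g.
        ``{"CAS": "chemical_id", "Medium": "habitat"}``. Unmapped canonical
        names are looked up directly in the header. ``chemical_name``,
        ``water_solubility`` and ``mode_of_action`` are optional.
    unit_multiplier : factor applied to concentration and solubility to
        bring them to µg/L (e.g. 1000 for a file in mg/L).

    Returns
    -------
    DataFrame with ``row_id`` (1-based data-row number in the file) and
    the canonical columns; enum tokens normalized case-insensitively.

    Raises
    ------
    SchemaError
        if a required mapped column is absent.
    ValidationError
        itemizing every row with a non-positive/non-numeric concentration
        or an unrecognized enum token.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {src: dst for src, dst in column_map.items()}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise SchemaError(f"mapped column(s) not found in file: {', '.join(missing)}")
    raw = raw.rename(columns=rename)

    required = [c for c in CANONICAL_COLUMNS
                if c not in ("chemical_name", "water_solubility", "mode_of_action")]
    absent = [c for c in required if c not in raw.columns]
    if absent:
        raise SchemaError(f"required column(s) missing: {', '.join(absent)}")

    n = len(raw)
    out = pd.DataFrame(index=raw.index)
    out["row_id"] = np.arange(1, n + 1)
    problems: list[tuple[int, str, str]] = []

    def _rows(mask: pd.Series) -> list[int]:
        return list(out.loc[mask, "row_id"])

    for col in ("chemical_id", "species_id"):
        out[col] = raw[col].str.strip()
        for r in _rows(out[col] == ""):
            problems.append((r, col, "empty identifier"))
    out["chemical_name"] = raw["chemical_name"].str.strip() if "chemical_name" in raw else ""

    for col, aliases in (
        ("taxonomic_group", _TAXON_ALIASES),
        ("habitat", _HABITAT_ALIASES),
        ("exposure_type", _EXPOSURE_ALIASES),
    ):
        norm = raw[col].map(lambda v: _normalize_token(v, aliases))
        for r, bad in zip(_rows(norm.isna()), raw.loc[norm.isna(), col]):
            problems.append((r, col, f"unknown token {bad!r}"))
        out[col] = norm

    out["effect_measure"] = raw["effect_measure"].str.strip().str.upper()
    for r in _rows(out["effect_measure"] == ""):
        problems.append((r, "effect_measure", "empty token"))

    if "mode_of_action" in raw:
        moa = raw["mode_of_action"].replace({"": "unclassified", "NA": "unclassified"})
        norm = moa.map(lambda v: _normalize_token(v, _MOA_ALIASES))
        for r, bad in zip(_rows(norm.isna()), raw.loc[norm.isna(), "mode_of_action"]):
            problems.append((r, "mode_of_action", f"unknown token {bad!r}"))
        out["mode_of_action"] = norm
    else:
        out["mode_of_action"] = "unclassified"

    conc = pd.to_numeric(raw["concentration"].replace({"": None, "NA": None}), errors="coerce")
    for r, bad in zip(_rows(conc.isna()), raw.loc[conc.isna(), "concentration"]):
        problems.append((r, "concentration", f"missing or non-numeric value {bad!r}"))
    for r in _rows(conc <= 0):
        problems.append((r, "concentration", "must be > 0"))
    out["concentration"] = conc * unit_multiplier

    if "water_solubility" in raw:
        sol = pd.to_numeric(raw["water_solubility"].replace({"": None, "NA": None}),
                            errors="coerce")
        bad_sol = sol.notna() & (sol <= 0)
        for r in _rows(bad_sol):
            problems.append((r, "water_solubility", "must be > 0 when present"))
        # non-numeric garbage (not empty/NA) is also itemized
        garbage = sol.isna() & ~raw["water_solubility"].isin(["", "NA"])
        for r, bad in zip(_rows(garbage), raw.loc[garbage, "water_solubility"]):
            problems.append((r, "water_solubility", f"non-numeric value {bad!r}"))
        out["water_solubility"] = sol * unit_multiplier
    else:
        out["water_solubility"] = np.nan

    if problems:
        raise ValidationError(sorted(problems))
    return out[["row_id", *CANONICAL_COLUMNS]]


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as CSV: header row, full float precision,
    empty cells for missing values, rows in the order given."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False, na_rep="")


@dataclass
class AuditStage:
    """In/out record counts and itemized removals for one pipeline stage."""

    name: str
    n_in: int
    n_out: int
    removed: list[tuple[str, str]] = field(default_factory=list)  # (identifier, reason)
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError(f"stage {self.name}: records_out {self.n_out} > records_in {self.n_in}")
        if self.n_in - self.n_out != len(self.removed):
            raise ValueError(
                f"stage {self.name}: removal count {len(self.removed)} "
                f"inconsistent with in/out counts {self.n_in}/{self.n_out}"
            )


class AuditTrail:
    """Ordered log of filtering stages with telescoping counts."""

    def __init__(self) -> None:
        self.stages: list[AuditStage] = []

    def add_stage(self, name: str, n_in: int, n_out: int,
                  removed: Sequence[tuple[str, str]] = (), **notes) -> AuditStage:
        stage = AuditStage(name, n_in, n_out, list(removed), dict(notes))
        self.stages.append(stage)
        return stage

    @property
    def consistent(self) -> bool:
        """Counts telescope within each unit of accounting.

        Stages that change the unit (records -> species -> chemicals)
        start a new telescope; within a run of stages sharing a unit,
        each stage's input count must equal the previous output count.
        """
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.notes.get("unit", "records") == prev.notes.get("unit", "records"):
                if cur.n_in != prev.n_out:
                    return False
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": s.name, "records_in": s.n_in, "records_out": s.n_out,
              "n_removed": len(s.removed),
              "unit": s.notes.get("unit", "records")} for s in self.stages]
        )

    def write(self, path: str | Path) -> None:
        """Structured plain-text dump, one stage per block."""
        with open(path, "w", encoding="utf-8") as fh:
            for s in self.stages:
                fh.write(f"[{s.name}] in={s.n_in} out={s.n_out} "
                         f"removed={len(s.removed)}\n")
                for key, val in s.notes.items():
                    fh.write(f"  note {key}={val}\n")
                for ident, reason in s.removed:
                    fh.write(f"  - {ident}\t{reason}\n")
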