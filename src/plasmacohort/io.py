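"""Reading and writing the tabular formats the pipeline consumes and emits.

The precursor report is the long tab-separated dialect written by DIA-style
search engines (one row per run x precursor, columns ``Run``, ``Precursor.Id``,
``Protein.Group``, ``Proteotypic``, ``Precursor.Charge``, ``Missed.Cleavages``,
``Precursor.Quantity``).  Sample annotations are CSV; matrices round-trip as
wide TSV with the feature id in the first column; validation reports are JSON.
All text is UTF-8 with '.' decimal separators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AnalysisBundle,
    QuantMatrix,
    SchemaError,
    SAMPLE_ROLES,
    medications_from_string,
    medications_to_string,
    validate_sample_table,
)

__all__ = [
    "REPORT_COLUMNS",
    "read_precursor_report",
    "write_precursor_report",
    "read_sample_annotation",
    "write_sample_annotation",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "parse_atc_code",
    "truncate_atc",
    "validate_bundle",
]

REPORT_COLUMNS = {
    "run": "Run",
    "precursor": "Precursor.Id",
    "protein_group": "Protein.Group",
    "proteotypic": "Proteotypic",
    "charge": "Precursor.Charge",
    "missed_cleavages": "Missed.Cleavages",
    "quantity": "Precursor.Quantity",
}

# ATC grammar: level 1 (anatomical letter), level 2 (+2 digits), level 3
# (+letter), level 4 (+letter), level 5 (+2 digits).  Codes may be truncated
# at any complete level.
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


class IntegrityError(ValueError):
    """Duplicate keys or cross-table inconsistencies in input files."""


def parse_atc_code(code: str) -> str | None:
    """Return the normalized code if it matches the ATC grammar, else None."""
    code = str(code).strip().upper()
    return code if _ATC_RE.match(code) else None


def truncate_atc(code: str, level: int) -> str:
    """Truncate an ATC code to level 1, 2, 3, 4 or 5 (prefix lengths 1/3/4/5/7)."""
    lengths = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}
    if level not in lengths:
        raise ValueError(f"ATC level must be 1-5, got {level}")
    return code[: lengths[level]]


# ---------------------------------------------------------------------------
# precursor report
# ---------------------------------------------------------------------------

def read_precursor_report(path: str | Path) -> tuple[QuantMatrix, pd.DataFrame]:
    """Read a long precursor report and pivot it to a matrix + metadata table.

    Zero or negative quantities denote non-detection and are converted to
    missing values (counted in the matrix log).  Duplicate (run, precursor)
    rows raise :class:`IntegrityError`.
    """
    path = Path(path)
    long = pd.read_csv(path, sep="\t", dtype={REPORT_COLUMNS["run"]: str,
                                              REPORT_COLUMNS["precursor"]: str})
    missing_cols = [c for c in REPORT_COLUMNS.values() if c not in long.columns]
    if missing_cols:
        raise SchemaError(f"precursor report lacks mandatory columns: {missing_cols}")

    key = [REPORT_COLUMNS["run"], REPORT_COLUMNS["precursor"]]
    dup = long.duplicated(subset=key)
    if dup.any():
        offenders = long.loc[dup, key].head(5).to_records(index=False).tolist()
        raise IntegrityError(f"duplicate (run, precursor) entries: {offenders}")

    quantities = pd.to_numeric(long[REPORT_COLUMNS["quantity"]], errors="coerce")
    nonpositive = int(((quantities <= 0) & quantities.notna()).sum())
    quantities = quantities.where(quantities > 0)
    long = long.assign(_q=quantities)

    wide = long.pivot(index=REPORT_COLUMNS["precursor"],
                      columns=REPORT_COLUMNS["run"], values="_q")
    wide.index.name = "precursor_id"
    wide.columns.name = "run"

    meta = (
        long.drop_duplicates(REPORT_COLUMNS["precursor"])
        .set_index(REPORT_COLUMNS["precursor"])
        .rename_axis("precursor_id")
    )
    peptide = meta.index.to_series().str.replace(r"\d+$", "", regex=True)
    meta = pd.DataFrame({
        "protein_group": meta[REPORT_COLUMNS["protein_group"]],
        "proteotypic": meta[REPORT_COLUMNS["proteotypic"]].astype(int).astype(bool),
        "charge": meta[REPORT_COLUMNS["charge"]].astype(int),
        "missed_cleavages": meta[REPORT_COLUMNS["missed_cleavages"]].astype(int),
        "peptide_length": peptide.str.len(),
    }).loc[wide.index]

    quant = QuantMatrix(
        data=wide, scale="linear", level="precursor",
        log={"source": str(path), "nonpositive_set_missing": nonpositive,
             "rows_read": int(len(long))},
    )
    return quant, meta


def write_precursor_report(path: str | Path, quant: QuantMatrix,
                           meta: pd.DataFrame) -> None:
    """Write a precursor matrix back to the long report dialect.

    Missing entries produce no row, so read/write round-trips conserve the
    set of observed entries.
    """
    quant.require(scale="linear", level="precursor")
    long = (
        quant.data.stack()
        .rename(REPORT_COLUMNS["quantity"])
        .reset_index()
        .rename(columns={"precursor_id": REPORT_COLUMNS["precursor"],
                         "run": REPORT_COLUMNS["run"]})
    )
    m = meta.loc[long[REPORT_COLUMNS["precursor"]]]
    long[REPORT_COLUMNS["protein_group"]] = m["protein_group"].to_numpy()
    long[REPORT_COLUMNS["proteotypic"]] = m["proteotypic"].astype(int).to_numpy()
    long[REPORT_COLUMNS["charge"]] = m["charge"].to_numpy()
    long[REPORT_COLUMNS["missed_cleavages"]] = m["missed_cleavages"].to_numpy()
    long = long[[REPORT_COLUMNS[k] for k in
                 ("run", "precursor", "protein_group", "proteotypic",
                  "charge", "missed_cleavages", "quantity")]]
    long.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-sample annotation CSV.

    Roles are normalized case-insensitively against the closed vocabulary;
    medication strings are parsed to ``[(atc_code, regular_flag), ...]`` with
    malformed ATC codes dropped (row retained) and recorded in
    ``table.attrs["warnings"]``.
    """
    table = pd.read_csv(path, dtype={"run": str, "plate": str, "well": str,
                                     "ms_batch": str})
    if "run" not in table.columns:
        raise SchemaError("sample annotation lacks a 'run' column")
    table = table.set_index("run")

    roles = table["role"].astype(str).str.strip().str.lower()
    known = {r.lower(): r for r in SAMPLE_ROLES}
    bad = sorted(set(roles) - set(known))
    if bad:
        raise SchemaError(f"unknown sample role values: {bad}")
    table["role"] = roles.map(known)

    for col, kind in (("age", float), ("bmi", float)):
        if col in table.columns:
            try:
                table[col] = pd.to_numeric(table[col])
            except (ValueError, TypeError) as exc:
                bad_rows = [i for i, v in enumerate(table[col])
                            if pd.notna(v) and not str(v).replace(".", "", 1)
                            .lstrip("-").isdigit()]
                raise SchemaError(
                    f"non-numeric {col} at row(s) {bad_rows[:5]}") from exc

    warnings: list[str] = []
    meds_parsed = []
    for run, raw in table.get("medications", pd.Series("", index=table.index)).items():
        parsed = []
        for code, flag in medications_from_string(raw if isinstance(raw, str) else ""):
            normalized = parse_atc_code(code)
            if normalized is None:
                warnings.append(f"{run}: dropped malformed ATC code {code!r}")
            else:
                parsed.append((normalized, flag))
        meds_parsed.append(parsed)
    table["medications"] = meds_parsed

    for col in ("sex", "age", "bmi", "hcu_history", "well"):
        if col not in table.columns:
            table[col] = pd.NA
    for col in ("fasting", "pregnant", "ever_pregnant"):
        if col not in table.columns:
            table[col] = pd.NA
        table[col] = pd.to_numeric(table[col], errors="coerce").astype("Int64")

    table.attrs["warnings"] = warnings
    validate_sample_table(table)
    return table


def write_sample_annotation(path: str | Path, samples: pd.DataFrame) -> None:
    out = samples.copy()
    out["medications"] = [medications_to_string(m) for m in out["medications"]]
    out.to_csv(path, index_label="run", float_format="%.17g")


# ---------------------------------------------------------------------------
# wide matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(path: str | Path, quant: QuantMatrix) -> None:
    quant.data.to_csv(path, sep="\t", index_label=quant.data.index.name or "feature",
                      float_format="%.17g")


def read_matrix_tsv(path: str | Path, scale: str, level: str) -> QuantMatrix:
    data = pd.read_csv(path, sep="\t", index_col=0)
    return QuantMatrix(data=data, scale=scale, level=level,
                       log={"source": str(path)})


# ---------------------------------------------------------------------------
# bundle validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    kind: str
    detail: str

    def as_dict(self) -> dict[str, str]:
        return {"kind": self.kind, "detail": self.detail}


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def as_dict(self) -> dict:
        return {"ok": self.ok,
                "violations": [v.as_dict() for v in self.violations]}


def validate_bundle(bundle: AnalysisBundle,
                    require_pools: bool = True) -> ValidationReport:
    """Cross-check matrix/annotation consistency; report-only, never raises.

    An empty violation list means the bundle is usable by the downstream
    preprocessing and association stages.
    """
    report = ValidationReport()
    add = lambda kind, detail: report.violations.append(Violation(kind, detail))

    runs_matrix = set(map(str, bundle.quant.samples))
    runs_table = set(map(str, bundle.samples.index))
    for run in sorted(runs_matrix - runs_table):
        add("orphan run", f"run {run} in matrix but not in sample table")
    for run in sorted(runs_table - runs_matrix):
        add("unquantified sample", f"run {run} annotated but absent from matrix")

    if bundle.quant.level == "precursor":
        missing_meta = bundle.quant.features.difference(bundle.meta.index)
        for pre in missing_meta[:20]:
            add("missing precursor meta", f"precursor {pre} has no meta record")

    study = bundle.samples[bundle.samples["role"] == "study"]
    for covariate in ("sex", "age", "bmi", "fasting"):
        bad = study.index[study[covariate].isna()]
        for run in bad:
            add("missing covariate", f"missing covariate: {covariate} for {run}")

    if require_pools:
        by_plate = bundle.samples.groupby("plate")["role"]
        for plate, roles in by_plate:
            if (roles == "pool").sum() == 0:
                add("no pool on plate",
                    f"plate {plate} has no pool sample; CV anchoring unavailable")

    if bundle.clinical is not None:
        shared = set(bundle.clinical.columns) & runs_table
        if not shared:
            add("clinical mismatch", "clinical table shares no runs with annotation")
    return report
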