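"""Core in-memory containers shared by every stage of the pipeline.

The package moves three tables through its stages:

``QuantMatrix``
    A rectangular quantity grid, features (peptide precursors or protein
    groups) by samples, carried as a pandas DataFrame in which ``NaN`` marks
    a missing (non-detected) quantity.  The matrix knows its scale (``linear``
    raw quantities vs ``log2``) and its level (``precursor`` vs ``protein``).

Precursor metadata and the sample annotation are plain DataFrames with a
documented schema; :func:`validate_precursor_meta` and
:func:`validate_sample_table` enforce it.  ``AnalysisBundle`` ties the three
together with an optional clinical-assay table and the simulation ground
truth when the bundle came from the generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

SAMPLE_ROLES = ("study", "pool", "blank", "commercial_serum", "commercial_plasma")

#: Columns every sample annotation table must carry.  Covariate columns may be
#: NA for non-study roles.
SAMPLE_COLUMNS = (
    "role",
    "plate",
    "well",
    "ms_batch",
    "sex",
    "age",
    "bmi",
    "fasting",
    "pregnant",
    "ever_pregnant",
    "hcu_history",
    "medications",
)

HCU_HISTORY_LEVELS = ("current", "previous", "never", "unknown")

PRECURSOR_META_COLUMNS = (
    "protein_group",
    "proteotypic",
    "charge",
    "missed_cleavages",
    "peptide_length",
)


class SchemaError(ValueError):
    """A table does not conform to its documented schema."""


class StateError(RuntimeError):
    """A pipeline operation was called on a matrix in the wrong state."""


@dataclass
class QuantMatrix:
    """Feature x sample quantity grid with an explicit scale and level.

    Parameters
    ----------
    data:
        DataFrame, rows indexed by feature id, columns by sample run id.
        ``NaN`` encodes a missing value.
    scale:
        ``"linear"`` (raw, strictly positive quantities) or ``"log2"``.
    level:
        ``"precursor"`` or ``"protein"``.
    log:
        Free-form provenance dict appended to by processing steps.
    """

    data: pd.DataFrame
    scale: str = "linear"
    level: str = "precursor"
    log: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.level not in ("precursor", "protein"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][:5].tolist()
            raise SchemaError(f"duplicate feature ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][:5].tolist()
            raise SchemaError(f"duplicate sample ids: {dup}")
        values = self.data.to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        if observed.size and not np.all(np.isfinite(observed)):
            raise SchemaError("observed quantities must be finite")
        if self.scale == "linear" and observed.size and np.any(observed <= 0):
            raise SchemaError("linear-scale quantities must be positive")

    # -- convenience -------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    @property
    def fully_observed(self) -> bool:
        return self.n_missing == 0

    def copy(self, **updates: Any) -> "QuantMatrix":
        """Shallow-configured deep-data copy, optionally overriding fields."""
        out = QuantMatrix(
            data=self.data.copy(),
            scale=self.scale,
            level=self.level,
            log=dict(self.log),
        )
        for key, value in updates.items():
            setattr(out, key, value)
        return out

    def require(self, *, scale: str | None = None, level: str | None = None,
                fully_observed: bool | None = None) -> None:
        """Raise :class:`StateError` unless the matrix is in the given state.

        Used by processing steps to enforce the fixed pipeline order
        (filter -> impute -> log2 -> normalize -> plate-correct -> summarize).
        """
        if scale is not None and self.scale != scale:
            raise StateError(f"expected {scale}-scale matrix, got {self.scale}")
        if level is not None and self.level != level:
            raise StateError(f"expected {level}-level matrix, got {self.level}")
        if fully_observed and not self.fully_observed:
            raise StateError(
                f"expected a fully observed matrix, {self.n_missing} entries missing"
            )


def validate_precursor_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the precursor metadata schema; returns the table unchanged."""
    missing = [c for c in PRECURSOR_META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"precursor meta lacks columns: {missing}")
    if meta.index.has_duplicates:
        raise SchemaError("duplicate precursor ids in meta")
    if (meta["charge"] < 1).any():
        raise SchemaError("precursor charge must be >= 1")
    if (meta["missed_cleavages"] < 0).any():
        raise SchemaError("missed cleavages must be >= 0")
    return meta


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample annotation schema; returns the table unchanged."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise SchemaError(f"sample table lacks columns: {missing}")
    if samples.index.has_duplicates:
        raise SchemaError("duplicate run ids in sample table")
    bad_roles = set(samples["role"]) - set(SAMPLE_ROLES)
    if bad_roles:
        raise SchemaError(f"unknown sample roles: {sorted(bad_roles)}")
    study = samples[samples["role"] == "study"]
    ages = study["age"].dropna()
    if (ages < 18).any():
        raise SchemaError("study participant age must be >= 18")
    fasting = study["fasting"].dropna()
    if not set(fasting.astype(int)) <= {0, 1}:
        raise SchemaError("fasting flag must be 0/1")
    if samples["plate"].isna().any() or (samples["plate"].astype(str) == "").any():
        raise SchemaError("plate ids must be non-empty")
    if samples["ms_batch"].isna().any():
        raise SchemaError("ms_batch ids must be non-empty")
    return samples


def study_samples(samples: pd.DataFrame) -> pd.DataFrame:
    return samples[samples["role"] == "study"]


@dataclass
class AnalysisBundle:
    """Quantity matrix + precursor metadata + sample annotation.

    ``clinical`` optionally carries a protein x sample table of clinical
    chemistry assay values for concordance checks; ``ground_truth`` is present
    only on simulated bundles.
    """

    quant: QuantMatrix
    meta: pd.DataFrame
    samples: pd.DataFrame
    clinical: pd.DataFrame | None = None
    ground_truth: Any = None

    def copy(self) -> "AnalysisBundle":
        return AnalysisBundle(
            quant=self.quant.copy(),
            meta=self.meta.copy(),
            samples=self.samples.copy(),
            clinical=None if self.clinical is None else self.clinical.copy(),
            ground_truth=self.ground_truth,
        )


def medications_to_string(meds: list[tuple[str, int]]) -> str:
    """Serialize [(atc_code, regular_flag), ...] to ``"A10BA02:1;C07AB02:0"``."""
    return ";".join(f"{code}:{int(flag)}" for code, flag in meds)


def medications_from_string(text: str) -> list[tuple[str, int]]:
    """Inverse of :func:`medications_to_string`; tolerates bare codes (regular=1)."""
    if not isinstance(text, str) or not text.strip():
        return []
    meds: list[tuple[str, int]] = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            code, flag = token.rsplit(":", 1)
            meds.append((code.strip(), int(flag)))
        else:
            meds.append((token, 1))
    return meds


def dataclass_to_dict(obj: Any) -> Any:
    """JSON-friendly view of (possibly nested) dataclasses / arrays."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: dataclass_to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): dataclass_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [dataclass_to_dict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
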