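"""Sample-level quality control and the CV metrics anchoring significance.

Two responsibilities:

* flag degraded runs from four acquisition health metrics (detected-precursor
  count, mean peptide length, mean charge, missed-cleavage rate) via robust
  z-scores, and
* compute per-protein coefficients of variation over pooled-QC wells
  (technical variance) and study wells (technical + biological), whose ratio
  — the relative CV — ranks how much biology a protein carries, and whose
  pool value anchors the dual significance rule used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QuantMatrix

__all__ = [
    "compute_cv",
    "cv_table",
    "sample_qc_metrics",
    "flag_outlier_samples",
    "assay_concordance",
    "OutlierReport",
]

QC_METRICS = ("n_detected_precursors", "mean_peptide_length", "mean_charge",
              "missed_cleavage_rate")


class UndefinedCVError(ValueError):
    pass


def compute_cv(values) -> float:
    """Coefficient of variation, percent: 100 * sd / mean (n-1 denominator).

    Defined for >= 2 observed linear-scale values with positive mean.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < 2:
        raise UndefinedCVError("CV needs at least 2 observed values")
    mean = arr.mean()
    if mean <= 0:
        raise UndefinedCVError("CV undefined for nonpositive mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def cv_table(protein_matrix: QuantMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-protein pool CV, study CV and relative CV (study / pool).

    CVs are computed on linear-scale abundances; a log2 matrix is
    back-transformed first.  Pool wells from all plates are pooled into one
    technical-CV estimate.  ``relative_cv`` is NaN where the pool CV is zero.
    """
    protein_matrix.require(level="protein")
    values = protein_matrix.values
    if protein_matrix.scale == "log2":
        values = 2.0 ** values

    roles = samples.reindex(protein_matrix.samples)["role"]
    pool_cols = (roles == "pool").to_numpy()
    study_cols = (roles == "study").to_numpy()
    if pool_cols.sum() == 0:
        raise UndefinedCVError(
            "no pool samples present: the CV-anchored significance rule "
            "cannot run without pooled QC wells")
    if study_cols.sum() == 0:
        raise UndefinedCVError("no study samples present")

    def _cv_block(block: np.ndarray) -> np.ndarray:
        n = np.sum(~np.isnan(block), axis=1)
        mean = np.nanmean(block, axis=1)
        sd = np.nanstd(block, axis=1, ddof=1)
        out = 100.0 * sd / mean
        out[(n < 2) | (mean <= 0)] = np.nan
        return out

    cv_pool = _cv_block(values[:, pool_cols])
    cv_study = _cv_block(values[:, study_cols])
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(cv_pool > 0, cv_study / cv_pool, np.nan)
    return pd.DataFrame(
        {"cv_pool": cv_pool, "cv_study": cv_study, "relative_cv": relative},
        index=protein_matrix.features,
    )


def sample_qc_metrics(quant: QuantMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample acquisition health metrics over the observed precursors.

    A sample observing zero precursors gets count 0 and NaN for the
    composition metrics (degenerate, but never dropped).
    """
    quant.require(level="precursor")
    observed = ~np.isnan(quant.values)
    meta = meta.loc[quant.features]
    length = meta["peptide_length"].to_numpy(dtype=float)
    charge = meta["charge"].to_numpy(dtype=float)
    missed = (meta["missed_cleavages"].to_numpy(dtype=float) >= 1).astype(float)

    n_det = observed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_len = (observed * length[:, None]).sum(axis=0) / n_det
        mean_charge = (observed * charge[:, None]).sum(axis=0) / n_det
        mc_rate = (observed * missed[:, None]).sum(axis=0) / n_det
    zero = n_det == 0
    for arr in (mean_len, mean_charge, mc_rate):
        arr[zero] = np.nan
    return pd.DataFrame(
        {"n_detected_precursors": n_det.astype(int),
         "mean_peptide_length": mean_len,
         "mean_charge": mean_charge,
         "missed_cleavage_rate": mc_rate},
        index=quant.samples,
    )


@dataclass
class OutlierReport:
    """Robust z-scores per metric plus the flag decision for every sample."""

    zscores: pd.DataFrame
    flagged: pd.Series
    reasons: dict[str, list[str]] = field(default_factory=dict)
    skipped_metrics: list[str] = field(default_factory=list)

    @property
    def flagged_ids(self) -> list[str]:
        return list(self.flagged.index[self.flagged])

    def as_frame(self) -> pd.DataFrame:
        out = self.zscores.add_prefix("z_")
        out["flagged"] = self.flagged
        out["reasons"] = [";".join(self.reasons.get(i, [])) for i in out.index]
        return out


def flag_outlier_samples(metrics: pd.DataFrame, samples: pd.DataFrame,
                         z_threshold: float = 5.0) -> OutlierReport:
    """Flag study samples whose robust z exceeds the threshold on any metric.

    Robust z = (x - median) / (1.4826 * MAD), with median and MAD taken over
    study-role samples only; pools, blanks and commercial references are never
    flagged.  Metrics with zero MAD are skipped with a warning entry.
    """
    roles = samples.reindex(metrics.index)["role"]
    study = metrics.index[(roles == "study").to_numpy()]
    if len(study) < 10:
        raise ValueError("need >= 10 study samples for stable robust medians")

    z = pd.DataFrame(np.nan, index=metrics.index, columns=list(QC_METRICS))
    skipped: list[str] = []
    for metric in QC_METRICS:
        x = metrics.loc[study, metric].astype(float)
        med = x.median()
        mad = float((x - med).abs().median())
        if mad == 0 or np.isnan(mad):
            skipped.append(metric)
            continue
        z[metric] = (metrics[metric].astype(float) - med) / (1.4826 * mad)

    exceeds = z.abs() > z_threshold
    is_study = roles.reindex(metrics.index) == "study"
    flagged = exceeds.any(axis=1) & is_study.to_numpy()
    reasons = {
        str(idx): [m for m in QC_METRICS if bool(exceeds.loc[idx, m])]
        for idx in metrics.index[flagged]
    }
    return OutlierReport(zscores=z, flagged=flagged, reasons=reasons,
                         skipped_metrics=skipped)


def assay_concordance(protein_matrix: QuantMatrix, clinical: pd.DataFrame,
                      pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Spearman rho between protein abundances and clinical assay values.

    ``pairs`` lists (protein_id, assay_id); correlation is pairwise-complete
    over shared samples and requires >= 3 paired observations.  Constant
    vectors yield NaN with an ``undefined`` flag.
    """
    shared = protein_matrix.samples.intersection(clinical.columns)
    rows = []
    for protein, assay in pairs:
        x = protein_matrix.data.loc[protein, shared].astype(float)
        y = clinical.loc[assay, shared].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3:
            raise ValueError(
                f"pair ({protein}, {assay}) has only {n} paired observations")
        if x[ok].nunique() < 2 or y[ok].nunique() < 2:
            rows.append({"protein": protein, "assay": assay, "n": n,
                         "rho": np.nan, "p": np.nan, "undefined": True})
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"protein": protein, "assay": assay, "n": n,
                     "rho": float(rho), "p": float(p), "undefined": False})
    return pd.DataFrame(rows)
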