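"""Precursor-to-protein processing chain.

Fixed stage order, enforced at run time:

1. drop precursors with too many missing values among study samples,
2. k-nearest-neighbor imputation within each MS batch (neighbors are
   precursor rows),
3. log2 transform,
4. cyclic loess normalization ("fast" variant against a mean reference),
5. plate-effect removal by per-row least squares on plate indicators,
6. Tukey median-polish summarization of proteotypic precursors to protein
   profiles.

Each step consumes and returns a :class:`~plasmacohort.containers.QuantMatrix`
and records its bookkeeping (dropped precursors, imputed entries, dropped
proteins) in the matrix log, so an end-to-end run can report the same
precursor/protein accounting a study would publish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import QuantMatrix, StateError

__all__ = [
    "PreprocessParams",
    "filter_missing_precursors",
    "knn_impute",
    "log2_transform",
    "cyclic_loess_normalize",
    "remove_plate_effects",
    "median_polish",
    "median_polish_summarize",
    "run_preprocess",
]


@dataclass
class PreprocessParams:
    max_missing_frac: float = 0.40   # strict ">" exclusion over study samples
    knn_k: int = 9
    knn_row_missing_cap: float = 0.5  # above this, fall back to row means
    loess_span: float = 0.7
    loess_iterations: int = 3
    polish_tol: float = 1e-6         # absolute log2 units
    polish_max_iter: int = 50

    def validate(self) -> None:
        for name in ("max_missing_frac", "knn_row_missing_cap", "loess_span"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("knn_k", "loess_iterations", "polish_max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _check_stage(quant: QuantMatrix, op: str, allowed: set[str | None]) -> None:
    stage = quant.log.get("stage")
    if stage not in allowed:
        raise StateError(
            f"{op} cannot run on a matrix in stage {stage!r}; the pipeline "
            "order is filter -> impute -> log2 -> normalize -> plate-correct "
            "-> summarize")


# ---------------------------------------------------------------------------
# 1. missingness filter
# ---------------------------------------------------------------------------

def filter_missing_precursors(quant: QuantMatrix, samples: pd.DataFrame,
                              max_missing_frac: float = 0.40) -> QuantMatrix:
    """Drop precursors missing in strictly more than ``max_missing_frac`` of
    study samples.  Missingness in pools, blanks and commercial references is
    ignored by this rule."""
    quant.require(level="precursor")
    _check_stage(quant, "filter_missing_precursors", {None, "raw"})
    roles = samples.reindex(quant.samples)["role"]
    study = (roles == "study").to_numpy()
    if study.sum() == 0:
        raise ValueError("no study samples: missingness filter undefined")
    frac = np.isnan(quant.values[:, study]).mean(axis=1)
    keep = frac <= max_missing_frac
    out = quant.copy()
    out.data = out.data.loc[keep]
    out.log["stage"] = "filtered"
    out.log["precursors_before_filter"] = int(len(quant.features))
    out.log["precursors_after_filter"] = int(keep.sum())
    return out


# ---------------------------------------------------------------------------
# 2. kNN imputation per MS batch
# ---------------------------------------------------------------------------

def knn_impute(quant: QuantMatrix, samples: pd.DataFrame,
               k: int = 9, row_missing_cap: float = 0.5) -> QuantMatrix:
    """Impute missing entries per MS batch with k-nearest precursor rows.

    For a missing entry (precursor p, sample s), the k precursor rows closest
    to p in Euclidean distance (over the batch columns where both rows are
    observed, NaN-rescaled) and themselves observed at s are averaged at s.
    Rows missing in more than ``row_missing_cap`` of a batch's columns fall
    back to the row's within-batch mean, then the row's global mean, then the
    batch grand mean.  The output has no missing entries.
    """
    quant.require()
    _check_stage(quant, "knn_impute", {None, "raw", "filtered"})
    out = quant.copy()
    data = out.data.to_numpy(dtype=float)
    batches = samples.reindex(quant.samples)["ms_batch"]
    row_global_mean = np.nanmean(data, axis=1)
    n_imputed = 0

    for batch in pd.unique(batches):
        cols = np.nonzero((batches == batch).to_numpy())[0]
        block = data[:, cols]
        if block.shape[0] < k + 1:
            raise ValueError(
                f"batch {batch!r} has {block.shape[0]} precursor rows, fewer "
                f"than k+1={k + 1}; reduce k")
        miss = np.isnan(block)
        if not miss.any():
            continue
        row_frac = miss.mean(axis=1)
        batch_row_mean = np.where(row_frac < 1.0,
                                  np.nanmean(np.where(miss, np.nan, block), axis=1),
                                  np.nan)
        grand = np.nanmean(block)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dist = nan_euclidean_distances(block)
        np.fill_diagonal(dist, np.inf)

        fallback_rows = row_frac > row_missing_cap
        for p in np.nonzero(miss.any(axis=1))[0]:
            targets = np.nonzero(miss[p])[0]
            if fallback_rows[p]:
                fill = batch_row_mean[p]
                if np.isnan(fill):
                    fill = row_global_mean[p]
                if np.isnan(fill):
                    fill = grand
                block[p, targets] = fill
                n_imputed += len(targets)
                continue
            for s in targets:
                donors = np.nonzero(~miss[:, s] & np.isfinite(dist[:, p]))[0]
                if donors.size == 0:
                    block[p, s] = batch_row_mean[p] if np.isfinite(
                        batch_row_mean[p]) else grand
                else:
                    nearest = donors[np.argsort(dist[donors, p],
                                                kind="stable")[:k]]
                    block[p, s] = block[nearest, s].mean()
                n_imputed += 1
        data[:, cols] = np.where(miss, block, data[:, cols])

    out.data = pd.DataFrame(data, index=quant.features, columns=quant.samples)
    out.log["stage"] = "imputed"
    out.log["imputed_entries"] = int(n_imputed)
    return out


def column_mean_impute(quant: QuantMatrix) -> QuantMatrix:
    """Baseline imputation: replace each missing entry by its sample's mean."""
    out = quant.copy()
    data = out.data.to_numpy(dtype=float)
    col_mean = np.nanmean(data, axis=0)
    miss = np.isnan(data)
    data[miss] = np.broadcast_to(col_mean, data.shape)[miss]
    out.data = pd.DataFrame(data, index=quant.features, columns=quant.samples)
    out.log["stage"] = "imputed"
    return out


# ---------------------------------------------------------------------------
# 3. log2
# ---------------------------------------------------------------------------

def log2_transform(quant: QuantMatrix) -> QuantMatrix:
    quant.require(scale="linear")
    values = quant.values
    if np.nanmin(values) <= 0:
        raise ValueError("nonpositive quantity: cannot log2 transform")
    out = quant.copy()
    out.data = np.log2(out.data)
    out.scale = "log2"
    if out.log.get("stage") == "imputed":
        out.log["stage"] = "log2"
    return out


# ---------------------------------------------------------------------------
# 4. cyclic loess ("fast")
# ---------------------------------------------------------------------------

def _group_adjusted_trend(m: np.ndarray, a: np.ndarray, groups: np.ndarray,
                          span: float, delta: float,
                          n_backfit: int = 4) -> np.ndarray:
    """M-vs-A loess trend fitted jointly with per-group (protein) offsets.

    A technical trend is a function of A only, while regulation and biology
    shift all precursors of one protein together regardless of their A
    positions.  Backfitting the additive model M = trend(A) + offset[group]
    (offsets centered so the sample-level shift stays in the trend) therefore
    attributes protein-coherent shifts to the offsets and returns a trend
    that is unbiased even when a large fraction of a small panel is
    genuinely regulated.  Only the trend is subtracted by the caller.
    """
    n_groups = int(groups.max()) + 1
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    offsets = np.zeros(n_groups)
    fitted = np.zeros_like(m)
    for _ in range(n_backfit):
        fitted = lowess(m - offsets[groups], a, frac=span, it=0, delta=delta,
                        return_sorted=False)
        resid = m - fitted
        offsets = np.bincount(groups, weights=resid,
                              minlength=n_groups) / counts
        # center on the median protein offset: a true sample-loading shift
        # moves every protein and survives the centering into the trend,
        # while a net shift carried by a regulated minority does not
        offsets -= np.median(offsets)
    return fitted


def cyclic_loess_normalize(quant: QuantMatrix, span: float = 0.7,
                           iterations: int = 3,
                           feature_groups: pd.Series | None = None) -> QuantMatrix:
    """Fast cyclic loess: each sample is loess-normalized against the rowwise
    mean reference on the M (difference) vs A (average) scale; the reference
    is recomputed every iteration.

    ``feature_groups`` (feature id -> protein group) enables the
    protein-adjusted trend fit, which keeps genuine protein-level regulation
    from dragging the curve and biasing unregulated features — material when
    the regulated fraction of a small panel is large.
    """
    quant.require(scale="log2", fully_observed=True)
    _check_stage(quant, "cyclic_loess_normalize", {None, "log2"})
    data = quant.values.copy()
    if data.shape[0] < 30:
        warnings.warn("cyclic loess on fewer than 30 features is unstable",
                      stacklevel=2)
    groups = None
    if feature_groups is not None:
        codes = pd.Categorical(feature_groups.reindex(quant.features)).codes
        if (codes >= 0).all():
            groups = codes.astype(int)
    for _ in range(iterations):
        reference = data.mean(axis=1)
        for j in range(data.shape[1]):
            a = 0.5 * (data[:, j] + reference)
            m = data[:, j] - reference
            delta = 0.02 * (a.max() - a.min())
            if groups is None:
                fitted = lowess(m, a, frac=span, it=0, delta=delta,
                                return_sorted=False)
            else:
                fitted = _group_adjusted_trend(m, a, groups, span, delta)
            data[:, j] -= fitted
    out = quant.copy()
    out.data = pd.DataFrame(data, index=quant.features, columns=quant.samples)
    out.log["stage"] = "normalized"
    return out


# ---------------------------------------------------------------------------
# 5. plate-effect removal
# ---------------------------------------------------------------------------

def remove_plate_effects(quant: QuantMatrix, samples: pd.DataFrame) -> QuantMatrix:
    """Subtract per-row least-squares plate effects (sum-to-zero contrasts).

    Row grand means are preserved exactly.  With a single plate the matrix is
    returned unchanged; single-sample plates are noted as unstable in the log
    but still corrected.
    """
    quant.require(scale="log2", fully_observed=True)
    _check_stage(quant, "remove_plate_effects", {None, "log2", "normalized"})
    plates = samples.reindex(quant.samples)["plate"]
    levels = pd.unique(plates)
    out = quant.copy()
    if len(levels) < 2:
        out.log["stage"] = "plate_corrected"
        out.log["plate_correction"] = "single plate: no-op"
        return out

    counts = plates.value_counts()
    unstable = sorted(counts.index[counts == 1])
    if unstable:
        out.log["unstable_plates"] = [str(p) for p in unstable]

    # sum-to-zero contrast design: k-1 columns, last plate = -1 row
    idx = pd.Index(levels).get_indexer(plates)
    k = len(levels)
    contrasts = np.zeros((len(plates), k - 1))
    for j in range(k - 1):
        contrasts[idx == j, j] = 1.0
    contrasts[idx == k - 1, :] = -1.0
    design = np.column_stack([np.ones(len(plates)), contrasts])

    data = out.data.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    plate_terms = contrasts @ coef[1:, :]            # samples x rows
    corrected = data - plate_terms.T
    # re-center so every row keeps its original grand mean
    corrected += (data.mean(axis=1) - corrected.mean(axis=1))[:, None]
    out.data = pd.DataFrame(corrected, index=quant.features, columns=quant.samples)
    out.log["stage"] = "plate_corrected"
    return out


# ---------------------------------------------------------------------------
# 6. median polish summarization
# ---------------------------------------------------------------------------

def median_polish(block: np.ndarray, tol: float = 1e-6,
                  max_iter: int = 50) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D array.

    Alternates row- and column-median sweeps until the largest absolute
    adjustment in a full sweep drops below ``tol`` or ``max_iter`` sweeps.
    Returns (overall, row_effects, col_effects, residuals) with
    ``block = overall + row[:, None] + col[None, :] + residuals``.
    """
    resid = np.asarray(block, dtype=float).copy()
    n_rows, n_cols = resid.shape
    overall = 0.0
    row = np.zeros(n_rows)
    col = np.zeros(n_cols)
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        row += rmed
        resid -= rmed[:, None]
        delta = np.median(row)
        row -= delta
        overall += delta

        cmed = np.median(resid, axis=0)
        col += cmed
        resid -= cmed[None, :]
        delta = np.median(col)
        col -= delta
        overall += delta

        if max(np.abs(rmed).max(initial=0.0), np.abs(cmed).max(initial=0.0)) < tol:
            break
    return overall, row, col, resid


def median_polish_summarize(quant: QuantMatrix, meta: pd.DataFrame,
                            tol: float = 1e-6, max_iter: int = 50) -> QuantMatrix:
    """Summarize proteotypic precursors to one log2 profile per protein group.

    Non-proteotypic precursors are discarded first; each protein's profile is
    the overall plus column effect of a median polish on its precursor block.
    Protein groups left without proteotypic precursors are dropped and logged.
    """
    quant.require(scale="log2", fully_observed=True)
    _check_stage(quant, "median_polish_summarize",
                 {None, "log2", "normalized", "plate_corrected"})
    meta = meta.loc[quant.features]
    proteo = meta["proteotypic"].astype(bool)
    dropped_proteins = sorted(
        set(meta["protein_group"]) - set(meta.loc[proteo, "protein_group"]))

    kept = quant.data.loc[proteo.to_numpy()]
    groups = meta.loc[proteo, "protein_group"]
    profiles = {}
    for protein, rows in kept.groupby(groups.to_numpy(), sort=True):
        overall, _, col, _ = median_polish(rows.to_numpy(), tol=tol,
                                           max_iter=max_iter)
        profiles[protein] = overall + col
    data = pd.DataFrame.from_dict(profiles, orient="index",
                                  columns=quant.samples)
    data.index.name = "protein"
    out = QuantMatrix(data=data, scale="log2", level="protein",
                      log=dict(quant.log))
    out.log["stage"] = "summarized"
    out.log["proteotypic_precursors"] = int(proteo.sum())
    out.log["proteins_summarized"] = int(len(profiles))
    out.log["proteins_dropped_no_proteotypic"] = dropped_proteins
    return out


# ---------------------------------------------------------------------------
# chain
# ---------------------------------------------------------------------------

def run_preprocess(quant: QuantMatrix, meta: pd.DataFrame,
                   samples: pd.DataFrame,
                   params: PreprocessParams | None = None,
                   drop_samples: list[str] | None = None) -> tuple[QuantMatrix, dict]:
    """Run the full fixed-order chain; returns (protein matrix, stage log).

    ``drop_samples`` (e.g. QC-flagged outlier runs) are removed from the
    matrix before any stage runs.
    """
    params = params or PreprocessParams()
    params.validate()
    work = quant.copy()
    work.log.setdefault("stage", "raw")
    if drop_samples:
        work.data = work.data.drop(columns=list(drop_samples), errors="ignore")
        work.log["dropped_samples"] = list(map(str, drop_samples))

    work = filter_missing_precursors(work, samples, params.max_missing_frac)
    work = knn_impute(work, samples, k=params.knn_k,
                      row_missing_cap=params.knn_row_missing_cap)
    work = log2_transform(work)
    work = cyclic_loess_normalize(work, span=params.loess_span,
                                  iterations=params.loess_iterations,
                                  feature_groups=meta["protein_group"])
    work = remove_plate_effects(work, samples)
    protein = median_polish_summarize(work, meta, tol=params.polish_tol,
                                      max_iter=params.polish_max_iter)
    return protein, dict(protein.log)
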