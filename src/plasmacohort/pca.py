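"""Z-scored PCA of the protein matrix and covariate attribution of components.

The exploratory question this answers: which sample-level factors drive the
dominant axes of proteome variation?  Proteins are autoscaled (zero mean,
unit sd) over the chosen sample subset, samples are decomposed by SVD, and
each principal component's scores are regressed jointly on the study
covariates and common medications; the ranked standardized coefficients name
the candidate drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QuantMatrix

__all__ = ["PCAResult", "zscore_pca", "pc_covariate_scan"]


@dataclass
class PCAResult:
    scores: pd.DataFrame          # sample x component
    loadings: pd.DataFrame        # protein x component (orthonormal columns)
    variance_explained: pd.Series
    dropped_proteins: list[str]


def zscore_pca(protein_matrix: QuantMatrix, samples: pd.DataFrame | None = None,
               subset: pd.Index | list[str] | None = None,
               n_components: int | None = None) -> PCAResult:
    """PCA of the z-score transformed protein matrix over a sample subset.

    Each protein row is centered and scaled to unit sd over the subset;
    zero-variance proteins are dropped with a log entry.  The decomposition
    is an SVD of the standardized sample x protein matrix; component signs
    are fixed so the loading of largest magnitude is positive.
    """
    protein_matrix.require(level="protein", fully_observed=True)
    data = protein_matrix.data
    if subset is not None:
        data = data.loc[:, list(subset)]
    if data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")

    values = data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [str(p) for p in data.index[~keep]]
    values = values[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[keep, None]

    # samples x proteins, SVD -> scores = U S, loadings = V
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components is None:
        n_components = rank
    n_components = min(n_components, rank)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]

    # deterministic sign: largest-|loading| entry positive per component
    for j in range(n_components):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0

    comp = [f"PC{i + 1}" for i in range(n_components)]
    total_var = (z ** 2).sum()
    return PCAResult(
        scores=pd.DataFrame(u * s, index=data.columns, columns=comp),
        loadings=pd.DataFrame(vt.T, index=data.index[keep], columns=comp),
        variance_explained=pd.Series(s ** 2 / total_var, index=comp),
        dropped_proteins=dropped,
    )


def pc_covariate_scan(pc_scores: pd.Series, design: pd.DataFrame) -> pd.DataFrame:
    """One joint multiple regression of a PC score on all design columns.

    ``design`` comes from :func:`plasmacohort.associate.build_design`
    (intercept included).  Returns one row per non-intercept term with the
    raw coefficient, its standardized coefficient (per response and predictor
    sd), t, p and Bonferroni-adjusted p, ranked by |standardized coefficient|.
    """
    shared = design.index.intersection(pc_scores.index)
    X = design.loc[shared].to_numpy(dtype=float)
    y = pc_scores.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j, name in enumerate(design.columns):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
                bad.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    n, p = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tstat = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)

    sd_y = y.std(ddof=1)
    rows = []
    for j, term in enumerate(design.columns):
        if term == "intercept":
            continue
        sd_x = X[:, j].std(ddof=1)
        rows.append({
            "term": term,
            "coefficient": float(coef[j]),
            "std_coefficient": float(coef[j] * sd_x / sd_y) if sd_y > 0 else np.nan,
            "se": float(se[j]),
            "t": float(tstat[j]),
            "p": float(pvals[j]),
        })
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonf"] = np.minimum(1.0, out["p"] * m)
    out["r_squared"] = 1.0 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum())
    return out.reindex(
        out["std_coefficient"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
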