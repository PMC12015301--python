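"""Per-protein regression against demographics and medications.

The model, fitted independently per protein by ordinary least squares:

    log2(abundance) ~ sex + age/10 + BMI category + fasting + HCU [+ ATC codes]

with sex coded F=1, age per decade, BMI as indicator contrasts against the
normal-weight category, fasting as the self-reported meal-within-12h flag and
HCU the binary hormonal-contraceptive exposure derived from ATC codes G03A /
G03H.  P-values are Bonferroni-adjusted across proteins within each term, and
a protein passes the *CV-anchored* rule only if, in addition, the absolute
log2 coefficient exceeds the protein's pooled-QC coefficient of variation —
i.e. the claimed difference is larger than the assay's technical wobble.

Also here: the ATC level 3/4 medication scan (regular use by a minimum user
count) and the sensitivity comparison of models with and without the HCU
term, which identifies sex/age associations that are really misattributed
contraceptive effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QuantMatrix
from .io import truncate_atc

__all__ = [
    "DEFAULT_TERMS",
    "encode_bmi_category",
    "define_hcu_flag",
    "analysis_study_samples",
    "build_design",
    "fit_per_protein",
    "bonferroni",
    "apply_significance_rule",
    "standardized_effects",
    "associate",
    "medication_scan",
    "MedicationScanResult",
    "sensitivity_compare",
    "SensitivityReport",
]

DEFAULT_TERMS = ("sex", "age_decade", "bmi", "fasting", "hcu")
BMI_INDICATORS = ("bmi_cat1", "bmi_cat3", "bmi_cat4")  # cat2 = reference
HCU_ATC3 = ("G03A", "G03H")


class RankError(ValueError):
    """Design matrix is rank deficient (constant or collinear columns)."""


def encode_bmi_category(bmi: float) -> int:
    """Clinical BMI class: 1 underweight (<18.5), 2 normal [18.5, 25),
    3 overweight [25, 30), 4 obese (>= 30)."""
    bmi = float(bmi)
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi}")
    if bmi < 18.5:
        return 1
    if bmi < 25.0:
        return 2
    if bmi < 30.0:
        return 3
    return 4


def define_hcu_flag(samples: pd.DataFrame) -> pd.Series:
    """Binary oral hormonal-contraceptive exposure per sample.

    1 iff any reported medication code truncates at ATC level 3 to G03A
    (hormonal contraceptives for systemic use) or G03H (antiandrogens).
    Topical contraceptives (G02B) deliberately do not count.
    """
    def _flag(meds) -> int:
        if not isinstance(meds, (list, tuple)):
            return 0
        for code, _regular in meds:
            if len(code) >= 4 and truncate_atc(code, 3) in HCU_ATC3:
                return 1
        return 0

    return samples["medications"].apply(_flag).astype(int)


def analysis_study_samples(samples: pd.DataFrame,
                           outlier_ids: list[str] | None = None,
                           exclude_pregnant: bool = True) -> pd.DataFrame:
    """Study-role rows minus QC-flagged outliers and (by default) pregnant
    participants — the analysis set every model is fitted on."""
    study = samples[samples["role"] == "study"]
    if outlier_ids:
        study = study.drop(index=[i for i in outlier_ids if i in study.index])
    if exclude_pregnant and "pregnant" in study.columns:
        preg = pd.to_numeric(study["pregnant"], errors="coerce").fillna(0)
        study = study[preg != 1]
    return study


def _medication_indicator(samples: pd.DataFrame, code: str,
                          regular_only: bool = True) -> pd.Series:
    def _has(meds) -> int:
        if not isinstance(meds, (list, tuple)):
            return 0
        for c, regular in meds:
            if (not regular_only or regular) and c.startswith(code):
                return 1
        return 0
    return samples["medications"].apply(_has).astype(int)


def build_design(samples: pd.DataFrame,
                 terms: tuple[str, ...] = DEFAULT_TERMS,
                 medication_codes: list[str] | None = None,
                 regular_only: bool = True) -> pd.DataFrame:
    """Numeric design matrix for the requested terms plus medication codes.

    Rows with a missing requested covariate are excluded (count in
    ``design.attrs["n_excluded"]``).  Term encodings: ``sex`` F=1;
    ``age_decade`` = age/10; ``bmi`` expands to category-1/3/4 indicators
    against the normal-weight reference; ``fasting`` and ``hcu`` binary;
    medication indicators count regular use only.  Constant or collinear
    columns raise :class:`RankError` naming the term.
    """
    medication_codes = medication_codes or []
    needed = {"sex": ["sex"], "age_decade": ["age"], "bmi": ["bmi"],
              "fasting": ["fasting"], "hcu": []}
    required_cols: list[str] = []
    for term in terms:
        if term not in needed:
            raise ValueError(f"unknown design term {term!r}")
        required_cols.extend(needed[term])

    keep = pd.Series(True, index=samples.index)
    for col in required_cols:
        keep &= samples[col].notna()
    included = samples[keep]

    design = pd.DataFrame(index=included.index)
    design["intercept"] = 1.0
    for term in terms:
        if term == "sex":
            design["sex"] = (included["sex"] == "F").astype(float)
        elif term == "age_decade":
            design["age_decade"] = included["age"].astype(float) / 10.0
        elif term == "bmi":
            cats = included["bmi"].astype(float).map(encode_bmi_category)
            for ind in BMI_INDICATORS:
                design[ind] = (cats == int(ind[-1])).astype(float)
        elif term == "fasting":
            design["fasting"] = included["fasting"].astype(float)
        elif term == "hcu":
            design["hcu"] = define_hcu_flag(included).astype(float)
    for code in medication_codes:
        design[code] = _medication_indicator(
            included, code, regular_only).astype(float)

    constant = [c for c in design.columns
                if c != "intercept" and design[c].nunique() < 2]
    if constant:
        raise RankError(f"constant design column(s): {constant}")
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        full_rank = np.linalg.matrix_rank(X)
        for j, name in enumerate(design.columns):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == full_rank:
                bad.append(name)
        raise RankError(f"collinear design column(s): {bad}")

    design.attrs["n_excluded"] = int((~keep).sum())
    return design


# ---------------------------------------------------------------------------
# OLS across proteins
# ---------------------------------------------------------------------------

def fit_per_protein(protein_matrix: QuantMatrix,
                    design: pd.DataFrame) -> pd.DataFrame:
    """OLS of every protein's log2 abundance on the design; long table out.

    Returns one row per (protein, non-intercept term) with the coefficient,
    its standard error, two-sided t statistic p-value.  All proteins share
    the design, so the normal equations are solved once.
    """
    protein_matrix.require(level="protein", fully_observed=True)
    runs = design.index
    Y = protein_matrix.data.loc[:, runs].to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"{n} samples cannot support {p} design terms")

    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv                         # proteins x terms
    resid = Y - B @ X.T
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(sigma2[:, None] * np.diag(xtx_inv)[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = B / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)

    records = []
    terms = [t for t in design.columns if t != "intercept"]
    term_idx = [design.columns.get_loc(t) for t in terms]
    for i, protein in enumerate(protein_matrix.features):
        for t_name, j in zip(terms, term_idx):
            records.append({
                "protein": protein, "term": t_name,
                "coefficient": float(B[i, j]), "se": float(se[i, j]),
                "t": float(tstat[i, j]), "p": float(pvals[i, j]),
            })
    out = pd.DataFrame(records)
    out.attrs["n_samples"] = n
    out.attrs["dof"] = dof
    return out


def bonferroni(p_values, m: int) -> np.ndarray:
    """min(1, m * p); the family is the set of proteins tested for a term."""
    p = np.asarray(p_values, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def standardized_effects(protein_matrix: QuantMatrix, design: pd.DataFrame,
                         records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Effect sizes: coefficients of the same fit on z-scored responses.

    Equivalent to dividing each protein's coefficients by its abundance sd
    over the fitted samples; t and p are invariant to the rescaling.  Joined
    onto ``records`` (fresh fit if omitted) as column ``effect_size``.
    """
    if records is None:
        records = fit_per_protein(protein_matrix, design)
    sd = protein_matrix.data.loc[:, design.index].std(axis=1, ddof=1)
    zero_var = sd.index[sd == 0]
    out = records.copy()
    sd_map = sd.replace(0.0, np.nan)
    out["effect_size"] = out["coefficient"] / out["protein"].map(sd_map)
    if len(zero_var):
        out.attrs["zero_variance_proteins"] = [str(p) for p in zero_var]
    return out


def apply_significance_rule(records: pd.DataFrame, cv_tbl: pd.DataFrame,
                            alpha: float = 0.05,
                            cv_threshold_mode: str = "literal") -> pd.DataFrame:
    """Bonferroni per term, then the dual significance rule.

    ``stat_significant``: Bonferroni-adjusted p (family = proteins within the
    term) below ``alpha``.  ``cv_anchored_significant``: additionally the
    absolute log2 coefficient exceeds the protein's pooled-QC CV threshold —
    ``cv_pool/100`` read as log2 units (``literal``, default) or the log2 sd
    implied by a log-normal with that linear CV (``log_sd``).  Proteins with
    no pool CV get ``cv_pool_defined = False`` and an unanchored flag.
    """
    if cv_threshold_mode not in ("literal", "log_sd"):
        raise ValueError(f"unknown cv_threshold_mode {cv_threshold_mode!r}")
    out = records.copy()
    out["p_bonf"] = np.nan
    for term, idx in out.groupby("term").groups.items():
        m = len(idx)
        out.loc[idx, "p_bonf"] = bonferroni(out.loc[idx, "p"], m)

    cv_pool = out["protein"].map(cv_tbl["cv_pool"])
    if cv_threshold_mode == "literal":
        threshold = cv_pool / 100.0
    else:
        threshold = np.sqrt(np.log(1.0 + (cv_pool / 100.0) ** 2)) / np.log(2.0)
    out["cv_pool_defined"] = cv_pool.notna()
    out["stat_significant"] = out["p_bonf"] < alpha
    out["cv_anchored_significant"] = (
        out["stat_significant"]
        & out["cv_pool_defined"]
        & (out["coefficient"].abs() > threshold)
    )
    return out


def associate(protein_matrix: QuantMatrix, design: pd.DataFrame,
              cv_tbl: pd.DataFrame, alpha: float = 0.05,
              cv_threshold_mode: str = "literal") -> pd.DataFrame:
    """Fit, standardize, adjust and flag in one call (the Fig 2-style table)."""
    records = fit_per_protein(protein_matrix, design)
    records = standardized_effects(protein_matrix, design, records)
    return apply_significance_rule(records, cv_tbl, alpha=alpha,
                                   cv_threshold_mode=cv_threshold_mode)


# ---------------------------------------------------------------------------
# medication scan
# ---------------------------------------------------------------------------

@dataclass
class MedicationScanResult:
    atc_level: int
    min_users: int
    user_counts: pd.Series                  # all codes seen at the level
    tested_codes: list[str]
    records: pd.DataFrame                   # AssociationRecords, medication terms
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def n_significant(self, code: str, anchored: bool = True) -> int:
        col = "cv_anchored_significant" if anchored else "stat_significant"
        sub = self.records[self.records["term"] == code]
        return int(sub[col].sum())


def eligible_medications(samples: pd.DataFrame, atc_level: int = 3,
                         min_users: int = 15,
                         regular_only: bool = True) -> tuple[pd.Series, list[str]]:
    """User counts per truncated ATC code and the codes meeting the cutoff."""
    if atc_level not in (3, 4):
        raise ValueError("atc_level must be 3 or 4")
    counts: dict[str, int] = {}
    for meds in samples["medications"]:
        if not isinstance(meds, (list, tuple)):
            continue
        seen = set()
        for code, regular in meds:
            if regular_only and not regular:
                continue
            if len(code) < (4 if atc_level == 3 else 5):
                continue
            seen.add(truncate_atc(code, atc_level))
        for c in seen:
            counts[c] = counts.get(c, 0) + 1
    series = pd.Series(counts, dtype=int).sort_values(ascending=False)
    tested = sorted(series.index[series >= min_users])
    return series, tested


def medication_scan(protein_matrix: QuantMatrix, samples: pd.DataFrame,
                    cv_tbl: pd.DataFrame, atc_level: int = 3,
                    min_users: int = 15, regular_only: bool = True,
                    alpha: float = 0.05, joint: bool = True) -> MedicationScanResult:
    """Scan ATC level 3 or 4 medications for plasma-proteome associations.

    Only codes taken regularly by at least ``min_users`` participants are
    tested.  By default all eligible codes enter one joint per-protein model
    together with sex, age, BMI and fasting; ``joint=False`` fits one model
    per code instead.
    """
    counts, tested = eligible_medications(samples, atc_level, min_users,
                                          regular_only)
    base_terms = ("sex", "age_decade", "bmi", "fasting")
    if not tested:
        return MedicationScanResult(atc_level, min_users, counts, [],
                                    pd.DataFrame(columns=["protein", "term"]),
                                    pd.DataFrame())
    if joint:
        design = build_design(samples, base_terms, medication_codes=tested,
                              regular_only=regular_only)
        records = associate(protein_matrix, design, cv_tbl, alpha=alpha)
        records = records[records["term"].isin(tested)].reset_index(drop=True)
    else:
        pieces = []
        for code in tested:
            design = build_design(samples, base_terms, medication_codes=[code],
                                  regular_only=regular_only)
            rec = associate(protein_matrix, design, cv_tbl, alpha=alpha)
            pieces.append(rec[rec["term"] == code])
        records = pd.concat(pieces, ignore_index=True)

    summary = pd.DataFrame({
        "atc_code": counts.index,
        "n_regular_users": counts.to_numpy(),
        "tested": [c in tested for c in counts.index],
    }).set_index("atc_code")
    summary["n_significant"] = [
        int(records.loc[(records["term"] == c),
                        "cv_anchored_significant"].sum()) if c in tested else 0
        for c in summary.index
    ]
    return MedicationScanResult(atc_level, min_users, counts, tested,
                                records, summary)


# ---------------------------------------------------------------------------
# sensitivity comparison (with vs without the HCU term)
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    significant_with: dict[str, set[str]]
    significant_without: dict[str, set[str]]
    misattributed: dict[str, set[str]]
    hcu_significant: set[str]
    paired_coefficients: pd.DataFrame   # protein, term, coef_with, coef_without

    def newly_significant(self, term: str) -> set[str]:
        return self.significant_without.get(term, set()) - \
            self.significant_with.get(term, set())


def sensitivity_compare(protein_matrix: QuantMatrix, samples: pd.DataFrame,
                        cv_tbl: pd.DataFrame, alpha: float = 0.05,
                        significance: str = "anchored") -> SensitivityReport:
    """Compare the full model (with HCU) against the reduced one (without).

    For every non-HCU term, a protein is *misattributed* if it becomes
    significant for that term only in the reduced model while being
    HCU-significant in the full model — the signature of a contraceptive
    effect masquerading as a sex or age association.
    """
    col = {"anchored": "cv_anchored_significant",
           "stat": "stat_significant"}[significance]
    full_design = build_design(samples, DEFAULT_TERMS)
    reduced_design = build_design(samples, ("sex", "age_decade", "bmi", "fasting"))
    full = associate(protein_matrix, full_design, cv_tbl, alpha=alpha)
    reduced = associate(protein_matrix, reduced_design, cv_tbl, alpha=alpha)

    hcu_sig = set(full.loc[(full["term"] == "hcu") & full[col], "protein"])
    terms = [t for t in reduced["term"].unique()]
    sig_with, sig_without, misattributed = {}, {}, {}
    for term in terms:
        with_set = set(full.loc[(full["term"] == term) & full[col], "protein"])
        without_set = set(reduced.loc[(reduced["term"] == term) & reduced[col],
                                      "protein"])
        sig_with[term] = with_set
        sig_without[term] = without_set
        misattributed[term] = (without_set - with_set) & hcu_sig

    paired = full[full["term"].isin(terms)][["protein", "term", "coefficient"]]
    paired = paired.rename(columns={"coefficient": "coef_with"}).merge(
        reduced[["protein", "term", "coefficient"]]
        .rename(columns={"coefficient": "coef_without"}),
        on=["protein", "term"],
    )
    return SensitivityReport(sig_with, sig_without, misattributed, hcu_sig,
                             paired)
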