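"""Hormonal-contraceptive analyses.

Five questions, each a thin composition over the association engine:

* which proteins shift with current oral hormonal-contraceptive use (HCU),
  estimated in women below 40 so age and sex cannot confound;
* how well a single marker protein separates users from a propensity-matched
  control group (optimal 1:1 matching on sex, age, BMI and fasting, AUROC);
* whether ethinylestradiol-containing combined oral contraceptives (EE) hit
  the proteome harder than bioidentical-estrogen (BE) or progestogen-only
  (P4) preparations, compared on effect sizes which are sample-size free;
* whether previous users still differ from never-users (lasting effects);
* whether per-protein HCU effect sizes replicate across two independently
  processed cohorts (Spearman concordance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.linear_model import LogisticRegression

from .associate import (
    BMI_INDICATORS,
    apply_significance_rule,
    associate,
    build_design,
    define_hcu_flag,
    encode_bmi_category,
    fit_per_protein,
    standardized_effects,
)
from .containers import QuantMatrix
from .io import truncate_atc

__all__ = [
    "subgroup_women_under40",
    "hcu_association",
    "MatchedSet",
    "optimal_pairing",
    "propensity_match",
    "ROCResult",
    "roc_auc",
    "load_preparation_map",
    "classify_coc",
    "EffectComparison",
    "compare_group_effects",
    "hcu_history_analysis",
    "cohort_concordance",
]

HCU_SUBGROUP_TERMS = ("age_decade", "bmi", "fasting", "hcu")
MATCH_COVARIATES = ("sex", "age", "bmi", "fasting")


def subgroup_women_under40(samples: pd.DataFrame,
                           exclude_pregnant: bool = True,
                           exclude_unknown_history: bool = False,
                           age_cutoff: float = 40.0) -> pd.DataFrame:
    """Female study participants strictly below the age cutoff (default 40).

    Pregnant participants are excluded by default; unknown contraceptive
    history is excluded only when the downstream analysis categorizes by
    history.
    """
    study = samples[samples["role"] == "study"]
    sub = study[(study["sex"] == "F") & (study["age"].astype(float) < age_cutoff)]
    if exclude_pregnant and "pregnant" in sub.columns:
        preg = pd.to_numeric(sub["pregnant"], errors="coerce").fillna(0)
        sub = sub[preg != 1]
    if exclude_unknown_history:
        sub = sub[sub["hcu_history"].isin(["current", "previous", "never"])]
    if len(sub) == 0:
        raise ValueError("no women below 40 in the sample table")
    return sub


def hcu_association(protein_matrix: QuantMatrix, subset: pd.DataFrame,
                    cv_tbl: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein HCU association within the women-under-40 subset.

    Model: log2 abundance ~ age/10 + BMI category + fasting + HCU (no sex
    term), with the dual CV-anchored significance rule applied.
    """
    design = build_design(subset, HCU_SUBGROUP_TERMS)
    return associate(protein_matrix, design, cv_tbl, alpha=alpha)


# ---------------------------------------------------------------------------
# propensity matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedSet:
    pairs: list[tuple[str, str]]          # (case, control)
    propensity: pd.Series                 # score per candidate sample
    total_distance: float

    @property
    def case_ids(self) -> list[str]:
        return [c for c, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [c for _, c in self.pairs]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "case": self.case_ids,
            "control": self.control_ids,
            "case_score": [self.propensity[c] for c in self.case_ids],
            "control_score": [self.propensity[c] for c in self.control_ids],
        })


def optimal_pairing(case_scores: pd.Series,
                    control_scores: pd.Series) -> tuple[list[tuple[str, str]], float]:
    """1:1 assignment minimizing total |propensity difference| (exact solver)."""
    if len(control_scores) < len(case_scores):
        raise ValueError(
            f"{len(control_scores)} controls cannot match {len(case_scores)} cases")
    cost = np.abs(case_scores.to_numpy()[:, None]
                  - control_scores.to_numpy()[None, :])
    rows, cols = linear_sum_assignment(cost)
    pairs = [(str(case_scores.index[i]), str(control_scores.index[j]))
             for i, j in zip(rows, cols)]
    return pairs, float(cost[rows, cols].sum())


def _match_design(samples: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov == "sex":
            cols.append((samples["sex"] == "F").astype(float).to_numpy())
        elif cov in ("age", "age_decade"):
            scale = 10.0 if cov == "age_decade" else 1.0
            cols.append(samples["age"].astype(float).to_numpy() / scale)
        elif cov == "bmi":
            cols.append(samples["bmi"].astype(float).to_numpy())
        elif cov == "fasting":
            cols.append(samples["fasting"].astype(float).to_numpy())
        else:
            raise ValueError(f"unknown matching covariate {cov!r}")
    return np.column_stack(cols)


def propensity_match(samples: pd.DataFrame, case_ids, control_ids,
                     covariates=MATCH_COVARIATES) -> MatchedSet:
    """Optimal 1:1 propensity-score matching of cases to controls.

    The propensity score is the fitted probability from a logistic regression
    of case status on the matching covariates over all candidates; pairs are
    then chosen by an exact assignment solver minimizing the total absolute
    score difference.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if len(control_ids) < len(case_ids):
        raise ValueError(
            f"need at least as many controls ({len(control_ids)}) as cases "
            f"({len(case_ids)})")
    candidates = samples.loc[case_ids + control_ids]
    X = _match_design(candidates, covariates)
    if np.isnan(X).any():
        raise ValueError("matching covariates must be complete")
    y = np.array([1] * len(case_ids) + [0] * len(control_ids))
    model = LogisticRegression(C=1e6, max_iter=2000)
    model.fit(X, y)
    scores = pd.Series(model.predict_proba(X)[:, 1], index=candidates.index)
    pairs, dist = optimal_pairing(scores.loc[case_ids], scores.loc[control_ids])
    return MatchedSet(pairs=pairs, propensity=scores, total_distance=dist)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float                      # Mann-Whitney pair statistic, ties 0.5

    def curve_auc(self) -> float:
        """Trapezoidal area under the (1-specificity, sensitivity) curve."""
        fpr = 1.0 - self.specificity
        order = np.argsort(fpr, kind="stable")
        return float(np.trapezoid(self.sensitivity[order], fpr[order]))


def roc_auc(marker_values, case_labels) -> ROCResult:
    """ROC curve and AUC of one marker for a binary label.

    AUC = (#{case > control} + 0.5 * #{ties}) / (n_case * n_control),
    computed via average ranks; the explicit curve spans every unique
    threshold (classification rule: value >= threshold -> case).
    """
    values = np.asarray(marker_values, dtype=float)
    labels = np.asarray(case_labels).astype(int)
    n_case = int(labels.sum())
    n_control = int((1 - labels).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("both classes must be non-empty")

    ranks = stats.rankdata(values)
    auc = (ranks[labels == 1].sum() - n_case * (n_case + 1) / 2) \
        / (n_case * n_control)

    thresholds = np.concatenate(([np.inf], np.unique(values)[::-1]))
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    case_vals = values[labels == 1]
    control_vals = values[labels == 0]
    for i, thr in enumerate(thresholds):
        sens[i] = np.mean(case_vals >= thr)
        spec[i] = np.mean(control_vals < thr)
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=float(auc))


# ---------------------------------------------------------------------------
# COC subtype classification and comparison
# ---------------------------------------------------------------------------

def load_preparation_map(path: str | Path | None = None) -> pd.Series:
    """Preparation code -> estrogen class (EE / BE / P4 / non_oral).

    Without a path, the package's bundled map is used.  The bundled table is
    a curated default covering common preparations; it is meant to be edited
    or replaced for a concrete formulary.
    """
    if path is None:
        source = resources.files("plasmacohort").joinpath(
            "data/coc_preparation_map.csv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    return table.set_index("preparation_code")["estrogen_class"]


def classify_coc(samples: pd.DataFrame,
                 preparation_map: pd.Series | None = None) -> pd.DataFrame:
    """Classify current HCU samples by the estrogen content of their COC.

    Classes: EE (ethinylestradiol), BE (bioidentical estrogen), P4
    (progestogen-only), non_oral (excluded from the subtype comparison),
    unclassified (preparation absent from the map; warned).
    """
    if preparation_map is None:
        preparation_map = load_preparation_map()
    flags = define_hcu_flag(samples)
    rows = []
    for run in samples.index[flags == 1]:
        codes = [c for c, _r in samples.loc[run, "medications"]
                 if len(c) >= 4 and truncate_atc(c, 3) in ("G03A", "G03H")]
        classes = {str(preparation_map.get(c, "unclassified")) for c in codes}
        if "unclassified" in classes and classes == {"unclassified"}:
            warnings.warn(f"unmapped contraceptive preparation(s) {codes} "
                          f"for {run}", stacklevel=2)
        for priority in ("non_oral", "EE", "BE", "P4", "unclassified"):
            if priority in classes:
                label = priority
                break
        rows.append({"run": run, "coc_class": label, "codes": ";".join(codes)})
    return pd.DataFrame(rows).set_index("run") if rows else pd.DataFrame(
        columns=["coc_class", "codes"])


@dataclass
class EffectComparison:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n_proteins: int
    paired: pd.DataFrame    # protein, effect_a, effect_b


def compare_group_effects(effects_a: pd.Series,
                          effects_b: pd.Series) -> EffectComparison:
    """OLS of group-B effect sizes on group-A effect sizes over shared proteins."""
    shared = effects_a.index.intersection(effects_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared proteins; need >= 3")
    a = effects_a.loc[shared].astype(float)
    b = effects_b.loc[shared].astype(float)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("degenerate (constant) effect vectors")
    fit = stats.linregress(a, b)
    return EffectComparison(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2), p_slope=float(fit.pvalue),
        n_proteins=int(len(shared)),
        paired=pd.DataFrame({"effect_a": a, "effect_b": b}),
    )


def coc_subtype_effects(protein_matrix: QuantMatrix, samples: pd.DataFrame,
                        cv_tbl: pd.DataFrame,
                        preparation_map: pd.Series | None = None,
                        alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Per-class (EE / BE / P4) association tables in women under 40.

    Non-users form the common reference; non-oral and unclassified users are
    excluded.  Each class is fitted in its own model (class users + non-users)
    adjusted for age, BMI and fasting.
    """
    sub = subgroup_women_under40(samples)
    classes = classify_coc(sub, preparation_map)
    nonusers = sub.index[define_hcu_flag(sub) == 0]
    out: dict[str, pd.DataFrame] = {}
    for label in ("EE", "BE", "P4"):
        users = classes.index[classes["coc_class"] == label]
        if len(users) == 0:
            continue
        block = sub.loc[list(nonusers) + list(users)]
        design = build_design(block, ("age_decade", "bmi", "fasting"))
        design[label] = [1.0 if run in set(users) else 0.0
                         for run in design.index]
        records = fit_per_protein(protein_matrix, design)
        records = standardized_effects(protein_matrix, design, records)
        records = apply_significance_rule(records, cv_tbl, alpha=alpha)
        out[label] = records[records["term"] == label].set_index("protein")
    return out


# ---------------------------------------------------------------------------
# lasting effects (current / previous / never)
# ---------------------------------------------------------------------------

def hcu_history_analysis(protein_matrix: QuantMatrix, samples: pd.DataFrame,
                         cv_tbl: pd.DataFrame, alpha: float = 0.05,
                         never_pregnant_only: bool = False) -> pd.DataFrame:
    """Current-vs-never and previous-vs-never contrasts in women under 40.

    A three-level group factor (never = reference) plus age and BMI enters a
    per-protein linear model; both contrasts are tested under the dual rule.
    ``never_pregnant_only`` re-runs on women who were never pregnant, to rule
    out recent-pregnancy carry-over.
    """
    sub = subgroup_women_under40(samples, exclude_unknown_history=True)
    if never_pregnant_only:
        ever = pd.to_numeric(sub["ever_pregnant"], errors="coerce").fillna(0)
        sub = sub[ever == 0]
    counts = sub["hcu_history"].value_counts()
    for group in ("current", "previous", "never"):
        if counts.get(group, 0) == 0:
            raise ValueError(f"history group {group!r} is empty")

    design = build_design(sub, ("age_decade", "bmi"))
    design["hcu_current"] = (sub.loc[design.index, "hcu_history"]
                             == "current").astype(float)
    design["hcu_previous"] = (sub.loc[design.index, "hcu_history"]
                              == "previous").astype(float)
    records = fit_per_protein(protein_matrix, design)
    records = standardized_effects(protein_matrix, design, records)
    records = apply_significance_rule(records, cv_tbl, alpha=alpha)
    return records[records["term"].isin(["hcu_current", "hcu_previous"])] \
        .reset_index(drop=True)


# ---------------------------------------------------------------------------
# cross-cohort concordance
# ---------------------------------------------------------------------------

def cohort_concordance(effects_a: pd.Series,
                       effects_b: pd.Series) -> tuple[float, pd.DataFrame]:
    """Spearman rho between per-protein effect sizes of two cohorts."""
    shared = effects_a.index.intersection(effects_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared proteins; need >= 3")
    paired = pd.DataFrame({"effect_a": effects_a.loc[shared].astype(float),
                           "effect_b": effects_b.loc[shared].astype(float)})
    rho = stats.spearmanr(paired["effect_a"], paired["effect_b"]).statistic
    return float(rho), paired
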