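"""End-to-end orchestration: simulate/load -> QC -> preprocess -> associate
-> contraceptive analyses -> report, driven by one serializable RunConfig.

Every run writes a directory of TSV/JSON artifacts plus a ``manifest.json``
recording parameter values, input hashes and per-stage record counts, so two
runs with the same configuration and seed produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associate import (
    analysis_study_samples,
    associate,
    build_design,
    define_hcu_flag,
    medication_scan,
    sensitivity_compare,
)
from .containers import AnalysisBundle, QuantMatrix
from .hcu import (
    coc_subtype_effects,
    compare_group_effects,
    hcu_association,
    hcu_history_analysis,
    propensity_match,
    roc_auc,
    subgroup_women_under40,
)
from .io import (
    read_matrix_tsv,
    read_precursor_report,
    read_sample_annotation,
    validate_bundle,
    write_matrix_tsv,
    write_precursor_report,
    write_sample_annotation,
)
from .pca import pc_covariate_scan, zscore_pca
from .preprocess import PreprocessParams, run_preprocess
from .qc import cv_table, flag_outlier_samples, sample_qc_metrics
from .simulate import CohortConfig, EffectSpec, GroundTruth, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "run_report", "write_bundle",
           "load_bundle"]


@dataclass
class RunConfig:
    """One file's worth of settings for a full pipeline run."""

    # input: either simulate (cohort settings) or load (two paths)
    precursor_report: str | None = None
    sample_annotation: str | None = None
    cohort: dict = field(default_factory=dict)      # CohortConfig overrides
    preprocess: dict = field(default_factory=dict)  # PreprocessParams overrides
    alpha: float = 0.05
    atc_level: int = 3
    min_users: int = 15
    cv_anchor: bool = True
    cv_threshold_mode: str = "literal"
    hcu_age_cutoff: float = 40.0
    match_covariates: tuple[str, ...] = ("sex", "age", "bmi", "fasting")
    qc_z_threshold: float = 5.0
    outdir: str = "run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "match_covariates" in raw:
            raw["match_covariates"] = tuple(raw["match_covariates"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["match_covariates"] = list(self.match_covariates)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    def cohort_config(self) -> CohortConfig:
        overrides = dict(self.cohort)
        effects = [EffectSpec(**e) if isinstance(e, dict) else e
                   for e in overrides.pop("effect_specs", [])]
        cfg = CohortConfig(seed=self.seed, effect_specs=effects, **overrides)
        return cfg

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(**self.preprocess)


def _sha256_frame(frame: pd.DataFrame) -> str:
    payload = frame.to_csv(float_format="%.12g").encode()
    return hashlib.sha256(payload).hexdigest()


def write_bundle(directory: str | Path, bundle: AnalysisBundle) -> None:
    """Serialize a bundle: long precursor TSV, annotation CSV, truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_precursor_report(directory / "precursor_report.tsv",
                           bundle.quant, bundle.meta)
    write_sample_annotation(directory / "samples.csv", bundle.samples)
    if bundle.ground_truth is not None:
        (directory / "ground_truth.json").write_text(
            bundle.ground_truth.to_json())


def load_bundle(directory: str | Path) -> AnalysisBundle:
    directory = Path(directory)
    quant, meta = read_precursor_report(directory / "precursor_report.tsv")
    samples = read_sample_annotation(directory / "samples.csv")
    truth = None
    truth_path = directory / "ground_truth.json"
    if truth_path.exists():
        truth = GroundTruth.from_json(truth_path.read_text())
    return AnalysisBundle(quant=quant, meta=meta, samples=samples,
                          ground_truth=truth)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}}

    # -- input -------------------------------------------------------------
    if config.precursor_report and config.sample_annotation:
        quant, meta = read_precursor_report(config.precursor_report)
        samples = read_sample_annotation(config.sample_annotation)
        bundle = AnalysisBundle(quant=quant, meta=meta, samples=samples)
        manifest["input"] = {"precursor_report": str(config.precursor_report),
                             "sample_annotation": str(config.sample_annotation)}
    else:
        bundle = simulate_cohort(config.cohort_config())
        manifest["input"] = {"simulated": True,
                             "cohort_seed": config.seed}
    manifest["input"]["matrix_sha256"] = _sha256_frame(bundle.quant.data)

    report = validate_bundle(bundle)
    (outdir / "validation.json").write_text(json.dumps(report.as_dict(),
                                                       indent=1))
    if not report.ok:
        raise PipelineError(
            "validate", f"{len(report.violations)} violations; see "
            f"{outdir / 'validation.json'}")

    # -- QC ----------------------------------------------------------------
    metrics = sample_qc_metrics(bundle.quant, bundle.meta)
    outliers = flag_outlier_samples(metrics, bundle.samples,
                                    z_threshold=config.qc_z_threshold)
    outliers.as_frame().to_csv(outdir / "sample_qc.tsv", sep="\t")
    manifest["stages"]["qc"] = {
        "samples": int(len(metrics)),
        "outliers_flagged": len(outliers.flagged_ids),
    }

    # -- preprocess ----------------------------------------------------------
    params = config.preprocess_params()
    protein, plog = run_preprocess(bundle.quant, bundle.meta, bundle.samples,
                                   params, drop_samples=outliers.flagged_ids)
    write_matrix_tsv(outdir / "protein_matrix.tsv", protein)
    manifest["stages"]["preprocess"] = {
        k: plog[k] for k in ("precursors_before_filter",
                             "precursors_after_filter", "imputed_entries",
                             "proteotypic_precursors", "proteins_summarized")
        if k in plog
    }

    cvs = cv_table(protein, bundle.samples)
    cvs.to_csv(outdir / "cv_table.tsv", sep="\t")
    manifest["stages"]["cv"] = {
        "median_cv_pool_pct": float(np.nanmedian(cvs["cv_pool"])),
        "median_cv_study_pct": float(np.nanmedian(cvs["cv_study"])),
    }

    # -- analysis sample set -------------------------------------------------
    samples = bundle.samples.copy()
    study = analysis_study_samples(samples, outlier_ids=outliers.flagged_ids)
    study = study[study.index.isin(protein.samples)]
    manifest["stages"]["analysis_set"] = {"n_study": int(len(study))}

    # -- exploration ---------------------------------------------------------
    pca = zscore_pca(protein, subset=study.index)
    pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pca.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
    design = build_design(study)
    scan = pc_covariate_scan(pca.scores["PC1"], design)
    scan.to_csv(outdir / "pc1_covariate_scan.tsv", sep="\t", index=False)
    manifest["stages"]["pca"] = {
        "pc1_variance": float(pca.variance_explained.iloc[0]),
        "pc1_top_term": str(scan.iloc[0]["term"]),
    }

    # -- associations ----------------------------------------------------------
    assoc = associate(protein, design, cvs, alpha=config.alpha,
                      cv_threshold_mode=config.cv_threshold_mode)
    assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    sig_col = ("cv_anchored_significant" if config.cv_anchor
               else "stat_significant")
    manifest["stages"]["associate"] = {
        "tests": int(len(assoc)),
        "significant": int(assoc[sig_col].sum()),
    }

    med = medication_scan(protein, study, cvs, atc_level=config.atc_level,
                          min_users=config.min_users, alpha=config.alpha)
    med.summary.to_csv(outdir / "medication_scan.tsv", sep="\t")
    med.records.to_csv(outdir / "medication_records.tsv", sep="\t", index=False)
    manifest["stages"]["medication_scan"] = {
        "codes_tested": len(med.tested_codes)}

    sens = sensitivity_compare(protein, study, cvs, alpha=config.alpha)
    sens.paired_coefficients.to_csv(outdir / "sensitivity_pairs.tsv",
                                    sep="\t", index=False)
    (outdir / "sensitivity.json").write_text(json.dumps({
        term: sorted(sens.misattributed[term]) for term in sens.misattributed
    }, indent=1))
    manifest["stages"]["sensitivity"] = {
        "misattributed_total": int(sum(len(v) for v in
                                       sens.misattributed.values()))}

    # -- contraceptive analyses ------------------------------------------------
    hcu_block: dict = {}
    try:
        women = subgroup_women_under40(study, age_cutoff=config.hcu_age_cutoff)
        sub_assoc = hcu_association(protein, women, cvs, alpha=config.alpha)
        sub_assoc.to_csv(outdir / "hcu_associations.tsv", sep="\t", index=False)
        hcu_rec = sub_assoc[sub_assoc["term"] == "hcu"]
        hcu_block["n_women_under_cutoff"] = int(len(women))
        hcu_block["n_hcu_significant"] = int(hcu_rec[sig_col].sum())

        flags = define_hcu_flag(women)
        cases = list(women.index[flags == 1])
        controls_pool = study.index[(define_hcu_flag(study) == 0)
                                    & study["sex"].notna()
                                    & study["bmi"].notna()]
        if cases and len(controls_pool) >= len(cases):
            top = hcu_rec.reindex(
                hcu_rec["effect_size"].abs().sort_values(ascending=False).index
            ).iloc[0]["protein"]
            matched = propensity_match(study, cases, list(controls_pool),
                                       covariates=config.match_covariates)
            matched.as_frame().to_csv(outdir / "matched_set.csv", index=False)
            ids = matched.case_ids + matched.control_ids
            labels = [1] * len(matched.case_ids) + [0] * len(matched.control_ids)
            roc = roc_auc(protein.data.loc[top, ids].to_numpy(), labels)
            pd.DataFrame({"threshold": roc.thresholds,
                          "sensitivity": roc.sensitivity,
                          "specificity": roc.specificity}).to_csv(
                outdir / "roc_curve.tsv", sep="\t", index=False)
            hcu_block["marker_protein"] = str(top)
            hcu_block["marker_auroc"] = roc.auc

        history = hcu_history_analysis(protein, study, cvs, alpha=config.alpha)
        history.to_csv(outdir / "hcu_history.tsv", sep="\t", index=False)
        hcu_block["previous_vs_never_significant"] = int(
            history.loc[history["term"] == "hcu_previous", sig_col].sum())

        subtype = coc_subtype_effects(protein, study, cvs, alpha=config.alpha)
        if "EE" in subtype and "BE" in subtype:
            comp = compare_group_effects(subtype["EE"]["effect_size"],
                                         subtype["BE"]["effect_size"])
            comp.paired.to_csv(outdir / "ee_be_effects.tsv", sep="\t")
            hcu_block["ee_be_slope"] = comp.slope
            hcu_block["ee_be_r_squared"] = comp.r_squared
    except ValueError as exc:
        hcu_block["skipped"] = str(exc)
    manifest["stages"]["hcu"] = hcu_block

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def run_report(run_directory: str | Path) -> list[Path]:
    """Render the standard figures from a completed run directory.

    Produces: PC1/PC2 scatter colored by HCU, per-term volcano plots,
    sensitivity identity-line plot, EE-vs-BE effect scatter and the marker
    ROC curve.  Every number plotted is read from a TSV artifact.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_directory)
    made: list[Path] = []

    def _save(fig, name: str) -> None:
        path = run / name
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        made.append(path)

    assoc_path = run / "associations.tsv"
    if not assoc_path.exists():
        raise FileNotFoundError(f"missing artifact: {assoc_path}")
    assoc = pd.read_csv(assoc_path, sep="\t")

    scores_path = run / "pca_scores.tsv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(scores["PC1"], scores.get("PC2", scores["PC1"] * 0),
                   s=8, alpha=0.6)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title("z-score PCA of study samples")
        _save(fig, "fig_pca.png")

    fig, axes = plt.subplots(1, max(1, assoc["term"].nunique()),
                             figsize=(3 * assoc["term"].nunique() + 1, 3),
                             squeeze=False)
    if len(assoc):
        for ax, (term, sub) in zip(axes[0], assoc.groupby("term")):
            colors = np.where(sub["cv_anchored_significant"], "crimson", "grey")
            y = -np.log10(np.maximum(sub["p_bonf"], 1e-300))
            ax.scatter(sub["coefficient"], y, s=8, c=colors)
            ax.set_title(term, fontsize=8)
            ax.set_xlabel("log2 coefficient", fontsize=7)
            ax.set_ylabel("-log10 adj. p", fontsize=7)
    else:
        axes[0][0].text(0.5, 0.5, "no significant proteins",
                        ha="center", va="center")
    _save(fig, "fig_volcano.png")

    pairs_path = run / "sensitivity_pairs.tsv"
    if pairs_path.exists():
        pairs = pd.read_csv(pairs_path, sep="\t")
        fig, ax = plt.subplots(figsize=(4, 4))
        for term, sub in pairs.groupby("term"):
            ax.scatter(sub["coef_with"], sub["coef_without"], s=8, label=term,
                       alpha=0.6)
        lim = np.nanmax(np.abs(pairs[["coef_with", "coef_without"]].to_numpy()))
        lim = lim if np.isfinite(lim) and lim > 0 else 1.0
        ax.plot([-lim, lim], [-lim, lim], "k-", lw=0.8)
        ax.set_xlabel("coefficient with HCU term")
        ax.set_ylabel("coefficient without HCU term")
        ax.legend(fontsize=6)
        _save(fig, "fig_sensitivity.png")

    ee_be = run / "ee_be_effects.tsv"
    if ee_be.exists():
        eff = pd.read_csv(ee_be, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(eff["effect_a"], eff["effect_b"], s=10)
        ax.set_xlabel("EE effect size")
        ax.set_ylabel("BE effect size")
        _save(fig, "fig_ee_be.png")

    roc_path = run / "roc_curve.tsv"
    if roc_path.exists():
        roc = pd.read_csv(roc_path, sep="\t")
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(1 - roc["specificity"], roc["sensitivity"], "-")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title("marker ROC")
        _save(fig, "fig_roc.png")

    return made
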