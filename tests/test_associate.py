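import numpy as np
import pandas as pd
import pytest

from plasmacohort.containers import QuantMatrix
from plasmacohort.associate import (
    DEFAULT_TERMS,
    MedicationScanResult,
    RankError,
    analysis_study_samples,
    apply_significance_rule,
    associate,
    bonferroni,
    build_design,
    define_hcu_flag,
    eligible_medications,
    encode_bmi_category,
    fit_per_protein,
    medication_scan,
    sensitivity_compare,
    standardized_effects,
)


def _samples(n, rng, hcu_every=4):
    idx = [f"s{j}" for j in range(n)]
    meds = [[("G03AA07", 1)] if j % hcu_every == 0 else []
            for j in range(n)]
    return pd.DataFrame({
        "role": "study",
        "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        "age": rng.uniform(20, 70, n).round(0),
        "bmi": rng.uniform(17, 35, n).round(1),
        "fasting": rng.integers(0, 2, n),
        "pregnant": 0,
        "medications": meds,
    }, index=idx)


class TestBMIEncoding:
    @pytest.mark.parametrize("bmi,cat", [
        (16.0, 1), (18.4, 1), (18.5, 2), (24.9, 2),
        (25.0, 3), (29.9, 3), (30.0, 4), (45.0, 4)])
    def test_boundaries(self, bmi, cat):
        assert encode_bmi_category(bmi) == cat

    @pytest.mark.parametrize("bad", [0.0, -3.0, float("nan"), float("inf")])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            encode_bmi_category(bad)


class TestHCUFlag:
    def test_definition(self):
        samples = pd.DataFrame({"medications": [
            [("G03AA07", 1)],           # combined oral contraceptive
            [("G03HB01", 0)],           # antiandrogen, irregular still counts
            [("G02BA03", 1)],           # topical: excluded
            [("C07AB02", 1)],           # unrelated drug
            [],
        ]}, index=list("abcde"))
        flags = define_hcu_flag(samples)
        assert list(flags) == [1, 1, 0, 0, 0]


class TestAnalysisStudySamples:
    def test_filters(self, rng):
        s = _samples(20, rng)
        s.loc["s0", "role"] = "pool"
        s.loc["s1", "pregnant"] = 1
        out = analysis_study_samples(s, outlier_ids=["s2", "missing"])
        assert "s0" not in out.index
        assert "s1" not in out.index
        assert "s2" not in out.index
        assert len(out) == 17

    def test_keep_pregnant_option(self, rng):
        s = _samples(10, rng)
        s.loc["s1", "pregnant"] = 1
        out = analysis_study_samples(s, exclude_pregnant=False)
        assert "s1" in out.index


class TestBuildDesign:
    def test_encodings(self, rng):
        s = _samples(40, rng)
        design = build_design(s)
        assert list(design.columns) == [
            "intercept", "sex", "age_decade", "bmi_cat1", "bmi_cat3",
            "bmi_cat4", "fasting", "hcu"]
        np.testing.assert_allclose(design["age_decade"],
                                   s["age"].astype(float) / 10.0)
        assert set(design["sex"].unique()) <= {0.0, 1.0}
        assert design.attrs["n_excluded"] == 0

    def test_missing_covariate_rows_counted(self, rng):
        s = _samples(40, rng)
        s.loc[["s3", "s7"], "bmi"] = np.nan
        design = build_design(s)
        assert design.attrs["n_excluded"] == 2
        assert "s3" not in design.index

    def test_constant_column_raises(self, rng):
        s = _samples(40, rng)
        s["fasting"] = 1
        with pytest.raises(RankError, match="fasting"):
            build_design(s)

    def test_collinear_medication_raises(self, rng):
        s = _samples(40, rng)
        # G03A indicator duplicates the hcu flag exactly
        with pytest.raises(RankError, match="G03A"):
            build_design(s, DEFAULT_TERMS, medication_codes=["G03A"])

    def test_unknown_term_rejected(self, rng):
        with pytest.raises(ValueError):
            build_design(_samples(20, rng), ("sex", "height"))


def _protein_qm(Y, index=None, columns=None):
    return QuantMatrix(
        pd.DataFrame(np.asarray(Y, dtype=float),
                     index=index or [f"P{i}" for i in range(len(Y))],
                     columns=columns),
        scale="log2", level="protein", log={"stage": "summarized"})


class TestFitPerProtein:
    def test_noiseless_recovery(self, rng):
        s = _samples(120, rng)
        design = build_design(s)
        X = design.to_numpy()
        betas = rng.normal(0, 1, size=(8, X.shape[1]))
        Y = betas @ X.T
        q = _protein_qm(Y, columns=design.index)
        out = fit_per_protein(q, design)
        for i in range(8):
            for j, term in enumerate(design.columns):
                if term == "intercept":
                    continue
                got = out[(out["protein"] == f"P{i}")
                          & (out["term"] == term)]["coefficient"].iloc[0]
                assert got == pytest.approx(betas[i, j], abs=1e-10)

    def test_too_few_samples(self, rng):
        s = _samples(8, rng)
        design = build_design(s, ("sex", "age_decade", "bmi", "fasting", "hcu"))
        q = _protein_qm(rng.normal(size=(3, len(design))),
                        columns=design.index)
        with pytest.raises(ValueError, match="samples"):
            fit_per_protein(q, design)

    def test_matches_scipy_reference(self, rng):
        from scipy import stats as sps
        n = 60
        x = rng.normal(0, 1, n)
        y = 0.7 * x + rng.normal(0, 0.5, n)
        design = pd.DataFrame({"intercept": 1.0, "x": x},
                              index=[f"s{j}" for j in range(n)])
        q = _protein_qm([y], columns=design.index)
        out = fit_per_protein(q, design).iloc[0]
        ref = sps.linregress(x, y)
        assert out["coefficient"] == pytest.approx(ref.slope, abs=1e-12)
        assert out["p"] == pytest.approx(ref.pvalue, rel=1e-9)


class TestBonferroni:
    def test_formula_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.4], 5), [0.05, 1.0])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bonferroni([0.5], 0)
        with pytest.raises(ValueError):
            bonferroni([1.5], 3)
        with pytest.raises(ValueError):
            bonferroni([np.nan], 3)


class TestSignificanceRule:
    def _records(self):
        return pd.DataFrame({
            "protein": ["P1", "P2", "P3", "P4"],
            "term": ["hcu"] * 4,
            "coefficient": [0.5, 0.05, 0.5, 0.5],
            "se": 0.01, "t": 10.0,
            "p": [1e-6, 1e-6, 0.5, 1e-6],
        })

    def _cv(self):
        return pd.DataFrame({"cv_pool": [10.0, 10.0, 10.0, np.nan]},
                            index=["P1", "P2", "P3", "P4"])

    def test_dual_rule_literal(self):
        out = apply_significance_rule(self._records(), self._cv())
        out = out.set_index("protein")
        # P1: small p and |0.5| > 0.10 -> both flags
        assert out.loc["P1", "stat_significant"]
        assert out.loc["P1", "cv_anchored_significant"]
        # P2: significant but coefficient below the CV anchor
        assert out.loc["P2", "stat_significant"]
        assert not out.loc["P2", "cv_anchored_significant"]
        # P3: large p
        assert not out.loc["P3", "stat_significant"]
        # P4: no pool CV -> never anchored
        assert not out.loc["P4", "cv_pool_defined"]
        assert not out.loc["P4", "cv_anchored_significant"]

    def test_bonferroni_family_is_proteins_within_term(self):
        out = apply_significance_rule(self._records(), self._cv())
        np.testing.assert_allclose(out["p_bonf"],
                                   np.minimum(1.0, out["p"] * 4))

    def test_log_sd_mode_threshold(self):
        out = apply_significance_rule(self._records(), self._cv(),
                                      cv_threshold_mode="log_sd")
        # log-normal sd in log2 units for CV 10%:
        thr = np.sqrt(np.log(1.0 + 0.01)) / np.log(2.0)
        assert thr < 0.5
        assert out.set_index("protein").loc["P1", "cv_anchored_significant"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            apply_significance_rule(self._records(), self._cv(),
                                    cv_threshold_mode="both")


class TestStandardizedEffects:
    def test_effect_size_is_coef_over_sd(self, rng):
        s = _samples(80, rng)
        design = build_design(s)
        Y = rng.normal(12, 1, size=(5, len(design)))
        q = _protein_qm(Y, columns=design.index)
        out = standardized_effects(q, design)
        sd = q.data.std(axis=1, ddof=1)
        np.testing.assert_allclose(
            out["effect_size"],
            out["coefficient"] / out["protein"].map(sd).to_numpy())


class TestMedicationScan:
    def test_eligible_counts_and_cutoff(self, rng):
        s = _samples(60, rng, hcu_every=3)  # 20 users of G03AA07
        counts, tested = eligible_medications(s, atc_level=3, min_users=15)
        assert counts["G03A"] == 20
        assert tested == ["G03A"]
        _, none = eligible_medications(s, atc_level=3, min_users=25)
        assert none == []

    def test_level4_truncation(self, rng):
        s = _samples(60, rng, hcu_every=3)
        counts, _ = eligible_medications(s, atc_level=4, min_users=1)
        assert counts["G03AA"] == 20

    def test_scan_detects_injected_association(self, protein_bundle,
                                               protein_cvs, protein_study):
        res = medication_scan(protein_bundle.quant, protein_study,
                              protein_cvs, min_users=10)
        assert isinstance(res, MedicationScanResult)
        assert "G03A" in res.tested_codes
        assert res.n_significant("G03A") >= 1
        assert res.summary.loc["G03A", "tested"]

    def test_empty_result_when_no_eligible_codes(self, protein_bundle,
                                                 protein_cvs, protein_study):
        res = medication_scan(protein_bundle.quant, protein_study,
                              protein_cvs, min_users=10 ** 6)
        assert res.tested_codes == []
        assert res.records.empty


class TestSensitivityCompare:
    def test_structure_and_misattribution_subsets(self, protein_bundle,
                                                  protein_cvs, protein_study):
        report = sensitivity_compare(protein_bundle.quant, protein_study,
                                     protein_cvs)
        for term in report.misattributed:
            assert report.misattributed[term] <= report.hcu_significant
            assert report.misattributed[term] <= \
                report.newly_significant(term)
        assert {"protein", "term", "coef_with", "coef_without"} <= \
            set(report.paired_coefficients.columns)
        # injected HCU effects are found in the full model
        assert len(report.hcu_significant) >= 1
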