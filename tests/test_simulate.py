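import numpy as np
import pandas as pd
import pytest

from plasmacohort.simulate import (
    CohortConfig,
    EffectSpec,
    GroundTruth,
    generate_cohort,
    generate_protein_bundle,
    inject_missingness,
    inject_outlier_samples,
    missingness_probability,
    simulate_cohort,
)


class TestPlateLayout:
    def test_full_plate_composition(self):
        cfg = CohortConfig(n_study_samples=158, n_plates=2, n_proteins=10,
                           seed=1)
        bundle = generate_cohort(cfg)
        for _, plate in bundle.samples.groupby("plate"):
            counts = plate["role"].value_counts()
            assert counts["study"] == 79
            assert counts["pool"] == 4
            assert counts["blank"] == 1
            assert counts["commercial_serum"] == 4
            assert counts["commercial_plasma"] == 8
            assert len(plate) == 96

    def test_partial_last_plate(self):
        cfg = CohortConfig(n_study_samples=100, n_plates=2, n_proteins=10,
                           seed=1)
        bundle = generate_cohort(cfg)
        assert (bundle.samples["role"] == "study").sum() == 100
        # QC complement is present on every plate regardless of fill level
        for _, plate in bundle.samples.groupby("plate"):
            assert (plate["role"] == "pool").sum() == 4

    def test_layout_overflow_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(wells_per_plate_study=90).validate()
        with pytest.raises(ValueError):
            CohortConfig(n_study_samples=200, n_plates=2).validate()


class TestDeterminism:
    def test_same_seed_same_bundle(self):
        cfg = CohortConfig(n_study_samples=79, n_plates=1, n_proteins=12,
                           seed=321)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.quant.data, b.quant.data)
        pd.testing.assert_frame_equal(
            a.samples.drop(columns="medications"),
            b.samples.drop(columns="medications"))
        assert list(a.samples["medications"]) == list(b.samples["medications"])

    def test_different_seed_differs(self):
        base = dict(n_study_samples=79, n_plates=1, n_proteins=12)
        a = simulate_cohort(CohortConfig(seed=1, **base))
        b = simulate_cohort(CohortConfig(seed=2, **base))
        assert not a.quant.data.equals(b.quant.data)


class TestDemographics:
    def test_hcu_only_in_women(self, small_bundle):
        from plasmacohort.associate import define_hcu_flag
        study = small_bundle.samples[small_bundle.samples["role"] == "study"]
        users = study[define_hcu_flag(study) == 1]
        assert len(users) > 0
        assert (users["sex"] == "F").all()

    def test_hcu_age_weighted(self):
        cfg = CohortConfig(n_study_samples=790, n_plates=10, n_proteins=5,
                           seed=9)
        bundle = generate_cohort(cfg)
        from plasmacohort.associate import define_hcu_flag
        study = bundle.samples[bundle.samples["role"] == "study"]
        women = study[study["sex"] == "F"]
        young = women[women["age"] < 40]
        old = women[women["age"] >= 50]
        assert define_hcu_flag(young).mean() > 5 * max(
            define_hcu_flag(old).mean(), 0.01)

    def test_history_levels_consistent(self, small_bundle):
        study = small_bundle.samples[small_bundle.samples["role"] == "study"]
        men = study[study["sex"] == "M"]
        assert set(men["hcu_history"].dropna()) <= {"never"}
        from plasmacohort.associate import define_hcu_flag
        current = study[define_hcu_flag(study) == 1]
        assert (current["hcu_history"] == "current").all()


class TestEffectInjection:
    def test_injected_effect_shifts_group_means(self):
        cfg = CohortConfig(n_study_samples=316, n_plates=4, n_proteins=10,
                           effect_specs=[EffectSpec("P0001", "sex", 1.0)],
                           seed=4)
        bundle = generate_protein_bundle(cfg)
        study = bundle.samples[bundle.samples["role"] == "study"]
        values = bundle.quant.data.loc["P0001", study.index]
        women = values[study["sex"] == "F"]
        men = values[study["sex"] == "M"]
        diff = women.mean() - men.mean()
        assert 0.8 < diff < 1.2

    def test_pools_carry_no_effects(self):
        cfg = CohortConfig(n_study_samples=79, n_plates=1, n_proteins=8,
                           effect_specs=[EffectSpec("P0001", "sex", 5.0)],
                           seed=4)
        bundle = generate_protein_bundle(cfg)
        pools = bundle.samples.index[bundle.samples["role"] == "pool"]
        pool_sd = bundle.quant.data.loc["P0001", pools].std(ddof=1)
        assert pool_sd < 1.0  # technical noise only, no 5-log2 split

    def test_unknown_effect_covariate_rejected(self):
        cfg = CohortConfig(n_study_samples=79, n_plates=1, n_proteins=5,
                           effect_specs=[EffectSpec("P0001", "shoe_size", 1.0)],
                           seed=4)
        with pytest.raises(ValueError):
            generate_cohort(cfg)


class TestGroundTruth:
    def test_offsets_sum_to_zero(self, small_bundle):
        truth = small_bundle.ground_truth
        assert np.allclose(truth.plate_offsets.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(truth.batch_offsets.sum(axis=1), 0.0, atol=1e-12)

    def test_masked_entries_recover_matrix(self):
        cfg = CohortConfig(n_study_samples=79, n_plates=1, n_proteins=10,
                           seed=6)
        full = generate_cohort(cfg)
        values_before = full.quant.data.copy()
        masked = inject_missingness(full.quant, cfg, full.ground_truth)
        ledger = full.ground_truth.masked_entries
        assert len(ledger) == masked.n_missing
        restored = masked.data.copy()
        for row in ledger.itertuples():
            restored.loc[row.feature, row.run] = row.value
        pd.testing.assert_frame_equal(restored, values_before)

    def test_json_round_trip(self, small_bundle):
        truth = small_bundle.ground_truth
        back = GroundTruth.from_json(truth.to_json())
        pd.testing.assert_series_equal(back.baseline, truth.baseline)
        pd.testing.assert_frame_equal(back.plate_offsets, truth.plate_offsets)
        assert back.outlier_samples == truth.outlier_samples
        assert [e.protein_id for e in back.effects] == \
            [e.protein_id for e in truth.effects]


class TestMissingness:
    def test_probability_monotone_in_intensity(self):
        q = np.linspace(5, 20, 50)
        p = missingness_probability(q, 0.02, 1.2, 9.0)
        assert np.all(np.diff(p) <= 0)
        assert np.all((p >= 0.02) & (p <= 1.0))

    def test_low_intensity_misses_more(self, small_bundle):
        truth_values = np.log2(
            pd.concat([small_bundle.ground_truth.masked_entries["value"]]))
        observed = np.log2(small_bundle.quant.values)
        assert truth_values.mean() < np.nanmean(observed)

    def test_zero_rates_no_missingness(self):
        cfg = CohortConfig(n_study_samples=79, n_plates=1, n_proteins=5,
                           mcar_rate=0.0, mnar_midpoint=-50.0, seed=2)
        bundle = generate_cohort(cfg)
        out = inject_missingness(bundle.quant, cfg)
        assert out.n_missing == 0


class TestOutliers:
    def test_count_and_ledger(self):
        cfg = CohortConfig(n_study_samples=158, n_plates=2, n_proteins=20,
                           outlier_fraction=0.05, seed=10)
        bundle = simulate_cohort(cfg)
        expected = round(0.05 * 158)
        assert len(bundle.ground_truth.outlier_samples) == expected
        roles = bundle.samples.loc[bundle.ground_truth.outlier_samples, "role"]
        assert (roles == "study").all()

    def test_degradation_shifts_composition(self):
        cfg = CohortConfig(n_study_samples=158, n_plates=2, n_proteins=30,
                           outlier_fraction=0.04, seed=11)
        bundle = simulate_cohort(cfg)
        from plasmacohort.qc import sample_qc_metrics
        metrics = sample_qc_metrics(bundle.quant, bundle.meta)
        out_ids = bundle.ground_truth.outlier_samples
        study = bundle.samples.index[bundle.samples["role"] == "study"]
        rest = [s for s in study if s not in out_ids]
        assert metrics.loc[out_ids, "n_detected_precursors"].mean() < \
            0.6 * metrics.loc[rest, "n_detected_precursors"].mean()

    def test_fraction_bounds(self, small_bundle):
        with pytest.raises(ValueError):
            inject_outlier_samples(small_bundle, 1.5)


class TestCalibration:
    def test_pool_cv_median_in_band(self):
        """technical_sd=0.21 log2 puts the median pool CV in [12%, 19%]."""
        from plasmacohort.qc import cv_table
        rng = np.random.default_rng(2024)
        medians = []
        for _ in range(20):
            cfg = CohortConfig(n_study_samples=79, n_plates=1, n_proteins=60,
                               seed=int(rng.integers(2 ** 31)))
            bundle = generate_protein_bundle(cfg)
            cvs = cv_table(bundle.quant, bundle.samples)
            medians.append(float(np.nanmedian(cvs["cv_pool"])))
        assert 12.0 <= float(np.median(medians)) <= 19.0


class TestProteinShortcut:
    def test_matches_precursor_route_in_structure(self):
        cfg = CohortConfig(n_study_samples=79, n_plates=1, n_proteins=15,
                           seed=3)
        bundle = generate_protein_bundle(cfg)
        assert bundle.quant.level == "protein"
        assert bundle.quant.scale == "log2"
        assert bundle.quant.fully_observed
        assert len(bundle.quant.features) == 15
        pd.testing.assert_index_equal(bundle.quant.samples,
                                      bundle.samples.index)
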