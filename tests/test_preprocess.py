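import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plasmacohort.containers import QuantMatrix, StateError
from plasmacohort.preprocess import (
    PreprocessParams,
    column_mean_impute,
    cyclic_loess_normalize,
    filter_missing_precursors,
    knn_impute,
    log2_transform,
    median_polish,
    median_polish_summarize,
    remove_plate_effects,
    run_preprocess,
)


def oracle_median_polish(block, tol=1e-6, max_iter=50):
    """Independent median-polish oracle: plain-Python row/column median
    sweeps with effect recentering, as Tukey describes the procedure."""
    b = [[float(v) for v in row] for row in block]
    n_rows, n_cols = len(b), len(b[0])
    overall = 0.0
    row_eff = [0.0] * n_rows
    col_eff = [0.0] * n_cols
    for _ in range(max_iter):
        largest = 0.0
        for i in range(n_rows):
            med = statistics.median(b[i])
            largest = max(largest, abs(med))
            row_eff[i] += med
            for j in range(n_cols):
                b[i][j] -= med
        shift = statistics.median(row_eff)
        overall += shift
        row_eff = [r - shift for r in row_eff]

        for j in range(n_cols):
            med = statistics.median([b[i][j] for i in range(n_rows)])
            largest = max(largest, abs(med))
            col_eff[j] += med
            for i in range(n_rows):
                b[i][j] -= med
        shift = statistics.median(col_eff)
        overall += shift
        col_eff = [c - shift for c in col_eff]
        if largest < tol:
            break
    return overall, row_eff, col_eff, b


def _qm(arr, scale="linear", level="precursor", stage=None):
    arr = np.asarray(arr, dtype=float)
    log = {} if stage is None else {"stage": stage}
    return QuantMatrix(
        pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        scale=scale, level=level, log=log)


def _roles(n_study, n_pool=0):
    roles = ["study"] * n_study + ["pool"] * n_pool
    return pd.DataFrame({"role": roles, "ms_batch": "b1", "plate": "p1"},
                        index=[f"s{j}" for j in range(len(roles))])


class TestStageOrder:
    def test_impute_before_filter_allowed_but_not_after_log2(self):
        q = _qm([[1.0, 2.0]] * 12, stage="log2", scale="log2")
        with pytest.raises(StateError):
            knn_impute(q, _roles(2))

    def test_normalize_requires_log2_stage(self, small_bundle):
        q = _qm(np.random.default_rng(0).uniform(1, 2, (40, 6)),
                stage="normalized", scale="log2")
        with pytest.raises(StateError):
            cyclic_loess_normalize(q)

    def test_summarize_rejects_unnormalized_linear(self):
        q = _qm([[1.0, 2.0]], scale="linear")
        with pytest.raises(StateError):
            median_polish_summarize(q, pd.DataFrame())

    def test_filter_rejects_filtered_matrix(self):
        q = _qm([[1.0, 2.0]], stage="filtered")
        with pytest.raises(StateError):
            filter_missing_precursors(q, _roles(2))


class TestMissingFilter:
    def test_strictly_greater_than_threshold(self):
        # 4 study samples: 2 missing = 50% > 40% -> dropped;
        # 1 missing = 25% <= 40% -> kept; missing in pools ignored.
        arr = np.array([
            [1.0, 2.0, np.nan, np.nan, np.nan],
            [1.0, 2.0, 3.0, np.nan, np.nan],
            [1.0, 2.0, 3.0, 4.0, np.nan],
        ])
        q = _qm(arr)
        out = filter_missing_precursors(q, _roles(4, n_pool=1))
        assert list(out.features) == ["f1", "f2"]
        assert out.log["precursors_before_filter"] == 3
        assert out.log["precursors_after_filter"] == 2

    def test_exact_boundary_kept(self):
        # exactly 40% missing (2 of 5) is kept (strict > rule)
        arr = np.array([[1.0, 2.0, 3.0, np.nan, np.nan]])
        out = filter_missing_precursors(_qm(arr), _roles(5))
        assert len(out.features) == 1


class TestKnnImpute:
    def test_output_fully_observed(self, small_bundle):
        filtered = filter_missing_precursors(small_bundle.quant,
                                             small_bundle.samples)
        imputed = knn_impute(filtered, small_bundle.samples)
        assert imputed.fully_observed
        assert imputed.log["imputed_entries"] == filtered.n_missing

    def test_observed_entries_untouched(self, small_bundle):
        filtered = filter_missing_precursors(small_bundle.quant,
                                             small_bundle.samples)
        imputed = knn_impute(filtered, small_bundle.samples)
        mask = ~filtered.data.isna()
        pd.testing.assert_frame_equal(imputed.data[mask], filtered.data[mask])

    def test_uses_neighbor_rows(self):
        # 11 identical rows + 1 row with a hole: the nearest rows carry the
        # exact value, so imputation is exact.
        base = np.tile(np.arange(1.0, 7.0), (12, 1))
        base[0, 3] = np.nan
        out = knn_impute(_qm(base), _roles(6), k=9)
        assert out.data.iloc[0, 3] == pytest.approx(4.0)

    def test_k_larger_than_rows_rejected(self):
        q = _qm(np.ones((5, 4)))
        with pytest.raises(ValueError):
            knn_impute(q, _roles(4), k=9)

    def test_batch_locality(self):
        # the missing entry's donors live in the same batch: giving batch 2
        # wildly different values must not leak into batch 1's imputation
        rng = np.random.default_rng(5)
        arr = np.tile(np.arange(1.0, 5.0), (12, 1))
        arr = np.hstack([arr, arr + 1000.0])
        arr[0, 1] = np.nan
        samples = pd.DataFrame({
            "role": "study",
            "ms_batch": ["b1"] * 4 + ["b2"] * 4,
            "plate": "p1"},
            index=[f"s{j}" for j in range(8)])
        q = QuantMatrix(pd.DataFrame(
            arr, index=[f"f{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(8)]))
        out = knn_impute(q, samples, k=9)
        assert out.data.iloc[0, 1] == pytest.approx(2.0)


class TestLog2:
    def test_values(self):
        out = log2_transform(_qm([[2.0, 8.0]]))
        np.testing.assert_allclose(out.values, [[1.0, 3.0]])
        assert out.scale == "log2"

    def test_rejects_nonpositive(self):
        with pytest.raises(StateError):
            log2_transform(_qm([[1.0]], scale="log2"))


class TestCyclicLoess:
    def test_removes_constant_offsets(self):
        rng = np.random.default_rng(0)
        base = rng.normal(13, 1.5, size=200)
        data = base[:, None] + rng.normal(0, 0.05, size=(200, 8))
        data[:, 0] += 0.5
        data[:, 1] -= 0.5
        out = cyclic_loess_normalize(_qm(data, scale="log2"))
        col_means = out.values.mean(axis=0)
        assert np.max(np.abs(col_means - col_means.mean())) < 0.01

    def test_requires_fully_observed(self):
        data = np.random.default_rng(0).normal(13, 1, (40, 4))
        data[0, 0] = np.nan
        with pytest.raises(StateError):
            cyclic_loess_normalize(_qm(data, scale="log2"))

    def test_warns_below_30_features(self):
        data = np.random.default_rng(0).normal(13, 1, (10, 4))
        with pytest.warns(UserWarning):
            cyclic_loess_normalize(_qm(data, scale="log2"))


class TestPlateCorrection:
    def test_single_plate_noop(self):
        data = np.random.default_rng(0).normal(13, 1, (5, 6))
        q = _qm(data, scale="log2")
        out = remove_plate_effects(q, _roles(6))
        np.testing.assert_array_equal(out.values, data)
        assert out.log["plate_correction"] == "single plate: no-op"

    def test_grand_means_preserved(self):
        rng = np.random.default_rng(1)
        data = rng.normal(13, 1, (20, 12))
        samples = pd.DataFrame(
            {"plate": ["p1"] * 6 + ["p2"] * 6},
            index=[f"s{j}" for j in range(12)])
        out = remove_plate_effects(_qm(data, scale="log2"), samples)
        np.testing.assert_allclose(out.values.mean(axis=1),
                                   data.mean(axis=1), atol=1e-10)

    def test_removes_known_offsets(self):
        rng = np.random.default_rng(2)
        base = rng.normal(13, 1, (30, 1))
        data = np.hstack([base + 0.4 + rng.normal(0, 0.01, (30, 8)),
                          base - 0.4 + rng.normal(0, 0.01, (30, 8))])
        samples = pd.DataFrame(
            {"plate": ["p1"] * 8 + ["p2"] * 8},
            index=[f"s{j}" for j in range(16)])
        out = remove_plate_effects(_qm(data, scale="log2"), samples)
        gap = (out.values[:, :8].mean(axis=1)
               - out.values[:, 8:].mean(axis=1))
        assert np.max(np.abs(gap)) < 0.02


class TestMedianPolish:
    def test_decomposition_identity(self, rng):
        block = rng.normal(0, 1, size=(6, 7))
        overall, row, col, resid = median_polish(block)
        np.testing.assert_allclose(
            overall + row[:, None] + col[None, :] + resid, block, atol=1e-12)

    def test_pure_additive_exact(self):
        row = np.array([0.0, 1.0, -1.0])
        col = np.array([2.0, -2.0, 0.0, 0.0])
        block = 5.0 + row[:, None] + col[None, :]
        overall, r, c, resid = median_polish(block)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)
        np.testing.assert_allclose(overall + c, 5.0 + col, atol=1e-9)

    def test_matches_independent_oracle_on_random_blocks(self, rng):
        for _ in range(200):
            shape = (int(rng.integers(1, 9)), int(rng.integers(1, 9)))
            block = rng.normal(10, 2, size=shape)
            overall, _, col, _ = median_polish(block)
            o_overall, _, o_col, _ = oracle_median_polish(block.tolist())
            np.testing.assert_allclose(overall + col,
                                       o_overall + np.asarray(o_col),
                                       atol=1e-8)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=1, max_value=6),
           st.integers(min_value=1, max_value=6),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_outlier_cell_resistance(self, nr, nc, seed):
        # a single wild cell moves the summarized profile by at most its
        # residual share; identity always holds
        r = np.random.default_rng(seed)
        block = r.normal(0, 1, size=(nr, nc))
        overall, row, col, resid = median_polish(block)
        np.testing.assert_allclose(
            overall + row[:, None] + col[None, :] + resid, block, atol=1e-10)


class TestSummarize:
    def test_non_proteotypic_excluded(self):
        data = np.array([[10.0, 10.0], [10.0, 10.0], [99.0, 99.0]])
        q = _qm(data, scale="log2")
        meta = pd.DataFrame({
            "protein_group": ["P1", "P1", "P1"],
            "proteotypic": [True, True, False],
            "charge": [2, 2, 2], "missed_cleavages": [0, 0, 0],
            "peptide_length": [9, 9, 9]}, index=q.features)
        out = median_polish_summarize(q, meta)
        np.testing.assert_allclose(out.data.loc["P1"], [10.0, 10.0])
        assert out.log["proteotypic_precursors"] == 2

    def test_protein_without_proteotypic_dropped(self):
        data = np.array([[10.0, 10.0], [12.0, 12.0]])
        q = _qm(data, scale="log2")
        meta = pd.DataFrame({
            "protein_group": ["P1", "P2"],
            "proteotypic": [True, False],
            "charge": [2, 2], "missed_cleavages": [0, 0],
            "peptide_length": [9, 9]}, index=q.features)
        out = median_polish_summarize(q, meta)
        assert list(out.features) == ["P1"]
        assert out.log["proteins_dropped_no_proteotypic"] == ["P2"]

    def test_offset_precursors_summarize_to_shifted_profile(self):
        # two precursors of one protein differing by a fixed ionization
        # offset: the summarized profile tracks the common sample effect
        sample_effect = np.array([0.0, 1.0, -1.0, 0.5])
        block = np.vstack([12.0 + sample_effect, 9.0 + sample_effect])
        q = _qm(block, scale="log2")
        meta = pd.DataFrame({
            "protein_group": ["P1", "P1"], "proteotypic": [True, True],
            "charge": [2, 2], "missed_cleavages": [0, 0],
            "peptide_length": [9, 9]}, index=q.features)
        out = median_polish_summarize(q, meta)
        profile = out.data.loc["P1"].to_numpy()
        np.testing.assert_allclose(np.diff(profile),
                                   np.diff(10.5 + sample_effect), atol=1e-9)


class TestRunPreprocess:
    def test_end_to_end_chain(self, small_bundle):
        protein, log = run_preprocess(small_bundle.quant, small_bundle.meta,
                                      small_bundle.samples)
        assert protein.level == "protein"
        assert protein.scale == "log2"
        assert protein.fully_observed
        assert log["stage"] == "summarized"
        assert log["precursors_after_filter"] <= log["precursors_before_filter"]

    def test_drop_samples_removed(self, small_bundle):
        victims = list(small_bundle.quant.samples[:2])
        protein, _ = run_preprocess(small_bundle.quant, small_bundle.meta,
                                    small_bundle.samples,
                                    drop_samples=victims)
        assert not set(victims) & set(protein.samples)

    def test_params_validated(self, small_bundle):
        with pytest.raises(ValueError):
            run_preprocess(small_bundle.quant, small_bundle.meta,
                           small_bundle.samples,
                           PreprocessParams(knn_k=0))


class TestColumnMeanImpute:
    def test_fills_with_sample_mean(self):
        arr = np.array([[1.0, np.nan], [3.0, 4.0]])
        out = column_mean_impute(_qm(arr))
        assert out.data.iloc[0, 1] == pytest.approx(4.0)
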