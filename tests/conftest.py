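"""Shared fixtures: one small precursor-level cohort and one mid-size
protein-level cohort, both seeded, reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from plasmacohort import (
    CohortConfig,
    EffectSpec,
    analysis_study_samples,
    cv_table,
    generate_protein_bundle,
    remove_plate_effects,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_bundle():
    """Precursor-level cohort with missingness and injected outliers."""
    cfg = CohortConfig(
        n_study_samples=158, n_plates=2, n_proteins=40,
        effect_specs=[EffectSpec("P0001", "hcu", 1.2),
                      EffectSpec("P0002", "sex", 0.6)],
        outlier_fraction=0.02, seed=20240601,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_bundle():
    """Fully observed precursor-level cohort (no missingness injected)."""
    from plasmacohort import generate_cohort
    cfg = CohortConfig(n_study_samples=79, n_plates=1, n_proteins=25,
                       seed=77)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def protein_bundle():
    """Protein-level cohort (generator shortcut), plate-corrected."""
    cfg = CohortConfig(
        n_study_samples=400, n_plates=6, n_proteins=60,
        effect_specs=[EffectSpec(f"P{i + 1:04d}", "hcu", b)
                      for i, b in enumerate([1.5, -1.2, 0.9, 0.8, -0.7])],
        seed=55,
    )
    bundle = generate_protein_bundle(cfg)
    bundle.quant = remove_plate_effects(bundle.quant, bundle.samples)
    return bundle


@pytest.fixture(scope="session")
def protein_cvs(protein_bundle):
    return cv_table(protein_bundle.quant, protein_bundle.samples)


@pytest.fixture(scope="session")
def protein_study(protein_bundle):
    return analysis_study_samples(protein_bundle.samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


@pytest.fixture()
def tiny_samples():
    """Hand-built six-sample annotation table for schema-level tests."""
    meds = [[("G03AA07", 1)], [], [("C07AB02", 1), ("N02BE01", 0)],
            [], [], []]
    return pd.DataFrame({
        "role": ["study", "study", "study", "study", "pool", "blank"],
        "plate": ["p1"] * 6,
        "well": ["A1", "A2", "A3", "A4", "H9", "H10"],
        "ms_batch": ["b1"] * 6,
        "sex": ["F", "M", "F", "M", pd.NA, pd.NA],
        "age": [25.0, 60.0, 35.0, 45.0, np.nan, np.nan],
        "bmi": [22.0, 31.0, 24.0, 27.5, np.nan, np.nan],
        "fasting": pd.array([0, 1, 0, 0, pd.NA, pd.NA], dtype="Int64"),
        "pregnant": pd.array([0, pd.NA, 0, pd.NA, pd.NA, pd.NA], dtype="Int64"),
        "ever_pregnant": pd.array([0, pd.NA, 1, pd.NA, pd.NA, pd.NA],
                                  dtype="Int64"),
        "hcu_history": ["current", pd.NA, "never", pd.NA, pd.NA, pd.NA],
        "medications": meds,
    }, index=pd.Index([f"run{i}" for i in range(1, 7)], name="run"))
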