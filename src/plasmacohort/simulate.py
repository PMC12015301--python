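"""Synthetic plasma-proteomics cohort generator.

Emulates the structure of a population-cohort DIA plasma proteome experiment:
96-well preparation plates carrying 79 study samples, 4 replicates of a pooled
QC sample, 1 procedural blank, 4 commercial serum and 8 commercial plasma
wells; plates grouped into MS acquisition batches; ~150 proteins each
represented by several peptide precursors; log-normal abundances with additive
log2 covariate effects (sex, age per decade, BMI category, fasting, hormonal
contraceptive use, other ATC-coded medications), plate and batch offsets,
per-protein biological and technical noise; intensity-dependent plus random
missingness; and optionally a minority of degraded outlier samples.

Every random draw that downstream recovery tests need (injected effects,
baselines, plate/batch offsets, noise scales, masked entries, outlier ids) is
recorded in a :class:`GroundTruth` object attached to the generated bundle.

Defaults are calibrated so that pooled-QC protein CVs land near a 15% median
(technical noise of 0.21 log2 units) and study CVs near 31%, the precision
regime of cohort-scale short-gradient DIA plasma data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    AnalysisBundle,
    QuantMatrix,
    validate_precursor_meta,
    validate_sample_table,
)

__all__ = [
    "DemographicParams",
    "EffectSpec",
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_protein_bundle",
    "inject_missingness",
    "inject_outlier_samples",
    "simulate_cohort",
]

# Fixed QC complement of a 96-well plate, in addition to the study wells.
POOLS_DEFAULT = 4
BLANKS_PER_PLATE = 1
SERUM_PER_PLATE = 4
PLASMA_PER_PLATE = 8

# Oral-contraceptive preparation codes the generator samples for current
# hormonal-contraceptive users, by estrogen class of the preparation.
EE_PREPARATIONS = ("G03AA07", "G03AA09", "G03AA10", "G03AA12", "G03AB04")
BE_PREPARATIONS = ("G03AA14", "G03AB08")
P4_PREPARATIONS = ("G03AC09",)
NON_ORAL_PREPARATIONS = ("G03AC08",)


@dataclass
class DemographicParams:
    """Marginal distributions of the study-sample covariates."""

    age_range: tuple[float, float] = (18.0, 85.0)
    female_fraction: float = 0.56
    bmi_mean: float = 25.5
    bmi_sd: float = 4.3
    bmi_min: float = 15.0
    fasting_rate: float = 0.062          # fraction reporting a meal < 12 h
    pregnancy_rate: float = 0.02         # current pregnancy, women <= 45
    previous_hcu_fraction: float = 0.79  # previous use among non-current women < 55
    #: class probabilities for the preparation a current user takes
    coc_class_probs: tuple[float, float, float, float] = (0.88, 0.06, 0.02, 0.04)


@dataclass(frozen=True)
class EffectSpec:
    """One injected covariate effect: ``beta`` log2 units per covariate unit.

    ``covariate`` is a design-vocabulary name (``sex``, ``age_decade``,
    ``bmi_cat1``/``bmi_cat3``/``bmi_cat4``, ``fasting``, ``hcu``) or an ATC
    code, in which case the indicator is 1 for samples regularly taking a
    medication whose code truncates to it.
    """

    protein_id: str
    covariate: str
    beta: float


@dataclass
class CohortConfig:
    """Full parameterization of one synthetic cohort."""

    n_study_samples: int = 790
    n_plates: int = 10
    wells_per_plate_study: int = 79
    pools_per_plate: int = POOLS_DEFAULT
    plates_per_batch: int = 3
    n_proteins: int = 148
    precursors_per_protein: tuple[int, int] = (2, 6)
    frac_proteotypic: float = 0.85
    hcu_prevalence_women_under40: float = 0.38
    demographics: DemographicParams = field(default_factory=DemographicParams)
    effect_specs: list[EffectSpec] = field(default_factory=list)
    #: prevalence of additional (non-contraceptive) regular medications
    medication_prevalence: dict[str, float] = field(default_factory=dict)
    baseline_mean: float = 13.0      # log2 units
    baseline_sd: float = 1.5
    plate_sd: float = 0.05           # log2, per protein x plate
    batch_sd: float = 0.05           # log2, per protein x MS batch
    biological_sd: float = 0.38      # log2, typical per-protein value
    technical_sd: float = 0.21       # log2; 0.21 ~ 15% linear CV
    biological_sd_spread: float = 0.3   # lognormal sigma of per-protein spread
    technical_sd_spread: float = 0.15
    precursor_offset_sd: float = 1.0    # fixed ionization offset per precursor
    precursor_noise_sd: float = 0.05    # per precursor x sample
    precursor_interaction_sd: float = 0.0  # optional precursor x sample terms
    blank_level: float = 6.0         # log2 noise floor of procedural blanks
    role_offset_sd: float = 0.5      # commercial serum/plasma vs pool profile
    mcar_rate: float = 0.02
    mnar_slope: float = 1.2          # logistic steepness on log2 intensity
    mnar_midpoint: float = 9.0       # log2 intensity of 50% detection
    outlier_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_proteotypic": self.frac_proteotypic,
            "hcu_prevalence_women_under40": self.hcu_prevalence_women_under40,
            "mcar_rate": self.mcar_rate,
            "outlier_fraction": self.outlier_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.frac_proteotypic <= 0:
            raise ValueError("frac_proteotypic must be > 0")
        for name in ("plate_sd", "batch_sd", "biological_sd", "technical_sd",
                     "precursor_offset_sd", "precursor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        fixed = BLANKS_PER_PLATE + SERUM_PER_PLATE + PLASMA_PER_PLATE
        if self.wells_per_plate_study + self.pools_per_plate + fixed > 96:
            raise ValueError(
                "plate layout exceeds 96 wells: "
                f"{self.wells_per_plate_study} study + {self.pools_per_plate} pools "
                f"+ {fixed} fixed QC wells"
            )
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.n_plates * self.wells_per_plate_study < self.n_study_samples:
            raise ValueError(
                f"{self.n_plates} plates x {self.wells_per_plate_study} study wells "
                f"cannot hold {self.n_study_samples} study samples"
            )
        lo, hi = self.precursors_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("precursors_per_protein must be a range with 1 <= lo <= hi")
        vocabulary = {"sex", "age_decade", "bmi_cat1", "bmi_cat3", "bmi_cat4",
                      "fasting", "hcu"}
        from .io import parse_atc_code
        for spec in self.effect_specs:
            if not np.isfinite(spec.beta):
                raise ValueError(f"effect beta must be finite: {spec}")
            if spec.covariate not in vocabulary \
                    and parse_atc_code(spec.covariate) is None:
                raise ValueError(
                    f"effect covariate {spec.covariate!r} is neither a design "
                    f"term ({sorted(vocabulary)}) nor an ATC code")


@dataclass
class GroundTruth:
    """Everything the generator drew that recovery tests need.

    ``plate_offsets`` / ``batch_offsets`` are protein x plate (batch) frames
    whose rows sum to zero; ``masked_entries`` records, for every quantity set
    missing, the feature id, run id and pre-missingness value.
    """

    effects: list[EffectSpec]
    baseline: pd.Series
    plate_offsets: pd.DataFrame
    batch_offsets: pd.DataFrame
    biological_sd: pd.Series
    technical_sd: pd.Series
    precursor_offsets: pd.Series
    outlier_samples: list[str] = field(default_factory=list)
    masked_entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["feature", "run", "value"])
    )

    def effect_frame(self, covariates: Sequence[str] | None = None) -> pd.DataFrame:
        """Dense protein x covariate beta matrix (zeros where no effect)."""
        proteins = self.baseline.index
        if covariates is None:
            covariates = sorted({e.covariate for e in self.effects})
        frame = pd.DataFrame(0.0, index=proteins, columns=list(covariates))
        for spec in self.effects:
            if spec.covariate in frame.columns:
                frame.loc[spec.protein_id, spec.covariate] += spec.beta
        return frame

    def beta(self, protein_id: str, covariate: str) -> float:
        return float(sum(e.beta for e in self.effects
                         if e.protein_id == protein_id and e.covariate == covariate))

    def record_masked(self, entries: pd.DataFrame) -> None:
        if not np.isfinite(entries["value"].to_numpy(dtype=float)).all():
            raise ValueError("masked-entry ledger values must be finite")
        frames = [f for f in (self.masked_entries, entries) if len(f)]
        self.masked_entries = (
            pd.concat(frames, ignore_index=True) if frames else entries
        )

    def to_json(self) -> str:
        payload = {
            "baseline": self.baseline.to_dict(),
            "plate_offsets": self.plate_offsets.to_dict(),
            "batch_offsets": self.batch_offsets.to_dict(),
            "biological_sd": self.biological_sd.to_dict(),
            "technical_sd": self.technical_sd.to_dict(),
            "precursor_offsets": self.precursor_offsets.to_dict(),
            "outlier_samples": list(self.outlier_samples),
            "masked_entries": self.masked_entries.to_dict(orient="list"),
        }
        payload["effects"] = [
            {"protein_id": e.protein_id, "covariate": e.covariate, "beta": e.beta}
            for e in self.effects
        ]
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        masked = pd.DataFrame(raw["masked_entries"])
        if masked.empty:
            masked = pd.DataFrame(columns=["feature", "run", "value"])
        return cls(
            effects=[EffectSpec(**e) for e in raw["effects"]],
            baseline=pd.Series(raw["baseline"]).rename_axis("protein"),
            plate_offsets=pd.DataFrame(raw["plate_offsets"])
            .rename_axis("protein"),
            batch_offsets=pd.DataFrame(raw["batch_offsets"])
            .rename_axis("protein"),
            biological_sd=pd.Series(raw["biological_sd"])
            .rename_axis("protein"),
            technical_sd=pd.Series(raw["technical_sd"]).rename_axis("protein"),
            precursor_offsets=pd.Series(raw["precursor_offsets"],
                                        dtype=float),
            outlier_samples=list(raw["outlier_samples"]),
            masked_entries=masked,
        )


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def _well_labels() -> list[str]:
    return [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def _draw_medications(rng: np.random.Generator, config: CohortConfig,
                      sex: str, age: float, hcu: bool) -> tuple[list[tuple[str, int]], str]:
    """Medication list for one participant and the contraceptive class drawn."""
    meds: list[tuple[str, int]] = []
    coc_class = ""
    if hcu:
        probs = np.asarray(config.demographics.coc_class_probs, dtype=float)
        probs = probs / probs.sum()
        cls = rng.choice(4, p=probs)
        pool = (EE_PREPARATIONS, BE_PREPARATIONS, P4_PREPARATIONS,
                NON_ORAL_PREPARATIONS)[cls]
        coc_class = ("EE", "BE", "P4", "non_oral")[cls]
        meds.append((str(rng.choice(pool)), 1))
    for code, prevalence in config.medication_prevalence.items():
        if rng.random() < prevalence:
            meds.append((code, int(rng.random() < 0.9)))
    return meds, coc_class


def _simulate_participants(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    demo = config.demographics
    n = config.n_study_samples
    lo, hi = demo.age_range
    age = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.random(n) < demo.female_fraction, "F", "M")
    bmi = np.maximum(rng.normal(demo.bmi_mean, demo.bmi_sd, size=n), demo.bmi_min)
    fasting = (rng.random(n) < demo.fasting_rate).astype(int)

    # Current hormonal-contraceptive use: women only, prevalence held at the
    # configured level below age 40 and decaying logistically above it.
    p_hcu = config.hcu_prevalence_women_under40 / (1.0 + np.exp((age - 40.0) / 2.0))
    p_hcu = np.where(age < 38.0, config.hcu_prevalence_women_under40, p_hcu)
    hcu = (sex == "F") & (rng.random(n) < p_hcu)

    pregnant = (sex == "F") & (age <= 45) & (rng.random(n) < demo.pregnancy_rate) & ~hcu
    p_ever = 0.9 / (1.0 + np.exp(-(age - 28.0) / 5.0))
    ever_pregnant = (sex == "F") & (rng.random(n) < p_ever)

    history = np.full(n, "unknown", dtype=object)
    history[sex == "M"] = "never"
    for i in range(n):
        if sex[i] != "F":
            continue
        if hcu[i]:
            history[i] = "current"
        else:
            frac = demo.previous_hcu_fraction if age[i] < 55 else 0.45
            history[i] = "previous" if rng.random() < frac else "never"
    # a small share of women have unusable questionnaire data
    unknown = (sex == "F") & ~hcu & (rng.random(n) < 0.02)
    history[unknown] = "unknown"

    meds, coc = [], []
    for i in range(n):
        m, c = _draw_medications(rng, config, sex[i], age[i], bool(hcu[i]))
        meds.append(m)
        coc.append(c)

    return pd.DataFrame({
        "sex": sex, "age": age, "bmi": bmi, "fasting": fasting,
        "hcu": hcu.astype(int), "pregnant": pregnant.astype(int),
        "ever_pregnant": ever_pregnant.astype(int), "hcu_history": history,
        "medications": meds, "coc_class": coc,
    })


def _build_sample_table(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    """Plate layout + participant covariates; index = run id in acquisition order."""
    participants = _simulate_participants(rng, config)
    order = rng.permutation(config.n_study_samples)  # random plate assignment
    wells = _well_labels()

    rows: list[dict] = []
    cursor = 0
    for plate_idx in range(config.n_plates):
        plate = f"plate{plate_idx + 1:02d}"
        batch = f"batch{plate_idx // config.plates_per_batch + 1:02d}"
        n_study = min(config.wells_per_plate_study,
                      config.n_study_samples - cursor)
        roles = (["study"] * n_study
                 + ["pool"] * config.pools_per_plate
                 + ["blank"] * BLANKS_PER_PLATE
                 + ["commercial_serum"] * SERUM_PER_PLATE
                 + ["commercial_plasma"] * PLASMA_PER_PLATE)
        for well, role in zip(wells, roles):
            row = {
                "role": role, "plate": plate, "well": well, "ms_batch": batch,
                "sex": pd.NA, "age": np.nan, "bmi": np.nan, "fasting": pd.NA,
                "pregnant": pd.NA, "ever_pregnant": pd.NA,
                "hcu_history": pd.NA, "medications": [],
                "hcu": pd.NA, "coc_class": pd.NA,
            }
            if role == "study":
                part = participants.iloc[order[cursor]]
                row.update({k: part[k] for k in (
                    "sex", "age", "bmi", "fasting", "pregnant", "ever_pregnant",
                    "hcu_history", "medications", "hcu", "coc_class")})
                cursor += 1
            rows.append(row)

    table = pd.DataFrame(rows)
    table.index = pd.Index(
        [f"run{i + 1:05d}" for i in range(len(table))], name="run"
    )
    return table


# ---------------------------------------------------------------------------
# abundance model
# ---------------------------------------------------------------------------

def _covariate_value(sample: pd.Series, covariate: str) -> float:
    """Design value of one covariate for one study sample."""
    if covariate == "sex":
        return 1.0 if sample["sex"] == "F" else 0.0
    if covariate == "age_decade":
        return float(sample["age"]) / 10.0
    if covariate.startswith("bmi_cat"):
        cat = int(covariate[-1])
        from .associate import encode_bmi_category
        return 1.0 if encode_bmi_category(float(sample["bmi"])) == cat else 0.0
    if covariate == "fasting":
        return float(sample["fasting"])
    if covariate == "hcu":
        return float(sample["hcu"])
    # ATC code: indicator for a regular medication truncating to the code
    for code, regular in sample["medications"]:
        if regular and code.startswith(covariate):
            return 1.0
    return 0.0


def _protein_log2(rng: np.random.Generator, config: CohortConfig,
                  samples: pd.DataFrame, truth: GroundTruth) -> pd.DataFrame:
    """Protein-level log2 abundance for every sample (fully observed)."""
    proteins = truth.baseline.index
    n_prot, n_samp = len(proteins), len(samples)
    mu = truth.baseline.to_numpy()[:, None]
    data = np.zeros((n_prot, n_samp))

    covariates = sorted({e.covariate for e in truth.effects})
    betas = truth.effect_frame(covariates).to_numpy() if covariates else None

    role = samples["role"].to_numpy()
    plate_cols = truth.plate_offsets.columns
    batch_cols = truth.batch_offsets.columns
    plate_idx = pd.Index(plate_cols).get_indexer(samples["plate"])
    batch_idx = pd.Index(batch_cols).get_indexer(samples["ms_batch"])
    bio_sd = truth.biological_sd.to_numpy()[:, None]
    tech_sd = truth.technical_sd.to_numpy()[:, None]

    role_offsets = {
        r: rng.normal(0.0, config.role_offset_sd, size=n_prot)
        for r in ("commercial_serum", "commercial_plasma")
    }

    for j, (run, sample) in enumerate(samples.iterrows()):
        r = role[j]
        if r == "blank":
            data[:, j] = config.blank_level + rng.normal(0.0, 0.3, size=n_prot)
            continue
        col = mu[:, 0].copy()
        if r == "study":
            if betas is not None:
                x = np.array([_covariate_value(sample, c) for c in covariates])
                col += betas @ x
            col += truth.plate_offsets.iloc[:, plate_idx[j]].to_numpy()
            col += truth.batch_offsets.iloc[:, batch_idx[j]].to_numpy()
            col += rng.normal(0.0, 1.0, size=n_prot) * bio_sd[:, 0]
        elif r in role_offsets:
            col += role_offsets[r]
        # pools: fixed reference profile, technical noise only
        col += rng.normal(0.0, 1.0, size=n_prot) * tech_sd[:, 0]
        data[:, j] = col

    return pd.DataFrame(data, index=proteins, columns=samples.index)


_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _precursor_structure(rng: np.random.Generator, config: CohortConfig,
                         proteins: pd.Index) -> pd.DataFrame:
    # Precursor ids follow the search-engine convention sequence + charge
    # (e.g. "ACDEFGHIK2"), so peptide length is recoverable from the id alone
    # and report round-trips stay consistent.
    lo, hi = config.precursors_per_protein
    rows = []
    seen: set[str] = set()
    for prot in proteins:
        n_pre = int(rng.integers(lo, hi + 1))
        proteo = rng.random(n_pre) < config.frac_proteotypic
        if not proteo.any():
            proteo[int(rng.integers(n_pre))] = True  # keep the protein summarizable
        for k in range(n_pre):
            charge = int(rng.choice([2, 3, 4], p=[0.70, 0.25, 0.05]))
            length = int(rng.integers(7, 31))
            while True:
                seq = "".join(rng.choice(_AMINO_ACIDS, size=length))
                pid = f"{seq}{charge}"
                if pid not in seen:
                    seen.add(pid)
                    break
            rows.append({
                "precursor_id": pid,
                "protein_group": prot,
                "proteotypic": bool(proteo[k]),
                "charge": charge,
                "missed_cleavages": int(rng.choice([0, 1, 2], p=[0.80, 0.17, 0.03])),
                "peptide_length": length,
            })
    meta = pd.DataFrame(rows).set_index("precursor_id")
    return meta


def _make_truth(rng: np.random.Generator, config: CohortConfig,
                proteins: pd.Index, plates: list[str], batches: list[str]) -> GroundTruth:
    n_prot = len(proteins)
    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, size=n_prot),
        index=proteins,
    )
    plate_off = rng.normal(0.0, config.plate_sd, size=(n_prot, len(plates)))
    plate_off -= plate_off.mean(axis=1, keepdims=True)  # sum-to-zero per protein
    batch_off = rng.normal(0.0, config.batch_sd, size=(n_prot, len(batches)))
    batch_off -= batch_off.mean(axis=1, keepdims=True)
    bio = config.biological_sd * np.exp(
        rng.normal(0.0, config.biological_sd_spread, size=n_prot))
    tech = config.technical_sd * np.exp(
        rng.normal(0.0, config.technical_sd_spread, size=n_prot))
    if config.biological_sd == 0:
        bio = np.zeros(n_prot)
    return GroundTruth(
        effects=list(config.effect_specs),
        baseline=baseline,
        plate_offsets=pd.DataFrame(plate_off, index=proteins, columns=plates),
        batch_offsets=pd.DataFrame(batch_off, index=proteins, columns=batches),
        biological_sd=pd.Series(bio, index=proteins),
        technical_sd=pd.Series(tech, index=proteins),
        precursor_offsets=pd.Series(dtype=float),
    )


def generate_cohort(config: CohortConfig) -> AnalysisBundle:
    """Generate a fully observed precursor-level cohort bundle.

    Study-sample protein log2 abundance is baseline + injected covariate
    effects + plate and batch offsets + biological + technical noise; pool
    wells carry the fixed reference profile plus technical noise only; blanks
    sit at a low noise floor.  Precursor quantities are
    ``2 ** (protein_log2 + fixed precursor offset + precursor noise)``.

    Use :func:`simulate_cohort` to also apply missingness and outliers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = _build_sample_table(rng, config)
    proteins = pd.Index([f"P{i + 1:04d}" for i in range(config.n_proteins)],
                        name="protein")
    plates = sorted(samples["plate"].unique())
    batches = sorted(samples["ms_batch"].unique())
    truth = _make_truth(rng, config, proteins, plates, batches)

    protein_log2 = _protein_log2(rng, config, samples, truth)
    meta = _precursor_structure(rng, config, proteins)
    offsets = pd.Series(
        rng.normal(0.0, config.precursor_offset_sd, size=len(meta)),
        index=meta.index,
    )
    truth.precursor_offsets = offsets

    prot_idx = proteins.get_indexer(meta["protein_group"])
    pre_log2 = protein_log2.to_numpy()[prot_idx, :] + offsets.to_numpy()[:, None]
    pre_log2 = pre_log2 + rng.normal(
        0.0, config.precursor_noise_sd, size=pre_log2.shape)
    if config.precursor_interaction_sd > 0:
        # optional non-additive precursor x sample structure, to stress the
        # additivity assumption behind median-polish summarization
        pre_log2 = pre_log2 + rng.normal(
            0.0, config.precursor_interaction_sd, size=pre_log2.shape)

    quant = QuantMatrix(
        data=pd.DataFrame(2.0 ** pre_log2, index=meta.index, columns=samples.index),
        scale="linear", level="precursor",
        log={"generator_seed": config.seed},
    )
    validate_precursor_meta(meta)
    validate_sample_table(samples)
    return AnalysisBundle(quant=quant, meta=meta, samples=samples,
                          ground_truth=truth)


def generate_protein_bundle(config: CohortConfig) -> AnalysisBundle:
    """Protein-level shortcut: the same cohort model without the precursor layer.

    Returns a fully observed log2 protein matrix over study and QC wells with
    the same sample annotation and ground truth as :func:`generate_cohort`.
    Intended for statistical studies (association power, type-I error, PCA)
    where the precursor-processing chain is not under test.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _build_sample_table(rng, config)
    proteins = pd.Index([f"P{i + 1:04d}" for i in range(config.n_proteins)],
                        name="protein")
    plates = sorted(samples["plate"].unique())
    batches = sorted(samples["ms_batch"].unique())
    truth = _make_truth(rng, config, proteins, plates, batches)
    protein_log2 = _protein_log2(rng, config, samples, truth)
    quant = QuantMatrix(data=protein_log2, scale="log2", level="protein",
                       log={"generator_seed": config.seed, "shortcut": "protein"})
    meta = pd.DataFrame(
        {"protein_group": proteins, "proteotypic": True, "charge": 2,
         "missed_cleavages": 0, "peptide_length": 15},
        index=proteins.rename("precursor_id"),
    )
    return AnalysisBundle(quant=quant, meta=meta, samples=samples,
                          ground_truth=truth)


# ---------------------------------------------------------------------------
# missingness and outliers
# ---------------------------------------------------------------------------

def missingness_probability(log2_quantity: np.ndarray, mcar_rate: float,
                            mnar_slope: float, mnar_midpoint: float) -> np.ndarray:
    """P(missing) = mcar + (1-mcar) * logistic(-slope * (log2 q - midpoint))."""
    z = -mnar_slope * (log2_quantity - mnar_midpoint)
    return mcar_rate + (1.0 - mcar_rate) / (1.0 + np.exp(-z))


def inject_missingness(quant: QuantMatrix, config: CohortConfig,
                       truth: GroundTruth | None = None,
                       rng: np.random.Generator | None = None) -> QuantMatrix:
    """Apply MCAR + intensity-dependent (MNAR) missingness to a linear matrix.

    Each entry goes missing independently with probability
    ``mcar + (1-mcar) * logistic(-slope * (log2 q - midpoint))``.  Masked
    entries and their pre-missingness values are appended to ``truth`` when
    given.
    """
    quant.require(scale="linear", fully_observed=True)
    if not 0.0 <= config.mcar_rate <= 1.0:
        raise ValueError("mcar_rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed + 101)
    values = quant.values
    p_miss = missingness_probability(
        np.log2(values), config.mcar_rate, config.mnar_slope, config.mnar_midpoint)
    mask = rng.random(values.shape) < p_miss

    out = quant.copy()
    data = out.data.to_numpy(dtype=float)
    if truth is not None and mask.any():
        rows, cols = np.nonzero(mask)
        truth.record_masked(pd.DataFrame({
            "feature": quant.features[rows],
            "run": quant.samples[cols],
            "value": data[rows, cols],
        }))
    data[mask] = np.nan
    out.data = pd.DataFrame(data, index=quant.features, columns=quant.samples)
    out.log["injected_missing"] = int(mask.sum())
    return out


def inject_outlier_samples(bundle: AnalysisBundle, fraction: float,
                           rng: np.random.Generator | None = None,
                           extra_missing: float = 0.55) -> AnalysisBundle:
    """Degrade ``round(fraction * n_study)`` study samples.

    Degraded runs lose a large extra share of their observed precursors, with
    the loss biased toward charge-2, fully cleaved peptides so that the
    surviving composition shifts in mean charge and missed-cleavage rate —
    the signature the sample-QC metrics are designed to catch.  Degraded run
    ids are recorded in the bundle's ground truth.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("outlier fraction must be in [0, 1)")
    if fraction == 0.0:
        return bundle
    if rng is None:
        rng = np.random.default_rng(bundle.quant.log.get("generator_seed", 0) + 202)
    study_ids = bundle.samples.index[bundle.samples["role"] == "study"]
    n_out = int(round(fraction * len(study_ids)))
    chosen = list(rng.choice(study_ids, size=n_out, replace=False))

    out = bundle.copy()
    out.ground_truth = bundle.ground_truth
    data = out.quant.data
    meta = out.meta.loc[data.index]
    # vulnerable precursors dropped 3x as readily as robust ones
    weight = np.where(
        (meta["charge"].to_numpy() == 2) & (meta["missed_cleavages"].to_numpy() == 0),
        3.0, 1.0)
    masked_frames = []
    for run in chosen:
        col = data[run].to_numpy(dtype=float)
        observed = np.nonzero(~np.isnan(col))[0]
        p = weight[observed] / weight[observed].sum()
        k = int(round(extra_missing * len(observed)))
        drop = rng.choice(observed, size=k, replace=False, p=p)
        masked_frames.append(pd.DataFrame({
            "feature": data.index[drop], "run": run, "value": col[drop]}))
        col[drop] = np.nan
        data[run] = col
    if out.ground_truth is not None:
        out.ground_truth.outlier_samples = sorted(
            set(out.ground_truth.outlier_samples) | set(map(str, chosen)))
        if masked_frames:
            out.ground_truth.record_masked(
                pd.concat(masked_frames, ignore_index=True))
    out.quant.log["injected_outliers"] = list(map(str, chosen))
    return out


def simulate_cohort(config: CohortConfig) -> AnalysisBundle:
    """Generate, then apply missingness and (if configured) outlier damage."""
    bundle = generate_cohort(config)
    bundle.quant = inject_missingness(bundle.quant, config, bundle.ground_truth)
    bundle = inject_outlier_samples(
        bundle, config.outlier_fraction,
        rng=np.random.default_rng(config.seed + 202))
    return bundle
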