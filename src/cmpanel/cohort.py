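"""Synthetic matched nested case-control proteomic cohorts.

Generates plasma circulating-microparticle (CMP) style protein abundance
tables for a placenta accreta spectrum (PAS) case-control study: cases matched
1:``match_ratio`` to controls on gestational age at sampling (within a window)
and fetus number, one second-trimester (T2) and one third-trimester (T3) draw
per subject, log-scale protein intensities with a subject-level random effect
shared across the two draws, and a small planted panel of proteins whose mean
is shifted in cases.  Clinical covariates follow the case-control contrasts of
the study population (older cases, more previa, grade distribution skewed to
grade 1) but are never fed to the classifier.

The generator starts at the quantified protein matrix: no spectra, peptides or
acquisition-level artifacts are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "AbundanceMatrix",
    "GroundTruth",
    "COHORT_COLUMNS",
    "generate_cohort",
    "validate_cohort",
    "reference_cohort",
]

#: Required columns of a clinical cohort table (one row per sample/draw).
COHORT_COLUMNS = [
    "sample_id",
    "subject_id",
    "status",
    "match_stratum",
    "trimester",
    "gestational_age_at_draw",
    "n_fetuses",
    "maternal_age",
    "n_prior_cesareans",
    "previa_at_delivery",
    "pas_grade",
    "diagnosis_mode",
    "ultrasound_detected",
]

# Clinical covariate frequencies among cases/controls (study-population
# structure): prior cesarean bins 0 / 1 / >=2, previa at delivery, PAS grade
# mix, per-grade antenatal ultrasound detection, and how the grade was
# determined (clinical vs histologic criteria vs both).
_CESAREAN_P = {"case": (0.657, 0.200, 0.143), "control": (0.786, 0.143, 0.071)}
_PREVIA_P = {"case": 8 / 35, "control": 6 / 70}
_GRADE_P = (27 / 35, 7 / 35, 1 / 35)  # grades 1, 2, 3 among cases
_ULTRASOUND_P = {1: 3 / 27, 2: 4 / 7, 3: 1.0}
_DIAGNOSIS_P = {
    1: (("clinical", 21 / 27), ("histologic", 0.0), ("both", 6 / 27)),
    2: (("clinical", 2 / 7), ("histologic", 1 / 7), ("both", 4 / 7)),
    3: (("clinical", 0.0), ("histologic", 0.0), ("both", 1.0)),
}
_MATERNAL_AGE = {"case": (36.9, 2.15), "control": (32.9, 2.0)}  # mean, SD
_GA_MEDIAN = {"T2": 26.0, "T3": 35.0}
_GA_SD = 2.0
_TWIN_RATE = 0.03

# Log2-intensity scale of the simulated protein matrix.
_BASELINE_MEAN = 20.0
_BASELINE_SD = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated cohort.

    Parameters
    ----------
    n_cases : int
        Number of PAS cases (default 35, the study's cohort size).
    n_controls : int or None
        Number of matched controls; defaults to ``match_ratio * n_cases``.
    n_proteins : int
        Size of the protein superset (default 500; the quantified-matrix size
        is a stand-in, exposed here because the real count is study-specific).
    n_planted : int
        Number of truly discriminative proteins (default 5, one panel's worth).
    effect_size : float
        Standardized case-control mean shift (Cohen's d) applied to planted
        proteins on the log scale, in both trimesters.
    within_subject_corr : float
        Correlation of a protein's value between the T2 and T3 draws of one
        subject, in [0, 1).
    missing_rate : float
        Probability a cell is missing at random, in [0, 1).
    match_ratio : int
        Controls per case (default 2).
    ga_window_weeks : float
        Gestational-age matching tolerance in weeks (default 1).
    seed : int
        Seed of the single RNG; outputs are a pure function of this config.
    """

    n_cases: int = 35
    n_controls: int | None = None
    n_proteins: int = 500
    n_planted: int = 5
    effect_size: float = 1.0
    within_subject_corr: float = 0.5
    missing_rate: float = 0.05
    match_ratio: int = 2
    ga_window_weeks: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        if self.match_ratio < 1:
            raise ConfigurationError("match_ratio must be >= 1")
        expected = self.match_ratio * self.n_cases
        if self.n_controls is None:
            object.__setattr__(self, "n_controls", expected)
        elif self.n_controls != expected:
            raise ConfigurationError(
                f"n_controls must equal match_ratio * n_cases = {expected}"
            )
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if not 0 <= self.n_planted <= self.n_proteins:
            raise ConfigurationError("n_planted must be in [0, n_proteins]")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not 0.0 <= self.within_subject_corr < 1.0:
            raise ConfigurationError("within_subject_corr must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.ga_window_weeks < 0:
            raise ConfigurationError("ga_window_weeks must be >= 0")


@dataclass
class AbundanceMatrix:
    """A samples x proteins log2-intensity table for one trimester.

    ``values`` holds NaN where a cell is missing; all non-missing values are
    finite.  Row order matches ``sample_ids``, column order ``protein_ids``.
    """

    sample_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray
    trimester: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.protein_ids)):
            raise ValueError("values shape does not match identifier lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein identifiers")
        present = ~np.isnan(self.values)
        if not np.isfinite(self.values[present]).all():
            raise ValueError("non-finite abundance values")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.protein_ids,
        )


@dataclass(frozen=True)
class GroundTruth:
    """The planted panel: which proteins carry signal and how much."""

    planted_protein_ids: tuple[str, ...]
    effect_sizes: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": list(self.planted_protein_ids),
                "effect_size": [self.effect_sizes[p] for p in self.planted_protein_ids],
            }
        )


def validate_cohort(cohort: pd.DataFrame, source: str = "clinical table") -> None:
    """Check a clinical table has the required columns and coherent labels."""
    from .errors import ParseError

    for col in COHORT_COLUMNS:
        if col not in cohort.columns:
            raise ParseError(f"{source}: missing required column '{col}'")
    bad_status = set(cohort["status"].unique()) - {"case", "control"}
    if bad_status:
        raise ParseError(f"{source}: invalid status values {sorted(bad_status)}")
    grades = cohort["pas_grade"].astype(int)
    case_mask = cohort["status"] == "case"
    if ((grades > 0) != case_mask).any():
        raise ParseError(f"{source}: pas_grade > 0 must hold exactly for cases")


def reference_cohort() -> pd.DataFrame:
    """A deterministic clinical table with the study population's composition.

    35 cases and 70 controls with the exact categorical mix of the cohort this
    pipeline models: cesarean-section history bins 23/7/5 (cases) vs 55/10/5
    (controls), 8 vs 6 with previa at delivery, 20 cases with neither prior
    cesarean nor previa, PAS grades 27/7/1 with antenatal ultrasound detection
    3/4/1 per grade, and grade determination 23 clinical / 1 histologic / 11
    concordant-both.  Continuous covariates are deterministic fillers.  Useful
    for worked examples and for checking the summary arithmetic against known
    counts; protein data are not included.
    """
    rows = []

    def add_subject(subject_id, stratum, status, ces, previa, grade, mode, us,
                    age, ga2, ga3):
        for t, ga in (("T2", ga2), ("T3", ga3)):
            rows.append(
                {
                    "sample_id": f"{subject_id}_{t}",
                    "subject_id": subject_id,
                    "status": status,
                    "match_stratum": stratum,
                    "trimester": t,
                    "gestational_age_at_draw": ga,
                    "n_fetuses": 1,
                    "maternal_age": age,
                    "n_prior_cesareans": ces,
                    "previa_at_delivery": previa,
                    "pas_grade": grade,
                    "diagnosis_mode": mode,
                    "ultrasound_detected": us,
                }
            )

    for i in range(1, 36):
        # grades: 1..27 -> grade 1, 28..34 -> grade 2, 35 -> grade 3
        grade = 1 if i <= 27 else (2 if i <= 34 else 3)
        if grade == 1:
            us = i <= 3  # 3 of 27 detected
            mode = "clinical" if i <= 21 else "both"  # 21 clinical, 6 both
        elif grade == 2:
            j = i - 27  # 1..7
            us = j <= 4  # 4 of 7 detected
            mode = "clinical" if j <= 2 else ("histologic" if j == 3 else "both")
        else:
            us, mode = True, "both"
        # cesarean bins 23 / 7 / 5; previa: 3 of the zero-cesarean cases plus
        # 5 others -> 8 total, leaving 20 with neither cesarean nor previa
        ces = 0 if i <= 23 else (1 if i <= 30 else 2)
        previa = i <= 3 or 24 <= i <= 28
        age = 36.9 + ((i % 7) - 3) * 0.7
        ga2 = 26.0 + ((i % 5) - 2) * 0.6
        ga3 = 35.0 + ((i % 5) - 2) * 0.6
        add_subject(f"CASE{i:02d}", f"M{i:02d}", "case", ces, previa, grade,
                    mode, us, age, ga2, ga3)
        for k in (1, 2):
            j = (i - 1) * 2 + k  # control index 1..70
            ces_c = 0 if j <= 55 else (1 if j <= 65 else 2)
            previa_c = j <= 6
            age_c = 32.9 + ((j % 7) - 3) * 0.65
            add_subject(f"CTRL{j:02d}", f"M{i:02d}", "control", ces_c,
                        previa_c, 0, "none", False, age_c,
                        ga2 + 0.3 * (-1) ** k, ga3 + 0.3 * (-1) ** k)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, AbundanceMatrix], pd.DataFrame, GroundTruth]:
    """Simulate one matched cohort with paired T2/T3 draws.

    Returns
    -------
    matrices : dict
        ``{"T2": AbundanceMatrix, "T3": AbundanceMatrix}`` over the same
        subjects in the same row order.
    cohort : pandas.DataFrame
        Clinical table, one row per sample (two per subject), columns
        :data:`COHORT_COLUMNS`.
    truth : GroundTruth
        Which proteins were planted and their true effect sizes.

    Notes
    -----
    Protein values are generated on the log2 scale as
    ``baseline_j + d * planted_j * case_i + sqrt(rho) * a_ij + sqrt(1-rho) * e_ijt``
    with ``a_ij`` a subject-by-protein random effect shared by the two draws
    and ``e_ijt`` draw-specific noise, so each protein has unit variance and
    the T2/T3 correlation of one subject's value is ``rho`` in expectation.
    Non-planted proteins have exactly zero case-control mean difference.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sub = cfg.n_cases + cfg.n_controls
    protein_ids = _protein_ids(cfg.n_proteins)

    # --- subjects, matching strata, clinical covariates -------------------
    rows = []
    subj_status = []
    case_width = max(2, len(str(cfg.n_cases)))
    ctrl_width = max(2, len(str(cfg.n_controls)))
    ctrl_counter = 0
    for c in range(cfg.n_cases):
        stratum = f"M{c + 1:0{case_width}d}"
        ga = {t: rng.normal(_GA_MEDIAN[t], _GA_SD) for t in ("T2", "T3")}
        n_fetuses = 1 + int(rng.random() < _TWIN_RATE)
        members = [(f"CASE{c + 1:0{case_width}d}", "case", ga)]
        for _ in range(cfg.match_ratio):
            ctrl_counter += 1
            ga_ctrl = {
                t: ga[t] + rng.uniform(-cfg.ga_window_weeks, cfg.ga_window_weeks)
                for t in ("T2", "T3")
            }
            members.append((f"CTRL{ctrl_counter:0{ctrl_width}d}", "control", ga_ctrl))
        for subject_id, status, ga_s in members:
            grade = (
                int(rng.choice([1, 2, 3], p=_GRADE_P)) if status == "case" else 0
            )
            if status == "case":
                modes, probs = zip(*_DIAGNOSIS_P[grade])
                diagnosis = str(rng.choice(modes, p=probs))
                ultrasound = bool(rng.random() < _ULTRASOUND_P[grade])
            else:
                diagnosis = "none"
                ultrasound = False
            age_mu, age_sd = _MATERNAL_AGE[status]
            maternal_age = float(rng.normal(age_mu, age_sd))
            ces = int(rng.choice([0, 1, 2], p=_CESAREAN_P[status]))
            previa = bool(rng.random() < _PREVIA_P[status])
            subj_status.append(1 if status == "case" else 0)
            for t in ("T2", "T3"):
                rows.append(
                    {
                        "sample_id": f"{subject_id}_{t}",
                        "subject_id": subject_id,
                        "status": status,
                        "match_stratum": stratum,
                        "trimester": t,
                        "gestational_age_at_draw": round(float(ga_s[t]), 2),
                        "n_fetuses": n_fetuses,
                        "maternal_age": round(maternal_age, 1),
                        "n_prior_cesareans": ces,
                        "previa_at_delivery": previa,
                        "pas_grade": grade,
                        "diagnosis_mode": diagnosis,
                        "ultrasound_detected": ultrasound,
                    }
                )
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    is_case = np.array(subj_status, dtype=float)  # per subject, T2/T3 row order

    # --- abundance values --------------------------------------------------
    planted_idx = np.sort(rng.choice(cfg.n_proteins, size=cfg.n_planted, replace=False))
    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=cfg.n_proteins)
    shift = np.zeros(cfg.n_proteins)
    shift[planted_idx] = cfg.effect_size
    rho = cfg.within_subject_corr
    subject_effect = rng.normal(size=(n_sub, cfg.n_proteins))
    matrices: dict[str, AbundanceMatrix] = {}
    subject_order = cohort.loc[cohort["trimester"] == "T2", "subject_id"].tolist()
    for t in ("T2", "T3"):
        noise = rng.normal(size=(n_sub, cfg.n_proteins))
        values = (
            baseline[None, :]
            + is_case[:, None] * shift[None, :]
            + np.sqrt(rho) * subject_effect
            + np.sqrt(1.0 - rho) * noise
        )
        if cfg.missing_rate > 0:
            values[rng.random(values.shape) < cfg.missing_rate] = np.nan
        matrices[t] = AbundanceMatrix(
            sample_ids=[f"{s}_{t}" for s in subject_order],
            protein_ids=list(protein_ids),
            values=values,
            trimester=t,
        )

    truth = GroundTruth(
        planted_protein_ids=tuple(protein_ids[i] for i in planted_idx),
        effect_sizes={protein_ids[i]: cfg.effect_size for i in planted_idx},
    )
    return matrices, cohort, truth
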