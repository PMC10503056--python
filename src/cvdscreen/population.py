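"""Synthetic survey populations for screening-program simulation.

The downstream pipeline consumes one row per adult with the cardiovascular
risk factors a screening clinic would measure (blood pressure, lipids,
glucose, smoking, BMI), a baseline EQ-5D utility, a survey weight and a
prior-CVD flag.  The generator here produces seedable cohorts with a
realistic *joint* structure — age-correlated blood pressure and utility,
sex-specific smoking, glucose-consistent diabetes flags, age-graded
prior-CVD prevalence — via a Gaussian copula over configurable marginals.

The default marginals are illustrative values for a South-Asian adult
population; they are not estimates of any particular survey's
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

#: Columns every population table must carry, in canonical order.
SCHEMA = [
    "person_id",
    "age",
    "sex",
    "sbp",
    "dbp",
    "total_cholesterol",
    "fasting_glucose",
    "random_glucose",
    "diabetes",
    "smoker",
    "bmi",
    "baseline_utility",
    "survey_weight",
    "prior_cvd",
]

BOOL_COLUMNS = ["diabetes", "smoker", "prior_cvd"]

#: Diagnostic glucose thresholds (mg/dL) used both by the generator (flag
#: consistency) and by the treatment rules downstream.
FASTING_GLUCOSE_DIABETES = 126.0
RANDOM_GLUCOSE_DIABETES = 200.0

#: Lowest value the EQ-5D-type utility index may take.
UTILITY_FLOOR = -0.59


class PopulationError(ValueError):
    """Invalid population specification or data."""


class SchemaError(PopulationError):
    """Required column missing from a population file."""


class ValidationError(PopulationError):
    """Rows violating record invariants, with row-level diagnostics."""

    def __init__(self, message: str, bad_rows: dict[int, str]):
        self.bad_rows = bad_rows
        detail = "; ".join(f"row {i}: {why}" for i, why in sorted(bad_rows.items()))
        super().__init__(f"{message}: {detail}")


@dataclass(frozen=True)
class Marginal:
    """One continuous marginal distribution, sampled through its ppf.

    family: 'normal' | 'truncnorm' | 'lognormal' | 'gamma' | 'uniform'
    params: family parameters — normal/truncnorm: (mean, sd); lognormal:
            (median, sigma_log); gamma: (mean, sd); uniform: (low, high)
    bounds: optional hard support (lo, hi); truncnorm truncates there,
            other families are clipped after sampling.
    """

    family: str
    params: tuple[float, ...]
    bounds: tuple[float, float] | None = None

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            x = stats.norm.ppf(u, loc=self.params[0], scale=self.params[1])
        elif self.family == "truncnorm":
            mean, sd = self.params
            lo, hi = self.bounds if self.bounds else (-np.inf, np.inf)
            a, b = (lo - mean) / sd, (hi - mean) / sd
            x = stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
        elif self.family == "lognormal":
            median, sigma = self.params
            x = stats.lognorm.ppf(u, s=sigma, scale=median)
        elif self.family == "gamma":
            mean, sd = self.params
            shape = (mean / sd) ** 2
            scale = sd**2 / mean
            x = stats.gamma.ppf(u, a=shape, scale=scale)
        elif self.family == "uniform":
            lo, hi = self.params
            x = lo + u * (hi - lo)
        else:
            raise PopulationError(f"unknown marginal family {self.family!r}")
        if self.bounds is not None and self.family != "truncnorm":
            x = np.clip(x, *self.bounds)
        return x


#: Copula field order.  dbp is derived (a linear regression on sbp plus
#: noise, capped below sbp) so the sbp > dbp invariant holds by
#: construction.
COPULA_FIELDS = [
    "age",
    "sbp",
    "total_cholesterol",
    "fasting_glucose",
    "random_glucose",
    "bmi",
    "baseline_utility",
]


def _default_marginals() -> dict[str, Marginal]:
    return {
        "age": Marginal("truncnorm", (52.0, 12.0), (35.0, 100.0)),
        "sbp": Marginal("truncnorm", (125.0, 17.0), (85.0, 240.0)),
        "dbp_residual": Marginal("normal", (0.0, 6.0)),
        "total_cholesterol": Marginal("truncnorm", (200.0, 40.0), (80.0, 450.0)),
        "fasting_glucose": Marginal("lognormal", (95.0, 0.20), (50.0, 450.0)),
        "random_glucose": Marginal("lognormal", (110.0, 0.26), (50.0, 500.0)),
        "bmi": Marginal("truncnorm", (24.5, 4.0), (14.0, 50.0)),
        "baseline_utility": Marginal("truncnorm", (0.90, 0.10), (UTILITY_FLOOR, 1.0)),
        "survey_weight": Marginal("gamma", (1.0, 0.5), (0.01, 20.0)),
    }


def _default_correlation() -> np.ndarray:
    r = np.eye(len(COPULA_FIELDS))
    pairs = {
        ("age", "sbp"): 0.25,
        ("age", "total_cholesterol"): 0.10,
        ("age", "fasting_glucose"): 0.15,
        ("age", "random_glucose"): 0.15,
        ("age", "bmi"): -0.05,
        ("age", "baseline_utility"): -0.20,
        ("sbp", "total_cholesterol"): 0.15,
        ("sbp", "fasting_glucose"): 0.15,
        ("sbp", "random_glucose"): 0.12,
        ("sbp", "bmi"): 0.25,
        ("sbp", "baseline_utility"): -0.10,
        ("total_cholesterol", "fasting_glucose"): 0.10,
        ("total_cholesterol", "random_glucose"): 0.08,
        ("total_cholesterol", "bmi"): 0.15,
        ("fasting_glucose", "random_glucose"): 0.60,
        ("fasting_glucose", "bmi"): 0.15,
        ("fasting_glucose", "baseline_utility"): -0.08,
        ("random_glucose", "bmi"): 0.12,
        ("random_glucose", "baseline_utility"): -0.08,
        ("bmi", "baseline_utility"): -0.05,
    }
    idx = {f: i for i, f in enumerate(COPULA_FIELDS)}
    for (a, b), rho in pairs.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
    return r


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a synthetic cohort.

    Attributes
    ----------
    n, seed
        Cohort size and random seed (identical spec + seed gives a
        byte-identical table).
    marginals
        Per-field :class:`Marginal` distributions; must include every
        copula field plus ``pulse_pressure`` and ``survey_weight``.
    correlation
        Normal-scores correlation matrix over :data:`COPULA_FIELDS`
        (symmetric, unit diagonal, positive semi-definite).  For a
        Gaussian copula the induced Spearman correlation is
        ``(6/pi)*arcsin(rho/2)``, within 0.02 of ``rho`` everywhere.
    sbp_age_slope, utility_age_slope
        Additive age gradients (per year, about ``age_ref``) applied on
        top of the copula draw.
    prior_cvd_intercept, prior_cvd_slope
        Logistic model for prior-CVD prevalence as a function of age.
    smoking_prevalence
        Sex-specific smoking probabilities.
    p_diabetes_diagnosed
        Probability that a person *below* the glucose thresholds still
        carries a diabetes diagnosis (treated/controlled disease).
    population_total
        Survey weights are normalised so they sum to this figure.
    """

    n: int
    seed: int
    marginals: dict[str, Marginal] = field(default_factory=_default_marginals)
    correlation: np.ndarray = field(default_factory=_default_correlation)
    sbp_age_slope: float = 0.25
    utility_age_slope: float = -0.003
    dbp_intercept: float = 45.0
    dbp_slope: float = 0.28
    age_ref: float = 52.0
    prior_cvd_intercept: float = -5.94
    prior_cvd_slope: float = 0.06
    smoking_prevalence: dict[str, float] = field(
        default_factory=lambda: {"male": 0.29, "female": 0.01}
    )
    p_male: float = 0.47
    p_diabetes_diagnosed: float = 0.04
    population_total: float = 10_000_000.0

    def validate(self) -> None:
        if self.n < 0:
            raise PopulationError(f"n must be non-negative, got {self.n}")
        r = np.asarray(self.correlation, dtype=float)
        k = len(COPULA_FIELDS)
        if r.shape != (k, k):
            raise PopulationError(f"correlation must be {k}x{k}, got {r.shape}")
        if not np.allclose(r, r.T):
            raise PopulationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise PopulationError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise PopulationError("correlation matrix is not positive semi-definite")
        for prob in (self.p_male, self.p_diabetes_diagnosed, *self.smoking_prevalence.values()):
            if not 0.0 <= prob <= 1.0:
                raise PopulationError(f"prevalence {prob} outside [0, 1]")
        missing = [f for f in COPULA_FIELDS + ["dbp_residual", "survey_weight"]
                   if f not in self.marginals]
        if missing:
            raise PopulationError(f"marginals missing for fields: {missing}")

    def with_(self, **kwargs) -> "PopulationSpec":
        return replace(self, **kwargs)


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a synthetic cohort according to ``spec``.

    Returns a DataFrame with the columns in :data:`SCHEMA`.  Continuous
    risk factors are coupled through a Gaussian copula; the derived
    diabetes flag is always consistent with the generated glucose values
    (fasting >= 126 or random >= 200 mg/dL implies diabetes).
    """
    spec.validate()
    n = spec.n
    if n == 0:
        return pd.DataFrame(columns=SCHEMA).astype({c: bool for c in BOOL_COLUMNS})

    rng = np.random.default_rng(spec.seed)
    r = np.asarray(spec.correlation, dtype=float)
    # eigen-decomposition square root: tolerant of semi-definite matrices
    w, v = np.linalg.eigh(r)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, len(COPULA_FIELDS))) @ root.T
    u = special.ndtr(z)

    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(COPULA_FIELDS):
        cols[name] = spec.marginals[name].ppf(u[:, j])

    age = cols["age"]
    d_age = age - spec.age_ref
    sbp = cols["sbp"] + spec.sbp_age_slope * d_age
    sbp = np.clip(sbp, 85.0, 260.0)
    resid = spec.marginals["dbp_residual"].ppf(rng.random(n))
    dbp = spec.dbp_intercept + spec.dbp_slope * sbp + resid
    dbp = np.clip(dbp, 40.0, sbp - 5.0)  # invariant sbp > dbp

    utility = cols["baseline_utility"] + spec.utility_age_slope * d_age
    utility = np.clip(utility, UTILITY_FLOOR, 1.0)

    sex = np.where(rng.random(n) < spec.p_male, "male", "female")
    p_smoke = np.where(
        sex == "male", spec.smoking_prevalence["male"], spec.smoking_prevalence["female"]
    )
    smoker = rng.random(n) < p_smoke

    fg, rg = cols["fasting_glucose"], cols["random_glucose"]
    diabetic_by_glucose = (fg >= FASTING_GLUCOSE_DIABETES) | (rg >= RANDOM_GLUCOSE_DIABETES)
    diagnosed = rng.random(n) < spec.p_diabetes_diagnosed
    diabetes = diabetic_by_glucose | diagnosed

    p_cvd = special.expit(spec.prior_cvd_intercept + spec.prior_cvd_slope * age)
    prior_cvd = rng.random(n) < p_cvd

    weight = spec.marginals["survey_weight"].ppf(rng.random(n))
    weight = weight * (spec.population_total / weight.sum())

    df = pd.DataFrame(
        {
            "person_id": np.arange(n, dtype=np.int64),
            "age": age,
            "sex": sex,
            "sbp": sbp,
            "dbp": dbp,
            "total_cholesterol": cols["total_cholesterol"],
            "fasting_glucose": fg,
            "random_glucose": rg,
            "diabetes": diabetes,
            "smoker": smoker,
            "bmi": cols["bmi"],
            "baseline_utility": utility,
            "survey_weight": weight,
            "prior_cvd": prior_cvd,
        }
    )
    return df[SCHEMA]


def _invariant_violations(df: pd.DataFrame) -> dict[int, str]:
    bad: dict[int, str] = {}

    def flag(mask: pd.Series, why: str) -> None:
        for i in df.index[np.asarray(mask, dtype=bool)]:
            bad.setdefault(int(i), why)

    flag(df[SCHEMA].isna().any(axis=1), "missing value")
    flag(~(df["sbp"] > df["dbp"]), "sbp must exceed dbp")
    flag(df["dbp"] <= 0, "dbp must be positive")
    for col in ("total_cholesterol", "fasting_glucose", "random_glucose", "bmi"):
        flag(df[col] <= 0, f"{col} must be positive")
    flag(df["baseline_utility"] > 1.0, "baseline_utility exceeds 1")
    flag(df["survey_weight"] < 0, "survey_weight negative")
    flag(df["age"] < 18, "age below 18")
    flag(
        (df["fasting_glucose"] >= FASTING_GLUCOSE_DIABETES) & ~df["diabetes"].astype(bool),
        "fasting glucose >= 126 but diabetes flag not set",
    )
    return bad


def validate_population(df: pd.DataFrame) -> pd.DataFrame:
    """Check a population table against the record invariants.

    Raises :class:`SchemaError` on missing columns and
    :class:`ValidationError` (listing offending rows) on invariant
    violations.  Extra columns are dropped with a logged notice.
    """
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"population table missing required columns: {missing}")
    extra = [c for c in df.columns if c not in SCHEMA]
    if extra:
        logger.info("ignoring extra population columns: %s", extra)
    df = df[SCHEMA].copy()
    bad = _invariant_violations(df)
    if bad:
        raise ValidationError("population rows violate invariants", bad)
    for c in BOOL_COLUMNS:
        df[c] = df[c].astype(bool)
    return df


def write_population(df: pd.DataFrame, path) -> None:
    df[SCHEMA].to_csv(path, index=False)


def load_population(path) -> pd.DataFrame:
    """Load and validate a population CSV (columns per :data:`SCHEMA`)."""
    df = pd.read_csv(path)
    return validate_population(df)
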