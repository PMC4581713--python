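"""Covariate schema and hazard specification for the synthetic screening cohort.

The defaults describe a Singapore Breast Cancer Screening Programme (SBCSP)
style population: women aged 50-64 recruited between October 1994 and
February 1997, followed through administrative censoring on 31 December 2011,
with the classical Gail-model risk factors plus ethnicity, body-mass index
and mammographic dense area as categorical covariates.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CategoricalVariable",
    "CovariateSchema",
    "HazardSpec",
    "SchemaError",
    "default_schema",
    "default_hazard_spec",
    "DAYS_PER_YEAR",
    "TEN_YEARS_DAYS",
]

DAYS_PER_YEAR = 365.25
#: ten years of follow-up, in days (the horizon of the absolute-risk score)
TEN_YEARS_DAYS = 3652


class SchemaError(ValueError):
    """Raised when a covariate schema or hazard specification is invalid."""


@dataclass(frozen=True)
class CategoricalVariable:
    """A categorical risk factor with population marginal frequencies.

    Parameters
    ----------
    name :
        Column name used in cohort tables.
    levels :
        Ordered level labels; the first entry is the reference level used
        for dummy coding and for the all-reference baseline profile.
    probs :
        Marginal probability of each level in the screening population.
    """

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise SchemaError(
                f"{self.name}: {len(self.levels)} levels but {len(self.probs)} probabilities"
            )
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"{self.name}: duplicate level labels")
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-12):
            raise SchemaError(
                f"{self.name}: probabilities must be nonnegative and sum to 1 (got {p.sum()!r})"
            )

    @property
    def reference(self) -> str:
        return self.levels[0]


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered collection of categorical risk factors."""

    variables: tuple[CategoricalVariable, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> CategoricalVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def subset(self, names: list[str]) -> "CovariateSchema":
        return CovariateSchema(tuple(self[n] for n in names))


@dataclass(frozen=True)
class HazardSpec:
    """Proportional-hazards data-generating specification.

    Event times are exponential with rate ``baseline_rate * exp(beta'x)``
    (per person-year) where the log hazard ratios ``beta`` act on dummy
    indicators of the non-reference covariate levels. Entry dates are uniform
    over the recruitment window and follow-up is administratively censored.
    """

    log_hazard_ratios: dict[str, dict[str, float]]
    baseline_rate: float
    recruitment_start: _dt.date = _dt.date(1994, 10, 1)
    recruitment_end: _dt.date = _dt.date(1997, 2, 28)
    censor_date: _dt.date = _dt.date(2011, 12, 31)

    def __post_init__(self) -> None:
        if not (self.baseline_rate > 0 and np.isfinite(self.baseline_rate)):
            raise SchemaError("baseline_rate must be positive and finite")
        for var, levels in self.log_hazard_ratios.items():
            for lvl, b in levels.items():
                if not np.isfinite(b):
                    raise SchemaError(f"non-finite log hazard ratio for {var}={lvl}")
        if self.censor_date <= self.recruitment_end:
            raise SchemaError("censor_date must be after the recruitment window")
        if self.recruitment_end <= self.recruitment_start:
            raise SchemaError("empty recruitment window")

    def with_baseline_rate(self, rate: float) -> "HazardSpec":
        return replace(self, baseline_rate=rate)

    def log_hr(self, variable: str, level: str, reference: str) -> float:
        if level == reference:
            return 0.0
        try:
            return self.log_hazard_ratios[variable][level]
        except KeyError as exc:
            raise SchemaError(
                f"no log hazard ratio configured for {variable}={level}"
            ) from exc

    def linear_predictor(self, covariates, schema: CovariateSchema) -> np.ndarray:
        """beta'x for each row of a covariate table (reference levels -> 0)."""
        lp = np.zeros(len(covariates), dtype=float)
        for var in schema.variables:
            if var.name not in self.log_hazard_ratios and len(var.levels) > 1:
                # all levels must resolve; log_hr raises on the first miss
                pass
            col = covariates[var.name].to_numpy()
            betas = np.array(
                [self.log_hr(var.name, lvl, var.reference) for lvl in var.levels]
            )
            idx = _level_codes(col, var)
            lp += betas[idx]
        return lp


def _level_codes(values: np.ndarray, var: CategoricalVariable) -> np.ndarray:
    lookup = {lvl: i for i, lvl in enumerate(var.levels)}
    try:
        return np.array([lookup[v] for v in values], dtype=int)
    except KeyError as exc:
        raise SchemaError(f"{var.name}: unknown level {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# Default population: pooled marginal counts of the SBCSP screening cohort
# (24,161 women; 680 incident cases = 106 in situ + 574 invasive).
# ---------------------------------------------------------------------------

_N_COHORT = 24_161

_POOLED_COUNTS: dict[str, dict[str, int]] = {
    "age_band": {"50-54": 227 + 7111, "55-59": 279 + 8651, "60-64": 174 + 7719},
    "ethnicity": {
        "Chinese": 583 + 19962,
        "Indian": 38 + 1085,
        "Malay": 36 + 1146,
        "Others": 23 + 1288,
    },
    "menarche_age": {">=14": 400 + 15317, "12-13": 241 + 7429, "<12": 39 + 735},
    "first_birth_age": {
        "<20": 80 + 4045,
        "20-24": 202 + 8862,
        "25-29_or_nulliparous": 286 + 7984,
        ">=30": 112 + 2590,
    },
    "first_degree_relatives": {"none": 644 + 22906, ">=1": (34 + 2) + (566 + 9)},
    "past_biopsy": {"no": 615 + 22266, "yes": 65 + 1215},
    "bmi": {
        "<20": 37 + 2567,
        "20-<24": 241 + 8503,
        "24-<28": 259 + 8273,
        ">=28": 143 + 4138,
    },
    "dense_area": {
        "<=10": 70 + 4723,
        "11-20": 221 + 8646,
        "21-30": 189 + 5299,
        "31-40": 108 + 2755,
        "41-50": 43 + 1225,
        "51-60": 49 + 833,
    },
}

# Hazard ratios of the fully adjusted model (Gail variables + BMI + density);
# reference levels carry HR 1 and are omitted.
_FULL_MODEL_HRS: dict[str, dict[str, float]] = {
    "age_band": {"55-59": 1.17, "60-64": 0.98},
    "ethnicity": {"Indian": 1.10, "Malay": 0.71, "Others": 1.05},
    "menarche_age": {"12-13": 1.14, "<12": 1.72},
    "first_birth_age": {"20-24": 1.14, "25-29_or_nulliparous": 1.63, ">=30": 1.97},
    "first_degree_relatives": {">=1": 1.78},
    "past_biopsy": {"yes": 1.66},
    "bmi": {"20-<24": 2.19, "24-<28": 2.66, ">=28": 3.37},
    "dense_area": {
        "11-20": 1.60,
        "21-30": 2.20,
        "31-40": 2.33,
        "41-50": 2.12,
        "51-60": 3.27,
    },
}

#: calibration target: incident breast-cancer cases over full follow-up
DEFAULT_TARGET_EVENTS = 106 + 574
#: default cohort size
DEFAULT_N_SUBJECTS = _N_COHORT


def default_schema() -> CovariateSchema:
    """Schema with the pooled covariate marginals of the screening cohort."""
    variables = []
    for name, counts in _POOLED_COUNTS.items():
        total = sum(counts.values())
        variables.append(
            CategoricalVariable(
                name=name,
                levels=tuple(counts),
                probs=tuple(c / total for c in counts.values()),
            )
        )
    return CovariateSchema(tuple(variables))


def default_hazard_spec(baseline_rate: float = 6.3e-4) -> HazardSpec:
    """Hazard specification with the fully adjusted hazard ratios as truth.

    The default ``baseline_rate`` (events per person-year for the
    all-reference profile) is a placeholder of the right order of magnitude;
    pipelines recalibrate it against the target event count with
    :func:`mammorisk.cohort.calibrate_baseline_rate`.
    """
    log_hrs = {
        var: {lvl: float(np.log(hr)) for lvl, hr in levels.items()}
        for var, levels in _FULL_MODEL_HRS.items()
    }
    return HazardSpec(log_hazard_ratios=log_hrs, baseline_rate=baseline_rate)
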