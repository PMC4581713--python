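"""Proportional-hazards risk models and 10-year absolute risk.

The modelling surface follows the Model/Results convention: build a
:class:`CoxRiskModel` from a cohort table and a :class:`ModelSpec`, call
``fit()``, and work with the returned :class:`CoxRiskResults` — fitted log
hazard ratios with Wald intervals, the 10-year cumulative baseline hazard
extracted at the reference covariate profile, per-subject absolute risks,
a proportional-hazards diagnostic and a printable summary.

Three nested specifications mirror a classical model-building sequence for
breast-cancer screening: the Gail variables refit to the cohort plus
ethnicity and BMI; the same plus mammographic dense-area categories; the
same plus a continuous genetic risk score.

Absolute risk comes from the survival function of the proportional-hazards
model, S(t|x) = exp(-e^{beta'x} H0(t)): the 10-year risk of a woman with
covariates x is 1 - S(10|x). Because the partial likelihood leaves H0
unestimated, H0(10y) is recovered from the Nelson-Aalen/Breslow cumulative
hazard evaluated at a reference profile x_ref (reference categories for the
categorical variables, the cohort-mean GRS for the continuous score):
H0(10y) = -log S^NA(10y | x_ref) / exp(beta' x_ref).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

logger = logging.getLogger(__name__)

from .schema import (
    TEN_YEARS_DAYS,
    CovariateSchema,
    SchemaError,
    default_schema,
)

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "CoxRiskModel",
    "CoxRiskResults",
    "FitError",
    "encode_design",
    "breslow_cumulative_hazard",
]

GRS_COLUMN = "grs"

_GAIL_BMI_BLOCK = [
    "age_band",
    "ethnicity",
    "menarche_age",
    "first_birth_age",
    "first_degree_relatives",
    "past_biopsy",
    "bmi",
]
_DENSITY_BLOCK = ["dense_area"]


class FitError(RuntimeError):
    """Raised when the partial-likelihood fit fails or is ill-posed."""


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate blocks enter the proportional-hazards model."""

    name: str
    covariates: tuple[str, ...]
    include_grs: bool = False

    @property
    def needs_density(self) -> bool:
        return "dense_area" in self.covariates


def _spec(name: str, blocks: Sequence[str], grs: bool) -> ModelSpec:
    return ModelSpec(name=name, covariates=tuple(blocks), include_grs=grs)


#: the nested model ladder, in increasing order of information
MODEL_SPECS: dict[str, ModelSpec] = {
    "gail_bmi": _spec("gail_bmi", _GAIL_BMI_BLOCK, False),
    "gail_bmi_density": _spec("gail_bmi_density", _GAIL_BMI_BLOCK + _DENSITY_BLOCK, False),
    "gail_bmi_density_grs": _spec(
        "gail_bmi_density_grs", _GAIL_BMI_BLOCK + _DENSITY_BLOCK, True
    ),
}


def encode_design(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    grs: np.ndarray | None = None,
    schema: CovariateSchema | None = None,
) -> pd.DataFrame:
    """Dummy-code the cohort for a model specification.

    One indicator column per non-reference level of each categorical block
    (named ``variable[level]``), plus an untransformed continuous ``grs``
    column when the specification includes the genetic risk score.
    """
    schema = schema if schema is not None else default_schema()
    cols: dict[str, np.ndarray] = {}
    for name in spec.covariates:
        var = schema[name]
        values = cohort[name].to_numpy()
        unseen = set(values) - set(var.levels)
        if unseen:
            raise SchemaError(f"{name}: unseen levels {sorted(unseen)}")
        for lvl in var.levels[1:]:
            cols[f"{name}[{lvl}]"] = (values == lvl).astype(float)
    if spec.include_grs:
        if grs is None:
            if GRS_COLUMN not in cohort.columns:
                raise SchemaError("specification includes GRS but no scores given")
            grs = cohort[GRS_COLUMN].to_numpy()
        g = np.asarray(grs, dtype=float)
        if len(g) != len(cohort):
            raise SchemaError("GRS vector length does not match cohort")
        cols[GRS_COLUMN] = g
    return pd.DataFrame(cols, index=cohort.index)


def breslow_cumulative_hazard(
    linear_predictor: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline cumulative hazard (Nelson-Aalen/Breslow) from a PH fit.

    Returns ``(event_times, H0)``: the step function
    ``H0(t) = sum_{t_i <= t} d_i / sum_{j at risk} exp(lp_j)``,
    i.e. the Nelson-Aalen estimator generalized to the proportional-hazards
    risk set. With a zero linear predictor it reduces to the classical
    Nelson-Aalen estimator.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    w = np.exp(np.asarray(linear_predictor, dtype=float))
    order = np.argsort(t, kind="stable")
    t, d, w = t[order], d[order], w[order]
    # risk set weight at each time = total minus weights of earlier exits
    cum_w = np.concatenate([[0.0], np.cumsum(w)])
    total = cum_w[-1]
    uniq, start = np.unique(t, return_index=True)
    at_risk = total - cum_w[start]
    d_at = np.add.reduceat(d, start)
    keep = d_at > 0
    increments = d_at[keep] / at_risk[keep]
    return uniq[keep], np.cumsum(increments)


class CoxRiskModel:
    """Cox proportional-hazards risk model for a screening cohort.

    Parameters
    ----------
    cohort :
        Cohort table with one row per woman: categorical risk-factor
        columns, follow-up ``time`` (days) and ``event`` indicator.
    spec :
        Which covariate blocks enter; one of :data:`MODEL_SPECS` or a
        custom :class:`ModelSpec`.
    grs :
        Genetic risk scores, required when ``spec.include_grs``; may also
        be supplied as a ``grs`` column of the cohort.
    schema :
        Covariate schema; defaults to the screening-population schema.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        spec: ModelSpec | str = "gail_bmi",
        grs: np.ndarray | None = None,
        schema: CovariateSchema | None = None,
    ) -> None:
        if isinstance(spec, str):
            spec = MODEL_SPECS[spec]
        self.spec = spec
        self.schema = schema if schema is not None else default_schema()
        self.cohort = cohort
        self.design = encode_design(cohort, spec, grs=grs, schema=self.schema)
        self.time = cohort["time"].to_numpy(dtype=float)
        self.event = cohort["event"].to_numpy(dtype=int)
        if self.event.sum() < 2:
            raise FitError("need at least two events to fit")
        const = [c for c in self.design.columns if self.design[c].nunique() <= 1]
        if const:
            raise FitError(f"constant design columns: {const}")

    @classmethod
    def from_dataframe(
        cls,
        cohort: pd.DataFrame,
        spec: ModelSpec | str = "gail_bmi",
        **kwargs,
    ) -> "CoxRiskModel":
        return cls(cohort, spec=spec, **kwargs)

    def fit(
        self,
        initial_point: np.ndarray | None = None,
        ridge_fallback: float = 1e-3,
    ) -> "CoxRiskResults":
        """Maximize the Efron partial likelihood and extract H0(10y).

        An unpenalized fit is attempted first. If it fails to converge —
        typically quasi-separation when a sparse covariate level carries no
        events in a small (e.g. cross-validation) subsample — the fit is
        retried with a small L2 penalty ``ridge_fallback``, which bounds
        the diverging coefficient while leaving well-identified ones
        essentially unchanged. Set ``ridge_fallback=0`` to disable.
        """
        df = self.design.copy()
        df["time"] = self.time
        df["event"] = self.event
        last_exc: Exception | None = None
        attempts: list[tuple[float, np.ndarray | None]] = [(0.0, initial_point)]
        if initial_point is not None:
            attempts.append((0.0, None))
        if ridge_fallback > 0:
            attempts.append((ridge_fallback, None))
        for penalizer, init in attempts:
            cph = CoxPHFitter(penalizer=penalizer)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cph.fit(
                        df,
                        duration_col="time",
                        event_col="event",
                        # copy: the optimizer iterates on this array in place
                        initial_point=None if init is None else np.array(init, dtype=float),
                        show_progress=False,
                    )
                except Exception as exc:  # lifelines convergence errors
                    last_exc = exc
                    continue
            beta = cph.params_.reindex(self.design.columns).copy()
            b = beta.to_numpy()
            # |log HR| > 15 is numerically divergent for these data
            if not np.all(np.isfinite(b)) or (penalizer == 0 and np.any(np.abs(b) > 15)):
                last_exc = FitError("divergent coefficients (possible separation)")
                continue
            if penalizer > 0:
                logger.warning(
                    "unpenalized fit failed; used ridge penalty %.1e", penalizer
                )
            return CoxRiskResults(model=self, _fitter=cph, params=beta)
        raise FitError(f"partial-likelihood fit failed: {last_exc}") from last_exc


@dataclass
class CoxRiskResults:
    """Fitted proportional-hazards risk model.

    Attributes
    ----------
    params :
        Log hazard ratios, indexed by design column.
    baseline_cumhaz_10y :
        H0 at ten years, extracted at the reference profile (lazy).
    """

    model: CoxRiskModel
    _fitter: CoxPHFitter
    params: pd.Series
    _h0_10y: float | None = field(default=None, repr=False)

    # -- coefficient-level quantities ------------------------------------
    @property
    def standard_errors(self) -> pd.Series:
        return self._fitter.standard_errors_.reindex(self.params.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald interval for the hazard ratios."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.standard_errors
        return pd.DataFrame(
            {
                "hr_lower": np.exp(self.params - z * se),
                "hr_upper": np.exp(self.params + z * se),
            },
            index=self.params.index,
        )

    @property
    def p_values(self) -> pd.Series:
        return self._fitter.summary["p"].reindex(self.params.index)

    @property
    def log_partial_likelihood(self) -> float:
        return float(self._fitter.log_likelihood_)

    @property
    def linear_predictor(self) -> np.ndarray:
        return self.model.design.to_numpy() @ self.params.to_numpy()

    # -- baseline hazard and absolute risk -------------------------------
    @property
    def reference_profile(self) -> np.ndarray:
        """x_ref: zeros for category dummies, cohort mean for the GRS."""
        x = np.zeros(len(self.params))
        if self.model.spec.include_grs:
            x[list(self.params.index).index(GRS_COLUMN)] = float(
                self.model.design[GRS_COLUMN].mean()
            )
        return x

    @property
    def baseline_cumhaz_10y(self) -> float:
        """H0(10y) = -log S^NA(10y | x_ref) / exp(beta' x_ref).

        S^NA is the Nelson-Aalen-based survival estimate at the reference
        profile, evaluated at the largest event time at or before ten
        years; zero (with no events before ten years) gives H0 = 0.
        """
        if self._h0_10y is None:
            self._h0_10y = self.cumulative_baseline_hazard(TEN_YEARS_DAYS)
        return self._h0_10y

    def cumulative_baseline_hazard(self, t_days: float) -> float:
        lp = self.linear_predictor
        x_ref = self.reference_profile
        lp_ref = float(x_ref @ self.params.to_numpy())
        times, h0 = breslow_cumulative_hazard(lp, self.model.time, self.model.event)
        idx = np.searchsorted(times, t_days, side="right") - 1
        if idx < 0:
            return 0.0
        # H(t|x_ref) = exp(lp_ref) * H0(t); S^NA = exp(-H); the quotient
        # recovers H0 exactly, kept in this form to mirror the definition
        s_na = np.exp(-np.exp(lp_ref) * h0[idx])
        return float(-np.log(s_na) / np.exp(lp_ref))

    def predict_risk_10y(
        self,
        cohort: pd.DataFrame | None = None,
        grs: np.ndarray | None = None,
    ) -> np.ndarray:
        """Ten-year absolute risk, 1 - exp(-e^{beta'x} H0(10y)), per woman."""
        if cohort is None:
            design = self.model.design
        else:
            design = encode_design(
                cohort, self.model.spec, grs=grs, schema=self.model.schema
            )
            design = design.reindex(columns=self.params.index, fill_value=0.0)
        lp = design.to_numpy() @ self.params.to_numpy()
        return 1.0 - np.exp(-np.exp(lp) * self.baseline_cumhaz_10y)

    # -- diagnostics ------------------------------------------------------
    def check_proportional_hazards(self, time_transform: str = "rank") -> pd.DataFrame:
        """Schoenfeld-residual test of proportional hazards.

        Correlates each covariate's scaled Schoenfeld residuals with
        transformed event time; returns per-covariate statistics and
        p-values. Small p-values flag time-varying effects.
        """
        res = proportional_hazard_test(
            self._fitter, self._fit_frame(), time_transform=time_transform
        )
        out = res.summary.reset_index().rename(columns={"index": "covariate"})
        return out

    def _fit_frame(self) -> pd.DataFrame:
        df = self.model.design.copy()
        df["time"] = self.model.time
        df["event"] = self.model.event
        return df

    def concordance(self, **kwargs) -> float:
        """Gonen-Heller concordance probability of this fit."""
        from .evaluation import concordance_probability

        return concordance_probability(self.linear_predictor, **kwargs)

    # -- reporting ---------------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table: HR, 95% interval, p-value per design column."""
        ci = self.conf_int()
        frame = pd.DataFrame(
            {
                "coef": self.params,
                "hazard_ratio": self.hazard_ratios,
                "hr_lower_95": ci["hr_lower"],
                "hr_upper_95": ci["hr_upper"],
                "se": self.standard_errors,
                "p": self.p_values,
            }
        )
        frame.index.name = "term"
        return frame

    def summary(self) -> str:
        lines = [
            f"Cox proportional-hazards risk model: {self.model.spec.name}",
            f"  subjects: {len(self.model.time)}    events: {int(self.model.event.sum())}",
            f"  log partial likelihood: {self.log_partial_likelihood:.2f}",
            f"  10-year cumulative baseline hazard: {self.baseline_cumhaz_10y:.5f}",
            "",
            self.summary_frame().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
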