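"""Synthetic screening-cohort generation.

Covariates are drawn independently from their population marginals; event
times follow an exponential proportional-hazards law whose baseline rate is
calibrated so that the expected number of incident cases over the full
follow-up matches a target count (680 by default, mirroring the screening
programme the generator emulates). Follow-up is administratively censored at
a fixed calendar date; there is no competing mortality or loss to follow-up.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .schema import (
    DAYS_PER_YEAR,
    DEFAULT_N_SUBJECTS,
    DEFAULT_TARGET_EVENTS,
    TEN_YEARS_DAYS,
    CovariateSchema,
    HazardSpec,
    SchemaError,
    default_hazard_spec,
    default_schema,
)

__all__ = [
    "sample_covariates",
    "simulate_outcomes",
    "calibrate_baseline_rate",
    "expected_event_count",
    "generate_cohort",
    "derive_label_10y",
    "read_cohort",
    "write_cohort",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Raised when no baseline rate can reach the requested event count."""


def sample_covariates(
    n: int, schema: CovariateSchema | None = None, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Draw ``n`` covariate rows, each variable independent of the others.

    Returns a DataFrame with one string-valued column per schema variable
    plus a ``subject_id`` column. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    schema = schema if schema is not None else default_schema()
    rng = np.random.default_rng(seed)
    data = {"subject_id": np.arange(n)}
    for var in schema.variables:
        codes = rng.choice(len(var.levels), size=n, p=var.probs)
        data[var.name] = np.asarray(var.levels, dtype=object)[codes]
    return pd.DataFrame(data)


def derive_label_10y(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Binary label: diagnosed within ten years (3,652 days) of entry."""
    return ((np.asarray(event) == 1) & (np.asarray(time) <= TEN_YEARS_DAYS)).astype(int)


def simulate_outcomes(
    covariates: pd.DataFrame,
    spec: HazardSpec | None = None,
    schema: CovariateSchema | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Attach entry dates, follow-up times and event indicators.

    Event times are exponential with rate ``baseline_rate * exp(beta'x)``
    (per person-year, converted to days); entry dates are uniform over the
    recruitment window; follow-up ends at the event or the administrative
    censoring date, whichever comes first. Times are reported at day
    resolution (minimum one day).
    """
    schema = schema if schema is not None else default_schema()
    spec = spec if spec is not None else default_hazard_spec()
    rng = np.random.default_rng(seed)
    n = len(covariates)

    lp = spec.linear_predictor(covariates, schema)
    rate_per_day = spec.baseline_rate * np.exp(lp) / DAYS_PER_YEAR

    window_days = (spec.recruitment_end - spec.recruitment_start).days
    entry_offset = rng.integers(0, window_days + 1, size=n)
    entry_dates = np.array(
        [spec.recruitment_start + _dt.timedelta(days=int(d)) for d in entry_offset]
    )
    admin_days = np.array(
        [(spec.censor_date - d).days for d in entry_dates], dtype=float
    )

    raw = rng.exponential(1.0, size=n) / rate_per_day
    event_days = np.maximum(np.ceil(raw), 1.0)
    event = (event_days <= admin_days).astype(int)
    time = np.where(event == 1, event_days, admin_days).astype(int)

    out = covariates.copy()
    out["entry_date"] = [d.isoformat() for d in entry_dates]
    out["time"] = time
    out["event"] = event
    out["label_10y"] = derive_label_10y(time, event)
    return out


def _profile_mixture(schema: CovariateSchema, spec: HazardSpec):
    """Enumerate the covariate mixture: (probability, hazard multiplier)."""
    probs = np.ones(1)
    mult = np.ones(1)
    for var in schema.variables:
        betas = np.array(
            [spec.log_hr(var.name, lvl, var.reference) for lvl in var.levels]
        )
        probs = np.outer(probs, np.asarray(var.probs)).ravel()
        mult = np.outer(mult, np.exp(betas)).ravel()
    return probs, mult


def expected_event_count(
    schema: CovariateSchema,
    spec: HazardSpec,
    n: int,
    n_entry_grid: int = 64,
) -> float:
    """Analytic expectation of incident cases under the generator.

    Averages the exponential cumulative incidence 1 - exp(-lambda0 r T)
    over the enumerated covariate mixture and a grid of entry dates spanning
    the recruitment window.
    """
    probs, mult = _profile_mixture(schema, spec)
    window_days = (spec.recruitment_end - spec.recruitment_start).days
    offsets = (np.arange(n_entry_grid) + 0.5) / n_entry_grid * window_days
    t_years = (
        (spec.censor_date - spec.recruitment_start).days - offsets
    ) / DAYS_PER_YEAR
    # mixture x entry-grid incidence, then collapse
    lam = spec.baseline_rate * mult[:, None] * t_years[None, :]
    inc = 1.0 - np.exp(-lam)
    return float(n * probs @ inc.mean(axis=1))


def calibrate_baseline_rate(
    schema: CovariateSchema | None = None,
    spec: HazardSpec | None = None,
    n: int = DEFAULT_N_SUBJECTS,
    target_events: int = DEFAULT_TARGET_EVENTS,
) -> float:
    """Root-find the baseline rate matching an expected event count.

    Returns lambda0 in events per person-year for the all-reference profile
    such that the analytic expected number of events equals
    ``target_events``.
    """
    schema = schema if schema is not None else default_schema()
    spec = spec if spec is not None else default_hazard_spec()
    if target_events >= n:
        raise CalibrationError("target_events must be smaller than the cohort size")
    if target_events < 0:
        raise CalibrationError("target_events must be nonnegative")
    if target_events == 0:
        return 0.0

    def excess(log_lam: float) -> float:
        s = spec.with_baseline_rate(float(np.exp(log_lam)))
        return expected_event_count(schema, s, n) - target_events

    lo, hi = np.log(1e-10), np.log(10.0)
    if excess(hi) < 0:
        raise CalibrationError("target event count unattainable at any baseline rate")
    return float(np.exp(brentq(excess, lo, hi, xtol=1e-12, rtol=1e-12)))


def generate_cohort(
    n: int = DEFAULT_N_SUBJECTS,
    target_events: int = DEFAULT_TARGET_EVENTS,
    schema: CovariateSchema | None = None,
    spec: HazardSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample covariates, calibrate the baseline rate and simulate outcomes."""
    schema = schema if schema is not None else default_schema()
    spec = spec if spec is not None else default_hazard_spec()
    lam = calibrate_baseline_rate(schema, spec, n=n, target_events=target_events)
    if lam == 0.0:
        lam = 1e-12
    spec = spec.with_baseline_rate(lam)
    ss = np.random.SeedSequence(seed)
    cov_seed, out_seed = ss.spawn(2)
    covs = sample_covariates(n, schema, seed=np.random.default_rng(cov_seed))
    return simulate_outcomes(covs, spec, schema, seed=np.random.default_rng(out_seed))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path, schema: CovariateSchema | None = None) -> pd.DataFrame:
    """Read a cohort CSV and check it against the schema.

    Raises :class:`~mammorisk.schema.SchemaError` on unknown covariate
    levels or inconsistent 10-year labels.
    """
    schema = schema if schema is not None else default_schema()
    df = pd.read_csv(path, dtype={v: str for v in schema.names})
    required = {"time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"cohort file missing columns: {sorted(missing)}")
    for var in schema.variables:
        if var.name not in df.columns:
            raise SchemaError(f"cohort file missing covariate column {var.name!r}")
        bad = set(df[var.name].unique()) - set(var.levels)
        if bad:
            raise SchemaError(f"{var.name}: unknown levels {sorted(bad)}")
    if (df["time"] <= 0).any():
        raise SchemaError("follow-up times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise SchemaError("event indicator must be binary")
    if "label_10y" not in df.columns:
        df["label_10y"] = derive_label_10y(df["time"].to_numpy(), df["event"].to_numpy())
    return df
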