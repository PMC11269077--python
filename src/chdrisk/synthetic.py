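"""Synthetic surgical registries with the structure the pipeline assumes.

Two linked generators:

* :func:`simulate_procedure_outcomes` draws a procedure-outcome table:
  per-procedure true mortality from a logit-normal law
  ``logit(p_j) ~ Normal(mu, tau^2)``, case volumes from a discretised
  log-uniform law (heavy-tailed, spanning a few cases to thousands, as
  real surgical volumes do), and deaths ``d_j ~ Binomial(n_j, p_j)``.
  True rates are returned separately so recovery tests can compare
  estimates against truth.
* :func:`simulate_patients` draws a patient-level registry: each patient
  gets a procedure (volume-weighted), mixed categorical/continuous
  preoperative covariates from configurable marginals, and an in-hospital
  death from a logistic model combining covariate effects with the
  procedure's random effect.  Missingness is applied completely at
  random per covariate, after the outcome is generated.

Defaults emulate the reference cohort: ~2.4% overall mortality, 105
procedure types, volumes from 3 to 8000, and ten covariates mirroring
the strongest preoperative risk factors (pulse-oximetry category, age,
preoperative mechanical ventilation, shunt directions, echo dimension
categories, surgical history, defect counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .stratify import assign_categories

__all__ = ["CovariateSpec", "RegistrySpec", "default_covariates", "null_spec",
           "simulate_procedure_outcomes", "simulate_patients", "simulate_registry"]


def _logit_normal_location(mean_rate, tau, quad_points=80):
    """Location mu with E[expit(mu + tau Z)] = mean_rate, by quadrature."""
    if tau == 0:
        return float(logit(mean_rate))
    from numpy.polynomial.hermite import hermgauss
    x, w = hermgauss(quad_points)

    def mean_of(mu):
        return float((w * expit(mu + np.sqrt(2) * tau * x)).sum() / np.sqrt(np.pi))

    return float(brentq(lambda m: mean_of(m) - mean_rate, -30.0, 10.0))


@dataclass
class CovariateSpec:
    """Marginal law, missingness, and outcome effect of one covariate.

    ``kind`` is ``"binary"``, ``"categorical"``, ``"ordinal"``, ``"count"``
    or ``"continuous"``.  Discrete kinds draw from ``levels`` with
    ``probs``; continuous kinds draw log-normally with ``log_mean`` /
    ``log_sd`` (clipped to ``clip``).  ``effect`` is a per-level dict of
    log-odds offsets for discrete kinds, or a slope on the standardised
    log value (continuous) / raw value (binary, count).
    ``missing`` is the MCAR missingness fraction in [0, 0.95].
    """
    kind: str
    levels: list | None = None
    probs: list | None = None
    log_mean: float = 0.0
    log_sd: float = 1.0
    clip: tuple | None = None
    missing: float = 0.0
    effect: object = 0.0

    def __post_init__(self):
        if not 0.0 <= self.missing <= 0.95:
            raise ValueError("missingness must be in [0, 0.95]")
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            if abs(p.sum() - 1.0) > 1e-6:
                raise ValueError("level probabilities must sum to 1")


def default_covariates() -> dict:
    """Ten covariates mirroring the reference cohort's top risk factors.

    Marginal level frequencies follow the cohort's descriptive table;
    effect signs follow the death/non-death contrasts there (e.g. low
    pulse-oximetry, preoperative ventilation, bidirectional shunts, small
    left atrium, reoperation, and younger age all raise the odds of
    in-hospital death).
    """
    return {
        "spo2_low": CovariateSpec("binary", levels=[0, 1], probs=[0.738, 0.262],
                                  missing=0.03, effect=1.6),
        "age_days": CovariateSpec("continuous", log_mean=np.log(300.0), log_sd=1.1,
                                  clip=(1, 6568), missing=0.0, effect=-0.55),
        "preop_mech_vent": CovariateSpec("binary", levels=[0, 1],
                                         probs=[0.911, 0.089], effect=1.4),
        "atrial_shunt": CovariateSpec(
            "categorical", levels=["none", "left_to_right", "right_to_left", "two_way"],
            probs=[0.3648, 0.4405, 0.0400, 0.1547], missing=0.05,
            effect={"none": 0.0, "left_to_right": 0.1, "right_to_left": 0.9,
                    "two_way": 0.9}),
        "pulmonary_insufficiency": CovariateSpec(
            "ordinal", levels=["negative", "slight", "mild", "mild_moderate",
                               "moderate", "moderate_severe", "severe"],
            probs=[0.1546, 0.5608, 0.2677, 0.0058, 0.0104, 0.0003, 0.0004],
            missing=0.05,
            effect={"negative": 0.8, "slight": 0.0, "mild": 0.1,
                    "mild_moderate": 0.3, "moderate": 0.6,
                    "moderate_severe": 0.8, "severe": 0.8}),
        "ventricular_shunt": CovariateSpec(
            "categorical", levels=["none", "left_to_right", "right_to_left", "two_way"],
            probs=[0.2727, 0.3529, 0.0021, 0.3723], missing=0.05,
            effect={"none": 0.4, "left_to_right": -0.9, "right_to_left": 0.8,
                    "two_way": 0.7}),
        "left_atrial_dimension": CovariateSpec(
            "ordinal", levels=["below_critical", "normal", "above_critical"],
            probs=[0.1247, 0.2171, 0.6582], missing=0.08,
            effect={"below_critical": 0.8, "normal": 0.3, "above_critical": 0.0}),
        "history_cardiac_surgery": CovariateSpec(
            "count", levels=[0, 1, 2], probs=[0.895, 0.098, 0.007], effect=1.2),
        "number_of_defects": CovariateSpec(
            "count", levels=list(range(8)),
            probs=[0.360, 0.236, 0.216, 0.094, 0.059, 0.027, 0.0075, 0.0005],
            effect=0.15),
    }


@dataclass
class RegistrySpec:
    """Study conditions of a synthetic registry.

    Defaults reproduce the scale of the reference cohort: 105 procedure
    types with logit-normal mortality heterogeneity around 2.4%
    (``mu = logit(0.024)``, ``tau = 0.9``), case volumes log-uniform on
    [3, 8000], 24,685 patients, and a ~2.4% overall death fraction
    (the intercept is solved so the mean simulated risk hits
    ``target_mortality`` unless ``base_log_odds`` is given explicitly).
    ``effect_scale`` multiplies every covariate effect (0 gives a null
    registry where no feature is informative).
    """
    n_procedures: int = 105
    n_patients: int = 24685
    mu: float | None = None
    tau: float = 0.9
    volume_range: tuple = (3, 8000)
    covariates: dict = field(default_factory=default_covariates)
    effect_scale: float = 1.0
    procedure_effect_scale: float = 1.0
    target_mortality: float = 0.024
    base_log_odds: float | None = None

    def __post_init__(self):
        if self.n_patients < self.n_procedures:
            raise ValueError("need n_patients >= n_procedures")
        if self.mu is None:
            # location of the logit-normal law such that the *mean* procedure
            # mortality equals target_mortality (the logit-normal mean exceeds
            # the inverse-logit of its location, noticeably at tau ~ 1)
            self.mu = _logit_normal_location(self.target_mortality, self.tau)


def simulate_procedure_outcomes(spec: RegistrySpec, seed=None):
    """Draw a procedure-outcome table; returns ``(table, true_rates)``.

    ``table`` has procedure/cases/deaths columns (cases always >= the
    volume-law floor of 3); ``true_rates`` carries the latent ``p_j`` for
    parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    J = spec.n_procedures
    lo, hi = spec.volume_range
    n = np.floor(np.exp(rng.uniform(np.log(lo), np.log(hi + 1), J))).astype(int)
    n = np.clip(n, lo, hi)
    b = spec.tau * rng.standard_normal(J) if spec.tau > 0 else np.zeros(J)
    p = expit(spec.mu + b)
    d = rng.binomial(n, p)
    names = [f"procedure_{j:03d}" for j in range(J)]
    table = pd.DataFrame({"procedure": names, "cases": n, "deaths": d})
    truth = pd.DataFrame({"procedure": names, "true_rate": p,
                          "random_effect": b})
    return table, truth


def _linear_predictor(spec, cov_values):
    """Covariate part of the patient-level log-odds (no intercept)."""
    eta = np.zeros(len(next(iter(cov_values.values()))))
    for name, cspec in spec.covariates.items():
        x = cov_values[name]
        if isinstance(cspec.effect, dict):
            lut = np.array([cspec.effect[lv] for lv in cspec.levels])
            eta += lut[x]
        elif cspec.kind == "continuous":
            z = (np.log(x) - cspec.log_mean) / cspec.log_sd
            eta += cspec.effect * z
        else:
            eta += cspec.effect * x.astype(float)
    return spec.effect_scale * eta


def simulate_patients(spec: RegistrySpec, procedures=None, truth=None,
                      strat=None, seed=None):
    """Draw a patient-level registry from the spec's study conditions.

    Patients are assigned procedures volume-weighted from ``procedures``
    (generated from the spec if not supplied, along with ``truth``).  The
    outcome is Bernoulli with log-odds
    ``beta0 + sum(effects) + procedure random effect``; missingness is
    applied after outcomes are drawn, so it never censors the endpoint.
    If ``strat`` is given, ``risk_category`` is filled from it.
    """
    rng = np.random.default_rng(seed)
    if procedures is None or truth is None:
        procedures, truth = simulate_procedure_outcomes(
            spec, rng.integers(2**31))
    n = spec.n_patients

    vol = procedures["cases"].to_numpy(dtype=float)
    proc_idx = rng.choice(len(procedures), size=n, p=vol / vol.sum())
    proc_names = procedures["procedure"].to_numpy()[proc_idx]
    proc_eff = (spec.procedure_effect_scale
                * truth["random_effect"].to_numpy()[proc_idx])

    # draw covariates (level indices for discrete kinds)
    raw = {}
    for name, cspec in spec.covariates.items():
        if cspec.kind == "continuous":
            x = np.exp(cspec.log_mean + cspec.log_sd * rng.standard_normal(n))
            if cspec.clip is not None:
                x = np.clip(x, *cspec.clip)
            raw[name] = x
        else:
            raw[name] = rng.choice(len(cspec.levels), size=n,
                                   p=np.asarray(cspec.probs, dtype=float))

    eta = _linear_predictor(spec, raw) + proc_eff
    if spec.base_log_odds is not None:
        beta0 = spec.base_log_odds
    else:
        beta0 = brentq(lambda c: expit(eta + c).mean() - spec.target_mortality,
                       -25.0, 10.0)
    died = rng.binomial(1, expit(eta + beta0))

    cols = {"patient_id": np.arange(n)}
    for name, cspec in spec.covariates.items():
        if cspec.kind == "continuous":
            vals = pd.Series(raw[name])
        elif cspec.kind in ("binary", "count"):
            vals = pd.Series(np.asarray(cspec.levels)[raw[name]], dtype=float)
        else:
            vals = pd.Series(pd.Categorical.from_codes(raw[name], cspec.levels))
        if cspec.missing > 0:
            mask = rng.random(n) < cspec.missing
            vals[mask] = np.nan
        cols[name] = vals
    cols["procedure_name"] = proc_names
    cols["died_in_hospital"] = died
    patients = pd.DataFrame(cols)
    if "age_days" in patients:
        patients["age_days"] = patients["age_days"].round().clip(lower=1)
    if strat is not None:
        patients = assign_categories(patients, strat)
    return patients


def simulate_registry(spec: RegistrySpec | None = None, seed=None):
    """Procedure table, truth, and patients in one seeded call."""
    spec = spec or RegistrySpec()
    rng = np.random.default_rng(seed)
    procedures, truth = simulate_procedure_outcomes(spec, rng.integers(2**31))
    patients = simulate_patients(spec, procedures, truth,
                                 seed=rng.integers(2**31))
    return {"spec": spec, "procedures": procedures, "truth": truth,
            "patients": patients}


def null_spec(**overrides) -> RegistrySpec:
    """Registry spec with all covariate effects switched off."""
    return replace(RegistrySpec(**overrides), effect_scale=0.0,
                   procedure_effect_scale=0.0)
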