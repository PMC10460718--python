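"""Structural population PK model of bempedoic acid.

Single transit absorption compartment emptying into a two-compartment
disposition system with linear elimination from the central compartment.  All
parameters are apparent (divided by the unobserved oral bioavailability F):
CL/F in L/h, Vc/F in L, first-order rates per hour.  The covariate model uses
power functions for continuous covariates,

    theta_TV = theta_ref * (x / x_ref) ** theta_x,

and proportional shifts for categorical indicators,

    theta_TV = theta_ref * (1 + theta_x * x),

with multiple effects on the same parameter combining multiplicatively.
Interindividual variability is log-normal: parameter * exp(eta).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PKParams",
    "CovariateEffect",
    "PopulationPKModel",
    "Regimen",
    "apply_covariates_pk",
    "hybrid_constants",
    "predict_concentration",
    "conc_matrix",
    "auc_ss",
    "cavg_ss",
    "qd_regimen",
    "cv_to_omega2",
    "omega2_to_cv",
    "load_pk_model",
    "final_pk_model",
    "ConfigurationError",
]


class ConfigurationError(KeyError):
    """A covariate named by an effect is absent from the subject's covariates."""


def cv_to_omega2(cv_percent: float) -> float:
    """Log-normal variance omega^2 from a coefficient of variation in percent."""
    cv = cv_percent / 100.0
    return math.log1p(cv * cv)


def omega2_to_cv(omega2: float) -> float:
    """Coefficient of variation in percent from a log-normal variance."""
    return math.sqrt(math.expm1(omega2)) * 100.0


@dataclasses.dataclass
class PKParams:
    """Individual-level structural PK parameters."""

    cl_f: float   # L/h
    vc_f: float   # L
    ka: float     # 1/h, transit/absorption rate
    k23: float    # 1/h, central -> peripheral
    k32: float    # 1/h, peripheral -> central
    f1_rel: float = 1.0  # relative bioavailability

    def __post_init__(self) -> None:
        for name in ("cl_f", "vc_f", "ka", "k23", "k32", "f1_rel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def k10(self) -> float:
        return self.cl_f / self.vc_f

    def with_eta(self, eta: Mapping[str, float]) -> "PKParams":
        """Apply log-normal random effects: parameter * exp(eta)."""
        kw = dataclasses.asdict(self)
        for name, e in eta.items():
            kw[name] = kw[name] * math.exp(e)
        return PKParams(**kw)


@dataclasses.dataclass
class CovariateEffect:
    """One covariate-parameter relationship (power or proportional-shift form)."""

    target: str          # parameter name, e.g. "cl_f"
    covariate: str       # covariate name looked up in the subject's covariates
    form: str            # "power" | "proportional"
    theta: float
    reference: float | None = None  # required for power form

    def __post_init__(self) -> None:
        if self.form not in ("power", "proportional"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "power" and (self.reference is None or self.reference <= 0):
            raise ValueError("power form requires a positive reference value")
        if self.form == "proportional" and self.theta <= -1:
            raise ValueError("proportional-shift theta must exceed -1 for positivity")

    def multiplier(self, x: float) -> float:
        if self.form == "power":
            return (x / self.reference) ** self.theta
        return 1.0 + self.theta * x


@dataclasses.dataclass
class PopulationPKModel:
    """Fixed effects, covariate effects, IIV variances and residual SDs."""

    thetas: PKParams
    covariate_effects: list[CovariateEffect] = dataclasses.field(default_factory=list)
    omega2: dict[str, float] = dataclasses.field(default_factory=dict)  # per-parameter IIV variance
    sigma_serial: float = 0.3    # log-additive residual SD, serial sampling
    sigma_sparse: float = 0.5    # log-additive residual SD, sparse sampling

    def __post_init__(self) -> None:
        for k, v in self.omega2.items():
            if v < 0:
                raise ValueError(f"omega2[{k}] must be >= 0")
        if self.sigma_serial <= 0 or self.sigma_sparse <= 0:
            raise ValueError("residual SDs must be > 0")

    @property
    def eta_names(self) -> list[str]:
        return [k for k, v in self.omega2.items() if v > 0]

    def food_ka_multiplier(self) -> float:
        """Combined proportional shift on Ka in the fed state."""
        m = 1.0
        for eff in self.covariate_effects:
            if eff.covariate == "food" and eff.target == "ka":
                m *= eff.multiplier(1.0)
        return m


def apply_covariates_pk(model: PopulationPKModel, cov: Mapping[str, float]) -> PKParams:
    """Typical-value parameters for one subject's covariate vector.

    Effects targeting the same parameter multiply; the order of
    ``model.covariate_effects`` is immaterial.  Raises
    :class:`ConfigurationError` naming any covariate an effect needs but the
    mapping lacks.
    """
    kw = dataclasses.asdict(model.thetas)
    for eff in model.covariate_effects:
        if eff.covariate not in cov:
            raise ConfigurationError(
                f"covariate {eff.covariate!r} required by effect on {eff.target} is missing"
            )
        kw[eff.target] *= eff.multiplier(float(cov[eff.covariate]))
    return PKParams(**kw)


def hybrid_constants(params: PKParams) -> tuple[float, float, float, float]:
    """Hybrid rate constants and half-lives of the two-compartment disposition.

    alpha and beta are the roots of ``s^2 - (k10+k23+k32) s + k10*k32 = 0``
    with ``alpha >= beta > 0``; half-lives are ln2/root.  Returns
    ``(alpha, beta, t_half_alpha, t_half_beta)``.
    """
    k10 = params.k10
    s = k10 + params.k23 + params.k32
    p = k10 * params.k32
    disc = s * s - 4.0 * p
    assert disc > 0, "discriminant must be positive for positive micro-constants"
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return alpha, beta, math.log(2) / alpha, math.log(2) / beta


@dataclasses.dataclass
class Regimen:
    """A dosing regimen: dose times (h), amounts (mg) and per-dose fed state."""

    times: np.ndarray
    amounts: np.ndarray
    food: np.ndarray  # boolean, per dose

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        self.food = np.asarray(self.food, dtype=bool)
        if not (len(self.times) == len(self.amounts) == len(self.food)):
            raise ValueError("times, amounts and food must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("dose times must be sorted")
        if np.any(self.times < 0):
            raise ValueError("dose times must be non-negative")


def qd_regimen(dose_mg: float, n_days: int, food: bool = False) -> Regimen:
    """Once-daily dosing for ``n_days`` days starting at time 0."""
    t = 24.0 * np.arange(n_days, dtype=float)
    return Regimen(t, np.full(n_days, dose_mg), np.full(n_days, food))


def _separate(lams: np.ndarray, rel: float = 1e-7) -> np.ndarray:
    """Nudge near-coincident exponents apart so the partial-fraction closed form
    stays finite; the perturbation is relative and tiny, so the result is the
    correct limit to well below solver tolerances."""
    lams = np.array(lams, dtype=float)
    for i in range(1, 3):
        for j in range(i):
            if abs(lams[i] - lams[j]) < rel * max(lams[i], lams[j], 1e-300):
                lams[i] = lams[i] * (1.0 + 10 * rel) + 1e-300
    return lams


def _single_dose_conc(params: PKParams, ka: float, t: np.ndarray) -> np.ndarray:
    """Unit-dose central concentration at times t >= 0 after one dose into the
    transit compartment (per mg of bioavailable dose)."""
    alpha, beta, _, _ = hybrid_constants(params)
    lam = _separate(np.array([alpha, beta, ka]))
    a, b, k = lam
    k32 = params.k32
    coef_a = (k32 - a) / ((k - a) * (b - a))
    coef_b = (k32 - b) / ((k - b) * (a - b))
    coef_k = (k32 - k) / ((a - k) * (b - k))
    t = np.asarray(t, dtype=float)
    pos = t >= 0
    out = np.zeros_like(t)
    tp = t[pos]
    out[pos] = (
        coef_a * np.exp(-a * tp) + coef_b * np.exp(-b * tp) + coef_k * np.exp(-k * tp)
    )
    return out * ka / params.vc_f


def predict_concentration(
    params: PKParams,
    regimen: Regimen,
    times: Sequence[float],
    food_ka_multiplier: float = 1.0,
) -> np.ndarray:
    """Central-compartment concentration (µg/mL) at the requested times.

    Closed-form solution of the linear transit -> central <-> peripheral system
    with elimination from the central compartment, superposed over doses.  Each
    dose enters the transit compartment scaled by ``f1_rel``; doses flagged as
    fed use ``ka * food_ka_multiplier``.
    """
    times = np.asarray(times, dtype=float)
    conc = np.zeros_like(times)
    for td, amt, fed in zip(regimen.times, regimen.amounts, regimen.food):
        if amt == 0:
            continue
        ka = params.ka * (food_ka_multiplier if fed else 1.0)
        conc = conc + amt * params.f1_rel * _single_dose_conc(params, ka, times - td)
    return np.maximum(conc, 0.0)  # guard rounding at the dose instant


def auc_ss(params: PKParams, dose_mg: float) -> float:
    """Steady-state AUC over one dosing interval, µg·h/mL: F1·dose / (CL/F)."""
    if dose_mg < 0:
        raise ValueError("dose must be >= 0")
    return params.f1_rel * dose_mg / params.cl_f


def cavg_ss(params: PKParams, dose_mg: float, tau_h: float = 24.0) -> float:
    """Average steady-state concentration for the given dosing interval, µg/mL."""
    return auc_ss(params, dose_mg) / tau_h


def conc_matrix(
    cl_f: np.ndarray,
    vc_f: np.ndarray,
    ka: np.ndarray,
    k23: np.ndarray,
    k32: np.ndarray,
    f1_rel: np.ndarray,
    regimen: Regimen,
    times: np.ndarray,
    food_ka_multiplier: float = 1.0,
) -> np.ndarray:
    """Vectorized closed-form concentrations for many subjects on one regimen.

    Parameter arrays are shape ``(n,)``; ``times`` is ``(n, T)`` (hours, may
    differ per subject).  Returns an ``(n, T)`` concentration matrix, µg/mL.
    Used by the simulator and the estimation engine, where per-subject Python
    loops would dominate the run time.
    """
    cl_f, vc_f, ka, k23, k32, f1_rel = (
        np.asarray(a, dtype=float) for a in (cl_f, vc_f, ka, k23, k32, f1_rel)
    )
    times = np.asarray(times, dtype=float)
    n, T = times.shape
    k10 = cl_f / vc_f
    s = k10 + k23 + k32
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k32, 0.0))
    alpha = 0.5 * (s + disc)   # (n,)
    beta = 0.5 * (s - disc)
    keep = regimen.amounts > 0
    tds = regimen.times[keep]
    amts = regimen.amounts[keep]
    feds = regimen.food[keep]
    conc = np.zeros_like(times)
    if not len(tds):
        return conc
    # doses are processed in chunks vectorized over (dose, subject, time);
    # chunking bounds the temporaries for long once-daily regimens
    chunk = max(1, int(2_000_000 // max(n * T, 1)))
    for c0 in range(0, len(tds), chunk):
        td = tds[c0:c0 + chunk][:, None]                    # (D, 1)
        amt = amts[c0:c0 + chunk][:, None]
        fed = feds[c0:c0 + chunk][:, None]
        k = ka[None, :] * np.where(fed, food_ka_multiplier, 1.0)   # (D, n)
        # keep the three exponents separated so partial fractions stay finite
        k = np.where(np.abs(k - alpha) < 1e-7 * np.maximum(k, alpha), k * (1 + 1e-6), k)
        k = np.where(np.abs(k - beta) < 1e-7 * np.maximum(k, beta), k * (1 + 1e-6), k)
        ca = (k32 - alpha) / ((k - alpha) * (beta - alpha))        # (D, n)
        cb = (k32 - beta) / ((k - beta) * (alpha - beta))
        ck = (k32 - k) / ((alpha - k) * (beta - k))
        dt = times[None, :, :] - td[:, :, None]                    # (D, n, T)
        pos = dt >= 0
        dtp = np.where(pos, dt, 0.0)
        term = (
            ca[:, :, None] * np.exp(-alpha[None, :, None] * dtp)
            + cb[:, :, None] * np.exp(-beta[None, :, None] * dtp)
            + ck[:, :, None] * np.exp(-k[:, :, None] * dtp)
        )
        dosed = np.where(pos, (amt * (k * f1_rel[None, :] / vc_f[None, :]))[:, :, None] * term, 0.0)
        conc += dosed.sum(axis=0)
    return np.maximum(conc, 0.0)


# ---------------------------------------------------------------------------
# Model specification I/O

def _model_from_dict(spec: Mapping) -> PopulationPKModel:
    thetas = PKParams(**spec["thetas"])
    effects = [CovariateEffect(**e) for e in spec.get("covariate_effects", [])]
    omega2 = {}
    for k, cv in spec.get("omega_cv", {}).items():
        omega2[k] = cv_to_omega2(cv)
    for k, v in spec.get("omega2", {}).items():
        omega2[k] = v
    sig = spec.get("sigma", {})
    return PopulationPKModel(
        thetas=thetas,
        covariate_effects=effects,
        omega2=omega2,
        sigma_serial=sig.get("serial", 0.3),
        sigma_sparse=sig.get("sparse", 0.5),
    )


def load_pk_model(path) -> PopulationPKModel:
    """Load a population PK model from its YAML specification."""
    with open(path) as fh:
        return _model_from_dict(yaml.safe_load(fh))


def final_pk_model() -> PopulationPKModel:
    """The final published population PK model (shipped as package data)."""
    ref = importlib.resources.files("pkpdkit.models") / "final_pk.yaml"
    return _model_from_dict(yaml.safe_load(ref.read_text()))
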