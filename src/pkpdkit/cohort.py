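"""Synthetic virtual cohorts with the statistical structure the analysis assumes.

The generator emulates the pooled-trial population: covariate marginals match
the published demographic summary (weight 85.1 ± 17.3 kg, eGFR 91.4 ± 24.5
mL/min, 59.3% male, ...), phase-1 serial and phase-3 sparse PK sampling
designs, log-normal interindividual variability, log-additive PK residual
error, additive + proportional LDL-C residual error, LLOQ censoring, placebo
arms with zero exposure, and imperfect dosing compliance.  Only marginals are
published, so the joint covariate structure is a minimal documented choice:
the weight mean shifts with sex (-10 kg for women) and eGFR declines linearly
with age.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .covariates import effect_covariates
from .events import COVARIATE_COLUMNS, RECORD_COLUMNS, EventTable
from .pd_model import PopulationPDModel, apply_covariates_pd
from .pk_model import (
    PopulationPKModel,
    Regimen,
    apply_covariates_pk,
    conc_matrix,
    qd_regimen,
)

__all__ = ["CohortSpec", "SimulatedTruth", "sample_covariates",
           "simulate_pk_dataset", "simulate_pkpd_dataset"]

#: Serial (phase-1-like) sampling times, hours after the first dose.
SERIAL_TIMES = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0])

#: Nominal sparse (phase-3-like) PK visit days; samples fall within the dosing
#: interval of the visit day at randomized clock times.
SPARSE_VISIT_DAYS = (14, 28, 56, 84)

#: LDL-C visit days for the phase-3-like design: baseline, then first
#: post-baseline sample on day 29 near steady state.
LDL_VISIT_DAYS = (0, 29, 57, 85)

#: Early LDL-C visit days for the phase-1/2-like subset that informs turnover.
LDL_EARLY_DAYS = (0, 4, 8, 15, 22, 29, 57, 85)


@dataclasses.dataclass
class CohortSpec:
    """Trial-design and covariate-distribution controls for one virtual cohort."""

    n_subjects: int = 100
    treated_fraction: float = 1.0     # remainder are placebo
    dose_mg: float = 180.0
    design: str = "serial"            # "serial" | "sparse" PK sampling
    duration_days: int = 84
    lloq: float = 0.01                # µg/mL, lower bound of the assay range
    fed: bool = False
    # covariate marginals (pooled-analysis defaults)
    male_fraction: float = 0.593
    age_mean: float = 60.5
    age_sd: float = 12.3
    age_range: tuple = (18.0, 89.0)
    weight_mean: float = 85.1
    weight_sd: float = 16.6           # within-sex SD; marginal ~17.3 with the sex shift
    weight_sex_shift: float = -10.0   # kg, added to the female mean
    weight_range: tuple = (42.5, 160.0)
    egfr_mean: float = 91.4
    egfr_sd: float = 22.4             # residual SD around the age trend
    egfr_age_slope: float = -0.8      # mL/min per year of age
    egfr_range: tuple = (16.9, 286.0)
    race_probs: tuple = (0.890, 0.092, 0.010, 0.008)   # white, black, asian, other
    hispanic_fraction: float = 0.092
    healthy_fraction: float = 0.082
    t2dm_fraction: float = 0.161
    hefh_fraction: float = 0.05
    statin_intensity_probs: tuple = (0.35, 0.15, 0.30, 0.20)  # none, low, moderate, high
    ezetimibe_fraction: float = 0.15
    prior_statin_fraction: float = 0.50
    prior_ezetimibe_fraction: float = 0.08
    noncompliant_fraction: float = 0.05   # draw compliance uniform(0.5, 1) for these
    pk_missing_fraction: float = 0.33     # treated subjects without PK observations
    ldl_early_fraction: float = 0.2       # subjects on the early-visit LDL schedule
    id_prefix: str = "S"                  # subject-ID prefix (keeps pooled cohorts unique)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for p in (self.race_probs, self.statin_intensity_probs):
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("categorical probabilities must sum to 1")


@dataclasses.dataclass
class SimulatedTruth:
    """Ground truth behind one simulated dataset (for recovery tests)."""

    etas: pd.DataFrame        # per-subject realized random effects
    params: pd.DataFrame      # per-subject individual structural parameters
    pred: pd.DataFrame        # noise-free predictions at the observation records


def _truncnorm(rng, mean, sd, lo, hi, n):
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
                              sd, size=bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def sample_covariates(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one covariate row per subject; marginals match the spec targets."""
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_subjects
    if n == 0:
        return pd.DataFrame(columns=COVARIATE_COLUMNS)
    ids = [f"{spec.id_prefix}{i + 1:04d}" for i in range(n)]
    female = rng.random(n) >= spec.male_fraction
    age = _truncnorm(rng, spec.age_mean, spec.age_sd, *spec.age_range, n=n)
    # male-group mean chosen so the sex-shifted mixture keeps the target marginal
    wmean = spec.weight_mean - spec.weight_sex_shift * (1.0 - spec.male_fraction)
    weight = _truncnorm(
        rng, wmean + spec.weight_sex_shift * female, spec.weight_sd, *spec.weight_range, n=n
    )
    egfr_mu = spec.egfr_mean + spec.egfr_age_slope * (age - spec.age_mean)
    egfr = _truncnorm(rng, egfr_mu, spec.egfr_sd, *spec.egfr_range, n=n)
    race = rng.choice(["white", "black", "asian", "other"], p=spec.race_probs, size=n)
    intensity = rng.choice(["none", "low", "moderate", "high"],
                           p=spec.statin_intensity_probs, size=n)
    on_statin = intensity != "none"
    which = rng.choice(["atorvastatin", "simvastatin", "rosuvastatin", "pravastatin"],
                       p=[0.45, 0.25, 0.20, 0.10], size=n)
    healthy = rng.random(n) < spec.healthy_fraction
    t2dm = (rng.random(n) < spec.t2dm_fraction) & ~healthy
    compliance = np.ones(n)
    noncomp = rng.random(n) < spec.noncompliant_fraction
    compliance[noncomp] = rng.uniform(0.5, 1.0, size=noncomp.sum())
    arm = np.where(np.arange(n) < round(spec.treated_fraction * n), "treated", "placebo")

    cov = pd.DataFrame(
        {
            "sex": np.where(female, "female", "male"),
            "age": np.round(age, 1),
            "weight": np.round(weight, 1),
            "race": race,
            "ethnicity": np.where(rng.random(n) < spec.hispanic_fraction, "hispanic", "not"),
            "egfr": np.round(egfr, 1),
            "albumin": np.round(_truncnorm(rng, 4.3, 0.3, 3.0, 5.5, n), 2),
            "bilirubin": np.round(np.exp(rng.normal(np.log(0.5), 0.35, n)), 2),
            "ast": np.round(np.exp(rng.normal(np.log(22.0), 0.3, n)), 1),
            "healthy": healthy.astype(int),
            "hyperlipidemia": (~healthy).astype(int),
            "t2dm": t2dm.astype(int),
            "hefh": (rng.random(n) < spec.hefh_fraction).astype(int),
            "atorvastatin": (on_statin & (which == "atorvastatin")).astype(int),
            "pravastatin": (on_statin & (which == "pravastatin")).astype(int),
            "rosuvastatin": (on_statin & (which == "rosuvastatin")).astype(int),
            "simvastatin": (on_statin & (which == "simvastatin")).astype(int),
            "metformin": (t2dm & (rng.random(n) < 0.7)).astype(int),
            "ezetimibe": (rng.random(n) < spec.ezetimibe_fraction).astype(int),
            "statin_intensity": intensity,
            "prior_statin": ((on_statin) | (rng.random(n) < 0.1)).astype(int),
            "prior_ezetimibe": (rng.random(n) < spec.prior_ezetimibe_fraction).astype(int),
            "compliance": np.round(compliance, 3),
            "arm": arm,
        },
        index=pd.Index(ids, name="ID"),
    )
    return cov


def _individual_pk(model, cov_frame, rng):
    """Typical parameters per subject, realized etas, individual parameters."""
    names = ["cl_f", "vc_f", "ka", "k23", "k32", "f1_rel"]
    tv = {}
    for sid, row in cov_frame.iterrows():
        p = apply_covariates_pk(model, effect_covariates(row))
        tv[sid] = [getattr(p, k) for k in names]
    tv = pd.DataFrame.from_dict(tv, orient="index", columns=names).reindex(cov_frame.index)
    etas = pd.DataFrame(0.0, index=cov_frame.index, columns=list(model.omega2))
    for k, w2 in model.omega2.items():
        if w2 > 0:
            etas[k] = rng.normal(0.0, np.sqrt(w2), size=len(cov_frame))
    ind = tv.copy()
    for k in etas.columns:
        ind[k] = ind[k] * np.exp(etas[k])
    return tv, etas, ind


def simulate_pk_dataset(
    spec: CohortSpec,
    model: PopulationPKModel,
    seed: int | None = None,
) -> tuple[EventTable, SimulatedTruth]:
    """Simulate dose and PK observation records for one cohort.

    Individual parameters are typical x exp(eta); observations are
    exp(log(ipred) + eps) with the residual SD chosen by the sampling design;
    values below the LLOQ are flagged BLQ.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cov = sample_covariates(spec, rng)
    n = len(cov)
    regimen = qd_regimen(spec.dose_mg, spec.duration_days, food=spec.fed)
    food_mult = model.food_ka_multiplier()
    sigma = model.sigma_serial if spec.design == "serial" else model.sigma_sparse

    tv, etas, ind = _individual_pk(model, cov, rng)

    if spec.design == "serial":
        times = np.broadcast_to(SERIAL_TIMES, (n, len(SERIAL_TIMES))).copy()
    else:
        cols = [
            (day - 1) * 24.0 + rng.uniform(1.0, 24.0, size=n)
            for day in SPARSE_VISIT_DAYS
            if day <= spec.duration_days
        ]
        if not cols:  # very short designs: one visit at the end of dosing
            cols = [(spec.duration_days - 1) * 24.0 + rng.uniform(1.0, 24.0, size=n)]
        times = np.sort(np.column_stack(cols), axis=1)

    treated = (cov["arm"] == "treated").to_numpy()
    conc = conc_matrix(
        ind["cl_f"], ind["vc_f"], ind["ka"], ind["k23"], ind["k32"], ind["f1_rel"],
        regimen, times, food_mult,
    )
    conc = conc * treated[:, None]
    eps = rng.normal(0.0, sigma, size=conc.shape)
    dv = np.where(conc > 0, np.exp(np.log(np.maximum(conc, 1e-30)) + eps), 0.0)

    rows = []
    pred_rows = []
    for i, sid in enumerate(cov.index):
        for td, amt, fed in zip(regimen.times, regimen.amounts, regimen.food):
            rows.append([sid, td, amt if treated[i] else 0.0, np.nan, 1, 1, 1, 0, int(fed), 1])
        for j, t in enumerate(times[i]):
            blq = int(dv[i, j] < spec.lloq)
            rows.append([sid, t, np.nan, dv[i, j], 1, 0, 0, blq, int(spec.fed), 1])
            pred_rows.append([sid, t, conc[i, j], dv[i, j]])
    rec = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    rec = rec.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
    rec["dv_kind"] = "pk"
    table = EventTable(rec, cov, spec.lloq)
    truth = SimulatedTruth(
        etas=etas,
        params=ind,
        pred=pd.DataFrame(pred_rows, columns=["ID", "TIME", "IPRED", "DV"]),
    )
    return table, truth


def simulate_pkpd_dataset(
    spec: CohortSpec,
    pk_model: PopulationPKModel,
    pd_model: PopulationPDModel,
    seed: int | None = None,
) -> tuple[EventTable, SimulatedTruth]:
    """Simulate a joint PK + LDL-C dataset for one cohort.

    LDL-C observations are scheduled at trial visits (baseline, then day 29
    onward; an early-visit subset informs turnover) with additive +
    proportional error.  The placebo arm has zero exposure.  A configurable
    fraction of treated subjects carries no PK observations.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pk_spec = dataclasses.replace(spec, seed=None)
    table, truth = simulate_pk_dataset(pk_spec, pk_model, seed=int(rng.integers(2**31 - 1)))
    cov = table.covariates
    n = len(cov)
    treated = (cov["arm"] == "treated").to_numpy()

    # strip PK observations from a fraction of treated subjects, and from the
    # placebo arm (no drug to measure)
    no_pk = ((rng.random(n) < spec.pk_missing_fraction) & treated) | ~treated
    no_pk_ids = set(cov.index[no_pk])
    rec = table.records
    drop = rec["ID"].isin(no_pk_ids) & (rec["EVID"] == 0)
    rec = rec[~drop].reset_index(drop=True)

    regimen = qd_regimen(spec.dose_mg, spec.duration_days, food=spec.fed)
    ind_pk = truth.params

    # PD individual parameters
    names = ["imax", "ic50", "baseline_ldl", "turn"]
    tv = {}
    for sid, row in cov.iterrows():
        p = apply_covariates_pd(pd_model, effect_covariates(row))
        tv[sid] = [getattr(p, k) for k in names]
    tv = pd.DataFrame.from_dict(tv, orient="index", columns=names).reindex(cov.index)
    pd_etas = pd.DataFrame(0.0, index=cov.index, columns=list(pd_model.omega2))
    for k, w2 in pd_model.omega2.items():
        if w2 > 0:
            pd_etas[k] = rng.normal(0.0, np.sqrt(w2), size=n)
    ind_pd = tv.copy()
    for k in pd_etas.columns:
        ind_pd[k] = ind_pd[k] * np.exp(pd_etas[k])
    ind_pd["imax"] = ind_pd["imax"].clip(upper=1.0)

    early = rng.random(n) < spec.ldl_early_fraction
    rows = []
    pred_rows = []
    grid = np.arange(0.0, spec.duration_days * 24.0 + 25.0, 2.0)
    kout = 1.0 / ind_pd["turn"].to_numpy()
    # closed-form LDL solution on a shared grid (linear time-varying ODE)
    conc_grid = conc_matrix(
        ind_pk["cl_f"], ind_pk["vc_f"], ind_pk["ka"], ind_pk["k23"], ind_pk["k32"],
        ind_pk["f1_rel"], regimen, np.broadcast_to(grid, (n, len(grid))).copy(),
        pk_model.food_ka_multiplier(),
    ) * treated[:, None]
    w = conc_grid / (ind_pd["ic50"].to_numpy()[:, None] + conc_grid)
    ekt = np.exp(kout[:, None] * grid[None, :])
    u = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(0.5 * np.diff(grid) * (w * ekt)[:, :-1] + 0.5 * np.diff(grid) * (w * ekt)[:, 1:], axis=1)],
        axis=1,
    )
    ldl_grid = ind_pd["baseline_ldl"].to_numpy()[:, None] * (
        1.0 - ind_pd["imax"].to_numpy()[:, None] * kout[:, None] * u / ekt
    )

    for i, sid in enumerate(cov.index):
        days = LDL_EARLY_DAYS if early[i] else LDL_VISIT_DAYS
        for d in days:
            if d > spec.duration_days + 1:
                continue
            t = d * 24.0
            f = float(np.interp(t, grid, ldl_grid[i]))
            dv = f * (1.0 + rng.normal(0.0, pd_model.sigma_prop)) + rng.normal(0.0, pd_model.sigma_add)
            rows.append([sid, t, np.nan, max(dv, 1.0), 2, 0, 0, 0, 0, 1])
            pred_rows.append([sid, t, f, max(dv, 1.0)])

    ldl_rec = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    rec = pd.concat([rec.drop(columns=["dv_kind"]), ldl_rec], ignore_index=True)
    rec["dv_kind"] = rec["DVID"].map({1: "pk", 2: "ldl"})
    rec = rec.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)

    cov = cov.copy()
    cov["baseline_ldl"] = np.round(ind_pd["baseline_ldl"], 1)

    etas = truth.etas.add_prefix("pk_").join(pd_etas.add_prefix("pd_"))
    params = ind_pk.join(ind_pd, rsuffix="_pd")
    pred = pd.DataFrame(pred_rows, columns=["ID", "TIME", "IPRED", "DV"])
    table = EventTable(rec, cov, spec.lloq)
    return table, SimulatedTruth(etas=etas, params=params, pred=pred)
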