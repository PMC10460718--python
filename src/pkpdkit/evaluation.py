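"""Visual predictive checks, residual diagnostics and model-health checks.

The VPC simulates replicate datasets conditioned on the observed design
(dosing, sampling times, covariates), bins observations by time, and compares
observed 5th/50th/95th percentiles with the simulation bands of the same
percentiles.  Percentiles use linear (type-7) interpolation throughout.  The
prediction-corrected variant scales observations and simulations by the ratio
of the bin-median population prediction to each record's own population
prediction before computing percentiles.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .estimate import ModelFit, PKProblem
from .events import EventTable
from .pk_model import PopulationPKModel

__all__ = ["VPCSummary", "vpc_pk", "health_checks", "residual_diagnostics"]

PCTS = (5.0, 50.0, 95.0)


@dataclasses.dataclass
class VPCSummary:
    """Binned observed percentiles and simulated percentile bands."""

    table: pd.DataFrame
    n_replicates: int
    prediction_corrected: bool

    def coverage(self, pct: float = 50.0) -> float:
        """Fraction of bins whose observed percentile lies inside the
        simulated 90% band of that percentile."""
        t = self.table
        lo, hi = t[f"sim_p{pct:g}_lo"], t[f"sim_p{pct:g}_hi"]
        obs = t[f"obs_p{pct:g}"]
        return float(((obs >= lo) & (obs <= hi)).mean())


def _vpc_core(times, y, pred, sims, bins, prediction_corrected):
    times = np.asarray(times, float)
    y = np.asarray(y, float)
    sims = np.asarray(sims, float)       # (n_rep, n_obs)
    if isinstance(bins, int):
        edges = np.unique(np.quantile(times, np.linspace(0, 1, bins + 1)))
    else:
        edges = np.asarray(bins, float)
    idx = np.clip(np.digitize(times, edges[1:-1]), 0, len(edges) - 2)

    if prediction_corrected:
        pred = np.asarray(pred, float)
        scale = np.ones_like(y)
        for b in range(len(edges) - 1):
            sel = idx == b
            if sel.any():
                med = np.median(pred[sel])
                scale[sel] = med / np.where(pred[sel] > 0, pred[sel], np.nan)
        y = y * scale
        sims = sims * scale[None, :]

    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            warnings.warn(f"empty VPC bin {b} dropped")
            continue
        row = {
            "bin": b,
            "t_lo": edges[b],
            "t_hi": edges[b + 1],
            "t_mid": float(np.median(times[sel])),
            "n": int(sel.sum()),
        }
        for p in PCTS:
            row[f"obs_p{p:g}"] = float(np.percentile(y[sel], p))
            sp = np.percentile(sims[:, sel], p, axis=1)
            row[f"sim_p{p:g}_lo"] = float(np.percentile(sp, 5))
            row[f"sim_p{p:g}_med"] = float(np.percentile(sp, 50))
            row[f"sim_p{p:g}_hi"] = float(np.percentile(sp, 95))
        rows.append(row)
    return pd.DataFrame(rows)


def vpc_pk(
    model: PopulationPKModel,
    table: EventTable,
    n_replicates: int = 200,
    bins: int | np.ndarray = 10,
    prediction_corrected: bool = False,
    seed: int | None = None,
    design: str = "serial",
) -> VPCSummary:
    """Visual predictive check of a population PK model against an event table.

    ``model`` may be the fitted model or any model to evaluate; replicates are
    simulated on the observed design (each subject's own dosing and sampling
    times and covariates) with fresh interindividual and residual variability.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    problem = PKProblem(model, table, estimate_effects=False)
    theta = {p.name: p.init for p in problem.params}
    mask = problem.mask
    q = problem.n_eta
    w2 = problem.omega_diag(theta) if q else np.empty(0)
    sigma = model.sigma_serial if design == "serial" else model.sigma_sparse

    logpred = problem.predict(theta, np.zeros((problem.n_subjects, q)))
    times = problem.times[mask]
    y = np.exp(problem.y[mask])
    pred = np.exp(logpred[mask])

    sims = np.empty((n_replicates, mask.sum()))
    for r in range(n_replicates):
        eta = rng.normal(0.0, np.sqrt(w2), size=(problem.n_subjects, q)) if q else np.zeros((problem.n_subjects, 0))
        f = problem.predict(theta, eta)
        eps = rng.normal(0.0, sigma, size=f.shape)
        sims[r] = np.exp(f + eps)[mask]

    tab = _vpc_core(times, y, pred, sims, bins, prediction_corrected)
    return VPCSummary(tab, n_replicates, prediction_corrected)


def health_checks(
    fit_or_corr,
    corr_threshold: float = 0.95,
    condition_threshold: float = 1000.0,
) -> dict:
    """Numerical health report of a fit's estimation covariance.

    Flags any off-diagonal correlation of estimates exceeding the threshold in
    magnitude and a correlation-matrix condition number (largest/smallest
    eigenvalue) above the cutoff, both signs of an ill-conditioned model.
    """
    if isinstance(fit_or_corr, ModelFit):
        corr = fit_or_corr.corr
    else:
        corr = pd.DataFrame(np.asarray(fit_or_corr, float))
    if corr is None:
        return {"available": False}
    R = corr.to_numpy()
    ev = np.linalg.eigvalsh(R)
    cond = float(ev[-1] / ev[0]) if ev[0] > 0 else float("inf")
    pairs = []
    names = list(corr.index)
    for i in range(len(names)):
        for j in range(i):
            if abs(R[i, j]) > corr_threshold:
                pairs.append((names[i], names[j], float(R[i, j])))
    return {
        "available": True,
        "condition_number": cond,
        "condition_flag": cond > condition_threshold,
        "extreme_correlations": pairs,
        "correlation_flag": bool(pairs),
        "corr_threshold": corr_threshold,
        "condition_threshold": condition_threshold,
    }


def residual_diagnostics(fit: ModelFit) -> dict[str, pd.DataFrame]:
    """Weighted residual tables and random-effect summaries for a fit.

    Returns population (PWRES) and individual (IWRES) weighted residuals
    against prediction and time, plus per-parameter eta summaries with
    empirical-Bayes shrinkage 1 - SD(EBE)/omega.  Plotting layers sit on top
    of these tables.
    """
    problem = fit.problem
    theta = {p.name: fit.estimates[p.name] for p in problem.params}
    eta_hat = fit.ebes.to_numpy()
    f_ind = problem.predict(theta, eta_hat)
    f_pop = problem.predict(theta, np.zeros_like(eta_hat))
    ri, vi = problem.residual(theta, f_ind)
    rp, vp = problem.residual(theta, f_pop)
    mask = problem.mask
    res = pd.DataFrame(
        {
            "ID": np.repeat(problem.subject_ids, mask.sum(axis=1)),
            "TIME": problem.times[mask],
            "IWRES": (ri / np.sqrt(vi))[mask],
            "PWRES": (rp / np.sqrt(vp))[mask],
            "PRED": f_pop[mask],
            "IPRED": f_ind[mask],
        }
    )
    etas = []
    for k, name in enumerate(problem.eta_names):
        w = np.sqrt(problem.omega_diag(theta)[k])
        sd = float(np.std(eta_hat[:, k], ddof=1)) if len(eta_hat) > 1 else 0.0
        etas.append({
            "eta": name, "mean": float(np.mean(eta_hat[:, k])), "sd": sd,
            "omega": w, "shrinkage": 1.0 - sd / w if w > 0 else float("nan"),
        })
    return {"residuals": res, "etas": pd.DataFrame(etas)}
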