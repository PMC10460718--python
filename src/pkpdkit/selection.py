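"""Covariate-model construction and selection procedures.

Three procedures are provided, all operating on an abstract refitter so they
apply equally to the Laplace NLME engine and to analytically tractable test
models:

* stepwise backward elimination — remove the covariate whose removal increases
  the OFV least, while that increase stays below the chi-square(1) threshold
  (10.828 at alpha = 0.001);
* forward selection — add the covariate with the largest OFV decrease at or
  above the threshold (used for concomitant-medication effects);
* the Wald Approximation Method (WAM) — rank all 2^k covariate sub-models by
  approximating the OFV of each restricted model with the Wald statistic of
  the excluded coefficients from the full model's covariance, score by
  Schwarz's Bayesian Criterion, and refit only the top-ranked few exactly.

A refitter is any callable ``refit(included: tuple[int, ...]) -> (ofv, fit)``
where ``included`` indexes the candidate covariate effects kept in the model;
``fit`` may be any object (or None).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "WAMResult",
    "ofv_threshold",
    "backward_eliminate",
    "forward_select",
    "wam_rank",
    "reduce_full_model",
]


def ofv_threshold(alpha: float = 0.001, df: int = 1) -> float:
    """Chi-square OFV threshold for nested model comparison (10.828 at defaults)."""
    return float(stats.chi2.ppf(1 - alpha, df))


@dataclasses.dataclass
class SelectionStep:
    candidate: int | None
    delta_ofv: float
    decision: str        # "removed" | "added" | "stopped" | "skipped"
    threshold: float
    tested: dict[int, float] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class SelectionTrace:
    """Replayable record of a stepwise selection run."""

    steps: list[SelectionStep]
    included: tuple[int, ...]
    ofv: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": i, "candidate": s.candidate, "delta_ofv": s.delta_ofv,
                 "decision": s.decision, "threshold": s.threshold}
                for i, s in enumerate(self.steps)
            ]
        )


Refitter = Callable[[tuple], tuple]


def backward_eliminate(
    refit: Refitter,
    candidates: Sequence[int],
    threshold: float | None = None,
) -> tuple[tuple, SelectionTrace]:
    """Stepwise backward elimination from the model containing all candidates.

    At each step every remaining candidate is removed in turn; the one whose
    removal raises the OFV least is eliminated if that rise is below the
    threshold.  Ties break on the smallest candidate index.  A refit failure
    for one candidate skips that candidate for the step and is recorded.
    Returns the retained candidate indices and the trace.
    """
    threshold = ofv_threshold() if threshold is None else threshold
    included = tuple(sorted(candidates))
    ofv_cur, _ = refit(included)
    steps: list[SelectionStep] = []
    while included:
        tested = {}
        for c in included:
            reduced = tuple(i for i in included if i != c)
            try:
                ofv_red, _ = refit(reduced)
            except Exception:
                steps.append(SelectionStep(c, float("nan"), "skipped", threshold))
                continue
            tested[c] = ofv_red - ofv_cur
        if not tested:
            break
        best = min(tested, key=lambda c: (tested[c], c))
        if tested[best] < threshold:
            included = tuple(i for i in included if i != best)
            ofv_cur = ofv_cur + tested[best]
            steps.append(SelectionStep(best, tested[best], "removed", threshold, tested))
        else:
            steps.append(SelectionStep(None, tested[best], "stopped", threshold, tested))
            break
    ofv_final, _ = refit(included)
    return included, SelectionTrace(steps, included, ofv_final)


def forward_select(
    refit: Refitter,
    candidates: Sequence[int],
    threshold: float | None = None,
    start: Sequence[int] = (),
) -> tuple[tuple, SelectionTrace]:
    """Stepwise forward selection starting from ``start`` (default: none).

    At each step the candidate producing the largest OFV decrease of at least
    the threshold enters; selection stops when no candidate qualifies.  With
    threshold 0 every candidate eventually enters (any non-increase counts).
    """
    threshold = ofv_threshold() if threshold is None else threshold
    included = tuple(sorted(start))
    remaining = [c for c in candidates if c not in included]
    ofv_cur, _ = refit(included)
    steps: list[SelectionStep] = []
    while remaining:
        tested = {}
        for c in remaining:
            try:
                ofv_new, _ = refit(tuple(sorted(included + (c,))))
            except Exception:
                steps.append(SelectionStep(c, float("nan"), "skipped", threshold))
                continue
            tested[c] = ofv_cur - ofv_new  # decrease in OFV
        if not tested:
            break
        best = max(tested, key=lambda c: (tested[c], -c))
        if tested[best] >= threshold:
            included = tuple(sorted(included + (best,)))
            remaining = [c for c in remaining if c != best]
            ofv_cur = ofv_cur - tested[best]
            steps.append(SelectionStep(best, -tested[best], "added", threshold, tested))
        else:
            steps.append(SelectionStep(None, -tested[best], "stopped", threshold, tested))
            break
    ofv_final, _ = refit(included)
    return included, SelectionTrace(steps, included, ofv_final)


@dataclasses.dataclass
class WAMResult:
    """Ranking of all covariate sub-models by the Wald approximation."""

    table: pd.DataFrame       # mask, wald, approx_ofv, n_params, sbc, rank
    refits: pd.DataFrame      # top-m exact refits with actual SBC
    n_obs: int


def wam_rank(
    ofv_full: float,
    theta: np.ndarray,
    cov: np.ndarray,
    n_obs: int,
    m: int = 15,
    refit: Refitter | None = None,
) -> WAMResult:
    """Wald Approximation Method over all 2^k covariate sub-models.

    For each sub-model the OFV increase from fixing the excluded coefficient
    subset ``e`` to zero is approximated by the Wald statistic
    ``theta_e' inv(Sigma_ee) theta_e`` using the partitioned covariance of the
    full fit.  Sub-models are scored with Schwarz's Bayesian Criterion,

        SBC = -1/2 (OFV_full + W) - 1/2 p ln(n_obs),

    with p the number of retained covariate coefficients, and ranked by
    descending SBC.  The top ``m`` models are refit exactly when a refitter is
    supplied.  Singular covariance partitions are flagged unrankable.
    """
    theta = np.asarray(theta, dtype=float)
    cov = np.asarray(cov, dtype=float)
    k = len(theta)
    rows = []
    for mask_bits in itertools.product([1, 0], repeat=k):
        keep = np.array(mask_bits, dtype=bool)
        excl = ~keep
        if excl.any():
            sub = cov[np.ix_(excl, excl)]
            try:
                wald = float(theta[excl] @ np.linalg.solve(sub, theta[excl]))
                if wald < 0:
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                rows.append({"mask": mask_bits, "wald": np.nan, "approx_ofv": np.nan,
                             "n_params": int(keep.sum()), "sbc": -np.inf,
                             "rankable": False})
                continue
        else:
            wald = 0.0
        p = int(keep.sum())
        sbc = -0.5 * (ofv_full + wald) - 0.5 * p * np.log(n_obs)
        rows.append({"mask": mask_bits, "wald": wald, "approx_ofv": ofv_full + wald,
                     "n_params": p, "sbc": sbc, "rankable": True})
    table = pd.DataFrame(rows)
    order = table["sbc"].rank(ascending=False, method="first")
    table["rank"] = order.astype(int)
    table = table.sort_values("rank").reset_index(drop=True)

    refit_rows = []
    if refit is not None:
        for _, row in table.head(m).iterrows():
            included = tuple(i for i, b in enumerate(row["mask"]) if b)
            ofv, _ = refit(included)
            sbc = -0.5 * ofv - 0.5 * row["n_params"] * np.log(n_obs)
            refit_rows.append({"mask": row["mask"], "ofv": ofv, "sbc_actual": sbc,
                               "sbc_approx": row["sbc"], "rank_approx": row["rank"]})
    refits = pd.DataFrame(refit_rows)
    if len(refits):
        refits["rank_actual"] = refits["sbc_actual"].rank(ascending=False, method="first").astype(int)
    return WAMResult(table=table, refits=refits, n_obs=n_obs)


def reduce_full_model(
    estimates: Sequence[float],
    ses: Sequence[float],
    min_effect: float = 0.1,
    min_ratio: float = 2.0,
) -> np.ndarray:
    """Retention mask for the working full model.

    Covariate coefficients with ``|estimate| < min_effect`` (negligible
    effect) or ``|estimate| / SE <= min_ratio`` (imprecise) are dropped.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(est) / se
    return (np.abs(est) >= min_effect) & (ratio > min_ratio)
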