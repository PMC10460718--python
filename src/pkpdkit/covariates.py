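"""Translate subject covariate rows into the indicator/continuous mapping the
covariate-effect specifications reference (e.g. ``sex == "female"`` becomes the
0/1 indicator ``female``)."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

__all__ = ["effect_covariates", "effect_covariate_frame"]


def effect_covariates(row: Mapping, food: float = 0.0) -> dict[str, float]:
    """Indicator/continuous covariate mapping for one subject.

    ``row`` is a row of an :class:`~pkpdkit.events.EventTable` covariate frame
    (or any mapping with the canonical column names).  ``food`` sets the fed
    indicator, which is a record-level state rather than a subject attribute.
    """
    g = lambda k, d=0: row.get(k, d) if hasattr(row, "get") else getattr(row, k, d)
    intensity = str(g("statin_intensity", "none"))
    out = {
        "female": 1.0 if str(g("sex", "male")) == "female" else 0.0,
        "black": 1.0 if str(g("race", "white")) == "black" else 0.0,
        "asian": 1.0 if str(g("race", "white")) == "asian" else 0.0,
        "hispanic": 1.0 if str(g("ethnicity", "not")) == "hispanic" else 0.0,
        "statin_low": 1.0 if intensity == "low" else 0.0,
        "statin_moderate": 1.0 if intensity == "moderate" else 0.0,
        "statin_high": 1.0 if intensity == "high" else 0.0,
        "food": float(food),
    }
    for name in (
        "age", "weight", "egfr", "albumin", "bilirubin", "ast", "baseline_ldl",
        "healthy", "hyperlipidemia", "t2dm", "hefh",
        "atorvastatin", "pravastatin", "rosuvastatin", "simvastatin",
        "metformin", "ezetimibe", "prior_statin", "prior_ezetimibe",
    ):
        v = g(name, None)
        if v is not None and not pd.isna(v):
            out[name] = float(v)
    return out


def effect_covariate_frame(covariates: pd.DataFrame, food: float = 0.0) -> pd.DataFrame:
    """Apply :func:`effect_covariates` to every subject; index is preserved."""
    rows = {sid: effect_covariates(row, food=food) for sid, row in covariates.iterrows()}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(covariates.index)
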