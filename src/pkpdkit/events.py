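"""Longitudinal dose/observation event tables and record-level exclusion filters.

The whole pipeline consumes one tabular format: one row per dose or observation
event, NONMEM-style columns (ID, TIME, AMT, DV, DVID, EVID, MDV, FOOD, OCC),
plus one column per subject-level covariate.  Times are decimal hours since each
subject's first administered dose; rate constants elsewhere in the package are
per hour to match.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EventTable",
    "ExclusionReport",
    "ParseError",
    "ConsistencyError",
    "read_event_table",
    "write_event_table",
    "apply_exclusions",
    "load_config",
    "COVARIATE_COLUMNS",
]


class ParseError(ValueError):
    """A malformed row in an event-table CSV."""


class ConsistencyError(ValueError):
    """An event table violating its own contract (e.g. observation without covariates)."""


#: Canonical subject-level covariate columns.  Categorical covariates are stored
#: as lowercase strings, indicator covariates as 0/1 integers.
COVARIATE_COLUMNS = [
    "sex",              # male | female
    "age",              # years
    "weight",           # kg
    "race",             # white | black | asian | other
    "ethnicity",        # hispanic | not
    "egfr",             # mL/min
    "albumin",          # g/dL
    "bilirubin",        # mg/dL
    "ast",              # U/L
    "healthy",          # 0/1
    "hyperlipidemia",   # 0/1
    "t2dm",             # 0/1
    "hefh",             # 0/1
    "atorvastatin",     # 0/1 concomitant
    "pravastatin",
    "rosuvastatin",
    "simvastatin",
    "metformin",
    "ezetimibe",
    "statin_intensity",  # none | low | moderate | high
    "prior_statin",     # 0/1
    "prior_ezetimibe",  # 0/1
    "baseline_ldl",     # mg/dL
    "compliance",       # fraction of planned doses taken
    "arm",              # treated | placebo
]

RECORD_COLUMNS = ["ID", "TIME", "AMT", "DV", "DVID", "EVID", "MDV", "BLQ", "FOOD", "OCC"]

_DVID_TO_KIND = {1: "pk", 2: "ldl"}
_KIND_TO_DVID = {v: k for k, v in _DVID_TO_KIND.items()}


@dataclasses.dataclass
class EventTable:
    """Dose and observation records plus one covariate row per subject.

    Attributes
    ----------
    records : pandas.DataFrame
        Columns ``RECORD_COLUMNS``; EVID 1 marks doses, EVID 0 observations;
        DVID is ``"pk"`` (µg/mL) or ``"ldl"`` (mg/dL); within a subject rows
        are sorted by time.
    covariates : pandas.DataFrame
        Indexed by subject ID, one row per subject.
    lloq : float
        Lower limit of quantification for PK observations, µg/mL.
    """

    records: pd.DataFrame
    covariates: pd.DataFrame
    lloq: float = 0.01

    @property
    def n_subjects(self) -> int:
        return self.records["ID"].nunique()

    @property
    def observations(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 1]

    def subject(self, subject_id) -> pd.DataFrame:
        return self.records[self.records["ID"] == subject_id]

    def validate(self) -> None:
        """Raise ConsistencyError on any contract violation."""
        rec = self.records
        if len(rec) == 0:
            return
        if (rec["TIME"] < 0).any():
            bad = rec.index[rec["TIME"] < 0][0]
            raise ConsistencyError(f"negative TIME at record {bad}")
        doses = rec["EVID"] == 1
        if (rec.loc[doses, "AMT"].fillna(0) < 0).any():
            raise ConsistencyError("negative dose amount")
        obs = rec[~doses & (rec["MDV"] == 0)]
        if obs["DV"].isna().any():
            bad = obs.index[obs["DV"].isna()][0]
            raise ConsistencyError(f"observation with MDV=0 but missing DV at record {bad}")
        for sid, grp in rec.groupby("ID", sort=False):
            if not grp["TIME"].is_monotonic_increasing:
                raise ConsistencyError(f"records of subject {sid!r} not sorted by time")
        obs_ids = set(rec.loc[~doses, "ID"].unique())
        missing = obs_ids - set(self.covariates.index)
        if missing:
            raise ConsistencyError(
                f"observation subjects without covariate rows: {sorted(map(str, missing))}"
            )

    def copy(self) -> "EventTable":
        return EventTable(self.records.copy(), self.covariates.copy(), self.lloq)


@dataclasses.dataclass
class ExclusionReport:
    """Counts from one pass of the record-level exclusion filters."""

    n_input_records: int
    n_input_observations: int
    n_postdose_pk: int
    n_blq_excluded: int
    n_predose_pk_excluded: int
    n_noncompliant_records: int
    n_noncompliant_subjects: int
    n_retained_records: int

    @property
    def blq_fraction_of_postdose(self) -> float:
        """BLQ exclusions as a fraction of post-dose PK samples."""
        return self.n_blq_excluded / self.n_postdose_pk if self.n_postdose_pk else 0.0

    @property
    def blq_fraction_of_all(self) -> float:
        """BLQ exclusions as a fraction of all observations."""
        return self.n_blq_excluded / self.n_input_observations if self.n_input_observations else 0.0

    @property
    def n_excluded(self) -> int:
        return self.n_blq_excluded + self.n_predose_pk_excluded + self.n_noncompliant_records


def _coerce_records(df: pd.DataFrame, path: str) -> pd.DataFrame:
    df = df.mask(df == ".")  # "." encodes missing numeric fields
    for col in ["TIME", "AMT", "DV"]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {col}: {exc}") from exc
    for col in ["DVID", "EVID", "MDV", "FOOD", "OCC"]:
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    return df


def read_event_table(path, lloq: float = 0.01) -> EventTable:
    """Read an event-table CSV; set BLQ flags on PK observations below ``lloq``.

    Missing numeric fields are encoded as ``"."``.  An empty file yields an
    empty table.  Raises :class:`ParseError` naming the offending line on a
    malformed row and :class:`ConsistencyError` if an observation subject has
    no covariate information.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return EventTable(
            pd.DataFrame(columns=RECORD_COLUMNS + ["dv_kind"]),
            pd.DataFrame(columns=COVARIATE_COLUMNS),
            lloq,
        )
    header = text.splitlines()[0].split(",")
    ncol = len(header)
    for lineno, line in enumerate(text.splitlines()[1:], start=2):
        if line.strip() and len(line.split(",")) != ncol:
            raise ParseError(f"{path} line {lineno}: expected {ncol} fields, got {len(line.split(','))}")
    df = pd.read_csv(io.StringIO(text), dtype={"ID": str})
    required = [c for c in RECORD_COLUMNS if c != "BLQ"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    df = _coerce_records(df, str(path))

    pk_obs = (df["EVID"] == 0) & (df["DVID"] == _KIND_TO_DVID["pk"]) & (df["MDV"] == 0)
    df["BLQ"] = (pk_obs & (df["DV"] < lloq)).astype(int)
    df["dv_kind"] = df["DVID"].map(_DVID_TO_KIND)

    cov_cols = [c for c in df.columns if c.lower() in COVARIATE_COLUMNS]
    cov = df.groupby("ID", sort=False)[cov_cols].first()
    cov.columns = [c.lower() for c in cov.columns]
    for col in ["age", "weight", "egfr", "albumin", "bilirubin", "ast",
                "baseline_ldl", "compliance"]:
        if col in cov.columns:
            cov[col] = pd.to_numeric(cov[col], errors="coerce")

    rec = df[RECORD_COLUMNS + ["dv_kind"]].copy()
    rec = rec.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
    table = EventTable(rec, cov, lloq)
    table.validate()
    return table


def write_event_table(table: EventTable, path) -> None:
    """Write the CSV form read by :func:`read_event_table` (round-trip safe)."""
    rec = table.records.copy()
    cov = table.covariates
    merged = rec.drop(columns=["dv_kind"]).merge(
        cov.rename(columns=str.upper), left_on="ID", right_index=True, how="left"
    )
    merged.to_csv(path, index=False, na_rep=".")


def apply_exclusions(table: EventTable, min_compliance: float = 0.8) -> tuple[EventTable, ExclusionReport]:
    """Apply the dataset exclusion filters and report counts per category.

    Removes, in this order of attribution:

    1. every record of any subject whose recorded dosing compliance is below
       ``min_compliance`` (subjects excluded wholesale);
    2. PK observations collected before the subject's first dose (pre-first-dose
       LDL-C observations are retained: they define baseline);
    3. post-dose PK observations below the limit of quantification.

    Idempotent, and conservation holds: retained + per-category counts equal the
    input record count.
    """
    if not (0 < min_compliance <= 1):
        raise ValueError("min_compliance must be in (0, 1]")
    rec = table.records
    n_in = len(rec)
    obs = rec["EVID"] == 0

    compliance = table.covariates.get("compliance")
    if compliance is not None:
        bad_subjects = set(compliance.index[compliance.fillna(1.0) < min_compliance])
    else:
        bad_subjects = set()
    noncomp = rec["ID"].isin(bad_subjects)

    first_dose = rec[rec["EVID"] == 1].groupby("ID")["TIME"].min()
    fdose = rec["ID"].map(first_dose)
    is_pk = obs & (rec["dv_kind"] == "pk")
    predose_pk = is_pk & (fdose.isna() | (rec["TIME"] < fdose)) & ~noncomp
    postdose_pk = is_pk & ~predose_pk & ~noncomp
    blq = postdose_pk & (rec["BLQ"] == 1)

    drop = noncomp | predose_pk | blq
    kept = rec[~drop].reset_index(drop=True)
    report = ExclusionReport(
        n_input_records=n_in,
        n_input_observations=int(obs.sum()),
        n_postdose_pk=int(postdose_pk.sum()),
        n_blq_excluded=int(blq.sum()),
        n_predose_pk_excluded=int(predose_pk.sum()),
        n_noncompliant_records=int(noncomp.sum()),
        n_noncompliant_subjects=len(bad_subjects & set(rec["ID"].unique())),
        n_retained_records=len(kept),
    )
    cov = table.covariates[~table.covariates.index.isin(bad_subjects)]
    return EventTable(kept, cov.copy(), table.lloq), report


def concat_tables(tables) -> EventTable:
    """Pool several event tables (subject IDs must be unique across inputs)."""
    tables = list(tables)
    rec = pd.concat([t.records for t in tables], ignore_index=True)
    cov = pd.concat([t.covariates for t in tables])
    if cov.index.duplicated().any():
        raise ConsistencyError("duplicate subject IDs across pooled tables")
    return EventTable(rec, cov, tables[0].lloq)


def load_config(path) -> Mapping:
    """Load the sidecar YAML config (lloq, compliance threshold, column mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("lloq", 0.01)
    cfg.setdefault("min_compliance", 0.8)
    return cfg
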