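"""Cohort construction: eligibility, index date, mean age, condition selection.

Turns raw diagnosis records into the analyzable cohort and condition universe:

* eligibility — every calendar year between a patient's first and last
  appearance must contain >=3 outpatient visits or >=1 hospitalisation;
* index date — earliest T2DM-coded visit; diagnoses before it do not count;
* age — mean of the (fractional) ages at the index date and at the last visit,
  stratified into six bands (<40, 40-49, ..., >=80);
* condition selection — ICD-10 chapters 1-14, cohort prevalence >= 1%,
  acute/chronic granularity rule, index code excluded.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .synthetic import AGE_BANDS

logger = logging.getLogger("multimorbnet")

DAYS_PER_YEAR = 365.25

VISIT_TYPES = ("outpatient", "inpatient")

DEFAULT_SCHEMA = {
    "events": ["patient_id", "visit_date", "visit_type", "icd10_code"],
    "patients": ["patient_id", "sex", "birth_date"],
    "catalog": ["code", "chapter", "chronic_flag", "is_t2dm_index"],
}


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


class MissingCodeError(KeyError):
    """Diagnosis code seen in events but absent from the condition catalog."""


class ConditionCatalog:
    """The analyzable condition universe with chapter and chronic/acute flags.

    Wraps a DataFrame with columns ``code`` (unique), ``chapter`` (1-22),
    ``chronic_flag`` (bool), ``is_t2dm_index`` (bool).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in DEFAULT_SCHEMA["catalog"] if c not in df.columns]
        if missing:
            raise SchemaError(f"catalog missing required columns: {missing}")
        df = df.copy()
        df["chronic_flag"] = df["chronic_flag"].astype(bool)
        df["is_t2dm_index"] = df["is_t2dm_index"].astype(bool)
        df["chapter"] = df["chapter"].astype(int)
        if df["code"].duplicated().any():
            dupes = df.loc[df["code"].duplicated(), "code"].tolist()
            raise SchemaError(f"catalog codes must be unique; duplicated: {dupes}")
        if not df["chapter"].between(1, 22).all():
            raise SchemaError("catalog chapters must lie in 1..22")
        self.df = df.sort_values("code", ignore_index=True)

    @property
    def t2dm_codes(self) -> frozenset[str]:
        return frozenset(self.df.loc[self.df["is_t2dm_index"], "code"])

    @property
    def chronic_codes(self) -> frozenset[str]:
        return frozenset(self.df.loc[self.df["chronic_flag"], "code"])

    def granularity(self) -> pd.Series:
        """'three_char' or 'four_plus_char' per code (presence of a subcode)."""
        return self.df["code"].map(
            lambda c: "four_plus_char" if len(c.replace(".", "")) > 3 else "three_char"
        )

    def analyzable_codes(self) -> frozenset[str]:
        """Codes eligible for the comorbidity universe.

        Chapters 1-14 only, index codes excluded, and the granularity rule: a
        three-character code is dropped when the catalog also carries four-plus
        character subcodes of it with *both* chronic and acute flags (in that
        case the subdivided codes stand in for it separately).
        """
        df = self.df
        keep = df["chapter"].between(1, 14) & ~df["is_t2dm_index"]
        stems = df["code"].str.replace(".", "", regex=False).str[:3]
        is_sub = df["code"].map(lambda c: len(c.replace(".", "")) > 3)
        sub = df[is_sub & keep]
        sub_stems = stems[sub.index]
        mixed = {
            stem
            for stem, grp in sub.groupby(sub_stems)
            if grp["chronic_flag"].nunique() == 2
        }
        three_char_dropped = ~is_sub & stems.isin(mixed)
        return frozenset(df.loc[keep & ~three_char_dropped, "code"])


def load_records(
    events_path,
    patients_path,
    catalog_path,
    schema_config: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ConditionCatalog]:
    """Read the three input CSVs, validate schema, parse and type columns.

    Malformed dates are dropped row-wise with a logged count; an unknown
    visit_type raises :class:`SchemaError` listing the allowed values.
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_config:
        schema.update(schema_config)

    events = pd.read_csv(events_path, dtype=str)
    patients = pd.read_csv(patients_path, dtype=str)
    catalog_df = pd.read_csv(catalog_path)

    for name, df, path in (("events", events, events_path), ("patients", patients, patients_path)):
        missing = [c for c in schema[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} file {path} missing required columns: {missing}")

    if len(events):
        bad_types = sorted(set(events["visit_type"]) - set(VISIT_TYPES))
        if bad_types:
            raise SchemaError(
                f"unknown visit_type values {bad_types}; allowed values: {list(VISIT_TYPES)}"
            )
    else:
        logger.warning("events file %s is empty", events_path)

    events = events.copy()
    events["visit_date"] = pd.to_datetime(events["visit_date"], errors="coerce")
    n_bad = int(events["visit_date"].isna().sum())
    if n_bad:
        logger.warning("dropped %d event rows with unparseable visit_date", n_bad)
        events = events.dropna(subset=["visit_date"])
    patients = patients.copy()
    patients["birth_date"] = pd.to_datetime(patients["birth_date"], errors="coerce")

    return events.reset_index(drop=True), patients.reset_index(drop=True), ConditionCatalog(catalog_df)


def apply_eligibility(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    exempt_partial_years: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain patients meeting the annual visit quota with clean demographics.

    A patient is eligible when every calendar year from their first to last
    appearance (inclusive) has >=3 outpatient visits or >=1 inpatient visit.
    With ``exempt_partial_years`` the first and last (partial) years are
    excused from the quota. Patients with conflicting sex records or missing
    sex/birth date are excluded.

    Returns ``(eligible_patients, exclusions)`` where exclusions has columns
    ``patient_id`` and ``reason`` in {conflicting_sex, missing_age_or_sex,
    insufficient_visits, no_visits}.
    """
    exclusions: list[pd.DataFrame] = []

    sex_counts = patients.groupby("patient_id")["sex"].nunique()
    conflicting = set(sex_counts[sex_counts > 1].index)
    missing = set(
        patients.loc[
            patients["sex"].isna()
            | patients["birth_date"].isna()
            | ~patients["sex"].isin(["male", "female"]),
            "patient_id",
        ]
    ) - conflicting

    dedup = patients.drop_duplicates("patient_id", keep="first")
    no_visits = set(dedup["patient_id"]) - set(events["patient_id"])

    year = events["visit_date"].dt.year
    per_year = (
        events.assign(year=year)
        .pivot_table(
            index=["patient_id", "year"],
            columns="visit_type",
            values="visit_date",
            aggfunc="count",
            fill_value=0,
        )
        .reset_index()
    )
    for col in VISIT_TYPES:
        if col not in per_year.columns:
            per_year[col] = 0
    per_year["qualifies"] = (per_year["outpatient"] >= 3) | (per_year["inpatient"] >= 1)

    grp = per_year.groupby("patient_id")
    first = grp["year"].min()
    last = grp["year"].max()
    span = last - first + 1
    if exempt_partial_years:
        interior = per_year[
            (per_year["year"] > per_year["patient_id"].map(first))
            & (per_year["year"] < per_year["patient_id"].map(last))
        ]
        ok_years = interior.groupby("patient_id")["qualifies"].sum()
        needed = (span - 2).clip(lower=0)
        qualifies = ok_years.reindex(span.index, fill_value=0) >= needed
    else:
        ok_years = grp["qualifies"].sum()
        qualifies = ok_years == span
    insufficient = set(qualifies[~qualifies].index)

    reasons = [
        (conflicting, "conflicting_sex"),
        (missing, "missing_age_or_sex"),
        (no_visits, "no_visits"),
        (insufficient, "insufficient_visits"),
    ]
    excluded: set[str] = set()
    for ids, reason in reasons:
        ids = ids - excluded
        excluded |= ids
        if ids:
            exclusions.append(pd.DataFrame({"patient_id": sorted(ids), "reason": reason}))
            logger.info("excluded %d patients: %s", len(ids), reason)

    eligible = dedup[~dedup["patient_id"].isin(excluded)].reset_index(drop=True)
    exclusions_df = (
        pd.concat(exclusions, ignore_index=True)
        if exclusions
        else pd.DataFrame(columns=["patient_id", "reason"])
    )
    return eligible, exclusions_df


def _age_at(dates: pd.Series, birth: pd.Series) -> pd.Series:
    return (dates - birth).dt.days / DAYS_PER_YEAR


def age_stratum(mean_age: float) -> str:
    """Map a mean age in years to one of the six study bands."""
    if mean_age < 40:
        return AGE_BANDS[0]
    if mean_age < 50:
        return AGE_BANDS[1]
    if mean_age < 60:
        return AGE_BANDS[2]
    if mean_age < 70:
        return AGE_BANDS[3]
    if mean_age < 80:
        return AGE_BANDS[4]
    return AGE_BANDS[5]


def _is_t2dm_event(codes: pd.Series, t2dm_code_set: Iterable[str]) -> pd.Series:
    t2dm = set(t2dm_code_set)
    stems = codes.str.split(".").str[0]
    return codes.isin(t2dm) | stems.isin(t2dm)


def compute_index_and_age(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    t2dm_code_set: Iterable[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign index date (earliest T2DM code), mean age, and age stratum.

    Mean age is the average of the patient's age at the index date and at the
    last visit date. Patients with no T2DM-coded event are excluded with
    reason ``no_t2dm_code``. Returns ``(cohort, exclusions)``.
    """
    is_t2dm = _is_t2dm_event(events["icd10_code"], t2dm_code_set)
    index_date = events[is_t2dm].groupby("patient_id")["visit_date"].min()
    last_visit = events.groupby("patient_id")["visit_date"].max()

    cohort = patients.merge(
        index_date.rename("index_date"), left_on="patient_id", right_index=True, how="left"
    ).merge(last_visit.rename("last_visit_date"), left_on="patient_id", right_index=True, how="left")

    no_t2dm = cohort["index_date"].isna()
    exclusions = pd.DataFrame(
        {"patient_id": cohort.loc[no_t2dm, "patient_id"], "reason": "no_t2dm_code"}
    ).reset_index(drop=True)
    if no_t2dm.any():
        logger.info("excluded %d patients: no_t2dm_code", int(no_t2dm.sum()))
    cohort = cohort[~no_t2dm].copy()

    age_index = _age_at(cohort["index_date"], cohort["birth_date"])
    age_last = _age_at(cohort["last_visit_date"], cohort["birth_date"])
    cohort["mean_age"] = (age_index + age_last) / 2.0
    cohort["age_stratum"] = cohort["mean_age"].map(age_stratum)
    cols = ["patient_id", "sex", "birth_date", "index_date", "last_visit_date", "mean_age", "age_stratum"]
    return cohort[cols].reset_index(drop=True), exclusions


@dataclasses.dataclass
class ConditionSelection:
    """Result of condition selection on a cohort."""

    universe: list[str]  # retained analyzable codes
    condition_sets: pd.DataFrame  # long format: patient_id, code (distinct)
    prevalence: pd.Series  # per retained code, fraction of cohort
    pair_eligible: frozenset[str]  # patients meeting the multimorbidity rule
    n_cohort: int
    dropped_unknown: list[str]
    dropped_low_prevalence: list[str]

    def sets_by_patient(self) -> dict[str, frozenset[str]]:
        mapping = {
            pid: frozenset(grp) for pid, grp in self.condition_sets.groupby("patient_id")["code"]
        }
        return mapping


def select_conditions(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    catalog: ConditionCatalog,
    min_prevalence: float = 0.01,
    on_missing: str = "warn",
    require_chronic_anchor: bool = True,
) -> ConditionSelection:
    """Build the analyzable condition universe and per-patient condition sets.

    Only diagnoses on/after each patient's index date count. Codes must be in
    the catalog's analyzable set (chapters 1-14, granularity rule, index code
    excluded) and reach ``min_prevalence`` in the pooled cohort. Patients
    satisfy the multimorbidity rule when they carry at least one chronic
    retained condition plus at least one other retained condition; only those
    patients contribute co-occurrence pairs downstream (their flag is exposed
    as ``pair_eligible``), though all patients contribute marginal counts.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be a fraction in (0, 1]")
    ev = events.merge(cohort[["patient_id", "index_date"]], on="patient_id", how="inner")
    ev = ev[ev["visit_date"] >= ev["index_date"]]

    analyzable = catalog.analyzable_codes()
    known = frozenset(catalog.df["code"])
    seen = set(ev["icd10_code"].unique())
    unknown = sorted(seen - known)
    if unknown:
        if on_missing == "error":
            raise MissingCodeError(f"codes in events but not in catalog: {unknown}")
        logger.warning("dropping %d codes absent from catalog: %s", len(unknown), unknown[:10])

    ev = ev[ev["icd10_code"].isin(analyzable)]
    pairs = ev[["patient_id", "icd10_code"]].drop_duplicates()
    n_cohort = int(cohort["patient_id"].nunique())
    counts = pairs["icd10_code"].value_counts()
    prevalence = counts / n_cohort
    retained = prevalence[prevalence >= min_prevalence]
    dropped_low = sorted(set(counts.index) - set(retained.index))
    if dropped_low:
        logger.info("dropped %d codes below %.1f%% prevalence", len(dropped_low), 100 * min_prevalence)

    sets_df = (
        pairs[pairs["icd10_code"].isin(retained.index)]
        .rename(columns={"icd10_code": "code"})
        .sort_values(["patient_id", "code"], ignore_index=True)
    )

    chronic = catalog.chronic_codes
    sizes = sets_df.groupby("patient_id")["code"].agg(
        n="size", n_chronic=lambda s: s.isin(chronic).sum()
    )
    if require_chronic_anchor:
        ok = sizes[(sizes["n"] >= 2) & (sizes["n_chronic"] >= 1)]
    else:
        ok = sizes[sizes["n"] >= 2]

    return ConditionSelection(
        universe=sorted(retained.index),
        condition_sets=sets_df,
        prevalence=prevalence.loc[sorted(retained.index)],
        pair_eligible=frozenset(ok.index),
        n_cohort=n_cohort,
        dropped_unknown=unknown,
        dropped_low_prevalence=dropped_low,
    )
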