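"""Person-level cohort table: ingest, validation, merge, profiles.

One row per person: a unique id, age in whole years at the index date, one
0/1 flag per catalogue disease, and two follow-up utilisation counts
(outpatient interactions; unplanned inpatient admissions).  Persons with no
flagged disease stay in the cohort — they contribute to the population size
``P`` and to prevalence denominators — but never produce a hyperedge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import DiseaseCatalogue, DiseaseSet

__all__ = [
    "ID_COL", "AGE_COL", "OUTCOME_COLS",
    "CohortValidationError", "Cohort", "CohortSummary",
    "read_cohort", "write_cohort", "merge_disease_pairs",
    "exact_profile", "empirical_summary",
]

ID_COL = "person_id"
AGE_COL = "age_years"
OUTCOME_COLS = ("outpatient_count", "inpatient_unplanned_count")


class CohortValidationError(ValueError):
    """Structural problem in a cohort table, naming the offending cell."""


class Cohort:
    """Validated cohort, stored as dense arrays for speed.

    Parameters
    ----------
    flags : (n, d) array of 0/1, column order = ``catalogue.names``
    ages : (n,) integer ages in years
    outpatient, inpatient : (n,) non-negative integer counts
    catalogue : DiseaseCatalogue
    person_id : optional (n,) ids; dropped by resampling operations
    """

    def __init__(self, flags, ages, outpatient, inpatient, catalogue: DiseaseCatalogue,
                 person_id=None):
        self.flags = np.ascontiguousarray(np.asarray(flags, dtype=np.int8))
        self.ages = np.asarray(ages, dtype=np.int64)
        self.outpatient = np.asarray(outpatient, dtype=np.int64)
        self.inpatient = np.asarray(inpatient, dtype=np.int64)
        self.catalogue = catalogue
        self.person_id = None if person_id is None else np.asarray(person_id)
        n = self.flags.shape[0]
        if self.flags.ndim != 2 or self.flags.shape[1] != len(catalogue):
            raise CohortValidationError(
                f"flags must be (n, {len(catalogue)}), got {self.flags.shape}"
            )
        for name, arr in (("ages", self.ages), ("outpatient", self.outpatient),
                          ("inpatient", self.inpatient)):
            if arr.shape != (n,):
                raise CohortValidationError(f"{name} must have length {n}")

    # -- construction / serialisation ------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, catalogue: DiseaseCatalogue) -> "Cohort":
        """Validate a raw table; errors name the offending row/column."""
        required = [ID_COL, AGE_COL, *catalogue.names, *OUTCOME_COLS]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing columns: {missing}")
        dup = pd.Index(df[ID_COL]).duplicated()
        if dup.any():
            row = int(np.flatnonzero(dup)[0])
            raise CohortValidationError(
                f"duplicate person_id {df[ID_COL].iloc[row]!r} at row {row}"
            )
        for col in catalogue.names:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = ~vals.isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"non-binary flag {df[col].iloc[row]!r} in column {col!r}, row {row}"
                )
        for col in (AGE_COL, *OUTCOME_COLS):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"invalid value {df[col].iloc[row]!r} in column {col!r}, row {row}"
                    " (expected a non-negative integer)"
                )
        return cls(
            df[list(catalogue.names)].to_numpy(dtype=np.int8),
            df[AGE_COL].to_numpy(dtype=np.int64),
            df[OUTCOME_COLS[0]].to_numpy(dtype=np.int64),
            df[OUTCOME_COLS[1]].to_numpy(dtype=np.int64),
            catalogue,
            person_id=df[ID_COL].to_numpy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        pid = self.person_id if self.person_id is not None else np.arange(self.n)
        data = {ID_COL: pid, AGE_COL: self.ages}
        for j, name in enumerate(self.catalogue.names):
            data[name] = self.flags[:, j]
        data[OUTCOME_COLS[0]] = self.outpatient
        data[OUTCOME_COLS[1]] = self.inpatient
        return pd.DataFrame(data)

    # -- basic properties --------------------------------------------------

    @property
    def n(self) -> int:
        return self.flags.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.flags.shape[1]

    def outcome(self, column: str) -> np.ndarray:
        if column == OUTCOME_COLS[0]:
            return self.outpatient
        if column == OUTCOME_COLS[1]:
            return self.inpatient
        raise KeyError(f"unknown outcome column {column!r}; expected one of {OUTCOME_COLS}")

    def carriers(self) -> np.ndarray:
        """Per-disease carrier counts |X_i|."""
        return self.flags.sum(axis=0, dtype=np.int64)

    def take(self, idx) -> "Cohort":
        """Row subset / resample (person ids dropped: resamples repeat rows)."""
        idx = np.asarray(idx)
        return Cohort(self.flags[idx], self.ages[idx], self.outpatient[idx],
                      self.inpatient[idx], self.catalogue)


def read_cohort(path, catalogue: DiseaseCatalogue) -> Cohort:
    """Read and validate a headered cohort CSV."""
    return Cohort.from_dataframe(pd.read_csv(path), catalogue)


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_dataframe().to_csv(path, index=False)


def merge_disease_pairs(cohort: Cohort, catalogue: DiseaseCatalogue | None = None) -> Cohort:
    """Collapse each merge-map pair into one OR'd flag.

    Outcome counts, ages and ids are untouched; a person's disease count
    drops by at most one per merged pair (when both sources were set).
    """
    cat = catalogue or cohort.catalogue
    if not cat.merge_map:
        return cohort
    for a, b, _ in cat.merge_map:
        if a not in cat.names or b not in cat.names:
            raise CohortValidationError(f"merge source {a!r}/{b!r} absent from catalogue")
    merged_cat = cat.merged()
    cols = {name: cohort.flags[:, j] for j, name in enumerate(cat.names)}
    for a, b, merged in cat.merge_map:
        cols[merged] = cols.pop(a) | cols.pop(b)
    flags = np.column_stack([cols[name] for name in merged_cat.names]).astype(np.int8)
    return Cohort(flags, cohort.ages, cohort.outpatient, cohort.inpatient,
                  merged_cat, person_id=cohort.person_id)


def exact_profile(flags_row, catalogue: DiseaseCatalogue) -> DiseaseSet | None:
    """The set of diseases flagged in a row (and no others); None if disease-free."""
    row = np.asarray(flags_row)
    members = tuple(catalogue.names[j] for j in np.flatnonzero(row))
    return DiseaseSet(members) if members else None


@dataclass
class CohortSummary:
    prevalence: pd.Series
    count_histograms: dict[str, pd.DataFrame]
    mean_count_by_n_diseases: pd.DataFrame


def empirical_summary(cohort: Cohort) -> CohortSummary:
    """Per-disease prevalence, gapless count histograms, mean counts by set size."""
    if cohort.n == 0:
        raise CohortValidationError("empirical_summary of an empty cohort")
    prevalence = pd.Series(cohort.flags.mean(axis=0), index=list(cohort.catalogue.names),
                           name="prevalence")
    hists = {}
    for col in OUTCOME_COLS:
        counts = cohort.outcome(col)
        freq = np.bincount(counts, minlength=int(counts.max()) + 1)
        hists[col] = pd.DataFrame({"count": np.arange(freq.size), "frequency": freq})
    ndis = cohort.flags.sum(axis=1)
    by = pd.DataFrame({
        "n_diseases": ndis,
        OUTCOME_COLS[0]: cohort.outpatient,
        OUTCOME_COLS[1]: cohort.inpatient,
    }).groupby("n_diseases").agg(
        n_persons=(OUTCOME_COLS[0], "size"),
        mean_outpatient=(OUTCOME_COLS[0], "mean"),
        mean_inpatient=(OUTCOME_COLS[1], "mean"),
    ).reset_index()
    return CohortSummary(prevalence, hists, by)
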