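"""Cohort construction: washout filtering, age restriction and stratification.

The screening analysis adjusts for age and calendar time by stratifying the
cohort into (sex, 10-year age band, 2-year period) cells — with the default
eight 10-year bands covering ages 0–79 and six 2-year windows tiling
2003–2014, that is 48 strata per sex.  Each patient belongs to exactly one
stratum, keyed by their first observed stay, and carries their full
2003–2014 diagnosis set; the per-stratum 2×2 tables downstream are
therefore built over disjoint patient sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .claims_io import ClaimsDataset

__all__ = ["StratumKey", "StratifiedCohort", "DEFAULT_BANDS_10Y", "DEFAULT_PERIODS",
           "washout_filter", "restrict_age", "assign_strata"]

DEFAULT_BANDS_10Y = tuple(range(0, 80, 10))
#: Six half-open 2-year calendar windows tiling 2003–2014.
DEFAULT_PERIODS = tuple((y, y + 1) for y in range(2003, 2014, 2))


class StratumKey(NamedTuple):
    sex: str
    age_band_10y: int
    period_start: int


@dataclass
class StratifiedCohort:
    """Patients partitioned into strata, with their lifetime diagnosis sets.

    ``patients``: DataFrame indexed by patient_id with columns sex,
    age_band_10y, period_start.  ``diagnoses_long``: DataFrame with columns
    patient_id, code (distinct pairs).
    """

    patients: pd.DataFrame
    diagnoses_long: pd.DataFrame
    bands: tuple[int, ...] = DEFAULT_BANDS_10Y
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def assignment(self) -> dict[str, StratumKey]:
        return {
            pid: StratumKey(row.sex, int(row.age_band_10y), int(row.period_start))
            for pid, row in self.patients.iterrows()
        }

    @property
    def strata_index(self) -> dict[StratumKey, set[str]]:
        out: dict[StratumKey, set[str]] = {}
        grouped = self.patients.groupby(["sex", "age_band_10y", "period_start"], sort=True)
        for (sex, b, p), sub in grouped:
            out[StratumKey(sex, int(b), int(p))] = set(sub.index)
        return out

    def diagnoses(self, patient_id: str) -> set[str]:
        d = self.diagnoses_long
        return set(d.loc[d["patient_id"] == patient_id, "code"])

    def stratum_sizes(self) -> pd.Series:
        return self.patients.groupby(["sex", "age_band_10y", "period_start"]).size()


def washout_filter(dataset: ClaimsDataset) -> ClaimsDataset:
    """Drop every stay of every patient with an admission in the washout window.

    Retained patients therefore have no recorded hospital contact before the
    observation window, so their observed diagnoses are plausibly incident.
    Idempotent; counts are recorded in ``meta`` (patients_removed/retained).
    """
    st = dataset.stays
    lo, hi = dataset.washout_window
    in_wash = (st["admission_date"] >= lo) & (st["admission_date"] <= hi)
    violators = set(st.loc[in_wash, "patient_id"])
    keep = ~st["patient_id"].isin(violators)
    return dataset.replace_stays(
        st[keep],
        washout_patients_removed=len(violators),
        washout_patients_retained=int(st.loc[keep, "patient_id"].nunique()),
    )


def restrict_age(dataset: ClaimsDataset, min_age: int, max_age: int) -> ClaimsDataset:
    """Keep patients whose 5-year age band at first stay lies within [min_age, max_age].

    Bounds follow the 5-year grid of the data: ``min_age`` is a band lower
    bound (multiple of 5) and ``max_age`` an inclusive upper age one below a
    band boundary (e.g. 20–79, 20–49, 50–79).
    """
    if min_age % 5 != 0 or (max_age + 1) % 5 != 0:
        raise ValueError(
            f"age bounds must align to the 5-year grid "
            f"(min multiple of 5, max ≡ 4 mod 5); got ({min_age}, {max_age})")
    if min_age > max_age:
        raise ValueError(f"min_age {min_age} exceeds max_age {max_age}")
    pat = dataset.patients()
    ok = pat[(pat["age_band"] >= min_age) & (pat["age_band"] + 4 <= max_age)].index
    st = dataset.stays
    keep = st["patient_id"].isin(set(ok))
    return dataset.replace_stays(st[keep], age_restricted=(min_age, max_age))


def assign_strata(
    dataset: ClaimsDataset,
    bands: tuple[int, ...] = DEFAULT_BANDS_10Y,
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS,
) -> StratifiedCohort:
    """Partition patients into (sex, 10-year band, 2-year period) strata.

    A patient's stratum is keyed by their first observed stay; their
    diagnosis set spans the whole observation window.  A patient whose age
    band or first-stay year falls outside the configured bands/periods
    raises ``ValueError``.
    """
    pat = dataset.patients()
    if len(pat):
        band10 = (pat["age_band"] // 10) * 10
        bad = ~band10.isin(bands)
        if bad.any():
            raise ValueError(
                f"age band(s) outside configured 10-year bands for patients "
                f"{list(pat.index[bad][:5])}")
        year = pat["first_admission"].dt.year
        period_start = np.full(len(pat), -1, dtype=int)
        for start, end in periods:
            period_start = np.where((year >= start) & (year <= end), start, period_start)
        if (period_start < 0).any():
            bad_ids = list(pat.index[period_start < 0][:5])
            raise ValueError(f"first stay outside configured periods for patients {bad_ids}")
        patients = pd.DataFrame(
            {"sex": pat["sex"], "age_band_10y": band10.astype(int),
             "period_start": period_start},
            index=pat.index,
        )
    else:
        patients = pd.DataFrame(
            {"sex": pd.Series(dtype=str), "age_band_10y": pd.Series(dtype=int),
             "period_start": pd.Series(dtype=int)},
            index=pd.Index([], name="patient_id"),
        )
    long = dataset.diagnosis_long()
    diag = long[["patient_id", "code"]].drop_duplicates(ignore_index=True)
    return StratifiedCohort(patients=patients, diagnoses_long=diag,
                            bands=tuple(bands), periods=tuple(periods))
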