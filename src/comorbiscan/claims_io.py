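"""Data model and I/O for longitudinal inpatient claims.

A claims dataset is a table of hospital stays: one row per admission with
patient ID, sex, 5-year age band, admission/discharge dates, a primary
diagnosis and a list of secondary diagnoses.  Diagnoses are level-3 ICD-10
codes (letter + two digits) restricted to the somatic-disease universe
A00–N99 (1,080 codes); primary and secondary diagnoses are treated as
equally relevant throughout the analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CODE_PATTERN",
    "IOConfig",
    "ClaimsDataset",
    "SchemaError",
    "ValidationError",
    "RowParseError",
    "is_valid_code",
    "code_universe",
    "read_claims",
    "write_claims",
    "diagnosis_events",
]

#: Level-3 ICD-10 code within the configured universe: letter A–N, two digits.
CODE_PATTERN = re.compile(r"^[A-N][0-9]{2}$")

REQUIRED_COLUMNS = (
    "patient_id",
    "sex",
    "age_band",
    "admission_date",
    "discharge_date",
    "primary_dx",
    "secondary_dx",
)

SEXES = ("F", "M")
AGE_BANDS_5Y = tuple(range(0, 100, 5))


class SchemaError(ValueError):
    """The input file does not have the required columns."""


class ValidationError(ValueError):
    """Dataset-level invariant violated (e.g. inconsistent sex per patient)."""


class RowParseError(ValueError):
    """A row could not be parsed; carries the 1-based data line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


def is_valid_code(code: str) -> bool:
    """True iff ``code`` is a level-3 code inside the A00–N99 universe."""
    return bool(CODE_PATTERN.match(code))


def code_universe() -> list[str]:
    """All letter+two-digit patterns A00 … N99 in lexicographic order.

    This enumerates the validation pattern; the WHO code list assigns
    meanings to 1,080 of these positions, but validation is purely
    structural.
    """
    return [f"{ch}{i:02d}" for ch in "ABCDEFGHIJKLMN" for i in range(100)]


@dataclass
class IOConfig:
    """Parsing conventions for the claims CSV."""

    secondary_sep: str = ";"
    date_format: str = "%Y-%m-%d"
    #: Drop stays whose admission date falls outside washout ∪ observation.
    drop_out_of_window: bool = True


@dataclass
class ClaimsDataset:
    """Hospital stays plus the observation and washout calendar windows.

    ``stays`` columns: patient_id (str), sex ('F'/'M'), age_band (int, lower
    bound of the 5-year band), admission_date / discharge_date
    (datetime64), primary_dx (str, possibly '' if the recorded code fell
    outside the universe), secondary_dx (separator-joined str, possibly '').
    """

    stays: pd.DataFrame
    observation_window: tuple[pd.Timestamp, pd.Timestamp]
    washout_window: tuple[pd.Timestamp, pd.Timestamp]
    meta: dict = field(default_factory=dict)
    secondary_sep: str = ";"
    _long: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    @property
    def n_stays(self) -> int:
        return len(self.stays)

    @property
    def n_patients(self) -> int:
        return self.stays["patient_id"].nunique()

    def diagnosis_long(self) -> pd.DataFrame:
        """One row per (stay, diagnosis): stay_idx, patient_id, code, admission_date.

        Primary and secondary diagnoses appear identically; codes duplicated
        within one stay occur once.  Cached after the first call.
        """
        if self._long is None:
            st = self.stays
            prim = pd.DataFrame(
                {
                    "stay_idx": st.index,
                    "patient_id": st["patient_id"].to_numpy(),
                    "code": st["primary_dx"].to_numpy(),
                    "admission_date": st["admission_date"].to_numpy(),
                }
            )
            has_sec = st["secondary_dx"] != ""
            sec_src = st.loc[has_sec]
            sec = pd.DataFrame(
                {
                    "stay_idx": sec_src.index,
                    "patient_id": sec_src["patient_id"].to_numpy(),
                    "code": sec_src["secondary_dx"].str.split(self.secondary_sep).to_numpy(),
                    "admission_date": sec_src["admission_date"].to_numpy(),
                }
            ).explode("code", ignore_index=True)
            out = pd.concat([prim, sec], ignore_index=True)
            out = out[out["code"] != ""]
            out = out.drop_duplicates(["stay_idx", "code"], ignore_index=True)
            self._long = out
        return self._long

    def patients(self) -> pd.DataFrame:
        """Per-patient frame (index patient_id): sex, age_band and date of first stay."""
        st = self.stays.sort_values("admission_date", kind="stable")
        first = st.drop_duplicates("patient_id", keep="first")
        return pd.DataFrame(
            {
                "sex": first["sex"].to_numpy(),
                "age_band": first["age_band"].to_numpy(),
                "first_admission": first["admission_date"].to_numpy(),
            },
            index=pd.Index(first["patient_id"], name="patient_id"),
        )

    def replace_stays(self, stays: pd.DataFrame, **meta) -> "ClaimsDataset":
        """New dataset sharing the windows, with fresh stays and extra meta."""
        return ClaimsDataset(
            stays=stays.reset_index(drop=True),
            observation_window=self.observation_window,
            washout_window=self.washout_window,
            meta={**self.meta, **meta},
            secondary_sep=self.secondary_sep,
        )


def _clean_codes(raw: list[str]) -> tuple[list[str], int]:
    """Keep in-universe codes (deduplicated, order preserved); count drops."""
    seen: dict[str, None] = {}
    dropped = 0
    for c in raw:
        c = c.strip()
        if not c:
            continue
        if is_valid_code(c):
            seen.setdefault(c, None)
        else:
            dropped += 1
    return list(seen), dropped


def read_claims(
    path: str | Path,
    config: IOConfig | None = None,
    observation_window: tuple[str, str] = ("2003-01-01", "2014-12-31"),
    washout_window: tuple[str, str] = ("1997-01-01", "2002-12-31"),
) -> ClaimsDataset:
    """Read and validate a claims CSV.

    Codes outside the A00–N99 universe are dropped (not the whole row) and
    counted in ``meta['n_codes_dropped']``.  A patient recorded with more
    than one sex raises :class:`ValidationError` naming the offending IDs.
    """
    config = config or IOConfig()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    obs = (pd.Timestamp(observation_window[0]), pd.Timestamp(observation_window[1]))
    wash = (pd.Timestamp(washout_window[0]), pd.Timestamp(washout_window[1]))

    n = len(df)
    if n == 0:
        stays = pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "sex": pd.Series(dtype=str),
                "age_band": pd.Series(dtype=int),
                "admission_date": pd.Series(dtype="datetime64[ns]"),
                "discharge_date": pd.Series(dtype="datetime64[ns]"),
                "primary_dx": pd.Series(dtype=str),
                "secondary_dx": pd.Series(dtype=str),
            }
        )
        return ClaimsDataset(stays, obs, wash, {"n_codes_dropped": 0},
                             secondary_sep=config.secondary_sep)

    adm = pd.to_datetime(df["admission_date"], format=config.date_format, errors="coerce")
    dis = pd.to_datetime(df["discharge_date"], format=config.date_format, errors="coerce")
    for name, parsed in (("admission_date", adm), ("discharge_date", dis)):
        bad = parsed.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise RowParseError(line, f"unparseable {name} {df[name].iloc[line - 1]!r}")
    bad_order = dis < adm
    if bad_order.any():
        line = int(np.flatnonzero(bad_order.to_numpy())[0]) + 1
        raise RowParseError(line, "discharge_date precedes admission_date")

    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        line = int(np.flatnonzero(bad_sex.to_numpy())[0]) + 1
        raise RowParseError(line, f"sex must be one of {SEXES}, got {df['sex'].iloc[line - 1]!r}")

    age = pd.to_numeric(df["age_band"], errors="coerce")
    bad_age = age.isna() | ~age.isin(AGE_BANDS_5Y)
    if bad_age.any():
        line = int(np.flatnonzero(bad_age.to_numpy())[0]) + 1
        raise RowParseError(line, f"age_band must be in {{0,5,…,95}}, got {df['age_band'].iloc[line - 1]!r}")

    sexes_per_patient = df.groupby("patient_id")["sex"].nunique()
    inconsistent = sexes_per_patient[sexes_per_patient > 1].index.tolist()
    if inconsistent:
        raise ValidationError(f"inconsistent sex for patient_id(s): {', '.join(map(str, inconsistent))}")

    n_dropped = 0
    primaries: list[str] = []
    secondaries: list[str] = []
    sep = config.secondary_sep
    for prim_raw, sec_raw in zip(df["primary_dx"], df["secondary_dx"]):
        prim_clean, d1 = _clean_codes([prim_raw])
        sec_clean, d2 = _clean_codes(sec_raw.split(sep) if sec_raw else [])
        n_dropped += d1 + d2
        prim = prim_clean[0] if prim_clean else ""
        sec = [c for c in sec_clean if c != prim]
        primaries.append(prim)
        secondaries.append(sep.join(sec))

    stays = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "sex": df["sex"].to_numpy(),
            "age_band": age.astype(int).to_numpy(),
            "admission_date": adm.to_numpy(),
            "discharge_date": dis.to_numpy(),
            "primary_dx": primaries,
            "secondary_dx": secondaries,
        }
    )

    n_outside = 0
    in_window = ((stays["admission_date"] >= wash[0]) & (stays["admission_date"] <= wash[1])) | (
        (stays["admission_date"] >= obs[0]) & (stays["admission_date"] <= obs[1])
    )
    if config.drop_out_of_window and not in_window.all():
        n_outside = int((~in_window).sum())
        stays = stays[in_window].reset_index(drop=True)

    return ClaimsDataset(
        stays,
        obs,
        wash,
        {"n_codes_dropped": n_dropped, "n_stays_outside_window": n_outside},
        secondary_sep=config.secondary_sep,
    )


def write_claims(dataset: ClaimsDataset, path: str | Path) -> None:
    """Write the stays table as CSV; ``read_claims`` round-trips it up to row order."""
    out = dataset.stays.copy()
    out["admission_date"] = out["admission_date"].dt.strftime("%Y-%m-%d")
    out["discharge_date"] = out["discharge_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def diagnosis_events(dataset: ClaimsDataset, code: str) -> dict[str, pd.Timestamp]:
    """First-diagnosis date of ``code`` per patient ever carrying it.

    The event date of a diagnosis is the admission date of the earliest stay
    carrying it, whether as primary or secondary diagnosis.
    """
    long = dataset.diagnosis_long()
    hits = long[long["code"] == code]
    if hits.empty:
        return {}
    return hits.groupby("patient_id")["admission_date"].min().to_dict()
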