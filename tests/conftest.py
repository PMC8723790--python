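import pandas as pd
import pytest

from comorbiscan.claims_io import ClaimsDataset

OBS = (pd.Timestamp("2003-01-01"), pd.Timestamp("2014-12-31"))
WASH = (pd.Timestamp("1997-01-01"), pd.Timestamp("2002-12-31"))

COLUMNS = ["patient_id", "sex", "age_band", "admission_date", "discharge_date",
           "primary_dx", "secondary_dx"]


def build_dataset(rows) -> ClaimsDataset:
    """Dataset from (pid, sex, band, admission, discharge, primary, secondary) tuples."""
    df = pd.DataFrame(list(rows), columns=COLUMNS)
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    df["age_band"] = df["age_band"].astype(int)
    df["secondary_dx"] = df["secondary_dx"].fillna("")
    return ClaimsDataset(df, OBS, WASH)


@pytest.fixture
def make_dataset():
    return build_dataset


@pytest.fixture
def two_stay_dataset():
    return build_dataset([
        ("p1", "F", 45, "2005-03-01", "2005-03-04", "I21", "E11;I10"),
        ("p2", "M", 60, "2007-06-10", "2007-06-12", "J44", ""),
    ])
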