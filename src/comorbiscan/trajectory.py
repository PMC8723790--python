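"""Time-directionality of diagnosis pairs.

For two diagnoses A and B, every patient carrying both is classified by the
gap between the first diagnosis of A and the first diagnosis of B into four
lag groups — same hospital stay, under 3 months (90 days), 3 to 12 months
(90–359 days), over one year (≥ 360 days; months are treated as 30 days) —
and by direction (A first, B first, or tied).  Per group the time order
ratio TOR(A→B) = N(A→B)/N(B→A) is tested against the null N(A→B) = N(B→A)
with an exact two-sided binomial test at success probability 1/2.

Same-stay pairs carry no direction and are counted as ties; patients whose
first diagnoses fall on the same date but in different stays are counted as
ties of the under-3-months group and flagged in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .claims_io import ClaimsDataset

__all__ = ["LAG_GROUPS", "TORResult", "lag_group", "binom_two_sided",
           "tor_analysis", "tor_to_frame", "significance_stars"]

LAG_GROUPS = ("same_stay", "under_3_months", "three_to_twelve_months", "over_one_year")

_DAYS_3M = 90
_DAYS_1Y = 360


@dataclass
class TORResult:
    code_a: str
    code_b: str
    group: str
    n_ab: int               # patients first diagnosed with A, then B
    n_ba: int               # patients first diagnosed with B, then A
    n_tied: int
    tor: float              # n_ab/n_ba; inf if n_ba == 0 < n_ab; nan if no directed pairs
    p_binom: Optional[float]
    n_same_date_ties: int = 0  # same-date firsts in different stays (counted in n_tied)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_binom)


def significance_stars(p: Optional[float]) -> str:
    if p is None:
        return ""
    if p < 1e-4:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _group_of_days(days: int) -> str:
    if days < _DAYS_3M:
        return "under_3_months"
    if days < _DAYS_1Y:
        return "three_to_twelve_months"
    return "over_one_year"


def _pair_events(dataset: ClaimsDataset, code_a: str, code_b: str) -> pd.DataFrame:
    """Per both-diagnosed patient: first dates of each code and same-stay flag."""
    long = dataset.diagnosis_long()
    sub = long[long["code"].isin((code_a, code_b))]
    first = sub.pivot_table(index="patient_id", columns="code",
                            values="admission_date", aggfunc="min")
    if code_a not in first.columns or code_b not in first.columns:
        return pd.DataFrame(columns=["first_a", "first_b", "same_stay"])
    both = first.dropna(subset=[code_a, code_b])
    if both.empty:
        return pd.DataFrame(columns=["first_a", "first_b", "same_stay"])
    # stays carrying both codes
    per_stay = sub.groupby(["stay_idx", "patient_id"])["code"].nunique()
    shared = per_stay[per_stay == 2].reset_index()
    shared_dates = sub.drop_duplicates("stay_idx").set_index("stay_idx")["admission_date"]
    shared = shared.assign(date=shared_dates.loc[shared["stay_idx"]].to_numpy())
    first_shared = shared.groupby("patient_id")["date"].min()
    out = pd.DataFrame({
        "first_a": both[code_a],
        "first_b": both[code_b],
    })
    fs = first_shared.reindex(out.index)
    out["same_stay"] = (out["first_a"] == out["first_b"]) & (fs == out["first_a"])
    return out


def lag_group(dataset: ClaimsDataset, patient: str, code_a: str, code_b: str,
              ) -> tuple[str, str]:
    """Lag group and direction ('A->B', 'B->A' or 'tied') for one patient."""
    ev = _pair_events(dataset, code_a, code_b)
    if patient not in ev.index:
        raise ValueError(f"patient {patient!r} lacks a first diagnosis of "
                         f"{code_a} and/or {code_b}")
    row = ev.loc[patient]
    if bool(row["same_stay"]):
        return "same_stay", "tied"
    delta = (row["first_a"] - row["first_b"]).days
    group = _group_of_days(abs(delta))
    if delta == 0:
        return group, "tied"
    return group, ("A->B" if delta < 0 else "B->A")


def binom_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial p-value at success probability 1/2.

    Two-sidedness by the minimum-likelihood method: the p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if n == 0:
        raise ValueError("binomial test undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(binomtest(k, n, 0.5).pvalue)


def tor_analysis(dataset: ClaimsDataset, code_a: str, code_b: str,
                 ) -> list[TORResult]:
    """Time-order ratios of (code_a, code_b) per lag group, with binomial tests.

    Ties contribute to neither directional count.  Empty groups report
    ``tor = nan`` and no p-value.
    """
    ev = _pair_events(dataset, code_a, code_b)
    counts = {g: {"ab": 0, "ba": 0, "tied": 0, "same_date": 0} for g in LAG_GROUPS}
    if len(ev):
        same = ev["same_stay"].to_numpy(dtype=bool)
        delta = (ev["first_a"] - ev["first_b"]).dt.days.to_numpy()
        counts["same_stay"]["tied"] = int(same.sum())
        rest = ~same
        d = delta[rest]
        groups = np.where(np.abs(d) < _DAYS_3M, "under_3_months",
                          np.where(np.abs(d) < _DAYS_1Y,
                                   "three_to_twelve_months", "over_one_year"))
        for g in LAG_GROUPS[1:]:
            sel = groups == g
            counts[g]["ab"] = int((d[sel] < 0).sum())
            counts[g]["ba"] = int((d[sel] > 0).sum())
            ties = int((d[sel] == 0).sum())
            counts[g]["tied"] = ties
            counts[g]["same_date"] = ties
    results = []
    for g in LAG_GROUPS:
        n_ab, n_ba = counts[g]["ab"], counts[g]["ba"]
        n_dir = n_ab + n_ba
        if n_dir == 0:
            tor, p = math.nan, None
        elif n_ba == 0:
            tor, p = math.inf, binom_two_sided(n_ab, n_dir)
        else:
            tor, p = n_ab / n_ba, binom_two_sided(n_ab, n_dir)
        results.append(TORResult(
            code_a=code_a, code_b=code_b, group=g,
            n_ab=n_ab, n_ba=n_ba, n_tied=counts[g]["tied"],
            tor=tor, p_binom=p, n_same_date_ties=counts[g]["same_date"]))
    return results


def tor_to_frame(results: list[TORResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "code_a": r.code_a, "code_b": r.code_b, "group": r.group,
        "n_ab": r.n_ab, "n_ba": r.n_ba, "n_tied": r.n_tied,
        "tor": r.tor, "p_binom": r.p_binom, "stars": r.stars,
    } for r in results])
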