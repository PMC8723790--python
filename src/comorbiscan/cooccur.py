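"""Per-stratum 2×2 co-occurrence tables and Cochran–Mantel–Haenszel pooling.

For a diagnosis pair (A, B), each stratum contributes a patient-level 2×2
cross-tabulation

    a = both A and B,  b = A only,  c = B only,  d = neither,

and strata are combined with the Mantel–Haenszel weighted averages

    OR_MH = Σ_i (a_i d_i / n_i) / Σ_i (b_i c_i / n_i)
    RR_MH = Σ_i (a_i (c_i + d_i) / n_i) / Σ_i (c_i (a_i + b_i) / n_i),

with a Robins–Breslow–Greenland standard error for log OR_MH and the CMH
chi-square test (1 df, no continuity correction) of the null hypothesis
that the two diagnoses co-occur independently.  Screening applies the
inclusion rule that every cell must exceed 4 patients, the thresholds
RR > 1.5 and p < 0.01, and a minimum of 1000 patient-level occurrences of
each code in each sex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.contingency_tables import StratifiedTable

from .cohort import StratifiedCohort, StratumKey

__all__ = [
    "ContingencyTable2x2", "PooledEstimate", "ScreenConfig", "PairScreenResult",
    "UndefinedEstimateError", "NoEstimateError",
    "build_tables", "crude_or", "crude_rr", "mh_pool", "screen_pairs", "screen_to_frame",
]

Z95 = norm.ppf(0.975)


class UndefinedEstimateError(ValueError):
    """A crude estimate has a zero denominator."""


class NoEstimateError(ValueError):
    """Every contingency table was excluded; nothing to pool."""


@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    stratum: Optional[StratumKey] = None
    excluded: bool = False

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class PooledEstimate:
    or_mh: float
    rr_mh: float
    se_log_or: float
    ci95_or: tuple[float, float]
    p_cmh: float
    n_strata_used: int
    n_strata_excluded: int


@dataclass
class ScreenConfig:
    """The screening filters, at their registry-scale defaults."""

    min_cell: int = 4          # strict: every cell must exceed this
    rr_threshold: float = 1.5
    p_threshold: float = 0.01
    min_occurrences: int = 1000
    #: 'either' keeps a pair passing RR/p in at least one sex; 'both' requires both.
    sex_rule: str = "either"

    def __post_init__(self):
        if self.min_cell < 0 or self.rr_threshold <= 0 or self.p_threshold <= 0 \
                or self.min_occurrences < 0:
            raise ValueError("screen thresholds must be positive")
        if self.sex_rule not in ("either", "both"):
            raise ValueError(f"sex_rule must be 'either' or 'both', got {self.sex_rule!r}")


@dataclass
class PairScreenResult:
    code_a: str
    code_b: str
    estimate_f: Optional[PooledEstimate]
    estimate_m: Optional[PooledEstimate]
    occurrences: dict[str, dict[str, int]]  # sex -> code -> n patients
    flags: list[str] = field(default_factory=list)
    kept: bool = False


def _presence(cohort: StratifiedCohort, code: str) -> np.ndarray:
    d = cohort.diagnoses_long
    carriers = d.loc[d["code"] == code, "patient_id"]
    return cohort.patients.index.isin(set(carriers))


def _strata_labels(cohort: StratifiedCohort) -> tuple[np.ndarray, list[StratumKey]]:
    pats = cohort.patients
    mi = pd.MultiIndex.from_arrays(
        [pats["sex"], pats["age_band_10y"], pats["period_start"]])
    codes, uniques = pd.factorize(mi, sort=True)
    keys = [StratumKey(s, int(b), int(p)) for s, b, p in uniques]
    return codes, keys


def _tables_from_presence(
    gid: np.ndarray, keys: list[StratumKey],
    pres_a: np.ndarray, pres_b: np.ndarray, min_cell: int,
) -> list[ContingencyTable2x2]:
    g = len(keys)
    n_g = np.bincount(gid, minlength=g)
    a_g = np.bincount(gid[pres_a & pres_b], minlength=g)
    na_g = np.bincount(gid[pres_a], minlength=g)
    nb_g = np.bincount(gid[pres_b], minlength=g)
    tables = []
    for i, key in enumerate(keys):
        if n_g[i] == 0:
            continue
        a = int(a_g[i])
        b = int(na_g[i] - a_g[i])
        c = int(nb_g[i] - a_g[i])
        d = int(n_g[i] - a - b - c)
        tables.append(ContingencyTable2x2(
            a, b, c, d, stratum=key,
            excluded=min(a, b, c, d) <= min_cell))
    return tables


def build_tables(
    cohort: StratifiedCohort, code_a: str, code_b: str, min_cell: int = 4,
) -> list[ContingencyTable2x2]:
    """One 2×2 table per non-empty stratum for the pair (code_a, code_b).

    Tables with any cell of ``min_cell`` or fewer patients are flagged
    ``excluded`` (the inclusion rule is a strict "each subgroup > 4").
    """
    if code_a == code_b:
        raise ValueError("co-occurrence of a code with itself is undefined")
    gid, keys = _strata_labels(cohort)
    return _tables_from_presence(
        gid, keys, _presence(cohort, code_a), _presence(cohort, code_b), min_cell)


def crude_or(table: ContingencyTable2x2) -> float:
    """Single-table odds ratio a·d/(b·c)."""
    if table.b * table.c == 0:
        raise UndefinedEstimateError(f"zero denominator in table {table.cells()}")
    return (table.a * table.d) / (table.b * table.c)


def crude_rr(table: ContingencyTable2x2) -> float:
    """Single-table risk ratio [a/(a+b)] / [c/(c+d)]."""
    if (table.a + table.b) == 0 or table.c == 0 or (table.c + table.d) == 0:
        raise UndefinedEstimateError(f"undefined risk ratio in table {table.cells()}")
    return (table.a / (table.a + table.b)) / (table.c / (table.c + table.d))


def mh_pool(tables: Iterable[ContingencyTable2x2]) -> PooledEstimate:
    """Mantel–Haenszel pooled OR and RR over the non-excluded tables.

    The log-OR standard error is Robins–Breslow–Greenland; the p-value is
    the CMH chi-square test (1 df) without continuity correction.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("mh_pool requires at least one table")
    used = [t for t in tables if not t.excluded]
    if not used:
        raise NoEstimateError("all tables excluded by the cell rule")
    arrays = [np.array([[t.a, t.b], [t.c, t.d]], dtype=float) for t in used]
    st = StratifiedTable(arrays)
    or_mh = float(st.oddsratio_pooled)
    rr_mh = float(st.riskratio_pooled)
    se = float(st.logodds_pooled_se)
    log_or = np.log(or_mh)
    ci = (float(np.exp(log_or - Z95 * se)), float(np.exp(log_or + Z95 * se)))
    p = float(st.test_null_odds(correction=False).pvalue)
    return PooledEstimate(
        or_mh=or_mh, rr_mh=rr_mh, se_log_or=se, ci95_or=ci, p_cmh=p,
        n_strata_used=len(used), n_strata_excluded=len(tables) - len(used))


def _passes(est: Optional[PooledEstimate], config: ScreenConfig) -> bool:
    return (est is not None
            and est.rr_mh > config.rr_threshold
            and est.p_cmh < config.p_threshold)


def screen_pairs(
    cohort: StratifiedCohort,
    universe: list[str],
    config: ScreenConfig | None = None,
) -> list[PairScreenResult]:
    """Screen every unordered pair of ``universe`` for sex-specific comorbidity.

    For each pair, per-sex MH-pooled estimates are computed over that sex's
    strata; a pair is kept when each code has at least ``min_occurrences``
    patient-level occurrences in each sex and the RR/p thresholds pass under
    the configured sex rule.  Every pair is returned with audit flags.
    """
    config = config or ScreenConfig()
    pats = cohort.patients
    gid, keys = _strata_labels(cohort)

    d = cohort.diagnoses_long.merge(
        pats[["sex"]], left_on="patient_id", right_index=True)
    occ_tab = d.groupby(["sex", "code"]).size()
    occ: dict[str, dict[str, int]] = {"F": {}, "M": {}}
    for (sex, code), cnt in occ_tab.items():
        occ[sex][code] = int(cnt)

    presence = {code: _presence(cohort, code) for code in universe}
    results: list[PairScreenResult] = []
    for code_a, code_b in itertools.combinations(universe, 2):
        pair_occ = {sex: {c: int(occ[sex].get(c, 0)) for c in (code_a, code_b)}
                    for sex in ("F", "M")}
        res = PairScreenResult(code_a, code_b, None, None, pair_occ)
        if any(pair_occ[sex][c] < config.min_occurrences
               for sex in ("F", "M") for c in (code_a, code_b)):
            res.flags.append("occurrence")
            results.append(res)
            continue
        passes = {}
        for sex in ("F", "M"):
            sel = (pats["sex"] == sex).to_numpy()
            tabs = _tables_from_presence(
                gid, keys, presence[code_a] & sel, presence[code_b] & sel,
                config.min_cell)
            tabs = [t for t in tabs if t.n > 0]
            try:
                est = mh_pool(tabs) if tabs else None
            except NoEstimateError:
                est = None
            if est is None:
                res.flags.append(f"no_estimate_{sex.lower()}")
            if sex == "F":
                res.estimate_f = est
            else:
                res.estimate_m = est
            passes[sex] = _passes(est, config)
        ok = (passes["F"] or passes["M"]) if config.sex_rule == "either" \
            else (passes["F"] and passes["M"])
        if not ok:
            res.flags.append("rr_p")
        res.kept = ok
        results.append(res)
    return results


_EDGE_COLUMNS = ["code_a", "code_b", "sex", "or_mh", "rr_mh", "ci_low", "ci_high",
                 "p_cmh", "n_strata_used", "occurrences_f_a", "occurrences_f_b",
                 "occurrences_m_a", "occurrences_m_b", "kept", "flags"]


def screen_to_frame(results: list[PairScreenResult]) -> pd.DataFrame:
    """Edge-list view of screening results, one row per (pair, sex)."""
    if not results:
        return pd.DataFrame(columns=_EDGE_COLUMNS)
    rows = []
    for r in results:
        for sex, est in (("F", r.estimate_f), ("M", r.estimate_m)):
            row = {
                "code_a": r.code_a, "code_b": r.code_b, "sex": sex,
                "or_mh": np.nan, "rr_mh": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "p_cmh": np.nan, "n_strata_used": 0,
                "occurrences_f_a": r.occurrences["F"][r.code_a],
                "occurrences_f_b": r.occurrences["F"][r.code_b],
                "occurrences_m_a": r.occurrences["M"][r.code_a],
                "occurrences_m_b": r.occurrences["M"][r.code_b],
                "kept": r.kept, "flags": ";".join(r.flags),
            }
            if est is not None:
                row.update(or_mh=est.or_mh, rr_mh=est.rr_mh,
                           ci_low=est.ci95_or[0], ci_high=est.ci95_or[1],
                           p_cmh=est.p_cmh, n_strata_used=est.n_strata_used)
            rows.append(row)
    return pd.DataFrame(rows)
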