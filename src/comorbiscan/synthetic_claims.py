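"""Synthetic longitudinal inpatient claims with planted statistical structure.

The generator emulates the registry the screening pipeline expects: patients
with a sex and a 5-year age band, hospital stays scattered over a 12-year
observation window (2003–2014) preceded by a 6-year washout window
(1997–2002), per-(sex, age band) baseline code prevalences, pairwise
comorbidity odds ratios that differ by sex, and planted diagnosis-order lags
for the time-directionality analysis.

Generative model, per patient:

* sex ~ Bernoulli(frac_female); age band drawn from the configured bands;
* every non-planted ("background") code present independently with its
  baseline prevalence;
* for each planted pair, code A is drawn at its marginal prevalence and the
  conditional probability of code B is tilted (:func:`tilt_conditional`) so
  that the patient-level odds ratio among *observed* patients of that sex
  and band equals the target exactly in expectation (see note below);
* the number of stay slots is 1 + Poisson(mean − 1) with admission dates
  uniform over the observation window; each present code lands on a
  uniformly chosen slot; slots that receive no code are not emitted
  (an admission always has a primary diagnosis);
* when both codes of a planted pair are present they receive dedicated
  stays: with probability ``direction_prob`` A's first diagnosis precedes
  B's, at a lag of max(1, round(Exponential(lag_days_mean))) days;
* a fraction ``washout_violation_prob`` of patients additionally receive a
  stay inside the washout window (carrying their earliest diagnosis, so the
  order of first diagnoses is unchanged).

Observation correction: a person with no diagnosed code never enters a
claims registry, which thins only the neither-A-nor-B cell of a pair's
2×2 table, by the probability 1 − q0 of carrying at least one other code.
The tilt therefore targets OR/(1 − q0) in the full simulated population so
that the odds ratio measured on the emitted dataset is the configured one.
"""

from __future__ import annotations

import datetime as _dt
import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .claims_io import ClaimsDataset, is_valid_code

__all__ = ["PlantedPair", "SimConfig", "InfeasibleORError", "tilt_conditional",
           "generate", "demo_config"]


class InfeasibleORError(ValueError):
    """No joint distribution in (0,1) realises the requested odds ratio."""


def tilt_conditional(p_a: float, p_b: float, target_or: float) -> tuple[float, float]:
    """Conditionals ``(P(B|A), P(B|not A))`` with marginal ``p_b`` and the given OR.

    Solves for the joint probability p11 = P(A and B) from the odds-ratio
    identity OR = p11·p00 / (p10·p01) under fixed marginals.  The quadratic
    is evaluated in the cancellation-free form

        p11 = 2·OR·p_a·p_b / (S + sqrt(S² − 4·OR·(OR−1)·p_a·p_b)),
        S   = 1 + (p_a + p_b)(OR − 1),

    which is continuous through OR = 1 (independence, p11 = p_a·p_b).
    """
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError(f"marginals must lie strictly in (0,1); got p_a={p_a}, p_b={p_b}")
    if not target_or > 0.0:
        raise ValueError(f"target_or must be positive; got {target_or}")
    s = 1.0 + (p_a + p_b) * (target_or - 1.0)
    disc = s * s - 4.0 * target_or * (target_or - 1.0) * p_a * p_b
    if disc < 0.0:
        raise InfeasibleORError(
            f"no solution for p_a={p_a}, p_b={p_b}, OR={target_or}")
    p11 = 2.0 * target_or * p_a * p_b / (s + math.sqrt(disc))
    p_b_given_a = p11 / p_a
    p_b_given_not_a = (p_b - p11) / (1.0 - p_a)
    eps = 1e-15
    if not (eps < p_b_given_a < 1.0 - eps and eps < p_b_given_not_a < 1.0 - eps):
        raise InfeasibleORError(
            f"tilted conditionals outside (0,1) for p_a={p_a}, p_b={p_b}, OR={target_or}: "
            f"P(B|A)={p_b_given_a}, P(B|not A)={p_b_given_not_a}")
    return p_b_given_a, p_b_given_not_a


class PlantedPair(BaseModel):
    """A diagnosis pair with sex-specific target odds ratios and time ordering."""

    code_a: str
    code_b: str
    or_female: float = Field(gt=0)
    or_male: float = Field(gt=0)
    #: P(first diagnosis of A precedes first diagnosis of B | both present).
    direction_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    lag_days_mean: float = Field(default=365.0, gt=0)

    @model_validator(mode="after")
    def _check_codes(self):
        for c in (self.code_a, self.code_b):
            if not is_valid_code(c):
                raise ValueError(f"planted code {c!r} outside the A00–N99 universe")
        if self.code_a == self.code_b:
            raise ValueError("planted pair codes must differ")
        return self


class SimConfig(BaseModel):
    """Configuration of the synthetic registry (JSON-serialisable)."""

    n_patients: int = Field(gt=0)
    frac_female: float = Field(default=0.51, ge=0.0, le=1.0)
    age_bands: list[int] = Field(default_factory=lambda: list(range(20, 80, 5)))
    age_band_weights: Optional[list[float]] = None
    #: Cascading prevalence map: key "default", then sex ("F"/"M"), then
    #: "SEX:BAND" (e.g. "F:45"); inner maps are code -> baseline probability.
    prevalence: dict[str, dict[str, float]]
    stays_per_patient_mean: float = Field(default=3.0, ge=1.0)
    mean_los_days: float = Field(default=5.8, gt=0)
    observation_window: tuple[_dt.date, _dt.date] = (_dt.date(2003, 1, 1), _dt.date(2014, 12, 31))
    washout_window: tuple[_dt.date, _dt.date] = (_dt.date(1997, 1, 1), _dt.date(2002, 12, 31))
    washout_violation_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    planted_pairs: list[PlantedPair] = Field(default_factory=list)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.washout_window[1] >= self.observation_window[0]:
            raise ValueError("washout window must end before the observation window starts")
        for key, mp in self.prevalence.items():
            for code, p in mp.items():
                if not is_valid_code(code):
                    raise ValueError(f"prevalence code {code!r} (key {key!r}) outside A00–N99")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence of {code} under {key!r} not in [0,1]: {p}")
        seen: set[str] = set()
        for pair in self.planted_pairs:
            for c in (pair.code_a, pair.code_b):
                if c in seen:
                    raise ValueError(f"code {c} appears in more than one planted pair")
                seen.add(c)
        if self.age_band_weights is not None and len(self.age_band_weights) != len(self.age_bands):
            raise ValueError("age_band_weights must match age_bands in length")
        return self

    def prevalence_for(self, sex: str, band: int) -> dict[str, float]:
        """Effective code -> prevalence map for one (sex, age band) cell."""
        out: dict[str, float] = {}
        for key in ("default", sex, f"{sex}:{band}"):
            out.update(self.prevalence.get(key, {}))
        return {c: p for c, p in out.items() if p > 0.0}


def _window_days(win: tuple[_dt.date, _dt.date]) -> int:
    return (win[1] - win[0]).days + 1


def _pair_conditionals(
    pairs: list[PlantedPair], pv: dict[str, float], sex: str, band: int,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Tilted conditionals per planted pair within one (sex, band) cell.

    The tilt targets OR/(1 − q0), where q0 is the probability that a patient
    carries none of the *other* codes: only the neither-cell of a pair is
    thinned when code-free persons never enter the registry.  Because q0 of
    one pair depends on the joint distribution of every other pair (whose
    codes are positively correlated within the pair), the joint
    probabilities are solved by fixed-point iteration; with a single pair
    this reduces to the closed form in one pass.
    """
    if not pairs:
        return {}
    planted = {c for p in pairs for c in (p.code_a, p.code_b)}
    bg_prod = float(np.prod([1.0 - p for c, p in pv.items() if c not in planted]))
    info = []
    for pair in pairs:
        p_a, p_b = pv.get(pair.code_a), pv.get(pair.code_b)
        if p_a is None or p_b is None:
            raise ValueError(
                f"planted pair {pair.code_a}-{pair.code_b}: missing prevalence "
                f"in stratum ({sex}, {band})")
        target = pair.or_female if sex == "F" else pair.or_male
        info.append((pair, p_a, p_b, target))
    p11 = [p_a * p_b for _, p_a, p_b, _ in info]
    conds: dict[tuple[str, str], tuple[float, float]] = {}
    for _ in range(200):
        new_p11 = []
        for j, (pair, p_a, p_b, target) in enumerate(info):
            q0 = bg_prod
            for k, (_, pa_k, pb_k, _) in enumerate(info):
                if k != j:
                    q0 *= 1.0 - pa_k - pb_k + p11[k]
            if q0 >= 1.0 - 1e-12:
                raise ValueError(
                    f"planted pair {pair.code_a}-{pair.code_b}: stratum "
                    f"({sex}, {band}) has no other code, the neither-cell "
                    "would be unobservable")
            try:
                pba, pbn = tilt_conditional(p_a, p_b, target / (1.0 - q0))
            except (InfeasibleORError, ValueError) as err:
                raise InfeasibleORError(
                    f"planted pair {pair.code_a}-{pair.code_b}, stratum "
                    f"({sex}, {band}): {err}") from err
            conds[(pair.code_a, pair.code_b)] = (pba, pbn)
            new_p11.append(pba * p_a)
        if max(abs(a - b) for a, b in zip(new_p11, p11)) < 1e-14:
            break
        p11 = new_p11
    return conds


def generate(config: SimConfig, seed: int | None = None) -> ClaimsDataset:
    """Draw a synthetic claims dataset under ``config``.

    ``seed`` overrides ``config.seed`` when given.  Patients who end up with
    no diagnosed code produce no stays and are absent from the output;
    ``meta['n_simulated']`` records the number of simulated persons.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    obs_days = _window_days(config.observation_window)
    wash_days = _window_days(config.washout_window)

    female = rng.random(n) < config.frac_female
    bands = np.asarray(config.age_bands)
    w = config.age_band_weights
    band = rng.choice(bands, size=n, p=(np.asarray(w) / np.sum(w)) if w else None)

    # stay slots: dates independent of disease burden by construction
    k_slots = 1 + rng.poisson(config.stays_per_patient_mean - 1.0, size=n)
    slot_start = np.concatenate([[0], np.cumsum(k_slots)])
    n_slots = int(slot_start[-1])
    slot_off = rng.integers(0, obs_days, size=n_slots)

    # assignments of codes to stays, accumulated as parallel arrays
    asg_key: list[np.ndarray] = []      # stay identity (slot id or fresh id)
    asg_owner: list[np.ndarray] = []    # patient index
    asg_off: list[np.ndarray] = []      # admission offset (days from obs start)
    asg_code: list[np.ndarray] = []     # code string
    next_key = n_slots

    def _on_slots(pids: np.ndarray, code: str) -> None:
        nonlocal asg_key
        slots = slot_start[pids] + rng.integers(0, k_slots[pids])
        asg_key.append(slots)
        asg_owner.append(pids)
        asg_off.append(slot_off[slots])
        asg_code.append(np.full(len(pids), code, dtype=object))

    def _dedicated(pids: np.ndarray, offs: np.ndarray, code: str) -> None:
        nonlocal next_key
        keys = np.arange(next_key, next_key + len(pids))
        next_key += len(pids)
        asg_key.append(keys)
        asg_owner.append(pids)
        asg_off.append(offs)
        asg_code.append(np.full(len(pids), code, dtype=object))

    planted_codes = {c for p in config.planted_pairs for c in (p.code_a, p.code_b)}

    for sex, sex_mask in (("F", female), ("M", ~female)):
        for b in bands:
            grp = np.flatnonzero(sex_mask & (band == b))
            if len(grp) == 0:
                continue
            pv = config.prevalence_for(sex, int(b))
            for code, p in pv.items():
                if code in planted_codes:
                    continue
                _on_slots(grp[rng.random(len(grp)) < p], code)
            conds = _pair_conditionals(config.planted_pairs, pv, sex, int(b))
            for pair in config.planted_pairs:
                p_a = pv[pair.code_a]
                pba, pbn = conds[(pair.code_a, pair.code_b)]
                has_a = rng.random(len(grp)) < p_a
                has_b = rng.random(len(grp)) < np.where(has_a, pba, pbn)
                _on_slots(grp[has_a & ~has_b], pair.code_a)
                _on_slots(grp[~has_a & has_b], pair.code_b)
                both = grp[has_a & has_b]
                if len(both):
                    # anchor the first event on an existing slot's date so the
                    # patient's first admission (hence the period stratum) has
                    # the same distribution as for every other patient
                    si = slot_start[both] + rng.integers(0, k_slots[both])
                    first = np.minimum(slot_off[si], obs_days - 2)
                    lag = np.maximum(1, np.round(rng.exponential(pair.lag_days_mean, len(both)))
                                     ).astype(np.int64)
                    lag = np.minimum(lag, obs_days - 1 - first)
                    second = first + lag
                    a_first = rng.random(len(both)) < pair.direction_prob
                    _dedicated(both, np.where(a_first, first, second), pair.code_a)
                    _dedicated(both, np.where(a_first, second, first), pair.code_b)

    asg = pd.DataFrame({
        "key": np.concatenate(asg_key) if asg_key else np.array([], dtype=np.int64),
        "owner": np.concatenate(asg_owner) if asg_owner else np.array([], dtype=np.int64),
        "off": np.concatenate(asg_off) if asg_off else np.array([], dtype=np.int64),
        "code": np.concatenate(asg_code) if asg_code else np.array([], dtype=object),
    })
    asg = asg.drop_duplicates(["key", "code"])

    # washout violators: an extra pre-2003 stay carrying the patient's
    # earliest diagnosis, so first-diagnosis order is preserved
    if config.washout_violation_prob > 0.0 and len(asg):
        viol = rng.random(n) < config.washout_violation_prob
        earliest = (asg.sort_values(["owner", "off"], kind="stable")
                    .drop_duplicates("owner", keep="first"))
        earliest = earliest[viol[earliest["owner"].to_numpy()]]
        m = len(earliest)
        if m:
            woff = rng.integers(0, wash_days, size=m) - wash_days  # negative: before obs start
            wkeys = np.arange(next_key, next_key + m)
            next_key += m
            asg = pd.concat([asg, pd.DataFrame({
                "key": wkeys,
                "owner": earliest["owner"].to_numpy(),
                "off": woff,
                "code": earliest["code"].to_numpy(),
            })], ignore_index=True)

    obs_start = pd.Timestamp(config.observation_window[0])

    if asg.empty:
        stays = pd.DataFrame({
            "patient_id": pd.Series(dtype=str), "sex": pd.Series(dtype=str),
            "age_band": pd.Series(dtype=int),
            "admission_date": pd.Series(dtype="datetime64[ns]"),
            "discharge_date": pd.Series(dtype="datetime64[ns]"),
            "primary_dx": pd.Series(dtype=str), "secondary_dx": pd.Series(dtype=str),
        })
        ds = ClaimsDataset(stays,
                           (pd.Timestamp(config.observation_window[0]),
                            pd.Timestamp(config.observation_window[1])),
                           (pd.Timestamp(config.washout_window[0]),
                            pd.Timestamp(config.washout_window[1])),
                           {"n_simulated": n, "n_patients_emitted": 0})
        return ds

    per_stay = (asg.groupby("key", sort=False)
                .agg(owner=("owner", "first"), off=("off", "first"),
                     joined=("code", ";".join))
                .reset_index(drop=True))
    per_stay = per_stay.sort_values(["owner", "off"], kind="stable").reset_index(drop=True)
    split = per_stay["joined"].str.split(";", n=1)
    primary = split.str[0]
    secondary = split.str[1].fillna("")

    owner = per_stay["owner"].to_numpy()
    pid_str = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    los = rng.poisson(config.mean_los_days, size=len(per_stay))
    admission = obs_start + pd.to_timedelta(per_stay["off"].to_numpy(), unit="D")

    stays = pd.DataFrame({
        "patient_id": pid_str[owner],
        "sex": np.where(female[owner], "F", "M"),
        "age_band": band[owner].astype(int),
        "admission_date": admission,
        "discharge_date": admission + pd.to_timedelta(los, unit="D"),
        "primary_dx": primary.to_numpy(),
        "secondary_dx": secondary.to_numpy(),
    })

    # stay-level long table (saves an explode downstream); per_stay rows came
    # from groupby order then a stable (owner, off) sort, so replaying that
    # sort on the per-key firsts recovers the key -> row mapping
    first_idx = asg.groupby("key", sort=False).agg(owner=("owner", "first"),
                                                   off=("off", "first"))
    order = first_idx.sort_values(["owner", "off"], kind="stable").index.to_numpy()
    row_of = pd.Series(np.arange(len(order)), index=order)
    long = pd.DataFrame({
        "stay_idx": row_of.loc[asg["key"].to_numpy()].to_numpy(),
        "patient_id": pid_str[asg["owner"].to_numpy()],
        "code": asg["code"].to_numpy(),
        "admission_date": (obs_start + pd.to_timedelta(asg["off"].to_numpy(), unit="D")),
    }).sort_values("stay_idx", kind="stable").reset_index(drop=True)

    ds = ClaimsDataset(
        stays,
        (pd.Timestamp(config.observation_window[0]), pd.Timestamp(config.observation_window[1])),
        (pd.Timestamp(config.washout_window[0]), pd.Timestamp(config.washout_window[1])),
        {"n_simulated": n, "n_patients_emitted": int(stays["patient_id"].nunique()),
         "seed": int(config.seed if seed is None else seed)},
    )
    ds._long = long
    return ds


def demo_config(n_patients: int = 50_000, seed: int = 20259) -> SimConfig:
    """A small registry with cardiometabolic flavour used by the analysis scripts.

    Baseline prevalences loosely follow inpatient 20–79-year-olds (hypertension
    common, infarction rare); three planted pairs exercise female-excess,
    male-excess and sex-neutral comorbidity plus diagnosis ordering:
    diabetes→CHD (E11–I25, odds ratio 6 in women vs 4 in men), lipid
    disorders→AMI (E78–I21, male excess) and nicotine→COPD (F17–J44,
    sex-neutral).
    """
    prevalence = {
        "default": {
            # background morbidity
            "I10": 0.20, "M54": 0.08, "K29": 0.05, "I48": 0.05, "A09": 0.03,
            "N39": 0.06, "J18": 0.03, "K80": 0.04,
            # planted-pair marginals
            "E11": 0.10, "I25": 0.10, "E78": 0.085, "I21": 0.020,
            "F17": 0.032, "J44": 0.034,
        },
        "F": {"C50": 0.02},
        "M": {"C61": 0.02},
    }
    return SimConfig(
        n_patients=n_patients,
        prevalence=prevalence,
        washout_violation_prob=0.05,
        planted_pairs=[
            PlantedPair(code_a="E11", code_b="I25", or_female=6.0, or_male=4.0,
                        direction_prob=0.75, lag_days_mean=400.0),
            PlantedPair(code_a="E78", code_b="I21", or_female=6.3, or_male=7.2,
                        direction_prob=0.6, lag_days_mean=350.0),
            PlantedPair(code_a="F17", code_b="J44", or_female=4.0, or_male=4.0,
                        direction_prob=0.8, lag_days_mean=500.0),
        ],
        seed=seed,
    )
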