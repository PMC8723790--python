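"""End-to-end orchestration: simulate/read → cohort → screen → sex differences → TOR.

A pipeline run is described by a :class:`PipelineConfig`, executes every
stage with explicit filter-step accounting, and writes its outputs (edge
list with sex-difference columns, TOR tables, baseline summary, stratum
sizes) plus a JSON manifest echoing the configuration and seed, so a run
can be reproduced bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import claims_io, cohort as cohort_mod, cooccur, sexdiff as sexdiff_mod, trajectory
from .claims_io import ClaimsDataset
from .synthetic_claims import SimConfig, generate

__all__ = ["CVD_COMORBIDITY_CODES", "TARGET_CODES", "BaselineSummary",
           "PipelineConfig", "baseline_summary", "run_pipeline"]

logger = logging.getLogger("comorbiscan")

#: Cardiovascular target diagnoses: acute myocardial infarction and chronic
#: ischemic heart disease.
TARGET_CODES = ("I21", "I25")

#: Comorbidity code-group preset: obesity, lipid disorders, nicotine
#: dependence, diabetes (E10–E14), renal failure (N17–N19), COPD, asthma,
#: respiratory failure.
CVD_COMORBIDITY_CODES = {
    "obesity": {"E66"},
    "lipid_disorders": {"E78"},
    "nicotine_dependence": {"F17"},
    "diabetes_mellitus": {"E10", "E11", "E12", "E13", "E14"},
    "renal_failure": {"N17", "N18", "N19"},
    "copd": {"J44"},
    "asthma": {"J45"},
    "respiratory_failure": {"J96"},
}


@dataclass
class BaselineSummary:
    """Per-sex and overall cohort characteristics, Table-1 style.

    ``stats`` rows: n_patients and mean/sd/se of stays, hospital days and
    diagnoses per patient; ``prevalence_pct`` rows: share (%) of patients
    with at least one code of each tracked group, NaN when undefined.
    """

    stats: pd.DataFrame
    prevalence_pct: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.stats, self.prevalence_pct])


def _mean_sd_se(x: pd.Series) -> tuple[float, float, float]:
    n = len(x)
    if n == 0:
        return (np.nan, np.nan, np.nan)
    m = float(x.mean())
    sd = float(x.std(ddof=0)) if n > 1 else 0.0
    return m, sd, sd / np.sqrt(n)


def baseline_summary(
    dataset: ClaimsDataset,
    code_groups: dict[str, set[str]] | None = None,
) -> BaselineSummary:
    """Cohort characteristics by sex: counts, utilisation, group prevalences."""
    code_groups = CVD_COMORBIDITY_CODES if code_groups is None else code_groups
    st = dataset.stays
    long = dataset.diagnosis_long()
    pat = dataset.patients()
    cols = ("all", "F", "M")

    stats_rows: dict[str, list[float]] = {}
    prev_rows: dict[str, list[float]] = {}
    for col in cols:
        sub = st if col == "all" else st[st["sex"] == col]
        ids = sub["patient_id"]
        n_pat = ids.nunique()
        stays_pp = ids.value_counts()
        days = (sub["discharge_date"] - sub["admission_date"]).dt.days
        days_pp = days.groupby(ids.to_numpy()).sum() if len(sub) else pd.Series(dtype=float)
        sub_ids = set(ids)
        dlong = long[long["patient_id"].isin(sub_ids)] if col != "all" else long
        dx_pp = dlong["patient_id"].value_counts().reindex(stays_pp.index, fill_value=0)
        stats_rows[col] = [float(n_pat), *_mean_sd_se(stays_pp),
                           *_mean_sd_se(days_pp), *_mean_sd_se(dx_pp)]
        for label, codes in code_groups.items():
            if n_pat == 0:
                prev = np.nan
            else:
                carriers = dlong.loc[dlong["code"].isin(codes), "patient_id"].nunique()
                prev = 100.0 * carriers / n_pat
            prev_rows.setdefault(f"prevalence_{label}_pct", []).append(prev)

    stat_index = ["n_patients",
                  "stays_mean", "stays_sd", "stays_se",
                  "hospital_days_mean", "hospital_days_sd", "hospital_days_se",
                  "diagnoses_mean", "diagnoses_sd", "diagnoses_se"]
    stats = pd.DataFrame({c: stats_rows[c] for c in cols}, index=stat_index)
    prev = pd.DataFrame({c: [prev_rows[k][i] for k in prev_rows]
                         for i, c in enumerate(cols)},
                        index=list(prev_rows))
    return BaselineSummary(stats=stats, prevalence_pct=prev)


class PipelineConfig(BaseModel):
    """Everything a reproducible screening run needs."""

    sim: Optional[SimConfig] = None
    input_csv: Optional[str] = None
    observation_window: tuple[str, str] = ("2003-01-01", "2014-12-31")
    washout_window: tuple[str, str] = ("1997-01-01", "2002-12-31")
    age_bounds: tuple[int, int] = (20, 79)
    bands_10y: list[int] = Field(default_factory=lambda: list(cohort_mod.DEFAULT_BANDS_10Y))
    periods: list[tuple[int, int]] = Field(default_factory=lambda: list(cohort_mod.DEFAULT_PERIODS))
    #: Codes entering the pairwise screen; None → target codes + preset groups.
    universe: Optional[list[str]] = None
    target_codes: list[str] = Field(default_factory=lambda: list(TARGET_CODES))
    min_cell: int = 4
    rr_threshold: float = 1.5
    p_threshold: float = 0.01
    min_occurrences: int = 1000
    sex_rule: str = "either"
    #: Optional (min_age, max_age) re-analysis subgroups, e.g. [(20,49),(50,79)].
    subgroup_splits: list[tuple[int, int]] = Field(default_factory=list)
    seed: int = 0
    out_dir: str = "results/pipeline"
    log_level: str = "INFO"

    def screen_config(self) -> cooccur.ScreenConfig:
        return cooccur.ScreenConfig(
            min_cell=self.min_cell, rr_threshold=self.rr_threshold,
            p_threshold=self.p_threshold, min_occurrences=self.min_occurrences,
            sex_rule=self.sex_rule)

    def effective_universe(self) -> list[str]:
        if self.universe is not None:
            return list(self.universe)
        codes = set(self.target_codes)
        for group in CVD_COMORBIDITY_CODES.values():
            codes |= group
        return sorted(codes)


def _sexdiff_row(est_f: cooccur.PooledEstimate, est_m: cooccur.PooledEstimate) -> dict:
    sd, p_sd = sexdiff_mod.sd_statistic(
        est_f.or_mh, est_f.se_log_or, est_m.or_mh, est_m.se_log_or)
    tier = sexdiff_mod.classify_sd(sd)
    if tier == "not_significant" or sd == 0.0:
        favored = "none"
    else:
        favored = "female_excess" if sd < 0 else "male_excess"
    return {"sd": sd, "p_sd": p_sd, "tier": tier, "favored_sex": favored}


def _screen_and_diff(strat, universe, screen_cfg) -> tuple[pd.DataFrame, list]:
    results = cooccur.screen_pairs(strat, universe, screen_cfg)
    edges = cooccur.screen_to_frame(results)
    diffs = []
    for r in results:
        if r.estimate_f is not None and r.estimate_m is not None:
            row = {"code_a": r.code_a, "code_b": r.code_b, "kept": r.kept,
                   **_sexdiff_row(r.estimate_f, r.estimate_m)}
            diffs.append(row)
    diff_frame = pd.DataFrame(diffs) if diffs else pd.DataFrame(
        columns=["code_a", "code_b", "kept", "sd", "p_sd", "tier", "favored_sex"])
    edges = edges.merge(diff_frame.drop(columns=["kept"]),
                        on=["code_a", "code_b"], how="left")
    return edges, results


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screening pipeline and write the report bundle.

    Returns a dict with the in-memory results (dataset, cohort, edge list,
    TOR tables, baseline summary, manifest).  Outputs land in
    ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(config.model_dump_json()),
                      "seed": config.seed, "counts": {}}

    if config.sim is not None:
        data = generate(config.sim, seed=config.seed)
        logger.info("simulated %d stays for %d patients",
                    data.n_stays, data.n_patients)
    elif config.input_csv:
        data = claims_io.read_claims(
            config.input_csv,
            observation_window=config.observation_window,
            washout_window=config.washout_window)
    else:
        raise ValueError("PipelineConfig needs either sim or input_csv")
    manifest["counts"]["input"] = {"stays": data.n_stays, "patients": data.n_patients}

    data = cohort_mod.washout_filter(data)
    manifest["counts"]["post_washout"] = {"stays": data.n_stays, "patients": data.n_patients}
    data = cohort_mod.restrict_age(data, *config.age_bounds)
    manifest["counts"]["post_age_restrict"] = {"stays": data.n_stays,
                                               "patients": data.n_patients}

    strat = cohort_mod.assign_strata(data, tuple(config.bands_10y),
                                     tuple(tuple(p) for p in config.periods))
    sizes = strat.stratum_sizes().rename("n_patients").reset_index()
    sizes.to_csv(out / "stratum_sizes.csv", index=False)

    universe = config.effective_universe()
    edges, results = _screen_and_diff(strat, universe, config.screen_config())
    edges.to_csv(out / "edge_list.csv", index=False)
    manifest["counts"]["pairs_screened"] = len(results)
    manifest["counts"]["pairs_kept"] = int(sum(r.kept for r in results))

    tor_frames = []
    targets = set(config.target_codes)
    for r in results:
        if r.kept and (r.code_a in targets) ^ (r.code_b in targets):
            # orient comorbidity → target
            a, b = (r.code_b, r.code_a) if r.code_a in targets else (r.code_a, r.code_b)
            tor_frames.append(trajectory.tor_to_frame(trajectory.tor_analysis(data, a, b)))
    tor_table = (pd.concat(tor_frames, ignore_index=True) if tor_frames
                 else pd.DataFrame(columns=["code_a", "code_b", "group", "n_ab",
                                            "n_ba", "n_tied", "tor", "p_binom", "stars"]))
    tor_table.to_csv(out / "tor.csv", index=False)

    base = baseline_summary(data)
    base.to_frame().to_csv(out / "baseline_summary.csv")

    subgroup_edges = {}
    for lo, hi in config.subgroup_splits:
        sub = cohort_mod.restrict_age(data, lo, hi)
        sub_strat = cohort_mod.assign_strata(sub, tuple(config.bands_10y),
                                             tuple(tuple(p) for p in config.periods))
        sub_edges, _ = _screen_and_diff(sub_strat, universe, config.screen_config())
        sub_edges.to_csv(out / f"edge_list_{lo}_{hi}.csv", index=False)
        subgroup_edges[(lo, hi)] = sub_edges

    manifest["outputs"] = sorted(p.name for p in out.glob("*.csv"))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"dataset": data, "cohort": strat, "edges": edges,
            "screen_results": results, "tor": tor_table, "baseline": base,
            "subgroup_edges": subgroup_edges, "manifest": manifest}
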