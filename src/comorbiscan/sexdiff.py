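"""Sex-difference statistic on pooled log odds ratios.

The contrast between a comorbidity's pooled odds ratio in male and female
patients is measured in units of pooled standard errors,

    SD = (log ORm − log ORf) / sqrt(SEm² + SEf²),

where SEm, SEf are the standard errors of the log ORs.  Under the null of
no sex difference SD is standard normal; P_SD is its two-sided tail
probability.  Tiers are assigned from |SD| at the cutpoints 2, 3, 4, 5
(the tier boundary 2 corresponds to P_SD = 0.0455, i.e. the two-sided
tail).  A negative SD means the odds ratio is larger in women
(female excess); positive means male excess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["TIERS", "SexDifferenceResult", "sd_statistic", "se_from_ci",
           "classify_sd", "sex_difference"]

Z95 = float(norm.ppf(0.975))

#: (upper bound of |SD|, tier name); the last tier is open-ended.
TIERS = (
    (2.0, "not_significant"),
    (3.0, "weak"),
    (4.0, "substantial"),
    (5.0, "strong"),
    (math.inf, "very_strong"),
)


@dataclass
class SexDifferenceResult:
    or_f: float
    or_m: float
    se_f: float
    se_m: float
    sd: float
    p_sd: float
    tier: str
    favored_sex: str  # 'female_excess', 'male_excess' or 'none'


def sd_statistic(or_f: float, se_f: float, or_m: float, se_m: float) -> tuple[float, float]:
    """The SD statistic and its two-sided normal p-value.

    ``se_f``/``se_m`` are standard errors on the log-OR scale.
    """
    if min(or_f, or_m, se_f, se_m) <= 0:
        raise ValueError("odds ratios and standard errors must be strictly positive")
    sd = (math.log(or_m) - math.log(or_f)) / math.hypot(se_m, se_f)
    p_sd = float(2.0 * norm.sf(abs(sd)))
    return sd, p_sd


def se_from_ci(or_value: float, ci_low: float, ci_high: float) -> float:
    """Recover the log-OR standard error from a printed 95% Wald interval.

    Inverts exp(log OR ± 1.96·SE): SE = (ln U − ln L) / (2·1.959964).
    """
    if not (0 < ci_low <= or_value <= ci_high):
        raise ValueError(
            f"expected 0 < low <= OR <= high, got ({or_value}, {ci_low}, {ci_high})")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)


def classify_sd(sd: float) -> str:
    """Significance tier from |SD| at the cutpoints 2, 3, 4, 5 (left-open)."""
    if not math.isfinite(sd):
        raise ValueError(f"SD must be finite, got {sd}")
    mag = abs(sd)
    for bound, tier in TIERS:
        if mag <= bound:
            return tier
    raise AssertionError("unreachable")


def sex_difference(
    or_f: float, ci_f: tuple[float, float], or_m: float, ci_m: tuple[float, float],
) -> SexDifferenceResult:
    """Full sex-difference result from per-sex ORs with 95% CIs."""
    se_f = se_from_ci(or_f, *ci_f)
    se_m = se_from_ci(or_m, *ci_m)
    sd, p_sd = sd_statistic(or_f, se_f, or_m, se_m)
    tier = classify_sd(sd)
    if tier == "not_significant" or sd == 0.0:
        favored = "none"
    else:
        favored = "female_excess" if sd < 0 else "male_excess"
    return SexDifferenceResult(or_f=or_f, or_m=or_m, se_f=se_f, se_m=se_m,
                               sd=sd, p_sd=p_sd, tier=tier, favored_sex=favored)
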