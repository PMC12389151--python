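"""E-values: robustness of an odds ratio to unmeasured confounding.

The E-value is the minimum strength of association, on the risk-ratio
scale, that an unmeasured confounder would need with both exposure and
outcome to explain an observed association away to the null:

    E = R + sqrt(R * (R - 1)),   R = max(OR, 1/OR).

With a rare outcome (prevalence well under ~15%) the odds ratio
approximates a risk ratio and is used directly; for common outcomes the
conventional square-root conversion ``R <- sqrt(R)`` is applied first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class EValueResult:
    odds_ratio: float
    evalue_point: float
    evalue_ci: float | None
    reciprocal_transformed: bool
    rare_outcome: bool


def _e_from_rr(rr: float) -> float:
    # rr >= 1 here
    return rr + math.sqrt(rr * (rr - 1.0))


def evalue_point(or_value: float, rare_outcome: bool = True) -> float:
    """E-value of a point estimate.

    Estimates below 1 are inverted first (the E-value is symmetric in
    OR and 1/OR), so E >= 1 always, with E = 1 exactly at the null.
    """
    if not or_value > 0:
        raise ValueError(f"odds ratio must be positive, got {or_value!r}")
    r = or_value if or_value >= 1.0 else 1.0 / or_value
    if not rare_outcome:
        r = math.sqrt(r)
    return _e_from_rr(r)


def evalue_ci(
    or_value: float, ci_low: float, ci_high: float, rare_outcome: bool = True
) -> float:
    """E-value of the confidence limit closer to the null.

    A confidence interval containing 1 can be explained by no unmeasured
    confounding at all, so its E-value is 1.
    """
    if not (ci_low <= or_value <= ci_high):
        raise ValueError(
            f"confidence interval ({ci_low}, {ci_high}) does not contain {or_value}"
        )
    if ci_low <= 1.0 <= ci_high:
        return 1.0
    limit = ci_low if or_value >= 1.0 else ci_high
    return evalue_point(limit, rare_outcome=rare_outcome)


def evalue(
    or_value: float,
    ci_low: float | None = None,
    ci_high: float | None = None,
    rare_outcome: bool = True,
) -> EValueResult:
    """Point and (optional) confidence-limit E-values in one record."""
    point = evalue_point(or_value, rare_outcome=rare_outcome)
    ci = (
        evalue_ci(or_value, ci_low, ci_high, rare_outcome=rare_outcome)
        if ci_low is not None and ci_high is not None
        else None
    )
    return EValueResult(
        odds_ratio=or_value,
        evalue_point=point,
        evalue_ci=ci,
        reciprocal_transformed=or_value < 1.0,
        rare_outcome=rare_outcome,
    )


def round_half_even(x: float, digits: int = 2) -> float:
    """Banker's rounding used for report tables; full precision is kept
    internally."""
    from decimal import ROUND_HALF_EVEN, Decimal

    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))
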