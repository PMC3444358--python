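"""Validation statistics for case-finding algorithms.

Covers the full diagnostic-test toolkit used to validate a rule-based
phenotyping algorithm:

* exact (Clopper–Pearson) binomial confidence intervals for every
  reported proportion;
* sensitivity, specificity, PPV and NPV from a 2×2 confusion table;
* prevalence-standardized PPV via the Bayes relation
  ``PPV = Se·π / (Se·π + (1−Sp)·(1−π))``, which re-expresses the
  predictive value at an assumed population prevalence π — the device
  that lets PPV be reported per 10-year age band without band-level case
  counts;
* age-stratified standardized PPV with prevalence borrowing: the 35–44
  band borrows the 45–54 prevalence and the open-ended 85+ band borrows
  the 75–84 prevalence (the prevalence source covers ages 45–84 only);
* clinician-verification summaries where "unsure" responses may be
  counted as positives (broad PPV) or not (definite PPV);
* responder/non-responder comparison tests: two-sample t (pooled or
  Welch) from summary statistics, Pearson chi-squared and Fisher's exact
  test on 2×2 tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError, DataError, StatisticalError

__all__ = [
    "AGE_BANDS",
    "ProportionEstimate",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "AgeStratumMetrics",
    "VerificationSummary",
    "GroupComparison",
    "exact_binomial_ci",
    "diagnostic_metrics",
    "standardized_ppv",
    "standardized_ppv_estimate",
    "age_band",
    "age_stratified_ppv",
    "verification_summary",
    "two_sample_t",
    "chi_squared_2x2",
    "fisher_exact_2x2",
    "round_half_up",
]

#: 10-year age bands over ages ≥ 35; the last band is open-ended.
AGE_BANDS = ("35-44", "45-54", "55-64", "65-74", "75-84", "85+")

#: bands whose prevalence must be supplied; the outer bands borrow from these.
PREVALENCE_BORROW = {"35-44": "45-54", "85+": "75-84"}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (55.25 → 55.3 at one decimal)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Proportions with exact CIs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion x/n with a confidence interval and the method that made it."""

    x: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "clopper-pearson"

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        return tuple(
            round_half_up(100.0 * v, decimals)
            for v in (self.estimate, self.ci_low, self.ci_high)
        )

    def to_dict(self) -> dict:
        return {
            "x": self.x, "n": self.n, "estimate": self.estimate,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "level": self.level, "method": self.method,
        }


def exact_binomial_ci(x: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Clopper–Pearson exact binomial interval for x successes out of n.

    The bounds are exact at the boundaries: ci_low = 0 when x = 0 and
    ci_high = 1 when x = n.
    """
    if n < 1:
        raise StatisticalError("exact_binomial_ci: undefined for n = 0")
    if not 0 <= x <= n:
        raise ValueError(f"exact_binomial_ci: need 0 ≤ x ≤ n, got x={x}, n={n}")
    low, high = proportion_confint(x, n, alpha=1 - level, method="beta")
    return ProportionEstimate(int(x), int(n), x / n, float(low), float(high), level)


# ---------------------------------------------------------------------------
# 2×2 diagnostic metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Test-vs-truth 2×2 cell counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise StatisticalError("confusion table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sample_prevalence(self) -> float:
        return (self.tp + self.fn) / self.n

    @classmethod
    def from_flags(cls, predicted: Iterable[bool], truth: Iterable[bool]) -> "ConfusionCounts":
        p = np.asarray(list(predicted), dtype=bool)
        t = np.asarray(list(truth), dtype=bool)
        if p.shape != t.shape:
            raise ValueError("predicted and truth must have equal length")
        return cls(
            tp=int((p & t).sum()), fp=int((p & ~t).sum()),
            fn=int((~p & t).sum()), tn=int((~p & ~t).sum()),
        )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Se/Sp/PPV/NPV with exact CIs; a metric is None when its denominator is 0."""

    sensitivity: ProportionEstimate | None
    specificity: ProportionEstimate | None
    ppv: ProportionEstimate | None
    npv: ProportionEstimate | None
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            name: (est.to_dict() if est is not None else None)
            for name, est in (
                ("sensitivity", self.sensitivity), ("specificity", self.specificity),
                ("ppv", self.ppv), ("npv", self.npv),
            )
        }


def diagnostic_metrics(c: ConfusionCounts, level: float = 0.95) -> DiagnosticMetrics:
    """Sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp),
    NPV tn/(tn+fn), each with a Clopper–Pearson CI.

    A metric whose denominator is zero is returned as None rather than
    failing the whole table.
    """
    def est(x: int, n: int) -> ProportionEstimate | None:
        return exact_binomial_ci(x, n, level) if n > 0 else None

    return DiagnosticMetrics(
        sensitivity=est(c.tp, c.tp + c.fn),
        specificity=est(c.tn, c.tn + c.fp),
        ppv=est(c.tp, c.tp + c.fp),
        npv=est(c.tn, c.tn + c.fn),
        counts=c,
    )


# ---------------------------------------------------------------------------
# Prevalence-standardized PPV
# ---------------------------------------------------------------------------

def standardized_ppv(se: float, sp: float, prevalence: float) -> float:
    """PPV at an assumed prevalence via Bayes: Se·π / (Se·π + (1−Sp)(1−π))."""
    for name, v in (("se", se), ("sp", sp), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"standardized_ppv: {name} must be in [0, 1], got {v}")
    num = se * prevalence
    den = num + (1.0 - sp) * (1.0 - prevalence)
    if den == 0.0:
        raise StatisticalError(
            "standardized_ppv undefined: no positives expected at this operating point"
        )
    return num / den


def standardized_ppv_estimate(
    se: ProportionEstimate,
    sp: ProportionEstimate,
    prevalence: float,
    level: float = 0.95,
) -> ProportionEstimate:
    """Standardized PPV with a delta-method CI propagated from Se and Sp.

    The variance of the Bayes expression is approximated from the binomial
    variances of Se and Sp; the interval is a normal approximation clipped
    to [0, 1] and labelled ``bayes-delta`` (approximate, unlike the exact
    intervals elsewhere).
    """
    ppv = standardized_ppv(se.estimate, sp.estimate, prevalence)
    a = se.estimate * prevalence
    b = (1.0 - sp.estimate) * (1.0 - prevalence)
    den = (a + b) ** 2
    d_se = prevalence * b / den
    d_sp = a * (1.0 - prevalence) / den
    var = (
        d_se**2 * se.estimate * (1 - se.estimate) / se.n
        + d_sp**2 * sp.estimate * (1 - sp.estimate) / sp.n
    )
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return ProportionEstimate(
        x=se.x, n=se.n, estimate=ppv,
        ci_low=max(0.0, ppv - half), ci_high=min(1.0, ppv + half),
        level=level, method="bayes-delta",
    )


# ---------------------------------------------------------------------------
# Age stratification
# ---------------------------------------------------------------------------

def age_band(age_years: int) -> str:
    """Map a completed age (≥35) to its 10-year band label."""
    if age_years < 35:
        raise ValueError(f"age_band: age {age_years} below the 35-year floor")
    if age_years >= 85:
        return "85+"
    lo = 35 + 10 * ((age_years - 35) // 10)
    return f"{lo}-{lo + 9}"


@dataclass(frozen=True)
class AgeStratumMetrics:
    """Standardized PPV for one age band at its (possibly borrowed) prevalence."""

    stratum: str
    prevalence: float
    prevalence_borrowed_from: str | None
    ppv: ProportionEstimate

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "prevalence": self.prevalence,
            "prevalence_borrowed_from": self.prevalence_borrowed_from,
            "ppv": self.ppv.to_dict(),
        }


def age_stratified_ppv(
    strata: Mapping[str, tuple[ProportionEstimate, ProportionEstimate]],
    prevalence_by_band: Mapping[str, float],
    level: float = 0.95,
) -> list[AgeStratumMetrics]:
    """Standardized PPV per age band with prevalence borrowing.

    ``strata`` maps band label → (Se, Sp) estimates for that band.
    ``prevalence_by_band`` must cover 45-54 … 75-84; the 35-44 band uses
    the 45-54 prevalence and the 85+ band the 75-84 prevalence, each
    flagged with the band it borrowed from.
    """
    required = [b for b in AGE_BANDS if b not in PREVALENCE_BORROW]
    missing = [b for b in required if b not in prevalence_by_band]
    if missing:
        raise ConfigurationError(
            f"prevalence table missing required band(s): {missing}"
        )
    out: list[AgeStratumMetrics] = []
    for band in AGE_BANDS:
        if band not in strata:
            continue
        se, sp = strata[band]
        if band in prevalence_by_band:
            prev, borrowed = prevalence_by_band[band], None
        else:
            borrowed = PREVALENCE_BORROW[band]
            prev = prevalence_by_band[borrowed]
        out.append(
            AgeStratumMetrics(
                stratum=band, prevalence=prev, prevalence_borrowed_from=borrowed,
                ppv=standardized_ppv_estimate(se, sp, prev, level),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Verification outcomes
# ---------------------------------------------------------------------------

VERIFICATION_OUTCOMES = ("confirmed", "unsure", "rejected")


@dataclass(frozen=True)
class VerificationSummary:
    """Clinician-verification tallies for an identified cohort.

    ``ppv_definite`` counts only confirmed diagnoses as positive;
    ``ppv_broad`` also counts "unsure" as positive — the rationale being
    that everyone flagged had healthcare contact for a lung-related issue
    and the clinician could not reject the diagnosis.
    """

    n: int
    confirmed: int
    unsure: int
    rejected: int
    ppv_definite: ProportionEstimate
    ppv_broad: ProportionEstimate

    def to_dict(self) -> dict:
        return {
            "n": self.n, "confirmed": self.confirmed, "unsure": self.unsure,
            "rejected": self.rejected,
            "ppv_definite": self.ppv_definite.to_dict(),
            "ppv_broad": self.ppv_broad.to_dict(),
        }

    @classmethod
    def from_counts(cls, confirmed: int, unsure: int, rejected: int,
                    level: float = 0.95) -> "VerificationSummary":
        n = confirmed + unsure + rejected
        if n == 0:
            raise DataError("verification_summary: no outcomes")
        return cls(
            n=n, confirmed=confirmed, unsure=unsure, rejected=rejected,
            ppv_definite=exact_binomial_ci(confirmed, n, level),
            ppv_broad=exact_binomial_ci(confirmed + unsure, n, level),
        )


def verification_summary(outcomes: Iterable[str], level: float = 0.95) -> VerificationSummary:
    """Tally per-person verification outcomes {confirmed, unsure, rejected}."""
    counts = {k: 0 for k in VERIFICATION_OUTCOMES}
    for o in outcomes:
        if o not in counts:
            raise DataError(f"verification_summary: unknown outcome {o!r}")
        counts[o] += 1
    return VerificationSummary.from_counts(
        counts["confirmed"], counts["unsure"], counts["rejected"], level
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    n1: int
    n2: int
    statistic: float
    test: str
    p_value: float

    def to_dict(self) -> dict:
        return {"n1": self.n1, "n2": self.n2, "statistic": self.statistic,
                "test": self.test, "p_value": self.p_value}


def two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> GroupComparison:
    """Two-sample t-test from summary statistics.

    ``variant="pooled"`` is the classic equal-variance test;
    ``variant="welch"`` drops the equal-variance assumption.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"two_sample_t: unknown variant {variant!r}")
    if n1 < 2 or n2 < 2:
        raise ValueError("two_sample_t: each group needs n ≥ 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("two_sample_t: standard deviations must be positive")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    return GroupComparison(
        n1=n1, n2=n2, statistic=float(res.statistic),
        test=f"t_{variant}", p_value=float(res.pvalue),
    )


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("expected a 2×2 table of non-negative counts")
    return arr


def chi_squared_2x2(table, correction: bool = False) -> GroupComparison:
    """Pearson chi-squared test on a 2×2 table.

    No continuity correction by default; ``correction=True`` applies
    Yates' correction. Requires positive row and column margins.
    """
    arr = _as_2x2(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatisticalError("chi_squared_2x2: zero margin")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=correction)
    return GroupComparison(
        n1=int(arr[0].sum()), n2=int(arr[1].sum()),
        statistic=float(stat), test="chi_squared", p_value=float(p),
    )


def fisher_exact_2x2(table) -> GroupComparison:
    """Fisher's exact test on a 2×2 table, two-sided.

    The two-sided p-value follows the probability-mass ordering: the sum
    of hypergeometric probabilities of all margin-fixed tables no more
    likely than the observed one. Degenerate tables (a zero margin)
    return p = 1.
    """
    arr = _as_2x2(table).astype(int)
    stat, p = sps.fisher_exact(arr, alternative="two-sided")
    return GroupComparison(
        n1=int(arr[0].sum()), n2=int(arr[1].sum()),
        statistic=float(stat), test="fisher_exact", p_value=float(p),
    )
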