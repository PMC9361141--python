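"""Trial design machinery for the two-arm prompt-app study.

Covers stratified permuted-block randomization (1:1, block size 4,
strata sex x ISI group <8 / 8-14 / >=15), the two-sample
normal-approximation sample-size formula, attrition inflation, Pearson
chi-square baseline tests (no continuity correction), the independent
samples t test on change scores, and CONSORT flow accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import ISIStratum, isi_stratum

__all__ = [
    "ARMS",
    "EnrollmentRecord",
    "PowerSpec",
    "ConsortEvents",
    "ConsortSummary",
    "TTestResult",
    "ChiSquareResult",
    "TrialOpsError",
    "stratum_label",
    "stratified_block_randomize",
    "required_sample_size",
    "inflate_for_attrition",
    "pearson_chi_square",
    "two_sample_t_change",
    "consort_accounting",
]

ARMS = ("SPA", "control")  # intervention (sleep prompt app) vs wait-list control
SEXES = ("female", "male")

DEFAULT_BLOCK_SIZE = 4


class TrialOpsError(ValueError):
    """Raised for invalid trial-design inputs."""


def stratum_label(sex: str, baseline_isi: int) -> str:
    """Randomization stratum: sex crossed with the ISI group (<8/8-14/>=15)."""
    if sex not in SEXES:
        raise TrialOpsError(f"unknown sex {sex!r}")
    return f"{sex}:{isi_stratum(baseline_isi).value}"


STRATA = tuple(f"{s}:{g.value}" for s in SEXES for g in ISIStratum)


@dataclass
class EnrollmentRecord:
    participant_id: str
    sex: str
    baseline_isi: int
    stratum: str = ""
    arm: Optional[str] = None

    def __post_init__(self) -> None:
        expected = stratum_label(self.sex, self.baseline_isi)
        if not self.stratum:
            self.stratum = expected
        elif self.stratum != expected:
            raise TrialOpsError(
                f"stratum {self.stratum!r} inconsistent with sex/ISI ({expected!r})"
            )


def _permuted_block(rng: np.random.Generator, block_size: int, ratio: tuple[int, int]) -> list[str]:
    per_unit = block_size // sum(ratio)
    block = [ARMS[0]] * (ratio[0] * per_unit) + [ARMS[1]] * (ratio[1] * per_unit)
    return list(rng.permutation(block))


def stratified_block_randomize(
    roster: Sequence[EnrollmentRecord],
    block_size: int = DEFAULT_BLOCK_SIZE,
    ratio: tuple[int, int] = (1, 1),
    *,
    seed: int,
) -> pd.DataFrame:
    """Assign arms by permuted blocks within sex x ISI strata.

    Each stratum consumes its own sequence of randomly permuted blocks
    (block size 4, 2 per arm at 1:1), drawn from a substream keyed by
    (seed, stratum index), so the allocation is a pure function of the
    arrival order and the seed, and adding participants to one stratum
    never perturbs another.  Returns a table with one row per
    participant: id, sex, baseline ISI, stratum, arm, block index.
    """
    if block_size % sum(ratio) != 0:
        raise TrialOpsError(f"block size {block_size} not a multiple of ratio {ratio}")
    for rec in roster:
        if rec.stratum not in STRATA:
            raise TrialOpsError(f"unknown stratum {rec.stratum!r}")
    streams = {
        s: np.random.default_rng([int(seed), i]) for i, s in enumerate(STRATA)
    }
    pending: dict[str, list[str]] = {s: [] for s in STRATA}
    block_counter: dict[str, int] = {s: 0 for s in STRATA}
    rows = []
    for rec in roster:
        s = rec.stratum
        if not pending[s]:
            pending[s] = _permuted_block(streams[s], block_size, ratio)
            block_counter[s] += 1
        arm = pending[s].pop(0)
        rec.arm = arm
        rows.append(
            {
                "participant_id": rec.participant_id,
                "sex": rec.sex,
                "baseline_isi": rec.baseline_isi,
                "stratum": s,
                "arm": arm,
                "block_index": block_counter[s],
            }
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "sex", "baseline_isi", "stratum", "arm", "block_index"]
    )


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the two-sample sample-size formula.

    ``delta`` is the detectable between-group difference in the outcome's
    units (here ISI points), ``sd`` its common standard deviation.
    """

    delta: float
    sd: float
    alpha: float = 0.05
    power: float = 0.80
    attrition_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise TrialOpsError("alpha and power must lie in (0, 1)")
        if self.delta <= 0 or self.sd <= 0:
            raise TrialOpsError("delta and sd must be positive")
        if not 0 <= self.attrition_rate < 1:
            raise TrialOpsError("attrition rate must be in [0, 1)")


def required_sample_size(spec: PowerSpec) -> int:
    """Per-group n from the normal-approximation two-sample formula.

    n = ceil( 2 (z_{1-alpha/2} + z_{power})^2 sd^2 / delta^2 ).
    """
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    n = 2 * (z_a + z_b) ** 2 * spec.sd**2 / spec.delta**2
    return math.ceil(n - 1e-12)


def inflate_for_attrition(n_total: int, rate: float) -> int:
    """Enrollment target: total n inflated multiplicatively for attrition."""
    if not 0 <= rate < 1:
        raise TrialOpsError("attrition rate must be in [0, 1)")
    return math.ceil(n_total * (1 + rate) - 1e-12)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray = field(repr=False, compare=False, default=None)


def pearson_chi_square(table) -> ChiSquareResult:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction (the form that reproduces published 2x2 baseline tests)."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or (counts < 0).any():
        raise TrialOpsError("table must be a 2-D array of nonnegative counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise TrialOpsError("every row and column marginal must be positive")
    res = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        expected=res.expected_freq,
    )


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float


def two_sample_t_change(scores_a, scores_b, *, alpha: float = 0.05) -> TTestResult:
    """Independent-samples t test (pooled variance) on change scores.

    Returns the mean difference a - b with its two-sided p and
    (1 - alpha) CI.  With zero pooled variance the comparison degenerates:
    a zero difference reports p = 1 with a point CI, a nonzero one p = 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise TrialOpsError("each sample needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise TrialOpsError("samples must be finite")
    diff = float(a.mean() - b.mean())
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return TTestResult(diff, diff, diff, 1.0 if diff == 0 else 0.0, df)
    res = stats.ttest_ind(a, b, equal_var=True)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return TTestResult(diff, float(ci.low), float(ci.high), float(res.pvalue), df)


@dataclass(frozen=True)
class ConsortEvents:
    """Raw flow counts from recruitment through analysis."""

    applied: int
    eligible: int
    allocated: Mapping[str, int]
    excluded_after_allocation: Mapping[str, int]
    analyzed: Mapping[str, int]
    exclusion_reasons: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ConsortSummary:
    applied: int
    eligible: int
    allocated: Mapping[str, int]
    excluded_after_allocation: Mapping[str, int]
    analyzed: Mapping[str, int]
    dropout_rate_pct: Mapping[str, float]  # per arm, percent to 1 dp


def consort_accounting(events: ConsortEvents) -> ConsortSummary:
    """Check flow consistency and derive per-arm dropout rates.

    Dropout rate is post-allocation exclusions over allocations in that
    arm, as a percentage rounded to 1 decimal place.
    """
    if events.eligible > events.applied:
        raise TrialOpsError("eligible cannot exceed applied")
    rates = {}
    for arm, n_alloc in events.allocated.items():
        excl = events.excluded_after_allocation.get(arm, 0)
        analyzed = events.analyzed.get(arm, 0)
        if analyzed > n_alloc:
            raise TrialOpsError(f"analyzed > allocated in arm {arm}")
        if analyzed != n_alloc - excl:
            raise TrialOpsError(
                f"arm {arm}: analyzed ({analyzed}) != allocated ({n_alloc}) "
                f"- excluded ({excl})"
            )
        rates[arm] = round(100.0 * excl / n_alloc, 1) if n_alloc else 0.0
    return ConsortSummary(
        applied=events.applied,
        eligible=events.eligible,
        allocated=dict(events.allocated),
        excluded_after_allocation=dict(events.excluded_after_allocation),
        analyzed=dict(events.analyzed),
        dropout_rate_pct=rates,
    )
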