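"""Questionnaire scoring and the eligibility screen.

Instruments covered:

* ISI — Insomnia Severity Index, 7 items scored 0-4, total 0-28; a total
  of 8 or more defines an "ISI-8 insomniac", and randomization strata
  cut the total at <8, 8-14, >=15.
* CFS — Chalder fatigue scale, 11 items Likert-scored 0-3; global 0-33,
  physical subscale items 1-7 (0-21), psychological items 8-11 (0-12).
  Only Likert scoring is implemented (no bimodal variant).
* HPQ — WHO Health and Work Performance Questionnaire short form:
  relative presenteeism = B11 (own 4-week performance, 0-10) divided by
  B9 (typical coworker performance, 0-10), bounded to [0.25, 2.0];
  absolute presenteeism = 10 x B11, 0-100.
* PHQ-9 — 9 items scored 0-3; used only for screening here (total >=10
  excludes, as does item 9, self-harm thoughts, at "more than half the
  days", i.e. response codes >=2).
* Lifestyle report — daily caffeine (95 mg per cup of coffee, 55 mg per
  cup of tea, 45 mg per cup of cola), BMI with obesity at >=25 kg/m2,
  alcohol/smoking/living/hypnotic-use items.

Responses with missing or out-of-range items score as invalid (a
:class:`ResponseError`); there is no prorating or imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "ResponseError",
    "ISIResponse",
    "CFSResponse",
    "HPQResponse",
    "PHQ9Response",
    "LifestyleReport",
    "ISIClass",
    "ISIStratum",
    "CFSScore",
    "ScreeningDecision",
    "score_isi",
    "isi_classify",
    "isi_stratum",
    "score_cfs",
    "relative_presenteeism",
    "absolute_presenteeism",
    "caffeine_mg",
    "bmi_obese",
    "score_phq9",
    "screen_eligibility",
    "RELATIVE_PRESENTEEISM_BOUNDS",
]

RELATIVE_PRESENTEEISM_BOUNDS = (0.25, 2.0)

CAFFEINE_MG = {"coffee": 95, "tea": 55, "cola": 45}


class ResponseError(ValueError):
    """Raised for missing or out-of-range questionnaire items."""


def _check_items(items: Sequence[int], n: int, lo: int, hi: int, name: str) -> tuple[int, ...]:
    items = tuple(items)
    if len(items) != n:
        raise ResponseError(f"{name} requires exactly {n} items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if not isinstance(v, int) or isinstance(v, bool) or not lo <= v <= hi:
            raise ResponseError(f"{name} item {i} must be an integer in {lo}..{hi}, got {v!r}")
    return items


@dataclass(frozen=True)
class ISIResponse:
    items: tuple[int, ...]
    administration_week: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", _check_items(self.items, 7, 0, 4, "ISI"))
        if not 0 <= self.administration_week <= 4:
            raise ResponseError("ISI administration week must be 0..4")


@dataclass(frozen=True)
class CFSResponse:
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", _check_items(self.items, 11, 0, 3, "CFS"))


@dataclass(frozen=True)
class HPQResponse:
    b9_others_performance: int
    b10_performance_1_2yr: int
    b11_performance_4wk: int

    def __post_init__(self) -> None:
        for name in ("b9_others_performance", "b10_performance_1_2yr", "b11_performance_4wk"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 10:
                raise ResponseError(f"HPQ {name} must be an integer in 0..10, got {v!r}")


@dataclass(frozen=True)
class PHQ9Response:
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", _check_items(self.items, 9, 0, 3, "PHQ-9"))

    @property
    def item9(self) -> int:
        return self.items[8]


@dataclass(frozen=True)
class LifestyleReport:
    cups_coffee: int
    cups_tea: int
    cups_cola: int
    height_cm: float
    weight_kg: float
    alcohol_freq: str = "never"  # never | sometimes | everyday
    smoker: bool = False
    lives_alone: bool = False
    hypnotic_use_weekly: bool = False
    alcohol_as_sleep_aid_weekly: bool = False

    def __post_init__(self) -> None:
        for name in ("cups_coffee", "cups_tea", "cups_cola"):
            if getattr(self, name) < 0:
                raise ResponseError(f"{name} must be >= 0")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ResponseError("height and weight must be positive")
        if self.alcohol_freq not in ("never", "sometimes", "everyday"):
            raise ResponseError(f"unknown alcohol_freq {self.alcohol_freq!r}")


class ISIClass(str, Enum):
    NON_INSOMNIAC = "non_insomniac"
    ISI8_INSOMNIAC = "isi8_insomniac"


class ISIStratum(str, Enum):
    LT8 = "lt8"
    S8_14 = "s8_14"
    GE15 = "ge15"


class CFSScore(NamedTuple):
    global_score: int
    physical: int
    psychological: int


def score_isi(r: ISIResponse) -> int:
    """Total ISI score: the plain item sum, 0 (none) to 28 (severe)."""
    return sum(r.items)


def isi_stratum(total: int) -> ISIStratum:
    if not 0 <= total <= 28:
        raise ResponseError(f"ISI total must be in 0..28, got {total}")
    if total < 8:
        return ISIStratum.LT8
    if total < 15:
        return ISIStratum.S8_14
    return ISIStratum.GE15


def isi_classify(total: int) -> tuple[ISIClass, ISIStratum]:
    """Insomnia status (cutoff >=8) and randomization stratum (<8/8-14/>=15)."""
    stratum = isi_stratum(total)
    cls = ISIClass.NON_INSOMNIAC if total < 8 else ISIClass.ISI8_INSOMNIAC
    return cls, stratum


def score_cfs(r: CFSResponse) -> CFSScore:
    """Likert-scored CFS: (global 0-33, physical 0-21, psychological 0-12)."""
    physical = sum(r.items[:7])
    psychological = sum(r.items[7:])
    return CFSScore(physical + psychological, physical, psychological)


def relative_presenteeism(r: HPQResponse) -> Optional[float]:
    """Own performance relative to coworkers, clipped to [0.25, 2.0].

    Undefined (None) when the coworker anchor B9 is 0.
    """
    if r.b9_others_performance == 0:
        return None
    lo, hi = RELATIVE_PRESENTEEISM_BOUNDS
    return min(hi, max(lo, r.b11_performance_4wk / r.b9_others_performance))


def absolute_presenteeism(r: HPQResponse) -> int:
    """10 x the 0-10 self-rating of 4-week performance (B11), giving 0-100.

    The source questionnaire's prose labels this input as the 1-2-year
    rating, but cites item code B11 (the 4-week rating); the 4-week B11
    is the standard convention and is what is used here.
    """
    return 10 * r.b11_performance_4wk


def caffeine_mg(r: LifestyleReport) -> int:
    """Estimated daily caffeine: 95/55/45 mg per cup of coffee/tea/cola."""
    return (
        CAFFEINE_MG["coffee"] * r.cups_coffee
        + CAFFEINE_MG["tea"] * r.cups_tea
        + CAFFEINE_MG["cola"] * r.cups_cola
    )


def bmi_obese(r: LifestyleReport) -> tuple[float, bool]:
    """BMI in kg/m2 and the obesity flag at the >=25 cutoff (inclusive)."""
    bmi = r.weight_kg / (r.height_cm / 100.0) ** 2
    return bmi, bmi >= 25.0


def score_phq9(r: PHQ9Response) -> int:
    return sum(r.items)


@dataclass(frozen=True)
class ScreeningDecision:
    eligible: bool
    failed: tuple[str, ...]


#: PHQ-9 response codes mean 0 "not at all", 1 "several days",
#: 2 "more than half the days", 3 "nearly every day".
_PHQ9_ITEM9_EXCLUDE = 2
_PHQ9_TOTAL_EXCLUDE = 10


def screen_eligibility(
    *,
    age: int,
    has_smartphone: bool,
    has_sleep_problem: bool,
    phq9: PHQ9Response,
    shift_worker: bool,
    timezone_travel: bool,
    device_supported: bool,
    judged_inappropriate: bool = False,
) -> ScreeningDecision:
    """Apply the trial's inclusion and exclusion criteria.

    Inclusion: working-age adult (>=20), owns a smartphone, reports a
    sleep problem.  Exclusion: unsupported device, shift work, imminent
    large time-zone change, PHQ-9 total >=10, PHQ-9 item 9 at "more than
    half the days" or worse, or investigator judgement.  Returns the
    decision together with every failed criterion.
    """
    failed: list[str] = []
    if age < 20:
        failed.append("inclusion-age")
    if not has_smartphone:
        failed.append("inclusion-smartphone")
    if not has_sleep_problem:
        failed.append("inclusion-sleep-problem")
    if not device_supported:
        failed.append("exclusion-device-unsupported")
    if shift_worker:
        failed.append("exclusion-shift-worker")
    if timezone_travel:
        failed.append("exclusion-timezone-travel")
    if score_phq9(phq9) >= _PHQ9_TOTAL_EXCLUDE:
        failed.append("exclusion-phq9-total")
    if phq9.item9 >= _PHQ9_ITEM9_EXCLUDE:
        failed.append("exclusion-phq9-item9")
    if judged_inappropriate:
        failed.append("exclusion-judged-inappropriate")
    return ScreeningDecision(eligible=not failed, failed=tuple(failed))
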