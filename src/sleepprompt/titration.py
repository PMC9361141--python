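"""Sleep-restriction therapy: weekly bedtime recommendation and titration.

Each week the participant enters a desired wake-up time; the recommended
bedtime is that wake time minus (previous week's mean total sleep time
+ 30 minutes).  The prescribed time in bed is then titrated from the
week's diary-derived mean sleep efficiency (SE):

    SE > 90%        -> extend time in bed by 15 minutes
    85% <= SE <= 90 -> keep the same prescription
    SE < 85%        -> restrict by a further 15 minutes

Restriction runs in program weeks 2-4.  Both boundary values (85 and 90)
map to "keep the same".  The prescription is clamped to a safety floor of
300 minutes (5 h, the usual sleep-restriction convention) and a cap of
600 minutes (10 h) that rejects degenerate inputs.  The +/-15 adjustment
moves the bedtime; the wake time is anchored by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .diary import ClockTime, WeeklySummary

__all__ = [
    "SleepSchedule",
    "TitrationError",
    "TIB_FLOOR",
    "TIB_CAP",
    "TITRATION_STEP",
    "recommend_bedtime",
    "adjust_time_in_bed",
    "initial_schedule",
    "schedule_next_week",
]

TIB_FLOOR = 300  # minutes; never prescribe less than 5 h in bed
TIB_CAP = 600  # minutes; reject degenerate (>10 h) prescriptions
TITRATION_STEP = 15  # minutes per weekly adjustment
_EXTRA_OVER_TST = 30  # minutes added to last week's mean TST

RESTRICTION_WEEKS = range(2, 5)


class TitrationError(ValueError):
    """Raised for degenerate or unusable titration inputs."""


@dataclass(frozen=True)
class SleepSchedule:
    """One participant-week sleep prescription.

    ``recommended_bed_time`` is the engine's suggestion; ``set_bed_time``
    is what the participant actually set (simulation makes them equal up
    to optional jitter).  ``prescribed_time_in_bed`` is the titrated
    allowance the weekly +/-15-minute rule acts on.
    """

    participant_id: str
    week_index: int
    desired_wake_time: ClockTime
    recommended_bed_time: ClockTime
    set_bed_time: ClockTime
    prescribed_time_in_bed: int

    def __post_init__(self) -> None:
        if not TIB_FLOOR <= self.prescribed_time_in_bed <= TIB_CAP:
            raise TitrationError(
                f"prescribed time in bed {self.prescribed_time_in_bed} min outside "
                f"[{TIB_FLOOR}, {TIB_CAP}]"
            )


def _clamp_tib(tib: float) -> int:
    """Apply the floor (clamp) and cap (reject) to a candidate prescription."""
    if tib > TIB_CAP:
        raise TitrationError(
            f"candidate time in bed {tib:.0f} min exceeds the {TIB_CAP}-min cap"
        )
    return max(TIB_FLOOR, int(round(tib)))


def recommend_bedtime(desired_wake: ClockTime, prior_mean_tst: float) -> ClockTime:
    """Bedtime = desired wake time - (prior week's mean TST + 30 min), mod 24 h.

    Raises :class:`TitrationError` when the prior mean is missing (carry the
    previous schedule forward instead) or implies a prescription above the
    cap; prescriptions under the floor are lifted to the floor.
    """
    if prior_mean_tst is None:
        raise TitrationError(
            "no usable prior-week summary; carry the previous schedule forward"
        )
    if prior_mean_tst <= 0:
        raise TitrationError(f"prior mean TST must be positive, got {prior_mean_tst}")
    tib = _clamp_tib(prior_mean_tst + _EXTRA_OVER_TST)
    return desired_wake.sub(tib)


def adjust_time_in_bed(weekly_se: float) -> int:
    """Weekly time-in-bed delta from mean sleep efficiency (percent)."""
    if not 0 <= weekly_se <= 100:
        raise TitrationError(f"sleep efficiency must be in [0, 100], got {weekly_se}")
    if weekly_se > 90:
        return TITRATION_STEP
    if weekly_se < 85:
        return -TITRATION_STEP
    return 0


def initial_schedule(summary: WeeklySummary, desired_wake: ClockTime) -> SleepSchedule:
    """Week-2 schedule seeded from the week-1 (baseline) diary.

    The first prescription is simply last week's mean TST + 30 minutes,
    clamped; titration proper starts the following week.
    """
    if not summary.adherent or summary.mean_total_sleep_time is None:
        raise TitrationError("week-1 diary not adherent; cannot seed a schedule")
    tib = _clamp_tib(summary.mean_total_sleep_time + _EXTRA_OVER_TST)
    bed = desired_wake.sub(tib)
    return SleepSchedule(
        participant_id=summary.participant_id,
        week_index=2,
        desired_wake_time=desired_wake,
        recommended_bed_time=bed,
        set_bed_time=bed,
        prescribed_time_in_bed=tib,
    )


def schedule_next_week(
    summary: WeeklySummary,
    desired_wake: ClockTime,
    current: SleepSchedule,
) -> SleepSchedule:
    """Titrate ``current`` into the next week's schedule.

    A non-adherent week (too few diary days) carries the current schedule
    forward unchanged apart from the week index.  Otherwise the prescribed
    time in bed moves by the +/-15-minute rule (clamped to the floor) and
    the bedtime is re-anchored to the desired wake time.
    """
    next_week = current.week_index + 1
    if not 2 <= next_week <= 4:
        raise TitrationError(f"titration runs in weeks 2-4, not week {next_week}")
    if not summary.adherent or summary.mean_sleep_efficiency is None:
        return replace(current, week_index=next_week, desired_wake_time=desired_wake)
    delta = adjust_time_in_bed(summary.mean_sleep_efficiency)
    new_tib = max(TIB_FLOOR, min(TIB_CAP, current.prescribed_time_in_bed + delta))
    bed = desired_wake.sub(new_tib)
    rec_bed = (
        recommend_bedtime(desired_wake, summary.mean_total_sleep_time)
        if summary.mean_total_sleep_time
        else bed
    )
    return SleepSchedule(
        participant_id=current.participant_id,
        week_index=next_week,
        desired_wake_time=desired_wake,
        recommended_bed_time=rec_bed,
        set_bed_time=bed,
        prescribed_time_in_bed=new_tib,
    )


# ---------------------------------------------------------------------------
# schedule I/O

def schedules_to_frame(schedules) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "week_index": s.week_index,
                "desired_wake": str(s.desired_wake_time),
                "recommended_bed": str(s.recommended_bed_time),
                "set_bed": str(s.set_bed_time),
                "prescribed_tib": s.prescribed_time_in_bed,
            }
            for s in schedules
        ]
    )


def frame_to_schedules(df) -> list[SleepSchedule]:
    return [
        SleepSchedule(
            participant_id=str(r["participant_id"]),
            week_index=int(r["week_index"]),
            desired_wake_time=ClockTime.parse(r["desired_wake"]),
            recommended_bed_time=ClockTime.parse(r["recommended_bed"]),
            set_bed_time=ClockTime.parse(r["set_bed"]),
            prescribed_time_in_bed=int(r["prescribed_tib"]),
        )
        for r in df.to_dict("records")
    ]
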