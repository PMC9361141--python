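"""Daily sleep diaries and the derived sleep variables.

The diary is the anchor of the whole intervention: each participant-day
records ten items (bedtime, sleep-onset latency, awakenings, final
awakening, bed-out latency, naps, daytime sleepiness times, pre-bed
behaviors, holiday flag), and from those the engine derives

    time in bed  (TIB) = final arising time - time of going to bed,
    total sleep time (TST) = TIB - SOL - WASO - bed-out latency,
    sleep efficiency (SE)  = 100 * TST / TIB,

where the final arising time is the final awakening time plus the bed-out
latency.  All arithmetic is in integer minutes; clock times carry no date,
so an arising clock at or before the bed clock is read as crossing
midnight (one added day, +1440 min).

Naps and sleepiness times are recorded and exported but never enter
TIB/TST/SE; they are state the prompt engine may condition on.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ClockTime",
    "DiaryEntry",
    "DailyMetrics",
    "WeeklySummary",
    "DiaryValidationError",
    "time_in_bed",
    "total_sleep_time",
    "sleep_efficiency",
    "daily_metrics",
    "summarize_week",
    "metrics_table",
    "read_diary_csv",
    "write_diary_csv",
    "read_diary_json",
    "write_diary_json",
    "MIN_ADHERENT_ENTRIES",
]

MINUTES_PER_DAY = 1440

#: Minimum diary entries in a week for its means to drive titration.
MIN_ADHERENT_ENTRIES = 3

_HHMM = re.compile(r"^(\d{1,2}):(\d{2})$")


class DiaryValidationError(ValueError):
    """Raised for internally inconsistent or out-of-range diary data."""


@dataclass(frozen=True, order=True)
class ClockTime:
    """A wall-clock time as integer minutes since midnight, in [0, 1440).

    Values are reduced modulo 1440 on construction, so arithmetic helpers
    can be chained freely; ``parse``/``str`` round-trip the "HH:MM" form.
    """

    minutes: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "minutes", int(self.minutes) % MINUTES_PER_DAY)

    @classmethod
    def parse(cls, text: str) -> "ClockTime":
        m = _HHMM.match(str(text).strip())
        if not m:
            raise DiaryValidationError(f"not a HH:MM clock time: {text!r}")
        hh, mm = int(m.group(1)), int(m.group(2))
        if hh >= 24 or mm >= 60:
            raise DiaryValidationError(f"clock time out of range: {text!r}")
        return cls(hh * 60 + mm)

    def add(self, minutes: int) -> "ClockTime":
        return ClockTime(self.minutes + minutes)

    def sub(self, minutes: int) -> "ClockTime":
        return ClockTime(self.minutes - minutes)

    def __str__(self) -> str:
        return f"{self.minutes // 60:02d}:{self.minutes % 60:02d}"


@dataclass(frozen=True)
class DiaryEntry:
    """One participant-day of the ten diary items."""

    participant_id: str
    date: _dt.date
    bed_time: ClockTime
    sleep_onset_latency: int
    n_awakenings: int
    awakening_duration: int  # wake after sleep onset (WASO), minutes
    final_awakening_time: ClockTime
    bed_out_latency: int
    nap_duration: int = 0
    sleepiness_times: tuple[ClockTime, ...] = ()
    alcohol: bool = False
    caffeine: bool = False
    smoking: bool = False
    hypnotic_use: bool = False
    is_holiday: bool = False

    def __post_init__(self) -> None:
        for name in (
            "sleep_onset_latency",
            "n_awakenings",
            "awakening_duration",
            "bed_out_latency",
            "nap_duration",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise DiaryValidationError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_awakenings == 0 and self.awakening_duration > 0:
            raise DiaryValidationError(
                "awakening_duration > 0 with n_awakenings == 0 is inconsistent"
            )
        object.__setattr__(self, "sleepiness_times", tuple(self.sleepiness_times))

    @property
    def final_arising_time(self) -> ClockTime:
        """Final awakening plus bed-out latency (when the bed is left)."""
        return self.final_awakening_time.add(self.bed_out_latency)


@dataclass(frozen=True)
class DailyMetrics:
    """Derived sleep variables for one diary day.

    Satisfies the conservation identity
    ``time_in_bed == total_sleep_time + SOL + WASO + bed-out latency``.
    """

    time_in_bed: int
    total_sleep_time: int
    sleep_efficiency: float  # percent, full precision; round at presentation


@dataclass(frozen=True)
class WeeklySummary:
    """Per-week diary aggregate feeding the sleep-restriction titration."""

    participant_id: str
    week_index: int
    n_entries: int
    mean_total_sleep_time: float | None
    mean_sleep_efficiency: float | None
    adherent: bool


def time_in_bed(entry: DiaryEntry) -> int:
    """Minutes from getting into bed to finally leaving it.

    The diary stores clock times only, so the interval is resolved by the
    wrap rule: an arising clock at or before the bed clock means the night
    crossed midnight and 1440 minutes are added.  A zero-length interval is
    rejected (it would poison the sleep-efficiency ratio downstream).
    """
    raw = entry.final_arising_time.minutes - entry.bed_time.minutes
    if raw <= 0:
        raw += MINUTES_PER_DAY
    if raw == MINUTES_PER_DAY and entry.final_arising_time == entry.bed_time:
        raise DiaryValidationError(
            f"zero-length bed interval on {entry.date} for {entry.participant_id}"
        )
    return raw


def total_sleep_time(entry: DiaryEntry) -> int:
    """TIB minus sleep-onset latency, WASO and bed-out latency, in minutes."""
    tib = time_in_bed(entry)
    tst = tib - entry.sleep_onset_latency - entry.awakening_duration - entry.bed_out_latency
    if tst < 0:
        raise DiaryValidationError(
            f"inconsistent diary on {entry.date}: SOL+WASO+bed-out latency "
            f"({tib - tst} min) exceed time in bed ({tib} min)"
        )
    return tst


def sleep_efficiency(entry: DiaryEntry) -> float:
    """Percentage of the bed interval spent asleep, in [0, 100]."""
    tib = time_in_bed(entry)
    return 100.0 * total_sleep_time(entry) / tib


def daily_metrics(entry: DiaryEntry) -> DailyMetrics:
    tib = time_in_bed(entry)
    tst = total_sleep_time(entry)
    return DailyMetrics(time_in_bed=tib, total_sleep_time=tst, sleep_efficiency=100.0 * tst / tib)


def summarize_week(
    entries: Sequence[DiaryEntry],
    week_index: int,
    *,
    min_entries: int = MIN_ADHERENT_ENTRIES,
) -> WeeklySummary:
    """Aggregate one participant's 7-day window of diary entries.

    Means are taken over the entries actually present; with fewer than
    ``min_entries`` days (default 3) the week is flagged non-adherent and
    the titration carries the previous schedule forward.
    """
    entries = list(entries)
    if len(entries) > 7:
        raise DiaryValidationError("a weekly window holds at most 7 entries")
    pids = {e.participant_id for e in entries}
    if len(pids) > 1:
        raise DiaryValidationError(f"entries from multiple participants: {sorted(pids)}")
    if not entries:
        return WeeklySummary("", week_index, 0, None, None, False)
    tsts = [total_sleep_time(e) for e in entries]
    ses = [sleep_efficiency(e) for e in entries]
    return WeeklySummary(
        participant_id=entries[0].participant_id,
        week_index=week_index,
        n_entries=len(entries),
        mean_total_sleep_time=sum(tsts) / len(tsts),
        mean_sleep_efficiency=sum(ses) / len(ses),
        adherent=len(entries) >= min_entries,
    )


# ---------------------------------------------------------------------------
# tabular I/O: CSV one row per participant-day, clocks "HH:MM", ISO dates

_FLAGS = ("alcohol", "caffeine", "smoking", "hypnotic_use")

_COLUMNS = [
    "participant_id",
    "date",
    "is_holiday",
    "bed_time",
    "sleep_onset_latency",
    "n_awakenings",
    "awakening_duration",
    "final_awakening_time",
    "bed_out_latency",
    "nap_duration",
    "sleepiness_times",
    *_FLAGS,
]


def _entry_to_record(e: DiaryEntry) -> dict:
    rec = {
        "participant_id": e.participant_id,
        "date": e.date.isoformat(),
        "is_holiday": int(e.is_holiday),
        "bed_time": str(e.bed_time),
        "sleep_onset_latency": e.sleep_onset_latency,
        "n_awakenings": e.n_awakenings,
        "awakening_duration": e.awakening_duration,
        "final_awakening_time": str(e.final_awakening_time),
        "bed_out_latency": e.bed_out_latency,
        "nap_duration": e.nap_duration,
        "sleepiness_times": ";".join(str(t) for t in e.sleepiness_times),
    }
    for f in _FLAGS:
        rec[f] = int(getattr(e, f))
    return rec


def _record_to_entry(rec: dict) -> DiaryEntry:
    missing = [c for c in _COLUMNS if c not in rec or pd.isna(rec[c])]
    # sleepiness_times may be legitimately empty; everything else is strict
    missing = [c for c in missing if c != "sleepiness_times"]
    if missing:
        raise DiaryValidationError(f"diary record missing fields: {missing}")
    raw_times = rec.get("sleepiness_times")
    times: tuple[ClockTime, ...] = ()
    if isinstance(raw_times, str) and raw_times.strip():
        times = tuple(ClockTime.parse(t) for t in raw_times.split(";"))
    return DiaryEntry(
        participant_id=str(rec["participant_id"]),
        date=_dt.date.fromisoformat(str(rec["date"])),
        is_holiday=bool(int(rec["is_holiday"])),
        bed_time=ClockTime.parse(rec["bed_time"]),
        sleep_onset_latency=int(rec["sleep_onset_latency"]),
        n_awakenings=int(rec["n_awakenings"]),
        awakening_duration=int(rec["awakening_duration"]),
        final_awakening_time=ClockTime.parse(rec["final_awakening_time"]),
        bed_out_latency=int(rec["bed_out_latency"]),
        nap_duration=int(rec["nap_duration"]),
        sleepiness_times=times,
        **{f: bool(int(rec[f])) for f in _FLAGS},
    )


def entries_to_frame(entries: Iterable[DiaryEntry]) -> pd.DataFrame:
    return pd.DataFrame([_entry_to_record(e) for e in entries], columns=_COLUMNS)


def frame_to_entries(df: pd.DataFrame) -> list[DiaryEntry]:
    return [_record_to_entry(rec) for rec in df.to_dict("records")]


def write_diary_csv(entries: Iterable[DiaryEntry], path) -> None:
    entries_to_frame(entries).to_csv(path, index=False)


def read_diary_csv(path) -> list[DiaryEntry]:
    return frame_to_entries(pd.read_csv(path, dtype=str))


def write_diary_json(entries: Iterable[DiaryEntry], path) -> None:
    records = [_entry_to_record(e) for e in entries]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=1)


def read_diary_json(path) -> list[DiaryEntry]:
    with open(path, encoding="utf-8") as fh:
        return [_record_to_entry(rec) for rec in json.load(fh)]


def metrics_table(entries: Sequence[DiaryEntry]) -> pd.DataFrame:
    """Tidy per-day table of the derived variables (the app's numeric view)."""
    rows = []
    for e in entries:
        m = daily_metrics(e)
        rows.append(
            {
                "participant_id": e.participant_id,
                "date": e.date.isoformat(),
                "time_in_bed": m.time_in_bed,
                "total_sleep_time": m.total_sleep_time,
                "sleep_efficiency": round(m.sleep_efficiency, 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "date", "time_in_bed", "total_sleep_time", "sleep_efficiency"],
    )
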