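"""Rule-based selection and scheduling of personalized prompt messages.

A prompt catalog holds short behavioral-change messages, each tagged with
a category (diary feedback, praise, sleep hygiene, stimulus control,
sleep restriction), one or more of four daily delivery slots (after
waking, around noon, evening, before bedtime), a priority, and a firing
condition — a small declarative predicate over participant state (diary
metrics, ISI, lifestyle habits, current schedule, adherence streak).

Program phase gates the categories: hygiene, diary feedback and praise
run in weeks 1-4; stimulus-control and sleep-restriction messages start
in week 2.  Delivery times are the slot anchors moved into the nearest
of the participant's stated receptive-time windows.  The engine is a pure
function of (catalog, state stream, delivery log): replaying the same
inputs yields the identical 28-day plan.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .diary import ClockTime, DiaryEntry, MINUTES_PER_DAY, daily_metrics
from .titration import SleepSchedule

__all__ = [
    "CATEGORIES",
    "SLOTS",
    "COOLDOWN_DAYS",
    "DAILY_CAP",
    "PRAISE_STREAK",
    "PromptRule",
    "PromptMessage",
    "ParticipantState",
    "DeliveryPlan",
    "phase_active",
    "eligible_messages",
    "select_message",
    "schedule_day",
    "run_program",
    "load_catalog",
    "save_catalog",
    "plans_to_frame",
]

CATEGORIES = ("diary_feedback", "praise", "hygiene", "stimulus_control", "restriction")
SLOTS = ("after_waking", "around_noon", "evening", "before_bedtime")

#: earliest active program week per category (program weeks are 1..4)
_PHASE_START = {
    "diary_feedback": 1,
    "praise": 1,
    "hygiene": 1,
    "stimulus_control": 2,
    "restriction": 2,
}

COOLDOWN_DAYS = 7  # a message is not repeated within this many days
DAILY_CAP = 4  # at most one message per slot
PRAISE_STREAK = 3  # consecutive diary days that trigger a praise message

_DEFAULT_ANCHORS = {"after_waking": "07:30", "around_noon": "12:00",
                    "evening": "18:00", "before_bedtime": "22:30"}


# ---------------------------------------------------------------------------
# rule language

_COMPARATORS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "in": lambda a, b: a in b,
    "is_true": lambda a, b: bool(a),
    "is_false": lambda a, b: not bool(a),
}


@dataclass(frozen=True)
class PromptRule:
    """A declarative, side-effect-free firing condition.

    ``predicate`` is a nested mapping: ``{"always": true}``, a comparison
    ``{"field": ..., "op": ..., "value": ...}``, or a boolean combinator
    ``{"all"|"any": [...]}`` / ``{"not": {...}}``.  Comparisons on state
    fields that are unavailable (e.g. no diary yet) evaluate to false, so
    every predicate is total over valid states; there is no general code
    execution.
    """

    rule_id: str
    predicate: Mapping
    priority: int = 0

    def evaluate(self, state: "ParticipantState") -> bool:
        return _eval_predicate(self.predicate, state)


def _eval_predicate(node: Mapping, state: "ParticipantState") -> bool:
    if "always" in node:
        return bool(node["always"])
    if "all" in node:
        return all(_eval_predicate(p, state) for p in node["all"])
    if "any" in node:
        return any(_eval_predicate(p, state) for p in node["any"])
    if "not" in node:
        return not _eval_predicate(node["not"], state)
    if "field" in node:
        op = node.get("op")
        if op not in _COMPARATORS:
            raise ValueError(f"unknown comparator {op!r}")
        value = state.resolve(node["field"])
        if value is None:
            return False
        try:
            return bool(_COMPARATORS[op](value, node.get("value")))
        except TypeError:
            return False
    raise ValueError(f"malformed predicate node: {node!r}")


@dataclass(frozen=True)
class PromptMessage:
    message_id: str
    category: str
    topic: str
    text: str
    slots: tuple[str, ...]
    rule: PromptRule

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.slots:
            raise ValueError(f"message {self.message_id} has no delivery slot")
        bad = set(self.slots) - set(SLOTS)
        if bad:
            raise ValueError(f"unknown slots {sorted(bad)} on {self.message_id}")


@dataclass
class ParticipantState:
    """Everything the rule engine may condition on for one participant-day."""

    participant_id: str
    sex: str
    age: int
    current_isi: int
    habits: Mapping[str, bool] = field(default_factory=dict)
    receptive_windows: Sequence[tuple[ClockTime, ClockTime]] = ()
    diary_history: Sequence[DiaryEntry] = ()
    schedule: Optional[SleepSchedule] = None
    study_day: int = 1
    adherence_streak: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.study_day <= 28:
            raise ValueError(f"study_day must be in 1..28, got {self.study_day}")
        ivs = sorted(self.receptive_windows, key=lambda w: w[0].minutes)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2.minutes < e1.minutes:
                raise ValueError("receptive windows must not overlap")

    @property
    def study_week(self) -> int:
        return (self.study_day - 1) // 7 + 1

    def resolve(self, name: str):
        """Look up a rule field; None when the state cannot answer it."""
        if name.startswith("habits."):
            return bool(self.habits.get(name.split(".", 1)[1], False))
        simple = {
            "sex": self.sex,
            "age": self.age,
            "current_isi": self.current_isi,
            "study_day": self.study_day,
            "study_week": self.study_week,
            "adherence_streak": self.adherence_streak,
        }
        if name in simple:
            return simple[name]
        if name == "prescribed_tib":
            return self.schedule.prescribed_time_in_bed if self.schedule else None
        last = self.diary_history[-1] if self.diary_history else None
        if name.startswith("last_") and last is None:
            return None
        if name == "last_se":
            return daily_metrics(last).sleep_efficiency
        if name == "last_tst":
            return daily_metrics(last).total_sleep_time
        if name == "last_sol":
            return last.sleep_onset_latency
        if name == "last_waso":
            return last.awakening_duration
        if name == "last_nap":
            return last.nap_duration
        if name in ("last_alcohol", "last_caffeine", "last_smoking", "last_hypnotic_use"):
            return getattr(last, name.removeprefix("last_"))
        if name == "weekly_se":
            week = [e for e in self.diary_history][-7:]
            if not week:
                return None
            return sum(daily_metrics(e).sleep_efficiency for e in week) / len(week)
        if name == "weekly_tst":
            week = [e for e in self.diary_history][-7:]
            if not week:
                return None
            return sum(daily_metrics(e).total_sleep_time for e in week) / len(week)
        raise ValueError(f"unknown rule field {name!r}")


@dataclass(frozen=True)
class DeliveryPlan:
    """The messages scheduled for one participant-day."""

    date: _dt.date
    items: tuple[tuple[ClockTime, str], ...]  # (delivery time, message_id)


# ---------------------------------------------------------------------------
# engine

def phase_active(category: str, study_week: int) -> bool:
    """Whether a message category is active in the given program week."""
    if category not in _PHASE_START:
        raise ValueError(f"unknown category {category!r}")
    if not 1 <= study_week <= 4:
        raise ValueError(f"study_week must be in 1..4, got {study_week}")
    return study_week >= _PHASE_START[category]


def eligible_messages(
    catalog: Sequence[PromptMessage], state: ParticipantState, slot: str
) -> list[PromptMessage]:
    """Catalog entries matching the slot, active phase and a true predicate."""
    if slot not in SLOTS:
        raise ValueError(f"unknown slot {slot!r}")
    return [
        m
        for m in catalog
        if slot in m.slots
        and phase_active(m.category, state.study_week)
        and m.rule.evaluate(state)
    ]


def select_message(
    eligible: Sequence[PromptMessage], history: Sequence[str]
) -> Optional[PromptMessage]:
    """Deterministic pick: highest priority, then least recently sent, then id.

    ``history`` lists previously sent message ids oldest first; a message
    never sent sorts before any sent one at equal priority.
    """
    if not eligible:
        return None
    last_index = {mid: i for i, mid in enumerate(history)}
    return min(
        eligible,
        key=lambda m: (-m.rule.priority, last_index.get(m.message_id, -1), m.message_id),
    )


def _circular_distance(a: int, b: int) -> int:
    d = abs(a - b) % MINUTES_PER_DAY
    return min(d, MINUTES_PER_DAY - d)


def slot_anchor(slot: str, state: ParticipantState) -> ClockTime:
    """The nominal delivery clock for a slot, personalized where possible.

    After-waking follows the last diary's final arising time + 30 min;
    before-bedtime sits 60 min ahead of the currently set bedtime; noon
    and evening are fixed at 12:00 and 18:00.
    """
    if slot == "after_waking" and state.diary_history:
        return state.diary_history[-1].final_arising_time.add(30)
    if slot == "before_bedtime" and state.schedule is not None:
        return state.schedule.set_bed_time.sub(60)
    return ClockTime.parse(_DEFAULT_ANCHORS[slot])


def _into_receptive_window(anchor: ClockTime, state: ParticipantState) -> ClockTime:
    """Move an anchor into the nearest receptive window (fallback: anchor)."""
    windows = list(state.receptive_windows)
    if not windows:
        return anchor
    for start, end in windows:
        if start.minutes <= anchor.minutes <= end.minutes:
            return anchor
    best = min(
        (
            (min(_circular_distance(anchor.minutes, edge.minutes) for edge in w), w)
            for w in windows
        ),
        key=lambda t: t[0],
    )[1]
    start, end = best
    ds = _circular_distance(anchor.minutes, start.minutes)
    de = _circular_distance(anchor.minutes, end.minutes)
    return start if ds <= de else end


def schedule_day(
    catalog: Sequence[PromptMessage],
    state: ParticipantState,
    date: _dt.date,
    log: Sequence[tuple[_dt.date, str]] = (),
) -> DeliveryPlan:
    """Build one day's delivery plan: at most one message per slot.

    Messages sent within the 7-day cool-down are excluded, as is anything
    already placed in an earlier slot the same day.  Each delivery time is
    the slot anchor mapped into the nearest receptive window.
    """
    history = [mid for _, mid in log]
    cooled = {mid for d, mid in log if 0 <= (date - d).days < COOLDOWN_DAYS}
    items: list[tuple[ClockTime, str]] = []
    sent_today: set[str] = set()
    for slot in SLOTS:
        candidates = [
            m
            for m in eligible_messages(catalog, state, slot)
            if m.message_id not in cooled and m.message_id not in sent_today
        ]
        chosen = select_message(candidates, history)
        if chosen is None:
            continue
        items.append((_into_receptive_window(slot_anchor(slot, state), state), chosen.message_id))
        sent_today.add(chosen.message_id)
        if len(items) >= DAILY_CAP:
            break
    return DeliveryPlan(date=date, items=tuple(items))


def run_program(
    catalog: Sequence[PromptMessage],
    day_states: Sequence[tuple[_dt.date, ParticipantState]],
) -> tuple[list[DeliveryPlan], list[tuple[_dt.date, str]]]:
    """Replay a (typically 28-day) state stream through the engine.

    Returns the per-day plans and the cumulative delivery log; both are a
    pure function of the inputs.
    """
    log: list[tuple[_dt.date, str]] = []
    plans: list[DeliveryPlan] = []
    for date, state in day_states:
        plan = schedule_day(catalog, state, date, log)
        plans.append(plan)
        log.extend((date, mid) for _, mid in plan.items)
    return plans, log


# ---------------------------------------------------------------------------
# catalog and plan I/O

_CATALOG_COLUMNS = ["message_id", "category", "topic", "slots", "priority", "condition", "text"]


def save_catalog(catalog: Sequence[PromptMessage], path) -> None:
    rows = [
        {
            "message_id": m.message_id,
            "category": m.category,
            "topic": m.topic,
            "slots": "|".join(m.slots),
            "priority": m.rule.priority,
            "condition": json.dumps(m.rule.predicate, separators=(",", ":")),
            "text": m.text,
        }
        for m in catalog
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, index=False)


def load_catalog(path) -> list[PromptMessage]:
    df = pd.read_csv(path, dtype=str)
    missing = set(_CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog file missing columns: {sorted(missing)}")
    out = []
    for r in df.to_dict("records"):
        out.append(
            PromptMessage(
                message_id=r["message_id"],
                category=r["category"],
                topic=r["topic"],
                text=r["text"],
                slots=tuple(r["slots"].split("|")),
                rule=PromptRule(
                    rule_id=f"rule:{r['message_id']}",
                    predicate=json.loads(r["condition"]),
                    priority=int(r["priority"]),
                ),
            )
        )
    return out


def plans_to_frame(
    participant_id: str, plans: Sequence[DeliveryPlan], catalog: Sequence[PromptMessage]
) -> pd.DataFrame:
    cat = {m.message_id: m.category for m in catalog}
    rows = [
        {
            "participant_id": participant_id,
            "date": p.date.isoformat(),
            "time": str(t),
            "message_id": mid,
            "category": cat.get(mid, ""),
        }
        for p in plans
        for t, mid in p.items
    ]
    return pd.DataFrame(rows, columns=["participant_id", "date", "time", "message_id", "category"])
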