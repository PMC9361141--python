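"""A representative seed catalog of prompt messages.

The production intervention used a far larger, clinician-authored message
bank; what is reproducible is the catalog schema and the selection
engine, so this module ships ~40 representative messages spanning the
five categories (diary feedback, praise, sleep hygiene, stimulus
control, sleep restriction) and the classic hygiene topics (daily
rhythm, light, sound, temperature, diet, exercise, bathing, alcohol,
smoking, caffeine, sleep duration, napping, emotional distress).  Users
load a full catalog from CSV via :func:`sleepprompt.prompts.load_catalog`
with the same schema.
"""

from __future__ import annotations

from .prompts import PRAISE_STREAK, PromptMessage, PromptRule

__all__ = ["seed_catalog"]


def _msg(mid, category, topic, slots, text, predicate=None, priority=0):
    return PromptMessage(
        message_id=mid,
        category=category,
        topic=topic,
        text=text,
        slots=tuple(slots),
        rule=PromptRule(rule_id=f"rule:{mid}", predicate=predicate or {"always": True},
                        priority=priority),
    )


def seed_catalog() -> list[PromptMessage]:
    """Build the built-in message catalog (deterministic, no I/O)."""
    m = _msg
    return [
        # -- diary feedback ------------------------------------------------
        m("DF01", "diary_feedback", "diary", ["after_waking"],
          "Good morning! Take a minute to fill in last night's sleep diary."),
        m("DF02", "diary_feedback", "efficiency", ["after_waking"],
          "Your sleep efficiency yesterday was above 90% - a very solid night.",
          {"field": "last_se", "op": "gt", "value": 90}, priority=2),
        m("DF03", "diary_feedback", "efficiency", ["after_waking"],
          "Last night's sleep efficiency dipped below 85%. Tonight, head to bed "
          "only when sleepy.",
          {"field": "last_se", "op": "lt", "value": 85}, priority=2),
        m("DF04", "diary_feedback", "duration", ["around_noon"],
          "Your diary shows under 6 hours of sleep last night. Guard your wind-down "
          "time tonight.",
          {"field": "last_tst", "op": "lt", "value": 360}, priority=1),
        m("DF05", "diary_feedback", "onset", ["evening"],
          "Falling asleep took over 30 minutes yesterday. A fixed pre-bed routine "
          "can shorten it.",
          {"field": "last_sol", "op": "gt", "value": 30}, priority=1),
        m("DF06", "diary_feedback", "waso", ["evening"],
          "You logged a long time awake during the night. Keep the bedroom dark "
          "and clocks out of sight.",
          {"field": "last_waso", "op": "gt", "value": 30}, priority=1),
        # -- praise --------------------------------------------------------
        m("PR01", "praise", "streak", ["around_noon"],
          "Great consistency - you have filled in your sleep diary several days "
          "running. Keep it up!",
          {"field": "adherence_streak", "op": "ge", "value": PRAISE_STREAK}, priority=3),
        m("PR02", "praise", "streak", ["evening"],
          "A full week of diary entries - excellent work. Your data make the "
          "advice sharper.",
          {"field": "adherence_streak", "op": "ge", "value": 7}, priority=3),
        m("PR03", "praise", "efficiency", ["after_waking"],
          "Two things to celebrate: a completed diary and sleep efficiency over "
          "90% last night.",
          {"all": [{"field": "adherence_streak", "op": "ge", "value": PRAISE_STREAK},
                   {"field": "last_se", "op": "gt", "value": 90}]}, priority=4),
        m("PR04", "praise", "schedule", ["before_bedtime"],
          "You have been keeping to your set bedtime - that regularity is what "
          "retrains your sleep.",
          {"field": "adherence_streak", "op": "ge", "value": 5}, priority=2),
        # -- sleep hygiene -------------------------------------------------
        m("HY01", "hygiene", "daily_rhythm", ["after_waking"],
          "Get up at about the same time every day, weekends included - the wake "
          "time sets your body clock."),
        m("HY02", "hygiene", "light", ["after_waking"],
          "Open the curtains or step outside soon after waking; morning light "
          "anchors your rhythm."),
        m("HY03", "hygiene", "light", ["before_bedtime"],
          "Dim the lights and put screens away in the hour before bed."),
        m("HY04", "hygiene", "sound", ["before_bedtime"],
          "A quiet bedroom helps: consider earplugs or masking noise if your "
          "street is loud."),
        m("HY05", "hygiene", "temperature", ["evening"],
          "Keep the bedroom on the cool side; a hot room fragments sleep."),
        m("HY06", "hygiene", "diet", ["evening"],
          "Finish dinner at least 2-3 hours before bedtime; heavy late meals "
          "disturb sleep."),
        m("HY07", "hygiene", "exercise", ["around_noon"],
          "Regular daytime exercise deepens sleep - even a brisk walk counts."),
        m("HY08", "hygiene", "exercise", ["evening"],
          "Avoid vigorous exercise within 2 hours of bedtime; wind down instead."),
        m("HY09", "hygiene", "bathing", ["evening"],
          "A warm bath 1-2 hours before bed helps your body cool into sleep."),
        m("HY10", "hygiene", "alcohol", ["evening"],
          "Alcohol may bring sleep on but breaks it up later - skip the nightcap.",
          {"any": [{"field": "habits.alcohol", "op": "is_true"},
                   {"field": "last_alcohol", "op": "is_true"}]}, priority=1),
        m("HY11", "hygiene", "smoking", ["before_bedtime"],
          "Nicotine is a stimulant; avoid smoking in the hours before bed.",
          {"field": "habits.smoking", "op": "is_true"}, priority=1),
        m("HY12", "hygiene", "caffeine", ["around_noon"],
          "Caffeine lingers 5-7 hours: make this your last coffee of the day.",
          {"any": [{"field": "habits.caffeine", "op": "is_true"},
                   {"field": "last_caffeine", "op": "is_true"}]}, priority=1),
        m("HY13", "hygiene", "caffeine", ["evening"],
          "An evening coffee or strong tea can cost you sleep tonight - try a "
          "caffeine-free drink.",
          {"any": [{"field": "habits.caffeine", "op": "is_true"},
                   {"field": "last_caffeine", "op": "is_true"}]}, priority=1),
        m("HY14", "hygiene", "sleep_duration", ["around_noon"],
          "Sleep need varies; daytime alertness, not hours in bed, is the best "
          "gauge of enough sleep."),
        m("HY15", "hygiene", "napping", ["around_noon"],
          "If you nap, keep it before 3 pm and under 30 minutes.",
          {"field": "last_nap", "op": "gt", "value": 30}, priority=1),
        m("HY16", "hygiene", "emotional_distress", ["evening"],
          "Set aside a brief 'worry time' early in the evening so concerns do "
          "not follow you to bed."),
        m("HY17", "hygiene", "hypnotics", ["evening"],
          "If you use sleeping pills or alcohol as a sleep aid, discuss a plan "
          "with your physician rather than stopping abruptly.",
          {"any": [{"field": "habits.hypnotic_use", "op": "is_true"},
                   {"field": "last_hypnotic_use", "op": "is_true"}]}, priority=1),
        m("HY18", "hygiene", "daily_rhythm", ["evening"],
          "Keep pre-bed routines in the same order each night; ritual is a cue "
          "for sleep."),
        # -- stimulus control (weeks 2-4) ----------------------------------
        m("SC01", "stimulus_control", "bed_sleep_only", ["before_bedtime"],
          "Use the bed only for sleep: no phone, work, or TV in bed."),
        m("SC02", "stimulus_control", "sleepy_only", ["before_bedtime"],
          "Go to bed only when you actually feel sleepy, not merely tired."),
        m("SC03", "stimulus_control", "leave_bed", ["before_bedtime"],
          "If you are awake in bed for around 15-20 minutes, get up, do "
          "something calm, and return only when sleepy.",
          {"field": "last_waso", "op": "gt", "value": 20}, priority=2),
        m("SC04", "stimulus_control", "fixed_wake", ["after_waking"],
          "Keep your alarm at the same time no matter how the night went."),
        m("SC05", "stimulus_control", "no_clockwatching", ["before_bedtime"],
          "Turn the clock face away - watching the minutes feeds wakefulness.",
          {"field": "last_sol", "op": "gt", "value": 20}, priority=1),
        m("SC06", "stimulus_control", "no_naps", ["around_noon"],
          "While retraining your sleep, skip daytime naps so pressure builds "
          "for tonight.",
          {"field": "last_nap", "op": "gt", "value": 0}, priority=1),
        # -- sleep restriction (weeks 2-4) ---------------------------------
        m("SR01", "restriction", "bedtime", ["before_bedtime"],
          "Your set bedtime is coming up - stay out of bed until then."),
        m("SR02", "restriction", "efficiency_up", ["evening"],
          "Last week's sleep efficiency was above 90%: you have earned 15 more "
          "minutes in bed.",
          {"field": "weekly_se", "op": "gt", "value": 90}, priority=2),
        m("SR03", "restriction", "efficiency_hold", ["evening"],
          "Sleep efficiency is in the 85-90% band - keep this week's schedule "
          "steady.",
          {"all": [{"field": "weekly_se", "op": "ge", "value": 85},
                   {"field": "weekly_se", "op": "le", "value": 90}]}, priority=2),
        m("SR04", "restriction", "efficiency_down", ["evening"],
          "Sleep efficiency fell below 85%; tightening time in bed by 15 minutes "
          "will consolidate your sleep.",
          {"field": "weekly_se", "op": "lt", "value": 85}, priority=2),
        m("SR05", "restriction", "wake_anchor", ["after_waking"],
          "Out of bed within a few minutes of your final awakening - long "
          "lie-ins dilute sleep efficiency.",
          {"field": "last_waso", "op": "ge", "value": 0}, priority=1),
        m("SR06", "restriction", "schedule", ["evening"],
          "Review tonight's schedule: bedtime follows your average sleep time "
          "plus 30 minutes, counted back from your wake-up time."),
    ]
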