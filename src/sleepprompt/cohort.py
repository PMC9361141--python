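"""Synthetic worker cohorts for exercising the intervention and trial code.

The generator emulates a 4-week, 2-arm trial in a working population
with mild insomnia: integer baseline ISI around 9.2, weekly ISI decline
that is steeper in the intervention (SPA) arm, realistic diary timing
distributions (late-evening bedtimes, lognormal sleep-onset latency,
occasional missing diary days), app-install dropout in the SPA arm, and
pre-post secondary outcomes (fatigue, presenteeism).

Weekly ISI follows a linear-trend random-intercept model

    isi[i, w] = b_i + w * (decline + arm_i * extra) + e[i, w]

with b_i ~ N(mean, intercept sd) and e ~ N(0, residual sd), rounded and
truncated to integers in [0, 28] — so the primary longitudinal model is
correctly specified by default (up to the rounding).  All randomness
flows from a single seed through named substreams, making every export
byte-identical under the same (config, seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .diary import ClockTime, DiaryEntry, summarize_week
from .instruments import ISIResponse
from .titration import (
    SleepSchedule,
    TitrationError,
    initial_schedule,
    schedule_next_week,
)
from .trial import ConsortEvents, EnrollmentRecord, stratified_block_randomize

__all__ = ["CohortConfig", "TrialData", "generate_cohort", "simulate_diary_stream",
           "simulate_trial", "isi_response_from_total"]

_STUDY_START = _dt.date(2021, 1, 4)  # fixed nominal start; dates are cosmetic

# substream ids off the user seed
_S_COHORT, _S_RANDOMIZE, _S_ISI, _S_DIARY, _S_SECONDARY, _S_DROPOUT = range(6)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the simulator.

    Defaults are calibrated to a mildly insomniac worker cohort: group
    mean ISI 9.2 at baseline declining to about 8.0 (control) and 6.8
    (intervention) by week 4, i.e. a control trend of -0.3 points/week
    and an extra -0.3 points/week under the intervention.
    """

    n_per_arm: int = 58
    baseline_isi_mean: float = 9.2
    baseline_isi_sd: float = 2.0  # between-participant intercept sd, points
    weekly_decline_control: float = -0.3  # points/week in the control arm
    extra_decline_spa: float = -0.3  # additional points/week under the app
    isi_noise_sd: float = 2.5  # residual sd, points
    bedtime_mean: str = "23:30"
    bedtime_sd: float = 40.0  # minutes
    wake_time_mean: str = "06:45"
    wake_time_sd: float = 25.0  # minutes
    sol_meanlog: float = 3.0  # lognormal sleep-onset latency, median ~20 min
    sol_sdlog: float = 0.6
    waso_mean: float = 20.0  # minutes
    waso_sd: float = 15.0
    diary_missing_rate: float = 0.10
    titration_response: float = 1.0  # SE percentage points gained per restriction week
    dropout_rate: float = 2 / 62  # app-install failures in the intervention arm
    female_fraction: float = 0.33
    age_mean: float = 40.6
    age_sd: float = 11.4

    def __post_init__(self) -> None:
        for name in ("diary_missing_rate", "dropout_rate", "female_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("baseline_isi_sd", "isi_noise_sd", "bedtime_sd", "wake_time_sd",
                     "waso_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be at least 2")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def isi_response_from_total(total: int, rng: np.random.Generator) -> ISIResponse:
    """Decompose an ISI total into a random valid 7-item response."""
    items = [0] * 7
    remaining = int(total)
    while remaining > 0:
        idx = [i for i in range(7) if items[i] < 4]
        items[int(rng.choice(idx))] += 1
        remaining -= 1
    return ISIResponse(items=tuple(items))


def generate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw the participant roster: demographics, habits, latent ISI intercept.

    ``baseline_isi`` is the observed week-0 ISI (latent intercept plus
    residual noise, rounded into [0, 28]); ``isi_intercept`` is the latent
    per-participant level that the weekly trajectories grow from.
    """
    rng = _rng(seed, _S_COHORT)
    n = 2 * config.n_per_arm
    intercept = rng.normal(config.baseline_isi_mean, config.baseline_isi_sd, n)
    baseline_noise = rng.normal(0.0, config.isi_noise_sd, n)
    baseline = np.clip(np.rint(intercept + baseline_noise), 0, 28).astype(int)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = np.clip(np.rint(rng.normal(config.age_mean, config.age_sd, n)), 20, 70).astype(int)
    # lifestyle habit prevalences typical of the target worker population
    habits = {
        "caffeine": rng.random(n) < 0.75,
        "alcohol": rng.random(n) < 0.70,
        "smoking": rng.random(n) < 0.06,
        "hypnotic_use": rng.random(n) < 0.05,
    }
    bed = [
        str(ClockTime.parse(config.bedtime_mean).add(int(d)))
        for d in np.rint(rng.normal(0, config.bedtime_sd, n))
    ]
    wake = [
        str(ClockTime.parse(config.wake_time_mean).add(int(d)))
        for d in np.rint(rng.normal(0, config.wake_time_sd, n))
    ]
    # one evening receptive window per participant, 3-4 h ending near bedtime
    windows = []
    for b in bed:
        end = ClockTime.parse(b).sub(int(rng.integers(15, 45)))
        start = end.sub(int(rng.integers(180, 240)))
        windows.append(f"{start}-{end}")
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "isi_intercept": intercept,
            "baseline_isi": baseline,
            "habit_caffeine": habits["caffeine"].astype(int),
            "habit_alcohol": habits["alcohol"].astype(int),
            "habit_smoking": habits["smoking"].astype(int),
            "habit_hypnotic_use": habits["hypnotic_use"].astype(int),
            "habitual_bedtime": bed,
            "habitual_wake": wake,
            "receptive_window": windows,
        }
    )


def _bounded_int(x: float, lo: int, hi: int) -> int:
    return int(min(hi, max(lo, round(x))))


def simulate_diary_stream(
    participant: pd.Series | dict,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    arm: str = "control",
) -> list[DiaryEntry]:
    """Simulate 28 diary days for one participant (with missing days).

    Control participants keep their habitual schedule throughout.  For
    intervention participants the weekly sleep-restriction titration is
    run on the accumulating diary (weeks 2-4): bedtime follows the
    prescribed schedule, and the waking overhead (SOL + WASO) shrinks by
    ``titration_response`` SE percentage points per active restriction
    week, emulating the consolidation the therapy aims for.
    """
    p = dict(participant)
    pid = str(p["participant_id"])
    habitual_bed = ClockTime.parse(p["habitual_bedtime"])
    wake = ClockTime.parse(p["habitual_wake"])
    entries: list[DiaryEntry] = []
    schedule: Optional[SleepSchedule] = None
    for week in range(1, 5):
        bed_target = schedule.set_bed_time if schedule is not None else habitual_bed
        week_entries: list[DiaryEntry] = []
        for day in range(7):
            date = _STUDY_START + _dt.timedelta(days=(week - 1) * 7 + day)
            if rng.random() < config.diary_missing_rate:
                continue
            bed = bed_target.add(int(rng.normal(0, 15)))
            arising = wake.add(int(rng.normal(0, 10)))
            if arising.minutes == bed.minutes:  # degenerate jitter collision
                bed = bed.sub(1)
            tib = (arising.minutes - bed.minutes) % 1440 or 1440
            sol = _bounded_int(rng.lognormal(config.sol_meanlog, config.sol_sdlog), 0, tib // 3)
            waso = _bounded_int(rng.normal(config.waso_mean, config.waso_sd), 0, tib // 3)
            bol = _bounded_int(rng.integers(2, 20), 0, tib // 6)
            if arm == "SPA" and week >= 2:
                # consolidation: shave SE points off the waking overhead
                cut = round(config.titration_response / 100.0 * tib * (week - 1))
                take = min(cut, waso)
                waso -= take
                sol = max(0, sol - (cut - take))
            # final arising = awakening + bed-out latency; keep arising fixed
            awakening = arising.sub(bol)
            n_wake = 0 if waso == 0 else 1 + int(rng.poisson(1.0))
            entry = DiaryEntry(
                participant_id=pid,
                date=date,
                is_holiday=date.weekday() >= 5,
                bed_time=bed,
                sleep_onset_latency=sol,
                n_awakenings=n_wake,
                awakening_duration=waso,
                final_awakening_time=awakening,
                bed_out_latency=bol,
                nap_duration=int(rng.integers(0, 40)) if rng.random() < 0.2 else 0,
                sleepiness_times=(ClockTime.parse("14:00"),) if rng.random() < 0.3 else (),
                alcohol=bool(p.get("habit_alcohol", 0)) and rng.random() < 0.3,
                caffeine=bool(p.get("habit_caffeine", 0)) and rng.random() < 0.8,
                smoking=bool(p.get("habit_smoking", 0)),
                hypnotic_use=bool(p.get("habit_hypnotic_use", 0)) and rng.random() < 0.5,
            )
            week_entries.append(entry)
        entries.extend(week_entries)
        if arm == "SPA" and week < 4:
            summary = summarize_week(week_entries, week)
            try:
                if schedule is None:
                    schedule = initial_schedule(summary, wake)
                else:
                    schedule = schedule_next_week(summary, wake, schedule)
            except TitrationError:
                pass  # non-adherent or degenerate week: keep current schedule
    return entries


@dataclass
class TrialData:
    """Everything one simulated trial produces, in analysis-ready form."""

    config: CohortConfig
    seed: int
    roster: pd.DataFrame  # + stratum, arm, block_index, dropout
    isi_long: pd.DataFrame  # participant_id, arm, week, isi (analyzed set)
    secondary: pd.DataFrame  # participant_id, arm, measure, baseline, posttest
    consort: ConsortEvents
    diaries: Optional[pd.DataFrame] = None

    def export(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.roster.to_csv(out / "roster.csv", index=False)
        self.isi_long.to_csv(out / "isi_long.csv", index=False)
        self.secondary.to_csv(out / "secondary.csv", index=False)
        if self.diaries is not None:
            self.diaries.to_csv(out / "diaries.csv", index=False)


#: Table-2-style pre-post behavior of the secondary measures:
#: (baseline mean, baseline sd, change mean SPA, change mean control, change sd)
_SECONDARY_SPECS = {
    "cfs_total": (16.0, 5.1, -2.2, -1.5, 4.5),
    "cfs_physical": (9.7, 3.8, -1.6, -1.5, 1.8),
    "cfs_psychological": (6.3, 1.9, -0.6, 0.0, 3.4),
    "absolute_presenteeism": (61.6, 16.0, 4.3, 3.2, 15.7),
    "relative_presenteeism": (0.94, 0.27, 0.03, 0.00, 0.30),
}


def simulate_trial(
    config: CohortConfig, seed: int, *, include_diaries: bool = True
) -> TrialData:
    """Run one full synthetic trial end to end.

    Generates the roster, randomizes it with the stratified permuted-block
    scheme, applies app-install dropout to the intervention arm, draws the
    weekly ISI stream from the linear-trend random-intercept model, draws
    pre-post secondary outcomes, and (optionally) simulates the 28-day
    diary of every analyzed participant, including the intervention arm's
    weekly titration.  Dropped participants contribute no outcome data and
    are excluded from the analysis set, exactly as the CONSORT flow counts
    them.
    """
    roster = generate_cohort(config, seed)
    records = [
        EnrollmentRecord(
            participant_id=r["participant_id"], sex=r["sex"], baseline_isi=int(r["baseline_isi"])
        )
        for _, r in roster.iterrows()
    ]
    rand_seed = int(_rng(seed, _S_RANDOMIZE).integers(2**31))
    allocation = stratified_block_randomize(records, seed=rand_seed)
    roster = roster.merge(
        allocation[["participant_id", "stratum", "arm", "block_index"]], on="participant_id"
    )
    drop_rng = _rng(seed, _S_DROPOUT)
    roster["dropout"] = (roster["arm"] == "SPA") & (
        drop_rng.random(len(roster)) < config.dropout_rate
    )
    analyzed = roster[~roster["dropout"]].reset_index(drop=True)

    isi_rng = _rng(seed, _S_ISI)
    rows = []
    slope = {
        "control": config.weekly_decline_control,
        "SPA": config.weekly_decline_control + config.extra_decline_spa,
    }
    for _, r in analyzed.iterrows():
        b = float(r["isi_intercept"])
        for week in range(5):
            if week == 0:
                isi = int(r["baseline_isi"])  # the screening measurement itself
            else:
                y = b + week * slope[r["arm"]] + isi_rng.normal(0, config.isi_noise_sd)
                isi = _bounded_int(y, 0, 28)
            rows.append(
                {
                    "participant_id": r["participant_id"],
                    "arm": r["arm"],
                    "week": week,
                    "isi": isi,
                }
            )
    isi_long = pd.DataFrame(rows)

    sec_rng = _rng(seed, _S_SECONDARY)
    sec_rows = []
    for _, r in analyzed.iterrows():
        for measure, (b_mean, b_sd, d_spa, d_ctl, d_sd) in _SECONDARY_SPECS.items():
            base = sec_rng.normal(b_mean, b_sd)
            delta = sec_rng.normal(d_spa if r["arm"] == "SPA" else d_ctl, d_sd)
            if measure.startswith("cfs"):
                hi = {"cfs_total": 33, "cfs_physical": 21, "cfs_psychological": 12}[measure]
                base_v: float = _bounded_int(base, 0, hi)
                post_v: float = _bounded_int(base + delta, 0, hi)
            elif measure == "absolute_presenteeism":
                base_v = 10 * _bounded_int(base / 10, 0, 10)
                post_v = 10 * _bounded_int((base + delta) / 10, 0, 10)
            else:
                base_v = float(np.clip(base, 0.25, 2.0))
                post_v = float(np.clip(base + delta, 0.25, 2.0))
            sec_rows.append(
                {
                    "participant_id": r["participant_id"],
                    "arm": r["arm"],
                    "measure": measure,
                    "baseline": base_v,
                    "posttest": post_v,
                }
            )
    secondary = pd.DataFrame(sec_rows)

    diaries = None
    if include_diaries:
        from .diary import entries_to_frame

        diary_rng = _rng(seed, _S_DIARY)
        all_entries = []
        for _, r in analyzed.iterrows():
            all_entries.extend(
                simulate_diary_stream(r, config, diary_rng, arm=str(r["arm"]))
            )
        diaries = entries_to_frame(all_entries)

    allocated = roster["arm"].value_counts().to_dict()
    dropped = roster[roster["dropout"]]["arm"].value_counts().to_dict()
    analyzed_counts = analyzed["arm"].value_counts().to_dict()
    consort = ConsortEvents(
        applied=len(roster),
        eligible=len(roster),
        allocated={a: int(allocated.get(a, 0)) for a in ("SPA", "control")},
        excluded_after_allocation={a: int(dropped.get(a, 0)) for a in ("SPA", "control")},
        analyzed={a: int(analyzed_counts.get(a, 0)) for a in ("SPA", "control")},
        exclusion_reasons={"SPA": "app install failure"},
    )
    return TrialData(
        config=config,
        seed=seed,
        roster=roster,
        isi_long=isi_long,
        secondary=secondary,
        consort=consort,
        diaries=diaries,
    )
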