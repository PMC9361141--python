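import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from sleepprompt.diary import (
    ClockTime,
    DiaryEntry,
    DiaryValidationError,
    daily_metrics,
    entries_to_frame,
    frame_to_entries,
    metrics_table,
    read_diary_csv,
    read_diary_json,
    sleep_efficiency,
    summarize_week,
    time_in_bed,
    total_sleep_time,
    write_diary_csv,
    write_diary_json,
)

from conftest import make_entry


class TestClockTime:
    @pytest.mark.parametrize("text", ["00:00", "06:45", "23:59", "12:00"])
    def test_parse_format_round_trip(self, text):
        assert str(ClockTime.parse(text)) == text

    def test_reduced_modulo_day(self):
        assert ClockTime(1440).minutes == 0
        assert ClockTime(-30).minutes == 1410
        assert ClockTime.parse("23:00").add(120) == ClockTime.parse("01:00")

    @pytest.mark.parametrize("bad", ["24:00", "7:60", "noon", "0700"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(DiaryValidationError):
            ClockTime.parse(bad)


class TestTimeInBed:
    @pytest.mark.parametrize(
        "bed,awakening,bol,expected",
        [
            ("23:30", "06:45", 15, 450),  # wraps midnight
            ("00:00", "08:00", 0, 480),  # no wrap
            ("22:00", "09:30", 30, 720),
        ],
    )
    def test_examples(self, bed, awakening, bol, expected):
        e = make_entry(bed=bed, awakening=awakening, bol=bol, sol=0, waso=0, n_awakenings=0)
        assert time_in_bed(e) == expected

    def test_zero_interval_rejected(self):
        e = make_entry(bed="22:00", awakening="22:00", bol=0, sol=0, waso=0, n_awakenings=0)
        with pytest.raises(DiaryValidationError):
            time_in_bed(e)


class TestDerivedVariables:
    def test_total_sleep_time_formula(self, entry):
        # TIB 450, SOL 20, WASO 25, bed-out 15
        assert time_in_bed(entry) == 450
        assert total_sleep_time(entry) == 390

    def test_tst_equals_tib_when_latencies_zero(self):
        e = make_entry(sol=0, waso=0, bol=0, n_awakenings=0)
        assert total_sleep_time(e) == time_in_bed(e)

    def test_inconsistent_diary_rejected(self):
        e = make_entry(bed="23:00", awakening="07:00", sol=300, waso=300, bol=300)
        with pytest.raises(DiaryValidationError):
            total_sleep_time(e)

    @pytest.mark.parametrize(
        "sol,waso,bol,expected",
        [(20, 25, 15, 86.7), (0, 0, 0, 100.0), (335, 100, 15, 0.0)],
    )
    def test_sleep_efficiency_examples(self, sol, waso, bol, expected):
        e = make_entry(sol=sol, waso=waso, bol=bol)
        assert round(sleep_efficiency(e), 1) == expected

    def test_awakenings_consistency_enforced(self):
        with pytest.raises(DiaryValidationError):
            make_entry(n_awakenings=0, waso=10)


# random valid diary nights for property tests
@st.composite
def diary_entries(draw):
    bed = draw(st.integers(0, 1439))
    tib = draw(st.integers(120, 720))
    sol = draw(st.integers(0, tib // 3))
    waso = draw(st.integers(0, tib // 3))
    bol = draw(st.integers(0, tib // 6))
    arising = ClockTime(bed + tib)
    return make_entry(
        bed=str(ClockTime(bed)),
        awakening=str(arising.sub(bol)),
        sol=sol,
        waso=waso,
        bol=bol,
        n_awakenings=0 if waso == 0 else 1,
    )


class TestInvariants:
    @given(diary_entries())
    @settings(max_examples=200, deadline=None)
    def test_conservation(self, e):
        """TIB - SOL - WASO - bed-out latency = TST, exactly, in integer minutes."""
        assert (
            time_in_bed(e)
            - e.sleep_onset_latency
            - e.awakening_duration
            - e.bed_out_latency
            == total_sleep_time(e)
        )

    @given(diary_entries(), st.integers(-1440, 1440))
    @settings(max_examples=200, deadline=None)
    def test_wrap_shift_invariance(self, e, offset):
        """Shifting bed and arising clocks jointly (mod 24 h) keeps TIB fixed."""
        shifted = make_entry(
            bed=str(e.bed_time.add(offset)),
            awakening=str(e.final_awakening_time.add(offset)),
            sol=e.sleep_onset_latency,
            waso=e.awakening_duration,
            bol=e.bed_out_latency,
            n_awakenings=e.n_awakenings,
        )
        assert time_in_bed(shifted) == time_in_bed(e)

    @given(diary_entries())
    @settings(max_examples=200, deadline=None)
    def test_se_bounded(self, e):
        assert 0.0 <= sleep_efficiency(e) <= 100.0

    def test_se_monotone_in_tst_at_fixed_tib(self):
        ses = [
            sleep_efficiency(make_entry(sol=s, waso=0, bol=0, n_awakenings=0))
            for s in range(0, 150, 10)
        ]
        assert ses == sorted(ses, reverse=True)


class TestWeeklySummary:
    def test_mean_over_identical_entries(self, week_of_entries):
        s = summarize_week(week_of_entries, 1)
        assert s.n_entries == 7
        assert s.mean_total_sleep_time == 390
        assert s.adherent

    def test_mean_is_brute_force_mean(self):
        entries = [make_entry(sol=50, waso=25, bol=15), make_entry(sol=0, waso=15, bol=15)]
        s = summarize_week(entries, 2)
        tsts = [total_sleep_time(e) for e in entries]
        assert s.mean_total_sleep_time == sum(tsts) / 2
        assert s.mean_sleep_efficiency == pytest.approx(
            sum(sleep_efficiency(e) for e in entries) / 2
        )
        assert s.n_entries == 2

    def test_empty_week(self):
        s = summarize_week([], 3)
        assert s.n_entries == 0 and not s.adherent
        assert s.mean_total_sleep_time is None and s.mean_sleep_efficiency is None

    def test_two_entries_not_adherent(self):
        assert not summarize_week([make_entry(), make_entry()], 1).adherent

    def test_mixed_participants_rejected(self):
        with pytest.raises(DiaryValidationError):
            summarize_week([make_entry(), make_entry(participant_id="P002")], 1)


class TestIO:
    def test_csv_round_trip(self, tmp_path, week_of_entries):
        path = tmp_path / "diary.csv"
        entries = [
            make_entry(
                date=e.date,
                sleepiness_times=(ClockTime.parse("14:00"),),
                caffeine=True,
                nap_duration=20,
            )
            for e in week_of_entries
        ]
        write_diary_csv(entries, path)
        assert read_diary_csv(path) == entries

    def test_json_round_trip(self, tmp_path, entry):
        path = tmp_path / "diary.json"
        write_diary_json([entry], path)
        assert read_diary_json(path) == [entry]

    def test_missing_field_invalidates(self, entry):
        df = entries_to_frame([entry]).drop(columns=["bed_time"])
        df["bed_time"] = None
        with pytest.raises(DiaryValidationError, match="missing"):
            frame_to_entries(df)

    def test_metrics_table_rounds_to_one_decimal(self, entry):
        t = metrics_table([entry])
        assert t.loc[0, "sleep_efficiency"] == 86.7
        assert t.loc[0, "time_in_bed"] == 450
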