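import datetime as dt

import pytest

from sleepprompt.diary import ClockTime, DiaryEntry


def make_entry(
    participant_id="P001",
    date=dt.date(2021, 1, 4),
    bed="23:30",
    sol=20,
    n_awakenings=2,
    waso=25,
    awakening="06:45",
    bol=15,
    **kwargs,
):
    """A valid diary night (TIB 450, TST 390, SE 86.7) unless overridden."""
    return DiaryEntry(
        participant_id=participant_id,
        date=date,
        bed_time=ClockTime.parse(bed),
        sleep_onset_latency=sol,
        n_awakenings=n_awakenings,
        awakening_duration=waso,
        final_awakening_time=ClockTime.parse(awakening),
        bed_out_latency=bol,
        **kwargs,
    )


@pytest.fixture
def entry():
    return make_entry()


@pytest.fixture
def week_of_entries():
    start = dt.date(2021, 1, 4)
    return [make_entry(date=start + dt.timedelta(days=i)) for i in range(7)]
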