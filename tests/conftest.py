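import math

import pytest

from anemotrack.trap_records import (
    CORNER_DIRECTIONS,
    COMPASS_POINTS,
    TrapCountRecord,
    expected_trap_class,
)


def make_record(**kw) -> TrapCountRecord:
    """A valid corner-trap record with overridable fields."""
    base = dict(
        night_id="2009-04-01",
        enclosure_id="E1",
        site="Fulani",
        side="North",
        season="dry",
        year=2009,
        orientation="corners_cardinal",
        trap_direction="N",
        trap_class="corner",
        check_index=0,
        count_male=1,
        count_female=2,
    )
    base.update(kw)
    if "trap_class" not in kw:
        base["trap_class"] = expected_trap_class(
            base["orientation"], base["trap_direction"]
        )
    return TrapCountRecord(**base)


def enclosure_rows(counts: dict[str, int], orientation="corners_cardinal",
                   check_index=0, **kw) -> list[TrapCountRecord]:
    """All-8-trap rows for one enclosure-night check; counts name totals per
    direction (put in count_female; others zero)."""
    rows = []
    for d in COMPASS_POINTS:
        rows.append(make_record(
            orientation=orientation,
            trap_direction=d,
            check_index=check_index,
            count_male=0,
            count_female=counts.get(d, 0),
            **kw,
        ))
    return rows


@pytest.fixture
def pi():
    return math.pi
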