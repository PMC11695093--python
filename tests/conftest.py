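import numpy as np
import pandas as pd
import pytest

import twinppd as tp


def make_registry(births_rows, events_rows=()):
    """Build a RawRegistry from plain tuples.

    births_rows: (birth_id, parent_id, role, birth_date, plurality, age,
                  year, art, cohab, primi)
    events_rows: (parent_id, event_date, kind, code)
    """
    births = pd.DataFrame(
        births_rows,
        columns=[
            "birth_id",
            "parent_id",
            "role",
            "birth_date",
            "plurality",
            "age_years",
            "calendar_year",
            "art_flag",
            "cohabiting_flag",
            "primiparous_flag",
        ],
    )
    events = pd.DataFrame(
        list(events_rows) or None,
        columns=["parent_id", "event_date", "kind", "code"],
    )
    return tp.RawRegistry(births=births, events=events)


def birth_row(
    birth_id="B1",
    parent_id="M1",
    role="mother",
    date="2010-06-15",
    plurality="singleton",
    age=30.0,
    year=2010,
    art=0,
    cohab=1,
    primi=1.0,
):
    return (birth_id, parent_id, role, date, plurality, age, year, art, cohab, primi)


@pytest.fixture(scope="session")
def scaled_fit():
    """Mother model fitted to one moderate paper-shaped scaled draw.

    Shared by effect-estimate and model tests that only need *a*
    well-behaved fitted model, not a particular scenario.
    """
    sc = tp.paper_shaped_scenario(n_births=20_000, seed=42, risk_scale=5.0)
    reg = tp.simulate_scenario(sc)
    cohort = tp.build_cohort(reg, role="mother")
    pp = tp.split_follow_up(cohort)
    spec = tp.ModelSpec(role="mother")
    knots = tp.default_knots(cohort, spec)
    fit = tp.fit_piecewise_poisson(pp, spec, knots)
    return sc, cohort, pp, fit
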