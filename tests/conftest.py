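import numpy as np
import pandas as pd
import pytest

from hbvar.synthetic_cohort import MMOL_MOL


def make_results(records):
    """Build a results table from (patient_id, date, value[, unit]) tuples."""
    rows = []
    for rec in records:
        pid, date, value = rec[0], rec[1], rec[2]
        unit = rec[3] if len(rec) > 3 else MMOL_MOL
        rows.append({"patient_id": pid, "date": pd.Timestamp(date), "value": float(value), "unit": unit})
    return pd.DataFrame(rows)


@pytest.fixture
def toy_cohort():
    """Three patients x two visits; pooled within variance 8, grand mean 52."""
    return make_results(
        [
            ("A", "2015-01-01", 40), ("A", "2015-02-01", 44),
            ("B", "2015-01-01", 50), ("B", "2015-02-01", 54),
            ("C", "2015-01-01", 60), ("C", "2015-02-01", 64),
        ]
    )


@pytest.fixture
def twelve_row_cohort():
    """Worked cleaning fixture; the hand-derived report is asserted in tests.

    P1 survives with 4 records after losing a same-day duplicate; P2 loses a
    percent-tagged row and a sub-20.1 row, then falls below the 4-measurement
    floor; P3 repeats 52.0 on four distinct dates and is excluded outright.
    """
    return make_results(
        [
            ("P1", "2015-01-10", 50.0),
            ("P1", "2015-01-10", 51.0),  # same-day duplicate, second in order
            ("P1", "2015-03-20", 52.5),
            ("P1", "2015-06-05", 47.9),
            ("P1", "2015-09-15", 49.5),
            ("P2", "2016-02-01", 6.5, "percent"),
            ("P2", "2016-04-01", 7.7),  # percent value mis-recorded as mmol/mol
            ("P2", "2016-06-01", 55.0),
            ("P3", "2014-01-05", 52.0),
            ("P3", "2014-04-05", 52.0),
            ("P3", "2014-08-05", 52.0),
            ("P3", "2014-12-05", 52.0),
        ]
    )


@pytest.fixture
def twelve_row_covariates():
    return pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3", "P4"],
            "bmi": [12.0, 25.0, 80.0, np.nan],
        }
    )
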