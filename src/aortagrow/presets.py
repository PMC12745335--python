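"""Reference nine-patient cohort inputs.

Clinical scalars of the acute type B dissection cohort that this
package's defaults emulate: admission brachial pressures, systolic flow
rates used for boundary-condition calibration (25 L/min population
average where echocardiography was unavailable), CTA dates, and false
lumen thrombus status.  These drive the synthetic pipeline's boundary
conditions and the desk-reproducible arithmetic (resistance calculation,
follow-up durations).
"""

from __future__ import annotations

from datetime import date

import pandas as pd

from .synthetic import PatientRecord

__all__ = ["reference_patients", "reference_flow_table"]

_ROWS = [
    # id, sbp, dbp, baseline, followup, flow L/min, thrombus
    ("P1", 159, 87, date(2015, 12, 16), date(2016, 8, 18), 25.00, True),
    ("P2", 119, 59, date(2015, 3, 19), date(2016, 11, 30), 8.89, True),
    ("P3", 127, 61, date(2008, 4, 1), date(2011, 6, 15), 24.18, False),
    ("P4", 147, 94, date(2013, 4, 6), date(2016, 10, 4), 26.64, False),
    ("P5", 191, 94, date(2016, 3, 25), date(2018, 10, 11), 25.00, True),
    ("P6", 136, 63, date(2010, 3, 15), date(2017, 8, 25), 15.06, True),
    ("P7", 156, 77, date(2023, 4, 10), date(2023, 7, 6), 26.70, True),
    ("P8", 183, 96, date(2009, 1, 15), date(2012, 3, 22), 25.00, False),
    ("P9", 168, 80, date(2011, 10, 20), date(2016, 3, 24), 25.00, True),
]


def reference_patients() -> list[PatientRecord]:
    """The nine cohort records (pressures mmHg, flows L/min)."""
    return [
        PatientRecord(patient_id=pid, sbp=sbp, dbp=dbp,
                      baseline_date=b, followup_date=f,
                      inlet_flow=q, thrombus_present=tb)
        for pid, sbp, dbp, b, f, q, tb in _ROWS
    ]


def reference_flow_table() -> pd.DataFrame:
    """Cohort table with the calculated total resistances (SBP/flow)."""
    recs = reference_patients()
    return pd.DataFrame({
        "patient_id": [r.patient_id for r in recs],
        "sbp_mmhg": [r.sbp for r in recs],
        "flow_l_min": [r.inlet_flow for r in recs],
        "calculated_resistance_mmhg_min_l":
            [r.sbp / r.inlet_flow for r in recs],
        "followup_years": [r.followup_years for r in recs],
        "thrombus": [r.thrombus_present for r in recs],
    })
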