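import numpy as np
import pytest

from camgfr.data_model import MG_DL, UMOL_L, Cohort, PatientRecord, convert_creatinine


def make_record(
    pid="p",
    age=60.0,
    sex="M",
    height=175.0,
    weight=80.0,
    cre_mgdl=1.0,
    measured_gfr=None,
    days_between=None,
) -> PatientRecord:
    return PatientRecord(
        patient_id=pid,
        age=age,
        sex=sex,
        height=height,
        weight=weight,
        creatinine=convert_creatinine(cre_mgdl, MG_DL, UMOL_L),
        creatinine_unit=UMOL_L,
        measured_gfr=measured_gfr,
        days_between=days_between,
    )


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def toy_cohort():
    """Deterministic 12-record cohort with measured GFR, both sexes."""
    rng = np.random.default_rng(42)
    records = []
    for i in range(12):
        records.append(
            make_record(
                pid=f"t{i:02d}",
                age=float(rng.uniform(20, 85)),
                sex="M" if i % 2 else "F",
                height=float(rng.uniform(150, 195)),
                weight=float(rng.uniform(45, 110)),
                cre_mgdl=float(rng.uniform(0.5, 3.0)),
                measured_gfr=float(rng.uniform(20, 140)),
                days_between=float(rng.integers(0, 30)),
            )
        )
    return Cohort(records, label="toy", creatinine_unit=UMOL_L)


@pytest.fixture
def grid_records():
    """Covariate grid spanning both sexes and a wide clinical range."""
    recs = []
    i = 0
    for sex in ("M", "F"):
        for age in (25.0, 55.0, 80.0):
            for cre in (0.5, 1.0, 2.5):
                recs.append(
                    make_record(
                        pid=f"g{i:02d}", age=age, sex=sex,
                        height=178.0 if sex == "M" else 162.0,
                        weight=84.0 if sex == "M" else 66.0,
                        cre_mgdl=cre,
                    )
                )
                i += 1
    return recs
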