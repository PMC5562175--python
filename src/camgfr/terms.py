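"""Candidate design terms for the square-root-GFR linear model.

Each term maps a patient record to one column of the design matrix.  Terms
carry hierarchy metadata: a polynomial or interaction term is admissible in a
model only when all of its lower-order parents are present (so e.g. ln(Cre)³
can never enter before ln(Cre)²).

The model's creatinine terms are powers of the natural log of serum
creatinine in the unit the coefficients assume; the evaluation functions take
that unit explicitly and convert from the record's own unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from camgfr.data_model import PatientRecord

__all__ = ["Term", "TERMS", "DEFAULT_POOL", "EQ1_TERMS", "INTERCEPT"]

INTERCEPT = "intercept"


@dataclass(frozen=True)
class Term:
    name: str
    parents: tuple[str, ...]
    func: Callable[[PatientRecord, str], float]
    label: str


def _ln_cre(record: PatientRecord, unit: str) -> float:
    cre = record.creatinine_in(unit)
    if not cre > 0:
        raise ValueError(f"creatinine must be positive for ln(Cre) (got {cre})")
    return math.log(cre)


TERMS: dict[str, Term] = {
    t.name: t
    for t in [
        Term("age", (), lambda r, u: r.age, "Age"),
        Term("bsa", (), lambda r, u: r.bsa, "BSA"),
        Term("height", (), lambda r, u: r.height, "Height"),
        Term("weight", (), lambda r, u: r.weight, "Weight"),
        Term("male", (), lambda r, u: 1.0 if r.is_male else 0.0, "Sex=M"),
        Term("ln_cre", (), _ln_cre, "ln(Cre)"),
        Term("ln_cre2", ("ln_cre",), lambda r, u: _ln_cre(r, u) ** 2, "ln(Cre)^2"),
        Term("ln_cre3", ("ln_cre", "ln_cre2"), lambda r, u: _ln_cre(r, u) ** 3, "ln(Cre)^3"),
        Term("male_age", ("male", "age"), lambda r, u: (r.age if r.is_male else 0.0), "Sex=M x Age"),
        Term("age_bsa", ("age", "bsa"), lambda r, u: r.age * r.bsa, "Age x BSA"),
    ]
}

#: Default stepwise candidate pool, in documented tie-break order.
DEFAULT_POOL: tuple[str, ...] = (
    "age",
    "bsa",
    "height",
    "weight",
    "male",
    "ln_cre",
    "ln_cre2",
    "ln_cre3",
    "male_age",
    "age_bsa",
)

#: The final model's term set (intercept implicit), in coefficient order
#: β1…β8: Age, BSA, ln(Cre), ln(Cre)², ln(Cre)³, Sex=M, Sex=M×Age, Age×BSA.
EQ1_TERMS: tuple[str, ...] = (
    "age",
    "bsa",
    "ln_cre",
    "ln_cre2",
    "ln_cre3",
    "male",
    "male_age",
    "age_bsa",
)
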