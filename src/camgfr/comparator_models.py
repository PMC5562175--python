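"""Published creatinine-based eGFR / creatinine-clearance equations.

Seven equations commonly used to estimate renal function from serum
creatinine and biometrics sit behind a uniform registry: Cockcroft-Gault
and Jelliffe (creatinine clearance), Wright, Martin, the Mayo quadratic,
4-variable IDMS MDRD, and CKD-EPI (2009, creatinine).  Each
:class:`ComparatorSpec` declares the creatinine unit its formula expects and
whether its native output is absolute (mL/min) or normalized to 1.73 m² of
body surface area; normalized outputs can be converted to absolute with
:func:`bsa_adjust`.

All coefficient values live in :mod:`camgfr.constants`, transcribed from
the primary references.  The MDRD and CKD-EPI race factors are implemented
but default to the non-black factor; pass ``black=True`` to apply them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from camgfr import constants
from camgfr.data_model import MG_DL, UMOL_L, PatientRecord

__all__ = [
    "ComparatorSpec",
    "COMPARATORS",
    "BSA_ADJUSTED_MODELS",
    "InputError",
    "ScaleError",
    "bsa_adjust",
    "estimate_comparator",
    "estimate_all",
]

REFERENCE_BSA = 1.73

#: Normalized models the comparison framework also evaluates BSA-adjusted.
BSA_ADJUSTED_MODELS = ("mayo", "jelliffe", "mdrd", "ckd_epi")


class InputError(ValueError):
    """Record lacks an input the formula requires."""


class ScaleError(ValueError):
    """BSA adjustment applied to a model whose output is already absolute."""


@dataclass(frozen=True)
class ComparatorSpec:
    model_id: str
    label: str
    output_scale: str  # "absolute" or "normalized"
    creatinine_unit: str
    required: tuple[str, ...]
    func: Callable[..., float]


def _require(record: PatientRecord, fields: tuple[str, ...], model_id: str) -> None:
    for f in fields:
        if getattr(record, f, None) is None:
            raise InputError(f"{model_id}: record {record.patient_id!r} lacks {f}")


def _cockcroft_gault(age, female, weight, scr_mgdl, **_):
    c = constants.COCKCROFT_GAULT
    val = (c["age_offset"] - age) * weight / (c["denominator"] * scr_mgdl)
    return val * c["female_factor"] if female else val


def _jelliffe(age, female, scr_mgdl, **_):
    c = constants.JELLIFFE_1973
    val = (c["base"] - c["age_slope"] * (age - c["age_offset"])) / scr_mgdl
    return val * c["female_factor"] if female else val


def _wright(age, female, bsa, scr_umol, **_):
    c = constants.WRIGHT
    val = (c["base"] - c["age_slope"] * age) * bsa / scr_umol
    return val * c["female_factor"] if female else val


def _martin(age, female, weight, scr_umol, **_):
    c = constants.MARTIN
    val = c["coefficient"] * weight * (1.0 - c["age_slope"] * age) / scr_umol
    return val * c["female_factor"] if female else val


def _mayo(age, female, scr_mgdl, **_):
    c = constants.MAYO_QUADRATIC
    scr = max(scr_mgdl, c["scr_floor"])
    expo = (
        c["intercept"]
        + c["inv_scr"] / scr
        + c["inv_scr2"] / scr**2
        + c["age"] * age
        + (c["female"] if female else 0.0)
    )
    return math.exp(expo)


def _mdrd(age, female, scr_mgdl, black=False, **_):
    c = constants.MDRD_175
    val = c["coefficient"] * scr_mgdl ** c["scr_exp"] * age ** c["age_exp"]
    if female:
        val *= c["female_factor"]
    if black:
        val *= c["black_factor"]
    return val


def _ckd_epi(age, female, scr_mgdl, black=False, **_):
    c = constants.CKD_EPI_2009
    kappa = c["kappa_female"] if female else c["kappa_male"]
    alpha = c["alpha_female"] if female else c["alpha_male"]
    ratio = scr_mgdl / kappa
    val = (
        c["coefficient"]
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** c["max_exp"]
        * c["age_base"] ** age
    )
    if female:
        val *= c["female_factor"]
    if black:
        val *= c["black_factor"]
    return val


COMPARATORS: dict[str, ComparatorSpec] = {
    s.model_id: s
    for s in [
        ComparatorSpec(
            "cockcroft_gault", "Cockcroft-Gault", "absolute", MG_DL,
            ("age", "sex", "weight", "creatinine"), _cockcroft_gault,
        ),
        ComparatorSpec(
            "jelliffe", "Jelliffe", "normalized", MG_DL,
            ("age", "sex", "creatinine"), _jelliffe,
        ),
        ComparatorSpec(
            "wright", "Wright", "absolute", UMOL_L,
            ("age", "sex", "height", "weight", "creatinine"), _wright,
        ),
        ComparatorSpec(
            "martin", "Martin", "absolute", UMOL_L,
            ("age", "sex", "weight", "creatinine"), _martin,
        ),
        ComparatorSpec(
            "mayo", "Mayo", "normalized", MG_DL,
            ("age", "sex", "creatinine"), _mayo,
        ),
        ComparatorSpec(
            "mdrd", "MDRD", "normalized", MG_DL,
            ("age", "sex", "creatinine"), _mdrd,
        ),
        ComparatorSpec(
            "ckd_epi", "CKD-EPI", "normalized", MG_DL,
            ("age", "sex", "creatinine"), _ckd_epi,
        ),
    ]
}


def estimate_comparator(
    model_id: str, record: PatientRecord, black: bool = False
) -> float:
    """Evaluate one published equation on its native scale.

    Normalized models return mL/min/1.73 m²; absolute models mL/min.  The
    record's creatinine is converted to the unit the formula expects.
    """
    try:
        spec = COMPARATORS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; known: {sorted(COMPARATORS)}"
        ) from None
    _require(record, spec.required, model_id)
    needs_bsa = "height" in spec.required and "weight" in spec.required
    return float(
        spec.func(
            age=record.age,
            female=not record.is_male,
            weight=record.weight,
            bsa=record.bsa if needs_bsa else None,
            scr_mgdl=record.creatinine_in(MG_DL),
            scr_umol=record.creatinine_in(UMOL_L),
            black=black,
        )
    )


def bsa_adjust(value: float, bsa: float) -> float:
    """Convert a normalized eGFR (mL/min/1.73 m²) to absolute mL/min."""
    if not (value > 0 and bsa > 0):
        raise ValueError(f"value and bsa must be positive (got {value}, {bsa})")
    return value * bsa / REFERENCE_BSA


def to_absolute(model_id: str, value: float, record: PatientRecord) -> float:
    """Native value → absolute mL/min (BSA-adjusting normalized models)."""
    spec = COMPARATORS[model_id]
    if spec.output_scale == "absolute":
        return value
    return bsa_adjust(value, record.bsa)


def estimate_all(
    record: PatientRecord,
    include_bsa_adjusted: bool = True,
    black: bool = False,
) -> dict[str, float | Exception]:
    """Evaluate every comparator on its native scale for one record.

    Returns a stable-label map of the 7 models plus, when requested, the 4
    BSA-adjusted variants (labelled ``"BSA-adj <model>"``, absolute mL/min).
    Per-model input failures are reported in-place as the exception, tagged
    by label, so one missing field does not sink the other models.
    """
    out: dict[str, float | Exception] = {}
    for model_id, spec in COMPARATORS.items():
        try:
            out[spec.label] = estimate_comparator(model_id, record, black=black)
        except (InputError, ValueError) as exc:
            out[spec.label] = exc
    if include_bsa_adjusted:
        for model_id in BSA_ADJUSTED_MODELS:
            spec = COMPARATORS[model_id]
            label = f"BSA-adj {spec.label}"
            native = out.get(spec.label)
            if isinstance(native, Exception):
                out[label] = native
                continue
            try:
                out[label] = bsa_adjust(native, record.bsa)
            except (ValueError, TypeError) as exc:
                out[label] = InputError(f"{label}: BSA unavailable ({exc})")
    return out
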