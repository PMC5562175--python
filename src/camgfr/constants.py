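"""Transcribed constants for the published eGFR equations and model defaults.

Comparator coefficients are transcribed from the primary references and kept
in one table so they can be audited line-by-line against those sources:

* Cockcroft & Gault, Nephron 16:31-41, 1976 (creatinine clearance, mL/min).
* Jelliffe, Ann Intern Med 79:604, 1973 variant (CrCl per 1.73 m²).
* Wright et al., Br J Cancer 84:452-459, 2001 (cancer cohort, mL/min).
* Martin et al., Br J Clin Pharmacol 45:523-526, 1998 (mL/min).
* Rule et al., Ann Intern Med 141:929-937, 2004 ("Mayo quadratic",
  mL/min/1.73 m², with the published 0.8 mg/dL creatinine floor).
* Levey et al., Ann Intern Med 145:247-254, 2006: 4-variable IDMS-traceable
  MDRD (coefficient 175, mL/min/1.73 m²).
* Levey et al., Ann Intern Med 150:604-612, 2009: CKD-EPI creatinine
  equation (mL/min/1.73 m²).

``DEFAULT_BETA`` holds the ground-truth coefficient vector used by the
synthetic-cohort generator and as the packaged point-estimation default.  It
is a synthetic stand-in on the published functional form (cubic ln-creatinine
square-root-GFR model): the vector was calibrated once against the published
cohort summaries (median measured GFR 81 mL/min, IQR 63-103, in a mixed-sex
cancer cohort of median age ~62; median 113 mL/min in young seminoma
patients) and is not a transcription of the originally fitted coefficients,
which are not redistributed here.
"""

from __future__ import annotations

from camgfr.data_model import MG_DL, UMOL_L

__all__ = [
    "DEFAULT_BETA",
    "MODEL_CREATININE_UNIT",
    "DEFAULT_SIGMA_SQRT",
    "COCKCROFT_GAULT",
    "JELLIFFE_1973",
    "WRIGHT",
    "MARTIN",
    "MAYO_QUADRATIC",
    "MDRD_175",
    "CKD_EPI_2009",
]

#: Creatinine unit the model coefficients assume.  All design construction
#: converts the record's creatinine to this unit before taking logs.
MODEL_CREATININE_UNIT = MG_DL

#: Residual standard deviation on the √GFR scale.  At √GFR ≈ 9 the delta
#: method gives a GFR-scale error of ≈ 2·√GFR·σ ≈ 15 mL/min, matching the
#: accuracy regime reported for creatinine-based estimation in cancer
#: cohorts.
DEFAULT_SIGMA_SQRT = 0.83

#: √GFR-scale coefficients, keyed by design term (creatinine in mg/dL).
#: Synthetic stand-in vector — see module docstring.  The age-related
#: decline is carried jointly by the main effect and the Age×BSA and
#: Sex×Age interactions (net ≈ −0.05 to −0.07 √(mL/min)/year, i.e. roughly
#: −1 mL/min/year around GFR 81); the cubic ln-creatinine polynomial is
#: strictly decreasing over the whole clinical creatinine range.
DEFAULT_BETA: dict[str, float] = {
    "intercept": 4.50,
    "age": 0.010,
    "bsa": 4.50,
    "ln_cre": -4.00,
    "ln_cre2": -0.90,
    "ln_cre3": -0.55,
    "male": 1.30,
    "male_age": -0.016,
    "age_bsa": -0.045,
}

# ---------------------------------------------------------------------------
# Comparator equation constants (see module docstring for sources).
# Each dict records the creatinine unit the formula expects and whether its
# native output is absolute mL/min or normalized mL/min/1.73 m².

COCKCROFT_GAULT = {
    "unit": MG_DL,
    "scale": "absolute",
    "age_offset": 140.0,
    "denominator": 72.0,
    "female_factor": 0.85,
}

JELLIFFE_1973 = {
    "unit": MG_DL,
    "scale": "normalized",
    "base": 98.0,
    "age_slope": 0.8,  # per year beyond age 20
    "age_offset": 20.0,
    "female_factor": 0.90,
}

WRIGHT = {
    "unit": UMOL_L,
    "scale": "absolute",
    "base": 6580.0,
    "age_slope": 38.8,
    "female_factor": 0.832,
}

MARTIN = {
    "unit": UMOL_L,
    "scale": "absolute",
    "coefficient": 163.0,
    "age_slope": 0.00496,
    "female_factor": 0.74,
}

MAYO_QUADRATIC = {
    "unit": MG_DL,
    "scale": "normalized",
    "intercept": 1.911,
    "inv_scr": 5.249,
    "inv_scr2": -2.114,
    "age": -0.00686,
    "female": -0.205,
    "scr_floor": 0.8,  # published low-creatinine floor (mg/dL)
}

MDRD_175 = {
    "unit": MG_DL,
    "scale": "normalized",
    "coefficient": 175.0,
    "scr_exp": -1.154,
    "age_exp": -0.203,
    "female_factor": 0.742,
    "black_factor": 1.212,
}

CKD_EPI_2009 = {
    "unit": MG_DL,
    "scale": "normalized",
    "coefficient": 141.0,
    "kappa_female": 0.7,
    "kappa_male": 0.9,
    "alpha_female": -0.329,
    "alpha_male": -0.411,
    "max_exp": -1.209,
    "age_base": 0.993,
    "female_factor": 1.018,
    "black_factor": 1.159,
}
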