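"""The square-root-scale GFR model: design, fitting, prediction, intervals.

The model regresses √GFR on age, Du Bois body surface area, a cubic
polynomial in ln(serum creatinine), a sex offset with a sex-by-age
interaction, and an age-by-BSA interaction:

    √GFR = β0 + β1·Age + β2·BSA + β3·ln(Cre) + β4·ln(Cre)² + β5·ln(Cre)³
           + (β6 + β7·Age)·[Sex = M] + β8·Age·BSA + ε,   ε ~ N(0, σ²)

A Box-Cox analysis of the response motivates the square-root scale (see
:mod:`camgfr.model_selection`); on that scale the residuals are close to
homoscedastic normal, so ordinary least squares applies and per-patient
predictive intervals follow from the classical linear-model theory: for a
new covariate row x the predictive distribution of √GFR is

    βᵀx + t_{n-p} · sqrt(σ̂² (1 + xᵀ(XᵀX)⁻¹x))

Intervals and threshold probabilities (e.g. P(GFR < 50 mL/min), the
cisplatin-caution cutoff) are obtained on the √ scale and mapped back by
squaring, clamping negative √-scale values at zero.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg
from scipy import stats

from camgfr import constants
from camgfr.data_model import Cohort, PatientRecord, normalize_unit
from camgfr.terms import EQ1_TERMS, INTERCEPT, TERMS

__all__ = [
    "FittingError",
    "CapabilityError",
    "FittedModel",
    "PredictionResult",
    "build_design_row",
    "build_design_matrix",
    "fit_sqrt_model",
    "default_model",
    "predict_sqrt",
    "predict_point",
    "predict_interval",
    "prob_below_threshold",
    "predict",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

SERIALIZATION_VERSION = 1


class FittingError(ValueError):
    """Design matrix cannot be fit (rank deficiency, too few records)."""


class CapabilityError(RuntimeError):
    """Operation needs fit metadata a coefficients-only model lacks."""


@dataclass(frozen=True)
class FittedModel:
    """A fitted (or published-coefficients) √GFR-scale linear model.

    ``beta`` is indexed by ``term_names`` (intercept first).  ``sigma2`` is
    the residual variance on the √ scale, ``xtx_inverse`` the (XᵀX)⁻¹ matrix
    used for leverages; both may be None for a coefficients-only model, which
    supports point prediction but not intervals.
    """

    beta: np.ndarray
    term_names: tuple[str, ...]
    creatinine_unit: str
    sigma2: float | None = None
    n_obs: int | None = None
    xtx_inverse: np.ndarray | None = None

    @property
    def p(self) -> int:
        return len(self.term_names)

    @property
    def df_resid(self) -> int:
        if self.n_obs is None:
            raise CapabilityError("model has no fitting sample size")
        return self.n_obs - self.p

    @property
    def has_interval_support(self) -> bool:
        return (
            self.sigma2 is not None
            and self.n_obs is not None
            and self.xtx_inverse is not None
        )

    def _require_intervals(self, what: str) -> None:
        if not self.has_interval_support:
            raise CapabilityError(
                f"{what} requires sigma2, n_obs and the cross-product inverse; "
                "this model carries point-estimate coefficients only — refit on "
                "data or load a full serialization"
            )


@dataclass(frozen=True)
class PredictionResult:
    """Point estimate, predictive interval and threshold probability."""

    egfr_point: float
    interval_low: float
    interval_high: float
    level: float
    prob_below_cutoff: float
    cutoff: float


def build_design_row(
    record: PatientRecord,
    term_names: Sequence[str] = EQ1_TERMS,
    creatinine_unit: str = constants.MODEL_CREATININE_UNIT,
) -> np.ndarray:
    """Evaluate the design terms for one record (intercept first).

    The record's creatinine is converted to `creatinine_unit` before the log
    terms are computed, so records may carry either unit.
    """
    unit = normalize_unit(creatinine_unit)
    row = np.empty(len(term_names) + 1)
    row[0] = 1.0
    for j, name in enumerate(term_names, start=1):
        row[j] = TERMS[name].func(record, unit)
    return row


def build_design_matrix(
    cohort: Cohort | Iterable[PatientRecord],
    term_names: Sequence[str] = EQ1_TERMS,
    creatinine_unit: str = constants.MODEL_CREATININE_UNIT,
) -> np.ndarray:
    records = cohort.records if isinstance(cohort, Cohort) else list(cohort)
    return np.vstack(
        [build_design_row(r, term_names, creatinine_unit) for r in records]
    )


def fit_sqrt_model(
    cohort: Cohort,
    term_names: Sequence[str] | None = None,
    creatinine_unit: str = constants.MODEL_CREATININE_UNIT,
) -> FittedModel:
    """Ordinary least squares of √(measured GFR) on the design terms.

    Defaults to the final model's term set.  σ² is estimated as RSS/(n−p)
    and the pivoted-QR factorization provides (XᵀX)⁻¹ for the interval
    machinery.  A rank-deficient design raises :class:`FittingError` naming
    the collinear terms.
    """
    names = tuple(term_names) if term_names is not None else EQ1_TERMS
    y = np.sqrt(cohort.measured_gfr)
    X = build_design_matrix(cohort, names, creatinine_unit)
    n, p = X.shape
    if n <= p:
        raise FittingError(f"need more records ({n}) than coefficients ({p})")
    Q, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < p:
        all_names = (INTERCEPT,) + names
        collinear = [all_names[piv[j]] for j in range(rank, p)]
        raise FittingError(f"rank-deficient design; collinear term(s): {collinear}")
    qty = Q.T @ y
    beta_piv = scipy.linalg.solve_triangular(R, qty)
    beta = np.empty(p)
    beta[piv] = beta_piv
    rinv = scipy.linalg.solve_triangular(R, np.eye(p))
    xtx_inv_piv = rinv @ rinv.T
    xtx_inv = np.empty((p, p))
    xtx_inv[np.ix_(piv, piv)] = xtx_inv_piv
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    return FittedModel(
        beta=beta,
        term_names=(INTERCEPT,) + names,
        creatinine_unit=normalize_unit(creatinine_unit),
        sigma2=sigma2,
        n_obs=n,
        xtx_inverse=xtx_inv,
    )


def default_model() -> FittedModel:
    """Packaged coefficients-only model (point prediction; no intervals)."""
    beta = np.array([constants.DEFAULT_BETA[k] for k in (INTERCEPT,) + EQ1_TERMS])
    return FittedModel(
        beta=beta,
        term_names=(INTERCEPT,) + EQ1_TERMS,
        creatinine_unit=constants.MODEL_CREATININE_UNIT,
    )


def _design_for(model: FittedModel, record: PatientRecord) -> np.ndarray:
    return build_design_row(record, model.term_names[1:], model.creatinine_unit)


def predict_sqrt(model: FittedModel, record: PatientRecord) -> float:
    """√GFR-scale linear predictor βᵀx (may be negative for extreme inputs)."""
    return float(model.beta @ _design_for(model, record))


def _leverage(model: FittedModel, record: PatientRecord) -> float:
    x = _design_for(model, record)
    return float(x @ model.xtx_inverse @ x)


def predict_point(
    model: FittedModel, record: PatientRecord, bias_corrected: bool = False
) -> float:
    """Point eGFR in mL/min: the squared √-scale prediction, clamped at 0.

    With ``bias_corrected=True`` the retransformation adds σ²(1+leverage) —
    the mean of the squared predictive distribution rather than the square of
    its mean.  The default is the uncorrected square.
    """
    m = predict_sqrt(model, record)
    if m < 0:
        logger.warning(
            "negative sqrt-scale prediction %.3f clamped to 0 for patient %s",
            m,
            record.patient_id,
        )
        m = 0.0
    if not bias_corrected:
        return m * m
    model._require_intervals("bias-corrected prediction")
    return m * m + model.sigma2 * (1.0 + _leverage(model, record))


def _predictive_sd(model: FittedModel, record: PatientRecord) -> float:
    return math.sqrt(model.sigma2 * (1.0 + _leverage(model, record)))


def predict_interval(
    model: FittedModel, record: PatientRecord, level: float = 0.95
) -> tuple[float, float]:
    """Predictive interval for the patient's true GFR (mL/min).

    √-scale endpoints βᵀx ± t_{n−p,(1+level)/2}·√(σ²(1+leverage)), clamped at
    zero and squared.  t rather than normal quantiles, since σ is estimated.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    model._require_intervals("predict_interval")
    m = predict_sqrt(model, record)
    s = _predictive_sd(model, record)
    tq = stats.t.ppf(0.5 + level / 2.0, df=model.df_resid)
    lo = max(0.0, m - tq * s)
    hi = max(0.0, m + tq * s)
    return lo * lo, hi * hi


def prob_below_threshold(
    model: FittedModel, record: PatientRecord, cutoff: float = 50.0
) -> float:
    """P(true GFR < cutoff mL/min) under the fitted predictive distribution.

    Computed on the √ scale: P(t_{n−p} < (√cutoff − βᵀx)/√(σ²(1+leverage))).
    """
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    model._require_intervals("prob_below_threshold")
    m = predict_sqrt(model, record)
    s = _predictive_sd(model, record)
    if s == 0.0:
        return float(math.sqrt(cutoff) > m)
    z = (math.sqrt(cutoff) - m) / s
    return float(stats.t.cdf(z, df=model.df_resid))


def predict(
    model: FittedModel,
    record: PatientRecord,
    level: float = 0.95,
    cutoff: float = 50.0,
) -> PredictionResult:
    """Full per-patient prediction: point, interval and P(GFR < cutoff)."""
    lo, hi = predict_interval(model, record, level)
    return PredictionResult(
        egfr_point=predict_point(model, record),
        interval_low=lo,
        interval_high=hi,
        level=level,
        prob_below_cutoff=prob_below_threshold(model, record, cutoff),
        cutoff=cutoff,
    )


def save_model(model: FittedModel, path: str | Path) -> None:
    """Serialize a model as versioned JSON (coefficients named by term)."""
    doc = {
        "format_version": SERIALIZATION_VERSION,
        "beta": {name: float(b) for name, b in zip(model.term_names, model.beta)},
        "term_order": list(model.term_names),
        "creatinine_unit": model.creatinine_unit,
        "sigma2": model.sigma2,
        "n_obs": model.n_obs,
        "xtx_inverse": (
            None if model.xtx_inverse is None else model.xtx_inverse.tolist()
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> FittedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model file version {doc.get('format_version')!r}")
    order = tuple(doc["term_order"])
    beta = np.array([doc["beta"][name] for name in order])
    xtx = doc.get("xtx_inverse")
    return FittedModel(
        beta=beta,
        term_names=order,
        creatinine_unit=normalize_unit(doc["creatinine_unit"]),
        sigma2=doc.get("sigma2"),
        n_obs=doc.get("n_obs"),
        xtx_inverse=None if xtx is None else np.asarray(xtx, dtype=float),
    )
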