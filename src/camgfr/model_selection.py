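"""Model-development machinery: response transform and term selection.

Covers the development pipeline for the √GFR model:

* **Box-Cox**: profile log-likelihood of the power family over a λ grid for
  a given linear model, used to choose the response scale (λ̂ ≈ 0.5 on data
  whose truth is linear on the square-root scale).
* **Selection criteria**: BIC, leave-one-out CV via the leverage (PRESS)
  shortcut, and k-fold CV with a seeded partition — all scored on the
  √-response scale, lower is better.
* **Forward stepwise search** from the intercept-only (null) model,
  honoring term hierarchy (a power or interaction may enter only after its
  parents), with repeated runs over independent fold partitions and a modal
  model report.
* **Diagnostics**: Cook's distances and a Breusch-Pagan heteroscedasticity
  test for the fitted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.diagnostic import het_breuschpagan

from camgfr import constants
from camgfr.cam_model import FittedModel, FittingError, build_design_matrix
from camgfr.data_model import Cohort
from camgfr.terms import DEFAULT_POOL, INTERCEPT, TERMS

__all__ = [
    "ModelSpec",
    "SelectionReport",
    "DiagnosticsReport",
    "box_cox_lambda",
    "criterion_score",
    "stepwise_select",
    "repeated_selection",
    "regression_diagnostics",
]

CRITERIA = ("bic", "loocv", "kfold")


@dataclass(frozen=True)
class ModelSpec:
    """An ordered set of design terms; the intercept is always implicit."""

    terms: tuple[str, ...] = ()

    def __post_init__(self):
        unknown = [t for t in self.terms if t not in TERMS]
        if unknown:
            raise ValueError(f"unknown term(s): {unknown}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"duplicate terms in {self.terms}")
        present = set(self.terms)
        for t in self.terms:
            missing = [p for p in TERMS[t].parents if p not in present]
            if missing:
                raise ValueError(
                    f"term {t!r} requires lower-order parent(s) {missing}"
                )

    def with_term(self, name: str) -> "ModelSpec":
        return ModelSpec(self.terms + (name,))

    @property
    def key(self) -> str:
        """Order-insensitive identity used for frequency tables."""
        return "+".join([INTERCEPT] + sorted(self.terms))

    def admissible_additions(self, pool: Sequence[str]) -> list[str]:
        present = set(self.terms)
        return [
            t
            for t in pool
            if t not in present and all(p in present for p in TERMS[t].parents)
        ]


@dataclass
class SelectionReport:
    """Outcome of (repeated) stepwise selection."""

    criterion: str
    chosen: ModelSpec
    frequencies: dict[str, int]
    trajectories: list[list[tuple[str, float]]]
    seeds: list[int]
    box_cox_lambda: float | None = None

    @property
    def reps(self) -> int:
        return sum(self.frequencies.values())


def _design_and_response(
    cohort: Cohort, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    y = np.sqrt(cohort.measured_gfr)
    X = build_design_matrix(cohort, spec.terms, constants.MODEL_CREATININE_UNIT)
    return X, y


def _ols_rss_and_hat(X: np.ndarray, y: np.ndarray):
    """Least-squares fit returning (beta, residuals, leverages, RSS)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise FittingError(f"rank-deficient design (rank {rank} < {p})")
    resid = y - X @ beta
    Q, _ = np.linalg.qr(X)
    hat = np.einsum("ij,ij->i", Q, Q)
    return beta, resid, hat, float(resid @ resid)


def box_cox_lambda(
    cohort: Cohort,
    spec: ModelSpec = ModelSpec(),
    grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Box-Cox transformation exponent for the linear model's response.

    For each λ on the grid the response is transformed by
    (y^λ − 1)/λ (λ ≠ 0; ln y at λ = 0), the linear model in `spec` is fit by
    OLS, and the profile log-likelihood

        ℓ(λ) = −(n/2)·ln(RSS_λ/n) + (λ − 1)·Σ ln y

    is evaluated.  Returns the maximizing λ and the (λ, ℓ) profile as an
    array of shape (len(grid), 2).  λ̂ ≈ 0.5 indicates a square-root
    response scale.
    """
    y = cohort.measured_gfr
    if not np.all(y > 0):
        raise ValueError("Box-Cox requires strictly positive responses")
    if float(np.var(y)) == 0.0:
        raise ValueError("degenerate response: zero variance")
    if grid is None:
        grid = np.arange(-1.0, 2.0 + 1e-9, 0.02)
    X = build_design_matrix(cohort, spec.terms, constants.MODEL_CREATININE_UNIT)
    n = len(y)
    log_y_sum = float(np.sum(np.log(y)))
    prof = np.empty((len(grid), 2))
    for i, lam in enumerate(grid):
        z = np.log(y) if abs(lam) < 1e-12 else (y**lam - 1.0) / lam
        _, _, _, rss = _ols_rss_and_hat(X, z)
        prof[i] = (lam, -0.5 * n * math.log(rss / n) + (lam - 1.0) * log_y_sum)
    best = int(np.argmax(prof[:, 1]))
    return float(prof[best, 0]), prof


def _kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def criterion_score(
    cohort: Cohort,
    spec: ModelSpec,
    criterion: str = "bic",
    k: int = 5,
    seed: int = 0,
) -> float:
    """Score a candidate model on the √ response scale; lower is better.

    * ``bic``: n·ln(RSS/n) + p·ln(n) (constant terms dropped, so scores are
      comparable only within one cohort).
    * ``loocv``: PRESS/n via the leverage shortcut (eᵢ/(1−hᵢᵢ))² — exactly
      the explicit leave-one-out refit, with no refitting loop.
    * ``kfold``: mean held-out squared error over a seeded k-fold partition.
    """
    X, y = _design_and_response(cohort, spec)
    n, p = X.shape
    if n <= p + 1:
        raise FittingError(f"need n > p + 1 (n={n}, p={p})")
    if criterion == "bic":
        _, _, _, rss = _ols_rss_and_hat(X, y)
        return float(n * math.log(rss / n) + p * math.log(n))
    if criterion == "loocv":
        _, resid, hat, _ = _ols_rss_and_hat(X, y)
        press = np.sum((resid / (1.0 - hat)) ** 2)
        return float(press / n)
    if criterion == "kfold":
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        folds = _kfold_indices(n, k, seed)
        sse = 0.0
        for f, idx in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            beta, _, rank, _ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
            if rank < p:
                raise FittingError(f"rank-deficient design in fold {f}")
            err = y[idx] - X[idx] @ beta
            sse += float(err @ err)
        return sse / n
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")


def stepwise_select(
    cohort: Cohort,
    pool: Sequence[str] = DEFAULT_POOL,
    criterion: str = "bic",
    k: int = 5,
    seed: int = 0,
    trajectory: list[tuple[str, float]] | None = None,
) -> ModelSpec:
    """Greedy forward search from the intercept-only (null) model.

    At each step the admissible term (hierarchy respected) that most
    improves the criterion is added; the search stops when no addition
    strictly improves.  Ties break toward the earliest term in pool order.
    An empty pool returns the null model.
    """
    spec = ModelSpec()
    score = criterion_score(cohort, spec, criterion, k, seed)
    if trajectory is not None:
        trajectory.append((INTERCEPT, score))
    while True:
        best_term, best_score = None, score
        for t in spec.admissible_additions(pool):
            s = criterion_score(cohort, spec.with_term(t), criterion, k, seed)
            if s < best_score:
                best_term, best_score = t, s
        if best_term is None:
            return spec
        spec, score = spec.with_term(best_term), best_score
        if trajectory is not None:
            trajectory.append((best_term, best_score))


def _child_seed(master: int, rep: int) -> int:
    # deterministic fan-out; kept below 2^31 for portability
    return int(np.random.SeedSequence([master, rep]).generate_state(1)[0] % (2**31))


def repeated_selection(
    cohort: Cohort,
    reps: int = 2000,
    criterion: str = "kfold",
    k: int = 5,
    seed: int = 0,
    pool: Sequence[str] = DEFAULT_POOL,
) -> SelectionReport:
    """Run stepwise selection over `reps` independent fold partitions.

    The random component of the k-fold criterion makes single selections
    noisy; the modal model over many repetitions is taken forward.  Child
    seeds are derived deterministically from the master seed and reported.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    freqs: dict[str, int] = {}
    specs: dict[str, ModelSpec] = {}
    trajectories: list[list[tuple[str, float]]] = []
    seeds = [_child_seed(seed, r) for r in range(reps)]
    for s in seeds:
        traj: list[tuple[str, float]] = []
        spec = stepwise_select(cohort, pool, criterion, k, s, trajectory=traj)
        freqs[spec.key] = freqs.get(spec.key, 0) + 1
        specs.setdefault(spec.key, spec)
        trajectories.append(traj)
    modal_key = max(freqs, key=lambda kk: (freqs[kk], -list(freqs).index(kk)))
    return SelectionReport(
        criterion=criterion,
        chosen=specs[modal_key],
        frequencies=freqs,
        trajectories=trajectories,
        seeds=seeds,
    )


@dataclass
class DiagnosticsReport:
    """Per-record influence and a heteroscedasticity check."""

    cooks_distance: np.ndarray
    leverage: np.ndarray
    flagged: list[str]
    cooks_threshold: float
    bp_statistic: float
    bp_pvalue: float

    @property
    def max_cooks_distance(self) -> float:
        return float(np.max(self.cooks_distance))


def regression_diagnostics(
    model: FittedModel, cohort: Cohort, cooks_threshold: float = 0.5
) -> DiagnosticsReport:
    """Cook's distances and a Breusch-Pagan test for the fitted model.

    Cook's distance Dᵢ = eᵢ²·hᵢᵢ / (p·σ̂²·(1−hᵢᵢ)²) flags influential
    records; the Breusch-Pagan auxiliary regression of squared residuals on
    the design tests the constant-variance assumption the predictive
    intervals rely on.
    """
    X, y = (
        build_design_matrix(cohort, model.term_names[1:], model.creatinine_unit),
        np.sqrt(cohort.measured_gfr),
    )
    n, p = X.shape
    resid = y - X @ model.beta
    Q, _ = np.linalg.qr(X)
    hat = np.einsum("ij,ij->i", Q, Q)
    sigma2 = float(resid @ resid) / (n - p)
    cooks = resid**2 * hat / (p * sigma2 * (1.0 - hat) ** 2)
    lm, lm_pvalue, _, _ = het_breuschpagan(resid, X)
    flagged = [
        cohort.records[i].patient_id for i in np.nonzero(cooks > cooks_threshold)[0]
    ]
    return DiagnosticsReport(
        cooks_distance=cooks,
        leverage=hat,
        flagged=flagged,
        cooks_threshold=cooks_threshold,
        bp_statistic=float(lm),
        bp_pvalue=float(lm_pvalue),
    )
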