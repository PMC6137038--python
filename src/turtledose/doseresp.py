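"""Dose-response products: mortality curves, point predictions, inversions.

Everything here works off logistic coefficients produced by the Monte Carlo
ensemble (typically its medians).  The headline quantities are

* the mortality-vs-load curve for a reference animal, with a pointwise
  min/max envelope over all Monte Carlo replicates;
* the load at which the mortality probability reaches a target (the 50%
  point is the ED50);
* the population ED50 — the load at which the *cohort-averaged* predicted
  mortality, mixing over each animal's CCL and age class, reaches 50%;
* "near-certain death": since a logistic curve never reaches exactly 1, the
  load where p first exceeds ``1 - tol`` (default tol 5e-3) stands in for
  probability 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .intervals import MCEnsemble, _as_frame
from .records import AGE4_CLASSES

NEAR_CERTAIN_TOL = 5e-3


@dataclass(frozen=True)
class PredictionContext:
    """Reference animal for curve prediction: the cohort's median CCL and
    its most common age class by default."""

    ccl_cm: float = 43.5
    age_class: str = "juvenile"
    load_grid: tuple[int, ...] = tuple(range(0, 251))

    def __post_init__(self):
        if not self.ccl_cm > 0:
            raise ValueError("ccl_cm must be positive")
        if self.age_class not in AGE4_CLASSES:
            raise ValueError(f"unknown age class {self.age_class!r}")
        grid = np.asarray(self.load_grid, float)
        if len(grid) and np.any(np.diff(grid) <= 0):
            raise ValueError("load_grid must be strictly increasing")
        if len(grid) and grid[0] < 0:
            raise ValueError("load_grid must be non-negative")


@dataclass
class DoseResponseCurve:
    context: PredictionContext
    p_median: np.ndarray
    p_lo: np.ndarray
    p_hi: np.ndarray
    source_label: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "load": list(self.context.load_grid),
            "p_median": self.p_median, "p_lo": self.p_lo,
            "p_hi": self.p_hi})


def _design_row(terms, context: PredictionContext, load: float) -> np.ndarray:
    """Design row for the reference animal at a given load, matching the
    ensemble's coefficient names."""
    row = np.zeros(len(terms))
    for i, t in enumerate(terms):
        if t == "intercept":
            row[i] = 1.0
        elif t == "debris_count":
            row[i] = load
        elif t == "ccl_cm":
            row[i] = context.ccl_cm
        elif t == "load_per_ccl":
            row[i] = load / context.ccl_cm
        elif t == "nw_residual":
            row[i] = 0.0  # average item-size mix
        elif t.startswith("age4["):
            row[i] = 1.0 if t == f"age4[{context.age_class}]" else 0.0
        else:
            raise ValueError(f"cannot evaluate design term {t!r}")
    return row


def _check_age(terms, context: PredictionContext) -> None:
    age_terms = [t for t in terms if t.startswith("age4[")]
    if age_terms and f"age4[{context.age_class}]" not in terms \
            and context.age_class != "adult":
        raise ValueError(
            f"age class {context.age_class!r} absent from the ensemble "
            "coefficients; it was not in the fitted data")


def predict_curve(ensemble: MCEnsemble, context: PredictionContext
                  ) -> DoseResponseCurve:
    """Median curve plus the pointwise min/max envelope over replicates."""
    terms = list(ensemble.median_coefficients.index)
    _check_age(terms, context)
    grid = np.asarray(context.load_grid, float)
    G = np.stack([_design_row(terms, context, L) for L in grid])
    B = ensemble.coef_matrix[terms].to_numpy(float)       # reps x k
    P = expit(G @ B.T)                                    # grid x reps
    p_median = expit(G @ ensemble.median_coefficients.to_numpy(float))
    return DoseResponseCurve(
        context=context, p_median=p_median,
        p_lo=P.min(axis=1), p_hi=P.max(axis=1),
        source_label=ensemble.spec.label)


def _linear_predictor(coefficients: pd.Series, context: PredictionContext
                      ) -> tuple[float, float]:
    """eta(load) = a + b * load for the reference animal."""
    terms = list(coefficients.index)
    _check_age(terms, context)
    beta = coefficients.to_numpy(float)
    a = float(_design_row(terms, context, 0.0) @ beta)
    b = float(_design_row(terms, context, 1.0) @ beta) - a
    return a, b


def mortality_at_load(coefficients: pd.Series, context: PredictionContext,
                      load: float) -> float:
    """Predicted probability of death due to plastic at a given load."""
    if load < 0:
        raise ValueError("load must be non-negative")
    a, b = _linear_predictor(coefficients, context)
    return float(expit(a + b * load))


def invert_for_probability(coefficients: pd.Series,
                           context: PredictionContext,
                           p_target: float,
                           tolerance: float = NEAR_CERTAIN_TOL) -> float:
    """Load (real-valued items) at which mortality reaches ``p_target``.

    Closed form: the linear predictor is affine in load.  Targets within
    ``tolerance`` of 1 are read as "numerically certain death" and solved at
    ``1 - tolerance``.  Requires a positive load coefficient.  Callers
    wanting whole "pieces" should round up.
    """
    if not 0.0 < p_target <= 1.0:
        raise ValueError("p_target must lie in (0, 1]")
    p_eff = min(p_target, 1.0 - tolerance)
    a, b = _linear_predictor(coefficients, context)
    if b <= 0:
        raise ValueError(
            "load coefficient is non-positive; the mortality curve does not "
            "increase with load")
    return float((logit(p_eff) - a) / b)


def load_at_near_certain_death(coefficients: pd.Series,
                               context: PredictionContext,
                               tolerance: float = NEAR_CERTAIN_TOL) -> float:
    """First load at which p >= 1 - tolerance (exact 1 is unattainable)."""
    return invert_for_probability(coefficients, context, 1.0 - tolerance,
                                  tolerance=tolerance)


def population_ed50(ensemble: MCEnsemble, records,
                    max_load: float = 1e6) -> float:
    """Load at which the cohort-averaged predicted mortality reaches 50%.

    Averages the per-animal curves over the observed mix of CCL and age
    classes (median ensemble coefficients), then solves for the crossing by
    monotone bisection.
    """
    df = _as_frame(records).reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no records to average over")
    contexts = [PredictionContext(ccl_cm=float(r.ccl_cm), age_class=r.age4,
                                  load_grid=(0,))
                for r in df.itertuples()]
    ab = np.array([_linear_predictor(ensemble.median_coefficients, c)
                   for c in contexts])
    a, b = ab[:, 0], ab[:, 1]
    if np.all(b <= 0):
        raise ValueError("no animal has a positive load slope; the averaged "
                         "curve cannot reach 0.5")

    def avg(load: float) -> float:
        return float(np.mean(expit(a + b * load)))

    if avg(0.0) >= 0.5:
        return 0.0
    if avg(max_load) < 0.5:
        raise ValueError(
            f"cohort-averaged mortality never reaches 0.5 on [0, {max_load}]"
            f"; maximum attained is {avg(max_load):.4f}")
    return float(brentq(lambda L: avg(L) - 0.5, 0.0, max_load,
                        xtol=1e-10, rtol=1e-12))
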