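"""Interval-valued mortality labels and the Monte Carlo logistic estimator.

Whether a necropsied turtle died *because of* its ingested plastic is only
partially observed.  Each cause-of-death category maps to an interval on the
probability that death was due to plastic:

* ``KNP`` (known, non-plastic) -> [0, 0] — the statistical control group;
* ``KP``  (known, plastic)     -> [1, 1] (or [0, 1] under the conservative
  variant that allows KP misclassification);
* ``Ukn`` and ``Ind``          -> [0, 1].

The dose-response is a logistic regression of this partially observed
response on the debris load.  Records with a point-valued interval enter
with a fixed 0/1 response; for every [0, 1] record a response is drawn
uniformly on (0, 1), the model is fit, and the draw-and-fit cycle is
repeated (1,000 times by default), yielding an ensemble of coefficient
estimates whose median and min/max envelope summarise the relationship and
its labelling uncertainty.

Fractional responses enter through the Bernoulli-form log-likelihood
``sum(y log p + (1 - y) log(1 - p))`` with ``p = logistic(X b)``, which is
linear in ``y`` and therefore identical to splitting each fractional record
into a weighted pair of 0/1 records (the "fractional logit" convention);
AIC is defined from this likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .records import AGE4_CLASSES, CAUSES, necropsy_frame

DOSE_MODEL_CODES = ("M1", "M2", "M3")

#: Load-term (dose) column per model: M1/M2 use the raw item count with CCL
#: as a separate covariate; M3 uses items per cm of CCL with age class.
LOAD_TERM = {"M1": "debris_count", "M2": "debris_count",
             "M3": "load_per_ccl"}

_SEPARATION_BOUND = 20.0
_MAX_FAILURE_SHARE = 0.05


@dataclass(frozen=True)
class IntervalLabel:
    """Bounds on the probability that a death was due to plastic."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (0.0 <= self.lo <= self.hi <= 1.0):
            raise ValueError(f"invalid interval [{self.lo}, {self.hi}]")

    @property
    def resolved(self) -> bool:
        return self.lo == self.hi


@dataclass(frozen=True)
class DoseModelSpec:
    """One of the three candidate dose-response models, optionally under the
    conservative (KP -> [0,1]) relabelling."""

    code: str
    conservative: bool = False

    def __post_init__(self):
        if self.code not in DOSE_MODEL_CODES:
            raise ValueError(f"unknown dose model code {self.code!r}")

    @property
    def load_term(self) -> str:
        return LOAD_TERM[self.code]

    @property
    def label(self) -> str:
        return self.code[1] + ("b" if self.conservative else "a")


def assign_interval(cod: str, conservative: bool = False) -> IntervalLabel:
    """Interval label for one cause-of-death category."""
    if cod not in CAUSES:
        raise ValueError(f"unknown cause of death {cod!r}")
    if cod == "KNP":
        return IntervalLabel(0.0, 0.0)
    if cod == "KP":
        return IntervalLabel(0.0, 1.0) if conservative else IntervalLabel(
            1.0, 1.0)
    return IntervalLabel(0.0, 1.0)  # Ukn, Ind


def nw_residuals(records) -> pd.DataFrame:
    """Number-weight residuals: an item-size-mix index per record.

    OLS of total debris mass on item count over records with >= 1 item and a
    recorded mass; residuals are mean-zero over those records by
    construction.  Ineligible records get residual 0 with
    ``nw_eligible = False``.
    """
    df = _as_frame(records)
    mass = pd.to_numeric(df["debris_mass_g"], errors="coerce")
    eligible = (df["debris_count"] >= 1) & mass.notna()
    n_eligible = int(eligible.sum())
    if n_eligible < 3:
        raise ValueError(
            f"need >= 3 records with debris and recorded mass to identify "
            f"the number-weight relationship, got {n_eligible}")
    x = df.loc[eligible, "debris_count"].to_numpy(float)
    y = mass[eligible].to_numpy(float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = pd.Series(0.0, index=df.index)
    resid[eligible] = y - X @ beta
    return pd.DataFrame({"nw_residual": resid, "nw_eligible": eligible})


@dataclass
class FractionalLogitFit:
    """A maximum-likelihood fractional-logit fit."""

    coefficients: pd.Series
    std_errors: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool
    separated: bool
    n_iter: int


def fit_fractional_logistic(design, response,
                            weights: Sequence[float] | None = None,
                            max_iter: int = 100,
                            tol: float = 1e-12) -> FractionalLogitFit:
    """Newton-Raphson fit of the fractional logit.

    ``design`` is a full-rank matrix (DataFrame columns become coefficient
    names); ``response`` takes values in [0, 1].  Perfect separation is
    flagged (iterations capped) rather than raised; rank deficiency is an
    error.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(float)
    else:
        X = np.asarray(design, float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(response, float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("response values must lie in [0, 1]")
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("response length does not match design rows")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")

    def loglik(beta):
        eta = X @ beta
        # numerically stable: y*log p + (1-y)*log(1-p) = y*eta - log(1+e^eta)
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    beta = np.zeros(k)
    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        grad = X.T @ (w * (y - p))
        wvar = w * p * (1.0 - p)
        hess = X.T @ (X * wvar[:, None])
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            break
        # step-halving line search keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            new = beta + scale * step
            ll_new = loglik(new)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        beta, ll_prev, ll = new, ll, ll_new
        if (np.max(np.abs(scale * step)) < tol * (1 + np.max(np.abs(beta)))
                or abs(ll - ll_prev) < tol * (1 + abs(ll))):
            converged = True
            break

    separated = bool(np.max(np.abs(beta)) > _SEPARATION_BOUND)
    p = expit(X @ beta)
    wvar = w * p * (1.0 - p)
    hess = X.T @ (X * wvar[:, None])
    try:
        cov = np.linalg.inv(hess + 1e-300 * np.eye(k))
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return FractionalLogitFit(
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        log_likelihood=ll, aic=2 * k - 2 * ll, n_obs=n,
        converged=converged and not separated, separated=separated,
        n_iter=it)


def build_dose_design(df: pd.DataFrame, spec: DoseModelSpec
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix for one dose model plus the row-inclusion mask.

    M1: intercept + count + CCL.  M2: M1 + number-weight residual (records
    with uncounted mass among debris-positive animals are excluded).  M3:
    intercept + count/CCL + age-class dummies (adult reference).
    """
    include = pd.Series(True, index=df.index)
    if spec.code in ("M1", "M2"):
        cols = {"intercept": np.ones(len(df)),
                "debris_count": df["debris_count"].to_numpy(float),
                "ccl_cm": df["ccl_cm"].to_numpy(float)}
        if spec.code == "M2":
            mass = pd.to_numeric(df["debris_mass_g"], errors="coerce")
            include = ~((df["debris_count"] >= 1) & mass.isna())
            nw = nw_residuals(df)
            cols["nw_residual"] = nw["nw_residual"].to_numpy(float)
        X = pd.DataFrame(cols, index=df.index)
    else:
        cols = {"intercept": np.ones(len(df)),
                "load_per_ccl": (df["debris_count"]
                                 / df["ccl_cm"]).to_numpy(float)}
        present = [a for a in AGE4_CLASSES if (df["age4"] == a).any()]
        ref = "adult" if "adult" in present else present[0]
        for a in present:
            if a != ref:
                cols[f"age4[{a}]"] = (df["age4"] == a).to_numpy(float)
        X = pd.DataFrame(cols, index=df.index)
    return X[include], include


@dataclass
class MCEnsemble:
    """Per-replicate fits from the Monte Carlo procedure plus summaries.

    ``coef_matrix`` holds one row per successful replicate (term columns);
    medians/envelopes are exact recomputations from it.
    """

    spec: DoseModelSpec
    coef_matrix: pd.DataFrame
    replicate_stats: pd.DataFrame   # rep, slope fields, loglik, aic
    median_coefficients: pd.Series
    envelope_lo: pd.Series
    envelope_hi: pd.Series
    mean_aic: float
    median_aic: float
    n_reps: int
    n_failed: int
    seed: int
    n_excluded: int = 0             # rows dropped (M2 missing mass)
    share_slope_significant: float = np.nan

    def summary_dict(self) -> dict:
        return {
            "model": self.spec.label,
            "code": self.spec.code,
            "conservative": self.spec.conservative,
            "median_coefficients": self.median_coefficients.to_dict(),
            "envelope_lo": self.envelope_lo.to_dict(),
            "envelope_hi": self.envelope_hi.to_dict(),
            "mean_aic": self.mean_aic,
            "median_aic": self.median_aic,
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
            "n_excluded": self.n_excluded,
            "seed": self.seed,
            "share_slope_significant": self.share_slope_significant,
            "draws_shared_across_specs": True,
            "aic_aggregation": "mean (median also reported)",
        }


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return necropsy_frame(records)


def _interval_bounds(df: pd.DataFrame, conservative: bool
                     ) -> tuple[np.ndarray, np.ndarray]:
    labels = [assign_interval(c, conservative) for c in df["cod"]]
    lo = np.array([l.lo for l in labels])
    hi = np.array([l.hi for l in labels])
    return lo, hi


def _replicate_draws(seed: int, rep: int, n: int) -> np.ndarray:
    """Uniform draws for replicate ``rep``; reproducible given (seed, rep)."""
    return np.random.default_rng([seed, rep]).uniform(size=n)


def mc_fit(records, spec: DoseModelSpec, n_reps: int = 1000,
           seed: int = 0) -> MCEnsemble:
    """Monte Carlo ensemble of fractional-logit dose-response fits."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    df = _as_frame(records).reset_index(drop=True)
    ensembles = _mc_ensembles(df, [spec], n_reps, seed)
    return ensembles[0]


def _mc_ensembles(df: pd.DataFrame, specs: list[DoseModelSpec],
                  n_reps: int, seed: int) -> list[MCEnsemble]:
    """Shared-draw Monte Carlo over several specs (paired comparisons).

    One uniform stream per replicate is drawn over the full record set and
    subset to each spec's included rows, so AIC differences between specs
    within a replicate reflect the model, not the draws.
    """
    lo_by_cons: dict[bool, np.ndarray] = {}
    hi_by_cons: dict[bool, np.ndarray] = {}
    designs, includes = [], []
    for spec in specs:
        if spec.conservative not in lo_by_cons:
            lo, hi = _interval_bounds(df, spec.conservative)
            lo_by_cons[spec.conservative] = lo
            hi_by_cons[spec.conservative] = hi
        X, include = build_dose_design(df, spec)
        designs.append(X)
        includes.append(include.to_numpy())

    results: list[dict] = [{"coefs": [], "stats": []} for _ in specs]
    # the widest uncertain set (conservative if any spec uses it) fixes the
    # draw vector length so draws stay aligned across specs
    any_cons = any(s.conservative for s in specs)
    if any_cons and True not in lo_by_cons:
        lo_by_cons[True], hi_by_cons[True] = _interval_bounds(df, True)
    master_unres = (lo_by_cons[any_cons] < hi_by_cons[any_cons])

    for r in range(n_reps):
        u = _replicate_draws(seed, r, int(master_unres.sum()))
        u_full = np.zeros(len(df))
        u_full[master_unres] = u
        for j, spec in enumerate(specs):
            lo = lo_by_cons[spec.conservative]
            hi = hi_by_cons[spec.conservative]
            unres = lo < hi
            y = lo.astype(float).copy()
            y[unres] = u_full[unres]
            inc = includes[j]
            try:
                fit = fit_fractional_logistic(designs[j], y[inc])
                if not np.all(np.isfinite(fit.coefficients)):
                    raise FloatingPointError("non-finite coefficients")
            except (ValueError, FloatingPointError):
                results[j]["stats"].append(
                    {"rep": r, "failed": True})
                continue
            load = spec.load_term
            slope = float(fit.coefficients[load])
            slope_se = float(fit.std_errors[load])
            slope_p = float(2 * stats.norm.sf(abs(slope / slope_se))) \
                if slope_se > 0 else 0.0
            results[j]["coefs"].append(
                fit.coefficients.rename(r))
            results[j]["stats"].append({
                "rep": r, "failed": False, "slope_estimate": slope,
                "slope_se": slope_se, "slope_p_value": slope_p,
                "log_likelihood": fit.log_likelihood, "aic": fit.aic,
                "separated": fit.separated})

    out = []
    for j, spec in enumerate(specs):
        stats_df = pd.DataFrame(results[j]["stats"])
        n_failed = int(stats_df["failed"].sum())
        if n_failed > _MAX_FAILURE_SHARE * n_reps:
            raise RuntimeError(
                f"{spec.label}: {n_failed}/{n_reps} Monte Carlo replicates "
                "failed rank/fit checks; the design is unstable for these "
                "records")
        coef = pd.DataFrame(results[j]["coefs"])
        ok = stats_df[~stats_df["failed"]]
        share_sig = float((ok["slope_p_value"] < 0.05).mean())
        out.append(MCEnsemble(
            spec=spec, coef_matrix=coef, replicate_stats=stats_df,
            median_coefficients=coef.median(axis=0),
            envelope_lo=coef.min(axis=0), envelope_hi=coef.max(axis=0),
            mean_aic=float(ok["aic"].mean()),
            median_aic=float(ok["aic"].median()),
            n_reps=n_reps, n_failed=n_failed, seed=seed,
            n_excluded=int((~includes[j]).sum()),
            share_slope_significant=share_sig))
    return out


def mc_model_selection(records, specs: list[DoseModelSpec],
                       n_reps: int = 1000, seed: int = 0
                       ) -> tuple[pd.DataFrame, list[MCEnsemble]]:
    """Mean-AIC comparison of dose models under shared per-replicate draws.

    Standard ("a") and conservative ("b") variants are ranked separately —
    their responses come from different labelled data, so their AICs are not
    comparable.
    """
    if not specs:
        raise ValueError("no specs supplied")
    df = _as_frame(records).reset_index(drop=True)
    ensembles = _mc_ensembles(df, specs, n_reps, seed)
    rows = [{"model": e.spec.label, "code": e.spec.code,
             "conservative": e.spec.conservative, "mean_aic": e.mean_aic,
             "median_aic": e.median_aic, "n_failed": e.n_failed,
             "n_excluded": e.n_excluded}
            for e in ensembles]
    table = pd.DataFrame(rows)
    parts = []
    for cons, grp in table.groupby("conservative", sort=True):
        grp = grp.sort_values("mean_aic", kind="mergesort").copy()
        grp["delta_aic"] = grp["mean_aic"] - grp["mean_aic"].iloc[0]
        grp["significant"] = grp["delta_aic"] >= 2.0
        parts.append(grp)
    return pd.concat(parts, ignore_index=True), ensembles
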