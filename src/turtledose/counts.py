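"""Negative-binomial regression of ingested-debris counts on cause of death.

Debris counts in necropsied turtles are strongly over-dispersed, so the
count model uses a negative-binomial (NB2) error with a log link.  Candidate
models combine cause of death (C), age class (A) and species (S); they are
ranked by AIC, and the hypothesised ordering of the cause coefficients
(Ukn & KNP < Ind < KP) is tested with Holm-corrected pairwise Wald
contrasts summarised as a compact letter display.

The dispersion ("size") parameter is estimated jointly by maximum
likelihood.  A fixed dispersion can be supplied instead; ``size = inf`` is
the Poisson limit, used as a closed-form cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import contrasts as ct
from .records import AGE4_CLASSES, CAUSES, SPECIES, necropsy_frame

#: Model codes: 0 intercept-only, C cause of death, A age class, S species;
#: "CA:S" adds the cause x age-class interaction to the three main effects.
MODEL_CODES = ("0", "C", "CA", "CS", "CAS", "CA:S")

_TERMS_BY_CODE = {
    "0": frozenset({"intercept"}),
    "C": frozenset({"intercept", "cause"}),
    "CA": frozenset({"intercept", "cause", "age_class"}),
    "CS": frozenset({"intercept", "cause", "species"}),
    "CAS": frozenset({"intercept", "cause", "age_class", "species"}),
    "CA:S": frozenset({"intercept", "cause", "age_class", "species",
                       "cause:age_class"}),
}

# flagged, not fatal: mirrors factor levels with (quasi-)complete separation
SEPARATION_COEF = 20.0
SEPARATION_SE = 1e3


@dataclass(frozen=True)
class CountModelSpec:
    """A candidate count model, identified by its short code."""

    code: str

    def __post_init__(self):
        if self.code not in MODEL_CODES:
            raise ValueError(f"unknown model code {self.code!r}; "
                             f"expected one of {MODEL_CODES}")

    @property
    def terms(self) -> frozenset[str]:
        return _TERMS_BY_CODE[self.code]


@dataclass(frozen=True)
class ReferenceLevels:
    """Reference (baseline) levels for the factor codings.

    Defaults: cause = first alphabetical KP-absent level (Ind), age = adult,
    species = green.
    """

    cause: str = "Ind"
    age: str = "adult"
    species: str = "green"


@dataclass
class CountModelFit:
    spec: CountModelSpec
    coefficients: pd.Series
    std_errors: pd.Series
    cov: pd.DataFrame
    dispersion: float            # NB size parameter (1/alpha); inf = Poisson
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool
    separation_flags: tuple[str, ...]
    refs: ReferenceLevels
    n_params: int                # coefficients + 1 for estimated dispersion
    cause_levels: tuple[str, ...] = ()   # observed levels, model order
    cause_ref: str | None = None         # effective reference level
    _design: pd.DataFrame = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)


def _effective_ref(present: list[str], preferred: str) -> str:
    """The configured reference if observed, else the first observed level
    (keeps the dummy coding full rank when a level is absent)."""
    return preferred if preferred in present else present[0]


def build_count_design(df: pd.DataFrame, spec: CountModelSpec,
                       refs: ReferenceLevels = ReferenceLevels()
                       ) -> pd.DataFrame:
    """Dummy-coded design matrix over the factor levels observed in the
    data; absent levels contribute no column."""
    n = len(df)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    terms = spec.terms
    cause_present = [c for c in CAUSES if (df["cod"] == c).any()]
    age_present = [a for a in AGE4_CLASSES if (df["age4"] == a).any()]
    cause_ref = _effective_ref(cause_present, refs.cause)
    age_ref = _effective_ref(age_present, refs.age)
    if "cause" in terms:
        for c in cause_present:
            if c != cause_ref:
                cols[f"cause[{c}]"] = (df["cod"] == c).to_numpy(float)
    if "age_class" in terms:
        for a in age_present:
            if a != age_ref:
                cols[f"age4[{a}]"] = (df["age4"] == a).to_numpy(float)
    if "species" in terms:
        sp_present = [s for s in SPECIES if (df["species"] == s).any()]
        sp_ref = _effective_ref(sp_present, refs.species)
        for s in sp_present:
            if s != sp_ref:
                cols[f"species[{s}]"] = (df["species"] == s).to_numpy(float)
    if "cause:age_class" in terms:
        for c in cause_present:
            if c == cause_ref:
                continue
            for a in age_present:
                if a == age_ref:
                    continue
                cell = (df["cod"] == c) & (df["age4"] == a)
                if cell.any():
                    cols[f"cause[{c}]:age4[{a}]"] = cell.to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return necropsy_frame(records)


def fit_nb_glm(records, spec: CountModelSpec,
               refs: ReferenceLevels = ReferenceLevels(),
               fixed_dispersion: float | None = None) -> CountModelFit:
    """Maximum-likelihood NB regression of debris count with log link.

    With ``fixed_dispersion`` the size parameter is held at the given value
    (``np.inf`` gives the Poisson GLM limit) and only the regression
    coefficients are estimated; otherwise dispersion is estimated jointly.
    Non-convergence and separation are flagged on the returned fit, never
    raised.
    """
    df = _as_frame(records)
    if len(df) == 0:
        raise ValueError("no records to fit")
    y = df["debris_count"].to_numpy(float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("debris_count must be non-negative integers")
    X = build_count_design(df, spec, refs)
    names = list(X.columns)
    k = len(names)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fixed_dispersion is not None:
            if fixed_dispersion == np.inf:
                family = sm.families.Poisson()
            else:
                family = sm.families.NegativeBinomial(
                    alpha=1.0 / fixed_dispersion)
            try:
                res = sm.GLM(y, X.to_numpy(), family=family).fit(
                    maxiter=200, tol=1e-10)
                params = np.asarray(res.params)
                bse = np.asarray(res.bse)
                cov = np.asarray(res.cov_params())
                llf = float(res.llf)
                converged = bool(res.converged)
            except Exception:
                params = np.full(k, np.nan)
                bse = np.full(k, np.nan)
                cov = np.full((k, k), np.nan)
                llf = np.nan
                converged = False
            size = float(fixed_dispersion)
            n_params = k  # dispersion not estimated
        else:
            try:
                model = sm.NegativeBinomial(y, X.to_numpy(),
                                            loglike_method="nb2")
                res = model.fit(disp=0, maxiter=2000, method="bfgs")
                if not res.mle_retvals.get("converged", False):
                    res = model.fit(disp=0, maxiter=2000, method="lbfgs",
                                    start_params=res.params)
                params = np.asarray(res.params[:-1])
                alpha = float(res.params[-1])
                try:
                    bse = np.asarray(res.bse[:-1])
                    cov = np.asarray(res.cov_params())[:k, :k]
                except Exception:
                    # singular Hessian under separation: keep the fit,
                    # surface unusable uncertainty as inf
                    bse = np.full(k, np.inf)
                    cov = np.full((k, k), np.inf)
                llf = float(res.llf)
                converged = (bool(res.mle_retvals.get("converged", False))
                             and np.all(np.isfinite(params)) and alpha > 0)
                size = 1.0 / alpha if alpha > 0 else np.inf
            except Exception:
                params = np.full(k, np.nan)
                bse = np.full(k, np.nan)
                cov = np.full((k, k), np.nan)
                llf, size, converged = np.nan, np.nan, False
            n_params = k + 1

    coefficients = pd.Series(params, index=names)
    std_errors = pd.Series(bse, index=names)
    flags = tuple(n for n, b, s in zip(names, params, bse)
                  if np.isfinite(b) and abs(b) > SEPARATION_COEF
                  and (not np.isfinite(s) or s > SEPARATION_SE))
    if not converged and not flags and np.all(y == 0):
        flags = ("intercept",)  # all-zero response: dispersion unidentifiable
    aic = 2 * n_params - 2 * llf if np.isfinite(llf) else np.nan
    cause_present = tuple(c for c in CAUSES if (df["cod"] == c).any())
    cause_ref = (_effective_ref(list(cause_present), refs.cause)
                 if "cause" in spec.terms and cause_present else None)
    return CountModelFit(
        spec=spec, coefficients=coefficients, std_errors=std_errors,
        cov=pd.DataFrame(cov, index=names, columns=names),
        dispersion=size, log_likelihood=llf, aic=aic, n_obs=len(df),
        converged=converged, separation_flags=flags, refs=refs,
        n_params=n_params, cause_levels=cause_present, cause_ref=cause_ref,
        _design=X, _y=y)


def overdispersion_check(fit: CountModelFit) -> tuple[float, int, float]:
    """Pearson chi-square goodness-of-fit of the count model.

    Returns ``(statistic, df, p)`` with ``df = n - k`` residual degrees of
    freedom; variance function ``mu + mu^2 / size``.
    """
    if fit._design is None or fit._y is None:
        raise ValueError("fit carries no data; refit before checking")
    if not fit.converged:
        raise ValueError("overdispersion check requires a converged fit")
    mu = np.exp(fit._design.to_numpy() @ fit.coefficients.to_numpy())
    var = mu + (mu ** 2) / fit.dispersion if np.isfinite(fit.dispersion) \
        else mu
    dof = fit.n_obs - len(fit.coefficients)
    if dof <= 0:
        raise ValueError("zero residual degrees of freedom: saturated model")
    statistic = float(np.sum((fit._y - mu) ** 2 / var))
    p = float(stats.chi2.sf(statistic, dof))
    return statistic, dof, p


def select_by_aic(records, specs: list[CountModelSpec],
                  refs: ReferenceLevels = ReferenceLevels(),
                  ) -> tuple[pd.DataFrame, dict[str, CountModelFit]]:
    """Fit all candidate specs and rank by AIC (ties go to fewer params).

    Non-converged fits are excluded from the ranking and reported in the
    table with ``converged = False``.  A delta of >= 2 AIC units over the
    best model is flagged as a significant difference.
    """
    if len(specs) < 2:
        raise ValueError("need at least two candidate specs")
    fits = {s.code: fit_nb_glm(records, s, refs) for s in set(specs)}
    rows = [{"code": s.code, "aic": fits[s.code].aic,
             "k": fits[s.code].n_params,
             "converged": fits[s.code].converged} for s in specs]
    table = pd.DataFrame(rows)
    ok = table[table["converged"]].sort_values(
        ["aic", "k"], kind="mergesort").reset_index(drop=True)
    bad = table[~table["converged"]].reset_index(drop=True)
    if len(ok) == 0:
        raise RuntimeError("no candidate model converged")
    best = ok["aic"].iloc[0]
    ok["delta_aic"] = ok["aic"] - best
    ok["significant"] = ok["delta_aic"] >= 2.0
    bad["delta_aic"] = np.nan
    bad["significant"] = False
    out = pd.concat([ok, bad], ignore_index=True)
    return out, fits


def cause_effects(fit: CountModelFit) -> tuple[pd.Series, pd.DataFrame]:
    """Cause-of-death level effects (observed levels only) and their
    covariance; the reference level enters at 0 (main effects only under
    interaction models)."""
    if fit.cause_ref is None:
        raise ValueError("fit does not include the cause-of-death term")
    levels = list(fit.cause_levels)
    eff = pd.Series(0.0, index=levels)
    cov = pd.DataFrame(0.0, index=levels, columns=levels)
    named = [c for c in levels if f"cause[{c}]" in fit.coefficients.index]
    for c in named:
        eff[c] = fit.coefficients[f"cause[{c}]"]
    for a in named:
        for b in named:
            cov.loc[a, b] = fit.cov.loc[f"cause[{a}]", f"cause[{b}]"]
    return eff, cov


def pairwise_cause_contrasts(fit: CountModelFit, alpha: float = 0.05
                             ) -> tuple[list[ct.ContrastResult],
                                        dict[str, str]]:
    """All six Holm-adjusted pairwise cause contrasts plus letter display."""
    eff, cov = cause_effects(fit)
    results = ct.pairwise_wald(eff, cov, alpha=alpha)
    letters = ct.compact_letters(eff, results, alpha=alpha)
    return results, letters
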