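"""Presence/absence model for debris in stranding-register necropsy reports.

Stranding-register records are too coarse for counts, so debris is scored
present/absent and modelled by logistic regression on the cause-of-death
category, a binary age class (adult / not adult) and a binary examination
variable (GIT examined at any level > 0 vs. not examined).  The cause term
uses cell-means coding (no intercept absorption) so all four cause
coefficients are reported directly; their standard errors therefore refer
to cell log-odds.  Candidate models are the power set of
{cause, adult, exam} ranked by AIC, and cause levels are compared pairwise
with Holm correction and a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import contrasts as ct
from .intervals import fit_fractional_logistic
from .records import CAUSES, strandnet_frame

TERMS = ("cause", "adult", "exam_binary")


def binarize_exam(exam_level: int) -> bool:
    """True iff the GIT was examined to any level (> 0)."""
    if exam_level not in (0, 1, 2, 3):
        raise ValueError(f"exam_level must be in 0..3, got {exam_level!r}")
    return exam_level > 0


@dataclass
class PresenceModelFit:
    terms: frozenset[str]
    coefficients: pd.Series
    std_errors: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool
    separated: bool
    cause_levels: tuple[str, ...]


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return strandnet_frame(records)


def build_presence_design(df: pd.DataFrame, terms) -> pd.DataFrame:
    """Design matrix: cause in cell-means coding (one column per observed
    level, no intercept); intercept only when cause is excluded."""
    terms = frozenset(terms)
    unknown = terms - set(TERMS)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    cols: dict[str, np.ndarray] = {}
    if "cause" in terms:
        for c in CAUSES:
            mask = (df["cod"] == c)
            if mask.any():
                cols[f"cause[{c}]"] = mask.to_numpy(float)
    else:
        cols["intercept"] = np.ones(len(df))
    if "adult" in terms:
        cols["adult"] = df["adult"].to_numpy(float)
    if "exam_binary" in terms:
        cols["exam_binary"] = np.array(
            [float(binarize_exam(l)) for l in df["exam_level"]])
    return pd.DataFrame(cols, index=df.index)


def fit_presence_model(records, terms=("cause", "adult", "exam_binary")
                       ) -> PresenceModelFit:
    """Maximum-likelihood binary logistic fit of debris presence.

    Species is never a term (too few records of most species to support
    it).  Separation is flagged on the fit, not raised.
    """
    df = _as_frame(records)
    if len(df) == 0:
        raise ValueError("no records to fit")
    X = build_presence_design(df, terms)
    y = df["debris_present"].astype(float).to_numpy()
    fit = fit_fractional_logistic(X, y)
    return PresenceModelFit(
        terms=frozenset(terms), coefficients=fit.coefficients,
        std_errors=fit.std_errors, cov=fit.cov,
        log_likelihood=fit.log_likelihood, aic=fit.aic, n_obs=fit.n_obs,
        converged=fit.converged, separated=fit.separated,
        cause_levels=tuple(c for c in CAUSES if (df["cod"] == c).any()))


def candidate_term_sets() -> list[frozenset[str]]:
    """The power set of {cause, adult, exam_binary} (8 candidates; the empty
    set is the intercept-only model)."""
    out = []
    for r in range(len(TERMS) + 1):
        out.extend(frozenset(c) for c in combinations(TERMS, r))
    return out


def presence_model_selection(records, term_sets=None
                             ) -> tuple[pd.DataFrame,
                                        dict[frozenset, PresenceModelFit]]:
    """AIC ranking of candidate presence models (ties to fewer params)."""
    if term_sets is None:
        term_sets = candidate_term_sets()
    if len(term_sets) == 0:
        raise ValueError("no candidate term sets")
    fits = {frozenset(t): fit_presence_model(records, t) for t in term_sets}
    rows = [{"terms": "+".join(sorted(t)) if t else "(intercept)",
             "aic": f.aic, "k": len(f.coefficients),
             "converged": f.converged or f.separated}
            for t, f in fits.items()]
    table = pd.DataFrame(rows).sort_values(
        ["aic", "k"], kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    table["significant"] = table["delta_aic"] >= 2.0
    return table, fits


def pairwise_cause_comparisons(fit: PresenceModelFit, alpha: float = 0.05
                               ) -> tuple[list[ct.ContrastResult],
                                          dict[str, str]]:
    """Holm-adjusted pairwise Wald contrasts among the cause cell means."""
    if "cause" not in fit.terms:
        raise ValueError("fit does not include the cause term")
    levels = [c for c in fit.cause_levels]
    names = [f"cause[{c}]" for c in levels]
    eff = pd.Series([fit.coefficients[n] for n in names], index=levels)
    cov = pd.DataFrame(fit.cov.loc[names, names].to_numpy(),
                       index=levels, columns=levels)
    results = ct.pairwise_wald(eff, cov, alpha=alpha)
    letters = ct.compact_letters(eff, results, alpha=alpha)
    return results, letters
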