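"""Negative-binomial count model: fits, AIC selection, cause contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from turtledose import CountModelSpec, fit_nb_glm, select_by_aic
from turtledose.contrasts import pairwise_wald, compact_letters
from turtledose.counts import (MODEL_CODES, overdispersion_check,
                               pairwise_cause_contrasts)
from turtledose.records import NecropsyRecord, necropsy_frame


def _cohort_df(counts, cods=None, ages=None, species=None):
    n = len(counts)
    return pd.DataFrame({
        "animal_id": [f"t{i}" for i in range(n)],
        "species": species if species is not None else ["green"] * n,
        "age_class": ages if ages is not None else ["juvenile"] * n,
        "age4": ages if ages is not None else ["juvenile"] * n,
        "ccl_cm": [40.0] * n,
        "cod": cods if cods is not None else ["Ukn"] * n,
        "debris_count": counts,
        "debris_mass_g": [0.1 * c for c in counts],
    })


def _nb2_loglik(y, mu, alpha):
    size = 1.0 / alpha
    return np.sum(gammaln(y + size) - gammaln(size) - gammaln(y + 1)
                  + size * np.log(size / (size + mu))
                  + y * np.log(mu / (size + mu)))


def test_intercept_only_matches_grid_search_oracle():
    """On an 8-record fixture the intercept-only NB MLE has
    mu = sample mean; verified against a brute-force likelihood grid."""
    y = np.array([0, 1, 2, 0, 5, 3, 1, 0])
    df = _cohort_df(list(y))
    fit = fit_nb_glm(df, CountModelSpec("0"))
    assert fit.converged
    # independent oracle: grid over (log mu, log alpha)
    best = (-np.inf, None, None)
    for logmu in np.linspace(-1, 2, 301):
        for logalpha in np.linspace(-3, 3, 121):
            ll = _nb2_loglik(y, np.exp(logmu), np.exp(logalpha))
            if ll > best[0]:
                best = (ll, logmu, logalpha)
    assert fit.coefficients["intercept"] == pytest.approx(best[1], abs=0.01)
    assert fit.coefficients["intercept"] == pytest.approx(np.log(y.mean()),
                                                          abs=1e-6)
    assert fit.log_likelihood == pytest.approx(best[0], abs=0.01)


def test_all_zero_counts_reports_separation_not_crash():
    df = _cohort_df([0] * 12)
    fit = fit_nb_glm(df, CountModelSpec("0"))
    assert not fit.converged
    assert fit.separation_flags


def test_equal_means_across_causes_gives_null_coefficients():
    """Generation-vs-fit consistency: equal NB means in all cause groups
    leave every cause coefficient within 3 SE of zero (n = 5000)."""
    rng = np.random.default_rng(12)
    n = 5000
    cods = rng.choice(["Ukn", "KNP", "Ind", "KP"], size=n)
    counts = rng.negative_binomial(0.5, 0.5 / (0.5 + 3.0), size=n)
    df = _cohort_df(list(counts), cods=list(cods))
    fit = fit_nb_glm(df, CountModelSpec("C"))
    assert fit.converged
    for term in fit.coefficients.index:
        if term.startswith("cause["):
            z = fit.coefficients[term] / fit.std_errors[term]
            assert abs(z) < 3.0, (term, z)


def test_poisson_limit_of_nb_matches_poisson_glm():
    """Dispersion constrained to the Poisson limit reproduces the Poisson
    GLM coefficients to 1e-6."""
    rng = np.random.default_rng(3)
    cods = list(rng.choice(["Ukn", "KNP"], size=300))
    counts = list(rng.poisson(2.0, size=300))
    df = _cohort_df(counts, cods=cods)
    near = fit_nb_glm(df, CountModelSpec("C"), fixed_dispersion=1e8)
    poisson = fit_nb_glm(df, CountModelSpec("C"), fixed_dispersion=np.inf)
    assert np.allclose(near.coefficients, poisson.coefficients, atol=1e-6)


def test_aic_ranking_invariant_to_spec_order(cohort):
    specs = [CountModelSpec(c) for c in MODEL_CODES]
    t1, _ = select_by_aic(cohort, specs)
    t2, _ = select_by_aic(cohort, specs[::-1])
    assert list(t1["code"]) == list(t2["code"])
    assert np.allclose(t1["aic"], t2["aic"], equal_nan=True)


def test_duplicate_spec_is_a_tie():
    df = _cohort_df([0, 1, 2, 3, 1, 0, 2, 5])
    table, _ = select_by_aic(df, [CountModelSpec("0"), CountModelSpec("0")])
    assert len(table) == 2
    assert table["aic"].iloc[0] == table["aic"].iloc[1]


def test_strong_cause_effect_selects_cause_model():
    """With a 10x mean ratio between causes, the cause model beats the
    intercept-only model by >= 2 AIC in nearly all replicates at n = 246."""
    rng = np.random.default_rng(5)
    wins = 0
    n_sims = 40
    for _ in range(n_sims):
        cods = rng.choice(["KNP", "KP"], size=246)
        mu = np.where(cods == "KP", 10.0, 1.0)
        counts = rng.negative_binomial(0.8, 0.8 / (0.8 + mu))
        counts[cods == "KP"] = np.maximum(counts[cods == "KP"], 1)
        df = _cohort_df(list(counts), cods=list(cods))
        table, _ = select_by_aic(df, [CountModelSpec("0"),
                                      CountModelSpec("C")])
        ok = table[table["converged"]]
        if ok["code"].iloc[0] == "C" and float(
                ok.set_index("code").loc["0", "delta_aic"]) >= 2:
            wins += 1
    assert wins >= 0.95 * n_sims, wins


def test_null_data_keeps_intercept_model_competitive():
    rng = np.random.default_rng(6)
    close = 0
    n_sims = 30
    for _ in range(n_sims):
        cods = rng.choice(["Ukn", "KNP", "Ind"], size=246)
        counts = rng.negative_binomial(0.8, 0.8 / (0.8 + 2.0), size=246)
        df = _cohort_df(list(counts), cods=list(cods))
        table, _ = select_by_aic(df, [CountModelSpec("0"),
                                      CountModelSpec("C")])
        ok = table[table["converged"]].set_index("code")
        if float(ok.loc["0", "delta_aic"]) < 2:
            close += 1
    assert close >= 0.7 * n_sims, close


def test_overdispersion_p_calibrated_under_poisson_truth():
    """Pearson goodness-of-fit p-values are near-uniform when the variance
    model is correct (Poisson data, Poisson-limit fit)."""
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(200):
        counts = list(rng.poisson(3.0, size=150))
        df = _cohort_df(counts)
        fit = fit_nb_glm(df, CountModelSpec("0"), fixed_dispersion=np.inf)
        _, _, p = overdispersion_check(fit)
        pvals.append(p)
    assert stats.kstest(pvals, "uniform").pvalue > 1e-3


def test_overdispersed_data_rejected_by_poisson_variant():
    rng = np.random.default_rng(8)
    rejections = 0
    for _ in range(200):
        counts = list(rng.negative_binomial(0.3, 0.3 / (0.3 + 3.0),
                                            size=150))
        df = _cohort_df(counts)
        fit = fit_nb_glm(df, CountModelSpec("0"), fixed_dispersion=np.inf)
        _, _, p = overdispersion_check(fit)
        rejections += p < 0.05
    assert rejections >= 180


def test_overdispersion_check_errors_on_zero_df():
    df = _cohort_df([1, 2], cods=["Ukn", "KNP"])
    fit = fit_nb_glm(df, CountModelSpec("C"), fixed_dispersion=np.inf)
    with pytest.raises(ValueError, match="degrees of freedom"):
        overdispersion_check(fit)


def test_identical_cause_effects_share_one_letter():
    eff = pd.Series([0.5, 0.5, 0.5, 0.5], index=["Ukn", "KNP", "Ind", "KP"])
    cov = pd.DataFrame(np.eye(4) * 0.04, index=eff.index, columns=eff.index)
    results = pairwise_wald(eff, cov)
    assert all(r.p_adjusted > 0.05 for r in results)
    letters = compact_letters(eff, results)
    assert len(set(letters.values())) == 1


def test_contrast_antisymmetry():
    eff = pd.Series([0.0, 1.0, 3.0], index=["a", "b", "c"])
    cov = pd.DataFrame(np.eye(3) * 0.1, index=eff.index, columns=eff.index)
    fwd = {r.pair: r.estimate for r in pairwise_wald(eff, cov)}
    rev = {r.pair: r.estimate
           for r in pairwise_wald(eff[::-1], cov.iloc[::-1, ::-1])}
    for (a, b), est in fwd.items():
        assert rev[(b, a)] == pytest.approx(-est)


def test_letters_invariant_to_relabelling():
    eff = pd.Series([0.0, 0.1, 3.0, 3.1], index=["w", "x", "y", "z"])
    cov = pd.DataFrame(np.eye(4) * 0.01, index=eff.index, columns=eff.index)
    letters = compact_letters(eff, pairwise_wald(eff, cov))
    renamed = eff.rename({"w": "p", "x": "q", "y": "r", "z": "s"})
    cov2 = cov.copy()
    cov2.index = cov2.columns = renamed.index
    letters2 = compact_letters(renamed, pairwise_wald(renamed, cov2))
    mapping = dict(zip("wxyz", "pqrs"))
    assert {mapping[k]: v for k, v in letters.items()} == letters2


def test_two_category_contrast_unadjusted():
    df = _cohort_df([0, 1, 5, 9, 2, 0, 7, 1],
                    cods=["Ukn", "Ukn", "KNP", "KNP"] * 2)
    fit = fit_nb_glm(df, CountModelSpec("C"))
    results, letters = pairwise_cause_contrasts(fit)
    assert len(results) == 1
    assert results[0].p_adjusted == pytest.approx(results[0].p_raw)


def test_contrasts_require_cause_term(cohort):
    fit = fit_nb_glm(cohort, CountModelSpec("0"))
    with pytest.raises(ValueError, match="cause"):
        pairwise_cause_contrasts(fit)


def test_parameter_recovery_with_known_effects():
    """Fitted coefficients at n = 5000 fall within 3 SE of the generating
    log-mean effects."""
    rng = np.random.default_rng(9)
    n = 5000
    cods = rng.choice(["Ukn", "KNP", "Ind", "KP"], size=n)
    truth = {"Ukn": 0.0, "KNP": 0.3, "Ind": 1.0, "KP": 1.6}  # vs Ukn ref
    base_mu = 1.5
    mu = base_mu * np.exp([truth[c] for c in cods])
    counts = rng.negative_binomial(0.8, 0.8 / (0.8 + mu))
    counts[cods == "KP"] = np.maximum(counts[cods == "KP"], 1)
    df = _cohort_df(list(counts), cods=list(cods))
    from turtledose.counts import ReferenceLevels
    fit = fit_nb_glm(df, CountModelSpec("C"),
                     refs=ReferenceLevels(cause="Ukn"))
    assert fit.converged
    for c in ("KNP", "Ind"):
        est = fit.coefficients[f"cause[{c}]"]
        se = fit.std_errors[f"cause[{c}]"]
        assert abs(est - truth[c]) < 3 * se, (c, est, truth[c], se)
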