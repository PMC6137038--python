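"""Synthetic necropsy cohorts and stranding-register record sets.

The generator emulates the statistical structure the downstream analyses
assume: a mixed-age, mixed-species cohort of dead turtles; over-dispersed
(negative-binomial) ingested-debris counts; total debris mass as a sum of
lognormal per-item masses; a latent logistic mortality process in debris
load per cm of curved carapace length (CCL); and a labelling process that
maps each death onto the four cause-of-death categories
Ukn / KNP / Ind / KP.

Competing-risk rule
-------------------
Every generated animal is dead (all records come from necropsies).  Given
the latent plastic-mortality propensity ``p`` and a constant external hazard
``h``, the death is attributed to plastic with probability ``p / (p + h)``
(and to an external cause otherwise).  Plastic deaths are labelled KP with
probability ``label_kp_given_plastic`` — but only when the animal actually
carries debris, since a "known plastic ingestion" diagnosis requires debris
in the gut — and Ind otherwise.  External deaths are labelled KNP with
probability ``label_knp_given_external`` and Ukn otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .records import (AGE_CLASSES, CAUSES, NecropsyRecord, SPECIES,
                      StrandNetRecord)

#: Cohort composition of the necropsy study: 246 animals,
#: 22 hatchlings / 24 post-hatchlings / 175 juveniles / 13 subadults /
#: 12 adults; 160 green / 52 hawksbill / 30 loggerhead / 1 flatback /
#: 1 olive ridley / 2 unidentified.
DEFAULT_AGE_COUNTS = (22, 24, 175, 13, 12)
DEFAULT_SPECIES_COUNTS = (160, 52, 30, 1, 1, 2)

#: Examination-level composition of the 706 stranding-register necropsy
#: reports: 185 not examined, 345/170/6 examined to levels 1/2/3.
DEFAULT_LEVEL_COUNTS = (185, 345, 170, 6)

_BASE_MU_BY_AGE = {
    # expected debris items per animal; hatchlings ingest none by default
    "hatchling": 0.0,
    "post_hatchling": 3.0,
    "juvenile": 2.0,
    "subadult": 1.0,
    "adult": 1.0,
}
_SPECIES_MU_FACTOR = {
    # greens ingest the most; hawksbills markedly less
    "green": 1.25,
    "hawksbill": 0.5,
    "loggerhead": 0.8,
    "flatback": 0.8,
    "olive_ridley": 0.8,
    "unidentified": 0.8,
}


def _default_mu_table() -> dict[tuple[str, str], float]:
    return {(a, s): _BASE_MU_BY_AGE[a] * _SPECIES_MU_FACTOR[s]
            for a in AGE_CLASSES for s in SPECIES}


def _norm(counts: Sequence[float]) -> tuple[float, ...]:
    t = float(sum(counts))
    return tuple(c / t for c in counts)


@dataclass
class GeneratorParams:
    """Parameters of the synthetic cohort generator.

    The logistic coefficients live on the load-per-CCL scale:
    ``logit(p) = true_intercept + true_age_offsets[age]
    + true_slope * debris_count / ccl_cm``.  The defaults place 22%
    mortality at a single ingested item and 50% at roughly 14 items for a
    43.5 cm animal.
    """

    n_animals: int = 246
    age_class_weights: tuple[float, ...] = _norm(DEFAULT_AGE_COUNTS)
    species_weights: tuple[float, ...] = _norm(DEFAULT_SPECIES_COUNTS)
    ccl_mean_by_age: Mapping[str, float] = field(default_factory=lambda: {
        "hatchling": 5.5, "post_hatchling": 12.0, "juvenile": 44.0,
        "subadult": 75.0, "adult": 95.0})
    ccl_sd_by_age: Mapping[str, float] = field(default_factory=lambda: {
        "hatchling": 0.7, "post_hatchling": 3.0, "juvenile": 13.0,
        "subadult": 9.0, "adult": 10.0})
    nb_mu_by_age_species: Mapping[tuple[str, str], float] = field(
        default_factory=_default_mu_table)
    nb_dispersion: float = 0.12          # NB size; small = heavy over-dispersion
    mass_per_item_log_mean: float = -3.5  # log-g; median item ~0.03 g
    mass_per_item_log_sd: float = 1.5
    #: share of debris-positive animals lacking a recorded mass
    mass_missing_prob: float = 11 / 58
    true_intercept: float = -1.4
    true_slope: float = 4.2
    true_age_offsets: Mapping[str, float] = field(default_factory=lambda: {
        a: 0.0 for a in AGE_CLASSES})
    external_hazard: float = 0.6
    label_kp_given_plastic: float = 0.6
    label_knp_given_external: float = 0.4
    seed: int = 0
    hatchlings_ingest: bool = False       # stress-test override

    def validate(self) -> None:
        def _prob_vector(name, v, n):
            v = np.asarray(v, dtype=float)
            if v.shape != (n,) or not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name}: must be {n} finite non-negative "
                                 "weights")
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name}: must sum to 1 (got {v.sum()!r})")

        _prob_vector("age_class_weights", self.age_class_weights,
                     len(AGE_CLASSES))
        _prob_vector("species_weights", self.species_weights, len(SPECIES))
        if not (np.isfinite(self.nb_dispersion) and self.nb_dispersion > 0):
            raise ValueError("nb_dispersion: must be > 0")
        for name in ("external_hazard", "label_kp_given_plastic",
                     "label_knp_given_external", "mass_missing_prob"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name}: must be a probability in [0,1]")
        for a in AGE_CLASSES:
            if self.ccl_mean_by_age[a] <= 0:
                raise ValueError(f"ccl_mean_by_age[{a}]: must be > 0")
            if self.ccl_sd_by_age[a] < 0:
                raise ValueError(f"ccl_sd_by_age[{a}]: must be >= 0")
        for key, mu in self.nb_mu_by_age_species.items():
            if not (np.isfinite(mu) and mu >= 0):
                raise ValueError(f"nb_mu_by_age_species[{key}]: must be >= 0")
        for name in ("true_intercept", "true_slope", "mass_per_item_log_mean",
                     "mass_per_item_log_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name}: must be finite")
        for a in AGE_CLASSES:
            if not np.isfinite(self.true_age_offsets[a]):
                raise ValueError(f"true_age_offsets[{a}]: must be finite")

    def with_(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


def _draw_ccl(rng: np.random.Generator, params: GeneratorParams,
              ages: np.ndarray) -> np.ndarray:
    """Normal per age class, truncated to strictly positive by redraw."""
    mean = np.array([params.ccl_mean_by_age[a] for a in ages])
    sd = np.array([params.ccl_sd_by_age[a] for a in ages])
    ccl = rng.normal(mean, sd)
    bad = ccl <= 0
    while bad.any():
        ccl[bad] = rng.normal(mean[bad], sd[bad])
        bad = ccl <= 0
    return ccl


def _draw_core(rng: np.random.Generator, params: GeneratorParams, n: int):
    """Shared latent machinery: covariates, counts, cause labels."""
    ages = rng.choice(AGE_CLASSES, size=n, p=params.age_class_weights)
    species = rng.choice(SPECIES, size=n, p=params.species_weights)
    ccl = _draw_ccl(rng, params, ages)

    mu = np.array([params.nb_mu_by_age_species[(a, s)]
                   for a, s in zip(ages, species)])
    if params.hatchlings_ingest and not params.nb_mu_by_age_species.get(
            ("hatchling", "green"), 0.0):
        # override the zero-debris default with the juvenile rate
        mu = np.where(ages == "hatchling",
                      [params.nb_mu_by_age_species[("juvenile", s)]
                       for s in species], mu)
    size = params.nb_dispersion
    p_nb = size / (size + np.maximum(mu, 1e-300))
    counts = np.where(mu > 0, rng.negative_binomial(size, np.clip(p_nb, 0, 1)),
                      0)

    offsets = np.array([params.true_age_offsets[a] for a in ages])
    p_plastic = expit(params.true_intercept + offsets
                      + params.true_slope * counts / ccl)
    denom = p_plastic + params.external_hazard
    with np.errstate(invalid="ignore"):
        prob_cause_plastic = np.where(denom > 0, p_plastic / denom, 0.0)
    plastic_death = rng.uniform(size=n) < prob_cause_plastic

    u_label = rng.uniform(size=n)
    cod = np.where(
        plastic_death,
        np.where((u_label < params.label_kp_given_plastic) & (counts >= 1),
                 "KP", "Ind"),
        np.where(u_label < params.label_knp_given_external, "KNP", "Ukn"))
    return ages, species, ccl, counts, cod


def generate_necropsy_cohort(params: GeneratorParams) -> list[NecropsyRecord]:
    """Simulate a necropsy cohort of ``params.n_animals`` dead turtles."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_animals
    ages, species, ccl, counts, cod = _draw_core(rng, params, n)

    # total mass = sum of per-item lognormal masses, floored at 0.01 g;
    # a share of debris-positive animals has the mass missing entirely
    masses: list[float | None] = []
    for k in counts:
        if k == 0:
            masses.append(0.0)
        else:
            total = float(rng.lognormal(params.mass_per_item_log_mean,
                                        params.mass_per_item_log_sd,
                                        size=int(k)).sum())
            masses.append(max(total, 0.01))
    missing = rng.uniform(size=n) < params.mass_missing_prob
    records = []
    for i in range(n):
        mass = masses[i]
        if counts[i] > 0 and missing[i]:
            mass = None
        rec = NecropsyRecord(
            animal_id=f"N{i:05d}", species=str(species[i]),
            age_class=str(ages[i]), ccl_cm=float(ccl[i]), cod=str(cod[i]),
            debris_count=int(counts[i]), debris_mass_g=mass)
        rec.validate()
        records.append(rec)
    return records


def generate_strandnet_records(
        params: GeneratorParams, n_records: int,
        detect_prob_by_level: Sequence[float] = (0.05, 0.5, 0.7, 0.95),
        level_weights: Sequence[float] = _norm(DEFAULT_LEVEL_COUNTS),
) -> list[StrandNetRecord]:
    """Simulate stranding-register reports observed through an
    examination-level detection filter.

    Each record has a true underlying debris presence (the NB count model,
    dichotomised at >= 1 item); the observer detects it with probability
    ``detect_prob_by_level[exam_level]``, which must be non-decreasing in
    level.  KP deaths are always recorded as debris-present — the diagnosis
    itself implies debris was seen.
    """
    params.validate()
    probs = np.asarray(detect_prob_by_level, dtype=float)
    if probs.shape != (4,) or np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("detect_prob_by_level: need 4 probabilities in [0,1]")
    if np.any(np.diff(probs) < 0):
        raise ValueError("detect_prob_by_level: must be non-decreasing in "
                         "examination level (more thorough examination cannot "
                         "detect less)")
    weights = np.asarray(level_weights, dtype=float)
    if weights.shape != (4,) or abs(weights.sum() - 1.0) > 1e-12:
        raise ValueError("level_weights: need 4 weights summing to 1")

    rng = np.random.default_rng(params.seed)
    ages, species, _ccl, counts, cod = _draw_core(rng, params, n_records)
    true_present = counts >= 1
    levels = rng.choice(4, size=n_records, p=weights)
    detected = rng.uniform(size=n_records) < probs[levels]
    observed = (true_present & detected) | (cod == "KP")

    records = []
    for i in range(n_records):
        rec = StrandNetRecord(
            record_id=f"S{i:05d}", debris_present=bool(observed[i]),
            exam_level=int(levels[i]), adult=bool(ages[i] == "adult"),
            cod=str(cod[i]), species=str(species[i]))
        rec.validate()
        records.append(rec)
    return records
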