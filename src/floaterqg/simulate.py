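"""Synthetic pedigree and phenotype generator.

Emulates a small closed passerine population founded by ~21 birds and
monitored over ~17 breeding seasons: socially monogamous pairs with
frequent extra-pair paternity, a male surplus of non-territorial
"floater" males, and complete observation of fledglings.  The generator
produces

* a :class:`~floaterqg.pedigree.Pedigree` (sire links optionally
  recorded only from a given season onward, emulating the later start of
  genetic paternity assignment — earlier cohorts then fail the
  four-grandparent filter exactly as in field pedigrees), and
* a male-season phenotype table with binary mating status driven by a
  latent logit model (quadratic age, inbreeding, size, additive-genetic,
  permanent-environment and year effects) and Poisson annual reproductive
  success (ARS) driven by status and quadratic age, with the extra-pair
  component (EPARS) obtained by binomial thinning for territorials and
  equal to ARS for floaters.

All randomness flows from ``SimulationConfig.rng_seed``; equal seeds give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree, RelatednessResult, additive_relationship, four_grandparent_filter, validate_pedigree

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "simulate_pedigree",
    "simulate_phenotypes",
    "simulate_dataset",
    "multivariate_normal_breeding_values",
    "behaviour_recovery_config",
    "animal_model_config",
]


class SimulationError(RuntimeError):
    """Raised when the simulated population cannot complete the run."""


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic population.

    Demography defaults are calibrated so that the default run yields a
    male-season table of roughly 700-1000 records on roughly 240-340
    distinct males over 17 seasons, with about a third of male-seasons
    spent floating — the scale of the field data set the analyses are
    designed for.  Latent-scale effect sizes mirror the magnitudes the
    fitted models report (standardized logit scale for behaviour; log
    scale for ARS).
    """

    # demography
    n_founders: int = 21
    founder_males: int = 11
    n_years: int = 17
    pairing_rate: float = 0.95          # P(an adult female pairs | males available)
    adult_survival: float = 0.68        # P(adult survives to next season)
    juvenile_survival: float = 0.70     # P(fledgling recruits | no crowding)
    fecundity: float = 5.0              # mean fledglings per paired female-season
    carrying_capacity: int = 58         # density-dependence scale for recruitment
    max_age: int = 10
    extra_pair_rate: float = 0.6        # P(offspring sired extra-pair)
    paternity_from_year: int = 6        # sires recorded in pedigree from this season
    # behaviour model (logit scale, standardized predictors; territorial = 1)
    beh_intercept: float = 1.1
    beh_age: float = 2.3
    beh_age2: float = -2.2
    beh_f: float = -0.35
    beh_tarsus: float = 0.45
    sigma2_A: float = 0.0               # additive-genetic variance, latent scale
    sigma2_PE: float = 0.6              # permanent-environment variance
    sigma2_year: float = 0.05           # season variance
    # ARS model (log scale); intercept calibrated so overall mean ARS ~ 2
    ars_intercept: float = -0.8
    ars_behaviour: float = 1.15         # territorial advantage
    ars_age: float = 1.30
    ars_age2: float = -0.88
    ars_sigma2_id: float = 0.10
    ars_sigma2_year: float = 0.05
    epars_thin: float = 0.6             # P(a territorial's fledgling is extra-pair)
    # tarsus: fixed at 21 days, no heritable component modelled
    tarsus_mean: float = 20.0
    tarsus_sd: float = 1.0
    # output policy for f: "four_grandparent" hides f for males failing the
    # filter (as in field data); "all" reports the phantom-founder f for everyone
    f_policy: str = "four_grandparent"
    rng_seed: int = 1

    def validate(self) -> None:
        if self.n_founders < 2 or not (0 < self.founder_males < self.n_founders):
            raise ValueError("need at least one founder of each sex")
        for name in ("pairing_rate", "adult_survival", "juvenile_survival",
                     "extra_pair_rate", "epars_thin"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("sigma2_A", "sigma2_PE", "sigma2_year",
                     "ars_sigma2_id", "ars_sigma2_year", "fecundity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.f_policy not in ("four_grandparent", "all"):
            raise ValueError(f"unknown f_policy {self.f_policy!r}")

    def as_dict(self) -> dict:
        return asdict(self)


def behaviour_recovery_config(seed: int = 1) -> SimulationConfig:
    """A smaller variant sized like the behaviour analysis (~360 records).

    Sire links are recorded from the first season and f is reported for
    every male, so the full table is complete-case for all predictors.
    """
    return replace(
        SimulationConfig(),
        n_years=9,
        adult_survival=0.50,
        carrying_capacity=70,
        paternity_from_year=1,
        f_policy="all",
        rng_seed=seed,
    )


def animal_model_config(seed: int = 1, *, latent_h2: float = 0.0) -> SimulationConfig:
    """Study conditions for variance-component recovery (~800 records).

    The latent behaviour model matches the animal model's structure
    exactly: quadratic age fixed effects only (no inbreeding or size
    effects, which the variance models do not fit), permanent-environment
    variance 0.6 and year variance 0.05, with sigma2_A solved from the
    requested latent-scale heritability h2 = sigma2_A / (sigma2_A +
    sigma2_PE + sigma2_year + pi^2/3).  Sire links are recorded from the
    first season so the pedigree is fully informative.
    """
    if not 0.0 <= latent_h2 < 1.0:
        raise ValueError("latent_h2 must be in [0, 1)")
    base = SimulationConfig()
    v_rest = base.sigma2_PE + base.sigma2_year + math.pi**2 / 3.0
    s2a = latent_h2 / (1.0 - latent_h2) * v_rest
    return replace(
        base,
        sigma2_A=s2a,
        beh_f=0.0,
        beh_tarsus=0.0,
        paternity_from_year=1,
        rng_seed=seed,
    )


def multivariate_normal_breeding_values(
    A: np.ndarray, sigma2_A: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw breeding values a ~ MVN(0, sigma2_A * A) via Cholesky.

    ``sigma2_A = 0`` returns exact zeros.  A small diagonal jitter
    (1e-10 on the correlation scale) absorbs round-off; a matrix that is
    not positive semi-definite beyond that raises ``ValueError``.
    """
    if sigma2_A < 0:
        raise ValueError("sigma2_A must be non-negative")
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("A must be square")
    if sigma2_A == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    try:
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    except np.linalg.LinAlgError as e:
        raise ValueError("relationship matrix is not positive semi-definite") from e
    return np.sqrt(sigma2_A) * (L @ rng.standard_normal(n))


def _standardize_col(x: np.ndarray) -> np.ndarray:
    # sample-sd convention, matching how the fitted models scale predictors
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Simulate the closed population's pedigree.

    Founders (year 0) are unrelated; each season, paired females fledge a
    Poisson number of offspring whose sire is the social male or, with
    probability ``extra_pair_rate``, a random adult male (floaters
    included).  Recruitment is density dependent.  Sires are recorded
    only from season ``paternity_from_year``; dams always.  The returned
    pedigree carries per-individual ``death_year`` metadata (last season
    alive) used by :func:`simulate_phenotypes`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    ids: list[str] = []
    sire: dict[str, str | None] = {}
    dam: dict[str, str | None] = {}
    birth: dict[str, int] = {}
    sex: dict[str, str] = {}
    death: dict[str, int] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:04d}"

    for k in range(cfg.n_founders):
        iid = new_id()
        ids.append(iid)
        sire[iid] = dam[iid] = None
        birth[iid] = 0
        sex[iid] = "M" if k < cfg.founder_males else "F"
        death[iid] = 0

    alive: set[str] = set(ids)

    for t in range(1, cfg.n_years + 1):
        males = sorted(i for i in alive if sex[i] == "M" and birth[i] < t)
        females = sorted(i for i in alive if sex[i] == "F" and birth[i] < t)
        if not males or not females:
            raise SimulationError(
                f"population lost a sex by season {t}; raise survival or fecundity"
            )
        for i in list(alive):
            death[i] = t  # provisionally alive through season t
        # pair formation: each female pairs with one distinct male while males last
        rng.shuffle(females)
        rng.shuffle(males)
        paired_f = [f for f in females if rng.random() < cfg.pairing_rate]
        n_pairs = min(len(paired_f), len(males))
        pairs = list(zip(paired_f[:n_pairs], males[:n_pairs]))
        # density dependence on recruitment; the quadratic term regulates
        # the population tightly around its ceiling, as management does
        crowding = 1.0 / (1.0 + (len(alive) / cfg.carrying_capacity) ** 2)
        recruits: list[str] = []
        for fem, soc in pairs:
            for _ in range(rng.poisson(cfg.fecundity)):
                iid = new_id()
                ids.append(iid)
                true_sire = soc if rng.random() >= cfg.extra_pair_rate else males[rng.integers(len(males))]
                sire[iid] = true_sire if t >= cfg.paternity_from_year else None
                dam[iid] = fem
                birth[iid] = t
                sex[iid] = "M" if rng.random() < 0.5 else "F"
                death[iid] = t
                if rng.random() < cfg.juvenile_survival * crowding:
                    recruits.append(iid)
        # adult survival into next season (sorted iteration keeps the
        # draw-to-individual mapping independent of set hashing)
        survivors = {
            i for i in sorted(alive)
            if rng.random() < cfg.adult_survival and (t - birth[i]) < cfg.max_age
        }
        alive = survivors | set(recruits)

    ped = Pedigree(ids, sire, dam, dict(birth), sex, death)
    validate_pedigree(ped).raise_if_fatal()
    return ped


def _lifespans(ped: Pedigree, cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, int]:
    """Last season alive per individual; redrawn when metadata is absent."""
    if ped.death_year:
        return ped.death_year
    death = {}
    for i in ped.ids:
        b = ped.birth_year[i]
        if b is None:
            continue
        age = 0
        while b + age < cfg.n_years and age < cfg.max_age and rng.random() < cfg.adult_survival:
            age += 1
        death[i] = b + age
    return death


def simulate_phenotypes(
    ped: Pedigree,
    cfg: SimulationConfig,
    relatedness: RelatednessResult | None = None,
) -> pd.DataFrame:
    """Generate the male-season phenotype table for a pedigree.

    One row per (male, season) while the male is alive and aged >= 1,
    with columns ``male_id, year, age, status, tarsus, f, ars, epars``.
    The latent behaviour model operates on within-table standardized
    predictors (age, age^2 built from standardized age, f, tarsus), so
    the generative coefficients live on the same scale the fitted models
    report.  ``f`` is reported as NaN for males failing the
    four-grandparent filter under the default ``f_policy``.
    """
    cfg.validate()
    rep = validate_pedigree(ped)
    if rep.errors:
        rep.raise_if_fatal()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 202]))

    if relatedness is None:
        relatedness = additive_relationship(ped)
    death = _lifespans(ped, cfg, rng)

    males = [
        i for i in ped.ids
        if ped.sex[i] == "M" and ped.birth_year[i] is not None and i in death
    ]
    rows = []
    for i in males:
        b = ped.birth_year[i]
        for t in range(b + 1, min(death[i], cfg.n_years) + 1):
            rows.append((i, t, t - b))
    if not rows:
        raise SimulationError("pedigree contains no adult male-seasons")

    df = pd.DataFrame(rows, columns=["male_id", "year", "age"])
    rec_males = list(dict.fromkeys(df["male_id"]))
    midx = {m: k for k, m in enumerate(rec_males)}

    # per-male quantities
    sub = relatedness.submatrix(rec_males)
    f_all = sub.f
    tarsus = cfg.tarsus_mean + cfg.tarsus_sd * rng.standard_normal(len(rec_males))
    a = multivariate_normal_breeding_values(
        np.asarray(sub.A, dtype=float), cfg.sigma2_A, rng
    )
    pe = np.sqrt(cfg.sigma2_PE) * rng.standard_normal(len(rec_males))
    years = np.arange(1, cfg.n_years + 1)
    yr_eff = np.sqrt(cfg.sigma2_year) * rng.standard_normal(len(years))

    mi = df["male_id"].map(midx).to_numpy()
    df["tarsus"] = np.round(tarsus[mi], 2)
    df["f"] = f_all[mi]

    age_s = _standardize_col(df["age"].to_numpy(dtype=float))
    age2_s = _standardize_col(age_s**2)
    f_s = _standardize_col(df["f"].to_numpy(dtype=float))
    tarsus_s = _standardize_col(df["tarsus"].to_numpy(dtype=float))

    eta = (
        cfg.beh_intercept
        + cfg.beh_age * age_s
        + cfg.beh_age2 * age2_s
        + cfg.beh_f * f_s
        + cfg.beh_tarsus * tarsus_s
        + a[mi]
        + pe[mi]
        + yr_eff[df["year"].to_numpy() - 1]
    )
    territorial = rng.random(len(df)) < 1.0 / (1.0 + np.exp(-eta))
    df["status"] = np.where(territorial, "territorial", "floater")

    # ARS: Poisson log-linear in status and quadratic age, with its own
    # individual and year random intercepts
    u_id = np.sqrt(cfg.ars_sigma2_id) * rng.standard_normal(len(rec_males))
    u_yr = np.sqrt(cfg.ars_sigma2_year) * rng.standard_normal(len(years))
    lp = (
        cfg.ars_intercept
        + cfg.ars_behaviour * territorial.astype(float)
        + cfg.ars_age * age_s
        + cfg.ars_age2 * age2_s
        + u_id[mi]
        + u_yr[df["year"].to_numpy() - 1]
    )
    ars = rng.poisson(np.exp(lp))
    epars = np.where(territorial, rng.binomial(ars, cfg.epars_thin), ars)
    df["ars"] = ars
    df["epars"] = epars

    if cfg.f_policy == "four_grandparent":
        known = four_grandparent_filter(ped, rec_males)
        df.loc[~df["male_id"].isin(known), "f"] = np.nan

    return df[["male_id", "year", "age", "status", "tarsus", "f", "ars", "epars"]]


def simulate_dataset(cfg: SimulationConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Pedigree plus phenotype table in one call (shared configuration)."""
    ped = simulate_pedigree(cfg)
    return ped, simulate_phenotypes(ped, cfg)
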