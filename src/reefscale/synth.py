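"""Synthetic inputs with known ground truth.

Three generators feed the pipeline in place of field data:

* a structural causal model (SCM) over five binary site variables —
  Human density, thermal stress anomalies (TSA), coral presence, marine
  protection (MPA) and community Structure — whose topology matches the
  protection graph (the three exogenous drivers determine MPA placement,
  MPA determines structure), together with its closed-form interventional
  ACE;
* long-format survey tables whose log-biomass vs log-mass relation has a
  prescribed slope per site;
* weekly sea-surface-temperature series with a controlled number of
  thermal-stress exceedance weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .causal import CausalGraph
from .metrics import binarize_at_median

__all__ = [
    "SCM_VARIABLES",
    "SCMConfig",
    "GroundTruth",
    "default_cpt",
    "true_graph",
    "generate_scm_table",
    "generate_survey_table",
    "generate_weekly_sst",
]

#: Column order of generated site tables.
SCM_VARIABLES = ("Human", "TSA", "Coral", "MPA", "Structure")


def default_cpt() -> dict[tuple[int, int, int], float]:
    """Default P(MPA=1 | Human, TSA, Coral): additive, faithful.

    Each driver shifts the protection probability by a distinct positive
    amount, so no conditional dependence cancels and every parent leaves
    a detectable marginal footprint.
    """
    base, b_h, b_t, b_c = 0.08, 0.28, 0.30, 0.26
    return {
        (h, t, c): base + b_h * h + b_t * t + b_c * c
        for h in (0, 1)
        for t in (0, 1)
        for c in (0, 1)
    }


@dataclass(frozen=True)
class SCMConfig:
    """Configuration of the site-table structural causal model.

    The latent community-structure score is
    ``score = base + beta * MPA + Normal(0, noise_sd)``; the observed
    Structure variable binarizes the score at the sample median. The
    default effect size ``beta = 1.14`` puts the closed-form
    interventional ACE near 0.43.
    """

    n: int = 10_000
    p_human: float = 0.5
    p_tsa: float = 0.5
    p_coral: float = 0.5
    cpt: Mapping[tuple[int, int, int], float] = field(default_factory=default_cpt)
    beta: float = 1.14
    base: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p, name in (
            (self.p_human, "p_human"),
            (self.p_tsa, "p_tsa"),
            (self.p_coral, "p_coral"),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        keys = {(h, t, c) for h in (0, 1) for t in (0, 1) for c in (0, 1)}
        if set(self.cpt) != keys:
            raise ValueError("CPT must cover all 8 (Human, TSA, Coral) configurations")
        for k, p in self.cpt.items():
            if not 0 <= p <= 1:
                raise ValueError(f"CPT entry {k} out of [0, 1]: {p}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def p_mpa(self) -> float:
        """Marginal P(MPA = 1) by summation over parent configurations."""
        total = 0.0
        for (h, t, c), p in self.cpt.items():
            w = (
                (self.p_human if h else 1 - self.p_human)
                * (self.p_tsa if t else 1 - self.p_tsa)
                * (self.p_coral if c else 1 - self.p_coral)
            )
            total += w * p
        return total


@dataclass(frozen=True)
class GroundTruth:
    """True graph and interventional ACE implied by an SCMConfig."""

    graph: CausalGraph
    true_ace: float
    score_median: float


def true_graph() -> CausalGraph:
    """The protection graph: Human -> MPA <- TSA, Coral -> MPA, MPA -> Structure."""
    return CausalGraph(
        nodes=SCM_VARIABLES,
        directed={
            ("Human", "MPA"),
            ("TSA", "MPA"),
            ("Coral", "MPA"),
            ("MPA", "Structure"),
        },
    )


def _population_median(cfg: SCMConfig) -> float:
    """Median of the latent score mixture (MPA on vs off)."""
    p1 = cfg.p_mpa()
    if cfg.noise_sd == 0:
        # two-point mixture; any threshold between the atoms separates them
        if cfg.beta == 0:
            return cfg.base
        return cfg.base + cfg.beta / 2.0
    lo, hi = cfg.base - 10 * cfg.noise_sd, cfg.base + cfg.beta + 10 * cfg.noise_sd
    lo, hi = min(lo, hi) - abs(cfg.beta), max(lo, hi) + abs(cfg.beta)

    def cdf(m: float) -> float:
        return (1 - p1) * stats.norm.cdf(m, cfg.base, cfg.noise_sd) + p1 * stats.norm.cdf(
            m, cfg.base + cfg.beta, cfg.noise_sd
        )

    return float(optimize.brentq(lambda m: cdf(m) - 0.5, lo, hi))


def _true_ace(cfg: SCMConfig, median: float) -> float:
    """Closed-form P(score > m | do(MPA=1)) - P(score > m | do(MPA=0))."""
    if cfg.noise_sd == 0:
        on = 1.0 if cfg.base + cfg.beta > median else 0.0
        off = 1.0 if cfg.base > median else 0.0
        return on - off
    on = stats.norm.sf(median, cfg.base + cfg.beta, cfg.noise_sd)
    off = stats.norm.sf(median, cfg.base, cfg.noise_sd)
    return float(on - off)


def generate_scm_table(cfg: SCMConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample a binary site table from the SCM and return its ground truth.

    The observed Structure column binarizes the latent score at the
    *sample* median (strictly above -> 1), mirroring how quantitative
    survey variables are dichotomized; the ground-truth ACE uses the
    *population* median, so estimator and truth coincide as n grows.

    Raises
    ------
    ValueError
        When every CPT row is 0 or 1 (a deterministic, unfaithful model).
    """
    if all(p in (0.0, 1.0) for p in cfg.cpt.values()):
        raise ValueError("degenerate CPT (all rows 0/1): SCM is deterministic/unfaithful")
    rng = np.random.default_rng(cfg.seed)
    human = (rng.uniform(size=cfg.n) < cfg.p_human).astype(int)
    tsa = (rng.uniform(size=cfg.n) < cfg.p_tsa).astype(int)
    coral = (rng.uniform(size=cfg.n) < cfg.p_coral).astype(int)
    p_mpa = np.array([cfg.cpt[(h, t, c)] for h, t, c in zip(human, tsa, coral)])
    mpa = (rng.uniform(size=cfg.n) < p_mpa).astype(int)
    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n) if cfg.noise_sd > 0 else 0.0
    score = cfg.base + cfg.beta * mpa + noise
    structure = binarize_at_median(score)
    data = pd.DataFrame(
        {
            "Human": human,
            "TSA": tsa,
            "Coral": coral,
            "MPA": mpa,
            "Structure": structure,
        },
        columns=list(SCM_VARIABLES),
    )
    median = _population_median(cfg)
    truth = GroundTruth(
        graph=true_graph(), true_ace=_true_ace(cfg, median), score_median=median
    )
    return data, truth


def generate_survey_table(
    n_sites: int,
    species_per_site: int,
    slope_per_site: Sequence[float],
    mass_range: tuple[float, float] = (1.0, 1e6),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    n_surveys: int = 2,
    year: int = 2015,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Survey tables with a prescribed biomass--size scaling slope per site.

    Per site, ``species_per_site`` masses are drawn log-uniformly on
    ``mass_range`` and biomasses follow
    ``log10 B = slope * log10 M + intercept + Normal(0, noise_sd)``.
    Each species is recorded in every one of ``n_surveys`` surveys with
    an equal biomass share, so yearly aggregation recovers the configured
    totals and the default community filter (>= 2 surveys, >= 5 species)
    retains every site. A trophic-level column increasing with log mass
    is attached.
    """
    slope_per_site = np.asarray(slope_per_site, dtype=float)
    if slope_per_site.size != n_sites:
        raise ValueError("need one slope per site")
    if species_per_site < 1:
        raise ValueError("species_per_site must be >= 1")
    lo, hi = mass_range
    if not 0 < lo < hi:
        raise ValueError("mass_range must be positive and increasing")
    rng = np.random.default_rng(seed)
    decades = np.log10(hi) - np.log10(lo)
    rows = []
    for s in range(n_sites):
        log_m = rng.uniform(np.log10(lo), np.log10(hi), size=species_per_site)
        log_b = slope_per_site[s] * log_m + intercept
        if noise_sd > 0:
            log_b = log_b + rng.normal(0.0, noise_sd, size=species_per_site)
        mass = 10.0**log_m
        biomass = 10.0**log_b
        tl = 1.0 + 2.0 * (log_m - np.log10(lo)) / decades
        for sv in range(n_surveys):
            share = biomass / n_surveys
            for sp in range(species_per_site):
                rows.append(
                    {
                        "site": f"site{s:03d}",
                        "year": year,
                        "survey": f"sv{sv}",
                        "species": f"sp{sp:04d}",
                        "mass": mass[sp],
                        "abundance": share[sp] / mass[sp],
                        "biomass": share[sp],
                        "tl": tl[sp],
                    }
                )
    return pd.DataFrame(rows)


def generate_weekly_sst(
    n_weeks: int,
    climatology_max,
    exceed_weeks: Sequence[int] = (),
    margin: float = 1.5,
    seed: int | None = None,
) -> np.ndarray:
    """Weekly SST sitting 0.5 degrees below the climatological maximum,
    except in ``exceed_weeks`` where it sits ``margin`` degrees above.

    With the strict > 1 degree anomaly rule, a margin above 1 makes every
    listed week a thermal-stress event and a margin of exactly 1 makes
    none. ``seed`` is accepted for interface uniformity; the series is
    deterministic.
    """
    clim = np.asarray(climatology_max, dtype=float)
    if clim.ndim == 0:
        clim = np.full(n_weeks, float(clim))
    if clim.shape != (n_weeks,):
        raise ValueError("climatology_max must be scalar or length n_weeks")
    idx = np.asarray(list(exceed_weeks), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_weeks):
        raise ValueError("exceed_weeks indices out of range")
    sst = clim - 0.5
    sst[idx] = clim[idx] + margin
    return sst
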