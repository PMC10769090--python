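"""Niche-model food webs and metabolic-scaling communities.

This module builds the theoretical engine: random food webs with
species-richness-dependent connectance, body masses that grow geometrically
with trophic level, mass-dependent trophic transfer efficiencies, per-species
biomass scaling coefficients derived from the energetic equivalence
hypothesis (EEH) with trophic transfer correction, and a size-selective
harvest that removes the largest individuals of the largest species.

The community-level summary is the slope ``k_c`` of an ordinary
least-squares fit of log biomass on log body mass: the biomass--size
spectrum. ``k_c = 0.25`` is the EEH expectation; larger values indicate
top-heavy communities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SimParams",
    "FoodWeb",
    "Community",
    "HarvestOutcome",
    "generate_niche_web",
    "trophic_levels",
    "assign_body_masses",
    "ppmr_pairs",
    "transfer_efficiencies",
    "species_scaling_coefficients",
    "simulate_community",
    "harvest_community",
    "run_experiment",
    "DEFAULT_TE_GRID",
]

#: TE_max levels swept by the replicated experiment.
DEFAULT_TE_GRID: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7)

#: Mass exponent of transfer efficiency: TE_i ∝ M_i^TE_MASS_EXPONENT.
TE_MASS_EXPONENT: float = -0.03

#: EEH baseline scaling coefficient (basal species, and the no-correction limit).
EEH_BASELINE: float = 0.25

#: Exponent linking species richness to connectance, C = S**CONNECTANCE_EXPONENT.
CONNECTANCE_EXPONENT: float = -0.65


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated community and of the harvest experiment.

    Attributes
    ----------
    S : int
        Number of species (default 35, the empirical median richness).
    Q : float
        Mean body-mass ratio between adjacent trophic levels (default 1e3).
    M0 : float
        Basal mass constant, arbitrary units (default 1).
    noise_sd : float
        Standard deviation of the trophic-level noise eps_i in the mass
        relation ``M_i = M0 * Q**(TL_i - 1 + eps_i)`` (default 1).
    TE_max : float
        Maximum trophic transfer efficiency, attained by the smallest
        (basal) species; in (0, 1).
    harvest_fraction : float
        Fraction of species subject to harvest (default 0.40).
    r_min : float
        Minimum removal level of a harvested species (default 0.30).
    sigma_intra : float
        S.d. (natural-log scale) of the intraspecific individual mass
        distribution used by the harvest mechanism (default 0.5). Zero
        makes all individuals identical, so harvest only removes
        individuals without changing mean mass.
    n_reps : int
        Replicate communities per TE_max level in ``run_experiment``.
    seed : int
        Root RNG seed.
    """

    S: int = 35
    Q: float = 1e3
    M0: float = 1.0
    noise_sd: float = 1.0
    TE_max: float = 0.5
    harvest_fraction: float = 0.40
    r_min: float = 0.30
    sigma_intra: float = 0.5
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError(f"S must be >= 2, got {self.S}")
        if self.Q <= 1:
            raise ValueError(f"Q must be > 1, got {self.Q}")
        if not 0 < self.TE_max < 1:
            raise ValueError(f"TE_max must be in (0, 1), got {self.TE_max}")
        if not 0 < self.harvest_fraction < 1:
            raise ValueError(
                f"harvest_fraction must be in (0, 1), got {self.harvest_fraction}"
            )
        if not 0 <= self.r_min < 1:
            raise ValueError(f"r_min must be in [0, 1), got {self.r_min}")
        if self.sigma_intra < 0:
            raise ValueError(f"sigma_intra must be >= 0, got {self.sigma_intra}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")

    @property
    def connectance_target(self) -> float:
        """Target connectance C = S**-0.65."""
        return float(self.S) ** CONNECTANCE_EXPONENT


@dataclass(frozen=True)
class FoodWeb:
    """Directed predation structure.

    ``adjacency[j, i]`` is True when species j is prey of predator i
    (links point from resource to consumer). Cannibalistic self-links are
    stripped at generation time.
    """

    adjacency: np.ndarray
    niche_values: np.ndarray

    @property
    def S(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    @property
    def connectance(self) -> float:
        """Realized connectance, links / S**2."""
        return self.n_links / self.S**2

    def prey_of(self, i: int) -> np.ndarray:
        """Indices of prey of predator ``i``."""
        return np.flatnonzero(self.adjacency[:, i])

    def basal_mask(self) -> np.ndarray:
        """Boolean mask of basal species (no prey)."""
        return ~self.adjacency.any(axis=0)

    def to_edge_list(self) -> list[tuple[int, int]]:
        """Links as (prey, predator) index pairs."""
        jj, ii = np.nonzero(self.adjacency)
        return list(zip(jj.tolist(), ii.tolist()))


@dataclass(frozen=True)
class Community:
    """A simulated community with its metabolic-scaling quantities."""

    web: FoodWeb
    TL: np.ndarray
    M: np.ndarray
    TE: np.ndarray
    k: np.ndarray
    B: np.ndarray
    k_c: float
    params: SimParams

    @property
    def S(self) -> int:
        return self.web.S

    def ppmr(self) -> dict[tuple[int, int], float]:
        """Predator-prey mass ratios for every trophic link."""
        return ppmr_pairs(self.M, self.web)


@dataclass(frozen=True)
class HarvestOutcome:
    """Result of size-selective harvest applied to a community."""

    harvested_ids: np.ndarray
    r: np.ndarray
    M_h: np.ndarray
    B_h: np.ndarray
    k_c_h: float


# ---------------------------------------------------------------------------
# Web generation (classic niche model)
# ---------------------------------------------------------------------------

def _draw_niche_web(S: int, C: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One raw draw of the niche model of Williams & Martinez.

    Each species gets a niche value n ~ U(0,1); a feeding range
    r = x*n with x ~ Beta(1, 1/(2C) - 1) so the expected connectance is C;
    and a range centre c ~ U(r/2, n). The species with the smallest niche
    value is forced basal (r = 0). Self-links are stripped.
    """
    n = rng.uniform(size=S)
    beta_b = 1.0 / (2.0 * C) - 1.0
    if beta_b <= 0:
        raise ValueError(f"connectance target {C} too large for the niche model")
    x = rng.beta(1.0, beta_b, size=S)
    r = x * n
    r[np.argmin(n)] = 0.0
    lo = r / 2.0
    centre = rng.uniform(lo, np.maximum(n, lo + 1e-12))
    adj = (np.abs(n[:, None] - centre[None, :]) <= (r[None, :] / 2.0))
    np.fill_diagonal(adj, False)
    return adj, n


def _web_is_valid(adj: np.ndarray) -> bool:
    """No isolated species, >=1 basal, all consumers fed from a basal species."""
    S = adj.shape[0]
    degree = adj.sum(axis=0) + adj.sum(axis=1)
    if S > 1 and (degree == 0).any():
        return False
    basal = ~adj.any(axis=0)
    if not basal.any():
        return False
    # every species reachable from some basal species along prey->predator links
    reached = basal.copy()
    frontier = basal.copy()
    while frontier.any():
        nxt = adj[frontier].any(axis=0) & ~reached
        if not nxt.any():
            break
        reached |= nxt
        frontier = nxt
    return bool(reached.all())


def generate_niche_web(
    S: int,
    connectance_target: float | None = None,
    seed: int | np.random.Generator = 0,
    *,
    rel_tol: float = 0.20,
    max_retries: int = 2000,
) -> FoodWeb:
    """Generate a niche-model food web matching a target connectance.

    Parameters
    ----------
    S : int
        Species richness (>= 2).
    connectance_target : float, optional
        Target links/S**2; defaults to ``S**-0.65``.
    seed : int or Generator
        RNG seed or generator.
    rel_tol : float
        Accept webs whose realized connectance is within this relative
        tolerance of the target.
    max_retries : int
        Draws attempted before giving up.

    Returns
    -------
    FoodWeb
        A web with at least one basal species, no isolated species, every
        consumer supported by a basal species, and no self-links.
    """
    if S < 2:
        raise ValueError(f"S must be >= 2, got {S}")
    if connectance_target is None:
        connectance_target = float(S) ** CONNECTANCE_EXPONENT
    if not 0 < connectance_target < 1:
        raise ValueError(f"connectance target must be in (0,1), got {connectance_target}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        adj, niche = _draw_niche_web(S, connectance_target, rng)
        realized = adj.sum() / S**2
        if abs(realized - connectance_target) > rel_tol * connectance_target:
            continue
        if not _web_is_valid(adj):
            continue
        return FoodWeb(adjacency=adj, niche_values=niche)
    raise RuntimeError(
        f"could not generate a valid niche web for S={S}, "
        f"target connectance={connectance_target:.4g} in {max_retries} draws"
    )


# ---------------------------------------------------------------------------
# Trophic levels, masses, transfer efficiency
# ---------------------------------------------------------------------------

def trophic_levels(web: FoodWeb) -> np.ndarray:
    """Prey-averaged trophic levels.

    Basal species sit at TL = 1; a consumer sits one level above the mean
    level of its prey. Solved as the linear system
    ``TL_i - mean_j(TL_j over prey j) = 1``.
    """
    adj = web.adjacency
    S = web.S
    n_prey = adj.sum(axis=0)
    A = np.eye(S)
    for i in range(S):
        if n_prey[i] > 0:
            A[i, adj[:, i]] = -1.0 / n_prey[i]
    b = np.ones(S)
    try:
        TL = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        cyc = np.flatnonzero(n_prey > 0)
        raise ValueError(
            f"trophic levels undefined: consumer cycle without basal support "
            f"among species {cyc.tolist()}"
        ) from exc
    if np.any(TL < 1 - 1e-9):
        cyc = np.flatnonzero(TL < 1 - 1e-9)
        raise ValueError(f"trophic levels below 1 for species {cyc.tolist()}")
    return TL


def assign_body_masses(
    TL: np.ndarray,
    Q: float = 1e3,
    M0: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Body masses ``M_i = M0 * Q**(TL_i - 1 + eps_i)``, eps ~ N(0, noise_sd^2)."""
    TL = np.asarray(TL, dtype=float)
    if np.any(TL < 1):
        raise ValueError("trophic levels must be >= 1")
    if Q <= 1:
        raise ValueError(f"Q must be > 1, got {Q}")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=TL.shape) if noise_sd > 0 else np.zeros_like(TL)
    return M0 * np.power(Q, TL - 1.0 + eps)


def ppmr_pairs(M: np.ndarray, web: FoodWeb) -> dict[tuple[int, int], float]:
    """Predator-prey mass ratios ``PPMR_ji = M_pred / M_prey`` per link.

    Keys are ``(prey j, predator i)`` index pairs, matching the adjacency
    orientation.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("masses must be strictly positive")
    return {(j, i): float(M[i] / M[j]) for j, i in web.to_edge_list()}


def transfer_efficiencies(M: np.ndarray, TE_max: float) -> np.ndarray:
    """Transfer efficiencies ``TE_i = TE_max * M_i**-0.03 / max_j(M_j**-0.03)``.

    The smallest species attains exactly TE_max; TE declines (weakly) with
    body mass.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("masses must be strictly positive")
    if not 0 < TE_max < 1:
        raise ValueError(f"TE_max must be in (0, 1), got {TE_max}")
    w = np.power(M, TE_MASS_EXPONENT)
    return TE_max * w / w.max()


def species_scaling_coefficients(
    web: FoodWeb,
    TE: np.ndarray,
    ppmr: dict[tuple[int, int], float],
) -> np.ndarray:
    """Per-species biomass scaling coefficients.

    Basal species take the EEH baseline ``k = 0.25``. A consumer with
    ``n_j`` prey takes

        k_i = 0.25 + (1/n_j) * sum_j t_ji / log(PPMR_ji)

    with ``t_ji = log(TE_i)`` when the predator outweighs its prey
    (PPMR > 1) and ``t_ji = log(1 - TE_i)`` when prey outweigh the
    predator (PPMR < 1), preserving the interpretation that higher
    transfer efficiency raises ``k``. Links with PPMR exactly 1 carry no
    information about the correction and are excluded.
    """
    TE = np.asarray(TE, dtype=float)
    if np.any((TE <= 0) | (TE >= 1)):
        raise ValueError("TE values must be in (0, 1)")
    S = web.S
    k = np.full(S, EEH_BASELINE)
    prey_lists: dict[int, list[float]] = {}
    for (j, i), ratio in ppmr.items():
        prey_lists.setdefault(i, []).append(ratio)
    for i, ratios in prey_lists.items():
        terms = []
        for ratio in ratios:
            if ratio > 1:
                terms.append(math.log(TE[i]) / math.log(ratio))
            elif ratio < 1:
                terms.append(math.log1p(-TE[i]) / math.log(ratio))
            # ratio == 1: excluded (log ratio undefined)
        if not terms:
            raise ValueError(
                f"species {i}: every predator-prey mass ratio equals 1; "
                "scaling correction undefined"
            )
        k[i] = EEH_BASELINE + sum(terms) / len(ratios)
    return k


# ---------------------------------------------------------------------------
# Community assembly and harvest
# ---------------------------------------------------------------------------

def simulate_community(
    params: SimParams,
    seed: int | None = None,
    *,
    ppmr_rule: str = "none",
    eeh_only: bool = False,
) -> Community:
    """Assemble one community: web, trophic levels, masses, TE, k, biomass.

    Biomass follows ``B_i = M_i**k_i`` (unit proportionality constant — the
    fitted slope is invariant to it) and ``k_c`` is the OLS slope of
    log B on log M.

    Parameters
    ----------
    params : SimParams
    seed : int, optional
        Overrides ``params.seed``.
    ppmr_rule : {"none", "gt1"}
        With ``"gt1"``, links whose predator-prey mass ratio is <= 1 are
        dropped before computing the scaling coefficients, so every
        retained link has the predator heavier than its prey (predators
        losing all prey revert to the basal baseline k = 0.25).
    eeh_only : bool
        Disable the trophic transfer correction entirely: every species
        keeps k = 0.25.
    """
    if ppmr_rule not in ("none", "gt1"):
        raise ValueError(f"unknown ppmr_rule {ppmr_rule!r}")
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    web_ss, mass_ss = root.spawn(2)
    web = generate_niche_web(
        params.S, params.connectance_target, np.random.default_rng(web_ss)
    )
    TL = trophic_levels(web)
    M = assign_body_masses(
        TL, params.Q, params.M0, params.noise_sd, np.random.default_rng(mass_ss)
    )
    ppmr = ppmr_pairs(M, web)
    if ppmr_rule == "gt1":
        ppmr = {pair: v for pair, v in ppmr.items() if v > 1}
    TE = transfer_efficiencies(M, params.TE_max)
    if eeh_only:
        k = np.full(params.S, EEH_BASELINE)
    else:
        k = species_scaling_coefficients(web, TE, ppmr)
    # fit in log space: log10 B = k * log10 M exactly, immune to the
    # under/overflow of M**k at extreme k (PPMR close to 1)
    log_m = np.log10(M)
    log_b = k * log_m
    k_c = float(np.polyfit(log_m, log_b, 1)[0])
    with np.errstate(over="ignore", under="ignore"):
        B = np.power(10.0, log_b)
    return Community(web=web, TL=TL, M=M, TE=TE, k=k, B=B, k_c=k_c, params=params)


def _survivor_fractions(r: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Biomass and mean-mass retention after removing the top-r mass quantile.

    Individual masses are lognormal with mean M and log-scale s.d. sigma.
    Removing the heaviest fraction r leaves a number fraction (1 - r), a
    biomass fraction Phi(z_{1-r} - sigma) (partial expectation of the
    lognormal), and a mean-mass ratio biomass_frac / (1 - r). sigma = 0
    collapses to pure abundance removal.
    """
    r = np.asarray(r, dtype=float)
    keep = np.clip(1.0 - r, 1e-12, 1.0)
    if sigma == 0:
        return keep.copy(), np.ones_like(keep)
    z = stats.norm.ppf(keep)
    biomass_frac = stats.norm.cdf(z - sigma)
    mass_ratio = biomass_frac / keep
    return biomass_frac, mass_ratio


def harvest_community(
    community: Community,
    params: SimParams | None = None,
    seed: int | np.random.Generator = 0,
) -> HarvestOutcome:
    """Apply size-selective harvest and refit the biomass-size slope.

    ``round(harvest_fraction * S)`` species are drawn without replacement
    with selection probability proportional to body mass (larger fish are
    likelier targets). Each harvested species loses its heaviest
    ``r_i ~ U[r_min, 1]`` fraction of individuals under a lognormal
    intraspecific size distribution, which lowers both its biomass and its
    mean body mass; unharvested species are untouched.
    """
    if params is None:
        params = community.params
    rng = np.random.default_rng(seed)
    S = community.S
    n_harvest = int(np.rint(params.harvest_fraction * S))
    n_harvest = max(1, min(S, n_harvest))
    weights = community.M / community.M.sum()
    harvested = np.sort(rng.choice(S, size=n_harvest, replace=False, p=weights))
    r = rng.uniform(params.r_min, 1.0, size=n_harvest)
    biomass_frac, mass_ratio = _survivor_fractions(r, params.sigma_intra)
    log_m_h = np.log10(community.M)
    log_b_h = community.k * log_m_h
    log_m_h[harvested] += np.log10(mass_ratio)
    log_b_h[harvested] += np.log10(biomass_frac)
    k_c_h = float(np.polyfit(log_m_h, log_b_h, 1)[0])
    M_h = community.M.copy()
    B_h = community.B.copy()
    M_h[harvested] *= mass_ratio
    B_h[harvested] *= biomass_frac
    return HarvestOutcome(
        harvested_ids=harvested, r=r, M_h=M_h, B_h=B_h, k_c_h=k_c_h
    )


def run_experiment(
    params: SimParams,
    te_grid: Sequence[float] = DEFAULT_TE_GRID,
):
    """Replicated protected-vs-harvested experiment over a TE_max sweep.

    For each TE_max level, ``params.n_reps`` independent communities are
    simulated and harvested; one row per replicate records the protected
    slope ``k_c`` and the harvested slope ``k_c_h``.

    Returns
    -------
    pandas.DataFrame
        Columns ``te_max, rep, k_c, k_c_h``.
    """
    import pandas as pd

    root = np.random.SeedSequence(params.seed)
    rows = []
    for te_max in te_grid:
        level_params = replace(params, TE_max=float(te_max))
        for rep in range(params.n_reps):
            com_ss, harv_ss = root.spawn(2)
            com_seed = int(com_ss.generate_state(1)[0] % (2**31))
            community = simulate_community(level_params, seed=com_seed)
            outcome = harvest_community(
                community, level_params, np.random.default_rng(harv_ss)
            )
            rows.append(
                {
                    "te_max": float(te_max),
                    "rep": rep,
                    "k_c": community.k_c,
                    "k_c_h": outcome.k_c_h,
                }
            )
    return pd.DataFrame(rows, columns=["te_max", "rep", "k_c", "k_c_h"])
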