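"""Community-structure statistics for survey tables.

Operates on long-format survey tables (one row per site, year, survey,
species) and on per-community vectors: the biomass--size scaling slope,
community-weighted mean body mass, Spearman rank correlation between body
mass and trophic level, the survey-effort filter, thermal-stress-anomaly
counting, rarefaction, two-sample Kolmogorov--Smirnov comparison, and
median binarization.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SURVEY_COLUMNS",
    "fit_scaling_coefficient",
    "community_weighted_mean_mass",
    "spearman_rho",
    "aggregate_surveys",
    "filter_communities",
    "tsa_count",
    "rarefaction_curve",
    "ks_two_sample",
    "binarize_at_median",
]

#: Required columns of a long-format survey table.
SURVEY_COLUMNS = ("site", "year", "survey", "species", "mass", "abundance", "biomass")


def fit_scaling_coefficient(M, B) -> tuple[float, float]:
    """OLS slope and intercept of log10 biomass on log10 body mass.

    The slope is the community scaling coefficient ``k_c``; higher values
    indicate a more top-heavy biomass--size spectrum. The slope is
    invariant to the (shared) logarithm base.

    Raises
    ------
    ValueError
        For fewer than 3 species, non-positive values, or zero variance
        in mass (the regressor).
    """
    M = np.asarray(M, dtype=float)
    B = np.asarray(B, dtype=float)
    if M.shape != B.shape or M.ndim != 1:
        raise ValueError("M and B must be 1-d arrays of equal length")
    if M.size < 3:
        raise ValueError(f"need >= 3 species to fit a slope, got {M.size}")
    if np.any(M <= 0) or np.any(B <= 0):
        raise ValueError("masses and biomasses must be strictly positive")
    x = np.log10(M)
    y = np.log10(B)
    if np.ptp(x) == 0:
        raise ValueError("all masses identical: slope undefined (zero-variance regressor)")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def community_weighted_mean_mass(M, abundance) -> float:
    """Abundance-weighted mean body mass, ``sum(a_i M_i) / sum(a_i)``."""
    M = np.asarray(M, dtype=float)
    a = np.asarray(abundance, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("total abundance is zero: CWM undefined")
    return float((a * M).sum() / total)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with midrank ties.

    Returns NaN when either vector is constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _check_survey(table: pd.DataFrame) -> None:
    missing = [c for c in SURVEY_COLUMNS[:-1] if c not in table.columns]
    # biomass may be derivable, but we require it for aggregation
    if "biomass" not in table.columns:
        missing.append("biomass")
    if missing:
        raise ValueError(f"survey table missing columns: {missing}")
    if table.duplicated(subset=["site", "year", "survey", "species"]).any():
        raise ValueError("duplicate (site, year, survey, species) keys in survey table")


def aggregate_surveys(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a survey table by site-year.

    Within a site-year, species biomass is summed across surveys (total
    biomass is conserved) and mean body mass is abundance-weighted; when
    all abundances are zero the plain mean is used. An optional ``tl``
    column (trophic level) is averaged.

    Returns one row per (site, year, species) with columns
    ``site, year, species, mass, abundance, biomass`` (+ ``tl``).
    """
    _check_survey(table)
    has_tl = "tl" in table.columns

    def _agg(g: pd.DataFrame) -> pd.Series:
        a = g["abundance"].to_numpy(float)
        m = g["mass"].to_numpy(float)
        mass = (a * m).sum() / a.sum() if a.sum() > 0 else m.mean()
        out = {
            "mass": mass,
            "abundance": a.sum(),
            "biomass": g["biomass"].sum(),
        }
        if has_tl:
            out["tl"] = g["tl"].mean()
        return pd.Series(out)

    agg = (
        table.groupby(["site", "year", "species"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    return agg


def filter_communities(
    table: pd.DataFrame,
    min_surveys: int = 2,
    min_species: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Yearly-aggregated community observations passing the effort filter.

    A site-year is retained when it was surveyed at least ``min_surveys``
    times that year and contains at least ``min_species`` species after
    aggregation (both thresholds inclusive).

    Returns
    -------
    (communities, species)
        ``communities``: one row per retained site-year with
        ``site, year, n_surveys, richness, k_c, cwm_mass`` and, when a
        ``tl`` column is present, ``rho_bm_tl``. ``k_c`` is NaN when the
        slope is undefined (fewer than 3 species with distinct masses).
        ``species``: the aggregated per-species rows of retained
        site-years.
    """
    _check_survey(table)
    has_tl = "tl" in table.columns
    base_cols = ["site", "year", "n_surveys", "richness", "k_c", "cwm_mass"] + (
        ["rho_bm_tl"] if has_tl else []
    )
    if table.empty:
        spp_cols = ["site", "year", "species", "mass", "abundance", "biomass"] + (
            ["tl"] if has_tl else []
        )
        return pd.DataFrame(columns=base_cols), pd.DataFrame(columns=spp_cols)
    effort = (
        table.groupby(["site", "year"])["survey"].nunique().rename("n_surveys")
    )
    agg = aggregate_surveys(table)
    richness = agg.groupby(["site", "year"])["species"].nunique().rename("richness")
    meta = pd.concat([effort, richness], axis=1).reset_index()
    keep = meta[(meta["n_surveys"] >= min_surveys) & (meta["richness"] >= min_species)]
    keys = set(map(tuple, keep[["site", "year"]].itertuples(index=False)))
    species = agg[[tuple(r) in keys for r in agg[["site", "year"]].itertuples(index=False)]]

    rows = []
    for (site, year), g in species.groupby(["site", "year"], sort=True):
        try:
            k_c, _ = fit_scaling_coefficient(g["mass"], g["biomass"])
        except ValueError:
            k_c = float("nan")
        row = {
            "site": site,
            "year": year,
            "n_surveys": int(effort.loc[(site, year)]),
            "richness": int(g["species"].nunique()),
            "k_c": k_c,
            "cwm_mass": community_weighted_mean_mass(g["mass"], g["abundance"]),
        }
        if has_tl:
            row["rho_bm_tl"] = spearman_rho(g["mass"], g["tl"])
        rows.append(row)
    communities = pd.DataFrame(rows, columns=base_cols)
    return communities, species.reset_index(drop=True)


def tsa_count(weekly_sst, climatology_max, threshold: float = 1.0) -> int:
    """Count thermal stress anomalies.

    A TSA event is a week in which sea surface temperature exceeds the
    maximum weekly climatological SST by strictly more than ``threshold``
    degrees C.
    """
    sst = np.asarray(weekly_sst, dtype=float)
    clim = np.asarray(climatology_max, dtype=float)
    if clim.ndim == 0:
        clim = np.full_like(sst, float(clim))
    if sst.shape != clim.shape:
        raise ValueError(
            f"length mismatch: SST has {sst.shape}, climatology has {clim.shape}"
        )
    return int(np.sum((sst - clim) > threshold))


def rarefaction_curve(
    site_year: pd.DataFrame,
    efforts: Sequence[int],
    n_resample: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Mean species richness as a function of sampling effort.

    For each effort ``e``, draws ``e`` surveys without replacement from
    the site-year's surveys, counts the pooled richness, and averages
    over ``n_resample`` resamples. At full effort the curve equals the
    observed richness with zero variance.

    Parameters
    ----------
    site_year : DataFrame
        Rows of one site-year with ``survey`` and ``species`` columns.
    efforts : sequence of int
        Numbers of surveys to draw; each must not exceed the surveys
        available.
    """
    if site_year.empty:
        raise ValueError("need at least one survey")
    surveys = sorted(site_year["survey"].unique())
    species_by_survey = [
        set(site_year.loc[site_year["survey"] == s, "species"]) for s in surveys
    ]
    n_avail = len(surveys)
    rng = np.random.default_rng(seed)
    means = {}
    for e in efforts:
        if not 1 <= e <= n_avail:
            raise ValueError(f"effort {e} exceeds available surveys ({n_avail})")
        if e == n_avail:
            means[e] = float(len(set().union(*species_by_survey)))
            continue
        richness = np.empty(n_resample)
        for b in range(n_resample):
            idx = rng.choice(n_avail, size=e, replace=False)
            richness[b] = len(set().union(*(species_by_survey[i] for i in idx)))
        means[e] = float(richness.mean())
    return pd.Series(means, name="mean_richness")


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov--Smirnov statistic and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def binarize_at_median(values) -> np.ndarray:
    """Binarize strictly above the median: ``v > median -> 1``, else 0.

    Ties at the median map to 0, so at most half the entries become 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    return (v > np.median(v)).astype(int)
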