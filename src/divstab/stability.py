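"""Spatial variability of biomass and the species-covariation statistic.

For each block of plots we compute the spatial mean µ, spatial standard
deviation σ, and coefficient of variation CV = σ/µ of total live biomass,
and the species covariation statistic

    covariation = σ_T² / (Σ_i σ_i)²

where σ_T² is the among-plot variance of total biomass and σ_i the
among-plot standard deviation of species i's biomass.  Covariation is the
spatial analog of temporal species synchrony: 1 when all species track the
environment in unison, 0 under perfect spatial compensation.

Per-species biomass is not measured directly; it is proxied by splitting
each plot's total live biomass according to the species' relative cover in
that plot.

Environmental heterogeneity is the mean pairwise Euclidean distance among a
block's plots in z-standardized soil/light space, with standardization
performed over the whole dataset so blocks are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .diversity import BlockCoverMatrix

__all__ = [
    "UndefinedMetricError",
    "SpeciesBiomassMatrix",
    "StabilitySummary",
    "species_biomass",
    "spatial_variability",
    "species_covariation",
    "standardize_soil",
    "environmental_heterogeneity",
    "SOIL_VARIABLES",
]

SOIL_VARIABLES = ("C_pct", "N_pct", "P_ppm", "K_ppm", "pH", "light")


class UndefinedMetricError(ValueError):
    """The requested statistic is undefined for this block (e.g. σ_i all 0)."""


@dataclass
class SpeciesBiomassMatrix:
    """Plots x taxa biomass proxy (g m⁻²); rows sum to plot total biomass."""

    plot_ids: Sequence[str]
    taxa: Sequence[str]
    biomass: np.ndarray

    def row_totals(self) -> np.ndarray:
        return self.biomass.sum(axis=1)


class StabilitySummary(NamedTuple):
    mu: float
    sigma: float
    cv: float
    log_cv: float  # NaN when cv == 0 (block excluded from log-scale fits)


def species_biomass(m: BlockCoverMatrix, biomass: np.ndarray) -> SpeciesBiomassMatrix:
    """Split each plot's biomass across species by relative cover.

    Summed cover can exceed 100%, so cover is first normalized to relative
    proportions within the plot; the resulting rows conserve plot biomass
    exactly.  Plots with zero biomass yield all-zero rows.
    """
    biomass = np.asarray(biomass, dtype=float)
    if biomass.shape != (m.n_plots,):
        raise ValueError("biomass vector length must equal the number of plots")
    if (biomass < 0).any():
        raise ValueError("biomass must be >= 0")
    totals = m.cover.sum(axis=1)
    bad = (biomass > 0) & (totals <= 0)
    if bad.any():
        plot = m.plot_ids[int(np.argmax(bad))]
        raise UndefinedMetricError(
            f"plot {plot!r} has positive biomass but zero summed cover; species proxy undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals[:, None] > 0, m.cover / np.where(totals == 0, 1, totals)[:, None], 0.0)
    return SpeciesBiomassMatrix(m.plot_ids, m.taxa, rel * biomass[:, None])


def spatial_variability(biomass: np.ndarray) -> StabilitySummary:
    """µ, σ (sample sd, n−1), CV = σ/µ, and ln CV of per-plot biomass."""
    b = np.asarray(biomass, dtype=float)
    if b.size < 2:
        raise ValueError("spatial variability requires >= 2 plots")
    mu = float(b.mean())
    if mu <= 0:
        raise UndefinedMetricError("mean biomass is 0; CV undefined")
    sigma = float(b.std(ddof=1))
    cv = sigma / mu
    log_cv = float(np.log(cv)) if cv > 0 else float("nan")
    return StabilitySummary(mu=mu, sigma=sigma, cv=cv, log_cv=log_cv)


def species_covariation(sb: SpeciesBiomassMatrix, variant: str = "squared") -> float:
    """Spatial species covariation of a block.

    ``squared`` (default) is σ_T²/(Σσ_i)², the dimensionless synchrony form
    bounded in [0, 1] by Cauchy–Schwarz.  ``as_printed`` divides by the
    unsquared Σσ_i instead; it carries units of biomass and is provided only
    for comparison with sources that print the formula that way.
    """
    x = np.asarray(sb.biomass, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("species covariation requires >= 2 plots")
    sigma_i = x.std(axis=0, ddof=1)
    denom = sigma_i.sum()
    if denom <= 0:
        raise UndefinedMetricError(
            "all species spatial standard deviations are 0; covariation undefined"
        )
    var_t = x.sum(axis=1).var(ddof=1)
    if variant == "squared":
        return float(var_t / denom**2)
    if variant == "as_printed":
        return float(var_t / denom)
    raise ValueError(f"unknown covariation variant {variant!r}")


def standardize_soil(
    soil: pd.DataFrame, variables: Sequence[str] = SOIL_VARIABLES
) -> pd.DataFrame:
    """Z-standardize soil/light variables over all plots in the dataset.

    Variables absent from the table are ignored; variables that are constant
    dataset-wide carry no heterogeneity information and are dropped with a
    warning.  Returns the key columns plus the standardized variables.
    """
    present = [v for v in variables if v in soil.columns]
    if not present:
        raise ValueError(f"no soil variables found among {list(variables)}")
    out = soil[["site_id", "block_id", "plot_id"]].copy()
    for v in present:
        col = pd.to_numeric(soil[v])
        sd = col.std(ddof=1)
        # tolerance: a numerically-constant column (sd at rounding level)
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(abs(col.mean()))):
            warnings.warn(f"soil variable {v!r} is constant dataset-wide; dropped")
            continue
        out[v] = (col - col.mean()) / sd
    if out.shape[1] == 3:
        raise ValueError("all soil variables are constant; heterogeneity undefined")
    return out


def environmental_heterogeneity(z: np.ndarray) -> float:
    """Mean pairwise Euclidean distance among a block's plots.

    ``z`` is the block's plots x variables matrix of dataset-standardized
    soil/light values.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("environmental heterogeneity requires >= 2 plots")
    return float(pdist(z, metric="euclidean").mean())
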