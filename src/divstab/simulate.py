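"""Seeded metacommunity simulator with known ground truth.

The generator emulates a distributed grassland survey: sites hold three
blocks of ten 25 m² plots; each plot has a latent environmental state
(block mean + within-block noise on a single axis); each site draws a
species pool whose size varies among sites, creating a diversity gradient.
Species respond to the environment through Gaussian niches: a fraction
``insurance_strength`` of the pool has niche optima dispersed along the
axis (the spatial-insurance mechanism — different species peak in
different patches), while the remainder share the central optimum.
Percent cover is the niche response times multiplicative lognormal noise,
recorded to the nearest 1% as in field protocols (so rare species register
as absent), and plot biomass is proportional to summed cover with
additional noise.

``apply_treatments`` turns a pre-treatment survey into the factorial
nutrient-addition / fencing phase: the ten treatments are assigned within
each block, nutrients shift the plot's latent environment (distinct shifts
per nutrient, so among-plot environmental variance rises), biomass is
multiplied by a treatment factor, and fertilization removes species with a
treatment-specific probability.

A DAG-linear generator (``simulate_dag_data``) provides ground-truth data
for SEM recovery and calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import SurveyDataset, write_survey
from .sem import DagSpec

__all__ = [
    "ConfigError",
    "SimConfig",
    "SimTruth",
    "default_treatment_effects",
    "simulate_survey",
    "apply_treatments",
    "make_fixture",
    "simulate_dag_data",
    "TREATMENTS",
]

#: The ten within-block treatments of the factorial experiment.
TREATMENTS = (
    "control", "N", "P", "Kmu", "NP", "NKmu", "PKmu", "NPKmu", "fence", "fence+NPKmu",
)

def default_nutrient_shifts() -> dict:
    """Latent-environment shift per added nutrient (distinct magnitudes and
    signs so each nutrient combination creates a distinct patch niche)."""
    return {"N": 1.2, "P": -0.9, "Kmu": 0.5}


class ConfigError(ValueError):
    """A SimConfig field is invalid."""


def default_treatment_effects() -> dict:
    """(biomass multiplier, per-species richness-loss probability) per treatment.

    Fertilization raises biomass and loses species (strongest for the full
    NPK mix); fencing raises biomass slightly without species loss.
    """
    return {
        "control": (1.0, 0.0),
        "N": (1.25, 0.10),
        "P": (1.10, 0.03),
        "Kmu": (1.05, 0.02),
        "NP": (1.35, 0.12),
        "NKmu": (1.30, 0.11),
        "PKmu": (1.15, 0.05),
        "NPKmu": (1.50, 0.15),
        "fence": (1.10, 0.0),
        "fence+NPKmu": (1.60, 0.15),
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults define the emulated study conditions."""

    n_sites: int = 83
    n_blocks_per_site: int = 3
    n_plots_per_block: int = 10
    pool_size_range: tuple[int, int] = (5, 50)
    niche_breadth: float = 0.6  # Gaussian niche sd on the latent axis
    env_sd_within_block: float = 1.0  # "h": patch-scale heterogeneity
    env_sd_between: float = 0.5  # block-mean spread within a site
    insurance_strength: float = 1.0  # fraction of pool with dispersed optima
    cover_noise_sd: float = 0.5  # lognormal sigma on cover
    cover_scale: float = 30.0  # peak expected cover (%) of one species
    biomass_per_cover: float = 3.0  # g m^-2 per summed cover %
    biomass_noise_sd: float = 0.2
    treatment_effects: dict = field(default_factory=default_treatment_effects)
    nutrient_env_shifts: dict = field(default_factory=default_nutrient_shifts)
    seed: int = 0

    def validate(self) -> None:
        checks = {
            "n_sites": self.n_sites >= 1,
            "n_blocks_per_site": self.n_blocks_per_site >= 1,
            "n_plots_per_block": self.n_plots_per_block >= 2,
            "pool_size_range": (
                len(self.pool_size_range) == 2
                and 2 <= self.pool_size_range[0] <= self.pool_size_range[1]
            ),
            "niche_breadth": self.niche_breadth > 0,
            "env_sd_within_block": self.env_sd_within_block >= 0,
            "env_sd_between": self.env_sd_between >= 0,
            "insurance_strength": 0 <= self.insurance_strength <= 1,
            "cover_noise_sd": self.cover_noise_sd >= 0,
            "cover_scale": self.cover_scale > 0,
            "biomass_per_cover": self.biomass_per_cover > 0,
            "biomass_noise_sd": self.biomass_noise_sd >= 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ConfigError(f"invalid SimConfig field {name!r}: {getattr(self, name)!r}")
        for t, (mult, loss) in self.treatment_effects.items():
            if t not in TREATMENTS:
                raise ConfigError(f"invalid SimConfig field 'treatment_effects': unknown treatment {t!r}")
            if mult < 0 or not (0 <= loss <= 1):
                raise ConfigError(
                    f"invalid SimConfig field 'treatment_effects': {t!r} -> ({mult}, {loss})"
                )
        for k in self.nutrient_env_shifts:
            if k not in ("N", "P", "Kmu"):
                raise ConfigError(
                    f"invalid SimConfig field 'nutrient_env_shifts': unknown nutrient {k!r}"
                )


@dataclass
class SimTruth:
    """Ground truth behind a simulated survey, reproducible from (config, seed)."""

    config: SimConfig
    pools: pd.DataFrame  # site_id, pool_size
    species: pd.DataFrame  # site_id, taxon, optimum
    env: pd.DataFrame  # site_id, block_id, plot_id, env (latent axis)


def _site_ids(n: int) -> list[str]:
    return [f"site{i:03d}" for i in range(1, n + 1)]


def _niche_cover(env: np.ndarray, optima: np.ndarray, cfg: SimConfig, rng) -> np.ndarray:
    """Expected cover matrix (plots x species) times lognormal noise, in %."""
    w2 = 2.0 * cfg.niche_breadth**2
    expected = cfg.cover_scale * np.exp(-((env[:, None] - optima[None, :]) ** 2) / w2)
    noise = np.exp(rng.normal(0.0, cfg.cover_noise_sd, size=expected.shape))
    cover = np.rint(expected * noise)  # recorded to the nearest 1%
    return np.clip(cover, 0.0, 100.0)


def _soil_from_env(env: np.ndarray, rng) -> dict:
    """Noisy linear soil/light readouts of the latent environmental axis."""
    n = len(env)
    return {
        "C_pct": 2.0 + 0.5 * env + rng.normal(0, 0.3, n),
        "N_pct": 0.2 + 0.05 * env + rng.normal(0, 0.05, n),
        "P_ppm": 30.0 + 8.0 * env + rng.normal(0, 5.0, n),
        "K_ppm": 150.0 + 30.0 * env + rng.normal(0, 20.0, n),
        "pH": 6.0 + 0.3 * env + rng.normal(0, 0.2, n),
        "light": np.clip(50.0 - 5.0 * env + rng.normal(0, 5.0, n), 0, 100),
    }


def simulate_survey(cfg: SimConfig) -> tuple[SurveyDataset, SimTruth]:
    """Generate a pre-treatment survey with known ground truth.

    Deterministic given (config, seed): the same configuration always
    yields byte-identical tables.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cover_rows = []
    biomass_rows = []
    soil_rows = []
    pool_rows = []
    species_rows = []
    env_rows = []
    climate_rows = []

    for site in _site_ids(cfg.n_sites):
        pool = int(rng.integers(cfg.pool_size_range[0], cfg.pool_size_range[1] + 1))
        n_dispersed = int(round(cfg.insurance_strength * pool))
        optima = np.zeros(pool)
        if n_dispersed > 0:
            optima[:n_dispersed] = rng.uniform(-2.2, 2.2, n_dispersed)
        taxa = [f"{site}_sp{i:03d}" for i in range(1, pool + 1)]
        pool_rows.append({"site_id": site, "pool_size": pool})
        species_rows.extend(
            {"site_id": site, "taxon": t, "optimum": o} for t, o in zip(taxa, optima)
        )
        climate_rows.append(
            {
                "site_id": site,
                "MAT": rng.uniform(-5, 25),
                "MAP": rng.uniform(200, 2500),
                "temp_range": rng.uniform(10, 40),
                "temp_sd": rng.uniform(2, 10),
                "precip_cv": rng.uniform(10, 60),
                "temp_wettest4": rng.uniform(-5, 25) + rng.uniform(0, 8),
            }
        )

        for b in range(1, cfg.n_blocks_per_site + 1):
            block = f"b{b}"
            block_mean = rng.normal(0.0, cfg.env_sd_between)
            env = block_mean + rng.normal(0.0, cfg.env_sd_within_block, cfg.n_plots_per_block)
            plots = [f"p{j:02d}" for j in range(1, cfg.n_plots_per_block + 1)]
            cover = _niche_cover(env, optima, cfg, rng)
            summed = cover.sum(axis=1)
            biomass = cfg.biomass_per_cover * summed * np.maximum(
                0.0, 1.0 + rng.normal(0.0, cfg.biomass_noise_sd, cfg.n_plots_per_block)
            )
            soil = _soil_from_env(env, rng)
            for j, plot in enumerate(plots):
                env_rows.append(
                    {"site_id": site, "block_id": block, "plot_id": plot, "env": env[j]}
                )
                biomass_rows.append(
                    {
                        "site_id": site,
                        "block_id": block,
                        "plot_id": plot,
                        "treatment": "pretreatment",
                        "live_biomass_g_m2": biomass[j],
                    }
                )
                soil_rows.append(
                    {
                        "site_id": site,
                        "block_id": block,
                        "plot_id": plot,
                        **{k: v[j] for k, v in soil.items()},
                    }
                )
                present = np.nonzero(cover[j] > 0)[0]
                cover_rows.extend(
                    {
                        "site_id": site,
                        "block_id": block,
                        "plot_id": plot,
                        "treatment": "pretreatment",
                        "taxon": taxa[s],
                        "cover": cover[j, s],
                    }
                    for s in present
                )

    data = SurveyDataset(
        cover=pd.DataFrame(cover_rows, columns=["site_id", "block_id", "plot_id", "treatment", "taxon", "cover"]),
        biomass=pd.DataFrame(biomass_rows),
        soil=pd.DataFrame(soil_rows),
        climate=pd.DataFrame(climate_rows),
        phase="pretreatment",
    )
    truth = SimTruth(
        config=replace(cfg),
        pools=pd.DataFrame(pool_rows),
        species=pd.DataFrame(species_rows),
        env=pd.DataFrame(env_rows),
    )
    return data, truth


def _treatment_shift(treatment: str, shifts: dict) -> float:
    return sum(v for k, v in shifts.items() if k in treatment)


def apply_treatments(data: SurveyDataset, cfg: SimConfig, truth: SimTruth) -> SurveyDataset:
    """Produce the post-treatment (enhanced heterogeneity) phase.

    Each block's plots receive the ten treatments in random order; nutrient
    combinations shift the plot's latent environment (raising among-plot
    environmental variance), cover is regenerated from the niche model at
    the shifted environment, fertilization removes species with the
    treatment's loss probability, and biomass is scaled by the treatment
    multiplier.
    """
    import warnings as _warnings

    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed), 1])
    optima_by_site = {
        site: grp.set_index("taxon")["optimum"]
        for site, grp in truth.species.groupby("site_id")
    }
    env_lookup = truth.env.set_index(["site_id", "block_id", "plot_id"])["env"]

    cover_rows = []
    biomass_rows = []
    soil_rows = []
    for site, block, bm, cv_long, _soil in data.iter_blocks():
        plots = list(bm["plot_id"])
        if len(plots) == cfg.n_plots_per_block == len(TREATMENTS):
            assigned = list(np.array(TREATMENTS)[rng.permutation(len(TREATMENTS))])
        else:
            _warnings.warn(
                f"block ({site}, {block}) has {len(plots)} plots, not {len(TREATMENTS)}; "
                "assigning a random treatment subset"
            )
            assigned = list(rng.choice(TREATMENTS, size=len(plots), replace=len(plots) > len(TREATMENTS)))
        optima = optima_by_site[site]
        taxa = list(optima.index)
        taxon_idx = {t: i for i, t in enumerate(taxa)}
        env = np.array([env_lookup[(site, block, p)] for p in plots])
        shifts = np.array([_treatment_shift(t, cfg.nutrient_env_shifts) for t in assigned])
        env_new = env + shifts

        # plots whose environment shifted re-express the niche model (with
        # fresh noise); unshifted plots keep their observed community, so an
        # all-identity treatment configuration is a strict no-op
        regen = _niche_cover(env_new, optima.to_numpy(), cfg, rng)
        bio_noise = np.maximum(0.0, 1.0 + rng.normal(0.0, cfg.biomass_noise_sd, len(plots)))
        orig_cover = np.zeros((len(plots), len(taxa)))
        plot_idx = {p: j for j, p in enumerate(plots)}
        for r in cv_long.itertuples(index=False):
            if r.taxon in taxon_idx:
                orig_cover[plot_idx[r.plot_id], taxon_idx[r.taxon]] = r.cover
        orig_biomass = bm["live_biomass_g_m2"].to_numpy(dtype=float)

        shifted = shifts != 0.0
        cover = np.where(shifted[:, None], regen, orig_cover)
        base_biomass = np.where(
            shifted, cfg.biomass_per_cover * regen.sum(axis=1) * bio_noise, orig_biomass
        )
        # fertilization-driven species loss, with biomass reduced pro rata
        for j, t in enumerate(assigned):
            loss = cfg.treatment_effects[t][1]
            if loss > 0:
                pre_sum = cover[j].sum()
                gone = rng.random(cover.shape[1]) < loss
                cover[j, gone] = 0.0
                if pre_sum > 0:
                    base_biomass[j] *= cover[j].sum() / pre_sum
        mults = np.array([cfg.treatment_effects[t][0] for t in assigned])
        biomass = base_biomass * mults
        soil = _soil_from_env(env_new, rng)
        # fertilized plots carry the added nutrients in their soil chemistry
        for j, t in enumerate(assigned):
            if "N" in t:
                soil["N_pct"][j] += 0.15
            if "P" in t:
                soil["P_ppm"][j] += 25.0
            if "Kmu" in t:
                soil["K_ppm"][j] += 60.0
        for j, plot in enumerate(plots):
            biomass_rows.append(
                {
                    "site_id": site,
                    "block_id": block,
                    "plot_id": plot,
                    "treatment": assigned[j],
                    "live_biomass_g_m2": biomass[j],
                }
            )
            soil_rows.append(
                {
                    "site_id": site,
                    "block_id": block,
                    "plot_id": plot,
                    **{k: v[j] for k, v in soil.items()},
                }
            )
            present = np.nonzero(cover[j] > 0)[0]
            cover_rows.extend(
                {
                    "site_id": site,
                    "block_id": block,
                    "plot_id": plot,
                    "treatment": assigned[j],
                    "taxon": taxa[s],
                    "cover": cover[j, s],
                }
                for s in present
            )

    return SurveyDataset(
        cover=pd.DataFrame(cover_rows, columns=["site_id", "block_id", "plot_id", "treatment", "taxon", "cover"]),
        biomass=pd.DataFrame(biomass_rows),
        soil=pd.DataFrame(soil_rows),
        climate=data.climate.copy() if data.climate is not None else None,
        phase="treatment_year",
    )


def make_fixture(scale: str, seed: int, out_dir, treatments: bool = False) -> dict:
    """Write a CSV fixture bundle; ``tiny`` for unit tests, ``paper_like``
    for the full 83-site x 3-block x 10-plot design shape."""
    if scale == "tiny":
        cfg = SimConfig(n_sites=3, n_blocks_per_site=4, pool_size_range=(4, 12), seed=seed)
    elif scale == "paper_like":
        cfg = SimConfig(seed=seed)
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    data, truth = simulate_survey(cfg)
    out = Path(out_dir)
    paths = write_survey(data, out)
    if treatments:
        post = apply_treatments(data, cfg, truth)
        paths.update(
            {f"post_{k}": v for k, v in write_survey(post, out / "post").items()}
        )
    return paths


def simulate_dag_data(
    dag: DagSpec,
    coefficients: dict,
    n_sites: int = 40,
    n_blocks_per_site: int = 3,
    site_sd: float = 0.3,
    exo_corr: float = 0.3,
    seed: int = 0,
    coefficients_post: Optional[dict] = None,
) -> pd.DataFrame:
    """Linear-Gaussian data from a DAG with known standardized coefficients.

    Exogenous nodes are standard normal (correlated-error pairs get
    correlation ``exo_corr``); each endogenous node is the structural sum
    plus a site random intercept (sd ``site_sd``) and residual noise scaled
    so its total variance is ~1, making the generating coefficients
    directly comparable with standardized path estimates.  When
    ``coefficients_post`` is given, a second phase is generated with those
    coefficients and the frames are stacked with a ``phase`` column.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    n = n_sites * n_blocks_per_site
    sites = np.repeat([f"site{i:03d}" for i in range(n_sites)], n_blocks_per_site)

    def one_phase(coefs: dict) -> pd.DataFrame:
        df = pd.DataFrame({"site_id": sites})
        exo = list(dag.exogenous)
        cov = np.eye(len(exo))
        for pair in dag.correlated:
            a, b = tuple(pair)
            if a in exo and b in exo:
                i, j = exo.index(a), exo.index(b)
                cov[i, j] = cov[j, i] = exo_corr
        vals = rng.multivariate_normal(np.zeros(len(exo)), cov, size=n)
        for i, node in enumerate(exo):
            df[node] = vals[:, i]
        order = list(nx.lexicographical_topological_sort(dag.graph()))
        for node in order:
            parents = dag.parents(node)
            if not parents:
                continue
            struct = np.zeros(n)
            for p in parents:
                beta = coefs.get((p, node), 0.0)
                struct += beta * df[p].to_numpy()
            site_eff = rng.normal(0.0, site_sd, n_sites)
            re = np.repeat(site_eff, n_blocks_per_site)
            var_eps = max(1.0 - float(np.var(struct)) - site_sd**2, 0.05)
            df[node] = struct + re + rng.normal(0.0, np.sqrt(var_eps), n)
        return df

    pre = one_phase(coefficients)
    if coefficients_post is None:
        return pre
    post = one_phase(coefficients_post)
    return pd.concat(
        [pre.assign(phase=0.0), post.assign(phase=1.0)], ignore_index=True
    )
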