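"""Readers, writers, and validation for long-format grassland survey tables.

The pipeline consumes a bundle of plain CSV files:

``cover.csv``
    one row per (plot, taxon): ``site_id, block_id, plot_id, treatment,
    taxon, cover`` with cover in percent.  Cover is estimated independently
    per species, so the summed cover of a plot may exceed 100% (multilayer
    canopies).
``biomass.csv``
    one row per plot: ``site_id, block_id, plot_id, treatment,
    live_biomass_g_m2``.
``soil.csv`` (optional)
    plot-keyed soil chemistry: ``C_pct, N_pct, P_ppm, K_ppm, pH, light``.
``climate.csv`` (optional)
    site-keyed covariates: ``MAT, MAP, temp_range, temp_sd, precip_cv,
    temp_wettest4``.

All files are UTF-8 with a header row and "." as decimal separator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "DataValidationError",
    "PlotObservation",
    "SurveyDataset",
    "DesignReport",
    "read_survey",
    "validate_design",
    "write_block_metrics",
    "read_block_metrics",
    "write_survey",
    "BLOCK_METRIC_COLUMNS",
    "TREATMENT_LABELS",
    "COVER_COLUMNS",
    "BIOMASS_COLUMNS",
    "SOIL_COLUMNS",
    "CLIMATE_COLUMNS",
]


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class DataValidationError(ValueError):
    """Values violate the domain invariants (negative cover, etc.)."""


#: Canonical treatment labels (ASCII; "μ" in input is normalized to "mu").
TREATMENT_LABELS = (
    "pretreatment",
    "control",
    "N",
    "P",
    "Kmu",
    "NP",
    "NKmu",
    "PKmu",
    "NPKmu",
    "fence",
    "fence+NPKmu",
)

COVER_COLUMNS = ["site_id", "block_id", "plot_id", "treatment", "taxon", "cover"]
BIOMASS_COLUMNS = ["site_id", "block_id", "plot_id", "treatment", "live_biomass_g_m2"]
SOIL_COLUMNS = ["site_id", "block_id", "plot_id", "C_pct", "N_pct", "P_ppm", "K_ppm", "pH", "light"]
CLIMATE_COLUMNS = ["site_id", "MAT", "MAP", "temp_range", "temp_sd", "precip_cv", "temp_wettest4"]

#: Stable column order for the per-block metric table.
BLOCK_METRIC_COLUMNS = [
    "site_id",
    "block_id",
    "n_plots",
    "alpha",
    "gamma",
    "beta_disp",
    "beta_whittaker",
    "beta_additive",
    "mu",
    "sigma",
    "cv",
    "log_cv",
    "covariation",
    "env_het",
]

_KEY = ["site_id", "block_id", "plot_id"]


@dataclass
class PlotObservation:
    """A single plot: species cover map, total live biomass, optional soil."""

    site_id: str
    block_id: str
    plot_id: str
    treatment: str
    cover: Mapping[str, float]
    live_biomass: float
    soil: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        for taxon, c in self.cover.items():
            if not np.isfinite(c) or c < 0:
                raise DataValidationError(
                    f"cover for {taxon!r} in plot {self.plot_id!r} is {c!r}; must be finite and >= 0"
                )
            if c > 100:
                raise DataValidationError(
                    f"cover for {taxon!r} in plot {self.plot_id!r} is {c}; per-taxon cover cannot exceed 100%"
                )
        if not np.isfinite(self.live_biomass) or self.live_biomass < 0:
            raise DataValidationError(
                f"live biomass of plot {self.plot_id!r} is {self.live_biomass!r}; must be finite and >= 0"
            )


@dataclass
class SurveyDataset:
    """Hierarchical site -> block -> plot survey data in long form.

    ``cover`` holds one row per (plot, taxon) with cover > 0; ``biomass``
    one row per plot.  ``soil`` and ``climate`` are optional side tables.
    """

    cover: pd.DataFrame
    biomass: pd.DataFrame
    soil: Optional[pd.DataFrame] = None
    climate: Optional[pd.DataFrame] = None
    phase: str = "pretreatment"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        _require_columns(self.cover, COVER_COLUMNS, "cover")
        _require_columns(self.biomass, BIOMASS_COLUMNS, "biomass")
        if self.soil is not None:
            _require_columns(self.soil, _KEY, "soil")
        if self.climate is not None:
            _require_columns(self.climate, ["site_id"], "climate")

        bad = self.cover.index[
            ~np.isfinite(self.cover["cover"]) | (self.cover["cover"] < 0)
        ]
        if len(bad):
            raise DataValidationError(
                f"negative or non-finite cover at cover-table rows {list(bad[:10])}"
            )
        bad = self.cover.index[self.cover["cover"] > 100]
        if len(bad):
            raise DataValidationError(
                f"per-taxon cover exceeds 100% at cover-table rows {list(bad[:10])}"
            )
        bm = self.biomass["live_biomass_g_m2"]
        bad = self.biomass.index[~np.isfinite(bm) | (bm < 0)]
        if len(bad):
            raise DataValidationError(
                f"negative or non-finite biomass at biomass-table rows {list(bad[:10])}"
            )
        if self.biomass.duplicated(_KEY).any():
            dupes = self.biomass.loc[self.biomass.duplicated(_KEY), _KEY]
            raise DataValidationError(
                f"duplicate (site_id, block_id, plot_id) in biomass table: {dupes.values[:5].tolist()}"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def plots(self) -> pd.DataFrame:
        """One row per plot (the biomass table keyed by site/block/plot)."""
        return self.biomass

    def n_sites(self) -> int:
        return self.biomass["site_id"].nunique()

    def iter_blocks(self) -> Iterator[tuple[str, str, pd.DataFrame, pd.DataFrame, Optional[pd.DataFrame]]]:
        """Yield (site_id, block_id, block_biomass, block_cover, block_soil)."""
        soil = self.soil
        cover_g = dict(tuple(self.cover.groupby(["site_id", "block_id"], sort=True)))
        soil_g = dict(tuple(soil.groupby(["site_id", "block_id"], sort=True))) if soil is not None else {}
        for (site, block), bm in self.biomass.groupby(["site_id", "block_id"], sort=True):
            cv = cover_g.get((site, block))
            if cv is None:
                cv = self.cover.iloc[0:0]
            yield site, block, bm.sort_values("plot_id"), cv, soil_g.get((site, block))

    def to_observations(self) -> list[PlotObservation]:
        """Materialize the per-plot view (mostly for interactive inspection)."""
        cover_maps: dict[tuple, dict] = {}
        for row in self.cover.itertuples(index=False):
            cover_maps.setdefault((row.site_id, row.block_id, row.plot_id), {})[row.taxon] = row.cover
        soil_maps: dict[tuple, dict] = {}
        if self.soil is not None:
            svars = [c for c in self.soil.columns if c not in _KEY]
            for row in self.soil.itertuples(index=False):
                soil_maps[(row.site_id, row.block_id, row.plot_id)] = {
                    v: getattr(row, v) for v in svars
                }
        out = []
        for row in self.biomass.itertuples(index=False):
            key = (row.site_id, row.block_id, row.plot_id)
            out.append(
                PlotObservation(
                    site_id=row.site_id,
                    block_id=row.block_id,
                    plot_id=row.plot_id,
                    treatment=row.treatment,
                    cover=cover_maps.get(key, {}),
                    live_biomass=row.live_biomass_g_m2,
                    soil=soil_maps.get(key),
                )
            )
        return out


@dataclass
class DesignReport:
    """Counts per design level plus deviations from the canonical layout."""

    n_sites: int
    n_blocks: int
    n_plots: int
    excluded_blocks: list = field(default_factory=list)  # < 2 plots: unusable
    warning_blocks: list = field(default_factory=list)  # != 10 plots: retained

    def summary(self) -> str:
        lines = [
            f"sites: {self.n_sites}, blocks: {self.n_blocks}, plots: {self.n_plots}",
        ]
        if self.excluded_blocks:
            lines.append(f"excluded (<2 plots): {self.excluded_blocks}")
        if self.warning_blocks:
            lines.append(f"non-canonical plot counts (!=10): {self.warning_blocks}")
        return "\n".join(lines)


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing required column(s): {missing}")


def _normalize_treatment(t: str) -> str:
    return str(t).strip().replace("μ", "mu")


def _canonical_taxa(taxa: pd.Series) -> pd.Series:
    """Exact string matching after whitespace/case normalization.

    The first spelling seen for each case-folded key becomes canonical; no
    synonym resolution is attempted.
    """
    stripped = taxa.astype(str).str.strip()
    canon: dict[str, str] = {}
    for t in stripped:
        canon.setdefault(t.casefold(), t)
    return stripped.str.casefold().map(canon)


def read_survey(
    cover_path,
    biomass_path,
    soil_path=None,
    climate_path=None,
    phase: str = "pretreatment",
) -> SurveyDataset:
    """Read and validate a survey bundle.

    Plots present in only one of the cover/biomass tables are reported via a
    warning and dropped.  Taxa are harmonized by exact case-normalized string
    match; rows with cover exactly 0 are treated as absences and dropped.
    """
    cover = pd.read_csv(cover_path)
    biomass = pd.read_csv(biomass_path)
    _require_columns(cover, COVER_COLUMNS, "cover")
    _require_columns(biomass, BIOMASS_COLUMNS, "biomass")

    for df in (cover, biomass):
        for c in _KEY:
            df[c] = df[c].astype(str)
        df["treatment"] = df["treatment"].map(_normalize_treatment)
    cover["taxon"] = _canonical_taxa(cover["taxon"])
    cover["cover"] = pd.to_numeric(cover["cover"])
    biomass["live_biomass_g_m2"] = pd.to_numeric(biomass["live_biomass_g_m2"])

    bad = cover.index[cover["cover"] < 0]
    if len(bad):
        raise DataValidationError(f"negative cover at cover.csv rows {list(bad[:10])}")
    bad = biomass.index[biomass["live_biomass_g_m2"] < 0]
    if len(bad):
        raise DataValidationError(f"negative biomass at biomass.csv rows {list(bad[:10])}")

    # drop recorded absences, then reconcile plot keys across the two tables
    cover = cover[cover["cover"] > 0].reset_index(drop=True)
    cover_keys = set(map(tuple, cover[_KEY].drop_duplicates().values))
    biomass_keys = set(map(tuple, biomass[_KEY].values))
    only_cover = cover_keys - biomass_keys
    only_biomass = biomass_keys - cover_keys
    if only_cover:
        warnings.warn(
            f"{len(only_cover)} plot(s) present in cover but not biomass were dropped: "
            f"{sorted(only_cover)[:5]}"
        )
        mask = [tuple(k) not in only_cover for k in cover[_KEY].values]
        cover = cover[mask].reset_index(drop=True)
    if only_biomass:
        # a plot can legitimately have zero recorded cover only if biomass is 0
        keep = []
        dropped = []
        for i, row in enumerate(biomass[_KEY + ["live_biomass_g_m2"]].values):
            key = tuple(row[:3])
            if key in only_biomass and row[3] > 0:
                dropped.append(key)
                keep.append(False)
            else:
                keep.append(True)
        if dropped:
            warnings.warn(
                f"{len(dropped)} plot(s) with positive biomass but no cover were dropped: "
                f"{dropped[:5]}"
            )
            biomass = biomass[keep].reset_index(drop=True)

    soil = None
    if soil_path is not None:
        soil = pd.read_csv(soil_path)
        _require_columns(soil, _KEY, "soil")
        for c in _KEY:
            soil[c] = soil[c].astype(str)
    climate = None
    if climate_path is not None:
        climate = pd.read_csv(climate_path)
        _require_columns(climate, ["site_id"], "climate")
        climate["site_id"] = climate["site_id"].astype(str)

    return SurveyDataset(cover=cover, biomass=biomass, soil=soil, climate=climate, phase=phase)


def validate_design(data: SurveyDataset) -> DesignReport:
    """Report counts per design level and flag non-canonical blocks.

    Blocks with fewer than 2 plots cannot support a spatial standard
    deviation and are listed as excluded; blocks with a plot count other
    than the canonical 10 are retained with a warning flag.
    """
    counts = data.biomass.groupby(["site_id", "block_id"])["plot_id"].nunique()
    excluded = [key for key, n in counts.items() if n < 2]
    warning = [key for key, n in counts.items() if n != 10 and n >= 2]
    return DesignReport(
        n_sites=data.biomass["site_id"].nunique(),
        n_blocks=len(counts),
        n_plots=int(counts.sum()),
        excluded_blocks=excluded,
        warning_blocks=warning,
    )


def write_block_metrics(metrics: pd.DataFrame, path) -> None:
    """Write the per-block metric table as CSV with a stable column order."""
    cols = [c for c in BLOCK_METRIC_COLUMNS if c in metrics.columns]
    cols += [c for c in metrics.columns if c not in cols]
    metrics.loc[:, cols].to_csv(path, index=False, float_format="%.17g")


def read_block_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "block_id"], "block metrics")
    for c in ("site_id", "block_id"):
        df[c] = df[c].astype(str)
    return df


def write_survey(data: SurveyDataset, out_dir) -> dict:
    """Write a SurveyDataset back out as a CSV bundle; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cover": out / "cover.csv",
        "biomass": out / "biomass.csv",
    }
    data.cover.to_csv(paths["cover"], index=False, float_format="%.17g")
    data.biomass.to_csv(paths["biomass"], index=False, float_format="%.17g")
    if data.soil is not None:
        paths["soil"] = out / "soil.csv"
        data.soil.to_csv(paths["soil"], index=False, float_format="%.17g")
    if data.climate is not None:
        paths["climate"] = out / "climate.csv"
        data.climate.to_csv(paths["climate"], index=False, float_format="%.17g")
    return paths
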