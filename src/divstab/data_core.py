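"""Plot-level grassland survey tables: parsing, validation, grid summaries.

The sampling design is nested: 1 m x 1 m *plots* sit inside 8 m x 8 m
homogeneous *grids*, which sit inside grassland *sites*.  Each plot carries a
species richness count and aboveground live biomass (g m^-2), the latter used
as the annual-productivity surrogate.  This module loads and validates the
plot table, derives per-grid summaries, and splits grids into near-equal
productivity groups (tertiles by default) for gradient analyses.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRASSLAND_TYPES = (
    "temperate",
    "temperate wet meadow",
    "Mediterranean",
    "tropical and subtropical",
    "alpine",
)

#: canonical column name -> default header in delimited input files
DEFAULT_DIALECT = {
    "site_id": "site",
    "grid_id": "grid",
    "plot_id": "plot",
    "richness": "richness",
    "biomass": "live_biomass",
    "grassland_type": "grassland_type",
    "longitude": "longitude",
    "latitude": "latitude",
}

PLOT_COLUMNS = ["site_id", "grid_id", "plot_id", "richness", "biomass", "grassland_type"]


class FormatError(ValueError):
    """The input file cannot be interpreted as a plot table."""


class ValidationError(ValueError):
    """The input parses but violates a data invariant."""


@dataclass
class Dataset:
    """A validated plot table plus site metadata.

    Attributes
    ----------
    plots
        One row per plot: ``site_id, grid_id, plot_id, richness, biomass,
        grassland_type``.  ``richness`` is an integer species count >= 1;
        ``biomass`` is positive aboveground live biomass in g m^-2.
    sites
        One row per site: ``site_id, longitude, latitude, hemisphere``
        (``"N"`` for latitude >= 0, else ``"S"``).
    """

    plots: pd.DataFrame
    sites: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["site_id", "longitude", "latitude", "hemisphere"]))

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def grid_ids(self) -> np.ndarray:
        return self.plots["grid_id"].unique()

    def validate(self, plots_per_grid: tuple[int, int] | None = None) -> "Dataset":
        """Check invariants; return self for chaining.

        Raises :class:`ValidationError` on richness < 1, non-positive
        biomass, duplicated (site, grid, plot) keys, a grid spanning more
        than one site, or (if ``plots_per_grid`` is given) grid sizes outside
        the declared inclusive range.
        """
        p = self.plots
        bad = p.index[(p["richness"] < 1) | (p["biomass"] <= 0)]
        if len(bad):
            raise ValidationError(
                f"{len(bad)} plots with richness < 1 or biomass <= 0 at rows "
                f"{list(bad[:10])}{'...' if len(bad) > 10 else ''}")
        dup = p.duplicated(subset=["site_id", "grid_id", "plot_id"])
        if dup.any():
            raise ValidationError(f"{int(dup.sum())} duplicate (site, grid, plot) keys")
        multi = p.groupby("grid_id")["site_id"].nunique()
        if (multi > 1).any():
            raise ValidationError(
                f"grids spanning multiple sites: {list(multi.index[multi > 1])}")
        if plots_per_grid is not None:
            lo, hi = plots_per_grid
            counts = p.groupby("grid_id").size()
            off = counts[(counts < lo) | (counts > hi)]
            if len(off):
                raise ValidationError(
                    f"grids with plot counts outside [{lo}, {hi}]: {dict(off)}")
        return self


def _read_delimited(path, delimiter: str | None) -> pd.DataFrame:
    try:
        if delimiter is None:
            with open(path, newline="") as fh:
                sample = fh.readline()
            if not sample.strip():
                raise FormatError(f"empty or unreadable delimited file: {path}")
            delimiter = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise FormatError(f"empty or unreadable delimited file: {path}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0 and df.shape[1] == 1:
        raise FormatError(f"no parseable columns in {path}")
    return df


def load_plots(path, dialect: dict[str, str] | None = None,
               delimiter: str | None = None) -> Dataset:
    """Load a delimited plot table into a validated :class:`Dataset`.

    Rows lacking a richness or live-biomass value are dropped (the number
    dropped is logged): plots where only total (live+litter) biomass was
    recorded carry no live-biomass entry and are excluded rather than
    imputed.  Remaining rows must satisfy richness >= 1 and biomass > 0.

    Parameters
    ----------
    path
        Delimited text file (comma or tab; auto-detected when ``delimiter``
        is None), UTF-8, one row per plot.
    dialect
        Mapping canonical name -> file header, overriding
        :data:`DEFAULT_DIALECT` entries.  Longitude/latitude columns are
        optional; when present, site metadata is extracted.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = _read_delimited(path, delimiter)

    missing = [names[c] for c in PLOT_COLUMNS[:5] if names[c] not in df.columns]
    if missing:
        raise FormatError(f"mandatory columns absent from {path}: {missing}")

    rename = {v: k for k, v in names.items() if v in df.columns}
    df = df.rename(columns=rename)
    if "grassland_type" not in df.columns:
        df["grassland_type"] = pd.NA

    n_raw = len(df)
    df = df.dropna(subset=["richness", "biomass"])
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("dropped %d of %d rows lacking richness or live biomass",
                    n_dropped, n_raw)
    if df.empty:
        raise FormatError(f"no complete plot rows in {path}")
    df = df.assign(richness=df["richness"].astype(int),
                   biomass=df["biomass"].astype(float))

    sites = pd.DataFrame(columns=["site_id", "longitude", "latitude", "hemisphere"])
    if {"longitude", "latitude"}.issubset(df.columns):
        sites = (df.groupby("site_id", as_index=False)[["longitude", "latitude"]]
                 .first())
        sites["hemisphere"] = np.where(sites["latitude"] >= 0, "N", "S")

    ds = Dataset(plots=df[PLOT_COLUMNS].reset_index(drop=True), sites=sites)
    return ds.validate()


def write_plots(ds: Dataset, path, delimiter: str = ",") -> None:
    """Write the canonical plot table (round-trips through :func:`load_plots`
    with the identity dialect)."""
    out = ds.plots.copy()
    if not ds.sites.empty:
        out = out.merge(ds.sites[["site_id", "longitude", "latitude"]],
                        on="site_id", how="left")
    out = out.rename(columns=DEFAULT_DIALECT)
    out.to_csv(path, sep=delimiter, index=False)


def summarize_grids(ds: Dataset) -> pd.DataFrame:
    """Per-grid summaries: mean productivity, mean richness, plot count.

    Returns a frame with columns ``grid_id, site_id, mean_productivity,
    mean_richness, n_plots, productivity_group`` (group initially unset).
    """
    if ds.plots.empty:
        raise ValidationError("cannot summarize an empty dataset")
    g = (ds.plots.groupby(["grid_id", "site_id"], as_index=False)
         .agg(mean_productivity=("biomass", "mean"),
              mean_richness=("richness", "mean"),
              n_plots=("plot_id", "size")))
    g["productivity_group"] = pd.NA
    return g


def split_by_productivity(grids: pd.DataFrame, n_groups: int = 3) -> pd.DataFrame:
    """Partition grids into ``n_groups`` near-equal groups by mean productivity.

    Grids are sorted ascending by ``(mean_productivity, grid_id)`` — the
    grid-id key makes ties deterministic — and cut into contiguous groups
    whose sizes differ by at most one, any remainder going to the
    higher-productivity groups.  With three groups the labels are ``low``,
    ``medium``, ``high``; otherwise ``q1..qn``.
    """
    n = len(grids)
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} grids, got {n}")
    order = grids.sort_values(
        ["mean_productivity", "grid_id"], kind="mergesort").index
    base, rem = divmod(n, n_groups)
    sizes = [base] * (n_groups - rem) + [base + 1] * rem
    if n_groups == 3:
        labels = ["low", "medium", "high"]
    else:
        labels = [f"q{i + 1}" for i in range(n_groups)]
    assignment = np.repeat(labels, sizes)
    out = grids.copy()
    out.loc[order, "productivity_group"] = assignment
    out["productivity_group"] = out["productivity_group"].astype(str)
    return out


def write_grid_summaries(grids: pd.DataFrame, path, delimiter: str = ",") -> None:
    grids.to_csv(path, sep=delimiter, index=False)


def tertile_datasets(ds: Dataset, grids: pd.DataFrame) -> dict[str, Dataset]:
    """Split a dataset into one :class:`Dataset` per productivity group."""
    if grids["productivity_group"].isna().any():
        raise ValueError("grids must be labeled by split_by_productivity first")
    out = {}
    for label, sub in grids.groupby("productivity_group"):
        mask = ds.plots["grid_id"].isin(sub["grid_id"])
        out[label] = Dataset(plots=ds.plots[mask].reset_index(drop=True),
                             sites=ds.sites)
    return out
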