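"""Predicted richness-spatial-stability relationship from grid-level lines.

Each grid's posterior-median intercept and slope define a predicted
richness-productivity line.  Because productive grids tend to carry
negative slopes and unproductive grids positive ones, the lines converge at
high richness: the across-grid spread of predicted productivity shrinks as
richness grows.  This module quantifies that convergence by repeatedly
subsampling a fixed number of plots per grid, evaluating each grid's line
at its sampled plots' richness values, pooling predictions across grids,
and computing the SD of predicted productivity at each richness level —
then regressing that SD on richness.

Predictions are line evaluations only (no plot-level noise): the quantity
of interest is the dispersion generated by between-grid differences in the
richness-productivity relationship, not residual noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from divstab.data_core import Dataset
from divstab.hier_bayes import HBPosterior

logger = logging.getLogger(__name__)


def build_grid_lines(post: HBPosterior, ds: Dataset) -> pd.DataFrame:
    """One predicted richness-productivity line per grid.

    Intercept = posterior median of alpha0_j plus the grid's site effect
    (posterior median, raw units); slope = posterior median of alpha1_j.
    Raises if the dataset contains a grid absent from the posterior.
    """
    extra = set(ds.plots["grid_id"].unique()) - set(post.grid_ids)
    if extra:
        raise ValueError(f"grids absent from posterior: {sorted(extra)}")
    raw = post.raw_draws()
    a0 = np.median(raw["alpha0"].reshape(-1, len(post.grid_ids)), axis=0)
    a1 = np.median(raw["alpha1"].reshape(-1, len(post.grid_ids)), axis=0)
    site_med = np.median(raw["a_site"].reshape(-1, len(post.site_ids)), axis=0)
    site_lookup = dict(zip(post.site_ids, site_med))
    grid_site = ds.plots.groupby("grid_id")["site_id"].first()
    lines = pd.DataFrame({"grid_id": post.grid_ids, "intercept": a0, "slope": a1})
    lines["intercept"] += lines["grid_id"].map(
        lambda gid: site_lookup.get(grid_site.get(gid), 0.0))
    return lines


@dataclass
class ResampleResult:
    """Per-richness-level SD of predicted productivity over replicates."""

    levels: np.ndarray          # richness levels with >= 2 pooled predictions
    sd_median: np.ndarray
    sd_lo: np.ndarray           # 2.5% over replicates
    sd_hi: np.ndarray           # 97.5%
    slope_median: float         # SD-on-richness regression slope
    slope_lo: float
    slope_hi: float
    reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"richness": self.levels, "sd_median": self.sd_median,
                             "sd_lo": self.sd_lo, "sd_hi": self.sd_hi})


def closed_form_level_sd(lines: pd.DataFrame, levels) -> np.ndarray:
    """Across-grid SD of line predictions at each richness level:
    SD_j(intercept_j + slope_j * k), the quantity the resampling estimates
    when every grid contributes plots at level k."""
    a0 = lines["intercept"].to_numpy()
    a1 = lines["slope"].to_numpy()
    return np.array([np.std(a0 + a1 * k, ddof=1) for k in np.asarray(levels)])


def resample_sd(lines: pd.DataFrame, ds: Dataset, n_plots: int = 60,
                reps: int = 1000, seed: int = 0,
                with_replacement: bool = False) -> ResampleResult:
    """Monte-Carlo SD of predicted productivity by richness level.

    Per replicate: sample ``n_plots`` plots from each grid (without
    replacement by default), evaluate the grid's line at each sampled
    plot's richness, pool predictions across grids, and compute the SD at
    each richness level (levels with fewer than two pooled predictions in a
    replicate are skipped and logged).  After ``reps`` replicates the
    per-level SD is summarized by its median and 95% interval, and a simple
    linear regression of SD on richness is fitted to the medians.

    Deterministic given ``seed``; the first replicates of a longer run
    coincide with a shorter run at the same seed.
    """
    plots = ds.plots
    counts = plots.groupby("grid_id").size()
    short = counts[counts < n_plots]
    if not with_replacement and len(short):
        raise ValueError(f"grids with fewer than {n_plots} plots: {dict(short)}")
    coef = lines.set_index("grid_id")
    grid_ids = [g for g in counts.index]
    rich_by_grid = [plots.loc[plots["grid_id"] == g, "richness"].to_numpy()
                    for g in grid_ids]
    a0 = coef.loc[grid_ids, "intercept"].to_numpy()
    a1 = coef.loc[grid_ids, "slope"].to_numpy()

    all_levels = np.unique(plots["richness"].to_numpy())
    lev_index = {k: i for i, k in enumerate(all_levels)}
    K = len(all_levels)
    sd_reps = np.full((reps, K), np.nan)
    rng = np.random.default_rng(seed)
    n_skipped = 0
    for rep in range(reps):
        pooled_r = []
        pooled_p = []
        for j, rich in enumerate(rich_by_grid):
            idx = (rng.choice(len(rich), n_plots, replace=True) if with_replacement
                   else rng.permutation(len(rich))[:n_plots])
            rs = rich[idx]
            pooled_r.append(rs)
            pooled_p.append(a0[j] + a1[j] * rs)
        rr = np.concatenate(pooled_r)
        pp = np.concatenate(pooled_p)
        order = np.argsort(rr, kind="mergesort")
        rr, pp = rr[order], pp[order]
        uniq, start = np.unique(rr, return_index=True)
        bounds = np.append(start, len(rr))
        for u, s0, s1 in zip(uniq, bounds[:-1], bounds[1:]):
            if s1 - s0 < 2:
                n_skipped += 1
                continue
            sd_reps[rep, lev_index[u]] = np.std(pp[s0:s1], ddof=1)
    if n_skipped:
        logger.info("skipped %d level-replicate cells with < 2 predictions",
                    n_skipped)

    valid = np.sum(np.isfinite(sd_reps), axis=0) > 0
    levels = all_levels[valid]
    with np.errstate(all="ignore"):
        med = np.nanmedian(sd_reps[:, valid], axis=0)
        lo = np.nanpercentile(sd_reps[:, valid], 2.5, axis=0)
        hi = np.nanpercentile(sd_reps[:, valid], 97.5, axis=0)

    # slope of SD on richness: fit per replicate for an interval, plus the
    # median-based point estimate
    slopes = []
    for rep in range(reps):
        row = sd_reps[rep]
        mask = np.isfinite(row)
        if mask.sum() >= 3:
            x = all_levels[mask].astype(float)
            res = sm.OLS(row[mask], sm.add_constant(x)).fit()
            slopes.append(res.params[1])
    slopes = np.asarray(slopes)
    fit_med = sm.OLS(med, sm.add_constant(levels.astype(float))).fit()
    return ResampleResult(
        levels=levels, sd_median=med, sd_lo=lo, sd_hi=hi,
        slope_median=float(np.median(slopes)) if len(slopes) else float(
            fit_med.params[1]),
        slope_lo=float(np.percentile(slopes, 2.5)) if len(slopes) else np.nan,
        slope_hi=float(np.percentile(slopes, 97.5)) if len(slopes) else np.nan,
        reps=reps, seed=seed)


def write_resample_result(res: ResampleResult, path, delimiter: str = ",") -> None:
    res.to_frame().to_csv(path, sep=delimiter, index=False)
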