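"""Spatial variability of productivity across plots, binned by richness.

"Spatial" here means across-plot: the dispersion of productivity among the
1 m^2 plots that share a species-richness level, measured as the standard
deviation SD (absolute variability, g m^-2) or the coefficient of variation
CV = SD / mean (relative, dimensionless).  Richness levels with too few
plots are merged into contiguous richness bins so every bin holds at least
``min_plots`` plots; simple linear/quadratic regressions of SD or CV on bin
richness then quantify the biodiversity-spatial-variability relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from divstab.data_core import Dataset


def variability_metrics(values) -> tuple[float, float, float]:
    """(sd, cv, mean) of a productivity sample.

    SD uses the n-1 denominator; CV = SD / mean.  An all-equal sample gives
    sd = cv = 0.  Raises for fewer than two values, or for CV at zero mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("variability needs at least two values")
    mu = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return 0.0, 0.0, mu
    if mu == 0.0:
        raise ValueError("CV undefined at zero mean")
    return sd, sd / mu, mu


def group_by_richness(ds: Dataset, min_plots: int = 3) -> pd.DataFrame:
    """Merge richness levels into contiguous bins of at least ``min_plots``.

    Every observed richness value starts as its own group.  Scanning from
    the highest richness downward, a deficient group (fewer than
    ``min_plots`` plots) is merged with its neighbor: the topmost group
    absorbs the next-lower group, any other deficient group is folded into
    the group above it.  Merging repeats until all groups qualify — so the
    sparse high-richness tail collapses into a single last bin while dense
    low-richness levels stay as singleton bins.

    Returns one row per group: ``richness_low, richness_high, richness``
    (plot-count-weighted mean richness, the regression abscissa),
    ``n_plots, mean_productivity, sd, cv``.
    """
    plots = ds.plots
    if len(plots) < min_plots:
        raise ValueError(f"only {len(plots)} plots; need at least {min_plots}")
    counts = plots.groupby("richness").size().sort_index()
    # groups as lists of member richness levels, ascending
    groups: list[list[int]] = [[int(r)] for r in counts.index]
    sizes = [int(counts.loc[g[0]]) for g in groups]

    while True:
        deficient = [i for i, s in enumerate(sizes) if s < min_plots]
        if not deficient:
            break
        i = deficient[-1]  # highest-richness deficient group
        if i == len(groups) - 1:
            j = i - 1      # topmost: absorb the next-lower group
        else:
            j = i + 1      # otherwise fold into the group above
        lo, hi = min(i, j), max(i, j)
        groups[lo] = groups[lo] + groups[hi]
        sizes[lo] = sizes[lo] + sizes[hi]
        del groups[hi], sizes[hi]

    rows = []
    for members in groups:
        sub = plots[plots["richness"].isin(members)]
        if len(sub) >= 2:
            sd, cv, mu = variability_metrics(sub["biomass"].to_numpy())
        else:  # possible only when min_plots == 1
            sd, cv, mu = np.nan, np.nan, float(sub["biomass"].iloc[0])
        rows.append({
            "richness_low": min(members), "richness_high": max(members),
            "richness": float(np.average(sub["richness"])),
            "n_plots": len(sub), "mean_productivity": mu, "sd": sd, "cv": cv,
        })
    return pd.DataFrame(rows)


@dataclass
class VariabilityRegression:
    response: str
    form: str
    coefficients: dict[str, float]
    r_squared: float
    p_value: float
    log_response: bool


def regress_variability(groups: pd.DataFrame, response: str = "sd",
                        form: str = "linear", log_response: bool = False,
                        abscissa: str = "richness") -> VariabilityRegression:
    """OLS regression of a dispersion metric on group richness.

    ``response`` is ``"sd"`` or ``"cv"``; ``form`` ``"linear"`` or
    ``"quadratic"``; with ``log_response`` the natural log of the metric is
    regressed instead (zero dispersion then raises).  The reported p-value
    is the regression F test.
    """
    if response not in ("sd", "cv"):
        raise ValueError("response must be 'sd' or 'cv'")
    if form not in ("linear", "quadratic"):
        raise ValueError("form must be 'linear' or 'quadratic'")
    need = 3 if form == "linear" else 4
    if len(groups) < need:
        raise ValueError(f"{form} regression needs >= {need} groups")
    x = groups[abscissa].to_numpy(dtype=float)
    if form == "quadratic" and len(np.unique(x)) < 3:
        raise ValueError("quadratic fit needs >= 3 distinct richness values")
    y = groups[response].to_numpy(dtype=float)
    if log_response:
        if np.any(y <= 0):
            raise ValueError("log response requires strictly positive metric")
        y = np.log(y)
    X = np.column_stack([x, x ** 2]) if form == "quadratic" else x[:, None]
    names = ["richness", "richness_sq"][:X.shape[1]]
    model = sm.OLS(y, sm.add_constant(X)).fit()
    coefs = {"intercept": float(model.params[0])}
    coefs.update({n: float(b) for n, b in zip(names, model.params[1:])})
    p = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 1.0
    rsq = float(model.rsquared) if np.isfinite(model.rsquared) else 0.0
    return VariabilityRegression(response=response, form=form,
                                 coefficients=coefs, r_squared=rsq,
                                 p_value=p, log_response=log_response)


def grid_level_variability(ds: Dataset) -> tuple[pd.DataFrame, dict]:
    """Per-grid dispersion and its correlation with grid mean richness.

    Returns (per-grid frame with ``grid_id, mean_richness, mean_productivity,
    sd, cv``, correlation dict with Pearson r and p for sd and cv against
    mean richness; ``None`` entries mark degenerate, zero-variance input).
    """
    small = ds.plots.groupby("grid_id").size()
    if (small < 2).any():
        raise ValueError(f"grids with < 2 plots: {list(small.index[small < 2])}")
    rows = []
    for gid, sub in ds.plots.groupby("grid_id"):
        sd, cv, mu = variability_metrics(sub["biomass"].to_numpy())
        rows.append({"grid_id": gid, "mean_richness": float(sub["richness"].mean()),
                     "mean_productivity": mu, "sd": sd, "cv": cv})
    per_grid = pd.DataFrame(rows)

    corr: dict[str, dict | None] = {}
    for metric in ("sd", "cv"):
        x = per_grid["mean_richness"].to_numpy()
        y = per_grid[metric].to_numpy()
        if len(per_grid) < 3 or np.std(x) == 0 or np.std(y) == 0:
            corr[metric] = None
        else:
            r, p = stats.pearsonr(x, y)
            corr[metric] = {"r": float(r), "p_value": float(p)}
    return per_grid, corr


def write_groups(groups: pd.DataFrame, path, delimiter: str = ",") -> None:
    groups.to_csv(path, sep=delimiter, index=False)
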