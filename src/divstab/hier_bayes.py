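"""Hierarchical Bayesian mean+variance model of grassland productivity.

The model couples the central tendency and the dispersion of plot
productivity to species richness inside a site > grid > plot hierarchy:

    y_i        ~ Normal(alpha0_j + alpha1_j * r_i + a_site, sigma_k)
    log sigma_k ~ Normal(beta0 + beta1 * k, sigma_beta)        (richness level k)
    alpha0_j   ~ Normal(g00 + g01*L_j + g02*P_j + g03*T_j, sigma_alpha0)
    alpha1_j   ~ Normal(g10 + g11 * grid_productivity_j, sigma_alpha1)
    a_site     ~ Normal(0, sigma_site)

``beta1`` is the biodiversity-spatial-variability effect; ``g11`` measures
how the grid-level richness-productivity slope shifts along the productivity
gradient.  A CV variant replaces log(sigma_k) with log(CV_k) in the
dispersion regression, coupling back to the likelihood through
sigma_k = CV_k * mu_k with mu_k the mean model-implied plot mean at level k
(recomputed at every draw).

Fitting is Metropolis-within-Gibbs: all normal-linear blocks (grid
intercept/slope pairs, site effects, the gamma and beta regressions) are
conjugate Gibbs updates; scale parameters are drawn from truncated
inverse-gamma conditionals; the level dispersions use vectorized adaptive
random-walk Metropolis on the log scale.  In the CV variant the grid and
site blocks use the conjugate normal as a Metropolis-Hastings proposal and
correct for the dispersion feedback exactly.

Internally productivity is divided by its global standard deviation and the
climate/grid-productivity covariates are standardized, so the "diffuse"
priors — Normal(0, 1e6) on locations, Uniform(0, 100) on scales — are
diffuse regardless of measurement units.  All reported draws are mapped
back to raw units (g m^-2); the transforms are linear and exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from divstab.data_core import Dataset

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)

SCALAR_PARAMS = ("beta0", "beta1", "gamma00", "gamma01", "gamma02", "gamma03",
                 "gamma10", "gamma11", "sigma_alpha0", "sigma_alpha1",
                 "sigma_site", "sigma_beta")


@dataclass
class HBModelSpec:
    """Model variant and prior settings.

    ``variant`` is ``"sd"`` (dispersion regression on log sigma_k) or
    ``"cv"`` (on log CV_k).  Location parameters get Normal(0,
    ``loc_prior_var``) priors, scales Uniform(0, ``sigma_upper``) — both on
    the internal standardized scale.
    """

    variant: str = "sd"
    loc_prior_var: float = 1.0e6
    sigma_upper: float = 100.0

    def __post_init__(self):
        if self.variant not in ("sd", "cv"):
            raise ValueError("variant must be 'sd' or 'cv'")


@dataclass
class HBPosterior:
    """Thinned post-burn-in MCMC draws plus metadata.

    ``draws`` maps parameter name to an array of shape (chain, draw) or
    (chain, draw, dim) on the internal standardized scale; use
    :meth:`raw_draws` for raw-unit (g m^-2) parameter draws.
    """

    draws: dict[str, np.ndarray]
    grid_ids: np.ndarray
    site_ids: np.ndarray
    levels: np.ndarray
    variant: str
    seed: int
    iterations: int
    burn_in: int
    thin: int
    scaling: dict
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def raw_draws(self) -> dict[str, np.ndarray]:
        """Back-transform draws to the raw data scale.

        Returns scalar parameters under their model names (beta0, beta1,
        gamma00..gamma03, gamma10, gamma11, sigma_*) with shape
        (chain, draw), plus vector blocks alpha0, alpha1 (chain, draw, J),
        a_site (chain, draw, S) and sigma_k (chain, draw, K).
        """
        sc = self.scaling
        s_y = sc["s_y"]
        slope_fac = s_y / sc["r_sd"]                # slope per raw species
        g0 = self.draws["gamma0"]
        g1 = self.draws["gamma1"]
        b = self.draws["beta"]
        cov_m, cov_s = sc["cov_mean"], sc["cov_sd"]
        out: dict[str, np.ndarray] = {}
        slopes = s_y * g0[..., 1:] / cov_s          # per raw covariate unit
        out["gamma00"] = s_y * (g0[..., 0] - np.sum(g0[..., 1:] * (cov_m / cov_s),
                                                    axis=-1))
        for m, name in enumerate(("gamma01", "gamma02", "gamma03")):
            out[name] = slopes[..., m]
        out["gamma11"] = slope_fac * g1[..., 1] / sc["g_sd"]
        out["gamma10"] = slope_fac * (g1[..., 0]
                                      - g1[..., 1] * sc["g_mean"] / sc["g_sd"])
        out["beta0"] = b[..., 0] + (np.log(s_y) if self.variant == "sd" else 0.0)
        out["beta1"] = b[..., 1]
        out["sigma_alpha0"] = s_y * self.draws["sigma_alpha0"]
        out["sigma_alpha1"] = slope_fac * self.draws["sigma_alpha1"]
        out["sigma_site"] = s_y * self.draws["sigma_site"]
        out["sigma_beta"] = self.draws["sigma_beta"]
        out["alpha1"] = slope_fac * self.draws["alpha1"]
        out["alpha0"] = (s_y * self.draws["alpha0"]
                         - out["alpha1"] * sc["r_mean"])
        out["a_site"] = s_y * self.draws["a_site"]
        if self.variant == "sd":
            out["sigma_k"] = s_y * np.exp(self.draws["log_sigma_k"])
        else:
            out["cv_k"] = np.exp(self.draws["log_cv_k"])
        return out

    def scalar_summary(self, probs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        raw = self.raw_draws()
        rows = []
        for name in SCALAR_PARAMS:
            d = raw[name].reshape(-1)
            qs = np.quantile(d, probs)
            rows.append({"parameter": name, "mean": float(d.mean()),
                         **{f"q{p}": float(q) for p, q in zip(probs, qs)}})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draw table: chain, draw, parameter, value (raw scale)."""
        raw = self.raw_draws()
        frames = []
        for name, arr in raw.items():
            if arr.ndim == 2:
                labels = [name]
                flat = arr[..., None]
            else:
                if name in ("alpha0", "alpha1"):
                    ids = self.grid_ids
                elif name == "a_site":
                    ids = self.site_ids
                else:
                    ids = self.levels
                labels = [f"{name}[{i}]" for i in ids]
                flat = arr
            nc, nd, npar = flat.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(nc), nd * npar),
                "draw": np.tile(np.repeat(np.arange(nd), npar), nc),
                "parameter": np.tile(labels, nc * nd),
                "value": flat.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass
class PpcReport:
    """Posterior predictive (Bayesian) p-values for several statistics."""

    p_values: dict[str, float]
    n_rep: int
    reported: tuple[str, ...] = ("mean", "sd", "plot")

    def reported_triple(self) -> tuple[float, ...]:
        return tuple(self.p_values[k] for k in self.reported)


# ---------------------------------------------------------------------------
# data preparation


class _Data:
    """Index arrays and standardized covariates for one survey."""

    def __init__(self, ds: Dataset, cov: pd.DataFrame, strict: bool = True):
        plots = ds.plots
        grid_ids, g = np.unique(plots["grid_id"].to_numpy(), return_inverse=True)
        if len(grid_ids) < 2:
            raise ValueError("model needs at least 2 grids")
        levels, k_idx = np.unique(plots["richness"].to_numpy(), return_inverse=True)
        if len(levels) < 2:
            raise ValueError("model needs at least 2 richness levels")
        site_per_grid_raw = (plots.groupby("grid_id")["site_id"].first()
                             .loc[grid_ids].to_numpy())
        site_ids, site_of_grid = np.unique(site_per_grid_raw, return_inverse=True)

        y_raw = plots["biomass"].to_numpy(dtype=float)
        s_y = float(np.std(y_raw, ddof=1))
        r_raw = plots["richness"].to_numpy(dtype=float)
        r_mean = float(r_raw.mean())
        r_sd = float(np.std(r_raw, ddof=1))
        if strict and s_y <= 0:
            raise ValueError("productivity has zero variance")
        if strict and r_sd <= 0:
            raise ValueError("richness has zero variance")
        s_y = s_y if s_y > 0 else 1.0
        r_sd = r_sd if r_sd > 0 else 1.0

        covi = cov.set_index("grid_id").loc[grid_ids]
        X = covi[["daylight", "precipitation", "temperature"]].to_numpy(float)
        cov_mean = X.mean(axis=0)
        cov_sd = X.std(axis=0, ddof=1)
        cov_sd[cov_sd == 0] = 1.0
        Xs = (X - cov_mean) / cov_sd

        n_plots = np.bincount(g)
        G_raw = np.bincount(g, weights=y_raw) / n_plots
        g_mean, g_sd = float(G_raw.mean()), float(np.std(G_raw, ddof=1))
        if g_sd == 0:
            g_sd = 1.0

        self.y = y_raw / s_y
        self.y_raw = y_raw
        # centered/scaled richness in the mean structure: keeps the grid
        # intercept interpretable as productivity at the survey's mean
        # richness and removes the intercept-slope collinearity that
        # otherwise couples the grid-line hierarchy to the self-referential
        # grid-productivity covariate
        self.r = (r_raw - r_mean) / r_sd
        self.r_raw = r_raw
        self.g = g
        self.k_idx = k_idx
        self.levels = levels.astype(float)
        self.n_k = np.bincount(k_idx)
        self.grid_ids = grid_ids
        self.site_ids = site_ids
        self.site_of_grid = site_of_grid
        self.s_of_plot = site_of_grid[g]
        self.J = len(grid_ids)
        self.S = len(site_ids)
        self.K = len(levels)
        self.N = len(y_raw)
        self.Z0 = np.column_stack([np.ones(self.J), Xs])
        self.Z1 = np.column_stack([np.ones(self.J), (G_raw - g_mean) / g_sd])
        self.Zk = np.column_stack([np.ones(self.K), self.levels])
        self.scaling = {"s_y": s_y, "cov_mean": cov_mean, "cov_sd": cov_sd,
                        "g_mean": g_mean, "g_sd": g_sd,
                        "r_mean": r_mean, "r_sd": r_sd}


# ---------------------------------------------------------------------------
# log posterior (raw scale; contract and test oracle)


def log_posterior(spec: HBModelSpec, ds: Dataset, cov: pd.DataFrame,
                  params: dict) -> float:
    """Unnormalized log posterior density at raw-scale parameter values.

    ``params`` holds ``alpha0``, ``alpha1`` (length J, ordered by sorted
    grid id), ``a_site`` (length S, sorted site id), ``gamma0`` (4),
    ``gamma1`` (2), ``beta`` (2), scale parameters ``sigma_alpha0``,
    ``sigma_alpha1``, ``sigma_site``, ``sigma_beta``, and per-level
    ``log_sigma_k`` (variant "sd") or ``log_cv_k`` (variant "cv").  Returns
    -inf for parameters outside the support (non-positive scales); no
    exception is raised for that case.
    """
    d = _Data(ds, cov, strict=False)
    # indexing only: the density is evaluated directly on raw data
    y = d.y_raw
    alpha0 = np.asarray(params["alpha0"], float)
    alpha1 = np.asarray(params["alpha1"], float)
    a_site = np.asarray(params["a_site"], float)
    gamma0 = np.asarray(params["gamma0"], float)
    gamma1 = np.asarray(params["gamma1"], float)
    beta = np.asarray(params["beta"], float)
    scales = np.array([params["sigma_alpha0"], params["sigma_alpha1"],
                       params["sigma_site"], params["sigma_beta"]], float)
    if np.any(scales <= 0):
        return -np.inf

    mu = alpha0[d.g] + alpha1[d.g] * d.r_raw + a_site[d.s_of_plot]
    if spec.variant == "sd":
        theta = np.asarray(params["log_sigma_k"], float)
        sigma_k = np.exp(theta)
    else:
        theta = np.asarray(params["log_cv_k"], float)
        mu_k = np.bincount(d.k_idx, weights=mu) / d.n_k
        if np.any(mu_k <= 0):
            return -np.inf
        sigma_k = np.exp(theta) * mu_k
    sig = sigma_k[d.k_idx]
    ll = float(np.sum(-np.log(sig) - 0.5 * ((y - mu) / sig) ** 2) - d.N * _HALF_LOG_2PI)

    def norm_lp(x, m, s):
        return float(np.sum(-np.log(s) - 0.5 * ((x - m) / s) ** 2)
                     - np.size(x) * _HALF_LOG_2PI)

    # hierarchical layers use raw covariates here
    X = cov.set_index("grid_id").loc[d.grid_ids][
        ["daylight", "precipitation", "temperature"]].to_numpy(float)
    G = np.bincount(d.g, weights=y) / np.bincount(d.g)
    lp = ll
    lp += norm_lp(theta, beta[0] + beta[1] * d.levels, params["sigma_beta"])
    lp += norm_lp(alpha0, gamma0[0] + X @ gamma0[1:], params["sigma_alpha0"])
    lp += norm_lp(alpha1, gamma1[0] + gamma1[1] * G, params["sigma_alpha1"])
    lp += norm_lp(a_site, 0.0, params["sigma_site"])
    loc = np.concatenate([gamma0, gamma1, beta])
    lp += norm_lp(loc, 0.0, np.sqrt(spec.loc_prior_var))
    if np.any(scales > spec.sigma_upper):
        return -np.inf
    lp += -4.0 * np.log(spec.sigma_upper)
    return lp


# ---------------------------------------------------------------------------
# sampler internals


def _trunc_invgamma_sd(rng, n, ss, upper, current):
    """Draw sigma with p(sigma) ∝ sigma^-n exp(-ss / 2 sigma^2) on (0, upper):
    sigma^2 ~ InvGamma((n-1)/2, ss/2) truncated.  Falls back to the current
    value if rejection fails (pathological, e.g. ss pushing past the bound)."""
    shape = 0.5 * (n - 1)
    if shape <= 0 or ss <= 0:
        return current
    for _ in range(100):
        v = (0.5 * ss) / rng.gamma(shape)
        if v < upper * upper:
            return float(np.sqrt(v))
    return current


def _mvn_reg_draw(rng, Z, resp, sigma, prior_var):
    """Conjugate draw for regression coefficients with N(0, prior_var) prior."""
    q = Z.shape[1]
    prec = Z.T @ Z / sigma ** 2 + np.eye(q) / prior_var
    chol = np.linalg.cholesky(prec)
    rhs = Z.T @ resp / sigma ** 2
    mean = np.linalg.solve(prec, rhs)
    z = rng.normal(size=q)
    return mean + np.linalg.solve(chol.T, z)




def _grid_gls(d: _Data, state: _State, w):
    """Per-grid GLS estimates of (intercept, slope) from the plot data alone
    (site effect removed), with their 2x2 sampling covariance."""
    resid = d.y - state.a_site[d.s_of_plot]
    sw = np.bincount(d.g, weights=w, minlength=d.J)
    swr = np.bincount(d.g, weights=w * d.r, minlength=d.J)
    swrr = np.bincount(d.g, weights=w * d.r * d.r, minlength=d.J)
    swy = np.bincount(d.g, weights=w * resid, minlength=d.J)
    swry = np.bincount(d.g, weights=w * d.r * resid, minlength=d.J)
    det = np.maximum(sw * swrr - swr * swr, 1e-12)
    hat0 = (swrr * swy - swr * swry) / det
    hat1 = (sw * swry - swr * swy) / det
    # inverse of the information matrix [[sw, swr], [swr, swrr]]
    V00 = swrr / det
    V01 = -swr / det
    V11 = sw / det
    return hat0, hat1, V00, V01, V11


def _pair_marginal_lp(dev0, dev1, V00, V01, V11, s0, s1):
    """Sum of bivariate normal log densities N((dev0, dev1); 0, V + diag(s0^2,
    s1^2)) up to constants."""
    v00 = V00 + s0 * s0
    v11 = V11 + s1 * s1
    det = v00 * v11 - V01 * V01
    quad = (v11 * dev0 ** 2 - 2.0 * V01 * dev0 * dev1 + v00 * dev1 ** 2) / det
    return float(-0.5 * np.sum(np.log(det) + quad))


def _marginal_pair_scale(rng, s0, s1, step, dev0, dev1, V00, V01, V11,
                         upper, which):
    """1-D random-walk Metropolis on log sigma_alpha0 (which=0) or
    log sigma_alpha1 (which=1) under the pair-marginalized likelihood."""
    cur = s0 if which == 0 else s1

    def lp(val):
        if val >= upper:
            return -np.inf
        a, b = (val, s1) if which == 0 else (s0, val)
        return _pair_marginal_lp(dev0, dev1, V00, V01, V11, a, b) + np.log(val)

    prop = float(np.exp(np.log(cur) + step * rng.normal()))
    if np.log(rng.uniform()) < lp(prop) - lp(cur):
        return prop, True
    return cur, False


def _joint_gamma_draw(rng, d: _Data, hat0, hat1, V00, V01, V11, s0, s1,
                      prior_var):
    """Conjugate joint draw of (gamma0, gamma1) with the grid lines
    marginalized: responses (hat0_j, hat1_j), covariance V_j + diag(s^2)."""
    v00 = V00 + s0 * s0
    v11 = V11 + s1 * s1
    det = v00 * v11 - V01 * V01
    a = v11 / det          # elements of V_j^{-1}
    b = -V01 / det
    c = v00 / det
    q0 = d.Z0.shape[1]
    q1 = d.Z1.shape[1]
    prec = np.zeros((q0 + q1, q0 + q1))
    prec[:q0, :q0] = d.Z0.T @ (d.Z0 * a[:, None])
    prec[:q0, q0:] = d.Z0.T @ (d.Z1 * b[:, None])
    prec[q0:, :q0] = prec[:q0, q0:].T
    prec[q0:, q0:] = d.Z1.T @ (d.Z1 * c[:, None])
    prec += np.eye(q0 + q1) / prior_var
    rhs = np.concatenate([
        d.Z0.T @ (a * hat0 + b * hat1),
        d.Z1.T @ (b * hat0 + c * hat1),
    ])
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    draw = mean + np.linalg.solve(chol.T, rng.normal(size=q0 + q1))
    return draw[:q0], draw[q0:]


class _State:
    __slots__ = ("alpha0", "alpha1", "a_site", "gamma0", "gamma1", "beta",
                 "theta", "sigma_a0", "sigma_a1", "sigma_site", "sigma_beta")


def _init_state(d: _Data, spec: HBModelSpec, rng) -> _State:
    st = _State()
    # per-grid least squares for intercept/slope starts
    a0 = np.empty(d.J)
    a1 = np.empty(d.J)
    ybar = np.bincount(d.g, weights=d.y) / np.bincount(d.g)
    rbar = np.bincount(d.g, weights=d.r) / np.bincount(d.g)
    sxy = np.bincount(d.g, weights=d.r * d.y) - np.bincount(d.g) * rbar * ybar
    sxx = np.bincount(d.g, weights=d.r * d.r) - np.bincount(d.g) * rbar * rbar
    ok = sxx > 1e-9
    a1[ok] = sxy[ok] / sxx[ok]
    a1[~ok] = 0.0
    a0 = ybar - a1 * rbar
    st.alpha0 = a0 + 0.05 * rng.normal(size=d.J)
    st.alpha1 = a1 + 0.01 * rng.normal(size=d.J)
    st.a_site = np.zeros(d.S)
    st.gamma0 = np.linalg.lstsq(d.Z0, st.alpha0, rcond=None)[0]
    st.gamma1 = np.linalg.lstsq(d.Z1, st.alpha1, rcond=None)[0]
    resid0 = st.alpha0 - d.Z0 @ st.gamma0
    resid1 = st.alpha1 - d.Z1 @ st.gamma1
    st.sigma_a0 = float(np.clip(np.std(resid0) + 1e-3, 1e-3, 50.0))
    st.sigma_a1 = float(np.clip(np.std(resid1) + 1e-3, 1e-3, 50.0))
    st.sigma_site = 0.5
    # level dispersion starts from empirical level SDs (or CVs)
    mu = st.alpha0[d.g] + st.alpha1[d.g] * d.r
    res = d.y - mu
    ss_k = np.bincount(d.k_idx, weights=res * res)
    sd_k = np.sqrt(ss_k / np.maximum(d.n_k, 2))
    sd_k = np.clip(sd_k, 1e-3, None)
    if spec.variant == "sd":
        st.theta = np.log(sd_k)
    else:
        mu_k = np.bincount(d.k_idx, weights=mu) / d.n_k
        mu_k = np.clip(mu_k, 1e-3, None)
        st.theta = np.log(sd_k / mu_k)
    st.theta = st.theta + 0.05 * rng.normal(size=d.K)
    st.beta = np.linalg.lstsq(d.Zk, st.theta, rcond=None)[0]
    st.sigma_beta = float(np.clip(np.std(st.theta - d.Zk @ st.beta) + 1e-3,
                                  1e-3, 10.0))
    return st


def _sigma_k_of(state: _State, d: _Data, variant: str):
    """Per-level SD implied by the dispersion parameters (and, in the CV
    variant, the current mean structure).  Returns (sigma_k, mu, valid)."""
    mu = (state.alpha0[d.g] + state.alpha1[d.g] * d.r
          + state.a_site[d.s_of_plot])
    if variant == "sd":
        return np.exp(state.theta), mu, True
    mu_k = np.bincount(d.k_idx, weights=mu) / d.n_k
    if np.any(mu_k <= 0):
        return None, mu, False
    return np.exp(state.theta) * mu_k, mu, True


def _loglik(d: _Data, mu, sigma_k):
    sig = sigma_k[d.k_idx]
    return float(np.sum(-np.log(sig) - 0.5 * ((d.y - mu) / sig) ** 2))


def _grid_block_params(d: _Data, state: _State, w):
    """Per-grid conjugate bivariate-normal parameters for (alpha0, alpha1)."""
    resid = d.y - state.a_site[d.s_of_plot]
    sw = np.bincount(d.g, weights=w)
    swr = np.bincount(d.g, weights=w * d.r)
    swrr = np.bincount(d.g, weights=w * d.r * d.r)
    swy = np.bincount(d.g, weights=w * resid)
    swry = np.bincount(d.g, weights=w * d.r * resid)
    m0 = d.Z0 @ state.gamma0
    m1 = d.Z1 @ state.gamma1
    p0 = 1.0 / state.sigma_a0 ** 2
    p1 = 1.0 / state.sigma_a1 ** 2
    A11 = sw + p0
    A12 = swr
    A22 = swrr + p1
    b1 = swy + m0 * p0
    b2 = swry + m1 * p1
    det = A11 * A22 - A12 * A12
    mean0 = (A22 * b1 - A12 * b2) / det
    mean1 = (A11 * b2 - A12 * b1) / det
    return (A11, A12, A22, det), (mean0, mean1)


def _grid_block_draw(rng, prec, mean):
    """Sample per-grid bivariate normals with precision [[A11,A12],[A12,A22]]
    via the 2x2 Cholesky of the precision matrix."""
    A11, A12, A22, det = prec
    mean0, mean1 = mean
    L11 = np.sqrt(A11)
    L21 = A12 / L11
    L22 = np.sqrt(A22 - L21 ** 2)
    z1 = rng.normal(size=len(mean0))
    z2 = rng.normal(size=len(mean0))
    # solve L^T x = z  for covariance-cholesky sampling from precision
    x2 = z2 / L22
    x1 = (z1 - L21 * x2) / L11
    return mean0 + x1, mean1 + x2


def _grid_block_logq(prec, mean, a0, a1):
    A11, A12, A22, det = prec
    d0 = a0 - mean[0]
    d1 = a1 - mean[1]
    quad = A11 * d0 ** 2 + 2 * A12 * d0 * d1 + A22 * d1 ** 2
    return float(0.5 * np.sum(np.log(det)) - 0.5 * np.sum(quad))


def _alpha_prior_lp(d: _Data, state: _State, a0, a1):
    m0 = d.Z0 @ state.gamma0
    m1 = d.Z1 @ state.gamma1
    lp = -0.5 * np.sum(((a0 - m0) / state.sigma_a0) ** 2) \
        - d.J * np.log(state.sigma_a0)
    lp += -0.5 * np.sum(((a1 - m1) / state.sigma_a1) ** 2) \
        - d.J * np.log(state.sigma_a1)
    return float(lp)


def fit_mcmc(spec: HBModelSpec, ds: Dataset, cov: pd.DataFrame,
             chains: int = 3, iterations: int = 20_000, burn_in: int = 10_000,
             thin: int = 5, seed: int = 0) -> HBPosterior:
    """Fit the hierarchical model by Metropolis-within-Gibbs MCMC.

    Runs ``chains`` independent chains of ``iterations`` sweeps, discarding
    ``burn_in`` and keeping every ``thin``-th draw.  Deterministic given
    ``seed``.  Metropolis proposal scales adapt toward ~40% acceptance
    during burn-in only; a chain ending outside 10-90% acceptance triggers
    a warning.
    """
    d = _Data(ds, cov)
    variant = spec.variant
    n_keep = (iterations - burn_in) // thin
    if n_keep < 1:
        raise ValueError("no draws retained: check iterations/burn_in/thin")

    store = {
        "alpha0": np.empty((chains, n_keep, d.J)),
        "alpha1": np.empty((chains, n_keep, d.J)),
        "a_site": np.empty((chains, n_keep, d.S)),
        "gamma0": np.empty((chains, n_keep, 4)),
        "gamma1": np.empty((chains, n_keep, 2)),
        "beta": np.empty((chains, n_keep, 2)),
        ("log_sigma_k" if variant == "sd" else "log_cv_k"):
            np.empty((chains, n_keep, d.K)),
        "sigma_alpha0": np.empty((chains, n_keep)),
        "sigma_alpha1": np.empty((chains, n_keep)),
        "sigma_site": np.empty((chains, n_keep)),
        "sigma_beta": np.empty((chains, n_keep)),
    }
    acc_report = {}

    for c in range(chains):
        rng = np.random.default_rng(seed + 1000 * c)
        st = _init_state(d, spec, rng)
        step_k = np.full(d.K, 0.3)
        step_a = {"a0": 0.3, "a1": 0.3}
        acc_a = {"a0": 0.0, "a1": 0.0}
        acc_k = np.zeros(d.K)
        n_prop = 0
        acc_alpha = 0.0
        n_alpha = 0
        kept = 0
        for it in range(iterations):
            sigma_k, mu, _ = _sigma_k_of(st, d, variant)
            w = 1.0 / sigma_k[d.k_idx] ** 2

            if variant == "sd":
                # ---- partially collapsed sweep (exact: sigma_k free of alpha)
                # site effects given current grid lines
                if d.S >= 2:
                    resid = d.y - st.alpha0[d.g] - st.alpha1[d.g] * d.r
                    sw_s = np.bincount(d.s_of_plot, weights=w, minlength=d.S)
                    swr_s = np.bincount(d.s_of_plot, weights=w * resid,
                                        minlength=d.S)
                    prec_s = sw_s + 1.0 / st.sigma_site ** 2
                    st.a_site = (swr_s / prec_s
                                 + rng.normal(size=d.S) / np.sqrt(prec_s))
                    st.sigma_site = _trunc_invgamma_sd(
                        rng, d.S, float(np.sum(st.a_site ** 2)),
                        spec.sigma_upper, st.sigma_site)

                # grid-line hierarchy: integrate the (alpha0, alpha1)
                # pair out of the sigma/gamma updates, then redraw the pair
                # (avoids both the funnel collapse and the intercept-slope
                # conditioning feedback)
                hat0, hat1, V00, V01, V11 = _grid_gls(d, st, w)
                dev0 = hat0 - d.Z0 @ st.gamma0
                dev1 = hat1 - d.Z1 @ st.gamma1
                st.sigma_a0, ok0 = _marginal_pair_scale(
                    rng, st.sigma_a0, st.sigma_a1, step_a["a0"], dev0, dev1,
                    V00, V01, V11, spec.sigma_upper, which=0)
                acc_a["a0"] += ok0
                st.sigma_a1, ok1 = _marginal_pair_scale(
                    rng, st.sigma_a0, st.sigma_a1, step_a["a1"], dev0, dev1,
                    V00, V01, V11, spec.sigma_upper, which=1)
                acc_a["a1"] += ok1
                st.gamma0, st.gamma1 = _joint_gamma_draw(
                    rng, d, hat0, hat1, V00, V01, V11,
                    st.sigma_a0, st.sigma_a1, spec.loc_prior_var)

                # redraw the grid lines from their full conditional
                prec, mean = _grid_block_params(d, st, w)
                st.alpha0, st.alpha1 = _grid_block_draw(rng, prec, mean)
            else:
                # ---- CV variant: conjugate-proposal MH (dispersion feedback)
                prec, mean = _grid_block_params(d, st, w)
                a0_new, a1_new = _grid_block_draw(rng, prec, mean)
                old0, old1 = st.alpha0, st.alpha1
                cur_lp = (_loglik(d, mu, sigma_k)
                          + _alpha_prior_lp(d, st, old0, old1))
                st.alpha0, st.alpha1 = a0_new, a1_new
                sig_new, mu_new, valid = _sigma_k_of(st, d, variant)
                n_alpha += 1
                if not valid:
                    st.alpha0, st.alpha1 = old0, old1
                else:
                    new_lp = (_loglik(d, mu_new, sig_new)
                              + _alpha_prior_lp(d, st, a0_new, a1_new))
                    w_new = 1.0 / sig_new[d.k_idx] ** 2
                    prec_r, mean_r = _grid_block_params(d, st, w_new)
                    logq_fwd = _grid_block_logq(prec, mean, a0_new, a1_new)
                    logq_rev = _grid_block_logq(prec_r, mean_r, old0, old1)
                    log_r = new_lp - cur_lp + logq_rev - logq_fwd
                    if np.log(rng.uniform()) < log_r:
                        acc_alpha += 1
                    else:
                        st.alpha0, st.alpha1 = old0, old1
                sigma_k, mu, _ = _sigma_k_of(st, d, variant)
                w = 1.0 / sigma_k[d.k_idx] ** 2

            # -- site effects (CV variant; the sd path updated them above)
            if variant == "cv" and d.S >= 2:
                resid = d.y - st.alpha0[d.g] - st.alpha1[d.g] * d.r
                if True:
                    old = st.a_site
                    sig_cur, mu_cur, _ = _sigma_k_of(st, d, variant)
                    w_cur = 1.0 / sig_cur[d.k_idx] ** 2
                    sw_s = np.bincount(d.s_of_plot, weights=w_cur, minlength=d.S)
                    swr_s = np.bincount(d.s_of_plot, weights=w_cur * resid,
                                        minlength=d.S)
                    prec_s = sw_s + 1.0 / st.sigma_site ** 2
                    mean_s = swr_s / prec_s
                    prop = mean_s + rng.normal(size=d.S) / np.sqrt(prec_s)
                    cur_lp = (_loglik(d, mu_cur, sig_cur)
                              - 0.5 * np.sum((old / st.sigma_site) ** 2))
                    st.a_site = prop
                    sig_new, mu_new, valid = _sigma_k_of(st, d, variant)
                    if not valid:
                        st.a_site = old
                    else:
                        new_lp = (_loglik(d, mu_new, sig_new)
                                  - 0.5 * np.sum((prop / st.sigma_site) ** 2))
                        w_new = 1.0 / sig_new[d.k_idx] ** 2
                        sw_r = np.bincount(d.s_of_plot, weights=w_new,
                                           minlength=d.S)
                        swr_r = np.bincount(d.s_of_plot, weights=w_new * resid,
                                            minlength=d.S)
                        prec_r = sw_r + 1.0 / st.sigma_site ** 2
                        mean_r = swr_r / prec_r
                        logq_fwd = float(0.5 * np.sum(np.log(prec_s))
                                         - 0.5 * np.sum(prec_s * (prop - mean_s) ** 2))
                        logq_rev = float(0.5 * np.sum(np.log(prec_r))
                                         - 0.5 * np.sum(prec_r * (old - mean_r) ** 2))
                        log_r = new_lp - cur_lp + logq_rev - logq_fwd
                        if not np.log(rng.uniform()) < log_r:
                            st.a_site = old

            # -- translation move along the likelihood-invariant direction
            # (a_site up, the site's grid intercepts down): decorrelates the
            # additively confounded site/grid levels
            if d.S >= 2:
                m0 = d.Z0 @ st.gamma0
                n_g = np.bincount(d.site_of_grid, minlength=d.S).astype(float)
                dev = np.bincount(d.site_of_grid, weights=st.alpha0 - m0,
                                  minlength=d.S)
                prec_t = n_g / st.sigma_a0 ** 2 + 1.0 / st.sigma_site ** 2
                mean_t = (dev / st.sigma_a0 ** 2
                          - st.a_site / st.sigma_site ** 2) / prec_t
                delta = mean_t + rng.normal(size=d.S) / np.sqrt(prec_t)
                st.a_site = st.a_site + delta
                st.alpha0 = st.alpha0 - delta[d.site_of_grid]

            # -- gamma regressions and their scales (CV variant)
            if variant == "cv":
                st.gamma0 = _mvn_reg_draw(rng, d.Z0, st.alpha0, st.sigma_a0,
                                          spec.loc_prior_var)
                st.gamma1 = _mvn_reg_draw(rng, d.Z1, st.alpha1, st.sigma_a1,
                                          spec.loc_prior_var)
                ss0 = float(np.sum((st.alpha0 - d.Z0 @ st.gamma0) ** 2))
                ss1 = float(np.sum((st.alpha1 - d.Z1 @ st.gamma1) ** 2))
                st.sigma_a0 = _trunc_invgamma_sd(rng, d.J, ss0,
                                                 spec.sigma_upper, st.sigma_a0)
                st.sigma_a1 = _trunc_invgamma_sd(rng, d.J, ss1,
                                                 spec.sigma_upper, st.sigma_a1)
                if d.S >= 2:
                    ss_site = float(np.sum(st.a_site ** 2))
                    st.sigma_site = _trunc_invgamma_sd(rng, d.S, ss_site,
                                                       spec.sigma_upper,
                                                       st.sigma_site)

            # -- dispersion regression
            st.beta = _mvn_reg_draw(rng, d.Zk, st.theta, st.sigma_beta,
                                    spec.loc_prior_var)
            ssb = float(np.sum((st.theta - d.Zk @ st.beta) ** 2))
            st.sigma_beta = _trunc_invgamma_sd(rng, d.K, ssb, spec.sigma_upper,
                                               st.sigma_beta)

            # -- level dispersions: vectorized random-walk Metropolis
            sigma_k, mu, _ = _sigma_k_of(st, d, variant)
            res2 = (d.y - mu) ** 2
            ss_level = np.bincount(d.k_idx, weights=res2, minlength=d.K)
            if variant == "sd":
                base = np.zeros(d.K)  # sigma_k = exp(theta)
            else:
                mu_k = np.bincount(d.k_idx, weights=mu) / d.n_k
                base = np.log(mu_k)   # sigma_k = exp(theta) * mu_k
            prior_mean = d.Zk @ st.beta

            theta_prop = st.theta + step_k * rng.normal(size=d.K)

            def _level_lp(th):
                log_sig = th + base
                return (-d.n_k * log_sig - 0.5 * ss_level * np.exp(-2.0 * log_sig)
                        - 0.5 * ((th - prior_mean) / st.sigma_beta) ** 2)

            log_r = _level_lp(theta_prop) - _level_lp(st.theta)
            accept = np.log(rng.uniform(size=d.K)) < log_r
            st.theta = np.where(accept, theta_prop, st.theta)
            acc_k += accept
            n_prop += 1

            # adaptation during burn-in
            if it < burn_in and n_prop == 50:
                rate = acc_k / n_prop
                step_k *= np.exp(np.clip(rate - 0.35, -0.5, 0.5))
                step_k = np.clip(step_k, 1e-3, 5.0)
                acc_k[:] = 0
                for key in step_a:
                    r = acc_a[key] / 50.0
                    step_a[key] = float(np.clip(
                        step_a[key] * np.exp(np.clip(r - 0.44, -0.5, 0.5)),
                        1e-3, 5.0))
                    acc_a[key] = 0.0
                n_prop = 0
            elif it == burn_in:
                acc_k[:] = 0
                n_prop = 0

            if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
                store["alpha0"][c, kept] = st.alpha0
                store["alpha1"][c, kept] = st.alpha1
                store["a_site"][c, kept] = st.a_site
                store["gamma0"][c, kept] = st.gamma0
                store["gamma1"][c, kept] = st.gamma1
                store["beta"][c, kept] = st.beta
                store["log_sigma_k" if variant == "sd" else "log_cv_k"][c, kept] = st.theta
                store["sigma_alpha0"][c, kept] = st.sigma_a0
                store["sigma_alpha1"][c, kept] = st.sigma_a1
                store["sigma_site"][c, kept] = st.sigma_site
                store["sigma_beta"][c, kept] = st.sigma_beta
                kept += 1

        rate_k = acc_k / max(n_prop, 1)
        acc_report[f"chain{c}_level_metropolis"] = float(np.mean(rate_k))
        if np.mean(rate_k) < 0.10 or np.mean(rate_k) > 0.90:
            warnings.warn(
                f"chain {c}: level-dispersion Metropolis acceptance "
                f"{np.mean(rate_k):.2f} outside [0.10, 0.90]", stacklevel=2)
        if variant == "cv" and n_alpha:
            acc_report[f"chain{c}_alpha_mh"] = acc_alpha / n_alpha

    return HBPosterior(draws=store, grid_ids=d.grid_ids, site_ids=d.site_ids,
                       levels=d.levels.astype(int), variant=variant, seed=seed,
                       iterations=iterations, burn_in=burn_in, thin=thin,
                       scaling=d.scaling, acceptance=acc_report)


def fit_cv_variant(spec: HBModelSpec | None, ds: Dataset, cov: pd.DataFrame,
                   **kwargs) -> HBPosterior:
    """Fit the CV-dispersion variant (log CV_k regressed on richness)."""
    base = spec or HBModelSpec()
    cv_spec = HBModelSpec(variant="cv", loc_prior_var=base.loc_prior_var,
                          sigma_upper=base.sigma_upper)
    return fit_mcmc(cv_spec, ds, cov, **kwargs)


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(post: HBPosterior, cutoff: float = 1.1
                 ) -> tuple[dict[str, float | None], bool]:
    """Split-chain potential scale reduction factor per parameter.

    Returns (PSRF per scalar parameter element, overall pass at ``cutoff``).
    A parameter with zero within-chain variance is reported as ``None``
    (not applicable) and does not fail the check.
    """
    import arviz as az

    if post.n_chains < 2:
        raise ValueError("PSRF needs at least 2 chains")
    if post.n_draws < 10:
        raise ValueError("PSRF needs at least 10 draws per chain")
    out: dict[str, float | None] = {}
    for name, arr in post.draws.items():
        rh = az.rhat(az.convert_to_dataset(arr[None] if arr.ndim == 1 else arr),
                     method="split")["x"].to_numpy()
        rh = np.atleast_1d(rh)
        if arr.ndim == 2:
            out[name] = None if not np.isfinite(rh[0]) else float(rh[0])
        else:
            for i in range(arr.shape[-1]):
                out[f"{name}[{i}]"] = (None if not np.isfinite(rh[i])
                                       else float(rh[i]))
    finite = [v for v in out.values() if v is not None]
    passed = bool(all(v < cutoff for v in finite)) if finite else False
    return out, passed


def posterior_predictive_pvalues(post: HBPosterior, spec: HBModelSpec,
                                 ds: Dataset, cov: pd.DataFrame,
                                 n_rep: int = 1000, seed: int = 0,
                                 reported: tuple[str, ...] = ("mean", "sd", "plot"),
                                 ) -> PpcReport:
    """Bayesian p-values from posterior predictive replicates.

    For ``n_rep`` retained draws (subsampled evenly across chains) a full
    replicate dataset is simulated from the likelihood conditional on that
    draw's grid/site/level parameters; P_B is the fraction of replicates
    whose statistic T(y_new) is >= T(y_obs) for T in mean, SD and CV across
    all plots, plus the plot-level exceedance probability.
    """
    if n_rep < 100:
        warnings.warn("n_rep < 100: Monte-Carlo error on P_B will be large",
                      stacklevel=2)
    d = _Data(ds, cov)
    rng = np.random.default_rng(seed)
    raw = post.raw_draws()
    total = post.n_chains * post.n_draws
    take = np.linspace(0, total - 1, min(n_rep, total)).astype(int)
    alpha0 = raw["alpha0"].reshape(total, -1)[take]
    alpha1 = raw["alpha1"].reshape(total, -1)[take]
    a_site = raw["a_site"].reshape(total, -1)[take]
    if post.variant == "sd":
        sigk = raw["sigma_k"].reshape(total, -1)[take]
    else:
        cvk = raw["cv_k"].reshape(total, -1)[take]

    y_obs = d.y_raw
    t_obs = {"mean": float(np.mean(y_obs)), "sd": float(np.std(y_obs, ddof=1)),
             "cv": float(np.std(y_obs, ddof=1) / np.mean(y_obs))}
    exceed = {"mean": 0, "sd": 0, "cv": 0}
    plot_exceed = 0.0
    for t in range(len(take)):
        mu = alpha0[t][d.g] + alpha1[t][d.g] * d.r_raw + a_site[t][d.s_of_plot]
        if post.variant == "sd":
            sig = sigk[t][d.k_idx]
        else:
            mu_k = np.bincount(d.k_idx, weights=mu) / d.n_k
            sig = (cvk[t] * np.abs(mu_k))[d.k_idx]
        y_new = mu + sig * rng.normal(size=d.N)
        m, s = float(np.mean(y_new)), float(np.std(y_new, ddof=1))
        exceed["mean"] += m >= t_obs["mean"]
        exceed["sd"] += s >= t_obs["sd"]
        exceed["cv"] += (s / m if m != 0 else np.inf) >= t_obs["cv"]
        plot_exceed += float(np.mean(y_new >= y_obs))
    nrep = len(take)
    p_values = {k: v / nrep for k, v in exceed.items()}
    p_values["plot"] = plot_exceed / nrep
    return PpcReport(p_values=p_values, n_rep=nrep, reported=reported)


def slope_gradient_summary(post: HBPosterior, grids: pd.DataFrame
                           ) -> tuple[pd.DataFrame, dict]:
    """Per-grid biodiversity-effect summaries plus the gradient slope.

    Returns (per-grid frame with posterior median and 95% CI of the
    richness-productivity slope alpha1_j, grid mean productivity and a flag
    for CIs excluding zero; dict with the median and 95% CI of g11, the
    slope of biodiversity effects on grid productivity).
    """
    raw = post.raw_draws()
    a1 = raw["alpha1"].reshape(-1, raw["alpha1"].shape[-1])
    lo, med, hi = np.quantile(a1, [0.025, 0.5, 0.975], axis=0)
    frame = pd.DataFrame({"grid_id": post.grid_ids, "slope_median": med,
                          "slope_lo": lo, "slope_hi": hi,
                          "excludes_zero": (lo > 0) | (hi < 0)})
    frame = frame.merge(grids[["grid_id", "mean_productivity"]], on="grid_id",
                        how="left")
    g11 = raw["gamma11"].reshape(-1)
    qlo, qmed, qhi = np.quantile(g11, [0.025, 0.5, 0.975])
    return frame, {"median": float(qmed), "lo": float(qlo), "hi": float(qhi),
                   "excludes_zero": bool(qlo > 0 or qhi < 0)}
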