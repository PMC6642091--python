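"""Covariance-based path analysis with maximum-likelihood estimation.

Observed-variable path models ("SEM" without latent measurement models):
directed regressions among observed variables plus free covariances among
exogenous variables (or among error terms).  With ``B`` the matrix of path
coefficients and ``Psi`` the covariance matrix of exogenous variables and
disturbances, the model-implied covariance is

    Sigma(theta) = (I - B)^-1  Psi  (I - B)^-T

and parameters minimize the ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over the free entries of ``B`` and ``Psi`` (sample covariance ``S`` with
denominator N-1).  The test statistic is (N-1) * F_min, asymptotically
chi-square with df = p(p+1)/2 - q under a correct model.  Standard errors
come from the observed information (numerical Hessian of F) at the optimum.

Model specs use a one-edge-per-line text DSL::

    richness -> productivity      # regression
    daylight <-> temperature      # covariance (exogenous or error)

Fit quality is summarized by the conventional index suite: absolute
(chi-square, GFI, AGFI, RMSEA), relative (NFI, RFI, IFI, TLI, CFI) and
parsimonious (NC, AIC, CAIC) indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class ConvergenceError(RuntimeError):
    """The optimizer failed to reach the gradient tolerance."""


class DataError(ValueError):
    """The sample covariance matrix is unusable (e.g. not positive definite)."""


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class PathModelSpec:
    """A directed-acyclic path diagram over observed variables.

    ``regressions`` are (source, target) pairs; ``covariances`` unordered
    pairs.  Every endogenous variable (one with at least one incoming
    regression) implicitly carries a free error variance; exogenous
    variables carry free variances.
    """

    regressions: tuple[tuple[str, str], ...]
    covariances: tuple[tuple[str, str], ...] = ()
    variables: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.variables:
            seen: dict[str, None] = {}
            for src, dst in self.regressions:
                seen.setdefault(src)
                seen.setdefault(dst)
            for a, b in self.covariances:
                seen.setdefault(a)
                seen.setdefault(b)
            object.__setattr__(self, "variables", tuple(seen))
        self._check_acyclic()

    def _check_acyclic(self):
        children: dict[str, list[str]] = {}
        for src, dst in self.regressions:
            children.setdefault(src, []).append(dst)
        state: dict[str, int] = {}

        def visit(v):
            if state.get(v) == 1:
                raise ValueError("directed edges contain a cycle")
            if state.get(v) == 2:
                return
            state[v] = 1
            for w in children.get(v, ()):
                visit(w)
            state[v] = 2

        for v in self.variables:
            visit(v)

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {dst for _, dst in self.regressions}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        endo = set(self.endogenous)
        return tuple(v for v in self.variables if v not in endo)

    @property
    def n_free(self) -> int:
        return len(self.regressions) + len(self.variables) + len(self.covariances)

    def degrees_of_freedom(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free


def parse_model(text: str) -> PathModelSpec:
    """Parse the one-edge-per-line DSL into a :class:`PathModelSpec`."""
    regressions, covariances = [], []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "<->" in line:
            a, b = (t.strip() for t in line.split("<->"))
            covariances.append((a, b))
        elif "->" in line:
            a, b = (t.strip() for t in line.split("->"))
            regressions.append((a, b))
        else:
            raise ValueError(f"cannot parse model line: {raw!r}")
    return PathModelSpec(tuple(regressions), tuple(covariances))


def saturated_spec(variables: list[str]) -> PathModelSpec:
    """Recursive just-identified model: each variable regressed on all
    previous ones (df = 0 by construction)."""
    regs = [(variables[j], variables[i])
            for i in range(1, len(variables)) for j in range(i)]
    return PathModelSpec(tuple(regs), variables=tuple(variables))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PathModelFit:
    spec: PathModelSpec
    n: int
    weights: dict[tuple[str, str], float]
    std_weights: dict[tuple[str, str], float]
    se: dict[tuple[str, str], float]
    std_se: dict[tuple[str, str], float]
    correlations: dict[tuple[str, str], float]
    smc: dict[str, float]
    error_variances: dict[str, float]
    fmin: float
    test_statistic: float
    df: int
    p_value: float | None
    sigma: np.ndarray
    sample_cov: np.ndarray
    grad_norm: float
    n_free: int


def _index_maps(spec: PathModelSpec):
    vidx = {v: i for i, v in enumerate(spec.variables)}
    b_idx = [(vidx[dst], vidx[src]) for src, dst in spec.regressions]
    c_idx = [(vidx[a], vidx[b]) for a, b in spec.covariances]
    return vidx, b_idx, c_idx


def _unpack(theta, p, b_idx, c_idx):
    nb = len(b_idx)
    B = np.zeros((p, p))
    for t, (i, j) in enumerate(b_idx):
        B[i, j] = theta[t]
    psi = np.zeros((p, p))
    d = np.exp(theta[nb:nb + p])
    psi[np.diag_indices(p)] = d
    for t, (i, j) in enumerate(c_idx):
        psi[i, j] = psi[j, i] = theta[nb + p + t]
    return B, psi


def _f_and_grad(theta, S, logdetS, b_idx, c_idx):
    p = S.shape[0]
    nb = len(b_idx)
    B, psi = _unpack(theta, p, b_idx, c_idx)
    A = np.linalg.inv(np.eye(p) - B)
    sigma = A @ psi @ A.T
    try:
        c_fac = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    logdet = 2.0 * np.sum(np.log(np.diag(c_fac)))
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + float(np.sum(sigma_inv * S)) - logdetS - p
    M = sigma_inv - sigma_inv @ S @ sigma_inv
    grad = np.empty_like(theta)
    SMA = sigma @ M @ A
    for t, (i, j) in enumerate(b_idx):
        grad[t] = 2.0 * SMA[j, i]
    AMA = A.T @ M @ A
    diag_psi = np.diag(psi)
    grad[nb:nb + p] = np.diag(AMA) * diag_psi  # log-variance chain rule
    for t, (i, j) in enumerate(c_idx):
        grad[nb + p + t] = 2.0 * AMA[i, j]
    return f, grad


def _start_values(S, spec, vidx):
    """Per-equation least-squares start: exact ML for recursive
    just-identified models, a good neighborhood otherwise."""
    p = S.shape[0]
    parents: dict[int, list[int]] = {}
    for src, dst in spec.regressions:
        parents.setdefault(vidx[dst], []).append(vidx[src])
    theta_b, psi_d = [], np.diag(S).copy()
    coef = {}
    for src, dst in spec.regressions:
        i, js = vidx[dst], parents[vidx[dst]]
        if i not in coef:
            Spp = S[np.ix_(js, js)]
            b = np.linalg.solve(Spp, S[js, i])
            coef[i] = dict(zip(js, b))
            psi_d[i] = max(S[i, i] - b @ S[js, i], 1e-3 * S[i, i])
        theta_b.append(coef[i][vidx[src]])
    theta_c = [S[vidx[a], vidx[b]] for a, b in spec.covariances]
    return np.concatenate([theta_b, np.log(psi_d), theta_c])


def fit_path_model(data: pd.DataFrame, spec: PathModelSpec,
                   gtol: float = 1e-6, max_iter: int = 10_000,
                   n_restarts: int = 3) -> PathModelFit:
    """Fit a path model by maximum likelihood.

    ``data`` must contain one column per spec variable (extra columns are
    ignored).  Raises :class:`DataError` for N <= p or a non-positive-
    definite sample covariance, :class:`ConvergenceError` (with the final
    gradient norm) if the quasi-Newton optimizer fails even after jittered
    restarts.
    """
    cols = list(spec.variables)
    X = data[cols].to_numpy(dtype=float)
    N, p = X.shape
    if N <= p:
        raise DataError(f"need more observations ({N}) than variables ({p})")
    S = np.cov(X, rowvar=False, ddof=1)
    return fit_path_model_from_cov(S, N, spec, gtol=gtol, max_iter=max_iter,
                                   n_restarts=n_restarts)


def fit_path_model_from_cov(S: np.ndarray, N: int, spec: PathModelSpec,
                            gtol: float = 1e-6, max_iter: int = 10_000,
                            n_restarts: int = 3) -> PathModelFit:
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    sign, logdetS = np.linalg.slogdet(S)
    if sign <= 0 or np.min(np.linalg.eigvalsh(S)) <= 0:
        raise DataError("sample covariance matrix is not positive definite")
    vidx, b_idx, c_idx = _index_maps(spec)
    df = spec.degrees_of_freedom()
    if df < 0:
        raise ValueError(f"model has negative degrees of freedom ({df})")

    theta0 = _start_values(S, spec, vidx)
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(1 + n_restarts):
        start = theta0 if attempt == 0 else theta0 + rng.normal(
            0.0, 0.1 * (1.0 + np.abs(theta0)))
        res = optimize.minimize(
            _f_and_grad, start, args=(S, logdetS, b_idx, c_idx),
            jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": max_iter})
        gnorm = float(np.max(np.abs(res.jac)))
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm < gtol:
            break
    res, gnorm = best
    if gnorm > 1e-4:
        raise ConvergenceError(
            f"ML optimization failed: gradient norm {gnorm:.3g} after "
            f"{1 + n_restarts} starts")

    theta = res.x
    fmin = max(float(res.fun), 0.0)
    B, psi = _unpack(theta, p, b_idx, c_idx)
    A = np.linalg.inv(np.eye(p) - B)
    sigma = A @ psi @ A.T

    sds = np.sqrt(np.diag(sigma))
    weights = {e: float(B[vidx[e[1]], vidx[e[0]]]) for e in spec.regressions}
    std_weights = {e: weights[e] * sds[vidx[e[0]]] / sds[vidx[e[1]]]
                   for e in spec.regressions}
    correlations = {
        e: float(psi[vidx[e[0]], vidx[e[1]]]
                 / np.sqrt(psi[vidx[e[0]], vidx[e[0]]]
                           * psi[vidx[e[1]], vidx[e[1]]]))
        for e in spec.covariances}
    smc = {v: 1.0 - psi[vidx[v], vidx[v]] / sigma[vidx[v], vidx[v]]
           for v in spec.endogenous}
    error_variances = {v: float(psi[vidx[v], vidx[v]]) for v in spec.variables}

    se_vec = _standard_errors(theta, S, logdetS, b_idx, c_idx, N)
    se = {e: float(se_vec[t]) for t, e in enumerate(spec.regressions)}
    std_se = {e: se[e] * sds[vidx[e[0]]] / sds[vidx[e[1]]]
              for e in spec.regressions}

    T_stat = (N - 1) * fmin
    p_value = float(stats.chi2.sf(T_stat, df)) if df > 0 else None
    return PathModelFit(
        spec=spec, n=N, weights=weights, std_weights=std_weights, se=se,
        std_se=std_se, correlations=correlations, smc=smc,
        error_variances=error_variances, fmin=fmin, test_statistic=T_stat,
        df=df, p_value=p_value, sigma=sigma, sample_cov=S, grad_norm=gnorm,
        n_free=spec.n_free)


def _standard_errors(theta, S, logdetS, b_idx, c_idx, N):
    """Asymptotic SEs from the observed information: acov = 2/(N-1) H^-1
    with H the Hessian of F, obtained by central differences of the
    analytic gradient."""
    q = len(theta)
    H = np.zeros((q, q))
    h = 1e-5 * (1.0 + np.abs(theta))
    for t in range(q):
        up, dn = theta.copy(), theta.copy()
        up[t] += h[t]
        dn[t] -= h[t]
        _, g_up = _f_and_grad(up, S, logdetS, b_idx, c_idx)
        _, g_dn = _f_and_grad(dn, S, logdetS, b_idx, c_idx)
        H[t] = (g_up - g_dn) / (2.0 * h[t])
    H = 0.5 * (H + H.T)
    try:
        acov = 2.0 / (N - 1) * np.linalg.inv(H)
        diag = np.clip(np.diag(acov), 0.0, None)
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        return np.full(q, np.nan)


def independence_fit(data_or_cov, N: int | None = None,
                     variables: list[str] | None = None) -> PathModelFit:
    """Closed-form fit of the independence (null) model: all variables
    uncorrelated with free variances.  F = -ln|R| with R the sample
    correlation matrix; df = p(p-1)/2."""
    if isinstance(data_or_cov, pd.DataFrame):
        cols = list(variables) if variables else list(data_or_cov.columns)
        X = data_or_cov[cols].to_numpy(dtype=float)
        N = X.shape[0]
        S = np.cov(X, rowvar=False, ddof=1)
    else:
        S = np.asarray(data_or_cov, dtype=float)
        cols = list(variables) if variables else [f"v{i}" for i in range(S.shape[0])]
        if N is None:
            raise ValueError("N is required with a covariance input")
    p = S.shape[0]
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    fmin = -float(np.linalg.slogdet(R)[1])
    fmin = max(fmin, 0.0)
    df = p * (p - 1) // 2
    T_stat = (N - 1) * fmin
    spec = PathModelSpec((), (), tuple(cols))
    return PathModelFit(
        spec=spec, n=N, weights={}, std_weights={}, se={}, std_se={},
        correlations={}, smc={}, error_variances={c: float(S[i, i])
                                                  for i, c in enumerate(cols)},
        fmin=fmin, test_statistic=T_stat, df=df,
        p_value=float(stats.chi2.sf(T_stat, df)) if df > 0 else None,
        sigma=np.diag(np.diag(S)), sample_cov=S, grad_norm=0.0, n_free=p)


# ---------------------------------------------------------------------------
# fit indices


@dataclass
class FitIndexReport:
    """Twelve conventional fit indices; ``None`` marks a not-applicable
    value (e.g. RMSEA of a saturated model)."""

    chi2: float
    df: int
    p_value: float | None
    gfi: float
    agfi: float | None
    rmsea: float | None
    nfi: float
    rfi: float | None
    ifi: float
    tli: float | None
    cfi: float
    nc: float | None
    aic: float
    caic: float
    n_free: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "chi2", "df", "p_value", "gfi", "agfi", "rmsea", "nfi", "rfi",
            "ifi", "tli", "cfi", "nc", "aic", "caic")}


def fit_indices(fit: PathModelFit, baseline: PathModelFit) -> FitIndexReport:
    """Compute the absolute/relative/parsimonious index suite.

    ``baseline`` must be the independence model on the same data (same N,
    same variables).
    """
    if baseline.n != fit.n:
        raise ValueError("baseline fitted on different N")
    chi2, df, q, N = fit.test_statistic, fit.df, fit.n_free, fit.n
    chi2_b, df_b = baseline.test_statistic, baseline.df

    sigma_inv_S = np.linalg.inv(fit.sigma) @ fit.sample_cov
    p = fit.sample_cov.shape[0]
    resid = sigma_inv_S - np.eye(p)
    gfi = 1.0 - np.trace(resid @ resid) / np.trace(sigma_inv_S @ sigma_inv_S)
    agfi = (1.0 - p * (p + 1) / (2.0 * df) * (1.0 - gfi)) if df > 0 else None
    rmsea = (float(np.sqrt(max(chi2 - df, 0.0) / (df * (N - 1))))
             if df > 0 else None)

    nfi = (chi2_b - chi2) / chi2_b if chi2_b > 0 else 1.0
    rfi = (1.0 - (chi2 / df) / (chi2_b / df_b)
           if df > 0 and df_b > 0 and chi2_b > 0 else None)
    ifi = (chi2_b - chi2) / (chi2_b - df) if chi2_b > df else 1.0
    if df > 0 and df_b > 0 and chi2_b > df_b:
        tli = ((chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1.0))
    else:
        tli = None
    num = max(chi2 - df, 0.0)
    if num < 1e-10:   # exact fit up to optimizer tolerance
        num = 0.0
    den = max(num, chi2_b - df_b, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)

    nc = chi2 / df if df > 0 else None
    aic = chi2 + 2.0 * q
    caic = chi2 + q * (np.log(N) + 1.0)
    return FitIndexReport(chi2=float(chi2), df=df, p_value=fit.p_value,
                          gfi=float(gfi),
                          agfi=None if agfi is None else float(agfi),
                          rmsea=rmsea, nfi=float(nfi),
                          rfi=None if rfi is None else float(rfi),
                          ifi=float(ifi),
                          tli=None if tli is None else float(tli),
                          cfi=float(cfi), nc=None if nc is None else float(nc),
                          aic=float(aic), caic=float(caic), n_free=q)


# ---------------------------------------------------------------------------
# multi-group fitting and model comparison


@dataclass
class MultiGroupFit:
    fits: dict[str, PathModelFit]
    pooled_statistic: float
    pooled_df: int
    pooled_p_value: float | None


def fit_multi_group(datasets: dict[str, pd.DataFrame],
                    spec: PathModelSpec) -> MultiGroupFit:
    """Simultaneous analysis of several groups with group-specific free
    parameters (no cross-group equality constraints): each group is fitted
    by ML and the pooled discrepancy is the sum of (N_g - 1) * F_g."""
    if len(datasets) < 2:
        raise ValueError("multi-group fitting needs at least two groups")
    fits = {}
    for label, df in datasets.items():
        try:
            fits[label] = fit_path_model(df, spec)
        except (DataError, ConvergenceError) as exc:
            raise type(exc)(f"group {label!r}: {exc}") from exc
    pooled = float(sum(f.test_statistic for f in fits.values()))
    pooled_df = int(sum(f.df for f in fits.values()))
    p = float(stats.chi2.sf(pooled, pooled_df)) if pooled_df > 0 else None
    return MultiGroupFit(fits=fits, pooled_statistic=pooled,
                         pooled_df=pooled_df, pooled_p_value=p)


def compare_models(fits: list[tuple[PathModelFit, FitIndexReport]],
                   close_fit_alpha: float = 0.05) -> tuple[list[int], int]:
    """Rank candidate models fitted to identical data.

    A model is *close-fitting* when its chi-square test does not reject
    (p >= ``close_fit_alpha``).  Close-fitting testable models outrank
    everything else and are ordered by AIC then CAIC (ascending); a
    saturated model (df = 0) carries no test of fit, so it can win only
    when no testable candidate fits closely.  Within the remaining models
    the order is again AIC then CAIC.  Returns (ranking as indices into
    ``fits``, selected index).
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_vals = {f.n for f, _ in fits}
    if len(n_vals) > 1:
        raise ValueError(f"fits computed on different N: {sorted(n_vals)}")

    def key(i):
        fit, rep = fits[i]
        close = fit.p_value is not None and fit.p_value >= close_fit_alpha
        return (0 if close else 1, rep.aic, rep.caic)

    ranking = sorted(range(len(fits)), key=key)
    return ranking, ranking[0]


# ---------------------------------------------------------------------------
# candidate models used by the grassland analysis


def climate_richness_productivity_spec(direct_paths: bool = True) -> PathModelSpec:
    """Candidate plot-level model: three growing-season climate covariates
    drive richness, richness drives productivity, with (optionally) direct
    climate -> productivity paths and free climate intercorrelations."""
    regs = [("daylight", "richness"), ("precipitation", "richness"),
            ("temperature", "richness"), ("richness", "productivity")]
    if direct_paths:
        regs += [("daylight", "productivity"), ("precipitation", "productivity"),
                 ("temperature", "productivity")]
    covs = [("daylight", "precipitation"), ("daylight", "temperature"),
            ("precipitation", "temperature")]
    return PathModelSpec(tuple(regs), tuple(covs))


def variability_model_specs() -> dict[str, PathModelSpec]:
    """The three competing richness-group models for productivity
    variability: richness and mean productivity both exogenous (a), richness
    upstream of productivity (b), productivity upstream of richness (c).
    ``n_plots`` is always an exogenous predictor of variability."""
    base = [("n_plots", "variability"), ("richness", "variability"),
            ("productivity", "variability")]
    return {
        "a": PathModelSpec(tuple(base),
                           (("richness", "productivity"),
                            ("n_plots", "richness"), ("n_plots", "productivity"))),
        "b": PathModelSpec(tuple(base + [("richness", "productivity")]),
                           (("n_plots", "richness"),)),
        "c": PathModelSpec(tuple(base + [("productivity", "richness")]),
                           (("n_plots", "productivity"),)),
    }


def prune_insignificant(data: pd.DataFrame, spec: PathModelSpec,
                        alpha: float = 0.05) -> tuple[PathModelSpec, PathModelFit]:
    """Backward-prune regressions whose Wald z test is not significant.

    Repeatedly drops the least significant regression (|estimate/SE| below
    the two-sided alpha critical value) and refits, until every retained
    path is significant.  Covariances are never pruned.
    """
    current = spec
    while True:
        fit = fit_path_model(data, current)
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        z = {e: abs(fit.weights[e]) / fit.se[e] if fit.se[e] > 0 else np.inf
             for e in current.regressions}
        worst = min(z, key=z.get)
        if z[worst] >= zcrit or len(current.regressions) == 1:
            return current, fit
        regs = tuple(e for e in current.regressions if e != worst)
        current = PathModelSpec(regs, current.covariances, current.variables)


def format_fit(fit: PathModelFit, indices: FitIndexReport | None = None) -> str:
    """Structured key-value text report of a fitted path model."""
    lines = [f"n\t{fit.n}", f"test_statistic\t{fit.test_statistic:.6g}",
             f"df\t{fit.df}",
             f"p_value\t{'NA' if fit.p_value is None else f'{fit.p_value:.4g}'}"]
    for (src, dst), w in fit.weights.items():
        lines.append(f"path\t{src} -> {dst}\t{w:.6g}\tstd={fit.std_weights[(src, dst)]:.6g}"
                     f"\tse={fit.se[(src, dst)]:.6g}")
    for (a, b), r in fit.correlations.items():
        lines.append(f"corr\t{a} <-> {b}\t{r:.6g}")
    for v, r2 in fit.smc.items():
        lines.append(f"smc\t{v}\t{r2:.6g}")
    if indices is not None:
        for k, v in indices.as_dict().items():
            lines.append(f"index\t{k}\t{'NA' if v is None else f'{v:.6g}'}")
    return "\n".join(lines) + "\n"
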