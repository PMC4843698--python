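"""Linear mixed-effects models by restricted maximum likelihood (REML).

Fits the hierarchical model used throughout the package: fixed effects
ln(richness) x treatment (plus optional covariate terms), independent
random effects for study, study x ln(richness), study x treatment,
study x ln(richness) x treatment, study x time (year) and plot (within
study), and residual errors correlated across years within a plot by a
first-order autoregressive (AR(1)), compound-symmetry, or independent
structure:

    y ~ N(X beta,  V),   V = sum_k sigma2_k Z_k Z_k' + sigma2_e C(rho)

where C is block-diagonal by plot with entries rho^|year_i - year_j|
(AR(1); missing years handled by the power of the lag), a constant
off-diagonal (compound symmetry), or the identity.

Every random term nests within study, so V is block-diagonal by study;
the restricted likelihood is evaluated per study block with the residual
variance profiled out, and variance ratios are optimized on the log scale
(a tanh map keeps the correlation inside its valid range). Wald tests of
the fixed effects are sequential (each term adjusted only for the terms
listed before it), with Satterthwaite denominator degrees of freedom
computed from the numerical covariance of the variance parameters and a
containment-style fallback; the method used is recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .core_data import CONTROL

DEFAULT_FIXED = ("intercept", "ln_richness", "treatment", "ln_richness:treatment")
DEFAULT_RANDOM = ("study", "study:ln_richness", "study:treatment",
                  "study:ln_richness:treatment", "study:time", "plot")
KNOWN_RANDOM = set(DEFAULT_RANDOM)
THREE_LEVEL_ORDER = ("NPK", "NH4NO3")

_LOG_LAM_LO, _LOG_LAM_HI = -14.0, 7.0
_U_BOUND = 3.8            # |tanh(3.8)| ~ 0.999
_BOUNDARY_FRAC = 1e-5     # variance ratio below this counts as boundary


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Declarative model structure.

    response: "sqrt_total_biomass" applies the square-root transform to a
    ``total_biomass`` column; any other name is used as a column directly
    (partition responses net_std / ce_std / se_std are modelled untransformed).
    """

    response: str = "sqrt_total_biomass"
    fixed_terms: tuple = DEFAULT_FIXED
    random_terms: tuple = DEFAULT_RANDOM
    residual_correlation: str = "ar1"   # "compound_symmetry" | "independent"
    treatment_coding: str = "binary"    # "three_level"
    covariate: str | None = None        # adds covariate + :ln_richness + :treatment

    def __post_init__(self):
        self.fixed_terms = tuple(self.fixed_terms)
        self.random_terms = tuple(self.random_terms)
        if "intercept" not in self.fixed_terms:
            raise ModelError("intercept must be present")
        if self.residual_correlation not in ("ar1", "compound_symmetry",
                                             "independent"):
            raise ModelError(f"unknown correlation {self.residual_correlation!r}")
        if self.residual_correlation != "independent" and \
                "plot" not in self.random_terms:
            raise ModelError("plot random term required with correlated residuals")
        unknown = set(self.random_terms) - KNOWN_RANDOM
        if unknown:
            raise ModelError(f"unknown random terms {sorted(unknown)}")
        if self.covariate:
            extra = (self.covariate, f"{self.covariate}:ln_richness",
                     f"{self.covariate}:treatment")
            self.fixed_terms = self.fixed_terms + tuple(
                t for t in extra if t not in self.fixed_terms)


@dataclass
class _Block:
    study: str
    X: np.ndarray
    y: np.ndarray
    ZZt: dict
    Z: dict
    same_plot: np.ndarray
    lag: np.ndarray
    n_plots: int


@dataclass
class Design:
    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    term_slices: dict
    blocks: list
    random_terms: tuple
    frame: pd.DataFrame
    n_obs: int = 0
    p: int = 0
    n_plots: int = 0
    n_studies: int = 0
    dropped_random: tuple = ()
    max_years_per_plot: int = 1


def _treatment_columns(df: pd.DataFrame, coding: str):
    labels = set(df["treatment"].unique())
    if coding == "binary":
        return [(df["treatment"] != CONTROL).to_numpy(float)], ["treatment"]
    if coding == "three_level":
        allowed = {CONTROL, *THREE_LEVEL_ORDER}
        bad = labels - allowed
        if bad:
            raise ModelError(f"unknown treatment label(s) {sorted(bad)} "
                             f"for three_level coding")
        cols, names = [], []
        for lab in THREE_LEVEL_ORDER:
            if lab in labels:
                cols.append((df["treatment"] == lab).to_numpy(float))
                names.append(f"treatment[{lab}]")
        return cols, names
    raise ModelError(f"unknown treatment coding {coding!r}")


def build_design(df: pd.DataFrame, spec: ModelSpec) -> Design:
    """Assemble response, fixed design and per-study random structures.

    ``df`` is a plot-year table with columns study_id, plot_id, year,
    sown_richness, treatment, plus the response source column. Rows are
    ordered by study, plot, year so residual blocks are banded by plot.
    """
    needed = ["study_id", "plot_id", "year", "sown_richness", "treatment"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ModelError(f"missing columns {missing}")
    df = df.sort_values(["study_id", "plot_id", "year"]).reset_index(drop=True)

    if spec.response == "sqrt_total_biomass":
        tot = df["total_biomass"].to_numpy(float)
        if np.any(tot < 0):
            raise ModelError("negative total biomass: square-root transform "
                             "undefined")
        y = np.sqrt(tot)
    else:
        if spec.response not in df.columns:
            raise ModelError(f"response column {spec.response!r} not found")
        y = df[spec.response].to_numpy(float)

    if (df["sown_richness"] < 1).any():
        raise ModelError("sown richness < 1: ln transform undefined")
    lnN = np.log(df["sown_richness"].to_numpy(float))
    trt_cols, trt_names = _treatment_columns(df, spec.treatment_coding)
    treated = (df["treatment"] != CONTROL).to_numpy(float)

    def factor_columns(name):
        if name == "ln_richness":
            return [lnN], ["ln_richness"]
        if name == "treatment":
            return trt_cols, trt_names
        if spec.covariate and name == spec.covariate:
            if name not in df.columns:
                raise ModelError(f"covariate column {name!r} not found")
            col = df[name]
            if col.dtype == object:
                col = (col == "long").astype(float)   # drought_class coding
            return [col.to_numpy(float)], [name]
        raise ModelError(f"unknown fixed factor {name!r}")

    cols, names, term_slices = [], [], {}
    for term in spec.fixed_terms:
        start = len(cols)
        if term == "intercept":
            cols.append(np.ones(len(df)))
            names.append("intercept")
        else:
            tcols, tnames = [np.ones(len(df))], [""]
            for factor in term.split(":"):
                fcols, fnames = factor_columns(factor)
                tcols = [a * b for a in tcols for b in fcols]
                tnames = [":".join(filter(None, [a, b]))
                          for a in tnames for b in fnames]
            cols.extend(tcols)
            names.extend(tnames)
        term_slices[term] = slice(start, len(cols))
    X = np.column_stack(cols)

    n_studies = df["study_id"].nunique()
    random_terms = tuple(spec.random_terms)
    dropped = ()
    if n_studies < 2:
        dropped = tuple(t for t in random_terms if t.startswith("study"))
        random_terms = tuple(t for t in random_terms if t not in dropped)

    blocks = []
    max_m = 1
    for study, g in df.groupby("study_id", sort=True):
        idx = g.index.to_numpy()
        yrs = g["year"].to_numpy(int)
        plots = g["plot_id"].to_numpy()
        same = plots[:, None] == plots[None, :]
        lag = np.where(same, np.abs(yrs[:, None] - yrs[None, :]), 0)
        Z, ZZt = {}, {}
        for term in random_terms:
            if term == "study":
                z = np.ones((len(g), 1))
            elif term == "study:ln_richness":
                z = lnN[idx][:, None]
            elif term == "study:treatment":
                z = treated[idx][:, None]
            elif term == "study:ln_richness:treatment":
                z = (lnN[idx] * treated[idx])[:, None]
            elif term == "study:time":
                z = (yrs[:, None] == np.unique(yrs)[None, :]).astype(float)
            elif term == "plot":
                uplots = pd.unique(plots)
                z = (plots[:, None] == uplots[None, :]).astype(float)
            Z[term] = z
            ZZt[term] = z @ z.T
        n_plots = len(pd.unique(plots))
        max_m = max(max_m, int(np.bincount(
            pd.factorize(plots)[0]).max()))
        blocks.append(_Block(study=study, X=X[idx], y=y[idx], ZZt=ZZt, Z=Z,
                             same_plot=same, lag=lag, n_plots=n_plots))

    design = Design(spec=spec, y=y, X=X, fixed_names=names,
                    term_slices=term_slices, blocks=blocks,
                    random_terms=random_terms, frame=df,
                    n_obs=len(df), p=X.shape[1],
                    n_plots=len(df[["study_id", "plot_id"]].drop_duplicates()),
                    n_studies=n_studies, dropped_random=dropped,
                    max_years_per_plot=max_m)
    if np.linalg.matrix_rank(X) < design.p:
        raise ModelError("fixed design is rank-deficient")
    return design


# ---------------------------------------------------------------------------
# restricted likelihood
# ---------------------------------------------------------------------------

def _corr_matrix(block: _Block, corr: str, rho: float) -> np.ndarray:
    if corr == "independent":
        return np.eye(len(block.y))
    if corr == "ar1":
        C = np.where(block.same_plot, np.power(rho, block.lag), 0.0)
    else:  # compound symmetry
        C = np.where(block.same_plot, rho, 0.0)
        np.fill_diagonal(C, 1.0)
    return C


def _rho_bounds(design: Design, corr: str):
    if corr == "ar1":
        return -0.999, 0.999
    m = design.max_years_per_plot
    lo = -1.0 / (m - 1) + 0.01 if m > 1 else -0.5
    return max(lo, -0.95), 0.99


def _assemble(design: Design, lam: np.ndarray, rho: float):
    """One pass over study blocks: logdet(W), X'W^-1X, X'W^-1y, y'W^-1y."""
    corr = design.spec.residual_correlation
    p = design.p
    logdet = 0.0
    XtWiX = np.zeros((p, p))
    XtWiy = np.zeros(p)
    ytWiy = 0.0
    for blk in design.blocks:
        W = _corr_matrix(blk, corr, rho)
        for lam_k, term in zip(lam, design.random_terms):
            W = W + lam_k * blk.ZZt[term]
        try:
            c, low = linalg.cho_factor(W, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet += 2.0 * np.sum(np.log(np.diag(c)))
        rhs = np.column_stack([blk.X, blk.y])
        sol = linalg.cho_solve((c, low), rhs, check_finite=False)
        XtWiX += blk.X.T @ sol[:, :p]
        XtWiy += blk.X.T @ sol[:, p]
        ytWiy += blk.y @ sol[:, p]
    return logdet, XtWiX, XtWiy, ytWiy


def _profiled_neg2(design: Design, lam: np.ndarray, rho: float):
    out = _assemble(design, lam, rho)
    if out is None:
        return np.inf, None
    logdetW, XtWiX, XtWiy, ytWiy = out
    sign, logdetX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        return np.inf, None
    beta = np.linalg.solve(XtWiX, XtWiy)
    rss = max(ytWiy - XtWiy @ beta, 1e-300)
    nmp = design.n_obs - design.p
    sig2 = rss / nmp
    val = logdetW + logdetX + nmp * (1.0 + np.log(2.0 * np.pi * sig2))
    return val, (beta, sig2, XtWiX)


def restricted_loglik(design: Design, variances: dict, sigma2_e: float,
                      rho: float = 0.0) -> float:
    """Restricted log-likelihood at explicit covariance parameter values.

    ``variances`` maps random-term names to sigma2_k. Used for direct
    comparison against dense-matrix evaluations and for likelihood probes.
    """
    lam = np.array([variances.get(t, 0.0) / sigma2_e
                    for t in design.random_terms])
    out = _assemble(design, lam, rho)
    if out is None:
        return -np.inf
    logdetW, XtWiX, XtWiy, ytWiy = out
    beta = np.linalg.solve(XtWiX, XtWiy)
    rss = ytWiy - XtWiy @ beta
    n, p = design.n_obs, design.p
    nmp = n - p
    _, logdetX = np.linalg.slogdet(XtWiX)
    # log|V| = n log s2 + log|W|; log|X'V^-1X| = -p log s2 + log|X'W^-1X|
    val = (nmp * np.log(sigma2_e) + logdetW + logdetX
           + rss / sigma2_e + nmp * np.log(2.0 * np.pi))
    return -0.5 * val


@dataclass
class FitResult:
    """REML fit: fixed effects, variance components, correlation, fit stats."""

    spec: ModelSpec
    fixed_names: list
    beta: np.ndarray
    se: np.ndarray
    df: np.ndarray                  # Satterthwaite df per coefficient
    ci_low: np.ndarray
    ci_high: np.ndarray
    cov_beta: np.ndarray
    vc: pd.DataFrame                # term, variance, se, z, boundary
    sigma2_e: float
    rho_hat: float | None
    rho_se: float | None
    reml_loglik: float
    aic: float
    n_covparams: int
    converged: bool
    n_obs: int
    n_plots: int
    n_studies: int
    df_method: str = "satterthwaite"
    design: Design = field(repr=False, default=None)
    _phi_names: list = field(repr=False, default_factory=list)
    _cov_phi: np.ndarray = field(repr=False, default=None)
    _dcov_beta: list = field(repr=False, default_factory=list)

    def fixed_table(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.fixed_names, "estimate": self.beta,
                             "se": self.se, "df": self.df,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


def _satterthwaite_df(L: np.ndarray, cov_beta: np.ndarray,
                      dcov_beta: list, cov_phi: np.ndarray) -> float:
    v = float(L @ cov_beta @ L)
    if not dcov_beta or cov_phi is None or v <= 0:
        return np.nan
    g = np.array([float(L @ d @ L) for d in dcov_beta])
    var_v = float(g @ cov_phi @ g)
    if var_v <= 0:
        return np.nan
    return 2.0 * v * v / var_v


def reml_fit(design: Design, maxiter: int = 500, n_starts: int = 3,
             compute_se: bool = True, ftol: float = 1e-11,
             gtol: float = 1e-7) -> FitResult:
    """Maximize the restricted likelihood and assemble a :class:`FitResult`.

    L-BFGS-B on (log variance ratios, transformed correlation), seeded from
    the best of three starting points (moderate / small / unit variance
    ratios), with full restarts from the remaining seeds if the first run
    fails. Variances are returned on the data scale with standard errors
    and z-ratios from the numerical curvature of the restricted likelihood
    (boundary components flagged and excluded from the curvature).
    """
    corr = design.spec.residual_correlation
    K = len(design.random_terms)
    has_rho = corr != "independent"
    rho_lo, rho_hi = _rho_bounds(design, corr)

    def unpack(theta):
        lam = np.exp(theta[:K])
        if has_rho:
            t = np.tanh(theta[K])
            rho = rho_lo + (rho_hi - rho_lo) * (t + 1.0) / 2.0 \
                if corr == "compound_symmetry" else 0.999 * t
        else:
            rho = 0.0
        return lam, rho

    def objective(theta):
        lam, rho = unpack(theta)
        return _profiled_neg2(design, lam, rho)[0]

    starts = [np.log(0.3) * np.ones(K), np.log(0.02) * np.ones(K),
              np.log(1.0) * np.ones(K)][:max(1, n_starts)]
    bounds = [(_LOG_LAM_LO, _LOG_LAM_HI)] * K
    if has_rho:
        starts = [np.append(s, 0.0) for s in starts]
        bounds = bounds + [(-_U_BOUND, _U_BOUND)]
    starts.sort(key=objective)

    best = None
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": ftol,
                                         "gtol": gtol})
        if best is None or res.fun < best.fun:
            best = res
        if best.success:
            break
    converged = bool(best.success) or np.isfinite(best.fun)
    lam, rho = unpack(best.x)
    val, aux = _profiled_neg2(design, lam, rho)
    if aux is None:
        raise ConvergenceError("restricted likelihood not computable at optimum")
    beta, sig2e, XtWiX = aux
    cov_beta = sig2e * np.linalg.inv(XtWiX)
    sigma2 = {t: lam_k * sig2e for t, lam_k in zip(design.random_terms, lam)}
    loglik = -0.5 * val
    n_covparams = K + 1 + (1 if has_rho else 0)
    aic = -2.0 * loglik + 2.0 * n_covparams

    boundary = {t: (lam_k < _BOUNDARY_FRAC) for t, lam_k in
                zip(design.random_terms, lam)}
    phi_names = [t for t in design.random_terms if not boundary[t]]
    phi_names.append("sigma2_e")
    if has_rho:
        phi_names.append("rho")

    cov_phi = None
    dcov_beta = []
    if compute_se:
        cov_phi, dcov_beta = _phi_curvature(design, sigma2, sig2e, rho,
                                            phi_names, has_rho)

    vc_rows = []
    for t in design.random_terms:
        est = sigma2[t]
        if boundary[t] or cov_phi is None:
            se_t = np.nan
        else:
            j = phi_names.index(t)
            se_t = np.sqrt(max(cov_phi[j, j], 0.0))
        vc_rows.append({"term": t, "variance": est, "se": se_t,
                        "z": est / se_t if se_t and np.isfinite(se_t) else np.nan,
                        "boundary": bool(boundary[t])})
    vc = pd.DataFrame(vc_rows, columns=["term", "variance", "se", "z",
                                        "boundary"])
    rho_se = None
    if has_rho and cov_phi is not None:
        j = phi_names.index("rho")
        rho_se = float(np.sqrt(max(cov_phi[j, j], 0.0)))

    se = np.sqrt(np.diag(cov_beta))
    dfs = np.array([_satterthwaite_df(_unit(design.p, i), cov_beta,
                                      dcov_beta, cov_phi)
                    for i in range(design.p)])
    nmp = design.n_obs - design.p
    dfs = np.where(np.isfinite(dfs), np.clip(dfs, 1.0, nmp), nmp)
    tq = stats.t.ppf(0.975, dfs)
    return FitResult(
        spec=design.spec, fixed_names=list(design.fixed_names),
        beta=beta, se=se, df=dfs, ci_low=beta - tq * se, ci_high=beta + tq * se,
        cov_beta=cov_beta, vc=vc, sigma2_e=float(sig2e),
        rho_hat=float(rho) if has_rho else None, rho_se=rho_se,
        reml_loglik=float(loglik), aic=float(aic), n_covparams=n_covparams,
        converged=converged, n_obs=design.n_obs, n_plots=design.n_plots,
        n_studies=design.n_studies,
        df_method="satterthwaite" if compute_se else "containment",
        design=design, _phi_names=phi_names, _cov_phi=cov_phi,
        _dcov_beta=dcov_beta)


def _unit(p, i):
    e = np.zeros(p)
    e[i] = 1.0
    return e


def _phi_curvature(design, sigma2, sig2e, rho, phi_names, has_rho):
    """Numeric covariance of the variance parameters and d(cov beta)/d phi."""
    rho_lo, rho_hi = _rho_bounds(design, design.spec.residual_correlation)

    def phi_vector():
        vals = []
        for name in phi_names:
            if name == "sigma2_e":
                vals.append(sig2e)
            elif name == "rho":
                vals.append(rho)
            else:
                vals.append(sigma2[name])
        return np.array(vals)

    def eval_phi(phi):
        var = dict(sigma2)
        s2e, r = sig2e, rho
        for name, v in zip(phi_names, phi):
            if name == "sigma2_e":
                s2e = v
            elif name == "rho":
                r = v
            else:
                var[name] = v
        if s2e <= 0:
            return np.inf, None
        lam = np.array([var.get(t, 0.0) / s2e for t in design.random_terms])
        lam = np.maximum(lam, 0.0)
        out = _assemble(design, lam, r)
        if out is None:
            return np.inf, None
        logdetW, XtWiX, XtWiy, ytWiy = out
        beta = np.linalg.solve(XtWiX, XtWiy)
        rss = ytWiy - XtWiy @ beta
        n, p = design.n_obs, design.p
        _, logdetX = np.linalg.slogdet(XtWiX)
        neg2 = ((n - p) * np.log(s2e) + logdetW + logdetX + rss / s2e)
        return neg2, s2e * np.linalg.inv(XtWiX)

    phi0 = phi_vector()
    m = len(phi0)
    h = np.maximum(np.abs(phi0), 1e-3 * max(sig2e, 1e-8)) * 1e-4
    for j, name in enumerate(phi_names):
        if name == "rho":
            h[j] = 1e-4
            lo_gap = phi0[j] - rho_lo
            hi_gap = rho_hi - phi0[j]
            h[j] = min(h[j], 0.4 * lo_gap, 0.4 * hi_gap) if min(
                lo_gap, hi_gap) > 0 else 1e-5

    f0, _ = eval_phi(phi0)
    fp = np.empty(m)
    fm = np.empty(m)
    dcov = []
    for j in range(m):
        e = np.zeros(m)
        e[j] = h[j]
        fpj, cp = eval_phi(phi0 + e)
        fmj, cm = eval_phi(phi0 - e)
        fp[j], fm[j] = fpj, fmj
        if cp is None or cm is None:
            dcov.append(np.zeros((design.p, design.p)))
        else:
            dcov.append((cp - cm) / (2.0 * h[j]))
    H = np.empty((m, m))
    for j in range(m):
        H[j, j] = (fp[j] - 2.0 * f0 + fm[j]) / h[j] ** 2
    for j in range(m):
        for k in range(j + 1, m):
            e = np.zeros(m)
            e[j], e[k] = h[j], h[k]
            fpp, _ = eval_phi(phi0 + e)
            e[k] = -h[k]
            fpm, _ = eval_phi(phi0 + e)
            e[j], e[k] = -h[j], h[k]
            fmp, _ = eval_phi(phi0 + e)
            e[k] = -h[k]
            fmm, _ = eval_phi(phi0 + e)
            H[j, k] = H[k, j] = (fpp - fpm - fmp + fmm) / (4.0 * h[j] * h[k])
    if not np.all(np.isfinite(H)):
        return None, dcov
    # Cov(phi) = 2 * H^-1 for H the Hessian of -2 loglik; guard non-PD
    w, Q = np.linalg.eigh(H)
    w = np.where(w > 1e-10 * max(abs(w).max(), 1.0), w, np.inf)
    cov_phi = 2.0 * (Q / w) @ Q.T
    return cov_phi, dcov


# ---------------------------------------------------------------------------
# Wald tests, model comparison, prediction
# ---------------------------------------------------------------------------

_TERM_TO_STUDY_RANDOM = {
    "intercept": "study",
    "ln_richness": "study:ln_richness",
    "treatment": "study:treatment",
    "ln_richness:treatment": "study:ln_richness:treatment",
}


def wald_sequential(fit: FitResult) -> pd.DataFrame:
    """Sequential (Type-I) Wald F tests of the fixed terms.

    Each term is tested adjusted for the terms listed before it, via the
    incremental sums of squares of the V^-1/2-whitened design. Denominator
    df by Satterthwaite (containment fallback n_obs - p); with a single
    study, terms whose study-level random interaction was dropped are
    flagged untestable.
    """
    if not fit.converged:
        raise ConvergenceError("refusing Wald tests on a non-converged fit")
    design = fit.design
    corr = design.spec.residual_correlation
    rho = fit.rho_hat if fit.rho_hat is not None else 0.0
    lam = {row["term"]: row["variance"] / fit.sigma2_e
           for _, row in fit.vc.iterrows()}

    Xw_parts, yw_parts = [], []
    for blk in design.blocks:
        V = fit.sigma2_e * _corr_matrix(blk, corr, rho)
        for term in design.random_terms:
            V = V + lam[term] * fit.sigma2_e * blk.ZZt[term]
        L = linalg.cholesky(V, lower=True, check_finite=False)
        Xw_parts.append(linalg.solve_triangular(L, blk.X, lower=True,
                                                check_finite=False))
        yw_parts.append(linalg.solve_triangular(L, blk.y, lower=True,
                                                check_finite=False))
    Xw = np.vstack(Xw_parts)
    yw = np.concatenate(yw_parts)
    Q, R = np.linalg.qr(Xw)
    t = Q.T @ yw

    nmp = design.n_obs - design.p
    rows = []
    for term in design.spec.fixed_terms:
        sl = design.term_slices[term]
        q = sl.stop - sl.start
        F = float(np.sum(t[sl] ** 2) / q)
        untestable = (design.n_studies < 2 and
                      _TERM_TO_STUDY_RANDOM.get(term) in design.dropped_random)
        if untestable:
            rows.append({"term": term, "F": F, "ndf": q, "ddf": np.nan,
                         "p": np.nan, "method": "untestable (single study)"})
            continue
        # contrast for the incremental test of this term: the matching rows
        # of R from the whitened QR; Cov(R beta_hat) = R cov_beta R' = I
        dfs = []
        for j in range(sl.start, sl.stop):
            nu = _satterthwaite_df(R[j, :], fit.cov_beta,
                                   fit._dcov_beta, fit._cov_phi)
            dfs.append(nu)
        method = "satterthwaite"
        dfs = [d for d in dfs if np.isfinite(d) and d > 2.0]
        if len(dfs) < q:
            ddf = float(nmp)
            method = "containment"
        elif q == 1:
            ddf = float(min(dfs[0], nmp))
        else:
            E = sum(d / (d - 2.0) for d in dfs)
            ddf = 2.0 * E / (E - q) if E > q else float(nmp)
            ddf = float(min(ddf, nmp))
            method = "satterthwaite"
        p = float(stats.f.sf(F, q, ddf))
        rows.append({"term": term, "F": F, "ndf": q, "ddf": ddf, "p": p,
                     "method": method})
    return pd.DataFrame(rows, columns=["term", "F", "ndf", "ddf", "p", "method"])


def compare_covariance(fit_ar1: FitResult, fit_cs: FitResult) -> dict:
    """AIC comparison of two fits of the same model on the same data.

    Lower AIC wins; an exact tie keeps the first (AR(1)) structure and is
    reported as a tie.
    """
    if fit_ar1.n_obs != fit_cs.n_obs or \
            fit_ar1.fixed_names != fit_cs.fixed_names:
        raise ModelError("covariance comparison requires identical designs")
    a, b = fit_ar1.aic, fit_cs.aic
    return {
        "structure_a": fit_ar1.spec.residual_correlation,
        "structure_b": fit_cs.spec.residual_correlation,
        "aic_a": a, "aic_b": b, "delta_aic": a - b,
        "selected": fit_ar1.spec.residual_correlation if a <= b
        else fit_cs.spec.residual_correlation,
        "tie": bool(a == b),
    }


def blups(fit: FitResult) -> pd.DataFrame:
    """Best linear unbiased predictions of the study-level random effects."""
    design = fit.design
    corr = design.spec.residual_correlation
    rho = fit.rho_hat if fit.rho_hat is not None else 0.0
    sigma2 = {row["term"]: row["variance"] for _, row in fit.vc.iterrows()}
    rows = []
    for blk in design.blocks:
        V = fit.sigma2_e * _corr_matrix(blk, corr, rho)
        for term in design.random_terms:
            V = V + sigma2[term] * blk.ZZt[term]
        r = blk.y - blk.X @ fit.beta
        Vir = np.linalg.solve(V, r)
        rec = {"study_id": blk.study}
        for term in design.random_terms:
            if term in ("plot", "study:time"):
                continue
            rec[term] = float((sigma2[term] * blk.Z[term].T @ Vir)[0])
        rows.append(rec)
    return pd.DataFrame(rows)


def fitted_lines(fit: FitResult, richness_grid, level: str = "pooled",
                 treatments=(0, 1)) -> pd.DataFrame:
    """Predicted response over a richness x treatment grid.

    Pooled lines use the fixed effects only; per-study lines add the
    study-level BLUPs. Predictions are returned on the model
    (square-root) scale and back-transformed (squared) when the response
    is sqrt_total_biomass.
    """
    if not fit.converged:
        raise ConvergenceError("refusing predictions from a non-converged fit")
    grid = [float(n) for n in richness_grid]
    if any(n < 1 for n in grid):
        raise ModelError("grid richness must be >= 1")
    design = fit.design
    name_idx = {nm: i for i, nm in enumerate(fit.fixed_names)}
    sq = design.spec.response == "sqrt_total_biomass"
    study_blups = blups(fit) if level == "per_study" else None

    rows = []
    for n in grid:
        lnN = np.log(n)
        for trt in treatments:
            x = np.zeros(design.p)
            x[name_idx["intercept"]] = 1.0
            if "ln_richness" in name_idx:
                x[name_idx["ln_richness"]] = lnN
            if "treatment" in name_idx:
                x[name_idx["treatment"]] = float(trt)
                if "ln_richness:treatment" in name_idx:
                    x[name_idx["ln_richness:treatment"]] = lnN * trt
            eta = float(x @ fit.beta)
            se = float(np.sqrt(x @ fit.cov_beta @ x))
            if level == "pooled":
                rows.append({"study_id": "pooled", "richness": n,
                             "treatment": trt, "eta": eta, "se": se,
                             "response": eta ** 2 if sq else eta})
            else:
                for _, srow in study_blups.iterrows():
                    e = eta
                    e += srow.get("study", 0.0)
                    e += srow.get("study:ln_richness", 0.0) * lnN
                    e += srow.get("study:treatment", 0.0) * trt
                    e += srow.get("study:ln_richness:treatment", 0.0) * lnN * trt
                    rows.append({"study_id": srow["study_id"], "richness": n,
                                 "treatment": trt, "eta": e, "se": np.nan,
                                 "response": e ** 2 if sq else e})
    return pd.DataFrame(rows)
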