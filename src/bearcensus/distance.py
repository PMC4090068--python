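"""Line-transect distance sampling: detection functions, AICc model
averaging, goodness of fit, stratified abundance, and the double-observer
g(0) pre-check.

The estimation chain mirrors conventional (CDS) and multiple-covariate
(MCDS) distance sampling.  Perpendicular distances x on [0, w] follow
f(x) = g(x)/mu, where g is the detection function (g(0) = 1) and
mu = integral of g over [0, w] is the effective strip width (ESW).  Group
density is the Horvitz–Thompson ratio n / (2 mu L); abundance multiplies by
stratum area and mean group size.  The survey CV combines encounter-rate,
detection and group-size components by the delta method.  Competing
detection models (uniform+cosine, half-normal, hazard-rate, covariate
scale models) are ranked by AICc and combined by Akaike weights with
unconditional variance.

A preliminary Huggins-type double-observer analysis (front vs rear
platform, conditional likelihood) checks the CDS assumption of perfect
detection on the line before the single-platform analysis is trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.special import erf
from scipy.stats import cramervonmises, chi2 as chi2_dist, kstest, norm

__all__ = [
    "VIS_LEVELS",
    "LIGHT_LEVELS",
    "ConvergenceError",
    "DetectionModelSpec",
    "DetectionFit",
    "GofResult",
    "AbundanceEstimate",
    "ModelAverage",
    "HugginsFit",
    "half_normal_esw",
    "fit_detection",
    "aicc",
    "akaike_weights",
    "goodness_of_fit",
    "estimate_abundance",
    "model_average",
    "fit_huggins_double_observer",
    "check_perfect_detection",
    "lognormal_interval",
]

VIS_LEVELS = ("poor/fair", "excellent")
LIGHT_LEVELS = ("overcast", "mostly cloudy", "partly cloudy/clear")
_COVARIATE_LEVELS = {"vis": VIS_LEVELS, "light": LIGHT_LEVELS}

Z95 = float(norm.ppf(0.975))


class ConvergenceError(RuntimeError):
    """Detection-function optimisation failed; carries diagnostics."""


def half_normal_esw(sigma_m: float | np.ndarray, w_m: float) -> float | np.ndarray:
    """Closed-form ESW of a half-normal detection function truncated at w."""
    sigma_m = np.asarray(sigma_m, float)
    return sigma_m * np.sqrt(np.pi / 2) * erf(w_m / (sigma_m * np.sqrt(2)))


def lognormal_interval(est: float, cv: float, z: float = Z95) -> tuple[float, float]:
    """Lognormal interval (est/C, est*C) with C = exp(z*sqrt(ln(1+cv^2)))."""
    if est <= 0 or not np.isfinite(cv) or cv <= 0:
        return (est, est)
    c = np.exp(z * np.sqrt(np.log1p(cv**2)))
    return (est / c, est * c)


@dataclass(frozen=True)
class DetectionModelSpec:
    """A candidate detection-function model.

    key: "uniform", "half-normal" or "hazard-rate"; cosine adjustment
    orders apply to the uniform key; covariates ("vis", "light") enter as
    log-linear terms on the scale of the half-normal/hazard-rate keys.
    ``truncation_m=None`` means the largest observed distance.
    """

    key: str = "half-normal"
    cosine_orders: tuple[int, ...] = ()
    covariates: tuple[str, ...] = ()
    truncation_m: float | None = None

    def __post_init__(self) -> None:
        if self.key not in ("uniform", "half-normal", "hazard-rate"):
            raise ValueError(f"unknown key function {self.key!r}")
        if self.covariates and self.key == "uniform":
            raise ValueError("covariates require a scale key (half-normal or hazard-rate)")
        for c in self.covariates:
            if c not in _COVARIATE_LEVELS:
                raise ValueError(f"unknown covariate {c!r}; expected subset of {tuple(_COVARIATE_LEVELS)}")
        if self.cosine_orders and self.key != "uniform":
            raise ValueError("cosine adjustments are implemented for the uniform key")
        if self.truncation_m is not None and self.truncation_m <= 0:
            raise ValueError("truncation must be positive")

    @property
    def label(self) -> str:
        parts = [self.key]
        if self.cosine_orders:
            parts.append("cos" + "".join(str(j) for j in self.cosine_orders))
        parts.extend(self.covariates)
        return "/".join(parts)


def _design_matrix(spec: DetectionModelSpec, obs: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(obs))]
    for cov in spec.covariates:
        levels = _COVARIATE_LEVELS[cov]
        vals = obs[cov].astype(str)
        bad = set(vals) - set(levels)
        if bad:
            raise ValueError(f"invalid {cov} categories {sorted(bad)}; allowed: {levels}")
        for lev in levels[1:]:
            cols.append((vals == lev).to_numpy(float))
    return np.column_stack(cols)


class _Likelihood:
    """Conditional likelihood of distances for one model spec."""

    def __init__(self, spec: DetectionModelSpec, x: np.ndarray, w: float, design: np.ndarray):
        self.spec = spec
        self.x = x
        self.w = w
        self.X = design
        self.n_beta = design.shape[1]
        if spec.key == "uniform":
            self.k = len(spec.cosine_orders)
        elif spec.key == "half-normal":
            self.k = self.n_beta
        else:  # hazard-rate: scale betas + shape
            self.k = self.n_beta + 1

    # -- uniform + cosine -------------------------------------------------
    def _series(self, x: np.ndarray, a: np.ndarray) -> np.ndarray:
        h = np.ones_like(x)
        for aj, j in zip(a, self.spec.cosine_orders):
            h = h + aj * np.cos(j * np.pi * x / self.w)
        return h

    def _series_integral(self, a: np.ndarray) -> float:
        grid = np.linspace(0.0, self.w, 4097)
        h = np.clip(self._series(grid, a), 0.0, None)
        return float(np.trapezoid(h, grid))

    # -- scale keys -------------------------------------------------------
    def _sigma(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(self.X @ theta[: self.n_beta])

    def _hr_esw(self, sigma: float, b: float) -> float:
        def g(t):
            if t <= 0:
                return 1.0
            return 1.0 - np.exp(-((t / sigma) ** (-b)))

        val, _ = integrate.quad(g, 0.0, self.w, epsrel=1e-6, limit=200)
        return val

    def esw_per_obs(self, theta: np.ndarray) -> np.ndarray:
        """ESW for each observation's covariate level."""
        if self.spec.key == "uniform":
            a = theta
            h0 = float(self._series(np.zeros(1), a)[0])
            if h0 <= 0:
                return np.full(len(self.x), np.nan)
            return np.full(len(self.x), self._series_integral(a) / h0)
        sigma = self._sigma(theta)
        if self.spec.key == "half-normal":
            return half_normal_esw(sigma, self.w)
        b = 1.0 + np.exp(theta[-1])
        uniq, inv = np.unique(sigma, return_inverse=True)
        mus = np.array([self._hr_esw(s, b) for s in uniq])
        return mus[inv]

    def g(self, x: np.ndarray, theta: np.ndarray, row: int = 0) -> np.ndarray:
        """Detection probability at distances x (covariates of ``row``)."""
        x = np.asarray(x, float)
        if self.spec.key == "uniform":
            h = np.clip(self._series(x, theta), 0.0, None)
            h0 = float(self._series(np.zeros(1), theta)[0])
            return h / h0
        sigma = float(np.exp(self.X[row] @ theta[: self.n_beta]))
        if self.spec.key == "half-normal":
            return np.exp(-(x**2) / (2 * sigma**2))
        b = 1.0 + np.exp(theta[-1])
        with np.errstate(divide="ignore", over="ignore"):
            return 1.0 - np.exp(-np.where(x > 0, (x / sigma) ** (-b), np.inf))

    def nll(self, theta: np.ndarray) -> float:
        if self.spec.key == "uniform":
            h = self._series(self.x, theta)
            if np.any(h <= 0):
                return 1e10
            total = self._series_integral(theta)
            if total <= 0:
                return 1e10
            return float(-(np.sum(np.log(h)) - len(self.x) * np.log(total)))
        sigma = self._sigma(theta)
        if self.spec.key == "half-normal":
            mu = half_normal_esw(sigma, self.w)
            return float(np.sum(self.x**2 / (2 * sigma**2) + np.log(mu)))
        b = 1.0 + np.exp(theta[-1])
        if b > 50 or np.any(sigma > 100 * self.w) or np.any(sigma < 1e-3):
            return 1e10
        uniq, inv = np.unique(sigma, return_inverse=True)
        mus = np.array([self._hr_esw(s, b) for s in uniq])
        gx = np.clip(self.g_all(theta), 1e-300, None)
        return float(-(np.sum(np.log(gx)) - np.sum(np.log(mus[inv]))))

    def g_all(self, theta: np.ndarray) -> np.ndarray:
        """g at each observed distance under its own covariates."""
        if self.spec.key == "uniform":
            h = np.clip(self._series(self.x, theta), 0.0, None)
            h0 = float(self._series(np.zeros(1), theta)[0])
            return h / h0
        sigma = self._sigma(theta)
        if self.spec.key == "half-normal":
            return np.exp(-(self.x**2) / (2 * sigma**2))
        b = 1.0 + np.exp(theta[-1])
        with np.errstate(divide="ignore", over="ignore"):
            return 1.0 - np.exp(-np.where(self.x > 0, (self.x / sigma) ** (-b), np.inf))

    def cdf_per_obs(self, q: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """F_i(q_i) = integral_0^{q_i} g_i / mu_i, per observation."""
        q = np.asarray(q, float)
        if self.spec.key == "half-normal":
            sigma = self._sigma(theta)
            num = sigma * np.sqrt(np.pi / 2) * erf(q / (sigma * np.sqrt(2)))
            return num / half_normal_esw(sigma, self.w)
        if self.spec.key == "uniform":
            grid = np.linspace(0.0, self.w, 4097)
            h = np.clip(self._series(grid, theta), 0.0, None)
            ch = integrate.cumulative_trapezoid(h, grid, initial=0.0)
            return np.interp(q, grid, ch) / ch[-1]
        # hazard-rate: numeric per unique sigma
        sigma = self._sigma(theta)
        b = 1.0 + np.exp(theta[-1])
        out = np.empty(len(q))
        for s in np.unique(sigma):
            sel = sigma == s
            grid = np.linspace(0.0, self.w, 4097)
            with np.errstate(divide="ignore", over="ignore"):
                h = 1.0 - np.exp(-np.where(grid > 0, (grid / s) ** (-b), np.inf))
            ch = integrate.cumulative_trapezoid(h, grid, initial=0.0)
            out[sel] = np.interp(q[sel], grid, ch) / ch[-1]
        return out


@dataclass
class DetectionFit:
    """A fitted (or fixed-parameter) detection function."""

    spec: DetectionModelSpec
    params: np.ndarray
    esw_m: float               # effective strip width (harmonic mean under covariates)
    esw_se_m: float
    p: float                   # mu / w
    p_se: float
    log_likelihood: float
    k: int                     # number of estimated parameters
    n: int
    aicc: float
    truncation_m: float
    estimated: bool = True     # False when parameters were fixed, not fitted
    _lik: _Likelihood | None = field(default=None, repr=False)
    _x: np.ndarray | None = field(default=None, repr=False)

    @property
    def esw_cv(self) -> float:
        return self.esw_se_m / self.esw_m if self.esw_m > 0 else np.nan

    def g(self, x, row: int = 0) -> np.ndarray:
        return self._lik.g(np.asarray(x, float), self.params, row)

    def pdf(self, x, row: int = 0) -> np.ndarray:
        mus = self._lik.esw_per_obs(self.params)
        mu = mus[row] if len(mus) else self.esw_m
        return self.g(x, row) / mu

    def cdf_transform(self) -> np.ndarray:
        """u_i = F_i(x_i): fitted probability-integral transform of the data."""
        return self._lik.cdf_per_obs(self._x, self.params)

    def cdf(self, x) -> np.ndarray:
        """CDF of perpendicular distance (first observation's covariates)."""
        lik = self._lik
        q = np.atleast_1d(np.asarray(x, float))
        full = _Likelihood(self.spec, q, self.truncation_m, np.repeat(lik.X[:1], len(q), axis=0))
        return full.cdf_per_obs(q, self.params)

    @classmethod
    def from_params(
        cls,
        spec: DetectionModelSpec,
        params: np.ndarray,
        observations: pd.DataFrame,
        truncation_m: float | None = None,
    ) -> "DetectionFit":
        """Build a fit object from known parameters (no estimation).

        Used for calibration studies and misspecification checks: K counts
        as 0 for goodness-of-fit degrees of freedom.
        """
        w = float(truncation_m if truncation_m is not None else spec.truncation_m
                  if spec.truncation_m is not None else observations["perp_distance_m"].max())
        obs = observations[observations["perp_distance_m"] <= w].reset_index(drop=True)
        x = obs["perp_distance_m"].to_numpy(float)
        design = _design_matrix(spec, obs)
        lik = _Likelihood(spec, x, w, design)
        params = np.asarray(params, float)
        mus = lik.esw_per_obs(params)
        mu_eff = len(x) / np.sum(1.0 / mus) if len(x) else float(np.mean(mus))
        ll = -lik.nll(params)
        return cls(
            spec=spec, params=params, esw_m=float(mu_eff), esw_se_m=0.0,
            p=float(mu_eff / w), p_se=0.0, log_likelihood=float(ll), k=0,
            n=len(x), aicc=np.nan, truncation_m=w, estimated=False,
            _lik=lik, _x=x,
        )


def _numeric_hessian(fun, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    hess = np.empty((n, n))
    f0 = fun(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                val = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / h[i] ** 2
            else:
                val = (
                    fun(theta + ei + ej) - fun(theta + ei - ej)
                    - fun(theta - ei + ej) + fun(theta - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def fit_detection(observations: pd.DataFrame, spec: DetectionModelSpec) -> DetectionFit:
    """Fit a detection function by maximum conditional likelihood.

    Distances beyond the truncation are dropped.  The likelihood is
    f(x_i) = g(x_i)/mu_i with covariates entering log-linearly on the scale
    parameter.  ESW uncertainty comes from the inverse observed information
    and the delta method; under covariates the reported ESW is the
    Horvitz–Thompson-consistent harmonic mean of per-observation ESWs.
    """
    w = float(spec.truncation_m if spec.truncation_m is not None
              else observations["perp_distance_m"].max())
    obs = observations[observations["perp_distance_m"] <= w].reset_index(drop=True)
    n = len(obs)
    if n < 10:
        raise ValueError(f"only {n} observations within truncation; need >= 10")
    if n < 20:
        warnings.warn(f"only {n} observations within truncation; estimates will be unstable", stacklevel=2)
    x = obs["perp_distance_m"].to_numpy(float)
    design = _design_matrix(spec, obs)
    lik = _Likelihood(spec, x, w, design)

    if lik.k == 0:  # uniform key, no adjustments: g = 1 exactly
        fit = DetectionFit(
            spec=spec, params=np.empty(0), esw_m=w, esw_se_m=0.0, p=1.0,
            p_se=0.0, log_likelihood=-n * np.log(w), k=0, n=n,
            aicc=aicc(-n * np.log(w), 0, n), truncation_m=w, _lik=lik, _x=x,
        )
        return fit

    sigma0 = max(np.sqrt(np.mean(x**2)), 1e-3)
    if spec.key == "uniform":
        theta0 = np.zeros(lik.k)
    elif spec.key == "half-normal":
        theta0 = np.r_[np.log(sigma0), np.zeros(lik.n_beta - 1)]
    else:
        theta0 = np.r_[np.log(0.7 * sigma0), np.zeros(lik.n_beta - 1), 0.0]

    res = optimize.minimize(lik.nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    if not res.success or not np.isfinite(res.fun) or res.fun >= 1e9:
        raise ConvergenceError(
            f"detection fit failed for {spec.label}: {res.message} "
            f"(n={n}, w={w:.0f} m, start={theta0})"
        )
    theta = res.x
    ll = -res.fun

    mus = lik.esw_per_obs(theta)
    mu_eff = n / np.sum(1.0 / mus)

    # delta-method SE of the effective ESW
    def mu_of(t):
        m = lik.esw_per_obs(t)
        return len(x) / np.sum(1.0 / m)

    se_mu = np.nan
    try:
        hess = _numeric_hessian(lik.nll, theta)
        cov = np.linalg.inv(hess)
        h = 1e-4 * np.maximum(np.abs(theta), 1.0)
        grad = np.array([
            (mu_of(theta + np.eye(len(theta))[i] * h[i]) - mu_of(theta - np.eye(len(theta))[i] * h[i]))
            / (2 * h[i]) for i in range(len(theta))
        ])
        v = float(grad @ cov @ grad)
        se_mu = np.sqrt(v) if v > 0 else np.nan
    except np.linalg.LinAlgError:
        warnings.warn(f"singular information matrix for {spec.label}; ESW SE unavailable", stacklevel=2)

    if spec.key == "uniform" and np.any(lik._series(np.linspace(0, w, 512), theta) < 0):
        warnings.warn("adjusted detection function went negative and was clipped", stacklevel=2)

    return DetectionFit(
        spec=spec, params=theta, esw_m=float(mu_eff),
        esw_se_m=float(se_mu), p=float(mu_eff / w),
        p_se=float(se_mu / w) if np.isfinite(se_mu) else np.nan,
        log_likelihood=float(ll), k=lik.k, n=n,
        aicc=aicc(ll, lik.k, n), truncation_m=w, _lik=lik, _x=x,
    )


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2K + 2K(K+1)/(n-K-1) (small-sample correction)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values, cutoff: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Delta-AICc and Akaike weights, restricted to models under the cutoff.

    Models at or beyond the cutoff receive weight 0; weights of the
    retained set are normalised to sum to 1.
    """
    a = np.asarray(aicc_values, float)
    delta = a - a.min()
    keep = delta < cutoff
    raw = np.where(keep, np.exp(-delta / 2.0), 0.0)
    return delta, raw / raw.sum()


@dataclass
class GofResult:
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    ks_stat: float
    ks_p: float
    cvm_stat: float
    cvm_p: float


def goodness_of_fit(fit: DetectionFit, n_bins: int = 8) -> GofResult:
    """Chi-squared, Kolmogorov–Smirnov and Cramér–von Mises fit checks.

    All three act on the fitted probability-integral transform
    u_i = F_i(x_i) (exactly uniform on [0,1] under the model, including
    covariate models).  Chi-squared uses equal-width u bins merged until
    every expected count is >= 5; its degrees of freedom are reduced by K
    only when the parameters were estimated from these data.
    """
    u = np.clip(fit.cdf_transform(), 0.0, 1.0)
    n = len(u)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(u, edges)
    # merge adjacent bins (right to left) until expected >= 5
    widths = np.diff(edges)
    while len(counts) > 1 and (n * widths).min() < 5.0:
        i = int(np.argmin(n * widths))
        j = i + 1 if i + 1 < len(counts) else i - 1
        lo, hi = sorted((i, j))
        counts = np.r_[counts[:lo], counts[lo] + counts[hi], counts[hi + 1:]]
        widths = np.r_[widths[:lo], widths[lo] + widths[hi], widths[hi + 1:]]
    expected = n * widths
    k_red = fit.k if fit.estimated else 0
    df = len(counts) - 1 - k_red
    if len(counts) < 2 or df < 1:
        warnings.warn("too few usable bins for the chi-squared check; omitted", stacklevel=2)
        chi2_stat, chi2_p, df = np.nan, np.nan, max(df, 0)
    else:
        chi2_stat = float(np.sum((counts - expected) ** 2 / expected))
        chi2_p = float(chi2_dist.sf(chi2_stat, df))

    ks = kstest(u, "uniform")
    cvm = cramervonmises(u, "uniform")
    return GofResult(
        chi2_stat=chi2_stat, chi2_df=int(df), chi2_p=chi2_p,
        ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
        cvm_stat=float(cvm.statistic), cvm_p=float(cvm.pvalue),
    )


@dataclass
class AbundanceEstimate:
    """Stratum abundance from a fitted detection function."""

    stratum: str
    n_groups: int
    effort_km: float
    area_km2: float
    group_density_per_km2: float
    mean_group_size: float
    n_hat: float               # independent individuals
    se: float
    cv: float
    ci_low: float
    ci_high: float
    cv_components: dict = field(default_factory=dict)


def estimate_abundance(
    fit: DetectionFit,
    observations: pd.DataFrame,
    transects: pd.DataFrame,
    stratum: str,
    area_km2: float,
    allow_single_transect: bool = False,
) -> AbundanceEstimate:
    """Horvitz–Thompson abundance for one stratum.

    Group density D = n / (2 mu L) with the pooled-detection ESW mu;
    N = D * A * mean group size (independent individuals).  The CV combines
    encounter-rate (length-weighted between-transect replication),
    detection and group-size components:
    CV(N)^2 = CV(n/L)^2 + CV(mu)^2 + CV(s)^2.
    """
    w = fit.truncation_m
    tr = transects[transects["stratum"] == stratum]
    if tr.empty:
        raise ValueError(f"no transects in stratum {stratum!r}")
    obs = observations[
        (observations["stratum"] == stratum) & (observations["perp_distance_m"] <= w)
    ]
    length_km = float(tr["length_km"].sum())
    n = len(obs)
    mu_km = fit.esw_m / 1000.0

    if n == 0:
        return AbundanceEstimate(
            stratum=stratum, n_groups=0, effort_km=length_km, area_km2=area_km2,
            group_density_per_km2=0.0, mean_group_size=np.nan, n_hat=0.0,
            se=np.nan, cv=np.nan, ci_low=0.0, ci_high=0.0,
            cv_components={"empty_stratum": True},
        )

    k = len(tr)
    if k < 2 and not allow_single_transect:
        raise ValueError(
            "encounter-rate variance needs >= 2 transects; "
            "pass allow_single_transect=True to force a point estimate"
        )

    sizes = obs["group_size"].to_numpy(float)
    sbar = float(sizes.mean())
    density_groups = n / (2.0 * mu_km * length_km)
    n_hat = density_groups * area_km2 * sbar

    # encounter-rate CV: length-weighted between-transect (replicate lines)
    er = n / length_km
    per = obs.groupby("transect_id").size()
    cv_er2 = 0.0
    if k >= 2:
        li = tr["length_km"].to_numpy(float)
        ni = np.array([per.get(t, 0) for t in tr["transect_id"]], float)
        var_er = k / (length_km**2 * (k - 1)) * np.sum(li**2 * (ni / li - er) ** 2)
        cv_er2 = var_er / er**2 if er > 0 else 0.0
    cv_mu2 = fit.esw_cv**2 if np.isfinite(fit.esw_cv) else 0.0
    cv_s2 = (sizes.std(ddof=1) / np.sqrt(n) / sbar) ** 2 if n > 1 and sbar > 0 else 0.0

    cv = float(np.sqrt(cv_er2 + cv_mu2 + cv_s2))
    se = cv * n_hat
    lo, hi = lognormal_interval(n_hat, cv)
    return AbundanceEstimate(
        stratum=stratum, n_groups=n, effort_km=length_km, area_km2=area_km2,
        group_density_per_km2=float(density_groups), mean_group_size=sbar,
        n_hat=float(n_hat), se=float(se), cv=cv, ci_low=lo, ci_high=hi,
        cv_components={"cv_encounter": float(np.sqrt(cv_er2)),
                       "cv_detection": float(np.sqrt(cv_mu2)),
                       "cv_group_size": float(np.sqrt(cv_s2))},
    )


@dataclass
class ModelAverage:
    """AICc-weighted abundance with unconditional variance."""

    members: pd.DataFrame      # label, aicc, delta, weight, n_hat, se
    n_bar: float
    se_unconditional: float
    cv: float
    ci_low: float
    ci_high: float


def model_average(
    estimates: list[AbundanceEstimate] | list[float],
    aicc_values: list[float],
    ses: list[float] | None = None,
    labels: list[str] | None = None,
    cutoff: float = 3.0,
) -> ModelAverage:
    """Average abundance over competing models by Akaike weight.

    N̄ = Σ w_i N_i; unconditional SE = Σ w_i sqrt(var_i + (N_i - N̄)^2)
    (between-model spread added to within-model variance); lognormal CI on
    N̄ from CV = SE_u / N̄.  Only models with ΔAICc < cutoff participate.
    """
    if len(estimates) == 0:
        raise ValueError("no member models to average")
    if isinstance(estimates[0], AbundanceEstimate):
        n_vals = np.array([e.n_hat for e in estimates])
        se_vals = np.array([e.se for e in estimates])
    else:
        n_vals = np.asarray(estimates, float)
        se_vals = np.asarray(ses, float)
    delta, w = akaike_weights(aicc_values, cutoff)
    if w.sum() == 0:
        raise ValueError("no models under the delta-AICc cutoff")
    n_bar = float(w @ n_vals)
    se_u = float(w @ np.sqrt(se_vals**2 + (n_vals - n_bar) ** 2))
    cv = se_u / n_bar
    lo, hi = lognormal_interval(n_bar, cv)
    members = pd.DataFrame(
        {
            "label": labels if labels is not None else [f"model{i+1}" for i in range(len(n_vals))],
            "aicc": np.asarray(aicc_values, float),
            "delta_aicc": delta,
            "weight": w,
            "n_hat": n_vals,
            "se": se_vals,
        }
    )
    return ModelAverage(members=members, n_bar=n_bar, se_unconditional=se_u,
                        cv=float(cv), ci_low=lo, ci_high=hi)


@dataclass
class HugginsFit:
    """Conditional double-observer detection estimates."""

    n_front: int
    n_rear: int
    m_both: int
    p_front: float
    p_rear: float
    p_front_se: float
    p_rear_se: float
    p0: float                  # pooled detection at the line, 1-(1-pf)(1-pr)
    p0_se: float

    @property
    def p0_ci(self) -> tuple[float, float]:
        lo = max(self.p0 - Z95 * self.p0_se, 0.0)
        hi = min(self.p0 + Z95 * self.p0_se, 1.0)
        return lo, hi


def fit_huggins_double_observer(records: pd.DataFrame) -> HugginsFit:
    """Huggins-type conditional MLEs from front/rear detection flags.

    For detected groups (seen by at least one platform) with boolean
    columns ``seen_front``/``seen_rear``: p_front = m / n_rear and
    p_rear = m / n_front, where m counts duplicates.  Pooled detection at
    distance zero is 1 - (1-p_front)(1-p_rear) with a delta-method SE
    (platform covariance ignored).
    """
    f = records["seen_front"].to_numpy(bool)
    r = records["seen_rear"].to_numpy(bool)
    if np.any(~f & ~r):
        raise ValueError("records must be conditional on detection by >= 1 platform")
    n_front, n_rear, m = int(f.sum()), int(r.sum()), int((f & r).sum())
    if m == 0:
        raise ValueError("zero duplicate detections: platform detection unidentifiable")
    pf, pr = m / n_rear, m / n_front
    se_f = np.sqrt(pf * (1 - pf) / n_rear)
    se_r = np.sqrt(pr * (1 - pr) / n_front)
    p0 = 1.0 - (1.0 - pf) * (1.0 - pr)
    var_p0 = (1 - pr) ** 2 * se_f**2 + (1 - pf) ** 2 * se_r**2
    return HugginsFit(
        n_front=n_front, n_rear=n_rear, m_both=m,
        p_front=float(pf), p_rear=float(pr),
        p_front_se=float(se_f), p_rear_se=float(se_r),
        p0=float(p0), p0_se=float(np.sqrt(var_p0)),
    )


@dataclass
class PerfectDetectionDecision:
    cds_permissible: bool
    p0: float
    inflation_factor: float
    message: str


def check_perfect_detection(fit: HugginsFit, threshold: float = 0.95) -> PerfectDetectionDecision:
    """Decide whether conventional distance sampling (g(0)=1) is tenable.

    CDS is permissible when the pooled detection-at-line point estimate
    meets the threshold or its 95% CI includes 1; otherwise densities
    should be inflated by 1/p(0).
    """
    lo, hi = fit.p0_ci
    ok = fit.p0 >= threshold or hi >= 1.0
    if ok:
        msg = (f"CDS permissible: pooled p(0) = {fit.p0:.4f} "
               f"(95% CI {lo:.4f}-{hi:.4f}), threshold {threshold}")
        factor = 1.0
    else:
        factor = 1.0 / fit.p0
        msg = (f"detection at the line imperfect: pooled p(0) = {fit.p0:.4f} "
               f"(95% CI {lo:.4f}-{hi:.4f}); inflate density by {factor:.4f}")
    return PerfectDetectionDecision(cds_permissible=ok, p0=fit.p0,
                                    inflation_factor=factor, message=msg)
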