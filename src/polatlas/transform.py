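"""Count filtering, pooled size factors, regularized NB Pearson residuals.

Counts at 1-kb standardized bound regions behave like single-cell RNA-seq
data: many samples, low counts, many zeroes. The transform therefore follows
the scRNA-seq playbook. Size factors come from a pooling-and-deconvolution
scheme restricted to the most "detectable" regions (median-of-ratios-style
estimators break down with the zero fraction seen here). Each region then
gets a negative-binomial intercept model ln(mu) = beta0 + ln(s) with
variance mu + alpha mu^2; the per-region overdispersion alpha is regularized
through a 20-bin mean-quantile trend (modal alpha per bin by KDE, linear
interpolation between bin centers). Pearson residuals
(x - mu) / sqrt(mu + alpha mu^2) are clipped symmetrically at
c = sqrt(9 + n/4), which loosens the small-n bound without changing large-n
behavior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Filtering and detectability
# ---------------------------------------------------------------------------

def filter_low_counts(counts: pd.DataFrame, min_reads: int = 1,
                      min_samples: int = 3) -> pd.DataFrame:
    """Keep regions with >= ``min_reads`` in at least ``min_samples`` samples."""
    detected = (counts >= min_reads).sum(axis=1)
    return counts.loc[detected >= min_samples]


def detectability_rank(counts: pd.DataFrame, top_frac: float = 0.05):
    """Order regions by detectability; return (ordering, top slice).

    Primary key: number of samples with >= 1 read; ties broken successively
    by the number of samples with >= 2, 3, 4, 5 reads; remaining ties break
    by region id so the ordering is deterministic. The top ``ceil(top_frac *
    n_regions)`` regions are returned as the pooling subset.
    """
    X = counts.to_numpy()
    order_df = pd.DataFrame(
        {f"d{t}": (X >= t).sum(axis=1) for t in range(1, 6)},
        index=counts.index)
    order_df["_id"] = counts.index
    ordering = order_df.sort_values(
        by=[f"d{t}" for t in range(1, 6)] + ["_id"],
        ascending=[False] * 5 + [True], kind="stable").index
    n_top = int(np.ceil(top_frac * len(counts)))
    return ordering, ordering[:n_top]


# ---------------------------------------------------------------------------
# Pooled size factors
# ---------------------------------------------------------------------------

def pooling_size_factors(counts: pd.DataFrame, pool_sizes=(11, 21, 31),
                         ridge_weight: float = 0.01) -> pd.Series:
    """Per-sample size factors by ring pooling and least-squares deconvolution.

    Samples are ordered by library size and arranged on a ring; for each pool
    size, every window of consecutive samples forms a pooled pseudo-sample
    whose scale relative to the average profile is a robust (median) ratio.
    The resulting linear system (one equation per pool, low-weight anchor
    equations tying each factor to its library size) is solved by least
    squares; factors are rescaled to mean 1. Non-positive solutions trigger a
    median-of-ratios fallback with a warning.

    ``counts`` should already be restricted to the detectability-top subset.
    """
    n = counts.shape[1]
    if n < 8:
        raise ValueError("need at least 8 samples for pooled size factors")
    sizes = [s for s in pool_sizes if s <= n] or [max(3, (n // 2) | 1)]
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with zero total count")
    order = np.argsort(lib, kind="stable")  # ring ordered by library size
    ref = X.mean(axis=1)
    ok = ref > 0

    rows, rhs = [], []
    for size in sizes:
        for start in range(n):
            pool = order[(start + np.arange(size)) % n]
            pooled = X[:, pool].sum(axis=1)
            theta = np.median(pooled[ok] / (ref[ok] * size))
            row = np.zeros(n)
            row[pool] = 1.0 / size
            rows.append(row)
            rhs.append(theta)
    # anchor equations keep the system full rank
    lib_norm = lib / lib.mean()
    for i in range(n):
        row = np.zeros(n)
        row[i] = ridge_weight
        rows.append(row)
        rhs.append(ridge_weight * lib_norm[i])
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    if np.any(sol <= 0):
        warnings.warn("non-positive deconvolved size factor; falling back to "
                      "median-of-ratios on the subset")
        logger.warning("size-factor fallback to median-of-ratios")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = X[ok] / ref[ok, None]
        sol = np.median(ratios, axis=0)
    sol = sol / sol.mean()
    return pd.Series(sol, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Regularized NB model
# ---------------------------------------------------------------------------

@dataclass
class NBModel:
    """Fitted regularized negative-binomial model for a count matrix.

    mu : regions x samples fitted means (exp(beta0_r) * s).
    alpha : per-region regularized overdispersion (trend-assigned).
    alpha_raw : per-region ML overdispersion before regularization (NaN when
        the fit did not converge).
    trend_logmu / trend_alpha : bin centers (log mean) and modal alpha used
        for interpolation; flat extrapolation beyond the outer bins.
    clip : residual clip bound c = sqrt(9 + n/4).
    converged : per-region convergence flags.
    """

    mu: pd.DataFrame
    alpha: pd.Series
    alpha_raw: pd.Series
    trend_logmu: np.ndarray
    trend_alpha: np.ndarray
    clip: float
    converged: pd.Series
    size_factors: pd.Series

    def alpha_at(self, mean: np.ndarray) -> np.ndarray:
        """Trend overdispersion at the given mean(s)."""
        return np.interp(np.log(np.maximum(mean, 1e-12)),
                         self.trend_logmu, self.trend_alpha)


def _nb_negloglik(params, x, log_s):
    beta0, log_alpha = params
    alpha = np.exp(log_alpha)
    mu = np.exp(beta0 + log_s)
    r = 1.0 / alpha
    # NB2 log pmf: lgamma(x+r) - lgamma(r) - lgamma(x+1)
    #              + r ln(r/(r+mu)) + x ln(mu/(r+mu))
    ll = (gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)
          + r * (np.log(r) - np.log(r + mu))
          + x * (np.log(mu) - np.log(r + mu)))
    return -ll.sum()


def fit_region_nb(x: np.ndarray, s: np.ndarray):
    """ML fit of an NB intercept model with ln(s) exposure for one region.

    Returns (beta0, alpha, converged). Optimization is a Nelder-Mead simplex
    over (beta0, ln alpha), initialized at the Poisson closed-form intercept.
    """
    log_s = np.log(s)
    total = x.sum()
    if total == 0:
        return -np.inf, np.nan, False
    beta0_init = np.log(total / s.sum())
    # moment initial alpha
    mu0 = np.exp(beta0_init + log_s)
    excess = np.mean((x - mu0) ** 2 - mu0)
    alpha_init = max(excess / np.mean(mu0 ** 2), 1e-4)
    res = optimize.minimize(
        _nb_negloglik, x0=[beta0_init, np.log(alpha_init)],
        args=(x.astype(float), log_s), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    beta0, log_alpha = res.x
    return float(beta0), float(np.exp(log_alpha)), bool(res.success)


def _modal_value(values: np.ndarray) -> float:
    """Mode of a sample by Gaussian KDE (Silverman bandwidth) on the log scale."""
    v = np.log(np.clip(values, 1e-6, None))
    if len(v) == 1 or np.allclose(v, v[0]):
        return float(np.exp(v[0]))
    kde = stats.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), 256)
    return float(np.exp(grid[np.argmax(kde(grid))]))


def fit_regularized_nb(counts: pd.DataFrame, size_factors: pd.Series,
                       n_bins: int = 20, max_regions: int = 5000,
                       seed: int = 0) -> NBModel:
    """Fit per-region NB models and regularize alpha along a mean trend.

    At most ``max_regions`` randomly chosen regions (seeded) are used to fit
    the mean-overdispersion trend; all regions receive the trend alpha at
    their fitted mean (regularization semantics). Non-converged regions are
    flagged and rely on the trend alone.
    """
    rng = np.random.default_rng(seed)
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    X = counts.to_numpy()
    n_regions, n_samples = X.shape

    beta0 = np.empty(n_regions)
    alpha_raw = np.full(n_regions, np.nan)
    converged = np.zeros(n_regions, dtype=bool)
    fit_idx = np.arange(n_regions)
    if n_regions > max_regions:
        fit_idx = np.sort(rng.choice(n_regions, size=max_regions, replace=False))
    fit_set = set(fit_idx.tolist())
    for i in range(n_regions):
        if i in fit_set:
            b0, a, conv = fit_region_nb(X[i], s)
        else:
            total = X[i].sum()
            b0 = np.log(total / s.sum()) if total > 0 else -np.inf
            a, conv = np.nan, False
        beta0[i] = b0
        if i in fit_set and conv:
            alpha_raw[i] = a
            converged[i] = True

    mean_fit = np.exp(beta0) * s.mean()
    good = converged & np.isfinite(alpha_raw) & (alpha_raw > 0)
    if good.sum() == 0:
        raise ValueError("no region converged; cannot fit overdispersion trend")
    log_mu = np.log(np.maximum(mean_fit[good], 1e-12))
    a_good = alpha_raw[good]
    n_bins_eff = int(min(n_bins, max(1, good.sum() // 5)))
    quantiles = np.quantile(log_mu, np.linspace(0, 1, n_bins_eff + 1))
    bins = np.clip(np.searchsorted(quantiles, log_mu, side="right") - 1,
                   0, n_bins_eff - 1)
    centers, modes = [], []
    for b in range(n_bins_eff):
        sel = bins == b
        if sel.sum() == 0:
            continue
        centers.append(log_mu[sel].mean())
        modes.append(_modal_value(a_good[sel]))
    trend_logmu = np.asarray(centers)
    trend_alpha = np.asarray(modes)

    alpha = np.interp(np.log(np.maximum(mean_fit, 1e-12)),
                      trend_logmu, trend_alpha)
    mu = np.exp(beta0)[:, None] * s[None, :]
    clip = float(np.sqrt(9.0 + n_samples / 4.0))
    return NBModel(
        mu=pd.DataFrame(mu, index=counts.index, columns=counts.columns),
        alpha=pd.Series(alpha, index=counts.index, name="alpha"),
        alpha_raw=pd.Series(alpha_raw, index=counts.index, name="alpha_raw"),
        trend_logmu=trend_logmu, trend_alpha=trend_alpha, clip=clip,
        converged=pd.Series(converged, index=counts.index, name="converged"),
        size_factors=pd.Series(s, index=counts.columns, name="size_factor"),
    )


def pearson_residuals(counts: pd.DataFrame, model: NBModel,
                      clip: float | None = None) -> pd.DataFrame:
    """Clipped NB Pearson residuals r = (x - mu) / sqrt(mu + alpha mu^2)."""
    c = model.clip if clip is None else float(clip)
    mu = model.mu.to_numpy()
    alpha = model.alpha.to_numpy()[:, None]
    var = mu + alpha * mu ** 2
    r = (counts.to_numpy() - mu) / np.sqrt(np.maximum(var, 1e-12))
    return pd.DataFrame(np.clip(r, -c, c), index=counts.index,
                        columns=counts.columns)


# ---------------------------------------------------------------------------
# sklearn-style transformer
# ---------------------------------------------------------------------------

class NBPearsonResiduals(TransformerMixin, BaseEstimator):
    """Regularized-NB Pearson-residual transform as an sklearn transformer.

    X follows the sklearn convention (samples x regions); internally the
    model is fitted per region across samples. ``fit`` filters low-count
    regions, computes pooled size factors on the detectability-top subset
    and fits the regularized NB model; ``transform`` returns clipped
    residuals for the retained regions.

    Parameters mirror the functional API; fitted attributes carry trailing
    underscores (``model_``, ``size_factors_``, ``regions_``).
    """

    def __init__(self, min_reads=1, min_samples=3, top_frac=0.05,
                 pool_sizes=(11, 21, 31), n_bins=20, max_regions=5000,
                 clip="auto", random_state=0):
        self.min_reads = min_reads
        self.min_samples = min_samples
        self.top_frac = top_frac
        self.pool_sizes = pool_sizes
        self.n_bins = n_bins
        self.max_regions = max_regions
        self.clip = clip
        self.random_state = random_state

    def _to_frame(self, X):
        if isinstance(X, pd.DataFrame):
            return X.T
        X = np.asarray(X)
        return pd.DataFrame(X.T)

    def fit(self, X, y=None):
        counts = self._to_frame(X)
        counts = filter_low_counts(counts, self.min_reads, self.min_samples)
        if len(counts) == 0:
            raise ValueError("no region passes the low-count filter")
        _, top = detectability_rank(counts, self.top_frac)
        self.size_factors_ = pooling_size_factors(counts.loc[top],
                                                  pool_sizes=self.pool_sizes)
        self.model_ = fit_regularized_nb(counts, self.size_factors_,
                                         n_bins=self.n_bins,
                                         max_regions=self.max_regions,
                                         seed=self.random_state)
        self.regions_ = counts.index
        return self

    def transform(self, X):
        counts = self._to_frame(X).loc[self.regions_]
        clip = None if self.clip == "auto" else self.clip
        return pearson_residuals(counts, self.model_, clip=clip).T


# ---------------------------------------------------------------------------
# Read-profile matrices
# ---------------------------------------------------------------------------

def profile_matrix(per_base_coverage: np.ndarray, window: int = 10):
    """Max-normalized windowed read profiles over standardized regions.

    Parameters
    ----------
    per_base_coverage : array (samples, regions, length); length must be a
        multiple of ``window``.

    Each sample is depth-normalized by its total reads, samples are pooled by
    summation, the pooled signal is summed within windows and each region row
    divided by its maximum window value (rowwise max 1). All-zero regions are
    dropped with a log message. Returns ``(profiles, mean_profile, kept)``.
    """
    cov = np.asarray(per_base_coverage, dtype=float)
    if cov.ndim != 3:
        raise ValueError("coverage must be (samples, regions, length)")
    n_samples, n_regions, length = cov.shape
    if length % window != 0:
        raise ValueError("region length must be divisible by window")
    totals = cov.sum(axis=(1, 2))
    if np.any(totals <= 0):
        raise ValueError("sample with zero total coverage")
    pooled = (cov / totals[:, None, None]).sum(axis=0)
    windows = pooled.reshape(n_regions, length // window, window).sum(axis=2)
    maxes = windows.max(axis=1)
    kept = maxes > 0
    if not np.all(kept):
        logger.info("dropping %d all-zero regions from profile matrix",
                    int((~kept).sum()))
    profiles = windows[kept] / maxes[kept, None]
    mean_profile = profiles.mean(axis=0) if len(profiles) else np.zeros(length // window)
    return profiles, mean_profile, np.flatnonzero(kept)
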