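"""Per-region Cox screening and maximally-selected log-rank cutpoints.

Every region's clipped Pearson residual enters a univariate Cox
proportional-hazards model against overall survival (Efron tie handling);
regions passing a 5% BH FDR on the Wald p-value are prognostic, with hazard
ratio > 1 meaning over-expression associates with worse survival. For
Kaplan-Meier display, the expression cutpoint of a single region is chosen
by the maximally selected log-rank statistic over the inner-quantile range
of candidate splits, with a permutation p-value correcting for the maximal
selection (a Monte-Carlo stand-in for the exact conditional method).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .annotate import bh_fdr

logger = logging.getLogger(__name__)


def _check_survival(survival: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "time", "event"}
    if not required <= set(survival.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if survival["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in survival table")
    if (survival["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return survival


def cox_screen(residuals: pd.DataFrame, survival: pd.DataFrame,
               fdr: float = 0.05) -> pd.DataFrame:
    """Univariate Cox PH screen of every region's residuals.

    Returns a DataFrame (log_hr, se, p_value, q_value, significant,
    skipped) indexed by region; constant covariates and non-converging fits
    are skipped (p = NaN, excluded from the FDR correction).
    """
    survival = _check_survival(survival)
    samples = [s for s in survival["sample_id"] if s in residuals.columns]
    if len(samples) < len(survival):
        raise KeyError("survival samples missing from residual columns")
    surv = survival.set_index("sample_id").loc[samples]
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 observed events")

    rows = []
    base = pd.DataFrame({"time": surv["time"].to_numpy(dtype=float),
                         "event": surv["event"].to_numpy(dtype=int)})
    for region in residuals.index:
        x = residuals.loc[region, samples].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            logger.info("skipping constant covariate at region %s", region)
            rows.append({"region": region, "log_hr": np.nan, "se": np.nan,
                         "p_value": np.nan, "skipped": True})
            continue
        df = base.copy()
        df["x"] = x
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            rows.append({"region": region,
                         "log_hr": float(cph.params_["x"]),
                         "se": float(cph.standard_errors_["x"]),
                         "p_value": float(cph.summary.loc["x", "p"]),
                         "skipped": False})
        except Exception:
            logger.info("Cox fit failed at region %s", region)
            rows.append({"region": region, "log_hr": np.nan, "se": np.nan,
                         "p_value": np.nan, "skipped": True})
    out = pd.DataFrame(rows).set_index("region")
    ok = ~out["p_value"].isna()
    out["q_value"] = np.nan
    out.loc[ok, "q_value"] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    out["significant"] = out["q_value"] <= fdr
    return out


# ---------------------------------------------------------------------------
# Log-rank machinery
# ---------------------------------------------------------------------------

def logrank_statistic(high: np.ndarray, time: np.ndarray,
                      event: np.ndarray) -> float:
    """Two-group log-rank chi-square statistic for a boolean split."""
    stats_ = _logrank_many(high[None, :], time, event)
    return float(stats_[0])


def _logrank_many(splits: np.ndarray, time: np.ndarray,
                  event: np.ndarray) -> np.ndarray:
    """Log-rank chi-square for many boolean splits (rows) at once."""
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    splits = splits[:, order].astype(float)
    # unique event times
    uniq, inv = np.unique(time, return_inverse=True)
    n_t = len(uniq)
    d = np.bincount(inv, weights=event, minlength=n_t)           # deaths at t
    removed = np.bincount(inv, minlength=n_t).astype(float)      # leaving at t
    n_at_risk = len(time) - np.concatenate(([0.0], np.cumsum(removed)[:-1]))

    # per-split group-1 at-risk and deaths per time (one-hot matmul keeps the
    # candidate x permutation loops out of Python)
    onehot = np.zeros((len(time), n_t))
    onehot[np.arange(len(time)), inv] = 1.0
    d1 = (splits * event[None, :]) @ onehot
    rem1 = splits @ onehot
    n1 = splits.sum(axis=1)[:, None] - np.concatenate(
        [np.zeros((len(splits), 1)), np.cumsum(rem1, axis=1)[:, :-1]], axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d[None, :] * n1 / n_at_risk[None, :]
        var = (d[None, :] * (n1 / n_at_risk) * (1 - n1 / n_at_risk)
               * (n_at_risk - d)[None, :] / np.maximum(n_at_risk - 1, 1)[None, :])
    use = (d > 0) & (n_at_risk > 1)
    U = np.nansum((d1 - expected)[:, use], axis=1)
    V = np.nansum(var[:, use], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, U ** 2 / V, 0.0)
    return chi2


def maxstat_cutpoint(expression: pd.Series, survival: pd.DataFrame,
                     quantile_range=(0.1, 0.9), n_perm: int = 10000,
                     seed: int = 0) -> dict:
    """Maximally selected log-rank cutpoint with a permutation p-value.

    Candidate cutpoints are the unique expression values inside the inner
    quantile range; the cutpoint maximizing the two-group log-rank statistic
    is selected and its p-value estimated by permuting the expression labels
    ``n_perm`` times (add-one Monte-Carlo estimate).
    """
    survival = _check_survival(survival)
    samples = list(survival["sample_id"])
    x = expression.loc[samples].to_numpy(dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    lo, hi = np.quantile(x, quantile_range)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    if len(candidates) == 0 or np.allclose(x, x[0]):
        raise ValueError("all expression values tied; no cutpoint")
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)

    def max_stat(values):
        splits = values[None, :] > candidates[:, None]
        ok = (splits.sum(axis=1) > 0) & (splits.sum(axis=1) < len(values))
        if not ok.any():
            return 0.0, candidates[0]
        chi2 = _logrank_many(splits[ok], time, event)
        best = int(np.argmax(chi2))
        return float(chi2[best]), float(candidates[ok][best])

    observed, cutpoint = max_stat(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        stat, _ = max_stat(x[rng.permutation(len(x))])
        if stat >= observed:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return {"cutpoint": cutpoint, "statistic": observed, "p_value": float(p),
            "n_candidates": int(len(candidates))}


def kaplan_meier_table(high: np.ndarray, survival: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier estimate per group (time, at-risk, survival)."""
    from lifelines import KaplanMeierFitter

    survival = _check_survival(survival)
    out = []
    for name, mask in (("high", np.asarray(high, bool)),
                       ("low", ~np.asarray(high, bool))):
        km = KaplanMeierFitter()
        km.fit(survival["time"][mask], survival["event"][mask])
        tbl = km.event_table.reset_index()
        tbl["survival"] = km.survival_function_.iloc[:, 0].to_numpy()
        tbl["group"] = name
        out.append(tbl[["group", "event_at", "at_risk", "survival"]]
                   .rename(columns={"event_at": "time"}))
    return pd.concat(out, ignore_index=True)
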