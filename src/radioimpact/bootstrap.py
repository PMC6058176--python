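"""Cluster bootstrap with BCa (bias-corrected and accelerated) intervals.

The resampling unit is the cluster — the unit of randomisation and the level
at which observations are dependent — drawn with replacement *within each
arm* so every replicate keeps the original number of intervention and
control clusters.  Matched-pair resampling (pairs drawn with replacement) is
available as an option.

Interval construction follows the standard BCa recipe:

    z0     = Phi^-1( #{theta* < theta_hat} / B )
    a      = sum (theta_bar - theta_i)^3 / (6 [sum (theta_bar - theta_i)^2]^{3/2})
             from a leave-one-cluster-out jackknife
    alpha1 = Phi( z0 + (z0 + z_{alpha/2}) / (1 - a (z0 + z_{alpha/2})) )
    alpha2 = Phi( z0 + (z0 + z_{1-alpha/2}) / (1 - a (z0 + z_{1-alpha/2})) )

with the interval endpoints taken as the (linearly interpolated) empirical
alpha1/alpha2 quantiles of the replicate estimates.  The two-sided p-value
is the smallest level at which the interval excludes the null value, found
by bisection on the nominal level.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_clusters(
    df: pd.DataFrame,
    rng: np.random.Generator,
    cluster_col: str = "cluster_id",
    stratify_col: str | None = "arm",
    unit: str = "cluster",
) -> pd.DataFrame:
    """One bootstrap replicate of a clustered table.

    ``unit='cluster'`` draws clusters with replacement within each stratum;
    ``unit='pair'`` draws matched pairs (``pair_id``) with replacement.
    Re-drawn copies of the same cluster get fresh ids so downstream models
    treat them as distinct clusters.
    """
    pieces = []
    if unit == "pair":
        pairs = np.sort(df["pair_id"].unique())
        chosen = rng.choice(pairs, size=len(pairs), replace=True)
        for k, pid in enumerate(chosen):
            piece = df[df["pair_id"] == pid].copy()
            piece[cluster_col] = piece[cluster_col].astype(str) + f"#r{k}"
            piece["pair_id"] = k
            pieces.append(piece)
    elif unit == "cluster":
        groups = [df] if stratify_col is None else [g for _, g in df.groupby(stratify_col, sort=True)]
        k = 0
        for g in groups:
            ids = np.sort(g[cluster_col].unique())
            chosen = rng.choice(ids, size=len(ids), replace=True)
            for cid in chosen:
                piece = g[g[cluster_col] == cid].copy()
                piece[cluster_col] = f"{cid}#r{k}"
                k += 1
                pieces.append(piece)
    else:
        raise ValueError(f"unknown resampling unit {unit!r}")
    return pd.concat(pieces, ignore_index=True)


def jackknife_frames(df: pd.DataFrame, cluster_col: str = "cluster_id"):
    """Yield the table with each cluster left out in turn (sorted cluster order)."""
    for cid in np.sort(df[cluster_col].unique()):
        yield cid, df[df[cluster_col] != cid].reset_index(drop=True)


# ---------------------------------------------------------------------------
# BCa formulas
# ---------------------------------------------------------------------------

def bca_alphas(z0: float, a: float, level: float) -> tuple[float, float]:
    """Adjusted quantile levels (alpha1, alpha2) for a nominal two-sided level."""
    alpha = 1.0 - level
    out = []
    for z_tail in (norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)):
        w = z0 + z_tail
        out.append(float(norm.cdf(z0 + w / (1.0 - a * w))))
    return out[0], out[1]


def jackknife_acceleration(jack: np.ndarray) -> float:
    """Acceleration constant from leave-one-out estimates (0 if no skew signal)."""
    jack = np.asarray(jack, dtype=float)
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((d**3).sum() / (6.0 * denom))


@dataclass
class BootstrapResult:
    """BCa bootstrap output for a (possibly vector-valued) statistic."""

    theta_hat: np.ndarray
    estimates: np.ndarray        # (B, k) replicate statistics
    jackknife: np.ndarray        # (G, k) leave-one-cluster-out statistics
    z0: np.ndarray
    a: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    level: float
    n_failed: int = 0
    degenerate: np.ndarray = field(default=None)

    def p_value(self, null: float = 0.0, component: int = 0) -> float:
        """Two-sided p-value by inverting the BCa interval for one component."""
        return bca_pvalue(
            float(self.theta_hat[component]),
            self.estimates[:, component],
            self.jackknife[:, component],
            null=null,
        )


def bca_interval(
    theta_hat: float, boot: np.ndarray, jack: np.ndarray, level: float = 0.95
) -> tuple[float, float, float, float, float, float, bool]:
    """BCa interval for a scalar statistic.

    Returns (lo, hi, z0, a, alpha1, alpha2, degenerate).  Degenerate means
    the replicate distribution carries no usable ordering information (all
    replicates identical, or the point estimate outside the replicate range
    so the bias-correction proportion is 0 or 1); the interval then
    collapses to the replicate range and is flagged.
    """
    boot = np.asarray(boot, dtype=float)
    B = len(boot)
    prop = float(np.mean(boot < theta_hat))
    a = jackknife_acceleration(jack)
    if np.allclose(boot, boot[0]) or prop == 0.0 or prop == 1.0:
        logger.warning("degenerate bootstrap distribution (prop=%s)", prop)
        z0 = norm.ppf(np.clip(prop, 0.5 / B, 1.0 - 0.5 / B))
        a1, a2 = bca_alphas(z0, a, level)
        return (
            float(np.quantile(boot, a1)),
            float(np.quantile(boot, a2)),
            float(z0),
            a,
            a1,
            a2,
            True,
        )
    z0 = float(norm.ppf(prop))
    a1, a2 = bca_alphas(z0, a, level)
    lo = float(np.quantile(boot, a1))
    hi = float(np.quantile(boot, a2))
    return lo, hi, z0, a, a1, a2, False


def bca_pvalue(theta_hat: float, boot: np.ndarray, jack: np.ndarray, null: float = 0.0) -> float:
    """Smallest two-sided level at which the BCa interval excludes ``null``.

    Monotone in the significance level (intervals shrink as the level
    drops), so a bisection on alpha converges; resolution ~1e-8.
    """
    boot = np.asarray(boot, dtype=float)
    prop = float(np.mean(boot < theta_hat))
    if np.allclose(boot, boot[0]) or prop in (0.0, 1.0):
        # no usable distribution: fall back to the replicate range
        return 0.0 if (null < boot.min() or null > boot.max()) else 1.0
    z0 = float(norm.ppf(prop))
    a = jackknife_acceleration(jack)

    def excluded(alpha: float) -> bool:
        a1, a2 = bca_alphas(z0, a, 1.0 - alpha)
        lo = np.quantile(boot, a1)
        hi = np.quantile(boot, a2)
        return bool(null < lo or null > hi)

    lo_a, hi_a = 1e-8, 1.0 - 1e-8
    if excluded(lo_a):
        return lo_a
    if not excluded(hi_a):
        return 1.0
    for _ in range(60):
        mid = 0.5 * (lo_a + hi_a)
        if excluded(mid):
            hi_a = mid
        else:
            lo_a = mid
    return float(hi_a)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def bca_bootstrap(
    df: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float | np.ndarray],
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    cluster_col: str = "cluster_id",
    stratify_col: str | None = "arm",
    unit: str = "cluster",
    max_failure_rate: float = 0.05,
) -> BootstrapResult:
    """Cluster bootstrap of an arbitrary statistic of a records table.

    ``statistic`` may return a scalar or a 1-d vector; intervals are built
    component-wise from a single replicate stream.  Replicates where the
    statistic raises are dropped and counted; more than ``max_failure_rate``
    failures is an error.
    """
    if B < 200:
        raise ValueError("need B >= 200 for interval construction")
    rng = np.random.default_rng(seed)
    theta_hat = np.atleast_1d(np.asarray(statistic(df), dtype=float))
    k = len(theta_hat)

    boot = np.full((B, k), np.nan)
    n_failed = 0
    for b in range(B):
        rep = resample_clusters(df, rng, cluster_col, stratify_col, unit)
        try:
            boot[b] = np.atleast_1d(np.asarray(statistic(rep), dtype=float))
        except Exception as exc:  # refit failure on a pathological resample
            n_failed += 1
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
    if n_failed > max_failure_rate * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap refits failed")
    boot = boot[~np.isnan(boot).any(axis=1)]

    jack = np.stack(
        [np.atleast_1d(np.asarray(statistic(sub), dtype=float)) for _, sub in jackknife_frames(df, cluster_col)]
    )

    lo = np.empty(k)
    hi = np.empty(k)
    z0 = np.empty(k)
    acc = np.empty(k)
    a1 = np.empty(k)
    a2 = np.empty(k)
    degen = np.zeros(k, dtype=bool)
    for j in range(k):
        lo[j], hi[j], z0[j], acc[j], a1[j], a2[j], degen[j] = bca_interval(
            float(theta_hat[j]), boot[:, j], jack[:, j], level
        )
    return BootstrapResult(
        theta_hat=theta_hat,
        estimates=boot,
        jackknife=jack,
        z0=z0,
        a=acc,
        ci_low=lo,
        ci_high=hi,
        alpha1=a1,
        alpha2=a2,
        level=level,
        n_failed=n_failed,
        degenerate=degen,
    )
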