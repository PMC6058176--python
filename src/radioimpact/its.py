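"""Interrupted time-series mixed-effects Poisson model for clustered monthly counts.

The model for the count of one diagnosis category in cluster i, month t:

    y_it | b_i ~ Poisson(mu_it),
    log mu_it = beta0 + beta_trend * t + month-of-year contrasts
               + beta_arm * 1[intervention] + beta_conf * confounder_i
               + sum_p beta_p * 1[intervention, period p]     (p in campaign years)
               + b_i,        b_i ~ N(0, sigma^2)

No exposure offset is used: the routine reporting system has no reliable
denominators, so raw monthly counts are modelled.  The period-by-arm
interaction coefficients are the log rate ratios of interest
(``exp(beta_p)`` = multiplicative change in the intervention arm relative to
the control-arm trajectory during campaign year p).

The marginal likelihood integrates the cluster random intercept by adaptive
Gauss-Hermite quadrature (default 9 nodes), centred and scaled at each
cluster's conditional mode.  Because the intercept enters additively on the
log scale, each cluster's integrand depends on the data only through three
sufficient statistics, which makes refits cheap enough for cluster
bootstrapping.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .utils import round_half_away

logger = logging.getLogger(__name__)

CAMPAIGN_PERIODS = ("year1", "year2", "year3")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class ITSDesign:
    """Response vector, fixed-effects design matrix and cluster grouping."""

    y: np.ndarray
    X: np.ndarray
    labels: list[str]
    cluster: np.ndarray          # integer codes 0..G-1, rows sorted by code
    cluster_ids: list            # original cluster labels, by code
    cluster_arm: np.ndarray      # arm label per cluster code
    category: str

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        category: str,
        periods: tuple[str, ...] = CAMPAIGN_PERIODS,
        check: bool = True,
    ) -> "ITSDesign":
        """Build the ITS design for one diagnosis category from a records table."""
        df = df.sort_values(["cluster_id", "month_index"], kind="stable").reset_index(drop=True)
        y = df[category].to_numpy(dtype=float)
        n = len(df)
        arm = (df["arm"] == "intervention").to_numpy(dtype=float)
        cols: list[np.ndarray] = [np.ones(n), df["month_index"].to_numpy(dtype=float)]
        labels = ["const", "month_index"]
        moy = df["month_of_year"].to_numpy()
        for m in range(2, 13):  # January is the reference month
            cols.append((moy == m).astype(float))
            labels.append(f"moy_{m}")
        cols.append(arm)
        labels.append("arm")
        cols.append(df["confounder_score"].to_numpy(dtype=float))
        labels.append("confounder_score")
        period = df["period"].to_numpy()
        for p in periods:
            cols.append(arm * (period == p))
            labels.append(f"arm:{p}")
        X = np.column_stack(cols)

        codes, uniques = pd.factorize(df["cluster_id"], sort=True)
        order = np.argsort(codes, kind="stable")
        y, X, codes = y[order], X[order], codes[order]
        cluster_arm = (
            df.iloc[order].groupby("cluster_id", sort=True)["arm"].first().to_numpy()
        )

        if check:
            arms_per = pd.Series(cluster_arm).value_counts()
            if arms_per.min() < 2 or len(arms_per) < 2:
                raise ValueError("need at least 2 clusters in each arm")
            if y.sum() == 0:
                raise ValueError(f"all-zero response for category {category!r}")
            # separation: a campaign period with zero counts in one arm
            for p in periods:
                for a in ("intervention", "control"):
                    mask = (period[order] == p) & ((df["arm"].to_numpy()[order] == a))
                    if mask.any() and y[mask].sum() == 0:
                        warnings.warn(
                            f"category {category!r}: zero counts in arm={a}, period={p} "
                            "(possible separation; interaction estimate unstable)",
                            RuntimeWarning,
                        )
        return cls(y, X, labels, codes, list(uniques), cluster_arm, category)


# ---------------------------------------------------------------------------
# marginal likelihood by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

class _MarginalLikelihood:
    """Negative marginal log-likelihood and analytic gradient.

    Works on rows pre-sorted by cluster code.  For fixed beta the cluster
    contribution depends on b only through
        g_i(b) = C_i + Y_i b - e^b M_i - b^2/(2 sigma^2)
    with Y_i = sum y, M_i = sum mu0, C_i = sum y*eta0, so the conditional
    mode has a one-dimensional Newton solve on cluster totals and the
    quadrature is G x K scalars regardless of cluster size.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, cluster: np.ndarray, n_nodes: int = 9):
        if np.any(np.diff(cluster) < 0):
            raise ValueError("rows must be sorted by cluster code")
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.p = self.X.shape[1]
        change = np.r_[True, cluster[1:] != cluster[:-1]]
        self.starts = np.flatnonzero(change)
        self.G = len(self.starts)
        sizes = np.diff(np.r_[self.starts, len(self.y)])
        self.row_cluster = np.repeat(np.arange(self.G), sizes)
        self.Y = np.add.reduceat(self.y, self.starts)
        self.Xty = self.X.T @ self.y
        self.const = -float(gammaln(self.y + 1.0).sum())
        self.z, self.w = np.polynomial.hermite.hermgauss(n_nodes)
        self._b = np.zeros(self.G)  # warm-started conditional modes

    def value_grad(self, theta: np.ndarray, with_hess: bool = False):
        beta, log_s = theta[: self.p], theta[self.p]
        s2 = np.exp(2.0 * log_s)
        eta0 = np.clip(self.X @ beta, -60.0, 60.0)
        mu0 = np.exp(eta0)
        M = np.add.reduceat(mu0, self.starts)
        Cy = np.add.reduceat(self.y * eta0, self.starts)

        # conditional mode per cluster (scalar, globally concave -> damped Newton)
        b = self._b.copy()
        for _ in range(200):
            eb = np.exp(b)
            f = self.Y - eb * M - b / s2
            if np.all(np.abs(f) <= 1e-9 * (1.0 + np.abs(self.Y))):
                break
            step = f / (eb * M + 1.0 / s2)
            np.clip(step, -4.0, 4.0, out=step)
            b += step
            np.clip(b, -40.0, 40.0, out=b)
        self._b = b.copy()

        h = np.exp(b) * M + 1.0 / s2          # curvature at the mode
        sc = np.sqrt(2.0 / h)                 # adaptive quadrature scale
        bk = b[:, None] + sc[:, None] * self.z[None, :]
        gk = (
            Cy[:, None]
            + self.Y[:, None] * bk
            - np.exp(bk) * M[:, None]
            - bk * bk / (2.0 * s2)
            + self.z[None, :] ** 2
        )
        m = gk.max(axis=1)
        q = self.w[None, :] * np.exp(gk - m[:, None])
        S = q.sum(axis=1)
        ll = float(
            (m + np.log(S) + np.log(sc) - 0.5 * np.log(2.0 * np.pi * s2)).sum() + self.const
        )

        P = q / S[:, None]                     # posterior quadrature weights
        Eeb = (P * np.exp(bk)).sum(axis=1)     # E[e^{b_i} | y]
        Eb2 = (P * bk * bk).sum(axis=1)        # E[b_i^2 | y]
        g_beta = self.Xty - self.X.T @ (mu0 * Eeb[self.row_cluster])
        g_logs = float((Eb2 / s2 - 1.0).sum())
        if not with_hess:
            return -ll, -np.r_[g_beta, g_logs]

        # observed information via the Louis identity: the Hessian of the
        # marginal log-likelihood is E[complete-data Hessian] + Var[score],
        # both posterior moments available from the same quadrature weights.
        ebk = np.exp(bk)
        Ee2b = (P * ebk * ebk).sum(axis=1)
        Eb4 = (P * bk**4).sum(axis=1)
        Eebb2 = (P * ebk * bk * bk).sum(axis=1)
        W = mu0 * Eeb[self.row_cluster]
        Xm = self.X * mu0[:, None]
        m_i = np.add.reduceat(Xm, self.starts, axis=0)      # (G, p) per-cluster sum mu0*x
        var_eb = Ee2b - Eeb**2
        H_bb = -(self.X.T @ (self.X * W[:, None])) + (m_i * var_eb[:, None]).T @ m_i
        cov_eb_b2 = Eebb2 - Eeb * Eb2
        H_bs = -(m_i * cov_eb_b2[:, None]).sum(axis=0) / s2
        H_ss = float((-2.0 * Eb2 / s2 + (Eb4 - Eb2**2) / (s2 * s2)).sum())
        k = self.p + 1
        H = np.empty((k, k))
        H[: self.p, : self.p] = H_bb
        H[: self.p, self.p] = H_bs
        H[self.p, : self.p] = H_bs
        H[self.p, self.p] = H_ss
        return -ll, -np.r_[g_beta, g_logs], -H


def _poisson_irls(y: np.ndarray, X: np.ndarray, n_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Plain Poisson GLM (log link) by IRLS; used only for starting values."""
    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    p = X.shape[1]
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.maximum(np.exp(eta), 1e-10)
        z = eta + (y - mu) / mu
        W = mu
        A = X.T @ (X * W[:, None]) + 1e-10 * np.eye(p)
        new = np.linalg.solve(A, X.T @ (W * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


@dataclass
class FitResult:
    """Maximum-likelihood fit of the mixed-effects Poisson ITS model."""

    params: pd.Series            # fixed-effect coefficients (log scale)
    re_sd: float                 # cluster random-intercept SD
    loglik: float
    converged: bool
    n_obs: int
    n_clusters: int
    theta: np.ndarray = field(repr=False, default=None)  # raw optimiser vector
    cov: np.ndarray | None = field(repr=False, default=None)  # fixed-effect covariance

    @property
    def re_var(self) -> float:
        return self.re_sd**2


_SIGMA_BOUNDS = (np.log(1e-4), np.log(10.0))


def fit_poisson_mixed(
    design: ITSDesign,
    start: np.ndarray | None = None,
    n_nodes: int = 9,
    compute_cov: bool = False,
    max_iter: int = 500,
) -> FitResult:
    """Maximise the marginal likelihood of the random-intercept Poisson model.

    ``start`` (a previous fit's ``theta``) warm-starts the optimiser, which
    is what makes cluster-bootstrap refits fast.  ``compute_cov`` inverts
    the analytic observed information for Wald inference.  Non-convergence
    is flagged on the result, never silently dropped.
    """
    ml = _MarginalLikelihood(design.y, design.X, design.cluster, n_nodes=n_nodes)
    p = ml.p
    if start is None:
        beta0 = _poisson_irls(design.y, design.X)
        theta0 = np.r_[beta0, np.log(0.2)]
    else:
        theta0 = np.asarray(start, dtype=float).copy()
    theta0[p] = np.clip(theta0[p], *_SIGMA_BOUNDS)

    theta, nll, converged = _newton_solve(ml, theta0, max_iter=max_iter)
    if not converged:
        # fall back to quasi-Newton from the same start
        res = minimize(
            ml.value_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(None, None)] * p + [_SIGMA_BOUNDS],
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-6, "maxcor": 25},
        )
        if res.fun <= nll:
            theta, nll = res.x, float(res.fun)
        theta2, nll2, converged = _newton_solve(ml, theta, max_iter=50)
        if nll2 <= nll:
            theta, nll = theta2, nll2
    if not converged:
        logger.warning("mixed Poisson fit did not converge for %r", design.category)
    cov = None
    if compute_cov:
        _, _, H = ml.value_grad(theta, with_hess=True)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
    return FitResult(
        params=pd.Series(theta[:p], index=design.labels),
        re_sd=float(np.exp(theta[p])),
        loglik=-nll,
        converged=converged,
        n_obs=len(design.y),
        n_clusters=design.n_clusters,
        theta=theta,
        cov=cov,
    )


def _newton_solve(
    ml: _MarginalLikelihood,
    theta0: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool]:
    """Damped Newton ascent on the marginal likelihood.

    Convergence is declared when successive log-likelihoods differ by less
    than ``tol``.  Indefinite Hessians get Levenberg damping; the log-sigma
    coordinate is kept inside its bounds by clipping.
    """
    theta = theta0.copy()
    p = ml.p
    f, g, H = ml.value_grad(theta, with_hess=True)
    converged = False
    for _ in range(max_iter):
        lam = 0.0
        for _try in range(8):
            try:
                Hd = H if lam == 0.0 else H + lam * np.diag(np.abs(np.diag(H)) + 1e-8)
                step = np.linalg.solve(Hd, -g)
                if np.isfinite(step).all():
                    break
            except np.linalg.LinAlgError:
                pass
            lam = 1e-4 if lam == 0.0 else lam * 10.0
        else:
            return theta, f, False
        # backtracking line search on the negative log-likelihood
        t = 1.0
        for _bt in range(40):
            cand = theta + t * step
            cand[p] = np.clip(cand[p], *_SIGMA_BOUNDS)
            out = ml.value_grad(cand, with_hess=True)
            if np.isfinite(out[0]) and out[0] < f + 1e-12:
                break
            t *= 0.5
        else:
            # no descent possible: treat a tiny gradient as converged
            converged = bool(np.max(np.abs(g)) < 1e-4 * (1.0 + abs(f)))
            return theta, f, converged
        f_new, g, H = out
        theta = cand
        if abs(f - f_new) < tol:
            f = f_new
            converged = True
            break
        f = f_new
    return theta, f, converged


# ---------------------------------------------------------------------------
# period effects
# ---------------------------------------------------------------------------

@dataclass
class PeriodEffect:
    """Campaign-period intervention rate ratio with optional interval and p-value."""

    category: str
    period: str
    rate_ratio: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None   # bootstrap-inversion p-value (primary)
    p_wald: float | None = None    # Wald p-value (secondary)

    @property
    def percent_change(self) -> int:
        """Displayed % change in consultations, rounded half away from zero."""
        return int(round_half_away(100.0 * (self.rate_ratio - 1.0)))


def period_rate_ratios(
    fit: FitResult, category: str | None = None, periods: tuple[str, ...] = CAMPAIGN_PERIODS
) -> list[PeriodEffect]:
    """Point-estimate rate ratios exp(beta_p) for each campaign-period interaction."""
    out = []
    for p in periods:
        label = f"arm:{p}"
        if label not in fit.params.index:
            raise KeyError(f"missing interaction term {label!r} in fit")
        beta = float(fit.params[label])
        p_wald = None
        if fit.cov is not None:
            j = list(fit.params.index).index(label)
            se = float(np.sqrt(max(fit.cov[j, j], 0.0)))
            if se > 0:
                from scipy.stats import norm

                p_wald = float(2.0 * norm.sf(abs(beta) / se))
        out.append(
            PeriodEffect(category=category, period=p, rate_ratio=float(np.exp(beta)), p_wald=p_wald)
        )
    return out


# ---------------------------------------------------------------------------
# cluster-bootstrap CIs for the period effects (fast numpy resampling path)
# ---------------------------------------------------------------------------

def bootstrap_period_effects(
    df: pd.DataFrame,
    category: str,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    n_nodes: int = 9,
    unit: str = "cluster",
    periods: tuple[str, ...] = CAMPAIGN_PERIODS,
    max_failure_rate: float = 0.05,
):
    """Period rate ratios with BCa cluster-bootstrap intervals for one category.

    Clusters are resampled with replacement within each arm (or matched
    pairs with ``unit='pair'``); each replicate refits the mixed model,
    warm-started at the full-data estimate, and all period interactions are
    collected from one replicate stream.  The acceleration constant comes
    from a leave-one-cluster-out jackknife.  Replicate resampling is driven
    by a single seeded generator, so runs are exactly reproducible.

    Returns ``(fit, BootstrapResult, [PeriodEffect...])`` where the
    bootstrap components are the log rate ratios in ``periods`` order.
    """
    from .bootstrap import BootstrapResult, bca_interval, bca_pvalue

    design = ITSDesign.from_frame(df, category, periods=periods)
    fit = fit_poisson_mixed(design, n_nodes=n_nodes, compute_cov=True)
    idx = [design.labels.index(f"arm:{p}") for p in periods]
    theta_hat = fit.params.to_numpy()[idx]

    # per-cluster row blocks (rows are sorted by cluster code)
    G = design.n_clusters
    blocks = [np.flatnonzero(design.cluster == g) for g in range(G)]
    arm_of = design.cluster_arm
    strata = (
        [np.flatnonzero(arm_of == a) for a in np.unique(arm_of)]
        if unit == "cluster"
        else None
    )
    if unit == "pair":
        pair_of = (
            df.sort_values(["cluster_id", "month_index"], kind="stable")
            .groupby("cluster_id", sort=True)["pair_id"]
            .first()
            .to_numpy()
        )
        pair_ids = np.unique(pair_of)
        pair_members = [np.flatnonzero(pair_of == pid) for pid in pair_ids]

    def refit(selection: np.ndarray) -> np.ndarray:
        rows = np.concatenate([blocks[g] for g in selection])
        sizes = np.array([len(blocks[g]) for g in selection])
        codes = np.repeat(np.arange(len(selection)), sizes)
        sub = ITSDesign(
            y=design.y[rows],
            X=design.X[rows],
            labels=design.labels,
            cluster=codes,
            cluster_ids=list(range(len(selection))),
            cluster_arm=arm_of[selection],
            category=category,
        )
        f = fit_poisson_mixed(sub, start=fit.theta, n_nodes=n_nodes)
        if not f.converged:
            raise RuntimeError("refit did not converge")
        return f.params.to_numpy()[idx]

    rng = np.random.default_rng(seed)
    boot = np.full((B, len(idx)), np.nan)
    n_failed = 0
    for b in range(B):
        if unit == "pair":
            chosen = rng.choice(len(pair_ids), size=len(pair_ids), replace=True)
            sel = np.concatenate([pair_members[c] for c in chosen])
        else:
            sel = np.concatenate(
                [rng.choice(s, size=len(s), replace=True) for s in strata]
            )
        try:
            boot[b] = refit(sel)
        except Exception as exc:
            n_failed += 1
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
    if n_failed > max_failure_rate * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap refits failed")
    boot = boot[~np.isnan(boot).any(axis=1)]

    jack = np.stack([refit(np.delete(np.arange(G), g)) for g in range(G)])

    k = len(idx)
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
    result = BootstrapResult(
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

    effects = period_rate_ratios(fit, category=category, periods=periods)
    for j, eff in enumerate(effects):
        eff.ci_low = float(np.exp(lo[j]))
        eff.ci_high = float(np.exp(hi[j]))
        eff.p_value = bca_pvalue(float(theta_hat[j]), boot[:, j], jack[:, j], null=0.0)
    return fit, result, effects
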