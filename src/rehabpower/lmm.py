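"""Two-level linear mixed model fit by maximum likelihood.

The model for subject j at session i is

    y_ij = beta0 + beta1*group_j + beta2*session_i
           + beta3*group_j*session_i + b0j + b1j*session_i + e_ij

with (b0j, b1j) ~ N(0, G) (unstructured 2x2) and e_ij ~ N(0, sigma^2),
session continuous and group a 0/1 treatment indicator.  Estimation is
full ML on the marginal Gaussian likelihood: writing V_j =
Z_j G Z_j' + sigma^2 I, both beta (by GLS) and sigma^2 are profiled out,
and the remaining criterion is minimized over the log-Cholesky factor of
D = G / sigma^2, which keeps G positive semidefinite by construction.

Fixed effects are tested two ways: Wald z (infinite denominator df, the
large-sample default of several packages) and F with *between-within*
denominator degrees of freedom, the convention that assigns
``n_obs - n_subjects - q1`` df to fixed effects that vary within subject
and ``n_subjects - q2`` df to those that are constant within subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datagen import validate_long

__all__ = [
    "LMMSpec",
    "LMMFit",
    "WaldTest",
    "fit_lmm",
    "bw_denominator_df",
    "wald_z",
    "wald_f",
    "icc",
    "fit_report",
]

FIXED_TERMS = ("intercept", "group", "session", "group:session")
#: terms whose value changes within a subject (level 1); the rest are level 2
LEVEL1_TERMS = frozenset({"session", "group:session"})


@dataclass(frozen=True)
class LMMSpec:
    """Model specification: which random effects to include.

    ``random_slope=False`` gives the random-intercept-only submodel used
    for the intraclass correlation; the fixed part is always the full
    group x session factorial (group coded treatment=1, session continuous).
    """

    random_slope: bool = True
    estimation: str = "ml"

    def __post_init__(self) -> None:
        if self.estimation != "ml":
            raise ValueError("only maximum likelihood estimation is supported")


@dataclass
class LMMFit:
    """Maximum-likelihood solution of the two-level growth model."""

    beta: np.ndarray
    beta_cov: np.ndarray
    G: np.ndarray
    sd_residual_hat: float
    loglik: float
    converged: bool
    n_obs: int
    n_subjects: int
    spec: LMMSpec
    terms: tuple[str, ...] = FIXED_TERMS
    boundary: bool = False
    optimizer_message: str = ""

    @property
    def sd_intercept_hat(self) -> float:
        return math.sqrt(max(self.G[0, 0], 0.0))

    @property
    def sd_slope_hat(self) -> float:
        if self.G.shape[0] < 2:
            return 0.0
        return math.sqrt(max(self.G[1, 1], 0.0))

    @property
    def corr_int_slope_hat(self) -> float:
        if self.G.shape[0] < 2:
            return float("nan")
        denom = self.sd_intercept_hat * self.sd_slope_hat
        if denom <= 0:
            return float("nan")
        return float(np.clip(self.G[0, 1] / denom, -1.0, 1.0))

    def se(self, term: str) -> float:
        k = self.terms.index(term)
        return math.sqrt(max(self.beta_cov[k, k], 0.0))

    def estimate(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])


@dataclass(frozen=True)
class WaldTest:
    term: str
    estimate: float
    se: float
    statistic: float
    df_num: int
    df_den: float  # math.inf for the z test
    p: float
    method: str  # "wald_z" | "f_between_within"


def _design_matrices(data: pd.DataFrame):
    """Build per-subject y, X, Z arrays (subject-major order)."""
    data = validate_long(data)
    labels = sorted(data["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    if data["session"].nunique() < 2:
        raise ValueError("at least two distinct session values are required")
    if data["y"].nunique() == 1:
        raise ValueError("outcome is constant; model is degenerate")
    treat = (data["group"] == labels[1]).to_numpy(float)
    s = data["session"].to_numpy()
    X = np.column_stack([np.ones_like(s), treat, s, treat * s])
    y = data["y"].to_numpy()
    codes, _ = pd.factorize(data["subject"], sort=True)
    n_subj = codes.max() + 1
    if n_subj < 4:
        # need >=2 per group for the factorial to be identifiable
        per_group = data.groupby("group")["subject"].nunique()
        if (per_group < 2).any():
            raise ValueError("at least 2 subjects per group are required")
    ys = [y[codes == j] for j in range(n_subj)]
    Xs = [X[codes == j] for j in range(n_subj)]
    Zs = [np.column_stack([np.ones(len(yj)), Xs_j[:, 2]]) for yj, Xs_j in zip(ys, Xs)]
    return ys, Xs, Zs, labels


class _ProfiledML:
    """-2 * profiled log-likelihood as a function of theta.

    theta parameterizes L with D = L L', G = sigma^2 * D:
    random intercept+slope -> theta = (log l11, l21, log l22);
    intercept only -> theta = (log l11,).
    When every subject shares the same session vector (balanced complete
    panels, the simulation's case) W = I + Z D Z' is common to all
    subjects, so its inverse and log-determinant are computed once.
    """

    def __init__(self, ys, Xs, Zs, q: int):
        self.q = q
        self.n = sum(len(yj) for yj in ys)
        self.p = Xs[0].shape[1]
        key0 = tuple(np.round(Zs[0][:, -1], 12))
        self.shared = all(
            Z.shape == Zs[0].shape and tuple(np.round(Z[:, -1], 12)) == key0 for Z in Zs
        )
        if self.shared:
            self.Y = np.stack(ys)          # (m, t)
            self.X = np.stack(Xs)          # (m, t, p)
            self.Z = Zs[0][:, :q]          # (t, q)
        else:
            self.ys = ys
            self.Xs = Xs
            self.Zs = [Z[:, :q] for Z in Zs]

    def _D(self, theta: np.ndarray) -> np.ndarray:
        if self.q == 1:
            return np.array([[math.exp(2.0 * theta[0])]])
        L = np.array([[math.exp(theta[0]), 0.0], [theta[1], math.exp(theta[2])]])
        return L @ L.T

    def _dD(self, theta: np.ndarray) -> list[np.ndarray]:
        """Derivatives of D = L L' w.r.t. the log-Cholesky parameters."""
        if self.q == 1:
            return [np.array([[2.0 * math.exp(2.0 * theta[0])]])]
        L = np.array([[math.exp(theta[0]), 0.0], [theta[1], math.exp(theta[2])]])
        Es = [
            np.array([[L[0, 0], 0.0], [0.0, 0.0]]),
            np.array([[0.0, 0.0], [1.0, 0.0]]),
            np.array([[0.0, 0.0], [0.0, L[1, 1]]]),
        ]
        return [E @ L.T + L @ E.T for E in Es]

    def neg2ll(self, theta: np.ndarray) -> float:
        val, *_ = self._solve(theta)
        return val

    def neg2ll_grad(self, theta: np.ndarray):
        """Value and analytic gradient of the profiled -2 log-likelihood.

        With beta and sigma^2 profiled out, the envelope theorem leaves
        d/dtheta_k = sum_j [ tr(W_j^-1 Z_j dD_k Z_j')
                             - u_jk' dD_k u_jk / sigma^2 ],
        u_jk = Z_j' W_j^-1 r_j.
        """
        val, beta, sigma2, _ = self._solve(theta)
        if beta is None:
            return np.inf, np.zeros_like(theta)
        D = self._D(theta)
        dDs = self._dD(theta)
        grad = np.zeros(len(theta))
        if self.shared:
            t = self.Z.shape[0]
            W = np.eye(t) + self.Z @ D @ self.Z.T
            Wi = np.linalg.inv(W)
            ZtWiZ = self.Z.T @ Wi @ self.Z                      # (q, q)
            R = self.Y - np.einsum("mtp,p->mt", self.X, beta)   # (m, t)
            U = R @ Wi @ self.Z                                 # (m, q)
            A = U.T @ U
            m = len(self.Y)
            for k, dD in enumerate(dDs):
                grad[k] = m * np.trace(ZtWiZ @ dD) - np.trace(A @ dD) / sigma2
        else:
            for yj, Xj, Zj in zip(self.ys, self.Xs, self.Zs):
                W = np.eye(len(yj)) + Zj @ D @ Zj.T
                Wi = np.linalg.inv(W)
                ZtWiZ = Zj.T @ Wi @ Zj
                u = Zj.T @ (Wi @ (yj - Xj @ beta))
                for k, dD in enumerate(dDs):
                    grad[k] += np.trace(ZtWiZ @ dD) - (u @ dD @ u) / sigma2
        return val, grad

    def _solve(self, theta: np.ndarray):
        """Return (-2 loglik, beta, sigma2, XtWiX_sum) at theta."""
        D = self._D(theta)
        if self.shared:
            t = self.Z.shape[0]
            W = np.eye(t) + self.Z @ D @ self.Z.T
            try:
                cW = np.linalg.cholesky(W)
            except np.linalg.LinAlgError:
                return np.inf, None, None, None
            logdetW = 2.0 * np.sum(np.log(np.diag(cW)))
            Wi = np.linalg.inv(W)
            XtWiX = np.einsum("mti,tk,mkj->ij", self.X, Wi, self.X)
            XtWiy = np.einsum("mti,tk,mk->i", self.X, Wi, self.Y)
            sum_logdet = len(self.Y) * logdetW
            try:
                beta = np.linalg.solve(XtWiX, XtWiy)
            except np.linalg.LinAlgError:
                return np.inf, None, None, None
            R = self.Y - np.einsum("mtp,p->mt", self.X, beta)
            rss = float(np.einsum("mt,tk,mk->", R, Wi, R))
        else:
            XtWiX = np.zeros((self.p, self.p))
            XtWiy = np.zeros(self.p)
            sum_logdet = 0.0
            pieces = []
            for yj, Xj, Zj in zip(self.ys, self.Xs, self.Zs):
                W = np.eye(len(yj)) + Zj @ D @ Zj.T
                try:
                    cW = np.linalg.cholesky(W)
                except np.linalg.LinAlgError:
                    return np.inf, None, None, None
                sum_logdet += 2.0 * np.sum(np.log(np.diag(cW)))
                Wi = np.linalg.inv(W)
                XtWiX += Xj.T @ Wi @ Xj
                XtWiy += Xj.T @ Wi @ yj
                pieces.append((yj, Xj, Wi))
            try:
                beta = np.linalg.solve(XtWiX, XtWiy)
            except np.linalg.LinAlgError:
                return np.inf, None, None, None
            rss = 0.0
            for yj, Xj, Wi in pieces:
                r = yj - Xj @ beta
                rss += float(r @ Wi @ r)
        if rss <= 0 or not np.isfinite(rss):
            return np.inf, None, None, None
        sigma2 = rss / self.n
        neg2 = self.n * math.log(2.0 * math.pi * sigma2) + sum_logdet + self.n
        return neg2, beta, sigma2, XtWiX


def _moment_start(ys, Xs, Zs, q: int) -> np.ndarray:
    """Data-driven start from per-subject OLS intercepts/slopes."""
    ints, slps, resid_ss, resid_n = [], [], 0.0, 0
    for yj, Zj in zip(ys, Zs):
        if len(yj) >= Zj.shape[1] + 1:
            coef, res, *_ = np.linalg.lstsq(Zj, yj, rcond=None)
            ints.append(coef[0])
            if Zj.shape[1] > 1:
                slps.append(coef[1])
            if len(res):
                resid_ss += float(res[0])
                resid_n += len(yj) - Zj.shape[1]
    s2 = resid_ss / max(resid_n, 1) if resid_n else 1.0
    s2 = max(s2, 1e-3)
    v_int = max(np.var(ints, ddof=1) if len(ints) > 1 else 1.0, 1e-4)
    if q == 1:
        return np.array([0.5 * math.log(v_int / s2)])
    v_slp = max(np.var(slps, ddof=1) if len(slps) > 1 else 1.0, 1e-4)
    c = np.corrcoef(ints, slps)[0, 1] if len(slps) > 1 else 0.0
    c = 0.0 if not np.isfinite(c) else float(np.clip(c, -0.95, 0.95))
    l11 = math.sqrt(v_int / s2)
    l21 = c * math.sqrt(v_slp / s2)
    l22 = math.sqrt(max(v_slp / s2 - l21**2, 1e-6))
    return np.array([math.log(l11), l21, math.log(l22)])


def fit_lmm(
    data: pd.DataFrame, spec: LMMSpec = LMMSpec(), xtol: float = 1e-10
) -> LMMFit:
    """Fit the growth model by full maximum likelihood.

    Multi-start quasi-Newton on the profiled objective (a moment-based
    start plus near-zero and inflated variance starts); the best
    log-likelihood wins.  Optimizer failure is reported via
    ``converged=False``, never an exception.  Handles unbalanced panels
    (subjects may have different session sets).
    """
    ys, Xs, Zs, _ = _design_matrices(data)
    q = 2 if spec.random_slope else 1
    obj = _ProfiledML(ys, Xs, Zs, q)

    starts = [_moment_start(ys, Xs, Zs, q)]
    if q == 1:
        starts += [np.array([math.log(0.1)]), np.array([math.log(10.0)])]
        bounds = [(-12.0, 12.0)]
    else:
        starts += [
            np.array([math.log(0.1), 0.0, math.log(0.1)]),
            np.array([math.log(10.0), 0.0, math.log(10.0)]),
        ]
        bounds = [(-12.0, 12.0), (-200.0, 200.0), (-12.0, 12.0)]

    best = None
    any_success = False
    messages = []
    for x0 in starts:
        res = optimize.minimize(
            obj.neg2ll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": xtol},
        )
        messages.append(str(res.message))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
        any_success = any_success or (res.success and np.isfinite(res.fun))

    n_subjects = len(ys)
    n_obs = obj.n
    if best is None or not np.isfinite(best.fun):
        p = Xs[0].shape[1]
        return LMMFit(
            beta=np.full(p, np.nan), beta_cov=np.full((p, p), np.nan),
            G=np.full((q, q), np.nan), sd_residual_hat=float("nan"),
            loglik=-np.inf, converged=False, n_obs=n_obs,
            n_subjects=n_subjects, spec=spec,
            optimizer_message="; ".join(messages),
        )

    neg2, beta, sigma2, XtWiX = obj._solve(best.x)
    D = obj._D(best.x)
    G = sigma2 * D
    beta_cov = sigma2 * np.linalg.inv(XtWiX)
    beta_cov = 0.5 * (beta_cov + beta_cov.T)
    # boundary: a variance collapsed to ~0 or correlation pinned at +-1
    at_edge = bool(np.any(np.abs(np.asarray(best.x)[[0, -1] if q == 2 else [0]]) > 11.5))
    if q == 2 and G[0, 0] > 0 and G[1, 1] > 0:
        at_edge = at_edge or abs(G[0, 1] / math.sqrt(G[0, 0] * G[1, 1])) > 0.9999
    return LMMFit(
        beta=beta, beta_cov=beta_cov, G=G,
        sd_residual_hat=math.sqrt(sigma2), loglik=-0.5 * neg2,
        converged=bool(any_success and np.isfinite(neg2)),
        n_obs=n_obs, n_subjects=n_subjects, spec=spec,
        boundary=at_edge, optimizer_message=str(best.message),
    )


def bw_denominator_df(n_obs: int, n_subjects: int, term: str) -> int:
    """Between-within denominator df for one fixed-effect term.

    Level-1 terms (varying within subject: session, group:session) get
    ``n_obs - n_subjects - q1`` with q1 = 2 level-1 fixed parameters;
    level-2 terms (intercept, group) get ``n_subjects - q2`` with q2 = 2.
    """
    if n_subjects < 2 or n_obs < n_subjects:
        raise ValueError("need n_obs >= n_subjects >= 2")
    if term not in FIXED_TERMS:
        raise KeyError(f"unknown term {term!r}")
    df = n_obs - n_subjects - 2 if term in LEVEL1_TERMS else n_subjects - 2
    if df <= 0:
        raise ValueError(f"design too small: df for {term!r} would be {df}")
    return df


def _check_testable(fit: LMMFit, term: str) -> tuple[float, float]:
    if not fit.converged:
        raise ValueError("cannot test a non-converged fit")
    est, se = fit.estimate(term), fit.se(term)
    if se <= 0 or not np.isfinite(se):
        raise ValueError(f"degenerate fit: SE for {term!r} is {se}")
    return est, se


def wald_z(fit: LMMFit, term: str) -> WaldTest:
    """Wald z test: estimate/SE referred to a standard normal."""
    est, se = _check_testable(fit, term)
    z = est / se
    return WaldTest(
        term=term, estimate=est, se=se, statistic=z, df_num=1,
        df_den=math.inf, p=2.0 * stats.norm.sf(abs(z)), method="wald_z",
    )


def wald_f(fit: LMMFit, term: str) -> WaldTest:
    """Squared Wald statistic referred to F(1, between-within df)."""
    est, se = _check_testable(fit, term)
    df_den = bw_denominator_df(fit.n_obs, fit.n_subjects, term)
    f = (est / se) ** 2
    return WaldTest(
        term=term, estimate=est, se=se, statistic=f, df_num=1,
        df_den=float(df_den), p=float(stats.f.sf(f, 1, df_den)),
        method="f_between_within",
    )


def icc(fit: LMMFit) -> float:
    """Intraclass correlation from a random-intercept-only fit.

    The share of total variance attributable to stable between-subject
    differences: Var(intercept) / (Var(intercept) + Var(residual)).
    """
    if fit.spec.random_slope:
        raise ValueError("ICC requires a random-intercept-only fit")
    v_int = float(fit.G[0, 0])
    total = v_int + fit.sd_residual_hat**2
    if total <= 0:
        raise ValueError("zero total variance; ICC undefined")
    return v_int / total


def fit_report(fit: LMMFit) -> str:
    """Plain-text report: fixed effects with both tests, then variance
    components, mirroring the usual mixed-model output layout."""
    lines = [
        "Linear mixed model (ML), random intercept + slope"
        if fit.spec.random_slope else "Linear mixed model (ML), random intercept",
        f"  subjects: {fit.n_subjects}   observations: {fit.n_obs}"
        f"   log-likelihood: {fit.loglik:.3f}   converged: {fit.converged}",
        "",
        f"{'term':<16}{'b':>9}{'SE':>8}{'95% CI':>18}{'F(df)':>16}{'p':>9}",
    ]
    for term in fit.terms:
        est, se = fit.estimate(term), fit.se(term)
        lo, hi = est - 1.96 * se, est + 1.96 * se
        try:
            wf = wald_f(fit, term)
            ftxt = f"F(1,{int(wf.df_den)})={wf.statistic:.2f}"
            ptxt = f"{wf.p:.4f}"
        except ValueError:
            ftxt, ptxt = "NA", "NA"
        lines.append(
            f"{term:<16}{est:>9.3f}{se:>8.3f}{f'[{lo:.2f}, {hi:.2f}]':>18}"
            f"{ftxt:>16}{ptxt:>9}"
        )
    lines.append("")
    lines.append(f"SD (intercept)     {fit.sd_intercept_hat:8.3f}")
    if fit.spec.random_slope:
        lines.append(f"SD (slope)         {fit.sd_slope_hat:8.3f}")
        lines.append(f"Corr (int, slope)  {fit.corr_int_slope_hat:8.3f}")
    lines.append(f"Residual SD        {fit.sd_residual_hat:8.3f}")
    if fit.boundary:
        lines.append("note: variance-component estimate at or near boundary")
    return "\n".join(lines)
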