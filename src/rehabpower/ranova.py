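"""Mixed between-within (split-plot) repeated-measures ANOVA.

One between-subject factor (two groups) crossed with one within-subject
factor (session, treated as discrete).  Includes Mauchly's sphericity
test and the Greenhouse-Geisser epsilon / corrected p-values for the
within-subject rows.  Unlike the mixed model, this analysis requires a
complete balanced panel: any missing (subject, session) cell is a hard
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datagen import validate_long

__all__ = [
    "WideMatrix",
    "AnovaRow",
    "AnovaTable",
    "IncompleteDataError",
    "to_wide",
    "ranova_mixed",
    "gg_epsilon",
    "mauchly_test",
    "gg_correct",
    "pooled_within_cov",
    "anova_report",
]


class IncompleteDataError(ValueError):
    """Raised when the panel has missing cells: repeated-measures ANOVA
    requires complete data."""


@dataclass(frozen=True)
class WideMatrix:
    """Subjects x sessions outcome matrix plus group labels."""

    values: np.ndarray          # (N, t)
    group: np.ndarray           # (N,) labels
    sessions: np.ndarray        # (t,) time codes
    subjects: np.ndarray        # (N,) ids

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[1] < 2:
            raise ValueError("wide matrix must be N x t with t >= 2")
        if np.isnan(v).any():
            raise IncompleteDataError("wide matrix contains missing cells")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_waves(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: float
    ms: float
    F: float | None = None
    p: float | None = None
    p_gg: float | None = None


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple[AnovaRow, ...]
    epsilon_gg: float
    mauchly_W: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    @property
    def ss_total(self) -> float:
        return sum(r.ss for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": r.source, "SS": r.ss, "df": r.df, "MS": r.ms,
                 "F": r.F, "p": r.p, "p_gg": r.p_gg}
                for r in self.rows
            ]
        )


def to_wide(data: pd.DataFrame) -> WideMatrix:
    """Pivot long data to a complete subjects x sessions matrix.

    Subjects are rows in stable sorted order, sessions columns in time
    order.  Raises :class:`IncompleteDataError` naming the offending
    subjects if any (subject, session) cell is absent — the analysis has
    no way to use partial trajectories.
    """
    data = validate_long(data)
    pivot = data.pivot(index="subject", columns="session", values="y").sort_index()
    if pivot.isna().any().any():
        bad = pivot.index[pivot.isna().any(axis=1)].tolist()
        raise IncompleteDataError(
            f"incomplete panel: subjects with missing sessions: {bad}"
        )
    groups = data.drop_duplicates("subject").set_index("subject")["group"]
    return WideMatrix(
        values=pivot.to_numpy(),
        group=groups.loc[pivot.index].to_numpy(),
        sessions=pivot.columns.to_numpy(float),
        subjects=pivot.index.to_numpy(),
    )


def _orthonormal_contrasts(t: int) -> np.ndarray:
    """(t-1) x t orthonormal basis orthogonal to the unit vector
    (normalized Helmert rows)."""
    H = np.zeros((t - 1, t))
    for k in range(1, t):
        H[k - 1, :k] = 1.0
        H[k - 1, k] = -k
        H[k - 1] /= math.sqrt(k * (k + 1))
    return H


def pooled_within_cov(w: WideMatrix) -> np.ndarray:
    """Pooled within-group sample covariance of the t repeated measures.

    Group means are removed first so genuine group effects do not
    masquerade as non-sphericity; divisor N - n_groups (unbiased pooled).
    """
    t = w.n_waves
    S = np.zeros((t, t))
    n_groups = 0
    for g in np.unique(w.group):
        block = w.values[w.group == g]
        n_groups += 1
        if len(block) > 1:
            c = block - block.mean(axis=0)
            S += c.T @ c
    denom = w.n_subjects - n_groups
    if denom <= 0:
        raise ValueError("insufficient data to estimate the within-group covariance")
    return S / denom


def gg_epsilon(w: WideMatrix | np.ndarray) -> float:
    """Box / Greenhouse-Geisser sphericity epsilon.

    ``eps = tr(M)^2 / ((t-1) tr(M^2))`` where M = C S C' with C an
    orthonormal contrast basis and S the pooled within-group covariance
    (a covariance matrix may be passed directly).  Equals 1 under exact
    sphericity and is bounded below by 1/(t-1); it shrinks both df of the
    within-subject F tests.
    """
    S = pooled_within_cov(w) if isinstance(w, WideMatrix) else np.asarray(w, float)
    t = S.shape[0]
    if t == 2:
        return 1.0  # a single difference score is trivially spherical
    C = _orthonormal_contrasts(t)
    M = C @ S @ C.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / ((t - 1) * tr2)
    return float(np.clip(eps, 1.0 / (t - 1), 1.0))


def mauchly_test(w: WideMatrix) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test on the contrast-transformed covariance.

    Returns (W, chi2, df, p) with W = |M| / (tr(M)/(t-1))^(t-1) and the
    standard chi-square approximation on df = t(t-1)/2 - 1, including
    Box's second-order correction term for the tail probability.  At
    t = 2 sphericity is vacuous: returns (1, 0, 0, 1).
    """
    t = w.n_waves
    if t == 2:
        return 1.0, 0.0, 0, 1.0
    S = pooled_within_cov(w)
    n_groups = len(np.unique(w.group))
    n_d = w.n_subjects - n_groups  # error df behind S
    if n_d <= t - 1:
        raise ValueError("error df too small for Mauchly's test")
    C = _orthonormal_contrasts(t)
    M = C @ S @ C.T
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise ValueError("contrast covariance is singular; sphericity test undefined")
    k = t - 1
    logW = logdet - k * math.log(np.trace(M) / k)
    W = math.exp(logW)
    rho = 1.0 - (2.0 * k**2 + k + 2.0) / (6.0 * k * n_d)
    chi2 = -n_d * rho * logW
    df = k * (k + 1) // 2 - 1
    # Box's second-order term sharpens the chi-square tail; the last factor
    # uses t (not k) to agree exactly with R's mauchly.test
    w2 = ((k + 2.0) * (k - 1.0) * (k - 2.0) * (2.0 * k**3 + 6.0 * k**2 + 3.0 * t + 2.0)
          / (288.0 * (n_d * k * rho) ** 2))
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return float(W), float(max(chi2, 0.0)), df, p


def gg_correct(F: float, df1: float, df2: float, eps: float) -> float:
    """p-value of F referred to F(eps*df1, eps*df2).

    With eps < 1 the reference distribution has a heavier right tail, so
    for any F in the rejection region (F above ~1.2-1.5, i.e. wherever the
    uncorrected p is small) the corrected p is larger and the corrected
    test rejects on a subset of the uncorrected test's rejections.  For
    very small F the two tail areas cross and p_gg can dip slightly below
    p; decisions at conventional alpha are unaffected.
    """
    if not 0 < eps <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    return float(stats.f.sf(F, eps * df1, eps * df2))


def ranova_mixed(w: WideMatrix) -> AnovaTable:
    """Split-plot decomposition for two groups x t sessions.

    Between-subject stratum: group tested against subjects-within-groups
    on (1, N-2) df.  Within-subject stratum: session and session x group
    tested against the subject x session residual on (t-1, (N-2)(t-1))
    df, with Greenhouse-Geisser corrected p-values alongside.
    """
    Y = w.values
    groups = np.unique(w.group)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups supported, found {len(groups)}")
    N, t = Y.shape
    if N < 4:
        raise ValueError("need at least 4 subjects (2 per group)")
    if np.ptp(Y) == 0:
        raise ValueError("constant outcome matrix; ANOVA is degenerate")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    sess_means = Y.mean(axis=0)
    ss_total = float(((Y - grand) ** 2).sum())

    ss_group = 0.0
    ss_subj = 0.0
    ss_cells = 0.0
    for g in groups:
        mask = w.group == g
        n_g = int(mask.sum())
        gm = Y[mask].mean()
        ss_group += t * n_g * (gm - grand) ** 2
        ss_subj += t * float(((subj_means[mask] - gm) ** 2).sum())
        cell = Y[mask].mean(axis=0)
        ss_cells += n_g * float(((cell - gm - sess_means + grand) ** 2).sum())
    ss_session = N * float(((sess_means - grand) ** 2).sum())
    ss_resid = ss_total - ss_group - ss_subj - ss_session - ss_cells

    df_group, df_subj = 1, N - 2
    df_sess = t - 1
    df_inter = t - 1
    df_resid = (N - 2) * (t - 1)

    ms_subj = ss_subj / df_subj
    ms_resid = ss_resid / df_resid
    F_group = (ss_group / df_group) / ms_subj
    F_sess = (ss_session / df_sess) / ms_resid
    F_inter = (ss_cells / df_inter) / ms_resid

    eps = gg_epsilon(w)
    try:
        W_m, chi2_m, df_m, p_m = mauchly_test(w)
    except ValueError:
        W_m, chi2_m, df_m, p_m = float("nan"), float("nan"), 0, float("nan")

    rows = (
        AnovaRow("group", ss_group, df_group, ss_group / df_group,
                 F_group, float(stats.f.sf(F_group, df_group, df_subj))),
        AnovaRow("subjects_within_group", ss_subj, df_subj, ms_subj),
        AnovaRow("session", ss_session, df_sess, ss_session / df_sess,
                 F_sess, float(stats.f.sf(F_sess, df_sess, df_resid)),
                 gg_correct(F_sess, df_sess, df_resid, eps)),
        AnovaRow("session:group", ss_cells, df_inter, ss_cells / df_inter,
                 F_inter, float(stats.f.sf(F_inter, df_inter, df_resid)),
                 gg_correct(F_inter, df_inter, df_resid, eps)),
        AnovaRow("residual", ss_resid, df_resid, ms_resid),
    )
    return AnovaTable(
        rows=rows, epsilon_gg=eps, mauchly_W=W_m, mauchly_chi2=chi2_m,
        mauchly_df=df_m, mauchly_p=p_m,
    )


def anova_report(table: AnovaTable) -> str:
    """Plain-text split-plot ANOVA table with sphericity diagnostics."""
    lines = [
        f"{'Source':<24}{'SS':>12}{'df':>6}{'F':>9}{'p':>9}{'GG p':>9}"
    ]
    for r in table.rows:
        F = f"{r.F:.3f}" if r.F is not None else ""
        p = f"{r.p:.4f}" if r.p is not None else ""
        pg = f"{r.p_gg:.4f}" if r.p_gg is not None else ""
        lines.append(f"{r.source:<24}{r.ss:>12.2f}{r.df:>6.0f}{F:>9}{p:>9}{pg:>9}")
    lines.append("")
    lines.append(
        f"Mauchly W = {table.mauchly_W:.4f}, chi2({table.mauchly_df}) = "
        f"{table.mauchly_chi2:.3f}, p = {table.mauchly_p:.4g}"
    )
    lines.append(f"Greenhouse-Geisser epsilon = {table.epsilon_gg:.4f}")
    return "\n".join(lines)
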