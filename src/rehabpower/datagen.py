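"""Synthetic two-group longitudinal growth-curve data.

Each subject j in group g follows a linear recovery trajectory

    Y_ij = (b0 + b0j) + (b1_g + b1j) * session_i + e_ij

with per-subject deviations (b0j, b1j) drawn from a bivariate normal with
standard deviations (sd_intercept, sd_slope) and correlation
corr_int_slope, and iid Gaussian residuals e_ij with SD sd_residual.  The
outcome emulates a neglect-severity score (lower = less severe), so a
beneficial treatment has a *negative* slope.

Default variance components are anchored to published mixed-model
estimates from a prism-adaptation neglect-rehabilitation panel:
intercept SD 8.42, slope SD 0.927, intercept-slope correlation -0.93,
residual SD 2.56.  Effect sizes are standardized by a separate
group-level slope SD of 2.00 (see :class:`EffectSpec`), which is a
scaling convention, not a generating parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "GeneratingModel",
    "EffectSpec",
    "DEFAULT_MODEL",
    "make_generating_model",
    "simulate_dataset",
    "marginal_mean",
    "marginal_variance",
    "marginal_covariance",
    "validate_long",
]

#: canonical long-format column order
LONG_COLUMNS = ("subject", "group", "session", "y")


@dataclass(frozen=True)
class StudyDesign:
    """Balanced two-group panel layout.

    Parameters
    ----------
    n_per_group
        Subjects in each of the two groups (total N = 2 * n_per_group).
    n_waves
        Number of assessment sessions (>= 2).
    session_values
        Time codes, strictly increasing, length ``n_waves``.  Default
        0, 1, ..., n_waves-1 so the intercept is baseline severity.
    group_labels
        (control, treatment) identifiers.
    """

    n_per_group: int
    n_waves: int
    session_values: tuple[float, ...] = ()
    group_labels: tuple[str, str] = ("control", "treatment")

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be a positive integer")
        if self.n_waves < 2:
            raise ValueError("a longitudinal design needs at least 2 waves")
        sessions = self.session_values or tuple(float(i) for i in range(self.n_waves))
        if len(sessions) != self.n_waves:
            raise ValueError("session_values length must equal n_waves")
        if any(b <= a for a, b in zip(sessions, sessions[1:])):
            raise ValueError("session_values must be strictly increasing")
        if len(set(self.group_labels)) != 2:
            raise ValueError("exactly two distinct group labels required")
        object.__setattr__(self, "session_values", tuple(float(s) for s in sessions))

    @property
    def n_total(self) -> int:
        return 2 * self.n_per_group


@dataclass(frozen=True)
class GeneratingModel:
    """Parameters of the two-level growth process."""

    fixed_intercept: float = 20.0
    slope_control: float = 0.0
    slope_treatment: float = 0.0
    sd_intercept: float = 8.42
    sd_slope: float = 0.927
    corr_int_slope: float = -0.93
    sd_residual: float = 2.56

    def __post_init__(self) -> None:
        for name in ("sd_intercept", "sd_slope", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.corr_int_slope) > 1:
            raise ValueError("corr_int_slope must lie in [-1, 1]")

    @property
    def random_effects_cov(self) -> np.ndarray:
        """Implied 2x2 covariance of (b0j, b1j); PSD by construction."""
        cov01 = self.corr_int_slope * self.sd_intercept * self.sd_slope
        return np.array(
            [[self.sd_intercept**2, cov01], [cov01, self.sd_slope**2]]
        )

    def slope_for(self, design: StudyDesign, group: str) -> float:
        if group == design.group_labels[0]:
            return self.slope_control
        if group == design.group_labels[1]:
            return self.slope_treatment
        raise KeyError(f"unknown group label {group!r}")


#: study-condition defaults for the simulation harness
DEFAULT_MODEL = GeneratingModel()


@dataclass(frozen=True)
class EffectSpec:
    """Standardized slope difference between treatment and control.

    ``d`` is the group slope difference in units of the group-level slope
    SD (``slope_sd_reference``, 2.00 by convention here).  Treatment is
    beneficial, i.e. its slope is *more negative* by d * slope_sd_reference.
    """

    d: float
    slope_sd_reference: float = 2.00

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("effect size d must be non-negative")
        if self.slope_sd_reference <= 0:
            raise ValueError("slope_sd_reference must be positive")

    @property
    def slope_difference(self) -> float:
        return -self.d * self.slope_sd_reference


def make_generating_model(
    effect: EffectSpec, base: GeneratingModel = DEFAULT_MODEL
) -> GeneratingModel:
    """Instantiate the generating model for one effect-size condition.

    The control slope is 0 and the treatment slope is
    ``-d * slope_sd_reference`` (d=0.20 -> -0.40, ..., d=1.00 -> -2.00);
    all variance parameters are copied from ``base``.
    """
    return replace(
        base, slope_control=0.0, slope_treatment=effect.slope_difference
    )


def simulate_dataset(
    design: StudyDesign,
    model: GeneratingModel,
    seed: int | np.random.Generator,
    return_effects: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one balanced complete panel from the growth model.

    Returns a tidy frame with columns ``subject, group, session, y`` in
    subject-major, session-minor order.  With ``return_effects=True`` a
    second frame holds the realized per-subject random effects
    (``b0j, b1j``) for moment checks.  Identical seed -> identical data.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, t = design.n_total, design.n_waves
    sessions = np.asarray(design.session_values)

    # bivariate-normal random effects via Cholesky of the implied covariance
    chol = np.linalg.cholesky(
        model.random_effects_cov + 1e-12 * np.eye(2)
    ) if model.sd_intercept > 0 or model.sd_slope > 0 else np.zeros((2, 2))
    raw = rng.standard_normal((n, 2))
    effects = raw @ chol.T  # columns: b0j, b1j

    groups = np.repeat(list(design.group_labels), design.n_per_group)
    slopes = np.where(
        groups == design.group_labels[0], model.slope_control, model.slope_treatment
    )
    resid = rng.standard_normal((n, t)) * model.sd_residual

    y = (
        model.fixed_intercept
        + effects[:, [0]]
        + (slopes[:, None] + effects[:, [1]]) * sessions[None, :]
        + resid
    )

    width = max(4, len(str(n)))
    subjects = np.array([f"S{i + 1:0{width}d}" for i in range(n)])
    data = pd.DataFrame(
        {
            "subject": np.repeat(subjects, t),
            "group": np.repeat(groups, t),
            "session": np.tile(sessions, n),
            "y": y.ravel(),
        }
    )
    if return_effects:
        eff = pd.DataFrame(
            {"subject": subjects, "group": groups, "b0j": effects[:, 0], "b1j": effects[:, 1]}
        )
        return data, eff
    return data


def marginal_mean(model: GeneratingModel, design: StudyDesign, group: str) -> np.ndarray:
    """E[Y_i] per session for one group."""
    s = np.asarray(design.session_values)
    return model.fixed_intercept + model.slope_for(design, group) * s


def marginal_variance(model: GeneratingModel, design: StudyDesign) -> np.ndarray:
    """Var[Y_i] per session (grows with session whenever sd_slope > 0)."""
    return np.diag(marginal_covariance(model, design))


def marginal_covariance(model: GeneratingModel, design: StudyDesign) -> np.ndarray:
    """Implied t x t covariance of the repeated measures.

    Cov[Y_i, Y_k] = Z G Z' + sigma^2 I with Z = [1, session]; this is
    compound-symmetric only when sd_slope = 0.
    """
    s = np.asarray(design.session_values)
    Z = np.column_stack([np.ones_like(s), s])
    return Z @ model.random_effects_cov @ Z.T + model.sd_residual**2 * np.eye(len(s))


def validate_long(data: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format contract and return a canonicalized copy.

    Requires columns subject/group/session/y, unique (subject, session)
    pairs, and one group per subject.
    """
    missing = set(LONG_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"long data missing columns: {sorted(missing)}")
    out = data.loc[:, list(LONG_COLUMNS)].copy()
    out["session"] = out["session"].astype(float)
    out["y"] = out["y"].astype(float)
    dup = out.duplicated(subset=["subject", "session"])
    if dup.any():
        keys = out.loc[dup, ["subject", "session"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (subject, session) pairs: {keys[:5]}")
    n_groups = out.groupby("subject")["group"].nunique()
    if (n_groups > 1).any():
        bad = n_groups[n_groups > 1].index.tolist()
        raise ValueError(f"subjects assigned to multiple groups: {bad[:5]}")
    return out.sort_values(["subject", "session"], kind="stable").reset_index(drop=True)
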