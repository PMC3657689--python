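"""Split-plot ANOVA: exact-arithmetic oracle, sphericity diagnostics,
structural invariants, and round-trips."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rehabpower.datagen import GeneratingModel, StudyDesign, simulate_dataset
from rehabpower.ranova import (
    IncompleteDataError,
    WideMatrix,
    gg_correct,
    gg_epsilon,
    mauchly_test,
    pooled_within_cov,
    ranova_mixed,
    to_wide,
)


def _wide(values, groups):
    values = np.asarray(values, float)
    n, t = values.shape
    return WideMatrix(
        values=values, group=np.asarray(groups),
        sessions=np.arange(t, dtype=float),
        subjects=np.array([f"s{i}" for i in range(n)]),
    )


# ---------------------------------------------------------------- to_wide

def test_to_wide_rearranges_cells():
    long = pd.DataFrame(
        {
            "subject": ["b", "b", "a", "a"],
            "group": ["g2", "g2", "g1", "g1"],
            "session": [0, 1, 0, 1],
            "y": [3.0, 4.0, 1.0, 2.0],
        }
    )
    w = to_wide(long)
    assert list(w.subjects) == ["a", "b"]
    assert np.allclose(w.values, [[1, 2], [3, 4]])
    assert list(w.group) == ["g1", "g2"]


def test_to_wide_names_incomplete_subjects():
    long = pd.DataFrame(
        {
            "subject": ["a", "a", "b"],
            "group": ["g1", "g1", "g2"],
            "session": [0, 1, 0],
            "y": [1.0, 2.0, 3.0],
        }
    )
    with pytest.raises(IncompleteDataError, match="b"):
        to_wide(long)


def test_long_wide_long_round_trip(small_panel):
    w = to_wide(small_panel)
    back = pd.DataFrame(
        {
            "subject": np.repeat(w.subjects, w.n_waves),
            "group": np.repeat(w.group, w.n_waves),
            "session": np.tile(w.sessions, w.n_subjects),
            "y": w.values.ravel(),
        }
    )
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), small_panel.reset_index(drop=True),
        check_dtype=False,
    )


# ---------------------------------------------------- split-plot decomposition

def _exact_split_plot(values, groups):
    """Cell-mean split-plot decomposition in exact rational arithmetic;
    written from the textbook definitions, independent of the package."""
    vals = [[Fraction(v) for v in row] for row in values]
    n, t = len(vals), len(vals[0])
    labels = sorted(set(groups))
    grand = sum(sum(r) for r in vals) / (n * t)
    subj_mean = [sum(r) / t for r in vals]
    sess_mean = [sum(vals[i][j] for i in range(n)) / n for j in range(t)]
    ss = {}
    ss["group"] = 0
    ss["subj"] = 0
    ss["inter"] = 0
    for g in labels:
        idx = [i for i in range(n) if groups[i] == g]
        gmean = sum(subj_mean[i] for i in idx) / len(idx)
        ss["group"] += t * len(idx) * (gmean - grand) ** 2
        ss["subj"] += t * sum((subj_mean[i] - gmean) ** 2 for i in idx)
        for j in range(t):
            cell = sum(vals[i][j] for i in idx) / len(idx)
            ss["inter"] += len(idx) * (cell - gmean - sess_mean[j] + grand) ** 2
    ss["session"] = n * sum((m - grand) ** 2 for m in sess_mean)
    ss_total = sum((vals[i][j] - grand) ** 2 for i in range(n) for j in range(t))
    ss["resid"] = ss_total - ss["group"] - ss["subj"] - ss["session"] - ss["inter"]
    return ss, ss_total


def test_split_plot_matches_exact_arithmetic_oracle():
    values = [[1, 2, 4], [3, 4, 5], [2, 4, 6], [4, 6, 8]]
    groups = ["A", "A", "B", "B"]
    ss, ss_total = _exact_split_plot(values, groups)
    table = ranova_mixed(_wide(values, groups))
    assert table.row("group").ss == pytest.approx(float(ss["group"]), abs=1e-10)
    assert table.row("subjects_within_group").ss == pytest.approx(float(ss["subj"]), abs=1e-10)
    assert table.row("session").ss == pytest.approx(float(ss["session"]), abs=1e-10)
    assert table.row("session:group").ss == pytest.approx(float(ss["inter"]), abs=1e-10)
    assert table.row("residual").ss == pytest.approx(float(ss["resid"]), abs=1e-10)
    assert table.ss_total == pytest.approx(float(ss_total), abs=1e-10)
    # df: (1, N-2) between; (t-1, (N-2)(t-1)) within
    assert table.row("group").df == 1
    assert table.row("subjects_within_group").df == 2
    assert table.row("residual").df == 4
    F = (float(ss["inter"]) / 2) / (float(ss["resid"]) / 4)
    assert table.row("session:group").F == pytest.approx(F, rel=1e-12)


def test_total_ss_invariant_under_group_permutation(small_panel):
    w = to_wide(small_panel)
    table = ranova_mixed(w)
    permuted = WideMatrix(
        values=w.values, group=w.group[::-1].copy(),
        sessions=w.sessions, subjects=w.subjects,
    )
    table_p = ranova_mixed(permuted)
    assert table_p.row("session").ss == pytest.approx(table.row("session").ss)
    assert table_p.ss_total == pytest.approx(table.ss_total)


def test_location_shift_leaves_all_ss_unchanged(small_panel):
    w = to_wide(small_panel)
    t1 = ranova_mixed(w)
    t2 = ranova_mixed(
        WideMatrix(values=w.values + 11.5, group=w.group,
                   sessions=w.sessions, subjects=w.subjects)
    )
    for r1, r2 in zip(t1.rows, t2.rows):
        assert r2.ss == pytest.approx(r1.ss, rel=1e-9, abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    hnp.arrays(
        np.float64, st.tuples(st.integers(4, 9), st.integers(2, 5)),
        elements=st.floats(-50, 50, allow_nan=False, width=32),
    )
)
def test_ss_conservation_and_epsilon_bounds(values):
    """On arbitrary matrices: component SS sum to the total SS about the
    grand mean, and the GG epsilon stays inside [1/(t-1), 1]."""
    n, t = values.shape
    values = values + np.arange(n)[:, None] * 1e-3  # break exact constancy
    groups = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    w = _wide(values, groups)
    table = ranova_mixed(w)
    total = float(((values - values.mean()) ** 2).sum())
    assert table.ss_total == pytest.approx(total, rel=1e-8, abs=1e-6)
    assert 1.0 / (t - 1) - 1e-12 <= table.epsilon_gg <= 1.0 + 1e-12
    # GG correction can only weaken evidence in the rejection region
    for src in ("session", "session:group"):
        row = table.row(src)
        if row.p <= 0.10:
            assert row.p_gg >= row.p - 1e-12


# ------------------------------------------------------------- sphericity

def test_epsilon_is_one_under_compound_symmetry():
    t = 4
    S = 2.0 * np.eye(t) + 1.0  # equal variances, equal covariances
    assert gg_epsilon(S) == pytest.approx(1.0)


def test_epsilon_two_waves_always_one(rng):
    vals = rng.normal(size=(8, 2))
    w = _wide(vals, ["a"] * 4 + ["b"] * 4)
    assert gg_epsilon(w) == 1.0
    W, chi2, df, p = mauchly_test(w)
    assert (W, chi2, df, p) == (1.0, 0.0, 0, 1.0)


def test_epsilon_contrast_form_agrees_with_box_element_formula():
    """Two classical expressions for epsilon - the orthonormal-contrast
    trace form and Box's direct element formula - agree to 1e-10 on the
    analytic covariance of a random-slope process."""
    design = StudyDesign(10, 6)
    from rehabpower.datagen import marginal_covariance
    S = marginal_covariance(
        GeneratingModel(sd_slope=2.0, sd_residual=2.56), design
    )
    t = S.shape[0]
    sbar_diag = np.trace(S) / t
    row_means = S.mean(axis=1)
    sbar = S.mean()
    num = (t * (sbar_diag - sbar)) ** 2
    den = (t - 1) * (
        (S**2).sum() - 2 * t * (row_means**2).sum() + t**2 * sbar**2
    )
    eps_box = num / den
    assert gg_epsilon(S) == pytest.approx(eps_box, abs=1e-10)


def test_mauchly_spherical_matrix_gives_W_one(rng):
    """Data whose contrast covariance is proportional to identity: W ~ 1,
    chi2 ~ 0.  Build it by drawing iid coordinates (covariance sigma^2 I)."""
    vals = rng.normal(size=(2000, 4))
    w = _wide(vals, ["a"] * 1000 + ["b"] * 1000)
    W, chi2, df, p = mauchly_test(w)
    assert df == 5
    assert W > 0.99
    assert p > 0.5


def test_gg_correct_limits():
    p_uncorrected = gg_correct(4.0, 5, 78, 1.0)
    from scipy import stats
    assert p_uncorrected == pytest.approx(stats.f.sf(4.0, 5, 78), rel=1e-12)
    assert gg_correct(4.0, 5, 78, 0.5) > p_uncorrected
    with pytest.raises(ValueError):
        gg_correct(4.0, 5, 78, 1.2)


def test_group_centering_hides_group_shift_from_epsilon(rng):
    """A pure group mean shift is not sphericity violation: epsilon from the
    pooled within-group covariance must be unaffected by the shift."""
    base = rng.normal(size=(40, 4))
    groups = ["a"] * 20 + ["b"] * 20
    shifted = base.copy()
    shifted[20:] += 25.0
    assert gg_epsilon(_wide(base, groups)) == pytest.approx(
        gg_epsilon(_wide(shifted, groups)), abs=1e-12
    )


def test_ranova_errors():
    vals = np.arange(12.0).reshape(4, 3)
    with pytest.raises(ValueError, match="two groups"):
        ranova_mixed(_wide(vals, ["a", "b", "c", "c"]))
    with pytest.raises(ValueError, match="constant|degenerate"):
        ranova_mixed(_wide(np.ones((4, 3)), ["a", "a", "b", "b"]))
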