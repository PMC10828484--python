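"""Cohort statistics: descriptives, group comparisons, correlations, and
the Gaussian-copula synthetic cohort generator."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from myosen.cohort import (CohortTable, MarginalSpec, chi2_test, cohen_class,
                           compare_groups, correlation_matrix, describe,
                           format_p, generate_cohort, quartiles,
                           rank_sum_test, spearman)
from myosen.presets import (DEFAULT_MARGINALS, TABLE1_CONTINGENCY,
                            default_rank_corr)


def _toy_cohort():
    df = pd.DataFrame({
        "id": [f"p{i}" for i in range(8)],
        "sex": ["M"] * 4 + ["F"] * 4,
        "age_years": [50.0, 60, 70, 80, 55, 65, 75, 85],
        "smoking": ["never", "never", "previous", "never",
                    "previous", "never", "current", "never"],
    })
    return CohortTable(df, {"age_years": ("years", "numeric"),
                            "smoking": ("", "categorical"),
                            "sex": ("", "categorical")})


def test_quartiles_use_linear_interpolation():
    med, (q1, q3) = quartiles([1, 2, 3, 4, 5])
    assert (med, q1, q3) == (3.0, 2.0, 4.0)


def test_describe_categorical_percentages():
    counts = {"never": 14, "previous": 10, "current": 0}
    df = pd.DataFrame({"id": range(24), "sex": "M",
                       "smoking": ["never"] * 14 + ["previous"] * 10})
    c = CohortTable(df, {"smoking": ("", "categorical")})
    out = describe(c, "smoking")["M"]
    assert out["pct"]["never"] == pytest.approx(58.3, abs=0.05)
    assert out["pct"]["previous"] == pytest.approx(41.7, abs=0.05)
    assert out["counts"].get("current", 0) == 0


def test_describe_flags_empty_stratum():
    c = _toy_cohort()
    c.df.loc[c.df.sex == "F", "age_years"] = np.nan
    out = describe(c, "age_years")
    assert out["F"] == {"missing": True}
    assert out["M"]["median"] == 65.0


def test_compare_groups_requires_both_sexes():
    c = _toy_cohort()
    c.df.loc[c.df.sex == "F", "age_years"] = np.nan
    with pytest.raises(ValueError, match="age_years"):
        compare_groups(c, "age_years")


def test_yates_correction_only_on_2x2():
    rng = np.random.default_rng(3)
    for _ in range(20):
        t22 = rng.integers(1, 30, size=(2, 2))
        chi2, _, _ = chi2_test(t22)
        raw = stats.chi2_contingency(t22, correction=False)[0]
        if not np.allclose((t22 - t22).sum(), 0) and chi2 != 0:
            assert chi2 <= raw  # Yates shrinks the statistic
        t23 = rng.integers(1, 30, size=(2, 3))
        chi2_3, _, _ = chi2_test(t23)
        assert chi2_3 == pytest.approx(
            stats.chi2_contingency(t23, correction=False)[0])


def test_printed_contingency_tables_reproduce_p_values():
    # the five sex-by-category tables published for the 40-person cohort
    expected = {"smoking": 0.46, "education": 0.83, "occupation": 0.35,
                "bmi_category": 0.87, "ewgsop2": 0.33}
    for name, want in expected.items():
        _, p, _ = chi2_test(TABLE1_CONTINGENCY[name])
        assert round(p, 2) == want


def test_exact_wilcoxon_on_separated_triples():
    _, p, method = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert method == "exact"
    assert p == pytest.approx(0.10, abs=1e-12)


def _enumeration_p(x, y):
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    sums = np.array([ranks[list(c)].sum()
                     for c in itertools.combinations(range(len(pooled)), n1)])
    mu = sums.mean()
    return float(np.mean(np.abs(sums - mu) >= abs(obs - mu) - 1e-9))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(2, 5), st.integers(2, 5), st.integers(0, 10_000))
def test_exact_path_equals_full_enumeration(n1, n2, seed):
    rng = np.random.default_rng(seed)
    vals = rng.permutation(50)[:n1 + n2].astype(float)
    x, y = vals[:n1], vals[n1:]
    _, p, method = rank_sum_test(x, y)
    assert method == "exact"
    assert p == pytest.approx(_enumeration_p(x, y), abs=1e-12)


def test_ties_fall_back_to_corrected_normal_approximation():
    _, p, method = rank_sum_test([1, 1, 2, 3], [2, 2, 3, 4])
    assert method == "asymptotic"
    assert 0 < p < 1


def test_p_value_formatting():
    assert format_p(0.004) == "< 0.01"
    assert format_p(0.46) == "0.46"
    assert format_p(1.0) == "1.00"


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------

def test_spearman_monotone_extremes_and_ties_example():
    x = [1, 2, 3, 4, 5]
    assert spearman(x, [10, 20, 30, 40, 50]).rho == pytest.approx(1.0)
    assert spearman(x, [9, 7, 5, 3, 1]).rho == pytest.approx(-1.0)
    r = spearman(x, [2, 1, 4, 3, 5])
    assert r.rho == pytest.approx(0.8)
    assert r.effect_class == "large"


def test_spearman_pairwise_deletion_and_degenerate_input():
    r = spearman([1, 2, 3, np.nan, 5], [2, 4, 6, 1, np.nan])
    assert r.n == 3
    flat = spearman([1, 2, 3, 4], [7, 7, 7, 7])
    assert flat.effect_class == "undefined" and np.isnan(flat.rho)
    with pytest.raises(ValueError):
        spearman([1, 2], [3, 4])


@pytest.mark.parametrize("rho,expected", [
    (-0.58, "large"), (0.5, "large"), (0.3, "medium"), (0.49, "medium"),
    (0.1, "small"), (0.29, "small"), (0.0, "negligible"), (-0.09, "negligible"),
])
def test_cohen_benchmarks(rho, expected):
    assert cohen_class(rho) == expected


def test_correlation_matrix_symmetric_consistent_with_spearman():
    c = generate_cohort(20, 20, DEFAULT_MARGINALS, default_rank_corr(), seed=9)
    varlist = ["age_years", "grip_kg", "pct_taf_2plus", "min_feret_mean"]
    mat, results = correlation_matrix(c, varlist, "M")
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 1.0)
    df = c.stratum("M")
    for r in results:
        direct = spearman(df[r.var_x], df[r.var_y])
        assert mat.loc[r.var_x, r.var_y] == pytest.approx(direct.rho)


def test_heatmap_renders(tmp_path):
    from myosen.cohort import plot_heatmap
    c = generate_cohort(15, 15, DEFAULT_MARGINALS, default_rank_corr(), seed=2)
    mat, _ = correlation_matrix(c, ["age_years", "grip_kg", "almi_kgm2"], "all")
    out = tmp_path / "heat.png"
    plot_heatmap(mat, out)
    assert out.stat().st_size > 0


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def test_identical_seed_reproduces_cohort():
    a = generate_cohort(12, 8, DEFAULT_MARGINALS, default_rank_corr(), seed=4)
    b = generate_cohort(12, 8, DEFAULT_MARGINALS, default_rank_corr(), seed=4)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_grip_cutoffs_drive_ewgsop2():
    c = generate_cohort(200, 200, DEFAULT_MARGINALS, None, seed=8)
    women = c.df[c.df.sex == "F"]
    men = c.df[c.df.sex == "M"]
    assert ((women.grip_kg < 16) == (women.ewgsop2 == "probable")).all()
    assert ((men.grip_kg < 27) == (men.ewgsop2 == "probable")).all()


def test_bmi_bands_drive_category():
    c = generate_cohort(100, 100, DEFAULT_MARGINALS, None, seed=8)
    d = c.df
    assert (d.loc[d.bmi_kgm2 < 25, "bmi_category"] == "normal").all()
    assert (d.loc[d.bmi_kgm2 > 30, "bmi_category"] == "obese").all()


def test_copula_recovers_target_rank_correlation():
    ms = {"a": MarginalSpec(10, 8, 12, "normal"),
          "b": MarginalSpec(5, 3, 8, "lognormal")}
    tg = pd.DataFrame([[1, -0.5], [-0.5, 1]], index=["a", "b"], columns=["a", "b"])
    rhos = [spearman(c.df["a"], c.df["b"]).rho
            for c in (generate_cohort(500, 500, ms, tg, seed=s)
                      for s in range(8))]
    assert abs(np.mean(rhos) + 0.5) < 0.05


def test_non_psd_target_raises_and_repair_fixes():
    ms = {k: MarginalSpec(1, 0.5, 1.5, "normal") for k in "abc"}
    bad = pd.DataFrame([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]],
                       index=list("abc"), columns=list("abc"))
    with pytest.raises(ValueError, match="positive semi-definite"):
        generate_cohort(10, 10, ms, bad, seed=0)
    c = generate_cohort(10, 10, ms, bad, seed=0, repair=True)
    assert len(c.df) == 20


def test_duplicate_ids_rejected():
    df = pd.DataFrame({"id": ["a", "a"], "sex": ["M", "F"], "x": [1.0, 2.0]})
    with pytest.raises(ValueError, match="unique"):
        CohortTable(df)


def test_lognormal_marginal_needs_positive_quartiles():
    with pytest.raises(ValueError):
        MarginalSpec(0.0, 0.0, 1.0, "lognormal").ppf(np.array([0.5]))
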