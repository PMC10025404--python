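"""Correlation statistics, Zellner–Siow Bayes factors, conditional probability."""

import numpy as np
import pandas as pd
import pytest

from gaeeg.inference import (bf01_correlation, bf01_partial,
                             conditional_probability, correlate,
                             jeffreys_label, partial_correlation,
                             partial_correlation_from_r, pearson,
                             pvalue_from_r)


def romberg_bf10(r, n, p=1, k=14):
    """Independent fixed-grid Romberg quadrature of the g-prior integral.

    Trapezoid sums on dyadically refined uniform grids over u in (0, 1)
    (g = u/(1-u)), then Richardson extrapolation.  Endpoint values use the
    analytic limits of the transformed integrand.
    """
    s = 1.0 - r * r

    def f(u):
        out = np.zeros_like(u)
        inner = (u > 0) & (u < 1)
        g = u[inner] / (1 - u[inner])
        lv = (0.5 * (n - p - 1) * np.log1p(g)
              - 0.5 * (n - 1) * np.log1p(s * g)
              - 1.5 * np.log(g) - n / (2 * g) - 2 * np.log1p(-u[inner]))
        out[inner] = np.exp(lv)
        # u -> 1 limit: s^{-(n-1)/2} * g^{(1-p)/2}; finite only for p = 1
        if p == 1:
            out[u == 1.0] = s ** (-0.5 * (n - 1))
        return out

    table = []
    for i in range(k):
        m = 2**i
        u = np.linspace(0.0, 1.0, m + 1)
        h = 1.0 / m
        vals = f(u)
        t = h * (vals.sum() - 0.5 * vals[0] - 0.5 * vals[-1])
        row = [t]
        for j, prev in enumerate(table[-1] if table else []):
            row.append(row[j] + (row[j] - prev) / (4 ** (j + 1) - 1))
        table.append(row)
    integral = table[-1][-1]
    return np.sqrt(n / (2 * np.pi)) * integral


def test_pearson_perfect_linear_relations():
    x = np.arange(10.0)
    assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pearson(x, -x)[0] == pytest.approx(-1.0)


def test_pearson_degenerate_inputs_raise():
    with pytest.raises(ValueError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson([1.0, 2.0], [1.0, 2.0])


@pytest.mark.parametrize("r,n,expected_p", [(-0.44, 27, 0.02),
                                            (-0.29, 50, 0.04)])
def test_t_transform_pvalues_match_reported_values(r, n, expected_p):
    assert round(pvalue_from_r(r, n), 2) == expected_p


def test_pvalue_invariant_under_affine_transforms():
    rng = np.random.default_rng(4)
    x = rng.normal(size=40)
    y = 0.3 * x + rng.normal(size=40)
    _, p0 = pearson(x, y)
    _, p1 = pearson(3.5 * x - 2.0, -0.7 * y + 11.0)
    assert p1 == pytest.approx(p0, rel=1e-9)


@pytest.mark.parametrize("r,n,expected", [
    (0.04, 27, 6.6), (-0.06, 27, 6.4), (-0.44, 27, 0.5), (-0.29, 50, 1.1),
])
def test_bf01_reproduces_reported_values(r, n, expected):
    assert bf01_correlation(r, n) == pytest.approx(expected, abs=0.3)


def test_bf01_symmetric_in_sign_of_r():
    for r in (0.1, 0.3, 0.6):
        assert bf01_correlation(r, 30) == bf01_correlation(-r, 30)


def test_bf01_matches_romberg_oracle_at_null():
    adaptive = 1.0 / bf01_correlation(0.0, 50)
    oracle = romberg_bf10(0.0, 50)
    assert adaptive == pytest.approx(oracle, rel=1e-4)


def test_bf01_decreasing_in_correlation_strength():
    for n in (20, 50):
        vals = [bf01_correlation(r, n) for r in np.arange(0.0, 0.95, 0.1)]
        assert np.all(np.diff(vals) < 0)


def test_bf01_at_null_increasing_in_sample_size():
    vals = [bf01_correlation(0.0, n) for n in (10, 20, 50, 100, 200)]
    assert np.all(np.diff(vals) > 0)


def test_bf01_input_validation():
    with pytest.raises(ValueError):
        bf01_correlation(1.0, 30)
    with pytest.raises(ValueError):
        bf01_correlation(0.2, 3)


def test_partial_correlation_closed_form_cases():
    assert partial_correlation_from_r(0.0, 0.0, 0.0) == 0.0
    assert partial_correlation_from_r(0.5, 0.5, 0.5) == pytest.approx(1 / 3)


def test_partial_correlation_removes_confounding():
    rng = np.random.default_rng(11)
    n = 10**4
    z = rng.normal(size=n)
    x = 1.5 * z + rng.normal(size=n)
    y = -2.0 * z + rng.normal(size=n)
    r_xy, _ = pearson(x, y)
    assert abs(r_xy) > 0.5
    assert abs(partial_correlation(x, y, z)) < 0.1


def test_residual_method_equals_recursion_for_one_covariate():
    rng = np.random.default_rng(12)
    x, y, z = rng.normal(size=(3, 200))
    r_resid = partial_correlation(x, y, z)
    r_rec = partial_correlation_from_r(pearson(x, y)[0], pearson(x, z)[0],
                                       pearson(y, z)[0])
    assert r_resid == pytest.approx(r_rec, abs=1e-10)


def test_partial_correlation_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(13)
    df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("xyzw"))
    ours = partial_correlation(df.x, df.y, df[["z", "w"]].values)
    theirs = float(pg.partial_corr(df, x="x", y="y",
                                   covar=["z", "w"])["r"].iloc[0])
    assert ours == pytest.approx(theirs, abs=1e-8)


def test_bf01_partial_equal_models_give_unity():
    assert bf01_partial(0.3, 0.3, 40, p=2, p_prime=2) == pytest.approx(1.0)


def test_bf01_partial_matches_romberg_ratio():
    n, p, p_prime = 40, 1, 1
    r2 = 0.2
    ours = bf01_partial(r2, r2, n, p, p_prime)
    oracle = romberg_bf10(np.sqrt(r2), n, p) / romberg_bf10(np.sqrt(r2), n, p)
    assert ours == pytest.approx(1.0 / oracle, rel=1e-4)


def test_bf01_partial_supports_null_for_irrelevant_covariate():
    rng = np.random.default_rng(14)
    bfs = []
    for _ in range(200):
        x = rng.normal(size=50)
        y = 0.8 * x + rng.normal(size=50)
        w = rng.normal(size=50)            # zero true effect
        design = np.column_stack([np.ones(50), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r2_reduced = 1 - np.sum((y - design @ beta) ** 2) / \
            np.sum((y - y.mean()) ** 2)
        design2 = np.column_stack([design, w])
        beta2, *_ = np.linalg.lstsq(design2, y, rcond=None)
        r2_full = 1 - np.sum((y - design2 @ beta2) ** 2) / \
            np.sum((y - y.mean()) ** 2)
        bfs.append(bf01_partial(max(r2_full, r2_reduced), r2_reduced,
                                50, p=1, p_prime=2))
    assert np.median(bfs) > 1.0


def test_quadrature_stable_under_tolerance_halving():
    from gaeeg.inference import _zs_integral
    for r in (0.0, 0.3, 0.6):
        a = _zs_integral(40, 1, 1 - r * r, epsrel=1e-10)
        b = _zs_integral(40, 1, 1 - r * r, epsrel=5e-11)
        assert a == pytest.approx(b, rel=1e-4)


@pytest.mark.parametrize("bf,expected", [
    (6.6, "moderate evidence for H0"),
    (1.5, "anecdotal evidence for H0"),
    (475.0, "decisive evidence for H0"),
    (15.0, "strong evidence for H0"),
    (50.0, "very strong evidence for H0"),
    (0.5, "anecdotal evidence for H1"),
    (0.05, "strong evidence for H1"),
])
def test_jeffreys_labels(bf, expected):
    assert jeffreys_label(bf) == expected


def test_correlate_bundles_simple_and_partial():
    rng = np.random.default_rng(15)
    x, y, z = rng.normal(size=(3, 40))
    simple = correlate(x, y)
    assert simple.kind == "simple" and 0 < simple.bf01
    partial = correlate(x, y, z)
    assert partial.kind == "partial"
    assert -1 <= partial.r <= 1 and partial.bf01 > 0


def test_conditional_probability_counts():
    df = pd.DataFrame({
        "cond": np.r_[np.ones(5), np.zeros(5)],
        "event": np.r_[np.ones(3), np.zeros(7)],
    })
    res = conditional_probability(df, ("cond", 0.5), ("event", 0.5),
                                  condition_is_percentile=False,
                                  event_is_percentile=False)
    assert res.probability == pytest.approx(0.6)
    assert (res.n_condition, res.n_joint) == (5, 3)


def test_conditional_probability_event_superset_gives_one():
    df = pd.DataFrame({"cond": [0, 0, 1, 2, 3], "event": [0, 1, 5, 6, 7]})
    res = conditional_probability(df, ("cond", 0.5), ("event", 0.5),
                                  condition_is_percentile=False,
                                  event_is_percentile=False)
    assert res.probability == 1.0


def test_conditional_probability_independent_features():
    rng = np.random.default_rng(16)
    df = pd.DataFrame({"a": rng.uniform(size=10**4),
                       "b": rng.uniform(size=10**4)})
    res = conditional_probability(df, ("a", 70.0), ("b", 70.0))
    assert res.probability == pytest.approx(0.30, abs=0.05)
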