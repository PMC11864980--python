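"""Statistical primitives against independent textbook-formula and
enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import t as t_dist

from sldep.exceptions import DegenerateInputError, GroupSizeError, ValidationError
from sldep.stats import (
    bh_adjust,
    pearson_columns,
    pearson_correlation,
    student_t_test,
    wilcoxon_rank_sum,
)

# ---------------------------------------------------------------------------
# oracles: written from first principles, independent of the implementation


def t_test_oracle(x, y, tail):
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    df = nx + ny - 2
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    if tail == "left":
        p = t_dist.cdf(t, df)
    elif tail == "right":
        p = t_dist.sf(t, df)
    else:
        p = min(2 * t_dist.sf(abs(t), df), 1.0)
    return t, p


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def ranksum_oracle(x, y, tail):
    """Closed-form rank-sum mean/variance, normal approximation, midranks."""
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = _midranks(list(x) + list(y))
    r1 = sum(ranks[:nx])
    mu = nx * (n + 1) / 2
    sigma = math.sqrt(nx * ny * (n + 1) / 12)
    z = (r1 - mu) / sigma
    phi = lambda v: 0.5 * (1 + math.erf(v / math.sqrt(2)))  # noqa: E731
    if tail == "left":
        p = phi(z)
    elif tail == "right":
        p = 1 - phi(z)
    else:
        p = min(2 * (1 - phi(abs(z))), 1.0)
    return z, p


def ranksum_exact_left_p(x, y):
    """Exact permutation-enumeration left-tail p for tie-free samples."""
    pooled = list(x) + list(y)
    ranks = _midranks(pooled)
    nx = len(x)
    observed = sum(ranks[:nx])
    stats = [
        sum(ranks[i] for i in combo) for combo in itertools.combinations(range(len(pooled)), nx)
    ]
    return sum(s <= observed for s in stats) / len(stats)


def bh_oracle(p):
    """Direct step-up definition: q_i = min over j>=rank(i) of p_(j) * m / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, idx in enumerate(order):
        q[idx] = min(p[order[j]] * (m / (j + 1)) for j in range(pos, m))
    return q


# ---------------------------------------------------------------------------
# Student's t


def test_t_identical_groups_is_centred():
    res = student_t_test([0, 1], [0, 1], tail="left")
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(0.5)
    assert res.effect_size == pytest.approx(0.0)
    assert res.df == 2


def test_t_matches_formula_oracle_on_fixed_example():
    x, y = [-1, -1.2, -0.8], [0, 0.2, -0.2]
    res = student_t_test(x, y, tail="left")
    t, p = t_test_oracle(x, y, "left")
    assert res.effect_size == pytest.approx(-1.0)
    assert res.statistic == pytest.approx(t, abs=1e-12)
    assert res.p_value == pytest.approx(p, abs=1e-12)


@pytest.mark.parametrize("tail", ["left", "right", "two"])
def test_t_matches_oracle_on_random_inputs(rng, tail):
    for _ in range(300):
        nx, ny = rng.integers(2, 12, size=2)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0.3, 1.5, ny)
        res = student_t_test(x, y, tail=tail)
        t, p = t_test_oracle(list(x), list(y), tail)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


def test_t_two_tail_equals_doubled_smaller_one_tail(rng):
    x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
    left = student_t_test(x, y, "left").p_value
    right = student_t_test(x, y, "right").p_value
    two = student_t_test(x, y, "two").p_value
    assert two == pytest.approx(min(1.0, 2 * min(left, right)), abs=1e-12)


def test_t_drops_nonfinite_listwise():
    res = student_t_test([1.0, np.nan, 2.0], [0.0, 1.0, np.inf], tail="two")
    assert (res.n_x, res.n_y) == (2, 2)


def test_t_error_paths():
    with pytest.raises(GroupSizeError):
        student_t_test([1.0], [0.0, 1.0])
    with pytest.raises(DegenerateInputError):
        student_t_test([1.0, 1.0], [1.0, 1.0])
    with pytest.raises(ValidationError):
        student_t_test([0, 1], [0, 1], tail="sideways")


def test_t_null_rejection_rate_is_nominal(rng):
    """Under the global null the left tail rejects at alpha in alpha of sims."""
    n_sim, alpha = 10_000, 0.05
    data = rng.normal(0, 1, size=(n_sim, 10))
    hits = sum(
        student_t_test(row[:5], row[5:], tail="left").p_value < alpha for row in data
    )
    rate = hits / n_sim
    mc_err = 3 * math.sqrt(alpha * (1 - alpha) / n_sim)
    assert abs(rate - alpha) <= mc_err


# ---------------------------------------------------------------------------
# Pearson


def test_pearson_perfect_lines():
    assert pearson_correlation([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
    assert pearson_correlation([1, 2, 3], [6, 4, 2]).r == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula(rng):
    for _ in range(300):
        n = rng.integers(3, 20)
        x = rng.normal(0, 1, n)
        y = 0.4 * x + rng.normal(0, 1, n)
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(pearson_oracle(list(x), list(y)), abs=1e-12)
        assert res.n == n


def test_pearson_pairwise_deletion_and_errors():
    res = pearson_correlation([1, 2, np.nan, 4], [1, 2, 3, 5])
    assert res.n == 3
    with pytest.raises(DegenerateInputError):
        pearson_correlation([1, 1, 1], [1, 2, 3])
    with pytest.raises(GroupSizeError):
        pearson_correlation([1, 2], [1, 2])


def test_pearson_columns_matches_scalar_path(rng):
    """The vectorised column screen agrees with the scalar routine."""
    X = rng.normal(0, 1, size=(30, 15))
    X[rng.random(X.shape) < 0.2] = np.nan
    X[:, 0] = 5.0  # constant -> untested
    y = rng.normal(0, 1, 30)
    r, n, p = pearson_columns(X, y)
    assert np.isnan(r[0]) and np.isnan(p[0])
    for j in range(1, 15):
        keep = np.isfinite(X[:, j]) & np.isfinite(y)
        if keep.sum() < 3:
            assert np.isnan(r[j])
            continue
        ref = pearson_correlation(X[keep, j], y[keep])
        assert r[j] == pytest.approx(ref.r, abs=1e-10)
        assert p[j] == pytest.approx(ref.p_value, abs=1e-10)
        assert n[j] == ref.n


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def test_ranksum_symmetric_tied_input():
    res = wilcoxon_rank_sum([1, 2], [1, 2], tail="left")
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(0.5)


def test_ranksum_matches_closed_form_oracle(rng):
    x, y = [1, 2], [3, 4]
    res = wilcoxon_rank_sum(x, y, tail="left")
    z, p = ranksum_oracle(x, y, "left")
    assert res.statistic == pytest.approx(z, abs=1e-12)
    assert res.p_value == pytest.approx(p, abs=1e-12)
    for tail in ("left", "right", "two"):
        for _ in range(200):
            nx, ny = rng.integers(1, 15, size=2)
            a = rng.normal(0, 1, nx)
            b = rng.normal(0.5, 1, ny)
            got = wilcoxon_rank_sum(a, b, tail=tail)
            z, p = ranksum_oracle(list(a), list(b), tail)
            assert got.statistic == pytest.approx(z, abs=1e-10)
            assert got.p_value == pytest.approx(p, abs=1e-10)


def test_ranksum_normal_approx_close_to_exact_enumeration(rng):
    """Tie-free small samples: approximate p within 0.08 of the exact p."""
    for _ in range(40):
        nx, ny = rng.integers(3, 7, size=2)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0, 1, ny)
        approx = wilcoxon_rank_sum(x, y, tail="left").p_value
        exact = ranksum_exact_left_p(list(x), list(y))
        assert abs(approx - exact) <= 0.08


def test_ranksum_empty_group_errors():
    with pytest.raises(GroupSizeError):
        wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_single_and_stepup_examples():
    assert bh_adjust([0.05]) == pytest.approx([0.05])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_matches_definition_oracle(rng):
    for _ in range(300):
        p = rng.random(int(rng.integers(1, 40)))
        q = bh_adjust(p)
        assert np.array_equal(q, bh_oracle(list(p)))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValidationError):
        bh_adjust([0.5, np.nan])


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=25))
def test_bh_invariants(p):
    q = bh_adjust(p)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all(q <= 1.0)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-15)


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=20),
    st.randoms(use_true_random=False),
)
def test_bh_permutation_equivariance(p, rnd):
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    q = bh_adjust(p)
    q_perm = bh_adjust([p[i] for i in perm])
    assert np.allclose(q_perm, [q[i] for i in perm], rtol=0, atol=0)
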