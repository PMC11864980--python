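"""Statistical primitives shared by every screening stage.

All group-comparison screens in this package reduce to four primitives:
the equal-variance (pooled) two-sample Student's t-test, the Pearson
product-moment correlation, the Wilcoxon rank-sum test under the normal
approximation, and Benjamini–Hochberg step-up adjustment of a p-value
vector. Each is a thin, validated wrapper over the corresponding
``scipy.stats`` routine, with a documented dialect:

* one-tailed p-values come from the signed statistic's own tail (never by
  halving a two-sided p);
* the t-test pools variances (it is the classical Student test, not Welch);
* the rank-sum test uses midranks for ties and the plain normal
  approximation — no tie-variance correction, no continuity correction;
* non-finite observations are dropped listwise within each group (tests)
  or pairwise (correlation).

Tails are spelled ``"left"``, ``"right"`` and ``"two"`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateInputError, GroupSizeError, ValidationError

TAILS = ("left", "right", "two")
_ALTERNATIVE = {"left": "less", "right": "greater", "two": "two-sided"}


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample location test."""

    statistic: float
    p_value: float
    tail: str
    n_x: int
    n_y: int
    df: Optional[float] = None
    effect_size: Optional[float] = None  # mean(x) - mean(y) where defined


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation over complete pairs."""

    r: float
    p_value: float
    n: int


def _check_tail(tail: str) -> str:
    if tail not in TAILS:
        raise ValidationError(f"tail must be one of {TAILS}, got {tail!r}")
    return tail


def _finite(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    return arr[np.isfinite(arr)]


def student_t_test(x, y, tail: str = "left") -> TestResult:
    """Pooled-variance two-sample Student's t-test.

    Non-finite values are dropped listwise within each group. Requires at
    least two finite observations per group and a strictly positive pooled
    variance; the degrees of freedom are ``n_x + n_y - 2`` and the effect
    size is ``mean(x) - mean(y)``.
    """
    _check_tail(tail)
    xa, ya = _finite(x), _finite(y)
    if len(xa) < 2 or len(ya) < 2:
        raise GroupSizeError(
            f"t-test needs >= 2 finite values per group, got {len(xa)} and {len(ya)}"
        )
    df = len(xa) + len(ya) - 2
    pooled = ((len(xa) - 1) * xa.var(ddof=1) + (len(ya) - 1) * ya.var(ddof=1)) / df
    if pooled <= 0.0:
        raise DegenerateInputError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind(xa, ya, equal_var=True, alternative=_ALTERNATIVE[tail])
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        tail=tail,
        n_x=len(xa),
        n_y=len(ya),
        df=float(df),
        effect_size=float(xa.mean() - ya.mean()),
    )


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson product-moment correlation over pairwise-complete observations.

    The two-sided p-value comes from the t transform with ``n - 2`` degrees
    of freedom. Raises :class:`DegenerateInputError` when either vector is
    constant after pairwise deletion (caller may convert to an excluded
    feature) and :class:`GroupSizeError` for fewer than three complete pairs.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.shape != ya.shape:
        raise ValidationError(f"length mismatch: {xa.shape} vs {ya.shape}")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        raise GroupSizeError(f"correlation needs >= 3 complete pairs, got {len(xa)}")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise DegenerateInputError("constant input: correlation undefined")
    res = sps.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(xa))


def wilcoxon_rank_sum(x, y, tail: str = "left") -> TestResult:
    """Wilcoxon rank-sum test, normal approximation.

    Midranks are used for ties; no tie-variance correction and no
    continuity correction are applied (this mirrors the classical
    large-sample rank-sum routine). The statistic is the z-score of the
    first sample's rank sum.
    """
    _check_tail(tail)
    xa, ya = _finite(x), _finite(y)
    if len(xa) == 0 or len(ya) == 0:
        raise GroupSizeError(
            f"rank-sum test needs non-empty groups, got {len(xa)} and {len(ya)}"
        )
    res = sps.ranksums(xa, ya, alternative=_ALTERNATIVE[tail])
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        tail=tail,
        n_x=len(xa),
        n_y=len(ya),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    Satisfies ``q >= p`` elementwise and is monotone non-decreasing along
    the sorted p-values. All inputs must be finite and in [0, 1].
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValidationError("p-values must be finite and within [0, 1]")
    return np.asarray(sps.false_discovery_control(p, method="bh"), dtype=float)


def pearson_columns(X, y):
    """Column-wise pairwise-complete Pearson correlation of ``X`` against ``y``.

    Vectorised workhorse behind the feature- and site-association screens.

    Parameters
    ----------
    X : (n_obs, n_cols) array-like, NaN = missing
    y : (n_obs,) array-like, NaN = missing

    Returns
    -------
    r, n, p : arrays of length n_cols
        ``r`` and ``p`` are NaN for columns that are untestable (fewer than
        three complete pairs, or either side constant on the complete pairs).
        ``p`` is the two-sided t-transform p-value; exactly 0.0 when |r| = 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError(f"shape mismatch: X {X.shape} vs y {y.shape}")
    # centring on the grand means keeps the sufficient-statistic algebra
    # well conditioned without a per-column second pass
    ym = np.nanmean(y) if np.isfinite(y).any() else 0.0
    with np.errstate(invalid="ignore"):
        Xc = X - np.nanmean(np.where(np.isfinite(X), X, np.nan))
    yc = y - ym
    W = np.isfinite(Xc) & np.isfinite(yc)[:, None]
    n = W.sum(axis=0)
    Xw = np.where(W, Xc, 0.0)
    Yw = np.where(W, yc[:, None], 0.0)
    sx, sy = Xw.sum(axis=0), Yw.sum(axis=0)
    sxx = np.einsum("ij,ij->j", Xw, Xw)
    syy = np.einsum("ij,ij->j", Yw, Yw)
    sxy = np.einsum("ij,ij->j", Xw, Yw)
    with np.errstate(invalid="ignore", divide="ignore"):
        nf = n.astype(float)
        cov = nf * sxy - sx * sy
        vx = nf * sxx - sx**2
        vy = nf * syy - sy**2
        # constancy must be decided on the raw values, not the centred sums,
        # which can carry rounding residue for a constant column
        x_spread = np.where(W, Xc, -np.inf).max(axis=0) > np.where(W, Xc, np.inf).min(axis=0)
        y_spread = np.where(W, yc[:, None], -np.inf).max(axis=0) > np.where(
            W, yc[:, None], np.inf
        ).min(axis=0)
        ok = (n >= 3) & (vx > 0) & (vy > 0) & x_spread & y_spread
        r = np.where(ok, cov / np.sqrt(np.where(ok, vx * vy, 1.0)), np.nan)
        r = np.clip(r, -1.0, 1.0)
        df = nf - 2.0
        rr = np.minimum(r * r, 1.0)
        t = r * np.sqrt(df / (1.0 - rr))
        p = 2.0 * sps.t.sf(np.abs(t), df)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        p = np.where(ok, np.minimum(p, 1.0), np.nan)
    return r, n.astype(int), p
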