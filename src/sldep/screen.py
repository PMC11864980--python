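"""Genome-wide differential-dependency screening.

Given a models × genes matrix of CRISPR gene-effect scores (Chronos scale:
0 at the negative-control median, −1 at the pan-essential median) and a
binary biomarker labelling of the models, every gene is tested for a shift
in dependency between biomarker-positive and biomarker-negative models with
a pooled-variance Student's t-test — left-tailed by default, because a
synthetic-lethal gene is *more* essential (more negative) in the positive
group. P-values are Benjamini–Hochberg adjusted across all tested genes of
one screen.

``threshold_sweep`` repeats the screen over a grid of region copy-number
thresholds (default 0.2–0.6 in steps of 0.1), re-deriving the positive
group at each threshold, to show that a hit is not an artefact of one
deletion cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, ValidationError
from .regions import STATUS_DELETED, call_region_status
from .stats import TAILS, bh_adjust

SCREEN_COLUMNS = ["gene", "effect_size", "statistic", "p_value", "q_value", "n_pos", "n_neg", "tested"]

POSITIVE = "positive"
NEGATIVE = "negative"


def _group_moments(values: np.ndarray, rows: np.ndarray):
    """Per-column count, mean and unbiased variance over ``rows``, NaN-aware."""
    mask = np.isfinite(values) & rows[:, None]
    n = mask.sum(axis=0)
    s = np.where(mask, values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        dev = np.where(mask, values - mean[None, :], 0.0)
        var = np.einsum("ij,ij->j", dev, dev) / np.where(n > 1, n - 1, 1)
    return n, mean, var


def _tail_p(t: np.ndarray, df: np.ndarray, tail: str) -> np.ndarray:
    if tail == "left":
        return sps.t.cdf(t, df)
    if tail == "right":
        return sps.t.sf(t, df)
    return np.minimum(2.0 * sps.t.sf(np.abs(t), df), 1.0)


def differential_dependency_screen(
    dep: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    tail: str = "left",
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Per-gene two-group t-test with BH adjustment across the screen.

    Parameters
    ----------
    dep : DataFrame, models (rows) × genes (columns); NaN = missing.
    labels : mapping model id -> "positive" | "negative". Models absent
        from the mapping are ignored.
    tail : test tail; "left" finds genes more essential in positives.
    min_group_size : per-gene floor on complete cases in *each* group;
        genes below it (or with zero pooled variance) are emitted as
        untested rows with NaN statistics, so the output always has one row
        per input gene.

    Returns
    -------
    DataFrame with columns ``gene, effect_size, statistic, p_value,
    q_value, n_pos, n_neg, tested``; tested rows first, sorted ascending by
    (q, p), then untested rows sorted by gene name.
    """
    if tail not in TAILS:
        raise ValidationError(f"tail must be one of {TAILS}")
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    bad = set(labels.unique()) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValidationError(f"unknown labels {sorted(bad)}")
    models = dep.index.intersection(labels.index)
    pos_models = models[labels.loc[models] == POSITIVE]
    neg_models = models[labels.loc[models] == NEGATIVE]
    if len(pos_models) < min_group_size or len(neg_models) < min_group_size:
        raise ConfigurationError(
            f"group sizes {len(pos_models)}/{len(neg_models)} below min_group_size={min_group_size}"
        )
    sub = dep.loc[models]
    values = sub.to_numpy(dtype=float)
    is_pos = sub.index.isin(pos_models)
    n1, m1, v1 = _group_moments(values, is_pos)
    n2, m2, v2 = _group_moments(values, ~is_pos)

    df = (n1 + n2 - 2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
    tested = (n1 >= min_group_size) & (n2 >= min_group_size) & (pooled > 0)
    p = np.full(values.shape[1], np.nan)
    if tested.any():
        p[tested] = _tail_p(t[tested], df[tested], tail)
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    out = pd.DataFrame(
        {
            "gene": dep.columns,
            "effect_size": np.where(tested, m1 - m2, np.nan),
            "statistic": np.where(tested, t, np.nan),
            "p_value": p,
            "q_value": q,
            "n_pos": n1,
            "n_neg": n2,
            "tested": tested,
        }
    )
    done = out[out["tested"]].sort_values(["q_value", "p_value", "gene"], kind="mergesort")
    rest = out[~out["tested"]].sort_values("gene", kind="mergesort")
    return pd.concat([done, rest]).reset_index(drop=True)


@dataclass
class SweepEntry:
    """One threshold's screen in a copy-number threshold sweep."""

    threshold: float
    n_pos: int
    n_neg: int
    skipped: bool
    table: Optional[pd.DataFrame]


def labels_from_region_values(region_values: pd.Series, threshold: float) -> pd.Series:
    """Positive = region value strictly below the deletion threshold."""
    finite = region_values.dropna()
    calls = [call_region_status(v, threshold) for v in finite]
    return pd.Series(
        [POSITIVE if c == STATUS_DELETED else NEGATIVE for c in calls], index=finite.index
    )


def threshold_sweep(
    dep: pd.DataFrame,
    region_values: pd.Series,
    thresholds: Iterable[float] = (0.2, 0.3, 0.4, 0.5, 0.6),
    tail: str = "left",
    min_group_size: int = 5,
) -> Dict[float, SweepEntry]:
    """Differential-dependency screen at each copy-number threshold.

    BH adjustment is applied within each threshold's screen independently.
    Thresholds whose positive group is smaller than ``min_group_size`` are
    flagged and skipped rather than raising.
    """
    thresholds = [float(t) for t in thresholds]
    if any(t <= 0 for t in thresholds) or sorted(thresholds) != thresholds:
        raise ValidationError("thresholds must be strictly positive and sorted ascending")
    out: Dict[float, SweepEntry] = {}
    for thr in thresholds:
        labels = labels_from_region_values(region_values, thr)
        n_pos = int((labels == POSITIVE).sum())
        n_neg = int((labels == NEGATIVE).sum())
        if n_pos < min_group_size or n_neg < min_group_size:
            out[thr] = SweepEntry(thr, n_pos, n_neg, skipped=True, table=None)
            continue
        table = differential_dependency_screen(dep, labels, tail=tail, min_group_size=min_group_size)
        out[thr] = SweepEntry(thr, n_pos, n_neg, skipped=False, table=table)
    return out


def read_dependency_csv(path) -> pd.DataFrame:
    """Models × genes gene-effect matrix (CSV, first column = model id)."""
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValidationError("duplicate model or gene identifiers in dependency matrix")
    return df.astype(float)


def read_labels_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"ModelID", "Label"}.issubset(df.columns):
        raise ValidationError("labels TSV needs columns ModelID, Label")
    return pd.Series(df["Label"].values, index=df["ModelID"].values)
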