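"""Univariate biomarker association and composite biomarker calls.

Once a candidate dependency (a single gene's profile across models) is in
hand, the questions are: which omics features track it, and which models
should be called biomarker-positive? The feature matrix concatenates
expression, gene-level copy number, genomic signatures and protein
abundance into one models × features table (feature names namespaced as
``<type>:<name>``), dropping any feature measured in fewer than ten models.
Each retained feature is correlated with the target dependency by
pairwise-complete Pearson within a chosen model subset, with BH adjustment
across the tested features.

The composite biomarker of the motivating analysis is a logical OR of a
region deletion (relative copy number < 0.4) and a microsatellite
contraction (weighted repeat length <= 9 units at the causal site, i.e. at
least two unit deletions from the 11-unit reference). A derived protein
feature — the minimum abundance across the members of a complex, here the
SKI complex — captures the fact that losing any one subunit destabilises
the whole complex.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .stats import bh_adjust, pearson_columns

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("expression", "copy_number", "signature", "protein")
MIN_MODELS_PER_FEATURE = 10

ASSOCIATION_COLUMNS = ["feature", "feature_type", "r", "n", "p_value", "q_value", "tested"]


def assemble_feature_matrix(
    sources: Sequence[Tuple[pd.DataFrame, str]],
    min_models: int = MIN_MODELS_PER_FEATURE,
) -> pd.DataFrame:
    """Concatenate typed omics matrices into one models × features table.

    Each source is ``(DataFrame models × features, feature_type)``; feature
    names are namespaced as ``<type>:<name>``. Features measured in fewer
    than ``min_models`` models are dropped (count logged). Model indexes
    are outer-joined.
    """
    if not sources:
        logger.warning("assemble_feature_matrix called with no sources; empty matrix")
        return pd.DataFrame()
    frames = []
    for matrix, ftype in sources:
        if ftype not in FEATURE_TYPES:
            raise ValidationError(f"unknown feature type {ftype!r}; expected one of {FEATURE_TYPES}")
        renamed = matrix.rename(columns={c: f"{ftype}:{c}" for c in matrix.columns})
        frames.append(renamed.astype(float))
    merged = pd.concat(frames, axis=1, join="outer")
    if merged.columns.duplicated().any():
        dups = sorted(set(merged.columns[merged.columns.duplicated()]))
        raise ValidationError(f"duplicate feature names after namespacing: {dups[:5]}")
    measured = merged.notna().sum(axis=0)
    keep = measured >= min_models
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d features measured in fewer than %d models", n_dropped, min_models)
    return merged.loc[:, keep]


def feature_type_of(feature: str) -> str:
    return feature.split(":", 1)[0] if ":" in feature else ""


def univariate_association(
    features: pd.DataFrame,
    target: pd.Series,
    model_subset: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Pairwise-complete Pearson of every feature against a target profile.

    Restricted to ``model_subset`` when given (e.g. the region-intact
    models). Constant or under-observed features are reported as untested
    rows with NaN statistics and excluded from the BH denominator. Output
    is sorted by q then |r| descending, untested features last.
    """
    if model_subset is not None:
        subset = pd.Index(model_subset)
        missing = subset.difference(features.index.union(target.index))
        if len(missing) == len(subset):
            raise ValidationError("model subset shares no models with the inputs")
        features = features.reindex(subset)
        target = target.reindex(subset)
    else:
        common = features.index.intersection(target.index)
        features = features.loc[common]
        target = target.loc[common]
    if target.notna().sum() < 3:
        raise ValidationError("target has fewer than 3 measured models in the subset")
    r, n, p = pearson_columns(features.to_numpy(dtype=float), target.to_numpy(dtype=float))
    tested = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    n_const = int((~tested).sum())
    if n_const:
        logger.info("%d features untested (constant or <3 complete pairs)", n_const)
    out = pd.DataFrame(
        {
            "feature": features.columns,
            "feature_type": [feature_type_of(c) for c in features.columns],
            "r": r,
            "n": n,
            "p_value": p,
            "q_value": q,
            "tested": tested,
        }
    )
    out["_absr"] = -np.abs(out["r"])
    done = out[out["tested"]].sort_values(["q_value", "_absr", "feature"], kind="mergesort")
    rest = out[~out["tested"]].sort_values("feature", kind="mergesort")
    return pd.concat([done, rest]).drop(columns="_absr").reset_index(drop=True)


def complex_min_feature(protein: pd.DataFrame, members: Sequence[str]) -> pd.Series:
    """Per-model minimum protein level across complex members.

    Missing whenever any member is unmeasured for that model — the minimum
    of a partially observed set is not identifiable.
    """
    unknown = [m for m in members if m not in protein.columns]
    if unknown:
        raise ValidationError(f"unknown complex members: {unknown}")
    if not members:
        raise ValidationError("members list is empty")
    return protein[list(members)].min(axis=1, skipna=False)


def call_biomarker_status(
    focad_region_cn: Mapping[str, float] | pd.Series,
    ttc37_site_length: Mapping[str, float] | pd.Series,
    cn_threshold: float = 0.4,
    repeat_threshold: float = 9.0,
) -> pd.DataFrame:
    """Composite biomarker call: region deletion OR microsatellite contraction.

    ``focad_deleted`` iff region copy-number value < ``cn_threshold``
    (strict); ``ttc37_contracted`` iff weighted repeat length <=
    ``repeat_threshold``; ``positive`` is their OR. Models missing a
    measurement are negative for that arm of the OR.
    """
    if cn_threshold <= 0 or repeat_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    cn = pd.Series(focad_region_cn, dtype=float)
    length = pd.Series(ttc37_site_length, dtype=float)
    models = cn.index.union(length.index).sort_values()
    cn = cn.reindex(models)
    length = length.reindex(models)
    focad_deleted = (cn < cn_threshold).fillna(False)
    ttc37_contracted = (length <= repeat_threshold).fillna(False)
    return pd.DataFrame(
        {
            "model_id": models,
            "focad_deleted": focad_deleted.values.astype(bool),
            "ttc37_contracted": ttc37_contracted.values.astype(bool),
            "positive": (focad_deleted | ttc37_contracted).values.astype(bool),
        }
    ).reset_index(drop=True)
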