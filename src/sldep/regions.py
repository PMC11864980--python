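"""Cytoband-level copy number from segment-level calls.

A cell model's relative copy number over a named genomic region (for the
motivating analysis, the 9p21.3 cytoband, chr9:19,900,000-25,600,000) is the
overlap-length-weighted average of the linear copy ratios of the segments
intersecting the region, log-transformed with a pseudocount of one,
``log2(ratio + 1)``. A model is called homozygously *deleted* for the region
when that value falls strictly below a threshold (default 0.4, the dashed
line of the motivating analysis); models whose segments cover too little of
the region are reported *missing* rather than guessed.

Coordinates are 0-based half-open. Averaging is performed on the linear
ratio and the log transform applied afterwards; the weighted mean is
normalised by covered length, not region length, so segmentation gaps do
not drag the estimate toward zero.

Segment tables use the SEG-like TSV dialect with header columns
``ModelID, Chromosome, Start, End, CopyRatio`` (linear ratio; 1.0 = normal
diploid dosage).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

SEG_COLUMNS = ["ModelID", "Chromosome", "Start", "End", "CopyRatio"]

STATUS_DELETED = "deleted"
STATUS_INTACT = "intact"
STATUS_MISSING = "missing"

_REGION_RE = re.compile(r"^(?:(?P<name>[\w.\-]+)=)?(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class GenomicRegion:
    """A named genomic interval, 0-based half-open."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"region {self.name}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        """Parse ``[name=]chrom:start-end`` (e.g. ``9p21.3=chr9:19900000-25600000``)."""
        m = _REGION_RE.match(text.strip())
        if not m:
            raise ValidationError(f"cannot parse region {text!r}; expected [name=]chrom:start-end")
        name = m.group("name") or f"{m.group('chrom')}:{m.group('start')}-{m.group('end')}"
        return cls(name, m.group("chrom"), int(m.group("start")), int(m.group("end")))


def read_seg(path, log2_input: bool = False) -> pd.DataFrame:
    """Read a SEG-like TSV of segment-level copy ratios.

    With ``log2_input=True`` the CopyRatio column is interpreted as
    ``log2(ratio + 1)`` values and converted back to the linear scale.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"ModelID": str, "Chromosome": str})
    except Exception as exc:  # noqa: BLE001 - surface as a parse error with path
        raise ParseError(str(exc), path=path) from exc
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns {missing}", path=path)
    df = df[SEG_COLUMNS].copy()
    for col in ("Start", "End", "CopyRatio"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df[["Start", "End", "CopyRatio"]].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ParseError(f"unparseable numeric fields on line(s) {[int(i) + 2 for i in bad[:5]]}", path=path)
    if log2_input:
        df["CopyRatio"] = np.exp2(df["CopyRatio"]) - 1.0
    validate_segments(df)
    return df


def write_seg(df: pd.DataFrame, path) -> None:
    df[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_segments(df: pd.DataFrame) -> None:
    """Check segment invariants: start < end, ratio >= 0, no intra-model overlap."""
    if (df["Start"] >= df["End"]).any():
        raise ValidationError("segments with Start >= End present")
    if (df["CopyRatio"] < 0).any():
        raise ValidationError("negative copy ratios present")
    s = df.sort_values(["ModelID", "Chromosome", "Start"])
    same = (s["ModelID"].values[1:] == s["ModelID"].values[:-1]) & (
        s["Chromosome"].values[1:] == s["Chromosome"].values[:-1]
    )
    overlap = same & (s["Start"].values[1:] < s["End"].values[:-1])
    if overlap.any():
        models = sorted(set(s["ModelID"].values[1:][overlap]))
        raise ValidationError(f"overlapping segments within model(s) {models[:5]}")


def log2_plus1(ratio):
    """``log2(ratio + 1)`` — the pseudocount-1 log transform of a linear copy ratio."""
    arr = np.asarray(ratio, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValidationError("copy ratio must be non-negative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(ratio) or arr.ndim == 0 else out


def call_region_status(value: float, threshold: float) -> str:
    """Deleted iff ``value < threshold`` (strictly); intact otherwise."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if not np.isfinite(value):
        return STATUS_MISSING
    return STATUS_DELETED if value < threshold else STATUS_INTACT


def weighted_region_ratio(segments: pd.DataFrame, region: GenomicRegion):
    """Overlap-weighted mean linear copy ratio of one model over ``region``.

    Returns ``(ratio, covered_fraction)``; ``ratio`` is NaN when no segment
    overlaps the region. Segments must belong to a single model.
    """
    if segments["ModelID"].nunique() > 1:
        raise ValidationError("weighted_region_ratio expects segments of a single model")
    validate_segments(segments)
    chrom = segments[segments["Chromosome"] == region.chromosome]
    if chrom.empty:
        return float("nan"), 0.0
    ov = np.minimum(chrom["End"].values, region.end) - np.maximum(chrom["Start"].values, region.start)
    ov = np.clip(ov, 0, None).astype(float)
    total = ov.sum()
    if total == 0:
        return float("nan"), 0.0
    ratio = float((chrom["CopyRatio"].values * ov).sum() / total)
    return ratio, float(total / region.length)


def region_cn_table(
    segments: pd.DataFrame,
    region: GenomicRegion,
    threshold: float = 0.4,
    coverage_floor: float = 0.5,
) -> pd.DataFrame:
    """Per-model region copy number and deletion call.

    Returns a DataFrame with one row per model in the segment table, sorted
    by model id, columns ``model_id, region, value, covered_fraction,
    status``. ``value`` is ``log2(weighted ratio + 1)`` (NaN with zero
    overlap). Models whose covered fraction is below ``coverage_floor`` get
    status ``missing``: the value is still reported when computable, only
    the deletion call is withheld.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    validate_segments(segments)
    columns = ["model_id", "region", "value", "covered_fraction", "status"]
    if segments.empty:
        return pd.DataFrame(columns=columns)
    models = np.sort(segments["ModelID"].unique())
    chrom = segments[segments["Chromosome"] == region.chromosome]
    ov = np.minimum(chrom["End"].values, region.end) - np.maximum(chrom["Start"].values, region.start)
    ov = np.clip(ov, 0, None).astype(float)
    grp = pd.DataFrame(
        {"ModelID": chrom["ModelID"].values, "w": ov, "wr": ov * chrom["CopyRatio"].values}
    ).groupby("ModelID")[["w", "wr"]].sum()
    grp = grp.reindex(models, fill_value=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(grp["w"].values > 0, grp["wr"].values / grp["w"].values, np.nan)
    covered = grp["w"].values / region.length
    value = np.log2(ratio + 1.0)
    with np.errstate(invalid="ignore"):
        status = np.where(
            (covered < coverage_floor) | ~np.isfinite(value),
            STATUS_MISSING,
            np.where(value < threshold, STATUS_DELETED, STATUS_INTACT),
        )
    return pd.DataFrame(
        {
            "model_id": models,
            "region": region.name,
            "value": value,
            "covered_fraction": covered,
            "status": status,
        }
    ).reset_index(drop=True)
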