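"""Microsatellite repeat-length inference and site-level association.

Tumour sequencing pipelines emit, per sample, a histogram of observed
repeat lengths for each catalogued microsatellite site. The weighted mean
of that histogram is a useful one-number summary of the site's repeat
length in the sample; stacking it over samples gives a sites × models
matrix. From that matrix this module derives:

* a per-model MSI score — the percentage of evaluated sites whose weighted
  length deviates from the catalogue reference by at least a threshold
  (default 0.5 repeat units), with MSI-high called above a score of 20.
  This deviation rule is a documented proxy for the upstream per-site
  classifier of MSIsensor-style callers, which is out of scope here;
* a site-level Pearson association of repeat length with a target
  dependency profile, typically restricted to the MSI-high models, to
  locate the causal site of a repeat-length-linked dependency.

On-disk dialect (the real caller's per-version formats vary, so this
package defines one reference dialect and keeps the reader pluggable): one
file per model named ``<ModelID>.dis``, consisting of two-line records —

    chr5 95507014-95507025 T 11
    9:3 10:12 11:85

i.e. a header line ``chromosome span repeat_unit reference_length`` and a
counts line of whitespace-separated ``length:read_count`` pairs (a single
``-`` denotes a site with no reads). Blank lines and ``#`` comments are
allowed between records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .biomarkers import univariate_association
from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

MSI_SCORE_CUTOFF = 20.0  # score strictly above => MSI-H
DEVIATION_THRESHOLD = 0.5  # repeat units; |weighted - reference| >= this => modified site


@dataclass(frozen=True)
class MicrosatelliteSite:
    """A catalogued microsatellite locus."""

    site_id: str  # "chrom:start-end"
    reference_length: int  # repeat units in the reference genome
    repeat_unit: str

    def __post_init__(self):
        if self.reference_length < 1:
            raise ValidationError(f"site {self.site_id}: reference length must be >= 1")


@dataclass(frozen=True)
class RepeatLengthDistribution:
    """Read-support histogram over repeat lengths at one site in one model."""

    site: MicrosatelliteSite
    counts: Mapping[int, int]  # repeat length -> read count

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))


def weighted_mean_length(dist: RepeatLengthDistribution) -> float:
    """Read-count-weighted mean repeat length; NaN when the site has no reads."""
    total = dist.total_reads
    if total <= 0:
        return float("nan")
    return float(sum(length * count for length, count in dist.counts.items()) / total)


def parse_site_distributions(path) -> List[RepeatLengthDistribution]:
    """Parse one model's ``.dis`` file (dialect in the module docstring)."""
    records: List[RepeatLengthDistribution] = []
    header: Optional[Tuple[MicrosatelliteSite, int]] = None
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                fields = line.split()
                if len(fields) != 4:
                    raise ParseError(
                        f"expected 'chrom span unit ref_length', got {line!r}", path, lineno
                    )
                chrom, span, unit, ref = fields
                try:
                    ref_length = int(ref)
                except ValueError:
                    raise ParseError(f"reference length {ref!r} is not an integer", path, lineno)
                try:
                    site = MicrosatelliteSite(f"{chrom}:{span}", ref_length, unit)
                except ValidationError as exc:
                    raise ParseError(str(exc), path, lineno)
                header = (site, lineno)
            else:
                site, _ = header
                counts: Dict[int, int] = {}
                for token in line.split() if line != "-" else ():
                    try:
                        length_s, count_s = token.split(":")
                        length, count = int(length_s), int(count_s)
                    except ValueError:
                        raise ParseError(f"bad length:count token {token!r}", path, lineno)
                    if length < 0 or count < 0:
                        raise ParseError(f"negative length or count in {token!r}", path, lineno)
                    counts[length] = counts.get(length, 0) + count
                dist = RepeatLengthDistribution(site, counts)
                if dist.total_reads == 0:
                    logger.warning("%s:%d: site %s has zero reads", path, lineno, site.site_id)
                records.append(dist)
                header = None
    if header is not None:
        raise ParseError(f"truncated record for site {header[0].site_id}", path, header[1])
    if not records:
        logger.warning("%s: empty distribution file", path)
    return records


def write_site_distributions(dists: Iterable[RepeatLengthDistribution], path) -> None:
    """Write records in the reference dialect (inverse of the parser)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for dist in dists:
            chrom, span = dist.site.site_id.split(":", 1)
            fh.write(f"{chrom} {span} {dist.site.repeat_unit} {dist.site.reference_length}\n")
            pairs = " ".join(f"{l}:{c}" for l, c in sorted(dist.counts.items()))
            fh.write((pairs or "-") + "\n")


@dataclass
class SiteLengthMatrix:
    """Sites × models weighted-mean repeat lengths plus site metadata."""

    lengths: pd.DataFrame  # index site_id, columns model ids; NaN = no reads
    sites: pd.DataFrame  # index site_id; columns reference_length, repeat_unit

    def __post_init__(self):
        if not self.lengths.index.equals(self.sites.index):
            raise ValidationError("lengths and sites indexes disagree")


def build_site_matrix(
    per_model: Mapping[str, Sequence[RepeatLengthDistribution]],
) -> SiteLengthMatrix:
    """Aggregate per-model distributions into a sites × models length matrix.

    Site and model orderings are deterministic (sorted). A model lacking
    reads (or a record) at a site yields a missing entry, never a dropped
    row. Conflicting reference lengths or repeat units for one site id
    raise a validation error.
    """
    meta: Dict[str, MicrosatelliteSite] = {}
    columns: Dict[str, Dict[str, float]] = {}
    for model_id in sorted(per_model):
        col: Dict[str, float] = {}
        for dist in per_model[model_id]:
            site = dist.site
            known = meta.get(site.site_id)
            if known is None:
                meta[site.site_id] = site
            elif (known.reference_length, known.repeat_unit) != (
                site.reference_length,
                site.repeat_unit,
            ):
                raise ValidationError(
                    f"conflicting metadata for site {site.site_id}: "
                    f"{(known.reference_length, known.repeat_unit)} vs "
                    f"{(site.reference_length, site.repeat_unit)}"
                )
            col[site.site_id] = weighted_mean_length(dist)
        columns[model_id] = col
    site_ids = sorted(meta)
    lengths = pd.DataFrame(
        {m: pd.Series(columns[m]).reindex(site_ids) for m in sorted(columns)}, index=site_ids
    )
    sites = pd.DataFrame(
        {
            "reference_length": [meta[s].reference_length for s in site_ids],
            "repeat_unit": [meta[s].repeat_unit for s in site_ids],
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    return SiteLengthMatrix(lengths=lengths, sites=sites)


def msi_score(
    matrix: SiteLengthMatrix,
    deviation_threshold: float = DEVIATION_THRESHOLD,
    score_cutoff: float = MSI_SCORE_CUTOFF,
) -> pd.DataFrame:
    """Per-model MSI score and MSI-H call.

    A site is *modified* for a model when its weighted length deviates from
    the reference by at least ``deviation_threshold`` repeat units; the
    score is 100 × modified / evaluated sites, and MSI-H means score
    strictly above ``score_cutoff``. Models with zero evaluated sites get a
    missing (NaN) score and a null call.
    """
    if deviation_threshold <= 0:
        raise ValidationError("deviation_threshold must be positive")
    ref = matrix.sites["reference_length"].to_numpy(dtype=float)[:, None]
    lengths = matrix.lengths.to_numpy(dtype=float)
    evaluated = np.isfinite(lengths)
    modified = evaluated & (np.abs(lengths - ref) >= deviation_threshold)
    n_eval = evaluated.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_eval > 0, 100.0 * modified.sum(axis=0) / n_eval, np.nan)
    is_msih = pd.array(score > score_cutoff, dtype="boolean")
    is_msih[n_eval == 0] = pd.NA
    return pd.DataFrame(
        {
            "model_id": matrix.lengths.columns,
            "score": score,
            "n_sites_evaluated": n_eval,
            "is_msih": is_msih,
        }
    ).reset_index(drop=True)


def site_dependency_association(
    matrix: SiteLengthMatrix,
    target: pd.Series,
    subset: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Pearson association of every site's repeat length with a dependency.

    ``subset`` is typically the MSI-high models; raw weighted lengths are
    correlated (no reference normalisation). Returns the standard
    association table sorted by q, constant sites reported untested.
    """
    models_by_sites = matrix.lengths.T
    out = univariate_association(models_by_sites, target, model_subset=subset)
    out = out.rename(columns={"feature": "site_id"})
    return out.drop(columns="feature_type")
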