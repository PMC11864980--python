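"""Anchor-vs-control modifier-screen analysis.

A modifier screen runs the same guide library through parallel arms — a
control arm and one or more *sensitized* arms carrying an anchor
perturbation (here, knockdown of the candidate dependency gene) — and asks
which genes' loss changes fitness only in the sensitized background.

Analysis steps, in order:

1. ``normalize_and_lfc``: reads-per-million per sample, then per-guide
   log2 fold change against the plasmid-DNA (pDNA) reference with a
   pseudocount.
2. ``arm_difference``: ΔLFC = LFC(sensitized) − LFC(control) per guide,
   matched by replicate and day.
3. ``gene_set_rank_test`` / ``modifier_gene_table``: left-tailed Wilcoxon
   rank-sum of a gene's ΔLFC observations (guide × replicate × arm) against
   all other guides' observations — a modifier whose loss rescues/kills
   specifically in the sensitized arms separates from the bulk.
4. ``scale_gene_effects``: per-arm gene effects (mean guide LFC — a
   deliberately simple estimator; full count-model deconvolution is out of
   scope) anchored so the negative-control median is exactly 0 and the
   positive-control (pan-essential) median exactly −1.

Sample metadata lives in a sample sheet with columns ``sample_id, arm,
replicate, day, is_pdna``; guide→gene mapping in a chip-style table
``guide_id, target, target_class`` with classes ``gene``,
``negative_control`` and ``positive_control``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateInputError, ValidationError
from .stats import TestResult, bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

CLASS_GENE = "gene"
CLASS_NEG = "negative_control"
CLASS_POS = "positive_control"
GUIDE_CLASSES = (CLASS_GENE, CLASS_NEG, CLASS_POS)

SAMPLE_SHEET_COLUMNS = ["sample_id", "arm", "replicate", "day", "is_pdna"]


def read_chip(path) -> pd.DataFrame:
    chip = pd.read_csv(path, sep="\t", dtype=str)
    if not {"guide_id", "target", "target_class"}.issubset(chip.columns):
        raise ValidationError("chip TSV needs columns guide_id, target, target_class")
    return validate_chip(chip)


def validate_chip(chip: pd.DataFrame) -> pd.DataFrame:
    if chip["guide_id"].duplicated().any():
        raise ValidationError("duplicate guide identifiers in chip table")
    bad = set(chip["target_class"]) - set(GUIDE_CLASSES)
    if bad:
        raise ValidationError(f"unknown target classes {sorted(bad)}")
    return chip


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns {missing}")
    sheet["is_pdna"] = sheet["is_pdna"].astype(bool)
    return sheet


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative counts in count matrix")
    return counts


def normalize_and_lfc(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-guide log2 fold change of each sample against the pDNA reference.

    Counts are scaled to reads per million within each sample, then
    ``LFC = log2((rpm_sample + pc) / (rpm_pdna + pc))``. With one flagged
    pDNA sample it references every screen sample; with one pDNA per
    replicate, samples are referenced within their replicate.
    """
    if pseudocount < 1:
        raise ValidationError("pseudocount must be >= 1")
    unknown = set(sample_sheet["sample_id"]) - set(counts.columns)
    if unknown:
        raise ValidationError(f"sample sheet references unknown samples {sorted(unknown)[:5]}")
    totals = counts[sample_sheet["sample_id"]].sum(axis=0)
    dead = totals.index[totals <= 0]
    if len(dead):
        raise ValidationError(f"zero-depth sample(s): {list(dead)}")
    rpm = counts[sample_sheet["sample_id"]] * (1e6 / totals)

    pdna = sample_sheet[sample_sheet["is_pdna"]]
    screens = sample_sheet[~sample_sheet["is_pdna"]]
    if len(pdna) == 0:
        raise ConfigurationError("no pDNA reference sample flagged")
    lfc = {}
    if len(pdna) == 1:
        ref = rpm[pdna["sample_id"].iloc[0]]
        for sid in screens["sample_id"]:
            lfc[sid] = np.log2((rpm[sid] + pseudocount) / (ref + pseudocount))
    elif pdna["replicate"].is_unique and set(screens["replicate"]) <= set(pdna["replicate"]):
        ref_by_rep = {row.replicate: rpm[row.sample_id] for row in pdna.itertuples()}
        for row in screens.itertuples():
            ref = ref_by_rep[row.replicate]
            lfc[row.sample_id] = np.log2((rpm[row.sample_id] + pseudocount) / (ref + pseudocount))
    else:
        raise ConfigurationError(
            "pDNA flags must mark exactly one sample, or one per replicate covering all replicates"
        )
    return pd.DataFrame(lfc, index=counts.index)


def arm_difference(
    lfc: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    sensitized_arm: str,
    control_arm: str,
    day: Optional[int] = None,
) -> pd.DataFrame:
    """Per-guide, per-replicate ΔLFC between a sensitized arm and the control arm.

    Samples are matched on (replicate, day); pass ``day`` to restrict to a
    single timepoint. Returns a long DataFrame with columns ``guide_id,
    replicate, day, arm, delta_lfc``. Unmatched replicates are logged;
    zero matches raise a configuration error.
    """
    sheet = sample_sheet[~sample_sheet["is_pdna"]]
    if day is not None:
        sheet = sheet[sheet["day"] == day]
    sens = sheet[sheet["arm"] == sensitized_arm].set_index(["replicate", "day"])["sample_id"]
    ctrl = sheet[sheet["arm"] == control_arm].set_index(["replicate", "day"])["sample_id"]
    if sens.index.duplicated().any() or ctrl.index.duplicated().any():
        raise ValidationError("multiple samples per (arm, replicate, day); cannot match")
    matched = sens.index.intersection(ctrl.index)
    unmatched = sens.index.symmetric_difference(ctrl.index)
    if len(unmatched):
        logger.warning("unmatched (replicate, day) pairs skipped: %s", list(unmatched))
    if len(matched) == 0:
        raise ConfigurationError(
            f"no matched replicates between arms {sensitized_arm!r} and {control_arm!r}"
        )
    blocks = []
    for rep, d in matched:
        delta = lfc[sens.loc[(rep, d)]] - lfc[ctrl.loc[(rep, d)]]
        blocks.append(
            pd.DataFrame(
                {
                    "guide_id": lfc.index,
                    "replicate": rep,
                    "day": d,
                    "arm": sensitized_arm,
                    "delta_lfc": delta.values,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


def gene_set_rank_test(
    deltas: pd.DataFrame,
    chip: pd.DataFrame,
    gene: str,
    tail: str = "left",
) -> TestResult:
    """Rank-sum test of one gene's ΔLFC observations against all other guides'.

    The unit of observation is guide × replicate × arm. Left tail asks
    whether the gene's guides deplete *more* in the sensitized arms.
    """
    target_of = chip.set_index("guide_id")["target"]
    genes = set(target_of.values)
    if gene not in genes:
        raise ValidationError(f"gene {gene!r} not present in chip table")
    targets = target_of.reindex(deltas["guide_id"]).values
    in_gene = targets == gene
    x = deltas.loc[in_gene, "delta_lfc"].to_numpy()
    y = deltas.loc[~in_gene, "delta_lfc"].to_numpy()
    return wilcoxon_rank_sum(x, y, tail=tail)


def modifier_gene_table(
    deltas: pd.DataFrame,
    chip: pd.DataFrame,
    tail: str = "left",
    include_controls: bool = False,
) -> pd.DataFrame:
    """Per-gene rank-sum screen over ΔLFC with BH adjustment.

    Control classes are excluded from the tested gene list by default but
    always remain in the comparison complement. Sorted ascending by p.
    """
    validate_chip(chip)
    tested_targets = chip if include_controls else chip[chip["target_class"] == CLASS_GENE]
    rows = []
    for gene in sorted(tested_targets["target"].unique()):
        res = gene_set_rank_test(deltas, chip, gene, tail=tail)
        in_gene = chip.set_index("guide_id")["target"].reindex(deltas["guide_id"]).values == gene
        rows.append(
            {
                "gene": gene,
                "n_obs": res.n_x,
                "median_delta_lfc": float(np.median(deltas.loc[in_gene, "delta_lfc"])),
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)


def gene_effects_from_lfc(
    lfc: pd.DataFrame,
    chip: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    day: Optional[int] = None,
) -> pd.DataFrame:
    """Raw per-arm gene effects: mean guide LFC per target, per arm.

    A deliberately simple substitute for count-model deconvolution; rows
    are targets (including control classes), columns arms.
    """
    sheet = sample_sheet[~sample_sheet["is_pdna"]]
    if day is not None:
        sheet = sheet[sheet["day"] == day]
    target_of = chip.set_index("guide_id")["target"]
    effects = {}
    for arm, arm_sheet in sheet.groupby("arm"):
        mean_lfc = lfc[list(arm_sheet["sample_id"])].mean(axis=1)
        effects[arm] = mean_lfc.groupby(target_of.reindex(mean_lfc.index).values).mean()
    return pd.DataFrame(effects)


@dataclass
class GeneEffectTable:
    """Scaled per-arm gene effects with the control anchors that produced them."""

    effects: pd.DataFrame  # targets × arms, scaled
    negative_control_median: pd.Series  # raw, per arm
    positive_control_median: pd.Series  # raw, per arm


def _lower_median(values: pd.DataFrame) -> pd.Series:
    """Lower middle order statistic per column.

    An actually observed value, so the affine anchoring below reproduces the
    control medians *bit-exactly* (an interpolated midpoint median would
    only anchor to within rounding).
    """
    arr = np.sort(values.to_numpy(dtype=float), axis=0)
    return pd.Series(arr[(arr.shape[0] - 1) // 2], index=values.columns)


def scale_gene_effects(raw: pd.DataFrame, chip: pd.DataFrame) -> GeneEffectTable:
    """Anchor gene effects so control medians are exactly 0 and −1 per arm.

    ``scaled = (x − median_neg) / (median_neg − median_pos)``, with the
    median taken as the lower middle order statistic (see
    :func:`_lower_median`). Raises on an empty control class, equal control
    medians, or positive controls that do not deplete below the negative
    controls (the anchoring is order-preserving only in that orientation).
    """
    validate_chip(chip)
    class_of = chip.drop_duplicates("target").set_index("target")["target_class"]
    class_of = class_of.reindex(raw.index)
    neg = raw.index[class_of == CLASS_NEG]
    pos = raw.index[class_of == CLASS_POS]
    if len(neg) == 0 or len(pos) == 0:
        raise ConfigurationError("both negative and positive control targets are required")
    med_neg = _lower_median(raw.loc[neg])
    med_pos = _lower_median(raw.loc[pos])
    if (med_neg == med_pos).any():
        raise DegenerateInputError("equal control medians; cannot anchor gene effects")
    if (med_pos > med_neg).any():
        raise DegenerateInputError(
            "positive-control median above negative-control median; check control classes"
        )
    scaled = (raw - med_neg) / (med_neg - med_pos)
    return GeneEffectTable(
        effects=scaled, negative_control_median=med_neg, positive_control_median=med_pos
    )
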