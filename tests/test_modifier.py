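"""Modifier-screen analysis: LFC normalisation, arm differencing, gene rank
tests and control-anchored scaling."""

import numpy as np
import pandas as pd
import pytest

from sldep.exceptions import ConfigurationError, DegenerateInputError, ValidationError
from sldep.modifier import (
    arm_difference,
    gene_effects_from_lfc,
    gene_set_rank_test,
    modifier_gene_table,
    normalize_and_lfc,
    scale_gene_effects,
    validate_chip,
)


def tiny_screen(counts_by_sample, arms):
    guides = [f"g{i}" for i in range(len(next(iter(counts_by_sample.values()))))]
    counts = pd.DataFrame(counts_by_sample, index=guides)
    rows = [{"sample_id": "pDNA", "arm": "pdna", "replicate": 0, "day": 0, "is_pdna": True}]
    for sid, (arm, rep, day) in arms.items():
        rows.append({"sample_id": sid, "arm": arm, "replicate": rep, "day": day, "is_pdna": False})
    return counts, pd.DataFrame(rows)


def test_lfc_zero_for_equal_rpm_and_limit_for_doubling():
    counts, sheet = tiny_screen(
        {"pDNA": [100, 100], "s1": [200, 200], "s2": [400_000, 100_000]},
        {"s1": ("control", 1, 13), "s2": ("control", 2, 13)},
    )
    lfc = normalize_and_lfc(counts, sheet, pseudocount=1)
    # s1 doubles every guide -> identical rpm -> LFC 0
    assert lfc["s1"].values == pytest.approx([0.0, 0.0], abs=1e-12)
    # s2: guide 0 doubles its share; large counts make the pseudocount negligible
    assert lfc.loc["g0", "s2"] == pytest.approx(np.log2(1.6), abs=1e-3)


def test_lfc_matches_direct_formula(rng):
    counts, sheet = tiny_screen(
        {
            "pDNA": rng.integers(50, 2000, 30),
            "s1": rng.integers(50, 2000, 30),
        },
        {"s1": ("control", 1, 13)},
    )
    lfc = normalize_and_lfc(counts, sheet, pseudocount=1)
    rpm = counts / counts.sum(axis=0) * 1e6
    expected = np.log2((rpm["s1"] + 1) / (rpm["pDNA"] + 1))
    assert lfc["s1"].values == pytest.approx(expected.values, abs=1e-12)


def test_lfc_per_replicate_pdna_references():
    guides = ["g0", "g1"]
    counts = pd.DataFrame(
        {"p1": [100, 300], "p2": [300, 100], "s1": [100, 300], "s2": [100, 300]}, index=guides
    )
    sheet = pd.DataFrame(
        [
            {"sample_id": "p1", "arm": "pdna", "replicate": 1, "day": 0, "is_pdna": True},
            {"sample_id": "p2", "arm": "pdna", "replicate": 2, "day": 0, "is_pdna": True},
            {"sample_id": "s1", "arm": "control", "replicate": 1, "day": 13, "is_pdna": False},
            {"sample_id": "s2", "arm": "control", "replicate": 2, "day": 13, "is_pdna": False},
        ]
    )
    lfc = normalize_and_lfc(counts, sheet)
    assert lfc["s1"].values == pytest.approx([0.0, 0.0], abs=1e-12)  # same reference
    assert lfc.loc["g0", "s2"] < 0 < lfc.loc["g1", "s2"]  # swapped reference


def test_lfc_error_paths():
    counts, sheet = tiny_screen({"pDNA": [1, 1], "s1": [0, 0]}, {"s1": ("control", 1, 13)})
    with pytest.raises(ValidationError, match="s1"):
        normalize_and_lfc(counts, sheet)
    counts2, sheet2 = tiny_screen({"pDNA": [1, 1], "s1": [1, 1]}, {"s1": ("control", 1, 13)})
    with pytest.raises(ValidationError):
        normalize_and_lfc(counts2, sheet2, pseudocount=0.5)
    sheet3 = sheet2.copy()
    sheet3["is_pdna"] = False
    with pytest.raises(ConfigurationError):
        normalize_and_lfc(counts2, sheet3)


def make_lfc_pair(values_ctrl, values_sens):
    guides = [f"g{i}" for i in range(len(values_ctrl))]
    lfc = pd.DataFrame({"c_r1": values_ctrl, "s_r1": values_sens}, index=guides)
    sheet = pd.DataFrame(
        [
            {"sample_id": "c_r1", "arm": "control", "replicate": 1, "day": 13, "is_pdna": False},
            {"sample_id": "s_r1", "arm": "sens", "replicate": 1, "day": 13, "is_pdna": False},
        ]
    )
    return lfc, sheet


def test_arm_difference_basics_and_antisymmetry(rng):
    vals = rng.normal(0, 1, 10)
    lfc, sheet = make_lfc_pair(vals, vals)
    assert arm_difference(lfc, sheet, "sens", "control")["delta_lfc"].values == pytest.approx(0.0)

    lfc2, _ = make_lfc_pair(vals, vals - 1.0)
    deltas = arm_difference(lfc2, sheet, "sens", "control")
    assert deltas["delta_lfc"].values == pytest.approx(-1.0)
    swapped = arm_difference(lfc2, sheet, "control", "sens")
    assert swapped["delta_lfc"].values == pytest.approx(-deltas["delta_lfc"].values)


def test_arm_difference_requires_matches():
    lfc, sheet = make_lfc_pair([0.0], [0.0])
    sheet.loc[1, "replicate"] = 2  # break the (replicate, day) match
    with pytest.raises(ConfigurationError):
        arm_difference(lfc, sheet, "sens", "control")


def chip_for(targets):
    return pd.DataFrame(
        {
            "guide_id": [f"g{i}" for i in range(len(targets))],
            "target": targets,
            "target_class": ["gene"] * len(targets),
        }
    )


def test_rank_test_tied_and_separated():
    deltas = pd.DataFrame({"guide_id": [f"g{i}" for i in range(8)], "delta_lfc": [0.5] * 8})
    chip = chip_for(["A"] * 4 + ["B"] * 4)
    res = gene_set_rank_test(deltas, chip, "A")
    assert res.p_value == pytest.approx(0.5)

    deltas2 = pd.DataFrame(
        {"guide_id": [f"g{i}" for i in range(10)], "delta_lfc": [-1.0] * 4 + [0.0] * 6}
    )
    chip2 = chip_for(["A"] * 4 + ["B"] * 6)
    res2 = gene_set_rank_test(deltas2, chip2, "A", tail="left")
    assert res2.p_value < 0.01  # 4 gene observations all below the complement

    with pytest.raises(ValidationError):
        gene_set_rank_test(deltas2, chip2, "missing")


def test_scale_gene_effects_anchors_and_formula():
    raw = pd.DataFrame({"arm": {"N1": 0.1, "P1": -1.9, "GX": -0.9}})
    chip = pd.DataFrame(
        {
            "guide_id": ["a", "b", "c"],
            "target": ["N1", "P1", "GX"],
            "target_class": ["negative_control", "positive_control", "gene"],
        }
    )
    scaled = scale_gene_effects(raw, chip)
    assert scaled.effects.loc["N1", "arm"] == 0.0
    assert scaled.effects.loc["P1", "arm"] == -1.0
    assert scaled.effects.loc["GX", "arm"] == pytest.approx(-0.5)

    degenerate = pd.DataFrame({"arm": {"N1": 0.0, "P1": 0.0, "GX": 1.0}})
    with pytest.raises(DegenerateInputError):
        scale_gene_effects(degenerate, chip)


def test_scaled_control_medians_bit_exact(modifier_screen_data):
    scr = modifier_screen_data
    lfc = normalize_and_lfc(scr.counts, scr.sample_sheet)
    raw = gene_effects_from_lfc(lfc, scr.chip, scr.sample_sheet, day=13)
    scaled = scale_gene_effects(raw, scr.chip)
    neg = scr.chip.loc[scr.chip["target_class"] == "negative_control", "target"].unique()
    pos = scr.chip.loc[scr.chip["target_class"] == "positive_control", "target"].unique()
    for arm in scaled.effects.columns:
        neg_sorted = np.sort(scaled.effects.loc[neg, arm].values)
        pos_sorted = np.sort(scaled.effects.loc[pos, arm].values)
        assert neg_sorted[(len(neg_sorted) - 1) // 2] == 0.0  # bit-exact anchor
        assert pos_sorted[(len(pos_sorted) - 1) // 2] == -1.0


def test_planted_modifier_has_smallest_p(cohort, modifier_screen_data):
    scr = modifier_screen_data
    lfc = normalize_and_lfc(scr.counts, scr.sample_sheet)
    deltas = pd.concat(
        [
            arm_difference(lfc, scr.sample_sheet, arm, "control", day=13)
            for arm in ("sensitized_1", "sensitized_2")
        ],
        ignore_index=True,
    )
    table = modifier_gene_table(deltas, scr.chip)
    assert table.iloc[0]["gene"] == cohort.truth.modifier_genes[0]
    assert table.iloc[0]["p_value"] < 0.01
    assert table.iloc[0]["median_delta_lfc"] < -1.0


def test_null_gene_pvalues_roughly_uniform(cohort, modifier_screen_data):
    """Sanity check, not a hard gate: non-modifier genes' rank-sum p-values
    should not pile up near zero."""
    scr = modifier_screen_data
    lfc = normalize_and_lfc(scr.counts, scr.sample_sheet)
    deltas = pd.concat(
        [
            arm_difference(lfc, scr.sample_sheet, arm, "control", day=13)
            for arm in ("sensitized_1", "sensitized_2")
        ],
        ignore_index=True,
    )
    table = modifier_gene_table(deltas, scr.chip)
    nulls = table[~table["gene"].isin(cohort.truth.modifier_genes)]["p_value"]
    assert nulls.median() > 0.05


def test_chip_validation():
    with pytest.raises(ValidationError):
        validate_chip(
            pd.DataFrame(
                {"guide_id": ["a", "a"], "target": ["X", "X"], "target_class": ["gene", "gene"]}
            )
        )
    with pytest.raises(ValidationError):
        validate_chip(
            pd.DataFrame({"guide_id": ["a"], "target": ["X"], "target_class": ["mystery"]})
        )
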