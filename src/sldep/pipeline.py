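"""End-to-end discovery pipeline: region CN -> screen -> biomarkers -> msat -> modifier.

Stage order mirrors the discovery logic: call region deletions from
segments, screen all gene dependencies against the deletion label (with an
optional threshold sweep), then characterise the top (or configured)
candidate gene — omics feature associations in region-intact models,
microsatellite site associations in MSI-high models, the composite
biomarker call — and finally analyse the anchored modifier screen.

Every output table carries a provenance comment header (package version,
config hash, seed); ``report.json`` assembles the headline numbers from
stage outputs only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd

from . import __version__
from . import biomarkers as bm
from . import microsat as ms
from . import modifier as mod
from . import regions, screen
from .exceptions import ConfigurationError, StageError

logger = logging.getLogger(__name__)

DEFAULT_REGION = "9p21.3=chr9:19900000-25600000"
DEFAULT_SWEEP = (0.2, 0.3, 0.4, 0.5, 0.6)
SKI_COMPLEX = ("TTC37", "SKIV2L", "WDR61")


@dataclass
class RunConfig:
    """Paths, thresholds and toggles for one pipeline run."""

    out_dir: str
    seg_path: Optional[str] = None
    dep_path: Optional[str] = None
    expression_path: Optional[str] = None
    protein_path: Optional[str] = None
    msat_dir: Optional[str] = None
    screen_counts_path: Optional[str] = None
    screen_chip_path: Optional[str] = None
    screen_samples_path: Optional[str] = None

    region: str = DEFAULT_REGION
    cn_threshold: float = 0.4
    coverage_floor: float = 0.5
    seg_log2_input: bool = False
    sweep_thresholds: Tuple[float, ...] = DEFAULT_SWEEP
    run_sweep: bool = True
    tail: str = "left"
    min_group_size: int = 5

    msi_deviation_threshold: float = ms.DEVIATION_THRESHOLD
    msi_score_cutoff: float = ms.MSI_SCORE_CUTOFF
    repeat_threshold: float = 9.0
    target_gene: Optional[str] = None  # default: top screen hit
    causal_site: Optional[str] = None  # default: top site association
    complex_members: Tuple[str, ...] = SKI_COMPLEX

    modifier_day: Optional[int] = None  # default: latest day in the sample sheet
    control_arm: str = "control"
    sensitized_arms: Optional[Tuple[str, ...]] = None  # default: all non-control arms
    lfc_pseudocount: float = 1.0

    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("sweep_thresholds", "sensitized_arms", "complex_members"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # run metadata, not analysis configuration
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def validate_paths(self) -> None:
        for name in (
            "seg_path",
            "dep_path",
            "expression_path",
            "protein_path",
            "msat_dir",
            "screen_counts_path",
            "screen_chip_path",
            "screen_samples_path",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{name}={value!r} does not exist")


@dataclass
class RunResult:
    report: dict
    out_dir: Path


def _write_table(df: pd.DataFrame, path: Path, meta: Dict[str, str]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all configured stages; see the module docstring for the flow."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"package": f"sldep {__version__}", "config": config.config_hash(), "seed": config.seed}
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    region_table = None
    region_values = None
    dep = None
    target_gene = config.target_gene
    site_matrix = None
    msi_table = None

    # --- stage: region copy number ---------------------------------------
    if config.seg_path is not None:
        try:
            region_def = regions.GenomicRegion.parse(config.region)
            segments = regions.read_seg(config.seg_path, log2_input=config.seg_log2_input)
            region_table = regions.region_cn_table(
                segments, region_def, threshold=config.cn_threshold, coverage_floor=config.coverage_floor
            )
            _write_table(region_table, out / "region_cn.tsv", meta)
            region_values = region_table.set_index("model_id")["value"]
            n_del = int((region_table["status"] == regions.STATUS_DELETED).sum())
            report["stages"]["region_cn"] = {
                "region": region_def.name,
                "n_models": len(region_table),
                "n_deleted": n_del,
                "n_missing": int((region_table["status"] == regions.STATUS_MISSING).sum()),
            }
            logger.info("region_cn: %d/%d models deleted at %.2f", n_del, len(region_table), config.cn_threshold)
        except Exception as exc:
            raise StageError("region_cn", str(exc)) from exc

    # --- stage: differential-dependency screen ----------------------------
    if config.dep_path is not None and region_table is not None:
        try:
            dep = screen.read_dependency_csv(config.dep_path)
            labels = screen.labels_from_region_values(region_values, config.cn_threshold)
            main = screen.differential_dependency_screen(
                dep, labels, tail=config.tail, min_group_size=config.min_group_size
            )
            _write_table(main, out / "dependency_screen.tsv", meta)
            if target_gene is None:
                target_gene = str(main.iloc[0]["gene"])
            top = main.iloc[0]
            report["stages"]["dep_screen"] = {
                "top_gene": str(top["gene"]),
                "top_effect_size": float(top["effect_size"]),
                "top_q": float(top["q_value"]),
                "n_tested": int(main["tested"].sum()),
                "target_gene": target_gene,
            }
            if config.run_sweep:
                sweep = screen.threshold_sweep(
                    dep,
                    region_values,
                    thresholds=config.sweep_thresholds,
                    tail=config.tail,
                    min_group_size=config.min_group_size,
                )
                sweep_report = {}
                for thr, entry in sweep.items():
                    if entry.skipped:
                        sweep_report[f"{thr:g}"] = {"skipped": True, "n_pos": entry.n_pos}
                        continue
                    _write_table(entry.table, out / f"dependency_screen_thr{thr:g}.tsv", meta)
                    where = entry.table.index[entry.table["gene"] == target_gene]
                    sweep_report[f"{thr:g}"] = {
                        "skipped": False,
                        "n_pos": entry.n_pos,
                        "top_gene": str(entry.table.iloc[0]["gene"]),
                        "target_rank": int(where[0] + 1) if len(where) else None,
                    }
                report["stages"]["threshold_sweep"] = sweep_report
        except StageError:
            raise
        except Exception as exc:
            raise StageError("dep_screen", str(exc)) from exc

    # --- stage: microsatellites -------------------------------------------
    if config.msat_dir is not None:
        try:
            per_model = {
                path.stem: ms.parse_site_distributions(path)
                for path in sorted(Path(config.msat_dir).glob("*.dis"))
            }
            if not per_model:
                raise ConfigurationError(f"no .dis files under {config.msat_dir}")
            site_matrix = ms.build_site_matrix(per_model)
            site_matrix.lengths.to_csv(out / "site_length_matrix.csv", index_label="site_id")
            msi_table = ms.msi_score(
                site_matrix,
                deviation_threshold=config.msi_deviation_threshold,
                score_cutoff=config.msi_score_cutoff,
            )
            _write_table(msi_table, out / "msi_status.tsv", meta)
            report["stages"]["msat"] = {
                "n_sites": len(site_matrix.sites),
                "n_models": site_matrix.lengths.shape[1],
                "n_msih": int((msi_table["is_msih"] == True).sum()),  # noqa: E712 - nullable bool
            }
            if dep is not None and target_gene is not None and target_gene in dep.columns:
                msih_models = msi_table.loc[msi_table["is_msih"] == True, "model_id"]  # noqa: E712
                assoc = ms.site_dependency_association(
                    site_matrix, dep[target_gene], subset=list(msih_models)
                )
                _write_table(assoc, out / "site_association.tsv", meta)
                top_site = assoc.iloc[0]
                report["stages"]["site_association"] = {
                    "target_gene": target_gene,
                    "n_msih": int(len(msih_models)),
                    "top_site": str(top_site["site_id"]),
                    "top_r": float(top_site["r"]),
                    "top_q": float(top_site["q_value"]),
                    "n_untested": int((~assoc["tested"]).sum()),
                }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("msat", str(exc)) from exc

    # --- stage: biomarker associations ------------------------------------
    if dep is not None and target_gene is not None and (
        config.expression_path or config.protein_path or region_values is not None
    ):
        try:
            sources = []
            protein = None
            if config.expression_path:
                expression = pd.read_csv(config.expression_path, index_col=0)
                sources.append((expression, "expression"))
            if config.protein_path:
                protein = pd.read_csv(config.protein_path, index_col=0)
                sources.append((protein, "protein"))
            if region_values is not None:
                region_name = regions.GenomicRegion.parse(config.region).name
                sources.append((region_values.to_frame(region_name), "copy_number"))
            if msi_table is not None:
                sig = msi_table.set_index("model_id")[["score"]].rename(columns={"score": "MSIScore"})
                sources.append((sig, "signature"))
            if protein is not None and all(m in protein.columns for m in config.complex_members):
                skic_min = bm.complex_min_feature(protein, list(config.complex_members))
                sources.append((skic_min.to_frame("SKIc_min"), "protein"))
            features = bm.assemble_feature_matrix(sources)
            # the paper's association runs in region-intact models only
            if region_table is not None:
                intact = region_table.loc[
                    region_table["status"] == regions.STATUS_INTACT, "model_id"
                ]
                subset = list(intact)
            else:
                subset = None
            assoc = bm.univariate_association(features, dep[target_gene], model_subset=subset)
            _write_table(assoc, out / "feature_association.tsv", meta)
            top_feature = assoc.iloc[0]
            report["stages"]["biomarkers"] = {
                "target_gene": target_gene,
                "n_features": int(features.shape[1]),
                "top_feature": str(top_feature["feature"]),
                "top_r": float(top_feature["r"]),
                "top_q": float(top_feature["q_value"]),
            }
            # composite biomarker call
            if region_values is not None and site_matrix is not None:
                causal = config.causal_site
                if causal is None and "site_association" in report["stages"]:
                    causal = report["stages"]["site_association"]["top_site"]
                if causal is not None and causal in site_matrix.lengths.index:
                    status = bm.call_biomarker_status(
                        region_values,
                        site_matrix.lengths.loc[causal],
                        cn_threshold=config.cn_threshold,
                        repeat_threshold=config.repeat_threshold,
                    )
                    _write_table(status, out / "biomarker_status.tsv", meta)
                    report["stages"]["biomarker_status"] = {
                        "causal_site": causal,
                        "n_positive": int(status["positive"].sum()),
                        "n_focad_deleted": int(status["focad_deleted"].sum()),
                        "n_ttc37_contracted": int(status["ttc37_contracted"].sum()),
                    }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("biomarkers", str(exc)) from exc

    # --- stage: modifier screen -------------------------------------------
    if config.screen_counts_path is not None:
        try:
            counts = mod.read_counts(config.screen_counts_path)
            chip = mod.read_chip(config.screen_chip_path)
            sheet = mod.read_sample_sheet(config.screen_samples_path)
            day = config.modifier_day
            if day is None:
                day = int(sheet.loc[~sheet["is_pdna"], "day"].max())
            arms = config.sensitized_arms
            if arms is None:
                arms = tuple(
                    a for a in sheet.loc[~sheet["is_pdna"], "arm"].unique() if a != config.control_arm
                )
            lfc = mod.normalize_and_lfc(counts, sheet, pseudocount=config.lfc_pseudocount)
            deltas = pd.concat(
                [mod.arm_difference(lfc, sheet, arm, config.control_arm, day=day) for arm in arms],
                ignore_index=True,
            )
            results = mod.modifier_gene_table(deltas, chip, tail=config.tail)
            _write_table(results, out / "modifier_screen.tsv", meta)
            raw_effects = mod.gene_effects_from_lfc(lfc, chip, sheet, day=day)
            scaled = mod.scale_gene_effects(raw_effects, chip)
            _write_table(
                scaled.effects.reset_index(names="target"), out / "modifier_gene_effects.tsv", meta
            )
            top_mod = results.iloc[0]
            report["stages"]["modifier_screen"] = {
                "day": day,
                "sensitized_arms": list(arms),
                "top_gene": str(top_mod["gene"]),
                "top_p": float(top_mod["p_value"]),
                "top_median_delta_lfc": float(top_mod["median_delta_lfc"]),
                "n_delta_obs": int(len(deltas)),
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("modifier_screen", str(exc)) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return RunResult(report=report, out_dir=out)
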