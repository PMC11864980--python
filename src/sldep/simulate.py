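"""Seeded synthetic cohort and modifier-screen generator with planted truth.

Emulates, at desk scale, the statistical structure of a cancer
dependency-map cohort in which a synthetic-lethal relationship is
discoverable: a fraction of models carry a homozygous deletion of a 9p21.3-
like region (segment copy ratio near zero across the cytoband), a fraction
are MSI-high (half of their microsatellite sites contracted), one causal
site's contraction gates a planted dependency, and gene-effect scores for
planted genes shift by a known δ in biomarker-positive models. A matching
anchor-arm modifier screen plants one modifier gene that depletes only in
the sensitized arms.

Every random draw flows from a single seeded ``numpy`` generator, so the
same configuration and seed reproduce byte-identical fixture files.

Deliberate margins (documented, not tuned): intact-model segment ratios
are clipped at 0.5 so no intact model can cross the 0.4 deletion call;
microsatellite read histograms use a symmetric deterministic stutter
(mean deviation exactly 0 for unmodified sites) and modified sites
contract by at least one full unit, so the |Δ| ≥ 0.5 site-modification
proxy and the score > 20 MSI-H call separate the planted classes exactly.
These margins are what make exact-recovery assertions meaningful; real
cohorts are noisier in both respects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .microsat import MicrosatelliteSite, RepeatLengthDistribution, write_site_distributions
from .regions import SEG_COLUMNS, GenomicRegion

REGION_9P21 = GenomicRegion("9p21.3", "chr9", 19_900_000, 25_600_000)
CHR9_LENGTH = 138_394_717
CHR5_LENGTH = 181_538_259
CAUSAL_SITE_ID = "chr5:95507014-95507025"
CAUSAL_SITE_REF_LENGTH = 11  # thymidine homopolymer
MODIFIER_GENE = "FOCAD"

BIOMARKER_KINDS = ("deletion", "msi", "either")


@dataclass(frozen=True)
class PlantedGene:
    """A gene given a dependency shift δ in biomarker-positive models."""

    gene: str
    biomarker: str  # deletion | msi | either
    delta: float

    def __post_init__(self):
        if self.biomarker not in BIOMARKER_KINDS:
            raise ConfigurationError(f"biomarker must be one of {BIOMARKER_KINDS}")


@dataclass(frozen=True)
class ProteinConfig:
    latent_sd: float = 0.3  # spread of the shared complex-abundance latent
    member_sd: float = 0.8  # member-specific measurement noise (dominates the latent)
    latent_shift: float = -1.0  # latent depression in biomarker-positive models
    n_noise_proteins: int = 50
    missing_rate: float = 0.05


@dataclass(frozen=True)
class ScreenConfig:
    n_target_genes: int = 40  # includes the planted modifier
    n_guides_per_gene: int = 4
    n_negative_controls: int = 20
    n_positive_controls: int = 20
    depth_mean: float = 500.0  # expected reads per guide per sample
    nb_dispersion: float = 0.1
    lethal_lfc_per_day: float = -0.15  # log2 units/day for lethal guides
    arms: Tuple[str, ...] = ("control", "sensitized_1", "sensitized_2")
    n_replicates: int = 3
    days: Tuple[int, ...] = (5, 9, 13)


def _default_planted() -> Tuple[PlantedGene, ...]:
    return (
        PlantedGene("G0000", "deletion", -0.5),
        PlantedGene("G0001", "msi", -0.5),
        PlantedGene("G0002", "either", -0.5),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic cohort and screen."""

    seed: int = 0
    n_models: int = 500
    frac_deleted: float = 0.10
    frac_msih: float = 0.15
    n_genes: int = 2000
    planted_sl_genes: Tuple[PlantedGene, ...] = field(default_factory=_default_planted)
    noise_sd: float = 0.2
    essential_frac: float = 0.10
    n_sites: int = 500
    causal_site_index: int = 0
    site_read_depth_mean: float = 30.0
    contraction_geometric_p: float = 0.5
    max_contraction: int = 5
    site_modified_frac: float = 0.5  # fraction of sites contracted per MSI-H model
    n_expression_features: int = 200
    protein: ProteinConfig = field(default_factory=ProteinConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def validate(self) -> None:
        for frac in (self.frac_deleted, self.frac_msih, self.essential_frac, self.site_modified_frac):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"fraction {frac} outside [0, 1]")
        if min(self.n_models, self.n_genes, self.n_sites) < 1:
            raise ConfigurationError("n_models, n_genes and n_sites must be >= 1")
        if not 0 <= self.causal_site_index < self.n_sites:
            raise ConfigurationError("causal_site_index out of range")
        if self.noise_sd <= 0 or self.site_read_depth_mean <= 0:
            raise ConfigurationError("noise_sd and site_read_depth_mean must be positive")
        genes = set(self._gene_names())
        kinds_needed = {p.biomarker for p in self.planted_sl_genes}
        for planted in self.planted_sl_genes:
            if planted.gene not in genes:
                raise ConfigurationError(f"planted gene {planted.gene} outside the gene namespace")
        if round(self.frac_deleted * self.n_models) == 0 and kinds_needed & {"deletion", "either"}:
            raise ConfigurationError("deletion-linked planted gene but zero deleted models requested")
        if round(self.frac_msih * self.n_models) == 0 and kinds_needed & {"msi", "either"}:
            raise ConfigurationError("MSI-linked planted gene but zero MSI-H models requested")

    def _model_names(self) -> List[str]:
        return [f"MODEL{i:04d}" for i in range(self.n_models)]

    def _gene_names(self) -> List[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @classmethod
    def from_mapping(cls, data: dict) -> "SimConfig":
        """Build a config from a nested plain dict (e.g. parsed YAML)."""
        data = dict(data)
        if "planted_sl_genes" in data:
            data["planted_sl_genes"] = tuple(
                PlantedGene(**p) if isinstance(p, dict) else PlantedGene(*p)
                for p in data["planted_sl_genes"]
            )
        if isinstance(data.get("protein"), dict):
            data["protein"] = ProteinConfig(**data["protein"])
        if isinstance(data.get("screen"), dict):
            sc = dict(data["screen"])
            for key in ("arms", "days"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            data["screen"] = ScreenConfig(**sc)
        return cls(**data)


@dataclass
class SimTruth:
    """Planted ground truth against which pipeline recovery is asserted."""

    deleted_models: List[str]
    msih_models: List[str]
    contracted_models: List[str]  # causal-site weighted length <= reference - 2
    biomarker_positive: List[str]  # deleted OR contracted
    causal_site: str
    sl_genes: List[dict]  # {gene, biomarker, delta}
    modifier_genes: List[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


@dataclass
class SiteCounts:
    """Read-length histograms for all models × sites, in dense array form.

    ``counts[m, s, j]`` is the read count for model ``m`` at site ``s`` at
    repeat length ``reference_length[s] + offsets[j]``.
    """

    models: List[str]
    sites: pd.DataFrame  # index site_id; columns reference_length, repeat_unit
    offsets: np.ndarray  # (n_offsets,) ints
    counts: np.ndarray  # (n_models, n_sites, n_offsets) ints

    def length_matrix(self) -> pd.DataFrame:
        """Sites × models weighted-mean repeat lengths (NaN where no reads)."""
        depth = self.counts.sum(axis=2, dtype=float)
        weighted = (self.counts * self.offsets[None, None, :]).sum(axis=2, dtype=float)
        ref = self.sites["reference_length"].to_numpy(dtype=float)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            lengths = np.where(depth > 0, ref + weighted / depth, np.nan)
        return pd.DataFrame(lengths.T, index=self.sites.index, columns=self.models)

    def model_distributions(self, model_id: str) -> List[RepeatLengthDistribution]:
        m = self.models.index(model_id)
        dists = []
        for s, (site_id, row) in enumerate(self.sites.iterrows()):
            site = MicrosatelliteSite(site_id, int(row["reference_length"]), row["repeat_unit"])
            nz = np.nonzero(self.counts[m, s])[0]
            counts = {
                int(row["reference_length"] + self.offsets[j]): int(self.counts[m, s, j]) for j in nz
            }
            dists.append(RepeatLengthDistribution(site, counts))
        return dists

    def iter_models(self) -> Iterator[Tuple[str, List[RepeatLengthDistribution]]]:
        for model_id in self.models:
            yield model_id, self.model_distributions(model_id)


@dataclass
class SimCohort:
    """Everything the discovery pipeline consumes, plus the planted truth."""

    config: SimConfig
    segments: pd.DataFrame  # SEG-like table
    dependency: pd.DataFrame  # models × genes
    expression: pd.DataFrame  # models × expression features
    protein: pd.DataFrame  # models × proteins
    site_counts: SiteCounts
    truth: SimTruth


def _choose_set(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    """Boolean mask with exactly round(frac * n) True entries."""
    mask = np.zeros(n, dtype=bool)
    k = int(round(frac * n))
    if k:
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def _make_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Site catalogue with the causal thymidine homopolymer at its index."""
    n_other = config.n_sites - 1
    chroms = rng.choice([f"chr{i}" for i in range(1, 23)], size=n_other)
    starts = rng.integers(10_000, 200_000_000, size=n_other)
    # resolve (vanishingly rare) coordinate collisions deterministically
    while pd.Index(list(zip(chroms, starts))).duplicated().any():
        dup = pd.Index(list(zip(chroms, starts))).duplicated()
        starts[dup] = rng.integers(10_000, 200_000_000, size=int(dup.sum()))
    ref_lengths = rng.integers(8, 26, size=n_other)
    units = rng.choice(list("ACGT"), size=n_other)
    rows = [
        {
            "site_id": f"{chroms[i]}:{starts[i]}-{starts[i] + ref_lengths[i]}",
            "reference_length": int(ref_lengths[i]),
            "repeat_unit": str(units[i]),
        }
        for i in range(n_other)
    ]
    rows.insert(
        config.causal_site_index,
        {
            "site_id": CAUSAL_SITE_ID,
            "reference_length": CAUSAL_SITE_REF_LENGTH,
            "repeat_unit": "T",
        },
    )
    return pd.DataFrame(rows).set_index("site_id")


def _simulate_site_counts(
    config: SimConfig, rng: np.random.Generator, msih: np.ndarray
) -> SiteCounts:
    n_models, n_sites = config.n_models, config.n_sites
    sites = _make_sites(config, rng)
    causal = config.causal_site_index
    p, max_k = config.contraction_geometric_p, config.max_contraction

    # contraction sizes: 0 = unmodified; MSI-H models contract exactly
    # site_modified_frac of the non-causal sites and always the causal site
    k = np.zeros((n_models, n_sites), dtype=np.int64)
    msih_rows = np.flatnonzero(msih)
    if len(msih_rows):
        non_causal = np.delete(np.arange(n_sites), causal)
        n_mod = int(round(config.site_modified_frac * len(non_causal)))
        if n_mod:
            order = rng.random((len(msih_rows), len(non_causal))).argsort(axis=1)[:, :n_mod]
            chosen = non_causal[order]
            draws = np.minimum(rng.geometric(p, size=chosen.shape), max_k)
            k[np.repeat(msih_rows, n_mod), chosen.ravel()] = draws.ravel()
        k[msih_rows, causal] = np.minimum(rng.geometric(p, size=len(msih_rows)), max_k)

    depth = rng.poisson(config.site_read_depth_mean, size=(n_models, n_sites))
    stutter = depth // 10  # symmetric reads one unit either side of the mode
    offsets = np.arange(-(max_k + 1), 2)
    counts = np.zeros((n_models, n_sites, len(offsets)), dtype=np.int64)
    center = (max_k + 1) - k  # index of offset -k
    np.put_along_axis(counts, center[..., None], (depth - 2 * stutter)[..., None], axis=2)
    np.put_along_axis(counts, (center - 1)[..., None], stutter[..., None], axis=2)
    np.put_along_axis(counts, (center + 1)[..., None], stutter[..., None], axis=2)
    return SiteCounts(models=config._model_names(), sites=sites, offsets=offsets, counts=counts)


def simulate_cohort(config: SimConfig = SimConfig()) -> SimCohort:
    """Generate the full synthetic cohort (see module docstring).

    Draw order is fixed, so a given config + seed is byte-reproducible.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    models = config._model_names()
    genes = config._gene_names()
    n = config.n_models

    deleted = _choose_set(rng, n, config.frac_deleted)
    msih = _choose_set(rng, n, config.frac_msih)

    # --- segments: chr9 tiled around the deleted region, plus chr5 ---
    boundaries = [
        ("chr9", 0, REGION_9P21.start),
        ("chr9", REGION_9P21.start, REGION_9P21.end),
        ("chr9", REGION_9P21.end, CHR9_LENGTH),
        ("chr5", 0, CHR5_LENGTH),
    ]
    base = np.clip(rng.normal(1.0, 0.1, size=(n, len(boundaries))), 0.5, None)
    deleted_ratio = rng.uniform(0.0, 0.15, size=n)
    base[deleted, 1] = deleted_ratio[deleted]
    segments = pd.DataFrame(
        {
            "ModelID": np.repeat(models, len(boundaries)),
            "Chromosome": np.tile([b[0] for b in boundaries], n),
            "Start": np.tile([b[1] for b in boundaries], n),
            "End": np.tile([b[2] for b in boundaries], n),
            "CopyRatio": base.ravel(),
        }
    )[SEG_COLUMNS]

    # --- microsatellite read histograms ---
    site_counts = _simulate_site_counts(config, rng, msih)
    causal_lengths = site_counts.length_matrix().loc[CAUSAL_SITE_ID].to_numpy(dtype=float)
    contracted = np.isfinite(causal_lengths) & (
        causal_lengths <= CAUSAL_SITE_REF_LENGTH - 2
    )
    biomarker = {"deletion": deleted, "msi": contracted, "either": deleted | contracted}

    # --- dependency matrix ---
    planted_idx = {p.gene for p in config.planted_sl_genes}
    eligible = [i for i, g in enumerate(genes) if g not in planted_idx]
    n_ess = int(round(config.essential_frac * config.n_genes))
    mu = np.zeros(config.n_genes)
    if n_ess:
        mu[rng.choice(eligible, size=min(n_ess, len(eligible)), replace=False)] = -1.0
    dep_values = mu[None, :] + rng.normal(0.0, config.noise_sd, size=(n, config.n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for planted in config.planted_sl_genes:
        dep_values[:, gene_pos[planted.gene]] += planted.delta * biomarker[planted.biomarker]
    dependency = pd.DataFrame(dep_values, index=models, columns=genes)

    # --- expression: mostly noise, plus two deletion-tracking transcripts ---
    expr_names = [f"EX{i:04d}" for i in range(config.n_expression_features)]
    expr = rng.normal(0.0, 1.0, size=(n, config.n_expression_features))
    expression = pd.DataFrame(expr, index=models, columns=expr_names)
    for marker in ("MTAP", "CDKN2A"):
        expression[marker] = 2.0 * (~deleted) + rng.normal(0.0, 0.5, size=n)

    # --- protein: co-stabilised complex members share a latent ---
    pc = config.protein
    latent = pc.latent_shift * biomarker["either"] + rng.normal(0.0, pc.latent_sd, size=n)
    protein = pd.DataFrame(index=models)
    for member in ("TTC37", "SKIV2L", "WDR61"):
        protein[member] = latent + rng.normal(0.0, pc.member_sd, size=n)
    for i in range(pc.n_noise_proteins):
        protein[f"PR{i:03d}"] = rng.normal(0.0, 1.0, size=n)
    if pc.missing_rate > 0:
        mask = rng.random(protein.shape) < pc.missing_rate
        protein = protein.mask(mask)

    model_arr = np.asarray(models)
    truth = SimTruth(
        deleted_models=sorted(model_arr[deleted]),
        msih_models=sorted(model_arr[msih]),
        contracted_models=sorted(model_arr[contracted]),
        biomarker_positive=sorted(model_arr[biomarker["either"]]),
        causal_site=CAUSAL_SITE_ID,
        sl_genes=[dataclasses.asdict(p) for p in config.planted_sl_genes],
        modifier_genes=[MODIFIER_GENE],
    )
    return SimCohort(
        config=config,
        segments=segments,
        dependency=dependency,
        expression=expression,
        protein=protein,
        site_counts=site_counts,
        truth=truth,
    )


@dataclass
class SimScreen:
    """Synthetic anchor-arm modifier screen."""

    chip: pd.DataFrame  # guide_id, target, target_class
    counts: pd.DataFrame  # guides × samples
    sample_sheet: pd.DataFrame


def simulate_modifier_screen(config: SimConfig, truth: SimTruth) -> SimScreen:
    """Negative-binomial guide counts for a three-arm anchored screen.

    Guide abundance starts from a lognormal pDNA pool; a sample at day *d*
    draws NB counts around ``pdna_share × 2^(fitness × d)``. The planted
    modifier gene is lethal only in sensitized arms; positive controls are
    lethal everywhere; negative controls are neutral.
    """
    config.validate()
    sc = config.screen
    rng = np.random.default_rng([config.seed, 2])

    targets = [MODIFIER_GENE] + [f"TGT{i:02d}" for i in range(1, sc.n_target_genes)]
    rows = [
        {"guide_id": f"{t}_g{j + 1}", "target": t, "target_class": "gene"}
        for t in targets
        for j in range(sc.n_guides_per_gene)
    ]
    rows += [
        {"guide_id": f"NEG{i:02d}_g1", "target": f"NEG{i:02d}", "target_class": "negative_control"}
        for i in range(sc.n_negative_controls)
    ]
    rows += [
        {"guide_id": f"ESS{i:02d}_g1", "target": f"ESS{i:02d}", "target_class": "positive_control"}
        for i in range(sc.n_positive_controls)
    ]
    chip = pd.DataFrame(rows)
    n_guides = len(chip)

    is_modifier = chip["target"].isin(truth.modifier_genes).to_numpy()
    is_pos = (chip["target_class"] == "positive_control").to_numpy()

    abund = rng.lognormal(mean=0.0, sigma=0.5, size=n_guides)
    share = abund / abund.sum()
    total_depth = sc.depth_mean * n_guides
    counts = {"pDNA": rng.poisson(share * total_depth)}
    sheet_rows = [{"sample_id": "pDNA", "arm": "pdna", "replicate": 0, "day": 0, "is_pdna": True}]
    shape = 1.0 / sc.nb_dispersion
    for arm in sc.arms:
        fitness = np.where(is_pos, sc.lethal_lfc_per_day, 0.0)
        if arm != "control":
            fitness = fitness + np.where(is_modifier, sc.lethal_lfc_per_day, 0.0)
        for rep in range(1, sc.n_replicates + 1):
            for day in sc.days:
                mu = share * total_depth * np.exp2(fitness * day)
                lam = rng.gamma(shape=shape, scale=mu / shape)
                sid = f"{arm}_r{rep}_d{day}"
                counts[sid] = rng.poisson(lam)
                sheet_rows.append(
                    {"sample_id": sid, "arm": arm, "replicate": rep, "day": day, "is_pdna": False}
                )
    counts_df = pd.DataFrame(counts, index=chip["guide_id"].values)
    counts_df.index.name = "guide_id"
    return SimScreen(chip=chip, counts=counts_df, sample_sheet=pd.DataFrame(sheet_rows))


# ---------------------------------------------------------------------------
# fixture-set writing


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_set(
    cohort: SimCohort, screen: Optional[SimScreen], directory
) -> Dict[str, str]:
    """Write all pipeline input files plus ``truth.json`` and ``manifest.json``.

    Returns the manifest (relative path -> sha256). File dialects are
    exactly those consumed by the reader functions of the analysis modules.
    """
    directory = Path(directory)
    (directory / "msat").mkdir(parents=True, exist_ok=True)
    cohort.segments.to_csv(directory / "segments.seg.tsv", sep="\t", index=False)
    cohort.dependency.to_csv(directory / "dependency.csv", index_label="ModelID")
    cohort.expression.to_csv(directory / "expression.csv", index_label="ModelID")
    cohort.protein.to_csv(directory / "protein.csv", index_label="ModelID")
    for model_id, dists in cohort.site_counts.iter_models():
        write_site_distributions(dists, directory / "msat" / f"{model_id}.dis")
    if screen is not None:
        (directory / "screen").mkdir(exist_ok=True)
        screen.counts.to_csv(directory / "screen" / "counts.tsv", sep="\t")
        screen.chip.to_csv(directory / "screen" / "chip.tsv", sep="\t", index=False)
        screen.sample_sheet.to_csv(directory / "screen" / "samples.tsv", sep="\t", index=False)
    (directory / "truth.json").write_text(cohort.truth.to_json())

    manifest: Dict[str, str] = {}
    for path in sorted(directory.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(directory))] = _sha256(path)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def verify_fixture_set(directory) -> List[str]:
    """Re-hash a fixture directory against its manifest; return mismatches."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    problems = []
    for rel, digest in manifest.items():
        path = directory / rel
        if not path.is_file():
            problems.append(f"missing: {rel}")
        elif _sha256(path) != digest:
            problems.append(f"hash mismatch: {rel}")
    return problems
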