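"""Synthetic case/control methylation-capture and small-RNA data with a
recorded ground truth.

The generator emulates the regional intensity structure of an MBD
capture experiment on a toy genome: promoters laid out in
non-overlapping slots, CpG sites clustered inside promoters (with
occasional large gaps that split methylation intervals), per-sample
read counts drawn from a negative-binomial (capture assays are
overdispersed; dispersion 0.1 by default) or Poisson noise family, 2-3
replicates per group, and a configurable fraction of planted
hyper/hypomethylated units with multiplicative effects.  Correlation
among CpG sites of one true unit is induced by a shared per-unit latent
factor, which is what makes correlation-based segmentation testable
against a known truth.  A matching generator produces small-RNA count
tables (tRF-dominant "sperm" or miRNA-dominant "mammary" composition)
with planted fold-changes.

Every dataset carries a :class:`SyntheticTruth` naming the planted
regions/features, their directions and effect sizes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quantify import IntensityMatrix
from .regions import GenomicRegion

SUBTYPE_PROFILES = {
    "sperm": {"tRF": 0.55, "miRNA": 0.25, "piRNA": 0.12, "rRNA": 0.05, "other": 0.03},
    "mammary": {"miRNA": 0.60, "tRF": 0.20, "piRNA": 0.08, "rRNA": 0.07, "other": 0.05},
}
SUBTYPE_LENGTH_NT = {"miRNA": 22, "tRF": 30, "piRNA": 28, "rRNA": 120, "other": 50}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the methylation-capture generator.

    depth is the mean read count per scored region in one sample;
    replicates_per_group defaults to 3 (capture designs here run 2-3
    replicates per group); effects are multiplicative folds on the case
    mean, split between hyper (x effect) and hypo (/ effect) according
    to hyper_fraction.
    """

    n_promoters: int = 100
    promoters_per_chrom: int = 500
    promoter_slot_bp: int = 20_000
    upstream_bp: int = 5000
    n_cpg_per_promoter: float = 5.0
    intra_unit_rho: float = 0.7
    depth: float = 200.0
    read_length: int = 36
    noise: str = "nb"
    dispersion: float = 0.1
    replicates_per_group: int = 3
    fraction_planted: float = 0.05
    effect_sizes: tuple[float, ...] = (4.0,)
    hyper_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters < 0 or self.depth <= 0 or self.read_length <= 0:
            raise ValueError("counts and depth must be positive")
        if not 0 <= self.fraction_planted < 1:
            raise ValueError("fraction_planted must be in [0, 1)")
        if not 0 <= self.intra_unit_rho <= 1:
            raise ValueError("intra_unit_rho must be in [0, 1]")
        if self.noise not in ("nb", "poisson"):
            raise ValueError("noise must be 'nb' or 'poisson'")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be >= 1")
        if any(e <= 0 or e == 1 for e in self.effect_sizes):
            raise ValueError("effect sizes must be positive and != 1")


@dataclass
class SyntheticTruth:
    """Planted differential regions/features with directions and effects."""

    planted_ids: tuple[str, ...]
    directions: dict[str, str]
    effects: dict[str, float]
    seed: int
    params: dict = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": list(self.planted_ids),
             "direction": [self.directions[i] for i in self.planted_ids],
             "effect": [self.effects[i] for i in self.planted_ids]}
        )

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        payload = {
            "planted_ids": list(self.planted_ids),
            "directions": dict(self.directions),
            "effects": {k: float(v) for k, v in self.effects.items()},
            "seed": int(self.seed),
            "params": plain(self.params),
            "members": {k: list(v) for k, v in self.members.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(tuple(payload["planted_ids"]), payload["directions"],
                   payload["effects"], payload["seed"],
                   payload.get("params", {}), payload.get("members", {}))


@dataclass
class SyntheticGenome:
    """Toy genome: TSS table, CpG sites with cluster metadata, chrom sizes."""

    tss_table: pd.DataFrame
    cpg_sites: list[GenomicRegion]
    site_meta: pd.DataFrame  # site_id, promoter_id, cluster_id
    chrom_sizes: dict[str, int]


def generate_genome(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Lay out promoters and clustered CpG sites on toy chromosomes.

    One chromosome per ``promoters_per_chrom`` promoters; each promoter
    occupies its own slot so promoters never overlap.  CpG sites inside
    a promoter are placed left to right with mostly small gaps
    (10-150 bp) and occasional large gaps (400-900 bp) so that both the
    merge and the split paths of segmentation are exercised.
    Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.upstream_bp + 400 > config.promoter_slot_bp:
        raise ValueError("promoter_slot_bp too small for upstream_bp: "
                         "infeasible promoter packing")
    tss_rows = []
    sites: list[GenomicRegion] = []
    meta_rows = []
    chrom_sizes: dict[str, int] = {}
    for p in range(config.n_promoters):
        chrom = f"chr{p // config.promoters_per_chrom + 1}"
        slot = p % config.promoters_per_chrom
        slot_start = slot * config.promoter_slot_bp
        chrom_sizes[chrom] = (slot + 1) * config.promoter_slot_bp + config.promoter_slot_bp
        gene = f"g{p:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exon_len = int(rng.integers(100, 301))
        if strand == "+":
            tss = slot_start + config.upstream_bp
            e_start, e_end = tss, tss + exon_len
            prom_start, prom_end = tss - config.upstream_bp, e_end
        else:
            tss = slot_start + config.promoter_slot_bp - config.upstream_bp
            e_start, e_end = tss + 1 - exon_len, tss + 1
            prom_start, prom_end = e_start, tss + config.upstream_bp
        tss_rows.append({"gene_id": gene, "chrom": chrom, "strand": strand,
                         "tss": tss, "exon1_start": e_start, "exon1_end": e_end})
        n_sites = int(rng.poisson(config.n_cpg_per_promoter))
        pos = prom_start + 100
        cluster = 0
        for k in range(n_sites):
            if k > 0:
                if rng.random() < 0.8:
                    gap = int(rng.integers(10, 151))
                else:
                    gap = int(rng.integers(400, 901))
                    cluster += 1
                pos += gap
            if pos >= prom_end - 10:
                break
            site_id = f"{gene}_s{k}"
            sites.append(GenomicRegion(chrom, pos, pos + 1, ".", "cpg_site", site_id))
            meta_rows.append({"site_id": site_id, "promoter_id": gene,
                              "cluster_id": f"{gene}_c{cluster}"})
    tss_table = pd.DataFrame(
        tss_rows, columns=["gene_id", "chrom", "strand", "tss",
                           "exon1_start", "exon1_end"])
    site_meta = pd.DataFrame(meta_rows, columns=["site_id", "promoter_id",
                                                 "cluster_id"])
    return SyntheticGenome(tss_table, sites, site_meta, chrom_sizes)


def _sample_names(config: GeneratorConfig) -> tuple[list[str], dict[str, str]]:
    samples = [f"case_{i + 1}" for i in range(config.replicates_per_group)] + \
              [f"control_{i + 1}" for i in range(config.replicates_per_group)]
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return samples, groups


def _plant(ids: list[str], config: GeneratorConfig,
           rng: np.random.Generator) -> tuple[tuple[str, ...], dict, dict]:
    n_plant = int(round(config.fraction_planted * len(ids)))
    chosen = sorted(rng.choice(len(ids), size=n_plant, replace=False).tolist())
    planted = tuple(ids[i] for i in chosen)
    directions, effects = {}, {}
    for pid in planted:
        hyper = rng.random() < config.hyper_fraction
        directions[pid] = "hyper" if hyper else "hypo"
        effects[pid] = float(rng.choice(config.effect_sizes))
    return planted, directions, effects


def _nb_counts(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with var = mean + dispersion * mean^2."""
    if dispersion < 1e-9:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def generate_intensities(genome: SyntheticGenome, config: GeneratorConfig,
                         rng: np.random.Generator | None = None,
                         as_reads: bool = False,
                         level: str = "promoter"):
    """Per-sample intensities (or raw reads) with planted effects.

    level="promoter": one scored region per gene; read counts per
    promoter per sample follow the noise family with mean
    depth x effect; as_reads=True emits uniformly placed reads of
    length L inside the promoter (exercising quantification) instead of
    the intensity matrix.

    level="cpg_site": a site x sample intensity matrix in which sites of
    one true methylation unit share a per-(unit, sample) latent gamma
    factor (intra-unit correlation rho) and planted units carry the
    effect in case samples; truth records each true unit's member sites.
    Matrix output only.

    Returns ``(matrix_or_read_sets, truth)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples, groups = _sample_names(config)
    L = config.read_length

    if level == "promoter":
        from .regions import PromoterSpec, define_promoters

        promoters = define_promoters(genome.tss_table,
                                     PromoterSpec(config.upstream_bp, True),
                                     genome.chrom_sizes)
        ids = [r.region_id for r in promoters]
        planted, directions, effects = _plant(ids, config, rng)
        counts = np.empty((len(promoters), len(samples)), dtype=int)
        for i, region in enumerate(promoters):
            for j, s in enumerate(samples):
                mean = config.depth
                if region.region_id in planted and groups[s] == "case":
                    eff = effects[region.region_id]
                    mean *= eff if directions[region.region_id] == "hyper" else 1 / eff
                disp = config.dispersion if config.noise == "nb" else 0.0
                counts[i, j] = _nb_counts(np.array(float(mean)), disp, rng)
        truth = SyntheticTruth(planted, directions, effects, config.seed,
                               params=asdict(config))
        if as_reads:
            read_sets = {}
            for j, s in enumerate(samples):
                rows = []
                for i, region in enumerate(promoters):
                    n = counts[i, j]
                    if n == 0:
                        continue
                    starts = rng.integers(region.start, region.end - L, size=n)
                    for st in np.sort(starts):
                        rows.append((region.chrom, int(st), int(st) + L))
                read_sets[s] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
            return read_sets, truth
        matrix = IntensityMatrix(promoters, samples, groups,
                                 counts.astype(float) * L)
        return matrix, truth

    if level != "cpg_site":
        raise ValueError(f"unknown level {level!r}")
    if as_reads:
        raise ValueError("read output is supported at promoter level only")

    # carve each geometric cluster into true units of 1-4 sites
    unit_of_site: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for cluster_id, grp in genome.site_meta.groupby("cluster_id", sort=False):
        site_ids = grp["site_id"].tolist()
        k = 0
        pos = 0
        while pos < len(site_ids):
            size = int(rng.integers(1, 5))
            unit_id = f"{cluster_id}_tu{k}"
            for sid in site_ids[pos:pos + size]:
                unit_of_site[sid] = unit_id
            members[unit_id] = site_ids[pos:pos + size]
            pos += size
            k += 1
    unit_ids = list(members)
    planted, directions, effects = _plant(unit_ids, config, rng)
    truth = SyntheticTruth(planted, directions, effects, config.seed,
                           params=asdict(config), members=members)

    site_index = {s.region_id: i for i, s in enumerate(genome.cpg_sites)}
    values = np.zeros((len(genome.cpg_sites), len(samples)))
    d = config.dispersion if config.noise == "nb" else 0.0
    rho = config.intra_unit_rho
    for unit_id, site_list in members.items():
        mu_site = config.depth * config.read_length / len(site_list)
        for j, s in enumerate(samples):
            eff = 1.0
            if unit_id in planted and groups[s] == "case":
                e = effects[unit_id]
                eff = e if directions[unit_id] == "hyper" else 1 / e
            shared_var = rho * d
            site_var = (1 - rho) * d
            a = rng.gamma(1 / shared_var, shared_var) if shared_var > 1e-12 else 1.0
            for sid in site_list:
                b = rng.gamma(1 / site_var, site_var) if site_var > 1e-12 else 1.0
                lam = mu_site * eff * a * b / config.read_length
                values[site_index[sid], j] = rng.poisson(lam) * config.read_length
    matrix = IntensityMatrix(genome.cpg_sites, samples, groups, values)
    return matrix, truth


def generate_unit_matrix(config: GeneratorConfig, n_units: int,
                         mean_sites: float = 5.0,
                         rng: np.random.Generator | None = None
                         ) -> tuple[IntensityMatrix, np.ndarray, SyntheticTruth]:
    """Unit-level intensity matrix with length-dependent background rates.

    Each methylation unit spans 1 + Poisson(mean_sites - 1) CpG sites;
    its mean read count scales with its site count (depth x
    n_sites / mean_sites), so longer units have proportionally stronger
    background intensity — the situation length stratification exists
    for.  Planted units carry the multiplicative effect in case
    samples.  Returns ``(matrix, site_counts, truth)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples, groups = _sample_names(config)
    site_counts = 1 + rng.poisson(max(mean_sites - 1.0, 0.0), size=n_units)
    regions = []
    pos = 0
    for i, n_sites in enumerate(site_counts):
        span = int(n_sites) * 100
        regions.append(GenomicRegion("chrU", pos, pos + span, ".", "unit",
                                     f"u{i:05d}"))
        pos += span + 500
    ids = [r.region_id for r in regions]
    planted, directions, effects = _plant(ids, config, rng)
    values = np.empty((n_units, len(samples)), dtype=float)
    d = config.dispersion if config.noise == "nb" else 0.0
    for i, region in enumerate(regions):
        mu = config.depth * site_counts[i] / mean_sites
        for j, s in enumerate(samples):
            eff = 1.0
            if region.region_id in planted and groups[s] == "case":
                e = effects[region.region_id]
                eff = e if directions[region.region_id] == "hyper" else 1 / e
            values[i, j] = _nb_counts(np.array(mu * eff), d, rng) * config.read_length
    matrix = IntensityMatrix(regions, samples, groups, values)
    truth = SyntheticTruth(planted, directions, effects, config.seed,
                           params=asdict(config))
    return matrix, site_counts.astype(float), truth


@dataclass(frozen=True)
class SmallRNAGenConfig:
    """Study conditions for the small-RNA count generator (4 replicates
    per group by default, negative-binomial counts)."""

    n_features: int = 500
    replicates_per_group: int = 4
    dispersion: float = 0.1
    fraction_planted: float = 0.0
    effect_sizes: tuple[float, ...] = (4.0,)
    up_fraction: float = 0.5
    tissue: str = "sperm"
    mean_log_expression: float = 5.0
    sd_log_expression: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue not in SUBTYPE_PROFILES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if not 0 <= self.fraction_planted < 1:
            raise ValueError("fraction_planted must be in [0, 1)")
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group")


def generate_smallrna(config: SmallRNAGenConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Small-RNA count table with planted fold-changes.

    Returns ``(counts, feature_meta, groups, truth)``: counts is a
    feature x sample integer table; feature_meta carries subtype and
    length_nt; subtype proportions follow the tissue profile
    (tRF-dominant sperm or miRNA-dominant mammary).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = [f"case_{i + 1}" for i in range(config.replicates_per_group)] + \
              [f"control_{i + 1}" for i in range(config.replicates_per_group)]
    groups = pd.Series({s: ("case" if s.startswith("case") else "control")
                        for s in samples}).reindex(samples)
    profile = SUBTYPE_PROFILES[config.tissue]
    subtypes = rng.choice(list(profile), size=config.n_features,
                          p=list(profile.values()))
    ids = [f"{subtypes[i]}_{i:04d}" for i in range(config.n_features)]
    base_mean = np.exp(rng.normal(config.mean_log_expression,
                                  config.sd_log_expression,
                                  size=config.n_features))
    n_plant = int(round(config.fraction_planted * config.n_features))
    chosen = sorted(rng.choice(config.n_features, size=n_plant,
                               replace=False).tolist())
    planted = tuple(ids[i] for i in chosen)
    directions, effects = {}, {}
    for i in chosen:
        up = rng.random() < config.up_fraction
        directions[ids[i]] = "up" if up else "down"
        effects[ids[i]] = float(rng.choice(config.effect_sizes))
    counts = np.empty((config.n_features, len(samples)), dtype=int)
    for i in range(config.n_features):
        for j, s in enumerate(samples):
            mean = base_mean[i]
            if ids[i] in planted and groups[s] == "case":
                e = effects[ids[i]]
                mean *= e if directions[ids[i]] == "up" else 1 / e
            counts[i, j] = _nb_counts(np.array(mean), config.dispersion, rng)
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="feature_id"),
                             columns=samples)
    meta = pd.DataFrame(
        {"subtype": subtypes,
         "length_nt": [SUBTYPE_LENGTH_NT[t] for t in subtypes]},
        index=counts_df.index)
    truth = SyntheticTruth(planted, directions, effects, config.seed,
                           params=asdict(config))
    return counts_df, meta, groups, truth
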