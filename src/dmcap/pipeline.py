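"""End-to-end orchestration: simulate -> quantify -> segment -> test -> report.

Stages communicate only through declared files under the run's output
directory, so any stage can be re-run or tested in isolation.  Every
run echoes its full configuration (plus seed and package version) into
a YAML provenance sidecar; re-running from the sidecar reproduces the
outputs byte for byte.  Output files contain no timestamps for that
reason.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import PermutationConfig, iterative_detect
from .io import (read_bed, read_count_table, read_groups, read_reads_bed,
                 write_bed, write_groups)
from .quantify import IntensityMatrix, build_intensity_matrix
from .regions import GenomicRegion, validate_regions
from .scores import FoldChangeParams, score_regions
from .segmentation import CpGUnitSegmenter
from .simulate import (GeneratorConfig, SmallRNAGenConfig, generate_genome,
                       generate_intensities, generate_smallrna)
from .smallrna import permutation_de, subtype_composition, tpm_normalize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Exactly one input source: ``generator`` (synthetic-data parameters)
    XOR ``inputs`` (paths to a site intensity matrix + group labels, or
    per-sample read BEDs + a regions BED).  ``smallrna`` configures the
    small-RNA branch the same way.
    """

    outdir: str = "dmcap_run"
    generator: dict | None = None
    inputs: dict | None = None
    smallrna: dict | None = None
    fold_change: dict = field(default_factory=dict)     # beta, L
    segmentation: dict = field(default_factory=dict)    # CpGUnitSegmenter params
    permutation: dict = field(default_factory=dict)     # PermutationConfig fields
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.generator is not None and self.inputs is not None:
            raise ValueError("generator and inputs are mutually exclusive")
        if self.generator is None and self.inputs is None and self.smallrna is None:
            raise ValueError("no input source configured: need generator, "
                             "inputs or a smallrna section")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_provenance(outdir: Path, config: RunConfig, seed: int | None) -> None:
    payload = {"config": config.to_dict(), "seed": seed, "version": __version__}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _load_input_matrix(inputs: Mapping, outdir: Path) -> IntensityMatrix:
    if "matrix" in inputs:
        return IntensityMatrix.from_tsv(inputs["matrix"], inputs["groups"])
    regions = read_bed(inputs["regions"], role=inputs.get("role", "cpg_site"))
    groups = read_groups(inputs["groups"])
    read_sets = {s: read_reads_bed(path, s)
                 for s, path in inputs["reads"].items()}
    return build_intensity_matrix(read_sets, regions, groups.to_dict())


def run_diffmeth(config: RunConfig, seed: int | None = None) -> dict[str, Path]:
    """Execute the differential-methylation pipeline end to end.

    Simulate (or load) site-level intensities, segment CpG sites into
    methylation units, aggregate unit intensities, score and run the
    iterative events-exclusive permutation test.  All outputs (and the
    echoed config) land under ``config.outdir``.  On a stage failure,
    partial outputs are preserved next to a FAILED marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outputs: dict[str, Path] = {}
    try:
        if config.generator is not None:
            gen_kwargs = dict(config.generator)
            if seed is not None:
                gen_kwargs["seed"] = seed
            if "effect_sizes" in gen_kwargs:
                gen_kwargs["effect_sizes"] = tuple(gen_kwargs["effect_sizes"])
            gen_cfg = GeneratorConfig(**gen_kwargs)
            genome = generate_genome(gen_cfg)
            matrix, truth = generate_intensities(genome, gen_cfg, level="cpg_site")
            genome.tss_table.to_csv(outdir / "tss.tsv", sep="\t", index=False)
            write_bed(genome.cpg_sites, outdir / "cpg_sites.bed")
            matrix.to_tsv(outdir / "site_matrix.tsv", outdir / "groups.tsv")
            truth.to_yaml(outdir / "truth.yaml")
            outputs.update(tss=outdir / "tss.tsv", truth=outdir / "truth.yaml",
                           site_matrix=outdir / "site_matrix.tsv")
        else:
            matrix = _load_input_matrix(config.inputs, outdir)

        report = validate_regions(matrix.regions)
        if not report.ok:
            raise ValueError(f"invalid region set: {report.counts()}")

        seg = CpGUnitSegmenter(**config.segmentation)
        seg.fit(matrix.values, sites=matrix.regions)
        write_bed([iv.region for iv in seg.intervals_], outdir / "intervals.bed")
        write_bed([u.region for u in seg.units_], outdir / "units.bed")
        seg.unit_map().to_csv(outdir / "unit_map.tsv", sep="\t", index=False)
        outputs.update(intervals=outdir / "intervals.bed",
                       units=outdir / "units.bed",
                       unit_map=outdir / "unit_map.tsv")

        unit_regions = [u.region for u in seg.units_]
        unit_values = np.vstack(
            [matrix.values[list(u.site_indices)].sum(axis=0) for u in seg.units_]
        ) if seg.units_ else np.zeros((0, len(matrix.samples)))
        unit_matrix = IntensityMatrix(unit_regions, matrix.samples,
                                      matrix.groups, unit_values)
        fc_params = FoldChangeParams(L=config.fold_change.get("L", 36),
                                     beta=config.fold_change.get("beta", 10.0))
        score_regions(unit_matrix, fc_params).to_csv(
            outdir / "unit_scores.tsv", sep="\t", index=False)
        outputs["unit_scores"] = outdir / "unit_scores.tsv"

        perm_kwargs = dict(config.permutation)
        if seed is not None:
            perm_kwargs["seed"] = seed
        perm_cfg = PermutationConfig(**perm_kwargs)
        lengths = np.array([u.n_sites for u in seg.units_], dtype=float)
        calls, log = iterative_detect(unit_matrix, lengths, fc_params, perm_cfg,
                                      role="unit")
        calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        log.to_csv(outdir / "iteration_log.tsv", sep="\t", index=False)
        outputs.update(calls=outdir / "calls.tsv",
                       iteration_log=outdir / "iteration_log.tsv")
        _write_provenance(outdir, config, seed)
        outputs["config"] = outdir / "config.yaml"
        return outputs
    except Exception:
        (outdir / "FAILED").write_text("pipeline stage failed; see logs\n")
        raise


def run_smallrna(config: RunConfig, seed: int | None = None) -> dict[str, Path]:
    """Small-RNA branch: counts -> TPM -> permutation DE -> reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    section = config.smallrna or {}
    outputs: dict[str, Path] = {}
    try:
        if "counts" in section:
            counts = read_count_table(section["counts"])
            groups = read_groups(section["groups"])
            meta = (read_count_table(section["features"])
                    if "features" in section else None)
        else:
            gen_kwargs = dict(section.get("generator", {}))
            if seed is not None:
                gen_kwargs["seed"] = seed
            if "effect_sizes" in gen_kwargs:
                gen_kwargs["effect_sizes"] = tuple(gen_kwargs["effect_sizes"])
            sm_cfg = SmallRNAGenConfig(**gen_kwargs)
            counts, meta, groups, truth = generate_smallrna(sm_cfg)
            counts.to_csv(outdir / "smallrna_counts.tsv", sep="\t")
            meta.to_csv(outdir / "smallrna_features.tsv", sep="\t")
            write_groups(groups, outdir / "smallrna_groups.tsv")
            truth.to_yaml(outdir / "smallrna_truth.yaml")
            outputs["smallrna_truth"] = outdir / "smallrna_truth.yaml"

        lengths = meta["length_nt"] if meta is not None and "length_nt" in meta \
            else None
        tpm = tpm_normalize(counts, lengths)
        tpm.to_csv(outdir / "smallrna_tpm.tsv", sep="\t")
        de = permutation_de(tpm, groups,
                            n_perm=section.get("n_perm", 10000),
                            seed=seed if seed is not None else section.get("seed", 0),
                            alpha=section.get("alpha", 0.05))
        if meta is not None and "subtype" in meta:
            de.insert(1, "subtype",
                      meta["subtype"].reindex(de["feature_id"]).to_numpy())
            subtype_composition(counts, meta["subtype"]).to_csv(
                outdir / "smallrna_composition.tsv", sep="\t")
            outputs["composition"] = outdir / "smallrna_composition.tsv"
        de.to_csv(outdir / "smallrna_results.tsv", sep="\t", index=False)
        outputs.update(tpm=outdir / "smallrna_tpm.tsv",
                       results=outdir / "smallrna_results.tsv")
        _write_provenance(outdir, config, seed)
        outputs["config"] = outdir / "config.yaml"
        return outputs
    except Exception:
        (outdir / "FAILED").write_text("pipeline stage failed; see logs\n")
        raise


def overlap_report(calls: pd.DataFrame,
                   gene_list: Iterable[str]) -> tuple[pd.DataFrame, dict]:
    """Intersect significant promoter-level calls with a gene list.

    ``calls`` must carry gene ids in its region_id column.  Returns the
    per-gene intersection table (gene, direction, M, q) and a count
    summary.
    """
    genes = set(gene_list)
    sig = calls[calls["significant"]] if "significant" in calls else calls
    hit = sig[sig["region_id"].isin(genes)]
    cols = [c for c in ("region_id", "direction", "M", "q") if c in hit.columns]
    table = hit[cols].rename(columns={"region_id": "gene_id"}).reset_index(drop=True)
    summary = {"n_calls": int(len(sig)), "n_genes": len(genes),
               "n_overlap": int(len(table))}
    return table, summary
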