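"""Genomic coordinate universe: promoters, CpG sites and CpG islands.

All coordinates are 0-based half-open (BED dialect) internally.  1-based
(GFF-style) inputs must be converted at read time; the IO helpers in
:mod:`dmcap.io` do this where applicable.  A single internal convention
prevents off-by-one drift across the pipeline.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("promoter", "cpg_island", "cpg_site", "interval", "unit")
STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicRegion:
    """A strand-aware half-open interval with a role tag.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : {"+", "-", "."}
    role : {"promoter", "cpg_island", "cpg_site", "interval", "unit"}
        What the region represents in the pipeline.  CpG sites are single
        bases (``end == start + 1``).
    region_id : str
        Identifier, unique within a region set.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    role: str = "interval"
    region_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.region_id!r}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "cpg_site" and self.end != self.start + 1:
            raise ValueError("cpg_site regions must be single bases")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicRegion") -> int:
        """Length in bases of the intersection with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class PromoterSpec:
    """How promoters are constructed around a TSS.

    ``upstream_bp`` bases upstream of the transcription start site are
    included, clipped at chromosome boundaries; when
    ``include_first_exon`` is set (the default) the promoter extends
    through the first exon, because methylation in the upstream region
    and first exon correlates most strongly with reduced expression.
    """

    upstream_bp: int = 5000
    include_first_exon: bool = True

    def __post_init__(self) -> None:
        if self.upstream_bp <= 0:
            raise ValueError("upstream_bp must be positive")


def define_promoters(
    tss_table: pd.DataFrame,
    spec: PromoterSpec = PromoterSpec(),
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicRegion]:
    """Construct one promoter region per gene from a flat TSS table.

    ``tss_table`` needs columns ``gene_id, chrom, strand, tss,
    exon1_start, exon1_end`` (0-based half-open exon coordinates).  For a
    + strand gene the promoter is ``[max(0, tss - upstream), exon1_end)``;
    for a - strand gene it is ``[exon1_start, min(chrom_len, tss +
    upstream))`` — the strand-mirrored construction.  Records on unknown
    chromosomes, or whose first exon lies on the wrong side of the TSS,
    are rejected with a logged warning.

    Returns the promoters in input order, ``region_id`` equal to
    ``gene_id``.
    """
    required = {"gene_id", "chrom", "strand", "tss", "exon1_start", "exon1_end"}
    missing = required - set(tss_table.columns)
    if missing:
        raise ValueError(f"tss_table missing columns: {sorted(missing)}")

    promoters: list[GenomicRegion] = []
    for row in tss_table.itertuples(index=False):
        chrom = str(row.chrom)
        tss = int(row.tss)
        e_start, e_end = int(row.exon1_start), int(row.exon1_end)
        strand = str(row.strand)
        if chrom_sizes is not None and chrom not in chrom_sizes:
            logger.warning("gene %s: unknown chromosome %s, record rejected",
                           row.gene_id, chrom)
            continue
        chrom_len = chrom_sizes[chrom] if chrom_sizes is not None else None
        if chrom_len is not None and not (0 <= tss < chrom_len):
            logger.warning("gene %s: TSS %d outside chromosome bounds, rejected",
                           row.gene_id, tss)
            continue
        if e_start >= e_end:
            logger.warning("gene %s: empty first exon, rejected", row.gene_id)
            continue
        if strand == "+":
            # exon1 must contain or abut the TSS from downstream
            if not (e_start <= tss < e_end):
                logger.warning("gene %s: first exon on wrong side of TSS, rejected",
                               row.gene_id)
                continue
            start = max(0, tss - spec.upstream_bp)
            end = e_end if spec.include_first_exon else tss
            if end <= start:  # degenerate when first exon excluded and tss == 0
                logger.warning("gene %s: empty promoter, rejected", row.gene_id)
                continue
        elif strand == "-":
            # on the minus strand the first exon ends at the TSS
            if not (e_start < e_end <= tss + 1) or e_end < tss:
                logger.warning("gene %s: first exon on wrong side of TSS, rejected",
                               row.gene_id)
                continue
            start = e_start if spec.include_first_exon else tss
            end = tss + spec.upstream_bp
            if chrom_len is not None:
                end = min(chrom_len, end)
            if end <= start:
                logger.warning("gene %s: empty promoter, rejected", row.gene_id)
                continue
        else:
            logger.warning("gene %s: unstranded record, rejected", row.gene_id)
            continue
        promoters.append(
            GenomicRegion(chrom, start, end, strand, "promoter", str(row.gene_id))
        )
    return promoters


@dataclass
class ValidationReport:
    """Report-only validation result; the pipeline refuses to proceed on errors."""

    errors: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def n_errors(self) -> int:
        return len(self.errors)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.errors:
            out[e["kind"]] = out.get(e["kind"], 0) + 1
        return out


def validate_regions(
    regions: Sequence[GenomicRegion] | pd.DataFrame,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ValidationReport:
    """Check a region set for duplicate ids, zero/negative-length regions
    and out-of-bounds coordinates.

    Accepts either constructed :class:`GenomicRegion` objects or a raw
    DataFrame with columns ``region_id, chrom, start, end`` (so malformed
    rows that the dataclass would refuse to build can still be reported).
    """
    if isinstance(regions, pd.DataFrame):
        rows = list(regions[["region_id", "chrom", "start", "end"]].itertuples(index=False))
    else:
        rows = [(r.region_id, r.chrom, r.start, r.end) for r in regions]

    report = ValidationReport()
    seen: dict[str, int] = {}
    for rid, chrom, start, end in rows:
        seen[rid] = seen.get(rid, 0) + 1
        if end <= start:
            report.errors.append(
                {"kind": "zero_length", "region_id": rid,
                 "message": f"[{start}, {end}) has non-positive length"}
            )
        if start < 0:
            report.errors.append(
                {"kind": "out_of_bounds", "region_id": rid,
                 "message": f"negative start {start}"}
            )
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                report.errors.append(
                    {"kind": "out_of_bounds", "region_id": rid,
                     "message": f"unknown chromosome {chrom}"}
                )
            elif end > chrom_sizes[chrom]:
                report.errors.append(
                    {"kind": "out_of_bounds", "region_id": rid,
                     "message": f"end {end} beyond {chrom} length {chrom_sizes[chrom]}"}
                )
    for rid, count in seen.items():
        if count > 1:
            report.errors.append(
                {"kind": "duplicate_id", "region_id": rid,
                 "message": f"region_id appears {count} times"}
            )
    return report


def regions_to_frame(regions: Iterable[GenomicRegion]) -> pd.DataFrame:
    """Tabular view of a region set (one row per region, BED-like columns)."""
    return pd.DataFrame(
        [
            {"region_id": r.region_id, "chrom": r.chrom, "start": r.start,
             "end": r.end, "strand": r.strand, "role": r.role}
            for r in regions
        ],
        columns=["region_id", "chrom", "start", "end", "strand", "role"],
    )


def frame_to_regions(frame: pd.DataFrame, role: str | None = None) -> list[GenomicRegion]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            GenomicRegion(
                str(row.chrom), int(row.start), int(row.end),
                str(getattr(row, "strand", ".")),
                role or str(getattr(row, "role", "interval")),
                str(row.region_id),
            )
        )
    return out
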