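"""Readers and writers for the plain-text formats the pipeline speaks.

BED (3/6 column) for region sets and read intervals, TSV for the TSS
table, chromosome sizes, group labels and count tables.  All tables are
tab-separated with a header row unless the format forbids one (BED).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .regions import GenomicRegion

TSS_COLUMNS = ["gene_id", "chrom", "strand", "tss", "exon1_start", "exon1_end"]


def read_bed(path: str | Path, role: str = "interval") -> list[GenomicRegion]:
    """Read a BED3/BED6 file into regions. Column 4 (name) becomes region_id."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {i + 1} has fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"{role}_{i}"
            strand = fields[5] if len(fields) > 5 else "."
            regions.append(GenomicRegion(chrom, start, end, strand, role, name))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED6 (name = region_id, score = 0)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t{r.strand}\n")


def read_reads_bed(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read aligned-read intervals from BED into a DataFrame
    (chrom, start, end, sample_id)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {i + 1} has fewer than 3 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    frame["sample_id"] = sample_id if sample_id is not None else Path(path).stem
    return frame


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    reads[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(TSS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: TSS table missing columns {sorted(missing)}")
    return frame


def write_tss_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame[TSS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chrom, length), no header."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_groups(path: str | Path) -> pd.Series:
    """Sample group labels from a two-column TSV (sample_id, group)."""
    frame = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(frame.columns):
        raise ValueError(f"{path}: group table needs sample_id and group columns")
    groups = frame.set_index("sample_id")["group"]
    bad = set(groups.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return groups


def write_groups(groups: pd.Series | Mapping[str, str], path: str | Path) -> None:
    series = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    series.rename("group").rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Feature x sample count/TPM table; first column is the feature id."""
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index(frame.columns[0])


def write_count_table(frame: pd.DataFrame, path: str | Path,
                      index_name: str = "feature_id") -> None:
    frame.rename_axis(index_name).to_csv(path, sep="\t")
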