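"""Regional methylation intensity from aligned capture reads.

The methylation intensity of a region is the total number of bases of
short reads falling inside it: each read contributes the length of its
intersection with the region, clipped at the region boundaries.  Reads
are used as given — no deduplication, quality filtering or (by default)
depth normalization.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .regions import GenomicRegion, frame_to_regions, regions_to_frame

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")


@dataclass(frozen=True)
class ReadInterval:
    """One aligned short read as a half-open genomic interval."""

    chrom: str
    start: int
    end: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"read [{self.start}, {self.end}) has non-positive length")


def _reads_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        frame = reads
    else:
        frame = pd.DataFrame(
            [(r.chrom, r.start, r.end) for r in reads],
            columns=["chrom", "start", "end"],
        )
    if len(frame) and (frame["end"] - frame["start"] <= 0).any():
        raise ValueError("reads with non-positive length are not allowed")
    return frame


def region_intensity(reads, region: GenomicRegion) -> float:
    """Total bases of reads overlapping ``region`` (per-base, clipped).

    ``reads`` may be a DataFrame with chrom/start/end columns or an
    iterable of :class:`ReadInterval`.  Returns 0.0 when nothing
    overlaps.
    """
    frame = _reads_frame(reads)
    if frame.empty:
        return 0.0
    on_chrom = frame[frame["chrom"] == region.chrom]
    if on_chrom.empty:
        return 0.0
    overlap = (
        np.minimum(on_chrom["end"].to_numpy(), region.end)
        - np.maximum(on_chrom["start"].to_numpy(), region.start)
    )
    return float(np.clip(overlap, 0, None).sum())


class IntensityMatrix:
    """Region x sample nonnegative methylation intensities with group labels.

    Attributes
    ----------
    regions : list of GenomicRegion
    samples : list of str
    groups : pd.Series
        Sample -> {"case", "control"}.
    values : ndarray, shape (n_regions, n_samples)
        Intensities in bases, all >= 0.
    """

    def __init__(self, regions: Sequence[GenomicRegion], samples: Sequence[str],
                 groups: Mapping[str, str] | pd.Series, values: np.ndarray):
        self.regions = list(regions)
        self.samples = list(samples)
        self.groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series)
                                else groups).reindex(self.samples)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if (self.values < 0).any():
            raise ValueError("intensities must be nonnegative")
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if (self.groups == g).sum() < 1:
                raise ValueError(f"group {g!r} has no samples")

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    @property
    def case_indices(self) -> np.ndarray:
        return np.flatnonzero((self.groups == "case").to_numpy())

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero((self.groups == "control").to_numpy())

    def to_tsv(self, path: str | Path, groups_path: str | Path | None = None) -> None:
        """Write as TSV with region metadata columns followed by sample columns;
        group labels go to a sidecar TSV when ``groups_path`` is given."""
        frame = regions_to_frame(self.regions)
        for j, s in enumerate(self.samples):
            frame[s] = self.values[:, j]
        frame.to_csv(path, sep="\t", index=False)
        if groups_path is not None:
            from .io import write_groups

            write_groups(self.groups, groups_path)

    @classmethod
    def from_tsv(cls, path: str | Path, groups_path: str | Path) -> "IntensityMatrix":
        from .io import read_groups

        frame = pd.read_csv(path, sep="\t")
        meta_cols = ["region_id", "chrom", "start", "end", "strand", "role"]
        samples = [c for c in frame.columns if c not in meta_cols]
        regions = frame_to_regions(frame[meta_cols])
        groups = read_groups(groups_path)
        return cls(regions, samples, groups.reindex(samples),
                   frame[samples].to_numpy(dtype=float))


def build_intensity_matrix(
    read_sets: Mapping[str, pd.DataFrame | Iterable[ReadInterval]],
    regions: Sequence[GenomicRegion],
    group_labels: Mapping[str, str],
    scale_to_equal_depth: bool = False,
) -> IntensityMatrix:
    """Assemble the region x sample intensity matrix from per-sample reads.

    Row order follows ``regions``, column order follows ``read_sets``
    insertion order.  A sample with zero reads yields an all-zero column
    (with a warning).  ``scale_to_equal_depth`` optionally rescales each
    column so all samples have equal total mapped bases (off by
    default; the standard analysis applies none).
    """
    samples = list(read_sets)
    trees: dict[str, IntervalTree] = {}
    for idx, region in enumerate(regions):
        trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, idx
        )
    values = np.zeros((len(regions), len(samples)), dtype=float)
    total_bases = np.zeros(len(samples))
    for j, sample in enumerate(samples):
        frame = _reads_frame(read_sets[sample])
        if frame.empty:
            logger.warning("sample %s has zero reads; all-zero column", sample)
            continue
        total_bases[j] = float((frame["end"] - frame["start"]).sum())
        for chrom, start, end in frame[["chrom", "start", "end"]].itertuples(index=False):
            tree = trees.get(chrom)
            if tree is None:
                continue
            for hit in tree.overlap(start, end):
                values[hit.data, j] += min(end, hit.end) - max(start, hit.begin)
    if scale_to_equal_depth and (total_bases > 0).all():
        values = values * (total_bases.mean() / total_bases)
    return IntensityMatrix(regions, samples, dict(group_labels), values)


def aggregate_groups(matrix: IntensityMatrix) -> pd.DataFrame:
    """Per-region mean intensity within each group.

    The replicate rule is the arithmetic mean (not the sum) so the
    fold-change stays comparable across unequal replicate counts.
    Returns a DataFrame with columns region_id, I_case, I_control.
    """
    i_case = matrix.values[:, matrix.case_indices].mean(axis=1)
    i_control = matrix.values[:, matrix.control_indices].mean(axis=1)
    return pd.DataFrame(
        {"region_id": matrix.region_ids, "I_case": i_case, "I_control": i_control}
    )
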