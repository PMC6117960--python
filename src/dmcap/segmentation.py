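"""Segmentation of CpG sites into methylation intervals and units.

Nearby CpG sites are first merged into methylation intervals of
flexible length, leaving out gaps with no or minimal CpG sites.  Each
interval is then divided into methylation units at break points of
minimal inter-site correlation, so that a unit contains a subset of
highly correlated nearby CpG sites.  The unit is the granule at which
permutation inference is run.

Correlation is computed across ALL samples (both groups pooled), so
segmentation is blind to case/control labels and cannot leak group
information into the null distribution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .regions import GenomicRegion


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation thresholds.

    gap_threshold : maximum gap in bp between consecutive CpG sites that
        still belong to one methylation interval (default 300, the scale
        of typical CpG clustering).
    corr_threshold : minimum adjacent-site correlation for two sites to
        remain joined in one unit (default 0.3, a weak-correlation floor).
    min_samples_for_corr : minimum number of samples required to compute
        adjacent-site correlations (default 4).
    break_mode : "threshold" cuts at every adjacent pair below
        corr_threshold (deterministic and order-free); "local_minimum"
        cuts only at strict local minima of the correlation sequence
        that are also below the threshold (sensitivity-analysis mode).
    """

    gap_threshold: int = 300
    corr_threshold: float = 0.3
    min_samples_for_corr: int = 4
    break_mode: str = "threshold"

    def __post_init__(self) -> None:
        if self.gap_threshold <= 0:
            raise ValueError("gap_threshold must be positive")
        if not -1.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must be in [-1, 1]")
        if self.break_mode not in ("threshold", "local_minimum"):
            raise ValueError(f"unknown break_mode {self.break_mode!r}")


@dataclass(frozen=True)
class MethylationInterval:
    """A run of nearby CpG sites separated by gaps below the threshold."""

    region: GenomicRegion
    sites: tuple[GenomicRegion, ...]
    site_indices: tuple[int, ...]  # positions in the input site list


@dataclass(frozen=True)
class MethylationUnit:
    """A maximal sub-run of an interval with highly correlated adjacent sites."""

    region: GenomicRegion
    parent_id: str
    sites: tuple[GenomicRegion, ...]
    site_indices: tuple[int, ...]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def length_bp(self) -> int:
        return self.region.end - self.region.start


def _check_sorted(sites: list[GenomicRegion]) -> None:
    keys = [(s.chrom, s.start) for s in sites]
    if keys != sorted(keys):
        raise ValueError("CpG sites must be sorted by (chrom, start)")
    if len(set(keys)) != len(keys):
        raise ValueError("CpG sites must be unique")


def merge_cpg_sites(sites: list[GenomicRegion],
                    gap_threshold: int = 300) -> list[MethylationInterval]:
    """Greedy single-pass merge of sorted CpG sites into intervals.

    A new interval starts whenever the gap to the previous site (bases
    between the previous site's end and the next site's start) exceeds
    ``gap_threshold``, or the chromosome changes.  The interval spans
    from the first member's start to the last member's end.
    """
    _check_sorted(sites)
    intervals: list[MethylationInterval] = []
    run: list[int] = []

    def flush(run_idx: list[int], k: int) -> MethylationInterval:
        members = tuple(sites[i] for i in run_idx)
        region = GenomicRegion(
            members[0].chrom, members[0].start, members[-1].end,
            ".", "interval", f"mi_{members[0].chrom}_{k}",
        )
        return MethylationInterval(region, members, tuple(run_idx))

    counters: dict[str, int] = {}
    for i, site in enumerate(sites):
        if run:
            prev = sites[run[-1]]
            if site.chrom != prev.chrom or site.start - prev.end > gap_threshold:
                k = counters.get(prev.chrom, 0)
                intervals.append(flush(run, k))
                counters[prev.chrom] = k + 1
                run = []
        run.append(i)
    if run:
        chrom = sites[run[0]].chrom
        intervals.append(flush(run, counters.get(chrom, 0)))
    return intervals


def adjacent_correlations(profiles: np.ndarray) -> np.ndarray:
    """Pearson correlation across samples for each consecutive site pair.

    ``profiles`` has shape (n_sites, n_samples); the result has length
    n_sites - 1.  A pair in which either profile has zero variance gets
    correlation 0 by convention ("uncorrelated"), preventing undefined
    values from silently joining or splitting units.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be 2-D (n_sites, n_samples)")
    n_sites = profiles.shape[0]
    if n_sites < 2:
        return np.empty(0)
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    ss = (centered ** 2).sum(axis=1)
    num = (centered[:-1] * centered[1:]).sum(axis=1)
    den = np.sqrt(ss[:-1] * ss[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def _break_positions(correlations: np.ndarray, params: SegmentationParams) -> list[int]:
    r = np.asarray(correlations, dtype=float)
    below = r < params.corr_threshold
    if params.break_mode == "threshold":
        return [i for i in range(len(r)) if below[i]]
    cuts = []
    for i in range(len(r)):
        left_ok = i == 0 or r[i] < r[i - 1]
        right_ok = i == len(r) - 1 or r[i] < r[i + 1]
        if below[i] and left_ok and right_ok:
            cuts.append(i)
    return cuts


def split_units(interval: MethylationInterval, correlations: np.ndarray,
                params: SegmentationParams = SegmentationParams()) -> list[MethylationUnit]:
    """Split one methylation interval into units at sub-threshold breaks.

    ``correlations[i]`` is the adjacent correlation between member sites
    i and i+1.  Units are maximal runs of sites joined by correlations
    at or above ``corr_threshold``; a single-site interval yields one
    single-site unit.  The units partition the interval's member sites.
    """
    n = len(interval.sites)
    if len(correlations) != max(0, n - 1):
        raise ValueError("correlations do not match the interval's site count")
    cuts = set(_break_positions(np.asarray(correlations), params))
    units: list[MethylationUnit] = []
    run_start = 0
    for i in range(n):
        if i == n - 1 or i in cuts:
            members = interval.sites[run_start:i + 1]
            idx = interval.site_indices[run_start:i + 1]
            region = GenomicRegion(
                members[0].chrom, members[0].start, members[-1].end, ".",
                "unit", f"{interval.region.region_id}_u{len(units)}",
            )
            units.append(MethylationUnit(region, interval.region.region_id,
                                         members, idx))
            run_start = i + 1
    return units


class CpGUnitSegmenter(BaseEstimator):
    """Segment CpG sites into methylation intervals and units.

    scikit-learn style estimator: ``fit(X, sites=...)`` takes the site
    intensity profiles ``X`` of shape (n_sites, n_samples) and the
    coordinate-sorted site regions, and produces fitted attributes.

    Parameters
    ----------
    gap_threshold, corr_threshold, min_samples_for_corr, break_mode
        See :class:`SegmentationParams`.

    Attributes
    ----------
    intervals_ : list of MethylationInterval
    units_ : list of MethylationUnit
    labels_ : ndarray of int, shape (n_sites,)
        Index into ``units_`` for every input site.
    adjacent_corr_ : dict interval_id -> ndarray of adjacent correlations
    """

    def __init__(self, gap_threshold: int = 300, corr_threshold: float = 0.3,
                 min_samples_for_corr: int = 4, break_mode: str = "threshold"):
        self.gap_threshold = gap_threshold
        self.corr_threshold = corr_threshold
        self.min_samples_for_corr = min_samples_for_corr
        self.break_mode = break_mode

    def _params(self) -> SegmentationParams:
        return SegmentationParams(self.gap_threshold, self.corr_threshold,
                                  self.min_samples_for_corr, self.break_mode)

    def fit(self, X, y=None, *, sites: list[GenomicRegion]):
        params = self._params()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != len(sites):
            raise ValueError("X must be (n_sites, n_samples) matching `sites`")
        if X.shape[1] < params.min_samples_for_corr:
            raise ValueError(
                f"need >= {params.min_samples_for_corr} samples to estimate "
                f"adjacent-site correlations, got {X.shape[1]}"
            )
        self.intervals_ = merge_cpg_sites(list(sites), params.gap_threshold)
        self.units_ = []
        self.adjacent_corr_ = {}
        labels = np.full(len(sites), -1, dtype=int)
        for interval in self.intervals_:
            profiles = X[list(interval.site_indices)]
            r = adjacent_correlations(profiles)
            self.adjacent_corr_[interval.region.region_id] = r
            for unit in split_units(interval, r, params):
                for i in unit.site_indices:
                    labels[i] = len(self.units_)
                self.units_.append(unit)
        self.labels_ = labels
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None, *, sites: list[GenomicRegion]) -> np.ndarray:
        return self.fit(X, sites=sites).labels_

    def unit_map(self) -> pd.DataFrame:
        """Tidy unit_id -> member site id map for the fitted segmentation."""
        rows = [
            {"unit_id": u.region.region_id, "interval_id": u.parent_id,
             "site_id": s.region_id}
            for u in self.units_ for s in u.sites
        ]
        return pd.DataFrame(rows, columns=["unit_id", "interval_id", "site_id"])
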