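"""Regional intensity quantification against a per-base counting oracle."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmcap import (GenomicRegion, IntensityMatrix, ReadInterval,
                   aggregate_groups, build_intensity_matrix, region_intensity)


def brute_force_intensity(reads: pd.DataFrame, region: GenomicRegion) -> int:
    """Independent oracle: count read coverage base by base inside the region."""
    total = 0
    for pos in range(region.start, region.end):
        for chrom, start, end in reads[["chrom", "start", "end"]].itertuples(index=False):
            if chrom == region.chrom and start <= pos < end:
                total += 1
    return total


def reads_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestRegionIntensity:
    @pytest.mark.parametrize(
        "reads,region_span,expected",
        [
            ([("chr1", 100, 136)], (0, 1000), 36),   # fully contained read
            ([("chr1", 990, 1026)], (0, 1000), 10),  # clipped at region end
            ([("chr1", 2000, 2036)], (0, 1000), 0),  # no overlap
            ([], (0, 1000), 0),
        ],
    )
    def test_examples(self, reads, region_span, expected):
        region = GenomicRegion("chr1", *region_span, ".", "promoter", "p")
        assert region_intensity(reads_frame(reads), region) == expected

    def test_negative_length_read_rejected(self):
        region = GenomicRegion("chr1", 0, 1000, ".", "promoter", "p")
        with pytest.raises(ValueError):
            region_intensity(reads_frame([("chr1", 100, 100)]), region)
        with pytest.raises(ValueError):
            ReadInterval("chr1", 100, 90)

    def test_matches_per_base_oracle(self, rng):
        region_starts = sorted(rng.choice(2000, size=8, replace=False))
        regions = [GenomicRegion("chr1", int(s), int(s) + int(rng.integers(20, 200)),
                                 ".", "promoter", f"p{i}")
                   for i, s in enumerate(region_starts)]
        for _ in range(25):
            n_reads = int(rng.integers(0, 60))
            starts = rng.integers(0, 2200, size=n_reads)
            reads = reads_frame([("chr1", int(s), int(s) + 36) for s in starts])
            for region in regions:
                assert region_intensity(reads, region) == \
                    brute_force_intensity(reads, region)

    def test_additivity_over_partition(self, rng):
        """Intensity over a region equals the sum over any two-way split."""
        reads = reads_frame(
            [("chr1", int(s), int(s) + 36) for s in rng.integers(0, 500, size=40)]
        )
        whole = GenomicRegion("chr1", 100, 400, ".", "interval", "w")
        for cut in (101, 150, 250, 399):
            left = GenomicRegion("chr1", 100, cut, ".", "interval", "l")
            right = GenomicRegion("chr1", cut, 400, ".", "interval", "r")
            assert region_intensity(reads, whole) == \
                region_intensity(reads, left) + region_intensity(reads, right)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 600), st.integers(1, 80))
    def test_adding_a_read_never_decreases_intensity(self, start, length):
        region = GenomicRegion("chr1", 100, 400, ".", "interval", "w")
        base = reads_frame([("chr1", 150, 186), ("chr1", 390, 426)])
        more = pd.concat(
            [base, reads_frame([("chr1", start, start + length)])],
            ignore_index=True,
        )
        assert region_intensity(more, region) >= region_intensity(base, region)


class TestBuildIntensityMatrix:
    def setup_method(self):
        self.region = GenomicRegion("chr1", 0, 1000, ".", "promoter", "p0")
        self.groups = {"s1": "case", "s2": "control"}

    def test_fully_contained_reads(self):
        read_sets = {
            "s1": reads_frame([("chr1", 100, 136)]),
            "s2": reads_frame([("chr1", 200, 236)]),
        }
        m = build_intensity_matrix(read_sets, [self.region], self.groups)
        assert m.values.tolist() == [[36.0, 36.0]]

    def test_empty_region_set(self):
        read_sets = {"s1": reads_frame([("chr1", 0, 36)]), "s2": reads_frame([])}
        m = build_intensity_matrix(read_sets, [], self.groups)
        assert m.values.shape == (0, 2)

    def test_column_permutation_equivariance(self):
        read_sets = {
            "s1": reads_frame([("chr1", 0, 36)]),
            "s2": reads_frame([("chr1", 0, 36), ("chr1", 50, 86)]),
        }
        m12 = build_intensity_matrix(read_sets, [self.region], self.groups)
        m21 = build_intensity_matrix(
            {"s2": read_sets["s2"], "s1": read_sets["s1"]},
            [self.region], self.groups)
        assert m12.samples == ["s1", "s2"]
        assert m21.samples == ["s2", "s1"]
        assert m12.values[:, ::-1].tolist() == m21.values.tolist()

    def test_zero_read_sample_gives_zero_column(self, caplog):
        read_sets = {"s1": reads_frame([("chr1", 0, 36)]), "s2": reads_frame([])}
        with caplog.at_level("WARNING"):
            m = build_intensity_matrix(read_sets, [self.region], self.groups)
        assert m.values[:, 1].tolist() == [0.0]
        assert any("zero reads" in rec.message for rec in caplog.records)

    def test_depth_scaling_flag(self):
        read_sets = {
            "s1": reads_frame([("chr1", 0, 36)]),
            "s2": reads_frame([("chr1", 0, 36), ("chr1", 100, 136)]),
        }
        m = build_intensity_matrix(read_sets, [self.region], self.groups,
                                   scale_to_equal_depth=True)
        # columns rescaled to the mean total (54 bases): 36*54/36, 72*54/72
        assert m.values.tolist() == [[54.0, 54.0]]


class TestAggregateGroups:
    def make(self, case_vals, ctrl_vals):
        regions = [GenomicRegion("chr1", 0, 10, ".", "promoter", "p")]
        samples = [f"c{i}" for i in range(len(case_vals))] + \
                  [f"k{i}" for i in range(len(ctrl_vals))]
        groups = {s: ("case" if s.startswith("c") else "control") for s in samples}
        values = np.array([case_vals + ctrl_vals], dtype=float)
        return IntensityMatrix(regions, samples, groups, values)

    def test_mean_of_replicates(self):
        agg = aggregate_groups(self.make([100, 200], [50]))
        assert agg["I_case"].tolist() == [150.0]
        assert agg["I_control"].tolist() == [50.0]

    def test_single_replicate_identity(self):
        agg = aggregate_groups(self.make([720], [360]))
        assert (agg["I_case"][0], agg["I_control"][0]) == (720.0, 360.0)

    def test_all_zero_region(self):
        agg = aggregate_groups(self.make([0, 0], [0, 0]))
        assert (agg["I_case"][0], agg["I_control"][0]) == (0.0, 0.0)


class TestIntensityMatrixValidation:
    def test_negative_values_rejected(self):
        regions = [GenomicRegion("chr1", 0, 10, ".", "promoter", "p")]
        with pytest.raises(ValueError):
            IntensityMatrix(regions, ["a", "b"], {"a": "case", "b": "control"},
                            np.array([[-1.0, 0.0]]))

    def test_missing_group_rejected(self):
        regions = [GenomicRegion("chr1", 0, 10, ".", "promoter", "p")]
        with pytest.raises(ValueError):
            IntensityMatrix(regions, ["a", "b"], {"a": "case", "b": "case"},
                            np.array([[1.0, 2.0]]))

    def test_tsv_round_trip(self, tmp_path):
        regions = [GenomicRegion("chr1", 0, 10, "+", "promoter", "p0"),
                   GenomicRegion("chr2", 5, 25, "-", "promoter", "p1")]
        m = IntensityMatrix(regions, ["a", "b"], {"a": "case", "b": "control"},
                            np.array([[1.5, 2.0], [0.0, 7.25]]))
        m.to_tsv(tmp_path / "m.tsv", tmp_path / "g.tsv")
        back = IntensityMatrix.from_tsv(tmp_path / "m.tsv", tmp_path / "g.tsv")
        assert back.regions == regions
        assert back.samples == m.samples
        assert np.array_equal(back.values, m.values)
        assert back.groups.tolist() == m.groups.tolist()
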