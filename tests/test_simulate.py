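"""Synthetic-data generator: determinism, planted effects, noise moments and
round-trips through the pipeline's readers and writers."""
import numpy as np
import pandas as pd
import pytest

from dmcap import (GeneratorConfig, SmallRNAGenConfig, SyntheticTruth,
                   build_intensity_matrix, generate_genome,
                   generate_intensities, generate_smallrna,
                   generate_unit_matrix)
from dmcap.io import read_reads_bed, write_reads_bed


class TestGenerateGenome:
    def test_deterministic_under_fixed_seed(self):
        cfg = GeneratorConfig(n_promoters=10, seed=42)
        g1, g2 = generate_genome(cfg), generate_genome(cfg)
        assert g1.tss_table.equals(g2.tss_table)
        assert g1.cpg_sites == g2.cpg_sites
        assert g1.chrom_sizes == g2.chrom_sizes

    def test_zero_promoters(self):
        genome = generate_genome(GeneratorConfig(n_promoters=0))
        assert genome.tss_table.empty and genome.cpg_sites == []

    def test_promoters_do_not_overlap(self):
        genome = generate_genome(GeneratorConfig(n_promoters=40, seed=1))
        from dmcap import PromoterSpec, define_promoters

        regions = define_promoters(genome.tss_table, PromoterSpec(),
                                   genome.chrom_sizes)
        by_chrom: dict = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a_end <= b_start
                       for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_cpg_count_matches_poisson_mean(self):
        cfg = GeneratorConfig(n_promoters=1000, n_cpg_per_promoter=5.0, seed=0)
        genome = generate_genome(cfg)
        mean = len(genome.cpg_sites) / cfg.n_promoters
        se = np.sqrt(5.0 / cfg.n_promoters)
        assert abs(mean - 5.0) < 3 * se

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            generate_genome(GeneratorConfig(n_promoters=5,
                                            promoter_slot_bp=4000))

    def test_gaps_exercise_merge_and_split(self):
        genome = generate_genome(GeneratorConfig(n_promoters=300, seed=2))
        n_clusters = genome.site_meta["cluster_id"].nunique()
        n_promoters_with_sites = genome.site_meta["promoter_id"].nunique()
        assert n_clusters > n_promoters_with_sites  # some large gaps drawn


class TestGenerateIntensities:
    def test_no_effect_groups_exchangeable(self):
        cfg = GeneratorConfig(n_promoters=500, fraction_planted=0.0,
                              depth=200, noise="poisson", seed=0)
        genome = generate_genome(cfg)
        matrix, truth = generate_intensities(genome, cfg, level="promoter")
        assert truth.planted_ids == ()
        case = matrix.values[:, matrix.case_indices].mean()
        ctrl = matrix.values[:, matrix.control_indices].mean()
        assert case / ctrl == pytest.approx(1.0, abs=0.02)

    def test_planted_two_fold_ratio(self):
        cfg = GeneratorConfig(n_promoters=1000, fraction_planted=0.5,
                              effect_sizes=(2.0,), hyper_fraction=1.0,
                              depth=200, noise="poisson", seed=1)
        genome = generate_genome(cfg)
        matrix, truth = generate_intensities(genome, cfg, level="promoter")
        assert len(truth.planted_ids) == 500
        planted = np.isin(np.array(matrix.region_ids), list(truth.planted_ids))
        case = matrix.values[np.ix_(planted, matrix.case_indices)].mean()
        ctrl = matrix.values[np.ix_(planted, matrix.control_indices)].mean()
        assert 1.8 < case / ctrl < 2.2

    def test_reads_deterministic_and_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_promoters=20, fraction_planted=0.1, depth=30,
                              seed=7)
        genome = generate_genome(cfg)
        reads_a, _ = generate_intensities(genome, cfg, as_reads=True)
        reads_b, _ = generate_intensities(genome, cfg, as_reads=True)
        sample = next(iter(reads_a))
        write_reads_bed(reads_a[sample], tmp_path / "a.bed")
        write_reads_bed(reads_b[sample], tmp_path / "b.bed")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()
        back = read_reads_bed(tmp_path / "a.bed", sample)
        assert back[["chrom", "start", "end"]].equals(
            reads_a[sample][["chrom", "start", "end"]])

    def test_reads_quantify_to_whole_read_multiples(self):
        """Generated reads lie fully inside their promoter, so quantified
        intensities are exact multiples of the read length."""
        cfg = GeneratorConfig(n_promoters=15, depth=20, seed=3)
        genome = generate_genome(cfg)
        read_sets, _ = generate_intensities(genome, cfg, as_reads=True)
        from dmcap import PromoterSpec, define_promoters

        promoters = define_promoters(genome.tss_table, PromoterSpec(),
                                     genome.chrom_sizes)
        groups = {s: ("case" if s.startswith("case") else "control")
                  for s in read_sets}
        matrix = build_intensity_matrix(read_sets, promoters, groups)
        assert np.all(matrix.values % cfg.read_length == 0)
        assert matrix.values.sum() > 0

    def test_site_level_intra_unit_correlation(self):
        cfg = GeneratorConfig(n_promoters=400, n_cpg_per_promoter=6.0,
                              intra_unit_rho=0.9, depth=200, seed=4)
        genome = generate_genome(cfg)
        matrix, truth = generate_intensities(genome, cfg, level="cpg_site")
        idx = {s.region_id: i for i, s in enumerate(matrix.regions)}
        within, across = [], []
        unit_list = [m for m in truth.members.values() if len(m) >= 2]
        for members in unit_list[:200]:
            a, b = matrix.values[idx[members[0]]], matrix.values[idx[members[1]]]
            if a.std() > 0 and b.std() > 0:
                within.append(np.corrcoef(a, b)[0, 1])
        flat = [m[0] for m in unit_list]
        for u, v in zip(flat, flat[1:]):
            a, b = matrix.values[idx[u]], matrix.values[idx[v]]
            if a.std() > 0 and b.std() > 0:
                across.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(within) > 0.5 > np.mean(across)


class TestGenerateUnitMatrix:
    def test_lengths_scale_background_intensity(self):
        cfg = GeneratorConfig(n_promoters=0, fraction_planted=0.0, seed=0)
        matrix, site_counts, _ = generate_unit_matrix(cfg, 2000)
        small = matrix.values[site_counts <= 2].mean()
        large = matrix.values[site_counts >= 8].mean()
        assert large > 2 * small

    def test_dispersion_zero_limit_is_poisson(self):
        cfg = GeneratorConfig(n_promoters=0, fraction_planted=0.0,
                              noise="nb", dispersion=1e-12, depth=100, seed=0)
        matrix, _, _ = generate_unit_matrix(cfg, 1000)
        counts = matrix.values / cfg.read_length
        ratio = counts.var(axis=1, ddof=1).mean() / counts.mean()
        assert ratio == pytest.approx(1.0, abs=0.1)


class TestGenerateSmallRNA:
    def test_zero_planted_fraction(self):
        counts, meta, groups, truth = generate_smallrna(
            SmallRNAGenConfig(n_features=50, seed=0))
        assert truth.planted_ids == ()
        assert counts.shape == (50, 8)
        assert (groups == "case").sum() == 4

    def test_deterministic(self):
        cfg = SmallRNAGenConfig(n_features=40, fraction_planted=0.2, seed=9)
        a = generate_smallrna(cfg)
        b = generate_smallrna(cfg)
        assert a[0].equals(b[0]) and a[3].planted_ids == b[3].planted_ids

    def test_tissue_composition_profiles(self):
        counts_s, meta_s, _, _ = generate_smallrna(
            SmallRNAGenConfig(n_features=2000, tissue="sperm", seed=1))
        counts_m, meta_m, _, _ = generate_smallrna(
            SmallRNAGenConfig(n_features=2000, tissue="mammary", seed=1))
        assert (meta_s["subtype"] == "tRF").mean() > \
            (meta_s["subtype"] == "miRNA").mean()
        assert (meta_m["subtype"] == "miRNA").mean() > \
            (meta_m["subtype"] == "tRF").mean()


class TestSyntheticTruth:
    def test_yaml_round_trip(self, tmp_path):
        truth = SyntheticTruth(("u1", "u2"), {"u1": "hyper", "u2": "hypo"},
                               {"u1": 4.0, "u2": 4.0}, seed=3,
                               params={"depth": 200.0, "effect_sizes": (4.0,)},
                               members={"u1": ["s1", "s2"]})
        truth.to_yaml(tmp_path / "truth.yaml")
        back = SyntheticTruth.from_yaml(tmp_path / "truth.yaml")
        assert back.planted_ids == truth.planted_ids
        assert back.directions == truth.directions
        assert back.members == {"u1": ["s1", "s2"]}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(fraction_planted=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(effect_sizes=(1.0,))
        with pytest.raises(ValueError):
            SmallRNAGenConfig(tissue="liver")
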