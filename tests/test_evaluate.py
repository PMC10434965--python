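"""Concordance cell accounting and harmonization; coverage and off-target
classification; locus screening."""

import numpy as np
import pandas as pd
import pytest

from panelforge.dataio import MISSING
from panelforge.evaluate import (
    ConcordanceReport,
    classify_offtarget,
    concordance,
    coverage_profile,
    screen_loci,
)

from conftest import make_dataset


class TestConcordance:
    def test_dataset_vs_itself_is_fully_identical(self, two_pop_dataset):
        rep = concordance(two_pop_dataset, two_pop_dataset)
        assert rep.percent_identical == pytest.approx(100.0)
        assert rep.discordant == 0
        assert rep.missingness_ratio is None  # 0/0
        assert rep.cells_reconcile()

    def test_printed_count_arithmetic(self):
        """Worked example at the reported scale: 47 samples x 3,562 sites with
        375 vs 46 one-sided missing cells gives ratio 8.15 and 0.66%
        discordance over the full cell grid."""
        total = 47 * 3562
        rep = ConcordanceReport(
            n_samples=47,
            n_sites=3562,
            identical=165_544,
            discordant=1_100,
            missing_in_a_called_in_b=375,
            called_in_a_missing_in_b=46,
            missing_in_both=total - 165_544 - 1_100 - 375 - 46,
            per_site_discordance=pd.DataFrame(),
            harmonization_log=pd.DataFrame(),
        )
        assert rep.cells_reconcile()
        assert rep.missingness_ratio == pytest.approx(8.15, abs=0.005)
        assert rep.percent_discordant == pytest.approx(0.66, abs=0.005)
        assert rep.percent_identical == pytest.approx(98.9, abs=0.05)

    def test_swapped_alleles_harmonized(self):
        a = make_dataset([[0], [2], [1]])
        b = make_dataset([[2], [0], [1]])
        b.markers.loc[0, ["ref", "alt"]] = ["G", "A"]  # swapped orientation
        rep = concordance(a, b)
        assert rep.identical == 3 and rep.discordant == 0
        assert rep.harmonization_log["action"].tolist() == ["swapped"]

    def test_incompatible_alleles_dropped_and_logged(self):
        a = make_dataset([[0, 1], [2, 1]])
        b = make_dataset([[0, 1], [2, 1]])
        b.markers.loc[1, ["ref", "alt"]] = ["C", "T"]
        rep = concordance(a, b)
        assert rep.n_sites == 1
        assert rep.harmonization_log["action"].tolist() == ["dropped"]

    def test_five_cells_partition_and_transpose_symmetry(self):
        rng = np.random.default_rng(0)
        A = rng.integers(-1, 3, (6, 10)).astype(np.int8)
        B = rng.integers(-1, 3, (6, 10)).astype(np.int8)
        a, b = make_dataset(A), make_dataset(B)
        ab = concordance(a, b)
        ba = concordance(b, a)
        assert ab.cells_reconcile() and ba.cells_reconcile()
        assert ab.identical == ba.identical and ab.discordant == ba.discordant
        assert ab.missing_in_a_called_in_b == ba.called_in_a_missing_in_b
        assert ab.called_in_a_missing_in_b == ba.missing_in_a_called_in_b

    def test_no_shared_samples_errors(self):
        a = make_dataset([[0]], samples=["x"])
        b = make_dataset([[0]], samples=["y"])
        with pytest.raises(ValueError, match="shared samples"):
            concordance(a, b)


class TestCoverage:
    def test_uniform_depth_saturates_curve(self):
        table = pd.DataFrame(np.full((3, 5), 20), index=list("abc"))
        prof = coverage_profile(table, thresholds=[1, 10, 20, 21])
        assert (prof.curves[10] == 1.0).all()
        assert (prof.curves[21] == 0.0).all()

    def test_zero_depth_gives_zero_curve(self):
        table = pd.DataFrame(np.zeros((2, 4)))
        prof = coverage_profile(table, thresholds=[1, 5])
        assert (prof.curves.to_numpy() == 0).all()

    def test_toy_table_matches_hand_computation(self):
        table = pd.DataFrame([[5, 10, 15, 20], [0, 10, 20, 30]], index=["a", "b"])
        prof = coverage_profile(table, thresholds=[10, 15])
        assert prof.curves.loc["a", 10] == 0.75
        assert prof.curves.loc["b", 10] == 0.75
        assert prof.curves.loc["a", 15] == 0.5
        assert prof.per_sample_mean["a"] == 12.5
        assert prof.per_sample_sd["a"] == pytest.approx(np.std([5, 10, 15, 20], ddof=1))
        assert prof.grand_mean == pytest.approx(13.75)

    def test_curves_non_increasing(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.poisson(25, (10, 50)))
        prof = coverage_profile(table)
        assert (prof.curves.diff(axis=1).fillna(0).to_numpy() <= 0).all()

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            coverage_profile(pd.DataFrame())


class TestOfftarget:
    def test_constructed_fixture_counts(self):
        chroms = ["1"] * 12 + ["2"] * 3
        pos = [
            1000,                      # target
            1100, 1120, 1151,          # near, near, far (151 bp)
            50_000, 50_500, 52_000,    # far cluster of 3
            90_000,                    # far singleton
            200_000,                   # target
            200_100, 200_150,          # near, near (inclusive boundary)
            400_000,                   # far singleton
            500, 700, 40_000,          # chr2: no targets -> far; cluster of 2 + 1
        ]
        G = np.tile(np.array([[0], [1], [2], [0]], dtype=np.int8), (1, len(pos)))
        ds = make_dataset(G, chroms=chroms, positions=pos)
        targets = [("1", 1000), ("1", 200_000)]
        rep = classify_offtarget(ds, targets, near_bp=150, cluster_gap=10_000)
        assert rep.n_target == 2
        assert rep.n_offtarget == 13
        near = set(zip(rep.table[rep.table.classification == "near"].chrom,
                       rep.table[rep.table.classification == "near"].pos))
        assert near == {("1", 1100), ("1", 1120), ("1", 200_100), ("1", 200_150)}
        assert rep.n_far == 9
        assert rep.fraction_near == pytest.approx(4 / 13)
        # chr2 has no targets: all far, infinite distance
        chr2 = rep.table[rep.table.chrom == "2"]
        assert (chr2.classification == "far").all()
        assert np.isinf(chr2.distance).all()
        # clusters: {1151}, {50000,50500,52000}, {90000}, {400000},
        # chr2 {500,700}, {40000}
        assert sorted(rep.clusters["n_snps"]) == [1, 1, 1, 1, 2, 3]

    def test_boundary_inclusive_at_near_bp(self):
        ds = make_dataset(np.array([[0, 1, 1], [1, 0, 1]], dtype=np.int8),
                          positions=[1000, 1150, 1151])
        rep = classify_offtarget(ds, [("1", 1000)], near_bp=150)
        cls = rep.table.set_index("pos")["classification"]
        assert cls[1150] == "near" and cls[1151] == "far"

    def test_far_clusters_grouped_by_gap(self):
        positions = [1000, 50_000, 50_500, 52_000, 90_000]
        ds = make_dataset(
            np.tile(np.array([[0], [1]], dtype=np.int8), (1, 5)), positions=positions
        )
        rep = classify_offtarget(ds, [("1", 1000)], near_bp=150, cluster_gap=10_000)
        assert rep.n_far == 4
        assert len(rep.clusters) == 2
        sizes = sorted(rep.clusters["n_snps"])
        assert sizes == [1, 3]

    def test_far_range_mirrors_reported_scale(self):
        # a SNP 31 kbp from the nearest target is classified far
        ds = make_dataset(np.array([[0, 1], [1, 0]], dtype=np.int8),
                          positions=[1000, 32_000])
        rep = classify_offtarget(ds, [("1", 1000)], near_bp=150)
        assert rep.table.iloc[0]["distance"] == 31_000
        assert rep.table.iloc[0]["classification"] == "far"

    def test_low_maf_fraction(self):
        ds = make_dataset(
            np.array([[0, 0, 1], [0, 1, 1], [0, 0, 2], [0, 0, 1]], dtype=np.int8),
            positions=[1000, 5000, 9000],
        )
        rep = classify_offtarget(ds, [("1", 1000)], maf_cut=0.2)
        # non-targets: pos 5000 maf 1/8 < 0.2; pos 9000 maf 3/8 >= 0.2
        assert rep.low_maf_fraction == pytest.approx(0.5)

    def test_empty_panel_rejected(self, two_pop_dataset):
        with pytest.raises(ValueError, match="empty"):
            classify_offtarget(two_pop_dataset, [])


class TestScreen:
    def test_counts_partition_samples(self):
        ds = make_dataset(np.array([[0], [1], [2], [MISSING]], dtype=np.int8))
        table = screen_loci(ds, [("1", 1000, "locus1")])
        row = table.iloc[0]
        assert (row.hom_ref, row.het, row.hom_alt, row.missing) == (1, 1, 1, 1)
        assert row.assayed

    def test_all_homozygous_reference_pattern(self):
        # the resistance-screen outcome: every sample hom-ref
        ds = make_dataset(np.zeros((5, 2), dtype=np.int8))
        table = screen_loci(ds, [("1", 1000, "a"), ("1", 2000, "b")])
        assert (table["hom_ref"] == 5).all()
        assert (table[["het", "hom_alt", "missing"]].to_numpy() == 0).all()

    def test_locus_absent_reported_not_assayed(self):
        ds = make_dataset(np.zeros((2, 1), dtype=np.int8))
        table = screen_loci(ds, [("7", 127_895_440, "vk1")])
        assert not table.iloc[0]["assayed"]
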