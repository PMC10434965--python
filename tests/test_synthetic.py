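"""Generator calibration: drift moments, HWE, LD, pedigrees, artefacts."""

import numpy as np
import pytest

from panelforge.dataio import MISSING, write_vcf
from panelforge.qc import pairwise_r2
from panelforge.synthetic_data import (
    PedigreeDesign,
    SimConfig,
    corrupt_genotypes,
    sim_genotypes,
    sim_pedigree,
    sim_seq_artifacts,
    sim_structured_freqs,
    sim_study,
)


class TestStructuredFreqs:
    def test_zero_drift_returns_ancestral_exactly(self):
        cfg = SimConfig(n_pops=3, n_markers=50, fst=0.0, seed=1)
        freqs = sim_structured_freqs(cfg)
        anc = freqs.attrs["ancestral"]
        for k in range(3):
            np.testing.assert_array_equal(freqs.iloc[k].to_numpy(), anc)

    def test_extreme_drift_concentrates_at_boundaries(self):
        cfg = SimConfig(
            n_pops=1, n_markers=4000, fst=0.999, anc_freq_range=(0.49, 0.51), seed=2
        )
        p = sim_structured_freqs(cfg).iloc[0].to_numpy()
        assert (np.minimum(p, 1 - p) < 0.05).mean() > 0.9

    def test_drift_variance_matches_balding_nichols_moment(self):
        # Var[p_k] = F p (1 - p): 10,000 replicate draws at p=0.5, F=0.1
        cfg = SimConfig(
            n_pops=1, n_markers=10_000, fst=0.1, anc_freq_range=(0.4999, 0.5001), seed=3
        )
        p = sim_structured_freqs(cfg).iloc[0].to_numpy()
        expected = 0.1 * 0.5 * 0.5
        assert abs(p.var() - expected) < 5 * expected / np.sqrt(10_000) * np.sqrt(2)
        assert abs(p.mean() - 0.5) < 0.01

    def test_complete_fixation_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SimConfig(fst=1.0).validate()


class TestGenotypes:
    def test_zero_markers_gives_valid_empty_dataset(self):
        cfg = SimConfig(n_pops=2, n_per_pop=5, n_markers=0, seed=0)
        ds = sim_genotypes(sim_structured_freqs(cfg), cfg)
        assert ds.n_markers == 0 and ds.n_samples == 10

    def test_mean_dosage_matches_hwe_expectation(self):
        cfg = SimConfig(
            n_pops=1,
            n_per_pop=400,
            n_markers=300,
            fst=0.0,
            anc_freq_range=(0.4999, 0.5001),
            miss_rate=0.0,
            seed=4,
        )
        ds = sim_genotypes(sim_structured_freqs(cfg), cfg)
        # binomial(2, 0.5) mean 1.0; SE of the grand mean over 120k draws tiny
        assert abs(ds.G.mean() - 1.0) < 0.01

    def test_hudson_fst_recovers_drift_parameter(self):
        cfg = SimConfig(
            n_pops=2, n_per_pop=100, n_markers=2000, fst=0.1, miss_rate=0.0, seed=5
        )
        ds, _, _ = sim_study(cfg)
        lab = ds.population_labels
        g1 = ds.G[lab == "pop1"].astype(float)
        g2 = ds.G[lab == "pop2"].astype(float)
        n1, n2 = 2 * len(g1), 2 * len(g2)
        p1, p2 = g1.mean(0) / 2, g2.mean(0) / 2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst_hat = num.sum() / den.sum()
        assert abs(fst_hat - 0.1) < 0.02

    def test_ld_blocks_create_high_adjacent_r2_and_leak_breaks_it(self):
        cfg = SimConfig(
            n_pops=1, n_per_pop=200, n_markers=200, fst=0.0, ld_block_size=5,
            ld_leak=0.05, miss_rate=0.0, seed=6,
        )
        ds = sim_genotypes(sim_structured_freqs(cfg), cfg)
        within = [pairwise_r2(ds.G[:, j], ds.G[:, j + 1]) for j in range(0, 200, 5)]
        assert np.mean(within) > 0.6
        # block size 1: independent markers, low r2
        cfg1 = SimConfig(
            n_pops=1, n_per_pop=200, n_markers=200, fst=0.0, ld_block_size=1,
            miss_rate=0.0, seed=6,
        )
        ds1 = sim_genotypes(sim_structured_freqs(cfg1), cfg1)
        indep = [pairwise_r2(ds1.G[:, j], ds1.G[:, j + 1]) for j in range(100)]
        assert np.mean(indep) < 0.1


class TestPedigree:
    def test_expected_kinships_follow_pedigree_theory(self):
        design = PedigreeDesign(n_parent_offspring=1, n_cousin=1)
        _, truth = sim_pedigree(np.full(50, 0.5), design, seed=0)
        d = truth.dyads.set_index(["sample_a", "sample_b"])
        assert d.loc[("ped_po1_f", "ped_po1_c"), "kinship"] == 0.25
        assert d.loc[("ped_po1_f", "ped_po1_c"), "degree"] == "1st"
        assert d.loc[("ped_cz2_c1", "ped_cz2_c2"), "kinship"] == 0.0625
        assert d.loc[("ped_cz2_c1", "ped_cz2_c2"), "degree"] == "3rd"

    def test_truth_table_complete_and_values_canonical(self, pedigree_study):
        ds, _, truth = pedigree_study
        samples = set(ds.samples)
        assert set(truth.dyads["sample_a"]) <= samples
        assert set(truth.dyads["sample_b"]) <= samples
        assert set(truth.dyads["kinship"]) <= {0.25, 0.125, 0.0625, 0.0}
        # symmetric pairs stored once
        keys = {tuple(sorted(p)) for p in zip(truth.dyads.sample_a, truth.dyads.sample_b)}
        assert len(keys) == len(truth.dyads)

    def test_mendelian_consistency_exhaustive(self, pedigree_study):
        ds, _, truth = pedigree_study
        idx = {s: i for i, s in enumerate(ds.samples)}
        compatible = {
            (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
            (1, 1): {0, 1, 2}, (1, 2): {1, 2}, (2, 2): {2},
        }
        for row in truth.parents.itertuples(index=False):
            gc = ds.G[idx[row.child]]
            gf = ds.G[idx[row.father]]
            gm = ds.G[idx[row.mother]]
            for c, f, m in zip(gc, gf, gm):
                key = tuple(sorted((int(f), int(m))))
                assert int(c) in compatible[key], (c, f, m)

    def test_full_sib_realized_kinship_near_quarter(self):
        """Gene-dropping at 5,000 markers: classical estimate with the true
        founder frequencies lands within +-0.03 of 0.25."""
        rng = np.random.default_rng(8)
        p = rng.uniform(0.2, 0.8, 5000)
        design = PedigreeDesign(n_full_sib=1)
        ds, truth = sim_pedigree(p, design, seed=8)
        i = ds.samples.index("ped_fs1_c1")
        j = ds.samples.index("ped_fs1_c2")
        gi, gj = ds.G[i].astype(float), ds.G[j].astype(float)
        phi = ((gi - 2 * p) * (gj - 2 * p)).sum() / (4 * (p * (1 - p)).sum())
        assert abs(phi - 0.25) < 0.03

    def test_out_of_order_pedigree_rejected(self):
        from panelforge.synthetic_data import _Pedigree

        ped = _Pedigree()
        with pytest.raises(ValueError, match="cyclic or out-of-order"):
            ped.add_child("child", "ghost_father", "ghost_mother")


class TestCorruption:
    def test_zero_rates_are_identity(self, two_pop_dataset):
        out = corrupt_genotypes(two_pop_dataset, 0.0, 0.0, seed=1)
        assert out.equals(two_pop_dataset)

    def test_full_missingness(self, two_pop_dataset):
        out = corrupt_genotypes(two_pop_dataset, 1.0, 0.0, seed=1)
        assert (out.G == MISSING).all()

    def test_missing_fraction_within_binomial_error(self):
        cfg = SimConfig(n_pops=1, n_per_pop=100, n_markers=100, miss_rate=0.0, seed=9)
        ds, _, _ = sim_study(cfg)
        out = corrupt_genotypes(ds, 0.1, 0.0, seed=9)
        frac = (out.G == MISSING).mean()
        sd = np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(frac - 0.1) < 3 * sd

    def test_errors_land_on_valid_other_dosages(self, two_pop_dataset):
        out = corrupt_genotypes(two_pop_dataset, 0.0, 1.0, seed=2)
        changed = (out.G != two_pop_dataset.G) | (out.G == MISSING)
        assert changed.all()
        assert set(np.unique(out.G)) <= {0, 1, 2}


class TestSeqArtifacts:
    def test_mean_depth_matches_target_regime(self):
        """The generator reproduces the ~27.6x mean target coverage regime."""
        cfg = SimConfig(n_pops=1, n_per_pop=50, n_markers=500, miss_rate=0.0, seed=10)
        ds, _, _ = sim_study(cfg)
        out, depth = sim_seq_artifacts(ds, cfg)
        assert abs(out.DP.mean() - 27.6) < 0.3
        # dispersion default targets an SD near 9.84
        assert abs(out.DP.std() - 9.84) < 1.0
        assert depth.shape == (50, 500)

    def test_zero_depth_means_all_missing(self, two_pop_dataset):
        cfg = SimConfig(mean_depth=0.0)
        out, _ = sim_seq_artifacts(two_pop_dataset, cfg)
        assert (out.DP == 0).all() and (out.G == MISSING).all()

    def test_gq_capped_and_monotone_in_dp(self, two_pop_dataset):
        cfg = SimConfig(mean_depth=60.0, seed=3)
        out, _ = sim_seq_artifacts(two_pop_dataset, cfg)
        assert out.GQ.max() <= 99
        flat_dp = out.DP.ravel()
        flat_gq = out.GQ.ravel()
        order = np.argsort(flat_dp)
        assert (np.diff(flat_gq[order]) >= 0).all()


def test_same_config_gives_byte_identical_vcf(tmp_path):
    cfg = SimConfig(n_pops=2, n_per_pop=10, n_markers=50, seed=11)
    for name in ("a.vcf", "b.vcf"):
        ds, _, _ = sim_study(cfg)
        ds, _ = sim_seq_artifacts(ds, cfg, np.random.default_rng(cfg.seed + 1))
        write_vcf(ds, tmp_path / name)
    assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()
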