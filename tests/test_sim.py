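"""Generators: determinism, planted-truth bookkeeping, and the distributional
contracts of the read/CGH/expression simulators."""

import numpy as np
import pytest
from scipy import stats

from clusterhop.core import GenomeSequence, Region, revcomp
from clusterhop import sim


class TestMakeReference:
    def test_requested_shape_and_determinism(self):
        g1 = sim.make_reference(2, [10000, 8000], 0.5, seed=1)
        g2 = sim.make_reference(2, [10000, 8000], 0.5, seed=1)
        assert g1.names() == ["chrI", "chrII"]
        assert [g1.length(n) for n in g1.names()] == [10000, 8000]
        assert g1 == g2
        assert sim.make_reference(2, [10000, 8000], 0.5, seed=2) != g1

    def test_gc_content_within_binomial_tolerance(self):
        # n = 100000 draws: sd of the GC fraction is sqrt(p(1-p)/n) ~ 0.0015,
        # so +/- 0.01 is a > 6-sigma band
        g = sim.make_reference(1, [100000], 0.38, seed=7)
        s = g["chrI"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.38) < 0.01
        assert set(s) <= set("ACGT")

    @pytest.mark.parametrize(
        "n,lengths,gc",
        [(2, [10000], 0.5), (1, [500], 0.5), (1, [10000], 0.0), (0, [], 0.5)],
    )
    def test_argument_validation(self, n, lengths, gc):
        with pytest.raises(ValueError):
            sim.make_reference(n, lengths, gc, seed=0)


class TestPlantClusterDuplication:
    def test_no_sites_is_identity(self, toy_reference):
        donor = Region("chrI", 12000, 16000)
        sample, truth = sim.plant_cluster_duplication(toy_reference, donor, [])
        assert sample == toy_reference
        assert truth.copy_count == 1

    def test_length_bookkeeping(self, toy_reference):
        donor = Region("chrI", 12000, 16000)
        sites = [("chrII", 3000), ("chrII", 9000)]
        sample, truth = sim.plant_cluster_duplication(toy_reference, donor, sites)
        assert sample.length("chrII") == toy_reference.length("chrII") + 8000
        assert sample.length("chrI") == toy_reference.length("chrI")
        assert truth.copy_count == 3

    def test_insertion_roundtrip_recovers_donor(self, toy_reference):
        # extracting donor-length windows at truth sites (shifted by prior
        # insertions on the same chromosome) must give back the donor exactly
        donor = Region("chrI", 12000, 16000)
        sites = [("chrII", 3000), ("chrII", 9000), ("chrI", 2000)]
        sample, truth = sim.plant_cluster_duplication(toy_reference, donor, sites)
        donor_seq = toy_reference.fetch(donor)
        per_chrom = {}
        for chrom, pos in truth.insertion_sites:
            per_chrom.setdefault(chrom, []).append(pos)
        for chrom, positions in per_chrom.items():
            for pos in positions:
                shift = sum(len(donor) for p in positions if p < pos)
                assert sample[chrom][pos + shift : pos + shift + len(donor)] == donor_seq

    def test_paper_style_coordinates(self, toy_reference):
        # recipient coordinates given 1-based (as printed) are converted at
        # the boundary; two interior sites -> three total cluster copies
        donor = Region("chrI", 16000, 20000)
        sites = [("chrII", 5560 - 1), ("chrII", 10671 - 1)]
        _, truth = sim.plant_cluster_duplication(toy_reference, donor, sites)
        assert truth.copy_count == 3

    def test_site_inside_donor_rejected(self, toy_reference):
        donor = Region("chrI", 12000, 16000)
        with pytest.raises(ValueError):
            sim.plant_cluster_duplication(toy_reference, donor, [("chrI", 13000)])
        with pytest.raises(ValueError):
            sim.plant_cluster_duplication(toy_reference, donor, [("chrX", 1)])


class TestSimulatePairedReads:
    def test_error_free_reads_are_exact_substrings(self, toy_reference):
        pairs = sim.simulate_paired_reads(toy_reference, 2.0, 151, 500, 12.5, 0.0, seed=3)
        assert len(pairs) > 0
        for p in pairs:
            c1, pos1, strand1 = p.origin1
            c2, pos2, strand2 = p.origin2
            assert (strand1, strand2) == ("+", "-")
            assert toy_reference[c1][pos1 : pos1 + 151] == p.seq1
            assert revcomp(toy_reference[c2][pos2 : pos2 + 151]) == p.seq2

    def test_pair_count_poisson(self):
        g = sim.make_reference(1, [1_000_000], 0.4, seed=9)
        pairs = sim.simulate_paired_reads(g, 30.0, 151, 500, 12.5, 0.0, seed=9)
        lam = 30.0 * 1_000_000 / (2 * 151)
        assert abs(len(pairs) - lam) < 3 * np.sqrt(lam)

    def test_insert_sizes_within_selection_window(self, toy_reference):
        pairs = sim.simulate_paired_reads(toy_reference, 5.0, 151, 500, 12.5, 0.0, seed=4)
        inserts = [p.origin2[1] + 151 - p.origin1[1] for p in pairs]
        frac = np.mean([(475 <= i <= 525) for i in inserts])
        assert frac >= 0.95

    def test_determinism(self, toy_reference):
        a = sim.simulate_paired_reads(toy_reference, 1.0, 151, 500, 12.5, 0.01, seed=8)
        b = sim.simulate_paired_reads(toy_reference, 1.0, 151, 500, 12.5, 0.01, seed=8)
        assert [(p.seq1, p.seq2) for p in a] == [(p.seq1, p.seq2) for p in b]

    def test_argument_validation(self, toy_reference):
        with pytest.raises(ValueError):
            sim.simulate_paired_reads(toy_reference, 1.0, 151, 300, 12.5, 0.0, seed=0)
        with pytest.raises(ValueError):
            sim.simulate_paired_reads(toy_reference, 1.0, 151, 500, 12.5, 0.5, seed=0)


class TestSimulateCGH:
    def test_planted_effect_centers_values(self):
        genes, strains = ["g1", "g2"], ["R1", "S1"]
        for effect in (1.0, -1.0):
            tab = sim.simulate_cgh(
                genes, strains, {("g1", "R1"): effect}, replicates=200,
                noise_sd=1e-4, seed=1,
            )
            grp = tab.set_index(["gene", "strain"])
            vals = grp.loc[("g1", "R1"), "log2_ratio"]
            assert abs(vals.mean() - effect) < 1e-4
            assert abs(grp.loc[("g2", "S1"), "log2_ratio"].mean()) < 1e-4

    def test_null_table_standard_error(self):
        reps = 12
        tab = sim.simulate_cgh(
            [f"g{i}" for i in range(200)], ["s1"], {}, replicates=reps,
            noise_sd=0.25, seed=2,
        )
        means = tab.groupby("gene")["log2_ratio"].mean()
        # per-gene mean has sd noise_sd/sqrt(reps); check the empirical sd
        se = 0.25 / np.sqrt(reps)
        assert abs(means.mean()) < 4 * se / np.sqrt(200)
        assert 0.7 * se < means.std() < 1.3 * se

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            sim.simulate_cgh(["g"], ["s"], {}, replicates=1)
        with pytest.raises(ValueError):
            sim.simulate_cgh(["g"], ["s"], {("bad", "s"): 1.0})


class TestSimulateExpression:
    GROUPS = {f"s{i}": "sensitive" for i in range(20)}

    def test_positive_block_correlates(self):
        mat = sim.simulate_expression(
            ["g1", "g2", "g3"], list(self.GROUPS), self.GROUPS,
            coexpr_blocks=[(["g1", "g2"], +1)], noise_sd=0.1, seed=3,
        )
        rho = stats.spearmanr(mat.loc["g1"], mat.loc["g2"]).statistic
        assert rho > 0.8

    def test_negative_block_anticorrelates(self):
        mat = sim.simulate_expression(
            ["g1", "g3"], list(self.GROUPS), self.GROUPS,
            coexpr_blocks=[(["g1", "g3"], -1)], noise_sd=0.1, seed=4,
        )
        rho = stats.spearmanr(mat.loc["g1"], mat.loc["g3"]).statistic
        assert rho < -0.8

    def test_null_pairwise_correlations_match_null_quantile(self):
        genes = [f"g{i}" for i in range(15)]
        mat = sim.simulate_expression(genes, list(self.GROUPS), self.GROUPS, seed=5)
        n = len(self.GROUPS)
        # permutation null quantile of |rho| at n strains, estimated once
        rng = np.random.default_rng(0)
        null = [
            abs(stats.spearmanr(rng.permutation(n), np.arange(n)).statistic)
            for _ in range(2000)
        ]
        q95 = np.quantile(null, 0.95)
        rhos = []
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                rhos.append(abs(stats.spearmanr(mat.iloc[i], mat.iloc[j]).statistic))
        assert np.mean(np.array(rhos) <= q95) >= 0.85  # binomial slack on 105 pairs

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_expression(
                ["g1", "g2"], list(self.GROUPS), self.GROUPS,
                coexpr_blocks=[(["g1", "g2"], 1), (["g2"], -1)],
            )
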