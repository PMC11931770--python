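"""Alignment, triage, pileup calling, motif discovery and normalization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from ptscope import community, ptseq
from ptscope.community import PTSystem, build_community, revcomp, simulate_ptseq_reads
from ptscope.lcms import PTProfile
from ptscope.ptseq import (
    GenomeStats,
    assign_reads,
    call_pileups,
    crossvalidate_lcms,
    cutoff_sweep,
    depth_profile,
    equivalent_pt_per_million,
    extract_windows,
    find_anchored_motifs,
    five_prime_depths,
    genome_features,
    genome_stats,
    gmm_cluster,
    select_candidate_genomes,
)


class TestAssignReads:
    GENOMES = {"gA": "ACGTACGGTTCAGCCATAGGCTTACGATCGTA", "gB": "TTGACCATAGGCTTAGGCAC"}

    def test_unique_read_has_weight_one(self):
        aln = assign_reads([("r1", "ACGTACGG")], self.GENOMES)
        assert len(aln) == 1
        row = aln.iloc[0]
        assert (row["genome"], row["pos0"], row["strand"]) == ("gA", 0, "+")
        assert row["n_hits"] == 1 and row["weight"] == 1.0

    def test_multi_mapper_split_across_genomes(self):
        aln = assign_reads([("r1", "CCATAGGC")], self.GENOMES)
        assert len(aln) == 2
        assert set(aln["genome"]) == {"gA", "gB"}
        assert (aln["weight"] == 0.5).all() and (aln["n_hits"] == 2).all()

    def test_minus_strand_five_prime_is_interval_end(self):
        read = revcomp(self.GENOMES["gA"][4:12])
        aln = assign_reads([("r1", read)], self.GENOMES)
        row = aln.iloc[0]
        assert (row["pos0"], row["strand"]) == (11, "-")

    def test_weights_sum_to_mapped_reads(self):
        reads = [("r1", "CCATAGGC"), ("r2", "ACGTACGG"), ("r3", "GGGGGGGG")]
        aln = assign_reads(reads, self.GENOMES)
        assert aln.groupby("read_id")["weight"].sum().sum() == pytest.approx(2.0)

    def test_unmappable_reads_are_not_an_error(self):
        aln = assign_reads([("r1", "GGGGGGGG")], self.GENOMES)
        assert len(aln) == 0


class TestGenomeStats:
    def test_no_reads_gives_zeros(self):
        aln = pd.DataFrame(columns=ptseq.ALIGNMENT_COLUMNS)
        st = genome_stats(aln, "g", 1000)
        assert (st.coverage, st.median_depth, st.dispersion) == (0.0, 0.0, 0.0)

    def test_uniform_tiling(self):
        rows = [
            (f"r{i}_{j}", "g", i * 10, "+", 1, 1.0, 10)
            for i in range(10)
            for j in range(3)
        ]
        aln = pd.DataFrame(rows, columns=ptseq.ALIGNMENT_COLUMNS)
        st = genome_stats(aln, "g", 100)
        assert st.coverage == 1.0
        assert st.median_depth == 3.0

    def test_depth_profile_matches_bruteforce_counter(self, small_community, small_alignments):
        g = small_community.genomes[0]
        fast = depth_profile(small_alignments, g.genome_id, g.length)
        slow = np.zeros(g.length)
        sub = small_alignments[small_alignments["genome"] == g.genome_id]
        for pos, strand, w, rl in zip(sub["pos0"], sub["strand"], sub["weight"], sub["read_len"]):
            if strand == "+":
                slow[pos:pos + rl] += w
            else:
                slow[pos - rl + 1:pos + 1] += w
        assert np.allclose(fast, slow)


class TestGMM:
    def test_recovers_planted_clouds(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (30, 3)), rng.normal(5, 0.3, (30, 3))])
        feats = pd.DataFrame(X)
        labels, _ = gmm_cluster(feats, k=2, seed=1)
        truth = np.array([0] * 30 + [1] * 30)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_same_seed_same_labels(self):
        rng = np.random.default_rng(3)
        feats = pd.DataFrame(rng.normal(size=(25, 3)))
        a, _ = gmm_cluster(feats, k=3, seed=7)
        b, _ = gmm_cluster(feats, k=3, seed=7)
        assert np.array_equal(a, b)

    def test_fewer_genomes_than_components_rejected(self):
        with pytest.raises(ValueError):
            gmm_cluster(pd.DataFrame(np.zeros((2, 3))), k=3, seed=0)

    def test_em_log_likelihood_non_decreasing(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(4, 1, (40, 3))])
        gm = GaussianMixture(
            n_components=2, covariance_type="diag", max_iter=1, warm_start=True,
            tol=0.0, reg_covar=1e-6, random_state=0,
        )
        bounds = []
        import warnings

        for _ in range(25):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(X)
            bounds.append(gm.lower_bound_)
        assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(bounds, bounds[1:]))


class TestSelection:
    @staticmethod
    def _stats(disps, covs):
        return [
            GenomeStats(f"g{i}", cov, 1.0, disp, 100.0)
            for i, (disp, cov) in enumerate(zip(disps, covs))
        ]

    def test_low_coverage_genome_excluded_despite_dispersion(self):
        stats = self._stats([0.5, 0.4, 0.6, 120.0], [0.8, 0.7, 0.9, 0.10])
        labels = np.array([0, 0, 0, 1])
        assert select_candidate_genomes(stats, labels) == set()

    def test_dispersed_covered_genomes_selected(self):
        stats = self._stats([0.5, 0.4, 0.6, 120.0, 80.0], [0.8, 0.7, 0.9, 0.5, 0.9])
        labels = np.array([0, 0, 0, 1, 2])
        assert select_candidate_genomes(stats, labels) == {"g3", "g4"}


class TestPileups:
    def test_called_site_positions_and_depths(self):
        genome = "ACGTACGTCAGTACGTACGTACGT"
        rows = [(f"r{i}", "g", 9, "+", 1, 1.0, 8) for i in range(16)]
        rows += [(f"q{i}", "g", 12, "-", 2, 0.5, 8) for i in range(4)]
        aln = pd.DataFrame(rows, columns=ptseq.ALIGNMENT_COLUMNS)
        sites = call_pileups(aln, "g", genome, cutoff=15)
        assert len(sites) == 1
        s = sites[0]
        assert (s.position, s.strand, s.depth) == (8, "+", 16.0)
        assert s.dinucleotide == "CA"
        assert s.window == genome[3:16]

    def test_fractional_depth_below_cutoff_not_called(self):
        rows = [(f"r{i}", "g", 10, "+", 2, 0.5, 8) for i in range(29)]
        aln = pd.DataFrame(rows, columns=ptseq.ALIGNMENT_COLUMNS)
        sites = call_pileups(aln, "g", "A" * 40, cutoff=15)
        assert sites == []  # 14.5 < 15

    def test_bruteforce_oracle_all_cutoffs(self, small_community, small_alignments):
        """Called sites equal an independent per-position counter at every
        cutoff 1..25 on a <= 50 kb community."""
        for g in small_community.genomes:
            counter: dict[tuple[int, str], float] = {}
            sub = small_alignments[small_alignments["genome"] == g.genome_id]
            for pos, strand, w in zip(sub["pos0"], sub["strand"], sub["weight"]):
                counter[(pos, strand)] = counter.get((pos, strand), 0.0) + w
            for cutoff in ptseq.SWEEP_CUTOFFS:
                expected = {
                    (c - 1 if strand == "+" else c + 1, strand)
                    for (c, strand), d in counter.items()
                    if d >= cutoff and 6 <= c <= g.length - 7
                }
                called = {
                    (s.position, s.strand)
                    for s in call_pileups(small_alignments, g.genome_id, g.sequence, cutoff)
                }
                assert called == expected

    def test_depth_conservation(self, small_community, small_alignments):
        total = sum(
            sum(five_prime_depths(small_alignments, g.genome_id).values())
            for g in small_community.genomes
        )
        n_mapped = small_alignments.groupby("read_id")["weight"].sum().sum()
        assert total == pytest.approx(n_mapped)

    def test_pipeline_invariant_to_read_order(self, small_community):
        reads = simulate_ptseq_reads(small_community, n_reads=2000, read_length=80, seed=55)
        shuffled = community.ReadSet(list(reversed(reads.reads)), reads.read_length)
        a = assign_reads(reads, small_community)
        b = assign_reads(shuffled, small_community)
        g = small_community.genomes[0]
        sa = call_pileups(a, g.genome_id, g.sequence, cutoff=3)
        sb = call_pileups(b, g.genome_id, g.sequence, cutoff=3)
        assert [(s.position, s.strand, s.depth) for s in sa] == [
            (s.position, s.strand, s.depth) for s in sb
        ]


class TestCutoffSweep:
    def _sim_alignments(self, seed=0):
        rng = np.random.default_rng(seed)
        genome = community._random_sequence(rng, 20_000, 0.5)
        rows = []
        rid = 0
        # Poisson(1) background 5'-end counts at 2000 random positions
        for pos in rng.integers(10, 19_000, size=2000):
            for _ in range(rng.poisson(1.0)):
                rows.append((f"b{rid}", "g", int(pos), "+", 1, 1.0, 50)); rid += 1
        # deep signal at CA positions
        ca_positions = [i for i in range(10, 19_000) if genome[i:i + 2] == "CA"][:100]
        for p in ca_positions:
            for _ in range(rng.poisson(25) + 20):
                rows.append((f"s{rid}", "g", p + 1, "+", 1, 1.0, 50)); rid += 1
        return pd.DataFrame(rows, columns=ptseq.ALIGNMENT_COLUMNS), genome

    def test_sweep_rows_and_monotonicity(self):
        aln, genome = self._sim_alignments()
        sweep = cutoff_sweep(aln, "g", genome, {"CA"})
        assert len(sweep) == 25
        assert (np.diff(sweep["n_sites"]) <= 0).all()

    def test_specificity_improves_with_cutoff(self):
        aln, genome = self._sim_alignments(seed=3)
        sweep = cutoff_sweep(aln, "g", genome, {"CA"}).set_index("cutoff")
        assert sweep.loc[15, "specificity"] > sweep.loc[1, "specificity"]

    def test_empty_target_set_rejected(self):
        aln = pd.DataFrame(columns=ptseq.ALIGNMENT_COLUMNS)
        with pytest.raises(ValueError):
            cutoff_sweep(aln, "g", "ACGT" * 100, set())


class TestWindows:
    def test_interior_window_centers_linkage_at_columns_5_and_6(self):
        genome = "ACGTACGTCAGTACGTACGT"
        site = ptseq.PileupSite("g", 8, "+", 20.0, "CA", "")
        (w,) = extract_windows([site], genome)
        assert len(w) == 13
        assert w[5:7] == "CA"

    def test_site_too_close_to_edge_skipped(self):
        genome = "ACGTACGTCAGTACGTACGT"
        site = ptseq.PileupSite("g", 3, "+", 20.0, "TA", "")
        assert extract_windows([site], genome) == []

    def test_minus_strand_window_is_reverse_complement_of_forward_slice(self):
        rng = np.random.default_rng(1)
        genome = community._random_sequence(rng, 60, 0.5)
        site = ptseq.PileupSite("g", 30, "-", 20.0, "", "")
        (w,) = extract_windows([site], genome)
        c = 29
        assert w == revcomp(genome[c - 6:c + 7])


class TestAnchoredMotifs:
    @staticmethod
    def _background(seed=0, n=50_000):
        return community._random_sequence(np.random.default_rng(seed), n, 0.5)

    def test_planted_cag_recovered(self):
        genome = self._background(1)
        positions = [i for i in range(10, 40_000) if genome[i:i + 3] == "CAG"][:200]
        windows = [genome[p - 5:p + 8] for p in positions]
        motifs = find_anchored_motifs(windows, genome)
        assert motifs[0].consensus == "C*AG"
        assert motifs[0].fold_enrichment > 10

    def test_uniform_windows_yield_no_motif(self):
        for seed in (11, 12, 13):
            rng = np.random.default_rng(seed)
            windows = [community._random_sequence(rng, 13, 0.5) for _ in range(300)]
            assert find_anchored_motifs(windows, self._background(2)) == []

    def test_bistranded_system_yields_both_orientations(self, study_pipeline):
        com = study_pipeline["community"]
        bistranded = next(
            g for g in com.genomes
            if g.systems and g.systems[0].strandedness == "bistranded"
        )
        sites = study_pipeline["called"][bistranded.genome_id]
        motifs = find_anchored_motifs([s.window for s in sites], bistranded.sequence)
        assert {m.consensus for m in motifs[:2]} == {"G*AAC", "G*TTC"}

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            find_anchored_motifs(["ACGTACGTACGTA"] * 5, self._background(3))


class TestEquivalentPT:
    def test_definition_arithmetic(self):
        prof = equivalent_pt_per_million({"g": {"CA": 100}}, {"g": 1_000_000}, {"g": 1.0})
        assert prof.levels["C*A"] == pytest.approx(50.0)

    def test_zero_sites_zero_level(self):
        prof = equivalent_pt_per_million({"g": {}}, {"g": 1000}, {"g": 1.0})
        assert prof.levels == {}

    def test_splitting_a_genome_leaves_levels_unchanged(self):
        one = equivalent_pt_per_million({"g": {"CA": 100}}, {"g": 1_000_000}, {"g": 1.0})
        two = equivalent_pt_per_million(
            {"g1": {"CA": 50}, "g2": {"CA": 50}},
            {"g1": 500_000, "g2": 500_000},
            {"g1": 0.5, "g2": 0.5},
        )
        assert two.levels["C*A"] == pytest.approx(one.levels["C*A"])

    def test_matches_expected_profile_exactly(self, study_community):
        com = study_community
        eq = equivalent_pt_per_million(
            com.site_counts(),
            {g.genome_id: g.length for g in com.genomes},
            dict(zip(com.genome_ids, com.abundances)),
        )
        expected = community.expected_lcms_profile(com)
        assert set(eq.levels) == set(expected.levels)
        for d in eq.levels:
            assert eq.levels[d] == pytest.approx(expected.levels[d], rel=1e-12)


class TestCrossValidation:
    LOD = {"G*A": 1.0, "G*C": 5.0, "C*A": 1.0}

    def test_identical_profiles_agree_without_flags(self):
        prof = PTProfile({"C*A": 10.0, "G*A": 5.0})
        report = crossvalidate_lcms(prof, prof, self.LOD)
        assert (report["ratio"] == 1.0).all()
        assert not report["below_lod"].any()

    def test_seq_only_signal_below_lod_is_flagged_not_discordant(self):
        report = crossvalidate_lcms(
            PTProfile({"G*C": 0.8, "G*A": 6.0}),
            PTProfile({"G*A": 6.0}),
            self.LOD,
        ).set_index("dinucleotide")
        assert bool(report.loc["G*C", "below_lod"])
        assert not bool(report.loc["G*A", "below_lod"])

    def test_disjoint_profiles_warn_but_return(self):
        report = crossvalidate_lcms(PTProfile({"C*A": 1.0}), PTProfile({"G*A": 1.0}), self.LOD)
        assert len(report) == 2


def test_occupancy_one_zero_background_calls_exactly_the_planted_sites():
    systems = (PTSystem("CAG", occupancy=1.0), PTSystem("GAAC", strandedness="bistranded", occupancy=1.0))
    com = build_community(
        n_genomes=2, genome_length=8000, pt_genome_fraction=1.0,
        systems=systems, seed=61, read_length=60,
    )
    reads = simulate_ptseq_reads(
        com, n_reads=60_000, read_length=60, background_nick_rate=0.0, seed=62
    )
    aln = assign_reads(reads, com)
    for g in com.genomes:
        called = {
            (s.position, s.strand)
            for s in call_pileups(aln, g.genome_id, g.sequence, cutoff=5)
        }
        planted = {(s.position, s.strand) for s in com.planted[g.genome_id]}
        assert called == planted
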