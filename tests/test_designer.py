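import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sairna.designer import (
    CategoryError,
    DesignConstraints,
    DesignError,
    GuideArm,
    NN_DG37,
    annealed_insert,
    asymmetry_score,
    build_guide,
    build_hairpin,
    build_sairna,
    build_shrna_5arm,
    build_shrna_classic,
    make_cloning_oligos,
    nn_stack_dg,
    rank_candidates,
    scan_target_sites,
)
from sairna.seqcore import NucSeq, SeqRecord, is_wc_pair

from .conftest import PROBE_WINDOW, make_site, random_rna, site_for


class TestScanTargetSites:
    def test_count_without_filters(self):
        rec = SeqRecord("m", NucSeq(random_rna(25, seed=3), "RNA"))
        c = DesignConstraints(stem_len=17, loop_len=4, gc_min=0, gc_max=1, max_homopolymer=25)
        sites = scan_target_sites(rec, c)
        assert [s.start for s in sites] == [1, 2, 3, 4, 5]

    def test_gc_filter_excludes_all_g(self):
        rec = SeqRecord("m", NucSeq("G" * 30, "RNA"))
        c = DesignConstraints(stem_len=17, loop_len=4, gc_min=0, gc_max=0.7, max_homopolymer=30)
        assert scan_target_sites(rec, c) == []

    def test_matches_brute_force_enumeration(self):
        seq = random_rna(200, seed=11)
        rec = SeqRecord("m", NucSeq(seq, "RNA"))
        c = DesignConstraints(stem_len=17, loop_len=4, gc_min=0, gc_max=1, max_homopolymer=200)
        got = [(s.start, s.window.residues) for s in scan_target_sites(rec, c)]
        want = [(i + 1, seq[i : i + 21]) for i in range(len(seq) - 21 + 1)]
        assert got == want

    def test_short_mrna_yields_empty(self):
        rec = SeqRecord("m", NucSeq("ACGU", "RNA"))
        assert scan_target_sites(rec, DesignConstraints()) == []

    def test_u_run_in_guide_filtered(self):
        # four consecutive A in the window complement to four U in the guide
        seq = "GC" + "AAAA" + random_rna(40, seed=5)
        rec = SeqRecord("m", NucSeq(seq, "RNA"))
        strict = DesignConstraints(stem_len=17, loop_len=4, gc_min=0, gc_max=1, max_homopolymer=3)
        lax = DesignConstraints(stem_len=17, loop_len=4, gc_min=0, gc_max=1, max_homopolymer=50)
        assert len(scan_target_sites(rec, strict)) < len(scan_target_sites(rec, lax))


class TestBuildGuide:
    def test_probe_window_guide(self, probe_site):
        g = build_guide(probe_site)
        assert g.seq.residues == "AGGCAAGCUGACCCUGAAGUU"

    def test_window_ending_in_u_pairs_the_forced_a(self):
        g = build_guide(make_site(PROBE_WINDOW[:-1] + "U"))
        assert g.seq[0] == "A" and not g.pos1_forced

    def test_window_ending_in_g_flags_mismatch(self, probe_site):
        g = build_guide(probe_site)  # probe window ends in G
        assert g.seq[0] == "A" and g.pos1_forced


class TestBuildSairna:
    def test_probe_hairpin_frozen(self, sairna_design):
        d = sairna_design
        assert d.arm5.residues == "AGGCAAGCUGACCCUGA"
        assert d.loop.residues == "AGUU"
        assert d.arm3.residues == "UCAGGGUCAGCUUGCCC"  # terminal U -> C mismatch
        assert len(d.core) == 38
        assert d.guide_arm is GuideArm.FIVE

    def test_stem18_total_length(self):
        d = build_sairna(site_for(18, 4), stem_len=18, loop_len=4)
        assert len(d.core) == 2 * 18 + 4

    def test_mismatch_base_a(self, probe_site):
        d = build_sairna(probe_site, 17, 4, mismatch_base="A")
        assert d.arm3[-1] == "A"
        for i in range(2, d.stem_len + 1):
            assert is_wc_pair(d.arm5[i - 1], d.arm3[d.stem_len - i], "RNA")

    @pytest.mark.parametrize("stem", [15, 19, 21])
    def test_stem_outside_range_redirects(self, stem):
        with pytest.raises(CategoryError):
            build_sairna(site_for(stem, 4), stem_len=stem)

    def test_guide_complementary_to_window(self, sairna_design):
        """Re-deriving the window from the guide recovers it except opposite
        guide position 1."""
        d = sairna_design
        window = d.site.window.residues
        rederived = d.guide.revcomp().residues  # complement of guide 1..21
        # guide position 1 sits opposite the window's LAST nucleotide
        assert rederived[:-1] == window[:-1]


class TestBuildShrnaClassic:
    def test_probe_guide_is_pure_antisense(self, probe_site):
        d = build_shrna_classic(probe_site)
        assert d.arm3.residues == "CGGCAAGCUGACCCUGAAGUU"
        assert d.guide_arm is GuideArm.THREE

    def test_core_length(self, probe_site):
        d = build_shrna_classic(probe_site)
        assert len(d.core) == 2 * 21 + 6


class TestBuildShrna5Arm:
    def test_stem24_core_length(self):
        d = build_shrna_5arm(site_for(24, 4), stem_len=24, loop_len=4)
        assert len(d.core) == 2 * 24 + 4

    def test_terminal_mismatch_base(self):
        d = build_shrna_5arm(site_for(22, 4), stem_len=22, loop_len=4)
        assert d.arm3[-1] == "C"

    def test_short_stem_rejected(self):
        with pytest.raises(CategoryError):
            build_shrna_5arm(site_for(18, 4), stem_len=18)


class TestAsymmetryScore:
    def test_symmetric_ends_score_zero(self):
        from sairna.designer import HairpinDesign

        arm5 = NucSeq("GCGCAAAAAAAAAGCGC", "RNA")
        d = HairpinDesign(
            arm5=arm5,
            loop=NucSeq("AAAA", "RNA"),
            arm3=arm5.revcomp(),
            guide_arm=GuideArm.FIVE,
            mismatches=frozenset(),
            stem_len=17,
            loop_len=4,
        )
        assert asymmetry_score(d) == pytest.approx(0.0)

    def test_au_rich_guide_end_negative(self):
        # guide (5' arm) starts AU-rich, passenger 5' end GC-rich
        window = "GGGCCCAUAUAUAUAUAUAUU"
        d = build_hairpin(make_site(window), 17, 4)
        assert asymmetry_score(d) < 0

    def test_matches_independent_resummation(self, sairna_design):
        d = sairna_design
        S = d.stem_len

        def dg_window(strand, positions):
            tot = 0.0
            for k in range(3):
                if positions[k] in d.mismatches or positions[k + 1] in d.mismatches:
                    continue
                di = strand[k : k + 2]
                tot += NN_DG37.get(di, NN_DG37.get(NucSeq(di, "RNA").revcomp().residues, 0.0))
            return tot

        dg_guide = dg_window(d.arm5.residues[:4], [1, 2, 3, 4])
        dg_pass = dg_window(d.arm3.residues[:4], [S, S - 1, S - 2, S - 3])
        expected = (-dg_guide) - (-dg_pass)
        assert asymmetry_score(d) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True)
    def test_antisymmetric_under_strand_swap(self, seed):
        d = build_hairpin(site_for(17, 4, seed=seed), 17, 4)
        # role swap on the same duplex: flip which arm carries the guide
        import dataclasses

        flipped = dataclasses.replace(d, guide_arm=GuideArm.THREE)
        assert asymmetry_score(flipped) == pytest.approx(-asymmetry_score(d))

    def test_short_stem_errors(self):
        d = build_hairpin(site_for(14, 4), 14, 4)
        with pytest.raises(DesignError):
            asymmetry_score(d, n_bp=15)


class TestStemPairingInvariant:
    @pytest.mark.parametrize("stem,loop", [(16, 4), (17, 4), (18, 7), (22, 4), (24, 7)])
    def test_all_undeclared_positions_pair(self, stem, loop):
        d = build_hairpin(site_for(stem, loop, seed=stem * loop), stem, loop)
        for i in range(1, stem + 1):
            paired = is_wc_pair(d.arm5[i - 1], d.arm3[stem - i], "RNA")
            assert paired == (i not in d.mismatches)


class TestRankCandidates:
    def test_single_design_is_itself(self, sairna_design):
        out = rank_candidates([sairna_design])
        assert out[0].design is sairna_design

    def test_permutation_invariant(self):
        designs = [build_hairpin(site_for(17, 4, seed=s), 17, 4) for s in range(6)]
        a = [r.design.site.window.residues for r in rank_candidates(designs)]
        b = [r.design.site.window.residues for r in rank_candidates(designs[::-1])]
        assert a == b

    def test_more_negative_asymmetry_ranks_first(self):
        designs = [build_hairpin(site_for(17, 4, seed=s), 17, 4) for s in range(8)]
        ranked = rank_candidates(designs, weights={"gc": 0, "homopolymer": 0, "offtarget": 0})
        scores = [asymmetry_score(r.design) for r in ranked]
        assert scores == sorted(scores)


class TestCloningOligos:
    def test_h1_vector_overhangs(self, sairna_design):
        pair = make_cloning_oligos(sairna_design, "H1_pSilencer")
        assert pair.top.residues.startswith("GATCC")
        assert pair.bottom.residues.startswith("AGCTT")
        assert pair.enzymes == ("BamHI", "HindIII")

    def test_internal_site_collision(self):
        # engineer a window whose hairpin DNA contains GGATCC
        site = make_site("AACUUCAGGGAUCCGCUUGCC" )
        d = build_shrna_classic(site)
        assert "GGATCC" in d.core.to_dna().residues
        with pytest.raises(DesignError, match="BamHI"):
            make_cloning_oligos(d, "H1_pSilencer")

    @pytest.mark.parametrize("vector", ["H1_pSilencer", "lenti_shRNA", "lenti_saiRNA_RZ"])
    def test_annealed_reconstruction(self, sairna_design, vector):
        pair = make_cloning_oligos(sairna_design, vector)
        insert = annealed_insert(pair)
        assert insert.residues == sairna_design.core.to_dna().residues + "T" * 6

    def test_terminator_length_configurable(self, sairna_design):
        pair = make_cloning_oligos(sairna_design, terminator_len=7)
        assert pair.insert.residues.endswith("T" * 7)


def test_nn_table_symmetric_lookup():
    # a stack read from either strand has one ΔG
    for d1, d2 in [("AG", "CU"), ("UG", "CA"), ("AC", "GU"), ("UC", "GA")]:
        assert nn_stack_dg(d1) == nn_stack_dg(d2)
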