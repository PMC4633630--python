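import numpy as np
import pandas as pd
import pytest

from sairna.processing import SimOptions, simulate
from sairna.profiler import (
    AnnotationSet,
    EndNoiseModel,
    MiRNAEntry,
    ProfilerError,
    ReadSet,
    classify,
    count_mirna,
    end_heterogeneity,
    normalize_mirna,
    preprocess,
    synth_reads,
)
from sairna.seqcore import read_fastq

from .conftest import random_rna

ADAPTOR = "UGGAAUUCUCGGGUGCCAAGG"


def reads_with_adaptor(*inserts):
    return [i + ADAPTOR for i in inserts]


class TestPreprocess:
    def test_21nt_insert_retained(self):
        rs = preprocess(reads_with_adaptor(random_rna(21, 1)), ADAPTOR)
        assert rs.total_useful == 1
        assert set(map(len, rs.reads)) == {21}

    def test_18nt_insert_removed(self):
        rs = preprocess(reads_with_adaptor(random_rna(18, 2)), ADAPTOR)
        assert rs.total_useful == 0

    def test_unclippable_read_removed(self):
        rs = preprocess([random_rna(40, 3)], ADAPTOR)
        assert rs.total_raw == 1 and rs.total_useful == 0

    def test_collapsing_multiplicities(self):
        ins = random_rna(22, 4)
        rs = preprocess(reads_with_adaptor(ins, ins, ins), ADAPTOR)
        assert rs.reads == {ins: 3} and rs.total_useful == 3

    def test_short_adaptor_rejected(self):
        with pytest.raises(ProfilerError):
            preprocess([], "ACGUA")


def mirna_fixture():
    # precursor with the mature sequence at positions 10..31 (22 nt)
    mature = random_rna(22, 10)
    pre = random_rna(9, 11) + mature + random_rna(15, 12)
    return MiRNAEntry("mir-syn-1", pre, 10, mature), mature, pre


class TestClassify:
    def test_sequential_precedence_mirna_before_rrna(self):
        entry, mature, pre = mirna_fixture()
        ann = AnnotationSet(mirnas=[entry], rrnas=[random_rna(50, 13) + mature])
        rs = ReadSet({mature: 4}, 4, 4)
        counts = classify(rs, ann)
        assert counts.counts["miRNA"] == 4 and counts.counts["rRNA"] == 0

    def test_construct_class_first(self, sairna_design):
        entry, mature, pre = mirna_fixture()
        ann = AnnotationSet(mirnas=[entry])
        guide = sairna_design.core.residues[:21]
        rs = ReadSet({guide: 5}, 5, 5)
        counts = classify(rs, ann, construct=sairna_design)
        assert counts.counts["construct"] == 5

    def test_counts_conserve_useful_total(self):
        entry, mature, _ = mirna_fixture()
        ann = AnnotationSet(mirnas=[entry], trnas=[random_rna(70, 14)])
        reads = {mature: 3, random_rna(24, 15): 2, ann.trnas[0][5:28]: 1}
        rs = ReadSet(reads, 6, 6)
        counts = classify(rs, ann)
        assert counts.total == rs.total_useful

    def test_matches_brute_force_substring_search(self):
        refs = [random_rna(100, s) for s in range(20, 24)]
        ann = AnnotationSet(trnas=[refs[0]], rrnas=[refs[1]], snornas=[refs[2]], other=[refs[3]])
        reads = {}
        for s in range(30):
            src = refs[s % 4]
            start = (7 * s) % 70
            reads[src[start : start + 25]] = reads.get(src[start : start + 25], 0) + 1
        rs = ReadSet(reads, sum(reads.values()), sum(reads.values()))
        counts = classify(rs, ann)
        order = ["tRNA", "rRNA", "snoRNA", "other"]
        brute = dict.fromkeys(order + ["unmapped"], 0)
        for seq, mult in reads.items():
            for cls, ref in zip(order, refs):
                if seq in ref:
                    brute[cls] += mult
                    break
            else:
                brute["unmapped"] += mult
        for cls in order:
            assert counts.counts[cls] == brute[cls]


class TestCountMirna:
    def test_exact_mature_counted(self):
        entry, mature, _ = mirna_fixture()
        counts = count_mirna(ReadSet({mature: 7}, 7, 7), AnnotationSet(mirnas=[entry]))
        assert counts["mir-syn-1"] == 7

    def test_templated_3prime_addition_counted(self):
        entry, mature, pre = mirna_fixture()
        plus1 = pre[9 : 9 + 23]  # mature + 1 templated nt
        counts = count_mirna(ReadSet({plus1: 2}, 2, 2), AnnotationSet(mirnas=[entry]))
        assert counts["mir-syn-1"] == 2

    def test_3prime_deletion_within_2nt_counted(self):
        entry, mature, _ = mirna_fixture()
        counts = count_mirna(
            ReadSet({mature[:-2]: 1}, 1, 1), AnnotationSet(mirnas=[entry])
        )
        assert counts["mir-syn-1"] == 1

    def test_3prime_variation_beyond_2nt_not_counted(self):
        entry, mature, _ = mirna_fixture()
        counts = count_mirna(
            ReadSet({mature[:-3]: 1}, 1, 1), AnnotationSet(mirnas=[entry])
        )
        assert counts["mir-syn-1"] == 0

    def test_shifted_5prime_not_counted(self):
        entry, mature, pre = mirna_fixture()
        shifted = pre[10 : 10 + 22]  # 5' end +1
        counts = count_mirna(ReadSet({shifted: 3}, 3, 3), AnnotationSet(mirnas=[entry]))
        assert counts["mir-syn-1"] == 0

    def test_untemplated_addition_not_counted(self):
        entry, mature, pre = mirna_fixture()
        nxt = pre[9 + 22]
        bad = "A" if nxt != "A" else "C"
        counts = count_mirna(
            ReadSet({mature + bad: 1}, 1, 1), AnnotationSet(mirnas=[entry])
        )
        assert counts["mir-syn-1"] == 0


class TestNormalizeMirna:
    def test_30_70_split(self):
        out = normalize_mirna(pd.Series({"a": 30, "b": 70}))
        assert out["a"] == pytest.approx(300_000)
        assert out["b"] == pytest.approx(700_000)

    def test_single_mirna_gets_the_million(self):
        assert normalize_mirna(pd.Series({"a": 12}))["a"] == pytest.approx(1_000_000)

    def test_sum_is_exactly_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.Series(rng.integers(1, 500, size=40))
        assert normalize_mirna(counts).sum() == pytest.approx(1_000_000)

    def test_scale_invariance(self):
        counts = pd.Series({"a": 3, "b": 11, "c": 5})
        assert normalize_mirna(counts).equals(normalize_mirna(counts * 17))

    def test_zero_total_errors(self):
        with pytest.raises(ProfilerError):
            normalize_mirna(pd.Series({"a": 0}))


class TestEndHeterogeneity:
    def test_identical_reads_fully_homogeneous(self, sairna_design):
        guide = sairna_design.core.residues[:21]
        rs = ReadSet({guide: 10}, 10, 10)
        iso = end_heterogeneity(rs, sairna_design)
        assert iso.homogeneity5["guide"] == 1.0

    def test_even_split_between_two_starts(self, sairna_design):
        core = sairna_design.core.residues
        rs = ReadSet({core[:21]: 5, core[1:22]: 5}, 10, 10)
        iso = end_heterogeneity(rs, sairna_design)
        assert iso.homogeneity5["guide"] == 0.5

    def test_fixed_5prime_variable_3prime(self, sairna_design):
        out = simulate(sairna_design, SimOptions(ribozyme="WT"))
        reads = synth_reads(out, depth=2000, rng_seed=1)
        rs = preprocess(reads, ADAPTOR)
        iso = end_heterogeneity(rs, sairna_design)
        assert iso.homogeneity5["guide"] == 1.0
        assert len(iso.per_strand["guide"]) >= 2  # distinct 3' isoforms

    def test_fractions_sum_to_one_per_strand(self, sairna_design):
        core = sairna_design.core.residues
        rs = ReadSet({core[:21]: 3, core[2:24]: 4, core[-21:]: 6}, 13, 13)
        iso = end_heterogeneity(rs, sairna_design)
        for strand, df in iso.per_strand.items():
            assert df["fraction"].sum() == pytest.approx(1.0)


class TestSynthReads:
    def test_seed_reproducibility(self, sairna_design, tmp_path):
        out = simulate(sairna_design, SimOptions(ribozyme="WT"))
        a = synth_reads(out, depth=500, rng_seed=7)
        b = synth_reads(out, depth=500, rng_seed=7)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]

    def test_zero_depth_empty(self, sairna_design):
        out = simulate(sairna_design, SimOptions(ribozyme="WT"))
        assert synth_reads(out, depth=0, rng_seed=1) == []

    def test_fastq_roundtrip(self, sairna_design, tmp_path):
        out = simulate(sairna_design, SimOptions(ribozyme="WT"))
        p = tmp_path / "lib.fq"
        written = synth_reads(out, depth=100, rng_seed=3, out_path=p)
        assert read_fastq(p) == written

    def test_zero_jitter_one_isoform_per_species(self, sairna_design):
        out = simulate(sairna_design, SimOptions(ribozyme="WT"))
        reads = synth_reads(out, depth=1000, rng_seed=2)
        uniq = {r.seq for r in reads}
        assert len(uniq) <= len(out.species)

    def test_species_proportions_recovered_within_3_sigma(self, sairna_design):
        """Round trip: simulate -> sample library -> clip/collapse -> the
        per-species read fractions match the simulated weights within
        binomial 3-sigma at depth 1e5."""
        out = simulate(sairna_design, SimOptions(ribozyme="WT"))
        depth = 100_000
        reads = synth_reads(out, depth=depth, rng_seed=11)
        rs = preprocess(reads, ADAPTOR)
        # species are distinguishable by their exact sequence here
        expected = {}
        for s in out.species:
            expected[s.seq.residues] = expected.get(s.seq.residues, 0.0) + s.weight
        for seq, p in expected.items():
            if len(seq) < 19:
                continue
            got = rs.reads.get(seq, 0) / depth
            sigma = (p * (1 - p) / depth) ** 0.5
            assert abs(got - p) <= 3 * sigma + 1e-12
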