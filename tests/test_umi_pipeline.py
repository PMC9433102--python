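"""Demultiplexing, UMI consensus, annotation, filtering and collapse."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from hypothesis import given
from hypothesis import strategies as st

from repseq.synthetic_data import (GenerativeConfig, simulate_cohort,
                                   simulate_reads, simulate_repertoire)
from repseq.umi_pipeline import (AnnotatedRecord, ClonotypeTable,
                                 ConsensusRecord, PipelineError, SampleId,
                                 TCRSequence, UMIGroup, annotate,
                                 build_consensus, collapse, demultiplex,
                                 filter_functional, group_by_umi,
                                 preprocess)

S1 = SampleId("D01", 1, "CD4_naive", "alpha")
S2 = SampleId("D02", 1, "CD4_naive", "alpha")


def read(seq, qual=35):
    rec = SeqRecord(Seq(seq), id="r")
    rec.letter_annotations["phred_quality"] = [qual] * len(seq)
    return rec


def group(sequences, umi="A" * 12, umi_quals=None, sample=S1):
    n = len(sequences)
    return UMIGroup(umi=umi, sample=sample, sequences=list(sequences),
                    qualities=[[35] * len(s) for s in sequences],
                    umi_qualities=list(umi_quals or [35.0] * n))


class TestDemultiplex:
    def test_single_barcode_preserves_stream(self):
        reads = [read("AAAA" + "C" * 30) for _ in range(10)]
        result = demultiplex(reads, {"AAAA": S1})
        assert len(result.by_sample[S1]) == 10
        assert result.n_undetermined == 0

    def test_unknown_barcode_routed_to_undetermined(self):
        result = demultiplex([read("TTTT" + "C" * 30)], {"AAAA": S1})
        assert result.n_undetermined == 1
        assert result.by_sample[S1] == []

    def test_exact_split_against_generator_truth(self):
        cfg = GenerativeConfig(n_donors=2, residual_sd=0, seed=5,
                               true_richness_by_subset={"CD4_naive": 30})
        _, truths = simulate_cohort(cfg)
        streams, samples = [], []
        for truth, bc in zip(truths, ("AAAACCCC", "GGGGTTTT")):
            table = simulate_repertoire(truth, "CD4_naive", "alpha", 50,
                                        seed=1)
            reads, _ = simulate_reads(table, 2, 0.0, bc, seed=2)
            streams.append(reads)
            samples.append(table.sample)
        pooled = streams[0] + streams[1]
        result = demultiplex(pooled, {"AAAACCCC": samples[0],
                                      "GGGGTTTT": samples[1]})
        assert len(result.by_sample[samples[0]]) == len(streams[0])
        assert len(result.by_sample[samples[1]]) == len(streams[1])

    def test_duplicate_sample_assignment_rejected(self):
        with pytest.raises(PipelineError):
            demultiplex([], {"AAAA": S1, "CCCC": S1})


class TestConsensus:
    def test_two_reads_insufficient(self):
        assert build_consensus(group(["ACGT"] * 2)) == []

    def test_three_identical_reads_yield_their_sequence(self):
        records = build_consensus(group(["ACGTACGT"] * 3))
        assert len(records) == 1
        assert records[0].sequence == "ACGTACGT"
        assert records[0].n_reads == 3

    def test_conflicting_sequences_split(self):
        """3+3 reads of two divergent sequences under one UMI give two
        consensus records, matching an exhaustive grouping oracle."""
        x, y = "ACGTACGTAC", "TGCATGCATG"
        records = build_consensus(group([x, y, x, y, x, y]))
        assert sorted(r.sequence for r in records) == sorted([x, y])
        # oracle: exhaustive pairwise clustering at <=1 mismatch
        seqs = [x, y, x, y, x, y]
        clusters = {}
        for s in seqs:
            placed = False
            for rep in clusters:
                if sum(a != b for a, b in zip(rep, s)) <= 1:
                    clusters[rep] += 1
                    placed = True
                    break
            if not placed:
                clusters[s] = 1
        expected = {rep for rep, n in clusters.items() if n >= 3}
        assert {r.sequence for r in records} == expected

    def test_sequencing_error_corrected_by_majority(self):
        good = "ACGTACGTAC"
        bad = "ACGTACGTAA"  # one substitution
        records = build_consensus(group([good, good, bad]))
        assert len(records) == 1
        assert records[0].sequence == good

    def test_low_umi_quality_reads_excluded(self):
        g = group(["ACGT"] * 3, umi_quals=[35.0, 35.0, 5.0])
        assert build_consensus(g, min_quality=10) == []


class TestAnnotate:
    def test_round_trip(self, reference):
        v = reference.v_segments[0]
        j = [s for s in reference.j_segments if s.chain == v.chain][0]
        cdr3 = "TGTGCAAGTCTT"
        rec = ConsensusRecord(S1, "A" * 12, v.tag + cdr3 + j.tag, 3)
        out = annotate(rec, reference)
        assert out is not None
        assert (out.tcr.v_gene, out.tcr.j_gene) == (v.name, j.name)
        assert out.tcr.cdr3_nt == cdr3
        assert out.tcr.cdr3_aa == str(Seq(cdr3).translate())

    def test_corrupted_tag_unannotated(self, reference):
        v = reference.v_segments[0]
        j = [s for s in reference.j_segments if s.chain == v.chain][0]
        bad_tag = "".join("A" if c != "A" else "C" for c in v.tag)
        rec = ConsensusRecord(S1, "A" * 12,
                              bad_tag + "TGTGCAAGTCTT" + j.tag, 3)
        assert annotate(rec, reference) is None

    def test_bulk_round_trip_accuracy(self, reference):
        """Error-free synthetic consensus records annotate back to their
        source clonotypes without loss."""
        cfg = GenerativeConfig(n_donors=1, seed=8,
                               true_richness_by_subset={"CD8_memory": 500})
        _, truths = simulate_cohort(cfg)
        table = simulate_repertoire(truths[0], "CD8_memory", "beta", 1000,
                                    seed=3)
        n_checked = 0
        for row in table.df.itertuples():
            seq = (reference.v(row.v_call).tag + row.junction
                   + reference.j(row.j_call).tag)
            out = annotate(ConsensusRecord(S1, "A" * 12, seq, 3),
                           reference)
            assert out is not None
            assert out.tcr.key("nt") == (row.chain, row.v_call,
                                         row.j_call, row.junction_aa,
                                         row.junction)
            n_checked += 1
        assert n_checked == table.n_clonotypes


def ann(cdr3_nt, n_reads=3, umi="A" * 12, sample=S1, v="TRAV1",
        j="TRAJ1"):
    tcr = TCRSequence("alpha", v, j, str(Seq(cdr3_nt).translate()),
                      cdr3_nt)
    return AnnotatedRecord(sample, umi, tcr, n_reads)


class TestFunctionalFilter:
    def test_stop_codon_removed(self):
        records = [ann("TGTTAACTT")]  # middle codon TAA = stop
        assert filter_functional(records) == []

    def test_functional_with_enough_reads_retained(self):
        records = [ann("TGTGCACTT", n_reads=3)]
        assert filter_functional(records) == records

    def test_mixed_set_exhaustive(self):
        stop = [ann("TGTTAACTT"), ann("TAGGCACTT")]
        weak = [ann("TGTGCAGCA", n_reads=2)]
        good = [ann("TGTGCA" + c) for c in
                ("CTT", "GAA", "CAA", "TAT", "TTT", "GGT", "CAT")]
        kept = filter_functional(stop + weak + good)
        assert kept == good


class TestCollapse:
    def test_same_clonotype_umis_accumulate(self):
        records = [ann("TGTGCACTT", umi=f"{'A' * 11}{b}")
                   for b in "ACGTA"[:5]]
        # 5 records, 4 distinct UMIs (A*12 appears twice)
        table = collapse(records)
        assert table.n_clonotypes == 1
        assert table.total_umi == 4

    def test_distinct_clonotypes_kept_apart(self):
        cdr3s = ["TGTGCACTT", "TGTGCAGAA", "TGTGCACAA", "TGTGCATAT",
                 "TGTGCATTT"]
        records = [ann(c, umi=f"{i:012d}".replace("0", "A").replace(
            "1", "C")) for i, c in enumerate(cdr3s)]
        table = collapse(records)
        assert table.n_clonotypes == 5
        assert set(table.df["duplicate_count"]) == {1}

    @given(st.lists(st.integers(min_value=0, max_value=9), min_size=1,
                    max_size=100))
    def test_counts_match_brute_force_tally(self, assignment):
        """Random UMI→clonotype assignment: collapse counts equal a
        dictionary tally."""
        cdr3s = ["TGTGCACTT", "TGTGCAGAA", "TGTGCACAA", "TGTGCATAT",
                 "TGTGCATTT", "TGTGCAGGT", "TGTGCACAT", "TGTGCAATT",
                 "TGTGCAAAA", "TGTGCATGT"]
        records = []
        for i, clone in enumerate(assignment):
            umi = np.base_repr(i, 4).zfill(12).translate(
                str.maketrans("0123", "ACGT"))
            records.append(ann(cdr3s[clone], umi=umi))
        table = collapse(records)
        tally = Counter(cdr3s[c] for c in assignment)
        observed = dict(zip(table.df["junction"],
                            table.df["duplicate_count"]))
        assert observed == dict(tally)
        assert table.total_umi == len(assignment)

    def test_mixed_samples_rejected(self):
        with pytest.raises(PipelineError):
            collapse([ann("TGTGCACTT"), ann("TGTGCAGAA", sample=S2)])


class TestEndToEnd:
    def test_error_free_pipeline_recovers_truth_exactly(self, reference):
        cfg = GenerativeConfig(n_donors=1, seed=13, error_rate=0.0,
                               true_richness_by_subset={"CD4_naive": 100})
        _, truths = simulate_cohort(cfg)
        table = simulate_repertoire(truths[0], "CD4_naive", "alpha", 200,
                                    seed=4)
        reads, _ = simulate_reads(table, 3, 0.0, "AAAACCCC", seed=5)
        result = preprocess(reads, {"AAAACCCC": table.sample}, reference,
                            pcr_times={table.sample: 1})
        out = result["tables"][table.sample]
        key_cols = ["v_call", "j_call", "junction_aa", "junction"]
        expected = (table.df.sort_values(key_cols, kind="mergesort")
                    .reset_index(drop=True))
        assert out.df[expected.columns.tolist()].equals(expected)

    def test_umi_count_conservation(self, reference):
        cfg = GenerativeConfig(n_donors=1, seed=14, error_rate=0.0,
                               true_richness_by_subset={"CD4_naive": 60})
        _, truths = simulate_cohort(cfg)
        table = simulate_repertoire(truths[0], "CD4_naive", "alpha", 120,
                                    seed=6)
        reads, sidecar = simulate_reads(table, 4, 0.0, "AAAACCCC", seed=7)
        result = preprocess(reads, {"AAAACCCC": table.sample}, reference,
                            pcr_times={table.sample: 1})
        assert result["tables"][table.sample].total_umi == len(sidecar)
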