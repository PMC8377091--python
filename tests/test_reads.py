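"""Read processing: demultiplexing, trimming, merging, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsaseq.experiments import (
    oracle_demux,
    oracle_edit_distance_prefix,
    oracle_quality_trim,
)
from bsaseq.pipeline import PipelineConfig, process_read_pairs
from bsaseq.reads import (
    SequenceRead,
    align_to_converted_reference,
    demultiplex_by_primer,
    merge_pairs,
    quality_trim,
    read_fastq,
    write_fastq,
)
from bsaseq.reference import ConvertedReference, ReferenceLocus, converted_strands
from bsaseq.simulate import simulate_reads


def mk(bases, q=30, rid="r"):
    quals = np.full(len(bases), q) if np.isscalar(q) else np.asarray(q)
    return SequenceRead(rid, bases, quals)


class TestDemultiplex:
    PRIMERS = {"L1": "ACGTACGTACGTACGTACGT", "L2": "TTTTGGGGCCCCAAAATTTT"}

    def test_exact_primer_assigned_and_trimmed(self):
        insert = "AAAACCCCGGGG"
        res = demultiplex_by_primer(mk(self.PRIMERS["L1"] + insert), self.PRIMERS, 0.2)
        assert res.locus == "L1"
        assert res.trimmed.bases == insert
        assert res.edit_distance == 0

    @pytest.mark.parametrize("n_subs,expected", [(4, "L1"), (5, None)])
    def test_error_rate_boundary(self, n_subs, expected):
        # 20-base primer at rate 0.2 admits exactly floor(0.2*20)=4 edits
        primer = list(self.PRIMERS["L1"])
        for i in range(n_subs):
            primer[2 * i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[primer[2 * i]]
        res = demultiplex_by_primer(mk("".join(primer) + "AAAA"), self.PRIMERS, 0.2)
        assert res.locus == expected

    def test_tie_is_ambiguous(self):
        primers = {"L1": "AAAA", "L2": "TTTT"}
        res = demultiplex_by_primer(mk("AATTGGGG"), primers, 0.5)
        assert res.locus is None and res.ambiguous

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_matches_edit_distance_oracle(self, data):
        rng_bases = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=45))
        got = demultiplex_by_primer(mk(rng_bases), self.PRIMERS, 0.2)
        assert got.locus == oracle_demux(rng_bases, self.PRIMERS, 0.2)

    def test_oracle_edit_distance_sanity(self):
        assert oracle_edit_distance_prefix("ACGT", "ACGTAAAA") == 0
        assert oracle_edit_distance_prefix("ACGT", "AGGTAAAA") == 1
        assert oracle_edit_distance_prefix("ACGT", "AGT") == 1  # deletion


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        read = mk("ACGTACGT", 40)
        assert quality_trim(read).bases == "ACGTACGT"

    def test_leading_trailing_removed(self):
        q = [10, 10, 10, 40, 40, 40, 40, 40, 10, 10]
        read = mk("AAACGTACGT", q)
        got = quality_trim(read, end_q=20, window=5, window_mean_q=30)
        assert got.bases == "CGTAC"

    def test_window_cut_at_first_failing_window(self):
        q = [40] * 6 + [10] * 6
        read = mk("ACGTACGTACGT", q)
        got = quality_trim(read, end_q=5, window=5, window_mean_q=30)
        # first window with mean < 30 starts at index 2: (40,40,40,40,10)=34,
        # (40,40,40,10,10)=28 -> cut at 2... verify against the oracle
        lo, hi = oracle_quality_trim(q, 5, 5, 30)
        assert got.bases == "ACGTACGTACGT"[lo:hi]

    @given(
        quals=st.lists(st.integers(min_value=0, max_value=45), min_size=0, max_size=60)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_window_oracle(self, quals):
        bases = "A" * len(quals)
        got = quality_trim(mk(bases, quals), 20, 5, 30)
        lo, hi = oracle_quality_trim(quals, 20, 5, 30)
        assert got.bases == bases[lo:hi]
        assert (got.qualities == np.asarray(quals[lo:hi])).all()

    @given(
        quals=st.lists(st.integers(min_value=0, max_value=45), min_size=1, max_size=60)
    )
    @settings(max_examples=200, deadline=None)
    def test_no_low_quality_leading_base_and_windows_pass(self, quals):
        got = quality_trim(mk("A" * len(quals), quals), 20, 5, 30)
        q = got.qualities
        if len(q):
            assert q[0] >= 20
        # every complete window fully inside the retained read passes
        for s in range(len(q) - 5 + 1):
            assert q[s : s + 5].mean() >= 30


class TestMergePairs:
    def frag_pair(self, rng, frag_len=300, read_len=250, q=38):
        frag = "".join(rng.choice(list("ACGT"), size=frag_len))
        r1 = mk(frag[:read_len], q)
        r2 = mk(frag[-read_len:], q).reverse_complement()
        return frag, r1, r2

    def test_overlapping_pair_reconstructs_fragment(self):
        rng = np.random.default_rng(0)
        frag, r1, r2 = self.frag_pair(rng)
        merged = merge_pairs(r1, r2)
        assert merged is not None
        assert merged.bases == frag
        assert len(merged) == 250 + 250 - 200

    def test_non_overlapping_pair_unmerged(self):
        rng = np.random.default_rng(1)
        frag = "".join(rng.choice(list("ACGT"), size=600))
        r1 = mk(frag[:250])
        r2 = mk(frag[-250:]).reverse_complement()
        assert merge_pairs(r1, r2) is None

    def test_mismatch_takes_higher_quality_base(self):
        rng = np.random.default_rng(9)
        frag = "".join(rng.choice(list("ACGT"), size=40))
        r1 = mk(frag[:25], 40)
        r2_seq = list(frag[15:])
        pos = 5  # fragment position 20, inside the 10-base overlap
        r2_seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r2_seq[pos]]
        r2 = mk("".join(r2_seq), 10).reverse_complement()
        merged = merge_pairs(r1, r2, min_overlap=5)
        assert merged is not None
        assert merged.bases == frag  # r1 (q=40) wins over r2 (q=10)
        assert merged.qualities[20] == 30  # |40 - 10| at the mismatch

    def test_consensus_quality_max_at_matches(self):
        rng = np.random.default_rng(2)
        frag, r1, r2 = self.frag_pair(rng)
        r2.qualities[:] = 20
        merged = merge_pairs(r1, r2)
        assert (merged.qualities[50:250] == 38).all()  # overlap: max(38, 20)


def _toy_locus():
    # CCGGA|TTCGA...: CpG at 1 and a second at 7
    seq = "ACGGATTCGATTAGGATTAGGATTAGGA"
    return ReferenceLocus("TOY", seq, len(seq))


class TestAlignment:
    def test_exact_converted_substring_recovers_offset(self):
        locus = _toy_locus()
        refs = converted_strands(locus)
        read = mk(refs[0].sequence[4:24])
        aln = align_to_converted_reference(read, refs, locus)
        assert aln is not None
        assert (aln.strand, aln.ref_start) == ("OT", 4)
        assert aln.cpg_calls == {7: "T"}

    def test_methylated_c_scores_identically(self):
        locus = _toy_locus()
        refs = converted_strands(locus)
        unmeth = refs[0].sequence[4:24]
        meth = unmeth[:3] + "C" + unmeth[4:]  # C at CpG position 7
        a1 = align_to_converted_reference(mk(unmeth), refs, locus)
        a2 = align_to_converted_reference(mk(meth), refs, locus)
        assert a1.score == a2.score
        assert a1.ref_start == a2.ref_start
        assert a2.cpg_calls == {7: "C"}

    def test_c_at_converted_position_is_mismatch(self):
        # asymmetry: read C over an ordinary converted (now T) position
        locus = _toy_locus()
        refs = converted_strands(locus)
        base = refs[0].sequence[4:24]
        off_cpg = base[:5] + "C" + base[6:]  # position 9: not a CpG column
        a_ref = align_to_converted_reference(mk(base), refs, locus)
        a_mut = align_to_converted_reference(mk(off_cpg), refs, locus)
        assert a_mut.score == a_ref.score - 2  # one match became a mismatch

    def test_empty_read_unaligned(self):
        locus = _toy_locus()
        assert align_to_converted_reference(mk(""), converted_strands(locus), locus) is None

    def test_indel_read_aligns_via_gapped_fallback(self):
        locus = _toy_locus()
        refs = converted_strands(locus)
        seq = refs[0].sequence
        read = mk(seq[2:12] + seq[13:26])  # 1-base deletion
        aln = align_to_converted_reference(read, refs, locus, min_score_fraction=0.7)
        assert aln is not None
        assert aln.ref_start == 2
        # bases after the deletion still map to their true columns
        assert aln.read_to_ref[-1] == 25

    def test_simulated_error_free_reads_realign_to_truth(self, small_config, small_cohort):
        from dataclasses import replace

        cfg = replace(
            small_config, conversion_failure_rate=0.0, seq_error_rate=0.0
        )
        inds, truth = small_cohort
        locus = cfg.loci[2]
        refs = converted_strands(locus)
        pairs = simulate_reads(inds[0], locus, truth, cfg, n_reads=100)
        pcfg = PipelineConfig(seed=0)
        alignments, counts = process_read_pairs(pairs, [locus], cfg.primers, pcfg)
        # every merged read must land at the forward-primer boundary
        assert counts.aligned == counts.merged == 100
        for aln in alignments[locus.name]:
            assert aln.ref_start == len(cfg.primers[locus.name].forward)


class TestFastqIO:
    def test_roundtrip_plain_and_gzip(self, tmp_path):
        reads = [mk("ACGT", [2, 40, 30, 33], rid="a"), mk("GG", [10, 11], rid="b")]
        for name in ("x.fastq", "x.fastq.gz"):
            path = tmp_path / name
            assert write_fastq(reads, path) == 2
            back = list(read_fastq(path))
            assert [r.bases for r in back] == ["ACGT", "GG"]
            assert all((a.qualities == b.qualities).all() for a, b in zip(reads, back))
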