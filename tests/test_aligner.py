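"""Best-hit aligner: seed index integrity, mismatch-count competition,
paired rescue, brute-force oracle equivalence, SAM bridge."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numtaudit import (Fragment, Genome, ReadConfig,
                       ReferenceSet, align_fragments, align_paired,
                       align_read, apply_snv, brute_force_align, build_index,
                       fragment_single_end, read_sam, revcomp, write_sam)
from numtaudit.synthetic_refs import NumtSpec, plant_numt


class TestSeedIndex:
    def test_forward_positions_count_l_minus_k_plus_one(self):
        seq = "ACGTACGTACGTAC"  # 14 bp -> 4 windows at k=11
        rs = ReferenceSet(Genome("m", seq))
        idx = build_index(rs, k=11)
        fwd = [(p, h) for kmer, hits in idx._map.items()
               for h in hits if h[2] == 0 for p in [h[1]]]
        assert len(fwd) == len(seq) - 11 + 1
        for i in range(len(seq) - 10):
            assert (0, i, 0) in idx.lookup(seq[i:i + 11].encode())

    def test_absent_kmer_empty(self, small_mito):
        idx = build_index(ReferenceSet(small_mito), k=19)
        assert idx.lookup(b"N" * 19) == []

    def test_every_entry_round_trips_to_its_kmer(self, small_mito):
        idx = build_index(ReferenceSet(small_mito), k=19)
        seq = small_mito.sequence
        for kmer, hits in idx._map.items():
            for ci, p0, strand in hits:
                window = seq[p0:p0 + 19]
                expected = window if strand == 0 else revcomp(window)
                assert expected.encode() == kmer

    def test_k_too_small_rejected(self, small_mito):
        with pytest.raises(ValueError, match="k=7"):
            build_index(ReferenceSet(small_mito), k=7)


class TestAlignRead:
    def test_exact_mito_read_maps_to_origin(self, small_mito):
        rs = ReferenceSet(small_mito)
        idx = build_index(rs)
        rec = align_read(small_mito.sequence[199:299], idx)
        assert (rec.contig, rec.pos, rec.strand) == ("chrM", 200, "+")
        assert rec.mismatches == 0 and not rec.ambiguous

    def test_revcomp_read_maps_minus_strand_same_locus(self, small_mito):
        idx = build_index(ReferenceSet(small_mito))
        rec = align_read(revcomp(small_mito.sequence[199:299]), idx)
        assert (rec.contig, rec.pos, rec.strand) == ("chrM", 200, "-")

    def test_alt_allele_read_captured_by_numt(self, omf):
        """A read one mismatch from chrM and identical to the nuMT gets the
        nuclear contig as its primary alignment."""
        refset, snv = omf
        idx = build_index(refset)
        mutated = apply_snv(refset.mito, snv)
        read = mutated.sequence[snv.pos - 50:snv.pos + 50]
        rec = align_read(read, idx)
        assert rec.contig == "chr1" and rec.mismatches == 0
        ref_read = refset.mito.sequence[snv.pos - 50:snv.pos + 50]
        assert align_read(ref_read, idx).contig == "chrM"

    def test_tie_is_ambiguous_with_deterministic_winner(self, small_mito):
        """An exact-copy nuMT puts in-segment reads one mismatch from
        nothing: equal scores at both loci, mito wins by contig order."""
        spec = NumtSpec(300, 300, (), "chr1", 100)
        rs = plant_numt(ReferenceSet(small_mito), spec, 800, seed=9)
        idx = build_index(rs)
        read = small_mito.sequence[349:449]  # fully inside the copy
        rec = align_read(read, idx)
        assert rec.ambiguous and rec.contig == "chrM"
        oracle = brute_force_align(read, rs)
        assert oracle == rec
        # reversed priority flips the winner
        rs_flip = ReferenceSet(small_mito, rs.nuclear, rs.planted,
                               mito_priority=False)
        assert align_read(read, build_index(rs_flip)).contig == "chr1"

    def test_unrelated_read_unmapped(self, small_mito):
        idx = build_index(ReferenceSet(small_mito))
        probe = "AT" * 50  # dinucleotide repeat absent from the screened genome
        rec = align_read(probe, idx)
        assert not rec.mapped and rec.contig is None
        assert brute_force_align(probe, ReferenceSet(small_mito)) == rec

    def test_read_shorter_than_seed_rejected(self, small_mito):
        idx = build_index(ReferenceSet(small_mito))
        with pytest.raises(ValueError, match="shorter than seed"):
            align_read("ACGT", idx)


class TestOracleEquivalence:
    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_align_read_equals_brute_force(self, omf, data):
        """Seed-and-extend and the exhaustive Hamming scan return identical
        records (locus, strand, mismatch count, ambiguity flag) for reads
        drawn from the fixture with up to 3 substitutions either strand."""
        refset, _ = omf
        idx = build_index(refset)
        L = len(refset.mito)
        start = data.draw(st.integers(1, L - 99))
        read = list(refset.mito.sequence[start - 1:start + 99])
        for _ in range(data.draw(st.integers(0, 3))):
            i = data.draw(st.integers(0, 99))
            read[i] = data.draw(st.sampled_from("ACGT"))
        read = "".join(read)
        if data.draw(st.booleans()):
            read = revcomp(read)
        assert align_read(read, idx) == brute_force_align(read, refset)

    def test_equivalence_on_every_fixture_read(self, omf_2kb):
        refset, snv = omf_2kb
        idx = build_index(refset)
        frags = fragment_single_end(refset.mito, ReadConfig(100, "single"))
        mut = fragment_single_end(apply_snv(refset.mito, snv),
                                  ReadConfig(100, "single"))
        for f in list(frags)[::7] + list(mut)[snv.pos - 100:snv.pos:5]:
            assert align_read(f.seq1, idx, read_id=f.read_id) == \
                brute_force_align(f.seq1, refset, read_id=f.read_id)


class TestSelfConsistency:
    def test_all_fragments_map_to_origin_without_numts(self, plain_refset):
        idx = build_index(plain_refset)
        frags = fragment_single_end(plain_refset.mito,
                                    ReadConfig(100, "single"))
        records = align_fragments(frags, idx)
        assert all(r.mapped for r in records)
        for f, r in zip(frags, records):
            assert (r.contig, r.pos, r.strand, r.mismatches) == \
                ("chrM", f.origin_start, "+", 0)
            assert not r.ambiguous


class TestAlignPaired:
    def _pair(self, genome, start, tlen, m=100):
        template = genome.sequence[start - 1:start - 1 + tlen]
        return Fragment(f"p|{start}", template[:m], revcomp(template[-m:]),
                        genome.name, start, tlen)

    def test_pairing_rescues_mate_from_short_numt(self, small_mito):
        """Mate1 sits inside an exact-copy nuMT (tie on its own) but the
        proper pairing on chrM keeps both mates there, unambiguously."""
        spec = NumtSpec(300, 150, (), "chr1", 100)
        rs = plant_numt(ReferenceSet(small_mito), spec, 800, seed=9)
        idx = build_index(rs)
        frag = self._pair(small_mito, 320, 200)  # mate1 in copy, mate2 out
        r1, r2 = align_paired(frag, idx, insert_range=(200, 200))
        assert r1.contig == r2.contig == "chrM"
        assert r1.proper_pair and r2.proper_pair
        assert (r1.pos, r2.pos) == (320, 420)
        # alone, mate1 is ambiguous between chrM and the copy
        assert align_read(frag.seq1, idx).ambiguous

    def test_pair_inside_numt_goes_to_numt(self, small_mito):
        """Both mates strictly better on the nuclear copy follow it."""
        mm_base = "A" if small_mito.base(309) != "A" else "C"
        spec = NumtSpec(300, 220, ((10, mm_base),), "chr1", 100)
        rs = plant_numt(ReferenceSet(small_mito), spec, 800, seed=9)
        # build the pair from the nuclear copy itself
        host = rs.get("chr1")
        template = host.sequence[99:99 + 200]
        frag = Fragment("n|1", template[:100], revcomp(template[-100:]),
                        "chr1", 100, 200)
        r1, r2 = align_paired(frag, build_index(rs),
                              insert_range=(200, 200))
        assert r1.contig == r2.contig == "chr1"
        assert r1.mismatches == r2.mismatches == 0

    def test_mates_without_proper_pairing_reported_unpaired(self, small_mito):
        """A chimeric template (mates from loci 600 bp apart) admits no
        proper pairing at insert 200 and falls back to unpaired records."""
        m1 = small_mito.sequence[99:199]
        m2 = revcomp(small_mito.sequence[799:899])
        frag = Fragment("c|1", m1, m2, "chrM", 100, 200)
        idx = build_index(ReferenceSet(small_mito))
        r1, r2 = align_paired(frag, idx, insert_range=(200, 200))
        assert not r1.proper_pair and not r2.proper_pair
        assert r1.pos == 100 and r2.pos == 800

    def test_single_end_input_rejected(self, small_mito):
        frag = Fragment("s|1", small_mito.sequence[:100], None, "chrM", 1, 100)
        with pytest.raises(ValueError, match="paired fragment"):
            align_paired(frag, build_index(ReferenceSet(small_mito)))


class TestSamBridge:
    def test_write_read_round_trip(self, omf_2kb, tmp_path):
        refset, _ = omf_2kb
        idx = build_index(refset)
        frags = fragment_single_end(refset.mito, ReadConfig(100, "single"))
        records = align_fragments(frags, idx)[:1000]
        path = tmp_path / "out.sam"
        write_sam(records, refset, path, frags.reads_by_id())
        assert read_sam(path, refset) == records

    def test_secondary_records_dropped_and_nm_recomputed(self, small_mito,
                                                         tmp_path):
        path = tmp_path / "ext.sam"
        seq = small_mito.sequence[:50]
        path.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:chrM\tLN:{len(small_mito)}\n"
            f"r1\t0\tchrM\t1\t60\t50M\t*\t0\t0\t{seq}\t{'I' * 50}\n"
            f"r1\t256\tchrM\t501\t0\t50M\t*\t0\t0\t{seq}\t{'I' * 50}\n"
            f"r2\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{'I' * 50}\n"
        )
        with pytest.warns(UserWarning, match="missing NM"):
            records = read_sam(path, ReferenceSet(small_mito))
        assert len(records) == 2  # secondary dropped
        assert records[0].mapped and records[0].mismatches == 0
        assert not records[1].mapped

    def test_unknown_contig_rejected(self, small_mito, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrX\tLN:5000\n"
            f"r1\t0\tchrX\t1\t60\t20M\t*\t0\t0\t{'A' * 20}\t{'I' * 20}\n"
        )
        with pytest.raises(ValueError, match="not in reference set"):
            read_sam(path, ReferenceSet(small_mito))
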