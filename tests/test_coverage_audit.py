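"""Depth profiles, the coverage-loss statistic, sweep locality, binning,
and the shifted-genome breakpoint scan."""

import pytest

from numtaudit import (AlignmentRecord, ReadConfig, SNV,
                       align_fragments, bin_losses, breakpoint_scan,
                       build_index, coverage_loss, depth_profile,
                       fragment_single_end, full_realignment_loss,
                       variant_sweep)
from numtaudit.coverage_audit import LossRecord, SweepContext


def _rec(read_id, pos, m=100, contig="chrM"):
    return AlignmentRecord(read_id, contig, pos, "+", 0, True,
                           read_length=m)


class TestDepthProfile:
    def test_flat_interior_at_read_length_without_numts(self, plain_refset):
        idx = build_index(plain_refset)
        frags = fragment_single_end(plain_refset.mito,
                                    ReadConfig(100, "single"))
        records = align_fragments(frags, idx)
        prof = depth_profile(records, 100, "chrM", len(plain_refset.mito))
        assert (prof.depth[99:-99] == 100).all()
        assert prof.depth.max() == 100

    def test_zero_records_all_zero(self):
        prof = depth_profile([], 100, "chrM", 500)
        assert (prof.depth == 0).all()

    def test_single_read_spans_its_window(self):
        prof = depth_profile([_rec("r", 1)], 100, "chrM", 500)
        assert (prof.depth[:100] == 1).all() and (prof.depth[100:] == 0).all()

    def test_record_past_contig_end_rejected(self):
        with pytest.raises(ValueError, match="outside contig"):
            depth_profile([_rec("r", 450)], 100, "chrM", 500)


class TestCoverageLoss:
    @pytest.mark.parametrize("ref,mut,expected", [
        (100, 0, 100.0), (100, 100, 0.0), (100, 33, 67.0),
        (100, 110, -10.0),  # gains are not clamped
    ])
    def test_arithmetic(self, ref, mut, expected):
        assert coverage_loss(ref, mut) == pytest.approx(expected)

    def test_zero_reference_depth_rejected(self):
        with pytest.raises(ValueError, match="zero reference depth"):
            coverage_loss(0, 0)


class TestVariantSweep:
    def test_focal_snv_loses_all_coverage(self, omf, se100):
        refset, snv = omf
        (rec,) = variant_sweep(refset, se100, [snv])
        assert rec.ref_depth == 100 and rec.mut_depth == 0
        assert rec.loss_pct == 100.0

    def test_no_numts_means_no_loss_anywhere_sampled(self, plain_refset,
                                                     se100):
        mito = plain_refset.mito
        snvs = [SNV("chrM", pos, mito.base(pos),
                    "A" if mito.base(pos) != "A" else "C")
                for pos in range(500, 560, 7)]
        records = variant_sweep(plain_refset, se100, snvs)
        assert all(r.loss_pct == 0.0 for r in records)

    def test_locality_matches_full_realignment_oracle(self, omf_2kb, se100):
        """The per-variant loss computed by re-aligning only overlapping
        fragments equals a from-scratch realignment of the whole mutated
        genome, at the focal SNV and at unconfounded neighbors."""
        refset, focal = omf_2kb
        mito = refset.mito
        probes = [focal]
        for pos in (focal.pos - 60, focal.pos + 30, 200, 1500):
            probes.append(SNV("chrM", pos, mito.base(pos),
                              "A" if mito.base(pos) != "A" else "G"))
        ctx = SweepContext(refset, se100)
        for snv in probes:
            fast = ctx.loss_for(snv)
            oracle = full_realignment_loss(refset, se100, snv)
            assert (fast.ref_depth, fast.mut_depth) == \
                (oracle.ref_depth, oracle.mut_depth), snv.notation

    def test_off_contig_snv_rejected(self, plain_refset, se100):
        with pytest.raises(ValueError, match="not the mitochondrial"):
            variant_sweep(plain_refset, se100,
                          [SNV("chr9", 10, "A", "C")])

    def test_read_conservation(self, omf, se100):
        """mapped + unmapped = simulated; depth mass = mapped x length."""
        refset, _ = omf
        ctx = SweepContext(refset, se100)
        n_mapped = sum(r.mapped for r in ctx.records)
        assert n_mapped + sum(not r.mapped for r in ctx.records) == \
            len(ctx.records)
        total = 0
        for g in [refset.mito] + refset.nuclear:
            total += depth_profile(ctx.records, 100, g.name,
                                   len(g)).depth.sum()
        assert total == n_mapped * 100


class TestBinLosses:
    def _records(self, losses, layout="single"):
        out = []
        for i, loss in enumerate(losses):
            snv = SNV("chrM", 100 + i, "A", "C")
            out.append(LossRecord(snv, 100, layout, 100,
                                  round(100 - loss)))
        return out

    def test_strict_threshold_counts(self):
        bins = bin_losses(self._records([0, 5, 15, 60]),
                          thresholds=(0, 10, 50))
        assert {th: n for th, (n, _) in bins.items()} == {0: 3, 10: 2, 50: 1}

    def test_empty_input_all_zero(self):
        assert all(v == (0, 0) for v in bin_losses([]).values())

    def test_distinct_positions_bounded_by_count(self):
        recs = self._records([20, 30, 40])
        # two records at the same position
        recs.append(LossRecord(SNV("chrM", 100, "A", "G"), 100, "single",
                               100, 70))
        bins = bin_losses(recs, thresholds=(10,))
        n, p = bins[10]
        assert n == 4 and p == 3 and p <= n

    def test_paired_end_floor_excludes_jitter(self):
        bins = bin_losses(self._records([2, 5], layout="paired"),
                          thresholds=(0,))
        assert bins[0] == (1, 1)  # the 2% loss sits below the >3% floor


class TestBreakpointScan:
    def test_no_numts_no_breakpoint_losses(self, plain_refset, se100):
        records = breakpoint_scan(plain_refset.mito, se100, window=25)
        assert len(records) == 2 * 25 * 3
        assert all(r.loss_pct == 0.0 for r in records)
        L = len(plain_refset.mito)
        positions = {r.snv.pos for r in records}
        assert positions == set(range(1, 26)) | set(range(L - 24, L + 1))

    def test_window_zero_empty(self, plain_refset, se100):
        assert breakpoint_scan(plain_refset.mito, se100, window=0) == []

    def test_invariant_to_shift_offset(self, plain_refset, se100):
        L = len(plain_refset.mito)
        a = breakpoint_scan(plain_refset.mito, se100, window=10,
                            shift_offset=L // 4)
        b = breakpoint_scan(plain_refset.mito, se100, window=10,
                            shift_offset=L // 2)
        assert [(r.snv, r.ref_depth, r.mut_depth) for r in a] == \
            [(r.snv, r.ref_depth, r.mut_depth) for r in b]

    def test_linear_genome_rejected(self, se100):
        from numtaudit import Genome
        with pytest.raises(ValueError, match="circular"):
            breakpoint_scan(Genome("m", "ACGT" * 200), se100)
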