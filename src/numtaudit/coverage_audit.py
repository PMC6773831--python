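"""Per-position depth, the coverage-loss statistic, and the variant sweep.

The central quantity of the audit is the percent loss of coverage at a
mutated mitochondrial position::

    loss_pct = 100 * (1 - mut_depth / ref_depth)

where ``ref_depth`` is the depth at the position when fragments of the
unaltered reference are aligned, and ``mut_depth`` the depth at the same
position when fragments of the mutated genome are aligned.  A loss of 100%
means every fragment carrying the alternative allele was captured by a
nuclear locus; the statistic is not clamped, so a negative loss records a
coverage gain.

The exhaustive sweep introduces all 3L possible SNVs one at a time.  Its
cost is kept desk-scale by a locality argument: a single substitution only
changes the fragments whose window overlaps the mutated position (at most
``read_length`` of them at step 1, or the templates overlapping it for
pairs), so per variant only those fragments are re-aligned and the cached
reference alignment supplies everything else.  A full-realignment oracle
verifies this optimization on small fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aligner import (DEFAULT_K, DEFAULT_MAX_MISMATCH, AlignmentRecord,
                      SeedIndex, align_fragments, build_index)
from .fragmenter import Fragment, FragmentSet, ReadConfig, fragment, shift_genome
from .mutagenesis import SNV, apply_snv, enumerate_snvs
from .synthetic_refs import BASES, Genome, ReferenceSet


@dataclass
class CoverageProfile:
    """Per-position read depth on one contig (1-based position ``p`` is
    ``depth[p - 1]``)."""

    contig: str
    depth: np.ndarray

    def at(self, pos: int) -> int:
        return int(self.depth[pos - 1])


@dataclass(frozen=True)
class LossRecord:
    """Coverage-loss result for one variant under one read configuration."""

    snv: SNV
    read_length: int
    layout: str
    ref_depth: int
    mut_depth: int

    @property
    def loss_pct(self) -> float:
        return coverage_loss(self.ref_depth, self.mut_depth)


def depth_profile(records: list[AlignmentRecord], read_length: int,
                  contig: str, contig_length: int) -> CoverageProfile:
    """Depth from mapped primary records: each adds 1 over
    ``[pos, pos + read_length - 1]`` on its contig.

    A record extending past the contig end signals a coordinate bug and is
    an error.  Ambiguous records count at their tie-break winner.
    """
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for rec in records:
        if not rec.mapped or rec.contig != contig:
            continue
        m = rec.read_length or read_length
        if rec.pos < 1 or rec.pos + m - 1 > contig_length:
            raise ValueError(
                f"record {rec.read_id} spans [{rec.pos}, {rec.pos + m - 1}] "
                f"outside contig {contig} of length {contig_length}"
            )
        diff[rec.pos - 1] += 1
        diff[rec.pos - 1 + m] -= 1
    return CoverageProfile(contig, np.cumsum(diff[:-1]))


def coverage_loss(ref_depth: int, mut_depth: int) -> float:
    """Percent coverage loss, ``100 * (1 - mut_depth / ref_depth)``.

    Not clamped: negative when coverage increased.  ``ref_depth`` must be
    positive — a position with zero reference depth cannot be audited.
    """
    if ref_depth <= 0:
        raise ValueError("cannot audit a position with zero reference depth")
    return 100.0 * (1.0 - mut_depth / ref_depth)


# ---------------------------------------------------------------------------
# Sweep machinery
# ---------------------------------------------------------------------------

def _overlapping_indices(frags: FragmentSet, pos: int,
                         max_tlen: int | None = None,
                         starts: list[int] | None = None) -> list[int]:
    """Indices of fragments whose template overlaps ``pos``.

    Fragments are ordered by origin start; with the longest possible
    template known, only starts in ``[pos - max_tlen + 1, pos]`` need
    scanning (located by bisection), keeping the sweep's per-variant work
    proportional to the read length rather than the genome length.
    """
    from bisect import bisect_left

    if max_tlen is None:
        max_tlen = (frags.config.insert_range[1]
                    if frags.config.layout == "paired"
                    else frags.config.read_length)
    if starts is None:
        starts = [f.origin_start for f in frags.fragments]
    lo = bisect_left(starts, pos - max_tlen + 1)
    out = []
    for i in range(lo, len(starts)):
        f = frags.fragments[i]
        if f.origin_start > pos:
            break
        if f.origin_start + f.template_length - 1 >= pos:
            out.append(i)
    return out


def _mutate_fragment(f: Fragment, snv: SNV) -> Fragment:
    """Rewrite a fragment's read bases where the template covers the SNV."""
    from dataclasses import replace
    from .synthetic_refs import revcomp

    m = len(f.seq1)
    off = snv.pos - f.origin_start  # 0-based offset within template
    seq1, seq2 = f.seq1, f.seq2
    if 0 <= off < m:
        assert seq1[off] == snv.ref, "fragment/SNV bookkeeping mismatch"
        seq1 = seq1[:off] + snv.alt + seq1[off + 1:]
    if seq2 is not None:
        start2 = f.template_length - m  # mate2 template offset
        if start2 <= off < f.template_length:
            fwd = revcomp(seq2)
            j = off - start2
            assert fwd[j] == snv.ref, "fragment/SNV bookkeeping mismatch"
            seq2 = revcomp(fwd[:j] + snv.alt + fwd[j + 1:])
    return replace(f, seq1=seq1, seq2=seq2)


class SweepContext:
    """Cached reference alignment for a (ReferenceSet, ReadConfig) pair."""

    def __init__(self, refset: ReferenceSet, cfg: ReadConfig,
                 k: int = DEFAULT_K,
                 max_mismatch: int = DEFAULT_MAX_MISMATCH):
        self.refset = refset
        self.cfg = cfg
        self.max_mismatch = max_mismatch
        self.index = build_index(refset, k)
        self.frags = fragment(refset.mito, cfg)
        self.memo: dict = {}
        self.records = align_fragments(self.frags, self.index, max_mismatch,
                                       memo=self.memo)
        self.profile = depth_profile(self.records, cfg.read_length,
                                     refset.mito.name, len(refset.mito))
        # records per fragment: SE -> 1, PE -> 2
        self._per_frag = 2 if cfg.layout == "paired" else 1
        self._starts = [f.origin_start for f in self.frags.fragments]

    def _frag_records(self, i: int) -> list[AlignmentRecord]:
        j = i * self._per_frag
        return self.records[j:j + self._per_frag]

    def loss_for(self, snv: SNV) -> LossRecord:
        """LossRecord for one SNV, re-aligning only overlapping fragments."""
        mito = self.refset.mito
        if snv.contig != mito.name:
            raise ValueError(f"SNV contig {snv.contig!r} is not the "
                             f"mitochondrial contig {mito.name!r}")
        if not 1 <= snv.pos <= len(mito):
            raise ValueError(f"SNV position {snv.pos} outside contig")
        if mito.base(snv.pos) != snv.ref:
            raise ValueError(
                f"ref allele mismatch at {snv.pos}: sweep genome has "
                f"{mito.base(snv.pos)}, SNV says {snv.ref}"
            )
        idx = _overlapping_indices(self.frags, snv.pos, starts=self._starts)
        ref_contrib = sum(
            rec.covers(mito.name, snv.pos)
            for i in idx for rec in self._frag_records(i)
        )
        mutated = FragmentSet(
            self.cfg,
            [_mutate_fragment(self.frags.fragments[i], snv) for i in idx],
            self.frags.source,
        )
        mut_records = align_fragments(mutated, self.index,
                                      self.max_mismatch, memo=self.memo)
        mut_contrib = sum(rec.covers(mito.name, snv.pos)
                          for rec in mut_records)
        ref_depth = self.profile.at(snv.pos)
        mut_depth = ref_depth - ref_contrib + mut_contrib
        return LossRecord(snv, self.cfg.read_length, self.cfg.layout,
                          ref_depth, mut_depth)


def variant_sweep(refset: ReferenceSet, cfg: ReadConfig,
                  snvs: list[SNV] | None = None, *, k: int = DEFAULT_K,
                  max_mismatch: int = DEFAULT_MAX_MISMATCH,
                  context: SweepContext | None = None,
                  progress: bool = False) -> list[LossRecord]:
    """Coverage loss for each SNV (all 3L when ``snvs`` is None).

    Results are independent of sweep order; per variant only the fragments
    overlapping the mutated position are re-aligned against the cached
    reference alignment.
    """
    if context is None:
        context = SweepContext(refset, cfg, k, max_mismatch)
    if snvs is None:
        snvs = enumerate_snvs(refset.mito)
    it = snvs
    if progress:
        from tqdm import tqdm
        it = tqdm(snvs, desc="variant sweep", unit="snv")
    return [context.loss_for(snv) for snv in it]


def full_realignment_loss(refset: ReferenceSet, cfg: ReadConfig, snv: SNV,
                          *, k: int = DEFAULT_K,
                          max_mismatch: int = DEFAULT_MAX_MISMATCH
                          ) -> LossRecord:
    """Oracle: loss computed by regenerating and re-aligning every fragment
    of the mutated genome from scratch (no locality optimization)."""
    mito = refset.mito
    index = build_index(refset, k)
    ref_records = align_fragments(fragment(mito, cfg), index, max_mismatch)
    mut_genome = apply_snv(mito, snv)
    mut_records = align_fragments(fragment(mut_genome, cfg), index,
                                  max_mismatch)
    ref_depth = depth_profile(ref_records, cfg.read_length, mito.name,
                              len(mito)).at(snv.pos)
    mut_depth = depth_profile(mut_records, cfg.read_length, mito.name,
                              len(mito)).at(snv.pos)
    return LossRecord(snv, cfg.read_length, cfg.layout, ref_depth, mut_depth)


# ---------------------------------------------------------------------------
# Binning and the breakpoint scan
# ---------------------------------------------------------------------------

#: Paired-end losses below this floor are attributed to insert-size jitter
#: and excluded before binning.
PAIRED_END_LOSS_FLOOR = 3.0


def bin_losses(records: list[LossRecord],
               thresholds: tuple[float, ...] = (0, 10, 20, 50),
               ) -> dict[float, tuple[int, int]]:
    """Counts of variants (and distinct positions) with loss strictly
    greater than each threshold.

    Paired-end records are first filtered to losses above the >3% floor,
    absorbing the depth jitter a variable insert size introduces.
    """
    out: dict[float, tuple[int, int]] = {}
    for th in thresholds:
        hits = [r for r in records
                if r.loss_pct > th
                and (r.layout != "paired"
                     or r.loss_pct > PAIRED_END_LOSS_FLOOR)]
        out[th] = (len(hits), len({r.snv.pos for r in hits}))
    return out


def breakpoint_scan(genome: Genome, cfg: ReadConfig, window: int = 100,
                    shift_offset: int | None = None, *, k: int = DEFAULT_K,
                    max_mismatch: int = DEFAULT_MAX_MISMATCH
                    ) -> list[LossRecord]:
    """Audit all SNVs within +/-``window`` bp of the linear breakpoint.

    The circular genome is rotated by ``shift_offset`` (default L/2) so the
    breakpoint-adjacent positions sit mid-contig, every such SNV is applied
    to the shifted genome, fragments are aligned against the shifted
    reference alone, and losses are reported in original coordinates.
    """
    if not genome.circular:
        raise ValueError("breakpoint scan requires a circular genome")
    L = len(genome)
    if shift_offset is None:
        shift_offset = L // 2
    shifted = shift_genome(genome, shift_offset)
    refset = ReferenceSet(shifted)
    ctx = SweepContext(refset, cfg, k, max_mismatch)
    out = []
    positions = list(range(L - window + 1, L + 1)) + list(range(1, window + 1))
    for pos in positions:
        pos_sh = ((pos - 1 - shift_offset) % L) + 1
        ref = shifted.base(pos_sh)
        for alt in BASES:
            if alt == ref:
                continue
            rec = ctx.loss_for(SNV(shifted.name, pos_sh, ref, alt))
            out.append(LossRecord(SNV(genome.name, pos, ref, alt),
                                  rec.read_length, rec.layout,
                                  rec.ref_depth, rec.mut_depth))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_loss_tsv(records: list[LossRecord], path,
                   header_lines: list[str] | None = None) -> None:
    """Sweep output TSV: contig, pos, ref, alt, read_length, layout,
    ref_depth, mut_depth, loss_pct."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("contig\tpos\tref\talt\tread_length\tlayout\t"
                 "ref_depth\tmut_depth\tloss_pct\n")
        for r in records:
            fh.write(f"{r.snv.contig}\t{r.snv.pos}\t{r.snv.ref}\t"
                     f"{r.snv.alt}\t{r.read_length}\t{r.layout}\t"
                     f"{r.ref_depth}\t{r.mut_depth}\t{r.loss_pct:.6g}\n")


def write_bedgraph(profile: CoverageProfile, path,
                   header_lines: list[str] | None = None) -> None:
    """Coverage profile as BedGraph (0-based half-open runs)."""
    depth = profile.depth
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(f'track type=bedGraph name="{profile.contig} depth"\n')
        start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[start]:
                fh.write(f"{profile.contig}\t{start}\t{i}\t"
                         f"{int(depth[start])}\n")
                start = i
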