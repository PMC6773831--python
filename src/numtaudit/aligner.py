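"""Embedded deterministic best-hit aligner and SAM bridge.

The decisive mechanism behind nuMT capture of mitochondrial reads is a
mismatch-count competition: a read goes to whichever locus — chrM or a
nuclear copy — it matches with fewer substitutions.  This module isolates
exactly that mechanism with a gapless (Hamming-scored) seed-and-extend
aligner:

* candidate loci are gathered from exact non-overlapping k-mer seeds
  (offsets 0, k, 2k, ...), so a read with ``m`` mismatches retains at
  least ``floor(read_length/k) - m`` intact seeds; with
  ``max_mismatch < floor(read_length/k)`` every viable locus is recovered;
* each candidate is scored by full-length Hamming distance on the
  appropriate strand; the minimum wins, ties are flagged ``ambiguous`` and
  broken deterministically by (contig order, position, ``+`` before ``-``).

Since the simulated reads are substitution-only, gapless scoring is exact
for this study and removes aligner heuristics (soft-clipping, gap
penalties, MAPQ models) as confounders.  A brute-force full-scan oracle
with the identical tie-break rule backs every result, and a SAM bridge
imports/exports primary alignments for comparison with external aligners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .fragmenter import Fragment, FragmentSet
from .synthetic_refs import ReferenceSet, revcomp

DEFAULT_K = 19
DEFAULT_MAX_MISMATCH = 4
#: A proper pair is preferred unless some unpaired placement combination is
#: better by at least this many total mismatches.
DEFAULT_PAIR_BONUS = 2
#: Template-length tolerance around the configured insert range.
DEFAULT_INSERT_TOL = 10


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's primary placement.

    ``ambiguous`` marks reads whose best score is attained at more than one
    locus (the analog of MAPQ 0); the reported locus is then the
    deterministic tie-break winner.  Unmapped records leave the locus
    fields unset.
    """

    read_id: str
    contig: str | None
    pos: int | None  # 1-based leftmost
    strand: str | None  # "+" | "-"
    mismatches: int | None
    mapped: bool
    ambiguous: bool = False
    proper_pair: bool = False
    read_length: int = 0

    def covers(self, contig: str, pos: int) -> bool:
        return (self.mapped and self.contig == contig
                and self.pos <= pos <= self.pos + self.read_length - 1)


def _unmapped(read_id: str, read_length: int) -> AlignmentRecord:
    return AlignmentRecord(read_id, None, None, None, None, False,
                           read_length=read_length)


class SeedIndex:
    """Exact k-mer index over every contig, both strands.

    Maps each k-mer to its occurrence list ``(contig_index, 0-based
    forward-strand leftmost position, strand)`` where ``contig_index``
    follows the reference set's tie-break order.
    """

    def __init__(self, refset: ReferenceSet, k: int = DEFAULT_K):
        if k < 11:
            raise ValueError(f"seed length k={k} too small (minimum 11)")
        self.k = k
        self.refset = refset
        self.order = [g.name for g in refset.contigs]
        self.arrays = {
            g.name: np.frombuffer(g.sequence.encode(), dtype=np.uint8)
            for g in refset.contigs
        }
        self._map: dict[bytes, list[tuple[int, int, int]]] = {}
        for ci, g in enumerate(refset.contigs):
            fwd = g.sequence.encode()
            rc = revcomp(g.sequence).encode()
            n = len(g)
            for i in range(n - k + 1):
                self._map.setdefault(fwd[i:i + k], []).append((ci, i, 0))
            for j in range(n - k + 1):
                self._map.setdefault(rc[j:j + k], []).append((ci, n - k - j, 1))

    def lookup(self, kmer: bytes) -> list[tuple[int, int, int]]:
        return self._map.get(kmer, [])


def build_index(refset: ReferenceSet, k: int = DEFAULT_K) -> SeedIndex:
    """Build the seed index (see :class:`SeedIndex`)."""
    return SeedIndex(refset, k)


# ---------------------------------------------------------------------------
# Candidate generation and scoring
# ---------------------------------------------------------------------------

def _candidates(read_b: bytes, index: SeedIndex) -> set[tuple[int, int, int]]:
    """Candidate placements ``(contig_idx, 0-based pos, strand)`` from
    non-overlapping seeds at offsets 0, k, 2k, ..."""
    m = len(read_b)
    k = index.k
    cands: set[tuple[int, int, int]] = set()
    for o in range(0, (m // k) * k, k):
        for ci, p0, strand in index.lookup(read_b[o:o + k]):
            if strand == 0:
                q0 = p0 - o
            else:
                q0 = p0 - (m - o - k)
            if 0 <= q0 <= len(index.arrays[index.order[ci]]) - m:
                cands.add((ci, q0, strand))
    return cands


def _score_candidates(read: str, index: SeedIndex,
                      cands) -> list[tuple[int, int, int, int]]:
    """Score candidates by Hamming distance; returns sorted
    ``(mismatches, contig_idx, pos0, strand)`` tuples."""
    m = len(read)
    fwd = np.frombuffer(read.encode(), dtype=np.uint8)
    rev = np.frombuffer(revcomp(read).encode(), dtype=np.uint8)
    scored = []
    for ci, q0, strand in cands:
        ref = index.arrays[index.order[ci]][q0:q0 + m]
        query = fwd if strand == 0 else rev
        mm = int(np.count_nonzero(ref != query))
        scored.append((mm, ci, q0, strand))
    scored.sort()
    return scored


def _pick(scored, index: SeedIndex, read_id: str, m: int,
          max_mismatch: int) -> AlignmentRecord:
    viable = [s for s in scored if s[0] <= max_mismatch]
    if not viable:
        return _unmapped(read_id, m)
    mm, ci, q0, strand = viable[0]
    n_best = sum(1 for s in viable if s[0] == mm)
    return AlignmentRecord(read_id, index.order[ci], q0 + 1,
                           "+" if strand == 0 else "-", mm, True,
                           ambiguous=n_best > 1, read_length=m)


def align_read(read: str, index: SeedIndex,
               max_mismatch: int = DEFAULT_MAX_MISMATCH,
               read_id: str = "read") -> AlignmentRecord:
    """Best-hit primary alignment of one read.

    Requires ``len(read) >= k``.  Candidate recovery is guaranteed whenever
    ``max_mismatch < floor(len(read) / k)``.
    """
    if len(read) < index.k:
        raise ValueError(
            f"read length {len(read)} shorter than seed length {index.k}"
        )
    cands = _candidates(read.encode(), index)
    scored = _score_candidates(read, index, cands)
    return _pick(scored, index, read_id, len(read), max_mismatch)


def brute_force_align(read: str, refset: ReferenceSet,
                      max_mismatch: int = DEFAULT_MAX_MISMATCH,
                      read_id: str = "read") -> AlignmentRecord:
    """Exhaustive Hamming scan over every position and strand of every
    contig; identical tie-break rule as :func:`align_read`.  Test oracle."""
    m = len(read)
    fwd = np.frombuffer(read.encode(), dtype=np.uint8)
    rev = np.frombuffer(revcomp(read).encode(), dtype=np.uint8)
    order = [g.name for g in refset.contigs]
    best: tuple[int, int, int, int] | None = None
    n_best = 0
    for ci, g in enumerate(refset.contigs):
        if len(g) < m:
            continue
        windows = sliding_window_view(
            np.frombuffer(g.sequence.encode(), dtype=np.uint8), m)
        for strand, query in ((0, fwd), (1, rev)):
            mm = np.count_nonzero(windows != query, axis=1)
            lo = int(mm.min())
            if lo > max_mismatch:
                continue
            count = int(np.count_nonzero(mm == lo))
            q0 = int(np.argmax(mm == lo))
            cand = (lo, ci, q0, strand)
            if best is None or lo < best[0]:
                best, n_best = cand, count
            elif lo == best[0]:
                n_best += count
                if cand < best:
                    best = cand
    if best is None:
        return _unmapped(read_id, m)
    mm_, ci, q0, strand = best
    return AlignmentRecord(read_id, order[ci], q0 + 1,
                           "+" if strand == 0 else "-", mm_, True,
                           ambiguous=n_best > 1, read_length=m)


# ---------------------------------------------------------------------------
# Paired-end joint placement
# ---------------------------------------------------------------------------

def align_paired(frag: Fragment, index: SeedIndex,
                 max_mismatch: int = DEFAULT_MAX_MISMATCH,
                 insert_range: tuple[int, int] | None = None,
                 pair_bonus: int = DEFAULT_PAIR_BONUS,
                 insert_tol: int = DEFAULT_INSERT_TOL,
                 ) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Jointly place an FR read pair.

    Proper pairings (mates on opposite strands, FR orientation, template
    length within ``insert_range`` +/- ``insert_tol``) are scored by total
    mismatch count; the best proper pairing wins unless some combination of
    independent unpaired placements beats it by at least ``pair_bonus``
    mismatches.  This is what lets a mate anchored on chrM rescue its
    partner from a short nuMT.
    """
    if frag.seq2 is None:
        raise ValueError("align_paired requires a paired fragment")
    if insert_range is None:
        insert_range = (frag.template_length, frag.template_length)
    m = len(frag.seq1)
    id1, id2 = frag.read_id + "/1", frag.read_id + "/2"

    c1 = _score_candidates(frag.seq1, index,
                           _candidates(frag.seq1.encode(), index))
    c2 = _score_candidates(frag.seq2, index,
                           _candidates(frag.seq2.encode(), index))
    c1 = [c for c in c1 if c[0] <= max_mismatch]
    c2 = [c for c in c2 if c[0] <= max_mismatch]

    lo, hi = insert_range
    pairs = []
    for mm1, ci1, q1, s1 in c1:
        for mm2, ci2, q2, s2 in c2:
            if ci1 != ci2 or s1 == s2:
                continue
            if s1 == 0:  # mate1 forward, mate2 reverse, mate1 upstream
                tlen = q2 + m - q1
            else:
                tlen = q1 + m - q2
            if tlen < m or not (lo - insert_tol <= tlen <= hi + insert_tol):
                continue
            pairs.append((mm1 + mm2, ci1, q1, q2, s1, mm1, mm2))
    pairs.sort()

    def single(read_id, scored, mlen):
        return _pick(scored, index, read_id, mlen, max_mismatch)

    unpaired_total = ((c1[0][0] if c1 else np.inf) +
                      (c2[0][0] if c2 else np.inf))
    if pairs and unpaired_total > pairs[0][0] - pair_bonus:
        joint, ci, q1, q2, s1, mm1, mm2 = pairs[0]
        amb = sum(1 for p in pairs if p[0] == joint) > 1
        name = index.order[ci]
        r1 = AlignmentRecord(id1, name, q1 + 1, "+" if s1 == 0 else "-",
                             mm1, True, ambiguous=amb, proper_pair=True,
                             read_length=m)
        r2 = AlignmentRecord(id2, name, q2 + 1, "-" if s1 == 0 else "+",
                             mm2, True, ambiguous=amb, proper_pair=True,
                             read_length=m)
        return r1, r2
    return (single(id1, c1, m), single(id2, c2, len(frag.seq2)))


# ---------------------------------------------------------------------------
# Fragment-set driver with sequence memoization
# ---------------------------------------------------------------------------

def align_fragments(frags: FragmentSet, index: SeedIndex,
                    max_mismatch: int = DEFAULT_MAX_MISMATCH,
                    pair_bonus: int = DEFAULT_PAIR_BONUS,
                    insert_tol: int = DEFAULT_INSERT_TOL,
                    memo: dict | None = None) -> list[AlignmentRecord]:
    """Align every fragment of a set, memoizing by read sequence.

    Alignment is a pure function of the read sequence(s), so heteroplasmy
    mixtures — which repeat identical fragment sets many times — align at
    the cost of one dictionary lookup per repeated read.
    """
    if memo is None:
        memo = {}
    paired = frags.config.layout == "paired"
    insert_range = frags.config.insert_range if paired else None
    out: list[AlignmentRecord] = []
    for f in frags:
        if paired:
            key = (f.seq1, f.seq2, f.template_length)
            hit = memo.get(key)
            if hit is None:
                hit = align_paired(f, index, max_mismatch,
                                   insert_range, pair_bonus, insert_tol)
                memo[key] = hit
            out.append(replace(hit[0], read_id=f.read_id + "/1"))
            out.append(replace(hit[1], read_id=f.read_id + "/2"))
        else:
            hit = memo.get(f.seq1)
            if hit is None:
                hit = align_read(f.seq1, index, max_mismatch, f.read_id)
                memo[f.seq1] = hit
            out.append(replace(hit, read_id=f.read_id))
    return out


# ---------------------------------------------------------------------------
# SAM bridge
# ---------------------------------------------------------------------------

def write_sam(records: list[AlignmentRecord], refset: ReferenceSet, path,
              reads_by_id: dict[str, str] | None = None) -> None:
    """Write primary records as SAM 1.6 (one @SQ line per contig).

    Sequences are emitted when available in ``reads_by_id`` (reverse
    complemented for minus-strand records, per SAM convention), else ``*``.
    Ambiguous records get MAPQ 0, unique ones MAPQ 60.
    """
    import pysam

    contigs = [refset.mito] + refset.nuclear
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": g.name, "LN": len(g)} for g in contigs],
    }
    tid = {g.name: i for i, g in enumerate(contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            seq = reads_by_id.get(rec.read_id) if reads_by_id else None
            flag = 0
            if not rec.mapped:
                flag |= 4
            else:
                if rec.strand == "-":
                    flag |= 16
                    if seq is not None:
                        seq = revcomp(seq)
                if rec.proper_pair:
                    flag |= 1 | 2
            a.flag = flag
            if seq is not None:
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(seq))
            if rec.mapped:
                a.reference_id = tid[rec.contig]
                a.reference_start = rec.pos - 1
                a.mapping_quality = 0 if rec.ambiguous else 60
                a.cigartuples = [(0, rec.read_length)]
                a.set_tag("NM", rec.mismatches)
            fh.write(a)


def read_sam(path, refset: ReferenceSet) -> list[AlignmentRecord]:
    """Load primary alignments from SAM/BAM as AlignmentRecords.

    Secondary and supplementary records are dropped; the unmapped flag is
    honored; mismatch counts come from the NM tag when present and are
    otherwise recomputed by gapless comparison against the reference (with
    a warning).  MAPQ 0 is interpreted as ambiguous.
    """
    import pysam

    known = {g.name for g in [refset.mito] + refset.nuclear}
    arrays = {g.name: np.frombuffer(g.sequence.encode(), dtype=np.uint8)
              for g in [refset.mito] + refset.nuclear}
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                continue
            rid = a.query_name
            if a.is_paired:
                rid += "/1" if a.is_read1 else "/2"
            rlen = a.query_length or (a.infer_query_length() or 0)
            if a.is_unmapped:
                out.append(_unmapped(rid, rlen))
                continue
            if a.reference_name not in known:
                raise ValueError(
                    f"SAM contig {a.reference_name!r} not in reference set"
                )
            if a.has_tag("NM"):
                nm = int(a.get_tag("NM"))
            else:
                warnings.warn(f"record {rid}: missing NM tag; recomputing "
                              f"mismatches by gapless comparison")
                ref = arrays[a.reference_name][
                    a.reference_start:a.reference_start + rlen]
                query = np.frombuffer(a.query_sequence.encode(),
                                      dtype=np.uint8)
                nm = int(np.count_nonzero(ref != query[:len(ref)]))
            out.append(AlignmentRecord(
                rid, a.reference_name, a.reference_start + 1,
                "-" if a.is_reverse else "+", nm, True,
                ambiguous=a.mapping_quality == 0,
                proper_pair=a.is_proper_pair, read_length=rlen))
    return out
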