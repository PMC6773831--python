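"""Synthetic mitochondrial and nuclear reference construction.

Real short-read studies of mitochondrial variant calling are confounded by
nuMTs: nuclear segments of mitochondrial origin that are nearly identical to
stretches of the mitochondrial genome.  This module builds reference sets
whose homology structure reproduces that situation synthetically, so the
whole audit pipeline is testable without downloading a real genome:

* a seeded random mitochondrial contig, screened so that no k-mer occurs
  twice (every error-free read maps back uniquely in the absence of nuMTs);
* nuclear contigs of i.i.d. random background into which copies of
  mitochondrial segments ("planted nuMTs") are inserted with a controlled
  set of mismatches;
* ready-made fixtures reproducing the canonical confounding geometries:
  a nuMT one mismatch away from the mitochondrial source, and a nuMT two
  mismatches away for studying haplotype-background effects.

Coordinates are 1-based inclusive throughout (matching mitochondrial variant
notation such as ``chrM:6023G>A``); conversion to 0-based happens only at
file-format boundaries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Largest read length the fixtures are sized for.
MAX_READ_LENGTH = 300

#: Default seed length used both by the aligner and by the repeat screen.
DEFAULT_SEED_K = 19


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """A named reference contig.

    Parameters
    ----------
    name : contig identifier (e.g. ``"chrM"``).
    sequence : uppercase A/C/G/T string; no ambiguity codes.
    circular : whether the molecule is circular (mitochondria are).
    """

    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.name!r}: sequence must be non-empty")
        bad = set(self.sequence) - set(BASES)
        if bad:
            pos = next(i for i, b in enumerate(self.sequence, start=1)
                       if b in bad)
            raise ValueError(
                f"genome {self.name!r}: non-ACGT base {self.sequence[pos - 1]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class NumtSpec:
    """Recipe for one planted nuMT.

    A segment of the mitochondrial contig starting at ``mito_start``
    (1-based) of ``length`` bp is copied, the listed mismatches are applied
    (offsets are 1-based within the segment), and the result is inserted
    into ``host_contig`` at ``host_insert_pos`` (1-based position the
    segment will occupy on the host).
    """

    mito_start: int
    length: int
    mismatches: tuple[tuple[int, str], ...]
    host_contig: str
    host_insert_pos: int

    def validate(self, mito: Genome) -> None:
        if not (1 <= self.mito_start and
                self.mito_start + self.length - 1 <= len(mito)):
            raise ValueError(
                f"nuMT segment [{self.mito_start}, "
                f"{self.mito_start + self.length - 1}] outside mito contig "
                f"of length {len(mito)}"
            )
        offsets = [off for off, _ in self.mismatches]
        if len(set(offsets)) != len(offsets):
            raise ValueError("duplicate mismatch offsets in NumtSpec")
        for off, base in self.mismatches:
            if not 1 <= off <= self.length:
                raise ValueError(f"mismatch offset {off} outside segment")
            if base not in BASES:
                raise ValueError(f"invalid substituted base {base!r}")
            src = mito.base(self.mito_start + off - 1)
            if base == src:
                raise ValueError(
                    f"mismatch at offset {off} equals the mito base {src!r}"
                )

    def segment(self, mito: Genome) -> str:
        """The nuclear-side sequence of the planted segment."""
        seg = list(mito.sequence[self.mito_start - 1:
                                 self.mito_start - 1 + self.length])
        for off, base in self.mismatches:
            seg[off - 1] = base
        return "".join(seg)


@dataclass
class ReferenceSet:
    """One mitochondrial contig plus zero or more nuclear contigs.

    ``mito_priority`` controls the contig order used for deterministic
    tie-breaking downstream: by default the mitochondrial contig sorts
    first, which is conservative for this audit (ambiguous reads are kept
    on chrM, understating nuMT capture).
    """

    mito: Genome
    nuclear: list[Genome] = field(default_factory=list)
    planted: list[NumtSpec] = field(default_factory=list)
    mito_priority: bool = True

    def __post_init__(self) -> None:
        names = [self.mito.name] + [g.name for g in self.nuclear]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate contig names in ReferenceSet: {names}")

    @property
    def contigs(self) -> list[Genome]:
        """Contigs in tie-break order."""
        if self.mito_priority:
            return [self.mito] + list(self.nuclear)
        return list(self.nuclear) + [self.mito]

    def get(self, name: str) -> Genome:
        for g in [self.mito] + self.nuclear:
            if g.name == name:
                return g
        raise KeyError(f"no contig named {name!r}")

    def with_mito(self, mito: Genome) -> "ReferenceSet":
        """A copy of this set with the mitochondrial contig replaced."""
        if mito.name != self.mito.name:
            raise ValueError("replacement mito contig must keep its name")
        return ReferenceSet(mito, list(self.nuclear), list(self.planted),
                            self.mito_priority)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _has_repeated_kmer(seq: str, k: int) -> bool:
    """True if any k-mer (canonical, i.e. strand-collapsed) occurs twice."""
    seen: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        canon = min(kmer, revcomp(kmer))
        if canon in seen:
            return True
        seen.add(canon)
    return False


def make_mito_genome(length: int, seed: int, *, name: str = "chrM",
                     k: int = DEFAULT_SEED_K, max_tries: int = 50) -> Genome:
    """Generate a circular mitochondrial contig with low self-similarity.

    The sequence is i.i.d. uniform ACGT, regenerated (deterministically,
    from sub-streams of ``seed``) until it contains no repeated k-mer on
    either strand, so that in the absence of nuMTs every error-free
    fragment maps back uniquely.
    """
    if length < 2 * MAX_READ_LENGTH:
        raise ValueError(
            f"mito genome length {length} too small: must be at least "
            f"{2 * MAX_READ_LENGTH} (twice the maximum supported read length)"
        )
    for attempt in range(max_tries):
        rng = np.random.default_rng([seed, attempt])
        seq = _random_bases(rng, length)
        if not _has_repeated_kmer(seq, k):
            return Genome(name, seq, circular=True)
    raise RuntimeError(
        f"could not generate a repeat-free {length} bp genome in "
        f"{max_tries} tries (k={k})"
    )


def plant_numt(refset: ReferenceSet, spec: NumtSpec, background_length: int,
               seed: int) -> ReferenceSet:
    """Insert a copied mitochondrial segment into a nuclear contig.

    If the host contig does not exist it is created as ``background_length``
    bp of seeded random background.  Planting a nuMT whose insertion point
    falls strictly inside an already-planted segment on the same host is
    rejected.  Returns a new ReferenceSet; the input is not modified.
    """
    spec.validate(refset.mito)

    # occupied intervals (start, length) of previously planted segments on
    # this host, in the host's current coordinates, replaying insertions in
    # planting order (a later insert upstream shifts earlier segments)
    occupied: list[tuple[int, int]] = []
    for prev in (p for p in refset.planted if p.host_contig == spec.host_contig):
        shifted = [(s + prev.length if s >= prev.host_insert_pos else s, ln)
                   for s, ln in occupied]
        occupied = shifted + [(prev.host_insert_pos, prev.length)]
    for start, ln in occupied:
        if start < spec.host_insert_pos < start + ln:
            raise ValueError(
                f"nuMT insertion at {spec.host_contig}:{spec.host_insert_pos} "
                f"overlaps a previously planted segment at [{start}, "
                f"{start + ln - 1}]"
            )

    try:
        host = refset.get(spec.host_contig)
        if host.name == refset.mito.name:
            raise ValueError("cannot plant a nuMT on the mitochondrial contig")
        background = host.sequence
        nuclear = [g for g in refset.nuclear if g.name != host.name]
    except KeyError:
        rng = np.random.default_rng([seed, len(refset.planted)])
        background = _random_bases(rng, background_length)
        nuclear = list(refset.nuclear)

    if not 1 <= spec.host_insert_pos <= len(background) + 1:
        raise ValueError(
            f"insert position {spec.host_insert_pos} outside host contig "
            f"(length {len(background)})"
        )
    seg = spec.segment(refset.mito)
    new_seq = (background[:spec.host_insert_pos - 1] + seg +
               background[spec.host_insert_pos - 1:])
    nuclear.append(Genome(spec.host_contig, new_seq, circular=False))
    nuclear.sort(key=lambda g: g.name)
    return ReferenceSet(refset.mito, nuclear,
                        list(refset.planted) + [spec], refset.mito_priority)


def _next_base(base: str) -> str:
    """A deterministic base different from ``base`` (cyclic in ACGT order)."""
    return BASES[(BASES.index(base) + 1) % 4]


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def one_mismatch_fixture(seed: int, *, mito_length: int = 16569,
                         flank: int = 100, host: str = "chr1",
                         background_length: int = 2000):
    """Reference set with one nuMT a single mismatch away from its source.

    The nuclear contig carries a copy of the mitochondrial segment spanning
    ``flank`` bp on each side of a focal position; the copy's single
    mismatch sits exactly at the focal position.  The returned SNV's alt
    allele equals the nuclear base, so applying it to the mitochondrial
    genome makes every read of length <= ``flank`` covering the focal
    position identical to the nuclear copy — the mechanism by which a
    variant's reads are captured by a nuMT, while reads carrying the
    reference allele still map to the mitochondrial contig.

    Returns ``(refset, snv)``.
    """
    from .mutagenesis import SNV  # local import avoids a module cycle

    mito = make_mito_genome(mito_length, seed)
    focal = mito_length // 2
    alt = _next_base(mito.base(focal))
    spec = NumtSpec(
        mito_start=focal - flank,
        length=2 * flank + 1,
        mismatches=((flank + 1, alt),),
        host_contig=host,
        host_insert_pos=background_length // 2,
    )
    refset = plant_numt(ReferenceSet(mito), spec, background_length, seed + 1)
    snv = SNV(mito.name, focal, mito.base(focal), alt)
    return refset, snv


def two_mismatch_fixture(seed: int, *, mito_length: int = 16569,
                         flank: int = 100, spacing: int = 5,
                         host: str = "chr1", background_length: int = 2000):
    """Reference set with one nuMT two mismatches away from its source.

    The two mismatches sit at a background position ``b`` and a focal
    position ``f = b - spacing`` (both inside any read covering either when
    ``spacing`` < read length).  The background SNV's alt equals the nuclear
    base at ``b`` and the focal SNV's alt equals the nuclear base at ``f``:
    introducing the background variant removes one mismatch between
    mitochondrial reads and the nuclear copy, so surrounding variants lose
    far more coverage on the background haplotype than on the reference one
    — the haplogroup-SNP exacerbation geometry.

    Returns ``(refset, background_snv, focal_snv)``.
    """
    from .mutagenesis import SNV

    mito = make_mito_genome(mito_length, seed)
    b = mito_length // 2
    f = b - spacing
    alt_b = _next_base(mito.base(b))
    alt_f = _next_base(mito.base(f))
    seg_start = f - flank
    seg_len = (b + flank) - seg_start + 1
    spec = NumtSpec(
        mito_start=seg_start,
        length=seg_len,
        mismatches=((f - seg_start + 1, alt_f), (b - seg_start + 1, alt_b)),
        host_contig=host,
        host_insert_pos=background_length // 2,
    )
    refset = plant_numt(ReferenceSet(mito), spec, background_length, seed + 1)
    background = SNV(mito.name, b, mito.base(b), alt_b)
    focal = SNV(mito.name, f, mito.base(f), alt_f)
    return refset, background, focal


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(refset: ReferenceSet, path) -> None:
    """Write all contigs as multi-record FASTA (60-column wrap)."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.name, description="")
        for g in [refset.mito] + refset.nuclear
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, mito_name: str = "chrM",
               circular_mito: bool = True) -> ReferenceSet:
    """Load a ReferenceSet from FASTA; ``mito_name`` flags the mito contig."""
    mito = None
    nuclear = []
    for rec in SeqIO.parse(str(path), "fasta"):
        g = Genome(rec.id, str(rec.seq).upper(),
                   circular=(rec.id == mito_name and circular_mito))
        if rec.id == mito_name:
            mito = g
        else:
            nuclear.append(g)
    if mito is None:
        raise ValueError(f"no contig named {mito_name!r} in {path}")
    return ReferenceSet(mito, nuclear)


def write_numt_table(refset: ReferenceSet, path) -> None:
    """Sidecar TSV describing every planted nuMT, for test introspection."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["host_contig", "host_insert_pos", "mito_start", "length",
                    "mismatches"])
        for s in refset.planted:
            mm = ",".join(f"{off}:{base}" for off, base in s.mismatches)
            w.writerow([s.host_contig, s.host_insert_pos, s.mito_start,
                        s.length, mm])
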