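"""Deterministic sliding-window read simulation.

A genome is tiled into fixed-length fragments in sliding windows (default
step 1 bp from position 1), single-end or paired-end, and written as FASTQ
with every base at Q40.  The simulation is substitution-free and
quality-free on purpose: any downstream coverage loss is then attributable
to the alignment competition between the mitochondrial contig and nuMTs,
not to sequencing noise.

With step 1 the maximum per-position depth equals the read length for
single-end reads (100x/150x/300x for 100/150/300 bp reads) and twice the
read length for paired-end reads at an insert equal to twice the read
length (200x/300x/600x), counting both mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .synthetic_refs import Genome, revcomp

#: Phred+33 encoding of quality 40.
Q40_CHAR = "I"


@dataclass(frozen=True)
class ReadConfig:
    """Read-simulation parameters.

    ``insert_size`` is the total template length: an ``int`` for a fixed
    insert, or an inclusive ``(lo, hi)`` integer range sampled uniformly
    per template with ``seed`` (mirroring aligners that require a non-zero
    insert-size standard deviation).  Insert 200 with 2x100 bp reads means
    abutting, non-overlapping mates.
    """

    read_length: int
    layout: str = "single"  # "single" | "paired"
    insert_size: int | tuple[int, int] | None = None
    step: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.layout not in ("single", "paired"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "paired":
            if self.insert_size is None:
                raise ValueError("paired layout requires insert_size")
            lo, hi = self.insert_range
            if lo > hi:
                raise ValueError("insert range lo > hi")
            if lo < self.read_length:
                raise ValueError(
                    f"insert size {lo} smaller than read length "
                    f"{self.read_length}"
                )

    @property
    def insert_range(self) -> tuple[int, int]:
        if isinstance(self.insert_size, int):
            return self.insert_size, self.insert_size
        lo, hi = self.insert_size  # type: ignore[misc]
        return int(lo), int(hi)


@dataclass(frozen=True)
class Fragment:
    """One simulated template: a single read or a proper FR pair.

    ``origin_start`` is the 1-based template start on the source contig;
    for paired layout ``seq2`` is the reverse complement of the template's
    terminal ``read_length`` bases.
    """

    read_id: str
    seq1: str
    seq2: str | None
    origin_contig: str
    origin_start: int
    template_length: int


@dataclass
class FragmentSet:
    """An ordered collection of fragments plus the config that made them."""

    config: ReadConfig
    fragments: list[Fragment] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def reads_by_id(self) -> dict[str, str]:
        """Map every read id (``/1``, ``/2`` suffixed for pairs) to its
        sequence, for pileup reconstruction."""
        out: dict[str, str] = {}
        for f in self.fragments:
            if f.seq2 is None:
                out[f.read_id] = f.seq1
            else:
                out[f.read_id + "/1"] = f.seq1
                out[f.read_id + "/2"] = f.seq2
        return out


def _read_id(contig: str, start: int, tlen: int, serial: int) -> str:
    return f"{contig}|{start}|{tlen}|{serial}"


def fragment_single_end(genome: Genome, cfg: ReadConfig) -> FragmentSet:
    """Tile the genome into forward-strand single-end reads.

    One fragment per window start ``1 .. L - read_length + 1`` (linear
    traversal even for circular genomes; use :func:`shift_genome` to audit
    the breakpoint), ordered by start position.
    """
    if cfg.layout != "single":
        raise ValueError("fragment_single_end requires layout='single'")
    m = cfg.read_length
    L = len(genome)
    if m > L:
        raise ValueError(f"read length {m} exceeds genome length {L}")
    frags = [
        Fragment(_read_id(genome.name, start, m, i),
                 genome.sequence[start - 1:start - 1 + m], None,
                 genome.name, start, m)
        for i, start in enumerate(range(1, L - m + 2, cfg.step))
    ]
    return FragmentSet(cfg, frags, genome.name)


def fragment_paired_end(genome: Genome, cfg: ReadConfig) -> FragmentSet:
    """Tile the genome into FR read pairs.

    Mate 1 is the template's first ``read_length`` bases on the forward
    strand; mate 2 is the reverse complement of its last ``read_length``
    bases.  Template lengths in a ``(lo, hi)`` range are drawn with
    ``cfg.seed`` and are reproducible.
    """
    if cfg.layout != "paired":
        raise ValueError("fragment_paired_end requires layout='paired'")
    m = cfg.read_length
    L = len(genome)
    lo, hi = cfg.insert_range
    if hi > L:
        raise ValueError(f"insert size {hi} exceeds genome length {L}")
    rng = np.random.default_rng(cfg.seed)
    frags = []
    serial = 0
    for start in range(1, L - lo + 2, cfg.step):
        tlen = int(rng.integers(lo, hi + 1)) if lo != hi else lo
        if start + tlen - 1 > L:
            tlen = lo  # fall back to the shortest insert near the end
            if start + tlen - 1 > L:
                break
        template = genome.sequence[start - 1:start - 1 + tlen]
        frags.append(Fragment(
            _read_id(genome.name, start, tlen, serial),
            template[:m], revcomp(template[-m:]),
            genome.name, start, tlen,
        ))
        serial += 1
    return FragmentSet(cfg, frags, genome.name)


def fragment(genome: Genome, cfg: ReadConfig) -> FragmentSet:
    """Dispatch on layout."""
    if cfg.layout == "single":
        return fragment_single_end(genome, cfg)
    return fragment_paired_end(genome, cfg)


def shift_genome(genome: Genome, offset: int) -> Genome:
    """Rotate a circular genome so position ``offset + 1`` becomes first.

    Position ``p`` on the original maps to ``((p - 1 - offset) mod L) + 1``
    on the shifted genome.  Used to audit variants near the linear
    breakpoint of the circular mitochondrial genome against a shifted
    reference.
    """
    if not genome.circular:
        raise ValueError(f"cannot shift linear genome {genome.name!r}")
    L = len(genome)
    if not 0 <= offset < L:
        raise ValueError(f"offset {offset} outside [0, {L})")
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    return Genome(genome.name, seq, circular=True)


def origin_depth(frags: FragmentSet, contig_length: int) -> np.ndarray:
    """Per-position depth (1-based position ``p`` at index ``p - 1``) when
    every read is counted at its simulated origin; both mates count."""
    m = frags.config.read_length
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for f in frags:
        diff[f.origin_start - 1] += 1
        diff[f.origin_start - 1 + m] -= 1
        if f.seq2 is not None:
            s2 = f.origin_start + f.template_length - m
            diff[s2 - 1] += 1
            diff[s2 - 1 + m] -= 1
    return np.cumsum(diff[:-1])


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def _fastq_paths(path) -> tuple[Path, Path]:
    p = Path(path)
    stem, suffix = (p.name[:-len("".join(p.suffixes))] or p.stem,
                    "".join(p.suffixes) or ".fastq")
    return (p.with_name(f"{stem}_R1{suffix}"),
            p.with_name(f"{stem}_R2{suffix}"))


def write_fastq(frags: FragmentSet, path) -> list[Path]:
    """Write fragments as FASTQ with every base at Q40.

    Single-end sets go to ``path``; paired-end sets go to synchronized
    ``_R1``/``_R2`` files (derived from ``path``) with matching read ids.
    Returns the paths written.
    """
    paired = frags.config.layout == "paired"
    try:
        if not paired:
            with open(path, "w") as fh:
                for f in frags:
                    fh.write(f"@{f.read_id}\n{f.seq1}\n+\n"
                             f"{Q40_CHAR * len(f.seq1)}\n")
            return [Path(path)]
        p1, p2 = _fastq_paths(path)
        with open(p1, "w") as fh1, open(p2, "w") as fh2:
            for f in frags:
                fh1.write(f"@{f.read_id}\n{f.seq1}\n+\n"
                          f"{Q40_CHAR * len(f.seq1)}\n")
                fh2.write(f"@{f.read_id}\n{f.seq2}\n+\n"
                          f"{Q40_CHAR * len(f.seq2)}\n")
        return [p1, p2]
    except OSError as exc:
        raise OSError(f"failed writing FASTQ to {path}: {exc}") from exc


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Parse a FASTQ file to ``(read_id, sequence, quality)`` tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33)
                        for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), quals))
    return out
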