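"""Single-nucleotide mutagenesis and heteroplasmy mixtures.

An exhaustive audit introduces every possible single-nucleotide variant,
one at a time: a genome of length L yields 3L mutated genomes (three
alternative alleles per position; 49,707 for a 16,569 bp mitochondrial
genome).  Heteroplasmy — several alleles coexisting across the cell's many
mtDNA copies — is modeled by exact copy-count mixing of reference and
mutant fragment sets (e.g. 1:1 for 50%, 95:5 for 5%), so the nominal minor
allele fraction at unconfounded positions is exact by construction rather
than a sampling estimate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .fragmenter import Fragment, FragmentSet
from .synthetic_refs import BASES, Genome, ReferenceSet

_NOTATION_RE = re.compile(r"^(?P<contig>[^:]+):(?P<pos>\d+)"
                          r"(?P<ref>[ACGT])>(?P<alt>[ACGT])$")


@dataclass(frozen=True)
class SNV:
    """A single-nucleotide substitution, 1-based, e.g. ``chrM:6023G>A``."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"invalid alleles {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} must be >= 1")

    @property
    def notation(self) -> str:
        return f"{self.contig}:{self.pos}{self.ref}>{self.alt}"

    @classmethod
    def from_notation(cls, text: str) -> "SNV":
        m = _NOTATION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse SNV notation {text!r}")
        return cls(m["contig"], int(m["pos"]), m["ref"], m["alt"])

    @property
    def inverse(self) -> "SNV":
        return SNV(self.contig, self.pos, self.alt, self.ref)


@dataclass(frozen=True)
class Mixture:
    """Exact copy counts of reference and mutant fragment sets."""

    ref_copies: int
    mut_copies: int

    def __post_init__(self) -> None:
        if self.ref_copies < 0 or self.mut_copies < 0:
            raise ValueError("copy counts must be non-negative")
        if self.ref_copies + self.mut_copies < 1:
            raise ValueError("at least one copy required")

    @property
    def nominal_heteroplasmy(self) -> float:
        return self.mut_copies / (self.ref_copies + self.mut_copies)


def enumerate_snvs(genome: Genome) -> list[SNV]:
    """All 3L SNVs, ordered by (position, alt in A<C<G<T order)."""
    out = []
    for pos, ref in enumerate(genome.sequence, start=1):
        if ref not in BASES:
            raise ValueError(
                f"non-ACGT base {ref!r} at {genome.name}:{pos}"
            )
        out.extend(SNV(genome.name, pos, ref, alt)
                   for alt in BASES if alt != ref)
    return out


def apply_snv(genome: Genome, snv: SNV) -> Genome:
    """Return a copy of the genome carrying the variant.

    The ref-allele check guards against coordinate bugs: the stated ref
    must match the sequence at the stated position.
    """
    if snv.contig != genome.name:
        raise ValueError(
            f"SNV contig {snv.contig!r} does not match genome {genome.name!r}"
        )
    if not 1 <= snv.pos <= len(genome):
        raise ValueError(f"position {snv.pos} outside genome of length "
                         f"{len(genome)}")
    actual = genome.base(snv.pos)
    if actual != snv.ref:
        raise ValueError(
            f"ref allele mismatch at {genome.name}:{snv.pos}: "
            f"SNV says {snv.ref}, sequence has {actual}"
        )
    seq = genome.sequence
    mutated = seq[:snv.pos - 1] + snv.alt + seq[snv.pos:]
    return Genome(genome.name, mutated, genome.circular)


def mix_fragments(ref_frags: FragmentSet, mut_frags: FragmentSet,
                  mix: Mixture) -> FragmentSet:
    """Concatenate copy-count multiples of two fragment sets.

    Output order is all reference copies followed by all mutant copies;
    read ids are re-serialized so every read id stays unique.  Both inputs
    must share an identical ReadConfig (otherwise depth arithmetic and the
    nominal allele fraction would be meaningless).
    """
    if ref_frags.config != mut_frags.config:
        raise ValueError("mixed fragment sets must share an identical "
                         "ReadConfig")
    out: list[Fragment] = []
    serial = 0
    for frags, copies in ((ref_frags, mix.ref_copies),
                          (mut_frags, mix.mut_copies)):
        for _ in range(copies):
            for f in frags:
                out.append(replace(
                    f,
                    read_id=f"{f.origin_contig}|{f.origin_start}|"
                            f"{f.template_length}|{serial}",
                ))
                serial += 1
    return FragmentSet(ref_frags.config, out, ref_frags.source)


# ---------------------------------------------------------------------------
# I/O: 4-column TSV and sites-only VCF
# ---------------------------------------------------------------------------

def write_snv_tsv(snvs: list[SNV], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\n")
        for s in snvs:
            fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\n")


def read_snv_tsv(path) -> list[SNV]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig"):
            fh.seek(0)
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, pos, ref, alt = line.split("\t")[:4]
            out.append(SNV(contig, int(pos), ref.strip(), alt.strip()))
    return out


def write_snv_vcf(snvs: list[SNV], refset: ReferenceSet, path) -> None:
    """Sites-only VCF 4.2 with contig headers taken from the reference set."""
    import pysam

    header = pysam.VariantHeader()
    for g in [refset.mito] + refset.nuclear:
        header.contigs.add(g.name, length=len(g))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for s in snvs:
            rec = vf.new_record(contig=s.contig, start=s.pos - 1,
                                stop=s.pos, alleles=(s.ref, s.alt))
            vf.write(rec)


def read_snv_vcf(path) -> list[SNV]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1:
                    out.append(SNV(rec.contig, rec.pos, rec.ref, alt))
    return out
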