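"""Pileup-based observed minor-allele-frequency estimation.

With error-free, quality-40 reads a counting estimator is exact: the
observed minor allele fraction at a position is simply the alternative
base count divided by the depth of the reads piling up there.  The bias
this package audits is a property of alignment, not of the caller — reads
carrying the alternative allele are captured by nuclear loci before any
caller sees them — so a likelihood-based caller is deliberately not
layered on top.

Under exact copy-count mixing the observed fraction has a closed form:
``observed = (d_mut * c_mut) / (d_mut * c_mut + d_ref * c_ref)`` where
``d_ref``/``d_mut`` are the retained per-copy depths of reference and
mutant fragment sets at the position and ``c_ref``/``c_mut`` the copy
counts.  The pipeline result is checked against this form in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .aligner import (DEFAULT_MAX_MISMATCH, AlignmentRecord, SeedIndex,
                      align_fragments, build_index)
from .coverage_audit import LossRecord
from .fragmenter import ReadConfig, fragment
from .mutagenesis import SNV, Mixture, apply_snv, mix_fragments
from .synthetic_refs import BASES, ReferenceSet

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default detection threshold on the observed minor allele fraction.
DEFAULT_DETECTION_THRESHOLD = 0.01


@dataclass
class Pileup:
    """Base counts at one position from mapped primary reads covering it."""

    contig: str
    pos: int
    counts: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in BASES})

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MafCall:
    """Observed vs nominal minor allele fraction at one audited variant.

    ``zero_depth`` flags the fully undetectable state (no reads at all at
    the position, so the observed fraction is reported as 0).
    """

    snv: SNV
    observed_maf: float
    nominal_maf: float
    depth: int
    detected: bool
    zero_depth: bool = False


def pileup_at(records: list[AlignmentRecord], reads_by_id: dict[str, str],
              contig: str, pos: int) -> Pileup:
    """Count the base each covering read contributes at ``pos``.

    Alignment is gapless, so a plus-strand read at leftmost ``p``
    contributes ``read[pos - p]`` and a minus-strand read contributes the
    complement of its stored sequence read off from the other end.
    """
    pile = Pileup(contig, pos)
    for rec in records:
        if not rec.covers(contig, pos):
            continue
        seq = reads_by_id[rec.read_id]
        if rec.strand == "+":
            base = seq[pos - rec.pos]
        else:
            base = _COMPLEMENT[seq[rec.pos + len(seq) - 1 - pos]]
        if base in pile.counts:
            pile.counts[base] += 1
    return pile


def observed_maf(pileup: Pileup, snv: SNV, nominal: float,
                 threshold: float = DEFAULT_DETECTION_THRESHOLD) -> MafCall:
    """Observed alternative-allele fraction and its detection status."""
    if pileup.depth == 0:
        return MafCall(snv, 0.0, nominal, 0, False, zero_depth=True)
    obs = pileup.counts[snv.alt] / pileup.depth
    return MafCall(snv, obs, nominal, pileup.depth, obs >= threshold)


def mixture_maf(refset: ReferenceSet, cfg: ReadConfig, snv: SNV,
                mix: Mixture, *, k: int = 19,
                max_mismatch: int = DEFAULT_MAX_MISMATCH,
                threshold: float = DEFAULT_DETECTION_THRESHOLD,
                index: SeedIndex | None = None,
                memo: dict | None = None) -> MafCall:
    """End-to-end observed MAF for one variant under a heteroplasmy mixture.

    Fragments the reference and the mutated mitochondrial genome, mixes the
    two sets at the given copy counts, aligns the mixture against the full
    reference set, and piles up at the variant position.
    """
    if index is None:
        index = build_index(refset, k)
    if memo is None:
        memo = {}
    mito = refset.mito
    ref_frags = fragment(mito, cfg)
    mut_frags = fragment(apply_snv(mito, snv), cfg)
    mixed = mix_fragments(ref_frags, mut_frags, mix)
    records = align_fragments(mixed, index, max_mismatch, memo=memo)
    pile = pileup_at(records, mixed.reads_by_id(), mito.name, snv.pos)
    return observed_maf(pile, snv, mix.nominal_heteroplasmy, threshold)


def bias_report(loss_records: list[LossRecord],
                maf_calls: list[MafCall]) -> pd.DataFrame:
    """Join coverage losses with observed MAFs into the per-variant bias
    table (``deficit = nominal - observed``).

    Both inputs must come from the same read configuration, matched by
    variant; a variant present on only one side is a configuration
    mismatch.
    """
    losses = {r.snv: r for r in loss_records}
    calls = {c.snv: c for c in maf_calls}
    if set(losses) != set(calls):
        raise ValueError("loss records and MAF calls cover different "
                         "variants; were they computed under the same "
                         "read configuration?")
    rows = []
    for snv in sorted(losses, key=lambda s: (s.pos, s.alt)):
        r, c = losses[snv], calls[snv]
        rows.append({
            "contig": snv.contig, "pos": snv.pos, "ref": snv.ref,
            "alt": snv.alt, "loss_pct": r.loss_pct,
            "nominal_maf": c.nominal_maf, "observed_maf": c.observed_maf,
            "deficit": c.nominal_maf - c.observed_maf,
            "depth": c.depth, "detected": c.detected,
        })
    return pd.DataFrame(rows)


def write_maf_tsv(calls: list[MafCall], path,
                  header_lines: list[str] | None = None) -> None:
    """Output TSV: contig, pos, ref, alt, nominal_maf, observed_maf,
    depth, detected."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("contig\tpos\tref\talt\tnominal_maf\tobserved_maf\t"
                 "depth\tdetected\n")
        for c in calls:
            fh.write(f"{c.snv.contig}\t{c.snv.pos}\t{c.snv.ref}\t"
                     f"{c.snv.alt}\t{c.nominal_maf:.6g}\t"
                     f"{c.observed_maf:.6g}\t{c.depth}\t"
                     f"{str(c.detected).lower()}\n")
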