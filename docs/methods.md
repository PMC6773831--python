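# Methods

## The phenomenon being modeled

Short-read alignment assigns each read to its best-scoring locus. When a
nuclear genome contains near-identical copies of mitochondrial sequence
(nuMTs), reads simulated (or sequenced) from the mitochondrial genome
compete between chrM and the nuMT, and the competition is decided by the
mismatch count on each side. A mitochondrial single-nucleotide variant can
tip this competition in either direction:

- if the variant's alternative allele **matches** the nuMT where the nuMT
  differs from chrM, reads carrying the variant become *closer* to the
  nuclear copy than to the mitochondrial reference and are captured by the
  nuclear locus;
- reads carrying the reference allele keep mapping to chrM.

The result is allele-specific coverage loss at the mitochondrial position
and a downward bias of the observed minor allele fraction (MAF) — a
reference bias introduced purely by alignment, before any variant caller
runs.

## Pipeline model

1. **Reference construction.** A circular mitochondrial contig of length L
   (default 16,569 bp, the canonical human mtDNA length) is drawn i.i.d.
   uniform over ACGT from a seeded generator and regenerated until no
   19-mer occurs twice on either strand. The screen uses the aligner's
   seed length, which guarantees that without nuMTs every error-free read
   has a unique exact placement; any observed coverage loss is then
   attributable to planted homology. Nuclear contigs are i.i.d. random
   background (only homology to the mitochondrial contig matters for the
   audit) into which copies of mitochondrial segments are inserted with an
   explicit mismatch list.

2. **Fragmentation.** Sliding windows of 1 bp from position 1, forward
   strand, substitution- and error-free, all bases Q40. Single-end reads of
   length m give maximum depth m (100×/150×/300× for the standard
   lengths); paired-end templates of total length t carry mate 1 as the
   first m bases and mate 2 as the reverse complement of the last m, so an
   abutting insert t = 2m doubles the maximum to 2m (200×/300×/600×).
   "Insert size" throughout means total template length. Circular genomes
   are fragmented linearly; the breakpoint is audited separately against a
   rotated reference (below). Reverse-strand simulation is unnecessary
   because the aligner scores both strands of every locus.

3. **Mutagenesis.** Every position contributes its three non-reference
   alleles, ordered (position, alt), 3L variants in total. Heteroplasmy is
   modeled by exact copy-count concatenation of reference and mutant
   fragment sets (1:1 for 50%, 95:5 for 5%): at unconfounded positions the
   nominal fraction is exact by construction, which isolates the alignment
   effect from sampling noise. A caller's stochastic view of heteroplasmy
   is deliberately not simulated.

4. **Alignment.** Gapless seed-and-extend: candidate loci are gathered
   from exact non-overlapping k-mers (k = 19) at read offsets 0, k, 2k, …
   on both strands of every contig, each candidate scored by full-length
   Hamming distance, minimum wins. A read with e mismatches destroys at
   most e seeds, so with max_mismatch = 4 < floor(100/19) = 5 every locus
   within the mismatch budget is recovered — the seed heuristic is exact
   here, and an exhaustive brute-force scan with the identical tie-break
   rule is used as an oracle in the tests. Ties set `ambiguous` (the
   analog of MAPQ 0) and are broken by contig order (mitochondrial contig
   first by default, which conservatively retains ambiguous reads on chrM
   and understates nuMT capture; a flag reverses the order), then
   position, then + before −. Ambiguous reads count toward coverage at
   their tie-break winner. Paired ends are placed jointly: FR-oriented
   placements on one contig with template length within the configured
   insert range ±10 bp are scored by total mismatches, and the best proper
   pairing is preferred unless independent unpaired placements beat it by
   ≥ 2 mismatches (`pair_bonus`). This is the mechanism by which a mate
   anchored on chrM rescues its partner from a short nuMT. Gapless scoring
   is exact for this study because the simulated reads contain only
   substitutions; it removes gap penalties, clipping and MAPQ heuristics
   as confounders while preserving the mismatch-count competition that
   drives the phenomenon. A development-time comparison against bwa mem on
   the one-mismatch fixture (via the SAM bridge) agreed on the primary
   contig for every read.

5. **Coverage audit.** Depth adds 1 per mapped primary record over its
   read span; paired mates are counted independently (equivalent to
   template counting at abutting inserts, and correct for longer ones).
   The loss statistic is `100 × (1 − mut_depth/ref_depth)`: the retained
   fraction `mut/ref` is the natural ratio, and expressing it as a loss is
   the only reading under which a position with zero mutant depth shows a
   "100% loss". Losses are not clamped (a negative loss records a gain);
   thresholds are strict (> 0%, > 10%, > 20%, > 50%); paired-end records
   are filtered to losses > 3% before binning, absorbing the depth jitter
   a variable insert introduces. The sweep exploits locality: a
   substitution only alters fragments whose template overlaps it, so per
   variant only those ≤ read_length (or ≤ insert) fragments are re-aligned
   against the cached reference alignment; the tests assert equality with
   a from-scratch full realignment. The breakpoint scan rotates the
   circular genome by L/2 (configurable), introduces every SNV within
   ±100 bp of the original breakpoint into the rotated genome, aligns
   against the rotated reference alone, and reports losses in original
   coordinates; with no nuMT overlapping the windows the result is
   invariant to the rotation offset.

6. **MAF estimation.** A counting pileup: the observed MAF is the
   alternative-base count over the depth of covering mapped reads. With
   error-free Q40 reads counting is exact, and the audited bias arises in
   alignment, upstream of any caller, so no likelihood model is layered on
   top. Under exact mixing the pipeline's observed MAF equals
   `d_mut·c_mut / (d_mut·c_mut + d_ref·c_ref)` with `d_ref`, `d_mut` the
   retained per-copy depths; the tests verify this closed form against the
   full pipeline. Detection uses an explicit threshold on the observed
   fraction (default 1%, configurable), reflecting the practical concern
   that a biased MAF may fall below a pipeline's screening cutoff.

7. **Haplotype-background scan.** For a background SNP b, every SNV within
   ±100 bp (excluding b's own position) is swept twice: on the plain
   genome and on the genome carrying b, with the second sweep's loss
   denominator taken from the background genome's own reference alignment
   so that b's solo loss does not contaminate the delta. A read carrying
   both b and a focal variant has two mismatches to the plain reference;
   if b's alternative allele matches a nuMT base, the nuclear side loses
   one mismatch and nearby variants are captured far more strongly —
   whereas a background in a region without nuclear homology leaves every
   delta at zero. The denominator convention is this package's explicit
   choice for the case where the background SNP itself loses coverage.
   Raw deltas are reported; no significance test is attached. A catalog of
   human haplogroup-defining SNPs (rCRS coordinates) ships with the
   package for external-mode runs against real references.

## Fixtures and their geometry

`one_mismatch_fixture` plants a nuMT copy of the segment ±`flank` bp
(default 100) around a focal mid-genome position, with its single mismatch
at the focus, and returns the SNV whose alternative allele equals the
nuclear base. Every read of length ≤ flank covering the focus then lies
inside the homologous segment: with the variant it is identical to the
nuclear copy (capture, 100% loss), while longer reads overhang into random
background and stay on chrM — reproducing the canonical
short-reads-lost / long-reads-recovered contrast and its monotone
improvement with read length and with pairing.

`two_mismatch_fixture` plants a copy with two mismatches a few bases apart
(background and focal positions, alternative alleles equal to the nuclear
bases), producing the background-exacerbation geometry: the focal variant
alone is nearly tied between the contigs (retained by the conservative
tie-break), but on the background haplotype the nuclear side wins outright.

## What the synthetic references do and do not emulate

The fixtures reproduce the *mechanism* — mismatch-count competition
between a mitochondrial locus and a nuclear copy at controlled divergence
— not the content of any real genome. Real references carry hundreds of
nuMTs of varying age, length and divergence, repeat structure inside the
mitochondrial genome itself, and an N in the reference mitochondrial
sequence; none of these are simulated (the mitochondrial contig is
explicitly screened repeat-free, and ambiguity codes are rejected).
Consequently the hermetic runs demonstrate directions, exact mechanisms
and conservation laws, but reference-genome-scale tallies (how many of the
3L variants are affected, and by how much) depend on the real nuMT
landscape and are only obtainable in external mode: align the simulated
FASTQ with a real aligner against a real reference and feed the SAM back
through `read_sam`.

## Numerical and sizing choices

- Coordinates are 1-based inclusive everywhere in the domain model;
  0-based conversions happen only at FASTA/FASTQ/SAM/VCF boundaries.
- All randomness (genome generation, nuclear background, insert-size
  sampling) flows from explicit integer seeds; orchestration derives
  per-stage seeds from a single run seed by hashing, and a serialized run
  config re-executes to byte-identical outputs.
- Defaults: k = 19, max_mismatch = 4, pair_bonus = 2, insert tolerance
  ±10 bp, detection threshold 0.01, paired-end binning floor 3%.
- The acceptance script runs the fixture stages at the canonical
  16,569 bp genome size (the locality sweep and sequence-memoized mixture
  alignment keep this a few seconds of work) and computes the 95:5
  mixture figure on a 2,000 bp unconfounded genome — exact copy-count
  mixing makes that fraction independent of genome size.
- Test fixtures use 1–3 kb genomes; the candidate-recovery guarantee
  (max_mismatch < floor(read_length/k)) holds for every configuration the
  suite exercises.

## Known limitations

- Gapless scoring cannot represent indel-containing variants or clipped
  alignments; indels and multi-nucleotide variants are out of scope.
- Sequencing error, base-quality variation and strand sampling are not
  simulated; the audit intentionally isolates the alignment effect.
- The ambiguity policy (count ties at the tie-break winner, mito first) is
  an explicit stance, not an emulation of any particular aligner's MAPQ
  filtering; a toggle reverses the contig priority for sensitivity
  analysis.
- `mix_fragments` models heteroplasmy as exact copy counts; a seeded
  binomial downsampling of mixtures is not implemented.
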