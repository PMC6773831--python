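"""Haplotype-background scans: how a pre-existing SNP changes the coverage
loss of every variant within a window around it.

A haplogroup-defining SNP present on a sample's mitochondrial background
adds one mismatch between that sample's reads and the reference
mitochondrial contig.  If the SNP's alternative allele happens to match a
nuMT (i.e. it removes a mitochondria/nuMT mismatch), reads carrying both
the SNP and a nearby variant are pulled toward the nuclear locus far more
strongly than reads carrying the variant alone — the background
"exacerbates" the loss.  SNPs in regions without nuclear homology leave
surrounding losses untouched.

The scan compares, for every SNV within a window of a background SNP, the
coverage loss on the plain reference against the loss on the
background-carrying genome.  The loss denominator for the background
branch is the background genome's own reference alignment, so a
background SNP that itself loses coverage does not contaminate the delta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .aligner import DEFAULT_K, DEFAULT_MAX_MISMATCH
from .coverage_audit import variant_sweep
from .fragmenter import ReadConfig
from .mutagenesis import SNV, apply_snv
from .synthetic_refs import BASES, ReferenceSet


@dataclass(frozen=True)
class ScanRow:
    focal: SNV
    loss_with_background: float
    loss_without_background: float

    @property
    def delta(self) -> float:
        return self.loss_with_background - self.loss_without_background


@dataclass
class BackgroundScanResult:
    """Per-focal-variant loss deltas around one background SNP."""

    background: SNV
    rows: list[ScanRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "background": self.background.notation,
            "contig": r.focal.contig, "pos": r.focal.pos,
            "ref": r.focal.ref, "alt": r.focal.alt,
            "loss_with_background": r.loss_with_background,
            "loss_without_background": r.loss_without_background,
            "delta": r.delta,
        } for r in self.rows])

    def summary(self) -> dict:
        deltas = [r.delta for r in self.rows]
        return {
            "background": self.background.notation,
            "n_focal": len(self.rows),
            "n_positive_delta": sum(1 for d in deltas if d > 0),
            "n_negative_delta": sum(1 for d in deltas if d < 0),
            "max_delta": max(deltas, default=0.0),
        }


def background_scan(refset: ReferenceSet, cfg: ReadConfig, background: SNV,
                    window: int = 100, *, k: int = DEFAULT_K,
                    max_mismatch: int = DEFAULT_MAX_MISMATCH
                    ) -> BackgroundScanResult:
    """Sweep all SNVs within ``+/-window`` bp of ``background`` with and
    without the background variant present.

    Focal positions span exactly the window around the background position
    (excluding the background position itself), truncated with a notice at
    contig ends.  Reads carrying both a focal variant and the background
    have two mismatches to the plain mitochondrial reference.
    """
    mito = refset.mito
    if background.contig != mito.name:
        raise ValueError("background SNV must sit on the mitochondrial "
                         "contig")
    if mito.base(background.pos) != background.ref:
        raise ValueError(
            f"background ref allele mismatch at {background.pos}: sequence "
            f"has {mito.base(background.pos)}, SNV says {background.ref}"
        )
    lo = background.pos - window
    hi = background.pos + window
    if lo < 1 or hi > len(mito):
        warnings.warn(
            f"scan window [{lo}, {hi}] truncated to contig bounds "
            f"[1, {len(mito)}]"
        )
        lo, hi = max(lo, 1), min(hi, len(mito))
    focal = [
        SNV(mito.name, pos, mito.base(pos), alt)
        for pos in range(lo, hi + 1) if pos != background.pos
        for alt in BASES if alt != mito.base(pos)
    ]

    without = variant_sweep(refset, cfg, focal, k=k,
                            max_mismatch=max_mismatch)
    refset_bg = refset.with_mito(apply_snv(mito, background))
    with_bg = variant_sweep(refset_bg, cfg, focal, k=k,
                            max_mismatch=max_mismatch)
    rows = [
        ScanRow(f, w.loss_pct, wo.loss_pct)
        for f, w, wo in zip(focal, with_bg, without)
    ]
    return BackgroundScanResult(background, rows)


# ---------------------------------------------------------------------------
# Background-SNP catalogs
# ---------------------------------------------------------------------------

def read_background_tsv(path) -> list[tuple[SNV, str]]:
    """Read a background-SNP catalog TSV (contig, pos, ref, alt, label).

    Catalog rows whose listed allele equals the reference base (diagnostic
    states the reference genome already carries) are skipped with a
    warning — they define no substitution to introduce.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "contig")):
                continue
            parts = line.rstrip("\n").split("\t")
            contig, pos, ref, alt = parts[:4]
            label = parts[4] if len(parts) > 4 else ""
            try:
                out.append((SNV(contig, int(pos), ref.strip(), alt.strip()),
                            label))
            except ValueError as exc:
                warnings.warn(f"skipping catalog row {line.strip()!r}: {exc}")
    return out


def write_scan_tsv(results: list[BackgroundScanResult], path,
                   header_lines: list[str] | None = None) -> None:
    """Long-format scan TSV plus nothing else; summaries are separate."""
    frames = [r.to_frame() for r in results]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
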