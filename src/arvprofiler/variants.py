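"""Minimal pileup-based substitution caller with hotspot annotation.

Contiguously mapped reads are piled up per target position; a variant is
emitted where the most frequent non-reference allele clears depth, allele
fraction and absolute alt-read thresholds.  Hotspot names (L702H / H875Y /
T878A analogs) are attached by (position, alt) lookup against the panel's
hotspot table — amino-acid naming is configuration, not codon translation.
Only substitutions are considered; the simulators emit no indels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import seq_codes
from .gene_model import HotspotDef, Interval, PanelConfig
from .rearrangements import ContigAlignment

BASES = "ACGT"

DEFAULT_MIN_DEPTH = 50
DEFAULT_MIN_VAF = 0.05
DEFAULT_MIN_ALT_READS = 5


@dataclass(frozen=True)
class PileupColumn:
    chrom: str
    position: int
    depth: int
    allele_counts: dict[str, int]


def pileup(
    alignments: list[ContigAlignment],
    targets: list[Interval],
) -> list[PileupColumn]:
    """Per-position base counts over the target intervals.

    ``alignments`` carry the read sequence already in reference orientation;
    ambiguous bases are excluded from allele counts but still add depth.
    """
    by_chrom: dict[str, list[ContigAlignment]] = {}
    for aln in alignments:
        by_chrom.setdefault(aln.chrom, []).append(aln)

    columns: list[PileupColumn] = []
    chrom_targets: dict[str, list[Interval]] = {}
    for t in targets:
        chrom_targets.setdefault(t.chrom, []).append(t)

    for chrom, tlist in chrom_targets.items():
        span = max(t.end for t in tlist)
        counts = np.zeros((span, 4), dtype=np.int64)
        depth = np.zeros(span, dtype=np.int64)
        for aln in by_chrom.get(chrom, []):
            codes = seq_codes(aln.oriented_seq)
            lo = max(aln.start, 0)
            hi = min(aln.end, span)
            if hi <= lo:
                continue
            codes = codes[lo - aln.start : hi - aln.start]
            pos = np.arange(lo, hi)
            depth[pos] += 1
            valid = codes >= 0
            np.add.at(counts, (pos[valid], codes[valid]), 1)
        for t in tlist:
            for p in range(t.start, t.end):
                columns.append(
                    PileupColumn(
                        chrom=chrom,
                        position=p,
                        depth=int(depth[p]),
                        allele_counts={
                            b: int(counts[p, i]) for i, b in enumerate(BASES)
                        },
                    )
                )
    return columns


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    position: int
    ref: str
    alt: str
    vaf: float
    depth: int
    alt_reads: int
    hotspot_name: str | None = None


def call_variants(
    columns: list[PileupColumn],
    ref_seqs: dict[str, str],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_vaf: float = DEFAULT_MIN_VAF,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
    hotspots: list[HotspotDef] = (),
) -> list[VariantCall]:
    """Threshold-based substitution calls with hotspot annotation."""
    hotspot_by_key = {(h.chrom, h.position, h.alt): h.name for h in hotspots}
    calls: list[VariantCall] = []
    for col in columns:
        if col.depth < min_depth:
            continue
        ref = ref_seqs[col.chrom][col.position]
        alts = [(n, b) for b, n in col.allele_counts.items() if b != ref]
        n_alt, alt = max(alts)
        if n_alt < min_alt_reads:
            continue
        vaf = n_alt / col.depth
        if vaf < min_vaf:
            continue
        calls.append(
            VariantCall(
                chrom=col.chrom,
                position=col.position,
                ref=ref,
                alt=alt,
                vaf=vaf,
                depth=col.depth,
                alt_reads=n_alt,
                hotspot_name=hotspot_by_key.get((col.chrom, col.position, alt)),
            )
        )
    return calls


def call_sample_variants(
    alignments: list[ContigAlignment],
    panel: PanelConfig,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_vaf: float = DEFAULT_MIN_VAF,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> list[VariantCall]:
    columns = pileup(alignments, panel.dna_targets + panel.control_targets)
    return call_variants(
        columns,
        panel.sequences(),
        min_depth=min_depth,
        min_vaf=min_vaf,
        min_alt_reads=min_alt_reads,
        hotspots=panel.hotspots,
    )


def write_vcf(calls: list[VariantCall], panel: PanelConfig, path) -> None:
    """Minimal VCF output (1-based positions, DP/AF and hotspot ID)."""
    import pysam

    header = pysam.VariantHeader()
    for name, seq in panel.sequences().items():
        header.contigs.add(name, length=len(seq))
    header.info.add("DP", 1, "Integer", "Read depth at the site")
    header.info.add("AF", 1, "Float", "Variant allele fraction")
    header.info.add("HOTSPOT", 1, "String", "Named hotspot mutation")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.chrom, c.position)):
            rec = vcf.new_record(
                contig=call.chrom,
                start=call.position,
                stop=call.position + 1,
                alleles=(call.ref, call.alt),
            )
            rec.info["DP"] = call.depth
            rec.info["AF"] = round(call.vaf, 6)
            if call.hotspot_name:
                rec.info["HOTSPOT"] = call.hotspot_name
            vcf.write(rec)
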