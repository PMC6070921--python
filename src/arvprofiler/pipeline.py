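"""Per-sample and per-cohort orchestration of the analysis stages.

RNA reads go through junction counting and fraction quantification; DNA
reads are mapped once, with the contiguous alignments shared between the
copy-number, rearrangement and pileup variant-calling stages; expression
counts are scored cohort-wide; everything is assembled into the cohort
table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import CopyNumberCall, call_copy_number
from .cohort import CohortResult, SampleSummary, build_cohort_table
from .expression import score_matrix
from .gene_model import PanelConfig
from .junctions import (
    JunctionCounts,
    SignatureMatcher,
    VariantFraction,
    build_signatures,
    canonical_junction_count,
    count_junctions,
    quantify_fractions,
    total_arv_fraction,
)
from .readio import Read, read_fastq
from .rearrangements import (
    BreakpointEvent,
    GenomeIndex,
    RearrangementResult,
    call_rearrangements,
)
from .variants import VariantCall, call_sample_variants

DEFAULT_ARFL_UPSTREAM = "E3"


@dataclass
class RnaAnalysis:
    counts: JunctionCounts
    fractions: list[VariantFraction]
    total_arv: float | None
    ar_fl_count: int


@dataclass
class DnaAnalysis:
    rearrangements: RearrangementResult
    cn: CopyNumberCall
    variant_calls: list[VariantCall]

    @property
    def events(self) -> list[BreakpointEvent]:
        return self.rearrangements.events


def analyze_rna(
    reads: list[Read] | list[str],
    panel: PanelConfig,
    matcher: SignatureMatcher | None = None,
    ar_fl_upstream: str = DEFAULT_ARFL_UPSTREAM,
) -> RnaAnalysis:
    if matcher is None:
        matcher = SignatureMatcher(build_signatures(panel))
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    counts = count_junctions(seqs, matcher)
    fractions = quantify_fractions(counts, panel)
    return RnaAnalysis(
        counts=counts,
        fractions=fractions,
        total_arv=total_arv_fraction(fractions),
        ar_fl_count=canonical_junction_count(counts, panel, ar_fl_upstream),
    )


def analyze_dna(
    reads: list[Read],
    panel: PanelConfig,
    index: GenomeIndex | None = None,
    min_support: int = 10,
) -> DnaAnalysis:
    if index is None:
        index = GenomeIndex.from_panel(panel)
    rr = call_rearrangements(reads, index, min_support=min_support)
    positions: dict[str, np.ndarray] = {}
    for chrom in {c.chrom for c in rr.contigs}:
        positions[chrom] = np.array(
            [c.start for c in rr.contigs if c.chrom == chrom]
        )
    cn = call_copy_number(positions, panel)
    calls = call_sample_variants(rr.contigs, panel)
    return DnaAnalysis(rearrangements=rr, cn=cn, variant_calls=calls)


def analyze_cohort(
    panel: PanelConfig,
    samples,
    include_dna: bool = True,
    ar_fl_upstream: str = DEFAULT_ARFL_UPSTREAM,
) -> CohortResult:
    """Analyse simulated samples in memory (see synthetic.simulate_cohort)."""
    matcher = SignatureMatcher(build_signatures(panel))
    index = GenomeIndex.from_panel(panel) if include_dna else None
    samples = list(samples)

    counts = pd.DataFrame.from_dict(
        {s.sample_id: s.expression_counts for s in samples}, orient="index"
    )
    scores = score_matrix(counts, panel)

    summaries = []
    for s in samples:
        rna = analyze_rna(s.rna_reads, panel, matcher, ar_fl_upstream)
        summary = SampleSummary(
            sample_id=s.sample_id,
            group=s.group,
            signalling_score=float(scores[s.sample_id]),
            arv_fractions=rna.fractions,
            ar_fl_count=rna.ar_fl_count,
        )
        if include_dna and s.dna_reads is not None:
            dna = analyze_dna(s.dna_reads, panel, index)
            summary.mutations = dna.variant_calls
            summary.cn = dna.cn
            summary.gsr_events = dna.events
        summaries.append(summary)
    return build_cohort_table(summaries)


def analyze_cohort_dir(
    panel: PanelConfig,
    cohort_dir: str | Path,
    include_dna: bool = True,
    ar_fl_upstream: str = DEFAULT_ARFL_UPSTREAM,
) -> CohortResult:
    """Analyse a cohort laid out on disk by synthetic.generate_cohort."""
    cohort_dir = Path(cohort_dir)
    truth = pd.read_csv(cohort_dir / "truth.tsv", sep="\t")
    counts = pd.read_csv(cohort_dir / "expression_counts.tsv", sep="\t",
                         index_col="sample")
    scores = score_matrix(counts, panel)
    matcher = SignatureMatcher(build_signatures(panel))
    index = GenomeIndex.from_panel(panel) if include_dna else None

    summaries = []
    for _, row in truth.iterrows():
        sample_id, group = str(row["sample"]), str(row["group"])
        sdir = cohort_dir / sample_id
        rna = analyze_rna(read_fastq(sdir / "rna.fastq"), panel, matcher,
                          ar_fl_upstream)
        summary = SampleSummary(
            sample_id=sample_id,
            group=group,
            signalling_score=float(scores[sample_id]),
            arv_fractions=rna.fractions,
            ar_fl_count=rna.ar_fl_count,
        )
        fq1, fq2 = sdir / "dna_1.fastq", sdir / "dna_2.fastq"
        if include_dna and fq1.exists():
            reads = read_fastq(fq1) + (read_fastq(fq2) if fq2.exists() else [])
            dna = analyze_dna(reads, panel, index)
            summary.mutations = dna.variant_calls
            summary.cn = dna.cn
            summary.gsr_events = dna.events
        summaries.append(summary)
    return build_cohort_table(summaries)
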