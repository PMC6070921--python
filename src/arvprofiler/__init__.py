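"""Targeted androgen-receptor profiling: splice-variant fractions from
junction signatures, window-coverage copy number, split-read rearrangements,
hotspot mutations, AR-signalling scores and cohort statistics — with a
synthetic-data generator providing ground truth for every stage."""

from importlib import resources

from .cnv import (
    CopyNumberCall,
    CoverageWindow,
    call_copy_number,
    classify_cn,
    normalize_and_estimate,
    window_counts,
)
from .cohort import (
    GroupComparison,
    SampleSummary,
    build_cohort_table,
    mann_whitney_u,
    spearman,
)
from .expression import classify_arv_level, normalize_counts, signalling_score
from .gene_model import (
    Exon,
    HotspotDef,
    Interval,
    JunctionDef,
    PanelConfig,
    PanelConfigError,
    junctions_by_upstream,
    load_panel,
    save_panel,
)
from .junctions import (
    JunctionCounts,
    Signature,
    SignatureMatcher,
    VariantFraction,
    assign_read,
    build_signatures,
    clopper_pearson_lower,
    count_junctions,
    quantify_fractions,
    total_arv_fraction,
)
from .pipeline import analyze_cohort, analyze_cohort_dir, analyze_dna, analyze_rna
from .readio import Read, read_fastq, write_fastq
from .rearrangements import (
    BreakpointEvent,
    GenomeIndex,
    SplitAlignment,
    call_rearrangements,
    classify_event,
    cluster_events,
    split_align,
)
from .synthetic import (
    CohortSpec,
    DnaTruth,
    GroupSpec,
    GsrEvent,
    RnaTruth,
    generate_cohort,
    mock_panel,
    simulate_cohort,
    simulate_dna_reads,
    simulate_rna_reads,
)
from .variants import PileupColumn, VariantCall, call_variants, pileup

__version__ = "0.1.0"


def example_panel() -> PanelConfig:
    """The packaged synthetic AR-like panel fixture (same catalog as
    :func:`arvprofiler.synthetic.mock_panel`, loaded from YAML)."""
    ref = resources.files("arvprofiler").joinpath("data/mock_ar_panel.yaml")
    with resources.as_file(ref) as path:
        return load_panel(path)
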