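"""Synthetic targeted-sequencing data with known truth.

This module generates the inputs every downstream stage is tested against:

* a deterministic mock AR-like panel (:func:`mock_panel`) with 8 canonical
  exons, 5 cryptic exons, an AR-FL junction chain plus six named splice
  variants, two autosomal control loci, capture targets and three hotspot
  positions (L702H/H875Y/T878A analogs);
* RNA reads drawn from isoform transcript sequences at controlled mixture
  fractions (:func:`simulate_rna_reads`);
* paired DNA reads with coverage proportional to copy number, engineered
  breakpoints at controlled variant allele fractions and hotspot mutations
  (:func:`simulate_dna_reads`);
* whole cohorts with a per-sample truth table (:func:`generate_cohort`).

The error model is substitution-only; fragment sizes are truncated-normal
(default 180 +/- 30 bp) in forward-reverse orientation; RNA reads are
single-end 150 bp in transcript orientation (the assay is strand-specific),
DNA reads are 150 bp paired-end.  Coverage is uniform within targets; no
PCR-duplicate, GC or capture-efficiency structure is modelled.  All
randomness flows from one master seed; per-sample seeds are derived by
stable hashing of (master seed, sample id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import apply_errors, revcomp, sample_rng
from .gene_model import (
    Exon,
    HotspotDef,
    Interval,
    JunctionDef,
    PanelConfig,
    RnaGene,
    junctions_by_upstream,
)
from .readio import Read, write_fastq


class ParameterError(ValueError):
    """Raised when a truth specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# Mock panel
# ---------------------------------------------------------------------------

_MOCK_SEED = 902137
_EXON_LEN = 160

# Exon composition of the named variants is configuration data, not code.
# The exact cryptic-exon pairing of each AR-V is not fully standardised; this
# catalog is a synthetic stand-in with one defensible assignment (AR-V7 joins
# E3 to CE3, AR-V9 joins E3 to CE5, AR-V3 joins E2 to CE4, ...).
_VARIANT_JUNCTIONS = [
    ("AR-V3", "E2", "CE4"),
    ("AR-V4", "E3", "CE4"),
    ("AR-V5", "E3", "CE2"),
    ("AR-V6", "E3", "CE1"),
    ("AR-V7", "E3", "CE3"),
    ("AR-V9", "E3", "CE5"),
]

AR_REGULATED_GENES = ("KLK3", "FKBP5", "TMPRSS2", "ACPP", "SLC45A3")
HOUSEKEEPING_GENES = ("TBP", "STARD7", "DDX1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=[0.27, 0.23, 0.23, 0.27]))


def mock_panel() -> PanelConfig:
    """Deterministic synthetic AR-like panel used throughout the test suite.

    Canonical exons E1..E8 (160 bp each) with the five cryptic exons CE1..CE5
    placed in the intron between E3 and E4; ~3.5 kb locus.  Control loci
    stand in for the autosomal control genes captured by the DNA assay.
    """
    rng = np.random.default_rng(_MOCK_SEED)

    layout: list[tuple[str, int]] = []
    pos = 150
    for name in ["E1", "E2", "E3"]:
        layout.append((name, pos))
        pos += _EXON_LEN + 110
    pos -= 30  # slightly tighter spacing ahead of the cryptic cluster
    for name in ["CE1", "CE2", "CE3", "CE4", "CE5"]:
        layout.append((name, pos))
        pos += _EXON_LEN + 80
    pos += 30
    for name in ["E4", "E5", "E6", "E7", "E8"]:
        layout.append((name, pos))
        pos += _EXON_LEN + 110
    locus_len = pos + 40
    locus_seq = _random_seq(rng, locus_len)

    exons = [
        Exon(name, start, start + _EXON_LEN, locus_seq[start : start + _EXON_LEN])
        for name, start in layout
    ]
    junctions = [
        JunctionDef("AR-FL", f"E{i}", f"E{i + 1}") for i in range(1, 8)
    ] + [JunctionDef(v, u, d) for v, u, d in _VARIANT_JUNCTIONS]

    control_loci = {
        "CTRL_FOXA1": _random_seq(rng, 1800),
        "CTRL_SPOP": _random_seq(rng, 1000),
    }

    exon_by = {name: start for name, start in layout}
    hotspot_specs = [
        ("L702H", exon_by["E4"] + 60),
        ("H875Y", exon_by["E8"] + 45),
        ("T878A", exon_by["E8"] + 54),
    ]
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    hotspots = [
        HotspotDef(name, "AR_mock", p, locus_seq[p], transition[locus_seq[p]])
        for name, p in hotspot_specs
    ]

    panel = PanelConfig(
        locus_name="AR_mock",
        locus_sequence=locus_seq,
        exons=exons,
        junctions=junctions,
        dna_targets=[
            Interval("AR_mock", 0, 1200),
            Interval("AR_mock", 1200, 2400),
            Interval("AR_mock", 2400, locus_len),
        ],
        control_targets=[
            Interval("CTRL_FOXA1", 100, 1700),
            Interval("CTRL_SPOP", 100, 900),
        ],
        rna_genes=[RnaGene(g, "ar_regulated") for g in AR_REGULATED_GENES]
        + [RnaGene(g, "housekeeping") for g in HOUSEKEEPING_GENES],
        hotspots=hotspots,
        control_loci=control_loci,
    )
    return panel.validate()


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------


def canonical_chain(panel: PanelConfig) -> list[str]:
    """Ordered canonical exon ids, reconstructed from the AR-FL junctions."""
    nxt = {j.upstream: j.downstream for j in panel.canonical_junctions()}
    starts = set(nxt) - set(nxt.values())
    if len(starts) != 1:
        raise ParameterError("canonical junctions do not form a single chain")
    chain = [starts.pop()]
    while chain[-1] in nxt:
        chain.append(nxt[chain[-1]])
    return chain


def transcript_exons(panel: PanelConfig, isoform: str) -> list[str]:
    chain = canonical_chain(panel)
    if isoform == panel.canonical_name:
        return chain
    junction = panel.junction_for_variant(isoform)
    idx = chain.index(junction.upstream)
    return chain[: idx + 1] + [junction.downstream]


def transcript_sequence(
    panel: PanelConfig, isoform: str
) -> tuple[str, list[tuple[JunctionDef, int]]]:
    """Spliced transcript sequence and the positions of its junctions."""
    exon_ids = transcript_exons(panel, isoform)
    by_key = {j.key: j for j in panel.junctions}
    seq_parts = []
    boundaries: list[tuple[JunctionDef, int]] = []
    pos = 0
    for i, exon_id in enumerate(exon_ids):
        exon = panel.exon_by_id(exon_id)
        seq_parts.append(exon.sequence)
        pos += len(exon.sequence)
        if i + 1 < len(exon_ids):
            key = (exon_id, exon_ids[i + 1])
            if key not in by_key:
                raise ParameterError(f"no catalogued junction for {key}")
            boundaries.append((by_key[key], pos))
    return "".join(seq_parts), boundaries


def isoform_mixture(panel: PanelConfig, fractions: dict[str, float]) -> dict[str, float]:
    """Isoform mixture weights realising the requested per-variant fractions.

    Fractions are defined within upstream-exon junction groups (the measured
    quantity), so the underlying transcript mixture has to account for the
    fact that a variant branching at a late exon also contributes reads to
    every earlier junction group.  Solved in closed form by a backward pass
    over the groups along the canonical chain.
    """
    chain = canonical_chain(panel)
    order = {e: i for i, e in enumerate(chain)}
    groups: dict[str, list[tuple[str, float]]] = {}
    for name, f in fractions.items():
        if not (0.0 <= f <= 1.0):
            raise ParameterError(f"fraction for {name} outside [0, 1]")
        junction = panel.junction_for_variant(name)
        groups.setdefault(junction.upstream, []).append((name, f))
    for up, members in groups.items():
        if sum(f for _, f in members) > 1.0 + 1e-12:
            raise ParameterError(
                f"fractions of variants sharing upstream exon {up} exceed 1"
            )
    if not groups:
        return {panel.canonical_name: 1.0}

    sorted_groups = sorted(groups.items(), key=lambda kv: order[kv[0]])
    masses: dict[str, float] = {}
    # deepest group first
    up, members = sorted_groups[-1]
    F = sum(f for _, f in members)
    if F >= 1.0 - 1e-12:
        m_fl, T = 0.0, 1.0
    else:
        m_fl, T = 1.0, 1.0 / (1.0 - F)
    for name, f in members:
        masses[name] = f * T
    for up, members in reversed(sorted_groups[:-1]):
        F = sum(f for _, f in members)
        if F >= 1.0 - 1e-12:
            raise ParameterError(
                f"fraction mass 1 at exon {up} leaves no transcripts for "
                f"junctions further downstream"
            )
        T = T / (1.0 - F)
        for name, f in members:
            masses[name] = f * T
    total = m_fl + sum(masses.values())
    weights = {name: m / total for name, m in masses.items()}
    weights[panel.canonical_name] = m_fl / total
    return weights


# ---------------------------------------------------------------------------
# RNA simulation
# ---------------------------------------------------------------------------


@dataclass
class RnaTruth:
    """Ground-truth parameters for one RNA read set.

    ``depth`` is the expected number of reads overlapping any given splice
    junction by at least one base; ``isoform_fractions`` are within
    upstream-exon-group transcript fractions (the remainder of each group is
    full-length AR).
    """

    isoform_fractions: dict[str, float] = field(default_factory=dict)
    depth: float = 500.0
    read_length: int = 150
    error_rate: float = 0.002
    seed: int = 0

    def validate(self, panel: PanelConfig) -> None:
        if self.depth <= 0:
            raise ParameterError("depth must be positive")
        if not (0.0 <= self.error_rate < 0.1):
            raise ParameterError("error_rate must be in [0, 0.1)")
        for name in self.isoform_fractions:
            panel.junction_for_variant(name)  # raises if unknown
        isoform_mixture(panel, self.isoform_fractions)  # raises if mass > 1


@dataclass
class RnaTruthRecord:
    """Exact bookkeeping of a realised RNA read set."""

    weights: dict[str, float]
    n_reads: dict[str, int]
    junction_spanning: dict[JunctionDef, int]
    min_overhang: int

    @property
    def n_total(self) -> int:
        return sum(self.n_reads.values())

    def group_denominator(self, panel: PanelConfig, upstream: str) -> int:
        groups = junctions_by_upstream(panel)
        return sum(self.junction_spanning.get(j, 0) for j in groups[upstream])

    def realized_fraction(self, panel: PanelConfig, variant: str) -> float | None:
        junction = panel.junction_for_variant(variant)
        denom = self.group_denominator(panel, junction.upstream)
        if denom == 0:
            return None
        return self.junction_spanning.get(junction, 0) / denom


def simulate_rna_reads(
    panel: PanelConfig,
    truth: RnaTruth,
    sample_id: str = "rna",
    truth_min_overhang: int = 10,
) -> tuple[list[Read], RnaTruthRecord]:
    """Draw single-end RNA reads from the isoform mixture.

    Read starts are uniform over each transcript; per-base substitution
    errors are independent; read ids encode the isoform of origin and the
    transcript start.  The truth record stores the exact number of realised
    reads spanning each junction with >= ``truth_min_overhang`` bases on both
    sides (the same overhang rule the quantifier applies).
    """
    truth.validate(panel)
    R = truth.read_length
    rng = np.random.default_rng(truth.seed)
    weights = isoform_mixture(panel, truth.isoform_fractions)

    isoforms = [name for name, w in weights.items() if w > 0.0]
    transcripts = {name: transcript_sequence(panel, name) for name in isoforms}
    for name in isoforms:
        if len(transcripts[name][0]) < R:
            raise ParameterError(f"transcript of {name} shorter than read length")

    expected = np.array(
        [
            weights[name] * truth.depth * (len(transcripts[name][0]) - R + 1) / (R - 1)
            for name in isoforms
        ]
    )
    n_total = rng.poisson(expected.sum())
    n_per = rng.multinomial(n_total, expected / expected.sum()) if n_total else np.zeros(
        len(isoforms), dtype=int
    )

    reads: list[Read] = []
    n_reads: dict[str, int] = {}
    junction_spanning: dict[JunctionDef, int] = {}
    for name, n in zip(isoforms, n_per):
        seq, boundaries = transcripts[name]
        n = int(n)
        n_reads[name] = n
        if n == 0:
            continue
        starts = rng.integers(0, len(seq) - R + 1, size=n)
        for junction, pos in boundaries:
            lo, hi = pos - R + truth_min_overhang, pos - truth_min_overhang
            count = int(np.count_nonzero((starts >= lo) & (starts <= hi)))
            junction_spanning[junction] = junction_spanning.get(junction, 0) + count
        raw = [seq[s : s + R] for s in starts]
        seqs = apply_errors(raw, truth.error_rate, rng)
        for k, (s, rs) in enumerate(zip(starts, seqs)):
            reads.append(Read(f"{sample_id}|{name}|{k}|{s}", rs))

    record = RnaTruthRecord(
        weights=weights,
        n_reads=n_reads,
        junction_spanning=junction_spanning,
        min_overhang=truth_min_overhang,
    )
    return reads, record


# ---------------------------------------------------------------------------
# DNA simulation
# ---------------------------------------------------------------------------

GSR_TYPES = ("deletion", "duplication", "inversion", "translocation")


@dataclass(frozen=True)
class GsrEvent:
    """An engineered structural rearrangement with one breakpoint pair.

    ``breakpoint_a`` is on the panel locus; ``breakpoint_b`` is on the locus
    too except for translocations, where it lies on ``partner_chrom``.
    """

    breakpoint_a: int
    breakpoint_b: int
    type: str
    vaf: float
    partner_chrom: str | None = None


@dataclass
class DnaTruth:
    """Ground-truth parameters for one paired-end DNA read set.

    ``depth`` is the expected read-base coverage of a two-copy region; a
    region at copy number c is covered at depth * c / 2, so an unaltered
    X-linked locus in a male genome (one copy) sits at half the control
    coverage.
    """

    ar_copy_number: float = 1.0
    control_copy_number: float = 2.0
    gsr_events: list[GsrEvent] = field(default_factory=list)
    hotspot_vafs: dict[str, float] = field(default_factory=dict)
    fragment_size_mean: float = 180.0
    fragment_size_sd: float = 30.0
    depth: float = 200.0
    read_length: int = 150
    error_rate: float = 0.002
    seed: int = 0

    def validate(self, panel: PanelConfig) -> None:
        if self.ar_copy_number <= 0 or self.control_copy_number <= 0:
            raise ParameterError("copy numbers must be positive")
        if self.depth <= 0:
            raise ParameterError("depth must be positive")
        L = len(panel.locus_sequence)
        for ev in self.gsr_events:
            if ev.type not in GSR_TYPES:
                raise ParameterError(f"unknown rearrangement type {ev.type!r}")
            if not (0.0 <= ev.vaf <= 1.0):
                raise ParameterError("event vaf outside [0, 1]")
            if not (0 < ev.breakpoint_a < L):
                raise ParameterError(
                    f"breakpoint {ev.breakpoint_a} outside locus [0, {L})"
                )
            if ev.type == "translocation":
                partner = ev.partner_chrom
                if partner is None or partner not in panel.control_loci:
                    raise ParameterError("translocation requires a partner locus")
                if not (0 < ev.breakpoint_b < len(panel.control_loci[partner])):
                    raise ParameterError("partner breakpoint outside locus")
            else:
                if not (0 < ev.breakpoint_b < L):
                    raise ParameterError(
                        f"breakpoint {ev.breakpoint_b} outside locus [0, {L})"
                    )
                if ev.breakpoint_a >= ev.breakpoint_b:
                    raise ParameterError("breakpoint_a must precede breakpoint_b")
        for name, vaf in self.hotspot_vafs.items():
            panel.hotspot_by_name(name)
            if not (0.0 <= vaf <= 1.0):
                raise ParameterError("hotspot vaf outside [0, 1]")


def derived_allele(panel: PanelConfig, event: GsrEvent) -> tuple[str, int]:
    """Rearranged allele sequence and the junction position within it."""
    L = panel.locus_sequence
    a, b = event.breakpoint_a, event.breakpoint_b
    if event.type == "deletion":
        return L[:a] + L[b:], a
    if event.type == "duplication":
        return L[:b] + L[a:], b
    if event.type == "inversion":
        return L[:a] + revcomp(L[a:b]) + L[b:], a
    if event.type == "translocation":
        partner = panel.control_loci[event.partner_chrom]
        return L[:a] + partner[b:], a
    raise ParameterError(f"unknown rearrangement type {event.type!r}")


def expected_breakends(event: GsrEvent, locus_name: str) -> tuple:
    """Canonical (chrom_a, bp_a, orient_a, chrom_b, bp_b, orient_b) tuple the
    split-read caller is expected to report for this event."""
    a, b = event.breakpoint_a, event.breakpoint_b
    if event.type == "deletion":
        return (locus_name, a, "+", locus_name, b, "+")
    if event.type == "duplication":
        return (locus_name, b, "+", locus_name, a, "+")
    if event.type == "inversion":
        return (locus_name, a, "+", locus_name, b, "-")
    if event.type == "translocation":
        return (locus_name, a, "+", event.partner_chrom, b, "+")
    raise ParameterError(event.type)


@dataclass
class EventTruth:
    event: GsrEvent
    n_junction_fragments: int = 0
    n_overlapping_fragments: int = 0  # all fragments overlapping breakpoint A
    n_split_reads: int = 0  # reads crossing with >= min_segment on both sides
    n_reference_spanning_reads: int = 0


@dataclass
class HotspotTruth:
    n_alt_fragments: int = 0
    n_fragments: int = 0
    n_alt_reads: int = 0
    n_reads: int = 0


@dataclass
class DnaTruthRecord:
    """Bookkeeping of a realised DNA read set.

    ``read_positions`` holds the reference start of every read originating
    from an unrearranged allele (rearranged-allele reads are excluded; at the
    low variant fractions simulated they perturb window counts negligibly).
    """

    n_fragments: dict[str, int]
    read_positions: dict[str, np.ndarray]
    events: list[EventTruth]
    hotspots: dict[str, HotspotTruth]
    min_segment: int


def simulate_dna_reads(
    panel: PanelConfig,
    truth: DnaTruth,
    sample_id: str = "dna",
    truth_min_segment: int = 25,
) -> tuple[list[Read], DnaTruthRecord]:
    """Draw paired-end DNA reads over the panel loci.

    Fragment counts per locus are proportional to copy number; for each
    rearrangement, fragments overlapping breakpoint_a derive from the
    rearranged allele with probability vaf; hotspot alternate alleles are
    emitted at their stated vaf.  Mates are forward-reverse with
    truncated-normal fragment sizes.
    """
    truth.validate(panel)
    R = truth.read_length
    rng = np.random.default_rng(truth.seed)
    seqs = panel.sequences()
    copy = {panel.locus_name: truth.ar_copy_number}
    for name in panel.control_loci:
        copy[name] = truth.control_copy_number

    reads: list[Read] = []
    n_fragments: dict[str, int] = {}
    read_positions: dict[str, list[np.ndarray]] = {c: [] for c in seqs}
    event_truths = [EventTruth(ev) for ev in truth.gsr_events]
    hotspot_truths = {name: HotspotTruth() for name in truth.hotspot_vafs}
    derived = [derived_allele(panel, ev) for ev in truth.gsr_events]

    for chrom, ref in seqs.items():
        L = len(ref)
        # expected count scales with the number of valid fragment positions,
        # not the raw locus length: this keeps the interior start density
        # (and hence the coverage ratio between loci of different sizes)
        # exactly proportional to copy number
        n_positions = max(L - truth.fragment_size_mean, 1.0)
        n_frag = rng.poisson(
            truth.depth * (copy[chrom] / 2.0) * n_positions / (2.0 * R)
        )
        n_fragments[chrom] = int(n_frag)
        if n_frag == 0:
            continue
        flens = np.rint(
            rng.normal(truth.fragment_size_mean, truth.fragment_size_sd, n_frag)
        ).astype(int)
        flens = np.clip(flens, 50, L)
        starts = rng.integers(0, L - flens + 1)

        origin = np.full(n_frag, -1, dtype=int)  # -1 = unrearranged allele
        if chrom == panel.locus_name:
            for ei, ev in enumerate(truth.gsr_events):
                bp = ev.breakpoint_a
                overlaps = (starts < bp) & (starts + flens > bp) & (origin == -1)
                idx = np.flatnonzero(overlaps)
                event_truths[ei].n_overlapping_fragments += int(idx.size)
                if idx.size == 0:
                    continue
                flagged = idx[rng.random(idx.size) < ev.vaf]
                origin[flagged] = ei
                event_truths[ei].n_junction_fragments += int(flagged.size)

        # hotspot substitutions on unrearranged fragments
        hotspot_sub: dict[int, list[tuple[int, str]]] = {}
        if chrom == panel.locus_name:
            for name, vaf in truth.hotspot_vafs.items():
                h = panel.hotspot_by_name(name)
                covers = (
                    (starts <= h.position)
                    & (starts + flens > h.position)
                    & (origin == -1)
                )
                idx = np.flatnonzero(covers)
                ht = hotspot_truths[name]
                ht.n_fragments += int(idx.size)
                alt_idx = idx[rng.random(idx.size) < vaf]
                ht.n_alt_fragments += int(alt_idx.size)
                alt_set = set(alt_idx.tolist())
                for i in idx:
                    off = h.position - int(starts[i])
                    flen = int(flens[i])
                    n_cov = int(off < R) + int(off >= flen - R)
                    ht.n_reads += n_cov
                    if int(i) in alt_set:
                        ht.n_alt_reads += n_cov
                        hotspot_sub.setdefault(int(i), []).append((off, h.alt))

        mseg = truth_min_segment
        raw_seqs: list[str] = []
        r1_pos = np.empty(n_frag, dtype=int)
        r2_pos = np.empty(n_frag, dtype=int)
        keep_pos = np.ones(n_frag, dtype=bool)
        for i in range(n_frag):
            x, flen, org = int(starts[i]), int(flens[i]), int(origin[i])
            if org == -1:
                frag = ref[x : x + flen]
                subs = hotspot_sub.get(i)
                if subs:
                    chars = list(frag)
                    for off, alt in subs:
                        chars[off] = alt
                    frag = "".join(chars)
            else:
                ev = truth.gsr_events[org]
                dseq, j = derived[org]
                delta = ev.breakpoint_a - x
                dstart = min(max(j - delta, 0), len(dseq) - flen)
                frag = dseq[dstart : dstart + flen]
                keep_pos[i] = False
                # reads crossing the junction with >= mseg on both sides
                joff = j - dstart
                for lo in (0, flen - R):  # R1 and R2 windows in fragment coords
                    lo = max(lo, 0)
                    win_len = min(R, flen)
                    rel = joff - lo
                    if mseg <= rel <= win_len - mseg:
                        event_truths[org].n_split_reads += 1
            raw_seqs.append(frag)
            r1_pos[i] = x
            r2_pos[i] = x + max(flen - R, 0)

        if chrom == panel.locus_name:
            for et in event_truths:
                bp = et.event.breakpoint_a
                norm = origin == -1
                span1 = norm & (starts <= bp - mseg) & (starts + np.minimum(flens, R) >= bp + mseg)
                s2 = starts + np.maximum(flens - R, 0)
                span2 = norm & (s2 <= bp - mseg) & (starts + flens >= bp + mseg)
                et.n_reference_spanning_reads += int(span1.sum()) + int(span2.sum())

        read_positions[chrom].append(r1_pos[keep_pos])
        read_positions[chrom].append(r2_pos[keep_pos])

        r1 = [s[:R] for s in raw_seqs]
        r2 = [revcomp(s[-R:]) if len(s) > R else revcomp(s) for s in raw_seqs]
        r1 = apply_errors(r1, truth.error_rate, rng)
        r2 = apply_errors(r2, truth.error_rate, rng)
        for i in range(n_frag):
            tag = "ref" if origin[i] == -1 else f"gsr{origin[i]}"
            stem = f"{sample_id}|{chrom}|{i}|{int(starts[i])}|{tag}"
            reads.append(Read(stem + "/1", r1[i]))
            reads.append(Read(stem + "/2", r2[i]))

    record = DnaTruthRecord(
        n_fragments=n_fragments,
        read_positions={
            c: np.sort(np.concatenate(p)) if p else np.empty(0, dtype=int)
            for c, p in read_positions.items()
        },
        events=event_truths,
        hotspots=hotspot_truths,
        min_segment=truth_min_segment,
    )
    return reads, record


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

DEFAULT_EXPRESSION_MEANS = {
    "KLK3": 3000.0,
    "FKBP5": 1200.0,
    "TMPRSS2": 1500.0,
    "ACPP": 900.0,
    "SLC45A3": 700.0,
    "TBP": 800.0,
    "STARD7": 600.0,
    "DDX1": 700.0,
}


def simulate_expression_counts(
    panel: PanelConfig,
    means: dict[str, float],
    dispersion: float,
    depth_factor: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Negative-binomial gene counts around the group means (Poisson when
    dispersion is 0); ``depth_factor`` scales all genes (library size)."""
    out = {}
    for gene in [g.id for g in panel.rna_genes]:
        mu = means[gene] * depth_factor
        if dispersion <= 0:
            out[gene] = int(rng.poisson(mu))
        else:
            r = 1.0 / dispersion
            out[gene] = int(rng.negative_binomial(r, r / (r + mu)))
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """Distribution over per-sample truth parameters for one sample group."""

    name: str
    n_samples: int
    arv_fraction_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    ar_abundance_range: tuple[float, float] = (1.0, 1.0)
    couple_arv_to_abundance: bool = False
    rna_depth: float = 400.0
    dna_depth: float = 150.0
    copy_number_choices: tuple[float, ...] = (1.0,)
    copy_number_weights: tuple[float, ...] | None = None
    hotspot_prob: float = 0.0
    hotspot_vaf_range: tuple[float, float] = (0.1, 0.5)
    gsr_prob: float = 0.0
    gsr_vaf_range: tuple[float, float] = (0.026, 0.109)
    expression_means: dict[str, float] | None = None
    expression_dispersion: float = 0.15

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ParameterError(f"group {self.name}: n_samples must be >= 1")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    seed: int = 0
    read_length: int = 150
    error_rate: float = 0.002
    fragment_size_mean: float = 180.0
    fragment_size_sd: float = 30.0

    def validate(self) -> None:
        for g in self.groups:
            g.validate()


@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    rna_truth: RnaTruth
    rna_reads: list[Read]
    rna_record: RnaTruthRecord
    dna_truth: DnaTruth
    dna_reads: list[Read] | None
    dna_record: DnaTruthRecord | None
    expression_counts: dict[str, int]
    ar_abundance: float


def _random_event(panel: PanelConfig, rng: np.random.Generator, vaf: float) -> GsrEvent:
    L = len(panel.locus_sequence)
    etype = GSR_TYPES[rng.integers(len(GSR_TYPES))]
    a = int(rng.integers(300, L - 650))
    if etype == "translocation":
        partner = sorted(panel.control_loci)[0]
        b = int(rng.integers(300, len(panel.control_loci[partner]) - 300))
        return GsrEvent(a, b, etype, vaf, partner)
    b = int(rng.integers(a + 300, L - 300))
    return GsrEvent(a, b, etype, vaf)


def _draw_sample_truth(
    panel: PanelConfig, spec: CohortSpec, group: GroupSpec, sample_id: str
) -> tuple[RnaTruth, DnaTruth, dict[str, float], float, np.random.Generator]:
    rng = sample_rng(spec.seed, sample_id)
    t = float(rng.random())
    lo, hi = group.ar_abundance_range
    abundance = lo + t * (hi - lo)
    fractions = {}
    for variant, (flo, fhi) in group.arv_fraction_ranges.items():
        if group.couple_arv_to_abundance:
            u = float(np.clip(t + rng.normal(0.0, 0.15), 0.0, 1.0))
        else:
            u = float(rng.random())
        fractions[variant] = flo + u * (fhi - flo)
    rna = RnaTruth(
        isoform_fractions=fractions,
        depth=group.rna_depth * abundance,
        read_length=spec.read_length,
        error_rate=spec.error_rate,
        seed=int(rng.integers(2**31 - 1)),
    )
    if group.copy_number_weights is not None:
        w = np.asarray(group.copy_number_weights, dtype=float)
        cn = float(rng.choice(group.copy_number_choices, p=w / w.sum()))
    else:
        cn = float(rng.choice(group.copy_number_choices))
    hotspots: dict[str, float] = {}
    if panel.hotspots and rng.random() < group.hotspot_prob:
        h = panel.hotspots[rng.integers(len(panel.hotspots))]
        hotspots[h.name] = float(rng.uniform(*group.hotspot_vaf_range))
    events: list[GsrEvent] = []
    if rng.random() < group.gsr_prob:
        events.append(
            _random_event(panel, rng, float(rng.uniform(*group.gsr_vaf_range)))
        )
    dna = DnaTruth(
        ar_copy_number=cn,
        gsr_events=events,
        hotspot_vafs=hotspots,
        fragment_size_mean=spec.fragment_size_mean,
        fragment_size_sd=spec.fragment_size_sd,
        depth=group.dna_depth,
        read_length=spec.read_length,
        error_rate=spec.error_rate,
        seed=int(rng.integers(2**31 - 1)),
    )
    return rna, dna, fractions, abundance, rng


def simulate_cohort(
    panel: PanelConfig, spec: CohortSpec, include_dna: bool = True
):
    """Yield :class:`SimulatedSample` records, one per cohort sample."""
    spec.validate()
    for group in spec.groups:
        for k in range(group.n_samples):
            sample_id = f"{group.name}_{k + 1:02d}"
            rna, dna, fractions, abundance, rng = _draw_sample_truth(
                panel, spec, group, sample_id
            )
            rna_reads, rna_record = simulate_rna_reads(panel, rna, sample_id)
            if include_dna:
                dna_reads, dna_record = simulate_dna_reads(panel, dna, sample_id)
            else:
                dna_reads, dna_record = None, None
            means = group.expression_means or DEFAULT_EXPRESSION_MEANS
            depth_factor = float(rng.lognormal(0.0, 0.25))
            counts = simulate_expression_counts(
                panel, means, group.expression_dispersion, depth_factor, rng
            )
            yield SimulatedSample(
                sample_id=sample_id,
                group=group.name,
                rna_truth=rna,
                rna_reads=rna_reads,
                rna_record=rna_record,
                dna_truth=dna,
                dna_reads=dna_reads,
                dna_record=dna_record,
                expression_counts=counts,
                ar_abundance=abundance,
            )


def truth_row(panel: PanelConfig, s: SimulatedSample) -> dict:
    row: dict = {"sample": s.sample_id, "group": s.group,
                 "ar_abundance": round(s.ar_abundance, 6)}
    for j in panel.variant_junctions():
        v = s.rna_truth.isoform_fractions.get(j.variant_name, 0.0)
        row[f"true_frac_{j.variant_name}"] = round(v, 6)
    row["ar_copy_number"] = s.dna_truth.ar_copy_number
    hs = s.dna_truth.hotspot_vafs
    row["hotspot"] = next(iter(hs), "")
    row["hotspot_vaf"] = round(next(iter(hs.values()), 0.0), 6)
    if s.dna_truth.gsr_events:
        ev = s.dna_truth.gsr_events[0]
        row.update(
            gsr_type=ev.type, gsr_bp_a=ev.breakpoint_a, gsr_bp_b=ev.breakpoint_b,
            gsr_vaf=round(ev.vaf, 6),
        )
    else:
        row.update(gsr_type="", gsr_bp_a=-1, gsr_bp_b=-1, gsr_vaf=0.0)
    return row


def generate_cohort(
    panel: PanelConfig,
    spec: CohortSpec,
    outdir: str | Path,
    include_dna: bool = True,
) -> pd.DataFrame:
    """Write a cohort to disk: per-sample FASTQs, a cohort expression-count
    table and a truth table.  Fully reproducible from the spec seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    expr_rows = {}
    for s in simulate_cohort(panel, spec, include_dna=include_dna):
        sdir = outdir / s.sample_id
        sdir.mkdir(exist_ok=True)
        write_fastq(s.rna_reads, sdir / "rna.fastq")
        if s.dna_reads is not None:
            write_fastq([r for r in s.dna_reads if r.id.endswith("/1")],
                        sdir / "dna_1.fastq")
            write_fastq([r for r in s.dna_reads if r.id.endswith("/2")],
                        sdir / "dna_2.fastq")
        rows.append(truth_row(panel, s))
        expr_rows[s.sample_id] = s.expression_counts
    truth = pd.DataFrame(rows)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    expr = pd.DataFrame.from_dict(expr_rows, orient="index")
    expr.index.name = "sample"
    expr.to_csv(outdir / "expression_counts.tsv", sep="\t")
    return truth


# -- canned study designs ----------------------------------------------------


def crpc_vs_naive_cohort(
    seed: int,
    n_per_group: int = 15,
    rna_depth: float = 350.0,
    naive_range: tuple[float, float] = (0.0, 0.02),
    crpc_range: tuple[float, float] = (0.05, 0.12),
) -> CohortSpec:
    """Two-group design contrasting hormone-naive samples (low AR-V
    fractions, diploid-equivalent AR) against CRPC metastases (high AR-V
    fractions coupled to elevated AR expression, amplified AR, occasional
    rearrangements and hotspot mutations)."""
    variants = ("AR-V3", "AR-V7", "AR-V9")
    naive = GroupSpec(
        name="hormone_naive",
        n_samples=n_per_group,
        arv_fraction_ranges={v: naive_range for v in variants},
        ar_abundance_range=(0.6, 1.2),
        rna_depth=rna_depth,
        copy_number_choices=(1.0,),
    )
    crpc = GroupSpec(
        name="CRPC_met",
        n_samples=n_per_group,
        arv_fraction_ranges={v: crpc_range for v in variants},
        ar_abundance_range=(1.5, 3.0),
        couple_arv_to_abundance=True,
        rna_depth=rna_depth,
        copy_number_choices=(1.0, 1.5, 4.0, 10.0, 30.0, 68.0),
        copy_number_weights=(0.17, 0.13, 0.25, 0.2, 0.15, 0.10),
        hotspot_prob=0.2,
        gsr_prob=0.17,
        expression_means={
            g: (m * 2.5 if g in AR_REGULATED_GENES else m)
            for g, m in DEFAULT_EXPRESSION_MEANS.items()
        },
    )
    return CohortSpec(groups=[naive, crpc], seed=seed)


def default_study_cohort(
    seed: int, n_pc: int = 24, n_lymph: int = 8, n_crpc: int = 30
) -> CohortSpec:
    """Three-group design mirroring a prostatectomy / lymph-node-metastasis /
    metastatic-CRPC targeted-panel study."""
    pc = GroupSpec(
        name="prostatectomy",
        n_samples=n_pc,
        arv_fraction_ranges={v: (0.0, 0.02) for v in ("AR-V3", "AR-V7", "AR-V9")},
        ar_abundance_range=(0.6, 1.3),
    )
    lymph = GroupSpec(
        name="lymph_node_met",
        n_samples=n_lymph,
        arv_fraction_ranges={v: (0.0, 0.03) for v in ("AR-V3", "AR-V7", "AR-V9")},
        ar_abundance_range=(0.6, 1.5),
    )
    crpc = GroupSpec(
        name="CRPC_met",
        n_samples=n_crpc,
        arv_fraction_ranges={
            "AR-V7": (0.01, 0.13),
            "AR-V3": (0.01, 0.07),
            "AR-V9": (0.01, 0.07),
        },
        ar_abundance_range=(1.2, 3.6),
        couple_arv_to_abundance=True,
        copy_number_choices=(1.0, 1.5, 4.0, 10.0, 30.0, 68.0),
        copy_number_weights=(0.17, 0.13, 0.25, 0.2, 0.15, 0.10),
        hotspot_prob=0.2,
        gsr_prob=0.17,
        expression_means={
            g: (m * 2.5 if g in AR_REGULATED_GENES else m)
            for g, m in DEFAULT_EXPRESSION_MEANS.items()
        },
    )
    return CohortSpec(groups=[pc, lymph, crpc], seed=seed)
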