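"""Split-read structural-rearrangement calling over the panel loci.

A read supports a breakpoint when its prefix and suffix map ungapped to two
discontiguous reference positions (either strand, possibly different loci),
each segment at least ``min_segment`` bases with at most
``max_mismatches_per_segment`` substitutions.  Split alignments are clustered
into events by breakpoint proximity and orientation, classified as deletion /
tandem duplication / inversion / translocation, filtered by split-read
support (default cut-off 10), and assigned a variant allele fraction
vaf = split support / (split support + reads spanning breakpoint A
contiguously by >= min_segment on both sides).

Because the panel reference is only kilobases, the split search is
exhaustive over all reference diagonals rather than heuristic: for a read
failing contiguous mapping, mismatch prefix sums against every placement of
the read and its reverse complement are evaluated.  Among valid splits the
one with the fewest total mismatches wins, with ties (micro-homology at the
junction) broken by the orientation-canonical breakend tuple, so both
sequencing orientations of a junction report the same leftmost-in-genome
breakpoint; truth comparisons still allow a tolerance of the homology
length.  Bases adjacent to the split must match exactly (``anchor``) so the
mismatch budget cannot carry a segment across the true junction.  Discordant
mate-pair spacing is not used to call events, only split reads are counted
(mates are mapped independently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp, seq_to_array
from .gene_model import PanelConfig

DEFAULT_MIN_SEGMENT = 25
DEFAULT_MAX_MM_PER_SEGMENT = 2
DEFAULT_MAX_NORMAL_GAP = 5
DEFAULT_TOLERANCE = 10
DEFAULT_MIN_SUPPORT = 10
# bases adjacent to the split that must match exactly on both segments, so
# the mismatch budget cannot carry a segment across the true junction (which
# would widen the effective junction-read window and bias VAF upward)
DEFAULT_ANCHOR = 4

_FLIP = {"+": "-", "-": "+"}


class GenomeIndex:
    """k-mer-seeded ungapped matcher over the concatenated panel sequences."""

    PAD = 300

    def __init__(self, seqs: dict[str, str], k: int = 16) -> None:
        self.k = k
        self.names = list(seqs)
        parts = ["N" * self.PAD]
        self.offsets: dict[str, int] = {}
        self.lengths: dict[str, int] = {}
        cursor = self.PAD
        for name in self.names:
            seq = seqs[name].upper()
            self.offsets[name] = cursor
            self.lengths[name] = len(seq)
            parts.append(seq)
            parts.append("N" * self.PAD)
            cursor += len(seq) + self.PAD
        self.concat = "".join(parts)
        self.arr = seq_to_array(self.concat)
        self._starts = np.array([self.offsets[n] for n in self.names])
        self._window_cache: dict[int, np.ndarray] = {}
        self.kmap: dict[str, list[int]] = {}
        for name in self.names:
            off = self.offsets[name]
            seq = seqs[name].upper()
            for i in range(len(seq) - k + 1):
                self.kmap.setdefault(seq[i : i + k], []).append(off + i)

    @classmethod
    def from_panel(cls, panel: PanelConfig, k: int = 16) -> "GenomeIndex":
        return cls(panel.sequences(), k=k)

    def windows(self, R: int) -> np.ndarray:
        W = self._window_cache.get(R)
        if W is None:
            W = np.lib.stride_tricks.sliding_window_view(self.arr, R)
            self._window_cache[R] = W
        return W

    def local(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._starts, gpos, side="right")) - 1
        name = self.names[i]
        return name, gpos - self.offsets[name]

    def _candidate_diagonals(self, read: str, probes: int = 4) -> set[int]:
        R, k = len(read), self.k
        if R < k:
            return set()
        cands: set[int] = set()
        positions = sorted({int(p) for p in np.linspace(0, R - k, probes)})
        for p in positions:
            for g in self.kmap.get(read[p : p + k], ()):
                cands.add(g - p)
        return cands

    def map_contiguous(self, read: str, max_mismatches: int = 4):
        """Best full-length ungapped placement of the read (either strand),
        or None if no placement has <= max_mismatches substitutions.

        Seeded by exact k-mers, so a read with no clean k-mer may be missed
        here; callers fall back to the exhaustive split search, which also
        detects contiguity.
        """
        R = len(read)
        best = None
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            arr = seq_to_array(oriented)
            for g in self._candidate_diagonals(oriented):
                if g < 0 or g + R > len(self.arr):
                    continue
                mm = int(np.count_nonzero(self.arr[g : g + R] != arr))
                if mm <= max_mismatches and (best is None or mm < best[0]):
                    best = (mm, g, strand, oriented)
        if best is None:
            return None
        mm, g, strand, oriented = best
        chrom, start = self.local(g)
        return ContigAlignment(chrom, start, start + R, strand, mm, oriented)


@dataclass(frozen=True)
class ContigAlignment:
    chrom: str
    start: int
    end: int
    strand: str
    n_mismatches: int
    oriented_seq: str  # read sequence in reference orientation


@dataclass(frozen=True)
class SplitAlignment:
    """A read split into two ungapped segments evidencing a breakpoint.

    ``breakends`` is the as-read tuple (chrom_a, bp_a, orient_a, chrom_b,
    bp_b, orient_b); ``canonical`` is invariant to the sequencing orientation
    of the read and is what clustering operates on.
    """

    read_id: str
    split: int
    segment_a: tuple[str, int, int, str]
    segment_b: tuple[str, int, int, str]
    breakends: tuple

    @property
    def canonical(self) -> tuple:
        return canonical_breakends(self.breakends)


def canonical_breakends(t: tuple) -> tuple:
    ca, pa, oa, cb, pb, ob = t
    flipped = (cb, pb, _FLIP[ob], ca, pa, _FLIP[oa])
    if (oa, ob) == ("-", "-"):
        return flipped
    if (oa, ob) == ("+", "+"):
        return t
    return t if (ca, pa) <= (cb, pb) else flipped


def classify_event(
    orient_a: str, orient_b: str, bp_a: int, bp_b: int, same_locus: bool
) -> str:
    """Rearrangement type from segment orientations and breakpoint order."""
    if not same_locus:
        return "translocation"
    if orient_a != orient_b:
        return "inversion"
    if orient_a == "+":
        return "deletion" if bp_b > bp_a else "duplication"
    return "deletion" if bp_a > bp_b else "duplication"


def _as_index(reference) -> GenomeIndex:
    if isinstance(reference, GenomeIndex):
        return reference
    if isinstance(reference, PanelConfig):
        return GenomeIndex.from_panel(reference)
    if isinstance(reference, dict):
        return GenomeIndex(reference)
    if isinstance(reference, str):
        return GenomeIndex({"ref": reference})
    raise TypeError(f"unsupported reference type {type(reference)!r}")


def _analyze_read(
    read: str,
    index: GenomeIndex,
    min_segment: int,
    max_mm: int,
    max_normal_gap: int,
    read_id: str = "read",
    anchor: int = DEFAULT_ANCHOR,
):
    """Exhaustive classification of one read: ('contig', aln), ('split', sa)
    or ('none', None)."""
    R = len(read)
    if R < 2 * min_segment:
        return ("none", None)
    W = index.windows(R)
    arr_f = seq_to_array(read)
    arr_r = seq_to_array(revcomp(read))
    max_total = 2 * max_mm

    f_head = np.count_nonzero(W[:, :min_segment] != arr_f[:min_segment], axis=1)
    f_tail = np.count_nonzero(W[:, R - min_segment :] != arr_f[R - min_segment :], axis=1)
    r_head = np.count_nonzero(W[:, :min_segment] != arr_r[:min_segment], axis=1)
    r_tail = np.count_nonzero(W[:, R - min_segment :] != arr_r[R - min_segment :], axis=1)
    Pf = np.flatnonzero(f_head <= max_mm)
    Sf = np.flatnonzero(f_tail <= max_mm)
    Sr = np.flatnonzero(r_head <= max_mm)
    Pr = np.flatnonzero(r_tail <= max_mm)

    # contiguity: any full placement within the doubled budget wins
    best_full = None
    for g in np.union1d(Pf, Sf):
        mm = int(np.count_nonzero(W[g] != arr_f))
        if mm <= max_total and (best_full is None or mm < best_full[0]):
            best_full = (mm, int(g), "+")
    for g in np.union1d(Sr, Pr):
        mm = int(np.count_nonzero(W[g] != arr_r))
        if mm <= max_total and (best_full is None or mm < best_full[0]):
            best_full = (mm, int(g), "-")
    if best_full is not None:
        mm, g, strand = best_full
        chrom, start = index.local(g)
        oriented = read if strand == "+" else revcomp(read)
        return ("contig", ContigAlignment(chrom, start, start + R, strand, mm, oriented))

    cum_f = {int(g): np.concatenate([[0], np.cumsum(W[g] != arr_f)]) for g in np.union1d(Pf, Sf)}
    cum_r = {int(g): np.concatenate([[0], np.cumsum(W[g] != arr_r)]) for g in np.union1d(Sr, Pr)}

    def seg_info(g: int, kind: str, s: int):
        chrom, l = index.local(g)
        if kind == "P+":
            return chrom, (chrom, l, l + s, "+"), l + s, "+"
        if kind == "S+":
            return chrom, (chrom, l + s, l + R, "+"), l + s, "+"
        if kind == "P-":
            return chrom, (chrom, l + R - s, l + R, "-"), l + R - s, "-"
        # S-
        return chrom, (chrom, l, l + R - s, "-"), l + R - s, "-"

    combos = (
        ("P+", "S+", Pf, Sf),
        ("P+", "S-", Pf, Sr),
        ("P-", "S+", Pr, Sf),
        ("P-", "S-", Pr, Sr),
    )
    # Among all valid splits, minimise total mismatches (i.e. maximise the
    # number of matched bases); break ties by the canonical breakend tuple so
    # micro-homology resolves to the leftmost junction in genome coordinates
    # regardless of the sequencing orientation of the read.
    best = None
    for s in range(min_segment, R - min_segment + 1):
        for pk, sk, pset, sset in combos:
            for g1 in pset:
                g1 = int(g1)
                if pk == "P+":
                    mm_p = int(cum_f[g1][s])
                    anchored_p = cum_f[g1][s] == cum_f[g1][s - anchor]
                else:
                    mm_p = int(cum_r[g1][R] - cum_r[g1][R - s])
                    anchored_p = cum_r[g1][R - s + anchor] == cum_r[g1][R - s]
                if mm_p > max_mm or not anchored_p:
                    continue
                for g2 in sset:
                    g2 = int(g2)
                    if sk == "S+":
                        mm_s = int(cum_f[g2][R] - cum_f[g2][s])
                        anchored_s = cum_f[g2][s + anchor] == cum_f[g2][s]
                    else:
                        mm_s = int(cum_r[g2][R - s])
                        anchored_s = cum_r[g2][R - s] == cum_r[g2][R - s - anchor]
                    if mm_s > max_mm or not anchored_s:
                        continue
                    # exclude near-contiguous placements
                    if pk == "P+" and sk == "S+" and abs(g2 - g1) <= max_normal_gap:
                        continue
                    if pk == "P-" and sk == "S-" and abs(g2 - g1) <= max_normal_gap:
                        continue
                    ca, seg_a, bp_a, oa = seg_info(g1, pk, s)
                    cb, seg_b, bp_b, ob = seg_info(g2, sk, s)
                    ends = (ca, bp_a, oa, cb, bp_b, ob)
                    key = (mm_p + mm_s, canonical_breakends(ends), s)
                    if best is None or key < best[0]:
                        best = (key, ends, seg_a, seg_b, s)
    if best is None:
        return ("none", None)
    _, ends, seg_a, seg_b, s = best
    return (
        "split",
        SplitAlignment(
            read_id=read_id, split=s, segment_a=seg_a, segment_b=seg_b,
            breakends=ends,
        ),
    )


def split_align(
    read: str,
    reference,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    max_mismatches_per_segment: int = DEFAULT_MAX_MM_PER_SEGMENT,
    max_normal_gap: int = DEFAULT_MAX_NORMAL_GAP,
    read_id: str = "read",
    anchor: int = DEFAULT_ANCHOR,
) -> SplitAlignment | None:
    """Two-segment ungapped split alignment of a read, or None.

    None is returned both when the read maps contiguously (within twice the
    per-segment mismatch budget) and when no valid split exists.
    """
    index = _as_index(reference)
    kind, payload = _analyze_read(
        read, index, min_segment, max_mismatches_per_segment, max_normal_gap,
        read_id, anchor,
    )
    return payload if kind == "split" else None


@dataclass
class BreakpointEvent:
    chrom_a: str
    breakpoint_a: int
    orient_a: str
    chrom_b: str
    breakpoint_b: int
    orient_b: str
    type: str
    n_split_support: int
    n_reference_spanning: int = 0
    vaf: float | None = None

    @property
    def breakends(self) -> tuple:
        return (self.chrom_a, self.breakpoint_a, self.orient_a,
                self.chrom_b, self.breakpoint_b, self.orient_b)


def cluster_events(
    splits: list[SplitAlignment],
    breakpoint_tolerance: int = DEFAULT_TOLERANCE,
) -> list[BreakpointEvent]:
    """Merge split alignments agreeing on orientations and (within tolerance)
    breakpoints; event breakpoints are the medians over cluster members."""
    if breakpoint_tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    groups: dict[tuple, list[tuple[int, int]]] = {}
    for sa in splits:
        ca, pa, oa, cb, pb, ob = sa.canonical
        groups.setdefault((ca, oa, cb, ob), []).append((pa, pb))
    events: list[BreakpointEvent] = []
    for (ca, oa, cb, ob), pairs in groups.items():
        pairs.sort()
        cluster: list[tuple[int, int]] = []
        clusters = []
        for pa, pb in pairs:
            if cluster and (
                abs(pa - cluster[-1][0]) > breakpoint_tolerance
                or abs(pb - cluster[-1][1]) > breakpoint_tolerance
            ):
                clusters.append(cluster)
                cluster = []
            cluster.append((pa, pb))
        if cluster:
            clusters.append(cluster)
        for members in clusters:
            pa_med = int(round(float(np.median([m[0] for m in members]))))
            pb_med = int(round(float(np.median([m[1] for m in members]))))
            events.append(
                BreakpointEvent(
                    chrom_a=ca,
                    breakpoint_a=pa_med,
                    orient_a=oa,
                    chrom_b=cb,
                    breakpoint_b=pb_med,
                    orient_b=ob,
                    type=classify_event(oa, ob, pa_med, pb_med, ca == cb),
                    n_split_support=len(members),
                )
            )
    events.sort(key=lambda e: (-e.n_split_support, e.chrom_a, e.breakpoint_a))
    return events


def event_vaf(n_split_support: int, n_reference_spanning: int) -> float | None:
    denom = n_split_support + n_reference_spanning
    if denom == 0:
        return None
    return n_split_support / denom


@dataclass
class RearrangementResult:
    events: list[BreakpointEvent]
    contigs: list[ContigAlignment]
    splits: list[SplitAlignment]
    n_reads: int = 0


def call_rearrangements(
    reads,
    reference,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    max_mismatches_per_segment: int = DEFAULT_MAX_MM_PER_SEGMENT,
    max_normal_gap: int = DEFAULT_MAX_NORMAL_GAP,
    breakpoint_tolerance: int = DEFAULT_TOLERANCE,
    min_support: int = DEFAULT_MIN_SUPPORT,
    anchor: int = DEFAULT_ANCHOR,
) -> RearrangementResult:
    """Full per-sample caller: map reads, collect splits, cluster, filter by
    split support and estimate per-event variant allele fractions.

    ``reads`` is an iterable of :class:`~arvprofiler.readio.Read` or plain
    sequences.  The returned contiguous alignments are reused by the pileup
    variant caller and coverage stages.
    """
    index = _as_index(reference)
    max_total = 2 * max_mismatches_per_segment
    contigs: list[ContigAlignment] = []
    splits: list[SplitAlignment] = []
    n_reads = 0
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        rid = f"read{n_reads}" if isinstance(read, str) else read.id
        n_reads += 1
        aln = index.map_contiguous(seq, max_mismatches=max_total)
        if aln is not None:
            contigs.append(aln)
            continue
        kind, payload = _analyze_read(
            seq, index, min_segment, max_mismatches_per_segment, max_normal_gap,
            rid, anchor,
        )
        if kind == "contig":
            contigs.append(payload)
        elif kind == "split":
            splits.append(payload)

    events = [
        e for e in cluster_events(splits, breakpoint_tolerance)
        if e.n_split_support >= min_support
    ]

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c.chrom for c in contigs}:
        starts = np.array([c.start for c in contigs if c.chrom == chrom])
        ends = np.array([c.end for c in contigs if c.chrom == chrom])
        by_chrom[chrom] = (starts, ends)
    for event in events:
        starts_ends = by_chrom.get(event.chrom_a)
        if starts_ends is None:
            spanning = 0
        else:
            starts, ends = starts_ends
            bp = event.breakpoint_a
            spanning = int(
                np.count_nonzero(
                    (starts <= bp - min_segment) & (ends >= bp + min_segment)
                )
            )
        event.n_reference_spanning = spanning
        event.vaf = event_vaf(event.n_split_support, spanning)

    return RearrangementResult(events=events, contigs=contigs, splits=splits,
                               n_reads=n_reads)


def write_bedpe(events: list[BreakpointEvent], path) -> None:
    """BEDPE-style TSV: one row per event with orientations, type, support
    and vaf."""
    with open(path, "w") as fh:
        fh.write(
            "chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\t"
            "orient_a\torient_b\ttype\tn_split_support\t"
            "n_reference_spanning\tvaf\n"
        )
        for e in events:
            vaf = "NA" if e.vaf is None else f"{e.vaf:.6g}"
            fh.write(
                f"{e.chrom_a}\t{e.breakpoint_a}\t{e.breakpoint_a + 1}\t"
                f"{e.chrom_b}\t{e.breakpoint_b}\t{e.breakpoint_b + 1}\t"
                f"{e.orient_a}\t{e.orient_b}\t{e.type}\t{e.n_split_support}\t"
                f"{e.n_reference_spanning}\t{vaf}\n"
            )
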