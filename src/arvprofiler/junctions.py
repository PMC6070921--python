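"""Splice-junction signature construction, read assignment and AR-V fractions.

Each catalogued splice junction is represented by a *signature*: the last
``flank`` (default 130) bases of the upstream exon concatenated with the
first ``flank`` bases of the downstream exon.  An RNA read supports a
junction when it aligns ungapped to that signature with a small mismatch
budget and covers the exon-exon boundary by at least ``min_overhang`` bases
on each side.  The relative expression of a splice isoform is then the read
count of its junction divided by the total count over all junctions sharing
the same upstream exon, reported together with the lower endpoint of an
exact (Clopper-Pearson) two-sided 95% binomial confidence interval.

Alignment is deliberately re-specified as direct ungapped matching with a
mismatch budget rather than an external aligner: it is deterministic,
oracle-checkable, and sufficient for substitution-only reads.  Ambiguous
reads that match two or more signatures equally well are left unassigned
rather than fractionally allocated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seq import revcomp, seq_to_array
from .gene_model import JunctionDef, PanelConfig, junctions_by_upstream

DEFAULT_FLANK = 130
DEFAULT_MIN_OVERHANG = 10
DEFAULT_MAX_MISMATCHES = 3


class SignatureError(ValueError):
    """Raised when the junction catalog yields degenerate signatures."""


@dataclass(frozen=True)
class Signature:
    """Concatenated flanking sequence uniquely identifying one junction."""

    junction: JunctionDef
    sequence: str
    junction_offset: int  # length of the upstream-exon contribution


def build_signatures(panel: PanelConfig, flank: int = DEFAULT_FLANK) -> list[Signature]:
    """One signature per catalogued junction; flanks truncate at exon ends."""
    signatures = []
    for junction in panel.junctions:
        up = panel.exon_by_id(junction.upstream).sequence
        down = panel.exon_by_id(junction.downstream).sequence
        up_part = up[-min(flank, len(up)):]
        down_part = down[: min(flank, len(down))]
        signatures.append(
            Signature(junction, up_part + down_part, len(up_part))
        )
    by_seq: dict[str, Signature] = {}
    for sig in signatures:
        other = by_seq.get(sig.sequence)
        if other is not None:
            raise SignatureError(
                f"junctions {other.junction.label()} and "
                f"{sig.junction.label()} yield identical signatures"
            )
        by_seq[sig.sequence] = sig
    return signatures


def export_signatures_fasta(signatures: list[Signature], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(s.sequence),
            id=f"{s.junction.variant_name}|{s.junction.label()}",
            description=f"junction_offset={s.junction_offset}",
        )
        for s in signatures
    ]
    SeqIO.write(records, str(path), "fasta")


# -- matching ----------------------------------------------------------------


class _LengthStructure:
    """Precomputed placement windows for one read length.

    For a read of length R, the valid placements against signature ``s``
    (boundary at J, length L) are offsets o in [J-R+mo, J-mo]: exactly those
    for which the read covers the boundary with >= mo bases on each side.
    Each placement is materialised as a length-R window of signature bytes,
    zero-padded where the read hangs over a signature end; mismatches are
    counted over the in-signature overlap only.
    """

    __slots__ = ("rows", "W", "pad", "exact", "left_clips", "right_clips", "R")

    def __init__(self, matcher: "SignatureMatcher", R: int) -> None:
        mo = matcher.min_overhang
        self.R = R
        rows: list[tuple[int, str, int]] = []  # (sig index, strand, offset)
        windows: list[np.ndarray] = []
        left_clips: set[int] = set()
        right_clips: set[int] = set()
        exact: dict[tuple[str, str], list[int]] | None = {}
        for si, sig in enumerate(matcher.signatures):
            for strand, seq, J in (
                ("+", sig.sequence, sig.junction_offset),
                ("-", revcomp(sig.sequence), len(sig.sequence) - sig.junction_offset),
            ):
                L = len(seq)
                if J < mo or L - J < mo or R < 2 * mo:
                    continue
                arr = seq_to_array(seq)
                for o in range(J - R + mo, J - mo + 1):
                    a = max(0, -o)              # left clip in read coords
                    c = max(0, o + R - L)       # right clip in read coords
                    if a and c:
                        exact = None  # signature shorter than read: no dict path
                    row = np.zeros(R, dtype=np.uint8)
                    row[a : R - c] = arr[o + a : o + R - c]
                    ridx = len(rows)
                    rows.append((si, strand, o))
                    windows.append(row)
                    if exact is not None:
                        if a:
                            key = ("L", seq[o + a : o + R])
                            left_clips.add(a)
                        elif c:
                            key = ("R", seq[o : o + R - c])
                            right_clips.add(c)
                        else:
                            key = ("F", seq[o : o + R])
                        exact.setdefault(key, []).append(ridx)
        self.rows = rows
        if rows:
            self.W = np.vstack(windows)
        else:
            self.W = np.zeros((0, R), dtype=np.uint8)
        # padding bytes always mismatch, so per-row overlap mismatches are
        # (full-window mismatches - number of padded positions)
        self.pad = np.count_nonzero(self.W == 0, axis=1)
        self.exact = exact
        self.left_clips = sorted(left_clips)
        self.right_clips = sorted(right_clips)


class SignatureMatcher:
    """Assigns reads to junction signatures by exhaustive ungapped matching.

    ``assign`` is the per-read reference path (a full Hamming scan over every
    valid placement of both read orientations); ``assign_many`` adds an
    exact-match dictionary fast path that short-circuits error-free reads and
    falls back to the full scan otherwise, with identical results.
    """

    def __init__(
        self,
        signatures: list[Signature],
        min_overhang: int = DEFAULT_MIN_OVERHANG,
        max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    ) -> None:
        if min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        self.signatures = list(signatures)
        self.min_overhang = min_overhang
        self.max_mismatches = max_mismatches
        self._structures: dict[int, _LengthStructure] = {}

    def _structure(self, R: int) -> _LengthStructure:
        st = self._structures.get(R)
        if st is None:
            st = _LengthStructure(self, R)
            self._structures[R] = st
        return st

    def _scan(self, read: str) -> JunctionDef | None:
        """Full Hamming scan over all valid placements; None if unassigned."""
        st = self._structure(len(read))
        if not st.rows:
            return None
        arr = seq_to_array(read)
        mm = np.count_nonzero(st.W != arr, axis=1) - st.pad
        best = int(mm.min())
        if best > self.max_mismatches:
            return None
        hits = {st.rows[i][0] for i in np.flatnonzero(mm == best)}
        if len(hits) != 1:
            return None
        return self.signatures[hits.pop()].junction

    def assign(self, read: str) -> JunctionDef | None:
        """Assign one read to a junction, or None when unassigned.

        Unassigned covers reads with no valid placement (e.g. lying entirely
        within one exon), reads over the mismatch budget, and reads matching
        two or more signatures equally well.
        """
        return self._scan(read)

    def _assign_fast(self, read: str, st: _LengthStructure) -> JunctionDef | None:
        if st.exact is not None:
            cands: list[int] = []
            hit = st.exact.get(("F", read))
            if hit:
                cands.extend(hit)
            for a in st.left_clips:
                hit = st.exact.get(("L", read[a:]))
                if hit:
                    cands.extend(hit)
            for c in st.right_clips:
                hit = st.exact.get(("R", read[:-c]))
                if hit:
                    cands.extend(hit)
            if cands:
                sigs = {st.rows[i][0] for i in cands}
                if len(sigs) != 1:
                    return None
                return self.signatures[sigs.pop()].junction
        return self._scan(read)

    def assign_many(self, reads) -> list[JunctionDef | None]:
        out = []
        for read in reads:
            st = self._structure(len(read))
            if not st.rows:
                out.append(None)
            else:
                out.append(self._assign_fast(read, st))
        return out


def assign_read(
    read: str,
    signatures: list[Signature],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> JunctionDef | None:
    """Functional wrapper around :meth:`SignatureMatcher.assign`."""
    return SignatureMatcher(signatures, min_overhang, max_mismatches).assign(read)


# -- counting ----------------------------------------------------------------


@dataclass
class JunctionCounts:
    """Per-junction read support for one sample."""

    counts: dict[JunctionDef, int]
    n_unmatched: int = 0
    n_ambiguous: int = 0

    @property
    def n_unassigned(self) -> int:
        return self.n_unmatched + self.n_ambiguous

    def get(self, junction: JunctionDef) -> int:
        return self.counts.get(junction, 0)


def count_junctions(
    reads,
    signatures: list[Signature] | SignatureMatcher,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> JunctionCounts:
    """Count junction-supporting reads; deterministic for a fixed read set.

    ``reads`` is an iterable of read sequences (strings).
    """
    if isinstance(signatures, SignatureMatcher):
        matcher = signatures
    else:
        matcher = SignatureMatcher(signatures, min_overhang, max_mismatches)
    reads = list(reads)
    counts: dict[JunctionDef, int] = {s.junction: 0 for s in matcher.signatures}
    n_unmatched = 0
    for junction in matcher.assign_many(reads):
        if junction is None:
            n_unmatched += 1
        else:
            counts[junction] += 1
    return JunctionCounts(counts=counts, n_unmatched=n_unmatched)


# -- fractions ---------------------------------------------------------------


def clopper_pearson_lower(k: int, n: int, confidence: float = 0.95) -> float:
    """Lower endpoint of the exact two-sided binomial confidence interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if k == 0:
        return 0.0
    alpha = 1.0 - confidence
    return float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))


@dataclass
class VariantFraction:
    """Per-variant transcript fraction with its CI95 lower bound.

    ``fraction`` and ``ci95_lower`` are None when the upstream-exon group has
    zero total reads (not quantifiable).
    """

    variant_name: str
    junction: JunctionDef
    numerator: int
    denominator: int
    fraction: float | None
    ci95_lower: float | None

    @property
    def quantifiable(self) -> bool:
        return self.fraction is not None


def quantify_fractions(
    counts: JunctionCounts,
    panel: PanelConfig,
    include_canonical: bool = False,
) -> list[VariantFraction]:
    """Per-variant fractions: junction count over the summed count of all
    junctions sharing the same upstream exon."""
    groups = junctions_by_upstream(panel)
    group_totals = {
        up: sum(counts.get(j) for j in js) for up, js in groups.items()
    }
    out = []
    for junction in panel.junctions:
        if not include_canonical and junction.variant_name == panel.canonical_name:
            continue
        num = counts.get(junction)
        denom = group_totals[junction.upstream]
        if denom > 0:
            frac = num / denom
            ci = clopper_pearson_lower(num, denom)
        else:
            frac = None
            ci = None
        out.append(
            VariantFraction(junction.variant_name, junction, num, denom, frac, ci)
        )
    return out


DEFAULT_COMBINED_VARIANTS = ("AR-V3", "AR-V7", "AR-V9")


def total_arv_fraction(
    fractions: list[VariantFraction],
    variants: tuple[str, ...] = DEFAULT_COMBINED_VARIANTS,
) -> float | None:
    """Combined point-estimate fraction of the named variants (each with its
    own upstream-exon denominator); None when any component is not
    quantifiable."""
    total = 0.0
    by_name = {f.variant_name: f for f in fractions}
    for name in variants:
        vf = by_name.get(name)
        if vf is None or vf.fraction is None:
            return None
        total += vf.fraction
    return total


def canonical_junction_count(
    counts: JunctionCounts, panel: PanelConfig, upstream: str = "E3"
) -> int:
    """Read support of the canonical (full-length) junction anchored at the
    given upstream exon; used as the AR-FL expression measure."""
    for junction in panel.canonical_junctions():
        if junction.upstream == upstream:
            return counts.get(junction)
    raise ValueError(f"no canonical junction with upstream exon {upstream!r}")


def write_fractions_tsv(fractions: list[VariantFraction], path) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tjunction\tnumerator\tdenominator\tfraction\tci95_lower\n")
        for f in fractions:
            frac = "NA" if f.fraction is None else f"{f.fraction:.6g}"
            ci = "NA" if f.ci95_lower is None else f"{f.ci95_lower:.6g}"
            fh.write(
                f"{f.variant_name}\t{f.junction.label()}\t{f.numerator}\t"
                f"{f.denominator}\t{frac}\t{ci}\n"
            )
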