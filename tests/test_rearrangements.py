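import pytest

from arvprofiler._seq import revcomp
from arvprofiler.rearrangements import (
    BreakpointEvent,
    SplitAlignment,
    call_rearrangements,
    canonical_breakends,
    classify_event,
    cluster_events,
    event_vaf,
    split_align,
)
from arvprofiler.synthetic import (
    DnaTruth,
    GsrEvent,
    expected_breakends,
    simulate_dna_reads,
)


class TestSplitAlign:
    def test_reference_read_maps_contiguously(self, panel, genome_index):
        read = panel.locus_sequence[500:650]
        assert split_align(read, genome_index) is None

    def test_constructed_deletion_read(self, panel, genome_index):
        L = panel.locus_sequence
        p, q = 1000, 2500
        read = L[p - 75 : p] + L[q : q + 75]
        sa = split_align(read, genome_index)
        assert sa is not None
        ca, pa, oa, cb, pb, ob = sa.canonical
        assert (pa, pb) == (p, q)
        assert (oa, ob) == ("+", "+")
        assert classify_event(oa, ob, pa, pb, ca == cb) == "deletion"

    def test_orientation_invariance(self, panel, genome_index):
        L = panel.locus_sequence
        read = L[925:1000] + revcomp(L[2925:3000])  # inversion-type junction
        sa_f = split_align(read, genome_index)
        sa_r = split_align(revcomp(read), genome_index)
        assert sa_f is not None and sa_r is not None
        assert sa_f.canonical == sa_r.canonical

    def test_too_short_segment_is_none(self, panel, genome_index):
        L = panel.locus_sequence
        read = L[990:1000] + L[2500:2640]  # prefix below min_segment
        sa = split_align(read, genome_index)
        assert sa is None or sa.segment_a[2] - sa.segment_a[1] >= 25

    def test_simulated_inversion_junction_reads_recovered(self, panel, genome_index):
        a, b = 900, 2900
        truth = DnaTruth(
            gsr_events=[GsrEvent(a, b, "inversion", 1.0)],
            depth=150, error_rate=0.0, seed=31,
        )
        reads, rec = simulate_dna_reads(panel, truth)
        junction_reads = [r for r in reads if "gsr0" in r.id]
        found = 0
        near = 0
        for r in junction_reads:
            sa = split_align(r.sequence, genome_index)
            if sa is None:
                continue
            found += 1
            _, pa, _, _, pb, _ = sa.canonical
            if abs(pa - a) <= 5 and abs(pb - b) <= 5:
                near += 1
        # junction reads with < 25 bp on one side are legitimately unsplittable
        assert found >= rec.events[0].n_split_reads * 0.95
        assert near >= 0.95 * found


class TestClassifyEvent:
    @pytest.mark.parametrize(
        "oa,ob,a,b,same,expect",
        [
            ("+", "+", 100, 500, True, "deletion"),
            ("+", "+", 500, 100, True, "duplication"),
            ("+", "-", 100, 500, True, "inversion"),
            ("-", "+", 100, 500, True, "inversion"),
            ("+", "+", 100, 500, False, "translocation"),
        ],
    )
    def test_orientation_logic(self, oa, ob, a, b, same, expect):
        assert classify_event(oa, ob, a, b, same) == expect

    def test_canonicalisation_maps_minus_pair_to_plus(self):
        t = ("c", 2500, "-", "c", 1000, "-")
        assert canonical_breakends(t) == ("c", 1000, "+", "c", 2500, "+")


def _split(pa, pb, oa="+", ob="+", chrom="c"):
    return SplitAlignment(
        read_id="r", split=75,
        segment_a=(chrom, pa - 75, pa, oa), segment_b=(chrom, pb, pb + 75, ob),
        breakends=(chrom, pa, oa, chrom, pb, ob),
    )


class TestClusterEvents:
    def test_identical_splits_merge(self):
        events = cluster_events([_split(1000, 2000)] * 12)
        assert len(events) == 1
        assert events[0].n_split_support == 12
        assert events[0].type == "deletion"

    def test_distant_clusters_stay_separate(self):
        splits = [_split(1000, 2000)] * 5 + [_split(1500, 2500)] * 5
        events = cluster_events(splits, breakpoint_tolerance=10)
        assert len(events) == 2

    def test_within_tolerance_merges_to_median(self):
        splits = [_split(1000 + d, 2000 + d) for d in (-3, -1, 0, 1, 3)]
        (event,) = cluster_events(splits, breakpoint_tolerance=10)
        assert (event.breakpoint_a, event.breakpoint_b) == (1000, 2000)


class TestVaf:
    def test_arithmetic(self):
        assert event_vaf(10, 90) == pytest.approx(0.10)
        assert event_vaf(10, 0) == 1.0
        assert event_vaf(0, 0) is None

    def test_full_vaf_event_has_no_spanning_reads(self, panel, genome_index):
        truth = DnaTruth(
            gsr_events=[GsrEvent(1200, 2200, "deletion", 1.0)],
            depth=120, seed=32,
        )
        reads, _ = simulate_dna_reads(panel, truth)
        rr = call_rearrangements(reads, genome_index, min_support=5)
        (event,) = [e for e in rr.events if e.type == "deletion"]
        assert event.n_reference_spanning == 0
        assert event.vaf == 1.0


class TestCaller:
    @pytest.mark.parametrize("etype,a,b", [
        ("deletion", 2240, 2910),
        ("duplication", 1000, 2500),
        ("inversion", 800, 3000),
        ("translocation", 1500, 700),
    ])
    def test_event_type_and_breakpoints_recovered(self, panel, genome_index,
                                                  etype, a, b):
        kw = {"partner_chrom": "CTRL_FOXA1"} if etype == "translocation" else {}
        truth = DnaTruth(
            gsr_events=[GsrEvent(a, b, etype, 0.2, **kw)], depth=400, seed=33
        )
        reads, _ = simulate_dna_reads(panel, truth)
        rr = call_rearrangements(reads, genome_index)
        assert len(rr.events) == 1
        ev = rr.events[0]
        assert ev.type == etype
        exp = expected_breakends(truth.gsr_events[0], panel.locus_name)
        assert (ev.chrom_a, ev.chrom_b) == (exp[0], exp[3])
        assert abs(ev.breakpoint_a - exp[1]) <= 5
        assert abs(ev.breakpoint_b - exp[4]) <= 5
        assert (ev.orient_a, ev.orient_b) == (exp[2], exp[5])

    def test_clean_sample_produces_no_events(self, panel, genome_index):
        truth = DnaTruth(depth=500, seed=34)
        reads, _ = simulate_dna_reads(panel, truth)
        rr = call_rearrangements(reads, genome_index)
        assert rr.events == []
        assert len(rr.splits) == 0

    def test_support_monotone_in_vaf(self, panel, genome_index):
        supports = []
        for vaf in (0.02, 0.05, 0.1, 0.5):
            truth = DnaTruth(
                gsr_events=[GsrEvent(1200, 2200, "deletion", vaf)],
                depth=400, seed=35,
            )
            reads, _ = simulate_dna_reads(panel, truth)
            rr = call_rearrangements(reads, genome_index, min_support=1)
            supports.append(sum(e.n_split_support for e in rr.events
                                if e.type == "deletion"))
        assert all(x <= y for x, y in zip(supports, supports[1:]))
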