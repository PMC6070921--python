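import numpy as np
import pytest
from scipy.stats import binom

from arvprofiler.cnv import window_counts
from arvprofiler.junctions import count_junctions
from arvprofiler.synthetic import (
    CohortSpec,
    DnaTruth,
    GroupSpec,
    GsrEvent,
    ParameterError,
    RnaTruth,
    generate_cohort,
    isoform_mixture,
    simulate_cohort,
    simulate_dna_reads,
    simulate_rna_reads,
    transcript_sequence,
)


def _binom99(n, p):
    return binom.ppf(0.005, n, p), binom.ppf(0.995, n, p)


class TestIsoformMixture:
    def test_pure_full_length(self, panel):
        assert isoform_mixture(panel, {}) == {"AR-FL": 1.0}

    def test_group_fractions_are_realised(self, panel):
        fr = {"AR-V7": 0.10, "AR-V9": 0.05, "AR-V3": 0.04}
        w = isoform_mixture(panel, fr)
        assert w["AR-FL"] + sum(w[v] for v in fr) == pytest.approx(1.0)
        # fraction of E3-anchored transcripts that are V7
        e3_mass = w["AR-FL"] + w["AR-V7"] + w["AR-V9"]
        assert w["AR-V7"] / e3_mass == pytest.approx(0.10)
        assert w["AR-V9"] / e3_mass == pytest.approx(0.05)
        # all transcripts carry E2
        assert w["AR-V3"] == pytest.approx(0.04)

    def test_mass_above_one_rejected(self, panel):
        with pytest.raises(ParameterError):
            isoform_mixture(panel, {"AR-V7": 0.7, "AR-V9": 0.4})


class TestRnaSimulation:
    def test_single_isoform_every_junction_read_is_v7(self, panel, matcher):
        truth = RnaTruth({"AR-V7": 1.0}, depth=100, error_rate=0.0, seed=1)
        reads, rec = simulate_rna_reads(panel, truth)
        assert set(rec.n_reads) == {"AR-V7"}
        counts = count_junctions([r.sequence for r in reads], matcher)
        v7 = panel.junction_for_variant("AR-V7")
        for j, n in counts.counts.items():
            if j != v7 and j.upstream not in ("E1", "E2"):
                assert n == 0
        assert counts.get(v7) == rec.junction_spanning[v7]

    def test_pure_fl_matches_no_variant_signature(self, panel, matcher):
        truth = RnaTruth({}, depth=100, error_rate=0.0, seed=2)
        reads, _ = simulate_rna_reads(panel, truth)
        counts = count_junctions([r.sequence for r in reads], matcher)
        assert all(counts.get(j) == 0 for j in panel.variant_junctions())

    def test_v7_share_within_binomial_99_interval(self, panel):
        truth = RnaTruth({"AR-V7": 0.10}, depth=2000, error_rate=0.0, seed=3)
        _, rec = simulate_rna_reads(panel, truth)
        v7 = panel.junction_for_variant("AR-V7")
        denom = rec.group_denominator(panel, "E3")
        lo, hi = _binom99(denom, 0.10)
        assert lo <= rec.junction_spanning[v7] <= hi

    def test_determinism_and_conservation(self, panel):
        truth = RnaTruth({"AR-V7": 0.05}, depth=300, seed=4)
        r1, rec1 = simulate_rna_reads(panel, truth)
        r2, rec2 = simulate_rna_reads(panel, truth)
        assert r1 == r2
        assert rec1.junction_spanning == rec2.junction_spanning
        assert len(r1) == sum(rec1.n_reads.values())

    def test_unknown_variant_rejected(self, panel):
        with pytest.raises(Exception):
            simulate_rna_reads(panel, RnaTruth({"AR-V99": 0.1}))


class TestDnaSimulation:
    def test_neutral_coverage_ratio_near_one(self, panel):
        truth = DnaTruth(ar_copy_number=2.0, control_copy_number=2.0,
                         depth=300, seed=5)
        _, rec = simulate_dna_reads(panel, truth)
        ar = window_counts(rec.read_positions, panel.dna_targets)
        ctrl = window_counts(rec.read_positions, panel.control_targets)
        ratio = np.mean([w.raw_count for w in ar]) / np.mean(
            [w.raw_count for w in ctrl]
        )
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_full_vaf_deletion_leaves_no_spanning_fragments(self, panel):
        ev = GsrEvent(1200, 2200, "deletion", 1.0)
        truth = DnaTruth(gsr_events=[ev], depth=500, seed=6)
        _, rec = simulate_dna_reads(panel, truth)
        et = rec.events[0]
        assert et.n_junction_fragments > 0
        assert et.n_reference_spanning_reads == 0

    def test_hotspot_alt_count_binomial(self, panel):
        truth = DnaTruth(hotspot_vafs={"T878A": 0.25}, depth=400, seed=7)
        _, rec = simulate_dna_reads(panel, truth)
        ht = rec.hotspots["T878A"]
        lo, hi = _binom99(ht.n_fragments, 0.25)
        assert lo <= ht.n_alt_fragments <= hi

    def test_breakpoint_outside_locus_rejected(self, panel):
        bad = GsrEvent(10, 10**6, "deletion", 0.5)
        with pytest.raises(ParameterError):
            simulate_dna_reads(panel, DnaTruth(gsr_events=[bad]))

    def test_coverage_linear_in_copy_number(self, panel):
        levels = [1, 2, 6, 20, 68]
        per_copy = []
        for cn in levels:
            depth = 600.0 if cn <= 2 else 200.0  # comparable per-level precision
            truth = DnaTruth(ar_copy_number=cn, depth=depth, seed=100 + cn)
            _, rec = simulate_dna_reads(panel, truth)
            ar = window_counts(rec.read_positions, panel.dna_targets)
            # interior windows only: read starts thin out near locus ends
            interior = [w.raw_count for w in ar if 400 <= w.interval.start <= 2800]
            per_copy.append(np.mean(interior) / (cn * depth))
        slope = np.mean(per_copy)
        assert np.all(np.abs(np.array(per_copy) / slope - 1.0) < 0.05)

    def test_determinism(self, panel):
        truth = DnaTruth(depth=100, seed=8)
        r1, _ = simulate_dna_reads(panel, truth)
        r2, _ = simulate_dna_reads(panel, truth)
        assert r1 == r2


class TestCohortGeneration:
    def _tiny_spec(self, seed=0):
        groups = [
            GroupSpec("g1", 3, {"AR-V7": (0.02, 0.12)}, rna_depth=60, dna_depth=30),
            GroupSpec("g2", 3, {}, rna_depth=60, dna_depth=30),
        ]
        return CohortSpec(groups=groups, seed=seed)

    def test_layout_and_truth_rows(self, panel, tmp_path):
        truth = generate_cohort(panel, self._tiny_spec(), tmp_path / "c1")
        assert len(truth) == 6
        dirs = sorted(p.name for p in (tmp_path / "c1").iterdir() if p.is_dir())
        assert dirs == sorted(truth["sample"])
        for d in dirs:
            assert (tmp_path / "c1" / d / "rna.fastq").exists()
            assert (tmp_path / "c1" / d / "dna_1.fastq").exists()

    def test_truth_table_byte_identical_across_runs(self, panel, tmp_path):
        generate_cohort(panel, self._tiny_spec(seed=9), tmp_path / "a")
        generate_cohort(panel, self._tiny_spec(seed=9), tmp_path / "b")
        assert (tmp_path / "a" / "truth.tsv").read_bytes() == (
            tmp_path / "b" / "truth.tsv"
        ).read_bytes()

    def test_fraction_distribution_support(self, panel):
        spec = CohortSpec(
            groups=[GroupSpec("CRPC", 12, {"AR-V7": (0.02, 0.12)}, rna_depth=50,
                              dna_depth=20)],
            seed=11,
        )
        for s in simulate_cohort(panel, spec, include_dna=False):
            f = s.rna_truth.isoform_fractions["AR-V7"]
            assert 0.02 <= f <= 0.12


def test_transcript_sequence_matches_exon_concatenation(panel):
    seq, boundaries = transcript_sequence(panel, "AR-V7")
    exons = [panel.exon_by_id(e).sequence for e in ("E1", "E2", "E3", "CE3")]
    assert seq == "".join(exons)
    v7 = panel.junction_for_variant("AR-V7")
    assert (v7, sum(len(e) for e in exons[:3])) in boundaries
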