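import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import OracleScanner, cp_lower_bisect, oracle_assign_pure
from arvprofiler._seq import revcomp
from arvprofiler.gene_model import Exon, Interval, JunctionDef, PanelConfig
from arvprofiler.junctions import (
    JunctionCounts,
    SignatureError,
    SignatureMatcher,
    assign_read,
    build_signatures,
    clopper_pearson_lower,
    count_junctions,
    quantify_fractions,
    total_arv_fraction,
)
from arvprofiler.synthetic import RnaTruth, simulate_rna_reads, transcript_sequence


class TestBuildSignatures:
    def test_full_flank_length_and_offset(self, panel, signatures):
        # all mock exons are >= 130 bp, so every signature is 130 + 130
        assert all(len(s.sequence) == 260 for s in signatures)
        assert all(s.junction_offset == 130 for s in signatures)

    def test_short_upstream_exon_truncates(self):
        seq = "".join(
            np.random.default_rng(0).choice(list("ACGT"), size=400)
        )
        panel = PanelConfig(
            locus_name="mini",
            locus_sequence=seq,
            exons=[Exon("E1", 10, 50, seq[10:50]), Exon("E2", 100, 380, seq[100:380])],
            junctions=[JunctionDef("AR-FL", "E1", "E2")],
            dna_targets=[Interval("mini", 0, 400)],
            control_targets=[],
            rna_genes=[],
            hotspots=[],
        ).validate()
        (sig,) = build_signatures(panel)
        assert len(sig.sequence) == 40 + 130
        assert sig.junction_offset == 40

    def test_signature_matches_exon_boundary(self, panel, signatures):
        for sig in signatures:
            up = panel.exon_by_id(sig.junction.upstream).sequence
            down = panel.exon_by_id(sig.junction.downstream).sequence
            assert sig.sequence == up[-130:] + down[:130]

    def test_duplicate_signatures_error_names_both(self, panel):
        # two junctions to cryptic exons with identical leading sequence
        seq = panel.locus_sequence
        ce3 = panel.exon_by_id("CE3")
        dup = seq[: ce3.start] + ce3.sequence + seq[ce3.start + 160 :]
        exons = [e if e.id != "CE4" else Exon("CE4", e.start, e.end, ce3.sequence)
                 for e in panel.exons]
        from dataclasses import replace

        broken = replace(panel, locus_sequence=dup, exons=exons)
        with pytest.raises(SignatureError, match="E3->CE3"):
            build_signatures(broken)


class TestAssignRead:
    def test_exact_center_read(self, panel, signatures, matcher):
        sig = next(s for s in signatures if s.junction.variant_name == "AR-V7")
        read = sig.sequence[55:205]  # central 150 bp, 75 each side
        assert matcher.assign(read) == sig.junction
        assert assign_read(read, signatures) == sig.junction

    def test_exon_interior_read_unassigned(self, panel, matcher):
        e3 = panel.exon_by_id("E3")
        read = e3.sequence[5:155]  # matches several signatures, overhang 0
        assert matcher.assign(read) is None

    def test_two_mismatches_still_assigns_v7(self, panel, signatures, matcher):
        sig = next(s for s in signatures if s.junction.variant_name == "AR-V7")
        read = list(sig.sequence[40:190])
        for pos in (20, 110):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        assert matcher.assign(read) == sig.junction
        assert oracle_assign_pure(read, signatures) == sig.junction

    def test_reverse_complement_orientation(self, panel, signatures, matcher):
        sig = next(s for s in signatures if s.junction.variant_name == "AR-V9")
        read = revcomp(sig.sequence[60:210])
        assert matcher.assign(read) == sig.junction

    def test_matches_pure_oracle_on_mixed_reads(self, panel, signatures, matcher):
        rng = np.random.default_rng(42)
        seq_v7, _ = transcript_sequence(panel, "AR-V7")
        seq_fl, _ = transcript_sequence(panel, "AR-FL")
        reads = []
        for _ in range(60):
            src = seq_v7 if rng.random() < 0.5 else seq_fl
            s = int(rng.integers(0, len(src) - 150))
            read = list(src[s : s + 150])
            for _ in range(int(rng.integers(0, 5))):  # up to 4 substitutions
                p = int(rng.integers(150))
                read[p] = "ACGT"[rng.integers(4)]
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(read)
        reads.append("".join(rng.choice(list("ACGT"), size=150)))  # random seq
        for read in reads:
            assert matcher.assign(read) == oracle_assign_pure(read, signatures)


class TestCountJunctions:
    def test_exact_center_reads_counted(self, signatures, matcher):
        sig = signatures[0]
        reads = [sig.sequence[55:205]] * 100
        counts = count_junctions(reads, matcher)
        assert counts.get(sig.junction) == 100
        assert sum(counts.counts.values()) == 100
        assert counts.n_unassigned == 0

    def test_empty_read_set(self, matcher):
        counts = count_junctions([], matcher)
        assert all(v == 0 for v in counts.counts.values())

    def test_matches_bruteforce_oracle_on_simulated_sample(
        self, panel, signatures, matcher
    ):
        truth = RnaTruth(
            {"AR-V7": 0.08, "AR-V3": 0.05}, depth=300, error_rate=0.002, seed=21
        )
        reads, _ = simulate_rna_reads(panel, truth)
        seqs = [r.sequence for r in reads]
        scanner = OracleScanner(signatures, read_length=150)
        expected = [scanner.assign(s) for s in seqs]
        got = matcher.assign_many(seqs)
        assert got == expected


class TestQuantifyFractions:
    def _counts(self, panel, mapping):
        counts = {j: 0 for j in panel.junctions}
        for (up, down), n in mapping.items():
            j = next(j for j in panel.junctions if j.key == (up, down))
            counts[j] = n
        return JunctionCounts(counts=counts)

    def test_fraction_arithmetic(self, panel):
        counts = self._counts(panel, {("E3", "E4"): 90, ("E3", "CE3"): 10})
        by_name = {f.variant_name: f for f in quantify_fractions(counts, panel)}
        v7 = by_name["AR-V7"]
        assert (v7.numerator, v7.denominator) == (10, 100)
        assert v7.fraction == pytest.approx(0.10)

    def test_zero_numerator(self, panel):
        counts = self._counts(panel, {("E3", "E4"): 50})
        v7 = {f.variant_name: f for f in quantify_fractions(counts, panel)}["AR-V7"]
        assert v7.fraction == 0.0 and v7.ci95_lower == 0.0

    def test_zero_denominator_not_quantifiable(self, panel):
        counts = self._counts(panel, {})
        for f in quantify_fractions(counts, panel):
            assert f.fraction is None and f.ci95_lower is None

    def test_group_fractions_sum_to_one(self, panel):
        counts = self._counts(
            panel, {("E3", "E4"): 70, ("E3", "CE3"): 20, ("E3", "CE5"): 10}
        )
        fractions = quantify_fractions(counts, panel, include_canonical=True)
        e3 = [f for f in fractions if f.junction.upstream == "E3"]
        assert sum(f.fraction for f in e3) == pytest.approx(1.0)

    def test_total_arv_fraction(self, panel):
        counts = self._counts(
            panel,
            {("E3", "E4"): 90, ("E3", "CE3"): 5, ("E3", "CE5"): 5,
             ("E2", "E3"): 98, ("E2", "CE4"): 2},
        )
        fractions = quantify_fractions(counts, panel)
        total = total_arv_fraction(fractions)
        assert total == pytest.approx(0.05 + 0.05 + 0.02)

    def test_total_arv_not_quantifiable_propagates(self, panel):
        counts = self._counts(panel, {("E3", "E4"): 90, ("E3", "CE3"): 10})
        # E2 group has zero denominator, so AR-V3 is not quantifiable
        assert total_arv_fraction(quantify_fractions(counts, panel)) is None


class TestClopperPearson:
    def test_matches_bisection_oracle(self):
        assert clopper_pearson_lower(10, 100) == pytest.approx(
            cp_lower_bisect(10, 100), abs=1e-8
        )
        assert clopper_pearson_lower(10, 100) == pytest.approx(0.049, abs=5e-4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(1, 500), frac=st.floats(0, 1))
    def test_lower_bound_below_fraction(self, n, frac):
        k = int(round(n * frac))
        lo = clopper_pearson_lower(k, n)
        assert 0.0 <= lo <= k / n

    def test_converges_to_fraction_with_depth(self):
        gaps = [0.10 - clopper_pearson_lower(n // 10, n) for n in (100, 1000, 10000)]
        assert gaps[0] > gaps[1] > gaps[2] > 0
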