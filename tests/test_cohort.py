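import numpy as np
import pytest

from _oracles import mw_exact_enum, spearman_oracle
from arvprofiler.cohort import (
    CohortError,
    SampleSummary,
    build_cohort_table,
    holm_adjust,
    mann_whitney_u,
    spearman,
    write_cohort_tsv,
)
from arvprofiler.junctions import VariantFraction


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        comp = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert comp.p_two_sided == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_small_groups(self):
        comp = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert comp.U == 0.0
        assert comp.method == "exact"
        assert comp.p_two_sided == pytest.approx(0.1)

    def test_symmetry_and_u_complement(self):
        a, b = [1.2, 3.4, 2.2, 9.0], [0.5, 4.4, 7.7]
        c1 = mann_whitney_u(a, b)
        c2 = mann_whitney_u(b, a)
        assert c1.p_two_sided == pytest.approx(c2.p_two_sided)
        assert c1.U + c2.U == len(a) * len(b)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(61)
        for _ in range(30):
            na = int(rng.integers(2, 6))
            nb = int(rng.integers(2, 11 - na))
            pooled = rng.permutation(np.arange(1.0, na + nb + 1))  # untied
            a, b = pooled[:na], pooled[na:]
            comp = mann_whitney_u(a, b)
            u_oracle, p_oracle = mw_exact_enum(a, b)
            assert comp.U == pytest.approx(u_oracle)
            assert comp.p_two_sided == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(CohortError):
            mann_whitney_u([], [1.0])

    def test_ties_fall_back_to_asymptotic(self):
        comp = mann_whitney_u([1, 1, 2], [2, 3, 3])
        assert comp.method == "asymptotic"
        assert 0 < comp.p_two_sided <= 1


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0 and p == 0.0
        rho, _ = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == -1.0

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(62)
        for _ in range(25):
            n = int(rng.integers(5, 20))
            x = rng.integers(0, 8, size=n).astype(float)  # ties likely
            y = x * 0.5 + rng.normal(size=n)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            rho, p = spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)
            assert 0 <= p <= 1

    def test_tied_fixture_of_eight(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        y = [2.1, 0.4, 3.3, 3.1, 5.0, 4.9, 7.2, 6.8]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(CohortError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_small_rejected(self):
        with pytest.raises(CohortError):
            spearman([1, 2, 3], [1, 2, 3])


def test_holm_adjustment_ordering():
    adj = holm_adjust([0.01, 0.04, 0.03])
    assert adj == pytest.approx([0.03, 0.06, 0.06])


# ---------------------------------------------------------------------------


def _fractions(panel, v3, v7, v9, denom=1000):
    out = []
    for name, frac in (("AR-V3", v3), ("AR-V7", v7), ("AR-V9", v9)):
        j = panel.junction_for_variant(name)
        k = int(round(frac * denom))
        from arvprofiler.junctions import clopper_pearson_lower

        out.append(VariantFraction(name, j, k, denom, k / denom,
                                   clopper_pearson_lower(k, denom)))
    return out


def _summary(panel, sid, group, v=0.0, score=0.0, ar_fl=500):
    return SampleSummary(
        sample_id=sid, group=group, signalling_score=score,
        arv_fractions=_fractions(panel, v, v, v), ar_fl_count=ar_fl,
    )


class TestCohortTable:
    def test_identical_groups_give_p_one_and_fixed_frequencies(self, panel):
        summaries = [
            _summary(panel, f"a{i}", "g1", v=0.02) for i in range(3)
        ] + [_summary(panel, f"b{i}", "g2", v=0.02) for i in range(3)]
        res = build_cohort_table(summaries)
        assert res.comparisons.loc[0, "p_two_sided"] == pytest.approx(1.0)
        freq = res.frequency.set_index("group")
        assert (freq["n_arv_high"] == [3, 3]).all()

    def test_frequency_rows_sum_to_group_sizes(self, panel):
        summaries = (
            [_summary(panel, f"a{i}", "g1", v=0.001 * (i + 1)) for i in range(4)]
            + [_summary(panel, f"b{i}", "g2", v=0.03 * (i + 1)) for i in range(3)]
        )
        summaries[0].arv_fractions = None  # assay not run
        res = build_cohort_table(summaries)
        freq = res.frequency.set_index("group")
        level_cols = [c for c in freq.columns if c.startswith("n_arv")]
        assert (freq[level_cols].sum(axis=1) == freq["n"]).all()

    def test_missing_fractions_excluded_pairwise_complete(self, panel):
        summaries = (
            [_summary(panel, f"a{i}", "g1", v=0.01) for i in range(4)]
            + [_summary(panel, f"b{i}", "g2", v=0.08) for i in range(4)]
        )
        summaries[0].arv_fractions = None
        res = build_cohort_table(summaries)
        assert res.comparisons.loc[0, "n_a"] + res.comparisons.loc[0, "n_b"] == 7
        assert sum(res.n_excluded.values()) == 1

    def test_single_group_rejected(self, panel):
        with pytest.raises(CohortError):
            build_cohort_table([_summary(panel, "a", "g1")])

    def test_table_roundtrip_exact(self, panel, tmp_path):
        rng = np.random.default_rng(63)
        summaries = [
            _summary(panel, f"s{i}", "g1" if i < 3 else "g2",
                     v=float(rng.random()) * 0.1,
                     score=float(rng.normal()), ar_fl=int(rng.integers(100, 900)))
            for i in range(6)
        ]
        res = build_cohort_table(summaries)
        write_cohort_tsv(res, tmp_path)
        from arvprofiler.cohort import read_cohort_tsv

        back = read_cohort_tsv(tmp_path / "cohort.tsv")
        for col in res.table.columns:
            a, b = res.table[col], back[col]
            if a.dtype.kind == "f":
                assert np.allclose(a.astype(float), b.astype(float),
                                   equal_nan=True, rtol=0, atol=0)
            else:
                assert (a.fillna("").astype(str) == b.fillna("").astype(str)).all()
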