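"""Cohort assembly, group comparisons and frequency summaries.

Per-sample results (mutations, copy number, rearrangements, signalling
score, AR-V fractions) are gathered into one table; combined AR-V3/V7/V9
fractions are compared between sample groups with the two-tailed unpaired
Mann-Whitney U test (exact for small untied samples, normal approximation
with tie and continuity corrections otherwise); associations between variant
expression and full-length AR are measured with Spearman's rank correlation
(p via the asymptotic t approximation); and a per-group frequency table of
mutation / copy-number / AR-V-level calls is produced.

Raw p-values are reported (mirroring a three-comparison design); a Holm
adjustment is available behind a flag.  Missing assay fields are excluded
pairwise-complete, never imputed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cnv import CopyNumberCall
from .expression import classify_arv_level
from .junctions import VariantFraction, total_arv_fraction
from .rearrangements import BreakpointEvent
from .variants import VariantCall

logger = logging.getLogger(__name__)

EXACT_MW_MAX_N = 20


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_two_sided: float
    method: str  # "exact" | "asymptotic"


def mann_whitney_u(
    values_a, values_b, group_a: str = "a", group_b: str = "b"
) -> GroupComparison:
    """Two-tailed unpaired Mann-Whitney U test.

    Exact p (full enumeration) when the pooled sample is small (n <= 20) and
    untied, otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise CohortError("empty group in Mann-Whitney comparison")
    pooled = np.concatenate([a, b])
    untied = np.unique(pooled).size == pooled.size
    if untied and pooled.size <= EXACT_MW_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        U=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method=method,
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rank correlation with midrank ties; two-sided p from the
    asymptotic t approximation with n-2 degrees of freedom."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = x.size
    if n < 4:
        raise CohortError("Spearman correlation requires n >= 4")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise CohortError("Spearman correlation undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def holm_adjust(pvalues: list[float]) -> list[float]:
    order = np.argsort(pvalues)
    m = len(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


# ---------------------------------------------------------------------------
# Sample summaries and the cohort table
# ---------------------------------------------------------------------------


@dataclass
class SampleSummary:
    """One per-sample record; fields are None when the assay was not run."""

    sample_id: str
    group: str
    mutations: list[VariantCall] | None = None
    cn: CopyNumberCall | None = None
    gsr_events: list[BreakpointEvent] | None = None
    signalling_score: float | None = None
    arv_fractions: list[VariantFraction] | None = None
    ar_fl_count: int | None = None

    def total_arv(self, variants=("AR-V3", "AR-V7", "AR-V9")) -> float | None:
        if self.arv_fractions is None:
            return None
        return total_arv_fraction(self.arv_fractions, variants)

    def arv_level(self) -> str | None:
        if self.arv_fractions is None:
            return None
        return classify_arv_level(self.total_arv())


@dataclass
class CohortResult:
    table: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    frequency: pd.DataFrame
    n_excluded: dict[str, int] = field(default_factory=dict)


def _summary_row(s: SampleSummary) -> dict:
    row: dict = {"sample": s.sample_id, "group": s.group}
    if s.mutations is None:
        row["mutations"] = None
        row["hotspots"] = None
    else:
        row["mutations"] = ";".join(
            f"{m.chrom}:{m.position}{m.ref}>{m.alt}" for m in s.mutations
        )
        row["hotspots"] = ";".join(
            m.hotspot_name for m in s.mutations if m.hotspot_name
        )
    row["cn_estimate"] = None if s.cn is None else s.cn.cn_estimate
    row["cn_label"] = None if s.cn is None else s.cn.label
    row["n_gsr_events"] = None if s.gsr_events is None else len(s.gsr_events)
    row["signalling_score"] = s.signalling_score
    if s.arv_fractions is not None:
        for f in s.arv_fractions:
            # reported as CI95 lower bounds, alongside the point estimates
            row[f"ci95_lower_{f.variant_name}"] = f.ci95_lower
            row[f"fraction_{f.variant_name}"] = f.fraction
            row[f"count_{f.variant_name}"] = f.numerator
    row["ar_fl_count"] = s.ar_fl_count
    row["total_arv_fraction"] = s.total_arv()
    row["arv_level"] = s.arv_level()
    return row


def build_cohort_table(
    summaries: list[SampleSummary],
    group_pairs: list[tuple[str, str]] | None = None,
    variants: tuple[str, ...] = ("AR-V3", "AR-V7", "AR-V9"),
    holm: bool = False,
) -> CohortResult:
    """Cohort matrix plus group comparisons, correlations and frequencies."""
    groups = sorted({s.group for s in summaries})
    if len(groups) < 2:
        raise CohortError("cohort table requires >= 2 groups")
    table = pd.DataFrame([_summary_row(s) for s in summaries])

    if group_pairs is None:
        group_pairs = list(itertools.combinations(groups, 2))

    n_excluded: dict[str, int] = {}
    comparisons = []
    for ga, gb in group_pairs:
        va = table.loc[table.group == ga, "total_arv_fraction"].dropna()
        vb = table.loc[table.group == gb, "total_arv_fraction"].dropna()
        excluded = int(
            ((table.group == ga) | (table.group == gb)).sum() - len(va) - len(vb)
        )
        if excluded:
            n_excluded[f"{ga}_vs_{gb}"] = excluded
            logger.warning(
                "%d samples excluded from %s vs %s (missing AR-V fractions)",
                excluded, ga, gb,
            )
        comp = mann_whitney_u(va, vb, ga, gb)
        comparisons.append(
            {
                "group_a": ga, "group_b": gb, "n_a": comp.n_a, "n_b": comp.n_b,
                "U": comp.U, "p_two_sided": comp.p_two_sided, "method": comp.method,
            }
        )
    comparisons = pd.DataFrame(comparisons)
    if holm and len(comparisons):
        comparisons["p_holm"] = holm_adjust(comparisons["p_two_sided"].tolist())

    correlations = []
    pairs = [(f"fraction_{v}", "ar_fl_count", f"{v}_vs_AR-FL") for v in variants]
    pairs.append(("total_arv_fraction", "ar_fl_count", "combined_vs_AR-FL"))
    pairs += [
        (f"fraction_{va}", f"fraction_{vb}", f"{va}_vs_{vb}")
        for va, vb in itertools.combinations(variants, 2)
    ]
    for xcol, ycol, name in pairs:
        if xcol not in table.columns or ycol not in table.columns:
            continue
        sub = table[[xcol, ycol]].dropna()
        try:
            rho, p = spearman(sub[xcol], sub[ycol])
        except CohortError:
            continue
        correlations.append({"pair": name, "n": len(sub), "rho": rho, "p": p})
    correlations = pd.DataFrame(correlations)

    freq_rows = []
    for g in groups:
        sub = table[table.group == g]
        row = {"group": g, "n": len(sub)}
        muts = sub["mutations"].dropna()
        row["n_mutation"] = int((muts != "").sum())
        row["n_cn_gain"] = int((sub["cn_label"] == "gain").sum())
        row["n_cn_amplification"] = int((sub["cn_label"] == "amplification").sum())
        row["n_gsr"] = int((sub["n_gsr_events"].dropna() > 0).sum())
        for level in ("negative", "low", "high", "not_assessable"):
            row[f"n_arv_{level}"] = int((sub["arv_level"] == level).sum())
        row["n_arv_missing"] = int(sub["arv_level"].isna().sum())
        freq_rows.append(row)
    frequency = pd.DataFrame(freq_rows)

    return CohortResult(
        table=table,
        comparisons=comparisons,
        correlations=correlations,
        frequency=frequency,
        n_excluded=n_excluded,
    )


def write_cohort_tsv(result: CohortResult, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # shortest round-trip float formatting keeps the TSVs value-exact
    fmt = {"sep": "\t", "index": False, "float_format": lambda v: repr(float(v))}
    result.table.to_csv(outdir / "cohort.tsv", **fmt)
    result.comparisons.to_csv(outdir / "comparisons.tsv", **fmt)
    result.correlations.to_csv(outdir / "correlations.tsv", **fmt)
    result.frequency.to_csv(outdir / "frequency.tsv", **fmt)


def read_cohort_tsv(path) -> pd.DataFrame:
    # round_trip parsing keeps re-read floats bit-identical to what was written
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
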