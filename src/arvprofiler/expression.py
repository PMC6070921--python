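"""Housekeeping-normalised expression and the summed z-score AR-signalling
statistic, plus the AR-V expression-level classification.

Per-sample gene counts are scaled by the geometric mean of the sample's
housekeeping-gene counts (with a 0.5 pseudocount for robustness to single
dropouts); per-gene z-scores are computed across the cohort (ddof = 1) and
the AR-signalling score is their sum over the five androgen-responsive
genes.  Total AR-V fractions are binned into negative (0), low (up to 5% of
AR transcript) and high (above 5%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gene_model import PanelConfig

PSEUDOCOUNT = 0.5
ARV_LEVEL_THRESHOLD = 0.05


class ExpressionError(ValueError):
    pass


def normalize_counts(
    counts: pd.DataFrame, housekeeping: list[str], pseudocount: float = PSEUDOCOUNT
) -> pd.DataFrame:
    """Divide each sample's counts by the geometric mean of its housekeeping
    counts (+pseudocount).  Rows are samples, columns genes."""
    missing = [g for g in housekeeping if g not in counts.columns]
    if missing:
        raise ExpressionError(f"housekeeping genes missing from matrix: {missing}")
    if (counts.values < 0).any():
        raise ExpressionError("negative counts")
    hk = counts[housekeeping].astype(float)
    all_zero = (hk.sum(axis=1) == 0)
    if all_zero.any():
        raise ExpressionError(
            "samples with all-zero housekeeping counts (non-normalizable): "
            f"{list(counts.index[all_zero])}"
        )
    size_factor = np.exp(np.log(hk + pseudocount).mean(axis=1))
    return counts.div(size_factor, axis=0)


def signalling_score(
    normalized: pd.DataFrame, ar_regulated: list[str]
) -> pd.Series:
    """Per-sample AR-signalling score: sum of cohort z-scores of the
    AR-regulated genes.  Zero-variance genes contribute z = 0."""
    if len(normalized) < 3:
        raise ExpressionError("signalling score requires a cohort of >= 3 samples")
    missing = [g for g in ar_regulated if g not in normalized.columns]
    if missing:
        raise ExpressionError(f"AR-regulated genes missing from matrix: {missing}")
    sub = normalized[ar_regulated].astype(float)
    sd = sub.std(axis=0, ddof=1)
    centred = sub - sub.mean(axis=0)
    z = centred.div(sd.replace(0.0, np.inf), axis=1)
    score = z.sum(axis=1)
    score.name = "signalling_score"
    return score


def score_matrix(counts: pd.DataFrame, panel: PanelConfig) -> pd.Series:
    normalized = normalize_counts(counts, panel.housekeeping_genes())
    return signalling_score(normalized, panel.ar_regulated_genes())


def classify_arv_level(total_fraction: float | None) -> str:
    """AR-V expression level: negative (0), low (<=5%), high (>5%); samples
    without a quantifiable fraction are not assessable."""
    if total_fraction is None:
        return "not_assessable"
    if not (0.0 <= total_fraction <= 1.0 + 1e-9):
        raise ExpressionError(f"fraction {total_fraction} outside [0, 1]")
    if total_fraction == 0.0:
        return "negative"
    if total_fraction <= ARV_LEVEL_THRESHOLD:
        return "low"
    return "high"


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return df


def write_scores_tsv(scores: pd.Series, levels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tsignalling_score\tarv_level\n")
        for sample, score in scores.items():
            fh.write(f"{sample}\t{score:.6g}\t{levels.get(sample, 'not_assessable')}\n")
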