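"""Window-coverage copy-number estimation over the targeted panel.

Aligned read counts are collected in overlapping 400 bp windows along the
capture targets; each AR-locus window count is divided by the median control
window count, and the median of those ratios, rescaled by the control
ploidy, is the AR copy-number estimate.  Classification follows the copy
thresholds: gain for more than one AR copy, amplification for more than two.

Normalisation is within-sample (AR windows against autosomal control-gene
windows), which removes library-depth effects without needing a reference
cohort.  Reads are counted by start position, which is unbiased for
uniformly placed reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_model import Interval, PanelConfig

DEFAULT_WINDOW = 400
DEFAULT_STEP = 200


class CnvError(ValueError):
    pass


@dataclass(frozen=True)
class CoverageWindow:
    interval: Interval
    raw_count: int
    ratio: float = float("nan")


def window_counts(
    read_positions: dict[str, np.ndarray],
    targets: list[Interval],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[CoverageWindow]:
    """Tile each target with overlapping windows and count read starts.

    ``read_positions`` maps sequence name to (not necessarily sorted) read
    start coordinates.  Windows are placed at ``step`` intervals from each
    target start and must lie fully inside the target.
    """
    if not targets:
        raise CnvError("no targets given")
    if step > window:
        raise CnvError(f"step {step} > window {window}: windows would not overlap")
    if step < 1 or window < 1:
        raise CnvError("window and step must be positive")
    out: list[CoverageWindow] = []
    for target in targets:
        pos = np.sort(np.asarray(read_positions.get(target.chrom, []), dtype=int))
        for start in range(target.start, target.end - window + 1, step):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, start + window, side="left")
            out.append(
                CoverageWindow(
                    Interval(target.chrom, start, start + window), int(hi - lo)
                )
            )
    return out


@dataclass(frozen=True)
class CopyNumberCall:
    cn_estimate: float
    label: str  # neutral | gain | amplification
    n_ar_windows: int = 0
    n_control_windows: int = 0


def classify_cn(cn_estimate: float) -> str:
    """Copy-number label: amplification above two copies, gain above one."""
    if cn_estimate > 2.0:
        return "amplification"
    if cn_estimate > 1.0:
        return "gain"
    return "neutral"


def normalize_and_estimate(
    ar_windows: list[CoverageWindow],
    control_windows: list[CoverageWindow],
    control_ploidy: float = 2.0,
) -> CopyNumberCall:
    """Median-of-ratios copy-number estimate.

    Each AR window count is divided by the median control window count; the
    median ratio times ``control_ploidy`` expresses the estimate in copies,
    so an unaltered one-copy X-linked locus in a male sample reports 1.0.
    """
    if not ar_windows or not control_windows:
        raise CnvError("need at least one AR window and one control window")
    control = np.array([w.raw_count for w in control_windows], dtype=float)
    med_control = float(np.median(control))
    if med_control <= 0:
        raise CnvError("all-zero control coverage; cannot normalise")
    ratios = np.array([w.raw_count for w in ar_windows], dtype=float) / med_control
    cn = float(np.median(ratios)) * control_ploidy
    return CopyNumberCall(
        cn_estimate=cn,
        label=classify_cn(cn),
        n_ar_windows=len(ar_windows),
        n_control_windows=len(control_windows),
    )


def call_copy_number(
    read_positions: dict[str, np.ndarray],
    panel: PanelConfig,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> CopyNumberCall:
    """Window counting plus normalisation against the panel's control targets."""
    ar = window_counts(read_positions, panel.dna_targets, window, step)
    control = window_counts(read_positions, panel.control_targets, window, step)
    return normalize_and_estimate(ar, control, control_ploidy=panel.control_ploidy)


def write_windows_bed(windows: list[CoverageWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.interval.chrom}\t{w.interval.start}\t{w.interval.end}\t"
                f"{w.raw_count}\n"
            )
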