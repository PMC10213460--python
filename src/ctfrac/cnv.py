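"""Copy-number analysis from binned read depth: log2 ratios, exact
piecewise-constant segmentation, SCA calling and coverage breadth.

Depth is consumed as a pre-binned BED-like table (chrom, start, end, mean
depth), as produced by samtools-style coverage summaries, so the module is
alignment-tool-agnostic.  Per-bin log2 copy ratios are taken against the
median autosomal depth, segmented by an exact dynamic program (least
squares plus a per-segment penalty), and screened for the clinically
relevant neuroblastoma aberrations: MYCN amplification, 11q deletion, and
any other segmental chromosomal aberration (SCA).  In a tumor/normal
mixture at tumor fraction f a segment of tumor copy number CN has expected
ratio ((1-f)*2 + f*CN)/2; inverting this at an assumed CN yields a simple
tumor-fraction estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCAReport",
    "BreadthReport",
    "GRCH38_WINDOWS",
    "normalize_log2",
    "segment",
    "call_segments",
    "call_sca",
    "coverage_breadth",
    "estimate_tumor_fraction",
    "estimate_tumor_fraction_from_segments",
]

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"

#: Default genomic windows (GRCh38): the MYCN locus on 2p24 and the q arm
#: of chromosome 11 (centromere to q terminus).
GRCH38_WINDOWS: dict[str, tuple[str, int, int]] = {
    "mycn": ("chr2", 15_900_000, 16_100_000),
    "chr11q": ("chr11", 53_400_000, 135_086_622),
}

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass(frozen=True)
class SCAReport:
    """Per-sample segmental-chromosomal-aberration summary."""

    sample_id: str
    mycn_amplified: bool
    del11q: bool
    other_sca: int

    @property
    def any_sca(self) -> bool:
        return self.mycn_amplified or self.del11q or self.other_sca > 0


@dataclass(frozen=True)
class BreadthReport:
    """Length-weighted fraction of bins at or above each depth threshold."""

    thresholds: tuple[float, ...]
    fractions: tuple[float, ...]


def normalize_log2(bins: pd.DataFrame) -> pd.DataFrame:
    """Per-bin log2 depth ratio against the median autosomal depth.

    Zero-depth bins are masked (NaN ratio) and sex chromosomes are excluded
    from the normalization median.  Returns a copy of the input with a
    ``log2_ratio`` column, sorted by (chrom, start).
    """
    for col in ("chrom", "start", "end", "depth"):
        if col not in bins.columns:
            raise ValueError(f"depth table missing column {col!r}")
    if (bins["depth"] < 0).any():
        raise ValueError("negative depth")
    out = bins.sort_values(["chrom", "start"]).reset_index(drop=True).copy()
    autosomal = out.loc[~out["chrom"].isin(SEX_CHROMS) & (out["depth"] > 0), "depth"]
    reference = autosomal if len(autosomal) else out.loc[out["depth"] > 0, "depth"]
    if len(reference) == 0:
        raise ValueError("all bins have zero depth")
    median = float(reference.median())
    with np.errstate(divide="ignore"):
        ratio = np.log2(out["depth"].to_numpy() / median)
    ratio[out["depth"].to_numpy() == 0] = np.nan
    out["log2_ratio"] = ratio
    return out


def _dp_segment_chrom(values: np.ndarray, penalty: float) -> list[tuple[int, int]]:
    """Exact least-squares segmentation of one value array.

    Minimizes sum of within-segment squared errors plus ``penalty`` per
    segment, by O(n^2) dynamic programming.  Returns half-open index
    intervals.
    """
    n = values.size
    s1 = np.concatenate(([0.0], np.cumsum(values)))
    s2 = np.concatenate(([0.0], np.cumsum(values**2)))
    best = np.full(n + 1, np.inf)
    best[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        i = np.arange(j)
        length = j - i
        sse = (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / length
        cost = best[:j] + sse + penalty
        k = int(np.argmin(cost))
        best[j] = cost[k]
        back[j] = k
    bounds = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j))
        j = i
    return bounds[::-1]


def default_penalty(values: np.ndarray) -> float:
    """BIC-flavoured per-segment penalty, 4*sigma^2*log(n), with sigma
    estimated robustly from successive differences.

    The factor 4 (twice the classical BIC rate) keeps isolated noisy bins
    from being split off as their own segments while leaving arm-scale
    steps, whose squared-error gain grows with segment length, easily
    detectable.
    """
    n = values.size
    if n < 2:
        return 1e-8
    diffs = np.abs(np.diff(values))
    sigma = np.median(diffs) / (0.6745 * np.sqrt(2.0))
    return max(4.0 * sigma**2 * np.log(n), 1e-8)


def segment(ratios: pd.DataFrame, penalty: Optional[float] = None) -> pd.DataFrame:
    """Segment per-bin log2 ratios into piecewise-constant pieces.

    ``ratios`` is the output of :func:`normalize_log2`; masked (NaN) bins
    are skipped.  Each chromosome is segmented independently and exactly;
    each segment's value is the mean of its member bins.  Returns a frame
    (chrom, start, end, log2_ratio, n_bins).
    """
    if "log2_ratio" not in ratios.columns:
        raise ValueError("ratios table missing 'log2_ratio' (run normalize_log2)")
    rows = []
    for chrom, sub in ratios.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        sub = sub.loc[np.isfinite(sub["log2_ratio"])]
        if len(sub) == 0:
            continue
        values = sub["log2_ratio"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        pen = default_penalty(values) if penalty is None else penalty
        for i, j in _dp_segment_chrom(values, pen):
            rows.append({
                "chrom": chrom,
                "start": int(starts[i]),
                "end": int(ends[j - 1]),
                "log2_ratio": float(values[i:j].mean()),
                "n_bins": j - i,
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2_ratio",
                                       "n_bins"])


def call_segments(
    segments: pd.DataFrame, gain_log2: float = 0.3, loss_log2: float = -0.3
) -> pd.DataFrame:
    """Annotate segments with a gain/loss/neutral call."""
    out = segments.copy()
    call = np.full(len(out), NEUTRAL, dtype=object)
    call[out["log2_ratio"].to_numpy() >= gain_log2] = GAIN
    call[out["log2_ratio"].to_numpy() <= loss_log2] = LOSS
    out["call"] = call
    return out


def _overlap(seg_start: int, seg_end: int, win_start: int, win_end: int) -> int:
    return max(0, min(seg_end, win_end) - max(seg_start, win_start))


def call_sca(
    segments: pd.DataFrame,
    gain_log2: float = 0.3,
    loss_log2: float = -0.3,
    amp_log2: float = 1.0,
    windows: Mapping[str, tuple[str, int, int]] = GRCH38_WINDOWS,
    del11q_min_fraction: float = 0.25,
    min_sca_bins: int = 5,
    sample_id: str = "",
) -> SCAReport:
    """Call MYCN amplification, 11q deletion and other SCAs from segments.

    MYCN amplification requires a segment overlapping the MYCN window with
    log2 >= ``amp_log2`` (high-level gain; simple gains do not trigger it).
    11q deletion requires at least ``del11q_min_fraction`` of the covered
    11q length to sit in segments with log2 <= ``loss_log2``.  Every other
    non-neutral segment of at least ``min_sca_bins`` bins outside those two
    windows counts toward ``other_sca`` — the size floor keeps isolated
    noisy bins from being reported as segmental aberrations.
    """
    for key in ("mycn", "chr11q"):
        if key not in windows:
            raise ValueError(f"windows config missing {key!r}")
    mycn_chrom, mycn_lo, mycn_hi = windows["mycn"]
    q_chrom, q_lo, q_hi = windows["chr11q"]
    segs = call_segments(segments, gain_log2, loss_log2)

    mycn_amplified = False
    q_total = 0
    q_loss = 0
    other = 0
    for row in segs.itertuples(index=False):
        mycn_ov = row.chrom == mycn_chrom and _overlap(row.start, row.end,
                                                       mycn_lo, mycn_hi) > 0
        if mycn_ov and row.log2_ratio >= amp_log2:
            mycn_amplified = True
        q_ov = _overlap(row.start, row.end, q_lo, q_hi) if row.chrom == q_chrom else 0
        if q_ov > 0:
            q_total += q_ov
            if row.log2_ratio <= loss_log2:
                q_loss += q_ov
        if row.call != NEUTRAL and not mycn_ov and q_ov == 0 \
                and row.n_bins >= min_sca_bins:
            other += 1
    del11q = q_total > 0 and q_loss / q_total >= del11q_min_fraction
    return SCAReport(sample_id=sample_id, mycn_amplified=mycn_amplified,
                     del11q=del11q, other_sca=other)


def coverage_breadth(
    bins: pd.DataFrame, thresholds: Sequence[float] = (10.0, 15.0, 20.0)
) -> BreadthReport:
    """Fraction of the binned reference at or above each depth threshold.

    Fractions are length-weighted so uneven bin sizes are handled; they are
    non-increasing in the threshold by construction.
    """
    lengths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    depth = bins["depth"].to_numpy(dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("empty depth table")
    fractions = tuple(float(lengths[depth >= t].sum() / total) for t in thresholds)
    return BreadthReport(thresholds=tuple(float(t) for t in thresholds),
                         fractions=fractions)


def estimate_tumor_fraction(log2_ratio: float, assumed_cn: float) -> float:
    """Tumor fraction from one aberrant segment's log2 ratio.

    Inverts the mixture expectation ratio = ((1-f)*2 + f*CN)/2, giving
    f = (2*2^log2 - 2)/(CN - 2), clipped to [0, 1].  Undefined at CN = 2.
    """
    if assumed_cn == 2:
        raise ValueError("tumor fraction is undefined for a copy-neutral segment")
    f_hat = (2.0 * 2.0**log2_ratio - 2.0) / (assumed_cn - 2.0)
    return float(np.clip(f_hat, 0.0, 1.0))


def estimate_tumor_fraction_from_bins(
    ratios: pd.DataFrame,
    window: tuple[str, int, int],
    assumed_cn: float,
    recenter: bool = True,
) -> float:
    """Tumor fraction from the mean bin log2 inside a known aberrant window.

    When the aberrant region is known up front (e.g. a diagnostic MYCN or
    11q event), averaging the per-bin ratios inside the window avoids any
    dependence on where the segmenter places boundaries at low
    signal-to-noise.  With ``recenter`` the window mean is taken relative
    to the mean log2 of all other bins, cancelling normalization shifts
    induced by the aberration itself.
    """
    chrom, lo, hi = window
    finite = ratios.loc[np.isfinite(ratios["log2_ratio"])]
    in_win = finite.loc[(finite["chrom"] == chrom)
                        & (finite["end"] > lo) & (finite["start"] < hi)]
    if len(in_win) == 0:
        raise ValueError("no bins inside the requested window")
    mean_log2 = float(in_win["log2_ratio"].mean())
    if recenter:
        out_win = finite.drop(in_win.index)
        if len(out_win):
            mean_log2 -= float(out_win["log2_ratio"].mean())
    return estimate_tumor_fraction(mean_log2, assumed_cn)


def estimate_tumor_fraction_from_segments(
    segments: pd.DataFrame,
    window: tuple[str, int, int],
    assumed_cn: float,
    recenter: bool = True,
) -> float:
    """Tumor fraction from the bin-weighted mean log2 of segments
    overlapping a genomic window of assumed tumor copy number.

    With ``recenter`` (default) the window's log2 is taken relative to the
    length-weighted median log2 of all segments outside the window, which
    removes the shift the aberration itself induces in the global
    normalization median.
    """
    chrom, lo, hi = window
    in_w, in_v, out_w, out_v = [], [], [], []
    for row in segments.itertuples(index=False):
        ov = _overlap(row.start, row.end, lo, hi) if row.chrom == chrom else 0
        if ov > 0:
            in_w.append(ov)
            in_v.append(row.log2_ratio)
        else:
            out_w.append(row.end - row.start)
            out_v.append(row.log2_ratio)
    if not in_w:
        raise ValueError("no segment overlaps the requested window")
    mean_log2 = float(np.average(in_v, weights=in_w))
    if recenter and out_v:
        order = np.argsort(out_v)
        v = np.asarray(out_v, dtype=float)[order]
        w = np.asarray(out_w, dtype=float)[order]
        cum = np.cumsum(w)
        baseline = float(v[np.searchsorted(cum, 0.5 * cum[-1])])
        mean_log2 -= baseline
    return estimate_tumor_fraction(mean_log2, assumed_cn)
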