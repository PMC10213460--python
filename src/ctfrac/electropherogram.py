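"""Electropherogram parsing, nucleosomal-region integration and the
mono-nucleosomal ratio statistic.

Capillary electrophoresis of plasma cfDNA (e.g. an Agilent TapeStation D1000
run) yields a fluorescence-versus-fragment-size trace with internal size
markers at 25 and 1500 bp.  Tumor-derived cfDNA is enriched in
mono-nucleosomal fragments (~100-200 bp), so the area of the 100-200 bp
region divided by the area of the whole low-molecular-weight window
(100-1000 bp) estimates the circulating-tumor-DNA content of the sample.
Samples with a ratio at or above 10% are called ``tumor`` (sufficient ctDNA
for downstream methylome/CNV sequencing), below it ``normal``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "RegionArea",
    "FractionResult",
    "MONO_REGION",
    "LMW_REGION",
    "DEFAULT_RATIO_THRESHOLD",
    "read_trace",
    "subtract_baseline",
    "integrate_region",
    "mono_nucleosomal_ratio",
    "classify_ratio",
    "estimate_mass",
    "flag_qubit_discrepancy",
]

#: Mono-nucleosomal analysis region, bp (half-open).
MONO_REGION = (100.0, 200.0)
#: Total low-molecular-weight analysis region, bp (half-open).
LMW_REGION = (100.0, 1000.0)
#: Decision threshold on the mono-nucleosomal ratio; >= threshold -> tumor.
DEFAULT_RATIO_THRESHOLD = 0.10

TUMOR = "tumor"
NORMAL = "normal"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Trace:
    """A calibrated electropherogram.

    Parameters
    ----------
    sample_id : str
        Sample identifier.
    size_bp : ndarray
        Strictly increasing fragment sizes in bp, length >= 2.
    fluorescence : ndarray
        Non-negative fluorescence intensities, same length as ``size_bp``.
    marker_lower_bp, marker_upper_bp : float
        Positions of the internal alignment markers (default 25 / 1500 bp).
        Both lie outside every analysis region, so marker peaks never
        contribute to region areas.
    """

    sample_id: str
    size_bp: np.ndarray
    fluorescence: np.ndarray
    marker_lower_bp: float = 25.0
    marker_upper_bp: float = 1500.0

    def __post_init__(self) -> None:
        size = np.asarray(self.size_bp, dtype=float)
        fluo = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "size_bp", size)
        object.__setattr__(self, "fluorescence", fluo)
        if size.ndim != 1 or fluo.ndim != 1 or size.shape != fluo.shape:
            raise ValueError("size_bp and fluorescence must be 1-D arrays of equal length")
        if size.size < 2:
            raise ValueError("trace needs at least two points")
        if not np.all(np.diff(size) > 0):
            raise ValueError("size_bp must be strictly increasing")
        if np.any(~np.isfinite(size)) or np.any(~np.isfinite(fluo)):
            raise ValueError("trace contains non-finite values")
        if size[0] > LMW_REGION[0] or size[-1] < LMW_REGION[1]:
            raise ValueError(
                "window incomplete: trace must span at least "
                f"[{LMW_REGION[0]:.0f}, {LMW_REGION[1]:.0f}] bp, "
                f"got [{size[0]:.1f}, {size[-1]:.1f}]"
            )


@dataclass(frozen=True)
class RegionArea:
    """Integrated fluorescence over a bp region, optionally calibrated to ng."""

    lower_bp: float
    upper_bp: float
    area: float
    mass_ng: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lower_bp > self.upper_bp:
            raise ValueError("inverted region bounds")


@dataclass(frozen=True)
class FractionResult:
    """Mono-nucleosomal ratio and tumor/normal call for one trace."""

    sample_id: str
    mono_area: RegionArea
    total_lmw_area: RegionArea
    ratio: float
    threshold: float = DEFAULT_RATIO_THRESHOLD
    label: str = INDETERMINATE


def read_trace(
    path: Union[str, Path], sample_id: Optional[str] = None
) -> Trace:
    """Read a two-column (size_bp, fluorescence) table into a validated Trace.

    A single header line is tolerated; rows are sorted by size and duplicate
    sizes collapsed by mean fluorescence.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        # Drop a header row if the first row is non-numeric.
        first = pd.to_numeric(df.iloc[0], errors="coerce")
        if first.isna().any():
            df = df.iloc[1:]
        df = df.iloc[:, :2].apply(pd.to_numeric, errors="raise")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    if df.shape[1] < 2 or len(df) < 2:
        raise ValueError(f"malformed trace file {path}: need two numeric columns")
    df.columns = ["size_bp", "fluorescence"]
    df = df.groupby("size_bp", as_index=False)["fluorescence"].mean()
    df = df.sort_values("size_bp")
    return Trace(
        sample_id=sample_id or path.stem,
        size_bp=df["size_bp"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
    )


def subtract_baseline(
    trace: Trace,
    method: str = "percentile",
    percentile: float = 5.0,
    marker_halfwidth_bp: float = 20.0,
) -> Trace:
    """Subtract a constant baseline and clip negatives to zero.

    The baseline is a low percentile (default 5th) of the off-peak signal,
    where "off-peak" excludes the neighbourhoods of the two alignment
    markers.  A constant offset added to a trace therefore leaves region
    areas essentially unchanged after subtraction.
    """
    if method != "percentile":
        raise ValueError(f"unknown baseline method {method!r}")
    size, fluo = trace.size_bp, trace.fluorescence
    off_peak = (np.abs(size - trace.marker_lower_bp) > marker_halfwidth_bp) & (
        np.abs(size - trace.marker_upper_bp) > marker_halfwidth_bp
    )
    ref = fluo[off_peak] if off_peak.any() else fluo
    baseline = np.percentile(ref, percentile)
    corrected = np.clip(fluo - baseline, 0.0, None)
    return Trace(
        sample_id=trace.sample_id,
        size_bp=size,
        fluorescence=corrected,
        marker_lower_bp=trace.marker_lower_bp,
        marker_upper_bp=trace.marker_upper_bp,
    )


def integrate_region(trace: Trace, lower_bp: float, upper_bp: float) -> RegionArea:
    """Trapezoidal integral of fluorescence over [lower_bp, upper_bp).

    Region edges falling between sample points are handled by linear
    interpolation, so area is additive over adjacent regions to rounding
    error.  The half-open convention is stated for the region definition;
    under trapezoidal integration of a piecewise-linear signal the endpoint
    itself carries zero measure.
    """
    if lower_bp > upper_bp:
        raise ValueError("inverted region bounds")
    size, fluo = trace.size_bp, trace.fluorescence
    if lower_bp < size[0] or upper_bp > size[-1]:
        raise ValueError("region outside trace window")
    if lower_bp == upper_bp:
        return RegionArea(lower_bp, upper_bp, 0.0)
    inside = (size > lower_bp) & (size < upper_bp)
    xs = np.concatenate(([lower_bp], size[inside], [upper_bp]))
    ys = np.interp(xs, size, fluo)
    area = float(np.trapezoid(ys, xs))
    return RegionArea(lower_bp, upper_bp, max(area, 0.0))


def classify_ratio(ratio: float, threshold: float = DEFAULT_RATIO_THRESHOLD) -> str:
    """Tumor/normal call from the mono-nucleosomal ratio (tie -> tumor)."""
    if not np.isfinite(ratio):
        return INDETERMINATE
    return TUMOR if ratio >= threshold else NORMAL


def mono_nucleosomal_ratio(
    trace: Trace, threshold: float = DEFAULT_RATIO_THRESHOLD
) -> FractionResult:
    """Compute r = area[100,200) / area[100,1000) and the tumor/normal call.

    The trace is assumed to be baseline-subtracted.  A zero total area makes
    the ratio undefined; the result is flagged ``indeterminate`` rather than
    raising, so cohort runs survive a bad file.
    """
    mono = integrate_region(trace, *MONO_REGION)
    total = integrate_region(trace, *LMW_REGION)
    if total.area > 0:
        ratio = mono.area / total.area
        label = classify_ratio(ratio, threshold)
    else:
        ratio = float("nan")
        label = INDETERMINATE
    return FractionResult(
        sample_id=trace.sample_id,
        mono_area=mono,
        total_lmw_area=total,
        ratio=ratio,
        threshold=threshold,
        label=label,
    )


def estimate_mass(
    trace: Trace,
    region: tuple[float, float] = LMW_REGION,
    calibration_ng_per_area: float = 1.0,
) -> float:
    """DNA mass (ng) in a bp region: area times a calibration constant.

    The instrument's fluorescence-to-mass calibration is a single
    proportionality constant; with the synthetic generator's convention of
    1 ng per unit area the default recovers simulated masses directly.
    """
    if calibration_ng_per_area <= 0:
        raise ValueError("calibration constant must be positive")
    return integrate_region(trace, *region).area * calibration_ng_per_area


def flag_qubit_discrepancy(
    electro_window_ng: float,
    qubit_ng: float,
    fold_threshold: float = 5.0,
    eps: float = 1e-9,
) -> bool:
    """Flag samples whose fluorometric (Qubit) total dwarfs the trace-window mass.

    Qubit quantifies double-stranded DNA of any size, while the trace window
    stops at 1000 bp; a large fold difference signals high-molecular-weight
    DNA (e.g. necrotic in origin) invisible to the electropherogram regions.
    """
    if electro_window_ng < 0 or qubit_ng < 0:
        raise ValueError("masses must be non-negative")
    if qubit_ng == 0:
        return False
    return qubit_ng / max(electro_window_ng, eps) >= fold_threshold
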