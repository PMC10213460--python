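"""Synthetic tumor/normal cfDNA mixtures with known ground truth.

Every downstream stage of the pipeline (trace integration, methylome
binning/classification, depth-based CNV calling, cohort statistics) is
exercised against data from this module, so each generator exposes the
ground-truth tumor fraction ``f`` and event list it used.

The three generators implement one shared mixture model: a sample is a
linear blend of a tumor compartment and a normal-cfDNA compartment at
tumor fraction ``f``.

* **Electropherogram traces** — a nucleosomal ladder of Gaussian peaks at
  multiples of ~167 bp.  The tumor compartment is dominated by the
  mono-nucleosomal peak with rapidly decaying multimers (truncated at the
  tri-nucleosome); the normal compartment carries multimer peaks of
  *increasing* quantity out to the hexa-nucleosome (~1000 bp).  Optional
  high-molecular-weight DNA sits beyond the 1000 bp analysis window and is
  seen only by fluorometric (Qubit) quantification.
* **Per-CpG methylation calls** — observed methylation at each site is the
  mixture ``(1-f)*beta_normal(site) + f*beta_tumor(site)`` with Poisson
  coverage and Binomial methylated counts.  Tumor hypomethylation blocks
  are planted in regions whose normal-plasma methylation is already
  intermediate (partially-methylated-domain-like), and short deeply
  unmethylated cores produce the sharp drops to <=0.25 seen in
  ctDNA-positive samples.
* **Binned read depth** — expected depth scales with the blended copy
  number ``((1-f)*2 + f*CN)/2``; counts are drawn Poisson or
  gamma-Poisson (negative-binomial) when overdispersion > 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .electropherogram import LMW_REGION, Trace

__all__ = [
    "FragmentomicsParams",
    "MethylomeSimParams",
    "CNVSimParams",
    "SimTruth",
    "SimSample",
    "CohortFixture",
    "TRUTH_TUMOR_FRACTION_CUTOFF",
    "simulate_trace",
    "simulate_methylome",
    "simulate_depth",
    "simulate_cohort",
    "synthetic_cnv_windows",
]

#: Simulation convention (not biology): a sample's true label is "tumor"
#: iff its tumor fraction is at or above this value, mirroring the
#: operational 10% ratio cut-off used downstream.
TRUTH_TUMOR_FRACTION_CUTOFF = 0.10


# ---------------------------------------------------------------------------
# electropherogram traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentomicsParams:
    """Parameters of the nucleosomal-ladder trace generator.

    The fluorescence-to-mass calibration is one constant fixed at
    1 ng per unit area, so integrating the noise-free signal over the
    100-1000 bp window returns ``total_mass`` exactly.
    """

    tumor_fraction: float = 0.5
    nucleosome_unit: float = 167.0
    n_tumor_peaks: int = 3
    tumor_peak_decay: float = 0.5
    normal_peak_growth: float = 1.3
    n_normal_peaks: int = 6
    peak_sigma: float = 10.0
    total_mass: float = 24.2
    baseline_noise_sd: float = 0.0
    high_mw_mass: float = 0.0
    high_mw_center: float = 1300.0
    high_mw_sigma: float = 80.0
    marker_positions: tuple[float, float] = (25.0, 1500.0)
    marker_area: float = 5.0
    marker_sigma: float = 2.0
    grid_start: float = 15.0
    grid_stop: float = 1700.0
    grid_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        for name in ("total_mass", "high_mw_mass", "baseline_noise_sd", "marker_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.tumor_peak_decay < 1.0:
            raise ValueError("tumor_peak_decay must lie in (0, 1)")
        if self.normal_peak_growth < 1.0:
            raise ValueError("normal_peak_growth must be >= 1")
        if self.n_tumor_peaks < 1 or self.n_normal_peaks < 1:
            raise ValueError("need at least one peak per compartment")


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def nucleosome_peak_weights(params: FragmentomicsParams) -> tuple[np.ndarray, np.ndarray]:
    """Peak centers (bp) and unnormalized mixture weights of the ladder."""
    f = params.tumor_fraction
    k_max = max(params.n_tumor_peaks, params.n_normal_peaks)
    centers = params.nucleosome_unit * np.arange(1, k_max + 1)
    weights = np.zeros(k_max)
    for k in range(1, params.n_tumor_peaks + 1):
        weights[k - 1] += f * params.tumor_peak_decay ** (k - 1)
    for k in range(1, params.n_normal_peaks + 1):
        weights[k - 1] += (1.0 - f) * params.normal_peak_growth ** (k - 1)
    return centers, weights


def simulate_trace(params: FragmentomicsParams, sample_id: str = "sim") -> Trace:
    """Simulate one calibrated electropherogram.

    The nucleosomal mixture is scaled so its noise-free integral over the
    100-1000 bp window equals ``total_mass`` (area units = ng).  Marker
    peaks and any high-molecular-weight hump lie outside that window.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    x = np.arange(params.grid_start, params.grid_stop + params.grid_step / 2,
                  params.grid_step, dtype=float)
    centers, weights = nucleosome_peak_weights(params)
    signal = np.zeros_like(x)
    for mu, w in zip(centers, weights):
        signal += w * _gauss(x, mu, params.peak_sigma)

    lo, hi = LMW_REGION
    in_window = (x >= lo) & (x <= hi)
    window_mass = np.trapezoid(signal[in_window], x[in_window])
    if window_mass > 0 and params.total_mass > 0:
        signal *= params.total_mass / window_mass
    else:
        signal[:] = 0.0

    for pos in params.marker_positions:
        signal += params.marker_area * _gauss(x, pos, params.marker_sigma)
    if params.high_mw_mass > 0:
        signal += params.high_mw_mass * _gauss(x, params.high_mw_center,
                                               params.high_mw_sigma)
    if params.baseline_noise_sd > 0:
        signal = signal + rng.normal(0.0, params.baseline_noise_sd, size=x.shape)
    return Trace(sample_id=sample_id, size_bp=x, fluorescence=signal,
                 marker_lower_bp=params.marker_positions[0],
                 marker_upper_bp=params.marker_positions[1])


# ---------------------------------------------------------------------------
# per-CpG methylation calls
# ---------------------------------------------------------------------------

Span = tuple[str, int, int]  # chrom, start_bin, end_bin (half-open, bin units)


@dataclass(frozen=True)
class MethylomeSimParams:
    """Parameters of the methylome call generator.

    ``block_spans`` are tumor hypomethylation blocks planted in
    partially-methylated-domain-like territory: their normal-plasma level
    ``beta_normal_block`` is intermediate, so the observed mixture dips
    below 0.5 already at moderate tumor fractions.  ``deep_spans`` are
    short deeply unmethylated cores (low even in normal plasma) that
    supply the sharp single-bin drops to <=0.25; they are kept shorter
    than the block-detection minimum so a pure-normal sample never shows
    a block.
    """

    n_chroms: int = 4
    bins_per_chrom: int = 300
    bin_size: int = 1000
    cpgs_per_bin: float = 8.0
    beta_normal: float = 0.85
    beta_tumor_background: float = 0.75
    beta_tumor_block: float = 0.15
    beta_normal_block: float = 0.52
    beta_tumor_deep: float = 0.0
    beta_normal_deep: float = 0.32
    block_spans: tuple[Span, ...] = (("chr1", 50, 90), ("chr2", 150, 190))
    deep_spans: tuple[Span, ...] = (("chr3", 100, 105), ("chr3", 200, 205))
    tumor_fraction: float = 0.5
    coverage_mean: float = 30.0
    phred_mean: float = 36.0
    phred_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta_normal", "beta_tumor_background", "beta_tumor_block",
                     "beta_normal_block", "beta_tumor_deep", "beta_normal_deep"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.n_chroms < 1 or self.bins_per_chrom < 1 or self.bin_size < 1:
            raise ValueError("genome dimensions must be positive")
        chroms = {f"chr{i + 1}" for i in range(self.n_chroms)}
        for chrom, start, end in tuple(self.block_spans) + tuple(self.deep_spans):
            if chrom not in chroms:
                raise ValueError(f"span on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.bins_per_chrom):
                raise ValueError(f"span ({chrom},{start},{end}) outside chromosome")


def methylome_beta_arrays(params: MethylomeSimParams) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (beta_normal, beta_tumor) arrays, one entry per bin."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i in range(params.n_chroms):
        chrom = f"chr{i + 1}"
        bn = np.full(params.bins_per_chrom, params.beta_normal)
        bt = np.full(params.bins_per_chrom, params.beta_tumor_background)
        out[chrom] = (bn, bt)
    for chrom, start, end in params.block_spans:
        bn, bt = out[chrom]
        bn[start:end] = params.beta_normal_block
        bt[start:end] = params.beta_tumor_block
    for chrom, start, end in params.deep_spans:
        bn, bt = out[chrom]
        bn[start:end] = params.beta_normal_deep
        bt[start:end] = params.beta_tumor_deep
    return out


def simulate_methylome(params: MethylomeSimParams) -> pd.DataFrame:
    """Simulate per-CpG methylation calls for one sample.

    Returns a bedGraph-like frame (chrom, start, end, methylated, total,
    phred) with 0-based coordinates.  Per site, coverage is Poisson and the
    methylated count Binomial at the mixed methylation level.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    f = params.tumor_fraction
    betas = methylome_beta_arrays(params)
    frames = []
    for chrom, (bn, bt) in betas.items():
        n_per_bin = rng.poisson(params.cpgs_per_bin, size=params.bins_per_chrom)
        total_sites = int(n_per_bin.sum())
        if total_sites == 0:
            continue
        bin_idx = np.repeat(np.arange(params.bins_per_chrom), n_per_bin)
        offsets = rng.integers(0, params.bin_size, size=total_sites)
        pos = bin_idx * params.bin_size + offsets
        pos, keep = np.unique(pos, return_index=True)
        bin_idx = bin_idx[keep]
        beta_obs = (1.0 - f) * bn[bin_idx] + f * bt[bin_idx]
        coverage = rng.poisson(params.coverage_mean, size=pos.size)
        methylated = rng.binomial(coverage, beta_obs)
        phred = np.clip(np.rint(rng.normal(params.phred_mean, params.phred_sd,
                                           size=pos.size)), 2, 60).astype(int)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": pos,
            "end": pos + 1,
            "methylated": methylated,
            "total": coverage,
            "phred": phred,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# binned read depth
# ---------------------------------------------------------------------------

CNSegment = tuple[str, int, int, int]  # chrom, start_bin, end_bin, tumor CN


@dataclass(frozen=True)
class CNVSimParams:
    """Parameters of the binned-depth generator.

    ``chrom_bins`` maps each chromosome to its number of bins; bins not
    covered by ``segment_table`` are copy-neutral (tumor CN = 2).
    ``overdispersion`` is the variance-to-mean ratio of the per-bin counts
    (1 = Poisson; >1 via gamma-Poisson mixing).
    """

    segment_table: tuple[CNSegment, ...] = ()
    chrom_bins: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 120, "chr2": 120, "chr11": 100, "chr17": 80})
    tumor_fraction: float = 0.5
    mean_depth: float = 30.0
    bin_size: int = 1_000_000
    overdispersion: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")
        if self.bin_size < 1:
            raise ValueError("bin_size must be positive")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, cn in self.segment_table:
            if chrom not in self.chrom_bins:
                raise ValueError(f"segment on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chrom_bins[chrom]):
                raise ValueError(f"segment ({chrom},{start},{end}) outside chromosome")
            if cn < 0 or int(cn) != cn:
                raise ValueError("tumor copy number must be a non-negative integer")
            for s, e in seen.setdefault(chrom, []):
                if start < e and s < end:
                    raise ValueError(f"overlapping segments on {chrom}")
            seen[chrom].append((start, end))


def expected_depth_per_bin(params: CNVSimParams) -> dict[str, np.ndarray]:
    """Noise-free expected depth per bin from the copy-number mixture."""
    f = params.tumor_fraction
    out = {}
    for chrom, n_bins in params.chrom_bins.items():
        cn = np.full(n_bins, 2.0)
        for c, start, end, tumor_cn in params.segment_table:
            if c == chrom:
                cn[start:end] = tumor_cn
        out[chrom] = params.mean_depth * ((1.0 - f) * 2.0 + f * cn) / 2.0
    return out


def simulate_depth(params: CNVSimParams) -> pd.DataFrame:
    """Simulate a BED-like per-bin depth table (chrom, start, end, depth)."""
    rng = np.random.default_rng(params.seed)
    expected = expected_depth_per_bin(params)
    frames = []
    for chrom, mu in expected.items():
        if params.overdispersion > 1.0:
            shape = mu / (params.overdispersion - 1.0)
            lam = rng.gamma(shape, params.overdispersion - 1.0)
        else:
            lam = mu
        depth = rng.poisson(lam).astype(float)
        starts = np.arange(mu.size) * params.bin_size
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + params.bin_size,
            "depth": depth,
        }))
    return pd.concat(frames, ignore_index=True)


def synthetic_cnv_windows(bin_size: int = 1_000_000) -> dict[str, tuple[str, int, int]]:
    """Genomic windows (MYCN-like locus, 11q-like arm) of the synthetic genome."""
    return {
        "mycn": ("chr2", 14 * bin_size, 18 * bin_size),
        "chr11q": ("chr11", 30 * bin_size, 100 * bin_size),
    }


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    patient_id: str
    timepoint: str  # "diagnosis" | "relapse"
    tumor_fraction: float
    true_label: str  # "tumor" | "normal"
    events: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = "tumor" if self.tumor_fraction >= TRUTH_TUMOR_FRACTION_CUTOFF else "normal"
        if self.true_label != expected:
            raise ValueError("true_label inconsistent with tumor fraction cut-off")


@dataclass
class SimSample:
    """One simulated sample: truth, trace, methylome calls and depth bins."""

    truth: SimTruth
    trace: Trace
    methylome: pd.DataFrame
    depth: pd.DataFrame
    total_mass_ng: float
    high_mw_mass_ng: float
    qubit_ng: float
    cnv_segments: tuple[CNSegment, ...]


FDist = Union[tuple[float, float], Callable[[np.random.Generator], float]]


def _draw_f(dist: FDist, rng: np.random.Generator) -> float:
    if callable(dist):
        return float(dist(rng))
    lo, hi = dist
    return float(rng.uniform(lo, hi))


@dataclass
class CohortFixture:
    """A simulated cohort plus its truth table; can be written to disk."""

    samples: list[SimSample]
    truth_table: pd.DataFrame
    params: dict

    def write(self, outdir: Union[str, Path]) -> Path:
        """Write trace CSVs, methylome/depth TSVs, the truth table and a
        JSON parameter sidecar under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.samples:
            sid = s.truth.sample_id
            pd.DataFrame({"size_bp": s.trace.size_bp,
                          "fluorescence": s.trace.fluorescence}).to_csv(
                outdir / f"{sid}.trace.csv", index=False, float_format="%.6g")
            s.methylome.to_csv(outdir / f"{sid}.methylome.tsv", sep="\t", index=False)
            s.depth.to_csv(outdir / f"{sid}.depth.tsv", sep="\t", index=False,
                           float_format="%.6g")
        self.truth_table.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                                float_format="%.6g")
        with open(outdir / "params.json", "w") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True, default=str)
        return outdir


# Tumor-genome CNV event menu for the synthetic mini-genome (bin units of the
# default CNVSimParams.chrom_bins layout).
_EVENT_MENU = {
    "mycn_amp": ("chr2", 14, 18, 20),
    "del11q": ("chr11", 30, 100, 1),
    "gain17q": ("chr17", 30, 80, 3),
}


def simulate_cohort(
    n_diagnosis: int,
    n_relapse: int,
    f_distributions: Optional[Mapping[str, FDist]] = None,
    seed: int = 0,
    noise_free_traces: bool = False,
    trace_defaults: Optional[FragmentomicsParams] = None,
    methylome_defaults: Optional[MethylomeSimParams] = None,
    cnv_defaults: Optional[CNVSimParams] = None,
    high_mw_prob: float = 0.1,
    total_mass_sigma: float = 0.4,
) -> CohortFixture:
    """Simulate a diagnosis/relapse cohort with paired patients.

    The first ``min(n_diagnosis, n_relapse)`` patients contribute a sample
    at both timepoints; the rest one sample each.  Tumor fractions are drawn
    from per-timepoint distributions (uniform bounds or a callable on the
    RNG); the defaults give diagnosis samples stochastically larger ``f``
    than relapse ones.  Total in-window DNA mass is drawn from the same
    log-normal (median 24.2 ng) at both timepoints, so only the
    mono-nucleosomal quantity differs systematically between arms.
    """
    if n_diagnosis < 1 or n_relapse < 1:
        raise ValueError("need at least one sample per timepoint")
    if f_distributions is None:
        f_distributions = {"diagnosis": (0.3, 0.9), "relapse": (0.0, 0.3)}
    f_diag, f_rel = f_distributions["diagnosis"], f_distributions["relapse"]
    if isinstance(f_diag, tuple) and isinstance(f_rel, tuple):
        if (f_diag[0] + f_diag[1]) < (f_rel[0] + f_rel[1]):
            raise ValueError("diagnosis f distribution must dominate relapse")
    rng = np.random.default_rng(seed)
    trace_p = trace_defaults or FragmentomicsParams(
        baseline_noise_sd=0.0 if noise_free_traces else 0.01)
    meth_p = methylome_defaults or MethylomeSimParams()
    cnv_p = cnv_defaults or CNVSimParams()

    n_pairs = min(n_diagnosis, n_relapse)
    plan: list[tuple[str, str]] = []  # (patient_id, timepoint)
    for i in range(n_diagnosis):
        plan.append((f"P{i + 1:03d}", "diagnosis"))
    for i in range(n_relapse):
        pid = f"P{i + 1:03d}" if i < n_pairs else f"P{n_diagnosis + (i - n_pairs) + 1:03d}"
        plan.append((pid, "relapse"))

    # One tumor-genome event set per patient, shared across timepoints.
    patient_events: dict[str, tuple[str, ...]] = {}
    for pid in dict.fromkeys(p for p, _ in plan):
        events = [name for name in _EVENT_MENU
                  if rng.random() < {"mycn_amp": 0.4, "del11q": 0.5, "gain17q": 0.5}[name]]
        if not events:
            events = ["del11q"]
        patient_events[pid] = tuple(events)

    samples: list[SimSample] = []
    rows = []
    for idx, (pid, timepoint) in enumerate(plan):
        sid = f"{pid}_{timepoint[:3]}"
        f = _draw_f(f_distributions[timepoint], rng)
        label = "tumor" if f >= TRUTH_TUMOR_FRACTION_CUTOFF else "normal"
        total_mass = float(np.exp(rng.normal(np.log(trace_p.total_mass),
                                             total_mass_sigma)))
        high_mw = float(rng.uniform(100.0, 900.0)) if rng.random() < high_mw_prob else 0.0
        sub_seed = int(rng.integers(0, 2**31 - 1))
        tp = dataclasses.replace(trace_p, tumor_fraction=f, total_mass=total_mass,
                                 high_mw_mass=high_mw, seed=sub_seed)
        trace = simulate_trace(tp, sample_id=sid)
        mp = dataclasses.replace(meth_p, tumor_fraction=f, seed=sub_seed + 1)
        meth = simulate_methylome(mp)
        segs = tuple(_EVENT_MENU[name] for name in patient_events[pid])
        cp = dataclasses.replace(cnv_p, segment_table=segs, tumor_fraction=f,
                                 seed=sub_seed + 2)
        depth = simulate_depth(cp)
        qubit = float((total_mass + high_mw) * np.exp(rng.normal(0.0, 0.05)))
        truth = SimTruth(sample_id=sid, patient_id=pid, timepoint=timepoint,
                         tumor_fraction=f, true_label=label,
                         events=patient_events[pid])
        samples.append(SimSample(truth=truth, trace=trace, methylome=meth,
                                 depth=depth, total_mass_ng=total_mass,
                                 high_mw_mass_ng=high_mw, qubit_ng=qubit,
                                 cnv_segments=segs))
        rows.append({"sample_id": sid, "patient_id": pid, "timepoint": timepoint,
                     "tumor_fraction": f, "true_label": label,
                     "events": ";".join(patient_events[pid]),
                     "total_mass_ng": total_mass, "high_mw_mass_ng": high_mw,
                     "qubit_ng": qubit})
    truth_table = pd.DataFrame(rows)
    params = {"n_diagnosis": n_diagnosis, "n_relapse": n_relapse, "seed": seed,
              "f_distributions": {k: str(v) for k, v in f_distributions.items()},
              "noise_free_traces": noise_free_traces,
              "high_mw_prob": high_mw_prob, "total_mass_sigma": total_mass_sigma,
              "trace_params": dataclasses.asdict(trace_p),
              "methylome_params": dataclasses.asdict(meth_p),
              "cnv_params": {**dataclasses.asdict(cnv_p),
                             "chrom_bins": dict(cnv_p.chrom_bins)}}
    return CohortFixture(samples=samples, truth_table=truth_table, params=params)
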