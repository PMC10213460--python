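"""End-to-end per-sample and per-cohort analysis.

Runs the three per-sample analyses (trace ratio, methylome classification,
depth-based CNV screen), combines them into the sequencing-based label and
assembles the record table consumed by the cohort-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from . import cohort as cohort_mod
from .cnv import GRCH38_WINDOWS, SCAReport, call_sca, normalize_log2, segment
from .electropherogram import (
    LMW_REGION,
    MONO_REGION,
    DEFAULT_RATIO_THRESHOLD,
    Trace,
    estimate_mass,
    flag_qubit_discrepancy,
    mono_nucleosomal_ratio,
    subtract_baseline,
)
from .methylome import (
    FilterConfig,
    MethylomeCall,
    bin_methylation,
    classify_methylome,
    detect_hypo_blocks,
    filter_calls,
)
from .synthetic import CohortFixture, synthetic_cnv_windows

__all__ = ["SampleAnalysis", "analyze_sample", "analyze_cohort"]


@dataclass
class SampleAnalysis:
    """All per-sample outputs needed by the cohort integration."""

    record: dict
    profile: pd.DataFrame  # binned methylation, for PCA
    sca: SCAReport
    methylome_call: MethylomeCall


def analyze_sample(
    sample_id: str,
    trace: Trace,
    methylome_calls: pd.DataFrame,
    depth_bins: pd.DataFrame,
    qubit_ng: Optional[float] = None,
    windows: Mapping[str, tuple[str, int, int]] = GRCH38_WINDOWS,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    calibration_ng_per_area: float = 1.0,
    filter_config: FilterConfig = FilterConfig(),
    bin_size: int = 1000,
    min_block_bins: int = 10,
    segment_penalty: Optional[float] = None,
) -> SampleAnalysis:
    """Run every per-sample stage and assemble one record."""
    corrected = subtract_baseline(trace)
    fraction = mono_nucleosomal_ratio(corrected, threshold=ratio_threshold)
    mono_ng = fraction.mono_area.area * calibration_ng_per_area
    total_ng = fraction.total_lmw_area.area * calibration_ng_per_area
    qubit_flag = (flag_qubit_discrepancy(total_ng, qubit_ng)
                  if qubit_ng is not None else False)

    filtered = filter_calls(methylome_calls, filter_config)
    profile = bin_methylation(filtered, bin_size=bin_size)
    blocks = detect_hypo_blocks(profile, min_len_bins=min_block_bins,
                                bin_size=bin_size)
    meth_call = classify_methylome(profile, blocks, sample_id=sample_id,
                                   min_block_bins=min_block_bins,
                                   bin_size=bin_size)

    ratios = normalize_log2(depth_bins)
    segments = segment(ratios, penalty=segment_penalty)
    sca = call_sca(segments, windows=windows, sample_id=sample_id)

    seq_label = cohort_mod.assign_sequencing_label(sca, meth_call.label)
    record = {
        "sample_id": sample_id,
        "ratio": fraction.ratio,
        "ratio_label": fraction.label,
        "mono_ng": mono_ng,
        "total_lmw_ng": total_ng,
        "qubit_ng": qubit_ng,
        "qubit_flag": qubit_flag,
        "methylome_label": meth_call.label,
        "min_bin_beta": meth_call.min_bin_beta,
        "mycn_amplified": sca.mycn_amplified,
        "del11q": sca.del11q,
        "other_sca": sca.other_sca,
        "any_sca": sca.any_sca,
        "sequencing_label": seq_label,
    }
    return SampleAnalysis(record=record, profile=profile, sca=sca,
                          methylome_call=meth_call)


@dataclass
class CohortAnalysis:
    """Record table plus the per-sample binned profiles of a cohort run."""

    records: pd.DataFrame
    profiles: dict[str, pd.DataFrame]
    methylome_labels: dict[str, str]


def analyze_cohort(
    fixture: CohortFixture,
    windows: Optional[Mapping[str, tuple[str, int, int]]] = None,
    **kwargs,
) -> CohortAnalysis:
    """Analyze every sample of a simulated cohort.

    ``windows`` defaults to the synthetic mini-genome's MYCN/11q windows
    (matching the fixture's CNV layout); pass explicit windows for other
    genomes.  Extra keyword arguments go to :func:`analyze_sample`.
    """
    if windows is None:
        bin_size = fixture.params["cnv_params"]["bin_size"]
        windows = synthetic_cnv_windows(bin_size)
    rows = []
    profiles: dict[str, pd.DataFrame] = {}
    labels: dict[str, str] = {}
    for sample in fixture.samples:
        truth = sample.truth
        analysis = analyze_sample(
            truth.sample_id, sample.trace, sample.methylome, sample.depth,
            qubit_ng=sample.qubit_ng, windows=windows, **kwargs)
        analysis.record.update({
            "patient_id": truth.patient_id,
            "timepoint": truth.timepoint,
            "true_label": truth.true_label,
            "tumor_fraction": truth.tumor_fraction,
        })
        rows.append(analysis.record)
        profiles[truth.sample_id] = analysis.profile
        labels[truth.sample_id] = analysis.methylome_call.label
    return CohortAnalysis(records=pd.DataFrame(rows), profiles=profiles,
                          methylome_labels=labels)
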