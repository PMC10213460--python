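"""Cohort-level integration: sequencing-based labels, methylome PCA and
clustering, ratio-vs-sequencing concordance, diagnosis/relapse comparisons
and cohort descriptives.

The sequencing-based label of a sample combines its copy-number screen and
its methylome classification: any segmental chromosomal aberration OR a
tumor methylome call makes the sample ``tumor``; the absence of both, with
a clean high-methylation profile, makes it ``normal``.  That label is the
reference against which the cheap electropherogram ratio rule is scored:
the concordance report counts evaluable samples, disagreements and the
success rate, and tabulates the failures together with their fluorometric
(Qubit) totals — the discordant cases are typically those carrying
high-molecular-weight DNA outside the trace window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .cnv import SCAReport

__all__ = [
    "TUMOR",
    "NORMAL",
    "INDETERMINATE",
    "TTestResult",
    "DiagnosisRelapseStats",
    "ConcordanceReport",
    "PCAClusterResult",
    "assign_sequencing_label",
    "methylome_pca",
    "concordance",
    "compare_diagnosis_relapse",
    "cohort_summary",
]

TUMOR = "tumor"
NORMAL = "normal"
INDETERMINATE = "indeterminate"


# ---------------------------------------------------------------------------
# sequencing-based label
# ---------------------------------------------------------------------------

def assign_sequencing_label(
    sca: Union[SCAReport, bool], methylome_label: str
) -> str:
    """Combine the CNV screen and the methylome call into one label.

    Tumor if any SCA or a tumor methylome; normal only when there is no SCA
    and the methylome is cleanly normal; indeterminate otherwise.
    """
    any_sca = sca.any_sca if isinstance(sca, SCAReport) else bool(sca)
    if any_sca or methylome_label == TUMOR:
        return TUMOR
    if methylome_label == NORMAL:
        return NORMAL
    return INDETERMINATE


# ---------------------------------------------------------------------------
# methylome PCA + clustering
# ---------------------------------------------------------------------------

@dataclass
class PCAClusterResult:
    """First two principal components and 2-group clustering of binned
    methylomes."""

    coords: pd.DataFrame  # sample_id, pc1, pc2
    cluster_labels: dict[str, str]  # sample_id -> tumor|normal
    n_bins_used: int
    explained_variance_ratio: tuple[float, ...]


def methylome_pca(
    profiles: Mapping[str, pd.DataFrame],
    methylome_labels: Optional[Mapping[str, str]] = None,
    n_top_bins: int = 10_000,
    n_components: int = 2,
    seed: int = 0,
) -> PCAClusterResult:
    """PCA of per-sample binned methylomes and k-means (k=2) clustering.

    Samples are represented over the intersection of their emitted bins,
    restricted to the ``n_top_bins`` highest-variance bins and
    column-centered.  The 2-group k-means runs on the first two components;
    the cluster richer in methylome-tumor calls is named ``tumor`` (without
    labels the lower-methylation cluster is named ``tumor``).
    """
    sample_ids = list(profiles)
    if len(sample_ids) < 3:
        raise ValueError("PCA needs at least 3 samples")
    indexed = {
        sid: prof.set_index(["chrom", "bin_start"])["beta"]
        for sid, prof in profiles.items()
    }
    common = None
    for series in indexed.values():
        idx = series.index
        common = idx if common is None else common.intersection(idx)
    if common is None or len(common) == 0:
        raise ValueError("samples share no common bins")
    common = common.sort_values()
    matrix = np.vstack([indexed[sid].loc[common].to_numpy() for sid in sample_ids])
    variances = matrix.var(axis=0)
    if matrix.shape[1] > n_top_bins:
        top = np.argsort(variances)[::-1][:n_top_bins]
        matrix = matrix[:, np.sort(top)]
    matrix = matrix - matrix.mean(axis=0, keepdims=True)

    k = min(n_components, len(sample_ids) - 1, matrix.shape[1])
    pca = PCA(n_components=k, random_state=seed)
    coords = pca.fit_transform(matrix)
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - coords.shape[1]))])
    evr = tuple(float(v) for v in pca.explained_variance_ratio_)

    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assignments = km.fit_predict(coords[:, :2])

    if methylome_labels:
        tumor_share = []
        for cluster in (0, 1):
            members = [sid for sid, a in zip(sample_ids, assignments) if a == cluster]
            calls = [methylome_labels.get(sid) for sid in members]
            n_tumor = sum(1 for c in calls if c == TUMOR)
            tumor_share.append(n_tumor / max(len(members), 1))
        tumor_cluster = int(np.argmax(tumor_share))
    else:
        # Fall back to mean methylation: lower global beta -> tumor cluster.
        mean_beta = np.array([indexed[sid].mean() for sid in sample_ids])
        tumor_cluster = int(np.argmin(
            [mean_beta[assignments == c].mean() if (assignments == c).any() else np.inf
             for c in (0, 1)]))
    cluster_labels = {
        sid: (TUMOR if a == tumor_cluster else NORMAL)
        for sid, a in zip(sample_ids, assignments)
    }
    coords_df = pd.DataFrame({"sample_id": sample_ids,
                              "pc1": coords[:, 0], "pc2": coords[:, 1]})
    return PCAClusterResult(coords=coords_df, cluster_labels=cluster_labels,
                            n_bins_used=matrix.shape[1],
                            explained_variance_ratio=evr)


# ---------------------------------------------------------------------------
# ratio-vs-sequencing concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    """Agreement between the ratio rule and the sequencing-based label."""

    n_evaluable: int
    n_failures: int
    success_rate: float  # percent, one decimal
    failure_table: pd.DataFrame


_FAILURE_COLUMNS = ["sample_id", "ratio", "ratio_label", "sequencing_label",
                    "qubit_ng", "qubit_flag"]


def concordance(records: pd.DataFrame) -> ConcordanceReport:
    """Score the electropherogram ratio label against the sequencing label.

    Only samples with determinate labels on both sides are evaluable; a
    failure is a disagreement.  The success rate is reported in percent to
    one decimal, and the failure table lists each discordant sample with
    its ratio and Qubit quantification.
    """
    determinate = records["ratio_label"].isin([TUMOR, NORMAL]) & \
        records["sequencing_label"].isin([TUMOR, NORMAL])
    evaluable = records.loc[determinate]
    if len(evaluable) == 0:
        raise ValueError("no evaluable records")
    disagree = evaluable["ratio_label"] != evaluable["sequencing_label"]
    failures = evaluable.loc[disagree]
    cols = {c: failures[c] if c in failures.columns else np.nan
            for c in _FAILURE_COLUMNS}
    failure_table = pd.DataFrame(cols).reset_index(drop=True)
    n_eval, n_fail = len(evaluable), int(disagree.sum())
    rate = round(100.0 * (n_eval - n_fail) / n_eval, 1)
    return ConcordanceReport(n_evaluable=n_eval, n_failures=n_fail,
                             success_rate=rate, failure_table=failure_table)


# ---------------------------------------------------------------------------
# diagnosis vs relapse comparison
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    """Two-tailed Student t-test summary."""

    mean_diagnosis: float
    mean_relapse: float
    t: float
    df: int
    p: float


@dataclass
class DiagnosisRelapseStats:
    """Quantity comparisons between diagnosis and relapse samples."""

    t_total: TTestResult
    t_mono: TTestResult
    t_mono_paired: Optional[TTestResult]
    n_pairs: int


def _student_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):  # zero pooled variance
        t, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    return TTestResult(mean_diagnosis=float(np.mean(a)),
                       mean_relapse=float(np.mean(b)),
                       t=t, df=len(a) + len(b) - 2, p=p)


def compare_diagnosis_relapse(
    records: pd.DataFrame,
    total_col: str = "total_lmw_ng",
    mono_col: str = "mono_ng",
) -> DiagnosisRelapseStats:
    """Compare DNA quantities at diagnosis vs relapse.

    Unpaired two-tailed Student t-tests (pooled variance) on the total
    low-molecular-weight mass and the mono-nucleosomal mass, plus a paired
    two-tailed t-test on patients sampled at both timepoints.  With no
    complete pair the paired test is skipped with a warning.
    """
    diag = records.loc[records["timepoint"] == "diagnosis"]
    rel = records.loc[records["timepoint"] == "relapse"]
    if len(diag) < 2 or len(rel) < 2:
        raise ValueError("need at least 2 samples per timepoint")
    t_total = _student_t(diag[total_col].to_numpy(), rel[total_col].to_numpy())
    t_mono = _student_t(diag[mono_col].to_numpy(), rel[mono_col].to_numpy())

    paired = diag.merge(rel, on="patient_id", suffixes=("_diag", "_rel"))
    t_paired: Optional[TTestResult] = None
    if len(paired) == 0:
        warnings.warn("no complete diagnosis/relapse pairs; paired test skipped")
    else:
        a = paired[f"{mono_col}_diag"].to_numpy()
        b = paired[f"{mono_col}_rel"].to_numpy()
        diffs = a - b
        if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
            t, p = (0.0, 1.0) if np.allclose(diffs, 0.0) else (np.inf, 0.0)
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        t_paired = TTestResult(mean_diagnosis=float(a.mean()),
                               mean_relapse=float(b.mean()),
                               t=t, df=len(paired) - 1, p=p)
    return DiagnosisRelapseStats(t_total=t_total, t_mono=t_mono,
                                 t_mono_paired=t_paired, n_pairs=len(paired))


# ---------------------------------------------------------------------------
# cohort descriptives
# ---------------------------------------------------------------------------

def cohort_summary(patients: pd.DataFrame) -> dict:
    """Descriptive counts/percentages for a patient table.

    Expects one row per patient with optional columns ``stage``, ``sex``,
    ``relapsed`` (boolean), ``age_months`` and ``time_to_relapse_months``;
    absent columns are simply omitted from the summary.
    """
    n = len(patients)
    summary: dict = {"n_patients": n}
    if n == 0:
        summary.update({"by_stage": {}, "by_sex": {},
                        "relapsed_n": 0, "relapsed_pct": 0.0})
        return summary
    if "stage" in patients.columns:
        summary["by_stage"] = patients["stage"].value_counts().to_dict()
    if "sex" in patients.columns:
        summary["by_sex"] = patients["sex"].value_counts().to_dict()
    if "relapsed" in patients.columns:
        relapsed = int(patients["relapsed"].sum())
        summary["relapsed_n"] = relapsed
        summary["relapsed_pct"] = round(100.0 * relapsed / n, 1)
    if "age_months" in patients.columns:
        summary["median_age_months"] = float(patients["age_months"].median())
    if "time_to_relapse_months" in patients.columns and "relapsed" in patients.columns:
        ttr = patients.loc[patients["relapsed"], "time_to_relapse_months"]
        if len(ttr):
            summary["median_time_to_relapse_months"] = float(ttr.median())
    return summary
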