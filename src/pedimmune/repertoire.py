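"""TCR-beta CDR3 repertoire statistics.

A clonotype is the set of T cells sharing one CDR3 amino-acid sequence,
quantified by its read count in a sample.  This module normalizes clone
counts (counts per million denominator reads, and intra-sample fraction
of total TCR reads), calls clonal expansion by the joint rule

    expanded  <=>  cpm > cohort-wide 99th percentile  AND  fraction > 1%

(both strict), partitions the cohort's distinct CDR3s against reference
repertoires (healthy-donor databases, normal tissues), and reports
descriptive CDR3 statistics (length distribution over distinct
sequences, per-sample unique-clone counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CloneTable, ReferenceCdr3Set


@dataclass
class ExpansionConfig:
    """Clonal-expansion rule parameters.

    cpm_denominator selects the counts-per-million denominator: total
    sequenced reads of the sample ("total_sample_reads") or the sample's
    total TCR reads ("total_tcr_reads").
    """

    cpm_percentile: float = 99.0
    fraction_threshold: float = 0.01
    cpm_denominator: str = "total_sample_reads"

    def __post_init__(self):
        if not 0 < self.cpm_percentile < 100:
            raise ValueError("cpm_percentile must be in (0, 100)")
        if not 0 < self.fraction_threshold < 1:
            raise ValueError("fraction_threshold must be in (0, 1)")
        if self.cpm_denominator not in ("total_sample_reads", "total_tcr_reads"):
            raise ValueError(f"unknown cpm denominator {self.cpm_denominator!r}")


def normalize_clones(table: CloneTable, cfg: ExpansionConfig | None = None) -> pd.DataFrame:
    """Per-clone cpm and intra-sample fraction.

    cpm = 1e6 * count / denominator; fraction = count / total TCR reads.
    """
    cfg = cfg or ExpansionConfig()
    if cfg.cpm_denominator == "total_sample_reads":
        if table.total_sample_reads is None:
            raise ValueError(
                f"sample {table.sample_id!r} has no total_sample_reads; "
                "set cpm_denominator='total_tcr_reads' to use TCR totals"
            )
        denom = table.total_sample_reads
    else:
        denom = table.total_tcr_reads
    counts = np.array(list(table.clones.values()), dtype=float)
    total_tcr = counts.sum()
    return pd.DataFrame(
        {
            "sample_id": table.sample_id,
            "cdr3_aa": list(table.clones.keys()),
            "count": counts.astype(int),
            "cpm": 1e6 * counts / denom,
            "fraction": counts / total_tcr,
        }
    )


def call_expansion(
    cohort: list[CloneTable],
    cfg: ExpansionConfig | None = None,
    patient_of: dict | None = None,
    group_of: dict | None = None,
):
    """Flag expanded clones across a cohort.

    The cpm threshold is the configured percentile of the pooled cpm
    values of *all* clones in the cohort (all samples plotted on common
    axes); a clone is expanded iff its cpm strictly exceeds that
    threshold and its intra-sample fraction strictly exceeds the fraction
    threshold.

    Returns
    -------
    calls : DataFrame
        One row per clone with cpm, fraction and the expanded flag.
    per_sample : DataFrame
        Per-sample boolean ``has_expanded``.
    per_group : DataFrame or None
        If ``group_of`` is given: per-group percentage of patients with
        >= 1 expanded tumor (a patient with several tumors counts once;
        requires ``patient_of``, else each sample is its own patient).
    cpm_threshold : float
    """
    cfg = cfg or ExpansionConfig()
    if not cohort:
        raise ValueError("empty cohort")
    calls = pd.concat([normalize_clones(t, cfg) for t in cohort], ignore_index=True)
    threshold = float(np.percentile(calls["cpm"].to_numpy(), cfg.cpm_percentile))
    calls["expanded"] = (calls["cpm"] > threshold) & (
        calls["fraction"] > cfg.fraction_threshold
    )
    per_sample = (
        calls.groupby("sample_id", sort=False)["expanded"]
        .any()
        .rename("has_expanded")
        .to_frame()
    )
    per_group = None
    if group_of is not None:
        patient_of = patient_of or {s: s for s in per_sample.index}
        ps = per_sample.reset_index()
        ps["patient"] = ps["sample_id"].map(patient_of)
        ps["group"] = ps["sample_id"].map(group_of)
        per_patient = ps.groupby(["group", "patient"])["has_expanded"].any()
        per_group = (
            per_patient.groupby("group")
            .agg(n_patients="size", n_expanded="sum")
            .assign(pct_expanded=lambda d: 100.0 * d["n_expanded"] / d["n_patients"])
        )
    return calls, per_sample, per_group, threshold


CATEGORIES = ("private", "reference_shared", "multi_tumor_private")


def partition_overlap(
    cohort: list[CloneTable],
    patient_of: dict,
    refs: list[ReferenceCdr3Set],
):
    """Partition the cohort's distinct CDR3s by sharing pattern.

    Categories (disjoint, exhaustive):

    - ``reference_shared``: present in at least one reference set;
    - ``multi_tumor_private``: absent from every reference but found in
      tumors of >= 2 distinct patients (the candidate tumor-reactive
      public clones);
    - ``private``: everything else (one patient, no reference hit).

    Returns (per_cdr3 DataFrame, summary DataFrame with counts and
    percentages per category).
    """
    for t in cohort:
        if t.sample_id not in patient_of:
            raise ValueError(f"sample {t.sample_id!r} not mapped to a patient")
    patients_of_cdr3: dict = {}
    for t in cohort:
        p = patient_of[t.sample_id]
        for cdr3 in t.clones:
            patients_of_cdr3.setdefault(cdr3, set()).add(p)
    ref_union = set().union(*(r.sequences for r in refs)) if refs else set()

    records = []
    for cdr3, patients in patients_of_cdr3.items():
        if cdr3 in ref_union:
            cat = "reference_shared"
        elif len(patients) >= 2:
            cat = "multi_tumor_private"
        else:
            cat = "private"
        records.append((cdr3, len(patients), cat))
    per_cdr3 = pd.DataFrame(records, columns=["cdr3_aa", "n_patients", "category"])
    total = len(per_cdr3)
    summary = (
        per_cdr3["category"]
        .value_counts()
        .reindex(CATEGORIES, fill_value=0)
        .rename("count")
        .to_frame()
        .assign(percentage=lambda d: 100.0 * d["count"] / total)
    )
    return per_cdr3, summary


def cdr3_stats(cohort: list[CloneTable], group_of: dict | None = None):
    """Descriptive CDR3 statistics.

    The length distribution weights each distinct CDR3 sequence once
    (not by read count).  Per-sample unique-clone counts and, if groups
    are given, the per-group median unique count are reported.
    """
    if not cohort:
        raise ValueError("empty cohort")
    distinct = set()
    for t in cohort:
        distinct.update(t.clones)
    lengths = pd.Series(sorted(len(c) for c in distinct))
    length_distribution = lengths.value_counts().sort_index().rename("n_cdr3")
    per_sample = pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in cohort],
            "n_unique_clones": [len(t.clones) for t in cohort],
            "total_tcr_reads": [t.total_tcr_reads for t in cohort],
        }
    ).set_index("sample_id")
    group_medians = None
    if group_of is not None:
        labels = per_sample.index.map(group_of)
        group_medians = (
            per_sample["n_unique_clones"].groupby(labels).median().rename("median_unique_clones")
        )
    return {
        "n_distinct_cdr3": len(distinct),
        "length_distribution": length_distribution,
        "median_length": float(lengths.median()),
        "per_sample": per_sample,
        "group_medians": group_medians,
    }


def diversity_indices(table: CloneTable) -> dict:
    """Auxiliary Shannon entropy and clonality (1 - normalized entropy)."""
    counts = np.array(list(table.clones.values()), dtype=float)
    p = counts / counts.sum()
    H = float(-(p * np.log(p)).sum())
    k = len(counts)
    clonality = 1.0 - H / math.log(k) if k > 1 else 1.0
    return {"shannon": H, "clonality": clonality, "richness": k}
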