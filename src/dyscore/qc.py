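"""Sample- and cell-level quality-control filtering.

Inclusion rules follow the study design this package emulates:

* single-cell data keep only cells with an overall read mapping rate of at
  least 50%;
* any sample/cell with fewer than 1000 detected genes is excluded, as is
  any with too few detected housekeeping genes — fewer than 65 of the
  curated 98 for bulk and Patch-seq-like data, or less than 66% of the
  list for droplet single-cell data (two dialects of the same rule);
* droplet cells with exceptionally high detection — more than 8000 genes
  or more than 37,500 UMIs — are treated as putative doublets/multiplets.

All boundary semantics are strict as phrased: 1000 genes, 65 housekeeping
genes, 50% mapping and 37,500 UMIs all pass. Bulk data get no default
mapping-rate cut (an optional threshold can be supplied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SINGLE_CELL, ExpressionDataset

logger = logging.getLogger(__name__)

LOW_MAPPING = "LOW_MAPPING"
LOW_GENES = "LOW_GENES"
LOW_HK = "LOW_HK"
DOUBLET_GENES = "DOUBLET_GENES"
DOUBLET_UMI = "DOUBLET_UMI"

REASON_CODES = (LOW_MAPPING, LOW_GENES, LOW_HK, DOUBLET_GENES, DOUBLET_UMI)

# Fallback housekeeping list size; callers normally pass the cohort's own list.
DEFAULT_HK_LIST_SIZE = 98


@dataclass
class QCThresholds:
    """Inclusion thresholds; defaults are the emulated study's values."""

    min_mapping_rate_sc: float = 0.50
    min_genes: int = 1000
    max_genes: int = 8000
    max_umis: int = 37500
    min_hk_genes: int = 65
    min_hk_fraction: float = 0.66
    hk_gene_list: frozenset[str] = field(default_factory=frozenset)
    min_mapping_rate_bulk: float | None = None  # no bulk cut by default

    def validate(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError(f"min_genes ({self.min_genes}) must be < max_genes ({self.max_genes})")
        for name in ("min_mapping_rate_sc", "min_hk_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.hk_gene_list and self.min_hk_genes > len(self.hk_gene_list):
            raise ValueError(
                f"min_hk_genes ({self.min_hk_genes}) exceeds the housekeeping "
                f"list size ({len(self.hk_gene_list)})"
            )


@dataclass
class QCReport:
    """Per-sample QC metrics and (after filtering) pass/fail flags.

    ``table`` columns: mapping_rate, n_genes_detected, n_hk_detected,
    n_umis, pass, fail_reasons (list of reason codes). Before a filter
    step is applied ``pass`` is NA and ``fail_reasons`` empty.
    """

    dataset: str
    modality: str
    table: pd.DataFrame
    hk_list_size: int
    flagged: bool = False

    @property
    def passing(self) -> pd.Index:
        if not self.flagged:
            raise ValueError("QC flags not yet applied; run filter_cells/filter_bulk_samples")
        return self.table.index[self.table["pass"].astype(bool)]

    @property
    def failing(self) -> pd.Index:
        if not self.flagged:
            raise ValueError("QC flags not yet applied; run filter_cells/filter_bulk_samples")
        return self.table.index[~self.table["pass"].astype(bool)]

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out["fail_reasons"] = [";".join(r) for r in out["fail_reasons"]]
        out.to_csv(path, sep="\t", index_label="sample")


def compute_qc_metrics(dataset: ExpressionDataset, hk_list: set[str] | frozenset[str]) -> QCReport:
    """Detection metrics per sample/cell; a gene is detected iff count >= 1.

    ``n_umis`` is the column sum of counts (total molecules for UMI data,
    total assigned reads otherwise). Mapping rates are consumed from the
    sample metadata (``mapping_rate`` column; NaN when absent).
    """
    if not hk_list:
        raise ValueError("hk_list must be non-empty")
    counts = dataset.counts
    if counts.shape[1] == 0:
        raise ValueError(f"dataset {dataset.name}: no samples")
    detected = counts.ge(1)
    hk_present = counts.index.intersection(pd.Index(sorted(hk_list)))
    if len(hk_present) == 0:
        logger.warning(
            "dataset %s: housekeeping list shares no genes with the matrix; "
            "n_hk_detected will be 0 for every sample", dataset.name,
        )
    if "mapping_rate" in dataset.samples.columns:
        mapping = dataset.samples["mapping_rate"].reindex(counts.columns).astype(float)
    else:
        mapping = pd.Series(np.nan, index=counts.columns)
    table = pd.DataFrame(
        {
            "mapping_rate": mapping,
            "n_genes_detected": detected.sum(axis=0).astype(int),
            "n_hk_detected": detected.loc[hk_present].sum(axis=0).astype(int)
            if len(hk_present) else 0,
            "n_umis": counts.sum(axis=0).astype(np.int64),
            "pass": pd.Series(pd.NA, index=counts.columns, dtype="boolean"),
            "fail_reasons": [[] for _ in range(counts.shape[1])],
        },
        index=counts.columns,
    )
    return QCReport(
        dataset=dataset.name, modality=dataset.modality, table=table,
        hk_list_size=len(hk_list),
    )


def _apply_flags(report: QCReport, reasons_per_sample: list[list[str]]) -> QCReport:
    table = report.table.copy()
    table["fail_reasons"] = [list(r) for r in reasons_per_sample]
    table["pass"] = pd.array([len(r) == 0 for r in reasons_per_sample], dtype="boolean")
    return QCReport(
        dataset=report.dataset, modality=report.modality, table=table,
        hk_list_size=report.hk_list_size, flagged=True,
    )


def _hk_fails(row: pd.Series, thresholds: QCThresholds, hk_list_size: int, fraction_dialect: bool) -> bool:
    if fraction_dialect:
        denom = hk_list_size or DEFAULT_HK_LIST_SIZE
        return row["n_hk_detected"] / denom < thresholds.min_hk_fraction
    return row["n_hk_detected"] < thresholds.min_hk_genes


def filter_cells(
    report: QCReport, thresholds: QCThresholds, umi_based: bool = True
) -> QCReport:
    """Flag single cells against the inclusion rules.

    The UMI doublet rule applies only to UMI-based (droplet) data; the
    fractional housekeeping dialect likewise. NaN mapping rates are not
    penalized (rate unavailable in the metadata).
    """
    thresholds.validate()
    reasons_all = []
    for _, row in report.table.iterrows():
        reasons = []
        if np.isfinite(row["mapping_rate"]) and row["mapping_rate"] < thresholds.min_mapping_rate_sc:
            reasons.append(LOW_MAPPING)
        if row["n_genes_detected"] < thresholds.min_genes:
            reasons.append(LOW_GENES)
        if _hk_fails(row, thresholds, report.hk_list_size, fraction_dialect=umi_based):
            reasons.append(LOW_HK)
        if row["n_genes_detected"] > thresholds.max_genes:
            reasons.append(DOUBLET_GENES)
        if umi_based and row["n_umis"] > thresholds.max_umis:
            reasons.append(DOUBLET_UMI)
        reasons_all.append(reasons)
    return _apply_flags(report, reasons_all)


def filter_bulk_samples(report: QCReport, thresholds: QCThresholds) -> QCReport:
    """Flag bulk samples: detected-genes and absolute housekeeping rules only.

    Doublet rules do not apply to bulk libraries. A mapping-rate cut is
    applied only when ``min_mapping_rate_bulk`` is explicitly set.
    """
    thresholds.validate()
    reasons_all = []
    for _, row in report.table.iterrows():
        reasons = []
        if (
            thresholds.min_mapping_rate_bulk is not None
            and np.isfinite(row["mapping_rate"])
            and row["mapping_rate"] < thresholds.min_mapping_rate_bulk
        ):
            reasons.append(LOW_MAPPING)
        if row["n_genes_detected"] < thresholds.min_genes:
            reasons.append(LOW_GENES)
        if _hk_fails(row, thresholds, report.hk_list_size, fraction_dialect=False):
            reasons.append(LOW_HK)
        reasons_all.append(reasons)
    return _apply_flags(report, reasons_all)


def apply_qc(
    dataset: ExpressionDataset,
    hk_list: set[str] | frozenset[str],
    thresholds: QCThresholds | None = None,
) -> tuple[ExpressionDataset, QCReport]:
    """Convenience: compute metrics, flag by modality, return filtered dataset."""
    thresholds = thresholds or QCThresholds()
    report = compute_qc_metrics(dataset, hk_list)
    if dataset.modality == SINGLE_CELL:
        report = filter_cells(report, thresholds, umi_based=dataset.umi_based)
    else:
        report = filter_bulk_samples(report, thresholds)
    return dataset.subset_samples(report.passing), report
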