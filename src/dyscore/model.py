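"""Model/Results interface over the full scoring workflow.

``DysregulationModel`` is built from a cohort of expression datasets (real
or simulated); ``fit()`` runs QC filtering, dual differential expression
per dataset, desirability scoring and ranking, and returns a
``DysregulationResults`` carrying the per-gene score table, per-dataset DE
tables and QC reports, with ``summary()``, RNK export, gene-set
enrichment and the label-permutation negative control hanging off it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import SINGLE_CELL, ExpressionDataset
from .de import run_de
from .gsea import (
    GeneSetCollection,
    label_permutation_control,
    preranked_gsea,
    restrict_and_filter,
)
from .qc import QCReport, QCThresholds, apply_qc
from .scoring import DesirabilityParams, group_score, score_genes, to_rnk
from .synthetic import CohortSpec, GroundTruth, generate_cohort

logger = logging.getLogger(__name__)


class DysregulationModel:
    """Multi-dataset gene dysregulation scoring model.

    Parameters
    ----------
    datasets : list of ExpressionDataset
        The cohort; each dataset is QC-filtered and tested independently.
    midbrain_detected : pandas.Series of bool, optional
        Per-gene adult-midbrain detection flags (genes absent from the
        annotation are treated as detected).
    hk_genes : set of str, optional
        Housekeeping gene ids used by the QC detection rule. Defaults to
        an empty set, which disables the housekeeping rule only if the
        thresholds' list is also empty; normally pass the cohort's list.
    qc_thresholds : QCThresholds, optional
    desirability : DesirabilityParams, optional
    """

    def __init__(
        self,
        datasets: list[ExpressionDataset],
        midbrain_detected: pd.Series | None = None,
        hk_genes: set[str] | frozenset[str] | None = None,
        qc_thresholds: QCThresholds | None = None,
        desirability: DesirabilityParams | None = None,
    ) -> None:
        if not datasets:
            raise ValueError("DysregulationModel requires at least one dataset")
        names = [d.name for d in datasets]
        if len(set(names)) != len(names):
            raise ValueError("dataset names must be unique")
        self.datasets = list(datasets)
        self.midbrain_detected = midbrain_detected
        self.hk_genes = frozenset(hk_genes) if hk_genes else frozenset()
        self.qc_thresholds = qc_thresholds or QCThresholds()
        self.desirability = desirability or DesirabilityParams()
        self.ground_truth: GroundTruth | None = None

    @classmethod
    def from_cohort_spec(
        cls,
        spec: CohortSpec,
        qc_thresholds: QCThresholds | None = None,
        desirability: DesirabilityParams | None = None,
    ) -> "DysregulationModel":
        """Simulate a cohort from a spec and build the model on it.

        The generator's housekeeping list and midbrain flags feed the QC
        and scoring stages; the ground truth is kept on the model for
        parameter-recovery checks.
        """
        datasets, truth = generate_cohort(spec)
        model = cls(
            datasets,
            midbrain_detected=truth.midbrain_detected,
            hk_genes=truth.housekeeping_genes,
            qc_thresholds=qc_thresholds,
            desirability=desirability,
        )
        model.ground_truth = truth
        return model

    def fit(self) -> "DysregulationResults":
        """Run QC -> DE -> scoring and return the results object."""
        qc_reports: dict[str, QCReport] = {}
        filtered: dict[str, ExpressionDataset] = {}
        for ds in self.datasets:
            hk = self.hk_genes or self.qc_thresholds.hk_gene_list
            if not hk:
                raise ValueError(
                    f"dataset {ds.name}: no housekeeping gene list available for QC"
                )
            kept, report = apply_qc(ds, hk, self.qc_thresholds)
            qc_reports[ds.name] = report
            if kept.n_samples == 0:
                raise ValueError(
                    f"dataset {ds.name}: every sample failed QC "
                    f"({report.table['fail_reasons'].map(len).sum()} flags)"
                )
            n_fail = len(report.failing)
            if n_fail:
                logger.info("dataset %s: excluded %d of %d samples at QC",
                            ds.name, n_fail, ds.n_samples)
            filtered[ds.name] = kept

        de_tables = {name: run_de(ds) for name, ds in filtered.items()}
        mb = self.midbrain_detected
        if mb is None:
            union = pd.Index([])
            for de in de_tables.values():
                union = union.union(de.index)
            mb = pd.Series(True, index=union)
        scores = score_genes(de_tables, mb, self.desirability)
        return DysregulationResults(self, filtered, qc_reports, de_tables, scores)


class DysregulationResults:
    """Fitted scoring results.

    Attributes
    ----------
    scores : pandas.DataFrame
        Per-gene score table sorted by rank (columns include per-dataset
        ``D:<name>``, concordance, ``D_overall`` and ``rank``).
    de_tables : dict of str -> DataFrame
        Per-dataset dual DE results.
    qc_reports : dict of str -> QCReport
    """

    def __init__(self, model, filtered_datasets, qc_reports, de_tables, scores) -> None:
        self.model = model
        self.filtered_datasets = filtered_datasets
        self.qc_reports = qc_reports
        self.de_tables = de_tables
        self.scores = scores

    @property
    def ranked(self) -> pd.Series:
        """Gene -> D_overall, sorted by rank (the RNK content)."""
        return to_rnk(self.scores)

    def to_rnk(self, path: str) -> pd.Series:
        return to_rnk(self.scores, path)

    def group_scores(self, subsets: dict[str, list[str]] | None = None) -> pd.DataFrame:
        """Geometric-mean D over dataset subsets (default: by modality)."""
        if subsets is None:
            subsets = {}
            sc = [d.name for d in self.model.datasets if d.modality == SINGLE_CELL]
            bulk = [d.name for d in self.model.datasets if d.modality != SINGLE_CELL]
            if sc:
                subsets["D_sc"] = sc
            if bulk:
                subsets["D_bulk"] = bulk
        out = {}
        for label, names in subsets.items():
            cols = [f"D:{n}" for n in names]
            missing = [c for c in cols if c not in self.scores.columns]
            if missing:
                raise ValueError(f"unknown datasets in subset {label}: {missing}")
            mat = self.scores[cols].to_numpy()
            out[label] = np.array([group_score(row) for row in mat])
        return pd.DataFrame(out, index=self.scores.index)

    def gsea(
        self,
        collection: GeneSetCollection,
        n_permutations: int = 1000,
        seed: int = 0,
        weight_exponent: float = 1.0,
        min_size: int = 15,
        max_size: int = 500,
    ) -> pd.DataFrame:
        """Pre-ranked GSEA of the D_overall-ranked gene list."""
        ranked = self.ranked
        restricted = restrict_and_filter(collection, ranked.index, min_size, max_size)
        return preranked_gsea(
            ranked, restricted, n_permutations=n_permutations,
            seed=seed, weight_exponent=weight_exponent,
        )

    def gsea_label_control(
        self,
        collection: GeneSetCollection,
        n_permutations: int = 1000,
        seed: int = 0,
        weight_exponent: float = 1.0,
        min_size: int = 15,
        max_size: int = 500,
    ) -> pd.DataFrame:
        """Label-permutation negative control of :meth:`gsea`."""
        ranked = self.ranked
        restricted = restrict_and_filter(collection, ranked.index, min_size, max_size)
        return label_permutation_control(
            ranked, restricted, seed=seed,
            n_permutations=n_permutations, weight_exponent=weight_exponent,
        )

    def summary(self, top_n: int = 10) -> str:
        """Human-readable fit summary.

        Reports per-dataset QC exclusions and expressed-gene counts, the
        ranked-universe size, and the top genes by D_overall.
        """
        lines = ["Multi-dataset gene dysregulation scoring", "=" * 44]
        lines.append(f"{'dataset':<16}{'samples':>9}{'excluded':>10}{'expressed':>11}")
        for ds in self.model.datasets:
            rep = self.qc_reports[ds.name]
            n_fail = len(rep.failing)
            n_expr = int(self.de_tables[ds.name]["expressed"].sum())
            lines.append(f"{ds.name:<16}{ds.n_samples:>9}{n_fail:>10}{n_expr:>11}")
        lines.append("")
        lines.append(f"ranked gene universe (expressed in >=1 dataset): {len(self.scores)}")
        lines.append("")
        lines.append(f"top {top_n} genes by D_overall:")
        head = self.scores.sort_values("rank").head(top_n)
        lines.append(f"{'rank':>5} {'gene':<12}{'D_overall':>10}{'concordance':>13}")
        for gene, row in head.iterrows():
            conc = row["concordance"]
            conc_s = f"{conc:.2f}" if np.isfinite(conc) else "NA"
            lines.append(f"{int(row['rank']):>5} {str(gene):<12}{row['D_overall']:>10.4f}{conc_s:>13}")
        return "\n".join(lines)
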