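"""End-to-end orchestration: simulate/load -> QC -> DE -> score -> enrich.

``run_pipeline`` executes the stages in order, writes every intermediate
table as TSV under the output directory and records a manifest (file
hashes, seeds, parameter snapshot, per-stage survivor counts) so reruns
with an identical config are bit-for-bit reproducible. Also hosts
artificial-bulk (pseudobulk) construction: per-subject sums of
single-cell counts that make single-cell datasets comparable to bulk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import BULK, SINGLE_CELL, ExpressionDataset, compute_tpm
from .de import write_de_table
from .gsea import GeneSetCollection, read_gmt, write_enrichment_tsv
from .model import DysregulationModel
from .qc import QCThresholds
from .scoring import DesirabilityParams
from .synthetic import CohortSpec, generate_genesets, read_cohort

logger = logging.getLogger(__name__)

STAGES = ("input", "qc", "de", "score", "gsea", "control")


def artificial_bulk(
    dataset: ExpressionDataset,
    subject_col: str = "subject",
    passing: pd.Index | None = None,
) -> ExpressionDataset:
    """Pseudobulk: sum counts across all cells of each subject.

    ``passing`` optionally restricts to QC-passing cells first. TPM is
    recomputed from the summed counts (total reads are conserved exactly).
    """
    if dataset.modality != SINGLE_CELL:
        raise ValueError(f"dataset {dataset.name} is not single-cell")
    ds = dataset if passing is None else dataset.subset_samples(passing)
    subjects = ds.samples[subject_col]
    if subjects.isna().any():
        bad = list(ds.samples.index[subjects.isna()])[:5]
        raise ValueError(f"cells with unknown subject: {bad}")
    groups = subjects.groupby(subjects).groups
    cols = {}
    meta_rows = {}
    for subj in sorted(groups, key=str):
        cells = list(groups[subj])
        cols[str(subj)] = ds.counts[cells].sum(axis=1)
        conds = ds.samples.loc[cells, "condition"].unique()
        if len(conds) != 1:
            raise ValueError(f"subject {subj}: inconsistent condition labels {list(conds)}")
        meta_rows[str(subj)] = {"subject": str(subj), "condition": conds[0]}
    counts = pd.DataFrame(cols, index=ds.counts.index)
    samples = pd.DataFrame.from_dict(meta_rows, orient="index")
    samples.index.name = "sample"
    return ExpressionDataset(
        name=f"{dataset.name}-pseudobulk",
        modality=BULK,
        counts=counts,
        tpm=compute_tpm(counts, dataset.gene_lengths),
        samples=samples,
        umi_based=False,
        gene_lengths=dataset.gene_lengths,
    )


@dataclass
class PipelineConfig:
    """Everything one run needs; either a cohort spec or an input directory."""

    cohort_spec: CohortSpec | None = None
    input_dir: str | None = None
    gmt_path: str | None = None  # None with cohort_spec => synthesize gene sets
    out_dir: str = "dyscore_run"
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    desirability: DesirabilityParams = field(default_factory=DesirabilityParams)
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    n_permutations: int = 1000
    gsea_weight: float = 1.0
    seed: int = 0
    run_control: bool = True
    n_random_sets: int = 20
    random_set_sizes: tuple[int, int] = (15, 100)

    def validate(self) -> None:
        if (self.cohort_spec is None) == (self.input_dir is None):
            raise ValueError("provide exactly one of cohort_spec or input_dir")
        if self.input_dir is not None and self.gmt_path is None:
            raise ValueError("gmt_path is required when loading a cohort from disk")


@dataclass
class RunManifest:
    """Per-stage provenance: hashes, parameters, survivor counts."""

    stages: list[dict]
    seed: int
    params: dict

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "params": self.params, "stages": self.stages},
                      fh, indent=2, sort_keys=True, default=str)

    def stage_names(self) -> list[str]:
        return [s["stage"] for s in self.stages]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    snap["qc_thresholds"]["hk_gene_list"] = sorted(config.qc_thresholds.hk_gene_list)
    return snap


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the pipeline; aborts with the stage name on failure.

    Partial outputs of a failed run are moved under ``<out_dir>/failed/``.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    stages: list[dict] = []
    current = "input"
    try:
        # ---- input ----------------------------------------------------
        if config.cohort_spec is not None:
            model = DysregulationModel.from_cohort_spec(
                config.cohort_spec, config.qc_thresholds, config.desirability
            )
            truth = model.ground_truth
            collection = (
                read_gmt(config.gmt_path) if config.gmt_path
                else generate_genesets(
                    truth, n_random_sets=config.n_random_sets,
                    size_range=config.random_set_sizes, seed=config.seed,
                )
            )
        else:
            datasets, truth = read_cohort(config.input_dir)
            model = DysregulationModel(
                datasets,
                midbrain_detected=truth.midbrain_detected,
                hk_genes=truth.housekeeping_genes,
                qc_thresholds=config.qc_thresholds,
                desirability=config.desirability,
            )
            model.ground_truth = truth
            collection = read_gmt(config.gmt_path)
        stages.append({
            "stage": "input",
            "n_datasets": len(model.datasets),
            "n_genes": int(model.datasets[0].counts.shape[0]),
            "n_samples": {d.name: d.n_samples for d in model.datasets},
            "seed": config.seed,
        })

        # ---- qc + de + score (model.fit) ------------------------------
        current = "qc"
        results = model.fit()
        files = []
        for name, rep in results.qc_reports.items():
            path = os.path.join(config.out_dir, f"qc.{name}.tsv")
            rep.to_tsv(path)
            files.append(path)
        stages.append({
            "stage": "qc",
            "excluded": {n: int(len(r.failing)) for n, r in results.qc_reports.items()},
            "passing": {n: int(len(r.passing)) for n, r in results.qc_reports.items()},
            "files": {os.path.basename(p): _sha256(p) for p in files},
        })

        current = "de"
        files = []
        for name, de in results.de_tables.items():
            path = os.path.join(config.out_dir, f"de.{name}.tsv")
            write_de_table(de, path)
            files.append(path)
        stages.append({
            "stage": "de",
            "expressed": {n: int(t["expressed"].sum()) for n, t in results.de_tables.items()},
            "files": {os.path.basename(p): _sha256(p) for p in files},
        })

        current = "score"
        score_path = os.path.join(config.out_dir, "scores.tsv")
        out_scores = results.scores.copy()
        out_scores.to_csv(score_path, sep="\t", index_label="gene")
        rnk_path = os.path.join(config.out_dir, "ranked.rnk")
        results.to_rnk(rnk_path)
        stages.append({
            "stage": "score",
            "n_ranked": int(len(results.scores)),
            "files": {os.path.basename(p): _sha256(p) for p in (score_path, rnk_path)},
        })

        current = "gsea"
        enrich = results.gsea(
            collection, n_permutations=config.n_permutations, seed=config.seed,
            weight_exponent=config.gsea_weight,
            min_size=config.gsea_min_size, max_size=config.gsea_max_size,
        )
        gsea_path = os.path.join(config.out_dir, "gsea.tsv")
        write_enrichment_tsv(enrich, gsea_path)
        stages.append({
            "stage": "gsea",
            "n_sets": int(len(enrich)),
            "n_fdr_lt_0.01": int((enrich["FDR_q"] < 0.01).sum()) if len(enrich) else 0,
            "seed": config.seed,
            "files": {os.path.basename(gsea_path): _sha256(gsea_path)},
        })

        if config.run_control:
            current = "control"
            control = results.gsea_label_control(
                collection, n_permutations=config.n_permutations, seed=config.seed,
                weight_exponent=config.gsea_weight,
                min_size=config.gsea_min_size, max_size=config.gsea_max_size,
            )
            ctrl_path = os.path.join(config.out_dir, "gsea_control.tsv")
            write_enrichment_tsv(control, ctrl_path)
            stages.append({
                "stage": "control",
                "n_sets": int(len(control)),
                "n_fdr_lt_0.01": int((control["FDR_q"] < 0.01).sum()) if len(control) else 0,
                "seed": config.seed,
                "files": {os.path.basename(ctrl_path): _sha256(ctrl_path)},
            })
    except Exception as exc:
        failed_dir = os.path.join(config.out_dir, "failed")
        os.makedirs(failed_dir, exist_ok=True)
        for entry in os.listdir(config.out_dir):
            src = os.path.join(config.out_dir, entry)
            if entry != "failed" and os.path.isfile(src):
                shutil.move(src, os.path.join(failed_dir, entry))
        raise RuntimeError(f"pipeline failed at stage '{current}': {exc}") from exc

    manifest = RunManifest(stages=stages, seed=config.seed, params=_params_snapshot(config))
    manifest.to_json(os.path.join(config.out_dir, "manifest.json"))
    return manifest


def report(manifest: RunManifest, out_dir: str, top_n: int = 10) -> str:
    """Markdown run summary from the manifest and the stage output files."""
    score_path = os.path.join(out_dir, "scores.tsv")
    gsea_path = os.path.join(out_dir, "gsea.tsv")
    if not os.path.exists(score_path) or not os.path.exists(gsea_path):
        raise FileNotFoundError(f"stage outputs missing under {out_dir}")
    scores = pd.read_csv(score_path, sep="\t", index_col=0)
    enrich = pd.read_csv(gsea_path, sep="\t", index_col=0)

    lines = ["# dyscore run report", ""]
    lines.append("## Stages")
    for st in manifest.stages:
        lines.append(f"- **{st['stage']}**: " + ", ".join(
            f"{k}={v}" for k, v in st.items() if k not in ("stage", "files")
        ))
    qc_stage = next((s for s in manifest.stages if s["stage"] == "qc"), None)
    if qc_stage:
        lines += ["", "## Samples excluded at QC"]
        for name, n in qc_stage["excluded"].items():
            lines.append(f"- {name}: {n}")
    lines += ["", f"## Top {top_n} genes by D_overall", "",
              "| rank | gene | D_overall | concordance |", "|---|---|---|---|"]
    for gene, row in scores.sort_values("rank").head(top_n).iterrows():
        conc = row["concordance"]
        conc_s = f"{conc:.2f}" if np.isfinite(conc) else "NA"
        lines.append(f"| {int(row['rank'])} | {gene} | {row['D_overall']:.4f} | {conc_s} |")
    lines += ["", "## Enrichment (head)", "",
              "| set | size | NES | FDR_q | FWER_p |", "|---|---|---|---|---|"]
    for name, row in enrich.head(top_n).iterrows():
        lines.append(
            f"| {name} | {int(row['size'])} | {row['NES']:.3f} "
            f"| {row['FDR_q']:.4f} | {row['FWER_p']:.4f} |"
        )
    ctrl_path = os.path.join(out_dir, "gsea_control.tsv")
    if os.path.exists(ctrl_path):
        ctrl = pd.read_csv(ctrl_path, sep="\t", index_col=0)
        lines += ["", "## Label-permutation control",
                  f"- sets at FDR_q < 0.01: {int((ctrl['FDR_q'] < 0.01).sum())} "
                  f"(observed run: {int((enrich['FDR_q'] < 0.01).sum())})"]
    return "\n".join(lines)
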