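"""Synthetic multi-dataset expression cohorts with known ground truth.

Emulates a Parkinson's-disease reprogrammed-neuron study design: a handful
of independent case/control datasets — droplet and Patch-seq-like
single-cell plus several bulk RNA-seq sets — sharing one gene universe.
Counts follow a gamma-Poisson (negative binomial) model with subject- and
cell-level library-size variation; a chosen subset of genes carries a
multiplicative condition effect (the planted differentially expressed
genes), housekeeping genes are highly expressed with low dispersion and no
effect, and a configurable fraction of samples/cells is planted to violate
specific QC rules. Everything is reproducible from one master seed; each
dataset draws from its own child stream so adding a dataset never perturbs
the others.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import BULK, SINGLE_CELL, ExpressionDataset, compute_tpm, write_dataset, read_dataset

# QC-failure reason codes the generator can plant.
LOW_MAPPING = "LOW_MAPPING"
LOW_GENES = "LOW_GENES"
LOW_HK = "LOW_HK"
DOUBLET_GENES = "DOUBLET_GENES"
DOUBLET_UMI = "DOUBLET_UMI"

PLANTABLE_REASONS = (LOW_MAPPING, LOW_GENES, LOW_HK, DOUBLET_GENES, DOUBLET_UMI)

_DEFAULT_MODALITIES = (SINGLE_CELL, SINGLE_CELL, BULK, BULK, BULK, BULK)


class CohortSpecError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design being emulated: six datasets
    (two single-cell — one droplet/UMI, one Patch-seq-like — and four
    bulk), ten subjects per condition per bulk dataset (~80 bulk samples
    in total) and 4 subjects x 40 cells per condition for single cell.
    """

    n_genes: int = 2000
    n_datasets: int = 6
    modality_per_dataset: tuple[str, ...] | None = None
    droplet_per_dataset: tuple[bool, ...] | None = None
    n_subjects_per_condition: int | tuple[int, ...] | None = None
    cells_per_subject: int = 40
    n_true_de_genes: int = 100
    effect_log2fc: float = 2.0
    concordant_fraction: float = 0.8
    n_housekeeping: int = 98
    qc_failure_rates: dict[str, float] = field(
        default_factory=lambda: {LOW_MAPPING: 0.02, LOW_GENES: 0.02, LOW_HK: 0.02, DOUBLET_UMI: 0.02}
    )
    dispersion: float = 0.15
    hk_dispersion: float = 0.05
    library_size_mean: float = 5e5
    sc_library_size_mean: float = 1.5e4
    abundance_sigma: float = 1.25
    midbrain_detected_prob: float = 0.85
    gene_length_bp: float = 1000.0
    seed: int = 0

    def resolved_modalities(self) -> tuple[str, ...]:
        if self.modality_per_dataset is None:
            if self.n_datasets == len(_DEFAULT_MODALITIES):
                return _DEFAULT_MODALITIES
            # generic: first third single-cell, rest bulk
            n_sc = max(1, self.n_datasets // 3) if self.n_datasets > 1 else 1
            return tuple([SINGLE_CELL] * n_sc + [BULK] * (self.n_datasets - n_sc))
        return tuple(self.modality_per_dataset)

    def resolved_droplet(self) -> tuple[bool, ...]:
        mods = self.resolved_modalities()
        if self.droplet_per_dataset is not None:
            return tuple(self.droplet_per_dataset)
        # first single-cell dataset is droplet/UMI-based, later ones Patch-seq-like
        out, seen_sc = [], 0
        for m in mods:
            if m == SINGLE_CELL:
                out.append(seen_sc == 0)
                seen_sc += 1
            else:
                out.append(False)
        return tuple(out)

    def resolved_subjects(self) -> tuple[int, ...]:
        mods = self.resolved_modalities()
        if self.n_subjects_per_condition is None:
            return tuple(4 if m == SINGLE_CELL else 10 for m in mods)
        if isinstance(self.n_subjects_per_condition, int):
            return tuple([self.n_subjects_per_condition] * self.n_datasets)
        return tuple(self.n_subjects_per_condition)

    def validate(self) -> None:
        def _positive(name: str, value: float) -> None:
            if not value > 0:
                raise CohortSpecError(f"{name} must be positive, got {value}")

        _positive("n_genes", self.n_genes)
        _positive("n_datasets", self.n_datasets)
        _positive("cells_per_subject", self.cells_per_subject)
        _positive("effect_log2fc", self.effect_log2fc)
        _positive("dispersion", self.dispersion)
        _positive("library_size_mean", self.library_size_mean)
        _positive("sc_library_size_mean", self.sc_library_size_mean)
        if self.n_true_de_genes < 0:
            raise CohortSpecError(f"n_true_de_genes must be >= 0, got {self.n_true_de_genes}")
        if self.n_housekeeping < 0:
            raise CohortSpecError(f"n_housekeeping must be >= 0, got {self.n_housekeeping}")
        if self.n_true_de_genes + self.n_housekeeping > self.n_genes:
            raise CohortSpecError(
                "n_true_de_genes + n_housekeeping exceeds n_genes "
                f"({self.n_true_de_genes} + {self.n_housekeeping} > {self.n_genes})"
            )
        if not 0.0 <= self.concordant_fraction <= 1.0:
            raise CohortSpecError(
                f"concordant_fraction must lie in [0,1], got {self.concordant_fraction}"
            )
        for reason, rate in self.qc_failure_rates.items():
            if reason not in PLANTABLE_REASONS:
                raise CohortSpecError(f"qc_failure_rates: unknown reason {reason!r}")
            if not 0.0 <= rate <= 1.0:
                raise CohortSpecError(f"qc_failure_rates[{reason}] must lie in [0,1], got {rate}")
        if self.qc_failure_rates.get(DOUBLET_GENES, 0) > 0 and self.n_genes <= 8000:
            raise CohortSpecError(
                "qc_failure_rates[DOUBLET_GENES] > 0 requires n_genes > 8000 "
                "(a cell cannot exceed the >8000 detected-genes doublet cut otherwise)"
            )
        mods = self.resolved_modalities()
        if len(mods) != self.n_datasets:
            raise CohortSpecError(
                f"modality_per_dataset has {len(mods)} entries for n_datasets={self.n_datasets}"
            )
        for m in mods:
            if m not in (BULK, SINGLE_CELL):
                raise CohortSpecError(f"modality_per_dataset: unknown modality {m!r}")
        subj = self.resolved_subjects()
        if len(subj) != self.n_datasets or any(s < 1 for s in subj):
            raise CohortSpecError("n_subjects_per_condition must be >= 1 for every dataset")
        if len(self.resolved_droplet()) != self.n_datasets:
            raise CohortSpecError(
                f"droplet_per_dataset has {len(self.resolved_droplet())} entries "
                f"for n_datasets={self.n_datasets}"
            )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    ``de_log2fc`` holds the signed planted log2 fold change per gene and
    dataset (0 for unplanted genes); ``de_genes``/``housekeeping_genes``
    are disjoint id sets; ``planted_qc_failures`` maps dataset name ->
    {sample id -> reason code}.
    """

    de_genes: set[str]
    housekeeping_genes: set[str]
    de_log2fc: pd.DataFrame
    midbrain_detected: pd.Series
    planted_qc_failures: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        if self.de_genes & self.housekeeping_genes:
            raise ValueError("de_genes and housekeeping_genes overlap")


def _dataset_names(spec: CohortSpec) -> list[str]:
    mods = spec.resolved_modalities()
    droplet = spec.resolved_droplet()
    names, n_sc, n_bulk = [], 0, 0
    for m, d in zip(mods, droplet):
        if m == SINGLE_CELL:
            n_sc += 1
            names.append(f"sc{n_sc}-{'droplet' if d else 'patch'}")
        else:
            n_bulk += 1
            names.append(f"bulk{n_bulk}")
    return names


def generate_cohort(spec: CohortSpec) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Draw a full cohort and its ground truth from a :class:`CohortSpec`.

    One master ``numpy.random.SeedSequence`` is spawned into a global
    stream (gene universe, planted structure) plus one stream per dataset,
    in dataset order, so dataset ``i`` is unchanged if later datasets are
    added or removed.
    """
    spec.validate()
    mods = spec.resolved_modalities()
    droplet = spec.resolved_droplet()
    subjects_per_cond = spec.resolved_subjects()
    names = _dataset_names(spec)

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_datasets + 1)
    rng_global = np.random.default_rng(children[0])

    genes = pd.Index([f"G{i:05d}" for i in range(1, spec.n_genes + 1)], name="gene")
    perm = rng_global.permutation(spec.n_genes)
    de_idx = perm[: spec.n_true_de_genes]
    hk_idx = perm[spec.n_true_de_genes: spec.n_true_de_genes + spec.n_housekeeping]
    de_genes = set(genes[de_idx])
    hk_genes = set(genes[hk_idx])

    # relative abundances; housekeeping genes are high-expressed
    abundance = rng_global.lognormal(mean=0.0, sigma=spec.abundance_sigma, size=spec.n_genes)
    abundance[hk_idx] *= 8.0
    abundance /= abundance.sum()

    dispersion = np.full(spec.n_genes, spec.dispersion)
    dispersion[hk_idx] = spec.hk_dispersion

    midbrain = pd.Series(
        rng_global.random(spec.n_genes) < spec.midbrain_detected_prob, index=genes,
        name="midbrain_detected",
    )

    # planted effect directions: concordant genes share one sign across all
    # datasets; the rest flip independently per dataset with probability 1/2.
    # The per-dataset flips are drawn from each dataset's own child stream
    # (first draw, fixed order) so adding a dataset never perturbs the others.
    n_conc = int(round(spec.concordant_fraction * spec.n_true_de_genes))
    shared_sign = rng_global.choice([-1.0, 1.0], size=spec.n_true_de_genes)
    lengths = pd.Series(spec.gene_length_bp, index=genes, name="length")
    de_log2fc = pd.DataFrame(0.0, index=genes, columns=names)

    datasets: list[ExpressionDataset] = []
    planted_fail: dict[str, dict[str, str]] = {}
    for d in range(spec.n_datasets):
        rng = np.random.default_rng(children[d + 1])
        signs = shared_sign.copy()
        n_flip = spec.n_true_de_genes - n_conc
        if n_flip > 0:
            signs[n_conc:] *= rng.choice([-1.0, 1.0], size=n_flip)
        if spec.n_true_de_genes:
            de_log2fc.iloc[de_idx, d] = signs * spec.effect_log2fc
        ds, fails = _generate_dataset(
            spec, names[d], mods[d], droplet[d], subjects_per_cond[d],
            genes, abundance, dispersion, de_log2fc[names[d]].to_numpy(),
            hk_idx, lengths, rng,
        )
        datasets.append(ds)
        planted_fail[names[d]] = fails

    truth = GroundTruth(
        de_genes=de_genes,
        housekeeping_genes=hk_genes,
        de_log2fc=de_log2fc,
        midbrain_detected=midbrain,
        planted_qc_failures=planted_fail,
    )
    return datasets, truth


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and NB dispersion alpha=disp."""
    shape = 1.0 / disp
    lam = rng.gamma(shape=shape[:, None], scale=mu * disp[:, None])
    return rng.poisson(lam)


def _generate_dataset(
    spec: CohortSpec,
    name: str,
    modality: str,
    umi_based: bool,
    n_subj: int,
    genes: pd.Index,
    abundance: np.ndarray,
    dispersion: np.ndarray,
    log2fc: np.ndarray,
    hk_idx: np.ndarray,
    lengths: pd.Series,
    rng: np.random.Generator,
) -> tuple[ExpressionDataset, dict[str, str]]:
    conditions = ["control", "PD"]
    subj_ids = [f"{name}-{c}{i+1}" for c in ("C", "P") for i in range(n_subj)]
    subj_cond = ["control"] * n_subj + ["PD"] * n_subj
    subj_factor = rng.lognormal(mean=0.0, sigma=0.2, size=2 * n_subj)

    if modality == SINGLE_CELL:
        cells_per = spec.cells_per_subject
        sample_subject = np.repeat(subj_ids, cells_per)
        sample_cond = np.repeat(subj_cond, cells_per)
        sample_ids = [f"{s}-c{i+1:03d}" for s in subj_ids for i in range(cells_per)]
        lib = (
            spec.sc_library_size_mean
            * np.repeat(subj_factor, cells_per)
            * rng.lognormal(mean=0.0, sigma=0.12, size=len(sample_ids))
        )
        # clean cells sit safely below the 37.5k UMI doublet cut
        lib = np.minimum(lib, 32000.0)
    else:
        sample_subject = np.array(subj_ids)
        sample_cond = np.array(subj_cond)
        sample_ids = list(subj_ids)
        lib = spec.library_size_mean * subj_factor

    n_samples = len(sample_ids)
    # condition effect split symmetrically between groups: PD x 2^(+fc/2),
    # control x 2^(-fc/2). The PD:control expected ratio is exactly 2^fc while
    # the planted signal leaves the two groups' expected library composition
    # identical, so null genes see no systematic TPM shift.
    effect = np.ones((len(genes), n_samples))
    is_pd = np.asarray(sample_cond) == "PD"
    effect[:, is_pd] = np.power(2.0, log2fc / 2.0)[:, None]
    effect[:, ~is_pd] = np.power(2.0, -log2fc / 2.0)[:, None]

    rel = abundance[:, None] * effect
    rel /= rel.sum(axis=0, keepdims=True)
    mu = rel * lib[None, :]
    counts = _nb_counts(rng, mu, dispersion).astype(np.int64)

    mapping_rate = rng.uniform(0.72, 0.95, size=n_samples)

    # plant QC failures: at most one reason per sample, realized so the
    # intended rule is violated unambiguously
    applicable = [LOW_GENES, LOW_HK]
    if modality == SINGLE_CELL:
        applicable = [LOW_MAPPING, LOW_GENES, LOW_HK] + (
            [DOUBLET_UMI, DOUBLET_GENES] if umi_based else [DOUBLET_GENES]
        )
    fails: dict[str, str] = {}
    for j in range(n_samples):
        for reason in applicable:
            rate = spec.qc_failure_rates.get(reason, 0.0)
            if rate > 0 and rng.random() < rate:
                fails[sample_ids[j]] = reason
                break
    for sid, reason in fails.items():
        j = sample_ids.index(sid)
        if reason == LOW_MAPPING:
            mapping_rate[j] = rng.uniform(0.20, 0.45)
        elif reason == LOW_GENES:
            keep = rng.choice(len(genes), size=min(500, len(genes) // 2), replace=False)
            mask = np.zeros(len(genes), dtype=bool)
            mask[keep] = True
            counts[~mask, j] = 0
        elif reason == LOW_HK:
            if len(hk_idx):
                keep_n = min(50, max(0, len(hk_idx) - 60))
                drop = rng.permutation(hk_idx)[keep_n:]
                counts[drop, j] = 0
        elif reason == DOUBLET_UMI:
            target = rng.uniform(1.3, 1.8) * 37500.0
            col = _nb_counts(rng, rel[:, j: j + 1] * target, dispersion)[:, 0]
            counts[:, j] = col
        elif reason == DOUBLET_GENES:
            # uniform high-coverage cell detecting well over 8000 genes
            flat = np.full(len(genes), 1.0 / len(genes))
            col = rng.poisson(flat * 12 * len(genes))
            counts[:, j] = np.maximum(counts[:, j], col)

    counts_df = pd.DataFrame(counts, index=genes, columns=pd.Index(sample_ids))
    tpm_df = compute_tpm(counts_df, lengths)
    samples = pd.DataFrame(
        {
            "subject": sample_subject,
            "condition": sample_cond,
            "mapping_rate": mapping_rate,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    ds = ExpressionDataset(
        name=name, modality=modality, counts=counts_df, tpm=tpm_df,
        samples=samples, umi_based=umi_based, gene_lengths=lengths,
    )
    return ds, fails


# ---------------------------------------------------------------------------
# Cohort I/O and gene-set generation
# ---------------------------------------------------------------------------

def write_cohort(
    datasets: list[ExpressionDataset], ground_truth: GroundTruth, dir_path: str
) -> dict[str, list[str]]:
    """Write a cohort to disk; returns a manifest of files per component."""
    for ds in datasets:
        if ds.counts.shape[0] == 0:
            raise ValueError(f"dataset {ds.name}: empty gene list, nothing written")
    os.makedirs(dir_path, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    for ds in datasets:
        manifest[ds.name] = write_dataset(ds, dir_path)
    gt_path = os.path.join(dir_path, "ground_truth.tsv")
    gt = pd.DataFrame(
        {
            "is_de": [g in ground_truth.de_genes for g in ground_truth.de_log2fc.index],
            "is_housekeeping": [
                g in ground_truth.housekeeping_genes for g in ground_truth.de_log2fc.index
            ],
            "midbrain_detected": ground_truth.midbrain_detected.to_numpy(),
        },
        index=ground_truth.de_log2fc.index,
    )
    gt = pd.concat([gt, ground_truth.de_log2fc.add_prefix("log2fc:")], axis=1)
    gt.to_csv(gt_path, sep="\t", index_label="gene")
    fails_path = os.path.join(dir_path, "planted_qc_failures.tsv")
    rows = [
        {"dataset": d, "sample": s, "reason": r}
        for d, m in ground_truth.planted_qc_failures.items()
        for s, r in m.items()
    ]
    pd.DataFrame(rows, columns=["dataset", "sample", "reason"]).to_csv(
        fails_path, sep="\t", index=False
    )
    order_path = os.path.join(dir_path, "datasets.tsv")
    pd.DataFrame({"name": [d.name for d in datasets]}).to_csv(order_path, sep="\t", index=False)
    manifest["ground_truth"] = [gt_path, fails_path, order_path]
    return manifest


def read_cohort(dir_path: str) -> tuple[list[ExpressionDataset], GroundTruth]:
    names = pd.read_csv(os.path.join(dir_path, "datasets.tsv"), sep="\t")["name"].tolist()
    datasets = [read_dataset(dir_path, n) for n in names]
    gt = pd.read_csv(os.path.join(dir_path, "ground_truth.tsv"), sep="\t", index_col=0)
    fc_cols = [c for c in gt.columns if c.startswith("log2fc:")]
    de_log2fc = gt[fc_cols].rename(columns=lambda c: c[len("log2fc:"):])
    fails_df = pd.read_csv(os.path.join(dir_path, "planted_qc_failures.tsv"), sep="\t")
    planted: dict[str, dict[str, str]] = {n: {} for n in names}
    for _, row in fails_df.iterrows():
        planted.setdefault(row["dataset"], {})[row["sample"]] = row["reason"]
    truth = GroundTruth(
        de_genes=set(gt.index[gt["is_de"]]),
        housekeeping_genes=set(gt.index[gt["is_housekeeping"]]),
        de_log2fc=de_log2fc,
        midbrain_detected=gt["midbrain_detected"].astype(bool),
        planted_qc_failures=planted,
    )
    return datasets, truth


def generate_genesets(
    ground_truth: GroundTruth,
    n_random_sets: int = 20,
    size_range: tuple[int, int] = (15, 100),
    seed: int = 0,
):
    """Build a gene-set collection: the planted DE set plus random decoys.

    Random sets draw members uniformly from the cohort's gene universe;
    sizes are uniform over ``size_range``. Returns a
    :class:`~dyscore.gsea.GeneSetCollection`.
    """
    from .gsea import GeneSet, GeneSetCollection

    universe = list(ground_truth.de_log2fc.index)
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise CohortSpecError(
            f"size_range {size_range} infeasible for a universe of {len(universe)} genes"
        )
    rng = np.random.default_rng(seed)
    sets = {
        "planted_de": GeneSet(
            "planted_de", "planted differentially expressed genes",
            tuple(sorted(ground_truth.de_genes)),
        )
    }
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sname = f"random_{i+1:03d}"
        sets[sname] = GeneSet(
            sname, "uniformly sampled decoy set",
            tuple(universe[j] for j in sorted(members)),
        )
    return GeneSetCollection(sets)
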