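import numpy as np
import pandas as pd
import pytest

from dyscore.datasets import BULK, SINGLE_CELL, ExpressionDataset, compute_tpm
from dyscore.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size cohort (2 sc + 4 bulk, 2000 genes) with planted QC failures."""
    spec = CohortSpec(seed=7)
    datasets, truth = generate_cohort(spec)
    return spec, datasets, truth


@pytest.fixture(scope="session")
def tiny_bulk_dataset():
    """Hand-sized bulk dataset (40 genes, 5+5 samples) for DE-path tests."""
    rng = np.random.default_rng(42)
    genes = pd.Index([f"g{i}" for i in range(40)], name="gene")
    samples = pd.Index([f"s{j}" for j in range(10)])
    mu = rng.lognormal(4, 1, size=40)
    counts = rng.poisson(mu[:, None], size=(40, 10))
    counts[0] = 0  # an all-zero (unexpressed) gene
    counts = pd.DataFrame(counts, index=genes, columns=samples)
    meta = pd.DataFrame(
        {"subject": samples, "condition": ["control"] * 5 + ["PD"] * 5,
         "mapping_rate": 0.9},
        index=samples,
    )
    return ExpressionDataset(
        name="tiny-bulk", modality=BULK, counts=counts,
        tpm=compute_tpm(counts), samples=meta,
    )


def make_sc_dataset(counts: pd.DataFrame, subjects=None, umi_based=True,
                    name="sc-test") -> ExpressionDataset:
    cells = counts.columns
    meta = pd.DataFrame(
        {
            "subject": subjects if subjects is not None else ["subj1"] * len(cells),
            "condition": ["PD"] * len(cells),
            "mapping_rate": 0.9,
        },
        index=cells,
    )
    return ExpressionDataset(
        name=name, modality=SINGLE_CELL, counts=counts,
        tpm=compute_tpm(counts), samples=meta, umi_based=umi_based,
    )
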