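"""Dual differential-expression testing and p-value combination.

Each dataset is tested for PD-vs-control differences twice per gene —
once on counts, once on TPM — and the two p-values are merged with the
logit (Mudholkar–George) combination. Fold changes from the two routes
are averaged arithmetically on the log2 scale.

Count route: for bulk data, a negative-binomial GLM Wald test on
median-of-ratios-normalized counts (dispersion by method of moments,
floored at 1e-8); for single-cell data, a Wilcoxon rank-sum test on
library-size-normalized counts. TPM route: Wilcoxon rank-sum on raw TPM.
Genes not expressed (< 1 TPM in fewer than 10% of samples) carry p = 1
on both routes and a zero fold change.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .datasets import BULK, SINGLE_CELL, ExpressionDataset

logger = logging.getLogger(__name__)

LOGIT_EPS = 1e-15
#: pseudocounts for log2 fold changes on the two measurement scales
PSEUDOCOUNT_COUNTS = 1.0
PSEUDOCOUNT_TPM = 0.01

DE_COLUMNS = (
    "expressed", "p_count", "p_tpm", "p_combined",
    "log2fc_count", "log2fc_tpm", "log2fc_mean",
)


# ---------------------------------------------------------------------------
# expression mask
# ---------------------------------------------------------------------------

def expressed_mask(
    tpm: pd.DataFrame, min_tpm: float = 1.0, min_fraction: float = 0.10
) -> pd.Series:
    """Genes expressed at >= ``min_tpm`` TPM in at least ``min_fraction`` of samples.

    The sample threshold is ``ceil(min_fraction * n_samples)``, so one
    qualifying sample out of ten suffices at the defaults.
    """
    if tpm.shape[0] == 0 or tpm.shape[1] == 0:
        raise ValueError("expressed_mask: empty TPM matrix")
    n_needed = math.ceil(min_fraction * tpm.shape[1])
    n_needed = max(n_needed, 1)
    return (tpm >= min_tpm).sum(axis=1).ge(n_needed).rename("expressed")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= 8 observations and the
    pooled sample is tie-free; tie-corrected normal approximation without
    continuity correction otherwise (so identical groups give exactly 1).
    A pooled sample with zero variance returns 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_test: both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    p = float(res.pvalue)
    if not np.isfinite(p):
        return 1.0
    return min(p, 1.0)


def wilcoxon_matrix(values: np.ndarray, group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation rank-sum test.

    ``values`` is genes x samples; ``group_a``/``group_b`` are boolean
    column masks. Used genome-wide when groups are large enough that the
    normal approximation applies; agrees with :func:`wilcoxon_test` there.
    """
    sub = values[:, group_a | group_b]
    in_a = group_a[group_a | group_b]
    n1, n2 = int(in_a.sum()), int((~in_a).sum())
    n = n1 + n2
    ranks = scipy.stats.rankdata(sub, axis=1)
    r1 = ranks[:, in_a].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene
    tie_term = np.zeros(sub.shape[0])
    for g in range(sub.shape[0]):
        _, counts = np.unique(sub[g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma2 > 0, (u1 - mu) / np.sqrt(np.maximum(sigma2, 1e-300)), 0.0)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    p[sigma2 <= 0] = 1.0
    return np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# bulk count test: NB GLM Wald on median-of-ratios-normalized counts
# ---------------------------------------------------------------------------

def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median of count/geometric-mean ratios.

    Only genes with strictly positive counts in every sample enter the
    reference; if none exist, total-count ratios are used instead.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if allpos.sum() >= 1:
        ref = np.exp(np.log(arr[allpos]).mean(axis=1))
        ratios = arr[allpos] / ref[:, None]
        sf = np.median(ratios, axis=0)
    else:
        logger.warning("no gene has positive counts in all samples; using total-count size factors")
        totals = arr.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    sf = np.where(sf > 0, sf, 1.0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _mom_dispersion(q: np.ndarray, in_a: np.ndarray) -> float:
    """Method-of-moments NB dispersion from normalized counts, pooled within groups."""
    groups = [q[in_a], q[~in_a]]
    n = len(q)
    var_w = sum((g.size - 1) * g.var(ddof=1) for g in groups if g.size > 1) / max(n - 2, 1)
    mean = q.mean()
    if mean <= 0:
        return 1e-8
    return max((var_w - mean) / mean**2, 1e-8)


def nb_wald_test(
    counts: np.ndarray,
    in_a: np.ndarray,
    size_factors: np.ndarray,
) -> float:
    """Wald p-value for the group coefficient of an NB GLM with log link.

    The model is ``counts ~ 1 + group`` with ``log(size_factor)`` offsets;
    the dispersion is a per-gene method-of-moments estimate. Returns 1 for
    all-zero genes; falls back to a rank-sum test on normalized counts if
    the IRLS fit fails to produce a finite Wald statistic.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        return 1.0
    q = counts / size_factors
    alpha = _mom_dispersion(q, in_a)
    x = sm.add_constant(in_a.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(
                counts, x, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(size_factors),
            )
            fit = model.fit(maxiter=50)
        p = float(fit.pvalues[1])
        if np.isfinite(p):
            return min(max(p, 0.0), 1.0)
    except Exception:  # singular fits, perfect separation, etc.
        pass
    return wilcoxon_test(q[in_a], q[~in_a])


def count_test(
    counts_per_group: tuple[np.ndarray, np.ndarray],
    modality: str,
    size_factors: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Count-route p-value for one gene.

    Single-cell: Wilcoxon rank-sum on normalized counts. Bulk: NB Wald
    (requires >= 2 samples per group).
    """
    a, b = (np.asarray(g, dtype=float) for g in counts_per_group)
    if a.size == 0 or b.size == 0:
        raise ValueError("count_test: both groups must be non-empty")
    if modality == SINGLE_CELL:
        if size_factors is not None:
            a = a / size_factors[0]
            b = b / size_factors[1]
        return wilcoxon_test(a, b)
    if a.size < 2 or b.size < 2:
        raise ValueError("count_test: bulk NB Wald needs >= 2 samples per group")
    if size_factors is None:
        sf = (np.ones_like(a), np.ones_like(b))
    else:
        sf = size_factors
    stacked = np.concatenate([a, b])
    in_a = np.concatenate([np.ones(a.size, bool), np.zeros(b.size, bool)])
    return nb_wald_test(stacked, in_a, np.concatenate([sf[0], sf[1]]))


# ---------------------------------------------------------------------------
# logit p-value combination (Mudholkar–George)
# ---------------------------------------------------------------------------

def combine_pvalues_logit(p_a, p_b):
    """Combine two p-values by the logit method.

    ``L = -sum(log(p_i / (1 - p_i)))`` is scaled by
    ``sqrt(3 (5k + 4) / (k pi^2 (5k + 2)))`` (k = 2) and referred to the
    upper tail of Student's t with ``5k + 4 = 14`` degrees of freedom.
    Inputs are clamped to ``[1e-15, 1 - 1e-15]``; scalars in, scalar out.
    """
    p = np.asarray([p_a, p_b], dtype=float)
    scalar = p.ndim == 1 and np.isscalar(p_a)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"p-values must lie in [0, 1], got ({p_a}, {p_b})")
    p = np.clip(p, LOGIT_EPS, 1.0 - LOGIT_EPS)
    k = 2
    L = -np.sum(np.log(p / (1.0 - p)), axis=0)
    t = L * math.sqrt(3.0 * (5 * k + 4) / (k * math.pi**2 * (5 * k + 2)))
    out = scipy.stats.t.sf(t, df=5 * k + 4)
    out = np.clip(out, np.nextafter(0.0, 1.0), 1.0)
    return float(out) if scalar else out


def combine_pvalues_logit_vec(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    """Vectorized logit combination over aligned p-value arrays."""
    pa = np.clip(np.asarray(p_a, float), LOGIT_EPS, 1 - LOGIT_EPS)
    pb = np.clip(np.asarray(p_b, float), LOGIT_EPS, 1 - LOGIT_EPS)
    k = 2
    L = -(np.log(pa / (1 - pa)) + np.log(pb / (1 - pb)))
    t = L * math.sqrt(3.0 * (5 * k + 4) / (k * math.pi**2 * (5 * k + 2)))
    return np.clip(scipy.stats.t.sf(t, df=5 * k + 4), np.nextafter(0.0, 1.0), 1.0)


def log2_fold_change(mean_case: float, mean_control: float, pseudocount: float) -> float:
    """``log2((mean_case + c) / (mean_control + c))`` with pseudocount c."""
    if mean_case < 0 or mean_control < 0:
        raise ValueError("group means must be non-negative")
    return math.log2((mean_case + pseudocount) / (mean_control + pseudocount))


# ---------------------------------------------------------------------------
# per-dataset driver
# ---------------------------------------------------------------------------

def run_de(
    dataset: ExpressionDataset,
    min_tpm: float = 1.0,
    min_fraction: float = 0.10,
    condition_col: str = "condition",
    case: str = "PD",
    control: str = "control",
) -> pd.DataFrame:
    """Dual DE test for one (QC-filtered) dataset.

    Returns one row per gene with columns ``expressed, p_count, p_tpm,
    p_combined, log2fc_count, log2fc_tpm, log2fc_mean``. Unexpressed genes
    carry p = 1 everywhere and zero fold changes.
    """
    cond = dataset.samples.loc[dataset.counts.columns, condition_col]
    in_case = (cond == case).to_numpy()
    in_ctrl = (cond == control).to_numpy()
    if in_case.sum() < 2 or in_ctrl.sum() < 2:
        raise ValueError(
            f"dataset {dataset.name}: need >= 2 samples per condition, "
            f"got {int(in_case.sum())} {case} / {int(in_ctrl.sum())} {control}"
        )
    expressed = expressed_mask(dataset.tpm, min_tpm=min_tpm, min_fraction=min_fraction)
    genes = dataset.counts.index
    exp_arr = expressed.to_numpy()

    counts = dataset.counts.to_numpy(dtype=float)
    tpm = dataset.tpm.to_numpy(dtype=float)

    p_count = np.ones(len(genes))
    p_tpm = np.ones(len(genes))
    fc_count = np.zeros(len(genes))
    fc_tpm = np.zeros(len(genes))

    if dataset.modality == BULK:
        sf = median_of_ratios_size_factors(dataset.counts).to_numpy()
        norm = counts / sf
        for i in np.flatnonzero(exp_arr):
            p_count[i] = nb_wald_test(counts[i], in_case, sf)
    else:
        # per-cell library-size normalization (counts per 10k)
        totals = counts.sum(axis=0)
        sf = np.where(totals > 0, totals / 1e4, 1.0)
        norm = counts / sf
        if exp_arr.any():
            p_count[exp_arr] = wilcoxon_matrix(norm[exp_arr], in_case, in_ctrl)

    if exp_arr.any():
        small = in_case.sum() <= 8 and in_ctrl.sum() <= 8
        if small:
            for i in np.flatnonzero(exp_arr):
                p_tpm[i] = wilcoxon_test(tpm[i, in_case], tpm[i, in_ctrl])
        else:
            p_tpm[exp_arr] = wilcoxon_matrix(tpm[exp_arr], in_case, in_ctrl)

    mean_case_n = norm[:, in_case].mean(axis=1)
    mean_ctrl_n = norm[:, in_ctrl].mean(axis=1)
    mean_case_t = tpm[:, in_case].mean(axis=1)
    mean_ctrl_t = tpm[:, in_ctrl].mean(axis=1)
    fc_count = np.log2((mean_case_n + PSEUDOCOUNT_COUNTS) / (mean_ctrl_n + PSEUDOCOUNT_COUNTS))
    fc_tpm = np.log2((mean_case_t + PSEUDOCOUNT_TPM) / (mean_ctrl_t + PSEUDOCOUNT_TPM))
    fc_count[~exp_arr] = 0.0
    fc_tpm[~exp_arr] = 0.0

    p_combined = np.ones(len(genes))
    p_combined[exp_arr] = combine_pvalues_logit_vec(p_count[exp_arr], p_tpm[exp_arr])

    out = pd.DataFrame(
        {
            "expressed": exp_arr,
            "p_count": p_count,
            "p_tpm": p_tpm,
            "p_combined": p_combined,
            "log2fc_count": fc_count,
            "log2fc_tpm": fc_tpm,
            "log2fc_mean": (fc_count + fc_tpm) / 2.0,
        },
        index=genes,
    )
    return out


def write_de_table(de: pd.DataFrame, path: str) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["expressed"] = df["expressed"].astype(bool)
    return df
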