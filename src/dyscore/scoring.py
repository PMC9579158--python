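"""Desirability-based per-gene dysregulation scoring.

Per dataset, three desirabilities are assigned to every gene:

* ``d_p`` — combined p-value mapped linearly from 1 (at the dataset's
  minimum observed p) down to 0.01 (at p > 0.05);
* ``d_fc`` — fold-change magnitude mapped linearly from 0.01 (fold
  change <= 1.25) up to 1 (fold change >= 2); direction is ignored here
  and handled by the cross-dataset concordance factor;
* ``d_mb`` — 1.0 if the gene's transcript is detected in adult midbrain,
  0.25 otherwise (a soft relevance prior).

These combine into ``D_dataset`` by a weighted geometric mean with
weights 1, 0.5 and 0.01; genes not expressed in a dataset are floored at
0.01. ``D_overall`` is the weighted geometric mean of all per-dataset
scores (equal weights) together with a fold-change-direction concordance
desirability carrying one tenth of the total weight. Genes are ranked by
decreasing ``D_overall``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCORE_COLUMNS = ("n_expressed_datasets", "concordance", "concordance_desirability",
                 "D_overall", "rank")


@dataclass
class DesirabilityParams:
    """Cut points, floors and weights of the desirability mappings."""

    p_high_cut: float = 0.05
    p_low_cut: float | str = "min"  # per-dataset minimum observed combined p
    fc_low_cut: float = 1.25
    fc_high_cut: float = 2.0
    d_min: float = 0.01
    d_max: float = 1.0
    midbrain_detected_score: float = 1.0
    midbrain_undetected_score: float = 0.25
    w_p: float = 1.0
    w_fc: float = 0.5
    w_mb: float = 0.01
    concordance_weight_share: float = 0.10

    def validate(self) -> None:
        if not 0 < self.d_min < self.d_max <= 1:
            raise ValueError(f"require 0 < d_min < d_max <= 1, got ({self.d_min}, {self.d_max})")
        if not self.fc_low_cut < self.fc_high_cut:
            raise ValueError(
                f"fc_low_cut ({self.fc_low_cut}) must be < fc_high_cut ({self.fc_high_cut})"
            )
        if min(self.w_p, self.w_fc, self.w_mb) <= 0:
            raise ValueError("desirability weights must be positive")
        if not 0 <= self.concordance_weight_share < 1:
            raise ValueError("concordance_weight_share must lie in [0, 1)")
        if isinstance(self.p_low_cut, str) and self.p_low_cut != "min":
            raise ValueError(f"p_low_cut must be a probability or 'min', got {self.p_low_cut!r}")

    def resolve_p_low(self, observed_p) -> float:
        """Numeric lower cut: the configured value, or the minimum observed p."""
        if self.p_low_cut == "min":
            arr = np.asarray(observed_p, dtype=float)
            if arr.size == 0:
                raise ValueError("cannot resolve p_low_cut='min' without observed p-values")
            return float(arr.min())
        return float(self.p_low_cut)


DEFAULT_PARAMS = DesirabilityParams()


def desirability_pvalue(p, params: DesirabilityParams = DEFAULT_PARAMS, p_low: float | None = None):
    """Map combined p-values to desirability.

    ``p <= p_low`` gives ``d_max``; ``p > p_high_cut`` gives ``d_min``;
    linear interpolation in p between the cuts. ``p_low`` is the resolved
    lower cut (the dataset's minimum observed p under the default
    ``p_low_cut='min'``). When the resolved minimum is itself above the
    upper cut, every gene maps to ``d_min`` (degenerate dataset, no
    significant genes); an explicitly configured numeric
    ``p_low_cut >= p_high_cut`` raises instead.
    """
    params.validate()
    arr = np.asarray(p, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p_low is None:
        p_low = params.resolve_p_low(arr)
    if p_low >= params.p_high_cut:
        if not isinstance(params.p_low_cut, str):
            raise ValueError(
                f"p_low_cut ({p_low}) must be below p_high_cut ({params.p_high_cut})"
            )
        out = np.full_like(arr, params.d_min)
    else:
        frac = (arr - p_low) / (params.p_high_cut - p_low)
        out = params.d_max - frac * (params.d_max - params.d_min)
        out = np.clip(out, params.d_min, params.d_max)
        out[arr > params.p_high_cut] = params.d_min
        out[arr <= p_low] = params.d_max
    return float(out[0]) if scalar else out


def desirability_foldchange(log2fc, params: DesirabilityParams = DEFAULT_PARAMS):
    """Map the fold-change magnitude ``2**|log2fc|`` to desirability.

    Linear interpolation in the fold change between ``fc_low_cut``
    (desirability ``d_min``) and ``fc_high_cut`` (``d_max``); symmetric in
    direction — up- and down-regulation score alike.
    """
    params.validate()
    arr = np.asarray(log2fc, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(~np.isfinite(arr)):
        raise ValueError("log2 fold changes must be finite")
    fc = np.power(2.0, np.abs(arr))
    frac = (fc - params.fc_low_cut) / (params.fc_high_cut - params.fc_low_cut)
    out = params.d_min + frac * (params.d_max - params.d_min)
    out = np.clip(out, params.d_min, params.d_max)
    return float(out[0]) if scalar else out


def desirability_midbrain(detected, params: DesirabilityParams = DEFAULT_PARAMS):
    """Adult-midbrain detection desirability: 1.0 if detected, 0.25 otherwise."""
    arr = np.asarray(detected, dtype=bool)
    scalar = arr.ndim == 0
    out = np.where(arr, params.midbrain_detected_score, params.midbrain_undetected_score)
    return float(out) if scalar else out


def weighted_geometric_mean(values, weights) -> float:
    """``exp(sum(w_i ln v_i) / sum(w_i))`` for strictly positive values."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(v <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.sum(w * np.log(v)) / np.sum(w)))


def d_dataset(
    d_p, d_fc, d_mb,
    params: DesirabilityParams = DEFAULT_PARAMS,
    expressed=True,
):
    """Per-dataset dysregulation score.

    Weighted geometric mean of the three desirabilities with weights
    (1, 0.5, 0.01); unexpressed genes get the ``d_min`` floor regardless
    of the desirabilities. Vectorized over aligned arrays.
    """
    params.validate()
    dp = np.atleast_1d(np.asarray(d_p, dtype=float))
    dfc = np.atleast_1d(np.asarray(d_fc, dtype=float))
    dmb = np.atleast_1d(np.asarray(d_mb, dtype=float))
    exp = np.atleast_1d(np.asarray(expressed, dtype=bool))
    dp, dfc, dmb, exp = np.broadcast_arrays(dp, dfc, dmb, exp)
    if np.any(dp <= 0) or np.any(dfc <= 0) or np.any(dmb <= 0):
        raise ValueError("desirabilities must be strictly positive")
    w_sum = params.w_p + params.w_fc + params.w_mb
    logd = (
        params.w_p * np.log(dp) + params.w_fc * np.log(dfc) + params.w_mb * np.log(dmb)
    ) / w_sum
    out = np.where(exp, np.exp(logd), params.d_min)
    return float(out[0]) if out.size == 1 and np.isscalar(d_p) else out


def concordance_factor(
    log2fc_expressed, params: DesirabilityParams = DEFAULT_PARAMS
) -> tuple[float, float]:
    """Fold-change-direction concordance across the expressed datasets.

    ``c = |n_up - n_down| / (n_up + n_down)`` over the expressed datasets
    with non-zero fold change; zero fold changes are excluded from both
    counts. The desirability is ``d_min + c * (1 - d_min)``. With a single
    expressed dataset c = 1; with none (or all-zero fold changes) the
    concordance is undefined (NaN) and the desirability floors at d_min.
    """
    params.validate()
    arr = np.asarray(log2fc_expressed, dtype=float)
    n_up = int(np.sum(arr > 0))
    n_down = int(np.sum(arr < 0))
    if n_up + n_down == 0:
        return float("nan"), params.d_min
    c = abs(n_up - n_down) / (n_up + n_down)
    return c, params.d_min + c * (1.0 - params.d_min)


def d_overall(
    d_datasets,
    concordance_desirability: float,
    params: DesirabilityParams = DEFAULT_PARAMS,
) -> float:
    """Cross-dataset dysregulation score.

    Weighted geometric mean of all per-dataset scores (weight 1 each)
    with the concordance desirability at a weight chosen so it carries
    ``concordance_weight_share`` of the total (for six datasets and a
    10% share: w_c = 2/3).
    """
    params.validate()
    ds = np.asarray(d_datasets, dtype=float)
    if ds.size == 0:
        raise ValueError("d_overall requires at least one dataset score")
    if np.any(ds <= 0) or concordance_desirability <= 0:
        raise ValueError("scores must be strictly positive")
    share = params.concordance_weight_share
    w_c = share / (1.0 - share) * ds.size if share > 0 else 0.0
    values = np.append(ds, concordance_desirability)
    weights = np.append(np.ones(ds.size), w_c)
    if w_c == 0:
        values, weights = ds, np.ones(ds.size)
    return weighted_geometric_mean(values, weights)


def group_score(d_datasets_subset) -> float:
    """Unweighted geometric mean of a subset of per-dataset scores.

    Used for modality-level summaries (e.g. the single-cell-only or
    bulk-only dysregulation strength of a gene); no concordance term.
    """
    ds = np.asarray(d_datasets_subset, dtype=float)
    if ds.size == 0:
        raise ValueError("group_score requires a non-empty subset")
    if np.any(ds <= 0):
        raise ValueError("scores must be strictly positive")
    return float(np.exp(np.mean(np.log(ds))))


def rank_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Assign ranks by decreasing ``D_overall``.

    Ties are broken deterministically: lower sum of combined p-values
    across datasets first, then lexicographic gene id. Returns the table
    sorted with a ``rank`` column (1 = most dysregulated).
    """
    if "D_overall" not in table.columns:
        raise ValueError("table lacks a D_overall column")
    tie = table["p_combined_sum"] if "p_combined_sum" in table.columns else pd.Series(
        0.0, index=table.index
    )
    key = pd.DataFrame(
        {"D": table["D_overall"].to_numpy(), "tie": tie.to_numpy(),
         "gid": table.index.astype(str)},
        index=pd.RangeIndex(len(table)),
    )
    pos = key.sort_values(["D", "tie", "gid"], ascending=[False, True, True],
                          kind="mergesort").index
    order = table.index[pos]
    out = table.loc[order].copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_genes(
    de_tables: dict[str, pd.DataFrame],
    midbrain_detected: pd.Series,
    params: DesirabilityParams = DEFAULT_PARAMS,
    universe: pd.Index | None = None,
) -> pd.DataFrame:
    """Full scoring table from per-dataset DE results.

    ``de_tables`` maps dataset name -> DE table (as from
    :func:`dyscore.de.run_de`). The gene universe defaults to the union of
    genes expressed in at least one dataset; genes unexpressed in a given
    dataset contribute the 0.01 floor there. Midbrain flags default to
    detected for genes absent from the annotation.

    Returns one row per gene with per-dataset ``d_p:<ds>``, ``d_fc:<ds>``,
    ``D:<ds>`` columns, the concordance factor and desirability,
    ``D_overall`` and ``rank`` (sorted by rank).
    """
    params.validate()
    if not de_tables:
        raise ValueError("score_genes requires at least one DE table")
    names = list(de_tables)
    if universe is None:
        expressed_any = None
        for name in names:
            exp = de_tables[name]["expressed"]
            expressed_any = exp if expressed_any is None else (
                expressed_any.reindex(expressed_any.index.union(exp.index), fill_value=False)
                | exp.reindex(expressed_any.index.union(exp.index), fill_value=False)
            )
        universe = expressed_any.index[expressed_any]
    universe = pd.Index(universe)

    mb = midbrain_detected.reindex(universe).fillna(True).astype(bool)
    d_mb = desirability_midbrain(mb.to_numpy(), params)

    table = pd.DataFrame(index=universe)
    D_cols = []
    fc_signs = pd.DataFrame(np.nan, index=universe, columns=names)
    p_sum = np.zeros(len(universe))
    n_expressed = np.zeros(len(universe), dtype=int)
    for name in names:
        de = de_tables[name].reindex(universe)
        expressed = de["expressed"].fillna(False).astype(bool).to_numpy()
        p = de["p_combined"].fillna(1.0).to_numpy()
        fc = de["log2fc_mean"].fillna(0.0).to_numpy()
        p_low = params.resolve_p_low(p[expressed]) if expressed.any() else params.p_high_cut
        dp = desirability_pvalue(np.clip(p, 1e-300, 1.0), params, p_low=p_low)
        dfc = desirability_foldchange(fc, params)
        D = d_dataset(dp, dfc, d_mb, params, expressed=expressed)
        table[f"d_p:{name}"] = dp
        table[f"d_fc:{name}"] = dfc
        table[f"D:{name}"] = D
        D_cols.append(f"D:{name}")
        fc_signs.loc[expressed, name] = fc[expressed]
        p_sum += p
        n_expressed += expressed.astype(int)
    table["d_mb"] = d_mb
    table["n_expressed_datasets"] = n_expressed
    table["p_combined_sum"] = p_sum

    conc = np.empty(len(universe))
    conc_d = np.empty(len(universe))
    fc_arr = fc_signs.to_numpy()
    for i in range(len(universe)):
        row = fc_arr[i]
        c, cd = concordance_factor(row[~np.isnan(row)], params)
        conc[i] = c
        conc_d[i] = cd
    table["concordance"] = conc
    table["concordance_desirability"] = conc_d

    D_mat = table[D_cols].to_numpy()
    share = params.concordance_weight_share
    w_c = share / (1.0 - share) * D_mat.shape[1] if share > 0 else 0.0
    w_total = D_mat.shape[1] + w_c
    log_D = (np.log(D_mat).sum(axis=1) + w_c * np.log(conc_d)) / w_total
    table["D_overall"] = np.exp(log_D)

    return rank_genes(table)


def to_rnk(scores: pd.DataFrame, path: str | None = None) -> pd.Series:
    """Ranked-list export: gene -> D_overall, sorted decreasing.

    Written as a two-column tab-separated RNK file when ``path`` is given.
    """
    ranked = scores.sort_values("rank")["D_overall"]
    if path is not None:
        ranked.to_csv(path, sep="\t", header=False)
    return ranked
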