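"""Self-contained pre-ranked gene-set enrichment analysis.

Implements the classic weighted Kolmogorov–Smirnov-like running-sum
statistic on an externally ranked gene list, with:

* gene-tag permutations (random same-size member draws from the ranked
  universe) as the null model,
* mean-division normalization (NES = ES divided by the mean magnitude of
  same-sign null ES for that set),
* nominal p-values from the same-sign null ES tail,
* FDR-q per the sign-stratified pooled-NES procedure (observed vs null
  tail fractions, clamped to [0, 1] and monotonized from the extreme
  end), and
* FWER p-values from the per-permutation maximum same-sign NES.

A label-permutation negative control (shuffling the gene <-> score
assignment before analysis) is provided to verify that reported
enrichments vanish on scrambled input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("size", "ES", "NES", "p_nominal", "FDR_q", "FWER_p", "leading_edge")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name}: duplicate members")


@dataclass
class GeneSetCollection:
    """Named gene sets, iteration order = insertion order."""

    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB members...).

    Trailing blank fields are dropped; duplicate members within a line are
    removed with a warning. Lines with fewer than three fields raise with
    the line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            seen, deduped = set(), []
            for m in members:
                if m in seen:
                    continue
                seen.add(m)
                deduped.append(m)
            if len(deduped) < len(members):
                logger.warning("%s:%d: set %s has duplicate members; deduplicated", path, lineno, name)
            sets[name] = GeneSet(name, desc, tuple(deduped))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def restrict_and_filter(
    collection: GeneSetCollection,
    universe,
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect members with the ranked universe and drop out-of-range sets.

    Size bounds are inclusive: a 15-member set survives ``min_size=15``.
    """
    universe = pd.Index(universe)
    if len(universe) == 0:
        raise ValueError("restrict_and_filter: empty universe")
    uni = set(universe)
    kept: dict[str, GeneSet] = {}
    for gs in collection:
        members = tuple(g for g in gs.genes if g in uni)
        if min_size <= len(members) <= max_size:
            kept[gs.name] = GeneSet(gs.name, gs.description, members)
    return GeneSetCollection(kept)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked: pd.Series, set_members, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score of one set.

    ``ranked`` is a gene -> score Series already sorted in ranking order
    (best first). Walking down the list, member hits add
    ``|score|**weight / N_R`` (``N_R`` the sum of hit weights) and misses
    subtract ``1/(N - N_hits)``; ES is the running-sum value of maximal
    absolute deviation with its sign. Returns ``(ES, running_sum,
    leading_edge)`` where the leading edge holds the hits at or before
    the positive extremum (ES > 0) or at/after the negative extremum.
    """
    scores = ranked.to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranked scores must be finite")
    genes = ranked.index
    members = set(set_members)
    unknown = members.difference(genes)
    if unknown:
        raise ValueError(f"set members outside the ranked universe: {sorted(unknown)[:5]}")
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    n = len(genes)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("enrichment_score: no set members in the universe")
    if n_hits == n:
        # no misses: the running sum climbs monotonically to exactly 1
        w = np.abs(scores) ** weight_exponent
        nr = w.sum()
        if nr <= 0:
            raise ValueError("all hit scores are zero; N_R undefined")
        running = np.cumsum(w) / nr
        return 1.0, running, list(genes)
    w = np.abs(scores) ** weight_exponent
    nr = w[hit].sum()
    if nr <= 0:
        raise ValueError("all hit scores are zero; N_R undefined")
    steps = np.where(hit, w / nr, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if abs(running[i_max]) >= abs(running[i_min]):
        es = float(running[i_max])
        leading = [g for g, h in zip(genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        es = float(running[i_min])
        leading = [g for g, h in zip(genes[i_min:], hit[i_min:]) if h]
    return es, running, leading


def _es_null_matrix(
    weights: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution from random same-size member draws.

    Vectorized over permutations: only the sorted hit positions matter.
    ``weights`` are ``|score|**exponent`` in ranking order.
    """
    n = weights.shape[0]
    m = set_size
    # sorted random m-subsets per permutation
    pos = np.empty((n_perm, m), dtype=np.int64)
    for r in range(n_perm):
        pos[r] = rng.choice(n, size=m, replace=False)
    pos.sort(axis=1)
    hit_w = weights[pos]
    nr = hit_w.sum(axis=1, keepdims=True)
    nr = np.where(nr > 0, nr, np.inf)  # all-zero draws give a flat (0) ES
    cum_hit = np.cumsum(hit_w, axis=1) / nr
    j = np.arange(1, m + 1)
    miss_denom = n - m
    # running sum just after hit j and just before hit j
    after = cum_hit - (pos + 1 - j) / miss_denom
    before = np.concatenate([np.zeros((n_perm, 1)), cum_hit[:, :-1]], axis=1) - (
        pos - (j - 1)
    ) / miss_denom
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    es = np.where(np.abs(hi) >= np.abs(lo), hi, lo)
    return es


def preranked_gsea(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a restricted collection.

    ``ranked`` maps gene -> ranking score; it is sorted internally by
    decreasing score (ties broken by gene id) so callers may pass an
    unsorted Series. The collection must already be restricted to the
    universe (see :func:`restrict_and_filter`). Returns one row per set:
    size, ES, NES, p_nominal, FDR_q, FWER_p and the leading-edge genes.

    Permutation draws consume a single generator in set-name-sorted order,
    making results independent of collection insertion order.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    names = sorted(collection.names())
    if not names:
        return pd.DataFrame(columns=list(RESULT_COLUMNS))
    key = pd.DataFrame(
        {"score": ranked.to_numpy(dtype=float), "gid": ranked.index.astype(str)},
        index=pd.RangeIndex(len(ranked)),
    )
    pos = key.sort_values(["score", "gid"], ascending=[False, True], kind="mergesort").index
    ranked = ranked.iloc[pos]
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent

    rng = np.random.default_rng(seed)
    rows = {}
    null_es = {}
    for name in names:
        gs = collection[name]
        es, _, leading = enrichment_score(ranked, gs.genes, weight_exponent)
        null = _es_null_matrix(weights, len(gs.genes), n_permutations, rng)
        rows[name] = {"size": len(gs.genes), "ES": es, "leading_edge": leading}
        null_es[name] = null

    # mean-division NES, per set and sign
    null_nes = {}
    for name in names:
        null = null_es[name]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        es = rows[name]["ES"]
        denom = pos_mean if es >= 0 else neg_mean
        if not np.isfinite(denom) or denom == 0:
            # no same-sign null ES for this set (can happen on heavily skewed
            # score lists); normalize by the overall null magnitude instead
            denom = np.abs(null).mean()
            logger.debug("set %s: no same-sign null ES; normalizing by mean |null ES|", name)
        rows[name]["NES"] = es / denom if denom > 0 else 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = np.where(null >= 0, null / pos_mean, null / neg_mean)
        nn[~np.isfinite(nn)] = 0.0
        null_nes[name] = nn
        # nominal p from the same-sign null ES tail
        if es >= 0:
            same = null[null >= 0]
            p_nom = float((same >= es).sum()) / len(same) if len(same) else 1.0
        else:
            same = null[null <= 0]
            p_nom = float((same <= es).sum()) / len(same) if len(same) else 1.0
        rows[name]["p_nominal"] = min(p_nom, 1.0)

    # FDR: sign-stratified pooled null NES vs observed NES tail fractions
    obs_nes = np.array([rows[n]["NES"] for n in names])
    pooled = np.concatenate([null_nes[n].ravel() for n in names])
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled <= 0]
    obs_pos = obs_nes[obs_nes >= 0]
    obs_neg = obs_nes[obs_nes <= 0]
    fdr = np.empty(len(names))
    for i, name in enumerate(names):
        nes = obs_nes[i]
        if nes >= 0:
            num = (pooled_pos >= nes).mean() if len(pooled_pos) else 0.0
            den = (obs_pos >= nes).mean() if len(obs_pos) else 1.0
        else:
            num = (pooled_neg <= nes).mean() if len(pooled_neg) else 0.0
            den = (obs_neg <= nes).mean() if len(obs_neg) else 1.0
        fdr[i] = min(num / den, 1.0) if den > 0 else 0.0
    # monotonize (BH-style): scanning from the least extreme |NES| toward the
    # most extreme, each set's q is the running minimum, so a more extreme set
    # never reports a larger q than a less extreme one
    for sign_mask in (obs_nes >= 0, obs_nes < 0):
        idx = np.flatnonzero(sign_mask)
        if len(idx) == 0:
            continue
        extremity = np.abs(obs_nes[idx])
        order_idx = idx[np.argsort(extremity, kind="mergesort")]
        fdr[order_idx] = np.minimum.accumulate(fdr[order_idx])

    # FWER: per-permutation max same-sign NES over all sets
    nes_null_mat = np.stack([null_nes[n] for n in names])  # sets x perms
    max_pos = np.max(np.where(nes_null_mat > 0, nes_null_mat, 0.0), axis=0)
    min_neg = np.min(np.where(nes_null_mat < 0, nes_null_mat, 0.0), axis=0)
    fwer = np.empty(len(names))
    for i in range(len(names)):
        nes = obs_nes[i]
        if nes >= 0:
            fwer[i] = float((max_pos >= nes).mean())
        else:
            fwer[i] = float((min_neg <= nes).mean())

    table = pd.DataFrame(
        {
            "size": [rows[n]["size"] for n in names],
            "ES": [rows[n]["ES"] for n in names],
            "NES": obs_nes,
            "p_nominal": [rows[n]["p_nominal"] for n in names],
            "FDR_q": fdr,
            "FWER_p": fwer,
            "leading_edge": [rows[n]["leading_edge"] for n in names],
        },
        index=pd.Index(names, name="set"),
    )
    return table.sort_values("NES", ascending=False)


def label_permutation_control(
    ranked: pd.Series,
    collection: GeneSetCollection,
    seed: int = 0,
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Negative control: scramble the gene <-> score assignment, rerun GSEA.

    Destroys any true relationship between gene identity and ranking
    score; on valid inputs no set should remain significant.
    """
    rng = np.random.default_rng(seed)
    shuffled_genes = ranked.index.to_numpy().copy()
    rng.shuffle(shuffled_genes)
    control = pd.Series(ranked.to_numpy(), index=pd.Index(shuffled_genes, name=ranked.index.name))
    return preranked_gsea(
        control, collection, n_permutations=n_permutations,
        seed=seed + 1, weight_exponent=weight_exponent,
    )


def write_enrichment_tsv(table: pd.DataFrame, path: str) -> None:
    out = table.copy()
    out["leading_edge"] = [";".join(le) for le in out["leading_edge"]]
    out.to_csv(path, sep="\t", index_label="set")
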