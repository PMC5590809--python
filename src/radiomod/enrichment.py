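"""Feature-pathway association scoring by weighted-rank gene-set enrichment.

For one radiomic feature, every gene is scored by Spearman's rho against the
feature across patients, weighted by -log10 of rho's p-value; the resulting
ranked list feeds a preranked gene-set enrichment statistic (weighted
Kolmogorov-Smirnov running sum).  Normalized enrichment scores (NES) over all
feature/pathway pairs form the association matrix that module discovery
biclusters.  A single-sample rank statistic provides per-patient pathway
enrichment scores for downstream prediction and module coherence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps -log10(p) finite


# ---------------------------------------------------------------------------
# Gene ranking
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted |rho| null distribution over all permutations (tie-free, n<=9)."""
    base = np.arange(1, n + 1, dtype=float)
    base_c = base - base.mean()
    denom = (base_c**2).sum()
    vals = []
    for perm in itertools.permutations(range(n)):
        r = base[list(perm)] - base.mean()
        vals.append(abs((base_c * r).sum() / denom))
    return np.sort(np.array(vals))


def _spearman_pvalues(rho: np.ndarray, n: int, exact_max_n: int = 9) -> np.ndarray:
    """Two-sided p-values for Spearman rho.

    Exact permutation enumeration for n <= 9 (tie-free null), otherwise the
    t-distribution approximation ``t = rho*sqrt((n-2)/(1-rho^2))``.
    """
    rho = np.clip(rho, -1.0, 1.0)
    if n <= exact_max_n:
        null = _exact_rho_null(n)
        # two-sided: fraction of |null| >= |rho| (with small tolerance)
        idx = np.searchsorted(null, np.abs(rho) - 1e-12, side="left")
        return (len(null) - idx) / len(null)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t) | np.isinf(t)] = 0.0  # |rho| == 1
    return p


def gene_feature_rank(expr: pd.DataFrame, feature: pd.Series) -> pd.Series:
    """Rank genes by signed, significance-weighted correlation with a feature.

    Parameters
    ----------
    expr : DataFrame, genes x patients
    feature : Series indexed by patient id

    Returns
    -------
    Series of scores ``rho * (-log10 p)`` indexed by gene, sorted descending,
    ties broken by gene id.  p is floored at 1e-300.
    """
    patients = expr.columns.intersection(feature.index)
    if len(patients) < 3:
        raise ValueError("need at least 3 aligned patients")
    f = feature.loc[patients].to_numpy(dtype=float)
    if np.ptp(f) == 0:
        raise ValueError("feature has zero variance; rank undefined")
    x = expr.loc[:, patients].to_numpy(dtype=float)
    n = len(patients)

    fr = stats.rankdata(f)
    xr = stats.rankdata(x, axis=1)
    fr_c = fr - fr.mean()
    xr_c = xr - xr.mean(axis=1, keepdims=True)
    denom = np.sqrt((xr_c**2).sum(axis=1) * (fr_c**2).sum())
    with np.errstate(invalid="ignore"):
        rho = (xr_c @ fr_c) / denom
    rho = np.where(denom == 0, 0.0, rho)  # constant genes: no association

    p = np.maximum(_spearman_pvalues(rho, n), P_FLOOR)
    scores = rho * (-np.log10(p))
    out = pd.Series(scores, index=expr.index)
    # descending score, deterministic id tie-break
    out = out.iloc[np.lexsort((out.index.astype(str), -out.to_numpy()))]
    return out


def filter_gene_sets(
    collection: dict[str, list[str]],
    universe,
    min_size: int = 15,
    max_size: int = 500,
) -> dict[str, list[str]]:
    """Intersect sets with the measured gene universe, then size-filter.

    Inclusive bounds; a set of 600 genes with 300 in the universe is kept.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    out = {}
    for set_id, genes in collection.items():
        members = sorted(set(genes) & universe)
        if min_size <= len(members) <= max_size:
            out[set_id] = members
    if not out:
        logger.warning("gene-set filter removed every set")
    return out


# ---------------------------------------------------------------------------
# Enrichment statistic
# ---------------------------------------------------------------------------

def _es_from_hits(
    positions: np.ndarray, hit_weights: np.ndarray, n_genes: int
) -> float:
    """Signed maximum deviation of the running sum, from hit positions only.

    ``positions`` are sorted 0-based ranks of the set's genes in the list;
    extremes of the running sum occur immediately before or after a hit, so
    only 2*m candidate deviations need checking.
    """
    m = len(positions)
    n_miss = n_genes - m
    if n_miss == 0:
        raise ValueError("gene set equals the whole universe")
    w_total = hit_weights.sum()
    if w_total <= 0:
        hit_weights = np.ones(m)
        w_total = float(m)
    cum_hit = np.cumsum(hit_weights) / w_total
    k = np.arange(m)
    miss_before = (positions - k) / n_miss  # misses strictly before k-th hit
    dev_after = cum_hit - miss_before  # running sum just after each hit
    prev_hit = np.concatenate(([0.0], cum_hit[:-1]))
    dev_before = prev_hit - miss_before  # just before each hit
    devs = np.concatenate((dev_after, dev_before))
    peak = np.abs(devs).max()
    # an exact +/- tie of the extreme deviation resolves positive
    return float(devs[np.abs(devs) == peak].max())


def enrichment_score(
    ranked: pd.Series, gene_set, weight_exp: float = 1.0
) -> float:
    """Weighted KS enrichment score of a gene set in a ranked list.

    Hits increment the running sum by ``|score|^weight_exp`` (normalized by
    the set total); misses decrement by ``1/(N - N_hit)``.  ES is the signed
    maximum deviation, in [-1, 1].
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    hit_mask = ranked.index.isin(gene_set)
    positions = np.flatnonzero(hit_mask)
    if positions.size == 0:
        raise ValueError("gene set disjoint from ranked universe")
    weights = np.abs(ranked.to_numpy()[positions]) ** weight_exp
    return _es_from_hits(positions, weights, len(ranked))


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p_value: float
    q_value: float = float("nan")


def _null_es(
    abs_scores: np.ndarray,
    set_size: int,
    n_perm: int,
    weight_exp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene-label permutation null: ES of random sets of the given size."""
    n = len(abs_scores)
    w = abs_scores**weight_exp
    out = np.empty(n_perm)
    for b in range(n_perm):
        pos = np.sort(rng.choice(n, size=set_size, replace=False))
        out[b] = _es_from_hits(pos, w[pos], n)
    return out


def preranked_gsea(
    ranked: pd.Series,
    collection: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exp: float = 1.0,
) -> list[EnrichmentResult]:
    """Preranked enrichment of every set, with a gene-label permutation null.

    NES = ES / mean |null ES| of the matching sign; p is the plus-one tail of
    the matching-sign null; q is Benjamini-Hochberg within the collection.
    The null depends only on set size, so sets of equal size share one null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scores = ranked.to_numpy(dtype=float)
    if np.all(scores == 0):
        raise ValueError("degenerate all-zero ranking")
    rng = np.random.default_rng(seed)
    abs_scores = np.abs(scores)
    gene_index = {g: i for i, g in enumerate(ranked.index)}

    null_cache: dict[int, np.ndarray] = {}
    results = []
    for set_id in sorted(collection):
        members = [g for g in collection[set_id] if g in gene_index]
        if not members:
            continue
        positions = np.sort(np.array([gene_index[g] for g in members]))
        es = _es_from_hits(
            positions, abs_scores[positions] ** weight_exp, len(scores)
        )
        m = len(positions)
        if m not in null_cache:
            null_cache[m] = _null_es(abs_scores, m, n_perm, weight_exp, rng)
        null = null_cache[m]
        same_sign = null[null > 0] if es >= 0 else -null[null < 0]
        if same_sign.size == 0:
            nes, p = 0.0, 1.0
        else:
            nes = es / same_sign.mean() if es >= 0 else -abs(es) / same_sign.mean()
            p = (1.0 + np.count_nonzero(same_sign >= abs(es))) / (
                1.0 + same_sign.size
            )
        results.append(EnrichmentResult(set_id=set_id, es=es, nes=nes, p_value=p))

    if results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def build_association_matrix(
    features: pd.DataFrame,
    expr: pd.DataFrame,
    collection: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exp: float = 1.0,
) -> pd.DataFrame:
    """NES for every (radiomic feature, pathway) pair.

    Parameters
    ----------
    features : DataFrame, patients x radiomic features
    expr : DataFrame, genes x patients

    Returns
    -------
    DataFrame, features x pathways, complete (no missing cells).
    """
    patients = features.index.intersection(expr.columns)
    collection = filter_gene_sets(collection, expr.index)
    rows = {}
    rng = np.random.default_rng(seed)
    for feat in features.columns:
        ranked = gene_feature_rank(expr, features.loc[patients, feat])
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = preranked_gsea(
            ranked, collection, n_perm=n_perm, seed=sub_seed, weight_exp=weight_exp
        )
        rows[feat] = {r.set_id: r.nes for r in res}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out = out.reindex(index=features.columns, columns=sorted(collection))
    if out.isna().any().any():
        raise RuntimeError("association matrix has missing cells")
    return out


# ---------------------------------------------------------------------------
# Per-patient pathway scores
# ---------------------------------------------------------------------------

def per_patient_enrichment(expr: pd.DataFrame, gene_set) -> pd.Series:
    """Single-sample rank-based enrichment score per patient.

    Each patient's genes are ordered by expression (descending, ties broken
    by gene id); the running-sum statistic is evaluated with linear
    descending rank weights.  The score is signed: member genes at the top
    of the profile give positive values.  Depends on within-patient ranks
    only, hence invariant under monotone transforms of each profile.
    """
    gene_set = set(gene_set) & set(expr.index)
    if not gene_set:
        raise ValueError("empty gene set (after universe intersection)")
    n = expr.shape[0]
    scores = {}
    gene_ids = expr.index.astype(str)
    for patient in expr.columns:
        col = expr[patient].to_numpy(dtype=float)
        order = np.lexsort((gene_ids, -col))
        ordered_genes = expr.index[order]
        weights = np.arange(n, 0, -1, dtype=float)  # N..1 down the list
        positions = np.flatnonzero(ordered_genes.isin(gene_set))
        scores[patient] = _es_from_hits(positions, weights[positions], n)
    return pd.Series(scores, index=expr.columns)


def pathway_score_table(
    expr: pd.DataFrame, collection: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-patient enrichment for every set: patients x pathways.

    Equivalent to calling :func:`per_patient_enrichment` per set, but the
    per-patient gene ordering is computed once and reused across sets.
    """
    n = expr.shape[0]
    gene_ids = expr.index.astype(str)
    set_ids = sorted(collection)
    member_masks = {}
    for set_id in set_ids:
        members = set(collection[set_id]) & set(expr.index)
        if not members:
            raise ValueError(f"set {set_id} disjoint from expression universe")
        member_masks[set_id] = expr.index.isin(members)
    weights = np.arange(n, 0, -1, dtype=float)
    out = np.empty((expr.shape[1], len(set_ids)))
    for j, patient in enumerate(expr.columns):
        col = expr[patient].to_numpy(dtype=float)
        order = np.lexsort((gene_ids, -col))
        for k, set_id in enumerate(set_ids):
            positions = np.flatnonzero(member_masks[set_id][order])
            out[j, k] = _es_from_hits(positions, weights[positions], n)
    return pd.DataFrame(out, index=expr.columns, columns=set_ids)
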