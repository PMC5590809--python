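"""Radiomic-pathway association modules: ISA biclustering and validation.

The NES association matrix is biclustered with the Iterative Signature
Algorithm over a liberal grid of row/column thresholds (1.5, 2.0, 2.5).
Candidates are pruned for redundancy by membership correlation, scored with
the coherence statistic r = mean(C_X) + mean(C_Y) (mean pairwise Spearman
correlation among the module's patient-level feature columns, plus the same
among its per-patient pathway score columns), and validated on an independent
cohort by a permutation null of random modules of identical dimensions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import base_feature_name

logger = logging.getLogger(__name__)


@dataclass
class Module:
    """A validated bicluster of radiomic features and pathways."""

    feature_ids: tuple[str, ...]
    pathway_ids: tuple[str, ...]
    r_stat: float = float("nan")
    p_perm: float = float("nan")
    q_fdr: float = float("nan")
    cohort_of_origin: str = ""
    module_id: str = ""
    robustness: float = float("nan")  # ISA fixed-point block strength

    def __post_init__(self) -> None:
        self.feature_ids = tuple(sorted(self.feature_ids))
        self.pathway_ids = tuple(sorted(self.pathway_ids))
        if not self.feature_ids or not self.pathway_ids:
            raise ValueError("module sides must be nonempty")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# ISA biclustering
# ---------------------------------------------------------------------------

def _zscore(a: np.ndarray, axis: int) -> np.ndarray:
    mu = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mu) / sd


def _threshold(scores: np.ndarray, t: float) -> np.ndarray:
    """Keep entries further than t standard deviations of the score vector."""
    sd = scores.std()
    if sd == 0:
        return np.zeros_like(scores)
    return np.where(np.abs(scores) > t * sd, scores, 0.0)


def isa_bicluster(
    m: pd.DataFrame,
    row_thresholds=(1.5, 2.0, 2.5),
    col_thresholds=(1.5, 2.0, 2.5),
    n_seeds: int = 100,
    seed: int = 0,
    max_iter: int = 50,
) -> list[Module]:
    """Run ISA from random sparse seeds over a threshold grid.

    The matrix is z-score normalized by rows (for scoring columns) and by
    columns (for scoring rows).  From a random sparse row-set, column scores
    are the row-signature means thresholded at ``t_col`` standard deviations;
    row scores the column-signature means thresholded at ``t_row``; alternate
    until the membership fixed point.  Non-converged seeds are discarded.
    Returns unique converged biclusters (no coherence statistics yet).
    """
    if m.isna().any().any():
        raise ValueError("association matrix must be complete")
    a = m.to_numpy(dtype=float)
    n_rows, n_cols = a.shape
    rowz = _zscore(a, axis=1)  # rows standardized: compares pathways
    colz = _zscore(a, axis=0)  # columns standardized: compares features
    rng = np.random.default_rng(seed)

    seen: set[tuple] = set()
    out: list[Module] = []
    p_in = max(2.0 / n_rows, 1.0 / n_rows)
    for t_row in row_thresholds:
        for t_col in col_thresholds:
            for _ in range(n_seeds):
                r = (rng.random(n_rows) < p_in).astype(float)
                if r.sum() == 0:
                    r[rng.integers(n_rows)] = 1.0
                prev_sig = None
                prev_vec = None
                converged = False
                for _it in range(max_iter):
                    denom_r = np.abs(r).sum()
                    c_scores = rowz.T @ r / denom_r
                    c = _threshold(c_scores, t_col)
                    if not np.any(c):
                        break
                    denom_c = np.abs(c).sum()
                    r_scores = colz @ c / denom_c
                    r = _threshold(r_scores, t_row)
                    if not np.any(r):
                        break
                    sig = (tuple(np.flatnonzero(r)), tuple(np.flatnonzero(c)))
                    # converged on the exact membership fixed point, or on a
                    # near-stationary score vector (correlation criterion, as
                    # reference ISA implementations use)
                    vec = np.concatenate((r, c))
                    if sig == prev_sig:
                        converged = True
                        break
                    if prev_vec is not None and prev_vec.shape == vec.shape:
                        na, nb = np.linalg.norm(prev_vec), np.linalg.norm(vec)
                        if na > 0 and nb > 0 and (prev_vec @ vec) / (na * nb) > 0.99:
                            prev_sig = sig
                            converged = True
                            break
                    prev_sig = sig
                    prev_vec = vec
                if not converged:
                    continue
                rows_idx, cols_idx = prev_sig
                if not rows_idx or not cols_idx:
                    continue
                if prev_sig in seen:
                    continue
                seen.add(prev_sig)
                # block strength: bilinear form of the converged score
                # vectors on the z-scored matrix; comparable across module
                # shapes, unlike the coherence statistic
                rn = np.linalg.norm(r)
                cn = np.linalg.norm(c)
                rob = float(abs(r @ ((rowz + colz) / 2.0) @ c) / (rn * cn))
                out.append(
                    Module(
                        feature_ids=tuple(m.index[list(rows_idx)]),
                        pathway_ids=tuple(m.columns[list(cols_idx)]),
                        robustness=rob,
                    )
                )
    if not out:
        logger.info("ISA found no biclusters (no signal above thresholds)")
    return out


# ---------------------------------------------------------------------------
# Coherence statistic and pruning
# ---------------------------------------------------------------------------

def _mean_pairwise_spearman(columns: pd.DataFrame) -> float:
    """Mean Spearman correlation over all column pairs; 1.0 for a singleton.

    The singleton convention (mean over an empty pair set = perfect
    self-coherence) keeps one-feature or one-pathway modules scorable.
    """
    k = columns.shape[1]
    if k < 2:
        return 1.0
    rho = stats.spearmanr(columns.to_numpy()).statistic
    if k == 2:
        return float(rho)
    iu = np.triu_indices(k, 1)
    return float(np.asarray(rho)[iu].mean())


def coherence_r(
    mod: Module, feature_table: pd.DataFrame, pathway_scores: pd.DataFrame
) -> float:
    """r = mean(C_X) + mean(C_Y) on patient-level data.

    C_X: pairwise Spearman correlations among the module's feature columns
    (patients x features); C_Y: same among its per-patient pathway score
    columns.  Patient-level data (not the NES matrix) is used so the same
    statistic is computable on an independent validation cohort.
    """
    missing = [f for f in mod.feature_ids if f not in feature_table.columns]
    missing += [p for p in mod.pathway_ids if p not in pathway_scores.columns]
    if missing:
        raise KeyError(f"cohort lacks module columns: {missing[:5]}")
    cx = _mean_pairwise_spearman(feature_table.loc[:, list(mod.feature_ids)])
    cy = _mean_pairwise_spearman(pathway_scores.loc[:, list(mod.pathway_ids)])
    return cx + cy


def deduplicate(
    candidates: list[Module],
    max_corr: float = 0.3,
    feature_universe=None,
    pathway_universe=None,
) -> list[Module]:
    """Greedy redundancy pruning by membership correlation.

    Candidates are visited in robustness order: the ISA fixed-point block
    strength when available, else |r_stat|.  (The coherence statistic is not
    shape-comparable — its singleton-side convention awards thin modules a
    free unit — so block strength decides precedence.)  A candidate is
    dropped when the Pearson correlation of its binary membership vector
    (features and pathways concatenated) with any retained module exceeds
    ``max_corr``.  Idempotent.
    """
    if not 0 < max_corr <= 1:
        raise ValueError("max_corr must be in (0, 1]")
    if not candidates:
        return []
    if feature_universe is None:
        feature_universe = sorted({f for c in candidates for f in c.feature_ids})
    if pathway_universe is None:
        pathway_universe = sorted({p for c in candidates for p in c.pathway_ids})
    f_idx = {f: i for i, f in enumerate(feature_universe)}
    p_idx = {p: i for i, p in enumerate(pathway_universe)}
    nf, npw = len(f_idx), len(p_idx)

    def membership(c: Module) -> np.ndarray:
        v = np.zeros(nf + npw)
        for f in c.feature_ids:
            v[f_idx[f]] = 1.0
        for p in c.pathway_ids:
            v[nf + p_idx[p]] = 1.0
        return v

    def _rank_key(c: Module):
        strength = (
            c.robustness
            if np.isfinite(c.robustness)
            else (abs(c.r_stat) if np.isfinite(c.r_stat) else 0.0)
        )
        return (-strength, c.feature_ids, c.pathway_ids)

    order = sorted(range(len(candidates)), key=lambda i: _rank_key(candidates[i]))
    kept: list[Module] = []
    kept_vecs: list[np.ndarray] = []
    for i in order:
        v = membership(candidates[i])
        redundant = False
        for u in kept_vecs:
            if np.std(u) == 0 or np.std(v) == 0:
                corr = 1.0 if np.array_equal(u, v) else 0.0
            else:
                corr = float(np.corrcoef(u, v)[0, 1])
            if corr > max_corr:
                redundant = True
                break
        if not redundant:
            kept.append(candidates[i])
            kept_vecs.append(v)
    return kept


# ---------------------------------------------------------------------------
# Permutation validation and FDR
# ---------------------------------------------------------------------------

def _standardized_ranks(df: pd.DataFrame) -> np.ndarray:
    """Column-wise average ranks, standardized to mean 0 / SD 1.

    With this transform the Pearson product ``z_i . z_j / n`` equals the
    Spearman correlation of columns i and j; constant columns map to zero.
    """
    r = stats.rankdata(df.to_numpy(dtype=float), axis=0)
    mu = r.mean(axis=0, keepdims=True)
    sd = r.std(axis=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (r - mu) / sd


def _mean_pairwise_from_z(z_cols: np.ndarray) -> float:
    """Mean pairwise Spearman of standardized-rank columns (1.0 if single).

    Uses sum_{i!=j} corr_ij = ||sum_i z_i||^2 / n - k.
    """
    n, k = z_cols.shape
    if k < 2:
        return 1.0
    s = z_cols.sum(axis=1)
    return float(((s @ s) / n - k) / (k * (k - 1)))


def permutation_validate(
    mod: Module,
    feature_table: pd.DataFrame,
    pathway_scores: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    _precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Plus-one permutation p-value of the module's coherence on a cohort.

    Null: r of random modules with the same (n features, m pathways), drawn
    without replacement from the cohort's columns.
    """
    n, m = len(mod.feature_ids), len(mod.pathway_ids)
    if n > feature_table.shape[1] or m > pathway_scores.shape[1]:
        raise ValueError("cohort has too few columns to sample the null")
    if _precomputed is None:
        zf = _standardized_ranks(feature_table)
        zp = _standardized_ranks(pathway_scores)
    else:
        zf, zp = _precomputed
    f_pos = [feature_table.columns.get_loc(f) for f in mod.feature_ids]
    p_pos = [pathway_scores.columns.get_loc(p) for p in mod.pathway_ids]
    observed = _mean_pairwise_from_z(zf[:, f_pos]) + _mean_pairwise_from_z(
        zp[:, p_pos]
    )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        fsel = rng.choice(zf.shape[1], size=n, replace=False)
        psel = rng.choice(zp.shape[1], size=m, replace=False)
        null_r = _mean_pairwise_from_z(zf[:, fsel]) + _mean_pairwise_from_z(
            zp[:, psel]
        )
        if null_r >= observed:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Module summaries
# ---------------------------------------------------------------------------

def module_size(mod: Module, n_features_total: int, m_pathways_total: int) -> float:
    """Relative size n/N + m/M."""
    if n_features_total <= 0 or m_pathways_total <= 0:
        raise ValueError("totals must be positive")
    return len(mod.feature_ids) / n_features_total + len(mod.pathway_ids) / m_pathways_total


def module_overlap(a: Module, b: Module) -> float:
    """Jaccard overlap of feature sets after collapsing transformations.

    Wavelet-band and LoG-scale prefixes are stripped so the same base
    feature under different transforms counts as shared.
    """
    fa = {base_feature_name(f) for f in a.feature_ids}
    fb = {base_feature_name(f) for f in b.feature_ids}
    union = fa | fb
    if not union:
        return 0.0
    return len(fa & fb) / len(union)


def discover_and_validate(
    assoc: pd.DataFrame,
    d1_features: pd.DataFrame,
    d1_pathway_scores: pd.DataFrame,
    d2_features: pd.DataFrame,
    d2_pathway_scores: pd.DataFrame,
    row_thresholds=(1.5, 2.0, 2.5),
    col_thresholds=(1.5, 2.0, 2.5),
    n_seeds: int = 100,
    n_perm: int = 1000,
    max_corr: float = 0.3,
    seed: int = 0,
    cohort_of_origin: str = "d1",
) -> list[Module]:
    """Full module chain: ISA -> coherence on d1 -> dedup -> validate on d2 -> FDR.

    Returns pruned candidates with r (discovery cohort), permutation p
    (validation cohort), and BH q over the pruned family.  Deduplication is
    applied before validation, mirroring a discovery-then-validation design.
    """
    candidates = isa_bicluster(
        assoc,
        row_thresholds=row_thresholds,
        col_thresholds=col_thresholds,
        n_seeds=n_seeds,
        seed=seed,
    )
    for c in candidates:
        c.r_stat = coherence_r(c, d1_features, d1_pathway_scores)
        c.cohort_of_origin = cohort_of_origin
    pruned = deduplicate(
        candidates,
        max_corr=max_corr,
        feature_universe=list(assoc.index),
        pathway_universe=list(assoc.columns),
    )
    rng = np.random.default_rng(seed)
    pre = (_standardized_ranks(d2_features), _standardized_ranks(d2_pathway_scores))
    for c in pruned:
        c.p_perm = permutation_validate(
            c,
            d2_features,
            d2_pathway_scores,
            n_perm=n_perm,
            seed=int(rng.integers(0, 2**31 - 1)),
            _precomputed=pre,
        )
    qs = fdr_adjust([c.p_perm for c in pruned])
    for i, (c, q) in enumerate(zip(pruned, qs)):
        c.q_fdr = float(q)
        c.module_id = f"M{i + 1}"
    return pruned


def modules_to_json(modules: list[Module], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in modules], fh, indent=2)


def overlap_edge_list(modules: list[Module]) -> pd.DataFrame:
    """Pairwise overlap summary (module_a, module_b, overlap)."""
    rows = []
    for i, a in enumerate(modules):
        for b in modules[i + 1 :]:
            rows.append(
                {
                    "module_a": a.module_id,
                    "module_b": b.module_id,
                    "overlap": module_overlap(a, b),
                }
            )
    return pd.DataFrame(rows, columns=["module_a", "module_b", "overlap"])
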