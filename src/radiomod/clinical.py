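"""Clinical associations of modules: survival, stage, histology, meta-analysis.

A module is scored against overall survival through the mean (direction-free)
concordance of its features, and against stage/histology through the mean
Kruskal-Wallis statistic; each statistic gets a permutation p-value per cohort
(null: random feature sets of equal size), and the two cohorts are combined by
a sample-size-weighted Fisher Z meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STAGE_LEVELS = ("I", "II", "III", "other")
HISTOLOGY_LEVELS = ("adenocarcinoma", "squamous", "other")
ENDPOINTS = ("OS", "stage", "histology")


@dataclass
class ClinicalModuleResult:
    module_id: str
    endpoint: str
    stat_d1: float
    p_d1: float
    stat_d2: float
    p_d2: float
    p_meta: float


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance_index(
    risk: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float]:
    """Harrell's C over comparable pairs, with a Noether-type standard error.

    A pair is comparable when the shorter observed time carries an event.
    Concordant: the higher risk fails first; risk ties count 1/2.  The
    standard error is the binomial-type large-sample approximation
    ``sqrt(C(1-C)/n_comparable)``.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = len(risk)
    conc = 0.0
    n_pairs = 0
    for i in range(n):
        if not event[i]:
            continue
        # patient i failed; comparable with anyone surviving past time[i]
        later = time > time[i]
        tie_t = (time == time[i]) & ~event  # censored exactly at event time
        comp = later | tie_t
        n_pairs += int(comp.sum())
        conc += np.count_nonzero(risk[i] > risk[comp])
        conc += 0.5 * np.count_nonzero(risk[i] == risk[comp])
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    ci = conc / n_pairs
    se = float(np.sqrt(max(ci * (1.0 - ci), 1e-12) / n_pairs))
    return float(ci), se


def module_os_association(
    feature_ids,
    feature_table: pd.DataFrame,
    clinical: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Prognostic strength of a module: mean |CI - 0.5| over its features.

    The absolute deviation makes the statistic direction-free, since
    features of one module may be prognostic in opposite directions.  The
    permutation null redraws random feature sets of the same size from the
    full table; p uses the plus-one convention.
    """
    feature_ids = list(feature_ids)
    missing = [f for f in feature_ids if f not in feature_table.columns]
    if missing:
        raise KeyError(f"features missing from table: {missing[:5]}")
    patients = feature_table.index.intersection(clinical.index)
    t = clinical.loc[patients, "os_time"].to_numpy(dtype=float)
    e = clinical.loc[patients, "os_event"].to_numpy(dtype=bool)

    def stat(cols) -> float:
        devs = []
        for c in cols:
            ci, _ = concordance_index(
                feature_table.loc[patients, c].to_numpy(), t, e
            )
            devs.append(abs(ci - 0.5))
        return float(np.mean(devs))

    observed = stat(feature_ids)
    rng = np.random.default_rng(seed)
    all_cols = np.asarray(feature_table.columns)
    count = 0
    for _ in range(n_perm):
        sel = rng.choice(all_cols, size=len(feature_ids), replace=False)
        if stat(sel) >= observed:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return observed, p


# ---------------------------------------------------------------------------
# Categorical endpoints
# ---------------------------------------------------------------------------

def kruskal_wallis_stat(values, groups) -> float:
    """Rank-based Kruskal-Wallis H with ties correction (0 if all tied)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if np.ptp(values) == 0:
        return 0.0  # all observations tied: no rank information
    return float(stats.kruskal(*samples).statistic)


def module_group_association(
    feature_ids,
    feature_table: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean Kruskal-Wallis H of a module's features vs a categorical factor."""
    feature_ids = list(feature_ids)
    patients = feature_table.index.intersection(groups.index)
    grp = groups.loc[patients].to_numpy()

    def stat(cols) -> float:
        return float(
            np.mean(
                [
                    kruskal_wallis_stat(
                        feature_table.loc[patients, c].to_numpy(), grp
                    )
                    for c in cols
                ]
            )
        )

    observed = stat(feature_ids)
    rng = np.random.default_rng(seed)
    all_cols = np.asarray(feature_table.columns)
    count = 0
    for _ in range(n_perm):
        sel = rng.choice(all_cols, size=len(feature_ids), replace=False)
        if stat(sel) >= observed:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return observed, p


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def meta_combine(p1: float, n1: int, p2: float, n2: int) -> float:
    """Sample-size-weighted Z combination of two one-sided p-values.

    ``z_i = Phi^{-1}(1 - p_i)``; ``z = (n1 z1 + n2 z2)/sqrt(n1^2 + n2^2)``;
    ``p = 1 - Phi(z)``.  Inputs of exactly 0 or 1 are clamped with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("weights must be positive")
    eps = 1e-15
    ps = []
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            logger.warning("meta_combine clamping boundary p-value %g", p)
            p = min(max(p, eps), 1.0 - eps)
        ps.append(p)
    z1, z2 = stats.norm.isf(ps[0]), stats.norm.isf(ps[1])
    z = (n1 * z1 + n2 * z2) / np.sqrt(n1**2 + n2**2)
    return float(stats.norm.sf(z))


def assess_modules_clinical(
    modules,
    d1_features: pd.DataFrame,
    d1_clinical: pd.DataFrame,
    d2_features: pd.DataFrame,
    d2_clinical: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """OS/stage/histology association of every module in both cohorts + meta.

    Returns one row per module x endpoint with per-cohort statistics and the
    weighted-Z combined p-value.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for mod in modules:
        for endpoint in ENDPOINTS:
            per_cohort = []
            for feats, clin in (
                (d1_features, d1_clinical),
                (d2_features, d2_clinical),
            ):
                s = int(rng.integers(0, 2**31 - 1))
                if endpoint == "OS":
                    stat, p = module_os_association(
                        mod.feature_ids, feats, clin, n_perm=n_perm, seed=s
                    )
                else:
                    stat, p = module_group_association(
                        mod.feature_ids,
                        feats,
                        clin[endpoint],
                        n_perm=n_perm,
                        seed=s,
                    )
                per_cohort.append((stat, p, len(feats.index.intersection(clin.index))))
            (s1, p1, n1), (s2, p2, n2) = per_cohort
            rows.append(
                ClinicalModuleResult(
                    module_id=mod.module_id,
                    endpoint=endpoint,
                    stat_d1=s1,
                    p_d1=p1,
                    stat_d2=s2,
                    p_d2=p2,
                    p_meta=meta_combine(p1, n1, p2, n2),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
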