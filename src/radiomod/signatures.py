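"""Radiomic pathway predictors and prognostic survival signatures.

Pathway activation (the sign of a patient's enrichment score) is predicted
from single radiomic features with univariate logistic models, judged by AUC
with Noether significance.  Prognostic signatures are built by mRMR feature
ranking followed by incremental Cox models selected by repeated random
cross-validation, and fused with clinical and gene-signature risk scores in a
final proportional-hazards model.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, NelsonAalenFitter
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .clinical import concordance_index

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pathway activation prediction
# ---------------------------------------------------------------------------

@dataclass
class PathwayPredictor:
    feature_id: str
    set_id: str
    intercept: float
    slope: float
    auc_train: float = float("nan")
    auc_val: float = float("nan")
    p_noether: float = float("nan")

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def pathway_activation_labels(scores: pd.Series) -> pd.Series:
    """Binarize per-patient enrichment: 1 if score > 0 else 0."""
    s = scores.astype(float)
    if (s == 0).any():
        logger.warning(
            "%d enrichment scores are exactly 0; labeled inactive",
            int((s == 0).sum()),
        )
    return (s > 0).astype(int)


def fit_univariate_predictor(
    feature: pd.Series, labels: pd.Series, feature_id: str = "", set_id: str = ""
) -> PathwayPredictor:
    """Maximum-likelihood univariate logistic fit of one feature.

    Perfectly separated data gets a slight ridge penalty (logged) so the
    slope stays finite; predicted probabilities remain monotone in the
    feature either way.
    """
    x = feature.to_numpy(dtype=float).reshape(-1, 1)
    y = labels.loc[feature.index].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    # near-unpenalized MLE; fall back to ridge under separation
    sep = _perfectly_separated(x[:, 0], y)
    c = 1.0 if sep else 1e8
    if sep:
        logger.warning("perfect separation for %s; ridge fallback", feature_id)
    model = LogisticRegression(C=c, solver="lbfgs", max_iter=2000)
    model.fit(x, y)
    pred = PathwayPredictor(
        feature_id=feature_id or str(feature.name),
        set_id=set_id,
        intercept=float(model.intercept_[0]),
        slope=float(model.coef_[0, 0]),
    )
    auc, p = auc_with_noether(pred.predict_proba(x[:, 0]), y)
    pred.auc_train = auc
    pred.p_noether = p
    return pred


def _perfectly_separated(x: np.ndarray, y: np.ndarray) -> bool:
    x0, x1 = x[y == 0], x[y == 1]
    return x0.max() < x1.min() or x1.max() < x0.min()


def auc_with_noether(
    probs: np.ndarray, labels: np.ndarray, exact_below: int = 50, seed: int = 0
) -> tuple[float, float]:
    """AUC as normalized Mann-Whitney U, with Noether one-sided significance.

    Ties count one half.  The null variance is Noether's
    ``(n0 + n1 + 1) / (12 n0 n1)`` for the large-sample normal test of
    AUC = 0.5; when ``n0*n1 < exact_below`` an exact label-permutation test
    replaces the normal approximation.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    def _auc(p, n):
        gt = (p[:, None] > n[None, :]).sum()
        eq = (p[:, None] == n[None, :]).sum()
        return (gt + 0.5 * eq) / (len(p) * len(n))

    auc = float(_auc(pos, neg))
    if n0 * n1 < exact_below:
        # exact permutation of labels (enumerate if feasible, else sample)
        n = n0 + n1
        idx = np.arange(n)
        combos = itertools.combinations(idx, n1)
        null = []
        for k, combo in enumerate(combos):
            if k >= 20000:
                break
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            null.append(_auc(probs[sel], probs[~sel]))
        null = np.asarray(null)
        p = float((1 + np.count_nonzero(null >= auc - 1e-12)) / (1 + len(null)))
    else:
        var0 = (n0 + n1 + 1.0) / (12.0 * n0 * n1)
        z = (auc - 0.5) / np.sqrt(var0)
        p = float(stats.norm.sf(z))
    return auc, p


def strongest_predictor_per_module(
    module,
    predictors: list[PathwayPredictor],
) -> PathwayPredictor:
    """The module's predictor with the highest training AUC (ties by id)."""
    members = [
        p
        for p in predictors
        if p.feature_id in module.feature_ids and p.set_id in module.pathway_ids
    ]
    if not members:
        raise ValueError("module has no predictors")
    return strongest_predictor(members)


def strongest_predictor(predictors: list[PathwayPredictor]) -> PathwayPredictor:
    """Argmax training AUC with deterministic id tie-break."""
    if not predictors:
        raise ValueError("no predictors")
    best = sorted(predictors, key=lambda p: (-p.auc_train, p.feature_id, p.set_id))
    return best[0]


# ---------------------------------------------------------------------------
# mRMR feature ranking for survival
# ---------------------------------------------------------------------------

def _martingale_residuals(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Residuals of the null survival model: event - H0(t) (Nelson-Aalen)."""
    naf = NelsonAalenFitter()
    naf.fit(time, event_observed=event)
    h0 = naf.cumulative_hazard_at_times(time).to_numpy()
    return event.astype(float) - h0


def mrmr_rank(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    k: int | None = None,
    redundancy_weight: float = 1.0,
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance feature ranking.

    Relevance: |Spearman rho| of each feature with the martingale residual
    of a null survival model (so relevance reflects association with the
    censoring-adjusted outcome).  Redundancy: mean |Spearman rho| with the
    already-selected features.  At each step the feature maximizing
    relevance - redundancy_weight * mean-redundancy is appended.  Constant
    columns are excluded with a warning.
    """
    cols = list(features.columns)
    x = features.to_numpy(dtype=float)
    keep = [i for i in range(x.shape[1]) if np.ptp(x[:, i]) > 0]
    if len(keep) < len(cols):
        logger.warning("excluding %d constant feature columns", len(cols) - len(keep))
    cols = [cols[i] for i in keep]
    x = x[:, keep]
    if k is None:
        k = len(cols)
    k = min(k, len(cols))

    resid = _martingale_residuals(np.asarray(time, float), np.asarray(event, bool))
    ranks = stats.rankdata(x, axis=0)
    rresid = stats.rankdata(resid)

    def _corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        d = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / d) if d > 0 else 0.0

    relevance = np.array([abs(_corr(ranks[:, j], rresid)) for j in range(len(cols))])
    selected: list[int] = []
    remaining = list(range(len(cols)))
    while len(selected) < k and remaining:
        if not selected:
            j = remaining[int(np.argmax(relevance[remaining]))]
        else:
            best_score, j = -np.inf, None
            for cand in remaining:
                red = np.mean(
                    [abs(_corr(ranks[:, cand], ranks[:, s])) for s in selected]
                )
                score = relevance[cand] - redundancy_weight * red
                if score > best_score:
                    best_score, j = score, cand
        selected.append(j)
        remaining.remove(j)
    return [cols[j] for j in selected]


# ---------------------------------------------------------------------------
# Incremental Cox signature
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSignature:
    feature_ids: list[str]
    coefficients: list[float]
    cv_mean_ci: float
    validation_ci: float = float("nan")
    cv_curve: list[float] = field(default_factory=list)

    def risk_score(self, features: pd.DataFrame) -> pd.Series:
        x = features.loc[:, self.feature_ids].to_numpy(dtype=float)
        return pd.Series(x @ np.asarray(self.coefficients), index=features.index)


def _fit_cox(df: pd.DataFrame, covariates: list[str], penalizer: float = 0.01):
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df[covariates + ["os_time", "os_event"]],
            duration_col="os_time",
            event_col="os_event",
        )
    return cph


def incremental_cox(
    ranked: list[str],
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    n_cv: int = 1000,
    seed: int = 0,
    max_size: int = 15,
    test_fraction: float = 0.3,
    penalizer: float = 0.01,
) -> SurvivalSignature:
    """Pick the signature size with the best cross-validated concordance.

    For model sizes 1..k (k = min(max_size, len(ranked))): fit a Cox model
    on random 70/30 resamples of the training cohort and score the held-out
    concordance; keep the size with the highest mean CI (smallest size on
    ties) and refit on the full cohort.  Non-convergent fits are skipped
    with a log entry.
    """
    if n_cv < 10:
        raise ValueError("n_cv must be >= 10")
    patients = features.index.intersection(clinical.index)
    df = features.loc[patients, ranked].copy()
    df["os_time"] = clinical.loc[patients, "os_time"].astype(float)
    df["os_event"] = clinical.loc[patients, "os_event"].astype(int)
    rng = np.random.default_rng(seed)
    n = len(df)
    n_test = max(2, int(round(test_fraction * n)))
    splits = [rng.permutation(n) for _ in range(n_cv)]

    k = min(max_size, len(ranked))
    mean_cis = []
    for size in range(1, k + 1):
        covs = ranked[:size]
        cis = []
        for perm in splits:
            test_idx = perm[:n_test]
            train_idx = perm[n_test:]
            train = df.iloc[train_idx]
            test = df.iloc[test_idx]
            if train["os_event"].sum() < 2 or test["os_event"].sum() < 1:
                continue
            try:
                cph = _fit_cox(train, covs, penalizer)
            except Exception as exc:  # non-convergence: skip split
                logger.info("cox fit failed at size %d: %s", size, exc)
                continue
            risk = cph.predict_partial_hazard(test[covs]).to_numpy()
            try:
                ci, _ = concordance_index(
                    risk,
                    test["os_time"].to_numpy(),
                    test["os_event"].to_numpy(dtype=bool),
                )
            except ValueError:
                continue
            cis.append(ci)
        mean_cis.append(np.mean(cis) if cis else np.nan)

    mean_cis = np.asarray(mean_cis)
    if np.all(np.isnan(mean_cis)):
        raise RuntimeError("no signature size produced a scoreable model")
    best_size = int(np.nanargmax(mean_cis)) + 1
    final = _fit_cox(df, ranked[:best_size], penalizer)
    return SurvivalSignature(
        feature_ids=ranked[:best_size],
        coefficients=[float(final.params_[f]) for f in ranked[:best_size]],
        cv_mean_ci=float(mean_cis[best_size - 1]),
        cv_curve=[float(v) for v in mean_cis],
    )


def validate_signature(
    sig: SurvivalSignature, features: pd.DataFrame, clinical: pd.DataFrame
) -> float:
    """Concordance of the fitted signature on an independent cohort."""
    patients = features.index.intersection(clinical.index)
    risk = sig.risk_score(features.loc[patients])
    ci, _ = concordance_index(
        risk.to_numpy(),
        clinical.loc[patients, "os_time"].to_numpy(dtype=float),
        clinical.loc[patients, "os_event"].to_numpy(dtype=bool),
    )
    sig.validation_ci = ci
    return ci


# ---------------------------------------------------------------------------
# Signature fusion
# ---------------------------------------------------------------------------

COMPONENT_SUBSETS = (
    ("clinical",),
    ("gene",),
    ("radiomic",),
    ("clinical", "radiomic"),
    ("clinical", "gene"),
    ("clinical", "gene", "radiomic"),
)


def combine_signatures(
    components_train: pd.DataFrame,
    clinical_train: pd.DataFrame,
    components_val: pd.DataFrame,
    clinical_val: pd.DataFrame,
    penalizer: float = 0.01,
) -> dict[tuple[str, ...], float]:
    """Cox-level fusion of per-patient risk components.

    ``components_*`` hold scalar risk scores per patient in columns named
    'clinical', 'gene', 'radiomic'.  For each component subset a Cox model is
    fitted on the training cohort and its linear predictor scored by
    concordance on the validation cohort.  Returns {subset: validation CI}.
    """
    out = {}
    for subset in COMPONENT_SUBSETS:
        cols = [c for c in subset if c in components_train.columns]
        if len(cols) != len(subset):
            continue
        df = components_train[cols].copy()
        pat = df.index.intersection(clinical_train.index)
        df = df.loc[pat]
        df["os_time"] = clinical_train.loc[pat, "os_time"].astype(float)
        df["os_event"] = clinical_train.loc[pat, "os_event"].astype(int)
        try:
            cph = _fit_cox(df, cols, penalizer)
        except Exception:
            logger.warning("collinear components %s; larger penalty", subset)
            cph = _fit_cox(df, cols, penalizer=1.0)
        patv = components_val.index.intersection(clinical_val.index)
        risk = cph.predict_partial_hazard(components_val.loc[patv, cols]).to_numpy()
        ci, _ = concordance_index(
            risk,
            clinical_val.loc[patv, "os_time"].to_numpy(dtype=float),
            clinical_val.loc[patv, "os_event"].to_numpy(dtype=bool),
        )
        out[subset] = ci
    return out


def compare_models_permutation(
    base_components: pd.DataFrame,
    added_component: pd.Series,
    clinical_train: pd.DataFrame,
    base_components_val: pd.DataFrame,
    added_component_val: pd.Series,
    clinical_val: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    penalizer: float = 0.01,
) -> tuple[float, float]:
    """Does adding one risk component significantly raise the validation CI?

    Statistic: CI(base + component) - CI(base).  Null: the added component is
    permuted across patients (in both cohorts), the augmented model refitted,
    and the statistic recomputed; p by the plus-one rule.  Identical models
    (constant added component) give p = 1.
    """
    def _ci_with(add_train, add_val) -> float:
        comp_t = base_components.copy()
        comp_v = base_components_val.copy()
        comp_t["added"] = np.asarray(add_train, dtype=float)
        comp_v["added"] = np.asarray(add_val, dtype=float)
        cols = list(comp_t.columns)
        df = comp_t.copy()
        df["os_time"] = clinical_train["os_time"].astype(float)
        df["os_event"] = clinical_train["os_event"].astype(int)
        cph = _fit_cox(df, cols, penalizer)
        risk = cph.predict_partial_hazard(comp_v[cols]).to_numpy()
        ci, _ = concordance_index(
            risk,
            clinical_val["os_time"].to_numpy(dtype=float),
            clinical_val["os_event"].to_numpy(dtype=bool),
        )
        return ci

    def _ci_base() -> float:
        cols = list(base_components.columns)
        df = base_components.copy()
        df["os_time"] = clinical_train["os_time"].astype(float)
        df["os_event"] = clinical_train["os_event"].astype(int)
        cph = _fit_cox(df, cols, penalizer)
        risk = cph.predict_partial_hazard(base_components_val[cols]).to_numpy()
        ci, _ = concordance_index(
            risk,
            clinical_val["os_time"].to_numpy(dtype=float),
            clinical_val["os_event"].to_numpy(dtype=bool),
        )
        return ci

    if np.ptp(np.asarray(added_component, float)) == 0:
        return 0.0, 1.0
    ci_base = _ci_base()
    observed = _ci_with(added_component, added_component_val) - ci_base
    rng = np.random.default_rng(seed)
    at = np.asarray(added_component, dtype=float)
    av = np.asarray(added_component_val, dtype=float)
    count = 0
    for _ in range(n_perm):
        stat = _ci_with(rng.permutation(at), rng.permutation(av)) - ci_base
        if stat >= observed:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return observed, p
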