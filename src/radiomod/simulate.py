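"""Synthetic phantoms and cohorts with planted, known structure.

Every downstream stage of the pipeline is exercised against ground truth
produced here: geometric phantom volumes with controllable texture for the
feature extractor, and paired cohorts (radiomic features, gene expression,
gene sets, survival/stage/histology) in which designated gene sets correlate
with designated features at a requested strength via a Gaussian copula, and
survival follows a proportional-hazards draw on a chosen feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import VolumeWithMask

logger = logging.getLogger(__name__)

SHAPE_KINDS = ("sphere", "ellipsoid", "cube", "blob")
TEXTURE_KINDS = ("constant", "gaussian_noise", "checkerboard", "gradient")


# ---------------------------------------------------------------------------
# Phantom volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom tumor volume.

    ``size_mm`` is the characteristic diameter (sphere/cube edge / blob
    extent); texture_params supplies per-texture knobs: ``value`` (constant
    level, default 100), ``sd`` (gaussian noise), ``period`` (checkerboard,
    voxels), ``slope`` (gradient units/voxel).
    """

    shape_kind: str = "sphere"
    size_mm: float = 20.0
    texture_kind: str = "gaussian_noise"
    texture_params: tuple = ()
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape {self.shape_kind}")
        if self.texture_kind not in TEXTURE_KINDS:
            raise ValueError(f"unknown texture {self.texture_kind}")
        if self.size_mm <= 0:
            raise ValueError("size_mm must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    def params(self) -> dict:
        return dict(self.texture_params)


def gen_phantom(spec: PhantomSpec) -> VolumeWithMask:
    """Generate a deterministic phantom volume with a connected mask.

    Background outside the mask is 0.  The same spec (including seed)
    always returns a bit-identical volume.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    half_extent_mm = spec.size_mm / 2.0
    margin_vox = 2
    shape = tuple(
        int(np.ceil(spec.size_mm / s)) + 2 * margin_vox for s in spacing
    )
    zz, yy, xx = np.meshgrid(
        *[np.arange(n, dtype=float) for n in shape], indexing="ij"
    )
    center = [(n - 1) / 2.0 for n in shape]
    # physical coordinates relative to center
    pz = (zz - center[0]) * spacing[0]
    py = (yy - center[1]) * spacing[1]
    px = (xx - center[2]) * spacing[2]

    if spec.shape_kind == "sphere":
        mask = pz**2 + py**2 + px**2 <= half_extent_mm**2
    elif spec.shape_kind == "ellipsoid":
        mask = (
            (pz / half_extent_mm) ** 2
            + (py / (0.75 * half_extent_mm)) ** 2
            + (px / (0.5 * half_extent_mm)) ** 2
        ) <= 1.0
    elif spec.shape_kind == "cube":
        mask = (
            (np.abs(pz) <= half_extent_mm)
            & (np.abs(py) <= half_extent_mm)
            & (np.abs(px) <= half_extent_mm)
        )
    else:  # blob: smoothed noise thresholded, largest connected component
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=max(shape) / 8.0)
        base = pz**2 + py**2 + px**2 <= half_extent_mm**2
        mask = base & (smooth > np.median(smooth[base]) - smooth[base].std())
        labeled, n_comp = ndimage.label(mask)
        if n_comp > 1:
            sizes = np.bincount(labeled.ravel())[1:]
            mask = labeled == (1 + int(np.argmax(sizes)))
    if not mask.any():
        raise ValueError("degenerate phantom: empty mask")

    p = spec.params()
    if spec.texture_kind == "constant":
        tex = np.full(shape, float(p.get("value", 100.0)))
    elif spec.texture_kind == "gaussian_noise":
        tex = float(p.get("value", 100.0)) + float(p.get("sd", 20.0)) * (
            rng.standard_normal(shape)
        )
    elif spec.texture_kind == "checkerboard":
        period = int(p.get("period", 2))
        cells = (zz // period + yy // period + xx // period).astype(int) % 2
        tex = float(p.get("value", 100.0)) + float(p.get("contrast", 50.0)) * cells
        sd = float(p.get("sd", 0.0))
        if sd > 0:
            tex = tex + sd * rng.standard_normal(shape)
    else:  # gradient along x
        tex = float(p.get("value", 100.0)) + float(p.get("slope", 2.0)) * xx

    intensities = np.where(mask, tex, 0.0)
    return VolumeWithMask(intensities, mask, tuple(spacing))


# ---------------------------------------------------------------------------
# Planted cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedDesign:
    """Ground-truth layout of a synthetic cohort.

    ``links`` plant (feature, gene set) correlations: genes of a linked set
    correlate with the linked feature at the requested Pearson strength in
    expectation.  Links sharing a connected component of the feature-set
    bipartite graph share one latent factor (so planted module features are
    mutually correlated; see docs).  ``survival_link`` ties the log-hazard
    to one feature.  Gene-universe default is desk-scale (2,000 genes);
    configurable upward.
    """

    n_patients: int = 150
    n_genes: int = 2000
    gene_sets: tuple = ()  # ((set_id, (gene ids, ...)), ...)
    links: tuple = ()  # ((feature_id, set_id, strength), ...)
    n_noise_features: int = 20
    survival_link: tuple = ("", 0.0)  # (feature_id, log-hazard per SD)
    censor_rate: float = 0.3
    median_survival: float = 24.0  # months, baseline
    # shared biology: latent factors giving block-correlated features and a
    # continuum of background gene-feature correlations, as in real cohorts
    n_background_factors: int = 5
    gene_background_loading: tuple[float, float] = (0.15, 0.45)
    feature_background_loading: tuple[float, float] = (0.3, 0.6)
    seed: int = 0

    def __post_init__(self):
        set_ids = {s for s, _ in self.gene_sets}
        for f, s, c in self.links:
            if s not in set_ids:
                raise ValueError(f"link references unknown set {s}")
            if abs(c) > 1:
                raise ValueError("correlation strength must be in [-1, 1]")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_patients < 3 or self.n_genes < 1:
            raise ValueError("degenerate design")


def default_gene_sets(
    n_sets: int = 25, set_size: int = 20, prefix: str = "SET"
) -> tuple:
    """Disjoint equal-size gene sets over the front of the gene universe."""
    sets = []
    for i in range(n_sets):
        genes = tuple(
            f"G{j:05d}" for j in range(i * set_size, (i + 1) * set_size)
        )
        sets.append((f"{prefix}{i:03d}", genes))
    return tuple(sets)


def _link_components(design: PlantedDesign):
    """Connected components of the bipartite (feature, set) link graph."""
    parent: dict[str, str] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for f, s, _ in design.links:
        union(f"F:{f}", f"S:{s}")
    comps: dict[str, list] = {}
    for f, s, c in design.links:
        comps.setdefault(find(f"F:{f}"), []).append((f, s, c))
    return list(comps.values())


@dataclass
class CohortBundle:
    """Aligned blocks of one cohort."""

    features: pd.DataFrame  # patients x radiomic features
    expression: pd.DataFrame  # genes x patients
    gene_sets: dict[str, list[str]]
    clinical: pd.DataFrame  # patients x (os_time, os_event, stage, histology)
    cohort_id: str = "cohort"


def _calibrate_censor_bound(t: np.ndarray, rate: float) -> float:
    """Upper bound of a U(0, c) censoring draw hitting the target rate.

    Solves mean_i P(U < t_i) = rate by bisection on the event-time sample;
    P(U(0,c) < t) = min(t/c, 1).
    """
    if rate <= 0:
        return float("inf")

    def frac(c):
        return float(np.minimum(t / c, 1.0).mean())

    lo, hi = t.min() / 100.0, t.max() * 100.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


STAGE_PROBS = {"I": 0.50, "II": 0.20, "III": 0.20, "other": 0.10}
HISTOLOGY_PROBS = {"adenocarcinoma": 0.55, "squamous": 0.30, "other": 0.15}


def gen_cohort(design: PlantedDesign, cohort_id: str = "cohort") -> CohortBundle:
    """Draw one cohort with the design's planted structure.

    Latent factors follow a Gaussian copula: within a link component with
    mean strength s, linked features load sqrt(s) on the component factor
    and member genes load sign * sqrt(s), giving gene-feature correlation
    ~ s and feature-feature correlation ~ s.  On top of the planted links,
    a small number of background factors carry shared biology: every
    feature and every unlinked gene loads moderately on one random factor,
    producing the block-correlated feature tables and the continuum of
    background gene-feature correlations seen in real cohorts (an iid
    background would make every planted gene a lone extreme outlier of the
    enrichment ranking, which real expression data never shows).  Survival
    is exponential proportional hazards on the standardized linked feature
    with uniform censoring calibrated to ``censor_rate``; stage and
    histology are drawn from fixed categorical mixtures.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_patients
    patients = [f"P{i:04d}" for i in range(n)]
    genes = [f"G{j:05d}" for j in range(design.n_genes)]
    gene_pos = {g: j for j, g in enumerate(genes)}
    gene_sets = {s: list(members) for s, members in design.gene_sets}
    for s, members in gene_sets.items():
        unknown = [g for g in members if g not in gene_pos]
        if unknown:
            raise ValueError(f"set {s} references unknown genes: {unknown[:3]}")

    n_bg = design.n_background_factors
    bg = rng.standard_normal((max(n_bg, 1), n))

    def _background(loading_range):
        """(loading, factor index) for one column, or (0, 0) without factors."""
        if n_bg == 0:
            return 0.0, 0
        lo, hi = loading_range
        return float(rng.uniform(lo, hi)) * float(rng.choice((-1.0, 1.0))), int(
            rng.integers(n_bg)
        )

    linked_genes = {
        g for f, s, c in design.links for g in gene_sets[s]
    }
    expr = np.empty((design.n_genes, n))
    for j, g in enumerate(genes):
        noise = rng.standard_normal(n)
        if g in linked_genes:
            expr[j] = noise  # overwritten below with the planted loading
        else:
            d, kf = _background(design.gene_background_loading)
            expr[j] = d * bg[kf] + np.sqrt(1 - d**2) * noise

    feat_cols: dict[str, np.ndarray] = {}

    def _feature_column(planted_loading=0.0, factor=None):
        a = planted_loading
        c, kf = _background(design.feature_background_loading)
        c = np.sign(c) * min(abs(c), np.sqrt(max(1.0 - a**2, 0.0)))
        noise = rng.standard_normal(n)
        base = a * factor if factor is not None else 0.0
        resid = max(1.0 - a**2 - c**2, 0.0)
        return base + c * bg[kf] + np.sqrt(resid) * noise

    comps = _link_components(design)
    for comp in comps:
        factor = rng.standard_normal(n)
        s_mean = float(np.mean([abs(c) for _, _, c in comp]))
        a = np.sqrt(s_mean) if s_mean > 0 else 0.0
        comp_feats = sorted({f for f, _, _ in comp})
        for f in comp_feats:
            feat_cols[f] = _feature_column(planted_loading=a, factor=factor)
        comp_sets = {}
        for f, s, c in comp:
            comp_sets.setdefault(s, []).append(c)
        for s, strengths in sorted(comp_sets.items()):
            c_mean = float(np.mean(strengths))
            sign = np.sign(c_mean) if c_mean != 0 else 1.0
            if a > 0:
                b = min(abs(c_mean) / a, 1.0) * sign
            else:
                b = 0.0
            for g in gene_sets[s]:
                noise = rng.standard_normal(n)
                expr[gene_pos[g]] = b * factor + np.sqrt(1 - b**2) * noise

    # features referenced only by the survival link still need columns
    surv_feat, beta = design.survival_link
    if surv_feat and surv_feat not in feat_cols:
        feat_cols[surv_feat] = _feature_column()
    for i in range(design.n_noise_features):
        feat_cols[f"noise_{i:03d}"] = _feature_column()

    features = pd.DataFrame(feat_cols, index=patients)
    expression = pd.DataFrame(expr, index=genes, columns=patients)

    # survival: exponential PH on the standardized linked feature
    if surv_feat:
        x = features[surv_feat].to_numpy()
        x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        lin = float(beta) * x
    else:
        lin = np.zeros(n)
    lam0 = np.log(2.0) / design.median_survival
    t_event = rng.exponential(1.0 / (lam0 * np.exp(lin)))
    if design.censor_rate > 0:
        c_max = _calibrate_censor_bound(t_event, design.censor_rate)
        t_cens = rng.uniform(0.0, c_max, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = t_event <= t_cens

    stage = rng.choice(
        list(STAGE_PROBS), size=n, p=list(STAGE_PROBS.values())
    )
    histology = rng.choice(
        list(HISTOLOGY_PROBS), size=n, p=list(HISTOLOGY_PROBS.values())
    )
    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event.astype(int),
            "stage": stage,
            "histology": histology,
        },
        index=patients,
    )
    return CohortBundle(
        features=features,
        expression=expression,
        gene_sets=gene_sets,
        clinical=clinical,
        cohort_id=cohort_id,
    )
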