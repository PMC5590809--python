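"""The radiomic feature bank: first-order, shape, texture, wavelet, LoG.

The default configuration enumerates exactly 636 named features:

================  =====================================================  =====
group             contents                                               count
================  =====================================================  =====
first order       14 intensity statistics                                   14
shape             8 size/shape descriptors                                   8
GLCM              23 co-occurrence features, 13 directions averaged          23
RLGL              11 run-length features, 13 directions averaged             11
GLSZM             14 size-zone features (direction-free)                     14
wavelet           8 stationary sub-bands x (14 + 23 + 11)                   384
LoG               13 sigmas (1.0..7.0 mm by 0.5) x 14 first-order           182
================  =====================================================  =====

The 440-feature "prior" subset is the bank without GLSZM and LoG (the
previously published intensity/shape/texture/wavelet set this bank extends).
Texture features operate on the discretized gray-level alphabet; adjacency is
one voxel on the grid; direction-dependent matrices are averaged over the 13
unique 3D directions.  Degenerate statistics (e.g. GLCM correlation of a
single-level image) return 0 with a logged warning rather than failing,
because constant wavelet sub-bands are routine on real masks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage

from .preprocess import (
    GrayVolume,
    VolumeWithMask,
    discretize,
    discretize_array,
    resample,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Bank enumeration
# ---------------------------------------------------------------------------

FIRST_ORDER_NAMES = (
    "energy",
    "entropy",
    "kurtosis",
    "maximum",
    "mean",
    "mean_absolute_deviation",
    "median",
    "minimum",
    "range",
    "root_mean_square",
    "skewness",
    "standard_deviation",
    "uniformity",
    "variance",
)

SHAPE_NAMES = (
    "volume",
    "surface_area",
    "surface_to_volume_ratio",
    "sphericity",
    "spherical_disproportion",
    "compactness1",
    "compactness2",
    "maximum_3d_diameter",
)

GLCM_NAMES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "imc1",
    "imc2",
    "idmn",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "sum_of_squares_variance",
)

RLGL_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

GLSZM_NAMES = (
    "small_zone_emphasis",
    "large_zone_emphasis",
    "gray_level_nonuniformity",
    "zone_size_nonuniformity",
    "zone_percentage",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_zone_low_gray_level_emphasis",
    "small_zone_high_gray_level_emphasis",
    "large_zone_low_gray_level_emphasis",
    "large_zone_high_gray_level_emphasis",
    "gray_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
)

#: 13 unique 3D directions (the canonical half of the 26-neighborhood),
#: axis order (z, y, x), first nonzero component positive.
DIRECTIONS = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

#: Sub-band labels of the one-level 3D stationary wavelet transform.
#: Letters are ordered (z, y, x); L = low-pass, H = high-pass.
WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

DEFAULT_LOG_SIGMAS_MM = tuple(np.arange(1.0, 7.01, 0.5))  # 13 scales


def _sigma_tag(sigma: float) -> str:
    return f"log_sigma_{str(float(sigma)).replace('.', '_')}_mm"


@dataclass(frozen=True)
class ExtractionConfig:
    """Pinned configuration of the feature bank.

    The defaults are the contract under which the bank enumerates 636
    features with a 440-feature prior subset; changing any field changes the
    provenance hash carried by every extracted vector.
    """

    bin_width: float = 25.0
    resample_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    resample: bool = True
    wavelet: str = "coif1"
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "bin_width": self.bin_width,
                "resample_spacing_mm": list(self.resample_spacing_mm),
                "resample": self.resample,
                "wavelet": self.wavelet,
                "log_sigmas_mm": [float(s) for s in self.log_sigmas_mm],
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def feature_bank(cfg: ExtractionConfig | None = None) -> list[str]:
    """Ordered names of the configured feature bank (636 under defaults)."""
    cfg = cfg or ExtractionConfig()
    names: list[str] = []
    names += [f"original_firstorder_{n}" for n in FIRST_ORDER_NAMES]
    names += [f"original_shape_{n}" for n in SHAPE_NAMES]
    names += [f"original_glcm_{n}" for n in GLCM_NAMES]
    names += [f"original_rlgl_{n}" for n in RLGL_NAMES]
    names += [f"original_glszm_{n}" for n in GLSZM_NAMES]
    for band in WAVELET_BANDS:
        names += [f"wavelet_{band}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
        names += [f"wavelet_{band}_glcm_{n}" for n in GLCM_NAMES]
        names += [f"wavelet_{band}_rlgl_{n}" for n in RLGL_NAMES]
    for sigma in cfg.log_sigmas_mm:
        names += [f"{_sigma_tag(sigma)}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
    return names


def prior_subset(cfg: ExtractionConfig | None = None) -> list[str]:
    """The previously published 440-feature subset (no GLSZM, no LoG)."""
    return [
        n
        for n in feature_bank(cfg)
        if "_glszm_" not in n and not n.startswith("log_sigma_")
    ]


# ---------------------------------------------------------------------------
# Group I: first-order statistics
# ---------------------------------------------------------------------------

def _first_order_values(values: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """First-order statistics of a masked value sample.

    ``levels`` is the discretized alphabet of the same voxels; entropy and
    uniformity are computed on its normalized histogram (log base 2).
    Skewness is the population third standardized moment; kurtosis the
    (non-excess) fourth.  Both are 0 for a constant sample.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = values.mean()
    var = values.var()  # population variance
    sd = np.sqrt(var)
    centered = values - mean
    if sd > 0:
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / sd**4)
    else:
        skew = kurt = 0.0
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    return {
        "energy": float((values**2).sum()),
        "entropy": entropy,
        "kurtosis": kurt,
        "maximum": float(values.max()),
        "mean": float(mean),
        "mean_absolute_deviation": float(np.abs(centered).mean()),
        "median": float(np.median(values)),
        "minimum": float(values.min()),
        "range": float(values.max() - values.min()),
        "root_mean_square": float(np.sqrt(np.mean(values**2))),
        "skewness": skew,
        "standard_deviation": float(sd),
        "uniformity": uniformity,
        "variance": float(var),
    }


def first_order(v: VolumeWithMask, bin_width: float = 25.0) -> pd.Series:
    """Group I statistics of masked voxel intensities."""
    v.require_nonempty()
    g = discretize(v, bin_width)
    vals = _first_order_values(v.masked_values(), g.levels[g.mask])
    return pd.Series(vals, index=list(FIRST_ORDER_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# Group II: shape
# ---------------------------------------------------------------------------

def shape_features(v: VolumeWithMask) -> pd.Series:
    """Size and shape of the mask, in physical units (mm).

    Surface area uses the voxel-face convention (sum of exposed voxel
    faces).  Maximum 3D diameter is the largest Euclidean distance between
    masked voxel centers (0 for a single voxel).
    """
    v.require_nonempty()
    sz, sy, sx = v.spacing_mm
    mask = v.mask
    n = v.n_masked
    voxel_vol = sz * sy * sx
    volume = n * voxel_vol

    face_areas = (sy * sx, sz * sx, sz * sy)  # faces perpendicular to z, y, x
    surface = 0.0
    for axis, area in enumerate(face_areas):
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        surface += np.count_nonzero(np.diff(padded, axis=axis)) * area

    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface
    disproportion = surface / (4.0 * np.pi * r_equiv**2)
    compactness1 = volume / (np.sqrt(np.pi) * surface ** (3.0 / 2.0))
    compactness2 = 36.0 * np.pi * volume**2 / surface**3

    # Diameter over boundary voxels only (interior voxels never realize it).
    boundary = mask & ~ndimage.binary_erosion(mask)
    coords = np.argwhere(boundary).astype(float) * np.array([sz, sy, sx])
    if len(coords) == 1:
        diameter = 0.0
    else:
        diff = coords[:, None, :] - coords[None, :, :]
        diameter = float(np.sqrt((diff**2).sum(-1)).max())

    return pd.Series(
        {
            "volume": volume,
            "surface_area": surface,
            "surface_to_volume_ratio": surface / volume,
            "sphericity": float(sphericity),
            "spherical_disproportion": float(disproportion),
            "compactness1": float(compactness1),
            "compactness2": float(compactness2),
            "maximum_3d_diameter": diameter,
        },
        index=list(SHAPE_NAMES),
        dtype=float,
    )


# ---------------------------------------------------------------------------
# Group III: GLCM
# ---------------------------------------------------------------------------

def _offset_slices(shape, off):
    src, dst = [], []
    for ax_len, d in zip(shape, off):
        if d >= 0:
            src.append(slice(0, ax_len - d))
            dst.append(slice(d, ax_len))
        else:
            src.append(slice(-d, ax_len))
            dst.append(slice(0, ax_len + d))
    return tuple(src), tuple(dst)


def glcm_matrix(g: GrayVolume, offset) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix for one direction."""
    src, dst = _offset_slices(g.levels.shape, offset)
    valid = g.mask[src] & g.mask[dst]
    a = g.levels[src][valid] - 1
    b = g.levels[dst][valid] - 1
    ng = g.n_levels
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return counts
    return counts / total


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_feature_values(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in ksum])
    kdiff = np.arange(0, ng, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in kdiff])

    entropy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(px).sum())
    pxy_outer = np.outer(px, px)
    both = (p > 0) & (pxy_outer > 0)
    hxy1 = float(-(p[both] * np.log2(pxy_outer[both])).sum())
    hxy2 = float(-_xlog2(pxy_outer).sum())

    if hx > 0:
        imc1 = (entropy - hxy1) / hx
    else:
        logger.warning("GLCM IMC1 undefined for single-level image; emitting 0")
        imc1 = 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(max(imc2_arg, 0.0)))

    if sigma_x > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_x) / (sigma_x * sigma_x))
    else:
        logger.warning("GLCM correlation undefined for single-level image; emitting 0")
        correlation = 0.0

    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum())

    sum_avg = float((ksum * p_sum).sum())
    diff_avg = float((kdiff * p_diff).sum())
    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu_x) ** 4 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu_x) ** 3 * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu_x) ** 2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": correlation,
        "difference_entropy": float(-_xlog2(p_diff).sum()),
        "difference_variance": float(((kdiff - diff_avg) ** 2 * p_diff).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "energy": float((p**2).sum()),
        "entropy": entropy,
        "homogeneity1": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "homogeneity2": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "imc1": float(imc1),
        "imc2": imc2,
        "idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": float(-_xlog2(p_sum).sum()),
        "sum_variance": float(((ksum - sum_avg) ** 2 * p_sum).sum()),
        "sum_of_squares_variance": float(((ii - mu_x) ** 2 * p).sum()),
    }


def glcm_features(g: GrayVolume) -> pd.Series:
    """22+1 co-occurrence features, averaged over the 13 directions."""
    acc = None
    n_used = 0
    for off in DIRECTIONS:
        p = glcm_matrix(g, off)
        if p.sum() == 0:
            continue  # no valid pair in this direction (thin masks)
        vals = _glcm_feature_values(p)
        acc = vals if acc is None else {k: acc[k] + vals[k] for k in acc}
        n_used += 1
    if acc is None:
        logger.warning("no co-occurring voxel pairs in any direction; GLCM set to 0")
        acc = {k: 0.0 for k in GLCM_NAMES}
        n_used = 1
    return pd.Series(
        {k: v / n_used for k, v in acc.items()}, index=list(GLCM_NAMES), dtype=float
    )


# ---------------------------------------------------------------------------
# Group III: RLGL (run-length)
# ---------------------------------------------------------------------------

def _shift_slab(arr: np.ndarray, shifts, fill=0):
    """out[x] = arr[x + shifts]; positions falling outside get ``fill``."""
    out = np.full_like(arr, fill)
    src2, dst2 = [], []
    for ax_len, s in zip(arr.shape, shifts):
        if s >= 0:
            dst2.append(slice(0, ax_len - s))
            src2.append(slice(s, ax_len))
        else:
            dst2.append(slice(-s, ax_len))
            src2.append(slice(0, ax_len + s))
    out[tuple(dst2)] = arr[tuple(src2)]
    return out


def run_length_matrix(g: GrayVolume, offset) -> np.ndarray:
    """Run-length counts N[gray-1, length-1] for one direction.

    Runs are maximal sequences of equal gray level along ``offset``,
    confined to the mask.  Conservation: sum_{g,l} N[g,l]*l equals the
    masked voxel count.
    """
    lev = np.where(g.mask, g.levels, 0)
    shape = lev.shape
    k = next(ax for ax, d in enumerate(offset) if d != 0)
    dk = offset[k]  # positive by canonical direction convention
    rest = tuple(d for ax, d in enumerate(offset) if ax != k)

    lev_m = np.moveaxis(lev, k, 0)
    r = np.zeros(shape, dtype=np.int64)
    r_m = np.moveaxis(r, k, 0)
    nk = shape[k]
    for idx in range(nk - 1, -1, -1):
        cur = lev_m[idx]
        nxt_idx = idx + dk
        if 0 <= nxt_idx < nk:
            nxt_lev = _shift_slab(lev_m[nxt_idx], rest)
            nxt_r = _shift_slab(r_m[nxt_idx], rest)
            cont = (cur > 0) & (nxt_lev == cur)
            r_m[idx] = np.where(cur > 0, 1 + np.where(cont, nxt_r, 0), 0)
        else:
            r_m[idx] = (cur > 0).astype(np.int64)

    # A run starts where the predecessor along offset is absent or differs.
    prev_lev = _shift_slab(lev, tuple(-d for d in offset))
    start = (lev > 0) & (prev_lev != lev)
    gvals = lev[start] - 1
    lvals = r[start] - 1
    if gvals.size == 0:
        return np.zeros((g.n_levels, 1), dtype=float)
    max_len = int(lvals.max()) + 1
    counts = np.bincount(
        gvals * max_len + lvals, minlength=g.n_levels * max_len
    ).reshape(g.n_levels, max_len)
    return counts.astype(float)


def _size_weighted_features(counts: np.ndarray, n_voxels: int):
    """Shared feature formulas of run-length and size-zone matrices.

    ``counts[g-1, s-1]`` are counts of runs/zones of gray level g and
    length/size s; emphasis features weight by 1/s^2, s^2, 1/g^2, g^2.
    """
    total = counts.sum()
    gl = np.arange(1, counts.shape[0] + 1, dtype=float)
    sz = np.arange(1, counts.shape[1] + 1, dtype=float)
    gg, ss = np.meshgrid(gl, sz, indexing="ij")
    p = counts / total
    return {
        "short": float((counts / ss**2).sum() / total),
        "long": float((counts * ss**2).sum() / total),
        "gln": float((counts.sum(axis=1) ** 2).sum() / total),
        "sln": float((counts.sum(axis=0) ** 2).sum() / total),
        "pct": float(total / n_voxels),
        "lgl": float((counts / gg**2).sum() / total),
        "hgl": float((counts * gg**2).sum() / total),
        "slgl": float((counts / (gg**2 * ss**2)).sum() / total),
        "shgl": float((counts * gg**2 / ss**2).sum() / total),
        "llgl": float((counts * ss**2 / gg**2).sum() / total),
        "lhgl": float((counts * gg**2 * ss**2).sum() / total),
        "_p": p,
        "_gg": gg,
        "_ss": ss,
    }


def rlgl_features(g: GrayVolume) -> pd.Series:
    """11 run-length features, averaged over the 13 directions."""
    n_vox = int(g.mask.sum())
    acc = np.zeros(len(RLGL_NAMES))
    for off in DIRECTIONS:
        counts = run_length_matrix(g, off)
        f = _size_weighted_features(counts, n_vox)
        acc += np.array(
            [
                f["short"],
                f["long"],
                f["gln"],
                f["sln"],
                f["pct"],
                f["lgl"],
                f["hgl"],
                f["slgl"],
                f["shgl"],
                f["llgl"],
                f["lhgl"],
            ]
        )
    return pd.Series(acc / len(DIRECTIONS), index=list(RLGL_NAMES), dtype=float)


# ---------------------------------------------------------------------------
# Group III: GLSZM (size zones)
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def size_zone_matrix(g: GrayVolume) -> np.ndarray:
    """Zone counts N[gray-1, size-1]; zones are 26-connected components."""
    zones: list[tuple[int, int]] = []
    for level in range(1, g.n_levels + 1):
        labeled, n_comp = ndimage.label(g.levels == level, structure=_STRUCT_26)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    counts = np.zeros((g.n_levels, max_size), dtype=float)
    for level, s in zones:
        counts[level - 1, s - 1] += 1
    return counts


def glszm_features(g: GrayVolume) -> pd.Series:
    """14 size-zone features (direction-free)."""
    counts = size_zone_matrix(g)
    n_vox = int(g.mask.sum())
    f = _size_weighted_features(counts, n_vox)
    p, gg, ss = f["_p"], f["_gg"], f["_ss"]
    mu_g = (p * gg).sum()
    mu_s = (p * ss).sum()
    glv = float((p * (gg - mu_g) ** 2).sum())
    zsv = float((p * (ss - mu_s) ** 2).sum())
    ps = p.sum(axis=0)
    zse = float(-_xlog2(ps).sum())
    return pd.Series(
        {
            "small_zone_emphasis": f["short"],
            "large_zone_emphasis": f["long"],
            "gray_level_nonuniformity": f["gln"],
            "zone_size_nonuniformity": f["sln"],
            "zone_percentage": f["pct"],
            "low_gray_level_zone_emphasis": f["lgl"],
            "high_gray_level_zone_emphasis": f["hgl"],
            "small_zone_low_gray_level_emphasis": f["slgl"],
            "small_zone_high_gray_level_emphasis": f["shgl"],
            "large_zone_low_gray_level_emphasis": f["llgl"],
            "large_zone_high_gray_level_emphasis": f["lhgl"],
            "gray_level_variance": glv,
            "zone_size_variance": zsv,
            "zone_size_entropy": zse,
        },
        index=list(GLSZM_NAMES),
        dtype=float,
    )


# ---------------------------------------------------------------------------
# Group IV: wavelet sub-bands
# ---------------------------------------------------------------------------

def wavelet_bands(
    intensities: np.ndarray, wavelet: str = "coif1"
) -> dict[str, np.ndarray]:
    """One-level 3D stationary (undecimated) wavelet decomposition.

    Returns the 8 sub-bands keyed LLL..HHH (letters ordered (z, y, x)).
    Odd axes are edge-padded to even length and cropped back, since the
    stationary transform requires even dimensions.
    """
    arr = np.asarray(intensities, dtype=float)
    w = pywt.Wavelet(wavelet)
    if min(arr.shape) < 2:
        raise ValueError("volume too small for one wavelet decomposition level")
    pad = [(0, n % 2) for n in arr.shape]
    padded = np.pad(arr, pad, mode="edge")
    coeffs = pywt.swtn(padded, w, level=1)[0]
    crop = tuple(slice(0, n) for n in arr.shape)
    out = {}
    for key, band in coeffs.items():
        label = "".join("L" if ch == "a" else "H" for ch in key)
        out[label] = band[crop]
    return out


def wavelet_features(
    v: VolumeWithMask, wavelet: str = "coif1", bin_width: float = 25.0
) -> pd.Series:
    """Group I + GLCM + RLGL features recomputed on each of the 8 sub-bands."""
    v.require_nonempty()
    bands = wavelet_bands(v.intensities, wavelet)
    pieces = []
    for label in WAVELET_BANDS:
        g = discretize_array(bands[label], v.mask, bin_width, v.spacing_mm)
        fo = _first_order_values(bands[label][v.mask], g.levels[g.mask])
        fo_s = pd.Series(fo, index=list(FIRST_ORDER_NAMES), dtype=float)
        fo_s.index = [f"wavelet_{label}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
        glcm = glcm_features(g)
        glcm.index = [f"wavelet_{label}_glcm_{n}" for n in GLCM_NAMES]
        rlgl = rlgl_features(g)
        rlgl.index = [f"wavelet_{label}_rlgl_{n}" for n in RLGL_NAMES]
        pieces += [fo_s, glcm, rlgl]
    return pd.concat(pieces)


# ---------------------------------------------------------------------------
# Group V: Laplacian of Gaussian
# ---------------------------------------------------------------------------

def log_filter(v: VolumeWithMask, sigma_mm: float) -> np.ndarray:
    """Laplacian-of-Gaussian response at a physical scale (sigma in mm)."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sigma_vox = [sigma_mm / s for s in v.spacing_mm]
    return ndimage.gaussian_laplace(v.intensities, sigma=sigma_vox)


def log_features(
    v: VolumeWithMask,
    sigmas_mm=DEFAULT_LOG_SIGMAS_MM,
    bin_width: float = 25.0,
) -> pd.Series:
    """Group I statistics of the LoG response at each scale."""
    v.require_nonempty()
    pieces = []
    for sigma in sigmas_mm:
        response = log_filter(v, float(sigma))
        g = discretize_array(response, v.mask, bin_width, v.spacing_mm)
        fo = _first_order_values(response[v.mask], g.levels[g.mask])
        s = pd.Series(fo, index=list(FIRST_ORDER_NAMES), dtype=float)
        s.index = [f"{_sigma_tag(sigma)}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
        pieces.append(s)
    return pd.concat(pieces)


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def extract_all(v: VolumeWithMask, cfg: ExtractionConfig | None = None) -> pd.Series:
    """Run the full bank on one volume: resample, discretize, all groups.

    Returns a Series in bank order with ``attrs['config_hash']`` set.
    """
    cfg = cfg or ExtractionConfig()
    v.require_nonempty()
    if cfg.resample and tuple(v.spacing_mm) != tuple(cfg.resample_spacing_mm):
        v = resample(v, cfg.resample_spacing_mm)
    g = discretize(v, cfg.bin_width)

    fo = first_order(v, cfg.bin_width)
    fo.index = [f"original_firstorder_{n}" for n in FIRST_ORDER_NAMES]
    sh = shape_features(v)
    sh.index = [f"original_shape_{n}" for n in SHAPE_NAMES]
    glcm = glcm_features(g)
    glcm.index = [f"original_glcm_{n}" for n in GLCM_NAMES]
    rlgl = rlgl_features(g)
    rlgl.index = [f"original_rlgl_{n}" for n in RLGL_NAMES]
    glszm = glszm_features(g)
    glszm.index = [f"original_glszm_{n}" for n in GLSZM_NAMES]
    wav = wavelet_features(v, cfg.wavelet, cfg.bin_width)
    log = log_features(v, cfg.log_sigmas_mm, cfg.bin_width)

    out = pd.concat([fo, sh, glcm, rlgl, glszm, wav, log])
    out = out.reindex(feature_bank(cfg))
    if out.isna().any():
        missing = list(out.index[out.isna()])
        raise RuntimeError(f"bank enumeration mismatch, missing {missing[:5]}")
    out.attrs["config_hash"] = cfg.config_hash()
    return out


def base_feature_name(name: str) -> str:
    """Collapse a bank name to its transformation-free base name.

    ``wavelet_HHH_glcm_entropy`` and ``log_sigma_2_0_mm_firstorder_entropy``
    collapse to ``glcm_entropy`` / ``firstorder_entropy``; used when two
    modules are compared for overlap.
    """
    import re

    return re.sub(r"^(original_|wavelet_[LH]{3}_|log_sigma_[0-9_]+_mm_)", "", name)
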