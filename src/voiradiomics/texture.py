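"""Gray-level quantization, texture matrices and the 43-feature texture set.

The texture block per extraction-parameter combination is:

- Global (3): variance, skewness, kurtosis of the 100-bin intensity
  histogram of the VOI;
- GLCM (9): energy, contrast, entropy, homogeneity, correlation,
  sum-average, variance, dissimilarity, autocorrelation;
- GLRLM (13): SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE,
  LRHGE, GLV, RLV;
- GLSZM (13): the zone analogues (SZE, LZE, GLN, ZSN, ZP, LGZE, HGZE,
  SZLGE, SZHGE, LZLGE, LZHGE, GLV, ZSV);
- NGTDM (5): coarseness, contrast, busyness, complexity, strength.

Conventions: GLCM pools distance-1 voxel pairs over the 13 unique 3D
directions into ONE symmetrized, normalized matrix (not per-direction
feature averaging); GLRLM pools runs over the same 13 directions; GLSZM
zones are 26-connected; NGTDM uses the mean of valid 26-neighbors.
Degenerate inputs (constant VOI, single-level matrices) yield the features'
defined limits, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# the 13 unique 3D directions (one per +/- pair of the 26-neighborhood)
DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

GLOBAL_FEATURES = ("variance", "skewness", "kurtosis")
GLCM_FEATURES = (
    "energy", "contrast", "entropy", "homogeneity", "correlation",
    "sum_average", "variance", "dissimilarity", "autocorrelation",
)
GLRLM_FEATURES = (
    "sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
    "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv",
)
GLSZM_FEATURES = (
    "sze", "lze", "gln", "zsn", "zp", "lgze", "hgze",
    "szlge", "szhge", "lzlge", "lzhge", "glv", "zsv",
)
NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

#: number of texture features per extraction-parameter combination
N_TEXTURE_FEATURES = (
    len(GLOBAL_FEATURES) + len(GLCM_FEATURES) + len(GLRLM_FEATURES)
    + len(GLSZM_FEATURES) + len(NGTDM_FEATURES)
)


@dataclass(frozen=True)
class QuantizedVoi:
    """Gray levels 1..ng inside the VOI, 0 outside."""

    levels: np.ndarray  # int array, 0 = outside mask
    ng: int
    scale_mm: float = float("nan")

    def __post_init__(self) -> None:
        lev = np.asarray(self.levels)
        inside = lev[lev > 0]
        if inside.size and inside.max() > self.ng:
            raise ValueError("levels exceed ng")
        object.__setattr__(self, "levels", lev.astype(np.int32))

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


@dataclass(frozen=True)
class TextureMatrices:
    glcm: np.ndarray       # ng x ng, symmetric, sums to 1
    glrlm: np.ndarray      # ng x Lmax integer run counts
    glszm: np.ndarray      # ng x Zmax integer zone counts
    ngtdm_s: np.ndarray    # per-level coarseness sums s(i), length ng
    ngtdm_n: np.ndarray    # per-level voxel counts n_i, length ng
    n_voxels: int


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(values: np.ndarray, mask: np.ndarray, algorithm: str, ng: int,
             scale_mm: float = float("nan")) -> QuantizedVoi:
    """Quantize in-mask intensities to gray levels 1..ng.

    ``uniform``: equal-width bins on the in-mask [min, max].
    ``equal``: equal-frequency bins at the in-mask quantiles.
    ``lloyd``: Lloyd-Max scalar quantizer (centroid/boundary iteration to
    1e-7 or 500 iterations, initialized at the equal-width centroids).

    A constant in-mask intensity maps every voxel to level 1 (texture
    features then take their degenerate values).
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(values, dtype=np.float64)[mask]
    if x.size == 0:
        raise ValueError("empty mask")
    lo, hi = x.min(), x.max()

    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi <= lo:  # constant VOI
        levels[mask] = 1
        return QuantizedVoi(levels, ng, scale_mm)

    if algorithm == "uniform":
        lev = np.minimum((np.floor((x - lo) / (hi - lo) * ng)).astype(np.int64) + 1, ng)
    elif algorithm == "equal":
        edges = np.quantile(x, np.arange(1, ng) / ng)
        lev = np.searchsorted(edges, x, side="left") + 1
    elif algorithm == "lloyd":
        lev = _lloyd_max(x, ng)
    else:
        raise ValueError(f"unknown quantization algorithm {algorithm!r}")

    levels[mask] = lev
    return QuantizedVoi(levels, ng, scale_mm)


def _lloyd_max(x: np.ndarray, ng: int, tol: float = 1e-7, max_iter: int = 500) -> np.ndarray:
    lo, hi = x.min(), x.max()
    centroids = lo + (np.arange(ng) + 0.5) * (hi - lo) / ng
    xs = np.sort(x)
    for _ in range(max_iter):
        bounds = 0.5 * (centroids[:-1] + centroids[1:])
        idx = np.searchsorted(bounds, xs, side="right")
        # conditional means per cell; empty cells keep their centroid
        sums = np.bincount(idx, weights=xs, minlength=ng)
        cnts = np.bincount(idx, minlength=ng)
        new = np.where(cnts > 0, sums / np.maximum(cnts, 1), centroids)
        shift = np.abs(new - centroids).max()
        centroids = new
        if shift < tol:
            break
    bounds = 0.5 * (centroids[:-1] + centroids[1:])
    return np.searchsorted(bounds, x, side="right").astype(np.int64) + 1


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def _shifted_views(a: np.ndarray, d: tuple[int, int, int]):
    """Views (src, dst) of ``a`` such that src[v] pairs with dst[v] = a[v + d]."""
    slc_src, slc_dst = [], []
    for step, n in zip(d, a.shape):
        if step == 0:
            slc_src.append(slice(None))
            slc_dst.append(slice(None))
        elif step > 0:
            slc_src.append(slice(0, n - step))
            slc_dst.append(slice(step, n))
        else:
            slc_src.append(slice(-step, n))
            slc_dst.append(slice(0, n + step))
    return a[tuple(slc_src)], a[tuple(slc_dst)]


def glcm_matrix(q: QuantizedVoi) -> np.ndarray:
    """Distance-1 co-occurrence matrix pooled over the 13 directions,
    symmetrized and normalized to sum 1."""
    lev = q.levels
    ng = q.ng
    counts = np.zeros((ng, ng), dtype=np.int64)
    for d in DIRECTIONS_13:
        a, b = _shifted_views(lev, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        flat = (a[valid].astype(np.int64) - 1) * ng + (b[valid] - 1)
        counts += np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no voxel pairs (single-voxel or disconnected VOI)")
    return counts / total


def glrlm_matrix(q: QuantizedVoi) -> np.ndarray:
    """Run-length matrix: runs of equal level pooled over the 13 directions.

    Row i (0-based) = level i+1; column l (0-based) = run length l+1.
    """
    lev = q.levels
    ng = q.ng
    max_len = max(lev.shape)
    counts = np.zeros((ng, max_len), dtype=np.int64)
    for d in DIRECTIONS_13:
        run_end = _run_lengths(lev, d)
        start_lev, start_len = run_end
        if start_lev.size:
            flat = (start_lev.astype(np.int64) - 1) * max_len + (start_len - 1)
            counts += np.bincount(flat, minlength=ng * max_len).reshape(ng, max_len)
    # trim trailing all-zero run-length columns (keep >= 1 column)
    nz = np.nonzero(counts.any(axis=0))[0]
    last = nz[-1] if nz.size else 0
    return counts[:, : last + 1]


def _run_lengths(lev: np.ndarray, d: tuple[int, int, int]):
    """Levels and lengths of all maximal runs along direction d.

    R[v] = remaining run length starting at v, computed plane-by-plane
    against the dominant axis of d; run starts are voxels whose predecessor
    along d is absent or of a different level.
    """
    valid = lev > 0
    # eq_next[v]: v+d in bounds, both valid, same level
    eq_next = np.zeros(lev.shape, dtype=bool)
    a_src, a_dst = _shifted_views(lev, d)
    src_view, _ = _shifted_views(eq_next, d)
    src_view[...] = (a_src > 0) & (a_dst > 0) & (a_src == a_dst)

    axis = next(i for i in (2, 1, 0) if d[i] != 0)  # iterate along this axis
    step = d[axis]
    n = lev.shape[axis]
    R = np.ones(lev.shape, dtype=np.int64)
    # process planes so that v + d is already final when v is visited
    order = range(n - 1, -1, -1) if step > 0 else range(n)
    sl = [slice(None)] * 3
    d_inplane = list(d)
    d_inplane[axis] = 0
    for k in order:
        k_next = k + step
        if k_next < 0 or k_next >= n:
            continue
        sl[axis] = k
        plane_eq = eq_next[tuple(sl)]
        sl_next = sl.copy()
        sl_next[axis] = k_next
        r_next = R[tuple(sl_next)]
        if any(d_inplane):
            # align the next plane with the in-plane part of d
            r_next = _shift_plane(r_next, d_inplane, axis)
        R[tuple(sl)] = np.where(plane_eq, r_next + 1, 1)

    # run starts: no equal predecessor along d
    eq_prev = np.zeros(lev.shape, dtype=bool)
    _, dst_view = _shifted_views(eq_prev, d)
    a_src, a_dst = _shifted_views(lev, d)
    dst_view[...] = (a_src > 0) & (a_dst > 0) & (a_src == a_dst)
    starts = valid & ~eq_prev
    return lev[starts], R[starts]


def _shift_plane(plane: np.ndarray, d3: list[int], axis: int) -> np.ndarray:
    """Shift a 2D plane by the in-plane components of a 3D direction so that
    out[v] = plane[v + d_inplane] (0 outside)."""
    d2 = [x for i, x in enumerate(d3) if i != axis]
    out = np.zeros_like(plane)
    src, dst = _shifted_views_2d(plane, d2)
    osrc, _ = _shifted_views_2d(out, d2)
    osrc[...] = dst
    return out


def _shifted_views_2d(a: np.ndarray, d: list[int]):
    slc_src, slc_dst = [], []
    for step, n in zip(d, a.shape):
        if step == 0:
            slc_src.append(slice(None))
            slc_dst.append(slice(None))
        elif step > 0:
            slc_src.append(slice(0, n - step))
            slc_dst.append(slice(step, n))
        else:
            slc_src.append(slice(-step, n))
            slc_dst.append(slice(0, n + step))
    return a[tuple(slc_src)], a[tuple(slc_dst)]


def glszm_matrix(q: QuantizedVoi) -> np.ndarray:
    """Size-zone matrix: 26-connected zones of equal level.

    Row i = level i+1; column s = zone size s+1.
    """
    lev = q.levels
    ng = q.ng
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for level in range(1, ng + 1):
        binary = lev == level
        if not binary.any():
            continue
        lab, n_lab = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((level, int(s)))
            max_size = max(max_size, int(s))
    counts = np.zeros((ng, max_size), dtype=np.int64)
    for level, s in zones:
        counts[level - 1, s - 1] += 1
    return counts


def ngtdm_matrix(q: QuantizedVoi) -> tuple[np.ndarray, np.ndarray]:
    """NGTDM sums s(i) and occurrence counts n_i.

    For each in-mask voxel with >= 1 valid 26-neighbor, accumulate
    ``|level - mean(valid neighbor levels)|`` into s(level).
    """
    lev = q.levels.astype(np.float64)
    valid = q.levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.correlate(lev * valid, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(valid.astype(np.float64), kernel, mode="constant", cval=0.0)
    has_nb = valid & (nb_cnt > 0)
    diffs = np.zeros(lev.shape)
    diffs[has_nb] = np.abs(lev[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    s = np.zeros(q.ng)
    n = np.zeros(q.ng, dtype=np.int64)
    if has_nb.any():
        idx = q.levels[has_nb] - 1
        np.add.at(s, idx, diffs[has_nb])
        n = np.bincount(idx, minlength=q.ng)
    return s, n


def build_texture_matrices(q: QuantizedVoi) -> TextureMatrices:
    s, n = ngtdm_matrix(q)
    return TextureMatrices(
        glcm=glcm_matrix(q),
        glrlm=glrlm_matrix(q),
        glszm=glszm_matrix(q),
        ngtdm_s=s,
        ngtdm_n=n,
        n_voxels=q.n_voxels,
    )


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def global_features(intensities: np.ndarray, n_bins: int = 100) -> dict[str, float]:
    """Variance, skewness and (non-excess) kurtosis of the binned in-mask
    intensity histogram; skewness/kurtosis are 0 for a degenerate histogram."""
    x = np.asarray(intensities, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return {"variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    hist, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    mu = float(np.sum(p * centers))
    var = float(np.sum(p * (centers - mu) ** 2))
    if var <= 0:
        return {"variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    skew = float(np.sum(p * (centers - mu) ** 3) / var**1.5)
    kurt = float(np.sum(p * (centers - mu) ** 4) / var**2)
    return {"variance": var, "skewness": skew, "kurtosis": kurt}


def glcm_features(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    sd_i = float(np.sqrt(np.sum((i - mu_i) ** 2 * p)))
    sd_j = float(np.sqrt(np.sum((j - mu_j) ** 2 * p)))
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    if sd_i * sd_j > 0:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p) / (sd_i * sd_j))
    else:
        correlation = 1.0  # constant-level limit: perfectly correlated
    return {
        "energy": float(np.sum(p**2)),
        "contrast": float(np.sum(p * (i - j) ** 2)),
        "entropy": entropy,
        "homogeneity": float(np.sum(p / (1.0 + np.abs(i - j)))),
        "correlation": correlation,
        "sum_average": float(np.sum((i + j) * p)),  # == sum_k k * p_{x+y}(k)
        "variance": float(np.sum((i - mu_i) ** 2 * p)),
        "dissimilarity": float(np.sum(p * np.abs(i - j))),
        "autocorrelation": float(np.sum(i * j * p)),
    }


def _rl_features(counts: np.ndarray, n_voxels: int, names: tuple[str, ...]) -> dict[str, float]:
    """Shared run-length / size-zone feature formulas on a level x length
    count matrix."""
    counts = counts.astype(np.float64)
    nr = counts.sum()
    if nr == 0:
        return {name: 0.0 for name in names}
    ng, lmax = counts.shape
    i = np.arange(1, ng + 1)[:, None].astype(np.float64)
    l = np.arange(1, lmax + 1)[None, :].astype(np.float64)
    p = counts / nr
    r_i = counts.sum(axis=1)
    r_l = counts.sum(axis=0)
    mu_i = float(np.sum(p * i))
    mu_l = float(np.sum(p * l))
    vals = [
        float(np.sum(counts / l**2) / nr),            # SRE / SZE
        float(np.sum(counts * l**2) / nr),            # LRE / LZE
        float(np.sum(r_i**2) / nr),                   # GLN
        float(np.sum(r_l**2) / nr),                   # RLN / ZSN
        float(nr / n_voxels),                         # RP / ZP
        float(np.sum(counts / i**2) / nr),            # LGRE / LGZE
        float(np.sum(counts * i**2) / nr),            # HGRE / HGZE
        float(np.sum(counts / (i**2 * l**2)) / nr),   # SRLGE / SZLGE
        float(np.sum(counts * i**2 / l**2) / nr),     # SRHGE / SZHGE
        float(np.sum(counts * l**2 / i**2) / nr),     # LRLGE / LZLGE
        float(np.sum(counts * i**2 * l**2) / nr),     # LRHGE / LZHGE
        float(np.sum(p * (i - mu_i) ** 2)),           # GLV
        float(np.sum(p * (l - mu_l) ** 2)),           # RLV / ZSV
    ]
    return dict(zip(names, vals))


def glrlm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rl_features(counts, n_voxels, GLRLM_FEATURES)


def glszm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rl_features(counts, n_voxels, GLSZM_FEATURES)


#: cap used for NGTDM coarseness when the denominator vanishes
COARSENESS_CAP = 1e6


def ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    n = n.astype(np.float64)
    total = n.sum()
    if total == 0:
        return {name: 0.0 for name in NGTDM_FEATURES}
    p = n / total
    ng = len(n)
    levels = np.arange(1, ng + 1, dtype=np.float64)
    active = p > 0
    n_active = int(active.sum())
    i = levels[active]
    pi = p[active]
    si = s[active]

    denom = float(np.sum(pi * si))
    coarseness = 1.0 / denom if denom > 0 else COARSENESS_CAP

    if n_active > 1:
        dif2 = (i[:, None] - i[None, :]) ** 2
        contrast = (
            float(np.sum(pi[:, None] * pi[None, :] * dif2))
            / (n_active * (n_active - 1))
            * float(s.sum() / total)
        )
        busy_den = float(np.sum(np.abs((i * pi)[:, None] - (i * pi)[None, :])))
        busyness = denom / busy_den if busy_den > 0 else 0.0
        absdif = np.abs(i[:, None] - i[None, :])
        pspsum = (pi * si)[:, None] + (pi * si)[None, :]
        complexity = float(np.sum(absdif * pspsum / (pi[:, None] + pi[None, :]))) / total
        strength_num = float(np.sum((pi[:, None] + pi[None, :]) * dif2))
        strength = strength_num / float(s.sum()) if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def texture_features(m: TextureMatrices, intensities: np.ndarray) -> dict[str, float]:
    """The full 43-feature texture block for one extraction combination.

    Keys are ``<family>.<feature>``; iteration order is fixed:
    global, glcm, glrlm, glszm, ngtdm.
    """
    out: dict[str, float] = {}
    for name, val in global_features(intensities).items():
        out[f"global.{name}"] = val
    for name, val in glcm_features(m.glcm).items():
        out[f"glcm.{name}"] = val
    for name, val in glrlm_features(m.glrlm, m.n_voxels).items():
        out[f"glrlm.{name}"] = val
    for name, val in glszm_features(m.glszm, m.n_voxels).items():
        out[f"glszm.{name}"] = val
    for name, val in ngtdm_features(m.ngtdm_s, m.ngtdm_n).items():
        out[f"ngtdm.{name}"] = val
    return out
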