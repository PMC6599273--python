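"""Grey-level texture-matrix features on a discretized 3D region.

All families operate on an integer label array ``A`` with levels
``1..n_levels`` inside the mask and ``0`` outside, typically the mask
bounding box.  Directional families (GLCM, GLRLM) use the 13 unique 3D
directions; GLCM and the primary GLRLM block average features over
directions, a second GLRLM block merges the matrices before computing
features.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glcm_features",
    "run_length_matrix",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

#: the 13 unique 3D offsets (z, y, x) up to sign
DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _shift_pairs(a: np.ndarray, offset: tuple[int, int, int]):
    """Views of ``a`` at x and x+offset over the overlapping region."""
    src, dst = [], []
    for o, s in zip(offset, a.shape):
        if o >= 0:
            src.append(slice(0, s - o))
            dst.append(slice(o, s))
        else:
            src.append(slice(-o, s))
            dst.append(slice(0, s + o))
    return a[tuple(src)], a[tuple(dst)]


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(labels: np.ndarray, n_levels: int, offset: tuple[int, int, int],
                distance: int = 1) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction."""
    off = tuple(int(o) * distance for o in offset)
    a, b = _shift_pairs(labels, off)
    valid = (a > 0) & (b > 0)
    i, j = a[valid], b[valid]
    m = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(m, (i - 1, j - 1), 1.0)
    return m + m.T


def glcm_features(labels: np.ndarray, n_levels: int, distance: int = 1) -> dict[str, float]:
    """The 25 co-occurrence features, averaged over the 13 directions."""
    per_dir = []
    for d in DIRECTIONS_13:
        m = glcm_matrix(labels, n_levels, d, distance)
        if m.sum() > 0:
            per_dir.append(_glcm_single(m))
    if not per_dir:
        return {k: np.nan for k in _glcm_single(np.ones((2, 2)))}
    return _nanmean_dicts(per_dir)


def _nanmean_dicts(dicts: list[dict[str, float]]) -> dict[str, float]:
    out = {}
    for k in dicts[0]:
        vals = [f[k] for f in dicts if not np.isnan(f[k])]
        out[k] = float(np.mean(vals)) if vals else np.nan
    return out


def _glcm_single(m: np.ndarray) -> dict[str, float]:
    ng = m.shape[0]
    p = m / m.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((ii * p).sum())
    var = float(((ii - mu) ** 2 * p).sum())

    k_diff = np.abs(ii - jj)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, k_diff.astype(int).ravel(), p.ravel())
    kd = np.arange(ng, dtype=np.float64)
    diff_avg = float((kd * p_diff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * p_diff).sum())
    nz = p_diff[p_diff > 0]
    diff_ent = float(-(nz * np.log2(nz)).sum())

    p_sum = np.zeros(2 * ng + 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    ks = np.arange(2 * ng + 1, dtype=np.float64)
    sum_avg = float((ks * p_sum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    nz = p_sum[p_sum > 0]
    sum_ent = float(-(nz * np.log2(nz)).sum())

    nzp = p[p > 0]
    hxy = float(-(nzp * np.log2(nzp)).sum())
    pxpy = np.outer(px, px)
    mask_p = p > 0
    mask_b = pxpy > 0
    hxy1 = float(-(p[mask_p & mask_b] * np.log2(pxpy[mask_p & mask_b])).sum())
    hxy2 = float(-(pxpy[mask_b] * np.log2(pxpy[mask_b])).sum())
    nzx = px[px > 0]
    hx = float(-(nzx * np.log2(nzx)).sum())
    ic1 = (hxy - hxy1) / hx if hx > 0 else np.nan
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off_diag = k_diff > 0
    inv_var = float((p[off_diag] / k_diff[off_diag] ** 2).sum()) if off_diag.any() else 0.0
    corr = (float((ii * jj * p).sum()) - mu * mu) / var if var > 0 else np.nan

    return {
        "joint_max": float(p.max()),
        "joint_avg": mu,
        "joint_var": var,
        "joint_entropy": hxy,
        "diff_avg": diff_avg,
        "diff_var": diff_var,
        "diff_entropy": diff_ent,
        "sum_avg": sum_avg,
        "sum_var": sum_var,
        "sum_entropy": sum_ent,
        "angular_second_moment": float((p ** 2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((k_diff * p).sum()),
        "inverse_difference": float((p / (1.0 + k_diff)).sum()),
        "inverse_difference_norm": float((p / (1.0 + k_diff / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + k_diff ** 2)).sum()),
        "inverse_difference_moment_norm": float((p / (1.0 + k_diff ** 2 / ng ** 2)).sum()),
        "inverse_variance": inv_var,
        "correlation": corr,
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "info_corr_1": ic1,
        "info_corr_2": ic2,
    }


# ---------------------------------------------------------------------------
# GLRLM


def run_length_matrix(labels: np.ndarray, n_levels: int,
                      direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix P(level, run length) for one direction.

    Voxels are grouped into lines parallel to the direction using the cross
    product of the voxel coordinate with the direction vector (constant
    along a line), sorted by position along the line, and run-length
    encoded.  Out-of-mask voxels (level 0) break runs.
    """
    idx = np.argwhere(labels > 0)
    max_run = max(labels.shape)
    m = np.zeros((n_levels, max_run), dtype=np.float64)
    if idx.size == 0:
        return m
    v = np.asarray(direction, dtype=np.int64)
    lev = labels[tuple(idx.T)]
    cross = np.cross(idx, v)  # constant along each line
    t = idx @ v  # strictly increasing along the line (step v.v)
    order = np.lexsort((t, cross[:, 2], cross[:, 1], cross[:, 0]))
    lev_s, t_s, cross_s = lev[order], t[order], cross[order]
    step = int(v @ v)
    same_line = np.all(cross_s[1:] == cross_s[:-1], axis=1)
    contiguous = (t_s[1:] - t_s[:-1]) == step
    same_level = lev_s[1:] == lev_s[:-1]
    cont = same_line & contiguous & same_level
    # run boundaries
    breaks = np.flatnonzero(~cont)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [lev_s.size - 1]))
    lengths = ends - starts + 1
    np.add.at(m, (lev_s[starts] - 1, lengths - 1), 1.0)
    return m


def _rlm_features(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = m.sum()
    if nr == 0:
        keys = ("sre lre lglre hglre srlgle srhgle lrlgle lrhgle gln glnn "
                "rln rlnn run_percentage gl_variance rl_variance run_entropy").split()
        return {k: np.nan for k in keys}
    i = np.arange(1, m.shape[0] + 1, dtype=np.float64)[:, None]
    r = np.arange(1, m.shape[1] + 1, dtype=np.float64)[None, :]
    p = m / nr
    ri = m.sum(axis=1)
    rj = m.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_r = float((r * p).sum())
    nzp = p[p > 0]
    return {
        "sre": float((m / r ** 2).sum() / nr),
        "lre": float((m * r ** 2).sum() / nr),
        "lglre": float((m / i ** 2).sum() / nr),
        "hglre": float((m * i ** 2).sum() / nr),
        "srlgle": float((m / (i ** 2 * r ** 2)).sum() / nr),
        "srhgle": float((m * i ** 2 / r ** 2).sum() / nr),
        "lrlgle": float((m * r ** 2 / i ** 2).sum() / nr),
        "lrhgle": float((m * i ** 2 * r ** 2).sum() / nr),
        "gln": float((ri ** 2).sum() / nr),
        "glnn": float((ri ** 2).sum() / nr ** 2),
        "rln": float((rj ** 2).sum() / nr),
        "rlnn": float((rj ** 2).sum() / nr ** 2),
        "run_percentage": float(nr / n_voxels),
        "gl_variance": float(((i - mu_i) ** 2 * p).sum()),
        "rl_variance": float(((r - mu_r) ** 2 * p).sum()),
        "run_entropy": float(-(nzp * np.log2(nzp)).sum()),
    }


def glrlm_features(labels: np.ndarray, n_levels: int) -> tuple[dict[str, float], dict[str, float]]:
    """Run-length features: (direction-averaged, merged-matrix) variants."""
    n_voxels = int((labels > 0).sum())
    mats = [run_length_matrix(labels, n_levels, d) for d in DIRECTIONS_13]
    per_dir = [_rlm_features(m, n_voxels) for m in mats if m.sum() > 0]
    if per_dir:
        averaged = _nanmean_dicts(per_dir)
    else:
        averaged = _rlm_features(np.zeros((n_levels, 1)), max(n_voxels, 1))
    merged = _rlm_features(sum(mats), n_voxels if n_voxels else 1)
    return averaged, merged


# ---------------------------------------------------------------------------
# GLSZM


def glszm_features(labels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Size-zone features; zones are 26-connected components of equal level."""
    zones: list[tuple[int, int]] = []  # (level, size)
    max_size = 1
    for g in range(1, n_levels + 1):
        comp, ncomp = ndimage.label(labels == g, structure=_STRUCT26)
        if ncomp:
            sizes = np.bincount(comp.ravel())[1:]
            for s in sizes:
                zones.append((g, int(s)))
            max_size = max(max_size, int(sizes.max()))
    keys = ("sae lae gln glnn szn sznn zone_percentage gl_variance "
            "zone_variance zone_entropy lglze hglze sahglze").split()
    if not zones:
        return {f"{k}": np.nan for k in keys}
    m = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, s in zones:
        m[g - 1, s - 1] += 1.0
    nz_total = m.sum()
    n_voxels = int((labels > 0).sum())
    i = np.arange(1, n_levels + 1, dtype=np.float64)[:, None]
    s = np.arange(1, max_size + 1, dtype=np.float64)[None, :]
    p = m / nz_total
    gi = m.sum(axis=1)
    sj = m.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_s = float((s * p).sum())
    nzp = p[p > 0]
    return {
        "sae": float((m / s ** 2).sum() / nz_total),
        "lae": float((m * s ** 2).sum() / nz_total),
        "gln": float((gi ** 2).sum() / nz_total),
        "glnn": float((gi ** 2).sum() / nz_total ** 2),
        "szn": float((sj ** 2).sum() / nz_total),
        "sznn": float((sj ** 2).sum() / nz_total ** 2),
        "zone_percentage": float(nz_total / n_voxels),
        "gl_variance": float(((i - mu_i) ** 2 * p).sum()),
        "zone_variance": float(((s - mu_s) ** 2 * p).sum()),
        "zone_entropy": float(-(nzp * np.log2(nzp)).sum()),
        "lglze": float((m / i ** 2).sum() / nz_total),
        "hglze": float((m * i ** 2).sum() / nz_total),
        "sahglze": float((m * i ** 2 / s ** 2).sum() / nz_total),
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_features(labels: np.ndarray, n_levels: int, alpha: int = 0) -> dict[str, float]:
    """Grey-level dependence features.

    A neighbour is *dependent* when its level differs from the centre by at
    most ``alpha``; dependence size is the dependent-neighbour count plus
    one (the centre).
    """
    inside = labels > 0
    dep = np.zeros(labels.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for off in (d, tuple(-c for c in d)):
            a, b = _shift_pairs(labels, off)
            ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
            # increment at the centre (source) position
            src = tuple(
                slice(0, s - o) if o >= 0 else slice(-o, s)
                for o, s in zip(off, labels.shape)
            )
            dep[src] += ok
    n = int(inside.sum())
    if n == 0:
        keys = ("sde lde gln dn dnn gl_variance dep_variance dep_entropy "
                "lgle hgle sdlgle sdhgle ldlgle ldhgle").split()
        return {k: np.nan for k in keys}
    lev = labels[inside]
    size = dep[inside] + 1
    max_dep = int(size.max())
    m = np.zeros((n_levels, max_dep), dtype=np.float64)
    np.add.at(m, (lev - 1, size - 1), 1.0)
    nd = m.sum()
    i = np.arange(1, n_levels + 1, dtype=np.float64)[:, None]
    j = np.arange(1, max_dep + 1, dtype=np.float64)[None, :]
    p = m / nd
    gi = m.sum(axis=1)
    dj = m.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    nzp = p[p > 0]
    return {
        "sde": float((m / j ** 2).sum() / nd),
        "lde": float((m * j ** 2).sum() / nd),
        "gln": float((gi ** 2).sum() / nd),
        "dn": float((dj ** 2).sum() / nd),
        "dnn": float((dj ** 2).sum() / nd ** 2),
        "gl_variance": float(((i - mu_i) ** 2 * p).sum()),
        "dep_variance": float(((j - mu_j) ** 2 * p).sum()),
        "dep_entropy": float(-(nzp * np.log2(nzp)).sum()),
        "lgle": float((m / i ** 2).sum() / nd),
        "hgle": float((m * i ** 2).sum() / nd),
        "sdlgle": float((m / (i ** 2 * j ** 2)).sum() / nd),
        "sdhgle": float((m * i ** 2 / j ** 2).sum() / nd),
        "ldlgle": float((m * j ** 2 / i ** 2).sum() / nd),
        "ldhgle": float((m * i ** 2 * j ** 2).sum() / nd),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(labels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Neighbourhood grey-tone difference features (coarseness, contrast,
    busyness, complexity, strength)."""
    inside = labels > 0
    vals = labels.astype(np.float64) * inside
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(inside.astype(np.float64), kernel,
                               mode="constant", cval=0.0)
    keys = ("ngtdm_coarseness ngtdm_contrast ngtdm_busyness "
            "ngtdm_complexity ngtdm_strength").split()
    valid = inside & (nb_cnt > 0)
    if not valid.any():
        return {k: np.nan for k in keys}
    nb_mean = nb_sum[valid] / nb_cnt[valid]
    lev = labels[valid]
    diff = np.abs(lev - nb_mean)
    s = np.zeros(n_levels)
    np.add.at(s, lev - 1, diff)
    n_i = np.bincount(lev, minlength=n_levels + 1)[1:].astype(np.float64)
    n_tot = n_i.sum()
    p = n_i / n_tot
    present = p > 0
    i = np.arange(1, n_levels + 1, dtype=np.float64)
    n_gp = int(present.sum())

    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if n_gp > 1:
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        ivals = i[present]
        di = ivals[:, None] - ivals[None, :]
        contrast = float((pi * pj * di ** 2).sum() / (n_gp * (n_gp - 1)) * s.sum() / n_tot)
        busy_den = float(np.abs(ivals[:, None] * pi - ivals[None, :] * pj).sum())
        busyness = ps / busy_den if busy_den > 0 else np.nan
        si = s[present]
        comp = float((np.abs(di) * (pi * si[:, None] + pj * si[None, :])
                      / (pi + pj)).sum() / n_tot)
        s_sum = float(s.sum())
        strength = float(((pi + pj) * di ** 2).sum() / s_sum) if s_sum > 0 else np.nan
    else:
        contrast = 0.0
        busyness = np.nan
        comp = 0.0
        strength = np.nan
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": comp,
        "ngtdm_strength": strength,
    }
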