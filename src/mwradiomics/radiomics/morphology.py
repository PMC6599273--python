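"""Morphology (shape) features of a binary mask.

Surface-based quantities use a marching-cubes mesh of the mask; axis
lengths come from the principal components of the voxel-centre point
cloud.  All lengths are in mm, areas in mm^2, volumes in mm^3.

Intensity-weighted centre-of-mass features weight each voxel by
``HU + 1024`` (attenuation above air) so that weights are positive for any
physical CT value; they are therefore *not* invariant under an artificial
HU offset, unlike the purely geometric features.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = ["morphology_features"]

_HU_AIR_OFFSET = 1024.0


def _mesh_surface_area(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    # light Gaussian smoothing before meshing suppresses the staircase
    # overestimate of marching cubes on hard binary masks
    from scipy import ndimage

    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 2), 0.8)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    except (ValueError, RuntimeError):
        return np.nan
    return float(measure.mesh_surface_area(verts, faces))


def morphology_features(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
) -> dict[str, float]:
    """The 38 morphology features (F50-F87)."""
    sp = np.asarray(spacing, dtype=np.float64)
    voxel_vol = float(np.prod(sp))
    idx = np.argwhere(mask)
    n = idx.shape[0]
    vol_mm3 = n * voxel_vol
    coords = idx * sp  # mm, (z, y, x)

    out: dict[str, float] = {
        "morph_volume_mm3": vol_mm3,
        "morph_volume_voxels": float(n),
    }

    surf = _mesh_surface_area(mask, tuple(sp)) if n > 0 else np.nan
    out["morph_surface_area_mm2"] = surf
    if np.isfinite(surf) and surf > 0 and vol_mm3 > 0:
        out["morph_surface_to_volume"] = surf / vol_mm3
        sphericity = (36.0 * np.pi * vol_mm3 ** 2) ** (1.0 / 3.0) / surf
        out["morph_sphericity"] = sphericity
        out["morph_compactness1"] = vol_mm3 / (np.sqrt(np.pi) * surf ** 1.5)
        out["morph_compactness2"] = 36.0 * np.pi * vol_mm3 ** 2 / surf ** 3
        out["morph_spherical_disproportion"] = 1.0 / sphericity
        out["morph_asphericity"] = (surf ** 3 / (36.0 * np.pi * vol_mm3 ** 2)) ** (1.0 / 3.0) - 1.0
    else:
        for k in ("morph_surface_to_volume", "morph_sphericity",
                  "morph_compactness1", "morph_compactness2",
                  "morph_spherical_disproportion", "morph_asphericity"):
            out[k] = np.nan

    # principal-component axis lengths (IBSI convention: 4*sqrt(eigenvalue))
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    if n >= 2:
        cov = centred.T @ centred / n
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        major, minor, least = (4.0 * np.sqrt(e) for e in eig)
        out.update({
            "morph_major_axis": major,
            "morph_minor_axis": minor,
            "morph_least_axis": least,
            "morph_elongation": np.sqrt(eig[1] / eig[0]) if eig[0] > 0 else np.nan,
            "morph_flatness": np.sqrt(eig[2] / eig[0]) if eig[0] > 0 else np.nan,
            "morph_pca_eig_major": float(eig[0]),
            "morph_pca_eig_minor": float(eig[1]),
            "morph_pca_eig_least": float(eig[2]),
        })
    else:
        for k in ("morph_major_axis", "morph_minor_axis", "morph_least_axis",
                  "morph_elongation", "morph_flatness", "morph_pca_eig_major",
                  "morph_pca_eig_minor", "morph_pca_eig_least"):
            out[k] = np.nan

    bbox_dims = (idx.max(axis=0) - idx.min(axis=0) + 1) * sp
    out["morph_bbox_dim_z"], out["morph_bbox_dim_y"], out["morph_bbox_dim_x"] = (
        float(d) for d in bbox_dims
    )
    bbox_vol = float(np.prod(bbox_dims))
    out["morph_bbox_volume"] = bbox_vol
    out["morph_extent"] = vol_mm3 / bbox_vol if bbox_vol > 0 else np.nan
    out["morph_equiv_sphere_diameter"] = 2.0 * (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)

    # convex hull (needs >= 4 non-coplanar points)
    try:
        hull = ConvexHull(coords)
        conv_vol = float(hull.volume)
        hull_pts = coords[hull.vertices]
        d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(-1)
        out["morph_max_diameter_3d"] = float(np.sqrt(d2.max()))
    except (QhullError, ValueError):
        conv_vol = np.nan
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1) if n <= 2000 else None
        out["morph_max_diameter_3d"] = float(np.sqrt(d2.max())) if d2 is not None else np.nan
    out["morph_convex_volume"] = conv_vol
    out["morph_solidity"] = vol_mm3 / conv_vol if conv_vol and conv_vol > 0 else np.nan

    out["morph_centroid_z"], out["morph_centroid_y"], out["morph_centroid_x"] = (
        float(c) for c in centroid
    )

    vals = np.asarray(volume, dtype=np.float64)[mask]
    out["morph_integrated_intensity"] = float(vals.mean() * vol_mm3)

    w = vals + _HU_AIR_OFFSET
    wsum = w.sum()
    if wsum > 0:
        wcom = (coords * w[:, None]).sum(axis=0) / wsum
    else:
        wcom = np.full(3, np.nan)
    out["morph_com_shift"] = float(np.linalg.norm(wcom - centroid))
    out["morph_wcom_x"] = float(wcom[2])
    out["morph_wcom_y"] = float(wcom[1])
    out["morph_wcom_z"] = float(wcom[0])

    radii = np.linalg.norm(centred, axis=1)
    out["morph_radius_mean"] = float(radii.mean())
    out["morph_radius_sd"] = float(radii.std())
    out["morph_radius_max"] = float(radii.max())

    # fraction of mask voxels with at least one 6-neighbour outside the mask
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    out["morph_border_fraction"] = float((n - eroded.sum()) / n) if n > 0 else np.nan
    return out
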