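"""Feature extraction facade: one call computes the full 364-entry vector."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .catalogue import CATALOGUE, FeatureCatalogue
from .firstorder import (discretize, hist_features, hist_gradient_features,
                         ivh_features, stat_features)
from .laws import laws_features
from .morphology import morphology_features
from .texture import (glcm_features, gldm_features, glrlm_features,
                      glszm_features, ngtdm_features)
from .wavelet import wavelet_features

__all__ = ["RadiomicsExtractor", "FeatureVector", "extract_all"]

#: margin (voxels) kept around the mask bounding box so that convolutional
#: features see their local context
_CROP_PAD = 8


@dataclass
class FeatureVector:
    """One extraction result: 364 named values for one mask role."""

    role: str
    values: pd.Series  # index = catalogue codes F1..F364
    names: tuple[str, ...]
    settings_digest: str
    n_missing: int = 0
    warnings: list[str] = field(default_factory=list)


class RadiomicsExtractor:
    """Deterministic 364-feature extractor (209 IBSI-style + 125 Laws +
    30 wavelet).

    Parameters
    ----------
    n_bins : fixed bin count for intensity discretization of the texture
        and histogram families (default 32 over the in-mask range).
    resample_isotropic : if True, trilinearly resample anisotropic input to
        1 mm isotropic voxels before extraction (masks resampled
        nearest-neighbour).  Off by default.
    catalogue : feature catalogue fixing names and order.
    """

    def __init__(self, n_bins: int = 32, resample_isotropic: bool = False,
                 catalogue: FeatureCatalogue = CATALOGUE):
        self.n_bins = int(n_bins)
        self.resample_isotropic = bool(resample_isotropic)
        self.catalogue = catalogue

    # -- public API ---------------------------------------------------------

    def extract(self, volume: np.ndarray, mask: np.ndarray,
                spacing: tuple[float, float, float],
                role: str = "lung_window") -> FeatureVector:
        """Extract all 364 features of ``volume`` restricted to ``mask``.

        An empty mask yields an all-missing vector with a warning; features
        undefined on degenerate masks (single voxel, bounding box below a
        family's minimum size) are missing (NaN).
        """
        vol = np.asarray(volume, dtype=np.float64)
        msk = np.asarray(mask, dtype=bool)
        if vol.shape != msk.shape:
            raise ValueError(f"volume {vol.shape} and mask {msk.shape} misaligned")
        sp = tuple(float(s) for s in spacing)
        warn_list: list[str] = []

        if not msk.any():
            warnings.warn("empty mask: emitting all-missing feature vector",
                          stacklevel=2)
            values = pd.Series(np.nan, index=list(self.catalogue.codes))
            return FeatureVector(role=role, values=values,
                                 names=self.catalogue.names,
                                 settings_digest=self._digest(),
                                 n_missing=len(values),
                                 warnings=["empty mask"])

        if self.resample_isotropic and len(set(sp)) > 1:
            zoom = np.asarray(sp) / 1.0
            vol = ndimage.zoom(vol, zoom, order=1)
            msk = ndimage.zoom(msk.astype(np.uint8), zoom, order=0).astype(bool)
            sp = (1.0, 1.0, 1.0)
            if not msk.any():
                msk = np.zeros(vol.shape, bool)

        vol_c, msk_c = _crop(vol, msk, _CROP_PAD)
        feats: dict[str, float] = {}

        vals = vol_c[msk_c]
        feats.update(stat_features(vals))
        feats.update(hist_features(vals, self.n_bins))
        feats.update(hist_gradient_features(vals, self.n_bins))
        feats.update(ivh_features(vals))
        feats.update(morphology_features(vol_c, msk_c, sp))

        labels = np.zeros(vol_c.shape, dtype=np.int64)
        labels[msk_c] = discretize(vals, self.n_bins)
        feats.update({f"glcm_d1_{k}": v for k, v in
                      glcm_features(labels, self.n_bins, distance=1).items()})
        feats.update({f"glcm_d2_{k}": v for k, v in
                      glcm_features(labels, self.n_bins, distance=2).items()})
        rlm_avg, rlm_merged = glrlm_features(labels, self.n_bins)
        feats.update({f"glrlm_{k}": v for k, v in rlm_avg.items()})
        feats.update({f"glrlm_merged_{k}": v for k, v in rlm_merged.items()})
        feats.update({f"glszm_{k}": v for k, v in
                      glszm_features(labels, self.n_bins).items()})
        feats.update({f"gldm_{k}": v for k, v in
                      gldm_features(labels, self.n_bins).items()})
        feats.update(ngtdm_features(labels, self.n_bins))

        feats.update(laws_features(vol_c, msk_c))
        feats.update(wavelet_features(vol_c, msk_c))

        feats["meta_voxel_dim_x"] = sp[2]
        feats["meta_voxel_dim_y"] = sp[1]
        feats["meta_voxel_dim_z"] = sp[0]
        feats["meta_voxel_volume"] = sp[0] * sp[1] * sp[2]

        ordered = [feats[name] for name in self.catalogue.names]
        values = pd.Series(ordered, index=list(self.catalogue.codes), dtype=float)
        n_missing = int(values.isna().sum())
        if n_missing:
            warn_list.append(f"{n_missing} features missing on degenerate input")
        return FeatureVector(role=role, values=values, names=self.catalogue.names,
                             settings_digest=self._digest(),
                             n_missing=n_missing, warnings=warn_list)

    # -- helpers ------------------------------------------------------------

    def _digest(self) -> str:
        key = f"bins={self.n_bins};resample={self.resample_isotropic};cat={self.catalogue.digest()}"
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def _crop(volume: np.ndarray, mask: np.ndarray, pad: int):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return volume[sl], mask[sl]


def extract_all(volume, mask: np.ndarray,
                catalogue: FeatureCatalogue = CATALOGUE,
                spacing: tuple[float, float, float] | None = None,
                role: str = "lung_window",
                n_bins: int = 32) -> FeatureVector:
    """Extract the full feature vector; thin wrapper over
    :class:`RadiomicsExtractor`.

    ``volume`` may be a :class:`~mwradiomics.phantoms.CTVolume` (spacing
    taken from it) or a plain array with ``spacing`` given.
    """
    data = getattr(volume, "data", volume)
    if spacing is None:
        spacing = getattr(volume, "spacing", None)
        if spacing is None:
            raise ValueError("spacing required when volume is a bare array")
    return RadiomicsExtractor(n_bins=n_bins, catalogue=catalogue).extract(
        data, mask, spacing, role=role)
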