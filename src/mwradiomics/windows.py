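"""CT window-level transforms and window-based nodule segmentation.

A CT *window* is the linear display mapping used by radiologists: HU values
below ``level - width/2`` render black, values above ``level + width/2``
render white.  Part-solid nodules look different under the two canonical
chest windows: the lung window (WW 1500 / WL -400) shows the whole lesion
including its ground-glass rim, while the mediastinal window (WW 400 /
WL 40) shows only the soft-tissue-density solid core.  Subtracting the
mediastinal-window mask from the lung-window mask yields the *difference
region* -- the non-solid habitat of the nodule.

Segmentation here is a deterministic threshold surrogate for radiologist
delineation: the 26-connected component of supra-threshold voxels grown
from a seed point, followed by one binary-closing pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "WindowSetting",
    "LUNG",
    "MEDIASTINAL",
    "NoduleMaskSet",
    "apply_window",
    "segment_window",
    "difference_region",
    "mask_volume",
    "build_mask_set",
]


@dataclass(frozen=True)
class WindowSetting:
    """A CT display window defined by width and level (both HU)."""

    width: float
    level: float
    #: HU threshold used by the segmentation surrogate; defaults to the
    #: window floor when not given.
    seg_threshold: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"window width must be positive, got {self.width}")

    @property
    def floor(self) -> float:
        return self.level - self.width / 2.0

    @property
    def ceiling(self) -> float:
        return self.level + self.width / 2.0

    @property
    def threshold(self) -> float:
        return self.floor if self.seg_threshold is None else self.seg_threshold


#: Standard lung window.  The -750 HU segmentation threshold captures
#: ground-glass opacity while excluding aerated parenchyma (~ -850 HU).
LUNG = WindowSetting(width=1500.0, level=-400.0, seg_threshold=-750.0, name="lung")

#: Standard mediastinal window.  The segmentation threshold is the window
#: floor (-160 HU): any tissue rendered non-black in this window.
MEDIASTINAL = WindowSetting(width=400.0, level=40.0, seg_threshold=-160.0, name="mediastinal")

# 26-connectivity in 3D and the closing structuring element (3x3x3 cube).
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def apply_window(volume: np.ndarray, setting: WindowSetting) -> np.ndarray:
    """Map an HU volume to display gray levels in [0, 1].

    ``display = clip((HU - floor) / width, 0, 1)``; monotone in HU.
    """
    vol = np.asarray(volume, dtype=np.float64)
    return np.clip((vol - setting.floor) / setting.width, 0.0, 1.0)


def segment_window(
    volume: np.ndarray,
    setting: WindowSetting,
    seed_point: tuple[int, int, int],
    threshold_override: float | None = None,
) -> np.ndarray:
    """Threshold-surrogate segmentation of one nodule under one window.

    Returns the 26-connected component of voxels with ``HU >= t`` that
    contains ``seed_point``, after one binary-closing pass with a 3x3x3
    structuring element.  An empty result (seed hyperintense but isolated
    after closing) is legitimate for purely ground-glass lesions under the
    mediastinal window and returns an all-False mask with a warning.

    Parameters
    ----------
    volume : HU array, axis order (z, y, x).
    setting : window whose segmentation threshold to use.
    seed_point : 0-based voxel index inside the nodule.
    threshold_override : replace the window's default threshold.
    """
    vol = np.asarray(volume)
    seed = tuple(int(c) for c in seed_point)
    if len(seed) != vol.ndim:
        raise ValueError("seed_point dimensionality does not match volume")
    if not all(0 <= c < s for c, s in zip(seed, vol.shape)):
        raise ValueError(f"seed point {seed} outside grid {vol.shape}")
    t = setting.threshold if threshold_override is None else float(threshold_override)
    above = vol >= t
    if not above[seed]:
        raise ValueError(
            f"seed not in nodule: voxel {seed} has HU {vol[seed]:.1f} < threshold {t:.1f}"
        )
    labels, _ = ndimage.label(above, structure=_STRUCT26)
    mask = labels == labels[seed]
    mask = ndimage.binary_closing(mask, structure=_STRUCT26)
    if not mask.any():
        warnings.warn("segmentation produced an empty mask after closing", stacklevel=2)
    return mask


def difference_region(lw_mask: np.ndarray, mw_mask: np.ndarray) -> np.ndarray:
    """Voxels in the lung-window mask but not the mediastinal-window mask."""
    lw = np.asarray(lw_mask, dtype=bool)
    mw = np.asarray(mw_mask, dtype=bool)
    if lw.shape != mw.shape:
        raise ValueError(f"mask shapes differ: {lw.shape} vs {mw.shape}")
    return lw & ~mw


def mask_volume(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Physical volume of a binary mask in mm^3 (voxel count x voxel volume)."""
    sp = np.asarray(spacing, dtype=float)
    if np.any(sp <= 0):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")
    return float(np.count_nonzero(mask) * np.prod(sp))


@dataclass
class NoduleMaskSet:
    """Aligned lung-window / mediastinal-window / difference-region masks."""

    lw_mask: np.ndarray
    mw_mask: np.ndarray
    dr_mask: np.ndarray
    seed_point: tuple[int, int, int]
    spacing: tuple[float, float, float]
    volumes_mm3: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.lw_mask.shape == self.mw_mask.shape == self.dr_mask.shape):
            raise ValueError("masks in a NoduleMaskSet must share one grid")
        if not self.volumes_mm3:
            self.volumes_mm3 = {
                "lung_window": mask_volume(self.lw_mask, self.spacing),
                "mediastinal_window": mask_volume(self.mw_mask, self.spacing),
                "difference_region": mask_volume(self.dr_mask, self.spacing),
            }


def build_mask_set(
    volume: np.ndarray,
    seed_point: tuple[int, int, int],
    spacing: tuple[float, float, float],
    lung: WindowSetting = LUNG,
    mediastinal: WindowSetting = MEDIASTINAL,
) -> NoduleMaskSet:
    """Segment one nodule under both windows and derive the difference region.

    With the default thresholds (-160 > -750) the mediastinal mask is nested
    inside the lung-window component before closing, so
    ``|DR| = |LW| - |MW|`` holds up to closing effects and exactly
    ``|DR| = |LW| - |LW & MW|`` always.
    """
    lw = segment_window(volume, lung, seed_point)
    vol = np.asarray(volume)
    if vol[tuple(int(c) for c in seed_point)] >= mediastinal.threshold:
        mw = segment_window(volume, mediastinal, seed_point)
    else:
        # Purely ground-glass at the seed: the solid core may still exist
        # elsewhere in the lung-window component; take supra-threshold
        # voxels inside it.
        above = (vol >= mediastinal.threshold) & lw
        if above.any():
            labels, _ = ndimage.label(above, structure=_STRUCT26)
            # largest solid component inside the lesion
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            mw = labels == int(np.argmax(counts))
            mw = ndimage.binary_closing(mw, structure=_STRUCT26)
        else:
            mw = np.zeros_like(lw)
    # enforce nesting so the difference-region identity is exact
    mw = mw & lw
    dr = difference_region(lw, mw)
    return NoduleMaskSet(lw_mask=lw, mw_mask=mw, dr_mask=dr, seed_point=tuple(seed_point), spacing=tuple(spacing))
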