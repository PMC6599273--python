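"""Laws texture-energy features.

The five classical 1D kernels (Level, Edge, Spot, Wave, Ripple)

    L5 = [ 1,  4, 6,  4,  1]
    E5 = [-1, -2, 0,  2,  1]
    S5 = [-1,  0, 2,  0, -1]
    W5 = [-1,  2, 0, -2,  1]
    R5 = [ 1, -4, 6, -4,  1]

combine into 5^3 = 125 separable 3D filters, applied along (z, y, x).  The
feature for each filter is the texture energy: the mean absolute filter
response over the mask voxels.  Every kernel except L5 sums to zero, so
the 124 filters containing at least one non-L5 factor vanish on constant
volumes and are invariant to an additive intensity offset.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

__all__ = ["KERNELS_1D", "laws_features"]

KERNELS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

_ORDER = ("L5", "E5", "S5", "W5", "R5")


def laws_features(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """All 125 Laws texture energies over the mask.

    Requires the mask bounding box to span at least 5 voxels per axis;
    otherwise every feature is missing (NaN).
    """
    mask = np.asarray(mask, dtype=bool)
    names = [f"laws_{a}{b}{c}" for a, b, c in itertools.product(_ORDER, repeat=3)]
    if not mask.any():
        return {n: np.nan for n in names}
    idx = np.argwhere(mask)
    span = idx.max(axis=0) - idx.min(axis=0) + 1
    if span.min() < 5:
        return {n: np.nan for n in names}
    vol = np.asarray(volume, dtype=np.float64)
    # pre-filter along z for each kernel, reuse across the 25 (y, x) combos
    out: dict[str, float] = {}
    zf = {k: ndimage.correlate1d(vol, KERNELS_1D[k], axis=0, mode="reflect")
          for k in _ORDER}
    for a in _ORDER:
        for b in _ORDER:
            yf = ndimage.correlate1d(zf[a], KERNELS_1D[b], axis=1, mode="reflect")
            for c in _ORDER:
                resp = ndimage.correlate1d(yf, KERNELS_1D[c], axis=2, mode="reflect")
                out[f"laws_{a}{b}{c}"] = float(np.abs(resp[mask]).mean())
    return out
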