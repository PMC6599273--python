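"""Wavelet sub-band features.

A two-level 3D stationary (undecimated) wavelet decomposition with the
orthogonal ``coif1`` wavelet and variance-preserving normalization.  The
undecimated transform keeps every sub-band on the original voxel grid, so
in-mask restriction needs no coefficient resampling, and with ``norm=True``
the sum of squared coefficients over all 15 sub-bands (7 level-1 details,
the level-2 approximation, 7 level-2 details) equals the input energy
exactly (Parseval).

Per sub-band two features are emitted: *energy* (mean squared coefficient
over mask voxels) and *entropy* (Shannon entropy, base 2, of the in-mask
squared-coefficient distribution).
"""

from __future__ import annotations

import numpy as np
import pywt

from .catalogue import WAVELET_SUBBANDS

__all__ = ["wavelet_features", "wavelet_subbands"]

_DETAIL_KEYS = ("aad", "ada", "add", "daa", "dad", "dda", "ddd")


def _pad_to_multiple(a: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[slice, ...]]:
    pads, sls = [], []
    for s in a.shape:
        target = max(mult * int(np.ceil(s / mult)), mult * 2)
        extra = target - s
        lo = extra // 2
        hi = extra - lo
        pads.append((lo, hi))
        sls.append(slice(lo, lo + s))
    return np.pad(a, pads, mode="symmetric"), tuple(sls)


def wavelet_subbands(volume: np.ndarray, wavelet: str = "coif1",
                     level: int = 2) -> dict[tuple[str, str], np.ndarray]:
    """The 15 stationary-wavelet sub-bands, each aligned to the input grid."""
    vol = np.asarray(volume, dtype=np.float64)
    padded, sls = _pad_to_multiple(vol, 2 ** level)
    coeffs = pywt.swtn(padded, wavelet, level=level, norm=True, trim_approx=True)
    # coeffs = [approx_L2, {details L2}, {details L1}]
    out: dict[tuple[str, str], np.ndarray] = {}
    for k in _DETAIL_KEYS:
        out[("L1", k)] = coeffs[2][k][sls]
    out[("L2", "aaa")] = coeffs[0][sls]
    for k in _DETAIL_KEYS:
        out[("L2", k)] = coeffs[1][k][sls]
    return out


def wavelet_features(volume: np.ndarray, mask: np.ndarray,
                     wavelet: str = "coif1") -> dict[str, float]:
    """The 30 wavelet features (energy + entropy per sub-band, F267-F296).

    Requires the mask bounding box to span at least 8 voxels per axis;
    otherwise every feature is missing (NaN).
    """
    mask = np.asarray(mask, dtype=bool)
    names = [f"wav_{lev}_{band}_{what}"
             for lev, band in WAVELET_SUBBANDS for what in ("energy", "entropy")]
    if not mask.any():
        return {n: np.nan for n in names}
    idx = np.argwhere(mask)
    span = idx.max(axis=0) - idx.min(axis=0) + 1
    if span.min() < 8:
        return {n: np.nan for n in names}
    bands = wavelet_subbands(volume, wavelet=wavelet)
    out: dict[str, float] = {}
    for lev, band in WAVELET_SUBBANDS:
        c2 = bands[(lev, band)][mask] ** 2
        energy = float(c2.mean())
        total = c2.sum()
        if total > 0:
            p = c2 / total
            p = p[p > 0]
            entropy = float(-(p * np.log2(p)).sum())
        else:
            entropy = 0.0
        out[f"wav_{lev}_{band}_energy"] = energy
        out[f"wav_{lev}_{band}_entropy"] = entropy
    return out
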