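"""The fixed 364-entry feature catalogue.

The extractor emits exactly 364 features per mask: 209 IBSI-style
(first-order statistics, intensity histogram, intensity-volume histogram,
morphology, grey-level co-occurrence / run-length / size-zone / dependence
/ neighbourhood-tone matrices, and grid metadata), 125 Laws texture
energies (all 5^3 separable 3D filters), and 30 wavelet sub-band features
(energy and entropy of the 15 sub-bands of a two-level stationary 3D
decomposition).

The ordering is contractual: feature ``F<i>`` never changes meaning across
versions.  Fixed anchor indices:

* F8   -- statistical 10th percentile
* F19  -- root mean square
* F44  -- volume at intensity fraction 90 (IVH)
* F87  -- intensity-weighted centre of mass, z
* F296 -- a level-2 wavelet sub-band feature (entropy of the L2 ddd band)
* F311 -- voxel dimension x
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

__all__ = ["FeatureDescriptor", "FeatureCatalogue", "build_catalogue", "CATALOGUE"]


@dataclass(frozen=True)
class FeatureDescriptor:
    index: int  # 1-based position in the catalogue
    family: str  # ibsi | laws | wavelet
    name: str

    @property
    def code(self) -> str:
        return f"F{self.index}"


_STAT = [
    "stat_mean", "stat_variance", "stat_skewness", "stat_kurtosis",
    "stat_median", "stat_minimum", "stat_maximum", "stat_p10",
    "stat_p25", "stat_p75", "stat_p90", "stat_iqr", "stat_range",
    "stat_mean_abs_dev", "stat_robust_mean_abs_dev", "stat_median_abs_dev",
    "stat_coeff_variation", "stat_quartile_coeff_dispersion", "stat_rms",
    "stat_energy", "stat_sd", "stat_sum", "stat_p5", "stat_p95",
    "stat_decile_range",
]

_HIST = [
    "hist_mean", "hist_variance", "hist_skewness", "hist_kurtosis",
    "hist_median", "hist_mode", "hist_p10", "hist_p90", "hist_iqr",
    "hist_range", "hist_mean_abs_dev", "hist_coeff_variation",
    "hist_entropy", "hist_uniformity", "hist_quartile_coeff_dispersion",
]

_IVH = [
    "ivh_vol_frac_10", "ivh_vol_frac_25", "ivh_vol_frac_50",
    "ivh_vol_frac_90",  # F44: volume at intensity fraction 90
    "ivh_int_frac_10", "ivh_int_frac_25", "ivh_int_frac_50",
    "ivh_int_frac_90", "ivh_auc",
]

_MORPH = [
    "morph_volume_mm3", "morph_volume_voxels", "morph_surface_area_mm2",
    "morph_surface_to_volume", "morph_sphericity", "morph_compactness1",
    "morph_compactness2", "morph_spherical_disproportion",
    "morph_asphericity", "morph_max_diameter_3d", "morph_major_axis",
    "morph_minor_axis", "morph_least_axis", "morph_elongation",
    "morph_flatness", "morph_pca_eig_major", "morph_pca_eig_minor",
    "morph_pca_eig_least", "morph_bbox_dim_z", "morph_bbox_dim_y",
    "morph_bbox_dim_x", "morph_bbox_volume", "morph_extent",
    "morph_equiv_sphere_diameter", "morph_convex_volume", "morph_solidity",
    "morph_centroid_z", "morph_centroid_y", "morph_centroid_x",
    "morph_integrated_intensity", "morph_com_shift", "morph_radius_mean",
    "morph_radius_sd", "morph_radius_max", "morph_border_fraction",
    "morph_wcom_x", "morph_wcom_y",
    "morph_wcom_z",  # F87: intensity-weighted centre of mass, z
]

_GLCM = [
    "joint_max", "joint_avg", "joint_var", "joint_entropy",
    "diff_avg", "diff_var", "diff_entropy",
    "sum_avg", "sum_var", "sum_entropy",
    "angular_second_moment", "contrast", "dissimilarity",
    "inverse_difference", "inverse_difference_norm",
    "inverse_difference_moment", "inverse_difference_moment_norm",
    "inverse_variance", "correlation", "autocorrelation",
    "cluster_tendency", "cluster_shade", "cluster_prominence",
    "info_corr_1", "info_corr_2",
]

_GLRLM = [
    "sre", "lre", "lglre", "hglre", "srlgle", "srhgle", "lrlgle",
    "lrhgle", "gln", "glnn", "rln", "rlnn", "run_percentage",
    "gl_variance", "rl_variance", "run_entropy",
]

_GLSZM = [
    "sae", "lae", "gln", "glnn", "szn", "sznn", "zone_percentage",
    "gl_variance", "zone_variance", "zone_entropy", "lglze", "hglze",
    "sahglze",
]

_GLDM = [
    "sde", "lde", "gln", "dn", "dnn", "gl_variance", "dep_variance",
    "dep_entropy", "lgle", "hgle", "sdlgle", "sdhgle", "ldlgle", "ldhgle",
]

_META = ["meta_voxel_dim_x", "meta_voxel_dim_y", "meta_voxel_dim_z",
         "meta_voxel_volume"]

_NGTDM = ["ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
          "ngtdm_complexity", "ngtdm_strength"]

_HIST_GRAD = ["hist_max_gradient", "hist_max_gradient_intensity",
              "hist_min_gradient", "hist_min_gradient_intensity"]

#: 1D Laws kernel names; the 125 filters are all ordered triples applied
#: along (z, y, x)
LAWS_KERNELS = ("L5", "E5", "S5", "W5", "R5")
_LAWS = [f"laws_{a}{b}{c}" for a, b, c in itertools.product(LAWS_KERNELS, repeat=3)]

#: wavelet sub-band order: level-1 detail bands, level-2 approximation,
#: level-2 detail bands; per band energy then entropy
WAVELET_SUBBANDS = (
    [("L1", k) for k in ("aad", "ada", "add", "daa", "dad", "dda", "ddd")]
    + [("L2", "aaa")]
    + [("L2", k) for k in ("aad", "ada", "add", "daa", "dad", "dda", "ddd")]
)
_WAVELET = [
    f"wav_{lev}_{band}_{what}"
    for lev, band in WAVELET_SUBBANDS
    for what in ("energy", "entropy")
]


class FeatureCatalogue:
    """Ordered, immutable list of the 364 feature descriptors."""

    def __init__(self, descriptors: list[FeatureDescriptor]):
        self.descriptors = tuple(descriptors)
        self.names = tuple(d.name for d in self.descriptors)
        self.codes = tuple(d.code for d in self.descriptors)
        self._by_code = {d.code: d for d in self.descriptors}
        self._by_name = {d.name: d for d in self.descriptors}

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, code: str) -> FeatureDescriptor:
        return self._by_code.get(code) or self._by_name[code]

    def family_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.descriptors:
            out[d.family] = out.get(d.family, 0) + 1
        return out

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256("\n".join(self.names).encode())
        return h.hexdigest()[:16]


def build_catalogue() -> FeatureCatalogue:
    blocks: list[tuple[str, list[str]]] = [
        ("ibsi", _STAT),                                  # F1-F25
        ("ibsi", _HIST),                                  # F26-F40
        ("ibsi", _IVH),                                   # F41-F49
        ("ibsi", _MORPH),                                 # F50-F87
        ("ibsi", [f"glcm_d1_{n}" for n in _GLCM]),        # F88-F112
        ("ibsi", [f"glrlm_{n}" for n in _GLRLM]),         # F113-F128
        ("ibsi", [f"glszm_{n}" for n in _GLSZM]),         # F129-F141
        ("laws", _LAWS),                                  # F142-F266
        ("wavelet", _WAVELET),                            # F267-F296
        ("ibsi", [f"gldm_{n}" for n in _GLDM]),           # F297-F310
        ("ibsi", _META),                                  # F311-F314
        ("ibsi", _NGTDM),                                 # F315-F319
        ("ibsi", [f"glcm_d2_{n}" for n in _GLCM]),        # F320-F344
        ("ibsi", [f"glrlm_merged_{n}" for n in _GLRLM]),  # F345-F360
        ("ibsi", _HIST_GRAD),                             # F361-F364
    ]
    descriptors = []
    i = 1
    for family, names in blocks:
        for name in names:
            descriptors.append(FeatureDescriptor(index=i, family=family, name=name))
            i += 1
    cat = FeatureCatalogue(descriptors)
    counts = cat.family_counts()
    assert len(cat) == 364, len(cat)
    assert counts == {"ibsi": 209, "laws": 125, "wavelet": 30}, counts
    assert cat["F8"].name == "stat_p10"
    assert cat["F19"].name == "stat_rms"
    assert cat["F44"].name == "ivh_vol_frac_90"
    assert cat["F87"].name == "morph_wcom_z"
    assert cat["F296"].name.startswith("wav_L2_")
    assert cat["F311"].name == "meta_voxel_dim_x"
    return cat


#: the shipped catalogue instance
CATALOGUE = build_catalogue()
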