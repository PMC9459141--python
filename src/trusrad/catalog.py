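"""The 851-descriptor radiomics catalog.

The catalog enumerates every feature the extraction protocol defines: seven
feature classes on the original image (shape 14, first-order 18, GLCM 24,
GLDM 14, GLRLM 16, GLSZM 16, NGTDM 5 = 107 descriptors) and the seven
non-shape classes replicated over the eight single-level wavelet sub-bands
(93 x 8 = 744), for 851 in total. Shape features are geometry of the mask,
so they exist only for the original image.

Only the descriptors in the selected signature (see
:mod:`trusrad.texture`) have numeric implementations; the rest are
catalogued so that tables can be schema-validated and unimplemented
requests fail loudly instead of silently returning numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

ORIGINAL = "original"
#: Sub-band keys: letter i is the filter applied along axis i
#: (L = low-pass, H = high-pass).
WAVELET_SUBBANDS = ("LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH", "LLL")

IMAGE_TYPES = (ORIGINAL,) + tuple(f"wavelet-{b}" for b in WAVELET_SUBBANDS)

SHAPE_FEATURES = (
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
)

FIRSTORDER_FEATURES = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "TotalEnergy", "Uniformity", "Variance",
)

GLCM_FEATURES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

GLDM_FEATURES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

GLRLM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)

NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "gldm": GLDM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """One catalogued radiomics descriptor.

    ``image_type`` is ``"original"`` or ``"wavelet-XXX"``; ``feature_class``
    one of the seven class identifiers; ``name`` the feature identifier
    within its class. Shape descriptors occur only with the original image.
    """

    image_type: str
    feature_class: str
    name: str

    def __post_init__(self) -> None:
        if self.image_type not in IMAGE_TYPES:
            raise ValueError(f"unknown image type {self.image_type!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.name not in FEATURE_CLASSES[self.feature_class]:
            raise ValueError(
                f"{self.name!r} is not a {self.feature_class} feature"
            )
        if self.feature_class == "shape" and self.image_type != ORIGINAL:
            raise ValueError("shape features exist only for the original image")

    @property
    def key(self) -> str:
        """Column-name form, e.g. ``wavelet-HHH_glszm_ZoneEntropy``."""
        return f"{self.image_type}_{self.feature_class}_{self.name}"


def catalog_features(image_types: tuple[str, ...] = IMAGE_TYPES) -> list[FeatureDescriptor]:
    """Enumerate the full descriptor catalog, optionally restricted.

    With the default image types this returns exactly 851 descriptors:
    107 on the original image and 93 per wavelet sub-band. Restricting to
    ``("original",)`` yields the 107 original-image descriptors.
    """
    out: list[FeatureDescriptor] = []
    for itype in image_types:
        for fclass, names in FEATURE_CLASSES.items():
            if fclass == "shape" and itype != ORIGINAL:
                continue
            out.extend(FeatureDescriptor(itype, fclass, n) for n in names)
    return out


def parse_key(key: str) -> FeatureDescriptor:
    """Parse a column name like ``original_firstorder_Range`` back into a
    descriptor, validating it against the catalog."""
    parts = key.split("_")
    if len(parts) != 3:
        raise ValueError(f"feature key {key!r} is not image-type_class_name")
    return FeatureDescriptor(parts[0], parts[1], parts[2])
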