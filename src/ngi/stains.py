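"""Beer–Lambert optical-density conversion and two-stain colour deconvolution.

Chromogenic IHC slides carry two dyes: a brown chromogen (AEC or DAB) marking
antibody binding and a blue hematoxylin counterstain marking nuclei.  Stain
amounts add linearly in optical density, OD = -log10(I/I0), so each pixel's
3-channel OD vector is (to first order) a non-negative combination of the two
stain OD vectors.  Unmixing is a per-pixel least-squares projection onto that
two-vector basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Hard ceiling on optical density; 8-bit images cannot resolve more.
OD_MAX = 3.0

MARKER_PANEL = ("Foxp3", "CD3", "CD8", "CD4", "Ki67", "CK")

# Published stain OD vectors (Ruifrok & Johnston colour-deconvolution set),
# normalised to unit length below.
_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.268, 0.570, 0.776)
_AEC = (0.274, 0.679, 0.680)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainBasis:
    """Pair of unit OD vectors spanning the chromogen/counterstain plane."""

    chromogen: np.ndarray
    hematoxylin: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "chromogen", _unit(self.chromogen))
        object.__setattr__(self, "hematoxylin", _unit(self.hematoxylin))
        if self.angle_deg <= 10.0:
            raise ValueError(
                f"stain vectors nearly collinear (angle {self.angle_deg:.2f} deg <= 10)"
            )

    @property
    def angle_deg(self) -> float:
        c = float(np.clip(np.dot(self.chromogen, self.hematoxylin), -1.0, 1.0))
        return float(np.degrees(np.arccos(c)))

    @property
    def matrix(self) -> np.ndarray:
        """3x2 mixing matrix with columns (chromogen, hematoxylin)."""
        return np.stack([self.chromogen, self.hematoxylin], axis=1)

    @classmethod
    def dab_hematoxylin(cls) -> "StainBasis":
        return cls(_DAB, _HEMATOXYLIN)

    @classmethod
    def aec_hematoxylin(cls) -> "StainBasis":
        return cls(_AEC, _HEMATOXYLIN)

    @classmethod
    def named(cls, name: str) -> "StainBasis":
        try:
            return {"dab": cls.dab_hematoxylin, "aec": cls.aec_hematoxylin}[name.lower()]()
        except KeyError:
            raise ValueError(f"unknown stain basis {name!r}; use 'dab' or 'aec'") from None


@dataclass
class StainRoundImage:
    """One digitised single-stain round: RGB pixels plus acquisition metadata."""

    marker_name: str
    rgb_pixels: np.ndarray  # H x W x 3, uint8 (or float pre-quantisation)
    pixel_size_um: float
    round_index: int = 1

    def __post_init__(self):
        if self.marker_name not in MARKER_PANEL:
            raise ValueError(f"unknown marker {self.marker_name!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.rgb_pixels.ndim != 3 or self.rgb_pixels.shape[2] != 3:
            raise ValueError("rgb_pixels must be H x W x 3")

    @property
    def shape(self) -> tuple:
        return self.rgb_pixels.shape[:2]


@dataclass
class OpticalDensityMaps:
    """Unmixed per-pixel stain amounts (both maps non-negative, NaN-free)."""

    chromogen_od: np.ndarray
    hematoxylin_od: np.ndarray

    def __post_init__(self):
        for m in (self.chromogen_od, self.hematoxylin_od):
            if np.isnan(m).any():
                raise ValueError("OD map contains NaN")


def estimate_background(rgb: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Per-channel white point: a high percentile of the image intensities.

    Robust stand-in for a calibration target on slides that are mostly glass.
    """
    return np.percentile(rgb.reshape(-1, 3).astype(float), percentile, axis=0)


def rgb_to_od(rgb: np.ndarray, background=None, od_max: float = OD_MAX) -> np.ndarray:
    """Convert 8-bit RGB to per-channel optical density.

    OD_c = -log10((I_c + 1) / (background_c + 1)), clipped to [0, od_max].
    The +1 pseudo-count keeps zero intensities finite.
    """
    rgb = np.asarray(rgb, dtype=float)
    if background is None:
        background = estimate_background(rgb)
    background = np.broadcast_to(np.asarray(background, dtype=float), (3,))
    if np.any(background <= 0):
        raise ValueError("background intensity must be positive")
    od = -np.log10((rgb + 1.0) / (background + 1.0))
    return np.clip(od, 0.0, od_max)


def od_to_rgb(od: np.ndarray, background=None) -> np.ndarray:
    """Inverse Beer–Lambert: OD back to (float) transmitted intensities."""
    if background is None:
        background = np.array([255.0, 255.0, 255.0])
    background = np.broadcast_to(np.asarray(background, dtype=float), (3,))
    return (background + 1.0) * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0


def mix_stains(chromogen_od: np.ndarray, hematoxylin_od: np.ndarray,
               basis: StainBasis) -> np.ndarray:
    """Forward model: scalar stain amounts to a 3-channel OD image."""
    c = np.asarray(chromogen_od, dtype=float)
    h = np.asarray(hematoxylin_od, dtype=float)
    return c[..., None] * basis.chromogen + h[..., None] * basis.hematoxylin


def separate_stains(od: np.ndarray, basis: StainBasis,
                    od_max: float = OD_MAX) -> OpticalDensityMaps:
    """Least-squares unmix of a 3-channel OD image into two stain maps.

    Each pixel's OD vector is projected onto the basis plane; negative
    coefficients (physically meaningless) are clipped to zero and the residual
    off-plane component is discarded.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim < 1 or od.shape[-1] != 3:
        raise ValueError("expected a (..., 3) OD array")
    pinv = np.linalg.pinv(basis.matrix)  # 2 x 3
    coef = od @ pinv.T
    coef = np.clip(coef, 0.0, od_max)
    return OpticalDensityMaps(chromogen_od=coef[..., 0], hematoxylin_od=coef[..., 1])
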