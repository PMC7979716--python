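"""Virtual multiplexed image: unmixed, co-registered per-marker OD maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .registration import RoundTransform, apply_transform
from .stains import OD_MAX, StainBasis, StainRoundImage, rgb_to_od, separate_stains


@dataclass
class VirtualMultiplexImage:
    """Fusion of all stain rounds onto one pixel grid.

    ``marker_od`` holds one chromogen OD map per marker; ``hematoxylin_od`` is
    the reference round's counterstain map (used for nucleus detection).
    ``valid_mask`` is the intersection of the warped round footprints — only
    pixels seen by every round are analysed.
    """

    marker_od: dict[str, np.ndarray]
    hematoxylin_od: np.ndarray
    pixel_size_um: float
    transforms: dict[str, RoundTransform]
    valid_mask: np.ndarray

    def __post_init__(self):
        shp = self.hematoxylin_od.shape
        for name, m in self.marker_od.items():
            if m.shape != shp:
                raise ValueError(f"marker map {name} shape {m.shape} != {shp}")
            if np.isnan(m).any():
                raise ValueError(f"marker map {name} contains NaN")
        if self.valid_mask.shape != shp:
            raise ValueError("valid_mask shape mismatch")

    @property
    def shape(self) -> tuple:
        return self.hematoxylin_od.shape

    @property
    def markers(self) -> list[str]:
        return list(self.marker_od)


def build_vdi(rounds: Sequence[StainRoundImage],
              transforms: Sequence[RoundTransform],
              basis: StainBasis,
              reference_marker: str | None = None) -> VirtualMultiplexImage:
    """Unmix each round, warp it into the reference frame and stack by marker.

    OD maps are resampled bilinearly; footprints with nearest-neighbour logic
    (a pixel is valid only if fully covered by the warped round).
    """
    if len(rounds) != len(transforms):
        raise ValueError("one transform per round required")
    shapes = {r.shape for r in rounds}
    if len(shapes) != 1:
        raise ValueError("all rounds must share one shape")
    shape = shapes.pop()

    if reference_marker is None:
        ref_i = next((i for i, t in enumerate(transforms) if t.is_identity(1e-6)), 0)
    else:
        ref_i = [r.marker_name for r in rounds].index(reference_marker)

    marker_od: dict[str, np.ndarray] = {}
    tf: dict[str, RoundTransform] = {}
    valid = np.ones(shape, dtype=bool)
    hema_ref = None
    ones = np.ones(shape, dtype=float)

    for i, (rnd, t) in enumerate(zip(rounds, transforms)):
        od = rgb_to_od(rnd.rgb_pixels)
        maps = separate_stains(od, basis)
        chrom = np.clip(apply_transform(maps.chromogen_od, t), 0.0, OD_MAX)
        foot = apply_transform(ones, t) > 0.999
        marker_od[rnd.marker_name] = chrom
        tf[rnd.marker_name] = t
        valid &= foot
        if i == ref_i:
            hema_ref = np.clip(apply_transform(maps.hematoxylin_od, t), 0.0, OD_MAX)

    return VirtualMultiplexImage(
        marker_od=marker_od,
        hematoxylin_od=hema_ref,
        pixel_size_um=rounds[0].pixel_size_um,
        transforms=tf,
        valid_mask=valid,
    )
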