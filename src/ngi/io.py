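"""Reading and writing the pipeline's on-disk artefacts.

Single-stain rounds are 8-bit RGB TIFF/PNG, one file per marker; the fused
virtual multiplexed image persists as a multi-page 32-bit float TIFF with
marker names in page metadata; transforms as JSON; zone masks as labelled
8-bit PNG (0 outside ROI, 1/2/3 for zones A/B/C).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .registration import RoundTransform
from .stains import MARKER_PANEL, StainRoundImage
from .vdi import VirtualMultiplexImage
from .zones import RegionMasks


def write_round(path, image: StainRoundImage):
    rgb = np.asarray(image.rgb_pixels)
    if rgb.dtype != np.uint8:
        rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb, metadata={
            "marker": image.marker_name,
            "pixel_size_um": image.pixel_size_um,
            "round_index": image.round_index,
        })
    else:
        iio.imwrite(path, rgb)


def read_round(path, marker: str, pixel_size_um: float,
               round_index: int | None = None) -> StainRoundImage:
    rgb = iio.imread(path)
    if rgb.ndim == 3 and rgb.shape[2] == 4:
        rgb = rgb[..., :3]
    if round_index is None:
        round_index = MARKER_PANEL.index(marker) + 1
    return StainRoundImage(marker_name=marker, rgb_pixels=np.asarray(rgb),
                           pixel_size_um=pixel_size_um, round_index=round_index)


def read_sample_dir(directory, pixel_size_um: float) -> list[StainRoundImage]:
    """Read one round per panel marker from ``<marker>.tiff`` (or .tif/.png)."""
    directory = Path(directory)
    rounds = []
    for i, marker in enumerate(MARKER_PANEL):
        for ext in (".tiff", ".tif", ".png"):
            p = directory / f"{marker}{ext}"
            if p.exists():
                rounds.append(read_round(p, marker, pixel_size_um, i + 1))
                break
        else:
            raise FileNotFoundError(f"no image for marker {marker} in {directory}")
    return rounds


def write_transforms(path, transforms: dict[str, RoundTransform] | list,
                     markers: list[str] | None = None):
    if isinstance(transforms, list):
        transforms = dict(zip(markers or MARKER_PANEL, transforms))
    payload = {m: t.to_dict() for m, t in transforms.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_transforms(path) -> dict[str, RoundTransform]:
    payload = json.loads(Path(path).read_text())
    return {m: RoundTransform.from_dict(d) for m, d in payload.items()}


def write_vdi(path, vdi: VirtualMultiplexImage):
    pages = [vdi.hematoxylin_od.astype(np.float32)]
    names = ["hematoxylin"]
    for m, arr in vdi.marker_od.items():
        pages.append(arr.astype(np.float32))
        names.append(m)
    tifffile.imwrite(path, np.stack(pages), metadata={
        "markers": names, "pixel_size_um": vdi.pixel_size_um,
    })


def write_zone_masks(path, masks: RegionMasks):
    iio.imwrite(Path(path), masks.label_image)


def write_ground_truth(path, ground_truth):
    ground_truth.cells.to_csv(path, index=False)
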