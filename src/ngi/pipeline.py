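"""End-to-end single-sample analysis: rounds in, metrics out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import SampleMetrics, compute_sample_metrics, qc_filter
from .phenotyping import NucleusParams, detect_nuclei, phenotype_cells
from .registration import RoundTransform, register_rounds
from .stains import StainBasis, StainRoundImage
from .vdi import VirtualMultiplexImage, build_vdi
from .zones import (RegionMasks, ZoneAreas, assign_cells_to_zones,
                    build_tumor_mask, detect_tissue_roi, partition_zones)


def _default_thresholds() -> dict:
    from .phenotyping import DEFAULT_THRESHOLD_OD
    from .stains import MARKER_PANEL
    return {m: DEFAULT_THRESHOLD_OD for m in MARKER_PANEL}


@dataclass
class PipelineConfig:
    stain_basis: str = "dab"
    reference_marker: str = "Foxp3"  # first round in the staining order
    thresholds: dict = field(default_factory=_default_thresholds)
    ring_width_um: float = 1.5
    ck_dilation_um: float = 2.0
    nucleus: NucleusParams = field(default_factory=NucleusParams)
    ck_mask_threshold: float = 0.2
    ck_min_object_area_um2: float = 200.0
    ck_fill_holes: bool = True
    band_width_um: float = 30.0
    min_roi_area_um2: float = 100_000.0

    @property
    def basis(self) -> StainBasis:
        return StainBasis.named(self.stain_basis)


@dataclass
class SampleResult:
    vdi: VirtualMultiplexImage
    transforms: list[RoundTransform]
    cells: pd.DataFrame
    masks: RegionMasks
    areas: ZoneAreas
    metrics: SampleMetrics


def run_sample(rounds: list[StainRoundImage], config: PipelineConfig | None = None,
               roi_mask: np.ndarray | None = None,
               transforms: list[RoundTransform] | None = None) -> SampleResult:
    """Run registration, fusion, phenotyping, zoning and metrics on one sample.

    ``roi_mask`` overrides the automatic tissue ROI (it is still clipped to
    the valid-pixel mask); pre-computed ``transforms`` skip registration.
    """
    config = config or PipelineConfig()
    basis = config.basis
    if transforms is None:
        transforms = register_rounds(rounds, basis, config.reference_marker)
    vdi = build_vdi(rounds, transforms, basis,
                    reference_marker=config.reference_marker)

    px = vdi.pixel_size_um
    if roi_mask is None:
        roi_mask = detect_tissue_roi(vdi.hematoxylin_od, pixel_size_um=px)
    roi = np.asarray(roi_mask, bool) & vdi.valid_mask

    detections = detect_nuclei(vdi.hematoxylin_od, px, config.nucleus,
                               valid_mask=roi)
    cells = phenotype_cells(detections, vdi, thresholds=config.thresholds,
                            ring_width_um=config.ring_width_um,
                            ck_dilation_um=config.ck_dilation_um)

    tumour = build_tumor_mask(vdi.marker_od["CK"], roi,
                              threshold=config.ck_mask_threshold,
                              min_object_area_um2=config.ck_min_object_area_um2,
                              fill_holes=config.ck_fill_holes,
                              pixel_size_um=px)
    masks, areas = partition_zones(tumour, roi, config.band_width_um, px)
    cells = assign_cells_to_zones(cells, masks)

    metrics = compute_sample_metrics(cells, areas)
    metrics.qc_pass = qc_filter(metrics, config.min_roi_area_um2)
    return SampleResult(vdi=vdi, transforms=transforms, cells=cells,
                        masks=masks, areas=areas, metrics=metrics)
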