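"""Nucleus detection, per-marker positivity calls and exclusive phenotypes.

Cells are found on the hematoxylin counterstain (form-and-size rules:
smoothed-OD maxima grown by watershed, filtered by equivalent diameter and
circularity).  Each marker is then called positive when the mean chromogen OD
over the marker's subcellular compartment reaches a fixed threshold — the
"any brown stained nucleus is positive" rule made quantitative — and the flag
pattern maps to exactly one of six exclusive phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, segmentation
from skimage.morphology import disk
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from .stains import MARKER_PANEL
from .vdi import VirtualMultiplexImage

PHENOTYPE_ORDER = ("CD8_T", "CD4_T", "Treg", "CD3_only", "tumour", "other")
IMMUNE_PHENOTYPES = ("CD8_T", "CD4_T", "Treg", "CD3_only")

DEFAULT_THRESHOLD_OD = 0.15


@dataclass
class NucleusParams:
    """Form-and-size gates for nucleus detection."""

    min_diameter_um: float = 4.0
    max_diameter_um: float = 14.0
    min_circularity: float = 0.55
    detection_threshold_od: float = 0.40
    smoothing_sigma_um: float = 0.75
    min_distance_um: float = 4.0


@dataclass
class NucleusDetections:
    """Detected nuclei: per-cell table plus the watershed label image."""

    table: pd.DataFrame  # cell_id, x_um, y_um, diameter_um, circularity
    labels: np.ndarray  # 0 = background; label i+1 = cell_id i

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MarkerCall:
    cell_id: int
    marker: str
    mean_od: float | None
    positive: bool
    compartment: str
    indeterminate: bool = False


def detect_nuclei(hematoxylin_od: np.ndarray, pixel_size_um: float,
                  params: NucleusParams | None = None,
                  valid_mask: np.ndarray | None = None) -> NucleusDetections:
    """Detect nuclei on the counterstain OD map.

    Smooth, threshold, split touching nuclei by watershed on the distance
    transform, then filter components by diameter and circularity
    (4*pi*A/P^2).  Detections whose centroid falls outside ``valid_mask`` are
    dropped.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    params = params or NucleusParams()
    sigma = params.smoothing_sigma_um / pixel_size_um
    sm = gaussian(np.asarray(hematoxylin_od, dtype=float), sigma=sigma,
                  preserve_range=True)
    binary = sm >= params.detection_threshold_od
    empty = NucleusDetections(
        table=pd.DataFrame(columns=["cell_id", "x_um", "y_um",
                                    "diameter_um", "circularity"]),
        labels=np.zeros_like(binary, dtype=np.int32),
    )
    if not binary.any():
        return empty

    dist = ndi.distance_transform_edt(binary)
    min_dist_px = max(1, int(round(params.min_distance_um / pixel_size_um)))
    peaks = peak_local_max(dist, min_distance=min_dist_px, labels=binary,
                           exclude_border=False)
    if peaks.size == 0:
        return empty
    markers = np.zeros_like(binary, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-dist, markers, mask=binary)

    rows = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 0
    for rp in measure.regionprops(labels, intensity_image=sm):
        area_px = rp.area
        diameter = 2.0 * np.sqrt(area_px / np.pi) * pixel_size_um
        perim = rp.perimeter
        circ = min(1.0, 4.0 * np.pi * area_px / perim ** 2) if perim > 0 else 0.0
        if not (params.min_diameter_um <= diameter <= params.max_diameter_um):
            continue
        if circ < params.min_circularity:
            continue
        cy, cx = rp.centroid_weighted
        if valid_mask is not None and not valid_mask[int(cy), int(cx)]:
            continue
        rows.append((next_id, (cx + 0.5) * pixel_size_um, (cy + 0.5) * pixel_size_um,
                     diameter, circ))
        keep[rp.label] = next_id + 1
        next_id += 1

    out_labels = keep[labels]
    table = pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um",
                                        "diameter_um", "circularity"])
    return NucleusDetections(table=table, labels=out_labels.astype(np.int32))


def _compartment_mask(nucleus_mask: np.ndarray, marker: str, pixel_size_um: float,
                      ring_width_um: float, ck_dilation_um: float) -> tuple[np.ndarray, str]:
    comp = {"Ki67": "nuclear", "Foxp3": "nuclear", "CK": "cytoplasmic"}.get(marker, "ring")
    if comp == "nuclear":
        return nucleus_mask, comp
    if comp == "ring":
        r = max(1, int(round(ring_width_um / pixel_size_um)))
        dil = ndi.binary_dilation(nucleus_mask, structure=disk(r))
        return dil & ~nucleus_mask, comp
    r = max(1, int(round(ck_dilation_um / pixel_size_um)))
    return ndi.binary_dilation(nucleus_mask, structure=disk(r)), comp


def cell_territories(detections: NucleusDetections, pixel_size_um: float,
                     max_extent_um: float = 4.0) -> np.ndarray:
    """Nearest-nucleus territory map: each pixel near a nucleus is assigned
    to its closest cell, so measurement compartments never leak onto a
    neighbour's stain."""
    dist_px = int(np.ceil(max_extent_um / pixel_size_um)) + 1
    return segmentation.expand_labels(detections.labels, distance=dist_px)


def call_marker_positivity(cell_id: int, detections: NucleusDetections,
                           marker_od_map: np.ndarray, marker: str,
                           threshold: float, pixel_size_um: float,
                           ring_width_um: float = 1.5,
                           ck_dilation_um: float = 2.0,
                           valid_mask: np.ndarray | None = None,
                           territory_labels: np.ndarray | None = None) -> MarkerCall:
    """Call one marker on one nucleus.

    Positive iff mean chromogen OD over the compartment >= threshold (closed
    boundary).  The compartment is clipped to the cell's territory when a
    territory map is given.  A compartment entirely outside the valid-pixel
    mask yields an indeterminate call.
    """
    if marker not in MARKER_PANEL:
        raise ValueError(f"unknown marker {marker!r}")
    lab = detections.labels
    # Work on a window around the nucleus; compartments extend a few pixels.
    margin = int(np.ceil(max(ring_width_um, ck_dilation_um) / pixel_size_um)) + 2
    rows, cols = np.nonzero(lab == cell_id + 1)
    if rows.size == 0:
        raise ValueError(f"cell_id {cell_id} has no nucleus footprint")
    y0, y1 = max(0, rows.min() - margin), min(lab.shape[0], rows.max() + margin + 1)
    x0, x1 = max(0, cols.min() - margin), min(lab.shape[1], cols.max() + margin + 1)
    nuc = lab[y0:y1, x0:x1] == cell_id + 1
    comp, comp_name = _compartment_mask(nuc, marker, pixel_size_um,
                                        ring_width_um, ck_dilation_um)
    if territory_labels is not None:
        comp = comp & (territory_labels[y0:y1, x0:x1] == cell_id + 1)
    if valid_mask is not None:
        comp = comp & valid_mask[y0:y1, x0:x1]
    if not comp.any():
        return MarkerCall(cell_id, marker, None, False, comp_name, indeterminate=True)
    mean_od = float(marker_od_map[y0:y1, x0:x1][comp].mean())
    return MarkerCall(cell_id, marker, mean_od, mean_od >= threshold, comp_name)


def assign_phenotype(flags: dict, mean_od: dict | None = None) -> tuple[str, bool]:
    """Map a complete marker-flag pattern to one exclusive phenotype.

    CD3+ cells resolve to CD8_T / CD4_T / Treg / CD3_only; CD3- cells are
    tumour if CK+ else other.  Conflicting CD3+ patterns (CD4+CD8+ or
    Foxp3+CD8+) are resolved toward the marker with the higher mean OD (ties
    to CD8) and reported via the returned conflict flag.  Foxp3+CD3+CD4-CD8-
    keeps marker-level Foxp3 positivity but phenotypes as CD3_only.  Ki67 is a
    modifier, never a phenotype.
    """
    for m in ("CD3", "CD4", "CD8", "Foxp3", "CK"):
        if m not in flags:
            raise ValueError(f"flag for {m} missing")
    mean_od = mean_od or {}
    if not flags["CD3"]:
        return ("tumour" if flags["CK"] else "other"), False

    cd4, cd8, foxp3 = flags["CD4"], flags["CD8"], flags["Foxp3"]
    conflict = False

    def od(m):
        v = mean_od.get(m)
        return -np.inf if v is None else v

    if cd4 and cd8:
        conflict = True
        if od("CD4") > od("CD8"):
            cd8 = False
        else:  # ties go to CD8
            cd4 = False
    if cd8 and foxp3:
        conflict = True
        if od("Foxp3") > od("CD8"):
            cd8 = False
        else:
            foxp3 = False
    if cd8:
        return "CD8_T", conflict
    if cd4 and foxp3:
        return "Treg", conflict
    if cd4:
        return "CD4_T", conflict
    return "CD3_only", conflict


def phenotype_cells(detections: NucleusDetections, vdi: VirtualMultiplexImage,
                    thresholds: dict | None = None, ring_width_um: float = 1.5,
                    ck_dilation_um: float = 2.0) -> pd.DataFrame:
    """Call all markers for all detected cells and assign phenotypes.

    Returns one row per cell with per-marker mean OD and flags, the exclusive
    phenotype, a conflict flag and an indeterminate flag (any compartment
    fully outside the valid-pixel mask).
    """
    thresholds = dict(thresholds or {})
    markers = [m for m in MARKER_PANEL if m in vdi.marker_od]
    territory = cell_territories(detections, vdi.pixel_size_um,
                                 max_extent_um=max(ring_width_um, ck_dilation_um) + 2.0)
    records = []
    for cell_id in detections.table["cell_id"]:
        row: dict = {"cell_id": int(cell_id)}
        flags, ods = {}, {}
        indet = False
        for m in markers:
            call = call_marker_positivity(
                int(cell_id), detections, vdi.marker_od[m], m,
                thresholds.get(m, DEFAULT_THRESHOLD_OD), vdi.pixel_size_um,
                ring_width_um=ring_width_um, ck_dilation_um=ck_dilation_um,
                valid_mask=vdi.valid_mask, territory_labels=territory,
            )
            flags[m] = call.positive
            ods[m] = call.mean_od
            indet |= call.indeterminate
            row[f"{m}_od"] = call.mean_od
            row[m] = call.positive
        phen, conflict = assign_phenotype(flags, ods)
        row["phenotype"] = phen
        row["conflict"] = conflict
        row["indeterminate"] = indet
        records.append(row)
    calls = pd.DataFrame(records)
    return detections.table.merge(calls, on="cell_id")
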