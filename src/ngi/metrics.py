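"""Sample-level immune-contexture readouts.

Reduces the per-cell phenotype table to the readouts reported per sample:
marker densities (cells/mm², overall and per zone A/B/C), proliferating
(Ki67+) fractions, exclusive CD3+ subset proportions, the proliferating
Foxp3+/CD8+ ratio, the immune share of proliferating cells, and QC.  Marker
densities use overlapping marker-level positivity (a Treg counts toward both
CD4+ and Foxp3+ density); subset proportions use the exclusive phenotypes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotyping import IMMUNE_PHENOTYPES
from .zones import ZoneAreas

DENSITY_MARKERS = ("CD3", "CD4", "CD8", "Foxp3")
ZONES = ("A", "B", "C")

#: ROI-area QC floor in µm²; smaller samples are excluded from analysis.
MIN_ROI_AREA_UM2 = 100_000.0


@dataclass
class SampleMetrics:
    density: dict  # marker -> {"total": .., "A": .., "B": .., "C": ..} cells/mm²
    pct_ki67: dict  # marker -> {"total": .., "A": .., ...} percent or None
    subset_proportions: dict | None  # CD8_T/CD4_T/Treg/CD3_only fractions of CD3+
    ratio_prolif_foxp3_cd8: float | None
    prolif_immune_fraction: float | None
    roi_area_um2: float
    tumour_area_fraction: float
    n_cells: int
    n_conflicts: int
    n_indeterminate: int
    n_outside_roi: int
    qc_pass: bool = True

    def to_row(self) -> dict:
        row: dict = {}
        for m in DENSITY_MARKERS:
            row[f"density_{m}_total"] = self.density[m]["total"]
            for z in ZONES:
                row[f"density_{m}_{z}"] = self.density[m][z]
            row[f"pct_ki67_{m}_total"] = self.pct_ki67[m]["total"]
            for z in ZONES:
                row[f"pct_ki67_{m}_{z}"] = self.pct_ki67[m][z]
        for ph in ("CD8_T", "CD4_T", "Treg", "CD3_only"):
            row[f"prop_{ph}"] = (None if self.subset_proportions is None
                                 else self.subset_proportions[ph])
        row.update(
            ratio_prolif_foxp3_cd8=self.ratio_prolif_foxp3_cd8,
            prolif_immune_fraction=self.prolif_immune_fraction,
            roi_area_um2=self.roi_area_um2,
            tumour_area_fraction=self.tumour_area_fraction,
            n_cells=self.n_cells,
            n_conflicts=self.n_conflicts,
            n_indeterminate=self.n_indeterminate,
            n_outside_roi=self.n_outside_roi,
            qc_pass=self.qc_pass,
        )
        return row

    def to_json(self) -> str:
        return json.dumps(self.to_row(), indent=2)


def _density(count: int, area_um2: float) -> float | None:
    if area_um2 <= 0:
        return None
    return count / (area_um2 / 1e6)


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_sample_metrics(cells: pd.DataFrame, areas: ZoneAreas) -> SampleMetrics:
    """Reduce a phenotyped, zoned cell table to sample-level metrics.

    Cells with zone ``none`` (outside the ROI) or an indeterminate marker
    call are excluded from every count and reported in the QC fields.
    Fractions with a zero denominator are None (missing), never 0.
    """
    if areas.roi_area_um2 <= 0:
        raise ValueError("zero ROI area")
    cells = cells.copy()
    if "zone" not in cells:
        raise ValueError("cells must carry a zone column")
    n_total = len(cells)
    outside = (cells["zone"] == "none").sum()
    indet = int(cells.get("indeterminate", pd.Series(False, index=cells.index)).sum())
    use = cells[(cells["zone"] != "none")
                & ~cells.get("indeterminate", pd.Series(False, index=cells.index))]

    density: dict = {}
    pct_ki67: dict = {}
    for m in DENSITY_MARKERS:
        pos = use[use[m].astype(bool)]
        density[m] = {"total": _density(len(pos), areas.roi_area_um2)}
        pct_ki67[m] = {"total": _pct(int((pos["Ki67"]).sum()), len(pos))}
        for z in ZONES:
            zi = pos[pos["zone"] == z]
            density[m][z] = _density(len(zi), areas.area_um2[z])
            pct_ki67[m][z] = _pct(int(zi["Ki67"].sum()), len(zi))

    cd3 = use[use["CD3"].astype(bool)]
    if len(cd3) > 0:
        props = {ph: (cd3["phenotype"] == ph).sum() / len(cd3)
                 for ph in ("CD8_T", "CD4_T", "Treg", "CD3_only")}
    else:
        props = None

    pk_f = pct_ki67["Foxp3"]["total"]
    pk_c = pct_ki67["CD8"]["total"]
    ratio = None if (pk_f is None or pk_c is None or pk_c == 0) else pk_f / pk_c

    prolif = use[use["Ki67"].astype(bool)]
    n_imm = int(prolif["phenotype"].isin(IMMUNE_PHENOTYPES).sum())
    n_tum = int((prolif["phenotype"] == "tumour").sum())
    pif = None if (n_imm + n_tum) == 0 else n_imm / (n_imm + n_tum)

    metrics = SampleMetrics(
        density=density,
        pct_ki67=pct_ki67,
        subset_proportions=props,
        ratio_prolif_foxp3_cd8=ratio,
        prolif_immune_fraction=pif,
        roi_area_um2=areas.roi_area_um2,
        tumour_area_fraction=areas.area_um2["A"] / areas.roi_area_um2,
        n_cells=n_total,
        n_conflicts=int(cells.get("conflict", pd.Series(False, index=cells.index)).sum()),
        n_indeterminate=indet,
        n_outside_roi=int(outside),
    )
    metrics.qc_pass = qc_filter(metrics)
    return metrics


def qc_filter(metrics: SampleMetrics, min_roi_area_um2: float = MIN_ROI_AREA_UM2) -> bool:
    """ROI-area QC: samples whose total ROI is below the floor are excluded.

    The boundary is closed on the inclusion side — an ROI exactly at the
    floor passes.
    """
    return bool(metrics.roi_area_um2 >= min_roi_area_um2)


def classify_til_dynamics(stils_t1: float | None, stils_t2: float | None) -> str | None:
    """Classify the sTIL change between two consecutive timepoints.

    Any increase counts as ``increase`` and any decrease as ``decrease``;
    ``stable`` requires the exact same percentage at both timepoints (no
    tolerance band).  Missing values yield None.
    """
    if stils_t1 is None or stils_t2 is None:
        return None
    if isinstance(stils_t1, float) and math.isnan(stils_t1):
        return None
    if isinstance(stils_t2, float) and math.isnan(stils_t2):
        return None
    for v in (stils_t1, stils_t2):
        if not 0 <= v <= 100:
            raise ValueError("sTILs percentages must be in [0, 100]")
    if stils_t2 > stils_t1:
        return "increase"
    if stils_t2 < stils_t1:
        return "decrease"
    return "stable"
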