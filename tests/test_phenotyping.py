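"""Nucleus detection, marker calls and exclusive phenotype assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ngi.evaluate import match_cells, phenotype_accuracy
from ngi.phenotyping import (NucleusDetections, NucleusParams, assign_phenotype,
                             call_marker_positivity, detect_nuclei,
                             phenotype_cells)


def _disk_map(shape, centres_px, radius_px, amplitude, background=0.0):
    arr = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for cx, cy in centres_px:
        arr[np.hypot(xx + 0.5 - cx, yy + 0.5 - cy) <= radius_px] = amplitude
    return arr


def test_blank_map_yields_no_detections():
    det = detect_nuclei(np.zeros((128, 128)), pixel_size_um=0.5)
    assert len(det) == 0


def test_grid_of_nuclei_all_detected_with_accurate_centroids():
    """40 rendered nuclei -> exactly 40 detections within 2 µm of truth."""
    px = 0.5
    centres = [(24 + 32 * i, 24 + 32 * j) for i in range(8) for j in range(5)]
    hema = _disk_map((192, 280), centres, radius_px=8, amplitude=0.7,
                     background=0.08)
    det = detect_nuclei(hema, px)
    assert len(det) == 40
    truth = pd.DataFrame({"x_um": [c[0] * px for c in centres],
                          "y_um": [c[1] * px for c in centres]})
    matched = match_cells(truth, det.table, max_dist_um=2.0)
    assert len(matched) == 40


def test_too_small_disk_rejected():
    params = NucleusParams(min_diameter_um=4.0)
    # diameter = min/2 = 2 µm -> radius 2 px at 0.5 µm/px
    hema = _disk_map((64, 64), [(32, 32)], radius_px=2, amplitude=0.7)
    det = detect_nuclei(hema, 0.5, params)
    assert len(det) == 0


def _single_cell_detections(shape=(64, 64), radius_px=8):
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    labels[np.hypot(xx - 32, yy - 32) <= radius_px] = 1
    table = pd.DataFrame({"cell_id": [0], "x_um": [16.0], "y_um": [16.0],
                          "diameter_um": [8.0], "circularity": [1.0]})
    return NucleusDetections(table=table, labels=labels)


def test_zero_od_compartment_is_negative():
    det = _single_cell_detections()
    call = call_marker_positivity(0, det, np.zeros((64, 64)), "Foxp3",
                                  threshold=0.15, pixel_size_um=0.5)
    assert not call.positive and not call.indeterminate


def test_mean_exactly_at_threshold_is_positive():
    det = _single_cell_detections()
    call = call_marker_positivity(0, det, np.full((64, 64), 0.15), "Foxp3",
                                  threshold=0.15, pixel_size_um=0.5)
    assert call.positive


def test_compartment_outside_valid_mask_is_indeterminate():
    det = _single_cell_detections()
    call = call_marker_positivity(0, det, np.ones((64, 64)), "CD3",
                                  threshold=0.15, pixel_size_um=0.5,
                                  valid_mask=np.zeros((64, 64), bool))
    assert call.indeterminate and not call.positive


def test_rendered_cd8_cell_mean_near_amplitude(clean_slide, small_config):
    """Noise-free CD8+ ring measurement recovers the amplitude within 15%."""
    import dataclasses
    from ngi.pipeline import run_sample
    rounds, gt = clean_slide
    res = run_sample(rounds)
    matched = match_cells(gt.cells, res.cells)
    cd8 = matched[matched["phenotype_true"] == "CD8_T"]
    assert (cd8["CD8"]).all()
    amp = small_config.chromogen_amplitude_od
    assert (np.abs(cd8["CD8_od"] - amp) <= 0.15 * amp).all()


def test_treg_pattern():
    flags = dict(CD3=True, CD4=True, Foxp3=True, CD8=False, CK=False)
    assert assign_phenotype(flags) == ("Treg", False)


def test_ck_only_is_tumour():
    flags = dict(CD3=False, CD4=False, Foxp3=False, CD8=False, CK=True)
    assert assign_phenotype(flags) == ("tumour", False)


def test_double_positive_resolved_by_od_with_conflict():
    flags = dict(CD3=True, CD4=True, CD8=True, Foxp3=False, CK=False)
    phen, conflict = assign_phenotype(flags, {"CD4": 0.5, "CD8": 0.3})
    assert phen == "CD4_T" and conflict
    phen, conflict = assign_phenotype(flags, {"CD4": 0.3, "CD8": 0.5})
    assert phen == "CD8_T" and conflict
    # tie goes to CD8
    phen, conflict = assign_phenotype(flags, {"CD4": 0.4, "CD8": 0.4})
    assert phen == "CD8_T" and conflict


def test_foxp3_without_cd4_is_cd3_only():
    flags = dict(CD3=True, CD4=False, CD8=False, Foxp3=True, CK=False)
    assert assign_phenotype(flags) == ("CD3_only", False)


def test_every_flag_pattern_maps_to_exactly_one_phenotype():
    for bits in itertools.product([False, True], repeat=5):
        flags = dict(zip(("CD3", "CD4", "CD8", "Foxp3", "CK"), bits))
        phen, _ = assign_phenotype(flags, {"CD4": 0.2, "CD8": 0.3, "Foxp3": 0.1})
        assert phen in ("CD8_T", "CD4_T", "Treg", "CD3_only", "tumour", "other")


def test_incomplete_flags_rejected():
    with pytest.raises(ValueError):
        assign_phenotype({"CD3": True})


def test_threshold_monotonicity(small_result, small_slide):
    """Raising a marker threshold never increases its positive count."""
    from ngi.phenotyping import detect_nuclei
    rounds, _ = small_slide
    vdi = small_result.vdi
    det = detect_nuclei(vdi.hematoxylin_od, vdi.pixel_size_um,
                        valid_mask=small_result.masks.roi_mask)
    low = phenotype_cells(det, vdi, thresholds={"CD8": 0.10})
    high = phenotype_cells(det, vdi, thresholds={"CD8": 0.30})
    assert high["CD8"].sum() <= low["CD8"].sum()


def test_marker_counts_dominate_subset_counts(small_result):
    cells = small_result.cells
    assert cells["CD8"].sum() >= (cells["phenotype"] == "CD8_T").sum()
    assert cells["CD4"].sum() >= ((cells["phenotype"] == "CD4_T").sum()
                                  + (cells["phenotype"] == "Treg").sum())


def test_phenotype_accuracy_on_default_noise_slide(small_slide, small_result):
    _, gt = small_slide
    matched = match_cells(gt.cells, small_result.cells)
    assert len(matched) >= 0.98 * len(gt.cells)
    assert phenotype_accuracy(matched) >= 0.95
    counts_true = gt.cells["phenotype"].value_counts()
    counts_meas = small_result.cells["phenotype"].value_counts()
    for phen, n in counts_true.items():
        if n >= 10:
            assert abs(counts_meas.get(phen, 0) - n) <= 0.1 * n
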