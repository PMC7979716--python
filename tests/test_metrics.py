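"""Sample-level contexture metrics, QC and sTIL dynamics."""

import math

import numpy as np
import pandas as pd
import pytest

from ngi.metrics import (classify_til_dynamics, compute_sample_metrics,
                         qc_filter)
from ngi.zones import ZoneAreas


def make_areas(a=10_000.0, b=5_000.0, c=85_000.0):
    return ZoneAreas(area_um2={"A": a, "B": b, "C": c}, roi_area_um2=a + b + c)


def make_cells(rows):
    cols = ["CD3", "CD4", "CD8", "Foxp3", "CK", "Ki67"]
    df = pd.DataFrame(rows, columns=["phenotype", "zone"] + cols)
    df.insert(0, "cell_id", range(len(df)))
    df["conflict"] = False
    df["indeterminate"] = False
    return df


def test_empty_table_gives_zero_densities_and_null_fractions():
    cells = make_cells([])
    m = compute_sample_metrics(cells, make_areas())
    for marker in ("CD3", "CD4", "CD8", "Foxp3"):
        assert m.density[marker]["total"] == 0
        assert m.pct_ki67[marker]["total"] is None
    assert m.subset_proportions is None
    assert m.prolif_immune_fraction is None
    assert m.ratio_prolif_foxp3_cd8 is None


def test_density_arithmetic():
    """5 CD8 T cells in a 0.005 mm² zone B -> 1000 cells/mm²."""
    rows = [("CD8_T", "B", True, False, True, False, False, False)] * 5
    m = compute_sample_metrics(make_cells(rows), make_areas(b=5_000.0))
    assert m.density["CD8"]["B"] == pytest.approx(1000.0)
    assert m.density["CD3"]["B"] == pytest.approx(1000.0)


def test_subset_proportions_sum_to_one():
    rows = (
        [("CD8_T", "B", True, False, True, False, False, False)] * 7
        + [("CD4_T", "B", True, True, False, False, False, True)] * 4
        + [("Treg", "C", True, True, False, True, False, False)] * 2
        + [("CD3_only", "A", True, False, False, False, False, False)] * 3
        + [("tumour", "A", False, False, False, False, True, True)] * 5
    )
    m = compute_sample_metrics(make_cells(rows), make_areas())
    assert sum(m.subset_proportions.values()) == pytest.approx(1.0, abs=1e-12)
    assert m.subset_proportions["CD8_T"] == pytest.approx(7 / 16)


def test_zone_counts_sum_to_total():
    rng = np.random.default_rng(0)
    rows = []
    for _ in range(200):
        phen = rng.choice(["CD8_T", "CD4_T", "Treg", "CD3_only", "tumour", "other"])
        zone = rng.choice(["A", "B", "C"])
        flags = {
            "CD8_T": (1, 0, 1, 0, 0), "CD4_T": (1, 1, 0, 0, 0),
            "Treg": (1, 1, 0, 1, 0), "CD3_only": (1, 0, 0, 0, 0),
            "tumour": (0, 0, 0, 0, 1), "other": (0, 0, 0, 0, 0),
        }[phen]
        rows.append((phen, zone, *map(bool, flags), bool(rng.uniform() < 0.3)))
    m = compute_sample_metrics(make_cells(rows), make_areas())
    areas = make_areas()
    for marker in ("CD3", "CD4", "CD8", "Foxp3"):
        per_zone = sum(m.density[marker][z] * areas.area_um2[z] / 1e6
                       for z in ("A", "B", "C"))
        total = m.density[marker]["total"] * areas.roi_area_um2 / 1e6
        assert per_zone == pytest.approx(total, abs=1e-9)


def test_marker_density_dominates_exclusive_subsets(small_result):
    m = small_result.metrics
    cells = small_result.cells
    use = cells[cells["zone"] != "none"]
    subtotal = sum((use["phenotype"] == p).sum()
                   for p in ("CD8_T", "CD4_T", "Treg", "CD3_only"))
    assert use["CD3"].sum() >= subtotal


def test_prolif_immune_fraction_excludes_other():
    rows = [
        ("CD8_T", "B", True, False, True, False, False, True),
        ("tumour", "A", False, False, False, False, True, True),
        ("tumour", "A", False, False, False, False, True, True),
        ("other", "C", False, False, False, False, False, True),
    ]
    m = compute_sample_metrics(make_cells(rows), make_areas())
    assert m.prolif_immune_fraction == pytest.approx(1 / 3)


def test_indeterminate_cells_excluded_and_counted():
    rows = [("CD8_T", "B", True, False, True, False, False, False)] * 3
    cells = make_cells(rows)
    cells.loc[0, "indeterminate"] = True
    m = compute_sample_metrics(cells, make_areas(b=2_000.0))
    assert m.n_indeterminate == 1
    assert m.density["CD8"]["B"] == pytest.approx(2 / 0.002)


def test_qc_boundary_is_closed():
    rows = [("CD8_T", "B", True, False, True, False, False, False)]
    m1 = compute_sample_metrics(make_cells(rows),
                                ZoneAreas({"A": 0, "B": 99_999.0, "C": 0}, 99_999.0))
    assert not qc_filter(m1)
    m2 = compute_sample_metrics(make_cells(rows),
                                ZoneAreas({"A": 0, "B": 100_000.0, "C": 0}, 100_000.0))
    assert qc_filter(m2)
    with pytest.raises(ValueError):
        compute_sample_metrics(make_cells(rows),
                               ZoneAreas({"A": 0, "B": 0, "C": 0}, 0.0))


@pytest.mark.parametrize("t1, t2, expected", [
    (10, 10, "stable"),
    (5, 20, "increase"),
    (20, 5, "decrease"),
    (0, 0, "stable"),
    (None, 10, None),
    (float("nan"), 10, None),
])
def test_til_dynamics_rule(t1, t2, expected):
    assert classify_til_dynamics(t1, t2) == expected


def test_til_dynamics_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_til_dynamics(-1, 50)


def test_metrics_row_round_trips_to_json(small_result):
    import json
    row = small_result.metrics.to_row()
    parsed = json.loads(json.dumps(row, default=float))
    # the compact fixture slide sits below the 100,000 µm² ROI floor, so the
    # QC flag must survive serialisation as a real boolean False
    assert parsed["qc_pass"] is (parsed["roi_area_um2"] >= 100_000)
    assert isinstance(parsed["qc_pass"], bool)
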