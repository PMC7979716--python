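"""Ground-truthed synthetic slides for the sequential-stain workflow.

The generator emulates the acquisition geometry of a six-round chromogenic
multiplexed IHC experiment: one ground-truth cell map (tumour nests packed
with cytokeratin-positive cells, T-cell subsets and other stromal cells
scattered across the three tumour-distance zones) is rendered six times, once
per marker, each render slightly misaligned, with the marker's chromogen in
the marker's subcellular compartment and hematoxylin in every nucleus.  The
forward model inverts the same Beer–Lambert law the analysis uses, so the
analysis pipeline can be scored against exact per-cell truth.

It emulates geometry and stain optics only — not tissue texture,
autofluorescence or staining-chemistry artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registration import RoundTransform, apply_transform
from .stains import MARKER_PANEL, StainBasis, StainRoundImage, mix_stains, od_to_rgb
from .zones import RegionMasks, partition_zones

PHENOTYPES = ("CD8_T", "CD4_T", "Treg", "CD3_only", "tumour", "other")

#: Marker flags implied by each exclusive phenotype (Ki67 is drawn separately).
PHENOTYPE_FLAGS: dict[str, frozenset] = {
    "CD8_T": frozenset({"CD3", "CD8"}),
    "CD4_T": frozenset({"CD3", "CD4"}),
    "Treg": frozenset({"CD3", "CD4", "Foxp3"}),
    "CD3_only": frozenset({"CD3"}),
    "tumour": frozenset({"CK"}),
    "other": frozenset(),
}

#: Subcellular compartment each marker is rendered in (and measured in).
MARKER_COMPARTMENT = {
    "Ki67": "nuclear", "Foxp3": "nuclear",
    "CD3": "ring", "CD4": "ring", "CD8": "ring",
    "CK": "cytoplasmic",
}


def _default_counts() -> dict:
    # CD3+ subset mix ~47/30/11/13% of ~400 CD3+ cells, a realistic regime
    # for an inflamed HER2+ tumour at this field size (the peritumoural band
    # stays below its geometric packing limit); "tumour": None packs the
    # nests to capacity.
    return {"CD8_T": 188, "CD4_T": 120, "Treg": 44, "CD3_only": 52,
            "other": 96, "tumour": None}


def _default_ki67() -> dict:
    # Proliferating fraction highest intratumourally, decreasing outward.
    return {"A": 0.30, "B": 0.20, "C": 0.10}


def _default_misalignment() -> dict:
    # (dx_px, dy_px, rotation_deg) content displacement per round; the
    # reference (first) round is held at identity so ground-truth coordinates
    # live in the reference frame.
    return {
        "Foxp3": (0.0, 0.0, 0.0),
        "CD3": (4.0, -3.0, 0.4),
        "CD8": (-5.0, 2.0, -0.3),
        "CD4": (3.0, 4.0, 0.6),
        "Ki67": (-2.0, -5.0, -0.5),
        "CK": (5.0, 3.0, 0.3),
    }


def _default_zone_mix() -> dict:
    # T cells concentrate in the proximal stromal band; the intratumoural
    # share is bounded by geometry — immune cells embedded in epithelium must
    # stay sparse enough that the CK carpet encloses each one.
    return {"A": 0.08, "B": 0.40, "C": 0.52}


def _default_other_mix() -> dict:
    # Stromal "other" cells (fibroblast-like) mostly away from tumour.
    return {"A": 0.03, "B": 0.30, "C": 0.67}


@dataclass
class SlideConfig:
    """Study conditions for one synthetic slide."""

    image_height_px: int = 1024
    image_width_px: int = 1024
    pixel_size_um: float = 0.5
    #: (centre_x_um, centre_y_um, radius_um) per tumour nest.
    tumour_nests: tuple = ((135.0, 145.0, 75.0), (360.0, 340.0, 90.0))
    n_cells_per_phenotype: dict = field(default_factory=_default_counts)
    ki67_rate_by_zone: dict = field(default_factory=_default_ki67)
    ki67_rate_tumour: float = 0.40
    chromogen_amplitude_od: float = 0.6
    hematoxylin_amplitude_od: float = 0.7
    tissue_background_od: float = 0.08
    round_misalignment: dict = field(default_factory=_default_misalignment)
    noise_sd_od: float = 0.02
    seed: int = 0

    nucleus_diameter_um: float = 8.0
    ring_width_um: float = 1.5
    ck_extra_radius_um: float = 4.0
    min_separation_um: float = 9.0
    #: tumour<->immune centre distance keeping membrane rings disjoint
    tumour_immune_separation_um: float = 11.5
    tumour_spacing_um: float = 10.0
    zone_margin_um: float = 4.0
    edge_margin_um: float = 8.0
    immune_zone_mix: dict = field(default_factory=_default_zone_mix)
    other_zone_mix: dict = field(default_factory=_default_other_mix)
    band_width_um: float = 30.0
    background_intensity: float = 250.0
    stain_basis: str = "dab"

    def __post_init__(self):
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.chromogen_amplitude_od <= 0:
            raise ValueError("chromogen_amplitude_od must be > 0")
        if self.noise_sd_od < 0:
            raise ValueError("noise_sd_od must be >= 0")
        for ph, n in self.n_cells_per_phenotype.items():
            if ph not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {ph!r}")
            if n is not None and n < 0:
                raise ValueError("cell counts must be >= 0")
        for z, r in self.ki67_rate_by_zone.items():
            if not 0 <= r <= 1:
                raise ValueError(f"ki67 rate for zone {z} outside [0, 1]")
        w = self.image_width_px * self.pixel_size_um
        h = self.image_height_px * self.pixel_size_um
        for cx, cy, r in self.tumour_nests:
            if not (r < cx < w - r and r < cy < h - r):
                raise ValueError(f"nest ({cx}, {cy}, r={r}) not inside the image")

    @property
    def width_um(self) -> float:
        return self.image_width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.image_height_px * self.pixel_size_um

    @property
    def basis(self) -> StainBasis:
        return StainBasis.named(self.stain_basis)


@dataclass
class GroundTruth:
    """Per-cell truth, true round transforms and the true tumour mask."""

    cells: pd.DataFrame  # cell_id, x_um, y_um, phenotype, zone, marker flags
    transforms: dict[str, RoundTransform]  # true *aligning* transforms
    tumour_mask: np.ndarray
    region_masks: RegionMasks
    config: SlideConfig


# ---------------------------------------------------------------------------
# cell placement


class _SpatialHash:
    """Uniform-grid min-separation check for dart-throwing placement."""

    def __init__(self, min_sep: float):
        self.min_sep = min_sep
        self.cell = min_sep
        self.grid: dict[tuple, list] = {}

    def _key(self, x, y):
        return (int(x // self.cell), int(y // self.cell))

    def ok(self, x, y) -> bool:
        kx, ky = self._key(x, y)
        for i in range(kx - 1, kx + 2):
            for j in range(ky - 1, ky + 2):
                for px, py in self.grid.get((i, j), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < self.min_sep ** 2:
                        return False
        return True

    def add(self, x, y):
        self.grid.setdefault(self._key(x, y), []).append((x, y))


def _eroded_zone_masks(masks: RegionMasks, margin_um: float,
                       edge_margin_um: float) -> dict[str, np.ndarray]:
    """Zone masks shrunk away from zone boundaries and image edges.

    Sampling positions from these keeps ground-truth zone labels unambiguous:
    no cell centroid sits within ``margin_um`` of a zone boundary, so small
    differences between the true nest outline and the analyser's CK-derived
    mask cannot flip labels.
    """
    from scipy import ndimage as ndi

    px = masks.pixel_size_um
    h, w = masks.roi_mask.shape
    edge = np.zeros((h, w), dtype=bool)
    m = int(math.ceil(edge_margin_um / px))
    edge[m:h - m, m:w - m] = True
    out = {}
    for name, mask in (("A", masks.tumour_mask_A), ("B", masks.proximal_band_B),
                       ("C", masks.distal_stroma_C)):
        if mask.any():
            interior = ndi.distance_transform_edt(mask, sampling=px) > margin_um
        else:
            interior = mask
        out[name] = interior & edge
    return out


def _sample_in_mask(rng, mask: np.ndarray, px: float, hash_: _SpatialHash,
                    max_tries: int = 2000) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise RuntimeError("no admissible pixels in zone")
    for _ in range(max_tries):
        i = int(rng.integers(rows.size))
        x = (cols[i] + rng.uniform(0.0, 1.0)) * px
        y = (rows[i] + rng.uniform(0.0, 1.0)) * px
        if hash_.ok(x, y):
            return x, y
    raise RuntimeError("requested cell count unplaceable in available area")


def _place_cells(config: SlideConfig, rng,
                 masks: RegionMasks) -> pd.DataFrame:
    zone_masks = _eroded_zone_masks(masks, config.zone_margin_um,
                                    config.edge_margin_um + config.zone_margin_um)
    # Intratumoural immune cells go deep into the nests: far enough from the
    # rim that they cannot block the outermost tumour row (which would carve
    # bays into the epithelium), so the carpet encloses every inclusion.
    a_inset = config.tumour_immune_separation_um + config.nucleus_diameter_um / 2.0
    zone_masks["A"] = zone_masks["A"] & _nest_disks(config, extra_um=-a_inset)
    # Same-class neighbours may touch; tumour and immune cells keep their
    # membrane compartments disjoint (larger cross-class separation).
    hash_ = _SpatialHash(config.min_separation_um)
    cross = _SpatialHash(config.tumour_immune_separation_um)
    # Intratumoural non-tumour cells keep wide mutual spacing: each carves an
    # isolated, fully enclosed hole in the epithelium carpet (chained holes
    # would open corridors to the stroma and make zone labels ill-defined);
    # exclusion lenses of two inclusions separate above ~1.5x the cross-class
    # distance.
    hash_intra = _SpatialHash(1.5 * config.tumour_immune_separation_um)
    records = []

    def zone_of(x, y):
        lab = masks.label_image
        code = lab[int(y // config.pixel_size_um), int(x // config.pixel_size_um)]
        return {1: "A", 2: "B", 3: "C"}.get(int(code), "none")

    # 1. Non-tumour cells first: they reserve space inside the nests too.
    for phen in ("CD8_T", "CD4_T", "Treg", "CD3_only", "other"):
        n = config.n_cells_per_phenotype.get(phen, 0) or 0
        mix = config.other_zone_mix if phen == "other" else config.immune_zone_mix
        zones = list(mix)
        probs = np.array([mix[z] for z in zones], dtype=float)
        probs = probs / probs.sum()
        draw_zones = rng.choice(zones, size=n, p=probs)
        for z in draw_zones:
            mask = zone_masks[z]
            if not mask.any():  # degenerate configs: fall back to any zone
                mask = zone_masks["C"]
            for _ in range(500):
                x, y = _sample_in_mask(rng, mask, config.pixel_size_um, hash_)
                if z != "A" or hash_intra.ok(x, y):
                    break
            else:
                raise RuntimeError(
                    "requested cell count unplaceable in available area")
            hash_.add(x, y)
            cross.add(x, y)  # only tumour candidates are checked against this
            if z == "A":
                hash_intra.add(x, y)
            records.append((x, y, phen, zone_of(x, y)))

    # 2. Tumour cells on a jittered hex grid packing each nest to its rim,
    #    so the CK render reproduces the nest outline.
    n_req = config.n_cells_per_phenotype.get("tumour", None)
    tumour_pts = []
    s = config.tumour_spacing_um
    nest_margin = config.nucleus_diameter_um / 2.0
    for cx, cy, r in config.tumour_nests:
        rows = int(math.ceil(2 * r / (s * math.sqrt(3) / 2))) + 2
        for j in range(-rows, rows + 1):
            y0 = cy + j * s * math.sqrt(3) / 2
            xoff = (s / 2) if j % 2 else 0.0
            cols_n = int(math.ceil(2 * r / s)) + 2
            for i in range(-cols_n, cols_n + 1):
                x0 = cx + xoff + i * s
                x = x0 + rng.uniform(-0.5, 0.5)
                y = y0 + rng.uniform(-0.5, 0.5)
                if (x - cx) ** 2 + (y - cy) ** 2 > (r - nest_margin) ** 2:
                    continue
                edge = config.edge_margin_um + config.zone_margin_um
                if not (edge < x < config.width_um - edge
                        and edge < y < config.height_um - edge):
                    continue
                if hash_.ok(x, y) and cross.ok(x, y):
                    hash_.add(x, y)
                    tumour_pts.append((x, y))
        # Saturating infill: immune cells reserved space on the lattice and
        # would otherwise leave bare corridors in the epithelium; dart-throw
        # extra tumour cells until no admissible position remains, which
        # bounds every uncovered gap below the closing radius.
        area = math.pi * r * r
        for _ in range(int(area / 4.0)):
            rad = (r - nest_margin) * math.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2.0 * math.pi)
            x, y = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
            edge = config.edge_margin_um + config.zone_margin_um
            if not (edge < x < config.width_um - edge
                    and edge < y < config.height_um - edge):
                continue
            if hash_.ok(x, y) and cross.ok(x, y):
                hash_.add(x, y)
                tumour_pts.append((x, y))
    if n_req is not None:
        if n_req > len(tumour_pts):
            raise RuntimeError(
                f"requested {n_req} tumour cells but only {len(tumour_pts)} fit in the nests"
            )
        idx = rng.choice(len(tumour_pts), size=n_req, replace=False)
        tumour_pts = [tumour_pts[int(i)] for i in sorted(idx)]
    for x, y in tumour_pts:
        records.append((x, y, "tumour", zone_of(x, y)))

    df = pd.DataFrame(records, columns=["x_um", "y_um", "phenotype", "zone"])
    df.insert(0, "cell_id", np.arange(len(df)))
    return df


def _draw_marker_flags(cells: pd.DataFrame, config: SlideConfig, rng) -> pd.DataFrame:
    cells = cells.copy()
    for m in ("CD3", "CD4", "CD8", "Foxp3", "CK"):
        cells[m] = [m in PHENOTYPE_FLAGS[p] for p in cells["phenotype"]]
    ki67 = np.zeros(len(cells), dtype=bool)
    for i, (phen, zone) in enumerate(zip(cells["phenotype"], cells["zone"])):
        rate = (config.ki67_rate_tumour if phen == "tumour"
                else config.ki67_rate_by_zone.get(zone, 0.0))
        ki67[i] = rng.uniform() < rate
    cells["Ki67"] = ki67
    return cells


# ---------------------------------------------------------------------------
# rendering


def _stamp(arr: np.ndarray, cx_px: float, cy_px: float, r_in_px: float,
           r_out_px: float, amplitude: float):
    """Max-composite an (anti-aliased) disk or annulus into ``arr``."""
    h, w = arr.shape
    x0 = max(0, int(math.floor(cx_px - r_out_px - 1)))
    x1 = min(w, int(math.ceil(cx_px + r_out_px + 2)))
    y0 = max(0, int(math.floor(cy_px - r_out_px - 1)))
    y1 = min(h, int(math.ceil(cy_px + r_out_px + 2)))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx + 0.5 - cx_px, yy + 0.5 - cy_px)
    w_out = np.clip(r_out_px + 0.5 - d, 0.0, 1.0)
    if r_in_px > 0:
        w_in = np.clip(d - r_in_px + 0.5, 0.0, 1.0)
        weight = np.minimum(w_out, w_in)
    else:
        weight = w_out
    sub = arr[y0:y1, x0:x1]
    np.maximum(sub, amplitude * weight, out=sub)


def render_round(ground_truth: GroundTruth, marker: str, config: SlideConfig,
                 quantize: bool = True) -> StainRoundImage:
    """Render one stain round from the ground-truth cell map.

    Every cell contributes hematoxylin at its nucleus; cells positive for
    ``marker`` contribute chromogen in the marker's compartment (nuclear disk
    for Ki67/Foxp3, perinuclear ring for CD3/CD4/CD8, cytoplasmic blob for
    CK).  The round's configured misalignment and additive OD noise are then
    applied, and intensities follow the inverse of the Beer–Lambert model in
    :func:`ngi.stains.rgb_to_od`.

    With ``quantize=False`` the float intensities are returned before the
    8-bit cast (useful for noise-free round-trip checks; uint8 rounding alone
    contributes up to ~3e-3 OD).
    """
    if marker not in MARKER_PANEL:
        raise ValueError(f"unknown marker {marker!r}")
    px = config.pixel_size_um
    shape = (config.image_height_px, config.image_width_px)
    hema = np.where(ground_truth.region_masks.roi_mask,
                    config.tissue_background_od, 0.0)
    chrom = np.zeros(shape, dtype=float)

    r_nuc = config.nucleus_diameter_um / 2.0 / px
    r_ring_out = r_nuc + config.ring_width_um / px
    r_ck = r_nuc + config.ck_extra_radius_um / px
    compartment = MARKER_COMPARTMENT[marker]
    # Half-pixel saturation margin where a compartment edge is measured:
    # the anti-aliased edge falls just outside the nominal band, so
    # compartment averages sit on the amplitude plateau.  The ring's outer
    # edge gets no margin — the detected footprint sits slightly inside the
    # rendered nucleus, so the measured band is already covered, and any
    # outward extension only bleeds onto neighbouring cells.
    sat = 0.5

    cells = ground_truth.cells
    pos = cells[marker].to_numpy()
    xs = cells["x_um"].to_numpy() / px
    ys = cells["y_um"].to_numpy() / px
    amp = config.chromogen_amplitude_od
    for i in range(len(cells)):
        _stamp(hema, xs[i], ys[i], 0.0, r_nuc, config.hematoxylin_amplitude_od)
        if not pos[i]:
            continue
        if compartment == "nuclear":
            _stamp(chrom, xs[i], ys[i], 0.0, r_nuc + sat, amp)
        elif compartment == "ring":
            _stamp(chrom, xs[i], ys[i], r_nuc - sat, r_ring_out, amp)
        else:  # cytoplasmic — rendered at the nominal radius: the measured
            # compartment sits well inside the blob, and the blob edge is the
            # tumour-mask boundary, which must match the ground-truth stamp
            _stamp(chrom, xs[i], ys[i], 0.0, r_ck, amp)

    round_index = MARKER_PANEL.index(marker) + 1
    misalign = ground_truth.transforms[marker].inverse()
    if not misalign.is_identity(1e-12):
        hema = apply_transform(hema, misalign)
        chrom = apply_transform(chrom, misalign)

    od = mix_stains(chrom, hema, config.basis)
    if config.noise_sd_od > 0:
        noise_rng = np.random.default_rng([config.seed % (2 ** 31), round_index, 104729])
        od = od + noise_rng.normal(0.0, config.noise_sd_od, od.shape)
    rgb = od_to_rgb(od, background=config.background_intensity)
    rgb = np.clip(rgb, 0.0, 255.0)
    if quantize:
        rgb = np.rint(rgb).astype(np.uint8)
    return StainRoundImage(marker_name=marker, rgb_pixels=rgb,
                           pixel_size_um=px, round_index=round_index)


def _nest_disks(config: SlideConfig, extra_um: float = 0.0) -> np.ndarray:
    shape = (config.image_height_px, config.image_width_px)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    px = config.pixel_size_um
    mask = np.zeros(shape, dtype=bool)
    for cx, cy, r in config.tumour_nests:
        mask |= (((xx + 0.5) * px - cx) ** 2 + ((yy + 0.5) * px - cy) ** 2
                 <= (r + extra_um) ** 2)
    return mask


def _true_tumour_mask(cells: pd.DataFrame, config: SlideConfig,
                      roi: np.ndarray) -> np.ndarray:
    """True CK-positive epithelium of the slide.

    Defined as the tumour mask built from the *ideal* CK render (noise-free,
    perfectly aligned): the union of tumour-cell cytoplasm disks, with the
    bays and holes left by interleaved immune cells closed and filled.  Using
    the same mask builder as the analysis keeps the boundary convention of
    ground truth and measurement identical; on real data they differ by
    noise, registration error and staining artefacts only.
    """
    from .zones import build_tumor_mask

    shape = (config.image_height_px, config.image_width_px)
    px = config.pixel_size_um
    ck = np.zeros(shape, dtype=float)
    r_ck = (config.nucleus_diameter_um / 2.0 + config.ck_extra_radius_um) / px
    tum = cells[cells["phenotype"] == "tumour"]
    for x, y in zip(tum["x_um"] / px, tum["y_um"] / px):
        _stamp(ck, x, y, 0.0, r_ck, config.chromogen_amplitude_od)
    return build_tumor_mask(ck, roi, pixel_size_um=px)


def generate_slide(config: SlideConfig | None = None
                   ) -> tuple[list[StainRoundImage], GroundTruth]:
    """Generate all six stain rounds plus the ground truth behind them."""
    config = config or SlideConfig()
    rng = np.random.default_rng(config.seed)
    shape = (config.image_height_px, config.image_width_px)
    px = config.pixel_size_um
    # The tissue (and hence the ROI) is inset from the frame so that every
    # misaligned round still covers it completely.
    m = int(math.ceil(config.edge_margin_um / px))
    roi = np.zeros(shape, dtype=bool)
    roi[m:shape[0] - m, m:shape[1] - m] = True

    # Placement uses provisional zones around the *expected CK extent* of the
    # nests (nest radius + cytoplasm overhang), so margins are measured from
    # where the rendered tumour boundary will actually sit.
    placement_A = _nest_disks(config, extra_um=config.ck_extra_radius_um)
    placement_masks, _ = partition_zones(placement_A, roi,
                                         config.band_width_um, px)
    cells = _place_cells(config, rng, placement_masks)

    tumour_mask = _true_tumour_mask(cells, config, roi)
    masks, _ = partition_zones(tumour_mask, roi, config.band_width_um, px)
    lab = masks.label_image
    codes = lab[np.minimum((cells["y_um"] / px).astype(int), shape[0] - 1),
                np.minimum((cells["x_um"] / px).astype(int), shape[1] - 1)]
    cells["zone"] = [{1: "A", 2: "B", 3: "C"}.get(int(c), "none") for c in codes]
    if (cells["zone"] == "none").any():
        raise RuntimeError("generator placed a cell outside its own ROI")
    cells = _draw_marker_flags(cells, config, rng)

    transforms = {}
    for m in MARKER_PANEL:
        dx, dy, rot = config.round_misalignment.get(m, (0.0, 0.0, 0.0))
        transforms[m] = RoundTransform(dx, dy, rot).inverse()

    gt = GroundTruth(cells=cells, transforms=transforms, tumour_mask=tumour_mask,
                     region_masks=masks, config=config)
    rounds = [render_round(gt, m, config) for m in MARKER_PANEL]
    return rounds, gt
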