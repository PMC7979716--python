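# Methods

## Stain model and unmixing

Chromogenic slides obey Beer–Lambert absorption to first order: per channel,
`OD_c = -log10((I_c + 1) / (I0_c + 1))`, where `I0` is the per-channel white
point (the 99th intensity percentile unless a calibration value is given) and
the +1 pseudo-count keeps zero intensities finite. OD is clipped to
[0, `od_max` = 3]: an 8-bit camera cannot resolve denser stain. Stain amounts
add linearly in OD, so a two-stain pixel is `a·v_chromogen + b·v_hematoxylin`
with unit OD vectors `v`. Unmixing solves this 3×2 least-squares system per
pixel with the pseudo-inverse, clips negative coefficients to zero and
discards the off-plane residual. The default basis is the published
DAB/hematoxylin OD-vector pair; an AEC alternative is selectable
(`StainBasis.named("aec")`) — both are brown-versus-blue problems and the
choice is a configuration constant, not logic.

Numerical note: 8-bit quantisation alone contributes up to ~3·10⁻³ OD at the
amplitudes used, so exact round-trip checks (10⁻⁶, 10⁻³) run on the
pre-quantisation float render; the 8-bit path is held to 10⁻². With additive
OD channel noise of sd σ the per-pixel least-squares coefficient error has
sd ≈ 1.66 σ (the pseudo-inverse row norm for this basis); unmixing is
unbiased, so the error of any compartment-scale average (≥ ~100 px) is an
order of magnitude smaller, and that aggregated error is what the acceptance
checks bound at 0.02 OD for σ = 0.02 — every downstream use of the maps is a
compartment mean, never a single pixel.

## Registration and fusion

Serial rounds image the same physical section, so the transform family is a
global similarity. Registration runs on the hematoxylin component (the only
stain present in every round): a coarse rotation grid (±4°, 0.5° steps) on a
~256-px pyramid level, refinement at half resolution (0.1° steps with
parabolic sub-step interpolation of the correlation score), then a final
sub-pixel translation by upsampled phase correlation at full resolution. The
score is normalised cross-correlation over the warped footprint; a score
below 0.2 raises a registration-failure error carrying the best score.
`RoundTransform` carries a scale field with a plausibility gate of
[0.9, 1.1], but the default estimator fixes scale at 1.0: restained rounds of
one section have no magnification change, and estimating a parameter known to
be 1 only adds variance. OD maps are warped bilinearly, masks by nearest
neighbour; the analysis is restricted to the valid-pixel mask, the
intersection of all warped round footprints. The reference round defaults to
Foxp3, the first round in the staining order.

## Cell detection and phenotyping

Nuclei are segmented on the smoothed (σ = 0.75 µm) hematoxylin OD at a
half-maximum threshold (0.40 OD against the ~0.78 peak of a stained nucleus
over tissue background), split by watershed on the distance transform, and
gated by equivalent diameter (4–14 µm) and circularity 4πA/P² ≥ 0.55.
Half-maximum thresholding keeps the detected footprint congruent with the
physical nucleus, which in turn keeps the measurement compartments aligned
with where the stain actually sits.

Marker calls average chromogen OD over the marker's compartment and compare
against a fixed threshold (default 0.15 OD, closed boundary: mean equal to
the threshold is positive). Compartments are clipped to the cell's
*territory* — the nearest-nucleus (expanded-watershed) region — so a cell
never measures its neighbour's membrane stain; in dense tumour nests this is
what keeps tumour cells from inheriting CD3 from adjacent T cells.
Compartments falling entirely outside the valid-pixel mask yield an
indeterminate call; such cells are excluded from all counts and reported in
QC. Fixed thresholds keep runs deterministic; the threshold is per-marker
configurable.

Phenotype assignment is exclusive and exhaustive: CD3⁻ cells are tumour if
CK⁺ else other; CD3⁺ cells resolve to CD8_T, CD4_T, Treg or CD3_only.
Contradictory patterns (CD4⁺CD8⁺, Foxp3⁺CD8⁺ — biologically rare, usually
segmentation bleed) resolve toward the marker with the higher mean OD, ties
to CD8, and increment a conflict counter. Foxp3⁺CD3⁺CD4⁻CD8⁻ counts toward
marker-level Foxp3 density but phenotypes as CD3_only. Ki67 is a modifier
flag, never a phenotype.

## Spatial zoning

The tumour mask comes from the CK map: light smoothing (σ = 1 µm, so isolated
noise pixels cannot be welded onto the rim by the closing step), threshold
0.2 OD within the ROI, 2 µm morphological closing (bridging the sub-cellular
gaps between touching tumour cells), removal of objects under 200 µm², and
hole filling (stromal lumina and immune inclusions are intratumoural).
Closing pads by edge replication, so image borders are not eroded.

Zones: A = tumour mask ∩ ROI; B = ROI pixels with Euclidean distance to A in
(0, 30 µm], computed with the exact distance transform — not iterated
structuring-element dilation, which imposes an octagonal metric; C = the
rest. The boundary is closed (exactly 30 µm is B). Distances are
centre-to-centre in pixel units × pixel size; cells take the zone of the
pixel containing their centroid (origin top-left, x = column, floor
convention); centroids outside the ROI get zone `none` and are QC-counted.
The A/B/C partition of the ROI is asserted exactly on every construction.
The ROI is a supplied polygon when available, otherwise automatic tissue
detection on smoothed hematoxylin (≥ 0.05 OD).

## Sample metrics

Densities use *marker-level* (overlapping) positivity — a Treg contributes to
both CD4⁺ and Foxp3⁺ density — because the conventional reporting places
CD3/CD4/CD8/Foxp3 densities side by side; subset *proportions* use the
exclusive phenotypes and are fractions of CD3⁺ cells. Ki67⁺ percentages are
per marker, overall and per zone. The proliferating-immune fraction is
Ki67⁺ immune / (Ki67⁺ immune + Ki67⁺ tumour), excluding "other" cells from
the denominator. Fractions with zero denominators are missing (None), never
zero, and propagate as missing. QC excludes samples with ROI area below
100 000 µm² — an area threshold: it is the only reading of an ROI size filter
consistent with "total region of interest". sTIL dynamics between two
timepoints: any increase is `increase`, any decrease `decrease`, and `stable`
requires the identical percentage (no tolerance band) — meaningful because
pathologist sTIL scores are reported on a coarse grid.

## Statistics

All tests are two-sided at α = 0.05 unless stated; no multiplicity
correction outside SAM. Exact p-values by full enumeration: Spearman
permutations at n ≤ 8, Wilcoxon sign-flips at effective n ≤ 12 (zero
differences dropped; midranks for ties, computed on doubled integer ranks so
the enumeration is exact), Mann–Whitney labellings at n₁+n₂ ≤ 12. Beyond
those sizes: t approximation (Spearman), normal approximation with tie and
continuity corrections (Wilcoxon), and normal approximation with tie
correction but *no* continuity correction (Mann–Whitney) so that the
two-group Kruskal–Wallis χ² p-value coincides with it algebraically. Paired
mean differences report a t-distribution CI with the paired-Wilcoxon p-value
(matching the convention of pairing a parametric effect size with a
nonparametric test). Logistic odds ratios are maximum-likelihood univariate
fits (statsmodels); OR per `unit_scale` units is exp(slope·scale) with the
Wald CI on the same scale; separation and non-convergence are flagged, not
raised.

Expression counts are log2(x+1)-transformed and normalised per sample so each
sample's housekeeping-gene mean equals the grand housekeeping mean
(ACTB, MRPL19, PSMC4, RPLP0, SF3A1).

Quantitative SAM for a continuous response: per gene, d = r/(s + s0) with r
the least-squares slope of expression on sTILs and s its standard error. The
fudge factor s0 is chosen among the percentiles of {s} to minimise the
coefficient of variation of the spread (windowed MADs over s-quantile bins)
of d — the samr-style criterion; a plain CV of d is degenerate under the
null where mean d ≈ 0. The null distribution of |d| comes from seeded
permutations of the response (default 1000; fewer than 50 is refused);
FDR(t) = median over permutations of #{|d*| ≥ t} / #{|d| ≥ t} with π₀ = 1
(conservative), and a gene's q-value is the minimum FDR over rejection
regions containing it, which makes q monotone non-increasing in |d| by
construction.

## Synthetic slide generator

The generator emulates the *geometry and optics* of the assay, not tissue
realism: circular nuclei (8 µm default) on a tissue background of faint
hematoxylin uptake (0.08 OD) inset 8 µm from the frame (so every misaligned
round still covers the whole ROI); tumour nests as disks packed with CK⁺
cells (10 µm hex lattice plus saturating random infill, so interleaved
immune cells never leave bare corridors in the epithelium); immune and
stromal cells placed by zone with a 4 µm margin to zone boundaries (keeping
ground-truth zone labels well defined under the analyser's CK-derived mask);
per-marker chromogen in the marker's compartment (with a half-pixel
anti-aliasing margin on measured edges; the ring's outer edge and the CK blob
are rendered at their nominal radii so they neither bleed onto neighbours nor
drift from the truth-mask boundary); per-round global misalignment; additive
OD noise (default sd 0.02); 8-bit quantisation. Same-class neighbours may
approach to 9 µm, while tumour and immune cells keep 11.5 µm so their
membrane compartments stay disjoint — without this, adjacent membrane rings
genuinely overlap and no measurement rule can separate them, a physical
limitation of the assay rather than of the code. Intratumoural immune
inclusions additionally stay 15.5 µm inside the nest rim and ~17 µm from each
other: each then carves an isolated, fully enclosed hole in the epithelium
that hole-filling restores, whereas chained or rim-adjacent inclusions would
open corridors to the stroma and make zone labels ill-defined. These
exclusion rules bound the intratumoural immune share the geometry can
support, which is why the default zone mix places 8% of T cells in zone A,
40% in the proximal band and 52% in distal stroma, and why the default cell
budget (~400 CD3+ cells at this field size) keeps the 22 µm eroded
peritumoural band below its random-packing jamming density.

The ground-truth tumour mask is defined as the mask the builder produces on
the ideal (noise-free, perfectly aligned) CK render: generator and analyser
then share one boundary convention, and on real data the two differ only by
noise, registration error and staining artefacts. Ground-truth zones apply
`partition_zones` to that mask — one zone definition everywhere.

Defaults are chosen to sit in the regime typical of inflamed HER2⁺ breast
tumours: ~400 CD3⁺ cells per quarter-mm² field with a 47/30/11/13 %
CD8_T/CD4_T/Treg/CD3_only split, immune density highest in the proximal
stromal band, Ki67⁺ immune fractions decreasing with distance from tumour
(30/20/10 % in A/B/C), tumour Ki67 40 %. What passing tests show is that the
*pipeline* recovers known truth under this forward model; they do not show
robustness to texture, autofluorescence, incomplete stripping, section loss
or non-rigid deformation, all of which are out of scope by design.

## Synthetic cohort generator

Three timepoints per patient (baseline, day 15, surgery). sTILs are drawn
from Beta distributions rescaled to [0, 100] (HR-negative mean 15 %,
HR-positive 8 %), shifted at day 15 by +12.5 points (HR-negative) or +2.1
(HR-positive) plus N(0, 10) noise, and at surgery by −21.5 (pathological
complete response) or −0.9 (residual disease) plus N(0, 8) — the effect
structure reported for anti-HER2 window trials. Scores are rounded to the
pathologist grid (nearest 5 below 10 %, nearest 10 above), which is what
makes exactly-stable trajectories possible; the rounding adds ≤ ~0.4 points
of bias to recovered shifts, well inside the CI widths at the default n.
pCR probabilities: 0.43 (HR−), 0.18 (HR+). The expression matrix has 555
panel genes plus the 5 housekeeping genes; ten immune genes (MS4A1, PD1,
CD8A, CD19, IKBKE, IDO1, TAP1, TYMP, CD3G, LAG3) track sTILs with Pearson
r = 0.5 on the log2 scale, the rest are null. `CohortEffects.null()` gives
the zero-effect configuration for null simulations.

## Problem sizes and determinism

Every stochastic procedure takes an explicit seed and is bit-reproducible;
the slide generator derives independent per-round noise streams from the
slide seed. The shipped test and acceptance runs use one full-size
1024×1024 px slide (0.5 µm/px, ~800 cells) at noise sd 0.05, a 512 px slide
for registration and CLI checks, 20 replicates for SAM operating
characteristics (500 genes × 60 samples, 200 permutations) and 100
replicates for cohort effect recovery — sizes at which the binomial error of
the measured rates is comfortably below the acceptance margins.

## Known limitations

Two-stain unmixing only (no 3+ chromogen support); rigid/similarity
registration only — by design, since rounds are restains of one section;
fixed OD thresholds rather than learned classifiers; tile-pyramid whole-slide
formats are out of scope (pre-extracted regions only); B-cell and macrophage
lineages are absent from the panel; membrane stains of cells closer than
~11 µm physically overlap and such conflicts are resolved heuristically (and
counted), not segmented.
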