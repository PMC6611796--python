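# Methods

This note documents the models, defaults and numerical choices behind
`pktscreen`, and what the synthetic generators do and do not emulate.

## Motility model

Cells move as a constant-speed directional persistent random walk
(PRW): the speed *s* (µm/min) is fixed and the heading angle diffuses on
the circle with rotational diffusion 1/*P*, where *P* (min) is the
persistence time. The per-step direction autocorrelation is exactly
e^(−Δt/P), and the ensemble mean-squared displacement follows the Fürth
form

MSD(t) = 2 s² P [ t − P (1 − e^(−t/P)) ],

ballistic (s²t²) for t ≪ P and diffusive (2s²P·t) for t ≫ P. We chose
the constant-speed variant over an Ornstein–Uhlenbeck velocity process
because its limits are exact and interpretable: with P → ∞ the path is a
straight line of length s·Δt·n, and the mean step length equals s·Δt
whenever Δt ≲ P. An optional white angular jitter (`turn_noise`, rad per
recorded step) adds extra decorrelation.

Paths are integrated with internal substeps (up to 64, chosen so the
substep is ≲ P/16). This keeps the MSD sampled at the recording interval
within well under 1% of the continuous closed form; without substepping,
the discrete-time MSD at short lags deviates by order Δt/P (≈ 6% at
Δt = P/5), which would violate the 5% agreement the tests require.
When P ≪ Δt the recorded step length is shorter than s·Δt because the
cell turns within one interval — that is physically correct, not a bug.

Defaults: PKT assays run 7 h (`duration = 420 min`); live imaging runs
12 h at 12-min intervals (61 frames). Pixel scales default to
0.65 µm/px for the ×10 PKT montages and 0.33 µm/px for the ×20
time-lapse — the objectives are known but the original pixel pitches are
not published, so both are configurable.

## PKT montage rendering and segmentation

The renderer draws a Poisson bead lawn (default 0.19 beads/µm², bead
radius 1.2 px) on a bright background (10 000 counts), clears all beads
within `track_width`/2 of each path (default width 15 µm), places a dark
elliptical cell body at each path end, and adds Gaussian noise
(σ = 150). The ground-truth label mask marks each track's cleared
pixels; overlapping swaths are rendered but flagged as collisions so
downstream fidelity tests can restrict themselves to non-colliding
configurations. Montages stand for 6 × 6 tile acquisitions
(`n_images = 36`); no point-spread function, illumination shading or
bead-phagocytosis kinetics are simulated. Passing tests on these images
therefore demonstrate correctness of the measurement chain, not
robustness to real transmitted-light artifacts (stitching seams, debris,
uneven lawns).

Segmentation inverts the render model: dark pixels are thresholded at
0.6× the image median; pixels darker than 0.25× the median are treated
as cell bodies, not bead texture. The local bead fraction is computed in
a 15-px sliding window; windows with < 5% bead coverage mark cleared
cores (essentially impossible inside an intact lawn, where coverage is
~30%), and cores are dilated by 5 px to recover the boundary, holes
filled, regions below 50 px² removed and border-touching regions
excluded by default. On noise-on renders this recovers disjoint tracks
with IoU ≈ 0.9 against ground truth. A blank or saturated image (dark
fraction < 0.1%) yields zero regions plus a QC warning. Cell bodies are
counted per region as connected very-dark blobs of ≥ 60 px² inside the
region's 3-px-eroded interior; only regions with exactly one cell are
accepted.

Morphometry uses standard region properties: net area = pixel count,
gross area = convex-hull area, major/minor axes from second central
moments, perimeter by the 4-direction Crofton estimator (bias ≲ 0.5% on
smooth shapes, which keeps a rasterized disc's roughness at ≈ 1.008),
roughness = P²/(4πA) and solidity = A/A_hull. The minor axis is floored
at 1 px — a digital region is at least one pixel wide — so the axial
ratio of a 1-px line is finite (≈ its length) rather than infinite. The
five named parameters are complemented by gross area, perimeter and
solidity to reach eight; the roughness definition and the identity of
the three unnamed parameters are this package's documented choice and
are configurable.

## Feature-level screen simulator

`generate_screen_plates` bypasses imaging and draws per-track features
directly: log-normal net area (median 10 000 px², σ_log 0.15), major
axis (160 px, σ_log 0.12), axial ratio (1.9, σ_log 0.10), roughness
1 + lognormal(2.2, 0.12) ≈ 3.2, logit-normal solidity (≈ 0.85); minor
axis, gross area and perimeter are derived so every internal invariant
(axial = major/minor, net ≤ gross, roughness consistency) holds by
construction. Baselines mimic an elongated mesenchymal line sitting
clear of every phenotype threshold: the long-smooth rule in particular
has no Z conditions, so a baseline axial ratio near its 2.1 cut would
misclassify nulls — 1.9 with σ_log 0.10 leaves ≈ 10 SE of margin after
well-median and replicate averaging. Track counts are Poisson with mean
40/well; two mock wells sit in column 1 of every plate; the replicate
structure is 2 technical × 2 biological plates. Gene effects are
multiplicative shifts of the generative medians (net area, major axis,
axial ratio, roughness). A 0.25× net-area effect yields replicate-mean
Z ≈ −5, comfortably past the −4 "small" cut, while null genes stay at
|Z| ≈ 0.1; this is what makes the planted-recovery checks sharp rather
than marginal. Per-plate/per-well random streams are split from the
master seed with `numpy.random.SeedSequence(seed, spawn_key=...)`, so
any subset of plates is reproducible in isolation.

The simulator draws features independently across parameters (no
realistic correlation structure) and plants effects as clean location
shifts; it exercises the analysis contract exactly but says nothing
about PhagoTracker-level image variability.

## Normalization, QC and classification

Robust Z uses the pooled *track-level* median and MAD of the plate's
mock wells with the 1.4826 normal-consistency constant. Pooling at
track level is the only option that is well-defined with just two mock
wells per plate; the choice is configurable. A zero mock MAD raises an
error naming the parameter. Well QC drops wells with < 10 accepted
tracks; replicate aggregation is the arithmetic mean of the available
replicate Z-scores (minimum 2), and knockdowns are excluded with < 3
images or with summed accepted tracks below the cell-line minimum
(60 Hs578T, 150 MDA-MB-231; the minima are applied to the sum over
replicates — applying them per replicate is the other defensible
reading).

The five class rules are applied exactly as printed, conjunctively, on
replicate-averaged raw medians (quantifier-native px units) and
Z-scores; the listed order (small, small round, big round, long rough,
long smooth) gives the primary class as first match, with all matches
retained for audit. That includes the big-round axial-ratio Z < −4
condition even though it is stricter than small-round's < −3. The
threshold table is versioned (`screen-2019-print`) and overridable.
Deconvolution declares a single siRNA concordant-significant at
|Z| ≥ 2.0 on net area or axial ratio with the SMARTpool's sign; a gene
validates with SMARTpool significance plus ≥ 2 concordant singles.
The 2.0 cut operationalizes "significant" and is configurable.

PCA of the treatments × parameters Z matrix is column-standardized;
constant columns are dropped with a warning, and each component's sign
is fixed by making its largest-magnitude loading positive, so results
are deterministic up to machine precision.

## Single-cell tracking and statistics

Frames are segmented by Gaussian smoothing (σ = 1 px), Otsu
thresholding with a 6-σ foreground/background contrast guard (so pure
noise yields zero cells), a binary opening, and a watershed split of
touching blobs seeded at distance-transform maxima (≥ 15 px apart).
Linking is greedy one-to-one by decreasing pixel overlap between
consecutive frames with `min_overlap_px = 1` — any overlap links, the
literal reading of overlap-based tracking. Gaps are not bridged and
divisions are not handled specially (the larger-overlap daughter
inherits the track). Trajectories need ≥ 2 h of continuous tracking; at
12-min sampling that is ≥ 11 samples, boundary inclusive.

Speed is total path length divided by duration; directionality is net
displacement over path length (0 for a stationary cell by convention).
The dual-control comparison runs Kruskal–Wallis across knockdown,
low-density control and high-density control, then Dunn's rank-based
pairwise z tests with tie correction and Bonferroni adjustment over the
3 pairwise comparisons (Dunn's classical form); the verdict is
significant only when both knockdown-vs-control comparisons reject at
α = 0.05 (gated on the omnibus test). Groups need ≥ 5 cells, otherwise
the verdict is "inconclusive" with a reason. Medians are reported with
distribution-free 95% CIs from binomial order statistics.

The movie generator renders cells as Gaussian blobs (σ = 15 px); with
`confine_grid` set, each cell's path reflects inside its own grid
territory with a 4σ margin, which guarantees non-contacting masks for
*any* seed — the fixture used for identity-preservation tests. Folding
a path changes its shape but not the recorded ground truth, so
estimated-vs-truth speed comparisons remain exact. Real movies have
touching cells, divisions, focus drift and uneven illumination; the
tracking tests certify the linking logic, not robustness to those.

## Morphology profiling

Nuclei are the primary objects; each nucleus is assigned the cell body
containing its centroid, and orphan nuclei are flagged and rejected
downstream. Features per cell: area, Crofton perimeter, form factor
4πA/P² (clipped to 1), nucleus area, and spike count. Spikes are
counted as morphological-opening residuals: the cell core is the opening
with a disk of diameter `width_max` (30 px), and every residual
component reaching ≥ `depth_min` (5 px) beyond the core is one spike.
(A convexity-defect count with the same two parameters was considered
and rejected: for cells with few protrusions the *inter*-spike defect is
intrinsically wider than any sensible `width_max`, so defect-based
counting cannot score 3–5-spike cells; opening-based residuals measure
the protrusion itself and count correctly from 1 spike upward.)

Images with > 150 cells are dropped. Knockdown profiles are per-feature
log2 fold changes of the well median against the pooled cells of the
plate's two mock wells; zero medians (possible for counts) are floored
at 0.25 before the ratio. Profiles are clustered with SciPy's
complete-linkage agglomerative clustering on Euclidean distances; merge
heights are non-decreasing by construction of complete linkage. SciPy's
tie-breaking is deterministic for a fixed input order but is not
guaranteed to pick the lowest index; tests therefore use tie-free
configurations. Dendrograms can be serialized as Newick text with each
merge at half its linkage height (ultrametric layout).

## Problem sizes used in the checks

The acceptance checks run at desk scale, chosen to finish in about a
minute while leaving the conclusions sharp: a 13 824-point factorial
grid around every classification threshold (exact agreement with an
independent rule transcription); 100 null screen simulations for mock
self-Z calibration; 20 seeds × 80 genes (10 planted small effects at
0.25×, 70 nulls) for sensitivity/false-positive measurement; one
61-frame movie of 20 confined cells for tracking fidelity; 1000 null
and 200 alternative replicates for the dual-control test's size and
power; an exhaustive 14 406-pattern enumeration of the deconvolution
rule; and 8 knockdown wells (two archetypes) for cluster recovery. A
full ~4200-gene screen is orders of magnitude larger; nothing in the
pipeline depends on problem size except wall time.

## Known limitations

- The segmentation stand-ins (bead-fraction clearing detector;
  Otsu+watershed cells) are calibrated to the synthetic render models,
  not to real PKT or GFP imagery, and do not reproduce the original
  analysis software's internals.
- Phenotype-class thresholds are applied in the quantifier's native
  pixel units; transferring them to another magnification requires
  rescaling the raw-value cut-offs (8000 px² net area, 180/200 px major
  axis).
- The simulators plant location-shift effects with independent feature
  noise; correlated multi-parameter phenotypes (e.g. small *and* round)
  are expressible but not calibrated against real screen covariances.
- Manual curation steps of real screens (visual phenotype review) are
  out of scope; classification here is purely rule-based.
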