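# Methods

## Colony branching process

A colony grows from one founder by synchronous binary divisions for
`generations` rounds (default 14, ≈1.6×10⁴ final cells — past the point
where a newly founded sector is large enough to score). At every division of
an *unswitched* cell, a loss-of-silencing event occurs with probability
`p_div` and permanently recombines the reporter cassette. Switched state is
heritable and irreversible; the excised DNA carries no origin of
replication, so reversion is not modeled. The founder itself may already be
switched at plating with probability `q_pre` (escape from drug
pre-selection), producing a fully green colony.

Two timing models are provided:

- **simple** (default): an event switches exactly one progeny, mother or
  daughter with probability ½ each. Live imaging showed no obvious
  mother–daughter bias, and this choice makes the expected half-sector
  frequency equal `p_div` exactly.
- **cell_cycle**: the event time is drawn uniformly in the cycle. An event
  before DNA replication (probability `f_pre_replication`, default 0.25 —
  a free parameter, not an inferred value) recombines the single cassette
  and both progeny inherit the switch; an event after replication acts on
  one of the two sister cassettes, switching exactly one progeny.

### Colony classification

Classification is event-based, matching the generative definition of each
phenotype rather than a pixel count:

- **full_green** — founder pre-switched, a both-progeny event at the first
  division, or the whole colony switched within the visible horizon;
- **half_sector** — a single-progeny event at the first division;
- **partial_sector** — any other event within the visible horizon;
- **red** — no events within the visible horizon.

Events after the **visible horizon** (default generation 6) never affect
the class: the sectors they found are too small to score, mirroring real
colonies in which small sectors need not reach the colony edge. A colony
with a first-division event plus later events in the other half is still
scored half-sectored — the half-green/half-red signature remains
recognizable, and this convention is what makes the estimator unbiased at
mutant-level rates (at 0.055 per division nearly every colony carries some
later event; disqualifying them would bias the estimate downward ~40% and
destroy the published fold-changes). For *rendered images*, where only a
green-pixel fraction is available, `classify_by_fraction` implements the
banded alternative (half = 0.5 ± 0.05 by default).

### Population sampler

`simulate_population` tracks only the number of unswitched cells per
generation: with `u` unswitched parents, the number of events is
Binomial(`u`, `p_div`) and (in cell_cycle mode) the both-progeny subset is
Binomial(events, `f_pre_replication`), so `u' = 2u − events − both`. Since
switched lineages double freely, the final green fraction is
`1 − u_G / 2^G`. This is O(generations) per colony batch and fully
vectorized across colonies; the explicit-tree backend (O(2^G) per colony)
remains available and the two are tested to agree in distribution.

### Switch-pattern taxonomy

For cell-cycle-mode events the classifier reproduces the live-imaging
taxonomy: bud stage at first detectable reporter signal × which progeny
remain green. Signal appears `gfp_delay` cycle fractions after the event
(default 0.5 — maturation of the fluorophore takes a substantial fraction
of a cycle). Bud emergence is tied to the start of replication
(`f_pre_replication`) and the small→large bud transition to
`large_bud_fraction` (default 0.7); detection past cytokinesis scores as
unbudded. Eight of the nine stage × progeny combinations carry the
conventional numbers 1–8; a large-budded cell with both progeny green falls
outside the numbered set and is returned with `number=None`. Pattern 3
(unbudded, both green) is labeled but deliberately not assigned a
mechanism. By construction — and verified by property test — both-progeny
patterns arise only from pre-replication events and single-progeny patterns
only from post-replication events.

## Rate estimation

`half_sector_frequency` evaluates
`half_sectored / (total − fully_green)`; a non-positive denominator raises
a degenerate-plate error. Partial sectors are tallied but never enter the
estimator. Replicates are summarized as mean ± sample (n−1) SD. Design
choices:

- **Student's t** is two-sided and equal-variance (the classical reading;
  with n = 3 per group Welch degrees of freedom are ill-behaved). Zero
  pooled variance is handled explicitly: equal means → t = 0, p = 1;
  different means → ±∞, p = 0, flagged degenerate. No multiple-testing
  correction is applied; raw p values are reported.
- **Fold-changes** are ratios of replicate means with a first-order
  delta-method SE (reported as plumbing, not an inference procedure).
- **Bootstrap CI** (optional): percentile bootstrap, default 2000
  resamples, redrawing each plate's (half, fully green, other) tally from a
  multinomial at observed proportions — i.e. resampling colonies within
  replicates.

## Synthetic smFISH data

Per-cell transcript counts come from three families chosen to span the
observed regimes: Poisson for a constitutively transcribed control gene;
negative binomial parameterized by (mean, variance) for the derepressed
reporter — the minimal two-moment overdispersed family, an explicit
assumption since only mean and variance are reported for that regime; and a
zero/expressing mixture for a bistable locus, with `pi_expressed` the
fraction of expressing cells and the expressed-component mean defaulting to
overall-mean / `pi_expressed`. A negative binomial with variance ≤ mean
falls back to Poisson with a logged warning.

Stacks emulate 60× widefield acquisition: 0.13 µm pixels, 0.2 µm z step,
lateral PSF σ 0.15 µm with axial σ = 2× lateral (typical widefield
anisotropy), constant background 10 with additive Gaussian noise σ 10 and
spot amplitude 100 (peak SNR 10) by default; Poisson shot noise is
available. Cells are non-overlapping ellipses (semi-axes ~N(2.2, 0.25) µm)
placed by bounded rejection sampling with a gap of at least
max(2, `min_separation`) pixels, so the optional 3D spot-separation floor
(used for detector validation) holds across cell boundaries as well as
within cells. Each transcript is rendered as an anisotropic 3D Gaussian at
a uniform position inside its cell's footprint and a uniform z away from
the stack faces; an optional `false_spot_rate` adds background blobs
emulating autofluorescent off-cell signal (default 0). Ground truth —
per-cell counts and sub-voxel centroids — is retained for scoring.

What the generator does **not** emulate: optical aberrations, spectral
bleed-through, photobleaching, z-dependent background, clumped or budding
cell geometry, segmentation error (masks are exact), or transcription-site
aggregates. Passing tests therefore demonstrate correctness of the
detection machinery under the stated optics, not robustness to every
artifact of real microscopy.

## Spot calling

The filter is a sign-flipped 3D Laplacian of Gaussian with per-axis voxel
sigmas converted from µm, implemented as separable correlations with
explicitly zero-sum second-derivative kernels, so a constant image yields
exactly zero response (to float roundoff) despite kernel truncation. The
response is scaled by the lateral voxel sigma squared so peak height tracks
blob amplitude.

Detection applies a fixed threshold — stored once per channel per
experiment and reused across samples — and groups voxels by
26-connectivity (the standard for 3D blobs). Components outside the
admissible size range (default [4, 200] voxels, derived from the default
PSF: a matched spot occupies ~30–60 voxels above threshold) are discarded.
A component with several distinct local maxima, each above 30% of the
component peak, is split by watershed into one call per maximum; this is
what resolves transcripts that overlap in a 2D projection but are separated
along z. Centroids are intensity-weighted over the (split) component in
voxel coordinates, z first, origin at the stack corner.

The optional threshold helper proposes median + k·MAD of the filtered
response (raw MAD, k = 8 by default). It is a convenience; the threshold is
otherwise explicit user input, since the published procedure did not state
its selection criterion.

Spots are assigned to the cell label under the rounded x–y of the centroid;
label-0 (background) calls stay in the spot table but leave per-cell
counts, and cells without spots count zero. Summaries report mean,
sample variance, % cells > 0 and > 1 spots, and the dispersion index
(variance/mean — 1 under Poisson). Detection is scored by one-to-one
greedy closest-first matching within a radius (default 3 voxels); greedy
matching is verified against exhaustive optimal assignment on small
fixtures.

## Plate rendering and counting

Colonies are disks (radius ~N(18, 2) px) placed without overlap; sector
classes render as bright wedges on the GFP channel (half = 180°, partial =
60°, full = 360°) and red colonies stay at background. Total counting
thresholds a channel in which every colony is bright (the composite),
labels 8-connected components, and discards components below a minimum area
(default 20 px, a noise guard). Touching colonies merge — a documented
limitation of component counting. Half-sector scoring from images is
deliberately not automated, matching the manual scoring of such assays.

## Reproducibility and numerics

Every stochastic operation requires an explicit seed or Generator; there is
no global RNG state. Orchestrated runs derive all per-stage streams from
one master seed via `SeedSequence.spawn`, log the config hash, and stamp it
into output CSVs, so identical configs give byte-identical outputs.

Problem sizes used by the test suite and acceptance script — 3 replicates
of 2×10⁵ colonies per strain, and ten 25×448×448 stacks of 30 cells (300
cells total) for the FISH round trip — were chosen so Monte-Carlo error is
well below the published precision of each quantity while a full run stays
in the tens of seconds on a laptop.

## Known limitations

- Colony geometry is non-spatial; sectors exist only as lineage fractions
  (wedges in the idealized renderer). Genetic drift at the growth front,
  nutrient gradients and 3D colony structure are out of scope.
- Re-establishment kinetics of silencing are not modeled: the reporter
  switch is permanent by design, so the simulator measures loss rates only.
- The cell-cycle timing model treats `f_pre_replication` and `gfp_delay`
  as free parameters; they position the pattern mix but are not fitted.
- The negative-binomial choice for overdispersed counts is a stand-in
  constrained only by the two reported moments.
- Whether published replicate spreads are SDs over replicate frequencies is
  assumed, not verifiable from the available text; sample variance (n−1) is
  assumed throughout.
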