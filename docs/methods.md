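# Methods

## The problem

Volume electron microscopy of the visual thalamus (lateral geniculate
nucleus, LGN) yields reconstructions of synaptic boutons whose axons of
origin — retina, cortex, brainstem, inhibitory sources — cannot be labeled
directly. Two morphological observables remain: the appearance of
mitochondria inside the bouton (light vs. dark vs. none) and the
reconstructed bouton volume. `boutonsort` implements a quantitative
workflow that turns these observables into putative-origin labels and then
quantifies how selectively the resulting input types innervate individual
dendrite segments.

The workflow has four stages:

1. **Unbiased terminal sampling (UTS).** A 3-D array of stereological
   counting frames collects a volume sample of boutons free of size bias.
2. **Mixture modeling.** Within each mitochondria family (LM = light
   mitochondria, retinal; DNM = dark-or-no mitochondria, non-retinal) the
   volume sample is modeled as a finite mixture of normals; the component
   count is chosen by the highest BIC.
3. **Cutoff estimation and classification.** Volume boundaries between
   adjacent components are estimated by Monte Carlo simulation (with an
   analytic crossing as oracle) and applied as half-open bins to label each
   bouton LM1–4 or DM1–5, mapped to putative origins.
4. **Selectivity analysis.** Per-segment terminal itemsets are mined for
   pairwise association rules (support, confidence, lift) and summarized as
   a confidence-weighted directed network ranked by outstrength.

Because the original tissue stacks are terabyte-scale and manually
annotated, the package ships a synthetic-data module that generates all
inputs with known ground truth; every stage is exercised end-to-end against
that ground truth.

## Default mixture specifications

The frozen defaults encode the published subpopulation structure: four LM
components and five DNM components. Component weights follow the printed
subpopulation shares renormalized within each family — DNM shares
37/21/12/9/2 % of all terminals become 37/81, 21/81, … of the family; LM
shares 6.8/8.6/1.5 % become 0.402/0.509/0.089. Two choices were open:

* The printed LM shares sum to 16.9 % of all boutons while the overall LM
  fraction is quoted as "about 18 %"; the defaults follow the
  per-subpopulation shares (the overall fraction is exposed separately as
  `DEFAULT_LM_FRACTION = 0.18`).
* The combined 1.5 % share of the two largest retinal subpopulations is not
  split in print; the defaults fix it at 0.060/0.029 within the family,
  a roughly 2:1 ratio consistent with the larger type being the rarer.

Means and SDs are not printed, so they were derived **once** by numeric
search and frozen as constants: SDs are set by a fixed rule (half the
distance from a provisional component center to its nearest cutoff, which
places each published cutoff roughly two SDs from both neighboring means),
then means are solved sequentially so that every adjacent weighted-density
crossing equals the published cutoff (LM: 1.31, 3.34, 7.22 μm³; DNM: 0.22,
0.39, 0.75, 1.95 μm³) to machine precision before rounding to 4 decimals.
The two-SD placement makes the components as resolvable as the published
frequency histograms show them to be — distinct modes with overlapping
tails. The derivation script is not rerun at runtime; tests assert the
closure property (crossings within ±0.05 μm³ of the published values).

Volumes are necessarily positive, so draws are resampled until positive
(zero-truncated normals). Every default component has less than 1 % of its
normal mass below zero, so the truncation shifts component means by well
under 2 % — a documented, negligible bias relative to the untruncated
model used for the crossing calibration.

## EM fitting and BIC selection

Mixtures are fitted on raw volumes (not log volumes: both normality and
lognormality are rejected for such data, and the subpopulation model treats
components as normal on the raw scale). Two 1-D variance structures are
scanned — equal variance across components and free per-component variance
— for k = 1..9 (`k_max=9` by default; the upper end is generous relative
to the 4–5 components the families contain). The selection criterion is

    BIC = 2·loglik − p·ln(n),  p = (k−1) + k + (k or 1),

with the highest BIC winning (mclust sign convention).

Numerical choices:

* variance floor 1e-6 μm⁶ against singular components;
* convergence when the relative log-likelihood change drops below 1e-8, or
  after 1,000 iterations;
* 10 restarts per fit: evenly spread quantile initialization, a 1-D
  k-means solution (k-means++ seeded — this reliably isolates small,
  well-separated components such as the ~3 % largest-retinal cluster), and
  8 random quantile spreads. Restarts are screened with 100-iteration EM
  runs and the best by log-likelihood is polished to full tolerance
  (the em-EM strategy); k = 1 is closed-form.
* components are reported sorted by mean; the per-iteration log-likelihood
  trace is kept on the fit object, and tests assert it never decreases.

All randomness descends from one explicit seed per call via
`numpy.random.SeedSequence` spawning, so BIC tables are bit-reproducible.

## Cutoff estimation

The boundary between two adjacent weighted normal components is defined
analytically as the crossing of w₁N(x; μ₁, σ₁) and w₂N(x; μ₂, σ₂) — the
point minimizing expected misclassification. For σ₁ = σ₂ the crossing is
unique and returned wherever it lies; for σ₁ ≠ σ₂ the log-density equality
is quadratic and the root inside (μ₁, μ₂) is returned, with an error
reporting both roots when neither falls in the interval.

The Monte Carlo route mirrors the published procedure: per iteration, each
component is simulated with 5× its observed cluster size (round(wᵢ·n),
relative sizes kept constant; draws truncated at zero like the generator),
and the per-iteration cutoff is the threshold minimizing total
misclassification between the two simulated samples, scanning midpoints of
the sorted pooled sample with ties broken toward the smallest threshold.
The reported boundary is the mean over R = 10,000 iterations with the
across-iteration SD alongside. What the published procedure calls a
per-simulation "cutoff" is not defined further; the minimum-
misclassification threshold was chosen because its expectation is exactly
the weighted-density crossing, which the tests verify (agreement within 2 %
for every adjacent default pair). The analytic route is also exposed as a
faster `--method analytic` option.

Classification uses half-open bins [low, high): a volume equal to a
boundary goes to the upper bin. The boundary convention is unstated in
print; half-open bins make the partition exact and reproducible. The F2
flag (pre- and postsynaptic appendage profile) is carried through but does
not affect volume classification. The origin map (LM1–4 → retinal, DM1 →
corticothalamic, DM2 → brainstem, DM3/DM4 → inhibitory, DM5 → RLD) is a
configurable table, since these attributions are putative.

## Stereological sampling

The sampling array defaults to the published design: six 15 × 15 grids of
2.5 μm counting frames on reference sections 33 sections apart (2.475 μm at
75 nm section thickness), 1,350 locations in all, of which a seeded uniform
draw examines a fraction (0.5 → exactly 675). A figure legend elsewhere
quotes 1,364 locations; the arithmetic value 6 × 15² = 1,350 is used.

Each frame is a classical unbiased counting frame. The design statement
"two inclusion and two exclusion sides" leaves the assignment open; the
implementation uses the standard convention — right and top edges include,
left and bottom edges exclude, with the forbidden line extended infinitely
upward from the top-left corner and downward from the bottom-right corner.
Frames are half-open [x₀, x₀+w) × [y₀, y₀+w) in 0-based voxel coordinates,
and the forbidden line sits just outside the frame's first column and row
(between voxel columns x₀−1 and x₀). With this discretization a plane tiled
by frames counts every connected blob exactly once, which the tests verify
by brute-force enumeration; two independent array placements on the same
stack give statistically indistinguishable volume samples.

A synapse whose blob intersects two reference sections is credited to the
lower-index grid only (logged); locations whose frame lies entirely within
a soma mask are tallied as `soma` and not sampled.

## Synthetic data: what it emulates and what it does not

* **Bouton populations** reproduce the mixture structure, family split and
  ground-truth component labels. They do not model measurement error of
  manual tracing, partial-volume effects at stack borders, or any
  correlation between volume and mitochondria appearance beyond the family
  split.
* **Segment datasets** reproduce the three cell classes (default counts
  43 X-like, 37 Y-like, 7 interneuron segments, matching the study's
  dataset sizes), branch-order caliber statistics (primary 1.09 ± 0.25 μm,
  secondary 0.75 ± 0.18, tertiary 0.66 ± 0.04), flag exclusivity (triads
  never with dendrodendritic puncta adherentia), and a tunable
  retinal/cortical segregation strength ε on X-like segments: with
  probability ε a segment hosts retinal (LM) or corticothalamic (DM1)
  terminals but not both; ε = 0 draws terminals independently. The default
  ε = 0.9 reflects the near-complete segregation reported on X-like arbors
  (lift ≈ 0.25 rather than exactly 0). Terminal counts per segment are
  Poisson (mean 8, minimum 1); spatial position along the segment is not
  modeled, so proximal/distal gradients are out of scope.
* **Label stacks** place non-overlapping spherical blobs with unique
  16-bit ids at 5 × 5 × 75 nm voxel anisotropy and Poisson counts. Blobs
  are geometric markers only — no EM texture, no membranes, no partial
  synapses at borders.

Consequently, passing tests demonstrate that the *statistical machinery*
(sampling unbiasedness, component recovery, cutoff estimation, selectivity
detection) behaves correctly under the stated generative model; they do not
validate the biological attributions or the performance under annotation
noise absent from the generator.

## Association analysis

Each dendrite segment is one transaction; items are terminal types with
retinal subpopulations grouped into a single LM item by default. The
published "95 % confidence interval" frequency filter is under-specified;
it is operationalized as a per-segment share threshold: on segments with at
least 40 terminals, a type contributing under 2.5 % of that segment's
terminals is dropped from the itemset. Both parameters are exposed; the
rule reproduces the stated effect (rare occurrences excluded only on
heavily innervated segments) transparently. Support, confidence and lift
are exact integer-count ratios; the rule table reports every ordered pair
(no thresholds), while the network applies a configurable pair-support
threshold (default 0.1) before summing outgoing confidences into
outstrengths.

## Statistics wrappers

Mann–Whitney U, Kruskal–Wallis and D'Agostino–Pearson tests delegate to
scipy. Dunn's post-hoc comparisons after Kruskal–Wallis are computed
directly (rank z-statistics with tie correction, Bonferroni adjustment),
as no post-hoc package is a dependency.

## Problem sizes used in tests

The test and acceptance workloads run at desk scale: family sample sizes
190 (LM) and 858 (DNM) as documented for the unbiased dataset; 20 seeded
replicates for model-selection checks; R = 10,000 Monte Carlo iterations at
multiplier 5 for cutoff estimation; synthetic stacks of 400 × 400 × 100–120
voxels with ~700–900 synapses; 200–300 segments for selectivity recovery.
The full suite completes in a few minutes on one CPU.

## Known limitations

* The calibration fixes means/SDs from printed cutoffs and shares; the
  true empirical components could differ in shape (skew, heavier tails).
* BIC selection at n = 190 with two components under 7 % weight is
  intrinsically marginal: single seeds can prefer 3 or 5 components, which
  is why recovery is asserted as the modal choice over 20 seeds.
* The Monte Carlo cutoff estimator carries a small finite-sample bias
  (≤ ~1.7 % on the sparsest default pair), inherited from the empirical
  minimum-misclassification threshold and its smallest-threshold
  tie-break; it vanishes as cluster sizes grow and stays within the 2 %
  oracle-agreement band at the documented sizes.
* The segment generator draws terminal types i.i.d. within a segment, so
  presence-lift under independence is only asymptotically 1 (shared
  terminal-count variation induces mild positive dependence); the [0.8,
  1.2] recovery band accounts for this.
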