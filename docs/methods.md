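# Methods

This note documents the generative models behind `neuroscreen.synth`, the
quantification operators they validate, the statistical procedures, and the
numerical design decisions. Nothing here states an empirical claim that is
not recomputed by the test suite or by `scripts/acceptance.py`.

## 1. Synthetic microscope fields

`OpticsParams` fixes the acquisition model: field size (default 256 x 256 px),
lateral sampling 0.65 um/px, constant background (10 a.u.), optional Gaussian
point-spread blur, Poisson shot noise on the signal and Gaussian read noise
(SD 2 a.u.). `noise_free()` disables the stochastic terms; ground-truth
equivalence checks run on noise-free fields so every deviation is
attributable to the measurement operator, not to noise.

`make_field_truth` plants, per field:

- **Somata** at integer pixel positions with a minimum separation (default
  26 px) and an edge margin, by rejection sampling.
- **Neurite arbors**: each cell grows `neurites_per_cell` polylines with a
  target arc length drawn from `neurite_length_um`. Segments advance along
  the 8 lattice directions (multiples of 45 degrees) with integer-pixel
  vertices and turns restricted to +/-45 degrees per segment.
- **Degeneration fragments, aggregates, reporter puncta**: small discs
  (radius ~1.4 px) placed in annuli around their cell with minimum mutual
  separation and clearance from previously rendered structures.
- **Identity flags**: TH-positive and marker-positive labels are Bernoulli
  draws per cell (`frac_th`, `frac_marker_positive`); a fraction of the
  mCherry puncta are dual-positive (GFP+), never more than the mCherry
  count — the tandem autophagy reporter loses GFP, not mCherry, upon
  acidification.

**Why lattice-direction neurites.** Downstream length measurement uses the
classical chain-code estimator (orthogonal skeleton steps count 1, diagonal
steps sqrt(2)). That estimator has a known digitisation bias of up to ~8%
for lines at intermediate angles, which would make a 3% ground-truth
tolerance unattainable for arbitrary-angle polylines. Restricting planted
segments to 45-degree multiples with integer vertices makes the rasterised
chain length equal the planted arc length exactly, so the tolerance tests
the operator (thresholding, skeletonisation, component filtering), not the
estimator's angle bias. The bias remains a documented limitation for real
images with arbitrary orientations.

**Why stroke-overlap rejection.** Near-parallel strokes from different
cells that touch would fuse into one thick ribbon whose skeleton collapses
to a single line, silently halving measured length. Candidate neurites
whose dilated stroke would touch existing structures (outside the cell's
own soma zone) are redrawn (up to 40 attempts, best candidate kept).

Rendering (`render_field`) draws per channel: nuclei as Gaussian blobs
(sigma 3 px), somata as discs, neurites as anti-aliased polylines,
fragments/aggregates/puncta as discs; TH and generic marker channels use a
5 px soma disc so a positive cell's nucleus footprint is fully covered.
Signal is max-combined, then blur, background, shot noise, read noise.
`FieldImage` round-trips through multi-page TIFF; `FieldGroundTruth`
round-trips through a JSON sidecar that carries the render seed, so a
re-render of parsed truth is bit-identical.

## 2. Plate simulation (table and image fidelity)

A screening run is a list of `CompoundEffect`s — `viability_fraction`
(multiplies surviving cells) and `th_ratio_multiplier` (multiplies the
TH/TUJ1 ratio) — laid out on standard 384-well plates: `dmso_per_plate`
vehicle wells head each plate, compounds occupy `n_replicates` adjacent
wells (default duplicate), runs spill onto further plates, and **all unused
wells are filled with vehicle**. With only 16-32 DMSO wells the null mean
and SD are themselves noisy enough to inflate the 2-SD flag rate well above
its nominal level on some plates; vehicle-filled spare wells are standard
screening practice and stabilise the null estimate (a 273-compound
duplicate run yields 222 DMSO wells across its two plates).

Table fidelity draws per-well summary measurements directly:

    nuclei  = round(cells_per_well * viability * exp(N(0, nuclei_cv)))
    ratio   = max(0, baseline_ratio * multiplier * (1 + N(0, ratio_cv)))
    th      = ratio * tuj1_intensity        (ratio identity exact)

with defaults `cells_per_well` 2000, `baseline_ratio` 0.30, `ratio_cv` 0.10,
`nuclei_cv` 0.05. Every well has an independent reproducible substream
(`SeedSequence(seed, spawn_key=(plate, crc32(well_key)))`; CRC32 rather than
Python's `hash`, which is salted per process). Image fidelity renders
fields per well with the compound's TH multiplier applied as channel gain
above background, leaving planted geometry untouched.

## 3. Image quantification

- **Nuclei**: global Otsu threshold (a featureless channel yields an
  unreachable threshold and zero cells), hole filling, minimum area 20 px,
  optional distance-transform watershed split of touching nuclei
  (peak separation 5 px). Cell ROIs expand nucleus labels outward by
  `roi_radius` (10 px) with nearest-nucleus assignment.
- **TH/TUJ1 ratio**: each channel thresholded independently, mean
  supra-threshold intensity over its own mask; per-field ratios averaged
  over fields with TUJ1 signal (NaN when none).
- **Neurite length**: threshold, skeletonise, drop skeleton components not
  longer than `branch_cutoff_px` (6 px), chain-code length (1 / sqrt(2));
  per-cell credit by nearest planted soma.
- **Axon degeneration index**: 1000 x (number of fragmented spots) /
  (total marker-positive area in um^2); spots are components within a
  3-60 px^2 area window whose skeleton is no longer than the branch cutoff.
- **Aggregates**: supra-threshold particles of >= 4 px^2, assigned to the
  ROI under their centroid; per-cell counts with mean +/- SEM helper.
- **Marker positivity**: percent of cells whose mean intensity over the
  nucleus mask reaches the threshold (default 50 a.u.).
- **Autophagic flux**: mCherry puncta from a white top-hat (disk radius 3)
  with prominence 30 and a 2-40 px^2 size window; a punctum is GFP+ iff the
  GFP top-hat on its own footprint exceeds the same prominence. The
  per-cell GFP+/mCherry+ ratio is therefore <= 1 by construction; cells
  with no mCherry puncta are excluded and listed.

## 4. Screen analytics

Null statistics are the sample mean/SD (n-1) of DMSO well ratios and the
mean DMSO nuclei count. Toxicity is strict: a well is toxic iff
`nuclei < (1 - 0.30) * mean_nuclei` ("more than 30%"); a compound with any
toxic well is discarded entirely. Hits use the duplicate-mean ratio:
z = (mean - null_mean) / null_sd, hit iff |z| > 2, restricted to the
increase direction by default. Because the duplicate mean has SD
sigma/sqrt(2), this compound-level rule flags ~0.5% of null compounds,
while individual wells exceed the 2-SD band at the textbook ~4.6% two-sided
rate; `well_exceedance_fraction` reports the latter as the rule's
per-measurement operating characteristic. Dose-response validation is a
classical one-way ANOVA over dose groups (>= 3 groups, >= 2 replicates
each; identical values give F = 0, p = 1) plus a Spearman rank trend of
group means versus dose.

## 5. Proteomics

The simulator works in log2 space: baselines N(25, 2); a planted
differential fraction (default 0.2, 90% up) shifts the mutant mean by
+/- `effect_size`; a restored fraction (default 0.5 of differential) has
its drug-group mean returned to control; i.i.d. N(0, noise_sd) per sample;
optional missing-completely-at-random dropout; quality flags planted on
non-differential rows only so flag filtering never removes planted signal.
Group sizes default to (3, 3, 2) — control, mutant, mutant + drug.

Analysis: parse the MaxQuant proteinGroups dialect (zero intensity =
missing; log2 of missing stays NaN, never -inf), drop flagged rows, keep
proteins with >= 2 valid values in >= 1 group, then a permutation one-way
ANOVA: the same label permutation is applied to every protein per round
(preserving between-protein correlation), and
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). Permutations that reproduce
the observed *partition* of samples — including swaps of the two
equal-sized groups, which leave F numerically unchanged — are rejected and
redrawn; without this the floor 1/(n_perm + 1) is unattainable at design
(3, 3, 2) because the control/mutant relabelling always ties F_obs. Welch
t contrasts (mutant-control, drug-mutant, drug-control) are computed
alongside because the groups are unbalanced.

Classification: dysregulated = ANOVA significant AND mutant-vs-control
Welch p < alpha AND |log2 fc| >= 0.5. The fold-change floor is a standard
volcano-plot guard: at n = 3 per group a bare p cutoff admits minuscule
but statistically significant shifts, which hurts precision against a
planted effect-size-based truth; both the ANOVA gate (`require_anova`) and
the floor (`min_abs_log2fc`) are configurable, including off. Restored =
dysregulated AND drug-vs-mutant Welch p < alpha with opposite sign AND
|drug mean - control mean| <= (1 - restore_fraction) x |mutant - control|
(default: at least halfway back). Restored is a subset of dysregulated by
construction.

Clustering z-scores each row (population SD; constant rows map to zeros;
optional row-mean completion of missing values, otherwise an error) and
applies average-linkage agglomeration on Euclidean distances
(`scipy.cluster.hierarchy`); tests verify the exact merge sequence and
heights against a brute-force O(n^3) reimplementation. Over-representation
is the upper-tail hypergeometric probability per gene set (sets clipped to
the universe, query must be a subset of the universe) with
Benjamini-Hochberg adjustment across sets.

## 6. Reproducibility

All stochastic procedures take explicit integer seeds; derived stream seeds
stay below 2^31. `permutation_anova` is deterministic in its seed, plate
tables in the `PlateSpec` seed (per-well substreams), field geometry and
rendering in the truth seed. `scripts/acceptance.py --seed S --out F`
recomputes every headline quantity from scratch; identical seeds give
byte-identical output.

## 7. What the generators do and do not emulate

Emulated: plate layout with vehicle controls and duplicates, compound
viability/ratio effects, multiplicative measurement noise, microscope
background/shot/read noise, MaxQuant-style missingness and quality flags,
full pharmacological rescue of restored proteins.

Not emulated: spatial plate effects (row/column/edge gradients — no B-score
correction, noted as an extension point), cell-to-cell ratio heterogeneity
within a well, optical crosstalk between channels, partial drug rescue,
intensity-dependent (MNAR) missingness, protein-protein correlation
structure, isotope/charge-level artefacts. The lattice-direction neurite
geometry (Section 1) trades angular realism for an exact length oracle.
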