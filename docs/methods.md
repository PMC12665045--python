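# Methods

## Connectivity probability and graph construction

The pipeline's primitive observation is a streamline count table: for each
seed region A, probabilistic tractography launches a fixed number of
streamlines (`voxels_per_roi × seeds_per_voxel`; 20 × 5000 = 100 000 under
the synthetic defaults) and records how many reach each target B.  The
connectivity probability `CP(A→B)` is the simple count ratio, so it is
scale-free in the number of launched streamlines and bounded in [0, 1],
attaining 1 exactly when every streamline connects.  No pathway-length
correction is applied: the dependence of streamline survival on distance is
multifactorial (crossing bundles, region sizes, bundle geometry) and no
single correction is defensible, so long-range attenuation is instead made
visible by the log₁₀ display transform (zero entries are masked, not −∞;
base 10 so color scales read in decades — the base is recorded in run
metadata).

Tractography is directional, so the seed-block CP matrix is asymmetric,
while degree/clustering/betweenness presuppose an undirected graph.  The
two directed estimates of a pair are reconciled before thresholding;
**max-symmetrization is the default** (a tract detected from either seeding
direction is evidence of the same anatomical connection), with `mean` and
the alias `directed_or` selectable, and the mode recorded in metadata.
Edges require CP *strictly greater than* the threshold `th`; the default
`th = 0.5` is the value used for all hub-rank analyses.

## Hub ranking

Degree, local clustering coefficient and betweenness centrality are
computed on the binary adjacency.  Betweenness sums over unordered node
pairs with no normalization constant; disconnected pairs contribute 0
(internally delegated to networkx and verified exactly against a
brute-force path-enumeration oracle in the test suite).  Two numerical
conventions the definitions leave open:

* **CC for degree < 2 is set to 1.0** (not the common 0.0).  Because low
  clustering is scored as hub-like, CC = 0 would catapult isolated and leaf
  nodes to the top of the CC ranking; assigning the maximally clustered
  value pushes degenerate nodes to the bottom, reserving low CC for genuine
  integrator nodes.
* **Ties receive the mean of the tied rank positions** (fractional ranks):
  deterministic, order-independent, and it preserves the rank-sum invariant
  Σ ranks = N(N+1)/2.

The hub rank is the mean of the three per-measure ranks (each in 1..N, N
most hub-like).  Relative hub rank divides by N, making the 27-node AAN
graph comparable with the 85-node whole-brain graph.  The whole-brain graph
is assembled from the symmetrized 27×27 seed block plus seed↔cortical edges
thresholded from the directed seed→cortical CP; cortical↔cortical edges are
structurally absent because no streamlines are seeded from cortex, and
cortical nodes are therefore target-only.

## Short/long-range profiling

Distances are Euclidean distances between ROI barycenters — unweighted
means of a label's voxel-center world coordinates (mm), with every voxel
weighted equally (binary manual annotations) and no resampling; volumes
are used in whatever space they are provided, with the space name recorded
from config.  A connection is short-range when its distance is ≤ `thQ` and
long-range otherwise; only connected pairs are counted (the pair must pass
the band's CP interval).  `thQ` has no canonical value; the default is the
subject's **median off-diagonal pairwise barycenter distance**, which
adapts across fetal and adult brain sizes, and an absolute `--thq-mm`
override is accepted and recorded.  CP bands are half-open intervals
(0.3, 0.5], (0.5, 0.7], (0.7, 1.0] so every suprathreshold edge falls in
exactly one band; band membership is tested on the symmetrized CP so the
partition and per-band degree identities hold exactly.

## Developmental typing

Presence of a directed connection in a subject means CP strictly above
`th_present` (default 0.2).  Typing is **directed** — no symmetrization —
because the seed→target and target→seed estimates are independent runs and
the sequence graph draws directed arrows; this choice is flagged in the
JSON export.  The presence pattern over age groups maps bijectively to the
seven type labels; support is `solid` when all subjects of every presenting
group agree, `dotted` otherwise.  Groups absent from a manifest simply
cannot occur in patterns, so partial cohorts remain usable.  No statistical
test is attached to type frequencies.

## Synthetic cohort model

The generator emulates the *structure* of a developing arousal network, not
diffusion physics: counts are simulated directly at the count-ratio level.

* **Nodes**: the 27 AAN nuclei with their anatomical clusters (medulla Me,
  pons P, midbrain Mi, diencephalon/forebrain DF), hemispheres and
  rostro-caudal order; optionally generic cortical targets (58 for the
  whole-brain analysis).
* **Geometry**: nuclei on a rostro-caudal axis, 4 mm between anatomical
  levels and ±4 mm lateral offsets for L/R twins, globally scaled per age
  group (fetal 0.55, infant 0.8, adult 1.0) so fetal distances are strictly
  smaller; label volumes are digital spheres at age-appropriate voxel sizes
  (0.4 / 0.7 / 0.75 mm, following typical postmortem dMRI resolutions).
* **True CP**: `p_within = 0.8` for rostro-caudally adjacent same-cluster
  pairs (index difference ≤ 2, covering L/R twins and the next level);
  `p_hub = 0.6` for any pair touching a planted hub (DR, VTA); all other
  pairs sit at `p_between_base = 0.05` plus an age-gated rise toward
  `p_between_adult = 0.55`.  The gate is `g = clip((α − 1.5·r)/0.1, 0, 1)`
  where `r` is the pair's normalized barycenter-distance rank and α the age
  factor (fetal 0.1, infant 0.5, adult 0.9): at α = 0 all pairs are at
  base, the nearest pairs reach the adult level first, and the longest
  pairs only as α → 1.  Under the defaults this yields essentially no
  between-cluster edges above CP 0.5 in fetal subjects, roughly the nearest
  quarter of them in infants and half in adults — the short-to-long-range
  developmental wave the analyses are designed to detect.
* **Noise**: each directed entry gets an independent Normal(0, 0.3)
  perturbation on the log-odds scale per subject (inter-subject
  variability), then binomial sampling over the launched total, whose
  ratio estimator is exactly the CP definition.  Directions are drawn
  independently so symmetrization is exercised by construction.  All
  randomness derives from one root seed via
  `SeedSequence((rng_seed, subject_index + 1))`, recorded with the
  ground truth.

What the generator does **not** emulate: spatially correlated false
positives along bundles, distance-dependent attenuation of CP,
partial-volume and registration errors, asymmetric L/R development, or
cortical↔cortical connectivity.  Passing recovery tests therefore show the
analysis code is correct and sensitive under the planted model's
conditions, not that tractography itself is accurate on real tissue.

## Verification problem sizes

The test suite and acceptance script run the full default cohort (7
subjects × 27 regions, 100 000 launched streamlines per seed), 100
replicate cohorts for hub/type recovery, 200 random ≤ 7-node graphs against
the brute-force betweenness/clustering oracles, and 100–200 randomized
matrices for the bound and partition checks; the whole run completes in
seconds on one CPU.  Recovery under the default noise level is high but
not perfect (~98% of directed pairs recover their planted developmental
type): pairs whose true CP lies near the 0.2 presence threshold can flip
in individual subjects, which is the expected behavior of a hard
threshold on a noisy estimate.

## Known limitations

* Real probtrackx outputs vary in layout; the reader expects one count TSV
  per subject plus a launched-totals sidecar and does not parse vendor
  formats directly.
* The CSV outputs do not embed provenance themselves; each run's JSON
  metadata file carries the config hash, thresholds, modes, seeds and
  output list, and a run is reconstructible from metadata + inputs.
* With very dense graphs (every node degree N−1) the three measures
  degenerate and hub ranks tie by construction; ranks remain well defined
  through the mean-of-ties rule.
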