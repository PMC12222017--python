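# Methods

`neckconn` implements the computational core of a comparative-connectomics
workflow for neck-connective neurons — the descending (DN) and ascending
(AN/SA) neurons that link an insect's brain to its ventral nerve cord
(VNC).  Given two sexed connectome datasets, the pipeline answers: which
neurons are left–right homologues within each dataset, which cell types
correspond across datasets, which types are present in only one sex
(sex-specific) or present in both but morphologically different (sexually
dimorphic), where each neuron collects and delivers its synapses, and how
directly each type is driven by each sensory modality.

## Morphological similarity (NBLAST)

Skeletons are resampled at 1 µm and reduced to *dotprops*: points with a
local dominant direction (the principal eigenvector of the covariance of
the k = 5 nearest points) and a colinearity score
α = (λ₁−λ₂)/(λ₁+λ₂+λ₃).  The raw score of query Q against target T sums,
over query points, a function of the nearest-target distance d and the
absolute tangent dot product:

    raw(Q, T) = Σᵢ s(dᵢ, |u_q·u_t|)

The published NBLAST scoring tables are trained on a specific light-level
template space and are not part of this package; the default score
function is the parametric surrogate

    s(d, dp) = dp · exp(−d²/(2σ²)) − c      σ = 3,000 nm, c = 0.1

which preserves the two properties the pipeline relies on — positive for
close aligned points, negative (−c) for unrelated ones — and a loader for
an externally tabulated (distance-bin × dot-product-bin) matrix is
provided for users who have one.  The *mean-normalized* score,
½·(raw(a,b)/raw(a,a) + raw(b,a)/raw(b,b)), is symmetric and equals 1 only
for identical clouds; every threshold below is expressed on this scale.

## Registration

Cross-dataset matching first carries dataset A's morphologies into dataset
B's space with an unregularized ("one-step") 3-D thin-plate spline,
kernel U(r) = r, fitted to a landmark-pair table.  The TPS interpolates
every landmark exactly (residual < 1e−6 nm) and reduces to the exact
affine map when the displacement field is affine.  After transforming the
points, tangents are re-derived from the warped cloud rather than pushed
through the Jacobian — simpler, and exact in the smooth-warp limit.

## Left–right pairing

Left neurons are mirrored about the sagittal plane (x → 2·midline − x)
and scored all-by-all against the right cohort.  Mutual best hits with
score ≥ θ_pair (default 0.4) become pairs.  A neuron whose top two
candidate scores differ by less than δ_group (default 0.05) cannot be
resolved into a pair; it is merged with its candidates into a larger
group, the behaviour expected for population types with several
indistinguishable members per side.

## Cross-dataset matching and confidence

Candidates (restricted to the same neuron class) are scored by

    combined = w_m · morph + w_c · conn        w_m = 0.7, w_c = 0.3

where `conn` is the cosine similarity of connectivity fingerprints —
partner-type weight profiles normalized per direction, concatenated over
inputs and outputs.  Morphology dominates because connectivity is used to
resolve ambiguous cases, not to drive the match.  A greedy mutual-best
assignment by descending combined score is taken; candidates below
θ_match (default 0.4) stay unmatched.  The 1–5 confidence formalizes a
manual scale; the only anchored fact is that "high" means > 3, so the
default bin edges 0.2/0.4/0.6/0.8 are configuration, not dogma.

## Dimorphism classification

The decision cascade runs per type, in order:

1. any member flagged neuropeptidergic, ascending-histaminergic or
   abdominal-innervating → **excluded** (these show morphological
   variability unrelated to sex);
2. unmatched across datasets and not well reconstructed →
   **reconstruction_issue**;
3. unmatched, well reconstructed, with a left–right partner →
   **sex_specific**;
4. matched but mean morphology score < τ_d (default 0.5) →
   **sexually_dimorphic**;
5. matched with unequal member counts across datasets →
   **biological_variation** (count differences also occur between the two
   sides of one individual and are not treated as dimorphism);
6. otherwise **matched_monomorphic**.

"Well reconstructed" is operationalized as no `truncated` flag and ≥ 50
skeleton nodes.  τ_d formalizes a judgment the original workflow made by
eye; it sits halfway between the homologue scores observed for preserved
types (≈ 0.7–0.9 after registration) and the planted dimorphic
displacement (≈ 0.3–0.4).  The cascade is applied at type level: a
surplus member of a matched population type is evidence about numbers,
not a sex-specific neuron, so it inherits the type's biological_variation
call rather than falling through the per-neuron "unmatched" branch.

## Anatomical annotation

* **Soma side** — left/right by the soma x relative to the midline
  (±2 µm dead zone → center); somaless neurons use their neck-plane
  crossing point; neither available → unknown.
* **Brain neuropil code** — a single neuropil if it holds ≥ 80% of the
  profile's synapses (postsynapses for DNs, presynapses for ANs); a
  `top_second` pair if the top two jointly reach 80% with ≥ 5% each;
  otherwise `multi`.
* **VNC neuropil code** — single two-letter code if one neuropil holds
  strictly > 80% (presynapses for DNs, postsynapses for ANs); else `ut`
  (upper tectulum) or `xl` (leg neuropils) when the respective region set
  jointly exceeds 80%; else `xn`; soma-only neurons are `XA`.  The brain
  threshold is ≥ and the VNC threshold is strict >, following the two
  rules' different phrasings; both are configurable.  The historical
  two-letter vocabulary uses "hl" for two different neuropils; the default
  code map disambiguates HTct → `ht` and keeps `hl` for LegNpT3, and the
  map is user-overridable.
* **Group resolution** — inconsistent codes within a pair/group are
  resolved by re-applying the rule to the member-mean fraction vector
  (equal member weight, hence permutation-invariant).
* **Tract** — the skeleton is reduced to its longest cable path from the
  VNC entry node and assigned to the tract whose centerline has minimal
  mean closest-point distance.  Tract meshes are dataset assets; given
  centerlines, the original cluster-then-label procedure collapses to
  nearest-centerline.

## Information-flow ranking

The source workflow delegates ranking to a previously published
traversal implementation whose parameters are not printed; this package
reimplements the family explicitly.  Per modality, seeds activate at step
0; at each later step an inactive neuron receiving fraction f of its
total input weight from active neurons fires with probability
min(1, f/f_max).  Rank = mean activation step over `runs` repetitions
(defaults f_max = 0.3, runs = 100, max_step = 20; unreached runs
contribute max_step + 1 so type means stay defined).  As f_max → 0 the
traversal reduces to BFS and ranks equal shortest-path hop counts, which
is how the implementation is validated.  Ranks are averaged by type and
can be clustered (Ward on Euclidean rank-vector distance, cut at a
configurable height).

## Connectivity summaries

Partner graphs keep edges with weight ≥ 10 synapses *and* > 0.5% of the
presynaptic neuron's dataset-wide output, then add back motor/sensory
(MN/SN/SA) partners at weight ≥ 5 to compensate for their systematically
sparser reconstruction.  The retained adjacency is converted to input
percent of the receiving neuron (dataset-wide denominator, so column sums
are bounded by 100) and averaged by type over all member combinations.
Stereotypy between hemispheres or datasets is the Pearson r of paired
weights plus the least-squares slope through the origin (Σab/Σa²); a
free-intercept slope is reported alongside, the through-origin form being
the default.  Effective connectivity sums products of input fractions
over paths of ≤ 2 hops.  Synapse density uses 5-µm voxels anchored to
voxel multiples of the bounding-box floor, after an optional strict
cleft-score > 50 filter.

## Synthetic data: what it emulates, and what it does not

The generator plants every answer the pipeline is asked to recover, in a
300 × 150 × 400 µm volume with the midline at x = 150 µm and eleven
z-stacked neuropil slabs.  Per type: a template skeleton descends along
one of five tract centerlines per side (per-type smooth wobble of 3 µm
and a per-type y-offset in ±30 µm keep types on a shared tract
separable), then arborizes by momentum random walk in its designated
neuropil boxes, with arbor cable ≈ main-neurite cable so that the
dimorphic manipulation always displaces a comparable share of the
morphology.  Right member = template + 400 nm node jitter; left member =
mirrored template + jitter; the male dataset applies a mirror-symmetric
affine + sinusoidal warp (amplitude 4–5 µm, wavelengths 150–250 µm) that
a TPS on a 6 × 4 × 7 landmark lattice approximates to well under the
NBLAST distance scale.  Dimorphic types additionally shift the male arbor
by (0, 15, 25) µm; sex-specific types are omitted from one dataset;
population types carry an extra member per side in one dataset;
excluded types carry the neuropeptidergic flag; truncated types appear
in one dataset only, cut to 30 nodes.  Synapses are multinomial over each
type's planted neuropil fractions; connectivity is feed-forward from
sensory seeds through interneuron layers into each type at its planted
depth (1–3), with per-type input and output weights plus rounded Gaussian
noise (σ_w = 5).  All randomness flows from one root seed through named
substreams.

What it deliberately does not emulate: EM imaging artifacts, segmentation
merge/split errors, realistic branching statistics, synapse placement on
the skeleton, neurotransmitters, or recurrent connectivity.  Passing the
recovery tests therefore demonstrates that the algorithms recover planted
structure under geometric jitter, smooth inter-dataset deformation and
connection noise — not that they would survive the full error spectrum of
real reconstructions.

## Problem sizes and numerical choices

Unit tests use a "tiny" configuration (8 types, ~40 matched neurons, two
modalities); the recovery and acceptance analyses use the default
configuration (60 types, ~400 neurons over both datasets) across several
generator seeds, a scale chosen so a full pipeline run takes tens of
seconds.  Hierarchical clustering uses Ward linkage by default (average
as fallback) on 1 − score distances; scipy's deterministic linkage
provides reproducible dendrograms.  Degenerate inputs are contracts, not
crashes: zero-synapse profiles annotate as `unassigned`, isolated neurons
get zero fingerprints (cosine defined as 0 against anything), empty edge
tables validate with a warning, and stereotypy on degenerate vectors
reports NaN rather than inventing a correlation.

## Known limitations

The information-flow parameters are not claimed to reproduce any
published rank values numerically.  Tract assignment requires centerline
geometry.  The confidence bins and τ_d are declared formalizations of
expert judgments; no numeric criterion exists to import.  The brain
neuropil rule is exercised against rule-level oracles only — the
synthetic datasets are VNC-style bundles and do not instantiate brain
synapse clouds.
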