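# Methods

## Scope and model

The package analyses one tandem repeat array per spacer record. A record is
modelled as `flank5 + background + array + background + flank3`, where the
flanks stand in for the conserved 5.8S/28S rRNA gene ends, the background is
species-specific spacer sequence, and the array is an ordered run of repeat
units. Units carry conserved terminal motifs — `GGGTG` at the 5' (5.8S) end
and `CAYCC` (IUPAC, matching CACCC/CATCC) at the 3' (28S) end — and derive
from a small set of family ("group") consensus sequences. All coordinates
are 0-based, half-open; all arrays are reported on the forward strand.

Sequence divergence is modelled throughout as Jukes–Cantor (uniform rates,
equal base frequencies). The forward simulator and the backward estimator
use the same model, so planted divergences are recovered in expectation by
`d = -(3/4) ln(1 - 4p/3)`.

## Synthetic data generator

`simulate.generate_dataset` plants a known architecture so detection,
grouping, and tree stages can be scored by parameter recovery. Default
study conditions (`barbirostris_like_config`): five species with 10/8/3/8/8
units, nine shared groups, and seven private "singleton" units; the A1-like
species cycles three groups with a private terminal unit; A2/A4/ca alternate
two groups; the A3-like species carries three mutually divergent singletons,
the first and last truncated to 74 and 81 nt; the A3-like background evolves
at three times the base rate.

Key parameters (defaults in parentheses):

* `unit_length_range` (95–112 nt): consensus lengths, drawn per group.
* `within_group_divergence` (0.03 substitutions/site): expected estimated JC
  distance between two copies of the same group.
* `between_group_divergence` (0.2): expected distance between two group
  consensi; singleton consensi sit at twice this from each other and
  ~1.5 times it from any group.
* `background_divergence` (0.05): pairwise spacer-background distance
  between species, scaled per species by `species_scale`.
* `within_species_divergence` (0.005): pairwise distance between isolines of
  one species, when `isolines_per_species > 1`.
* `indel_rate` (0.0): per-site rate of small (1–3 nt) insertions/deletions
  planted in unit interiors, never in motifs. The default keeps planted
  coordinates exact; tests that exercise indel handling set it explicitly.

Two design choices matter for interpretation:

1. **Divergence targets are hit exactly in expectation.** Star branches are
   solved through the JC semigroup identity `p(2b) = 2p(b) - (4/3)p(b)^2`,
   and motif protection rescales the per-site substitution probability so the
   whole-sequence estimated distance matches the target despite invariant
   motif positions. A target is rejected as saturated when the required
   per-substitutable-site difference probability pushes the JC log argument
   below 0.1.
2. **Substitution counts are conditioned on their expectation** (stochastic
   rounding, placement uniform among substitutable sites). Every moment used
   by the distance estimator is unchanged, but the planted divergence has
   far smaller variance than an independent per-site process, so recovery
   tests measure pipeline behaviour rather than generator noise. With
   independent per-site draws at these lengths (~100 nt units), realised
   cross-group distances would stray below the 0.1 grouping threshold in a
   material fraction of datasets, which is a property of sampling noise, not
   of the pipeline under test.

What the generator does **not** emulate: unequal crossing-over or gene
conversion dynamics (array structure is drawn, not evolved), secondary
structure, composition bias, rate heterogeneity across sites, and large
indels. Passing recovery tests therefore demonstrate correctness of the
detection/grouping/tree machinery under the stated model, not robustness to
every feature of real spacers.

## Repeat detection

`self_dotplot` indexes 11-mers, scans every seeded diagonal exhaustively
(vectorised equality), merges exact runs greedily across single mismatches
while the merged identity stays ≥ `min_identity` (0.7), and reports maximal
runs ≥ 30 nt once each. With `min_identity = 1.0` the output is exactly the
maximal exact self-matches, which is how the detector is checked against a
brute-force all-offset oracle. The 30-nt floor mirrors what is resolvable on
a dot plot and deliberately excludes microsatellites.

`infer_array` clusters match offsets (±3 nt) and takes as period the
smallest offset-cluster centre or pairwise offset difference (≥ 30 nt) under
which ≥ 60% of matched length lies near multiples of the candidate; the
near-multiple allowance grows mildly with the period (up to ±12) because
alternating arrays with unequal unit lengths a and b place offsets at
`k(a+b)/2 ± |a-b|/2`. The span is the densest contiguous block of
period-consistent matches; dispersed duplications (no adjacency) return "no
array" rather than an error.

`delimit_units` anchors unit starts on terminal-motif junctions (a `CAYCC`
expansion followed within ≤ 4 nt by `GGGTG`), deduplicated at a 40-nt
minimum separation. Between anchors, boundaries fall back to a periodic
grid snapped to nearby 5' motif occurrences (window = period/3, at least
10 nt), re-anchoring after each cut so unit-length variation does not
accumulate; units cut without any motif evidence are flagged `periodic`.
A fragment shorter than half the period betrays a chance motif junction
inside a real unit and is merged into whichever neighbour restores roughly
one period — genuinely truncated terminal units (0.74–0.93 of the period in
the default conditions) sit well above this floor.

`find_repeat_array` combines the two signals. Junction scanning also
rescues arrays whose units have decayed beyond mutual self-similarity (the
A3-like case, identity ≈ 0.67 < the detector's floor): terminal motifs
persist even when unit interiors have diverged, and the published analysis
of such arrays likewise required evidence beyond self-comparison. When
several candidate terminal boundaries exist, candidates are scored by
per-column global-alignment identity against the junction-delimited interior
units, tie-broken toward the periodic grid.

## Unit grouping

Units are aligned with a sequence-only progressive aligner: pairwise global
alignments (affine gaps; match 1, mismatch −1, open −4, extend −1, via
Biopython's PairwiseAligner) give identity-based guide distances, an NJ
guide tree orders the merges, and profiles merge by aligning their
column-majority consensus strings (ties broken in fixed A<C<G<T order) and
propagating gaps. Structure-aware alignment is intentionally out of scope;
the distance stage consumes any alignment.

JC distances use pairwise deletion: for each pair, only columns where both
rows carry A/C/G/T are compared; ambiguity codes count as gaps
(conservative). Grouping applies single linkage at `d < 0.1`, then two
logged overrides driven by bootstrap supports (default cutoff 70%, exposed
as a parameter since "high support" has no canonical number):

* **merge**: a lone unit joins a group when {unit} ∪ (subset of the group)
  is a supported clade *and* the unit's nearest group member lies within
  1.5× the threshold. The distance guard restricts the override to
  borderline cases (the motivating case sits at 0.109 against a 0.1
  threshold); deeply divergent units stay ungrouped no matter how well they
  cluster, which also matches the observed behaviour of divergent terminal
  units that form a well-supported clade of their own yet remain ungrouped.
* **split**: a component is cut when it is partitioned by two disjoint
  supported clades, severing sub-threshold links between distinct families.

Group ids are numbered from 1 in order of first appearance; singleton
components are reported as ungrouped.

## Trees

NJ is implemented directly (the agglomeration order and degeneracy handling
are part of the package's contract): minimal-Q selection in row-major order
(deterministic lowest-index tie-breaking), negative branch estimates clamped
to zero with the deficit moved to the sister branch, final three-node join
by the closed form. Trees are carried as dendropy objects; an independent
NJ implementation (scikit-bio) serves as a cross-check in the test suite
only. Bootstrap replicates resample columns with replacement; replicate
distance matrices cap saturated or information-free pairs just below the JC
ceiling rather than aborting the replicate set (the original matrix still
raises). Supports are written as integer percentages on internal node
labels. `compare_trees` counts the symmetric difference of non-trivial
bipartitions and lists the conflicts; externally produced newick trees are
accepted so distance-based trees can be compared against trees from other
methods. Species trees are unrooted unless outgroup taxa are supplied, in
which case the tree is rerooted on the branch subtending the outgroup.

## Masking and species trees

`mask_repeats` excises the array span exactly (lossless: masked pieces plus
the excised substring reconstruct the original). `align_and_filter` aligns
the masked spacers with the same progressive engine and, by default,
removes every column containing a gap before distances are computed,
reporting the removed-column count; columns without gaps are never removed.

## Problem sizes and determinism

All randomness flows from one top-level seed through named per-stage
substreams (`stage_seed`), making every pipeline output byte-reproducible.
The test suite exercises 50 generator seeds for parameter recovery with 100
bootstrap replicates per dataset, 100 random additive matrices for NJ, 20
spacers for the detection oracle, and three seeds × 100 replicates for the
species-tree property; the acceptance script uses 1000 bootstrap replicates
on a single dataset. These sizes keep the whole suite near half a minute on
one CPU while leaving the measured recovery rates (≥ 98% of records, 50/50
seeds at the defaults) comfortably above the asserted bounds.

## Known limitations

* Terminal units of fully decayed arrays can gain or lose up to ~45 nt of
  background when a chance motif occurrence outcompetes the true boundary
  (observed in ~1% of default-condition records); resolving these requires
  cross-species comparison, which the per-record detector does not attempt.
* A chance interior junction ≥ 40 nt from both true boundaries can still
  split a unit when both fragments exceed half the period; this is rare
  (~0.4% of records) and surfaces as one extra, ungrouped fragment.
* The period estimator assumes one array per record; records with several
  unrelated repeat families report only the densest array.
* Grouping outcomes are alignment-sensitive: a structure-aware aligner
  could place gaps differently and shift near-threshold distances.
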