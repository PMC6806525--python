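# Methods

## Model and procedure

`coreclust` formalizes a consensus strategy for RNA 3D structure
prediction: homologous sequences from one family share a conserved 3D
core, so the fold most consistently produced across de novo decoy
ensembles of several homologs is the best available estimate of the
native fold of the target sequence.

**Conserved core.** The core is defined purely from the alignment: the
set of columns at which every selected sequence has a residue. Column
`c` maps, for sequence `s`, to the number of residues of `s` strictly
before `c` — a 0-based index into the ungapped chain. Structure files
are indexed positionally (chain order as read), not by PDB residue
numbers, because decoy generators renumber inconsistently; the residue
order of each decoy must therefore match its sequence in the alignment.
No conservation scoring is applied beyond the all-ungapped rule; an
optional `min_ungapped_fraction` can relax it for diagnosing which
sequences break the core, but the default (1.0) is the behavior used
throughout.

**Redundancy reduction.** Optional greedy filtering in record order:
a record is dropped when its identity with any kept record reaches the
threshold (default 0.9). Identity = matching unambiguous residues over
columns where at least one of the pair is non-gap; gap–gap columns are
ignored and ambiguity codes never match (even when identical). Greedy
scanning is deterministic and order-dependent by design — reproducibility
was preferred over an optimization step with no published description.

**Core RMSD.** Each model contributes one C3′ coordinate per core
column. For a pair of models the metric is the minimum RMSD over proper
rigid motions, computed by the covariance-SVD (Kabsch) solution with the
determinant sign correction that excludes reflections. Because every
core trace has the same length, models of homologs with different
sequence lengths are directly comparable; full-atom RMSD is not, which
is why the single-atom core metric drives both clustering and the
cross-homolog evaluation. The all-vs-all matrix is computed once per
unordered pair with batched 3×3 SVDs (n ≈ 500 takes ~1 s on one CPU)
and stored dense (text serialization: id header plus 3-decimal rows).

**Clustering.** Neighbor = pair at core RMSD strictly below the cutoff;
a model is not its own neighbor. Clusters are extracted greedily: the
unassigned model with the most unassigned neighbors becomes the medoid
(ties → lower energy rank, then lexicographic id — the published
procedure is silent and determinism is required), its unassigned
neighbors join it, and the process repeats; neighborless models end as
singletons. The cutoff search starts at 0.5 Å and increments by 0.5 Å
until the criterion holds:

* `one_of_six`: first cluster strictly greater than n/6 (for 500
  structures: over 83, i.e. ≥ 84);
* `half`: first three clusters at least ⌈n/2⌉ (for 500: ≥ 250).

The strict inequality for `one_of_six` follows the published phrasing
("over 80" of 500) and keeps the degenerate case sane: with a handful of
mutually distant structures, a singleton "first cluster" does not
terminate the search. A `max_cutoff` guard (50 Å) converts pathological
non-termination into an error that reports the trajectory of
first-cluster sizes.

**Selection.** Two published rules are implemented. `cluster_scan`
(default): the first target-sequence model scanning clusters in
extraction order and members in within-cluster order (medoid first, then
by distance to medoid). `max_neighbors`: the target model with the most
neighbors at the terminating cutoff, ties broken by lower energy rank.
The report records which rule fired and the remaining target models as
runner-ups.

**Evaluation.** Heavy-atom RMSD pairs non-hydrogen atoms by per-residue
name intersection (decoys differ in atom completeness) and requires
equal residue counts — it is a target-vs-reference metric only. INF is
the geometric mean of precision and recall over interaction sets; it is
reported as `NA`, never coerced to 0, when a denominator vanishes.
Interaction sets come from dot-bracket strings (with (), [], {} as
independent pseudoknot layers), from TSV lists produced by any external
annotator, or from a minimal geometric detector: base pairs need a
C1′–C1′ distance in [8, 12] Å and a closest Watson–Crick-edge
donor/acceptor contact under 3.5 Å; stacking needs sequence-nonadjacent
bases with centroids under 5.5 Å and plane normals within 30°. The
thresholds are configurable defaults; the detector makes no claim to
reproduce a full contact classifier and exists so INF can be computed
without one.

**CLANS export.** Pairs below a distance threshold are connected with
attraction `1 − d/threshold`. Any strictly decreasing map gives the same
graph topology, which is what the cluster map is read for; the linear
form is the simplest such choice. Thresholds of 6 Å and 9 Å are the
documented presets for compact and diverse ensembles respectively. An
experimental reference structure can be appended as an extra node with
its own distances to every model.

## Synthetic benchmark generator

The generator emulates the exact input layout of a real run: an aligned
FASTA over a target plus homologs, one directory of ranked PDB decoys
per homolog, and a name→files mapping. Defaults are the study
conditions used throughout the acceptance checks: 5 homologs × 100
decoys, 3 planted clusters, `within_sigma` 1 Å, `between_shift` 12 Å.

* **Backbone.** An idealized A-form-like hairpin: per-residue rise
  2.8 Å, twist 32.7°, C3′ at radius 9.4 Å, with the two stem strands
  antiparallel on one axis and loop/linker residues placed on an arc
  solved (by root-finding on the subtended angle) so that consecutive
  C3′–C3′ steps match the 6 Å linker step. Each residue carries P, C3′,
  C1′ and a planar base triad (N1/C2/N3/C4) positioned so that the
  geometric detector recovers exactly the planted pairing: paired WC
  edges meet at 3.4 Å while the nearest non-paired combination is over
  4 Å. A 20-residue core with helix fraction 0.6 is the default; the
  core length mainly sets how sharply core RMSD concentrates.
* **Homologs.** All homologs share the core coordinates; each splices a
  homolog-specific insertion (length 2+h by default) at its own position,
  gapped out in the alignment, so the conserved core recovers exactly
  the planted core columns. Core sequences are mutated at 25% per
  position, keeping pairwise identities below the 0.9 redundancy
  threshold. Insertions are schematic extended offshoots; their backbone
  continuity is not physical, which is irrelevant to the claims under
  test.
* **Planted clusters.** Cluster 0 is the reference conformation; cluster
  k rigidly displaces everything beyond a hinge at the core midpoint by
  a translation of magnitude k·`between_shift` plus a 25k° rotation. A
  hinge motion is used deliberately: a *global* rigid motion is
  invisible to RMSD after optimal superposition and would not separate
  clusters at all, whereas a hinge changes the shape by an amount
  controlled by the shift. Decoys are assigned to clusters with weights
  ∝ 2^(K−k) — a dominant conformation plus progressively rarer ones, the
  typical shape of real decoy ensembles — and energy ranks are assigned
  independently of cluster labels.
* **Noise.** After the cluster motion, every atom is displaced by an
  isotropic Gaussian with RMS 3D magnitude `within_sigma` (per
  coordinate: σ/√3). Two same-cluster decoys then sit near
  `within_sigma·√2` in core RMSD (slightly less after the superposition
  correction), so the default 1 Å noise puts within-cluster distances
  around 1.4 Å and the 12 Å hinge shift puts between-cluster distances
  several-fold higher; the generator warns when
  `between_shift ≤ 4·within_sigma`. With `within_sigma = 0`, same-cluster
  core RMSDs collapse to 0.
* **What it does not emulate.** Thermodynamics, sequence-dependent
  folding, realistic energy rankings, alternative secondary structures,
  or decoys with missing residues. Passing the planted-partition checks
  therefore demonstrates the correctness of the consensus machinery —
  core mapping, metric, clustering, selection — not the accuracy of any
  folding engine on real families.

## Numerical choices

* Superposition demands ≥ 3 points and rejects collinear point sets
  (second singular value ≤ 1e-8 of the first); RMSD values are clamped
  at 0 before the square root to absorb float cancellation (identical
  inputs return ~1e-8, not exactly 0).
* Distance matrices are validated symmetric, finite, non-negative and
  zero-diagonal on construction; the text reader re-symmetrizes to guard
  hand-edited files.
* Neighbor comparison is strict (`<`), matching the stopping examples
  and keeping singletons well-defined; criterion thresholds are the
  integer rules given above.
* Ranks default to 100 models per homolog (lexicographic file order
  within a homolog, or an explicit rank column in the mapping); model
  ids embed the zero-padded rank so id order equals rank order.
* Only the first MODEL of a multi-model PDB is read; altloc entries
  other than blank/'A' are ignored; `C3*`-style legacy names are
  normalized to `C3'`; models missing a C3′ atom (or a mapped core
  residue) are rejected with the offending residue/column named.

## Problem sizes

The test suite and acceptance checks run the full pipeline at the study
scale of 500 models (5 homologs × 100 decoys) per seed, 5 seeds, plus
oracle comparisons on 200 random superposition pairs and 50 random 60×60
matrices; the complete suite takes about a minute on one CPU.

## Known limitations

* Residue correspondence is positional; decoys whose chains do not match
  their alignment sequence one-to-one are rejected rather than aligned.
* The geometric interaction detector is a deliberately minimal stand-in
  for a proper contact classifier; its INF values on noisy decoys are
  conservative (jitter of ~1 Å breaks 3.4 Å WC contacts).
* `half`/`one_of_six` stopping is a heuristic tuned to ensembles of a
  few hundred structures; for very small n it can terminate before
  clusters are fully assembled (the strict `one_of_six` rule mitigates,
  but does not remove, this).
* mmCIF input, hydrogens, energy-weighted consensus scoring and the
  CLANS layout engine itself are out of scope.
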