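# Methods

## Scope and data model

`ptmimpact` operates downstream of molecular dynamics: snapshot
energies, per-residue decompositions, trajectories, secondary-structure
assignments and orthologue alignments are *inputs*. The package never
evaluates a force field, runs generalized Born solvation, assigns
secondary structure, or builds alignments; it implements the
bookkeeping, metrics and statistics that turn those inputs into
statements about how PTMs affect protein–protein binding.

## Dataset curation

A structure enters the analysis set only if all criteria hold: no
fusion chains, no engineered mutations, chain-averaged percentage of
the full protein length that was crystallized ≥ 70%, chain-averaged
percentage of crystallized residues actually resolved ≥ 70%,
resolution ≤ 3.0 Å (inclusive: "3.0 Å or better"; not applicable to
NMR, and methods other than X-ray/NMR skip the criterion with a
warning), not membrane-embedded, more than one chain, and at least one
mapped PTM site. Averages are per structure, not dataset-wide, since
filtering is a per-structure decision. The resolved percentage uses
the crystallized construct as denominator — a residue can only be "in
a gap" relative to what was crystallized.

Duplicate representations of the same complex — identity defined as
the multiset of protein accessions across chains, so a homodimer and a
heterodimer of the same protein differ — are collapsed by lowest
resolution, then highest mean resolved percentage, then smallest
structure id. The last tie-break is a declared convention; resolution
values are floats and real ties essentially occur only between
processed copies of the same deposition. NMR structures (no
resolution) rank after any X-ray structure at this step.

The MD job inventory follows from condition coverage: every kept
structure gets one non-modified control run, plus one modified run per
condition (normal/stress) with mapped sites. Coverage (92, 5, 82)
yields (179, 174, 87) runs, 440 total.

## PTM catalogue

Sites are validated against the full protein sequence (residue letter
at the 1-based position must match, and the type/residue combination
must be legal: acetylation on K; phosphorylation on S, T or Y) and
mapped onto chains through an explicit residue map. The map is a
required input because deposition-to-sequence numbering offsets are
not derivable from the site table alone; sites in crystallographic
gaps or outside the crystallized construct are dropped with reasons.
Multiplicity statistics are per "unique chain" — one (structure,
chain, condition) key — so each subunit of a homomultimer counts
separately, mirroring how gaps can differ between subunits.

## Energetics

All energies are kcal/mol; table readers refuse any other declared
unit rather than converting. The per-snapshot identity
ΔG = G_complex − G_receptor − G_ligand is averaged over snapshots;
SEM uses the sample standard deviation (absent for one snapshot). The
state-contribution split expresses each role's ΔG (modified minus
non-modified mean) as a signed percentage of the sum of the three
absolute ΔG values, so absolute percentages total 100; the identity
ΔΔG_bind = ΔG_complex − ΔG_receptor − ΔG_ligand is verified to 1e-9
in tests. The split degenerates when all three ΔG are zero, which is
raised as an error rather than reported as 0/0.

Interface classification is strict: |per-residue ΔΔG contribution| >
0.5 kcal/mol, boundary excluded ("larger than"). Residues present in
only one variant's decomposition (gap asymmetry between subunits)
contribute zero in the other variant and are flagged, not silently
matched. The long-range gap of a chain — overall ΔΔG_bind minus the
sum of its per-site local deltas — is classified against an error band
of width sem; the band is the caller's choice, and root-sum-square
propagation of the two variant SEMs is the suggested default since no
canonical formula exists for it. A configurable cutoff (default
5 kcal/mol) flags residues with outstanding contribution differences
for case-study inspection.

## Conformational change

RMSD uses unweighted coordinates after least-squares (Kabsch)
superposition; mass weighting is deliberately not offered. The Kabsch
implementation corrects reflection solutions to proper rotations
(det +1) and rejects collinear geometries. An unfitted mode exists and
is used in tests to pin translation behaviour.

The variant comparison metric is (AUC_mod − AUC_nonmod)/duration with
trapezoidal integration — equal to the difference of time-averaged
RMSDs for a common time grid — and requires both series to span the
same interval.

Clustering is the gromos/Daura greedy algorithm on the pairwise fitted
RMSD matrix: the frame with the most neighbours within the cutoff
becomes a centre, centre plus neighbours are removed, repeat. All ties
(neighbour counts, equal cluster sizes) break to the lowest frame
index. The cutoff is quoted in nm (default 0.25, i.e. 2.5 Å) following
the convention of the MD tools that popularized the method; internal
lengths are Å. `gromos_cluster` clusters exactly the frames it is
given; the pipeline-level `representative_rmsd` applies the
production-tail default (last half of each trajectory, configurable)
before clustering and then reports the fitted RMSD between the
largest-cluster representatives.

The periodic-image check computes the minimum distance between the
atom set and its 26 orthorhombic neighbour-cell translations;
violation is distance < 12 Å by default, the production nonbonded
cutoff, since a molecule within interaction range of its own image
invalidates the energy analysis. Coordinates must be pre-wrapped;
non-orthorhombic boxes are out of scope.

## Conservation and taxonomy

The conservation fraction of a site is the share of non-reference
alignment records satisfying the type rule. Conventions: the reference
record is excluded from the denominator; records entirely gapped at
the relevant columns count as non-conserving (not excluded); the ±1
acetylation window operates in alignment-column space, and window
columns falling off the alignment edge count as non-matching; one
record = one count (paralog duplicates are not collapsed). The LCA of
the conserving taxa is computed on a parent-pointer taxonomy by
pairwise depth-equalizing walks, cross-checked in tests against
root-path intersection.

DSSP 8-letter codes simplify as H/G/I → H (helix), E/B → E (sheet),
S/T/C/"-" → C (non-structured). Secondary-structure preference
compares the H/E/C placement of PTM sites against matched non-modified
residues of the same amino-acid type. The conservation-vs-effect
correlation defaults to Pearson (Spearman available); the choice is
open in the source material, and the null-simulation test bounds are
method-agnostic.

## Statistics

The unpaired t-test defaults to the Student pooled-variance variant
(Welch by flag) because the source analyses say only "unpaired
t-test"; with exactly one zero-variance group the implementation falls
back to Welch, and two zero-variance groups with equal means return
p = 1 by convention. Cohen's d uses the pooled (n−1) standard
deviation; the reported d is the absolute value with the signed value
retained. Bands: d > 0.8 large, 0.5–0.8 medium, 0.2–0.5 small,
otherwise negligible.

## Synthetic data generator

The generator defines the study conditions for all property tests.
Defaults: 100 snapshots per run (matching the 100 equally spaced
conformational snapshots used for end-point averaging); type-specific
local effect means mu = −1.0 (acetyl-K), +1.5 (phospho-S), +1.0
(phospho-T), +1.0 (phospho-Y) kcal/mol with sigma_local = 0.5 —
chosen so acetylation is net locally stabilizing and phosphorylation
destabilizing, with serine the strongest destabilizer, emulating the
qualitative direction pattern of the motivating analyses rather than
any real distribution; a chain-level long-range term ~ N(0, 2.0)
spread over non-site residues; unbound-state shifts ~ N(0, 1.0);
snapshot noise sd 2.0 kcal/mol. Noise is centred within each run, so
the realized mean ΔG difference equals the generated local + long-range
sum exactly and decompositions sum to their variant's mean ΔG — this
is what makes exact-recovery tests meaningful. Alignments conserve
each site per ortholog independently (Bernoulli, default p = 0.7 over
50 orthologues), with the acetylation realization placed at the column
or one off with equal chance and all rule-relevant columns scrubbed of
accidental matches. Trajectory pairs share an initial ideal helix
(2.3 Å radius, 1.5 Å rise, 100°/residue CA trace) and drift through a
non-rigid bending mode with jitter; the modified endpoint is displaced
by delta along an independent non-rigid mode, so representative-RMSD
recovery is monotone in delta. Randomness derives from one root seed
combined with a CRC of the per-generator stream name, so adding a
generator never perturbs existing outputs.

What the generator does *not* emulate: physically realistic energy
component magnitudes or correlations, autocorrelated MD noise,
snapshot-level decomposition noise (decomposition tables are means),
sequence evolution beyond per-site Bernoulli conservation, side-chain
degrees of freedom in trajectories. Passing tests therefore
demonstrate correctness of the bookkeeping, metrics and statistics
under controlled conditions — not predictive accuracy on real
simulation data.

## Problem sizes

The test and reproduction runs use deliberately desk-scale sizes: a
30-complex cohort at 25 snapshots for the pipeline-level metrics,
200-site runs for effect-size recovery, 10-frame trajectories for the
clustering oracle comparisons (200 replicates), 100 random taxonomies
for LCA cross-checks, and 10,000 replicates at n = 50 for the t-test
calibration. Cohort-scale MD (hundreds of simulations) is explicitly
out of scope; the published cohort-level statistics can be recomputed
with `tests/test_acceptance.py::test_supplementary_table_statistics`
once the original study's supplementary tables are exported to TSV
under `data/supplementary/` (they are third-party data and are not
redistributed here, so that check reports failure in their absence).

## Known limitations

- The entropy term −TS is carried through when supplied but no
  estimator is provided; omission biases absolute ΔG_bind, largely
  cancelling in ΔΔG_bind.
- Unbound-state energies are assumed to come from the complex
  trajectories (single-trajectory end-point protocol); independent
  unbound simulations are not modelled.
- The residue map between structure numbering and protein positions
  must be supplied; no SIFTS-style derivation is attempted.
- Periodic-image checks assume orthorhombic boxes and pre-wrapped
  coordinates.
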