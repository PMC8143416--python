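# ptmimpact

Post-translational modifications (PTMs) such as lysine acetylation and
serine/threonine/tyrosine phosphorylation tune how proteins bind their
partners — directly at interaction interfaces, and indirectly through
conformational (allosteric) changes. `ptmimpact` is an analysis toolkit
for quantifying those effects from molecular-dynamics-derived energy
data in the MM/GBSA (molecular mechanics with generalized Born and
surface-area solvation) end-point framework. It is aimed at structural
bioinformaticians who run MD simulations of modified vs non-modified
protein complexes and need the downstream bookkeeping: dataset
curation, PTM-to-structure mapping, free-energy differences and their
per-residue decomposition, conformational-change metrics, conservation
scoring, and effect-size statistics.

## The model

The single-snapshot free energy of a species is

```
G = E_bonded + E_electrostatic + E_vdW + G_polar + G_nonpolar − TS
```

with the entropy term omitted by default, as is common for end-point
estimates. The binding free energy of one subunit (the ligand) to the
rest of the complex (the receptor) is the snapshot average

```
ΔG_bind = ⟨ G_complex − G_receptor − G_ligand ⟩
```

and the effect of a set of PTMs is

```
ΔΔG_bind = ΔG_bind(modified) − ΔG_bind(non-modified)
```

negative ΔΔG_bind meaning the modifications stabilize binding. An
n-meric complex yields n ΔG_bind values, one per ligand-vs-rest
partition. Per-residue decomposition deltas locate the effect: a
residue with |ΔΔG_bind contribution| > 0.5 kcal/mol is classified as
interface-located, and the gap between a chain's overall ΔΔG_bind and
the sum of its local per-site contributions measures long-range
(allosteric) action. Conformational change is quantified by fitted
RMSD against the initial structure, the time-normalized difference of
RMSD areas between variants, and the fitted RMSD between
representatives of the largest gromos (Daura) clusters of each
production tail. Conservation of a PTM site across orthologue
alignments uses type-specific rules (acetyl-K tolerates a ±1 column
shift; phospho-S/T accept S or T at the exact column; phospho-Y is
strict), and the set of conserving taxa is summarized by its lowest
common ancestor in a taxonomy tree. Group comparisons use the unpaired
t-test and Cohen's d.

Because real cohorts require hundreds of MD simulations, the package
ships a seed-deterministic synthetic-data generator
(`ptmimpact.synthetic`) that emulates every input — curation metadata,
PTM tables, snapshot energy and decomposition tables with known local
and long-range effects, trajectory pairs with controlled divergence,
alignments with known conservation probability — so the entire
pipeline is testable against ground truth.

## Worked example

Generate one modified/non-modified pair of MM/GBSA snapshot tables for
a dimer with two acetylation sites and one phosphosite, then run the
energetics stage:

```python
from ptmimpact import synthetic, energetics

cfg = synthetic.GeneratorConfig(seed=42)
sites = [("A", 12, "acetyl_K"), ("A", 57, "acetyl_K"), ("B", 33, "phospho_S")]
snap_nm, snap_m, dec_nm, dec_m, truth = synthetic.gen_energy_tables(cfg, sites)

be_nm = energetics.binding_energy(snap_nm)
be_m = energetics.binding_energy(snap_m)
result = energetics.ddg(be_m, be_nm)
print(f"ddG_bind = {result.ddg:+.2f} kcal/mol ({result.effect})")

for d in energetics.residue_contribution_delta(dec_m, dec_nm):
    if (d.chain_id, d.resnum) in {(c, r) for c, r, _ in sites}:
        print(f"site {d.chain_id}{d.resnum}: delta {d.delta:+.2f} kcal/mol,"
              f" interface={d.interface}")
```

prints

```
ddG_bind = -1.77 kcal/mol (stabilizing)
site A12: delta -0.55 kcal/mol, interface=True
site A57: delta -0.63 kcal/mol, interface=True
site B33: delta +1.10 kcal/mol, interface=True
```

The two acetylations contribute locally stabilizing (negative) terms
and the phosphorylation a destabilizing one; all three exceed the
0.5 kcal/mol interface threshold. The overall ΔΔG_bind (−1.77) is more
stabilizing than the sum of the local site terms (−0.08), so
`energetics.local_vs_global_gap` attributes the remainder
(−1.69 kcal/mol here) to long-range effects, and
`energetics.state_contribution_split` apportions it between the bound
and unbound states (complex −82.4%, receptor −5.3%, ligand −12.4% for
this system).

A command-line entry point mirrors the library:
`ptmimpact synth all --seed 42 --out cohort/` writes a complete fixture
cohort, and `ptmimpact curate`, `ptmimpact ptm map`,
`ptmimpact energetics ddg`, `ptmimpact conf cluster`,
`ptmimpact conserve score`, `ptmimpact stats-compare` operate on the
tabular/FASTA/Newick files documented in each module.

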