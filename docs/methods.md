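# Methods

## The reduced alphabet and scaffold

The SCAA maps each of the 20 standard amino acids to one of six class
representatives (D, Q, H, S, Y, V). Fourteen of the twenty assignments
are fixed by published triad translations of deposited TCR–antigen
complexes; the remaining six (C, M, W, I, S→itself, H→itself, N) follow
the chemical-class logic of BLOSUM-style clustering: cysteine joins the
hydroxyl-polar class (thiol ≈ small polar), methionine and isoleucine
the aliphatic hydrophobics, tryptophan the aromatics, asparagine the
amide class. The table ships as a two-column CSV asset
(`scaadock/data/scaa_table.csv`) so alternative alphabets can be
substituted without code changes. Glycine is special-cased only by
position: at a triad position it translates to V (hydrophobic, as the
attested translations require); everywhere else it is the inert spacer.

Antigen positions are numbered P1…P9 from the N terminus. The scaffold
template (`AntigenTemplate`) renders a triad into `GGXGXGGXG`;
templates with other lengths or triad positions are ordinary values,
not special cases.

## Peptide construction

Backbones are grown atom by atom with natural-extension-of-reference-
frame (NeRF) placement from a single table of canonical bond lengths
and angles (Engh–Huber-style ideal values: N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å; N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°).
Because every atom is placed from exact internal coordinates, bond
lengths are exact to numerical precision regardless of the requested
dihedrals, and measured Φ/Ψ of a built chain reproduce the inputs to
better than 10⁻³ degrees — both properties are tested. The first
residue defines the frame: N at the origin, CA on +x, C in the
xy-plane. Carbonyl oxygens are placed in the peptide plane anti to the
next amide nitrogen.

Sidechains come from per-residue internal-coordinate templates (all 20
residues) with χ angles from a single most-common-rotamer table
(χ = 180° where no entry exists). Cβ placement uses the torsion
C-N-CA-CB = −122.55°, which yields L-chirality (improper N-CA-C-CB
negative — tested). Aromatic rings are built with 0°/180° ring torsions
and are therefore exactly planar. Histidine is built and scored as the
doubly N-protonated imidazolium (+1), reflecting the mildly acidic
extracellular milieu of many immune contexts; the flag lives in residue
metadata. Hydrogens are never built; all scoring is heavy-atom.

The default scaffold dihedral table is an extended β-like conformation
(Φ = −139°, Ψ = 135° at every position), shipped as a CSV asset and
labeled as a stand-in: users studying a particular receptor should
supply the Φ/Ψ profile of an MHC-groove-bound antigen via
`DihedralTable.from_csv`.

## Restraints

The default AIR scheme ties the peptide's P2 Cα / P3 Cβ / P4 Cα to the
Cα of the CDR3α loop's central residue, and P4 Cα / P5 Cβ / P6 Cα to
the CDR3β center, with a flat bottom between 4 and 8 Å and force
constant 50 kcal mol⁻¹ Å⁻² (the ambiguity-driven-docking convention).
The loop center is the lower-median residue of the annotated range.
Ambiguity is aggregated as d_eff = (Σ pairs d⁻⁶)^(−1/6), which never
exceeds the minimum pairwise distance and decreases monotonically as
pairs are added; a per-pair "split" export mode is available for
engines that count restraints differently. A glycine occupying a Cβ
slot degrades that pair to Cα with a logged warning. Restraints export
to an `assign`-statement table (bounds written center/minus/plus, so
[4, 8] Å becomes `6.0 2.0 2.0`) and to JSON.

## Docking engine and force field

Both molecules are fully rigid. The intermolecular score is
deliberately simple: 12-6 Lennard-Jones with per-element parameters
(C, N, O, S; well depths 0.10–0.35 kcal/mol, rmin/2 1.75–2.00 Å,
Lorentz–Berthelot combination), Coulomb electrostatics over coarse
heavy-atom charges (backbone amide dipole with hydrogens lumped onto
their heavy atoms; formal charges split over terminal polar atoms:
Asp/Glu −0.5 per carboxylate O, Lys +1 on NZ, Arg +0.5 per NH,
His(+1) +0.5 per ring N; small hydroxyl/amide dipoles), a
distance-dependent dielectric ε(r) = 4r, a 12 Å cutoff with no
switching function, plus the flat-bottom AIR penalty. E_total is the
weighted sum of the three terms (unit weights by default). Absolute
energies from this force field are not comparable to any published
molecular-mechanics engine; only relative and statistical behaviour is
claimed, which is all the downstream analysis uses.

Pose generation: initial placements combine a uniform random rotation
(normalized Gaussian quaternion) with a translation that puts each
restraint's ligand-anchor centroid at a random distance near the
middle of the flat bottom from its receptor target (solved by least
squares when the two restraints compete), so most starts already
satisfy the AIRs. Refinement has three seeded stages: a geometric
overlap-relief that translates the ligand away from interpenetrating
receptor atoms (raw LJ gradients are useless at such separations), a
Metropolis Monte Carlo walk (default 600 steps, 2°/0.3 Å step sizes
with a 15% admixture of 6× larger jumps, geometric cooling from 4.0 to
0.2 in energy units, rotations applied about the ligand centroid), and
a derivative-free Nelder–Mead polish of the best pose, followed by a
few basin-hopping rounds (perturb, re-polish, keep improvements). If a
walk ends wedged at positive energy the whole cycle restarts from the
current best, at most twice. `MCSchedule.thorough()` provides a
heavier-hopping variant for convergence studies. Everything is driven
by one `numpy` Generator, so a fixed seed reproduces a pose set
bit-for-bit.

All poses are retained and sorted by E_total; per-peptide statistics
average over the full ensemble, mirroring the screening design this
package implements, where the 100-pose mean (not the minimum) is the
per-peptide descriptor.

## Metrics and analysis

Contacts are intermolecular heavy-atom pairs closer than 6.0 Å
(configurable; the value was chosen to give counts of order 10²–10³
for a 9-mer against a receptor surface, the magnitude reported for
such screens). Ligand RMSD to a reference pose is computed without
refitting, since the receptor frame is shared; Kabsch superposition
(SVD with reflection guard) is available for cross-complex comparison
and is tested against a rotation-grid oracle.

Per-peptide records carry E_i/C_i means, sample SDs (ddof = 1; the SD
of a single observation is defined as 0) and SEMs. The best-binder
window is centered on the unweighted means of E_i and C_i across the
library with half-widths of one standard deviation of those per-peptide
means across the library (the spread visible in an energy–contact
map); a "sem" mode divides by √N for users who prefer the standard
error of the center. The boundary is closed. On records whose (E_i,
C_i) are independent standard normal, membership converges to
P(|Z| ≤ 1)² ≈ 0.466, which the tests verify by Monte Carlo.

Positional heatmaps average E_i per SCAA class and triad position over
a chosen subset (window members by default, switchable to the full
library); empty cells are NaN, never zero. The reduction rule excludes,
per position, only a unique global maximum of mean energy — ties
propose nothing and minima are never excluded, because an apparent
energetic preference may reflect force-field bias rather than a true
anchor requirement. Proposals are advisory: the CLI requires
confirmation (or `--auto`) before applying them.

## Synthetic fixtures

`make_mock_receptor` builds two rigid 7-residue poly-alanine strands at
extended dihedrals, parallel, 12 Å apart, groove axis along x, annotated
as CDR3α/β with central residues 4. It supplies exactly what the
pipeline needs — two loop centers to restrain against and steric bulk
to dock around — and imitates nothing else about TCR geometry.

`make_planted_complex` places a library peptide so both AIRs measure
d_eff = 6.0 ± 0.1 Å with no steric clash. Construction is deterministic
given its seed: the docking protocol itself explores the
restraint-satisfying region (24 refined starts); the deepest free
minima are projected onto the d_eff = 6 Å shell under a stiff pin
penalty; and the projected candidates are probe-docked with an internal
seed, planting beside the attractor the protocol most reliably
revisits. The planted pose therefore sits as close to a genuine basin
of the energy landscape as the 6 Å requirement allows, which is what
makes it a usable recovery oracle.

`make_synthetic_records` generates per-peptide records with planted
per-class/per-position energy offsets plus Gaussian noise (baselines
E ≈ −15 kcal/mol, C ≈ 280, typical of the docking fixture), and
`make_gaussian_records` provides the independent-normal ensemble for
window-statistics oracles.

What the fixtures do *not* show: recovery on the two-strand groove says
nothing about pose accuracy on a real TCR (no loop flexibility, no MHC,
a toy force field), and synthetic records bypass docking entirely —
they validate the statistics, not the physics.

## Problem sizes and numerical choices

The default test and acceptance runs use 100 poses per docking
experiment, 10,000 records for window statistics, and the full
216-peptide enumeration for combinatorial checks; the end-to-end
pipeline test docks a 2-peptide sub-library at reduced Monte Carlo
length, exercising every stage at small scale. Nelder–Mead tolerances
(xatol 10⁻⁵–10⁻⁶) and the MC schedule are package defaults, all
overridable through `MCSchedule` and `ScoringParams`.

## Known limitations

- The planted-pose recovery experiment is stochastic. The d_eff = 6 Å
  requirement places the plant near, but rarely exactly at, the
  landscape's deepest attractor, and the 100-start protocol revisits
  that basin with limited frequency; at some seeds the closest of 100
  poses lands just outside 2 Å. The ensemble-level statistics (energy
  SEM of 2–3%, contact counts) are stable across seeds.
- The force field has no solvation beyond the distance-dependent
  dielectric, no hydrogens, and a hard cutoff; energies are
  pipeline-internal quantities.
- Rigid receptor and rigid ligand throughout: conformational selection
  and induced fit are out of scope by design.
- The 2.5 × 10⁶-peptide decamer proposal for the MHC-II side is
  supported only as `library_size` arithmetic with user-chosen
  alphabets; its exact positional restrictions are not reconstructable
  and are not guessed.
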