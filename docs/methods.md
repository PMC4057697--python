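# Methods

This note documents the models, criteria, numerical choices and known
limitations behind `ppargpharm`.

## Coordinate conventions and structure ingestion

All analysis uses the author residue numbering of the source PDB entry;
nothing is renumbered, so residues can be addressed the way the
literature addresses them (Ser289, His323, His449, Tyr473, …).  PDB
reading is backed by gemmi; the package then partitions records into
protein chains, het groups and waters, keeps MODEL 1 only, and resolves
alternate locations to the highest-occupancy conformer (ties broken
alphabetically by altloc) so ingestion is deterministic.  Input
hydrogens are kept; every geometric operation states whether it uses
heavy atoms only.

Ligand bonds are taken from an mmCIF chemical-component definition when
one is supplied; otherwise they are perceived from distances (bond iff
d ≤ r_i + r_j + 0.45 Å with single-bond covalent radii), terminal
oxygens closer than 1.30 Å are typed as carbonyls, and 5/6-rings are
marked aromatic on a geometric criterion (best-fit-plane deviation
≤ 0.15 Å and all ring bonds within aromatic-range lengths per element
pair).  This perception runs on bare HETATM coordinates before any
charge model exists, which is why it is geometric rather than
valence-model based; on embedded 3D structures of all twenty amino acids
it reproduces the reference bond graph exactly (tested against RDKit
topology as an independent oracle).

## Protonation at pH 7.4

Ionisation is assigned by fixed pKa rules at physiological pH: Asp/Glu
side chains deprotonated, Lys/Arg protonated, Cys/Tyr/Ser/Thr neutral.
Histidine tautomers are chosen by enumerating Nδ-H and Nε-H and counting
the hydrogen bonds each would satisfy against polar neighbours within
2.5–3.5 Å (atoms of the histidine itself excluded); the Nε-H tautomer is
the default when nothing decides.  Hydroxyl and thiol hydrogens are
placed at the staggered torsions {−60°, 60°, 180°} and the rotamer
satisfying the most hydrogen bonds wins, ties going to the numerically
lowest torsion.  The 2.5 Å floor in the satisfied-bond count exists to
keep covalently adjacent atoms from masquerading as partners; intra-residue
contacts are excluded for the same reason.  Ligand rules: carboxylic
acids deprotonated (−1), aliphatic amines protonated (+1),
thiazolidinedione ring N–H neutral; all overridable per component id.
Only the pH 7.4 table ships — other pH values raise `NotImplementedError`
rather than silently misassigning.  This rule-based scheme deliberately
replaces titration-free-energy optimisation: it is deterministic,
desk-scale, and sufficient for the geometric hydrogen-bond detection it
feeds.

## Superposition and RMSD

The optimal rigid superposition is the standard SVD solution of the
orthogonal Procrustes problem with the reflection guard (sign flip of
the smallest singular vector when the candidate rotation has negative
determinant).  Chains are paired Cα-to-Cα by identical author number
(and name, when both are present; mismatching names are dropped and
logged) — the declared convention for targets with missing residues.
Receptor-chain auto-detection picks the chain with the best
residue-number overlap with the template; a per-entry override exists.
RMSD on a ligand atom selection superposes *on the selection itself*
(so a heteroatoms-only comparison is aligned on the heteroatoms), and
per-atom distances after superposition are reported.

Ligand relaxation minimises with MMFF94s from the crystallographic pose
— no conformer search — with a 1e-4 kcal/mol/Å gradient tolerance and a
2000-step cap, chosen for determinism on one machine.  Eclipsed-symmetric
saddle points are genuine fixed points of a local minimiser, which is
why the relaxation tests start slightly off-symmetric.

## Pocket, interactions, helix-12 contacts

A pocket residue has ≥ 1 heavy atom within 4.5 Å of ≥ 1 ligand heavy
atom; waters are excluded.  Heavy atoms only: X-ray inputs lack
hydrogens and placed hydrogens would make pocket membership depend on
the protonation model.  Occurrence statistics across complexes are keyed
by (residue name, author number).

Hydrogen bonds use fixed geometric criteria — D···A ≤ 3.5 Å and
D–H···A ≥ 120° when a donor hydrogen exists — replacing trained
probabilistic scores with something reproducible and tunable.
Donor/acceptor typing: N/O/S with an attached hydrogen donate; oxygens
always accept; nitrogens accept when bare (≤ 3 connections, no positive
charge); thioether sulphur is excluded.  Salt bridges are oppositely
charged N/O pairs ≤ 4.0 Å.  Water bridges are waters with simultaneous
contacts to a ligand polar atom and a protein polar atom; water
hydrogens are not modelled, so water-involved contacts are accepted on
distance alone (the angle term only applies where a donor hydrogen
exists).

The helix annotation (H1–H12 ranges on the 206–477 numbering) ships as a
frozen configuration consistent with the published anchor residues
(Ser289 ∈ H3, His323/Tyr327 ∈ H5, Lys319 ∈ H4, His449 ∈ H11,
Tyr473 ∈ H12, Lys474/Tyr477 after H12, His466 in the H10/11–H12 linker);
anchors are asserted at load time.  Ser342 is labelled β-sheet here —
the common secondary-structure assignment — and the H5 label it carries
in parts of the literature is logged as a discrepancy rather than
enforced.  A DSSP-based recompute function (`compute_helix_annotation`,
via mdtraj) regenerates ranges from any structure, numbering helical
segments sequentially.  "Vicinity of H12" spans the H10/11–H12 linker
through the chain terminus, so contacts of His466, Lys474 and Tyr477
are in scope.  Protein–protein contacts require exactly one partner in
the focus region and |Δresidue| > 2, excluding the helix's own i,i+4
pattern; unique contacts are the holo-minus-apo set keyed by residue
pair and interaction type.

## Pharmacophore model

Annotation points follow the atom/projected/centroid taxonomy: Don/Acc/
Cat/Ani/HydA on atoms, Don2/Acc2 projected 2.8 Å along hydrogen or
lone-pair directions, Aro/PiR at aromatic ring centroids, Hyd at
centroids of hydrophobic-atom clusters (single-linkage, 2.0 Å link
distance; a hydrophobic atom is a carbon with no N/O/F neighbour and no
formal charge).  Delocalised charge groups (carboxylate, guanidinium-like)
are annotated at the group centroid.  Metal-ligator and ring-projection
kinds are recognised in the taxonomy but not emitted — no metal sites or
π-projection features appear in this workflow.

The query is built from the annotation points of the aligned most-active
agonists: per feature, points of the allowed kinds are complete-linkage
clustered at 2.0 Å, and the cluster supported by the most distinct
actives (restricted to the feature's stated pocket arm when arm
reference points are configured) becomes the centroid; ties break by
distance to the arm reference, then by coordinates.  Feature radii
default to 1.2 Å (per-feature overrides), encoding the permissible
geometric variation.  Matching is static — the ligand must already be in
the template frame; a frame-mismatch heuristic (every annotation point
farther than 25 Å from every centroid) catches untransformed input.  The
classification rule is `(F1 ∨ F2) ∧ F3 ∧ (F4 ∨ F5 ∨ F6 ∨ F7)`; the
explanation lists failed clauses.  Feature-vector ordering and
"most-active" selection use the lower bound of interval activity data.

## Synthetic fixtures: what they emulate and what they do not

The generator builds ideal α-helices (φ = −57°, ψ = −47°, standard
peptide geometry, idealised side-chain rotamers; glycine flanks keep the
contact helices slim) arranged radially around ligands assembled from
parameterised fragments (phenyl, alkyl, methane, carboxylate, hydroxyl,
amide, protonated amine, thiazolidinedione head).  Placement is a seeded
search over sphere directions, a cone azimuth and a spin about the
contact-bond axis; for hydroxyl/thiol donors the spin is solved
analytically so that the rotamer the protonation module will actually
select points straight at the planted acceptor.  Exclusion rules keep
every non-planted polar pair beyond 3.65 Å and every non-planted residue
strictly outside the pocket cutoff (0.05 Å clearance — sufficient
because the geometry is deterministic), so detected interactions equal
planted ones exactly.  Dead-ended arrangements restart deterministically
with derived sub-seeds.  Fixtures are written as real PDB files and
re-read through the parser, so tests exercise ingestion rather than
bypassing it; regeneration under a fixed seed is byte-identical.

These fixtures emulate contact geometry, not proteins: there is no
realistic fold, no crystallographic disorder, no missing residues, no
alternate conformers beyond what tests construct, and the ligands are
small fragment assemblies rather than drug-sized molecules.  Passing
tests therefore demonstrate that the criteria and bookkeeping are
implemented exactly as specified — not that the criteria themselves
recover every interaction in real, noisy structures.

Expected annotation counts in manifests come from per-fragment tables
plus a bond-graph connected-component count for hydrophobic clusters —
a different route than the annotator's distance-linkage clustering, so
the comparison is not circular.

## Internal geometry conventions

The internal-coordinate placement routine (`place_atom`) uses a
left-handed torsion screw sense: the IUPAC dihedral of the placed atom
is the negative of the torsion argument.  Every torsion table in the
package uses the same convention, so results are self-consistent; the
convention is asserted by a property test and documented on the
function.

## Reference-data availability

The analyses that reproduce published reference numbers (template LBD
residue count, relaxed-rosiglitazone RMSD, cross-complex ligand RMSD
band, superposition RMSD band, pocket union/intersection of the nine
most active complexes, key hydrogen-bond residues, and the feature-vector
table) require the ~25 PDB entries of the evaluation set.  Those entries
are fetched on demand and cached (`cache/<accession>.pdb`); the
corresponding acceptance tests fail with an explicit fetch error when
neither network nor cache is available, while everything synthetic runs
offline.  The packaged activity table (complex, ligand, EC50 interval,
printed feature vectors) ships as CSV and drives ordering, most-active
selection and the classification consistency check.

## Verification study sizes

`scripts/acceptance.py` uses: 4 random point sets (n = 4–10) for the
rotation-grid oracle (7 nested refinement rounds × 300 samples), a
10-residue helix for transform recovery, 10 noise draws at σ = 0.5 Å,
8 toy complexes for pocket/H-bond/water-bridge recovery, 4 for salt
bridges, 60 noisy copies for the brute-force pocket comparison, 8
fragment specs for annotation bookkeeping, and the full 128-vector
truth table plus the 21-row activity table for the classification rule.
These sizes keep the full study under half a minute while every
quantity is recomputed from scratch at run time.
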