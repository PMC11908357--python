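# Methods

This note documents the models, rules and numerical choices behind each
stage of the curation workflow, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Splitting model

A deposited entry is decomposed around each ligand occurrence. Two ligand
classes exist: *small molecules* (a residue whose name matches a CCD code
supplied by a reference-dataset row; each copy across chains is its own
instance) and *polymers* (a whole short chain, at least 2 and fewer than
20 residues — typically peptides, oligosaccharides or oligonucleotides).
Association is chain-wise: any biopolymer chain with a heavy atom closer
than `protein_assoc_cutoff` (10 Å, strict inequality, any-heavy-atom
minimum distance) to any ligand heavy atom is kept whole; chains are never
trimmed to the contact shell, because binding-site completeness matters
more than file size. `HETATM` residues with a heavy atom closer than
`additive_cutoff` (4 Å) to the associated protein become additives; waters
count as additives by default (`drop_waters` removes them). Residues
serving as the ligand of another bundle of the same entry are excluded
from additives, so roles are disjoint within a bundle. Distance scans run
on heavy atoms only, through a k-d tree; a brute-force all-pairs scan is
the test oracle.

## Filters

Four rules, all evaluated on every bundle (no short-circuit) so a report
lists every defect:

* **covalent binder** — any CONECT pair joining a ligand atom to a protein
  atom; absence of CONECT records passes vacuously. Covalent binding
  involves bond formation and needs different physics than non-covalent
  scoring.
* **rare element** — any ligand element outside `allowed_elements`
  (default H, C, N, O, F, P, S, Cl, Br, I). Such ligands are too sparse to
  learn from. An element symbol not in the periodic table raises a data
  error instead of a filter verdict.
* **small ligand** — fewer than `min_heavy_atoms` (4) heavy atoms:
  O₂-, CO₂-, azide-sized binders are out of scope.
* **steric clash** — minimum protein–ligand heavy-atom distance below
  `clash_cutoff` (2 Å). Sub-bonding contacts are electron-density
  artifacts, and this rule also catches covalent binders whose bond was
  never recorded in CONECT.

All "closer than" cutoffs are strict (<); a pair at exactly the cutoff
passes. Additives are excluded from the clash scan: the rule concerns
protein–ligand pairs.

## Ligand fixing

Crystallographic ligand records carry only elements and coordinates. The
repair pipeline is: *perceive → reference → validate → transfer →
protonate*, and it never moves a heavy atom (input/output heavy-atom RMSD
is exactly zero, asserted at run time).

**Perception.** Atoms are bonded when their distance is below
(r_cov(i)+r_cov(j)) × `bond_perception_tolerance` (1.3; covalent radii
from the periodic-table tables shipped with the cheminformatics toolkit).
Provisional orders are all single — they are untrusted by construction,
which is why the matching step ignores them. Disconnected fragments are
kept and flagged.

**Reference resolution.** Precedence: user override table (CSV of code →
corrected SMILES, for depositions known to be wrong) → CCD/BIRD lookup
(an offline table-backed fetcher and a cached network fetcher are
interchangeable; the lookup-function contract is code → SMILES or
not-found) → peptide builder. The peptide builder handles polymers made
only of standard alpha-amino acids: residues are joined by amide-bond
formation with free neutral termini and L stereocenters; anything else
(cyclic peptides, disulfide-linked polymers, non-standard monomers) is an
unresolvable reference and the entry is excluded, since its correctness
cannot be verified automatically. Multi-fragment references keep the
largest organic fragment (counter-ions stripped).

**Geometric validation.** Some deposited reference SMILES are corrupted
with all bonds single. These are caught by comparing the reference's
carbon hybridizations against the crystal geometry: a 3-substituent
carbon that is planar (out-of-plane torsion below
`planarity_tolerance_deg`, 10°) cannot be sp³, and a clearly pyramidal one
(above 25°) cannot be sp²; for 2-substituent carbons a bond angle above
118° argues against sp³, flagged only when at least two such atoms concur
(a single wide angle can be ring strain). The check needs an atom mapping
and is therefore inconclusive (passes) when the graphs are not
isomorphic — the transfer step then fails with its own diagnostic.

**Bond-order transfer.** The inferred and reference heavy-atom graphs are
compared by element-labelled graph isomorphism (VF2; bond orders ignored).
If isomorphic, orders, aromaticity, hybridization and formal charges are
copied through the mapping onto the crystal coordinates; any one of
multiple automorphic mappings is chemically equivalent. A mismatch —
different atom counts or connectivity — means missing atoms or distorted
geometry, and the entry is excluded with a diagnostic naming the
difference. Stereochemistry is then re-assigned from the 3D coordinates,
not taken from the reference string: the crystal geometry is the ground
truth being curated.

**Protonation (pH 7.4).** A fixed, ordered SMARTS rule set, chosen for
high-throughput determinism over per-molecule pKa estimation:

1. deprotonate carboxylic/sulfonic/sulfinic/phosphonic acids, thiophenols,
   hydrazoic acid, tetrazoles and N-hydroxy groups; neutral nitro groups
   are normalized to the charge-separated form;
2. deprotonate enols in the O=C−C=C−OH motif;
3. protonate guanidines/amidines (the sp² nitrogen), then aliphatic
   amines, then isolated aliphatic imines — never anilines, never amines
   whose nitrogen touches an atom other than C or H, never amide-adjacent
   nitrogens;
4. among protonated amine nitrogens within three bonds of each other
   (diamines, piperazines) exactly one keeps its proton: the nitrogen with
   more heavy-atom substituents is returned to neutral, ties broken by
   canonical atom rank. Two adjacent cations are not a realistic state at
   physiological pH.

Every pattern requires the pre-transformation charge state, so the whole
assignment is idempotent. Explicit hydrogens are added last, at standard
geometry. Whether non-conjugated imines should be protonated is genuinely
ambiguous; the rule set protonates amidine/guanidine-like nitrogens and
isolated aliphatic imines and logs each hit, so the decision is auditable.

## Protein fixing

**Detection.** The full deposited sequence per chain comes from the mmCIF
header (`pdbx_poly_seq_scheme`, unmodeled positions marked by a missing
author number) rather than SEQRES, which in some depositions omits the
unmodeled residues — and a naive rebuild from such a SEQRES would fuse the
gap with an unphysical peptide bond. Missing atoms are template heavy
atoms absent from modeled residues; missing residues form segments,
classified terminal when they touch either sequence end.

**Repair rules.** Missing atoms are always rebuilt; internal segments are
rebuilt when their length is ≤ `missing_segment_max` (10; a gap of exactly
10 is rebuilt — "longer than" is strict); terminal segments and longer
gaps are left absent, because they usually correspond to disordered
regions, unexpressed constructs or purification tags, and the chain break
is preserved in numbering and connectivity. Every added atom carries
`is_experimental = False` (serialized as occupancy 0.00) and a REMARK
annotation in the output PDB.

**Geometry.** Missing atoms are placed by superposing an idealized
conformer of the residue (embedded once from a per-residue template with
a fixed seed, then force-field relaxed) onto at least three shared atoms
by least-squares (Kabsch). Missing segments are grown from the preceding
anchor with ideal backbone internal geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å; angles 111.2°/116.2°/121.7°) and a single shared (φ, ψ) pair
scanned on a 12° grid so that the grown chain closes onto the next
anchor's nitrogen; among closing candidates (gap < 1.2 Å) the one with
the largest clearance from existing atoms wins, and any candidate with an
atom within 1 Å of an existing non-anchor atom is rejected. Loop
*conformation* quality is explicitly out of scope — the subsequent
constrained minimization relieves residual strain, which is the division
of labour the workflow is designed around. A residue that cannot be
repaired fails the entry only when it lies within the association cutoff
of the ligand; elsewhere it is logged and tolerated.

**Hydrogenation.** Titration states at pH 7.4 are fixed: LYS and ARG
cationic, ASP and GLU anionic (carboxylates), protonated N-terminus,
deprotonated C-terminus, CYS neutral unless its Sγ is within
`disulfide_cutoff` (2.3 Å) of another Sγ. Histidine stays neutral; the
Nδ-H (HID) vs Nε-H (HIE) tautomer is chosen per histidine by counting
polar heavy atoms (N/O of other residues) within 3.5 Å of each ring
nitrogen and putting the proton on the *less*-contacted nitrogen, leaving
the contacted one free to accept — protein neighbourhoods are donor-rich
(backbone amides, hydroxyls), so a nearby polar atom is most often a
donor. Ties, including the isolated-histidine case, default to HIE, the
common convention. Hydrogens are generated from the molecular graph with
coordinates at standard geometry; heavy atoms are never moved, and
protonation strips existing hydrogens first so it is idempotent.

Bond perception for the protein molecule is template-based per residue
with two permitted inter-residue bond types: peptide C(i)–N(i+1) between
sequence-adjacent residues and Sγ–Sγ disulfides. Any other inter-residue
proximity bond (possible near approximately-placed rebuilt atoms) is
removed, and peptide bonds the reader missed are added when the C–N
distance is below 2.5 Å.

## Refinement

The fixed protein and ligand are combined into one system and minimized
under the UFF force field — chosen as a single uniform classical force
field that parameterizes both the protein and arbitrary organic ligands —
in vacuum, with no periodic box, since only local relaxation of hydrogens
and rebuilt atoms is wanted. The constraint is a *contract*: every
experimentally resolved atom must end at exactly its input coordinate.
It is enforced with fixed points in the minimizer, which removes those
degrees of freedom from the optimization outright, so the contract holds
to machine precision; the result records the maximum constrained-atom
displacement (must be 0) and the initial/final energies (final ≤ initial
whenever the initial energy is finite). Minimization caps at
`minimize_max_iterations` (10,000) steps. A non-finite initial energy —
residual overlap among added atoms — triggers one deterministic 0.05 Å
perturbation of movable atoms before failing. No stochastic steps are
taken, so repeated runs give identical coordinates. Additives are not
part of the minimized system (configurable); they are deposited as a
separate PDB.

Ligand partial-charge electrostatics are not included in the vacuum UFF
minimization; for hydrogen placement and clash relief the bonded plus
van-der-Waals terms dominate, and no scoring claim is made from the
energies — they serve as a monotonicity diagnostic only.

## Affinity normalization

Annotations of the form `<measure><qualifier><value><unit>` with measure
∈ {Kd, Ki, IC50, EC50}, qualifier ∈ {=, ~, >, <, >=, <=} and units fM–M
are parsed to molar. ΔG = R·T·ln K with R = 8.31446×10⁻³ kJ mol⁻¹ K⁻¹,
attached only to exact (qualifier "=") Kd or Ki: IC50/EC50 depend on
assay conditions and inhibition mechanism and are carried through
unconverted, and range qualifiers block conversion but the records are
retained for censored-data use. T is fixed at 298.15 K (standard
conditions; configurable) — the thermodynamic relation itself does not
fix a temperature, so one must be chosen. Records merge by (entry,
ligand, measurement) with source precedence biolip > moad > other,
value conflicts logged, and any Ki *or* Kd above `max_valid_ki` (10³ M —
a physically meaningless affinity) dropped with reason `invalid-affinity`;
the rule is applied to both constants since both are equilibrium
constants. Unparseable rows are quarantined with their raw text, never
silently dropped.

## Analysis

*Rotamer changes.* Copies of the same chain in a crystal are resolved
against separate electron density, so their side-chain conformations are
independent observations. Residues are paired by identical sequence
position; a residue is "near the site" when any heavy atom in either
chain is within `site_cutoff` (default 10 Å, reusing the association
cutoff — the definition is a documented choice, and conclusions depend on
it) of a ligand heavy atom. χ1–χ4 are computed from the standard
rotamer-library atom quadruples; a change is any defined χ differing by
more than `rotamer_angle_cutoff` (60°) under the periodic difference,
with the 2-fold-symmetric terminal torsions (ASP χ2, GLU χ3, PHE/TYR χ2)
folded by 180° so equivalent-atom naming cannot fake a change. GLY and
ALA have no χ and are excluded from counts. The comparison is symmetric
in the chain order.

*RMSD* is computed after optimal least-squares rigid superposition
(Kabsch SVD with the proper-rotation determinant correction); the test
oracle is Horn's closed-form quaternion method, an independent
derivation.

*Ligand properties* are the eight standard descriptors (molecular weight,
Crippen cLogP, fragment-contribution TPSA, rotatable bonds excluding
amides and ring bonds, heavy atoms, H-bond donors/acceptors by the
Lipinski definitions, and QED), computed on the implicit-hydrogen graph.

## Synthetic fixtures

The generator emulates exactly the information content of a deposited
entry: an ATOM block for a receptor, a bare HETATM block for the ligand
(hydrogens stripped, no bond orders), CONECT records for intra-ligand
bonds, and an mmCIF-style header with the full sequence and per-position
modeled flags. The receptor is an ideal-geometry polyalanine α-helix
(φ = −57°, ψ = −47°, standard bond lengths/angles, L-configured CB
placement) with optional side-chain substitutions built from the same
idealized templates the repair module uses; the ligand (benzamidine by
default — aromatic ring plus a protonatable amidine) is conformer-embedded
from SMILES with a seeded ETKDG and placed by seeded rotation plus
bisection along a fixed direction until the minimum heavy-atom distance
equals the requested value (default 4 Å). Ten injectable defects map
one-to-one onto filter and fixer code paths, and each fixture carries a
machine-readable manifest of the stage at which the pipeline must stop,
making the integration test data-driven. Generation is a pure function of
(spec, seed): identical inputs give byte-identical files.

What the fixtures deliberately do **not** emulate: real protein folds and
packing (a single helix has no tertiary contacts), crystallographic noise
and anisotropy, alternate conformations with partial occupancies beyond
the simple alt-loc case, multi-copy assemblies, and chemically exotic
ligands (organometallics, macrocycles). Passing the fixture suite
therefore demonstrates that the *logic* of every stage — thresholds,
classifications, graph matching, constraint handling — is correct on
well-posed inputs; it does not by itself certify behaviour on pathological
real depositions, which is why the structure readers are deliberately
tolerant and every exclusion is logged rather than silent.

## Verification problem sizes

The default verification suite uses 20-residue receptors (8 residues for
the 100-complex clash-oracle scan), a 55-molecule drug-like round-trip
panel, and 3–4 full constrained minimizations of ~350-atom systems;
together they exercise every stage in well under a minute of compute
apiece while keeping each check interpretable.

## Known limitations

* Bond-order transfer requires a correct, resolvable reference; ligands
  without one (most non-peptidic polymers) are excluded by design rather
  than guessed at.
* The protonation rules are deterministic pattern rules, not pKa
  predictions; unusual microstates (e.g. proximal acid/base pairs with
  shifted pKa) follow the rules, not the thermodynamics.
* Rebuilt loops have idealized, closure-optimized backbones; they mark
  *presence*, not conformational truth.
* The HID/HIE criterion is a geometric heuristic; it does not model the
  hydrogen-bond network self-consistently across neighbouring titratable
  sites.
* Refinement energies are UFF vacuum energies, meaningful only as a
  decrease diagnostic.
* mmCIF support is header-only; entries whose coordinates exist only in
  mmCIF (very large structures) are out of scope, as is crystallographic
  symmetry expansion.
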