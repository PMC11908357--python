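# plcurate

Curation workflow for non-covalent protein–ligand complex structures with
binding-affinity annotations.

Deposited crystal structures are an awkward starting point for scoring
functions and structure-based ML: ligands come as bare `HETATM` blocks
without bond orders, charges or hydrogens; binding sites may have missing
side-chain atoms or whole missing loops; some "ligands" are covalent
adducts or crystallographic artifacts with sub-2 Å contacts; and the
affinity annotations mix Kd, Ki, IC50 and EC50 across units and sources.
`plcurate` turns such raw inputs into consistent, chemistry-complete
complexes:

1. **Split** each entry into ligand, protein and additives. A ligand is
   either a small molecule named by a Chemical Component Dictionary (CCD)
   code, or a short polymer chain (2–19 residues). Every biopolymer chain
   with a heavy atom within 10 Å of the ligand is the associated protein;
   `HETATM` residues within 4 Å of that protein (ions, solvents,
   co-factors) are additives.
2. **Filter** out complexes that cannot be modelled as non-covalent
   binding: ligands covalently bonded to the protein (CONECT evidence),
   ligands with elements outside {H, C, N, O, F, P, S, Cl, Br, I}, ligands
   with fewer than 4 heavy atoms, and complexes with protein–ligand
   heavy-atom pairs closer than 2 Å.
3. **Fix the ligand**: perceive connectivity from interatomic distances,
   obtain a reference SMILES (override table → CCD lookup → peptide
   builder for standard-amino-acid polymers), verify the reference's
   carbon hybridizations against the crystal geometry, transfer bond
   orders / aromaticity / formal charges through an element-labelled graph
   isomorphism onto the crystal coordinates, and assign pH 7.4 protonation
   states from a fixed SMARTS rule set (acids, nitro, thiophenols, azides
   and N-oxides deprotonated; aliphatic amines and guanidines/imines
   protonated; anilines and hetero-substituted amines untouched; one
   proton per diamine/piperazine; O=C−C=C−OH enols deprotonated).
4. **Fix the protein**: compare the model against the full deposited
   sequence from the mmCIF header, rebuild missing heavy atoms and short
   internal gaps (≤ 10 residues) from idealized residue templates, leave
   terminal and long gaps absent with the chain break preserved, then add
   hydrogens with fixed titration states (LYS/ARG⁺, ASP/GLU⁻, neutral HIS
   with the Nδ/Nε tautomer chosen per histidine, CYS neutral unless
   disulfide-bonded).
5. **Refine** the recombined complex by constrained energy minimization:
   every experimentally resolved atom is frozen; only hydrogens and
   rebuilt atoms move.
6. **Normalize affinities**: parse heterogeneous annotations to molar
   units, convert exact Kd/Ki to binding free energies via
   ΔG = RT ln K (T = 298.15 K), drop invalid values (Ki or Kd > 10³ M),
   and merge multi-source tables with provenance.

A deterministic synthetic-complex generator (`plcurate.fixtures`) builds
toy receptor–ligand systems with injectable defects so that every filter
and failure mode is exercised offline, without any database download.

## Worked example

Generate a clean synthetic complex and curate it:

```bash
plcurate fixtures make --seed 11 --out entry/
plcurate curate entry --input entry/ --out curated/
```

which prints

```
entry: succeeded
  entry_FIX1_LIG_B_1: succeeded
    split: ok
    filter: ok
    ligand_fix: ok
    protein_fix: ok
    refine: ok: E 2044.8 -> 790.8
```

`curated/entry_FIX1_LIG_B_1/` then holds `protein.pdb` (hydrogenated,
with REMARK lines naming every rebuilt atom), `ligand.sdf` (correct bond
orders and formal charges in the charge block) and `stages.json`. The
refine line reports the force-field energy before and after constrained
minimization — it decreases because added hydrogens relax, while every
deposited coordinate is unchanged. Injecting a defect flips the outcome;
for example `--defect create_clash:1.5` yields

```
entry: filter-rejected
  entry_FIX1_LIG_B_1: filter-rejected
    split: ok
    filter: steric-clash: ligand C3(#120) vs protein CB(#67) at 1.50 A < 2.0 A
```

the 1.50 Å being exactly the injected contact distance.

Affinity normalization from the library:

```python
>>> from plcurate.affinity import parse_affinity
>>> rec = parse_affinity("Kd=2nM")
>>> rec.value_molar, round(rec.delta_g, 2)
(2e-09, -49.65)
```

−49.65 kJ/mol is RT ln(2×10⁻⁹) at 298.15 K.

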