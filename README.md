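# ncaatools

Tools for preparing **non-canonical amino acids (ncAAs)** — post-translationally
modified residues, unnatural side chains, non-ribosomal building blocks —
for NMR structure calculation with CYANA- and CNS-family software.

Structure calculation engines only know residues that exist in their
libraries. For anything beyond the 20 canonical amino acids the user must
supply a residue template with correct connectivity, **IUPAC-conformant
atom names**, and (for side-chain cyclised peptides such as disulfide-rich
toxins or vancomycin) a way of expressing the cross-link inside a
torsion-angle-dynamics tree. This package automates those steps for
structural biologists and peptide chemists:

* **`ncaatools.namer`** — automatic IUPAC naming of arbitrary side chains.
  Heavy atoms are labelled by their bond distance *d* from Cα with a
  transliterated Greek letter (β for *d* = 1, γ for *d* = 2, …, ω for
  *d* = 23, then two-letter codes αα…ωω from *d* = 24, giving 600 positions
  in total) plus a chain number for branches at equal distance. Chain
  priority follows the Cahn–Ingold–Prelog rules on the hierarchical
  digraph (unsaturations expanded into phantom duplicate atoms);
  graph-identical branches at a tetrahedral centre are ordered
  geometrically by the sign of the 4×4 determinant
  det[(x,y,z,1) of branch₁; branch₂; centre; anchor], the same construction
  that numbers prochiral methylene hydrogens (H*ₓ*2/H*ₓ*3).
* **`ncaatools.template`** — recognition of the capped submission formats
  Ace–Ala–X–Ala–NMe (internal), X–Ala–NMe (N-terminal) and Ace–Ala–X
  (C-terminal), and excision of the central group X as a standalone,
  renamed residue with CCD-style component-CIF output.
* **`ncaatools.linker`** — side-chain cross-linking for CYANA: two residue
  templates, each extended at least one atom beyond the linking bond, are
  merged by retyping the extension atoms (and their hydrogens, never
  PSEUDO atoms) as `DUMMY`, generating one upper-distance restraint
  (default limit 0.04 Å, weight 10) per overlap-atom pair, and emitting
  the sequence-file `link` statement that removes the repulsion between
  the linking atoms. After the calculation, `finalize_structure` strips
  the DUMMY atoms from the model ensemble and restores residue names
  (e.g. CYSX → CYS).
* **`ncaatools.cnspatch`** — CNS building blocks: standard backbone atom
  types and charges are retained for N, HN, CA, HA, CB, O; every other
  atom receives a fresh type, and the residual charge is folded into the
  non-backbone atom of largest |q| so the residue keeps its net charge.
* **`ncaatools.fixtures`** — programmatic generation of every test input
  (canonical residues, capped templates, extended-cysteine libraries,
  random side chains) from internal coordinates, plus an independent
  brute-force CIP oracle used to cross-check the namer.

## Worked example: a disulfide via DUMMY-overlap templates

```bash
# an extended cysteine template: Cα–Cβ–Sγ plus the partner's Sγ′–Cβ′ copy
ncaatools fixtures cysx-lib -o cysx.lib

cat > spec.yaml <<EOF
residue_a: {res_index: 3}
residue_b: {res_index: 12}
linking_bond: [SG, SG]
overlap_pairs:
  - {ext: a, ext_atom: SGX, real_atom: SG}
  - {ext: a, ext_atom: CBX, real_atom: CB}
  - {ext: b, ext_atom: SGX, real_atom: SG}
  - {ext: b, ext_atom: CBX, real_atom: CB}
EOF

ncaatools link cysx.lib cysx.lib spec.yaml \
    --lib-out linked.lib --upl-out link.upl --seq-out link.seq \
    --registry-out registry.json
cat link.upl
```

```
   3 CYSX  SGX     12 CYSX  SG        0.04    10.00
   3 CYSX  CBX     12 CYSX  CB        0.04    10.00
  12 CYSX  SGX      3 CYSX  SG        0.04    10.00
  12 CYSX  CBX      3 CYSX  CB        0.04    10.00
```

Each line pins one extension copy (e.g. `SGX` of residue 3) onto the real
atom it duplicates in the partner residue, to within 0.04 Å at weight 10 —
tight enough to fuse the two half-links into one covalent geometry during
torsion-angle dynamics, while the `link.seq` statement
(`link SG 3 SG 12`) switches off the non-bonded repulsion between the two
sulfurs. In `linked.lib` the four extension atoms (`SGX`, `CBX` and their
hydrogens) are retyped `DUMMY`; nothing else in the templates changes.
After the structure calculation:

```bash
ncaatools finalize models.pdb --registry registry.json \
    --rename CYSX=CYS -o final.pdb
```

removes every DUMMY atom from every model and renames the residues, giving
a deposition-ready ensemble.

Naming works the same way from the shell — `ncaatools rename orn.pdb -o
orn.tab` writes the old→new table (side chain CB, CG, CD, NE for
ornithine), and `ncaatools excise capped.pdb --cif-out orn.cif` recognises
a capped template and writes the excised, renamed component.

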