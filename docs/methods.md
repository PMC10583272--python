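# Methods

This note records the algorithms, conventions and design decisions behind
`ncaatools`, in the spirit of a software-methods appendix: what each
procedure assumes, which knobs matter, and what the synthetic test inputs
do and do not demonstrate.

## Molecular graphs

All algorithms operate on an explicit molecular graph: atoms with element,
coordinates and flags, bonds with order (1, 2, 3 or aromatic). Bonds and
hydrogens must be present in the input — nothing is perceived from
coordinates. PDB input therefore requires CONECT records (orders default
to single); Mol2 carries orders in its bond table. Inputs whose heavy-atom
valences suggest missing hydrogens are flagged and logged but not
rejected, since the defect may be confined to a region the caller does not
use.

## Side-chain naming

**Positions.** Heavy side-chain atoms are labelled by bond distance from
Cα, measured through side-chain bonds only (backbone N and C′ are removed
before the breadth-first search, so proline's Cδ is three bonds out, not
two via the ring nitrogen). Distance *d* maps to a transliterated Greek
letter — the table is α A, β B, γ G, δ D, ε E, ζ Z, η H, θ Q, ι I, κ K,
λ L, μ M, ν V, ξ X, ο O, π P, ρ R, σ S, τ T, υ U, φ F, χ C, ψ Y, ω W, and
is configurable — with α reserved for position 1 (the Cα itself, *d* = 0).
Two-letter codes αα…ωω begin at *d* = 24 (position 25), for 600 positions
in total. This is the only convention under which the single letters end
at ω (*d* = 23) and the label space closes at ωω.

**Chain numbers.** Branches at equal distance are disambiguated by a chain
number; the higher-priority branch gets the lower number. Priority is CIP
rule 1a on the hierarchical digraph: unsaturated bonds are expanded into
phantom duplicate atoms (one per end per extra bond order); aromatic
systems are handled Kekulé-free, each aromatic atom gaining a single
duplicate of its own element, so that graph-equivalent ring branches
remain equivalent (phenylalanine's two ortho carbons must tie). Branch
comparison is a recursive lexicographic comparison of (atomic number,
ordered child list), children sorted by the same ordering and padded with
phantoms; ring closures contribute childless duplicates of the revisited
atom. This depth-first recursion can in principle diverge from a strict
breadth-first sphere-by-sphere reading in contrived molecules; for
amino-acid side chains in the tested corpus the two agree, and the
brute-force oracle (below) pins the implemented semantics.

**Geometry.** A tie between exactly two graph-identical branches at a
tetrahedral atom is broken geometrically: the sign of the 4×4 determinant
whose rows are the homogeneous coordinates of the two candidates, the
central atom, and the anchor atom on the path back to Cα (which always
carries the highest priority, so its identity need not be known). Swapping
the candidates or reflecting all coordinates flips the sign, which is what
makes the assignment stereochemically meaningful: a d-residue receives
swapped numbers on its diastereotopic pairs — both the prochiral
methylene hydrogens (H*ₓ*2/H*ₓ*3) and geometrically resolved heavy pairs
(leucine Cδ1/Cδ2, valine Cγ1/Cγ2). Planar centres and three-way ties are
left in input order and recorded as arbitrary in the audit trail; they are
rotationally or symmetrically equivalent, so no observable assignment
hangs on them. The degeneracy threshold is |det| < 1e−9 relative to the
product of the edge lengths.

**Sweep and repairs.** Assignment proceeds shell by shell outward. Parents
are visited in order of their own chain number; each parent's best child
continues its chain, further children open new chains with the next free
number. An atom reached at the same distance from two parents (a ring
join) keeps the lower number on offer — this is what leaves
phenylalanine's ζ carbon on chain 1 and hence unnumbered. A final re-pass
pools the chains first opened inside graph-identical sibling branches and
re-deals them branch by branch, so a duplicated aromatic ring holds a
consecutive block of chain numbers rather than numbers interleaved with
its twin's.

**Names.** Heavy atom: element + positional letter + chain number, the
number dropped for a chain-1 atom that is the sole heavy occupant of its
shell. Applied literally this yields `CD` for isoleucine's δ-methyl where
archives use `CD1`; the deviation list ships with the package and a
`sticky_suffix` option restores the suffix after any upstream branch.
Hydrogens take H + the parent's positional part, numbered 2/3 by the
determinant for tetrahedral methylenes, 1..n by input order for rotational
sets (methyls, planar NH₂) — those indices are physically arbitrary and
are the one place where naming is not invariant under input-order
permutation (the name multiset still is). Pseudoatoms (Q + positional
part) are emitted for methyl and methylene groups and for
symmetry-equivalent aromatic CH pairs. Backbone atoms keep fixed names
(N, H, CA, HA, C, O, OXT); an N-methylated backbone names its methyl CN
with hydrogens HN1–3.

## Capped templates

The recognised constructs are Ace–Ala–X–Ala–NMe, X–Ala–NMe and Ace–Ala–X.
The classifier cuts the molecule at backbone amide bonds — C(=O)–N single
bonds whose nitrogen continues into a further heavy atom, a condition that
protects primary side-chain amides (Asn, Gln) — orders the fragments
N→C, and matches caps and flanking alanines structurally (either Cα
stereochemistry is accepted, since d-flanks arise from mirrored
templates). Position in the chain then identifies X, so X may itself be an
alanine. A group X containing further internal secondary amides would be
cut too and is reported as ambiguous rather than guessed at. Excision
returns X with its severed backbone atoms listed as attachment-point
annotations (no phantom atoms) and its side chain named as above.

## Library linking

A link spec names the two templates, their residue indices in the target
sequence, the linking bond, and the overlap pairs: each pair identifies
one extension-copy atom in one template with the real atom it duplicates
in the other. The extension is computed as the connected component beyond
the linking atom and validated both ways — every heavy extension atom must
be mapped, every mapped atom must lie in the extension — so partial
retyping cannot happen silently. Extension atoms and their hydrogens are
retyped `DUMMY` in place (PSEUDO records are never altered); the raw
record lines are preserved verbatim apart from the type-code field, and
re-linking a linked template is a no-op. One restraint per mapped pair is
written, in that pair's direction; for a symmetric link such as a
disulfide, where one template serves as both inputs, the two directions
give the familiar four restraints. Hydrogens retyped alongside their
parent get restraints only on request. The default limit (0.04 Å) and
weight (10) are configuration values: any positive limit within
experimental uncertainty serves, the weight making one overlap pair count
like ten distance restraints.

The exact CYANA `.lib` column layout and sequence-file link syntax are
dialects of this package (CYLIB-style records; `link <atom> <res> <atom>
<res>`); round-trips are byte-faithful, and conformance to a particular
CYANA build is deliberately not claimed.

Post-calculation cleanup operates on PDB text directly: registry-listed
atoms are dropped from every model, residue codes rewritten, serials
repacked per model. With nothing to do the text passes through
byte-identical. A residue engaged in two links is handled by feeding the
output template back in as input; there is no multi-link planner.

## CNS building blocks

The retained-backbone list is N, HN, CA, HA, CB, O — the carbonyl carbon
is deliberately not on it, and `retain_c=True` exposes the choice rather
than silently "fixing" it. Non-backbone atoms get fresh two-letter+index
type names scoped to the residue. The residual charge — target net charge
minus retained-backbone charges minus the input non-backbone charges — is
added to the non-backbone atom of largest |q|, ties broken by atom name
for determinism; conservation is enforced to 1e−6 e. Type names across
independently generated blocks are made unique by a deterministic letter
suffix, merging parameter-identical duplicates silently and never touching
a numeric parameter. Backbone-modified residues may retain a subset of the
standard names (`allow_missing_backbone`), with linkage statements left to
the user.

## Synthetic inputs and the oracle

All test inputs are generated from internal coordinates: ideal tetrahedral
(109.47°) and trigonal angles, a small element-pair bond-length table,
planar polygons for rings, deterministic direction slots so that growth
order fixes stereochemistry. This gives chemically meaningless but
stereochemically definite geometry — exactly what the algorithms consume.
Consequences worth keeping in mind: proline's ring is topologically closed
but geometrically open; random side chains are acyclic, single-bonded
trees over {C, N, O, S} (unsaturation and rings are exercised by the
canonical residues and purpose-built toys); nothing is energy-minimised.
Passing tests therefore demonstrate correctness of graph logic, priority
ordering and stereo-assignment on well-formed explicit-hydrogen inputs,
not robustness to distorted experimental coordinates.

The brute-force CIP oracle is an independent re-implementation used only
in tests: its own adjacency, its own breadth-first distances, its own
duplicate handling, fully materialised digraph trees compared by explicit
recursion without memoisation, capped at 25 heavy atoms. It shares only
the determinant construction with the namer, since both sides must consult
the same geometric convention for a tie. Agreement is enforced over every
canonical residue, the priority toys, and 200 seeded random side chains.

## Numerical and policy choices, at a glance

| Choice | Default | Why |
| --- | --- | --- |
| Degeneracy tolerance (determinant) | 1e−9 × edge-length product | platform-stable scale-free cutoff |
| Aromatic duplication | one self-duplicate per aromatic atom | keeps symmetric ring branches tied without choosing a Kekulé structure |
| Restraint limit / weight | 0.04 Å / 10 | conventional values; must only be > 0 and within experimental precision |
| Charge tolerance | 1e−6 e | bookkeeping guard, far below charge-model precision |
| Sole-occupant suffix | dropped (literal rule) | deviations documented; `sticky_suffix` restores common usage |
| Methyl/rotational H indices | input order | physically arbitrary; only the multiset is meaningful |

## Known limitations

Full CIP beyond rule 1a (mass numbers, E/Z and like/unlike descriptors) is
out of scope, as is bond or aromaticity perception, multi-residue groups
of interest, backbone (head-to-tail) cyclisation, and running any
structure-calculation engine. The oracle's exponential tree
materialisation limits it to small molecules by design.
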