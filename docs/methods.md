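# Methods

## Scaffold model

A cata-condensed polybenzenoid hydrocarbon (cc-PBH) has no carbon shared
by three rings, so its ring-adjacency (dualist) graph is a tree. We pin
each ring to a cell of the hexagonal lattice in axial coordinates; an
edge of the tree joins lattice-adjacent cells. One hard constraint is
enforced during growth: two rings fused to the same ring may not occupy
mutually adjacent cells (a 60° annulation angle), because the two outer
rings would then share a carbon with the central ring — that is
peri-condensation, outside this space. Everything else is allowed,
including embeddings where two non-fused rings land on adjacent cells or
on the same cell; those scaffolds are helicenes, which physically wind
out of plane, and are flagged rather than rejected. Fusion is defined
*only* by tree edges, never by incidental lattice adjacency, so helicene
graphs are built correctly despite their overlapping planar projections.

Enumeration is breadth-first growth: every scaffold with *n* rings
spawns children by attaching one hexagon at every admissible
(vertex, direction) slot; children are canonicalized and deduplicated.
The canonical code is the lexicographic minimum, over all 12 dihedral
direction maps of the lattice and all root choices, of a rooted
serialization of the direction-labelled tree. This is invariant under
rotation, reflection (hence mirror — enantiomeric helicenes are counted
once, as free isomers) and translation, and is bit-stable across runs.
Growth to 6 rings yields 1, 2, 5, 12, 37 scaffolds; the classic
catafusene series continues 123, 446 at 7, 8 rings, which the
implementation also reproduces (soft-capped at 8; untested beyond).

At 2–6 rings cells never repeat ([7]helicene is the smallest overlap),
but vertices are identified by tree position rather than coordinate, so
the representation remains valid through the soft cap.

## Isomer counting

(BN)₁ doping replaces two carbons by one B and one N without touching
hydrogens. Since B ≠ N, placements are ordered pairs of distinct atom
positions, and molecules are orbits of such pairs under the parent
graph's automorphism group (computed by VF2 self-isomorphism with
(element, h_count) vertex colors on the hydrogen-suppressed graph;
abstract-graph automorphisms include the molecular mirror, consistent
with free-isomer scaffold counting). Enumeration picks the smallest pair
per orbit; Burnside's lemma — (1/|G|)·Σ_g f_g(f_g−1) over fixed-atom
counts f_g — provides an independent count, asserted equal everywhere.
Naphthalene (|G| = 4, fixed-point counts 90 + 2 + 0 + 0) gives 23;
benzene (a test input outside the 2-ring-minimum space, |G| = 12) gives
the 3 azaborines.

## Descriptors

* **n_rings** — ring count.
* **n_LL** — longest straight dualist run, in tricyclic units: a run of
  L collinear rings contains L − 2 linearly annulated tricycles; a
  middle ring is "linear" exactly when its two fusion bonds are on
  opposite hexagon edges, which on the lattice means both run edges have
  the same direction. n_LL ≤ n_rings − 2 with equality iff fully linear.
* **b_inner / n_inner** — 1 iff the atom belongs to two rings (i.e. sits
  on a fusion bond); such an atom carries no hydrogen and makes three
  ring bonds.
* **n_SP** — graph distance between B and N minus one: the number of
  carbons on the shortest path between them. Ties in path choice are
  irrelevant because only the length is used. n_SP = 0 iff B–N bonded.
* **n_DR** — disrupted rings. A ring containing B or N cannot keep an
  uncompromised Clar sextet, and rings between the two heteroatoms are
  forced quinoidal. We count the union of all rings containing B, all
  rings containing N, and the rings on the dualist-tree path between a
  B-host and an N-host, minimizing the union over host choices when a
  heteroatom is inner (two host rings). The inner-atom convention (both
  host rings count; path minimized) is a deliberate interpretation of
  the quinoidal-propagation argument, isolated in `compute_n_DR` so it
  can be swapped without touching anything else. Bounds: 1 ≤ n_DR ≤
  n_rings.

The "five features" expand to a six-component numeric vector because the
inner/outer classification is one flag per heteroatom.

## Geometry filtration

Bond perception uses d(i,j) ≤ 1.2·(r_cov,i + r_cov,j) with Cordero
covalent radii (H 0.31, B 0.84, C 0.76, N 0.71 Å); separations under
0.4 Å are treated as corrupt geometry. Rearrangement is an
element-respecting graph-isomorphism test between the explicit-hydrogen
reference graph and the perceived graph — the same decision boundary as
comparing connectivity-layer InChI strings, with no external toolkit in
the loop. The rules: a molecule is discarded if *any* of its (up to six:
2 methods × 3 charge states) records rearranged; it is kept-but-flagged
if any ionic record carries an imaginary-frequency mark (flagged
molecules stay in the dataset but are excluded from adiabatic
ionization/affinity analyses); missing records produce a warning and
evaluation on what is present. Filtration is monotone: extra rearranged
records can only demote a molecule.

Test geometries come from the package itself: exact lattice coordinates
(1.40 Å bonds, 1.09 Å C–H) with rings lifted 0.5 Å per dualist-depth
step. When any non-bonded pair still comes within 1.9 Å (helicenes and
tight cove/fjord motifs), a seeded ETKDG distance-geometry embedding
with MMFF refinement is used instead. Under this rule, perception
recovers the reference bond set exactly for all 57 scaffolds.

## Synthetic property surface

The generator emulates the *statistical shape* of the DFT dataset, not
its values, so the analysis stage has a ground-truth surface to recover:

* gap (eV) = 7.2 − 0.18·n_rings − 0.10·n_LL − 0.45·n_DR
  + 1.2/(n_SP + 1) + 0.12·(n_SP odd) + inner/outer offset
  (−0.06 both-outer … +0.06 both-inner) + N(0, 0.12), clipped at 0.
* E_rel (kcal/mol) = 1.6·n_SP + 3.5·n_DR − 12·[n_SP = 0]
  + B/N-position offsets (B-inner stabilizing, consistent with the
  B–C/C–C bond-energy argument) + N(0, 2.0), then shifted so each
  n_rings group's minimum is exactly 0.

Coefficient choices encode the qualitative relationships: gap decreases
with size, linear stretch and disruption; the 1/n term gives the
polyene-like decay with B–N separation and the parity term the odd/even
zigzag of the two resonance series; bonded B–N pairs are strongly
stabilized electrostatically. n_DR deliberately carries the dominant gap
coefficient, reflecting disruption of cyclic conjugation as the
strongest single effect. One documented ambiguity: descriptive text
about E_rel versus n_DR can be read in either direction; the generator's
default follows the thermodynamic rationale (more disruption → less
stable → higher E_rel) and exposes the sign as a plain coefficient
(`erel_DR_coef`) rather than hard-coding the reading.

HOMO/LUMO are centered at −3.5 eV so gap = LUMO − HOMO holds exactly;
SPE is synthesized in Hartree as −153·n_rings + E_rel/627.5095, so the
curation step can recover E_rel from SPE exactly. About 6.6 % of records
get an imaginary-frequency flag. Everything is driven by one
`numpy.random.default_rng(seed)` stream; zero-noise configs reproduce
the closed forms to machine precision.

What the generator does *not* emulate: real DFT noise structure
(systematic, not i.i.d. Gaussian), interactions between descriptors
beyond additivity, torsional-strain contributions of specific nonplanar
motifs, and any quantitative energy scale. Passing tests therefore
demonstrate that the pipeline recovers known structure from data of this
shape — not that the descriptors explain real DFT chemistry, which
requires the published property tables (the analysis stage accepts them
via the same CSV schema; on those, the reference accuracy to approach is
MAE ≈ 0.26 eV / R² ≈ 0.90 for the gap and ≈ 4.31 kcal/mol / R² ≈ 0.93
for E_rel).

## Regression stage

LightGBM regressors with library-default hyperparameters (fixed seed,
single thread; defaults because the point is feature sufficiency, not
tuning), trained on the six feature columns only. Protocol: one random
non-stratified 75:25 train/test split; 5-fold cross-validation *within*
the training portion (reported alongside, not used for selection); MAE
and R² on the held-out quarter. R² for a constant target is reported as
an explicit 0.0. Ablation retrains once per dropped feature and reports
the test-MAE delta against the full-feature baseline; "most important
feature" is the one whose removal costs the most MAE.

## Problem sizes and determinism

The full 6-ring space (57 scaffolds, 23,894 isomers) enumerates and
featurizes in a few seconds; tests exercise the full space where an
invariant claims it and the 4-ring space (901 isomers) where a
distributional property is enough. All stochastic stages take explicit
seeds; pipeline reruns with the same config are byte-identical.

## Known limitations

* Scaffold enumeration is validated to 6 rings against published counts
  and to 8 against the catafusene series; no claims beyond 8 rings.
* Only (BN)₁ substitution is supported — one B, one N, isoelectronic.
  Multiple BN pairs and NH/BH-type doping are out of scope.
* No Kekulé or resonance-structure machinery: the line-notation export
  is connectivity-only (bracket atoms, single bonds), adequate for
  round-tripping and interop but not for depiction as an aromatic
  SMILES.
* The filtration stage consumes imaginary-frequency flags; it does not
  compute frequencies.
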