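# Methods

This note documents the models and algorithms implemented in
`aminereact`, the defaults and why they were chosen, what the synthetic
fixtures do and do not emulate, and the numerical decisions that affect
results.

## Scope and pipeline

One scoring run executes: parse → clean (waters always removed, hetero
groups unless `keep_hetero`) → optional chain-subset selection →
geometric hydrogen placement → per-atom SASA → per-site pKa → secondary
structure → hydrogen-bond detection → Coulomb electrostatics →
rules-based classification.  Every stage is recomputed on the selected
chain subset; nothing is cached across subsets, so monomer-vs-dimer
comparisons are internally consistent.  A site is an α-amino group (the
backbone N of each chain's first standard residue) or an ε-amino group
(each lysine's NZ); an N-terminal lysine contributes both.

Only the first model of a multi-model file is scored, and alternate
locations collapse to the highest-occupancy conformer (ties → altloc
"A"): the predictors are all single-conformation quantities.

## Exposed surface area

Lee–Richards slicing: each atom's van-der-Waals sphere is inflated by
the probe radius *r_p*; the inflated sphere is cut into `resolution`
(default 100) z-slabs; per slab, circle–circle intersection against
every neighbouring inflated sphere yields occluded arcs, and the
accessible arc fraction times the slab's lateral area 2πR·dz is
accumulated.  Neighbour search uses a `scipy.spatial.cKDTree` (the
established equivalent of the cell grid such codes traditionally use).
A deterministic golden-spiral Shrake–Rupley sampler is available via
`sasa.algorithm = shrake-rupley`, and a seeded Monte-Carlo estimator
(`mc_sasa_oracle`) provides an independent route used as the test
oracle; the implementation is additionally cross-checked in the suite
against an external Shrake–Rupley code on matched radii.

Radii are ProtOr-style atom-class values (backbone carbonyl C 1.61,
aromatic C 1.76, aliphatic C 1.88, N 1.64, carbonyl O 1.42, hydroxyl O
1.46, S 1.77 Å) with element fallbacks.  Hydrogens carry radius 0 and
are excluded: ESA is defined on the crystallographic heavy atoms, so
placing hydrogens never changes areas.  Residue ESA is the plain sum of
the residue's atom areas.

The default probe radius is 4.2 Å — the effective radius used for the
NHS-ester ATRP initiator; larger values (tens of Å) emulate PEG-scale
reagents.  The value is passed through as a radius exactly as given,
without reinterpretation.  Numerical notes: coincident atom centres are
treated as mutually occluding duplicates (area 0, warning); a single
occluding arc of half-width ≥ π covers the whole slab circle; z-slicing
makes per-atom areas orientation-dependent at O(1/resolution) — areas
are translation-invariant to 1e-6 but agree across rotations only to
~0.3% at the default 100 slices (the suite pins both behaviours).
Accuracy at the defaults: isolated-sphere and two-sphere closed forms
reproduce to <0.5% and <1%; the Monte-Carlo oracle agrees within 3
standard errors on random clusters.

## Empirical pKa

The built-in backend is deliberately simple; its only downstream role
is the pKa ≤ 10.3 branch.  For a site with model pKa (10.5 for ε-amino,
8.0 for α-amino — the standard model values of fast empirical
predictors):

* desolvation shift: +0.01 per heavy atom within 9 Å of the amine
  nitrogen beyond a 280-atom baseline (never negative — an isolated
  amine scores exactly its model value);
* charge–charge shift: for every charged group centre within 7 Å
  (Asp/Glu carboxylate O, C-terminal OXT as anions; Arg CZ, other Lys
  NZ, N-terminal backbone N as cations), ±0.5·(1 − d/7) — anions raise,
  cations lower.  Groups on the site's own residue are part of the site,
  not its environment, and are excluded.

The terms are reported per site and sum exactly to the prediction.  All
constants are config fields.  pH never enters the pKa itself; the
virtual pH (default 8.0) is protocol metadata.  A PROPKA-compatible
predictor plugs in as the `external` backend behind the same
`(model, site, config) → PkaResult` contract and fails fast at
configuration time when the optional dependency is missing.  The
heuristic is *not* a quantitative pKa method: it captures the direction
and rough size of burial and charge effects, which is what the single
branch threshold consumes.

## Secondary structure

Native Kabsch–Sander rules (no external DSSP binary).  Backbone H-bond
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol; a
bond requires E < −0.5, with at most the two lowest-energy acceptors
per donor.  Self and peptide-bonded neighbour pairs are excluded (the
covalent geometry would otherwise fabricate E ≈ −2.6 "bonds" between
adjacent residues; the exclusion matches the behaviour of the
established implementations).  Prolines and residues without a
preceding carbonyl do not donate.  When no explicit amide H is present
the classic coordinate estimate is used: 1.01 Å from N along the
bisector of N→C(prev) and N→O(prev); explicit hydrogens, when placed,
take precedence.

Assignment: n-turns (bond i+n → i, n = 3,4,5, over covalently
continuous stretches), minimal-helix rule (two consecutive turns at
i−1, i → helix of length n), parallel/antiparallel bridge rules,
ladders (bridges with an adjacent bridged residue) → E, isolated
bridges → B, turns → T, bends (CA(i−2)–CA(i)–CA(i+2) angle > 70°) → S.
Competing claims resolve by the fixed priority H > E > G > I > B > T >
S > '-'; helix therefore wins a helix/strand tie.  The 3-state collapse
is the standard convention {H,G,I}→helix, {E,B}→strand, {T,S,-}→coil,
and is total — every residue with a full backbone receives a class,
everything else is coil for classification purposes.

## Hydrogen bonds and donor status

Geometric criteria on explicit hydrogens: covalent D–H ≤ 1.2 Å, donor
N/O, acceptor N/O/S, D–A ≤ 3.0 Å and D–H–A ≥ 150° (both configurable;
these are the customary defaults of trajectory-analysis tools).
Intra-residue pairs are excluded; salt bridges count when the geometry
qualifies.  Note the classical formulation of this family of criteria
uses the H···A distance; this module deliberately adopts the D–A
convention and exposes the cutoff so either convention can be dialled
in.  A site is a donor iff its amine nitrogen donates in ≥ 1 bond —
acceptor-only involvement does not count.  Because the geometric
protonation rule adds no hydrogens to chain N-termini (there is no
preceding carbonyl to define them), α-amino groups are donors only when
the input structure already carries their hydrogens.

## Electrostatics

Bare Coulomb sum over all PQR charges, k = 332.0637 kcal·Å/(mol·e²),
default dielectric ε = 1 (the input charges are already force-field
assigned; with ε = 1 the 100 kcal/mol flag threshold sits in the
intended magnitude regime).  No distance cutoff — the full O(n²) sum is
cheap at protein scale and equals the brute-force oracle exactly.
Atoms of the target's own residue are excluded so the quantity is a
local-environment energy rather than a self energy
(`charge.exclude_same_residue` switches this off).  Pairs closer than
0.5 Å are unphysical and skipped with a warning.  ε sites evaluate NZ;
α sites evaluate the backbone N (the natural analogue).  The
low-positive-charge flag is strict: E must exceed 100 kcal/mol.

## Decision tree

The tree is a reconstruction.  The ESA, pKa and helix branches and
their thresholds (50 Å², 10.3, 100 kcal/mol) are fixed by reported
behaviour; the placement and direction of the H-donor and charge
branches are this package's design: donation sequesters the amine →
slow; a low-positive-charge environment favours acylation of the
neutral amine → fast.  Boundary semantics are pinned by tests: ESA
exactly 50 is reactive, pKa exactly 10.3 passes toward fast.  The rule
set is data, not code — an ordered list of condition → outcome lines,
serializable and swappable via `classifier.rules` — so a corrected tree
can be dropped in without a release.  Each classification carries its
`rule_path` audit trail.

## Synthetic fixtures

All tests and the acceptance script run on generated systems:

* ideal peptides/helices from exact backbone dihedrals (NeRF chain
  construction; φ = −57°, ψ = −47°, ω = 180° for helices);
* an antiparallel two-strand sheet built by placing a rigid copy of a
  (−139°, 135°) strand with a frozen transform refined against the
  Kabsch–Sander energies of the intended bond registry;
* pseudo-atom sphere clusters with analytic areas (isolated sphere,
  two-sphere overlap, an enclosing icosahedral shell, a deep cylinder
  whose floor atom seals at large probes);
* point-charge systems, including the calibration pair — two unit
  charges at 332.0637/100 = 3.320637 Å, exactly 100 kcal/mol at ε = 1 —
  and mirror-symmetric cancelling layouts;
* homodimers by rigid duplication onto a new chain (far copies leave
  areas bit-identical; contact copies bury the interface);
* a "buried lysine" pocket (glycine-walled cylinder, opening radius
  12 Å) whose lysine is slow-reacting at the 4.2 Å probe and collapses
  to ESA 0 / non-reacting by a 30 Å probe.

These fixtures have exact, independently computable properties, which
is what makes the oracle tests sharp — but they are idealized: no
side-chain rotamer variety, no crystallographic noise, no realistic
packing density, and formal charges instead of force-field PQR charges.
Passing them demonstrates the algorithms are implemented correctly, not
that predictions on real structures are accurate; the regression tests
against reference crystal structures cover the latter and require the
user to supply the PDB files (they are not redistributed here).

## Problem sizes and determinism

Default test/acceptance problem sizes — 12-residue peptides, ≤ 8-atom
sphere clusters, 2·10⁴ Monte-Carlo points, a ~370-atom pocket protein —
were chosen so every algorithm's behaviour is exercised at sizes where
the independent oracles (closed forms, brute-force sums, exhaustive
enumerations) are exact and fast.  Runs are deterministic: fixed seeds
for every stochastic component, ordered site tables, and a
machine-precision long-format CSV that is byte-identical across reruns
of the same inputs and configuration.

## Known limitations

* The built-in pKa heuristic ignores hydrogen-bond and titration
  coupling terms (the `hbond_shift` slot is reported as 0); quantitative
  pKa work should use the external backend.
* Chain N-termini are never auto-protonated, so their H-donor flag
  depends on the input structure.
* No mmCIF input, no BIOMT assembly expansion, no force-field charge
  assignment (the PQR is consumed as-is), no Poisson–Boltzmann
  screening, and no modelling of reagent/polymer dynamics — the probe
  radius is a purely geometric surrogate for reagent size.
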