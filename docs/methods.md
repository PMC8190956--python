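# Methods

This note documents the models and procedures implemented in `fragmbe`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Many-body expansion

For N fragments, every nonempty subset S has an energy E(S) and an
increment

    Δε(S) = Σ_{T ⊆ S} (−1)^{|S|−|T|} E(T),      E(∅) = 0,

computed by one-shot inclusion–exclusion (Möbius inversion) rather than by
recursively subtracting lower-order increments. Both definitions are
algebraically identical; the one-shot form avoids accumulating rounding
through intermediate increments, and the recursive form is retained in the
test suite as an independent oracle. Subset evaluations are pure and
memoized by (system fingerprint, region fingerprint), so vacuum and
embedded evaluations of the same subset never collide, each subset is
computed at most once, and results are independent of evaluation order
(subsets are processed by size, then lexicographically — relevant if
evaluations are ever distributed).

Binding quantities, reported in kcal/mol (1 Hartree = 627.509474
kcal/mol; conversion applied only at the reporting boundary):

* ΔE = E(full) − Σ_X E_X (binding energy),
* ΔE² = Σ pair increments (two-body part),
* ΔE_coop = ΔE − ΔE² (cooperativity: all terms of order ≥ 3).

## Fragment-pairwise decomposition contract

A backend maps (system, per-fragment treatment) to a total energy
partitioned exactly into per-fragment intra terms and unordered pair inter
terms, with optional per-channel splits that close entry-wise. Treatment
levels: HIGH (full), LOW (HIGH minus the backend's correlation channel —
the mean-field analog), CHARGES (fragment replaced by its fixed site
charges scaled by α), ABSENT (removed). Backends must report *all* terms,
including environment-involving ones; the embedding drivers discard
environment terms through an explicit, separately tested extraction step,
so what is neglected is visible in the code rather than buried in a
backend. The interpretation of the basis tag carried by a level is
backend-defined (the classical backend ignores it), including whether an
environment's basis functions overlap the subsystem region.

## Classical polarizable backend

The desk-scale backend is a rigid-fragment polarizable force field:

* pairwise, between sites of different fragments only: Coulomb
  `q_i q_j / r`, repulsion `B_ij / r¹²`, dispersion `−C_ij / r⁶` with
  geometric-mean combining rules `B_ij = √(B_i B_j)`, `C_ij = √(C_i C_j)`
  (standard choice; nothing in the framework depends on it);
* self-consistent induction: dipoles `μ_i = α_i (E_i^perm + Σ_j T_ij μ_j)`
  on polarizable sites of HIGH/LOW fragments. CHARGES sites polarize
  others but are never polarized — the defining asymmetry of electrostatic
  embedding. Dispersion acts only between two HIGH sites, so
  E(HIGH) − E(LOW) equals the dispersion sum exactly, mirroring the
  correlation/mean-field split.

Intra-fragment nonbonded terms are excluded entirely, so an isolated rigid
monomer has energy 0 and the decomposition's diagonal is a pure
electronic-preparation analog: the dipole self-energy `|μ_i|²/(2α_i)`,
non-negative by construction. Every pairwise term (charge–charge,
repulsion, dispersion, charge–dipole, dipole–dipole) is assigned to its
fragment pair, so the partition identity holds to machine precision — it
is an identity of the bookkeeping, not a tolerance.

Numerical choices:

* The dipole–dipole tensor is damped at short range by the exponential
  Thole-style factors λ₃ = 1 − e^(−a u³), λ₅ = 1 − (1 + a u³) e^(−a u³)
  with u = r/(α_i α_j)^(1/6) and dimensionless width a = 0.39 (the
  conventional value; config-exposed). Larger a means weaker damping;
  a → ∞ recovers the bare tensor. Charge–dipole fields are undamped.
* The induction equations are solved by dense direct solve by default
  (adequate below a few thousand sites) or by fixed-point iteration
  (max 200 iterations, residual < 1e-10). Both routes agree to better
  than 1e-9 Hartree; a non-convergent or near-singular solve raises an
  error carrying the smallest eigenvalue of the response matrix, the
  signature of a polarization catastrophe.
* No randomness anywhere in the backend; repeated evaluation is bitwise
  reproducible.

Default pseudo-water parameters: O-like site q = −0.8 e, α = 1.2 Bohr³;
H-like q = +0.4 e, α = 0.3 Bohr³; repulsion/dispersion on the O-like site
only, chosen so the O···O pair potential B/r¹² − C/r⁶ has its minimum at
5.7 Bohr with well depth 2×10⁻³ Hartree (B = ε·r_m¹², C = 2ε·r_m⁶). The
values are not fitted to real water energetics; they only need to produce
bound, polar, polarizable clusters with genuine many-body character.
The table is config-overridable per element.

## Embedded two-body drivers

Three batches of independent evaluations: isolated monomers E_X; embedded
monomers, giving E_X^intra,1(S); embedded dimers, giving
E_X(XY)^intra,2(S) and E_XY^int,2(S). Electronic preparation energies:

    ΔE_X^el-prep,1(S) = E_X^intra,1(S) − E_X
    ΔE_X^el-prep,2(S) = ΔE_X^el-prep,1(S)
                        + Σ_{Y≠X} [E_X(XY)^intra,2(S) − E_X^intra,1(S)]

The environment-induced distortion of X enters **once**, through the
embedded monomer; each dimer contributes only the additional distortion
caused by its partner. This bookkeeping was a genuinely open design
point: the alternative — referencing every dimer's intra term directly to
the isolated monomer — counts the environment distortion (n−1) times and
overshoots the total by (n−2)·Σ_X ΔE_X^el-prep,1(S), which for polar
clusters is far larger than the two-body truncation error being repaired.
With the form above, the embedded monomer step is a required input of the
final energy, not merely a diagnostic; on the classical backend the
mean-field-embedded two-body total is then *exact* (a LOW environment
captures all induction, and dispersion is strictly pairwise), and in
general the residual error is confined to beyond-pairwise correlation
effects.

Assembled quantities (Hartree internally):

    E      = Σ_X E_X + Σ_X ΔE_X^el-prep,2(S) + Σ_{X<Y} E_XY^int,2(S)
    ΔE_emb = E − Σ_X E_X

Environment schemes: a mean-field-like environment (LOW level, optional
reduced basis tag), or point charges scaled by α, derived from one
whole-system charge computation (EE1) or per-fragment computations (EE2).
On the classical backend EE1 and EE2 coincide (site charges are fixed
properties); with quantum backends they differ and the optimal charge
type/α is application-specific. α = 0 reduces every embedded quantity
bitwise to its vacuum counterpart, so the driver degrades gracefully to
the plain two-body expansion. Isolated monomer energies are computed in
the subsystem treatment without any environment (they precede embedding)
and are shared with the vacuum MBE through the common memo store.

### Shared-reference shortcut

When subsystem and environment share one mean-field reference (same
environment level and basis tag), the reference pieces of every extraction
reassemble to the full-system reference energy and the assembled total is
algebraically equal to

    E = E_ref + Σ_{X<Y} E_XY,corr(S) − (n−2) Σ_X E_X,corr(S),

with the correlation parts taken as the subsystem-restricted correlation
channel of each embedded extraction. The multiplicity (n−2) is *derived*
by requiring equality with the term-wise assembly — substituting
extraction = reference part + correlation part into the driver formula
makes the reference intra terms appear (n−1) times from the dimers and
−(n−2) times from the monomer corrections — and the equality is locked by
a test on the classical backend (reference = dispersion-free full-system
energy, correlation = dispersion channel), where it holds to the solver
tolerance. The shortcut refuses point-charge environments and mismatched
basis tags, which do not share a reference.

## Interaction and cooperativity maps

Symmetric fragment×fragment matrices in kcal/mol: diagonal = electronic
preparation, off-diagonal = pair interaction. The full map (from the
supersystem decomposition) sums to ΔE; the two-body map (from all vacuum
dimers) sums to ΔE²; their element-wise difference sums to ΔE_coop —
these conservation identities are asserted on every system the suite
touches. Channel maps (electrostatic/repulsion/dispersion/induction for
the classical backend) sum element-wise to the main map. Maps are stored
at full precision, displayed at two decimals, and serialized as CSV
(label header, symmetric body, trailing TOTAL cell) with a JSON mirror;
the optional heat plot is a thin matplotlib rendering of the same matrix.

Comparison statistics (MAE, maximum absolute deviation) use round-half-up
at the requested decimal, applied after aggregation: the transcribed
discussion prints the same quantity as 0.33 (table, two decimals) and 0.3
(prose, one decimal), and half-up is the only rounding consistent with
both for a computed 0.3267.

## Extrapolation utilities

PNO extrapolation `E = E_loose + F (E_tight − E_loose)` with F = 1.5 by
default; the CBS pair uses `E(X) = E_CBS + A e^(−α√X)` for the reference
(α = 5.46 for cardinals 3/4) and `E_CBS = (X^β E_X − Y^β E_Y)/(X^β − Y^β)`
with β = 3 for correlation. All three are linear, so they commute with
binding-energy assembly; the tests pin this to 1e-12. Back-solving the
transcribed hexamer tables for the extrapolation factor yields an
effective F ≈ 1.7 between the printed threshold columns and the printed
extrapolated column — consistently across isomers — indicating the
published extrapolation was applied to a sub-component of the correlation
energy that is not separable from the printed data. No test or reported
quantity ties the formula to that column; the package reports the formula
value for the printed inputs as-is.

## Packaged tables and their statistics

The four transcribed benchmark tables are rebuilt from literals on every
load, pinned by SHA-256 checksums of their canonical CSV form, and never
mutated in place. Known internal inconsistencies of the source are carried
in the fixture notes rather than resolved: the prose maximum deviation of
0.14 kcal/mol for the mean-field embedding vs the printed column maximum
of 0.16; the prose two-body correlation error of 0.36 vs the printed-value
difference of 0.37; the prose DZ-environment mean-field error of 1.22 vs
the printed-value difference of 1.23. The reproduction functions always
report what the printed numbers give.

## Synthetic clusters: what they do and do not show

The generator places rigid pseudo-water fragments with seeded uniform
random positions and orientations (uniform quaternion rotations) in a
cubic box (default edge 12 Bohr), rejecting placements with any
interfragment site distance below 4 Bohr. Defaults were chosen once to
yield compact, mutually polarizing clusters — the regime where two-body
truncation visibly fails — and are not tuned per test. Generated clusters
emulate the many-body *structure* of hydrogen-bonded aggregates
(polarization cooperativity, short-range repulsion, pairwise dispersion)
but not their quantitative energetics: there is no charge transfer, no
exchange anisotropy, no geometry relaxation, and the monomer energy is 0
by convention. Passing tests therefore certify the algebra and the
drivers — exactness of the expansion, conservation of the maps, the
embedding limits and improvement — not chemical accuracy for real water.
Problem sizes used throughout (n ≤ 6 fragments, 3 sites each, ten
5-fragment clusters for the improvement measurement) keep the full
2ⁿ-subset expansions exact references rather than sampled estimates.

## Known limitations

* Quantum-chemistry backends are interface stubs: nothing parses external
  program output, and population-analysis charge providers are hooks.
* The embedded drivers stop at dimers (no embedded three-body terms) and
  perform no counterpoise correction or distance-based pair screening.
* The classical backend's LOW level is a physics analog of a mean-field
  treatment, not an approximation hierarchy with a basis-set dimension;
  basis tags only affect cache identity and validation.
* Charges of a CHARGES fragment are its stored site charges; external
  point-charge files can be written but are not an input channel of the
  drivers.
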