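# Methods

This note documents the models, conventions, numerical choices and known
limitations of `puckerfit`.  Everything stated here is computed by the
package's own tests or by `scripts/acceptance.py`.

## Pseudorotation convention

A furanose ring's conformation is parameterized by the
Altona–Sundaralingam pair (P, τm).  The five endocyclic torsions are
defined on the atom quadruples (ring order C1′, C2′, C3′, C4′, O4′):

| torsion | quadruple |
|---------|-----------------------|
| ν0 | C4′–O4′–C1′–C2′ |
| ν1 | O4′–C1′–C2′–C3′ |
| ν2 | C1′–C2′–C3′–C4′ |
| ν3 | C2′–C3′–C4′–O4′ |
| ν4 | C3′–C4′–O4′–C1′ |

with νj = τm·cos(P + 144°(j−2)), so ν2 (about C2′–C3′) carries the pure
cos P term.  The inverse uses
tan P = ((ν4+ν1) − (ν3+ν0)) / (2 ν2 (sin 36° + sin 72°)), evaluated with a
two-argument arctangent on the numerator and denominator; τm follows as
√(num² + den²)/(2(sin 36° + sin 72°)), which stays exact on the
cos P = 0 meridians.  The round trip is exact to < 1e-13 degrees over
1000 random states.  Phases are stored in [0°, 360°); analysis maps them
to (−180°, 180°] so the Northern hemicycle is the symmetric interval
−90° ≤ P < 90°.  Dihedral signs follow the IUPAC convention (cis = 0,
clockwise positive viewed along the central bond).

## Ring embedding

`embed_ring` places a template at a target (P, τm) by Levenberg–Marquardt
least squares over the 15 Cartesian coordinates of the ring atoms, with
four residual groups:

* the five per-torsion deviations from the cosine pattern (scale 0.01°),
* ring bond lengths restrained to template values (scale 0.0002 Å),
* ring bond angles restrained softly (scale 40°),
* the two phase-defining torsion combinations — the numerator and
  denominator above — pinned at scale 0.001°.

The last group is the important design choice.  A closed five-ring with
fixed bond lengths has only four pucker degrees of freedom, while the
cosine pattern imposes five targets: for rings with unequal C–O/C–C bond
lengths the pattern is unrealizable by ~0.7° at the worst scan windows,
no matter how the angles relax.  Pinning the phase-defining combinations
makes the *measured* (P, τm) — the quantity the scan controls and the
analysis consumes — exact (≤ 0.002° over all 480 windows of the test
set), bonds stay within 0.004 Å of the template, and the irreducible
pattern deviation (≤ 1.0°, the convergence guard) is absorbed where it is
physically cheapest, the bond angles.  Exocyclic substituents are carried
rigidly in the local frame of their anchor ring atom (spanned with its two
ring neighbors); they are not relaxed.  The optimizer starts from the
template ring displaced along the out-of-plane cosine pattern (90° phase
lead relative to the torsion pattern), which breaks the planar mirror
degeneracy.

A target amplitude of 35° is used for scans — a typical furanose pucker
amplitude — exposed as `ScanSpec.amplitude_deg`.  Amplitudes ≥ 60° are
rejected as outside the furanose regime.

## Conformer ensembles

Scans place one frame per 18° window (20 windows; the interval is
configurable but must divide 360).  Pose randomization perturbs only
rotatable exocyclic torsions (bonds from a ring atom to a non-hydrogen
substituent with atoms beyond it, e.g. C–OH), uniform in ±30°; the ring is
the controlled variable and stays at the window's embedded geometry.
Templates whose substituents have no rotatable torsion (e.g. pure fluoro)
yield identical poses within a window; this is intentional, not an error —
the ensemble arithmetic (frames = windows × poses per window × templates)
is preserved.

Culling is greedy keep-first in generation order: a frame survives iff its
Kabsch RMSD (proper rotations only; heavy atoms by default) to every
previously kept frame is at least the threshold (1 Å default).  The
keep-first rule makes the operation deterministic and idempotent, which an
unordered "remove if close to any other" rule is not.

## Energy model

Additive potential with harmonic bonds/angles, a 1–3 exclusion, 1–4
scaling divisors 1.2 (electrostatic) and 2.0 (van der Waals), full pair
sums beyond (no cutoff — the molecules are < 30 atoms), Lorentz–Berthelot
combination A = ε(r*ᵢ+r*ⱼ)¹², B = 2ε(r*ᵢ+r*ⱼ)⁶, ε = √(εᵢεⱼ), and the
electrostatic constant k_C = 332.0522 kcal·Å/(mol·e²).  Dihedral terms
are V_n[1 + cos(nφ − γ)] with n ∈ {1,2,3}, γ ∈ {0°, 180°}; the
coefficient is V_n itself (no implicit division by 2), and the frcmod
reader/writer maps V_n = PK/IDIVF so files remain Amber-conventional.
Improper torsions are not modeled: none of the refit classes are
impropers and the test set defines none.  Wildcard (`X`) dihedral types
are honored on lookup, with specific keys shadowing wildcards; an
explicitly empty specific entry also shadows a wildcard, which is how the
fitter zeroes adjustable classes.

The per-term decomposition satisfies total = Σ components to 1e-9 and the
energy is rigid-motion invariant to 1e-8 kcal/mol (both tested).

## Torsion fitting

At fixed coordinates the dihedral energy is linear in the V_n, so the
residual fit is ordinary least squares.  Design columns hold
Σ(1 + cos nφ) over the torsions matching each adjustable class; γ is
resolved analytically from the coefficient sign via
V[1 + cos(nφ − 180°)] = V[1 − cos nφ] (exactly equivalent to a discrete
γ search, up to a constant absorbed by the offsets).  V_n = 0 is reported
with γ = 0.  Per-molecule offset columns are mandatory: reference and MM
energy zeros are incommensurate, and the synthetic oracle deliberately
injects hidden per-molecule offsets so a fitter without them fails
loudly.  Frames are equally weighted (an optional Boltzmann weighting is
not provided; nothing in the workflow requires it).  Classes absent from
every template are dropped from the design rather than fitted as zero
columns.  Rank-deficient designs fall back to a small ridge (1e-8) and
are flagged on the result object.  Standard errors come from
σ²(XᵀX)⁻¹.

**Identifiability.**  Two degeneracies matter in practice.  (1) On a
near-tetrahedral carbon the three substituent torsions differ by ≈120°,
so their n = 3 columns nearly coincide: classes sharing a central bond are
not separable from a single template.  (2) A ring-bond dihedral sweeps
only ≈ ±τm about one offset over the pseudorotation cycle, so cos φ,
cos 2φ, cos 3φ of one class are locally polynomial-collinear — with
0.5 kcal/mol noise the single-template standard errors reach hundreds of
kcal/mol.  Both are resolved exactly as in the real workflow: fitting
jointly across templates whose substitution patterns and stereochemistry
shift the dihedral offsets (up/down placement moves the arc by ±120°).
The noiseless recovery check therefore uses a diverse 8-template subset
(all seven classes recovered to < 1e-4 kcal/mol; through-origin slope of
refit-MM vs reference within 1e-6 of 1), and the noisy check fits the
vicinal F/OH class across its eight stereoisomer templates at 124 poses ×
20 windows each (recovery within 10%, standard errors ≈ 0.03 kcal/mol).

**Convergence.**  The 5% rule: converged iff every |ΔV_n|/max(|V_n|,
0.01 kcal/mol) < 0.05 and every γ unchanged (γ of negligible terms, both
below the 0.01 floor, is exempt — its sign is noise).  The alternating
outer loop (torsion fit ↔ charge refit) compares each fit with the
previous *fit*, so the earliest possible convergence is iteration 2 — a
fit followed by a no-change confirmation pass.

## Charge fitting

Constrained linear least squares on V(r) = k_C Σ q/|r − r_a| over shell
grids, with the net charge enforced exactly by a Lagrange multiplier and
an optional harmonic restraint toward a prior set (the iterative workflow
uses weight 1e-4 toward the previous iteration for stability; plain fits
use 0).  Shell grids are seeded-uniform points between 1.4× and 2.0× the
van-der-Waals radii with an absolute 1 Å exclusion floor (polar hydrogens
have tiny r*).  Multi-conformer fitting is joint over concatenated grids.
The IpolQ combination is the vacuum/solvated midpoint
q = (q_vac + q_solv)/2; on oracle grids built from q_vac and q_vac + δq
the answer q_vac + δq/2 is analytic, and the fit recovers it to < 1e-6 e.
Symmetry equivalencing (e.g. averaging methyl hydrogens) is not applied.

## Synthetic data

The oracle draws hidden V_n uniform in [0.05, 2.0] kcal/mol with γ random
in {0°, 180°} for each periodicity of each adjustable class, hidden
vacuum charges (template charges plus a ±0.02 e perturbation re-summed to
the net charge), zero-sum polarization perturbations δq uniform in
±0.05 e, and hidden per-molecule offsets uniform in ±20 kcal/mol;
reference energies are exact MM under the hidden truth plus optional
homoscedastic Gaussian noise (σ exposed; no claim is made about the error
structure of real quantum-chemical references).  The 24-template test set
enumerates mono-fluoro (4), F/OH disubstituted (16, all up/down
stereochemistries), gem-difluoro (2) and mono-hydroxy (2) patterns on an
idealized tetrahydrofuran frame with GAFF-style types assigned by local
environment and simple per-type charges balanced on the carbons.  The
bundled `gaff_like.frcmod` carries representative general-force-field
starting values covering every type in the set.

What passing these tests shows: the geometry, generation, fitting and
analysis machinery is correct and self-consistent, including at the full
study scale (59,520 frames).  What they do not show: anything about real
fluorosugar energetics — the oracle has no gauche/anomeric physics, the
templates are idealized, and noiseless recovery says nothing about basis
sets or conformational strain in real reference data.

## Problem sizes

Scans are 20 windows × 24 templates (480 embeddings, ≈ 25 s); the
noiseless recovery fit uses 8 templates × 120 frames; the noisy recovery
fit uses 8 templates × 2480 frames (19,840 rows); charge fits use ≈ 30×
more grid points than atoms.  These sizes reproduce the study's ensemble
arithmetic at full scale while keeping the whole acceptance run under a
minute of compute.

## Known limitations

* The embedding reports exact measured phase but tolerates ≤ 1° deviation
  from the ideal cosine torsion pattern (unavoidable; see above).
* Wildcard dihedral parameters are matched only as X–b–c–X.
* mol2 is the only template format with full fidelity (types + charges +
  bonds); PDB/XYZ carry coordinates only.
* No periodic boundaries, cutoffs, or solvent models; trajectories from
  solvated simulations are analysis inputs, not something the package
  produces.
* The frcmod writer emits IDIVF = 1 and {0°, 180°} phases only (the
  reader accepts other phases in a warn-and-accept mode).
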