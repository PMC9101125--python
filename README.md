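# puckerfit

Pseudorotation-aware force-field refinement for fluoro- and
hydroxy-substituted furanose rings.

## The problem

Additive molecular-mechanics force fields historically do poorly on highly
substituted five-membered sugar rings: the gauche and anomeric effects of
electronegative substituents (F, OH) bias the ring pucker in ways that
pairwise potentials with generic torsion parameters do not capture.  The
standard remedy is to refit the torsion Fourier coefficients (and the
partial charges) of the affected dihedral classes against reference
energies that span the whole pseudorotation cycle of the sugar.

`puckerfit` implements that workflow end to end:

1. **Pucker mathematics** (Altona–Sundaralingam).  The conformation of a
   furanose ring is described by a phase angle *P* and amplitude *τm*
   through the five endocyclic torsions

       ν_j = τm · cos(P + 144°·(j − 2)),   j = 0..4

   with the inverse
   `tan P = ((ν4 + ν1) − (ν3 + ν0)) / (2 ν2 (sin 36° + sin 72°))`.
   The package converts both ways, measures (P, τm) from Cartesian
   coordinates, and *embeds* a template molecule at any target pucker by
   restrained Gauss–Newton optimization of the ring atoms.

2. **Conformer generation.**  Scans of the full pseudorotation circle at a
   fixed interval (default 18°, i.e. 20 windows), randomized pose
   ensembles per window (exocyclic torsions perturbed, ring frozen), and
   greedy pairwise culling at an RMSD threshold (default 1 Å, Kabsch
   superposition over heavy atoms).

3. **MM energies.**  The additive potential

       E = Σ K_b (b − b0)² + Σ K_θ (θ − θ0)²
         + Σ_{i<j} [ A_ij/r¹² − B_ij/r⁶ + k_C q_i q_j / r ]
         + Σ_dihedrals Σ_{n=1..3} V_n [1 + cos(n φ − γ)]

   with Amber conventions (k_C = 332.0522 kcal·Å/mol·e², 1–4 scaling
   1.2/2.0, Lorentz–Berthelot combination), evaluated exactly (no cutoff)
   with a per-term breakdown.

4. **Torsion fitting.**  Because the dihedral sum is linear in V_n at
   fixed coordinates, fitting V_n to the residual between reference and
   fixed-parameter MM energies is linear least squares; the phase offset
   γ ∈ {0°, 180°} is resolved analytically by the sign of the coefficient.
   Per-molecule offset columns absorb the incommensurate energy zeros.
   The fit is exposed statsmodels-style: `TorsionFitModel(problem).fit()`
   returns a `TorsionFitResults` with coefficients, standard errors,
   residuals and a `summary()` table.

5. **Charge fitting.**  `ESPChargeModel` fits atom-centered charges to
   electrostatic-potential grids by constrained least squares (exact
   net-charge Lagrange constraint, optional restraint to a prior set);
   `combine_ipolq` forms implicitly polarized charges as the midpoint of
   vacuum and solvated-environment fits.

6. **Iterative refinement.**  `iterate_fit` alternates torsion and charge
   fitting with the 5 % convergence rule: the loop stops when every V_n
   changed by less than 5 % (with every γ unchanged) and every charge
   changed by less than 5 %.

7. **Pucker analysis.**  Phase time series, probability histograms,
   percent-North (%N, the population with −90° ≤ P < 90°), per-window
   energy-error statistics (μ, σ, μ±2σ), and the through-origin regression
   `E_MM = slope · E_ref` with its uncentered r².

Because quantum-chemical reference data cannot be bundled, the package
ships a first-class **synthetic oracle**: hidden "true" torsion
coefficients, charges, polarization perturbations and per-molecule offsets
drawn from a seed, from which reference energies and ESP grids are
generated exactly.  Every fitting stage is therefore testable by parameter
recovery, and a 24-template synthetic test set of mono/di-fluoro and
hydroxy furanoses (all stereochemistries, including gem-difluoro) is built
programmatically.

## Worked example

```python
import numpy as np
import puckerfit as pf

templates = pf.build_test_set()          # 24 synthetic furanoses
params = pf.default_parameters()         # GAFF-like starting point
tpl = templates[8]                       # 2'-F / 3'-OH ribo-like ring

# hidden truth for the vicinal F/OH torsion class
key = ("f", "c3", "c3", "oh")
hidden = params.copy()
hidden.set_dihedral(key, [(1, 0.8, 0.0), (3, 0.25, 180.0)])

# ensemble + synthetic reference energies
poses = pf.random_poses(tpl, pf.ScanSpec(poses_per_window=12), seed=3)
ref = np.array([e.total for e in pf.batch_energies(tpl, poses, hidden)])

problem = pf.FitProblem(entries=[(tpl, poses, ref)],
                        base_params=params, adjustable=[key])
result = pf.TorsionFitModel(problem).fit()
print(result.summary())
```

prints

```
Torsion fit results
===================
frames: 240   SSE: 2.01081e-27 kcal^2/mol^2   iterations: 1   converged: True

dihedral class    n         Vn  gamma     se(Vn)
f-c3-c3-oh        1    0.80000      0    0.00000
f-c3-c3-oh        2    0.00000      0    0.00000
f-c3-c3-oh        3    0.25000    180    0.00000

offset[T09] = 0.5000 kcal/mol
```

i.e. the hidden V1 = 0.8 kcal/mol (γ = 0) and V3 = 0.25 kcal/mol
(γ = 180°) are recovered exactly from noiseless references, with the n = 2
term correctly identified as absent.  The 0.5 kcal/mol offset is the
constant the γ = 180 identity V[1 + cos(nφ − 180)] = V[1 − cos nφ] moves
between the Fourier term and the per-molecule offset — the energies
themselves are identical.

A command-line interface mirrors the stages
(`puckerfit scan | poses | cull | energy | fit-torsions | fit-charges |
analyze | simulate-oracle`); run `puckerfit --help`.

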