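# gridbind

Absolute protein–ligand binding free energies from restrained umbrella
sampling, via non-parametric reweighting of biased collective-variable (CV)
trajectories.

## The problem

Distance-based umbrella sampling can pull a ligand out of its binding pocket
and give a PMF along the protein–ligand distance, but slow degrees of
freedom — the ligand's orientation and the internal conformations of both
partners — make the calculation converge poorly. A practical remedy is to
*restrain* those degrees of freedom during the pulling simulations and remove
the restraints afterwards with analytic correction terms, stratifying the
binding free energy into independently converged pieces.

`gridbind` implements the analysis side of that strategy for people who
already have biased CV trajectories (e.g. NAMD colvars output) or want to
study the estimator itself on solvable toy systems:

1. **Reweighting** (`gridbind.reweight`). Frames from all umbrella windows
   are pooled and each frame gets a weight from the self-consistent
   equations (an MBAR-type estimator)

   ```
   w_k = c / Σ_i n_i exp(-(U_i(r_k) - F_i)/RT),
   exp(-F_i/RT) = Σ_k w_k exp(-U_i(r_k)/RT),
   ```

   where U_i is window i's total bias energy and F_i its perturbed free
   energy.

2. **Grid PMF** (`gridbind.pmf`). The weights build a 3-D PMF
   ΔG(**x**) = −RT ln p(**x**) over voxels of the ligand position **x**
   relative to the pocket center (the minimum-PMF voxel defines **x** = 0),
   plus 1-D PMFs over any CV and radially averaged profiles.

3. **Restraint corrections** (`gridbind.orientation`,
   `gridbind.corrections`). An always-on harmonic restraint ½kζ² is removed
   with ΔU = −RT ln(⟨e^(−kζ²/2RT)⟩_bulk / ⟨e^(−kζ²/2RT)⟩_pocket), each
   average a quadrature over the restrained variable's 1-D PMF. For the
   orientation angle Ω (the quaternion rotation angle to a reference
   orientation) the bulk PMF is analytic: p(Ω) = (1 − cos Ω)/π. Nested
   restraints are removed one at a time with explicit conditioning metadata.

4. **Budget assembly** (`gridbind.binding`). The standard binding free
   energy is

   ```
   ΔG° = -ΔG(x_B) + Σ ΔU + ΔG_V,
   ΔG_V = -RT ln(V_P / V_B),   V_P = Σ_voxels e^(-ΔG(x)/RT) · v³,
   ```

   with V_B = 1 L/N_A ≈ 1661 Å³ the 1 M standard-state volume, and
   K_d = exp(ΔG°/RT) M.

5. **Errors** (`gridbind.uncertainty`). A block Bayesian bootstrap: frames
   are grouped into contiguous blocks per window, Dirichlet-reweighted, and
   the whole estimator (including the reweighting solve) is re-run per
   resample.

6. **Synthetic systems** (`gridbind.synth`). Metropolis samplers on analytic
   potentials under harmonic biases, and a Gaussian-pocket toy binding
   system whose exact ΔG° comes from 1-D quadrature — every pipeline stage
   is testable without MD.

## Worked example

Run the full pipeline on the toy system — a Gaussian binding pocket of depth
10 kcal/mol and width 2 Å with an internal angle coupled to the pocket
(stiffness 5 kcal/mol/rad²), sampled with 31 distance windows
(k = 2 kcal mol⁻¹ Å⁻²) and an always-on orientation restraint of
0.5 kcal mol⁻¹ deg⁻², exactly the restrained protocol in miniature:

```
$ gridbind synth toy --eps 10 --sigma 2 --kappa-omega 5 \
      --restrain-omega 0.5 --windows 31 --n 1500 --bootstrap 100 --seed 11
oracle: dG(xB) = 8.8182 kcal/mol, V_P = 2.2032 A^3, dG0 = -4.8687 kcal/mol
pipeline: dG0 = -5.1326 +/- 0.1624 kcal/mol (terms: {"grid_pmf_difference":
-9.0968, "dg_volume": 3.1643, "du_omega": 0.8})
```

Reading the output: the quadrature oracle says the true standard binding
free energy of this toy system is −4.87 kcal/mol. The pipeline — Metropolis
umbrella sampling, reweighting, 3-D grid PMF, bulk plateau, Boltzmann pocket
volume, orientation-restraint correction — estimates −5.13 ± 0.16 kcal/mol,
recovering the truth within two bootstrap standard deviations, with the
budget split into the grid-PMF difference (−9.10), the standard-state volume
term (+3.16) and the restraint correction (+0.80).

The same stages run on real trajectory files:

```
gridbind reweight --config windows.yaml --cvs x,y,z,d,omega \
    --degrees omega -o weighted.csv w*.colvars.traj
gridbind gridpmf --samples weighted.csv -o grid.json
gridbind radial  --grid grid.json -o radial.csv
gridbind volume  --grid grid.json -o volume.json
gridbind orient-ref --bin-deg 1 --temp 300 -o bulk_omega.csv
gridbind correct --pocket pocket_omega.csv --bulk bulk_omega.csv \
    --k 0.5 --k-unit degree -o du_omega.json
gridbind assemble --budget budget.json -o dg0.json
```

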