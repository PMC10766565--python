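# Methods

This note records the models, numerical choices and limitations behind
`gridbind`, in the order the pipeline uses them.

## Reweighting estimator

Pooled frames from N umbrella windows are weighted by the self-consistent
pair of equations

    w_k = c / Σ_i n_i exp(-(U_i(r_k) - F_i)/RT)
    exp(-F_i/RT) = Σ_k w_k exp(-U_i(r_k)/RT)

with U_i the total bias energy of window i evaluated on frame k, n_i the
number of frames contributed by window i, and c the normalization making
Σ w_k = 1. This is the multistate reweighting (MBAR-type) fixed point. The
equal-count form (all n_i equal) is the special case; the implementation
keeps the general n_i because real trajectories end up unequal after
equilibration discards (a configurable leading-fraction drop per window,
default 0).

**Solver.** The fixed point is also the stationary point of a convex
log-likelihood in the F_i. `solve_weights` minimizes that objective with
L-BFGS (analytic gradient) and then polishes with the fixed-point iteration
until max_i |ΔF_i| < tol (default 1e-8 kcal/mol, max 10 000 iterations,
F_1 ≡ 0 anchor, F initialized at 0). Pure fixed-point iteration
(`warm_start=False`) reaches the same solution but needs orders of magnitude
more sweeps on long window ladders; the test suite checks both paths agree
to 1e-9 kcal/mol and match an independently written brute-force iteration.
All exponentials are evaluated against running maximum shifts; the inner
loops are single matrix products with a precomputed exp(-βU) table, so a
31-window × ~50 000-frame solve takes well under a second. Non-convergence
within max_iter sets `converged=False` on the result instead of raising; a
window whose bias is infinite on every frame raises a singularity error.

## PMFs

1-D PMFs use the nearest-bin weighted histogram: each frame is assigned to
the closest bin center (an exact tie goes to the lower-index bin), the PMF
is −RT ln of the accumulated weight, min-shifted to 0 over occupied bins.
Unoccupied bins are flagged, never given imputed values.

The 3-D grid PMF bins the ligand position on a cubic lattice anchored at the
coordinate origin (voxel v = floor(x / voxel_size)), so halving the voxel
size refines each voxel into exactly 8 children and Boltzmann-recoarsening
reproduces the parent grid to rounding error (a test invariant). The voxel
with the largest accumulated weight defines x = 0 and ΔG(0) = 0. Default
voxel size 1 Å, matching the radial resolution at which the profiles are
read; radial shell averages (default shell width 1 Å) report the mean and
population standard deviation of ΔG over the voxels in each shell.

**Bulk plateau.** ΔG(x_B) is estimated from a spherical shell in the bulk as
−RT ln(total shell weight / geometric voxel count of the shell). Dividing by
the geometric count rather than the occupied count keeps the estimate
unbiased when the chain visits only part of a large bulk shell; occupied-only
averaging would condition on visitation and bias the plateau down. The
pipeline default shell is 0.5–2.5 Å inside the outermost window center.

Ligand positions are taken as given in the protein-fixed frame; no alignment
is performed (the upstream CV engine already computed x).

## Orientation angle

Ω is the rotation angle of the optimal-superposition quaternion between the
ligand's current and reference orientations, in [0, π]. From an Euler triple
(φ, θ, ψ) it is computed with the half-angle identity

    cos(Ω/2) = cos(φ/2)cos(θ/2)cos(ψ/2) + sin(φ/2)sin(θ/2)sin(ψ/2),

which is the scalar quaternion component of the intrinsic z–y–x composition
Rz(φ)Ry(θ)Rx(ψ); the tests verify it against the convention-independent
rotation-matrix trace. |cos(Ω/2)| maps the quaternion double cover onto
[0, π].

For a freely tumbling ligand the orientation is uniform (Haar) on SO(3) and
Ω has the closed-form density p(Ω) = (1 − cos Ω)/π. The numeric reference
(`bulk_orientation_pmf(method="lattice")`) reproduces this by accumulating Ω
over a discretized Euler lattice (default 1°, i.e. 360 × 360 × 180 cells).
Two numerical details matter:

- **Measure.** The z–y–x chart's Haar weight is cos(pitch) with pitch in
  [−π/2, π/2] — equivalently sin θ on θ ∈ [0, π] after θ = pitch + π/2. The
  lattice integrates in the pitch variable. Applying a sin-weight directly
  to the half-angle identity's middle angle (i.e. treating it as a
  proper-Euler polar angle) does *not* produce the rotation-angle density;
  the mismatch is O(1), not a discretization artifact.
- **Binning.** Each lattice cell's weight is shared linearly between the two
  nearest Ω bins (cloud-in-cell). Nearest-bin assignment aliases at ~4e-3
  sup error at 1° resolution; linear sharing brings it to ~6e-4, and the
  error falls further as the lattice is refined.

For correction-term quadrature the closed form is evaluated directly on a
fine grid (`method="closed-form"`, default 0.01°): a stiff restraint (e.g.
0.5 kcal mol⁻¹ deg⁻² ≈ 1641 kcal mol⁻¹ rad⁻²) confines the integrand to a
few hundredths of a radian, far below the 1° histogram resolution.

## Restraint corrections

An always-on harmonic restraint ½kζ² is removed with

    ΔU = -RT ln [ ⟨e^(−kζ²/2RT)⟩_bulk / ⟨e^(−kζ²/2RT)⟩_pocket ],

each average computed by trapezoidal quadrature over the variable's 1-D PMF
(log-space accumulation; an average that underflows raises an error asking
for a finer grid rather than returning 0). k = 0 returns exactly 1, and ΔU
is antisymmetric under swapping the two PMFs — both are test anchors.
Because the quadrature runs in log space, PMF values far above the minimum
contribute e^(−ΔF/RT) and need no explicit truncation; RMSD-type variables
on [0, ∞) are handled by whatever grid extent the input PMF provides.

Nested restraints are removed one at a time. Each chain link carries
`conditioned_on`, the list of CVs still restrained when that link's PMFs
were measured; `chain_corrections` validates the metadata against the chain
order before computing anything, because silently mixing a conditioned and
an unconditioned PMF is the easiest way to get a wrong (and
plausible-looking) answer. Force constants quoted per degree² are converted
to radian units by (180/π)² at the input boundary; everything internal is
radians and kcal/mol.

## Volume terms and assembly

    V_P = Σ_occupied voxels e^(−ΔG(x)/RT) · (voxel size)³
    ΔG_V = −RT ln(V_P / V_B),  V_B = 1 L / N_A ≈ 1661 Å³

All occupied voxels enter V_P; voxels away from the pocket contribute
e^(−ΔG/RT) ≈ 0, so no explicit pocket boundary is needed (the cumulative
series over voxels sorted by ascending ΔG is returned so convergence can be
inspected; an optional radius cutoff exists only for sensitivity analysis).
The budget is assembled in the tabulated sign convention,

    ΔG° = grid term + Σ ΔU + ΔG_V,   grid term = −ΔG(x_B) ≤ 0,

and K_d = exp(ΔG°/RT) M. Per-term standard deviations combine as a root sum
of squares; the grid and volume terms are bootstrapped jointly (they come
from the same grid), so their shared spread is carried on one slot rather
than double-counted. Temperatures are always explicit parameters: 300 K for
the simulation-derived quantities, 298.15 K for calorimetry comparisons.

## Block Bayesian bootstrap

Each window's frames are split into contiguous blocks (default 20 per
window; the last block absorbs the remainder). Per resample, each window
independently draws Dirichlet(1,…,1) weights over its blocks; every frame's
multiplicity is its block weight × block count, renormalized so the window's
total equals its frame count — this preserves the per-window sample-size
structure the reweighting denominator depends on. The full estimator
(including the reweighting solve, warm-started from the unperturbed
solution) is re-run per resample; the default is 100 resamples. Failed
resamples are excluded with a warning rather than retried (seed
reproducibility); more than 10% failures is a hard error. Same seed ⇒
bit-identical resamples. On iid data the bootstrap s.d. of a mean calibrates
to the analytic standard error within ~30%; on autocorrelated series the
error estimate grows with block length, as it should.

## Synthetic systems and what they do (and do not) show

The toy binding system is a point ligand in a Gaussian pocket,

    U(x, ω) = −ε e^(−|x|²/2σ²) + ½ κ_Ω e^(−|x|²/2σ²) ω²,

with an internal angle ω ∈ [0, π] of flat base measure, coupled to the
pocket through the same Gaussian envelope. Defaults: ε = 10 kcal/mol,
σ = 2 Å, box side 30 Å, T = 300 K, and — matching the study conditions the
pipeline emulates — 31 distance windows (k = 2 kcal mol⁻¹ Å⁻²) spanning the
pocket to the bulk, an orientation restraint of 0.5 kcal mol⁻¹ deg⁻², and
100 bootstrap resamples. The flat base measure for ω keeps the quadrature
oracle exactly one-dimensional (the SO(3) rotation-angle measure is
exercised separately by the orientation module); the pocket depth and width
give a ΔG(x_B) of ~9 kcal/mol and a pocket volume of a few Å³, i.e. a
strong, well-localized binder at desk scale. Sampling is plain Metropolis —
one joint Gaussian move for the free coordinates plus one reflected move per
bounded coordinate per sweep, with the angle step shrunk to the restrained
width so stiff restraints do not freeze the chain. There is no replica
exchange: the reweighting estimator is exchange-agnostic, so bias-exchange
bookkeeping would add nothing testable.

The quadrature oracle evaluates the radial free energy G(|x|) (angle
integrated out), the pocket volume and ΔG° on a 0.01 Å radial grid and
reports the change under 2× refinement (kept below 1e-4 kcal/mol). With
ε = 0 the PMF is identically zero and ΔG° reduces to the pure
standard-state volume term over the nominal pocket region (default radius:
a quarter of the box side).

What passing toy-system tests shows: the estimator chain — pooling,
reweighting, voxel binning, plateau estimation, Boltzmann volume, restraint
correction, error propagation — is internally consistent and statistically
calibrated, including the central claim that restrained and unrestrained
protocols agree after correction. What it does not show: anything about
force-field accuracy, about sampling convergence of real molecular systems
(the toy has no metastability beyond the pocket itself), or about the
quality of the CVs computed upstream.

## Known limitations

- The restrained-protocol pocket volume uses the restrained grid PMF
  (ΔU(x) ≈ constant inside the pocket); with a position-dependent restraint
  effect this is an approximation. The correction module reports ΔU near
  the pocket so the assumption can be checked per system.
- The bulk plateau assumes the outer windows genuinely reach
  non-interacting separations; the radial profile should be inspected for
  flatness before trusting ΔG(x_B).
- The colvars-dialect reader expects a '#' header naming columns and
  numeric whitespace-separated rows; exotic colvars output options (vector
  CVs in brackets, multi-line records) are out of scope.
- Frames missing any declared CV are rejected, not imputed — every bias
  energy must be evaluable for every pooled frame.
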