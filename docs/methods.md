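# Methods

This note documents the models, numerical choices and limitations of
`cowflow`. It is the design record: everything here is implemented and
exercised by the test suite; no empirical claim is made beyond what the
tests and `scripts/acceptance.py` compute.

## The phantom

No deposited imaging data exist for this problem, so the package
generates its own study object. The template is a circle-of-Willis-*like*
network, not any subject's anatomy: a core ring (left/right ICA termini,
basilar tip, A1/Acom, P1, and both posterior communicating arteries —
one closed loop) with six distal trunks (MCA, ACA, PCA, left and right)
that carry the outlets. Outlets are distributed round-robin over the
trunks; each trunk grows a binary tree toward Fibonacci-spiral directions
on a 26° spherical cap, which keeps sibling subtrees in disjoint angular
sectors. Two geometric guards exist purely for image fidelity: a minimum
split angle (46°) so sibling tubes do not fuse when rasterized, and a
minimum segment length of a few radii so 3D thinning cannot erode a
terminal branch into its parent junction (parallel thinning removes free
ends of blunt, grid-aligned cylinders; the basilar inlet is deliberately
slightly oblique for the same reason).

Radii follow Murray's physiological branching rule r_parent³ = Σ r_child³
upward from the leaf radii, which are drawn uniformly per leaf. For
imaging experiments a `min_radius` floor keeps every vessel resolvable
(≥ 3 voxels radius at the default 0.32 mm spacing); the study
configuration draws leaf radii *above* that floor (0.85–1.25 mm) so that
outlet prominence is a meaningful ordering rather than a tie-break.

Rasterization treats each edge as a capsule, supersamples the lumen
indicator 3× per axis and box-averages, giving sub-voxel partial-volume
mixing at the wall. Noise is additive Gaussian by default (`rician=True`
switches to magnitude-image Rician noise); the ground-truth mask is the
noise-free occupancy ≥ 0.5 indicator. A voxel budget (default 4×10⁷)
guards against accidentally huge grids.

Inlet waveforms are a fixed truncated-Fourier cardiac shape (four cosine
harmonics, systolic peak at 15 % of the period, scaled so the minimum is
exactly mean·(1 − pulsatility)). Period 1.0 s and pulsatility 0.5 are
declared defaults — the reference measurements report only the mean
inflow rates per inlet (3.434/3.065/2.332 ×10⁻³ l/s for ICAr/ICAl/BA),
which the waveform integral matches to 1e−9 relative.

What the phantom does **not** emulate: flow-related enhancement and other
MR physics, vessel curvature between junctions (edges are straight
capsules), wall motion, and anatomical variation of the ring (no fetal or
hypoplastic variants). Passing recovery tests therefore demonstrates the
pipeline's correctness on geometrically clean, high-SNR data, not
robustness to clinical acquisition artifacts.

## Segmentation

The chain mirrors standard interactive angiography workflows. Vesselness
is the Hessian-eigenvalue tubular-structure filter at six scales
(σ = 1…6 voxels), fused by per-voxel maximum; shape parameters default to
α = β = 0.5 with the structure-norm constant c chosen per scale as half
the maximum Hessian norm (the filter's conventional default; supplying a
fixed `c` makes responses comparable across scale subsets). Region
growing admits a voxel iff it is 26-connected to a seed through admitted
voxels and |I(v) − I(seed)| ≤ 0.02·I(seed) — a *static per-seed band*, so
the result is independent of traversal order and idempotent; the mask is
the union over seeds. By default growing runs on the vesselness-fused
intermediate volume (a flag switches to raw intensities).

A strict 2 % band cannot capture partial-volume boundary voxels: on an
honestly rasterized tube the grown mask sits ~0.4 voxel inside the true
wall, and at 10 % noise the band admits almost nothing. The end-to-end
`segment_volume` therefore finishes with a **half-maximum refinement**,
the automated counterpart of the manual post-processing step of
interactive pipelines and the standard full-width-at-half-maximum
criterion for lumen sizing: lumen and background levels are estimated as
medians inside/outside the (dilated) mask and every voxel above the
midpoint that is 26-connected to the mask is accreted. On noise-free
phantoms this recovers the occupancy-0.5 surface essentially exactly;
with noise at 10 % of contrast the Dice against ground truth stays above
0.95 in practice (the acceptance threshold is 0.90).

Surface extraction runs marching cubes at iso-level 0.5 on a Gaussian-
smoothed (σ = 0.5 voxel) indicator; foreground voxel centres are clamped
just above the iso level so smoothing can never erase a thin feature (an
unclamped σ = 0.5 kernel drops an isolated voxel below 0.5 and would
delete it). Laplacian smoothing is the plain umbrella operator (vertex →
vertex + step·(ring centroid − vertex); defaults 20 iterations, step 0.5);
it shrinks convex regions, which the tests document rather than hide —
volume-preserving (Taubin) smoothing was deliberately not used because
the emulated workflow names plain Laplacian smoothing. End-cutting slices
each opening with the plane through the end point normal to the local
centerline tangent. The cut is implemented as an exact triangle clip
restricted to a ball of 3 local radii around the end, because an infinite
plane would decapitate unrelated vessels crossing it elsewhere; the open
loop is then extruded prismatically (default 5 mm) and the planar
cross-section area recorded per opening.

## Centerline graph, trimming, aneurysms

The lumen mask is thinned to a voxel skeleton; voxels with ≠ 2 skeleton
neighbours become nodes, chains become edges with length = polyline arc
length and radius = median inscribed-sphere radius along the chain
(median, not mean, because clearance drops near junctions and tips).
Spurs shorter than 2× their radius are pruned; runs of degree-2 nodes are
merged (lengths summed, radius length-weighted — preserves series
Poiseuille resistance under mild taper better than an unweighted mean).
Openings are bound to degree-1 nodes by a globally optimal assignment
(Hungarian algorithm on within-tolerance distances); by default an
unbindable opening is an error, while the study pipeline uses
`strict=False`, which drops unbound *outlets* with a warning (thinning
occasionally swallows one tip of a 60-outlet phantom; inlets are always
strict).

"Most prominent" outlet = largest cross-sectional area πr², ties broken
lexicographically — area is the one outlet attribute the emulated
workflow tabulates. Trimming removes all other outlets and iteratively
deletes the dangling chains this creates; edges on paths from inlets to
kept outlets keep their exact geometry (asserted in tests), so complex
and trimmed models differ only in topology downstream of removed outlets.

An aneurysm is a compliant 0D side chamber, not a meshed sac: the target
edge is split at the arc position and a neck edge (radius = neck-to-parent
ratio × parent radius, default ratio 1 = diameter-matched; length 1 mm)
connects to a sac node carrying volume and compliance. Defaults: sac
volume 100 mm³ (a typical large saccular aneurysm), compliance
10⁻¹² m³/Pa — free parameters of the surrogate, configurable and swept in
tests. The default pathological configuration places IA-A on the right
and IA-B on the left middle cerebral artery.

## Reduced-order hemodynamics

The 3D finite-volume solve of the emulated workflow is replaced by a
resistive network model that preserves the mechanism under study —
split-driven flow redistribution. Each vessel edge is a Poiseuille
resistor 8μL/(πr⁴) (μ = 0.004 Pa·s, ρ = 1055 kg/m³); inlet flows are
prescribed waveforms; **every outlet receives fraction rᵢⁿ/Σrⱼⁿ (n = 2 ⇒
proportional to area) of the total instantaneous inflow**, computed
globally over all outlets. Global splitting is the default because with
three inlets and a communicating loop a per-branch assignment is
ill-defined (the loop mixes territories); a `per_branch` mode exists for
comparison. Interior and loop flows follow from the nodal pressure solve
(weighted graph Laplacian, reference node at zero pressure, direct sparse
LU factorized once since the matrix is time-invariant). Sacs obey
C·dP_sac/dt = (P_neck − P_sac)/R_neck by implicit Euler, which adds C/Δt
to the sac diagonal. Time stepping: Δt = 1 ms, three cycles from zero sac
pressure, last cycle evaluated (with the default sac time constant
R·C ≈ 10⁻⁴ s the third and second cycles agree to ≪ 1 % RMS; the
protocol is kept for fidelity). Flow conservation at interior nodes is
exact to solver precision (asserted < 10⁻¹⁰ of peak flow at every step).

Vessels carry no inertance or compliance — the model is quasi-static in
the vessel network. Consequences: pressure and flow are in phase, wave
propagation and pulse-wave damping are absent, and sac filling is driven
only by local pressure oscillation through the tiny compliance, so NIR
magnitudes are far below those of a 3D sac with resolved intrasaccular
flow. Deltas between paired models remain meaningful; absolute sac
numbers are surrogates. Edge wall shear is the Poiseuille value
τ = 4μQ/(πr³) (signed); sac "WSS" is the neck-edge shear, reported
explicitly as `wss_proxy`.

Full velocity profiles are reconstructed analytically: the edge flow
series is Fourier-decomposed; the mean maps to the parabolic profile and
each harmonic k to the annular-Bessel Womersley solution at
α_k = r√(kωρ/μ), normalized so each harmonic carries exactly its flow.
Radial samples sit on Gauss–Legendre nodes whose quadrature weights
(2πr dr) reproduce Q(t) to ~10⁻¹³ for band-limited inputs (the acceptance
bound is 0.5 %).

## Evaluation statistics

All period integrals are trapezoidal: closed grids (first = last sample)
integrate directly, open periodic grids average with wrap-around (the
plain mean on uniform grids, hence exactly phase-invariant). TAWSS is the
period mean of |τ|. OSI = ½(1 − |∫τ|/∫|τ|) — the standard definition,
adopted because only the name is given in the emulated workflow; the
identically-zero series is defined as OSI 0 with a warning. NIR is the
positive part of the neck flow in ml/s ("into the sac" is positive by the
solver's neck-edge orientation). V_Norm = V·A_plane/Q_plane; its
area-weighted plane mean is 1 by construction (checked to 10⁻³ quadrature
tolerance), and V is the plane-normal velocity component — the only one
the reduced model defines. Centerline velocity is the cross-section mean
Q̄/(πr²) at equidistant arc-length stations; when comparing paired models
the *complex* path's radius profile is used for both (the lumen geometry
is shared by construction; only the flows differ), so deltas isolate the
flow effect from chain-merging bookkeeping. The delta convention is fixed
globally: δX = X_complex − X_trimmed, negative when the trimmed model
overestimates.

## The four-case study

`run_study` executes phantom → rasterization → segmentation → skeleton
graph → {complex, trimmed to 10} → {physiological, + 2 MCA aneurysms} →
four pulsatile solves → metrics → two paired reports. Problem sizes were
chosen so the default run finishes in a few minutes on one CPU: template
scale 0.8 (≈ 45 mm extent, ≈ 200³ voxels at 0.32 mm), 60 outlets, 3 cycles
of 1000 steps. `skip_imaging=True` starts from the template network
directly. Every artifact (networks, waveforms, per-edge results, metrics,
reports, resolved config) is written with fixed float formatting and
hashed into `manifest.json`; reruns with the same config are
bit-identical. Volumes are written as uncompressed NIfTI so hashes do not
depend on compression timestamps.

## Known limitations

- Straight-segment geometry: no curvature-driven secondary flow exists
  even in principle; Womersley profiles are axisymmetric by construction,
  so the profile-shape asymmetries a 3D solve shows cannot appear.
- The Murray split is an outlet boundary condition, not a result: outlet
  flows are imposed, so complex-vs-trimmed differences arise from the
  split set and the loop pressure solve, not from peripheral impedance.
- 0D sacs cannot reproduce intrasaccular flow patterns; δNIR/δWSS between
  paired models are orders of magnitude smaller than those of resolved 3D
  sacs and should be read as directional surrogates.
- Thinning-based skeletons occasionally lose one tip of a very dense
  60-outlet phantom; the tolerant binding mode (study default) drops such
  outlets explicitly rather than mislabeling them.
- The segmentation operating point assumes bright-lumen, high-SNR volumes
  (7T ToF-like); it is untested on low-contrast or bias-field-corrupted
  data, which the phantom does not model.
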