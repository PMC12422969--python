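# Methods

This note documents the models, estimators and numerical choices behind
`ampardyn`, what the synthetic-data generators do and do not emulate, and
the limitations a user should know before trusting a number.

## Conformational coordinates

A two-lobed (clamshell) dimer is reduced to centroids of Cα atoms over
four lobe selections: upper and lower lobe of subunit 1 (`com1`, `com2`),
upper and lower lobe of subunit 2 (`com3`, `com4`), plus the joint
centroids of both upper lobes (`com13`) and both lower lobes (`com24`).
The default lobe partition for the receptor N-terminal domain is upper =
residues 117–243 and 354–380, lower = 1–116 and 244–353, in
mature-peptide numbering (signal peptide removed). Structures read from
files keep their author numbering; a per-structure `numbering_offset`
(default 0) maps file numbering to mature numbering at selection time, so
no offset is ever hard-coded — for deposited models the offset must be
verified against marker residues before analysis.

Centroids are unweighted means of the selected Cα positions; because all
Cα atoms have the same mass this equals a mass-weighted mean restricted
to Cα.

**Displacement torsion** is the signed dihedral over the ordered points
(com2, com1, com3, com4) in the standard atan2 (IUPAC) convention. The
sequence runs lower₁ → upper₁ → upper₂ → lower₂: the com1–com3 segment is
the rotation axis and the angle measures the rotation of the two lower
lobes relative to each other. One wording issue deserves a note: the
natural reading of "ends with the lower lobe of the second subunit"
fixes the fourth point as com4; a label that would instead repeat com3
(an upper-lobe centroid) cannot close a dihedral that measures
lower-lobe rotation, so com4 is used.

**Opening angle**: v₁ = com2 − com13 and v₂ = com4 − com13 are projected
onto the plane perpendicular to the axis â from com24 to a ghost point
g2 = com24 + 0.5 Å · n̂, where n̂ ∝ (com1 − com24) × (com3 − com24) is the
normal of the plane through com24 and the two upper-lobe centroids. The
returned value is the signed angle from projected v₁ to projected v₂
about â. Projecting removes the component of the apparent angle change
that comes from displacement rather than opening. The sign is fixed by
the ghost-axis direction as constructed; consumers comparing against
magnitude-only conventions can take absolute values.

Both coordinates are invariant under rigid motion of the whole dimer
(tested to 1e-8°), the torsion is invariant under subunit relabelling
(dihedral reversal symmetry) and flips sign under mirror reflection.
Angles are handled in radians internally and reported in degrees.

Degenerate inputs raise: collinear (com24, com1, com3) leaves the ghost
point undefined; lobe vectors parallel to the projection axis leave the
opening undefined; collinear dihedral points leave the torsion undefined.

## Structure I/O

PDB and mmCIF are read and written through gemmi. Altlocs keep the
highest-occupancy conformer, ties broken by file order. Hydrogens are
excluded from selections by default; all interface metrics are
heavy-atom. Trajectories are multi-model PDB files or plain-text XYZ
frame series mapped onto a topology structure; binary trajectory formats
are out of scope. Superposition uses the Kabsch/SVD solution
(scipy's `Rotation.align_vectors` on centred coordinates); near-collinear
point sets are rejected as ill-conditioned rather than silently solved.
The PDB text format carries three decimals, so round-trip fidelity is
1e-3 Å and angle recoveries through PDB files are good to ~0.01°;
in-memory pipelines are exact.

## Interface metrics

Contacts are residue pairs whose minimum heavy-atom distance is at most
the cutoff; the default cutoff is 4.0 Å (a common heavy-atom contact
threshold — configurable, since footprint figures rarely state one).
Footprint differences compare residue-pair identities only, never
distances, and refuse to compare footprints computed at different
cutoffs. Contact footprints are monotone in the cutoff by construction.
Marker-pair distances support Cα, Cζ (e.g. arginine stacking distances)
and closest-heavy rules. Interface expansion between two structures is
measured as the difference of their centroid separations, and
inter-protomer displacement as the rotation angle
arccos((tr R − 1)/2) of the transform superposing the second protomer
after aligning the first.

## Well-tempered metadynamics

The bias is a sum of diagonal 2-D Gaussians. Well-tempered deposition
uses h = h₀·exp(−V(s)/kB·ΔT) with ΔT = (γ−1)·T; defaults are the
standard production values γ = 10, T = 300 K, h₀ = 1.2 kJ/mol, one hill
per 10 ps. kB is fixed at 0.0083144621 kJ/mol/K. Torsion-like CVs are
periodic with period 360° (or 2π) and minimum-image differences are used
everywhere, including HILLS metadata read from `#! SET min/max` lines.

Adaptive hill widths follow a diffusion-style estimator: σ_j is the RMS
displacement of CV j over the trailing τ_D = 10 ps window, measured
relative to the current CV value, floored (default 0.05 CV units in the
toy driver, 0.01 in the bare rule) and optionally capped. Before the
window fills, a configured initial width (default 0.3) is used — the
upstream engine's exact pre-window behaviour is not documented, so this
is an explicit package choice.

Two FES reconstructions are provided and labelled in `FESurface.method`:

- **sum_hills**: F(s) = −(γ/(γ−1))·V(s, t_final), min-shifted to zero.
- **histogram**: from CV samples of the biased run. The stationary
  form F(s) = −kB(T+ΔT)·ln ρ̂(s) inverts the well-tempered stationary
  distribution and is the default. It is exact only insofar as the bias
  has converged: a residual bias error ε(s) enters the estimate
  amplified by γ, which at desk-scale run lengths (tens of ns of toy
  dynamics) dominates the result. The driver therefore supports freezing
  the bias after a deposition phase; samples collected under a *fixed*
  bias V follow P ∝ exp(−(F+V)/kBT) exactly, and passing that bias as
  `final_bias` switches the estimator to the exact inversion
  F = −kBT·ln ρ̂ − V, whose errors stay on the physical-temperature
  scale. The benchmark uses this route. Histograms are kernel-smoothed
  (Gaussian, width in CV units, periodic wrapping where declared);
  unvisited nodes are NaN.

### Toy Langevin driver

CV-space dynamics is overdamped (Brownian):
s ← s + (dt/ξ)(−∇U − ∇V) + √(2kBT·dt/ξ)·η. The thermostat/integrator
stack of production MD engines is deliberately out of scope; the
stationary distribution, which is all the FES estimators consume, does
not depend on ξ. Walkers share one bias (multiple-walkers scheme) and
deposit sequentially at each deposition time. Reflective walls at the
declared CV domain confine the walkers (hard-wall restraint); a
single-step excursion larger than the domain raises a stability error
naming the step. Identical seeds give bit-identical hills and samples.

### Double-well benchmark

The calibrated benchmark (`metadyn.double_well_benchmark`) uses
U = 6·((x)² − 1)² + 2.837·x + 15·y² kJ/mol. The quartic pair of wells is
symmetric; the linear tilt is chosen so the Boltzmann-quadrature
free-energy difference between the x<0 and x>0 basins is 5.0 kJ/mol at
300 K (the reference is recomputed by quadrature at run time, never
hard-coded). Run conditions: 4 walkers, ξ = 30 kJ·mol⁻¹·ps·Å⁻²,
dt = 0.2 ps, 6 ns of deposition followed by 18 ns of frozen-bias
sampling, σ floor 0.05 / cap 0.5. The barrier (6 kJ/mol) is low enough
that the biased walkers cross basins every few tens of ps, which is what
makes a desk-scale run statistically meaningful; both reconstruction
routes recover the reference within 1 kJ/mol at these settings
(hill-sum fluctuates ±0.5, the corrected histogram ±0.15 across seeds).
Basin free energies are Boltzmann-integrated over each half-grid rather
than read off single nodes, which is robust to node-level noise.

## Patch-clamp kinetics

**Decay fits.** The peak is the extremum of |I − median(I)| (the median
tracks the resting/steady level whether or not a pre-stimulus baseline
is recorded); the fit window runs from the first post-peak sample at or
below 90% of the peak amplitude to the sweep end (user-adjustable). One-
or two-exponential models plus a fitted steady-state baseline are solved
by Levenberg–Marquardt from three deterministic starts with
log-parameterized time constants; components are normalized τf ≤ τs and
τw,des uses the amplitude-weighted formula. Amplitudes are referenced to
the window start (as in common acquisition software), which matters when
comparing to generative amplitudes defined at the peak. Flat traces are
rejected as degenerate.

**Recovery fits.** Free parameters are y₀, a₁, k₁, k₂ (bounded,
amplitudes in [0, 1], rates positive via log-parameterization); slopes
m₁ = 4, m₂ = 1 and y_max = 1 are fixed by default, matching the steep
recovery profiles the functional form was chosen for. τ_i = 1/k_i and
τw,rec = (τ₁a₁ + τ₂(y_max − a₁ − y₀))/(y_max − y₀). At least 6 points
are required.

**NSFA.** Ensemble mean and variance (ddof = 1) are computed per sample
across ≥ 20 sweeps over the desensitizing phase (peak of |Ī| to sweep
end), grouped into 10 amplitude bins (equal sample count by default,
equal width by flag), and fitted with σ² = i·Ī − Ī²/N + sgn·σ_b². The
model is linear in (i, 1/N, σ_b²) and solved by ordinary least squares —
no iteration, no starting values. The background term is additive
(variances add) by default; the printed-convention sign (−σ₀²) is
available via `background_sign=-1` and flips only the reported σ₀², not
the fit. If a background window is supplied, its measured variance is
subtracted from σ²(t) before fitting instead. Non-concave variance–mean
data (fitted 1/N ≤ 0) yields a warning carried in the result rather than
an exception. Derived quantities: chord conductance γ = i/V_h (pS, with
V_h in mV and i in pA; default −60 mV, no junction-potential
correction), peak open probability P_open = Ī_peak/(N·i). The parabola
vertex identity (Ī = iN/2, σ² = i²N/4 + σ_b²) holds algebraically for
every fit and is asserted in tests.

**Rectification index.** RI = −(I₊₄₀ − I₀)/(I₋₆₀ − I₀) from
sweep-averaged ramp currents; an ohmic conductance reversing at 0 mV
gives exactly 2/3, a channel fully blocked above 0 mV gives 0. The RI is
invariant under uniform current scaling.

## Synthetic data: what it does and does not emulate

`make_two_lobe_dimer` builds each lobe as a seeded Gaussian Cα cloud
(s.d. 5 Å, 60 residues by default — a realistic clamshell-lobe size) and
translates rigid copies onto centroid positions constructed in closed
form so the prescribed torsion θ and opening ψ are realized exactly
before noise: with upper centroids at (±d/2, 0, 0), lower centroids sit
at depth m = h·cos(θ/2) with out-of-plane offsets ∓h·sin(θ/2) (torsion)
and in-plane offsets ±q, q = −m·tan(ψ/2) (opening), d = h = 30 Å.
Because the coordinates depend only on centroids, subunit placement by
translation is sufficient. The construction degenerates only as |θ| or
|ψ| approach 180°. Generated dimers have no secondary structure, no
side chains and no inter-lobe covalent connectivity — they validate the
geometry pipeline, not force-field behaviour.

`make_channel_sweeps` realizes the exact statistical model NSFA assumes:
per sample, open channels ~ Binomial(N, p(t)) with current = count·i
plus Gaussian baseline noise. Gating correlations between successive
samples are not modelled — NSFA itself assumes none, so recovery tests
validate the estimator under its own model, not the model against real
channels. The default open-probability course rises with τ = 0.3 ms and
desensitizes with τ = 5 ms to a 5% plateau, typical fast-desensitizing
AMPAR scales.

`make_recovery_series` and `make_iv_ramp` evaluate the fitted functional
forms directly (plus optional noise), so fits on them test estimator
correctness, not functional-form adequacy. The default recovery
intervals follow the two-pulse protocol (2 ms steps to 40 ms, then
10 ms steps). Rectification uses a Boltzmann open-fraction block — a
phenomenological stand-in for intracellular polyamine block.

All generators are bit-reproducible in (spec, seed).

## Known limitations

- No all-atom MD: the toy driver works in CV space directly; nothing
  here validates the force-field dynamics of a real domain dimer.
- The stationary-form histogram estimator should not be trusted on
  short runs without the `final_bias` correction (see above).
- The decay-fit peak finder assumes a single dominant transient per
  sweep; multi-pulse sweeps must be windowed by the caller.
- Footprints use a fixed distance cutoff, not buried surface area or
  energetics; occupancy weighting is not applied.
- mmCIF writing goes through gemmi's default mmCIF document; exotic
  annotations are not preserved on round trip.
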