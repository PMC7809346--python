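# Methods

This note records the models, conventions, parameter choices and known
limitations behind `glypath`, in the spirit of a simulation package's model
documentation.  Units throughout: energies kcal/mol, lengths Å, times fs,
temperatures K; k_B = 0.0019872 kcal mol⁻¹ K⁻¹.

## Ring puckering

The forward Cremer–Pople transform fits the unique mean plane through the
six ring atoms (Σz_j = 0 and both first-harmonic plane conditions hold to
1e−9), then projects the out-of-plane displacements onto the m = 2
cos/sin harmonics and the alternating m = 3 mode, giving (q_x, q_y, q_z)
and the spherical (Q, θ, φ).  Atom 1 is O5 and the traversal order is
O5, C1, …, C5 — the standard carbohydrate convention under which the 4C1
chair of a β-D-pyranose maps to θ ≈ 0 (verified against relaxed 3-D sugar
geometries).  Rings with Q < 0.05 Å are reported planar and carry no
angular coordinates; arccos is unstable there and no conformer is defined.

The 38 canonical conformers are **generated, not transcribed**: each is an
ideal displacement pattern (chairs: alternating; boats: two para atoms
displaced together; skew-boats: two meta atoms displaced oppositely;
envelopes: one atom; half-chairs: two adjacent atoms oppositely), run
through the same forward transform to yield its reference (θ, φ).  The
classifier is therefore phase-consistent with the transform by
construction; the φ longitudes are this package's own convention and are
internally consistent rather than matched to any external script.
Classification minimizes great-circle distance; a secondary label is
attached when the runner-up is closer than 1.5× the nearest distance,
which reproduces mixed labels such as "2SO/2,5B" at equatorial midpoints.

The conformational FEL lives on the (q_x, q_y) disk at roughly constant Q;
disk points are classified by mapping radius → θ via arcsin(r/Q).

## Synthetic landscapes

Potentials are sums of *negative isotropic Gaussians* (basins) plus quartic
confinement walls — every term has analytic gradients and the construction
has closed-form structure.  For two isotropic equal-width wells with
collinear centers the first-order saddle lies exactly on the joining
segment (the perpendicular Hessian is positive there), so ground-truth
minima/saddle/barrier are obtained by 1-D critical-point finding (brentq on
the directional derivative) — independent dense-grid minimax search is used
as an oracle in the tests.  Well depths are calibrated at construction by a
2-D root solve so the stated truths hold exactly:

- **Conformational landscape** (CVs q_x, q_y): chair basin at the disk
  center, distorted basin at the 2SO/2,5B midpoint longitude at radius
  0.55 Å, well width 0.12 Å, radial wall at 0.85 Å.  The distorted basin is
  1.0 kcal/mol below the chair (the near-isoenergetic dual-conformer
  situation); the saddle sits 4.0 kcal/mol above the global minimum.  The
  interconversion barrier is not an experimentally anchored number; it was
  chosen once so that the default metadynamics protocol converges within
  2000 hills at kT = 0.596 kcal/mol, and is flagged as a stand-in.
- **Reaction landscape** (CVs CV1–CV3, difference-of-distance coordinates
  of the three bond changes of an inverting glycosidase): reactant basin at
  (−0.75, −0.75, −0.75) Å, product basin at +0.75, widths 0.55 Å, box walls
  at ±1.6 Å.  The reactant-side barrier is 14.1 kcal/mol and the reaction
  free energy −3.0 kcal/mol, both multiplied by a **desk factor**
  (default 0.35 → barrier 4.935 kcal/mol) so that barrier crossing and
  unbiased committor shooting are affordable on one CPU; set the factor to
  1 for the full-scale landscape.  The −3.0 kcal/mol exothermicity is a
  generic choice for a hydrolytic step, not a fitted value.
- **1-D double well** (barrier 3.0, offset 0.5 kcal/mol): the smallest
  system on which barrier-recovery protocols are exercised.

Ring-trajectory and kinetics generators return their ground truth with the
data (`RingTrajectory.dwell_plan`, `DataFrame.attrs["truth"]`); downstream
tests always compare against these stored truths.  All generators are
seed-deterministic.

## Sampling

CVs are propagated directly with BAOAB Langevin dynamics (timestep 0.12 fs,
mass 50 internal units).  This *replaces* first-principles propagation; the
claim being verified is the bias logic and the analysis chain, not the
energetics.  **Friction defaults to 0.1 fs⁻¹**: the velocity relaxation
time (1/γ_f = 10 fs) must stay below the hill-deposition interval (24–42 fs
at paces 200–350), otherwise consecutive hills correlate with the walker's
ballistic motion ("hill surfing") and visibly distort reconstructed
profiles — with friction 0.01 fs⁻¹ we measured barrier errors of
1–2 kcal/mol on the 1-D double well that vanish at 0.1 fs⁻¹.

Well-tempered deposition: hill k has height w·exp(−V_bias(s_k)/(k_B ΔT))
with ΔT = (γ−1)T, evaluated at the deposition point before the hill is
added; γ = ∞ recovers standard metadynamics.  Bias evaluation is an exact
sum over all hills (no cutoff), vectorized; the brute-force sum is the test
oracle at 1e−10.  CVs are non-periodic with quartic walls; wall/restraint
placement is configurable since no external reference fixes it.

Hills logs are whitespace-separated text with a `#! FIELDS` header naming
time, centers, sigmas, height and bias factor, and `#! SET` lines declaring
units (PLUMED-compatible column order).  Heights declared in kJ/mol are
converted on read (÷4.184); malformed lines and non-monotonic times are
errors with line numbers.

## FEL analysis

Reconstruction uses the well-tempered estimator
F = −(γ/(γ−1))·ΣGaussians, min-normalized, on a grid covering the hill
bounding box plus a 3σ margin (101 points/axis in 1–2 D, 41 in 3 D —
sub-0.01 Å resolution on the pucker disk at ~10⁴–10⁵ grid points).
Projections are Boltzmann integrals −kT ln ∫ e^(−F/kT); projection can only
lower minimax barriers (asserted against the 3-D oracle).

Minima: local grid minima filtered by topographic prominence (lowest escape
level − minimum energy > 1.0 kcal/mol default), so deposition ripple does
not spawn spurious basins.  MFEP: Dijkstra-style minimax search over
8-connected (2-D) / 26-connected (3-D) grid moves, ties broken by lower
path-integrated energy; deterministic and checkable against an independent
connectivity-threshold oracle, which is how the "minimum free energy
pathway" drawn on a gridded FEL is operationalized here (a string method is
deliberately avoided as harder to oracle-check).

**Basin free-energy differences are Boltzmann-integrated** over grid points
within 0.2 Å of each basin center rather than read off single grid minima:
integration averages the deposition ripple, and for basins of equal
curvature (true of the generators by construction) the difference is an
unbiased estimate of the minima gap.  Across four seeds of the default
conformational protocol the basin-integrated estimate landed within
0.25 kcal/mol of truth where single-point estimates strayed up to 1 kcal/mol.

Convergence monitoring reconstructs the FEL at hill-count checkpoints and
tracks that basin difference; "converged" means the last 3 checkpoints vary
by < 0.25 kcal/mol.  Under the default 2-D protocol (hills of 1.0 kcal/mol)
the tail still fluctuates by ~0.3–0.4 kcal/mol — the stopping rule then
correctly reports *not yet converged* even though the final estimate is
within ±0.5 of truth; a finer-hill 1-D run does satisfy the rule, and that
is where the protocol's positive branch is exercised.

Height-sensitivity protocol: a base run is propagated until the bias at the
start basin reaches ~55% of a reference barrier; each alternative Gaussian
height is then run independently from that restart configuration and its
barrier estimated from the reconstructed FEL; the spread across heights and
the consistency of the basin ordering are reported.

## Committor analysis

Commitment basins are ellipsoids around the landscape minima with radii
equal to the generator well widths — the natural basin-core scale; no
external reference defines stopping regions, so this is a documented
default.  Shooting trajectories draw Maxwell–Boltzmann velocities, run
unbiased Langevin dynamics, and stop at first basin entry; trajectories
exceeding the step cap count as "uncommitted", are excluded from the ratio,
and invalidate a candidate beyond a 10% fraction.  Refinement tests 23
candidates (the saddle plus uniform samples in a 0.15 Å ball around it)
with 20 shots each; the acceptance window [0.35, 0.65] is ±1.5 binomial SD
around 0.5 at n = 20.  Committor monotonicity along the MFEP and agreement
of the accepted candidate with a large-n re-shoot are property-tested.

## Geometry and kinetics

Reaction CVs are differences of two interatomic distances with the sign
fixed by pair order.  Running averages are centered 5-point moving means
with truncated edge windows (no reflected/invented data).  Dihedrals follow
the standard signed atan2 construction, cross-checked against an
independent MD-analysis library.  State summaries report per-distance
mean ± SD over non-overlapping R/TS/P frame windows plus a majority-vote
ring conformer.

Calibration lines keep a free intercept (instrument offset).  The
Michaelis–Menten fit is nonlinear least squares on v = kcat·[S]/(K_M+[S]);
designs whose maximum [S] < 2·K_M are flagged non-saturating, in which case
only kcat/K_M is reliably identified (asserted via fit covariance).  Eyring
conversions use transmission coefficient 1 and default to 313.15 K (40 °C,
the assay temperature); the formula and temperature are stated choices
since rate→barrier conversions are convention-dependent.

## What the synthetic data do and do not show

The generators emulate the *statistical structure* the analysis assumes:
two-basin landscapes with known gaps and saddles, conformer dwell patterns
with coordinate noise, intensity readouts with relative Gaussian noise.
They do not emulate electronic-structure energetics, multi-basin FELs with
intermediate minima, anisotropic/curved basins, correlated experimental
error, or finite-sampling artifacts of real MD.  Passing tests therefore
demonstrate correctness of the transforms, estimators and protocols under
controlled conditions — not the accuracy of any physical prediction for a
real enzyme.  Crystal-structure checks run on synthetic dual-altloc
reconstructions written by the package's own PDB layer; parsing deposited
entries uses the same code path but is not exercised offline.

## Problem sizes

Default analysis sizes were chosen so the full validation chain runs on a
single CPU: 2000-hill × 200-step conformational runs, 3000-hill 1-D runs,
41³ reaction grids, 23 × 20 committor shots (plus n = 200–400 re-shoots in
property tests).  These are the package's standing defaults, not limits of
the method.

## Known limitations

- No reweighting/on-the-fly estimators and no block-analysis error bars for
  the FEL (future work); uncertainty is assessed by seed replication.
- The minimax MFEP is grid-resolution-limited; saddle positions are exact
  only to one grid cell.
- `refine_ts` samples candidates geometrically around the saddle rather
  than from stored trajectory frames; with a trajectory available, frames
  falling in the saddle region are the natural candidate pool.
- Single-walker metadynamics only; no adaptive Gaussians or multiple-walker
  variants.
- PDB is the only required structure dialect; five-membered-ring
  pseudorotation and alternative pucker parameterizations are out of scope.
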