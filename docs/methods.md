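# Methods

## Scope and conventions

All analyses assume a flat bilayer whose average plane is perpendicular to
the third coordinate axis (Oz) in an orthorhombic periodic box; triclinic
cells are rejected at read time. Units are fixed throughout: nm for
lengths, ns for times, degrees for angles, elementary charges (e) for
partial charges, mV for potentials, mol/L for the bulk electrolyte and
µmol/L for surfactant concentrations. Analysis windows follow the
"last N ns" convention common for equilibrated trajectories; when no
window is given the full trajectory is used and a notice is logged.

## Membrane frame and leaflets

The membrane centre of a frame is the mean z of all lipid-phosphorus
(LIPID_P) atoms; a per-frame recentring makes every profile and band
definition drift-free (an all-lipid centre-of-mass alternative is exposed
as a switch). A molecule belongs to the UPPER leaflet when its reference
atom — N⁺ for cationic surfactants, S for SDS, the hydroxyl O for
cholesterol, P for lipids — lies above the centre. The leaflet's *outward*
normal (+Oz above, −Oz below) is used for all orientation angles, so the
two monolayers pool into one distribution and a molecule pointing "into
the water" looks the same in either leaflet.

## Orientation angles

η is the angle between the outward normal and the head vector
h = r(para C) − r(N⁺); θ between the normal and the tail vector
t = r(terminal C) − r(N⁺ or S). Anchor pairs are unwrapped by minimum
image relative to the charged anchor before the vectors are built, so
molecules straddling the periodic boundary are handled exactly. Records
with coincident anchors (zero-length vectors) are skipped with a logged
warning. Angle densities are plain normalised histograms on [0°, 180°]
with a 2° default bin — fine enough to resolve ≈20° features without
noise — and the mode is reported as the bin centre of maximal density.
Note that with wide distributions (κ ≈ 8, circular SD ≈ 20°) the
histogram argmax wanders by a few degrees between realisations; pooled
means are the stable summary and are what the recovery tests check.

## Charge-density profiles

Layers are S_z(z − dz, z + dz] on a grid of step 0.1 nm covering ±3.5 nm.
The half-width dz is an independent parameter defaulting to step/2, which
tiles the slab: summing density × area × 2dz over the grid then returns
each group's total charge exactly (the conservation check demands 1e-6 e).
Point partial charges are binned by atom position with no spreading or
smoothing, matching a per-layer sum. Extrema are local maxima/minima
exceeding a noise floor of 3× the median absolute density over the
outermost 1 nm at each grid end (where only baseline noise lives);
all-zero profiles yield an empty peak set. The thickness proxy is the
distance between the two dominant negative phosphorus extrema.

## Cholesterol clusters and plunge events

The contact graph uses minimum-image O–O distances with a 0.7-nm cutoff;
components are found with scipy's sparse graph machinery (tests verify
exact agreement with an exhaustive breadth-first search on hundreds of
random periodic configurations). Clustering is done in 3D over both
leaflets — a 0.7-nm O–O contact across leaflets is geometrically
near-impossible in an intact bilayer, so this rarely differs from
per-leaflet clustering — and the cutoff must stay below half the smallest
box edge for the minimum-image convention to be unambiguous; larger
cutoffs are rejected rather than silently miscounted. Size-1 components
are counted, and the distribution object also reports the
singleton-free convention.

A plunge event opens when a cholesterol O enters |z − z_c| < 0.3 nm and
closes when it leaves; dwell is the time between the first inside frame
and the first outside frame, events shorter than 1 ns are discarded, and
`reached_interface` flags excursions within half the band of the centre.
The band half-width and minimum dwell are analysis defaults (the
underlying phenomenon is described only qualitatively); both are exposed.
Events truncated by the trajectory ends carry
`returned_to_same_leaflet = None` since the prior or posterior leaflet is
unobserved.

## Electrostatic measurement model

The Grahame equation ψ₀ = (2RT/F)·asinh(σ/√(8ε₀ε_r RT c)) (1:1
electrolyte; defaults 20 mM, 295 K, ε_r = 80) maps surface charge density
(e/nm²) to the diffuse-layer potential; its closed-form inverse is used
for round trips. ΔΦ_b is identified with the diffuse-layer change only —
dipole-potential changes are set to zero, consistent with IFC and
nonactin readings coinciding when adsorbates neither cross the membrane
nor disturb the monolayer dipoles.

Adsorption is a Langmuir isotherm Γ = Γ_max·K·c_s/(1 + K·c_s) with the
subsurface concentration c_s = c·exp(−z F ψ₀/RT) carrying the Boltzmann
factor of the self-generated potential, σ = z·Γ, closed by ψ₀ =
Grahame(σ). The fixed point is solved by damped iteration (adaptive
damping halves on oscillation) to |Δψ₀| < 1e-6 mV, with a hard cap of
10⁴ iterations; a `feedback=False` switch reproduces the naive
Langmuir + Grahame composition. Fits of (K, Γ_max) run in log-parameters
(Levenberg–Marquardt) for positivity; curves whose potential spread stays
under 1 mV are flagged unidentifiable instead of fitted. Initial guesses
come from the data (Γ_max from the largest potential via the inverse
Grahame map, K from the mid-range concentration).

The IFC scan model is the electrostriction parabola
C(U) = C₀(1 + α(U − Φ_in)²), quadratic in U, fitted by ordinary
polynomial least squares; the vertex is Φ_in, its standard error follows
from the polynomial covariance by the delta method, and scans whose
fitted minimum falls outside the scanned range (or whose fit is
non-convex) raise a range error. Higher-order electrostriction terms are
ignored. The nonactin conversion uses the monovalent-cation carrier
convention ΔΦ_b = (RT/F)·ln(G₀/G): positive adsorbed charge raises the
barrier and lowers the conductance. The formula's sign convention is a
modelling choice documented here because instrument conventions vary.

## Synthetic systems

The generator emulates statistical structure only — no force field, no
dynamics, no thermodynamic realism. Lipids sit on jittered lattices at
z = ±leaflet_z (spacing √(area per lipid), default 0.7 nm²) carrying −1 e
at the phosphorus plane and +1 e at the choline plane 0.1 nm further out.
Surfactants are three-point anchor triplets: the charged anchor at a
prescribed depth (default 2.5 nm), the para carbon at 0.45 nm along a
direction whose polar angle from the outward normal is a von Mises draw
about η₀ with concentration κ, and the terminal carbon at 1.30 nm along
an independent θ draw; azimuths are uniform. Molecules are split evenly
between leaflets. Cholesterol O positions follow a Thomas process per
leaflet (Poisson parents, Gaussian offspring, exact total count), so the
cluster-size distribution has a tunable, analytically understood target.
Frames add i.i.d. Gaussian jitter (default σ = 0.05 nm) to every
coordinate; one seeded `numpy.random.Generator` drives every draw, making
output bit-reproducible.

Two deliberate statistical details:

* **Folded draws are mean-corrected.** A polar angle lives on [0°, 180°];
  folding a circular von Mises draw at the pole skews its mean toward 90°
  when the centre is within ~2 circular SDs of 180°. The generator
  numerically offsets the draw centre so the *realized* mean equals the
  prescribed η₀/θ₀, which is the contract the recovery tests rely on.
* **Jitter tilts measured angles.** Isotropic positional noise of SD σ on
  both endpoints of a vector of length L biases its measured polar angle
  by ≈ (σ√2/L)²·cot(ψ), about −1.2° on η at the defaults (σ = 0.05 nm,
  L = 0.45 nm) and −0.3° on θ. This is a genuine property of measuring
  angles on noisy coordinates and is left uncorrected; recovery tests use
  a 3-standard-error tolerance with the standard error taken over
  per-molecule means, because each molecule's angle draw persists across
  frames (frames are not independent samples of the angle).

Synthetic measurement curves add seeded Gaussian noise (mV) to the model
potentials and build one IFC scan per concentration with the vertex at
that concentration's noisy potential, sampled on a ±80 mV grid of 33
points around the vertex with multiplicative capacitance noise (default
1%; the closure analyses use 0.2%, the resolution of a good capacitance
bridge, since the vertex precision — not the model — limits parameter
recovery at low concentrations).

What passing tests on these systems do *not* show: real bilayers have
correlated undulations, protrusions and finite-width atom distributions
rather than i.i.d. jitter around planes; real angle distributions need
not be von Mises; real cholesterol kinetics produce time-correlated
cluster evolution, whereas generated frames are exchangeable. The
generator validates the *estimators*, not the physics.

## Problem sizes and numerical defaults

The standard test-bed sizes are 100–200 lipids per leaflet, up to 500
surfactants, 80 cholesterols, and 50–100 frames — large enough that
statistical tolerances (3 SE recovery, mirror symmetry within 3
Monte-Carlo SEs per bin, median parameter errors under 10% across 200
replicates) are meaningful, and small enough that the whole pipeline runs
in seconds. Tie-breaks and degenerate inputs are handled explicitly:
zero-length orientation vectors are skipped, all-zero profiles return
empty peak sets, flat adsorption curves are flagged unidentifiable,
monotone capacitance scans raise range errors, and empty cholesterol
selections return empty cluster lists.
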