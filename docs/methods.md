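# Methods

## Transport model and its assumptions

The engine performs continuous-energy, analog (no variance reduction)
Monte Carlo transport of neutrons and photons on a uniform voxel lattice,
one material per voxel. Free flights are exponential with the local total
macroscopic cross section Σ_t = Σᵢ ρᵢσᵢ,total(E); the flight distance is
resampled at each voxel entry (the exponential is memoryless, so this is
statistically identical to carrying a remaining optical depth and keeps
the random-number stream independent of the cross-section cache state).

The collision kernel is deliberately minimal but exact within its scope:

* **Neutrons** — isotropic-in-CM elastic scattering off stationary targets
  of mass ratio A (E′/E ∈ [α, 1], α = ((A−1)/(A+1))²; lab-frame direction
  rotated consistently), and radiative capture, which terminates the branch
  and may emit one isotropic capture photon that is transported within the
  same history. Inelastic scattering, thermal S(α,β) and free-gas target
  motion are out of scope: below ~0.1 eV neutrons do not thermalize
  realistically. The algorithmic machinery (search, caching, tallying) is
  exercised identically either way; absolute dose values are those of the
  toy physics, not of tissue.
* **Photons** — photoelectric absorption; Compton scattering with the
  scattering cosine drawn from the Klein–Nishina differential cross section
  by rejection (the scoring function is bounded by 2 for every energy, so a
  uniform proposal is exact); pair production above 2mₑc² = 1.022 MeV,
  terminating the photon without annihilation quanta (their transport
  would add no algorithmic coverage). Electrons are never banked; charged
  particles deposit locally through the heating number, which is the
  standard BNCT approximation (the dose is carried by heavy ions, whose
  range is about a cell diameter).

A *history* is a source particle plus all of its secondaries; tally
statistics are formed over histories, so capture photons contribute to
their parent's per-history tally. Histories terminate on escape,
absorption, energy below cutoff (neutron 10⁻⁵ eV, photon 1 keV — the
synthetic grid floors), or a 10⁵-collision safety cap (counted and logged,
never silently truncated).

Every source of randomness in history h of a run with root seed s comes
from the substream `SeedSequence(entropy=s, spawn_key=(h,))`. Histories are
processed in fixed blocks of 1024 and block sums are reduced in block
order, so the output is bit-identical for any worker count. The block size
itself fixes the grouping of floating-point additions and is therefore an
internal constant rather than a configuration knob.

## Dose response and units

Track-length estimation: a segment ℓ (cm) in a voxel of volume V scores
flux φ = ℓ/V (cm⁻²) and dose t = φ·Σᵢρᵢσᵢ(E)Hᵢ(E)/ρ_mass in MeV/g per
source particle. Units: E in eV, σ in barn, ρᵢ in atoms/(barn·cm) — so ρσ
is cm⁻¹ — H in MeV, mass density in g/cm³. ρᵢ is interpreted as *number*
density; that is the only reading under which the response has dose units.
Neutron segments score the full response into the neutron component
(boron included) and the ¹⁰B-only term additionally into the boron
component; photon segments score the photon component.

The heating number Hᵢ(E) is the reaction-weighted mean local deposit per
collision: elastic contributes the mean recoil 2A/(A+1)²·E, capture the
charged-particle Q-value only — the capture photon's energy is *excluded*
from H and carried by the emitted secondary, which avoids double counting;
photoelectric deposits E, Compton the mean Klein–Nishina electron energy,
pair E − 1.022 MeV.

## Synthetic nuclear data

The generator builds pointwise tables on log-spaced grids (2000 nodes;
neutrons 10⁻⁵ eV–20 MeV, photons 1 keV–20 MeV) from three functional
forms: constant, 1/v (σ_ref·√(E_ref/E)), and a log-Gaussian resonance
bump. The default five-nuclide tissue set (H-1, C-12, N-14, O-16, B-10)
uses familiar thermal-capture magnitudes (B-10 3837 b at 0.0253 eV, H-1
0.332 b with a 2.224 MeV capture photon, B-10 depositing 2.31 MeV charged
with a 0.478 MeV photon) over flat elastic channels, with a resonance bump
on O-16 to exercise that form. What the tables emulate is the *structure*
of a real pointwise library — strictly ascending grids, the
total-equals-sum-of-partials rule, nonnegative heating, a thresholded pair
channel — which is everything the transport and search algorithms consume.
What they do not emulate is evaluated physics: resonance ladders, angular
distributions, secondary spectra. Passing tests therefore validate the
algorithms and their equivalences, not dosimetric accuracy for real
tissue.

Interpolation is linear–linear in (E, σ), the dominant convention for
pointwise libraries and exactly testable. Because lin-lin interpolation
commutes with summation, assembling Σ_t from interpolated partials equals
interpolating the stored total to round-off.

One wrinkle: the pair partial is zero at every node below 1.022 MeV, but
lin-lin interpolation between the last zero node and the first positive
node leaks a sliver of pair cross section just below threshold. The
macroscopic assembly clamps the pair channel to zero at and below
threshold (reducing Σ_t accordingly), so the threshold rule holds for
every energy, not just at nodes.

## Energy-interval search

Both lookups share one edge convention — intervals left-closed, a node-exact
energy belongs to the interval starting there, E = E_max maps to the last
interval — so they are exactly interchangeable. The hash table places M
nodes uniform in ln E across exactly the old grid's range (M defaults to
4× the node count, rounded up to a power of two); for each uniform cell it
stores the last old node at or below the cell's lower edge. A lookup maps
E through u = ⌊(ln E − ln E_min)·M/(ln E_max − ln E_min)⌋, clamped to
[0, M−2]. That factor-M map can land one cell right of the cell the table
was built for; a short backward guard absorbs this and any exp/ln
round-off, preserving exact equivalence with bisection on the whole
domain (property-tested over random grids, node-exact and
just-below-node probes). Lookup cost is asserted as comparison counts —
O(1) versus O(log n) — never as wall-clock time, keeping the suite
hardware-independent.

## Lattice conventions

Voxels are half-open in every axis; a particle exactly on a shared face
belongs to the voxel it is entering. During marching, the integer voxel
indices are the source of truth: the next voxel comes from the boundary
crossing itself, never from re-flooring a floating-point position. A
corner-exact crossing (per-axis distances tied within 10⁻¹²·min spacing)
steps every tied axis at once. A history starting outside the lattice is
advanced to its ray-box entry point plus a nudge of 10⁻⁹·min spacing. ROI
masks use voxel-center membership.

## Phantoms

* `homogeneous-slab` — 50×1×1 voxels (1 mm × 10 cm × 10 cm), uniform
  25 ppm tissue; the rig for attenuation oracles.
* `cube-with-tumor` — 24³ voxels of 2.5 mm at scale 1: ICRU-like
  four-component soft tissue (H 10.1 / C 11.1 / N 2.6 / O 76.2 % by mass,
  1 g/cm³) at the clinical blood boron loading of 25 ppm ¹⁰B, a central
  spherical tumor ROI at 75 ppm (radius 15 % of the side), and a one-voxel
  air shell.
* `head-like-ellipsoid` — the clinical grid: 0.75 mm × 0.75 mm × 5 mm
  pitch, 259×289×34 voxels at scale 1, an ellipsoidal head in air with an
  off-axis tumor sphere.

`scale` shrinks voxel counts (pitch preserved) so tests run at desk scale.
Boron is added as a mass-ppm trace without re-normalizing the host
composition — a ≤10⁻⁴ relative effect at BNCT loadings.

## Source model

The clinical beam is modeled as a monodirectional uniform disc with the
grouped spectrum 1 % thermal (< 1 eV), 98 % epithermal (1 eV–0.1 MeV),
1 % fast (> 0.1 MeV, capped at the 20 MeV library ceiling). Within a group
the energy is log-uniform (flat in lethargy) — the conventional neutronics
default when only group fractions are specified. The rotationally
symmetric source type samples its radius from a histogram profile,
uniform in area within a bin, with uniform azimuth about the axis; a
histogram is the least-committal profile given that no functional form is
specified for real beam ports.

## Tally statistics

With per-history tallies tᵢ, mean = Σtᵢ/N and error = √((Σtᵢ²/N −
mean²)/(N−1)); relative errors are reported in percent and defined as 0
where the mean is 0. Fragment mode commits t and t² per segment; history
mode sums a history's fragments per voxel (in a sparse map, since a
history touches few voxels) before squaring. Means agree to ≤10⁻¹²
relative (the difference is float reordering only); the fragment-mode
error is voxelwise ≤ the exact error, with the shortfall growing with
voxel revisits. The paired-mode acceptance test prints the measured
average underestimate as a diagnostic; its magnitude is model-dependent
(it depends on how often histories recross voxels), so it is logged, not
asserted.

The N^(−1/2) error-scaling check runs on the absorber slab, where each
history contributes at most one bounded track per voxel and the variance
estimator is in the central-limit regime from N = 10³. In the scattering
cube the thermal random-walk track lengths are heavy-tailed and the
estimated error converges more slowly at these history counts — a real
property of analog Monte Carlo, not of the implementation.

## Comparison analytics

Gamma uses voxel centers only (no sub-voxel interpolation): with the
clinical 5 mm slice pitch and a 1 mm distance-to-agreement the z direction
reduces to a pure dose test, which this reproduces faithfully. The
inclusion mask (reference dose > 1 % of the reference maximum) is defined
on the reference grid; pass is strictly γ < 1; reported γ values are the
minimum found within 3× the DTA radius (beyond one radius the spatial term
alone already exceeds 1, so pass/fail needs only the inner search). Both
criteria are fractions of the reference maximum, making the pass rate
exactly invariant under rescaling both grids.

DVH curves use the ≥ convention on edges spanning [0, ROI max] plus one
closing edge just above the maximum, so the curve starts at 1, is
nonincreasing, and ends at 0 even for uniform dose. The ROI-mean dose's
relative error combines per-voxel absolute errors in quadrature assuming
independent voxels; for strongly correlated voxel tallies (same histories)
this is an approximation, noted here because no batch statistics are kept.

## Problem sizes

The test and acceptance runs use the cube phantom at scale 0.5 (12³
voxels) with 10³–1.6×10⁴ histories, the 10-voxel absorber slab with 10⁵
histories, and 10⁶ source-energy draws for spectrum checks — sizes chosen
so every check completes in seconds on one core while leaving each
statistical assertion at least ~3σ of resolution.

## Known limitations

No inelastic or thermal scattering, no free-gas motion, no fission, no
variance reduction, no CSG geometry, no electron transport, no
annihilation quanta, no real evaluated data, no biological (RBE/CBE)
weighting. Statistical errors in fragment mode are underestimated by
construction; the exact per-history mode exists precisely to quantify
that. Wall-clock speedups are not asserted anywhere; all efficiency claims
are made through operation counters and the FOM algebra.
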