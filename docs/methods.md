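# Methods

This note records the models, conventions and numerical choices behind
each analysis, what the synthetic generators do and do not emulate, and
the design decisions taken where more than one convention is defensible.
Units are Å, ps and degrees everywhere; correlation times are reported in
ns. Frame ranges are 0-based and half-open.

## System model and roles

Analyses are *name-driven*: a `TopologyRoleMap` declares, per lipid, which
atoms are sn-1 chain carbons (C71..C82, contiguous from C71), sn-2 carbons
(C83..C92), chain hydrogens (each referencing its parent carbon), sugar
ring anchors (C1, C4, C1′, C4′, at most one each) and other headgroup
atoms. Masses are inferred from the element letter of the atom name.
Boxes are orthorhombic; triclinic cells are rejected — the lamellar cells
this package targets are orthorhombic under anisotropic pressure scaling,
and supporting shear would complicate every minimum-image code path for no
use case we have.

All inter-atom displacements use the minimum-image convention (component
range [−L/2, L/2)); intramolecular geometry (torsions, chain vectors, ring
vectors) is computed after unwrapping each lipid along its bonded atom
sequence, so wrapped trajectories are safe input. Torsions follow the
atan2 sign convention used by the major trajectory toolkits (checked
against MDAnalysis in the test suite); trans is +180°.

## Analysis window and block averaging

Production analysis discards the leading fraction of frames (default 20%,
the convention of keeping the last 160 ns of a 200 ns run) and splits the
window into equal blocks — 5 by default for density profiles — dropping a
final partial block. Standard errors are standard deviations of block
means over √(blocks).

## Packing

**Area per lipid** is `Lx·Ly / n_leaflet` per frame. This assumes the
leaflets tile the full xy plane, which holds for lamellar phases.

**Local density profile.** Mass histograms along z (bin 0.5 Å by default)
normalised to amu/Å³ by the slab volume `Lx·Ly·Δz`, accumulated per block
and per component (sugar = ring anchors + headgroup atoms, chain = chain
carbons + hydrogens). The z extent is taken from the first window frame;
the profile conserves the total selected mass per frame exactly (asserted
in tests).

**d-spacing.** The repeat distance is the mean separation of consecutive
maxima of the (periodically continued) sugar-component profile. Peaks are
local maxima of a lightly smoothed profile (3-bin moving average) with
prominence at least 20% of the profile range — the prominence floor keeps
counting noise inside a broad headgroup band from fragmenting one maximum
into several — and are refined by parabolic interpolation through the
three neighbouring bins. Peak-to-peak separation is our convention; a
density profile only defines d up to the choice between peak separation,
profile periodicity, or box-length arguments, and for a double bilayer
whose apposed headgroup sheets merge into one maximum per inter-bilayer
contact, all three coincide at Lz/2.

**RDF.** `g(r) = ⟨ΔN(r, r+δr)⟩/(4π r² δr ρ)` with δr = 0.1 Å, minimum-image
distances, averaged over reference atoms and frames; ρ counts the targets
actually available to a reference (intra-lipid pairs are excluded by
default — a chain-packing RDF compares a carbon with the same carbon on
*neighbouring* lipids; exact zero distances, i.e. the reference itself,
are always dropped). The spherical-shell normalisation is kept even
though chain packing in a lamella is quasi-two-dimensional; a `mode="2d"`
variant (in-plane distances, `2π r δr` shells, area density) is provided
because on a planar slab the 1/r² factor of the 3-D form biases the
apparent first maximum downward by ≈ 2σ²/r for jitter σ. `r_max` may not
exceed half the smallest box length. `first_peak()` reports the maximum
at r ≥ 2 Å; below the physical contact distance a handful of accidental
close pairs (the generator has no excluded volume) would otherwise
dominate after division by a vanishing shell volume.

## Chain conformation

**Rotamer windows.** trans iff |θ| ≥ 120°, gauche± otherwise by sign,
with the 120° boundary counting as trans — the standard three-fold
symmetric alkane split. gauche+ and gauche− are pooled into P(gauche)
(they are reported separately too). A 12-carbon chain has 9 torsions,
labelled C71–C74 … C79–C82 by their first and fourth carbon.

**Tilt.** θ = arccos(v·ẑ) of the chain vector against the *fixed* +z axis
(not an instantaneous fitted normal: the lamellae are built normal to z
and the 0°/180° semantics of tilt assume a fixed reference). Histograms
use 2° bins over [0°, 180°]; peaks are local maxima of the 3-bin moving
average, reported in descending height at bin-centre resolution.

**Protrusion.** A lipid-frame is protruding when its chain angle lies in
[70°, 180°] for a leaflet whose chains point along +z (mirrored for the
others; leaflet orientation is detected from the mean head-to-tail z
displacement). The window is an operational definition: chains at or past
~70° point sideways or back into the headgroup region. The lower edge is
configurable; results for well-separated tilt populations (ordered modes
near 15–25°, flipped modes near 155–165°) are insensitive to it by tens
of degrees.

## Leaflet assignment

Per-lipid headgroup-centre z values (wrap-safe means over the declared
headgroup atoms) are sorted and cut at the three largest gaps; groups are
labelled 1..4 by ascending mean z. Separability requires the smallest cut
gap to exceed both 1.2× the largest and 6× the median intra-cluster gap —
the median term makes the check robust to a single stray lipid; failing
either raises with the suggestion to supply an explicit `leaflet_hint`.
This is deterministic, parameter-free in the count of leaflets, and
permutation-invariant in lipid order.

## Reorientational dynamics

`C2(t) = ⟨P2(μ(t₀)·μ(t₀+t))⟩` uses *all* valid time origins (maximally
overlapping windows) and is then averaged over lipids/vectors; averaging
C2 before fitting (rather than fitting per lipid and averaging τ) is the
convention adopted, with the per-lipid spread propagated into σ_τ. The
implementation expands P2 through the tensor identity
`P2(u·v) = (3 Σᵢⱼ uᵢuⱼ·vᵢvⱼ − 1)/2` and autocorrelates the nine product
series by FFT — exactly the all-origins average, to rounding, verified
against the double-loop definition in the tests.

**Fitting.** `a·exp(−t/τ_fit)` is fitted unweighted to lags before C2
first drops below 0.05 (tail noise dominates beyond); τ is the trapezoidal
integral of the *fitted* curve on the lag grid plus the analytic tail
`a·τ_fit·exp(−t_max/τ_fit)`, and the direct analytic integral `a·τ_fit`
is reported alongside — the two readings of "fit then integrate" agree
for well-sampled decays. σ_τ is the larger of the delta-method fit
uncertainty and the per-vector spread (standard error over up to 32
individually fitted series). A fit whose τ exceeds 100× the time window
is flagged rather than silently returned. Correlation-time profiles
average each carbon's C2 over that carbon's hydrogens and all lipids
before fitting; ring vectors are fitted per mode.

## Synthetic generators

The lamellar generator emulates the study geometry: 4 leaflets of 64
lipids (8×8 square lattice, lattice constant 6.28 Å ⇒ A = 39.4 Ų),
repeat spacing d = 32.2 Å (box height 2d), chains of ideal geometry
(1.53 Å bonds, 111° angles, torsions exactly 180°/±60° plus optional
jitter, built by internal-coordinate chain extension), whole chains
rotated to tilt angles drawn from a configurable mode mixture (default a
single 15° mode, the pre-tilt of the modelled lamellar crystal), and a
rigid five-atom pseudo-disaccharide headgroup spanning ~5 Å along the
layer normal. Headgroup planes sit 2.5 Å either side of each lamellar
interface so the two apposed sugar sheets merge into a single density
maximum per contact — as in an anhydrous stack — while the headgroup
*centres* stay four-modal in z for leaflet clustering (slab jitter sd
0.3 Å, per-atom thermal jitter sd 0.8 Å; larger jitters make leaflets 2
and 3 overlap in z and defeat any z-based clustering). Default gauche
probability is 0.16 per torsion (the maltoside-like chain average; 0.14,
0.20 and 0.40 emulate the cellobioside-like, isomaltoside-like and
branched-fluid disorder levels). Torsions and tilts are resampled
independently every frame: gauche fractions and tilt histograms are
marginal statistics, so persistence is irrelevant to them, and temporal
correlation is exercised separately by the diffusion generators. Every
sampled state is recorded in a `GroundTruth` object sufficient to predict
all downstream estimators without re-simulation; everything is
reproducible bit-for-bit from the seed.

What the generator does **not** emulate: excluded volume (chains of
opposite leaflets interpenetrate freely, so mid-chain RDFs show close
contacts a real system would not), realistic energetics, sugar ring
puckering, solvent, and any temporal correlation within the lamellar
trajectory itself. Passing tests therefore demonstrate estimator
correctness — normalisation, windows, geometry, statistics — not
force-field realism.

**Rotational diffusion.** Each step applies a rotation drawn as a 3-D
Gaussian rotation vector with per-component variance `2 D_r Δt` (uniform
axis, chi-distributed angle), giving `C2(t) = exp(−6 D_r t)` in the
small-step regime; steps with `D_r Δt > 0.1` are refused. Vectors are
renormalised each step (unit to 1e−9). The C–H profile generator freezes
an all-trans backbone and rides each carbon's two hydrogens on
independent diffusion series with that carbon's rate, so each C–H
correlation time has the closed form `1/(6 D_r)`; the three ring vectors
can be driven the same way.

**Hexagonal slab / density stack.** The slab is commensurate with its box
for even side counts (first RDF maximum exactly at the lattice constant
a, six neighbours each); the density stack places headgroup atoms
Gaussian-about planes separated by d with uniform filler slabs between.

## Problem sizes used in the shipped runs

Test and driver runs are sized for a laptop-class single core: lamellar
fixtures of 16–64 lipids per leaflet and 20–500 frames; diffusion
recoveries at 10⁵ steps × 100 vectors for the τ ∈ {1, 10, 45}·10³-step
grid, and 160 ns of 5 ps frames × 512 vectors for the 45/78 ns
literature-scale recoveries; 100 scaled replicates (4000 steps × 16
vectors) for the σ_τ coverage property. These sizes put the statistical
error of each recovery several times below its acceptance margin.

## Known limitations

- Leaflet assignment is z-clustering on one frame; systems with exchanging
  or curved leaflets need an explicit `leaflet_hint`.
- The LDP assumes a (near-)constant box height over the window.
- Single-exponential fits are the only decay model; stretched or
  multi-exponential relaxation will be summarised by an effective τ and a
  larger σ_τ, not resolved.
- `extract_d_spacing` reports the mean peak separation; for profiles whose
  headgroup maxima are not equally spaced the single number hides the
  alternation.
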