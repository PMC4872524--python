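# Methods

This note records the models implemented in `microtrap`, the assumptions
behind them, the parameter choices that matter, and what the synthetic-data
tests do and do not demonstrate.

## Trap-unit geometry

A trapping unit is drawn in 2-D plan view, origin at junction A, x along the
trapping path (Path 1), bypass loop on +y.  Path 1 is five regions in series:
entrance pocket, trapping gap, middle chamber, exit gap, exit pocket.  The
catalogue dimensions specify the gap (width/length), chamber (width/length),
pocket lengths and the bypass width and total length; they do not specify the
pocket widths.  We model the pockets as **linear tapers from the chamber
width down to the gap width** over the tabulated pocket lengths — the funnel
shape seen in device schematics, and the only choice that introduces no free
parameter.  Channel cross-sections are treated as rectangular throughout; the
fabricated devices have rounded profiles at the valve seat (a resist-reflow
artefact needed for valve sealing), which we do not model.

The bypass is drawn as a rectangular U whose arms attach immediately up- and
downstream of the two junctions, with arm length chosen so the centreline
length equals the tabulated bypass length.  Both catalogue designs then yield
the same arm length (325 μm), which supports this reconstruction.  The loop
shape only affects the field solver mildly (corner cutting shortens the
effective bypass by ~6 %); the resistance network depends on length and
cross-section alone.

The valve footprint is the overlap of a 40 μm wide control channel with the
middle chamber, centred on it, spanning the full chamber width.  "Valve on"
removes these cells from the fluid mask (binary closure); partial closure can
be represented in the network model only, as a resistance multiplier.

Rasterization is cell-centred with half-open extents.  Finite particle size
is handled by **erosion of the fluid mask by the particle radius** (disk
structuring element; inlet and outlet columns are treated as open boundaries,
not walls).  A gap narrower than the particle diameter therefore becomes
impassable to particle centres, while remaining open to fluid — matching the
physical trapping mechanism.  Resolved particle–wall hydrodynamics is out of
scope.

## Resistance network

Per-segment resistance uses the rectangular-duct law R = fRe·L·η/(2·Dh²·A)
with the Shah–London fifth-order polynomial for fRe(α), α = min(W,H)/max(W,H).
Tapered segments integrate the local straight-duct resistance density along
the length by composite Simpson quadrature (64 intervals; a degenerate taper
reproduces the straight closed form to 10⁻¹⁰ relative).  Junction and minor
losses at the two junctions are neglected, as appropriate at Re ~ 10⁻³
(Re = ρūDh/η ≈ 1.9·10⁻³ at 100 μm/s in the main channel).  Flow is split
between the two paths as parallel resistors (Δp₁ = Δp₂, Q₁/Q₂ = R₂/R₁); an
occupied trap or closed valve zeroes Q₁ entirely ("total plug" idealization;
a partial-plug multiplier is available for sensitivity studies).  A
`lump_pockets` option replaces each pocket+gap pair by a single gap-width
segment of the combined length, bracketing the taper assumption from the
resistive side.

Measured ratios (water, any drive — the ratio is geometry-only):
design 1 Q₂/Q₁ = 0.639 at H = 15 μm, 1.014 at H = 25 μm; design 2 0.667 and
0.900.  Design 1 at 25 μm height violates the Q₂/Q₁ < 1 rule under this
model, which is why the transmission study below uses H = 15 μm: the
reference 3-D simulation demonstrates a working trap (62 % trap-path
transmission, consistent with this network's 61 % flux fraction at H = 15),
and the cell experiments used the 5 μm-gap device at 15 μm height.

Units are SI internally; geometry is specified in μm and flow drives in μl/h
or mean inlet velocity (Q = ū·A over the main-channel cross-section).

## Depth-averaged flow solver

A full 3-D finite-element simulation is replaced by the
**depth-averaged Brinkman equation**

    −η ∇²ū + (12η/H²) ū + ∇p = 0,    ∇·ū = 0,

i.e. Hele-Shaw out-of-plane drag plus the in-plane viscous term with no-slip
sidewalls.  The in-plane term matters here: the trapping gap is narrower than
the channel depth, so sidewall drag dominates its resistance — a pure
Hele-Shaw (Darcy) solve misestimates the gap resistance by a factor ≈ 4 and
with it the whole flow split.  With the Brinkman form, straight-segment
resistances agree with the 1-D Brinkman closed form to ≤ 2 % and with the
Shah–London duct network to ≤ 11 % over the aspect ratios present.

Discretization: MAC staggered grid on the fluid mask; uniform-flux (plug)
inlet at the stated mean velocity, zero-pressure outlet, no-slip walls via
ghost velocities (first-order wall placement).  The saddle-point system is
solved by sparse LU factorization; continuity holds to machine precision
(relative residual ~10⁻¹²), and inlet/outlet flux balance is enforced to
10⁻⁶.  At dx = 0.5 μm the design-1 unit has ≈ 10⁵ fluid cells and solves in
a few seconds in ≲ 1 GB.

**Known model discrepancy.**  The 2-D gate-flux ratio Q₂/Q₁ for design 1
(H = 15) is 0.908 vs the network's 0.639, i.e. the flux fraction entering
the trap path is 52.4 % vs 61.0 %.  The excess Path-1 resistance is junction
dissipation: in the Brinkman model disturbances decay over the screening
length H/√12 ≈ 4.3 μm, so the jets at the gap mouths and the contractions at
the pocket throats dissipate over several micrometres — comparable to the
5 μm gap itself.  In the true 3-D Stokes flow these adjustment zones are
shorter, so the 2-D model systematically under-predicts the trap-path
fraction by ~8 percentage points for this geometry.  The discrepancy is
converged under grid refinement (ratio 0.872 at dx = 1.0, 0.908 at 0.5,
~0.92 extrapolated) and is reported as-is.

With the valve sealed, the trapping path is a dead-end stub; the only
remaining flow inside it is a shear-driven eddy entering at the stub mouth
and decaying like exp(−x/ℓ) with ℓ = H/√12.  Net through-flux across the gap
is zero to machine precision; the residual eddy speed is probed in the
**gap throat** (the middle half of each gap segment — the end cells adjoin
the junction transition zones), where it is ≈ 4.6·10⁻⁴ of the mean inlet
velocity.

## Particle tracing

Tracers are massless (Stokes number ≪ 1 at Re ~ 10⁻³; 10 μm polystyrene at
1050 kg/m³ has a relaxation time of microseconds against transit times of
seconds) and advected by classic RK4 with a per-particle adaptive step
bounded by a CFL-like displacement limit.  Particle centres are confined to
the eroded mask; a step that would leave it is retried at half length and
then projected tangentially along the wall using the distance-transform
gradient, so grazing trajectories slide around corners instead of pinning.
A particle is `stuck` when it stops progressing (e.g. seeded exactly on the
dividing streamline, it ends at the junction-corner stagnation point).

The flow field is solved on the **full** fluid mask even when tracing
finite-size particles: fluid passes the gap that the particle cannot.  (An
eroded-mask solve would make the trapping path a dead end and force a zero
trap fraction, contradicting the reference study, whose virtual tracers pass
through the mechanical trap.)

Fates are assigned at gate crossings: the Path-1 gate is a transverse cut
just inside the entrance pocket (at 20 % of the pocket length — far enough
in to be unambiguous, shallow enough to remain reachable after erosion by
realistic particle radii), the bypass gate a cut across the first loop arm.
Uniform seeding places particles at equal spacing across the eroded inlet
opening (the reference protocol); flux-weighted seeding samples the inlet
velocity profile, making the trap fraction a direct Monte-Carlo estimate of
the gate-flux split — the two agree to within binomial error at n = 10⁴.

Reference-scale result (design 1, H = 15 μm, dx = 0.5 μm, 100 μm/s, 100
uniformly seeded 10 μm tracers): 52 % trap path, 47 % bypass, 1 stuck, vs
the reference 62 %/38 %; with the valve sealed, 100 % bypass.  The ±10-point
shortfall is the junction-dissipation artefact discussed above.

## Array simulation

Event-based and replayable.  Routing at each unit: occupied or valve-closed
units always bypass; otherwise deterministic routing follows the larger
branch flow and stochastic routing draws trap with probability Q₁/(Q₁+Q₂)
(the flux-weighted streamline fraction, consistent with the transport
module).  Occupied-trap blocking is total, matching the design intent; the
inter-unit main-channel resistance is neglected (not quantified in the
source material).  Release closes a valve, pops the held particle into the
main flow and re-routes it downstream; `guard_downstream` treats empty
downstream traps as sealed for the passage, which is what makes release
order irrelevant (verified exhaustively over all 120 orders on a 5-unit
array).

The occupancy classifier encodes the observed bead-trapping regimes: a
particle no larger than the gap passes through; width or height ≥ 2× the
particle admits side-by-side or stacked pairs; a particle ≥ 0.8× the
narrowest bore dimension risks clogging (0.8 is a chosen heuristic constant,
exposed as a parameter — the source observations are qualitative).  Trap
capacity is derived from the flags (1, 2 or 4).  The classifier is
qualitative context; it does not predict wet-lab efficiency percentages.

## PALM synthetic data and estimators

The generator emulates a PALM acquisition of centromere-like foci: 8
clusters of 200 nm diameter (uniform disks), 50 emitters each, 5000 frames,
placed ≥ 600 nm apart in a 4×4 μm field of view.  Photophysics is a per-
emitter two-state Markov chain: fresh activation with probability 0.002 per
frame, plus on-state persistence 0.6 (mean on-run ≈ 2.5 frames) — chosen to
give ~2 active emitters per frame and ~6·10³ same-emitter adjacent-frame
pairs over the acquisition, the sparse-activation regime PALM operates in.
Persistence is what makes nearest-neighbour precision estimation possible at
all: with memoryless blinking, same-emitter adjacent-frame pairs would be
rare compared with intra-cluster false pairs.  Localizations add isotropic
Gaussian error σ_true (default 12 nm); false localizations arrive uniformly
at 0.01 μm⁻² per frame.  The generator does **not** model PSF fitting,
drift, photon-count-dependent precision, emitter re-activation statistics
beyond the two-state chain, or 3-D effects — so estimator tests demonstrate
statistical correctness of the analysis, not robustness to real-data
artefacts.

`nn_precision` pairs each localization with its nearest neighbour in the
following frame within 100 nm (default chosen to keep false-pair
contamination low at the default density), bins the distances (2 nm bins)
and fits A·(r/s²)exp(−r²/2s²) + B·r — Rayleigh for same-emitter pairs (the
displacement of two independent Gaussian localizations has scale √2·σ_loc)
plus a linear false-pair background.  σ_loc = s/√2, with a bootstrap
percentile CI.  Across σ_true ∈ {5, 12, 20} nm the estimator is biased by
≲ 3 % (nearest-neighbour selection slightly favours short distances) with
95 %-CI coverage ≥ 80 % over 20 replicates.

`cluster_centromeres` links localizations within 50 nm and keeps connected
components with ≥ 10 members.  The diameter estimate is 2√2 × RMS distance
to the centroid — exactly the full width for a uniform disk — with the
localization error removed in quadrature (σ_loc² per coordinate).  On the
default synthetic data all 8 planted 200 nm clusters are recovered with
diameters within 15 %.  "Cluster size" for real, non-disk structures depends
on this convention.

`render_map` is a 2-D histogram at a chosen pixel size with an optional
Gaussian blur (the image is padded before blurring so total intensity is
conserved).

## Problem sizes and determinism

Default study sizes: dx = 0.5 μm for the transmission study (10 cells across
the 5 μm gap; dx = 1.0 μm for quick looks), 100 tracers for transmission
fractions, 10⁴ for the flux-weighted consistency check, 5000-frame PALM
acquisitions.  Field solves and uniform-seeded tracing are fully
deterministic; random seeds control flux-weighted seeding, stochastic array
routing and the PALM generator/bootstrap.

## Known limitations

- Depth-averaged junction dissipation under-predicts the trap-path fraction
  by ~8 points for the catalogue geometry (quantified above).
- Rectangular cross-sections throughout; the reflowed (rounded) profiles of
  the fabricated device are not represented.
- Valve mechanics (membrane deflection, partial closure, the ejection
  impulse it imparts) are reduced to a binary mask change.
- Bead–wall contact is a kinematic slide of the bead centre along the eroded
  boundary; lubrication and contact forces are not modelled, so fates of
  particles seeded within ~1 seed-spacing of the dividing streamline are
  model-dependent.
- The array model ignores inter-unit channel resistance and hydrodynamic
  interactions between suspended particles.
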