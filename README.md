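# microtrap

Design and simulation toolkit for **valve-controlled hydrodynamic single-cell
trap arrays**, with a companion module for **single-molecule localization
microscopy (PALM) analysis** of the cells such devices are built to image.

Microfluidic trap arrays immobilize single cells in mechanical pockets using
nothing but flow: each trapping unit offers two parallel routes between
junctions A and B — a short, straight trapping path (Path 1: a funnel-shaped
pocket, a narrow trapping gap, a middle chamber, and their mirror images) and
a long bypass loop (Path 2).  A pneumatic valve over the middle chamber can
seal Path 1 on demand, which both prevents trapping and ejects an already
captured cell — so traps can be loaded and emptied selectively, in any order.
Long-term immobilization is what makes super-resolution imaging of live cells
practical, and PALM data from such trapped cells is the second half of this
package's scope.

## The models

**Resistance network (`microtrap.hydraulics`).**  For fully developed laminar
flow in a rectangular duct,

    Δp = fRe · L · ū · η / (2 Dh²),      Dh = 4A/P,

where *fRe* is the Shah–London constant of the duct aspect ratio
(96 → 56.91 from parallel plates to a square duct).  Each channel segment is a
hydraulic resistor R = Δp/Q; Path 1 (five resistors in series, tapers
integrated by quadrature) competes with the bypass in parallel, Δp₁ = Δp₂.
The design rule for a working trap is **Q₂/Q₁ < 1**: more flow must pass
through the empty trap than around it.  Both catalogue designs (5 μm gap /
25 μm channels, and 3 μm gap / 15 μm channels, from the device dimension
catalogue) satisfy it at 15 μm channel height.

**Depth-averaged flow + particle tracing (`microtrap.transport`).**  The 3-D
creeping flow is reduced to the 2-D Brinkman equation
−η∇²ū + (12η/H²)ū + ∇p = 0, ∇·ū = 0 (Hele-Shaw drag plus in-plane viscosity
with no-slip sidewalls), solved on a rasterized trap unit with a MAC
staggered-grid sparse direct solve.  Massless tracers advected through the
field yield the **trap/bypass transmission probabilities**; sealing the valve
reroutes 100 % of particles to the bypass.

**Array logic (`microtrap.arraysim`)** simulates sequential filling,
valve-scheduled release and re-trapping over many units, plus a
particle-size/channel-dimension occupancy classifier (single, stacked pairs,
side-by-side pairs, gap pass-through, blockage risk).

**PALM analysis (`microtrap.palm`)** generates synthetic localization tables
(clustered emitters, Markov on/off photophysics, Gaussian localization error)
and estimates the localization precision by nearest-neighbour analysis —
adjacent-frame pair distances follow a Rayleigh law of scale √2·σ_loc — and
finds centromere-like clusters with a density-based search, reporting
error-deconvolved diameters.

## Worked example

Check the design rule for the 5 μm-gap device at 15 μm height:

```text
$ microtrap design-check --design 1 --height 15 --flow 20ul/h
    region  W_um  L_um  Dh_um   fRe  R_Pa_s_per_m3  dp_Pa
 pocket_in    15    10     15 56.92      1.229e+13  41.66
    gap_in     5     5    7.5 68.38      4.052e+13  137.3
   chamber    25    50  18.75 59.94      1.137e+13  38.52
   gap_out     5     5    7.5 68.38      4.052e+13  137.3
pocket_out    15    10     15 56.92      1.229e+13  41.66
    bypass    25   805  18.75 59.94       1.83e+14  396.5

Q2/Q1 = 0.6393  ->  criterion PASSED (need < 1)
```

The per-region table lists the mean width and length, hydraulic diameter,
fRe, resistance and pressure drop at 20 μl/h; the ratio 0.64 < 1 means 61 %
of the flow threads the empty trap, so an arriving cell is pulled in.

Trace 100 tracers through the solved flow field (valve open), then simulate
and analyse a synthetic PALM acquisition:

```text
$ microtrap trace --design 1 --height 15 --valve off --n 100 --dx 0.5 --seed 7
{ "n": 100, "counts": {"trap": 52, "bypass": 47, "outlet": 0, "stuck": 1}, ... }
gate fluxes: Q1/(Q1+Q2) = 0.5241, Q2/Q1 = 0.9079

$ microtrap palm-sim --clusters 8 --sigma 12 --frames 5000 --seed 7 -o locs.csv
wrote 10824 localizations to locs.csv
$ microtrap palm-precision locs.csv
localization precision: 11.9 nm (95% CI 11.8-12.1 nm, 6676 pairs)
$ microtrap palm-clusters locs.csv --radius 50 --min-points 10 --sigma-loc 12
8 clusters, mean diameter 198 nm
```

52 % of the tracers enter the trapping path (62 % in the reference 3-D
finite-element study; the 2-D depth-averaged model dissipates extra energy at
the gap junctions — see `docs/methods.md`).  The precision estimator recovers
the simulated 12 nm localization error, and the cluster finder recovers all
eight planted 200 nm centromere-like clusters.

With `--valve on`, every tracer reports to the bypass (`p_bypass = 1.0`) and
the residual speed in the trapping-gap throat is below 10⁻³ of the inlet mean
— the basis of valve-controlled release.

## Layout

```
src/microtrap/
  geometry.py    trap-unit geometry, catalogue presets, rasterization
  hydraulics.py  duct resistance network, Q2/Q1 criterion
  transport.py   Brinkman flow solver, particle tracing, gate fluxes
  arraysim.py    array fill / release / re-trap simulation, fit classifier
  palm.py        synthetic localizations, NN precision, cluster finder
  cli.py         `microtrap` command-line interface
docs/methods.md  model assumptions, parameter choices, limitations
```
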