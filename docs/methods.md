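# Methods

## Scope and model

`hemowss` post-processes time-resolved wall-shear-stress (WSS) vector
fields on triangulated vessel surfaces into the standard cycle-averaged
hemodynamic indicators (TAWSS, OSI, RRT, TransWSS, OSItr), classifies
low/normal/high WSS zones, quantifies branch take-off morphometry, and
keeps outlet flow-split and inflow Reynolds bookkeeping. It does not solve
the 3-D Navier–Stokes equations: spatially resolved fields from
patient-specific CFD are *inputs*. The one flow model the package does
solve — pulsatile Newtonian flow in a rigid straight tube (Womersley
flow) — is the exact unsteady reduction of the incompressible
Navier–Stokes equations for a unidirectional axial profile, where the
convective term vanishes identically and continuity holds by
construction. It serves two roles: a physically valid generator of WSS
time signals, and (via an independent finite-difference discretisation)
a numerical cross-check of the closed form.

## Units and data model

Coordinates are millimetres, stresses pascals, times seconds; every
output file records these units. A `SurfaceMesh` carries node
coordinates, triangle connectivity, and outward unit normals; a
`WssSeries` carries strictly increasing sample times within `[0, T)`, the
period `T`, and one WSS vector per node per sample, interpreted
periodically. WSS is tangential by definition but discrete CFD exports
violate tangency by discretisation noise, so tangency is enforced at load
time by projecting each vector onto the local tangent plane
(`v − (v·n)n`) rather than by rejecting the file.

## Cycle integration

All cycle integrals use the periodic trapezoidal rule: trapezoids between
consecutive samples plus an explicit wrap-around segment from the last
sample back to the first, one period later. This closes the cycle exactly,
handles non-uniform analysis grids (clinically marked instants are rarely
equispaced), and reduces to `mean(f)·T` on uniform grids. For smooth
integrands the rule is second-order; the suite measures the observed
order ≥ 1.9 on Womersley-driven series sampled on a deliberately
non-uniform grid (uniform sampling of a band-limited integrand would be
integrated exactly and show no error to measure).

## Indicator definitions and degeneracies

- `TAWSS = (1/T)∮|WSS|dt`; `OSI = 0.5(1 − |∮WSS dt|/∮|WSS|dt)`;
  `TransWSS = (1/T)∮|WSS·(n×ê_m)|dt` with `ê_m` the unit cycle-mean WSS
  vector and `n` the outward wall normal (the cross product needs the
  wall normal to be meaningful); `OSItr = TransWSS/TAWSS`;
  `RRT = k/((1−2·OSI)·TAWSS)`.
- RRT is only defined up to proportionality. The default is `k = 1` (bare
  reciprocal). Published tables sometimes carry an unstated
  normalisation; `calibrate_rrt_constant` recovers `k` from one reference
  row (`k = RRT·(1−2·OSI)·TAWSS`), after which the other rows of an
  internally consistent table reproduce at their printed precision. On
  the four-row tear table used in the acceptance suite the row-implied
  constants agree to a coefficient of variation of ≈ 2 % (a max–min
  spread would be larger only because one printed RRT value has a single
  significant digit).
- Degenerate nodes are flagged invalid, never returned as infinities:
  zero cycle-mean magnitude invalidates OSI; `OSI ≥ 0.5 − 1e−9` or zero
  TAWSS invalidates RRT; a vanishing cycle-mean *vector* invalidates
  TransWSS/OSItr. "Vanishing" is relative — `|∮WSS dt|` below `1e−12`
  of `∮|WSS|dt` — because a perfectly symmetric oscillation sums to
  machine epsilon, not zero.
- Zone thresholds are strict: TAWSS below 0.4 Pa is low, above 5 Pa is
  high, and boundary values are normal.
- The washing-direction metric operationalises the qualitative
  distinction between axial washing and circumferential flushing by an
  impinging jet: the angle `arccos(|ê_m·â|) ∈ [0°, 90°]` between the
  cycle-mean WSS direction and the local axial direction, labelled
  *circumferential* above a 45° threshold (the boundary itself counts as
  axial, with a 1e−9-degree guard against round-off). There is no
  community-standard formula for this; the construction is this package's
  choice and is flagged as such in the API docs.

## Womersley module

The pressure-gradient forcing is a complex Fourier series
`G(t) = Re Σ C_k e^{ikωt}`; calculations stay complex throughout and take
the real part only at output, avoiding phase bookkeeping errors. The
wall shear of harmonic `k` simplifies to
`Re[C_k R J₁(Λ_k)/(Λ_k J₀(Λ_k)) e^{ikωt}]` with `Λ_k = i^{3/2}α_k`, which
limits to the quasi-steady `C_k R/2` as `α_k → 0`.

The finite-difference oracle is Crank–Nicolson on the radial diffusion
equation with the axisymmetric Laplacian, symmetry at the axis (L'Hôpital
form `4(u₁−u₀)/Δr²`), no-slip at the wall, and a one-sided second-order
wall-gradient stencil for WSS. It marches from rest for 5 cycles by
default and reports the cycle-to-cycle L₂ change as a periodicity
diagnostic. The start-up transient decays per cycle by
`exp(−2π j₀₁²/α₁²)` (j₀₁ ≈ 2.405), so at aortic Womersley numbers
(α₁ ≈ 25) it persists for many tens of cycles; validation against the
closed form is therefore run at α₁ ≈ 3–5 (2 mm tube at 0.8 s period),
where 5–8 cycles reduce the transient below the comparison tolerances.
This is a property of the physics, not of the scheme, and the analytic
solution is exact at every α.

## Inflow waveform and flow scale

The inflow is a cross-section mean velocity (not a volumetric flow; the
two are convertible through the inlet area, but one convention had to be
fixed because Reynolds bookkeeping uses a mean velocity directly). The
built-in aortic-like template — a Gaussian systolic bump centred at `T/4`
(width `T/10`) over a 0.12-relative diastolic baseline, band-limited to
10 harmonics — is synthesised once, deterministically, and rescaled so
its cycle mean hits the target. The default target mean, 0.11354 m/s, is
the value that closes `Re = ρUD/μ = 1090` for the 32 mm inlet diameter
and blood properties ρ = 1050 kg/m³, μ = 3.5×10⁻³ kg/m·s. The default
period is 0.8 s — chosen so the four named analysis instants
(T1 = 0.11 s … T4 = 0.58 s, early systole through early diastole) fit
inside one cycle — and is configurable, as is the waveform itself via
spec files.

## Morphometrics

Branch angle α is the elevation of the branch axis above the wall
tangent plane (`90° − angle(axis, normal)`); β is the angle to a
reference axis supplied by the caller — either the main-vessel
centerline tangent or a global vertical axis. The two references
genuinely differ for a curved vessel and published tables do not always
say which was used, so `BranchGeometry` makes the reference explicit
rather than guessing. Both angles are reported folded into `[0°, 90°]`
since orientation signs are conventionally undefined. Hydraulic diameter
is `4·area/perimeter` with shoelace area on the best-fit section plane
(bit-reproducible, no meshing dependence); branch calibre is the mean
equivalent-area diameter `2√(area/π)`. Centerline frames use centered
finite differences for tangents and parallel transport for the
transverse pair, which avoids frame flips along curved vessels at the
cost of path dependence (irrelevant for a single traversal).

## Outlet splits

Fractions are stored per vessel; bilateral entries count twice in the
closure check. This convention is forced by arithmetic: for the
reference split (carotids 6.48 %, subclavians 18.15 %, mammaries 8.73 %,
each bilateral), only `2·(6.48+18.15+8.73) + 33.28 = 100` closes the
mass balance. `complete_split` resolves exactly one unknown outlet from
the remainder and `outlet_flows` conserves the inlet flow to rounding.

## Synthetic data: what it emulates and what it does not

The generators produce structured tube and branched-tube meshes with
exactly radial normals, Womersley WSS series (spatially uniform, exactly
tangent), inverse-designed oscillation fields, and jet-impingement
patterns. Geodesic distances on tubes use the unrolled
(axial, arc-length) chart, exact for a cylinder. Specific choices:

- `prescribed_osi_field` uses a two-sample, two-phase construction
  (`+2τ(1−s)·ê` then `−2τs·ê` for equal half-cycles): under the periodic
  trapezoidal rule its OSI equals the target `s` and its TAWSS the scale
  `τ` to machine precision, for every `s ∈ [0, 0.5]`.
- `jet_impingement_field` decays magnitude as a Gaussian of geodesic
  distance, radiates directions from the impingement point in the chart
  with a 4× axial or circumferential bias, and modulates the whole
  pattern by the inflow waveform normalised to unit mean — so cycle-mean
  magnitudes equal the spatial pattern and the field ties back to the
  inflow drive. It is phenomenological: it reproduces the *pattern* a
  jet leaves on the wall (a connected high-WSS zone, circumferential
  washing on the impingement ring), not jet physics.
- `make_branched_tube` realises a requested (α, β) pair exactly by
  tilting the main tube from the vertical reference by α+β in one plane.
  Pairs with α > β are impossible when β is measured against an axis
  lying in the tangent plane (the minimum achievable angle is α), which
  is precisely why the β reference is kept independent; with the
  vertical reference every pair in `(0°, 90°]²` is realisable. The
  returned `BranchGeometry` is exact ground truth; recovery from the
  meshed geometry (computed normals, stub ring centroids) is accurate to
  well under a degree at the default resolutions.

Passing tests on these fields demonstrates the correctness of the
indicator arithmetic, integration, classification, and recovery logic.
They do not demonstrate robustness to real CFD exports' spatial
inhomogeneity, mesh irregularity, or measurement noise beyond the
tangency projection.

## Numerical and I/O choices

- Area-weighted node normals on an analytic cylinder reproduce the exact
  radial normals to machine precision at interior nodes; one-sided
  triangle stars at the open ends tilt the average circumferentially by
  O(Δθ), so generated meshes carry exact analytic normals and the
  recomputation invariant is asserted on interior nodes.
- Probing defaults to barycentric interpolation in the nearest triangle
  with a 2 mm off-surface fallback to the nearest node (wall "projection
  zones" are physical locations, not mesh nodes); both modes are exposed
  because published point values may be either point samples or
  small-area averages.
- The exchange format is an npz archive (`nodes, triangles, normals,
  times, period, wss`); legacy ASCII VTK polydata (POINTS/POLYGONS/
  POINT_DATA) is read and written for interoperability with
  visualisation tools, with per-file `TIME`/`PERIOD` field data.
- Report CSVs use `.` decimals and 6 significant digits; reruns with the
  same configuration are byte-identical, and each run log records a
  configuration hash.

## Problem sizes

Default test and acceptance workloads are deliberately desk-scale:
tubes of a few hundred to a few thousand nodes, 2–100 samples per cycle,
finite-difference grids up to 200 radial points × 2000 steps × 5 cycles,
and 1000-series random sweeps. These sizes keep every check exact or
statistically stable while running the whole suite in seconds.

## Known limitations

- No 3-D flow solution, no elastic walls, no non-Newtonian rheology.
- The jet generator is phenomenological (see above).
- The exact-normal and chart-geodesic shortcuts apply to generated
  tubes; arbitrary imported meshes fall back to area-weighted normals
  and Euclidean probing.
- RRT's proportionality constant is user-supplied or calibrated; the
  package takes no position on any particular table's normalisation.
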