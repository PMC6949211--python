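# Methods

This note records the models implemented by `airwayloss`, the conventions
and defaults chosen where several were defensible, and what the synthetic
datasets do and do not establish about real airway data.

## Lumen morphometrics

A lumen is described by a triangulated, watertight surface mesh (mm) and
an ordered centerline polyline. The centerline is resampled to uniform
arclength spacing (default 1 mm, comparable to the finest clinical slice
thickness) by linear interpolation; slicing frames use central-difference
tangents (one-sided at the ends) — a simple frame that is adequate for the
gently curving, branch-free conduits this package targets. Each plane/mesh
intersection may contain several closed loops near branches or folded
anatomy; only the loop whose centroid lies nearest the centerline point is
kept. Area is the planar polygon area of the in-plane projection
(`shapely`), perimeter the loop length, hydraulic diameter 4A/P. On a
faceted cylinder the sliced area converges to πr² at second order in the
facet edge length (inscribed-polygon bias), which bounds the discretisation
error of all mesh-derived areas.

Profiles are reported on a signed station axis x = s − s_carina so the
carina sits at x = 0 and superior stations are negative. The constriction
ratio is (A_ref − A_min)/A_ref with A_ref linearly interpolated at a
user-named reference station (anatomically, the first tracheal ring; a
mesh cannot identify it, so it is a required input). A_ref may instead be
supplied directly, e.g. when the reference plane was measured on another
scan of the same subject; only then can the ratio be negative (lumen wider
than the reference), which is flagged rather than rejected. The
constricted length is the contiguous run containing the minimum where
A ≤ (1 − threshold)·A_ref (threshold 0.35 by default), with endpoints
located by linear interpolation in x. Local minima of a profile are found
on equal-value runs, so a flat-bottomed dip counts once and is reported at
the midpoint of the flat.

## Plane-sampled flow fields and reductions

Flow data are time-resolved samples on centerline-normal planes: point
positions (mm), velocity (m/s), static pressure (Pa). Quadrature weights
come from a Delaunay triangulation of the in-plane points (one third of
each incident triangle's area per vertex), rescaled to sum exactly to the
section area; since sample rings are co-circular the triangulation is not
unique, but any of its realisations integrates smooth fields to the same
order. Geometric quantities stay in mm/mm² so that plane integrals of
velocity are directly in mL/s (1 mm²·m/s = 1 mL/s); energy fluxes carry a
single 10⁻⁶ factor to watts.

Time averaging is the arithmetic mean over snapshots at t ≥ a discard
window (default 0.05 s) that removes start-up transients. The fluctuation
RMS is the pointwise RMS of |u − ū|, i.e. of the fluctuation-vector
magnitude; published work does not always state whether turbulence
intensity uses vector-magnitude or per-component RMS, so the convention is
fixed here and documented: TI = ⟨RMS|u′|⟩_area / u_ref, with u_ref the
bulk velocity at a user-named reference plane (by default the first-ring
plane).

## Energy flux, cumulative loss, resistance

For a rigid duct with steady inflow, time averaging removes the unsteady
kinetic-energy term of the mechanical-energy balance, and the accumulated
dissipation between the inlet plane and station x is the difference of
mean energy fluxes — no pointwise dissipation field is required. Boundary
shear work is neglected (rigid, no-slip walls). Two flux conventions are
implemented: `mean_field` (integral of the product of time-averaged total
pressure and time-averaged normal velocity — the practical choice when
only mean fields are stored) and `full_average` (time mean of instantaneous
integrals). They coincide on steady fields; their difference on
fluctuating fields is the turbulent transport term, exposed via
`turbulent_transport_flux` rather than silently absorbed. `cumulative_loss`
requires plane flowrates to agree within 1% (mass conservation) before
differencing fluxes.

The resistance profile uses the area-weighted mean of the time-mean
**total** pressure: R(x) = (⟨P_tot⟩_inlet − ⟨P_tot⟩_x)/Q. Whether static or
total pressure should be area-averaged is a genuine convention choice;
total pressure is the default because it makes R(inlet) = 0 exactly and
the overall R equal ΔP/Q, and both are computable from the same fields.
Area averaging across an expanding lumen can make R appear to overshoot
downstream of a constriction; this is a property of the averaging, not of
the flow, and is left visible.

## Orifice power law

ΔP = ½ ρ K (Q/A_C)ⁿ with A_C the throat area. With n fixed (the usual
n = 2), K is fitted by relative-error least squares — minimising
Σ(pred/obs − 1)² — because fit quality for such tables is quoted as a
percentage error across flowrates; the estimator is closed-form
(K = Σr/Σr², r = c/ΔP, c = ½ρ(Q/A_C)ⁿ). With n free, an ordinary
least-squares line in log ΔP vs log Q gives (n, K). Loss tables never
state the air density they assume, and ρ and K enter only as a product, so
every fit also reports K·ρ; the default ρ = 1.2 kg·m⁻³ (air at ~20 °C) is
configurable and logged. The engineering reference coefficient K = 1.2 for
idealized tracheal stenoses (Brouns et al.) is stored as a named constant.
Resistance scaling follows the published convention of applying the full
exponent to R = ΔP/Q — i.e. R·(Q₂/Q₁)² — even though the power law itself
implies R ∝ Q^(n−1); the function takes the exponent explicitly so either
convention is available. Unit conversion uses 1 cmH₂O = 98.0665 Pa.

## Synthetic airway and flow generator

The generator emulates the study conditions rather than any convenient
regime. The default lumen is an elliptical tube (minor/major ratio 0.8,
equivalent radius 6.1 mm ⇒ base area ≈ 117 mm², the first-ring area of the
most constricted scan), body length 110 mm with 35 mm straight extrusions
at each end (≈3 hydraulic diameters, as used to extend imaged geometry),
and a Gaussian *area* dip of depth 0.825 and σ = 12.5 mm — reproducing the
82.5% constriction ratio and ≈33 mm constricted length of the severe
pre-operative state. The area law A(x) = A₀(1 − c·exp(−(x−x₀)²/2σ²)) is
exact by construction (the radii scale with √ of the area factor), which
gives closed-form oracles: minimum area (1−c)A₀ and 35%-reduction length
2σ√(2·ln(c/0.35)). Meshes are generated deterministically (no RNG) and
watertight; at the default 1 mm edge length mesh-derived areas agree with
the analytic law to ≈0.4%.

Flow fields are plug, parabolic (exact laminar ellipse solution,
u = 2U(1−t²) on scaled boundary rings), or top-hat orifice-jet profiles
scaled to a prescribed bulk flowrate (default 392 mL/s = 23.5 L/min, the
study's steady inspiration). Fluctuations are zero-mean white noise in
time and space with prescribed fluctuation-vector RMS (default 5% of
bulk), seeded; white noise cannot reproduce the spectra or coherent
structures of real laryngeal turbulence — it exists to exercise the
averaging, RMS, and turbulence-intensity operators, not to model jets.
Snapshots default to 40 at dt = 5 ms (0.2 s of signal, first 0.05 s
discarded, mirroring the averaging protocol of the source simulations).

The orifice dataset imposes constant total pressure upstream of the throat
(loss-free Bernoulli: static pressure falls as the area contracts) and an
irreversible total-pressure drop of ½ρK_true(Q/A_C)^n_true distributed as
a smoothstep over a mixing length downstream (default 5 hydraulic
diameters, mimicking the gradual energy-flux decline of a breaking-up
jet). Velocities are plug in this dataset so the plane-averaged and
flux-averaged total pressures coincide and the injected loss is recovered
exactly up to quadrature and noise. Consequently, passing tests show the
*accounting operators* are correct; they do not show that real
constriction losses follow the imposed law — that is the modelling
assumption under test when the package is applied to real data.

## Numerical choices and limitations

* Plane sampling uses 16 concentric rings by default (24 in the Poiseuille
  oracles); quadrature errors on smooth profiles are then ≲0.2%, well
  inside the 0.5–1% bands asserted in tests.
* The station grid for flow accounting (default 10 mm) always includes the
  throat station; a profile whose minimum is not unique is rejected rather
  than silently disambiguated.
* End caps of generated meshes are excluded from slicing by a 1 mm margin;
  slicing a cap-tangent plane is an error, not a zero.
* Reports are byte-deterministic for a fixed config and seed; the config
  hash excludes only the output directory.
* Pipeline problem sizes (10 mm plane spacing, 16 rings, 40 snapshots,
  four flowrates) were chosen as the coarsest grid whose quadrature error
  stays an order of magnitude inside the tested tolerances; halving the
  spacing changes recovered losses by <0.1%.
* Not modelled: airway wall compliance, branch-aware centerlines, wall
  shear stress (requires near-wall gradients), spectral turbulence, and
  any Navier–Stokes solving — the package post-processes flow fields, it
  does not produce them.
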