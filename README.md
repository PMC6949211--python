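# airwayloss

Quantitative post-processing for tracheal-compression studies: lumen
morphometrics from surface geometry, energy-flux and resistance accounting
on planar flow samples, and orifice power-law pressure-loss models.

## The problem

Extrinsic tracheal compression (for example by a retrosternal goitre)
progressively narrows the airway lumen, and the work of breathing rises
steeply with the severity of the constriction. Two complementary views
quantify this:

* **Geometry.** From a segmented lumen surface and its centerline, the
  cross-sectional area profile A(x) locates and grades the constriction.
  Severity is the constriction ratio
  (CSA<sub>ref</sub> − CSA<sub>min</sub>)/CSA<sub>ref</sub> relative to the
  first-tracheal-ring area, and the constricted length is the contiguous
  extent where the area is reduced by at least 35%.

* **Flow energetics.** On each centerline-normal plane the mean energy flux

  E<sub>F</sub> = ∫<sub>S</sub> (**u**·**n**) [P<sub>s</sub> + ½ρ|**u**|²] dS

  measures the power carried by the flow; its streamwise decrease from the
  inlet is the accumulated viscous dissipation, and
  R(x) = (⟨P<sub>tot</sub>⟩<sub>inlet</sub> − ⟨P<sub>tot</sub>⟩<sub>x</sub>)/Q
  is the airway resistance profile. Across a severe constriction the loss
  behaves like an orifice plate,

  ΔP = ½ ρ K (Q/A<sub>C</sub>)<sup>n</sup>,

  with throat area A<sub>C</sub>, loss coefficient K ≈ 1 and exponent
  n ≈ 2 — so a single computed loss scales to other flowrates by
  (Q₂/Q₁)².

High-fidelity simulation fields behind published loss figures are rarely
deposited, so `airwayloss` ships a synthetic generator
(`airwayloss.synthetic`) that produces watertight stenosed-airway meshes
and time-resolved plane-sampled flow fields with *known* injected losses.
Every operator in the package is validated against that ground truth and
against closed-form duct flows (Poiseuille, Bernoulli, orifice).

## Worked example

Fit the orifice law to a published flowrate/pressure-loss table (losses in
Pa from the first tracheal ring to the outlet of a trachea whose minimum
area is 20.5 mm²) and predict the loss from a literature coefficient:

```python
from airwayloss import lossmodel, reference

fit = reference.fit_reference_k(rho=1.2, fixed_n=2.0)
print(f"K = {fit.model.K:.3f}  (K*rho = {fit.K_rho:.3f}, "
      f"max error {100 * fit.max_relative_error:.1f}%)")

dp = reference.predict_reference_dp(rho=1.2, K=lossmodel.K_ORIFICE_REFERENCE)
print(f"dP(K=1.2, Q=392 mL/s) = {dp:.1f} Pa")
```

prints

```
K = 0.927  (K*rho = 1.113, max error 1.8%)
dP(K=1.2, Q=392 mL/s) = 263.3 Pa
```

i.e. with the exponent fixed at 2, a single coefficient K ≈ 0.93 describes
the table across a two-fold flowrate range to within 2%, and the generic
orifice-plate coefficient K = 1.2 over-predicts the subglottic loss — both
with the caveat that the data constrain only the product K·ρ, which is why
the fit reports it alongside K.

The full synthetic pipeline (generate airway → slice → sample flow →
energy/resistance → fit) runs from the command line:

```sh
airwayloss report --outdir out --seed 0
# constriction ratio 82.5%  K(n=2) 1.191  R_total 0.674 Pa mL^-1 s
```

The report recovers the injected loss coefficient (1.2) to within 1% and
writes CSV tables (`area_profile.csv`, `energy_flux.csv`,
`resistance.csv`, `pressure_loss_table.csv`), figures, and a provenance
block (config hash, seed, version) to `out/`. Other subcommands
(`synth-airway`, `synth-flow`, `geom-profile`, `energy`, `resistance`,
`fit-powerlaw`, `verify-published`) expose the individual stages; see
`airwayloss --help`.

## Layout

| module | contents |
| --- | --- |
| `airwayloss.geometry` | centerlines, plane slicing, area profiles, constriction metrics |
| `airwayloss.sampling` | plane-sample containers, time averaging, flowrate, turbulence intensity |
| `airwayloss.energy` | energy flux, cumulative loss, resistance profiles |
| `airwayloss.lossmodel` | orifice power law: predict, fit, scale, unit conversion |
| `airwayloss.synthetic` | stenosed-airway and analytic flow-field generator |
| `airwayloss.reference` | embedded published tables and their verification |
| `airwayloss.pipeline` / `airwayloss.cli` | configuration, end-to-end runs, reports |

See `docs/methods.md` for the models, conventions, and numerical choices.
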