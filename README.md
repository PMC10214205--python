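# crowdsense

Quantifying steric crowding on membrane surfaces from the binding of
macromolecular sensors.

The surfaces of cells are coated with a dense layer of proteins and glycans
(the glycocalyx) that sterically hinders large soluble molecules —
antibodies, lectins, viral particles — from reaching binding sites near the
membrane. `crowdsense` implements the computational framework behind
*crowding sensors*: probes whose loss of effective binding affinity on a
crowded surface reports the crowding free energy directly,

    ΔU = kB·T · ln(KD / KD0),        Π = ΔU / Veff,

where KD and KD0 are the effective dissociation constants on the crowded
and bare surface, and Π is the osmotic pressure the surface layer exerts on
a probe of excluded volume Veff. Everything is expressed as ratios, so
sensor chemistry and detector units cancel.

The package is aimed at membrane biophysicists and quantitative cell
biologists and contains three legs plus supporting infrastructure:

* `crowdsense.theory` — closed-form adsorption thermodynamics: ΔU ↔ KD/KD0,
  osmotic pressures and excluded-volume conventions, Debye lengths,
  grafting geometry, an Alexander–de Gennes brush insertion penalty, and a
  bivalent-antibody avidity correction.
* `crowdsense.simulate` — coarse-grained Brownian dynamics of bead-spring
  (Kremer–Grest) polymer brushes grafted to a flat membrane, with optional
  screened-Coulomb (Yukawa) charge, plus Widom test-particle insertion to
  measure the probe free energy U(z) and KD/KD0.
* `crowdsense.isotherm` — the flow-cytometry pipeline: per-event
  anchor-channel normalization and gating, Langmuir isotherms,
  low-concentration slope ratios and full Langmuir fits, single-cell
  crowding distributions, expression binning, and ANOVA/Tukey group
  comparisons.
* `crowdsense.csop` — offset-calibrated mean surface-height analysis
  (⟨h⟩ = h_measured − ⟨h_offset⟩) for treatment comparisons.
* `crowdsense.synth` — seeded generators for every input (event tables,
  populations, height tables, named scenario presets), so the entire
  pipeline runs and is tested without any experimental data.
* `crowdsense.protocols` — end-to-end study protocols wiring the above
  together; `crowdsense.cli` exposes everything as the `crowdsense`
  command.

## Worked example

Crowding energy and osmotic pressure of a surface that weakens antibody
binding 20-fold:

```bash
$ crowdsense theory energy --kd-ratio 20
{
  "input": {"kd_ratio": 20.0},
  "units": "kBT",
  "value": 2.995732273553991
}

$ crowdsense theory pressure --delta-u 2.996 --probe-nm 10 --convention sphere_radius
{
  "convention": "sphere_radius",
  "input": {"delta_u_kBT": 2.996, "temperature_K": 298.0, "veff_nm3": 4188.79},
  "units": "Pa",
  "value": 2942.75
}
```

A 20-fold affinity loss is a ~3 kBT penalty; spread over the excluded
volume of a 10-nm probe it corresponds to ~2.9 kPa of surface osmotic
pressure — a large pressure, but localized within nanometres of the
membrane.

The same measurement end-to-end on synthetic cytometry data — generate a
bare-bead reference and a crowded sample whose true KD is 55% higher, then
recover that factor from the event table alone:

```python
>>> from crowdsense.protocols import slope_ratio_recovery
>>> r = slope_ratio_recovery(kd0_nM=10.0, true_kd_ratio=1.55,
...                          concs_nM=(0.25, 0.5, 1.0, 2.0),
...                          n_events_per_conc=20_000, seed=7)
>>> round(r.percent_increase, 1), round(r.delta_u_kBT, 3)
(50.5, 0.409)
```

The recovered 50.5% KD increase sits within the estimator's documented
linearization bias of the true 55%; the attached ΔU ≈ 0.41 kBT is the
crowding energy a 10-nm sensor reports on that surface. And a single-cell
population whose geometric-mean crowding is 22-fold:

```python
>>> from crowdsense.protocols import population_recovery
>>> pop = population_recovery(geometric_mean_ratio=22.0, cv=0.3,
...                           n_cells=5_000, seed=11)
>>> round(pop.mean, 1), round(pop.cv, 2)
(21.5, 0.33)
```

Simulating the brush itself (a 100-chain box of 3-bead, 4-nm-domain
chains at 10,000 chains/µm², then Widom-inserting a 10-nm probe at contact)
takes a few minutes:

```python
>>> from crowdsense.protocols import fib_brush_kd_ratio
>>> round(fib_brush_kd_ratio(beads_per_chain=3, seed=43).kd_ratio, 1)  # ~1 min
33.0
```

Even the 3-domain brush raises the probe's effective KD well beyond the
2-fold floor measured on reconstituted protein surfaces; the steric penalty
at contact is ln 33 ≈ 3.5 kBT.

## Documentation

`docs/methods.md` describes the models, estimators, parameter choices,
noise assumptions, and known limitations in detail.
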