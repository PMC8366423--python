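# nrfisher

Fisher-information analysis and counting-statistics experiment
simulation for neutron reflectometry.

Neutron reflectometry infers the depth profile of thin-film and
soft-matter samples (thicknesses, scattering length densities,
roughnesses, hydrations) from specular reflectivity curves r(Q).
Parameter uncertainties are traditionally obtained by Bayesian sampling,
which is far too slow for decisions *during* beamtime.  `nrfisher`
instead exploits the fact that neutron counts are Poisson distributed:
with per-bin incident counts s_i and model reflectivities r_i(ξ), the
Fisher information matrix of the M model parameters ξ is available in
closed form,

    g = Jᵀ M J ,   J_ij = ∂r_i/∂ξ_j ,   M = diag(s_i / r_i) ,

and the Cramér–Rao bound turns it into parameter uncertainties
ε_j = √(g⁻¹)_jj, confidence ellipses, and — because g is exactly linear
in counting time τ — the projection ε ∝ τ^(−1/2).  This enables
millisecond-scale answers to experimental-design questions: how long to
count, which measurement angle, which solvent contrast to measure next.

The package is aimed at reflectometry practitioners and instrument
scientists.  It provides:

* `reflectivity` — Abelès matrix forward model with Névot–Croce
  roughness, Gaussian dQ/Q resolution smearing, scale and background;
* `instrument` — simulation of counting experiments from a wavelength
  flux profile: Q binning, slit-law angle scaling, Poisson count draws;
* `fisher` — Jacobian, FI matrix, uncertainties, confidence ellipses,
  the exact Poisson Kullback–Leibler oracle, likelihood, differential-
  evolution fitting and a Metropolis–Hastings cross-check sampler;
* `design` — uncertainty-vs-time scans, FI-vs-contrast scans,
  estimator-bias estimation and an Anscombe/Hotelling t² comparison of
  measured vs simulated counting statistics;
* `bilayer` — a supported DMPC-style bilayer parameterized by area per
  molecule and bulk-water contrast SLD, for contrast-choice studies;
* `dataio`/`cli` — ASCII dataset and flux-table readers/writers, YAML
  model configs, and an `nrfisher` command-line tool.

## Worked example

Simulate a two-angle measurement of the built-in two-film reference
sample (790.7 Å Si / 297.9 Å Cu on quartz) and ask what the data are
worth:

```python
import numpy as np
import nrfisher as nf

model = nf.table1_model()
flux = nf.synthetic_flux_profile()          # Maxwellian stand-in spectrum
conditions = [
    nf.MeasurementCondition(angle=0.7, time=450.0, n_points=70),
    nf.MeasurementCondition(angle=2.0, time=1800.0, n_points=70),
]

layers = model.structure.layers
params = nf.ParameterSet([
    nf.Parameter("si_thickness", [(layers[0], "thickness")], (600, 990)),
    nf.Parameter("cu_thickness", [(layers[1], "thickness")], (225, 370)),
])

datasets = [nf.expected_counts(model, flux, c) for c in conditions]
analysis = nf.fisher_matrix([model, model], datasets, params)
print(analysis.report())

scan = nf.uncertainty_vs_time(
    [model], flux, conditions, [1.0, 10.0, 100.0, 1000.0], params
)
print("slopes:", scan.slopes)
```

Output:

```
parameter                            value       epsilon       FI diag
si_thickness                         790.7     0.0419624       569.271
cu_thickness                         297.9     0.0139369       5160.72
slopes: [-0.5 -0.5]
```

The `epsilon` column is the Cramér–Rao uncertainty for the 7.5 + 30 min
schedule: the Cu thickness is constrained to ±0.014 Å and the thicker Si
film to ±0.042 Å (the FI diagonal shows Cu carrying ~9× more information
per Å²).  The time-scan slopes are −½ exactly: counting 100× longer
shrinks every uncertainty tenfold, which is how the package projects
when a measurement can stop.

The same machinery drives contrast choice for a supported lipid
bilayer — `nf.contrast_scan` computes each parameter's information
across the H₂O–D₂O range and reproduces the classic blind spot where
the solvent matches the SiO₂ SLD — and `nrfisher simulate | fisher |
time-scan | contrast-scan | compare` expose the pipeline on the command
line.

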