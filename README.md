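# leupet

Kinetic modelling of L-[1-¹¹C]leucine PET for quantifying regional rates of
cerebral protein synthesis (rCPS), with explicit treatment of tissue kinetic
heterogeneity.

## The problem

Voxelwise quantification of dynamic PET data usually assumes each voxel is
kinetically homogeneous. For the leucine method, a homogeneous tissue is
described by the rate constants K₁ (plasma→tissue transport, mL/g/min),
k₂+k₃ (efflux plus catabolism, min⁻¹), k₄ (incorporation into protein,
min⁻¹) and the blood volume fraction V_b. The physiological outputs are

    rCPS = K₁ k₄ / (k₂+k₃) · C_p          λ = (k₂+k₃) / (k₂+k₃+k₄)

where C_p is the unlabeled plasma leucine concentration (nmol/mL) and λ is
the fraction of the tissue precursor pool derived from arterial plasma. The
measured tissue activity is a trapping term plus one equilibrating
exponential-convolution term (rate β = k₂+k₃+k₄) plus a blood contribution.

Real voxels, however, often contain mixtures of kinetically distinct tissue
(gray/white borders, partial-volume effects), and applying the homogeneous
model to such data biases rCPS. `leupet` implements both voxelwise
estimators used to study this:

* **BFM** (basis function method) — homogeneous model; grid search over β
  with weighted linear least squares per grid point, non-negativity
  constrained fallback.
* **SAIF** (spectral analysis with a bandpass filter) — heterogeneous-capable;
  one weighted non-negative least squares fit over a dictionary of trapping,
  in-band equilibrating, and blood columns. The number of surviving in-band
  components measures kinetic heterogeneity.

The package also ships everything needed to evaluate the two estimators
without access to measured scanner data: a synthetic arterial input set, a
19-entry reference library of regional kinetics, a two-subregion
heterogeneous construction that preserves weighted rCPS exactly, a
count-statistics Gaussian noise model, a dynamic 3D brain phantom, and the
Monte Carlo / resolution-degradation experiment drivers.

## Worked example

Build a heterogeneous tissue (two subregions, equal weights, equal λ, 5×
ratio of lumped rates), simulate its noise-free TAC on the standard 42-frame
90-min protocol, and fit with both estimators:

```python
from leupet import (FrameSchedule, HomogeneousParams, derive_heterogeneous,
                    heterogeneous_tac, make_input_functions)
from leupet.estimators import BasisSet, bfm_fit, saif_fit

inputs = make_input_functions()                 # 2-min infusion input set
schedule = FrameSchedule.default_protocol()     # 16x15s ... 14x300s
basis = BasisSet(inputs, schedule)              # shared fit dictionary

h = HomogeneousParams(K1=0.05, k2k3=0.10, k4=0.04, Vb=0.05)
mix = derive_heterogeneous(h)                   # truth: rCPS = 2.40
tac = heterogeneous_tac(mix, inputs, schedule)

print(saif_fit(tac, basis).summary())
print(bfm_fit(tac, basis).summary())
```

Output:

```
SAIF kinetic fit
----------------------------------
K1         0.05000  mL/g/min
lambda     0.71434
rCPS       2.39954  nmol/g/min
Vb         0.05000
WRSS    1.3528e-07
components 2

BFM kinetic fit
----------------------------------
K1         0.04561  mL/g/min
lambda     0.66749
rCPS       2.72624  nmol/g/min
Vb         0.05427
WRSS       0.69176
beta       0.15650  1/min
```

SAIF detects both subregions (`components 2`) and recovers the true rCPS of
2.40 nmol/g/min to 0.02%. BFM, forced to describe the mixture with a single
β, overestimates rCPS by ~14% — the model-mismatch bias that makes
heterogeneity-aware analysis necessary at low spatial resolution.

The same objects drive the larger experiments:

```python
from leupet.experiments import MonteCarloConfig, run_monte_carlo
report = run_monte_carlo(MonteCarloConfig("heterogeneous", "roi", n_reps=200, seed=1))
print(report.summary())          # bias% / RMSE% per method and parameter
```

A `leupet` console script exposes the pipeline stages
(`simulate-inputs`, `fit`, `mc-study`, `phantom`, `smooth`,
`region-summary`, `hetero-map`); every subcommand takes `--seed`.

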