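# ephyslink

**From ion-channel gene expression to neuronal electrophysiology through a
biophysical bottleneck.**

Patch-seq experiments record, from the same cortical neuron, both its
single-cell transcriptome and its membrane-voltage response to current
injection. `ephyslink` connects the two through mechanistically
interpretable quantities: it fits a 13-parameter Hodgkin-Huxley-type model
to each cell's response using simulation-based inference, and then
predicts those fitted biophysical parameters from gene expression with a
sparse linear model. The package is aimed at computational
neuroscientists who want an end-to-end, testable implementation of this
statistical-biophysical bridge that runs on synthetic data out of the box.

## What is inside

1. **Biophysical model** (`model`, `kinetics`, `simulator`) — a
   single-compartment neuron with transient Na+, Na+, delayed-rectifier
   K+, muscarinic K+, Kv3.1 and high-threshold Ca²⁺ currents,

       C_m dV/dt = Σ_x ḡ_x · gates_x · (E_x − V) + I_inj + I_noise,

   13 free parameters θ (capacitance, input resistance, time constant,
   six maximal conductances, leak reversal, muscarinic time-constant
   scale, threshold shift V_T, and a rate-to-steady-state scale r_SS that
   controls action-potential width), simulated under a 300 pA / 600 ms
   step protocol with Gaussian current noise, at 25 °C via Q10 scaling.

2. **Summary features** (`features`) — 23 electrophysiological statistics
   x (spike shape, counts, adaptation, latency, voltage moments) with
   explicit defined/undefined semantics, variance-stabilizing transforms
   and library-based z-scoring.

3. **Simulation library** (`library`) — batched prior simulation at scale,
   the "best Euclidean" nearest-simulation baseline, and a
   model-mismatch diagnostic.

4. **Posterior estimation** (`inference`, `mdn`) — a conditional density
   estimator q(θ|x) (mixture density network) trained under several
   schedules: standard NPE on all simulations, and the noise-robust
   variant **NPE-N**, which trains on simulations near the observations
   with isotropic noise (σ = 0.1 z-units) added to their standardized
   features so the posterior tolerates systematic model-data mismatch.
   MAP estimates are the best of 10 000 posterior draws; posterior
   entropy scores per-cell uncertainty.

5. **Gene linkage** (`srrr`) — rank-2 sparse reduced-rank regression
   Y ≈ XWVᵀ with a per-gene elastic-net penalty, cross-validated along a
   penalty path, plus family-level comparison of fitted vs predicted
   parameter matrices (variance-normalized Euclidean distance).

6. **Synthetic cohorts** (`synthetic`) — family-structured ground-truth
   parameters, simulated responses (optionally shifted in feature space to
   emulate model mismatch) and negative-binomial gene counts coupled to
   the parameters through a sparse rank-2 loading matrix.

See `docs/methods.md` for model equations, conventions and limitations.

## Worked example

The numbered drivers under `analysis/` run the pipeline on synthetic data
and write tables to `results/`:

```bash
python analysis/01_build_prior_library.py --n 12000 --seed 42
python analysis/02_nearest_simulation_baseline.py
python analysis/03_fit_posteriors.py
python analysis/04_link_genes_to_parameters.py
```

Step 01 reports the library yield:

```
 n_draws  defined_fraction  scaled_to_15M_draws_millions
   12000          0.413417                       6.20125

41.3% of prior simulations have all 23 features well defined (scaled: 6.2M of 15M draws).
```

i.e. ~41 % of random parameter vectors produce a response in which all 23
features exist (spiking, measurable widths, finite ratios). Step 03
compares posterior-training schedules on 30 synthetic cells whose
features were shifted by +0.5 SD in AP width to emulate model mismatch:

```
         training  n_pairs  map_fail_pct  map_distance_mean  post_fail_pct  post_distance_mean
     standard NPE     4961           6.7               3.32           31.7                4.08
NPE-N (sigma=0.1)     1916           3.3               3.61           23.0                3.85
```

`map_fail_pct` is the percentage of cells whose MAP-parameter simulation
has at least one undefined feature; `map_distance_mean` is the Euclidean
distance (in z-scored feature space) between each cell and its MAP
simulation. Noise-robust training halves the MAP failure rate and lowers
the posterior-draw failure rate; at this desk scale and mild shift the
MAP distances of the two schemes are statistically indistinguishable
(see `docs/methods.md`, scale limitations). Step 04 predicts parameters
from the synthetic gene counts:

```
MAP-based linkage (30 cells): best CV R^2 = -0.004 +- 0.009 (~4 genes)
ground-truth linkage: predicting true parameters from 120 genes
best CV R^2 = 0.122 +- 0.065 at lambda 0.8407 (~32 genes)
family-level variance-normalized distance: 3.14
28 genes selected; 7 of 12 truly coupled genes recovered.
```

With only 30 cells the per-cell posterior error swamps the gene signal in
the MAP-based regression (R² ≈ 0), while the same pipeline on the
ground-truth parameters recovers most of the truly coupled genes — a
cohort-size limitation, not a failure of the regression.

Smaller entry points, if you prefer the API:

```python
from ephyslink import (DEFAULT_PRIOR, StimulusProtocol, sample_prior,
                       simulate, extract_features, BiophysParams)
theta = sample_prior(DEFAULT_PRIOR, n=1, seed=0)[0]
trace = simulate(BiophysParams.from_array(theta), StimulusProtocol(), seed=0)
fv = extract_features(trace)
print(fv["ap_count"], fv["vm_mean"])
```

A thin CLI (`ephyslink simulate|features|library|train|evaluate|link|synth|run`)
wraps the same functions; `ephyslink run --outdir out/` executes the whole
pipeline from one YAML config.

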