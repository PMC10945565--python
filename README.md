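# statedyn

Latent-dynamics modeling of multichannel neural time series: oscillatory
burst detection and dynamic functional network analysis with generative
models, plus the static (time-averaged) network analyses needed to
compare against them.

Neural recordings (MEG/EEG source parcels, LFP, ECoG) contain transient
events — oscillatory bursts, network activations — whose timing and
duration are not known in advance. `statedyn` finds them with two
data-driven generative models:

- **Gaussian hidden Markov model (HMM).** A latent state
  `θ_t ∈ {1..K}` follows a Markov chain with transition matrix
  `A_ij = p(θ_t = j | θ_{t-1} = i)`; observations are drawn from the
  active state's distribution, `x_t | θ_t = k ~ N(μ_k, D_k)`.  States
  are mutually exclusive: each visit is a burst or a network
  activation.  Inference is exact (forward-backward, Viterbi), training
  is EM (or variational Bayes with conjugate priors), and model runs
  are compared by variational free energy.
- **Dynamic mode mixture (DyNeMo-style).**  Observations mix J modes
  convexly at every sample: `x_t ~ N(Σ_j α_jt μ_j, Σ_j α_jt D_j)` with
  `α_t = softmax(θ_t)` and a learned causal Gaussian prior
  `p(θ_t | θ_{1:t-1})`.  Inference is amortized variational: an encoder
  maps local data features to the posterior over the logits.

Around the models sit the standard pipeline stages: time-delay embedding
(TDE) and amplitude-envelope (AE) data preparation, PCA, multitaper
state/mode spectra, coherence and amplitude-envelope-correlation
networks, NNMF frequency bands, burst/network summary statistics
(fractional occupancy, lifetimes, intervals, switching rates), and
max-statistic permutation tests for group inference — all validated
end-to-end on synthetic data with known ground truth (the `simulate`
module).

## Worked example: burst detection

```python
import numpy as np
import statedyn as sd

# 400 s of a single channel with 10 Hz and 25 Hz bursts in noise
spec = sd.BurstSimSpec(n_samples=40_000, seed=0)
ts, mask = sd.sample_bursts(spec)

# prepare: time-delay embedding (+-7 lags) + standardization
prepared = sd.prepare_tde_pipeline(ts, n_embeddings=15)

# 3-state TDE-HMM, best of 3 runs by variational free energy
ens = sd.fit_ensemble(lambda: sd.GaussianHMM(prepared, 3),
                      n_runs=3, seed=0, fit_kwargs={"n_iter": 100})
best = sd.select_best_run(ens)
print(best.summary())
```

```
Gaussian hidden Markov model
==============================================
states:             3
channels:           15
subjects:           1
samples:            39986
algorithm:          em
means pinned:       True
free energy:        722297.6432
iterations:         12

state  frac. occupancy  stay prob.
    0           0.1039      0.9690
    1           0.7747      0.9924
    2           0.1213      0.9702
```

States 0 and 2 are the two burst states (~10–12% of time each); state 1
is the non-oscillatory background.  Their spectral identity and
dynamics:

```python
se = sd.multitaper_state_spectra(ts, best.state_probabilities(),
                                 sample_offsets=[prepared.index_maps[0][0]])
path = best.viterbi()[0]
fo = best.fractional_occupancies()
lifetimes = sd.mean_lifetime(path, ts.sampling_frequency)[0]
for k in sorted(np.argsort(fo)[:2]):          # the two low-occupancy states
    sel = se.frequencies > 2
    peak = se.frequencies[sel][np.argmax(se.psd[0, k, 0, sel])]
    print(f"state {k}: PSD peak {peak:.1f} Hz, "
          f"occupancy {fo[k]:.2f}, mean lifetime {lifetimes[k]:.2f} s")
```

```
state 0: PSD peak 10.0 Hz, occupancy 0.10, mean lifetime 0.36 s
state 2: PSD peak 25.0 Hz, occupancy 0.12, mean lifetime 0.36 s
```

The burst states peak exactly at the simulated carrier frequencies (10
and 25 Hz) and their mean lifetimes recover the simulated mean burst
duration (0.4 s) within ~10%.  The same objects drive the multi-region
network pipelines
(`sd.run_pipeline` with an `hmm` or `dynemo` model block) and the static
pipeline.

## Command line

```bash
statedyn simulate --config sim.yaml --output data/
statedyn pipeline --config pipeline.yaml --data data/ --seed 1 --output results/
```

The pipeline YAML names the workflow (`burst`, `dynamic_network` or
`static`), the preparation (`tde` with `n_embeddings`/`n_components`, or
`ae` with a band), the model (`hmm`/`dynemo`, `n_states`, `n_runs`) and
the spectral options; every run writes a provenance JSON with the
config hash, seeds and the free energies of all runs.

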