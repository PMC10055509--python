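# neurosgm

Spectral graph model (SGM) analysis of regional brain-activity power
spectra, for researchers studying how global network physiology shapes
resting-state electrophysiology (MEG/EEG source spectra) — in particular
the slowing of neural timescales reported in Alzheimer's disease.

The SGM is a linear, analytic model: every cortical region hosts a
linearized excitatory–inhibitory circuit, and the excitatory populations
are coupled across regions through the structural connectome with
conduction delays. The steady-state response at angular frequency ω is
obtained in closed form from the eigenmodes (λ_k, u_k, v_k) of a complex
Laplacian L(ω) = I − α·N(C ∘ e^{−jωD/v}):

    X(ω) = Σ_k  u_k v_kᴴ P(ω) H_local(ω) / (jω + λ_k F_G(ω)/τ_G)

Seven spatially invariant parameters govern the response — local time
constants τ_e, τ_i, local gains g_ei, g_ii, the long-range excitatory time
constant τ_G, global coupling α and conduction speed v — and are inferred
per subject by maximizing the sum of a *spectral correlation* (mean
per-region Pearson r between modeled and observed dB spectra over 1–35 Hz)
and a *spatial correlation* (network-smoothed similarity x̃ᵀ‖C+wI‖ỹ of
alpha-band power maps) with stability-constrained dual annealing.

On top of subject-level inference the package provides the cohort layer of
such a study: covariate-adjusted group comparison with least-squares means,
cognition regressions (MMSE/CDR), random-forest classification under nested
stratified cross-validation, a parameter-ablation experiment, intrinsic
timescale estimation (1/e autocorrelation decay), and seeded synthetic-data
generators (connectomes, subject spectra, AR(1) time series, two-group
cohorts) that stand in for clinical data in every test.

See `docs/methods.md` for the model, assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
import neurosgm as ns

# synthetic 16-region connectome and the default 1-35 Hz grid
graph = ns.synth_connectome(16, seed=100)
grid = ns.FrequencyGrid.default()

# a "subject": spectra generated at tau_G = 20 ms plus 1 dB noise
truth = ns.SGMParameters(tau_G=0.020)
spectra = ns.synth_subject_spectrum(truth, graph, grid, noise_db=1.0, seed=7)

# infer the seven parameters (reduced maxiter for a quick demo)
result = ns.fit_subject(spectra, graph, ns.FitConfig(maxiter=100, seed=1))
print(f"tau_G recovered: {result.params.tau_G * 1e3:.2f} ms (truth 20.00)")
print(f"spectral r = {result.spectral_r:.3f}, "
      f"spatial r = {result.spatial_r:.3f}, "
      f"objective = {result.objective:.3f}, stage {result.stage_used}")
```

prints

```
tau_G recovered: 20.77 ms (truth 20.00)
spectral r = 0.995, spatial r = 0.841, objective = 1.836, stage 1
```

i.e. the long-range time constant is recovered to within 0.8 ms under 1 dB
measurement noise; the spectral term is near its ceiling of 1, while the
network-smoothed spatial term tops out below 1 by construction (see
`docs/methods.md`).

The same flow scales to a cohort from the command line:

```bash
neurosgm all --out runs/demo --seed 7     # simulate -> fit -> analyze
                                          #   -> classify -> ablate
```

which writes a self-contained run directory: the simulated dataset
(connectome, per-subject spectra and time series, cohort table with
ground-truth parameters), per-subject fits, and JSON/Markdown reports for
the group comparison, cognition regressions, timescale analysis,
classification and the parameter ablation.

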