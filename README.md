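# glifkit

Generalized leaky integrate-and-fire (GLIF) neuron models: simulation,
two-stage fitting from current-clamp sweeps, spike-time evaluation, and
unsupervised cell-type clustering — exercised end-to-end on synthetic
ground-truth neurons.

Point-neuron models that reproduce a neuron's spike times from its injected
current are both a dimensionality reduction of intracellular
electrophysiology and a building block for network models. `glifkit`
implements a nested family of five such models and the full workflow a
modeler needs around them. It is aimed at computational neuroscientists who
want to fit interpretable spiking models to current-clamp data, score how
well those models predict hold-out spike trains, and ask whether the fitted
parameters separate cell types.

## The model

Between spikes the state evolves linearly:

    C dV/dt  = I_e(t) + Σ_j I_j(t) − (V − E_L)/R
    dΘ_s/dt  = −b_s Θ_s
    dI_j/dt  = −k_j I_j                 (j = 1, 2)
    dΘ_v/dt  = a_v (V − E_L) − b_v Θ_v

A spike fires when `V > Θ_∞ + Θ_s + Θ_v`; after a refractory period `δt`
the state is reset by `V ← E_L + f_v (V⁻ − E_L) − δV`, `Θ_s ← Θ_s + δΘ_s`,
`I_j ← I_j + δI_j`, with `Θ_v` unchanged. Level 1 is the classic LIF;
levels 2–5 successively add reset rules, two after-spike currents, their
combination, and a voltage-dependent threshold. Fitting is two-stage:
linear regressions extract every parameter directly from the protocol
sweeps, then the instantaneous threshold `Θ_∞` alone is refined by
Nelder–Mead against a maximum-likelihood objective built on the intrinsic
membrane noise (MLIN), using a forced-spike paradigm in which the model is
reset at the recorded spike times. Performance is the explained-variance
ratio of spike trains binned at 10 ms, relative to how well repeated trials
explain each other. Partitions of cells are compared with the adjusted Rand
index and the adjusted variation of information (shuffle-baselined, upper
bound `ln n`).

See `docs/methods.md` for the full model, estimator, and design notes.

## Worked example

Fit a level-3 model (LIF + after-spike currents) to a synthetic neuron whose
true parameters are known, then evaluate it on hold-out noise:

```python
from glifkit import GLIFParameters
from glifkit.synth import SyntheticCell, synthesize_sweeps
from glifkit.pipeline import fit_and_evaluate_cell

params = GLIFParameters(
    level=3, C=150e-12, R=180e6, E_L=-75e-3, theta_inf=-45e-3,
    spike_cut=4e-3, k=(100.0, 10.0), delta_I=(-25e-12, -6e-12),
)
cell = SyntheticCell(params=params, seed=7, noise_sd=0.2e-3)
synthesize_sweeps(cell)

report = fit_and_evaluate_cell(cell.sweeps, level=3)
fit = report["params"]
print(f"C    {fit.C*1e12:6.1f} pF   (truth {params.C*1e12:.1f})")
print(f"R    {fit.R/1e6:6.1f} MOhm (truth {params.R/1e6:.1f})")
print(f"Th   {fit.theta_inf*1e3:6.2f} mV   (truth {params.theta_inf*1e3:.2f})")
print(f"dI   {fit.delta_I[0]*1e12:5.1f}, {fit.delta_I[1]*1e12:4.1f} pA  (truth -25.0, -6.0)")
print(f"EV ratio: train {report['ev_train'].ratio:.3f}, hold-out {report['ev_test'].ratio:.3f}")
```

prints

```
C     147.6 pF   (truth 150.0)
R     180.3 MOhm (truth 180.0)
Th   -44.77 mV   (truth -45.00)
dI   -25.4, -6.2 pA  (truth -25.0, -6.0)
EV ratio: train 0.926, hold-out 0.871
```

The passive parameters come back within ~2 %, the after-spike current
amplitudes and decay-rate pair are recovered from the discrete library, the
optimized threshold sits within a quarter millivolt of truth, and the model
explains ~90 % of the explainable spike-time variance of the hold-out noise
at a 0.2 mV intrinsic-noise level.

The same workflow scales to populations: `glifkit.pipeline.run_pipeline`
synthesizes a population from cell archetypes, fits every cell at the
requested levels, applies the 20 % training-EV exclusion rule, and clusters
the fitted parameters (iterative binary splitting with SVM node validation),
reporting ARI/AVOI against the generating archetypes.

A command-line surface mirrors the library:

```sh
glifkit synth --n-per-archetype 2 --seed 0 --out pop/
glifkit fit --sweeps pop/cell000 --level 3 --out params.json
glifkit optimize --params params.json --sweeps pop/cell000 --out params_opt.json
glifkit evaluate --params params_opt.json --test-sweeps pop/cell000 --dt 0.01
glifkit run --config config.yaml --seed 1 --out results/
```

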