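# sptstates

Single-particle-tracking analysis of interfacial enzyme mobility: from
TIRF-like movies or trajectory tables to diffusion coefficients,
HMM-resolved mobility states, state-exchange rates, and
transition-state-theory energies.

## The problem

Enzymes working at a water–lipid interface (the reference system is a
lipase on a spin-coated lipid film) do not diffuse homogeneously: single
molecules switch between an arrested state whose apparent motion is pure
localization error, a slow state, and a fast state, and the balance between
these states tracks catalytic performance. Ensemble assays average all of
this away. Surface SPT resolves it, but turning thousands of short, noisy
trajectories into state occupancies, exchange rates `k_ij` and energy
barriers requires a statistical chain that this package implements
end-to-end, together with a ground-truth simulator for validating every
step.

## The model

* Step lengths of a 2D Brownian trajectory at lag `t` follow
  `p(r, t, D) = r/(2Dt) · exp(−r²/4Dt)`; the per-trajectory MLE is the
  binning-free closed form `D̂ = Σr²/(4nt)`.
* Mobility states are a shared hidden Markov model over all traces with
  gamma step-length emissions per state, trained by Baum–Welch; the state
  count (1–4) is chosen by BIC, and traces are segmented with Viterbi.
* Each adjacent segment pair is a transition event on a transition density
  plot (TDP); k-means + 2D Gaussian-mixture clustering assigns events to
  ordered state pairs, and censoring-aware exponential dwell MLEs give the
  rate matrix `k_ij` (s⁻¹).
* Transition-state theory converts rates into energies at `T = 298 K`:
  `Eₐ = −RT ln(h·k_ij/(k_B·T))` and `ΔG = −RT ln(k_ij/k_ji)` (kJ/mol).

The simulator generates switching-diffusion trajectories from a
continuous-time Markov chain (exponential dwells in real time), Brownian
displacements, Gaussian localization noise, photobleaching-limited track
lengths, and can render 16-bit TIRF-like movies through an EMCCD camera
model. See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from sptstates.config import SimulationConfig
from sptstates import simulate, linking, mobility, states, kinetics

cfg = SimulationConfig(seed=1, n_particles=300)      # 3-state reference regime
traj = simulate.simulate_trajectories(cfg)
traj = linking.filter_tracks(traj, min_steps=10)
traces = linking.all_step_traces(traj, cfg.frame_interval)

est = mobility.estimate_all(traces)
print(round(est["D_um2_s"].mean(), 4))               # 0.0161

model = states.fit_hmm(traces, n_states=3, seed=1)
print(np.round(model.state_means, 3))                # [0.029 0.06  0.159]

segmented = states.segment_all(model, traces)
print(np.round(states.occupancy(segmented, 3), 2))   # [0.34 0.61 0.05]

print(round(kinetics.energy_barrier(2.48), 1))       # 70.7
print(round(kinetics.energy_barrier(0.27), 1))       # 76.2
```

The mean diffusion coefficient (0.0161 µm²/s) is the occupancy-weighted
average over the three states; the fitted state mean steps (0.029, 0.060,
0.159 µm) recover the immobile state at the localization-error floor of
0.03 µm; occupancies echo the stationary distribution of the simulated
rate matrix (0.35/0.58/0.07); the last two lines are the Eyring barriers
at the extremes of the reference rate range, in kJ/mol.

The same chain is available from the shell:

```bash
sptstates simulate --seed 1 --n-particles 300 --outdir run
sptstates diffuse run/trajectories.csv
sptstates hmm run/trajectories.csv --outdir run
sptstates kinetics run/segmentation.csv run/hmm_model.json --outdir run
# or, driven by a JSON config with entry at any stage:
sptstates run-all --config config.json
```

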