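# ringbump

Simulation and theory of **multi-bump ring continuous-attractor networks**:
how the number of activity bumps affects the robustness of path integration
to biological noise.

Continuous attractor networks (CANs) are the leading circuit model for head
direction cells and grid cells. They hold localized bumps of activity whose
position on a ring encodes a coordinate, and they *path integrate* by moving
the bumps in proportion to a velocity-like drive. A ring of `N` neurons per
population can carry one bump or several equally spaced bumps; `ringbump`
builds these networks, measures how the three biologically relevant noise
sources degrade their coordinate estimate, and provides the matching
analytic theory. It is aimed at computational neuroscientists studying
attractor dynamics and noise in neural integrators.

## Model

Two populations α ∈ {L, R} of `N` neurons carry synaptic inputs g obeying

    τ dg_α(x,t)/dt + g_α(x,t) = Σ_β ∫ dy W_β(x,y) s_β(y,t) + A ±_α γ b(t) + ζ_α(x,t),

with firing rates s = φ[g] (ReLU by default), resting input A, drive b
coupled with strength γ (negatively to L, positively to R), and noise ζ.
The connectivity is local inhibition strongest at the inhibition distance l,

    W(x) = w (cos(πx/l) − 1)/2  for |x| < 2l,  else 0,

with the outputs of L and R shifted by ∓ξ neurons, which lets a drive move
the bumps. The kernel amplitude is rescaled as w = 8M/N so the bump shape is
invariant across bump numbers M and sizes N.

Key analytic results implemented here, all expressed through the baseline
rate profile s(x):

- wavelength selection: the bump distance λ maximizes the kernel spectrum
  W̃(q) and equals **2.28 l**; choosing l = 0.44 N/M yields M bumps;
- path-integration velocity v_drive = −γbξ ∫s″ / (τ ∫(s′)²);
- diffusion from input noise D_input = σ²Δt / (4τ² ∫(s′)²) and from Poisson
  spiking D_spike = F ∫s(s′)² / (4τ² [∫(s′)²]²);
- quenched connectivity noise V produces a drift field v_conn(θ), bump
  trapping below an escape drive b₀, and speed irregularities above it;
- a Lyapunov functional that the noiseless dynamics never increase, whose
  minimum selects the preferred bump number.

Network distances can map onto a linear coordinate (fixed length per
neuron) or a circular coordinate (one bump distance = 360°, with γ rescaled
∝ N/M). Under linear mapping, more bumps suppress all three noise effects
(D ∝ N/M²); under circular mapping the advantage disappears. A
mutual-information readout (discretized single-neuron activity vs. a
coordinate grid, optionally joined with coarse location cues) quantifies
the same trends in bits.

## Worked example

```python
import numpy as np
from ringbump import (ModelConfig, build_connectivity, baseline_profile,
                      form_bumps, count_bumps, bump_positions,
                      preferred_wavelength, predict_drive_velocity,
                      predict_input_diffusion, run_tracked, estimate_velocity)
from ringbump.simulate import NO_NOISE, relax_to_steady_state

cfg = ModelConfig(N=200, M=3, l=29.0)          # 200 neurons, 3 bumps
conn = build_connectivity(cfg)
print(f"preferred wavelength: {preferred_wavelength(cfg):.1f} neurons "
      f"({preferred_wavelength(cfg)/cfg.l:.2f} x inhibition distance)")

state = form_bumps(cfg, conn, rng=0)
S = np.maximum(state.g_L, 0) + np.maximum(state.g_R, 0)
print(f"bumps formed: {count_bumps(S)} at positions "
      f"{np.round(np.sort(bump_positions(S, 3)), 1)}")

g = baseline_profile(cfg, conn)
traj = run_tracked(cfg, conn, 1.0, NO_NOISE, 5000.0,
                   relax_to_steady_state(cfg, conn), rng=1)
print(f"bump velocity at drive b=1: measured {estimate_velocity(traj).v:.1f} "
      f"neurons/s, predicted {predict_drive_velocity(cfg, g, 1.0):.1f} neurons/s")
print(f"input-noise diffusion coefficient (sigma=0.5): "
      f"{predict_input_diffusion(cfg, g, 0.5):.2f} neurons^2/s")
```

Output:

```
preferred wavelength: 66.1 neurons (2.28 x inhibition distance)
bumps formed: 3 at positions [ 50.5 117.1 183.8]
bump velocity at drive b=1: measured 36.9 neurons/s, predicted 36.8 neurons/s
input-noise diffusion coefficient (sigma=0.5): 0.62 neurons^2/s
```

The network forms exactly three equally spaced bumps (spacing 200/3 ≈ 66.7
neurons, matching the predicted 2.28 l), the measured bump velocity agrees
with the analytic prediction to well under 5%, and the diffusion
coefficient sets the scale of path-integration error under input noise.

## Command-line interface

Each experiment family is reproducible from a flat YAML config with a seed:

```bash
ringbump form      --config cfg.yaml --seed 0 --out results/
ringbump drive     --config cfg.yaml --seed 0 --out results/
ringbump diffusion --config cfg.yaml --seed 0 --out results/   # 48 replicates
ringbump spiking   --config cfg.yaml --seed 0 --out results/
ringbump escape    --config cfg.yaml --seed 0 --out results/
ringbump speed     --config cfg.yaml --seed 0 --out results/
ringbump mi        --config cfg.yaml --seed 0 --out results/ --mapping circular
ringbump scaling-suite --seed 0 --out results/
```

All outputs are tab-separated tables whose header comments carry the
resolved configuration and seed.

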