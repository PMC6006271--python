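# barrelsim

A spiking-network model of a single barreloid/barrel system of the rodent
whisker pathway, for studying how synaptic adaptation reshapes the cortical
coding of whisker-deflection **velocity** and **angular direction**.

The circuit contains 240 thalamocortical (TC) relay cells split into eight
direction groups, 100 fast-spiking (FS) inhibitory interneurons and 160
regular-spiking (RS) excitatory cells split into eight direction domains.
TC cells are stochastic spike sources (0 or 1 spikes per deflection):
deflection *direction* is encoded by the spatial pattern of TC spike
probabilities across groups (0.8, 0.7, 0.4, 0.15, 0.1 at offsets
0°–180° from each group's preferred direction), while deflection *velocity*
is encoded by TC population synchrony — spike times are inverse-Gaussian
with mean 10 ms and standard deviation σ ∈ {1, 1.25, 1.5, 1.75, 2} ms, with
1/σ standing in for velocity.

FS and RS membrane potentials follow a non-dimensional leaky
integrate-and-fire equation,

    dV/dt = −g (V − V_rest) + I(t),        g = 0.05 ms⁻¹,

with threshold 1, reset to rest and a 2 ms refractory clamp, integrated by
forward Euler at dt = 0.01 ms.  Each presynaptic spike injects an
instantaneous-rise exponential-decay current kernel
A·exp(−α(t − t_spike − d)) after the projection's latency d; FS-origin
kernels enter with negative sign (feedforward inhibition).  Adaptation
following repetitive whisker stimulation is a static parameter change:
the TC→RS amplitude is halved and the FS→RS amplitude reduced to a tenth.

On top of the simulator the package provides the analysis battery used to
characterize the circuit: per-cell spike probability and first-spike
jitter, velocity/direction tuning ratios, the E/(E+I) balance of peak TC
excitation versus peak FS inhibition in RS cells, and single-trial linear
population classifiers — a net-spike-count classifier for velocity and a
domain-response-quotient classifier for direction.

## Worked example

```python
from barrelsim import ModelParams, StimulusSpec, build_wiring, run_condition
from barrelsim.metrics import (
    domain_spike_probability, mean_peak_current_ratio, spike_jitter,
)
import numpy as np

params = ModelParams()
wiring = build_wiring(params, seed=0)
spec = StimulusSpec(direction_deg=0, sigma_ms=1.0)  # preferred direction, high velocity

for adapted in (False, True):
    trials = run_condition(wiring, params, spec, n_trials=600,
                           base_seed=0, adapted=adapted)
    cells = [int(c) for c in wiring.rs_cells_in_domain(0)]
    p = domain_spike_probability(trials, wiring, 0)
    jit = np.nanmean([spike_jitter(trials, c) for c in cells])
    ratio = mean_peak_current_ratio(trials, cells)
    print(f"{'post' if adapted else 'pre'}-adaptation: "
          f"spike prob {p:.3f}, jitter {jit:.3f} ms, E/(E+I) {ratio:.3f}")
```

prints

```
pre-adaptation: spike prob 0.980, jitter 0.179 ms, E/(E+I) 0.210
post-adaptation: spike prob 0.416, jitter 0.272 ms, E/(E+I) 0.568
```

Before adaptation a high-velocity preferred-direction deflection drives
almost every aligned-domain RS cell to spike, tightly time-locked (jitter
below 0.2 ms) because potent feedforward inhibition — roughly four times
the peak of TC excitation (E/(E+I) ≈ 0.21) — closes the integration window
almost immediately.  After adaptation the response probability drops by
half, spike timing loosens, and the E/(E+I) balance swings toward
excitation (≈ 0.57) because inhibition is weakened far more than
excitation.

A CLI wraps the same pipeline for shell use:

```bash
barrelsim simulate --trials 600 --sigma 1 --direction 0 --out out/
barrelsim sweep --trials 600 --sigmas 1,1.25,1.5,1.75,2 --out out/
barrelsim classify --trials 600 --seed 0
barrelsim report --summary out/summary.csv
```

`sweep` writes spike rasters, per-cell summary tables, classification
reports and a manifest from which any run can be replayed exactly.

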