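# Methods

## Model

The package simulates one barreloid/barrel system: the thalamic relay
population serving a single whisker and the cortical column it drives.

**Populations and labels.** 240 TC cells in eight direction groups of 30;
100 FS inhibitory cells; 160 RS excitatory cells in eight direction
domains of 20.  Direction labels are the multiples of 45° in [0°, 360°);
all direction dependence enters through the minimal circular offset
between two labels, which lies in {0°, 45°, 90°, 135°, 180°}.  Domains
are purely categorical — no spatial (pinwheel) geometry is modelled.

**Connectivity.** Random but fixed: sampled once per experiment from a
dedicated wiring sub-stream of the master seed and reused across all
trials and both adaptation states.  Connection probabilities: TC→FS 0.65,
FS→FS 0.5 (no autapses), FS→RS 1, RS→RS all-to-all without autapses, and
TC→RS falling with group–domain offset as 0.7 / 0.5 / 0.3 / 0.15 / 0.1.
The unweighted mean of those five values is 0.35; the group-weighted
expected TC in-degree of an RS cell is 30·(0.7 + 2·0.5 + 2·0.3 + 2·0.15 +
0.1) = 81, and realized wiring is tested against 81 (the package reports
both conventions, since 240·0.35 = 84).  Autapses are excluded wherever a
population projects to itself: a self-synapse has no biological reading
in this circuit.

**Membrane and synapse dynamics.** Non-dimensional leaky
integrate-and-fire: dV/dt = −g(V − V_rest) + I(t) with g = 0.05 ms⁻¹
(membrane time constant 20 ms), V_rest = 0, threshold 1, instantaneous
reset and a 2 ms clamp at rest after each spike.  A presynaptic spike at
t_r adds the kernel A·exp(−α(t − t_r − d)) for t ≥ t_r + d.  Per
projection (TC→FS, TC→RS, FS→FS, FS→RS, RS→RS): amplitudes A = 0.3,
0.06, 0.1, 0.04, 0.008 ms⁻¹; decay rates α = 0.73, 0.75, 0.18, 0.18,
0.24 ms⁻¹; latencies d = 0, 0, 0, 2, 2 ms.  Amplitudes are stored
positive; FS-origin kernels are subtracted in the current sum.  That sign
convention is forced: the parameter table lists positive amplitudes for
synapses that must inhibit, and a signless sum could not.

**Adaptation.** A static parameter transformation, not a dynamical
process: TC→RS amplitude ×0.5, FS→RS amplitude ×0.1, everything else
untouched.  An idempotence guard prevents double application.  The
repetitive (~20 Hz) stimulus train that produces this state biologically
is not simulated.

**Stimulus.** Each TC cell fires 0 or 1 spikes per deflection.  Spike
probability depends only on the offset between the cell's group and the
stimulus direction (0.8, 0.7, 0.4, 0.15, 0.1), making the expected
population spike count 30·(0.8 + 2·0.7 + 2·0.4 + 2·0.15 + 0.1) = 102 for
every direction and velocity.  Spike times of spiking cells are i.i.d.
inverse-Gaussian with mean 10 ms and SD σ ∈ {1, 1.25, 1.5, 1.75, 2} ms;
1/σ is the velocity proxy.  The inverse Gaussian is parameterized by
moment matching (shape λ = μ³/σ²), the only information-preserving
reading of a distribution specified by mean and SD.  Spike occurrence and
spike timing come from independent sub-streams of the trial seed, so
occurrence patterns can be held fixed while timing is resampled.

## Numerical scheme

Forward Euler at dt = 0.01 ms.  All trials of a condition are integrated
simultaneously (state arrays of shape n_trials × n_cells), which keeps
600-trial conditions to seconds of wall time without compiled extensions.
Synaptic state decays by the exact factor exp(−α·dt) per step, so kernel
values at grid points carry no integration error; a TC spike falling
between grid points is injected at the next grid point with the exact
kernel value there, A·exp(−α·(t_grid − t_spike)).  A spike is recorded
when V ≥ 1 after an Euler update and stamped at the update's target
time; the refractory clamp holds V at rest for the following 2 ms.
Delayed synaptic events sit in a ring buffer indexed by arrival step.
Trials last 40 ms: the 10 ms-mean spike-time distribution at worst-case
σ = 2 leaves tail mass below 10⁻⁶ beyond the window once latencies and
kernel decay are accounted for; TC spikes drawn beyond the window (a
negligible set) are dropped.

For every RS cell the integrator tracks the trial maxima of the net
TC-origin current and of the magnitude of the net FS-origin current;
full current and membrane-potential traces are stored only for
explicitly designated cells.

## Response measures

An RS cell's single-trial response is binary — the model, like the cells
it describes, rarely fires more than one spike per deflection — so the
response probability is the fraction of trials with ≥ 1 spike, and jitter
is the population SD of *first*-spike times over spiking trials
(undefined, reported NaN, below two spiking trials).  Tuning ratios are
the response at the preferred stimulus over the mean response: for
velocity the mean runs over the five σ values; for direction over the
five *distinct* offsets 0°–180°.  The five-value direction convention is
used uniformly because it is the one under which the TC spike-probability
table yields the tuning ratio 1.86 (0.8/0.43); averaging over all eight
directions with multiplicity would give 1.88.  Responses at ±θ are pooled
wherever a direction axis is reported (equidistant-direction
aggregation).

The excitation–inhibition balance of an RS cell on a trial is
maxE/(maxE + maxI), with maxE the peak net TC-origin current and maxI
the peak magnitude of the net FS-origin current.  The headline quantity
is the mean over trials (and aligned-domain cells) of the per-trial
ratio; the ratio of trial-mean peaks is also computed as a diagnostic —
the two differ by well under 0.01 in practice.

## Single-trial classifiers

**Velocity.** The net cortical response (total RS spikes in a trial) is
the decision variable.  Training fixes the per-σ mean counts; cutoffs
are the midpoints between adjacent class means, and a trial is correct
when its count falls in its own class's interval.  A count exactly on a
cutoff goes to the lower-velocity side (counts fall with σ, so that is
the side with the smaller mean).  Classifiers are fitted separately for
the two adaptation states, whose mean responses differ.

**Direction** (0° deflections).  The decision variable is the direction
quotient: the 0° domain's per-cell response divided by the per-cell
cortical response, which removes the 20-vs-160 population imbalance (a
trial with all spikes inside the target domain scores 8).  The cutoff is
the midpoint between the trial-averaged quotients of the target domain
and of the pooled 45°/315° domains; a trial is correct when its quotient
strictly exceeds the cutoff.  One cutoff is fitted per velocity.

By default classifiers are fitted on one half of the trials and scored
on the held-out half (`split="half"`); `split="none"` fits and scores on
the same set, for comparison with analyses that do not state a split.
The two modes give indistinguishable conclusions here because the
cutoffs depend only on class means estimated from hundreds of trials.

**Silent trials.** A trial with zero cortical spikes has an undefined
direction quotient and carries no direction signal.  The default policy
(`undefined="drop"`) excludes such trials from the accuracy denominator;
`undefined="incorrect"` scores them as misclassified.  Drop is the
default because it is the only policy under which the model's
post-adaptation direction classification is high and uniform across
velocities while remaining internally consistent: after adaptation at
σ = 2 the RS spike probability is ~0.02, so roughly half the trials are
silent, and scoring them as errors would cap low-velocity accuracy near
the non-silent fraction — conflating detectability (did the cortex
respond at all) with discriminability (which direction the response
indicates), which are distinct questions.  The accuracy report carries
the per-class trial counts, so either reading can be reconstructed.

## Reproducibility

Seed hierarchy: a master seed owns a wiring sub-stream and per-condition
stimulus streams; per-trial seeds are derived by counter, so adding
trials or conditions never perturbs existing ones.  Sweeps write a
manifest (config, parameter hash, condition seeds) from which every
numeric output replays byte-for-byte.

## What the tests do and do not show

All results are in-silico properties of this circuit under its stated
stimulus ensemble.  The stimulus generator emulates the first-order
facts of barreloid coding — direction-dependent spike counts, synchrony-
coded velocity, at most one spike per cell — but not trial-to-trial
correlations between TC cells, adaptation of the thalamic response
itself, multi-whisker receptive fields, or high-frequency stimulation
regimes.  Passing tests therefore certify the mechanism (threshold
nonlinearity plus differentially weakened feedforward inhibition
reshaping velocity and direction codes), not quantitative agreement with
any particular recording.

Problem sizes: quantitative checks of the peak-current balance use the
full 600 trials per condition; the qualitative figure-level property
suite runs on a 150-trial grid at stimulus direction 0°, reading the
response at offset θ from the RS domain preferred at θ — statistically
identical, by the circuit's rotational symmetry, to deflecting at θ and
reading the 0° domain, and the ±θ domain pair implements the
equidistant-direction pooling.

## Known limitations

- RS→RS synapses are included but inert at the default amplitude (zeroing
  them changes per-cell spike probabilities by < 0.02); they are retained
  for structural fidelity.
- Velocity-tuning ratios are undefined (NaN) for domains that are
  entirely silent at every velocity, as happens post-adaptation at
  offsets ≥ 90°; analyses skip undefined entries rather than imputing.
- The refractory clamp quantizes to the integration grid, so the minimum
  inter-spike interval is 2 ms + one dt.
- No membrane noise or spontaneous activity: an empty stimulus produces
  exact silence.
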