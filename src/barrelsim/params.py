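"""Biophysical parameters of the single-barrel circuit model.

The model describes one barreloid/barrel system: 240 thalamocortical (TC)
relay cells in 8 direction groups drive 100 fast-spiking (FS) inhibitory
cells and 160 regular-spiking (RS) excitatory cells (8 direction domains).
Membrane dynamics are a non-dimensional leaky integrate-and-fire equation

    dV/dt = -g (V - V_rest) + I(t)

with threshold 1, reset to ``v_rest`` and a 2 ms refractory clamp.  Each
presynaptic spike injects an instantaneous-rise, exponential-decay current
kernel ``A * exp(-alpha * (t - t_spike - d))`` after a synaptic latency
``d``.  FS-origin kernels enter the postsynaptic current with negative
sign (they are inhibitory); amplitudes are stored positive.

Adaptation after repetitive whisker stimulation is modelled as a static
parameter change: the TC->RS amplitude is halved and the FS->RS amplitude
is reduced to one tenth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

#: The five synaptic projections of the circuit, in a fixed canonical order.
PROJECTIONS = ("tc->fs", "tc->rs", "fs->fs", "fs->rs", "rs->rs")

#: Direction labels used throughout: multiples of 45 degrees.
DIRECTIONS = (0, 45, 90, 135, 180, 225, 270, 315)

#: Distinct angular offsets between a preferred direction and a stimulus.
OFFSETS = (0, 45, 90, 135, 180)

_DEFAULT_AMPLITUDE = {
    "tc->fs": 0.3,
    "tc->rs": 0.06,
    "fs->fs": 0.1,
    "fs->rs": 0.04,
    "rs->rs": 0.008,
}
_DEFAULT_DECAY = {
    "tc->fs": 0.73,
    "tc->rs": 0.75,
    "fs->fs": 0.18,
    "fs->rs": 0.18,
    "rs->rs": 0.24,
}
_DEFAULT_DELAY = {
    "tc->fs": 0.0,
    "tc->rs": 0.0,
    "fs->fs": 0.0,
    "fs->rs": 2.0,
    "rs->rs": 2.0,
}
_DEFAULT_P_TC_RS = {0: 0.7, 45: 0.5, 90: 0.3, 135: 0.15, 180: 0.1}


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class ModelParams:
    """All constants of the circuit model.

    Attributes
    ----------
    n_tc, n_tc_groups, tc_group_size
        Barreloid size and its partition into direction groups.
    n_fs
        Number of fast-spiking inhibitory cells.
    n_rs, n_rs_domains, rs_domain_size
        Cortical excitatory population and its direction domains.
    g
        Leak conductance in 1/ms; 1/g is the 20 ms membrane time constant.
    v_rest, v_thresh
        Non-dimensional resting and threshold potentials.
    refractory_ms
        Post-spike clamp duration at ``v_rest``.
    dt_ms
        Forward-Euler integration step.
    trial_duration_ms
        Length of one simulated deflection trial.  40 ms comfortably
        contains the 10 ms-mean TC spike-time distribution (worst-case
        sigma 2 ms), the 2 ms synaptic latencies and the kernel decays.
    amplitude, decay, delay
        Per-projection synaptic kernel parameters (1/ms, 1/ms, ms).
    p_tc_fs, p_fs_fs, p_fs_rs
        Direction-independent connection probabilities.
    p_tc_rs_by_offset
        TC->RS connection probability as a function of the angular offset
        between the TC group and the RS domain preferred directions.
    adapt_factor_tc_rs, adapt_factor_fs_rs
        Amplitude scale factors applied by :func:`apply_adaptation`.
    adapted
        Flag recording whether adaptation scaling has been applied.
    """

    n_tc: int = 240
    n_tc_groups: int = 8
    tc_group_size: int = 30
    n_fs: int = 100
    n_rs: int = 160
    n_rs_domains: int = 8
    rs_domain_size: int = 20

    g: float = 0.05
    v_rest: float = 0.0
    v_thresh: float = 1.0
    refractory_ms: float = 2.0
    dt_ms: float = 0.01
    trial_duration_ms: float = 40.0

    amplitude: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDE)
    )
    decay: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DECAY))
    delay: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DELAY))

    p_tc_fs: float = 0.65
    p_fs_fs: float = 0.5
    p_fs_rs: float = 1.0
    p_tc_rs_by_offset: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_P_TC_RS)
    )

    adapt_factor_tc_rs: float = 0.5
    adapt_factor_fs_rs: float = 0.1
    adapted: bool = False

    def __post_init__(self) -> None:
        if self.n_tc != self.n_tc_groups * self.tc_group_size:
            raise ParameterError("n_tc must equal n_tc_groups * tc_group_size")
        if self.n_rs != self.n_rs_domains * self.rs_domain_size:
            raise ParameterError("n_rs must equal n_rs_domains * rs_domain_size")
        if self.g <= 0 or self.dt_ms <= 0:
            raise ParameterError("g and dt_ms must be positive")
        if self.refractory_ms < 0 or self.trial_duration_ms <= 0:
            raise ParameterError("durations must be non-negative")
        for proj in PROJECTIONS:
            if proj not in self.amplitude or proj not in self.decay or proj not in self.delay:
                raise ParameterError(f"missing kernel parameters for projection {proj!r}")
            if self.amplitude[proj] < 0 or self.decay[proj] < 0 or self.delay[proj] < 0:
                raise ParameterError(f"kernel parameters for {proj!r} must be non-negative")
        for p in (self.p_tc_fs, self.p_fs_fs, self.p_fs_rs, *self.p_tc_rs_by_offset.values()):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("connection probabilities must lie in [0, 1]")
        if set(self.p_tc_rs_by_offset) != set(OFFSETS):
            raise ParameterError("p_tc_rs_by_offset must be keyed by offsets 0..180")

    @property
    def membrane_tau_ms(self) -> float:
        """Membrane time constant 1/g (20 ms with defaults)."""
        return 1.0 / self.g

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


def apply_adaptation(params: ModelParams) -> ModelParams:
    """Return parameters in the adapted state.

    TC->RS amplitude is multiplied by ``adapt_factor_tc_rs`` (0.5) and
    FS->RS amplitude by ``adapt_factor_fs_rs`` (0.1); everything else is
    unchanged.  Applying the scaling twice is an error, guarded by the
    ``adapted`` flag.
    """
    if params.adapted:
        raise ParameterError("adaptation scaling already applied")
    amplitude = dict(params.amplitude)
    amplitude["tc->rs"] *= params.adapt_factor_tc_rs
    amplitude["fs->rs"] *= params.adapt_factor_fs_rs
    return params.replace(amplitude=amplitude, adapted=True)
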