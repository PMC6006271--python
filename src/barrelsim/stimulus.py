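"""Stochastic thalamocortical spike sets encoding deflection direction and velocity.

Each whisker deflection elicits at most one spike per TC cell.  Direction
is encoded by the distribution of spike probabilities across the eight TC
direction groups (0.8, 0.7, 0.4, 0.15, 0.1 at offsets 0..180 degrees from
the stimulus direction); velocity is encoded by population synchrony: the
spike times of spiking cells are i.i.d. inverse-Gaussian with mean 10 ms
and a standard deviation of 1, 1.25, 1.5, 1.75 or 2 ms (high to low
velocity).  The reciprocal of that standard deviation serves as the
velocity proxy on all analysis axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .network import STIMULUS_STREAM, InvalidDirectionError, Wiring, angular_offset

#: TC spike probability by angular offset from the stimulus direction.
TC_SPIKE_PROB = {0: 0.8, 45: 0.7, 90: 0.4, 135: 0.15, 180: 0.1}

#: The five spike-time standard deviations (ms), high to low velocity.
SIGMAS = (1.0, 1.25, 1.5, 1.75, 2.0)


def tc_spike_probability(offset: int) -> float:
    """Spike probability of a TC cell at a given offset from the stimulus."""
    if offset not in TC_SPIKE_PROB:
        raise InvalidDirectionError(f"offset {offset!r} not in {sorted(TC_SPIKE_PROB)}")
    return TC_SPIKE_PROB[offset]


def invgauss_shape(mean_ms: float, sd_ms: float) -> float:
    """Shape parameter lambda of an inverse Gaussian with given mean and SD.

    The distribution is parameterized by moment matching: with mean mu and
    shape lambda the variance is mu^3 / lambda, so lambda = mu^3 / sd^2.
    """
    if mean_ms <= 0 or sd_ms <= 0:
        raise ValueError("mean and SD must be positive")
    return mean_ms**3 / sd_ms**2


@dataclass(frozen=True)
class StimulusSpec:
    """A single whisker deflection: angular direction plus spike-time spread."""

    direction_deg: int = 0
    sigma_ms: float = 1.0
    mean_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.direction_deg % 45 != 0 or not (0 <= self.direction_deg < 360):
            raise InvalidDirectionError(
                f"direction {self.direction_deg!r} is not a multiple of 45 in [0, 360)"
            )
        if self.sigma_ms <= 0 or self.mean_ms <= 0:
            raise ValueError("sigma_ms and mean_ms must be positive")

    @property
    def velocity_proxy(self) -> float:
        """1/sigma, the stand-in for deflection velocity on figure axes."""
        return 1.0 / self.sigma_ms


@dataclass
class TCSpikeSet:
    """Sampled TC spike times for one trial (NaN where a cell did not spike)."""

    spike_time_ms: np.ndarray  # (n_tc,) float, NaN = no spike
    stimulus: StimulusSpec
    seed: int = 0

    @property
    def spiking_cells(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.spike_time_ms))

    @property
    def n_spikes(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.spike_time_ms)))


def _invgauss_frozen(mean_ms: float, sd_ms: float):
    lam = invgauss_shape(mean_ms, sd_ms)
    # scipy's invgauss(mu, scale) has mean mu*scale and shape = scale
    return stats.invgauss(mu=mean_ms / lam, scale=lam)


def spike_probability_per_cell(spec: StimulusSpec, wiring: Wiring) -> np.ndarray:
    """Per-TC-cell spike probability for a stimulus, from group offsets."""
    offsets = np.array(
        [angular_offset(g, spec.direction_deg) for g in wiring.tc_group_of]
    )
    return np.array([TC_SPIKE_PROB[o] for o in offsets])


def draw_tc_spikes(spec: StimulusSpec, wiring: Wiring, seed: int) -> TCSpikeSet:
    """Sample one trial's TC spike set.

    Spike occurrence and spike timing use independent sub-streams of the
    trial seed, so occurrence patterns can be held fixed while timing is
    resampled.  Deterministic given ``seed``.
    """
    seq = np.random.SeedSequence(seed, spawn_key=(STIMULUS_STREAM,))
    occ_rng, time_rng = (np.random.default_rng(s) for s in seq.spawn(2))

    p = spike_probability_per_cell(spec, wiring)
    spikes = occ_rng.random(p.shape) < p

    times = np.full(p.shape, np.nan)
    n = int(spikes.sum())
    if n:
        dist = _invgauss_frozen(spec.mean_ms, spec.sigma_ms)
        times[spikes] = dist.rvs(size=n, random_state=time_rng)
    return TCSpikeSet(spike_time_ms=times, stimulus=spec, seed=seed)


def expected_total_spikes(spec: StimulusSpec, wiring: Wiring) -> float:
    """Expected TC population spike count (102 by default, any direction)."""
    return float(spike_probability_per_cell(spec, wiring).sum())


def raster_frame(spike_sets, wiring: Wiring, trials: Optional[list] = None):
    """Tabulate spike sets as a raster: (trial, cell_id, group_deg, spike_time_ms)."""
    import pandas as pd

    rows = []
    for i, ss in enumerate(spike_sets):
        trial = trials[i] if trials is not None else i
        for cell in ss.spiking_cells:
            rows.append(
                (trial, int(cell), int(wiring.tc_group_of[cell]), float(ss.spike_time_ms[cell]))
            )
    return pd.DataFrame(rows, columns=["trial", "cell_id", "group_deg", "spike_time_ms"])
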