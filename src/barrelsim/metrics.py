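"""Single-cell and population response measures.

An RS cell's single-trial response is binary (it spikes or it does not);
its response probability is the fraction of trials with at least one
spike.  Jitter is the standard deviation of first-spike times over the
trials on which the cell spiked.  Tuning ratios divide the response at
the preferred stimulus by the mean response over the stimulus set; for
direction the mean runs over the five distinct angular offsets
(0..180 degrees), the convention under which the TC spike-probability
table (0.8, 0.7, 0.4, 0.15, 0.1) gives the tuning ratio 1.86.

Undefined quantities (jitter with fewer than two spiking trials, ratios
with zero denominator) are reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dynamics import TrialResult
from .network import Wiring
from .params import DIRECTIONS, OFFSETS


@dataclass(frozen=True)
class CellResponseSummary:
    """Binary-response statistics of one RS cell over a trial set."""

    cell: int
    spike_probability: float
    jitter_ms: float  # NaN when fewer than 2 spiking trials
    n_trials: int
    n_spiking_trials: int


def spike_probability(trials: Sequence[TrialResult], cell: int) -> float:
    """Fraction of trials on which the cell fires at least one spike."""
    if not trials:
        raise ValueError("empty trial list")
    return float(np.mean([cell in t.rs_spikes for t in trials]))


def first_spike_times(trials: Sequence[TrialResult], cell: int) -> np.ndarray:
    """First-spike times of the cell on its spiking trials."""
    return np.array(
        [t.rs_spikes[cell][0] for t in trials if cell in t.rs_spikes]
    )


def spike_jitter(trials: Sequence[TrialResult], cell: int) -> float:
    """Population SD of first-spike times over spiking trials (NaN if < 2)."""
    times = first_spike_times(trials, cell)
    if len(times) < 2:
        return float("nan")
    return float(np.std(times))


def summarize_cell(trials: Sequence[TrialResult], cell: int) -> CellResponseSummary:
    times = first_spike_times(trials, cell)
    return CellResponseSummary(
        cell=cell,
        spike_probability=spike_probability(trials, cell),
        jitter_ms=float(np.std(times)) if len(times) >= 2 else float("nan"),
        n_trials=len(trials),
        n_spiking_trials=len(times),
    )


def tuning_ratio(
    responses: Mapping,
    reference,
    averaging_set: Optional[Iterable] = None,
) -> float:
    """Response at the reference stimulus over the mean response.

    ``averaging_set`` defaults to all keys of ``responses``.  Returns NaN
    when the mean response is zero (undefined ratio).
    """
    keys = list(averaging_set) if averaging_set is not None else list(responses)
    mean = float(np.mean([responses[k] for k in keys]))
    if mean == 0:
        return float("nan")
    return float(responses[reference]) / mean


def velocity_tuning_ratio(responses_by_sigma: Mapping[float, float]) -> float:
    """Response at the highest velocity (smallest sigma) over the mean."""
    return tuning_ratio(responses_by_sigma, min(responses_by_sigma))


def direction_tuning_ratio(responses_by_offset: Mapping[int, float]) -> float:
    """Response at offset 0 over the mean across the five distinct offsets."""
    return tuning_ratio(responses_by_offset, 0, averaging_set=OFFSETS)


def peak_current_ratio(trial: TrialResult, cell: int) -> float:
    """Peak-magnitude balance E/(E+I) of TC excitation vs FS inhibition.

    maxE is the trial maximum of the net TC-origin current into the cell
    and maxI the maximum magnitude of the net FS-origin current; NaN when
    both are zero.
    """
    max_e = float(trial.peak_tc_current[cell])
    max_i = float(trial.peak_fs_current[cell])
    if max_e == 0 and max_i == 0:
        return float("nan")
    return max_e / (max_e + max_i)


def mean_peak_current_ratio(
    trials: Sequence[TrialResult], cells: Sequence[int]
) -> float:
    """Trial-averaged per-trial peak-current ratio over a cell set."""
    ratios = [peak_current_ratio(t, c) for t in trials for c in cells]
    return float(np.nanmean(ratios))


def ratio_of_mean_peaks(
    trials: Sequence[TrialResult], cells: Sequence[int]
) -> float:
    """Alternative convention: ratio of trial-mean peaks (diagnostic)."""
    e = np.mean([[t.peak_tc_current[c] for c in cells] for t in trials])
    i = np.mean([[t.peak_fs_current[c] for c in cells] for t in trials])
    if e + i == 0:
        return float("nan")
    return float(e / (e + i))


def population_counts(
    trial: TrialResult, wiring: Wiring
) -> Tuple[int, Dict[int, int]]:
    """Net cortical RS spike count and its split across direction domains."""
    per_domain = {d: 0 for d in DIRECTIONS}
    for cell, times in trial.rs_spikes.items():
        per_domain[int(wiring.rs_domain_of[cell])] += len(times)
    return sum(per_domain.values()), per_domain


def net_counts(trials: Sequence[TrialResult], wiring: Wiring) -> np.ndarray:
    """Net cortical spike count per trial."""
    return np.array([population_counts(t, wiring)[0] for t in trials])


def domain_spike_probability(
    trials: Sequence[TrialResult], wiring: Wiring, domain_deg: int
) -> float:
    """Mean single-cell spike probability across a direction domain."""
    cells = wiring.rs_cells_in_domain(domain_deg)
    return float(np.mean([spike_probability(trials, int(c)) for c in cells]))


def pooled_offset_trials(
    trials_by_direction: Mapping[int, Sequence[TrialResult]], offset: int
) -> list:
    """Pool trials whose stimulus direction sits at +/-offset from 0 degrees.

    Implements the equidistant-direction aggregation used on direction
    axes (trials at 45 and 315 degrees pool into the 45-degree point).
    """
    dirs = {d for d in trials_by_direction if min(d % 360, 360 - d % 360) == offset}
    pooled = []
    for d in sorted(dirs):
        pooled.extend(trials_by_direction[d])
    return pooled


def summary_table(
    trials_by_condition: Mapping, wiring: Wiring, cells: Sequence[int]
):
    """Long-format summary: one row per cell x condition.

    ``trials_by_condition`` maps (direction_deg, sigma_ms, adapted) to a
    trial list.  Columns: condition fields, cell, spike probability,
    jitter, and the cell's trial-mean peak-current ratio.
    """
    import pandas as pd

    rows = []
    for (direction, sigma, adapted), trials in trials_by_condition.items():
        for cell in cells:
            s = summarize_cell(trials, cell)
            rows.append(
                {
                    "direction_deg": direction,
                    "sigma_ms": sigma,
                    "adapted": adapted,
                    "cell": cell,
                    "domain_deg": int(wiring.rs_domain_of[cell]),
                    "spike_probability": s.spike_probability,
                    "jitter_ms": s.jitter_ms,
                    "peak_current_ratio": mean_peak_current_ratio(trials, [cell]),
                }
            )
    return pd.DataFrame(rows)
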