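"""Forward-Euler integration of the FS/RS membrane equations.

Membrane potentials follow dV/dt = -g (V - V_rest) + I(t) with threshold
1, instantaneous reset and a 2 ms refractory clamp at rest.  Each
presynaptic spike injects an instantaneous-rise exponential-decay kernel
after the projection's latency; the total current is the sum of kernels,
with FS-origin kernels entering negatively (inhibition).

The integrator steps all trials of a condition simultaneously (state
arrays of shape ``(n_trials, n_cells)``).  Kernel decay is applied as an
exact per-step factor ``exp(-alpha * dt)``, so current values at grid
points carry no integration error; TC spikes, which fall between grid
points, are injected at the next grid point with weight
``A * exp(-alpha * (t_grid - t_spike))``, i.e. the exact kernel value
there.  Spikes detected at an Euler update are stamped at the update's
target time; a cortical spike at time t begins to contribute to its
targets at t + delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .network import STIMULUS_STREAM, Wiring
from .params import ModelParams, apply_adaptation
from .stimulus import StimulusSpec, TCSpikeSet


class IntegrationError(RuntimeError):
    """Non-finite state or inconsistent dimensions during integration."""


def synaptic_kernel(t, t_spike, amplitude: float, decay: float, delay: float = 0.0):
    """Current kernel of a single presynaptic spike.

    Zero before ``t_spike + delay``; ``amplitude * exp(-decay * (t -
    t_spike - delay))`` afterwards.  Vectorized over ``t``.
    """
    if amplitude < 0 or decay < 0:
        raise ValueError("amplitude and decay must be non-negative")
    t = np.asarray(t, dtype=float)
    dt_on = t - np.asarray(t_spike, dtype=float) - delay
    return np.where(dt_on >= 0, amplitude * np.exp(-decay * np.clip(dt_on, 0, None)), 0.0)


@dataclass
class TrialResult:
    """Spike output of one simulated deflection trial.

    ``peak_tc_current`` and ``peak_fs_current`` hold, for every RS cell,
    the trial maximum of the net TC-origin current and of the magnitude
    of the net FS-origin current (both reported positive; the FS current
    itself is negative by the sign convention).  Full per-step traces are
    kept only for explicitly recorded cells: ``recorded_currents[cell]``
    maps ``"tc"``/``"fs"``/``"rs"`` to current arrays on the dt grid (the
    FS one non-positive) and ``"v"`` to the membrane potential trace.
    """

    fs_spikes: Dict[int, np.ndarray]
    rs_spikes: Dict[int, np.ndarray]
    peak_tc_current: np.ndarray
    peak_fs_current: np.ndarray
    stimulus: StimulusSpec
    adapted: bool
    seed: int
    recorded_currents: Optional[Dict[int, Dict[str, np.ndarray]]] = None
    n_rs: int = 160
    n_fs: int = 100

    def rs_spiked(self) -> np.ndarray:
        """Boolean (n_rs,): did each RS cell spike at least once."""
        out = np.zeros(self.n_rs, dtype=bool)
        out[list(self.rs_spikes)] = True
        return out

    def rs_first_spike(self) -> np.ndarray:
        """First RS spike time per cell (NaN where silent)."""
        out = np.full(self.n_rs, np.nan)
        for cell, times in self.rs_spikes.items():
            out[cell] = times[0]
        return out

    def rs_spike_counts(self) -> np.ndarray:
        out = np.zeros(self.n_rs, dtype=int)
        for cell, times in self.rs_spikes.items():
            out[cell] = len(times)
        return out


def _spikes_by_trial(steps, trials, cells, dt, n_trials):
    """Group (step, trial, cell) spike records into per-trial dicts."""
    per_trial: List[Dict[int, list]] = [dict() for _ in range(n_trials)]
    for s, tr, c in zip(steps, trials, cells):
        per_trial[tr].setdefault(int(c), []).append((s + 1) * dt)
    return [
        {c: np.asarray(sorted(ts)) for c, ts in d.items()} for d in per_trial
    ]


def simulate_trials(
    wiring: Wiring,
    params: ModelParams,
    tc_spike_sets: Sequence[TCSpikeSet],
    record_cells: Optional[Sequence[int]] = None,
    external_current: Optional[Dict[str, float]] = None,
) -> List[TrialResult]:
    """Integrate a batch of trials that share wiring and parameters.

    Deterministic: the only randomness lives in the TC spike sets.
    ``external_current`` adds a constant drive per population (a
    diagnostic hook; the model itself has no background input).
    """
    n_trials = len(tc_spike_sets)
    if n_trials == 0:
        return []
    n_fs, n_rs, n_tc = params.n_fs, params.n_rs, params.n_tc
    for proj, (npre, npost) in {
        "tc->fs": (n_tc, n_fs),
        "tc->rs": (n_tc, n_rs),
        "fs->fs": (n_fs, n_fs),
        "fs->rs": (n_fs, n_rs),
        "rs->rs": (n_rs, n_rs),
    }.items():
        if wiring.conn[proj].shape != (npre, npost):
            raise IntegrationError(
                f"wiring projection {proj!r} has shape {wiring.conn[proj].shape}, "
                f"expected {(npre, npost)}"
            )

    dt = params.dt_ms
    n_steps = int(round(params.trial_duration_ms / dt))
    A = params.amplitude
    dk = {p: math.exp(-params.decay[p] * dt) for p in A}
    delay_steps = {p: int(round(params.delay[p] / dt)) for p in A}
    ref_steps = int(round(params.refractory_ms / dt))
    g, v_rest, v_thresh = params.g, params.v_rest, params.v_thresh
    ext_fs = (external_current or {}).get("fs", 0.0)
    ext_rs = (external_current or {}).get("rs", 0.0)

    C_tcfs = wiring.conn["tc->fs"].astype(float)
    C_tcrs = wiring.conn["tc->rs"].astype(float)
    C_fsfs = wiring.conn["fs->fs"].astype(float)
    C_fsrs = wiring.conn["fs->rs"].astype(float)
    C_rsrs = wiring.conn["rs->rs"].astype(float)

    # --- flatten TC spike events, sorted by arrival step -----------------
    ev_trial, ev_cell, ev_time = [], [], []
    for i, ss in enumerate(tc_spike_sets):
        cells = ss.spiking_cells
        ev_trial.append(np.full(cells.shape, i))
        ev_cell.append(cells)
        ev_time.append(ss.spike_time_ms[cells])
    ev_trial = np.concatenate(ev_trial) if ev_trial else np.empty(0, int)
    ev_cell = np.concatenate(ev_cell).astype(int) if len(ev_cell) else np.empty(0, int)
    ev_time = np.concatenate(ev_time) if len(ev_time) else np.empty(0)
    ev_step = np.ceil(ev_time / dt).astype(int)
    keep = ev_step < n_steps  # spikes beyond the trial window are dropped
    ev_trial, ev_cell, ev_time, ev_step = (
        a[keep] for a in (ev_trial, ev_cell, ev_time, ev_step)
    )
    order = np.argsort(ev_step, kind="stable")
    ev_trial, ev_cell, ev_time, ev_step = (
        a[order] for a in (ev_trial, ev_cell, ev_time, ev_step)
    )
    grid_offset = ev_step * dt - ev_time  # in [0, dt)
    w_fs = A["tc->fs"] * np.exp(-params.decay["tc->fs"] * grid_offset)
    w_rs = A["tc->rs"] * np.exp(-params.decay["tc->rs"] * grid_offset)
    bounds = np.searchsorted(ev_step, np.arange(n_steps + 1))

    # --- state ----------------------------------------------------------
    V_fs = np.full((n_trials, n_fs), v_rest)
    V_rs = np.full((n_trials, n_rs), v_rest)
    s_tcfs = np.zeros((n_trials, n_fs))
    s_fsfs = np.zeros((n_trials, n_fs))
    s_tcrs = np.zeros((n_trials, n_rs))
    s_fsrs = np.zeros((n_trials, n_rs))
    s_rsrs = np.zeros((n_trials, n_rs))
    ref_until_fs = np.full((n_trials, n_fs), -1)
    ref_until_rs = np.full((n_trials, n_rs), -1)
    peak_tc = np.zeros((n_trials, n_rs))
    peak_fs = np.zeros((n_trials, n_rs))

    # pending cortical arrivals: ring indexed by arrival step
    ring_len = n_steps + max(delay_steps.values()) + 2
    pending: Dict[str, list] = {
        p: [None] * ring_len for p in ("fs->fs", "fs->rs", "rs->rs")
    }

    fs_steps, fs_trials, fs_cells = [], [], []
    rs_steps, rs_trials, rs_cells = [], [], []

    record_cells = list(record_cells) if record_cells is not None else []
    if record_cells:
        rec_idx = np.asarray(record_cells, dtype=int)
        rec_tc = np.zeros((n_trials, n_steps, len(rec_idx)))
        rec_fs = np.zeros((n_trials, n_steps, len(rec_idx)))
        rec_rs = np.zeros((n_trials, n_steps, len(rec_idx)))
        rec_v = np.zeros((n_trials, n_steps, len(rec_idx)))

    def _queue(proj, step, trials, cells):
        slot = pending[proj][step]
        if slot is None:
            pending[proj][step] = [trials, cells]
        else:
            slot[0] = np.concatenate([slot[0], trials])
            slot[1] = np.concatenate([slot[1], cells])

    def _inject(proj, s, C, step):
        slot = pending[proj][step]
        if slot is not None:
            np.add.at(s, slot[0], A[proj] * C[slot[1]])
            pending[proj][step] = None

    for n in range(n_steps):
        # decay synaptic states to time t_n
        s_tcfs *= dk["tc->fs"]
        s_tcrs *= dk["tc->rs"]
        s_fsfs *= dk["fs->fs"]
        s_fsrs *= dk["fs->rs"]
        s_rsrs *= dk["rs->rs"]

        # TC arrivals at t_n (exact kernel value at the grid point)
        lo, hi = bounds[n], bounds[n + 1]
        if hi > lo:
            tr, ce = ev_trial[lo:hi], ev_cell[lo:hi]
            np.add.at(s_tcfs, tr, w_fs[lo:hi, None] * C_tcfs[ce])
            np.add.at(s_tcrs, tr, w_rs[lo:hi, None] * C_tcrs[ce])

        # cortical arrivals at t_n
        _inject("fs->fs", s_fsfs, C_fsfs, n)
        _inject("fs->rs", s_fsrs, C_fsrs, n)
        _inject("rs->rs", s_rsrs, C_rsrs, n)

        I_fs = s_tcfs - s_fsfs
        I_rs = s_tcrs - s_fsrs + s_rsrs

        np.maximum(peak_tc, s_tcrs, out=peak_tc)
        np.maximum(peak_fs, s_fsrs, out=peak_fs)
        if record_cells:
            rec_tc[:, n, :] = s_tcrs[:, rec_idx]
            rec_fs[:, n, :] = -s_fsrs[:, rec_idx]
            rec_rs[:, n, :] = s_rsrs[:, rec_idx]
            rec_v[:, n, :] = V_rs[:, rec_idx]

        # Euler update t_n -> t_{n+1}
        V_fs += dt * (-g * (V_fs - v_rest) + I_fs + ext_fs)
        V_rs += dt * (-g * (V_rs - v_rest) + I_rs + ext_rs)
        V_fs[ref_until_fs >= n] = v_rest
        V_rs[ref_until_rs >= n] = v_rest

        sp_fs = V_fs >= v_thresh
        if sp_fs.any():
            tr, ce = np.nonzero(sp_fs)
            fs_steps.append(np.full(tr.shape, n))
            fs_trials.append(tr)
            fs_cells.append(ce)
            V_fs[tr, ce] = v_rest
            ref_until_fs[tr, ce] = n + ref_steps
            _queue("fs->fs", n + 1 + delay_steps["fs->fs"], tr, ce)
            _queue("fs->rs", n + 1 + delay_steps["fs->rs"], tr, ce)
        sp_rs = V_rs >= v_thresh
        if sp_rs.any():
            tr, ce = np.nonzero(sp_rs)
            rs_steps.append(np.full(tr.shape, n))
            rs_trials.append(tr)
            rs_cells.append(ce)
            V_rs[tr, ce] = v_rest
            ref_until_rs[tr, ce] = n + ref_steps
            _queue("rs->rs", n + 1 + delay_steps["rs->rs"], tr, ce)

    if not (np.isfinite(V_fs).all() and np.isfinite(V_rs).all()):
        raise IntegrationError("non-finite membrane potential")

    def _cat(parts):
        return np.concatenate(parts) if parts else np.empty(0, int)

    fs_by_trial = _spikes_by_trial(
        _cat(fs_steps), _cat(fs_trials), _cat(fs_cells), dt, n_trials
    )
    rs_by_trial = _spikes_by_trial(
        _cat(rs_steps), _cat(rs_trials), _cat(rs_cells), dt, n_trials
    )

    results = []
    for i, ss in enumerate(tc_spike_sets):
        rec = None
        if record_cells:
            rec = {
                int(c): {
                    "tc": rec_tc[i, :, k].copy(),
                    "fs": rec_fs[i, :, k].copy(),
                    "rs": rec_rs[i, :, k].copy(),
                    "v": rec_v[i, :, k].copy(),
                }
                for k, c in enumerate(rec_idx)
            }
        results.append(
            TrialResult(
                fs_spikes=fs_by_trial[i],
                rs_spikes=rs_by_trial[i],
                peak_tc_current=peak_tc[i].copy(),
                peak_fs_current=peak_fs[i].copy(),
                stimulus=ss.stimulus,
                adapted=params.adapted,
                seed=ss.seed,
                recorded_currents=rec,
                n_rs=n_rs,
                n_fs=n_fs,
            )
        )
    return results


def simulate_trial(
    wiring: Wiring,
    params: ModelParams,
    tc_spikes: TCSpikeSet,
    record_cells: Optional[Sequence[int]] = None,
    external_current: Optional[Dict[str, float]] = None,
) -> TrialResult:
    """Integrate a single trial (see :func:`simulate_trials`)."""
    return simulate_trials(
        wiring, params, [tc_spikes], record_cells, external_current
    )[0]


def trial_seed(base_seed: int, trial_index: int) -> np.random.SeedSequence:
    """Deterministic per-trial seed stream; counter-based, so extending a
    run never perturbs earlier trials."""
    return np.random.SeedSequence(base_seed, spawn_key=(STIMULUS_STREAM, trial_index))


def run_condition(
    wiring: Wiring,
    params: ModelParams,
    spec: StimulusSpec,
    n_trials: int,
    base_seed: int,
    adapted: bool = False,
    record_cells: Optional[Sequence[int]] = None,
    batch_size: int = 600,
) -> List[TrialResult]:
    """Simulate ``n_trials`` i.i.d. deflection trials of one condition.

    If ``adapted`` and the parameters are not yet in the adapted state,
    the adaptation scaling is applied here.  Trial i draws its TC spikes
    from a deterministic sub-seed of ``base_seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if adapted and not params.adapted:
        params = apply_adaptation(params)

    from .stimulus import _invgauss_frozen, spike_probability_per_cell

    p_cell = spike_probability_per_cell(spec, wiring)
    results: List[TrialResult] = []
    for start in range(0, n_trials, batch_size):
        stop = min(start + batch_size, n_trials)
        spike_sets = []
        for i in range(start, stop):
            seq = trial_seed(base_seed, i)
            occ_rng, time_rng = (np.random.default_rng(s) for s in seq.spawn(2))
            spikes = occ_rng.random(p_cell.shape) < p_cell
            times = np.full(p_cell.shape, np.nan)
            k = int(spikes.sum())
            if k:
                dist = _invgauss_frozen(spec.mean_ms, spec.sigma_ms)
                times[spikes] = dist.rvs(size=k, random_state=time_rng)
            spike_sets.append(TCSpikeSet(spike_time_ms=times, stimulus=spec, seed=i))
        results.extend(simulate_trials(wiring, params, spike_sets, record_cells))
    return results
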