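"""Grid-based simulation of the LIF network with alpha-current synapses.

Subthreshold dynamics are integrated exactly: the linear system
``(y1, y2, U)`` with ``U = V - E_L``,

    dy1/dt = -y1/tau_s
    dy2/dt =  y1 - y2/tau_s
    dU/dt  = -U/tau_m + y2/C_m

is advanced per ``dt`` step with the precomputed propagator ``expm(A dt)``.
An incoming spike of weight ``w`` (pA) increments ``y1`` by ``w e / tau_s`` so
that the postsynaptic current ``y2`` traces ``w * alpha(t)`` with the peak
value ``w`` at lag ``tau_s``.  Threshold crossings are detected at grid points
only; on a crossing the membrane is reset and clamped for the refractory
period while the synaptic states keep evolving.

Stimulus parrots carry no dynamics: each Poisson input event reappears as an
output spike after the input delay ``d_STIM``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .connectivity import ConnectionTable, PopulationGeometry
from .params import NetworkParams, threshold_rate

__all__ = [
    "SpikeData",
    "alpha_kernel",
    "propagator",
    "LIFIntegrator",
    "poisson_drive",
    "parrot_output",
    "generate_stim_trains",
    "run_simulation",
]


@dataclass
class SpikeData:
    """Per-population spike events on the ``dt`` grid.

    ``pops`` maps population label to ``(ids, times_ms)`` arrays sorted by
    time.  ``T`` is the duration of the record (times lie in ``[0, T)``) and
    ``dt`` its resolution.
    """

    pops: dict
    T: float
    dt: float


def alpha_kernel(t, tau_s: float):
    """Dimensionless alpha kernel ``(t/tau_s) e^(1 - t/tau_s)`` for t >= 0.

    Peaks at 1 for ``t = tau_s``; zero for ``t <= 0`` (Heaviside onset).
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    t = np.asarray(t, dtype=np.float64)
    out = np.where(t > 0, (t / tau_s) * np.exp(1.0 - t / tau_s), 0.0)
    return out if out.ndim else float(out)


def propagator(p: NetworkParams) -> np.ndarray:
    """Exact one-step propagator of the (y1, y2, U) subthreshold system."""
    A = np.array([
        [-1.0 / p.tau_s, 0.0, 0.0],
        [1.0, -1.0 / p.tau_s, 0.0],
        [0.0, 1.0 / p.C_m, -1.0 / p.tau_m],
    ])
    return expm(A * p.dt)


class LIFIntegrator:
    """Vectorized LIF population state advanced one grid step at a time.

    Used directly by the network loop and by the oracle tests; ``step``
    returns the indices of units that fired.
    """

    def __init__(self, p: NetworkParams, n: int):
        self.p = p
        self.n = n
        P = propagator(p)
        self.p11 = P[0, 0]
        self.p21, self.p22 = P[1, 0], P[1, 1]
        self.p31, self.p32, self.p33 = P[2, 0], P[2, 1], P[2, 2]
        self.amp = math.e / p.tau_s  # y1 increment per pA of weight
        self.y1 = np.zeros(n)
        self.y2 = np.zeros(n)
        self.U = np.zeros(n)  # V - E_L; initial condition V = E_L
        self.ref = np.zeros(n, dtype=np.int64)
        self.ref_steps = round(p.tau_ref / p.dt)
        self.theta = p.V_theta - p.E_L
        self.u_reset = p.V_reset - p.E_L

    @property
    def V(self) -> np.ndarray:
        return self.U + self.p.E_L

    def step(self, y1_input=None) -> np.ndarray:
        """Advance one ``dt`` step.

        ``y1_input`` holds the summed ``y1`` increments (already scaled by
        ``e/tau_s``) of events arriving at the end of the step.
        """
        y1, y2 = self.y1, self.y2
        self.U = self.p31 * y1 + self.p32 * y2 + self.p33 * self.U
        self.y2 = self.p21 * y1 + self.p22 * y2
        self.y1 = self.p11 * y1
        if y1_input is not None:
            self.y1 += y1_input
        refr = self.ref > 0
        if refr.any():
            self.U[refr] = self.u_reset
            self.ref[refr] -= 1
        fired = np.nonzero(~refr & (self.U >= self.theta))[0]
        if fired.size:
            self.U[fired] = self.u_reset
            self.ref[fired] = self.ref_steps
        return fired


def poisson_drive(rate: float, n_steps: int, n_units: int, rng, dt: float):
    """Independent Poisson event counts per step and unit (mean rate*dt)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    lam = rate * dt * 1e-3  # rate in 1/s, dt in ms
    if lam == 0.0:
        return np.zeros((n_steps, n_units), dtype=np.int64)
    return rng.poisson(lam, size=(n_steps, n_units))


def parrot_output(event_times, d_STIM: float):
    """Repeat input events as output spikes delayed by ``d_STIM`` (ms)."""
    return np.asarray(event_times, dtype=np.float64) + d_STIM


def generate_stim_trains(p: NetworkParams, geom_STIM: PopulationGeometry, rng):
    """Output spikes of all parrots: (ids, times_ms, emission_steps).

    Poisson inputs are drawn on grid steps in ``[T_STIM, T_STIM + t_STIM)``;
    a count of ``m`` at one step yields ``m`` coincident output spikes
    (parrots repeat every event).  Output times are ``input + d_STIM``.
    """
    n = len(geom_STIM)
    first = math.ceil(p.T_STIM / p.dt - 1e-9)
    last = math.ceil((p.T_STIM + p.t_STIM) / p.dt - 1e-9)  # exclusive
    n_win = max(0, last - first)
    if n == 0 or n_win == 0 or p.nu_STIM == 0:
        return (np.empty(0, np.int64), np.empty(0), np.empty(0, np.int64))
    counts = rng.poisson(p.nu_STIM * p.dt * 1e-3, size=(n_win, n))
    steps, units = np.nonzero(counts)
    reps = counts[steps, units]
    steps = np.repeat(steps, reps) + first
    units = np.repeat(units, reps)
    d_steps = round(p.d_STIM / p.dt)
    emission = steps + d_steps
    times = emission * p.dt
    order = np.argsort(emission, kind="stable")
    return geom_STIM.ids[units[order]], times[order], emission[order]


class _CSR:
    """Connections grouped by source ID for fast spike delivery."""

    def __init__(self, table: ConnectionTable, id_to_slot, n_source_ids: int):
        order = np.argsort(table.source, kind="stable")
        self.targets = id_to_slot(table.target[order])
        self.weights = table.weight[order]
        self.delays = table.delay[order]
        counts = np.bincount(table.source, minlength=n_source_ids + 1)
        self.indptr = np.concatenate([[0], np.cumsum(counts)])

    def gather(self, source_ids):
        idx = np.concatenate(
            [np.arange(self.indptr[s], self.indptr[s + 1]) for s in source_ids]
        ) if len(source_ids) else np.empty(0, np.intp)
        return self.targets[idx], self.weights[idx], self.delays[idx]


def run_simulation(p: NetworkParams, geometries: dict, connections: ConnectionTable,
                   rng, stim_only: bool = False) -> SpikeData:
    """Simulate the network and return post-transient spikes.

    The record drops the first ``T_trans`` ms and shifts times so that the
    retained spikes start at 0.  With ``stim_only`` the EX/IN dynamics are
    skipped and only the parrot population is driven.
    """
    geom_EX, geom_IN, geom_STIM = (geometries[k] for k in ("EX", "IN", "STIM"))
    rng_net, rng_stim = rng.spawn(2)
    stim_ids, stim_times, stim_steps = generate_stim_trains(p, geom_STIM, rng_stim)

    raw = {"STIM": (stim_ids, stim_times)}
    if stim_only:
        raw["EX"] = (np.empty(0, np.int64), np.empty(0))
        raw["IN"] = (np.empty(0, np.int64), np.empty(0))
    else:
        raw.update(_run_network(
            p, geom_EX, geom_IN, connections, rng_net, stim_steps, stim_ids))

    pops = {}
    for label, (ids, times) in raw.items():
        keep = (times >= p.T_trans) & (times < p.T_sim)
        pops[label] = (ids[keep], times[keep] - p.T_trans)
    return SpikeData(pops=pops, T=p.T_record, dt=p.dt)


def _run_network(p, geom_EX, geom_IN, connections, rng, stim_steps, stim_ids):
    n_ex, n_in = len(geom_EX), len(geom_IN)
    N = n_ex + n_in
    all_ids = np.concatenate([geom_EX.ids, geom_IN.ids])
    id0 = int(all_ids.min()) if N else 1
    if N and not np.array_equal(all_ids, np.arange(id0, id0 + N)):
        raise ValueError("EX/IN geometry IDs must form one contiguous block")
    if len(connections):
        bad_t = ~np.isin(connections.target, all_ids, assume_unique=False)
        if bad_t.any():
            raise ValueError("connection targets reference IDs outside EX/IN geometry")

    def id_to_slot(ids):
        return (np.asarray(ids, dtype=np.int64) - id0).astype(np.intp)

    max_id = id0 + N - 1
    if len(connections):
        max_id = max(max_id, int(connections.source.max()))
    if len(stim_ids):
        max_id = max(max_id, int(stim_ids.max()))
    csr = _CSR(connections, id_to_slot, max_id)
    D = int(connections.delay.max()) + 1 if len(connections) else 2
    buffer = np.zeros((D, N))

    lif = LIFIntegrator(p, N)
    nu_ext = p.eta * threshold_rate(p) if p.eta > 0 else 0.0
    drive_inc = p.J * lif.amp

    # group parrot emissions by step for delivery into the recurrent loop
    stim_by_step: dict[int, np.ndarray] = {}
    if len(stim_steps):
        uniq, start = np.unique(stim_steps, return_index=True)
        splits = np.split(np.arange(len(stim_steps)), start[1:])
        for s, seg in zip(uniq, splits):
            stim_by_step[int(s)] = stim_ids[seg]

    n_steps = p.n_steps
    out_ids, out_steps = [], []
    chunk = 1000
    counts = None
    for n in range(n_steps):
        if nu_ext > 0 and n % chunk == 0:
            counts = rng.poisson(nu_ext * p.dt * 1e-3, size=(min(chunk, n_steps - n), N))
        slot = (n + 1) % D
        y1_in = buffer[slot].copy()
        buffer[slot] = 0.0
        if nu_ext > 0:
            y1_in += counts[n % chunk] * drive_inc
        fired = lif.step(y1_in)
        arrival_step = n + 1
        if fired.size:
            out_ids.append(fired + id0)
            out_steps.append(np.full(fired.size, arrival_step, dtype=np.int64))
            t, w, d = csr.gather(fired + id0)
            if len(t):
                np.add.at(buffer, ((arrival_step + d) % D, t), w * lif.amp)
        parrots = stim_by_step.get(arrival_step)
        if parrots is not None:
            t, w, d = csr.gather(parrots)
            if len(t):
                np.add.at(buffer, ((arrival_step + d) % D, t), w * lif.amp)

    if out_ids:
        ids = np.concatenate(out_ids)
        times = np.concatenate(out_steps) * p.dt
    else:
        ids = np.empty(0, np.int64)
        times = np.empty(0)
    ex_mask = ids <= (geom_EX.ids.max() if n_ex else 0)
    return {
        "EX": (ids[ex_mask], times[ex_mask]),
        "IN": (ids[~ex_mask], times[~ex_mask]),
    }
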