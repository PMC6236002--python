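"""Spatiotemporal binning of spike data into instantaneous spike-count rates.

A spike of a unit at position ``(x, y)`` (mm) and time ``t`` (ms) lands in the
half-open bin ``lx = floor((x + L/2)/dl)``, ``ly = floor((y + L/2)/dl)``,
``k = floor(t/dt_bin)``; the bin value is the spike count divided by the
temporal bin width, in spikes/s.  The grid has ``L/dl`` bins per spatial axis
and ``T/dt_bin`` temporal bins.

The ``align="center"`` variant shifts the temporal partition by half a bin so
that bin ``k`` covers ``[k dt_bin - dt_bin/2, k dt_bin + dt_bin/2)``; this is
the animation-frame convention in which a frame is centered on its time step.
File output always uses the left-edge convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import PopulationGeometry
from .simulator import SpikeData

__all__ = ["BinnedRates", "bin_spikes", "bin_spikedata", "total_rate_series"]


@dataclass
class BinnedRates:
    """Instantaneous spike-count rate grid of one population.

    ``rates`` has shape ``(Lx, Ly, K)`` in spikes/s; every value is an
    integer multiple of ``1/dt_bin`` and the sum ``rates * dt_bin`` equals
    the population's spike count (conservation).
    """

    population: str
    rates: np.ndarray
    dt_bin: float   # ms
    dl_bin: float   # mm
    L: float        # mm
    T: float        # ms

    @property
    def shape(self):
        return self.rates.shape

    def counts(self) -> np.ndarray:
        return np.rint(self.rates * self.dt_bin * 1e-3).astype(np.int64)


def bin_spikes(ids, times, pos_ids, x, y, dt_bin, dl_bin, L, T,
               population: str = "", align: str = "left") -> BinnedRates:
    """Bin spike events into a ``(Lx, Ly, K)`` rate grid.

    Parameters
    ----------
    ids, times:
        Spike events (unit ID, time in ms); times must lie in ``[0, T)``.
    pos_ids, x, y:
        Unit positions; every spiking ID must be present.  Positions must lie
        in ``[-L/2, L/2)``; a position exactly on the right/top boundary is
        wrapped to bin 0 (torus) with a warning.
    align:
        ``"left"`` for the file-format convention, ``"center"`` for
        animation-style frames (indices clipped to the grid).
    """
    Lx = round(L / dl_bin)
    K = round(T / dt_bin)
    ids = np.asarray(ids, dtype=np.int64)
    times = np.asarray(times, dtype=np.float64)
    pos_ids = np.asarray(pos_ids, dtype=np.int64)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.any((x < -L / 2) | (x > L / 2)) or np.any((y < -L / 2) | (y > L / 2)):
        raise ValueError(f"positions outside [-{L/2}, {L/2})")
    if times.size and (times.min() < 0 or times.max() >= T):
        raise ValueError(f"spike times outside [0, {T}) ms")

    order = np.argsort(pos_ids)
    pos_sorted = pos_ids[order]
    loc = np.searchsorted(pos_sorted, ids)
    if ids.size and (np.any(loc >= len(pos_sorted)) or
                     np.any(pos_sorted[np.minimum(loc, len(pos_sorted) - 1)] != ids)):
        raise ValueError("spike IDs missing from the position table")
    sel = order[loc] if ids.size else np.empty(0, np.intp)

    lx = np.floor((x[sel] + L / 2) / dl_bin).astype(np.intp)
    ly = np.floor((y[sel] + L / 2) / dl_bin).astype(np.intp)
    if np.any(lx >= Lx) or np.any(ly >= Lx):
        warnings.warn("position on the domain boundary wrapped to bin 0 (torus)")
        lx %= Lx
        ly %= Lx
    # the 1e-7 epsilon keeps grid times (n*dt) from flooring one bin low
    # when t/dt_bin is an integer that is not exactly representable
    if align == "center":
        k = np.floor(times / dt_bin + 0.5 + 1e-7).astype(np.intp).clip(0, K - 1)
    elif align == "left":
        k = np.floor(times / dt_bin + 1e-7).astype(np.intp).clip(0, K - 1)
    else:
        raise ValueError("align must be 'left' or 'center'")

    counts = np.zeros((Lx, Lx, K), dtype=np.float64)
    np.add.at(counts, (lx, ly, k), 1.0)
    rates = counts / (dt_bin * 1e-3)
    return BinnedRates(population, rates, dt_bin, dl_bin, L, T)


def bin_spikedata(spikes: SpikeData, geometries: dict, dt_bin, dl_bin, L,
                  align: str = "left") -> dict:
    """Bin every population of a simulation record; returns label -> grid."""
    out = {}
    for label, (ids, times) in spikes.pops.items():
        geom: PopulationGeometry = geometries[label]
        out[label] = bin_spikes(
            ids, times, geom.ids, geom.x, geom.y,
            dt_bin, dl_bin, L, spikes.T, population=label, align=align,
        )
    return out


def total_rate_series(binned: dict):
    """Population-summed rate series and per-population fractions.

    ``nu_k = sum_X sum_lx sum_ly rates / (Lx * Ly)`` per temporal bin, plus
    each population's share of the grand sum.  Bins with no activity report
    fraction 0 for every population (finite values for stacked displays).
    """
    grids = list(binned.values())
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or g.dt_bin != ref.dt_bin or g.dl_bin != ref.dl_bin:
            raise ValueError("populations have mismatched bin grids")
    Lx, Ly, _ = ref.shape
    pop_sums = {label: g.rates.sum(axis=(0, 1)) for label, g in binned.items()}
    grand = sum(pop_sums.values())
    nu_k = grand / (Lx * Ly)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = {
            label: np.where(grand > 0, s / np.where(grand > 0, grand, 1.0), 0.0)
            for label, s in pop_sums.items()
        }
    return nu_k, fractions
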