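"""Deterministic toy datasets for fast testing of every downstream module.

A :class:`ToySpec` describes a miniature layered recording — a few units on a
small sheet for a short duration — together with scripted spike patterns
whose binned footprints are predictable (a single spike in a named bin, a
planar wave sweeping across columns).  ``make_toy_dataset`` writes the spike,
position and binned files in the standard text formats so the io layer,
binning and the views can be exercised in milliseconds.

Fixtures are committed as generator code only, never as data artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .binning import bin_spikes

__all__ = ["ToySpec", "make_toy_dataset", "PRESETS"]


@dataclass
class ToySpec:
    """Description of a miniature dataset (all sizes deliberately tiny)."""

    populations: dict = field(default_factory=lambda: {"A": 20})
    L: float = 1.0          # mm
    T: float = 20.0         # ms
    dt_bin: float = 1.0     # ms
    dl_bin: float = 0.25    # mm
    seed: int = 0
    patterns: list = field(default_factory=list)

    def validate(self) -> None:
        if any(n > 100 for n in self.populations.values()):
            raise ValueError("toy populations are capped at 100 units")
        if self.L > 1.0 or self.T > 100.0:
            raise ValueError("toy extent/duration exceeded (L <= 1 mm, T <= 100 ms)")


def _bin_center(spec: ToySpec, lx, ly):
    x = (lx + 0.5) * spec.dl_bin - spec.L / 2
    y = (ly + 0.5) * spec.dl_bin - spec.L / 2
    return x, y


def make_toy_dataset(spec: ToySpec, outdir) -> dict:
    """Write spike/position/binned files; returns per-population metadata.

    Patterns (each a dict with a ``kind`` key, applied to ``population``):

    * ``single_bin``: one spike of unit 0 (moved to the bin center) in the
      spatiotemporal bin ``(lx, ly, k)``,
    * ``wave``: a planar wave along x: all units of column ``round(speed*k)``
      spike once in temporal bin ``k`` (``speed`` in bins per bin),
    * ``uniform``: every unit spikes once per temporal bin.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    Lx = round(spec.L / spec.dl_bin)
    K = round(spec.T / spec.dt_bin)

    meta = {}
    next_id = 1
    for label, n in spec.populations.items():
        ids = np.arange(next_id, next_id + n, dtype=np.int64)
        next_id += n
        x = rng.uniform(-spec.L / 2, spec.L / 2, n)
        y = rng.uniform(-spec.L / 2, spec.L / 2, n)
        sp_ids, sp_t = [], []
        for pat in spec.patterns:
            if pat.get("population", label) != label:
                continue
            kind = pat["kind"]
            if kind == "single_bin":
                x[0], y[0] = _bin_center(spec, pat["lx"], pat["ly"])
                sp_ids.append(ids[0])
                sp_t.append((pat["k"] + 0.5) * spec.dt_bin)
            elif kind == "wave":
                speed = pat.get("speed", 1.0)
                cols = np.floor((x + spec.L / 2) / spec.dl_bin).astype(int)
                for k in range(K):
                    col = round(speed * k)
                    if col >= Lx:
                        break
                    for u in np.nonzero(cols == col)[0]:
                        sp_ids.append(ids[u])
                        sp_t.append((k + 0.5) * spec.dt_bin)
            elif kind == "uniform":
                for k in range(K):
                    sp_ids.extend(ids.tolist())
                    sp_t.extend([(k + 0.5) * spec.dt_bin] * n)
            else:
                raise ValueError(f"unknown pattern kind: {kind}")
        sp_ids = np.asarray(sp_ids, dtype=np.int64)
        sp_t = np.asarray(sp_t, dtype=np.float64)
        order = np.argsort(sp_t, kind="stable")
        sp_ids, sp_t = sp_ids[order], sp_t[order]

        io_formats.write_spikes(outdir / f"spikes_{label}.dat", sp_ids, sp_t)
        io_formats.write_positions(outdir / f"positions_{label}.dat", ids, x, y)
        binned = bin_spikes(sp_ids, sp_t, ids, x, y, spec.dt_bin, spec.dl_bin,
                            spec.L, spec.T, population=label)
        io_formats.write_binned(outdir / f"binned_{label}.dat", binned.rates)
        meta[label] = {
            "ids": ids, "x": x, "y": y,
            "spike_ids": sp_ids, "spike_times": sp_t,
            "shape": (Lx, Lx, K),
        }
    return meta


PRESETS = {
    "empty": ToySpec(patterns=[]),
    "single-spike": ToySpec(
        patterns=[{"kind": "single_bin", "population": "A", "lx": 3, "ly": 1, "k": 7}]
    ),
    "wave": ToySpec(
        populations={"A": 40},
        patterns=[{"kind": "wave", "population": "A", "speed": 0.25}],
    ),
    "uniform": ToySpec(patterns=[{"kind": "uniform", "population": "A"}]),
}
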