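"""Unit placement and distance-dependent wiring on the torus.

Excitatory (EX) and inhibitory (IN) units are placed uniformly on the square
sheet ``[-L/2, L/2)^2``; stimulus (STIM) parrots are placed uniformly inside a
disc of radius ``R_STIM`` around the origin.  Recurrent connections use
convergent fixed in-degree sampling: each target draws exactly
``round(c * N_X)`` sources from population ``X``, with categorical weights
given by the Gaussian profile ``p_YX(r) = exp(-r^2 / (2 sigma_YX^2))``
evaluated at torus distances.  Sampling is with replacement (multapses
allowed) excluding the target itself (no autapses).  The divergent STIM->EX
projection gives every parrot exactly ``K_STIM`` targets drawn uniformly, with
replacement, among EX units within torus distance ``R``.

Transmission delays follow ``d_YX(r) = d0_YX + r / v_YX`` (no distance term
when the velocity is absent), rounded to the simulation grid with a one-step
floor: spike events live on the ``dt`` grid, so a zero delay is not
representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .params import NetworkParams

__all__ = [
    "PopulationGeometry",
    "ConnectionTable",
    "torus_distance",
    "gaussian_profile",
    "delay_steps",
    "sample_positions",
    "build_geometries",
    "build_recurrent",
    "build_stim",
]


@dataclass
class PopulationGeometry:
    """Unit IDs and positions (mm) of one population."""

    label: str
    ids: np.ndarray   # contiguous positive int64, globally unique
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ConnectionTable:
    """Synapse records: source ID, target ID, weight (pA), delay (dt steps)."""

    source: np.ndarray
    target: np.ndarray
    weight: np.ndarray
    delay: np.ndarray

    def __len__(self) -> int:
        return len(self.source)

    @staticmethod
    def empty() -> "ConnectionTable":
        return ConnectionTable(
            np.empty(0, np.int64), np.empty(0, np.int64),
            np.empty(0, np.float64), np.empty(0, np.int64),
        )

    @staticmethod
    def concatenate(tables) -> "ConnectionTable":
        return ConnectionTable(
            np.concatenate([t.source for t in tables]),
            np.concatenate([t.target for t in tables]),
            np.concatenate([t.weight for t in tables]),
            np.concatenate([t.delay for t in tables]),
        )

    def write_text(self, path) -> None:
        """Debugging dump: ``source target weight_pA delay_steps`` rows."""
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            for s, t, w, d in zip(self.source, self.target, self.weight, self.delay):
                fh.write(f"{int(s)} {int(t)} {w:g} {int(d)}\n")


def torus_distance(a, b, L: float):
    """Euclidean distance with per-axis periodic wrap (minimum image).

    ``a`` and ``b`` are ``(..., 2)`` position arrays in mm; points outside the
    domain are wrapped in first.  The result never exceeds ``L / sqrt(2)``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    d = np.abs(a - b) % L
    d = np.minimum(d, L - d)
    return np.hypot(d[..., 0], d[..., 1])


def gaussian_profile(r, sigma: float):
    """Connection-probability kernel ``exp(-r^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = np.asarray(r, dtype=np.float64)
    return np.exp(-(r ** 2) / (2.0 * sigma ** 2))


def delay_steps(r, d0: float, v: float | None, dt: float):
    """Distance-dependent delay in integer ``dt`` steps, floored at one step.

    ``r`` in mm, ``d0`` in ms, ``v`` in m/s (``None`` drops the distance
    term; note mm / (m/s) = ms so no numeric conversion is needed).
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("distances must be >= 0")
    if d0 < 0:
        raise ValueError("delay offset must be >= 0")
    d = d0 + (r / v if v is not None else 0.0)
    steps = np.maximum(1, np.rint(d / dt)).astype(np.int64)
    return steps if steps.ndim else int(steps)


def sample_positions(label: str, params: NetworkParams, rng, id_start: int = 1
                     ) -> PopulationGeometry:
    """Draw unit positions for one population.

    EX/IN are uniform on the half-open square; STIM is uniform on the disc of
    radius ``R_STIM`` (polar sampling with a square-root radial transform).
    """
    n = {"EX": params.N_EX, "IN": params.N_IN, "STIM": params.N_STIM}[label]
    ids = np.arange(id_start, id_start + n, dtype=np.int64)
    if n == 0:
        return PopulationGeometry(label, ids, np.empty(0), np.empty(0))
    if label == "STIM":
        radius = params.R_STIM * np.sqrt(rng.random(n))
        angle = rng.random(n) * 2.0 * np.pi
        x = radius * np.cos(angle)
        y = radius * np.sin(angle)
    else:
        x = rng.uniform(-params.L / 2, params.L / 2, n)
        y = rng.uniform(-params.L / 2, params.L / 2, n)
    return PopulationGeometry(label, ids, x, y)


def build_geometries(params: NetworkParams, rng) -> dict:
    """Place all three populations with contiguous global ID blocks."""
    geoms = {}
    start = 1
    for label in ("EX", "IN", "STIM"):
        geom = sample_positions(label, params, rng, id_start=start)
        geoms[label] = geom
        start += len(geom)
    return geoms


def _draw_sources(tx, ty, sx, sy, k, sigma, L, rng, self_index=None):
    """Draw ``k`` source indices with Gaussian-of-distance categorical weights.

    Sampling is with replacement; ``self_index`` (if given) is excluded by
    zeroing its weight.
    """
    d = torus_distance(
        np.stack([np.broadcast_to(tx, sx.shape), np.broadcast_to(ty, sy.shape)], -1),
        np.stack([sx, sy], -1),
        L,
    )
    w = gaussian_profile(d, sigma)
    if self_index is not None:
        w = w.copy()
        w[self_index] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("no admissible sources (all categorical weights zero)")
    # inverse-CDF sampling; cheaper than rng.choice for repeated small draws
    cdf = np.cumsum(w)
    return np.searchsorted(cdf, rng.random(k) * total, side="right").clip(0, len(w) - 1)


def build_recurrent(geom_EX: PopulationGeometry, geom_IN: PopulationGeometry,
                    params: NetworkParams, rng) -> ConnectionTable:
    """Fixed in-degree recurrent wiring for all EX and IN targets."""
    sources = {"EX": geom_EX, "IN": geom_IN}
    tables = []
    for src_label, src in sources.items():
        k = round(params.c * len(src))
        if k == 0:
            continue
        if len(src) == 0:
            raise ValueError(
                f"source population {src_label} is empty but in-degree {k} requested"
            )
        for tgt_label, tgt in (("EX", geom_EX), ("IN", geom_IN)):
            if len(tgt) == 0:
                continue
            pair = f"{tgt_label}_{src_label}"
            sigma = params.sigma_YX[pair]
            weight = params.g_YX[pair] * params.J
            d0, v = params.d0_YX[pair], params.v_YX[pair]
            src_ids, tgt_ids, delays = [], [], []
            for i in range(len(tgt)):
                self_index = i if src_label == tgt_label else None
                picks = _draw_sources(
                    tgt.x[i], tgt.y[i], src.x, src.y, k, sigma, params.L, rng,
                    self_index=self_index,
                )
                r = torus_distance(
                    np.stack([np.broadcast_to(tgt.x[i], picks.shape),
                              np.broadcast_to(tgt.y[i], picks.shape)], -1),
                    np.stack([src.x[picks], src.y[picks]], -1),
                    params.L,
                )
                src_ids.append(src.ids[picks])
                tgt_ids.append(np.full(k, tgt.ids[i], dtype=np.int64))
                delays.append(delay_steps(r, d0, v, params.dt))
            src_ids = np.concatenate(src_ids)
            tables.append(ConnectionTable(
                src_ids,
                np.concatenate(tgt_ids),
                np.full(src_ids.shape, weight, dtype=np.float64),
                np.concatenate(delays),
            ))
    if not tables:
        return ConnectionTable.empty()
    return ConnectionTable.concatenate(tables)


def build_stim(geom_STIM: PopulationGeometry, geom_EX: PopulationGeometry,
               params: NetworkParams, rng) -> ConnectionTable:
    """Divergent STIM->EX wiring: ``K_STIM`` targets per parrot inside the mask.

    Targets are drawn uniformly with replacement among EX units within torus
    distance ``R`` (multapses allowed, matching divergent mask connections in
    grid-based network simulators).  An empty mask raises an error naming the
    offending unit.
    """
    if params.K_STIM == 0 or len(geom_STIM) == 0:
        return ConnectionTable.empty()
    if len(geom_EX) == 0:
        raise ValueError("EX population is empty but K_STIM > 0")
    # periodic neighbor search; cKDTree boxsize requires coordinates in [0, L)
    shift = params.L / 2.0
    tree = cKDTree(
        np.mod(np.column_stack([geom_EX.x + shift, geom_EX.y + shift]), params.L),
        boxsize=params.L,
    )
    queries = np.mod(
        np.column_stack([geom_STIM.x + shift, geom_STIM.y + shift]), params.L
    )
    candidates = tree.query_ball_point(queries, params.R)
    weight = params.g_YX["EX_STIM"] * params.J
    delay = delay_steps(np.float64(0.0), params.d0_YX["EX_STIM"],
                        params.v_YX.get("EX_STIM"), params.dt)
    src_ids, tgt_ids = [], []
    for i, cand in enumerate(candidates):
        if not cand:
            raise ValueError(
                f"STIM unit {int(geom_STIM.ids[i])} has no EX candidates within "
                f"mask radius {params.R} mm"
            )
        cand = np.asarray(cand)
        picks = cand[rng.integers(0, len(cand), params.K_STIM)]
        src_ids.append(np.full(params.K_STIM, geom_STIM.ids[i], dtype=np.int64))
        tgt_ids.append(geom_EX.ids[picks])
    src_ids = np.concatenate(src_ids)
    return ConnectionTable(
        src_ids,
        np.concatenate(tgt_ids),
        np.full(src_ids.shape, weight, dtype=np.float64),
        np.full(src_ids.shape, delay, dtype=np.int64),
    )
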