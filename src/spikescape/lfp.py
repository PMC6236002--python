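"""Phenomenological spike-to-LFP forward model.

The pipeline maps binned population spiking to extracellular potentials on a
square electrode grid in four stages:

1. **Passive cable response.**  A ball-and-stick neuron (spherical soma plus a
   vertical dendritic stick of ``n_dend`` equal segments) inherits the point
   neuron's membrane capacitance: the soma radius is chosen so that the total
   membrane area equals ``C_m / c_m``.  A single synapse activation injects an
   alpha-shaped current (the network's synapse model) either distributed
   evenly along the stick (excitatory sources) or onto the soma (inhibitory
   sources).  The linear compartment system, augmented with the two synaptic
   state variables, is advanced by its exact exponential propagator per ``dt``
   step; transmembrane currents follow from the axial-coupling identity, which
   conserves charge to machine precision.

2. **Electrostatic forward model.**  In a homogeneous ohmic medium of
   conductivity ``sigma_e`` the soma contributes as a spherical (point-like)
   source and each dendritic segment as a line source with the closed-form
   potential of the point kernel integrated along its axis.  Source-electrode
   distances are floored at the segment radius.  Electrode contacts are
   squares of side ``dl_phi`` in the z = 0 plane, averaged on an m x m grid.

3. **Kernel assembly.**  For each presynaptic population X the out-degree
   ``K_X`` is distributed over spatial bins proportionally to the connection
   profile evaluated at bin-center distances (Gaussian for EX/IN, mask disc
   for STIM).  The kernel ``H_X(displacement, lag)`` is the synapse-count map
   spatially convolved (with periodic wrap) with the single-synapse response
   delayed by the distance-dependent conduction delay.

4. **LFP synthesis.**  Spikes are binned at ``(dl_phi, dt)``, smoothed by a
   normalized boxcar of length ``dt_bin``, convolved with ``H_X`` in space
   (circular) and time (linear), summed over populations, low-pass filtered
   (4th-order zero-phase Butterworth at 0.4 / dt_bin kHz) and downsampled to
   ``dt_bin``.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import expm
from scipy.signal import butter, lfilter, sosfiltfilt

from .binning import bin_spikes
from .params import LFPParams, NetworkParams, derive, derive_soma_radius
from .simulator import SpikeData

__all__ = [
    "CableModel",
    "PassiveResponse",
    "SingleSynapseResponse",
    "KernelSet",
    "LFPGrid",
    "build_cable",
    "solve_passive_response",
    "line_source_factor",
    "point_source_factor",
    "geometry_factors",
    "forward_potential",
    "contact_average_factors",
    "single_synapse_kernel",
    "activated_synapse_counts",
    "assemble_kernel",
    "build_kernels",
    "synthesize_lfp",
]

_MV_PER_PA = 1e-3  # pA / (S/m * um) -> mV


@dataclass
class CableModel:
    """Unbranched soma+stick compartment chain (lengths in um).

    Compartment 0 is the soma, modeled as a sphere for membrane area and for
    the forward model, and as the area-equivalent cylinder (length equal to
    its diameter) for the axial path.  Compartments 1..n_dend are the stick
    segments stacked along +z starting at the soma surface.
    """

    z0: np.ndarray        # segment start, um
    z1: np.ndarray        # segment end, um
    radius: np.ndarray    # um
    area: np.ndarray      # um^2
    C: np.ndarray         # pF
    g: np.ndarray         # leak, nS
    L_ax: np.ndarray      # axial coupling Laplacian, nS
    E_L: float            # mV
    tau_s: float          # synaptic current time constant, ms
    r_soma: float         # um

    @property
    def n_comp(self) -> int:
        return len(self.C)


def build_cable(p: NetworkParams, lp: LFPParams, n_dend: int | None = None) -> CableModel:
    """Construct the ball-and-stick model from network + LFP parameters."""
    if n_dend is None:
        n_dend = lp.n_dend
    if n_dend == 0:
        r_soma = math.sqrt(p.C_m * 100.0 / lp.c_m / (4.0 * math.pi))
    else:
        r_soma = derive_soma_radius(lp, p.C_m)
    c_m = lp.c_m * 0.01        # pF / um^2
    r_a = lp.r_a * 1e-5        # GOhm * um

    n = n_dend + 1
    radius = np.full(n, lp.r_dend)
    radius[0] = r_soma
    length = np.full(n, lp.L_dend / max(n_dend, 1))
    length[0] = 2.0 * r_soma
    z0 = np.empty(n)
    z1 = np.empty(n)
    z0[0], z1[0] = -r_soma, r_soma
    for i in range(1, n):
        z0[i] = z1[i - 1]
        z1[i] = z0[i] + length[i]
    area = 2.0 * math.pi * radius * length
    area[0] = 4.0 * math.pi * r_soma ** 2
    C = c_m * area
    g = C / p.tau_m

    L_ax = np.zeros((n, n))
    for i in range(n - 1):
        R = (r_a * length[i] / 2.0 / (math.pi * radius[i] ** 2)
             + r_a * length[i + 1] / 2.0 / (math.pi * radius[i + 1] ** 2))
        ga = 1.0 / R
        L_ax[i, i] -= ga
        L_ax[i + 1, i + 1] -= ga
        L_ax[i, i + 1] += ga
        L_ax[i + 1, i] += ga
    return CableModel(z0, z1, radius, area, C, g, L_ax,
                      E_L=p.E_L, tau_s=p.tau_s, r_soma=r_soma)


@dataclass
class PassiveResponse:
    """Time-resolved response of the cable to one synapse activation."""

    t: np.ndarray        # ms
    I_m: np.ndarray      # (n_t, n_comp) transmembrane currents, pA
    V: np.ndarray        # (n_t, n_comp) membrane potentials, mV
    I_syn: np.ndarray    # (n_t, n_comp) synaptic input currents, pA


def solve_passive_response(cable: CableModel, syn_kind: str, weight: float,
                           duration: float, dt: float, t_act: float = 0.0
                           ) -> PassiveResponse:
    """Exact-propagator solution for a single alpha-current synapse.

    ``syn_kind`` is ``"dendritic"`` (total current split evenly over the
    stick segments, excitatory convention) or ``"somatic"`` (inhibitory
    convention).  The synapse activates at ``t_act`` (must lie on the grid);
    total injected current is ``weight * alpha(t - t_act)``.
    """
    n = cable.n_comp
    frac = np.zeros(n)
    if syn_kind == "dendritic" and n > 1:
        frac[1:] = 1.0 / (n - 1)
    elif syn_kind in ("somatic", "dendritic"):
        frac[0] = 1.0  # soma-only model: all input on the single compartment
    else:
        raise ValueError("syn_kind must be 'dendritic' or 'somatic'")

    m = n + 2  # state: (y1, y2, U_0..U_{n-1})
    A = np.zeros((m, m))
    A[0, 0] = -1.0 / cable.tau_s
    A[1, 0] = 1.0
    A[1, 1] = -1.0 / cable.tau_s
    A[2:, 1] = frac / cable.C
    A[2:, 2:] = (cable.L_ax - np.diag(cable.g)) / cable.C[:, None]
    P = expm(A * dt)

    n_t = round(duration / dt) + 1
    i_act = round(t_act / dt)
    amp = weight * math.e / cable.tau_s
    states = np.zeros((n_t, m))
    s = np.zeros(m)
    if i_act == 0:
        s[0] += amp
    states[0] = s
    for i in range(1, n_t):
        s = P @ s
        if i == i_act:
            s[0] += amp
        states[i] = s

    U = states[:, 2:]
    I_m = U @ cable.L_ax.T  # axial inflow == membrane outflow, charge-exact
    I_syn = states[:, 1:2] * frac[None, :]
    t = np.arange(n_t) * dt
    return PassiveResponse(t=t, I_m=I_m, V=U + cable.E_L, I_syn=I_syn)


def point_source_factor(distance, sigma_e: float, min_distance: float = 0.0):
    """Potential per unit current of a point/sphere source, mV per pA."""
    d = np.maximum(np.asarray(distance, dtype=np.float64), min_distance)
    return _MV_PER_PA / (4.0 * math.pi * sigma_e * d)


def line_source_factor(z0, z1, rho, z_e, sigma_e: float, min_rho: float = 0.0):
    """Closed-form line-source potential per unit current, mV per pA.

    The point kernel integrated along the segment axis from ``z0`` to ``z1``
    for an electrode at lateral distance ``rho`` and height ``z_e`` (um).
    """
    rho = np.maximum(np.asarray(rho, dtype=np.float64), min_rho)
    a = z0 - np.asarray(z_e, dtype=np.float64)
    b = z1 - np.asarray(z_e, dtype=np.float64)
    log_term = np.log(
        (b + np.sqrt(b ** 2 + rho ** 2)) / (a + np.sqrt(a ** 2 + rho ** 2))
    )
    return _MV_PER_PA / (4.0 * math.pi * sigma_e * (z1 - z0)) * log_term


def geometry_factors(cable: CableModel, points, sigma_e: float) -> np.ndarray:
    """Per-compartment forward factors for electrodes at ``points`` (um).

    Returns ``(n_points, n_comp)`` in mV per pA.  The soma maps through the
    sphere/point formula, stick segments through the line-source integral;
    distances are floored at the respective radius.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = cable.n_comp
    F = np.empty((len(pts), n))
    d_soma = np.sqrt(((pts - [0.0, 0.0, 0.0]) ** 2).sum(axis=1))
    F[:, 0] = point_source_factor(d_soma, sigma_e, min_distance=cable.r_soma)
    rho = np.hypot(pts[:, 0], pts[:, 1])
    for i in range(1, n):
        F[:, i] = line_source_factor(
            cable.z0[i], cable.z1[i], rho, pts[:, 2], sigma_e,
            min_rho=cable.radius[i],
        )
    return F


def forward_potential(cable: CableModel, I_m: np.ndarray, point, sigma_e: float
                      ) -> np.ndarray:
    """Extracellular potential time series (mV) at one electrode position."""
    F = geometry_factors(cable, [point], sigma_e)[0]
    return I_m @ F


def contact_average_factors(cable: CableModel, center_xy, side: float,
                            sigma_e: float, m: int = 10) -> np.ndarray:
    """Forward factors averaged over a square contact in the z = 0 plane.

    The contact of side length ``side`` (um) centered at ``center_xy`` is
    sampled on an ``m x m`` regular grid; ``m = 1`` reduces to center-point
    evaluation.
    """
    cx, cy = center_xy
    offs = (np.arange(m) + 0.5) / m - 0.5
    gx, gy = np.meshgrid(cx + offs * side, cy + offs * side, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(m * m)])
    return geometry_factors(cable, pts, sigma_e).mean(axis=0)


@dataclass
class SingleSynapseResponse:
    """Contact-averaged potential traces at the unique bin distances."""

    syn_kind: str
    weight: float          # pA
    distances: np.ndarray  # um, sorted unique bin center-to-center distances
    series: np.ndarray     # (n_r, n_t) mV
    dt: float              # ms
    t_act: float           # ms


def _grid_displacements(L_mm: float, dl_phi_um: float):
    """Minimum-image displacement indices and distances of the periodic grid."""
    Lphi = round(L_mm * 1000.0 / dl_phi_um)
    idx = np.arange(Lphi)
    m = (idx + Lphi // 2) % Lphi - Lphi // 2
    mx, my = np.meshgrid(m, m, indexing="ij")
    r_um = np.hypot(mx, my) * dl_phi_um
    return Lphi, r_um


def single_synapse_kernel(p: NetworkParams, lp: LFPParams, syn_kind: str,
                          weight: float, contact_m: int = 10) -> SingleSynapseResponse:
    """Spatially averaged potential of one synapse activation.

    The ball-and-stick neuron sits at the center of a reference bin; traces
    are evaluated at the unique subset of bin center-to-center distances of
    the periodic electrode grid (rotational symmetry of the cell makes the
    response a function of distance only), for a duration of twice the
    activation time ``tau_syn_act`` at resolution ``dt``.
    """
    _, r_um = _grid_displacements(p.L, lp.dl_phi)
    distances = np.unique(np.round(r_um, 6))
    cable = build_cable(p, lp)
    resp = solve_passive_response(
        cable, syn_kind, weight,
        duration=2.0 * lp.tau_syn_act, dt=p.dt, t_act=lp.tau_syn_act,
    )
    F = np.stack([
        contact_average_factors(cable, (r, 0.0), lp.dl_phi, lp.sigma_e, m=contact_m)
        for r in distances
    ])
    series = F @ resp.I_m.T
    return SingleSynapseResponse(
        syn_kind=syn_kind, weight=weight, distances=distances,
        series=series, dt=p.dt, t_act=lp.tau_syn_act,
    )


def activated_synapse_counts(X: str, p: NetworkParams, lp: LFPParams):
    """Per-bin activated synapse counts ``K_b`` on the periodic grid.

    The presynaptic out-degree ``K_X`` is split over bins proportionally to
    the connection profile at bin-center distances: the Gaussian kernel for
    EX/IN sources, the cut-off mask disc for STIM.  Returns ``(K_map, r_mm)``
    arrays of shape ``(Lphi, Lphi)`` in roll (minimum-image) coordinates.
    """
    _, r_um = _grid_displacements(p.L, lp.dl_phi)
    r_mm = r_um / 1000.0
    if X == "STIM":
        profile = (r_mm <= p.R).astype(np.float64)
    else:
        sigma = p.sigma_YX[f"EX_{X}"]
        profile = np.exp(-(r_mm ** 2) / (2.0 * sigma ** 2))
    K_X = derive(p, lp).K_X[X]
    return K_X * profile / profile.sum(), r_mm


def assemble_kernel(resp: SingleSynapseResponse, K_map: np.ndarray,
                    r_mm: np.ndarray, d0: float, v: float | None, dt: float,
                    mode: str = "convolution") -> np.ndarray:
    """Population kernel ``H_X(displacement, lag)`` in mV per spike.

    ``mode="convolution"`` (default): the synapse-count map is spatially
    convolved, with periodic wrap, with the single-synapse response delayed
    per postsynaptic bin by the conduction delay at that bin's distance.
    ``mode="radial"`` applies each distance's delay to the whole response
    field instead, weighting by the summed count at that distance (the
    literal distance-sum reading; kept as a documented alternative).
    """
    Lphi = K_map.shape[0]
    n_t = resp.series.shape[1]
    # nearest-match lookup of each cell's distance in the unique-distance table
    lookup = np.argmin(np.abs(r_mm[..., None] * 1000.0 - resp.distances), axis=-1)
    phi_field = resp.series[lookup]  # (Lphi, Lphi, n_t)
    H = np.zeros((Lphi, Lphi, n_t))

    def _delay_steps(r):
        d = d0 + (r / v if v is not None else 0.0)
        return int(round(d / dt))

    truncated = False
    if mode == "convolution":
        for bi in range(Lphi):
            for bj in range(Lphi):
                K = K_map[bi, bj]
                if K == 0.0:
                    continue
                s = _delay_steps(r_mm[bi, bj])
                if s >= n_t:
                    truncated = True
                    continue
                if s > 0 and np.abs(phi_field[..., n_t - s:]).max() > 0:
                    truncated = True
                rolled = np.roll(phi_field, shift=(bi, bj), axis=(0, 1))
                H[..., s:] += K * rolled[..., : n_t - s]
    elif mode == "radial":
        for r in np.unique(np.round(r_mm, 9)):
            sel = np.round(r_mm, 9) == r
            K = K_map[sel].sum()
            if K == 0.0:
                continue
            s = _delay_steps(r)
            if s >= n_t:
                truncated = True
                continue
            if s > 0 and np.abs(phi_field[..., n_t - s:]).max() > 0:
                truncated = True
            H[..., s:] += K * phi_field[..., : n_t - s]
    else:
        raise ValueError("mode must be 'convolution' or 'radial'")
    if truncated:
        warnings.warn("delayed kernel response truncated by the 2*tau_syn_act "
                      "lag window")
    return H


@dataclass
class KernelSet:
    """Spike-to-LFP kernels per presynaptic population."""

    kernels: dict          # label -> (Lphi, Lphi, n_lag) mV per spike
    dt: float              # ms
    dl_phi: float          # um

    @property
    def n_lag(self) -> int:
        return next(iter(self.kernels.values())).shape[2]


_SYN_PLACEMENT = {"EX": "dendritic", "IN": "somatic", "STIM": "dendritic"}


def _cache_key(p, lp, X, mode):
    doc = json.dumps({"net": asdict(p), "lfp": asdict(lp), "X": X, "mode": mode},
                     sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:24]


def build_kernels(p: NetworkParams, lp: LFPParams,
                  populations=("EX", "IN", "STIM"), mode: str = "convolution",
                  cache_dir=None) -> KernelSet:
    """Assemble (or load from cache) the kernel of every population."""
    kernels = {}
    for X in populations:
        cache_path = None
        if cache_dir is not None:
            cache_path = Path(cache_dir) / f"kernel_{X}_{_cache_key(p, lp, X, mode)}.npz"
            if cache_path.exists():
                kernels[X] = np.load(cache_path)["H"]
                continue
        weight = p.g_YX[f"EX_{X}"] * p.J
        resp = single_synapse_kernel(p, lp, _SYN_PLACEMENT[X], weight)
        K_map, r_mm = activated_synapse_counts(X, p, lp)
        H = assemble_kernel(resp, K_map, r_mm, p.d0_YX[f"EX_{X}"],
                            p.v_YX.get(f"EX_{X}"), p.dt, mode=mode)
        kernels[X] = H
        if cache_path is not None:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            np.savez_compressed(cache_path, H=H)
    return KernelSet(kernels=kernels, dt=p.dt, dl_phi=lp.dl_phi)


@dataclass
class LFPGrid:
    """Synthesized potential on the electrode grid, downsampled to dt_bin."""

    values: np.ndarray   # (Lphi, Lphi, K) mV
    dt_bin: float        # ms
    dl_phi: float        # um
    L: float             # mm


def synthesize_lfp(spikes: SpikeData, geometries: dict, kernels: KernelSet,
                   p: NetworkParams, lp: LFPParams) -> LFPGrid:
    """Superpose delayed, distance-weighted kernels over binned spiking.

    Populations and spatial bins sum linearly; the output is low-pass
    filtered and downsampled to the preprocessing resolution ``dt_bin``.
    """
    dl_phi_mm = lp.dl_phi / 1000.0
    Lphi = round(p.L / dl_phi_mm)
    n_steps = round(spikes.T / spikes.dt)
    n_lag = kernels.n_lag
    n_box = round(p.dt_bin / spikes.dt)
    nfft = int(2 ** np.ceil(np.log2(n_steps + n_lag - 1)))

    acc_f = None
    for X, H in kernels.kernels.items():
        ids, times = spikes.pops.get(X, (np.empty(0, np.int64), np.empty(0)))
        geom = geometries[X]
        counts = bin_spikes(
            ids, times, geom.ids, geom.x, geom.y,
            dt_bin=spikes.dt, dl_bin=dl_phi_mm, L=p.L, T=spikes.T,
            population=X,
        ).rates * (spikes.dt * 1e-3)  # back to raw counts per dt step
        if n_box > 1:
            counts = lfilter(np.ones(n_box) / n_box, [1.0], counts, axis=2)
        Sf = np.fft.rfftn(counts, s=(Lphi, Lphi, nfft), axes=(0, 1, 2))
        Hf = np.fft.rfftn(H, s=(Lphi, Lphi, nfft), axes=(0, 1, 2))
        acc_f = Sf * Hf if acc_f is None else acc_f + Sf * Hf
    phi = np.fft.irfftn(acc_f, s=(Lphi, Lphi, nfft), axes=(0, 1, 2))[..., :n_steps]

    fs = 1000.0 / spikes.dt                  # Hz
    fc = 0.4 / p.dt_bin * 1000.0             # Hz
    if fc < fs / 2:
        sos = butter(4, fc, fs=fs, output="sos")
        phi = sosfiltfilt(sos, phi, axis=2)
    values = phi[..., n_box - 1::n_box]
    return LFPGrid(values=np.ascontiguousarray(values),
                   dt_bin=p.dt_bin, dl_phi=lp.dl_phi, L=p.L)
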