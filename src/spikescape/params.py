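"""Model, simulation, preprocessing and LFP-prediction parameters.

The defaults describe a spatially extended balanced random network: excitatory
(EX) and inhibitory (IN) leaky integrate-and-fire point neurons with
alpha-shaped postsynaptic currents, placed uniformly on a square sheet of side
``L`` with periodic (torus) boundaries, plus a stimulus population (STIM) of
parrot units confined to a central disc.  A second parameter block configures
the phenomenological spike-to-LFP forward model built on a passive
ball-and-stick cable neuron.

Unit conventions are fixed per field (ms, mm, pA, mV, pF, 1/s for the network;
uF/cm^2, Ohm*cm, um, S/m for the LFP model).  All conversions happen inside
the operations of this package, never at call sites.

Dictionary-valued connection parameters are keyed ``"Y_X"`` where ``Y`` is the
target (postsynaptic) population and ``X`` the source.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field, replace

__all__ = [
    "NetworkParams",
    "LFPParams",
    "DerivedParams",
    "threshold_rate",
    "derive_soma_radius",
    "derive",
    "load_config",
    "write_config",
    "scaled",
]

#: relative tolerance for "integer multiple" invariant checks
REL_TOL = 1e-9

RECURRENT_PAIRS = ("EX_EX", "EX_IN", "IN_EX", "IN_IN")


def _default_g():
    # relative synaptic strengths g_YX: sign and magnitude depend on the source
    return {"EX_EX": 1.0, "EX_IN": -4.5, "IN_EX": 1.0, "IN_IN": -4.5, "EX_STIM": 1.0}


def _default_sigma():
    return {p: 0.3 for p in RECURRENT_PAIRS}


def _default_d0():
    d = {p: 0.5 for p in RECURRENT_PAIRS}
    d["EX_STIM"] = 0.5
    return d


def _default_v():
    # conduction velocity in m/s; the STIM->EX projection has no distance term
    return {p: 2.0 for p in RECURRENT_PAIRS}


def _is_multiple(a: float, b: float) -> bool:
    """True when ``a`` is a positive integer multiple of ``b`` (rel. tol 1e-9)."""
    if b <= 0 or a <= 0:
        return False
    k = round(a / b)
    return k >= 1 and abs(a - k * b) <= REL_TOL * max(abs(a), abs(b))


@dataclass
class NetworkParams:
    """Simulation, network and preprocessing parameters."""

    # global simulation
    T_sim: float = 1500.0      #: simulation duration, ms
    dt: float = 0.1            #: temporal resolution, ms
    T_trans: float = 500.0     #: discarded startup transient, ms
    T_STIM: float = 999.0      #: start of Poisson input to STIM, ms
    t_STIM: float = 50.0       #: duration of STIM onset, ms
    # populations and external input
    N_EX: int = 20000
    N_IN: int = 5000
    N_STIM: int = 975
    L: float = 4.0             #: side length of the square sheet, mm
    eta: float = 2.0           #: external rate relative to threshold rate
    R_STIM: float = 0.5        #: radius of the STIM placement disc, mm
    nu_STIM: float = 300.0     #: Poisson rate per parrot, 1/s
    # connections
    c: float = 0.1             #: recurrent connection probability
    J: float = 40.0            #: reference synaptic strength, pA
    g_YX: dict = field(default_factory=_default_g)
    R: float = 0.1             #: STIM->EX cut-off mask radius, mm
    K_STIM: int = 300          #: out-degree per STIM unit
    sigma_YX: dict = field(default_factory=_default_sigma)  #: mm
    d0_YX: dict = field(default_factory=_default_d0)        #: ms
    v_YX: dict = field(default_factory=_default_v)          #: m/s
    d_STIM: float = 0.5        #: Poisson-to-parrot delay, ms
    # neuron model
    C_m: float = 100.0         #: membrane capacitance, pF
    tau_m: float = 20.0        #: membrane time constant, ms
    E_L: float = 0.0           #: resting potential, mV
    V_theta: float = 20.0      #: firing threshold, mV
    V_reset: float = 0.0       #: reset potential, mV
    tau_ref: float = 2.0       #: absolute refractory period, ms
    tau_s: float = 0.5         #: PSC time constant, ms
    # preprocessing
    dt_bin: float = 1.0        #: temporal bin width, ms
    dl_bin: float = 0.1        #: spatial bin width, mm

    def validate(self) -> None:
        errors = []
        for name in ("dt", "tau_s", "tau_m", "C_m", "T_sim", "L", "dt_bin", "dl_bin"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0 (got {getattr(self, name)})")
        if self.tau_ref < 0:
            errors.append(f"tau_ref must be >= 0 (got {self.tau_ref})")
        if self.J <= 0:
            errors.append(f"J must be > 0 (got {self.J})")
        if not _is_multiple(self.dt_bin, self.dt):
            errors.append(
                f"dt_bin ({self.dt_bin}) must be an integer multiple of dt ({self.dt})"
            )
        if not _is_multiple(self.L, self.dl_bin):
            errors.append(f"L ({self.L}) must be an integer multiple of dl_bin ({self.dl_bin})")
        if not 0 <= self.T_trans <= self.T_sim:
            errors.append("T_trans must lie in [0, T_sim]")
        elif self.T_sim > self.T_trans and not _is_multiple(
            self.T_sim - self.T_trans, self.dt_bin
        ):
            errors.append("T_sim - T_trans must be an integer multiple of dt_bin")
        for name in ("N_EX", "N_IN", "N_STIM", "K_STIM"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if self.eta < 0:
            errors.append("eta must be >= 0")
        if self.nu_STIM < 0:
            errors.append("nu_STIM must be >= 0")
        if not 0 <= self.c <= 1:
            errors.append("c must lie in [0, 1]")
        for pair in RECURRENT_PAIRS:
            if self.sigma_YX.get(pair, 0) <= 0:
                errors.append(f"sigma_YX[{pair}] must be > 0")
            if self.v_YX.get(pair, 0) is not None and self.v_YX.get(pair, 0) <= 0:
                errors.append(f"v_YX[{pair}] must be > 0")
        for key, val in self.d0_YX.items():
            if val < 0:
                errors.append(f"d0_YX[{key}] must be >= 0")
        if errors:
            raise ValueError("invalid network parameters:\n  " + "\n  ".join(errors))

    @property
    def n_steps(self) -> int:
        return round(self.T_sim / self.dt)

    @property
    def T_record(self) -> float:
        """Length of the retained (post-transient) record, ms."""
        return self.T_sim - self.T_trans


@dataclass
class LFPParams:
    """Parameters of the ball-and-stick LFP forward model."""

    c_m: float = 1.0           #: specific membrane capacitance, uF/cm^2
    r_a: float = 150.0         #: axial resistivity, Ohm*cm
    L_dend: float = 500.0      #: dendritic stick length, um
    r_dend: float = 2.5        #: dendritic stick radius, um
    n_dend: int = 11           #: number of dendritic segments
    tau_syn_act: float = 25.0  #: synapse activation time tau^s, ms
    dl_phi: float = 400.0      #: electrode separation / LFP spatial bin, um
    sigma_e: float = 0.3       #: extracellular conductivity, S/m

    def validate(self) -> None:
        errors = []
        if self.n_dend < 0:
            errors.append("n_dend must be >= 0")
        for name in ("c_m", "r_a", "sigma_e", "dl_phi", "tau_syn_act", "r_dend"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be > 0")
        if self.L_dend < 0:
            errors.append("L_dend must be >= 0")
        if errors:
            raise ValueError("invalid LFP parameters:\n  " + "\n  ".join(errors))


@dataclass
class DerivedParams:
    nu_theta: float    #: threshold rate, 1/s
    nu_ext: float      #: external Poisson rate eta * nu_theta, 1/s
    g_L: float         #: passive leak conductivity c_m / tau_m, S/m^2
    r_soma: float      #: soma radius of the ball-and-stick model, um
    K_X: dict          #: average out-degree per presynaptic population


def threshold_rate(p: NetworkParams) -> float:
    """Threshold rate nu_theta in 1/s.

    The hypothetical external Poisson rate that brings the mean membrane
    potential to threshold: ``(V_theta - E_L) C_m / (e J tau_m tau_s)``.
    The mV*pF/(pA*ms*ms) bookkeeping yields 1/ms, converted to 1/s.
    """
    if p.J <= 0 or p.tau_m <= 0 or p.tau_s <= 0:
        raise ValueError("J, tau_m and tau_s must be positive")
    per_ms = (p.V_theta - p.E_L) * p.C_m / (math.e * p.J * p.tau_m * p.tau_s)
    return per_ms * 1e3


def derive_soma_radius(lp: LFPParams, C_m: float) -> float:
    """Soma radius (um) preserving the point neuron's total capacitance.

    The sphere surface ``4 pi r_soma^2`` plus the dendritic lateral surface
    ``2 pi r_dend L_dend`` must equal the total membrane area ``C_m / c_m``.

    Parameters
    ----------
    lp:
        LFP model parameters (``c_m`` in uF/cm^2, lengths in um).
    C_m:
        Point-neuron membrane capacitance in pF.
    """
    # C_m [pF] / c_m [uF/cm^2] in um^2:  1 pF / (1 uF/cm^2) = 100 um^2
    total_area = C_m * 100.0 / lp.c_m
    radicand = total_area / (4.0 * math.pi) - lp.r_dend * lp.L_dend / 2.0
    if radicand <= 0:
        raise ValueError(
            "dendritic membrane area exceeds the total area C_m/c_m; "
            "no positive soma radius exists"
        )
    return math.sqrt(radicand)


def derive(p: NetworkParams, lp: LFPParams) -> DerivedParams:
    """Compute all derived quantities from a validated parameter set."""
    nu_theta = threshold_rate(p)
    # c_m in F/m^2: 1 uF/cm^2 = 1e-2 F/m^2; tau_m in s
    g_L = (lp.c_m * 1e-2) / (p.tau_m * 1e-3)
    K_rec = (p.N_EX + p.N_IN) * p.c
    return DerivedParams(
        nu_theta=nu_theta,
        nu_ext=p.eta * nu_theta,
        g_L=g_L,
        r_soma=derive_soma_radius(lp, p.C_m),
        K_X={"EX": K_rec, "IN": K_rec, "STIM": float(p.K_STIM)},
    )


# ---------------------------------------------------------------------------
# configuration files


def _merge(cls, defaults: dict, overrides: dict, unknown: list, prefix=""):
    out = dict(defaults)
    for key, val in overrides.items():
        if key not in defaults:
            unknown.append(prefix + key)
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(None, defaults[key], val, unknown, prefix=key + ".")
        else:
            out[key] = val
    return out


def load_config(path) -> tuple[NetworkParams, LFPParams]:
    """Read a flat JSON config; missing keys fall back to the defaults.

    Unknown keys raise a warning, invariant violations raise ``ValueError``
    listing the offending fields.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    net_defaults = asdict(NetworkParams())
    lfp_defaults = asdict(LFPParams())
    unknown: list[str] = []
    net_over = {k: v for k, v in raw.items() if k in net_defaults}
    lfp_over = {k: v for k, v in raw.items() if k in lfp_defaults}
    for k in raw:
        if k not in net_defaults and k not in lfp_defaults:
            unknown.append(k)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {', '.join(sorted(unknown))}")
    nested_unknown: list[str] = []
    net = NetworkParams(**_merge(None, net_defaults, net_over, nested_unknown))
    lfp = LFPParams(**_merge(None, lfp_defaults, lfp_over, nested_unknown))
    if nested_unknown:
        warnings.warn(f"ignoring unknown config keys: {', '.join(sorted(nested_unknown))}")
    net.validate()
    lfp.validate()
    return net, lfp


def write_config(path, p: NetworkParams, lp: LFPParams) -> None:
    doc = {**asdict(p), **asdict(lp)}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def scaled(p: NetworkParams, factor: float) -> NetworkParams:
    """Desk-scale variant of a parameter set.

    Population sizes and the STIM out-degree scale by ``factor`` while
    synaptic weights scale by ``1/factor``, so each neuron's summed input
    is preserved on average (the threshold rate, and with it the external
    drive, rescales consistently because it is proportional to ``1/J``).
    The STIM mask radius grows by ``1/sqrt(factor)`` to keep the expected
    number of in-mask target candidates scale invariant.
    """
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    if factor == 1.0:
        return replace(p)
    return replace(
        p,
        N_EX=max(1, round(p.N_EX * factor)),
        N_IN=max(1, round(p.N_IN * factor)),
        N_STIM=max(1, round(p.N_STIM * factor)),
        K_STIM=max(1, round(p.K_STIM * factor)),
        J=p.J / factor,
        R=min(p.R / math.sqrt(factor), p.L / 2.0),
    )
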