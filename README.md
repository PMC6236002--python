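# spikescape

Simulation and offline visualization of spatially organized spiking-network
activity: a leaky integrate-and-fire (LIF) network with distance-dependent
connectivity on a 2D torus, spatiotemporal binning of spike data into
instantaneous spike-count rates, a kernel-based biophysical forward model for
LFP-like signals, and scriptable implementations of the four standard
"views" of layered network activity (rate images, cube glyphs, stacked rate
series, rate iso-surfaces).

It is aimed at computational neuroscientists who want a self-contained,
deterministic pipeline from model parameters to renderable activity data in
plain-text exchange formats, without a browser-based or GUI toolchain.

## Model

The network consists of an excitatory population EX (20,000 neurons), an
inhibitory population IN (5,000) and a stimulus population STIM (975 parrot
units), placed on a 4 mm x 4 mm sheet with periodic boundaries.  EX/IN
neurons are LIF units with alpha-shaped postsynaptic currents,

    dV/dt = -(V - E_L)/tau_m + I_syn(t)/C_m,
    alpha(t) = (t/tau_s) e^(1 - t/tau_s) Theta(t),

so a connection of reference strength J = 40 pA peaks at exactly J at lag
tau_s.  Recurrent wiring uses convergent fixed in-degree sampling with a
Gaussian distance kernel p_YX(r) = exp(-r^2 / 2 sigma_YX^2) on the torus
metric, and linear distance-dependent delays d_YX(r) = d0 + r/v_YX.  Every
neuron receives Poisson drive at nu_ext = eta * nu_theta, where the threshold
rate is

    nu_theta = (V_theta - E_L) C_m / (e J tau_m tau_s).

STIM parrots repeat a 300 Hz Poisson input (active for 50 ms) and project
divergently to 300 EX targets each inside a 0.1 mm mask.

Spikes are binned into instantaneous spike-count rates nu_beta =
count / dt_bin on an (lx, ly, k) grid.  LFP-like signals are synthesized by
convolving binned spiking with population kernels H_X(displacement, lag)
built from a passive ball-and-stick neuron (soma radius derived by
preserving the point neuron's membrane capacitance, r_soma ~ 13.1 um), a
line-source/point-source electrostatic forward model, per-bin activated
synapse counts, and conduction delays.

## Worked example

```python
from spikescape import (NetworkParams, LFPParams, threshold_rate,
                        derive_soma_radius, run_all)

p, lp = NetworkParams(), LFPParams()
print(f"threshold rate nu_theta = {threshold_rate(p):.1f} 1/s")
print(f"external rate  nu_ext   = {p.eta * threshold_rate(p):.1f} 1/s")
print(f"soma radius    r_soma   = {derive_soma_radius(lp, p.C_m):.1f} um")
manifest = run_all((p, lp), seed=1, outdir="out", scale=0.1)
```

prints

```
threshold rate nu_theta = 1839.4 1/s
external rate  nu_ext   = 3678.8 1/s
soma radius    r_soma   = 13.1 um
[build] 3 outputs, 0.953 s
[simulate] 3 outputs, 3.836 s
[preprocess] 3 outputs, 0.507 s
[lfp] 1 outputs, 0.622 s
[render] 4 outputs, 1.524 s
```

The threshold rate is the hypothetical Poisson rate that brings the mean
membrane potential to threshold; with eta = 2 every neuron is driven at
twice that rate, keeping the network in an active asynchronous state.  The
soma radius makes the ball-and-stick model's membrane area equal C_m / c_m.
The pipeline call runs a 1/10-scale network for 1.5 s, discards the 500 ms
startup transient, writes raw spike/position files, binned rate files
(dt_bin = 1 ms, dl_bin = 0.1 mm), the LFP grid on the 400 um electrode
lattice, and one rendered frame per view, all under `out/` together with a
manifest of content checksums.

The same stages are available from the shell:

```sh
spikescape pipeline run --seed 1 --outdir out --scale 0.1
spikescape simulate --seed 1 --outdir out --stim-only
spikescape render --view 4 --binned out --config cfg.json --k 504 --iso 100 \
    --out surface.obj
```

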