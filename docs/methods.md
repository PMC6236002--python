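# Methods

## Network model

EX and IN are leaky integrate-and-fire point neurons with static,
current-based synapses with an alpha-shaped time course.  The subthreshold
state of each neuron is the linear triple (y1, y2, U) with U = V - E_L:

    y1' = -y1/tau_s,   y2' = y1 - y2/tau_s,   U' = -U/tau_m + y2/C_m.

An incoming event of weight w (pA) increments y1 by w*e/tau_s, so the
postsynaptic current y2 traces w*alpha(t) with peak w at lag tau_s.  The
state is advanced per dt = 0.1 ms step with the exact matrix exponential of
this system, not an explicit Euler rule: at this dt an Euler step visibly
distorts the 0.5 ms alpha current, while the propagator is exact for
arbitrary step size.  Threshold crossings are detected at grid points only;
on a crossing the neuron emits a spike time-stamped at the step end, V is
reset and clamped for tau_ref = 2 ms while the synaptic states keep
evolving.  Initial conditions are V = E_L with zero synaptic states; the
discarded 500 ms startup transient makes this choice immaterial to outputs.

Event delivery uses per-step ring buffers of length max-delay+1.  Delays are
d_YX(r) = d0 + r/v_YX rounded to the nearest dt step with a one-step floor
(a zero delay is not representable in a grid-based event loop).  Spike times
therefore live on the dt grid, written with one decimal; the reader also
accepts the integer-step dialect.

STIM parrots carry no dynamics: Poisson input events drawn per grid step in
[T_STIM, T_STIM + t_STIM) reappear as output spikes d_STIM later, duplicates
preserved.  The external drive nu_ext = eta*nu_theta and the parrot drive
are Poisson counts per (step, unit) from named generator streams.

### Connectivity

Positions are uniform on the half-open square [-L/2, L/2)^2 (STIM: uniform
on the R_STIM disc via the square-root radial transform).  Distances use the
minimum-image torus metric, so no distance exceeds L/sqrt(2).

Recurrent wiring is convergent with fixed in-degree: each target draws
exactly round(c*N_X) sources from population X by inverse-CDF sampling of
the categorical distribution with weights p_YX(r) over all candidates.
Sampling is with replacement (multapses allowed) and excludes the target
itself (no autapses): replacement keeps the per-draw weights exact and
matches common topology-layer practice, while autapses would produce
pathological self-excitation.  There is no hard cut-off mask on the
recurrent kernels; the torus metric alone bounds distances.

The STIM projection is divergent with fixed out-degree: each parrot selects
K_STIM = 300 EX targets uniformly, with replacement, among the units inside
the 0.1 mm mask (periodic neighbor search).  With the default densities the
mask contains a few tens of candidates, so multapses are an intrinsic
feature of this projection, as they are for divergent masked connections in
grid-based simulators; an empty mask is an error naming the offending unit.

### Desk scaling

`params.scaled(p, F)` produces reduced-size variants for desktop runs:
population sizes and K_STIM scale by F, synaptic weights by 1/F.  Because
nu_theta is proportional to 1/J, the external drive rescales automatically
so that the mean input per neuron is preserved (fluctuations grow, as in any
downscaled diffusive network).  The STIM mask radius grows by 1/sqrt(F) so
the expected number of in-mask candidates is scale invariant; without this a
1/10-scale run almost surely encounters an empty mask.  Full-scale
parameters are never altered.

## Binning

A spike at (x, y, t) lands in lx = floor((x + L/2)/dl), ly likewise, and
k = floor(t/dt_bin), all half-open; the bin value is count/dt_bin in
spikes/s.  Summing rate*dt_bin over the grid recovers the spike count
exactly, for any bin sizes.  A small epsilon (1e-7 bins) guards the floor
against grid times whose quotient is an unrepresentable integer (0.3/0.1).
Positions exactly on the right/top boundary cannot be generated but are
wrapped to bin 0 (torus) with a warning when read from files.

File formats follow the shared text conventions: two-column spikes,
three-column positions, four-column binned rates with zero rows omitted.
Analog grids (LFP) reuse the binned format but retain zero rows, since zero
is informative for a signed signal.  Writers emit one fixed dialect with
rows ordered k-fastest; readers key rows by their indices and accept any
ordering.

Temporal alignment has two conventions.  File data use left-edge bins
[k*dt_bin, (k+1)*dt_bin).  Animation frames are centered on their time step,
[k*dt_bin - dt_bin/2, k*dt_bin + dt_bin/2); stimulus onset and duration are
measured on such frames, which is why a stimulus whose first spikes occur at
499.5 ms (post-transient) registers in frame 500 and spans 50 frames.

## LFP forward model

The spike-to-LFP kernel H_X of presynaptic population X is built in four
steps.

**Ball-and-stick response.**  The cable has a spherical soma and a vertical
stick of n_dend = 11 equal segments attached at the soma surface.  The soma
radius preserves the point neuron's capacitance, 4*pi*r_soma^2 +
2*pi*r_dend*L_dend = C_m/c_m, giving r_soma = 13.1 um with the defaults.
Leak conductivity is g_L = c_m/tau_m per area; the axial path treats the
soma as its area-equivalent cylinder (length = diameter) and couples
neighboring segment centers through r_a.  A single synapse injects
w*alpha(t - tau_act) — split evenly over the stick segments for excitatory
sources (EX, STIM), all on the soma for inhibitory ones — and the full
linear system (y1, y2, U_0..U_n) is advanced by its exact exponential
propagator, the same scheme family as the network neurons.  Transmembrane
currents are computed from the axial-coupling identity I_m = L_ax U, which
conserves charge to machine precision by construction (the axial Laplacian
has zero column sums).

**Electrostatics.**  In a homogeneous ohmic medium of conductivity sigma_e,
the soma contributes phi = I/(4 pi sigma_e d) as a sphere/point source and
each stick segment as a line source, the closed-form integral of the point
kernel along the segment axis.  Source-electrode distances are floored at
the respective radius to avoid the 1/d singularity.  Electrode contacts are
squares of side dl_phi = 400 um in the z = 0 plane, averaged on an m x m
midpoint grid with m = 10.  Directly over the cell the clamped 1/d integrand
makes this average converge only at roughly O(1/m) (about 1.6% residual at
m = 10 against a converged reference); one bin away the m = 10 average is
converged below 0.1%.  The central-bin kernel value therefore carries a
percent-level quadrature bias, acceptable for a display-oriented signal and
configurable via `contact_m`.

**Kernel assembly.**  The out-degree K_X = (N_EX + N_IN)*c (or K_STIM) is
split over spatial bins proportionally to the connection profile at
bin-center distances — the Gaussian kernel for EX/IN, the cut-off mask disc
for STIM (with dl_phi = 400 um the 0.1 mm mask collapses onto the reference
bin).  Exploiting rotational symmetry, single-synapse responses are
evaluated at the unique minimum-image bin distances up to sqrt(2)*L/2.  The
default assembly is the convolutional reading: H_X(D, lag) = sum over bins b
of K_b * phi(|D - D_b|, lag - d(|D_b|)) with periodic wrap, i.e. a 2D
spatial convolution of the delayed responses with the synapse-count map.  A
literal distance-sum alternative (each distance's delay applied to the whole
response field) is kept behind `mode="radial"`.  Delayed tails that leave
the 2*tau_act lag window are truncated with a warning; with tau_act = 25 ms
and millisecond-scale delays the truncated mass is the far tail of the
membrane relaxation.  Kernels are cached to disk keyed by a parameter hash.

**Synthesis.**  Spikes are binned at (dl_phi, dt), smoothed with a
normalized boxcar of length dt_bin (which removes the temporal offset
against the dt_bin-binned rate data), convolved with H_X — circularly in
space (torus), linearly in time, via a 3D FFT — and summed over populations.
The result is low-pass filtered with a 4th-order zero-phase Butterworth at
0.4/dt_bin kHz (80% of the post-decimation Nyquist) and downsampled to
dt_bin, sampling each boxcar window at its last step so LFP samples align
with the corresponding rate bins.  The exact filter design is a package
choice; any standard anti-aliasing low-pass yields visually equivalent
output.

## Views

View 1 slices the rate grid at one temporal bin and maps values through a
256-entry black-red-yellow-white lookup table with monotonically increasing
lightness (piecewise-linear; exact perceptual equidistance is approximated,
not certified).  The color range is shared across populations and, by
default, across the whole record.  View 2 emits one cube per nonzero bin
with volume proportional to the rate (edge capped at the bin width; linear
side-length scaling optional) plus marginal sums along each axis.  View 3
returns the total rate nu_k = sum over populations and bins / (Lx*Ly)
together with stacked per-population fractions; empty bins report fraction 0
rather than NaN, and hiding a population removes it from the stack only,
never from nu_k.  View 4 runs marching cubes (scikit-image) on the
(x, y, lag) volume with edge interpolation; values exactly at the iso-level
are nudged up by 1e-5 of the level — large enough to survive the float32
cast inside the extraction routine — and vertices are scaled to mm/ms.
Meshes export as Wavefront OBJ, images as PNG (views 1 and 3 also SVG).
Raw-data variants place one marker per spike at the emitting unit's position
at native dt resolution, with an every-n-th-unit dilution option.

## Synthetic fixtures

The toy generator writes miniature datasets (at most 100 units, 1 mm,
100 ms) with scripted patterns whose binned footprints are closed-form: a
single spike in a named bin, a planar wave of known slope, a uniform
drumbeat.  They exercise the file formats, binning identities and view
geometry, but contain none of the correlation structure, rate inhomogeneity
or scale of simulated network output — tests passing on fixtures validate
the processing chain, not network dynamics.  Network-level behavior is
covered separately by the desk-scale simulation tests.

## Problem sizes used in tests

The test suite runs the full stimulus population (975 parrots) for timing
and rate checks, full-scale stimulus wiring (20,000 EX targets) for degree
checks, and a 1/10-scale network (2,500 neurons, 625,000 synapses, 1.5 s at
dt = 0.1 ms) for the end-to-end pipeline; these sizes keep the whole suite
in the tens of seconds on one core while exercising every code path at
realistic densities.

## Known limitations

* Spike-LFP responses are homogeneous within and across bins: one cell
  morphology, bin-center geometry, population-averaged synapse counts.
  Per-neuron morphological heterogeneity and active conductances are out of
  scope.
* The extracellular medium is linear, isotropic, homogeneous and ohmic.
* The contact average over the reference bin carries a percent-level
  quadrature bias (see above).
* The colormap approximates perceptual uniformity; no colorimetric
  calibration is performed.
* Rendering is offline and static; interactive cameras, animation loops and
  GUI controls are explicitly not goals.
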