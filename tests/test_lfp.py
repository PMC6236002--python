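import dataclasses
import math

import numpy as np
import pytest

from spikescape import LFPParams, NetworkParams, connectivity as cn, lfp
from spikescape.simulator import SpikeData


@pytest.fixture(scope="module")
def cable():
    return lfp.build_cable(NetworkParams(), LFPParams())


@pytest.fixture(scope="module")
def dend_resp(cable):
    return lfp.solve_passive_response(cable, "dendritic", 40.0, 50.0, 0.1,
                                      t_act=25.0)


class TestCable:
    def test_capacitance_preserved(self, cable, net):
        assert cable.C.sum() == pytest.approx(net.C_m, rel=1e-12)
        assert cable.n_comp == 12

    def test_charge_conservation(self, dend_resp):
        residual = np.abs(dend_resp.I_m.sum(axis=1)).max()
        assert residual <= 1e-10 * np.abs(dend_resp.I_m).max()

    def test_zero_weight_silent(self, cable):
        resp = lfp.solve_passive_response(cable, "somatic", 0.0, 50.0, 0.1,
                                          t_act=25.0)
        assert np.abs(resp.I_m).max() == 0.0

    def test_causality(self, dend_resp):
        assert np.abs(dend_resp.I_m[dend_resp.t < 25.0]).max() == 0.0

    def test_linearity_in_weight(self, cable):
        r1 = lfp.solve_passive_response(cable, "dendritic", 40.0, 50.0, 0.1, 25.0)
        r2 = lfp.solve_passive_response(cable, "dendritic", 80.0, 50.0, 0.1, 25.0)
        np.testing.assert_allclose(r2.I_m, 2 * r1.I_m, rtol=1e-12, atol=1e-15)

    def test_single_compartment_rc_oracle(self, net, lfp_params):
        """Soma-only model against the closed-form RC response to an alpha
        current ``w (t/ts) e^(1-t/ts)``: with a = 1/ts, b = 1/tau_m,
        V(t) = (w e a / C) [ t e^{-at}/(b-a) - (e^{-at}-e^{-bt})/(b-a)^2 ]."""
        single = lfp.build_cable(net, lfp_params, n_dend=0)
        w = 40.0
        resp = lfp.solve_passive_response(single, "somatic", w, 50.0, 0.1,
                                          t_act=0.0)
        t = resp.t
        a, b = 1.0 / net.tau_s, 1.0 / net.tau_m
        V = (w * math.e * a / net.C_m) * (
            t * np.exp(-a * t) / (b - a)
            - (np.exp(-a * t) - np.exp(-b * t)) / (b - a) ** 2
        )
        scale = np.abs(V).max()
        np.testing.assert_allclose(resp.V[:, 0], V + net.E_L,
                                   atol=1e-6 * scale, rtol=0)
        # an isolated compartment carries no net membrane current
        assert np.abs(resp.I_m).max() <= 1e-10 * np.abs(resp.I_syn).max()


class TestForwardModel:
    def test_point_source_value(self):
        # 1 nA at 1 mm in a 0.3 S/m medium
        phi_mV = 1000.0 * lfp.point_source_factor(1000.0, 0.3)
        assert phi_mV * 1e-3 == pytest.approx(2.653e-7, rel=1e-3)

    def test_line_source_far_field_limit(self):
        z0, z1 = 100.0, 145.0  # 45 um segment
        rho = 100.0 * (z1 - z0)
        line = lfp.line_source_factor(z0, z1, rho, 0.0, 0.3)
        point = lfp.point_source_factor(
            math.hypot(rho, (z0 + z1) / 2), 0.3)
        assert line == pytest.approx(point, rel=1e-4)

    def test_line_source_against_quadrature(self):
        from scipy.integrate import quad

        z0, z1, rho = 13.0, 58.0, 2 * (58.0 - 13.0)
        closed = lfp.line_source_factor(z0, z1, rho, 0.0, 0.3)
        integrand = lambda z: 1.0 / math.hypot(rho, z)
        val, _ = quad(integrand, z0, z1, epsabs=1e-14, epsrel=1e-12)
        expected = 1e-3 / (4 * math.pi * 0.3 * (z1 - z0)) * val
        assert closed == pytest.approx(expected, rel=1e-6)

    def test_distance_clamping(self, cable):
        near = lfp.geometry_factors(cable, [[0.0, 0.0, 0.0]], 0.3)[0]
        at_radius = lfp.geometry_factors(cable, [[cable.r_soma, 0.0, 0.0]], 0.3)[0]
        assert near[0] == pytest.approx(at_radius[0])

    def test_contact_average_center_reduction(self, cable):
        m1 = lfp.contact_average_factors(cable, (500.0, 0.0), 400.0, 0.3, m=1)
        direct = lfp.geometry_factors(cable, [[500.0, 0.0, 0.0]], 0.3)[0]
        np.testing.assert_allclose(m1, direct)

    def test_contact_average_convergence(self, cable):
        # away from the cell the m=10 grid is converged to < 1e-3
        a10 = lfp.contact_average_factors(cable, (400.0, 0.0), 400.0, 0.3, m=10)
        a20 = lfp.contact_average_factors(cable, (400.0, 0.0), 400.0, 0.3, m=20)
        assert np.abs(a10 - a20).max() / np.abs(a20).max() < 1e-3
        # over the cell the clamped 1/d integrand slows convergence; the
        # refinement error must still shrink monotonically
        ref = lfp.contact_average_factors(cable, (0.0, 0.0), 400.0, 0.3, m=160)
        errs = [
            np.abs(lfp.contact_average_factors(cable, (0.0, 0.0), 400.0, 0.3,
                                               m=m) - ref).max()
            for m in (5, 10, 20, 40)
        ]
        assert errs == sorted(errs, reverse=True)


class TestSingleSynapseResponse:
    def test_polarity_dendritic_vs_somatic(self, net, lfp_params):
        resp_d = lfp.single_synapse_kernel(net, lfp_params, "dendritic", 40.0,
                                           contact_m=4)
        resp_s = lfp.single_synapse_kernel(net, lfp_params, "somatic", 40.0,
                                           contact_m=4)
        # opposite dominant polarity at the reference bin for same-sign weight
        peak_d = resp_d.series[0][np.argmax(np.abs(resp_d.series[0]))]
        peak_s = resp_s.series[0][np.argmax(np.abs(resp_s.series[0]))]
        assert peak_d * peak_s < 0
        # regression of the sign convention: dendritic excitation yields a
        # positive near-soma deflection (return current), somatic a negative
        assert peak_d > 0 and peak_s < 0

    def test_distances_cover_torus(self, net, lfp_params):
        resp = lfp.single_synapse_kernel(net, lfp_params, "dendritic", 1.0,
                                         contact_m=1)
        assert resp.distances[0] == 0.0
        assert resp.distances[-1] == pytest.approx(
            math.sqrt(2) * net.L / 2 * 1000.0, rel=1e-6)


class TestSynapseCounts:
    def test_normalization_and_value(self, net, lfp_params):
        K_map, _ = lfp.activated_synapse_counts("EX", net, lfp_params)
        assert K_map.sum() == pytest.approx(2500.0, rel=1e-12)
        K_in, _ = lfp.activated_synapse_counts("IN", net, lfp_params)
        assert K_in.sum() == pytest.approx(2500.0, rel=1e-12)

    def test_stim_mask_concentrates_at_origin(self, net, lfp_params):
        K_map, r = lfp.activated_synapse_counts("STIM", net, lfp_params)
        assert K_map[0, 0] == pytest.approx(300.0)
        assert K_map.sum() == pytest.approx(300.0)

    def test_narrow_kernel_limit(self, net, lfp_params):
        p = dataclasses.replace(net, sigma_YX={k: 1e-6 for k in net.sigma_YX})
        K_map, _ = lfp.activated_synapse_counts("EX", p, lfp_params)
        assert K_map[0, 0] == pytest.approx(K_map.sum())


@pytest.fixture(scope="module")
def resp():
    return lfp.single_synapse_kernel(NetworkParams(), LFPParams(),
                                     "dendritic", 40.0, contact_m=2)


class TestKernelAssembly:

    def test_identity_convolution(self, resp, net, lfp_params):
        K_map = np.zeros((10, 10))
        K_map[0, 0] = 1.0
        _, r_mm = lfp.activated_synapse_counts("EX", net, lfp_params)
        H = lfp.assemble_kernel(resp, K_map, r_mm, d0=0.0, v=None, dt=0.1)
        lookup = np.argmin(
            np.abs(r_mm[..., None] * 1000.0 - resp.distances), axis=-1)
        np.testing.assert_allclose(H, resp.series[lookup], rtol=1e-12)

    def test_isotropy_on_grid(self, net, lfp_params):
        kernels = lfp.build_kernels(net, lfp_params, populations=("EX",))
        H = kernels.kernels["EX"]
        # same displacement magnitude -> same kernel, to 1e-9
        np.testing.assert_allclose(H[1, 0], H[0, 1], atol=1e-9 * np.abs(H).max())
        np.testing.assert_allclose(H[1, 0], H[9, 0], atol=1e-9 * np.abs(H).max())
        np.testing.assert_allclose(H[3, 4], H[4, 3], atol=1e-9 * np.abs(H).max())

    def test_zero_reference_strength_zero_kernel(self, net, lfp_params):
        resp = lfp.single_synapse_kernel(net, lfp_params, "dendritic", 0.0,
                                         contact_m=1)
        K_map, r_mm = lfp.activated_synapse_counts("EX", net, lfp_params)
        H = lfp.assemble_kernel(resp, K_map, r_mm, 0.5, 2.0, 0.1)
        assert np.abs(H).max() == 0.0

    def test_radial_mode_runs(self, resp, net, lfp_params):
        K_map, r_mm = lfp.activated_synapse_counts("EX", net, lfp_params)
        H_conv = lfp.assemble_kernel(resp, K_map, r_mm, 0.5, 2.0, 0.1)
        H_rad = lfp.assemble_kernel(resp, K_map, r_mm, 0.5, 2.0, 0.1,
                                    mode="radial")
        assert H_conv.shape == H_rad.shape
        # both readings agree at the reference displacement onset sample
        assert np.sign(H_conv[0, 0].max()) == np.sign(H_rad[0, 0].max())


def _point_spike_data(net, t_spike=100.0, bin_center=(0.2, 0.2)):
    geom = cn.PopulationGeometry(
        "EX", np.array([1]), np.array([bin_center[0]]), np.array([bin_center[1]]))
    spikes = SpikeData(
        pops={"EX": (np.array([1]), np.array([t_spike]))}, T=200.0, dt=net.dt)
    return {"EX": geom}, spikes


@pytest.fixture(scope="module")
def kernels():
    return lfp.build_kernels(NetworkParams(), LFPParams(), populations=("EX",))


class TestSynthesis:

    def test_grid_shape(self, net, lfp_params, kernels):
        geoms, spikes = _point_spike_data(net)
        grid = lfp.synthesize_lfp(spikes, geoms, kernels, net, lfp_params)
        assert grid.values.shape == (10, 10, 200)

    def test_no_spikes_zero_lfp(self, net, lfp_params, kernels):
        geoms, _ = _point_spike_data(net)
        spikes = SpikeData(pops={"EX": (np.array([], np.int64), np.array([]))},
                           T=200.0, dt=net.dt)
        grid = lfp.synthesize_lfp(spikes, geoms, kernels, net, lfp_params)
        assert np.abs(grid.values).max() == 0.0

    def test_superposition(self, net, lfp_params, kernels):
        geoms, _ = _point_spike_data(net)
        sa = SpikeData(pops={"EX": (np.array([1]), np.array([50.0]))},
                       T=200.0, dt=net.dt)
        sb = SpikeData(pops={"EX": (np.array([1]), np.array([120.0]))},
                       T=200.0, dt=net.dt)
        sab = SpikeData(
            pops={"EX": (np.array([1, 1]), np.array([50.0, 120.0]))},
            T=200.0, dt=net.dt)
        ga = lfp.synthesize_lfp(sa, geoms, kernels, net, lfp_params).values
        gb = lfp.synthesize_lfp(sb, geoms, kernels, net, lfp_params).values
        gab = lfp.synthesize_lfp(sab, geoms, kernels, net, lfp_params).values
        np.testing.assert_allclose(gab, ga + gb, rtol=1e-12,
                                   atol=1e-12 * np.abs(gab).max())

    def test_impulse_response_is_filtered_kernel(self, net, lfp_params, kernels):
        """A single spike reproduces the boxcar+low-pass filtered kernel."""
        from scipy.signal import butter, lfilter, sosfiltfilt

        geoms, spikes = _point_spike_data(net, t_spike=50.0)
        grid = lfp.synthesize_lfp(spikes, geoms, kernels, net, lfp_params)
        H = kernels.kernels["EX"]
        n_steps = round(spikes.T / net.dt)
        n_box = round(net.dt_bin / net.dt)
        # spike lands in spatial bin (5, 5) at step 500
        delta = np.zeros(n_steps)
        delta[500] = 1.0
        sig = lfilter(np.ones(n_box) / n_box, [1.0], delta)
        sos = butter(4, 0.4 / net.dt_bin * 1000.0, fs=1000.0 / net.dt,
                     output="sos")
        for gx, gy in [(5, 5), (7, 5), (0, 9)]:
            expected = np.convolve(sig, H[(gx - 5) % 10, (gy - 5) % 10])[:n_steps]
            expected = sosfiltfilt(sos, expected)[n_box - 1::n_box]
            np.testing.assert_allclose(grid.values[gx, gy], expected,
                                       atol=1e-10 * np.abs(H).max())

    def test_kernel_cache_round_trip(self, net, lfp_params, tmp_path):
        k1 = lfp.build_kernels(net, lfp_params, populations=("STIM",),
                               cache_dir=tmp_path)
        k2 = lfp.build_kernels(net, lfp_params, populations=("STIM",),
                               cache_dir=tmp_path)
        np.testing.assert_array_equal(k1.kernels["STIM"], k2.kernels["STIM"])
        assert list(tmp_path.glob("kernel_STIM_*.npz"))
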