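"""ID neuron dynamics: derivatives, integration, energy and resistance."""

import numpy as np
import pytest
from scipy.integrate import quad

from idpcg.activation import ActivationSpec, g_inverse_output
from idpcg.dynamics import (
    IDParams,
    InstabilityError,
    NeuronState,
    Synapses,
    du_dt,
    dx_dt,
    energy,
    energy_rate,
    integrate,
    negative_region_bound,
    phi,
    resistance_region,
)


def make_net(n, seed, w_scale=0.5, h_scale=0.3, symmetric=True):
    rng = np.random.default_rng(seed)
    A = rng.normal(0, w_scale, (n, n))
    W = (A + A.T) / 2 if symmetric else A
    np.fill_diagonal(W, 0.0)
    return Synapses(W=W, h=rng.normal(0, h_scale, n))


class TestDerivatives:
    def test_single_neuron_decay(self):
        p = IDParams()
        syn = Synapses(W=np.zeros((1, 1)), h=np.zeros(1))
        st = NeuronState(u=np.array([2.0]), x=np.array([0.0]))
        assert du_dt(st, syn, p) == pytest.approx([-2.0])

    def test_two_neuron_substitution(self):
        p = IDParams()
        syn = Synapses(W=np.array([[0.0, 1.0], [1.0, 0.0]]), h=np.zeros(2))
        st = NeuronState(u=np.zeros(2), x=np.array([0.5, -0.5]))
        assert du_dt(st, syn, p) == pytest.approx([-0.5, 0.5])

    def test_du_matches_index_loop_oracle(self, rng):
        n = 6
        syn = make_net(n, 42, symmetric=False)
        p = IDParams(tau=1.7)
        st = NeuronState(u=rng.normal(size=n), x=rng.uniform(-0.8, 0.8, n))
        oracle = np.array(
            [
                (sum(syn.W[i, j] * st.x[j] for j in range(n) if j != i) + syn.h[i] - st.u[i]) / p.tau
                for i in range(n)
            ]
        )
        assert np.max(np.abs(du_dt(st, syn, p) - oracle)) < 1e-12

    def test_dx_nullcline_and_substitution(self):
        p = IDParams(K=1.0)
        act = p.activation()
        x = np.array([0.3, -0.6])
        st = NeuronState(u=np.asarray(act.g(x)), x=x)
        assert dx_dt(st, p, act) == pytest.approx([0.0, 0.0], abs=1e-14)
        st2 = NeuronState(u=np.array([0.5]), x=np.array([0.0]))
        assert dx_dt(st2, p, act) == pytest.approx([5.0])

    def test_dx_matches_index_loop_oracle(self, rng):
        n = 5
        p = IDParams(K=0.7, tau_x=0.2)
        act = p.activation()
        st = NeuronState(u=rng.normal(size=n), x=rng.uniform(-0.8, 0.8, n))
        oracle = np.array(
            [(st.u[i] - g_inverse_output(st.x[i], p.K)) / p.tau_x for i in range(n)]
        )
        assert np.max(np.abs(dx_dt(st, p, act) - oracle)) < 1e-12

    def test_shape_mismatch_rejected(self):
        syn = make_net(3, 0)
        st = NeuronState(u=np.zeros(2), x=np.zeros(2))
        with pytest.raises(ValueError):
            du_dt(st, syn, IDParams())


class TestStructuralValidation:
    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            Synapses(W=np.eye(2), h=np.zeros(2))

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError):
            IDParams(tau=0.1, tau_x=1.0)

    def test_self_connection_rejected(self):
        with pytest.raises(ValueError):
            IDParams(a_self=0.5)


class TestIntegration:
    def test_equilibrium_stays_fixed(self):
        p = IDParams(K=0.0)
        act = p.activation()
        x0 = np.array([0.4])
        u0 = np.asarray(act.g(x0))
        syn = Synapses(W=np.zeros((1, 1)), h=u0.copy())  # du = 0 there
        traj = integrate(NeuronState(u=u0, x=x0), syn, p, act, dt=0.005, n_steps=1000)
        assert np.max(np.abs(traj.x - x0)) < 1e-8
        assert np.max(np.abs(traj.u - u0)) < 1e-8

    def test_decoupled_neuron_relaxes_to_origin(self):
        p = IDParams(K=0.0)
        act = p.activation()
        syn = Synapses(W=np.zeros((1, 1)), h=np.zeros(1))
        traj = integrate(
            NeuronState(u=np.array([0.5]), x=np.array([0.2])), syn, p, act, dt=0.005, n_steps=2000
        )
        assert abs(traj.x[-1, 0]) < 1e-3
        assert abs(traj.u[-1, 0]) < 1e-3

    def test_rk4_order(self):
        p = IDParams()
        act = p.activation()
        syn = make_net(4, 9)
        rng = np.random.default_rng(5)
        st = NeuronState(u=rng.normal(0, 0.5, 4), x=rng.uniform(-0.4, 0.4, 4))
        ref = integrate(st, syn, p, act, dt=0.000625, n_steps=3200, record_energy=False)
        coarse = integrate(st, syn, p, act, dt=0.005, n_steps=400, record_energy=False)
        fine = integrate(st, syn, p, act, dt=0.0025, n_steps=800, record_energy=False)
        e_coarse = np.max(np.abs(coarse.x[-1] - ref.x[-1]))
        e_fine = np.max(np.abs(fine.x[-1] - ref.x[-1]))
        assert 8 < e_coarse / e_fine < 32  # 4th-order: halving dt ~ /16

    def test_dt_guard(self):
        p = IDParams()
        with pytest.raises(ValueError):
            integrate(
                NeuronState(u=np.zeros(1), x=np.zeros(1)),
                Synapses(W=np.zeros((1, 1)), h=np.zeros(1)),
                p,
                p.activation(),
                dt=p.tau_x,
                n_steps=10,
            )

    def test_divergence_reported_with_step(self):
        p = IDParams()
        syn = Synapses(W=np.zeros((1, 1)), h=np.array([5e6]))
        with pytest.raises(InstabilityError) as exc:
            integrate(
                NeuronState(u=np.zeros(1), x=np.zeros(1)), syn, p, p.activation(),
                dt=0.005, n_steps=5000,
            )
        assert exc.value.step > 0


class TestPhiAndResistance:
    def test_phi_values(self):
        p = IDParams(tau=1.0, tau_x=0.1)
        assert phi(np.array([0.0]), p, p.activation())[0] == pytest.approx(1.1)
        p2 = IDParams(K=2.0)
        assert phi(np.array([0.0]), p2, p2.activation())[0] == pytest.approx(-0.9)

    def test_phi_matches_finite_difference_of_g(self):
        p = IDParams(K=1.5)
        act = p.activation()
        h = 1e-5
        for x in np.linspace(-0.85, 0.85, 21):
            fd = (g_inverse_output(x + h, p.K) - g_inverse_output(x - h, p.K)) / (2 * h)
            assert phi(np.array([x]), p, act)[0] == pytest.approx(fd + p.ratio, abs=1e-6)

    def test_region_k0_always_positive(self):
        p = IDParams(K=0.0)
        act = p.activation()
        assert all(
            resistance_region(x, p, act) == "positive" for x in np.linspace(-0.95, 0.95, 41)
        )

    def test_region_boundary_k3(self):
        # analytic boundary: 1/(1-x^2) = K - tau_x/tau  =>  |x| = 0.809427
        p = IDParams(K=3.0)
        act = p.activation()
        bound = negative_region_bound(3.0, p)
        assert bound == pytest.approx(np.sqrt(1 - 1 / 2.9), abs=1e-12)
        for x in np.linspace(-0.95, 0.95, 101):
            expected = "negative" if abs(x) < bound else "positive"
            assert resistance_region(x, p, act) == expected

    def test_boundary_tie_counts_positive(self):
        # K = 1 + tau_x/tau makes phi(0) exactly zero
        p = IDParams(K=1.1)
        assert phi(np.array([0.0]), p, p.activation())[0] == pytest.approx(0.0, abs=1e-14)
        assert resistance_region(0.0, p, p.activation()) == "positive"

    def test_no_negative_region_for_small_K(self):
        assert negative_region_bound(1.0, IDParams()) is None


class TestEnergy:
    def test_zero_state_zero_energy(self):
        p = IDParams()
        act = p.activation()
        syn = Synapses(W=np.zeros((2, 2)), h=np.zeros(2))
        st = NeuronState(u=np.zeros(2), x=np.zeros(2))
        assert energy(st, syn, p, act, np.zeros(2)) == 0.0

    @pytest.mark.parametrize("x", [0.3, -0.3, 0.7, -0.7])
    @pytest.mark.parametrize("K", [0.0, 2.0])
    def test_g_integral_closed_form_vs_quadrature(self, x, K):
        act = ActivationSpec(form="exact_arctanh", K=K)
        val, _ = quad(lambda s: g_inverse_output(s, K), 0.0, x, epsabs=1e-12)
        assert float(act.g_antiderivative(x)) == pytest.approx(val, abs=1e-8)

    def test_permutation_symmetry(self, rng):
        n = 4
        syn = make_net(n, 77)
        p = IDParams()
        act = p.activation()
        u = rng.normal(size=n)
        x = rng.uniform(-0.7, 0.7, n)
        xr = rng.normal(size=n)
        e0 = energy(NeuronState(u, x), syn, p, act, xr)
        perm = np.array([2, 0, 3, 1])
        syn_p = Synapses(W=syn.W[np.ix_(perm, perm)], h=syn.h[perm])
        e1 = energy(NeuronState(u[perm], x[perm]), syn_p, p, act, xr[perm])
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_rate_zero_when_stationary(self):
        p = IDParams()
        st = NeuronState(u=np.zeros(3), x=np.full(3, 0.2))
        assert energy_rate(st, p, p.activation(), np.zeros(3)) == 0.0

    def test_rate_negative_under_positive_friction(self, rng):
        p = IDParams(K=0.0)  # phi > 0 everywhere
        st = NeuronState(u=np.zeros(3), x=rng.uniform(-0.8, 0.8, 3))
        assert energy_rate(st, p, p.activation(), rng.normal(size=3)) < 0.0


class TestLyapunovBehaviour:
    def test_energy_descends_in_positive_resistance(self):
        p = IDParams(K=0.0)
        act = p.activation()
        syn = make_net(4, 3)
        rng = np.random.default_rng(4)
        st = NeuronState(u=rng.normal(0, 0.5, 4), x=rng.uniform(-0.5, 0.5, 4))
        traj = integrate(st, syn, p, act, dt=0.005, n_steps=2000)
        assert np.max(np.diff(traj.energies)) < 1e-6

    def test_negative_region_state_gains_energy(self):
        p = IDParams(K=3.0)
        act = p.activation()
        st = NeuronState(u=np.array([0.0]), x=np.array([0.3]))  # inside |x| < 0.8094
        rate = dx_dt(st, p, act)
        assert energy_rate(st, p, act, rate) > 0.0

    def test_energy_rate_formula_matches_trajectory(self):
        p = IDParams()
        act = p.activation()
        syn = make_net(4, 21)
        rng = np.random.default_rng(22)
        st = NeuronState(u=rng.normal(0, 0.5, 4), x=rng.uniform(-0.5, 0.5, 4))
        dt = 0.005
        traj = integrate(st, syn, p, act, dt=dt, n_steps=1500)
        fd = (traj.energies[2:] - traj.energies[:-2]) / (2 * dt)
        form = np.array(
            [energy_rate(traj.state(k), p, act, traj.x_rates[k]) for k in range(1, 1500)]
        )
        rel = np.abs(fd - form) / np.maximum(1.0, np.abs(form))
        assert rel.max() < 0.02

    def test_second_order_form_residual(self):
        # tau_x x'' + phi x' = (W x + h - g(x)) / tau along a trajectory
        p = IDParams()
        act = p.activation()
        syn = make_net(3, 8)
        rng = np.random.default_rng(9)
        st = NeuronState(u=rng.normal(0, 0.5, 3), x=rng.uniform(-0.4, 0.4, 3))
        dt = 0.0025
        traj = integrate(st, syn, p, act, dt=dt, n_steps=2000)
        X = traj.x
        xdd = (X[2:] - 2 * X[1:-1] + X[:-2]) / dt**2
        xd = (X[2:] - X[:-2]) / (2 * dt)
        ph = np.array([phi(X[k], p, act) for k in range(1, len(X) - 1)])
        g = np.array([np.asarray(act.g(X[k])) for k in range(1, len(X) - 1)])
        rhs = (X[1:-1] @ syn.W.T + syn.h - g) / p.tau
        resid = p.tau_x * xdd + ph * xd - rhs
        # skip the first 50 ms: the stiff initial transient dominates the
        # O(dt^2) error of the finite-difference second derivative there
        assert np.max(np.abs(resid[20:])) < 1e-3


class TestTrajectoryExport:
    def test_text_roundtrip_columns(self, tmp_path):
        p = IDParams()
        syn = make_net(2, 1)
        traj = integrate(
            NeuronState(u=np.array([0.1, -0.2]), x=np.zeros(2)), syn, p, p.activation(),
            dt=0.005, n_steps=10,
        )
        out = tmp_path / "traj.tsv"
        traj.to_text(out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["time", "u0", "u1", "x0", "x1", "E"]
        assert len(lines) == 12
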