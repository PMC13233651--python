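import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from epicosim import field as fd

from reference import dense_field_reference


def _random_setup(n, seed, mean_degree=6.0, max_delay_ms=3.0):
    """Random sparse connectome + local kernel on n nodes."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 10, (n, 3))
    conn = fd.random_connectome(pos, mean_degree=mean_degree, seed=seed)
    # clip tract lengths so delays stay small
    tl = conn.tract_lengths.copy()
    tl.data = np.minimum(tl.data, max_delay_ms * conn.conduction_speed)
    conn = fd.SparseConnectome(
        weights=conn.weights, tract_lengths=tl,
        conduction_speed=conn.conduction_speed,
    )
    kmask = rng.uniform(size=(n, n)) < 0.1
    np.fill_diagonal(kmask, False)
    kernel = fd.LocalKernel(
        sp.csr_matrix(kmask * rng.uniform(0, 1, (n, n))), sigma=2.0, cutoff=6.0
    )
    return conn, kernel


class TestInitialization:
    def test_no_onset_all_at_stable_point(self):
        st = fd.initialize_states(5, [])
        np.testing.assert_array_equal(st.as_array(), np.tile(fd.STABLE_POINT[:, None], (1, 5)))

    def test_single_onset_node(self):
        st = fd.initialize_states(5, [3])
        np.testing.assert_array_equal(st.as_array()[:, 3], fd.ONSET_POINT)
        np.testing.assert_array_equal(st.as_array()[:, 0], fd.STABLE_POINT)

    def test_all_onset_uniform(self):
        st = fd.initialize_states(4, range(4))
        np.testing.assert_array_equal(st.as_array(), np.tile(fd.ONSET_POINT[:, None], (1, 4)))

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            fd.initialize_states(0, [])


class TestGlobalCoupling:
    def test_zero_weights_give_zero_input(self):
        conn = fd.SparseConnectome.empty(4)
        hist = fd.HistoryBuffer(4, 3, np.ones(4))
        out = fd.compute_global_coupling(hist, conn, np.ones(4), k=0.636)
        np.testing.assert_array_equal(out, 0.0)

    def test_uniform_state_zero_delay_vanishes(self):
        n = 5
        w = sp.csr_matrix(np.ones((n, n)) - np.eye(n))
        tl = w.copy()
        tl.data = np.full_like(tl.data, 1e-9)  # ~zero delay
        conn = fd.SparseConnectome(weights=w, tract_lengths=tl)
        x1 = np.full(n, 0.7)
        hist = fd.HistoryBuffer(n, 2, x1)
        out = fd.compute_global_coupling(hist, conn, x1, k=0.636)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_three_node_chain_matches_dense_history(self):
        # chain 0 -> 1 -> 2 with unit weights, delays 0 and 2 steps
        dt = 0.1
        w = sp.csr_matrix(
            np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]])
        )
        tl = w.copy()
        tl.data = np.array([0.0 * 3.0, 2 * dt * 3.0])  # 0 and 2 steps at speed 3
        tl.data = np.maximum(tl.data, 1e-12)
        conn = fd.SparseConnectome(weights=w, tract_lengths=tl)
        hist = fd.HistoryBuffer(3, 5, np.zeros(3))
        series = [np.array([0.1, 0.2, 0.3]), np.array([0.4, 0.5, 0.6]),
                  np.array([0.7, 0.8, 0.9])]
        for x in series:
            hist.push(x)
        x_now = series[-1]
        out = fd.compute_global_coupling(hist, conn, x_now, k=1.0, dt=dt)
        # node 1 <- node 0 at delay 0; node 2 <- node 1 at delay 2 steps
        expected = np.array(
            [0.0, series[-1][0] - x_now[1], series[-3][1] - x_now[2]]
        )
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_delay_beyond_depth_errors(self):
        hist = fd.HistoryBuffer(2, 3, np.zeros(2))
        with pytest.raises(ValueError):
            hist.read(np.array([0]), np.array([3]))

    def test_read_at_zero_delay_is_current(self):
        hist = fd.HistoryBuffer(2, 4, np.zeros(2))
        hist.push(np.array([1.0, 2.0]))
        np.testing.assert_array_equal(
            hist.read(np.array([0, 1]), np.array([0, 0])), [1.0, 2.0]
        )


class TestLocalCoupling:
    def _kernel(self, mat):
        return fd.LocalKernel(sp.csr_matrix(mat), sigma=2.0, cutoff=6.0)

    def test_all_below_threshold_zero(self):
        params = fd.SEMParameters()
        k = self._kernel(np.array([[0, 1.0], [1.0, 0]]))
        lc = fd.compute_local_coupling(
            np.full(2, -2.0), np.full(2, -1.0), k, params
        )
        for term in lc:
            np.testing.assert_array_equal(term, 0.0)

    def test_single_neighbor_above_threshold(self):
        # gamma11 = 0.34, K = 0.5 -> lc11 = 0.17
        params = fd.SEMParameters()
        k = self._kernel(np.array([[0, 0.5], [0, 0]]))
        x1 = np.array([-2.0, 0.0])  # neighbor above theta11 = -1
        x2 = np.array([-1.0, -1.0])  # everyone below theta22
        lc11, lc12, lc22 = fd.compute_local_coupling(x1, x2, k, params)
        assert lc11[0] == pytest.approx(0.34 * 0.5)
        assert lc12[0] == pytest.approx(0.064 * 0.5)
        np.testing.assert_array_equal(lc22, 0.0)

    def test_linearity_in_gamma(self):
        rng = np.random.default_rng(3)
        k = self._kernel(rng.uniform(0, 1, (6, 6)))
        x1, x2 = rng.uniform(-2, 1, 6), rng.uniform(-2, 1, 6)
        p1 = fd.SEMParameters()
        p2 = dataclasses.replace(
            p1, gamma11=2 * p1.gamma11, gamma12=2 * p1.gamma12,
            gamma22=2 * p1.gamma22,
        )
        lc1 = fd.compute_local_coupling(x1, x2, k, p1)
        lc2 = fd.compute_local_coupling(x1, x2, k, p2)
        for a, b in zip(lc1, lc2):
            np.testing.assert_allclose(b, 2 * a, rtol=1e-14)

    def test_shape_mismatch_errors(self):
        k = self._kernel(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            fd.compute_local_coupling(np.zeros(2), np.zeros(2), k, fd.SEMParameters())


class TestDerivatives:
    def test_tt_scales_all_derivatives(self):
        st = fd.initialize_states(3, [1])
        p1 = fd.SEMParameters(x0=-1.9)
        p2 = dataclasses.replace(p1, tt=2 * p1.tt)
        d1 = fd.sem_derivatives(st, p1)
        d2 = fd.sem_derivatives(st, p2)
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-14)

    def test_stable_point_is_nearly_stationary(self):
        """The propagation-zone node (x0 = -1.9) initialized at the printed
        resting values stays near them: x1/x2/g within 0.3, the fast
        recovery variable y1 relaxes by < 0.75 to the nearby equilibrium,
        and z only drifts on the tau0 time scale."""
        conn = fd.SparseConnectome.empty(1)
        kernel = fd.LocalKernel.empty(1)
        rec = fd.run_field(
            1, conn, kernel, fd.SEMParameters(x0=-1.9), [], duration=1000.0
        )
        init = fd.STABLE_POINT
        for idx, tol in ((0, 0.3), (1, 0.75), (3, 0.3), (5, 0.3)):
            dev = np.abs(rec.states[:, idx, 0] - init[idx]).max()
            assert dev < tol, f"state {idx} deviated by {dev}"
        z_drift = np.abs(rec.states[:, 2, 0] - init[2]).max()
        assert z_drift < 2.0 * 1000.0 / fd.SEMParameters().tau0 + 0.05

    def test_non_finite_state_rejected(self):
        st = fd.initialize_states(2, [])
        st.x1[0] = np.nan
        with pytest.raises(ValueError):
            fd.sem_derivatives(st, fd.SEMParameters())


class TestFixedPoint:
    def test_residual_below_tolerance(self):
        fp = fd.find_fixed_point(fd.SEMParameters(), -1.9)
        st = fd.SEMState.from_array(fp[:, None])
        res = fd.sem_derivatives(st, dataclasses.replace(fd.SEMParameters(), x0=-1.9))
        assert np.linalg.norm(res) < 1e-10

    def test_x1_near_printed_resting_value(self):
        fp = fd.find_fixed_point(fd.SEMParameters(), -1.9)
        assert abs(fp[0] - (-1.5)) < 0.3

    def test_continuity_along_x0_sweep(self):
        params = fd.SEMParameters()
        prev = None
        for x0 in np.linspace(-2.2, -1.9, 13):
            fp = fd.find_fixed_point(params, float(x0), guess=prev)
            if prev is not None:
                # small x0 increments move the equilibrium by small amounts
                assert abs(fp[0] - prev[0]) < 0.05
                assert np.linalg.norm(fp - prev) < 1.0
            prev = fp


class TestHeunStep:
    def _uncoupled(self, n=1):
        return fd.SparseConnectome.empty(n), fd.LocalKernel.empty(n)

    def test_fixed_point_is_stationary(self):
        conn, kernel = self._uncoupled()
        fp = fd.find_fixed_point(fd.SEMParameters(), -1.9)
        st = fd.SEMState.from_array(fp[:, None])
        hist = fd.HistoryBuffer(1, 1, st.x1)
        out = fd.heun_step(
            st, dataclasses.replace(fd.SEMParameters(), x0=-1.9),
            conn, kernel, hist, dt=0.1,
        )
        np.testing.assert_allclose(out.as_array(), st.as_array(), atol=1e-9)

    def test_halving_dt_is_third_order_in_one_step(self):
        # Richardson: one Heun step has local error O(dt^3)
        conn, kernel = self._uncoupled()
        params = fd.SEMParameters(x0=-1.6)

        def one_step(dt, substeps):
            st = fd.initialize_states(1, [0])
            hist = fd.HistoryBuffer(1, 1, st.x1)
            for _ in range(substeps):
                st = fd.heun_step(st, params, conn, kernel, hist, dt)
            return st.as_array()

        exact = one_step(0.4 / 64, 64)
        err1 = np.abs(one_step(0.4, 1) - exact).max()
        err2 = np.abs(one_step(0.2, 2) - exact).max()
        # per-step error dt^3, accumulated over 1/dt steps -> global dt^2
        ratio = err1 / err2
        assert 2.5 < ratio < 6.0

    def test_decoupled_nodes_step_independently(self):
        conn, kernel = self._uncoupled(3)
        params = fd.SEMParameters(x0=np.array([-1.6, -1.9, -2.2]))
        st = fd.initialize_states(3, [0])
        hist = fd.HistoryBuffer(3, 1, st.x1)
        joint = fd.heun_step(st, params, conn, kernel, hist, dt=0.1)
        for i, x0 in enumerate((-1.6, -1.9, -2.2)):
            c1, k1 = self._uncoupled(1)
            sti = fd.SEMState.from_array(st.as_array()[:, [i]])
            hi = fd.HistoryBuffer(1, 1, sti.x1)
            alone = fd.heun_step(
                sti, fd.SEMParameters(x0=x0), c1, k1, hi, dt=0.1
            )
            np.testing.assert_allclose(
                joint.as_array()[:, i], alone.as_array()[:, 0], atol=1e-14
            )


class TestRunField:
    def _uncoupled(self, n=1):
        return fd.SparseConnectome.empty(n), fd.LocalKernel.empty(n)

    def test_zero_duration_records_initial_state_only(self):
        conn, kernel = self._uncoupled()
        rec = fd.run_field(1, conn, kernel, fd.SEMParameters(), [], 0.0)
        assert rec.states.shape[0] == 1
        np.testing.assert_array_equal(rec.states[0, :, 0], fd.STABLE_POINT)

    def test_epileptogenic_node_completes_a_seizure_cycle(
        self, single_node_seizure
    ):
        rec = single_node_seizure
        s = rec.x2[:, 0] - rec.x1[:, 0]
        # large-amplitude ictal oscillation ...
        assert s.min() < -1.5 and s.max() > 1.2
        # ... followed by return toward rest (x1 near -1.5 at the end)
        tail = rec.x1[-2000:, 0]
        assert np.abs(tail - (-1.5)).max() < 0.5

    def test_propagation_zone_node_stays_at_rest(self):
        conn, kernel = self._uncoupled()
        rec = fd.run_field(
            1, conn, kernel, fd.SEMParameters(x0=-1.9), [],
            duration=20000.0, monitor_stride=10,
        )
        assert np.abs(rec.x1[:, 0] - (-1.5)).max() < 0.5

    def test_bit_identical_reruns(self):
        conn, kernel = _random_setup(20, seed=4)
        params = fd.SEMParameters(x0=-1.9)
        a = fd.run_field(20, conn, kernel, params, [0, 1], 100.0)
        b = fd.run_field(20, conn, kernel, params, [0, 1], 100.0)
        assert a.states.tobytes() == b.states.tobytes()

    def test_compiled_loop_matches_python_steps(self):
        n = 12
        conn, kernel = _random_setup(n, seed=9)
        params = fd.SEMParameters(x0=-1.9)
        rec = fd.run_field(n, conn, kernel, params, [0], duration=5.0)
        st = fd.initialize_states(n, [0])
        depth = int(conn.delay_steps(0.1).max(initial=0)) + 1
        hist = fd.HistoryBuffer(n, depth, st.x1)
        for _ in range(50):
            st = fd.heun_step(st, params, conn, kernel, hist, 0.1)
        np.testing.assert_allclose(
            rec.states[-1], st.as_array(), atol=1e-10
        )

    def test_sparse_matches_dense_full_history_reference(self):
        n = 40
        conn, kernel = _random_setup(n, seed=21)
        params = fd.SEMParameters(x0=-1.9)
        rec = fd.run_field(n, conn, kernel, params, [0, 1, 2], duration=50.0)
        dsteps_mat = np.zeros((n, n), dtype=int)
        coo = conn.tract_lengths.tocoo()
        steps = np.floor(coo.data / conn.conduction_speed / 0.1 + 0.5).astype(int)
        dsteps_mat[coo.row, coo.col] = steps
        ref = dense_field_reference(
            fd.initialize_states(n, [0, 1, 2]).as_array(),
            params.x0_array(n),
            conn.weights.toarray(),
            dsteps_mat,
            kernel.matrix.toarray(),
            params,
            0.1,
            500,
        )
        assert np.abs(rec.states - ref).max() < 1e-10

    def test_excitability_monotonicity(self):
        conn, kernel = self._uncoupled()
        horizons = {}
        for x0 in (-2.2, -1.9, -1.6):
            rec = fd.run_field(
                1, conn, kernel, fd.SEMParameters(x0=x0), [],
                duration=8000.0, monitor_stride=10,
            )
            crossed = np.flatnonzero(rec.x1[:, 0] > -1.0)
            horizons[x0] = rec.times[crossed[0]] if len(crossed) else np.inf
        assert horizons[-2.2] == np.inf
        assert horizons[-1.9] == np.inf
        assert horizons[-1.6] < 8000.0

    def test_recurrence_period_scales_with_tau0(self):
        conn, kernel = self._uncoupled()
        periods = {}
        for tau0 in (1428.0, 2857.0, 5714.0):
            params = fd.SEMParameters(x0=-1.6, tau0=tau0)
            rec = fd.run_field(
                1, conn, kernel, params, [],
                duration=16000.0 * tau0 / 2857.0 + 12000.0, monitor_stride=10,
            )
            ict = (rec.x1[:, 0] > -1.0).astype(int)
            onsets = rec.times[1:][np.diff(ict) == 1]
            assert len(onsets) >= 2, f"need two seizures at tau0={tau0}"
            periods[tau0] = float(np.mean(np.diff(onsets)))
        slopes = [
            (periods[2857.0] - periods[1428.0]) / (2857.0 - 1428.0),
            (periods[5714.0] - periods[2857.0]) / (5714.0 - 2857.0),
        ]
        assert abs(slopes[1] - slopes[0]) / slopes[0] < 0.30

    def test_divergence_reported(self):
        conn, kernel = self._uncoupled()
        params = fd.SEMParameters(x0=-1.6)
        with pytest.raises(FloatingPointError):
            fd.run_field(1, conn, kernel, params, [0], 1000.0, dt=50.0)


class TestLocalKernelBuild:
    def test_kernel_respects_cutoff_and_excludes_self(self, small_mesh):
        from epicosim import geometry as geo

        geod = geo.geodesic_distances(small_mesh, cutoff=6.0)
        k = fd.build_local_kernel(geod, sigma=2.0, cutoff=4.0)
        coo = k.matrix.tocoo()
        assert (coo.row != coo.col).all()
        d = geod.toarray()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            assert d[i, j] <= 4.0
            assert v == pytest.approx(np.exp(-d[i, j] / 2.0))

    def test_row_normalization(self, small_mesh):
        from epicosim import geometry as geo

        geod = geo.geodesic_distances(small_mesh, cutoff=6.0)
        k = fd.build_local_kernel(geod, normalize=True)
        rows = np.asarray(k.matrix.sum(axis=1)).ravel()
        nz = rows > 0
        np.testing.assert_allclose(rows[nz], 1.0, rtol=1e-12)
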