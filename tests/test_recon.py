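"""Model-based reconstruction components: Sobolev weights, the alpha
schedule, the joint soft-threshold, constraint projection, the linearized
forward operator, and small end-to-end solves."""

import numpy as np
import pytest

from radstar.containers import CoilSensitivities, MultiEchoKspace
from radstar.phantom import (
    CoilModel,
    Ellipse,
    PhantomSpec,
    Tissue,
    ground_truth_maps,
    simulate_coils,
    simulate_kspace,
    tube_roi_masks,
)
from radstar.recon import (
    ReconConfig,
    ReconState,
    alpha_schedule,
    forward_operator,
    irgnm_fista,
    joint_l1_prox,
    project_constraints,
    sobolev_weight,
    synthesize_weighted_image,
)
from radstar.signal_model import FatSpectrum, ParameterMaps
from radstar.trajectory import EchoTrain, build_trajectory


class TestSobolevWeight:
    def test_centre_weight_is_one(self):
        assert sobolev_weight(np.zeros(2), 22.0, 4.0) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # s = 22 mm^2, l = 4, |k|^2 = 1/22 mm^-2 -> (1 + 1)^2 = 4
        k = np.array([np.sqrt(1.0 / 22.0), 0.0])
        assert sobolev_weight(k, 22.0, 4.0) == pytest.approx(4.0)

    def test_strictly_increasing_with_radius(self):
        r = np.linspace(0, 1, 50)
        k = np.stack([r, np.zeros_like(r)], axis=-1)
        w = sobolev_weight(k, 22.0, 4.0)
        assert np.all(np.diff(w) > 0)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            sobolev_weight(np.zeros(2), -1.0, 4.0)


class TestAlphaSchedule:
    def test_printed_schedule(self):
        cfg = ReconConfig()
        assert alpha_schedule(0, cfg) == 1.0
        assert alpha_schedule(1, cfg) == pytest.approx(1.0 / 3.0)
        assert alpha_schedule(10, cfg) == 0.002  # floor alpha_min

    def test_monotone_nonincreasing(self):
        cfg = ReconConfig()
        vals = [alpha_schedule(n, cfg) for n in range(12)]
        assert np.all(np.diff(vals) <= 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(alpha0=0.001, alpha_min=0.002)
        with pytest.raises(ValueError):
            ReconConfig(reduction_factor=1.0)


class TestJointL1Prox:
    def test_zero_threshold_identity(self, rng):
        maps = [rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
                for _ in range(3)]
        out = joint_l1_prox(maps, 0.0)
        for a, b in zip(maps, out):
            assert np.linalg.norm(a - b) / np.linalg.norm(a) < 1e-10

    def test_group_shrinkage_closed_form(self):
        """A single joint coefficient of l2 magnitude 2 shrinks to 1.5 at
        threshold 0.5 with its direction preserved."""
        import pywt

        n = 32
        # build maps from a single detail coefficient in each of the 3 maps
        coeffs = pywt.wavedec2(np.zeros((n, n)), "db4", mode="periodization", level=4)
        template = [coeffs[0]] + [
            tuple(np.zeros_like(b) for b in lev) for lev in coeffs[1:]
        ]
        vals = np.array([1.2, -1.6, 0.0])  # joint l2 magnitude exactly 2
        maps = []
        for v in vals:
            c = [template[0].copy()] + [
                tuple(b.copy() for b in lev) for lev in template[1:]
            ]
            c[3][1][3, 4] = v
            maps.append(pywt.waverec2(c, "db4", mode="periodization"))
        mag = np.linalg.norm(vals)
        out = joint_l1_prox(maps, 0.5)
        out_coeffs = [
            pywt.wavedec2(o, "db4", mode="periodization", level=4) for o in out
        ]
        got = np.array([oc[3][1][3, 4] for oc in out_coeffs])
        expected = vals * (1.0 - 0.5 / mag)
        assert np.allclose(got, expected, atol=1e-10)

    def test_below_threshold_zeroed(self):
        import pywt

        n = 32
        coeffs = pywt.wavedec2(np.zeros((n, n)), "db4", mode="periodization", level=4)
        c = [coeffs[0]] + [tuple(np.zeros_like(b) for b in lev) for lev in coeffs[1:]]
        c[1][0][1, 1] = 0.3
        m = pywt.waverec2(c, "db4", mode="periodization")
        out = joint_l1_prox([m, np.zeros((n, n)), np.zeros((n, n))], 0.5)
        assert np.linalg.norm(out[0]) < 1e-10

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            joint_l1_prox([np.zeros((16, 16))] * 3, -0.1)


class TestProjectConstraints:
    def _state(self, r2s):
        maps = ParameterMaps.zeros((4, 4))
        maps.r2star = np.asarray(r2s, dtype=float)
        return ReconState(
            maps=maps,
            coils=CoilSensitivities(np.ones((1, 4, 4), complex)),
            alpha=1.0,
            gn_iteration=0,
        )

    def test_negative_clamped_to_zero(self):
        s = self._state(np.full((4, 4), -5.0))
        project_constraints(s, ReconConfig())
        assert np.all(s.maps.r2star == 0.0)

    def test_interior_point_unchanged_and_idempotent(self):
        s = self._state(np.full((4, 4), 50.0))
        cfg = ReconConfig()
        project_constraints(s, cfg)
        assert np.all(s.maps.r2star == 50.0)
        once = s.maps.r2star.copy()
        project_constraints(s, cfg)
        assert np.array_equal(once, s.maps.r2star)

    def test_cap_applied(self):
        s = self._state(np.full((4, 4), 1e4))
        project_constraints(s, ReconConfig())
        assert np.all(s.maps.r2star == 500.0)


class TestForwardOperator:
    @pytest.fixture(scope="class")
    def setup(self):
        n = 16
        traj = build_trajectory(4, 3, n)
        echoes = EchoTrain(2.37, 1.88, 3)
        spectrum = FatSpectrum()
        coils = CoilSensitivities(np.ones((1, n, n), complex))
        return n, traj, echoes, spectrum, coils

    def _state(self, maps, coils):
        return ReconState(maps=maps, coils=coils, alpha=1.0, gn_iteration=0)

    def test_zero_maps_give_zero_data(self, setup):
        n, traj, echoes, spectrum, coils = setup
        data = forward_operator(
            self._state(ParameterMaps.zeros((n, n)), coils), traj, echoes, spectrum
        )
        assert np.allclose(data, 0.0)

    def test_delta_object_closed_form(self, setup):
        """Single-pixel water object with a flat coil: every sample is the
        model signal times a unit-magnitude phase factor."""
        n, traj, echoes, spectrum, coils = setup
        maps = ParameterMaps.zeros((n, n))
        maps.water[n // 2 + 2, n // 2 - 1] = 1.5
        maps.r2star[:] = 30.0
        data = forward_operator(self._state(maps, coils), traj, echoes, spectrum)
        for m, te in enumerate(echoes.times_ms):
            expected_mag = 1.5 * np.exp(-te * 1e-3 * 30.0)
            assert np.allclose(np.abs(data[0, m]), expected_mag, rtol=1e-6)

    def test_linear_in_water_and_fat(self, setup, rng):
        n, traj, echoes, spectrum, coils = setup
        r2s = np.abs(rng.standard_normal((n, n))) * 20
        fb0 = rng.standard_normal((n, n)) * 10

        def make(w, f):
            m = ParameterMaps(
                water=w, fat=f, r2star=r2s.copy(), fb0=fb0.copy()
            )
            return forward_operator(self._state(m, coils), traj, echoes, spectrum)

        w1 = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        f1 = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        w2 = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        f2 = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        lhs = make(2.0 * w1 + w2, 2.0 * f1 + f2)
        rhs = 2.0 * make(w1, f1) + make(w2, f2)
        assert np.allclose(lhs, rhs, atol=1e-6 * np.linalg.norm(rhs))

    def test_coil_object_gauge_invariance(self, setup, rng):
        """Scaling coils by g and (W, F) by 1/g leaves the data invariant."""
        n, traj, echoes, spectrum, _ = setup
        maps = ParameterMaps(
            water=rng.standard_normal((n, n)) + 0j,
            fat=rng.standard_normal((n, n)) + 0j,
            r2star=np.abs(rng.standard_normal((n, n))) * 30,
            fb0=rng.standard_normal((n, n)) * 20,
        )
        cmaps = rng.standard_normal((3, n, n)) + 1j * rng.standard_normal((3, n, n))
        g = 2.3 - 1.1j
        d1 = forward_operator(
            self._state(maps, CoilSensitivities(cmaps)), traj, echoes, spectrum
        )
        maps2 = ParameterMaps(
            water=maps.water / g, fat=maps.fat / g,
            r2star=maps.r2star.copy(), fb0=maps.fb0.copy(),
        )
        d2 = forward_operator(
            self._state(maps2, CoilSensitivities(cmaps * g)), traj, echoes, spectrum
        )
        assert np.allclose(d1, d2, atol=1e-9 * np.linalg.norm(d1))


class TestSynthesizedImage:
    def test_te_zero_gives_modulus_of_total_signal(self, rng):
        maps = ParameterMaps(
            water=rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8)),
            fat=rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8)),
            r2star=np.abs(rng.standard_normal((8, 8))) * 40,
            fb0=rng.standard_normal((8, 8)) * 30,
        )
        state = ReconState(
            maps=maps, coils=CoilSensitivities(np.ones((1, 8, 8), complex)),
            alpha=0.002, gn_iteration=10,
        )
        img = synthesize_weighted_image(state, 0.0)
        assert np.allclose(img, np.abs(maps.water + maps.fat))

    def test_closed_form_decay_and_monotonicity(self):
        maps = ParameterMaps.zeros((4, 4))
        maps.water[:] = 2.0
        maps.r2star[:] = 10.0
        state = ReconState(
            maps=maps, coils=CoilSensitivities(np.ones((1, 4, 4), complex)),
            alpha=0.002, gn_iteration=10,
        )
        img60 = synthesize_weighted_image(state, 60.0)
        assert np.allclose(img60, 2.0 * np.exp(-0.6))
        tes = [0.0, 10.0, 30.0, 60.0, 90.0]
        mags = [synthesize_weighted_image(state, te)[0, 0] for te in tes]
        assert np.all(np.diff(mags) < 0)

    def test_negative_te_rejected(self):
        state = ReconState(
            maps=ParameterMaps.zeros((4, 4)),
            coils=CoilSensitivities(np.ones((1, 4, 4), complex)),
            alpha=1.0, gn_iteration=0,
        )
        with pytest.raises(ValueError):
            synthesize_weighted_image(state, -1.0)


class TestIrgnmSmall:
    def test_zero_data_returns_zero_maps(self):
        n = 16
        traj = build_trajectory(4, 3, n)
        echoes = EchoTrain(2.37, 1.88, 3)
        y = MultiEchoKspace(
            data=np.zeros((2, 3, 4, n), complex), traj=traj, echoes=echoes,
            fov_mm=128.0,
        )
        state = irgnm_fista(y, cfg=ReconConfig(n_gn=3, n_fista=5))
        assert np.linalg.norm(state.maps.water) < 1e-3
        assert np.linalg.norm(state.maps.fat) < 1e-3

    def test_misfit_non_increasing(self, single_tube_phantom, eight_coils):
        """Data misfit does not grow across outer iterations."""
        n = 32
        ph = PhantomSpec(
            regions=single_tube_phantom.regions, fov_mm=128.0, base_resolution=n
        )
        traj = build_trajectory(10, 7, n)
        echoes = EchoTrain(2.37, 1.88, 7)
        y = simulate_kspace(ph, eight_coils, traj, echoes, noise_sd=0.0, dc_norm=100.0)
        state = irgnm_fista(y, cfg=ReconConfig(n_gn=6, n_fista=20))
        h = state.misfit_history
        assert all(b <= a * 1.001 for a, b in zip(h, h[1:]))
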