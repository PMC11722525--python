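"""NUFFT forward/adjoint accuracy against direct DFT summation, the
dot-product (exact adjoint) identity, and the Toeplitz normal operator."""

import numpy as np
import pytest

from radstar.nufft import (
    GriddedOperatorPlan,
    NufftPlan,
    nufft_adjoint,
    nufft_forward,
    ramp_dcf,
    toeplitz_normal,
)
from radstar.trajectory import build_trajectory


def direct_dft(image, coords):
    n1, n2 = image.shape
    x1 = np.arange(n1) - n1 // 2
    x2 = np.arange(n2) - n2 // 2
    X1, X2 = np.meshgrid(x1, x2, indexing="ij")
    return np.array(
        [
            np.sum(image * np.exp(-2j * np.pi * (k[0] * X1 / n1 + k[1] * X2 / n2)))
            for k in coords
        ]
    )


@pytest.fixture(scope="module")
def random_case(rng):
    n = 16
    img = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    coords = rng.uniform(-n / 2, n / 2, size=(50, 2))
    return img, coords


class TestForward:
    def test_matches_direct_dft(self, random_case):
        img, coords = random_case
        rel = np.linalg.norm(
            nufft_forward(img, coords) - direct_dft(img, coords)
        ) / np.linalg.norm(direct_dft(img, coords))
        assert rel < 1e-6

    def test_delta_image_constant_magnitude(self):
        n = 16
        img = np.zeros((n, n), complex)
        img[n // 2, n // 2] = 1.0  # delta at the image-centre origin
        coords = np.random.default_rng(0).uniform(-n / 2, n / 2, (40, 2))
        samples = nufft_forward(img, coords)
        assert np.allclose(np.abs(samples), 1.0, atol=1e-6)

    def test_zero_image(self, random_case):
        _, coords = random_case
        assert np.allclose(nufft_forward(np.zeros((16, 16)), coords), 0.0)

    def test_out_of_box_coords_rejected(self):
        with pytest.raises(ValueError):
            NufftPlan((16, 16), np.array([[9.0, 0.0]]))


class TestAdjoint:
    def test_dot_product_identity(self, random_case, rng):
        img, coords = random_case
        plan = NufftPlan(img.shape, coords)
        y = rng.standard_normal(len(coords)) + 1j * rng.standard_normal(len(coords))
        lhs = np.vdot(y, plan.forward(img))
        rhs = np.vdot(plan.adjoint(y), img)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_matches_explicit_dft_conjugate_transpose(self, rng):
        n = 8
        coords = rng.uniform(-n / 2, n / 2, size=(30, 2))
        x = np.arange(n) - n // 2
        A = np.exp(
            -2j
            * np.pi
            * (
                coords[:, 0, None] * np.repeat(x, n)[None, :]
                + coords[:, 1, None] * np.tile(x, n)[None, :]
            )
            / n
        )
        y = rng.standard_normal(30) + 1j * rng.standard_normal(30)
        got = nufft_adjoint(y, coords, (n, n)).ravel()
        want = A.conj().T @ y
        assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-6

    def test_dc_sample_gives_constant_image(self):
        img = nufft_adjoint(np.array([1.0 + 0j]), np.array([[0.0, 0.0]]), (16, 16))
        assert np.allclose(img, img[0, 0], atol=1e-6)
        assert img[0, 0] == pytest.approx(1.0, abs=1e-6)


class TestToeplitz:
    @pytest.fixture(scope="class")
    def radial_case(self, rng):
        n = 32
        traj = build_trajectory(5, 3, n)
        coords = traj.echo_coords(1)
        img = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        plan = NufftPlan((n, n), coords)
        toep = GriddedOperatorPlan.from_radial(
            (n, n), traj.angles[0, :, 1], np.arange(n) - n // 2
        )
        return img, plan, toep, coords

    def test_equals_adjoint_of_forward(self, radial_case):
        img, plan, toep, _ = radial_case
        ref = plan.adjoint(plan.forward(img))
        rel = np.linalg.norm(toeplitz_normal(toep, img) - ref) / np.linalg.norm(ref)
        assert rel < 1e-5

    def test_generic_kernel_path_agrees(self, radial_case):
        img, plan, _, coords = radial_case
        ref = plan.adjoint(plan.forward(img))
        toep = GriddedOperatorPlan.from_coords(img.shape, coords)
        rel = np.linalg.norm(toep.apply(img) - ref) / np.linalg.norm(ref)
        assert rel < 1e-5

    def test_linearity(self, radial_case, rng):
        img, _, toep, _ = radial_case
        img2 = rng.standard_normal(img.shape) + 1j * rng.standard_normal(img.shape)
        a, b = 1.7 - 0.3j, -0.4 + 2.2j
        lhs = toep.apply(a * img + b * img2)
        rhs = a * toep.apply(img) + b * toep.apply(img2)
        assert np.allclose(lhs, rhs, atol=1e-8 * np.linalg.norm(lhs))

    def test_hermitian_positive_semidefinite(self, radial_case, rng):
        _, _, toep, _ = radial_case
        for _ in range(5):
            v = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
            quad = np.vdot(v, toep.apply(v))
            assert quad.real >= -1e-6 * np.vdot(v, v).real
            assert abs(quad.imag) < 1e-6 * abs(quad)

    def test_batched_apply_matches_loop(self, radial_case, rng):
        _, _, toep, _ = radial_case
        batch = rng.standard_normal((3, 32, 32)) + 1j * rng.standard_normal((3, 32, 32))
        got = toep.apply(batch)
        for i in range(3):
            assert np.allclose(got[i], toep.apply(batch[i]))


def test_ramp_dcf_proportional_to_radius():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 4.0]])
    w = ramp_dcf(coords)
    assert w[1] == pytest.approx(1.0)
    assert w[3] == pytest.approx(5.0)
    assert 0 < w[0] <= w[1]
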