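import numpy as np
import pytest

from bistacert.domain_of_attraction import (
    AxisBox,
    GrowthSchedule,
    certify_box,
    check_certificate,
    default_gamma_grid,
    grow_box,
    sample_box,
    to_absolute,
    to_shifted,
    verify_box_by_simulation,
)
from bistacert.domain_of_attraction.certify import DACertificate
from bistacert.network_model import quadratic_decomposition


@pytest.fixture(scope="module")
def quad_1d(toys_module):
    toy = toys_module["bistable_1d"]
    return quadratic_decomposition(toy.network, None, np.array([0.0]))


@pytest.fixture(scope="module")
def toys_module():
    from bistacert.network_model import toy_models

    return toy_models()


@pytest.fixture(scope="module")
def quad_2d(toys_module):
    toy = toys_module["bistable_2d"]
    return quadratic_decomposition(toy.network, None, np.array([1.0, 0.25]))


class TestAxisBox:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            AxisBox(np.array([1.0]), np.array([0.5]))

    def test_shifted_needs_interior_origin(self):
        with pytest.raises(ValueError):
            AxisBox(np.array([0.1]), np.array([1.0]), "shifted")

    def test_face_normals_describe_box(self, rng):
        box = AxisBox(np.array([-1.0, -2.0]), np.array([0.5, 3.0]), "shifted")
        A = box.face_normals()
        assert A.shape == (4, 2)
        for _ in range(50):
            x = rng.uniform(-3, 4, size=2)
            inside = box.contains(x)
            assert inside == bool(np.all(A @ x <= 1.0 + 1e-12))

    def test_vertices(self):
        box = AxisBox(np.array([-1.0, -1.0]), np.array([1.0, 2.0]), "shifted")
        V = box.vertices()
        assert V.shape == (4, 2)
        assert {tuple(v) for v in V} == {
            (-1.0, -1.0), (-1.0, 2.0), (1.0, -1.0), (1.0, 2.0),
        }

    def test_shift_roundtrip(self):
        box = AxisBox(np.array([1.0, 2.0]), np.array([3.0, 5.0]))
        xe = np.array([2.0, 3.0])
        back = to_absolute(to_shifted(box, xe), xe)
        np.testing.assert_allclose(back.lower, box.lower, atol=1e-12)
        np.testing.assert_allclose(back.upper, box.upper, atol=1e-12)

    def test_equilibrium_on_face_rejected(self):
        box = AxisBox(np.array([1.0]), np.array([3.0]))
        with pytest.raises(ValueError, match="strictly inside"):
            to_shifted(box, np.array([1.0]))

    def test_symmetric_box_stays_symmetric(self):
        box = AxisBox(np.array([1.0]), np.array([3.0]))
        shifted = to_shifted(box, np.array([2.0]))
        np.testing.assert_allclose(shifted.lower, -shifted.upper)

    def test_json_roundtrip(self):
        box = AxisBox(np.array([0.25, 1e-7]), np.array([1.0 / 3.0, 2.0]))
        back = AxisBox.from_dict(box.to_dict(["a", "b"]), names=["a", "b"])
        np.testing.assert_array_equal(back.lower, box.lower)
        np.testing.assert_array_equal(back.upper, box.upper)


class TestCertify1D:
    def test_symmetric_boxes_certifiable(self, quad_1d):
        for u in (0.5, 0.85, 0.95):
            box = AxisBox(np.array([-u]), np.array([u]), "shifted")
            assert certify_box(quad_1d, box).feasible, u

    def test_box_crossing_unstable_point_never_certifiable(self, quad_1d):
        box = AxisBox(np.array([-0.5]), np.array([1.1]), "shifted")
        res = certify_box(quad_1d, box)
        assert not res.feasible
        assert all(status == "infeasible" for _, status, _ in res.gamma_status)

    def test_certificate_margins_recheck(self, quad_1d):
        box = AxisBox(np.array([-0.85]), np.array([0.85]), "shifted")
        res = certify_box(quad_1d, box)
        cert = res.certificate
        margins = check_certificate(quad_1d, cert)
        assert min(margins.values()) >= 0
        assert 0 < cert.gamma < 1
        assert np.linalg.eigvalsh(cert.M)[0] > 0

    def test_shrinking_preserves_certifiability(self, quad_1d):
        box = AxisBox(np.array([-0.9]), np.array([0.9]), "shifted")
        assert certify_box(quad_1d, box).feasible
        for factor in (0.6, 0.25):
            assert certify_box(quad_1d, box.scaled(factor)).feasible

    def test_grow_never_crosses_unstable_equilibrium(self, quad_1d):
        seed = AxisBox(np.array([-0.1]), np.array([0.1]), "shifted")
        box, cert = grow_box(quad_1d, seed,
                             GrowthSchedule(factor=1.1, max_steps=80,
                                            nonneg_floor=False))
        assert box.upper[0] <= 1.0
        assert box.upper[0] >= 0.8  # conservative but not vacuous
        assert box.lower[0] <= seed.lower[0]
        assert check_certificate(quad_1d, cert)["vertex_derivative"] >= 0

    def test_grow_requires_certifiable_seed(self, quad_1d):
        seed = AxisBox(np.array([-0.5]), np.array([1.2]), "shifted")
        with pytest.raises(ValueError, match="seed box"):
            grow_box(quad_1d, seed)


class TestCertifyLinear:
    def test_linear_system_box_certifiable(self, toys_module):
        net = toys_module["linear_2d"].network
        quad = quadratic_decomposition(net, None, np.zeros(2))
        box = AxisBox(np.array([-1.0, -1.0]), np.array([1.0, 1.0]), "shifted")
        res = certify_box(quad, box)
        assert res.feasible

    def test_linear_growth_reaches_cap(self, toys_module):
        net = toys_module["linear_2d"].network
        quad = quadratic_decomposition(net, None, np.zeros(2))
        seed = AxisBox(np.array([-0.5, -0.5]), np.array([0.5, 0.5]), "shifted")
        box, _ = grow_box(quad, seed,
                          GrowthSchedule(factor=1.5, max_steps=12,
                                         nonneg_floor=False))
        assert box.volume() > 8 * seed.volume()  # global DA: grows freely

    def test_non_hurwitz_rejected(self, toys_module):
        net = toys_module["bistable_1d"].network
        quad = quadratic_decomposition(net, None, np.array([1.0]))  # unstable
        box = AxisBox(np.array([-0.1]), np.array([0.1]), "shifted")
        with pytest.raises(ValueError, match="Hurwitz"):
            certify_box(quad, box)


class TestCertify2D:
    def test_certified_box_sound_by_simulation(self, toys_module, quad_2d):
        toy = toys_module["bistable_2d"]
        seed = AxisBox(np.array([-0.05, -0.02]), np.array([0.05, 0.02]),
                       "shifted")
        box, cert = grow_box(quad_2d, seed,
                             GrowthSchedule(factor=1.3, max_steps=30))
        xe = np.array([1.0, 0.25])
        frac = verify_box_by_simulation(
            toy.network, None, to_absolute(box, xe), xe,
            n_samples=50, seed=7, horizon=60.0, tol=0.01,
        )
        assert frac == 1.0

    def test_box_straddling_saddle_fails_simulation(self, toys_module):
        toy = toys_module["bistable_2d"]
        xe = np.array([1.0, 0.25])
        box = AxisBox(np.array([0.5, 0.05]), np.array([4.5, 4.5]), "absolute")
        frac = verify_box_by_simulation(toy.network, None, box, xe,
                                        n_samples=30, seed=3, horizon=60.0)
        assert frac < 1.0

    def test_certified_box_excludes_saddle(self, quad_2d):
        # the saddle (2, 1) sits at (1, 0.75) in shifted coordinates
        box = AxisBox(np.array([-0.5, -0.2]), np.array([1.1, 0.85]), "shifted")
        res = certify_box(quad_2d, box)
        assert not res.feasible


class TestSampling:
    def test_sample_box_within_bounds(self, rng):
        box = AxisBox(np.array([0.0, -1.0]), np.array([2.0, 1.0]))
        pts = sample_box(box, 64, rng)
        assert pts.shape == (64, 2)
        assert np.all(pts >= box.lower) and np.all(pts <= box.upper)

    def test_sampling_deterministic_under_seed(self):
        box = AxisBox(np.array([0.0]), np.array([1.0]))
        a = sample_box(box, 16, np.random.default_rng(5))
        b = sample_box(box, 16, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestCertificateSerialization:
    def test_roundtrip_full_precision(self, quad_1d):
        res = certify_box(quad_1d,
                          AxisBox(np.array([-0.7]), np.array([0.7]), "shifted"))
        cert = res.certificate
        back = DACertificate.from_dict(cert.to_dict())
        np.testing.assert_array_equal(back.M, cert.M)
        assert back.gamma == cert.gamma
        np.testing.assert_array_equal(back.scaling, cert.scaling)


def test_default_gamma_grid_inside_unit_interval():
    g = default_gamma_grid()
    assert len(g) == 24
    assert g[0] > 0 and g[-1] < 1
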