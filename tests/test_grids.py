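"""Grid interpolation (naive vs precomputed), atom/pose scoring, bump filter."""

import numpy as np
import pytest

from minidock.errors import InputError, OutOfGridError
from minidock.fixtures import AnalyticField, PseudoAtom
from minidock.grids import (
    AtomScoreParams,
    BumpLimit,
    GridBundle,
    Lattice,
    PoseStatus,
    ScalarGrid,
    atom_energy,
    pose_energy,
    precompute,
    read_grid,
    trilinear_naive,
    write_grid,
)


def random_grid(rng, dims=(6, 5, 7), spacing=0.5):
    lat = Lattice(rng.normal(size=3), spacing, dims)
    return ScalarGrid(lat, rng.normal(size=dims))


def constant_bundle(value_rep=0.0, value_att=0.0, phi=0.0, dsv=0.0,
                    dims=(4, 4, 4), spacing=1.0):
    lat = Lattice(np.zeros(3), spacing, dims)
    mk = lambda v, kind: ScalarGrid(lat, np.full(dims, float(v)), kind)
    return GridBundle(mk(value_rep, "vdw_repulsive"), mk(value_att, "vdw_attractive"),
                      mk(phi, "electrostatic"), mk(dsv, "desolvation"))


class TestTrilinear:
    def test_exact_at_lattice_nodes(self):
        rng = np.random.default_rng(0)
        g = random_grid(rng)
        for _ in range(20):
            idx = tuple(rng.integers(0, d) for d in g.lattice.dims)
            pt = g.lattice.origin + g.lattice.spacing * np.array(idx)
            assert trilinear_naive(g, pt) == pytest.approx(g.values[idx], abs=1e-12)

    def test_reproduces_affine_fields_exactly(self):
        lat = Lattice(np.array([-1.0, 0.0, 2.0]), 0.7, (5, 6, 4))
        f = lambda p: 2 * p[..., 0] - p[..., 1] + 3 * p[..., 2] + 0.5
        axes = [lat.axis_points(i) for i in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        g = ScalarGrid(lat, f(np.stack([xx, yy, zz], axis=-1)))
        rng = np.random.default_rng(1)
        for _ in range(50):
            pt = lat.origin + rng.uniform(0, 1, 3) * (np.array(lat.dims) - 1) * lat.spacing
            assert trilinear_naive(g, pt) == pytest.approx(float(f(pt)), rel=1e-12)

    def test_cube_center_is_corner_mean(self):
        lat = Lattice(np.zeros(3), 1.0, (2, 2, 2))
        vals = np.arange(8, dtype=float).reshape(2, 2, 2)
        g = ScalarGrid(lat, vals)
        assert trilinear_naive(g, [0.5, 0.5, 0.5]) == pytest.approx(vals.mean())

    def test_outside_box_raises(self):
        g = random_grid(np.random.default_rng(2))
        with pytest.raises(OutOfGridError):
            trilinear_naive(g, g.lattice.origin - 1.0)

    def test_bounded_by_cube_corners(self):
        rng = np.random.default_rng(3)
        g = random_grid(rng)
        lat = g.lattice
        for _ in range(200):
            pt = lat.origin + rng.uniform(0, 1, 3) * (np.array(lat.dims) - 1) * lat.spacing
            v = trilinear_naive(g, pt)
            assert g.values.min() - 1e-12 <= v <= g.values.max() + 1e-12


class TestPrecomputed:
    def test_matches_naive_on_random_queries(self):
        rng = np.random.default_rng(4)
        g = random_grid(rng, dims=(8, 7, 6))
        fast = precompute(g)
        pts = g.lattice.origin + rng.uniform(0, 1, size=(10_000, 3)) * \
            (np.array(g.lattice.dims) - 1) * g.lattice.spacing
        got = fast.interpolate(pts)
        want = np.array([trilinear_naive(g, p) for p in pts[:500]])
        np.testing.assert_allclose(got[:500], want, rtol=1e-10, atol=1e-12)

    def test_exact_at_lattice_nodes(self):
        rng = np.random.default_rng(5)
        g = random_grid(rng)
        fast = precompute(g)
        for _ in range(25):
            idx = tuple(rng.integers(0, d) for d in g.lattice.dims)
            pt = g.lattice.origin + g.lattice.spacing * np.array(idx)
            assert fast.interpolate(pt[None])[0] == pytest.approx(g.values[idx], abs=1e-12)

    def test_constant_grid_constant_cubes(self):
        lat = Lattice(np.zeros(3), 1.0, (4, 4, 4))
        fast = precompute(ScalarGrid(lat, np.full((4, 4, 4), 3.25)))
        assert np.all(fast.corners == 3.25)

    def test_memory_is_eight_corner_records(self):
        g = random_grid(np.random.default_rng(6), dims=(5, 5, 5))
        fast = precompute(g)
        assert fast.corners.shape == (4, 4, 4, 8)


class TestAtomEnergy:
    def test_null_atom_scores_zero(self):
        b = constant_bundle(1.0, 2.0, -3.0, 0.5)
        e = atom_energy(AtomScoreParams(), [1.5, 1.5, 1.5], b)
        assert e["total"] == 0.0

    def test_unit_charge_reads_potential(self):
        b = constant_bundle(phi=-5.0)
        e = atom_energy(AtomScoreParams(charge=1.0), [1.0, 1.0, 1.0], b)
        assert e["electrostatic"] == pytest.approx(-5.0)
        assert e["total"] == pytest.approx(-5.0)

    def test_matches_analytic_pair_energy(self):
        """Fine grid sampled from a single pseudo-atom LJ+Coulomb field."""
        pseudo = PseudoAtom(np.zeros(3), sqrt_a=2.0, sqrt_b=5.0, charge=0.5,
                            desolv_amplitude=0.3)
        fld = AnalyticField((pseudo,))
        lat = Lattice(np.array([1.0, -1.0, -1.0]), 0.2, (16, 11, 11))
        bundle = fld.sample(lat)
        params = AtomScoreParams(sqrt_a=3.0, sqrt_b=20.0, charge=-0.4,
                                 desolvation_energy=0.8)
        probe = np.array([2.5, 0.13, 0.21])
        got = atom_energy(params, probe, bundle)
        want = (params.sqrt_a * fld.repulsive(probe)[0]
                - params.sqrt_b * fld.attractive(probe)[0]
                + params.charge * fld.potential(probe)[0]
                + params.desolvation_energy * fld.desolvation(probe)[0])
        assert got["total"] == pytest.approx(want, rel=0.02)


class TestPoseEnergy:
    def test_empty_field_scores_zero(self):
        b = constant_bundle()
        coords = np.array([[1, 1, 1], [2, 2, 2.0]])
        total, breakdown, status = pose_energy(coords, [AtomScoreParams()] * 2, b)
        assert status is PoseStatus.SCORED and total == 0.0
        assert breakdown.shape == (2, 3)

    def test_bump_threshold_semantics(self):
        b = constant_bundle(value_rep=60.0)
        p = [AtomScoreParams(sqrt_a=1.0)]
        total, breakdown, status = pose_energy(
            np.array([[1.0, 1.0, 1.0]]), p, b, BumpLimit(50.0))
        assert status is PoseStatus.BUMPED and total is None and breakdown is None
        total, _, status = pose_energy(np.array([[1.0, 1.0, 1.0]]), p, b, BumpLimit(None))
        assert status is PoseStatus.SCORED and total == pytest.approx(60.0)

    def test_bump_uses_running_sum(self):
        b = constant_bundle(value_rep=6.0)
        p = [AtomScoreParams(sqrt_a=1.0)] * 10  # cumulative 60 > 50
        _, _, status = pose_energy(np.full((10, 3), 1.0), p, b, BumpLimit(50.0))
        assert status is PoseStatus.BUMPED
        _, _, status = pose_energy(np.full((8, 3), 1.0), p[:8], b, BumpLimit(50.0))
        assert status is PoseStatus.SCORED

    def test_out_of_grid_atom_rejects_pose(self):
        b = constant_bundle()
        _, _, status = pose_energy(np.array([[1, 1, 1], [99, 0, 0.0]]),
                                   [AtomScoreParams()] * 2, b)
        assert status is PoseStatus.OUT_OF_GRID

    def test_total_equals_breakdown_sum(self):
        rng = np.random.default_rng(7)
        fld = AnalyticField((PseudoAtom(np.array([1.5, 1.5, 1.5]), 1e-3, 0.1, 0.2, 0.2),))
        bundle = fld.sample(Lattice(np.zeros(3), 0.5, (7, 7, 7)))
        coords = rng.uniform(0.5, 2.5, size=(6, 3))
        params = [AtomScoreParams(*np.abs(rng.normal(size=2)), rng.normal(),
                                  abs(rng.normal())) for _ in range(6)]
        total, breakdown, status = pose_energy(coords, params, bundle, BumpLimit(None))
        assert status is PoseStatus.SCORED
        assert total == pytest.approx(breakdown.sum(), abs=1e-9)

    def test_scoring_twice_bitwise_identical(self):
        b = constant_bundle(1.0, 0.5, -2.0, 0.1)
        coords = np.array([[1.1, 1.2, 1.3], [2.0, 1.0, 2.5]])
        params = [AtomScoreParams(0.3, 0.2, 0.1, 0.4)] * 2
        t1, b1, _ = pose_energy(coords, params, b)
        t2, b2, _ = pose_energy(coords, params, b)
        assert t1 == t2 and np.array_equal(b1, b2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            pose_energy(np.zeros((2, 3)), [AtomScoreParams()], constant_bundle())


class TestGridIO:
    @pytest.mark.parametrize("binary", [False, True])
    @pytest.mark.parametrize("suffix", [".grid", ".grid.gz"])
    def test_round_trip(self, tmp_path, binary, suffix):
        g = random_grid(np.random.default_rng(8))
        path = tmp_path / f"test{suffix}"
        write_grid(ScalarGrid(g.lattice, g.values, "electrostatic", "kcal/(mol e)"),
                   path, binary=binary)
        back = read_grid(path)
        assert back.kind == "electrostatic"
        assert back.lattice.dims == g.lattice.dims
        assert back.lattice.spacing == pytest.approx(g.lattice.spacing)
        np.testing.assert_allclose(back.values, g.values,
                                   atol=0 if binary else 1e-15)
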