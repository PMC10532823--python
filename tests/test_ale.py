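import math

import numpy as np
import pytest

from parcale.ale import (
    FWHM_TO_SIGMA,
    GridSpec,
    KernelModel,
    MapKind,
    NullModel,
    NullTables,
    ScalarMap,
    ThresholdSpec,
    ale_union,
    build_null,
    experiment_contribution,
    gaussian_kernel_map,
    kernel_fwhm,
    modeled_activation_map,
    voxel_p_map,
)
from parcale.coords import Experiment, Focus, Space, StudySet
from parcale.simulate import SimulationConfig, simulate_studyset


def _exp(eid, foci, n=12):
    return Experiment(eid, n, [Focus(*f, Space.MNI) for f in foci], Space.MNI)


class TestKernelFwhm:
    def test_zero_subject_term_gives_template_fwhm(self):
        k = KernelModel(fwhm_template=6.0, fwhm_subject=0.0)
        for n in (1, 10, 1000):
            assert kernel_fwhm(n, k) == pytest.approx(6.0)

    def test_single_subject_zero_template(self):
        k = KernelModel(fwhm_template=0.0, fwhm_subject=9.0)
        assert kernel_fwhm(1, k) == pytest.approx(9.0)

    def test_closed_form_oracle(self):
        # independent evaluation of FWHM = 2*sqrt(2 ln 2)*sqrt(st^2 + ss^2/N)
        k = KernelModel(fwhm_template=6.0, fwhm_subject=12.0)
        c = 2.0 * math.sqrt(2.0 * math.log(2.0))
        st, ss = 6.0 / c, 12.0 / c
        expected = c * math.sqrt(st**2 + ss**2 / 16.0)
        assert kernel_fwhm(16, k) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(6.7082039, abs=1e-6)  # 6*sqrt(1+1/4)

    def test_strictly_decreasing_in_n_with_template_limit(self):
        k = KernelModel()
        vals = [kernel_fwhm(n, k) for n in range(1, 200)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert kernel_fwhm(10**9, k) == pytest.approx(k.fwhm_template, rel=1e-6)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            kernel_fwhm(0)


class TestModeledActivation:
    def test_kernel_sums_to_one_over_unmasked_grid(self, tiny_grid):
        kern = gaussian_kernel_map(Focus(0, 0, 0), tiny_grid, fwhm=4.0)
        assert kern.sum() == pytest.approx(1.0, abs=1e-6)

    def test_kernel_matches_dense_bruteforce_evaluation(self, tiny_grid):
        # oracle: evaluate the Gaussian at every voxel center, normalize by
        # the full-lattice sum
        focus = Focus(1.0, -2.0, 0.5)
        fwhm = 5.0
        sigma = fwhm * FWHM_TO_SIGMA
        kern = gaussian_kernel_map(focus, tiny_grid, fwhm)
        ax = tiny_grid.axis_coords()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        d2 = (xx - focus.x) ** 2 + (yy - focus.y) ** 2 + (zz - focus.z) ** 2
        dense = np.exp(-0.5 * d2 / sigma**2)
        dense /= dense.sum()
        np.testing.assert_allclose(kern, dense, rtol=0, atol=1e-9)

    def test_coincident_foci_equal_single_focus_map(self, tiny_grid):
        e1 = _exp("a", [(0, 0, 0)])
        e2 = _exp("b", [(0, 0, 0), (0, 0, 0)])
        m1 = modeled_activation_map(e1, tiny_grid)
        m2 = modeled_activation_map(e2, tiny_grid)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_ma_bounded_and_zero_outside_mask(self, coarse_grid):
        e = _exp("a", [(-42, 22, 18), (10, -60, 44)])
        m = modeled_activation_map(e, coarse_grid)
        assert m.kind == MapKind.MA
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0
        assert np.all(m.values[~coarse_grid.mask] == 0.0)

    def test_far_outside_focus_skipped_with_warning(self, tiny_grid):
        e = _exp("a", [(0, 0, 0), (500, 500, 500)])
        with pytest.warns(UserWarning, match="skipped"):
            m = modeled_activation_map(e, tiny_grid)
        ref = modeled_activation_map(_exp("a", [(0, 0, 0)]), tiny_grid)
        np.testing.assert_array_equal(m.values, ref.values)

    def test_wrong_space_rejected(self, tiny_grid):
        e = Experiment("t", 10, [Focus(0, 0, 0, Space.TAL)], Space.TAL)
        with pytest.raises(ValueError, match="MNI"):
            modeled_activation_map(e, tiny_grid)


class TestAleUnion:
    def _map(self, grid, value, sid):
        vals = np.full(grid.shape, value)
        vals[~grid.mask] = 0.0
        return ScalarMap(grid=grid, values=vals, kind=MapKind.MA, source_id=sid)

    def test_single_map_is_identity(self, tiny_grid):
        m = self._map(tiny_grid, 0.3, "a")
        np.testing.assert_allclose(ale_union([m]).values, m.values, atol=1e-15)

    def test_union_of_two_halves_is_three_quarters(self, tiny_grid):
        maps = [self._map(tiny_grid, 0.5, s) for s in "ab"]
        np.testing.assert_allclose(ale_union(maps).values, 0.75, atol=1e-12)

    def test_union_spot_value_three_maps(self, tiny_grid):
        maps = [self._map(tiny_grid, v, s) for v, s in [(0.1, "a"), (0.2, "b"), (0.3, "c")]]
        np.testing.assert_allclose(ale_union(maps).values, 0.496, atol=1e-12)

    def test_order_invariance_is_bitwise(self, coarse_grid):
        s, _ = simulate_studyset(SimulationConfig(n_experiments=6, seed=7), coarse_grid)
        mas = [modeled_activation_map(e, coarse_grid) for e in s.experiments]
        a = ale_union(mas)
        b = ale_union(list(reversed(mas)))
        assert np.array_equal(a.values, b.values)

    def test_monotone_in_experiments_and_dominates_max(self, coarse_grid):
        s, _ = simulate_studyset(SimulationConfig(n_experiments=5, seed=3), coarse_grid)
        mas = [modeled_activation_map(e, coarse_grid) for e in s.experiments]
        partial = ale_union(mas[:4])
        full = ale_union(mas)
        assert np.all(full.values >= partial.values - 1e-15)
        stack = np.stack([m.values for m in mas])
        assert np.all(full.values >= stack.max(axis=0) - 1e-12)

    def test_grid_mismatch_and_empty_rejected(self, tiny_grid, coarse_grid):
        with pytest.raises(ValueError):
            ale_union([])
        with pytest.raises(ValueError, match="grid"):
            ale_union([self._map(tiny_grid, 0.1, "a"), self._map(coarse_grid, 0.1, "b")])


class TestVoxelP:
    def _null(self, values):
        return NullTables(
            voxel_null=np.sort(np.asarray(values, float)),
            cluster_extent_null=[0],
            ale_crit=0.0,
            seed=0,
            n_permutations=1,
        )

    def test_zero_ale_gives_p_one(self, tiny_grid):
        ale = ScalarMap(tiny_grid, np.zeros(tiny_grid.shape), MapKind.ALE)
        p = voxel_p_map(ale, self._null([0.0, 0.1, 0.2]))
        assert np.all(p.values[tiny_grid.mask] == 1.0)

    def test_above_all_null_hits_correction_floor(self, tiny_grid):
        vals = np.full(tiny_grid.shape, 0.9)
        ale = ScalarMap(tiny_grid, vals, MapKind.ALE)
        p = voxel_p_map(ale, self._null([0.1, 0.2, 0.3]))
        assert np.all(p.values[tiny_grid.mask] == pytest.approx(1.0 / 4.0))

    def test_matches_counting_oracle(self, tiny_grid):
        rng = np.random.default_rng(11)
        null = rng.random(200)
        vals = rng.random(tiny_grid.shape)
        ale = ScalarMap(tiny_grid, vals, MapKind.ALE)
        p = voxel_p_map(ale, self._null(null))
        expected = np.empty_like(vals)
        for idx in np.ndindex(tiny_grid.shape):  # brute-force count
            expected[idx] = ((null >= vals[idx]).sum() + 1) / (null.size + 1)
        np.testing.assert_allclose(p.values, expected, atol=1e-15)

    def test_monotone_nonincreasing_in_ale(self, tiny_grid):
        rng = np.random.default_rng(5)
        null = self._null(rng.random(100))
        lo = ScalarMap(tiny_grid, np.full(tiny_grid.shape, 0.2), MapKind.ALE)
        hi = ScalarMap(tiny_grid, np.full(tiny_grid.shape, 0.6), MapKind.ALE)
        assert np.all(
            voxel_p_map(hi, null).values[tiny_grid.mask]
            <= voxel_p_map(lo, null).values[tiny_grid.mask]
        )


class TestBuildNull:
    def test_seeded_determinism(self, coarse_grid):
        s, _ = simulate_studyset(SimulationConfig(n_experiments=4, seed=2), coarse_grid)
        kwargs = dict(
            g=coarse_grid,
            k=KernelModel(),
            nm=NullModel(n_permutations=5, seed=42),
            t=ThresholdSpec(),
        )
        n1 = build_null(s, **kwargs)
        n2 = build_null(s, **kwargs)
        assert np.array_equal(n1.voxel_null, n2.voxel_null)
        assert n1.cluster_extent_null == n2.cluster_extent_null
        assert n1.ale_crit == n2.ale_crit

    def test_extent_null_bounds(self, coarse_grid):
        s, _ = simulate_studyset(SimulationConfig(n_experiments=4, seed=2), coarse_grid)
        n = build_null(
            s, coarse_grid, KernelModel(), NullModel(n_permutations=10, seed=1), ThresholdSpec()
        )
        assert len(n.cluster_extent_null) == 10
        assert all(0 <= e <= coarse_grid.n_inmask for e in n.cluster_extent_null)
        assert n.voxel_null.size == 10 * coarse_grid.n_inmask

    def test_null_dominates_null_data_max(self, coarse_grid):
        # a study set generated with no convergence should rarely beat the
        # null distribution of the map maximum (the relevant calibration
        # statistic for the observed peak)
        wins = 0
        reps = 40
        n_perm = 50
        for seed in range(reps):
            s, _ = simulate_studyset(
                SimulationConfig(n_experiments=5, report_prob=0.0, seed=seed), coarse_grid
            )
            mas = [modeled_activation_map(e, coarse_grid) for e in s.experiments]
            ale = ale_union(mas)
            null = build_null(
                s,
                coarse_grid,
                KernelModel(),
                NullModel(n_permutations=n_perm, seed=seed + 500),
                ThresholdSpec(),
            )
            if ale.values.max() < np.quantile(null.max_ale_null, 0.999):
                wins += 1
        assert wins >= 0.95 * reps


class TestExperimentContribution:
    def _grid5(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-4, -4, -4]
        return GridSpec((5, 5, 5), affine, 2.0, np.ones((5, 5, 5), bool))

    def test_single_experiment_contributes_everything(self):
        g = self._grid5()
        e = _exp("only", [(0, 0, 0)])
        mas = [modeled_activation_map(e, g)]
        s = StudySet("s", [e])
        vox = np.argwhere(np.ones(g.shape, bool))
        contrib = experiment_contribution(vox, s, mas)
        assert contrib["only"] == pytest.approx(1.0)

    def test_identical_experiments_share_equally(self):
        g = self._grid5()
        ea, eb = _exp("a", [(0, 0, 0)]), _exp("b", [(0, 0, 0)])
        s = StudySet("s", [ea, eb])
        mas = [modeled_activation_map(e, g) for e in s.experiments]
        vox = np.argwhere(np.ones(g.shape, bool))
        contrib = experiment_contribution(vox, s, mas)
        assert contrib["a"] == pytest.approx(contrib["b"], rel=1e-12)

    def test_matches_leave_one_out_bruteforce(self):
        g = self._grid5()
        exps = [
            _exp("a", [(0, 0, 0)], n=8),
            _exp("b", [(2, 2, 0)], n=20),
            _exp("c", [(-2, 0, 2), (0, 2, -2)], n=40),
        ]
        s = StudySet("s", exps)
        mas = [modeled_activation_map(e, g) for e in exps]
        vox = np.argwhere(np.ones(g.shape, bool))
        contrib = experiment_contribution(vox, s, mas)
        idx = tuple(vox.T)
        full = ale_union(mas).values[idx].sum()
        for i, e in enumerate(exps):  # oracle: rerun the union from scratch
            rest = ale_union([m for j, m in enumerate(mas) if j != i]).values[idx].sum()
            assert contrib[e.id] == pytest.approx((full - rest) / full, abs=1e-10)
        assert all(0.0 <= c <= 1.0 for c in contrib.values())

    def test_zero_ale_cluster_rejected(self, tiny_grid):
        e = _exp("a", [(0, 0, 0)])
        s = StudySet("s", [e])
        m = ScalarMap(tiny_grid, np.zeros(tiny_grid.shape), MapKind.MA, source_id="a")
        with pytest.raises(ValueError, match="zero"):
            experiment_contribution(np.array([[0, 0, 0]]), s, [m])
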