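import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antagmap.errors import ConfigError, InputError
from antagmap.synthetic_data import ImagingScenario, cube_region, gen_imaging_cohort
from antagmap.vbm import (
    GlmResult,
    ImagingCohort,
    build_design,
    fit_voxelwise_glm,
    label_peak,
    max_t_null,
    permutation_peak_fwe,
    threshold_clusters,
    voxel_to_world,
)


def _tiny_cohort(y, x, covariates=None):
    """Single-voxel cohort from explicit outcome and dosage vectors."""
    n = len(y)
    return ImagingCohort(
        volumes=np.asarray(y, dtype=float).reshape(n, 1, 1, 1),
        mask=np.ones((1, 1, 1), dtype=bool),
        covariates=covariates if covariates is not None else pd.DataFrame(index=range(n)),
        dosage=pd.DataFrame({"rs1": np.asarray(x, dtype=float)}),
    )


class TestFitVoxelwiseGlm:
    def test_single_voxel_matches_closed_form_simple_regression(self):
        # intercept + dosage only; hand-computable normal equations
        x = np.array([0.0, 1.0, 1.0, 2.0, 2.0])
        y = np.array([1.0, 2.0, 2.5, 3.9, 4.1])
        xc = x - x.mean()
        beta = float(xc @ y / (xc @ xc))
        resid = y - y.mean() - beta * xc
        se = np.sqrt((resid @ resid) / 3 / (xc @ xc))
        expected_t = beta / se

        result = fit_voxelwise_glm(_tiny_cohort(y, x), "rs1")
        assert result.df == 3
        assert result.t[0, 0, 0] == pytest.approx(expected_t, rel=1e-12)
        assert result.beta[0, 0, 0] == pytest.approx(beta, rel=1e-12)

    def test_matches_statsmodels_on_random_designs(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(7, 13))
            n_cov = int(rng.integers(0, 3))
            x = rng.uniform(0, 2, size=n)
            cov = pd.DataFrame(
                {f"c{i}": rng.standard_normal(n) for i in range(n_cov)},
                index=range(n),
            )
            y = rng.standard_normal(n)
            result = fit_voxelwise_glm(_tiny_cohort(y, x, cov), "rs1")
            X = sm.add_constant(np.column_stack([x] + [cov[c] for c in cov.columns]))
            fit = sm.OLS(y, X).fit()
            assert result.t[0, 0, 0] == pytest.approx(fit.tvalues[1], rel=1e-8)

    def test_constant_dosage_is_rank_deficiency_error(self):
        with pytest.raises(InputError, match="dosage"):
            fit_voxelwise_glm(_tiny_cohort(np.arange(6.0), np.ones(6)), "rs1")

    def test_empty_mask_rejected(self):
        cohort = _tiny_cohort(np.arange(5.0), [0, 1, 2, 1, 0])
        cohort.mask[:] = False
        with pytest.raises(InputError):
            fit_voxelwise_glm(cohort, "rs1")

    def test_planted_effect_raises_t_inside_region(self):
        region = ((2, 2, 2), (2, 2, 3), (2, 3, 2))
        diffs = []
        for seed in range(50):
            cohort, _ = gen_imaging_cohort(
                ImagingScenario(shape=(10, 10, 10), n_subjects=20,
                                effect_voxels=region, effect_size=0.5, seed=seed)
            )
            t = fit_voxelwise_glm(cohort, "rs1").t
            inside = np.mean([t[v] for v in region])
            outside_mask = np.ones(t.shape, dtype=bool)
            for v in region:
                outside_mask[v] = False
            diffs.append(inside - t[outside_mask].mean())
        diffs = np.array(diffs)
        assert diffs.mean() > 0
        assert (diffs > 0).mean() >= 0.8

    def test_negating_volumes_negates_t_map(self):
        cohort, _ = gen_imaging_cohort(ImagingScenario(n_subjects=15, seed=3))
        t_pos = fit_voxelwise_glm(cohort, "rs1").t
        flipped = ImagingCohort(
            volumes=-cohort.volumes, mask=cohort.mask,
            covariates=cohort.covariates, dosage=cohort.dosage, affine=cohort.affine,
        )
        t_neg = fit_voxelwise_glm(flipped, "rs1").t
        np.testing.assert_allclose(t_neg[cohort.mask], -t_pos[cohort.mask], rtol=1e-9)

    def test_collinear_covariate_named(self):
        n = 10
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2, n)
        cov = pd.DataFrame({"dup": x})  # identical to the dosage column
        with pytest.raises(InputError, match="dup"):
            build_design(_tiny_cohort(rng.standard_normal(n), x, cov), "rs1")


def _result_from_tmap(t, df=30, affine=None):
    return GlmResult(
        t=t, beta=np.zeros_like(t), df=df,
        mask=np.ones(t.shape, dtype=bool),
        affine=np.eye(4) if affine is None else affine,
        design_columns=["intercept", "dosage"],
    )


class TestThresholdClusters:
    def test_single_blob_reported_with_size(self):
        t = np.zeros((8, 8, 8))
        blob = cube_region((4, 4, 4), half=1)[:12]
        for v in blob:
            t[v] = 6.0
        t[blob[0]] = 8.5
        (cluster,) = threshold_clusters(_result_from_tmap(t))
        assert cluster.k == 12
        assert cluster.peak_t == pytest.approx(8.5)
        assert cluster.peak_index == blob[0]

    def test_extent_rule_is_strict(self):
        # k > 10 required: a 10-voxel component fails, an 11-voxel one passes
        def line_tmap(n_voxels):
            t = np.zeros((12, 12, 12))
            for i in range(n_voxels):
                t[i, 0, 0] = 6.0
            return t

        assert threshold_clusters(_result_from_tmap(line_tmap(10)), k_min=11) == []
        clusters = threshold_clusters(_result_from_tmap(line_tmap(11)), k_min=11)
        assert len(clusters) == 1 and clusters[0].k == 11

    def test_corner_touching_blobs_depend_on_connectivity(self):
        t = np.zeros((6, 6, 6))
        a = [(1, 1, 1), (1, 1, 2), (1, 2, 1), (2, 1, 1), (1, 2, 2), (2, 1, 2),
             (2, 2, 1), (2, 2, 2), (1, 3, 1), (3, 1, 1), (1, 1, 3)]
        b = [(3, 3, 3), (3, 3, 4), (3, 4, 3), (4, 3, 3), (3, 4, 4), (4, 3, 4),
             (4, 4, 3), (4, 4, 4), (3, 5, 3), (5, 3, 3), (3, 3, 5)]
        for v in a + b:
            t[v] = 6.0
        res = _result_from_tmap(t)
        assert len(threshold_clusters(res, connectivity=6, k_min=11)) == 2
        assert len(threshold_clusters(res, connectivity=26, k_min=11)) == 1

    def test_negative_direction_finds_negative_blob(self):
        t = np.zeros((8, 8, 8))
        for v in cube_region((4, 4, 4), half=1)[:12]:
            t[v] = -6.0
        assert threshold_clusters(_result_from_tmap(t), direction="positive") == []
        (cluster,) = threshold_clusters(_result_from_tmap(t), direction="negative")
        assert cluster.peak_t < 0
        assert cluster.direction == "negative"

    def test_cluster_forming_threshold_uses_t_distribution(self):
        df = 30
        t_star = stats.t.isf(0.001, df)
        t = np.zeros((8, 8, 8))
        for v in cube_region((4, 4, 4), half=1)[:12]:
            t[v] = t_star - 0.01  # just below the one-sided 0.001 cutoff
        assert threshold_clusters(_result_from_tmap(t, df=df)) == []

    def test_peak_world_coordinates_via_affine(self):
        affine = np.array(
            [[2.0, 0, 0, -10.0], [0, 2.0, 0, -10.0], [0, 0, 2.0, -10.0], [0, 0, 0, 1.0]]
        )
        t = np.zeros((8, 8, 8))
        for v in cube_region((4, 4, 4), half=1)[:12]:
            t[v] = 6.0
        t[4, 4, 4] = 9.0
        (cluster,) = threshold_clusters(_result_from_tmap(t, affine=affine))
        assert cluster.peak_mni == (-2.0, -2.0, -2.0)

    def test_matches_floodfill_oracle_on_random_grids(self):
        def floodfill(grid, connectivity):
            offs = [
                (dx, dy, dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)
                and (
                    (connectivity == 6 and abs(dx) + abs(dy) + abs(dz) == 1)
                    or (connectivity == 18 and abs(dx) + abs(dy) + abs(dz) <= 2)
                    or connectivity == 26
                )
            ]
            seen = set()
            comps = []
            todo = list(map(tuple, np.argwhere(grid)))
            member = set(todo)
            for start in todo:
                if start in seen:
                    continue
                comp = set()
                stack = [start]
                while stack:
                    v = stack.pop()
                    if v in comp:
                        continue
                    comp.add(v)
                    for o in offs:
                        w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                        if w in member and w not in comp:
                            stack.append(w)
                seen |= comp
                comps.append(frozenset(comp))
            return set(comps)

        rng = np.random.default_rng(23)
        for connectivity in (6, 18, 26):
            for _ in range(8):
                grid = rng.random((8, 8, 8)) < 0.2
                t = np.where(grid, 10.0, 0.0)
                clusters = threshold_clusters(
                    _result_from_tmap(t), connectivity=connectivity, k_min=1
                )
                got = {
                    frozenset(
                        map(tuple, np.argwhere(_recover_component(t, c, connectivity)))
                    )
                    for c in clusters
                }
                assert got == floodfill(grid, connectivity)


def _recover_component(t, cluster, connectivity):
    from scipy import ndimage

    structures = {
        6: ndimage.generate_binary_structure(3, 1),
        18: ndimage.generate_binary_structure(3, 2),
        26: ndimage.generate_binary_structure(3, 3),
    }
    labels, _ = ndimage.label(t > 0, structure=structures[connectivity])
    return labels == labels[cluster.peak_index]


class TestPermutationFwe:
    def _cohort(self, seed=0, **kw):
        kw.setdefault("shape", (10, 10, 10))
        kw.setdefault("n_subjects", 24)
        return gen_imaging_cohort(ImagingScenario(seed=seed, **kw))[0]

    def test_seed_reproducibility(self):
        cohort = self._cohort()
        a = max_t_null(cohort, "rs1", n_perm=50, seed=5)
        b = max_t_null(cohort, "rs1", n_perm=50, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_single_permutation_bounds(self):
        cohort = self._cohort(effect_voxels=cube_region((5, 5, 5), 1),
                              effect_size=2.0, n_subjects=40)
        result = fit_voxelwise_glm(cohort, "rs1")
        clusters = threshold_clusters(result, k_min=1)
        assert clusters
        out = permutation_peak_fwe(cohort, "rs1", clusters, n_perm=1, seed=0)
        assert all(c.peak_p_fwe in (0.5, 1.0) for c in out)

    def test_invalid_n_perm(self):
        cohort = self._cohort()
        with pytest.raises(InputError):
            max_t_null(cohort, "rs1", n_perm=0, seed=0)

    def test_reduced_model_t_equals_full_model_t(self):
        # the Frisch–Waugh–Lovell reduction used for permutations must
        # reproduce the full-design dosage t exactly on the unpermuted data
        from antagmap.vbm import _fwl_tmap, _residualize

        cohort = self._cohort(seed=4)
        full = fit_voxelwise_glm(cohort, "rs1")
        x_res, y_res, df, _ = _residualize(cohort, "rs1")
        reduced = _fwl_tmap(x_res, y_res, df)
        np.testing.assert_allclose(reduced, full.t[cohort.mask], rtol=1e-9)

    def test_subject_order_invariance_of_fit_and_pvalues(self):
        cohort = self._cohort(seed=8, effect_voxels=cube_region((5, 5, 5), 1),
                              effect_size=1.5, n_subjects=40)
        rng = np.random.default_rng(1)
        perm = rng.permutation(cohort.n_subjects)
        shuffled = ImagingCohort(
            volumes=cohort.volumes[perm],
            mask=cohort.mask,
            covariates=cohort.covariates.iloc[perm].reset_index(drop=True),
            dosage=cohort.dosage.iloc[perm].reset_index(drop=True),
            affine=cohort.affine,
        )
        t1 = fit_voxelwise_glm(cohort, "rs1").t
        t2 = fit_voxelwise_glm(shuffled, "rs1").t
        np.testing.assert_allclose(t1, t2, rtol=1e-9)

        c1 = threshold_clusters(fit_voxelwise_glm(cohort, "rs1"), k_min=1)
        p1 = permutation_peak_fwe(cohort, "rs1", c1, n_perm=400, seed=0)[0].peak_p_fwe
        c2 = threshold_clusters(fit_voxelwise_glm(shuffled, "rs1"), k_min=1)
        p2 = permutation_peak_fwe(shuffled, "rs1", c2, n_perm=400, seed=0)[0].peak_p_fwe
        # the permutation stream acts on row order, so the estimates agree to
        # Monte-Carlo resolution rather than bit-for-bit
        assert abs(p1 - p2) <= 2 * np.sqrt(0.5 * 0.5 / 400) + 2 / 401


class TestLabelPeak:
    def _atlas(self):
        vol = np.zeros((6, 6, 6), dtype=int)
        vol[2, 2, 2] = 5
        return vol, np.eye(4), {5: "regionA"}

    def test_labeled_voxel(self):
        vol, aff, lut = self._atlas()
        assert label_peak((2.0, 2.0, 2.0), vol, aff, lut) == ("regionA", False)

    def test_background_is_unlabeled(self):
        vol, aff, lut = self._atlas()
        assert label_peak((0.0, 0.0, 0.0), vol, aff, lut) == ("unlabeled", False)

    def test_out_of_field_flagged(self):
        vol, aff, lut = self._atlas()
        label, flag = label_peak((100.0, 0.0, 0.0), vol, aff, lut)
        assert (label, flag) == ("unlabeled", True)

    def test_nearest_voxel_rounding_through_affine(self):
        vol, _, lut = self._atlas()
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        assert label_peak((4.4, 4.4, 3.8), vol, aff, lut) == ("regionA", False)


def test_voxel_to_world_applies_affine():
    aff = np.array([[2, 0, 0, -4], [0, 2, 0, -4], [0, 0, 2, -4], [0, 0, 0, 1]], dtype=float)
    assert voxel_to_world((2, 0, 1), aff) == (0.0, -4.0, -2.0)
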