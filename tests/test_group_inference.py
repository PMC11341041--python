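"""Voxel-wise GLM, cluster formation, permutation cluster FDR, seed maps."""

import numpy as np
import pytest
from scipy import stats

from boldgraph.group_inference import (
    ClusterResult, GroupDesign, cluster_fdr, form_clusters, residualize_scores,
    seed_connectivity, voxelwise_glm,
)


def make_design(n1=10, n2=10, seed=0):
    rng = np.random.default_rng(seed)
    return GroupDesign(group=np.r_[np.ones(n1), np.zeros(n2)],
                       age=rng.normal(36, 13, n1 + n2),
                       gender=(rng.random(n1 + n2) < 0.5).astype(float))


def flood_fill_components(supra, connectivity_offsets):
    """Brute-force connected-component oracle on a boolean 3D array."""
    comps, seen = [], set()
    coords = {tuple(c) for c in np.argwhere(supra)}
    for start in sorted(coords):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            for off in connectivity_offsets:
                nb = tuple(np.add(v, off))
                if nb in coords and nb not in comp:
                    stack.append(nb)
        seen |= comp
        comps.append(comp)
    return comps


def offsets_18():
    out = []
    for d in np.ndindex(3, 3, 3):
        off = np.array(d) - 1
        s = np.abs(off).sum()
        if 1 <= s <= 2:
            out.append(tuple(off))
    return out


class TestVoxelwiseGLM:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        design = make_design(3, 3, seed=1)
        maps = rng.standard_normal((6, 10))
        t, df = voxelwise_glm(maps, design)
        assert df == 2
        x = np.column_stack([np.ones(6), design.group, design.age, design.gender])
        xtx_inv = np.linalg.inv(x.T @ x)
        for v in range(10):
            beta = xtx_inv @ x.T @ maps[:, v]
            resid = maps[:, v] - x @ beta
            se = np.sqrt(resid @ resid / df * xtx_inv[1, 1])
            assert t[v] == pytest.approx(beta[1] / se, abs=1e-10)

    def test_null_covariates_reduce_to_two_sample_t(self):
        # with covariate coefficients truly zero the GLM t tracks the pooled t
        rng = np.random.default_rng(2)
        design = make_design(60, 60, seed=2)
        maps = rng.standard_normal((120, 2000))
        t_glm, _ = voxelwise_glm(maps, design)
        g = design.group.astype(bool)
        t_plain = stats.ttest_ind(maps[g], maps[~g]).statistic
        assert np.corrcoef(t_glm, t_plain)[0, 1] > 0.95
        # both should be ~ standard t under the null
        assert abs(t_glm.mean()) < 0.1
        assert t_glm.std() == pytest.approx(1.0, abs=0.1)
        # distributions agree: two-sample KS between the t maps is small
        ks = stats.ks_2samp(t_glm, t_plain).statistic
        assert ks < 0.05

    def test_degenerate_covariates_rejected(self):
        design = GroupDesign.__new__(GroupDesign)
        design.group = np.r_[np.ones(4), np.zeros(4)]
        design.age = np.full(8, 40.0)       # constant -> collinear with intercept
        design.gender = np.r_[np.ones(4), np.zeros(4)]  # identical to group
        with pytest.raises(ValueError, match="collinear"):
            voxelwise_glm(np.random.default_rng(0).standard_normal((8, 5)), design)


class TestFormClusters:
    def test_empty_when_nothing_suprathreshold(self):
        assert form_clusters(np.zeros((4, 4, 4)), df=30) == []

    def test_single_isolated_voxel(self):
        t = np.zeros((5, 5, 5))
        t[2, 2, 2] = 5.0
        (c,) = form_clusters(t, df=30)
        assert c.extent == 1 and c.peak_index == (2, 2, 2) and c.sign == 1

    def test_l_shaped_blob_single_cluster_under_18_connectivity(self):
        t = np.zeros((6, 6, 6))
        blob = [(1, 1, 1), (2, 1, 1), (3, 1, 1), (3, 2, 1), (3, 2, 2)]
        for v in blob:
            t[v] = 4.0
        clusters = form_clusters(t, df=30, connectivity=18)
        assert len(clusters) == 1 and clusters[0].extent == 5
        oracle = flood_fill_components(t > stats.t.isf(0.001, 30), offsets_18())
        assert len(oracle) == 1 and oracle[0] == {tuple(v) for v in clusters[0].voxels}

    def test_positive_and_negative_tails_separate(self):
        t = np.zeros((5, 5, 5))
        t[0, 0, 0], t[4, 4, 4] = 6.0, -6.0
        clusters = form_clusters(t, df=20)
        signs = sorted(c.sign for c in clusters)
        assert signs == [-1, 1]
        neg = [c for c in clusters if c.sign < 0][0]
        assert neg.peak_t == -6.0

    def test_agrees_with_flood_fill_on_random_instances(self, rng):
        for _ in range(10):
            t = rng.standard_normal((16, 16, 16)) * 2
            clusters = form_clusters(t, df=25, connectivity=18)
            thr = stats.t.isf(0.001, 25)
            oracle = (flood_fill_components(t > thr, offsets_18())
                      + flood_fill_components(-t > thr, offsets_18()))
            got = sorted(sorted(map(tuple, c.voxels)) for c in clusters)
            want = sorted(sorted(c) for c in oracle)
            assert got == want

    def test_affine_maps_peak_to_world_mm(self):
        t = np.zeros((4, 4, 4))
        t[1, 2, 3] = 9.0
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-10, -10, -10]
        (c,) = form_clusters(t, df=10, affine=affine)
        assert c.peak_coordinate == (-7.0, -4.0, -1.0)


class TestClusterFDR:
    def test_planted_blob_detected_and_p_bounds_hold(self):
        rng = np.random.default_rng(3)
        design = make_design(9, 9, seed=3)
        maps = rng.standard_normal((18, 10, 10, 10))
        maps[:9, 4:7, 4:7, 4:7] += 2.5  # 27-voxel blob
        clusters, null_max = cluster_fdr(maps, design, n_perm=200, seed=5)
        assert clusters, "blob not found"
        top = clusters[0]
        assert top.extent >= 15 and top.sign == 1
        assert top.p_uncorrected >= 1 / 201
        assert top.q_fdr < 0.05
        for c in clusters:
            assert 1 / 201 <= c.p_uncorrected <= 1.0
            assert c.q_fdr >= c.p_uncorrected - 1e-12

    def test_extent_smaller_than_all_null_maxima_gives_p_one(self):
        c = ClusterResult(voxels=np.zeros((1, 3), int), extent=1, peak_t=4.0,
                          peak_index=(0, 0, 0))
        null = np.full(100, 50)
        p = (1 + (null >= c.extent).sum()) / (1 + 100)
        assert p == 1.0

    def test_too_few_distinct_relabelings_rejected(self):
        design = make_design(2, 2, seed=0)
        maps = np.random.default_rng(0).standard_normal((4, 5, 5, 5))
        with pytest.raises(ValueError, match="distinct"):
            cluster_fdr(maps, design, n_perm=100)


class TestResidualize:
    def test_orthogonal_values_just_demeaned(self, rng):
        cov = np.column_stack([rng.standard_normal(20)])
        q, _ = np.linalg.qr(np.column_stack([np.ones(20), cov]))
        vals = rng.standard_normal(20)
        vals -= q @ (q.T @ vals)  # orthogonal to intercept and covariate
        resid = residualize_scores(vals + 3.0, cov)
        np.testing.assert_allclose(resid, vals, atol=1e-10)

    def test_exact_linear_function_gives_zero(self, rng):
        age = rng.normal(40, 10, 15)
        resid = residualize_scores(2.0 * age - 5.0, age)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_matches_lstsq_oracle(self, rng):
        vals = rng.standard_normal(20)
        cov = rng.standard_normal((20, 2))
        x = np.column_stack([np.ones(20), cov])
        beta, *_ = np.linalg.lstsq(x, vals, rcond=None)
        np.testing.assert_allclose(residualize_scores(vals, cov),
                                   vals - x @ beta, atol=1e-10)


class TestSeedConnectivity:
    def test_single_voxel_seed_equals_its_correlation_map(self, rng):
        vols = [rng.standard_normal((4, 4, 4, 40)) for _ in range(8)]
        seed = np.zeros((4, 4, 4), dtype=bool)
        seed[0, 0, 0] = True
        design = make_design(4, 4, seed=7)
        t_map, supra, df = seed_connectivity(seed, vols, design)
        # oracle: per-subject voxel-vs-seed correlation, Fisher z, GLM
        z = []
        for v in vols:
            sts = v[0, 0, 0]
            flat = v.reshape(-1, 40)
            r = np.array([np.corrcoef(sts, f)[0, 1] for f in flat])
            z.append(np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7)))
        t_oracle, _ = voxelwise_glm(np.asarray(z), design)
        np.testing.assert_allclose(t_map.ravel(), t_oracle, atol=1e-8)
        assert df == 4

    def test_degenerate_all_voxels_equal_seed_capped(self, rng):
        ts = rng.standard_normal(30)
        vol = np.tile(ts, (3, 3, 3, 1))
        seed = np.zeros((3, 3, 3), dtype=bool)
        seed[1, 1, 1] = True
        vols = [vol + 0.0 for _ in range(8)]
        design = make_design(4, 4, seed=8)
        # all z maps identical and at the cap -> zero variance -> t = 0 everywhere
        t_map, supra, _ = seed_connectivity(seed, vols, design)
        assert np.isfinite(t_map).all()
        assert not supra.any()

    def test_empty_seed_rejected(self, rng):
        with pytest.raises(ValueError):
            seed_connectivity(np.zeros((2, 2, 2), bool),
                              [rng.standard_normal((2, 2, 2, 10))], make_design(2, 2))

    def test_planted_seed_target_coupling_exceeds_t2(self):
        # group-1 subjects share a seed<->target signal; target voxels must
        # light up at the descriptive |t| > 2 threshold in most runs
        hits = 0
        for run in range(10):
            rng = np.random.default_rng(100 + run)
            design = make_design(9, 9, seed=run)
            vols = []
            for s in range(18):
                v = rng.standard_normal((4, 4, 4, 120))
                common = rng.standard_normal(120)
                v[0, 0, 0] += common  # seed voxel
                if design.group[s] == 1:
                    v[3, 3, 3] += 0.8 * common  # target coupling in group 1 only
                vols.append(v)
            seed = np.zeros((4, 4, 4), dtype=bool)
            seed[0, 0, 0] = True
            t_map, supra, _ = seed_connectivity(seed, vols, design)
            hits += bool(supra[3, 3, 3] and t_map[3, 3, 3] > 2)
        assert hits >= 8
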