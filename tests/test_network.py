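"""ROI extraction, Fisher-z connectivity, edge-wise tests, NBS, edge export."""

import numpy as np
import pandas as pd
import pytest

from boldgraph.network import (
    ConnectivityMatrix, connectivity_matrix, edgewise_ttest, export_edges,
    extract_roi_series, nbs, write_circos_links,
)
from boldgraph.simulate import make_parcellation


def union_find_components(edges, n_nodes):
    """Brute-force component oracle over an undirected edge list."""
    parent = list(range(n_nodes))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    groups = {}
    for i, j in edges:
        groups.setdefault(find(i), set()).add(tuple(sorted((i, j))))
    return sorted(sorted(g) for g in groups.values())


class TestExtractRoiSeries:
    def test_single_voxel_roi_passthrough(self, rng):
        parc = np.zeros((2, 2, 2), dtype=int)
        parc[0, 0, 0], parc[1, 1, 1] = 1, 2
        vol = rng.standard_normal((2, 2, 2, 15))
        out = extract_roi_series(vol, parc)
        np.testing.assert_array_equal(out[:, 0], vol[0, 0, 0])
        np.testing.assert_array_equal(out[:, 1], vol[1, 1, 1])

    def test_uniform_roi_mean_equals_member(self, rng):
        parc, _ = make_parcellation((4, 4, 4), 2)
        ts = rng.standard_normal(10)
        vol = np.where((parc == 1)[..., None], ts, 0.0)
        out = extract_roi_series(vol, parc)
        np.testing.assert_allclose(out[:, 0], ts)

    def test_empty_label_raises(self, rng):
        parc = np.zeros((3, 3, 3), dtype=int)
        parc[0, 0, 0] = 3  # labels 1 and 2 missing
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            extract_roi_series(rng.standard_normal((3, 3, 3, 5)), parc)


class TestConnectivityMatrix:
    def test_identical_series_capped_finite(self, rng):
        ts = rng.standard_normal(50)
        cm = connectivity_matrix(np.column_stack([ts, ts]))
        assert cm.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))
        assert np.isfinite(cm.z).all()

    def test_independent_series_z_near_zero(self, rng):
        t = 2000
        cm = connectivity_matrix(rng.standard_normal((t, 4)))
        off = cm.z[np.triu_indices(4, 1)]
        assert np.abs(off).max() < 3 / np.sqrt(t - 3)

    def test_known_r_maps_to_known_z(self):
        # construct two series with exact sample correlation 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0] * 25)
        y = 0.5 * x + np.sqrt(0.75) * np.array([1.0, 1.0, -1.0, -1.0] * 25)
        cm = connectivity_matrix(np.column_stack([x, y]))
        assert cm.z[0, 1] == pytest.approx(0.5493, abs=1e-4)

    def test_symmetry_and_zero_diagonal(self, rng):
        cm = connectivity_matrix(rng.standard_normal((40, 6)))
        np.testing.assert_array_equal(cm.z, cm.z.T)
        np.testing.assert_array_equal(np.diag(cm.z), 0.0)

    def test_zero_variance_roi_rejected(self, rng):
        x = rng.standard_normal((20, 3))
        x[:, 1] = 7.0
        with pytest.raises(ValueError, match="1"):
            connectivity_matrix(x)


class TestEdgewiseTTest:
    def test_identical_groups_give_zero_t(self, rng):
        z = rng.standard_normal((4, 5, 5))
        z = (z + z.transpose(0, 2, 1)) / 2
        mats = np.concatenate([z, z])
        group = np.r_[np.ones(4), np.zeros(4)]
        et = edgewise_ttest(mats, group)
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(et.t[iu], 0.0, atol=1e-10)
        np.testing.assert_allclose(et.p[iu], 1.0, atol=1e-10)

    def test_study_sized_groups_df_33(self, rng):
        mats = rng.standard_normal((35, 4, 4))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        et = edgewise_ttest(mats, np.r_[np.ones(17), np.zeros(18)])
        assert et.df == 33

    def test_single_edge_textbook_formula(self):
        x1 = np.array([0.8, 1.1, 0.9, 1.2])
        x2 = np.array([0.2, 0.4, 0.3])
        mats = np.zeros((7, 2, 2))
        mats[:, 0, 1] = mats[:, 1, 0] = np.r_[x1, x2]
        et = edgewise_ttest(mats, np.r_[np.ones(4), np.zeros(3)])
        sp2 = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
        sp2 /= 5
        t_oracle = (x1.mean() - x2.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 3))
        assert et.t[0, 1] == pytest.approx(t_oracle, abs=1e-12)
        assert et.t[0, 1] == et.t[1, 0]

    def test_zero_variance_edge_flagged(self):
        mats = np.zeros((6, 2, 2))
        mats[:, 0, 1] = mats[:, 1, 0] = 1.0
        et = edgewise_ttest(mats, np.r_[np.ones(3), np.zeros(3)])
        assert et.undefined[0, 1]
        assert et.t[0, 1] == 0.0


class TestNBS:
    def _planted_mats(self, rng, n1=12, n2=12, n_roi=12, dz=1.2,
                      edges=((0, 1), (1, 2), (2, 3))):
        mats = 0.1 * rng.standard_normal((n1 + n2, n_roi, n_roi))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        for i, j in edges:
            mats[:n1, i, j] += dz
            mats[:n1, j, i] += dz
        group = np.r_[np.ones(n1), np.zeros(n2)]
        return mats, group

    def test_single_strong_edge_extent_one(self, rng):
        mats, group = self._planted_mats(rng, edges=((3, 7),))
        res = nbs(mats, group, primary_p=1e-4, tail="greater", n_perm=200, seed=1)
        assert res.components
        assert res.components[0]["extent"] == 1
        assert res.components[0]["edges"] == [(3, 7)]

    def test_components_match_union_find_oracle(self, rng):
        for trial in range(10):
            edges = set()
            while len(edges) < 8:
                i, j = rng.integers(0, 10, 2)
                if i != j:
                    edges.add(tuple(sorted((int(i), int(j)))))
            mats, group = self._planted_mats(rng, n_roi=10, edges=tuple(edges))
            res = nbs(mats, group, primary_p=1e-4, tail="greater", n_perm=100, seed=trial)
            got = sorted(sorted(c["edges"]) for c in res.components)
            et = edgewise_ttest(mats, group)
            supra = [(i, j) for i in range(10) for j in range(i + 1, 10)
                     if et.t[i, j] > res.t_threshold]
            assert got == union_find_components(supra, 10)
            assert set(supra) >= edges

    def test_planted_component_significant(self, rng):
        mats, group = self._planted_mats(rng)
        res = nbs(mats, group, primary_p=1e-4, tail="greater", n_perm=500, seed=3)
        assert res.components[0]["extent"] == 3
        assert res.components[0]["p_fwer"] < 0.05
        assert res.components[0]["p_fwer"] >= 1 / 501

    def test_no_suprathreshold_edges_valid_empty_result(self, rng):
        mats = 0.01 * rng.standard_normal((10, 6, 6))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        res = nbs(mats, np.r_[np.ones(5), np.zeros(5)], n_perm=100, seed=0)
        assert res.components == []

    def test_node_relabeling_invariance(self, rng):
        mats, group = self._planted_mats(rng, n_roi=8, edges=((0, 1), (1, 2)))
        res_a = nbs(mats, group, n_perm=300, seed=11)
        perm = rng.permutation(8)
        mats_p = mats[:, perm][:, :, perm]
        res_b = nbs(mats_p, group, n_perm=300, seed=11)
        pa = sorted(c["p_fwer"] for c in res_a.components)
        pb = sorted(c["p_fwer"] for c in res_b.components)
        ea = sorted(c["extent"] for c in res_a.components)
        eb = sorted(c["extent"] for c in res_b.components)
        assert pa == pb and ea == eb

    def test_stricter_primary_threshold_never_grows_components(self, rng):
        mats, group = self._planted_mats(rng, dz=0.8)
        loose = nbs(mats, group, primary_p=1e-3, n_perm=100, seed=2)
        strict = nbs(mats, group, primary_p=1e-5, n_perm=100, seed=2)
        max_loose = max((c["extent"] for c in loose.components), default=0)
        max_strict = max((c["extent"] for c in strict.components), default=0)
        assert max_strict <= max_loose

    def test_less_tail_finds_decreases(self, rng):
        mats, group = self._planted_mats(rng, dz=-1.2, edges=((2, 5), (5, 8)))
        res = nbs(mats, group, tail="less", n_perm=200, seed=4)
        assert res.components[0]["edges"] == [(2, 5), (5, 8)]


class TestExportEdges:
    def _labels(self, n=6):
        return pd.DataFrame({"label_id": range(1, n + 1),
                             "name": [f"region{k}" for k in range(1, n + 1)],
                             "network": ["a"] * n})

    def _result(self, comps, tail="greater"):
        from boldgraph.network import NBSResult
        return NBSResult(components=comps, null_max_extents=np.zeros(100),
                         primary_p=1e-4, tail=tail, t_threshold=4.0, df=10)

    def _edge_test(self, n=6):
        from boldgraph.network import EdgeTest
        t = np.arange(n * n, dtype=float).reshape(n, n)
        t = (t + t.T) / 2
        return EdgeTest(t=t, df=10, p=np.ones((n, n)), undefined=np.zeros((n, n), bool))

    def test_empty_result_header_only(self, tmp_path):
        df = export_edges(self._result([]), self._edge_test(), self._labels())
        assert df.empty and list(df.columns) == ["node1", "node2", "t", "p_fwer", "sign"]
        write_circos_links(df, self._labels(), tmp_path / "links.tsv")
        lines = (tmp_path / "links.tsv").read_text().strip().splitlines()
        assert lines == ["node1\tnode2\tt\tp_fwer\tsign"]

    def test_single_edge_names_resolved(self):
        df = export_edges(self._result([{"edges": [(0, 2)], "extent": 1, "p_fwer": 0.01}]),
                          self._edge_test(), self._labels())
        assert len(df) == 1
        assert df.node1[0] == "region1" and df.node2[0] == "region3"
        assert df.sign[0] == 1

    def test_duplicate_symmetric_edges_deduplicated(self):
        comps = [{"edges": [(0, 2), (2, 0)], "extent": 2, "p_fwer": 0.01}]
        df = export_edges(self._result(comps), self._edge_test(), self._labels())
        assert len(df) == 1
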