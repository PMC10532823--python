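import numpy as np
import pandas as pd
import pytest

from parcale.ale import GridSpec, ThresholdSpec
from parcale.atlas import (
    AtlasIntegrityError,
    ParcelInfo,
    ParcellationAtlas,
    cluster_parcel_overlap,
    parcels_to_networks,
    read_atlas,
    resample_labels_nearest,
)
from parcale.clusters import label_clusters
from parcale.simulate import make_toy_atlas


def _grid(shape=(8, 8, 8), vox=2.0, origin=None):
    affine = np.diag([vox, vox, vox, 1.0])
    if origin is not None:
        affine[:3, 3] = origin
    return GridSpec(shape, affine, vox, np.ones(shape, bool))


def _atlas_two_parcels(g):
    labels = np.zeros(g.shape, dtype=np.int32)
    labels[:4] = 1
    labels[4:] = 2
    table = {
        1: ParcelInfo("P01", "L", "DMN"),
        2: ParcelInfo("P01", "R", "CEN"),
    }
    return ParcellationAtlas(grid=g, labels=labels, table=table)


class TestAtlasIntegrity:
    def test_volume_label_missing_from_table_named(self):
        g = _grid()
        labels = np.zeros(g.shape, dtype=np.int32)
        labels[0, 0, 0] = 7
        with pytest.raises(AtlasIntegrityError, match="7"):
            ParcellationAtlas(grid=g, labels=labels, table={})

    def test_duplicate_tagged_names_rejected(self):
        g = _grid()
        labels = np.zeros(g.shape, dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[1, 0, 0] = 2
        table = {1: ParcelInfo("A", "L", "DMN"), 2: ParcelInfo("A", "L", "CEN")}
        with pytest.raises(AtlasIntegrityError, match="duplicate"):
            ParcellationAtlas(grid=g, labels=labels, table=table)

    def test_round_trip_through_files(self, tmp_path, coarse_grid):
        atlas = make_toy_atlas(coarse_grid, parcels_per_hemisphere=3)
        atlas.save(tmp_path / "a.nii", tmp_path / "a.tsv")
        back = read_atlas(tmp_path / "a.nii", tmp_path / "a.tsv", coarse_grid)
        np.testing.assert_array_equal(back.labels, atlas.labels)
        assert back.table == atlas.table

    def test_table_missing_id_on_read(self, tmp_path, coarse_grid):
        atlas = make_toy_atlas(coarse_grid, parcels_per_hemisphere=2)
        atlas.save(tmp_path / "a.nii", tmp_path / "a.tsv")
        df = pd.read_csv(tmp_path / "a.tsv", sep="\t")
        df[df.label_id != 1].to_csv(tmp_path / "a.tsv", sep="\t", index=False)
        with pytest.raises(AtlasIntegrityError, match=r"\[1\]"):
            read_atlas(tmp_path / "a.nii", tmp_path / "a.tsv", coarse_grid)


class TestResampling:
    def test_nearest_neighbor_matches_bruteforce(self):
        src = _grid((6, 6, 6), vox=4.0, origin=(-10, -10, -10))
        dst = _grid((10, 10, 10), vox=2.0, origin=(-9, -9, -9))
        rng = np.random.default_rng(31)
        labels = rng.integers(0, 5, size=src.shape).astype(np.int32)
        out = resample_labels_nearest(labels, src.affine, dst)
        src_centers = src.voxel_to_mm(np.argwhere(np.ones(src.shape, bool)))
        src_idx = np.argwhere(np.ones(src.shape, bool))
        for v in map(tuple, np.argwhere(np.ones(dst.shape, bool))):
            mm = dst.voxel_to_mm(np.array(v))
            d = np.linalg.norm(src_centers - mm, axis=1)
            order = np.argsort(d)
            # skip ambiguous ties between distinct labels
            nearest = src_idx[order[0]]
            if d[order[1]] - d[order[0]] < 1e-9:
                continue
            assert out[v] == labels[tuple(nearest)]

    def test_resampling_preserves_label_inventory(self, coarse_grid, sim_grid):
        atlas = make_toy_atlas(coarse_grid, parcels_per_hemisphere=3)
        out = resample_labels_nearest(atlas.labels, coarse_grid.affine, sim_grid)
        assert set(np.unique(out)) <= set(np.unique(atlas.labels))


class TestOverlap:
    def test_cluster_inside_one_parcel(self):
        g = _grid()
        atlas = _atlas_two_parcels(g)
        supra = np.zeros(g.shape, bool)
        supra[1:3, 1:3, 1:3] = True
        cs = label_clusters(supra, g)
        df = cluster_parcel_overlap(cs, atlas)
        assert len(df) == 1
        row = df.iloc[0]
        assert row.parcel == "L_P01"
        assert row.pct_of_cluster == pytest.approx(100.0)
        assert row.n_voxels == 8

    def test_straddling_cluster_six_four_split(self):
        g = _grid()
        atlas = _atlas_two_parcels(g)
        supra = np.zeros(g.shape, bool)
        supra[:4, 0, 0] = True  # 4 voxels in L (block boundary at x index 4)
        supra[4:10, 0, 0] = True  # remaining 4 voxels in R
        supra[0:2, 1, 0] = True  # 2 more in L -> 6 L / 4 R
        cs = label_clusters(supra, g)
        assert len(cs) == 1
        df = cluster_parcel_overlap(cs, atlas)
        by = dict(zip(df.parcel, df.pct_of_cluster))
        assert by["L_P01"] == pytest.approx(60.0)
        assert by["R_P01"] == pytest.approx(40.0)

    def test_matches_exhaustive_tally_and_sums_to_100(self, coarse_grid):
        atlas = make_toy_atlas(coarse_grid, parcels_per_hemisphere=4)
        rng = np.random.default_rng(7)
        supra = (rng.random(coarse_grid.shape) < 0.05) & coarse_grid.mask
        # also include out-of-mask voxels to exercise the unlabeled share
        supra |= rng.random(coarse_grid.shape) < 0.01
        cs = label_clusters(supra, coarse_grid)
        df = cluster_parcel_overlap(cs, atlas)
        tagged = {lab: info.tagged_name for lab, info in atlas.table.items()}
        for c in cs.clusters:
            counts: dict[str, int] = {}
            for v in map(tuple, c.voxels):  # voxel-by-voxel oracle
                lab = int(atlas.labels[v])
                counts[tagged.get(lab, "<unlabeled>")] = counts.get(tagged.get(lab, "<unlabeled>"), 0) + 1
            sub = df[df.cluster_id == c.id]
            assert dict(zip(sub.parcel, sub.n_voxels)) == counts
            assert sub.pct_of_cluster.sum() == pytest.approx(100.0, abs=1e-6)
        parcel_sizes = atlas.parcel_sizes()
        for name, grp in df[df.parcel != "<unlabeled>"].groupby("parcel"):
            lab = atlas.by_tagged_name()[name]
            assert grp.n_voxels.sum() <= parcel_sizes[lab]

    def test_grid_mismatch_rejected(self, coarse_grid):
        g = _grid()
        atlas = _atlas_two_parcels(g)
        supra = np.zeros(coarse_grid.shape, bool)
        supra[20, 20, 20] = True
        cs = label_clusters(supra, coarse_grid)
        with pytest.raises(ValueError, match="grids"):
            cluster_parcel_overlap(cs, atlas)


class TestNetworks:
    def _atlas(self, assignments):
        g = _grid()
        labels = np.zeros(g.shape, dtype=np.int32)
        table = {}
        for i, (name, hemi, net) in enumerate(assignments, start=1):
            labels[i - 1, 0, 0] = i
            table[i] = ParcelInfo(name, hemi, net)
        return ParcellationAtlas(grid=g, labels=labels, table=table)

    def test_empty_parcel_set_gives_empty_summary(self):
        atlas = self._atlas([("A", "L", "DMN")])
        assert parcels_to_networks(set(), atlas) == {}

    def test_right_lateralized_cen_pair(self):
        atlas = self._atlas([("a32pr", "R", "CEN"), ("IP2", "R", "CEN")])
        out = parcels_to_networks({"R_a32pr", "R_IP2"}, atlas)
        assert set(out) == {"CEN"}
        assert out["CEN"]["R"] == ["R_IP2", "R_a32pr"]
        assert out["CEN"]["L"] == []

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(13)
        nets = ["DMN", "CEN", "salience", "limbic"]
        assignments = [
            (f"X{i}", "L" if rng.random() < 0.5 else "R", nets[int(rng.integers(0, 4))])
            for i in range(8)
        ]
        atlas = self._atlas(assignments)
        tagged = [f"{h}_{n}" for n, h, _ in assignments]
        out = parcels_to_networks(set(tagged), atlas)
        expected: dict[str, dict[str, list[str]]] = {}
        for (name, hemi, net), t in zip(assignments, tagged):  # brute-force group-by
            expected.setdefault(net, {"L": [], "R": []})[hemi].append(t)
        for net in expected:
            for h in ("L", "R"):
                expected[net][h].sort()
        assert out == expected

    def test_unknown_parcel_named_in_error(self):
        atlas = self._atlas([("A", "L", "DMN")])
        with pytest.raises(KeyError, match="R_ghost"):
            parcels_to_networks({"L_A", "R_ghost"}, atlas)
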