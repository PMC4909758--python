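"""Seed-target tables, inclusion threshold, voxel maps, splitting, volumes."""

import numpy as np
import pytest

import bgconnect as bg
from bgconnect.errors import ConfigError
from bgconnect.track_selection import LabelSequence

SS = bg.StructureSet({"STN": 1, "SNc": 2, "SNr": 3, "GPe": 4, "GPi": 5, "capsule": 6})


def seq_of(sid, *labels):
    return LabelSequence(sid, [(l, i * 2, i * 2 + 1) for i, l in enumerate(labels)])


class TestSeedTargetTable:
    def test_simple_percentage(self):
        seqs = [seq_of(i, 1, 3) for i in range(3)] + [seq_of(i, 1) for i in range(3, 10)]
        t = bg.seed_target_table(seqs, SS)
        assert t.totals["STN"] == 10
        assert t.counts.loc["SNr", "STN"] == 3
        assert t.percent.loc["SNr", "STN"] == 30.0

    def test_double_exit_counted_once(self):
        # a track leaving the STN at two borders: STN GPe STN SNr
        t = bg.seed_target_table([seq_of(0, 1, 4, 1, 3)], SS)
        assert t.totals["STN"] == 1
        assert t.counts.loc["GPe", "STN"] == 1
        assert t.counts.loc["SNr", "STN"] == 1

    def test_multi_target_column_sums_exceed_100(self):
        seqs = [seq_of(i, 1, 2, 3, 4) for i in range(5)]
        t = bg.seed_target_table(seqs, SS)
        assert t.percent["STN"].sum() > 100.0

    def test_union_semantics_for_composites(self):
        # one track touches both SN parts, one only SNc
        seqs = [seq_of(0, 1, 2, 3), seq_of(1, 1, 2)]
        t = bg.seed_target_table(seqs, SS)
        assert t.counts.loc["SN", "STN"] == 2  # not 3: union, no double count
        assert (
            t.counts.loc["SN", "STN"]
            <= t.counts.loc["SNc", "STN"] + t.counts.loc["SNr", "STN"]
        )

    def test_seed_vs_itself_blank(self):
        t = bg.seed_target_table([seq_of(0, 1, 2)], SS)
        assert np.isnan(t.percent.loc["STN", "STN"])
        assert np.isnan(t.percent.loc["SN", "SNc"])  # composite containing the seed

    def test_unknown_target_rejected(self):
        with pytest.raises(ConfigError):
            bg.seed_target_table([seq_of(0, 1, 2)], SS, targets=["nonesuch"])

    def test_phantom_ground_truth(self, paper_phantom):
        _, seqs = bg.select_seed_tracks(
            paper_phantom.tractogram, paper_phantom.volume, paper_phantom.structures
        )
        t = bg.seed_target_table(seqs, paper_phantom.structures)
        gt = paper_phantom.ground_truth
        assert t.totals.equals(gt.seed_totals)
        assert t.counts.equals(gt.seed_target_counts)
        # count(s, t) never exceeds total_tracks(s); percentages in [0, 100]
        for s in t.counts.columns:
            assert (t.counts[s] <= t.totals[s]).all()
        vals = t.percent.values
        finite = vals[~np.isnan(vals)]
        assert ((finite >= 0) & (finite <= 100)).all()


class TestInclusionThreshold:
    def _table(self, rows):
        seqs = []
        sid = 0
        for _ in range(100):
            seqs.append(seq_of(sid, 1))
            sid += 1
        # rows: dict target_label -> count of STN tracks also touching it
        for lbl, n in rows.items():
            for _ in range(n):
                seqs.append(seq_of(sid, 1, lbl))
                sid += 1
        return bg.seed_target_table(seqs, SS)

    def test_below_threshold_everywhere_dropped(self):
        t = self._table({6: 1})  # capsule on ~0.99% of 101 STN tracks
        kept = bg.apply_inclusion_threshold(t, 1.0)
        assert "capsule" in kept.dropped_targets

    def test_retained_if_any_seed_reaches_threshold(self):
        # capsule reaches 50% for GPe tracks though <1% for STN
        seqs = [seq_of(i, 1) for i in range(200)]
        seqs.append(seq_of(200, 1, 6))
        seqs += [seq_of(300 + i, 4, 6) for i in range(5)]
        t = bg.seed_target_table(seqs, SS)
        assert t.percent.loc["capsule", "STN"] < 1.0
        kept = bg.apply_inclusion_threshold(t, 1.0)
        assert "capsule" in kept.percent.index

    def test_zero_threshold_is_identity(self, paper_phantom):
        _, seqs = bg.select_seed_tracks(
            paper_phantom.tractogram, paper_phantom.volume, paper_phantom.structures
        )
        t = bg.seed_target_table(seqs, paper_phantom.structures)
        kept = bg.apply_inclusion_threshold(t, 0.0)
        assert list(kept.percent.index) == list(t.percent.index)


class TestVoxelMap:
    @pytest.fixture()
    def corridor_world(self):
        """A nucleus entered through two disjoint corridors; only corridor A
        continues to the target."""
        grid = np.zeros((30, 10, 5), dtype=np.int32)
        grid[10:15, :, :] = 2   # nucleus (SNc stand-in)
        grid[20:25, :, :] = 1   # target (STN stand-in)
        vol = bg.LabelVolume(grid, np.eye(4))
        ss = bg.StructureSet({"STN": 1, "SNc": 2, "SNr": 3, "GPe": 4, "GPi": 5})
        tracks = []
        for i in range(4):  # corridor A: y=2, reaches the target
            x = np.linspace(0, 24, 120)
            tracks.append(
                bg.Streamline(np.stack([x, np.full_like(x, 2.0), np.full_like(x, 2.0)], 1), id=i)
            )
        for i in range(4, 7):  # corridor B: y=7, stops inside the nucleus
            x = np.linspace(0, 14, 80)
            tracks.append(
                bg.Streamline(np.stack([x, np.full_like(x, 7.0), np.full_like(x, 2.0)], 1), id=i)
            )
        return tracks, vol, ss

    def test_two_corridor_map(self, corridor_world):
        tracks, vol, ss = corridor_world
        vm = bg.voxel_projection_map(tracks, vol, ss, "SNc", "STN")
        a = vm.values[10:15, 2, 2]
        b = vm.values[10:15, 7, 2]
        untraversed = vm.values[10:15, 4, 2]
        assert (a == 100.0).all()
        assert (b == 0.0).all()
        assert np.isnan(untraversed).all()
        # outside the nucleus everything is NaN
        assert np.isnan(vm.values[0, 2, 2]) and np.isnan(vm.values[22, 2, 2])

    def test_partial_fraction(self, corridor_world):
        tracks, vol, ss = corridor_world
        # route corridor B through the same voxels as A: 4 of 7 reach target
        moved = [
            bg.Streamline(np.stack([s.points[:, 0], np.full(len(s), 2.0), np.full(len(s), 2.0)], 1), id=s.id)
            for s in tracks
        ]
        vm = bg.voxel_projection_map(moved, vol, ss, "SNc", "STN")
        np.testing.assert_allclose(vm.values[10:15, 2, 2], 100 * 4 / 7)

    def test_track_through_voxel_twice_counts_once(self, corridor_world):
        _, vol, ss = corridor_world
        x = np.concatenate([np.linspace(0, 24, 120), np.linspace(24, 0, 120)])
        back_and_forth = bg.Streamline(
            np.stack([x, np.full_like(x, 2.0), np.full_like(x, 2.0)], 1), id=0
        )
        vm = bg.voxel_projection_map([back_and_forth], vol, ss, "SNc", "STN")
        assert (vm.values[10:15, 2, 2] == 100.0).all()

    def test_nifti_output_aligned(self, corridor_world, tmp_path):
        import nibabel as nib

        tracks, vol, ss = corridor_world
        vm = bg.voxel_projection_map(tracks, vol, ss, "SNc", "STN")
        vm.to_nifti(tmp_path / "m.nii.gz")
        img = nib.load(str(tmp_path / "m.nii.gz"))
        assert img.shape == vol.shape
        np.testing.assert_allclose(img.affine, vol.affine)


class TestSplitStructure:
    def test_symmetric_box_equal_halves(self):
        grid = np.zeros((20, 10, 10), dtype=np.int32)
        grid[2:18, 3:7, 3:7] = 4
        vol = bg.LabelVolume(grid, np.eye(4))
        out, la, lp = bg.split_structure(vol, 4)
        na = np.count_nonzero(out.grid == la)
        np_ = np.count_nonzero(out.grid == lp)
        assert abs(na - np_) <= 1
        assert na + np_ == np.count_nonzero(grid == 4)
        assert np.count_nonzero(out.grid == 4) == 0

    def test_principal_axis_is_longest_extent(self):
        # box elongated along y: the splitting plane separates low/high y
        grid = np.zeros((10, 30, 10), dtype=np.int32)
        grid[4:7, 2:28, 4:7] = 4
        vol = bg.LabelVolume(grid, np.eye(4))
        out, la, lp = bg.split_structure(vol, 4)
        ys_a = np.argwhere(out.grid == la)[:, 1]
        ys_p = np.argwhere(out.grid == lp)[:, 1]
        assert ys_a.min() > ys_p.max()  # A side is anterior (+y)

    def test_degenerate_rejected(self):
        grid = np.zeros((5, 5, 5), dtype=np.int32)
        grid[1, 1, 1] = 4
        with pytest.raises(ConfigError):
            bg.split_structure(bg.LabelVolume(grid, np.eye(4)), 4)

    def test_halves_union_equals_whole_per_track(self, paper_phantom):
        """A track intersects GPe iff it intersects one of its halves."""
        vol, ss = paper_phantom.volume, paper_phantom.structures
        lbl = ss.label("GPe")
        split_vol, la, lp = bg.split_structure(vol, lbl)
        for s in paper_phantom.tractogram.streamlines[::20]:
            whole = lbl in bg.label_sequence(s, vol).label_set()
            parts = bg.label_sequence(s, split_vol).label_set()
            assert whole == bool({la, lp} & parts)


class TestStructureVolume:
    def test_voxel_arithmetic(self):
        grid = np.zeros((10, 10, 10), dtype=np.int32)
        grid.flat[:100] = 2
        vol = bg.LabelVolume(grid, np.diag([0.3, 0.3, 0.3, 1.0]))
        assert bg.structure_volume(vol, 2) == pytest.approx(2.7)

    def test_absent_label_is_zero(self, identity_volume):
        assert bg.structure_volume(identity_volume, 99) == 0.0

    def test_ellipsoids_close_to_analytic(self, paper_phantom):
        for s in paper_phantom.spec.structures:
            if s.geometry.kind != "ellipsoid":
                continue
            v = bg.structure_volume(paper_phantom.volume, s.label)
            assert v == pytest.approx(s.geometry.analytic_volume, rel=0.10)
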