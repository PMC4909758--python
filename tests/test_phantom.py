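"""Phantom generation: rasterization, bundle synthesis, ground truth."""

import numpy as np
import pandas as pd
import pytest

import bgconnect as bg
from bgconnect.errors import PhantomSpecError
from bgconnect.phantom import Geometry, StructureGeom


def small_spec(structures, bundles=(), obstacle=None, seed=0, step=0.2,
               grid=(40, 40, 40), voxel=0.5):
    return bg.PhantomSpec(
        structures=list(structures), bundles=list(bundles), grid_shape=grid,
        voxel_size=voxel, obstacle=obstacle, rng_seed=seed, step=step,
    )


CORE_GEOMS = [
    StructureGeom("STN", 1, Geometry("ellipsoid", (5.0, 5.0, 10.0), (2.0, 2.0, 2.0))),
    StructureGeom("SNc", 2, Geometry("ellipsoid", (5.0, 12.0, 10.0), (2.0, 2.0, 2.0))),
    StructureGeom("SNr", 3, Geometry("ellipsoid", (5.0, 5.0, 4.0), (2.0, 2.0, 2.0))),
    StructureGeom("GPe", 4, Geometry("ellipsoid", (15.0, 5.0, 10.0), (2.0, 2.0, 2.0))),
    StructureGeom("GPi", 5, Geometry("ellipsoid", (15.0, 12.0, 10.0), (2.0, 2.0, 2.0))),
]


class TestRasterize:
    def test_sphere_against_brute_force(self):
        centre = (15.0, 15.0, 4.0)
        geom = Geometry("ellipsoid", centre, (1.5, 1.5, 1.5))
        spec = small_spec([StructureGeom("sphere", 1, geom)])
        vol = bg.rasterize_structures(spec)
        # independent brute force over all voxel centres
        expected = 0
        for i in range(40):
            for j in range(40):
                for k in range(40):
                    p = np.array([i, j, k]) * 0.5
                    if np.sum(((p - np.array(centre)) / 1.5) ** 2) <= 1.0:
                        expected += 1
        assert np.count_nonzero(vol.grid == 1) == expected

    def test_touching_boxes_allowed(self):
        a = StructureGeom("STN", 1, Geometry("box", (4.0, 5.0, 5.0), (1.0, 1.0, 1.0)))
        # shares the x=5 face with a; voxel centres are at multiples of 0.5,
        # the face plane x=5.0 holds voxel centres claimed by whichever box
        # contains them first -> boundary-inclusive contains would clash, so
        # offset by one voxel to make interiors disjoint
        b = StructureGeom("SNc", 2, Geometry("box", (6.5, 5.0, 5.0), (1.0, 1.0, 1.0)))
        spec = small_spec([a, b])
        vol = bg.rasterize_structures(spec)
        assert np.count_nonzero(vol.grid == 1) > 0
        assert np.count_nonzero(vol.grid == 2) > 0

    def test_overlap_rejected_with_pair_named(self):
        a = StructureGeom("STN", 1, Geometry("ellipsoid", (5.0, 5.0, 5.0), (2.0, 2.0, 2.0)))
        b = StructureGeom("SNc", 2, Geometry("ellipsoid", (6.0, 5.0, 5.0), (2.0, 2.0, 2.0)))
        spec = small_spec([a, b])
        with pytest.raises(PhantomSpecError, match="STN.*SNc|SNc.*STN"):
            bg.rasterize_structures(spec)

    def test_volume_conservation(self, paper_phantom):
        vol = paper_phantom.volume
        total = sum(np.count_nonzero(vol.grid == s.label) for s in paper_phantom.spec.structures)
        assert total + np.count_nonzero(vol.grid == 0) == vol.grid.size


class TestSynthesize:
    def test_straight_bundle_label_sequence(self):
        spec = small_spec(CORE_GEOMS, [bg.BundleSpec(["STN", "GPe"], 10, "straight", 0.2)])
        res = bg.make_phantom(spec)
        for s in res.tractogram:
            assert bg.label_sequence(s, res.volume).labels() == [1, 4]

    def test_pass_through_ordering(self):
        spec = small_spec(CORE_GEOMS, [bg.BundleSpec(["STN", "SNc", "SNr"], 5, "straight", 0.1)])
        res = bg.make_phantom(spec)
        for s in res.tractogram:
            assert bg.label_sequence(s, res.volume).labels() == [1, 2, 3]

    def test_arc_avoids_obstacle_per_vertex(self, paper_phantom):
        """Brute-force vertex oracle: no vertex of an arc-routed streamline
        maps into the obstacle label."""
        spec = paper_phantom.spec
        cap = spec.structure_set().label("capsule")
        offset = 0
        found_arc = False
        for b in spec.bundles:
            sls = paper_phantom.tractogram.streamlines[offset : offset + b.n_streamlines]
            offset += b.n_streamlines
            if b.route != "arc-around-obstacle":
                continue
            found_arc = True
            for s in sls:
                assert not (paper_phantom.volume.labels_at(s.points) == cap).any()
        assert found_arc

    def test_through_route_hits_obstacle(self, paper_phantom):
        spec = paper_phantom.spec
        cap = spec.structure_set().label("capsule")
        offset = 0
        found = False
        for b in spec.bundles:
            sls = paper_phantom.tractogram.streamlines[offset : offset + b.n_streamlines]
            offset += b.n_streamlines
            if b.route != "through-obstacle":
                continue
            found = True
            for s in sls:
                assert (paper_phantom.volume.labels_at(s.points) == cap).any()
        assert found

    def test_vertex_spacing_bounded(self, paper_phantom):
        for s in paper_phantom.tractogram.streamlines[::40]:
            steps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
            assert steps.max() <= paper_phantom.spec.step + 1e-9

    def test_impossible_arc_raises(self):
        from bgconnect.errors import GenerationError

        # a wall spanning the whole grid cross-section between STN and GPe
        # leaves no free corridor for an arc route
        wall = StructureGeom("wall", 9, Geometry("box", (10.0, 20.0, 20.0), (0.6, 60.0, 60.0)))
        spec = small_spec(
            CORE_GEOMS + [wall],
            [bg.BundleSpec(["STN", "GPe"], 1, "arc-around-obstacle")],
            obstacle="wall",
        )
        with pytest.raises(GenerationError):
            bg.make_phantom(spec)


class TestDeterminism:
    def test_same_seed_byte_identical_tck(self, tmp_path):
        spec = small_spec(CORE_GEOMS, [bg.BundleSpec(["STN", "GPe"], 8, "straight", 0.3)], seed=9)
        bg.make_phantom(spec, out_dir=tmp_path / "a")
        bg.make_phantom(spec, out_dir=tmp_path / "b")
        a = (tmp_path / "a" / "phantom.tck").read_bytes()
        b = (tmp_path / "b" / "phantom.tck").read_bytes()
        # strip the timestamped header; payload must be byte-identical
        assert a.split(b"END")[-1] == b.split(b"END")[-1]

    def test_zero_bundles_empty_world(self):
        spec = small_spec(CORE_GEOMS, [])
        res = bg.make_phantom(spec)
        assert res.tractogram.count == 0
        assert (res.ground_truth.direct_counts.values == 0).all()
        assert (res.ground_truth.seed_target_counts.values == 0).all()


class TestPaperLikePreset:
    def test_volume_ratios_within_10pct(self, paper_phantom):
        """Rasterized volume ratios approximate the segmented specimen's
        nucleus volumes (100.5 : 138.8 : 142.6 : 611.9 : 271.8 mm^3)."""
        target = {"STN": 100.5, "SNc": 138.8, "SNr": 142.6, "GPe": 611.9, "GPi": 271.8}
        vol = paper_phantom.volume
        ss = paper_phantom.structures
        measured = {n: bg.structure_volume(vol, ss.label(n)) for n in target}
        norm_m = sum(measured.values())
        norm_t = sum(target.values())
        for n in target:
            assert measured[n] / norm_m == pytest.approx(target[n] / norm_t, rel=0.10)

    def test_connection_classes_present(self, paper_phantom):
        routes = {b.route for b in paper_phantom.spec.bundles}
        assert routes == {"straight", "arc-around-obstacle", "through-obstacle"}
        paths = [tuple(b.visit_path) for b in paper_phantom.spec.bundles]
        assert ("STN", "SNc", "SNr") in paths  # pass-through
        assert any(len(p) == 3 and p[1] == "STN" for p in paths)  # double exit


class TestGroundTruth:
    def _truth(self, bundles, obstacle=None):
        structures = CORE_GEOMS + (
            [StructureGeom("capsule", 6, Geometry("box", (10.0, 8.0, 10.0), (0.5, 3.0, 3.0)))]
            if obstacle
            else []
        )
        spec = small_spec(structures, bundles, obstacle=obstacle)
        return bg.ground_truth_tables(spec)

    def test_single_pair_bundle(self):
        gt = self._truth([bg.BundleSpec(["STN", "GPe"], 7)])
        assert gt.direct_counts.loc["STN", "GPe"] == 7
        assert gt.seed_totals["STN"] == 7 and gt.seed_totals["GPe"] == 7

    def test_pass_through_forbids_skip_pair(self):
        gt = self._truth([bg.BundleSpec(["STN", "SNc", "SNr"], 5)])
        assert gt.direct_counts.loc["STN", "SNc"] == 5
        assert gt.direct_counts.loc["SNc", "SNr"] == 5
        assert gt.direct_counts.loc["STN", "SNr"] == 0
        # but the table-2 twin counts the indirect STN-SNr connection
        assert gt.seed_target_counts.loc["SNr", "STN"] == 5

    def test_aux_in_path_is_transparent(self):
        gt = self._truth(
            [bg.BundleSpec(["GPe", "capsule", "SNr"], 4)], obstacle="capsule"
        )
        assert gt.direct_counts.loc["GPe", "SNr"] == 4
        assert gt.seed_target_counts.loc["capsule", "GPe"] == 4

    def test_through_route_adds_obstacle_to_targets(self):
        gt = self._truth(
            [bg.BundleSpec(["STN", "GPe"], 3, "through-obstacle")], obstacle="capsule"
        )
        assert gt.seed_target_counts.loc["capsule", "STN"] == 3
        assert gt.direct_counts.loc["STN", "GPe"] == 3


class TestSpecValidation:
    def test_yaml_roundtrip(self, tmp_path):
        spec = bg.paper_like_spec(n_tracks=50, rng_seed=3)
        spec.to_yaml(tmp_path / "spec.yaml")
        back = bg.PhantomSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.to_dict() == spec.to_dict()

    def test_unknown_bundle_structure_rejected(self):
        with pytest.raises(PhantomSpecError):
            small_spec(CORE_GEOMS, [bg.BundleSpec(["STN", "nonesuch"], 1)])

    def test_consecutive_repeat_rejected(self):
        with pytest.raises(PhantomSpecError):
            bg.BundleSpec(["STN", "STN"], 1)

    def test_short_path_rejected(self):
        with pytest.raises(PhantomSpecError):
            bg.BundleSpec(["STN"], 1)
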