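"""Per-seed connectivity tables, inclusion threshold, voxel maps, splitting.

Table semantics ("co-intersection counting"): a track *connects* a seed to a
target iff the same track intersects both — pass-throughs included, endpoints
not privileged.  Each track is counted once per (seed, target) pair even if
it leaves the seed at two different borders, so a seed's percentages over
many targets routinely add up to more than 100%.  Composite structures (SN,
GP) use union semantics: a track touching both SNc and SNr counts once
toward SN.

The voxel projection map localises a seed structure's connectivity: for each
voxel of the structure, the percentage of tracks traversing that voxel that
also reach the target.  Voxels traversed by no track carry NaN, never 0, so
downstream statistics are not biased by no-data voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .streamline_io import LabelVolume, Streamline, StructureSet, world_to_voxel
from .track_selection import LabelSequence

__all__ = [
    "ConnectivityTable",
    "VoxelMap",
    "seed_target_table",
    "apply_inclusion_threshold",
    "voxel_projection_map",
    "split_structure",
    "structure_volume",
]

log = logging.getLogger(__name__)


@dataclass
class ConnectivityTable:
    """Per-seed track totals, per-(seed, target) counts and percentages.

    ``counts`` and ``percent`` are target-by-seed DataFrames; ``totals`` maps
    each seed to its number of intersecting tracks.  Cells where the target's
    label set overlaps the seed's (the target *is* the seed, or contains it,
    or is contained in it) are NaN — a structure is not its own projection
    site.
    """

    totals: pd.Series
    counts: pd.DataFrame
    percent: pd.DataFrame
    dropped_targets: list[str] | None = None


@dataclass
class VoxelMap:
    """Figure-4-style per-voxel projection fractions.

    ``values`` is a float array aligned to the source label volume: for each
    voxel of ``structure`` traversed by at least one track, the percentage of
    traversing tracks that also intersect ``target``; NaN elsewhere.
    """

    structure: str
    target: str
    values: np.ndarray
    affine: np.ndarray

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.Nifti1Image(self.values.astype(np.float32), self.affine).to_filename(str(path))


def seed_target_table(
    sequences: Iterable[LabelSequence],
    structures: StructureSet,
    seeds: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
) -> ConnectivityTable:
    """Build the seed-versus-target connectivity table.

    ``seeds`` defaults to the five core nuclei (the table's columns);
    ``targets`` defaults to every named structure and composite.  Both direct
    and indirect connections count — any co-intersection by one track.
    """
    if seeds is None:
        seeds = list(structures.core_five)
    if targets is None:
        targets = [n for n in structures.names] + [c for c in structures.composites]
    for name in list(seeds) + list(targets):
        if name not in structures:
            raise ConfigError(f"unknown structure name {name!r}")

    seed_sets = {s: structures.labels_for(s) for s in seeds}
    target_sets = {t: structures.labels_for(t) for t in targets}

    track_sets = [seq.label_set() for seq in sequences]
    totals = pd.Series(
        {s: sum(1 for ls in track_sets if ls & seed_sets[s]) for s in seeds},
        dtype=np.int64,
    )
    counts = pd.DataFrame(0, index=list(targets), columns=list(seeds), dtype=np.int64)
    for ls in track_sets:
        if not ls:
            continue
        hit_seeds = [s for s in seeds if ls & seed_sets[s]]
        if not hit_seeds:
            continue
        for t in targets:
            if ls & target_sets[t]:
                for s in hit_seeds:
                    counts.loc[t, s] += 1

    percent = counts.astype(float)
    for s in seeds:
        tot = totals[s]
        percent[s] = 100.0 * counts[s] / tot if tot > 0 else np.nan
    # a structure is not its own projection site: blank overlapping cells
    for t in targets:
        for s in seeds:
            if target_sets[t] & seed_sets[s]:
                percent.loc[t, s] = np.nan
    return ConnectivityTable(totals, counts, percent)


def apply_inclusion_threshold(
    table: ConnectivityTable, threshold: float = 1.0
) -> ConnectivityTable:
    """Drop targets below the inclusion threshold.

    A target row survives iff its percentage reaches ``threshold`` for at
    least one seed ("at least 1% of the fibers connecting to either of the
    nuclei").  Dropped targets are recorded on the returned table and logged.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ConfigError("threshold must be within [0, 100]")
    pct = table.percent
    keep_mask = (pct >= threshold).any(axis=1)
    if threshold == 0.0:
        keep_mask[:] = True
    dropped = [t for t in pct.index if not keep_mask[t]]
    if dropped:
        log.info("inclusion threshold %.3g%% dropped targets: %s", threshold, dropped)
    return ConnectivityTable(
        table.totals,
        table.counts.loc[keep_mask],
        table.percent.loc[keep_mask],
        dropped_targets=dropped,
    )


def voxel_projection_map(
    streamlines: Iterable[Streamline],
    volume: LabelVolume,
    structures: StructureSet,
    structure: str,
    target: str,
) -> VoxelMap:
    """Map where within ``structure`` the tracks to ``target`` originate.

    For each voxel of ``structure``: denominator = number of tracks with at
    least one vertex in that voxel; numerator = those tracks that also
    intersect ``target`` anywhere along their course.  A track traversing a
    voxel twice counts once in both terms.  Untraversed voxels are NaN.
    """
    for name in (structure, target):
        if name not in structures:
            raise ConfigError(f"unknown structure name {name!r}")
    struct_labels = structures.labels_for(structure)
    target_labels = structures.labels_for(target)
    struct_mask = np.isin(volume.grid, list(struct_labels))

    den = np.zeros(volume.shape, dtype=np.int64)
    num = np.zeros(volume.shape, dtype=np.int64)
    for sl in streamlines:
        idx, inside = world_to_voxel(sl.points, volume)
        idx = idx[inside]
        if len(idx) == 0:
            continue
        vertex_labels = volume.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        reaches_target = bool(np.isin(vertex_labels, list(target_labels)).any())
        in_struct = np.isin(vertex_labels, list(struct_labels))
        if not in_struct.any():
            continue
        vox = np.unique(idx[in_struct], axis=0)
        den[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
        if reaches_target:
            num[vox[:, 0], vox[:, 1], vox[:, 2]] += 1

    values = np.full(volume.shape, np.nan)
    traversed = struct_mask & (den > 0)
    values[traversed] = 100.0 * num[traversed] / den[traversed]
    return VoxelMap(structure, target, values, volume.affine.copy())


def split_structure(
    volume: LabelVolume,
    label: int,
    plane_rule: str = "principal",
    new_labels: tuple[int, int] | None = None,
) -> tuple[LabelVolume, int, int]:
    """Split one structure into anteromedial/posterolateral halves.

    The default plane passes through the structure's voxel centroid with
    normal along its first principal axis (direction of longest spatial
    extent), computed on voxel-centre world coordinates.  ``plane_rule`` may
    also be ``"x"``, ``"y"`` or ``"z"`` for an axis-aligned (world-axis)
    split.  The normal is oriented toward the anterior (+y), falling back to
    medial (-x) then superior (+z), so sublabel A is the anteromedial half;
    voxels exactly on the plane go to side A.

    Returns a new LabelVolume where the structure's voxels carry the two new
    sublabels, plus the (A, P) labels used.
    """
    ii = np.argwhere(volume.grid == label)
    if len(ii) < 3:
        raise ConfigError(f"structure label {label} has fewer than 3 voxels; cannot split")
    world = ii @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    centroid = world.mean(axis=0)
    centred = world - centroid
    if plane_rule == "principal":
        # first principal axis of the voxel-centre cloud
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        normal = vt[0]
    elif plane_rule in ("x", "y", "z"):
        normal = np.zeros(3)
        normal["xyz".index(plane_rule)] = 1.0
    else:
        raise ConfigError(f"unknown plane rule {plane_rule!r}")
    # orient toward anterior, then medial, then superior
    for ref in (np.array([0.0, 1.0, 0.0]), np.array([-1.0, 0.0, 0.0]),
                np.array([0.0, 0.0, 1.0])):
        d = float(normal @ ref)
        if abs(d) > 1e-9:
            if d < 0:
                normal = -normal
            break
    side_a = centred @ normal >= 0

    if new_labels is None:
        base = int(volume.grid.max())
        new_labels = (base + 1, base + 2)
    label_a, label_p = new_labels
    grid = volume.grid.copy()
    a_idx = ii[side_a]
    p_idx = ii[~side_a]
    grid[a_idx[:, 0], a_idx[:, 1], a_idx[:, 2]] = label_a
    grid[p_idx[:, 0], p_idx[:, 1], p_idx[:, 2]] = label_p
    return LabelVolume(grid, volume.affine.copy()), int(label_a), int(label_p)


def structure_volume(volume: LabelVolume, label: int) -> float:
    """Structure volume in mm³ (voxel count × voxel volume)."""
    n = int(np.count_nonzero(volume.grid == label))
    if n == 0:
        log.warning("label %d absent from volume; volume reported as 0", label)
    return n * volume.voxel_volume
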