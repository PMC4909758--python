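"""Synthetic connectivity phantoms with exact ground truth.

The specimen behind the analysis this package implements was never
deposited, so every stage is validated against phantoms instead: analytic
structure geometries (ellipsoids and boxes) rasterized onto a ~0.5 mm
isotropic grid, plus streamline bundles whose structure-visit paths are
*stated*, not estimated.  Because each bundle declares its visit path, the
connectivity tables the pipeline should produce follow in closed form
(:func:`ground_truth_tables`), and pipeline output can be checked by exact
integer equality.

Bundle routes mirror the connection archetypes of the real data: straight
corridors between nuclei, arcs that circle anteriorly around a "capsule"
obstacle, and bundles that cross straight through it.  Streamline synthesis
verifies every generated track against its declared visit path on the
rasterized grid and resamples the jitter on violation, so the ground truth
is guaranteed, not merely probable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import GenerationError, PhantomSpecError
from .streamline_io import (
    CORE_FIVE,
    LabelVolume,
    Streamline,
    StructureSet,
    Tractogram,
    write_label_volume,
    write_tck,
)

__all__ = [
    "Geometry",
    "StructureGeom",
    "BundleSpec",
    "PhantomSpec",
    "GroundTruth",
    "PhantomResult",
    "rasterize_structures",
    "synthesize_bundle",
    "ground_truth_tables",
    "make_phantom",
    "paper_like_spec",
    "random_spec",
]

ROUTES = ("straight", "arc-around-obstacle", "through-obstacle")


@dataclass(frozen=True)
class Geometry:
    """An analytic ellipsoid or axis-aligned box in world mm."""

    kind: str  # "ellipsoid" | "box"
    centre: tuple[float, float, float]
    semi_axes: tuple[float, float, float]  # box: half-extents

    def __post_init__(self):
        if self.kind not in ("ellipsoid", "box"):
            raise PhantomSpecError(f"unknown geometry kind {self.kind!r}")
        if any(a <= 0 for a in self.semi_axes):
            raise PhantomSpecError("semi-axes must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (N, 3) world-mm points (boundary inclusive)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        rel = (pts - np.asarray(self.centre)) / np.asarray(self.semi_axes)
        if self.kind == "ellipsoid":
            return np.einsum("ij,ij->i", rel, rel) <= 1.0
        return np.all(np.abs(rel) <= 1.0, axis=1)

    @property
    def analytic_volume(self) -> float:
        a, b, c = self.semi_axes
        if self.kind == "ellipsoid":
            return 4.0 / 3.0 * np.pi * a * b * c
        return 8.0 * a * b * c


@dataclass(frozen=True)
class StructureGeom:
    name: str
    label: int
    geometry: Geometry


@dataclass
class BundleSpec:
    """A family of streamlines sharing one declared visit path.

    ``visit_path`` lists the structures the streamlines pass through, in
    order (length >= 2; names may repeat non-consecutively, e.g. a track that
    leaves a nucleus and re-enters it).  ``route`` selects how legs blocked
    by the obstacle are handled: arcs detour around it, "through" crosses it.
    ``jitter`` is the lateral Gaussian perturbation (mm) applied per
    streamline.
    """

    visit_path: list[str]
    n_streamlines: int
    route: str = "straight"
    jitter: float = 0.0

    def __post_init__(self):
        if len(self.visit_path) < 2:
            raise PhantomSpecError("visit_path needs at least 2 structures")
        if any(a == b for a, b in zip(self.visit_path, self.visit_path[1:])):
            raise PhantomSpecError("visit_path may not repeat a structure consecutively")
        if self.n_streamlines < 1:
            raise PhantomSpecError("n_streamlines must be >= 1")
        if self.route not in ROUTES:
            raise PhantomSpecError(f"unknown route {self.route!r}")
        if self.jitter < 0:
            raise PhantomSpecError("jitter must be >= 0")


@dataclass
class PhantomSpec:
    """Full description of a synthetic world.

    Defaults follow the real acquisition: 0.5 mm isotropic voxels and a
    0.05 mm streamline step.
    """

    structures: list[StructureGeom]
    bundles: list[BundleSpec] = field(default_factory=list)
    grid_shape: tuple[int, int, int] = (90, 90, 70)
    voxel_size: float = 0.5
    obstacle: str | None = None
    rng_seed: int = 0
    step: float = 0.05

    def __post_init__(self):
        names = [s.name for s in self.structures]
        labels = [s.label for s in self.structures]
        if len(set(names)) != len(names) or len(set(labels)) != len(labels):
            raise PhantomSpecError("structure names and labels must be unique")
        if any(l <= 0 for l in labels):
            raise PhantomSpecError("structure labels must be positive")
        known = set(names)
        for b in self.bundles:
            unknown = [n for n in b.visit_path if n not in known]
            if unknown:
                raise PhantomSpecError(f"bundle references unknown structures {unknown}")
            if b.route == "arc-around-obstacle" and self.obstacle in b.visit_path:
                raise PhantomSpecError(
                    "arc route cannot also list the obstacle in its visit_path"
                )
        if self.obstacle is not None and self.obstacle not in known:
            raise PhantomSpecError(f"obstacle {self.obstacle!r} is not a structure")

    def structure(self, name: str) -> StructureGeom:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    def structure_set(self) -> StructureSet:
        labels = {s.name: s.label for s in self.structures}
        return StructureSet(labels)

    # -- YAML round-trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size": self.voxel_size,
            "obstacle": self.obstacle,
            "rng_seed": self.rng_seed,
            "step": self.step,
            "structures": [
                {
                    "name": s.name,
                    "label": s.label,
                    "kind": s.geometry.kind,
                    "centre": list(s.geometry.centre),
                    "semi_axes": list(s.geometry.semi_axes),
                }
                for s in self.structures
            ],
            "bundles": [
                {
                    "visit_path": list(b.visit_path),
                    "n_streamlines": b.n_streamlines,
                    "route": b.route,
                    "jitter": b.jitter,
                }
                for b in self.bundles
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "PhantomSpec":
        structures = [
            StructureGeom(
                s["name"],
                int(s["label"]),
                Geometry(s.get("kind", "ellipsoid"), tuple(s["centre"]), tuple(s["semi_axes"])),
            )
            for s in raw["structures"]
        ]
        bundles = [
            BundleSpec(
                list(b["visit_path"]),
                int(b["n_streamlines"]),
                b.get("route", "straight"),
                float(b.get("jitter", 0.0)),
            )
            for b in raw.get("bundles", [])
        ]
        return cls(
            structures=structures,
            bundles=bundles,
            grid_shape=tuple(raw.get("grid_shape", (90, 90, 70))),
            voxel_size=float(raw.get("voxel_size", 0.5)),
            obstacle=raw.get("obstacle"),
            rng_seed=int(raw.get("rng_seed", 0)),
            step=float(raw.get("step", 0.05)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Closed-form expectations for the analysis of one phantom.

    ``direct_counts``: symmetric core-five segment counts.  ``seed_totals``
    and ``seed_target_counts``: Table-2-style per-seed track totals and
    per-(target, seed) co-intersection counts.  ``visit_paths``: the intended
    visit path per streamline (obstacle crossings included).
    """

    direct_counts: pd.DataFrame
    seed_totals: pd.Series
    seed_target_counts: pd.DataFrame
    visit_paths: list[list[str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "direct_counts": {
                f"{a}|{b}": int(self.direct_counts.loc[a, b])
                for a in self.direct_counts.index
                for b in self.direct_counts.columns
            },
            "seed_totals": {k: int(v) for k, v in self.seed_totals.items()},
            "seed_target_counts": {
                f"{t}|{s}": int(self.seed_target_counts.loc[t, s])
                for t in self.seed_target_counts.index
                for s in self.seed_target_counts.columns
            },
            "visit_paths": self.visit_paths,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class PhantomResult:
    volume: LabelVolume
    tractogram: Tractogram
    structures: StructureSet
    ground_truth: GroundTruth
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Rasterization


def _grid_affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spec.voxel_size
    return aff


def rasterize_structures(spec: PhantomSpec) -> LabelVolume:
    """Rasterize analytic geometries: a voxel gets the label of the geometry
    containing its centre.  Any voxel claimed twice aborts with the names of
    the colliding pair."""
    shape = tuple(spec.grid_shape)
    grid = np.zeros(shape, dtype=np.int32)
    ax = [np.arange(n) * spec.voxel_size for n in shape]
    for s in spec.structures:
        c = np.asarray(s.geometry.centre)
        r = np.asarray(s.geometry.semi_axes)
        # bounding slab per axis keeps rasterization O(structure volume)
        lo = [np.searchsorted(ax[i], c[i] - r[i] - spec.voxel_size) for i in range(3)]
        hi = [np.searchsorted(ax[i], c[i] + r[i] + spec.voxel_size) for i in range(3)]
        xs, ys, zs = np.meshgrid(
            ax[0][lo[0]:hi[0]], ax[1][lo[1]:hi[1]], ax[2][lo[2]:hi[2]], indexing="ij"
        )
        centres = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
        inside = s.geometry.contains(centres)
        sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        inside3 = inside.reshape(sub.shape)
        clash = inside3 & (sub != 0)
        if clash.any():
            other = int(sub[clash][0])
            other_name = next(t.name for t in spec.structures if t.label == other)
            raise PhantomSpecError(
                f"structures {other_name!r} and {s.name!r} overlap after rasterization"
            )
        sub[inside3] = s.label
    return LabelVolume(grid, _grid_affine(spec))


# ---------------------------------------------------------------------------
# Streamline synthesis


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at spacing <= step (arc-length parametrised)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = seg > 1e-12
    points = np.vstack([points[0], points[1:][keep]])
    seg = seg[keep]
    if len(points) < 2:
        raise GenerationError("degenerate path")
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    total = cum[-1]
    n = max(2, int(np.ceil(total / step)) + 1)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(t, cum, points[:, d])
    return out


def _leg_blocked(a: np.ndarray, b: np.ndarray, obstacle: Geometry) -> bool:
    t = np.linspace(0.0, 1.0, 200)[:, None]
    return bool(obstacle.contains(a + t * (b - a)).any())


def _dilated(geom: Geometry, margin: float) -> Geometry:
    """The geometry grown by ``margin`` mm — a point this close to the
    analytic surface can still land in a voxel whose centre is inside, so
    route avoidance must clear the dilated shape, not the exact one."""
    return Geometry(geom.kind, geom.centre, tuple(s + margin for s in geom.semi_axes))


_DETOUR_DIRS = [
    np.array([0.0, 1.0, 0.0]),   # anterior first: "circle anteriorly around"
    np.array([0.0, -1.0, 0.0]),
    np.array([0.0, 0.0, 1.0]),
    np.array([0.0, 0.0, -1.0]),
    np.array([1.0, 0.0, 0.0]),
    np.array([-1.0, 0.0, 0.0]),
]


def _circle_through(a: np.ndarray, apex: np.ndarray, b: np.ndarray, n: int = 200) -> np.ndarray:
    """Points along the circular arc a -> apex -> b (three non-collinear points)."""
    # plane basis
    u = apex - a
    v = b - a
    normal = np.cross(u, v)
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise GenerationError("collinear arc points")
    normal /= nn
    e1 = u / np.linalg.norm(u)
    e2 = np.cross(normal, e1)
    # 2D coordinates in the plane through a
    def to2d(p):
        d = p - a
        return np.array([d @ e1, d @ e2])
    p1, p2, p3 = to2d(a), to2d(apex), to2d(b)
    # circumcentre in 2D
    ax_, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax_ * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-9:
        raise GenerationError("collinear arc points")
    ux = ((ax_**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax_**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax_ - cx) + (cx**2 + cy**2) * (bx - ax_)) / d
    centre2 = np.array([ux, uy])
    r = np.linalg.norm(p1 - centre2)
    th1 = np.arctan2(*(p1 - centre2)[::-1])
    th2 = np.arctan2(*(p2 - centre2)[::-1])
    th3 = np.arctan2(*(p3 - centre2)[::-1])
    # sweep from th1 to th3 passing through th2
    def unwrap(th, ref):
        while th < ref:
            th += 2 * np.pi
        return th
    # sweep direction chosen so the apex angle lies between start and end
    fwd2, fwd3 = unwrap(th2, th1), unwrap(th3, th1)
    if fwd2 <= fwd3:
        thetas = np.linspace(th1, fwd3, n)          # counterclockwise
    else:
        thetas = np.linspace(th1, fwd3 - 2 * np.pi, n)  # clockwise
    pts2 = centre2 + r * np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    return a + np.outer(pts2[:, 0], e1) + np.outer(pts2[:, 1], e2)


def _arc_leg(
    a: np.ndarray, b: np.ndarray, avoid: Sequence[Geometry], spec: PhantomSpec
) -> np.ndarray:
    """A circular detour from a to b clearing every geometry in ``avoid``
    (the obstacle plus all structures that are not the leg's endpoints),
    preferring the anterior direction — the 'circle anteriorly around the
    capsule' archetype."""
    mid = 0.5 * (a + b)
    world_hi = (np.asarray(spec.grid_shape) - 1) * spec.voxel_size
    reach = max(max(g.semi_axes) for g in avoid) + np.linalg.norm(b - a)
    leg_dir = (b - a) / np.linalg.norm(b - a)
    for direction in _DETOUR_DIRS:
        if abs(direction @ leg_dir) > 0.9:  # detour must be lateral to the leg
            continue
        for detour in np.arange(2.0, reach + 8.0, 0.5):
            apex = mid + direction * detour
            if np.any(apex < 0) or np.any(apex > world_hi):
                break
            arc = _circle_through(a, apex, b, n=400)
            if np.any(arc < -0.25) or np.any(arc > world_hi + 0.25):
                continue
            if not any(g.contains(arc).any() for g in avoid):
                return arc
    raise GenerationError("no arc corridor around the obstacle")


def _base_path(bundle: BundleSpec, spec: PhantomSpec) -> np.ndarray:
    """Control polyline through the visit-path centroids, legs routed per
    the bundle's route archetype."""
    centres = [np.asarray(spec.structure(n).geometry.centre, dtype=float)
               for n in bundle.visit_path]
    obstacle = spec.structure(spec.obstacle).geometry if spec.obstacle else None
    # half-voxel rasterization margin: a point within this distance of a
    # geometry can still land in one of its voxels
    margin = 0.5 * spec.voxel_size * np.sqrt(3.0)
    pieces = [centres[0][None, :]]
    for (a_name, a), (b_name, b) in zip(
        zip(bundle.visit_path, centres), zip(bundle.visit_path[1:], centres[1:])
    ):
        if (
            bundle.route == "arc-around-obstacle"
            and obstacle is not None
            and _leg_blocked(a, b, _dilated(obstacle, margin))
        ):
            avoid = [
                _dilated(s.geometry, margin)
                for s in spec.structures
                if s.name not in (a_name, b_name)
            ]
            leg = _arc_leg(a, b, avoid, spec)
        else:
            leg = np.linspace(a, b, 64)
        pieces.append(leg[1:])
    return np.vstack(pieces)


def _visit_runs(labels: np.ndarray) -> list[int]:
    """Nonzero run labels of a per-vertex label array (independent of the
    track_selection implementation; used to verify synthesis)."""
    runs: list[int] = []
    prev = 0
    for l in labels:
        if l != prev:
            if l != 0:
                runs.append(int(l))
            prev = int(l)
    return runs


def _expected_ok(
    runs: list[int], bundle: BundleSpec, spec: PhantomSpec, name_to_label: dict[str, int]
) -> bool:
    obstacle_label = name_to_label[spec.obstacle] if spec.obstacle else None
    stripped = [r for r in runs if r != obstacle_label]
    base = [name_to_label[n] for n in bundle.visit_path if n != spec.obstacle]
    if stripped != base:
        return False
    has_obstacle = obstacle_label is not None and obstacle_label in runs
    if bundle.route == "through-obstacle":
        return has_obstacle
    if bundle.route == "arc-around-obstacle":
        return not has_obstacle
    return has_obstacle == (spec.obstacle in bundle.visit_path)


def synthesize_bundle(
    bundle: BundleSpec,
    spec: PhantomSpec,
    volume: LabelVolume,
    rng: np.random.Generator,
    id_offset: int = 0,
    max_attempts: int = 60,
) -> list[Streamline]:
    """Generate the bundle's streamlines and verify each against its
    declared visit path on the rasterized grid.

    Jitter is a per-streamline lateral offset (truncated Gaussian, capped at
    2 sigma) plus verification-with-resampling, so every returned streamline
    realises ``visit_path`` exactly (with the obstacle appearing iff the
    route or path says so).  Raises :class:`GenerationError` when no valid
    realisation exists, e.g. an arc route with no free corridor.
    """
    name_to_label = {s.name: s.label for s in spec.structures}
    base = _base_path(bundle, spec)
    base_dense = _resample_polyline(base, spec.step)
    # overall lateral frame for jitter offsets
    chord = base_dense[-1] - base_dense[0]
    chord_n = np.linalg.norm(chord)
    if chord_n < 1e-9:
        chord = np.array([1.0, 0.0, 0.0])
        chord_n = 1.0
    chord = chord / chord_n
    helper = np.array([0.0, 0.0, 1.0]) if abs(chord[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(chord, helper)
    u /= np.linalg.norm(u)
    v = np.cross(chord, u)

    out: list[Streamline] = []
    for k in range(bundle.n_streamlines):
        ok = False
        for attempt in range(max_attempts):
            if bundle.jitter > 0 and not (attempt == max_attempts - 1):
                off = rng.normal(0.0, bundle.jitter, size=2)
                off = np.clip(off, -2 * bundle.jitter, 2 * bundle.jitter)
                offset = off[0] * u + off[1] * v
            else:
                offset = np.zeros(3)  # last attempt: the unjittered base path
            pts = base_dense + offset
            runs = _visit_runs(volume.labels_at(pts))
            if _expected_ok(runs, bundle, spec, name_to_label):
                out.append(Streamline(pts.copy(), id=id_offset + k))
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not realise bundle {bundle.visit_path} ({bundle.route}) "
                f"after {max_attempts} attempts"
            )
    return out


# ---------------------------------------------------------------------------
# Ground truth


def _effective_path(bundle: BundleSpec, spec: PhantomSpec) -> list[str]:
    """The visit path a synthesized streamline actually realises, with the
    obstacle inserted for through-routes."""
    if bundle.route != "through-obstacle" or spec.obstacle is None:
        return list(bundle.visit_path)
    obstacle_geom = spec.structure(spec.obstacle).geometry
    path: list[str] = [bundle.visit_path[0]]
    for a_name, b_name in zip(bundle.visit_path, bundle.visit_path[1:]):
        a = np.asarray(spec.structure(a_name).geometry.centre, dtype=float)
        b = np.asarray(spec.structure(b_name).geometry.centre, dtype=float)
        if a_name != spec.obstacle and b_name != spec.obstacle and _leg_blocked(a, b, obstacle_geom):
            path.append(spec.obstacle)
        path.append(b_name)
    return path


def ground_truth_tables(spec: PhantomSpec, structures: StructureSet | None = None) -> GroundTruth:
    """Closed-form expectations from the bundle declarations alone.

    Direct counts: each bundle's visit path, filtered to the five core
    nuclei, contributes one segment per consecutive pair of distinct core
    names, times its number of streamlines.  Seed/target counts: one count
    per (seed, target) pair of structures the path touches — set semantics,
    so double exits and re-entries count once, matching the
    "each track is counted once" table rule.
    """
    if structures is None:
        structures = spec.structure_set()
    core = [n for n in structures.core_five]
    direct = pd.DataFrame(0, index=core, columns=core, dtype=np.int64)
    seeds = list(structures.core_five)
    targets = [n for n in structures.names] + list(structures.composites)
    totals = pd.Series(0, index=seeds, dtype=np.int64)
    stc = pd.DataFrame(0, index=targets, columns=seeds, dtype=np.int64)
    seed_sets = {s: structures.labels_for(s) for s in seeds}
    target_sets = {t: structures.labels_for(t) for t in targets}
    name_to_label = {s.name: s.label for s in spec.structures}

    visit_paths: list[list[str]] = []
    for bundle in spec.bundles:
        path = _effective_path(bundle, spec)
        visit_paths.extend([list(path)] * bundle.n_streamlines)
        n = bundle.n_streamlines
        core_path = [p for p in path if p in core]
        for a, b in zip(core_path, core_path[1:]):
            if a != b:
                direct.loc[a, b] += n
                direct.loc[b, a] += n
        labels_touched = {name_to_label[p] for p in path}
        hit = [s for s in seeds if labels_touched & seed_sets[s]]
        for s in hit:
            totals[s] += n
        for t in targets:
            if labels_touched & target_sets[t]:
                for s in hit:
                    stc.loc[t, s] += n
    return GroundTruth(direct, totals, stc, visit_paths)


# ---------------------------------------------------------------------------
# Whole phantoms


def make_phantom(spec: PhantomSpec, out_dir: str | Path | None = None) -> PhantomResult:
    """Rasterize, synthesize all bundles, and derive the ground truth.

    Deterministic given ``spec.rng_seed``.  With ``out_dir`` the phantom is
    also written to disk: ``phantom.tck``, ``labels.nii.gz``,
    ``structures.yaml``, ``ground_truth.json``, ``spec.yaml``.
    """
    volume = rasterize_structures(spec)
    structures = spec.structure_set()
    rng = np.random.default_rng(spec.rng_seed)
    streamlines: list[Streamline] = []
    for bundle in spec.bundles:
        streamlines.extend(
            synthesize_bundle(bundle, spec, volume, rng, id_offset=len(streamlines))
        )
    tractogram = Tractogram(
        streamlines,
        header={"phantom_seed": str(spec.rng_seed), "step_mm": str(spec.step)},
    )
    truth = ground_truth_tables(spec, structures)
    result = PhantomResult(volume, tractogram, structures, truth, spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tck(tractogram, out / "phantom.tck")
        write_label_volume(volume, out / "labels.nii.gz")
        structures.to_yaml(out / "structures.yaml")
        truth.to_json(out / "ground_truth.json")
        spec.to_yaml(out / "spec.yaml")
    return result


# ---------------------------------------------------------------------------
# Presets

# Semi-axes chosen so analytic ellipsoid volumes match the segmented nuclei
# volumes of the source specimen (STN 100.5, SNc 138.8, SNr 142.6, GPe 611.9,
# GPi 271.8 mm^3), with a 2:1.5:1 aspect.  Scene: GP lateral of a capsule
# slab, STN/SN medial-inferior of it, in RAS world mm.
_PAPER_VOLUMES = {"STN": 100.5, "SNc": 138.8, "SNr": 142.6, "GPe": 611.9, "GPi": 271.8}
_PAPER_CENTRES = {
    "STN": (14.0, 18.0, 18.0),
    "SNc": (12.0, 17.0, 11.0),
    "SNr": (12.0, 10.0, 11.0),
    "GPe": (34.0, 16.0, 20.0),
    "GPi": (32.0, 16.0, 12.0),
}
_PAPER_LABELS = {"STN": 1, "SNc": 2, "SNr": 3, "GPe": 4, "GPi": 5}
_CAPSULE = StructureGeom(
    "capsule", 6, Geometry("box", (24.0, 15.5, 17.5), (1.75, 10.5, 12.5))
)

# bundle classes named in the source's results, with weights roughly echoing
# the relative prominence of each connection class
_PAPER_BUNDLES: list[tuple[list[str], str, float]] = [
    (["STN", "GPi"], "arc-around-obstacle", 6.0),
    (["STN", "GPe"], "arc-around-obstacle", 4.0),
    (["STN", "GPe"], "through-obstacle", 4.0),
    (["STN", "SNc"], "straight", 10.0),
    (["STN", "SNr"], "straight", 10.0),
    (["SNc", "SNr"], "straight", 18.0),
    (["SNc", "GPi"], "arc-around-obstacle", 3.0),
    (["SNr", "GPi"], "arc-around-obstacle", 3.0),
    (["SNr", "GPi"], "through-obstacle", 3.0),
    (["SNr", "GPe"], "through-obstacle", 4.0),
    (["SNc", "GPe"], "through-obstacle", 2.0),
    (["GPe", "GPi"], "straight", 20.0),
    (["STN", "SNc", "SNr"], "straight", 5.0),       # pass-through path
    (["GPe", "STN", "SNr"], "through-obstacle", 4.0),  # double exit from the STN
    (["GPi", "STN", "SNc"], "arc-around-obstacle", 4.0),
]


def _ellipsoid_semi_axes(volume_mm3: float, aspect=(2.0, 1.5, 1.0)) -> tuple[float, float, float]:
    abc = volume_mm3 * 3.0 / (4.0 * np.pi)
    s = (abc / np.prod(aspect)) ** (1.0 / 3.0)
    return tuple(float(s * a) for a in aspect)


def paper_like_spec(n_tracks: int = 600, rng_seed: int = 0, step: float = 0.05,
                    jitter: float = 0.3) -> PhantomSpec:
    """The canned scene: five nuclei with the segmented volume ratios, a
    capsule obstacle between GP and STN/SN, and a bundle for every connection
    class observed in the source data (straight, anterior arcs, straight
    crossings, a pass-through path and a double-exit path).

    ``n_tracks`` is distributed over the bundle classes by weight.
    """
    structures = [
        StructureGeom(
            name,
            _PAPER_LABELS[name],
            Geometry("ellipsoid", _PAPER_CENTRES[name], _ellipsoid_semi_axes(v)),
        )
        for name, v in _PAPER_VOLUMES.items()
    ]
    structures.append(_CAPSULE)
    weights = np.array([w for _, _, w in _PAPER_BUNDLES])
    counts = np.maximum(1, np.round(weights / weights.sum() * n_tracks).astype(int))
    bundles = [
        BundleSpec(list(path), int(n), route, jitter)
        for (path, route, _), n in zip(_PAPER_BUNDLES, counts)
    ]
    return PhantomSpec(
        structures=structures,
        bundles=bundles,
        grid_shape=(90, 90, 70),
        voxel_size=0.5,
        obstacle="capsule",
        rng_seed=rng_seed,
        step=step,
    )


def random_spec(rng_seed: int, step: float = 0.15, max_bundles: int = 8) -> PhantomSpec:
    """A randomized phantom for property testing: the paper-like scene with
    perturbed nucleus centres and a random mix of bundle classes (straight,
    arc, through-obstacle, pass-through, double-exit), counts and jitters.

    The coarser default step keeps randomized sweeps fast; visit sequences
    are step-invariant well below the 0.5 mm voxel size.
    """
    rng = np.random.default_rng(rng_seed)
    # a common rigid translation randomises voxel-grid alignment without
    # risking structure overlap; per-structure jitter stays within the
    # tightest inter-structure slack (~0.3 mm between SNc and SNr)
    shift = rng.uniform(-1.2, 1.2, size=3)
    structures = []
    for name, v in _PAPER_VOLUMES.items():
        centre = np.asarray(_PAPER_CENTRES[name]) + shift + rng.uniform(-0.1, 0.1, size=3)
        structures.append(
            StructureGeom(
                name,
                _PAPER_LABELS[name],
                Geometry("ellipsoid", tuple(centre), _ellipsoid_semi_axes(v)),
            )
        )
    cap_centre = tuple(np.asarray(_CAPSULE.geometry.centre) + shift)
    structures.append(
        StructureGeom("capsule", 6, Geometry("box", cap_centre, _CAPSULE.geometry.semi_axes))
    )
    n_bundles = int(rng.integers(2, max_bundles + 1))
    choice_idx = rng.choice(len(_PAPER_BUNDLES), size=n_bundles, replace=True)
    bundles = []
    for i in choice_idx:
        path, route, _ = _PAPER_BUNDLES[int(i)]
        bundles.append(
            BundleSpec(
                list(path),
                int(rng.integers(1, 9)),
                route,
                float(rng.uniform(0.0, 0.35)),
            )
        )
    return PhantomSpec(
        structures=structures,
        bundles=bundles,
        obstacle="capsule",
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        step=step,
    )
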