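"""Streamline and label-volume I/O plus coordinate plumbing.

Conventions
-----------
* Streamline coordinates are world millimetres in the same (RAS) space as the
  label volume's NIfTI affine.  No implicit axis flips are applied anywhere:
  TCK files already store world-mm coordinates and NIfTI affines map voxel
  indices to world mm, so the two formats share a space by definition.  (TRK
  files do *not* — TRK is deliberately unsupported.)
* Voxel lookup uses the voxel-centre convention: the affine maps integer
  indices to voxel centres, so a world point belongs to the voxel whose index
  is the *rounded* inverse-affine image of the point.  Ties at .5 round half
  away from zero.

TCK reading/writing is delegated to :mod:`nibabel.streamlines`; this module
adds the validation contract (magic line, supported datatypes, header-count
versus payload consistency) on top.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml
from nibabel.streamlines import tck as nib_tck
from nibabel.streamlines.tractogram_file import DataError, HeaderError
from nibabel.streamlines.header import Field as NibField
from nibabel.streamlines.tractogram import Tractogram as _NibTractogram

from .errors import ConfigError, CorruptFileError, FormatError, UnsupportedDatatypeError

__all__ = [
    "Streamline",
    "Tractogram",
    "LabelVolume",
    "StructureSet",
    "read_tck",
    "write_tck",
    "read_label_volume",
    "write_label_volume",
    "world_to_voxel",
    "voxel_to_world",
    "densify",
]

CORE_FIVE = ("STN", "SNc", "SNr", "GPe", "GPi")
DEFAULT_SEEDS = ("STN", "SN", "GP")
DEFAULT_COMPOSITES = {"SN": ("SNc", "SNr"), "GP": ("GPe", "GPi")}


@dataclass
class Streamline:
    """An ordered polyline in world-mm coordinates.

    Parameters
    ----------
    points : (N, 3) float array
        Vertex coordinates in millimetres, N >= 2.
    id : int
        Index within the parent tractogram.
    """

    points: np.ndarray
    id: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("streamline points must be an (N, 3) array")

    def validate(self) -> None:
        """Check the streamline invariants, raising ``ValueError`` on failure."""
        if len(self.points) < 2:
            raise ValueError("streamline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("streamline contains non-finite coordinates")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps <= 0):
            raise ValueError("consecutive streamline points must be distinct")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Tractogram:
    """A collection of streamlines with header metadata."""

    streamlines: list[Streamline] = field(default_factory=list)
    header: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __len__(self) -> int:
        return len(self.streamlines)


class LabelVolume:
    """An integer 3D label grid with a voxel-index -> world-mm affine.

    Label 0 is background; every nonzero value is one structure.
    """

    def __init__(self, grid: np.ndarray, affine: np.ndarray):
        grid = np.asarray(grid)
        if grid.ndim != 3:
            raise FormatError("label grid must be 3-dimensional")
        if not np.issubdtype(grid.dtype, np.integer):
            raise FormatError("label grid must be integer-typed")
        if grid.min(initial=0) < 0:
            raise FormatError("labels must be non-negative")
        affine = np.asarray(affine, dtype=np.float64)
        if affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        det = np.linalg.det(affine)
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise FormatError("affine is not invertible")
        self.grid = grid
        self.affine = affine
        self._inv_affine = np.linalg.inv(affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the grid."""
        found = np.unique(self.grid)
        return found[found != 0]

    def labels_at(self, points: np.ndarray) -> np.ndarray:
        """Label under each world-mm point; out-of-grid points map to 0."""
        idx, inside = world_to_voxel(points, self)
        idx = np.atleast_2d(idx)
        inside = np.atleast_1d(inside)
        out = np.zeros(len(idx), dtype=self.grid.dtype)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.grid[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


class StructureSet:
    """Registry mapping structure names to labels.

    Distinguishes the five core nuclei (STN, SNc, SNr, GPe, GPi), the seed
    structures used for track selection (by default STN, SN, GP where
    SN = SNc ∪ SNr and GP = GPe ∪ GPi), and any auxiliary target ROIs
    (internal capsule, red nucleus, ...).  Composite names carry no label of
    their own; they resolve to the union of their members' labels.
    """

    def __init__(
        self,
        labels: Mapping[str, int],
        core_five: Sequence[str] = CORE_FIVE,
        seeds: Sequence[str] = DEFAULT_SEEDS,
        composites: Mapping[str, Sequence[str]] | None = None,
    ):
        composites = dict(composites) if composites is not None else {
            k: v for k, v in DEFAULT_COMPOSITES.items() if all(m in labels for m in v)
        }
        self._labels = {str(k): int(v) for k, v in labels.items()}
        if len(set(self._labels.values())) != len(self._labels):
            raise ConfigError("structure labels must be unique")
        if 0 in self._labels.values():
            raise ConfigError("label 0 is reserved for background")
        self.composites = {str(k): tuple(v) for k, v in composites.items()}
        for comp, members in self.composites.items():
            if comp in self._labels:
                raise ConfigError(f"composite {comp!r} clashes with a labelled structure")
            missing = [m for m in members if m not in self._labels]
            if missing:
                raise ConfigError(f"composite {comp!r} references unknown members {missing}")
        self.core_five = tuple(core_five)
        if len(self.core_five) != 5 or len(set(self.core_five)) != 5:
            raise ConfigError("core_five must name exactly 5 distinct structures")
        # a core nucleus may itself be a composite (e.g. a GPe split into
        # anterior/posterior halves still counts as one nucleus)
        missing = [n for n in self.core_five if n not in self._labels and n not in self.composites]
        if missing:
            raise ConfigError(f"core structures missing from label map: {missing}")
        self.seeds = tuple(s for s in seeds if s in self._labels or s in self.composites)
        if not self.seeds:
            raise ConfigError("no seed structure resolves to a label")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._labels)

    @property
    def aux_targets(self) -> tuple[str, ...]:
        """Labelled structures that are not one of the five core nuclei."""
        return tuple(n for n in self._labels if n not in self.core_five)

    def __contains__(self, name: str) -> bool:
        return name in self._labels or name in self.composites

    def label(self, name: str) -> int:
        return self._labels[name]

    def name_of(self, label: int) -> str:
        for n, l in self._labels.items():
            if l == label:
                return n
        raise KeyError(label)

    def labels_for(self, name: str) -> frozenset[int]:
        """Label set for a name; composites expand to their members' labels."""
        if name in self._labels:
            return frozenset({self._labels[name]})
        if name in self.composites:
            return frozenset(self._labels[m] for m in self.composites[name])
        raise ConfigError(f"unknown structure name {name!r}")

    def core_labels(self) -> frozenset[int]:
        out: set[int] = set()
        for n in self.core_five:
            out |= self.labels_for(n)
        return frozenset(out)

    def core_label_map(self) -> dict[int, str]:
        """Map each (member) label of a core nucleus to the nucleus name."""
        out: dict[int, str] = {}
        for n in self.core_five:
            for l in self.labels_for(n):
                out[l] = n
        return out

    def seed_labels(self) -> frozenset[int]:
        out: set[int] = set()
        for s in self.seeds:
            out |= self.labels_for(s)
        return frozenset(out)

    def as_dict(self) -> dict:
        return {
            "labels": dict(self._labels),
            "core_five": list(self.core_five),
            "seeds": list(self.seeds),
            "composites": {k: list(v) for k, v in self.composites.items()},
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StructureSet":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("structure file must hold a mapping")
        if "labels" in raw:
            return cls(
                raw["labels"],
                core_five=raw.get("core_five", CORE_FIVE),
                seeds=raw.get("seeds", DEFAULT_SEEDS),
                composites=raw.get("composites"),
            )
        # flat {name: label} form with reserved keys
        reserved = {"core_five", "seeds", "composites"}
        labels = {k: v for k, v in raw.items() if k not in reserved}
        return cls(
            labels,
            core_five=raw.get("core_five", CORE_FIVE),
            seeds=raw.get("seeds", DEFAULT_SEEDS),
            composites=raw.get("composites"),
        )


# ---------------------------------------------------------------------------
# TCK I/O


def read_tck(path: str | Path) -> Tractogram:
    """Read an MRtrix .tck track file.

    Raises
    ------
    FormatError
        Missing ``mrtrix tracks`` magic line.
    UnsupportedDatatypeError
        Payload datatype other than Float32LE/Float32BE.
    CorruptFileError
        Truncated payload, or a header ``count`` disagreeing with the number
        of streamlines actually present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tck = nib_tck.TckFile.load(str(path), lazy_load=False)
    except HeaderError as e:
        msg = str(e)
        if "magic" in msg.lower():
            raise FormatError(f"{path}: not a TCK file ({msg})") from e
        raise UnsupportedDatatypeError(f"{path}: {msg}") from e
    except (DataError, ValueError, OSError) as e:
        raise CorruptFileError(f"{path}: corrupt TCK payload ({e})") from e

    header = {k: v for k, v in tck.header.items() if not k.startswith("_")}
    streamlines = [
        Streamline(np.asarray(pts, dtype=np.float64), id=i)
        for i, pts in enumerate(tck.streamlines)
    ]
    # the raw "count" header line is the declared value; nibabel's
    # nb_streamlines field reflects what was actually read
    declared = header.get("count", header.get(NibField.NB_STREAMLINES))
    if declared is not None:
        try:
            declared = int(declared)
        except (TypeError, ValueError):
            raise CorruptFileError(f"{path}: unparsable count field {declared!r}")
        if declared != len(streamlines):
            raise CorruptFileError(
                f"{path}: header count {declared} != {len(streamlines)} streamlines in payload"
            )
    header["count"] = len(streamlines)
    return Tractogram(streamlines, header)


def _config_digest(header: Mapping) -> str:
    keys = sorted((str(k), str(v)) for k, v in header.items())
    return hashlib.sha256(repr(keys).encode()).hexdigest()[:16]


def write_tck(tractogram: Tractogram, path: str | Path) -> None:
    """Write a tractogram as MRtrix .tck (Float32LE payload).

    The header records the generating tool and a digest of the provenance
    entries so reruns can be matched to their configuration.  An empty
    tractogram produces a valid zero-count file.
    """
    from . import __version__

    extras = {
        str(k): str(v)
        for k, v in tractogram.header.items()
        if k not in {"count", "datatype", "file", "magic_number", "endianness",
                     "nb_streamlines", "voxel_to_rasmm", "timestamp"}
    }
    extras.setdefault("bgconnect_version", __version__)
    extras["config_digest"] = _config_digest(extras)
    nib_t = _NibTractogram(
        [np.asarray(s.points, dtype=np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib_tck.TckFile(nib_t, header=extras).save(str(path))


# ---------------------------------------------------------------------------
# NIfTI label volumes


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI-1 integer label volume.

    Float-typed files are accepted only when every value is an exact integer.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if np.issubdtype(data.dtype, np.floating):
        if np.isnan(data).any():
            raise FormatError(f"{path}: NaNs in label data")
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise FormatError(f"{path}: non-integer values in label data")
        data = rounded.astype(np.int32)
    elif not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"{path}: unsupported label dtype {data.dtype}")
    return LabelVolume(np.ascontiguousarray(data), img.affine)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.grid.astype(np.int32), volume.affine)
    img.to_filename(str(path))


# ---------------------------------------------------------------------------
# Coordinate transforms


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.trunc(x + np.copysign(0.5, x)).astype(np.int64)


def world_to_voxel(points: np.ndarray, volume: LabelVolume):
    """Map world-mm points to integer voxel indices (voxel-centre convention).

    Returns ``(indices, inside)``: nearest voxel index per point and a flag
    that is False for points whose nearest voxel lies outside the grid
    (callers treat those as background).  Ties at .5 round half away from
    zero.  Accepts a single (3,) point or an (N, 3) array; output shape
    follows the input.
    """
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    hom = pts @ volume._inv_affine[:3, :3].T + volume._inv_affine[:3, 3]
    idx = _round_half_away(hom)
    inside = np.all((idx >= 0) & (idx < np.asarray(volume.shape)), axis=1)
    if single:
        return idx[0], bool(inside[0])
    return idx, inside


def voxel_to_world(indices: np.ndarray, volume: LabelVolume) -> np.ndarray:
    """World-mm coordinates of voxel centres."""
    idx = np.asarray(indices, dtype=np.float64)
    single = idx.ndim == 1
    idx = np.atleast_2d(idx)
    pts = idx @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    return pts[0] if single else pts


def densify(streamline: Streamline, max_spacing: float) -> Streamline:
    """Insert linearly interpolated vertices so no step exceeds ``max_spacing``.

    Original vertices and their order are preserved; a streamline already
    finer than ``max_spacing`` is returned unchanged.  Needed only when the
    tracking step size exceeds roughly half the voxel size — at the native
    0.05 mm step on a 0.5 mm grid the label sequence is already lossless.
    """
    if max_spacing <= 0:
        raise ValueError("max_spacing must be positive")
    pts = streamline.points
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.all(steps <= max_spacing):
        return streamline
    pieces = []
    for i, d in enumerate(steps):
        n_sub = max(1, int(np.ceil(d / max_spacing)))
        t = np.linspace(0.0, 1.0, n_sub, endpoint=False)[:, None]
        pieces.append(pts[i] + t * (pts[i + 1] - pts[i]))
    pieces.append(pts[-1:])
    return Streamline(np.vstack(pieces), id=streamline.id)
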