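"""Selection of seed-intersecting tracks and structure-visit compression.

A track "visits" a structure iff at least one of its vertices maps into that
structure's voxels (vertex membership, not geometric segment crossing).  At
the native tracking step of 0.05 mm against 0.5 mm voxels this is lossless;
for coarser inputs :func:`bgconnect.streamline_io.densify` should be applied
first.  A consequence worth knowing: a diagonal corner-cutting crossing that
places no vertex inside a voxel is *not* a visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .streamline_io import LabelVolume, Streamline, StructureSet, Tractogram

__all__ = [
    "LabelSequence",
    "label_sequence",
    "label_sequences",
    "intersects",
    "select_seed_tracks",
]


@dataclass
class LabelSequence:
    """Run-length compressed structure visits of one streamline.

    ``visits`` holds ``(label, first_vertex, last_vertex)`` for every maximal
    run of consecutive vertices inside one nonzero label; background runs are
    omitted.  Spans are strictly increasing and no two consecutive visits
    share a label.
    """

    streamline_id: int
    visits: list[tuple[int, int, int]] = field(default_factory=list)

    def labels(self) -> list[int]:
        """Visit labels in order (may repeat on re-entry)."""
        return [v[0] for v in self.visits]

    def label_set(self) -> frozenset[int]:
        return frozenset(v[0] for v in self.visits)

    def reversed(self, n_vertices: int) -> "LabelSequence":
        """The sequence of the point-reversed streamline (used in tests)."""
        rev = [
            (lab, n_vertices - 1 - last, n_vertices - 1 - first)
            for lab, first, last in reversed(self.visits)
        ]
        return LabelSequence(self.streamline_id, rev)


def _compress_runs(labels: np.ndarray, streamline_id: int) -> LabelSequence:
    """Run-length compress a per-vertex label array, dropping background."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return LabelSequence(streamline_id, [])
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [labels.size - 1]))
    visits = [
        (int(labels[s]), int(s), int(e))
        for s, e in zip(starts, ends)
        if labels[s] != 0
    ]
    return LabelSequence(streamline_id, visits)


def label_sequence(streamline: Streamline, volume: LabelVolume) -> LabelSequence:
    """Compress one streamline into its ordered structure visits.

    Each vertex is mapped to its nearest voxel; out-of-grid vertices count as
    background.  A track entirely in background yields an empty visit list.
    """
    labels = volume.labels_at(streamline.points)
    return _compress_runs(labels, streamline.id)


def label_sequences(tractogram: Tractogram, volume: LabelVolume) -> list[LabelSequence]:
    """Label sequences for every streamline, batched for speed.

    Equivalent to ``[label_sequence(s, volume) for s in tractogram]`` but
    performs a single vectorised voxel lookup over all vertices.
    """
    if tractogram.count == 0:
        return []
    lengths = [len(s) for s in tractogram.streamlines]
    all_pts = np.concatenate([s.points for s in tractogram.streamlines], axis=0)
    all_labels = volume.labels_at(all_pts)
    out = []
    offset = 0
    for s, n in zip(tractogram.streamlines, lengths):
        out.append(_compress_runs(all_labels[offset : offset + n], s.id))
        offset += n
    return out


def intersects(seq: LabelSequence, labels: Iterable[int]) -> bool:
    """True iff any visit's label is in ``labels``.

    ``labels`` are integer labels; expand composite structures (SN, GP) with
    :meth:`StructureSet.labels_for` before calling.
    """
    label_set = frozenset(labels)
    return any(v[0] in label_set for v in seq.visits)


def select_seed_tracks(
    tractogram: Tractogram,
    volume: LabelVolume,
    structures: StructureSet,
    min_visit_vertices: int = 1,
) -> tuple[list[int], list[LabelSequence]]:
    """Keep exactly the tracks whose visits intersect any seed structure.

    Mirrors the selection step of the source pipeline: only tracks
    intersecting the STN, SN, or GP proceed to connectivity analysis.
    Returns ``(selected_ids, label_sequences)`` where the sequences cover the
    *selected* tracks only, for downstream reuse.

    ``min_visit_vertices`` sets the minimum dwell (vertices inside a
    structure) for a visit to count; the default of 1 means a single-vertex
    touch is a visit.
    """
    seed_labels = structures.seed_labels()
    seqs = label_sequences(tractogram, volume)
    if min_visit_vertices > 1:
        seqs = [_apply_min_dwell(q, min_visit_vertices) for q in seqs]
    selected_ids: list[int] = []
    selected_seqs: list[LabelSequence] = []
    for seq in seqs:
        if intersects(seq, seed_labels):
            selected_ids.append(seq.streamline_id)
            selected_seqs.append(seq)
    return selected_ids, selected_seqs


def save_sequences(sequences: Iterable[LabelSequence], path) -> None:
    """Write visit lists to the pipeline's JSON exchange format."""
    import json

    payload = {
        "tracks": [
            {"id": q.streamline_id, "visits": [list(v) for v in q.visits]}
            for q in sequences
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_sequences(path) -> list[LabelSequence]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    return [
        LabelSequence(int(t["id"]), [tuple(int(x) for x in v) for v in t["visits"]])
        for t in payload["tracks"]
    ]


def _apply_min_dwell(seq: LabelSequence, min_vertices: int) -> LabelSequence:
    kept = [v for v in seq.visits if v[2] - v[1] + 1 >= min_vertices]
    # dropping short visits can make adjacent same-label runs; re-merge
    merged: list[tuple[int, int, int]] = []
    for v in kept:
        if merged and merged[-1][0] == v[0]:
            merged[-1] = (v[0], merged[-1][1], v[2])
        else:
            merged.append(list(v))  # type: ignore[arg-type]
    return LabelSequence(seq.streamline_id, [tuple(v) for v in merged])
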