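"""Direct inter-nucleus segments and the asymmetric direct-connection matrix.

A *direct* connection joins two of the five core nuclei (STN, SNc, SNr, GPe,
GPi) without passing through a third member of that set.  Auxiliary ROIs
(internal capsule, anterior commissure, ...) are transparent: a segment that
crosses the capsule between two nuclei is still direct — only the five core
nuclei break directness.

Counts are over *segments*, not tracks: one track cut into three direct
segments contributes three counts.  Segments are unordered pairs because
tractography cannot infer direction, so the count matrix is symmetric.  The
percentage matrix is column-normalised (each column = share of that
structure's direct connections) and therefore generally asymmetric even
though the counts are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .streamline_io import StructureSet
from .track_selection import LabelSequence

__all__ = [
    "DirectSegment",
    "DirectMatrix",
    "subsample_tracks",
    "cut_direct_segments",
    "direct_counts",
    "normalize_direct",
    "direct_matrix",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirectSegment:
    """A sub-streamline joining two distinct core nuclei directly.

    ``span`` is (last vertex inside the first structure, first vertex inside
    the second); no vertex strictly between them maps to a core nucleus.
    """

    streamline_id: int
    endpoints: frozenset[int]
    span: tuple[int, int]

    def __post_init__(self):
        if len(self.endpoints) != 2:
            raise ValueError("segment endpoints must be two distinct labels")


@dataclass
class DirectMatrix:
    """Symmetric segment counts and column-normalised percentages."""

    counts: pd.DataFrame
    percent: pd.DataFrame


def subsample_tracks(ids: Sequence[int], n: int, rng_seed: int) -> list[int]:
    """Draw ``n`` track ids without replacement, deterministically.

    Mirrors the compute-budget subsampling of the original analysis (9000 of
    the selected tracks).  ``n`` larger than the population takes everything
    and logs a warning.  Output is sorted for reproducibility.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    ids = list(ids)
    if n >= len(ids):
        if n > len(ids):
            log.warning("subsample n=%d exceeds population %d; taking all", n, len(ids))
        return sorted(ids)
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(ids), size=n, replace=False)
    return sorted(ids[i] for i in chosen)


def cut_direct_segments(
    seq: LabelSequence,
    core_labels: Iterable[int] | dict[int, object],
    dedupe_per_track: bool = False,
) -> list[DirectSegment]:
    """Cut one track's visit sequence into direct core-to-core segments.

    Visits to non-core labels are discarded first (they do not break
    directness); each consecutive pair of core visits belonging to
    *different* nuclei yields one segment.  Re-entry into the same nucleus
    with no other core nucleus in between yields nothing (the matrix has no
    diagonal).  With ``dedupe_per_track`` a repeated unordered pair within
    one track is emitted only once.

    ``core_labels`` is either the set of core labels, or a mapping from
    label to a nucleus key for the case where one nucleus spans several
    labels (e.g. split anterior/posterior halves).
    """
    if isinstance(core_labels, dict):
        group = dict(core_labels)
    else:
        group = {l: l for l in core_labels}
    filtered = [v for v in seq.visits if v[0] in group]
    segments: list[DirectSegment] = []
    seen: set[frozenset] = set()
    for (la, _, last_a), (lb, first_b, _) in zip(filtered, filtered[1:]):
        if group[la] == group[lb]:
            continue
        pair = frozenset((la, lb))
        if dedupe_per_track:
            gpair = frozenset((group[la], group[lb]))
            if gpair in seen:
                continue
            seen.add(gpair)
        segments.append(DirectSegment(seq.streamline_id, pair, (last_a, first_b)))
    return segments


def direct_counts(
    segments: Iterable[DirectSegment], structures: StructureSet
) -> pd.DataFrame:
    """Symmetric 5x5 segment counts over the core nuclei (diagonal zero)."""
    names = list(structures.core_five)
    label_to_name = structures.core_label_map()
    counts = pd.DataFrame(0, index=names, columns=names, dtype=np.int64)
    for seg in segments:
        a, b = sorted(seg.endpoints)
        na, nb = label_to_name[a], label_to_name[b]
        counts.loc[na, nb] += 1
        counts.loc[nb, na] += 1
    return counts


def normalize_direct(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise counts to percentages.

    Column j holds each partner's share of structure j's direct connections,
    so every nonzero column sums to 100.  All-zero columns stay zero and are
    logged rather than producing NaNs.
    """
    if not np.allclose(counts.values, counts.values.T):
        raise ValueError("direct counts must be symmetric")
    if np.any(np.diag(counts.values) != 0):
        raise ValueError("direct counts must have a zero diagonal")
    totals = counts.sum(axis=0)
    percent = counts.astype(float).copy()
    for col in counts.columns:
        t = totals[col]
        if t > 0:
            percent[col] = 100.0 * counts[col] / t
        else:
            percent[col] = 0.0
            log.warning("structure %s has no direct connections; column left at 0", col)
    return percent


def direct_matrix(
    sequences: Iterable[LabelSequence],
    structures: StructureSet,
    subsample_n: int | None = None,
    rng_seed: int = 0,
    dedupe_per_track: bool = False,
) -> tuple[DirectMatrix, list[DirectSegment]]:
    """Cut, count and normalise in one call.

    ``subsample_n`` restricts the analysis to a random subset of tracks (the
    original analysis used 9000); ``None`` uses the full population, the
    recommended default for phantoms.
    """
    sequences = list(sequences)
    if subsample_n is not None:
        keep = set(
            subsample_tracks([s.streamline_id for s in sequences], subsample_n, rng_seed)
        )
        sequences = [s for s in sequences if s.streamline_id in keep]
    core = {l: n for l, n in structures.core_label_map().items()}
    segments: list[DirectSegment] = []
    for seq in sequences:
        segments.extend(cut_direct_segments(seq, core, dedupe_per_track=dedupe_per_track))
    counts = direct_counts(segments, structures)
    return DirectMatrix(counts, normalize_direct(counts)), segments
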