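"""Per-nucleotide coverage tracks and the cross-library end-count matrix.

Three track kinds are supported: ``full`` (every aligned read base),
``end3`` (one count per read at its 3'-terminal aligned base) and ``end5``
(mirror). Soft/hard clips never contribute; neither do D/N reference gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .errors import ConfigError, InputError
from .formats import AlignmentRecord

TRACK_KINDS = ("full", "end3", "end5")

PositionKey = Tuple[str, int, str]  # (replicon, 0-based position, strand)


@dataclass
class CoverageTrack:
    replicon: str
    strand: str
    kind: str
    values: np.ndarray

    def __post_init__(self):
        if self.kind not in TRACK_KINDS:
            raise ConfigError(f"unknown track kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.int64)


def _terminal_positions(aln: AlignmentRecord) -> Tuple[int, int]:
    """(end3, end5) 0-based reference positions of the terminal aligned bases."""
    blocks = aln.aligned_blocks()
    if not blocks:
        raise InputError(f"read {aln.read_id}: no aligned bases")
    left = blocks[0][0]
    right = blocks[-1][1] - 1
    if aln.strand == "+":
        return right, left
    return left, right


def compute_coverage(
    alignments: Sequence[AlignmentRecord],
    replicon_lengths: Mapping[str, int],
    kind: str = "end3",
) -> List[CoverageTrack]:
    """Tally one coverage track per (replicon, strand) over all alignments.

    ``full`` increments every M/=/X reference base of a read; ``end3``
    increments exactly one position per read (rightmost aligned base on
    ``+``, leftmost on ``-``); ``end5`` is the mirror.

    Raises :class:`InputError` if an alignment extends past the replicon.
    """
    if kind not in TRACK_KINDS:
        raise ConfigError(f"unknown track kind {kind!r}")
    arrays: Dict[Tuple[str, str], np.ndarray] = {
        (rep, strand): np.zeros(length, dtype=np.int64)
        for rep, length in replicon_lengths.items()
        for strand in "+-"
    }
    for aln in alignments:
        key = (aln.replicon, aln.strand)
        if key not in arrays:
            raise InputError(f"read {aln.read_id}: unknown replicon {aln.replicon!r}")
        track = arrays[key]
        if aln.end > track.size or aln.start < 0:
            raise InputError(
                f"read {aln.read_id}: alignment [{aln.start},{aln.end}) exceeds "
                f"replicon {aln.replicon} (length {track.size})"
            )
        if kind == "full":
            for s, e in aln.aligned_blocks():
                track[s:e] += 1
        else:
            end3, end5 = _terminal_positions(aln)
            track[end3 if kind == "end3" else end5] += 1
    return [
        CoverageTrack(replicon=rep, strand=strand, kind=kind, values=arr)
        for (rep, strand), arr in sorted(arrays.items())
    ]


def tracks_by_key(tracks: Sequence[CoverageTrack]) -> Dict[Tuple[str, str], np.ndarray]:
    return {(t.replicon, t.strand): t.values for t in tracks}


@dataclass
class EndCountMatrix:
    """Candidate positions x libraries matrix of read-terminus counts.

    Plus- and minus-strand positions live in one keyed row set; the strand
    is part of the key, so "integration" is concatenation, never summation.
    """

    positions: List[PositionKey]
    counts: np.ndarray  # shape (n_positions, n_libraries), int64
    library_ids: List[str]

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if not np.issubdtype(arr.dtype, np.integer):
            if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr % 1 != 0)):
                raise InputError("end counts must be integers")
            arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            raise InputError("end counts must be non-negative")
        self.counts = arr
        if self.counts.shape != (len(self.positions), len(self.library_ids)):
            raise ConfigError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.positions)} positions x {len(self.library_ids)} libraries"
            )

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def subset(self, mask: np.ndarray) -> "EndCountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return EndCountMatrix(
            positions=[p for p, keep in zip(self.positions, mask) if keep],
            counts=self.counts[mask],
            library_ids=list(self.library_ids),
        )


def build_end_count_matrix(
    tracks_by_library: Mapping[str, Sequence[CoverageTrack]],
) -> EndCountMatrix:
    """Union of nonzero end positions across libraries, zero-filled elsewhere.

    All libraries must share the same replicon/strand track set and kind.
    """
    library_ids = list(tracks_by_library.keys())
    if not library_ids:
        raise ConfigError("no libraries given")
    per_lib = {lib: tracks_by_key(tracks_by_library[lib]) for lib in library_ids}
    key_sets = {lib: frozenset(d) for lib, d in per_lib.items()}
    first = key_sets[library_ids[0]]
    for lib, keys in key_sets.items():
        if keys != first:
            raise ConfigError(f"library {lib!r} has a different replicon/strand set")
    kinds = {t.kind for tracks in tracks_by_library.values() for t in tracks}
    if len(kinds) > 1:
        raise ConfigError(f"mixed track kinds in matrix input: {sorted(kinds)}")

    positions: List[PositionKey] = []
    columns: List[np.ndarray] = []
    for rep, strand in sorted(first):
        stacked = np.stack([per_lib[lib][(rep, strand)] for lib in library_ids], axis=1)
        nonzero = np.flatnonzero(stacked.any(axis=1))
        positions.extend((rep, int(pos), strand) for pos in nonzero)
        columns.append(stacked[nonzero])
    counts = (
        np.concatenate(columns, axis=0)
        if columns
        else np.zeros((0, len(library_ids)), dtype=np.int64)
    )
    return EndCountMatrix(positions=positions, counts=counts, library_ids=library_ids)
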