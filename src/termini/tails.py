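"""Untemplated 3' tail profiling from locally aligned reads.

A tail is the soft-clipped block at the read's 3' side; it is trusted only
when the read starts (in read orientation) with a contiguous aligned block
of at least ``min_anchor`` nucleotides. Any 5' soft clip fails the anchor
rule. Tails are stored and reported in read orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError
from .formats import AlignmentRecord

BASES = "ACGT"


@dataclass(frozen=True)
class TailRecord:
    read_id: str
    replicon: str
    strand: str
    last_matched_position: int  # reference position of the aligned base next to the tail
    anchor_length: int
    tail_sequence: str


def _read_orientation_cigar(aln: AlignmentRecord) -> Tuple[Tuple[str, int], ...]:
    return tuple(reversed(aln.cigar)) if aln.strand == "-" else aln.cigar


def extract_tails(
    alignments: Sequence[AlignmentRecord],
    min_anchor: int = 10,
) -> List[TailRecord]:
    """Soft-clipped 3' tails from reads satisfying the 5' anchor rule.

    In read orientation the CIGAR must open with an M/=/X block of at least
    ``min_anchor`` nt (hard clips ignored, a 5' soft clip is disqualifying)
    and close with a soft clip of >= 1 nt, which becomes the tail. On the
    minus strand the read's 3' tail is the leading soft clip in reference
    orientation; the reverse-complemented stored sequence already restores
    read orientation.
    """
    records: List[TailRecord] = []
    for aln in alignments:
        cigar = [(op, n) for op, n in _read_orientation_cigar(aln) if op != "H"]
        if not cigar:
            continue
        head_op, head_n = cigar[0]
        if head_op not in "M=X":
            continue  # 5' soft clip (or gap) breaks the anchor
        anchor = 0
        for op, n in cigar:
            if op in "M=X":
                anchor += n
            else:
                break
        if anchor < min_anchor:
            continue
        tail_op, tail_n = cigar[-1]
        if tail_op != "S":
            continue
        if aln.read_sequence is None:
            raise InputError(f"read {aln.read_id}: sequence missing ('*'), cannot extract tail")
        tail_seq = aln.read_sequence[-tail_n:]
        blocks = aln.aligned_blocks()
        last_matched = blocks[-1][1] - 1 if aln.strand == "+" else blocks[0][0]
        records.append(
            TailRecord(
                read_id=aln.read_id,
                replicon=aln.replicon,
                strand=aln.strand,
                last_matched_position=last_matched,
                anchor_length=anchor,
                tail_sequence=tail_seq,
            )
        )
    return records


@dataclass
class TailSummary:
    n_records: int
    length_counts: Dict[int, int]
    quantiles: Dict[str, float]  # q25/q50/q75/q95, type-7 interpolation
    base_frequencies: np.ndarray  # (max_positions, 4) for A/C/G/T; NaN where unobserved
    position_depth: np.ndarray  # non-N observations per tail position

    def fraction_at_most(self, length: int) -> float:
        total = sum(self.length_counts.values())
        return sum(n for L, n in self.length_counts.items() if L <= length) / total


def summarize_tails(records: Sequence[TailRecord], max_positions: int = 50) -> TailSummary:
    """Length distribution and positional base composition of tails.

    Position p (1-based within the tail) frequencies are computed from all
    tails long enough to reach p; N bases are excluded from denominators.
    """
    if not records:
        raise InputError("no tail records to summarize")
    lengths = np.array([len(r.tail_sequence) for r in records])
    length_counts: Dict[int, int] = {}
    for L in lengths:
        length_counts[int(L)] = length_counts.get(int(L), 0) + 1
    quantiles = {
        f"q{int(q * 100)}": float(np.quantile(lengths, q)) for q in (0.25, 0.5, 0.75, 0.95)
    }
    tallies = np.zeros((max_positions, 4), dtype=np.int64)
    base_index = {b: i for i, b in enumerate(BASES)}
    for r in records:
        for pos, base in enumerate(r.tail_sequence[:max_positions]):
            i = base_index.get(base.upper())
            if i is not None:
                tallies[pos, i] += 1
    depth = tallies.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(depth[:, None] > 0, tallies / np.maximum(depth, 1)[:, None], np.nan)
    return TailSummary(
        n_records=len(records),
        length_counts=length_counts,
        quantiles=quantiles,
        base_frequencies=freqs,
        position_depth=depth,
    )


def tails_to_fasta(records: Sequence[TailRecord]) -> str:
    lines = []
    for r in records:
        lines.append(f">{r.read_id}:{r.replicon}:{r.last_matched_position}:{r.strand}")
        lines.append(r.tail_sequence)
    return "".join(line + "\n" for line in lines)


def length_histogram_tsv(summary: TailSummary) -> str:
    lines = ["length\tcount"]
    for L in sorted(summary.length_counts):
        lines.append(f"{L}\t{summary.length_counts[L]}")
    return "".join(line + "\n" for line in lines)


def base_frequency_tsv(summary: TailSummary) -> str:
    lines = ["position\tA\tC\tG\tT\tdepth"]
    for i in range(summary.base_frequencies.shape[0]):
        if summary.position_depth[i] == 0:
            continue
        row = "\t".join(f"{v:.6f}" for v in summary.base_frequencies[i])
        lines.append(f"{i + 1}\t{row}\t{summary.position_depth[i]}")
    return "".join(line + "\n" for line in lines)
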