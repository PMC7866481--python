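"""Readers and writers for the standard formats the pipeline touches.

SAM and GFF3 use 1-based coordinates on disk; everything internal is
0-based half-open. Conversion happens exactly once, at the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import pysam
from Bio import SeqIO

from .errors import (
    DesignError,
    FormatError,
    GffFormatError,
    SamFormatError,
    UnknownRepliconError,
)

PathLike = Union[str, os.PathLike]

_CIGAR_OPS = "MIDNSHP=X"
_QUERY_OPS = frozenset("MIS=X")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: GFF3 types mapped onto the closed feature-class set; anything absent
#: falls back to ``other``. A value of ``None`` drops the feature.
DEFAULT_CLASS_MAP: Mapping[str, Optional[str]] = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ncRNA": "ncRNA",
    "sRNA": "ncRNA",
    "tmRNA": "ncRNA",
    "region": None,
    "gene": None,
    "exon": None,
}

FEATURE_CLASSES = ("CDS", "tRNA", "rRNA", "ncRNA", "other")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped, primary alignment in internal coordinates.

    ``start`` is the 0-based leftmost reference position; ``cigar`` is kept
    in reference orientation; ``read_sequence`` is stored in the original
    read orientation (reverse-complemented relative to the SAM SEQ field
    for minus-strand records), or ``None`` when SEQ was ``*``.
    """

    read_id: str
    replicon: str
    strand: str
    start: int
    cigar: tuple
    read_sequence: Optional[str] = None
    mapq: int = 0
    is_mapped: bool = True
    is_primary: bool = True

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MDN=X")

    @property
    def end(self) -> int:
        """0-based exclusive rightmost reference coordinate."""
        return self.start + self.reference_span

    def aligned_blocks(self) -> list:
        """Reference intervals (0-based half-open) covered by M/=/X ops."""
        blocks = []
        pos = self.start
        for op, n in self.cigar:
            if op in "M=X":
                if blocks and blocks[-1][1] == pos:
                    blocks[-1][1] = pos + n
                else:
                    blocks.append([pos, pos + n])
                pos += n
            elif op in "DN":
                pos += n
        return [tuple(b) for b in blocks]

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_OPS)


@dataclass(frozen=True)
class Feature:
    """Annotated genomic feature in 0-based half-open coordinates."""

    feature_id: str
    replicon: str
    strand: str
    start: int
    end: int
    feature_class: str

    def __post_init__(self):
        if self.start >= self.end:
            raise GffFormatError(
                f"feature {self.feature_id}: empty interval [{self.start},{self.end})"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise GffFormatError(
                f"feature {self.feature_id}: unknown class {self.feature_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing library in a two-condition design."""

    library_id: str
    condition: str  # "reference" or "test"
    replicate_index: int

    def __post_init__(self):
        if self.condition not in ("reference", "test"):
            raise DesignError(
                f"library {self.library_id}: condition must be "
                f"'reference' or 'test', got {self.condition!r}"
            )
        if self.replicate_index < 1:
            raise DesignError(f"library {self.library_id}: replicate_index must be >= 1")


def check_design(design: Sequence[SampleDesign]) -> None:
    """Validate uniqueness and >=2 replicates per condition."""
    ids = [d.library_id for d in design]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate library ids in design")
    for cond in ("reference", "test"):
        n = sum(1 for d in design if d.condition == cond)
        if n < 2:
            raise DesignError(f"condition {cond!r} has {n} libraries; need >= 2")


def _strand_of(flag_reverse: bool) -> str:
    return "-" if flag_reverse else "+"


def read_alignments(
    path: PathLike,
    unique_only: bool = True,
    min_mapq: int = 1,
) -> list:
    """Parse a SAM file into mapped, primary :class:`AlignmentRecord` objects.

    Coordinates are converted to 0-based; FLAG bit 16 becomes strand ``-``.
    Secondary and supplementary alignments are dropped. With ``unique_only``
    (default), a record is kept only if it carries ``NH:i:1`` or, lacking an
    NH tag, has MAPQ >= ``min_mapq``.

    Raises
    ------
    SamFormatError
        On a malformed record, naming the offending data line.
    UnknownRepliconError
        When a record names a replicon absent from the ``@SQ`` header.
    """
    records = []
    n_seen = 0
    try:
        handle = pysam.AlignmentFile(os.fspath(path), "r", check_sq=True)
    except ValueError as exc:
        raise SamFormatError(f"{path}: invalid SAM header: {exc}") from exc
    with handle:
        references = set(handle.references)
        _validate_rnames(path, references)
        iterator = handle.fetch(until_eof=True)
        while True:
            try:
                aln = next(iterator)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                _classify_sam_error(path, n_seen + 1, references, exc)
            n_seen += 1
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if unique_only:
                if aln.has_tag("NH"):
                    if aln.get_tag("NH") != 1:
                        continue
                elif aln.mapping_quality < min_mapq:
                    continue
            seq = aln.query_sequence
            if seq is not None and aln.is_reverse:
                seq = revcomp(seq)
            cigar = tuple(
                (_CIGAR_OPS[op], length) for op, length in (aln.cigartuples or ())
            )
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    replicon=aln.reference_name,
                    strand=_strand_of(aln.is_reverse),
                    start=aln.reference_start,
                    cigar=cigar,
                    read_sequence=seq,
                    mapq=aln.mapping_quality,
                )
            )
    return records


def _validate_rnames(path, references):
    """htslib downgrades unknown RNAMEs to unmapped with a warning; the
    contract wants a hard reference error, so pre-scan the RNAME column."""
    with open(path) as fh:
        data_line = 0
        for line in fh:
            if line.startswith("@"):
                continue
            data_line += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                continue  # malformed; let the real parser raise a format error
            if fields[2] != "*" and fields[2] not in references:
                raise UnknownRepliconError(
                    f"{path}: data line {data_line}: unknown replicon {fields[2]!r}"
                )


def _classify_sam_error(path, data_line, references, exc):
    """Re-read the offending data line to tell reference errors from parse errors."""
    try:
        with open(path) as fh:
            body = [ln for ln in fh if not ln.startswith("@")]
        fields = body[data_line - 1].rstrip("\n").split("\t")
        rname = fields[2] if len(fields) > 2 else "*"
        if rname != "*" and rname not in references:
            raise UnknownRepliconError(
                f"{path}: data line {data_line}: unknown replicon {rname!r}"
            ) from exc
    except (OSError, IndexError):
        pass
    raise SamFormatError(f"{path}: malformed SAM record at data line {data_line}: {exc}") from exc


def read_sam_replicon_lengths(path: PathLike) -> dict:
    """Replicon lengths from the ``@SQ`` header of a SAM file."""
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=True) as handle:
        return dict(zip(handle.references, handle.lengths))


def read_features(
    source: Union[PathLike, IO[str], str],
    class_map: Optional[Mapping[str, Optional[str]]] = None,
) -> list:
    """Parse GFF3 into :class:`Feature` objects (0-based half-open).

    ``class_map`` maps GFF3 type column values to feature classes; types
    not present map to ``other``; a ``None`` value drops the feature.
    """
    if class_map is None:
        class_map = DEFAULT_CLASS_MAP
    lines = _as_lines(source)
    features = []
    auto = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GffFormatError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
        replicon, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GffFormatError(f"GFF3 line {lineno}: non-integer coordinates") from exc
        if end1 < start1:
            raise GffFormatError(f"GFF3 line {lineno}: end {end1} < start {start1}")
        if strand not in ("+", "-"):
            raise GffFormatError(f"GFF3 line {lineno}: missing strand {strand!r}")
        fclass = class_map.get(ftype, "other")
        if fclass is None:
            continue
        fid = _attr(attrs, "ID") or _attr(attrs, "locus_tag") or _attr(attrs, "Name")
        if fid is None:
            auto += 1
            fid = f"feature_{auto}"
        features.append(
            Feature(
                feature_id=fid,
                replicon=replicon,
                strand=strand,
                start=start1 - 1,
                end=end1,
                feature_class=fclass,
            )
        )
    return features


def _attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def _as_lines(source) -> Iterable[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    text_or_path = os.fspath(source) if isinstance(source, os.PathLike) else source
    if isinstance(text_or_path, str) and ("\n" in text_or_path or "\t" in text_or_path):
        return text_or_path.splitlines()
    with open(text_or_path) as fh:
        return fh.read().splitlines()


def read_fasta(path: PathLike) -> dict:
    """FASTA -> {replicon: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_ends_bed(ends: Sequence) -> str:
    """Render differential ends as BED6 text, sorted by (chrom, start).

    Score carries the mean log2 fold change with 4 decimals.
    """
    ordered = sorted(ends, key=lambda e: (e.replicon, e.start, e.strand))
    lines = [
        f"{e.replicon}\t{e.start}\t{e.end}\tend_{i}\t{e.mean_log2fc:.4f}\t{e.strand}"
        for i, e in enumerate(ordered, start=1)
    ]
    return "".join(line + "\n" for line in lines)


def parse_bed6(text: str) -> list:
    """Parse BED6 text into (chrom, start, end, name, score, strand) tuples."""
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        cols = line.split("\t")
        if len(cols) < 6:
            raise FormatError(f"BED line {lineno}: expected 6 columns")
        rows.append((cols[0], int(cols[1]), int(cols[2]), cols[3], float(cols[4]), cols[5]))
    return rows


def write_bedgraph(values, replicon: str) -> str:
    """Run-length encode a per-base vector as bedGraph (nonzero runs only)."""
    import numpy as np

    values = np.asarray(values)
    lines = []
    if values.size:
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                lines.append(f"{replicon}\t{s}\t{e}\t{v:g}")
    return "".join(line + "\n" for line in lines)


def read_design_table(path: PathLike):
    """Read a sample design TSV with columns library_id, condition, replicate
    and an optional sam column; returns (designs, {library_id: sam_path})."""
    import csv

    designs, sam_paths = [], {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "library_id" not in reader.fieldnames:
            raise FormatError(f"{path}: design table needs a library_id column")
        for row in reader:
            designs.append(
                SampleDesign(
                    library_id=row["library_id"],
                    condition=row["condition"],
                    replicate_index=int(row.get("replicate", row.get("replicate_index", 1))),
                )
            )
            if row.get("sam"):
                sam_paths[row["library_id"]] = row["sam"]
    return designs, sam_paths
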