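"""Feature assignment, class summaries and flank-window extraction.

Ends are assigned strand-specifically; an end that overlaps no same-strand
feature falls into the residual UTR class. When several feature classes
overlap one end, the class is chosen by priority tRNA > rRNA > ncRNA >
CDS > other (stable-RNA genes are short and often nested in mRNA context).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .endcall import DifferentialEnd
from .errors import InputError, UnknownRepliconError
from .formats import Feature, revcomp

CLASS_PRIORITY = ("tRNA", "rRNA", "ncRNA", "CDS", "other")
UTR_CLASS = "UTR"


@dataclass
class AnnotatedEnd:
    end: DifferentialEnd
    assigned_features: List[Feature] = field(default_factory=list)
    assigned_class: str = UTR_CLASS


@dataclass
class ClassSummary:
    """Counts per (feature class + UTR, direction), plus per-gene tallies of
    enriched ends (absolute and per-kb)."""

    counts: Dict[Tuple[str, str], int]
    per_gene_counts: Dict[str, int]
    per_gene_per_kb: Dict[str, float]
    n_ends: int


def assign_features(
    ends: Sequence[DifferentialEnd],
    features: Sequence[Feature],
    known_replicons: Optional[Sequence[str]] = None,
) -> List[AnnotatedEnd]:
    """Attach every same-strand overlapping feature to each end.

    Overlap means a nonempty half-open interval intersection on the same
    strand. With no overlap the end is classed UTR.
    """
    if known_replicons is not None:
        known = set(known_replicons)
        for e in ends:
            if e.replicon not in known:
                raise UnknownRepliconError(f"end on unknown replicon {e.replicon!r}")
    index: Dict[Tuple[str, str], Tuple[List[int], List[Feature]]] = {}
    for key, group in _group_features(features).items():
        group.sort(key=lambda f: f.start)
        index[key] = ([f.start for f in group], group)

    annotated = []
    for e in ends:
        hits: List[Feature] = []
        entry = index.get((e.replicon, e.strand))
        if entry is not None:
            starts, group = entry
            # candidates must start before the end's right edge
            hi = bisect.bisect_left(starts, e.end)
            for f in group[:hi]:
                if f.end > e.start:
                    hits.append(f)
        cls = UTR_CLASS
        if hits:
            present = {f.feature_class for f in hits}
            cls = next(c for c in CLASS_PRIORITY if c in present)
        annotated.append(AnnotatedEnd(end=e, assigned_features=hits, assigned_class=cls))
    return annotated


def _group_features(features: Sequence[Feature]) -> Dict[Tuple[str, str], List[Feature]]:
    grouped: Dict[Tuple[str, str], List[Feature]] = {}
    for f in features:
        grouped.setdefault((f.replicon, f.strand), []).append(f)
    return grouped


def summarize_classes(
    annotated: Sequence[AnnotatedEnd],
    features: Sequence[Feature],
) -> ClassSummary:
    """Tally (class, direction) cells and per-gene enriched-end counts.

    Per-kb values normalize the absolute enriched count by feature length:
    count * 1000 / length.
    """
    counts: Dict[Tuple[str, str], int] = {}
    per_gene: Dict[str, int] = {}
    for a in annotated:
        key = (a.assigned_class, a.end.direction)
        counts[key] = counts.get(key, 0) + 1
        if a.end.direction == "enriched":
            for f in a.assigned_features:
                per_gene[f.feature_id] = per_gene.get(f.feature_id, 0) + 1
    lengths = {f.feature_id: f.length for f in features}
    per_kb = {
        fid: n * 1000.0 / lengths[fid] for fid, n in per_gene.items() if fid in lengths
    }
    return ClassSummary(
        counts=counts,
        per_gene_counts=per_gene,
        per_gene_per_kb=per_kb,
        n_ends=len(annotated),
    )


def extract_flanks(
    ends: Sequence[DifferentialEnd],
    genome: Mapping[str, str],
    length: int,
    side: str = "upstream",
    dedupe_overlapping: bool = False,
) -> List[Tuple[DifferentialEnd, str]]:
    """Sequence windows flanking each end's terminal base, reported 5'->3'.

    For a + strand end with terminal position t the upstream window is
    genome[t-length+1 .. t] (terminal base included) and the downstream
    window genome[t+1 .. t+length]; minus-strand windows are mirrored and
    reverse-complemented. Windows truncated by a replicon boundary are
    dropped with a warning — never silently shortened.
    """
    if length < 1:
        raise InputError(f"window length must be >= 1, got {length}")
    if side not in ("upstream", "downstream"):
        raise InputError(f"side must be 'upstream' or 'downstream', got {side!r}")
    if dedupe_overlapping:
        ends = _drop_overlapping(ends)
    out: List[Tuple[DifferentialEnd, str]] = []
    n_dropped = 0
    for e in ends:
        if e.replicon not in genome:
            raise UnknownRepliconError(f"replicon {e.replicon!r} absent from FASTA")
        seq = genome[e.replicon]
        t = e.terminal_position
        if e.strand == "+":
            lo, hi = (t - length + 1, t + 1) if side == "upstream" else (t + 1, t + length + 1)
            window = seq[max(lo, 0) : hi]
            if lo < 0 or hi > len(seq):
                window = ""  # force drop
            flank = window
        else:
            lo, hi = (t, t + length) if side == "upstream" else (t - length, t)
            window = seq[max(lo, 0) : hi]
            if lo < 0 or hi > len(seq):
                window = ""
            flank = revcomp(window)
        if len(flank) != length:
            n_dropped += 1
            continue
        out.append((e, flank))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} flank windows truncated at replicon boundaries",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def _drop_overlapping(ends: Sequence[DifferentialEnd]) -> List[DifferentialEnd]:
    """Keep only ends whose intervals overlap no other end on the same strand."""
    keep = []
    for e in ends:
        clash = any(
            o is not e
            and o.replicon == e.replicon
            and o.strand == e.strand
            and o.start < e.end
            and e.start < o.end
            for o in ends
        )
        if not clash:
            keep.append(e)
    return keep


def flanks_to_fasta(flanks: Sequence[Tuple[DifferentialEnd, str]], side: str, length: int) -> str:
    lines = []
    for e, seq in flanks:
        lines.append(f">{e.replicon}:{e.terminal_position}:{e.strand}:{side}{length}")
        lines.append(seq)
    return "".join(line + "\n" for line in lines)


def unstructured_fraction(mfe_values: Sequence[float], tol: float = 1e-9) -> float:
    """Fraction of folding energies equal to 0.0 kcal/mol within tolerance."""
    values = list(mfe_values)
    if not values:
        raise InputError("cannot compute a fraction of an empty MFE list")
    n_zero = sum(1 for v in values if abs(v) <= tol)
    return n_zero / len(values)
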