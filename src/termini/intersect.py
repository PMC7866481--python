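"""Comparison of two differential-end sets: windowed same-strand matching,
fold-change quadrant classification, and a Fisher's exact overlap test
against a genome-size-derived universe of possible ends.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .endcall import DifferentialEnd
from .errors import InputError

QUADRANTS = ("A+B+", "A+B-", "A-B+", "A-B-")


@dataclass
class EndMatch:
    end_a: DifferentialEnd
    end_b: DifferentialEnd

    @property
    def lfc_a(self) -> float:
        return self.end_a.mean_log2fc

    @property
    def lfc_b(self) -> float:
        return self.end_b.mean_log2fc

    @property
    def quadrant(self) -> str:
        a = "+" if self.lfc_a > 0 else "-"
        b = "+" if self.lfc_b > 0 else "-"
        return f"A{a}B{b}"


@dataclass
class MatchSummary:
    n_pairs: int
    unique_a: int
    unique_b: int


def window_match(
    set_a: Sequence[DifferentialEnd],
    set_b: Sequence[DifferentialEnd],
    window: int = 1,
) -> Tuple[List[EndMatch], MatchSummary]:
    """All same-strand overlaps after extending A intervals by ``window`` nt.

    Every overlapping (A, B) pair is reported; the summary counts pairs and
    distinct matched ends on each side.
    """
    if window < 0:
        raise InputError(f"window must be >= 0, got {window}")
    by_key: Dict[Tuple[str, str], List[DifferentialEnd]] = {}
    for b in set_b:
        by_key.setdefault((b.replicon, b.strand), []).append(b)
    index: Dict[Tuple[str, str], Tuple[List[int], List[DifferentialEnd]]] = {}
    for key, group in by_key.items():
        group.sort(key=lambda e: e.start)
        index[key] = ([e.start for e in group], group)

    matches: List[EndMatch] = []
    seen_a, seen_b = set(), set()
    for a in set_a:
        entry = index.get((a.replicon, a.strand))
        if entry is None:
            continue
        starts, group = entry
        lo, hi = a.start - window, a.end + window
        for b in group[: bisect.bisect_left(starts, hi)]:
            if b.end > lo:
                matches.append(EndMatch(end_a=a, end_b=b))
                seen_a.add(id(a))
                seen_b.add(id(b))
    summary = MatchSummary(n_pairs=len(matches), unique_a=len(seen_a), unique_b=len(seen_b))
    return matches, summary


def quadrant_counts(
    matches: Sequence[EndMatch],
    totals_b: Optional[Dict[str, int]] = None,
) -> Tuple[Dict[str, int], Dict[str, float]]:
    """Counts per sign quadrant plus percentages of B-direction totals.

    ``totals_b`` may supply the full B-set sizes per direction
    ({"enriched": n, "depleted": m}); by default the distinct B ends seen in
    the matches are used as denominators.
    """
    counts = {q: 0 for q in QUADRANTS}
    b_by_dir: Dict[str, set] = {"enriched": set(), "depleted": set()}
    for m in matches:
        counts[m.quadrant] += 1
        b_by_dir[m.end_b.direction].add(id(m.end_b))
    if totals_b is None:
        totals_b = {d: len(s) for d, s in b_by_dir.items()}
    percentages = {}
    for q in QUADRANTS:
        direction = "enriched" if q.endswith("+") else "depleted"
        denom = totals_b.get(direction, 0)
        percentages[q] = 100.0 * counts[q] / denom if denom else 0.0
    return counts, percentages


def estimate_universe(
    genome_length: int,
    set_a: Sequence[DifferentialEnd],
    set_b: Sequence[DifferentialEnd],
) -> int:
    """floor(genome_length / (mean width A + mean width B)).

    ``genome_length`` is the single-stranded total over replicons; mean
    widths are the average distribution sizes of the two end sets.
    """
    if not set_a or not set_b:
        raise InputError("both end sets must be nonempty to estimate the universe")
    mean_a = sum(e.distribution_size for e in set_a) / len(set_a)
    mean_b = sum(e.distribution_size for e in set_b) / len(set_b)
    return math.floor(genome_length / (mean_a + mean_b))


@dataclass
class OverlapTestInput:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int

    @property
    def table(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        a_only = self.n_a - self.n_overlap
        b_only = self.n_b - self.n_overlap
        neither = self.universe - self.n_a - self.n_b + self.n_overlap
        return ((self.n_overlap, a_only), (b_only, neither))

    def __post_init__(self):
        (o, ao), (bo, ne) = self.table
        if min(o, ao, bo, ne) < 0:
            raise InputError(
                f"inconsistent overlap table: overlap={o}, A-only={ao}, "
                f"B-only={bo}, neither={ne}"
            )


def build_overlap_table(
    set_a: Sequence[DifferentialEnd],
    set_b: Sequence[DifferentialEnd],
    genome_length: int,
    window: int = 1,
) -> OverlapTestInput:
    """Collapse matched pairs to distinct overlaps and frame the 2x2 table.

    The overlap cell is min(distinct matched A ends, distinct matched B
    ends) so it never exceeds either margin.
    """
    _, summary = window_match(set_a, set_b, window=window)
    n_overlap = min(summary.unique_a, summary.unique_b)
    universe = estimate_universe(genome_length, set_a, set_b)
    return OverlapTestInput(
        n_a=len(set_a), n_b=len(set_b), n_overlap=n_overlap, universe=universe
    )


@dataclass
class FisherResult:
    log10_p: float

    @property
    def p(self) -> float:
        return 10.0**self.log10_p if self.log10_p > -300 else 0.0


def fisher_two_tail(table, rel_tol: float = 1e-7) -> FisherResult:
    """Two-tailed Fisher's exact test, computed entirely in log space.

    Sums hypergeometric probabilities of all tables (at fixed margins) whose
    probability is <= the observed table's probability, with a relative
    cushion of ``rel_tol`` on the comparison. The result carries log10(p)
    so probabilities far below float underflow remain reportable.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise InputError("table entries must be non-negative")
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0 or row1 == 0 or col1 == 0 or row1 == n_total or col1 == n_total:
        return FisherResult(log10_p=0.0)
    k_min = max(0, row1 + col1 - n_total)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    logpmf = stats.hypergeom.logpmf(ks, n_total, col1, row1)
    log_obs = stats.hypergeom.logpmf(a, n_total, col1, row1)
    include = logpmf <= log_obs + math.log1p(rel_tol)
    log_p = float(logsumexp(logpmf[include]))
    return FisherResult(log10_p=min(log_p / math.log(10.0), 0.0))


def intersection_report(
    set_a: Sequence[DifferentialEnd],
    set_b: Sequence[DifferentialEnd],
    genome_length: int,
    window: int = 1,
    totals_b: Optional[Dict[str, int]] = None,
) -> dict:
    """JSON-ready summary of a two-set comparison."""
    matches, summary = window_match(set_a, set_b, window=window)
    counts, percentages = quadrant_counts(matches, totals_b=totals_b)
    table_input = build_overlap_table(set_a, set_b, genome_length, window=window)
    fisher = fisher_two_tail(table_input.table)
    return {
        "n_A": len(set_a),
        "n_B": len(set_b),
        "pairs": summary.n_pairs,
        "unique_A": summary.unique_a,
        "unique_B": summary.unique_b,
        "quadrants": counts,
        "quadrant_percent_of_B": percentages,
        "universe": table_input.universe,
        "overlap": table_input.n_overlap,
        "fisher_log10_p": fisher.log10_p,
        "fisher_p": fisher.p,
    }
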