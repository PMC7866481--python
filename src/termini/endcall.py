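"""Statistical core: candidate filtering, normalization, per-position
negative-binomial testing and merging of significant positions into
differential ends.

The test is a deliberately transparent two-group NB Wald test: size factors
by median-of-ratios, a method-of-moments dispersion shared across positions
(optionally per-position), a delta-method standard error on the log2 ratio
of condition means, two-sided normal p-values and Benjamini-Hochberg
adjustment. No dispersion or fold-change shrinkage is applied; correctness
is established through calibration properties rather than replication of
any particular reference tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .coverage import CoverageTrack, EndCountMatrix, tracks_by_key
from .errors import ConfigError, DesignError, InputError
from .formats import SampleDesign, check_design

DISPERSION_FLOOR = 1e-8
LOG2FC_CONTINUITY = 0.5


@dataclass
class FilterConfig:
    """Thresholds of the calling chain.

    Defaults: end coverage >= 10 in at least one library, end/full signal
    ratio > 0.05 in that same library, |log2FC| >= 1, BH-adjusted p <= 0.05,
    and a 3-nt merge distance.
    """

    min_end_count: int = 10
    min_ratio: float = 0.05
    lfc_cutoff: float = 1.0
    alpha: float = 0.05
    merge_distance: int = 3

    def __post_init__(self):
        if min(self.min_end_count, self.min_ratio, self.lfc_cutoff, self.merge_distance) < 0:
            raise ConfigError("all thresholds must be >= 0")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0,1), got {self.alpha}")


@dataclass
class PositionTestResult:
    replicon: str
    position: int
    strand: str
    basemean: float
    log2fc: float
    p: float
    padj: float = float("nan")

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.replicon, self.position, self.strand)


@dataclass
class DifferentialEnd:
    """A merged run of significant positions on one strand.

    ``distribution_size`` is the interval span in nt; member positions are
    pairwise chained within the merge distance.
    """

    replicon: str
    start: int
    end: int
    strand: str
    n_positions: int
    mean_log2fc: float
    mixed_sign: bool = False
    member_positions: Tuple[int, ...] = field(default_factory=tuple)

    @property
    def distribution_size(self) -> int:
        return self.end - self.start

    @property
    def direction(self) -> str:
        return "enriched" if self.mean_log2fc > 0 else "depleted"

    @property
    def terminal_position(self) -> int:
        """The 3'-most member position (rightmost on +, leftmost on -)."""
        return self.end - 1 if self.strand == "+" else self.start


def filter_masks(
    matrix: EndCountMatrix,
    full_tracks_by_library: Mapping[str, Sequence[CoverageTrack]],
    cfg: FilterConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """(count_mask, joint_mask) over matrix rows.

    ``count_mask``: some library reaches ``min_end_count`` end counts.
    ``joint_mask``: some single library passes the count threshold AND has
    end/full ratio > ``min_ratio`` (full = 0 fails in that library).
    """
    n = matrix.n_positions
    full = np.zeros_like(matrix.counts, dtype=np.float64)
    for j, lib in enumerate(matrix.library_ids):
        if lib not in full_tracks_by_library:
            raise ConfigError(f"missing full coverage track for library {lib!r}")
        keyed = tracks_by_key(full_tracks_by_library[lib])
        for i, (rep, pos, strand) in enumerate(matrix.positions):
            values = keyed.get((rep, strand))
            if values is None:
                raise ConfigError(f"library {lib!r}: no full track for {(rep, strand)}")
            full[i, j] = values[pos]
    counts = matrix.counts
    count_pass = counts >= cfg.min_end_count
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(full > 0, counts / np.where(full > 0, full, 1), 0.0)
    ratio_pass = (full > 0) & (ratio > cfg.min_ratio)
    count_mask = count_pass.any(axis=1) if n else np.zeros(0, dtype=bool)
    joint_mask = (count_pass & ratio_pass).any(axis=1) if n else np.zeros(0, dtype=bool)
    return count_mask, joint_mask


def filter_positions(
    matrix: EndCountMatrix,
    full_tracks_by_library: Mapping[str, Sequence[CoverageTrack]],
    cfg: FilterConfig,
) -> EndCountMatrix:
    """Keep a position iff one library passes count and ratio thresholds jointly."""
    _, joint = filter_masks(matrix, full_tracks_by_library, cfg)
    return matrix.subset(joint)


def estimate_size_factors(matrix: EndCountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    s_j = median over rows i with all-positive counts of k_ij / geomean_i.
    Falls back (with a warning) to library-total ratios when no row has a
    positive geometric mean.
    """
    counts = np.asarray(matrix.counts, dtype=np.float64)
    if counts.size == 0:
        raise InputError("cannot estimate size factors from an empty matrix")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        warnings.warn(
            "no position with positive counts in every library; "
            "falling back to library-total normalization",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise InputError("a library has zero total counts; cannot normalize")
        return totals / np.exp(np.mean(np.log(totals)))
    rows = counts[positive]
    geomean = np.exp(np.log(rows).mean(axis=1, keepdims=True))
    return np.median(rows / geomean, axis=0)


def estimate_dispersion(
    norm_counts: np.ndarray,
    condition_index: np.ndarray,
    size_factors: np.ndarray,
    method: str = "common",
) -> np.ndarray:
    """Method-of-moments NB dispersion on normalized counts.

    Within-condition means are subtracted; the pooled residual variance of
    position i estimates mean_j(1/s_j) * mu_i + alpha * mu_i^2, which is
    solved for alpha. ``common`` (default) averages the per-position
    estimates into a single dataset-wide value; ``per-position`` keeps them
    separate. Estimates are floored at 1e-8.
    """
    n_pos, n_lib = norm_counts.shape
    groups = np.unique(condition_index)
    centered = norm_counts.astype(np.float64).copy()
    for g in groups:
        cols = condition_index == g
        centered[:, cols] -= centered[:, cols].mean(axis=1, keepdims=True)
    df = n_lib - len(groups)
    if df <= 0:
        raise DesignError("need at least one residual degree of freedom per position")
    pooled_var = (centered**2).sum(axis=1) / df
    mu = norm_counts.mean(axis=1)
    poisson_term = mu * np.mean(1.0 / size_factors)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mu > 0, (pooled_var - poisson_term) / np.maximum(mu, 1e-300) ** 2, 0.0)
    if method == "per-position":
        return np.maximum(alpha_raw, DISPERSION_FLOOR)
    if method != "common":
        raise ConfigError(f"unknown dispersion method {method!r}")
    usable = mu > 0
    common = alpha_raw[usable].mean() if usable.any() else 0.0
    return np.full(n_pos, max(common, DISPERSION_FLOOR))


def test_positions(
    matrix: EndCountMatrix,
    design: Sequence[SampleDesign],
    size_factors: Optional[np.ndarray] = None,
    dispersion: str = "common",
) -> List[PositionTestResult]:
    """Two-group NB Wald test at every matrix position.

    Per position: normalized counts n_ij = k_ij / s_j; condition means
    mu_ref, mu_test; log2fc = log2((mu_test + 0.5) / (mu_ref + 0.5));
    Wald z from the delta method on NB variance mu + alpha*mu^2; two-sided
    normal p; BH adjustment across all tested positions. Results keep the
    input row order.
    """
    check_design(design)
    by_id = {d.library_id: d for d in design}
    missing = [lib for lib in matrix.library_ids if lib not in by_id]
    if missing:
        raise DesignError(f"libraries absent from design: {missing}")
    counts = matrix.counts
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.round(counts)):
            raise InputError("count matrix must contain integers")
    condition_index = np.array(
        [1 if by_id[lib].condition == "test" else 0 for lib in matrix.library_ids]
    )
    for g, name in ((0, "reference"), (1, "test")):
        if (condition_index == g).sum() < 2:
            raise DesignError(f"condition {name!r} has fewer than 2 replicates")
    if size_factors is None:
        size_factors = estimate_size_factors(matrix)
    size_factors = np.asarray(size_factors, dtype=np.float64)
    if (size_factors <= 0).any():
        raise InputError("size factors must be positive")

    norm = counts / size_factors[np.newaxis, :]
    alpha = estimate_dispersion(norm, condition_index, size_factors, method=dispersion)

    c = LOG2FC_CONTINUITY
    ln2 = np.log(2.0)
    ref_cols = condition_index == 0
    test_cols = condition_index == 1
    mu_ref = norm[:, ref_cols].mean(axis=1)
    mu_test = norm[:, test_cols].mean(axis=1)
    basemean = norm.mean(axis=1)
    log2fc = np.log2(mu_test + c) - np.log2(mu_ref + c)

    inv_s = 1.0 / size_factors
    var_parts = []
    for cols, mu in ((ref_cols, mu_ref), (test_cols, mu_test)):
        m = cols.sum()
        # Var(mean of n_ij) with Var(n_ij) = mu/s_j + alpha*mu^2 (NB on raw scale)
        var_mean = (mu[:, None] * inv_s[None, cols] + alpha[:, None] * mu[:, None] ** 2).sum(
            axis=1
        ) / m**2
        var_parts.append(var_mean / ((mu + c) ** 2 * ln2**2))
    se = np.sqrt(var_parts[0] + var_parts[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    padj = adjust_bh(p) if p.size else np.array([])

    return [
        PositionTestResult(
            replicon=rep,
            position=pos,
            strand=strand,
            basemean=float(basemean[i]),
            log2fc=float(log2fc[i]),
            p=float(p[i]),
            padj=float(padj[i]),
        )
        for i, (rep, pos, strand) in enumerate(matrix.positions)
    ]


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved.

    padj_(i) = min(1, min_{j >= i} p_(j) * m / j) over the ascending sort.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    monotone = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(monotone, 1.0)
    return out


def select_and_merge(
    results: Sequence[PositionTestResult],
    cfg: FilterConfig,
) -> List[DifferentialEnd]:
    """Threshold on |log2fc| and padj, then chain-merge per (replicon, strand).

    Positions p < q belong to the same end iff q - p - 1 <= merge_distance;
    each merged end records its span, member count and arithmetic-mean
    log2fc, with direction taken from the mean's sign. Mixed-sign members
    are merged regardless of sign and flagged.
    """
    kept: Dict[Tuple[str, str], List[PositionTestResult]] = {}
    n_dropped = 0
    for r in results:
        if np.isnan(r.padj):
            n_dropped += 1
            continue
        if abs(r.log2fc) >= cfg.lfc_cutoff and r.padj <= cfg.alpha:
            kept.setdefault((r.replicon, r.strand), []).append(r)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} positions with undefined padj", RuntimeWarning)

    ends: List[DifferentialEnd] = []
    for (rep, strand), members in kept.items():
        members.sort(key=lambda r: r.position)
        run: List[PositionTestResult] = []
        for r in members:
            if run and r.position - run[-1].position - 1 > cfg.merge_distance:
                ends.append(_finish_run(rep, strand, run))
                run = []
            run.append(r)
        if run:
            ends.append(_finish_run(rep, strand, run))
    ends.sort(key=lambda e: (e.replicon, e.start, e.strand))
    return ends


def _finish_run(rep: str, strand: str, run: List[PositionTestResult]) -> DifferentialEnd:
    lfcs = [r.log2fc for r in run]
    return DifferentialEnd(
        replicon=rep,
        start=run[0].position,
        end=run[-1].position + 1,
        strand=strand,
        n_positions=len(run),
        mean_log2fc=float(np.mean(lfcs)),
        mixed_sign=(min(lfcs) < 0 < max(lfcs)),
        member_positions=tuple(r.position for r in run),
    )


def merge_ends(ends: Sequence[DifferentialEnd], merge_distance: int = 3) -> List[DifferentialEnd]:
    """Re-merge already-merged ends with the same gap rule (idempotency helper)."""
    by_key: Dict[Tuple[str, str], List[DifferentialEnd]] = {}
    for e in ends:
        by_key.setdefault((e.replicon, e.strand), []).append(e)
    merged: List[DifferentialEnd] = []
    for (rep, strand), group in by_key.items():
        group.sort(key=lambda e: e.start)
        current = group[0]
        acc = [current]
        for e in group[1:]:
            if e.start - acc[-1].end <= merge_distance:
                acc.append(e)
            else:
                merged.append(_combine(rep, strand, acc))
                acc = [e]
        merged.append(_combine(rep, strand, acc))
    merged.sort(key=lambda e: (e.replicon, e.start, e.strand))
    return merged


def _combine(rep: str, strand: str, group: List[DifferentialEnd]) -> DifferentialEnd:
    if len(group) == 1:
        return group[0]
    n = sum(e.n_positions for e in group)
    mean = sum(e.mean_log2fc * e.n_positions for e in group) / n
    members = tuple(p for e in group for p in e.member_positions)
    return DifferentialEnd(
        replicon=rep,
        start=group[0].start,
        end=group[-1].end,
        strand=strand,
        n_positions=n,
        mean_log2fc=float(mean),
        mixed_sign=any(e.mixed_sign for e in group)
        or (min(e.mean_log2fc for e in group) < 0 < max(e.mean_log2fc for e in group)),
        member_positions=members,
    )
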