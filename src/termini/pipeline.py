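"""End-to-end orchestration: alignments -> coverage -> count matrix ->
filters -> NB test -> merge -> annotation, with a machine-readable run
manifest. Outputs are deterministic: identical inputs give byte-identical
files (no timestamps, fixed float formats, sorted keys)."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np

from . import __version__
from .annotate import AnnotatedEnd, assign_features
from .coverage import build_end_count_matrix, compute_coverage
from .endcall import (
    DifferentialEnd,
    FilterConfig,
    PositionTestResult,
    estimate_size_factors,
    filter_masks,
    select_and_merge,
    test_positions,
)
from .errors import ConfigError, DesignError
from .formats import (
    SampleDesign,
    check_design,
    read_alignments,
    read_features,
    read_sam_replicon_lengths,
    write_bedgraph,
    write_ends_bed,
)

logger = logging.getLogger("termini")

PathLike = Union[str, os.PathLike]


@dataclass
class RunManifest:
    version: str
    end_kind: str
    inputs: Dict[str, str]  # path -> sha256
    config: dict
    counts: Dict[str, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


@dataclass
class PipelineResult:
    ends: List[DifferentialEnd]
    annotated: Optional[List[AnnotatedEnd]]
    results: List[PositionTestResult]
    size_factors: np.ndarray
    manifest: RunManifest


def _sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ends_to_tsv(ends: Sequence[DifferentialEnd]) -> str:
    header = (
        "replicon\tstart\tend\tstrand\tdistribution_size\tn_positions\t"
        "mean_log2fc\tdirection\tmixed_sign\tmember_positions"
    )
    lines = [header]
    for e in sorted(ends, key=lambda e: (e.replicon, e.start, e.strand)):
        members = ",".join(str(p) for p in e.member_positions)
        lines.append(
            f"{e.replicon}\t{e.start}\t{e.end}\t{e.strand}\t{e.distribution_size}\t"
            f"{e.n_positions}\t{e.mean_log2fc:.6f}\t{e.direction}\t"
            f"{int(e.mixed_sign)}\t{members}"
        )
    return "".join(line + "\n" for line in lines)


def read_ends_tsv(path: PathLike) -> List[DifferentialEnd]:
    ends = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            members = tuple(
                int(p) for p in cols[idx["member_positions"]].split(",") if p
            )
            ends.append(
                DifferentialEnd(
                    replicon=cols[idx["replicon"]],
                    start=int(cols[idx["start"]]),
                    end=int(cols[idx["end"]]),
                    strand=cols[idx["strand"]],
                    n_positions=int(cols[idx["n_positions"]]),
                    mean_log2fc=float(cols[idx["mean_log2fc"]]),
                    mixed_sign=bool(int(cols[idx["mixed_sign"]])),
                    member_positions=members,
                )
            )
    return ends


def positions_to_tsv(results: Sequence[PositionTestResult]) -> str:
    lines = ["replicon\tposition\tstrand\tbasemean\tlog2fc\tp\tpadj"]
    for r in results:
        lines.append(
            f"{r.replicon}\t{r.position}\t{r.strand}\t{r.basemean:.6f}\t"
            f"{r.log2fc:.6f}\t{r.p:.6g}\t{r.padj:.6g}"
        )
    return "".join(line + "\n" for line in lines)


def annotated_to_tsv(annotated: Sequence[AnnotatedEnd]) -> str:
    header = (
        "replicon\tstart\tend\tstrand\tdistribution_size\tmean_log2fc\t"
        "direction\tassigned_class\tfeature_ids"
    )
    lines = [header]
    for a in annotated:
        e = a.end
        fids = ",".join(f.feature_id for f in a.assigned_features)
        lines.append(
            f"{e.replicon}\t{e.start}\t{e.end}\t{e.strand}\t{e.distribution_size}\t"
            f"{e.mean_log2fc:.6f}\t{e.direction}\t{a.assigned_class}\t{fids}"
        )
    return "".join(line + "\n" for line in lines)


def run_end_pipeline(
    sam_paths: Mapping[str, PathLike],
    design: Sequence[SampleDesign],
    gff3_path: Optional[PathLike] = None,
    fasta_path: Optional[PathLike] = None,
    cfg: Optional[FilterConfig] = None,
    end_kind: str = "end3",
    outdir: Optional[PathLike] = None,
    dispersion: str = "common",
    write_coverage: bool = False,
    threads: int = 1,
) -> PipelineResult:
    """Run the full differential-end chain and optionally write outputs.

    ``end_kind`` selects 3' or 5' terminus analysis. ``threads`` is accepted
    for interface stability; all stages are deterministic regardless of its
    value. Replicon lengths are taken from the SAM headers.
    """
    if cfg is None:
        cfg = FilterConfig()
    if end_kind not in ("end3", "end5"):
        raise ConfigError(f"end_kind must be 'end3' or 'end5', got {end_kind!r}")
    check_design(design)
    missing = [d.library_id for d in design if d.library_id not in sam_paths]
    if missing:
        raise DesignError(f"no SAM path for libraries: {missing}")
    ordered_libs = [d.library_id for d in design]

    replicon_lengths = read_sam_replicon_lengths(sam_paths[ordered_libs[0]])
    end_tracks: Dict[str, list] = {}
    full_tracks: Dict[str, list] = {}
    for lib in ordered_libs:
        logger.info("[coverage] library %s", lib)
        lengths = read_sam_replicon_lengths(sam_paths[lib])
        if lengths != replicon_lengths:
            raise ConfigError(f"library {lib!r}: SAM header replicons differ")
        alignments = read_alignments(sam_paths[lib])
        end_tracks[lib] = compute_coverage(alignments, replicon_lengths, kind=end_kind)
        full_tracks[lib] = compute_coverage(alignments, replicon_lengths, kind="full")

    logger.info("[matrix] building end-count matrix")
    matrix = build_end_count_matrix(end_tracks)
    count_mask, joint_mask = filter_masks(matrix, full_tracks, cfg)
    filtered = matrix.subset(joint_mask)
    logger.info(
        "[filter] %d positions -> %d after count filter -> %d after ratio filter",
        matrix.n_positions,
        int(count_mask.sum()),
        filtered.n_positions,
    )

    if filtered.n_positions:
        factors = estimate_size_factors(filtered)
        results = test_positions(filtered, design, size_factors=factors, dispersion=dispersion)
    else:
        factors = np.ones(len(ordered_libs))
        results = []
    ends = select_and_merge(results, cfg)
    n_significant = sum(
        1
        for r in results
        if abs(r.log2fc) >= cfg.lfc_cutoff and r.padj <= cfg.alpha and not np.isnan(r.padj)
    )
    logger.info("[call] %d significant positions -> %d merged ends", n_significant, len(ends))

    annotated = None
    if gff3_path is not None:
        features = read_features(gff3_path)
        annotated = assign_features(ends, features, known_replicons=replicon_lengths)

    inputs = {str(p): _sha256(p) for p in sorted({str(v) for v in sam_paths.values()})}
    for extra in (gff3_path, fasta_path):
        if extra is not None:
            inputs[str(extra)] = _sha256(extra)
    manifest = RunManifest(
        version=__version__,
        end_kind=end_kind,
        inputs=inputs,
        config={
            "min_end_count": cfg.min_end_count,
            "min_ratio": cfg.min_ratio,
            "lfc_cutoff": cfg.lfc_cutoff,
            "alpha": cfg.alpha,
            "merge_distance": cfg.merge_distance,
            "dispersion": dispersion,
        },
        counts={
            "positions_in": matrix.n_positions,
            "after_count_filter": int(count_mask.sum()),
            "after_ratio_filter": filtered.n_positions,
            "significant_positions": n_significant,
            "merged_ends": len(ends),
        },
    )

    if outdir is not None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        _write_text(os.path.join(outdir, "ends.bed"), write_ends_bed(ends))
        _write_text(os.path.join(outdir, "ends.tsv"), ends_to_tsv(ends))
        _write_text(os.path.join(outdir, "positions.tsv"), positions_to_tsv(results))
        if annotated is not None:
            _write_text(os.path.join(outdir, "annotated.tsv"), annotated_to_tsv(annotated))
        _write_text(os.path.join(outdir, "manifest.json"), manifest.to_json())
        if write_coverage:
            for lib in ordered_libs:
                for track in end_tracks[lib] + full_tracks[lib]:
                    name = f"{lib}.{track.strand}.{track.kind}.bedgraph"
                    _write_text(
                        os.path.join(outdir, name.replace("+", "plus").replace("-", "minus")),
                        write_bedgraph(track.values, track.replicon),
                    )

    return PipelineResult(
        ends=ends,
        annotated=annotated,
        results=results,
        size_factors=np.asarray(factors),
        manifest=manifest,
    )


def _write_text(path: str, text: str) -> None:
    with open(path, "w") as fh:
        fh.write(text)
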