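"""Self-contained synthetic datasets: genome, annotation, per-library
strand-specific single-end alignments with planted read-terminus pileups,
and a truth table for recovery scoring.

Counts at planted ends are negative-binomial (gamma-Poisson) with a
condition-specific log2 effect; a configurable fraction of reads carries an
untemplated G-rich 3' tail emitted as a soft clip with a consistent CIGAR.
Reads are emitted as already-aligned SAM so the whole pipeline is testable
without a mapper.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .formats import SampleDesign, revcomp

END_KINDS = ("termination", "cleavage", "exo_stall")


@dataclass(frozen=True)
class PlantedEnd:
    """A ground-truth read-terminus pileup position."""

    replicon: str
    position: int  # 0-based 3'-terminal aligned base
    strand: str
    kind: str = "cleavage"
    base_mean: float = 100.0
    log2_effect: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self):
        if self.base_mean <= 0:
            raise ConfigError(f"planted end at {self.position}: base_mean must be > 0")
        if self.kind not in END_KINDS:
            raise ConfigError(f"planted end at {self.position}: unknown kind {self.kind!r}")


@dataclass
class SimConfig:
    replicons: Dict[str, int] = field(default_factory=lambda: {"chr": 100_000})
    n_replicates: int = 3
    read_length: int = 75
    depths: Union[float, Dict[str, float]] = 1.0
    dispersion: float = 0.05
    ends: List[PlantedEnd] = field(default_factory=list)
    background_reads: int = 0
    tail_fraction: float = 0.0
    tail_g_fraction: float = 0.7
    tail_length_mean: float = 8.0
    max_tail_length: int = 40
    n_features: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 20:
            raise ConfigError("read_length must be >= 20")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        for e in self.ends:
            if e.replicon not in self.replicons:
                raise ConfigError(f"planted end on unknown replicon {e.replicon!r}")
            if not 0 <= e.position < self.replicons[e.replicon]:
                raise ConfigError(
                    f"planted end position {e.position} outside replicon {e.replicon!r}"
                )

    def library_ids(self) -> List[str]:
        return [
            f"{cond}_{i}"
            for cond in ("reference", "test")
            for i in range(1, self.n_replicates + 1)
        ]

    def depth_of(self, library_id: str) -> float:
        if isinstance(self.depths, Mapping):
            return float(self.depths.get(library_id, 1.0))
        return float(self.depths)


@dataclass
class SimulatedDataset:
    genome: Dict[str, str]
    gff3: str
    sams: Dict[str, str]  # library_id -> SAM text
    truth: pd.DataFrame
    design: List[SampleDesign]
    planted_read_counts: Dict[str, int]  # per library, excluding background
    background_read_counts: Dict[str, int]

    def write(self, outdir: Union[str, os.PathLike]) -> Dict[str, str]:
        """Write FASTA/GFF3/SAM/TSV files; returns the path map."""
        from .formats import write_fasta

        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        fasta = os.path.join(outdir, "genome.fasta")
        write_fasta(self.genome, fasta)
        paths["fasta"] = fasta
        gff = os.path.join(outdir, "annotation.gff3")
        with open(gff, "w") as fh:
            fh.write(self.gff3)
        paths["gff3"] = gff
        for lib, text in self.sams.items():
            sam = os.path.join(outdir, f"{lib}.sam")
            with open(sam, "w") as fh:
                fh.write(text)
            paths[lib] = sam
        truth = os.path.join(outdir, "truth.tsv")
        self.truth.to_csv(truth, sep="\t", index=False)
        paths["truth"] = truth
        design = os.path.join(outdir, "design.tsv")
        with open(design, "w") as fh:
            fh.write("library_id\tcondition\treplicate\tsam\n")
            for d in self.design:
                fh.write(
                    f"{d.library_id}\t{d.condition}\t{d.replicate_index}\t"
                    f"{os.path.join(outdir, d.library_id + '.sam')}\n"
                )
        paths["design"] = design
        return paths


def _sample_nb(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Gamma-Poisson draw with Var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return int(rng.poisson(lam))


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _auto_features(cfg: SimConfig) -> str:
    """Non-overlapping features tiled over each replicon, GFF3 text."""
    class_cycle = ["CDS", "CDS", "CDS", "tRNA", "ncRNA", "CDS", "rRNA", "CDS"]
    lines = ["##gff-version 3"]
    idx = 0
    for rep, length in cfg.replicons.items():
        span = max(length // max(cfg.n_features, 1), 300)
        pos = 50
        while pos + 200 < length and idx < cfg.n_features * len(cfg.replicons):
            ftype = class_cycle[idx % len(class_cycle)]
            strand = "+" if idx % 2 == 0 else "-"
            end1 = min(pos + span - 100, length)
            lines.append(
                f"{rep}\tsim\t{ftype}\t{pos + 1}\t{end1}\t.\t{strand}\t.\tID=gene_{idx + 1}"
            )
            pos += span
            idx += 1
    return "".join(line + "\n" for line in lines) if len(lines) > 1 else lines[0] + "\n"


def _sam_header(replicons: Mapping[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for rep, length in replicons.items():
        lines.append(f"@SQ\tSN:{rep}\tLN:{length}")
    return "".join(line + "\n" for line in lines)


def _emit_read(
    genome: Mapping[str, str],
    read_id: str,
    replicon: str,
    terminal_pos: int,
    strand: str,
    read_length: int,
    tail: str,
) -> Optional[str]:
    """One SAM line whose 3'-terminal aligned base is ``terminal_pos``.

    The tail (possibly empty) is appended to the read's 3' end as a soft
    clip; the aligned block shrinks so the total read length is constant.
    Returns None when the read would overhang the replicon.
    """
    seq = genome[replicon]
    aligned_len = read_length - len(tail)
    if aligned_len < 1:
        return None
    if strand == "+":
        start = terminal_pos - aligned_len + 1
        if start < 0 or terminal_pos >= len(seq):
            return None
        ref_block = seq[start : terminal_pos + 1]
        sam_seq = ref_block + tail
        cigar = f"{aligned_len}M" + (f"{len(tail)}S" if tail else "")
        flag = 0
        pos1 = start + 1
    else:
        end = terminal_pos + aligned_len
        if terminal_pos < 0 or end > len(seq):
            return None
        ref_block = seq[terminal_pos:end]
        sam_seq = revcomp(tail) + ref_block if tail else ref_block
        cigar = (f"{len(tail)}S" if tail else "") + f"{aligned_len}M"
        flag = 16
        pos1 = terminal_pos + 1
    qual = "I" * len(sam_seq)
    return (
        f"{read_id}\t{flag}\t{replicon}\t{pos1}\t60\t{cigar}\t*\t0\t0\t"
        f"{sam_seq}\t{qual}\tNH:i:1"
    )


def _draw_tail(rng: np.random.Generator, cfg: SimConfig) -> str:
    length = int(min(rng.geometric(1.0 / cfg.tail_length_mean), cfg.max_tail_length))
    bases = []
    for _ in range(length):
        if rng.random() < cfg.tail_g_fraction:
            bases.append("G")
        else:
            bases.append("ACT"[rng.integers(0, 3)])
    return "".join(bases)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Deterministic synthetic dataset for the given configuration.

    The seed drives one root generator for the genome and per-library
    substreams derived from (seed, library index), so outputs are
    byte-identical across runs and stable under per-library parallelism.
    """
    genome_rng = np.random.default_rng([cfg.seed, 0xBEEF])
    genome = {rep: _random_genome(genome_rng, n) for rep, n in cfg.replicons.items()}
    gff3 = _auto_features(cfg)

    design = [
        SampleDesign(library_id=lib, condition=lib.rsplit("_", 1)[0], replicate_index=int(lib.rsplit("_", 1)[1]))
        for lib in cfg.library_ids()
    ]
    sams: Dict[str, str] = {}
    planted_counts: Dict[str, int] = {}
    background_counts: Dict[str, int] = {}

    for lib_index, d in enumerate(design):
        rng = np.random.default_rng([cfg.seed, 1 + lib_index])
        depth = cfg.depth_of(d.library_id)
        lines: List[str] = []
        n_read = 0
        for end_index, end in enumerate(cfg.ends):
            mean = depth * end.base_mean
            if d.condition == "test":
                mean *= 2.0**end.log2_effect
            k = _sample_nb(rng, mean, cfg.dispersion)
            for _ in range(k):
                terminal = end.position
                if end.jitter_sd > 0:
                    terminal += int(round(rng.normal(0.0, end.jitter_sd)))
                tail = _draw_tail(rng, cfg) if rng.random() < cfg.tail_fraction else ""
                n_read += 1
                line = _emit_read(
                    genome,
                    f"{d.library_id}.e{end_index}.r{n_read}",
                    end.replicon,
                    terminal,
                    end.strand,
                    cfg.read_length,
                    tail,
                )
                if line is None:
                    n_read -= 1
                    continue
                lines.append(line)
        planted_counts[d.library_id] = len(lines)
        reps = list(cfg.replicons.items())
        n_bg = 0
        for b in range(cfg.background_reads):
            rep, length = reps[int(rng.integers(0, len(reps)))]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                terminal = int(rng.integers(cfg.read_length - 1, length))
            else:
                terminal = int(rng.integers(0, length - cfg.read_length + 1))
            line = _emit_read(
                genome,
                f"{d.library_id}.bg{b}",
                rep,
                terminal,
                strand,
                cfg.read_length,
                "",
            )
            if line is not None:
                lines.append(line)
                n_bg += 1
        background_counts[d.library_id] = n_bg
        sams[d.library_id] = _sam_header(cfg.replicons) + "".join(l + "\n" for l in lines)

    truth = pd.DataFrame(
        [
            {
                "replicon": e.replicon,
                "position": e.position,
                "strand": e.strand,
                "kind": e.kind,
                "base_mean": e.base_mean,
                "log2_effect": e.log2_effect,
            }
            for e in cfg.ends
        ],
        columns=["replicon", "position", "strand", "kind", "base_mean", "log2_effect"],
    )
    return SimulatedDataset(
        genome=genome,
        gff3=gff3,
        sams=sams,
        truth=truth,
        design=design,
        planted_read_counts=planted_counts,
        background_read_counts=background_counts,
    )


@dataclass
class RecoveryScore:
    sensitivity: float
    precision: float
    sign_accuracy: float
    n_called: int
    n_truth: int
    zero_called: bool = False


def score_recovery(
    called: Sequence,
    truth: Union[pd.DataFrame, Sequence[PlantedEnd]],
    tolerance: int = 3,
) -> RecoveryScore:
    """Match called ends to ground truth within a positional tolerance.

    A truth end is recovered when a same-strand called end lies within
    ``tolerance`` nt and carries a matching effect sign. Each called end is
    assigned to at most one truth end (nearest; leftmost truth position on
    ties). Sensitivity is over truth ends with nonzero effect; precision is
    the fraction of called ends matching such a truth end. With nothing
    called, precision is reported as 1.0 with ``zero_called`` set.
    """
    if tolerance < 0:
        raise InputError(f"tolerance must be >= 0, got {tolerance}")
    if isinstance(truth, pd.DataFrame):
        rows = truth.to_dict("records")
    else:
        rows = [
            {
                "replicon": e.replicon,
                "position": e.position,
                "strand": e.strand,
                "log2_effect": e.log2_effect,
            }
            for e in truth
        ]
    nonzero = [r for r in rows if r["log2_effect"] != 0]
    if not called:
        return RecoveryScore(
            sensitivity=0.0 if nonzero else 1.0,
            precision=1.0,
            sign_accuracy=1.0,
            n_called=0,
            n_truth=len(nonzero),
            zero_called=True,
        )

    recovered = set()
    n_match_position = 0
    n_match_sign = 0
    for e in called:
        candidates = []
        for i, r in enumerate(nonzero):
            if r["replicon"] != e.replicon or r["strand"] != e.strand:
                continue
            p = r["position"]
            if e.start <= p < e.end:
                dist = 0
            elif p < e.start:
                dist = e.start - p
            else:
                dist = p - (e.end - 1)
            if dist <= tolerance:
                candidates.append((dist, p, i))
        if not candidates:
            continue
        candidates.sort()
        _, _, i = candidates[0]
        n_match_position += 1
        if math.copysign(1, nonzero[i]["log2_effect"]) == math.copysign(1, e.mean_log2fc):
            n_match_sign += 1
            recovered.add(i)
    sensitivity = len(recovered) / len(nonzero) if nonzero else 1.0
    precision = n_match_sign / len(called)
    sign_accuracy = n_match_sign / n_match_position if n_match_position else 1.0
    return RecoveryScore(
        sensitivity=sensitivity,
        precision=precision,
        sign_accuracy=sign_accuracy,
        n_called=len(called),
        n_truth=len(nonzero),
    )
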