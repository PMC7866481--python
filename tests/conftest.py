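import numpy as np
import pytest

from termini.formats import SampleDesign


def sam_text(records, replicons=None):
    """Build SAM text from (qname, flag, rname, pos1, mapq, cigar, seq) tuples."""
    if replicons is None:
        replicons = {"chr1": 100_000}
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for rep, length in replicons.items():
        lines.append(f"@SQ\tSN:{rep}\tLN:{length}")
    for rec in records:
        qname, flag, rname, pos1, mapq, cigar, seq = rec[:7]
        tags = "\t" + "\t".join(rec[7:]) if len(rec) > 7 else ""
        qual = "I" * len(seq) if seq != "*" else "*"
        lines.append(
            f"{qname}\t{flag}\t{rname}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}{tags}"
        )
    return "".join(line + "\n" for line in lines)


@pytest.fixture
def write_sam(tmp_path):
    def _write(records, replicons=None, name="test.sam"):
        path = tmp_path / name
        path.write_text(sam_text(records, replicons))
        return path

    return _write


@pytest.fixture
def design_3v3():
    return [
        SampleDesign(f"{cond}_{i}", cond, i)
        for cond in ("reference", "test")
        for i in (1, 2, 3)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
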