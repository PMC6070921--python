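"""Read container and FASTQ I/O.

Reads are simulated and analysed in memory as plain (id, sequence) records;
FASTQ is the on-disk interchange format.  Parsing goes through
pysam.FastxFile; writing emits constant-quality records (the simulators do
not model quality scores beyond a constant Q).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pysam

CONSTANT_QUAL_CHAR = "I"  # Q40


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(
                f"@{read.id}\n{read.sequence}\n+\n"
                f"{CONSTANT_QUAL_CHAR * len(read.sequence)}\n"
            )


def read_fastq(path: str | Path) -> list[Read]:
    out = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            out.append(Read(entry.name, entry.sequence.upper()))
    return out


def sequences(reads) -> list[str]:
    return [r.sequence for r in reads]
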