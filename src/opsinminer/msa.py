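"""Multiple sequence alignment via MAFFT.

Thin subprocess wrapper; sequences go in and come back in input order as
equal-length gapped strings keyed by record id.  MAFFT is deterministic
for a fixed input, so downstream placement and substitution calls are
reproducible.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .seq import SequenceRecord


def align_msa(records: list[SequenceRecord]) -> dict[str, str]:
    """Align amino-acid records with MAFFT; return id -> gapped row.

    Ids are replaced by positional tags for the subprocess call so that
    arbitrary identifiers survive untouched.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences to align")
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        with open(infile, "w") as fh:
            for i, rec in enumerate(records):
                fh.write(f">s{i}\n{rec.seq}\n")
        proc = subprocess.run(
            ["mafft", "--auto", "--amino", "--quiet", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
    rows: dict[str, str] = {}
    tag = None
    chunks: list[str] = []
    order: list[str] = []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if tag is not None:
                rows[tag] = "".join(chunks)
            tag = line[1:].strip()
            order.append(tag)
            chunks = []
        else:
            chunks.append(line.strip())
    if tag is not None:
        rows[tag] = "".join(chunks)
    if len(rows) != len(records):
        raise RuntimeError("MAFFT returned an unexpected number of sequences")
    return {rec.id: rows[f"s{i}"].upper() for i, rec in enumerate(records)}
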