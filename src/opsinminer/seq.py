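"""Sequence records, FASTA I/O, pairwise alignment and bovine-rhodopsin numbering.

All residue positions in this package are 1-based.  Positions of opsin
residues are reported in *bovine numbering*: the position of the aligned
residue in bovine rhodopsin (UniProt P02699, 348 aa), the community
standard for opsins.  The retinal-binding lysine is bovine position 296.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from Bio import Align
from Bio.Align import substitution_matrices

AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_AMBIG = frozenset("X")
NT_LETTERS = frozenset("ACGT")
NT_AMBIG = frozenset("N")

CLASS_LABELS = frozenset({"LWS", "MWS", "SWS_UV", "NONOPSIN", "UNKNOWN"})
GROUP_LABELS = frozenset({"BAIKAL_LWS", "EUROPEAN_LWS", "EUROPEAN_MWS", "OTHER"})

#: Bovine-numbered sites implicated in invertebrate spectral tuning.
TUNING_SITES = frozenset({90, 109, 115, 123})

#: Bovine-numbered position of the retinal-binding (Schiff-base) lysine.
K296 = 296


class _Unaligned:
    """Sentinel for a reference position that falls in an alignment gap."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNALIGNED"

    def __bool__(self):
        return False


UNALIGNED = _Unaligned()


@dataclasses.dataclass
class SequenceRecord:
    """A named, ungapped amino-acid or nucleotide sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    seq : str
        Residues; uppercase letters of the declared alphabet plus the
        ambiguity code (``X`` for amino acids, ``N`` for nucleotides).
    alphabet : {"aa", "nt"}
    species, class_label, group : str, optional
        Annotations carried through the pipeline.  ``class_label`` is one
        of LWS / MWS / SWS_UV / NONOPSIN / UNKNOWN; ``group`` is the
        contrast group used in substitution profiling.
    """

    id: str
    seq: str
    alphabet: Literal["aa", "nt"] = "aa"
    species: str | None = None
    class_label: str | None = None
    group: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.seq = self.seq.upper()
        if self.alphabet == "aa":
            allowed = AA_LETTERS | AA_AMBIG
        elif self.alphabet == "nt":
            allowed = NT_LETTERS | NT_AMBIG
        else:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        for i, ch in enumerate(self.seq):
            if ch not in allowed:
                raise ValueError(
                    f"illegal {self.alphabet} residue {ch!r} at position "
                    f"{i + 1} of sequence {self.id!r}"
                )
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.group is not None and self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group {self.group!r}")

    def __len__(self):
        return len(self.seq)


def _parse_header(header: str) -> dict:
    """Parse ``id key=value key=value`` FASTA headers."""
    parts = header.split()
    fields = {"id": parts[0]}
    for token in parts[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            if key in ("class", "species", "group"):
                fields["class_label" if key == "class" else key] = value
    return fields


def read_fasta(path: str | Path, alphabet: Literal["aa", "nt"]) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Header annotations of the form ``key=value`` (keys ``class``,
    ``species``, ``group``) are parsed into record fields.  Raises on an
    empty file, duplicate ids, or illegal residue characters.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        fields = _parse_header(header)
        if fields["id"] in seen:
            raise ValueError(f"duplicate sequence id {fields['id']!r} in {path}")
        seen.add(fields["id"])
        records.append(SequenceRecord(seq="".join(chunks), alphabet=alphabet, **fields))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with ``id key=value`` headers (lossless round-trip)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.class_label is not None:
                header += f" class={rec.class_label}"
            if rec.species is not None:
                header += f" species={rec.species}"
            if rec.group is not None:
                header += f" group={rec.group}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def bovine_rhodopsin() -> SequenceRecord:
    """The packaged bovine rhodopsin reference (UniProt P02699, 348 aa)."""
    ref = resources.files("opsinminer.data") / "bovine_rhodopsin.fasta"
    with resources.as_file(ref) as path:
        return read_fasta(path, "aa")[0]


@dataclasses.dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring for amino-acid alignments.

    Defaults are BLOSUM62 with gap open 11 / extend 1, the de facto
    protein-search standard.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def make_aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        aligner.mode = mode
        return aligner


DEFAULT_PARAMS = AlignmentParams()


@dataclasses.dataclass
class PairwiseAlignment:
    """A pairwise alignment as two equal-length gapped strings."""

    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    score: float
    mode: Literal["global", "local"] = "global"

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings must have equal length")

    def columns(self):
        return zip(self.aligned_query, self.aligned_ref)


def _check_aa(rec: SequenceRecord):
    if rec.alphabet != "aa":
        raise ValueError(f"sequence {rec.id!r} is not amino-acid")


def global_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignmentParams = DEFAULT_PARAMS
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment of two proteins.

    Deterministic: among co-optimal alignments the aligner's first
    traceback is returned.
    """
    _check_aa(a)
    _check_aa(b)
    aligner = params.make_aligner("global")
    aln = aligner.align(a.seq, b.seq)[0]
    return PairwiseAlignment(
        query_id=a.id,
        ref_id=b.id,
        aligned_query=str(aln[0]),
        aligned_ref=str(aln[1]),
        score=float(aln.score),
        mode="global",
    )


def local_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignmentParams = DEFAULT_PARAMS
) -> PairwiseAlignment:
    """Optimal local (Smith-Waterman, affine-gap) alignment of two proteins."""
    _check_aa(a)
    _check_aa(b)
    aligner = params.make_aligner("local")
    aln = aligner.align(a.seq, b.seq)[0]
    return PairwiseAlignment(
        query_id=a.id,
        ref_id=b.id,
        aligned_query=str(aln[0]),
        aligned_ref=str(aln[1]),
        score=float(aln.score),
        mode="local",
    )


def percent_identity(
    aln: PairwiseAlignment,
    denominator: Literal["shorter_seq", "alignment_cols"] = "shorter_seq",
) -> float:
    """Fraction of identical residue columns in a pairwise alignment.

    ``X`` never counts as identical.  The denominator is either the
    ungapped length of the shorter sequence (cd-hit convention) or the
    number of alignment columns.
    """
    n_ident = sum(
        1
        for qa, ra in aln.columns()
        if qa == ra and qa != "-" and qa != "X"
    )
    if denominator == "shorter_seq":
        denom = min(
            len(aln.aligned_query.replace("-", "")),
            len(aln.aligned_ref.replace("-", "")),
        )
    elif denominator == "alignment_cols":
        denom = len(aln.aligned_query)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero-length denominator")
    return n_ident / denom


@dataclasses.dataclass
class PositionMap:
    """Correspondence between reference (bovine) numbering and query positions.

    ``mapping`` holds, for each 1-based reference position aligned to a
    query residue, the 1-based query position.  Reference positions that
    fall in alignment gaps are absent and resolve to :data:`UNALIGNED`.
    """

    ref_id: str
    ref_length: int
    mapping: dict[int, int]

    def get(self, ref_pos: int):
        if not 1 <= ref_pos <= self.ref_length:
            raise ValueError(
                f"reference position {ref_pos} outside [1, {self.ref_length}]"
            )
        return self.mapping.get(ref_pos, UNALIGNED)


def map_to_reference(
    query: SequenceRecord,
    reference: SequenceRecord,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> PositionMap:
    """Globally align ``query`` to the numbering reference and build a PositionMap."""
    aln = global_align(query, reference, params)
    mapping: dict[int, int] = {}
    q_pos = 0
    r_pos = 0
    for qa, ra in aln.columns():
        if qa != "-":
            q_pos += 1
        if ra != "-":
            r_pos += 1
            if qa != "-":
                mapping[r_pos] = q_pos
    return PositionMap(ref_id=reference.id, ref_length=len(reference), mapping=mapping)


def residue_at(query: SequenceRecord, pmap: PositionMap, ref_pos: int):
    """Query residue at the site homologous to ``ref_pos``, or UNALIGNED."""
    q_pos = pmap.get(ref_pos)
    if q_pos is UNALIGNED:
        return UNALIGNED
    return query.seq[q_pos - 1]
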