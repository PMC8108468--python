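"""Opsin mining in transcriptome assemblies.

The pipeline turns nucleotide contigs into a per-species inventory of
distinct visual opsin transcripts:

1. six-frame ORF extraction (maximal ATG-to-stop, both strands);
2. homology prescreen against a class-labelled opsin reference database
   (Smith-Waterman, Karlin-Altschul E-value);
3. the Schiff-base check: the candidate must carry a lysine at the site
   homologous to bovine rhodopsin Lys296, which separates true opsins
   from related GPCRs (octopamine / adrenergic receptors score well in
   homology searches but lack this lysine);
4. a length filter (Met start and length >= mean reference length);
5. class assignment (LWS / MWS / SWS_UV) by neighbour-joining placement
   among the reference sequences — nearest leaf by patristic distance;
6. greedy identity clustering within each species so that >95%-identical
   transcripts (e.g. assembler isoforms, or the same transcript from
   several assemblies of one species) are reported once.

Every stage is individually switchable.  Rejected candidates are kept in
an audit list with the reason, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq
from skbio import DistanceMatrix
from skbio.tree import nj

from .msa import align_msa
from .seq import (
    DEFAULT_PARAMS,
    K296,
    UNALIGNED,
    AlignmentParams,
    SequenceRecord,
    bovine_rhodopsin,
    global_align,
    local_align,
    map_to_reference,
    percent_identity,
    residue_at,
    write_fasta,
)

logger = logging.getLogger("opsinminer")

# Karlin-Altschul parameters for gapped BLOSUM62 with gap open 11 / extend 1
# (the standard values used by protein search tools for this scoring).
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclasses.dataclass
class OrfCandidate:
    """An open reading frame extracted from a contig.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on the
    *forward* strand of the contig, covering exactly the codons of
    ``peptide`` (the stop codon is excluded).  ``frame`` is +1/+2/+3 on
    the forward strand, -1/-2/-3 on the reverse complement.  ``truncated``
    marks ORFs that run off the contig edge without an in-frame stop.
    """

    contig_id: str
    frame: int
    start: int
    end: int
    peptide: str
    starts_with_met: bool
    truncated: bool = False

    @property
    def id(self) -> str:
        sign = "+" if self.frame > 0 else ""
        return f"{self.contig_id}|{sign}{self.frame}|{self.start}-{self.end}"

    def extract_cds(self, contig: SequenceRecord) -> str:
        """Nucleotides of this ORF in reading orientation (for verification)."""
        sub = contig.seq[self.start - 1 : self.end]
        if self.frame < 0:
            sub = str(Seq(sub).reverse_complement())
        return sub


@dataclasses.dataclass
class ReferenceDB:
    """Class-labelled amino-acid opsin database used for prescreen and placement."""

    records: list[SequenceRecord]

    def __post_init__(self):
        if not self.records:
            raise ValueError("reference database is empty")
        for rec in self.records:
            if rec.class_label not in {"LWS", "MWS", "SWS_UV"}:
                raise ValueError(
                    f"reference record {rec.id!r} lacks a valid opsin class label"
                )

    @property
    def mean_length(self) -> float:
        return sum(len(r) for r in self.records) / len(self.records)

    @property
    def classes(self) -> set[str]:
        return {r.class_label for r in self.records}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDB":
        from .seq import read_fasta

        return cls(read_fasta(path, "aa"))


@dataclasses.dataclass
class BestHit:
    ref_id: str
    score: float
    evalue: float


@dataclasses.dataclass
class OpsinCall:
    """A candidate transcript with its filter verdicts and class assignment."""

    candidate: OrfCandidate
    species: str
    best_db_hit: BestHit | None = None
    class_assigned: str | None = None  # LWS / MWS / SWS_UV / REJECTED
    k296_ok: bool | None = None
    k296_query_pos: int | None = None
    length_ok: bool | None = None
    cluster_id: int | None = None
    is_representative: bool = False
    reject_reason: str | None = None

    @property
    def peptide(self) -> str:
        return self.candidate.peptide

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(
            id=self.candidate.id,
            seq=self.peptide,
            alphabet="aa",
            species=self.species,
            class_label=self.class_assigned
            if self.class_assigned in {"LWS", "MWS", "SWS_UV"}
            else None,
        )


# ---------------------------------------------------------------------------
# Stage 1: ORF extraction


def _scan_frame(protein: str, offset: int, n_codons: int, has_tail_stop_info: list[bool],
                min_aa_len: int):
    """Yield (codon_start, peptide, truncated) for maximal M..stop ORFs in one frame."""
    segments = []
    seg_start = 0
    for i, ch in enumerate(protein):
        if ch == "*":
            segments.append((seg_start, i, False))
            seg_start = i + 1
    if seg_start < len(protein):
        segments.append((seg_start, len(protein), True))  # no in-frame stop
    for seg_start, seg_end, truncated in segments:
        seg = protein[seg_start:seg_end]
        m = seg.find("M")
        if m < 0:
            continue
        peptide = seg[m:]
        if len(peptide) >= min_aa_len:
            yield seg_start + m, peptide, truncated


def find_orfs(contig: SequenceRecord, min_aa_len: int = 100) -> list[OrfCandidate]:
    """All maximal ATG-to-stop ORFs of length >= ``min_aa_len`` in six frames.

    "Maximal" means starting at the first ATG after the previous in-frame
    stop.  ORFs reaching the contig edge without a stop are reported with
    ``truncated=True``.  Coordinates are always on the forward strand.
    """
    if contig.alphabet != "nt":
        raise ValueError("find_orfs requires a nucleotide sequence")
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")
    n = len(contig.seq)
    if n < 3:
        return []
    orfs: list[OrfCandidate] = []
    fwd = contig.seq
    rev = str(Seq(fwd).reverse_complement())
    for strand, seqstr in ((1, fwd), (-1, rev)):
        for offset in range(3):
            n_codons = (len(seqstr) - offset) // 3
            if n_codons == 0:
                continue
            coding = seqstr[offset : offset + 3 * n_codons]
            protein = str(Seq(coding).translate())
            for codon_start, peptide, truncated in _scan_frame(
                protein, offset, n_codons, [], min_aa_len
            ):
                # coordinates on the scanned strand, 1-based
                s = offset + 3 * codon_start + 1
                e = s + 3 * len(peptide) - 1
                if strand == 1:
                    start, end = s, e
                else:
                    start, end = n - e + 1, n - s + 1
                orfs.append(
                    OrfCandidate(
                        contig_id=contig.id,
                        frame=strand * (offset + 1),
                        start=start,
                        end=end,
                        peptide=peptide,
                        starts_with_met=True,
                        truncated=truncated,
                    )
                )
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


# ---------------------------------------------------------------------------
# Stage 2: homology prescreen


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """E-value of a local-alignment score for query length m, subject length n."""
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def prescreen(
    candidates: Sequence[OrfCandidate],
    db: ReferenceDB,
    evalue: float = 1e-5,
    min_score: float | None = None,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[tuple[OrfCandidate, BestHit]]:
    """Retain candidates with a significant local-alignment hit in the database.

    The default threshold is a Karlin-Altschul E-value <= ``evalue``
    against the best-scoring database record; pass ``min_score`` to use a
    raw-score cut-off instead.
    """
    retained: list[tuple[OrfCandidate, BestHit]] = []
    for cand in candidates:
        query = SequenceRecord(id="q", seq=cand.peptide, alphabet="aa")
        best: BestHit | None = None
        for ref in db.records:
            aln = local_align(query, ref, params)
            if best is None or aln.score > best.score:
                best = BestHit(
                    ref_id=ref.id,
                    score=aln.score,
                    evalue=karlin_altschul_evalue(
                        aln.score, len(cand.peptide), len(ref)
                    ),
                )
        assert best is not None
        keep = (best.score >= min_score) if min_score is not None else (
            best.evalue <= evalue
        )
        if keep:
            retained.append((cand, best))
    return retained


# ---------------------------------------------------------------------------
# Stage 3: the Schiff-base lysine check


def check_k296(
    candidate_peptide: SequenceRecord,
    bovine: SequenceRecord | None = None,
    params: AlignmentParams = DEFAULT_PARAMS,
):
    """True iff the candidate carries K at the site homologous to bovine Lys296.

    Returns ``(flag, mapped_query_position_or_UNALIGNED)``.  An unaligned
    site (the alignment puts a gap under position 296) fails the check.
    """
    if bovine is None:
        bovine = bovine_rhodopsin()
    pmap = map_to_reference(candidate_peptide, bovine, params)
    res = residue_at(candidate_peptide, pmap, K296)
    if res is UNALIGNED:
        return False, UNALIGNED
    return res == "K", pmap.get(K296)


# ---------------------------------------------------------------------------
# Stage 4: length filter


def length_filter(
    calls: Sequence[OpsinCall], db: ReferenceDB, enabled: bool = True
) -> list[OpsinCall]:
    """Keep calls that start with Met and are at least the mean database length.

    Short, possibly fragmentary transcripts are prone to misclassification;
    when ``enabled`` is False the input passes through unchanged (the flag
    is still recorded on every call).
    """
    mean_len = db.mean_length
    for call in calls:
        call.length_ok = (
            call.candidate.starts_with_met and len(call.peptide) >= mean_len
        )
    if not enabled:
        return list(calls)
    return [c for c in calls if c.length_ok]


# ---------------------------------------------------------------------------
# Stage 5: class assignment by tree placement


@dataclasses.dataclass
class PlacementTree:
    """Audit record of one placement: the NJ tree and the decision."""

    newick: str
    candidate_id: str
    nearest_ref_id: str
    nearest_distance: float
    tied_ref_ids: list[str]


def _p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing residues over pairwise-complete columns."""
    shared = 0
    diff = 0
    for a, b in zip(row_a, row_b):
        if a in "-X" or b in "-X":
            continue
        shared += 1
        if a != b:
            diff += 1
    if shared == 0:
        return 1.0
    return diff / shared


def assign_class(
    candidate: SequenceRecord,
    db: ReferenceDB,
    tie_tol: float = 1e-9,
) -> tuple[str, PlacementTree]:
    """Assign an opsin class by neighbour-joining placement.

    The candidate is aligned together with all database records; a NJ
    tree is built from p-distances and the class of the reference leaf
    with minimum patristic distance to the candidate is returned.  Ties
    are broken by majority class among the tied leaves, then by
    lexicographic class name.
    """
    if len(db.classes) < 2:
        raise ValueError("reference database must contain at least two classes")
    cand_tag = "__query__"
    query = SequenceRecord(id=cand_tag, seq=candidate.seq, alphabet="aa")
    rows = align_msa([query] + list(db.records))
    ids = [cand_tag] + [r.id for r in db.records]
    n = len(ids)
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = _p_distance(rows[ids[i]], rows[ids[j]])
            mat[i][j] = mat[j][i] = d
    dm = DistanceMatrix(mat, ids)
    tree = nj(dm)
    patristic = tree.tip_tip_distances()
    class_of = {r.id: r.class_label for r in db.records}
    dists = {rid: patristic[cand_tag, rid] for rid in class_of}
    dmin = min(dists.values())
    tied = sorted(rid for rid, d in dists.items() if d <= dmin + tie_tol)
    tally = Counter(class_of[rid] for rid in tied)
    top = max(tally.values())
    winner = sorted(c for c, k in tally.items() if k == top)[0]
    nearest = min(tied, key=lambda rid: (dists[rid], rid))
    placement = PlacementTree(
        newick=str(tree),
        candidate_id=candidate.id,
        nearest_ref_id=nearest,
        nearest_distance=dists[nearest],
        tied_ref_ids=tied,
    )
    return winner, placement


# ---------------------------------------------------------------------------
# Stage 6: greedy identity clustering


def cluster_identity(
    calls: Sequence[OpsinCall],
    threshold: float = 0.95,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[OpsinCall]:
    """Greedy longest-first clustering of calls at an identity threshold.

    Peptides are sorted by length (descending; ties by id for
    determinism).  Each peptide joins the first existing cluster whose
    *representative* (founding, longest member) shares global-alignment
    identity strictly greater than ``threshold`` with it, using the
    shorter sequence as denominator (cd-hit semantics); otherwise it
    founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(calls, key=lambda c: (-len(c.peptide), c.candidate.id))
    reps: list[OpsinCall] = []
    for call in ordered:
        placed = False
        for cid, rep in enumerate(reps):
            aln = global_align(
                SequenceRecord(id="a", seq=call.peptide, alphabet="aa"),
                SequenceRecord(id="b", seq=rep.peptide, alphabet="aa"),
                params,
            )
            if percent_identity(aln, "shorter_seq") > threshold:
                call.cluster_id = cid
                call.is_representative = False
                placed = True
                break
        if not placed:
            call.cluster_id = len(reps)
            call.is_representative = True
            reps.append(call)
    return list(ordered)


# ---------------------------------------------------------------------------
# Orchestration


@dataclasses.dataclass
class PipelineConfig:
    """Tunable knobs of the mining pipeline (defaults mirror standard use)."""

    min_aa_len: int = 100
    prescreen_evalue: float = 1e-5
    prescreen_min_score: float | None = None
    k296_check: bool = True
    length_filter: bool = True
    classify: bool = True
    cluster: bool = True
    cluster_threshold: float = 0.95
    params: AlignmentParams = dataclasses.field(default_factory=AlignmentParams)


@dataclasses.dataclass
class PipelineResult:
    """Everything the pipeline produced: accepted calls, audit trail, counts."""

    accepted: list[OpsinCall]
    rejected: list[OpsinCall]
    stage_counts: dict[str, int]
    placements: list[PlacementTree]

    @property
    def representatives(self) -> list[OpsinCall]:
        return [c for c in self.accepted if c.is_representative]

    def class_table(self) -> pd.DataFrame:
        """Distinct (cluster-representative) opsin transcripts per species and class."""
        rows = [
            {"species": c.species, "class": c.class_assigned}
            for c in self.representatives
        ]
        if not rows:
            return pd.DataFrame(columns=["species", "class", "n_transcripts"])
        return (
            pd.DataFrame(rows)
            .groupby(["species", "class"])
            .size()
            .reset_index(name="n_transcripts")
        )

    def calls_table(self) -> pd.DataFrame:
        rows = []
        for call in self.accepted + self.rejected:
            rows.append(
                {
                    "species": call.species,
                    "candidate": call.candidate.id,
                    "contig": call.candidate.contig_id,
                    "frame": call.candidate.frame,
                    "length_aa": len(call.peptide),
                    "class": call.class_assigned,
                    "k296_ok": call.k296_ok,
                    "length_ok": call.length_ok,
                    "cluster_id": call.cluster_id,
                    "is_representative": call.is_representative,
                    "reject_reason": call.reject_reason,
                    "best_hit": call.best_db_hit.ref_id if call.best_db_hit else None,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.calls_table().to_csv(outdir / "calls.tsv", sep="\t", index=False)
        self.class_table().to_csv(outdir / "class_counts.tsv", sep="\t", index=False)
        reps = [c.as_record() for c in self.representatives]
        if reps:
            write_fasta(reps, outdir / "representatives.fasta")
        with open(outdir / "placements.nwk", "w") as fh:
            for p in self.placements:
                fh.write(p.newick.strip() + "\n")
        with open(outdir / "log.txt", "w") as fh:
            for stage, count in self.stage_counts.items():
                fh.write(f"{stage}\t{count}\n")


def run_pipeline(
    assemblies: Iterable[tuple[str, list[SequenceRecord]]],
    db: ReferenceDB,
    config: PipelineConfig | None = None,
    bovine: SequenceRecord | None = None,
) -> PipelineResult:
    """Run the full mining pipeline over (species, contigs) assemblies.

    Assemblies of the same species are pooled before clustering, so a
    species sequenced and assembled several times still yields one count
    per distinct transcript.
    """
    config = config or PipelineConfig()
    if bovine is None:
        bovine = bovine_rhodopsin()

    per_species: dict[str, list[OrfCandidate]] = {}
    n_contigs = 0
    for species, contigs in assemblies:
        bucket = per_species.setdefault(species, [])
        for contig in contigs:
            n_contigs += 1
            bucket.extend(find_orfs(contig, config.min_aa_len))

    accepted: list[OpsinCall] = []
    rejected: list[OpsinCall] = []
    placements: list[PlacementTree] = []
    counts = {
        "contigs": n_contigs,
        "orfs": sum(len(v) for v in per_species.values()),
        "prescreen": 0,
        "k296": 0,
        "length": 0,
        "classified": 0,
        "representatives": 0,
    }

    for species, candidates in per_species.items():
        hits = prescreen(
            candidates,
            db,
            evalue=config.prescreen_evalue,
            min_score=config.prescreen_min_score,
            params=config.params,
        )
        counts["prescreen"] += len(hits)
        calls = [
            OpsinCall(candidate=cand, species=species, best_db_hit=hit)
            for cand, hit in hits
        ]

        survivors: list[OpsinCall] = []
        for call in calls:
            rec = SequenceRecord(id=call.candidate.id, seq=call.peptide, alphabet="aa")
            ok, pos = check_k296(rec, bovine, config.params)
            call.k296_ok = ok
            call.k296_query_pos = None if pos is UNALIGNED else pos
            if config.k296_check and not ok:
                call.class_assigned = "REJECTED"
                call.reject_reason = "no lysine at the bovine-296-homologous site"
                rejected.append(call)
            else:
                survivors.append(call)
        counts["k296"] += len(survivors)

        kept = length_filter(survivors, db, enabled=config.length_filter)
        kept_ids = {id(c) for c in kept}
        for call in survivors:
            if id(call) not in kept_ids:
                call.class_assigned = "REJECTED"
                call.reject_reason = "short or non-Met-start transcript"
                rejected.append(call)
        counts["length"] += len(kept)

        for call in kept:
            if config.classify:
                cls, placement = assign_class(
                    SequenceRecord(
                        id=call.candidate.id, seq=call.peptide, alphabet="aa"
                    ),
                    db,
                )
                call.class_assigned = cls
                placements.append(placement)
            else:
                call.class_assigned = "UNKNOWN"
        counts["classified"] += len(kept)

        if config.cluster:
            cluster_identity(kept, config.cluster_threshold, config.params)
        else:
            for i, call in enumerate(kept):
                call.cluster_id = i
                call.is_representative = True
        accepted.extend(kept)

    counts["representatives"] = sum(1 for c in accepted if c.is_representative)
    if not accepted:
        logger.warning("no opsin transcripts found in any assembly")
    for stage, count in counts.items():
        logger.info("stage %-16s %d", stage, count)
    return PipelineResult(
        accepted=accepted,
        rejected=rejected,
        stage_counts=counts,
        placements=placements,
    )
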