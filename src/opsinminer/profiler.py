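"""MWS-like substitution profiling in LWS opsins.

The contrast: Lake Baikal amphipods express only LWS opsins, while
European *Gammarus* species retain both LWS and MWS opsins.  A residue is
called an *MWS-like substitution* when, at an alignment column mapped to
a bovine-rhodopsin position, it

* occurs in at least one Baikal LWS sequence,
* occurs in at least one European MWS sequence, and
* occurs in no European LWS sequence.

Such residues are candidate spectral-tuning changes: sites where some
Baikal LWS opsins look like MWS opsins rather than like their LWS
orthologs.  Events are keyed by (bovine position, residue); the same
column can yield several events for different residues.  Gaps and the
ambiguity residue X never count as occurrences.

The minimum number of MWS carriers and the maximum number of European
LWS carriers are configurable, so stricter or looser definitions can be
compared on the same alignment.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Sequence

from .msa import align_msa
from .seq import TUNING_SITES, SequenceRecord, bovine_rhodopsin

_BOVINE_ROW_ID = "__bovine__"


@dataclasses.dataclass
class GroupedAlignment:
    """A multiple alignment of grouped opsins plus the bovine numbering row.

    ``rows`` maps sequence id to its gapped row; ``groups`` maps sequence
    id to its contrast group.  ``bovine_map`` maps each bovine position
    (1-based) to its alignment column (1-based); positions gapped out of
    the alignment are absent.
    """

    rows: dict[str, str]
    groups: dict[str, str]
    bovine_row: str
    bovine_map: dict[int, int]

    @property
    def n_columns(self) -> int:
        return len(self.bovine_row)

    def ids_in_group(self, group: str) -> list[str]:
        return sorted(i for i, g in self.groups.items() if g == group)

    def residues_at(self, column: int, ids: Sequence[str]) -> dict[str, list[str]]:
        """Residue -> carrier ids at a 1-based column; gaps and X excluded."""
        out: dict[str, list[str]] = defaultdict(list)
        for sid in ids:
            ch = self.rows[sid][column - 1]
            if ch not in "-X":
                out[ch].append(sid)
        return out


def build_grouped_alignment(
    seqs: Sequence[SequenceRecord],
    bovine: SequenceRecord | None = None,
) -> GroupedAlignment:
    """Align grouped sequences together with the bovine reference.

    Every input record must carry a ``group``; all three contrast groups
    (BAIKAL_LWS, EUROPEAN_LWS, EUROPEAN_MWS) must be represented.
    """
    if bovine is None:
        bovine = bovine_rhodopsin()
    present = {s.group for s in seqs}
    for needed in ("BAIKAL_LWS", "EUROPEAN_LWS", "EUROPEAN_MWS"):
        if needed not in present:
            raise ValueError(f"group {needed} is missing from the input")
    for s in seqs:
        if s.group is None:
            raise ValueError(f"sequence {s.id!r} has no group label")
    bovine_tagged = SequenceRecord(id=_BOVINE_ROW_ID, seq=bovine.seq, alphabet="aa")
    rows = align_msa([bovine_tagged] + list(seqs))
    bovine_row = rows.pop(_BOVINE_ROW_ID)
    bovine_map: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(bovine_row, start=1):
        if ch != "-":
            pos += 1
            bovine_map[pos] = col
    return GroupedAlignment(
        rows=rows,
        groups={s.id: s.group for s in seqs},
        bovine_row=bovine_row,
        bovine_map=bovine_map,
    )


@dataclasses.dataclass(frozen=True)
class SubstitutionEvent:
    """One MWS-like substitution: a residue at a bovine-numbered position."""

    bovine_pos: int
    residue: str
    carriers: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.carriers)

    @property
    def is_tuning_site(self) -> bool:
        return self.bovine_pos in TUNING_SITES

    def __repr__(self):
        star = "*" if self.is_tuning_site else ""
        return (
            f"SubstitutionEvent({self.residue}{self.bovine_pos}{star}, "
            f"count={self.count})"
        )


def call_mws_like(
    ga: GroupedAlignment,
    min_mws_carriers: int = 1,
    max_euro_lws_carriers: int = 0,
) -> list[SubstitutionEvent]:
    """Call MWS-like substitutions over all bovine-mapped columns.

    With the defaults, a residue qualifies when it is present in >= 1
    European MWS row and absent from every European LWS row.  Events are
    returned sorted by descending carrier count, then by bovine position.
    """
    baikal = ga.ids_in_group("BAIKAL_LWS")
    euro_lws = ga.ids_in_group("EUROPEAN_LWS")
    euro_mws = ga.ids_in_group("EUROPEAN_MWS")
    events: list[SubstitutionEvent] = []
    for bovine_pos, col in sorted(ga.bovine_map.items()):
        baikal_res = ga.residues_at(col, baikal)
        if not baikal_res:
            continue
        mws_res = ga.residues_at(col, euro_mws)
        lws_res = ga.residues_at(col, euro_lws)
        for residue, carriers in baikal_res.items():
            if len(mws_res.get(residue, [])) < min_mws_carriers:
                continue
            if len(lws_res.get(residue, [])) > max_euro_lws_carriers:
                continue
            events.append(
                SubstitutionEvent(
                    bovine_pos=bovine_pos,
                    residue=residue,
                    carriers=frozenset(carriers),
                )
            )
    events.sort(key=lambda e: (-e.count, e.bovine_pos, e.residue))
    return events


def occurrence_spectrum(
    events: Sequence[SubstitutionEvent], threshold: int = 10
) -> tuple[list[int], int]:
    """Descending carrier counts and how many events exceed ``threshold``.

    The comparison is strict ("more than ``threshold`` times").
    """
    counts = sorted((e.count for e in events), reverse=True)
    return counts, sum(1 for c in counts if c > threshold)


@dataclasses.dataclass
class CooccurrenceResult:
    """Observed vs independence-expected co-occurrence of chosen events."""

    events: list[SubstitutionEvent]
    observed_count: int
    total: int
    expected_fraction: float
    observed_fraction: float

    def report(self) -> str:
        k = len(self.events)
        labels = ", ".join(f"{e.residue}{e.bovine_pos}" for e in self.events)
        return (
            f"{k} substitutions ({labels}) co-occur in {self.observed_count} of "
            f"{self.total} sequences ({self.observed_fraction * 100:.1f}%); "
            f"{self.expected_fraction * 100:.1f}% expected if independent"
        )


def cooccurrence(
    ga: GroupedAlignment, events: Sequence[SubstitutionEvent]
) -> CooccurrenceResult:
    """Compare joint carriage of k events with the independence expectation.

    The expected fraction is the product of the marginal carrier
    frequencies; the observed count is the size of the intersection of
    the carrier sets among all Baikal LWS sequences.
    """
    if len(events) < 2:
        raise ValueError("co-occurrence needs at least two events")
    baikal = set(ga.ids_in_group("BAIKAL_LWS"))
    total = len(baikal)
    for e in events:
        if not e.carriers <= baikal or e.bovine_pos not in ga.bovine_map:
            raise ValueError(f"event {e!r} does not belong to this alignment")
    joint = set.intersection(*(set(e.carriers) for e in events))
    expected = 1.0
    for e in events:
        expected *= e.count / total
    return CooccurrenceResult(
        events=list(events),
        observed_count=len(joint),
        total=total,
        expected_fraction=expected,
        observed_fraction=len(joint) / total,
    )


def events_table(events: Sequence[SubstitutionEvent]):
    """Events as a tidy DataFrame (bovine_pos, residue, count, tuning flag, carriers)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "bovine_pos": e.bovine_pos,
                "residue": e.residue,
                "count": e.count,
                "tuning_site": e.is_tuning_site,
                "carriers": ",".join(sorted(e.carriers)),
            }
            for e in events
        ]
    )
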