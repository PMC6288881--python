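"""Unique-best alignment selection and Crick-to-Watson lift-over.

The four per-conversion-pair hit streams are merged per read and the single
best alignment is the one with the uniquely least number of mismatches;
ties at the minimum make the read ambiguous and it is discarded.  Hits from
Crick-converted genomes are lifted to Watson coordinates first, and hits
that land on the same (sequence, Watson position, strand) via two
conversion pairs are collapsed into one before the uniqueness test — a read
with no C or G is identical under both conversions and would otherwise
always tie with itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .aligner_core import AlignmentHit
from .genome_prep import tag_strand

RESOLVED = "resolved"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


class InternalConsistencyError(RuntimeError):
    """Hits for one read disagree on invariant fields."""


@dataclass(frozen=True)
class ResolvedAlignment:
    """The surviving unique-best alignment of one read, in Watson coordinates."""

    read_id: str
    pair_tag: str
    seq_name: str
    watson_pos: int
    watson_strand: str  # '+' for W-* tags, '-' for C-* tags
    mismatches: int
    read_len: int
    orig_seq: Optional[str] = None


def crick_to_watson(pos_c: int, read_len: int, seq_len: int) -> int:
    """Lift a 0-based Crick-orientation start to the Watson strand.

    An interval of length L starting at pos_c on the Crick strand covers
    Watson positions [seq_len - pos_c - L, seq_len - pos_c).
    """
    if pos_c < 0 or pos_c > seq_len - read_len:
        raise InternalConsistencyError(
            f"crick position {pos_c} out of range for seq_len={seq_len}, "
            f"read_len={read_len}"
        )
    return seq_len - pos_c - read_len


def lift_hit(hit: AlignmentHit, source_lengths: Dict[str, int]) -> Tuple[str, int, str]:
    """(seq_name, watson_pos, watson_strand) of a hit."""
    strand = tag_strand(hit.pair_tag)
    if strand == "+":
        return hit.seq_name, hit.pos, "+"
    seq_len = source_lengths[hit.seq_name]
    return hit.seq_name, crick_to_watson(hit.pos, hit.read_len, seq_len), "-"


def select_best(
    hits: Sequence[AlignmentHit],
    max_mm: int,
    source_lengths: Dict[str, int],
    orig_seq: Optional[str] = None,
) -> Tuple[str, Optional[ResolvedAlignment]]:
    """Apply the unique-least-mismatch rule to all hits of one read.

    Returns (status, alignment): RESOLVED with the winner, AMBIGUOUS when
    two or more distinct placements tie at the minimum, UNMAPPED when no
    hit survives the cutoff.  Output is independent of hit order.
    """
    surviving = [h for h in hits if h.mismatches <= max_mm]  # re-check cutoff
    if not surviving:
        return UNMAPPED, None

    read_id = surviving[0].read_id
    read_len = surviving[0].read_len
    for h in surviving:
        if h.read_id != read_id or h.read_len != read_len:
            raise InternalConsistencyError(
                f"inconsistent hits for read {read_id!r}: "
                f"({h.read_id!r}, len {h.read_len}) vs ({read_id!r}, len {read_len})"
            )

    # Collapse coincident placements reached via different conversion pairs;
    # keep the lower mismatch count (deterministic tie-break on pair_tag for
    # reproducibility only — the placement is identical either way).
    placements: Dict[Tuple[str, int, str], AlignmentHit] = {}
    for h in sorted(surviving, key=lambda h: (h.mismatches, h.pair_tag)):
        key = lift_hit(h, source_lengths)
        placements.setdefault(key, h)

    best_mm = min(h.mismatches for h in placements.values())
    best = [(key, h) for key, h in placements.items() if h.mismatches == best_mm]
    if len(best) > 1:
        return AMBIGUOUS, None

    (seq_name, watson_pos, strand), hit = best[0]
    return RESOLVED, ResolvedAlignment(
        read_id=read_id,
        pair_tag=hit.pair_tag,
        seq_name=seq_name,
        watson_pos=watson_pos,
        watson_strand=strand,
        mismatches=hit.mismatches,
        read_len=read_len,
        orig_seq=orig_seq,
    )


def merge_copartitioned(streams):
    """Zero-shuffle merge of co-partitioned keyed streams, grouped per read.

    All hits (and the carried original-sequence records) of a read already
    live in the same partition index, so grouping is partition-local; the
    engine's union raises if the streams are not actually co-partitioned.
    """
    from . import parallel_engine

    unioned = parallel_engine.co_union(streams)
    # contract assertion: each key is confined to a single partition
    seen: Dict[object, int] = {}
    for i, part in enumerate(unioned.partitions):
        for key, _ in part:
            j = seen.setdefault(key, i)
            if j != i:
                raise parallel_engine.ContractViolationError(
                    f"key {key!r} present in partitions {j} and {i}: "
                    "streams were not co-partitioned"
                )
    return parallel_engine.group_by_key_local(unioned)


@dataclass
class RunStats:
    """Per-run read accounting (conservation: total == sum of the classes)."""

    total: int = 0
    resolved: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    quality_dropped: int = 0

    def conserved(self) -> bool:
        return self.total == (
            self.resolved + self.ambiguous + self.unmapped + self.quality_dropped
        )
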