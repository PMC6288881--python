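"""Seed-and-extend mapping of converted reads against converted genomes.

Every transformed read is aligned end-to-end and ungapped against the
converted genomes of its candidate pairs.  Seeding uses exact k-mer lookups
at non-overlapping offsets 0, k, 2k, ... plus a tail seed at ``L - k``;
by pigeonhole over the disjoint prefix seeds, any placement with at most
``floor(L / k) - 1`` mismatches is guaranteed to be found, and a 0-mismatch
placement is always found.

An external three-letter backend (e.g. a Bowtie2 wrapper emitting SAM with
NM tags) can be plugged in behind the same hit semantics.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_prep import (
    RULE_CT,
    RULE_GA,
    ConvertedGenome,
    GenomePack,
    InvalidParameterError,
    SeedIndex,
    encode_seq,
)
from .read_transform import TransformedRead

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 4

#: (read conversion, genome tag) pairs mapped per library mode.
NON_DIRECTIONAL_PAIRS: Tuple[Tuple[str, str], ...] = (
    (RULE_CT, "W-CT"),
    (RULE_CT, "C-CT"),
    (RULE_GA, "W-GA"),
    (RULE_GA, "C-GA"),
)
DIRECTIONAL_PAIRS: Tuple[Tuple[str, str], ...] = (
    (RULE_CT, "W-CT"),
    (RULE_CT, "C-CT"),
)


class BackendError(RuntimeError):
    """An external aligner backend failed or is unavailable."""


@dataclass(frozen=True)
class AlignmentHit:
    """One candidate placement of a converted read on a converted genome.

    ``pos`` is 0-based on the converted genome's own orientation (Crick
    coordinates for C-* tags); lift-over to Watson happens in the resolver.
    ``mismatches`` is the Hamming distance in converted (three-letter) space.
    """

    read_id: str
    pair_tag: str
    seq_name: str
    pos: int
    mismatches: int
    read_len: int


def candidate_pairs(library: str) -> List[Tuple[str, str]]:
    """(read conversion, genome tag) pairs to map for a library mode."""
    if library == "non-directional":
        return list(NON_DIRECTIONAL_PAIRS)
    if library == "directional":
        return list(DIRECTIONAL_PAIRS)
    raise InvalidParameterError(f"unknown library mode {library!r}")


def seed_offsets(read_len: int, k: int) -> List[int]:
    """Non-overlapping seed offsets 0, k, 2k, ... plus the tail offset L-k."""
    offs = list(range(0, read_len - k + 1, k))
    if offs and offs[-1] != read_len - k:
        offs.append(read_len - k)
    return offs


_POW_CACHE: Dict[int, np.ndarray] = {}


def _powers(k: int) -> np.ndarray:
    pows = _POW_CACHE.get(k)
    if pows is None:
        pows = (np.uint64(1) << (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)))
        _POW_CACHE[k] = pows
    return pows


def align_read(
    tr: TransformedRead,
    genome: ConvertedGenome,
    index: SeedIndex,
    max_mm: int = DEFAULT_MAX_MISMATCH,
    _rcodes: Optional[np.ndarray] = None,
) -> List[AlignmentHit]:
    """All end-to-end ungapped placements with Hamming distance <= max_mm.

    Placements are found by exact k-mer seeding followed by full-length
    verification against the encoded genome; duplicates (same sequence and
    position) are reported once.  Reads shorter than k are skipped (logged,
    counted unmapped by the caller).
    """
    if max_mm < 0:
        raise InvalidParameterError(f"max_mm={max_mm} must be >= 0")
    k = index.k
    read_len = len(tr.conv_seq)
    if read_len < k:
        logger.warning(
            "read %s shorter than seed length (%d < %d): skipped",
            tr.read_id, read_len, k,
        )
        return []
    rcodes = _rcodes if _rcodes is not None else encode_seq(tr.conv_seq)
    pows = _powers(k)
    offsets = seed_offsets(read_len, k)

    # pre-pack each seed once; seeds containing N cannot match the index
    seed_vals: List[Tuple[int, int]] = []
    for off in offsets:
        window = rcodes[off : off + k]
        if (window >= 4).any():
            continue
        seed_vals.append((off, int((window.astype(np.uint64) * pows).sum())))

    hits: List[AlignmentHit] = []
    for name, gcodes in index.codes.items():
        glen = len(gcodes)
        if read_len > glen:
            continue
        seen: set = set()
        for off, val in seed_vals:
            for p0 in index.lookup_code(name, val):
                p = int(p0) - off
                if p < 0 or p + read_len > glen or p in seen:
                    continue
                seen.add(p)
                mm = int(np.count_nonzero(gcodes[p : p + read_len] != rcodes))
                if mm <= max_mm:
                    hits.append(
                        AlignmentHit(
                            read_id=tr.read_id,
                            pair_tag=index.tag,
                            seq_name=name,
                            pos=p,
                            mismatches=mm,
                            read_len=read_len,
                        )
                    )
    return hits


def align_read_pairs(
    tr_list: Sequence[TransformedRead],
    pack: GenomePack,
    library: str,
    max_mm: int = DEFAULT_MAX_MISMATCH,
) -> List[AlignmentHit]:
    """Align the transformed forms of one read over all candidate pairs."""
    by_conv = {tr.conv: tr for tr in tr_list}
    hits: List[AlignmentHit] = []
    for conv, tag in candidate_pairs(library):
        tr = by_conv.get(conv)
        if tr is None:
            continue
        hits.extend(align_read(tr, pack.genomes[tag], pack.indexes[tag], max_mm))
    return hits


# --------------------------------------------------------------------------
# External backend adapter


@dataclass
class BackendConfig:
    """How to invoke an external three-letter aligner for one genome tag.

    ``cmd_template`` is formatted with ``{genome_fasta}``, ``{reads_fastq}``
    and ``{out_sam}``; the backend must write SAM with an NM tag.
    """

    cmd_template: str
    executable: str


def parse_backend_sam(
    sam_path: str | Path, pair_tag: str, max_mm: int
) -> List[AlignmentHit]:
    """Parse backend SAM into hits with :func:`align_read` semantics.

    Mismatch counts come from the backend's NM (edit distance) tag; mapped
    records whose NM exceeds ``max_mm`` are excluded, as are unmapped ones.
    """
    import pysam

    hits: List[AlignmentHit] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            try:
                nm = int(rec.get_tag("NM"))
            except KeyError as exc:
                raise BackendError(
                    f"backend SAM record {rec.query_name!r} lacks NM tag"
                ) from exc
            if nm > max_mm:
                continue
            hits.append(
                AlignmentHit(
                    read_id=rec.query_name,
                    pair_tag=pair_tag,
                    seq_name=rec.reference_name,
                    pos=int(rec.reference_start),
                    mismatches=nm,
                    read_len=int(rec.query_length),
                )
            )
    return hits


def external_backend_align(
    reads_fastq: str | Path,
    pack_dir: str | Path,
    pair_tag: str,
    config: BackendConfig,
    max_mm: int = DEFAULT_MAX_MISMATCH,
    workdir: Optional[str | Path] = None,
) -> List[AlignmentHit]:
    """Run an external aligner over one converted genome and adapt its SAM."""
    if shutil.which(config.executable) is None:
        raise BackendError(
            f"backend executable {config.executable!r} not found on PATH; "
            "use the internal aligner (--backend internal) instead"
        )
    workdir = Path(workdir) if workdir is not None else Path(pack_dir)
    out_sam = workdir / f"backend.{pair_tag}.sam"
    cmd = config.cmd_template.format(
        genome_fasta=str(Path(pack_dir) / f"{pair_tag}.fa"),
        reads_fastq=str(reads_fastq),
        out_sam=str(out_sam),
    )
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise BackendError(
            f"backend command failed (exit {proc.returncode}): {proc.stderr[-500:]}"
        )
    return parse_backend_sam(out_sam, pair_tag, max_mm)
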