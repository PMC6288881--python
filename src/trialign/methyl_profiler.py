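"""Per-read methylation calling, SAM output and per-site aggregation.

Calls are made by comparing each resolved read against the ORIGINAL
(unconverted) reference.  CT-type alignments (pair tags W-CT / C-CT) carry
information about cytosines on the read's own biological strand: a read C
over a reference C is methylated, a read T is unmethylated.  GA-type
alignments (W-GA / C-GA, the complement strands of a non-directional
library) carry the opposite strand's cytosine information as G/A over a
reference G.

Call letters follow the familiar Z/X/H convention: Z/z for CpG, X/x for
CHG, H/h for CHH, uppercase = methylated, '.' = no cytosine information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .genome_prep import ReferenceGenome, reverse_complement
from .resolver import ResolvedAlignment

CONTEXT_LETTER = {"CpG": "Z", "CHG": "X", "CHH": "H"}
LETTER_CONTEXT = {v: k for k, v in CONTEXT_LETTER.items()}

#: strand whose cytosines a pair tag reports on (opposite of the alignment
#: strand for GA-type tags).
CALL_STRAND = {"W-CT": "+", "C-CT": "-", "W-GA": "-", "C-GA": "+"}


class InvalidCallError(ValueError):
    """Context requested at a position that is not a cytosine on that strand."""


@dataclass(frozen=True)
class CallSite:
    """One cytosine observation: Watson coordinates + context + state."""

    seq_name: str
    watson_pos: int
    strand: str
    context: str
    methylated: bool
    context_truncated: bool = False


@dataclass(frozen=True)
class MethylationCall:
    """Per-read call string (read orientation) plus its per-cytosine sites."""

    read_id: str
    calls: str
    sites: Tuple[CallSite, ...]


def classify_context(
    ref: ReferenceGenome, seq_name: str, watson_pos: int, strand: str
) -> Tuple[str, bool]:
    """Cytosine context (CpG/CHG/CHH) using the strand's own downstream bases.

    Returns (context, truncated): positions within two bases of the sequence
    end lack full context and default to CHH with the flag set.
    """
    seq = ref.sequences[seq_name]
    if strand == "+":
        if seq[watson_pos] != "C":
            raise InvalidCallError(
                f"{seq_name}:{watson_pos}:+ is {seq[watson_pos]!r}, not C"
            )
        d1 = seq[watson_pos + 1] if watson_pos + 1 < len(seq) else None
        d2 = seq[watson_pos + 2] if watson_pos + 2 < len(seq) else None
    elif strand == "-":
        if seq[watson_pos] != "G":
            raise InvalidCallError(
                f"{seq_name}:{watson_pos}:- is {seq[watson_pos]!r}, not C on Crick"
            )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        d1 = comp[seq[watson_pos - 1]] if watson_pos - 1 >= 0 else None
        d2 = comp[seq[watson_pos - 2]] if watson_pos - 2 >= 0 else None
    else:
        raise InvalidCallError(f"unknown strand {strand!r}")

    if d1 is None or (d1 != "G" and d2 is None):
        return "CHH", True
    if d1 == "G":
        return "CpG", False
    if d2 == "G":
        return "CHG", False
    return "CHH", False


def call_read(aln: ResolvedAlignment, ref: ReferenceGenome) -> MethylationCall:
    """Call methylation for one resolved read against the original reference."""
    if aln.orig_seq is None:
        raise InvalidCallError(f"read {aln.read_id!r}: original sequence missing")
    seq = ref.sequences[aln.seq_name]
    L = aln.read_len
    if aln.watson_pos < 0 or aln.watson_pos + L > len(seq):
        raise InvalidCallError(
            f"read {aln.read_id!r}: coordinates overflow {aln.seq_name} "
            f"({aln.watson_pos}+{L} > {len(seq)})"
        )
    segment = seq[aln.watson_pos : aln.watson_pos + L]

    # Reference in read orientation, and the (ref base, meth base, unmeth
    # base) triple the pair tag makes informative.
    if aln.pair_tag in ("W-CT", "W-GA"):
        ref_read_orient = segment  # read is in Watson orientation
    else:
        ref_read_orient = reverse_complement(segment)
    if aln.pair_tag in ("W-CT", "C-CT"):
        ref_base, meth_base, unmeth_base = "C", "C", "T"
    else:
        ref_base, meth_base, unmeth_base = "G", "G", "A"
    call_strand = CALL_STRAND[aln.pair_tag]

    calls = ["."] * L
    sites: List[CallSite] = []
    for i, rb in enumerate(ref_read_orient):
        if rb != ref_base:
            continue
        read_base = aln.orig_seq[i]
        if read_base == meth_base:
            methylated = True
        elif read_base == unmeth_base:
            methylated = False
        else:
            continue  # sequencing error or variant: no information
        if aln.pair_tag in ("W-CT", "W-GA"):
            wpos = aln.watson_pos + i
        else:
            wpos = aln.watson_pos + L - 1 - i
        context, truncated = classify_context(ref, aln.seq_name, wpos, call_strand)
        letter = CONTEXT_LETTER[context]
        calls[i] = letter if methylated else letter.lower()
        sites.append(
            CallSite(
                seq_name=aln.seq_name,
                watson_pos=wpos,
                strand=call_strand,
                context=context,
                methylated=methylated,
                context_truncated=truncated,
            )
        )
    return MethylationCall(read_id=aln.read_id, calls="".join(calls), sites=tuple(sites))


@dataclass(frozen=True)
class SiteCounts:
    """Aggregated methylation evidence at one cytosine position."""

    seq_name: str
    watson_pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        if self.coverage == 0:
            raise ZeroDivisionError("methylation level undefined at coverage 0")
        return self.n_meth / self.coverage


def aggregate_sites(calls: Iterable[MethylationCall]) -> List[SiteCounts]:
    """Sum per-read calls into per-position counts, ordered by (seq, pos, strand)."""
    acc: Dict[Tuple[str, int, str], List] = {}
    for call in calls:
        for site in call.sites:
            key = (site.seq_name, site.watson_pos, site.strand)
            entry = acc.setdefault(key, [site.context, 0, 0])
            if site.methylated:
                entry[1] += 1
            else:
                entry[2] += 1
    out = []
    for (seq_name, pos, strand) in sorted(acc):
        context, n_meth, n_unmeth = acc[(seq_name, pos, strand)]
        out.append(
            SiteCounts(
                seq_name=seq_name,
                watson_pos=pos,
                strand=strand,
                context=context,
                n_meth=n_meth,
                n_unmeth=n_unmeth,
            )
        )
    return out


def write_site_tsv(sites: Sequence[SiteCounts], path: str | Path) -> None:
    """Write the site report: seq, 1-based pos, strand, context, counts, level."""
    with open(path, "w") as fh:
        fh.write("seq\tpos\tstrand\tcontext\tn_meth\tn_unmeth\tlevel\n")
        for s in sites:
            fh.write(
                f"{s.seq_name}\t{s.watson_pos + 1}\t{s.strand}\t{s.context}\t"
                f"{s.n_meth}\t{s.n_unmeth}\t{s.level:.6g}\n"
            )


def write_sam(
    items: Sequence[Tuple[ResolvedAlignment, Optional[MethylationCall]]],
    ref: ReferenceGenome,
    path: str | Path,
) -> None:
    """Write resolved alignments (+ calls) as coordinate-sorted SAM.

    FLAG 0/16 by strand, 1-based POS, MAPQ 255, CIGAR <L>M; SEQ (and the
    ZM call string) are reverse-complemented/reversed for '-' alignments
    per SAM convention.  Tags: NM mismatches, ZC conversion pair tag, ZM
    call string.
    """
    import pysam

    names = list(ref.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(ref.sequences[n])} for n in names],
        "PG": [{"ID": "trialign", "PN": "trialign"}],
    }
    order = {n: i for i, n in enumerate(names)}
    items = sorted(items, key=lambda t: (order[t[0].seq_name], t[0].watson_pos, t[0].read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln, call in items:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.flag = 0 if aln.watson_strand == "+" else 16
            seg.reference_id = order[aln.seq_name]
            seg.reference_start = aln.watson_pos
            seg.mapping_quality = 255
            seg.cigarstring = f"{aln.read_len}M"
            seq = aln.orig_seq or ""
            zm = call.calls if call is not None else ""
            if aln.watson_strand == "-":
                seq = reverse_complement(seq) if seq else seq
                zm = zm[::-1]
            seg.query_sequence = seq or None
            tags = [("NM", aln.mismatches), ("ZC", aln.pair_tag)]
            if call is not None:
                tags.append(("ZM", zm))
            seg.set_tags(tags)
            out.write(seg)


def calls_from_sam(sam_path: str | Path, ref: ReferenceGenome) -> List[MethylationCall]:
    """Reconstruct per-read calls from a SAM written by :func:`write_sam`."""
    import pysam

    out: List[MethylationCall] = []
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped or not rec.has_tag("ZM"):
                continue
            zm = str(rec.get_tag("ZM"))
            tag = str(rec.get_tag("ZC"))
            strand = CALL_STRAND[tag]
            sites = []
            for j, letter in enumerate(zm):
                if letter == ".":
                    continue
                sites.append(
                    CallSite(
                        seq_name=rec.reference_name,
                        watson_pos=rec.reference_start + j,
                        strand=strand,
                        context=LETTER_CONTEXT[letter.upper()],
                        methylated=letter.isupper(),
                    )
                )
            calls = zm if not rec.is_reverse else zm[::-1]
            out.append(
                MethylationCall(read_id=rec.query_name, calls=calls, sites=tuple(sites))
            )
    return out
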