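"""Converted reference genomes and their k-mer seed indexes.

Three-letter alignment maps bisulfite reads against four transformed copies
of the reference: the Watson and Crick strands, each with either every C
replaced by T (``CT`` rule) or every G replaced by A (``GA`` rule).  This
module builds those four genomes, the exact-k-mer seed index used by the
internal aligner, and a persistent on-disk "genome pack".
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

PACK_FORMAT_VERSION = 1

#: The four converted-genome tags: Watson/Crick strand x CT/GA rule.
TAGS = ("W-CT", "W-GA", "C-CT", "C-GA")

RULE_CT = "CT"
RULE_GA = "GA"

_ALPHABET = frozenset("ACGTN")
_INVALID_RE = re.compile(r"[^ACGTN]")
_IUPAC_RE = re.compile(r"[RYSWKMBDHVU]")

_CT_TABLE = str.maketrans("C", "T")
_GA_TABLE = str.maketrans("G", "A")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

# byte codes: A=0 C=1 G=2 T=3, N (and anything else) = 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class InvalidSequenceError(ValueError):
    """A nucleotide string contains a character outside {A,C,G,T,N}."""


class InvalidParameterError(ValueError):
    """A parameter is outside its documented range."""


class PackError(RuntimeError):
    """A genome pack directory is missing or corrupt."""


class PackChecksumWarning(UserWarning):
    """The pack was built from a FASTA with a different checksum."""


def _check_alphabet(seq: str, what: str = "sequence") -> None:
    m = _INVALID_RE.search(seq)
    if m is not None:
        raise InvalidSequenceError(
            f"invalid character {m.group()!r} in {what} at position {m.start()}"
        )


def convert_sequence(seq: str, rule: str) -> str:
    """Apply a three-letter conversion rule to an uppercase sequence.

    ``CT`` replaces every C with T; ``GA`` replaces every G with A.  All
    other characters (including N) are unchanged and length is preserved.
    """
    _check_alphabet(seq)
    if rule == RULE_CT:
        return seq.translate(_CT_TABLE)
    if rule == RULE_GA:
        return seq.translate(_GA_TABLE)
    raise InvalidParameterError(f"unknown conversion rule {rule!r}")


def reverse_complement(seq: str) -> str:
    """Standard reverse complement over {A,C,G,T,N} (N maps to N)."""
    _check_alphabet(seq)
    return seq.translate(_RC_TABLE)[::-1]


def normalize_sequence(raw: str, name: str = "?") -> str:
    """Uppercase a raw FASTA sequence; map non-N IUPAC ambiguity codes to N."""
    seq = raw.upper()
    if _IUPAC_RE.search(seq):
        n = len(_IUPAC_RE.findall(seq))
        logger.warning(
            "sequence %s: %d IUPAC ambiguity bases mapped to N", name, n
        )
        seq = _IUPAC_RE.sub("N", seq)
    _check_alphabet(seq, what=f"sequence {name}")
    return seq


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


@dataclass(frozen=True)
class ReferenceGenome:
    """An ordered set of named, validated nucleotide sequences (Watson strand)."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise InvalidSequenceError("reference genome has no sequences")
        for name, seq in self.sequences.items():
            if not seq:
                raise InvalidSequenceError(f"sequence {name!r} is empty")
            _check_alphabet(seq, what=f"sequence {name!r}")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def checksum(self) -> str:
        h = hashlib.md5()
        for name, seq in self.sequences.items():
            h.update(name.encode())
            h.update(b"\0")
            h.update(seq.encode())
            h.update(b"\0")
        return h.hexdigest()

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        sequences: Dict[str, str] = {}
        for name, seq in _iter_fasta(path):
            if name in sequences:
                raise InvalidSequenceError(f"duplicate sequence name {name!r}")
            sequences[name] = normalize_sequence(seq, name=name)
        return cls(sequences)


def _iter_fasta(path: str | Path) -> Iterator[Tuple[str, str]]:
    from Bio import SeqIO

    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, str(rec.seq)


@dataclass(frozen=True)
class ConvertedGenome:
    """One of the four three-letter reference transformations.

    Crick-tagged genomes are stored in Crick orientation; the resolver lifts
    their coordinates back to Watson.  ``source_lengths`` are the Watson
    lengths needed for that lift-over (identical to the converted lengths).
    """

    tag: str
    sequences: Dict[str, str]
    source_lengths: Dict[str, int]

    def __post_init__(self) -> None:
        if self.tag not in TAGS:
            raise InvalidParameterError(f"unknown genome tag {self.tag!r}")

    @property
    def rule(self) -> str:
        return tag_rule(self.tag)


def tag_rule(tag: str) -> str:
    """Conversion rule (CT or GA) of a genome tag."""
    return tag.split("-", 1)[1]


def tag_strand(tag: str) -> str:
    """Watson strand symbol implied by a genome tag: '+' for W-*, '-' for C-*."""
    return "+" if tag.startswith("W") else "-"


def make_converted_genomes(ref: ReferenceGenome) -> Dict[str, ConvertedGenome]:
    """Build the four converted genomes from a Watson-strand reference.

    W-CT = CT(watson); W-GA = GA(watson); C-CT = CT(revcomp(watson));
    C-GA = GA(revcomp(watson)), applied per sequence.
    """
    lengths = ref.lengths
    watson = ref.sequences
    crick = {n: reverse_complement(s) for n, s in watson.items()}
    out = {}
    for tag in TAGS:
        strand_seqs = watson if tag.startswith("W") else crick
        rule = tag_rule(tag)
        out[tag] = ConvertedGenome(
            tag=tag,
            sequences={n: convert_sequence(s, rule) for n, s in strand_seqs.items()},
            source_lengths=dict(lengths),
        )
    return out


def _kmer_scan(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Return (positions, packed 2-bit values) of all N-free k-mers."""
    m = len(codes) - k + 1
    if m <= 0:
        return np.empty(0, np.int64), np.empty(0, np.uint64)
    vals = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        vals = (vals << two) | codes[j : j + m].astype(np.uint64)
    bad = (codes >= 4).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    pos = np.nonzero(valid)[0].astype(np.int64)
    return pos, vals[pos]


def kmer_code(kmer: str) -> Optional[int]:
    """Pack an N-free k-mer into its 2-bit integer code (None if it has N)."""
    codes = encode_seq(kmer)
    if (codes >= 4).any():
        return None
    val = np.uint64(0)
    two = np.uint64(2)
    for c in codes:
        val = (val << two) | np.uint64(c)
    return int(val)


class SeedIndex:
    """Exact k-mer index over one converted genome.

    Stores, per sequence, the sorted packed k-mer values alongside their
    start positions, plus the encoded sequence itself (used by the aligner
    for full-length verification).  k-mers containing N are not indexed.
    """

    def __init__(
        self,
        k: int,
        tag: str,
        codes: Dict[str, np.ndarray],
        sorted_vals: Dict[str, np.ndarray],
        sorted_pos: Dict[str, np.ndarray],
    ) -> None:
        self.k = k
        self.tag = tag
        self.codes = codes
        self._svals = sorted_vals
        self._spos = sorted_pos

    @classmethod
    def build(cls, genome: ConvertedGenome, k: int) -> "SeedIndex":
        if k < 1:
            raise InvalidParameterError(f"seed length k={k} must be >= 1")
        shortest = min(len(s) for s in genome.sequences.values())
        if k > shortest:
            raise InvalidParameterError(
                f"seed length k={k} exceeds shortest sequence length {shortest}"
            )
        codes, svals, spos = {}, {}, {}
        for name, seq in genome.sequences.items():
            c = encode_seq(seq)
            pos, vals = _kmer_scan(c, k)
            order = np.argsort(vals, kind="stable")  # stable: ties stay position-sorted
            codes[name] = c
            svals[name] = vals[order]
            spos[name] = pos[order]
        return cls(k, genome.tag, codes, svals, spos)

    @property
    def sequence_names(self) -> List[str]:
        return list(self.codes)

    def lookup_code(self, seq_name: str, code: int) -> np.ndarray:
        """Sorted start positions of a packed k-mer in one sequence."""
        sv = self._svals[seq_name]
        c = np.uint64(code)
        lo = np.searchsorted(sv, c, side="left")
        hi = np.searchsorted(sv, c, side="right")
        return self._spos[seq_name][lo:hi]

    def lookup(self, seq_name: str, kmer: str) -> List[int]:
        if len(kmer) != self.k:
            raise InvalidParameterError(
                f"query length {len(kmer)} != index k {self.k}"
            )
        code = kmer_code(kmer)
        if code is None:
            return []
        return [int(p) for p in self.lookup_code(seq_name, code)]

    def to_table(self) -> Dict[str, Dict[str, List[int]]]:
        """Materialize {seq_name: {kmer: [positions]}} — for small genomes only."""
        out: Dict[str, Dict[str, List[int]]] = {}
        letters = "ACGT"
        for name in self.codes:
            table: Dict[str, List[int]] = {}
            sv, sp = self._svals[name], self._spos[name]
            for v, p in zip(sv.tolist(), sp.tolist()):
                kmer = "".join(
                    letters[(v >> (2 * (self.k - 1 - j))) & 3] for j in range(self.k)
                )
                table.setdefault(kmer, []).append(p)
            out[name] = table
        return out

    def save(self, path: str | Path) -> None:
        arrays = {}
        for name in self.codes:
            arrays[f"vals::{name}"] = self._svals[name]
            arrays[f"pos::{name}"] = self._spos[name]
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path, k: int, genome: ConvertedGenome) -> "SeedIndex":
        with np.load(path) as data:
            svals = {}
            spos = {}
            for key in data.files:
                kind, name = key.split("::", 1)
                if kind == "vals":
                    svals[name] = data[key]
                elif kind == "pos":
                    spos[name] = data[key]
        codes = {n: encode_seq(s) for n, s in genome.sequences.items()}
        missing = set(codes) - set(svals)
        if missing:
            raise PackError(f"index {path} missing sequences: {sorted(missing)}")
        return cls(k, genome.tag, codes, svals, spos)


def build_seed_index(genome: ConvertedGenome, k: int) -> SeedIndex:
    """Build the exact-k-mer seed index of one converted genome."""
    return SeedIndex.build(genome, k)


@dataclass
class GenomePack:
    """The four converted genomes + indexes + the original reference."""

    ref: ReferenceGenome
    genomes: Dict[str, ConvertedGenome]
    indexes: Dict[str, SeedIndex]
    k: int
    checksum: str = field(default="")

    def __post_init__(self) -> None:
        if not self.checksum:
            self.checksum = self.ref.checksum()

    @classmethod
    def build(cls, ref: ReferenceGenome, k: int = 20) -> "GenomePack":
        genomes = make_converted_genomes(ref)
        indexes = {tag: build_seed_index(g, k) for tag, g in genomes.items()}
        return cls(ref=ref, genomes=genomes, indexes=indexes, k=k)


def _write_fasta(path: Path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def save_genome_pack(out_dir: str | Path, pack: GenomePack) -> Path:
    """Persist a genome pack: source FASTA, four converted FASTAs, indexes, metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta(out / "source.fa", pack.ref.sequences)
    for tag, genome in pack.genomes.items():
        _write_fasta(out / f"{tag}.fa", genome.sequences)
        pack.indexes[tag].save(out / f"index.{tag}.npz")
    meta = {
        "format_version": PACK_FORMAT_VERSION,
        "k": pack.k,
        "source_checksum": pack.checksum,
        "sequences": pack.ref.lengths,
        "tags": list(TAGS),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def load_genome_pack(
    pack_dir: str | Path, expect_fasta: Optional[str | Path] = None
) -> GenomePack:
    """Load a genome pack; round-trip inverse of :func:`save_genome_pack`.

    If ``expect_fasta`` is given, its checksum is compared with the pack's
    recorded source checksum and a :class:`PackChecksumWarning` is issued on
    mismatch.
    """
    pack_dir = Path(pack_dir)
    meta_path = pack_dir / "meta.json"
    if not meta_path.exists():
        raise PackError(f"not a genome pack: missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    k = int(meta["k"])

    src = pack_dir / "source.fa"
    if not src.exists():
        raise PackError(f"genome pack missing component: {src}")
    ref = ReferenceGenome.from_fasta(src)

    genomes: Dict[str, ConvertedGenome] = {}
    indexes: Dict[str, SeedIndex] = {}
    lengths = ref.lengths
    for tag in TAGS:
        fa = pack_dir / f"{tag}.fa"
        idx = pack_dir / f"index.{tag}.npz"
        if not fa.exists():
            raise PackError(f"genome pack missing component: {fa}")
        if not idx.exists():
            raise PackError(f"genome pack missing component: {idx}")
        seqs = dict(_iter_fasta(fa))
        genomes[tag] = ConvertedGenome(tag=tag, sequences=seqs, source_lengths=dict(lengths))
        indexes[tag] = SeedIndex.load(idx, k, genomes[tag])

    pack = GenomePack(
        ref=ref, genomes=genomes, indexes=indexes, k=k,
        checksum=str(meta.get("source_checksum", "")),
    )
    if pack.checksum != ref.checksum():
        raise PackError("genome pack source.fa does not match recorded checksum")
    if expect_fasta is not None:
        supplied = ReferenceGenome.from_fasta(expect_fasta).checksum()
        if supplied != pack.checksum:
            warnings.warn(
                f"genome pack {pack_dir} was built from a FASTA with checksum "
                f"{pack.checksum}, supplied FASTA has {supplied}",
                PackChecksumWarning,
                stacklevel=2,
            )
    return pack
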