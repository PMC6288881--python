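"""Bisulfite read simulator with truth records, plus evaluation metrics.

Reads are drawn uniformly from a (synthetic or supplied) genome, given a
per-cytosine methylation state by context, bisulfite-converted, and then
corrupted with substitution errors whose per-position probability follows
an exponential decay along the read: ``p_i = A * exp(-i / tau)`` with
``tau = L / 3`` and ``A`` normalized so the mean per-bp rate equals the
requested error rate.  Qualities encode ``p_i`` on the Phred scale.

Randomness is organised so that runs with the same seed but different
error rates share every other random choice (locus, strand class,
methylation, conversion, even the substituted bases): the error sets are
then nested in the error rate, which makes mappability/accuracy trends
directly comparable across rates.

Evaluation follows the standard simulated-read bookkeeping: TP = correctly
mapped, FP = incorrectly mapped, FN = unmapped (ambiguous counts as
unmapped); mappability = mapped/total, precision = TP/(TP+FP),
sensitivity = TP/(TP+FN), accuracy = TP/(TP+FP+FN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .genome_prep import (
    InvalidParameterError,
    ReferenceGenome,
    reverse_complement,
)
from .methyl_profiler import classify_context

ORIGIN_CLASSES = ("OT", "OB", "CTOT", "CTOB")

#: Watson-strand alignment orientation of each origin class.
ORIGIN_STRAND = {"OT": "+", "OB": "-", "CTOT": "-", "CTOB": "+"}

#: Strand whose cytosines the read's methylation states describe.
ORIGIN_CALL_STRAND = {"OT": "+", "OB": "-", "CTOT": "+", "CTOB": "-"}

TRUTH_COLUMNS = ("read_id", "seq", "pos", "strand", "origin", "cytosines")


class EvaluationError(ValueError):
    """Truth records do not cover the evaluated alignments."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (all probabilities in [0,1])."""

    n_reads: int
    read_len: int = 95
    library: str = "non-directional"
    error_rate: float = 0.0
    conversion_rate: float = 1.0
    p_cpg: float = 0.7
    p_chg: float = 0.02
    p_chh: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise InvalidParameterError("n_reads must be >= 1")
        for name in ("error_rate", "conversion_rate", "p_cpg", "p_chg", "p_chh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0,1]")
        if self.library not in ("directional", "non-directional"):
            raise InvalidParameterError(f"unknown library {self.library!r}")

    @property
    def context_probs(self) -> Dict[str, float]:
        return {"CpG": self.p_cpg, "CHG": self.p_chg, "CHH": self.p_chh}


@dataclass(frozen=True)
class TruthCytosine:
    watson_pos: int
    strand: str
    context: str
    methylated: bool


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    seq_name: str
    watson_pos: int
    strand: str
    origin: str
    cytosines: Tuple[TruthCytosine, ...]


def synth_genome(
    length: int,
    gc: float = 0.41,
    repeat_spec: Optional[Dict[str, int]] = None,
    seed: int = 0,
    name: str = "synth1",
) -> ReferenceGenome:
    """Deterministic random genome with optional planted duplicate blocks.

    ``repeat_spec``: {"block_len": L, "n_copies": c} copies one random block
    to c-1 additional positions (overwriting), creating mapping ambiguity.
    """
    if length < 1:
        raise InvalidParameterError("genome length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise InvalidParameterError(f"gc={gc} outside [0,1]")
    rng = np.random.default_rng([seed, 0xFEED])
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    if repeat_spec:
        block_len = int(repeat_spec["block_len"])
        n_copies = int(repeat_spec.get("n_copies", 2))
        if block_len > length or n_copies < 2:
            raise InvalidParameterError(f"infeasible repeat_spec {repeat_spec!r}")
        src = int(rng.integers(0, length - block_len + 1))
        block = bases[src : src + block_len].copy()
        for _ in range(n_copies - 1):
            dst = int(rng.integers(0, length - block_len + 1))
            bases[dst : dst + block_len] = block
    return ReferenceGenome({name: bases.tobytes().decode("ascii")})


def error_profile(read_len: int, error_rate: float) -> np.ndarray:
    """Per-position error probabilities: truncated exponential decay.

    ``p_i = A * exp(-i / tau)`` with ``tau = read_len / 3``; A is chosen so
    that ``mean(p_i) == error_rate`` (values are capped at 0.95, which only
    binds at extreme rates).
    """
    if error_rate == 0.0:
        return np.zeros(read_len)
    tau = read_len / 3.0
    shape = np.exp(-np.arange(read_len) / tau)
    amp = error_rate * read_len / shape.sum()
    return np.minimum(amp * shape, 0.95)


def quality_string(p: np.ndarray) -> str:
    """Phred(+33) encoding of per-position error probabilities (Q clamped 2..40)."""
    with np.errstate(divide="ignore"):
        q = np.where(p > 0, -10.0 * np.log10(np.maximum(p, 1e-10)), 40.0)
    q = np.clip(np.rint(q), 2, 40).astype(int)
    return "".join(chr(33 + v) for v in q)


def _convert_fragment(
    ref: ReferenceGenome,
    seq_name: str,
    pos: int,
    read_len: int,
    biological_strand: str,
    cfg: SimConfig,
    rng_meth: np.random.Generator,
    rng_conv: np.random.Generator,
) -> Tuple[str, List[TruthCytosine]]:
    """Bisulfite-convert one fragment on its biological strand.

    Returns the converted fragment in the biological strand's 5'->3'
    orientation plus the drawn truth methylation states (Watson coords).
    """
    watson = ref.sequences[seq_name][pos : pos + read_len]
    if biological_strand == "+":
        frag = list(watson)
    else:
        frag = list(reverse_complement(watson))
    probs = cfg.context_probs
    cytosines: List[TruthCytosine] = []
    for j, base in enumerate(frag):
        if base != "C":
            continue
        wpos = pos + j if biological_strand == "+" else pos + read_len - 1 - j
        context, _ = classify_context(ref, seq_name, wpos, biological_strand)
        methylated = bool(rng_meth.random() < probs[context])
        if not methylated and rng_conv.random() < cfg.conversion_rate:
            frag[j] = "T"
        cytosines.append(
            TruthCytosine(
                watson_pos=wpos,
                strand=biological_strand,
                context=context,
                methylated=methylated,
            )
        )
    return "".join(frag), cytosines


def simulate_read(
    cfg: SimConfig,
    ref: ReferenceGenome,
    index: int,
    profile: np.ndarray,
    seq_names: Sequence[str],
    seq_weights: np.ndarray,
) -> Tuple[str, str, TruthRecord]:
    """Generate one read: (sequence, quality, truth).

    Independent child RNG streams per purpose keep everything except the
    error events identical across error rates (common random numbers).
    """
    L = cfg.read_len
    rng_loc = np.random.default_rng([cfg.seed, index, 0])
    rng_meth = np.random.default_rng([cfg.seed, index, 1])
    rng_conv = np.random.default_rng([cfg.seed, index, 2])
    rng_err = np.random.default_rng([cfg.seed, index, 3])
    rng_sub = np.random.default_rng([cfg.seed, index, 4])

    si = int(rng_loc.choice(len(seq_names), p=seq_weights))
    seq_name = seq_names[si]
    seq_len = len(ref.sequences[seq_name])
    pos = int(rng_loc.integers(0, seq_len - L + 1))
    classes = ORIGIN_CLASSES if cfg.library == "non-directional" else ORIGIN_CLASSES[:2]
    origin = str(classes[int(rng_loc.integers(0, len(classes)))])

    bio_strand = ORIGIN_CALL_STRAND[origin]
    converted, cytosines = _convert_fragment(
        ref, seq_name, pos, L, bio_strand, cfg, rng_meth, rng_conv
    )
    # CTOT/CTOB reads are the complements of the converted OT/OB molecules.
    read_seq = converted if origin in ("OT", "OB") else reverse_complement(converted)

    # Positional errors; the uniforms are drawn for every position so the
    # substituted bases at shared error positions match across error rates.
    u_err = rng_err.random(L)
    u_sub = rng_sub.random(L)
    if cfg.error_rate > 0:
        arr = bytearray(read_seq, "ascii")
        letters = b"ACGT"
        for i in np.nonzero(u_err < profile)[0]:
            orig = arr[i]
            k = letters.find(orig)
            if k < 0:  # N stays N
                continue
            arr[i] = letters[(k + 1 + int(u_sub[i] * 3)) % 4]
        read_seq = arr.decode("ascii")

    read_id = f"simread_{index:07d}"
    truth = TruthRecord(
        read_id=read_id,
        seq_name=seq_name,
        watson_pos=pos,
        strand=ORIGIN_STRAND[origin],
        origin=origin,
        cytosines=tuple(cytosines),
    )
    return read_seq, quality_string(profile), truth


def iter_simulated(cfg: SimConfig, ref: ReferenceGenome) -> Iterator[Tuple[str, str, TruthRecord]]:
    L = cfg.read_len
    seq_names = list(ref.sequences)
    spans = np.array(
        [len(ref.sequences[n]) - L + 1 for n in seq_names], dtype=float
    )
    if (spans <= 0).any():
        raise InvalidParameterError(
            f"read_len={L} exceeds a reference sequence length"
        )
    weights = spans / spans.sum()
    profile = error_profile(L, cfg.error_rate)
    for i in range(cfg.n_reads):
        yield simulate_read(cfg, ref, i, profile, seq_names, weights)


def _cytosines_to_text(cytosines: Sequence[TruthCytosine]) -> str:
    if not cytosines:
        return "."
    return ";".join(
        f"{c.watson_pos}:{c.strand}:{c.context}:{'M' if c.methylated else 'U'}"
        for c in cytosines
    )


def _cytosines_from_text(text: str) -> Tuple[TruthCytosine, ...]:
    if text in (".", ""):
        return ()
    out = []
    for item in text.split(";"):
        pos, strand, context, state = item.split(":")
        out.append(
            TruthCytosine(
                watson_pos=int(pos),
                strand=strand,
                context=context,
                methylated=(state == "M"),
            )
        )
    return tuple(out)


def simulate_reads(
    cfg: SimConfig, ref: ReferenceGenome, out_prefix: str | Path
) -> Tuple[Path, Path]:
    """Write <prefix>.fastq and <prefix>.truth.tsv; returns both paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fastq = Path(f"{out_prefix}.fastq")
    truth_path = Path(f"{out_prefix}.truth.tsv")
    with open(fastq, "w") as fq, open(truth_path, "w") as tr:
        tr.write("\t".join(TRUTH_COLUMNS) + "\n")
        for seq, qual, truth in iter_simulated(cfg, ref):
            fq.write(f"@{truth.read_id}\n{seq}\n+\n{qual}\n")
            tr.write(
                f"{truth.read_id}\t{truth.seq_name}\t{truth.watson_pos}\t"
                f"{truth.strand}\t{truth.origin}\t"
                f"{_cytosines_to_text(truth.cytosines)}\n"
            )
    return fastq, truth_path


def read_truth(path: str | Path) -> Dict[str, TruthRecord]:
    """Load a truth TSV keyed by read id."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise EvaluationError(f"truth file {path} missing columns {sorted(missing)}")
    out: Dict[str, TruthRecord] = {}
    for row in df.itertuples(index=False):
        out[row.read_id] = TruthRecord(
            read_id=row.read_id,
            seq_name=row.seq,
            watson_pos=int(row.pos),
            strand=row.strand,
            origin=row.origin,
            cytosines=_cytosines_from_text(row.cytosines),
        )
    return out


@dataclass(frozen=True)
class EvalMetrics:
    """TP/FP/FN and the four derived fractions for a run against truth."""

    tp: int
    fp: int
    fn: int
    total: int
    mappability: float
    precision: float
    sensitivity: float
    accuracy: float
    undefined: Tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> Dict[str, object]:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "total": self.total,
            "mappability": self.mappability,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "accuracy": self.accuracy,
            "undefined": list(self.undefined),
        }


def compute_metrics(tp: int, fp: int, fn: int, total: int) -> EvalMetrics:
    """Instantiate the metric formulas; undefined ratios become NaN + flag."""
    mapped = tp + fp
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    return EvalMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        total=total,
        mappability=ratio(mapped, total, "mappability"),
        precision=ratio(tp, mapped, "precision"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        accuracy=ratio(tp, tp + fp + fn, "accuracy"),
        undefined=tuple(undefined),
    )


def evaluate(
    sam_path: str | Path,
    truth_path: str | Path,
    tolerance: int = 0,
) -> EvalMetrics:
    """Score a SAM against truth records.

    A mapped read is correct iff its (sequence, Watson position, strand)
    match truth within ``tolerance`` bases (0 = exact).  Reads absent from
    the SAM (unmapped or discarded as ambiguous) count as FN.
    """
    import pysam

    truth = read_truth(truth_path)
    tp = fp = 0
    seen = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            rid = rec.query_name
            rec_truth = truth.get(rid)
            if rec_truth is None:
                raise EvaluationError(f"read {rid!r} in SAM has no truth record")
            if rid in seen:
                raise EvaluationError(f"read {rid!r} reported more than once")
            seen.add(rid)
            strand = "-" if rec.is_reverse else "+"
            correct = (
                rec.reference_name == rec_truth.seq_name
                and strand == rec_truth.strand
                and abs(rec.reference_start - rec_truth.watson_pos) <= tolerance
            )
            if correct:
                tp += 1
            else:
                fp += 1
    total = len(truth)
    fn = total - tp - fp
    return compute_metrics(tp, fp, fn, total)


def truth_site_levels(
    truth: Dict[str, TruthRecord],
    resolved_ids: Optional[set] = None,
) -> Dict[Tuple[str, int, str], Tuple[str, int, int]]:
    """Per-site (context, n_meth, n_unmeth) implied by truth records.

    Restricted to ``resolved_ids`` when given, so the comparison against
    pipeline aggregation covers exactly the same reads.
    """
    acc: Dict[Tuple[str, int, str], List] = {}
    for rid, rec in truth.items():
        if resolved_ids is not None and rid not in resolved_ids:
            continue
        for c in rec.cytosines:
            key = (rec.seq_name, c.watson_pos, c.strand)
            entry = acc.setdefault(key, [c.context, 0, 0])
            entry[1 if c.methylated else 2] += 1
    return {k: (v[0], v[1], v[2]) for k, v in acc.items()}
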