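"""Keyed-partition data-flow executor with deterministic hash partitioning.

A local stand-in for a distributed key-value engine: records live in
explicit partitions, a portable hash decides placement, co-partitioned
streams can be unioned without any cross-partition movement, and every
record move is counted so shuffle-avoidance contracts can be asserted.

``run_pipeline`` wires the four alignment phases over this engine.  In
balance mode it re-hashes partitions at the two known imbalance points:
right after input load (chunked input gives unequal partitions) and right
after best-alignment filtering (per-partition survival rates differ).
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Dict, Iterable, List, Optional, Sequence, Tuple

from . import aligner_core, genome_prep, methyl_profiler, read_transform, resolver

logger = logging.getLogger(__name__)

FNV64_OFFSET_BASIS = 14695981039346656037
FNV64_PRIME = 1099511628211
_MASK64 = (1 << 64) - 1


class ContractViolationError(RuntimeError):
    """A partitioning contract (co-partitioning, stream shape) was violated."""


def fnv1a64(data: bytes) -> int:
    """FNV-1a 64-bit hash; deterministic across runs, platforms and processes."""
    h = FNV64_OFFSET_BASIS
    for byte in data:
        h = ((h ^ byte) * FNV64_PRIME) & _MASK64
    return h


def portable_hash(key: Any) -> int:
    """Deterministic 64-bit hash of a record key (str or bytes)."""
    if isinstance(key, str):
        key = key.encode("utf-8")
    elif not isinstance(key, (bytes, bytearray)):
        key = repr(key).encode("utf-8")
    return fnv1a64(bytes(key))


@dataclass
class PartitionedStream:
    """Keyed records laid out in explicit partitions.

    ``partitioner_id`` identifies the hash function + partition count that
    placed the records (or a chunking token for file-order input); streams
    derived per-partition inherit it, which is what makes a later union
    shuffle-free.
    """

    partitions: List[List[Tuple[Any, Any]]]
    partitioner_id: Optional[str] = None

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    def sizes(self) -> List[int]:
        return [len(p) for p in self.partitions]

    def records(self) -> Iterable[Tuple[Any, Any]]:
        for part in self.partitions:
            yield from part

    def count(self) -> int:
        return sum(self.sizes())


def hash_partitioner_id(n: int) -> str:
    return f"fnv1a64%{n}"


def _hash_part(key: Any, n: int) -> int:
    return portable_hash(key) % n


def partition_by_hash(records: Iterable[Tuple[Any, Any]], n: int) -> PartitionedStream:
    """Place records into ``portable_hash(key) mod n`` partitions."""
    if n < 1:
        raise ContractViolationError(f"n_partitions={n} must be >= 1")
    parts: List[List[Tuple[Any, Any]]] = [[] for _ in range(n)]
    for key, value in records:
        parts[_hash_part(key, n)].append((key, value))
    return PartitionedStream(partitions=parts, partitioner_id=hash_partitioner_id(n))


_CHUNK_TOKEN = 0


def partition_by_chunks(records: Sequence[Tuple[Any, Any]], n: int) -> PartitionedStream:
    """Split records into n contiguous file-order chunks (HDFS-style input).

    Each call gets a fresh chunk token: two independently chunked streams are
    never considered co-partitioned, but streams derived from this one are.
    """
    global _CHUNK_TOKEN
    if n < 1:
        raise ContractViolationError(f"n_partitions={n} must be >= 1")
    _CHUNK_TOKEN += 1
    size, extra = divmod(len(records), n)
    parts, start = [], 0
    for i in range(n):
        stop = start + size + (1 if i < extra else 0)
        parts.append(list(records[start:stop]))
        start = stop
    return PartitionedStream(partitions=parts, partitioner_id=f"chunk#{_CHUNK_TOKEN}%{n}")


def repartition(stream: PartitionedStream, n: int) -> Tuple[PartitionedStream, int]:
    """Re-hash every record into ``portable_hash(key) mod n`` partitions.

    Returns the new stream and the number of records that changed partition
    (the shuffle cost).  Re-running with the same hash and n moves nothing.
    """
    if n < 1:
        raise ContractViolationError(f"n_partitions={n} must be >= 1")
    parts: List[List[Tuple[Any, Any]]] = [[] for _ in range(n)]
    moved = 0
    for i, part in enumerate(stream.partitions):
        for key, value in part:
            j = _hash_part(key, n)
            parts[j].append((key, value))
            if j != i:
                moved += 1
    return PartitionedStream(partitions=parts, partitioner_id=hash_partitioner_id(n)), moved


def co_union(streams: Sequence[PartitionedStream]) -> PartitionedStream:
    """Union co-partitioned streams partition-by-partition, moving nothing.

    All inputs must share the same partitioner id and partition count;
    partition i of the output is the concatenation of partition i of each
    input (the zero-shuffle merge).
    """
    if not streams:
        raise ContractViolationError("co_union of zero streams")
    pid = streams[0].partitioner_id
    n = streams[0].n_partitions
    for s in streams[1:]:
        if s.n_partitions != n:
            raise ContractViolationError(
                f"co_union partition count mismatch: {s.n_partitions} != {n}"
            )
        if s.partitioner_id != pid or pid is None:
            raise ContractViolationError(
                f"co_union partitioner mismatch: {s.partitioner_id!r} != {pid!r}"
            )
    parts = [
        [rec for s in streams for rec in s.partitions[i]] for i in range(n)
    ]
    return PartitionedStream(partitions=parts, partitioner_id=pid)


def map_partitions(
    stream: PartitionedStream,
    fn: Callable[[List[Tuple[Any, Any]]], List[Tuple[Any, Any]]],
) -> PartitionedStream:
    """Apply a per-partition function; partitioning is preserved."""
    return PartitionedStream(
        partitions=[fn(part) for part in stream.partitions],
        partitioner_id=stream.partitioner_id,
    )


def group_by_key_local(stream: PartitionedStream) -> PartitionedStream:
    """Group records by key within each partition (no movement)."""

    def _group(part: List[Tuple[Any, Any]]) -> List[Tuple[Any, List[Any]]]:
        grouped: Dict[Any, List[Any]] = {}
        for key, value in part:
            grouped.setdefault(key, []).append(value)
        return list(grouped.items())

    return map_partitions(stream, _group)


def skew(sizes: Sequence[int]) -> float:
    """max/mean partition size (1.0 = perfectly even; inf if empty mean)."""
    if not sizes or sum(sizes) == 0:
        return float("inf")
    mean = sum(sizes) / len(sizes)
    return max(sizes) / mean


# --------------------------------------------------------------------------
# Pipeline over the engine


@dataclass
class PipelineConfig:
    pack_dir: Optional[str] = None
    reads_path: Optional[str] = None
    out_sam: Optional[str] = None
    library: str = "non-directional"
    max_mm: int = aligner_core.DEFAULT_MAX_MISMATCH
    min_mean_q: float = 0.0
    n_partitions: Optional[int] = None
    workers: int = 1
    balance: bool = False
    site_tsv: Optional[str] = None

    def resolved_partitions(self) -> int:
        return self.n_partitions if self.n_partitions else max(1, self.workers) * 4


@dataclass
class RunResult:
    resolved: List[resolver.ResolvedAlignment]
    calls: List[methyl_profiler.MethylationCall]
    stats: Dict[str, Any]


# Per-worker broadcast of the genome pack: loaded once per process, reused by
# every partition task that lands there.
_WORKER_PACK: Optional[genome_prep.GenomePack] = None
_WORKER_FRESH = False


def _init_worker(pack_dir: str) -> None:
    global _WORKER_PACK, _WORKER_FRESH
    _WORKER_PACK = genome_prep.load_genome_pack(pack_dir)
    _WORKER_FRESH = True


def _take_staging_flag() -> int:
    global _WORKER_FRESH
    if _WORKER_FRESH:
        _WORKER_FRESH = False
        return 1
    return 0


def _phase2_task(
    part: List[Tuple[str, read_transform.ReadRecord]],
    library: str,
    max_mm: int,
    min_mean_q: float,
) -> Dict[str, Any]:
    """Quality-filter, transform and align one partition of reads."""
    pack = _WORKER_PACK
    staged = _take_staging_flag()
    hit_parts: Dict[str, List[Tuple[str, aligner_core.AlignmentHit]]] = {
        tag: [] for tag in genome_prep.TAGS
    }
    read_part: List[Tuple[str, Tuple[str, str]]] = []  # (rid, ("seq", orig))
    dropped = 0
    for rid, rec in part:
        if not read_transform.quality_filter(rec, min_mean_q):
            dropped += 1
            continue
        read_part.append((rid, ("seq", rec.seq)))
        for tr in read_transform.transforms_for_library(rec, library):
            for conv, tag in aligner_core.candidate_pairs(library):
                if conv != tr.conv:
                    continue
                for hit in aligner_core.align_read(
                    tr, pack.genomes[tag], pack.indexes[tag], max_mm
                ):
                    hit_parts[tag].append((rid, hit))
    return {
        "hits": hit_parts,
        "reads": read_part,
        "dropped": dropped,
        "staged": staged,
    }


def _phase4_task(
    part: List[Tuple[str, resolver.ResolvedAlignment]],
) -> Dict[str, Any]:
    """Call methylation for one partition of resolved alignments."""
    pack = _WORKER_PACK
    staged = _take_staging_flag()
    out = []
    for rid, aln in part:
        out.append((rid, methyl_profiler.call_read(aln, pack.ref)))
    return {"calls": out, "staged": staged}


def run_pipeline(
    config: PipelineConfig,
    pack: Optional[genome_prep.GenomePack] = None,
    records: Optional[List[read_transform.ReadRecord]] = None,
) -> RunResult:
    """Execute the four pipeline phases over the partitioned engine.

    ``pack``/``records`` may be passed directly (tests, library use); with
    ``workers > 1`` a ``pack_dir`` is required so each worker process can
    stage the reference once.
    """
    if pack is None:
        if config.pack_dir is None:
            raise ContractViolationError("no genome pack supplied")
        pack = genome_prep.load_genome_pack(config.pack_dir)
    if records is None:
        if config.reads_path is None:
            raise ContractViolationError("no reads supplied")
        records = list(read_transform.read_fastx(config.reads_path))

    n_parts = config.resolved_partitions()
    stats: Dict[str, Any] = {
        "total_reads": len(records),
        "library": config.library,
        "max_mismatch": config.max_mm,
        "n_partitions": n_parts,
        "workers": config.workers,
        "balance": config.balance,
        "moved_after_load": 0,
        "moved_after_filter": 0,
        "phase3_merge_moved": 0,
        "broadcast_stagings": 0,
    }

    # Phase 1: key-value records, chunked like file input.
    keyed = [(r.read_id, r) for r in records]
    stream = partition_by_chunks(keyed, n_parts)
    stats["partition_sizes_input"] = stream.sizes()
    if config.balance:
        stream, moved = repartition(stream, n_parts)
        stats["moved_after_load"] = moved
    stats["partition_sizes_phase1"] = stream.sizes()

    # Phase 2: per-partition transform + align (worker processes if asked).
    global _WORKER_PACK, _WORKER_FRESH
    use_pool = config.workers > 1
    if use_pool:
        if config.pack_dir is None:
            raise ContractViolationError("workers > 1 requires pack_dir")
        with ProcessPoolExecutor(
            max_workers=config.workers,
            initializer=_init_worker,
            initargs=(str(config.pack_dir),),
        ) as pool:
            phase2 = list(
                pool.map(
                    _phase2_task,
                    stream.partitions,
                    [config.library] * n_parts,
                    [config.max_mm] * n_parts,
                    [config.min_mean_q] * n_parts,
                )
            )
    else:
        _WORKER_PACK, _WORKER_FRESH = pack, True
        phase2 = [
            _phase2_task(part, config.library, config.max_mm, config.min_mean_q)
            for part in stream.partitions
        ]

    stats["quality_dropped"] = sum(r["dropped"] for r in phase2)
    stats["broadcast_stagings"] += sum(r["staged"] for r in phase2)

    # Four mapRDD streams + the carried-read stream, all inheriting the
    # phase-1 partitioner (derived per-partition, hence co-partitioned).
    pid = stream.partitioner_id
    map_streams = {
        tag: PartitionedStream(
            partitions=[r["hits"][tag] for r in phase2], partitioner_id=pid
        )
        for tag in genome_prep.TAGS
    }
    read_stream = PartitionedStream(
        partitions=[r["reads"] for r in phase2], partitioner_id=pid
    )

    # Phase 3: zero-shuffle merge, group by read id, unique-best selection.
    merged = resolver.merge_copartitioned(
        [read_stream] + [map_streams[tag] for tag in genome_prep.TAGS]
    )
    stats["phase3_merge_moved"] = 0  # co_union raised if movement were needed

    resolved_parts: List[List[Tuple[str, resolver.ResolvedAlignment]]] = []
    n_resolved = n_ambiguous = n_unmapped = 0
    for part in merged.partitions:
        out_part = []
        for rid, values in part:
            orig_seq = None
            hits = []
            for v in values:
                if isinstance(v, tuple) and v and v[0] == "seq":
                    orig_seq = v[1]
                else:
                    hits.append(v)
            status, aln = resolver.select_best(
                hits, config.max_mm, pack.ref.lengths, orig_seq=orig_seq
            )
            if status == resolver.RESOLVED:
                out_part.append((rid, aln))
                n_resolved += 1
            elif status == resolver.AMBIGUOUS:
                n_ambiguous += 1
            else:
                n_unmapped += 1
        resolved_parts.append(out_part)
    resolved_stream = PartitionedStream(partitions=resolved_parts, partitioner_id=pid)
    stats.update(resolved=n_resolved, ambiguous=n_ambiguous, unmapped=n_unmapped)
    stats["partition_sizes_filtered"] = resolved_stream.sizes()

    if config.balance:
        resolved_stream, moved = repartition(resolved_stream, n_parts)
        stats["moved_after_filter"] = moved
    stats["partition_sizes_phase4"] = resolved_stream.sizes()

    # Phase 4: methylation profiling (reference broadcast once per worker).
    if use_pool:
        with ProcessPoolExecutor(
            max_workers=config.workers,
            initializer=_init_worker,
            initargs=(str(config.pack_dir),),
        ) as pool:
            phase4 = list(pool.map(_phase4_task, resolved_stream.partitions))
    else:
        _WORKER_PACK, _WORKER_FRESH = pack, True
        phase4 = [_phase4_task(part) for part in resolved_stream.partitions]
    stats["broadcast_stagings"] += sum(r["staged"] for r in phase4)

    calls_by_id = {rid: call for r in phase4 for rid, call in r["calls"]}
    resolved_alns = sorted(
        (aln for _, aln in resolved_stream.records()),
        key=lambda a: (a.seq_name, a.watson_pos, a.read_id),
    )
    calls = [calls_by_id[a.read_id] for a in resolved_alns]

    if config.out_sam:
        methyl_profiler.write_sam(
            list(zip(resolved_alns, calls)), pack.ref, config.out_sam
        )
    if config.site_tsv:
        sites = methyl_profiler.aggregate_sites(calls)
        methyl_profiler.write_site_tsv(sites, config.site_tsv)

    assert (
        stats["total_reads"]
        == n_resolved + n_ambiguous + n_unmapped + stats["quality_dropped"]
    ), "read count conservation violated"
    return RunResult(resolved=resolved_alns, calls=calls, stats=stats)


def write_stats(stats: Dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats, indent=2, sort_keys=True))
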