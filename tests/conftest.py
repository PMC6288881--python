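"""Shared fixtures and the independent brute-force alignment oracle."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from trialign import genome_prep as gp
from trialign import read_transform as rt
from trialign import simeval as se

_COMP = str.maketrans("ACGTN", "TGCAN")


def oracle_revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def oracle_resolve(
    ref_seqs: Dict[str, str],
    orig_seq: str,
    max_mm: int,
    library: str = "non-directional",
) -> Tuple[str, Optional[Tuple[str, int, str, int]]]:
    """Brute-force all-offset, all-four-genome resolution of one read.

    Independent of the package's seeded aligner: conversions are done with
    str.replace, every offset of every converted genome is Hamming-scored
    with a sliding window, coincident placements are collapsed to their
    minimum, and the unique-least-mismatch rule is applied.

    Returns (status, (seq_name, watson_pos, strand, mismatches) | None).
    """
    reads = {"CT": orig_seq.replace("C", "T"), "GA": orig_seq.replace("G", "A")}
    if library == "non-directional":
        pairs = [("CT", "W-CT"), ("CT", "C-CT"), ("GA", "W-GA"), ("GA", "C-GA")]
    else:
        pairs = [("CT", "W-CT"), ("CT", "C-CT")]
    L = len(orig_seq)
    placements: Dict[Tuple[str, int, str], int] = {}
    for conv, tag in pairs:
        read = np.frombuffer(reads[conv].encode(), np.uint8)
        for name, watson in ref_seqs.items():
            g = watson if tag.startswith("W") else oracle_revcomp(watson)
            g = g.replace("C", "T") if tag.endswith("CT") else g.replace("G", "A")
            if L > len(g):
                continue
            garr = np.frombuffer(g.encode(), np.uint8)
            mms = (sliding_window_view(garr, L) != read).sum(axis=1)
            strand = "+" if tag.startswith("W") else "-"
            for p in np.nonzero(mms <= max_mm)[0]:
                wpos = int(p) if strand == "+" else len(g) - int(p) - L
                key = (name, wpos, strand)
                mm = int(mms[p])
                if mm < placements.get(key, max_mm + 1):
                    placements[key] = mm
    if not placements:
        return "unmapped", None
    best_mm = min(placements.values())
    best = [(k, v) for k, v in placements.items() if v == best_mm]
    if len(best) > 1:
        return "ambiguous", None
    (name, wpos, strand), mm = best[0]
    return "resolved", (name, wpos, strand, mm)


def sim_records(
    cfg: se.SimConfig, ref: gp.ReferenceGenome
) -> Tuple[List[rt.ReadRecord], Dict[str, se.TruthRecord]]:
    """Materialize simulated reads as records plus their truth map."""
    records, truths = [], {}
    for seq, qual, truth in se.iter_simulated(cfg, ref):
        records.append(rt.ReadRecord(truth.read_id, seq, qual))
        truths[truth.read_id] = truth
    return records, truths


@pytest.fixture(scope="session")
def toy_ref() -> gp.ReferenceGenome:
    return gp.ReferenceGenome({"chr1": "AACG"})


@pytest.fixture(scope="session")
def small_ref() -> gp.ReferenceGenome:
    return se.synth_genome(4000, gc=0.45, seed=11)


@pytest.fixture(scope="session")
def small_pack(small_ref) -> gp.GenomePack:
    return gp.GenomePack.build(small_ref, k=12)


@pytest.fixture(scope="session")
def small_sim(small_ref):
    cfg = se.SimConfig(n_reads=300, read_len=60, seed=7)
    return sim_records(cfg, small_ref)
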