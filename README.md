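# trialign

A self-contained three-letter bisulfite-sequencing alignment toolkit:

- **Genome preparation** — builds the four converted reference genomes
  (Watson/Crick strand × C→T / G→A) with exact k-mer seed indexes, persisted
  as a reusable *genome pack* directory.
- **Alignment** — converts each read in silico (C→T and, for non-directional
  libraries, G→A), maps every form end-to-end and ungapped against its
  candidate converted genomes by seed-and-extend, then keeps only the
  alignment with the *uniquely least* number of mismatches; ties are
  discarded as ambiguous. Crick hits are lifted back to Watson coordinates.
- **Methylation profiling** — compares each resolved read with the original
  (unconverted) reference, emits Bismark-style per-read call strings
  (`Z/z` CpG, `X/x` CHG, `H/h` CHH; uppercase = methylated) in SAM, and
  aggregates per-site methylation levels to TSV.
- **Parallel engine** — a local keyed-partition executor mirroring a
  distributed data-flow: deterministic FNV-1a-64 hash partitioning,
  zero-shuffle co-partitioned union for merging the four hit streams,
  optional `--balance` re-partitioning at the two load-imbalance points
  (after input load and after best-alignment filtering), and movement
  counters that make the shuffle-avoidance contracts testable. Plain and
  balance modes produce identical output.
- **Simulator + evaluation** — a bisulfite read simulator (OT/OB/CTOT/CTOB
  origins, per-context methylation probabilities, exponential-decay
  positional error model, truth records) and the standard simulated-read
  metrics: mappability, precision, sensitivity, accuracy from TP/FP/FN.

## CLI

```sh
# 1. build the genome pack (four converted genomes + indexes)
trialign prepare-genome --fasta genome.fa --out pack/ --seed-len 20

# 2. (optional) simulate reads with truth records
trialign simulate --out-prefix sim --n-reads 50000 --read-len 95 \
    --error-rate 0.01 --seed 42 --synth-len 1000000

# 3. align (writes SAM + run-statistics JSON; --balance enables re-hashing)
trialign align --genome-pack pack/ --reads sim.fastq --out out.sam \
    --partitions 8 --balance --max-mismatch 4 --library non-directional \
    --site-tsv sites.tsv

# 4. score against simulator truth
trialign evaluate --sam out.sam --truth sim.truth.tsv --out metrics.json

# 5. per-site methylation report from an existing SAM
trialign methyl-report --sam out.sam --genome-pack pack/ --out sites.tsv
```

Every command writes its resolved configuration as `<output>.config.json`
for provenance. A flat `key=value` file can pre-set options via
`--config`; explicit flags win.

## Output formats

- **SAM** — FLAG 0/16 by strand, MAPQ 255, CIGAR `<L>M`, tags `NM:i`
  (mismatches in converted space), `ZC:Z` (conversion pair: W-CT, W-GA,
  C-CT, C-GA), `ZM:Z` (call string, oriented with SEQ).
- **Site TSV** — `seq, pos (1-based), strand, context, n_meth, n_unmeth,
  level`.
- **Truth TSV** — `read_id, seq, pos (0-based Watson), strand, origin,
  cytosines` where `cytosines` is `pos:strand:context:M|U` entries joined
  by `;` (`.` if none).
- **Run statistics JSON** — read accounting (resolved/ambiguous/unmapped/
  quality-dropped), per-stage partition sizes, records moved by each
  repartition, and the phase-3 merge movement counter (always 0).

## Notes & limits

- Alignment is ungapped and end-to-end; with seed length k and read length
  L, any placement with at most `floor(L/k) - 1` mismatches is guaranteed
  to be found (0-mismatch recall is exact). Default `--max-mismatch 4`.
- Single-end reads only; no paired-end, trimming, or duplicate handling.
- An external SAM-emitting aligner can be adapted through
  `trialign.aligner_core.external_backend_align` (requires NM tags).
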