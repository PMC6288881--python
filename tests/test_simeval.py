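import math

import numpy as np
import pytest

from conftest import sim_records
from trialign import genome_prep as gp
from trialign import parallel_engine as pe
from trialign import read_transform as rt
from trialign import simeval as se


class TestSynthGenome:
    def test_seeded_determinism(self):
        a = se.synth_genome(5000, gc=0.5, seed=3)
        b = se.synth_genome(5000, gc=0.5, seed=3)
        assert a.sequences == b.sequences

    def test_different_seed_differs(self):
        a = se.synth_genome(5000, seed=3)
        b = se.synth_genome(5000, seed=4)
        assert a.sequences != b.sequences

    def test_gc_zero_is_at_only(self):
        g = se.synth_genome(2000, gc=0.0, seed=1)
        assert set(g.sequences["synth1"]) <= {"A", "T"}

    def test_gc_fraction_approximate(self):
        g = se.synth_genome(100_000, gc=0.41, seed=1)
        seq = g.sequences["synth1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.41) < 0.01

    def test_planted_repeat_block(self):
        g = se.synth_genome(
            20_000, seed=5, repeat_spec={"block_len": 2000, "n_copies": 2}
        )
        seq = g.sequences["synth1"]
        # the duplicated 2 kb block appears at least twice
        found = False
        for start in range(0, len(seq) - 2000):
            block = seq[start : start + 2000]
            first = seq.find(block)
            if first != -1 and seq.find(block, first + 1) != -1:
                found = True
                break
        assert found

    def test_infeasible_spec(self):
        with pytest.raises(gp.InvalidParameterError):
            se.synth_genome(100, repeat_spec={"block_len": 500, "n_copies": 2})


class TestErrorProfile:
    def test_zero_rate_is_zero(self):
        assert not se.error_profile(95, 0.0).any()

    def test_mean_matches_requested_rate(self):
        for e in (0.01, 0.02, 0.05):
            p = se.error_profile(95, e)
            assert np.mean(p) == pytest.approx(e, rel=1e-9)

    def test_exponential_decay_shape(self):
        p = se.error_profile(95, 0.02)
        assert (np.diff(p) < 0).all()  # strictly decaying
        tau = 95 / 3
        assert p[1] / p[0] == pytest.approx(math.exp(-1 / tau))

    def test_quality_encodes_profile(self):
        p = se.error_profile(10, 0.02)
        q = se.quality_string(p)
        assert len(q) == 10
        # early positions are noisier -> lower quality characters
        assert q[0] <= q[-1]


class TestSimulateReads:
    def test_byte_identical_determinism(self, small_ref, tmp_path):
        cfg = se.SimConfig(n_reads=50, read_len=40, seed=13, error_rate=0.01)
        f1, t1 = se.simulate_reads(cfg, small_ref, tmp_path / "a")
        f2, t2 = se.simulate_reads(cfg, small_ref, tmp_path / "b")
        assert f1.read_bytes() == f2.read_bytes()
        assert t1.read_bytes() == t2.read_bytes()

    def test_error_free_unmethylated_read_is_converted_fragment(self):
        # all-A/T/C genome fragment with p=0 everywhere collapses to CT(watson)
        ref = gp.ReferenceGenome({"s": "ACTACCATCA" * 20})
        cfg = se.SimConfig(
            n_reads=30, read_len=30, seed=2, p_cpg=0.0, p_chg=0.0, p_chh=0.0,
            library="directional",
        )
        for seq, _, truth in se.iter_simulated(cfg, ref):
            if truth.origin != "OT":
                continue
            frag = ref.sequences["s"][truth.watson_pos : truth.watson_pos + 30]
            assert seq == frag.replace("C", "T")

    def test_fully_methylated_cytosines_protected(self):
        ref = gp.ReferenceGenome({"s": "AACGAACGAA" * 20})
        cfg = se.SimConfig(
            n_reads=30, read_len=20, seed=2, p_cpg=1.0, p_chg=1.0, p_chh=1.0,
            library="directional",
        )
        for seq, _, truth in se.iter_simulated(cfg, ref):
            if truth.origin != "OT":
                continue
            frag = ref.sequences["s"][truth.watson_pos : truth.watson_pos + 20]
            assert seq == frag  # every methylated C kept

    def test_mean_error_count_matches_binomial_expectation(self, small_ref):
        e, L, n = 0.02, 95, 4000
        ref = se.synth_genome(20_000, seed=31)
        clean = se.SimConfig(n_reads=n, read_len=L, seed=77, error_rate=0.0)
        noisy = se.SimConfig(n_reads=n, read_len=L, seed=77, error_rate=e)
        diffs = [
            sum(a != b for a, b in zip(s1, s2))
            for (s1, _, _), (s2, _, _) in zip(
                se.iter_simulated(clean, ref), se.iter_simulated(noisy, ref)
            )
        ]
        mean = float(np.mean(diffs))
        expected = e * L  # 1.9
        sigma = math.sqrt(L * e * (1 - e) / n)
        assert abs(mean - expected) <= 3 * sigma

    def test_common_random_numbers_nest_error_sets(self):
        ref = se.synth_genome(10_000, seed=8)
        cfgs = [
            se.SimConfig(n_reads=60, read_len=60, seed=5, error_rate=e)
            for e in (0.0, 0.01, 0.02)
        ]
        runs = [list(se.iter_simulated(c, ref)) for c in cfgs]
        for (s0, _, t0), (s1, _, t1), (s2, _, t2) in zip(*runs):
            assert t0 == t1 == t2  # locus/class/methylation identical
            d01 = {i for i, (a, b) in enumerate(zip(s0, s1)) if a != b}
            d02 = {i for i, (a, b) in enumerate(zip(s0, s2)) if a != b}
            assert d01 <= d02  # error positions nest with the rate

    def test_directional_library_has_no_complement_classes(self):
        ref = se.synth_genome(5000, seed=9)
        cfg = se.SimConfig(n_reads=80, read_len=40, seed=9, library="directional")
        origins = {t.origin for _, _, t in se.iter_simulated(cfg, ref)}
        assert origins <= {"OT", "OB"}

    def test_non_directional_uses_all_classes(self):
        ref = se.synth_genome(5000, seed=9)
        cfg = se.SimConfig(n_reads=200, read_len=40, seed=9)
        origins = {t.origin for _, _, t in se.iter_simulated(cfg, ref)}
        assert origins == {"OT", "OB", "CTOT", "CTOB"}

    def test_truth_tsv_roundtrip(self, small_ref, tmp_path):
        cfg = se.SimConfig(n_reads=25, read_len=40, seed=4)
        _, truth_path = se.simulate_reads(cfg, small_ref, tmp_path / "x")
        loaded = se.read_truth(truth_path)
        original = {t.read_id: t for _, _, t in se.iter_simulated(cfg, small_ref)}
        assert loaded == original

    def test_invalid_config(self):
        with pytest.raises(gp.InvalidParameterError):
            se.SimConfig(n_reads=0)
        with pytest.raises(gp.InvalidParameterError):
            se.SimConfig(n_reads=1, error_rate=1.5)

    def test_read_longer_than_genome(self):
        ref = gp.ReferenceGenome({"s": "ACGT"})
        cfg = se.SimConfig(n_reads=1, read_len=10)
        with pytest.raises(gp.InvalidParameterError):
            list(se.iter_simulated(cfg, ref))


def _write_sam(path, mapped):
    lines = ["@HD\tVN:1.6", "@SQ\tSN:s\tLN:10000"]
    for rid, pos, strand in mapped:
        flag = 16 if strand == "-" else 0
        lines.append(
            f"{rid}\t{flag}\ts\t{pos + 1}\t255\t10M\t*\t0\t0\tAAAAAAAAAA\t*\tNM:i:0"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_truth(path, rows):
    lines = ["\t".join(se.TRUTH_COLUMNS)]
    for rid, pos, strand in rows:
        lines.append(f"{rid}\ts\t{pos}\t{strand}\tOT\t.")
    path.write_text("\n".join(lines) + "\n")


class TestEvaluate:
    def test_formula_instantiation(self, tmp_path):
        truth = [(f"r{i}", i * 10, "+") for i in range(100)]
        mapped = truth[:95]  # 95 mapped, all correct
        _write_sam(tmp_path / "a.sam", mapped)
        _write_truth(tmp_path / "a.tsv", truth)
        m = se.evaluate(tmp_path / "a.sam", tmp_path / "a.tsv")
        assert (m.tp, m.fp, m.fn) == (95, 0, 5)
        assert m.mappability == 0.95
        assert m.precision == 1.0
        assert m.sensitivity == 0.95
        assert m.accuracy == 0.95

    def test_incorrect_positions_are_fp(self, tmp_path):
        truth = [(f"r{i}", i * 10, "+") for i in range(100)]
        mapped = truth[:90] + [(f"r{i}", i * 10 + 5, "+") for i in range(90, 100)]
        _write_sam(tmp_path / "a.sam", mapped)
        _write_truth(tmp_path / "a.tsv", truth)
        m = se.evaluate(tmp_path / "a.sam", tmp_path / "a.tsv")
        assert (m.tp, m.fp, m.fn) == (90, 10, 0)
        assert m.precision == 0.9
        assert m.accuracy == 0.9

    def test_strand_mismatch_is_fp(self, tmp_path):
        _write_sam(tmp_path / "a.sam", [("r0", 0, "-")])
        _write_truth(tmp_path / "a.tsv", [("r0", 0, "+")])
        m = se.evaluate(tmp_path / "a.sam", tmp_path / "a.tsv")
        assert (m.tp, m.fp) == (0, 1)

    def test_tolerance_window(self, tmp_path):
        _write_sam(tmp_path / "a.sam", [("r0", 3, "+")])
        _write_truth(tmp_path / "a.tsv", [("r0", 0, "+")])
        assert se.evaluate(tmp_path / "a.sam", tmp_path / "a.tsv").tp == 0
        assert se.evaluate(tmp_path / "a.sam", tmp_path / "a.tsv", tolerance=5).tp == 1

    def test_zero_mapped_reports_nan_with_flag(self, tmp_path):
        _write_sam(tmp_path / "a.sam", [])
        _write_truth(tmp_path / "a.tsv", [("r0", 0, "+")])
        m = se.evaluate(tmp_path / "a.sam", tmp_path / "a.tsv")
        assert m.mappability == 0.0
        assert math.isnan(m.precision)
        assert "precision" in m.undefined

    def test_unknown_read_id_errors(self, tmp_path):
        _write_sam(tmp_path / "a.sam", [("ghost", 0, "+")])
        _write_truth(tmp_path / "a.tsv", [("r0", 0, "+")])
        with pytest.raises(se.EvaluationError, match="ghost"):
            se.evaluate(tmp_path / "a.sam", tmp_path / "a.tsv")


class TestPipelineProperties:
    def test_precision_one_and_high_mappability_at_zero_error(
        self, small_ref, small_pack, small_sim, tmp_path
    ):
        records, truths = small_sim
        sam = tmp_path / "out.sam"
        pe.run_pipeline(
            pe.PipelineConfig(out_sam=str(sam), n_partitions=2),
            pack=small_pack,
            records=records,
        )
        truth_path = tmp_path / "t.tsv"
        _rows = [
            f"{t.read_id}\t{t.seq_name}\t{t.watson_pos}\t{t.strand}\t{t.origin}\t."
            for t in truths.values()
        ]
        truth_path.write_text("\t".join(se.TRUTH_COLUMNS) + "\n" + "\n".join(_rows) + "\n")
        m = se.evaluate(sam, truth_path)
        assert m.precision == 1.0
        assert m.mappability >= 0.99

    def test_metrics_monotone_in_error_rate(self, tmp_path):
        ref = se.synth_genome(30_000, seed=19)
        pack = gp.GenomePack.build(ref, k=20)
        results = []
        for e in (0.0, 0.01, 0.02):
            cfg = se.SimConfig(n_reads=400, read_len=95, seed=19, error_rate=e)
            fq, truth = se.simulate_reads(cfg, ref, tmp_path / f"sim{e}")
            sam = tmp_path / f"out{e}.sam"
            pe.run_pipeline(
                pe.PipelineConfig(out_sam=str(sam), n_partitions=2),
                pack=pack,
                records=list(rt.read_fastx(fq)),
            )
            results.append(se.evaluate(sam, truth))
        maps = [m.mappability for m in results]
        accs = [m.accuracy for m in results]
        assert maps[0] >= maps[1] >= maps[2]
        assert accs[0] >= accs[1] >= accs[2]
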