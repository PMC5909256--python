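"""Generators and the precision/recall evaluator."""

import math

import numpy as np
import pytest

from splitindel import simulate as sim


class TestMakeReference:
    def test_seeded_determinism(self):
        assert sim.make_reference(1000, 0.5, 42) == sim.make_reference(1000, 0.5, 42)
        assert sim.make_reference(1000, 0.5, 42) != sim.make_reference(1000, 0.5, 43)

    def test_gc_fraction_concentrates(self):
        seq = sim.make_reference(100_000, 0.6, 7)
        gc = sum(b in "GC" for b in seq) / len(seq)
        assert abs(gc - 0.6) < 0.02

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            sim.make_reference(0)


class TestImplantVariants:
    def test_length_arithmetic(self):
        ref = sim.make_reference(50_000, 0.5, 1)
        dels = [sim.TruthVariant("c", 10_000, "DEL", 160)]
        alt, _ = sim.implant_variants(ref, dels)
        assert len(alt) == len(ref) - 160
        ins = [sim.TruthVariant("c", 10_000, "INS", 20, "ACGTACGTACGTACGTACGT")]
        alt, _ = sim.implant_variants(ref, ins)
        assert len(alt) == len(ref) + 20

    def test_overlapping_specs_rejected(self):
        ref = sim.make_reference(5000, 0.5, 1)
        overlapping = [
            sim.TruthVariant("c", 1000, "DEL", 500),
            sim.TruthVariant("c", 1200, "DEL", 100),
        ]
        with pytest.raises(ValueError):
            sim.implant_variants(ref, overlapping)

    def test_size_sweep_truth_vcf_roundtrips(self, tmp_path):
        ref = sim.make_reference(50_000, 0.5, 2)
        sweep = [
            sim.normalize_variant(ref, sim.TruthVariant("chr1", 3000 * (i + 1), "DEL", s))
            for i, s in enumerate([10, 50, 100, 500, 1000])
        ]
        path = sim.write_truth_vcf(sweep, ref, str(tmp_path / "truth.vcf"), rname="chr1")
        res = sim.evaluate_calls(path, sweep, "exact")
        assert res.precision == 1.0 and res.recall == 1.0

    def test_match_blocks_tile_the_alt_haplotype(self):
        ref = sim.make_reference(30_000, 0.5, 3)
        truth = sim.random_truth(ref, "c", 2, 2, (10, 200), (10, 50), seed=4, spacing=400)
        alt, blocks = sim.implant_variants(ref, truth)
        for blk in blocks:
            assert alt[blk.alt_start : blk.alt_end] == ref[blk.ref_start : blk.ref_start + blk.alt_end - blk.alt_start]


class TestEmitChimericSam:
    def test_emitter_and_reconstruction_are_inverse(self, dna_fixture):
        """Every truth variant is recovered exactly from the emitted chimeras
        (kind, size, leftmost breakpoint)."""
        from splitindel.calling import call_indels

        calls = call_indels(dna_fixture.redefined_bam, reference=dna_fixture.ref_fasta)
        res = sim.evaluate_calls(calls, dna_fixture.truth, "exact")
        assert res.precision == 1.0 and res.recall == 1.0

    def test_deterministic_for_fixed_seed(self):
        ref = sim.make_reference(20_000, 0.5, 5)
        truth = sim.random_truth(ref, "c", 1, 1, (50, 200), (10, 40), seed=6, spacing=400)
        a = sim.emit_chimeric_sam("c", ref, truth, seed=7)
        b = sim.emit_chimeric_sam("c", ref, truth, seed=7)
        assert a == b

    def test_junction_mode_offsets(self):
        """An intron-sized junction chimera has target offset = read offset +
        intron length."""
        ref = sim.make_reference(10_000, 0.5, 8)
        intron = sim.TruthVariant("c", 4000, "DEL", 2000, annotation="SPLICE_JUNCTION")
        sam = sim.emit_chimeric_sam("c", ref, [intron], depth=4, seed=9)
        body = [l for l in sam.splitlines() if not l.startswith("@")]
        assert body
        for line in body:
            fields = line.split("\t")
            sa = next(t for t in fields[11:] if t.startswith("SA:Z:"))
            pos, sa_pos = int(fields[3]), int(sa[5:].split(",")[1])
            assert abs(sa_pos - pos) > 2000  # target offset exceeds the read span


class TestSimulateReads:
    CFG = sim.SimConfig(read_len=100, coverage=30, variant_fraction=0.5, error_rate=0.001, seed=1)

    def test_read_length_floor_enforced(self):
        with pytest.raises(ValueError):
            sim.SimConfig(read_len=50)

    def test_coverage_and_error_rate(self):
        ref = sim.make_reference(50_000, 0.5, 10)
        reads = sim.simulate_reads(ref, ref, self.CFG)
        total = sum(len(r.seq) for r in reads)
        assert abs(total / len(ref) - 30) / 30 < 0.1
        # substitution rate: compare ref-haplotype reads with their source
        errs = bases = 0
        for r in reads[:2000]:
            src = ref[r.hap_start : r.hap_start + 100]
            errs += sum(a != b for a, b in zip(r.seq, src))
            bases += 100
        assert 0.0002 < errs / bases < 0.005

    def test_seeded_fastq_is_byte_identical(self, tmp_path):
        ref = sim.make_reference(20_000, 0.5, 11)
        for tag in ("a", "b"):
            reads = sim.simulate_reads(ref, ref, self.CFG)
            sim.write_fastq(reads, str(tmp_path / f"{tag}_1.fq"), str(tmp_path / f"{tag}_2.fq"))
        assert (tmp_path / "a_1.fq").read_bytes() == (tmp_path / "b_1.fq").read_bytes()
        assert (tmp_path / "a_2.fq").read_bytes() == (tmp_path / "b_2.fq").read_bytes()

    def test_variant_fraction_splits_haplotypes(self):
        ref = sim.make_reference(50_000, 0.5, 12)
        reads = sim.simulate_reads(ref, ref, self.CFG)
        alt_frac = sum(r.hap == "alt" for r in reads) / len(reads)
        assert abs(alt_frac - 0.5) < 0.05


class TestEvaluateCalls:
    TRUTH = [("c", 100 * (i + 1), "DEL", 10 + i) for i in range(10)]

    def test_identity(self):
        res = sim.evaluate_calls(list(self.TRUTH), list(self.TRUTH), "exact")
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)

    def test_partial_overlap(self):
        calls = list(self.TRUTH[:8]) + [("c", 5000, "DEL", 99), ("c", 6000, "INS", 12)]
        res = sim.evaluate_calls(calls, self.TRUTH, "exact")
        assert res.recall == pytest.approx(0.8)
        assert res.precision == pytest.approx(0.8)

    def test_empty_calls_na_precision(self):
        res = sim.evaluate_calls([], self.TRUTH, "exact")
        assert res.precision is None
        assert res.recall == 0.0

    def test_window_matching_relaxes_position_only(self):
        shifted = [("c", p + 3, k, s) for (_, p, k, s) in self.TRUTH]
        assert sim.evaluate_calls(shifted, self.TRUTH, "exact").recall == 0.0
        assert sim.evaluate_calls(shifted, self.TRUTH, "window", window=5).recall == 1.0
        wrong_size = [("c", p, k, s + 1) for (_, p, k, s) in self.TRUTH]
        assert sim.evaluate_calls(wrong_size, self.TRUTH, "window", window=5).recall == 0.0

    def test_invariant_to_record_order_and_chrom_labels(self):
        rng = np.random.default_rng(0)
        calls = list(self.TRUTH)
        rng.shuffle(calls)
        res = sim.evaluate_calls(calls, self.TRUTH, "exact")
        relabeled = [("X" + c, p, k, s) for (c, p, k, s) in self.TRUTH]
        res2 = sim.evaluate_calls(relabeled, [("X" + c, p, k, s) for (c, p, k, s) in self.TRUTH], "exact")
        assert res.recall == res2.recall == 1.0

    def test_one_to_one_matching(self):
        """Two calls at the same event consume only one truth entry."""
        calls = [("c", 100, "DEL", 10), ("c", 100, "DEL", 10)]
        res = sim.evaluate_calls(calls, [("c", 100, "DEL", 10)], "exact")
        assert res.tp == 1 and res.fp == 1


def test_called_vafs_within_binomial_bounds(dna_fixture):
    """At 50% variant fraction, each called VAF lies inside the central 99%
    binomial band for its observed depth."""
    from scipy.stats import binom

    from splitindel.calling import call_indels

    calls = call_indels(dna_fixture.redefined_bam, reference=dna_fixture.ref_fasta)
    assert calls
    for c in calls:
        lo, hi = binom.ppf([0.005, 0.995], c.depth, 0.5)
        assert lo / c.depth <= c.vaf <= hi / c.depth
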