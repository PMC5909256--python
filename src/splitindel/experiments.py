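"""End-to-end validation experiments on synthetic data.

Each function runs the full pipeline (generate -> redefine -> call ->
evaluate) under one controlled condition and returns the measured
quantities.  They exist so that the same experiment can be executed from the
test suite and from the reproduction script without duplication.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import calling, reconstruct, splice
from . import simulate as sim
from .oracle import brute_force_indel


def inverse_pair_experiment(
    seed: int,
    tmpdir: str | None = None,
    ref_len: int = 1_000_000,
    n_del: int = 30,
    n_ins: int = 30,
    depth: int = 50,
    variant_fraction: float = 0.5,
) -> dict:
    """Implant indels, emit idealized chimeras, rebuild and call them.

    Deletions span 10-1000 bp, insertions 10-85 bp (the spannable range for
    100 bp reads).  Every breakpoint is covered by ``depth`` reads (50, the
    whole-genome coverage the benchmark design uses) at a heterozygous 0.5
    variant fraction.  Calls are matched against truth exactly (identical
    chromosome, position, type, size).
    """
    rng = np.random.default_rng(seed)
    with tempfile.TemporaryDirectory(dir=tmpdir) as d:
        rname = "chr1"
        ref = sim.make_reference(ref_len, 0.5, int(rng.integers(2**31)))
        truth = sim.random_truth(
            ref, rname, n_del=n_del, n_ins=n_ins,
            del_sizes=(10, 1000), ins_sizes=(10, 85), seed=int(rng.integers(2**31)),
        )
        sam = sim.emit_chimeric_sam(
            rname, ref, truth, read_len=100, depth=depth,
            variant_fraction=variant_fraction, seed=int(rng.integers(2**31)),
        )
        raw = str(Path(d) / "raw.bam")
        sim.sam_to_bam(sam, raw)
        redefined = str(Path(d) / "redefined.bam")
        summary = reconstruct.redefine_bam(raw, redefined)
        fasta = sim.write_fasta(str(Path(d) / "ref.fa"), rname, ref)
        calls = calling.call_indels(redefined, reference=fasta)
        res = sim.evaluate_calls(calls, truth, "exact")
    return {
        "precision": res.precision,
        "recall": res.recall,
        "f1": res.f1,
        "n_variants": len(truth),
        "n_calls": len(calls),
        "build_summary": summary,
    }


def simulated_reads_experiment(
    seed: int,
    aligner: str = "builtin",
    tmpdir: str | None = None,
    ref_len: int = 300_000,
    coverage: float = 50.0,
    n_del: int = 12,
    n_ins: int = 8,
    min_del_size: int = 50,
    window: int = 5,
) -> dict:
    """Simulate 2x100 bp reads at the given coverage over an implanted
    reference and measure precision/recall for deletions >= ``min_del_size``
    with position matching relaxed by ±``window``.

    ``aligner`` selects the read-to-chimera path: ``builtin`` maps reads
    through their recorded provenance; ``bwa`` runs the external chimera-aware
    aligner on the simulated FASTQ.
    """
    rng = np.random.default_rng(seed)
    with tempfile.TemporaryDirectory(dir=tmpdir) as d:
        rname = "chr1"
        ref = sim.make_reference(ref_len, 0.5, int(rng.integers(2**31)))
        truth = sim.random_truth(
            ref, rname, n_del=n_del, n_ins=n_ins,
            del_sizes=(10, 1000), ins_sizes=(10, 85), seed=int(rng.integers(2**31)),
        )
        alt, blocks = sim.implant_variants(ref, truth)
        cfg = sim.SimConfig(
            read_len=100, coverage=coverage, variant_fraction=0.5,
            error_rate=0.001, seed=int(rng.integers(2**31)),
        )
        reads = sim.simulate_reads(ref, alt, cfg)
        fasta = sim.write_fasta(str(Path(d) / "ref.fa"), rname, ref)
        raw = str(Path(d) / "raw.bam")
        if aligner == "builtin":
            sam = sim.align_by_provenance(reads, rname, ref, blocks)
            sim.sam_to_bam(sam, raw)
        elif aligner == "bwa":
            fq1, fq2 = str(Path(d) / "r1.fq"), str(Path(d) / "r2.fq")
            sim.write_fastq(reads, fq1, fq2)
            sim.align_with_bwa(fasta, fq1, fq2, raw)
        else:
            raise ValueError(f"unknown aligner {aligner!r}")
        redefined = str(Path(d) / "redefined.bam")
        reconstruct.redefine_bam(raw, redefined)
        calls = calling.call_indels(redefined, reference=fasta)
        del_truth = [v for v in truth if v.kind == "DEL" and v.size >= min_del_size]
        del_calls = [c for c in calls if c.kind == "DEL" and c.size >= min_del_size]
        res = sim.evaluate_calls(del_calls, del_truth, "window", window=window)
        all_res = sim.evaluate_calls(calls, truth, "window", window=window)
    return {
        "del_precision": res.precision,
        "del_recall": res.recall,
        "all_precision": all_res.precision,
        "all_recall": all_res.recall,
        "n_reads": len(reads),
        "n_del_truth": len(del_truth),
    }


def oracle_experiment(seed: int, n_cases: int = 1000) -> dict:
    """Fraction of random chimeric pairs where reconstruction agrees with the
    brute-force all-splits oracle in kind, size and leftmost breakpoint."""
    rng = np.random.default_rng(seed)
    cfg = reconstruct.ReconstructConfig()
    agree = 0
    for i in range(n_cases):
        case = sim.random_chimeric_case(rng)
        pair = sim.case_to_pair(case, rl_upstream=bool(i % 2))
        ev = reconstruct.reconstruct_indel(pair, cfg)
        orc = brute_force_indel(case.ref, case.read)
        if ev is None or orc is None:
            continue
        start, _ = calling.left_normalize(
            case.rname, ev.ref_break, ev.kind, ev.size, ev.inserted_seq, case.ref
        )
        if (ev.kind, ev.size, start) == (orc.kind, orc.size, orc.ref_break):
            agree += 1
    return {"agreement": agree / n_cases, "n_cases": n_cases}


def rna_mode_experiment(seed: int, tmpdir: str | None = None, depth: int = 16) -> dict:
    """RNA-mode specificity on a synthetic spliced gene.

    Junction chimeras over annotated GT..AG introns must yield zero PASS
    deletion calls, while the implanted intra-exonic deletion with non-motif
    breakpoints must be called PASS and flagged as an exitron candidate
    (there are no DNA-level calls to explain it).
    """
    rng = np.random.default_rng(seed)
    with tempfile.TemporaryDirectory(dir=tmpdir) as d:
        fx = sim.build_rna_fixture(seed=int(rng.integers(2**31)))
        sam = sim.emit_chimeric_sam(
            fx.rname, fx.ref, fx.variants, read_len=100, depth=depth,
            variant_fraction=0.6, seed=int(rng.integers(2**31)),
        )
        raw = str(Path(d) / "rna.bam")
        sim.sam_to_bam(sam, raw)
        redefined = str(Path(d) / "redefined.bam")
        reconstruct.redefine_bam(raw, redefined)
        fasta = sim.write_fasta(str(Path(d) / "ref.fa"), fx.rname, fx.ref)
        gtf = Path(d) / "genes.gtf"
        gtf.write_text(fx.gtf_text)
        calls = calling.call_indels(redefined, reference=fasta)
        idx = splice.load_splice_sites(str(gtf))
        calls = splice.filter_rna_deletions(calls, idx, fasta)
        coding = splice.load_coding_exons(str(gtf))
        calls = splice.flag_exitron_candidates(calls, coding, dna_calls=[])
        junction_keys = {v.key for v in fx.junctions}
        junction_pass = sum(1 for c in calls if c.is_pass and c.key in junction_keys)
        pass_dels = [c for c in calls if c.is_pass and c.kind == "DEL"]
        exitron_calls = [c for c in calls if c.exitron]
        exitron_recovered = any(c.key == fx.exitron.key for c in exitron_calls)
    return {
        "n_junctions": len(fx.junctions),
        "n_junction_calls": sum(1 for c in calls if c.key in junction_keys),
        "junction_pass_calls": junction_pass,
        "pass_deletions": len(pass_dels),
        "exitron_candidates": len(exitron_calls),
        "exitron_recovered": exitron_recovered,
        "exitron_size": fx.exitron.size,
    }
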