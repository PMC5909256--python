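"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from splitindel import reconstruct
from splitindel import simulate as sim


@dataclass
class DnaFixture:
    rname: str
    ref: str
    ref_fasta: str
    truth: list
    raw_bam: str
    redefined_bam: str
    summary: dict


@pytest.fixture(scope="session")
def dna_fixture(tmp_path_factory) -> DnaFixture:
    """A 200 kb reference with 10 implanted indels, chimeric reads at 50%
    variant fraction, and the redefined BAM built from them."""
    d = tmp_path_factory.mktemp("dna")
    rname = "chr1"
    ref = sim.make_reference(200_000, 0.5, seed=101)
    truth = sim.random_truth(
        ref, rname, n_del=5, n_ins=5, del_sizes=(10, 1000), ins_sizes=(10, 85), seed=102
    )
    sam = sim.emit_chimeric_sam(
        rname, ref, truth, read_len=100, depth=20, variant_fraction=0.5, seed=103
    )
    raw_bam = str(d / "raw.bam")
    sim.sam_to_bam(sam, raw_bam)
    ref_fasta = sim.write_fasta(str(d / "ref.fa"), rname, ref)
    redefined = str(d / "redefined.bam")
    summary = reconstruct.redefine_bam(raw_bam, redefined)
    return DnaFixture(rname, ref, ref_fasta, truth, raw_bam, redefined, summary)


@dataclass
class RnaPipelineFixture:
    fx: sim.RnaFixture
    ref_fasta: str
    gtf_path: str
    redefined_bam: str


@pytest.fixture(scope="session")
def rna_fixture(tmp_path_factory) -> RnaPipelineFixture:
    """Synthetic 5-exon gene: junction chimeras over GT..AG introns plus one
    112 bp intra-exonic deletion with non-motif breakpoints."""
    d = tmp_path_factory.mktemp("rna")
    fx = sim.build_rna_fixture(seed=7)
    sam = sim.emit_chimeric_sam(
        fx.rname, fx.ref, fx.variants, read_len=100, depth=16, variant_fraction=0.6, seed=8
    )
    raw = str(d / "rna.bam")
    sim.sam_to_bam(sam, raw)
    redefined = str(d / "rna.redefined.bam")
    reconstruct.redefine_bam(raw, redefined)
    ref_fasta = sim.write_fasta(str(d / "ref.fa"), fx.rname, fx.ref)
    gtf_path = str(d / "genes.gtf")
    Path(gtf_path).write_text(fx.gtf_text)
    return RnaPipelineFixture(fx, ref_fasta, gtf_path, redefined)
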