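"""Synthetic references, implanted indel truth sets, and chimera-style reads.

Everything the pipeline consumes can be generated here without an external
aligner or any download: random references, truth variants implanted into an
alternative haplotype, BWA-MEM-like chimeric SAM records (clip at the
junction, single ``SA`` alternative, MAPQ 60), paired-end reads with
substitution errors, and a provenance-based aligner that maps simulated reads
back to the reference through the known variant set.  A thin adapter runs a
real chimera-aware aligner (``bwa mem``) when one is on PATH.

The module also houses the precision/recall evaluator used to compare call
sets against truth (match rule: identical chromosome, type and size, with the
position either exact or relaxed by a window).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .calling import IndelCall, left_normalize

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def make_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random reference sequence with the requested GC fraction (seeded)."""
    if length <= 0:
        raise ValueError("reference length must be positive")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def write_fasta(path: str, rname: str, seq: str, width: int = 70) -> str:
    with open(path, "w") as fh:
        fh.write(f">{rname}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")
    pysam.faidx(str(path))
    return str(path)


@dataclass(frozen=True)
class TruthVariant:
    """An implanted indel: ``start`` is 0-based (first deleted base for DEL,
    insertion point for INS)."""

    rname: str
    start: int
    kind: str  # "DEL" | "INS"
    size: int
    inserted_seq: str = ""
    annotation: str = "GENOMIC"  # GENOMIC | SPLICE_JUNCTION | EXITRON

    @property
    def end(self) -> int:
        return self.start + (self.size if self.kind == "DEL" else 0)

    @property
    def key(self) -> tuple:
        return (self.rname, self.start, self.kind, self.size)


def normalize_variant(ref: str, v: TruthVariant) -> TruthVariant:
    start, seq = left_normalize(v.rname, v.start, v.kind, v.size, v.inserted_seq, ref)
    if start == v.start:
        return v
    return TruthVariant(v.rname, start, v.kind, v.size, seq or "", v.annotation)


def random_truth(
    ref: str,
    rname: str,
    n_del: int,
    n_ins: int,
    del_sizes: tuple[int, int] = (10, 1000),
    ins_sizes: tuple[int, int] = (10, 85),
    seed: int = 0,
    spacing: int = 600,
) -> list[TruthVariant]:
    """Non-overlapping left-normalized truth variants at well-spaced positions.

    Variants are placed on a regular grid with jitter so that no read or
    fragment can span two events; every variant is left-normalized against
    the reference before being returned.
    """
    rng = np.random.default_rng(seed)
    n = n_del + n_ins
    usable = len(ref) - 2 * spacing
    slot = usable // n
    if slot < del_sizes[1] + 2 * spacing // 2:
        raise ValueError("reference too short for the requested variant set")
    kinds = ["DEL"] * n_del + ["INS"] * n_ins
    rng.shuffle(kinds)
    variants: list[TruthVariant] = []
    for i, kind in enumerate(kinds):
        lo, hi = del_sizes if kind == "DEL" else ins_sizes
        size = int(rng.integers(lo, hi + 1))
        margin = del_sizes[1] if kind == "DEL" else 0
        start = spacing + i * slot + int(rng.integers(0, max(slot - margin - spacing, 1)))
        if kind == "DEL":
            v = TruthVariant(rname, start, "DEL", size)
        else:
            ins = "".join(rng.choice(list("ACGT"), size=size))
            v = TruthVariant(rname, start, "INS", size, ins)
        variants.append(normalize_variant(ref, v))
    variants.sort(key=lambda v: v.start)
    for a, b in zip(variants, variants[1:]):
        if a.end >= b.start:
            raise ValueError("variant placement produced an overlap; use a longer reference")
    return variants


class MatchBlock(NamedTuple):
    """One contiguous alt<->ref match segment of the implanted haplotype."""

    alt_start: int
    alt_end: int
    ref_start: int


def implant_variants(ref: str, variants: list[TruthVariant]) -> tuple[str, list[MatchBlock]]:
    """Apply a sorted non-overlapping variant set to the reference.

    Returns the alternative haplotype and the list of match blocks tiling it
    (inserted stretches fall between blocks; deletions are ref jumps).
    """
    parts: list[str] = []
    blocks: list[MatchBlock] = []
    ref_cursor = 0
    alt_cursor = 0
    for v in sorted(variants, key=lambda v: v.start):
        if v.start < ref_cursor or v.end > len(ref):
            raise ValueError(f"variant at {v.start} overlaps a previous one or exceeds the reference")
        chunk = ref[ref_cursor : v.start]
        parts.append(chunk)
        blocks.append(MatchBlock(alt_cursor, alt_cursor + len(chunk), ref_cursor))
        alt_cursor += len(chunk)
        if v.kind == "DEL":
            ref_cursor = v.start + v.size
        else:
            if len(v.inserted_seq) != v.size:
                raise ValueError(f"INS at {v.start} lacks a size-{v.size} inserted sequence")
            parts.append(v.inserted_seq)
            alt_cursor += v.size
            ref_cursor = v.start
    tail = ref[ref_cursor:]
    parts.append(tail)
    blocks.append(MatchBlock(alt_cursor, alt_cursor + len(tail), ref_cursor))
    return "".join(parts), blocks


def write_truth_vcf(variants: list[TruthVariant], ref: str, path: str, rname: str | None = None) -> str:
    """Write a left-aligned truth VCF (sequence-explicit alleles)."""
    header = pysam.VariantHeader()
    name = rname or (variants[0].rname if variants else "ref")
    header.contigs.add(name, length=len(ref))
    header.info.add("SVTYPE", 1, "String", "Type of event")
    header.info.add("SVLEN", 1, "Integer", "Event size; negative for deletions")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: v.start):
            if v.start < 1:
                raise ValueError("truth variant too close to the contig start to anchor")
            rec = vcf.new_record()
            rec.contig = v.rname
            rec.start = v.start - 1
            anchor = ref[v.start - 1]
            if v.kind == "DEL":
                rec.alleles = (ref[v.start - 1 : v.start + v.size], anchor)
                rec.info["SVLEN"] = -v.size
            else:
                rec.alleles = (anchor, anchor + v.inserted_seq)
                rec.info["SVLEN"] = v.size
            rec.info["SVTYPE"] = v.kind
            vcf.write(rec)
    return str(path)


# ---------------------------------------------------------------------------
# SAM record assembly


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str
    pos: int  # 0-based
    mapq: int
    cigar: str
    seq: str
    tags: list = field(default_factory=list)

    def to_line(self) -> str:
        tags = "".join(f"\t{t}" for t in self.tags)
        return (
            f"{self.qname}\t{self.flag}\t{self.rname}\t{self.pos + 1}\t{self.mapq}\t"
            f"{self.cigar}\t*\t0\t0\t{self.seq}\t{'I' * len(self.seq)}{tags}"
        )


def sam_document(records: list[SamRecord], contigs: dict) -> str:
    """Coordinate-sorted SAM text with HD/SQ headers."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    order = {name: i for i, name in enumerate(contigs)}
    for rec in sorted(records, key=lambda r: (order[r.rname], r.pos)):
        lines.append(rec.to_line())
    return "\n".join(lines) + "\n"


def sam_to_bam(sam_text: str, bam_path: str) -> str:
    """Materialize SAM text as a sorted, indexed BAM."""
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(sam_text)
        sam_path = fh.name
    try:
        pysam.sort("-o", str(bam_path), sam_path)
        pysam.index(str(bam_path))
    finally:
        Path(sam_path).unlink(missing_ok=True)
    return str(bam_path)


def _chimeric_records(
    qname: str,
    rname: str,
    seq: str,
    up_pos: int,
    up_cigar: str,
    down_pos: int,
    down_cigar: str,
    rl_upstream: bool,
    mapq: int = 60,
) -> SamRecord:
    """One representative record plus its SA tag for a two-block chimera."""
    if rl_upstream:
        pos, cigar = up_pos, up_cigar
        sa = f"SA:Z:{rname},{down_pos + 1},+,{down_cigar},{mapq},0;"
    else:
        pos, cigar = down_pos, down_cigar
        sa = f"SA:Z:{rname},{up_pos + 1},+,{up_cigar},{mapq},0;"
    return SamRecord(qname, 0, rname, pos, mapq, cigar, seq, [sa])


def emit_chimeric_sam(
    rname: str,
    ref: str,
    variants: list[TruthVariant],
    read_len: int = 100,
    depth: int = 12,
    variant_fraction: float = 1.0,
    seed: int = 0,
    min_anchor: int = 12,
    min_ins_anchor: int = 5,
) -> str:
    """Idealized chimera-aware aligner output for an implanted truth set.

    For every variant, ``depth`` breakpoint-covering reads are emitted; each
    read comes from the alternative haplotype with probability
    ``variant_fraction`` (a split read with a clip at the junction and a
    single SA alternative) and otherwise from the reference haplotype (plain
    full-M record).  The representative alignment alternates between the
    upstream (MS) and downstream (SM) block so both orientations are
    exercised.  Insertions wider than the read minus two anchors cannot be
    spanned and yield a soft-clipped record without an SA tag, as a real
    aligner would produce.
    """
    if read_len < 75:
        raise ValueError("read_len must be >= 75")
    rng = np.random.default_rng(seed)
    records: list[SamRecord] = []
    counter = 0
    for v in variants:
        b = v.start
        for j in range(depth):
            counter += 1
            qname = f"sim{counter}"
            if rng.random() >= variant_fraction:
                offset = int(rng.integers(1, read_len))
                pos = min(max(b - offset, 0), len(ref) - read_len)
                records.append(
                    SamRecord(qname, 0, rname, pos, 60, f"{read_len}M", ref[pos : pos + read_len])
                )
                continue
            rl_upstream = bool(j % 2)
            if v.kind == "DEL":
                a1 = int(rng.integers(min_anchor, read_len - min_anchor + 1))
                a2 = read_len - a1
                if b - a1 < 0 or v.end + a2 > len(ref):
                    continue
                seq = ref[b - a1 : b] + ref[v.end : v.end + a2]
                records.append(
                    _chimeric_records(
                        qname, rname, seq,
                        b - a1, f"{a1}M{a2}S",
                        v.end, f"{a1}S{a2}M",
                        rl_upstream,
                    )
                )
            else:
                if v.size > read_len - 2 * min_ins_anchor:
                    a1 = read_len // 2
                    pos = b - a1
                    seq = ref[pos : b] + v.inserted_seq[: read_len - a1]
                    records.append(
                        SamRecord(qname, 0, rname, pos, 60, f"{a1}M{read_len - a1}S", seq)
                    )
                    continue
                a1 = int(rng.integers(min_ins_anchor, read_len - v.size - min_ins_anchor + 1))
                a2 = read_len - v.size - a1
                if b - a1 < 0 or b + a2 > len(ref):
                    continue
                seq = ref[b - a1 : b] + v.inserted_seq + ref[b : b + a2]
                records.append(
                    _chimeric_records(
                        qname, rname, seq,
                        b - a1, f"{a1}M{v.size + a2}S",
                        b, f"{a1 + v.size}S{a2}M",
                        rl_upstream,
                    )
                )
    return sam_document(records, {rname: len(ref)})


def _match_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


@dataclass(frozen=True)
class ChimericCase:
    """One random split-read scenario: reference, read, and the two blocks
    (as SAM-style pos/CIGAR) an aligner would report for it."""

    ref: str
    read: str
    rname: str
    up_pos: int
    up_cigar: str
    down_pos: int
    down_cigar: str
    kind: str
    size: int


def random_chimeric_case(
    rng: np.random.Generator,
    read_len: int = 100,
    ref_len_range: tuple[int, int] = (2000, 5000),
    del_range: tuple[int, int] = (1, 500),
    ins_range: tuple[int, int] = (1, 60),
    extend: bool | None = None,
    rname: str = "ref",
) -> ChimericCase:
    """A random reference with one implanted indel and one split read over it.

    With ``extend`` (default: random), the two blocks are maximally extended
    across the junction the way a local aligner extends exact matches, which
    turns junction microhomology into overlapping read intervals; otherwise
    the split is clean at the implant position.
    """
    L = read_len
    ref = make_reference(int(rng.integers(*ref_len_range)), 0.5, int(rng.integers(2**31)))
    kind = "DEL" if rng.random() < 0.5 else "INS"
    do_extend = bool(rng.integers(2)) if extend is None else extend
    if kind == "DEL":
        size = int(rng.integers(del_range[0], del_range[1] + 1))
        a1 = int(rng.integers(20, L - 20 + 1))
        b = int(rng.integers(L, len(ref) - size - L))
        read = ref[b - a1 : b] + ref[b + size : b + size + (L - a1)]
        h_right = h_left = 0
        if do_extend:
            h_right = min(_match_len(ref[b:], ref[b + size :]), L - a1 - 1)
            h_left = min(
                _match_len(ref[b - 1 :: -1], ref[b + size - 1 :: -1]), a1 - 1
            )
        m1 = a1 + h_right
        return ChimericCase(
            ref, read, rname,
            b - a1, f"{m1}M{L - m1}S",
            b + size - h_left, f"{a1 - h_left}S{L - a1 + h_left}M",
            kind, size,
        )
    size = int(rng.integers(ins_range[0], min(ins_range[1], L - 40) + 1))
    a1 = int(rng.integers(20, L - size - 20 + 1))
    a2 = L - size - a1
    b = int(rng.integers(L, len(ref) - L))
    ins = "".join(rng.choice(list("ACGT"), size=size))
    read = ref[b - a1 : b] + ins + ref[b : b + a2]
    h_right = h_left = 0
    if do_extend:
        # the upstream match runs on into the inserted bases while they
        # happen to equal the reference; the downstream match runs back
        h_right = min(_match_len(read[a1:], ref[b:]), size + a2 - 1)
        h_left = min(_match_len(read[a1 + size - 1 :: -1], ref[b - 1 :: -1]), a1 - 1)
    m1 = a1 + h_right
    q2 = a1 + size - h_left
    return ChimericCase(
        ref, read, rname,
        b - a1, f"{m1}M{L - m1}S",
        b - h_left, f"{q2}S{L - q2}M",
        kind, size,
    )


def case_to_pair(case: ChimericCase, rl_upstream: bool = True):
    """Build the :class:`~splitindel.reconstruct.ChimericPair` for a case."""
    from .alignment import to_block
    from .reconstruct import ChimericPair

    up = to_block(case.rname, case.up_pos + 1, "+", case.up_cigar)
    down = to_block(case.rname, case.down_pos + 1, "+", case.down_cigar)
    rl, al = (up, down) if rl_upstream else (down, up)
    return ChimericPair(rl=rl, al=al, read_len=len(case.read), seq=case.read, query_name="case")


# ---------------------------------------------------------------------------
# Paired-end read simulation and the provenance aligner


@dataclass(frozen=True)
class SimConfig:
    """Read-simulation settings (paired-end, uniform substitution errors,
    constant qualities — the caller does not use base qualities)."""

    read_len: int = 100
    coverage: float = 50.0
    variant_fraction: float = 0.5
    error_rate: float = 0.001
    fragment_mean: int = 300
    fragment_sd: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 75:
            raise ValueError("read_len must be >= 75 (the tool's input contract)")


class SimRead(NamedTuple):
    name: str
    seq: str  # forward (reference-orientation) sequence
    hap: str  # "ref" | "alt"
    hap_start: int
    is_reverse: bool


def simulate_reads(ref: str, alt: str, cfg: SimConfig) -> list[SimRead]:
    """Paired-end reads drawn from the ref/alt haplotypes.

    Each fragment comes from the alternative haplotype with probability
    ``cfg.variant_fraction``; both mates are returned as forward-orientation
    sequences with provenance (haplotype and haplotype coordinate) recorded.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.read_len
    n_frags = int(round(cfg.coverage * len(ref) / (2 * L)))
    reads: list[SimRead] = []
    haps = {"ref": ref, "alt": alt}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for i in range(n_frags):
        hap = "alt" if rng.random() < cfg.variant_fraction else "ref"
        hs = haps[hap]
        flen = int(np.clip(rng.normal(cfg.fragment_mean, cfg.fragment_sd), 2 * L, len(hs)))
        start = int(rng.integers(0, len(hs) - flen + 1))
        for mate, (s, rev) in enumerate(((start, False), (start + flen - L, True))):
            seq = hs[s : s + L]
            n_err = rng.binomial(L, cfg.error_rate)
            if n_err:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                for p in rng.integers(0, L, size=n_err):
                    arr[p] = bases[(np.searchsorted(bases, arr[p]) + rng.integers(1, 4)) % 4]
                seq = arr.tobytes().decode()
            reads.append(SimRead(f"frag{i}/{mate + 1}", seq, hap, s, rev))
    return reads


def write_fastq(reads: Iterable[SimRead], r1_path: str, r2_path: str) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for read in reads:
            fh = f2 if read.name.endswith("/2") else f1
            seq = revcomp(read.seq) if read.is_reverse else read.seq
            fh.write(f"@{read.name.split('/')[0]}\n{seq}\n+\n{'I' * len(seq)}\n")


def _map_alt_interval(blocks: list[MatchBlock], a: int, b: int) -> list[tuple[int, int, int | None]]:
    """Tile alt interval [a, b) into (qoff, length, ref_start|None) pieces.

    ``None`` marks inserted (reference-less) stretches between match blocks.
    """
    pieces: list[tuple[int, int, int | None]] = []
    cursor = a
    for blk in blocks:
        if blk.alt_end <= a:
            continue
        if blk.alt_start >= b:
            break
        if blk.alt_start > cursor:  # inserted stretch before this block
            pieces.append((cursor - a, blk.alt_start - cursor, None))
            cursor = blk.alt_start
        lo = max(cursor, blk.alt_start)
        hi = min(b, blk.alt_end)
        if hi > lo:
            pieces.append((lo - a, hi - lo, blk.ref_start + (lo - blk.alt_start)))
            cursor = hi
    if cursor < b:
        pieces.append((cursor - a, b - cursor, None))
    return pieces


def align_by_provenance(
    reads: list[SimRead],
    rname: str,
    ref: str,
    blocks: list[MatchBlock],
    min_anchor: int = 15,
    min_ins_anchor: int = 5,
    mapq: int = 60,
) -> str:
    """Map simulated reads back to the reference through the variant map.

    This emulates what a chimera-aware aligner reports, using the reads'
    recorded provenance instead of sequence search: reads inside one match
    block become full-M records, reads spanning one junction become a clipped
    representative plus an SA alternative (when both anchors reach
    ``min_anchor`` / ``min_ins_anchor``), and reads whose short side cannot
    anchor are soft-clipped without an SA tag.
    """
    records: list[SamRecord] = []
    for idx, read in enumerate(reads):
        L = len(read.seq)
        flag = 16 if read.is_reverse else 0
        qname = read.name.split("/")[0]
        if read.hap == "ref":
            records.append(SamRecord(qname, flag, rname, read.hap_start, mapq, f"{L}M", read.seq))
            continue
        pieces = _map_alt_interval(blocks, read.hap_start, read.hap_start + L)
        matches = [p for p in pieces if p[2] is not None]
        if not matches:
            continue  # read entirely inside an insertion: unmappable
        if len(matches) == 1:
            qoff, ln, rstart = matches[0]
            cigar = (f"{qoff}S" if qoff else "") + f"{ln}M" + (f"{L - qoff - ln}S" if L - qoff - ln else "")
            records.append(SamRecord(qname, flag, rname, rstart, mapq, cigar, read.seq))
            continue
        (q1, l1, r1), (q2, l2, r2) = matches[0], matches[1]
        gap = q2 - (q1 + l1)  # inserted read bases between the blocks
        jump = r2 - (r1 + l1)  # reference bases skipped between the blocks
        anchor_needed = min_anchor if jump > 0 and gap == 0 else min_ins_anchor
        if len(matches) > 2 or min(l1, l2) < anchor_needed or (gap > 0 and jump > 0):
            qoff, ln, rstart = max(matches, key=lambda p: p[1])
            cigar = (f"{qoff}S" if qoff else "") + f"{ln}M" + (f"{L - qoff - ln}S" if L - qoff - ln else "")
            records.append(SamRecord(qname, flag, rname, rstart, mapq, cigar, read.seq))
            continue
        up_cigar = (f"{q1}S" if q1 else "") + f"{l1}M{L - q1 - l1}S"
        down_cigar = f"{q2}S{l2}M" + (f"{L - q2 - l2}S" if L - q2 - l2 else "")
        records.append(
            _chimeric_records(
                qname, rname, read.seq,
                r1 - 0, up_cigar,
                r2, down_cigar,
                rl_upstream=bool(idx % 2),
                mapq=mapq,
            )
        )
    return sam_document(records, {rname: len(ref)})


# ---------------------------------------------------------------------------
# External aligner adapter


def external_aligner_available() -> bool:
    return shutil.which("bwa") is not None


def align_with_bwa(ref_fasta: str, fq1: str, fq2: str, out_bam: str, threads: int = 1) -> str:
    """Run ``bwa mem`` (chimera-aware) and produce a sorted, indexed BAM."""
    if not external_aligner_available():
        raise RuntimeError("bwa is not on PATH")
    subprocess.run(["bwa", "index", str(ref_fasta)], check=True, capture_output=True)
    with tempfile.NamedTemporaryFile(suffix=".sam", delete=False) as fh:
        sam_path = fh.name
    try:
        with open(sam_path, "w") as out:
            subprocess.run(
                ["bwa", "mem", "-t", str(threads), str(ref_fasta), str(fq1), str(fq2)],
                check=True,
                stdout=out,
                stderr=subprocess.DEVNULL,
            )
        pysam.sort("-o", str(out_bam), sam_path)
        pysam.index(str(out_bam))
    finally:
        Path(sam_path).unlink(missing_ok=True)
    return str(out_bam)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalResult:
    precision: float | None
    recall: float | None
    f1: float | None
    tp: int
    fp: int
    fn: int
    table: pd.DataFrame


def _as_keys(obj) -> list[tuple]:
    """Coerce a call/truth collection into (rname, start, kind, size) keys."""
    if isinstance(obj, (str, Path)):
        keys = []
        for v in VCF(str(obj)):
            svtype = v.INFO.get("SVTYPE")
            if svtype in ("DEL", "INS"):
                kind = svtype
                size = abs(int(v.INFO.get("SVLEN")))
            else:
                diff = len(v.REF) - len(v.ALT[0])
                if diff == 0:
                    continue
                kind = "DEL" if diff > 0 else "INS"
                size = abs(diff)
            keys.append((v.CHROM, v.POS, kind, size))
        return keys
    keys = []
    for item in obj:
        if isinstance(item, (IndelCall, TruthVariant)):
            keys.append(item.key)
        else:
            keys.append(tuple(item))
    return keys


def evaluate_calls(calls, truth, match_mode: str = "exact", window: int = 0) -> EvalResult:
    """Precision/recall/F1 of a call set against a truth set.

    A call matches a truth variant when chromosome, kind and size are
    identical and the positions agree exactly (``match_mode='exact'``) or
    within ±``window`` (``match_mode='window'``).  Matching is one-to-one
    (nearest position first).  Precision is ``None`` (NA) when there are no
    calls, recall ``None`` when there is no truth.
    """
    if match_mode not in ("exact", "window"):
        raise ValueError("match_mode must be 'exact' or 'window'")
    w = window if match_mode == "window" else 0
    call_keys = _as_keys(calls)
    truth_keys = _as_keys(truth)
    unmatched_calls: dict[tuple, list[int]] = {}
    for rname, pos, kind, size in call_keys:
        unmatched_calls.setdefault((rname, kind, size), []).append(pos)
    for lst in unmatched_calls.values():
        lst.sort()
    rows = []
    tp = 0
    for rname, pos, kind, size in sorted(truth_keys):
        candidates = unmatched_calls.get((rname, kind, size), [])
        best = None
        for p in candidates:
            if abs(p - pos) <= w and (best is None or abs(p - pos) < abs(best - pos)):
                best = p
        if best is not None:
            candidates.remove(best)
            tp += 1
            rows.append({"rname": rname, "pos": pos, "kind": kind, "size": size,
                         "status": "TP", "called_pos": best})
        else:
            rows.append({"rname": rname, "pos": pos, "kind": kind, "size": size,
                         "status": "FN", "called_pos": None})
    fp = sum(len(v) for v in unmatched_calls.values())
    for (rname, kind, size), positions in sorted(unmatched_calls.items()):
        for p in positions:
            rows.append({"rname": rname, "pos": p, "kind": kind, "size": size,
                         "status": "FP", "called_pos": p})
    fn = len(truth_keys) - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    f1 = None
    if precision and recall and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalResult(precision, recall, f1, tp, fp, fn, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# RNA fixture: a multi-exon gene with canonical introns and one exitron


@dataclass
class RnaFixture:
    rname: str
    ref: str
    gtf_text: str
    junctions: list[TruthVariant]
    exitron: TruthVariant

    @property
    def variants(self) -> list[TruthVariant]:
        return sorted([*self.junctions, self.exitron], key=lambda v: v.start)


def build_rna_fixture(
    seed: int = 0,
    n_exons: int = 5,
    exon_len: int = 400,
    intron_len: int = 1500,
    flank: int = 1000,
    exitron_size: int = 112,
    exitron_exon: int = 2,
    rname: str = "chrT",
) -> RnaFixture:
    """A synthetic gene whose introns are canonical GT..AG and annotated.

    Spliced-transcript reads over this gene produce deletion-like chimeras at
    every junction (all of which the RNA filter must reject), while one
    intra-exonic deletion with engineered non-motif breakpoints placed in the
    middle of an exon mimics an exitron and must survive the filter.
    """
    length = 2 * flank + n_exons * exon_len + (n_exons - 1) * intron_len
    seq = list(make_reference(length, 0.5, seed))
    exon_starts = [flank + i * (exon_len + intron_len) for i in range(n_exons)]
    junctions = []
    for i in range(n_exons - 1):
        s = exon_starts[i] + exon_len  # 0-based intron start
        e = exon_starts[i + 1]  # 0-based intron end (exclusive)
        seq[s : s + 2] = "GT"
        seq[e - 2 : e] = "AG"
        # no homology across the junction, so the deletion cannot left-shift
        # away from the annotated boundary
        seq[s - 1] = "C"
        junctions.append(TruthVariant(rname, s, "DEL", e - s, annotation="SPLICE_JUNCTION"))
    ex_start = exon_starts[exitron_exon] + (exon_len - exitron_size) // 2
    seq[ex_start : ex_start + 2] = "AA"
    seq[ex_start + exitron_size - 2 : ex_start + exitron_size] = "TT"
    # make the breakpoint context non-repetitive so the event cannot left-shift
    seq[ex_start - 1] = "C"
    seq[ex_start + exitron_size - 1] = "T"
    ref = "".join(seq)
    exitron = normalize_variant(
        ref, TruthVariant(rname, ex_start, "DEL", exitron_size, annotation="EXITRON")
    )
    gtf_lines = []
    gene_start, gene_end = exon_starts[0] + 1, exon_starts[-1] + exon_len  # 1-based inclusive
    attrs = 'gene_id "SYNG1"; transcript_id "SYNG1.t1";'
    gtf_lines.append(f"{rname}\tsyn\tgene\t{gene_start}\t{gene_end}\t.\t+\t.\t" + 'gene_id "SYNG1";')
    gtf_lines.append(f"{rname}\tsyn\ttranscript\t{gene_start}\t{gene_end}\t.\t+\t.\t{attrs}")
    for s in exon_starts:
        gtf_lines.append(f"{rname}\tsyn\texon\t{s + 1}\t{s + exon_len}\t.\t+\t.\t{attrs}")
        gtf_lines.append(f"{rname}\tsyn\tCDS\t{s + 1}\t{s + exon_len}\t.\t+\t0\t{attrs}")
    return RnaFixture(rname, ref, "\n".join(gtf_lines) + "\n", junctions, exitron)
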