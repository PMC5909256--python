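"""Chimeric-alignment reconstruction: the algorithmic core.

A chimera-aware DNA aligner (BWA-MEM style) represents a read spanning a
large deletion or a mid-sized insertion as two linear alignments: the
representative alignment (RL, the record itself) and a single alternative
alignment (AL, encoded in the ``SA`` tag).  Ordering the two aligned blocks by
read coordinate and comparing the *target offset* (difference of reference
start positions) with the read-coordinate offset recovers the event::

    net = (r_start2 - r_start1) - (q_start2 - q_start1)

    net > 0  ->  deletion of net bases
    net < 0  ->  insertion of -net bases (novel sequence or tandem duplication)

Junction microhomology (both blocks claiming the same read bases) is trimmed
from the upstream block, which places the breakpoint at its leftmost
(VCF-normalised) position.  The read's CIGAR is then rewritten as a single
linear alignment containing an explicit ``D``/``I`` op, and a *redefined* BAM
is emitted in which every input record appears exactly once.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from enum import Enum

import pysam

from .alignment import (
    CigarOp,
    LinearBlock,
    cigar_to_string,
    parse_cigar,
    parse_sa_tag,
    query_length,
    to_block,
)

logger = logging.getLogger(__name__)

_OP2INT = {op: i for i, op in enumerate("MIDNSHP=X")}


class RejectReason(Enum):
    MULTIMAP = "MULTIMAP"
    LOWQ = "LOWQ"
    SECONDARY = "SECONDARY"
    DUP = "DUP"
    UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class ReconstructConfig:
    """Filter and reconstruction thresholds.

    Defaults mirror the method's published settings: representative and
    alternative alignments both require MAPQ >= 60, duplicates are dropped,
    and junction microhomology beyond ``max_read_overlap`` bases disqualifies
    the pair ("large overlaps").
    """

    mapq_cutoff: int = 60
    sa_mapq_cutoff: int = 60
    max_read_overlap: int = 10
    min_indel_size: int = 1
    drop_duplicates: bool = True

    def __post_init__(self) -> None:
        for name in ("mapq_cutoff", "sa_mapq_cutoff", "max_read_overlap", "min_indel_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ChimericPair:
    """Representative block (from the record) plus its single SA alternative."""

    rl: LinearBlock
    al: LinearBlock
    read_len: int
    seq: str | None
    query_name: str


@dataclass(frozen=True)
class IndelEvent:
    """A reconstructed deletion or insertion.

    ``ref_break`` is the 0-based reference position immediately after the
    (overlap-trimmed) upstream block: for a DEL the first deleted base, for an
    INS the position the novel sequence is inserted before.  ``inserted_seq``
    is ``None`` when the bases could not be recovered from the read.
    """

    rname: str
    kind: str  # "DEL" | "INS"
    ref_break: int
    size: int
    inserted_seq: str | None
    read_overlap: int
    source_read: str

    @property
    def ref_end(self) -> int:
        return self.ref_break + (self.size if self.kind == "DEL" else 0)


def eligible_read(rec: pysam.AlignedSegment, cfg: ReconstructConfig) -> tuple[bool, RejectReason | None]:
    """Preprocessing filter: multi-mapped (XA), low-MAPQ, secondary, duplicate."""
    if rec.is_unmapped:
        return False, RejectReason.UNMAPPED
    if rec.is_secondary:
        return False, RejectReason.SECONDARY
    if cfg.drop_duplicates and rec.is_duplicate:
        return False, RejectReason.DUP
    if rec.has_tag("XA"):
        return False, RejectReason.MULTIMAP
    if rec.mapping_quality < cfg.mapq_cutoff:
        return False, RejectReason.LOWQ
    return True, None


def extract_chimeric(rec: pysam.AlignedSegment, cfg: ReconstructConfig) -> ChimericPair | None:
    """Pair the record (RL) with its single qualifying SA hit (AL).

    Returns ``None`` when the record carries no SA tag, more than one
    alternative hit, a low-MAPQ alternative, no stored sequence, or hard
    clips (hard-clipped records lack the bases needed for reconstruction).
    """
    if not rec.has_tag("SA"):
        return None
    hits = parse_sa_tag(rec.get_tag("SA"))
    if len(hits) != 1:
        return None
    hit = hits[0]
    if hit.mapq < cfg.sa_mapq_cutoff:
        return None
    seq = rec.query_sequence
    if seq is None:
        return None
    cigar = rec.cigarstring
    if cigar is None or "H" in cigar:
        return None
    strand = "-" if rec.is_reverse else "+"
    rl = to_block(rec.reference_name, rec.reference_start + 1, strand, cigar)
    al = to_block(hit.rname, hit.pos, hit.strand, parse_cigar(hit.cigar))
    return ChimericPair(rl=rl, al=al, read_len=len(seq), seq=seq, query_name=rec.query_name)


def reconstruct_indel(pair: ChimericPair, cfg: ReconstructConfig) -> IndelEvent | None:
    """Infer the indel implied by a chimeric pair, or ``None``.

    Requirements: same chromosome and strand; blocks ordered by read
    coordinate must form an MS (upstream) + SM (downstream) pair; junction
    read overlap (microhomology) at most ``cfg.max_read_overlap``; a non-zero
    net offset of at least ``cfg.min_indel_size``.  Junctions implying a
    combined deletion+insertion (read gap with DEL geometry, or reference gap
    with INS geometry) are rejected as complex.
    """
    rl, al = pair.rl, pair.al
    if rl.rname != al.rname or rl.strand != al.strand:
        return None
    if rl.q_start == al.q_start:
        return None
    b1, b2 = (rl, al) if rl.q_start < al.q_start else (al, rl)
    if b1.cls != "MS" or b2.cls != "SM":
        return None
    overlap = max(0, b1.q_end - b2.q_start)
    if overlap > cfg.max_read_overlap:
        return None
    if b1.q_end - overlap <= b1.q_start:
        return None  # overlap would consume the whole upstream block
    net = (b2.r_start - b1.r_start) - (b2.q_start - b1.q_start)
    if net == 0 or abs(net) < cfg.min_indel_size:
        return None
    ref_break = b1.r_end - overlap
    if ref_break < 0:
        return None
    if net > 0:
        # deletion: the two blocks must abut in read space after trimming
        if b2.q_start != b1.q_end - overlap:
            return None
        return IndelEvent(
            rname=rl.rname,
            kind="DEL",
            ref_break=ref_break,
            size=net,
            inserted_seq="",
            read_overlap=overlap,
            source_read=pair.query_name,
        )
    size = -net
    ins_start = b1.q_end - overlap
    trim2 = ins_start + size - b2.q_start
    if trim2 < 0 or trim2 > b2.q_end - b2.q_start:
        return None  # complex junction or insertion swallowing the downstream block
    if pair.seq is not None and 0 <= ins_start and ins_start + size <= pair.read_len:
        inserted: str | None = pair.seq[ins_start : ins_start + size]
    else:
        inserted = None
    return IndelEvent(
        rname=rl.rname,
        kind="INS",
        ref_break=ref_break,
        size=size,
        inserted_seq=inserted,
        read_overlap=overlap,
        source_read=pair.query_name,
    )


def _trim_query_end(ops: tuple[CigarOp, ...], n: int) -> list[CigarOp]:
    """Remove ``n`` query bases from the end of an aligned op list."""
    out = list(ops)
    while n > 0 and out:
        length, op = out[-1]
        if op in "DN":  # no query bases; a deletion at the cut edge is dropped
            out.pop()
            continue
        take = min(n, length)
        n -= take
        if take == length:
            out.pop()
        else:
            out[-1] = CigarOp(length - take, op)
    while out and out[-1].op in "DN":
        out.pop()
    return out


def _trim_query_start(ops: tuple[CigarOp, ...], n: int) -> list[CigarOp]:
    out = list(ops)
    while n > 0 and out:
        length, op = out[0]
        if op in "DN":
            out.pop(0)
            continue
        take = min(n, length)
        n -= take
        if take == length:
            out.pop(0)
        else:
            out[0] = CigarOp(length - take, op)
    while out and out[0].op in "DN":
        out.pop(0)
    return out


def _merge_ops(ops: list[CigarOp]) -> list[CigarOp]:
    merged: list[CigarOp] = []
    for item in ops:
        if item.length == 0:
            continue
        if merged and merged[-1].op == item.op:
            merged[-1] = CigarOp(merged[-1].length + item.length, item.op)
        else:
            merged.append(item)
    return merged


def rewritten_cigar(pair: ChimericPair, ev: IndelEvent) -> tuple[int, list[CigarOp]]:
    """Linearised CIGAR for the pair's read, and its new 0-based position.

    Layout: ``[lead S] upstream-ops (overlap-trimmed) + D/I + downstream-ops
    + [trail S]``.  Query-consuming ops always sum to the read length.
    """
    b1, b2 = (pair.rl, pair.al) if pair.rl.q_start < pair.al.q_start else (pair.al, pair.rl)
    ov = ev.read_overlap
    ops: list[CigarOp] = []
    if b1.q_start > 0:
        ops.append(CigarOp(b1.q_start, "S"))
    ops.extend(_trim_query_end(b1.ops, ov))
    ops.append(CigarOp(ev.size, "D" if ev.kind == "DEL" else "I"))
    if ev.kind == "DEL":
        ops.extend(b2.ops)
    else:
        ops.extend(_trim_query_start(b2.ops, (b1.q_end - ov) + ev.size - b2.q_start))
    if pair.read_len - b2.q_end > 0:
        ops.append(CigarOp(pair.read_len - b2.q_end, "S"))
    ops = _merge_ops(ops)
    if query_length(ops) != pair.read_len:
        raise RuntimeError(
            f"rewritten CIGAR {cigar_to_string(ops)} does not consume read "
            f"length {pair.read_len} for {pair.query_name}"
        )
    return b1.r_start, ops


def rewrite_record(
    rec: pysam.AlignedSegment, pair: ChimericPair, ev: IndelEvent
) -> pysam.AlignedSegment:
    """Rewrite a chimeric record as a linear alignment containing the event.

    The SA tag is removed (the alignment is no longer chimeric) and the
    original CIGAR is preserved in an ``OC`` tag.
    """
    new_pos, ops = rewritten_cigar(pair, ev)
    out = pysam.AlignedSegment(header=rec.header)
    out.query_name = rec.query_name
    out.flag = rec.flag
    out.reference_id = rec.reference_id
    out.reference_start = new_pos
    out.mapping_quality = rec.mapping_quality
    out.cigartuples = [(_OP2INT[op], n) for n, op in ops]
    out.next_reference_id = rec.next_reference_id
    out.next_reference_start = rec.next_reference_start
    out.template_length = rec.template_length
    out.query_sequence = rec.query_sequence
    out.query_qualities = rec.query_qualities
    for tag, value in rec.get_tags():
        if tag == "SA":
            continue
        out.set_tag(tag, value)
    out.set_tag("OC", rec.cigarstring, value_type="Z")
    return out


def redefine_bam(in_bam: str, out_bam: str, cfg: ReconstructConfig | None = None) -> dict:
    """Rewrite every reconstructable chimeric read; pass all others through.

    Input must be coordinate-sorted (rewriting can move records left, so the
    output is re-sorted and indexed).  Record count is conserved: ineligible
    reads are emitted verbatim so downstream depth is unchanged.  Returns a
    run summary with per-reason reject counts and per-kind event counts.
    """
    cfg = cfg or ReconstructConfig()
    summary: dict = {
        "records_in": 0,
        "records_out": 0,
        "rejects": {r.value: 0 for r in RejectReason},
        "chimeric_pairs": 0,
        "rewritten": 0,
        "events": {"DEL": 0, "INS": 0},
    }
    with pysam.AlignmentFile(in_bam, check_sq=False) as src:
        so = (src.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(
                f"{in_bam} is not coordinate-sorted (SO={so!r}); "
                "sort it first, e.g. with 'samtools sort'"
            )
        tmp_fd, tmp_path = tempfile.mkstemp(
            suffix=".bam", dir=os.path.dirname(os.path.abspath(out_bam)) or "."
        )
        os.close(tmp_fd)
        try:
            with pysam.AlignmentFile(tmp_path, "wb", template=src) as dst:
                for rec in src.fetch(until_eof=True):
                    summary["records_in"] += 1
                    ok, reason = eligible_read(rec, cfg)
                    new_rec = rec
                    if not ok:
                        summary["rejects"][reason.value] += 1
                    else:
                        pair = extract_chimeric(rec, cfg)
                        if pair is not None:
                            summary["chimeric_pairs"] += 1
                            ev = reconstruct_indel(pair, cfg)
                            if ev is not None:
                                new_rec = rewrite_record(rec, pair, ev)
                                summary["rewritten"] += 1
                                summary["events"][ev.kind] += 1
                    dst.write(new_rec)
                    summary["records_out"] += 1
            pysam.sort("-o", out_bam, tmp_path)
            pysam.index(out_bam)
        finally:
            if os.path.exists(tmp_path):
                os.unlink(tmp_path)
    logger.info("redefine_bam summary: %s", json.dumps(summary))
    return summary
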