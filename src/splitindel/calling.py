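"""Locus-level indel calling from a redefined BAM, and VCF serialization.

After chimeric reads have been rewritten with explicit ``D``/``I`` CIGAR ops,
calling reduces to a pileup-style scan: every distinct (chrom, position, kind,
size, inserted sequence) observed in reads of sufficient mapping quality
becomes a candidate, supported by the number of distinct read names carrying
it.  Depth is the number of qualifying reads covering the left breakpoint
base, and VAF = support / depth.  This per-breakpoint depth is known to
underestimate the true variant fraction for large deletions (only chimeric
reads contribute support); the redefined BAM itself is the supported hand-off
to external re-estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass
class IndelCall:
    """One locus-level call.

    ``start`` is 0-based: the first deleted base for a DEL, the insertion
    point for an INS.  The 1-based VCF POS (anchor base immediately upstream)
    is therefore numerically equal to ``start``.
    """

    rname: str
    start: int
    kind: str  # "DEL" | "INS"
    size: int
    support: int = 0
    depth: int = 0
    vaf: float = 0.0
    inserted_seq: str | None = ""
    filters: set = field(default_factory=set)
    exitron: bool = False
    size_mod3: int | None = None

    @property
    def end(self) -> int:
        """0-based end of the affected reference interval."""
        return self.start + (self.size if self.kind == "DEL" else 0)

    @property
    def key(self) -> tuple:
        return (self.rname, self.start, self.kind, self.size)

    @property
    def is_pass(self) -> bool:
        return not self.filters


@dataclass(frozen=True)
class CallConfig:
    """Calling thresholds.

    Defaults are the germline settings: pileup MAPQ >= 15, at least 2
    supporting reads, VAF >= 0.05, any indel length.  The tumor analyses use
    ``min_vaf=0.10, min_indel_len=10`` (see the CLI presets).
    """

    pileup_min_mapq: int = 15
    min_support: int = 2
    min_vaf: float = 0.05
    min_indel_len: int = 1
    target_regions: dict | None = None  # rname -> IntervalTree

    def __post_init__(self) -> None:
        if not (0 < self.min_vaf <= 1):
            raise ValueError("min_vaf must lie in (0, 1]")
        if min(self.pileup_min_mapq, self.min_support, self.min_indel_len) < 0:
            raise ValueError("thresholds must be >= 0")


def compute_vaf(support: int, depth: int) -> float | None:
    """Variant allele fraction; ``None`` (locus skipped) at zero depth."""
    if depth == 0:
        return None
    if not (0 <= support <= depth):
        raise ValueError(f"invalid support/depth pair ({support}, {depth})")
    return support / depth


def left_normalize(
    rname: str, start: int, kind: str, size: int, seq: str | None, ref: str
) -> tuple[int, str | None]:
    """Shift an indel to its smallest reference coordinate (VCF left-align)."""
    if kind == "DEL":
        while start > 0 and ref[start - 1] == ref[start + size - 1]:
            start -= 1
        return start, ""
    if not seq:
        return start, seq
    s = seq
    while start > 0 and ref[start - 1] == s[-1]:
        s = ref[start - 1] + s[:-1]
        start -= 1
    return start, s


def load_target_regions(bed_path: str) -> dict:
    """BED file -> per-chromosome interval trees (full-containment queries)."""
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _contained(trees: dict, rname: str, start: int, end: int) -> bool:
    tree = trees.get(rname)
    if tree is None:
        return False
    return any(iv.begin <= start and end <= iv.end for iv in tree.overlap(start, max(end, start + 1)))


def call_indels(
    bam_path: str, cfg: CallConfig | None = None, reference: dict | str | None = None
) -> list[IndelCall]:
    """Aggregate per-read D/I evidence from an indexed BAM into calls.

    ``reference`` (a FASTA path or a dict of chromosome sequences) enables
    left-normalization of events before aggregation, so reads reporting the
    same indel at shifted positions within a homopolymer collapse into one
    call.  Support counts distinct read names per locus.  Calls are returned
    in deterministic (coordinate, kind, size) order.
    """
    cfg = cfg or CallConfig()
    ref_seqs = _load_reference(reference)
    events: dict[tuple, set[str]] = {}
    with pysam.AlignmentFile(bam_path) as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path} has no index; run samtools index first")
        for rec in bam.fetch():
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
                continue
            if rec.mapping_quality < cfg.pileup_min_mapq:
                continue
            for key in _read_events(rec, cfg.min_indel_len, ref_seqs):
                events.setdefault(key, set()).add(rec.query_name)

        calls: list[IndelCall] = []
        for (rname, start, kind, size, ins_seq), qnames in events.items():
            support = len(qnames)
            if support < cfg.min_support:
                continue
            depth_pos = start if kind == "DEL" else max(start - 1, 0)
            depth = bam.count(
                rname,
                depth_pos,
                depth_pos + 1,
                read_callback=lambda r: (
                    not r.is_secondary
                    and not r.is_duplicate
                    and r.mapping_quality >= cfg.pileup_min_mapq
                ),
            )
            depth = max(depth, support)
            vaf = compute_vaf(support, depth)
            if vaf is None or vaf < cfg.min_vaf:
                continue
            call = IndelCall(
                rname=rname,
                start=start,
                kind=kind,
                size=size,
                support=support,
                depth=depth,
                vaf=vaf,
                inserted_seq=ins_seq if kind == "INS" else "",
            )
            if cfg.target_regions is not None and not _contained(
                cfg.target_regions, rname, min(call.start, depth_pos), max(call.end, call.start + 1)
            ):
                continue
            calls.append(call)
    calls.sort(key=lambda c: (c.rname, c.start, c.kind, c.size))
    return calls


def _load_reference(reference: dict | str | None) -> dict | None:
    if reference is None or isinstance(reference, dict):
        return reference
    seqs = {}
    with pysam.FastaFile(reference) as fa:
        for name in fa.references:
            seqs[name] = fa.fetch(name)
    return seqs


def _read_events(rec, min_len: int, ref_seqs: dict | None):
    """Yield (rname, start, kind, size, inserted_seq) for each D/I in a read."""
    rname = rec.reference_name
    refpos = rec.reference_start
    qpos = 0
    seq = rec.query_sequence or ""
    for op, length in rec.cigartuples or []:
        if op in (0, 7, 8):  # M/=/X
            refpos += length
            qpos += length
        elif op == 1:  # I
            if length >= min_len:
                ins = seq[qpos : qpos + length] if seq else None
                start = refpos
                if ref_seqs is not None and rname in ref_seqs and ins:
                    start, ins = left_normalize(rname, start, "INS", length, ins, ref_seqs[rname])
                yield (rname, start, "INS", length, ins or "")
            qpos += length
        elif op == 2:  # D
            if length >= min_len:
                start = refpos
                if ref_seqs is not None and rname in ref_seqs:
                    start, _ = left_normalize(rname, start, "DEL", length, "", ref_seqs[rname])
                yield (rname, start, "DEL", length, "")
            refpos += length
        elif op == 3:  # N
            refpos += length
        elif op == 4:  # S
            qpos += length


def somatic_filter(
    tumor_calls: list[IndelCall],
    normal_calls: list[IndelCall],
    normal_bam: str | None = None,
    breakpoint_window: int = 5,
) -> list[IndelCall]:
    """Flag tumor calls with matched-normal evidence as ``IN_NORMAL``.

    Two criteria: (1) subtraction — an identical (coordinate, kind, size)
    call exists in the normal call set; (2) split-read check — the normal BAM
    contains a clipped or indel-carrying read whose clip/indel point lies
    within ``breakpoint_window`` bases of either tumor breakpoint.  Calls are
    annotated in place and the full list returned; somatic calls are those
    without the flag.
    """
    normal_keys = {c.key for c in normal_calls}
    bam = pysam.AlignmentFile(normal_bam) if normal_bam else None
    try:
        for call in tumor_calls:
            call.filters.discard("IN_NORMAL")
            if call.key in normal_keys:
                call.filters.add("IN_NORMAL")
                continue
            if bam is None:
                continue
            breakpoints = {call.start, call.end}
            if any(
                _normal_breakpoint_evidence(bam, call.rname, bp, breakpoint_window)
                for bp in breakpoints
            ):
                call.filters.add("IN_NORMAL")
    finally:
        if bam is not None:
            bam.close()
    return tumor_calls


def _normal_breakpoint_evidence(bam, rname: str, bp: int, window: int) -> bool:
    if rname not in bam.references:
        return False
    lo = max(bp - window - 1, 0)
    for rec in bam.fetch(rname, lo, bp + window + 1):
        if rec.is_unmapped or rec.is_secondary or rec.cigartuples is None:
            continue
        points = []
        first_op = rec.cigartuples[0][0]
        last_op = rec.cigartuples[-1][0]
        if first_op in (4, 5):
            points.append(rec.reference_start)
        if last_op in (4, 5):
            points.append(rec.reference_end)
        refpos = rec.reference_start
        for op, length in rec.cigartuples:
            if op in (0, 2, 3, 7, 8):
                if op == 2:
                    points.extend((refpos, refpos + length))
                refpos += length
            elif op == 1:
                points.append(refpos)
        if any(abs(p - bp) <= window for p in points):
            return True
    return False


def select_somatic(calls: list[IndelCall]) -> list[IndelCall]:
    return [c for c in calls if "IN_NORMAL" not in c.filters]


_VCF_FILTERS = {
    "NEAR_SPLICE": "Deletion breakpoint within the splice-site window of an annotated splice site",
    "SPLICE_MOTIF": "Deleted interval bounded by a canonical splice motif (GT-AG/GC-AG/AT-AC)",
    "IN_NORMAL": "Matching call or breakpoint split-read evidence in the matched normal",
}


def build_vcf_header(reference_fasta: str, sample_name: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    with pysam.FastaFile(reference_fasta) as fa:
        for name, length in zip(fa.references, fa.lengths):
            header.contigs.add(name, length=length)
    header.info.add("END", 1, "Integer", "End of the affected reference interval")
    header.info.add("SVTYPE", 1, "String", "Type of event (DEL or INS)")
    header.info.add("SVLEN", 1, "Integer", "Event size; negative for deletions")
    header.info.add("AO", 1, "Integer", "Reads supporting the event")
    header.info.add("DP", 1, "Integer", "Qualifying read depth at the left breakpoint")
    header.info.add("AF", "A", "Float", "Variant allele fraction (AO/DP)")
    header.info.add("EXITRON_CANDIDATE", 0, "Flag", "Deletion fully inside a coding exon, absent from DNA calls")
    header.info.add("SIZE_MOD3", 1, "Integer", "Event size modulo 3 (exitron candidates)")
    for name, desc in _VCF_FILTERS.items():
        header.filters.add(name, None, None, desc)
    header.formats.add("DP", 1, "Integer", "Qualifying read depth at the left breakpoint")
    header.formats.add("AO", 1, "Integer", "Reads supporting the event")
    header.formats.add("AF", "A", "Float", "Variant allele fraction")
    header.add_sample(sample_name)
    return header


def write_vcf(
    calls: list[IndelCall],
    reference_fasta: str,
    sample_name: str,
    out_path: str,
    symbolic_threshold: int = 100,
) -> str:
    """Serialize calls to a VCF 4.2 file.

    Events below ``symbolic_threshold`` with recoverable sequence are written
    with explicit REF/ALT alleles; larger (or sequence-unrecoverable) events
    use symbolic ``<DEL>``/``<INS>`` alleles with END and SVLEN.  POS is the
    1-based anchor base immediately before the event.  Calls whose anchor or
    span falls outside the reference are dropped with a warning.
    """
    header = build_vcf_header(reference_fasta, sample_name)
    contig_len = {name: header.contigs[name].length for name in header.contigs}
    with pysam.FastaFile(reference_fasta) as fa, pysam.VariantFile(out_path, "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.rname, c.start, c.kind, c.size)):
            if call.rname not in contig_len:
                raise ValueError(f"call contig {call.rname!r} missing from reference")
            if call.start < 1 or call.end > contig_len[call.rname]:
                logger.warning("dropping call at %s:%d (outside reference)", call.rname, call.start)
                continue
            anchor = fa.fetch(call.rname, call.start - 1, call.start).upper()
            explicit = call.size < symbolic_threshold and (
                call.kind == "DEL" or call.inserted_seq
            )
            # pysam start is 0-based: VCF POS = call.start (the anchor base)
            if explicit and call.kind == "DEL":
                ref_allele = fa.fetch(call.rname, call.start - 1, call.start + call.size).upper()
                rec = vcf.new_record(
                    contig=call.rname, start=call.start - 1, alleles=(ref_allele, anchor)
                )
            elif explicit:
                rec = vcf.new_record(
                    contig=call.rname,
                    start=call.start - 1,
                    alleles=(anchor, anchor + call.inserted_seq.upper()),
                )
            else:
                rec = vcf.new_record(
                    contig=call.rname,
                    start=call.start - 1,
                    stop=call.start + (call.size if call.kind == "DEL" else 0),
                    alleles=(anchor, f"<{call.kind}>"),
                )
            rec.info["SVTYPE"] = call.kind
            rec.info["SVLEN"] = -call.size if call.kind == "DEL" else call.size
            rec.info["AO"] = call.support
            rec.info["DP"] = call.depth
            rec.info["AF"] = (round(call.vaf, 6),)
            if call.exitron:
                rec.info["EXITRON_CANDIDATE"] = True
                rec.info["SIZE_MOD3"] = call.size % 3
            if call.filters:
                for f in sorted(call.filters):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            rec.samples[sample_name]["DP"] = call.depth
            rec.samples[sample_name]["AO"] = call.support
            rec.samples[sample_name]["AF"] = (round(call.vaf, 6),)
            vcf.write(rec)
    return out_path
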