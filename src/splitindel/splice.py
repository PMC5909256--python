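"""RNA-mode post-filters: splicing-aware deletion filtering and exitron flags.

On RNA-seq aligned with a DNA chimera-aware aligner, a spliced read over an
intron looks exactly like a read over a genomic deletion.  A deletion call is
therefore kept only if it can NOT be explained as splicing:

1. neither breakpoint lies within ``splice_window`` (default 20 bp) of an
   annotated splice site (internal exon boundaries from a GTF), and
2. the deleted interval is not bounded by a canonical splice motif
   (GT..AG, GC..AG or AT..AC, checked on both genomic strands by default).

Deletions surviving both filters but fully contained in a coding exon are a
signature of *exitron* splicing (an intron entirely inside a coding exon)
when no matching DNA-level call exists; these are flagged as candidates, with
size mod 3 recorded (bona fide exitrons are enriched for frame-preserving,
multiple-of-three sizes).
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field

import gffutils
import pysam
from intervaltree import IntervalTree

from .calling import IndelCall

logger = logging.getLogger(__name__)

#: canonical intron-terminal dinucleotide pairs, DNA alphabet, (donor, acceptor)
SPLICE_MOTIFS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})
#: the same motifs read on the opposite genomic strand
SPLICE_MOTIFS_REVCOMP = frozenset({("CT", "AC"), ("CT", "GC"), ("GT", "AT")})


@dataclass(frozen=True)
class RnaFilterConfig:
    splice_window: int = 20
    check_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.splice_window < 0:
            raise ValueError("splice_window must be >= 0")


@dataclass
class SpliceSiteIndex:
    """Per-chromosome sorted annotated splice positions (0-based).

    A site is an internal exon boundary: the 0-based end of a non-terminal
    exon (donor side) or the 0-based start of a non-initial exon (acceptor
    side).  ``strands`` maps (chrom, pos) to the transcript strand(s).
    """

    sites: dict = field(default_factory=dict)  # rname -> sorted list[int]
    strands: dict = field(default_factory=dict)  # (rname, pos) -> set[str]

    def add(self, rname: str, pos: int, strand: str) -> None:
        self.sites.setdefault(rname, []).append(pos)
        self.strands.setdefault((rname, pos), set()).add(strand)

    def finalize(self) -> None:
        for rname in self.sites:
            self.sites[rname] = sorted(set(self.sites[rname]))

    def near(self, rname: str, pos: int, window: int) -> bool:
        """True iff any site on ``rname`` lies within ±window of ``pos``."""
        positions = self.sites.get(rname)
        if not positions:
            return False
        i = bisect_left(positions, pos - window)
        return i < len(positions) and positions[i] <= pos + window

    def __len__(self) -> int:
        return sum(len(v) for v in self.sites.values())


def _gtf_db(gtf_path: str) -> gffutils.FeatureDB:
    return gffutils.create_db(
        gtf_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )


def load_splice_sites(gtf_path: str) -> SpliceSiteIndex:
    """Collect internal exon boundaries of every transcript in a GTF.

    Terminal transcript boundaries are excluded (they are transcript ends,
    not splice sites); duplicated sites across transcripts collapse to one.
    """
    db = _gtf_db(gtf_path)
    by_transcript: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes.get("transcript_id", [exon.seqid + ":na"])[0]
        by_transcript.setdefault(tid, []).append(exon)
    idx = SpliceSiteIndex()
    if not by_transcript:
        warnings.warn(f"no exon features found in {gtf_path}; splice index is empty")
        return idx
    for exons in by_transcript.values():
        exons.sort(key=lambda e: e.start)
        for e in exons[:-1]:
            idx.add(e.seqid, e.end, e.strand)  # 0-based exon end (donor side)
        for e in exons[1:]:
            idx.add(e.seqid, e.start - 1, e.strand)  # 0-based exon start (acceptor)
    idx.finalize()
    return idx


def load_coding_exons(gtf_path: str) -> dict:
    """Coding-exon intervals (CDS features) as per-chromosome interval trees."""
    db = _gtf_db(gtf_path)
    trees: dict[str, IntervalTree] = {}
    n = 0
    for feat in db.features_of_type("CDS"):
        trees.setdefault(feat.seqid, IntervalTree()).addi(feat.start - 1, feat.end)
        n += 1
    if n == 0:
        warnings.warn(f"no CDS features in {gtf_path}; falling back to exon features")
        for feat in db.features_of_type("exon"):
            trees.setdefault(feat.seqid, IntervalTree()).addi(feat.start - 1, feat.end)
    return trees


def near_splice_site(call, idx: SpliceSiteIndex, window: int = 20) -> bool:
    """True iff either deletion breakpoint is within ±window of a splice site."""
    return idx.near(call.rname, call.start, window) or idx.near(
        call.rname, call.start + call.size, window
    )


def motif_match(call, reference, check_both_strands: bool = True) -> bool:
    """True iff the deleted interval is bounded by a canonical splice motif.

    The check reads the first two and last two bases of the deleted interval
    (the donor/acceptor dinucleotides of the putative intron).  ``reference``
    is a FASTA path, a :class:`pysam.FastaFile`, or a dict of sequences.
    """
    start, end = call.start, call.start + call.size
    seq = _fetch(reference, call.rname, start, end)
    if seq is None:
        raise ValueError(f"deleted interval {call.rname}:{start}-{end} outside reference")
    if len(seq) < 2:
        return False
    pair = (seq[:2].upper(), seq[-2:].upper())
    if pair in SPLICE_MOTIFS:
        return True
    return check_both_strands and pair in SPLICE_MOTIFS_REVCOMP


def _fetch(reference, rname: str, start: int, end: int) -> str | None:
    if isinstance(reference, dict):
        seq = reference.get(rname)
        if seq is None or start < 0 or end > len(seq):
            return None
        return seq[start:end]
    if isinstance(reference, str):
        with pysam.FastaFile(reference) as fa:
            return _fetch_fa(fa, rname, start, end)
    return _fetch_fa(reference, rname, start, end)


def _fetch_fa(fa: pysam.FastaFile, rname: str, start: int, end: int) -> str | None:
    if rname not in fa.references or start < 0 or end > fa.get_reference_length(rname):
        return None
    return fa.fetch(rname, start, end)


def filter_rna_deletions(
    calls: list[IndelCall],
    idx: SpliceSiteIndex,
    reference,
    cfg: RnaFilterConfig | None = None,
) -> list[IndelCall]:
    """Annotate deletion calls explainable as splicing; keep everything.

    A DEL is retained (PASS) iff it is neither near an annotated splice site
    nor bounded by a splice motif; rejected calls carry ``NEAR_SPLICE`` /
    ``SPLICE_MOTIF`` in their filter set (emitted to the VCF FILTER column)
    rather than being dropped.  INS calls pass through unchanged.  The filter
    is idempotent.
    """
    cfg = cfg or RnaFilterConfig()
    ref_seqs = reference
    if isinstance(reference, str):
        ref_seqs = pysam.FastaFile(reference)
    for call in calls:
        if call.kind != "DEL":
            continue
        call.filters.discard("NEAR_SPLICE")
        call.filters.discard("SPLICE_MOTIF")
        if near_splice_site(call, idx, cfg.splice_window):
            call.filters.add("NEAR_SPLICE")
        if motif_match(call, ref_seqs, cfg.check_both_strands):
            call.filters.add("SPLICE_MOTIF")
    if ref_seqs is not reference:
        ref_seqs.close()
    return calls


def flag_exitron_candidates(
    calls: list[IndelCall],
    coding_exons: dict,
    dna_calls: list[IndelCall] | None = None,
) -> list[IndelCall]:
    """Flag retained deletions fully inside one coding exon as exitron candidates.

    When ``dna_calls`` is provided, a deletion with an identical
    (coordinate, kind, size) DNA-level call is a genomic deletion and is not
    flagged.  ``size_mod3`` is recorded on every candidate (frame-preserving
    exitrons have size % 3 == 0).
    """
    dna_keys = {c.key for c in dna_calls} if dna_calls is not None else set()
    for call in calls:
        call.exitron = False
        call.size_mod3 = None
        if call.kind != "DEL" or call.filters:
            continue
        tree = coding_exons.get(call.rname)
        if tree is None:
            continue
        contained = any(
            iv.begin <= call.start and call.end <= iv.end
            for iv in tree.overlap(call.start, call.end)
        )
        if not contained:
            continue
        if call.key in dna_keys:
            continue
        call.exitron = True
        call.size_mod3 = call.size % 3
    return calls
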