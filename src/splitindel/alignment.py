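"""Alignment-level data model: CIGAR strings, SA tags and linear-block classes.

A chimeric (split) read is stored in SAM as one representative alignment plus
an ``SA`` optional tag listing its other segment(s).  Everything downstream of
the aligner works on the *linear blocks* of such a read: the read interval and
reference interval covered by each aligned segment, plus a three-way class --

* ``MS``: left part mapped, right part soft-clipped (e.g. ``40M60S``)
* ``SM``: left part soft-clipped, right part mapped (e.g. ``40S60M``)
* ``O``:  anything else (both-clipped, unclipped, or spliced ``N`` CIGARs)

Internal coordinates are 0-based half-open; SAM positions are converted at
the boundary only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple

CIGAR_OPS = "MIDNSH=X"
#: ops that consume query (read) bases
QUERY_OPS = frozenset("MIS=X")
#: ops that consume reference bases
REF_OPS = frozenset("MDN=X")
#: aligned ops: consume both query and reference
ALIGNED_OPS = frozenset("M=X")
CLIP_OPS = frozenset("SH")

_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")


class CigarOp(NamedTuple):
    length: int
    op: str


class CigarError(ValueError):
    """Raised for malformed CIGAR or SA-tag text."""


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse a SAM CIGAR string into a list of :class:`CigarOp`.

    Raises :class:`CigarError` naming the offending position for malformed
    input.  Reserializing the result with :func:`cigar_to_string` reproduces
    ``text`` exactly.
    """
    if not text or text == "*":
        raise CigarError("empty or absent CIGAR string")
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR {text!r} at position {pos}")
        length, op = int(m.group(1)), m.group(2)
        if op not in CIGAR_OPS:
            raise CigarError(f"unknown CIGAR op {op!r} at position {m.start(2)}")
        if length < 1:
            raise CigarError(f"zero-length CIGAR op at position {m.start()}")
        ops.append(CigarOp(length, op))
        pos = m.end()
    if pos != len(text):
        raise CigarError(f"malformed CIGAR {text!r} at position {pos}")
    return ops


def cigar_to_string(ops: list[CigarOp]) -> str:
    return "".join(f"{n}{op}" for n, op in ops)


def query_length(ops: list[CigarOp]) -> int:
    """Total query bases consumed (M/I/S/=/X); equals len(SEQ) when present."""
    return sum(n for n, op in ops if op in QUERY_OPS)


def reference_span(ops: list[CigarOp]) -> int:
    """Total reference bases consumed (M/D/N/=/X)."""
    return sum(n for n, op in ops if op in REF_OPS)


def full_read_length(ops: list[CigarOp]) -> int:
    """Query length including hard-clipped bases (full original read)."""
    return query_length(ops) + sum(n for n, op in ops if op == "H")


def _leading_clip(ops: list[CigarOp]) -> int:
    n = 0
    for length, op in ops:
        if op in CLIP_OPS:
            n += length
        else:
            break
    return n


def _trailing_clip(ops: list[CigarOp]) -> int:
    n = 0
    for length, op in reversed(ops):
        if op in CLIP_OPS:
            n += length
        else:
            break
    return n


def classify_linear(ops: list[CigarOp]) -> str:
    """Classify a linear alignment as ``MS``, ``SM`` or ``O``.

    Classification looks only at terminal clips (S or H); internal I/D ops do
    not change the class.  CIGARs containing ``N`` (an aligner-asserted splice)
    are always ``O``.
    """
    if any(op == "N" for _, op in ops):
        return "O"
    lead = _leading_clip(ops) > 0
    trail = _trailing_clip(ops) > 0
    if trail and not lead:
        return "MS"
    if lead and not trail:
        return "SM"
    return "O"


class SaHit(NamedTuple):
    """One record of a SAM ``SA`` tag: ``rname,pos,strand,CIGAR,mapQ,NM;``."""

    rname: str
    pos: int  # 1-based, as in the tag
    strand: str
    cigar: str
    mapq: int
    nm: int

    def to_string(self) -> str:
        return f"{self.rname},{self.pos},{self.strand},{self.cigar},{self.mapq},{self.nm};"


def parse_sa_tag(text: str) -> list[SaHit]:
    """Parse an ``SA`` tag value into its hits; the empty string yields []."""
    hits: list[SaHit] = []
    if not text:
        return hits
    for rec in text.split(";"):
        if not rec:
            continue
        fields = rec.split(",")
        if len(fields) != 6:
            raise CigarError(f"malformed SA record {rec!r}: expected 6 fields")
        rname, pos, strand, cigar, mapq, nm = fields
        if strand not in "+-":
            raise CigarError(f"malformed SA strand {strand!r} in {rec!r}")
        try:
            hit = SaHit(rname, int(pos), strand, cigar, int(mapq), int(nm))
        except ValueError as exc:
            raise CigarError(f"malformed SA record {rec!r}: {exc}") from exc
        parse_cigar(cigar)  # validate
        hits.append(hit)
    return hits


@dataclass(frozen=True)
class LinearBlock:
    """The aligned portion of one linear alignment of a (possibly split) read.

    ``q_start``/``q_end`` delimit the read bases covered by aligned ops
    (0-based half-open, in the orientation of the stored SEQ; hard-clipped
    bases count toward the clip).  ``r_start``/``r_end`` delimit the reference
    interval (0-based half-open).  ``ops`` keeps the aligned (non-clip) CIGAR
    ops for later rewriting.
    """

    rname: str
    strand: str
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    cls: str
    ops: tuple[CigarOp, ...]

    @property
    def read_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def ref_span(self) -> int:
        return self.r_end - self.r_start


def to_block(rname: str, pos: int, strand: str, cigar: list[CigarOp] | str) -> LinearBlock:
    """Build a :class:`LinearBlock` from SAM fields (``pos`` is 1-based)."""
    ops = parse_cigar(cigar) if isinstance(cigar, str) else cigar
    lead = _leading_clip(ops)
    trail = _trailing_clip(ops)
    total = full_read_length(ops)
    aligned = tuple(
        CigarOp(n, op) for n, op in ops if op not in CLIP_OPS
    )
    r_start = pos - 1
    return LinearBlock(
        rname=rname,
        strand=strand,
        q_start=lead,
        q_end=total - trail,
        r_start=r_start,
        r_end=r_start + reference_span(ops),
        cls=classify_linear(ops),
        ops=aligned,
    )
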