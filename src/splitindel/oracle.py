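"""Brute-force split-matching oracle for validating indel reconstruction.

Completely independent of the chimeric-pair arithmetic: given a read and a
small reference, it tries every split of the read into an exactly-matching
prefix and suffix and enumerates every single-event (one DEL or one INS)
explanation.  The minimal-size explanation at its leftmost valid breakpoint
is returned.  Quadratic and meant for references of a few kb only.
"""

from __future__ import annotations

from typing import NamedTuple


class OracleEvent(NamedTuple):
    kind: str  # "DEL" | "INS"
    size: int
    ref_break: int  # leftmost valid 0-based breakpoint


def _occurrences(ref: str, pattern: str) -> list[int]:
    out = []
    i = ref.find(pattern)
    while i != -1:
        out.append(i)
        i = ref.find(pattern, i + 1)
    return out


def _leftmost_del(ref: str, read: str, k: int, end1: int, p2: int) -> int:
    """Slide a DEL placement left one base at a time while the shifted suffix
    still matches: needs no new search, only a single-character check."""
    while k > 0 and p2 > 0 and ref.startswith(read[k - 1 :], p2 - 1):
        k -= 1
        end1 -= 1
        p2 -= 1
    return end1


def _leftmost_ins(ref: str, read: str, k1: int, end1: int, size: int) -> int:
    while k1 > 0 and end1 > 0 and ref.startswith(read[k1 - 1 + size :], end1 - 1):
        k1 -= 1
        end1 -= 1
    return end1


def brute_force_indel(ref: str, read: str, min_anchor: int = 16) -> OracleEvent | None:
    """Enumerate all prefix/suffix exact-match explanations of ``read``.

    Both parts must be at least ``min_anchor`` bases to be *found* (shorter
    anchors match the reference by chance and do not identify a unique
    event); an anchored candidate is then slid leftward base by base, which
    requires no search, so junction homology longer than the anchor slack
    still resolves to the true leftmost placement.  Deletions arise from one
    split whose suffix matches downstream of the prefix end; insertions from
    a split pair whose skipped read bases sit between a prefix and a suffix
    that abut on the reference.  Among all candidate events the smallest
    wins, ties resolved to the leftmost breakpoint.
    """
    L = len(read)
    candidates: list[OracleEvent] = []
    prefix_occ = {
        k: _occurrences(ref, read[:k]) for k in range(min_anchor, L - min_anchor + 1)
    }
    for k, p1s in prefix_occ.items():
        suffix = read[k:]
        for p1 in p1s:
            end1 = p1 + k
            for p2 in _occurrences(ref, suffix):
                if p2 > end1:
                    candidates.append(
                        OracleEvent("DEL", p2 - end1, _leftmost_del(ref, read, k, end1, p2))
                    )
    for k1, p1s in prefix_occ.items():
        for p1 in p1s:
            end1 = p1 + k1
            for k2 in range(k1 + 1, L - min_anchor + 1):
                if ref.startswith(read[k2:], end1):
                    candidates.append(
                        OracleEvent(
                            "INS", k2 - k1, _leftmost_ins(ref, read, k1, end1, k2 - k1)
                        )
                    )
    if not candidates:
        return None
    size = min(c.size for c in candidates)
    return min((c for c in candidates if c.size == size), key=lambda c: c.ref_break)
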