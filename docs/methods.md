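# Methods

## Chimeric-alignment model

A chimera-aware local aligner reports a read spanning a large indel as two
linear alignments of the same record: the representative alignment (the SAM
line itself) and one alternative segment in the `SA` tag
(`rname,pos,strand,CIGAR,mapQ,NM;`). Each linear alignment is reduced to a
*block*: the read interval and reference interval covered by its aligned
(non-clip) CIGAR ops, plus a class — `MS` (mapped then soft-clipped), `SM`
(soft-clipped then mapped) or `O` (anything else). Classification depends
only on terminal clips; hard clips count as clips; CIGARs containing `N` are
always `O` because `N` is an aligner-asserted splice and lies outside the
chimeric model.

Reconstruction orders the two blocks by read coordinate and requires an
`MS` upstream block and an `SM` downstream block on the same chromosome and
strand. With 0-based starts `q1,q2` (read) and `r1,r2` (reference):

```
overlap = max(0, q_end1 − q2)              # junction microhomology
net     = (r2 − r1) − (q2 − q1)
net > 0 → DEL(size = net);   net < 0 → INS(size = −net)
ref_break = r_end1 − overlap               # leftmost placement
```

The overlap is trimmed from the upstream block in both read and reference
space, which yields the leftmost valid breakpoint for deletions directly.
For insertions whose homology manifests as maximal aligner extension rather
than read-interval overlap, the leftmost representation is restored by
standard VCF left-normalisation at the calling stage (see below). The
inserted sequence is `read[q_end1 − overlap : q_end1 − overlap + size]`; for
tandem-duplication geometry this interval reaches into (or swallows) the
downstream block, which is handled by trimming the downstream ops.

Degenerate junctions are rejected rather than guessed at:

* read-gap + deletion geometry (unaligned read bases at a junction whose net
  offset is positive) and reference-gap + insertion geometry are combined
  DEL+INS events — the single-event model does not apply;
* pairs overlapping by more than `max_read_overlap` (default 10 bp) are
  discarded as "large overlaps"; junction microhomology is typically a few
  bases, and a 10 bp cap rejects alignment artifacts while keeping real
  junctions (exposed as `--max-overlap`);
* hard-clipped representative records are never reconstructed (the clipped
  bases are absent, so sequence recovery and CIGAR rewriting are
  ill-defined); hard-clipped `SA` entries still serve as coordinates.

## CIGAR rewriting and the redefined BAM

A reconstructed read's CIGAR becomes
`[lead S] upstream-ops(trimmed) + (size D | size I) + downstream-ops(trimmed) + [trail S]`,
with the record moved to the upstream block's position, the `SA` tag removed
(the alignment is no longer chimeric, which also makes a second build pass a
no-op) and the original CIGAR preserved in `OC`. Query-consuming ops must
sum exactly to the read length; a violation is an internal error, never
silently corrected. `redefine_bam` writes every input record exactly once —
rewritten where an event was reconstructed, verbatim otherwise — so
downstream depth is conserved; output is re-sorted and indexed because
rewriting can move records leftward. Reads are reconstructed only if they
pass the preprocessing filters: no `XA` tag (multi-mapped), MAPQ ≥ 60 for
both the record and its `SA` hit, not secondary, not duplicate-flagged
(duplicates are assumed marked upstream; `--keep-duplicates` overrides), and
exactly one `SA` hit. Each mate is processed independently; no insert-size
evidence is used — the model is purely split-read.

## Calling

Calling scans the redefined BAM once: every `D`/`I` op in a read with MAPQ
≥ 15 contributes a candidate keyed by (chromosome, position, type, size,
inserted sequence), supported by distinct read names (a query name never
counts twice at one locus, so a rewritten primary and a surviving mate
cannot double-vote). When the reference is available each candidate is
left-normalised before aggregation, so homology-shifted observations of the
same event collapse into one key. Depth is the number of qualifying reads
covering the left breakpoint base (the anchor base for insertions), and
VAF = support/depth. Thresholds: support ≥ 2, VAF ≥ 0.05, size ≥ 1 by
default; the tumor preset raises these to VAF ≥ 0.10 and size ≥ 10.
An optional BED restricts output to calls fully contained in a region.

Two known biases are documented rather than corrected. First, only
breakpoint-spanning split reads support a large deletion while every
read covering the breakpoint counts toward depth, so VAF underestimates the
true allele fraction for large events; the redefined BAM is the supported
hand-off to re-estimators that realign clipped reads. Second, depth for a
deletion is measured at the left breakpoint, not averaged over the span —
the cheapest well-defined choice; for well-behaved coverage the difference
is noise.

Somatic status uses two criteria against a matched normal: subtraction
(an identical chromosome/position/type/size call in the normal call set) and
a split-read check (any clipped or indel-carrying normal read whose
clip/indel point lies within 5 bp of either tumor breakpoint). Either flags
the call `IN_NORMAL`.

## VCF output

VCF 4.2 via htslib. `POS` is the 1-based anchor base before the event.
Events smaller than 100 bp with recoverable sequence get explicit REF/ALT
alleles; larger or sequence-unrecoverable events are symbolic
(`<DEL>`/`<INS>` with `END`, `SVLEN`). The 100 bp switch keeps REF alleles
short while remaining round-trippable: the evaluator matches on
(chromosome, POS, type, |SVLEN|) either way. Rejected RNA-mode deletions are
*written*, not dropped, carrying `NEAR_SPLICE`/`SPLICE_MOTIF`/`IN_NORMAL`
FILTER values — auditability, and the exitron analysis consumes the same
stream. Calls whose anchor or span leaves the contig are dropped with a
warning.

## RNA mode

Splice sites are the internal exon boundaries of every transcript in the
GTF (terminal transcript ends excluded, duplicates collapsed), held as
sorted per-chromosome positions with O(log n) window queries. A deletion is
splice-explainable if **either** breakpoint lies within ±20 bp of a site —
one shared boundary is enough to suspect splicing — or if the first two and
last two bases of the deleted interval form a canonical donor/acceptor pair
(`GT-AG`, `GC-AG`, `AT-AC`). Both genomic orientations are checked by
default because unannotated antisense transcription exists;
`--single-strand-motif` restricts to the forward orientation. Insertions
pass through untouched: splicing cannot mimic an insertion.

Exitron candidates are retained (PASS) deletions fully contained in one
coding exon (CDS features; exons as fallback) with no identical DNA-level
call. The definition is deliberately candidate-level — a confirmatory DNA
sample or wet-lab assay is the arbiter — and each candidate records
`SIZE_MOD3`, since genuine exitrons are enriched for frame-preserving
multiple-of-three sizes. There is no formal community definition of an
exitron call; this containment + DNA-absence rule is this package's
operationalisation.

## Synthetic data

The generators emulate the study conditions end to end. `make_reference`
draws i.i.d. bases at a target GC (uniform 50% by default — no repeats, no
chromosome structure). `random_truth` places non-overlapping variants on a
jittered grid with ≥ 600 bp spacing so no fragment spans two events, and
left-normalises them; default sizes are 10–1000 bp for deletions and
10–85 bp for insertions (85 bp is the widest insertion a 100 bp read can
span with usable anchors, and matches the insertion ceiling observed with
real 100 bp data). `emit_chimeric_sam` produces idealized aligner output:
breakpoint-covering reads become MS+SM chimeras with MAPQ 60 and exact
coordinates, alternating which block is the representative; reference-
haplotype reads become plain `100M` records, giving binomial support at the
chosen variant fraction (default 0.5, a heterozygous germline event).
`simulate_reads` adds the realistic layer: 2×100 bp pairs (read length
≥ 75 bp enforced), fragment length N(300, 30), uniform substitution errors
at 0.1%, constant Q30-style qualities (the caller ignores base quality).
Reads are mapped back either by the *provenance aligner* — coordinates
derived from the known variant map, chimeras emitted when both anchors reach
15 bp (5 bp for insertions), clipped records otherwise — or by a real
`bwa mem` run through the external adapter.

What passing on this data does **not** show: behaviour in repeats and
segmental duplications (where MAPQ filters and unique-anchor assumptions
bite), aligner-specific clip placement quirks, indel error processes,
coverage waves, or multi-event haplotypes. The generators are deliberately
clean so that failures indict the algorithm, not the fixture.

## Validation experiments and problem sizes

The experiment suite (also run by `scripts/acceptance.py`) uses: a 1 Mb
reference with 30+30 implanted indels, each breakpoint covered by 50 reads
at 0.5 variant fraction (the heterozygous 50× condition), for the exact
inverse test; a 300 kb
reference at 50× (≈150 000 reads) for the simulated-read test through both
aligner paths, scoring deletions ≥ 50 bp with ±5 bp position matching; 1000
random ≤ 5 kb references for oracle equivalence; and a 10 kb five-exon gene
(400 bp exons, 1.5 kb GT..AG introns, one 112 bp mid-exon deletion with
engineered non-motif, non-shifting breakpoints) for RNA specificity. Bulk
invariants (query-length conservation, record conservation, build and filter
idempotence, threshold monotonicity) run on ≥ 10⁴ random cases each. These
sizes give every event type double-digit replication while keeping the whole
suite around half a minute on one core.

The brute-force oracle is independent of the pair arithmetic: it tries every
split of the read into an exactly-matching prefix and suffix (each ≥ 16 bp,
below which chance matches are expected on a multi-kb reference) and returns
the minimal single-event explanation at its leftmost breakpoint.
Reconstruction output is left-normalised before comparison, since the oracle
enumerates placements while the pair arithmetic sees only the placement the
aligner chose.

## Numerical and tie-breaking choices

* Internal coordinates are 0-based half-open everywhere; SAM and VCF
  conversion happens only at the I/O boundary.
* Blocks with equal read starts, whole-block overlaps, and events smaller
  than `min_indel_size` reconstruct to nothing rather than something
  arbitrary.
* `support > depth` cannot happen by construction except for an insertion
  whose anchor base precedes the read start; depth is clamped up to support
  in that corner.
* Zero-depth loci are skipped (VAF undefined), zero-length references and
  malformed CIGAR/SA/GTF inputs raise with the offending position named.
* Determinism: all generators are pure functions of their seed; call output
  order is (chromosome, position, type, size); evaluator matching is
  nearest-position one-to-one.

## Limitations

Inversions, translocations and inter-chromosomal events are out of scope by
the same-chromosome/strand rule. Insertions longer than the read minus two
anchors are invisible to a single split read (the 85 bp ceiling at 2×100 bp).
There is no genotyping model, no base-quality weighting, no multi-sample
joint calling, and no assembly-based recovery of long insertions. RNA-mode
specificity is bounded by annotation completeness: an unannotated intron
with non-canonical motifs is indistinguishable from a genomic deletion
without matched DNA.
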