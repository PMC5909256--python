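# splitindel

Split-read detection of **large deletions and mid-sized insertions** from
DNA-seq or RNA-seq alignments, with splice-aware filtering for RNA data.

Short-read aligners cannot represent a read spanning a large indel as one
linear alignment. A chimera-aware aligner such as BWA-MEM instead reports a
*chimeric* alignment: a representative record with part of the read
soft-clipped, plus a single alternative segment encoded in the `SA` tag.
`splitindel` parses these chimeras, reconstructs the underlying indel,
rewrites each read as a linear alignment with an explicit `D`/`I` CIGAR
operation, and calls indels from the redefined BAM. The redefined BAM is a
first-class output that downstream callers can consume directly.

This matters most for RNA-seq, where spliced aligners mark large deletions as
junctions and DNA-style callers drown in splice-induced false positives:
`splitindel` removes deletion calls explainable as splicing and flags the
remainder that sit entirely inside coding exons as candidate **exitrons**
(exonic introns — non-canonical splicing that mimics a genomic deletion).

## The model

Order the two aligned blocks of a chimeric read by read coordinate. With
`q` the read-interval starts and `r` the reference-interval starts
(0-based), the net offset is

```
net = (r2 − r1) − (q2 − q1)        # target offset minus read offset
net > 0  →  deletion of net bases
net < 0  →  insertion of −net bases (novel sequence or tandem duplication)
```

The upstream block must be mapped-then-clipped (`MS`), the downstream block
clipped-then-mapped (`SM`), both on the same chromosome and strand. Junction
microhomology — read bases claimed by both blocks — is trimmed from the
upstream block, placing the breakpoint at its leftmost (VCF-normalised)
position; pairs overlapping by more than 10 bp (configurable) are rejected.
Calling is a pileup over the redefined BAM: reads with MAPQ ≥ 15 vote per
distinct (position, type, size, sequence) event, requiring ≥ 2 supporting
reads and VAF = support/depth above threshold (defaults 0.05 germline,
0.10 with `--preset tumor`).

In RNA mode a deletion is reported only if **(1)** neither breakpoint lies
within 20 bp of an annotated splice site (GTF exon boundaries) and **(2)**
the deleted interval is not bounded by a canonical splice motif
(`GT..AG`, `GC..AG`, `AT..AC`, both strands). Surviving deletions fully
contained in a coding exon and absent from DNA-level calls are annotated
`EXITRON_CANDIDATE`.

## Worked example

The package ships generators for everything it consumes, so a complete run
needs no external data. Simulate a 100 kb reference with five implanted
indels covered by chimeric reads at 50% variant fraction:

```python
from splitindel import simulate as sim
ref = sim.make_reference(100_000, gc=0.5, seed=42)
truth = sim.random_truth(ref, "chr1", n_del=3, n_ins=2,
                         del_sizes=(50, 800), ins_sizes=(10, 60), seed=43)
sam = sim.emit_chimeric_sam("chr1", ref, truth, read_len=100, depth=20,
                            variant_fraction=0.5, seed=44)
sim.sam_to_bam(sam, "raw.bam")
sim.write_fasta("ref.fa", "chr1", ref)
```

then run the two-step workflow:

```console
$ splitindel build --bam raw.bam --out redefined.bam
{ "records_in": 100, "records_out": 100, ...,
  "chimeric_pairs": 46, "rewritten": 46, "events": {"DEL": 29, "INS": 17} }

$ splitindel call --bam redefined.bam --ref ref.fa --out calls.vcf --preset germline
{ "mode": "dna", "calls": 5, "pass": 5, ... }
```

All 46 chimeric reads were rewritten with explicit indel CIGARs, and the five
implanted events are called exactly (`grep -v '^##' calls.vcf`):

```
#CHROM  POS    ID  REF  ALT     QUAL FILTER INFO
chr1    983    .   G    GCTCG…  .    PASS   SVTYPE=INS;SVLEN=39;AO=8;DP=20;AF=0.4
chr1    33214  .   C    <DEL>   .    PASS   END=33709;SVTYPE=DEL;SVLEN=-495;AO=10;DP=20;AF=0.5
chr1    57244  .   G    <DEL>   .    PASS   END=58002;SVTYPE=DEL;SVLEN=-758;AO=11;DP=20;AF=0.55
chr1    60735  .   A    <DEL>   .    PASS   END=61534;SVTYPE=DEL;SVLEN=-799;AO=8;DP=20;AF=0.4
chr1    90766  .   A    AATTA…  .    PASS   SVTYPE=INS;SVLEN=11;AO=9;DP=20;AF=0.45
```

`POS` is the 1-based anchor base before each event; events ≥ 100 bp are
written symbolically with `END`/`SVLEN`; `AO/DP/AF` give supporting reads,
breakpoint depth and variant allele fraction (the implanted variant fraction
was 0.5). For RNA data add `--mode rna --gtf genes.gtf` to annotate
splice-explainable deletions (`NEAR_SPLICE`, `SPLICE_MOTIF` FILTER values)
and exitron candidates.

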