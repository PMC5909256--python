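"""Chimeric-pair reconstruction: filters, offset arithmetic, CIGAR rewriting."""

import numpy as np
import pysam
import pytest

from splitindel import simulate as sim
from splitindel.alignment import cigar_to_string, to_block
from splitindel.calling import left_normalize
from splitindel.oracle import brute_force_indel
from splitindel.reconstruct import (
    ChimericPair,
    ReconstructConfig,
    RejectReason,
    eligible_read,
    extract_chimeric,
    reconstruct_indel,
    redefine_bam,
    rewritten_cigar,
)

CFG = ReconstructConfig()


def _segment(header, cigar="40M60S", mapq=60, flag=0, tags=(), pos=1000):
    rec = pysam.AlignedSegment(header=header)
    rec.query_name = "r1"
    rec.flag = flag
    rec.reference_id = 0
    rec.reference_start = pos
    rec.mapping_quality = mapq
    rec.cigarstring = cigar
    rec.query_sequence = "A" * 100
    for tag, value in tags:
        rec.set_tag(tag, value)
    return rec


@pytest.fixture(scope="module")
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chr1", "LN": 1_000_000}]}
    )


@pytest.mark.parametrize(
    "kwargs, reason",
    [
        ({"tags": [("XA", "chr2,+100,100M,0;")]}, RejectReason.MULTIMAP),
        ({"mapq": 59}, RejectReason.LOWQ),
        ({"flag": 0x100}, RejectReason.SECONDARY),
        ({"flag": 0x400}, RejectReason.DUP),
        ({}, None),
    ],
)
def test_eligible_read_reasons(header, kwargs, reason):
    ok, why = eligible_read(_segment(header, **kwargs), CFG)
    assert ok is (reason is None)
    assert why == reason


def test_duplicates_kept_when_configured(header):
    cfg = ReconstructConfig(drop_duplicates=False)
    ok, _ = eligible_read(_segment(header, flag=0x400), cfg)
    assert ok


def test_extract_chimeric_requires_single_confident_hit(header):
    two = _segment(header, tags=[("SA", "chr1,1201,+,40S60M,60,0;chr1,99,+,50S50M,60,0;")])
    assert extract_chimeric(two, CFG) is None
    lowq = _segment(header, tags=[("SA", "chr1,1201,+,40S60M,30,0;")])
    assert extract_chimeric(lowq, CFG) is None
    none = _segment(header)
    assert extract_chimeric(none, CFG) is None
    good = _segment(header, tags=[("SA", "chr1,1201,+,40S60M,60,0;")])
    pair = extract_chimeric(good, CFG)
    assert pair is not None
    assert pair.rl.cls == "MS" and pair.al.cls == "SM"


def _pair(up, down, read_len=100, seq=None, rl_upstream=True):
    u = to_block(*up)
    d = to_block(*down)
    rl, al = (u, d) if rl_upstream else (d, u)
    return ChimericPair(rl=rl, al=al, read_len=read_len, seq=seq or "A" * read_len, query_name="q")


class TestReconstructArithmetic:
    def test_large_deletion(self):
        """Target offset 200 vs read offset 40 -> 160 bp deletion at 1040."""
        pair = _pair(("chr1", 1001, "+", "40M60S"), ("chr1", 1201, "+", "40S60M"))
        ev = reconstruct_indel(pair, CFG)
        assert (ev.kind, ev.size, ev.ref_break) == ("DEL", 160, 1040)

    def test_novel_insertion(self):
        seq = "A" * 50 + "ACGTACGTACGTACGTACGT" + "A" * 30
        pair = _pair(("chr2", 2001, "+", "50M50S"), ("chr2", 2051, "+", "70S30M"), seq=seq)
        # same-chromosome pair on a two-contig mock: rname check only
        ev = reconstruct_indel(pair, CFG)
        assert (ev.kind, ev.size, ev.ref_break) == ("INS", 20, 2050)
        assert ev.inserted_seq == seq[50:70]

    def test_tandem_duplication_geometry(self):
        """Target offset (20) shorter than read offset (60): 40 bp insertion."""
        pair = _pair(("chr3", 3001, "+", "60M40S"), ("chr3", 3021, "+", "60S40M"))
        ev = reconstruct_indel(pair, CFG)
        assert (ev.kind, ev.size) == ("INS", 40)

    def test_representative_may_be_downstream_block(self):
        pair = _pair(("chr1", 1001, "+", "40M60S"), ("chr1", 1201, "+", "40S60M"), rl_upstream=False)
        ev = reconstruct_indel(pair, CFG)
        assert (ev.kind, ev.size, ev.ref_break) == ("DEL", 160, 1040)

    def test_cross_chromosome_and_strand_rejected(self):
        u = to_block("chr1", 1001, "+", "40M60S")
        d = to_block("chr2", 1201, "+", "40S60M")
        assert reconstruct_indel(ChimericPair(u, d, 100, "A" * 100, "q"), CFG) is None
        d2 = to_block("chr1", 1201, "-", "40S60M")
        assert reconstruct_indel(ChimericPair(u, d2, 100, "A" * 100, "q"), CFG) is None

    def test_wrong_class_geometry_rejected(self):
        # two MS blocks cannot bracket a junction
        pair = _pair(("chr1", 1001, "+", "40M60S"), ("chr1", 1201, "+", "60M40S"))
        assert reconstruct_indel(pair, CFG) is None

    def test_large_overlap_rejected(self):
        # blocks share 20 read bases > max_read_overlap
        pair = _pair(("chr1", 1001, "+", "60M40S"), ("chr1", 1241, "+", "40S60M"))
        assert reconstruct_indel(pair, CFG) is None
        relaxed = ReconstructConfig(max_read_overlap=25)
        assert reconstruct_indel(pair, relaxed) is not None

    def test_microhomology_trimmed_to_leftmost_breakpoint(self):
        """4 bp junction homology: breakpoint reported at its leftmost
        placement, size unchanged."""
        pair = _pair(("chr1", 1001, "+", "44M56S"), ("chr1", 1201, "+", "40S60M"))
        ev = reconstruct_indel(pair, CFG)
        assert ev.read_overlap == 4
        assert (ev.kind, ev.size, ev.ref_break) == ("DEL", 160, 1040)


def test_sign_law_exhaustive():
    """Implanting DEL(d) gives net +d and INS(i) gives net -i for every size
    in [1, 500] at 10 random split points each."""
    rng = np.random.default_rng(0)
    for size in range(1, 501):
        for _ in range(10):
            a1 = int(rng.integers(20, 81))
            b = 10_000
            pair = _pair(
                ("chr1", b - a1 + 1, "+", f"{a1}M{100 - a1}S"),
                ("chr1", b + size + 1, "+", f"{a1}S{100 - a1}M"),
            )
            ev = reconstruct_indel(pair, CFG)
            assert (ev.kind, ev.size) == ("DEL", size)
            read_len = size + a1 + 60
            pair = _pair(
                ("chr1", b - a1 + 1, "+", f"{a1}M{read_len - a1}S"),
                ("chr1", b + 1, "+", f"{a1 + size}S{read_len - a1 - size}M"),
                read_len=read_len,
            )
            ev = reconstruct_indel(pair, CFG)
            assert (ev.kind, ev.size) == ("INS", size)


def test_oracle_equivalence_sample():
    """Reconstruction agrees with the brute-force all-splits oracle in kind,
    size and leftmost breakpoint on random small references."""
    rng = np.random.default_rng(11)
    for i in range(200):
        case = sim.random_chimeric_case(rng)
        pair = sim.case_to_pair(case, rl_upstream=bool(i % 2))
        ev = reconstruct_indel(pair, CFG)
        orc = brute_force_indel(case.ref, case.read)
        assert ev is not None and orc is not None
        start, _ = left_normalize(
            case.rname, ev.ref_break, ev.kind, ev.size, ev.inserted_seq, case.ref
        )
        assert (ev.kind, ev.size, start) == (orc.kind, orc.size, orc.ref_break)


class TestRewrite:
    def test_deletion_rewrite(self):
        pair = _pair(("chr1", 1001, "+", "40M60S"), ("chr1", 1201, "+", "40S60M"))
        ev = reconstruct_indel(pair, CFG)
        pos, ops = rewritten_cigar(pair, ev)
        assert pos == 1000
        assert cigar_to_string(ops) == "40M160D60M"

    def test_insertion_rewrite(self):
        pair = _pair(("chr2", 2001, "+", "50M50S"), ("chr2", 2051, "+", "70S30M"))
        ev = reconstruct_indel(pair, CFG)
        pos, ops = rewritten_cigar(pair, ev)
        assert pos == 2000
        assert cigar_to_string(ops) == "50M20I30M"

    def test_full_tandem_duplication_rewrite_has_no_tail_match(self):
        pair = _pair(("chr3", 3001, "+", "60M40S"), ("chr3", 3021, "+", "60S40M"))
        ev = reconstruct_indel(pair, CFG)
        pos, ops = rewritten_cigar(pair, ev)
        assert cigar_to_string(ops) == "60M40I"

    def test_query_conservation_randomized(self):
        rng = np.random.default_rng(5)
        for i in range(500):
            case = sim.random_chimeric_case(rng, ref_len_range=(1500, 2500))
            pair = sim.case_to_pair(case, rl_upstream=bool(i % 2))
            ev = reconstruct_indel(pair, CFG)
            assert ev is not None
            _, ops = rewritten_cigar(pair, ev)  # raises if query sum is off
            assert sum(n for n, op in ops if op in "MIS=X") == pair.read_len


class TestRedefineBam:
    def test_passthrough_without_chimeras(self, tmp_path):
        ref = sim.make_reference(5000, 0.5, seed=3)
        # variant_fraction 0 emits plain full-M reads only
        sam = sim.emit_chimeric_sam(
            "chr1", ref, [sim.TruthVariant("chr1", 2000, "DEL", 50)],
            read_len=100, depth=8, variant_fraction=0.0, seed=4,
        )
        bam = str(tmp_path / "in.bam")
        sim.sam_to_bam(sam, bam)
        summary = redefine_bam(bam, str(tmp_path / "out.bam"))
        assert summary["rewritten"] == 0
        assert summary["records_in"] == summary["records_out"] == 8

    def test_record_conservation_and_rewrites(self, dna_fixture):
        s = dna_fixture.summary
        assert s["records_in"] == s["records_out"]
        assert s["rewritten"] > 0
        assert s["events"]["DEL"] > 0 and s["events"]["INS"] > 0

    def test_rewritten_records_carry_indel_and_no_sa(self, dna_fixture):
        n_indel = 0
        with pysam.AlignmentFile(dna_fixture.redefined_bam) as bam:
            for rec in bam.fetch():
                if rec.has_tag("OC"):
                    assert not rec.has_tag("SA")
                    assert any(op in (1, 2) for op, _ in rec.cigartuples)
                    n_indel += 1
        assert n_indel == dna_fixture.summary["rewritten"]

    def test_unsorted_input_rejected(self, tmp_path):
        sam = "@HD\tVN:1.6\tSO:queryname\n@SQ\tSN:chr1\tLN:1000\n"
        path = tmp_path / "unsorted.sam"
        path.write_text(sam)
        with pytest.raises(ValueError, match="sort"):
            redefine_bam(str(path), str(tmp_path / "out.bam"))
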