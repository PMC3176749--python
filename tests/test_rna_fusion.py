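"""Junction database enumeration, the 10 bp overlap rule, polarity
filtering, and end-to-end specificity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairfuse.refalign import (
    Alignment,
    GeneModel,
    Genome,
    ReadPair,
    SeedIndex,
    Transcript,
    make_transcript,
    revcomp,
)
from pairfuse.rna_fusion import (
    JunctionDbConfig,
    JunctionHit,
    annotate_readthrough,
    build_junction_db,
    junction_read_scan,
    mate_polarity_filter,
    run_rna_pipeline,
    stage1_filter,
)
from pairfuse.synthetic_data import RnaSimConfig, simulate_rna

from helpers import expected_junction_count


def _toy_pair_of_genes(rng, n_a=2, n_b=2, exon_len=120):
    """Two genes on one contig with given exon counts."""
    bases = np.frombuffer(b"ACGT", np.uint8)

    def exons(offset, n):
        out = []
        pos = offset
        for _ in range(n):
            out.append((pos, pos + exon_len))
            pos += exon_len + 250
        return out, pos

    ex_a, end_a = exons(100, n_a)
    ex_b, end_b = exons(end_a + 500, n_b)
    seq = rng.choice(bases, size=end_b + 200).tobytes().decode()
    genome = Genome({"c": seq})
    ga = GeneModel("GA", "c", "+", ex_a)
    gb = GeneModel("GB", "c", "+", ex_b)
    genes = {"GA": ga, "GB": gb}
    txs = {
        "GA-wt": make_transcript("GA-wt", ga, genome),
        "GB-wt": make_transcript("GB-wt", gb, genome),
    }
    return genome, genes, txs


# ---------------------------------------------------------------------------
# Junction database
# ---------------------------------------------------------------------------

def test_junction_db_two_by_two(rng):
    _, genes, txs = _toy_pair_of_genes(rng, 2, 2)
    recs = build_junction_db("GA", "GB", genes, txs)
    assert len(recs) == 10  # 4 + 4 + 1 + 1
    cats = [r.category for r in recs]
    assert cats.count("A-B") == 4 and cats.count("B-A") == 4
    assert cats.count("A-A") == 1 and cats.count("B-B") == 1


def test_junction_db_five_by_two(rng):
    _, genes, txs = _toy_pair_of_genes(rng, 5, 2)
    recs = build_junction_db("GA", "GB", genes, txs)
    assert len(recs) == 31  # 10 + 10 + 10 + 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n_a=st.integers(1, 8), n_b=st.integers(1, 8))
def test_junction_db_matches_ordered_pair_oracle(n_a, n_b):
    rng = np.random.default_rng(n_a * 10 + n_b)
    _, genes, txs = _toy_pair_of_genes(rng, n_a, n_b)
    recs = build_junction_db("GA", "GB", genes, txs)
    assert len(recs) == expected_junction_count(n_a, n_b)
    assert len({r.record_id for r in recs}) == len(recs)


def test_junction_record_geometry(rng):
    _, genes, txs = _toy_pair_of_genes(rng, 2, 2, exon_len=120)
    recs = build_junction_db("GA", "GB", genes, txs, JunctionDbConfig(flank=66))
    for r in recs:
        assert len(r.sequence) == 132  # exons >= 66 nt: full flanks
        assert r.offset == 66
        assert not r.shortened
    # cumulative flank: the A.e2|B.e1 record's 5' flank ends exon 2 of the
    # spliced GA transcript
    rec = next(r for r in recs if r.record_id.startswith("GA.e2|GB.e1"))
    assert rec.sequence[:66] == txs["GA-wt"].sequence[240 - 66 : 240]


def test_short_exon_flagged(rng):
    _, genes, txs = _toy_pair_of_genes(rng, 2, 2, exon_len=40)
    recs = build_junction_db("GA", "GB", genes, txs, JunctionDbConfig(flank=66))
    # first exon on the 5' side has only 40 nt of cumulative sequence
    first = [r for r in recs if r.exon5 == 1 and r.gene5 == "GA"]
    assert all(r.shortened for r in first)


# ---------------------------------------------------------------------------
# Junction read scan: the 10 bp rule and uniqueness
# ---------------------------------------------------------------------------

def test_junction_scan_overlap_rule(rng):
    _, genes, txs = _toy_pair_of_genes(rng, 2, 2)
    recs = build_junction_db("GA", "GB", genes, txs)
    rec = next(r for r in recs if r.category == "A-B")
    # 76-mer centered on the junction: overlaps (38, 38)
    read = rec.sequence[rec.offset - 38 : rec.offset + 38]
    hits = junction_read_scan([("p", 1, read)], recs)
    assert len(hits) == 1
    assert (hits[0].overlap5, hits[0].overlap3) == (38, 38)
    # only 9 nt on the 3' side: rejected by the 10 bp rule
    read9 = rec.sequence[rec.offset - 29 : rec.offset + 9]
    assert junction_read_scan([("p", 1, read9)], recs) == []
    # exactly 10 on each side passes at reduced length
    read10 = rec.sequence[rec.offset - 28 : rec.offset + 10]
    hits10 = junction_read_scan([("p", 1, read10)], recs)
    assert len(hits10) == 1 and hits10[0].overlap3 == 10


def test_junction_scan_requires_uniqueness(rng):
    _, genes, txs = _toy_pair_of_genes(rng, 2, 2)
    recs = build_junction_db("GA", "GB", genes, txs)
    rec = next(r for r in recs if r.category == "A-B")
    twin = JunctionRecordTwin = type(rec)(
        gene5="GX",
        exon5=1,
        gene3="GY",
        exon3=1,
        category="A-B",
        sequence=rec.sequence,
        offset=rec.offset,
    )
    read = rec.sequence[rec.offset - 30 : rec.offset + 30]
    assert junction_read_scan([("p", 1, read)], recs + [twin]) == []


def test_raising_min_overlap_is_monotone(locus):
    """Raising O_min never increases any candidate's junction-read count."""
    weights = {"ERRLIKE-wt": 10.0, "E2-C3": 5.0, "C11LIKE-wt": 0.0}
    iso = {**locus.transcripts, **locus.fusion_transcripts}
    iso = {t: iso[t] for t in weights}
    cfg = RnaSimConfig(isoform_weights=weights, n_pairs=6000, seed=13)
    reads, _ = simulate_rna(iso, cfg, locus.truth.fusion_junction_pos)
    totals = {}
    for o_min in (10, 20, 30):
        res = run_rna_pipeline(
            reads, locus.genes, locus.transcripts, JunctionDbConfig(min_overlap=o_min)
        )
        totals[o_min] = (
            int(res.table.total_count.iloc[0]) if len(res.table) else 0
        )
    assert totals[10] >= totals[20] >= totals[30]
    assert totals[10] > 0


# ---------------------------------------------------------------------------
# Polarity: all strand/side combinations
# ---------------------------------------------------------------------------

@pytest.fixture()
def polarity_setup(rng):
    genome, genes, txs = _toy_pair_of_genes(rng, 3, 3, exon_len=200)
    recs = build_junction_db("GA", "GB", genes, txs)
    # fusion GA.e2 -> GB.e2 (cross category A-B)
    rec = next(r for r in recs if r.record_id.startswith("GA.e2|GB.e2:A-B"))
    gene_of = {t: x.gene_id for t, x in txs.items()}
    return genes, txs, gene_of, rec


def _mate(target, start, strand, read_len=76, unique=True):
    return Alignment("p", 2, target, start, strand, 0, unique, read_len)


def test_polarity_all_combinations(polarity_setup):
    """Enumeration over junction-read strand x mate gene x mate strand: only
    the two configurations compatible with the fused gene order pass."""
    genes, txs, gene_of, rec = polarity_setup
    hit_fwd = JunctionHit("p", 1, rec, rec.offset - 38, "+", 0, 38, 38)
    hit_rev = JunctionHit("p", 1, rec, rec.offset - 38, "-", 0, 38, 38)
    # GB exon 2 starts at 200 in the GB transcript; a mate at 300 is
    # downstream of the junction; GA exon 2 ends at 400 in the GA transcript
    cases = [
        (hit_fwd, _mate("GB-wt", 300, "-"), True),
        (hit_fwd, _mate("GB-wt", 300, "+"), False),  # wrong mate orientation
        (hit_fwd, _mate("GB-wt", 50, "-"), False),  # upstream of junction
        (hit_fwd, _mate("GA-wt", 100, "-"), False),  # wrong gene
        (hit_rev, _mate("GA-wt", 150, "+"), True),
        (hit_rev, _mate("GA-wt", 150, "-"), False),
        (hit_rev, _mate("GA-wt", 500, "+"), False),  # downstream of junction
        (hit_rev, _mate("GB-wt", 300, "+"), False),  # wrong gene
    ]
    for hit, mate, want in cases:
        v = mate_polarity_filter(hit, mate, genes, txs, gene_of, max_insert=600)
        assert v.consistent is want, (hit.strand, mate.target_id, mate.strand, v.reason)


def test_polarity_insert_bound_and_orphan(polarity_setup):
    genes, txs, gene_of, rec = polarity_setup
    hit = JunctionHit("p", 1, rec, rec.offset - 38, "+", 0, 38, 38)
    ok = mate_polarity_filter(hit, _mate("GB-wt", 300, "-"), genes, txs, gene_of, 600)
    assert ok.consistent and ok.implied_fragment is not None
    far = mate_polarity_filter(hit, _mate("GB-wt", 300, "-"), genes, txs, gene_of, 100)
    assert not far.consistent and far.reason == "implied fragment too long"
    orphan = mate_polarity_filter(hit, None, genes, txs, gene_of, 600)
    assert not orphan.consistent and orphan.reason == "orphan mate"
    multi = mate_polarity_filter(
        hit, _mate("GB-wt", 300, "-", unique=False), genes, txs, gene_of, 600
    )
    assert not multi.consistent


# ---------------------------------------------------------------------------
# Read-through annotation
# ---------------------------------------------------------------------------

def test_readthrough_annotation(rng):
    _, genes, _ = _toy_pair_of_genes(rng, 2, 2)
    ga, gb = genes["GA"], genes["GB"]
    assert annotate_readthrough(ga, gb) is True  # GA upstream of GB, + strand
    assert annotate_readthrough(gb, ga) is False  # reversed order: a fusion
    far = GeneModel("GF", "c", "+", [(x + 200_000, y + 200_000) for x, y in gb.exons])
    assert annotate_readthrough(ga, far) is False  # beyond the gap
    other = GeneModel("GO", "c2", "+", gb.exons)
    assert annotate_readthrough(ga, other) is False  # different contig


def test_fusion_candidate_not_readthrough(locus):
    """The emulated fusion reverses the genomic gene order, so it must not be
    explainable by read-through transcription."""
    assert (
        annotate_readthrough(locus.genes["ERRLIKE"], locus.genes["C11LIKE"]) is False
    )
    assert (
        annotate_readthrough(locus.genes["C11LIKE"], locus.genes["ERRLIKE"]) is True
    )


# ---------------------------------------------------------------------------
# Stage 1 and end-to-end null specificity
# ---------------------------------------------------------------------------

def test_stage1_retains_junction_spanning_pair(locus):
    fus = locus.fusion_transcripts["E2-C3"].sequence
    jp = locus.truth.fusion_junction_pos["E2-C3"]
    frag = fus[jp - 200 : jp + 150]
    pair = ReadPair("p", frag[:76], revcomp(frag[-76:]))
    index = SeedIndex({t: x.sequence for t, x in locus.transcripts.items()})
    assert stage1_filter([pair], index) == [pair]
    assert stage1_filter([], index) == []


def test_wildtype_pool_yields_no_consistent_hits(locus):
    """Specificity under the null: a wild-type-only pool at zero sequencing
    error produces zero consistent junction hits even with 1% chimeras."""
    weights = {"ERRLIKE-wt": 2.0, "C11LIKE-wt": 1.0, "ERRLIKEPARA-wt": 1.0}
    cfg = RnaSimConfig(
        isoform_weights=weights, n_pairs=15_000, error_rate=0.0, chimera_rate=0.01,
        seed=29,
    )
    reads, _ = simulate_rna(locus.transcripts, cfg)
    res = run_rna_pipeline(reads, locus.genes, locus.transcripts)
    assert len(res.table) == 0
    assert sum(v.consistent for v in res.verdicts) == 0
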