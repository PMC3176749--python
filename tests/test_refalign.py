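"""I/O round-trips and seeded-aligner correctness against brute force."""

import numpy as np
import pytest

from pairfuse.refalign import (
    FormatError,
    GeneModel,
    Genome,
    ReadPair,
    SeedIndex,
    align_all,
    align_pair_concordant,
    align_single,
    extract_transcript_seq,
    make_transcript,
    read_bed12,
    read_fasta,
    read_fastq_pairs,
    revcomp,
    write_bed12,
    write_fasta,
    write_fastq_pairs,
)

from helpers import brute_force_placements


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def test_fasta_round_trip(tmp_path):
    g = Genome({"a": "ACGTACGTAC", "b": "GGGCCCAATT" * 20})
    p = tmp_path / "g.fa"
    write_fasta(g, p)
    g2 = read_fasta(p)
    assert g2.contigs == g.contigs


def test_fasta_lowercase_uppercased(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">x\nacgtacgtac\n")
    assert read_fasta(p).contigs == {"x": "ACGTACGTAC"}


def test_fasta_bad_character(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">x\nACGTXACGT\n")
    with pytest.raises(FormatError):
        read_fasta(p)


def test_fasta_empty_file_warns(tmp_path, caplog):
    p = tmp_path / "g.fa"
    p.write_text("")
    with caplog.at_level("WARNING", logger="pairfuse"):
        g = read_fasta(p)
    assert g.contigs == {}
    assert any("no records" in r.message for r in caplog.records)


def test_fastq_pair_round_trip_and_n_rejection(tmp_path):
    pairs = [
        ReadPair("p0", "ACGT" * 10, "TTGC" * 10),
        ReadPair("p1", "N" * 20 + "ACGT" * 5, "ACGT" * 10),  # 50% N: rejected
    ]
    p1, p2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
    write_fastq_pairs(pairs, p1, p2)
    loaded = read_fastq_pairs(p1, p2, "s")
    assert [p.pair_id for p in loaded] == ["p0"]
    assert loaded[0].seq1 == pairs[0].seq1


# ---------------------------------------------------------------------------
# BED12 and transcript extraction
# ---------------------------------------------------------------------------

def _bed_line(chrom, start, name, sizes, offs, strand="+"):
    end = start + offs[-1] + sizes[-1]
    return "\t".join(
        [
            chrom,
            str(start),
            str(end),
            name,
            "0",
            strand,
            str(start),
            str(end),
            "0",
            str(len(sizes)),
            ",".join(map(str, sizes)),
            ",".join(map(str, offs)),
        ]
    )


def test_bed12_two_blocks_length(tmp_path, random_genome):
    p = tmp_path / "t.bed"
    p.write_text(_bed_line("toy", 100, "G1.t1", [100, 100], [0, 300]) + "\n")
    genes, txs = read_bed12(p, random_genome)
    assert len(txs["G1.t1"]) == 200
    assert genes["G1"].exons == [(100, 200), (400, 500)]


def test_bed12_minus_strand_revcomp(tmp_path, random_genome):
    plus = _bed_line("toy", 100, "G1.t1", [60, 60], [0, 200], "+")
    minus = _bed_line("toy", 100, "G2.t1", [60, 60], [0, 200], "-")
    p = tmp_path / "t.bed"
    p.write_text(plus + "\n" + minus + "\n")
    _, txs = read_bed12(p, random_genome)
    assert txs["G2.t1"].sequence == revcomp(txs["G1.t1"].sequence)


def test_bed12_blocks_out_of_order_error(tmp_path, random_genome):
    p = tmp_path / "t.bed"
    p.write_text(_bed_line("toy", 100, "G1.t1", [100, 100], [150, 0]) + "\n")
    with pytest.raises(FormatError):
        read_bed12(p, random_genome)


def test_bed12_block_count_mismatch_error(tmp_path, random_genome):
    line = _bed_line("toy", 100, "G1.t1", [100, 100], [0, 300])
    cols = line.split("\t")
    cols[10] = "100"  # one size, two starts
    p = tmp_path / "t.bed"
    p.write_text("\t".join(cols) + "\n")
    with pytest.raises(FormatError):
        read_bed12(p, random_genome)


def test_bed12_round_trip_lossless(tmp_path, locus):
    p1 = tmp_path / "a.bed"
    write_bed12(locus.genes, locus.transcripts, p1)
    genes2, txs2 = read_bed12(p1, locus.genome)
    p2 = tmp_path / "b.bed"
    write_bed12(genes2, txs2, p2)
    assert p1.read_text() == p2.read_text()
    for tid, tx in locus.transcripts.items():
        assert txs2[tid].sequence == tx.sequence


def test_extract_transcript_seq_plus_minus_and_skip(random_genome):
    seq = random_genome["toy"]
    gene_p = GeneModel("gp", "toy", "+", [(0, 10), (20, 30), (40, 50)])
    gene_m = GeneModel("gm", "toy", "-", [(0, 10), (20, 30), (40, 50)])
    assert extract_transcript_seq(gene_p, [0, 1], random_genome) == seq[0:10] + seq[20:30]
    assert extract_transcript_seq(gene_m, [2, 1, 0], random_genome) == revcomp(
        seq[0:10] + seq[20:30] + seq[40:50]
    )
    # exon skip: indices [0, 2] omit the middle exon
    assert extract_transcript_seq(gene_p, [0, 2], random_genome) == seq[0:10] + seq[40:50]
    with pytest.raises(IndexError):
        extract_transcript_seq(gene_p, [0, 7], random_genome)


# ---------------------------------------------------------------------------
# Aligner vs brute force
# ---------------------------------------------------------------------------

def _mutate(rng, s, k):
    arr = list(s)
    for i in rng.choice(len(s), size=k, replace=False):
        arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
    return "".join(arr)


def test_aligner_agrees_with_brute_force(random_genome, rng):
    """Exhaustive agreement of the seeded search with an all-positions scan
    for the read lengths this package processes."""
    index = SeedIndex(random_genome.contigs)
    seq = random_genome["toy"]
    for trial in range(60):
        L = int(rng.choice([38, 50, 76, 80]))
        start = int(rng.integers(0, len(seq) - L))
        read = seq[start : start + L]
        n_mut = int(rng.integers(0, 4))  # sometimes beyond max_mismatch
        read = _mutate(rng, read, n_mut)
        if rng.random() < 0.5:
            read = revcomp(read)
        got = set(align_all(read, index, max_mismatch=2))
        want = brute_force_placements(read, random_genome.contigs, 2)
        assert got == want


def test_aligner_exact_short_reads_agree(random_genome, rng):
    index = SeedIndex(random_genome.contigs)
    seq = random_genome["toy"]
    for _ in range(20):
        start = int(rng.integers(0, len(seq) - 20))
        read = seq[start : start + 20]
        got = {p for p in align_all(read, index, 0)}
        want = brute_force_placements(read, random_genome.contigs, 0)
        assert got == want


def test_align_single_unique_and_duplicate(rng):
    core = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=500).tobytes().decode()
    dup = core[100:180]
    genome = {"c": core + "T" * 40 + dup}  # the 80-mer occurs twice
    index = SeedIndex(genome)
    unique_read = core[300:380]
    a = align_single(unique_read, index)
    assert a is not None and a.is_unique and a.mismatches == 0
    a2 = align_single(dup, index)
    assert a2 is not None and not a2.is_unique


def test_uniqueness_symmetric_under_revcomp(random_genome, rng):
    index = SeedIndex(random_genome.contigs)
    seq = random_genome["toy"]
    for _ in range(20):
        start = int(rng.integers(0, len(seq) - 60))
        read = seq[start : start + 60]
        a = align_single(read, index)
        b = align_single(revcomp(read), index)
        assert a is not None and b is not None
        assert a.is_unique == b.is_unique
        assert a.mismatches == b.mismatches


def test_no_placement_beyond_max_mismatch(random_genome, rng):
    seq = random_genome["toy"]
    index = SeedIndex(random_genome.contigs)
    read = _mutate(rng, seq[500:576], 12)  # far beyond 2 mismatches
    assert brute_force_placements(read, random_genome.contigs, 2) == set()
    assert align_single(read, index, 2) is None


def test_read_shorter_than_minimum_rejected(random_genome):
    index = SeedIndex(random_genome.contigs)
    with pytest.raises(ValueError):
        align_single("ACGTACGTAC", index)


def test_n_never_matches():
    index = SeedIndex({"t": "ACGTACGTACGTACGTACGTACGT"})
    read = "ACGTACGTACGTACGTACGT"
    a = align_single(read, index, 0)
    assert a is not None
    read_n = read[:10] + "N" + read[11:]
    assert align_single(read_n, index, 0) is None


# ---------------------------------------------------------------------------
# Pair concordance
# ---------------------------------------------------------------------------

def _tx_targets(rng):
    bases = np.frombuffer(b"ACGT", np.uint8)
    t1 = rng.choice(bases, size=1200).tobytes().decode()
    t2 = rng.choice(bases, size=1200).tobytes().decode()
    return {"t1": t1, "t2": t2}


def test_pair_concordant_at_350(rng):
    targets = _tx_targets(rng)
    index = SeedIndex(targets)
    frag = targets["t1"][200:550]  # 350 bp fragment
    pair = ReadPair("p", frag[:76], revcomp(frag[-76:]))
    res = align_pair_concordant(pair, index, max_insert=600)
    assert res is not None
    a1, a2 = res
    assert a1.target_id == a2.target_id == "t1"
    assert {a1.strand, a2.strand} == {"+", "-"}


def test_pair_straddling_two_transcripts_is_leftover(rng):
    targets = _tx_targets(rng)
    index = SeedIndex(targets)
    pair = ReadPair("p", targets["t1"][100:176], revcomp(targets["t2"][500:576]))
    assert align_pair_concordant(pair, index, 600) is None


def test_pair_ff_orientation_is_leftover(rng):
    """All four strand combinations: only FR (either mate forward) with the
    forward mate leftmost is concordant."""
    targets = _tx_targets(rng)
    index = SeedIndex(targets)
    frag = targets["t1"][200:550]
    fwd, rev = frag[:76], frag[-76:]
    # FF: both mates in fragment-forward orientation
    assert align_pair_concordant(ReadPair("p", fwd, rev), index, 600) is None
    # RR
    assert (
        align_pair_concordant(ReadPair("p", revcomp(fwd), revcomp(rev)), index, 600)
        is None
    )
    # RF outward (reverse mate leftmost)
    assert (
        align_pair_concordant(ReadPair("p", revcomp(fwd), rev), index, 600) is None
    )
    # FR proper, either mate listed first
    assert align_pair_concordant(ReadPair("p", fwd, revcomp(rev)), index, 600)
    assert align_pair_concordant(ReadPair("p", revcomp(rev), fwd), index, 600)


def test_pair_insert_bound(rng):
    targets = _tx_targets(rng)
    index = SeedIndex(targets)
    frag = targets["t1"][100:900]  # implied fragment 800 > 600
    pair = ReadPair("p", frag[:76], revcomp(frag[-76:]))
    assert align_pair_concordant(pair, index, 600) is None
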