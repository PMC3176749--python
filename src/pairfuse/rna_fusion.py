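"""Fusion-transcript discovery from paired-end RNA reads.

The pipeline mirrors a junction-database search with polarity-aware false
discovery control:

1. paired-end alignment to the annotated transcriptome; concordant pairs are
   set aside, the rest are "leftovers";
2. leftover mates aligned singly with a unique-placement requirement; pairs
   whose mates land uniquely in two different genes nominate candidate gene
   pairs (A, B);
3. for each candidate pair an exhaustive junction database is built: every
   ordered cross-gene exon junction (A-B and B-A) and every within-gene
   ordered exon pair (A-A, B-B, exon skips included), each record carrying up
   to F nt of cumulative spliced flank on either side;
4. leftover single reads that failed transcriptome alignment are scanned
   against the junction database, requiring a unique best placement with at
   least O_min nt on BOTH sides of the junction;
5. each junction hit's mate must lie on the far side of the junction in FR
   orientation within the insert bound ("polarity"); homology artifacts fail
   this test;
6. candidates are ranked by total consistent junction-read count, annotated
   for read-through plausibility, and assigned q-values from a Poisson null
   whose mean combines the candidate's inconsistent-polarity hits and an
   expected ligation-chimera contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .refalign import (
    Alignment,
    GeneModel,
    ReadPair,
    SeedIndex,
    Transcript,
    align_all,
    align_pair_concordant,
    align_single,
)

logger = logging.getLogger("pairfuse")


@dataclass
class JunctionDbConfig:
    flank: int = 66  # F = 76 - O_min: any informative 76-mer fits on a record
    min_overlap: int = 10
    categories: tuple[str, ...] = ("A-B", "B-A", "A-A", "B-B")

    def __post_init__(self) -> None:
        if self.flank < self.min_overlap:
            raise ValueError("flank must be >= min_overlap")


@dataclass
class JunctionRecord:
    """One hypothetical exon-exon junction.

    The sequence is flank5 (last F nt of the 5' gene's cumulative spliced
    sequence through exon5) + flank3 (first F nt of the 3' gene's cumulative
    spliced sequence from exon3 on); ``offset`` marks the boundary.
    """

    gene5: str
    exon5: int  # 1-based exon number in transcription order
    gene3: str
    exon3: int
    category: str
    sequence: str
    offset: int
    shortened: bool = False

    @property
    def record_id(self) -> str:
        return f"{self.gene5}.e{self.exon5}|{self.gene3}.e{self.exon3}:{self.category}"


@dataclass
class PolarityVerdict:
    consistent: bool
    reason: str = ""
    implied_fragment: Optional[int] = None


@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    junction_counts: dict[str, int] = field(default_factory=dict)
    read_ids: list[str] = field(default_factory=list)
    inconsistent_count: int = 0
    readthrough: bool = False
    est_false_count: float = 0.0
    p_value: float = 1.0
    q_value: float = 1.0

    @property
    def total_count(self) -> int:
        return sum(self.junction_counts.values())


# ---------------------------------------------------------------------------
# Stage 1: paired transcriptome filter
# ---------------------------------------------------------------------------

def stage1_filter(
    pairs: Iterable[ReadPair],
    tx_index: SeedIndex,
    max_insert: int = 600,
    max_mismatch: int = 2,
) -> list[ReadPair]:
    """Remove pairs concordant on any annotated transcript; return leftovers."""
    leftovers = []
    for pair in pairs:
        if align_pair_concordant(pair, tx_index, max_insert, max_mismatch) is None:
            leftovers.append(pair)
    return leftovers


# ---------------------------------------------------------------------------
# Stage 2: discordant gene pairs
# ---------------------------------------------------------------------------

def discordant_gene_pairs(
    leftovers: Iterable[ReadPair],
    tx_index: SeedIndex,
    gene_of_transcript: Mapping[str, str],
    max_mismatch: int = 2,
) -> tuple[dict[tuple[str, str], list[str]], dict[tuple[str, int], Optional[Alignment]]]:
    """Unordered gene pairs supported by leftover pairs whose two mates map
    uniquely to two different genes.

    Also returns the per-mate single alignments (cached for later stages).
    """
    gene_pairs: dict[tuple[str, str], list[str]] = {}
    mate_alignments: dict[tuple[str, int], Optional[Alignment]] = {}
    for pair in leftovers:
        a1 = align_single(pair.seq1, tx_index, max_mismatch, pair.pair_id, 1)
        a2 = align_single(pair.seq2, tx_index, max_mismatch, pair.pair_id, 2)
        mate_alignments[(pair.pair_id, 1)] = a1
        mate_alignments[(pair.pair_id, 2)] = a2
        if a1 is None or a2 is None or not a1.is_unique or not a2.is_unique:
            continue
        g1 = gene_of_transcript[a1.target_id]
        g2 = gene_of_transcript[a2.target_id]
        if g1 == g2:
            continue
        key = tuple(sorted((g1, g2)))
        gene_pairs.setdefault(key, []).append(pair.pair_id)
    return gene_pairs, mate_alignments


# ---------------------------------------------------------------------------
# Junction database
# ---------------------------------------------------------------------------

def _cumulative_flanks(
    gene: GeneModel, tx: Transcript, flank: int
) -> tuple[list[str], list[str]]:
    """(flank5[i], flank3[i]) per exon i in transcription order.

    flank5[i] = last F nt of the spliced sequence through exon i;
    flank3[i] = first F nt of the spliced sequence from exon i onwards.
    """
    bounds = tx.exon_boundaries(gene)
    seq = tx.sequence
    f5, f3 = [], []
    for i in range(len(tx.exon_indices)):
        end = bounds[i + 1]
        start = bounds[i]
        f5.append(seq[max(0, end - flank) : end])
        f3.append(seq[start : start + flank])
    return f5, f3


def build_junction_db(
    gene_a: str,
    gene_b: str,
    genes: Mapping[str, GeneModel],
    transcripts: Mapping[str, Transcript],
    config: JunctionDbConfig | None = None,
) -> list[JunctionRecord]:
    """All hypothetical junctions for a candidate gene pair.

    Cross-gene categories enumerate every ordered exon pair in both
    directions; within-gene categories enumerate every ordered pair i<j in
    transcription order (exon skips included).
    """
    config = config or JunctionDbConfig()
    primary: dict[str, Transcript] = {}
    for tx in transcripts.values():
        primary.setdefault(tx.gene_id, tx)
    records: list[JunctionRecord] = []

    flanks = {}
    for g in (gene_a, gene_b):
        if g not in primary:
            raise KeyError(f"gene {g} has no annotated transcript")
        flanks[g] = _cumulative_flanks(genes[g], primary[g], config.flank)

    def add(g5: str, i5: int, g3: str, i3: int, cat: str) -> None:
        f5 = flanks[g5][0][i5]
        f3 = flanks[g3][1][i3]
        shortened = len(f5) < config.flank or len(f3) < config.flank
        records.append(
            JunctionRecord(
                gene5=g5,
                exon5=i5 + 1,
                gene3=g3,
                exon3=i3 + 1,
                category=cat,
                sequence=f5 + f3,
                offset=len(f5),
                shortened=shortened,
            )
        )

    n_a = len(primary[gene_a].exon_indices)
    n_b = len(primary[gene_b].exon_indices)
    if "A-B" in config.categories:
        for i in range(n_a):
            for j in range(n_b):
                add(gene_a, i, gene_b, j, "A-B")
    if "B-A" in config.categories:
        for i in range(n_b):
            for j in range(n_a):
                add(gene_b, i, gene_a, j, "B-A")
    if "A-A" in config.categories:
        for i in range(n_a):
            for j in range(i + 1, n_a):
                add(gene_a, i, gene_a, j, "A-A")
    if "B-B" in config.categories:
        for i in range(n_b):
            for j in range(i + 1, n_b):
                add(gene_b, i, gene_b, j, "B-B")
    return records


# ---------------------------------------------------------------------------
# Junction read scan
# ---------------------------------------------------------------------------

@dataclass
class JunctionHit:
    pair_id: str
    side: int
    record: JunctionRecord
    start: int
    strand: str
    mismatches: int
    overlap5: int
    overlap3: int


def junction_read_scan(
    reads: Iterable[tuple[str, int, str]],
    records: list[JunctionRecord],
    min_overlap: int = 10,
    max_mismatch: int = 2,
) -> list[JunctionHit]:
    """Scan single reads against the junction database.

    ``reads`` yields (pair_id, side, sequence).  A hit requires a unique best
    placement across the whole database with at least ``min_overlap`` nt on
    both sides of the record's junction offset.
    """
    by_id = {r.record_id: r for r in records}
    if not by_id:
        return []
    index = SeedIndex({rid: r.sequence for rid, r in by_id.items()})
    hits: list[JunctionHit] = []
    for pair_id, side, seq in reads:
        aln = align_single(seq, index, max_mismatch, pair_id, side)
        if aln is None or not aln.is_unique:
            continue
        rec = by_id[aln.target_id]
        L = len(seq)
        ov5 = rec.offset - aln.start
        ov3 = aln.start + L - rec.offset
        if ov5 < min_overlap or ov3 < min_overlap:
            continue
        hits.append(
            JunctionHit(
                pair_id, side, rec, aln.start, aln.strand, aln.mismatches, ov5, ov3
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Mate polarity filter
# ---------------------------------------------------------------------------

def mate_polarity_filter(
    hit: JunctionHit,
    mate: Optional[Alignment],
    genes: Mapping[str, GeneModel],
    transcripts: Mapping[str, Transcript],
    gene_of_transcript: Mapping[str, str],
    max_insert: int = 600,
) -> PolarityVerdict:
    """Check that the mate lies on the far side of the junction in the
    orientation implied by the fused gene order.

    A forward junction read (fusion-transcript sense) demands a
    reverse-oriented mate within the 3' gene downstream of the junction; a
    reverse junction read demands a forward mate within the 5' gene upstream.
    Homology-driven junction hits fail this polarity test.
    """
    if mate is None or not mate.is_unique:
        return PolarityVerdict(False, "orphan mate")
    rec = hit.record
    mate_gene = gene_of_transcript[mate.target_id]
    mate_tx = transcripts[mate.target_id]
    bounds = mate_tx.exon_boundaries(genes[mate_gene])

    primary: dict[str, Transcript] = {}
    for tx in transcripts.values():
        primary.setdefault(tx.gene_id, tx)

    # junction position in fusion-transcript coordinates
    g5_tx = primary[rec.gene5]
    cum5 = g5_tx.exon_boundaries(genes[rec.gene5])[rec.exon5]
    read_len = hit.overlap5 + hit.overlap3

    if hit.strand == "+":
        if mate_gene != rec.gene3:
            return PolarityVerdict(False, "mate not in 3' gene")
        if mate.strand != "-":
            return PolarityVerdict(False, "mate orientation")
        g3_tx = primary[rec.gene3]
        cum3_start = g3_tx.exon_boundaries(genes[rec.gene3])[rec.exon3 - 1]
        if mate.target_id != g3_tx.transcript_id:
            # mate on a non-primary isoform of the right gene: accept with
            # coordinates on that isoform's shared frame if possible
            cum3_start = bounds[0]
        if mate.start < cum3_start:
            return PolarityVerdict(False, "mate upstream of junction")
        junc_read_start_fusion = cum5 - hit.overlap5
        mate_end_fusion = cum5 + (mate.start - cum3_start) + mate.read_len
        frag = mate_end_fusion - junc_read_start_fusion
        if frag > max_insert:
            return PolarityVerdict(False, "implied fragment too long", frag)
        return PolarityVerdict(True, "", frag)
    else:
        if mate_gene != rec.gene5:
            return PolarityVerdict(False, "mate not in 5' gene")
        if mate.strand != "+":
            return PolarityVerdict(False, "mate orientation")
        if mate.end > cum5:
            return PolarityVerdict(False, "mate downstream of junction")
        junc_read_end_fusion = cum5 + hit.overlap3
        frag = junc_read_end_fusion - mate.start
        if frag > max_insert:
            return PolarityVerdict(False, "implied fragment too long", frag)
        return PolarityVerdict(True, "", frag)


# ---------------------------------------------------------------------------
# Read-through annotation
# ---------------------------------------------------------------------------

def annotate_readthrough(
    gene5: GeneModel, gene3: GeneModel, max_gap: int = 100_000
) -> bool:
    """True iff canonical transcription could explain the junction: the 5'
    gene lies transcriptionally upstream of the 3' gene on the same contig
    and strand within ``max_gap``."""
    if gene5.contig != gene3.contig or gene5.strand != gene3.strand:
        return False
    if gene5.strand == "+":
        return gene5.end <= gene3.start and gene3.start - gene5.end <= max_gap
    return gene3.end <= gene5.start and gene5.start - gene3.end <= max_gap


# ---------------------------------------------------------------------------
# Ranking and FDR
# ---------------------------------------------------------------------------

def rank_and_fdr(
    candidates: list[FusionCandidate],
    n_scanned_reads: int,
    chimera_rate: float,
    db_length_share: Mapping[tuple[str, str], float],
) -> pd.DataFrame:
    """Rank candidates by total consistent junction count and attach q-values.

    The per-candidate null mean is the candidate's inconsistent-polarity hit
    count plus the expected chimera-driven hit count (global chimeric-pair
    rate x reads scanned x the candidate's share of total junction-database
    length) — a declared reconstruction of the study's unpublished false
    discovery model.  q-values are Benjamini-Hochberg over per-candidate
    Poisson tail p-values.
    """
    kept = [c for c in candidates if c.total_count > 0]
    if not kept:
        return pd.DataFrame(
            columns=[
                "gene5",
                "gene3",
                "total_count",
                "junctions",
                "readthrough",
                "inconsistent",
                "est_false",
                "p_value",
                "q_value",
            ]
        )
    for c in kept:
        share = db_length_share.get((c.gene5, c.gene3), 0.0)
        chim = chimera_rate * n_scanned_reads * share
        c.est_false_count = c.inconsistent_count + chim
        c.p_value = float(stats.poisson.sf(c.total_count - 1, c.est_false_count))
    pvals = np.array([c.p_value for c in kept])
    qvals = stats.false_discovery_control(pvals, method="bh")
    for c, q in zip(kept, qvals):
        c.q_value = float(q)
    kept.sort(key=lambda c: (-c.total_count, c.q_value, c.gene5, c.gene3))
    return pd.DataFrame(
        {
            "gene5": [c.gene5 for c in kept],
            "gene3": [c.gene3 for c in kept],
            "total_count": [c.total_count for c in kept],
            "junctions": [
                ";".join(f"{k}:{v}" for k, v in sorted(c.junction_counts.items()))
                for c in kept
            ],
            "readthrough": [c.readthrough for c in kept],
            "inconsistent": [c.inconsistent_count for c in kept],
            "est_false": [c.est_false_count for c in kept],
            "p_value": [c.p_value for c in kept],
            "q_value": [c.q_value for c in kept],
        }
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class RnaPipelineResult:
    table: pd.DataFrame
    candidates: list[FusionCandidate]
    hits: list[JunctionHit]
    verdicts: list[PolarityVerdict]
    n_leftover: int
    n_scanned: int
    records: list[JunctionRecord]


def run_rna_pipeline(
    pairs: list[ReadPair],
    genes: Mapping[str, GeneModel],
    transcripts: Mapping[str, Transcript],
    config: JunctionDbConfig | None = None,
    max_insert: int = 600,
    max_mismatch: int = 2,
    chimera_rate: Optional[float] = None,
    readthrough_gap: int = 100_000,
) -> RnaPipelineResult:
    """Run the complete RNA fusion-discovery pipeline on in-memory reads."""
    config = config or JunctionDbConfig()
    gene_of_transcript = {tid: tx.gene_id for tid, tx in transcripts.items()}
    tx_index = SeedIndex({tid: tx.sequence for tid, tx in transcripts.items()})

    leftovers = stage1_filter(pairs, tx_index, max_insert, max_mismatch)
    gene_pairs, mate_alignments = discordant_gene_pairs(
        leftovers, tx_index, gene_of_transcript, max_mismatch
    )

    if chimera_rate is None:
        n_total = max(len(pairs), 1)
        n_discordant = sum(len(v) for v in gene_pairs.values())
        chimera_rate = n_discordant / n_total

    # combined junction DB over all candidate gene pairs
    records: list[JunctionRecord] = []
    seen_ids: set[str] = set()
    pair_of_record: dict[str, tuple[str, str]] = {}
    for ga, gb in sorted(gene_pairs):
        for rec in build_junction_db(ga, gb, genes, transcripts, config):
            if rec.record_id in seen_ids:
                continue
            seen_ids.add(rec.record_id)
            records.append(rec)
            pair_of_record[rec.record_id] = (ga, gb)

    # reads to scan: leftover mates lacking a unique transcriptome placement
    to_scan: list[tuple[str, int, str]] = []
    seq_of = {}
    for pair in leftovers:
        seq_of[(pair.pair_id, 1)] = pair.seq1
        seq_of[(pair.pair_id, 2)] = pair.seq2
        for side, seq in ((1, pair.seq1), (2, pair.seq2)):
            aln = mate_alignments.get((pair.pair_id, side))
            if aln is None or not aln.is_unique:
                to_scan.append((pair.pair_id, side, seq))

    hits = junction_read_scan(to_scan, records, config.min_overlap, max_mismatch)

    # polarity filtering; aggregate per ordered (gene5, gene3)
    cands: dict[tuple[str, str], FusionCandidate] = {}
    verdicts: list[PolarityVerdict] = []
    for hit in hits:
        rec = hit.record
        mate_side = 2 if hit.side == 1 else 1
        mate = mate_alignments.get((hit.pair_id, mate_side))
        verdict = mate_polarity_filter(
            hit, mate, genes, transcripts, gene_of_transcript, max_insert
        )
        verdicts.append(verdict)
        if rec.category not in ("A-B", "B-A"):
            continue  # within-gene records only absorb ambiguous reads
        key = (rec.gene5, rec.gene3)
        cand = cands.setdefault(key, FusionCandidate(rec.gene5, rec.gene3))
        if verdict.consistent:
            jid = f"e{rec.exon5}|e{rec.exon3}"
            cand.junction_counts[jid] = cand.junction_counts.get(jid, 0) + 1
            cand.read_ids.append(f"{hit.pair_id}/{hit.side}")
        else:
            cand.inconsistent_count += 1

    for (g5, g3), cand in cands.items():
        cand.readthrough = annotate_readthrough(genes[g5], genes[g3], readthrough_gap)

    # junction-DB length share per ordered candidate pair
    total_len = sum(len(r.sequence) for r in records) or 1
    share: dict[tuple[str, str], float] = {}
    for rec in records:
        if rec.category in ("A-B", "B-A"):
            key = (rec.gene5, rec.gene3)
            share[key] = share.get(key, 0.0) + len(rec.sequence) / total_len

    table = rank_and_fdr(list(cands.values()), len(to_scan), chimera_rate, share)
    return RnaPipelineResult(
        table=table,
        candidates=list(cands.values()),
        hits=hits,
        verdicts=verdicts,
        n_leftover=len(leftovers),
        n_scanned=len(to_scan),
        records=records,
    )
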