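"""Shared sequence/annotation data model, standard-format I/O, and a seeded aligner.

The aligner is a deliberately small, deterministic stand-in for a production
short-read mapper, adequate for the desk-scale references this package works
on (tens of kilobases): exact-seed lookup with gapless mismatch extension on
both strands.  Seeds are placed by pigeonhole — ``max_mismatch + 1`` disjoint
seeds per read — so any placement with at most ``max_mismatch`` substitutions
is guaranteed to be found (the seeded search provably agrees with a
brute-force all-positions scan).  Indels and spliced alignment are out of
scope by contract.

Coordinates are 0-based, half-open throughout; 1-based inclusive appears only
in human-readable reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("pairfuse")

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_N_BYTE = ord("N")

#: default length below which a read is refused by the aligner
MIN_READ_LEN = 20
#: default maximum substitutions tolerated in a full-length placement
MAX_MISMATCH = 2
#: default seed length; 12 so that a 38-mer still carries 3 disjoint seeds
SEED_LEN = 12


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ/BED/TSV input."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """A toy reference: contig name -> uppercase ACGTN sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} has empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]


@dataclass
class GeneModel:
    """Exon-structured gene annotation on the toy genome.

    ``exons`` are genomic intervals (0-based half-open), ascending and
    non-overlapping regardless of strand.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"gene {self.gene_id}: bad exon interval ({s},{e})")
            if s < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons out of order or overlapping"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    def transcription_order(self) -> list[int]:
        """Exon indices (into ``exons``) in 5'->3' transcription order."""
        idx = list(range(len(self.exons)))
        return idx if self.strand == "+" else idx[::-1]


@dataclass
class Transcript:
    """A spliced isoform: ordered exon subset of one gene plus its sequence.

    ``exon_indices`` index into the gene's genomic-ascending exon list and are
    listed in transcription order (ascending for + genes, descending for −).
    """

    transcript_id: str
    gene_id: str
    exon_indices: list[int]
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def exon_boundaries(self, gene: GeneModel) -> list[int]:
        """Cumulative transcript coordinates of exon starts, plus total length.

        boundaries[i] is the transcript coordinate where the i-th exon (in
        transcription order of this transcript) begins; boundaries[-1] is the
        transcript length.
        """
        lens = gene.exon_lengths()
        out = [0]
        for idx in self.exon_indices:
            out.append(out[-1] + lens[idx])
        return out


@dataclass
class ReadPair:
    """A paired-end read in FR orientation relative to its source fragment."""

    pair_id: str
    seq1: str
    seq2: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise ValueError(f"pair {self.pair_id}: empty mate sequence")


@dataclass(frozen=True)
class Alignment:
    """A gapless placement of one mate on a transcript or contig."""

    pair_id: str
    side: int  # 1 or 2
    target_id: str
    start: int
    strand: str
    mismatches: int
    is_unique: bool
    read_len: int = 0

    @property
    def end(self) -> int:
        return self.start + self.read_len


# ---------------------------------------------------------------------------
# FASTA / FASTQ / BED12 / sample sheet I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly multi-record) FASTA into a Genome; bases uppercased."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-ACGTN characters {sorted(bad)}"
            )
        if rec.id in contigs:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        contigs[rec.id] = seq
    if not contigs:
        logger.warning("FASTA %s contained no records; empty genome", path)
    return Genome(contigs)


def write_fasta(genome: Genome | Mapping[str, str], path: str | Path) -> Path:
    contigs = genome.contigs if isinstance(genome, Genome) else dict(genome)
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in contigs.items()]
    SeqIO.write(records, str(path), "fasta")
    return Path(path)


def read_fastq_pairs(
    path1: str | Path,
    path2: str | Path,
    sample_id: str = "",
    max_n_frac: float = 0.10,
) -> list[ReadPair]:
    """Read two synchronized FASTQ files into ReadPairs.

    Qualities are parsed but unused.  Pairs where either mate has more than
    ``max_n_frac`` ambiguous (N) bases are rejected at load.
    """
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    pairs: list[ReadPair] = []
    n_rejected = 0
    for rec1, rec2 in zip(it1, it2, strict=True):
        s1, s2 = str(rec1.seq).upper(), str(rec2.seq).upper()
        if s1.count("N") > max_n_frac * len(s1) or s2.count("N") > max_n_frac * len(s2):
            n_rejected += 1
            continue
        pid = rec1.id.removesuffix("/1")
        pairs.append(ReadPair(pid, s1, s2, sample_id))
    if n_rejected:
        logger.info("rejected %d pairs with >%d%% N", n_rejected, int(100 * max_n_frac))
    return pairs


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> tuple[Path, Path]:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")
    return Path(path1), Path(path2)


def extract_transcript_seq(
    gene: GeneModel, exon_indices: Sequence[int], genome: Genome
) -> str:
    """Spliced sequence of the chosen exons, reverse-complemented for − genes.

    ``exon_indices`` are given in transcription order (descending genomic
    index for − strand genes).
    """
    contig = genome[gene.contig]
    for i in exon_indices:
        if not 0 <= i < len(gene.exons):
            raise IndexError(f"gene {gene.gene_id}: exon index {i} out of range")
    if gene.strand == "+":
        return "".join(contig[s:e] for s, e in (gene.exons[i] for i in exon_indices))
    # − strand: indices arrive in transcription order (genomic descending);
    # splice in genomic order then reverse-complement the whole.
    genomic = sorted(exon_indices)
    spliced = "".join(contig[s:e] for s, e in (gene.exons[i] for i in genomic))
    return revcomp(spliced)


def make_transcript(
    transcript_id: str,
    gene: GeneModel,
    genome: Genome,
    exon_indices: Sequence[int] | None = None,
) -> Transcript:
    """Build a Transcript (all exons by default) with its spliced sequence."""
    if exon_indices is None:
        exon_indices = gene.transcription_order()
    seq = extract_transcript_seq(gene, exon_indices, genome)
    return Transcript(transcript_id, gene.gene_id, list(exon_indices), seq)


def read_bed12(path: str | Path, genome: Genome) -> tuple[dict[str, GeneModel], dict[str, Transcript]]:
    """Read BED12 gene models: one transcript per record.

    Records are grouped into genes by an optional 13th column (gene name) or,
    absent that, by the record-name prefix before the first ``.``.
    """
    raw: list[tuple[str, str, str, str, list[tuple[int, int]], int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected >=12 BED columns")
            chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
            strand = cols[5]
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(
                    f"{path}:{lineno}: blockSizes/blockStarts count != blockCount"
                )
            exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
            for (s0, e0), (s1, _) in zip(exons, exons[1:]):
                if s1 < e0:
                    raise FormatError(f"{path}:{lineno}: blocks out of order/overlap")
            if exons[-1][1] > end:
                raise FormatError(f"{path}:{lineno}: blocks exceed chromEnd")
            if chrom not in genome.contigs:
                raise FormatError(f"{path}:{lineno}: unknown contig {chrom!r}")
            if exons[-1][1] > len(genome[chrom]):
                raise FormatError(f"{path}:{lineno}: record exceeds contig bounds")
            gene_name = cols[12] if len(cols) > 12 and cols[12] else name.split(".")[0]
            raw.append((name, gene_name, chrom, strand, exons, lineno))

    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    by_gene: dict[str, list[tuple]] = {}
    for rec in raw:
        by_gene.setdefault(rec[1], []).append(rec)
    for gene_name, recs in by_gene.items():
        contig = recs[0][2]
        strand = recs[0][3]
        all_exons = sorted({iv for rec in recs for iv in rec[4]})
        gene = GeneModel(gene_name, contig, strand, all_exons)
        genes[gene_name] = gene
        exon_index = {iv: i for i, iv in enumerate(all_exons)}
        for name, _, _, _, exons, _ in recs:
            idx = [exon_index[iv] for iv in exons]
            if strand == "-":
                idx = idx[::-1]
            transcripts[name] = make_transcript(name, gene, genome, idx)
    return genes, transcripts


def write_bed12(
    genes: Mapping[str, GeneModel],
    transcripts: Mapping[str, Transcript],
    path: str | Path,
) -> Path:
    with open(path, "w") as fh:
        for tid, tx in transcripts.items():
            gene = genes[tx.gene_id]
            genomic_idx = sorted(tx.exon_indices)
            exons = [gene.exons[i] for i in genomic_idx]
            start, end = exons[0][0], exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in exons)
            offs = ",".join(str(s - start) for s, _ in exons)
            fh.write(
                "\t".join(
                    [
                        gene.contig,
                        str(start),
                        str(end),
                        tid,
                        "0",
                        gene.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(exons)),
                        sizes,
                        offs,
                        tx.gene_id,
                    ]
                )
                + "\n"
            )
    return Path(path)


def read_sample_sheet(path: str | Path):
    """TSV with columns sample_id, role (tumor|normal|pool), fastq1, fastq2."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role", "fastq1", "fastq2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    bad = set(df["role"]) - {"tumor", "normal", "pool"}
    if bad:
        raise FormatError(f"{path}: unknown roles {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    return df


# ---------------------------------------------------------------------------
# Seeded aligner
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact k-mer index over a set of target sequences.

    k defaults to 12 so that a read of length >= 3k (every 38-mer and 76-mer)
    carries max_mismatch+1 = 3 disjoint seeds, guaranteeing full sensitivity
    at up to 2 substitutions by pigeonhole.
    """

    def __init__(self, targets: Mapping[str, str], seed_len: int = SEED_LEN):
        self.seed_len = seed_len
        self.targets: dict[str, str] = dict(targets)
        self.encoded: dict[str, np.ndarray] = {
            tid: np.frombuffer(seq.encode(), dtype=np.uint8)
            for tid, seq in self.targets.items()
        }
        index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.targets.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((tid, i))
        self._index = index

    def candidate_starts(self, query: str, max_mismatch: int) -> set[tuple[str, int]]:
        k = self.seed_len
        L = len(query)
        n_seeds = max_mismatch + 1
        if L >= n_seeds * k and n_seeds > 1:
            span = (L - k) / (n_seeds - 1)
            offsets = sorted({round(i * span) for i in range(n_seeds)})
        else:
            offsets = sorted({0, max(0, L - k)})
        out: set[tuple[str, int]] = set()
        for off in offsets:
            for tid, pos in self._index.get(query[off : off + k], ()):
                start = pos - off
                if 0 <= start <= len(self.targets[tid]) - L:
                    out.add((tid, start))
        return out


def _count_mismatches(
    index: SeedIndex, tid: str, start: int, query: str, qarr: np.ndarray, has_n: bool
) -> int:
    L = len(query)
    tslice = index.targets[tid][start : start + L]
    if not has_n and tslice == query:
        return 0
    tarr = index.encoded[tid][start : start + L]
    diff = int(np.count_nonzero(tarr != qarr))
    # N never matches anything, including N
    both_n = int(np.count_nonzero((tarr == _N_BYTE) & (qarr == _N_BYTE)))
    return diff + both_n


def align_all(
    read: str,
    index: SeedIndex,
    max_mismatch: int = MAX_MISMATCH,
    min_read_len: int = MIN_READ_LEN,
) -> list[tuple[str, int, str, int]]:
    """All placements of ``read`` on both strands with <= max_mismatch subs.

    Returns (target_id, start, strand, mismatches) tuples, deterministically
    ordered.  Full sensitivity is guaranteed for reads of length >=
    (max_mismatch+1) * seed_len.
    """
    if len(read) < min_read_len:
        raise ValueError(f"read shorter than minimum length {min_read_len}")
    results: list[tuple[str, int, str, int]] = []
    for strand, query in (("+", read), ("-", revcomp(read))):
        has_n = "N" in query
        qarr = np.frombuffer(query.encode(), dtype=np.uint8)
        for tid, start in sorted(index.candidate_starts(query, max_mismatch)):
            mm = _count_mismatches(index, tid, start, query, qarr, has_n)
            if mm <= max_mismatch:
                results.append((tid, start, strand, mm))
    results.sort(key=lambda r: (r[3], r[0], r[1], r[2]))
    return results


def align_single(
    read: str,
    index: SeedIndex,
    max_mismatch: int = MAX_MISMATCH,
    pair_id: str = "",
    side: int = 1,
    min_read_len: int = MIN_READ_LEN,
) -> Optional[Alignment]:
    """Best placement of a single read, or None if nothing <= max_mismatch.

    ``is_unique`` is True iff exactly one placement achieves the minimal
    mismatch count (ties are conservatively non-unique).
    """
    placements = align_all(read, index, max_mismatch, min_read_len)
    if not placements:
        return None
    best_mm = placements[0][3]
    best = [p for p in placements if p[3] == best_mm]
    tid, start, strand, mm = best[0]
    return Alignment(
        pair_id=pair_id,
        side=side,
        target_id=tid,
        start=start,
        strand=strand,
        mismatches=mm,
        is_unique=len(best) == 1,
        read_len=len(read),
    )


def align_pair_concordant(
    pair: ReadPair,
    index: SeedIndex,
    max_insert: int,
    max_mismatch: int = MAX_MISMATCH,
) -> Optional[tuple[Alignment, Alignment]]:
    """Concordant placement of a pair on one target, or None (a "leftover").

    Concordant means: both mates on the same target in FR orientation (one
    mate forward, the other reverse, forward mate leftmost) with implied
    fragment length between the read length and ``max_insert``.
    """
    if max_insert <= max(len(pair.seq1), len(pair.seq2)):
        raise ValueError("max_insert must exceed both read lengths")
    p1 = align_all(pair.seq1, index, max_mismatch)
    p2 = align_all(pair.seq2, index, max_mismatch)
    if not p1 or not p2:
        return None
    by_target: dict[str, list[tuple[int, str, int]]] = {}
    for tid, start, strand, mm in p2:
        by_target.setdefault(tid, []).append((start, strand, mm))
    best: Optional[tuple[int, Alignment, Alignment]] = None
    L1, L2 = len(pair.seq1), len(pair.seq2)
    for tid, s1, strand1, mm1 in p1:
        for s2, strand2, mm2 in by_target.get(tid, ()):
            if strand1 == strand2:
                continue
            if strand1 == "+":
                fwd_start, rev_end = s1, s2 + L2
            else:
                fwd_start, rev_end = s2, s1 + L1
            frag = rev_end - fwd_start
            if frag < max(L1, L2) or frag > max_insert:
                continue
            total = mm1 + mm2
            if best is None or total < best[0]:
                a1 = Alignment(pair.pair_id, 1, tid, s1, strand1, mm1, True, L1)
                a2 = Alignment(pair.pair_id, 2, tid, s2, strand2, mm2, True, L2)
                best = (total, a1, a2)
    if best is None:
        return None
    return best[1], best[2]
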