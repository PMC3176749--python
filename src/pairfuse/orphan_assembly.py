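"""Reference-free breakpoint discovery from orphan read ends.

Pairs in which one mate aligns near the locus of interest and the other
fails to align at all carry breakpoint-crossing sequence in the unaligned
("orphan") mate.  Orphans are collected per 200 bp window of the anchored
mate (plus-anchor and minus-anchor classes separately), assembled with a
small de Bruijn assembler (a desk-scale stand-in for a production de novo
assembler), screened by tiling each contig into 80-mers against the
reference, checked for sample-specific support, and split-aligned to
nominate breakpoint coordinates.  A per-position 80-mer multi-mapping scan
quantifies the method's mappability blind spot.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .refalign import Genome, ReadPair, revcomp

logger = logging.getLogger("pairfuse")


# ---------------------------------------------------------------------------
# Orphan collection
# ---------------------------------------------------------------------------

@dataclass
class OrphanWindowSet:
    anchor: int
    radius: int
    window: int
    # (strand_class, window_index) -> list of orphan sequences
    windows: dict[tuple[str, int], list[str]] = field(default_factory=dict)

    @property
    def n_orphans(self) -> int:
        return sum(len(v) for v in self.windows.values())


def collect_orphans(
    pairs: Iterable[ReadPair],
    placements: pd.DataFrame,
    contig: str,
    anchor: int,
    radius: int = 20_000,
    window: int = 200,
) -> OrphanWindowSet:
    """Collect unaligned mates of pairs anchored within ``radius`` of
    ``anchor``, windowed by the aligned mate's start, split by the aligned
    mate's strand."""
    seq_of: dict[tuple[str, int], str] = {}
    for p in pairs:
        seq_of[(p.pair_id, 1)] = p.seq1
        seq_of[(p.pair_id, 2)] = p.seq2
    lo, hi = anchor - radius, anchor + radius
    out = OrphanWindowSet(anchor, radius, window)
    for row in placements.itertuples(index=False):
        for a_side, o_side in ((1, 2), (2, 1)):
            a_contig = getattr(row, f"contig{a_side}")
            a_start = getattr(row, f"start{a_side}")
            o_contig = getattr(row, f"contig{o_side}")
            if a_contig != contig or o_contig != "":
                continue
            if not getattr(row, f"unique{a_side}"):
                continue
            if not lo <= a_start < hi:
                continue
            strand = getattr(row, f"strand{a_side}")
            widx = (a_start - lo) // window
            out.windows.setdefault((strand, widx), []).append(
                seq_of[(row.pair_id, o_side)]
            )
    if out.n_orphans == 0:
        logger.warning("no orphan ends collected around %s:%d", contig, anchor)
    return out


# ---------------------------------------------------------------------------
# De Bruijn assembly
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    sequence: str
    k: int
    support: int  # minimum k-mer coverage along the contig
    sample_id: str = ""
    provenance: str = ""
    tile_outcomes: list[str] = field(default_factory=list)
    unaligned_tiles: Optional[int] = None
    sample_specific: Optional[bool] = None

    def __len__(self) -> int:
        return len(self.sequence)


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def assemble(
    reads: list[str],
    k: int = 31,
    min_coverage: int = 2,
    sample_id: str = "",
    provenance: str = "",
) -> list[Contig]:
    """Assemble reads into unitigs of a k-mer de Bruijn graph.

    k-mers with canonical coverage below ``min_coverage`` are pruned;
    maximal unbranched paths are emitted.  The procedure is deterministic and
    independent of read order: nodes are visited in lexicographic order and
    each contig is reported in its canonical (lexicographically smaller)
    orientation.  Raises if no read reaches length k.
    """
    usable = [r for r in reads if len(r) >= k]
    if not usable:
        raise ValueError(f"no read of length >= k={k}")

    counts: Counter[str] = Counter()
    for read in usable:
        for strand_seq in (read, revcomp(read)):
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i : i + k]
                if "N" in kmer:
                    continue
                counts[_canonical(kmer)] += 1
    # both orientations of every read are counted, so canonical coverage is
    # twice the read support
    solid = {
        km
        for km, c in counts.items()
        if c >= 2 * min_coverage
    }
    nodes: set[str] = set()
    for km in solid:
        nodes.add(km)
        nodes.add(revcomp(km))

    def succs(km: str) -> list[str]:
        return [km[1:] + b for b in "ACGT" if km[1:] + b in nodes]

    def preds(km: str) -> list[str]:
        return [b + km[:-1] for b in "ACGT" if b + km[:-1] in nodes]

    def cov(km: str) -> int:
        return counts[_canonical(km)] // 2

    visited: set[str] = set()
    contigs: list[Contig] = []

    def emit(path: list[str]) -> None:
        seq = path[0] + "".join(p[-1] for p in path[1:])
        canon = min(seq, revcomp(seq))
        support = min(cov(p) for p in path)
        contigs.append(Contig(canon, k, support, sample_id, provenance))

    # unitig starts: nodes that cannot be uniquely extended backwards
    for start in sorted(nodes):
        if start in visited:
            continue
        p = preds(start)
        if len(p) == 1 and len(succs(p[0])) == 1:
            continue  # interior of a unitig
        path = [start]
        visited.add(start)
        cur = start
        while True:
            s = succs(cur)
            if len(s) != 1:
                break
            nxt = s[0]
            if len(preds(nxt)) != 1 or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        emit(path)
    # pure cycles (rare at toy scale): start at lexicographic minimum
    for start in sorted(nodes):
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        cur = start
        while True:
            s = succs(cur)
            if len(s) != 1 or s[0] in visited:
                break
            path.append(s[0])
            visited.add(s[0])
            cur = s[0]
        emit(path)

    # canonical orientation makes every contig appear twice; deduplicate
    uniq: dict[str, Contig] = {}
    for c in contigs:
        prev = uniq.get(c.sequence)
        if prev is None or c.support > prev.support:
            uniq[c.sequence] = c
    out = sorted(uniq.values(), key=lambda c: (-len(c.sequence), c.sequence))
    return out


# ---------------------------------------------------------------------------
# Exact-match machinery for tiling / mappability
# ---------------------------------------------------------------------------

class ExactMatcher:
    """Counts exact occurrences of fixed-length words in a genome (both
    strands)."""

    def __init__(self, genome: Genome | Mapping[str, str], word: int):
        self.word = word
        contigs = genome.contigs if isinstance(genome, Genome) else dict(genome)
        table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in contigs.items():
            for i in range(len(seq) - word + 1):
                w = seq[i : i + word]
                if "N" in w:
                    continue
                table.setdefault(w, []).append((name, i))
        self._table = table

    def count(self, w: str) -> int:
        fwd = len(self._table.get(w, ()))
        rc = revcomp(w)
        if rc == w:
            return fwd
        return fwd + len(self._table.get(rc, ()))

    def locate_unique(self, w: str) -> Optional[tuple[str, int, str]]:
        fwd = self._table.get(w, [])
        rev = self._table.get(revcomp(w), [])
        if len(fwd) + len(rev) != 1:
            return None
        if fwd:
            return (*fwd[0], "+")
        return (*rev[0], "-")


# ---------------------------------------------------------------------------
# Tiling screen
# ---------------------------------------------------------------------------

def tile_offsets(length: int, tile: int, step: int) -> list[int]:
    """Offsets 0, step, 2*step, ... plus a final end-anchored tile."""
    if length < tile:
        raise ValueError("contig shorter than tile")
    offs = list(range(0, length - tile + 1, step))
    if offs[-1] != length - tile:
        offs.append(length - tile)
    return offs


def tile_and_screen(
    contig: Contig,
    matcher: ExactMatcher,
    tile: int = 80,
    step: int = 80,
    multimap_threshold: int = 10,
) -> Contig:
    """Fragment the contig into tiling 80-mers, classify each against the
    reference (absent / unique / multi), and flag the contig for scrutiny iff
    at least one tile is absent from the reference."""
    assert matcher.word == tile
    outcomes = []
    n_absent = 0
    for off in tile_offsets(len(contig.sequence), tile, step):
        w = contig.sequence[off : off + tile]
        c = matcher.count(w)
        if c == 0:
            outcomes.append("absent")
            n_absent += 1
        elif c > multimap_threshold:
            outcomes.append("multi")
        elif c == 1:
            outcomes.append("unique")
        else:
            outcomes.append("repeat")
    contig.tile_outcomes = outcomes
    contig.unaligned_tiles = n_absent
    return contig


# ---------------------------------------------------------------------------
# Sample specificity
# ---------------------------------------------------------------------------

def sample_specificity(
    contig: Contig,
    sample_reads: Mapping[str, Iterable[str]],
    genome: Optional[Genome] = None,
    tile: int = 80,
    step: int = 80,
    min_reads: int = 2,
    min_overlap: int = 20,
) -> tuple[bool, dict[str, int]]:
    """Is the contig's novel (reference-absent) sequence supported by reads
    of exactly one sample?

    A read supports the contig when it matches the contig exactly (either
    strand) overlapping an absent tile by at least ``min_overlap`` and — when
    a reference genome is supplied — is itself absent from the reference
    (reads explainable by the reference are not evidence for the novel
    junction).
    """
    if len(sample_reads) < 2:
        raise ValueError("sample specificity needs >= 2 samples")
    if contig.unaligned_tiles is None:
        raise ValueError("run tile_and_screen first")
    ref_seqs = list(genome.contigs.values()) if genome is not None else []
    offs = tile_offsets(len(contig.sequence), tile, step)
    absent_iv = [
        (off, off + tile)
        for off, oc in zip(offs, contig.tile_outcomes)
        if oc == "absent"
    ]
    seq = contig.sequence
    counts: dict[str, int] = {}
    for sample, reads in sample_reads.items():
        c = 0
        for read in reads:
            hit = -1
            for q in (read, revcomp(read)):
                hit = seq.find(q)
                if hit >= 0:
                    break
            if hit < 0:
                continue
            if ref_seqs:
                rc = revcomp(read)
                if any(read in r or rc in r for r in ref_seqs):
                    continue
            span = (hit, hit + len(read))
            for s, e in absent_iv:
                if min(span[1], e) - max(span[0], s) >= min_overlap:
                    c += 1
                    break
        counts[sample] = c
    supported = [s for s, c in counts.items() if c >= min_reads]
    if supported:
        contig.sample_specific = len(supported) == 1
    else:
        contig.sample_specific = False
    return bool(contig.sample_specific), counts


# ---------------------------------------------------------------------------
# Breakpoint nomination
# ---------------------------------------------------------------------------

@dataclass
class BreakpointCandidate:
    contig_seq: str
    ref_contig: str
    # reference join: prefix ends at ``end`` (exclusive), suffix resumes at
    # ``start``; for a tandem duplication start < end
    end: int
    start: int
    orientation: str
    support: int


def canonical_breakpoint(ref: str, end: int, start: int) -> tuple[int, int]:
    """Left-align a junction (end -> start) through its micro-homology."""
    while end > 0 and start > 0 and ref[end - 1] == ref[start - 1]:
        end -= 1
        start -= 1
    return end, start


def nominate_breakpoint(
    contigs: list[Contig],
    genome: Genome,
    matcher: Optional[ExactMatcher] = None,
    anchor_len: int = 31,
) -> list[BreakpointCandidate]:
    """Split-align scrutinized contigs to nominate breakpoints.

    The contig's prefix and suffix are anchored uniquely in the reference and
    extended to their maximal exact matches; when they place at distinct loci
    the junction (prefix-end reference coordinate, suffix-start reference
    coordinate) is reported, left-aligned through any micro-homology.
    """
    matcher = matcher or ExactMatcher(genome, anchor_len)
    assert matcher.word == anchor_len
    out = []
    for contig in contigs:
        if not contig.unaligned_tiles:
            continue  # fully explained by the reference
        bp = _split_align(contig, genome, matcher, anchor_len)
        if bp is not None:
            out.append(bp)
    return out


def _split_align(
    contig: Contig, genome: Genome, matcher: ExactMatcher, k: int
) -> Optional[BreakpointCandidate]:
    for seq in (contig.sequence, revcomp(contig.sequence)):
        if len(seq) < 2 * k:
            continue
        loc_p = matcher.locate_unique(seq[:k])
        loc_s = matcher.locate_unique(seq[-k:])
        if loc_p is None or loc_s is None:
            continue
        if loc_p[2] != "+" or loc_s[2] != "+":
            continue
        ref_name, pos_p = loc_p[0], loc_p[1]
        ref_name_s, pos_s = loc_s[0], loc_s[1]
        if ref_name != ref_name_s:
            continue  # cross-contig joins not modeled here
        ref = genome[ref_name]
        # extend the prefix match forward to its maximal length
        i = k
        while i < len(seq) and pos_p + i < len(ref) and seq[i] == ref[pos_p + i]:
            i += 1
        if i >= len(seq):
            continue  # contig fully reference
        # the suffix placement maps contig coordinate x to reference
        # coordinate pos_s + x - (len(seq) - k); extend backwards maximally
        j0 = len(seq) - k
        while j0 > 0:
            ref_coord = pos_s + (j0 - 1) - (len(seq) - k)
            if ref_coord < 0 or seq[j0 - 1] != ref[ref_coord]:
                break
            j0 -= 1
        if j0 > i:
            continue  # prefix and suffix do not meet: unresolved middle
        junction_c = j0  # junction placed at leftmost compatible position
        end = pos_p + junction_c
        start = pos_s + junction_c - (len(seq) - k)
        if end == start:
            continue  # contiguous reference, no junction
        end, start = canonical_breakpoint(ref, end, start)
        orientation = "tandem" if start < end else "deletion-like"
        return BreakpointCandidate(
            contig_seq=contig.sequence,
            ref_contig=ref_name,
            end=end,
            start=start,
            orientation=orientation,
            support=contig.support,
        )
    return None


# ---------------------------------------------------------------------------
# Mappability blind spots
# ---------------------------------------------------------------------------

@dataclass
class MappabilityReport:
    contig: str
    start: int
    end: int
    tile: int
    threshold: int
    n_tiles: int
    n_blind: int

    @property
    def fraction(self) -> float:
        return self.n_blind / self.n_tiles if self.n_tiles else 0.0


def mappability(
    genome: Genome,
    interval: tuple[str, int, int],
    tile: int = 80,
    step: int = 1,
    threshold: int = 10,
    matcher: Optional[ExactMatcher] = None,
) -> MappabilityReport:
    """Per-position 80-mer multi-mapping scan of an interval.

    A tile is "blind" when it has more than ``threshold`` exact matches in
    the whole genome (both strands counted).
    """
    contig, s, e = interval
    seq = genome[contig]
    if not 0 <= s < e <= len(seq):
        raise ValueError("interval outside genome")
    if e - s < tile:
        raise ValueError("interval shorter than tile length")
    matcher = matcher or ExactMatcher(genome, tile)
    assert matcher.word == tile
    n_tiles = 0
    n_blind = 0
    for off in range(s, e - tile + 1, step):
        n_tiles += 1
        if matcher.count(seq[off : off + tile]) > threshold:
            n_blind += 1
    return MappabilityReport(contig, s, e, tile, threshold, n_tiles, n_blind)
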