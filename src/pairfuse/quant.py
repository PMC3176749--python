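"""Expression ranking and relative isoform abundance from paired-end reads.

Gene expression rank uses unique single-read counts normalized per kilobase
of exon model per million aligned reads.  Isoform abundance uses a binary
compatibility EM over paired-end reads: a pair is compatible with an isoform
when both mates align contiguously in FR orientation with an implied
fragment length inside the insert model's support, and the likelihood is

    L(theta) = prod_r sum_i theta_i * a_ri / l_i

with a_ri in {0,1} and effective length l_i = max(1, L_i - mean_frag + 1).
The fitted mixture weights are read-generating fractions; the reported
relative (molar) abundances divide out the effective lengths.  The EM trace
is asserted monotone at every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .refalign import (
    Alignment,
    GeneModel,
    ReadPair,
    SeedIndex,
    Transcript,
    align_all,
)

logger = logging.getLogger("pairfuse")


# ---------------------------------------------------------------------------
# Gene expression rank
# ---------------------------------------------------------------------------

def gene_expression_rank(
    alignments: Iterable[Alignment],
    genes: Mapping[str, GeneModel],
    gene_of_transcript: Mapping[str, str],
) -> pd.DataFrame:
    """Rank genes by read density (reads per kb of exon model per million).

    Only unique alignments are counted; rank 1 is the most abundant gene.
    """
    counts: dict[str, int] = {g: 0 for g in genes}
    total = 0
    for aln in alignments:
        if not aln.is_unique:
            continue
        gene = gene_of_transcript.get(aln.target_id, aln.target_id)
        if gene not in counts:
            continue
        counts[gene] += 1
        total += 1
    if total == 0:
        raise ValueError("no uniquely aligned reads; cannot rank expression")
    rows = []
    for g, c in counts.items():
        length = sum(genes[g].exon_lengths())
        density = c / (length / 1e3) / (total / 1e6)
        rows.append((g, c, length, density))
    df = pd.DataFrame(rows, columns=["gene_id", "count", "length", "density"])
    df = df.sort_values(["density", "gene_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# Isoform abundance EM
# ---------------------------------------------------------------------------

@dataclass
class InsertModel:
    """Truncated-normal fragment length prior; support = [lo, hi]."""

    mean: float = 350.0
    sd: float = 30.0

    @property
    def lo(self) -> float:
        return max(0.0, self.mean - 4 * self.sd)

    @property
    def hi(self) -> float:
        return self.mean + 4 * self.sd


@dataclass
class AbundanceEstimate:
    isoform_ids: list[str]
    theta: np.ndarray  # relative molar abundance (sums to 1)
    read_fractions: np.ndarray  # EM mixture weights (read-generating shares)
    effective_lengths: np.ndarray
    log_likelihood: list[float]
    n_reads: int
    unique_support: dict[str, int]
    no_direct_evidence: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "isoform": self.isoform_ids,
                "theta": self.theta,
                "effective_length": self.effective_lengths,
                "unique_support": [self.unique_support[t] for t in self.isoform_ids],
                "no_direct_evidence": [
                    t in self.no_direct_evidence for t in self.isoform_ids
                ],
            }
        )


def pair_compatibility(
    pair: ReadPair,
    index: SeedIndex,
    isoform_ids: list[str],
    insert: InsertModel,
    max_mismatch: int = 2,
) -> np.ndarray:
    """Binary compatibility of one pair against each isoform.

    Compatible = some FR placement combination on that isoform with implied
    fragment length in the insert model's support.
    """
    L1, L2 = len(pair.seq1), len(pair.seq2)
    p1 = align_all(pair.seq1, index, max_mismatch)
    p2 = align_all(pair.seq2, index, max_mismatch)
    out = np.zeros(len(isoform_ids), dtype=bool)
    if not p1 or not p2:
        return out
    pos = {tid: i for i, tid in enumerate(isoform_ids)}
    by_target: dict[str, list[tuple[int, str]]] = {}
    for tid, start, strand, _ in p2:
        by_target.setdefault(tid, []).append((start, strand))
    lo = max(insert.lo, max(L1, L2))
    for tid, s1, strand1, _ in p1:
        i = pos[tid]
        if out[i]:
            continue
        for s2, strand2 in by_target.get(tid, ()):
            if strand1 == strand2:
                continue
            if strand1 == "+":
                frag = (s2 + L2) - s1
            else:
                frag = (s1 + L1) - s2
            if lo <= frag <= insert.hi:
                out[i] = True
                break
    return out


def isoform_em(
    pairs: list[ReadPair],
    isoforms: Mapping[str, Transcript] | Mapping[str, str],
    insert: InsertModel | None = None,
    max_mismatch: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AbundanceEstimate:
    """Estimate relative isoform abundances theta by EM.

    Estimates are invariant to isoform input order (ids are sorted
    internally) and the log-likelihood is asserted non-decreasing.
    """
    insert = insert or InsertModel()
    seqs = {
        tid: (t.sequence if isinstance(t, Transcript) else t)
        for tid, t in isoforms.items()
    }
    ids = sorted(seqs)
    index = SeedIndex({t: seqs[t] for t in ids})
    compat = []
    for pair in pairs:
        row = pair_compatibility(pair, index, ids, insert, max_mismatch)
        if row.any():
            compat.append(row)
    if not compat:
        raise ValueError("no read pair is compatible with any isoform")
    A = np.array(compat, dtype=float)  # n x k
    n, k = A.shape
    lens = np.array([len(seqs[t]) for t in ids], float)
    eff = np.maximum(1.0, lens - insert.mean + 1.0)

    W = A / eff  # a_ri / l_i
    alpha = np.full(k, 1.0 / k)  # read-generating mixture weights
    trace: list[float] = []
    for _ in range(max_iter):
        num = W * alpha
        denom = num.sum(axis=1)
        ll = float(np.log(denom).sum())
        if trace:
            assert ll >= trace[-1] - 1e-9, "EM log-likelihood decreased"
            if abs(ll - trace[-1]) < tol * abs(trace[-1]):
                trace.append(ll)
                break
        trace.append(ll)
        resp = num / denom[:, None]
        alpha = resp.mean(axis=0)
    alpha = alpha / alpha.sum()
    # molar abundance: reads are drawn per molecule proportionally to the
    # number of fragment placements, so divide out the effective length
    theta = (alpha / eff) / (alpha / eff).sum()

    unique = A.sum(axis=1) == 1
    support = {
        t: int((A[unique][:, i] > 0).sum()) for i, t in enumerate(ids)
    }
    no_evidence = [t for t in ids if support[t] == 0]
    return AbundanceEstimate(
        isoform_ids=ids,
        theta=theta,
        read_fractions=alpha,
        effective_lengths=eff,
        log_likelihood=trace,
        n_reads=n,
        unique_support=support,
        no_direct_evidence=no_evidence,
    )
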