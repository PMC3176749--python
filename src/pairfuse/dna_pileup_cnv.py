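"""DNA-side evidence for genomic rearrangement.

Three layers:

* anomalous read-pair flagging — pairs whose two uniquely mapped ends are
  more than 1 kb apart (inconsistent with <0.8 kb library inserts), not in
  FR-inward orientation, or on different contigs;

* a 2-D pile-up test — anomalous pairs are histogrammed by the bin of the
  (+)-oriented end against the bin of the (−)-oriented end; each cell is
  tested against a Poisson null whose mean is the anomalous-pair total times
  the product of position-specific coverage marginals (the capture bias,
  estimated from ALL uniquely aligned read starts per strand), with
  Benjamini-Hochberg control over all bias-covered cells and 8-connected
  merging of significant cells into clusters;

* binned tumor/normal copy number — deduplicated single-read counts in 100 bp
  bins, point estimate rho = 2 (t/T)/(n/N) and an exact (Clopper-Pearson)
  confidence interval on the conditional binomial proportion t/(t+n) mapped
  to the rho scale.

A tandem duplication is called when a cluster shows the everted-orientation
signature ((+) end downstream joined to (−) end upstream) and the interior
copy number steps significantly above the exterior (expected 1.5x for a
heterozygous duplication in a diploid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .refalign import ReadPair, SeedIndex, align_single

logger = logging.getLogger("pairfuse")

MAX_SEPARATION = 1_000


# ---------------------------------------------------------------------------
# Alignment of pairs to the genome (tabular form for binning)
# ---------------------------------------------------------------------------

def align_pairs_to_genome(
    pairs: Iterable[ReadPair],
    index: SeedIndex,
    max_mismatch: int = 2,
) -> pd.DataFrame:
    """Align both mates of each pair singly; one row per pair.

    Columns: pair_id, contig1/start1/strand1/unique1 (and side 2), read_len.
    Unaligned sides carry contig "" and start -1.
    """
    rows = []
    for pair in pairs:
        rec = [pair.pair_id, pair.sample_id, len(pair.seq1)]
        for side, seq in ((1, pair.seq1), (2, pair.seq2)):
            aln = align_single(seq, index, max_mismatch, pair.pair_id, side)
            if aln is None:
                rec.extend(["", -1, ".", False])
            else:
                rec.extend([aln.target_id, aln.start, aln.strand, aln.is_unique])
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "sample_id",
            "read_len",
            "contig1",
            "start1",
            "strand1",
            "unique1",
            "contig2",
            "start2",
            "strand2",
            "unique2",
        ],
    )


# ---------------------------------------------------------------------------
# Anomalous pair flagging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnomalousPair:
    pair_id: str
    contig1: str
    start1: int
    strand1: str
    contig2: str
    start2: int
    strand2: str
    separation: int
    reason: str  # distance | orientation | cross-contig

    @property
    def plus_start(self) -> Optional[int]:
        if self.strand1 == "+":
            return self.start1
        if self.strand2 == "+":
            return self.start2
        return None

    @property
    def minus_start(self) -> Optional[int]:
        if self.strand1 == "-":
            return self.start1
        if self.strand2 == "-":
            return self.start2
        return None


def flag_anomalous(
    placements: pd.DataFrame,
    max_sep: int = MAX_SEPARATION,
) -> list[AnomalousPair]:
    """Classify uniquely-both-mapped pairs as concordant or anomalous.

    FR-inward with separation <= max_sep is concordant; anything else is
    flagged with reason cross-contig, orientation, or distance.
    """
    out: list[AnomalousPair] = []
    both = placements[(placements.unique1) & (placements.unique2)]
    for row in both.itertuples(index=False):
        reason = None
        sep = abs(row.start2 - row.start1)
        if row.contig1 != row.contig2:
            reason = "cross-contig"
        else:
            if row.strand1 == row.strand2:
                reason = "orientation"
            else:
                plus_start = row.start1 if row.strand1 == "+" else row.start2
                minus_start = row.start1 if row.strand1 == "-" else row.start2
                inward = plus_start <= minus_start
                if not inward:
                    reason = "orientation"
                elif sep > max_sep:
                    reason = "distance"
        if reason is None:
            continue
        out.append(
            AnomalousPair(
                row.pair_id,
                row.contig1,
                row.start1,
                row.strand1,
                row.contig2,
                row.start2,
                row.strand2,
                sep,
                reason,
            )
        )
    return out


# ---------------------------------------------------------------------------
# PCR-duplicate removal
# ---------------------------------------------------------------------------

def dedup_pairs(placements: pd.DataFrame) -> pd.DataFrame:
    """Collapse pairs with identical (start1, strand1, start2, strand2)."""
    return placements.drop_duplicates(
        subset=["contig1", "start1", "strand1", "contig2", "start2", "strand2"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# 2-D pile-up test
# ---------------------------------------------------------------------------

@dataclass
class PileupCluster:
    cells: list[tuple[int, int]]
    n_pairs: int
    plus_mode: int  # modal (+)-end read start
    minus_mode: int  # modal (−)-end read start
    plus_end: int  # modal (+)-end read END (start + read_len)
    q_min: float


def pileup_test(
    anomalous: list[AnomalousPair],
    placements: pd.DataFrame,
    region: tuple[str, int, int],
    bin_size: int = 500,
    fdr_level: float = 0.05,
    read_len: int = 80,
    min_pairs: int = 3,
) -> list[PileupCluster]:
    """Nominate significant anomalous-pair pile-ups.

    The null mean for cell (i,j) is T * p_i * q_j where p and q are the
    position-specific coverage marginals of (+) and (−) uniquely aligned read
    starts (all reads, not only anomalous ones — the shared capture bias),
    and T is the anomalous-pair total.  BH is applied over every cell with
    positive bias on both axes; significant cells are merged 8-connectedly.
    Clusters supported by fewer than ``min_pairs`` anomalous pairs are not
    reported: with near-zero cell means the Poisson tail declares any
    two-pair coincidence significant, so a support floor (standard in
    discordant-pair structural-variant calling) backs the statistical call.
    """
    contig, rstart, rend = region
    if rend - rstart < bin_size:
        raise ValueError("region smaller than one bin")
    nbins = int(np.ceil((rend - rstart) / bin_size))

    # coverage marginals from all uniquely aligned read starts
    plus_cov = np.zeros(nbins)
    minus_cov = np.zeros(nbins)
    for side in (1, 2):
        sub = placements[
            (placements[f"unique{side}"]) & (placements[f"contig{side}"] == contig)
        ]
        starts = sub[f"start{side}"].to_numpy()
        strands = sub[f"strand{side}"].to_numpy()
        inb = (starts >= rstart) & (starts < rend)
        b = ((starts[inb] - rstart) // bin_size).astype(int)
        st = strands[inb]
        np.add.at(plus_cov, b[st == "+"], 1)
        np.add.at(minus_cov, b[st == "-"], 1)
    if plus_cov.sum() == 0 or minus_cov.sum() == 0:
        return []
    p = plus_cov / plus_cov.sum()
    q = minus_cov / minus_cov.sum()

    # 2-D histogram of anomalous pairs ((+) end bin x (−) end bin)
    usable = []
    for a in anomalous:
        if a.contig1 != contig or a.contig2 != contig:
            continue
        ps, ms = a.plus_start, a.minus_start
        if ps is None or ms is None:
            continue
        if not (rstart <= ps < rend and rstart <= ms < rend):
            continue
        usable.append((a, (ps - rstart) // bin_size, (ms - rstart) // bin_size))
    T = len(usable)
    if T == 0:
        return []
    C = np.zeros((nbins, nbins))
    for _, i, j in usable:
        C[i, j] += 1

    lam = T * np.outer(p, q)
    valid = lam > 0
    pvals = np.ones_like(lam)
    pvals[valid] = stats.poisson.sf(C[valid] - 1, lam[valid])
    flat = pvals[valid]
    qvals_flat = stats.false_discovery_control(flat, method="bh")
    qvals = np.ones_like(lam)
    qvals[valid] = qvals_flat
    sig = (qvals <= fdr_level) & (C > 0)
    if not sig.any():
        return []

    labels, n_lab = ndimage.label(sig, structure=np.ones((3, 3), dtype=int))
    clusters: list[PileupCluster] = []
    for lab in range(1, n_lab + 1):
        cells = [tuple(c) for c in np.argwhere(labels == lab)]
        cellset = set(cells)
        members = [a for a, i, j in usable if (i, j) in cellset]
        if len(members) < min_pairs:
            continue
        plus_starts = [a.plus_start for a in members]
        minus_starts = [a.minus_start for a in members]
        plus_mode = int(pd.Series(plus_starts).mode().iloc[0])
        minus_mode = int(pd.Series(minus_starts).mode().iloc[0])
        clusters.append(
            PileupCluster(
                cells=sorted(cells),
                n_pairs=len(members),
                plus_mode=plus_mode,
                minus_mode=minus_mode,
                plus_end=plus_mode + read_len,
                q_min=float(qvals[tuple(np.array(cells).T)].min()),
            )
        )
    clusters.sort(key=lambda c: -c.n_pairs)
    return clusters


# ---------------------------------------------------------------------------
# Copy number profile
# ---------------------------------------------------------------------------

def _clopper_pearson(x: int, m: int, conf: float) -> tuple[float, float]:
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, m - x + 1))
    hi = 1.0 if x == m else float(stats.beta.ppf(1 - alpha / 2, x + 1, m - x))
    return lo, hi


def copy_number_profile(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    region: tuple[str, int, int],
    bin_size: int = 100,
    conf: float = 0.95,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Per-bin copy number rho = 2 (t/T)/(n/N) with exact CIs.

    Inputs are deduplicated pair placements; every uniquely aligned read
    start is counted singly.  Bins with zero normal reads (or total depth
    below ``min_depth``) are masked.  The CI is Clopper-Pearson on the
    conditional proportion pi = t/(t+n), mapped to the rho scale by
    rho = 2 (pi/(1-pi)) (N/T).
    """
    contig, rstart, rend = region
    nbins = int(np.ceil((rend - rstart) / bin_size))

    def bin_counts(df: pd.DataFrame) -> np.ndarray:
        c = np.zeros(nbins, dtype=int)
        for side in (1, 2):
            sub = df[(df[f"unique{side}"]) & (df[f"contig{side}"] == contig)]
            starts = sub[f"start{side}"].to_numpy()
            inb = (starts >= rstart) & (starts < rend)
            np.add.at(c, ((starts[inb] - rstart) // bin_size).astype(int), 1)
        return c

    t = bin_counts(tumor)
    n = bin_counts(normal)
    T_tot, N_tot = int(t.sum()), int(n.sum())
    if T_tot == 0 or N_tot == 0:
        raise ValueError("no aligned reads in region for one of the samples")
    scale = N_tot / T_tot

    rows = []
    for i in range(nbins):
        start = rstart + i * bin_size
        masked = n[i] == 0 or (t[i] + n[i]) < min_depth
        if masked:
            rows.append((start, int(t[i]), int(n[i]), np.nan, np.nan, np.nan, True))
            continue
        rho = 2.0 * (t[i] / T_tot) / (n[i] / N_tot)
        m = int(t[i] + n[i])
        lo_pi, hi_pi = _clopper_pearson(int(t[i]), m, conf)
        lo = 2.0 * (lo_pi / (1 - lo_pi)) * scale if lo_pi < 1 else np.inf
        hi = 2.0 * (hi_pi / (1 - hi_pi)) * scale if hi_pi < 1 else np.inf
        rows.append((start, int(t[i]), int(n[i]), rho, lo, hi, False))
    return pd.DataFrame(
        rows, columns=["bin_start", "t", "n", "rho", "ci_lo", "ci_hi", "masked"]
    )


def interior_exterior_ratio(
    profile: pd.DataFrame,
    interval: tuple[int, int],
    bin_size: int = 100,
    margin: int = 200,
) -> tuple[float, float, float]:
    """(mean interior rho, mean exterior rho, their ratio).

    Bins within ``margin`` of either breakpoint are excluded from both sets
    (junction-crossing reads are unalignable and deplete those bins).
    """
    s, e = interval
    ok = ~profile.masked
    starts = profile.bin_start
    ends = starts + bin_size
    interior = ok & (starts >= s + margin) & (ends <= e - margin)
    exterior = ok & ((ends <= s - margin) | (starts >= e + margin))
    mi = float(profile.loc[interior, "rho"].mean())
    me = float(profile.loc[exterior, "rho"].mean())
    return mi, me, mi / me


# ---------------------------------------------------------------------------
# Rearrangement model fit
# ---------------------------------------------------------------------------

@dataclass
class RearrangementCall:
    call_type: str  # tandem_duplication | unresolved | none
    interval: Optional[tuple[int, int]] = None
    cluster: Optional[PileupCluster] = None
    interior_rho: float = float("nan")
    exterior_rho: float = float("nan")
    ratio: float = float("nan")
    p_value: float = 1.0
    junction_seq: str = ""
    cnv_flag: bool = False


def fit_duplication_model(
    clusters: list[PileupCluster],
    profile: pd.DataFrame,
    bin_size: int = 100,
    margin: int = 200,
    alpha: float = 0.01,
) -> RearrangementCall:
    """Reconcile pile-up clusters with the copy-number step.

    A tandem duplication requires a cluster with the everted signature (the
    (+) end downstream of the (−) end: reference join interval end -> start)
    AND a significant interior-vs-exterior copy-number step.  Copy-number
    variation without a usable cluster yields an "unresolved" call.
    """
    everted = [c for c in clusters if c.plus_end > c.minus_mode]
    for cluster in sorted(everted, key=lambda c: -c.n_pairs):
        interval = (cluster.minus_mode, cluster.plus_end)
        mi, me, ratio = interior_exterior_ratio(profile, interval, bin_size, margin)
        p = _step_test(profile, interval, bin_size, margin)
        if p <= alpha and ratio > 1.0:
            return RearrangementCall(
                "tandem_duplication",
                interval=interval,
                cluster=cluster,
                interior_rho=mi,
                exterior_rho=me,
                ratio=ratio,
                p_value=p,
            )
    # no breakpoint cluster: is there CNV evidence at all?
    cnv = _any_cnv(profile)
    if cnv:
        return RearrangementCall("unresolved", cnv_flag=True)
    return RearrangementCall("none")


def _step_test(
    profile: pd.DataFrame, interval: tuple[int, int], bin_size: int, margin: int
) -> float:
    """Two-sided test of equal tumor share interior vs exterior (aggregate
    2x2 contingency on pooled deduplicated counts)."""
    s, e = interval
    ok = ~profile.masked
    starts = profile.bin_start
    ends = starts + bin_size
    interior = ok & (starts >= s + margin) & (ends <= e - margin)
    exterior = ok & ((ends <= s - margin) | (starts >= e + margin))
    table = np.array(
        [
            [profile.loc[interior, "t"].sum(), profile.loc[interior, "n"].sum()],
            [profile.loc[exterior, "t"].sum(), profile.loc[exterior, "n"].sum()],
        ]
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(table)[1])


def _any_cnv(profile: pd.DataFrame, null_rho: float = 2.0, min_run: int = 3) -> bool:
    """CNV evidence: a run of >= min_run unmasked bins whose 95% CI excludes
    the diploid value."""
    ok = ~profile.masked
    exclude = ok & ((profile.ci_lo > null_rho) | (profile.ci_hi < null_rho))
    run = 0
    for flag in exclude:
        run = run + 1 if flag else 0
        if run >= min_run:
            return True
    return False
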