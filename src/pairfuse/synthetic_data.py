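"""Synthetic data generator: every input the pipeline needs, with the
statistical structure the analysis assumes.

Two instruments are emulated:

* an mRNA paired-end library from a two-gene adjacent locus carrying fusion
  isoforms at configurable molar ratios (default 40:10:1:0), 350 bp
  fragments, mixed 76/38 nt reads, substitution errors, and ligation-chimera
  artifact pairs;

* capture-enriched genomic paired-end libraries from a diploid locus with an
  optional heterozygous tandem duplication, a smooth position-specific
  coverage bias shared across samples (capture-probe inhomogeneity), PCR
  duplicates, and a small rate of ligation-artifact pairs.

Everything is reproducible from (config, seed); truth tables record fragment
provenance, haplotype, junction-spanning status and PCR-duplicate labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .refalign import Genome, GeneModel, ReadPair, Transcript, make_transcript, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Locus specification and construction
# ---------------------------------------------------------------------------

@dataclass
class ParalogSpec:
    """Plant a diverged copy of the downstream gene on another contig."""

    identity: float = 0.95
    contig: str = "chr_paralog"
    flank: int = 2_000


@dataclass
class LocusSpec:
    """Two same-strand neighboring genes: ``gene_up`` (5 exons, genomic
    upstream; the 3' fusion partner) and ``gene_down`` (3 exons, downstream;
    the 5' fusion partner), separated by a ~1 kb intergenic gap.

    Defaults give a ~48 kb locus in which the canonical tandem duplication
    (from gene_up intron 2 to gene_down intron 2) spans ~8.5 kb.
    """

    contig: str = "chr11_toy"
    gene_up_id: str = "C11LIKE"
    gene_down_id: str = "ERRLIKE"
    n_exons_up: int = 5
    n_exons_down: int = 3
    exon_len_range: tuple[int, int] = (220, 380)
    intron_len_range: tuple[int, int] = (1_100, 1_700)
    gap: int = 1_000
    flank: int = 18_000
    paralog: Optional[ParalogSpec] = field(default_factory=ParalogSpec)

    def __post_init__(self) -> None:
        if self.n_exons_up < 5 or self.n_exons_down < 2:
            raise ValueError("gene_up needs >=5 exons, gene_down >=2")
        if not 200 <= self.gap:
            raise ValueError("intergenic gap too small")


@dataclass
class LocusTruth:
    """Ground truth recorded at construction time."""

    dup_interval: tuple[int, int]
    dup_junction_seq: str
    fusion_junction_pos: dict[str, int]  # transcript coord of the RNA junction
    fusion_junction_exons: dict[str, tuple[int, int]]  # (gene_down exon#, gene_up exon#) 1-based
    rna_junction_seqs: dict[str, str]


@dataclass
class SimLocus:
    genome: Genome
    genes: dict[str, GeneModel]
    transcripts: dict[str, Transcript]  # annotated (wild-type) transcriptome
    fusion_transcripts: dict[str, Transcript]  # NOT in the annotation
    truth: LocusTruth
    spec: LocusSpec


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def build_locus(spec: LocusSpec | None = None, seed: int = 0) -> SimLocus:
    """Construct the toy locus, its annotation, fusion isoforms and truth.

    Gene order on the + strand is gene_up (the 3' fusion partner) then
    gene_down (the 5' partner); fusion transcripts join gene_down exon 2 to
    gene_up exon 3/4/5, an order inconsistent with canonical read-through
    transcription.
    """
    spec = spec or LocusSpec()
    rng = np.random.default_rng(seed)

    def gene_coords(offset: int, n_exons: int) -> tuple[list[tuple[int, int]], int]:
        pos = offset
        exons = []
        for i in range(n_exons):
            elen = int(rng.integers(*spec.exon_len_range))
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_exons - 1:
                pos += int(rng.integers(*spec.intron_len_range))
        return exons, pos

    up_exons, up_end = gene_coords(spec.flank, spec.n_exons_up)
    down_exons, down_end = gene_coords(up_end + spec.gap, spec.n_exons_down)
    total = down_end + spec.flank
    seq = _random_seq(rng, total)
    contigs = {spec.contig: seq}

    gene_up = GeneModel(spec.gene_up_id, spec.contig, "+", up_exons)
    gene_down = GeneModel(spec.gene_down_id, spec.contig, "+", down_exons)
    genes = {gene_up.gene_id: gene_up, gene_down.gene_id: gene_down}

    genome = Genome(contigs)
    transcripts = {
        f"{gene_up.gene_id}-wt": make_transcript(f"{gene_up.gene_id}-wt", gene_up, genome),
        f"{gene_down.gene_id}-wt": make_transcript(
            f"{gene_down.gene_id}-wt", gene_down, genome
        ),
    }

    # paralog of gene_down on its own contig, same exon structure
    if spec.paralog is not None:
        p = spec.paralog
        span = gene_down.end - gene_down.start
        body = _mutate(rng, seq[gene_down.start : gene_down.end], 1.0 - p.identity)
        pseq = _random_seq(rng, p.flank) + body + _random_seq(rng, p.flank)
        contigs[p.contig] = pseq
        genome = Genome(contigs)
        pexons = [
            (s - gene_down.start + p.flank, e - gene_down.start + p.flank)
            for s, e in gene_down.exons
        ]
        para_id = f"{gene_down.gene_id}PARA"
        gene_para = GeneModel(para_id, p.contig, "+", pexons)
        genes[para_id] = gene_para
        transcripts[f"{para_id}-wt"] = make_transcript(f"{para_id}-wt", gene_para, genome)

    # fusion isoforms: gene_down exons 1-2 followed by gene_up exon j..end
    down_tx_seq = transcripts[f"{gene_down.gene_id}-wt"].sequence
    up_lens = gene_up.exon_lengths()
    down_lens = gene_down.exon_lengths()
    prefix = down_tx_seq[: down_lens[0] + down_lens[1]]
    up_tx_seq = transcripts[f"{gene_up.gene_id}-wt"].sequence
    up_bounds = [0]
    for ln in up_lens:
        up_bounds.append(up_bounds[-1] + ln)

    fusion_transcripts: dict[str, Transcript] = {}
    junction_pos: dict[str, int] = {}
    junction_exons: dict[str, tuple[int, int]] = {}
    rna_junction_seqs: dict[str, str] = {}
    for j in (3, 4, 5):
        if j > gene_up.n_exons:
            continue
        tid = f"E2-C{j}"
        tail = up_tx_seq[up_bounds[j - 1] :]
        fseq = prefix + tail
        fusion_transcripts[tid] = Transcript(
            tid, f"{gene_down.gene_id}:{gene_up.gene_id}", [0, 1] + list(range(j - 1, gene_up.n_exons)), fseq
        )
        junction_pos[tid] = len(prefix)
        junction_exons[tid] = (2, j)
        rna_junction_seqs[tid] = prefix[-40:] + tail[:40]

    # default tandem duplication: gene_up intron 2 midpoint -> gene_down
    # intron 2 midpoint (covers gene_up exons 3..end and gene_down exons 1-2)
    s_mid = (up_exons[1][1] + up_exons[2][0]) // 2
    e_mid = (down_exons[1][1] + down_exons[2][0]) // 2
    dup = (s_mid, e_mid)
    dup_junction_seq = seq[e_mid - 80 : e_mid] + seq[s_mid : s_mid + 80]

    truth = LocusTruth(
        dup_interval=dup,
        dup_junction_seq=dup_junction_seq,
        fusion_junction_pos=junction_pos,
        fusion_junction_exons=junction_exons,
        rna_junction_seqs=rna_junction_seqs,
    )
    return SimLocus(genome, genes, transcripts, fusion_transcripts, truth, spec)


# ---------------------------------------------------------------------------
# RNA simulation
# ---------------------------------------------------------------------------

@dataclass
class RnaSimConfig:
    """Paired-end cDNA library model.

    ``isoform_weights`` are molar abundances; a fragment's isoform is drawn
    proportionally to weight x (isoform length - fragment length + 1), the
    number of valid placements, which makes the generator the exact sampling
    model assumed by the quantification EM.
    """

    isoform_weights: dict[str, float] = field(default_factory=dict)
    n_pairs: int = 50_000
    read_len_long: int = 76
    read_len_short: int = 38
    long_fraction: float = 0.27  # the study mixed ~30M 76 nt and ~80M 38 nt pairs
    frag_mean: float = 350.0
    frag_sd: float = 30.0
    error_rate: float = 0.005
    chimera_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.isoform_weights or all(w <= 0 for w in self.isoform_weights.values()):
            raise ValueError("isoform_weights must contain a positive weight")
        for name in ("long_fraction", "error_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    return _mutate(rng, seq, rate)


def simulate_rna(
    isoforms: dict[str, Transcript] | dict[str, str],
    config: RnaSimConfig,
    junction_pos: dict[str, int] | None = None,
    min_overlap: int = 10,
    sample_id: str = "rna_pool",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate an FR paired-end cDNA library with chimera artifacts.

    Returns the read pairs and a truth table labelling each pair
    {normal, chimera}, its source isoform(s), fragment coordinates, and —
    when ``junction_pos`` marks fusion junctions — whether each mate spans a
    junction with at least ``min_overlap`` nt on both sides.
    """
    seqs = {
        tid: (t.sequence if isinstance(t, Transcript) else t)
        for tid, t in isoforms.items()
    }
    junction_pos = junction_pos or {}
    rng = np.random.default_rng(config.seed)
    tids = sorted(config.isoform_weights)
    weights = np.array([config.isoform_weights[t] for t in tids], float)
    lens = np.array([len(seqs[t]) for t in tids], float)

    read_lens = np.where(
        rng.random(config.n_pairs) < config.long_fraction,
        config.read_len_long,
        config.read_len_short,
    )
    lo = float(read_lens.max())
    frag_lens = np.rint(
        _trunc_normal(rng, config.frag_mean, config.frag_sd, lo, config.frag_mean + 4 * config.frag_sd, config.n_pairs)
    ).astype(int)
    is_chimera = rng.random(config.n_pairs) < config.chimera_rate
    flip = rng.random(config.n_pairs) < 0.5

    pairs: list[ReadPair] = []
    rows = []
    n_resampled = 0

    def draw_fragment(fl: int) -> tuple[str, int]:
        """Pick (isoform, start) for a fragment of length fl."""
        eff = np.maximum(lens - fl + 1, 0.0)
        w = weights * eff
        tot = w.sum()
        if tot <= 0:
            raise ValueError("fragment longer than every weighted isoform")
        i = int(rng.choice(len(tids), p=w / tot))
        start = int(rng.integers(0, int(eff[i])))
        return tids[i], start

    for n in range(config.n_pairs):
        fl = int(frag_lens[n])
        L = int(read_lens[n])
        # resample fragments that fit nowhere at this length
        while np.all(np.maximum(lens - fl + 1, 0.0) * weights <= 0):
            n_resampled += 1
            fl = int(
                np.rint(
                    _trunc_normal(rng, config.frag_mean, config.frag_sd, lo, config.frag_mean + 4 * config.frag_sd, 1)
                )[0]
            )
        tid_a, start_a = draw_fragment(fl)
        frag_a = seqs[tid_a][start_a : start_a + fl]
        if is_chimera[n]:
            fl_b = int(frag_lens[n])
            tid_b, start_b = draw_fragment(fl_b)
            frag_b = seqs[tid_b][start_b : start_b + fl_b]
            fwd, rev = frag_a[:L], revcomp(frag_b[-L:])
            kind, tid2, start2 = "chimera", tid_b, start_b
            span_fwd = _spans(tid_a, start_a, start_a + L, junction_pos, min_overlap)
            span_rev = _spans(tid_b, start_b + fl_b - L, start_b + fl_b, junction_pos, min_overlap)
        else:
            fwd, rev = frag_a[:L], revcomp(frag_a[-L:])
            kind, tid2, start2 = "normal", tid_a, start_a
            span_fwd = _spans(tid_a, start_a, start_a + L, junction_pos, min_overlap)
            span_rev = _spans(tid_a, start_a + fl - L, start_a + fl, junction_pos, min_overlap)
        fwd = _apply_errors(rng, fwd, config.error_rate)
        rev = _apply_errors(rng, rev, config.error_rate)
        pid = f"rna{n:07d}"
        if flip[n]:
            pairs.append(ReadPair(pid, rev, fwd, sample_id))
            span1, span2 = span_rev, span_fwd
        else:
            pairs.append(ReadPair(pid, fwd, rev, sample_id))
            span1, span2 = span_fwd, span_rev
        rows.append(
            (
                pid,
                kind,
                tid_a,
                tid2,
                start_a,
                fl,
                L,
                bool(flip[n]),
                span1,
                span2,
            )
        )

    truth = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "kind",
            "isoform",
            "isoform2",
            "frag_start",
            "frag_len",
            "read_len",
            "flipped",
            "read1_junction",
            "read2_junction",
        ],
    )
    return pairs, truth


def _spans(
    tid: str, lo: int, hi: int, junction_pos: dict[str, int], min_overlap: int
) -> str:
    jp = junction_pos.get(tid)
    if jp is None:
        return ""
    if lo + min_overlap <= jp <= hi - min_overlap:
        return tid
    return ""


# ---------------------------------------------------------------------------
# DNA simulation
# ---------------------------------------------------------------------------

@dataclass
class CaptureBias:
    """Smooth positive coverage-bias function shared across samples.

    A mixture of Gaussian bumps over the locus, emulating capture-probe
    hybridization inhomogeneity.  Deterministic given (length, bias_seed), so
    tumor and normal libraries built over the same locus share it exactly.
    """

    n_bumps: int = 8
    amplitude: float = 2.0
    bias_seed: int = 1234

    def weights(self, length: int) -> np.ndarray:
        rng = np.random.default_rng(self.bias_seed)
        x = np.arange(length, dtype=float)
        w = np.ones(length)
        centers = rng.uniform(0, length, self.n_bumps)
        widths = rng.uniform(length / 40, length / 10, self.n_bumps)
        amps = rng.uniform(0.2, self.amplitude, self.n_bumps)
        for c, s, a in zip(centers, widths, amps):
            w += a * np.exp(-0.5 * ((x - c) / s) ** 2)
        return w


@dataclass
class DnaSimConfig:
    """Capture-enriched genomic paired-end library model."""

    contig: str = "chr11_toy"
    dup_interval: tuple[int, int] = (0, 0)
    dup_zygosity: str = "het"  # het | hom | none
    tumor_purity: float = 1.0
    capture_bias: CaptureBias = field(default_factory=CaptureBias)
    dup_rate_pcr: float = 0.10
    chimera_rate: float = 0.005
    n_pairs: int = 10_000
    read_len: int = 80
    frag_mean: float = 400.0
    frag_sd: float = 80.0
    frag_max: int = 780
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dup_zygosity not in ("het", "hom", "none"):
            raise ValueError("dup_zygosity must be het|hom|none")
        if not 0 < self.tumor_purity <= 1:
            raise ValueError("tumor_purity must be in (0,1]")
        if self.frag_max >= 1000:
            raise ValueError("frag_max must stay <1000 so true pairs are never anomalous")


def apply_tandem_duplication(seq: str, interval: tuple[int, int]) -> str:
    s, e = interval
    if not 0 <= s < e <= len(seq):
        raise ValueError("duplication interval exceeds contig")
    return seq[:e] + seq[s:e] + seq[e:]


def simulate_dna(
    genome: Genome,
    config: DnaSimConfig,
    role: str,
    sample_id: str | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate one capture-enriched genomic paired-end library.

    Two haplotypes are held per cell; for a ``het`` duplication in a tumor,
    one haplotype carries the tandem duplication.  Fragment starts are drawn
    proportionally to the shared capture bias; PCR duplicates are appended
    with identical coordinates at rate ``dup_rate_pcr``; ``chimera_rate`` of
    pairs join reads from two independent fragments (ligation artifacts).
    """
    if role not in ("tumor", "normal"):
        raise ValueError("role must be tumor or normal")
    sample_id = sample_id or role
    ref = genome[config.contig]
    s, e = config.dup_interval
    has_dup = role == "tumor" and config.dup_zygosity != "none" and e > s
    rng = np.random.default_rng(config.seed)
    L = config.read_len

    bias_ref = config.capture_bias.weights(len(ref))
    haps: list[str] = [ref, ref]
    hap_bias = [bias_ref, bias_ref]
    junction_hap_pos: Optional[int] = None
    if has_dup:
        dup_seq = apply_tandem_duplication(ref, (s, e))
        dup_bias = np.concatenate([bias_ref[:e], bias_ref[s:e], bias_ref[e:]])
        which = [1] if config.dup_zygosity == "het" else [0, 1]
        for h in which:
            haps[h] = dup_seq
            hap_bias[h] = dup_bias
        junction_hap_pos = e  # hap coordinate joining ref e-1 -> ref s

    # per-pair haplotype: tumor cells (purity) carry the event haplotype(s);
    # for het, half of tumor-cell fragments come from the duplicated haplotype
    if has_dup:
        p_hap1 = config.tumor_purity * (0.5 if config.dup_zygosity == "het" else 1.0)
    else:
        p_hap1 = 0.5  # the two haplotypes are identical; split evenly
    hap_choice = np.where(rng.random(config.n_pairs) < p_hap1, 1, 0)

    frag_lens = np.rint(
        _trunc_normal(
            rng, config.frag_mean, config.frag_sd, 2 * L, float(config.frag_max), config.n_pairs
        )
    ).astype(int)
    is_chimera = rng.random(config.n_pairs) < config.chimera_rate
    flip = rng.random(config.n_pairs) < 0.5

    # inverse-CDF sampling of fragment starts from the bias distribution
    cdfs = []
    for h in (0, 1):
        w = hap_bias[h]
        cdfs.append(np.cumsum(w) / w.sum())

    def draw_start(h: int, fl: int) -> int:
        cdf = cdfs[h]
        while True:
            pos = int(np.searchsorted(cdf, rng.random()))
            if pos + fl <= len(haps[h]):
                return pos

    pairs: list[ReadPair] = []
    rows = []
    for n in range(config.n_pairs):
        h = int(hap_choice[n])
        fl = int(frag_lens[n])
        start = draw_start(h, fl)
        hap = haps[h]
        fwd = hap[start : start + L]
        rev = revcomp(hap[start + fl - L : start + fl])
        kind = "normal"
        start2, h2 = start, h
        if is_chimera[n]:
            kind = "chimera"
            h2 = int(hap_choice[int(rng.integers(config.n_pairs))])
            fl2 = int(frag_lens[int(rng.integers(config.n_pairs))])
            start2 = draw_start(h2, fl2)
            rev = revcomp(haps[h2][start2 + fl2 - L : start2 + fl2])
        pid = f"{sample_id}_{n:07d}"
        spans = False
        if junction_hap_pos is not None and h == 1 and kind == "normal":
            j = junction_hap_pos
            spans = (start < j < start + L) or (start + fl - L < j < start + fl)
        if flip[n]:
            r1, r2 = rev, fwd
        else:
            r1, r2 = fwd, rev
        pairs.append(ReadPair(pid, r1, r2, sample_id))
        rows.append((pid, kind, h, start, fl, bool(flip[n]), spans, False, ""))
        # PCR duplicates: identical molecule re-sequenced
        d = 0
        while rng.random() < config.dup_rate_pcr:
            d += 1
            dpid = f"{pid}_dup{d}"
            pairs.append(ReadPair(dpid, r1, r2, sample_id))
            rows.append((dpid, kind, h, start, fl, bool(flip[n]), spans, True, pid))

    truth = pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "kind",
            "haplotype",
            "frag_start",
            "frag_len",
            "flipped",
            "spans_junction",
            "is_duplicate",
            "dup_of",
        ],
    )
    return pairs, truth
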