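"""End-to-end drivers wiring the DNA evidence arm together.

These are convenience compositions of the module-level operations —
simulate/load, align, deduplicate, pile-up test, copy number, orphan-end
assembly — used by the command-line interface, the test-suite and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import dna_pileup_cnv as dna
from . import orphan_assembly as oa
from .refalign import Genome, ReadPair, SeedIndex
from .synthetic_data import DnaSimConfig, SimLocus, simulate_dna


@dataclass
class DnaArmResult:
    placements_tumor: pd.DataFrame
    placements_normal: pd.DataFrame
    anomalous: list[dna.AnomalousPair]
    clusters: list[dna.PileupCluster]
    profile: pd.DataFrame
    call: dna.RearrangementCall
    contigs: list[oa.Contig]
    breakpoints: list[oa.BreakpointCandidate]


def run_dna_arm(
    genome: Genome,
    tumor_pairs: list[ReadPair],
    normal_pairs: list[ReadPair],
    contig: str,
    region: Optional[tuple[int, int]] = None,
    pileup_bin: int = 500,
    cn_bin: int = 100,
    fdr_level: float = 0.05,
    max_sep: int = 1_000,
    max_mismatch: int = 2,
    assemble_k: int = 31,
    min_coverage: int = 2,
    anchor: Optional[int] = None,
    radius: int = 20_000,
    window: int = 200,
) -> DnaArmResult:
    """Run the full DNA arm on in-memory tumor and matched-normal libraries."""
    seq = genome[contig]
    lo, hi = region if region is not None else (0, len(seq))
    index = SeedIndex(genome.contigs)

    pt = dna.dedup_pairs(dna.align_pairs_to_genome(tumor_pairs, index, max_mismatch))
    pn = dna.dedup_pairs(dna.align_pairs_to_genome(normal_pairs, index, max_mismatch))

    anoms = dna.flag_anomalous(pt, max_sep)
    read_len = len(tumor_pairs[0].seq1) if tumor_pairs else 80
    clusters = dna.pileup_test(
        anoms, pt, (contig, lo, hi), pileup_bin, fdr_level, read_len
    )
    profile = dna.copy_number_profile(pt, pn, (contig, lo, hi), cn_bin)
    call = dna.fit_duplication_model(clusters, profile, cn_bin)

    # orphan-end assembly around the anchor (cluster midpoint if not given)
    if anchor is None:
        if clusters:
            anchor = (clusters[0].minus_mode + clusters[0].plus_end) // 2
        else:
            anchor = (lo + hi) // 2
    orphans = oa.collect_orphans(tumor_pairs, pt, contig, anchor, radius, window)
    all_orphans = [s for v in orphans.windows.values() for s in v]
    contigs: list[oa.Contig] = []
    breakpoints: list[oa.BreakpointCandidate] = []
    if all_orphans and any(len(s) >= assemble_k for s in all_orphans):
        contigs = oa.assemble(
            all_orphans, k=assemble_k, min_coverage=min_coverage, sample_id="tumor"
        )
        contigs = [c for c in contigs if len(c.sequence) >= 80]
        if contigs:
            matcher = oa.ExactMatcher(genome, 80)
            contigs = [oa.tile_and_screen(c, matcher) for c in contigs]
            breakpoints = oa.nominate_breakpoint(contigs, genome, anchor_len=assemble_k)
    return DnaArmResult(pt, pn, anoms, clusters, profile, call, contigs, breakpoints)


def simulate_and_run_dna_arm(
    locus: SimLocus,
    n_pairs: int = 12_000,
    seed: int = 0,
    dup_zygosity: str = "het",
    **kwargs,
) -> tuple[DnaArmResult, DnaSimConfig]:
    """Simulate a tumor/normal pair over a built locus and run the DNA arm."""
    cfg = DnaSimConfig(
        contig=locus.spec.contig,
        dup_interval=locus.truth.dup_interval,
        dup_zygosity=dup_zygosity,
        n_pairs=n_pairs,
        seed=seed,
    )
    tumor, _ = simulate_dna(locus.genome, cfg, "tumor")
    normal_cfg = DnaSimConfig(**{**cfg.__dict__, "seed": seed + 500_000})
    normal, _ = simulate_dna(locus.genome, normal_cfg, "normal")
    result = run_dna_arm(
        locus.genome,
        tumor,
        normal,
        locus.spec.contig,
        **kwargs,
    )
    return result, cfg
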