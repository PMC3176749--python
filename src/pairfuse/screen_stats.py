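"""Cohort screening statistics and report generation.

A sample is called fusion-positive only when a strict majority of its
technical replicates detect a fusion product; prevalence over the cohort is
reported with an exact (Clopper-Pearson) binomial confidence interval,
pooled across collection sites.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger("pairfuse")


@dataclass
class ScreenRecord:
    sample_id: str
    site: str
    replicates: list[bool]
    isoforms: set[str] = field(default_factory=set)

    @property
    def positive(self) -> bool:
        return call_positive(self.replicates)


@dataclass
class PrevalenceEstimate:
    positives: int
    total: int
    conf: float
    ci: tuple[float, float]
    per_site: dict[str, tuple[int, int]]

    @property
    def proportion(self) -> float:
        return self.positives / self.total


def call_positive(replicates: Sequence[bool]) -> bool:
    """Strict majority rule: positive iff more than half of the technical
    replicates are positive (ties are negative)."""
    if not replicates:
        raise ValueError("at least one replicate required")
    return sum(bool(r) for r in replicates) * 2 > len(replicates)


def exact_binomial_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval for x successes in
    n trials."""
    if n < 1 or not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n, n >= 1")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def prevalence(records: Iterable[ScreenRecord], conf: float = 0.95) -> PrevalenceEstimate:
    """Pooled prevalence across sites with the exact CI; per-site counts are
    preserved.  Duplicate sample ids are an integrity error."""
    records = list(records)
    if not records:
        raise ValueError("no screen records")
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in screen records")
    per_site: dict[str, tuple[int, int]] = {}
    x = 0
    for r in records:
        pos, tot = per_site.get(r.site, (0, 0))
        p = r.positive
        per_site[r.site] = (pos + int(p), tot + 1)
        x += int(p)
    n = len(records)
    return PrevalenceEstimate(x, n, conf, exact_binomial_ci(x, n, conf), per_site)


def read_screen_tsv(path) -> list[ScreenRecord]:
    """TSV columns: sample_id, site, replicates (e.g. "+,+,-"), isoforms."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        reps = [tok in ("+", "1", "T", "true", "True") for tok in str(row.replicates).split(",")]
        iso = set()
        if hasattr(row, "isoforms") and isinstance(row.isoforms, str):
            iso = {t for t in row.isoforms.split(",") if t}
        out.append(ScreenRecord(row.sample_id, row.site, reps, iso))
    return out


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def _verdict(has_rna: bool, has_dna_breakpoint: bool, has_cnv: bool) -> str:
    if has_rna and has_dna_breakpoint:
        return "rearrangement-supported fusion"
    if has_rna and has_cnv:
        return "fusion transcript with copy-number support"
    if has_rna:
        return "unconfirmed fusion transcript"
    if has_dna_breakpoint or has_cnv:
        return "rearrangement without detected fusion transcript"
    return "no evidence"


def report(
    rna_table: Optional[pd.DataFrame] = None,
    cn_profile: Optional[pd.DataFrame] = None,
    rearrangement: Optional[object] = None,
    breakpoints: Optional[list] = None,
    prevalence_estimate: Optional[PrevalenceEstimate] = None,
    out_markdown=None,
    out_json=None,
) -> tuple[str, dict]:
    """Assemble a deterministic markdown report and machine-readable summary
    reconciling the RNA and DNA evidence arms."""
    if all(
        x is None
        for x in (rna_table, cn_profile, rearrangement, breakpoints, prevalence_estimate)
    ):
        raise ValueError("report needs at least one arm's outputs")

    has_rna = rna_table is not None and len(rna_table) > 0
    has_bp = bool(breakpoints) or (
        rearrangement is not None
        and getattr(rearrangement, "call_type", "") == "tandem_duplication"
    )
    has_cnv = rearrangement is not None and (
        getattr(rearrangement, "call_type", "") in ("tandem_duplication", "unresolved")
    )
    verdict = _verdict(has_rna, has_bp, has_cnv)

    lines = ["# pairfuse report", "", f"**Verdict:** {verdict}", ""]
    summary: dict = {"verdict": verdict}
    if has_rna:
        top = rna_table.iloc[0]
        lines += [
            "## Fusion transcript candidates",
            "",
            rna_table.to_markdown(index=False),
            "",
        ]
        summary["top_candidate"] = {
            "gene5": top.gene5,
            "gene3": top.gene3,
            "total_count": int(top.total_count),
            "q_value": float(top.q_value),
        }
    if rearrangement is not None:
        lines += [
            "## Genomic rearrangement",
            "",
            f"call: {rearrangement.call_type}",
        ]
        summary["rearrangement"] = {"call_type": rearrangement.call_type}
        if getattr(rearrangement, "interval", None):
            iv = rearrangement.interval
            lines.append(
                f"interval: {iv[0] + 1:,}-{iv[1]:,} (1-based inclusive); "
                f"interior/exterior copy-number ratio "
                f"{rearrangement.ratio:.2f}"
            )
            summary["rearrangement"].update(
                {"interval": list(iv), "ratio": float(rearrangement.ratio)}
            )
        lines.append("")
    if breakpoints:
        lines += ["## Assembled breakpoints", ""]
        for bp in breakpoints:
            lines.append(
                f"- {bp.ref_contig}: join {bp.end:,} -> {bp.start:,} "
                f"({bp.orientation}, support {bp.support})"
            )
        lines.append("")
        summary["breakpoints"] = [
            {"contig": bp.ref_contig, "end": int(bp.end), "start": int(bp.start)}
            for bp in breakpoints
        ]
    if prevalence_estimate is not None:
        pe = prevalence_estimate
        lines += [
            "## Cohort prevalence",
            "",
            f"{pe.positives} of {pe.total} positive: {round(100 * pe.proportion)}% "
            f"(exact binomial {int(100 * pe.conf)}% CI: "
            f"{round(100 * pe.ci[0])}% to {round(100 * pe.ci[1])}%)",
            "",
        ]
        summary["prevalence"] = {
            "positives": pe.positives,
            "total": pe.total,
            "proportion": pe.proportion,
            "ci": list(pe.ci),
            "per_site": {k: list(v) for k, v in pe.per_site.items()},
        }
    md = "\n".join(lines)
    if out_markdown:
        with open(out_markdown, "w") as fh:
            fh.write(md)
    if out_json:
        with open(out_json, "w") as fh:
            json.dump(summary, fh, indent=2)
    return md, summary
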