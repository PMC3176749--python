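"""Independent oracles used by the test-suite.

These deliberately avoid the package's own search machinery: brute-force
scans and closed-form enumerations that the implementations are checked
against.
"""

from __future__ import annotations

from pairfuse.refalign import revcomp


def brute_force_placements(
    read: str, targets: dict[str, str], max_mismatch: int
) -> set[tuple[str, int, str, int]]:
    """All-positions, both-strand scan counting substitutions directly.

    N never matches any base (including N).
    """
    out = set()
    for strand, query in (("+", read), ("-", revcomp(read))):
        L = len(query)
        for tid, seq in targets.items():
            for start in range(len(seq) - L + 1):
                mm = 0
                for a, b in zip(query, seq[start : start + L]):
                    if a != b or a == "N" or b == "N":
                        mm += 1
                        if mm > max_mismatch:
                            break
                else:
                    out.add((tid, start, strand, mm))
    return out


def expected_junction_count(n_a: int, n_b: int) -> int:
    """Ordered-pair enumeration: cross junctions in both directions plus all
    within-gene ordered pairs i<j."""
    cross = 2 * n_a * n_b
    within = n_a * (n_a - 1) // 2 + n_b * (n_b - 1) // 2
    return cross + within
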