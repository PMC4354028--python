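"""Independent brute-force oracles used by the tests.

Deliberately naive: pure-Python min/max scans per CpG, no vectorisation,
no reuse of the package's margin code beyond the MarkerCandidate container.
"""

from __future__ import annotations


def brute_margin(g1: list[float], g2: list[float]) -> tuple[float, str, float | None]:
    """(margin, direction, cutoff) by direct enumeration of both directions."""
    m_hypo = min(g2) - max(g1)
    m_hyper = min(g1) - max(g2)
    if m_hypo >= m_hyper:
        cutoff = (max(g1) + min(g2)) / 2.0
        return m_hypo, "hypo_in_group1", (cutoff if m_hypo > 0 else None)
    cutoff = (min(g1) + max(g2)) / 2.0
    return m_hyper, "hyper_in_group1", (cutoff if m_hyper > 0 else None)


def brute_rank(matrix, annotations, group1="pluripotent", group2="somatic"):
    """Per-CpG margins sorted by (-margin, cpg_id), computed row by row."""
    ids1 = [a.sample_id for a in annotations if a.label == group1]
    ids2 = [a.sample_id for a in annotations if a.label == group2]
    out = []
    for cpg in matrix.cpg_ids:
        row = matrix.row(cpg)
        g1 = [float(row[s]) for s in ids1]
        g2 = [float(row[s]) for s in ids2]
        margin, direction, cutoff = brute_margin(g1, g2)
        out.append((cpg, margin, direction, cutoff))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
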