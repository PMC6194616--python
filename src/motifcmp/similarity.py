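"""Pairwise motif similarity by exhaustive ungapped alignment.

Two PWMs are superposed at every relative offset, on both strands, and the
similarity of each candidate superposition is the mean per-column
similarity over the overlapping window, expressed as a percentage.  The
column metric is ``1 - SSD/2`` where SSD is the sum of squared
probability differences: 1 for identical columns, 0 for disjoint point
masses.  This metric is bounded, defined for zero-variance (uniform)
columns, and maps directly onto a 0-100% similarity cutoff scale.

A minimum-overlap floor (default ``min(4, widths)``) prevents spurious
perfect matches on one-column superpositions.  Ties between equally
scoring superpositions are broken deterministically: larger overlap, then
forward strand, then smaller absolute offset, then the negative offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .motif_io import Motif, PWM, to_pwm

ColumnMetric = Callable[[Sequence[float], Sequence[float]], float]


def reverse_complement(pwm: PWM) -> PWM:
    """Reverse the column order and complement each column (A<->T, C<->G).

    With the alphabet fixed to A,C,G,T the complement is a reversal of the
    base axis, so the whole operation is ``probs[::-1, ::-1]``.  The
    operation is an involution.
    """
    return PWM(pwm.probs[::-1, ::-1].copy(), pseudocount=pwm.pseudocount)


def column_similarity(col_a: Sequence[float], col_b: Sequence[float]) -> float:
    """Similarity of two stochastic columns: 1 - (sum squared diff) / 2.

    Equals 1 iff the columns are identical and 0 iff they are point masses
    on different bases (SSD = 2, the maximum for stochastic vectors).
    """
    ssd = 0.0
    for a, b in zip(col_a, col_b):
        d = a - b
        ssd += d * d
    return 1.0 - ssd / 2.0


@dataclass(frozen=True)
class AlignmentResult:
    """Best ungapped superposition of motif B onto motif A.

    ``offset`` is the start of B relative to the start of A after orienting
    B to the reported strand (i.e. for ``strand == "reverse"`` the offset
    refers to the reverse complement of B).
    """

    offset: int
    strand: str  # "forward" | "reverse"
    overlap: int
    score_percent: float


@dataclass(frozen=True)
class MotifMatch:
    query_id: str
    query_tool: str
    target_id: str
    target_tool: str
    alignment: AlignmentResult


def align(
    pwm_a: PWM,
    pwm_b: PWM,
    min_overlap: int | None = None,
    metric: ColumnMetric = column_similarity,
) -> AlignmentResult:
    """Exhaustively align two PWMs over all offsets and both strands.

    Every offset with at least ``min_overlap`` overlapping columns is
    scored as ``100 * mean(metric(column pairs))`` and the maximum is
    returned under the deterministic tie-breaking chain described in the
    module docstring.
    """
    wa, wb = pwm_a.width, pwm_b.width
    if min_overlap is None:
        min_overlap = min(4, wa, wb)
    min_overlap = max(1, min(min_overlap, wa, wb))

    a_cols = pwm_a.probs.tolist()
    candidates = (
        ("forward", pwm_b.probs.tolist()),
        ("reverse", reverse_complement(pwm_b).probs.tolist()),
    )

    best: AlignmentResult | None = None
    best_key: tuple | None = None
    for strand, b_cols in candidates:
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo = max(0, offset)
            hi = min(wa, offset + wb)
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            total = 0.0
            for j in range(lo, hi):
                total += metric(a_cols[j], b_cols[j - offset])
            score = 100.0 * (total / overlap)
            key = (
                score,
                overlap,
                1 if strand == "forward" else 0,
                -abs(offset),
                1 if offset < 0 else 0,
            )
            if best_key is None or key > best_key:
                best_key = key
                best = AlignmentResult(offset, strand, overlap, score)
    assert best is not None  # min_overlap <= min width guarantees a candidate
    return best


def align_motifs(
    a: Motif,
    b: Motif,
    min_overlap: int | None = None,
    pseudocount: float = 0.25,
    metric: ColumnMetric = column_similarity,
) -> AlignmentResult:
    """Align two count motifs after PWM conversion with a pseudocount."""
    return align(
        to_pwm(a, pseudocount), to_pwm(b, pseudocount), min_overlap, metric
    )


def best_matches(
    query: Motif,
    collection: Sequence[Motif],
    k: int = 5,
    min_overlap: int | None = None,
    pseudocount: float = 0.25,
) -> list[MotifMatch]:
    """Rank a collection by alignment score against a query motif.

    Returns the ``k`` highest-scoring matches in non-increasing score
    order; ties are broken by (tool label, motif id) lexicographically so
    rankings are reproducible.  An empty collection yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    qp = to_pwm(query, pseudocount)
    scored = [
        MotifMatch(
            query_id=query.id,
            query_tool=query.tool,
            target_id=t.id,
            target_tool=t.tool,
            alignment=align(qp, to_pwm(t, pseudocount), min_overlap),
        )
        for t in collection
    ]
    scored.sort(
        key=lambda m: (-m.alignment.score_percent, m.target_tool, m.target_id)
    )
    return scored[:k]


def matches_to_rows(matches: Sequence[MotifMatch]) -> list[dict]:
    """Flatten matches to TSV-ready records (rank is 1-based)."""
    return [
        {
            "query_id": m.query_id,
            "query_tool": m.query_tool,
            "rank": i + 1,
            "target_id": m.target_id,
            "target_tool": m.target_tool,
            "score_percent": m.alignment.score_percent,
            "strand": m.alignment.strand,
            "offset": m.alignment.offset,
            "overlap": m.alignment.overlap,
        }
        for i, m in enumerate(matches)
    ]
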