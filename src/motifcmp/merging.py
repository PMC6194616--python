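"""Redundancy reduction by fusing similar motifs.

Two motifs are fused by superposing them at their best alignment (reverse
complementing the second when the best alignment is on the reverse
strand) and summing base *counts* column-wise over the union span, so
that motifs backed by more sites dominate the fusion.  A fusion is
accepted only when the merged motif still aligns to *both* parents at or
above the similarity threshold — the acceptance guard that keeps merging
from drifting away from the motifs it replaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .motif_io import Motif, to_pwm
from .similarity import align


@dataclass
class MergeOutcome:
    accepted: bool
    merged: Motif | None
    parent_ids: tuple[str, str]
    scores_vs_parents: tuple[float, float]


@dataclass
class MergeLogEntry:
    """One attempted fusion, for the merge audit log."""

    id_a: str
    id_b: str
    pair_score: float
    score_vs_a: float
    score_vs_b: float
    accepted: bool


def merge_pair(
    a: Motif,
    b: Motif,
    threshold_percent: float = 75.0,
    pseudocount: float = 0.25,
    min_overlap: int | None = None,
) -> MergeOutcome:
    """Fuse two motifs at their best alignment; accept only if the product
    stays within the similarity threshold of both parents.

    The merged width is the union span of the aligned windows; overlapped
    columns sum both parents' counts, flanking columns carry the single
    covering parent's counts.  Merged nsites is the parents' sum and the
    merged motif carries no significance of its own.
    """
    res = align(to_pwm(a, pseudocount), to_pwm(b, pseudocount), min_overlap)
    b_counts = b.counts
    if res.strand == "reverse":
        b_counts = b_counts[::-1, ::-1]
    wa, wb = a.width, b.width
    start = min(0, res.offset)
    width = max(wa, res.offset + wb) - start
    merged_counts = np.zeros((width, 4))
    merged_counts[-start : -start + wa] += a.counts
    merged_counts[res.offset - start : res.offset - start + wb] += b_counts
    merged = Motif(
        id=f"merge({a.id},{b.id})",
        counts=merged_counts,
        tool="merged",
        nsites=a.nsites + b.nsites,
        significance_kind="none",
    )
    mp = to_pwm(merged, pseudocount)
    score_a = align(mp, to_pwm(a, pseudocount), min_overlap).score_percent
    score_b = align(mp, to_pwm(b, pseudocount), min_overlap).score_percent
    accepted = score_a >= threshold_percent and score_b >= threshold_percent
    return MergeOutcome(
        accepted=accepted,
        merged=merged if accepted else None,
        parent_ids=(a.id, b.id),
        scores_vs_parents=(score_a, score_b),
    )


def merge_collection(
    motifs: Sequence[Motif],
    threshold_percent: float = 75.0,
    pseudocount: float = 0.25,
    min_overlap: int | None = None,
    log: list[MergeLogEntry] | None = None,
) -> list[Motif]:
    """Greedy best-pair-first agglomeration of a motif collection.

    Repeatedly aligns all current pairs, attempts to fuse the
    highest-scoring pair at or above the threshold, replaces the pair with
    the fusion on acceptance (the fusion takes the earlier parent's
    position) and marks the pair ineligible on rejection; stops when no
    eligible pair remains.  Rejected pairs are not retried after unrelated
    merges, which bounds the work.  Output preserves first-appearance
    order; fused motifs are named ``merge(idA,idB)``.
    """
    if not motifs:
        raise ValueError("merge_collection requires a non-empty motif list")
    # slots keep first-appearance order; identity is positional, so motifs
    # with equal ids from different tools are still distinct
    slots: list[Motif | None] = list(motifs)
    ineligible: set[frozenset[int]] = set()

    def pair_score(i: int, j: int) -> float:
        return align(
            to_pwm(slots[i], pseudocount),
            to_pwm(slots[j], pseudocount),
            min_overlap,
        ).score_percent

    while True:
        live = [i for i, m in enumerate(slots) if m is not None]
        best_pair = None
        best_score = -1.0
        for x in range(len(live)):
            for y in range(x + 1, len(live)):
                i, j = live[x], live[y]
                if frozenset((i, j)) in ineligible:
                    continue
                s = pair_score(i, j)
                if s > best_score:
                    best_score = s
                    best_pair = (i, j)
        if best_pair is None or best_score < threshold_percent:
            break
        i, j = best_pair
        outcome = merge_pair(
            slots[i], slots[j], threshold_percent, pseudocount, min_overlap
        )
        if log is not None:
            log.append(
                MergeLogEntry(
                    id_a=slots[i].id,
                    id_b=slots[j].id,
                    pair_score=best_score,
                    score_vs_a=outcome.scores_vs_parents[0],
                    score_vs_b=outcome.scores_vs_parents[1],
                    accepted=outcome.accepted,
                )
            )
        if outcome.accepted:
            slots[i] = outcome.merged
            slots[j] = None
        else:
            ineligible.add(frozenset((i, j)))
    return [m for m in slots if m is not None]
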