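"""Cross-tool aggregation of significant motifs.

Given the significant motifs from two or more de novo motif finders, this
module derives the three headline comparison products:

* **global (common) significant motifs** — motifs for which every other
  tool reports a counterpart above the similarity cutoff;
* **local significant motifs** — motifs significant within one tool's
  output but lacking a qualifying match across the others;
* **best common motif** — one representative group, selected first by the
  number of supporting tools (popular vote) and then by the highest mean
  similarity of its members to the anchor.

The default cutoff of 75% mirrors the similarity threshold conventionally
used to call two motifs "the same".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .motif_io import Motif
from .similarity import align, to_pwm


@dataclass
class ComparisonConfig:
    """Knobs of a comparison run.

    cutoff_percent : similarity (0-100) above which two motifs are
        counterparts; default 75.
    top_n : how many top significant motifs per tool enter the comparison.
    k_best_matches : matches reported per query in best-match tables.
    require_all_tools : when True (default) a global motif needs a
        counterpart in *every* other tool; when False a majority
        (>= half of the tools, anchor included) suffices.
    pseudocount : added to counts before PWM conversion.
    """

    cutoff_percent: float = 75.0
    top_n: int = 10
    k_best_matches: int = 5
    require_all_tools: bool = True
    min_overlap: int | None = None
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff_percent <= 100.0:
            raise ValueError("cutoff_percent must be in [0, 100]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.k_best_matches < 1:
            raise ValueError("k_best_matches must be >= 1")


@dataclass
class GlobalGroup:
    """A motif found by multiple tools: an anchor plus its best counterpart
    per tool, each with its similarity to the anchor (anchor's own tool is
    included at 100)."""

    anchor: Motif
    members: dict[str, tuple[Motif, float]]

    @property
    def support(self) -> int:
        return len(self.members)

    def mean_member_score(self) -> float:
        """Mean similarity of the non-anchor members to the anchor."""
        scores = [
            s for tool, (m, s) in self.members.items() if tool != self.anchor.tool
        ]
        return sum(scores) / len(scores) if scores else 100.0

    def member_key(self) -> frozenset:
        return frozenset((tool, m.id) for tool, (m, _) in self.members.items())


@dataclass
class EnsembleReport:
    global_groups: list[GlobalGroup]
    local_by_tool: dict[str, list[Motif]]
    best_common: GlobalGroup | None
    cutoff_percent: float = 75.0


def top_n(motifs: Sequence[Motif], n: int) -> list[Motif]:
    """First ``n`` motifs after ranking by significance.

    Motifs with p- or e-values are ordered ascending (most significant
    first); motifs with a tool-native score or no significance retain their
    input order, after the p/e-ranked ones.  The sort is stable for ties.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        motifs,
        key=lambda m: (
            m.significance_value
            if m.significance_kind in ("p_value", "e_value")
            else float("inf")
        ),
    )
    return ranked[:n]


def _best_counterpart(
    anchor: Motif,
    others: Sequence[Motif],
    config: ComparisonConfig,
) -> tuple[Motif, float] | None:
    """Highest-scoring motif of another tool against the anchor, or None."""
    best = None
    best_score = -1.0
    ap = to_pwm(anchor, config.pseudocount)
    for m in others:
        res = align(ap, to_pwm(m, config.pseudocount), config.min_overlap)
        if res.score_percent > best_score:
            best_score = res.score_percent
            best = m
    if best is None:
        return None
    return best, best_score


def find_global_significant(
    tool_lists: Mapping[str, Sequence[Motif]],
    config: ComparisonConfig | None = None,
) -> list[GlobalGroup]:
    """Groups of motifs shared across tools.

    A motif is an anchor iff, for every other tool (or a majority when
    ``require_all_tools`` is off), that tool's best-scoring motif against
    it reaches the cutoff.  Groups are emitted in anchor tool-label order
    then anchor list rank; groups with identical member sets are collapsed,
    keeping the first.
    """
    config = config or ComparisonConfig()
    if len(tool_lists) < 2:
        raise ValueError("comparison requires motifs from at least two tools")
    tools = sorted(tool_lists)
    n_tools = len(tools)
    groups: list[GlobalGroup] = []
    seen: set[frozenset] = set()
    for tool in tools:
        for anchor in tool_lists[tool]:
            members: dict[str, tuple[Motif, float]] = {tool: (anchor, 100.0)}
            qualified = True
            for other in tools:
                if other == tool:
                    continue
                hit = _best_counterpart(anchor, tool_lists[other], config)
                if hit is not None and hit[1] >= config.cutoff_percent:
                    members[other] = hit
                elif config.require_all_tools:
                    qualified = False
                    break
            if config.require_all_tools:
                ok = qualified
            else:
                ok = len(members) >= n_tools / 2 and len(members) >= 2
            if ok:
                group = GlobalGroup(anchor=anchor, members=members)
                key = group.member_key()
                if key not in seen:
                    seen.add(key)
                    groups.append(group)
    return groups


def find_local_significant(
    tool_lists: Mapping[str, Sequence[Motif]],
    groups: Sequence[GlobalGroup],
) -> dict[str, list[Motif]]:
    """Per tool, the significant motifs absent from every global group,
    in their original rank order."""
    grouped: set[tuple[str, str]] = set()
    for g in groups:
        for tool, (m, _) in g.members.items():
            grouped.add((tool, m.id))
    return {
        tool: [m for m in motifs if (tool, m.id) not in grouped]
        for tool, motifs in tool_lists.items()
    }


def select_best_common(groups: Sequence[GlobalGroup]) -> GlobalGroup | None:
    """The best-supported group: majority of tools first, then the highest
    mean member similarity, then the anchor id for determinism."""
    if not groups:
        return None
    return min(
        groups,
        key=lambda g: (-g.support, -g.mean_member_score(), g.anchor.id),
    )


def build_report(
    tool_lists: Mapping[str, Sequence[Motif]],
    config: ComparisonConfig | None = None,
) -> EnsembleReport:
    """Run the full comparison: global groups, locals, best common motif."""
    config = config or ComparisonConfig()
    groups = find_global_significant(tool_lists, config)
    locals_ = find_local_significant(tool_lists, groups)
    return EnsembleReport(
        global_groups=groups,
        local_by_tool=locals_,
        best_common=select_best_common(groups),
        cutoff_percent=config.cutoff_percent,
    )
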