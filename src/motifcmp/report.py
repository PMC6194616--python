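"""Serialization of comparison results to report artifacts."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .ensemble import EnsembleReport, GlobalGroup
from .motif_io import Motif, write_meme_minimal
from .similarity import MotifMatch, matches_to_rows


def global_groups_tsv(groups: Sequence[GlobalGroup], path: str | Path) -> None:
    lines = ["group\tanchor_id\tanchor_tool\tsupport\ttool\tmember_id\tscore_percent"]
    for gi, g in enumerate(groups, 1):
        for tool in sorted(g.members):
            m, s = g.members[tool]
            lines.append(
                f"{gi}\t{g.anchor.id}\t{g.anchor.tool}\t{g.support}\t"
                f"{tool}\t{m.id}\t{s:.4f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def locals_tsv(local_by_tool: Mapping[str, Sequence[Motif]], path: str | Path) -> None:
    lines = ["tool\tmotif_id\tsignificance_kind\tsignificance_value\tconsensus"]
    for tool in sorted(local_by_tool):
        for m in local_by_tool[tool]:
            sig = "" if m.significance_value is None else f"{m.significance_value:g}"
            lines.append(
                f"{tool}\t{m.id}\t{m.significance_kind}\t{sig}\t{m.consensus()}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def best_matches_tsv(
    matches_by_query: Mapping[str, Sequence[MotifMatch]], path: str | Path
) -> None:
    header = (
        "query_id\tquery_tool\trank\ttarget_id\ttarget_tool\t"
        "score_percent\tstrand\toffset\toverlap"
    )
    lines = [header]
    for _qid, matches in matches_by_query.items():
        for row in matches_to_rows(matches):
            lines.append(
                "\t".join(
                    [
                        row["query_id"],
                        row["query_tool"],
                        str(row["rank"]),
                        row["target_id"],
                        row["target_tool"],
                        f"{row['score_percent']:.4f}",
                        row["strand"],
                        str(row["offset"]),
                        str(row["overlap"]),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def anchors_meme(groups: Sequence[GlobalGroup], path: str | Path) -> None:
    write_meme_minimal([g.anchor for g in groups], path)


def text_report(report: EnsembleReport) -> str:
    """Human-readable summary of the three comparison categories."""
    lines = [
        "Motif comparison report",
        f"similarity cutoff: {report.cutoff_percent:.1f}%",
        "",
        f"Global (common) significant motifs: {len(report.global_groups)}",
    ]
    for gi, g in enumerate(report.global_groups, 1):
        lines.append(
            f"  group {gi}: anchor {g.anchor.id} [{g.anchor.tool}], "
            f"support {g.support} tools"
        )
        for tool in sorted(g.members):
            m, s = g.members[tool]
            lines.append(f"    {tool}: {m.id} ({s:.1f}%) {m.consensus()}")
    lines.append("")
    lines.append("Local significant motifs (tool-specific):")
    for tool in sorted(report.local_by_tool):
        ids = ", ".join(m.id for m in report.local_by_tool[tool]) or "(none)"
        lines.append(f"  {tool}: {ids}")
    lines.append("")
    if report.best_common is not None:
        bc = report.best_common
        lines.append(
            f"Best common motif: {bc.anchor.id} [{bc.anchor.tool}], "
            f"support {bc.support}, mean member similarity "
            f"{bc.mean_member_score():.1f}%"
        )
    else:
        lines.append("Best common motif: none (no global group)")
    return "\n".join(lines) + "\n"
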