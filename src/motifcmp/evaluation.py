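"""Binding-site prediction accuracy at nucleotide and site level.

Predicted binding sites are scored against known (implanted) sites with
six statistics.  At the nucleotide level, every position of every
sequence is classified as TP/FP/TN/FN against the position-wise union of
each site set, yielding

    nSn  = TP / (TP + FN)            sensitivity
    nPPV = TP / (TP + FP)            positive predictive value
    nSp  = TN / (TN + FP)            specificity
    nCC  = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))
                                      correlation coefficient (Matthews)

At the site level, a known site counts as found when some predicted site
on the same sequence overlaps it by at least a fraction of its length
(default 0.25, at least 1 bp); predicted sites are scored symmetrically:

    sSn  = known sites found / known sites
    sPPV = predicted sites confirmed / predicted sites

Statistics whose denominator is zero are flagged undefined (``None``) and
skipped when averaging across datasets, mirroring how tools that report
no motif are handled in multi-dataset summaries.

Coordinates are 0-based half-open internally (BED convention); strand is
recorded but ignored in overlap computations, since implanted-site ground
truth is positional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

STAT_NAMES = ("nSn", "nPPV", "nSp", "nCC", "sSn", "sPPV")


@dataclass(frozen=True)
class BindingSite:
    """An interval on a named sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "."  # "+", "-", "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid site {self.seq_id}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConfusionCounts:
    """Nucleotide-level confusion plus site-level hit tallies."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0
    site_known_hit: int = 0
    site_known_total: int = 0
    site_pred_hit: int = 0
    site_pred_total: int = 0


@dataclass
class EvaluationResult:
    """The six accuracy statistics; ``None`` marks an undefined value."""

    nSn: float | None = None
    nPPV: float | None = None
    nSp: float | None = None
    nCC: float | None = None
    sSn: float | None = None
    sPPV: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in STAT_NAMES}


def _validate_sites(
    sites: Sequence[BindingSite], seq_lengths: Mapping[str, int], label: str
) -> None:
    for s in sites:
        if s.seq_id not in seq_lengths:
            raise ValueError(f"{label} site on unknown sequence {s.seq_id!r}")
        if s.end > seq_lengths[s.seq_id]:
            raise ValueError(
                f"{label} site {s.seq_id}:{s.start}-{s.end} exceeds sequence "
                f"length {seq_lengths[s.seq_id]}"
            )


def nucleotide_confusion(
    known: Sequence[BindingSite],
    predicted: Sequence[BindingSite],
    seq_lengths: Mapping[str, int],
) -> ConfusionCounts:
    """Position-wise TP/FP/TN/FN over all sequences.

    Overlapping sites of the same class are unioned first, so a position
    covered twice by known sites is one known position.
    """
    _validate_sites(known, seq_lengths, "known")
    _validate_sites(predicted, seq_lengths, "predicted")
    counts = ConfusionCounts()
    for seq_id, length in seq_lengths.items():
        k = np.zeros(length, dtype=bool)
        p = np.zeros(length, dtype=bool)
        for s in known:
            if s.seq_id == seq_id:
                k[s.start : s.end] = True
        for s in predicted:
            if s.seq_id == seq_id:
                p[s.start : s.end] = True
        counts.TP += int(np.sum(k & p))
        counts.FP += int(np.sum(~k & p))
        counts.FN += int(np.sum(k & ~p))
        counts.TN += int(np.sum(~k & ~p))
    return counts


def _overlap(a: BindingSite, b: BindingSite) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def site_counts(
    known: Sequence[BindingSite],
    predicted: Sequence[BindingSite],
    overlap_fraction: float = 0.25,
) -> ConfusionCounts:
    """Site-level hit tallies under a fractional-overlap rule.

    A known site is hit when some predicted site on the same sequence
    overlaps at least ``overlap_fraction`` of the known site's length
    (inclusive boundary, minimum 1 bp); predicted sites are judged by the
    symmetric rule against their own length.
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    counts = ConfusionCounts()
    counts.site_known_total = len(known)
    counts.site_pred_total = len(predicted)
    for ks in known:
        need = max(1.0, overlap_fraction * ks.length)
        if any(
            ps.seq_id == ks.seq_id and _overlap(ks, ps) >= need
            for ps in predicted
        ):
            counts.site_known_hit += 1
    for ps in predicted:
        need = max(1.0, overlap_fraction * ps.length)
        if any(
            ks.seq_id == ps.seq_id and _overlap(ks, ps) >= need for ks in known
        ):
            counts.site_pred_hit += 1
    return counts


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_stats(counts: ConfusionCounts) -> EvaluationResult:
    """The six statistics from confusion counts; zero denominators yield
    ``None`` rather than 0."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    denom = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    ncc = (tp * tn - fn * fp) / denom if denom > 0 else None
    return EvaluationResult(
        nSn=_ratio(tp, tp + fn),
        nPPV=_ratio(tp, tp + fp),
        nSp=_ratio(tn, tn + fp),
        nCC=ncc,
        sSn=_ratio(counts.site_known_hit, counts.site_known_total),
        sPPV=_ratio(counts.site_pred_hit, counts.site_pred_total),
    )


def evaluate(
    known: Sequence[BindingSite],
    predicted: Sequence[BindingSite],
    seq_lengths: Mapping[str, int],
    overlap_fraction: float = 0.25,
) -> tuple[ConfusionCounts, EvaluationResult]:
    """Full evaluation of one dataset: confusion counts and statistics."""
    counts = nucleotide_confusion(known, predicted, seq_lengths)
    sites = site_counts(known, predicted, overlap_fraction)
    counts.site_known_hit = sites.site_known_hit
    counts.site_known_total = sites.site_known_total
    counts.site_pred_hit = sites.site_pred_hit
    counts.site_pred_total = sites.site_pred_total
    return counts, compute_stats(counts)


def average_stats(results: Sequence[EvaluationResult]) -> EvaluationResult:
    """Arithmetic mean per statistic, skipping undefined values."""
    if not results:
        raise ValueError("average_stats requires at least one result")
    out = {}
    for name in STAT_NAMES:
        vals = [getattr(r, name) for r in results if getattr(r, name) is not None]
        out[name] = sum(vals) / len(vals) if vals else None
    return EvaluationResult(**out)


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str | Path, one_based: bool = False) -> list[BindingSite]:
    """Read sites from BED (or 1-based inclusive TSV when ``one_based``)."""
    sites = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        start, end = int(f[1]), int(f[2])
        if one_based:
            start -= 1
        strand = f[5] if len(f) >= 6 else "."
        sites.append(BindingSite(f[0], start, end, strand))
    return sites


def write_bed(sites: Sequence[BindingSite], path: str | Path, name: str = "site") -> None:
    lines = [
        f"{s.seq_id}\t{s.start}\t{s.end}\t{name}_{i + 1}\t0\t{s.strand if s.strand in '+-' else '.'}"
        for i, s in enumerate(sites)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def stats_table(
    rows: Mapping[str, EvaluationResult], path: str | Path | None = None
) -> str:
    """Render per-dataset statistics as TSV in the canonical column order;
    undefined values print as NA."""
    lines = ["dataset\t" + "\t".join(STAT_NAMES)]
    for name, r in rows.items():
        vals = [
            "NA" if v is None else f"{v:.4f}" for v in r.as_dict().values()
        ]
        lines.append(name + "\t" + "\t".join(vals))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
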