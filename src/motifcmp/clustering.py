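"""Distance matrices and hierarchical motif trees.

Motif relatedness is summarised as ``d = 1 - similarity/100`` (so
identical motifs sit at distance 0 and disjoint point-mass motifs at 1)
and clustered agglomeratively.  Average linkage (UPGMA) is the default
for similarity-derived distances; complete and single linkage are
available.  Trees are written as Newick with ultrametric branch lengths:
a pair of clusters merging at height *h* joins at elevation *h/2*, so the
cophenetic distance between any two leaves reproduces their merge height.

A comparison run conventionally produces two trees: one over the global
(common) significant motifs and one over the full multi-tool collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .motif_io import Motif, to_pwm
from .similarity import align

LINKAGES = ("average", "complete", "single")


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise motif distances in [0, 1]."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(["motif"] + self.labels)]
        for label, row in zip(self.labels, self.d):
            lines.append("\t".join([label] + [f"{v:.6f}" for v in row]))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class MotifTree:
    """Agglomerative merge history over motif labels.

    ``merges`` is a SciPy-style linkage matrix: row k joins clusters
    ``merges[k, 0]`` and ``merges[k, 1]`` (indices < n are leaves, n + k
    the cluster formed at step k) at height ``merges[k, 2]``.
    """

    labels: list[str]
    merges: np.ndarray
    linkage_method: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string with half-height ultrametric branch lengths."""
        n = len(self.labels)
        # node -> (newick fragment without branch length, elevation)
        frags: dict[int, tuple[str, float]] = {
            i: (_quote_label(self.labels[i]), 0.0) for i in range(n)
        }
        for k, (ia, ib, h, _) in enumerate(self.merges):
            a, ea = frags.pop(int(ia))
            b, eb = frags.pop(int(ib))
            elev = h / 2.0
            frags[n + k] = (
                f"({a}:{elev - ea:.10g},{b}:{elev - eb:.10g})",
                elev,
            )
        (root, _), = frags.values()
        return root + ";"


def _quote_label(label: str) -> str:
    if any(c in label for c in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def distance_matrix(
    motifs: Sequence[Motif],
    min_overlap: int | None = None,
    pseudocount: float = 0.25,
) -> DistanceMatrix:
    """All-pairs best alignment scores converted to distances 1 - s/100."""
    if len(motifs) < 2:
        raise ValueError("distance matrix requires at least two motifs")
    pwms = [to_pwm(m, pseudocount) for m in motifs]
    n = len(motifs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = align(pwms[i], pwms[j], min_overlap).score_percent
            d[i, j] = d[j, i] = 1.0 - s / 100.0
    return DistanceMatrix(labels=[m.id for m in motifs], d=d)


def build_tree(dm: DistanceMatrix, linkage_method: str = "average") -> MotifTree:
    """Agglomerative clustering of a distance matrix.

    Leaves joined at lower heights are more similar; for the monotone
    linkages offered here the merge heights are non-decreasing.
    """
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    merges = linkage(squareform(dm.d, checks=False), method=linkage_method)
    return MotifTree(labels=list(dm.labels), merges=merges, linkage_method=linkage_method)


def write_newick(tree: MotifTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
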