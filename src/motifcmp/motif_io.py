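"""Reading, filtering and writing DNA motif matrices.

Motifs flow through the package as position frequency matrices (PFMs, base
counts per column) tagged with the tool that produced them and a per-motif
significance value.  Three interchange formats are supported:

* MEME minimal motif text format (read/write) — the lingua franca of de
  novo motif finders; stores letter probabilities plus ``nsites`` and an
  optional E-value.
* JASPAR PFM, 2016+ dialect (read/write) — ``>ID name`` headers followed
  by one bracketed count row per base.
* TRANSFAC matrix blocks (read) — ``AC``/``ID`` records, a ``P0`` header
  row and numbered position rows terminated by ``//``.

The alphabet is fixed to DNA in the order A, C, G, T; ambiguity codes are
rejected.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

ALPHABET = "ACGT"

#: nsites assumed when an input format does not state how many sites back a
#: matrix; merging weights need some value.
DEFAULT_NSITES = 20.0

#: Significance cutoffs applied by default, one per significance kind.
#: Motifs carrying a tool-native score (or no significance at all) are
#: treated as pre-filtered by the producing tool and always kept.
DEFAULT_THRESHOLDS: Mapping[str, float] = {"p_value": 0.05, "e_value": 0.05}

SIGNIFICANCE_KINDS = ("p_value", "e_value", "tool_score", "none")


class MotifParseError(ValueError):
    """Raised when a motif file does not conform to its declared format."""


@dataclass
class Motif:
    """A named base-count matrix with provenance and significance metadata.

    Parameters
    ----------
    id : str
        Motif identifier, unique within one tool's output list.
    counts : ndarray of shape (width, 4)
        Non-negative base counts per column, alphabet order A, C, G, T.
        Counts may be real-valued (MEME probabilities scaled by nsites are
        kept unrounded).
    tool : str
        Label of the producing motif finder (e.g. ``"MEME"``, ``"ChIPMunk"``).
    nsites : float
        Number of sites contributing to the matrix; defaults to 20 when the
        source format does not record it.
    significance_value : float or None
        P-value, E-value or tool-native score; ``None`` when absent.
    significance_kind : str
        One of ``p_value``, ``e_value``, ``tool_score``, ``none``.
    name : str
        Optional secondary name (JASPAR's second header token).
    """

    id: str
    counts: np.ndarray
    tool: str = "other"
    nsites: float = DEFAULT_NSITES
    significance_value: float | None = None
    significance_kind: str = "none"
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"motif {self.id!r}: counts must be width x 4")
        if self.counts.shape[0] < 1:
            raise ValueError(f"motif {self.id!r}: width must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.id!r}: negative counts")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError(f"motif {self.id!r}: column with zero total count")
        if self.significance_kind not in SIGNIFICANCE_KINDS:
            raise ValueError(
                f"motif {self.id!r}: unknown significance kind "
                f"{self.significance_kind!r}"
            )
        if self.significance_kind in ("p_value", "e_value"):
            if self.significance_value is None:
                raise ValueError(
                    f"motif {self.id!r}: {self.significance_kind} declared "
                    "but no value given"
                )
            if self.significance_value < 0:
                raise ValueError(f"motif {self.id!r}: negative significance")
        if self.nsites <= 0:
            raise ValueError(f"motif {self.id!r}: nsites must be positive")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        """Majority base per column (ties broken by alphabet order)."""
        return "".join(ALPHABET[j] for j in self.counts.argmax(axis=1))


@dataclass
class PWM:
    """Column-stochastic position weight matrix derived from a count matrix."""

    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be width x 4")
        colsums = self.probs.sum(axis=1)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(self.probs < 0):
            raise ValueError("PWM entries must be non-negative")

    @property
    def width(self) -> int:
        return self.probs.shape[0]


def to_pwm(motif: Motif, pseudocount: float = 0.25) -> PWM:
    """Convert counts to probabilities with an additive pseudocount.

    probs[j, b] = (counts[j, b] + pseudocount) / (colsum_j + 4 * pseudocount)
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c = motif.counts + pseudocount
    return PWM(c / c.sum(axis=1, keepdims=True), pseudocount=pseudocount)


def filter_significant(
    motifs: Sequence[Motif],
    thresholds: Mapping[str, float] | None = None,
) -> list[Motif]:
    """Keep motifs whose p/e-value is at or below the per-kind cutoff.

    The boundary is inclusive (a value equal to the cutoff passes).  Motifs
    with ``tool_score`` or ``none`` significance are kept unconditionally;
    input order is preserved and the operation is idempotent.
    """
    cuts = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        cuts.update(thresholds)
    kept = []
    for m in motifs:
        if m.significance_kind in ("p_value", "e_value"):
            if m.significance_value <= cuts[m.significance_kind]:
                kept.append(m)
        else:
            kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_minimal(path: str | Path, tool: str = "other") -> list[Motif]:
    """Parse a MEME minimal motif text file into Motifs.

    Letter probabilities are converted back to counts by scaling with
    ``nsites`` (no rounding).  ``E=`` on the matrix header line becomes an
    e-value significance; otherwise the motif carries no significance.
    """
    lines = Path(path).read_text().splitlines()
    motifs: list[Motif] = []
    saw_version = False
    i = 0
    n = len(lines)

    def err(lineno: int, msg: str) -> MotifParseError:
        return MotifParseError(f"{path}:{lineno}: {msg}")

    while i < n:
        line = lines[i].strip()
        if line.startswith("MEME version"):
            saw_version = True
        elif line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip()
            if alpha.upper() != "ACGT":
                raise err(i + 1, f"non-DNA alphabet {alpha!r}")
        elif line.startswith("MOTIF"):
            if not saw_version:
                raise err(i + 1, "MOTIF block before MEME version line")
            toks = line.split()
            if len(toks) < 2:
                raise err(i + 1, "MOTIF line without identifier")
            mid = toks[1]
            mname = toks[2] if len(toks) > 2 else ""
            # advance to the letter-probability header
            j = i + 1
            while j < n and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise err(j + 1, f"motif {mid!r} has no matrix")
                j += 1
            if j >= n:
                raise err(i + 1, f"motif {mid!r} has no letter-probability matrix")
            header = lines[j].strip()
            attrs = dict(re.findall(r"(\w+)=\s*(\S+)", header))
            alength = int(attrs.get("alength", 4))
            if alength != 4:
                raise err(j + 1, f"alength= {alength} (DNA requires 4)")
            w = int(attrs["w"]) if "w" in attrs else None
            nsites = float(attrs["nsites"]) if "nsites" in attrs else DEFAULT_NSITES
            evalue = float(attrs["E"]) if "E" in attrs else None
            rows = []
            j += 1
            while j < n:
                row = lines[j].strip()
                if not row or row.startswith(("MOTIF", "URL")):
                    break
                vals = row.split()
                if len(vals) != 4:
                    raise err(j + 1, f"expected 4 columns, got {len(vals)}")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    raise err(j + 1, f"non-numeric matrix entry in {row!r}")
                j += 1
            if w is not None and len(rows) != w:
                raise err(j, f"motif {mid!r}: w= {w} but {len(rows)} rows")
            if not rows:
                raise err(j, f"motif {mid!r}: empty matrix")
            probs = np.array(rows)
            motifs.append(
                Motif(
                    id=mid,
                    name=mname,
                    counts=probs * nsites,
                    tool=tool,
                    nsites=nsites,
                    significance_value=evalue,
                    significance_kind="e_value" if evalue is not None else "none",
                )
            )
            i = j
            continue
        i += 1
    if not saw_version:
        raise MotifParseError(f"{path}:1: missing 'MEME version' header")
    return motifs


def write_meme_minimal(motifs: Iterable[Motif], path: str | Path) -> None:
    """Write motifs as a MEME minimal text file (probabilities + nsites)."""
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    out += [
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
    ]
    for m in motifs:
        header = f"MOTIF {m.id}" + (f" {m.name}" if m.name else "")
        out.append(header)
        attrs = f"letter-probability matrix: alength= 4 w= {m.width} nsites= {m.nsites:g}"
        if m.significance_kind == "e_value":
            attrs += f" E= {m.significance_value:g}"
        out.append(attrs)
        probs = m.counts / m.counts.sum(axis=1, keepdims=True)
        for row in probs:
            out.append(" ".join(f"{v:.6f}" for v in row))
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFM


_JASPAR_ROW = re.compile(r"^([ACGTacgtUuNn])\s*\[\s*([^\]]*)\s*\]\s*$")


def read_jaspar_pfm(path: str | Path, tool: str = "other") -> list[Motif]:
    """Parse JASPAR 2016+ PFM records (``>ID name`` + four bracketed rows)."""
    lines = Path(path).read_text().splitlines()
    motifs: list[Motif] = []
    i = 0
    n = len(lines)

    def err(lineno: int, msg: str) -> MotifParseError:
        return MotifParseError(f"{path}:{lineno}: {msg}")

    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise err(i + 1, f"expected '>' header, got {line!r}")
        toks = line[1:].split(None, 1)
        if not toks:
            raise err(i + 1, "empty header")
        mid = toks[0]
        mname = toks[1].strip() if len(toks) > 1 else ""
        rows: dict[str, list[float]] = {}
        for k in range(4):
            if i + 1 + k >= n:
                raise err(n, f"motif {mid!r}: truncated record")
            m = _JASPAR_ROW.match(lines[i + 1 + k].strip())
            if not m:
                raise err(i + 2 + k, f"motif {mid!r}: malformed base row")
            base = m.group(1).upper()
            if base not in ALPHABET:
                raise err(i + 2 + k, f"motif {mid!r}: non-DNA base {base!r}")
            try:
                rows[base] = [float(v) for v in m.group(2).split()]
            except ValueError:
                raise err(i + 2 + k, f"motif {mid!r}: non-numeric count")
        missing = [b for b in ALPHABET if b not in rows]
        if missing:
            raise err(i + 1, f"motif {mid!r}: missing base rows {missing}")
        widths = {len(rows[b]) for b in ALPHABET}
        if len(widths) != 1:
            raise err(i + 1, f"motif {mid!r}: ragged rows (widths {sorted(widths)})")
        counts = np.array([rows[b] for b in ALPHABET]).T
        motifs.append(
            Motif(
                id=mid,
                name=mname,
                counts=counts,
                tool=tool,
                nsites=float(counts.sum(axis=1).max()),
                significance_kind="none",
            )
        )
        i += 5
    return motifs


def write_jaspar_pfm(motifs: Iterable[Motif], path: str | Path) -> None:
    out = []
    for m in motifs:
        out.append(f">{m.id}" + (f" {m.name}" if m.name else ""))
        for b, col in zip(ALPHABET, m.counts.T):
            out.append(f"{b} [ " + " ".join(f"{v:g}" for v in col) + " ]")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# TRANSFAC matrix blocks


def read_transfac(path: str | Path, tool: str = "other") -> list[Motif]:
    """Parse TRANSFAC matrix blocks (AC/ID, P0 header, numbered rows, //)."""
    lines = Path(path).read_text().splitlines()
    motifs: list[Motif] = []
    i = 0
    n = len(lines)

    def err(lineno: int, msg: str) -> MotifParseError:
        return MotifParseError(f"{path}:{lineno}: {msg}")

    block_start = None
    acc = None
    ident = None
    order = None
    rows: list[list[float]] = []
    in_matrix = False
    for i, raw in enumerate(lines):
        line = raw.rstrip()
        if not line.strip():
            continue
        tag = line[:2]
        if tag == "AC":
            acc = line[2:].strip()
            block_start = i + 1
        elif tag == "ID":
            ident = line[2:].strip()
            if block_start is None:
                block_start = i + 1
        elif tag == "P0" or tag == "PO":
            bases = line[2:].split()
            if [b.upper() for b in bases] != list(ALPHABET):
                raise err(i + 1, f"P0 row must list A C G T, got {bases}")
            order = [ALPHABET.index(b.upper()) for b in bases]
            in_matrix = True
            rows = []
        elif tag == "//":
            if not in_matrix:
                if acc is None and ident is None:
                    continue
                raise err(i + 1, "matrix block without P0 line")
            if not rows:
                raise err(i + 1, "matrix block with no position rows")
            counts = np.array(rows)
            mid = acc or ident or f"transfac_{len(motifs) + 1}"
            motifs.append(
                Motif(
                    id=mid,
                    name=ident or "",
                    counts=counts,
                    tool=tool,
                    nsites=float(counts.sum(axis=1).max()),
                    significance_kind="none",
                )
            )
            acc = ident = None
            in_matrix = False
            rows = []
            block_start = None
        elif in_matrix and line[:2].strip().isdigit():
            vals = line.split()
            # position index, four counts, optional consensus letter
            if len(vals) < 5:
                raise err(i + 1, f"position row needs 4 counts: {line!r}")
            try:
                nums = [float(v) for v in vals[1:5]]
            except ValueError:
                raise err(i + 1, f"non-numeric count in {line!r}")
            reordered = [0.0] * 4
            for pos, val in zip(order, nums):
                reordered[pos] = val
            rows.append(reordered)
    if in_matrix or acc is not None or ident is not None:
        if not in_matrix and rows == []:
            raise err(n, "unterminated block without P0 line")
        raise err(n, "unterminated matrix block (missing //)")
    return motifs
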