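"""Synthetic binding-site benchmarks with known ground truth.

Emulates the construction of the classic assessment datasets for motif
discovery tools: random background sequences — either uniform i.i.d.
("generic" stand-in) or sampled from a Markov chain of order 3
("markov") — into which binding sites sampled from a PWM are implanted
at known, non-overlapping positions.  Every generated dataset carries its
truth coordinates, so binding-site predictions can be scored against an
exact answer, and evaluating the truth against itself must yield perfect
statistics.

Sixteen dataset shapes (sequence count x length, background type) follow
the published benchmark table; the actual site instances are synthetic —
sampled from a supplied or seeded PWM, not from a curated database.

All outputs are pure functions of their parameters and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluation import BindingSite, write_bed
from .motif_io import ALPHABET, PWM

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 16 benchmark dataset shapes: label -> (type, species, transcription
#: factor, number of sequences, sequence length).
TABLE2_DATASETS: dict[str, tuple[str, str, str, int, int]] = {
    "hm01g": ("generic", "Homo sapiens", "AP-1", 18, 2000),
    "hm04g": ("generic", "Homo sapiens", "c-Jun", 13, 2000),
    "hm08m": ("markov", "Homo sapiens", "CREB", 15, 500),
    "hm15g": ("generic", "Homo sapiens", "NF-1", 4, 2000),
    "hm17g": ("generic", "Homo sapiens", "NF-kappaB", 11, 500),
    "hm19g": ("generic", "Homo sapiens", "Sp1", 5, 500),
    "hm22g": ("generic", "Homo sapiens", "USF", 16, 500),
    "hm22m": ("markov", "Homo sapiens", "USF", 16, 500),
    "mus09g": ("generic", "Mus musculus", "POU2F1", 2, 500),
    "mus10g": ("generic", "Mus musculus", "Sp1", 13, 1000),
    "mus11m": ("markov", "Mus musculus", "Sp1", 12, 500),
    "yst01g": ("generic", "Saccharomyces cerevisiae", "ABF1", 9, 1000),
    "yst02g": ("generic", "Saccharomyces cerevisiae", "GAL4", 4, 500),
    "yst03m": ("markov", "Saccharomyces cerevisiae", "GCN4", 8, 500),
    "yst06g": ("generic", "Saccharomyces cerevisiae", "MCM1", 7, 500),
    "yst09g": ("generic", "Saccharomyces cerevisiae", "CAR1", 16, 1000),
}


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MarkovModel:
    """Fixed-order Markov chain over A,C,G,T.

    ``transitions`` has shape (4**order, 4): row r is the distribution of
    the next base given the preceding k-mer with radix-4 code r (A=0 ...
    T=3, leftmost base most significant).  ``initial`` is a distribution
    over the 4**order starting k-mers.  Order 0 reduces to an i.i.d. base
    model with a single transition row.
    """

    order: int
    transitions: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        nstates = 4**self.order
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transitions.shape != (nstates, 4):
            raise ValueError(f"transitions must be {nstates} x 4")
        if self.initial.shape != (nstates,):
            raise ValueError(f"initial must have length {nstates}")
        if np.any(np.abs(self.transitions.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")

    @staticmethod
    def kmer_code(kmer: str) -> int:
        code = 0
        for b in kmer:
            code = code * 4 + _BASE_INDEX[b]
        return code

    @staticmethod
    def code_kmer(code: int, order: int) -> str:
        out = []
        for _ in range(order):
            out.append(ALPHABET[code % 4])
            code //= 4
        return "".join(reversed(out))


def uniform_markov(order: int = 0) -> MarkovModel:
    """A maximally uninformative chain: every conditional uniform."""
    nstates = 4**order
    return MarkovModel(
        order=order,
        transitions=np.full((nstates, 4), 0.25),
        initial=np.full(nstates, 1.0 / nstates),
    )


def random_markov(
    order: int = 3,
    seed: int | np.random.Generator | None = None,
    concentration: float = 5.0,
) -> MarkovModel:
    """A seeded random chain with Dirichlet-sampled conditionals.

    ``concentration`` controls how far the conditionals stray from
    uniform (larger = closer to uniform); the default gives the mildly
    biased composition typical of genomic background.
    """
    rng = _as_rng(seed)
    nstates = 4**order
    trans = rng.dirichlet([concentration] * 4, size=nstates)
    init = rng.dirichlet([concentration] * nstates) if nstates > 1 else np.ones(1)
    return MarkovModel(order=order, transitions=trans, initial=init)


def fit_markov(
    sequences: Sequence[str], order: int, pseudocount: float = 1.0
) -> MarkovModel:
    """Maximum-likelihood transition table with an additive pseudocount.

    Fitting a user-supplied background corpus (e.g. real promoters) lets
    generated datasets mimic its local composition.
    """
    if not sequences or all(len(s) == 0 for s in sequences):
        raise ValueError("fit_markov requires a non-empty corpus")
    nstates = 4**order
    trans_counts = np.full((nstates, 4), pseudocount)
    init_counts = np.full(nstates, pseudocount)
    for seq in sequences:
        seq = seq.upper()
        if any(b not in _BASE_INDEX for b in seq):
            raise ValueError("corpus contains non-ACGT characters")
        for i in range(len(seq) - order):
            state = MarkovModel.kmer_code(seq[i : i + order])
            trans_counts[state, _BASE_INDEX[seq[i + order]]] += 1
            init_counts[state] += 1
    return MarkovModel(
        order=order,
        transitions=trans_counts / trans_counts.sum(axis=1, keepdims=True),
        initial=init_counts / init_counts.sum(),
    )


def generate_background(
    model: MarkovModel | None,
    n: int,
    length: int,
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """``n`` random sequences of exactly ``length`` bases.

    ``model=None`` gives uniform i.i.d. bases; otherwise the chain is
    started from its initial k-mer distribution and extended base by
    base.  Output is fully reproducible from the seed.
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    rng = _as_rng(seed)
    bases = np.array(list(ALPHABET))
    seqs = []
    if model is None or (model.order == 0 and np.allclose(model.transitions, 0.25)):
        for _ in range(n):
            seqs.append("".join(bases[rng.integers(0, 4, size=length)]))
        return seqs
    k = model.order
    for _ in range(n):
        out: list[str] = []
        if k > 0:
            state = int(rng.choice(len(model.initial), p=model.initial))
            out.extend(MarkovModel.code_kmer(state, k))
        else:
            state = 0
        while len(out) < length:
            b = int(rng.choice(4, p=model.transitions[state]))
            out.append(ALPHABET[b])
            if k > 0:
                state = (state * 4 + b) % (4**k)
        seqs.append("".join(out[:length]))
    return seqs


def sample_site(pwm: PWM, seed: int | np.random.Generator | None = None) -> str:
    """One site drawn column-wise from a PWM; length equals the width."""
    rng = _as_rng(seed)
    return "".join(
        ALPHABET[int(rng.choice(4, p=col))] for col in pwm.probs
    )


def random_pwm(
    width: int = 8,
    seed: int | np.random.Generator | None = None,
    concentration: float = 0.3,
) -> PWM:
    """A seeded random motif model with informative (peaky) columns."""
    rng = _as_rng(seed)
    return PWM(rng.dirichlet([concentration] * 4, size=width))


@dataclass
class BenchmarkDataset:
    """Synthetic sequences plus the exact coordinates of implanted sites."""

    name: str
    sequences: list[tuple[str, str]]  # (id, DNA)
    truth: list[BindingSite]
    implanted_pwm: PWM
    dataset_type: str = "generic"  # "generic" | "markov"

    @property
    def seq_lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.sequences}

    def write(self, outdir: str | Path, params: dict | None = None) -> None:
        """FASTA + BED truth + JSON sidecar with generator parameters."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / f"{self.name}.fasta", "w") as fh:
            for sid, seq in self.sequences:
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        write_bed(self.truth, outdir / f"{self.name}.truth.bed", name=self.name)
        sidecar = {
            "name": self.name,
            "dataset_type": self.dataset_type,
            "n_sequences": len(self.sequences),
            "sequence_length": len(self.sequences[0][1]) if self.sequences else 0,
            "n_truth_sites": len(self.truth),
            "pwm_width": self.implanted_pwm.width,
            "pwm": self.implanted_pwm.probs.tolist(),
        }
        if params:
            sidecar.update(params)
        (outdir / f"{self.name}.json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )


def _draw_starts(
    rng: np.random.Generator, length: int, width: int, k: int, max_rounds: int = 1000
) -> list[int]:
    """k non-overlapping uniform start positions, by rejection."""
    hi = length - width
    for _ in range(max_rounds):
        starts = sorted(int(s) for s in rng.integers(0, hi + 1, size=k))
        if all(b - a >= width for a, b in zip(starts, starts[1:])):
            return starts
    raise RuntimeError(
        f"could not place {k} non-overlapping sites of width {width} "
        f"in length {length} after {max_rounds} attempts"
    )


def implant(
    background: Sequence[str],
    pwm: PWM,
    sites_per_seq: int = 1,
    seed: int | np.random.Generator | None = None,
    name: str = "synthetic",
    dataset_type: str = "generic",
) -> BenchmarkDataset:
    """Implant PWM-sampled sites into background sequences.

    Each sequence receives ``sites_per_seq`` non-overlapping sites at
    uniform positions; a uniform strand is drawn per site and minus-strand
    sites are implanted as the reverse complement of the sampled site.
    Sites *replace* the background bases, preserving sequence length.
    Truth records every placement.
    """
    if sites_per_seq < 1:
        raise ValueError("sites_per_seq must be >= 1")
    w = pwm.width
    rng = _as_rng(seed)
    sequences: list[tuple[str, str]] = []
    truth: list[BindingSite] = []
    for i, bg in enumerate(background):
        if sites_per_seq * w > len(bg):
            raise ValueError(
                f"{sites_per_seq} sites of width {w} cannot fit in "
                f"length {len(bg)}"
            )
        sid = f"{name}_seq{i + 1}"
        seq = list(bg)
        for start in _draw_starts(rng, len(bg), w, sites_per_seq):
            site = sample_site(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = site if strand == "+" else site.translate(_COMPLEMENT)[::-1]
            seq[start : start + w] = placed
            truth.append(BindingSite(sid, start, start + w, strand))
        sequences.append((sid, "".join(seq)))
    return BenchmarkDataset(
        name=name,
        sequences=sequences,
        truth=truth,
        implanted_pwm=pwm,
        dataset_type=dataset_type,
    )


def emulate_table2(
    name: str,
    pwm: PWM | None = None,
    seed: int | np.random.Generator | None = None,
    sites_per_seq: int = 1,
) -> BenchmarkDataset:
    """A dataset with the shape of one of the 16 benchmark rows.

    ``generic`` rows use a uniform background; ``markov`` rows use a
    seeded random order-3 chain.  When no PWM is supplied, a seeded random
    8-column motif is implanted.
    """
    if name not in TABLE2_DATASETS:
        raise ValueError(
            f"unknown dataset {name!r}; valid names: "
            + ", ".join(sorted(TABLE2_DATASETS))
        )
    dtype, _species, _tf, n_seqs, length = TABLE2_DATASETS[name]
    rng = _as_rng(seed)
    if pwm is None:
        pwm = random_pwm(width=8, seed=rng)
    model = random_markov(order=3, seed=rng) if dtype == "markov" else None
    background = generate_background(model, n_seqs, length, seed=rng)
    return implant(
        background,
        pwm,
        sites_per_seq=sites_per_seq,
        seed=rng,
        name=name,
        dataset_type=dtype,
    )
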