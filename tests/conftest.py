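from __future__ import annotations

import numpy as np
import pytest

from motifcmp import Motif, PWM


MEME_TWO_MOTIFS = """\
MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF M1 first
letter-probability matrix: alength= 4 w= 4 nsites= 10 E= 1e-3
1.000000 0.000000 0.000000 0.000000
0.000000 1.000000 0.000000 0.000000
0.000000 0.000000 1.000000 0.000000
0.200000 0.300000 0.100000 0.400000

MOTIF M2
letter-probability matrix: alength= 4 w= 5 nsites= 24 E= 0.2
0.250000 0.250000 0.250000 0.250000
0.500000 0.500000 0.000000 0.000000
0.000000 0.000000 0.000000 1.000000
0.125000 0.125000 0.250000 0.500000
1.000000 0.000000 0.000000 0.000000
"""

JASPAR_TWO_MOTIFS = """\
>MA0001.1 AGL3
A [ 0 3 79 40 66 48 65 11 65 0 ]
C [ 94 75 4 3 1 2 5 2 3 3 ]
G [ 1 0 3 4 1 0 5 3 28 88 ]
T [ 2 19 11 50 29 47 22 81 1 6 ]
>MA0002.1
A [ 4 19 0 0 0 0 ]
C [ 16 0 20 0 0 0 ]
G [ 0 1 0 20 0 20 ]
T [ 0 0 0 0 20 0 ]
"""

TRANSFAC_ONE_BLOCK = """\
AC M00001
ID V$MYOD_01
P0      A      C      G      T
01      1      2      2      0      S
02      2      1      2      0      R
03      3      0      1      1      A
04      0      5      0      0      C
05      5      0      0      0      A
//
"""


@pytest.fixture
def meme_file(tmp_path):
    p = tmp_path / "two.meme"
    p.write_text(MEME_TWO_MOTIFS)
    return p


@pytest.fixture
def jaspar_file(tmp_path):
    p = tmp_path / "two.pfm"
    p.write_text(JASPAR_TWO_MOTIFS)
    return p


@pytest.fixture
def transfac_file(tmp_path):
    p = tmp_path / "one.transfac"
    p.write_text(TRANSFAC_ONE_BLOCK)
    return p


def make_random_pwm(rng: np.random.Generator, width: int | None = None,
                    concentration: float = 0.5) -> PWM:
    if width is None:
        width = int(rng.integers(4, 16))
    return PWM(rng.dirichlet([concentration] * 4, size=width))


def make_random_motif(rng: np.random.Generator, mid: str, tool: str = "other",
                      width: int | None = None, nsites: float = 20.0,
                      **kwargs) -> Motif:
    if width is None:
        width = int(rng.integers(4, 16))
    counts = rng.dirichlet([0.5] * 4, size=width) * nsites
    return Motif(id=mid, counts=counts, tool=tool, nsites=nsites, **kwargs)


def point_mass_motif(mid: str, bases: str, tool: str = "other",
                     scale: float = 10.0, **kwargs) -> Motif:
    """A motif whose columns put all mass on the given base string."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((len(bases), 4))
    for j, b in enumerate(bases):
        counts[j, idx[b]] = scale
    return Motif(id=mid, counts=counts, tool=tool, **kwargs)
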