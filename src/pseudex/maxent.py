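"""Loaders for externally published maximum-entropy splice-site tables.

The published donor/acceptor maximum-entropy models ship as directories of
plain-text probability tables: ``me2x5`` (one ratio per line for each of the
4^7 donor 7-mers left after fixing the GT) for the 9-mer donor model, and
``me2x3acc1`` .. ``me2x3acc9`` (the inclusion-exclusion decomposition of the
21-mer left after fixing the AG) for the 23-mer acceptor model. Lines are
ordered lexicographically over A<C<G<T. This module consumes that layout
verbatim and reproduces the published scoring arithmetic:

    donor:    log2( P_cons(+1)P_cons(+2)/P_bg(+1)P_bg(+2) * me2x5[rest] )
    acceptor: log2( P_cons(-2)P_cons(-1)/P_bg * t1*t2*t3*t4*t5/(t6*t7*t8*t9) )

The tables themselves are user-supplied inputs; nothing here re-derives them.
"""

from __future__ import annotations

import math
import os

from .motifs import ACCEPTOR_POSITIONS, DONOR_POSITIONS, MotifModel

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

_BGD = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
# Consensus-position frequencies at the fixed dinucleotides, as published.
_DONOR_CONS1 = {"A": 0.004, "C": 0.0032, "G": 0.9896, "T": 0.0022}  # +1 (G)
_DONOR_CONS2 = {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9884}  # +2 (T)
_ACC_CONS1 = {"A": 0.9903, "C": 0.0032, "G": 0.0034, "T": 0.0030}  # -2 (A)
_ACC_CONS2 = {"A": 0.0027, "C": 0.0037, "G": 0.9905, "T": 0.0030}  # -1 (G)


def _seq_index(seq: str) -> int:
    i = 0
    for b in seq:
        i = i * 4 + _BASE_INDEX[b]
    return i


def _load_table(path: str, k: int) -> list[float]:
    with open(path) as fh:
        values = [float(line) for line in fh if line.strip()]
    if len(values) != 4**k:
        raise ValueError(
            f"{path}: expected {4 ** k} entries for {k}-mers, found {len(values)}"
        )
    return values


def load_maxent_donor(directory: str, name: str = "maxent-donor") -> MotifModel:
    """Donor model from a directory containing ``me2x5``."""
    table = _load_table(os.path.join(directory, "me2x5"), 7)

    def scorer(window: str) -> float:
        cons = (
            _DONOR_CONS1[window[3]]
            * _DONOR_CONS2[window[4]]
            / (_BGD[window[3]] * _BGD[window[4]])
        )
        rest = window[:3] + window[5:]
        return math.log2(cons * table[_seq_index(rest)])

    return MotifModel(name, "donor", DONOR_POSITIONS, scorer, f"dir:{directory}")


# (offset, length) of each acceptor sub-table over the 21-mer remainder, and
# whether it contributes to the numerator or denominator.
_ACC_SEGMENTS = [
    (0, 7, True),
    (7, 7, True),
    (14, 7, True),
    (4, 7, True),
    (11, 7, True),
    (4, 3, False),
    (7, 4, False),
    (11, 3, False),
    (14, 4, False),
]


def load_maxent_acceptor(directory: str, name: str = "maxent-acceptor") -> MotifModel:
    """Acceptor model from a directory containing ``me2x3acc1``..``me2x3acc9``."""
    tables = [
        _load_table(os.path.join(directory, f"me2x3acc{i + 1}"), k)
        for i, (_, k, _num) in enumerate(_ACC_SEGMENTS)
    ]

    def scorer(window: str) -> float:
        # window positions -20..-1,+1..+3; the AG sits at indices 18,19
        cons = (
            _ACC_CONS1[window[18]]
            * _ACC_CONS2[window[19]]
            / (_BGD[window[18]] * _BGD[window[19]])
        )
        rest = window[:18] + window[20:]
        num, den = 1.0, 1.0
        for (off, k, is_num), table in zip(_ACC_SEGMENTS, tables):
            v = table[_seq_index(rest[off : off + k])]
            if is_num:
                num *= v
            else:
                den *= v
        return math.log2(cons * num / den)

    return MotifModel(name, "acceptor", ACCEPTOR_POSITIONS, scorer, f"dir:{directory}")
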