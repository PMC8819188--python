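"""Hexamer splicing-regulatory scoring (delta-Hx) and IUPAC motif scanning.

An exon's regulatory content is summarised as the sum of a score table over
all overlapping 6-mers; the effect of a mutation is the mutant total minus the
wild-type total (delta-Hx). A positive delta is read as a net gain of exonic
splicing enhancer character and/or loss of silencer character. Whole-sequence
subtraction is the definition of record -- it covers indels -- and the faster
windowed route for SNVs is required to agree with it exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .model import InstigatingMutation
from .sequences import apply_mutation, check_dna


@dataclass
class HexamerTable:
    """Scores over {A,C,G,T}^6; missing entries default to 0 with a warning."""

    scores: dict[str, float]
    name: str = "hexamer"
    provenance: str = ""
    _warned: set = field(default_factory=set, repr=False)

    def score(self, hexamer: str) -> float:
        try:
            return self.scores[hexamer]
        except KeyError:
            if hexamer not in self._warned:
                warnings.warn(
                    f"{self.name}: no score for hexamer {hexamer}, using 0",
                    stacklevel=2,
                )
                self._warned.add(hexamer)
            return 0.0

    @classmethod
    def from_file(cls, path: str, name: str | None = None) -> "HexamerTable":
        """Read a two-column HEXAMER<TAB>score table."""
        scores = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                hx, s = line.split("\t")
                scores[check_dna(hx, what="hexamer")] = float(s)
        return cls(scores, name or path, provenance=f"file:{path}")


@dataclass(frozen=True)
class DeltaHx:
    wt_total: float
    mut_total: float

    @property
    def delta(self) -> float:
        return self.mut_total - self.wt_total

    def direction(self, tol: float = 0.0) -> str:
        return predict_directionality(self, tol)


def per_base_table(values: dict[str, float], name: str = "per-base") -> HexamerTable:
    """A fully specified table where a hexamer scores the sum of per-base
    values -- handy as a packaged toy table with a nonzero delta for every
    substitution when the four base values are distinct."""
    from itertools import product

    scores = {
        "".join(h): sum(values[b] for b in h) for h in product("ACGT", repeat=6)
    }
    return HexamerTable(scores, name, provenance="derived per-base")


def toy_hexamer_table() -> HexamerTable:
    return per_base_table(
        {"A": 0.3, "C": -0.2, "G": 0.1, "T": -0.4}, name="toy-hexamer"
    )


def zero_hexamer_table() -> HexamerTable:
    from itertools import product

    return HexamerTable(
        {"".join(h): 0.0 for h in product("ACGT", repeat=6)},
        "zero-hexamer",
        "null model",
    )


def total_hexamer_score(seq: str, table: HexamerTable) -> float:
    """Sum of table scores over all overlapping 6-mers (< 6 nt scores 0)."""
    seq = check_dna(seq)
    return sum(table.score(seq[i : i + 6]) for i in range(len(seq) - 5))


def delta_hx(
    wt_seq: str,
    mutation: InstigatingMutation,
    table: HexamerTable,
    *,
    seq_start: int = 0,
) -> DeltaHx:
    """Mutant-minus-wild-type total hexamer score for a mutation inside
    ``wt_seq`` (which covers genomic [seq_start, seq_start + len)).

    SNVs are computed on the <= 6 windows overlapping the changed base and
    asserted equal to the full-sequence subtraction; indels always use the
    full subtraction.
    """
    wt_seq = check_dna(wt_seq)
    if not mutation.overlaps(seq_start, seq_start + len(wt_seq)) and not (
        mutation.genomic_start == mutation.genomic_end
        and seq_start <= mutation.genomic_start <= seq_start + len(wt_seq)
    ):
        raise ValueError(f"mutation {mutation.hgvs_cdna} outside the scored sequence")
    mut_seq = apply_mutation(wt_seq, mutation, seq_start)
    wt_total = total_hexamer_score(wt_seq, table)
    mut_total = total_hexamer_score(mut_seq, table)
    if mutation.is_snv:
        i = mutation.genomic_start - seq_start
        lo = max(0, i - 5)
        hi = min(len(wt_seq), i + 6)
        local = total_hexamer_score(mut_seq[lo:hi], table) - total_hexamer_score(
            wt_seq[lo:hi], table
        )
        # the windowed shortcut must agree with the definition of record
        assert abs(local - (mut_total - wt_total)) < 1e-9
    return DeltaHx(wt_total, mut_total)


def predict_directionality(d: DeltaHx, tol: float = 0.0) -> str:
    """gain / loss / neutral by the sign of delta-Hx beyond ``tol``."""
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    if d.delta > tol:
        return "gain"
    if d.delta < -tol:
        return "loss"
    return "neutral"


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def iupac_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC[c] for c in pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in {pattern!r}") from exc


def scan_motifs(seq: str, motifs: list[str]) -> list[tuple[str, int]]:
    """All exact IUPAC matches as (motif, 0-based offset); overlaps allowed."""
    seq = check_dna(seq)
    hits = []
    for motif in motifs:
        rx = iupac_regex(motif)
        pos = 0
        while True:
            m = rx.search(seq, pos)
            if not m:
                break
            hits.append((motif, m.start()))
            pos = m.start() + 1
    return hits
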