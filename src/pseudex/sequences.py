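"""Sequence access helpers.

The analysis only ever needs short windows out of large reference sequences, so
everything funnels through :class:`SequenceSource`, which wraps either a plain
``{chrom: sequence}`` mapping (synthetic loci, tests) or a ``pyfaidx.Fasta``
handle (real FASTA on disk). All coordinates are 0-based half-open on the
reference strand.
"""

from __future__ import annotations

from typing import Mapping

from Bio.Seq import reverse_complement

_ACGT = frozenset("ACGT")


def check_dna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase ``seq`` and reject non-ACGT characters."""
    seq = seq.upper()
    bad = set(seq) - _ACGT
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    return reverse_complement(seq)


class SequenceSource:
    """Uniform windowed access to reference sequences by chromosome."""

    def __init__(self, source) -> None:
        self._source = source

    @classmethod
    def from_fasta(cls, path: str) -> "SequenceSource":
        import pyfaidx

        return cls(pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True))

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Return [start, end) on the reference strand, reverse-complemented
        when ``strand`` is '-'. Out-of-range requests raise."""
        if start < 0 or end < start:
            raise ValueError(f"bad window [{start}, {end})")
        record = self._source[chrom]
        seq = str(record[start:end]).upper()
        if len(seq) != end - start:
            raise ValueError(
                f"window [{start}, {end}) extends beyond {chrom} "
                f"(got {len(seq)} nt)"
            )
        return revcomp(seq) if strand == "-" else seq

    def chrom_length(self, chrom: str) -> int:
        return len(self._source[chrom])

    def __contains__(self, chrom: str) -> bool:
        if isinstance(self._source, Mapping):
            return chrom in self._source
        try:
            self._source[chrom]
            return True
        except KeyError:
            return False


def apply_mutation(seq: str, mut, seq_start: int = 0) -> str:
    """Apply one mutation to a reference-strand sequence.

    ``seq`` covers genomic [seq_start, seq_start + len(seq)); the mutation's
    footprint must lie inside it. Returns the mutant sequence (its length
    changes for indels).
    """
    s = mut.genomic_start - seq_start
    e = mut.genomic_end - seq_start
    if s < 0 or e > len(seq):
        raise ValueError(f"mutation {mut.hgvs_cdna} outside sequence window")
    if mut.kind == "SNV":
        if mut.ref_allele and seq[s] != mut.ref_allele:
            raise ValueError(
                f"{mut.hgvs_cdna}: reference mismatch at {mut.genomic_start} "
                f"(expected {mut.ref_allele}, found {seq[s]})"
            )
        return seq[:s] + mut.alt_allele + seq[s + 1 :]
    if mut.kind == "deletion":
        return seq[:s] + seq[e:]
    if mut.kind == "insertion":
        return seq[:s] + mut.alt_allele + seq[s:]
    if mut.kind == "delins":
        return seq[:s] + mut.alt_allele + seq[e:]
    if mut.kind == "inversion":
        return seq[:s] + revcomp(seq[s:e]) + seq[e:]
    raise ValueError(f"cannot apply mutation of kind {mut.kind!r}")


def shift_after(mut, pos: int) -> int:
    """Map a reference coordinate to the mutant sequence's coordinate axis.

    Positions 5' of the mutation are unchanged; positions 3' shift by the
    length change. Positions inside a deleted span collapse to its start.
    """
    delta = len(mut.alt_allele) - (mut.genomic_end - mut.genomic_start)
    if mut.kind == "insertion":
        delta = len(mut.alt_allele)
    if pos <= mut.genomic_start:
        return pos
    if pos >= mut.genomic_end:
        return pos + delta
    return mut.genomic_start
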