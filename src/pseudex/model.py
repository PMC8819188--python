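"""Core domain types for the pseudoexon catalogue.

A pseudoexon (PE) is a continuous intronic tract that is spliced into mature
transcripts as though it were an exon, typically after a pathogenic mutation.
These types hold one catalogued PE, the gene it sits in, and the instigating
mutation(s), using 0-based half-open genomic intervals on the reference (+)
strand throughout; strand is an explicit flag and all human-facing coordinates
(HGVS, printed tables) are 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

PE_ID_RE = re.compile(r"^[A-Z0-9]+(-[A-Z0-9]+)*-\d+-\d+[a-z]?$")

VALID_KINDS = ("SNV", "deletion", "insertion", "delins", "inversion", "rearrangement")


class ValidationError(ValueError):
    """Raised when a record violates a structural invariant."""


@dataclass
class GeneContext:
    """A minimal transcript model: ordered exons plus CDS start.

    ``exons`` are 0-based half-open intervals on the reference strand, sorted
    5'->3' in *transcript* order (ascending genomic coordinate for '+' strand
    genes, descending for '-'). ``cds_start_offset`` is the number of spliced
    transcript nucleotides 5' of the first coding base (0 when the transcript
    starts at the CDS).
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_offset: int = 0
    polyadenylation_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.exons:
            if not s < e:
                raise ValidationError(f"exon interval has start >= end: [{s}, {e})")
        genomic_sorted = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 < e1:
                raise ValidationError("exons overlap")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if list(self.exons) != expected:
            raise ValidationError("exons are not sorted in transcript order")

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def intron(self, index: int) -> tuple[int, int]:
        """Genomic interval of intron ``index`` (1-based, transcript order)."""
        if not 1 <= index <= self.n_introns:
            raise ValidationError(
                f"intron index {index} out of range 1..{self.n_introns}"
            )
        a = self.exons[index - 1]
        b = self.exons[index]
        if self.strand == "+":
            return (a[1], b[0])
        return (b[1], a[0])


@dataclass
class PseudoexonRecord:
    """One catalogued pseudoexon variant."""

    pe_id: str
    gene_context: GeneContext
    intron_index: int
    pe_start: int
    pe_end: int
    acceptor_dinuc: str = "AG"
    donor_dinuc: str = "GT"
    is_terminal: bool = False
    polya_confirmed: bool = False
    splice_evidence_acceptor: bool = False
    splice_evidence_donor: bool = False
    cell_types: list[str] = field(default_factory=list)
    citations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pe_start >= self.pe_end:
            raise ValidationError(
                f"{self.pe_id}: pe_start ({self.pe_start}) must be < pe_end "
                f"({self.pe_end})"
            )
        if self.intron_index < 1:
            raise ValidationError(f"{self.pe_id}: intron_index must be >= 1")
        if self.pe_id and not PE_ID_RE.match(self.pe_id):
            raise ValidationError(f"malformed pe_id: {self.pe_id!r}")

    @property
    def length(self) -> int:
        return self.pe_end - self.pe_start

    @property
    def strand(self) -> str:
        return self.gene_context.strand

    @property
    def acceptor_boundary(self) -> int:
        """Genomic coordinate of the first PE base (acceptor side), 0-based."""
        return self.pe_start if self.strand == "+" else self.pe_end - 1

    @property
    def donor_boundary(self) -> int:
        """Genomic coordinate of the last PE base (donor side), 0-based."""
        return self.pe_end - 1 if self.strand == "+" else self.pe_start

    @property
    def has_splice_evidence(self) -> bool:
        return self.splice_evidence_acceptor or self.splice_evidence_donor


@dataclass
class InstigatingMutation:
    """A parsed variant with genomic mapping.

    ``ref_allele``/``alt_allele`` are on the reference (+) strand; the original
    transcript-strand HGVS string is kept verbatim in ``hgvs_cdna``. For an SNV
    ``genomic_end == genomic_start + 1``; for a pure insertion the interval is
    empty (``genomic_end == genomic_start``) and ``alt_allele`` holds the
    inserted sequence.
    """

    hgvs_cdna: str
    kind: str
    genomic_start: int
    genomic_end: int
    ref_allele: str = ""
    alt_allele: str = ""
    size: int = 0

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValidationError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "SNV":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValidationError(f"{self.hgvs_cdna}: SNV alleles must be 1 nt")
            if self.ref_allele == self.alt_allele:
                raise ValidationError(f"{self.hgvs_cdna}: SNV ref == alt")
            if self.genomic_end != self.genomic_start + 1:
                raise ValidationError(f"{self.hgvs_cdna}: SNV interval must be 1 nt")
        if self.kind == "deletion" and self.size != self.genomic_end - self.genomic_start:
            raise ValidationError(
                f"{self.hgvs_cdna}: deletion size {self.size} != span "
                f"{self.genomic_end - self.genomic_start}"
            )

    @property
    def is_snv(self) -> bool:
        return self.kind == "SNV"

    def overlaps(self, start: int, end: int) -> bool:
        """True if the mutation's genomic footprint intersects [start, end)."""
        if self.genomic_start == self.genomic_end:  # insertion point
            return start < self.genomic_start < end
        return self.genomic_start < end and start < self.genomic_end


@dataclass
class CatalogueEntry:
    """One catalogue row: a PE variant plus its instigating mutation(s)."""

    record: PseudoexonRecord
    mutations: list[InstigatingMutation] = field(default_factory=list)
    category: object | None = None  # ClassificationResult once classified
    frame_preserving: bool | None = None


def is_transition(ref: str, alt: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine substitution."""
    return {ref.upper(), alt.upper()} in ({"A", "G"}, {"C", "T"})
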