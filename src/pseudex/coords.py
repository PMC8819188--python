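"""cDNA <-> genomic <-> splice-site-relative coordinate mapping.

Conventions (all strand-aware, transcript 5'->3'):

* ``c.N`` maps through the spliced transcript: transcript position
  ``cds_start_offset + N`` for N >= 1, ``cds_start_offset + N + 1`` for
  negative (5'UTR) N.
* Intronic offsets: ``c.N+k`` is k nt into the intron 3' of the anchor exon's
  donor; ``c.N-k`` is k nt 5' of the anchor exon's acceptor.
* Site-relative labels on a pseudoexon: A+1 is the first PE base, A-1 the last
  intronic base 5' of the acceptor; D-1 is the last PE base, D+1 the first
  intronic base 3' of the donor. A position that admits both an A- and a
  D-relative label gets the one with the smaller absolute offset (ties go to
  the acceptor side).
"""

from __future__ import annotations

from dataclasses import dataclass

from .hgvs import CdnaPosition
from .model import GeneContext, PseudoexonRecord


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class SiteRelativePosition:
    """A splice-site-relative label such as A+32 or D+1."""

    site: str  # 'A' (acceptor) or 'D' (donor)
    offset: int  # never 0

    def __str__(self) -> str:
        return f"{self.site}{self.offset:+d}"


def _transcript_index(pos: CdnaPosition, context: GeneContext) -> int:
    """1-based position of the anchor along the spliced transcript."""
    if pos.anchor > 0:
        t = context.cds_start_offset + pos.anchor
    else:
        t = context.cds_start_offset + pos.anchor + 1
        if t < 1:
            raise CoordinateError(
                f"anchor c.{pos.anchor} lies 5' of the transcript start"
            )
    total = sum(e - s for s, e in context.exons)
    if t > total:
        raise CoordinateError(f"anchor c.{pos.anchor} beyond transcript end")
    return t


def _exon_of_transcript_index(t: int, context: GeneContext) -> tuple[int, int, int]:
    """Return (exon_index_0based, nt_into_exon_0based, genomic_position)."""
    acc = 0
    for i, (s, e) in enumerate(context.exons):
        n = e - s
        if t <= acc + n:
            k = t - acc - 1  # 0-based into the exon, transcript direction
            g = s + k if context.strand == "+" else e - 1 - k
            return i, k, g
        acc += n
    raise CoordinateError(f"transcript position {t} beyond transcript end")


def cdna_to_genomic(pos: CdnaPosition, context: GeneContext) -> int:
    """Map a cDNA position to a 0-based genomic coordinate.

    Intronic offsets are only meaningful from an exon-boundary anchor; an
    offset hanging off a mid-exon anchor raises :class:`CoordinateError`.
    """
    t = _transcript_index(pos, context)
    i, k, g = _exon_of_transcript_index(t, context)
    step = 1 if context.strand == "+" else -1
    if pos.offset == 0:
        return g
    s, e = context.exons[i]
    exon_len = e - s
    if pos.offset > 0:
        if k != exon_len - 1:
            raise CoordinateError(
                f"+{pos.offset} offset from non-donor-boundary anchor "
                f"c.{pos.anchor}"
            )
        if i == len(context.exons) - 1:
            raise CoordinateError("donor offset from the final exon")
        return g + step * pos.offset
    if k != 0:
        raise CoordinateError(
            f"{pos.offset} offset from non-acceptor-boundary anchor c.{pos.anchor}"
        )
    if i == 0:
        raise CoordinateError("acceptor offset from the first exon")
    return g + step * pos.offset


def genomic_to_cdna(g: int, context: GeneContext) -> CdnaPosition:
    """Inverse of :func:`cdna_to_genomic` for exonic and intronic positions.

    Intronic positions are labelled from the nearer exon boundary (ties go to
    the upstream donor, matching the usual reporting convention).
    """
    step = 1 if context.strand == "+" else -1

    def cdna_anchor_of(t: int) -> int:
        c = t - context.cds_start_offset
        return c if c >= 1 else c - 1

    acc = 0
    for i, (s, e) in enumerate(context.exons):
        lo, hi = (s, e)
        if lo <= g < hi:
            k = (g - lo) if context.strand == "+" else (hi - 1 - g)
            return CdnaPosition(cdna_anchor_of(acc + k + 1))
        acc += e - s
    # intronic: find the flanking exons in transcript order
    t_running = 0
    for i in range(len(context.exons) - 1):
        s1, e1 = context.exons[i]
        t_running += e1 - s1
        s2, e2 = context.exons[i + 1]
        if context.strand == "+":
            ilo, ihi = e1, s2
            if not ilo <= g < ihi:
                continue
            d_donor = g - ilo + 1
            d_acc = ihi - g
        else:
            ilo, ihi = e2, s1
            if not ilo <= g < ihi:
                continue
            d_donor = ihi - g
            d_acc = g - ilo + 1
        if d_donor <= d_acc:
            return CdnaPosition(cdna_anchor_of(t_running), d_donor)
        return CdnaPosition(cdna_anchor_of(t_running + 1), -d_acc)
    raise CoordinateError(f"genomic position {g} outside the transcript span")


def relative_to_pe(g: int, record: PseudoexonRecord) -> SiteRelativePosition:
    """Label a genomic position relative to a PE's acceptor and donor."""
    if record.strand == "+":
        # A+1 = pe_start; A-1 = pe_start - 1; D-1 = pe_end - 1; D+1 = pe_end
        a_off = g - record.pe_start + 1 if g >= record.pe_start else g - record.pe_start
        d_off = g - record.pe_end + 1 if g >= record.pe_end else g - record.pe_end
    else:
        # A+1 = pe_end - 1; A-1 = pe_end; D-1 = pe_start; D+1 = pe_start - 1
        a_off = record.pe_end - g if g <= record.pe_end - 1 else -(g - record.pe_end + 1)
        d_off = record.pe_start - g if g < record.pe_start else -(g - record.pe_start + 1)
    if abs(a_off) <= abs(d_off):
        return SiteRelativePosition("A", a_off)
    return SiteRelativePosition("D", d_off)


def pe_position_of(rel: SiteRelativePosition, record: PseudoexonRecord) -> int:
    """Reconstruct the genomic position a site-relative label refers to."""
    if record.strand == "+":
        if rel.site == "A":
            return record.pe_start + rel.offset - 1 if rel.offset > 0 else record.pe_start + rel.offset
        return record.pe_end + rel.offset - 1 if rel.offset > 0 else record.pe_end + rel.offset
    if rel.site == "A":
        return record.pe_end - rel.offset if rel.offset > 0 else record.pe_end - rel.offset - 1
    return record.pe_start - rel.offset if rel.offset > 0 else record.pe_start - rel.offset - 1
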