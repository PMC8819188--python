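"""Reading-frame, premature-termination, NMD and exon-status annotation.

Inclusion of a pseudoexon changes the spliced transcript: a PE whose length is
not a multiple of 3 shifts the downstream reading frame, and any in-frame stop
codon introduced by the PE (or by the shifted frame downstream of it) is a
premature termination codon (PTC). A PTC normally routes the transcript to
nonsense-mediated decay (NMD) unless it lies fewer than 55 nt upstream of the
final exon-exon junction (or in the last exon). PEs with splicing evidence in
normal cells are flagged as candidate poison exons (ORF-disrupting) or novel
canonical exons (ORF-preserving), and terminal pseudoexons are recognised by a
novel acceptor, no sense-strand canonical overlap, and a confirmed
polyadenylation site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .catalogue import validate_pseudoexon
from .model import GeneContext, PseudoexonRecord
from .sequences import SequenceSource, check_dna

NMD_ESCAPE_DISTANCE = 55
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class TranscriptEffect:
    frame_preserved: bool | None
    novel_stop: int | None  # nt into the PE of the stop codon's first base
    ptc_distance_to_final_junction: int | None
    nmd_predicted: bool
    poison_candidate: bool
    novel_exon_candidate: bool
    terminal_pe: bool

    def __post_init__(self) -> None:
        assert not (self.poison_candidate and self.novel_exon_candidate)


def frame_and_ptc(
    upstream_cds: str, pe_seq: str, downstream_cds: str
) -> tuple[bool, int | None, int | None]:
    """Scan for the first novel in-frame stop introduced by a PE.

    ``upstream_cds`` runs from the CDS start (its length sets the incoming
    phase); returns (frame_preserved, stop offset relative to the PE's first
    base or None, 0-based position of the stop codon's first base in the
    spliced CDS axis or None). With a preserved frame only codons overlapping
    the PE are novel; with a frameshift the scan continues into the downstream
    CDS until a stop or the sequence ends.
    """
    upstream_cds = check_dna(upstream_cds)
    pe_seq = check_dna(pe_seq)
    downstream_cds = check_dna(downstream_cds)
    frame_preserved = len(pe_seq) % 3 == 0
    full = upstream_cds + pe_seq + downstream_cds
    pe_lo = len(upstream_cds)
    pe_hi = pe_lo + len(pe_seq)
    for i in range(0, len(full) - 2, 3):
        if i + 3 <= pe_lo:
            continue  # codon entirely 5' of the PE: unchanged
        if frame_preserved and i >= pe_hi:
            break  # downstream codons are unchanged when the frame holds
        if full[i : i + 3] in STOP_CODONS:
            return frame_preserved, i - pe_lo, i
    return frame_preserved, None, None


def nmd_predicted(ptc_pos: int, final_junction_pos: int) -> bool:
    """The 55-nt rule on the spliced-transcript axis.

    ``ptc_pos`` is the position just 3' of the stop codon's last base and
    ``final_junction_pos`` the final exon-exon junction, both on the same
    spliced axis. A stop in the last exon (at or past the junction) escapes;
    a stop less than 55 nt upstream escapes; exactly 55 nt still triggers NMD.
    """
    if ptc_pos > final_junction_pos:
        return False
    return final_junction_pos - ptc_pos >= NMD_ESCAPE_DISTANCE


def spliced_transcript_parts(
    record: PseudoexonRecord, context: GeneContext, seqs: SequenceSource
) -> tuple[str, str, str, int]:
    """CDS split at the PE insertion point plus the final-junction position.

    Returns (upstream CDS, PE sequence, downstream CDS, final exon-exon
    junction position on the CDS-relative axis of the mutant transcript).
    """
    strand = context.strand
    exon_seqs = [seqs.fetch(context.chrom, s, e, strand) for s, e in context.exons]
    pe_seq = seqs.fetch(context.chrom, record.pe_start, record.pe_end, strand)
    i = record.intron_index  # PE spliced between exon i and exon i+1 (1-based)
    up_tx = "".join(exon_seqs[:i])
    down_tx = "".join(exon_seqs[i:])
    cds0 = context.cds_start_offset
    upstream_cds = up_tx[cds0:]
    # junction between the last two exons of the mutant transcript, measured
    # from the CDS start
    if record.is_terminal:
        final_junction = len(upstream_cds) + len(pe_seq)  # PE is the last exon
        down_tx = ""
    else:
        final_junction = (
            len(upstream_cds) + len(pe_seq) + len(down_tx) - len(exon_seqs[-1])
        )
    return upstream_cds, pe_seq, down_tx, final_junction


def annotate_effect(
    record: PseudoexonRecord,
    context: GeneContext,
    seqs: SequenceSource,
) -> TranscriptEffect:
    """Full transcript-level annotation for one catalogued PE."""
    if context.cds_start_offset is None:
        warnings.warn(
            f"{record.pe_id}: no CDS phase; frame fields unset", stacklevel=2
        )
        frame_preserved: bool | None = None
        stop_in_pe = ptc_pos = None
        nmd = False
    else:
        upstream, pe_seq, downstream, final_junction = spliced_transcript_parts(
            record, context, seqs
        )
        frame_preserved, stop_in_pe, ptc_start = frame_and_ptc(
            upstream, pe_seq, downstream
        )
        ptc_pos = None if ptc_start is None else ptc_start + 3
        nmd = nmd_predicted(ptc_pos, final_junction) if ptc_pos is not None else False

    orf_disrupted = (frame_preserved is False) or (stop_in_pe is not None)
    evidence = record.has_splice_evidence
    poison = evidence and orf_disrupted
    novel_exon = (
        evidence and frame_preserved is True and stop_in_pe is None
    )
    overlap_violations = [
        v
        for v in validate_pseudoexon(record, context, seqs)
        if v.kind in ("overlap", "adjacency")
    ]
    terminal = (
        record.is_terminal and record.polya_confirmed and not overlap_violations
    )
    return TranscriptEffect(
        frame_preserved=frame_preserved,
        novel_stop=stop_in_pe,
        ptc_distance_to_final_junction=(
            None
            if ptc_pos is None
            else final_junction - ptc_pos
        ),
        nmd_predicted=nmd,
        poison_candidate=poison,
        novel_exon_candidate=novel_exon,
        terminal_pe=terminal,
    )
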