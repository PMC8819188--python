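"""Synthetic loci, latent pseudoexons and implanted instigating mutations.

Each synthetic locus is a two-exon toy gene whose intron carries one latent
pseudoexon with the full anatomy the analysis relies on: a canonical-dinucleotide
acceptor (AG) behind a pyrimidine-rich tract, a branch-point adenosine inside
an AG-free zone bounded by an upstream AG, and a sub-consensus GT donor with
headroom for improvement. Mutations are implanted so that, under the packaged
toy models, exactly one classifier rule (and no earlier rule) fires -- the
implant category is the ground truth for recovery tests.

Catalogue-level defaults follow the published study conditions: a category mix
proportional to 210:53:14:37:35 over the five major mutation groups, a
transition:transversion ratio of 165:92, and a 15.7% normal-cell
splice-evidence rate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .catalogue import write_catalogue, write_contexts
from .classify import FlankingSubtype, MutationCategory
from .coords import genomic_to_cdna
from .model import (
    CatalogueEntry,
    GeneContext,
    InstigatingMutation,
    PseudoexonRecord,
)
from .motifs import ACCEPTOR_CONSENSUS, DONOR_CONSENSUS
from .sequences import revcomp

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TI = {"A": "G", "G": "A", "C": "T", "T": "C"}


class NotImplantableError(ValueError):
    """The requested category cannot be realised in this locus."""


_DEFAULT_MIX = {
    MutationCategory.DONOR_MOTIF: 210.0,
    MutationCategory.ACCEPTOR_MOTIF: 53.0,
    MutationCategory.BRANCHPOINT: 14.0,
    MutationCategory.INTERNAL_ESE_ESS: 37.0,
    # the distal group (35) mixes several mechanisms; simulated as definition
    # loss in the facing canonical exon plus proximal intronic changes
    MutationCategory.FLANKING_EXON_DEFINITION_LOSS: 35.0 * 0.6,
    MutationCategory.PROXIMAL_INTRONIC_MOTIF: 35.0 * 0.4,
}


@dataclass
class SimParams:
    """Generator settings; the defaults are the study conditions."""

    seed: int
    n_entries: int = 200
    category_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    ti_weight: float = 165.0
    tv_weight: float = 92.0
    evidence_rate: float = 0.157
    pe_length_range: tuple[int, int] = (50, 250)
    gc_content: float = 0.42
    intron_length_range: tuple[int, int] = (1800, 3000)
    exon_length: int = 120
    strands: tuple[str, ...] = ("+", "-")

    @property
    def p_transition(self) -> float:
        return self.ti_weight / (self.ti_weight + self.tv_weight)

    def mix_probabilities(self) -> tuple[list, np.ndarray]:
        cats = list(self.category_mix)
        w = np.array([self.category_mix[c] for c in cats], dtype=float)
        return cats, w / w.sum()


@dataclass
class Locus:
    """One synthetic gene with its latent PE (reference-strand sequence)."""

    chrom: str
    strand: str
    seq: str
    context: GeneContext
    record: PseudoexonRecord
    # transcript-axis landmarks (see _build_tx_locus)
    tx_len: int
    tx: dict

    def tx2g(self, p: int) -> int:
        """Transcript-axis base position -> reference-strand coordinate."""
        return p if self.strand == "+" else self.tx_len - 1 - p

    def tx_interval(self, s: int, e: int) -> tuple[int, int]:
        if self.strand == "+":
            return (s, e)
        return (self.tx_len - e, self.tx_len - s)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _scrub_ag(buf: np.ndarray, lo: int, hi: int) -> None:
    """Remove every AG dinucleotide whose A lies in [lo, hi)."""
    for i in range(lo, min(hi, len(buf) - 1)):
        if buf[i] == "A" and buf[i + 1] == "G":
            buf[i + 1] = "T"


def _draw_tv_partner(rng: np.random.Generator, ref: str) -> str:
    options = [b for b in "ACGT" if b != ref and b != _TI[ref]]
    return options[rng.integers(len(options))]


def generate_locus(
    params: SimParams, rng: np.random.Generator, index: int = 0
) -> Locus:
    """Build one synthetic locus with a latent, valid pseudoexon.

    The PE has donor dinucleotide GT and acceptor dinucleotide AG by
    construction, a planted branch-point heptamer ~25 nt from the acceptor, an
    AG-free zone bounded by an AG ~45 nt out, and designated "fixable"
    positions in the donor (+4) and acceptor (-3) windows whose planted
    reference base already encodes the transition/transversion draw for a
    later motif implant.
    """
    il = int(rng.integers(*params.intron_length_range))
    pe_max = min(params.pe_length_range[1], il - 1300)
    if pe_max < params.pe_length_range[0]:
        raise NotImplantableError("intron too short for the PE length range")
    pe_len = int(rng.integers(params.pe_length_range[0], pe_max + 1))
    ex = params.exon_length
    pad = 100
    e1 = (pad, pad + ex)
    intron = (e1[1], e1[1] + il)
    e2 = (intron[1], intron[1] + ex)
    L = e2[1] + pad
    buf = _random_seq(rng, L, params.gc_content)

    # canonical host-intron sites (strong)
    b1 = e1[1]
    buf[b1 - 3 : b1 + 6] = list(DONOR_CONSENSUS)
    b2 = e2[0]
    buf[b2 - 20 : b2 + 3] = list(ACCEPTOR_CONSENSUS)

    # place the PE with clearance for branch/proximal/facing geometry
    d5 = int(rng.integers(650, il - pe_len - 650 + 1))
    a_tx = intron[0] + d5  # first PE base
    d_tx = a_tx + pe_len  # first base after the PE (donor boundary)

    # PE acceptor: pyrimidine tract (4 depressed positions), AG core, and a
    # -3 base that is off-consensus but repairable
    tract = ["T"] * 17
    for off in (2, 6, 10, 14):
        tract[off] = "C"
    acc_ti = bool(rng.random() < params.p_transition)
    minus3 = "T" if acc_ti else ("A", "G")[rng.integers(2)]
    buf[a_tx - 20 : a_tx - 3] = tract
    buf[a_tx - 3] = minus3
    buf[a_tx - 2 : a_tx] = list("AG")
    buf[a_tx : a_tx + 3] = list("GTA")

    # PE donor: GT with two off-consensus intronic positions (+4 fixable)
    don_ti = bool(rng.random() < params.p_transition)
    plus4 = "G" if don_ti else ("C", "T")[rng.integers(2)]
    buf[d_tx - 3 : d_tx] = list("CAG")
    buf[d_tx : d_tx + 2] = list("GT")
    buf[d_tx + 2] = "A"
    buf[d_tx + 3] = plus4
    buf[d_tx + 4] = "G"
    buf[d_tx + 5] = "A"  # +6 off-consensus
    buf[d_tx + 6] = "C"  # D+7 pyrimidine (leaves the purine rule silent)

    # branch point 25 nt from the acceptor AG, inside the AG-free zone
    ag_anchor = a_tx - 2  # first base of the acceptor AG
    bp_tx = ag_anchor - 25
    buf[bp_tx - 5 : bp_tx + 2] = list("TACTAAC")
    # bounding AG 45 nt out, flanked by T to keep the destruction clean
    bound_tx = ag_anchor - 45  # the A of the bounding AG
    buf[bound_tx - 1] = "T"
    buf[bound_tx : bound_tx + 2] = list("AG")
    buf[bound_tx + 2] = "T"
    _scrub_ag(buf, bound_tx + 2, ag_anchor - 1)
    # clear a stretch beyond the bound so destroying it visibly grows the zone
    _scrub_ag(buf, bound_tx - 60, bound_tx - 1)

    pa_tx = e2[1] + 30  # polyadenylation site in the 3' flank
    tx_seq = "".join(buf)

    strand = params.strands[int(rng.integers(len(params.strands)))]
    gene = f"SYN{index:04d}"
    chrom = f"chr_{gene}"
    if strand == "+":
        seq = tx_seq
        exons = [e1, e2]
        pe_iv = (a_tx, d_tx)
        pa = [pa_tx]
    else:
        seq = revcomp(tx_seq)
        conv = lambda iv: (L - iv[1], L - iv[0])
        exons = [conv(e1), conv(e2)]
        pe_iv = conv((a_tx, d_tx))
        pa = [L - 1 - pa_tx]
    context = GeneContext(
        gene_symbol=gene,
        transcript_id=f"SYN_T{index:04d}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start_offset=0,
        polyadenylation_sites=pa,
    )
    record = PseudoexonRecord(
        pe_id=f"{gene}-1-1",
        gene_context=context,
        intron_index=1,
        pe_start=pe_iv[0],
        pe_end=pe_iv[1],
    )
    tx = {
        "exon1": e1, "exon2": e2, "intron": intron,
        "a_tx": a_tx, "d_tx": d_tx, "bp_tx": bp_tx, "bound_tx": bound_tx,
        "acc_fix_ti": acc_ti, "don_fix_ti": don_ti, "pa_tx": pa_tx,
    }
    return Locus(chrom, strand, seq, context, record, L, tx)


def _snv(locus: Locus, tx_pos: int, tx_alt: str) -> InstigatingMutation:
    """Build an SNV at a transcript-axis position, with its cDNA name."""
    g = locus.tx2g(tx_pos)
    tx_ref = locus.seq[g] if locus.strand == "+" else _COMPLEMENT[locus.seq[g]]
    if tx_ref == tx_alt:
        raise ValueError("implant would be a no-op")
    cpos = genomic_to_cdna(g, locus.context)
    hgvs = f"c.{cpos}{tx_ref}>{tx_alt}"
    if locus.strand == "+":
        ref, alt = tx_ref, tx_alt
    else:
        ref, alt = _COMPLEMENT[tx_ref], _COMPLEMENT[tx_alt]
    return InstigatingMutation(hgvs, "SNV", g, g + 1, ref, alt, 1)


def _tx_base(locus: Locus, tx_pos: int) -> str:
    g = locus.tx2g(tx_pos)
    b = locus.seq[g]
    return b if locus.strand == "+" else _COMPLEMENT[b]


def implant_mutation(
    locus: Locus,
    category: MutationCategory,
    rng: np.random.Generator,
    p_ti: float | None = None,
) -> tuple[InstigatingMutation, MutationCategory, FlankingSubtype | None]:
    """Construct a mutation whose classifier rule for ``category`` -- and no
    earlier rule -- fires under the packaged toy models."""
    tx = locus.tx
    p_ti = 165.0 / 257.0 if p_ti is None else p_ti

    def draw_alt(ref: str) -> str:
        if rng.random() < p_ti:
            return _TI[ref]
        return _draw_tv_partner(rng, ref)

    if category == MutationCategory.DONOR_MOTIF:
        # repair the off-consensus +4 position toward the consensus A
        return _snv(locus, tx["d_tx"] + 3, "A"), category, None

    if category == MutationCategory.ACCEPTOR_MOTIF:
        # repair the -3 position toward the consensus C
        return _snv(locus, tx["a_tx"] - 3, "C"), category, None

    if category == MutationCategory.BRANCHPOINT:
        # destroy the bounding AG: the AG-exclusion zone strictly grows
        pos = tx["bound_tx"] + 1  # the G
        alt = draw_alt("G")
        return _snv(locus, pos, alt), category, None

    if category == MutationCategory.INTERNAL_ESE_ESS:
        lo, hi = tx["a_tx"] + 5, tx["d_tx"] - 10
        pos = int(rng.integers(lo, hi))
        ref = _tx_base(locus, pos)
        return _snv(locus, pos, draw_alt(ref)), category, None

    if category == MutationCategory.FLANKING_EXON_DEFINITION_LOSS:
        # break the facing canonical donor's +1 G
        pos = tx["exon1"][1]
        return (
            _snv(locus, pos, draw_alt("G")),
            category,
            FlankingSubtype.FACING_SITE_LOSS,
        )

    if category == MutationCategory.PROXIMAL_INTRONIC_MOTIF:
        side = rng.integers(2)
        d = int(rng.integers(130, 551))
        pos = tx["a_tx"] - d if side == 0 else tx["d_tx"] + 6 + d
        ref = _tx_base(locus, pos)
        return _snv(locus, pos, draw_alt(ref)), category, None

    if category == MutationCategory.POLYA_LOSS_READTHROUGH:
        if not locus.context.polyadenylation_sites:
            raise NotImplantableError("locus has no polyadenylation site")
        pa = locus.context.polyadenylation_sites[0]
        start, end = pa - 10, pa + 10
        return (
            InstigatingMutation(
                f"g.{start + 1}_{end}del", "deletion", start, end, "", "", end - start
            ),
            category,
            None,
        )

    if category == MutationCategory.INTERNAL_DELETION_JUXTAPOSITION:
        raise NotImplantableError(
            "synthetic introns are far below the large-deletion threshold"
        )
    raise NotImplantableError(f"no implant recipe for {category}")


@dataclass
class SyntheticCatalogue:
    entries: list[CatalogueEntry]
    contexts: dict[str, GeneContext]
    sequences: dict[str, str]
    truth: list[dict]
    params: SimParams

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_catalogue(self.entries, os.path.join(outdir, "catalogue.tsv"))
        write_contexts(self.contexts, os.path.join(outdir, "contexts.json"))
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write("#pe_id\tcategory\tsubtype\n")
            for t in self.truth:
                fh.write(
                    f"{t['pe_id']}\t{t['category'].value}\t"
                    f"{t['subtype'].value if t['subtype'] else ''}\n"
                )
        with open(os.path.join(outdir, "loci.fasta"), "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def generate_catalogue(params: SimParams) -> SyntheticCatalogue:
    """A full synthetic catalogue at the parameterised study conditions."""
    rng = np.random.default_rng(params.seed)
    cats, probs = params.mix_probabilities()
    entries: list[CatalogueEntry] = []
    contexts: dict[str, GeneContext] = {}
    sequences: dict[str, str] = {}
    truth: list[dict] = []
    for i in range(params.n_entries):
        locus = generate_locus(params, rng, index=i)
        cat = cats[int(rng.choice(len(cats), p=probs))]
        mut, category, subtype = implant_mutation(
            locus, cat, rng, params.p_transition
        )
        rec = locus.record
        if rng.random() < params.evidence_rate:
            which = rng.integers(3)
            rec.splice_evidence_acceptor = which in (0, 2)
            rec.splice_evidence_donor = which in (1, 2)
        entries.append(CatalogueEntry(record=rec, mutations=[mut]))
        contexts[locus.context.gene_symbol] = locus.context
        sequences[locus.chrom] = locus.seq
        truth.append(
            {"pe_id": rec.pe_id, "category": category, "subtype": subtype}
        )
    return SyntheticCatalogue(entries, contexts, sequences, truth, params)
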