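"""Rule-based classification of pseudoexon-instigating mutations.

Each catalogued (pseudoexon, mutation-set) pair is assigned to exactly one
category by an ordered decision procedure that mirrors how the mutations act:

1. donor-motif creation/enhancement (including the +7 pyrimidine-to-purine
   extension of the 9-mer window),
2. acceptor-motif enhancement at the -3..-1 core,
3. branch-point "circuit closing" (AGEZ growth, branch-score gain, a branch
   point moved closer, or a new tract pyrimidine),
4. PE-internal changes (very large deletions juxtaposing a latent splice-site
   pair; otherwise hexamer enhancer/silencer shifts),
5. distal mechanisms (loss of flanking canonical exon definition, sibling-PE
   activation, polyadenylation loss with readthrough, proximal intronic
   motifs),
6. unknown.

Motif-window mutations whose score change is within a negligibility threshold
fall through to later rules with a flag, reproducing how near-neutral splice
score changes are treated as internal/regulatory events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .branchpoint import (
    AgezReport,
    best_branchpoint,
    branchpoint_delta,
    BranchPointDelta,
    compute_agez,
)
from .hexamer import DeltaHx, HexamerTable, scan_motifs, total_hexamer_score, toy_hexamer_table, zero_hexamer_table
from .model import CatalogueEntry, GeneContext, InstigatingMutation, PseudoexonRecord
from .motifs import (
    MotifModel,
    toy_acceptor_model,
    toy_branch_model,
    toy_donor_model,
    zero_model,
)
from .sequences import SequenceSource, apply_mutation, revcomp

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PURINES = ("A", "G")
_PYRIMIDINES = ("C", "T")


class MutationCategory(str, Enum):
    DONOR_MOTIF = "DONOR_MOTIF"
    ACCEPTOR_MOTIF = "ACCEPTOR_MOTIF"
    BRANCHPOINT = "BRANCHPOINT"
    INTERNAL_ESE_ESS = "INTERNAL_ESE_ESS"
    INTERNAL_DELETION_JUXTAPOSITION = "INTERNAL_DELETION_JUXTAPOSITION"
    FLANKING_EXON_DEFINITION_LOSS = "FLANKING_EXON_DEFINITION_LOSS"
    SIBLING_PE_ACTIVATION = "SIBLING_PE_ACTIVATION"
    POLYA_LOSS_READTHROUGH = "POLYA_LOSS_READTHROUGH"
    PROXIMAL_INTRONIC_MOTIF = "PROXIMAL_INTRONIC_MOTIF"
    UNKNOWN = "UNKNOWN"


class FlankingSubtype(str, Enum):
    FACING_SITE_LOSS = "facing_site_loss"
    WHOLE_EXON_SKIP = "whole_exon_skip"
    FLANKING_ESE_LOSS = "flanking_ese_loss"
    NEXT_BUT_ONE = "next_but_one"


@dataclass
class ClassificationResult:
    category: MutationCategory
    subcategory: FlankingSubtype | None = None
    evidence: dict = field(default_factory=dict)
    negligible_motif_effect: bool = False

    @property
    def label(self) -> str:
        if self.subcategory is not None:
            return f"{self.category.value}:{self.subcategory.value}"
        return self.category.value


@dataclass
class ClassifierConfig:
    """Tunable thresholds of the decision procedure."""

    epsilon: float = 0.5  # bits; |delta| at or below this is "negligible"
    large_deletion_threshold: int = 10_000  # nt; internal juxtaposition rule
    proximal_window: int = 600  # nt from the PE for the proximal-intronic rule
    branch_search_window: int = 100  # nt 5' of the acceptor
    agez_scan_limit: int = 500
    allow_gc_donors: bool = False
    cryptic_site_threshold: float = 3.0  # bits; competing-site warning scan
    annotation_motifs: tuple[str, ...] = ()  # IUPAC motifs attached as evidence


@dataclass
class ModelSet:
    donor: MotifModel
    acceptor: MotifModel
    branch: MotifModel
    hexamer: HexamerTable

    @classmethod
    def packaged(cls) -> "ModelSet":
        return cls(
            toy_donor_model(), toy_acceptor_model(), toy_branch_model(),
            toy_hexamer_table(),
        )

    @classmethod
    def null(cls) -> "ModelSet":
        return cls(
            zero_model("donor"), zero_model("acceptor"), zero_model("branch"),
            zero_hexamer_table(),
        )


class MissingSequenceError(ValueError):
    """Sequence for a needed scoring window is unavailable; names the window."""


# ---------------------------------------------------------------------------
# window geometry (reference-strand spans; extraction is strand-aware)

def donor_span(strand: str, exon: tuple[int, int]) -> tuple[int, int]:
    s, e = exon
    return (e - 3, e + 6) if strand == "+" else (s - 6, s + 3)


def acceptor_span(strand: str, exon: tuple[int, int]) -> tuple[int, int]:
    s, e = exon
    return (s - 20, s + 3) if strand == "+" else (e - 3, e + 20)


def acceptor_core_span(strand: str, exon: tuple[int, int]) -> tuple[int, int]:
    """The A-3..A-1 intronic core where acceptor-motif SNVs concentrate."""
    s, e = exon
    return (s - 3, s) if strand == "+" else (e, e + 3)


def _shift(pos: int, muts: list[InstigatingMutation]) -> int:
    """Map a reference coordinate onto the mutant axis (non-overlapping muts)."""
    delta = 0
    for m in muts:
        change = len(m.alt_allele) - (m.genomic_end - m.genomic_start)
        if m.genomic_end <= pos:
            delta += change
        elif m.genomic_start < pos:
            delta += m.genomic_start - pos  # inside a deleted span
    return pos + delta


def _mutant_slice(
    ref_slice: str, slice_start: int, muts: list[InstigatingMutation]
) -> str:
    out = ref_slice
    for m in sorted(muts, key=lambda m: -m.genomic_start):
        out = apply_mutation(out, m, slice_start)
    return out


def site_delta(
    seqs: SequenceSource,
    chrom: str,
    strand: str,
    kind: str,
    exon: tuple[int, int],
    muts: list[InstigatingMutation],
    model: MotifModel,
) -> tuple[float, float]:
    """(before, after) motif score of one splice site under a mutation set.

    The window is re-anchored on the (possibly shifted) exon boundary in the
    mutant sequence, so indels that move the boundary are rescored on the
    reconstructed junction. Mutations that do not touch the window leave the
    score unchanged.
    """
    span_fn = donor_span if kind == "donor" else acceptor_span
    lo, hi = span_fn(strand, exon)
    relevant = [m for m in muts if m.overlaps(lo, hi)]
    slack = 10 + sum(m.size + len(m.alt_allele) for m in relevant)
    slo, shi = max(0, lo - slack), hi + slack
    try:
        ref_slice = seqs.fetch(chrom, slo, shi)
    except (KeyError, ValueError) as exc:
        raise MissingSequenceError(
            f"{kind} window [{lo},{hi}) on {chrom}: {exc}"
        ) from exc
    wt_window = ref_slice[lo - slo : hi - slo]
    if strand == "-":
        wt_window = revcomp(wt_window)
    before = model.score(wt_window)
    if not relevant:
        return before, before
    mut_slice = _mutant_slice(ref_slice, slo, relevant)
    s2 = _shift(exon[0], relevant)
    e2 = _shift(exon[1], relevant)
    mlo, mhi = span_fn(strand, (s2, e2))
    mut_window = mut_slice[mlo - slo : mhi - slo]
    if len(mut_window) != model.width:
        return before, before  # window destroyed by the length change
    if strand == "-":
        mut_window = revcomp(mut_window)
    return before, model.score(mut_window)


def _tx_alleles(m: InstigatingMutation, strand: str) -> tuple[str, str]:
    if strand == "+" or not m.is_snv:
        return m.ref_allele, m.alt_allele
    return _COMPLEMENT[m.ref_allele], _COMPLEMENT[m.alt_allele]


def _branch_region_span(record: PseudoexonRecord, window: int) -> tuple[int, int]:
    """Reference span of the `window` nt 5' of the PE acceptor AG."""
    if record.strand == "+":
        return (record.pe_start - 2 - window, record.pe_start - 2)
    return (record.pe_end + 2, record.pe_end + 2 + window)


def _upstream_of_acceptor(
    seqs: SequenceSource,
    record: PseudoexonRecord,
    muts: list[InstigatingMutation],
    scan: int,
) -> str:
    """Transcript-orientation sequence 5' of the acceptor AG (AG excluded),
    after applying ``muts``; 3' end abuts the AG."""
    chrom = record.gene_context.chrom
    strand = record.strand
    slack = 10 + sum(m.size + len(m.alt_allele) for m in muts)
    if strand == "+":
        anchor = record.pe_start - 2  # just 5' of the acceptor AG
        slo = max(0, anchor - scan - slack)
        ref_slice = seqs.fetch(chrom, slo, anchor + slack)
        a2 = _shift(anchor, muts) - slo
        mut_slice = _mutant_slice(ref_slice, slo, [m for m in muts if m.overlaps(slo, anchor + slack)])
        return mut_slice[max(0, a2 - scan) : a2]
    anchor = record.pe_end + 2
    shi = anchor + scan + slack
    slo = max(0, anchor - slack)
    ref_slice = seqs.fetch(chrom, slo, shi)
    a2 = _shift(anchor, muts) - slo
    mut_slice = _mutant_slice(ref_slice, slo, [m for m in muts if m.overlaps(slo, shi)])
    region = mut_slice[a2 : a2 + scan]
    return revcomp(region)


def _branch_state(
    seqs: SequenceSource,
    record: PseudoexonRecord,
    muts: list[InstigatingMutation],
    models: ModelSet,
    config: ClassifierConfig,
) -> tuple[AgezReport, float | None, int | None]:
    upstream = _upstream_of_acceptor(seqs, record, muts, config.agez_scan_limit)
    agez = compute_agez(upstream, config.agez_scan_limit)
    best = best_branchpoint(upstream, models.branch, config.branch_search_window)
    if best is None:
        return agez, None, None
    return agez, best.score, best.distance_to_acceptor


def circuit_rule(d: BranchPointDelta) -> bool:
    """The branch-point "close the circuit" test: the mutation enlarged the
    AGEZ, improved the best branch score, or moved a branch point closer.
    Pyrimidine gain deliberately does not count here -- it extends category
    membership, not the circuit."""
    return d.agez_increased or d.bps_increased or d.moved_closer


def _pe_delta_hx(
    seqs: SequenceSource,
    record: PseudoexonRecord,
    muts: list[InstigatingMutation],
    table: HexamerTable,
) -> DeltaHx:
    chrom = record.gene_context.chrom
    strand = record.strand
    relevant = [m for m in muts if m.overlaps(record.pe_start, record.pe_end)]
    slack = 10 + sum(m.size + len(m.alt_allele) for m in relevant)
    slo = max(0, record.pe_start - slack)
    shi = record.pe_end + slack
    ref_slice = seqs.fetch(chrom, slo, shi)
    wt = ref_slice[record.pe_start - slo : record.pe_end - slo]
    mut_slice = _mutant_slice(ref_slice, slo, relevant)
    s2 = _shift(record.pe_start, relevant) - slo
    e2 = _shift(record.pe_end, relevant) - slo
    mut = mut_slice[s2:e2]
    if strand == "-":
        wt, mut = revcomp(wt), revcomp(mut)
    return DeltaHx(total_hexamer_score(wt, table), total_hexamer_score(mut, table))


def _exon_delta_hx(seqs, context, exon, muts, table) -> DeltaHx:
    rec_like_start, rec_like_end = exon
    relevant = [m for m in muts if m.overlaps(rec_like_start, rec_like_end)]
    slack = 10 + sum(m.size + len(m.alt_allele) for m in relevant)
    slo = max(0, rec_like_start - slack)
    ref_slice = seqs.fetch(context.chrom, slo, rec_like_end + slack)
    wt = ref_slice[rec_like_start - slo : rec_like_end - slo]
    mut_slice = _mutant_slice(ref_slice, slo, relevant)
    s2 = _shift(rec_like_start, relevant) - slo
    e2 = _shift(rec_like_end, relevant) - slo
    mut = mut_slice[s2:e2]
    if context.strand == "-":
        wt, mut = revcomp(wt), revcomp(mut)
    return DeltaHx(total_hexamer_score(wt, table), total_hexamer_score(mut, table))


def _pe_distance(m: InstigatingMutation, record: PseudoexonRecord) -> int:
    """Shortest distance (nt) from a mutation's footprint to the PE."""
    if m.overlaps(record.pe_start, record.pe_end):
        return 0
    if m.genomic_end <= record.pe_start:
        return record.pe_start - m.genomic_end + 1
    return m.genomic_start - record.pe_end + 1


def classify_mutation(
    entry: CatalogueEntry,
    context: GeneContext,
    seqs: SequenceSource,
    models: ModelSet,
    config: ClassifierConfig | None = None,
    siblings: list[CatalogueEntry] | None = None,
) -> ClassificationResult:
    """Assign one catalogue entry to a mutation category with evidence."""
    config = config or ClassifierConfig()
    rec = entry.record
    muts = entry.mutations
    strand = rec.strand
    chrom = context.chrom
    if not muts:
        return ClassificationResult(MutationCategory.UNKNOWN, evidence={})
    negligible = False
    pe_exon = (rec.pe_start, rec.pe_end)

    # --- rule 1: donor motif -----------------------------------------------
    d_lo, d_hi = donor_span(strand, pe_exon)
    if any(m.overlaps(d_lo, d_hi) for m in muts):
        before, after = site_delta(
            seqs, chrom, strand, "donor", pe_exon, muts, models.donor
        )
        delta = after - before
        if delta > config.epsilon:
            return ClassificationResult(
                MutationCategory.DONOR_MOTIF,
                evidence={"donor_before": before, "donor_after": after,
                          "donor_delta": delta},
            )
        if abs(delta) <= config.epsilon:
            negligible = True
    # +7 purine-extension check (a qualitative donor rule, outside the 9-mer)
    from .coords import pe_position_of, SiteRelativePosition

    d_plus7 = pe_position_of(SiteRelativePosition("D", 7), rec)
    for m in muts:
        if m.is_snv and m.genomic_start == d_plus7:
            ref, alt = _tx_alleles(m, strand)
            if ref in _PYRIMIDINES and alt in _PURINES:
                return ClassificationResult(
                    MutationCategory.DONOR_MOTIF,
                    evidence={"donor_plus7_purine": f"{ref}>{alt} at D+7"},
                    negligible_motif_effect=negligible,
                )

    # --- rule 2: acceptor motif core ---------------------------------------
    c_lo, c_hi = acceptor_core_span(strand, pe_exon)
    a_lo, a_hi = acceptor_span(strand, pe_exon)
    if any(m.overlaps(a_lo, a_hi) for m in muts):
        before, after = site_delta(
            seqs, chrom, strand, "acceptor", pe_exon, muts, models.acceptor
        )
        delta = after - before
        if any(m.overlaps(c_lo, c_hi) for m in muts) and delta > config.epsilon:
            return ClassificationResult(
                MutationCategory.ACCEPTOR_MOTIF,
                evidence={"acceptor_before": before, "acceptor_after": after,
                          "acceptor_delta": delta},
                negligible_motif_effect=negligible,
            )
        if abs(delta) <= config.epsilon:
            negligible = True

    # --- rule 3: branch point ----------------------------------------------
    b_lo, b_hi = _branch_region_span(rec, config.branch_search_window)
    if any(m.overlaps(b_lo, b_hi) for m in muts):
        wt_state = _branch_state(seqs, rec, [], models, config)
        mut_state = _branch_state(seqs, rec, muts, models, config)
        d = branchpoint_delta(wt_state, mut_state, mutations=muts, strand=strand)
        if circuit_rule(d) or d.pyrimidine_gain:
            return ClassificationResult(
                MutationCategory.BRANCHPOINT,
                evidence={
                    "agez": (d.agez_before, d.agez_after),
                    "bps": (d.bps_before, d.bps_after),
                    "moved_closer": d.moved_closer,
                    "pyrimidine_gain": d.pyrimidine_gain,
                    "circuit": circuit_rule(d),
                },
                negligible_motif_effect=negligible,
            )

    # --- rule 4: inside the PE ---------------------------------------------
    inside = [m for m in muts if m.overlaps(rec.pe_start, rec.pe_end)]
    if inside:
        big_del = [
            m for m in inside
            if m.kind == "deletion" and m.size > config.large_deletion_threshold
        ]
        if big_del:
            return ClassificationResult(
                MutationCategory.INTERNAL_DELETION_JUXTAPOSITION,
                evidence={"deletion_size": big_del[0].size,
                          "note": "latent acceptor-donor pair juxtaposed"},
                negligible_motif_effect=negligible,
            )
        dhx = _pe_delta_hx(seqs, rec, muts, models.hexamer)
        if abs(dhx.delta) > 0:
            return ClassificationResult(
                MutationCategory.INTERNAL_ESE_ESS,
                evidence={"delta_hx": dhx.delta, "direction": dhx.direction()},
                negligible_motif_effect=negligible,
            )

    # --- rule 5: distal mechanisms -----------------------------------------
    i = rec.intron_index
    exons = context.exons
    up_exon = exons[i - 1] if i - 1 < len(exons) else None
    down_exon = exons[i] if i < len(exons) else None

    def _facing(kind: str, exon) -> ClassificationResult | None:
        span_fn = donor_span if kind == "donor" else acceptor_span
        lo, hi = span_fn(strand, exon)
        if not any(m.overlaps(lo, hi) for m in muts):
            return None
        model = models.donor if kind == "donor" else models.acceptor
        before, after = site_delta(seqs, chrom, strand, kind, exon, muts, model)
        if after - before < -config.epsilon:
            return ClassificationResult(
                MutationCategory.FLANKING_EXON_DEFINITION_LOSS,
                FlankingSubtype.FACING_SITE_LOSS,
                evidence={f"facing_{kind}_before": before,
                          f"facing_{kind}_after": after},
                negligible_motif_effect=negligible,
            )
        return None

    # facing sites: the upstream exon's donor and the downstream exon's acceptor
    if up_exon is not None:
        res = _facing("donor", up_exon)
        if res:
            return res
    if down_exon is not None:
        res = _facing("acceptor", down_exon)
        if res:
            return res

    # whole-exon skip: the flanking exon's *other* splice site is destroyed
    for exon, kind in ((up_exon, "acceptor"), (down_exon, "donor")):
        if exon is None:
            continue
        span_fn = donor_span if kind == "donor" else acceptor_span
        lo, hi = span_fn(strand, exon)
        if not any(m.overlaps(lo, hi) for m in muts):
            continue
        model = models.donor if kind == "donor" else models.acceptor
        before, after = site_delta(seqs, chrom, strand, kind, exon, muts, model)
        if after - before < -config.epsilon:
            return ClassificationResult(
                MutationCategory.FLANKING_EXON_DEFINITION_LOSS,
                FlankingSubtype.WHOLE_EXON_SKIP,
                evidence={f"flanking_exon_{kind}_loss": after - before},
                negligible_motif_effect=negligible,
            )

    # enhancer loss inside a flanking exon
    for exon in (up_exon, down_exon):
        if exon is None:
            continue
        if any(m.overlaps(*exon) for m in muts):
            dhx = _exon_delta_hx(seqs, context, exon, muts, models.hexamer)
            if dhx.delta < 0:
                return ClassificationResult(
                    MutationCategory.FLANKING_EXON_DEFINITION_LOSS,
                    FlankingSubtype.FLANKING_ESE_LOSS,
                    evidence={"flanking_delta_hx": dhx.delta},
                    negligible_motif_effect=negligible,
                )

    # next-but-one neighbour exons
    for j in (i - 2, i + 1):
        if 0 <= j < len(exons) and any(m.overlaps(*exons[j]) for m in muts):
            return ClassificationResult(
                MutationCategory.FLANKING_EXON_DEFINITION_LOSS,
                FlankingSubtype.NEXT_BUT_ONE,
                evidence={"next_but_one_exon": j + 1},
                negligible_motif_effect=negligible,
            )

    # sibling-PE activation: the mutation enhances a co-catalogued PE's motif
    for sib in siblings or []:
        srec = sib.record
        if srec.pe_id == rec.pe_id or srec.intron_index != rec.intron_index:
            continue
        s_exon = (srec.pe_start, srec.pe_end)
        for kind, model in (("donor", models.donor), ("acceptor", models.acceptor)):
            span_fn = donor_span if kind == "donor" else acceptor_span
            lo, hi = span_fn(strand, s_exon)
            if not any(m.overlaps(lo, hi) for m in muts):
                continue
            before, after = site_delta(
                seqs, chrom, strand, kind, s_exon, muts, model
            )
            if after - before > config.epsilon:
                return ClassificationResult(
                    MutationCategory.SIBLING_PE_ACTIVATION,
                    evidence={"sibling": srec.pe_id, "site": kind,
                              "delta": after - before},
                    negligible_motif_effect=negligible,
                )

    # polyadenylation loss with readthrough
    pa = context.polyadenylation_sites
    if pa:
        for m in muts:
            if m.kind == "deletion" and all(
                m.genomic_start <= p < m.genomic_end for p in pa
            ):
                return ClassificationResult(
                    MutationCategory.POLYA_LOSS_READTHROUGH,
                    evidence={"deleted_polya_sites": len(pa)},
                    negligible_motif_effect=negligible,
                )

    # proximal intronic motifs: same intron, beyond all motif windows
    try:
        intron = context.intron(i)
    except Exception:
        intron = None
    if intron is not None:
        ilo, ihi = min(intron), max(intron)
        for m in muts:
            if not m.overlaps(ilo, ihi):
                continue
            dist = _pe_distance(m, rec)
            if 0 < dist <= config.proximal_window:
                ev: dict = {"distance_to_pe": dist}
                if config.annotation_motifs:
                    lo2 = max(0, m.genomic_start - 10)
                    region = seqs.fetch(chrom, lo2, m.genomic_end + 10)
                    mut_region = _mutant_slice(
                        region, lo2, [m]
                    )
                    if strand == "-":
                        mut_region = revcomp(mut_region)
                    ev["motif_hits"] = scan_motifs(
                        mut_region, list(config.annotation_motifs)
                    )
                return ClassificationResult(
                    MutationCategory.PROXIMAL_INTRONIC_MOTIF,
                    evidence=ev,
                    negligible_motif_effect=negligible,
                )

    return ClassificationResult(
        MutationCategory.UNKNOWN, evidence={}, negligible_motif_effect=negligible
    )


def batch_classify(
    entries: list[CatalogueEntry],
    contexts: dict[str, GeneContext],
    seqs: SequenceSource,
    models: ModelSet,
    config: ClassifierConfig | None = None,
) -> tuple[list[ClassificationResult], Counter, dict[str, str]]:
    """Classify a whole catalogue; deterministic and order-independent.

    Returns (results aligned with ``entries``, category tally, per-entry
    errors). Entries in the same gene and intron are offered to each other as
    candidate siblings. Errors are collected, not raised; failed entries are
    tallied as UNKNOWN.
    """
    config = config or ClassifierConfig()
    by_intron: dict[tuple[str, int], list[CatalogueEntry]] = {}
    for e in entries:
        key = (e.record.gene_context.gene_symbol, e.record.intron_index)
        by_intron.setdefault(key, []).append(e)
    results: list[ClassificationResult] = []
    errors: dict[str, str] = {}
    tally: Counter = Counter()
    for e in entries:
        gene = e.record.gene_context.gene_symbol
        context = e.record.gene_context
        sibs = [
            s for s in by_intron[(gene, e.record.intron_index)]
            if s.record.pe_id != e.record.pe_id
        ]
        try:
            res = classify_mutation(e, context, seqs, models, config, siblings=sibs)
        except Exception as exc:  # collected, not fatal
            errors[e.record.pe_id] = str(exc)
            res = ClassificationResult(
                MutationCategory.UNKNOWN, evidence={"error": str(exc)}
            )
        results.append(res)
        e.category = res
        tally[res.category] += 1
    return results, tally, errors
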