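"""Recursive-splice-site overlap and catalogue summary statistics.

Recursive splice sites (RSSes) are intronic positions used for stepwise intron
removal; a pseudoexon whose acceptor or donor boundary coincides with a
published RSS coordinate is evidence that the PE co-opts a functional splicing
element. Matching is exact-coordinate by default (published PE/RSS overlaps
are exact hits on the same assembly), with an optional tolerance for liftover
slop. Summary statistics cover category tallies, the positional spectrum of
splice-motif SNVs, the transition:transversion split, splice-evidence rates
and PE size ranges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassificationResult, MutationCategory
from .coords import relative_to_pe
from .model import CatalogueEntry, is_transition
from .motifs import ACCEPTOR_CONSENSUS, DONOR_CONSENSUS

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class RssSite:
    chrom: str
    position: int  # 0-based coordinate of the boundary base
    kind: str = "either"  # 'acceptor' | 'donor' | 'either'
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("RSS position must be >= 0")


def read_rss_sites(path: str, source: str = "", kind: str = "either") -> list[RssSite]:
    """Load an RSS coordinate set.

    Accepts BED3+ (chrom, start, end, ...; the position is the interval
    start) and a bare 2-column (chrom, pos) variant, both 0-based.
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed line {line!r}")
            sites.append(
                RssSite(fields[0], int(fields[1]), kind, source or path)
            )
    return sites


@dataclass(frozen=True)
class RssMatch:
    pe_id: str
    side: str  # 'acceptor' | 'donor'
    source: str
    rss_position: int


def match_rss(
    entries: list[CatalogueEntry],
    rss: list[RssSite],
    tolerance: int = 0,
) -> list[RssMatch]:
    """PE boundaries coinciding with RSS coordinates.

    A PE matches when the distance between one of its boundary bases (first
    base on the acceptor side, last base on the donor side) and an RSS
    position is at most ``tolerance`` and the RSS kind is compatible. Each
    (pe, side, source) pair is reported once; output order follows the entry
    list for determinism but carries no meaning.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    seen = set()
    out: list[RssMatch] = []
    by_chrom: dict[str, list[RssSite]] = {}
    for site in rss:
        by_chrom.setdefault(site.chrom, []).append(site)
    for e in entries:
        rec = e.record
        chrom = rec.gene_context.chrom
        for side, boundary in (
            ("acceptor", rec.acceptor_boundary),
            ("donor", rec.donor_boundary),
        ):
            for site in by_chrom.get(chrom, []):
                if site.kind not in ("either", side):
                    continue
                if abs(boundary - site.position) <= tolerance:
                    key = (rec.pe_id, side, site.source)
                    if key not in seen:
                        seen.add(key)
                        out.append(
                            RssMatch(rec.pe_id, side, site.source, site.position)
                        )
    return out


def associated_entries(
    entries: list[CatalogueEntry], matches: list[RssMatch]
) -> list[str]:
    """PE ids sharing a gene+intron with any coordinate-matched PE (sibling
    PE variants of an RSS-associated pseudoexon count as associated)."""
    matched_ids = {m.pe_id for m in matches}
    introns = {
        (e.record.gene_context.gene_symbol, e.record.intron_index)
        for e in entries
        if e.record.pe_id in matched_ids
    }
    return sorted(
        e.record.pe_id
        for e in entries
        if (e.record.gene_context.gene_symbol, e.record.intron_index) in introns
    )


# ---------------------------------------------------------------------------
# summary statistics

_DONOR_POSITIONS = list(range(-3, 0)) + list(range(1, 8))  # D-3..D+7
_ACCEPTOR_POSITIONS = list(range(-20, 0)) + list(range(1, 4))  # A-20..A+3

# modal consensus base per motif position (the +7 donor extension is a purine
# bias; A is the modal base there)
_DONOR_MODAL = {p: b for p, b in zip(list(range(-3, 0)) + list(range(1, 7)), DONOR_CONSENSUS)}
_DONOR_MODAL[7] = "A"
_ACCEPTOR_MODAL = {
    p: b for p, b in zip(_ACCEPTOR_POSITIONS, ACCEPTOR_CONSENSUS)
}


@dataclass
class PositionalHistogram:
    """SNV counts per motif position keyed by reference base, with an "Other"
    tier for alternates that are not the modal consensus base."""

    donor: dict[int, Counter] = field(
        default_factory=lambda: {p: Counter() for p in _DONOR_POSITIONS}
    )
    acceptor: dict[int, Counter] = field(
        default_factory=lambda: {p: Counter() for p in _ACCEPTOR_POSITIONS}
    )
    other: int = 0

    @property
    def total(self) -> int:
        return sum(
            sum(c.values()) for c in self.donor.values()
        ) + sum(sum(c.values()) for c in self.acceptor.values())


def _category_of(entry: CatalogueEntry):
    c = entry.category
    if isinstance(c, ClassificationResult):
        return c.category
    if isinstance(c, str):
        return c.split(":")[0]
    return None


def positional_snv_histogram(entries: list[CatalogueEntry]) -> PositionalHistogram:
    """Positional spectrum of donor/acceptor splice-motif SNVs.

    Only entries classified as donor- or acceptor-motif mutations contribute;
    positions are site-relative (A-20..A+3 and D-3..D+7) on the transcript
    strand, keyed by the transcript-strand reference base.
    """
    hist = PositionalHistogram()
    for e in entries:
        cat = _category_of(e)
        if cat not in (
            MutationCategory.DONOR_MOTIF,
            MutationCategory.ACCEPTOR_MOTIF,
            str(MutationCategory.DONOR_MOTIF.value),
            str(MutationCategory.ACCEPTOR_MOTIF.value),
        ):
            continue
        rec = e.record
        for m in e.mutations:
            if not m.is_snv:
                continue
            rel = relative_to_pe(m.genomic_start, rec)
            ref, alt = m.ref_allele, m.alt_allele
            if rec.strand == "-":
                ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            if cat in (MutationCategory.DONOR_MOTIF, "DONOR_MOTIF"):
                # donor positions: D-3..D+7 relative to the donor boundary
                if rel.site != "D" or rel.offset not in _DONOR_MODAL:
                    continue
                hist.donor[rel.offset][ref] += 1
                if alt != _DONOR_MODAL[rel.offset]:
                    hist.other += 1
            else:
                if rel.site != "A" or rel.offset not in _ACCEPTOR_MODAL:
                    continue
                hist.acceptor[rel.offset][ref] += 1
                if alt != _ACCEPTOR_MODAL[rel.offset]:
                    hist.other += 1
    return hist


@dataclass
class SummaryReport:
    n_entries: int
    category_tally: Counter
    histogram: PositionalHistogram
    transitions: int
    transversions: int
    evidence_count: int
    size_min: int | None
    size_median: float | None
    size_max: int | None

    @property
    def evidence_fraction(self) -> float:
        return self.evidence_count / self.n_entries if self.n_entries else 0.0

    @property
    def n_snvs(self) -> int:
        return self.transitions + self.transversions

    def to_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "category_tally": {
                (k.value if isinstance(k, MutationCategory) else str(k)): v
                for k, v in sorted(
                    self.category_tally.items(), key=lambda kv: str(kv[0])
                )
            },
            "transitions": self.transitions,
            "transversions": self.transversions,
            "evidence_count": self.evidence_count,
            "evidence_fraction": round(self.evidence_fraction, 4),
            "size_min": self.size_min,
            "size_median": self.size_median,
            "size_max": self.size_max,
        }


def summarize_catalogue(
    entries: list[CatalogueEntry],
    classifications: list[ClassificationResult] | None = None,
) -> SummaryReport:
    """Deterministic whole-catalogue summary."""
    if classifications is not None:
        for e, c in zip(entries, classifications):
            e.category = c
    tally: Counter = Counter()
    ti = tv = evidence = 0
    sizes = []
    for e in entries:
        cat = _category_of(e)
        if cat is not None:
            tally[cat] += 1
        if e.record.has_splice_evidence:
            evidence += 1
        sizes.append(e.record.length)
        for m in e.mutations:
            if m.is_snv:
                if is_transition(m.ref_allele, m.alt_allele):
                    ti += 1
                else:
                    tv += 1
    return SummaryReport(
        n_entries=len(entries),
        category_tally=tally,
        histogram=positional_snv_histogram(entries),
        transitions=ti,
        transversions=tv,
        evidence_count=evidence,
        size_min=min(sizes) if sizes else None,
        size_median=float(np.median(sizes)) if sizes else None,
        size_max=max(sizes) if sizes else None,
    )
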