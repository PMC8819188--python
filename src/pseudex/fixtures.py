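"""Packaged reference fixtures: the curated branch-point mutation table and
the recursive-splice-site overlap table.

``table1`` holds the 14 catalogued branch-point-enhancing mutations with their
AGEZ sizes, maximum branch-point scores (before -> after where the value
changed), moved-closer annotations and tract-pyrimidine-gain flags. ``table2``
holds the 8 pseudoexon variants whose splice sites coincide with 7 confirmed
intronic recursive splice sites, with their printed 1-based GRCh38 coordinates
and maximum-entropy scores. Values are encoded exactly as published; scores in
these tables are consumed as data, never recomputed here.

The gene contexts attached to the table2 catalogue entries are synthetic
scaffolds (flanking exons at placeholder positions) because the real
transcript annotations are external inputs; PE coordinates, strands and
chromosomes are the published ones.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .branchpoint import BranchPointDelta
from .model import CatalogueEntry, GeneContext, PseudoexonRecord
from .overlap import RssSite


@dataclass(frozen=True)
class Table1Row:
    pe_id: str
    gene: str
    intron: int
    mutations: tuple[str, ...]
    agez_before: int
    agez_after: int
    bps_before: float
    bps_after: float
    moved_closer: bool
    pyr_snv: bool | None  # None for deletions (flag inapplicable)

    def to_delta(self) -> BranchPointDelta:
        return BranchPointDelta(
            agez_before=self.agez_before,
            agez_after=self.agez_after,
            bps_before=self.bps_before,
            bps_after=self.bps_after,
            moved_closer=self.moved_closer,
            pyrimidine_gain=bool(self.pyr_snv),
        )


@dataclass(frozen=True)
class Table2Row:
    pe_id: str
    gene: str
    chrom: str
    strand: str
    intron: int
    start: int  # printed, 1-based inclusive
    end: int
    size: int
    mutation: str
    site_label: str
    me_a_before: float | None
    me_a_after: float | None
    me_d_before: float | None
    me_d_after: float | None
    rss_side: str  # 'acceptor' | 'donor' | 'none'
    rss_coord: int | None  # printed, 1-based
    pe_source: str
    rss_source: str

    @property
    def pe_start(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def pe_end(self) -> int:
        return self.end


def _read_rows(name: str) -> list[dict[str, str]]:
    path = resources.files("pseudex.data").joinpath(name)
    with path.open() as fh:
        first = fh.readline().lstrip("#").strip().split("\t")
        reader = csv.DictReader(fh, fieldnames=first, delimiter="\t")
        return list(reader)


def _opt_float(v: str) -> float | None:
    v = v.strip()
    return float(v) if v else None


def table1_rows() -> list[Table1Row]:
    out = []
    for r in _read_rows("table1.tsv"):
        pyr = r["pyr_snv"].strip()
        out.append(
            Table1Row(
                pe_id=f"{r['gene']}-{r['intron']}-{r['variant']}",
                gene=r["gene"],
                intron=int(r["intron"]),
                mutations=tuple(r["mutations"].split(";")),
                agez_before=int(r["agez_before"]),
                agez_after=int(r["agez_after"]),
                bps_before=float(r["bps_before"]),
                bps_after=float(r["bps_after"]),
                moved_closer=r["moved_closer"].strip() == "1",
                pyr_snv=None if pyr == "NA" else pyr == "Yes",
            )
        )
    return out


def table2_rows() -> list[Table2Row]:
    out = []
    for r in _read_rows("table2.tsv"):
        rss = r["rss_coord"].strip()
        out.append(
            Table2Row(
                pe_id=f"{r['gene']}-{r['intron']}-{r['variant']}",
                gene=r["gene"],
                chrom=r["chrom"],
                strand=r["strand"],
                intron=int(r["intron"]),
                start=int(r["start"]),
                end=int(r["end"]),
                size=int(r["size"]),
                mutation=r["mutation"],
                site_label=r["site_label"],
                me_a_before=_opt_float(r["me_a_before"]),
                me_a_after=_opt_float(r["me_a_after"]),
                me_d_before=_opt_float(r["me_d_before"]),
                me_d_after=_opt_float(r["me_d_after"]),
                rss_side=r["rss_side"],
                rss_coord=int(rss) if rss else None,
                pe_source=r["pe_source"],
                rss_source=r["rss_source"],
            )
        )
    return out


def load_fixtures(name: str):
    """Structured rows of a packaged fixture table ('table1' or 'table2')."""
    if name == "table1":
        return table1_rows()
    if name == "table2":
        return table2_rows()
    raise ValueError(f"unknown fixture {name!r} (expected 'table1' or 'table2')")


def table1_deltas() -> list[tuple[str, BranchPointDelta]]:
    """The curated branch-point rows as before/after delta records."""
    return [(r.pe_id, r.to_delta()) for r in table1_rows()]


def _synthetic_context(row: Table2Row) -> GeneContext:
    """Placeholder transcript scaffold around a published PE interval.

    Synthetic: flanking exon positions are invented (the real annotations are
    external); chromosome, strand and PE coordinates are the published ones.
    """
    lo, hi = row.pe_start, row.pe_end
    exon_a = (lo - 1500, lo - 1400)
    exon_b = (hi + 1400, hi + 1500)
    exons = [exon_a, exon_b] if row.strand == "+" else [exon_b, exon_a]
    # pad the exon list so the PE's intron index exists
    n_lead = row.intron - 1
    lead = []
    for k in range(n_lead):
        off = (n_lead - k) * 300
        if row.strand == "+":
            lead.append((exon_a[0] - off - 100, exon_a[0] - off))
        else:
            lead.append((exon_b[1] + off, exon_b[1] + off + 100))
    exons = lead + exons
    return GeneContext(
        gene_symbol=row.gene,
        transcript_id="synthetic",
        chrom=row.chrom,
        strand=row.strand,
        exons=exons,
        cds_start_offset=0,
    )


def table2_entries() -> list[CatalogueEntry]:
    """The 8 RSS-associated PE variants as catalogue entries."""
    entries = []
    for row in table2_rows():
        context = _synthetic_context(row)
        record = PseudoexonRecord(
            pe_id=row.pe_id,
            gene_context=context,
            intron_index=row.intron,
            pe_start=row.pe_start,
            pe_end=row.pe_end,
            splice_evidence_acceptor=row.rss_side == "acceptor",
            splice_evidence_donor=row.rss_side == "donor",
            cell_types=[c for c in row.pe_source.split(";") if c],
        )
        entries.append(CatalogueEntry(record=record, mutations=[]))
    return entries


def table2_rss_sites() -> list[RssSite]:
    """The 7 confirmed recursive splice sites (0-based positions)."""
    sites = []
    seen = set()
    for row in table2_rows():
        if row.rss_coord is None:
            continue
        key = (row.chrom, row.rss_coord - 1)
        if key in seen:
            continue
        seen.add(key)
        sites.append(
            RssSite(row.chrom, row.rss_coord - 1, row.rss_side, row.rss_source)
        )
    return sites
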