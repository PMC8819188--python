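"""Catalogue I/O, pseudoexon ID assignment, and definition-based validation.

The catalogue is a tab-separated table with a ``#``-prefixed header; one row
per PE variant, mutations ";"-joined as cDNA variant strings, booleans as 0/1.
Gene contexts (exon structures) are a separate JSON document so the catalogue
stays a flat, diffable table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

from . import hgvs
from .coords import cdna_to_genomic
from .model import (
    CatalogueEntry,
    GeneContext,
    InstigatingMutation,
    PseudoexonRecord,
    ValidationError,
)
from .sequences import SequenceSource

COLUMNS = [
    "pe_id", "gene", "transcript", "chrom", "strand", "pe_start", "pe_end",
    "acceptor_dinuc", "donor_dinuc", "mutations",
    "splice_evidence_acceptor", "splice_evidence_donor",
    "is_terminal", "polya_confirmed", "frame_preserving", "category",
    "cell_types", "citations",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class CatalogueFormatError(ValueError):
    """A malformed catalogue row; names the row and column."""


def mutation_from_hgvs(s: str, context: GeneContext) -> InstigatingMutation:
    """Parse a cDNA variant string and anchor it on the genome."""
    v = hgvs.parse_cdna_variant(s)
    strand = context.strand

    def conv(allele: str) -> str:
        if strand == "+" or not allele:
            return allele
        return "".join(_COMPLEMENT[b] for b in reversed(allele))

    g1 = cdna_to_genomic(v.start, context)
    if v.kind == "SNV":
        return InstigatingMutation(s, "SNV", g1, g1 + 1, conv(v.ref), conv(v.alt), 1)
    g2 = cdna_to_genomic(v.end, context) if v.end is not None else g1
    lo, hi = min(g1, g2), max(g1, g2)
    if v.kind == "insertion":
        # inserted between the two flanking bases; on the reference axis the
        # insertion point sits just after the lower coordinate
        point = hi
        return InstigatingMutation(
            s, "insertion", point, point, "", conv(v.alt), v.size or len(v.alt)
        )
    span = hi - lo + 1
    size = v.size or span
    if v.kind == "deletion" and v.end is None and size > 1:
        # legacy size-suffixed deletion whose range could not be normalised
        hi = lo + size - 1
        span = size
    if v.kind == "deletion" and size != span:
        raise CatalogueFormatError(
            f"{s}: deletion size {size} inconsistent with span {span}"
        )
    kind = v.kind
    return InstigatingMutation(s, kind, lo, hi + 1, conv(v.ref), conv(v.alt), size)


def _parse_bool(value: str) -> bool:
    return value.strip() in ("1", "true", "True", "yes")


def _parse_list(value: str) -> list[str]:
    value = value.strip()
    return [x for x in value.split(";") if x] if value else []


def read_catalogue(path: str, contexts: dict[str, GeneContext]) -> list[CatalogueEntry]:
    """Read a catalogue TSV; every referenced gene must be in ``contexts``."""
    entries: list[CatalogueEntry] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip().split("\t")
                continue
            if header is None:
                raise CatalogueFormatError(f"{path}: missing '#' header line")
            fields = line.split("\t")
            if len(fields) != len(header):
                raise CatalogueFormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            try:
                entries.append(_entry_from_row(row, contexts))
            except (ValidationError, ValueError, KeyError) as exc:
                raise CatalogueFormatError(f"{path}:{lineno}: {exc}") from exc
    return entries


def _entry_from_row(row: dict[str, str], contexts: dict[str, GeneContext]) -> CatalogueEntry:
    gene = row["gene"]
    if gene not in contexts:
        raise CatalogueFormatError(f"unknown gene {gene!r} (no context supplied)")
    context = contexts[gene]
    pe_id = row["pe_id"]
    intron_index = _infer_intron_index(pe_id)
    record = PseudoexonRecord(
        pe_id=pe_id,
        gene_context=context,
        intron_index=intron_index,
        pe_start=int(row["pe_start"]),
        pe_end=int(row["pe_end"]),
        acceptor_dinuc=row.get("acceptor_dinuc", "AG") or "AG",
        donor_dinuc=row.get("donor_dinuc", "GT") or "GT",
        is_terminal=_parse_bool(row.get("is_terminal", "0")),
        polya_confirmed=_parse_bool(row.get("polya_confirmed", "0")),
        splice_evidence_acceptor=_parse_bool(row.get("splice_evidence_acceptor", "0")),
        splice_evidence_donor=_parse_bool(row.get("splice_evidence_donor", "0")),
        cell_types=_parse_list(row.get("cell_types", "")),
        citations=_parse_list(row.get("citations", "")),
    )
    mutations = [
        mutation_from_hgvs(s, context) for s in _parse_list(row.get("mutations", ""))
    ]
    fp = row.get("frame_preserving", "").strip()
    entry = CatalogueEntry(
        record=record,
        mutations=mutations,
        category=row.get("category", "").strip() or None,
        frame_preserving=_parse_bool(fp) if fp else None,
    )
    return entry


def _infer_intron_index(pe_id: str) -> int:
    parts = pe_id.split("-")
    try:
        return int(parts[-2])
    except (IndexError, ValueError):
        raise CatalogueFormatError(f"cannot infer intron index from pe_id {pe_id!r}")


def write_catalogue(entries: list[CatalogueEntry], path: str) -> None:
    """Write entries as TSV; ``read_catalogue`` round-trips field-for-field."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(COLUMNS) + "\n")
        for e in entries:
            r = e.record
            category = e.category
            if category is not None and not isinstance(category, str):
                category = getattr(category, "label", str(category))
            fields = [
                r.pe_id,
                r.gene_context.gene_symbol,
                r.gene_context.transcript_id,
                r.gene_context.chrom,
                r.gene_context.strand,
                str(r.pe_start),
                str(r.pe_end),
                r.acceptor_dinuc,
                r.donor_dinuc,
                ";".join(m.hgvs_cdna for m in e.mutations),
                str(int(r.splice_evidence_acceptor)),
                str(int(r.splice_evidence_donor)),
                str(int(r.is_terminal)),
                str(int(r.polya_confirmed)),
                "" if e.frame_preserving is None else str(int(e.frame_preserving)),
                category or "",
                ";".join(r.cell_types),
                ";".join(r.citations),
            ]
            fh.write("\t".join(fields) + "\n")


def assign_pe_id(
    gene: str,
    intron_index: int,
    new_record: PseudoexonRecord,
    existing: list[PseudoexonRecord],
) -> str:
    """Assign the next unique PE ID within one gene+intron.

    A new PE sharing an acceptor or donor genomic boundary with an existing
    numbered PE reuses that number with the next letter suffix; the existing
    sharer is renamed in place to gain the letter "a" if it had none.
    Otherwise the next free number (no letter) is used. Deterministic given
    insertion order, and idempotent over an already-IDed catalogue.
    """
    if intron_index < 1:
        raise ValidationError("intron_index must be >= 1")
    import re as _re

    def parse_id(pe_id: str) -> tuple[int, str]:
        m = _re.match(r"^.*-(\d+)([a-z]?)$", pe_id)
        if not m:
            raise ValidationError(f"existing record has malformed id {pe_id!r}")
        return int(m.group(1)), m.group(2)

    for rec in existing:
        if (
            rec.acceptor_boundary == new_record.acceptor_boundary
            or rec.donor_boundary == new_record.donor_boundary
        ):
            number, letter = parse_id(rec.pe_id)
            group = [r for r in existing if parse_id(r.pe_id)[0] == number]
            letters = sorted(parse_id(r.pe_id)[1] for r in group)
            if letters == [""]:
                rec.pe_id = f"{gene}-{intron_index}-{number}a"
                next_letter = "b"
            else:
                next_letter = chr(ord(max(l for l in letters if l)) + 1)
            return f"{gene}-{intron_index}-{number}{next_letter}"
    numbers = {parse_id(r.pe_id)[0] for r in existing}
    n = 1
    while n in numbers:
        n += 1
    return f"{gene}-{intron_index}-{n}"


@dataclass(frozen=True)
class Violation:
    kind: str  # 'overlap' | 'adjacency' | 'duplication'
    message: str


def validate_pseudoexon(
    record: PseudoexonRecord,
    context: GeneContext,
    seqs: SequenceSource | None = None,
) -> list[Violation]:
    """Check the defining constraints of a pseudoexon.

    A PE must not overlap, adjoin (share a boundary coordinate with), or
    exactly duplicate the sense-strand sequence of any canonical exon.
    Antisense overlap is permitted. The duplication check needs sequence
    access and is skipped with a warning when none is given.
    """
    violations: list[Violation] = []
    for i, (s, e) in enumerate(context.exons, start=1):
        if record.pe_start < e and s < record.pe_end:
            violations.append(
                Violation(
                    "overlap",
                    f"PE [{record.pe_start},{record.pe_end}) overlaps exon {i} "
                    f"[{s},{e})",
                )
            )
        elif record.pe_end == s or record.pe_start == e:
            violations.append(
                Violation(
                    "adjacency",
                    f"PE [{record.pe_start},{record.pe_end}) adjoins exon {i} "
                    f"[{s},{e})",
                )
            )
    if seqs is None:
        warnings.warn(
            f"{record.pe_id or 'PE'}: no sequence source; duplication check skipped",
            stacklevel=2,
        )
        return violations
    chrom = context.chrom
    pe_seq = seqs.fetch(chrom, record.pe_start, record.pe_end, context.strand)
    for i, (s, e) in enumerate(context.exons, start=1):
        if e - s != record.length:
            continue
        if seqs.fetch(chrom, s, e, context.strand) == pe_seq:
            violations.append(
                Violation(
                    "duplication",
                    f"PE sequence exactly duplicates exon {i} [{s},{e})",
                )
            )
    return violations


def write_contexts(contexts: dict[str, GeneContext], path: str) -> None:
    payload = {
        name: {
            "gene_symbol": c.gene_symbol,
            "transcript_id": c.transcript_id,
            "chrom": c.chrom,
            "strand": c.strand,
            "exons": [list(x) for x in c.exons],
            "cds_start_offset": c.cds_start_offset,
            "polyadenylation_sites": list(c.polyadenylation_sites),
        }
        for name, c in contexts.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_contexts(path: str) -> dict[str, GeneContext]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        name: GeneContext(
            gene_symbol=d["gene_symbol"],
            transcript_id=d["transcript_id"],
            chrom=d["chrom"],
            strand=d["strand"],
            exons=[tuple(x) for x in d["exons"]],
            cds_start_offset=d.get("cds_start_offset", 0),
            polyadenylation_sites=d.get("polyadenylation_sites", []),
        )
        for name, d in payload.items()
    }
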