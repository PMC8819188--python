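"""Parsing and formatting of the cDNA variant grammar used in PE reports.

Only the small variant grammar that actually occurs in pseudoexon catalogues
is supported: substitutions, deletions (range, bare, legacy ``del55``
size-suffixed and sequence-suffixed forms), insertions, deletion-insertions,
duplications and inversions, each with optional intronic ``+n``/``-n`` offsets
on either bound. Both the ASCII hyphen and the typographic minus sign are
accepted in offsets, and whitespace inside the string is ignored, because
published reports mix all of these.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


class HgvsParseError(ValueError):
    """Unparseable variant string; carries the offending token."""

    def __init__(self, message: str, token: str = "") -> None:
        super().__init__(message)
        self.token = token


@dataclass(frozen=True)
class CdnaPosition:
    """A cDNA coordinate: coding anchor plus optional intronic offset.

    ``anchor`` is 1-based into the CDS (negative for 5'UTR positions, where
    -1 is the base immediately 5' of the start codon; there is no zero).
    ``offset`` is 0 for exonic positions, +n for n nt 3' of the anchor exon's
    donor site, -n for n nt 5' of the anchor exon's acceptor site.
    """

    anchor: int
    offset: int = 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.anchor)
        return f"{self.anchor}{self.offset:+d}"


@dataclass(frozen=True)
class ParsedVariant:
    """The result of parsing one ``c.`` variant string."""

    start: CdnaPosition
    end: CdnaPosition | None
    kind: str  # SNV | deletion | insertion | delins | inversion
    ref: str
    alt: str
    size: int

    @property
    def span(self) -> tuple[CdnaPosition, CdnaPosition]:
        return (self.start, self.end if self.end is not None else self.start)


_POS_RE = r"(?P<{p}anchor>-?\d+)(?P<{p}offset>[+\-]\d+)?"
_VARIANT_RE = re.compile(
    r"^c\."
    + _POS_RE.format(p="")
    + r"(?:_" + _POS_RE.format(p="b") + r")?"
    + r"(?P<rest>.*)$"
)
_SNV_RE = re.compile(r"^(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_DEL_RE = re.compile(r"^del(?P<suffix>[ACGT]+|\d+)?$")
_DELINS_RE = re.compile(r"^del(?:[ACGT]+|\d+)?ins(?P<alt>[ACGT]+)$")
_INS_RE = re.compile(r"^ins(?P<alt>[ACGT]+)$")


def _normalise(s: str) -> str:
    # Unicode minus/dashes and stray spaces appear in published variant codes.
    return (
        s.replace("−", "-")
        .replace("–", "-")
        .replace("→", ">")
        .replace(" ", "")
    )


def _parse_pos(anchor: str, offset: str | None) -> CdnaPosition:
    a = int(anchor)
    if a == 0:
        raise HgvsParseError("cDNA position 0 does not exist", anchor)
    return CdnaPosition(a, int(offset) if offset else 0)


def parse_cdna_variant(s: str) -> ParsedVariant:
    """Parse a ``c.``-prefixed variant string.

    >>> v = parse_cdna_variant("c.3994-159A>G")
    >>> (v.start.anchor, v.start.offset, v.kind, v.ref, v.alt)
    (3994, -159, 'SNV', 'A', 'G')
    """
    raw = s
    s = _normalise(s)
    m = _VARIANT_RE.match(s)
    if not m or not s.startswith("c."):
        raise HgvsParseError(f"cannot parse variant {raw!r}", raw)
    start = _parse_pos(m.group("anchor"), m.group("offset"))
    end = None
    if m.group("banchor") is not None:
        end = _parse_pos(m.group("banchor"), m.group("boffset"))
    rest = m.group("rest")

    snv = _SNV_RE.match(rest)
    if snv:
        if end is not None:
            raise HgvsParseError(f"SNV with a range: {raw!r}", rest)
        return ParsedVariant(start, None, "SNV", snv["ref"], snv["alt"], 1)

    delins = _DELINS_RE.match(rest)
    if delins:
        size = _range_size(start, end)
        return ParsedVariant(start, end, "delins", "", delins["alt"], size)

    dele = _DEL_RE.match(rest)
    if dele:
        suffix = dele["suffix"]
        if suffix and suffix.isdigit():
            # legacy size-suffixed form, e.g. c.163+696del55: start given,
            # span implied -- normalise to a range at format time
            size = int(suffix)
            if end is None and size > 1:
                if start.offset != 0:
                    end = CdnaPosition(start.anchor, start.offset + size - 1)
                else:
                    end = CdnaPosition(start.anchor + size - 1)
            return ParsedVariant(start, end, "deletion", "", "", size)
        ref = suffix or ""
        size = len(ref) if ref else _range_size(start, end)
        return ParsedVariant(start, end, "deletion", ref, "", size)

    ins = _INS_RE.match(rest)
    if ins:
        return ParsedVariant(start, end, "insertion", "", ins["alt"], len(ins["alt"]))

    if rest == "dup":
        size = _range_size(start, end)
        return ParsedVariant(start, end, "insertion", "", "", size)

    if rest == "inv":
        return ParsedVariant(start, end, "inversion", "", "", _range_size(start, end))

    raise HgvsParseError(f"unsupported variant tail {rest!r} in {raw!r}", rest)


def _range_size(start: CdnaPosition, end: CdnaPosition | None) -> int:
    """Span of a range in nt, computable without a transcript only when both
    bounds share an anchor context (same exon, or same intron side)."""
    if end is None:
        return 1
    if start.anchor == end.anchor and start.offset != 0 and end.offset != 0:
        return abs(end.offset - start.offset) + 1
    if start.offset == 0 and end.offset == 0:
        return abs(end.anchor - start.anchor) + 1
    # mixed bounds (e.g. exonic-to-intronic): size needs the transcript map
    return 0


def format_variant(v: ParsedVariant) -> str:
    """Render back to a canonical string (legacy forms are normalised)."""
    pos = str(v.start)
    if v.end is not None:
        pos = f"{v.start}_{v.end}"
    if v.kind == "SNV":
        return f"c.{pos}{v.ref}>{v.alt}"
    if v.kind == "deletion":
        return f"c.{pos}del"
    if v.kind == "insertion":
        return f"c.{pos}ins{v.alt}" if v.alt else f"c.{pos}dup"
    if v.kind == "delins":
        return f"c.{pos}delins{v.alt}"
    if v.kind == "inversion":
        return f"c.{pos}inv"
    raise ValueError(f"unknown kind {v.kind!r}")
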