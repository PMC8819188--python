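# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open intervals on the reference (+)
strand, with strand an explicit flag; human-facing output (cDNA variant
strings, printed table coordinates) is 1-based. cDNA position `c.N+k` denotes
k nt into the intron 3′ of the anchor exon's donor and `c.N-k` k nt 5′ of its
acceptor; mapping an intronic offset from a non-boundary anchor is an error.
Intronic positions map back to cDNA from the nearer exon boundary, ties going
to the upstream donor.

Site-relative labels on a pseudoexon: **A+1** is the first PE base and **A−1**
the last intronic base 5′ of the acceptor; **D−1** is the last PE base and
**D+1** the first intronic base 3′ of the donor. A position admitting both an
A- and a D-relative label receives the one with the smaller absolute offset
(ties go to the acceptor side). This convention reproduces the labels used in
curated PE tables (a donor-creating SNV at the first downstream base is D+1;
an acceptor −3 SNV is A−3).

## Splice-motif scoring

Motif scores are log₂(model/background) in bits over fixed windows: donor
9-mer (exonic −3..−1, intronic +1..+6), acceptor 23-mer (intronic −20..−1,
exonic +1..+3). Two model families satisfy the contract:

* an **additive position-weight model** (sum of per-position weights). The
  packaged toy models weight +1 for the consensus base and −1 otherwise
  (donor consensus CAG|GTAAGT; acceptor: a pyrimidine tract, the yAG core and
  exonic GTT). They exist so analyses and tests are self-contained — they are
  not calibrated to any published scale;
* loaders for externally published **maximum-entropy tables**, consuming the
  published directory layout verbatim (`me2x5` for donors; `me2x3acc1..9`
  with the standard inclusion-exclusion decomposition for acceptors) and
  reproducing the published scoring arithmetic. Published web-tool scores are
  therefore reproduced only when the published tables are supplied; the
  package never silently approximates them, and curated table scores shipped
  as fixtures are treated as data, not recomputation targets.

The donor window deliberately stays a 9-mer. The +7 position, where canonical
donors show a purine bias, is handled as a separate qualitative check: a
pyrimidine→purine SNV at D+7 counts as a donor-motif event without widening
the scored window.

Candidate-site scans require the canonical dinucleotides (GT at +1..+2 for
donors — GC only behind an `allow_gc` flag — and AG at −2..−1 for acceptors)
unless the filter is disabled. Non-canonical acceptor dinucleotides are
characterised by their Hamming distance from AG; observed non-canonical PE
acceptors sit at distance ≤ 1 (the one-nucleotide rule).

Minor-spliceosome (U12) calls require both the conserved donor heptamer and a
branch motif near the partner acceptor. The published motif strings are
RNA-ambiguous, so both are configurable IUPAC patterns; the defaults read
them in DNA as `RTATCCT` (donor +1..+7) and `CCTTWAY` (branch), i.e. U→T with
the weakly specified positions left degenerate.

## Branch points and the AG-exclusion zone

The AGEZ is counted **strictly between** the bounding upstream AG and the
acceptor AG — neither dinucleotide included. Published AGEZ figures do not
state their endpoint convention, so curated values are consumed as fixture
data rather than recomputed. The default scan limit is 500 nt and the branch
search window 100 nt (catalogued branch-point mutations lie ≲90 nt from the
acceptor); both are configurable.

Branch candidates are adenosines scored over a 7-mer window with the branch A
fixed at position 6 of 7 (toy consensus TACTAAC). The published SVM branch
scorer is deliberately not replicated; its printed scores are inputs. The
**circuit rule** is: AGEZ increased, or best branch score increased, or a
branch point moved closer with its score not worse. Pyrimidine gain (an SNV
whose transcript-strand alternate is C/T, a crude proxy for polypyrimidine
tract/U2AF65 strengthening) extends branch-point *category membership* but
deliberately does not count toward the circuit rule, preserving the curated
table's 12-of-14 split.

## Hexamer regulatory scoring (ΔHx)

ΔHx is the mutant-minus-wild-type sum of a hexamer score table over all
overlapping 6-mers of the exon sequence. Whole-sequence subtraction is the
definition of record (it covers indels); the windowed shortcut for SNVs is
computed and asserted equal at run time. Directionality uses a tolerance of
exactly 0 by default (only the sign is interpreted). The scored sequence is
the PE/exon proper, without flanking intronic bases — published analyses do
not state whether terminal-SNV windows extended into the intron, and the
narrower choice is the reproducible one. The packaged toy table scores each
hexamer as a sum of distinct per-base values, which guarantees a nonzero ΔHx
for every substitution; published hexamer tables load from two-column
`HEXAMER<TAB>score` files.

## The classification procedure

Rules fire in a fixed order; the first hit wins. ε (negligible motif-score
change) defaults to 0.5 bits — the catalogued precedent treats a near-zero
acceptor change as "negligible" without quantifying it, so the threshold is
explicit and configurable. A motif-window mutation with |Δ| ≤ ε falls through
to later rules with a `negligible_motif_effect` flag (so an exonic A+3 SNV
with negligible acceptor change classifies as internal ESE/ESS).

1. donor: mutation in D−3..D+6 with Δdonor > ε, or pyrimidine→purine at D+7;
2. acceptor: mutation in A−3..A−1 with Δacceptor > ε (deeper tract positions
   fall to the branch-point rule, matching where acceptor SNVs concentrate);
3. branch point: mutation within the branch window 5′ of the acceptor and any
   of {AGEZ increased, branch score increased, moved closer, pyrimidine gain};
4. inside the PE: a deletion > 10 kb (the documented internal-juxtaposition
   cases) → internal deletion juxtaposition; otherwise |ΔHx| > 0 → internal
   ESE/ESS;
5. outside the PE: facing canonical site weakened (the upstream exon's donor
   or downstream exon's acceptor, Δ < −ε); flanking exon's far site destroyed
   (whole-exon skip); ΔHx < 0 inside a flanking exon; mutation in a
   next-but-one exon; a co-catalogued sibling PE's motif enhanced in the same
   intron; a deletion removing every transcript polyadenylation site; or a
   same-intron position within 600 nt of the PE (covers the catalogued
   26–581 nt proximal examples) → proximal intronic motif;
6. unknown.

Windows are re-anchored on the (possibly shifted) boundary in the mutant
sequence, so indels spanning a window are rescored on the reconstructed
junction; a length change that leaves no full-width window flags the site as
destroyed rather than scoring a partial window. Speculative trans-factor
mechanisms (FUS, hnRNP K, KHDRBS1 binding and splicing order) are out of
scope as decision inputs; IUPAC motif-scan hits can be attached to proximal
calls as annotations only.

## Transcript effects

Frame preservation is PE length divisible by 3. The novel-stop scan walks
codons of upstream-CDS + PE (+ downstream CDS when the frame shifts) and
reports the first stop whose codon overlaps the PE or lies downstream of a
frameshift. The NMD boundary is: a PTC escapes only when its end lies *fewer
than* 55 nt upstream of the final exon-exon junction (exactly 55 still
triggers NMD) or in the last exon. Poison-exon candidacy requires normal-cell
splice evidence at ≥1 site plus a disrupted ORF; novel-exon candidacy
requires evidence plus an intact frame and no novel stop; the two are
mutually exclusive by construction. Terminal-PE status requires the terminal
flag, a confirmed polyadenylation site, and no sense-strand canonical
overlap. Splice evidence is a catalogue input flag — the heterogeneous
EST/RNA-seq evidence behind it is not re-mined, and evidence tiers are
collapsed to one boolean per site.

## RSS overlap and statistics

RSS coordinate sets load from BED3 (position = interval start) or a bare
2-column chrom/pos variant, 0-based. A PE matches when a boundary base (first
base on the acceptor side, last on the donor side) is within `tolerance`
(default 0 — published overlaps are exact hits) of an RSS position of
compatible kind. Catalogue entries sharing a gene+intron with a matched PE
are reported separately as "associated": in the packaged curated table the
7 exact matches cover 7 distinct sites while 8 PE variants are associated,
because two variants share one intron. Transitions are A↔G / C↔T; the
positional SNV spectrum covers A−20..A+3 and D−3..D+7 keyed by
transcript-strand reference base, with alternates that are not the modal
consensus base tallied as "Other".

## Synthetic data

Each locus is a two-exon gene (120 nt exons, 100 nt pads, intron drawn from
1.8–3 kb) whose intron carries one latent PE (50–250 nt, ≥650 nt from either
intron end) with: a consensus-strong host donor and acceptor; a PE acceptor
AG behind a 17-nt pyrimidine tract with four depressed positions and an
off-consensus, repairable −3 base; a PE donor GT with repairable +4 and
depressed +6; a TACTAAC branch heptamer 25 nt from the acceptor inside a
scrubbed AG-free zone bounded by an AG 45 nt out (with a further 60 nt
scrubbed beyond it, so destroying the bound strictly grows the zone); a D+7
pyrimidine (keeping the purine rule silent unless implanted); and one
polyadenylation site 30 nt past the last exon. Strand is drawn uniformly and
minus-strand loci are stored reverse-complemented, exercising every
strand-aware path.

Implants are constructed so the target rule and no earlier rule fires: donor
= repair +4 toward consensus; acceptor = repair −3; branch point = destroy
the bounding AG; internal = any interior SNV (the per-base toy table makes
every substitution ΔHx-visible); flanking = break the facing donor's +1 G;
proximal = an SNV 130–550 nt from the PE beyond all windows. The
transition:transversion draw (p = 165/257) is encoded in the planted
reference base for the motif-repair implants and in the drawn alternate for
the rest. The distal group's 35/349 mass is split 60% flanking / 40%
proximal: the catalogued distal set mixes several mechanisms with no stated
per-mechanism rates, and these two are the deterministic, sequence-decidable
representatives. Internal deletion juxtaposition is not implantable at these
locus sizes (it needs a >10 kb deletion) and raises instead.

What the generator does **not** emulate: realistic human intron base
composition beyond GC content, transposable-element structure, multi-exon
genes with long-range splicing order effects, quantitative inclusion levels,
or mutations whose mechanism is genuinely ambiguous. Passing recovery tests
therefore shows the decision procedure is implemented and identifiable under
its own assumptions — not that real catalogues classify with the same
accuracy.

## Problem sizes and determinism

The generator is fully seed-deterministic (byte-identical output per seed).
Tests and the acceptance script use catalogues of up to 500 entries and
1000-entry evidence-rate checks, with binomial 3σ bounds for all stochastic
comparisons; the curated-table computations are exact and instantaneous.
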