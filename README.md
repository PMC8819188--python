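# pseudex

Characterisation of pathogenic **pseudoexons** (PEs) — intronic tracts that
are spliced into mature transcripts as though they were exons, usually after a
deep-intronic mutation. The package is aimed at splicing researchers and
variant curators who maintain catalogues of PE reports and want the derived
annotations recomputed reproducibly rather than by hand in spreadsheets.

## What it computes

Given a PE catalogue (TSV), gene contexts (exon structures, JSON) and
reference sequence (FASTA), `pseudex`:

* parses the instigating mutations from cDNA variant strings
  (`c.3994-159A>G`, `c.2113+461_2113+473del`, legacy `del55` forms, intronic
  offsets on either bound) and maps them between cDNA, genomic, and
  splice-site-relative coordinates (A±n / D±n, where A+1 is the first PE base
  and D+1 the first intronic base 3′ of the PE);
* scores donor (9-mer, −3..+6) and acceptor (23-mer, −20..+3) splice motifs in
  log₂-odds bits under pluggable models — a packaged additive position-weight
  model, or externally published maximum-entropy table directories consumed
  verbatim;
* measures the **AG-exclusion zone** (AGEZ) upstream of each acceptor, scans
  it for branch-point adenosines, and evaluates the branch-point **circuit
  rule**: a mutation "closes the circuit" when it enlarges the AGEZ, improves
  an in-range branch motif, or moves a branch point closer to the acceptor
  (with new tract pyrimidines as a fourth, weaker signal);
* computes hexamer enhancer/silencer deltas (ΔHx = mutant total − wild-type
  total over all overlapping 6-mers) and their gain/loss directionality;
* classifies every (PE, mutation-set) pair into a mechanistic taxonomy —
  donor motif, acceptor motif, branch point, internal ESE/ESS, internal
  deletion juxtaposition, flanking-exon definition loss (facing-site loss,
  whole-exon skip, flanking ESE loss, next-but-one), sibling-PE activation,
  polyadenylation loss with readthrough, proximal intronic motif, unknown —
  with an evidence trail for the fired rule;
* annotates transcript effects: reading frame, novel stop codons, the 55-nt
  NMD rule, poison-exon / novel-exon candidacy, terminal-PE status;
* overlaps PE splice-site boundaries with recursive-splice-site (RSS)
  coordinate sets (BED) and summarises catalogues (category tallies,
  positional SNV spectra, transition:transversion counts, splice-evidence
  rates, size ranges);
* generates fully deterministic synthetic catalogues — loci with latent PEs
  and implanted mutations of every category at a configurable mix — so the
  whole pipeline is testable without downloads.

## Worked example

```python
from pseudex import (SimParams, generate_catalogue, SequenceSource,
                     batch_classify, summarize_catalogue)
from pseudex.classify import ModelSet

cat = generate_catalogue(SimParams(seed=42, n_entries=500))
seqs = SequenceSource(cat.sequences)
results, tally, errors = batch_classify(
    cat.entries, cat.contexts, seqs, ModelSet.packaged())
print({k.value: v for k, v in tally.items()})
summary = summarize_catalogue(cat.entries, results)
print(summary.transitions, summary.transversions,
      round(summary.evidence_fraction, 3))
```

prints

```
{'DONOR_MOTIF': 316, 'ACCEPTOR_MOTIF': 64, 'INTERNAL_ESE_ESS': 52,
 'FLANKING_EXON_DEFINITION_LOSS': 34, 'BRANCHPOINT': 19,
 'PROXIMAL_INTRONIC_MOTIF': 15}
320 180 0.138
```

— 500 synthetic entries classified with zero errors; every implanted category
is recovered (the tally equals the generator's truth table), the
transition:transversion split (320:180 ≈ 1.78) matches the configured 165:92
ratio, and the splice-evidence fraction is within binomial noise of the
configured 15.7% rate.

The same stages are available from the shell:

```bash
pseudex simulate --n 200 --seed 7 --out-dir sim/
pseudex classify --catalogue sim/catalogue.tsv --contexts sim/contexts.json \
                 --fasta sim/loci.fasta --out sim/classified.tsv
pseudex stats --catalogue sim/classified.tsv --contexts sim/contexts.json
pseudex rss-overlap --catalogue sim/catalogue.tsv --contexts sim/contexts.json \
                    --rss sites.bed
```

## Layout

```
src/pseudex/
  model.py       domain types (gene context, PE record, mutation, entry)
  hgvs.py        cDNA variant grammar
  coords.py      cDNA <-> genomic <-> site-relative mapping
  motifs.py      splice-motif models, deltas, candidate-site scans
  maxent.py      published maximum-entropy table loaders
  branchpoint.py AGEZ, branch-point scan, circuit deltas
  hexamer.py     hexamer tables, delta-Hx, IUPAC motif scan
  catalogue.py   TSV/JSON I/O, PE ID assignment, validation
  classify.py    the ordered mutation-classification procedure
  effects.py     frame/PTC/NMD/poison/novel/terminal annotation
  overlap.py     RSS matching and summary statistics
  simulate.py    synthetic loci, implants, catalogues
  fixtures.py    packaged curated tables
  cli.py         click CLI (`pseudex`)
```

See `docs/methods.md` for the model conventions, thresholds and the
generator's scope and limitations.
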