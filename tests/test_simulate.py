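"""Synthetic-data generator: determinism, anatomy, mixes, fixture integrity."""

import hashlib

import numpy as np
import pytest

from pseudex.branchpoint import compute_agez
from pseudex.classify import MutationCategory
from pseudex.fixtures import load_fixtures, table1_rows, table2_rows
from pseudex.sequences import SequenceSource
from pseudex.simulate import (
    NotImplantableError,
    SimParams,
    generate_catalogue,
    generate_locus,
    implant_mutation,
)


class TestLocus:
    def test_same_seed_gives_identical_sequences(self):
        a = generate_catalogue(SimParams(seed=123, n_entries=5))
        b = generate_catalogue(SimParams(seed=123, n_entries=5))
        assert a.sequences == b.sequences

    def test_different_seeds_differ(self):
        a = generate_catalogue(SimParams(seed=1, n_entries=2))
        b = generate_catalogue(SimParams(seed=2, n_entries=2))
        assert a.sequences != b.sequences

    def test_gc_content_tracks_request(self):
        rng = np.random.default_rng(5)
        params = SimParams(seed=5, gc_content=0.42)
        gc = at = 0
        for i in range(60):
            loc = generate_locus(params, rng, i)
            gc += sum(loc.seq.count(b) for b in "GC")
            at += sum(loc.seq.count(b) for b in "AT")
        assert abs(gc / (gc + at) - 0.42) < 0.02

    def test_pe_has_canonical_dinucleotides(self, rng):
        params = SimParams(seed=9)
        for i in range(20):
            loc = generate_locus(params, rng, i)
            rec = loc.record
            pe = SequenceSource({loc.chrom: loc.seq}).fetch(
                loc.chrom, rec.pe_start, rec.pe_end, rec.strand
            )
            flank = SequenceSource({loc.chrom: loc.seq}).fetch(
                loc.chrom, rec.pe_start - 2, rec.pe_end + 2, rec.strand
            )
            assert flank[:2] == "AG"  # acceptor dinucleotide just 5'
            assert flank[-2:] == "GT"  # donor dinucleotide just 3'
            assert len(pe) == rec.length

    def test_planted_agez_anatomy(self, rng):
        params = SimParams(seed=21, strands=("+",))
        loc = generate_locus(params, rng, 0)
        a = loc.tx["a_tx"]
        upstream = loc.seq[a - 2 - 500 : a - 2]
        r = compute_agez(upstream)
        assert r.length == 43  # bounding AG planted 45 nt out


class TestImplants:
    def test_branchpoint_implant_strictly_grows_the_zone(self, rng):
        params = SimParams(seed=33, strands=("+",))
        for i in range(10):
            loc = generate_locus(params, rng, i)
            mut, _, _ = implant_mutation(loc, MutationCategory.BRANCHPOINT, rng)
            a = loc.tx["a_tx"]
            before = compute_agez(loc.seq[a - 2 - 500 : a - 2])
            mutant = (
                loc.seq[: mut.genomic_start]
                + mut.alt_allele
                + loc.seq[mut.genomic_end :]
            )
            after = compute_agez(mutant[a - 2 - 500 : a - 2])
            assert after.length > before.length

    def test_unimplantable_category_raises(self, rng):
        loc = generate_locus(SimParams(seed=1), rng, 0)
        with pytest.raises(NotImplantableError):
            implant_mutation(
                loc, MutationCategory.INTERNAL_DELETION_JUXTAPOSITION, rng
            )


class TestCatalogue:
    def test_zero_entries_yields_headers_only(self, tmp_path):
        cat = generate_catalogue(SimParams(seed=1, n_entries=0))
        cat.write(tmp_path)
        lines = (tmp_path / "catalogue.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_category_counts_within_binomial_bounds(self):
        cat = generate_catalogue(SimParams(seed=7, n_entries=400))
        from collections import Counter

        counts = Counter(t["category"] for t in cat.truth)
        cats, probs = cat.params.mix_probabilities()
        for c, p in zip(cats, probs):
            mean = 400 * p
            sd = (400 * p * (1 - p)) ** 0.5
            assert abs(counts.get(c, 0) - mean) <= 3 * sd

    def test_evidence_rate_within_bounds(self):
        cat = generate_catalogue(
            SimParams(seed=15, n_entries=1000, evidence_rate=0.157)
        )
        frac = sum(
            e.record.has_splice_evidence for e in cat.entries
        ) / 1000
        assert 0.13 <= frac <= 0.19

    def test_truth_labels_align_with_entries(self):
        cat = generate_catalogue(SimParams(seed=2, n_entries=25))
        assert [t["pe_id"] for t in cat.truth] == [
            e.record.pe_id for e in cat.entries
        ]

    def test_written_tree_is_complete(self, tmp_path):
        cat = generate_catalogue(SimParams(seed=3, n_entries=4))
        cat.write(tmp_path)
        for name in ("catalogue.tsv", "contexts.json", "truth.tsv",
                     "loci.fasta"):
            assert (tmp_path / name).exists()


class TestFixtures:
    def test_table1_has_fourteen_rows(self):
        assert len(load_fixtures("table1")) == 14

    def test_table2_has_eight_rows_and_seven_sites(self):
        rows = load_fixtures("table2")
        assert len(rows) == 8
        coords = {r.rss_coord for r in rows if r.rss_coord}
        assert len(coords) == 7

    def test_published_sizes_are_internally_consistent(self):
        for r in table2_rows():
            assert r.size == r.end - r.start + 1

    def test_gla_row_size(self):
        (gla,) = [r for r in table2_rows() if r.gene == "GLA"]
        assert (gla.start, gla.end, gla.size) == (101401233, 101401347, 115)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError):
            load_fixtures("table3")

    def test_fixture_checksums(self):
        # freeze every numeric cell of the packaged tables
        from importlib import resources

        digests = {}
        for name in ("table1.tsv", "table2.tsv"):
            data = resources.files("pseudex.data").joinpath(name).read_bytes()
            digests[name] = hashlib.sha256(data).hexdigest()
        assert digests == {
            "table1.tsv": "ceaf2796f4fc7b84dcd5b55adf336c7c7bc5a5f8719095994acbdc12886008fd",
            "table2.tsv": "236d7668f546e3d56dce049c0d4adb0efb27cd2eef7a58928424a8a46edfe90c",
        }

    def test_table1_mutation_strings_parse(self):
        from pseudex.hgvs import parse_cdna_variant

        for r in table1_rows():
            for m in r.mutations:
                parse_cdna_variant(m)
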