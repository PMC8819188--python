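"""Domain types, catalogue round-trips, ID assignment and PE validation."""

import pytest

from pseudex.catalogue import (
    assign_pe_id,
    read_catalogue,
    validate_pseudoexon,
    write_catalogue,
)
from pseudex.model import (
    CatalogueEntry,
    GeneContext,
    InstigatingMutation,
    PseudoexonRecord,
    ValidationError,
)
from pseudex.sequences import SequenceSource
from pseudex.simulate import SimParams, generate_catalogue


def _pe(ctx, start, end, pe_id="TOY-1-1"):
    return PseudoexonRecord(pe_id, ctx, 1, start, end)


class TestInvariants:
    def test_empty_interval_rejected(self, plus_gene):
        with pytest.raises(ValidationError):
            _pe(plus_gene, 100, 100)

    def test_snv_must_change_base(self):
        with pytest.raises(ValidationError):
            InstigatingMutation("c.1A>A", "SNV", 10, 11, "A", "A", 1)

    def test_deletion_size_must_match_span(self):
        with pytest.raises(ValidationError):
            InstigatingMutation("c.1_5del", "deletion", 10, 15, "", "", 4)

    def test_exons_must_follow_transcript_order(self):
        with pytest.raises(ValidationError):
            GeneContext("G", "T", "c", "+", [(200, 300), (100, 150)])

    def test_malformed_pe_id_rejected(self, plus_gene):
        with pytest.raises(ValidationError):
            _pe(plus_gene, 10, 20, pe_id="toy_1_1")


class TestAssignPeId:
    def test_distinct_pes_get_sequential_numbers(self, plus_gene):
        a = _pe(plus_gene, 5000, 5100, "ATM-17-1")
        b = _pe(plus_gene, 6000, 6100, "ATM-17-0a")  # id ignored, geometry used
        assert assign_pe_id("ATM", 17, b, [a]) == "ATM-17-2"

    def test_shared_acceptor_gains_letters(self, plus_gene):
        a = _pe(plus_gene, 5000, 5100, "ATM-27-1")
        b = _pe(plus_gene, 5000, 5150, "ATM-27-0a")
        new_id = assign_pe_id("ATM", 27, b, [a])
        assert new_id == "ATM-27-1b"
        assert a.pe_id == "ATM-27-1a"  # the sharer is renamed in place

    def test_first_pe_in_empty_intron(self, plus_gene):
        b = _pe(plus_gene, 5000, 5100, "X-5-0a")
        assert assign_pe_id("X", 5, b, []) == "X-5-1"

    def test_idempotent_over_lettered_group(self, plus_gene):
        a = _pe(plus_gene, 5000, 5100, "ATM-27-1a")
        b = _pe(plus_gene, 5000, 5150, "ATM-27-1b")
        c = _pe(plus_gene, 5000, 5200, "ATM-27-0a")
        assert assign_pe_id("ATM", 27, c, [a, b]) == "ATM-27-1c"
        assert a.pe_id == "ATM-27-1a"

    def test_bad_intron_index(self, plus_gene):
        with pytest.raises(ValidationError):
            assign_pe_id("X", 0, _pe(plus_gene, 1, 2, "X-1-1"), [])


class TestValidate:
    def test_disjoint_pe_is_clean(self, plus_gene):
        pe = _pe(plus_gene, 1150, 1190)
        with pytest.warns(UserWarning):
            assert validate_pseudoexon(pe, plus_gene) == []

    def test_adjacency_is_flagged(self, plus_gene):
        pe = _pe(plus_gene, 1195, 1200)
        with pytest.warns(UserWarning):
            (v,) = validate_pseudoexon(pe, plus_gene)
        assert v.kind == "adjacency"

    def test_overlap_is_flagged(self, plus_gene):
        pe = _pe(plus_gene, 1250, 1350)
        with pytest.warns(UserWarning):
            kinds = {v.kind for v in validate_pseudoexon(pe, plus_gene)}
        assert "overlap" in kinds

    def test_sequence_duplication_is_flagged(self, plus_gene):
        seq = "A" * 1000 + "ACGT" * 25 + "T" * 100 + "ACGT" * 25 + "C" * 5000
        seqs = SequenceSource({"chrT": seq})
        pe = _pe(plus_gene, 1200, 1300)  # would also overlap; move it
        ctx = GeneContext("TOY", "T", "chrT", "+", [(1000, 1100)], 0)
        pe = PseudoexonRecord("TOY-1-1", ctx, 1, 1200, 1300)
        # duplicate exon1's sequence elsewhere
        assert seq[1000:1100] == seq[1200:1300]
        kinds = {v.kind for v in validate_pseudoexon(pe, ctx, seqs)}
        assert kinds == {"duplication"}

    def test_generated_records_are_valid(self):
        cat = generate_catalogue(SimParams(seed=5, n_entries=25))
        seqs = SequenceSource(cat.sequences)
        for e in cat.entries:
            assert validate_pseudoexon(e.record, e.record.gene_context, seqs) == []


class TestRoundTrip:
    def test_empty_catalogue(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_catalogue([], p)
        assert read_catalogue(p, {}) == []
        assert p.read_text().startswith("#")

    def test_write_read_identity(self, tmp_path):
        cat = generate_catalogue(SimParams(seed=9, n_entries=30))
        p = tmp_path / "cat.tsv"
        write_catalogue(cat.entries, p)
        back = read_catalogue(str(p), cat.contexts)
        assert len(back) == len(cat.entries)
        for a, b in zip(cat.entries, back):
            assert a.record.pe_id == b.record.pe_id
            assert a.record.pe_start == b.record.pe_start
            assert a.record.pe_end == b.record.pe_end
            assert a.record.splice_evidence_acceptor == b.record.splice_evidence_acceptor
            assert [m.hgvs_cdna for m in a.mutations] == [
                m.hgvs_cdna for m in b.mutations
            ]
            assert [(m.genomic_start, m.genomic_end, m.ref_allele, m.alt_allele)
                    for m in a.mutations] == [
                (m.genomic_start, m.genomic_end, m.ref_allele, m.alt_allele)
                for m in b.mutations
            ]

    def test_multi_mutation_row_round_trips(self, tmp_path, plus_gene):
        from pseudex.catalogue import mutation_from_hgvs

        rec = _pe(plus_gene, 5000, 5100)
        muts = [
            mutation_from_hgvs("c.100+50A>G", plus_gene),
            mutation_from_hgvs("c.100+60C>T", plus_gene),
        ]
        p = tmp_path / "two.tsv"
        write_catalogue([CatalogueEntry(record=rec, mutations=muts)], p)
        row = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        assert "c.100+50A>G;c.100+60C>T" in row
        (back,) = read_catalogue(str(p), {"TOY": plus_gene})
        assert len(back.mutations) == 2

    def test_curated_rss_table_reads_as_eight_entries(self, tmp_path):
        from pseudex.fixtures import table2_entries

        entries = table2_entries()
        ctxs = {e.record.gene_context.gene_symbol: e.record.gene_context
                for e in entries}
        p = tmp_path / "table2_catalogue.tsv"
        write_catalogue(entries, p)
        back = read_catalogue(str(p), ctxs)
        assert sorted(e.record.pe_id for e in back) == [
            "ATM-27-1a", "ATM-27-1b", "COL4A5-6-1", "FBOX38-9-1",
            "GLA-3-1", "MCCC2-10-1", "NPHP3-3-1", "OCRL-4-1",
        ]

    def test_validation_error_names_the_row(self, tmp_path, plus_gene):
        p = tmp_path / "bad.tsv"
        good = _pe(plus_gene, 5000, 5100)
        write_catalogue([CatalogueEntry(record=good)], p)
        text = p.read_text().replace("5100", "5000")
        p.write_text(text)
        with pytest.raises(Exception, match=":2"):
            read_catalogue(str(p), {"TOY": plus_gene})
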