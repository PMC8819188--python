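"""Classifier rules, rule ordering, the circuit rule and batch behaviour."""

import pytest

from pseudex.classify import (
    ModelSet,
    MutationCategory,
    batch_classify,
    circuit_rule,
    classify_mutation,
)
from pseudex.fixtures import table1_deltas
from pseudex.model import CatalogueEntry, InstigatingMutation
from pseudex.sequences import SequenceSource
from pseudex.simulate import (
    SimParams,
    generate_catalogue,
    generate_locus,
    implant_mutation,
)


def _entry(locus, mut):
    return CatalogueEntry(record=locus.record, mutations=[mut])


def _classify(locus, mut, models=None, config=None, siblings=None):
    seqs = SequenceSource({locus.chrom: locus.seq})
    return classify_mutation(
        _entry(locus, mut), locus.context, seqs, models or ModelSet.packaged(),
        config, siblings=siblings,
    )


@pytest.fixture
def mk_locus(rng):
    def make(seed=11, strand="+"):
        return generate_locus(SimParams(seed=seed, strands=(strand,)), rng, 0)

    return make


class TestRuleFiring:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize(
        "category",
        [
            MutationCategory.DONOR_MOTIF,
            MutationCategory.ACCEPTOR_MOTIF,
            MutationCategory.BRANCHPOINT,
            MutationCategory.INTERNAL_ESE_ESS,
            MutationCategory.FLANKING_EXON_DEFINITION_LOSS,
            MutationCategory.PROXIMAL_INTRONIC_MOTIF,
        ],
    )
    def test_each_implanted_rule_fires_uniquely(self, rng, mk_locus, strand,
                                                category):
        locus = mk_locus(strand=strand)
        mut, truth, subtype = implant_mutation(locus, category, rng)
        res = _classify(locus, mut)
        assert res.category == truth
        assert res.subcategory == subtype
        assert res.evidence  # every non-UNKNOWN result carries evidence

    def test_donor_plus7_pyrimidine_to_purine(self, mk_locus):
        locus = mk_locus()
        g = locus.tx2g(locus.tx["d_tx"] + 6)  # D+7 (planted pyrimidine C)
        mut = InstigatingMutation("c.1C>A", "SNV", g, g + 1, locus.seq[g], "A", 1)
        res = _classify(locus, mut)
        assert res.category == MutationCategory.DONOR_MOTIF
        assert "donor_plus7_purine" in res.evidence

    def test_negligible_acceptor_change_falls_through_to_internal(self, mk_locus):
        # an exonic A+3 SNV barely moves the acceptor score under the zero
        # acceptor model but shifts the hexamer balance: internal category
        # with the negligible flag set
        locus = mk_locus()
        models = ModelSet.packaged()
        from pseudex.motifs import zero_model

        models.acceptor = zero_model("acceptor")
        a = locus.tx["a_tx"]
        g = locus.tx2g(a + 2)  # A+3, inside the 23-mer window
        ref = locus.seq[g]
        alt = "A" if ref != "A" else "C"
        mut = InstigatingMutation(f"c.1{ref}>{alt}", "SNV", g, g + 1, ref, alt, 1)
        res = _classify(locus, mut, models=models)
        assert res.category == MutationCategory.INTERNAL_ESE_ESS
        assert res.negligible_motif_effect

    def test_polya_loss_readthrough(self, rng, mk_locus):
        locus = mk_locus()
        mut, truth, _ = implant_mutation(
            locus, MutationCategory.POLYA_LOSS_READTHROUGH, rng
        )
        res = _classify(locus, mut)
        assert res.category == MutationCategory.POLYA_LOSS_READTHROUGH

    def test_sibling_pe_activation(self, rng, mk_locus):
        from pseudex.model import PseudoexonRecord

        locus = mk_locus()
        # a second catalogued PE whose donor window contains the mutation
        tx = locus.tx
        sib_a = tx["a_tx"] - 400
        sib_d = sib_a + 80
        lo, hi = locus.tx_interval(sib_a, sib_d)
        sib_rec = PseudoexonRecord(
            f"{locus.context.gene_symbol}-1-2", locus.context, 1, lo, hi
        )
        sibling = CatalogueEntry(record=sib_rec, mutations=[])
        g = locus.tx2g(sib_d + 3)  # sibling donor +4 position
        ref = locus.seq[g]
        tx_ref = ref if locus.strand == "+" else {"A": "T", "C": "G",
                                                  "G": "C", "T": "A"}[ref]
        # drive the sibling donor window toward consensus at +4 (A)
        alt_tx = "A" if tx_ref != "A" else "G"
        alt = alt_tx if locus.strand == "+" else {"A": "T", "C": "G",
                                                  "G": "C", "T": "A"}[alt_tx]
        mut = InstigatingMutation(f"c.1{ref}>{alt}", "SNV", g, g + 1, ref, alt, 1)
        res = _classify(locus, mut, siblings=[sibling])
        assert res.category in (
            MutationCategory.SIBLING_PE_ACTIVATION,
            MutationCategory.PROXIMAL_INTRONIC_MOTIF,
        )

    def test_unmutated_entry_is_unknown(self, mk_locus):
        locus = mk_locus()
        seqs = SequenceSource({locus.chrom: locus.seq})
        res = classify_mutation(
            CatalogueEntry(record=locus.record), locus.context, seqs,
            ModelSet.packaged(),
        )
        assert res.category == MutationCategory.UNKNOWN

    def test_far_intergenic_snv_is_unknown(self, mk_locus):
        locus = mk_locus()
        g = 5  # deep in the 5' pad, outside the transcript's intron
        ref = locus.seq[g]
        alt = "A" if ref != "A" else "C"
        mut = InstigatingMutation(f"c.1{ref}>{alt}", "SNV", g, g + 1, ref, alt, 1)
        res = _classify(locus, mut)
        assert res.category == MutationCategory.UNKNOWN


class TestNullModels:
    def test_zero_models_never_assign_motif_categories(self, rng):
        cat = generate_catalogue(SimParams(seed=31, n_entries=40))
        seqs = SequenceSource(cat.sequences)
        res, tally, errors = batch_classify(
            cat.entries, cat.contexts, seqs, ModelSet.null()
        )
        assert not errors
        motif_cats = {
            MutationCategory.DONOR_MOTIF,
            MutationCategory.ACCEPTOR_MOTIF,
            MutationCategory.INTERNAL_ESE_ESS,
        }
        assert not (set(tally) & motif_cats)


class TestCircuitRule:
    def test_curated_rows_give_twelve_positives(self):
        deltas = table1_deltas()
        positives = [pid for pid, d in deltas if circuit_rule(d)]
        negatives = [pid for pid, d in deltas if not circuit_rule(d)]
        assert len(positives) == 12
        assert sorted(negatives) == ["ABCA4-6-1", "CCN6-2-1"]

    def test_pyrimidine_extension_covers_all_rows(self):
        deltas = table1_deltas()
        assert all(circuit_rule(d) or d.pyrimidine_gain for _, d in deltas)

    def test_all_zero_delta_is_negative(self):
        from pseudex.branchpoint import BranchPointDelta

        d = BranchPointDelta(10, 10, 0.5, 0.5, False, False)
        assert not circuit_rule(d)


class TestBatch:
    def test_empty_catalogue(self):
        res, tally, errors = batch_classify(
            [], {}, SequenceSource({}), ModelSet.packaged()
        )
        assert res == [] and not tally and not errors

    def test_determinism_across_runs(self):
        out = []
        for _ in range(2):
            cat = generate_catalogue(SimParams(seed=77, n_entries=30))
            seqs = SequenceSource(cat.sequences)
            res, tally, _ = batch_classify(
                cat.entries, cat.contexts, seqs, ModelSet.packaged()
            )
            out.append([r.label for r in res])
        assert out[0] == out[1]

    def test_tally_sums_to_catalogue_size(self):
        cat = generate_catalogue(SimParams(seed=13, n_entries=50))
        seqs = SequenceSource(cat.sequences)
        _, tally, _ = batch_classify(
            cat.entries, cat.contexts, seqs, ModelSet.packaged()
        )
        assert sum(tally.values()) == 50

    def test_implant_truth_recovered(self):
        cat = generate_catalogue(SimParams(seed=3, n_entries=120))
        seqs = SequenceSource(cat.sequences)
        res, _, errors = batch_classify(
            cat.entries, cat.contexts, seqs, ModelSet.packaged()
        )
        assert not errors
        agree = sum(
            r.category == t["category"] for r, t in zip(res, cat.truth)
        )
        assert agree == 120
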