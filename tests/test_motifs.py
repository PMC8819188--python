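"""Splice-motif scoring: additive models, deltas, site scans, MaxEnt layout."""

import math

import pytest

from pseudex.model import InstigatingMutation
from pseudex.motifs import (
    DONOR_CONSENSUS,
    acceptor_dinuc_distance,
    delta_site_score,
    find_candidate_sites,
    score_acceptor,
    score_donor,
    spliceosome_type,
    toy_acceptor_model,
    toy_donor_model,
    zero_model,
)

from conftest import random_dna


class TestScoring:
    def test_zero_model_scores_everything_zero(self, rng):
        zd, za = zero_model("donor"), zero_model("acceptor")
        for _ in range(5):
            assert score_donor(random_dna(rng, 9), zd) == 0.0
            assert score_acceptor(random_dna(rng, 23), za) == 0.0

    def test_toy_donor_consensus_sums(self):
        m = toy_donor_model()
        assert score_donor("CAGGTAAGT", m) == 9.0
        assert score_donor("CAGGTAAGA", m) == 7.0

    def test_toy_acceptor_consensus_sum(self):
        m = toy_acceptor_model()
        consensus = "T" * 17 + "CAG" + "GTT"
        assert score_acceptor(consensus, m) == 23.0

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            score_donor("CAGGTANGT", toy_donor_model())

    def test_additive_delta_depends_only_on_changed_positions(self, rng):
        m = toy_donor_model()
        for _ in range(20):
            w = random_dna(rng, 9)
            base = m.score(w)
            for i in range(9):
                for b in "ACGT":
                    if b == w[i]:
                        continue
                    mutant = w[:i] + b + w[i + 1 :]
                    expected = (
                        m.weights[(m.positions[i], b)]
                        - m.weights[(m.positions[i], w[i])]
                    )
                    assert m.score(mutant) - base == pytest.approx(expected)


class TestDeltaSiteScore:
    def _snv(self, pos, ref, alt):
        return InstigatingMutation(f"c.{pos}{ref}>{alt}", "SNV", pos, pos + 1,
                                   ref, alt, 1)

    def test_snv_outside_window_is_neutral(self):
        m = toy_donor_model()
        d = delta_site_score("CAGGTAAGT", self._snv(500, "A", "G"), m,
                             window_start=100)
        assert d.delta == 0.0

    def test_consensus_restoring_snv(self):
        m = toy_donor_model()
        w = "CAGATAAGT"  # +1 is A instead of consensus G
        d = delta_site_score(w, self._snv(103, "A", "G"), m, window_start=100)
        assert d.before == 7.0 and d.after == 9.0 and d.delta == 2.0

    def test_random_snvs_equal_independent_rescoring(self, rng):
        m = toy_donor_model()
        for _ in range(50):
            w = random_dna(rng, 9)
            i = int(rng.integers(9))
            alts = [b for b in "ACGT" if b != w[i]]
            alt = alts[int(rng.integers(3))]
            d = delta_site_score(w, self._snv(1000 + i, w[i], alt), m,
                                 window_start=1000)
            oracle = m.score(w[:i] + alt + w[i + 1 :]) - m.score(w)
            assert d.delta == pytest.approx(oracle)

    def test_deletion_rescored_on_reconstructed_window(self):
        m = toy_donor_model()
        ctx = "AAAA" + "CAGGGTAAGT" + "AAAA"  # extra G inside the motif
        mut = InstigatingMutation("c.1del", "deletion", 107, 108, "", "", 1)
        d = delta_site_score(ctx[4:13], mut, m, window_start=104,
                             context_seq=ctx, context_start=100)
        assert not d.window_destroyed
        assert d.after == m.score("CAGGTAAGT")

    def test_length_change_without_context_flags_window_destroyed(self):
        m = toy_donor_model()
        mut = InstigatingMutation("c.1_5del", "deletion", 102, 107, "", "", 5)
        d = delta_site_score("CAGGTAAGT", mut, m, window_start=100)
        assert d.window_destroyed and d.delta == 0.0


class TestFindCandidates:
    def test_no_gt_means_no_donors(self):
        sites = find_candidate_sites("ACACACACACACACACAC", toy_donor_model(),
                                     "donor", -100)
        assert sites == []

    def test_infinite_threshold_empty(self, rng):
        seq = random_dna(rng, 300)
        assert find_candidate_sites(seq, toy_donor_model(), "donor",
                                    math.inf) == []

    @pytest.mark.parametrize("kind", ["donor", "acceptor"])
    def test_matches_brute_force_enumeration(self, rng, kind):
        model = toy_donor_model() if kind == "donor" else toy_acceptor_model()
        seq = random_dna(rng, 200)
        got = find_candidate_sites(seq, model, kind, 0.0)
        expected = []
        if kind == "donor":
            for b in range(3, len(seq) - 5):
                if seq[b : b + 2] != "GT":
                    continue
                s = model.score(seq[b - 3 : b + 6])
                if s >= 0.0:
                    expected.append((b, s))
        else:
            for b in range(20, len(seq) - 2):
                if seq[b - 2 : b] != "AG":
                    continue
                s = model.score(seq[b - 20 : b + 3])
                if s >= 0.0:
                    expected.append((b, s))
        assert [(s.position, s.score) for s in got] == expected

    def test_gc_donors_only_behind_flag(self):
        seq = "AAAA" + "CAG" + "GC" + "AAGG" + "AAAA"
        assert find_candidate_sites(seq, toy_donor_model(), "donor", -100) == []
        got = find_candidate_sites(seq, toy_donor_model(), "donor", -100,
                                   allow_gc=True)
        assert [s.position for s in got] == [7]


class TestAuxiliaryChecks:
    def test_canonical_donor_is_u2(self):
        assert spliceosome_type("GTAAGTAAA", "T" * 40) == "U2"

    def test_u12_donor_without_branch_motif_is_u2(self):
        # matches the minor-spliceosome donor heptamer but no branch motif
        assert spliceosome_type("GTATCCTAA", "T" * 40) == "U2"

    def test_u12_donor_with_branch_motif(self):
        branch = "T" * 20 + "CCTTTAC" + "T" * 13
        assert spliceosome_type("ATATCCTAA", branch) == "putative_U12"

    @pytest.mark.parametrize("dinuc,d", [("AG", 0), ("CG", 1), ("AT", 1),
                                         ("TG", 1), ("TT", 2)])
    def test_acceptor_dinuc_distance(self, dinuc, d):
        assert acceptor_dinuc_distance(dinuc) == d


class TestMaxEntLayout:
    """Synthetic tables in the published directory layout; with all table
    entries equal to 1 the score reduces to the consensus log-odds term."""

    @pytest.fixture
    def table_dir(self, tmp_path):
        (tmp_path / "me2x5").write_text("1.0\n" * 4**7)
        for i, k in zip(range(1, 10), [7, 7, 7, 7, 7, 3, 4, 3, 4]):
            (tmp_path / f"me2x3acc{i}").write_text("1.0\n" * 4**k)
        return str(tmp_path)

    def test_donor_consensus_log_odds(self, table_dir):
        from pseudex.maxent import load_maxent_donor

        m = load_maxent_donor(table_dir)
        expected = math.log2(0.9896 * 0.9884 / (0.23 * 0.27))
        assert m.score(DONOR_CONSENSUS) == pytest.approx(expected)

    def test_acceptor_consensus_log_odds(self, table_dir):
        from pseudex.maxent import load_maxent_acceptor

        m = load_maxent_acceptor(table_dir)
        expected = math.log2(0.9903 * 0.9905 / (0.27 * 0.23))
        assert m.score("T" * 17 + "CAG" + "GTT") == pytest.approx(expected)

    def test_nonconsensus_dinucleotide_penalised(self, table_dir):
        from pseudex.maxent import load_maxent_donor

        m = load_maxent_donor(table_dir)
        assert m.score("CAGATAAGT") < m.score(DONOR_CONSENSUS)

    def test_truncated_table_rejected(self, tmp_path):
        from pseudex.maxent import load_maxent_donor

        (tmp_path / "me2x5").write_text("1.0\n" * 100)
        with pytest.raises(ValueError, match="expected"):
            load_maxent_donor(str(tmp_path))
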