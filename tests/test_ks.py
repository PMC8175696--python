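"""Unit and property tests for the NG86 Ks/Ka engine and RBH orthology."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wgtkit import (
    CodonPair,
    build_distribution,
    jukes_cantor,
    ng86_pairwise,
    ng86_site_counts,
    rbh_orthologs,
)
from wgtkit.errors import InputError
from wgtkit.ks import SENSE_CODONS

from conftest import oracle_ng86, oracle_site_counts, random_sense_codons


class TestSiteCounts:
    def test_phenylalanine_third_position_twofold(self):
        # only TTT->TTC is synonymous among the nine single-base changes
        syn, nonsyn = ng86_site_counts("TTT")
        assert syn == pytest.approx(1 / 3)
        assert nonsyn == pytest.approx(8 / 3)

    def test_glycine_third_position_fourfold(self):
        syn, nonsyn = ng86_site_counts("GGG")
        assert syn == pytest.approx(1.0)
        assert nonsyn == pytest.approx(2.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(InputError):
            ng86_site_counts("TAA")

    def test_ambiguous_base_rejected(self):
        with pytest.raises(InputError):
            ng86_site_counts("ANT")

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_matches_enumeration_oracle_and_sums_to_three(self, codon):
        syn, nonsyn = ng86_site_counts(codon)
        o_syn, o_nonsyn = oracle_site_counts(codon)
        assert syn == pytest.approx(o_syn)
        assert syn + nonsyn == pytest.approx(3.0)


class TestPairwise:
    def test_identical_sequences_zero_distance(self):
        est = ng86_pairwise(("TTTGGGAAA", "TTTGGGAAA"))
        assert est.Sd == est.Nd == 0
        assert est.ks == 0.0 and est.ka == 0.0
        assert not est.saturated

    def test_worked_single_synonymous_difference(self):
        est = ng86_pairwise(("TTTGGGAAA", "TTCGGGAAA"))
        assert est.S == pytest.approx(5 / 3)
        assert est.Sd == pytest.approx(1.0)
        assert est.p_s == pytest.approx(0.6)
        assert est.ks == pytest.approx(-0.75 * math.log(0.2))
        assert est.ka == 0.0

    def test_saturated_pair_flagged_ks_undefined(self):
        # two-codon pair where every synonymous site differs
        est = ng86_pairwise(("GGGGGA", "GGAGGG"))
        assert est.p_s >= 0.75
        assert est.saturated
        assert math.isnan(est.ks)

    def test_length_mismatch_and_frame_errors(self):
        with pytest.raises(InputError):
            ng86_pairwise(("TTT", "TTTAAA"))
        with pytest.raises(InputError):
            ng86_pairwise(("TTTA", "TTTA"))

    def test_internal_stop_is_error(self):
        with pytest.raises(InputError):
            ng86_pairwise(("TAAGGG", "TTTGGG"))

    def test_ambiguous_codon_skipped_from_both_counts(self):
        clean = ng86_pairwise(("TTTGGG", "TTCGGG"))
        with_n = ng86_pairwise(("TTTGGGANA", "TTCGGGAAA"))
        assert with_n.S == pytest.approx(clean.S)
        assert with_n.Sd == pytest.approx(clean.Sd)
        assert with_n.n_skipped == 1

    def test_exhaustive_single_codon_pairs_match_oracle(self):
        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                est = ng86_pairwise((a, b))
                ora = oracle_ng86(a, b)
                assert est.S == pytest.approx(ora["S"]), (a, b)
                assert est.Sd == pytest.approx(ora["Sd"]), (a, b)
                assert est.Nd == pytest.approx(ora["Nd"]), (a, b)

    def test_random_multi_codon_pairs_match_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 4))
            a = random_sense_codons(rng, n)
            b = random_sense_codons(rng, n)
            est = ng86_pairwise((a, b))
            ora = oracle_ng86(a, b)
            assert est.S == pytest.approx(ora["S"])
            assert est.Sd == pytest.approx(ora["Sd"], abs=1e-9)
            # compare corrected distances away from saturation, where the
            # log correction does not amplify float rounding unboundedly
            if not math.isnan(ora["ks"]) and ora["p_s"] < 0.7:
                assert est.ks == pytest.approx(ora["ks"])

    def test_agrees_with_biopython_ng86_on_stop_free_neighbourhoods(self, rng):
        """Independent cross-check against Bio.codonalign's NG86 on pairs
        whose codons have no stop-codon single-base neighbours (where the
        stop-renormalisation conventions cannot differ)."""
        import warnings

        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        safe = [
            c for c in SENSE_CODONS
            if all(
                c[:i] + b + c[i + 1 :] not in ("TAA", "TAG", "TGA")
                for i in range(3)
                for b in "ACGT"
            )
        ]
        for _ in range(20):
            # moderate divergence: mutate ~30% of codons so p stays well
            # below saturation and the comparison is numerically stable
            idx = rng.integers(0, len(safe), size=30)
            a_codons = [safe[i] for i in idx]
            b_codons = [
                safe[rng.integers(0, len(safe))] if rng.random() < 0.3 else c
                for c in a_codons
            ]
            a, b = "".join(a_codons), "".join(b_codons)
            est = ng86_pairwise((a, b))
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            if est.saturated or math.isnan(est.ks) or est.p_s > 0.6:
                continue
            assert est.ks == pytest.approx(ds, rel=0.02, abs=0.01)
            assert est.ka == pytest.approx(dn, rel=0.02, abs=0.01)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_site_conservation(self, seed, n_codons):
        rng = np.random.default_rng(seed)
        a = random_sense_codons(rng, n_codons)
        b = random_sense_codons(rng, n_codons)
        ab, ba = ng86_pairwise((a, b)), ng86_pairwise((b, a))
        assert ab.S + ab.N == pytest.approx(3 * n_codons)
        assert ab.Sd == pytest.approx(ba.Sd)
        assert ab.Nd == pytest.approx(ba.Nd)
        assert ab.S == pytest.approx(ba.S)


class TestJukesCantor:
    @given(st.floats(0.0, 0.7499), st.floats(0.0, 0.7499))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing_below_saturation(self, p1, p2):
        lo, hi = sorted((p1, p2))
        if hi - lo > 1e-12:
            assert jukes_cantor(lo) < jukes_cantor(hi)
        else:
            assert jukes_cantor(lo) <= jukes_cantor(hi)

    def test_saturation_boundary(self):
        assert math.isnan(jukes_cantor(0.75))
        assert jukes_cantor(0.0) == 0.0


class TestDistribution:
    def test_identical_pairs_give_zero_distribution(self):
        dist = build_distribution([("TTTGGG", "TTTGGG")] * 3)
        assert list(dist.values) == [0.0, 0.0, 0.0]
        assert dist.saturated_count == 0

    def test_saturated_pairs_excluded_and_counted(self):
        dist = build_distribution([("GGGGGA", "GGAGGG"), ("TTTGGG", "TTTGGG")])
        assert len(dist) == 1
        assert dist.saturated_count == 1

    def test_all_saturated_warns_not_raises(self):
        with pytest.warns(UserWarning):
            dist = build_distribution([("GGGGGA", "GGAGGG")])
        assert len(dist) == 0

    def test_simulated_pairs_recover_target_mean(self):
        from wgtkit import gen_cds_pair

        pairs = [gen_cds_pair(0.65, 0.0, 300, seed)[:2] for seed in range(200)]
        dist = build_distribution(pairs)
        assert np.mean(dist.values) == pytest.approx(0.65, abs=0.05)


class TestRbh:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["query", "subject", "bitscore", "evalue"])

    def test_mutual_best_returned(self):
        ab = self._table([("a1", "b1", 500, 1e-50), ("a1", "b2", 100, 1e-10)])
        ba = self._table([("b1", "a1", 480, 1e-48), ("b2", "a1", 90, 1e-9)])
        assert rbh_orthologs(ab, ba) == [("a1", "b1")]

    def test_non_reciprocal_excluded(self):
        ab = self._table([("a1", "b1", 500, 1e-50), ("a2", "b1", 400, 1e-40)])
        ba = self._table([("b1", "a2", 480, 1e-48)])
        assert rbh_orthologs(ab, ba) == [("a2", "b1")]

    def test_bitscore_tie_broken_by_evalue_then_id(self):
        ab = self._table([("a1", "b1", 500, 1e-50), ("a1", "b2", 500, 1e-40)])
        ba = self._table([("b1", "a1", 500, 1e-50), ("b2", "a1", 500, 1e-40)])
        assert rbh_orthologs(ab, ba) == [("a1", "b1")]

    def test_row_order_invariance(self, rng):
        rows = [
            ("a1", "b1", 500, 1e-50), ("a1", "b2", 500, 1e-50),
            ("a2", "b2", 400, 1e-40), ("a2", "b1", 300, 1e-30),
            ("a3", "b3", 200, 1e-20),
        ]
        back = [
            ("b1", "a1", 500, 1e-50), ("b2", "a2", 410, 1e-41),
            ("b2", "a1", 400, 1e-40), ("b3", "a3", 210, 1e-21),
        ]
        reference = rbh_orthologs(self._table(rows), self._table(back))
        for _ in range(10):
            perm = list(rng.permutation(len(rows)))
            perm_b = list(rng.permutation(len(back)))
            shuffled = rbh_orthologs(
                self._table([rows[i] for i in perm]),
                self._table([back[i] for i in perm_b]),
            )
            assert shuffled == reference
        # output is one-to-one
        firsts = [a for a, _ in reference]
        seconds = [b for _, b in reference]
        assert len(set(firsts)) == len(firsts)
        assert len(set(seconds)) == len(seconds)

    def test_empty_tables(self):
        empty = self._table([])
        assert rbh_orthologs(empty, empty) == []
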