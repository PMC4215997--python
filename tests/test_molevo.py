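"""NG86 Ka/Ks, backtranslation, Jukes-Cantor dating, pair summaries.

The NG86 implementation is checked three ways: against frozen values from
an independent brute-force site/pathway enumeration of a 12-codon toy
pair, against Biopython's NG86 routine on random evolved pairs, and by
parameter recovery on sequences simulated with known synonymous
divergence.
"""

import math
import warnings

import numpy as np
import pytest

from genefam import molevo
from genefam.model import KaKsConfig
from genefam.phylo import Alignment
from genefam.simulate import evolve_cds, random_cds

# toy pair: one synonymous 3rd-position change (GGG->GGA) and one
# nonsynonymous 1st-position change (TTT->CTT) across 12 codons
TOY_A = "ATGAAACCTGGGTTTGCAGATCACAGATATGTCCTG"
TOY_B = "ATGAAACCTGGACTTGCAGATCACAGATATGTCCTG"
# frozen from the independent enumeration oracle
TOY = dict(S=8.0, N=28.0, Sd=1.0, Nd=1.0,
           ks=0.1367411676, ka=0.0365926231)


def caln(**seqs):
    return molevo.CodonAlignment.from_dict(seqs)


class TestBacktranslate:
    def test_gap_becomes_codon_gap(self):
        aln = Alignment.from_dict({"a": "M-K", "b": "MLK"})
        out = molevo.backtranslate_alignment(
            aln, {"a": "ATGAAA", "b": "ATGCTTAAA"})
        assert out.row("a") == "ATG---AAA"
        assert out.row("b") == "ATGCTTAAA"

    def test_internal_stop_rejected(self):
        aln = Alignment.from_dict({"a": "M*K", "b": "MLK"})
        with pytest.raises(ValueError, match="stop"):
            molevo.backtranslate_alignment(
                aln, {"a": "ATGTAAAAA", "b": "ATGCTTAAA"})

    def test_length_mismatch_rejected(self):
        aln = Alignment.from_dict({"a": "MK", "b": "MK"})
        with pytest.raises(ValueError, match="divisible"):
            molevo.backtranslate_alignment(aln, {"a": "ATGAA", "b": "ATGAAA"})

    def test_translation_mismatch_names_position(self):
        aln = Alignment.from_dict({"a": "MK", "b": "MK"})
        with pytest.raises(ValueError, match="column 1"):
            molevo.backtranslate_alignment(
                aln, {"a": "ATGCCC", "b": "ATGAAA"})

    def test_trailing_stop_tolerated(self):
        aln = Alignment.from_dict({"a": "MK", "b": "MK"})
        out = molevo.backtranslate_alignment(
            aln, {"a": "ATGAAATAA", "b": "ATGAAA"})
        assert out.row("a") == out.row("b") == "ATGAAA"


class TestNg86:
    def test_identical_sequences(self):
        r = molevo.ng86_kaks(caln(a=TOY_A, b=TOY_A), ("a", "b"))
        assert r.ka == 0.0 and r.ks == 0.0
        assert not r.ratio_defined

    def test_toy_pair_matches_enumeration_oracle(self):
        r = molevo.ng86_kaks(caln(a=TOY_A, b=TOY_B), ("a", "b"))
        assert r.syn_sites == pytest.approx(TOY["S"])
        assert r.nonsyn_sites == pytest.approx(TOY["N"])
        assert r.syn_diffs == pytest.approx(TOY["Sd"])
        assert r.nonsyn_diffs == pytest.approx(TOY["Nd"])
        assert r.ks == pytest.approx(TOY["ks"], abs=1e-9)
        assert r.ka == pytest.approx(TOY["ka"], abs=1e-9)

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(0)
        a = random_cds(40, rng)
        b = evolve_cds(a, 15e6, 6.1e-9, 0.5, rng)
        r = molevo.ng86_kaks(caln(a=a, b=b), ("a", "b"))
        assert r.syn_sites + r.nonsyn_sites == pytest.approx(3 * r.n_codons)

    def test_symmetric_in_sequence_order(self):
        rng = np.random.default_rng(1)
        a = random_cds(40, rng)
        b = evolve_cds(a, 15e6, 6.1e-9, 0.5, rng)
        r1 = molevo.ng86_kaks(caln(a=a, b=b), ("a", "b"))
        r2 = molevo.ng86_kaks(caln(a=a, b=b), ("b", "a"))
        assert r1.ka == pytest.approx(r2.ka)
        assert r1.ks == pytest.approx(r2.ks)

    def test_gap_codons_dropped(self):
        r_full = molevo.ng86_kaks(caln(a=TOY_A, b=TOY_B), ("a", "b"))
        r_gap = molevo.ng86_kaks(
            caln(a="---" + TOY_A[3:], b=TOY_B), ("a", "b"))
        assert r_gap.n_codons == r_full.n_codons - 1

    def test_all_gap_pair_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            molevo.ng86_kaks(caln(a="---AAA", b="ATG---"), ("a", "b"))

    def test_jc_singularity_flagged(self):
        # force ps >= 3/4 with wildly divergent short sequences
        r = molevo.ng86_kaks(caln(a="TTATTATTATTA", b="CTGCTGCTGCTG"), ("a", "b"))
        assert not (r.jc_valid_ks and r.jc_valid_ka) or r.ratio is not None

    def test_matches_biopython_ng86(self):
        """Independent cross-check against Bio.codonalign's NG86."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = random_cds(60, rng)
            b = evolve_cds(a, 20e6, 6.1e-9, 0.4, rng)
            mine = molevo.ng86_kaks(caln(a=a, b=b), ("a", "b"))
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert mine.ka == pytest.approx(dn, abs=1e-9)
            assert mine.ks == pytest.approx(ds, abs=1e-9)

    def test_simulated_ks_recovery(self):
        """Mean NG86 estimates recover simulated Ks/Ka within 10%."""
        lam = 6.1e-9
        rng = np.random.default_rng(42)
        for target_ks, omega in [(0.1, 0.2), (0.2, 0.5)]:
            years = target_ks / (2 * lam)  # per-lineage time; Ks = 2*lam*T
            ks_vals, ka_vals = [], []
            for _ in range(25):
                anc = random_cds(500, rng)
                d1 = evolve_cds(anc, years, lam, omega, rng)
                d2 = evolve_cds(anc, years, lam, omega, rng)
                r = molevo.ng86_kaks(caln(a=d1, b=d2), ("a", "b"))
                ks_vals.append(r.ks)
                ka_vals.append(r.ka)
            mean_ks = np.mean(ks_vals)
            assert abs(mean_ks - target_ks) / target_ks < 0.10
            assert abs(np.mean(ka_vals) / mean_ks - omega) / omega < 0.15


class TestDating:
    @pytest.mark.parametrize("ks, expected", [
        (0.1177, 9.65),
        (0.0909, 7.45),
        (0.0, 0.0),
    ])
    def test_published_dates(self, ks, expected):
        t = molevo.date_duplication(ks, KaKsConfig())
        assert molevo.round_half_up(t, 2) == expected

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            molevo.date_duplication(-0.1)

    def test_linear_in_ks_inverse_in_lam(self):
        c1 = KaKsConfig(lam=6.1e-9)
        c2 = KaKsConfig(lam=12.2e-9)
        assert molevo.date_duplication(0.2, c1) == \
            pytest.approx(2 * molevo.date_duplication(0.1, c1))
        assert molevo.date_duplication(0.1, c2) == \
            pytest.approx(molevo.date_duplication(0.1, c1) / 2)


class TestPairTableArithmetic:
    def test_ratio_column_consistent(self, pairs):
        """Every printed Ka/Ks ratio equals ka/ks at 4-decimal rounding."""
        for p in pairs:
            assert molevo.round_half_up(p.ka / p.ks, 4) == pytest.approx(
                p.ratio, abs=1e-12)

    def test_printed_dates_follow_clock(self, pairs):
        cfg = KaKsConfig()
        for p in pairs:
            assert molevo.round_half_up(
                molevo.date_duplication(p.ks, cfg), 2) == p.date_mya

    def test_summary_means(self, pairs):
        s = molevo.summarize_pairs(pairs, 0.3)
        assert molevo.round_half_up(s.ks_mean, 4) == 0.1682
        assert molevo.round_half_up(s.date_mean, 2) == 13.78
        assert s.n_segmental_ratio_below == 8
        assert (s.n_large, s.n_small) == (13, 4)

    def test_empty_summary(self):
        s = molevo.summarize_pairs([], 0.3)
        assert s.n_pairs == 0 and s.ks_mean is None and s.date_mean is None
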