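"""Sequence-grammar unit and property tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from idrcond import config, grammar as g
from oracles import idr_runs_bruteforce, patch_fraction_bruteforce, rg_fraction_bruteforce


# ---------------------------------------------------------------------------
# IDR calling, llIDR selection, segmentation
# ---------------------------------------------------------------------------

class TestCallIdrs:
    def test_single_full_length_region(self):
        t = g.DisorderTrack("p", np.full(50, 0.9))
        assert [(r.start, r.end) for r in g.call_idrs(t)] == [(0, 50)]

    def test_all_ordered_gives_nothing(self):
        t = g.DisorderTrack("p", np.full(50, 0.1))
        assert g.call_idrs(t) == []

    def test_run_boundaries_and_strict_length(self):
        scores = np.full(100, 0.1)
        scores[10:46] = 0.8  # 36 residues -> reported
        t = g.DisorderTrack("p", scores)
        assert [(r.start, r.end) for r in g.call_idrs(t)] == [(10, 46)]
        scores2 = np.full(100, 0.1)
        scores2[10:40] = 0.8  # exactly 30 -> not reported (strict >)
        assert g.call_idrs(g.DisorderTrack("p", scores2)) == []

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(200):
            scores = rng.random(rng.integers(31, 200))
            t = g.DisorderTrack("p", scores)
            got = [(r.start, r.end) for r in g.call_idrs(t, min_len=5)]
            assert got == idr_runs_bruteforce(scores, min_len=5)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            g.DisorderTrack("p", np.array([]))


class TestLlidrSelection:
    @pytest.mark.parametrize("start,end,plen,expected", [
        (100, 1200, 1500, True),    # internal, length 1100 > 1000
        (0, 1100, 1500, False),     # touches N-terminus
        (400, 1500, 1500, False),   # touches C-terminus
        (100, 1100, 1500, False),   # length exactly 1000 (strict >)
        (100, 1101, 1500, True),    # length 1001
    ])
    def test_three_criteria(self, start, end, plen, expected):
        out = g.select_llidrs([g.IDRRegion("p", start, end)], plen)
        assert out[0].is_llidr is expected

    def test_region_beyond_protein_rejected(self):
        with pytest.raises(ValueError):
            g.select_llidrs([g.IDRRegion("p", 0, 200)], 100)


class TestSegmentation:
    @pytest.mark.parametrize("length,expected", [
        (1050, [200] * 5 + [50]),   # tail 50 >= 30 kept
        (1020, [200] * 4 + [220]),  # tail 20 < 30 merged backwards
        (200, [200]),
        (400, [200, 200]),
        (230, [200, 30]),
        (229, [229]),
        (30, [30]),
    ])
    def test_block_arithmetic(self, length, expected):
        segs = g.segment_region(g.IDRRegion("p", 0, length))
        assert [e - s for s, e in segs.segments] == expected

    def test_segments_tile_region_from_offset(self):
        segs = g.segment_region(g.IDRRegion("p", 17, 17 + 1020))
        assert segs.segments[0][0] == 17
        assert segs.segments[-1][1] == 17 + 1020

    def test_too_short_region_rejected(self):
        with pytest.raises(ValueError):
            g.segment_region(g.IDRRegion("p", 0, 29))

    def test_exhaustive_small_cases_obey_rules(self):
        for length in range(30, 700):
            sizes = [e - s for s, e in
                     g.segment_region(g.IDRRegion("p", 0, length)).segments]
            assert sum(sizes) == length
            assert all(s >= 30 for s in sizes)
            assert all(s == 200 for s in sizes[:-1])
            assert sizes[-1] < 200 + 30


# ---------------------------------------------------------------------------
# Composition, charge, pI
# ---------------------------------------------------------------------------

class TestComposition:
    def test_fraction_sum_and_identities(self, rng, random_sequences):
        for seq in random_sequences(200, 60):
            comp = g.composition_features(seq)
            charge = g.charge_global_features(seq)
            fracs = comp[[f"Frac {a}" for a in config.AMINO_ACIDS]]
            assert abs(fracs.sum() - 1.0) < 1e-12
            assert ((fracs >= 0) & (fracs <= 1)).all()
            assert charge["FCR"] == comp["Frac K+R"] + comp["Frac D+E"]
            assert charge["NCPR"] == comp["Frac K+R"] - comp["Frac D+E"]

    @pytest.mark.parametrize("seq,name,value", [
        ("KRKR", "Frac K+R", 1.0),
        ("KRKR", "log10(K/R)", 0.0),
        ("GGGG", "log10(K/R)", 0.0),        # pseudocount identity
        ("DDDDEEEE", "Frac D+E", 1.0),
        ("DDDDEEEE", "log10(E/D)", 0.0),    # log10(5/5)
        ("KKKE", "log10(K/R)", math.log10(4.0)),
    ])
    def test_hand_counted(self, seq, name, value):
        assert g.composition_features(seq)[name] == pytest.approx(value, abs=1e-12)

    @pytest.mark.parametrize("seq,fcr,ncpr", [
        ("KKDD", 1.0, 0.0),
        ("KKKK", 1.0, 1.0),
        ("GGGG", 0.0, 0.0),
        ("KKRDE", 1.0, 0.2),
    ])
    def test_charge_scalars(self, seq, fcr, ncpr):
        ch = g.charge_global_features(seq)
        assert ch["FCR"] == pytest.approx(fcr)
        assert ch["NCPR"] == pytest.approx(ncpr)


class TestIsoelectricPoint:
    @staticmethod
    def _net(seq, ph):
        pka = config.PKA_EMBOSS
        c = {a: seq.count(a) for a in "KRHDECY"}
        pos = 1 / (1 + 10 ** (ph - pka["Nterm"]))
        pos += sum(c[a] / (1 + 10 ** (ph - pka[a])) for a in "KRH")
        neg = 1 / (1 + 10 ** (pka["Cterm"] - ph))
        neg += sum(c[a] / (1 + 10 ** (pka[a] - ph)) for a in "DECY")
        return pos - neg

    @pytest.mark.parametrize("seq", ["GGGG", "KKKK", "DDDD", "KRDEHCY", "ASGM"])
    def test_matches_root_finding_oracle(self, seq):
        expected = brentq(lambda ph: self._net(seq, ph), 0, 14, xtol=1e-10)
        pi = g.isoelectric_point(seq)
        assert abs(self._net(seq, pi)) < 1e-4  # the stated convergence rule
        assert pi == pytest.approx(expected, abs=0.01)

    def test_neutral_backbone_is_pka_midpoint(self):
        # termini only: symmetric titration around the mean of the two pKas
        mid = (config.PKA_EMBOSS["Nterm"] + config.PKA_EMBOSS["Cterm"]) / 2
        assert g.isoelectric_point("GGGG") == pytest.approx(mid, abs=0.01)


# ---------------------------------------------------------------------------
# Block / RG patch features
# ---------------------------------------------------------------------------

class TestBlockFeatures:
    @pytest.mark.parametrize("seq,name,value", [
        ("EEEE", "Block E", 1.0),
        ("EEE", "Block E", 0.0),            # needs >= 4 occurrences
        ("EEAAEEAAEE", "Block E", 1.0),     # gaps of 2 chain through
        ("EEAAAEEEE", "Block E", 4 / 9),    # gap of 3 breaks the chain
        ("RGRG", "RG-stretch", 1.0),
        ("RGAAARG", "RG-stretch", 0.0),     # 3 residues between dimers
        ("RGAARG", "RG-stretch", 1.0),      # 2 residues between dimers
        ("RGGGGG", "RG-stretch", 0.0),      # single dimer
    ])
    def test_stated_rules(self, seq, name, value):
        assert g.block_features(seq)[name] == pytest.approx(value)

    def test_matches_enumeration_on_binary_alphabet(self):
        # every length-10 sequence over {E, S}
        for code in range(2 ** 10):
            seq = "".join("E" if code >> i & 1 else "S" for i in range(10))
            bf = g.block_features(seq)
            for a in ("E", "S"):
                assert bf[f"Block {a}"] == pytest.approx(
                    patch_fraction_bruteforce(seq, a)), seq

    def test_matches_enumeration_on_random_sequences(self, rng, random_sequences):
        for seq in random_sequences(200, 30):
            bf = g.block_features(seq)
            for a in set(seq) - {"W"}:
                assert bf[f"Block {a}"] == pytest.approx(
                    patch_fraction_bruteforce(seq, a)), (seq, a)
            assert bf["RG-stretch"] == pytest.approx(
                rg_fraction_bruteforce(seq)), seq


# ---------------------------------------------------------------------------
# Patterning z-scores
# ---------------------------------------------------------------------------

class TestPatterning:
    def test_diblock_is_blocky(self):
        z, flagged = g.patterning_zscores("E" * 10 + "K" * 10,
                                          n_shuffles=500, seed=7)
        assert z["z pos-neg"] > 3
        assert "z pos-neg" not in flagged

    def test_sparse_class_flagged_zero(self):
        z, flagged = g.patterning_zscores("SSSSSSSSSSK", n_shuffles=100, seed=0)
        assert z["z pos-neg"] == 0.0
        assert "z pos-neg" in flagged

    def test_deterministic_per_seed(self):
        seq = "EKSPGAEKSPGAEKSPGA"
        z1, _ = g.patterning_zscores(seq, n_shuffles=100, seed=3)
        z2, _ = g.patterning_zscores(seq, n_shuffles=100, seed=3)
        pd.testing.assert_series_equal(z1, z2)

    def test_shuffle_count_floor(self):
        with pytest.raises(ValueError):
            g.patterning_zscores("EKEKEKEKEKEK", n_shuffles=10, seed=0)

    def test_null_sequences_center_on_zero(self, rng):
        # sequences drawn from their own shuffle null: z approximately N(0,1)
        base = list("E" * 8 + "K" * 8 + "S" * 14)
        zs = []
        for i in range(60):
            seq = "".join(rng.permutation(base))
            z, _ = g.patterning_zscores(
                seq, n_shuffles=300, seed=1000 + i,
                pairs=(("pos", "neg"),))
            zs.append(z["z pos-neg"])
        assert abs(np.mean(zs)) < 0.3
        assert 0.6 < np.std(zs) < 1.4


# ---------------------------------------------------------------------------
# Assembly, variability, rewiring
# ---------------------------------------------------------------------------

class TestFeatureVector:
    def test_ninety_named_values_in_fixed_order(self):
        fv = g.feature_vector("EKSPGAEKSPGAEKSPGA", n_shuffles=100, seed=0)
        assert len(fv.values) == 90
        assert tuple(fv.values.index) == g.FEATURE_NAMES

    def test_glycine_homopolymer(self):
        fv = g.feature_vector("G" * 40, n_shuffles=100, seed=0)
        assert fv.values["FCR"] == 0.0
        assert fv.values["NCPR"] == 0.0
        blocks = [n for n in g.FEATURE_NAMES if n.startswith("Block ")]
        for name in blocks:
            assert fv.values[name] == (1.0 if name == "Block G" else 0.0)
        assert fv.values["RG-stretch"] == 0.0

    def test_identical_input_identical_vector(self):
        a = g.feature_vector("EKSPGAY" * 6, n_shuffles=100, seed=5)
        b = g.feature_vector("EKSPGAY" * 6, n_shuffles=100, seed=5)
        pd.testing.assert_series_equal(a.values, b.values)


class TestVariability:
    def _fv(self, seq):
        return g.feature_vector(seq, n_shuffles=100, seed=0)

    def test_identical_segments_zero_sd(self):
        vecs = [self._fv("EKSPGAY" * 6)] * 3
        prof = g.feature_variability(vecs)
        assert prof.defined
        assert np.nanmax(prof.sd.to_numpy()) < 1e-12

    def test_population_sd_of_ncpr(self):
        vecs = [self._fv("K" * 20 + "SPGAY" * 2), self._fv("E" * 20 + "SPGAY" * 2)]
        # substitute clean +1/-1 NCPR columns to check the SD formula itself
        vecs[0].values["NCPR"], vecs[1].values["NCPR"] = 1.0, -1.0
        prof = g.feature_variability(vecs)
        assert prof.sd["NCPR"] == pytest.approx(1.0)

    def test_three_segments_match_direct_formula(self):
        seqs = ["EKSPGAY" * 6, "KKSPGAY" * 6, "EESPGAY" * 6]
        vecs = [self._fv(s) for s in seqs]
        prof = g.feature_variability(vecs)
        direct = np.std([v.values["NCPR"] for v in vecs], ddof=0)
        assert prof.sd["NCPR"] == pytest.approx(direct)

    def test_single_segment_undefined(self):
        prof = g.feature_variability([self._fv("EKSPGAY" * 6)])
        assert not prof.defined
        assert prof.sd.isna().all()


class TestRewiring:
    @pytest.mark.parametrize("seq,mode,expected", [
        ("DDEE", "AtoB", "RRKK"),
        ("DDEE", "BtoA", "DDEE"),       # no basic residues: fixed point
        ("DDEE", "AtoNon", "SSSS"),
        ("KRKR", "BtoA", "EDED"),
        ("KRKR", "BtoNon", "SSSS"),
        ("GAGA", "AtoB", "GAGA"),
    ])
    def test_substitution_maps(self, seq, mode, expected):
        assert g.rewire_charges(seq, mode) == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            g.rewire_charges("DDEE", "XtoY")

    @staticmethod
    def _ncpr(seq):
        return (sum(seq.count(a) for a in "KR")
                - sum(seq.count(a) for a in "DE")) / len(seq)

    def test_atob_strictly_increases_ncpr(self, rng, random_sequences):
        for seq in random_sequences(100, 40):
            out = g.rewire_charges(seq, "AtoB")
            if any(a in seq for a in "DE"):
                assert self._ncpr(out) > self._ncpr(seq)
            else:
                assert out == seq
            # symmetry: BtoA mirrors AtoB
            back = g.rewire_charges(seq, "BtoA")
            if any(a in seq for a in "KR"):
                assert self._ncpr(back) < self._ncpr(seq)

    def test_balanced_substitution_minimizes_ncpr(self, rng, random_sequences):
        for seq in random_sequences(100, 30):
            out = g.rewire_charges(seq, "BS")
            assert len(out) == len(seq)
            # exhaustive oracle over substitution counts
            n_basic = sum(seq.count(a) for a in "KR")
            n_acid = sum(seq.count(a) for a in "DE")
            best = min(abs((n_basic - n_acid) + 2 * s) / len(seq)
                       for s in range(n_acid + 1))
            assert abs(self._ncpr(out)) == pytest.approx(best)
            # only acidic positions change, and only to basic residues
            for a, b in zip(seq, out):
                if a != b:
                    assert a in "DE" and b in "KR"

    def test_balanced_substitution_example(self):
        out = g.rewire_charges("DDDDKK", "BS")
        assert self._ncpr(out) == 0.0
        assert out == "RDDDKK"  # one substitution suffices, leftmost first
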