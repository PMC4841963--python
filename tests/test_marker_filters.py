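from __future__ import annotations

import numpy as np
import pytest
from Bio.Restriction import Restriction
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from genicmark.io_formats import TranscriptSeq, VariantRecord
from genicmark.marker_filters import (
    FilterFlags,
    RestrictionEnzyme,
    allele_contexts,
    apply_all,
    count_site_matches,
    flag_cef,
    flag_cl60,
    flag_cs60,
    flag_hv,
    load_enzymes,
)

from .conftest import random_dna
from .oracles import (
    brute_force_cl,
    brute_force_cs,
    brute_force_hv,
    cut_positions,
    differential_enzymes_by_digestion,
)


class TestCs60:
    def test_pair_at_50_both_flagged(self):
        assert flag_cs60([100, 150]) == [True, True]

    def test_pair_at_exactly_60_passes(self):
        assert flag_cs60([100, 160]) == [False, False]

    def test_single_variant_unflagged(self):
        assert flag_cs60([500]) == [False]

    def test_unsorted_input_and_duplicates(self):
        assert flag_cs60([300, 100, 100]) == [False, True, True]

    @settings(max_examples=80, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=1999), min_size=1, max_size=40))
    def test_oracle_equivalence(self, positions):
        assert flag_cs60(positions) == brute_force_cs(positions)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=1999), min_size=1, max_size=20),
        st.integers(min_value=61, max_value=120),
    )
    def test_growing_threshold_never_unflags(self, positions, bigger):
        base = flag_cs60(positions, 60)
        grown = flag_cs60(positions, bigger)
        assert all(g or not b for b, g in zip(base, grown))


class TestCl60:
    def test_59_flagged(self):
        assert flag_cl60(59, 1000) is True

    def test_60_passes(self):
        assert flag_cl60(60, 1000) is False

    def test_right_edge(self):
        assert flag_cl60(950, 1000) is True  # 49 nt from the right edge
        assert flag_cl60(939, 1000) is False  # exactly 60 from the right edge

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            flag_cl60(1000, 1000)

    @settings(max_examples=80, deadline=None)
    @given(st.integers(min_value=0, max_value=1999))
    def test_oracle_equivalence(self, pos):
        assert flag_cl60(pos, 2000) == brute_force_cl(pos, 2000)


class TestHv:
    def test_six_in_90_all_flagged(self):
        positions = [100, 118, 136, 154, 172, 190]  # span 90 nt
        assert flag_hv(positions) == [True] * 6

    def test_five_in_90_none_flagged(self):
        positions = [100, 120, 140, 160, 180]
        assert flag_hv(positions) == [False] * 5

    def test_six_spanning_exactly_100_not_flagged(self):
        positions = [100, 120, 140, 160, 180, 200]  # span 100 > window-1
        assert flag_hv(positions) == [False] * 6

    @settings(max_examples=80, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=1999), min_size=1, max_size=40))
    def test_oracle_equivalence(self, positions):
        assert flag_hv(positions) == brute_force_hv(positions)


ENZYMES = load_enzymes()
SITES = {e.name: e.site for e in ENZYMES}


class TestCountSiteMatches:
    def test_iupac_degenerate_w(self):
        enzyme = RestrictionEnzyme("AvaII", "GGWCC")
        assert count_site_matches("AAGGACCAA", enzyme) >= 1
        assert count_site_matches("AAGGTCCAA", enzyme) >= 1
        assert count_site_matches("AAGGGCCAA", enzyme) == 0

    def test_palindrome_counted_on_both_strands(self):
        enzyme = RestrictionEnzyme("EcoRI", "GAATTC")
        assert count_site_matches("AAGAATTCAA", enzyme) == 2  # fwd + rev strand

    def test_non_palindromic_site_found_on_reverse(self):
        enzyme = RestrictionEnzyme("FokI-like", "GGATG")
        assert count_site_matches("AACATCCAA", enzyme) == 1  # revcomp CATCC

    @pytest.mark.parametrize("enzyme", ENZYMES, ids=lambda e: e.name)
    @pytest.mark.parametrize("seed", [0, 1])
    def test_against_biopython_restriction(self, enzyme, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 500) + enzyme.site + random_dna(rng, 500)
        bio = getattr(Restriction, enzyme.name)
        n_bio = len(bio.search(Seq(seq)))
        # catalogue sites are palindromic: two strand matches per locus
        assert count_site_matches(seq, enzyme) == 2 * n_bio


class TestFlagCef:
    def test_destroyed_ecori_site_is_differential(self):
        rng = np.random.default_rng(0)
        left, right = _scrub(random_dna(rng, 80)), _scrub(random_dna(rng, 80))
        seq = left + "GAATTC" + right
        pos = len(left) + 2  # the first A of GAATTC
        ts = TranscriptSeq("t1", seq)
        v = VariantRecord("t1", pos, "A", ("C",))
        cef_pass, names = flag_cef(v, ts, ENZYMES)
        assert cef_pass
        assert "EcoRI" in names

    def test_no_site_no_pass(self):
        rng = np.random.default_rng(1)
        seq = _scrub(random_dna(rng, 300))
        ts = TranscriptSeq("t1", seq)
        v = VariantRecord("t1", 150, seq[150], (_other(seq[150]),))
        # the substituted base itself may create a site; check via oracle
        ref_ctx, alt_ctx = allele_contexts(v, ts)[0]
        expected = differential_enzymes_by_digestion(ref_ctx, alt_ctx, SITES)
        cef_pass, names = flag_cef(v, ts, ENZYMES)
        assert cef_pass == bool(expected)

    def test_multiallelic_passes_if_any_alt_differential(self):
        rng = np.random.default_rng(2)
        left, right = _scrub(random_dna(rng, 80)), _scrub(random_dna(rng, 80))
        seq = left + "GGATCC" + right
        pos = len(left)  # first G of the BamHI site
        ts = TranscriptSeq("t1", seq)
        v = VariantRecord("t1", pos, "G", ("A", "C"))
        cef_pass, names = flag_cef(v, ts, ENZYMES)
        assert cef_pass
        assert "BamHI" in names

    def test_indel_breaking_site(self):
        rng = np.random.default_rng(3)
        left, right = _scrub(random_dna(rng, 80)), _scrub(random_dna(rng, 80))
        left = left[:-1] + "G"  # deletion must not recreate the site
        seq = left + "AAGCTT" + right
        pos = len(left)
        ts = TranscriptSeq("t1", seq)
        v = VariantRecord("t1", pos, seq[pos : pos + 2], (seq[pos],))  # deletion
        cef_pass, names = flag_cef(v, ts, ENZYMES)
        assert cef_pass
        assert "HindIII" in names


def _other(base: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[base]


def _scrub(seq: str) -> str:
    """Remove accidental catalogue sites so fixtures are unambiguous."""
    seq = list(seq)
    for _ in range(100):
        dirty = False
        text = "".join(seq)
        for site in SITES.values():
            for s in cut_positions(text, site):
                seq[s + 2] = _other(seq[s + 2])
                dirty = True
                break
            if dirty:
                break
        if not dirty:
            return "".join(seq)
    raise AssertionError("could not scrub fixture")


class TestCefDigestionOracle:
    @pytest.mark.parametrize("seed", range(25))
    def test_random_2kb_snps(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 2000)
        # plant a site for half the fixtures so differentials are common
        if seed % 2 == 0:
            enz = ENZYMES[seed % len(ENZYMES)]
            at = int(rng.integers(200, 1800))
            seq = seq[:at] + enz.site + seq[at + len(enz.site) :]
        ts = TranscriptSeq("t1", seq)
        for _ in range(5):
            pos = int(rng.integers(60, 1940))
            ref = seq[pos]
            v = VariantRecord("t1", pos, ref, (_other(ref),))
            ref_ctx, alt_ctx = allele_contexts(v, ts)[0]
            expected = differential_enzymes_by_digestion(ref_ctx, alt_ctx, SITES)
            cef_pass, names = flag_cef(v, ts, ENZYMES)
            assert set(names) == expected
            assert cef_pass == bool(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_indels(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = random_dna(rng, 2000)
        ts = TranscriptSeq("t1", seq)
        for _ in range(5):
            pos = int(rng.integers(60, 1900))
            if rng.random() < 0.5:
                v = VariantRecord("t1", pos, seq[pos : pos + 3], (seq[pos],))
            else:
                v = VariantRecord("t1", pos, seq[pos], (seq[pos] + "ACG",))
            ref_ctx, alt_ctx = allele_contexts(v, ts)[0]
            expected = differential_enzymes_by_digestion(ref_ctx, alt_ctx, SITES)
            cef_pass, names = flag_cef(v, ts, ENZYMES)
            assert set(names) == expected


class TestApplyAll:
    def _variants(self, seq, positions):
        return [VariantRecord("t1", p, seq[p], (_other(seq[p]),)) for p in positions]

    def test_failing_only_cef_is_not_filtered(self):
        rng = np.random.default_rng(5)
        seq = _scrub(random_dna(rng, 1000))
        ts = TranscriptSeq("t1", seq)
        (v,) = self._variants(seq, [500])
        (flags,) = apply_all([v], [ts])
        if not flags.cef_pass:
            assert not flags.filtered
        assert not (flags.cs60 or flags.cl60 or flags.hv)

    def test_clean_caps_site_is_filtered(self):
        rng = np.random.default_rng(6)
        left, right = _scrub(random_dna(rng, 400)), _scrub(random_dna(rng, 400))
        seq = left + "GAATTC" + right
        pos = len(left) + 2
        ts = TranscriptSeq("t1", seq)
        v = VariantRecord("t1", pos, "A", ("C",))
        (flags,) = apply_all([v], [ts])
        assert flags.filtered
        assert flags.flag_names == ()

    def test_filtered_invariant(self):
        f = FilterFlags(cs60=False, cl60=False, hv=False, cef_pass=True)
        assert f.filtered
        for bad in (
            FilterFlags(True, False, False, True),
            FilterFlags(False, True, False, True),
            FilterFlags(False, False, True, True),
            FilterFlags(False, False, False, False),
        ):
            assert not bad.filtered

    def test_order_invariance(self, rng):
        seq = random_dna(rng, 1500)
        ts = TranscriptSeq("t1", seq)
        positions = [70, 120, 400, 900, 1200, 1210, 1220, 1230, 1240, 1250]
        variants = self._variants(seq, positions)
        fwd = apply_all(variants, [ts])
        perm = list(reversed(range(len(variants))))
        rev = apply_all([variants[i] for i in perm], [ts])
        for i, j in enumerate(perm):
            assert fwd[j] == rev[i]

    def test_shrinking_catalogue_never_enables_cef(self, rng):
        seq = random_dna(rng, 800)
        ts = TranscriptSeq("t1", seq)
        variants = self._variants(seq, [200, 400, 600])
        full = apply_all(variants, [ts], ENZYMES)
        subset = apply_all(variants, [ts], ENZYMES[:5])
        for f_full, f_sub in zip(full, subset):
            assert not (f_sub.cef_pass and not f_full.cef_pass)

    def test_missing_transcript_errors(self):
        v = VariantRecord("missing", 10, "A", ("G",))
        with pytest.raises(KeyError):
            apply_all([v], [TranscriptSeq("t1", "ACGT" * 100)])


class TestLoadEnzymes:
    def test_default_catalogue(self):
        enzymes = load_enzymes()
        assert len(enzymes) == 20
        assert all(len(e.site) >= 4 for e in enzymes)
        by_name = {e.name: e.site for e in enzymes}
        assert by_name["EcoRI"] == "GAATTC"

    def test_custom_catalogue(self, tmp_path):
        p = tmp_path / "enz.tsv"
        p.write_text("name\tsite\tcommon\nHincII\tGTYRAC\tyes\n")
        (enz,) = load_enzymes(p)
        assert enz.site == "GTYRAC"

    def test_short_site_rejected(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "ACG")

    def test_bad_iupac_rejected(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("bad", "ACGQ")
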