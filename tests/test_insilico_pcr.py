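"""Virtual PCR: IUPAC matching, binding-site search, amplicon profiling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampbias.insilico_pcr import (
    IUPAC_EXPANSION,
    AlphabetError,
    PrimerPair,
    degeneracy,
    find_binding_site,
    gc_fraction,
    iupac_match,
    profile_panel,
    reverse_complement,
    virtual_pcr,
)
from ampbias.synthetic_data import synthesize_template

# Independent oracle: IUPAC code definitions written out from first
# principles (two-base codes by name, three-base codes as "not X").
ORACLE_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT",  # not A
    "D": "AGT",  # not C
    "H": "ACT",  # not G
    "V": "ACG",  # not T
    "N": "ACGT",
}


def brute_force_site(template, primer, max_gaps=1):
    """Enumerate every placement (internal gaps only); min (mm, gaps, start)."""

    def match(p, t):
        if t == "N":
            return p == "N"
        return t in IUPAC_EXPANSION[p]

    def hamming(p, t):
        return sum(not match(a, b) for a, b in zip(p, t))

    m, n = len(primer), len(template)
    cands = []
    for start in range(n - m + 1):
        cands.append((hamming(primer, template[start:start + m]), 0, start))
    if max_gaps >= 1:
        for skip in range(1, m - 1):  # internal primer-base deletion
            sub = primer[:skip] + primer[skip + 1:]
            for start in range(n - (m - 1) + 1):
                cands.append(
                    (hamming(sub, template[start:start + m - 1]), 1, start)
                )
        for gap in range(1, m):  # internal template-base insertion
            for start in range(n - (m + 1) + 1):
                seg = template[start:start + m + 1]
                cands.append((hamming(primer, seg[:gap] + seg[gap + 1:]), 1, start))
    return min(cands)


class TestIupacMatch:
    def test_degenerate_base_matches_expansion_members(self):
        assert iupac_match("R", "A")
        assert iupac_match("R", "G")
        assert not iupac_match("R", "C")
        assert iupac_match("A", "A")

    @pytest.mark.parametrize(
        "code,base", list(itertools.product(sorted(IUPAC_EXPANSION), "ACGT"))
    )
    def test_truth_table_matches_expansion_oracle(self, code, base):
        assert iupac_match(code, base) == (base in ORACLE_EXPANSION[code])

    def test_invalid_symbols_are_named(self):
        with pytest.raises(AlphabetError, match="Z"):
            iupac_match("Z", "A")
        with pytest.raises(AlphabetError):
            iupac_match("A", "R")  # ambiguous template base rejected

    def test_degeneracy_counts(self):
        assert degeneracy("ACGT") == 1
        assert degeneracy("RN") == 2 * 4


class TestFindBindingSite:
    def test_planted_exact_site(self, rng):
        primer = "GCCGGTAAAACTCGTGCCAGC"
        flank = "".join(rng.choice(list("ACGT"), 30))
        tpl = flank + primer + flank[::-1]
        site = find_binding_site(tpl, primer)
        assert (site.mismatches, site.gaps, site.start) == (0, 0, 30)
        assert site.end == 30 + len(primer)

    def test_planted_single_substitution(self, rng):
        primer = "GCCGGTAAAACTCGTGCCAGC"
        mutated = primer[:10] + "T" + primer[11:]  # A -> T internal
        tpl = "ACGT" * 10 + mutated + "TGCA" * 10
        site = find_binding_site(tpl, primer)
        assert (site.mismatches, site.gaps, site.start) == (1, 0, 40)

    def test_insertion_in_binding_region_found_as_gap(self, panel_by_name, rng):
        # A 1-bp insertion offsets the site; the gapped placement must beat
        # every ungapped one on mismatches.
        pair = panel_by_name["MiFishU"]
        tpl = synthesize_template(pair, 0, 0, 0.5, 120, rng, fwd_insertion_at=10)
        site = find_binding_site(tpl, pair.forward)
        mm_ungapped, _, _ = brute_force_site(tpl, pair.forward, max_gaps=0)
        assert site.gaps == 1
        assert site.offset != 0 or site.mismatches < mm_ungapped
        assert site.mismatches < mm_ungapped

    def test_not_found_is_none_not_error(self):
        assert find_binding_site("ACGT" * 20, "GGGGGGGGGGGGGGGG", max_mismatches=2) is None

    def test_empty_template_is_input_error(self):
        with pytest.raises(AlphabetError):
            find_binding_site("", "ACGT")

    def test_reverse_role_searches_minus_strand(self, rng):
        primer = "CATAGTGGGGTATCTAATCCCAGTTTG"
        flank = "".join(rng.choice(list("ACGT"), 25))
        tpl = flank + reverse_complement(primer) + flank
        site = find_binding_site(tpl, primer, role="reverse")
        assert site.mismatches == 0
        assert site.strand == "-"
        assert site.start == 25

    @pytest.mark.parametrize("seed", range(40))
    def test_plant_and_recover_matches_brute_force(self, panel, seed):
        rng = np.random.default_rng(seed)
        pair = panel[seed % len(panel)]
        mm = int(rng.integers(0, 5))
        gapped = bool(rng.integers(0, 2))
        kw = {}
        if gapped:
            kw["fwd_insertion_at"] = int(rng.integers(5, len(pair.forward) - 4))
        tpl = synthesize_template(pair, mm, 0, 0.45, 150, rng, **kw)
        site = find_binding_site(tpl, pair.forward)
        bf_mm, bf_g, bf_start = brute_force_site(tpl, pair.forward)
        assert (site.mismatches, site.gaps, site.start) == (bf_mm, bf_g, bf_start)
        assert (site.mismatches, site.gaps) == (mm, 1 if gapped else 0)


class TestVirtualPcr:
    def test_constructed_insert_length_and_gc(self, panel_by_name):
        pair = panel_by_name["MarVer3"]
        tpl = (
            "AGACGAGAAGACCCTATG" + "ATGC" * 25 + reverse_complement("GGATTGCGCTGTTATCCC")
        )
        prof, insert = virtual_pcr(tpl, pair)
        assert prof.amplifiable
        assert prof.length_bp == 100
        assert prof.gc == pytest.approx(0.5)
        assert insert == "ATGC" * 25
        assert (prof.mm_fwd, prof.mm_rev) == (0, 0)

    @pytest.mark.parametrize("insert,expected", [("AAAA", 0.0), ("GGCC", 1.0)])
    def test_gc_boundaries(self, panel_by_name, insert, expected):
        pair = panel_by_name["MarVer3"]
        tpl = "AGACGAGAAGACCCTATG" + insert + reverse_complement("GGATTGCGCTGTTATCCC")
        prof, _ = virtual_pcr(tpl, pair)
        assert prof.gc == pytest.approx(expected)

    def test_inverted_sites_flagged_not_raised(self, panel_by_name):
        pair = panel_by_name["MarVer3"]
        tpl = reverse_complement("GGATTGCGCTGTTATCCC") + "AGACGAGAAGACCCTATG"
        prof, insert = virtual_pcr(tpl, pair, both_orientations=False)
        assert not prof.amplifiable
        assert prof.reason in ("sites_overlapping_or_inverted", "empty_insert")
        assert insert == ""

    def test_reverse_complement_symmetry(self, panel, rng):
        for pair in panel:
            tpl = synthesize_template(pair, 2, 1, 0.42, 140, rng)
            fwd_prof, _ = virtual_pcr(tpl, pair)
            rc_prof, _ = virtual_pcr(reverse_complement(tpl), pair)
            assert fwd_prof.amplifiable and rc_prof.amplifiable
            assert (fwd_prof.mm_fwd, fwd_prof.mm_rev) == (rc_prof.mm_fwd, rc_prof.mm_rev)
            assert fwd_prof.length_bp == rc_prof.length_bp
            assert fwd_prof.gc == pytest.approx(rc_prof.gc)

    def test_degeneracy_monotonicity(self, rng):
        # widening a primer base to a superset code never adds mismatches
        supersets = {"A": "RWMDHVN", "C": "YSMBHVN", "G": "RSKBDVN", "T": "YWKBDHN"}
        primer = "GCCGGTAAAACTCGTGCCAGC"
        tpl = "ACGT" * 8 + primer[:8] + "T" + primer[9:] + "GTCA" * 8
        base_site = find_binding_site(tpl, primer)
        for pos in range(len(primer)):
            wide = primer[:pos] + supersets[primer[pos]][0] + primer[pos + 1:]
            site = find_binding_site(tpl, wide)
            assert site.mismatches <= base_site.mismatches


class TestProfilePanel:
    def test_planted_grid_recovered(self, panel, rng):
        pairs = panel[:2]
        planted = {}
        templates = {}
        for i, mm in enumerate([(0, 0), (1, 0), (2, 1)]):
            for pair in pairs:
                tid = f"sp{i}"
                planted[(tid, pair.marker_name)] = mm
            # one template per species containing only the first pair's site
        for i, mm in enumerate([(0, 0), (1, 0), (2, 1)]):
            templates[f"sp{i}"] = synthesize_template(pairs[0], *mm, 0.5, 100, rng)
        table = profile_panel(templates, pairs)
        assert len(table) == 6
        # deterministic row order: template order x panel order
        assert list(table["species"][:2]) == ["sp0", "sp0"]
        own = table[table["marker"] == pairs[0].marker_name].set_index("species")
        for i, (mf, mr) in enumerate([(0, 0), (1, 0), (2, 1)]):
            assert own.loc[f"sp{i}", "mm_fwd"] == mf
            assert own.loc[f"sp{i}", "mm_rev"] == mr

    def test_absent_pair_row_not_amplifiable(self, panel, rng):
        # a 12S template carries no 16S binding sites at a strict ceiling
        tpl = synthesize_template(panel[0], 0, 0, 0.5, 100, rng)
        table = profile_panel({"sp": tpl}, [panel[3]], max_mismatches=4)
        assert not table["amplifiable"].iloc[0]

    def test_duplicate_template_ids_rejected(self, panel):
        with pytest.raises(ValueError, match="duplicate"):
            profile_panel([("a", "ACGT" * 30), ("a", "TGCA" * 30)], [panel[0]])


@settings(max_examples=50, deadline=None)
@given(
    a=st.text(alphabet="ACGT", min_size=1, max_size=80),
    b=st.text(alphabet="ACGT", min_size=1, max_size=80),
)
def test_gc_concatenation_is_length_weighted_mean(a, b):
    combined = gc_fraction(a + b)
    expected = (gc_fraction(a) * len(a) + gc_fraction(b) * len(b)) / (len(a) + len(b))
    assert combined == pytest.approx(expected)
    assert 0.0 <= combined <= 1.0


def test_primer_pair_validates_alphabet():
    with pytest.raises(AlphabetError):
        PrimerPair("bad", "12S", "ACGTX", "ACGT")
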