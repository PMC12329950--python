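import numpy as np
import pytest

from markerkit import datasets
from markerkit.errors import DesignError, ValidationError
from markerkit.scar import (
    DesignConstraints,
    PrimerPair,
    assess_specificity,
    design_scar_primers,
    estimate_tm,
    find_primer_sites,
    insilico_pcr,
    reverse_complement,
    specificity_matrix,
)
from markerkit.synthetic import DecoySpec, TemplateLayout, gen_pcr_template

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def oracle_sites(template, primer, max_mismatch, zone):
    """Naive sliding-window scan over both strands (independent oracle)."""
    hits = []
    rc = reverse_complement(primer)
    k = len(primer)
    for off in range(len(template) - k + 1):
        win = template[off : off + k]
        mm = sum(t not in IUPAC[p] for p, t in zip(primer, win))
        tail = sum(t not in IUPAC[p] for p, t in zip(primer[-zone:], win[-zone:]))
        if mm <= max_mismatch and tail == 0:
            hits.append((off + 1, "+", mm))
        mm = sum(t not in IUPAC[p] for p, t in zip(rc, win))
        tail = sum(t not in IUPAC[p] for p, t in zip(rc[:zone], win[:zone]))
        if mm <= max_mismatch and tail == 0:
            hits.append((off + 1, "-", mm))
    return sorted(hits)


class TestPrimerSites:
    def test_exact_embedded_site(self):
        template = "T" * 20 + "GGAACACGAAGAGCATGAAC" + "T" * 20
        hits = find_primer_sites(template, "GGAACACGAAGAGCATGAAC")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand, hits[0].mismatches) == (21, "+", 0)

    def test_internal_mismatch_tolerated_3prime_not(self):
        primer = "ACGTACGTACGTACGTACGT"
        internal = "ACGTACGAACGTACGTACGT"  # pos 8 mismatch
        terminal = "ACGTACGTACGTACGTACGA"  # 3' end mismatch
        t1 = "TTTT" + internal + "TTTT"
        t2 = "TTTT" + terminal + "TTTT"
        assert find_primer_sites(t1, primer, max_mismatch=1)
        assert not [
            h for h in find_primer_sites(t2, primer, max_mismatch=1)
            if h.strand == "+"
        ]

    def test_iupac_class_matching(self):
        # Y matches C or T but not A/G
        assert [h for h in find_primer_sites("CCATGCC", "AYG") if h.strand == "+"]
        assert [h for h in find_primer_sites("CCACGCC", "AYG") if h.strand == "+"]
        assert not [
            h for h in find_primer_sites("CCAAGCC", "AYG") if h.strand == "+"
        ]

    def test_primer_longer_than_template_gives_no_hits(self):
        assert find_primer_sites("ACG", "ACGTACGT") == []

    def test_matches_sliding_window_oracle(self, rng):
        primer = "ACGTWCGTAY"
        for _ in range(10):
            template = "".join(rng.choice(list("ACGT"), size=200))
            for mm in (0, 1, 2):
                got = sorted(
                    (h.start, h.strand, h.mismatches)
                    for h in find_primer_sites(template, primer, max_mismatch=mm)
                )
                assert got == oracle_sites(template, primer, mm, 3)


class TestInsilicoPcr:
    def test_constructed_template_gives_223bp_product(self):
        pair = datasets.SCAR_PAIRS["A_annua"]
        rng = np.random.default_rng(0)
        spacer = "".join(rng.choice(list("ACGT"), size=184))
        template = pair.forward + spacer + reverse_complement(pair.reverse)
        hits = insilico_pcr(template, pair)
        assert len(hits) == 1
        assert hits[0].length == 223

    def test_template_without_site_yields_nothing(self):
        pair = datasets.SCAR_PAIRS["A_annua"]
        assert insilico_pcr("ACGT" * 100, pair) == []

    def test_strand_symmetry(self, rng):
        pair = datasets.SCAR_PAIRS["A_monosperma"]
        layout = TemplateLayout(spacers={"A_monosperma": 324})
        tpl = gen_pcr_template({"A_monosperma": pair}, layout, seed=4)
        fwd_hits = insilico_pcr(tpl.seqs[0], pair)
        rev_hits = insilico_pcr(reverse_complement(tpl.seqs[0]), pair)
        assert [h.length for h in fwd_hits] == [h.length for h in rev_hits] == [361]

    @pytest.mark.parametrize("spacer", [0, 1, 17, 100, 250, 500])
    def test_length_identity_over_spacers(self, spacer, rng):
        pair = PrimerPair("x", "GGAACACGAAGAGCATGAAC", "CCATTACGCCACCCACTAC")
        mid = "".join(rng.choice(list("ACGT"), size=spacer))
        template = "TT" + pair.forward + mid + reverse_complement(pair.reverse) + "TT"
        hits = insilico_pcr(template, pair)
        assert [h.length for h in hits] == [len(pair.forward) + spacer + len(pair.reverse)]

    def test_products_over_cap_discarded(self):
        pair = PrimerPair("x", "GGAACACGAAGAGCATGAAC", "CCATTACGCCACCCACTAC")
        template = pair.forward + "A" * 600 + reverse_complement(pair.reverse)
        assert insilico_pcr(template, pair, max_product=500) == []


class TestSpecificity:
    def test_diagonal_templates_are_specific(self):
        pairs = list(datasets.SCAR_PAIRS.values())
        spacers = {
            sp: datasets.SCAR_PAIRS[sp].product_length
            - len(datasets.SCAR_PAIRS[sp].forward)
            - len(datasets.SCAR_PAIRS[sp].reverse)
            for sp in datasets.SPECIES
        }
        templates = gen_pcr_template(
            dict(datasets.SCAR_PAIRS), TemplateLayout(spacers=spacers), seed=11
        )
        df = specificity_matrix(pairs, templates)
        expected = np.eye(4, dtype=int)
        assert np.array_equal(df.loc[[p.name for p in pairs], list(datasets.SPECIES)].values, expected)
        ok = assess_specificity(
            df, {datasets.SCAR_PAIRS[sp].name: sp for sp in datasets.SPECIES}
        )
        assert all(ok.values())

    def test_shared_site_flags_non_specific(self):
        pair = PrimerPair("p", "GGAACACGAAGAGCATGAAC", "CCATTACGCCACCCACTAC")
        core = pair.forward + "A" * 50 + reverse_complement(pair.reverse)
        df = specificity_matrix([pair], {"own": core, "other": "GG" + core})
        assert df.loc["p"].sum() == 2
        assert not assess_specificity(df, {"p": "own"})["p"]

    def test_decoy_with_mismatches_does_not_amplify(self):
        pair = datasets.SCAR_PAIRS["A_judaica"]
        layout = TemplateLayout(
            spacers={"A_judaica": 265},
            decoys=[DecoySpec("A_judaica", pair.forward, 2)],
        )
        tpl = gen_pcr_template({"A_judaica": pair}, layout, seed=5)
        hits = insilico_pcr(tpl.seqs[0], pair, max_mismatch=0)
        assert [h.length for h in hits] == [303]


class TestTm:
    @pytest.mark.parametrize("primer,tm", [("AAAA", 8.0), ("GGGG", 16.0)])
    def test_wallace_rule(self, primer, tm):
        assert estimate_tm(primer) == tm

    def test_20mer_with_half_gc(self):
        assert estimate_tm("AT" * 5 + "GC" * 5) == 60.0

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValidationError):
            estimate_tm("ACGTN")


class TestDesign:
    @staticmethod
    def synthetic_fragment(rng, length=500, decamer="GGCACTGAGG"):
        interior = "".join(rng.choice(list("ACGT"), size=length - 20))
        return decamer + interior + reverse_complement(decamer)

    def test_primers_exclude_decamer_regions(self, rng):
        frag = self.synthetic_fragment(rng)
        pairs = design_scar_primers(frag, "GGCACTGAGG")
        assert pairs
        for pair in pairs[:20]:
            fpos = frag.find(pair.forward)
            rpos = frag.find(reverse_complement(pair.reverse))
            assert fpos >= 10
            assert rpos + len(pair.reverse) <= len(frag) - 10

    def test_short_fragment_rejected(self):
        with pytest.raises(DesignError):
            design_scar_primers("GGCACTGAGG" + "A" * 10 + "CCTCAGTGCC", "GGCACTGAGG")

    def test_fragment_must_be_decamer_flanked(self, rng):
        frag = "T" * 500
        with pytest.raises(DesignError):
            design_scar_primers(frag, "GGCACTGAGG")

    def test_impossible_constraints_give_empty_list(self, rng):
        frag = self.synthetic_fragment(rng)
        cons = DesignConstraints(gc_min=99.0, gc_max=100.0)
        assert design_scar_primers(frag, "GGCACTGAGG", cons) == []

    def test_designed_pairs_amplify_one_product_of_predicted_length(self, rng):
        frag = self.synthetic_fragment(rng)
        pairs = design_scar_primers(frag, "GGCACTGAGG")
        for pair in pairs[:5]:
            hits = insilico_pcr(frag, pair)
            assert len(hits) == 1
            assert hits[0].length == pair.product_length

    def test_scar_length_validator(self):
        for sp, pair in datasets.SCAR_PAIRS.items():
            pair.validate_scar()
        lengths = {
            sp: (len(p.forward), len(p.reverse))
            for sp, p in datasets.SCAR_PAIRS.items()
        }
        assert lengths == {
            "A_annua": (20, 19),
            "A_herba-alba": (19, 20),
            "A_monosperma": (19, 18),
            "A_judaica": (20, 18),
        }
        with pytest.raises(ValidationError):
            PrimerPair("short", "ACGTACGTACGT", "ACGTACGTACGTACGTAC").validate_scar()
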