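"""Digestion (cut to completion, fragment selection) and sticky-end ligation."""

import random

import pytest

from cfsim.digest import cut_all, ends_compatible, simulate_digest, simulate_ligate
from cfsim.dna import Chem, Polynucleotide, Protrusion, equivalent
from cfsim.errors import DigestError, LigationError
from cfsim.fixtures import make_primer_pair, make_random_dna
from cfsim.pcr import simulate_pcr


class TestCutAll:
    def test_two_fragment_scenario_preserves_outer_chemistry(self, fig2_style_substrate, table):
        """An EcoRI digest of a BamHI/XmaI-ended linear DNA yields two
        fragments; the dephosphorylated BamHI end survives on fragment 0 and
        both fresh EcoRI ends are phosphorylated AATT 5' overhangs."""
        frags = cut_all(fig2_style_substrate, [table.lookup("EcoRI")])
        assert len(frags) == 2
        left, right = frags
        assert left.ext5 == "GATC" and left.mod_ext5 is Chem.HYDROXYL
        assert left.ext3 == "AATT" and left.ext3_kind is Protrusion.FIVE_PRIME
        assert left.mod_ext3 is Chem.PHOSPHATE
        assert right.ext5 == "AATT" and right.mod_ext5 is Chem.PHOSPHATE
        assert right.ext3 == "CCGG" and right.mod_ext3 is Chem.PHOSPHATE

    def test_single_cut_linearises_plasmid(self, table):
        plasmid = make_random_dna(300, seed=21, circular=True,
                                  required_sites=[("GAATTC", 150)])
        frags = cut_all(plasmid, [table.lookup("EcoRI")])
        assert len(frags) == 1
        frag = frags[0]
        assert not frag.is_circular
        assert frag.ext5 == frag.ext3 == "AATT"
        assert frag.mod_ext5 is Chem.PHOSPHATE and frag.mod_ext3 is Chem.PHOSPHATE
        assert len(frag.sequence) + len(frag.ext5) == 300

    def test_zero_sites_returns_parent_unchanged(self, table):
        dna = make_random_dna(200, seed=22, forbidden_patterns=["GAATTC"])
        assert cut_all(dna, [table.lookup("EcoRI")]) == [dna]

    def test_three_prime_overhang_cutter(self, table):
        dna = make_random_dna(120, seed=23, required_sites=[("CTGCAG", 60)])
        left, right = cut_all(dna, [table.lookup("PstI")])
        assert left.ext3 == "TGCA" and left.ext3_kind is Protrusion.THREE_PRIME

    def test_single_stranded_substrate_rejected(self, table):
        with pytest.raises(DigestError):
            cut_all(Polynucleotide.oligo("ACGT" * 10), [table.lookup("EcoRI")])

    def test_digestion_is_idempotent(self, table):
        enzymes = [table.lookup("EcoRI"), table.lookup("BsaI")]
        plasmid = make_random_dna(
            500, seed=24, circular=True,
            required_sites=[("GAATTC", 100), ("GGTCTC", 300)],
        )
        frags = cut_all(plasmid, enzymes)
        for frag in frags:
            assert cut_all(frag, enzymes) == [frag]

    def test_circular_fragment_zero_starts_at_first_cut_of_first_enzyme(self, table):
        plasmid = make_random_dna(
            400, seed=25, circular=True,
            required_sites=[("GGATCC", 50), ("GAATTC", 200)],
        )
        # EcoRI listed first: fragment 0 begins at the EcoRI cut (pos 201)
        frags = cut_all(plasmid, [table.lookup("EcoRI"), table.lookup("BamHI")])
        assert len(frags) == 2
        assert frags[0].ext5 == "AATT" and frags[0].ext3 == "GATC"

    def test_conservation_on_circular_parents(self, table):
        """Sum of duplex length + one overhang per junction equals the
        parent length, over many seeded random plasmids."""
        enz = [table.lookup("EcoRI"), table.lookup("BamHI"), table.lookup("PstI")]
        for seed in range(40):
            plasmid = make_random_dna(
                600, seed=1000 + seed, circular=True,
                required_sites=[("GAATTC", 50), ("GGATCC", 250), ("CTGCAG", 450)],
            )
            frags = cut_all(plasmid, enz)
            assert len(frags) == 3
            assert sum(len(f.sequence) + len(f.ext5) for f in frags) == 600


class TestSimulateDigest:
    def test_fragment_zero_is_left_fragment(self, fig2_style_substrate, table):
        polyB = simulate_digest(fig2_style_substrate, ["EcoRI"], 0, table, "polyB")
        assert polyB.ext5 == "GATC" and polyB.mod_ext5 is Chem.HYDROXYL
        assert polyB.name == "polyB"

    def test_central_fragment_of_tailed_amplicon_is_number_one(self, table):
        template = make_random_dna(300, seed=26,
                                   forbidden_patterns=["GAATTC", "GGATCC"])
        fwd, rev = make_primer_pair(template, (0, 300), 20,
                                    fwd_tail="AAGAATTC", rev_tail="AAGGATCC")
        amplicon = simulate_pcr(fwd, rev, template, "pcrpdt")
        insert = simulate_digest(amplicon, ["EcoRI", "BamHI"], 1, table, "insert")
        assert insert.ext5 == "AATT" and insert.ext3 == "GATC"
        assert insert.sequence in amplicon.sequence

    def test_out_of_range_fragselect_reports_count(self, fig2_style_substrate, table):
        with pytest.raises(DigestError, match="2 fragment"):
            simulate_digest(fig2_style_substrate, ["EcoRI"], 5, table)


class TestEndsCompatible:
    FIVE, THREE, BLUNT = Protrusion.FIVE_PRIME, Protrusion.THREE_PRIME, Protrusion.BLUNT

    @pytest.mark.parametrize("l_ext,l_kind,r_ext,r_kind,expected", [
        ("AATT", FIVE, "AATT", FIVE, True),     # palindromic sticky pair
        ("AATT", FIVE, "GATC", FIVE, False),    # different overhangs
        ("", BLUNT, "", BLUNT, True),           # blunt joins blunt
        ("TGCA", THREE, "TGCA", THREE, True),   # 3' protrusions pair too
        ("AATT", FIVE, "AATT", THREE, False),   # protrusion kinds must match
    ])
    def test_pairs(self, l_ext, l_kind, r_ext, r_kind, expected):
        assert ends_compatible(l_ext, l_kind, r_ext, r_kind) is expected


class TestSimulateLigate:
    def test_religation_of_two_fragments_restores_parent(self, fig2_style_substrate, table):
        frags = cut_all(fig2_style_substrate, [table.lookup("EcoRI")])
        religated = simulate_ligate(frags, "relig")
        assert equivalent(religated, fig2_style_substrate)

    def test_self_circularisation_length(self, table):
        plasmid = make_random_dna(300, seed=27, circular=True,
                                  required_sites=[("GAATTC", 150)])
        frag = cut_all(plasmid, [table.lookup("EcoRI")])[0]
        circle = simulate_ligate([frag], "circ")
        assert circle.is_circular
        assert len(circle.sequence) == len(frag.sequence) + len(frag.ext5)
        assert equivalent(circle, plasmid)

    def test_hydroxyl_junction_blocks_ligation(self, table):
        plasmid = make_random_dna(300, seed=28, circular=True,
                                  required_sites=[("GAATTC", 150)])
        frag = cut_all(plasmid, [table.lookup("EcoRI")])[0]
        from dataclasses import replace
        dephos = replace(frag, mod_ext5=Chem.HYDROXYL, mod_ext3=Chem.HYDROXYL)
        with pytest.raises(LigationError):
            simulate_ligate([dephos, make_random_dna(100, seed=29)])

    def test_incompatible_mixture_enumerates_ends(self, table):
        a = make_random_dna(150, seed=30, required_sites=[("GAATTC", 70)])
        frag = cut_all(a, [table.lookup("EcoRI")])[0]
        b = make_random_dna(150, seed=31, required_sites=[("CTGCAG", 70)])
        fragb = cut_all(b, [table.lookup("PstI")])[1]
        with pytest.raises(LigationError, match="no.*compatible"):
            simulate_ligate([frag, fragb])

    def test_digest_ligate_round_trip_many_random_plasmids(self, table):
        """Any plasmid whose digest yields mutually unique sticky ends must
        re-ligate into a molecule equivalent to the parent (200 seeded
        random plasmids, three different enzymes)."""
        enzymes = [table.lookup("EcoRI"), table.lookup("BamHI"), table.lookup("PstI")]
        rng = random.Random(555)
        for _ in range(200):
            positions = sorted(rng.sample(range(30, 570), 3))
            if min(b - a for a, b in zip(positions, positions[1:])) < 12:
                continue
            plasmid = make_random_dna(
                600, seed=rng.randrange(2**31), circular=True,
                required_sites=[
                    ("GAATTC", positions[0]),
                    ("GGATCC", positions[1]),
                    ("CTGCAG", positions[2]),
                ],
            )
            frags = cut_all(plasmid, enzymes)
            assert len(frags) == 3
            rng.shuffle(frags)
            assert equivalent(simulate_ligate(frags, "re"), plasmid)
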