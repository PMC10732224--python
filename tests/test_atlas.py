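"""Knot atlas: roster, constructions, verification, connected sums."""

import numpy as np
import pytest

from writhenet.atlas import (ConstructionError, atlas_table, connected_sum,
                             constructible_names, get_entry, seed_embedding)
from writhenet.tangles import continued_fraction


class TestRoster:
    def test_prime_counts_to_seven_crossings(self):
        primes = [e for e in atlas_table()
                  if e.name[0].isdigit() and e.crossing_number <= 7]
        assert len(primes) == 15  # incl. the unknot: the 15-class problem

    def test_prime_counts_to_ten_crossings(self):
        primes = [e for e in atlas_table()
                  if e.name[0].isdigit() and e.crossing_number <= 10]
        assert len(primes) == 250

    def test_mutants_share_unknot_determinant(self):
        # Conway and Kinoshita-Terasaka share Delta with the unknot
        assert get_entry("K11n34").det1 == 1
        assert get_entry("K11n42").det1 == 1
        assert get_entry("0_1").det1 == 1

    def test_unknown_name_rejected(self):
        with pytest.raises(ConstructionError):
            get_entry("99_99")

    def test_rational_determinants_match_continued_fractions(self):
        # |Delta(-1)| of a 2-bridge knot is the continued-fraction numerator
        for name in ("4_1", "5_2", "6_1", "6_2", "6_3", "7_3", "7_5"):
            entry = get_entry(name)
            assert entry.det1 == continued_fraction(list(entry.conway))[0]


class TestSeedEmbeddings:
    @pytest.mark.parametrize("name", ["0_1", "3_1", "4_1", "5_1", "5_2",
                                      "6_2", "7_4", "8_20"])
    def test_seed_verifies_reference_determinant(self, name):
        emb = seed_embedding(name, 100)
        assert emb.reference_det1 == get_entry(name).det1
        conf = emb.conformation
        assert conf.n_beads == 100
        lengths = conf.bond_lengths()
        assert lengths.min() > 0.8 and lengths.max() < 1.2

    def test_seed_is_deterministic_and_canonical(self):
        a = seed_embedding("3_1", 100).conformation.positions
        b = seed_embedding("3_1", 100).conformation.positions
        assert np.array_equal(a, b)
        assert np.allclose(a.mean(axis=0), 0.0, atol=1e-8)

    def test_bead_budget_floor(self):
        with pytest.raises(ConstructionError):
            seed_embedding("8_20", 30)  # 8 crossings need >= 64 beads

    def test_unconstructible_entry_raises(self):
        assert "9_1" not in constructible_names()
        with pytest.raises(ConstructionError):
            seed_embedding("9_1", 100)


class TestComposites:
    def test_square_and_granny_determinants(self):
        # square = 3_1^l # 3_1^r, granny = 3_1^l # 3_1^l: both inherit
        # Delta = (t^2 - t + 1)^2, so (|D(-1)|, |D(-2)|) = (9, 49)
        for name in ("square", "granny"):
            emb = seed_embedding(name, 100)
            assert (emb.reference_det1, emb.reference_det2) == (9, 49)

    def test_same_alexander_trio(self):
        # the square, granny and 8_20 classes share the Alexander polynomial
        assert get_entry("square").det1 == get_entry("granny").det1 == \
            get_entry("8_20").det1 == 9

    def test_square_writhe_cancels_by_chirality(self):
        from writhenet.writhe import global_writhe
        emb = seed_embedding("square", 100)
        granny = seed_embedding("granny", 100)
        # opposite-handed factors nearly cancel; same-handed add up
        assert abs(global_writhe(emb.conformation)) < \
            abs(global_writhe(granny.conformation))

    def test_connected_sum_multiplicativity(self):
        t31 = seed_embedding("3_1", 60)
        t41 = seed_embedding("4_1", 60)
        summed = connected_sum(t31, t41, n_beads=120)
        assert summed.reference_det1 == 15  # 3 * 5
        trefoils = connected_sum(t31, t31, n_beads=120)
        assert trefoils.reference_det1 == 9


class TestMutantCertification:
    """The packaged 11-crossing mutants are knotted, Alexander-trivial
    and distinct."""

    def test_diagrams_certify_the_conway_kt_pair(self):
        from writhenet.atlas import mutant_diagram
        from writhenet.oracle import alexander_polynomial, jones_is_unknot
        for name in ("K11n34", "K11n42"):
            diag, meta = mutant_diagram(name)
            # a nontrivial knot with trivial Alexander polynomial needs
            # >= 11 crossings; exactly two such knots have 11
            assert diag.n_crossings == 11
            assert alexander_polynomial(diag) == [1]
            assert not jones_is_unknot(diag)

    def test_mutants_are_distinct_knots(self):
        # mutants share Alexander and Jones, but their knot groups admit
        # different numbers of homomorphisms into PSL(2,7)
        from writhenet.atlas import mutant_diagram
        from writhenet.grouprep import count_homomorphisms
        counts = {}
        for name in ("K11n34", "K11n42"):
            diag, meta = mutant_diagram(name)
            counts[name] = count_homomorphisms(diag, "PSL27")
            assert counts[name] == meta["psl27_homomorphisms"]
        assert counts["K11n34"] != counts["K11n42"]

    def test_seed_embeddings_load_and_verify(self):
        for name in ("K11n34", "K11n42"):
            emb = seed_embedding(name, 200)
            assert emb.reference_det1 == 1
            assert emb.conformation.n_beads == 200
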