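import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crninfer.library import (
    AnsatzLibrary,
    LibraryError,
    SpeciesSet,
    autoregulation_reduced_library,
    autoregulation_true_library,
    build_stoichiometric_matrix,
    enumerate_ansatz,
    format_reaction,
    library_preset,
    load_library,
    lotka_volterra_library,
    parse_reaction,
    save_library,
    LV_TRUE_INDICES,
)


@pytest.fixture
def py_species():
    return SpeciesSet(("P", "Y"))


class TestParsing:
    @pytest.mark.parametrize(
        "text, reactants, products",
        [
            ("Y -> 2 Y", {"Y": 1}, {"Y": 2}),
            ("P + Y -> 2 P", {"P": 1, "Y": 1}, {"P": 2}),
            ("2Y -> 0", {"Y": 2}, {}),
            ("0 -> P", {}, {"P": 1}),
        ],
    )
    def test_examples(self, py_species, text, reactants, products):
        rxn = parse_reaction(text, py_species)
        assert dict(rxn.reactants) == reactants
        assert dict(rxn.products) == products

    def test_identity_reaction_rejected(self, py_species):
        with pytest.raises(LibraryError, match="no net change"):
            parse_reaction("P -> P", py_species)

    def test_unknown_species(self, py_species):
        with pytest.raises(LibraryError, match="unknown species"):
            parse_reaction("Q -> P", py_species)

    def test_order_above_two_rejected(self, py_species):
        with pytest.raises(LibraryError, match="order"):
            parse_reaction("2 P + Y -> P", py_species)

    def test_species_name_beats_coefficient_prefix(self):
        sp = SpeciesSet(("P", "P2"))
        rxn = parse_reaction("P2 -> 2 P", sp)
        assert dict(rxn.reactants) == {"P2": 1}
        assert dict(rxn.products) == {"P": 2}

    def test_round_trip_through_writer(self, py_species):
        for text in ("Y -> 2 Y", "P + Y -> 2 P", "2 Y -> 0"):
            rxn = parse_reaction(text, py_species)
            assert parse_reaction(format_reaction(rxn), py_species) == rxn


class TestEnumeration:
    def test_two_species_two_templates(self):
        sp = SpeciesSet(("A", "B"))
        libm = enumerate_ansatz(sp, ["A -> 2A", "A -> 0"])
        assert libm.n_reactions == 4

    def test_bimolecular_needs_distinct_pair(self):
        sp = SpeciesSet(("A",))
        with pytest.raises(LibraryError):
            enumerate_ansatz(sp, ["A + B -> 2A"])

    def test_empty_template_set(self):
        with pytest.raises(LibraryError):
            enumerate_ansatz(SpeciesSet(("A",)), [])

    def test_species_order_invariance_up_to_relabeling(self):
        t = ["A -> B", "2A -> B", "A + B -> C"]
        l1 = enumerate_ansatz(SpeciesSet(("X", "Y", "Z")), t)
        l2 = enumerate_ansatz(SpeciesSet(("Z", "Y", "X")), t)
        assert {str(r) for r in l1.reactions} == {str(r) for r in l2.reactions}

    def test_no_duplicates_and_order_bound(self):
        libm = enumerate_ansatz(SpeciesSet(("A", "B", "C")),
                                ["full_second_order", "conversion", "decay"])
        keys = [r.key() for r in libm.reactions]
        assert len(keys) == len(set(keys))
        for r in libm.reactions:
            assert sum(dict(r.reactants).values()) <= 2
            assert sum(dict(r.products).values()) <= 2


class TestStoichiometry:
    @pytest.mark.parametrize(
        "text, row",
        [
            ("Y -> 2 Y", (0, 1)),
            ("P + Y -> 2 P", (1, -1)),
            ("P -> 0", (-1, 0)),
        ],
    )
    def test_rows(self, py_species, text, row):
        libm = AnsatzLibrary(py_species, [parse_reaction(text, py_species)])
        assert tuple(build_stoichiometric_matrix(libm)[0]) == row

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_matrix_matches_naive_recount(self, data):
        sp = SpeciesSet(("A", "B", "C"))
        libm = enumerate_ansatz(sp, ["full_second_order", "conversion",
                                     "decay", "splitting"])
        idx = data.draw(st.integers(0, libm.n_reactions - 1))
        rxn = libm.reactions[idx]
        row = np.zeros(3, dtype=int)
        for name, mult in rxn.products:
            row[sp.index(name)] += mult
        for name, mult in rxn.reactants:
            row[sp.index(name)] -= mult
        assert np.array_equal(libm.stoich[idx], row)
        assert set(np.unique(libm.stoich)) <= {-2, -1, 0, 1, 2}


class TestPresets:
    def test_lv_preset_has_16_with_truth_at_234(self):
        libm = lotka_volterra_library()
        assert libm.n_reactions == 16
        assert LV_TRUE_INDICES == (2, 3, 4)
        assert str(libm.reactions[2]) == "Y -> 2 Y"
        assert str(libm.reactions[3]) == "P + Y -> 2 P"
        assert str(libm.reactions[4]) == "P -> 0"

    def test_autoreg_truth_has_8_reactions(self):
        assert autoregulation_true_library().n_reactions == 8

    def test_reduced_autoreg_contains_truth(self):
        red = autoregulation_reduced_library()
        assert red.n_reactions == 49
        truth = autoregulation_true_library()
        for rxn in truth.reactions:
            red.index_of(rxn)  # raises if absent
        # the four known binding/expression reactions lead the ordering
        assert [str(r) for r in red.reactions[:4]] == [
            "P2 + g -> gP2", "gP2 -> P2 + g", "g -> g + r", "r -> P + r"]

    def test_unknown_preset(self):
        with pytest.raises(LibraryError):
            library_preset("nope")


class TestIO:
    def test_save_load_save_byte_identical(self, tmp_path):
        libm = lotka_volterra_library()
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        save_library(libm, p1)
        loaded = load_library(p1)
        save_library(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert [str(r) for r in loaded.reactions] == [str(r) for r in libm.reactions]

    def test_duplicate_line_reported(self, tmp_path):
        p = tmp_path / "dup.txt"
        p.write_text("species: A, B\nA -> B\nA -> B\n")
        with pytest.raises(LibraryError, match="line 3.*duplicate"):
            load_library(p)

    def test_empty_library_rejected(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("species: A, B\n# nothing\n")
        with pytest.raises(LibraryError):
            load_library(p)

    def test_parse_error_carries_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("species: A, B\nA -> B\nA -> Q\n")
        with pytest.raises(LibraryError, match="line 3"):
            load_library(p)
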