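"""Compound model: nomenclature, classification, flags, mass arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bilesalts.compounds import (
    BileSaltDescriptor,
    CandidateClass,
    CompoundType,
    Conjugation,
    Junction,
    ModificationFlag,
    REGISTRY,
    TerminalGroup,
    annotate_peaks,
    classify_type,
    enumerate_search_space,
    flag_unusual,
    formula_string,
    molecular_formula,
    mz_mh_minus,
    parse_name,
    render_name,
)
from bilesalts.errors import (
    ConfigurationError,
    ParseError,
    UnsupportedScaffoldError,
    ValidationError,
)

# Independent mass oracle: hand-counted formulas summed with a test-local
# atomic-mass table (values independent of the implementation's table source).
ORACLE_MASS = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
               "O": 15.9949146221, "S": 31.97207069}
ORACLE_PROTON = 1.00727646688


def oracle_mz(formula: dict) -> float:
    return sum(ORACLE_MASS[el] * n for el, n in formula.items()) - ORACLE_PROTON


class TestParsing:
    @pytest.mark.parametrize(
        "name,expected",
        [
            (
                "3α,7α-dihydroxy-5β-cholan-24-oic acid",
                BileSaltDescriptor(24, TerminalGroup.ACID, Junction.FIVE_BETA,
                                   {(3, "a"), (7, "a")}),
            ),
            (
                "3α,7α,12α,24R-tetrahydroxy-5β-cholestan-27-oic acid",
                BileSaltDescriptor(27, TerminalGroup.ACID, Junction.FIVE_BETA,
                                   {(3, "a"), (7, "a"), (12, "a"), (24, "R")}),
            ),
            (
                "3α-hydroxy-12-oxo-5β-cholan-24-oic acid",
                BileSaltDescriptor(24, TerminalGroup.ACID, Junction.FIVE_BETA,
                                   {(3, "a")}, oxo_positions={12}),
            ),
            (
                "3a,12a-dihydroxy-5b-chol-22-en-24-oic acid",
                BileSaltDescriptor(24, TerminalGroup.ACID, Junction.FIVE_BETA,
                                   {(3, "a"), (12, "a")}, double_bonds={22}),
            ),
            (
                "5b-cholestane-3a,7a,12a,26-tetrol",
                BileSaltDescriptor(27, TerminalGroup.ALCOHOL, Junction.FIVE_BETA,
                                   {(3, "a"), (7, "a"), (12, "a")}),
            ),
            (
                "3a,12a-dihydroxy-24-nor-5b-cholan-23-oic acid",
                BileSaltDescriptor(23, TerminalGroup.ACID, Junction.FIVE_BETA,
                                   {(3, "a"), (12, "a")}),
            ),
        ],
    )
    def test_systematic_names(self, name, expected):
        assert parse_name(name) == expected

    @pytest.mark.parametrize(
        "spelling",
        [
            "3α,7α-dihydroxy-5β-cholan-24-oic acid",
            "3a,7a-dihydroxy-5b-cholan-24-oic acid",
            "3alpha,7alpha-dihydroxy-5beta-cholan-24-oic acid",
            "CDCA",
            "chenodeoxycholic acid",
        ],
    )
    def test_greek_spellings_and_trivial_names_agree(self, spelling):
        assert parse_name(spelling) == parse_name("cdca")

    @pytest.mark.parametrize(
        "trivial,systematic",
        [
            ("cholic acid", "3a,7a,12a-trihydroxy-5b-cholan-24-oic acid"),
            ("varanic acid", "3a,7a,12a,24R-tetrahydroxy-5b-cholestan-27-oic acid"),
            ("pythocholic acid", "3a,12a,16a-trihydroxy-5b-cholan-24-oic acid"),
            ("bitocholic acid", "3a,12a,23R-trihydroxy-5b-cholan-24-oic acid"),
            ("ursodeoxycholic acid", "3a,7b-dihydroxy-5b-cholan-24-oic acid"),
            ("allocholic acid", "3a,7a,12a-trihydroxy-5a-cholan-24-oic acid"),
            ("hyocholic acid", "3a,6a,7a-trihydroxy-5b-cholan-24-oic acid"),
            ("b-muricholic acid", "3a,6b,7b-trihydroxy-5b-cholan-24-oic acid"),
            ("12-oxo-lca", "3a-hydroxy-12-oxo-5b-cholan-24-oic acid"),
        ],
    )
    def test_registry_matches_systematic(self, trivial, systematic):
        assert parse_name(trivial) == parse_name(systematic)

    def test_conjugation_prefixes(self):
        g = parse_name("glycocholic acid")
        assert g.conjugation is Conjugation.GLYCINE
        assert g.deconjugated() == parse_name("cholic acid")
        t = parse_name("tauro-chenodeoxycholic acid")
        assert t.conjugation is Conjugation.TAURINE
        s = parse_name("5b-cholestane-3a,7a,12a,26-tetrol sulfate")
        assert s.conjugation is Conjugation.SULFATE

    @pytest.mark.parametrize(
        "bad",
        ["", "not-a-bile-acid", "3q-hydroxy-5b-cholan-24-oic acid",
         "3a,7a-trihydroxy-5b-cholan-24-oic acid",  # multiplier mismatch
         "3a-hydroxy-5b-cholan-26-oic acid"],  # suffix inconsistent with C24
    )
    def test_parse_errors(self, bad):
        with pytest.raises(ParseError):
            parse_name(bad)

    def test_hydroxyl_oxo_clash_is_validation_error(self):
        with pytest.raises(ValidationError):
            parse_name("3a-hydroxy-3-oxo-5b-cholan-24-oic acid")

    def test_registry_round_trips(self):
        for descriptor in set(REGISTRY.values()):
            assert parse_name(render_name(descriptor)) == descriptor


_nuclear = st.sampled_from([(1, "a"), (1, "b"), (3, "a"), (6, "a"), (6, "b"),
                            (7, "a"), (7, "b"), (12, "a"), (15, "a"), (16, "a")])
_sidechain = st.sampled_from([(22, ""), (23, "R"), (24, "R"), (25, "")])


@st.composite
def descriptors(draw):
    carbon = draw(st.sampled_from([23, 24, 27]))
    terminal = (TerminalGroup.ALCOHOL if carbon == 27 and draw(st.booleans())
                else TerminalGroup.ACID)
    hydroxyls = set(draw(st.lists(_nuclear, max_size=3, unique=True)))
    if carbon == 27:
        hydroxyls |= set(draw(st.lists(_sidechain, max_size=2, unique_by=lambda x: x[0])))
    oh_positions = {p for p, _ in hydroxyls}
    oxo = draw(st.sets(st.sampled_from([7, 11, 12]), max_size=2)) - oh_positions
    bonds = draw(st.sets(st.sampled_from([22]), max_size=1))
    junction = draw(st.sampled_from([Junction.FIVE_ALPHA, Junction.FIVE_BETA]))
    conj = draw(st.sampled_from(list(Conjugation)))
    if len({p for p, _ in hydroxyls}) < len(hydroxyls):
        hydroxyls = {(p, o) for p, o in hydroxyls}
        seen, dedup = set(), set()
        for p, o in sorted(hydroxyls):
            if p not in seen:
                seen.add(p)
                dedup.add((p, o))
        hydroxyls = dedup
    return BileSaltDescriptor(carbon, terminal, junction, frozenset(hydroxyls),
                              frozenset(oxo), frozenset(bonds), conj)


class TestRoundTrip:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(descriptors())
    def test_render_parse_round_trip(self, d):
        assert parse_name(render_name(d)) == d


class TestClassification:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("cdca", CompoundType.C24_ACID),
            ("cholic acid", CompoundType.C24_ACID),
            ("3a,7a,12a-trihydroxy-5b-cholestan-27-oic acid", CompoundType.C27_ACID),
            ("varanic acid", CompoundType.C27_ACID),
            ("5b-cholestane-3a,7a,12a,26-tetrol", CompoundType.C27_ALCOHOL),
            ("3a,12a-dihydroxy-24-nor-5b-cholan-23-oic acid", CompoundType.OTHER),
        ],
    )
    def test_three_broad_types(self, name, expected):
        assert classify_type(parse_name(name)) is expected

    def test_conjugation_does_not_change_type(self):
        assert classify_type(parse_name("taurocholic acid").deconjugated()) \
            is CompoundType.C24_ACID


class TestModificationFlags:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("pythocholic acid", {ModificationFlag.DEOXY_7, ModificationFlag.OH_16A}),
            ("ursodeoxycholic acid", {ModificationFlag.UDCA_7B}),
            ("cholic acid", set()),
            ("allocholic acid", {ModificationFlag.ALLO_5A}),
            ("bitocholic acid", {ModificationFlag.DEOXY_7, ModificationFlag.OH_23R}),
            ("b-muricholic acid", {ModificationFlag.OH_6B, ModificationFlag.UDCA_7B}),
            ("7-oxo-dca", {ModificationFlag.OXO_7}),
        ],
    )
    def test_flag_predicates(self, name, expected):
        assert flag_unusual(parse_name(name)) == frozenset(expected)

    def test_turtle_22_hydroxylation_flag(self):
        d = parse_name("3a,7a,12a,22-tetrahydroxy-5b-cholestan-27-oic acid")
        assert ModificationFlag.OH_22_C27 in flag_unusual(d)


class TestMassArithmetic:
    @pytest.mark.parametrize(
        "name,formula,expected_mz",
        [
            ("cholic acid", {"C": 24, "H": 40, "O": 5}, 407.2803),
            ("varanic acid", {"C": 27, "H": 46, "O": 6}, 465.3222),
            ("glycocholic acid", {"C": 26, "H": 43, "N": 1, "O": 6}, 464.3018),
            ("taurocholic acid", {"C": 26, "H": 45, "N": 1, "O": 7, "S": 1}, 514.2844),
            ("lithocholic acid", {"C": 24, "H": 40, "O": 3}, 375.2905),
        ],
    )
    def test_formula_and_mz_against_hand_counts(self, name, formula, expected_mz):
        d = parse_name(name)
        got = {el: n for el, n in molecular_formula(d).items() if n}
        assert got == formula
        assert mz_mh_minus(d) == pytest.approx(expected_mz, abs=1e-4)
        assert mz_mh_minus(d) == pytest.approx(oracle_mz(formula), abs=1e-4)

    def test_formula_strings(self):
        assert formula_string(molecular_formula(parse_name("cholic acid"))) == "C24H40O5"
        assert formula_string(
            molecular_formula(parse_name("glycocholic acid"))
        ) == "C26H43NO6"

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(descriptors())
    def test_conjugation_mass_deltas(self, d):
        base = d.deconjugated()
        deltas = {Conjugation.GLYCINE: 57.0215, Conjugation.TAURINE: 107.0041,
                  Conjugation.SULFATE: 79.9568}
        for conj, delta in deltas.items():
            conjugated = BileSaltDescriptor(
                base.carbon_count, base.terminal_group, base.junction,
                base.hydroxyls, base.oxo_positions, base.double_bonds, conj,
            )
            assert mz_mh_minus(conjugated) - mz_mh_minus(base) == \
                pytest.approx(delta, abs=1e-4)

    def test_hydroxyl_and_double_bond_increments(self):
        lca = parse_name("lithocholic acid")
        dca = parse_name("deoxycholic acid")
        assert mz_mh_minus(dca) - mz_mh_minus(lca) == \
            pytest.approx(ORACLE_MASS["O"], abs=1e-4)
        ene = parse_name("3a-hydroxy-5b-chol-22-en-24-oic acid")
        assert mz_mh_minus(lca) - mz_mh_minus(ene) == \
            pytest.approx(2 * ORACLE_MASS["H"], abs=1e-4)

    def test_unsupported_scaffold(self):
        d = BileSaltDescriptor(25, TerminalGroup.ACID)
        with pytest.raises(UnsupportedScaffoldError):
            molecular_formula(d)


class TestAnnotation:
    def test_sloth_coprolite_style_peaks(self):
        anns = annotate_peaks([(464.30, 100.0), (514.28, 50.0)], tolerance=0.05)
        labels0 = [a.candidate.label for a in anns[0]]
        assert "glycine-conjugated trihydroxy C24 bile acid" in labels0
        labels1 = [a.candidate.label for a in anns[1]]
        assert "taurine-conjugated trihydroxy C24 bile acid" in labels1

    def test_low_mass_peak_has_no_candidates(self):
        assert annotate_peaks([(100.0, 1.0)], tolerance=0.05) == [[]]

    def test_sorted_by_absolute_mass_error(self):
        hits = annotate_peaks([(464.30, 1.0)], tolerance=0.5)[0]
        deltas = [abs(h.delta_mz) for h in hits]
        assert deltas == sorted(deltas)

    def test_exhaustive_against_brute_force(self, rng):
        # independent enumeration: direct descriptor construction per combo
        space = enumerate_search_space()
        peaks = [(float(rng.uniform(300, 600)), 1.0) for _ in range(25)]
        tolerance = 0.5
        results = annotate_peaks(peaks, tolerance=tolerance, search_space=space)
        for (mz, _), hits in zip(peaks, results):
            got = {(h.candidate.scaffold, h.candidate.n_hydroxyl,
                    h.candidate.n_oxo, h.candidate.n_double_bond,
                    h.candidate.conjugation) for h in hits}
            expected = set()
            for scaffold, carbon, terminal in (
                ("C23_acid", 23, TerminalGroup.ACID),
                ("C24_acid", 24, TerminalGroup.ACID),
                ("C27_acid", 27, TerminalGroup.ACID),
                ("C27_alcohol", 27, TerminalGroup.ALCOHOL),
            ):
                for noh, noxo, nene, conj in itertools.product(
                    range(5), range(3), range(3), list(Conjugation)
                ):
                    d = BileSaltDescriptor(
                        carbon, terminal, Junction.FIVE_BETA,
                        frozenset((p, "") for p in (3, 7, 12, 16, 1)[:noh]),
                        frozenset((6, 11, 15)[:noxo]),
                        frozenset((22, 4, 14)[:nene]),
                        conj,
                    )
                    if abs(mz - mz_mh_minus(d)) <= tolerance:
                        expected.add((scaffold, noh, noxo, nene, conj))
            assert got == expected

    def test_configuration_errors(self):
        with pytest.raises(ConfigurationError):
            annotate_peaks([(400.0, 1.0)], tolerance=0.0)
        with pytest.raises(ConfigurationError):
            enumerate_search_space(scaffolds=())
        with pytest.raises(ValidationError):
            annotate_peaks([(-5.0, 1.0)])
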