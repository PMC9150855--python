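"""Composition parsing, mass arithmetic, isotopes and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glyconodule.glycan_model import (
    Composition,
    CompositionError,
    DEFAULT_BOUNDS,
    SODIUM_ADDUCT,
    adduct_mz,
    classify,
    elemental_formula,
    enumerate_database,
    format_composition,
    formula_monoisotopic_mass,
    glycopeptide_offset,
    isotope_pattern,
    make_record,
    neutral_mass,
    parse_composition,
    read_database_csv,
    write_database_csv,
)

compositions = st.builds(
    Composition,
    hex=st.integers(0, 9),
    hexnac=st.integers(0, 6),
    dhex=st.integers(0, 3),
    pent=st.integers(0, 1),
).filter(lambda c: not c.is_empty())


# ---------------------------------------------------------------------------
# Parsing and formatting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,expected",
    [
        ("Hex:5 HexNAc:4 dHex:3 Pent:1", Composition(5, 4, 3, 1)),
        ("Hex:3 HexNAc:2", Composition(3, 2, 0, 0)),
        ("Hex:4 HexNAc:3 dHex:2 Pent:1", Composition(4, 3, 2, 1)),
        ("Pent:1 Hex:3 HexNAc:2", Composition(3, 2, 0, 1)),  # order-free
    ],
)
def test_parse_composition(text, expected):
    assert parse_composition(text) == expected


@pytest.mark.parametrize(
    "bad",
    ["NeuAc:1 Hex:3", "Hex:-1", "Hex:1.5", "Hex", "", "Hex:2 Hex:3"],
)
def test_parse_rejects_malformed(bad):
    with pytest.raises(CompositionError):
        parse_composition(bad)


def test_parse_rejection_names_unknown_token():
    with pytest.raises(CompositionError, match="NeuAc"):
        parse_composition("NeuAc:2")


@settings(derandomize=True, max_examples=100)
@given(compositions)
def test_format_parse_roundtrip(c):
    assert parse_composition(format_composition(c)) == c


# ---------------------------------------------------------------------------
# Masses
# ---------------------------------------------------------------------------

def test_neutral_mass_values():
    assert neutral_mass(Composition(5, 4, 3, 1)) == pytest.approx(2210.8082, abs=1e-4)
    assert neutral_mass(Composition(3, 2, 0, 0)) == pytest.approx(910.3278, abs=1e-4)


def test_empty_glycan_rejected():
    with pytest.raises(CompositionError, match="empty"):
        neutral_mass(Composition(0, 0, 0, 0))
    with pytest.raises(CompositionError):
        elemental_formula(Composition(0, 0, 0, 0))


def test_sodiated_anchor_mzs():
    """The three printed Lewis-a glycan m/z values reproduce to 3 decimals."""
    anchors = {
        "Hex:5 HexNAc:4 dHex:3 Pent:1": 2233.797,
        "Hex:4 HexNAc:4 dHex:2 Pent:1": 1925.687,
        "Hex:4 HexNAc:3 dHex:2 Pent:1": 1722.607,
    }
    for text, expected in anchors.items():
        mz = adduct_mz(neutral_mass(parse_composition(text)), SODIUM_ADDUCT)
        assert round(mz, 3) == expected


def test_sodium_adduct_delta():
    assert SODIUM_ADDUCT.mass_delta == pytest.approx(22.989218, abs=1e-5)


def test_adduct_mz_validation():
    with pytest.raises(ValueError):
        adduct_mz(-5.0, SODIUM_ADDUCT)


@settings(derandomize=True, max_examples=100)
@given(compositions, compositions)
def test_mass_additivity(c1, c2):
    """Merging two glycans shares one water: masses add minus 18.010565."""
    merged = c1.merge(c2)
    assert neutral_mass(merged) == pytest.approx(
        neutral_mass(c1) + neutral_mass(c2) - 18.010565, abs=1e-9
    )


def test_glycopeptide_offset():
    assert glycopeptide_offset(Composition(5, 4, 3, 1)) == pytest.approx(
        2192.7976, abs=1e-4
    )
    assert glycopeptide_offset(Composition(0, 1, 0, 0)) == pytest.approx(
        203.0794, abs=1e-4
    )


@settings(derandomize=True, max_examples=50)
@given(compositions)
def test_offset_plus_water_is_neutral_mass(c):
    assert glycopeptide_offset(c) + 18.010565 == pytest.approx(
        neutral_mass(c), abs=1e-9
    )


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "comp,expected",
    [
        (Composition(3, 2, 0, 0), {"C": 34, "H": 58, "N": 2, "O": 26}),
        (Composition(0, 1, 0, 0), {"C": 8, "H": 15, "N": 1, "O": 6}),
        (Composition(1, 0, 1, 0), {"C": 12, "H": 22, "O": 10}),
    ],
)
def test_elemental_formula(comp, expected):
    assert elemental_formula(comp) == expected


@settings(derandomize=True, max_examples=200)
@given(compositions)
def test_formula_mass_matches_residue_mass(c):
    """Formula-derived monoisotopic mass agrees with residue-sum mass."""
    assert formula_monoisotopic_mass(elemental_formula(c)) == pytest.approx(
        neutral_mass(c), abs=1e-4
    )


# ---------------------------------------------------------------------------
# Isotope envelopes
# ---------------------------------------------------------------------------

def _envelope_oracle(formula, n_peaks):
    """Independent atom-by-atom convolution of element distributions."""
    iso = {
        "C": [0.9893, 0.0107],
        "H": [0.999885, 0.000115],
        "N": [0.99636, 0.00364],
        "O": [0.99757, 0.00038, 0.00205],
    }
    dist = np.array([1.0])
    for el, n in formula.items():
        for _ in range(n):
            dist = np.convolve(dist, iso[el])
    dist = dist[:n_peaks]
    if len(dist) < n_peaks:
        dist = np.pad(dist, (0, n_peaks - len(dist)))
    return dist / dist.sum()


def test_isotope_single_carbon():
    pattern = isotope_pattern({"C": 1}, 2)
    assert pattern[0][0] == 0.0
    assert [round(a, 4) for _, a in pattern] == [0.9893, 0.0107]


def test_isotope_matches_convolution_oracle():
    pattern = isotope_pattern({"C": 34, "H": 58, "N": 2, "O": 26}, 4)
    oracle = _envelope_oracle({"C": 34, "H": 58, "N": 2, "O": 26}, 4)
    assert np.allclose([a for _, a in pattern], oracle, atol=1e-6)


@settings(derandomize=True, max_examples=50)
@given(compositions, st.integers(2, 6))
def test_isotope_normalization_and_ordering(c, k):
    pattern = isotope_pattern(elemental_formula(c), k)
    abundances = [a for _, a in pattern]
    assert sum(abundances) == pytest.approx(1.0, abs=1e-9)
    assert all(a >= 0 for a in abundances)
    offsets = [o for o, _ in pattern]
    assert offsets == sorted(offsets)


def test_isotope_rejects_bad_input():
    with pytest.raises(ValueError):
        isotope_pattern({"C": 5}, 0)
    with pytest.raises(ValueError):
        isotope_pattern({}, 3)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "comp,classes,capacity",
    [
        (Composition(5, 4, 3, 1),
         {"complex", "core-fucosylated", "xylosylated", "lewis-a"}, 2),
        (Composition(3, 2, 1, 1),
         {"paucimannose", "core-fucosylated", "xylosylated"}, 0),
        (Composition(9, 2, 0, 0), {"oligomannose"}, 0),
        (Composition(5, 2, 0, 0), {"oligomannose"}, 0),
        (Composition(4, 2, 1, 0), {"paucimannose", "core-fucosylated"}, 0),
        (Composition(4, 3, 2, 1),
         {"complex", "core-fucosylated", "xylosylated", "lewis-a"}, 1),
    ],
)
def test_classify(comp, classes, capacity):
    got_classes, got_capacity = classify(comp)
    assert got_classes == classes
    assert got_capacity == capacity


def test_classify_non_core():
    classes, capacity = classify(Composition(3, 1, 0, 0))
    assert classes == {"non-core"}
    assert capacity == 0


@settings(derandomize=True, max_examples=200)
@given(compositions)
def test_backbone_classes_mutually_exclusive(c):
    classes, capacity = classify(c)
    backbone = classes & {"oligomannose", "paucimannose", "complex"}
    assert len(backbone) <= 1
    assert ("lewis-a" in classes) == (capacity >= 1)


FIG2_UPPER = [  # conserved truncated glycans
    "Hex:3 HexNAc:2 Pent:1",
    "Hex:3 HexNAc:2 dHex:1",
    "Hex:3 HexNAc:2 dHex:1 Pent:1",
    "Hex:4 HexNAc:2 Pent:1",
]
FIG2_LOWER = [  # mutant-elevated complex glycans
    "Hex:4 HexNAc:3 dHex:2 Pent:1",
    "Hex:5 HexNAc:3 dHex:2 Pent:1",
    "Hex:4 HexNAc:4 dHex:2 Pent:1",
    "Hex:5 HexNAc:4 dHex:2 Pent:1",
    "Hex:5 HexNAc:4 dHex:3 Pent:1",
]


def test_panel_partition_upper_paucimannose_lower_lewis_a():
    """The four truncated panel glycans are paucimannose with no Lewis-a
    capacity; the five mutant-elevated ones all have capacity >= 1."""
    for text in FIG2_UPPER:
        classes, capacity = classify(parse_composition(text))
        assert capacity == 0
        assert "paucimannose" in classes
    for text in FIG2_LOWER:
        _, capacity = classify(parse_composition(text))
        assert capacity >= 1


# ---------------------------------------------------------------------------
# Database enumeration and serialization
# ---------------------------------------------------------------------------

def test_enumerate_contains_and_excludes():
    records = enumerate_database(
        {"hex": 6, "hexnac": 5, "dhex": 3, "pent": 1}, (1000.0, 5000.0)
    )
    comps = {r.composition for r in records}
    assert Composition(5, 4, 3, 1) in comps
    assert Composition(2, 2, 0, 0) not in comps  # m/z below 1000


def test_enumerate_exhaustive_tiny():
    records = enumerate_database(
        {"hex": 3, "hexnac": 2, "dhex": 0, "pent": 0}, (0.0, 1e9)
    )
    assert [r.composition for r in records] == [
        Composition(2, 2, 0, 0),
        Composition(3, 2, 0, 0),
    ]


def test_enumerate_no_duplicates_and_sorted():
    records = enumerate_database(DEFAULT_BOUNDS, (1000.0, 5000.0))
    comps = [r.composition for r in records]
    assert len(comps) == len(set(comps))
    masses = [r.neutral_mass for r in records]
    assert masses == sorted(masses)
    assert all(r.classes or r.lewis_a_capacity == 0 for r in records)


def test_database_csv_roundtrip(tmp_path):
    records = enumerate_database(
        {"hex": 4, "hexnac": 3, "dhex": 1, "pent": 1}, (1000.0, 5000.0)
    )
    path = tmp_path / "db.csv"
    write_database_csv(records, path)
    loaded = read_database_csv(path)
    assert [r.composition for r in loaded] == [r.composition for r in records]
    assert [r.id for r in loaded] == [r.id for r in records]


def test_record_invariants():
    r = make_record(Composition(5, 4, 3, 1))
    assert r.neutral_mass == pytest.approx(
        formula_monoisotopic_mass(r.formula), abs=1e-4
    )
    assert ("lewis-a" in r.classes) == (r.lewis_a_capacity >= 1)
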