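"""Plant N-glycan composition model: parsing, masses, adducts, isotopes, classes.

A glycan is identified at *composition* level — an integer count vector over the
four monosaccharide families seen in plant N-glycans released by PNGase
treatment: hexose (Hex: Man/Gal/Glc), N-acetylhexosamine (HexNAc: GlcNAc),
deoxyhexose (dHex: Fuc) and pentose (Pent: Xyl). Linkage isomers are not
distinguished; structural labels (oligomannose, paucimannose, complex,
core-fucosylated, xylosylated, Lewis-a) are inferred from counts with the
caveats documented in :func:`classify`.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Composition",
    "AdductSpec",
    "GlycanRecord",
    "WATER_MASS",
    "RESIDUE_MASSES",
    "SODIUM_ADDUCT",
    "PROTON_ADDUCT",
    "parse_composition",
    "format_composition",
    "neutral_mass",
    "adduct_mz",
    "elemental_formula",
    "formula_monoisotopic_mass",
    "isotope_pattern",
    "classify",
    "make_record",
    "glycopeptide_offset",
    "enumerate_database",
    "write_database_csv",
    "read_database_csv",
    "write_database_json",
    "read_database_json",
]

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

#: Monoisotopic residue masses in Da (monosaccharide minus water, i.e. the mass
#: added per glycosidic bond). 6-decimal constants chosen to reproduce
#: sodiated glycan m/z values to 3 decimal places.
RESIDUE_MASSES: Mapping[str, float] = {
    "Hex": 162.052824,
    "HexNAc": 203.079373,
    "dHex": 146.057909,
    "Pent": 132.042259,
}

#: Monoisotopic mass of water; a free reducing glycan is residue sum + water.
WATER_MASS: float = 18.010565

#: Canonical monosaccharide name order for formatting.
_NAME_ORDER = ("Hex", "HexNAc", "dHex", "Pent")
_FIELD_BY_NAME = {"Hex": "hex", "HexNAc": "hexnac", "dHex": "dhex", "Pent": "pent"}

#: Residue elemental formulas (residue = monosaccharide - H2O).
_RESIDUE_FORMULAS: Mapping[str, Mapping[str, int]] = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dHex": {"C": 6, "H": 10, "O": 4},
    "Pent": {"C": 5, "H": 8, "O": 4},
}
_WATER_FORMULA: Mapping[str, int] = {"H": 2, "O": 1}

#: Monoisotopic atomic masses.
_ATOMIC_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
}

#: Aggregated per-element isotope distributions used for envelope prediction.
#: Each entry maps a nominal mass offset (in 13C-spacing units) to abundance.
#: 17O contributes at +1 and 18O at +2; heavier natural isotopes of C/H/N/O
#: are negligible for glycan-sized molecules.
_ELEMENT_ISOTOPES: Mapping[str, Sequence[float]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
}

#: Mass spacing between successive aggregated isotopologue peaks (13C - 12C).
ISOTOPE_SPACING: float = 1.0033548378

#: Mass of the electron, subtracted when a cation adduct carries the charge.
_ELECTRON_MASS: float = 0.000548579909

_TOKEN_RE = re.compile(r"^([A-Za-z]+):(-?\d+(?:\.\d+)?)$")


class CompositionError(ValueError):
    """Raised for malformed composition strings or invalid count vectors."""


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Composition:
    """Monosaccharide count vector identifying one glycan mass species."""

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    pent: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "pent"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise CompositionError(f"{name} count must be an integer, got {v!r}")
            if v < 0:
                raise CompositionError(f"{name} count must be >= 0, got {v}")

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.pent

    def is_empty(self) -> bool:
        return self.total_residues == 0

    def merge(self, other: "Composition") -> "Composition":
        """Componentwise sum (two glycans condensing share one water)."""
        return Composition(
            self.hex + other.hex,
            self.hexnac + other.hexnac,
            self.dhex + other.dhex,
            self.pent + other.pent,
        )

    def __str__(self) -> str:
        return format_composition(self)


def parse_composition(text: str) -> Composition:
    """Parse a ``"Hex:a HexNAc:b dHex:c Pent:d"`` composition string.

    Token order is free and omitted monosaccharides default to zero.
    Unknown names, duplicate names, negative or non-integer counts are
    rejected with the offending token named.
    """
    if not isinstance(text, str):
        raise CompositionError(f"composition must be a string, got {type(text).__name__}")
    counts: dict[str, int] = {}
    tokens = text.split()
    if not tokens:
        raise CompositionError("empty composition string")
    for tok in tokens:
        m = _TOKEN_RE.match(tok)
        if not m:
            raise CompositionError(f"malformed token {tok!r} (expected '<name>:<count>')")
        name, raw = m.group(1), m.group(2)
        if name not in _FIELD_BY_NAME:
            raise CompositionError(
                f"unknown monosaccharide {name!r} in token {tok!r}; "
                f"expected one of {', '.join(_NAME_ORDER)}"
            )
        if "." in raw:
            raise CompositionError(f"non-integer count in token {tok!r}")
        value = int(raw)
        if value < 0:
            raise CompositionError(f"negative count in token {tok!r}")
        if name in counts:
            raise CompositionError(f"duplicate monosaccharide {name!r}")
        counts[name] = value
    return Composition(**{_FIELD_BY_NAME[n]: c for n, c in counts.items()})


def format_composition(c: Composition) -> str:
    """Canonical text form: fixed name order, zero-count names omitted."""
    parts = [
        f"{name}:{getattr(c, _FIELD_BY_NAME[name])}"
        for name in _NAME_ORDER
        if getattr(c, _FIELD_BY_NAME[name]) > 0
    ]
    if not parts:
        raise CompositionError("cannot format an empty composition")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# Masses and adducts
# ---------------------------------------------------------------------------

def neutral_mass(c: Composition) -> float:
    """Monoisotopic mass (Da) of the free reducing glycan: residues + water."""
    if c.is_empty():
        raise CompositionError("empty glycan: all monosaccharide counts are zero")
    return (
        c.hex * RESIDUE_MASSES["Hex"]
        + c.hexnac * RESIDUE_MASSES["HexNAc"]
        + c.dhex * RESIDUE_MASSES["dHex"]
        + c.pent * RESIDUE_MASSES["Pent"]
        + WATER_MASS
    )


@dataclass(frozen=True)
class AdductSpec:
    """Ionization adduct: label, mass delta (electron-corrected) and charge."""

    name: str
    mass_delta: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")


#: [M+Na]+ — the adduct used for plant N-glycan MALDI annotation.
#: 22.989770 (Na) minus the electron mass carried away on ionization.
SODIUM_ADDUCT = AdductSpec("+Na", 22.989770 - _ELECTRON_MASS, 1)

#: [M+H]+ for completeness.
PROTON_ADDUCT = AdductSpec("+H", 1.0078250319 - _ELECTRON_MASS, 1)

#: Implausible-adduct deltas used for decoy false-discovery estimation.
#: Elements that do not cationize glycans under MALDI (METASPACE-style decoys).
DECOY_ADDUCTS: tuple[AdductSpec, ...] = (
    AdductSpec("+Cr", 51.940506 - _ELECTRON_MASS, 1),
    AdductSpec("+B", 11.009305 - _ELECTRON_MASS, 1),
    AdductSpec("+Ti", 47.947946 - _ELECTRON_MASS, 1),
    AdductSpec("+Mn", 54.938045 - _ELECTRON_MASS, 1),
    AdductSpec("+Co", 58.933195 - _ELECTRON_MASS, 1),
    AdductSpec("+Ni", 57.935343 - _ELECTRON_MASS, 1),
    AdductSpec("+Cu", 62.929598 - _ELECTRON_MASS, 1),
    AdductSpec("+Zn", 63.929142 - _ELECTRON_MASS, 1),
    AdductSpec("+Ag", 106.905097 - _ELECTRON_MASS, 1),
    AdductSpec("+Sn", 119.902195 - _ELECTRON_MASS, 1),
)


def adduct_mz(mass: float, adduct: AdductSpec = SODIUM_ADDUCT) -> float:
    """m/z of the adducted ion: (neutral mass + delta) / charge."""
    if mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {mass}")
    if adduct.charge < 1:
        raise ValueError("adduct charge must be >= 1")
    return (mass + adduct.mass_delta) / adduct.charge


def glycopeptide_offset(c: Composition) -> float:
    """Mass shift a glycan adds to an Asn-linked peptide (neutral mass − water)."""
    return neutral_mass(c) - WATER_MASS


# ---------------------------------------------------------------------------
# Elemental formulas and isotope envelopes
# ---------------------------------------------------------------------------

def elemental_formula(c: Composition) -> dict[str, int]:
    """Elemental counts (C,H,N,O) of the free glycan."""
    if c.is_empty():
        raise CompositionError("empty glycan: all monosaccharide counts are zero")
    counts = {"C": 0, "H": 0, "N": 0, "O": 0}
    residue_n = {"Hex": c.hex, "HexNAc": c.hexnac, "dHex": c.dhex, "Pent": c.pent}
    for residue, n in residue_n.items():
        for el, k in _RESIDUE_FORMULAS[residue].items():
            counts[el] += n * k
    for el, k in _WATER_FORMULA.items():
        counts[el] += k
    return {el: n for el, n in counts.items() if n > 0}


def formula_monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental formula."""
    return sum(_ATOMIC_MASSES[el] * n for el, n in formula.items())


def _poly_power(base: np.ndarray, n: int, max_len: int) -> np.ndarray:
    """base(x)^n by exponentiation-by-squaring, truncated to max_len terms."""
    result = np.array([1.0])
    acc = base.astype(float)
    while n > 0:
        if n & 1:
            result = np.convolve(result, acc)[:max_len]
        n >>= 1
        if n:
            acc = np.convolve(acc, acc)[:max_len]
    return result


def isotope_pattern(
    formula: Mapping[str, int], n_peaks: int = 4
) -> list[tuple[float, float]]:
    """Aggregated isotopologue envelope of an elemental formula.

    Per-element isotope distributions are convolved (binned at integer
    nominal-mass offsets), truncated to ``n_peaks`` and renormalized to sum 1.
    Returns ``[(mass_offset_da, abundance), ...]`` with the monoisotopic peak
    first; mass offsets use the 13C spacing, which dominates CHNO envelopes.
    """
    if n_peaks < 1:
        raise ValueError(f"n_peaks must be >= 1, got {n_peaks}")
    if not formula or all(n == 0 for n in formula.values()):
        raise ValueError("empty elemental formula")
    dist = np.array([1.0])
    for el, n in formula.items():
        if n < 0:
            raise ValueError(f"negative element count for {el}")
        if n == 0:
            continue
        if el not in _ELEMENT_ISOTOPES:
            raise ValueError(f"unsupported element {el!r} (expected C,H,N,O)")
        base = np.asarray(_ELEMENT_ISOTOPES[el], dtype=float)
        dist = np.convolve(dist, _poly_power(base, int(n), n_peaks))[:n_peaks]
    if len(dist) < n_peaks:
        dist = np.pad(dist, (0, n_peaks - len(dist)))
    dist = dist / dist.sum()
    return [(i * ISOTOPE_SPACING, float(a)) for i, a in enumerate(dist)]


# ---------------------------------------------------------------------------
# Structural classification
# ---------------------------------------------------------------------------

#: Mutually exclusive backbone classes.
_BACKBONE_CLASSES = ("oligomannose", "paucimannose", "complex")


def classify(c: Composition) -> tuple[frozenset[str], int]:
    """Composition-level structural classes and Lewis-a capacity.

    Requires the HexNAc2 chitobiose core (hexnac >= 2); otherwise returns an
    empty class set with the ``non-core`` flag. Rules:

    * oligomannose — HexNAc2, no Fuc/Xyl, Hex >= 5 (Man5–Man9 ladder);
    * paucimannose — HexNAc2 with Hex <= 4 (vacuolar-truncated; core Fuc/Xyl
      allowed);
    * complex — HexNAc >= 3 (antennal GlcNAc present);
    * core-fucosylated — dHex >= 1 (caveat: a lone dHex may instead be an
      antennal Lewis fucose; compositions cannot distinguish the isomers);
    * xylosylated — Pent >= 1;
    * lewis-a — capacity >= 1, where capacity = min(Hex−3, HexNAc−2, dHex−1)
      clipped at 0: each Lewis-a motif needs an antennal GlcNAc, a Gal and a
      Fuc beyond the Man3GlcNAc2 core, with one dHex reserved as putative
      core fucose.
    """
    if c.hexnac < 2:
        return frozenset({"non-core"}), 0
    classes: set[str] = set()
    if c.hexnac == 2 and c.dhex == 0 and c.pent == 0 and c.hex >= 5:
        classes.add("oligomannose")
    if c.hexnac == 2 and c.hex <= 4:
        classes.add("paucimannose")
    if c.hexnac >= 3:
        classes.add("complex")
    if c.dhex >= 1:
        classes.add("core-fucosylated")
    if c.pent >= 1:
        classes.add("xylosylated")
    capacity = max(0, min(c.hex - 3, c.hexnac - 2, c.dhex - 1))
    if capacity >= 1:
        classes.add("lewis-a")
    return frozenset(classes), capacity


# ---------------------------------------------------------------------------
# Database enumeration (combinatorial stand-in for a curated glycan DB)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlycanRecord:
    """One database entry: composition plus derived mass/class annotations."""

    composition: Composition
    neutral_mass: float
    formula: Mapping[str, int] = field(hash=False)
    classes: frozenset[str] = frozenset()
    lewis_a_capacity: int = 0
    id: str = ""

    @property
    def mz_na(self) -> float:
        return adduct_mz(self.neutral_mass, SODIUM_ADDUCT)


def _record_id(c: Composition) -> str:
    return f"H{c.hex}N{c.hexnac}F{c.dhex}P{c.pent}"


def make_record(c: Composition) -> GlycanRecord:
    """Build a :class:`GlycanRecord` (mass, formula, classes) for a composition."""
    classes, capacity = classify(c)
    return GlycanRecord(
        composition=c,
        neutral_mass=neutral_mass(c),
        formula=elemental_formula(c),
        classes=classes,
        lewis_a_capacity=capacity,
        id=_record_id(c),
    )


#: Default enumeration bounds (max counts per monosaccharide).
DEFAULT_BOUNDS: Mapping[str, int] = {"hex": 9, "hexnac": 6, "dhex": 3, "pent": 1}

#: Default annotation m/z window (Da), matching FTICR acquisition range.
DEFAULT_MZ_WINDOW: tuple[float, float] = (1000.0, 5000.0)


def enumerate_database(
    bounds: Mapping[str, int] | None = None,
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
    adduct: AdductSpec = SODIUM_ADDUCT,
) -> list[GlycanRecord]:
    """Enumerate N-glycan compositions whose adduct m/z falls in a window.

    Compositions run over hexnac in [2, bounds], hex in [2, bounds] and
    dhex/pent in [0, bounds] — every candidate carries the chitobiose core and
    at least the two core mannoses. Records are deduplicated and sorted by
    neutral mass.
    """
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    low, high = mz_window
    if not low < high:
        raise ValueError(f"invalid m/z window {mz_window}")
    for key, v in b.items():
        if v < 0:
            raise ValueError(f"negative bound for {key}")
    seen: set[Composition] = set()
    records: list[GlycanRecord] = []
    for nh in range(2, b["hexnac"] + 1):
        for h in range(2, b["hex"] + 1):
            for f in range(0, b["dhex"] + 1):
                for p in range(0, b["pent"] + 1):
                    c = Composition(h, nh, f, p)
                    if c in seen:
                        continue
                    seen.add(c)
                    mz = adduct_mz(neutral_mass(c), adduct)
                    if low <= mz <= high:
                        records.append(make_record(c))
    records.sort(key=lambda r: r.neutral_mass)
    return records


# ---------------------------------------------------------------------------
# Database serialization
# ---------------------------------------------------------------------------

def _records_to_frame(records: Iterable[GlycanRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "composition": format_composition(r.composition),
                "neutral_mass": round(r.neutral_mass, 6),
                "mz_Na": round(r.mz_na, 6),
                "formula": "".join(f"{el}{n}" for el, n in sorted(r.formula.items())),
                "classes": ";".join(sorted(r.classes)),
                "lewis_a_capacity": r.lewis_a_capacity,
            }
        )
    return pd.DataFrame(rows)


def write_database_csv(records: Iterable[GlycanRecord], path: str | Path) -> None:
    _records_to_frame(records).to_csv(path, index=False)


def read_database_csv(path: str | Path) -> list[GlycanRecord]:
    df = pd.read_csv(path)
    return [make_record(parse_composition(s)) for s in df["composition"]]


def write_database_json(records: Iterable[GlycanRecord], path: str | Path) -> None:
    payload = _records_to_frame(records).to_dict(orient="records")
    Path(path).write_text(json.dumps(payload, indent=1))


def read_database_json(path: str | Path) -> list[GlycanRecord]:
    payload = json.loads(Path(path).read_text())
    return [make_record(parse_composition(row["composition"])) for row in payload]
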