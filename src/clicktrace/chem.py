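"""Exact-mass arithmetic for mass-tag tracing.

The analytical backbone of the pipeline is the fixed monoisotopic mass
difference between a bioorthogonal dietary analog and its native
counterpart.  For propargylcholine — choline with one N-methyl replaced by
a propargyl group — that difference is a formula delta of two carbon atoms,
hence exactly +24.000000 Da on the monoisotopic scale (carbon-12 defines
the unified atomic mass unit).  Every downstream step (exclusivity
filtering, tagged/native pairing, annotation, MS2 diagnostics) reduces to
arithmetic on the quantities computed here.

Quaternary-ammonium analytes (choline, acylcholines) are permanent +1
cations observed as [M]+; their m/z is the formula mass minus one electron
mass.  Zwitterionic lipids such as lysophosphatidylcholines are modelled
through their protonated cation formula.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "AVERAGE_MASS",
    "ChemicalFormula",
    "parse_formula",
    "monoisotopic_mz",
    "average_mz",
    "ppm_error",
    "TagDefinition",
    "PROPARGYL_TAG",
    "SpeciesClass",
    "MetaboliteSpecies",
    "apply_tag",
    "FattyAcid",
    "DEFAULT_FATTY_ACIDS",
    "build_acylcholine_library",
    "lpc_species",
    "choline_species",
    "library_to_dataframe",
    "write_library_csv",
    "CHOLINE",
    "PROPARGYLCHOLINE",
]

# CODATA/NIST monoisotopic atomic masses (Da), most abundant isotope.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

# Standard atomic weights (average masses); exposed because low-resolution
# targeted methods quote averaged m/z (e.g. choline monitored at m/z 104.2).
AVERAGE_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "K": 39.098,
    "Cl": 35.45,
}

ELECTRON_MASS: float = 0.000548579909  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """An element -> count map with non-negative integer counts.

    Arithmetic never produces negative counts: subtracting more atoms of an
    element than are present raises ``ValueError``.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, n in self.counts.items():
            if not isinstance(n, int) or isinstance(n, bool):
                raise TypeError(f"count for {element!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {element!r}: {n}")
            if n > 0:
                clean[element] = n
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ChemicalFormula(merged)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            have = merged.get(element, 0)
            if n > have:
                raise ValueError(
                    f"cannot remove {n} {element} from formula with {have}"
                )
            merged[element] = have - n
        return ChemicalFormula(merged)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        total = 0.0
        for element, n in self.counts.items():
            try:
                total += n * MONOISOTOPIC_MASS[element]
            except KeyError:
                raise KeyError(f"no tabulated monoisotopic mass for {element!r}")
        return total

    @property
    def average_mass(self) -> float:
        """Neutral average mass in Da (standard atomic weights)."""
        total = 0.0
        for element, n in self.counts.items():
            try:
                total += n * AVERAGE_MASS[element]
            except KeyError:
                raise KeyError(f"no tabulated average mass for {element!r}")
        return total

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        parts: list[str] = []

        def emit(element: str) -> None:
            n = self.counts.get(element, 0)
            if n == 1:
                parts.append(element)
            elif n > 1:
                parts.append(f"{element}{n}")

        if "C" in self.counts:
            emit("C")
            emit("H")
            rest = sorted(e for e in self.counts if e not in ("C", "H"))
        else:
            rest = sorted(self.counts)
        for element in rest:
            emit(element)
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-notation formula string such as ``"C21H44NO2"``.

    An omitted count means 1.  Unknown element symbols (anything outside the
    embedded mass table) and malformed strings raise ``ValueError``.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        if not match.group(0):
            break
        element, digits = match.group(1), match.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return ChemicalFormula(counts)


def monoisotopic_mz(formula: ChemicalFormula, charge: int) -> float:
    """m/z of an ion: (monoisotopic mass − charge × electron mass) / |charge|.

    For cations the electrons carried away by the charge are subtracted; this
    electron-mass correction matters at sub-ppm accuracy on a high-resolution
    instrument.
    """
    if charge == 0:
        raise ValueError("charge must be non-zero for an m/z")
    return (formula.monoisotopic_mass - charge * ELECTRON_MASS) / abs(charge)


def average_mz(formula: ChemicalFormula, charge: int) -> float:
    """Average-mass m/z, for comparison with low-resolution targeted values."""
    if charge == 0:
        raise ValueError("charge must be non-zero for an m/z")
    return (formula.average_mass - charge * ELECTRON_MASS) / abs(charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# Tag and species definitions
# ---------------------------------------------------------------------------

_CHOLINE_FORMULA = ChemicalFormula({"C": 5, "H": 14, "N": 1, "O": 1})  # cation
_H2O = ChemicalFormula({"H": 2, "O": 1})
_H = ChemicalFormula({"H": 1})
_GPC_FORMULA = ChemicalFormula({"C": 8, "H": 20, "N": 1, "O": 6, "P": 1})


@dataclass(frozen=True)
class TagDefinition:
    """A mass tag defined by the formula difference tagged − native.

    The default propargyl tag replaces one N-methyl (CH3) with a propargyl
    group (C3H3): a net gain of C2, i.e. exactly +24.000000 Da.  The
    diagnostic fragments are the native and tagged choline headgroup cations
    seen in MS2.
    """

    name: str
    formula_delta: ChemicalFormula
    diagnostic_fragment_native: float
    diagnostic_fragment_tagged: float

    @property
    def mass_delta(self) -> float:
        return self.formula_delta.monoisotopic_mass

    def __post_init__(self) -> None:
        expected = self.diagnostic_fragment_native + self.mass_delta
        if abs(self.diagnostic_fragment_tagged - expected) > 1e-6:
            raise ValueError(
                "tagged diagnostic fragment must equal native + mass_delta"
            )


PROPARGYL_TAG = TagDefinition(
    name="propargyl",
    formula_delta=ChemicalFormula({"C": 2}),
    diagnostic_fragment_native=monoisotopic_mz(_CHOLINE_FORMULA, +1),
    diagnostic_fragment_tagged=monoisotopic_mz(_CHOLINE_FORMULA, +1) + 24.0,
)


class SpeciesClass(str, Enum):
    CHOLINE = "choline"
    ACYLCHOLINE = "acylcholine"
    LPC = "lysophosphatidylcholine"
    OTHER = "other"


@dataclass(frozen=True)
class MetaboliteSpecies:
    """A named ionic species with a formula, charge and theoretical m/z."""

    name: str
    formula: ChemicalFormula
    charge: int = +1
    species_class: SpeciesClass = SpeciesClass.OTHER
    tagged: bool = False

    @property
    def theoretical_mz(self) -> float:
        return monoisotopic_mz(self.formula, self.charge)


def apply_tag(native: MetaboliteSpecies, tag: TagDefinition = PROPARGYL_TAG) -> MetaboliteSpecies:
    """Return the tagged analog of a native species (charge unchanged)."""
    if native.tagged:
        raise ValueError(f"species {native.name!r} is already tagged")
    name = native.name
    if name.endswith("-NC"):
        name = name[:-3] + "-PC"
    else:
        name = f"propargyl-{name}" if name == "choline" else f"{name}+{tag.name}"
    if native.name == "choline":
        name = "propargylcholine"
    return MetaboliteSpecies(
        name=name,
        formula=native.formula + tag.formula_delta,
        charge=native.charge,
        species_class=native.species_class,
        tagged=True,
    )


@dataclass(frozen=True)
class FattyAcid:
    """An acyl chain: carbon count, double bonds, optional hydroxylation."""

    carbons: int
    double_bonds: int = 0
    hydroxyl: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("fatty acid needs at least 2 carbons")
        if self.double_bonds < 0:
            raise ValueError("double bond count must be non-negative")

    @property
    def formula(self) -> ChemicalFormula:
        # CnH(2n-2d)O2, +O if hydroxylated
        counts = {
            "C": self.carbons,
            "H": 2 * self.carbons - 2 * self.double_bonds,
            "O": 3 if self.hydroxyl else 2,
        }
        return ChemicalFormula(counts)

    @property
    def label(self) -> str:
        if self.hydroxyl:
            base = f"C{self.carbons}(OH)"
            if self.double_bonds:
                base = f"C{self.carbons}:{self.double_bonds}(OH)"
            return base
        return f"C{self.carbons}:{self.double_bonds}"


# The acylcholine series produced by L. reuteri cultured with choline:
# 14:0, 16:0, 18:0, 18:1, 18:2, 18(OH) (modelled hydroxy-stearoyl), 19:1.
DEFAULT_FATTY_ACIDS: tuple[FattyAcid, ...] = (
    FattyAcid(14, 0),
    FattyAcid(16, 0),
    FattyAcid(18, 0),
    FattyAcid(18, 1),
    FattyAcid(18, 2),
    FattyAcid(18, 0, hydroxyl=True),
    FattyAcid(19, 1),
)


def choline_species() -> MetaboliteSpecies:
    return MetaboliteSpecies(
        name="choline",
        formula=_CHOLINE_FORMULA,
        charge=+1,
        species_class=SpeciesClass.CHOLINE,
    )


CHOLINE = choline_species()
PROPARGYLCHOLINE = apply_tag(CHOLINE)


def build_acylcholine_library(
    fatty_acids: Sequence[FattyAcid | tuple] = DEFAULT_FATTY_ACIDS,
    tag: TagDefinition = PROPARGYL_TAG,
) -> list[MetaboliteSpecies]:
    """Native (NC) and tagged (PC) acylcholine cations for each acyl chain.

    The acyl ester formula is choline + fatty acid − H2O (Fischer
    esterification); the species stay permanent +1 cations.
    """
    library: list[MetaboliteSpecies] = []
    for fa in fatty_acids:
        if not isinstance(fa, FattyAcid):
            fa = FattyAcid(*fa)
        ester = _CHOLINE_FORMULA + fa.formula - _H2O
        native = MetaboliteSpecies(
            name=f"{fa.label}-NC",
            formula=ester,
            charge=+1,
            species_class=SpeciesClass.ACYLCHOLINE,
            tagged=False,
        )
        library.append(native)
        library.append(apply_tag(native, tag))
    return library


def lpc_species(carbons: int, double_bonds: int) -> MetaboliteSpecies:
    """A lysophosphatidylcholine observed as the protonated [M+H]+ cation.

    Built as glycerophosphocholine + fatty acid − H2O, then protonated; the
    stored formula is the cation formula so the +1 charge convention applies
    uniformly.
    """
    fa = FattyAcid(carbons, double_bonds)
    neutral = _GPC_FORMULA + fa.formula - _H2O
    return MetaboliteSpecies(
        name=f"LPC {carbons}:{double_bonds}",
        formula=neutral + _H,
        charge=+1,
        species_class=SpeciesClass.LPC,
    )


def library_to_dataframe(library: Iterable[MetaboliteSpecies]):
    """Species library as a DataFrame (name, formula, charge, m/z, class, tagged)."""
    import pandas as pd

    rows = [
        {
            "name": s.name,
            "formula": s.formula.hill(),
            "charge": s.charge,
            "theoretical_mz": s.theoretical_mz,
            "species_class": s.species_class.value,
            "tagged": s.tagged,
        }
        for s in library
    ]
    return pd.DataFrame(
        rows,
        columns=["name", "formula", "charge", "theoretical_mz", "species_class", "tagged"],
    )


def write_library_csv(library: Iterable[MetaboliteSpecies], path) -> None:
    library_to_dataframe(library).to_csv(path, index=False, float_format="%.6f")


def read_library_csv(path) -> list[MetaboliteSpecies]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        MetaboliteSpecies(
            name=row["name"],
            formula=parse_formula(row["formula"]),
            charge=int(row["charge"]),
            species_class=SpeciesClass(row["species_class"]),
            tagged=bool(row["tagged"]),
        )
        for _, row in df.iterrows()
    ]
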