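"""Glycosphingolipid nomenclature, elemental composition, and ion m/z.

Shorthand names follow the lipidomics convention for sphingolipids: a class
token (Svennerholm root for gangliosides, composition token otherwise), the
sphingoid base as ``carbons:double_bonds;O<oxygens>`` (e.g. ``18:1;O2``), a
slash, and the N-linked fatty acyl as ``carbons:double_bonds`` with an
optional ``;O``/``;O<n>`` hydroxylation suffix, plus an optional deuterium
label ``-d3``/``-d5``/``-d9`` on internal standards, e.g.
``GM3 18:1;O2/18:0-d5``.  The legacy ``d18:1`` dialect is accepted on input
and normalised to ``18:1;O2`` on output.

Elemental bookkeeping is delegated to :class:`pyteomics.mass.Composition`;
deuterium is carried as the explicit isotope ``H[2]``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from pyteomics import mass as ptmass

from .errors import GSLParseError, RegistryError

# Proton mass (Da) used for every charge; includes the electron so that
# computed values reproduce printed two-decimal m/z of reference ions.
PROTON = 1.007276

#: Anhydro (residue) formulas of the monosaccharides occurring in GSL glycans.
RESIDUE_FORMULAS: dict[str, str] = {
    "Hex": "C6H10O5",
    "HexNAc": "C8H13NO5",
    "dHex": "C6H10O4",
    "Neu5Ac": "C11H17NO8",
    "Neu5Gc": "C11H17NO9",
}

#: Formula deltas of glycan modifications.
MOD_FORMULAS: dict[str, str] = {
    "sulfate": "SO3",
    "oacetyl": "C2H2O",
}

H2O = "H2O"


def formula(text: str) -> ptmass.Composition:
    """Parse an elemental formula string into a Composition."""
    return ptmass.Composition(formula=text)


def monoisotopic_mass(composition: ptmass.Composition | str) -> float:
    """Monoisotopic mass (Da) of an elemental composition.

    Accepts either a Composition or a formula string.  Deuterium must be
    given as the isotope ``H[2]``.  Unknown elements raise
    :class:`pyteomics.auxiliary.PyteomicsError`.
    """
    if isinstance(composition, str):
        composition = formula(composition)
    return ptmass.calculate_mass(composition=composition)


def formula_to_string(composition: ptmass.Composition) -> str:
    """Hill-ish rendering (C, H, then alphabetical) of a composition."""
    comp = {k: v for k, v in composition.items() if v}
    parts = []
    for el in ("C", "H"):
        if el in comp:
            n = comp.pop(el)
            parts.append(el + (str(n) if n != 1 else ""))
    for el in sorted(comp):
        n = comp[el]
        shown = "D" if el == "H[2]" else el
        parts.append(shown + (str(n) if n != 1 else ""))
    return "".join(parts)


# ---------------------------------------------------------------------------
# ceramide building blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphingoidBase:
    """A sphingoid base ``carbons:double_bonds;O<oxygens>``.

    The free base has formula C_c H_(2c-2d+3) N O_n: e.g. sphingosine
    (18:1;O2) is C18H37NO2.
    """

    carbons: int
    double_bonds: int
    oxygens: int = 2

    def __post_init__(self):
        if not (14 <= self.carbons <= 26):
            raise ValueError(f"sphingoid carbons out of range: {self.carbons}")
        if not (0 <= self.double_bonds <= 3):
            raise ValueError(f"sphingoid double bonds out of range: {self.double_bonds}")
        if not (2 <= self.oxygens <= 4):
            raise ValueError(f"sphingoid oxygens out of range: {self.oxygens}")

    @property
    def formula(self) -> ptmass.Composition:
        c, d, n = self.carbons, self.double_bonds, self.oxygens
        return ptmass.Composition(C=c, H=2 * c - 2 * d + 3, N=1, O=n)

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds};O{self.oxygens}"


@dataclass(frozen=True)
class FattyAcyl:
    """An N-linked fatty acyl chain; the free acid is C_x H_(2x-2y) O_(2+h)."""

    carbons: int
    double_bonds: int = 0
    hydroxyls: int = 0

    def __post_init__(self):
        if not (10 <= self.carbons <= 26):
            raise ValueError(f"fatty acyl carbons out of range: {self.carbons}")
        if not (0 <= self.double_bonds <= 3):
            raise ValueError(f"fatty acyl double bonds out of range: {self.double_bonds}")
        if not (0 <= self.hydroxyls <= 2):
            raise ValueError(f"fatty acyl hydroxyls out of range: {self.hydroxyls}")

    @property
    def formula(self) -> ptmass.Composition:
        x, y, h = self.carbons, self.double_bonds, self.hydroxyls
        return ptmass.Composition(C=x, H=2 * x - 2 * y, O=2 + h)

    def __str__(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.hydroxyls == 1:
            s += ";O"
        elif self.hydroxyls > 1:
            s += f";O{self.hydroxyls}"
        return s


_LABEL_RE = re.compile(r"^d(\d+)$")


@dataclass(frozen=True)
class Ceramide:
    """Sphingoid base N-acylated with a fatty acid (amide bond loses H2O).

    ``label`` is an optional deuterium label ``d<K>`` substituting K
    hydrogens by deuterium, as carried by internal standards.
    """

    base: SphingoidBase
    acyl: FattyAcyl
    label: str = ""

    def __post_init__(self):
        if self.label and not _LABEL_RE.match(self.label):
            raise ValueError(f"bad isotope label: {self.label!r}")

    @property
    def deuterium_count(self) -> int:
        m = _LABEL_RE.match(self.label) if self.label else None
        return int(m.group(1)) if m else 0

    @property
    def formula(self) -> ptmass.Composition:
        comp = self.base.formula + self.acyl.formula - formula(H2O)
        k = self.deuterium_count
        if k:
            if k > comp["H"]:
                raise ValueError("deuterium label exceeds available hydrogens")
            comp["H"] -= k
            comp["H[2]"] += k
        return comp

    def __str__(self) -> str:
        s = f"{self.base}/{self.acyl}"
        if self.label:
            s += f"-{self.label}"
        return s


# ---------------------------------------------------------------------------
# glycan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of monosaccharide residues and modifications in the glycan."""

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neu5ac: int = 0
    neu5gc: int = 0
    sulfate: int = 0
    oacetyl: int = 0

    def __post_init__(self):
        for name in ("hex", "hexnac", "dhex", "neu5ac", "neu5gc", "sulfate", "oacetyl"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} count")
        if self.total_monosaccharides > 15:
            raise ValueError("glycan exceeds 15 monosaccharides")

    @property
    def total_monosaccharides(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.neu5ac + self.neu5gc

    @property
    def formula(self) -> ptmass.Composition:
        comp = ptmass.Composition()
        for key, res in (
            ("hex", "Hex"), ("hexnac", "HexNAc"), ("dhex", "dHex"),
            ("neu5ac", "Neu5Ac"), ("neu5gc", "Neu5Gc"),
        ):
            n = getattr(self, key)
            if n:
                comp += formula(RESIDUE_FORMULAS[res]) * n
        for key in ("sulfate", "oacetyl"):
            n = getattr(self, key)
            if n:
                comp += formula(MOD_FORMULAS[key]) * n
        return comp


_RES_TO_FIELD = {"Hex": "hex", "HexNAc": "hexnac", "dHex": "dhex",
                 "Neu5Ac": "neu5ac", "Neu5Gc": "neu5gc"}


@dataclass(frozen=True)
class TopologyNode:
    """One residue in the rooted glycan tree.

    ``parent`` is the index of the parent node, or -1 for attachment to the
    ceramide.  Modifications (O-acetyl, sulfate) ride with the residue that
    carries them and stay on its B/Y fragments.
    """

    residue: str
    parent: int
    oacetyl: int = 0
    sulfate: int = 0

    def __post_init__(self):
        if self.residue not in RESIDUE_FORMULAS:
            raise ValueError(f"unknown residue {self.residue!r}")

    @property
    def formula(self) -> ptmass.Composition:
        comp = formula(RESIDUE_FORMULAS[self.residue])
        if self.oacetyl:
            comp += formula(MOD_FORMULAS["oacetyl"]) * self.oacetyl
        if self.sulfate:
            comp += formula(MOD_FORMULAS["sulfate"]) * self.sulfate
        return comp


def composition_from_topology(topology: tuple[TopologyNode, ...]) -> GlycanComposition:
    counts: dict[str, int] = {}
    for node in topology:
        counts[_RES_TO_FIELD[node.residue]] = counts.get(_RES_TO_FIELD[node.residue], 0) + 1
        counts["oacetyl"] = counts.get("oacetyl", 0) + node.oacetyl
        counts["sulfate"] = counts.get("sulfate", 0) + node.sulfate
    return GlycanComposition(**counts)


# ---------------------------------------------------------------------------
# class registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassInfo:
    name: str
    series: str  # ganglio | neolacto | neutral | sulfatide
    topology: tuple[TopologyNode, ...]
    composition: GlycanComposition
    default_ion_neg: str
    default_ion_pos: str
    isomer_tag: str = ""  # e.g. "a"/"b" for GD1a/GD1b; same mass, CCS-resolved

    @property
    def sialic_count(self) -> int:
        return self.composition.neu5ac + self.composition.neu5gc


@lru_cache(maxsize=1)
def class_registry() -> dict[str, ClassInfo]:
    """The versioned GSL class registry shipped with the package."""
    text = resources.files("gsl4d.data").joinpath("classes.json").read_text()
    raw = json.loads(text)
    registry: dict[str, ClassInfo] = {}
    for name, entry in raw["classes"].items():
        topo = tuple(
            TopologyNode(
                residue=n["r"], parent=n["p"],
                oacetyl=n.get("oac", 0), sulfate=n.get("so3", 0),
            )
            for n in entry["topology"]
        )
        registry[name] = ClassInfo(
            name=name,
            series=entry["series"],
            topology=topo,
            composition=composition_from_topology(topo),
            default_ion_neg=entry["ion_neg"],
            default_ion_pos=entry["ion_pos"],
            isomer_tag=entry.get("isomer_tag", ""),
        )
    return registry


def class_info(class_name: str) -> ClassInfo:
    try:
        return class_registry()[class_name]
    except KeyError:
        raise RegistryError(f"unknown GSL class {class_name!r}") from None


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GSLSpecies:
    """A GSL molecular species: registry glycan joined to a ceramide.

    ``ceramide`` may be None for placeholder (count-only) entries whose
    sphingoid base or acyl chain is not identified; such species have no
    defined mass.
    """

    class_name: str
    glycan: GlycanComposition
    topology: tuple[TopologyNode, ...] = field(repr=False)
    ceramide: Ceramide | None

    @property
    def is_placeholder(self) -> bool:
        return self.ceramide is None

    @property
    def name(self) -> str:
        return format_species_name(self)

    def __str__(self) -> str:
        return self.name


def make_species(class_name: str, ceramide: Ceramide | None) -> GSLSpecies:
    info = class_info(class_name)
    return GSLSpecies(
        class_name=class_name,
        glycan=info.composition,
        topology=info.topology,
        ceramide=ceramide,
    )


#: Accepted aliases for class tokens (input only; canonical key on output).
CLASS_ALIASES = {
    "O-acetyl GD1": "OAc-GD1",
    "O-Ac-GD1": "OAc-GD1",
}

_CER_RE = re.compile(
    r"^(?:d(?P<legacy_c>\d+):(?P<legacy_d>\d+)"     # legacy d18:1
    r"|(?P<bc>\d+):(?P<bd>\d+);O(?P<bo>\d+))"       # 18:1;O2
    r"/(?P<ac>\d+):(?P<ad>\d+)(?P<ah>;O\d*)?"       # 18:0 or 24:0;O / ;O2
    r"(?:-(?P<label>d\d+))?$"                       # -d5
)


def parse_ceramide(text: str) -> Ceramide:
    m = _CER_RE.match(text)
    if not m:
        raise GSLParseError(
            f"malformed ceramide string {text!r}", token=text, position=0
        )
    if m.group("legacy_c"):
        base = SphingoidBase(int(m.group("legacy_c")), int(m.group("legacy_d")), 2)
    else:
        base = SphingoidBase(int(m.group("bc")), int(m.group("bd")), int(m.group("bo")))
    hydrox = 0
    if m.group("ah"):
        digits = m.group("ah")[2:]
        hydrox = int(digits) if digits else 1
    acyl = FattyAcyl(int(m.group("ac")), int(m.group("ad")), hydrox)
    return Ceramide(base=base, acyl=acyl, label=m.group("label") or "")


def parse_species_name(name: str) -> GSLSpecies:
    """Parse a shorthand species name, e.g. ``"GD1 18:1;O2/18:0"``.

    Raises :class:`GSLParseError` naming the unknown class token or the
    position of a malformed ceramide string.
    """
    text = name.strip()
    m = re.match(r"^(?P<cls>.+?)\s+(?P<cer>d?\d.*)$", text)
    if not m:
        raise GSLParseError(f"cannot split {name!r} into class and ceramide",
                            token=text)
    cls = m.group("cls").strip()
    cls = CLASS_ALIASES.get(cls, cls)
    if cls not in class_registry():
        raise GSLParseError(f"unknown class token {cls!r}", token=cls, position=0)
    try:
        cer = parse_ceramide(m.group("cer"))
    except GSLParseError as err:
        err.position = m.start("cer")
        raise
    return make_species(cls, cer)


def format_species_name(species: GSLSpecies) -> str:
    """Canonical shorthand form; inverse of :func:`parse_species_name`."""
    if species.ceramide is None:
        return f"{species.class_name} (unidentified ceramide)"
    return f"{species.class_name} {species.ceramide}"


def elemental_formula(species: GSLSpecies) -> ptmass.Composition:
    """Full elemental composition: ceramide + anhydro residues + modifications."""
    if species.ceramide is None:
        raise ValueError(f"placeholder species {species.class_name} has no formula")
    return species.ceramide.formula + species.glycan.formula


def species_mass(species: GSLSpecies) -> float:
    """Monoisotopic neutral mass M (Da)."""
    return monoisotopic_mass(elemental_formula(species))


# ---------------------------------------------------------------------------
# ion types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonType:
    """An ionisation form, e.g. ``[M-2H]2-`` or ``[M+HCOOH-2H]2-``.

    ``neutral_delta`` is the formula of everything gained or lost other
    than the z transferred protons (stored as a string; may be signed via
    negative counts in the parsed composition).
    """

    name: str
    polarity: str  # "+" or "-"
    charge: int
    neutral_delta_formula: str = ""  # e.g. "CH2O2" for formate adduct

    def __post_init__(self):
        if self.polarity not in "+-":
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def neutral_delta(self) -> ptmass.Composition:
        comp = ptmass.Composition()
        for sign, part in re.findall(r"([+-]?)([A-Za-z0-9\[\]]+)", self.neutral_delta_formula):
            term = formula(part)
            comp = comp - term if sign == "-" else comp + term
        return comp

    def mz(self, neutral_mass: float) -> float:
        sign = 1.0 if self.polarity == "+" else -1.0
        return (neutral_mass + monoisotopic_mass(self.neutral_delta)
                + sign * self.charge * PROTON) / self.charge


_ION_RE = re.compile(r"^\[M(?P<terms>[^\]]*)\](?P<z>\d*)(?P<pol>[+-])$")
_TERM_RE = re.compile(r"([+-])(\d*)((?:[A-Z][a-z]?\d*)+)")


def parse_ion(name: str) -> IonType:
    """Parse an ion-type name like ``[M-2H]2-`` or ``[M+HCOOH-2H]2-``."""
    m = _ION_RE.match(name.replace(" ", ""))
    if not m:
        raise GSLParseError(f"cannot parse ion type {name!r}", token=name)
    z = int(m.group("z") or 1)
    pol = m.group("pol")
    delta = ptmass.Composition()
    for sign, count, part in _TERM_RE.findall(m.group("terms")):
        term = formula(part) * (int(count) if count else 1)
        delta = delta - term if sign == "-" else delta + term
    # split off the z transferred protons; the remainder is the neutral delta
    sign = 1 if pol == "+" else -1
    delta["H"] -= sign * z
    gains = ptmass.Composition({k: v for k, v in delta.items() if v > 0})
    losses = ptmass.Composition({k: -v for k, v in delta.items() if v < 0})
    neutral = formula_to_string(gains) if gains else ""
    if losses:
        neutral += "-" + formula_to_string(losses)
    return IonType(name=name, polarity=pol, charge=z, neutral_delta_formula=neutral)


def ion_mz(species: GSLSpecies, ion: IonType | str) -> float:
    """m/z of the given ion of a species (proton mass 1.007276 per charge)."""
    if isinstance(ion, str):
        ion = parse_ion(ion)
    return ion.mz(species_mass(species))


def default_ion_type(class_name: str, polarity: str) -> IonType:
    """The class's predominant ion type in the requested polarity."""
    info = class_info(class_name)
    name = info.default_ion_neg if polarity == "-" else info.default_ion_pos
    return parse_ion(name)
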