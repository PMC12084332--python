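"""In-silico glycosidic/ceramide fragmentation and diagnostic-ion screening.

Glycosidic B/Y ions are generated at every bond of the registry topology
tree; cleaving a branch bond yields the branch as the B ion, and
modifications (O-acetyl, sulfate) ride with the residue that carries them.
All fragments are generated singly charged, matching the nominal diagnostic
ions used for class screening: 290 (deprotonated Neu5Ac B), 581 (disialo
Neu5Ac2 B, characteristic of b-series GD1), 332 (O-acetyl Neu5Ac), 306
(Neu5Gc) in negative mode; 274 (Neu5Ac oxonium - H2O) and the sphingoid
base ions 264/262 (18:1;O2 / 18:2;O2) in positive mode; plus the neutral
losses of one hexose (162.0528) and of lactose (342.1162) used to screen
neutral GSLs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

from pyteomics import mass as ptmass

from . import chem
from .chem import PROTON, GSLSpecies, formula, monoisotopic_mass
from .spectra import Spectrum


def nominal_mz(mz: float) -> int:
    """Integer nominal mass: round half away from zero."""
    return int(math.floor(mz + 0.5)) if mz >= 0 else -int(math.floor(-mz + 0.5))


@dataclass(frozen=True)
class FragmentIon:
    """One singly charged fragment (or neutral-loss) ion."""

    label: str
    formula: str
    mz: float
    polarity: str
    nominal: int

    @classmethod
    def from_neutral(cls, label: str, neutral: ptmass.Composition, polarity: str):
        m = monoisotopic_mass(neutral)
        mz = m + PROTON if polarity == "+" else m - PROTON
        return cls(label=label, formula=chem.formula_to_string(neutral),
                   mz=mz, polarity=polarity, nominal=nominal_mz(mz))


def _subtree(topology, i: int) -> list[int]:
    members = [i]
    frontier = [i]
    while frontier:
        nxt = [j for j, node in enumerate(topology) if node.parent in frontier]
        members += nxt
        frontier = nxt
    return members


def glycosidic_fragments(species: GSLSpecies, polarity: str,
                         include_cz: bool = False) -> list[FragmentIon]:
    """B and Y ions at every glycosidic bond of the topology tree.

    B ions retain the non-reducing side (sum of anhydro residues of the
    cleaved subtree); Y ions retain the ceramide side.  C/Z ions (B+H2O,
    Y-H2O) are generated on request but take part in no diagnostic rule.
    """
    if not species.topology:
        raise ValueError(f"species {species.class_name} has no glycan topology")
    precursor = chem.elemental_formula(species)
    water = formula(chem.H2O)
    topo = species.topology
    out: list[FragmentIon] = []
    oac = formula(chem.MOD_FORMULAS["oacetyl"])
    for i, node in enumerate(topo):
        sub = _subtree(topo, i)
        b_neutral = ptmass.Composition()
        n_oac = 0
        for j in sub:
            b_neutral += topo[j].formula
            n_oac += topo[j].oacetyl
        y_neutral = precursor - b_neutral
        tag = f"{node.residue}@{i}"
        b_variants = [(f"B[{tag}]", b_neutral)]
        if n_oac:
            # O-acetyl is labile and readily lost from sialylated B ions
            b_variants.append((f"B-OAc[{tag}]", b_neutral - oac * n_oac))
        for lbl, neutral in b_variants:
            out.append(FragmentIon.from_neutral(lbl, neutral, polarity))
            if polarity == "+":
                # oxonium ions routinely shed water; the dehydrated Neu5Ac
                # oxonium is the nominal-274 sialylation diagnostic
                out.append(FragmentIon.from_neutral(
                    lbl.replace("B", "B-H2O", 1), neutral - water, polarity))
        out.append(FragmentIon.from_neutral(f"Y[{tag}]", y_neutral, polarity))
        if include_cz:
            out.append(FragmentIon.from_neutral(f"C[{tag}]", b_neutral + water, polarity))
            out.append(FragmentIon.from_neutral(f"Z[{tag}]", y_neutral - water, polarity))
    # non-glycosidic signature losses observed for the relevant classes:
    # SO3 loss from sulfatides, and loss of free lactose (anhydro-Hex2 +
    # H2O, 342.1162) from a root-attached unmodified Hex-Hex chain
    n_sulf = sum(node.sulfate for node in topo)
    if n_sulf:
        out.append(FragmentIon.from_neutral(
            "NL[SO3]", precursor - formula(chem.MOD_FORMULAS["sulfate"]), polarity))
    if (len(topo) >= 2 and topo[0].residue == "Hex" and not topo[0].sulfate
            and not topo[0].oacetyl and topo[1].residue == "Hex"
            and topo[1].parent == 0 and not topo[1].sulfate and not topo[1].oacetyl):
        lactose = formula(chem.RESIDUE_FORMULAS["Hex"]) * 2 + water
        out.append(FragmentIon.from_neutral("NL[lactose]", precursor - lactose,
                                            polarity))
    return out


def ceramide_fragments(species: GSLSpecies) -> list[FragmentIon]:
    """Positive-mode ceramide-derived ions.

    Emits the sphingoid-base ions [base+H-H2O]+ and [base+H-2H2O]+ (the
    latter are the nominal 264/262 diagnostics for 18:1;O2 / 18:2;O2), and
    precursor-minus-fatty-acyl neutral-loss ions (loss of the free fatty
    acid and of its ketene).
    """
    if species.ceramide is None:
        raise ValueError("placeholder ceramide has no fragments")
    cer = species.ceramide
    water = formula(chem.H2O)
    base = cer.base.formula
    precursor = chem.elemental_formula(species)
    acid = cer.acyl.formula
    ketene = acid - water
    out = [
        FragmentIon.from_neutral("Sphingoid[base-H2O]", base - water, "+"),
        FragmentIon.from_neutral("Sphingoid[base-2H2O]", base - water - water, "+"),
        FragmentIon.from_neutral("NL[fatty acid]", precursor - acid, "+"),
        FragmentIon.from_neutral("NL[fatty acyl ketene]", precursor - ketene, "+"),
    ]
    return out


# ---------------------------------------------------------------------------
# diagnostic catalog and screening
# ---------------------------------------------------------------------------

_NEU5AC = formula(chem.RESIDUE_FORMULAS["Neu5Ac"])
_NEU5GC = formula(chem.RESIDUE_FORMULAS["Neu5Gc"])
_HEX = formula(chem.RESIDUE_FORMULAS["Hex"])
_OAC = formula(chem.MOD_FORMULAS["oacetyl"])
_SO3 = formula(chem.MOD_FORMULAS["sulfate"])
_H2O = formula(chem.H2O)


def _m(comp) -> float:
    return monoisotopic_mass(comp)


def diagnostic_catalog(polarity: str) -> list[tuple[str, float, int]]:
    """(flag name, exact m/z or neutral-loss mass, nominal) diagnostics.

    Exact values are computed from atomic masses at call time; the nominal
    values are their integer roundings.  Entries whose name starts with
    ``loss:`` are neutral losses tested against precursor - peak.
    """
    if polarity == "-":
        entries = [
            ("sialylated_neg", _m(_NEU5AC) - PROTON),
            ("disialo_element", _m(_NEU5AC * 2) - PROTON),
            ("o_acetyl_sialic", _m(_NEU5AC + _OAC) - PROTON),
            ("neu5gc", _m(_NEU5GC) - PROTON),
            ("loss:sulfate_signature", _m(_SO3)),
        ]
    elif polarity == "+":
        sphingoid_18_1 = chem.SphingoidBase(18, 1, 2).formula
        sphingoid_18_2 = chem.SphingoidBase(18, 2, 2).formula
        entries = [
            ("sialylated_pos", _m(_NEU5AC) + PROTON - _m(_H2O)),
            ("sphingoid_18_1", _m(sphingoid_18_1 - _H2O - _H2O) + PROTON),
            ("sphingoid_18_2", _m(sphingoid_18_2 - _H2O - _H2O) + PROTON),
            ("loss:hex_loss", _m(_HEX)),
            ("loss:hex2_loss", _m(_HEX * 2 + _H2O)),  # free lactose, 342.1162
        ]
    else:
        raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")
    return [(name, mz, nominal_mz(mz)) for name, mz in entries]


@dataclass(frozen=True)
class DiagnosticFlagSet:
    """Booleans set by matching catalog diagnostics in one spectrum."""

    sialylated_neg: bool = False
    sialylated_pos: bool = False
    disialo_element: bool = False
    o_acetyl_sialic: bool = False
    neu5gc: bool = False
    sphingoid_18_1: bool = False
    sphingoid_18_2: bool = False
    hex_loss: bool = False
    hex2_loss: bool = False
    sulfate_signature: bool = False

    def any(self) -> bool:
        return any(getattr(self, f.name) for f in dc_fields(self))

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


#: Default fragment matching tolerance (mDa); fragments are noisier than
#: precursors, whose windows are 2-5 mDa.
DEFAULT_FRAGMENT_TOL_MDA = 10.0


def classify_spectrum(spectrum: Spectrum, polarity: str,
                      fragment_tol_mDa: float = DEFAULT_FRAGMENT_TOL_MDA,
                      ) -> DiagnosticFlagSet:
    """Set a flag iff some peak (or precursor neutral loss) lies within
    tolerance of the catalog's exact mass."""
    tol = fragment_tol_mDa / 1000.0
    flags: dict[str, bool] = {}
    if len(spectrum) == 0:
        return DiagnosticFlagSet()
    for name, exact, _nom in diagnostic_catalog(polarity):
        if name.startswith("loss:"):
            key = name[5:]
            if spectrum.precursor_mz is None:
                flags[key] = False
                continue
            losses = spectrum.precursor_mz - spectrum.mz
            flags[key] = bool((abs(losses - exact) <= tol).any())
        else:
            flags[name] = bool((abs(spectrum.mz - exact) <= tol).any())
    return DiagnosticFlagSet(**flags)


def expected_flags(species: GSLSpecies, polarity: str) -> dict[str, bool]:
    """Flags implied by a species' composition/topology (used by round-trip
    property tests and the synthetic generator)."""
    comp = species.glycan
    topo = species.topology
    adjacent_sia = any(
        node.residue == "Neu5Ac" and node.parent >= 0
        and topo[node.parent].residue == "Neu5Ac"
        for node in topo
    )
    children = {i: [] for i in range(len(topo))}
    for j, node in enumerate(topo):
        if node.parent >= 0:
            children[node.parent].append(j)
    has_leaf_hex = any(
        node.residue == "Hex" and not children[i]
        and not node.sulfate and not node.oacetyl
        for i, node in enumerate(topo)
    )
    root_lactose = (len(topo) >= 2 and topo[0].residue == "Hex"
                    and topo[1].residue == "Hex" and topo[1].parent == 0
                    and not (topo[0].sulfate or topo[1].sulfate
                             or topo[0].oacetyl or topo[1].oacetyl))
    out = {f.name: False for f in dc_fields(DiagnosticFlagSet())}
    if polarity == "-":
        out["sialylated_neg"] = comp.neu5ac > 0
        out["disialo_element"] = adjacent_sia
        out["o_acetyl_sialic"] = comp.oacetyl > 0
        out["neu5gc"] = comp.neu5gc > 0
        out["sulfate_signature"] = comp.sulfate > 0
    else:
        out["sialylated_pos"] = comp.neu5ac > 0
        if species.ceramide is not None:
            base = species.ceramide.base
            out["sphingoid_18_1"] = (base.carbons, base.double_bonds, base.oxygens) == (18, 1, 2)
            out["sphingoid_18_2"] = (base.carbons, base.double_bonds, base.oxygens) == (18, 2, 2)
        out["hex_loss"] = has_leaf_hex
        out["hex2_loss"] = root_lactose
    return out
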