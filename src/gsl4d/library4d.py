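"""4D reference-library model, builder, serialization, and serum fixture.

A library entry ties one GSL species/ion form to its four descriptors:
theoretical m/z, mean retention time (min), mean collisional cross section
(Å²), and an optional reference MS/MS spectrum, plus the extract fraction
it is observed in (1 = neutral GSLs and sulfatides, 2 = sialylated GSLs).

The packaged serum fixture enumerates the published per-(subclass,
sphingoid base, acyl range) species counts for human serum (376 species:
129 ganglio, 30 sialylated neolacto, 145 neutral, 72 sulfatide).  The
printed inventory gives carbon ranges, not explicit chain lists, so the
fixture fills each row's count deterministically (even acyl carbons
ascending first, then odd, then higher double-bond/hydroxylation
variants); counts, not membership, are the contract.  Fixture RT/CCS come
from a deterministic monotone surrogate model (RT grows with acyl length,
falls with unsaturation and glycan size; CCS grows with both mass and
glycan size) anchored to measured reference values where published; they
exercise the matching logic and are not scientific reference values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .chem import Ceramide, FattyAcyl, GSLSpecies, SphingoidBase
from .errors import GSLError, LibrarySchemaError
from .spectra import Spectrum, read_msp, write_msp

LIB_COLUMNS = ["name", "class", "ion", "polarity", "charge", "mz", "rt_min",
               "ccs_A2", "fraction", "provenance", "spectrum_ref"]


@dataclass
class LibraryEntry4D:
    """One species/ion form with its 4D descriptors."""

    name: str
    class_name: str
    ion_name: str
    polarity: str
    charge: int
    mz: float  # nan for placeholder (unidentified-ceramide) entries
    rt_min: float
    ccs_A2: float
    fraction: int
    provenance: str = "fixture"
    spectrum_ref: str = ""
    species: GSLSpecies | None = field(default=None, repr=False)
    spectrum: Spectrum | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.rt_min <= 0 or self.ccs_A2 <= 0:
            raise ValueError(f"{self.name}: rt and ccs must be positive")
        if self.fraction not in (1, 2):
            raise ValueError(f"{self.name}: fraction must be 1 or 2")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.name, self.ion_name, self.polarity)


class Library4D:
    """A named, versioned collection of 4D library entries."""

    def __init__(self, name: str, version: str = "1", entries=()):
        self.name = name
        self.version = version
        self._entries: list[LibraryEntry4D] = []
        self._index: dict[tuple, int] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: LibraryEntry4D) -> None:
        if entry.key in self._index:
            raise LibrarySchemaError(
                f"duplicate library entry {entry.key}", rows=[entry.key])
        self._index[entry.key] = len(self._entries)
        self._entries.append(entry)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __getitem__(self, i: int) -> LibraryEntry4D:
        return self._entries[i]

    def by_name(self, name: str) -> list[LibraryEntry4D]:
        return [e for e in self._entries if e.name == name]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self._entries:
            counts[e.class_name] = counts.get(e.class_name, 0) + 1
        return counts

    def series_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self._entries:
            try:
                series = chem.class_info(e.class_name).series
            except GSLError:
                series = "unknown"
            counts[series] = counts.get(series, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self._entries:
            rows.append({
                "name": e.name, "class": e.class_name, "ion": e.ion_name,
                "polarity": e.polarity, "charge": e.charge, "mz": e.mz,
                "rt_min": e.rt_min, "ccs_A2": e.ccs_A2, "fraction": e.fraction,
                "provenance": e.provenance, "spectrum_ref": e.spectrum_ref,
            })
        return pd.DataFrame(rows, columns=LIB_COLUMNS)


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------


def build_library(runs: list[list[dict]], name: str = "library",
                  provenance: str = "standard") -> Library4D:
    """Average replicate-run descriptors into one library.

    Each run is a list of per-species observations with keys ``name``,
    ``polarity``, ``rt_min``, ``ccs_A2`` and optional ``ion``, ``fraction``,
    ``ccs`` anchors.  RT and CCS become arithmetic means over the runs in
    which the species appears; m/z is the theoretical ion m/z.
    """
    grouped: dict[str, list[dict]] = {}
    for run in runs:
        for obs in run:
            grouped.setdefault(obs["name"], []).append(obs)
    lib = Library4D(name=name)
    for sp_name, observations in grouped.items():
        polarities = {o["polarity"] for o in observations}
        if len(polarities) > 1:
            raise GSLError(
                f"inconsistent polarity across runs for {sp_name}: {polarities}")
        polarity = polarities.pop()
        species = chem.parse_species_name(sp_name)
        ion_name = observations[0].get("ion") or chem.default_ion_type(
            species.class_name, polarity).name
        ion = chem.parse_ion(ion_name)
        lib.add(LibraryEntry4D(
            name=sp_name,
            class_name=species.class_name,
            ion_name=ion_name,
            polarity=polarity,
            charge=ion.charge,
            mz=chem.ion_mz(species, ion),
            rt_min=float(np.mean([o["rt_min"] for o in observations])),
            ccs_A2=float(np.mean([o["ccs_A2"] for o in observations])),
            fraction=int(observations[0].get("fraction",
                                             2 if polarity == "-" else 1)),
            provenance=provenance,
            species=species,
        ))
    return lib


# ---------------------------------------------------------------------------
# serum fixture (published species inventory of human serum)
# ---------------------------------------------------------------------------

# One row per (subclass, sphingoid base, acyl-carbon range, double-bond
# range, hydroxylation range): (class, base, cmin, cmax, dbmin, dbmax,
# hmin, hmax, n_species).  A base of None marks "unidentified sphingoid
# base" placeholder rows (count-only).
TABLE_ROWS: list[tuple] = [
    # gangliosides (129)
    ("GM3", "18:0;O2", 14, 22, 0, 0, 0, 0, 5),
    ("GM3", "18:1;O2", 10, 26, 0, 3, 0, 0, 37),
    ("GM3", "18:0;O3", 16, 22, 0, 0, 0, 0, 2),
    ("GM3", "18:1;O3", 10, 24, 0, 2, 0, 0, 22),
    ("GM2", "18:1;O2", 16, 18, 0, 1, 0, 0, 3),
    ("GM1", "18:1;O2", 16, 18, 0, 0, 0, 0, 2),
    ("GD3", "18:0;O2", 16, 16, 0, 0, 0, 0, 1),
    ("GD3", "18:1;O2", 14, 24, 0, 2, 0, 0, 15),
    ("GD3", "18:1;O3", 16, 16, 0, 0, 0, 0, 1),
    ("GD2", "18:1;O2", 16, 24, 0, 1, 0, 0, 4),
    ("GD1", "18:0;O2", 16, 16, 0, 0, 0, 0, 1),
    ("GD1", "18:1;O2", 14, 24, 0, 2, 0, 0, 15),
    ("GD1", "18:1;O3", 16, 18, 0, 0, 0, 0, 2),
    ("GT1b", "18:0;O2", 16, 16, 0, 0, 0, 0, 1),
    ("GT1b", "18:1;O2", 14, 24, 0, 2, 0, 0, 12),
    ("GQ1b", "18:1;O2", 16, 18, 0, 0, 0, 0, 2),
    ("OAc-GD1", "18:1;O2", 16, 18, 0, 1, 0, 0, 3),
    ("Fuc-GD1", "18:1;O2", 20, 20, 0, 0, 0, 0, 1),
    # sialylated neolacto-series (30)
    ("Neu5Ac-nLc4Cer", "18:1;O2", 14, 24, 0, 2, 0, 0, 10),
    ("Neu5Ac-nLc6Cer", "18:1;O2", 16, 24, 0, 2, 0, 0, 6),
    ("Neu5Ac-nLc8Cer", "18:1;O2", 16, 24, 0, 1, 0, 0, 3),
    ("Neu5Ac-nLc10Cer", "18:1;O2", 16, 16, 0, 0, 0, 0, 1),
    ("Neu5Ac-Fuc-nLc6Cer", "18:1;O2", 16, 18, 0, 1, 0, 0, 3),
    ("Neu5Ac-Fuc-nLc8Cer", "18:1;O2", 16, 24, 0, 1, 0, 0, 3),
    ("Neu5Ac-Fuc-nLc10Cer", "18:1;O2", 16, 16, 0, 0, 0, 0, 1),
    ("Neu5Ac-Fuc-nLc12Cer", "18:1;O2", 16, 16, 0, 0, 0, 0, 1),
    ("Neu5Ac-Fuc2-nLc10Cer", "18:1;O2", 16, 16, 0, 0, 0, 0, 1),
    ("Neu5Ac-Fuc2-nLc12Cer", "18:1;O2", 16, 16, 0, 0, 0, 0, 1),
    # neutral glycosphingolipids (145)
    ("HexCer", "16:1;O2", 18, 24, 0, 1, 0, 1, 8),
    ("HexCer", "17:1;O2", 24, 24, 0, 0, 0, 0, 1),
    ("HexCer", "18:1;O2", 16, 24, 0, 2, 0, 1, 19),
    ("HexCer", "18:2;O2", 16, 24, 0, 1, 0, 1, 13),
    ("HexCer", "18:0;O3", 16, 24, 0, 1, 0, 1, 3),
    ("HexCer", "18:0;O4", 24, 24, 1, 1, 0, 0, 1),
    ("Hex2Cer", "16:1;O2", 14, 24, 0, 2, 0, 1, 11),
    ("Hex2Cer", "16:2;O2", 16, 16, 0, 0, 0, 0, 1),
    ("Hex2Cer", "17:1;O2", 16, 24, 0, 1, 0, 0, 4),
    ("Hex2Cer", "17:2;O2", 16, 16, 0, 0, 0, 0, 1),
    ("Hex2Cer", "18:0;O2", 16, 16, 0, 0, 0, 0, 1),
    ("Hex2Cer", "18:1;O2", 12, 24, 0, 2, 0, 1, 19),
    ("Hex2Cer", "18:2;O2", 12, 24, 0, 2, 0, 1, 14),
    ("Hex2Cer", "18:1;O3", 16, 16, 0, 0, 0, 0, 1),
    ("Hex2Cer", None, 0, 0, 0, 0, 0, 0, 1),
    ("Hex3Cer", "16:1;O2", 12, 22, 0, 0, 0, 1, 6),
    ("Hex3Cer", "17:1;O2", 16, 18, 0, 0, 0, 0, 2),
    ("Hex3Cer", "18:0;O2", 16, 16, 0, 0, 0, 0, 1),
    ("Hex3Cer", "18:1;O2", 10, 24, 0, 2, 0, 1, 13),
    ("Hex3Cer", "18:2;O2", 12, 24, 0, 1, 0, 1, 11),
    ("Hex3Cer", None, 0, 0, 0, 0, 0, 0, 1),
    ("HexNAcHex3Cer", "16:1;O2", 16, 16, 0, 0, 0, 0, 1),
    ("HexNAcHex3Cer", "17:1;O2", 16, 16, 0, 0, 0, 0, 1),
    ("HexNAcHex3Cer", "18:1;O2", 14, 24, 0, 1, 0, 0, 5),
    ("HexNAcHex3Cer", "18:2;O2", 16, 22, 0, 0, 0, 0, 2),
    ("HexNAcHex3Cer", None, 0, 0, 0, 0, 0, 0, 2),
    ("HexNAcHex4Cer", "18:1;O2", 16, 16, 0, 0, 0, 0, 1),
    ("Fuc-HexNAcHex3Cer", "18:1;O2", 16, 16, 0, 0, 0, 0, 1),
    # sulfatides (72)
    ("SHexCer", "16:1;O2", 16, 24, 0, 1, 0, 1, 7),
    ("SHexCer", "17:1;O2", 16, 16, 0, 0, 0, 1, 2),
    ("SHexCer", "18:0;O2", 16, 16, 0, 0, 0, 1, 2),
    ("SHexCer", "18:1;O2", 14, 24, 0, 1, 0, 1, 17),
    ("SHexCer", "18:2;O2", 16, 24, 0, 1, 0, 1, 14),
    ("SHexCer", "16:0;O3", 18, 24, 0, 1, 0, 1, 3),
    ("SHexCer", "18:0;O3", 16, 24, 0, 1, 0, 1, 5),
    ("SHexCer", "18:1;O3", 16, 16, 0, 0, 1, 1, 1),
    ("SHexCer", "18:0;O4", 24, 24, 2, 2, 0, 0, 1),
    ("SHexCer", None, 0, 0, 0, 0, 0, 0, 6),
    ("SHex2Cer", "16:1;O2", 18, 18, 0, 0, 1, 1, 1),
    ("SHex2Cer", "18:1;O2", 16, 24, 0, 1, 0, 1, 5),
    ("SHex2Cer", "18:2;O2", 16, 24, 0, 1, 0, 0, 4),
    ("SHex2Cer", None, 0, 0, 0, 0, 0, 0, 4),
]

#: Measured CCS anchors (Å²) overriding the surrogate model.
ANCHOR_CCS = {
    ("GD1b 18:1;O2/18:0", "-"): 456.4,
    ("GD1 18:1;O2/18:0", "-"): 456.4,
}


def _enumerate_acyls(cmin, cmax, dbmin, dbmax, hmin, hmax, count):
    """Deterministic fill of a printed species count from a carbon range:
    even carbons ascending first, then odd, then extra double-bond and
    hydroxylation variants."""
    candidates = []
    for db in range(dbmin, dbmax + 1):
        for h in range(hmin, hmax + 1):
            for parity in (0, 1):
                for c in range(cmin, cmax + 1):
                    if c % 2 == parity:
                        candidates.append((parity, db, h, c))
    # evens across all (db, h) before odds, then by db, h, carbons
    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    if count > len(candidates):
        raise ValueError("species count exceeds enumerable combinations")
    return [(c, db, h) for _, db, h, c in candidates[:count]]


def _surrogate_rt_ccs(species: GSLSpecies, charge: int) -> tuple[float, float]:
    """Monotone surrogate descriptors: RT rises with acyl-chain carbons and
    falls with unsaturation and glycan size; CCS rises with glycan size and
    chain length."""
    cer = species.ceramide
    c_total = cer.base.carbons + cer.acyl.carbons
    db_total = cer.base.double_bonds + cer.acyl.double_bonds
    oh_total = (cer.base.oxygens - 2) + cer.acyl.hydroxyls
    nglyc = species.glycan.total_monosaccharides + species.glycan.sulfate
    # chain extension: linear (neolacto-type) glycans are more elongated
    # than branched isomers of the same composition, so TIMS resolves them
    depths = {}
    for i, node in enumerate(species.topology):
        depths[i] = 1 + (depths[node.parent] if node.parent >= 0 else 0)
    depth = max(depths.values(), default=0)
    rt = 16.0 + 0.30 * (c_total - 34) - 0.55 * db_total - 0.35 * oh_total \
        - 0.85 * nglyc
    rt = max(rt, 0.5)
    ccs = (180.0 + 26.0 * nglyc + 8.0 * depth + 2.6 * (c_total - 34)
           - 1.4 * db_total) / math.sqrt(charge) * (1.25 if charge > 1 else 1.0)
    return round(rt, 3), round(ccs, 2)


def serum_fixture() -> Library4D:
    """The packaged human-serum 4D library fixture (376 entries)."""
    lib = Library4D(name="4D-serum-fixture", version="1")
    placeholder_counter: dict[str, int] = {}
    for row in TABLE_ROWS:
        cls, base_str, cmin, cmax, dbmin, dbmax, hmin, hmax, count = row
        info = chem.class_info(cls)
        sialylated = info.series in ("ganglio", "neolacto")
        polarity = "-" if sialylated else "+"
        fraction = 2 if sialylated else 1
        ion = chem.default_ion_type(cls, polarity)
        if base_str is None:
            for _ in range(count):
                placeholder_counter[cls] = placeholder_counter.get(cls, 0) + 1
                k = placeholder_counter[cls]
                lib.add(LibraryEntry4D(
                    name=f"{cls} unidentified-{k}",
                    class_name=cls, ion_name=ion.name, polarity=polarity,
                    charge=ion.charge, mz=float("nan"),
                    rt_min=10.0 + 0.1 * k, ccs_A2=200.0 + k,
                    fraction=fraction, provenance="fixture",
                ))
            continue
        bc, bd, bo = _parse_base(base_str)
        for c, db, h in _enumerate_acyls(cmin, cmax, dbmin, dbmax, hmin, hmax, count):
            cer = Ceramide(SphingoidBase(bc, bd, bo), FattyAcyl(c, db, h))
            species = chem.make_species(cls, cer)
            rt, ccs = _surrogate_rt_ccs(species, ion.charge)
            name = species.name
            ccs = ANCHOR_CCS.get((name, polarity), ccs)
            lib.add(LibraryEntry4D(
                name=name, class_name=cls, ion_name=ion.name,
                polarity=polarity, charge=ion.charge,
                mz=chem.ion_mz(species, ion), rt_min=rt, ccs_A2=ccs,
                fraction=fraction, provenance="fixture", species=species,
            ))
    return lib


def _parse_base(text: str) -> tuple[int, int, int]:
    cd, oxy = text.split(";O")
    c, d = cd.split(":")
    return int(c), int(d), int(oxy)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_library(lib: Library4D, path: str | Path) -> None:
    """Write TSV (columns: LIB_COLUMNS) or JSON mirror by extension; a
    sibling ``<stem>.msp`` carries reference spectra if any entry has one."""
    path = Path(path)
    frame = lib.to_frame()
    spectra = []
    for e in lib:
        if e.spectrum is not None:
            ref = e.spectrum_ref or f"{e.name} {e.ion_name}"
            e.spectrum_ref = ref
            e.spectrum.title = ref
            spectra.append(e.spectrum)
    frame = lib.to_frame()
    if path.suffix.lower() == ".json":
        payload = {"name": lib.name, "version": lib.version,
                   "entries": frame.where(pd.notna(frame), None).to_dict("records")}
        path.write_text(json.dumps(payload, indent=1))
    else:
        with open(path, "w") as fh:
            fh.write(f"# library={lib.name} version={lib.version}\n")
            frame.to_csv(fh, sep="\t", index=False, na_rep="")
    if spectra:
        write_msp(spectra, path.with_suffix(".msp"))


def load_library(path: str | Path) -> Library4D:
    """Load a TSV or JSON library; re-attaches MSP spectra when present.

    Schema violations raise :class:`LibrarySchemaError` listing the
    offending rows.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        frame = pd.DataFrame(payload["entries"], columns=LIB_COLUMNS)
        name, version = payload.get("name", path.stem), str(payload.get("version", "1"))
    else:
        with open(path) as fh:
            header = fh.readline()
            name, version = path.stem, "1"
            if header.startswith("#"):
                meta = dict(tok.split("=", 1) for tok in header[1:].split())
                name = meta.get("library", name)
                version = meta.get("version", version)
                frame = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                frame = pd.read_csv(fh, sep="\t")
    missing = [c for c in LIB_COLUMNS if c not in frame.columns]
    if missing:
        raise LibrarySchemaError(f"missing columns: {missing}")
    bad = frame[(frame["polarity"].isin(["+", "-"]) == False)  # noqa: E712
                | (frame["fraction"].isin([1, 2]) == False)]  # noqa: E712
    if len(bad):
        raise LibrarySchemaError("invalid polarity/fraction values",
                                 rows=bad.index.tolist())
    spectra_by_ref: dict[str, Spectrum] = {}
    msp_path = path.with_suffix(".msp")
    if msp_path.exists():
        for sp in read_msp(msp_path):
            spectra_by_ref[sp.title] = sp
    lib = Library4D(name=name, version=version)
    for idx, row in frame.iterrows():
        try:
            species = chem.parse_species_name(row["name"])
        except GSLError:
            species = None
        ref = "" if pd.isna(row["spectrum_ref"]) else str(row["spectrum_ref"])
        try:
            lib.add(LibraryEntry4D(
                name=row["name"], class_name=row["class"],
                ion_name=row["ion"], polarity=row["polarity"],
                charge=int(row["charge"]),
                mz=float(row["mz"]) if pd.notna(row["mz"]) else float("nan"),
                rt_min=float(row["rt_min"]), ccs_A2=float(row["ccs_A2"]),
                fraction=int(row["fraction"]), provenance=str(row["provenance"]),
                spectrum_ref=ref, species=species,
                spectrum=spectra_by_ref.get(ref),
            ))
        except LibrarySchemaError as err:
            raise LibrarySchemaError(str(err), rows=[int(idx)]) from None
    return lib
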