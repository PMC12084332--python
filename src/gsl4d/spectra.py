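"""MS/MS spectrum container and MGF/MSP readers/writers.

MGF goes through :mod:`pyteomics.mgf` (``PEPMASS`` carries the precursor
m/z).  MSP is the plain NIST text dialect (``Name:`` / ``PrecursorMZ:`` /
``Num Peaks:`` followed by ``mz intensity`` pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import mgf as ptmgf


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    charge: int | None = None
    polarity: str | None = None  # "+" | "-" | None
    title: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> np.ndarray:
        return np.column_stack([self.mz, self.intensity])


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra = []
    with ptmgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            precursor = float(pepmass[0]) if pepmass else None
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            spectra.append(Spectrum(
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                precursor_mz=precursor,
                charge=charge,
                title=str(params.get("title", "")),
            ))
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    entries = []
    for i, sp in enumerate(spectra):
        params = {"title": sp.title or f"spectrum_{i}"}
        if sp.precursor_mz is not None:
            params["pepmass"] = sp.precursor_mz
        if sp.charge is not None:
            params["charge"] = sp.charge
        entries.append({
            "m/z array": sp.mz,
            "intensity array": sp.intensity,
            "params": params,
        })
    ptmgf.write(entries, str(path), file_mode="w")


def read_msp(path: str | Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    name = ""
    precursor: float | None = None
    meta: dict = {}
    mzs: list[float] = []
    ints: list[float] = []

    def flush():
        nonlocal name, precursor, meta, mzs, ints
        if name or mzs:
            spectra.append(Spectrum(
                mz=np.array(mzs), intensity=np.array(ints),
                precursor_mz=precursor, title=name, metadata=dict(meta),
            ))
        name, precursor, meta, mzs, ints = "", None, {}, [], []

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            flush()
            continue
        if ":" in line and not line[0].isdigit():
            key, _, value = line.partition(":")
            key = key.strip().lower()
            value = value.strip()
            if key == "name":
                name = value
            elif key in ("precursormz", "precursor_mz"):
                precursor = float(value)
            elif key == "num peaks":
                pass
            else:
                meta[key] = value
        else:
            parts = line.replace("\t", " ").split()
            mzs.append(float(parts[0]))
            ints.append(float(parts[1]) if len(parts) > 1 else 1.0)
    flush()
    return spectra


def write_msp(spectra: list[Spectrum], path: str | Path) -> None:
    lines: list[str] = []
    for i, sp in enumerate(spectra):
        lines.append(f"Name: {sp.title or f'spectrum_{i}'}")
        if sp.precursor_mz is not None:
            lines.append(f"PrecursorMZ: {sp.precursor_mz:.4f}")
        for key, value in sp.metadata.items():
            lines.append(f"{key}: {value}")
        lines.append(f"Num Peaks: {len(sp)}")
        for m, inten in zip(sp.mz, sp.intensity):
            lines.append(f"{m:.4f} {inten:.1f}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
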