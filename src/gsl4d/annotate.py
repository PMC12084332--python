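"""Tolerance-window matching of LC-TIMS-MS features against a 4D library.

A feature matches a library entry when every *active* window passes: m/z
always (window in mDa), RT and CCS when the descriptor is present on both
sides, and the MS/MS score when both query and reference spectra exist.
Candidates are ranked by a composite score that weights the normalized
descriptor deltas and the spectral score, with mass carrying the largest
weight; ties break deterministically (smaller |dCCS|, then |dmz|, then
name).  Features matching no entry are reported as "unknown".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fragments
from .fragments import DiagnosticFlagSet
from .library4d import Library4D, LibraryEntry4D
from .spectra import Spectrum, read_mgf

FEATURE_COLUMNS = ["sample_id", "fraction", "polarity", "mz", "z", "rt_min",
                   "ccs_A2", "area", "spectrum_id"]


@dataclass
class ToleranceConfig:
    """Matching windows; defaults sit inside the validated working ranges
    (m/z 2-5 mDa, RT 0.1-0.5 min, CCS 0.1-2.0 %, MS/MS score 500-900)."""

    mz_mDa: float = 5.0
    rt_min: float = 0.5
    ccs_pct: float = 2.0
    msms_score_min: float = 500.0
    msigma: float | None = None  # accepted for config compatibility; unused

    def __post_init__(self):
        if min(self.mz_mDa, self.rt_min, self.ccs_pct, self.msms_score_min) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Feature:
    """One detected feature (one sample, one fraction, one polarity)."""

    sample_id: str
    fraction: int
    polarity: str
    mz: float
    charge: int
    rt_min: float | None = None
    ccs_A2: float | None = None
    area: float = 0.0
    spectrum_id: str = ""
    spectrum: Spectrum | None = field(default=None, repr=False)


@dataclass
class Annotation:
    """One candidate assignment of a library entry to a feature."""

    feature: Feature
    entry: LibraryEntry4D | None
    delta_mz_mDa: float = math.nan
    delta_rt_min: float = math.nan
    delta_ccs_pct: float = math.nan
    msms_score: float | None = None
    score: float = 0.0
    rank: int = 0
    status: str = "unknown"  # annotated | partial-evidence | unknown
    flags: DiagnosticFlagSet = field(default_factory=DiagnosticFlagSet)

    @property
    def name(self) -> str:
        return self.entry.name if self.entry is not None else "unknown"


def spectral_score(query: Spectrum, reference: Spectrum,
                   fragment_tol_mDa: float = fragments.DEFAULT_FRAGMENT_TOL_MDA,
                   ) -> float:
    """1000 x cosine similarity over tolerance-matched peak pairs.

    Greedy nearest-m/z pairing within tolerance; unmatched peaks on either
    side contribute only to the norms.  Symmetric and invariant to
    intensity scaling.  Empty input scores 0 with a warning.
    """
    if len(query) == 0 or len(reference) == 0:
        warnings.warn("spectral_score: empty spectrum scores 0")
        return 0.0
    tol = fragment_tol_mDa / 1000.0
    used_ref: set[int] = set()
    dot = 0.0
    for qm, qi in zip(query.mz, query.intensity):
        deltas = np.abs(reference.mz - qm)
        order = np.argsort(deltas)
        for j in order:
            if deltas[j] > tol:
                break
            if j not in used_ref:
                used_ref.add(int(j))
                dot += qi * reference.intensity[j]
                break
    norm = float(np.linalg.norm(query.intensity) * np.linalg.norm(reference.intensity))
    if norm == 0:
        return 0.0
    return 1000.0 * dot / norm


def _entry_deltas(feature: Feature, entry: LibraryEntry4D):
    dmz = (feature.mz - entry.mz) * 1000.0
    drt = (feature.rt_min - entry.rt_min) if feature.rt_min is not None else None
    dccs = (100.0 * (feature.ccs_A2 - entry.ccs_A2) / entry.ccs_A2
            if feature.ccs_A2 is not None else None)
    return dmz, drt, dccs


def match_features(features: list[Feature], library: Library4D,
                   tol: ToleranceConfig | None = None,
                   fragment_tol_mDa: float = fragments.DEFAULT_FRAGMENT_TOL_MDA,
                   ) -> list[Annotation]:
    """Annotate each feature against the library; one Annotation per
    (feature, passing entry), plus an "unknown" record for unmatched
    features.  rank 1 is the best composite score for that feature."""
    tol = tol or ToleranceConfig()
    out: list[Annotation] = []
    for feature in features:
        flags = DiagnosticFlagSet()
        if feature.spectrum is not None:
            flags = fragments.classify_spectrum(feature.spectrum, feature.polarity,
                                                fragment_tol_mDa)
        candidates: list[Annotation] = []
        for entry in library:
            if entry.polarity != feature.polarity or math.isnan(entry.mz):
                continue
            dmz, drt, dccs = _entry_deltas(feature, entry)
            if abs(dmz) > tol.mz_mDa:
                continue
            if drt is not None and abs(drt) > tol.rt_min:
                continue
            if dccs is not None and abs(dccs) > tol.ccs_pct:
                continue
            msms = None
            if feature.spectrum is not None and entry.spectrum is not None:
                msms = spectral_score(feature.spectrum, entry.spectrum,
                                      fragment_tol_mDa)
                if msms < tol.msms_score_min:
                    continue
            # composite: weighted normalized agreement, missing dimensions
            # renormalized; mass is the strongest evidence
            terms = [(0.4, 1.0 - abs(dmz) / tol.mz_mDa)]
            if drt is not None:
                terms.append((0.2, 1.0 - abs(drt) / tol.rt_min))
            if dccs is not None:
                terms.append((0.2, 1.0 - abs(dccs) / tol.ccs_pct))
            if msms is not None:
                terms.append((0.2, msms / 1000.0))
            wsum = sum(w for w, _ in terms)
            score = sum(w * v for w, v in terms) / wsum
            partial = feature.rt_min is None or feature.ccs_A2 is None
            candidates.append(Annotation(
                feature=feature, entry=entry, delta_mz_mDa=dmz,
                delta_rt_min=math.nan if drt is None else drt,
                delta_ccs_pct=math.nan if dccs is None else dccs,
                msms_score=msms, score=score,
                status="partial-evidence" if partial else "annotated",
                flags=flags,
            ))
        if not candidates:
            out.append(Annotation(feature=feature, entry=None, flags=flags))
            continue
        candidates.sort(key=lambda a: (
            -a.score,
            abs(a.delta_ccs_pct) if not math.isnan(a.delta_ccs_pct) else math.inf,
            abs(a.delta_mz_mDa),
            a.entry.name,
        ))
        for i, cand in enumerate(candidates, start=1):
            cand.rank = i
        out.extend(candidates)
    return out


def screen_candidates(features: list[Feature], polarity: str,
                      mode: str = "sialylated",
                      fragment_tol_mDa: float = fragments.DEFAULT_FRAGMENT_TOL_MDA,
                      ) -> list[Feature]:
    """Diagnostic-ion pre-filter applied before annotation.

    ``sialylated`` keeps features whose spectra carry the Neu5Ac B ion
    (nominal 290) in negative mode, or the dehydrated Neu5Ac oxonium
    (nominal 274) in positive mode; ``neutral`` keeps features showing a
    one-hexose (162) or lactose (342) neutral loss.  Features without a
    spectrum are dropped.
    """
    kept = []
    for feature in features:
        if feature.spectrum is None:
            continue
        flags = fragments.classify_spectrum(feature.spectrum, polarity,
                                            fragment_tol_mDa)
        if mode == "sialylated":
            ok = flags.sialylated_neg if polarity == "-" else flags.sialylated_pos
        elif mode == "neutral":
            ok = flags.hex_loss or flags.hex2_loss
        else:
            raise ValueError(f"unknown screening mode {mode!r}")
        if ok:
            kept.append(feature)
    return kept


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------


def read_features(path: str | Path, mgf: str | Path | None = None) -> list[Feature]:
    """Read a feature CSV; attach spectra from an MGF by spectrum_id/title."""
    frame = pd.read_csv(path)
    spectra: dict[str, Spectrum] = {}
    if mgf is not None:
        for sp in read_mgf(mgf):
            spectra[sp.title] = sp
    features = []
    for _, row in frame.iterrows():
        sid = "" if "spectrum_id" not in row or pd.isna(row.get("spectrum_id")) \
            else str(row["spectrum_id"])
        features.append(Feature(
            sample_id=str(row["sample_id"]), fraction=int(row["fraction"]),
            polarity=str(row["polarity"]), mz=float(row["mz"]),
            charge=int(row["z"]),
            rt_min=float(row["rt_min"]) if pd.notna(row.get("rt_min")) else None,
            ccs_A2=float(row["ccs_A2"]) if pd.notna(row.get("ccs_A2")) else None,
            area=float(row.get("area", 0.0)),
            spectrum_id=sid, spectrum=spectra.get(sid),
        ))
    return features


def annotations_to_frame(annotations: list[Annotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        f = a.feature
        rows.append({
            "sample_id": f.sample_id, "fraction": f.fraction,
            "polarity": f.polarity, "mz": f.mz, "z": f.charge,
            "rt_min": f.rt_min, "ccs_A2": f.ccs_A2, "area": f.area,
            "spectrum_id": f.spectrum_id, "name": a.name,
            "delta_mz_mDa": a.delta_mz_mDa, "delta_rt_min": a.delta_rt_min,
            "delta_ccs_pct": a.delta_ccs_pct, "msms_score": a.msms_score,
            "score": a.score, "rank": a.rank, "status": a.status,
            "flags": ";".join(k for k, v in a.flags.as_dict().items() if v),
        })
    return pd.DataFrame(rows)
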