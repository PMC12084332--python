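"""Partition-corrected semi-quantification for two-fraction serum extracts.

Deuterated internal standards (ISTDs) spiked before extraction partition
between the neutral/sulfatide fraction (1) and the sialylated fraction
(2).  The fraction-2 partition percentage of an ISTD is

    A = 100 * area_f2 / (area_f1 + area_f2)

Strategy I corrects each sample with the cohort-average partition Abar of
reference extracts (only fraction 2 need be measured per sample); Strategy
II uses each sample's own partition A (both fractions measured).  In both,
the ISTD amount present in fraction 2 is B = spiked_nmol * A/100 and the
analyte amount is C = (analyte area / ISTD area) * B, with areas taken
from fraction 2.  The combined strategy applies a base strategy to all
samples and recomputes samples whose ISTD partitions are outliers with
the alternate strategy.

Concentrations are reported as ng per µL serum using the species'
monoisotopic mass and the extracted serum volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .errors import GSLError

#: Fraction-2 ISTD-class assignments (the cross-class map validated as the
#: best-performing "sub-strategy 3").
SUBSTRATEGY3_ISTD_MAP: dict[str, str] = {
    "GM1": "GM1 18:1;O2/18:0-d5",
    "GM2": "GM2 18:1;O2/16:0-d9",
    "GM3": "GM3 18:1;O2/18:0-d5",
    "GD3": "GD3 18:1;O2/18:0-d3",
    "GD2": "GD3 18:1;O2/18:0-d3",
    "GD1": "GD3 18:1;O2/18:0-d3",
    "GT1b": "GD3 18:1;O2/18:0-d3",
    "GQ1b": "GD3 18:1;O2/18:0-d3",
}

#: ISTD spiking scheme: 12.5 µL of a 20 µg/mL mixture per sample.
DEFAULT_SPIKE_VOLUME_UL = 12.5
DEFAULT_SPIKE_CONC_UG_PER_ML = 20.0


def spiked_amount_nmol(volume_uL: float, conc_ug_per_mL: float,
                       molecular_mass: float) -> float:
    """nmol of ISTD spiked: (volume x concentration) mass over molar mass."""
    ug = volume_uL * conc_ug_per_mL / 1000.0
    return ug * 1000.0 / molecular_mass


@dataclass
class QuantConfig:
    """Configuration of the semi-quantification pipeline."""

    istd_map: dict[str, str] = field(
        default_factory=lambda: dict(SUBSTRATEGY3_ISTD_MAP))
    spiked_nmol: dict[str, float] = field(default_factory=dict)
    strategy: str = "combined"
    cv_threshold_pct: float = 35.0
    serum_volume_uL: float = 300.0
    combined_base: str = "I"  # base strategy; the other corrects outliers
    outlier_k_mad: float = 3.5
    outlier_abs_pct: float = 15.0

    def __post_init__(self):
        if not self.spiked_nmol:
            self.spiked_nmol = {
                istd: spiked_amount_nmol(
                    DEFAULT_SPIKE_VOLUME_UL, DEFAULT_SPIKE_CONC_UG_PER_ML,
                    chem.species_mass(chem.parse_species_name(istd)))
                for istd in set(self.istd_map.values())
            }
        for istd, amount in self.spiked_nmol.items():
            if amount <= 0:
                raise ValueError(f"non-positive spiked amount for {istd}")
        if self.combined_base not in ("I", "II"):
            raise ValueError("combined_base must be 'I' or 'II'")

    @property
    def istd_names(self) -> list[str]:
        return sorted(set(self.istd_map.values()))


def partition_percent(area_f1: float, area_f2: float) -> float:
    """Fraction-2 partition percentage A; nan when both areas are 0."""
    total = area_f1 + area_f2
    if total <= 0:
        return math.nan
    return min(max(100.0 * area_f2 / total, 0.0), 100.0)


def partition_table(areas: pd.DataFrame, istd_names: list[str]) -> pd.DataFrame:
    """Per-(ISTD, sample) partition records from a two-fraction area table.

    ``areas`` columns: sample_id, species, fraction, area.
    Returns columns: istd, sample_id, area_f1, area_f2, A_pct.
    """
    rows = []
    sub = areas[areas["species"].isin(istd_names)]
    for (istd, sample), grp in sub.groupby(["species", "sample_id"], sort=True):
        a1 = float(grp.loc[grp["fraction"] == 1, "area"].sum())
        a2 = float(grp.loc[grp["fraction"] == 2, "area"].sum())
        rows.append({"istd": istd, "sample_id": sample, "area_f1": a1,
                     "area_f2": a2, "A_pct": partition_percent(a1, a2)})
    return pd.DataFrame(rows, columns=["istd", "sample_id", "area_f1",
                                       "area_f2", "A_pct"])


def average_partition(partitions: pd.DataFrame) -> dict[str, float]:
    """Cohort average partition Abar per ISTD (mean over samples)."""
    return partitions.groupby("istd")["A_pct"].mean().to_dict()


def _species_class(name: str) -> str | None:
    try:
        return chem.parse_species_name(name).class_name
    except GSLError:
        return None


def _species_mass_or_nan(name: str) -> float:
    try:
        return chem.species_mass(chem.parse_species_name(name))
    except (GSLError, ValueError):
        return math.nan


def _quantify_fraction2(f2: pd.DataFrame, a_by_sample_istd, config: QuantConfig,
                        strategy: str) -> pd.DataFrame:
    """Shared Eq. core: B = spiked x A/100, C = ratio x B, per sample."""
    records = []
    for sample, grp in f2.groupby("sample_id", sort=True):
        istd_areas = {
            istd: float(grp.loc[grp["species"] == istd, "area"].sum())
            for istd in config.istd_names
        }
        for _, row in grp.iterrows():
            species = row["species"]
            if species in config.istd_names:
                continue
            cls = _species_class(species)
            rec = {"sample_id": sample, "species": species, "class": cls,
                   "istd": None, "A_pct": math.nan, "B_nmol": math.nan,
                   "C_nmol": math.nan, "conc_ng_per_uL": math.nan,
                   "strategy": strategy, "corrected": False, "status": "ok"}
            istd = config.istd_map.get(cls) if cls else None
            if istd is None:
                rec["status"] = "unmapped_class"
                records.append(rec)
                continue
            rec["istd"] = istd
            a_pct = a_by_sample_istd(sample, istd)
            istd_area = istd_areas.get(istd, 0.0)
            if not istd_area or math.isnan(a_pct):
                rec["status"] = "missing_istd"
                records.append(rec)
                continue
            b = config.spiked_nmol[istd] * a_pct / 100.0
            c = float(row["area"]) / istd_area * b
            mw = _species_mass_or_nan(species)
            rec.update(A_pct=a_pct, B_nmol=b, C_nmol=c,
                       conc_ng_per_uL=c * mw / config.serum_volume_uL)
            records.append(rec)
    return pd.DataFrame(records)


def quantify_strategy_I(f2_areas: pd.DataFrame, abar: dict[str, float],
                        config: QuantConfig) -> pd.DataFrame:
    """Strategy I: cohort-average partition Abar; needs only fraction 2."""
    f2 = f2_areas[f2_areas.get("fraction", 2) == 2] \
        if "fraction" in f2_areas.columns else f2_areas
    needed = {
        config.istd_map[cls]
        for cls in {_species_class(s) for s in f2["species"].unique()}
        if cls in config.istd_map
    }
    missing = sorted(istd for istd in needed if istd not in abar)
    if missing:
        raise GSLError(f"no cohort-average partition for ISTDs: {missing}")
    return _quantify_fraction2(f2, lambda s, istd: abar[istd], config, "I")


def quantify_strategy_II(areas: pd.DataFrame, config: QuantConfig) -> pd.DataFrame:
    """Strategy II: per-sample partition; needs both fractions per sample."""
    partitions = partition_table(areas, config.istd_names)
    lookup = {(r["sample_id"], r["istd"]): r["A_pct"]
              for _, r in partitions.iterrows()}
    f2 = areas[areas["fraction"] == 2]
    return _quantify_fraction2(
        f2, lambda s, istd: lookup.get((s, istd), math.nan), config, "II")


def detect_partition_outliers(partitions: pd.DataFrame,
                              k_mad: float = 3.5,
                              abs_pct: float = 15.0) -> set[str]:
    """Samples whose partition of any ISTD deviates from the cohort median
    by more than k x MAD or by more than ``abs_pct`` percentage points."""
    samples = partitions["sample_id"].unique()
    if len(samples) < 3:
        warnings.warn("fewer than 3 samples: outlier detection skipped")
        return set()
    flagged: set[str] = set()
    for istd, grp in partitions.groupby("istd"):
        a = grp["A_pct"].to_numpy(dtype=float)
        med = float(np.nanmedian(a))
        mad = float(np.nanmedian(np.abs(a - med)))
        for sample, val in zip(grp["sample_id"], a):
            if math.isnan(val):
                continue
            dev = abs(val - med)
            if (mad > 0 and dev > k_mad * mad) or dev > abs_pct:
                flagged.add(sample)
    return flagged


def quantify_combined(areas: pd.DataFrame, config: QuantConfig,
                      abar: dict[str, float] | None = None) -> pd.DataFrame:
    """Base strategy for all samples; partition outliers recomputed with
    the alternate strategy and marked ``corrected``.

    ``abar`` defaults to the cohort average over the supplied samples.
    """
    partitions = partition_table(areas, config.istd_names)
    if abar is None:
        abar = average_partition(partitions)
    base, alt = (("I", "II") if config.combined_base == "I" else ("II", "I"))

    def run(strategy: str, frame: pd.DataFrame) -> pd.DataFrame:
        if strategy == "I":
            return quantify_strategy_I(frame[frame["fraction"] == 2], abar, config)
        return quantify_strategy_II(frame, config)

    result = run(base, areas)
    flagged = detect_partition_outliers(partitions, config.outlier_k_mad,
                                        config.outlier_abs_pct)
    if flagged:
        redo = run(alt, areas[areas["sample_id"].isin(flagged)])
        redo = redo.assign(corrected=True)
        result = pd.concat(
            [result[~result["sample_id"].isin(flagged)], redo],
            ignore_index=True,
        ).sort_values(["sample_id", "species"], ignore_index=True)
    return result


def cv_table(concentrations: pd.DataFrame,
             threshold_pct: float = 35.0,
             value_col: str = "C_nmol") -> tuple[pd.DataFrame, dict]:
    """Per-species CV% over replicate samples and the share below threshold.

    CV uses the sample standard deviation (ddof=1).  Species whose mean is
    zero (or with <2 replicates) are excluded and counted.
    """
    rows = []
    excluded = 0
    for species, grp in concentrations.groupby("species", sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2 or np.mean(vals) == 0:
            excluded += 1
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        rows.append({"species": species, "n": len(vals), "mean": mean,
                     "sd": sd, "cv_pct": 100.0 * sd / mean})
    table = pd.DataFrame(rows, columns=["species", "n", "mean", "sd", "cv_pct"])
    summary = {
        "n_species": len(table),
        "n_excluded": excluded,
        "threshold_pct": threshold_pct,
        "pct_below": (100.0 * float((table["cv_pct"] < threshold_pct).mean())
                      if len(table) else math.nan),
    }
    return table, summary


def normalize_fraction1(areas: pd.DataFrame, istd_name: str) -> pd.DataFrame:
    """Fraction-1 read-out: analyte areas normalized to one ISTD's area
    per sample (unitless ratios; used for neutral GSLs and sulfatides)."""
    records = []
    f1 = areas[areas["fraction"] == 1] if "fraction" in areas.columns else areas
    for sample, grp in f1.groupby("sample_id", sort=True):
        istd_area = float(grp.loc[grp["species"] == istd_name, "area"].sum())
        for _, row in grp.iterrows():
            if row["species"] == istd_name:
                continue
            ok = istd_area > 0
            records.append({
                "sample_id": sample, "species": row["species"],
                "norm_abundance": (float(row["area"]) / istd_area if ok else math.nan),
                "status": "ok" if ok else "missing_istd",
            })
    return pd.DataFrame(records)
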