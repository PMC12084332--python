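"""Seeded generators for every upstream input of the pipeline.

The cohort generator emulates the two-fraction serum extraction design:
deuterated ISTDs spiked at known amounts partition between fractions with
the reproducibility measured for reference serum (fraction-2 means/CVs of
78.70/5.59, 80.40/2.94, 75.99/3.95 and 70.35/7.40 %CV for GD3-d3, GM1-d5,
GM2-d9 and GM3-d5 respectively); species abundances are lognormal across
samples; peak areas carry multiplicative lognormal noise (areas are
positive and CVs are quoted as percentages); partition draws are normal,
truncated to (0, 100).  Response factors default to 1 (the
semi-quantification assumption that an analyte responds like its ISTD).

Feature descriptors are the fixture-library values plus Gaussian jitter;
a truth file records every drawn quantity so recovery can be asserted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem, fragments, library4d, quantify
from .annotate import Feature
from .spectra import Spectrum

#: Fraction-2 partition truth (mean %, CV %) per ISTD in reference serum.
DEFAULT_PARTITION_TRUTH: dict[str, tuple[float, float]] = {
    "GD3 18:1;O2/18:0-d3": (78.70, 5.59),
    "GM1 18:1;O2/18:0-d5": (80.40, 2.94),
    "GM2 18:1;O2/16:0-d9": (75.99, 3.95),
    "GM3 18:1;O2/18:0-d5": (70.35, 7.40),
}


def default_species(n: int = 24) -> list[str]:
    """A deterministic sialylated subset of the serum fixture covering the
    ISTD-mapped classes (round-robin across classes)."""
    lib = library4d.serum_fixture()
    by_class: dict[str, list[str]] = {}
    for e in lib:
        if e.class_name in quantify.SUBSTRATEGY3_ISTD_MAP and e.species is not None:
            by_class.setdefault(e.class_name, []).append(e.name)
    picked: list[str] = []
    i = 0
    while len(picked) < n:
        advanced = False
        for cls in sorted(by_class):
            names = by_class[cls]
            if i < len(names):
                picked.append(names[i])
                advanced = True
                if len(picked) == n:
                    break
        if not advanced:
            break
        i += 1
    return picked


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    seed: int = 0
    n_samples: int = 6
    species: list[str] = field(default_factory=default_species)
    conc_median_nmol: float = 0.05
    conc_cv_pct: float = 50.0
    conc_law: dict[str, tuple[float, float]] = field(default_factory=dict)
    partition_truth: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARTITION_TRUTH))
    area_cv_pct: float = 7.0
    istd_total_area: float = 1.0e6
    response_factor: dict[str, float] = field(default_factory=dict)
    group_effect: dict[str, float] = field(default_factory=dict)
    n_case: int = 0  # last n_case samples form the "case" group
    sigma_mz_mDa: float = 0.0
    sigma_rt_min: float = 0.0
    sigma_ccs_pct: float = 0.0

    def __post_init__(self):
        for istd, (mean, cv) in self.partition_truth.items():
            if not (0 < mean < 100) or cv < 0:
                raise ValueError(f"bad partition truth for {istd}")
        if self.area_cv_pct < 0 or self.conc_cv_pct < 0:
            raise ValueError("CVs must be non-negative")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    def group_of(self, sample_id: str) -> str:
        idx = int(sample_id[1:]) - 1
        return "case" if idx >= self.n_samples - self.n_case else "control"


def _lognormal_factor(rng: np.random.Generator, cv_pct: float, size=None):
    """Unit-median multiplicative noise with the requested CV."""
    if cv_pct <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + (cv_pct / 100.0) ** 2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd <= 0:
        return mean
    for _ in range(1000):
        val = rng.normal(mean, sd)
        if lo < val < hi:
            return float(val)
    return float(min(max(mean, lo + 1e-9), hi - 1e-9))


def simulate_cohort(config: SimConfig) -> dict:
    """Generate a two-fraction cohort: area table, per-fraction feature
    tables with 4D descriptors, and the ground-truth record."""
    rng = np.random.default_rng(config.seed)
    lib = library4d.serum_fixture()
    entries = {e.name: e for e in lib}
    quant_cfg = quantify.QuantConfig()
    samples = config.sample_ids()

    area_rows: list[dict] = []
    features_f1: list[Feature] = []
    features_f2: list[Feature] = []
    truth_partition: dict[str, dict[str, float]] = {}
    truth_conc: dict[str, dict[str, float]] = {}

    partition_by_sample: dict[tuple[str, str], float] = {}
    for istd, (mean, cv) in config.partition_truth.items():
        truth_partition[istd] = {}
        sd = mean * cv / 100.0
        for sample in samples:
            a = _truncated_normal(rng, mean, sd, 0.0, 100.0)
            truth_partition[istd][sample] = a
            partition_by_sample[(sample, istd)] = a
            noise = _lognormal_factor(rng, config.area_cv_pct, 2)
            a2 = config.istd_total_area * a / 100.0 * noise[0]
            a1 = config.istd_total_area * (1.0 - a / 100.0) * noise[1]
            area_rows.append({"sample_id": sample, "species": istd,
                              "fraction": 1, "area": a1})
            area_rows.append({"sample_id": sample, "species": istd,
                              "fraction": 2, "area": a2})

    for name in config.species:
        truth_conc[name] = {}
        cls = chem.parse_species_name(name).class_name
        istd = quant_cfg.istd_map.get(cls)
        if istd is None or istd not in config.partition_truth:
            raise ValueError(f"species {name}: class {cls} has no ISTD with "
                             f"partition truth")
        median, cv = config.conc_law.get(
            name, (config.conc_median_nmol, config.conc_cv_pct))
        rf = config.response_factor.get(cls, 1.0)
        fold = config.group_effect.get(name, 1.0)
        entry = entries.get(name)
        for sample in samples:
            c = median * _lognormal_factor(rng, cv)
            if config.group_of(sample) == "case":
                c *= fold
            truth_conc[name][sample] = c
            a_pct = partition_by_sample[(sample, istd)]
            b = quant_cfg.spiked_nmol[istd] * a_pct / 100.0
            istd_area_f2 = config.istd_total_area * a_pct / 100.0
            area = istd_area_f2 * (c / b) * rf \
                * _lognormal_factor(rng, config.area_cv_pct)
            area_rows.append({"sample_id": sample, "species": name,
                              "fraction": 2, "area": area})
            if entry is not None:
                features_f2.append(Feature(
                    sample_id=sample, fraction=2, polarity=entry.polarity,
                    mz=entry.mz + rng.normal(0, config.sigma_mz_mDa) / 1000.0,
                    charge=entry.charge,
                    rt_min=entry.rt_min + rng.normal(0, config.sigma_rt_min),
                    ccs_A2=entry.ccs_A2 * (1 + rng.normal(
                        0, config.sigma_ccs_pct) / 100.0),
                    area=area, spectrum_id=f"{sample}:{name}",
                ))

    areas = pd.DataFrame(area_rows, columns=["sample_id", "species",
                                             "fraction", "area"])
    # note: the recorded generator partition is the *drawn* A; the measured
    # Eq.(1) partition additionally carries the area noise
    truth = {
        "seed": config.seed,
        "partition": truth_partition,
        "concentration_nmol": truth_conc,
        "spiked_nmol": dict(quant_cfg.spiked_nmol),
        "groups": {s: config.group_of(s) for s in samples},
    }
    return {"areas": areas, "features_f1": features_f1,
            "features_f2": features_f2, "truth": truth}


def simulate_partition_replicates(istd: str, n: int, seed: int,
                                  truth: tuple[float, float] | None = None,
                                  area_cv_pct: float = 7.0) -> pd.DataFrame:
    """Replicate two-fraction extracts of one ISTD (reference-serum style);
    returns the Eq.(1) partition table."""
    mean, cv = truth or DEFAULT_PARTITION_TRUTH[istd]
    config = SimConfig(seed=seed, n_samples=n, species=[],
                       partition_truth={istd: (mean, cv)},
                       area_cv_pct=area_cv_pct)
    cohort = simulate_cohort(config)
    return quantify.partition_table(cohort["areas"], [istd])


def simulate_spectra(species_names: list[str], polarity: str,
                     noise_peaks: int = 0, seed: int = 0,
                     intensity_scale: float = 1000.0) -> list[Spectrum]:
    """Diagnostic-ion-bearing MS/MS spectra from the in-silico fragment
    sets (glycosidic ions; ceramide ions in positive mode), with optional
    random decoy peaks.  Placeholder species are skipped with a warning."""
    import warnings

    rng = np.random.default_rng(seed)
    out: list[Spectrum] = []
    for name in species_names:
        species = chem.parse_species_name(name)
        if species.is_placeholder:
            warnings.warn(f"skipping placeholder species {name}")
            continue
        frags = fragments.glycosidic_fragments(species, polarity)
        if polarity == "+":
            frags = frags + fragments.ceramide_fragments(species)
        mzs = [f.mz for f in frags]
        intens = rng.uniform(0.05, 1.0, size=len(mzs)) * intensity_scale
        if noise_peaks:
            mzs = mzs + list(rng.uniform(150.0, 2000.0, size=noise_peaks))
            intens = np.concatenate([
                intens, rng.uniform(0.01, 0.2, size=noise_peaks) * intensity_scale])
        ion = "[M-H]1-" if polarity == "-" else "[M+H]1+"
        out.append(Spectrum(
            mz=np.array(mzs), intensity=np.asarray(intens),
            precursor_mz=chem.ion_mz(species, ion), charge=1,
            polarity=polarity, title=name,
        ))
    return out


def simulate_calibration(slope: float = 1.0, sigma: float = 0.0,
                         seed: int = 0, intercept: float = 0.0,
                         design: np.ndarray | None = None) -> pd.DataFrame:
    """Calibration points y = intercept + slope*x + N(0, sigma^2) on the
    two-fold 8-point dilution design (0.039 to 5 pmol/µL by default)."""
    from .validate import dilution_series

    x = dilution_series() if design is None else np.asarray(design, float)
    rng = np.random.default_rng(seed)
    y = intercept + slope * x + rng.normal(0.0, sigma, size=len(x))
    return pd.DataFrame({"x": x, "y": y})
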