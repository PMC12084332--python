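"""Differential abundance between groups: Mann-Whitney U with
Benjamini-Hochberg adjustment, optional sex stratification, and
class-level aggregation.

The exact null distribution is used for small, tie-free comparisons;
otherwise the normal approximation with tie correction applies.
Significance stars follow the usual thresholds (* p<0.05, ** p<0.01,
*** p<0.001) on the raw p value; the BH-adjusted p value is reported
alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 8  # exact U distribution when both groups are this small


@dataclass
class GroupDesign:
    """sample -> group assignment with optional sex/age covariates
    (age is carried but unused by the nonparametric test)."""

    group: dict[str, str]
    sex: dict[str, str] = field(default_factory=dict)
    age: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroupDesign":
        design = cls(group=dict(zip(frame["sample_id"], frame["group"])))
        if "sex" in frame.columns:
            design.sex = dict(zip(frame["sample_id"], frame["sex"]))
        if "age" in frame.columns:
            design.age = dict(zip(frame["sample_id"], frame["age"]))
        return design


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N
                         and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_table(concentrations: pd.DataFrame, design: GroupDesign,
                       stratify_by_sex: bool = False,
                       value_col: str = "C_nmol") -> pd.DataFrame:
    """Per-species two-sided Mann-Whitney U between the two design groups,
    BH-adjusted across species (within stratum when stratified).

    ``concentrations`` columns: sample_id, species, and ``value_col``.
    Species with fewer than 2 samples in either group are skipped with a
    reason.
    """
    groups = sorted(set(design.group.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1, g2 = groups
    frame = concentrations.copy()
    frame["group"] = frame["sample_id"].map(design.group)
    if stratify_by_sex:
        frame["stratum"] = frame["sample_id"].map(design.sex)
    else:
        frame["stratum"] = "all"

    out_rows = []
    for stratum, sub in frame.groupby("stratum", sort=True):
        rows = []
        for species, grp in sub.groupby("species", sort=True):
            a = grp.loc[grp["group"] == g1, value_col].dropna().to_numpy(float)
            b = grp.loc[grp["group"] == g2, value_col].dropna().to_numpy(float)
            if len(a) < 2 or len(b) < 2:
                rows.append({"stratum": stratum, "species": species,
                             "n1": len(a), "n2": len(b), "U": math.nan,
                             "p": math.nan, "skipped": "group with <2 samples"})
                continue
            u, p = _mwu(a, b)
            rows.append({"stratum": stratum, "species": species,
                         "n1": len(a), "n2": len(b), "U": u, "p": p,
                         "skipped": ""})
        stratum_frame = pd.DataFrame(rows)
        tested = stratum_frame["p"].notna()
        stratum_frame["p_adj"] = math.nan
        if tested.any():
            stratum_frame.loc[tested, "p_adj"] = multipletests(
                stratum_frame.loc[tested, "p"], method="fdr_bh")[1]
        stratum_frame["stars"] = [
            significance_stars(p) if not math.isnan(p) else ""
            for p in stratum_frame["p"]
        ]
        out_rows.append(stratum_frame)
    return pd.concat(out_rows, ignore_index=True)


def class_totals(concentrations: pd.DataFrame,
                 class_map: dict[str, str] | None = None,
                 value_col: str = "C_nmol") -> pd.DataFrame:
    """Per-subclass summed abundance per sample.

    ``class_map`` maps species name to subclass; when omitted, the "class"
    column of the input is used.  Unmapped species raise an error listing
    them.
    """
    frame = concentrations.copy()
    if class_map is not None:
        frame["class"] = frame["species"].map(class_map)
    elif "class" not in frame.columns:
        raise ValueError("no class column and no class_map given")
    unmapped = sorted(frame.loc[frame["class"].isna(), "species"].unique())
    if unmapped:
        raise ValueError(f"species without a subclass mapping: {unmapped}")
    totals = (frame.groupby(["sample_id", "class"], sort=True)[value_col]
              .sum().reset_index())
    return totals.rename(columns={value_col: "total"})
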