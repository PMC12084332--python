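"""Partition-corrected semi-quantification (Strategies I/II/combined)."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsl4d import chem, quantify, synthetic
from gsl4d.quantify import QuantConfig


@pytest.fixture(scope="module")
def config():
    return QuantConfig()


@pytest.fixture(scope="module")
def noiseless_cohort():
    cfg = synthetic.SimConfig(seed=3, n_samples=5, area_cv_pct=0.0,
                              species=synthetic.default_species(12))
    return synthetic.simulate_cohort(cfg)


class TestPartition:
    def test_symmetry(self):
        assert quantify.partition_percent(100, 100) == 50.0

    def test_all_in_fraction2(self):
        assert quantify.partition_percent(0, 42) == 100.0

    def test_both_zero_undefined(self):
        assert math.isnan(quantify.partition_percent(0, 0))

    def test_replicates_recover_reference_mean(self):
        """Replicate two-fraction extracts at the GD3-d3 reference truth
        (78.70% in fraction 2) recover the mean partition via Eq. (1)."""
        table = synthetic.simulate_partition_replicates(
            "GD3 18:1;O2/18:0-d3", n=1000, seed=42)
        assert table["A_pct"].mean() == pytest.approx(78.70, abs=0.5)

    @given(a1=st.floats(0, 1e6), a2=st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_bounded(self, a1, a2):
        a = quantify.partition_percent(a1, a2)
        assert 0 <= a <= 100
        assert quantify.partition_percent(a1, a2) + quantify.partition_percent(a2, a1) \
            == pytest.approx(100.0, abs=1e-9)


class TestSpikedAmount:
    def test_paper_spike_is_quarter_microgram(self):
        ug = quantify.DEFAULT_SPIKE_VOLUME_UL * quantify.DEFAULT_SPIKE_CONC_UG_PER_ML / 1000
        assert ug == pytest.approx(0.25)

    def test_unit_arithmetic(self):
        assert quantify.spiked_amount_nmol(12.5, 20.0, 1250.0) == pytest.approx(0.200)

    def test_zero_volume(self):
        assert quantify.spiked_amount_nmol(0.0, 20.0, 1250.0) == 0.0


class TestStrategyI:
    def test_unit_ratio_full_partition(self, config):
        istd = "GD3 18:1;O2/18:0-d3"
        spiked = config.spiked_nmol[istd]
        f2 = pd.DataFrame([
            {"sample_id": "s1", "species": istd, "fraction": 2, "area": 500.0},
            {"sample_id": "s1", "species": "GD3 18:1;O2/18:0", "fraction": 2,
             "area": 500.0},
        ])
        res = quantify.quantify_strategy_I(f2, {istd: 100.0}, config)
        assert res.loc[0, "C_nmol"] == pytest.approx(spiked)

    def test_ratio2_half_partition(self):
        istd = "GD3 18:1;O2/18:0-d3"
        config = QuantConfig(spiked_nmol={istd: 0.2,
                                          **{k: 0.2 for k in set(
                                              quantify.SUBSTRATEGY3_ISTD_MAP.values())}})
        f2 = pd.DataFrame([
            {"sample_id": "s1", "species": istd, "fraction": 2, "area": 100.0},
            {"sample_id": "s1", "species": "GD3 18:1;O2/18:0", "fraction": 2,
             "area": 200.0},
        ])
        res = quantify.quantify_strategy_I(f2, {i: 50.0 for i in config.istd_names},
                                           config)
        assert res.loc[0, "C_nmol"] == pytest.approx(0.2)

    def test_equals_strategy_II_when_partition_is_average(self, config):
        """With every sample's partition pinned to the cohort mean,
        Strategies I and II coincide exactly."""
        cfg = synthetic.SimConfig(
            seed=9, n_samples=4, area_cv_pct=0.0,
            species=synthetic.default_species(10),
            partition_truth={k: (mean, 0.0) for k, (mean, _cv)
                             in synthetic.DEFAULT_PARTITION_TRUTH.items()})
        cohort = synthetic.simulate_cohort(cfg)
        areas = cohort["areas"]
        partitions = quantify.partition_table(areas, config.istd_names)
        abar = quantify.average_partition(partitions)
        res1 = quantify.quantify_strategy_I(areas[areas["fraction"] == 2],
                                            abar, config)
        res2 = quantify.quantify_strategy_II(areas, config)
        merged = res1.merge(res2, on=["sample_id", "species"], suffixes=("_1", "_2"))
        assert len(merged) == len(res1)
        assert np.allclose(merged["C_nmol_1"], merged["C_nmol_2"], rtol=1e-12)

    def test_missing_istd_flagged(self, config):
        f2 = pd.DataFrame([
            {"sample_id": "s1", "species": "GD3 18:1;O2/18:0", "fraction": 2,
             "area": 200.0},
        ])
        res = quantify.quantify_strategy_I(
            f2, {i: 78.7 for i in config.istd_names}, config)
        assert res.loc[0, "status"] == "missing_istd"


class TestStrategyII:
    def test_noiseless_round_trip(self, noiseless_cohort, config):
        res = quantify.quantify_strategy_II(noiseless_cohort["areas"], config)
        truth = noiseless_cohort["truth"]["concentration_nmol"]
        assert len(res) and (res["status"] == "ok").all()
        for _, row in res.iterrows():
            expected = truth[row["species"]][row["sample_id"]]
            assert row["C_nmol"] == pytest.approx(expected, rel=1e-9)

    def test_full_partition_equals_single_fraction(self, config):
        istd = "GD3 18:1;O2/18:0-d3"
        areas = pd.DataFrame([
            {"sample_id": "s1", "species": istd, "fraction": 1, "area": 0.0},
            {"sample_id": "s1", "species": istd, "fraction": 2, "area": 400.0},
            {"sample_id": "s1", "species": "GD3 18:1;O2/18:0", "fraction": 2,
             "area": 200.0},
        ])
        res = quantify.quantify_strategy_II(areas, config)
        assert res.loc[0, "A_pct"] == 100.0
        assert res.loc[0, "C_nmol"] == pytest.approx(
            0.5 * config.spiked_nmol[istd])

    def test_c_proportional_to_partition(self, config):
        istd = "GD3 18:1;O2/18:0-d3"
        rows = []
        for sample, a_pct in (("s1", 80.0), ("s2", 40.0)):
            rows += [
                {"sample_id": sample, "species": istd, "fraction": 1,
                 "area": 1000 * (100 - a_pct) / 100},
                {"sample_id": sample, "species": istd, "fraction": 2,
                 "area": 1000 * a_pct / 100},
                {"sample_id": sample, "species": "GD3 18:1;O2/18:0",
                 "fraction": 2, "area": 1000 * a_pct / 100},
            ]
        res = quantify.quantify_strategy_II(pd.DataFrame(rows), config)
        by_sample = res.set_index("sample_id")["C_nmol"]
        assert by_sample["s1"] == pytest.approx(2 * by_sample["s2"])

    def test_scale_invariance(self, noiseless_cohort, config):
        areas = noiseless_cohort["areas"]
        res = quantify.quantify_strategy_II(areas, config)
        scaled = areas.copy()
        factor = scaled["sample_id"].map(
            {s: 3.5 for s in scaled["sample_id"].unique()})
        scaled["area"] = scaled["area"] * factor
        res_scaled = quantify.quantify_strategy_II(scaled, config)
        assert np.allclose(res["C_nmol"], res_scaled["C_nmol"], rtol=1e-12)

    def test_stochastic_recovery(self, config):
        """Lognormal area noise at ~7% CV and 1000 replicates: mean
        partition and mean concentration within 1% relative of truth."""
        species = ["GD3 18:1;O2/18:0"]
        cfg = synthetic.SimConfig(seed=21, n_samples=1000, species=species,
                                  conc_cv_pct=0.0, area_cv_pct=7.0)
        cohort = synthetic.simulate_cohort(cfg)
        res = quantify.quantify_strategy_II(cohort["areas"], config)
        truth_c = cohort["truth"]["concentration_nmol"][species[0]]
        assert res["C_nmol"].mean() == pytest.approx(
            np.mean(list(truth_c.values())), rel=0.01)
        partitions = quantify.partition_table(cohort["areas"],
                                              ["GD3 18:1;O2/18:0-d3"])
        truth_a = cohort["truth"]["partition"]["GD3 18:1;O2/18:0-d3"]
        assert partitions["A_pct"].mean() == pytest.approx(
            np.mean(list(truth_a.values())), rel=0.01)


class TestOutliersAndCombined:
    def _areas_with_outlier(self, config, shift=-30.0):
        cfg = synthetic.SimConfig(seed=13, n_samples=6, area_cv_pct=0.0,
                                  species=synthetic.default_species(6),
                                  partition_truth={
                                      k: (m, 0.0) for k, (m, _c)
                                      in synthetic.DEFAULT_PARTITION_TRUTH.items()})
        cohort = synthetic.simulate_cohort(cfg)
        areas = cohort["areas"].copy()
        # sample S006: move ISTD area from fraction 2 to fraction 1
        for istd in config.istd_names:
            sel = (areas["sample_id"] == "S006") & (areas["species"] == istd)
            f2 = areas.loc[sel & (areas["fraction"] == 2), "area"].iloc[0]
            moved = f2 * (-shift) / 100.0
            areas.loc[sel & (areas["fraction"] == 2), "area"] = f2 - moved
            areas.loc[sel & (areas["fraction"] == 1), "area"] += moved
        return cohort, areas

    def test_identical_samples_not_flagged(self, config):
        cfg = synthetic.SimConfig(seed=2, n_samples=5, area_cv_pct=0.0,
                                  species=[],
                                  partition_truth={
                                      k: (m, 0.0) for k, (m, _c)
                                      in synthetic.DEFAULT_PARTITION_TRUTH.items()})
        cohort = synthetic.simulate_cohort(cfg)
        partitions = quantify.partition_table(cohort["areas"], config.istd_names)
        assert quantify.detect_partition_outliers(partitions) == set()

    def test_shifted_sample_flagged(self, config):
        _, areas = self._areas_with_outlier(config)
        partitions = quantify.partition_table(areas, config.istd_names)
        assert quantify.detect_partition_outliers(partitions) == {"S006"}

    def test_rule_at_infinity_flags_nothing(self, config):
        _, areas = self._areas_with_outlier(config)
        partitions = quantify.partition_table(areas, config.istd_names)
        assert quantify.detect_partition_outliers(
            partitions, k_mad=math.inf, abs_pct=math.inf) == set()

    def test_small_cohort_warns(self, config):
        partitions = pd.DataFrame([
            {"istd": "x", "sample_id": "s1", "area_f1": 1, "area_f2": 3,
             "A_pct": 75.0},
            {"istd": "x", "sample_id": "s2", "area_f1": 1, "area_f2": 1,
             "A_pct": 50.0},
        ])
        with pytest.warns(UserWarning):
            assert quantify.detect_partition_outliers(partitions) == set()

    def test_combined_no_outliers_is_base(self, config):
        cfg = synthetic.SimConfig(seed=8, n_samples=5, area_cv_pct=0.0,
                                  species=synthetic.default_species(8),
                                  partition_truth={
                                      k: (m, 0.0) for k, (m, _c)
                                      in synthetic.DEFAULT_PARTITION_TRUTH.items()})
        areas = synthetic.simulate_cohort(cfg)["areas"]
        partitions = quantify.partition_table(areas, config.istd_names)
        abar = quantify.average_partition(partitions)
        base = quantify.quantify_strategy_I(areas[areas["fraction"] == 2],
                                            abar, config)
        combined = quantify.quantify_combined(areas, config)
        merged = base.merge(combined, on=["sample_id", "species"],
                            suffixes=("_b", "_c"))
        assert np.allclose(merged["C_nmol_b"], merged["C_nmol_c"], rtol=1e-12)
        assert not combined["corrected"].any()

    def test_combined_corrects_only_flagged(self, config):
        _, areas = self._areas_with_outlier(config)
        combined = quantify.quantify_combined(areas, config)
        assert set(combined.loc[combined["corrected"], "sample_id"]) == {"S006"}
        partitions = quantify.partition_table(areas, config.istd_names)
        abar = quantify.average_partition(partitions)
        base = quantify.quantify_strategy_I(areas[areas["fraction"] == 2],
                                            abar, config)
        merged = base.merge(combined, on=["sample_id", "species"],
                            suffixes=("_b", "_c"))
        unflagged = merged[merged["sample_id"] != "S006"]
        assert np.allclose(unflagged["C_nmol_b"], unflagged["C_nmol_c"],
                           rtol=1e-12)
        flagged = merged[merged["sample_id"] == "S006"]
        assert not np.allclose(flagged["C_nmol_b"], flagged["C_nmol_c"])

    def test_base_strategy_selectable(self, config):
        _, areas = self._areas_with_outlier(config)
        cfg2 = QuantConfig(combined_base="II")
        combined = quantify.quantify_combined(areas, cfg2)
        corrected = combined[combined["corrected"]]
        assert set(corrected["strategy"]) == {"I"}


class TestCvTable:
    def test_identical_replicates(self):
        conc = pd.DataFrame([
            {"sample_id": s, "species": "GM3 18:1;O2/18:0", "C_nmol": 0.5}
            for s in ("a", "b", "c")
        ])
        table, summary = quantify.cv_table(conc)
        assert table.loc[0, "cv_pct"] == 0.0
        assert summary["pct_below"] == 100.0

    def test_two_replicates_closed_form(self):
        conc = pd.DataFrame([
            {"sample_id": "a", "species": "X", "C_nmol": 1.0},
            {"sample_id": "b", "species": "X", "C_nmol": 3.0},
        ])
        table, _ = quantify.cv_table(conc)
        assert table.loc[0, "cv_pct"] == pytest.approx(70.7107, abs=1e-3)

    def test_threshold_share(self):
        rows = []
        for i, cv_target in enumerate([10, 20, 50, 80]):
            mean = 100.0
            sd = cv_target
            rows += [{"sample_id": "a", "species": f"sp{i}",
                      "C_nmol": mean - sd / math.sqrt(2)},
                     {"sample_id": "b", "species": f"sp{i}",
                      "C_nmol": mean + sd / math.sqrt(2)}]
        table, summary = quantify.cv_table(pd.DataFrame(rows), threshold_pct=35.0)
        assert summary["pct_below"] == pytest.approx(50.0)

    def test_zero_mean_excluded(self):
        conc = pd.DataFrame([
            {"sample_id": "a", "species": "X", "C_nmol": 0.0},
            {"sample_id": "b", "species": "X", "C_nmol": 0.0},
        ])
        table, summary = quantify.cv_table(conc)
        assert len(table) == 0 and summary["n_excluded"] == 1


class TestNormalizeFraction1:
    ISTD = "GM3 18:1;O2/18:0-d5"

    def frame(self, analyte_area, istd_area):
        return pd.DataFrame([
            {"sample_id": "s1", "species": self.ISTD, "fraction": 1,
             "area": istd_area},
            {"sample_id": "s1", "species": "SHexCer 18:1;O2/24:1",
             "fraction": 1, "area": analyte_area},
        ])

    def test_equal_areas_give_one(self):
        res = quantify.normalize_fraction1(self.frame(100.0, 100.0), self.ISTD)
        assert res.loc[0, "norm_abundance"] == 1.0

    def test_scale_invariance(self):
        r1 = quantify.normalize_fraction1(self.frame(50.0, 100.0), self.ISTD)
        r2 = quantify.normalize_fraction1(self.frame(100.0, 200.0), self.ISTD)
        assert r1.loc[0, "norm_abundance"] == r2.loc[0, "norm_abundance"]

    def test_zero_analyte(self):
        res = quantify.normalize_fraction1(self.frame(0.0, 100.0), self.ISTD)
        assert res.loc[0, "norm_abundance"] == 0.0

    def test_missing_istd_flagged(self):
        res = quantify.normalize_fraction1(self.frame(10.0, 0.0), self.ISTD)
        assert res.loc[0, "status"] == "missing_istd"


def test_concentration_readout_units(config):
    """C (nmol) converts to ng/µL serum via the species' monoisotopic mass."""
    istd = "GD3 18:1;O2/18:0-d3"
    areas = pd.DataFrame([
        {"sample_id": "s1", "species": istd, "fraction": 1, "area": 250.0},
        {"sample_id": "s1", "species": istd, "fraction": 2, "area": 750.0},
        {"sample_id": "s1", "species": "GD3 18:1;O2/18:0", "fraction": 2,
         "area": 750.0},
    ])
    res = quantify.quantify_strategy_II(areas, config)
    mw = chem.species_mass(chem.parse_species_name("GD3 18:1;O2/18:0"))
    expected = res.loc[0, "C_nmol"] * mw / config.serum_volume_uL
    assert res.loc[0, "conc_ng_per_uL"] == pytest.approx(expected)
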