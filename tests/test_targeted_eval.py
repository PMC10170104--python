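import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabextract.data import load_bundled_registry
from metabextract.feature_io import (CompoundRecord, CompoundRegistry, Polarity,
                                     ValidationError)
from metabextract.synthetic_data import (EffectSpec, PlantedCompound,
                                         SimulationConfig, simulate)
from metabextract.targeted_eval import (cv_percent, match_compounds,
                                        normalize_to_reference,
                                        summarize_compounds)

from conftest import make_table


def mini_registry(records=None):
    if records is None:
        records = [CompoundRecord("Tryptophan", Polarity.POS, 205.097, 139.0, 452.0,
                                  True, True, "Indolyl carboxylic acids", "MOINT",
                                  None, "HMDB0000929", "C00078")]
    return CompoundRegistry(records)


def one_feature_table(mz, rt):
    return make_table({"feat1": [10.0, 11.0]},
                      feature_meta=pd.DataFrame({"mz": [mz], "rt": [rt],
                                                 "annotation": [""]},
                                                index=pd.Index(["feat1"])),
                      sample_meta=[("s1", "I", "STUDY", 1), ("s2", "I", "STUDY", 2)])


class TestMatchCompounds:
    def test_tryptophan_within_tolerance(self):
        table = one_feature_table(205.0975, 140.0)
        matches, unmatched = match_compounds(table, mini_registry(), 5.0, 10.0)
        assert len(matches) == 1
        # (205.0975 - 205.097) / 205.097 * 1e6
        assert matches[0].mz_error_ppm == pytest.approx(2.4379, abs=1e-3)
        assert matches[0].rt_error_s == pytest.approx(1.0)

    def test_63ppm_off_is_no_candidate(self):
        table = one_feature_table(205.110, 140.0)
        matches, unmatched = match_compounds(table, mini_registry(), 5.0, 10.0)
        assert matches == []
        assert unmatched[0].reason == "no m/z candidate"

    def test_rt_out_of_window(self):
        table = one_feature_table(205.0975, 400.0)
        matches, unmatched = match_compounds(table, mini_registry(), 5.0, 10.0)
        assert matches == []
        assert unmatched[0].reason == "rt out of window"

    def test_nearest_in_mz_wins(self):
        table = make_table(
            {"f_2ppm": [1.0, 1.0], "f_4ppm": [1.0, 1.0]},
            feature_meta=pd.DataFrame({
                "mz": [205.097 * (1 + 2e-6), 205.097 * (1 + 4e-6)],
                "rt": [139.0, 139.0], "annotation": ["", ""]},
                index=pd.Index(["f_2ppm", "f_4ppm"])),
            sample_meta=[("s1", "I", "STUDY", 1), ("s2", "I", "STUDY", 2)])
        matches, _ = match_compounds(table, mini_registry(), 5.0, 10.0)
        assert matches[0].feature_id == "f_2ppm"

    def test_polarity_mismatch_is_error(self):
        neg_only = mini_registry([CompoundRecord(
            "Glucose", Polarity.NEG, 179.056, 26.0, None, True, False,
            "Carbohydrates", "MOINT", None, None, "C00031")])
        table = one_feature_table(179.056, 26.0)  # table is POS
        with pytest.raises(ValidationError, match="polarity"):
            match_compounds(table, neg_only, 5.0, 10.0)

    def test_matched_plus_unmatched_covers_applicable_registry(self):
        cfg = SimulationConfig(n_features=80, replicates={"I": 3, "III": 3},
                               n_qc=2, base_cv=0.1, lipophilic_fraction=0.0,
                               seed=3)
        table, _ = simulate(cfg)
        registry = load_bundled_registry()
        matches, unmatched = match_compounds(table, registry)
        applicable = registry.for_run(table.run)
        assert len(matches) + len(unmatched) == len(applicable)

    def test_undetected_for_run_skipped(self):
        # Dimethylarginine is flagged not-detected on the RP column
        registry = load_bundled_registry()
        applicable = {r.name for r in registry.for_run(one_feature_table(1, 1).run)}
        assert "Dimethylarginine" not in applicable
        assert "Tryptophan" in applicable


class TestNormalize:
    def test_reference_self_normalizes_to_one(self):
        out = normalize_to_reference({"I": [10.0, 10.0, 10.0]}, "I")
        assert np.allclose(out["I"], 1.0)

    def test_definition(self):
        out = normalize_to_reference({"I": [10.0, 10.0], "III": [20.0, 30.0]}, "I")
        assert np.allclose(out["III"], [2.0, 3.0])

    def test_all_missing_reference_flagged(self):
        with pytest.raises(ValueError, match="NOT_NORMALIZABLE"):
            normalize_to_reference({"I": [np.nan, np.nan], "III": [1.0, 2.0]}, "I")

    def test_zero_mean_reference_flagged(self):
        with pytest.raises(ValueError, match="NOT_NORMALIZABLE"):
            normalize_to_reference({"I": [0.0, 0.0], "III": [1.0]}, "I")

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.001, 1e6))
    def test_scale_invariance(self, c):
        base = {"I": np.array([5.0, 6.0, 7.0]), "III": np.array([9.0, 10.0])}
        out1 = normalize_to_reference(base, "I")
        out2 = normalize_to_reference({g: v * c for g, v in base.items()}, "I")
        for g in base:
            assert np.allclose(out1[g], out2[g], rtol=1e-9)


class TestCV:
    def test_zero_variance(self):
        assert cv_percent([10.0, 10.0, 10.0]) == 0.0

    def test_sample_sd_convention(self):
        assert cv_percent([8.0, 10.0, 12.0]) == pytest.approx(20.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.001, 1e5))
    def test_scale_invariant(self, c):
        vals = np.array([8.0, 10.0, 12.0])
        assert cv_percent(vals * c) == pytest.approx(cv_percent(vals), rel=1e-9)

    def test_location_variant(self):
        assert cv_percent([8.0, 10.0, 12.0]) != pytest.approx(
            cv_percent([108.0, 110.0, 112.0]))

    def test_mean_zero_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([-1.0, 1.0])


class TestSummaries:
    def _scenario_table(self, seed=5):
        planted = [
            PlantedCompound("LipidStd", 500.5, 600.0, "lipophilic"),
            PlantedCompound("AminoA", 150.1, 30.0, "amino"),
            PlantedCompound("Neutral", 300.3, 200.0, "planted_other"),
        ]
        registry = CompoundRegistry([
            CompoundRecord("LipidStd", Polarity.POS, 500.5, 600.0, None, True,
                           False, "Fatty acids", "IS", 1, None, None),
            CompoundRecord("AminoA", Polarity.POS, 150.1, 30.0, None, True,
                           False, "Amino acids", "MOINT", None, None, "C99999"),
            CompoundRecord("Neutral", Polarity.POS, 300.3, 200.0, None, True,
                           False, "Purines", "MOINT", None, None, None),
        ])
        cfg = SimulationConfig(
            n_features=40, replicates={"I": 5, "III": 5}, n_qc=2,
            base_cv=0.05, lipophilic_fraction=0.0,
            effects=[EffectSpec(target="lipophilic", groups=("III",), fold_change=0.02),
                     EffectSpec(target="amino", groups=("III",), fold_change=2.0)],
            seed=seed, planted=planted)
        table, _ = simulate(cfg)
        return table, registry

    def test_lipophilic_is_lost_in_two_phase_group(self):
        table, registry = self._scenario_table()
        matches, _ = match_compounds(table, registry)
        summaries, _ = summarize_compounds(table, registry, matches, "I")
        lipid = next(s for s in summaries if s.compound == "LipidStd")
        assert lipid.mean_norm["III"] < 0.1

    def test_amino_gain_raises_aggregate(self):
        # amino-class fold 2 only (no competing lipophilic loss)
        planted = [PlantedCompound("AminoA", 150.1, 30.0, "amino"),
                   PlantedCompound("AminoB", 160.1, 35.0, "amino"),
                   PlantedCompound("Neutral", 300.3, 200.0, "planted_other")]
        registry = CompoundRegistry([
            CompoundRecord("AminoA", Polarity.POS, 150.1, 30.0, None, True,
                           False, "Amino acids", "MOINT", None, None, None),
            CompoundRecord("AminoB", Polarity.POS, 160.1, 35.0, None, True,
                           False, "Amino acids", "MOINT", None, None, None),
            CompoundRecord("Neutral", Polarity.POS, 300.3, 200.0, None, True,
                           False, "Purines", "MOINT", None, None, None)])
        cfg = SimulationConfig(
            n_features=40, replicates={"I": 5, "III": 5}, n_qc=2,
            base_cv=0.05, lipophilic_fraction=0.0,
            effects=[EffectSpec(target="amino", groups=("III",), fold_change=2.0)],
            seed=5, planted=planted)
        table, _ = simulate(cfg)
        matches, _ = match_compounds(table, registry)
        summaries, panel = summarize_compounds(table, registry, matches, "I")
        amino = next(s for s in summaries if s.compound == "AminoA")
        assert amino.mean_norm["III"] == pytest.approx(2.0, rel=0.2)
        assert panel.mean_of_means["III"] > panel.mean_of_means["I"]

    def test_noiseless_identical_groups(self):
        planted = [PlantedCompound("X", 123.4, 100.0, "planted_other")]
        registry = CompoundRegistry([CompoundRecord(
            "X", Polarity.POS, 123.4, 100.0, None, True, False, "Purines",
            "MOINT", None, None, None)])
        cfg = SimulationConfig(n_features=10, replicates={"I": 3, "III": 3},
                               n_qc=2, base_cv=0.0, lipophilic_fraction=0.0,
                               seed=8, planted=planted)
        table, _ = simulate(cfg)
        matches, _ = match_compounds(table, registry)
        summaries, panel = summarize_compounds(table, registry, matches, "I")
        assert summaries[0].mean_norm["I"] == pytest.approx(1.0)
        assert summaries[0].mean_norm["III"] == pytest.approx(1.0)
        assert summaries[0].cv_pct["I"] == pytest.approx(0.0)
        assert panel.mean_of_means["III"] == pytest.approx(1.0)

    def test_reference_group_mean_is_exactly_one(self):
        table, registry = self._scenario_table(seed=6)
        matches, _ = match_compounds(table, registry)
        summaries, _ = summarize_compounds(table, registry, matches, "I")
        for s in summaries:
            if not s.flag:
                assert s.mean_norm["I"] == pytest.approx(1.0, rel=1e-12)

    def test_missing_reference_group_is_error(self):
        table, registry = self._scenario_table()
        matches, _ = match_compounds(table, registry)
        with pytest.raises(ValidationError, match="reference"):
            summarize_compounds(table, registry, matches, "IV")
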