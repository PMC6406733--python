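import numpy as np
import pandas as pd
import pytest

from exprphylo.io_formats import ScreenDataset
from exprphylo.screen_analysis import (
    density_replicate_correlation,
    fold_change_table,
    plate_position_qc,
    resensitization,
    resistance_calls,
)
from exprphylo.synthetic_data import ScreenSpec, simulate_screen


def make_screen(records):
    cols = ["plate_id", "well_row", "well_col", "drug_id", "control_kind",
            "treatment", "knockdown", "density", "signal"]
    return ScreenDataset(pd.DataFrame(records, columns=cols))


def drug_wells(drug, veh, tgf, density="low", plate=None, start_col=0, kd="siCtrl"):
    plate = plate or f"p_{density}"
    recs = []
    for k, s in enumerate(veh):
        recs.append((f"{plate}_v", 0, start_col + k, drug, None, "vehicle", kd, density, s))
    for k, s in enumerate(tgf):
        recs.append((f"{plate}_t", 0, start_col + k, drug, None, "tgfb", kd, density, s))
    return recs


class TestFoldChange:
    def test_simple_ratio(self):
        screen = make_screen(drug_wells("d1", [1.0, 1.0], [1.5, 1.5]))
        table = fold_change_table(screen)
        assert table.per_drug.loc["d1", "fold_change"] == pytest.approx(1.5)

    def test_equal_means_give_one(self):
        screen = make_screen(drug_wells("d1", [2.0, 4.0], [3.0, 3.0]))
        assert fold_change_table(screen).per_drug.loc["d1", "fold_change"] == 1.0

    def test_scale_invariance(self):
        base = make_screen(drug_wells("d1", [1.0, 2.0], [2.0, 2.5]))
        scaled = make_screen(drug_wells("d1", [10.0, 20.0], [20.0, 25.0]))
        assert fold_change_table(base).per_drug.equals(
            fold_change_table(scaled).per_drug
        )

    def test_densities_averaged(self):
        recs = drug_wells("d1", [1.0], [2.0], density="low")
        recs += drug_wells("d1", [1.0], [1.0], density="high")
        table = fold_change_table(make_screen(recs))
        assert table.per_drug.loc["d1", "fold_change"] == pytest.approx(1.5)

    def test_missing_condition_names_drug(self):
        recs = drug_wells("d1", [1.0], [1.5]) + [
            ("px", 5, 5, "d2", None, "vehicle", "siCtrl", "low", 1.0)
        ]
        with pytest.raises(ValueError, match="d2"):
            fold_change_table(make_screen(recs))


class TestResistanceCalls:
    def test_three_way_calls(self):
        recs = (
            drug_wells("d1", [1.0], [1.5], start_col=0)
            + drug_wells("d2", [1.0], [0.7], start_col=5)
            + drug_wells("d3", [1.0], [1.0], start_col=10)
        )
        calls = resistance_calls(fold_change_table(make_screen(recs)))
        assert calls.attrs["counts"] == {"resistant": 1, "sensitive": 1, "neutral": 1}
        assert calls.loc["d1", "call"] == "resistant"

    def test_fractions_sum_to_one(self):
        recs = []
        for i, fc in enumerate([1.4, 0.6, 1.0, 2.0, 0.9]):
            recs += drug_wells(f"d{i}", [1.0], [fc], start_col=4 * i)
        calls = resistance_calls(fold_change_table(make_screen(recs)))
        c = calls.attrs["counts"]
        assert sum(c.values()) == calls.attrs["n_drugs"]
        assert calls.attrs["fraction_resistant"] == pytest.approx(2 / 5)


class TestResensitization:
    def _tables(self, ctrl_fc, kd_fc):
        recs_c, recs_k = [], []
        for i, (c, k) in enumerate(zip(ctrl_fc, kd_fc)):
            recs_c += drug_wells(f"d{i}", [1.0], [c], start_col=4 * i)
            recs_k += drug_wells(f"d{i}", [1.0], [k], start_col=4 * i, kd="siATG16L1")
        return (
            fold_change_table(make_screen(recs_c), arm="ctrl"),
            fold_change_table(make_screen(recs_k), arm="kd"),
        )

    def test_below_one_rule(self):
        ctrl, kd = self._tables([1.5, 0.8, 1.3], [0.9, 0.5, 1.2])
        out = resensitization(ctrl, kd, rule="below_one")
        assert out.loc["d0", "resensitized"]
        assert not out.loc["d1", "resensitized"]  # never resistant
        assert not out.loc["d2", "resensitized"]  # kd still > 1
        assert out.attrs["n_resistant_ctrl"] == 2

    def test_relative_drop_rule(self):
        ctrl, kd = self._tables([1.5], [1.4])
        out = resensitization(ctrl, kd, rule="relative_drop", relative_drop=0.2)
        assert not out.loc["d0", "resensitized"]  # needs <= 1.2
        out2 = resensitization(ctrl, kd, rule="relative_drop", relative_drop=0.05)
        assert out2.loc["d0", "resensitized"]  # needs <= 1.425

    def test_panel_mismatch_rejected(self):
        ctrl, _ = self._tables([1.5], [1.0])
        _, kd = self._tables([1.5, 1.2], [1.0, 1.0])
        with pytest.raises(ValueError, match="d1"):
            resensitization(ctrl, kd)


class TestQc:
    def test_constant_signal_r2_zero(self):
        recs = [
            ("p1", r, c, "", "DMSO", "vehicle", "siCtrl", "low", 5.0)
            for r in range(2)
            for c in range(4)
        ]
        qc = plate_position_qc(make_screen(recs))
        assert qc.position_r2 == 0.0

    def test_linear_gradient_r2_one(self):
        recs = [
            ("p1", 0, c, "", "empty", "vehicle", "siCtrl", "low", 1.0 + c)
            for c in range(8)
        ]
        qc = plate_position_qc(make_screen(recs), n_cols=8)
        assert qc.position_r2 == pytest.approx(1.0)
        assert "position_effect" in qc.flags

    def test_simulated_no_gradient_low_r2(self):
        screen, _ = simulate_screen(ScreenSpec(seed=2024))
        assert plate_position_qc(screen).position_r2 < 0.1

    def test_too_few_control_wells(self):
        recs = [("p1", 0, 0, "", "DMSO", "vehicle", "siCtrl", "low", 5.0)]
        with pytest.raises(ValueError, match="control wells"):
            plate_position_qc(make_screen(recs))


class TestDensityCorrelation:
    def test_identical_means_r_one(self):
        recs = []
        for i, s in enumerate([1.0, 2.0, 3.0]):
            recs += drug_wells(f"d{i}", [s], [s + 1], density="low", start_col=4 * i)
            recs += drug_wells(f"d{i}", [s], [s + 1], density="high", start_col=4 * i)
        out = density_replicate_correlation(make_screen(recs))
        assert out["vehicle"] == pytest.approx(1.0)
        assert out["tgfb"] == pytest.approx(1.0)

    def test_anticorrelated_minus_one(self):
        lows = [1.0, 2.0, 3.0]
        highs = [3.0, 2.0, 1.0]
        recs = []
        for i, (lo, hi) in enumerate(zip(lows, highs)):
            recs += drug_wells(f"d{i}", [lo], [lo], density="low", start_col=4 * i)
            recs += drug_wells(f"d{i}", [hi], [hi], density="high", start_col=4 * i)
        out = density_replicate_correlation(make_screen(recs))
        assert out["vehicle"] == pytest.approx(-1.0)

    def test_missing_density_rejected(self):
        recs = drug_wells("d1", [1.0], [1.0], density="low")
        with pytest.raises(ValueError, match="high"):
            density_replicate_correlation(make_screen(recs))


class TestPlantedRecovery:
    def test_planted_resistant_set_recovered_exactly(self):
        resistant = tuple(range(0, 119, 4))  # 30 planted drugs
        spec = ScreenSpec(
            resistant_drugs=resistant, tgfb_effect=0.8, noise_cv=0.03, seed=77
        )
        screen, truth = simulate_screen(spec)
        calls = resistance_calls(fold_change_table(screen))
        called = set(calls.index[calls["call"] == "resistant"])
        assert called == set(truth["resistant_drugs"])

    def test_per_plate_scaling_invariance(self):
        spec = ScreenSpec(resistant_drugs=(0, 5), tgfb_effect=0.8, seed=3)
        screen, _ = simulate_screen(spec)
        scaled = screen.wells.copy()
        # multiply BOTH conditions of the high-density plates by a constant
        mask = scaled["density"] == "high"
        scaled.loc[mask, "signal"] *= 7.5
        t1 = fold_change_table(screen)
        t2 = fold_change_table(ScreenDataset(scaled))
        pd.testing.assert_frame_equal(t1.per_drug, t2.per_drug)
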