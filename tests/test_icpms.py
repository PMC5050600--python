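"""ICP-MS quality-control operations."""

import numpy as np
import pandas as pd
import pytest

from napus_phenomics import defaults
from napus_phenomics.icpms import (
    ElementPanel, FLAG_DRIFT, FLAG_HALF_LOD, FLAG_OUTLIER, LodTable, QcError,
    TissueConcMatrix, compute_lod, crm_recovery, drift_correct,
    process_tissue, remove_outliers, retain_elements, substitute_half_lod,
    subtract_blanks, to_tissue_concentration,
)
from napus_phenomics.simulate import GenerativeModel, simulate_icpms_runs, proportional_panel


def _run_table(readings, roles, positions=None, run_id="r1"):
    n = len(readings)
    return pd.DataFrame({
        "run_id": [run_id] * n,
        "position": positions if positions is not None else range(1, n + 1),
        "role": roles,
        "tissue": ["leaf"] * n,
        "genotype_id": [None] * n,
        "pot_id": [f"p{i}" for i in range(n)],
        "dry_mass_g": [0.2] * n,
        "digest_volume_l": [0.015] * n,
        "dilution": [5.0] * n,
        "El": readings,
    })


class TestBlankSubtraction:
    def test_subtracts_run_mean_blank(self):
        runs = _run_table([10.0, 1.0, 3.0], ["sample", "blank", "blank"])
        out = subtract_blanks(runs)
        assert out.loc[0, "El"] == pytest.approx(8.0)

    def test_negative_corrected_reading_retained(self):
        runs = _run_table([1.0, 2.0, 2.0], ["sample", "blank", "blank"])
        out = subtract_blanks(runs)
        assert out.loc[0, "El"] == pytest.approx(-1.0)

    def test_run_without_blanks_raises(self):
        runs = _run_table([10.0], ["sample"])
        with pytest.raises(QcError, match="r1"):
            subtract_blanks(runs)


class TestDriftCorrection:
    def test_constant_references_leave_values_unchanged(self):
        roles = ["reference"] + ["sample"] * 4 + ["reference"]
        runs = _run_table([100.0, 7.0, 8.0, 9.0, 10.0, 100.0], roles)
        out = drift_correct(runs)
        np.testing.assert_allclose(out.loc[1:4, "El"], [7, 8, 9, 10])

    def test_linear_interpolation_between_references(self):
        # references at positions 1 and 11 read 95 and 105 (run mean 100)
        roles = (["reference"] + ["sample"] * 9 + ["reference"])
        readings = [95.0] + [50.0] * 9 + [105.0]
        runs = _run_table(readings, roles)
        out = drift_correct(runs)
        # at position 6 the interpolated factor is exactly 1
        assert out.loc[5, "El"] == pytest.approx(50.0)
        # at position 10 the factor is 104/100
        assert out.loc[9, "El"] == pytest.approx(50.0 / 1.04)

    def test_single_reference_skips_run(self):
        runs = _run_table([100.0, 5.0], ["reference", "sample"])
        out = drift_correct(runs)
        assert out.loc[1, "El"] == 5.0

    def test_corrector_inverts_simulated_linear_drift(self):
        pots = pd.DataFrame({
            "pot_id": [f"p{i}" for i in range(80)],
            "genotype_id": [f"g{i % 20}" for i in range(80)],
            "habit": ["winter_osr"] * 80,
            "polytunnel": ["A"] * 80, "replicate": [1] * 80,
            "sub_block": [1] * 80,
        })
        model = GenerativeModel(drift_amplitude=0.1)
        runs = simulate_icpms_runs(pots, model, run_size=50, seed=9,
                                   tissue="seed")
        out = drift_correct(runs)
        for run_id, sub in out.groupby("run_id"):
            refs = sub[sub["role"] == "reference"]
            cv = refs["K"].std() / refs["K"].mean()
            assert cv == pytest.approx(0.0, abs=1e-12)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "reading, dilution, volume, mass, expected",
        [
            (10.0, 5.0, 0.015, 0.200, 3.75),
            (0.0, 5.0, 0.015, 0.200, 0.0),
            (1.0, 1.0, 0.0115, 0.015, 0.76667),
        ],
    )
    def test_solution_to_tissue(self, reading, dilution, volume, mass, expected):
        assert to_tissue_concentration(reading, dilution, volume, mass) == \
            pytest.approx(expected, rel=1e-4)

    def test_zero_mass_rejected(self):
        with pytest.raises(QcError):
            to_tissue_concentration(1.0, 1.0, 0.01, 0.0)


class TestLod:
    def test_identical_blanks_give_zero_lod(self):
        blanks = pd.DataFrame({"El": [2.0, 2.0, 2.0]})
        table = compute_lod(blanks, 5.0, 0.015, 0.200)
        assert table.lod["El"] == 0.0

    def test_three_blank_lod_value(self):
        # SD of {1,2,3} is 1 ug/L; 3 x 1 x 5 x 0.015 L / 0.200 g = 1.125 mg/kg
        blanks = pd.DataFrame({"El": [1.0, 2.0, 3.0]})
        table = compute_lod(blanks, 5.0, 0.015, 0.200)
        assert table.lod["El"] == pytest.approx(1.125)

    def test_lod_inversely_proportional_to_notional_mass(self):
        blanks = pd.DataFrame({"El": [1.0, 2.0, 3.0]})
        leaf = compute_lod(blanks, 5.0, 0.015, 0.200)
        seed = compute_lod(blanks, 5.0, 0.015, 0.015)
        assert seed.lod["El"] == pytest.approx(leaf.lod["El"] * 0.200 / 0.015)

    def test_single_blank_rejected(self):
        with pytest.raises(QcError):
            compute_lod(pd.DataFrame({"El": [1.0]}), 5.0, 0.015, 0.2)


class TestElementRetention:
    def test_leaf_panel_retains_21(self):
        panel = ElementPanel("leaf", defaults.LEAF_ELEMENTS,
                             defaults.LEAF_EXCLUDED)
        assert len(retain_elements(panel)) == 21

    def test_seed_panel_retains_15_despite_unmonitored_exclusions(self):
        panel = ElementPanel("seed", defaults.SEED_ELEMENTS,
                             defaults.SEED_EXCLUDED)
        retained = retain_elements(panel)
        assert len(retained) == 15
        # Cr and Pb are on the exclusion list but were never monitored
        assert {"Cr", "Pb"} & set(defaults.SEED_ELEMENTS) == set()

    def test_empty_exclusion_is_identity(self):
        panel = ElementPanel("leaf", defaults.LEAF_ELEMENTS, ())
        assert retain_elements(panel) == list(defaults.LEAF_ELEMENTS)


def _matrix(values: dict[str, list[float]]) -> TissueConcMatrix:
    vals = pd.DataFrame(values, dtype=float)
    return TissueConcMatrix("leaf", vals,
                            pd.DataFrame(FLAG_DRIFT, index=vals.index,
                                         columns=vals.columns))


class TestHalfLod:
    def test_below_lod_replaced_with_half_lod(self):
        m = substitute_half_lod(_matrix({"El": [0.4, 2.0]}),
                                LodTable("leaf", 0.2, {"El": 1.0}))
        assert m.values.loc[0, "El"] == 0.5
        assert m.flags.loc[0, "El"] == FLAG_HALF_LOD
        assert m.values.loc[1, "El"] == 2.0

    def test_boundary_value_at_lod_unchanged(self):
        m = substitute_half_lod(_matrix({"El": [1.0]}),
                                LodTable("leaf", 0.2, {"El": 1.0}))
        assert m.values.loc[0, "El"] == 1.0
        assert m.flags.loc[0, "El"] == FLAG_DRIFT

    def test_negative_blank_corrected_value_substituted(self):
        m = substitute_half_lod(_matrix({"El": [-0.3]}),
                                LodTable("leaf", 0.2, {"El": 1.0}))
        assert m.values.loc[0, "El"] == 0.5

    def test_missing_lod_for_retained_element_raises(self):
        with pytest.raises(QcError):
            substitute_half_lod(_matrix({"El": [1.0, 2.0]}),
                                LodTable("leaf", 0.2, {}))


class TestOutlierScreen:
    def test_constant_column_removes_nothing(self):
        m, n = remove_outliers(_matrix({"El": [5.0] * 10}))
        assert n == 0 and m.values["El"].notna().all()

    def test_single_huge_value_within_5sd_is_kept(self):
        # {1 x 9, 1000}: mean 100.9, SD 315.9, threshold ~1680 -> none removed
        m, n = remove_outliers(_matrix({"El": [1.0] * 9 + [1000.0]}))
        assert n == 0

    def test_low_outlier_retained_one_sided(self):
        vals = [10.0] * 20 + [-1000.0]
        m, n = remove_outliers(_matrix({"El": vals}))
        assert n == 0
        assert m.values.loc[20, "El"] == -1000.0

    def test_clear_high_outlier_removed_once(self):
        vals = list(np.linspace(9, 11, 40)) + [1e6]
        m, n = remove_outliers(_matrix({"El": vals}))
        assert n == 1
        assert np.isnan(m.values.loc[40, "El"])
        assert m.flags.loc[40, "El"] == FLAG_OUTLIER


class TestCrmRecovery:
    def test_recovery_examples(self):
        rec = crm_recovery({"A": 1.0, "B": 0.68, "C": 0.0},
                           {"A": 1.0, "B": 1.0, "C": 2.0})
        assert rec["A"] == 100.0
        assert rec["B"] == pytest.approx(68.0)
        assert rec["C"] == 0.0

    def test_nonpositive_certified_rejected(self):
        with pytest.raises(QcError):
            crm_recovery({"A": 1.0}, {"A": 0.0})


class TestPipeline:
    @pytest.fixture(scope="class")
    @staticmethod
    def leaf_qc():
        panel = proportional_panel(120)
        pots = pd.DataFrame({
            "pot_id": [f"p{i}" for i in range(120)],
            "genotype_id": [g.id for g in panel],
            "habit": [g.habit.value for g in panel],
            "polytunnel": ["A"] * 120, "replicate": [1] * 120,
            "sub_block": np.arange(120) % 4 + 1,
        })
        model = GenerativeModel(drift_amplitude=0.1)
        runs, truth = simulate_icpms_runs(pots, model, run_size=60, seed=21,
                                          tissue="leaf", return_truth=True)
        return runs, truth

    def test_drift_correction_lowers_recovery_error(self, leaf_qc):
        runs, truth = leaf_qc
        panel = ElementPanel("leaf", defaults.LEAF_ELEMENTS,
                             defaults.LEAF_EXCLUDED)
        truth = truth.set_index("pot_id")

        def rmse(result):
            vals = result.matrix.values.copy()
            vals.index = result.matrix.meta["pot_id"]
            err = []
            for el in ("K", "Ca", "S", "Mg"):
                t = truth.loc[vals.index, el]
                err.append(((vals[el] - t) / t.mean()) ** 2)
            return float(np.sqrt(pd.concat(err).mean()))

        with_drift = process_tissue(runs, panel, 0.200,
                                    apply_drift_correction=True)
        without = process_tissue(runs, panel, 0.200,
                                 apply_drift_correction=False)
        assert rmse(with_drift) < rmse(without)

    def test_cell_conservation(self, leaf_qc):
        runs, _ = leaf_qc
        panel = ElementPanel("leaf", defaults.LEAF_ELEMENTS,
                             defaults.LEAF_EXCLUDED)
        result = process_tissue(runs, panel, 0.200)
        n_final = int(result.matrix.values.notna().sum().sum())
        assert result.n_raw_cells == (n_final + result.n_outliers_removed
                                      + result.n_excluded_element_cells)

    def test_flags_mutually_consistent(self, leaf_qc):
        runs, _ = leaf_qc
        panel = ElementPanel("leaf", defaults.LEAF_ELEMENTS,
                             defaults.LEAF_EXCLUDED)
        result = process_tissue(runs, panel, 0.200)
        vals = result.matrix.values.to_numpy()
        removed = (result.matrix.flags == FLAG_OUTLIER).to_numpy()
        substituted = (result.matrix.flags == FLAG_HALF_LOD).to_numpy()
        assert not (removed & substituted).any()
        assert np.isnan(vals[removed]).all()
        assert not np.isnan(vals[substituted]).any()
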