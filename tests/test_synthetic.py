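"""Cohort generator: signal forms, calibration and determinism."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from xerpred.synthetic import (
    CohortConfig,
    GroundTruthVoxel,
    coeffs_for_int_mid,
    generate_cohort,
    generate_dce_series,
    generate_dwi_signal,
    generate_gland_maps,
    solve_effect_sizes,
    write_cohort,
)


class TestGroundTruthVoxel:
    def test_ve_identity_enforced(self):
        with pytest.raises(ValueError, match="ve_true"):
            GroundTruthVoxel(0.3, 2.0, 0.5, 1e-3, 0.0, 0.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            GroundTruthVoxel(-0.1, 2.0, -0.05, 1e-3, 0.0, 0.05)


class TestDwiSignal:
    def test_mono_exponential_value(self):
        gt = GroundTruthVoxel(0.0, 1.0, 0.0, 1.0e-3, 0.0, 0.05)
        sig = generate_dwi_signal(gt, b_values=[800.0])
        assert sig.signals[0] == pytest.approx(1000.0 * np.exp(-0.8), rel=1e-9)

    def test_b_zero_normalisation(self):
        gt = GroundTruthVoxel(0.0, 1.0, 0.0, 1.0e-3, 0.35, 0.05)
        sig = generate_dwi_signal(gt, b_values=[0.0, 500.0])
        assert sig.signals[0] == pytest.approx(1000.0)

    def test_fast_pseudo_diffusion_suppressed_at_high_b(self):
        gt = GroundTruthVoxel(0.0, 1.0, 0.0, 1.0e-3, 0.1, 0.05)
        sig = generate_dwi_signal(gt, b_values=[800.0])
        expected = 0.9 * 1000.0 * np.exp(-0.8)
        assert sig.signals[0] == pytest.approx(expected, rel=1e-3)

    def test_negative_b_rejected(self):
        gt = GroundTruthVoxel(0.0, 1.0, 0.0, 1e-3, 0.0, 0.05)
        with pytest.raises(ValueError, match="non-negative"):
            generate_dwi_signal(gt, b_values=[-5.0])

    def test_noise_reproducible_under_seed(self):
        gt = GroundTruthVoxel(0.0, 1.0, 0.0, 1e-3, 0.1, 0.05)
        s1 = generate_dwi_signal(gt, noise_sd=0.02, rng=3)
        s2 = generate_dwi_signal(gt, noise_sd=0.02, rng=3)
        np.testing.assert_array_equal(s1.signals, s2.signals)


class TestDceSeries:
    def test_zero_transfer_flat_series(self):
        gt = GroundTruthVoxel(0.0, 1.0, 0.0, 1e-3, 0.0, 0.05)
        ser = generate_dce_series(gt, as_signal=False)
        np.testing.assert_allclose(ser.values, 0.0, atol=1e-15)

    def test_baseline_phases_carry_no_contrast(self):
        gt = GroundTruthVoxel(0.4, 2.0, 0.2, 1e-3, 0.0, 0.05)
        ser = generate_dce_series(gt, as_signal=False)
        np.testing.assert_allclose(ser.values[:3], 0.0, atol=1e-12)
        assert ser.values[10] > 0


class TestGlandMaps:
    def test_determinism(self):
        cfg = CohortConfig(seed=4)
        v1 = generate_gland_maps(cfg, 0, rng=9)
        v2 = generate_gland_maps(cfg, 0, rng=9)
        assert [v.ktrans_true for v in v1] == [v.ktrans_true for v in v2]

    def test_voxel_count_minimum_enforced(self):
        cfg = CohortConfig()
        cfg.voxels_per_gland = 50
        with pytest.raises(ValueError, match="voxels_per_gland"):
            generate_gland_maps(cfg, 0)

    @pytest.mark.parametrize("group,p10,p25", [(0, 0.28, 0.15), (1, 0.21, 0.13)])
    def test_monte_carlo_calibration(self, group, p10, p25):
        """Median of per-gland P10(Ktrans)/P25(ve) hits the group target."""
        cfg = CohortConfig(seed=2)
        rng = np.random.default_rng(10 + group)
        p10s, p25s = [], []
        for _ in range(300):
            voxels = generate_gland_maps(cfg, group, rng=rng)
            k = np.array([v.ktrans_true for v in voxels])
            ve = np.array([v.ve_true for v in voxels])
            p10s.append(np.percentile(k, 10))
            p25s.append(np.percentile(ve, 25))
        assert np.median(p10s) == pytest.approx(p10, rel=0.05)
        assert np.median(p25s) == pytest.approx(p25, rel=0.05)

    def test_ve_identity_holds_per_voxel(self):
        voxels = generate_gland_maps(CohortConfig(seed=0), 1, rng=0)
        for v in voxels[:10]:
            assert v.ve_true == pytest.approx(v.ktrans_true / v.kep_true, abs=1e-12)


class TestCohort:
    def test_prevalence_near_target(self):
        cfg = CohortConfig(n_patients=2000, seed=13)
        table, _ = generate_cohort(cfg)
        assert table["XER_12"].mean() == pytest.approx(1 / 3, abs=0.03)

    def test_null_effects_give_target_prevalence(self):
        cfg = CohortConfig(
            n_patients=500, seed=14,
            effect_sizes={f: 0.0 for f in CohortConfig().group_medians},
        )
        table, _ = generate_cohort(cfg)
        assert table["XER_12"].mean() == pytest.approx(1 / 3, abs=0.05)

    def test_byte_identical_under_fixed_seed(self):
        cfg = CohortConfig(n_patients=60, seed=5)
        t1, _ = generate_cohort(cfg)
        t2, _ = generate_cohort(cfg)
        assert t1.to_csv() == t2.to_csv()

    def test_group_medians_track_calibration_targets(self):
        cfg = CohortConfig(n_patients=4000, seed=6)
        table, _ = generate_cohort(cfg)
        g0 = table[table["XER_12"] == 0]
        g1 = table[table["XER_12"] == 1]
        assert g0["V65_pct"].median() == pytest.approx(6.5, rel=0.15)
        assert g1["V65_pct"].median() == pytest.approx(10.1, rel=0.15)
        assert g0["XQ_Int_mid"].median() == pytest.approx(51.5, rel=0.15)
        assert g1["XQ_Int_mid"].median() == pytest.approx(82.9, rel=0.15)
        assert g0["ve_P25"].median() == pytest.approx(0.15, rel=0.15)

    def test_effect_sizes_finite_and_signed(self):
        beta = solve_effect_sizes(CohortConfig())
        assert all(np.isfinite(list(beta.values())))
        assert beta["XQ_Int_mid"] > 0  # toxicity raises acute symptom burden

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            CohortConfig(prevalence=1.5)
        with pytest.raises(ValueError, match="10 patients"):
            CohortConfig(n_patients=5)


class TestWriteCohort(object):
    def test_cohort_directory_layout(self, tmp_path):
        cfg = CohortConfig(n_patients=10, seed=3)
        table = write_cohort(cfg, tmp_path)
        assert (tmp_path / "cohort.csv").exists()
        pdir = tmp_path / table["patient_id"].iloc[0]
        for name in (
            "dwi_signals.csv", "dce_series.csv", "dvh_parotid_combined.csv",
            "dvh_smg_combined.csv", "xq.csv", "ground_truth.json",
        ):
            assert (pdir / name).exists(), name
        gt = json.loads((pdir / "ground_truth.json").read_text())
        assert gt["label"] in (0, 1)
        xq = pd.read_csv(pdir / "xq.csv")
        assert list(xq.columns) == ["week"] + [f"q{i}" for i in range(1, 9)]

    def test_written_cohort_deterministic(self, tmp_path):
        cfg = CohortConfig(n_patients=10, seed=8)
        write_cohort(cfg, tmp_path / "a")
        write_cohort(cfg, tmp_path / "b")
        for name in ("cohort.csv", "P001/dwi_signals.csv", "P001/xq.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name


def test_int_mid_coefficients_closed_form():
    a0, a1, a2 = coeffs_for_int_mid(60.0)
    assert a0 == 0.0
    assert a0 * 3 + a1 * 4.5 + a2 * 9 == pytest.approx(60.0)
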