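"""Synthetic EHR generator: determinism, margins, decoy insensitivity."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from medwas import (SimulationConfig, build_cohort, default_code_lists,
                    emit_decoys, generate_cohort, load_code_lists, map_orders,
                    per_medication_prevalence, window_exposure)
from medwas.pipeline import screen_synthetic


def small_config(**overrides):
    kw = dict(n_deliveries=2000, n_medications=8, exposure_prevalence=0.03, seed=5)
    kw.update(overrides)
    return SimulationConfig(**kw)


class TestGenerate:
    def test_seed_determinism_byte_identical(self, tmp_path):
        a = generate_cohort(small_config())
        b = generate_cohort(small_config())
        for x, y in ((a.deliveries, b.deliveries), (a.orders, b.orders),
                     (a.diagnoses, b.diagnoses)):
            pd.testing.assert_frame_equal(x, y)
        pa, pb = tmp_path / "a", tmp_path / "b"
        a.write(pa), b.write(pb)
        for name in ("deliveries.csv", "orders.csv", "diagnoses.csv", "truth.json"):
            assert (pa / name).read_bytes() == (pb / name).read_bytes()

    def test_different_seed_changes_tables(self):
        a = generate_cohort(small_config())
        b = generate_cohort(small_config(seed=6))
        assert not a.deliveries.equals(b.deliveries)

    def test_zero_exposure_prevalence_emits_no_orders(self):
        c = generate_cohort(small_config(exposure_prevalence=0.0))
        assert c.orders.empty

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            small_config(art_prevalence=1.5)
        with pytest.raises(ValueError):
            small_config(n_deliveries=0)
        with pytest.raises(ValueError):
            small_config(gold_standard_ids=("nonexistent-med",))

    def test_ages_truncated_and_near_configured_mean(self):
        c = generate_cohort(small_config(n_deliveries=20000))
        ages = c.deliveries["maternal_age"]
        assert ages.between(12, 55).all()
        assert ages.mean() == pytest.approx(29.5, abs=0.3)

    def test_mb_codes_dated_exactly_at_delivery_iff_outcome(self, code_lists):
        c = generate_cohort(small_config())
        cohort = build_cohort(c.deliveries, c.diagnoses, code_lists)
        merged = cohort.merge(c.latent, on="delivery_id", suffixes=("", "_true"))
        assert (merged["mb"] == merged["mb_true"]).all()
        assert (merged["art"] == merged["art_true"]).all()
        assert (merged["infertility"] == merged["infertility_true"]).all()

    def test_margin_calibration_null_betas(self):
        """Null cohort at n=50,000: empirical MB rate within 3 MC SDs of 2.47%."""
        n = 50000
        p = 0.0247
        cfg = SimulationConfig(n_deliveries=n, n_medications=5,
                               exposure_prevalence=0.01,
                               baseline_mb_logit=float(logit(p)),
                               beta_age=0.0, beta_art=0.0, beta_infertility=0.0,
                               seed=12345)
        c = generate_cohort(cfg)
        rate = c.latent["mb"].mean()
        assert abs(rate - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_exposure_margin_matches_configured_prevalence(self, code_lists):
        cfg = small_config(n_deliveries=20000, exposure_prevalence=0.02)
        c = generate_cohort(cfg)
        cohort = build_cohort(c.deliveries, c.diagnoses, code_lists)
        matrix = window_exposure(cohort, map_orders(c.orders, cfg.annotations()))
        p_any = 1 - (1 - 0.02) ** cfg.n_medications
        observed = matrix.any_exposure().mean()
        assert abs(observed - p_any) < 3 * np.sqrt(p_any * (1 - p_any) / cfg.n_deliveries)

    def test_per_medication_prevalence_inverts_any_exposure(self):
        p = per_medication_prevalence(0.0296, 123)
        assert 1 - (1 - p) ** 123 == pytest.approx(0.0296)

    def test_correlated_block_hook(self):
        meds = SimulationConfig(n_medications=8).medication_ids()[:2]
        cfg = small_config(n_deliveries=20000, exposure_prevalence=0.1,
                           exposure_blocks=(tuple(meds),), block_correlation=0.9)
        c = generate_cohort(cfg)
        base = generate_cohort(small_config(n_deliveries=20000, exposure_prevalence=0.1))
        # correlated blocks concentrate orders on fewer patients
        assert c.orders["patient_id"].nunique() < base.orders["patient_id"].nunique()


class TestDecoys:
    def test_zero_fraction_is_identity(self):
        c = generate_cohort(small_config())
        d = emit_decoys(c, small_config())
        pd.testing.assert_frame_equal(c.orders, d.orders)
        pd.testing.assert_frame_equal(c.diagnoses, d.diagnoses)

    def test_decoys_never_change_downstream_assignments(self, code_lists):
        cfg_clean = small_config(n_deliveries=3000)
        cfg_decoy = small_config(n_deliveries=3000, decoy_fraction=0.2)
        clean = generate_cohort(cfg_clean)
        noisy = generate_cohort(cfg_decoy)
        assert len(noisy.diagnoses) > len(clean.diagnoses)
        assert len(noisy.orders) > len(clean.orders)
        for c, cfg in ((clean, cfg_clean), (noisy, cfg_decoy)):
            cohort = build_cohort(c.deliveries, c.diagnoses, code_lists)
            matrix = window_exposure(cohort, map_orders(c.orders, cfg.annotations()))
            merged = cohort.merge(c.latent, on="delivery_id", suffixes=("", "_true"))
            assert (merged["mb"] == merged["mb_true"]).all()
            assert (merged["art"] == merged["art_true"]).all()
            assert (merged["infertility"] == merged["infertility_true"]).all()
            any_exp = matrix.any_exposure().reindex(c.latent["delivery_id"]).astype(int)
            assert (any_exp.to_numpy() == c.latent["any_exposure"].to_numpy()).all()

    def test_mid_pregnancy_mb_decoy_does_not_set_outcome(self, code_lists):
        c = generate_cohort(small_config(decoy_fraction=0.5))
        cohort = build_cohort(c.deliveries, c.diagnoses, code_lists)
        merged = cohort.merge(c.latent, on="delivery_id", suffixes=("", "_true"))
        false_pos = merged[(merged["mb"] == 1) & (merged["mb_true"] == 0)]
        assert false_pos.empty


def test_planted_effect_recovered_at_scale(code_lists):
    """Planted OR of 6 on one medication is inside the downstream 95% CI."""
    med = "clomiphene"
    cfg = SimulationConfig(
        n_deliveries=50000, n_medications=5, exposure_prevalence=0.01,
        beta_medication={med: float(np.log(6.0))}, seed=2718)
    _, _, _, results = screen_synthetic(cfg, models=("model1",))
    row = results["model1"].frame.set_index("medication_id").loc[med]
    assert row["converged"] == 1
    assert row["ci_low"] <= 6.0 <= row["ci_high"]
    assert row["sig_nominal"] == 1
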