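"""Population synthesis: truncated sampling, derived anthropometrics, bounds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fractrial import (
    PopulationConfig,
    compute_bmi,
    derive_tibia_length,
    derive_weight,
    generate_population,
    sample_truncated,
    summarize_population,
)
from fractrial._rng import stream


class TestSampleTruncated:
    def test_degenerate_sd_returns_mean(self, rng):
        assert sample_truncated(25.0, 0.0, 18.0, 35.0, rng) == 25.0

    def test_moments_match_truncated_normal_law(self, rng):
        mean, sd, lo, hi = 26.0, 3.5, 18.0, 35.0
        n = 100_000
        draws = sample_truncated(mean, sd, lo, hi, rng, size=n)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        exp_mean, exp_var = stats.truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
        se = np.sqrt(exp_var / n)
        assert abs(draws.mean() - exp_mean) < 3 * se
        assert np.all((draws >= lo) & (draws <= hi))

    def test_empty_mass_raises(self, rng):
        with pytest.raises(ValueError, match="mass"):
            sample_truncated(100.0, 1.0, 18.0, 35.0, rng)

    def test_invalid_interval_and_sd(self, rng):
        with pytest.raises(ValueError):
            sample_truncated(25.0, -1.0, 18.0, 35.0, rng)
        with pytest.raises(ValueError):
            sample_truncated(25.0, 1.0, 35.0, 18.0, rng)


class TestWeightBmi:
    def test_index_patient_metadata(self):
        # 1.79 m at BMI 24.81 corresponds to 79.5 kg and back
        assert derive_weight(24.81, 1.79) == pytest.approx(79.50, abs=0.01)
        assert compute_bmi(79.5, 1.79) == pytest.approx(24.81, abs=0.005)

    @pytest.mark.parametrize(
        "bmi,height,weight", [(25.0, 1.60, 64.0), (1.0, 1.0, 1.0)]
    )
    def test_direct_products(self, bmi, height, weight):
        assert derive_weight(bmi, height) == pytest.approx(weight, rel=1e-12)
        assert compute_bmi(weight, height) == pytest.approx(bmi, rel=1e-12)

    @given(
        w=st.floats(30, 200),
        h=st.floats(1.2, 2.2),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, w, h):
        assert derive_weight(compute_bmi(w, h), h) == pytest.approx(w, rel=1e-12)

    @pytest.mark.parametrize("fn", [derive_weight, compute_bmi])
    def test_nonpositive_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-1.0, 1.7)
        with pytest.raises(ValueError):
            fn(25.0, 0.0)


class TestTibiaLength:
    def test_linear_formula_zero_noise(self):
        cfg = PopulationConfig(tibia_resid_sd=0.0)
        assert derive_tibia_length(1.797, 0, cfg) == pytest.approx(404.1, abs=0.05)
        assert derive_tibia_length(1.60, 0, cfg) == pytest.approx(322.7, abs=0.05)
        # index-patient magnitude: 1.79 m -> ~401 mm
        assert derive_tibia_length(1.79, 0, cfg) == pytest.approx(401.2, abs=0.5)

    def test_zero_noise_is_deterministic(self):
        cfg = PopulationConfig(tibia_resid_sd=0.0)
        assert derive_tibia_length(1.75, 3, cfg) == derive_tibia_length(1.75, 3, cfg)

    def test_out_of_bounds_height_rejected(self, rng):
        cfg = PopulationConfig()
        with pytest.raises(ValueError):
            derive_tibia_length(2.10, 0, cfg, rng)


class TestGeneratePopulation:
    def test_bounds_and_weight_identity(self):
        cfg = PopulationConfig(seed=3)
        pop = generate_population(cfg, 2000, rng=stream(3, "population"))
        lo_h, hi_h = cfg.height_bounds
        lo_b, hi_b = cfg.bmi_bounds
        assert pop["height_m"].between(lo_h, hi_h).all()
        assert pop["bmi"].between(lo_b, hi_b).all()
        assert pop["age_group"].between(0, cfg.n_groups - 1).all()
        np.testing.assert_allclose(
            pop["weight_kg"], pop["bmi"] * pop["height_m"] ** 2, rtol=1e-9
        )
        assert (pop["tibia_length_mm"] > 0).all()

    def test_seed_determinism_byte_identical_csv(self, tmp_path):
        cfg = PopulationConfig(seed=11)
        frames = []
        for name in ("a.csv", "b.csv"):
            pop = generate_population(cfg, 200, rng=stream(11, "population"))
            pop.to_csv(tmp_path / name, index=False)
            frames.append(pop)
        pd.testing.assert_frame_equal(*frames)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_population(PopulationConfig(), 0)

    def test_group_moment_recovery(self):
        cfg = PopulationConfig(seed=5)
        pop = generate_population(cfg, 100_000, rng=stream(5, "population"))
        table = summarize_population(pop).set_index("age_group")
        h_mean = cfg._per_group("height_mean")
        h_sd = cfg._per_group("height_sd")
        lo, hi = cfg.height_bounds
        for g in range(cfg.n_groups):
            a, b = (lo - h_mean[g]) / h_sd[g], (hi - h_mean[g]) / h_sd[g]
            exp_mean, exp_var = stats.truncnorm.stats(
                a, b, loc=h_mean[g], scale=h_sd[g], moments="mv"
            )
            n_g = table.loc[g, "height_m_count"]
            se = np.sqrt(exp_var / n_g)
            assert abs(table.loc[g, "height_m_mean"] - exp_mean) < 3 * se


class TestConfigValidation:
    def test_unordered_bounds_rejected(self):
        with pytest.raises(ValueError, match="bmi_bounds"):
            PopulationConfig(bmi_bounds=(35.0, 18.0))

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(group_weights=[0.5, 0.5])  # wrong length for 8 groups
        with pytest.raises(ValueError):
            PopulationConfig(group_weights=[1.0 / 8] * 7 + [0.5])

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(height_sd=-0.01)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(hieght_mean=1.8)


class TestSummarizePopulation:
    def test_zero_sd_population_has_zero_spread(self):
        cfg = PopulationConfig(seed=2, height_sd=0.0, bmi_sd=0.0, tibia_resid_sd=0.0)
        pop = generate_population(cfg, 400, rng=stream(2, "population"))
        table = summarize_population(pop)
        assert np.allclose(table["height_m_std"], 0.0)
        assert np.allclose(table["bmi_std"], 0.0)

    def test_single_avatar_sd_is_missing(self):
        pop = pd.DataFrame(
            {"id": [0], "age_group": [0], "height_m": [1.7], "bmi": [24.0],
             "weight_kg": [24.0 * 1.7**2], "tibia_length_mm": [380.0]}
        )
        table = summarize_population(pop)
        assert np.isnan(table.loc[0, "height_m_std"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_population(pd.DataFrame(columns=["age_group", "height_m", "bmi", "weight_kg"]))
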