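"""Synthetic registry generator: determinism, calibration and serialization."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from edrisk import ConfigurationError, RegistryParseError, simulate


class TestCodeUniverse:
    def test_degenerate_spread_forces_risk_to_tier_center(self):
        cfg = simulate.SimulationConfig(
            n_codes=4, n_tiers=2, tier_risk_centers=(0.05, 0.80),
            tier_proportions=(0.5, 0.5), tier_risk_spread=math.inf, seed=1)
        uni = simulate.generate_code_universe(cfg)
        for t, c in [(1, 0.05), (2, 0.80)]:
            assert np.all(uni.true_risk[uni.tier == t] == c)
        assert sorted(np.bincount(uni.tier)[1:]) == [2, 2]

    def test_same_seed_reproduces_identical_universe(self):
        cfg = simulate.SimulationConfig(n_codes=50, seed=42)
        a = simulate.generate_code_universe(cfg)
        b = simulate.generate_code_universe(cfg)
        assert a.codes == b.codes
        np.testing.assert_array_equal(a.true_risk, b.true_risk)
        np.testing.assert_array_equal(a.tier, b.tier)
        np.testing.assert_array_equal(a.frequency_weight, b.frequency_weight)

    def test_tier_mean_risks_track_centers(self):
        # Monte-Carlo check against the Beta mean: with spread 200 the
        # within-tier sd is < 0.04, so tier means land within 0.03 of centers.
        cfg = simulate.SimulationConfig(n_codes=510, tier_risk_spread=200.0, seed=5)
        uni = simulate.generate_code_universe(cfg)
        for t, c in zip(range(1, 5), cfg.tier_risk_centers):
            assert abs(uni.true_risk[uni.tier == t].mean() - c) < 0.03

    def test_nonincreasing_tier_centers_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate.SimulationConfig(n_tiers=2, tier_risk_centers=(0.5, 0.3),
                                      tier_proportions=(0.5, 0.5))

    def test_codes_unique_and_well_formed(self, small_registry):
        uni, _ = small_registry
        assert len(set(uni.codes)) == len(uni.codes)
        assert all(simulate._CODE_RE.match(c) for c in uni.codes)

    def test_zipf_weight_slope(self):
        cfg = simulate.SimulationConfig(n_codes=300, zipf_exponent=1.3, seed=2)
        uni = simulate.generate_code_universe(cfg)
        w = np.sort(uni.frequency_weight)[::-1]
        ranks = np.arange(1, len(w) + 1)
        slope = np.polyfit(np.log(ranks), np.log(w), 1)[0]
        assert abs(slope - (-1.3)) < 0.1


class TestPresentations:
    def test_single_code_marginal_rate(self):
        cfg = simulate.SimulationConfig(
            n_presentations=100_000, n_codes=1, n_tiers=1,
            tier_risk_centers=(0.5,), tier_proportions=(1.0,),
            tier_risk_spread=math.inf, covariate_effects={}, seed=3)
        uni = simulate.generate_code_universe(cfg)
        df = simulate.generate_presentations(uni, cfg)
        assert abs(df["admitted"].mean() - 0.5) < 0.01

    def test_zero_presentations_yields_empty_frame(self):
        cfg = simulate.SimulationConfig(n_presentations=0, n_codes=5, seed=0)
        uni = simulate.generate_code_universe(cfg)
        df = simulate.generate_presentations(uni, cfg)
        assert len(df) == 0 and list(df.columns) == simulate.REGISTRY_COLUMNS

    def test_same_seed_reproduces_identical_registry(self):
        cfg = simulate.SimulationConfig(n_presentations=2_000, seed=9)
        uni = simulate.generate_code_universe(cfg)
        pd.testing.assert_frame_equal(
            simulate.generate_presentations(uni, cfg),
            simulate.generate_presentations(uni, cfg))

    def test_marginal_rate_matches_frequency_weighted_mean(self):
        # with no covariate effects the marginal admission rate converges to
        # sum(w_c * risk_c); allow 3 binomial standard errors
        cfg = simulate.SimulationConfig(n_presentations=50_000,
                                        covariate_effects={}, seed=17)
        uni = simulate.generate_code_universe(cfg)
        df = simulate.generate_presentations(uni, cfg)
        expected = float(np.sum(uni.frequency_weight * uni.true_risk))
        se = math.sqrt(expected * (1 - expected) / len(df))
        assert abs(df["admitted"].mean() - expected) < 3 * se

    def test_empirical_code_frequencies_follow_zipf(self):
        cfg = simulate.SimulationConfig(n_presentations=100_000, n_codes=300,
                                        zipf_exponent=1.0, seed=21)
        uni = simulate.generate_code_universe(cfg)
        df = simulate.generate_presentations(uni, cfg)
        counts = df["icd10"].value_counts().to_numpy()[:100]
        ranks = np.arange(1, len(counts) + 1)
        slope = np.polyfit(np.log(ranks), np.log(counts), 1)[0]
        assert abs(slope - (-1.0)) < 0.1

    def test_tachycardia_effect_recovered_by_logistic_refit(self):
        # parameter-recovery oracle: simulate with a single covariate effect
        # at a fixed code, then refit admission on the tachycardia indicator
        cfg = simulate.SimulationConfig(
            n_presentations=200_000, n_codes=1, n_tiers=1,
            tier_risk_centers=(0.3,), tier_proportions=(1.0,),
            covariate_effects={"tachycardia": math.log(1.46)}, seed=3)
        uni = simulate.generate_code_universe(cfg)
        df = simulate.generate_presentations(uni, cfg)
        tach = (df["pulse"] > 90).astype(float)
        fit = sm.Logit(df["admitted"], sm.add_constant(tach)).fit(disp=False)
        assert 1.35 <= math.exp(fit.params.iloc[1]) <= 1.58

    def test_empty_universe_rejected(self):
        cfg = simulate.SimulationConfig(n_presentations=10, n_codes=2, seed=0)
        uni = simulate.generate_code_universe(cfg)
        empty = simulate.CodeUniverse(codes=(), true_risk=np.array([]),
                                      tier=np.array([]), frequency_weight=np.array([]))
        with pytest.raises(ConfigurationError):
            simulate.generate_presentations(empty, cfg)


class TestRegistryIO:
    def test_round_trip_identity(self, tmp_path, small_registry):
        _, df = small_registry
        df = df.head(1000)
        path = tmp_path / "reg.csv"
        simulate.write_registry(df, path)
        back = simulate.read_registry(path)
        pd.testing.assert_frame_equal(back, df.reset_index(drop=True))

    def test_bad_admitted_value_names_row_and_column(self, tmp_path):
        from .conftest import make_records
        df = make_records(["A09", "J10"], [0, 1]).astype({"admitted": object})
        df.loc[1, "admitted"] = "maybe"
        path = tmp_path / "reg.csv"
        df.to_csv(path, index=False)
        with pytest.raises(RegistryParseError, match=r"row 1.*admitted"):
            simulate.read_registry(path)

    def test_bad_code_pattern_rejected(self, tmp_path):
        from .conftest import make_records
        df = make_records(["A9X7", "J10"], [0, 1])
        path = tmp_path / "reg.csv"
        df.to_csv(path, index=False)
        with pytest.raises(RegistryParseError, match="icd10"):
            simulate.read_registry(path)

    def test_header_only_file_gives_empty_frame(self, tmp_path):
        path = tmp_path / "reg.csv"
        path.write_text(",".join(simulate.REGISTRY_COLUMNS) + "\n")
        assert len(simulate.read_registry(path)) == 0
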