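import numpy as np
import pandas as pd
import pytest
from scipy import stats

import traitnet as tn
from traitnet.errors import ConfigError, TraitnetError


class TestSimulateBM:
    def test_zero_rate_returns_root_value(self, hand_tree):
        vals = tn.simulate_bm(hand_tree, sigma2=0.0, root_value=4.2, seed=0)
        assert all(v == 4.2 for v in vals.values())

    def test_negative_rate_rejected(self, hand_tree):
        with pytest.raises(TraitnetError):
            tn.simulate_bm(hand_tree, sigma2=-1.0)

    def test_star_tree_tips_independent_unit_variance(self):
        star = tn.star_tree(4)
        draws = np.array(
            [list(tn.simulate_bm(star, 1.0, seed=s).values()) for s in range(10_000)]
        )
        emp = np.cov(draws.T)
        assert np.allclose(np.diag(emp), 1.0, atol=0.05)
        off = emp[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_hand_tree_covariance_matches_shared_paths(self, hand_tree):
        draws = np.array(
            [list(tn.simulate_bm(hand_tree, 1.0, seed=s).values()) for s in range(10_000)]
        )
        emp = np.cov(draws.T)  # preorder leaf order: A, B, C
        assert emp[0, 0] == pytest.approx(2.0, abs=0.1)
        assert emp[0, 1] == pytest.approx(1.0, abs=0.1)
        assert abs(emp[0, 2]) < 0.07


class TestGenerateDataset:
    def test_determinism_byte_identical(self):
        cfg = dict(module_spec={"m": ["LSS", "LS"]}, module_loading=0.7, seed=99)
        t1, _, _, g1 = tn.generate_dataset(tn.SyntheticConfig(**cfg))
        t2, _, _, g2 = tn.generate_dataset(tn.SyntheticConfig(**cfg))
        pd.testing.assert_frame_equal(t1.data, t2.data)
        assert g1 == g2

    def test_shape_matches_design(self):
        table, tree, env, truth = tn.generate_dataset(tn.SyntheticConfig(seed=0))
        assert len(table) == 8 * 3 * 3
        assert len(table.trait_codes) == 26
        assert tree.n_tips == 8
        assert len(env) == 3
        assert len(truth["ephemeral_species"]) == 4

    def test_planted_elevation_slope_recovered(self):
        cfg = tn.SyntheticConfig(
            elevation_slopes={"LDMC": 5.0}, species_sd=0.0, noise_sd=0.1,
            n_replicates=5, seed=3,
        )
        table, _, _, _ = tn.generate_dataset(cfg)
        means = table.data.groupby("elevation_m")["LDMC"].mean()
        slope = stats.linregress(means.index / 1000.0, means.values).slope
        assert slope == pytest.approx(5.0, abs=0.5)

    def test_planted_type_offset_recovered(self):
        cfg = tn.SyntheticConfig(type_offsets={"LN": 2.0}, species_sd=0.0, seed=4)
        table, _, _, truth = tn.generate_dataset(cfg)
        means = table.data.groupby("plant_type")["LN"].mean()
        assert means["ephemeral"] - means["non_ephemeral"] == pytest.approx(2.0, abs=0.3)

    def test_module_loading_gives_rho_squared_correlation(self):
        members = ["LSS", "LS", "LNSC", "RSS", "RS"]
        cfg = tn.SyntheticConfig(
            module_spec={"carb": members}, module_loading=0.9, species_sd=0.0,
            n_replicates=25, seed=6,
        )
        table, _, _, _ = tn.generate_dataset(cfg)
        rho = tn.spearman_matrix(table).rho
        within = [rho.loc[a, b] for i, a in enumerate(members) for b in members[i + 1:]]
        outside = [rho.loc["LDMC", m] for m in members]
        assert np.mean(within) == pytest.approx(0.81, abs=0.06)
        assert np.abs(outside).max() < 0.2

    def test_k_increases_with_signal_lambda(self):
        """Phylogenetic signal planted by the BM blend is monotone in lambda.

        A 32-tip tree is used: with few tips the null (white-noise) K is
        already close to 1 and the contrast is uninformative.
        """
        tree32 = tn.simulate_tree(32, seed=15)
        mean_k = []
        for lam in (0.0, 0.5, 1.0):
            ks = []
            for s in range(25):
                cfg = tn.SyntheticConfig(
                    n_species=32, n_ephemeral=16, traits=["LDMC"],
                    signal_lambda=lam, tree=tree32, seed=100 + s,
                )
                table, tree, _, _ = tn.generate_dataset(cfg)
                x = table.species_means()["LDMC"].to_dict()
                ks.append(tn.blomberg_k(tree, x).K)
            mean_k.append(np.mean(ks))
        assert mean_k[0] < mean_k[1] < mean_k[2]
        assert mean_k[2] > mean_k[0] + 0.3

    def test_config_validation(self):
        with pytest.raises(ConfigError, match="unknown trait"):
            tn.generate_dataset(tn.SyntheticConfig(module_spec={"m": ["NOPE"]}))
        with pytest.raises(ConfigError, match="more than one module"):
            tn.generate_dataset(
                tn.SyntheticConfig(module_spec={"a": ["LSS"], "b": ["LSS"]})
            )
        with pytest.raises(ConfigError):
            tn.generate_dataset(tn.SyntheticConfig(noise_sd=0.0))
        with pytest.raises(ConfigError):
            tn.generate_dataset(tn.SyntheticConfig(module_spec={"a": ["LSS"]}, module_loading=1.0))


class TestGenerateSurvey:
    def test_single_species_gets_full_importance(self):
        survey = tn.generate_survey(2, 5, {"A": 1.0}, seed=0)
        iv = tn.important_value(survey)
        assert iv.importance_values["A"] == pytest.approx(1.0)

    def test_same_seed_identical(self):
        s1 = tn.generate_survey(3, 5, {"A": 2.0, "B": 1.0}, seed=7)
        s2 = tn.generate_survey(3, 5, {"A": 2.0, "B": 1.0}, seed=7)
        pd.testing.assert_frame_equal(s1.data, s2.data)

    def test_weight_ordering_reflected_in_iv(self):
        survey = tn.generate_survey(3, 40, {"heavy": 9.0, "light": 1.0}, seed=1)
        iv = tn.important_value(survey)
        ranked = tn.rank_species(iv, 2)
        assert ranked == ["heavy", "light"]

    def test_zero_quadrats_rejected(self):
        with pytest.raises(TraitnetError):
            tn.generate_survey(1, 0, {"A": 1.0}, seed=0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(TraitnetError):
            tn.generate_survey(1, 1, {"A": 0.0}, seed=0)
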