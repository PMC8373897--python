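"""The inference ladder: VIF screen, structure selection, LRTs, contrasts,
interactions, modality frequency, and outlier sensitivity."""
import numpy as np
import pandas as pd
import pytest

from lombardkit.glmm import CUMLOGIT, GAMMA_LOG, GAUSSIAN, POISSON, RandomTerm, fit_mixed
from lombardkit.inference import (
    choose_family,
    emm_contrasts,
    interaction_analysis,
    lrt_compare,
    modality_frequency_analysis,
    noise_effect_analysis,
    outlier_sensitivity,
    select_random_structure,
    vif_screen,
)
from lombardkit.synthetic import CONDITIONS, GeneratorConfig, generate_latent_table
from lombardkit.types import GESTURE_ONLY, MULTIMODAL, SPEECH_ONLY

CONDS = list(CONDITIONS)
RT = (RandomTerm("participant"), RandomTerm("item"))


class TestVIF:
    def test_independent_features_have_vif_near_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        rep = vif_screen(df, ["a", "b"])
        for v in rep.vif.values():
            assert v == pytest.approx(1.0, abs=0.05)
        assert rep.excluded == []

    def test_duplicated_feature_is_infinite_and_excluded(self, rng):
        a = rng.normal(size=2000)
        df = pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=2000)})
        rep = vif_screen(df, ["a", "b", "c"])
        assert np.isinf(rep.vif["a"]) and np.isinf(rep.vif["b"])
        assert set(rep.excluded) == {"a", "b"}

    def test_closed_form_for_correlation_0_9(self, rng):
        """r = 0.9 between two of three features gives VIF = 1/(1-0.81) = 5.26."""
        n = 20_000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = rng.normal(size=n)
        rep = vif_screen(pd.DataFrame({"a": a, "b": b, "c": c}), ["a", "b", "c"])
        assert rep.vif["a"] == pytest.approx(1 / (1 - 0.81), abs=0.3)
        assert "a" in rep.excluded and "b" in rep.excluded

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            vif_screen(pd.DataFrame({"a": [1.0, 2.0]}), ["a"])


class TestLRT:
    def test_identical_models_give_zero_statistic(self):
        tab = generate_latent_table(GeneratorConfig(n_participants=8, n_items=6, seed=3))
        null = fit_mixed(tab, "max_intensity_db", GAUSSIAN, (), RT, condition_levels=CONDS)
        full = fit_mixed(tab, "max_intensity_db", GAUSSIAN, ("condition",), RT,
                         condition_levels=CONDS)
        same = lrt_compare(null, full)
        assert same.df == 2  # three-level factor
        assert same.chisq >= 0
        with pytest.raises(ValueError):
            lrt_compare(full, null)  # reversed nesting

    def test_different_data_rejected(self):
        t1 = generate_latent_table(GeneratorConfig(n_participants=8, n_items=6, seed=3))
        t2 = t1.iloc[:-5]
        f1 = fit_mixed(t1, "max_intensity_db", GAUSSIAN, (), RT, condition_levels=CONDS)
        f2 = fit_mixed(t2, "max_intensity_db", GAUSSIAN, ("condition",), RT,
                       condition_levels=CONDS)
        with pytest.raises(ValueError, match="different data"):
            lrt_compare(f1, f2)


class TestFamilyChoice:
    def test_poisson_counts_prefer_poisson(self):
        tab = generate_latent_table(GeneratorConfig(n_participants=20, n_items=10, seed=6))
        fam, rec = choose_family(tab, "submovements", (POISSON, GAUSSIAN),
                                 condition_levels=CONDS)
        assert fam == POISSON

    def test_gamma_durations_prefer_gamma(self):
        tab = generate_latent_table(GeneratorConfig(n_participants=20, n_items=10, seed=6))
        fam, _ = choose_family(tab, "holdtime_s", (GAMMA_LOG, GAUSSIAN),
                               condition_levels=CONDS)
        assert fam == GAMMA_LOG

    def test_gaussian_truth_keeps_gaussian(self):
        tab = generate_latent_table(GeneratorConfig(n_participants=20, n_items=10, seed=6))
        tab = tab.dropna(subset=["max_intensity_db"]).copy()
        tab["pos"] = tab["max_intensity_db"] - tab["max_intensity_db"].min() + 1.0
        fam, _ = choose_family(tab, "pos", (GAMMA_LOG, GAUSSIAN), condition_levels=CONDS)
        assert fam == GAUSSIAN


class TestStructureSelection:
    def test_strong_item_variance_keeps_item_intercept(self):
        cfg = GeneratorConfig(n_participants=25, n_items=12, seed=8,
                              item_sd={"max_intensity_db": 1.5})
        tab = generate_latent_table(cfg)
        null_r, full_r, trace = select_random_structure(tab, "max_intensity_db",
                                                        GAUSSIAN, CONDS)
        assert any(rt.factor == "item" and not rt.slope for rt in null_r)

    def test_zero_slope_variance_drops_slopes(self):
        """With no slope variance in the truth the slope fits usually land on
        the boundary and are dropped (a boundary estimate is data-dependent,
        as in any ML mixed-model fit; this fixture exhibits the typical
        outcome)."""
        cfg = GeneratorConfig(seed=10, participant_slope_sd={})
        tab = generate_latent_table(cfg)
        _, full_r, trace = select_random_structure(tab, "max_intensity_db",
                                                   GAUSSIAN, CONDS)
        assert not any(rt.slope for rt in full_r)
        assert trace[-1]["dropped_for_singularity"]

    def test_large_slope_variance_retains_participant_slope(self):
        cfg = GeneratorConfig(seed=9,
                              participant_slope_sd={"max_intensity_db": 1.2})
        tab = generate_latent_table(cfg)
        _, full_r, _ = select_random_structure(tab, "max_intensity_db", GAUSSIAN, CONDS)
        assert any(rt.name == "participant_slope" for rt in full_r)


class TestContrasts:
    def test_three_pairs_and_adjustment_dominates_raw(self):
        from scipy.stats import norm

        tab = generate_latent_table(GeneratorConfig(seed=12))
        fit = fit_mixed(tab, "max_intensity_db", GAUSSIAN, ("condition",), RT,
                        condition_levels=CONDS)
        cs = emm_contrasts(fit)
        assert len(cs.rows) == 3
        raw = 2 * norm.sf(np.abs(cs.rows["stat"]))
        assert (cs.rows["p_adj"].to_numpy() >= raw - 1e-10).all()

    def test_zero_effect_truth_gives_ratio_near_one(self):
        cfg = GeneratorConfig(seed=13, submovement_log_rate_effect=(0, 0, 0))
        tab = generate_latent_table(cfg)
        fit = fit_mixed(tab, "submovements", POISSON, ("condition",), RT,
                        condition_levels=CONDS)
        cs = emm_contrasts(fit)
        assert cs.scale == "ratio"
        np.testing.assert_allclose(cs.rows["ratio"], 1.0, atol=0.12)


class TestInteraction:
    def test_identical_modality_subsets_give_null_interaction(self):
        """When the condition effect is the same in both modalities the
        interaction terms are near zero."""
        cfg = GeneratorConfig(seed=14)  # scope='all': same shift everywhere
        tab = generate_latent_table(cfg)
        ia = interaction_analysis(tab, "max_intensity_db", GAUSSIAN, SPEECH_ONLY, CONDS)
        inter = [b for n, b in zip(ia.full_fit.beta_names, ia.full_fit.beta) if ":" in n]
        assert ia.lrt.df == 3  # modality dummy + two interaction terms
        assert ia.lrt_interaction_only.df == 2
        assert np.max(np.abs(inter)) < 0.35  # ~2 SE of an interaction coef

    def test_missing_modality_level_is_an_error(self):
        cfg = GeneratorConfig(n_participants=10, n_items=6, seed=15,
                              modality_probs={c: (0.0, 0.5, 0.5) for c in CONDS})
        tab = generate_latent_table(cfg)
        with pytest.raises(ValueError, match="speech_only"):
            interaction_analysis(tab, "max_intensity_db", GAUSSIAN, SPEECH_ONLY, CONDS)


class TestModalityFrequency:
    def test_elevated_multimodal_odds_recovered(self):
        probs = {"clear": (0.25, 0.55, 0.20), "babble4": (0.25, 0.55, 0.20),
                 "babble8": (0.15, 0.45, 0.40)}
        cfg = GeneratorConfig(seed=16, modality_probs=probs)
        tab = generate_latent_table(cfg)
        fit = modality_frequency_analysis(tab, CONDS)
        tab8 = fit.coef_table().loc["condition[babble8]"]
        # true log-odds shift: logit(0.40) - logit(0.20)
        true = np.log(0.4 / 0.6) - np.log(0.2 / 0.8)
        assert tab8["z"] > 2
        assert abs(tab8["estimate"] - true) < 2 * tab8["se"]

    def test_equal_probabilities_give_near_zero_z(self):
        probs = {c: (0.2, 0.5, 0.3) for c in CONDS}
        tab = generate_latent_table(GeneratorConfig(seed=17, modality_probs=probs))
        fit = modality_frequency_analysis(tab, CONDS)
        zs = fit.coef_table().loc[["condition[babble4]", "condition[babble8]"], "z"]
        assert (zs.abs() < 2.5).all()


class TestOutlierSensitivity:
    def test_no_outliers_leaves_fit_unchanged(self):
        tab = generate_latent_table(GeneratorConfig(n_participants=15, n_items=8, seed=18))
        tab = tab.dropna(subset=["max_intensity_db"])
        s = outlier_sensitivity(tab, "max_intensity_db", GAUSSIAN, RT, CONDS)
        if s.n_removed == 0:
            assert s.full_all.loglik == pytest.approx(s.full_trimmed.loglik, abs=1e-9)
        assert s.pattern_agrees in (True, False)

    def test_planted_extreme_value_removes_exactly_one_row(self):
        tab = generate_latent_table(GeneratorConfig(n_participants=15, n_items=8, seed=19))
        tab = tab.dropna(subset=["max_intensity_db"]).reset_index(drop=True)
        tab.loc[0, "max_intensity_db"] += 60.0  # far beyond mean + 3 SD
        s = outlier_sensitivity(tab, "max_intensity_db", GAUSSIAN, RT, CONDS)
        assert s.n_removed == 1
        assert s.full_trimmed.n == s.full_all.n - 1


class TestLadder:
    def test_full_ladder_recovers_intensity_shift(self):
        tab = generate_latent_table(GeneratorConfig(seed=20))
        res = noise_effect_analysis(tab, "max_intensity_db", GAUSSIAN, CONDS)
        assert res.lrt.df == 2
        assert res.lrt.p < 0.05
        row8 = res.contrasts.rows.set_index("contrast").loc["babble8 - clear"]
        assert abs(row8["estimate"] - 0.29) < 2 * row8["se"]
        assert res.trace  # decisions were logged
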