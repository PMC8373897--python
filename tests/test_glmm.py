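"""The mixed-model engine, checked against independent implementations.

Gaussian fits are compared with statsmodels MixedLM (single grouping) and
with R lme4 (crossed random effects, via Rscript); Poisson and gamma
Laplace fits are compared with lme4::glmer; the cumulative-logit model is
checked by its reduction to fixed-effects ordered/binary logistic
regression when the random variance vanishes.
"""
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from lombardkit.glmm import CUMLOGIT, GAMMA_LOG, GAUSSIAN, POISSON, RandomTerm, fit_mixed

CONDS = ["clear", "babble4", "babble8"]
EFF = {"clear": 0.0, "babble4": 0.3, "babble8": 0.6}


@pytest.fixture(scope="module")
def crossed_table():
    rng = np.random.default_rng(5)
    npart, nitem = 20, 8
    bp = rng.normal(0, 1.0, npart)
    bi = rng.normal(0, 0.5, nitem)
    rows = []
    for p in range(npart):
        for i in range(nitem):
            c = CONDS[rng.integers(3)]
            y = 5 + EFF[c] + bp[p] + bi[i] + rng.normal(0, 0.8)
            lam = np.exp(1.0 + 0.5 * EFF[c] + 0.3 * bp[p])
            rows.append(dict(participant=f"p{p}", item=f"i{i}", condition=c, y=y,
                             cnt=rng.poisson(lam),
                             dur=rng.gamma(3, np.exp(0.2 + EFF[c]) / 3)))
    return pd.DataFrame(rows)


RT = (RandomTerm("participant"), RandomTerm("item"))


class TestGaussian:
    def test_matches_statsmodels_mixedlm_single_grouping(self, crossed_table):
        import statsmodels.formula.api as smf

        ours = fit_mixed(crossed_table, "y", GAUSSIAN, ("condition",),
                         (RandomTerm("participant"),), condition_levels=CONDS)
        ref = smf.mixedlm("y ~ condition", crossed_table,
                          groups=crossed_table["participant"]).fit(reml=False)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-3)
        # same cell means regardless of reference coding
        cell_ours = ours.beta[0] + np.array([0, ours.beta[1], ours.beta[2]])
        ref_map = dict(zip(ref.fe_params.index, ref.fe_params.values))
        base = ref_map["Intercept"]
        cell_ref = np.array([
            base + ref_map.get("condition[T.clear]", 0.0),
            base,  # babble4 is statsmodels' alphabetical reference
            base + ref_map.get("condition[T.babble8]", 0.0),
        ])
        np.testing.assert_allclose(np.sort(cell_ours), np.sort(cell_ref), atol=1e-3)

    def test_zero_variance_truth_flags_singular(self, rng):
        rows = []
        for p in range(12):
            for i in range(40):
                c = CONDS[rng.integers(3)]
                rows.append(dict(participant=f"p{p}", item=f"i{i%5}", condition=c,
                                 y=2.0 + EFF[c] + rng.normal(0, 1.0)))
        df = pd.DataFrame(rows)
        fit = fit_mixed(df, "y", GAUSSIAN, ("condition",), RT, condition_levels=CONDS)
        assert fit.singular
        assert set(fit.singular_terms) <= {"participant", "item"}


@pytest.fixture(scope="module")
def lme4_reference(crossed_table, tmp_path_factory):
    """Fit the same three models with lme4 through Rscript."""
    tmp = tmp_path_factory.mktemp("lme4")
    csv = tmp / "data.csv"
    crossed_table.to_csv(csv, index=False)
    script = tmp / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        df <- read.csv("{csv}")
        df$condition <- factor(df$condition, levels=c("clear","babble4","babble8"))
        m1 <- lmer(y ~ condition + (1|participant) + (1|item), df, REML=FALSE)
        m2 <- glmer(cnt ~ condition + (1|participant) + (1|item), df, family=poisson)
        m3 <- glmer(dur ~ condition + (1|participant) + (1|item), df,
                    family=Gamma(link="log"))
        out <- c(logLik(m1), fixef(m1), logLik(m2), fixef(m2), fixef(m3))
        cat(sprintf("%.6f", out), sep="\\n")
    """))
    res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         timeout=300)
    assert res.returncode == 0, res.stderr
    vals = [float(x) for x in res.stdout.strip().splitlines()]
    return {
        "gauss_ll": vals[0], "gauss_beta": vals[1:4],
        "pois_ll": vals[4], "pois_beta": vals[5:8],
        "gamma_beta": vals[8:11],
    }


class TestAgainstLme4:
    def test_gaussian_crossed_random_intercepts(self, crossed_table, lme4_reference):
        fit = fit_mixed(crossed_table, "y", GAUSSIAN, ("condition",), RT,
                        condition_levels=CONDS)
        assert fit.loglik == pytest.approx(lme4_reference["gauss_ll"], abs=1e-3)
        np.testing.assert_allclose(fit.beta, lme4_reference["gauss_beta"], atol=1e-3)

    def test_poisson_laplace(self, crossed_table, lme4_reference):
        fit = fit_mixed(crossed_table, "cnt", POISSON, ("condition",), RT,
                        condition_levels=CONDS)
        assert fit.loglik == pytest.approx(lme4_reference["pois_ll"], abs=0.05)
        np.testing.assert_allclose(fit.beta[1:], lme4_reference["pois_beta"][1:],
                                   atol=5e-3)
        assert fit.beta[0] == pytest.approx(lme4_reference["pois_beta"][0], abs=0.03)

    def test_gamma_log_laplace(self, crossed_table, lme4_reference):
        fit = fit_mixed(crossed_table, "dur", GAMMA_LOG, ("condition",), RT,
                        condition_levels=CONDS)
        np.testing.assert_allclose(fit.beta, lme4_reference["gamma_beta"], atol=5e-3)


class TestPoissonReduction:
    def test_zero_variance_matches_fixed_effects_glm(self, rng):
        import statsmodels.api as sm

        n = 500
        cond = np.array(CONDS)[rng.integers(0, 3, n)]
        lam = np.exp(1.2 + np.vectorize(EFF.get)(cond))
        df = pd.DataFrame({"participant": "p0", "item": "i0", "condition": cond,
                           "cnt": rng.poisson(lam)})
        fit = fit_mixed(df, "cnt", POISSON, ("condition",), (RandomTerm("participant"),),
                        condition_levels=CONDS)
        X = pd.get_dummies(pd.Categorical(cond, CONDS), drop_first=True).astype(float)
        X.insert(0, "const", 1.0)
        ref = sm.GLM(df["cnt"].to_numpy(), X, family=sm.families.Poisson()).fit()
        assert fit.singular
        np.testing.assert_allclose(fit.beta, ref.params.values, atol=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-2)


class TestCumulativeLogit:
    def _ordinal_table(self, rng, n=600, sd_p=0.0):
        cuts = np.array([-1.0, 0.5, 1.5])
        part = rng.integers(0, 10, n)
        bp = rng.normal(0, sd_p, 10)
        cond = np.array(CONDS)[rng.integers(0, 3, n)]
        lat = np.vectorize(EFF.get)(cond) + bp[part] + rng.logistic(size=n)
        return pd.DataFrame({"participant": [f"p{i}" for i in part], "item": "i0",
                             "condition": cond, "va": np.searchsorted(cuts, lat)})

    def test_reduces_to_ordered_logit_without_random_variance(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        df = self._ordinal_table(rng, sd_p=0.0)
        fit = fit_mixed(df, "va", CUMLOGIT, ("condition",), (RandomTerm("participant"),),
                        condition_levels=CONDS)
        dummies = pd.get_dummies(pd.Categorical(df.condition, CONDS),
                                 drop_first=True).astype(float)
        ref = OrderedModel(df["va"], dummies, distr="logit").fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params.values[:2], atol=2e-3)
        assert fit.singular

    def test_two_level_ordinal_equals_logistic_regression(self, rng):
        """A binary cumulative-logit likelihood is the logistic-regression
        likelihood with the threshold playing the negative intercept; with
        the random term removed the fits coincide exactly."""
        import statsmodels.api as sm

        df = self._ordinal_table(rng, sd_p=0.0)
        df["hi"] = (df["va"] >= 2).astype(int)
        fit = fit_mixed(df, "hi", CUMLOGIT, ("condition",), (), condition_levels=CONDS)
        dummies = pd.get_dummies(pd.Categorical(df.condition, CONDS),
                                 drop_first=True).astype(float)
        X = sm.add_constant(dummies)
        ref = sm.Logit(df["hi"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params.values[1:], atol=1e-3)
        assert -fit.params[0] == pytest.approx(ref.params.values[0], abs=1e-3)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_quadrature_node_stability(self, rng):
        """Adaptive Gauss-Hermite with 5 vs 21 nodes agrees to < 1e-2."""
        df = self._ordinal_table(rng, n=150, sd_p=0.8)
        f5 = fit_mixed(df, "va", CUMLOGIT, ("condition",), (RandomTerm("participant"),),
                       condition_levels=CONDS, nagq=5)
        f21 = fit_mixed(df, "va", CUMLOGIT, ("condition",), (RandomTerm("participant"),),
                        condition_levels=CONDS, nagq=21)
        assert np.max(np.abs(f5.params - f21.params)) < 1e-2

    def test_single_observed_level_rejected(self):
        df = pd.DataFrame({"participant": "p0", "item": "i0",
                           "condition": ["clear"] * 10, "va": [2] * 10})
        with pytest.raises(ValueError, match="two observed levels"):
            fit_mixed(df, "va", CUMLOGIT, ("condition",), (RandomTerm("participant"),),
                      condition_levels=CONDS)


class TestInputValidation:
    def test_family_constraints(self, crossed_table):
        bad = crossed_table.assign(cnt=lambda d: d["cnt"] - 10)
        with pytest.raises(ValueError, match="non-negative"):
            fit_mixed(bad, "cnt", POISSON, ("condition",), RT)
        bad2 = crossed_table.assign(dur=0.0)
        with pytest.raises(ValueError, match="positive"):
            fit_mixed(bad2, "dur", GAMMA_LOG, ("condition",), RT)
        with pytest.raises(ValueError, match="family"):
            fit_mixed(crossed_table, "y", "weibull", ("condition",), RT)
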