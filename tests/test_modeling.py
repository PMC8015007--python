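import numpy as np
import pandas as pd
import pytest

from tmtdiff import modeling
from tmtdiff.design import ExperimentDesign
from tmtdiff.errors import ContrastError
from tmtdiff.modeling import (
    EBPrior,
    ModelSpec,
    adjust_bh,
    choose_model,
    estimate_eb_prior,
    fit_protein,
    group_comparison,
    moderate,
    pairwise_contrasts,
)

contrast_test = modeling.test_contrast  # plain alias: keep pytest from collecting it


def design(M, T, conditions=("A", "B"), B=2, has_reference=False):
    return ExperimentDesign(
        n_mixtures=M,
        techreps_per_mixture={f"Mixture{i + 1}": T for i in range(M)},
        conditions=list(conditions),
        bioreps={(f"Mixture{i + 1}", c): B for i in range(M) for c in conditions},
        has_reference=has_reference,
        balanced=True,
    )


def summaries(M=1, T=1, conditions=("A", "B"), B=2, values=None, protein="P1",
              sigma=0.0, seed=0):
    """Balanced summary rows; ``values``: dict condition -> mean."""
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(M):
        mixture = f"Mixture{m + 1}"
        for t in range(T):
            run = f"{mixture}_T{t + 1}"
            for c in conditions:
                for b in range(B):
                    mean = values[c] if values else 0.0
                    rows.append({
                        "Protein": protein, "Mixture": mixture,
                        "TechRepMixture": f"T{t + 1}", "Run": run,
                        "Channel": f"{c}{b}", "Condition": c,
                        "BioReplicate": f"{mixture}_{c}_b{b}",
                        "Abundance": mean + rng.normal(0, sigma),
                        "NFeatures": 1,
                    })
    return pd.DataFrame(rows)


class TestChooseModel:
    def test_full_when_multi_mixture_multi_techrep(self):
        # PAPER design: five mixtures, three technical replicates each
        assert choose_model(design(5, 3)).label == "full"

    def test_single_run(self):
        # PAPER design: single mixture profiled in a single MS run
        assert choose_model(design(1, 1)).label == "single_run"

    def test_multi_mixture_no_techrep(self):
        # PAPER design: three mixtures, no technical replicates
        spec = choose_model(design(3, 1))
        assert spec.label == "multi_mixture"
        assert spec.random_terms == ["mixture"]

    def test_single_mixture_techrep(self):
        spec = choose_model(design(1, 3))
        assert spec.label == "single_mixture_techrep"
        assert spec.random_terms == ["techrep", "subject"]

    def test_per_protein_mixture_reduction(self):
        # protein observed in one mixture of a 3-mixture design
        pat = summaries(M=3, T=1).query("Mixture == 'Mixture1'")
        spec = choose_model(design(3, 1), pat)
        assert not spec.has_mixture_effect


class TestFitProtein:
    def test_noiseless_single_run(self):
        rows = summaries(values={"A": 5.0, "B": 7.0})
        fit = fit_protein(rows, choose_model(design(1, 1)))
        assert fit.converged
        diff = fit.condition_estimates["B"] - fit.condition_estimates["A"]
        assert diff == pytest.approx(2.0, abs=1e-12)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_reml_matches_balanced_anova_oracle(self):
        # one-way random-effects layout: C conditions, B subjects, T reps
        rng = np.random.default_rng(3)
        C, B, T = 3, 4, 3
        rows = []
        for ci, cond in enumerate(["A", "B", "C"][:C]):
            for b in range(B):
                subj = rng.normal(0, 0.5)
                for t in range(T):
                    rows.append({
                        "Protein": "P1", "Mixture": "Mixture1",
                        "TechRepMixture": f"T{t}", "Run": f"run{t}",
                        "Channel": f"{cond}{b}", "Condition": cond,
                        "BioReplicate": f"{cond}_b{b}",
                        "Abundance": ci + subj + rng.normal(0, 0.3),
                        "NFeatures": 1,
                    })
        df = pd.DataFrame(rows)
        spec = ModelSpec(False, False, True, "single_mixture_techrep")
        fit = fit_protein(df, spec)

        # classical balanced ANOVA method-of-moments oracle
        piv = df.pivot_table(index="BioReplicate", columns="TechRepMixture",
                             values="Abundance")
        subj_means = piv.mean(axis=1)
        mse = float(((piv.sub(subj_means, axis=0)) ** 2).to_numpy().sum()
                    / (C * B * (T - 1)))
        cond_of = df.groupby("BioReplicate")["Condition"].first()
        cond_means = subj_means.groupby(cond_of).transform("mean")
        ms_subj = float(T * ((subj_means - cond_means) ** 2).sum() / (C * (B - 1)))
        sigma_s_mom = (ms_subj - mse) / T

        assert fit.sigma2 == pytest.approx(mse, abs=1e-6)
        assert fit.varcomps["subject"] == pytest.approx(sigma_s_mom, abs=1e-6)

    def test_one_condition_missing(self):
        rows = summaries(values={"A": 5.0, "B": 7.0})
        fit = fit_protein(rows[rows["Condition"] == "A"], choose_model(design(1, 1)))
        assert fit.issue == "oneConditionMissing"

    def test_no_data(self):
        rows = summaries(values={"A": 5.0, "B": 7.0}).assign(Abundance=np.nan)
        fit = fit_protein(rows, choose_model(design(1, 1)))
        assert fit.issue == "completeMissing"

    def test_satterthwaite_df_balanced_oracle(self):
        # contrast variance proportional to a single between-subject mean
        # square => Satterthwaite df equals its df C*(B-1)
        rng = np.random.default_rng(9)
        C, B, T = 2, 6, 3
        rows = []
        for cond in ("A", "B"):
            for b in range(B):
                subj = rng.normal(0, 0.5)
                for t in range(T):
                    rows.append({
                        "Protein": "P1", "Mixture": "Mixture1",
                        "TechRepMixture": f"T{t}", "Run": f"run{t}",
                        "Channel": f"{cond}{b}", "Condition": cond,
                        "BioReplicate": f"{cond}_b{b}",
                        "Abundance": subj + rng.normal(0, 0.3),
                        "NFeatures": 1,
                    })
        fit = fit_protein(pd.DataFrame(rows),
                          ModelSpec(False, False, True, "single_mixture_techrep"))
        c = np.array([1.0, -1.0])
        df = fit._model.satterthwaite_df(c, fit._fit)
        assert df == pytest.approx(C * (B - 1), rel=0.01)


class TestEBPrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = estimate_eb_prior([(2.0, 10.0)] * 20)
        assert np.isinf(prior.d0)
        # the log-variance moment matching bias-corrects each log s2 by
        # digamma(df/2) - log(df/2), so the zero-dispersion prior scale is
        # the common variance times exp(log(df/2) - digamma(df/2))
        from scipy.special import digamma
        expected = 2.0 * np.exp(np.log(5.0) - digamma(5.0))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-9)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(17)
        d0_true, s0_true, df = 4.0, 2.0, 10.0
        n = 5000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = sigma2 * rng.chisquare(df, size=n) / df
        prior = estimate_eb_prior(zip(s2, np.full(n, df)))
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.15)

    def test_single_protein_identity_prior(self):
        prior = estimate_eb_prior([(2.0, 10.0)])
        assert prior.d0 == 0.0


class TestModerate:
    def _fit(self, s2=2.0, df=3.0):
        return modeling.FitResult(protein="P", model_used="single_run",
                                  sigma2=s2, residual_df=df, converged=True)

    def test_identity_prior(self):
        s2, inc = moderate(self._fit(), EBPrior.identity())
        assert s2 == 2.0 and inc == 0.0

    def test_infinite_d0_full_shrinkage(self):
        s2, inc = moderate(self._fit(), EBPrior(d0=np.inf, s0_sq=1.5))
        assert s2 == 1.5 and inc == 1e6

    def test_arithmetic(self):
        s2, inc = moderate(self._fit(s2=2.0, df=3.0), EBPrior(d0=3.0, s0_sq=1.0))
        assert s2 == pytest.approx(1.5)
        assert inc == 3.0

    def test_shrinks_between_bounds(self):
        rng = np.random.default_rng(4)
        prior = EBPrior(d0=5.0, s0_sq=1.3)
        for _ in range(100):
            s2 = float(rng.uniform(0.01, 10))
            df = float(rng.uniform(1, 50))
            tilde, _ = moderate(self._fit(s2=s2, df=df), prior)
            assert min(s2, prior.s0_sq) - 1e-12 <= tilde <= max(s2, prior.s0_sq) + 1e-12


class TestTestContrast:
    def test_noiseless_null_protein(self):
        rows = summaries(values={"A": 5.0, "B": 5.0})
        fit = fit_protein(rows, choose_model(design(1, 1)))
        res = contrast_test(fit, moderate(fit, EBPrior.identity()),
                            {"A": 1.0, "B": -1.0})
        assert res["log2FC"] == 0.0
        assert res["pvalue"] == 1.0

    def test_absent_condition_flagged(self):
        rows = summaries(conditions=("A", "B", "C"),
                         values={"A": 5.0, "B": 6.0, "C": 7.0})
        rows = rows[rows["Condition"] != "C"]
        fit = fit_protein(rows, choose_model(design(1, 1, conditions=("A", "B", "C"))))
        res = contrast_test(fit, moderate(fit, EBPrior.identity()),
                            {"A": 1.0, "C": -1.0, "B": 0.0})
        assert res["issue"] == "oneConditionMissing"
        assert np.isnan(res["pvalue"])

    def test_nonzero_weight_sum_raises(self):
        rows = summaries(values={"A": 5.0, "B": 7.0})
        fit = fit_protein(rows, choose_model(design(1, 1)))
        with pytest.raises(ContrastError):
            contrast_test(fit, (1.0, 0.0), {"A": 1.0, "B": -0.5})

    def test_small_bias_at_known_truth(self):
        # 30 channels per condition, true difference 1.0
        rng = np.random.default_rng(21)
        estimates = []
        for rep in range(40):
            rows = summaries(B=30, values={"A": 10.0, "B": 11.0}, sigma=0.3,
                             seed=rep)
            fit = fit_protein(rows, choose_model(design(1, 1)))
            res = contrast_test(fit, moderate(fit, EBPrior.identity()),
                                {"B": 1.0, "A": -1.0})
            estimates.append(res["log2FC"])
        assert abs(np.mean(estimates) - 1.0) < 0.05


def bh_oracle(pvals):
    """Sort-based BH: adj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * pvals[i] / rank_from_top)
        adj[i] = min(running, 1.0)
    return adj


class TestAdjustBH:
    def _frame(self, pvals, label="L1"):
        return pd.DataFrame({
            "Protein": [f"P{i}" for i in range(len(pvals))],
            "Label": label, "log2FC": 0.0, "SE": 1.0, "DF": 10.0,
            "tvalue": 0.0, "pvalue": pvals, "adj.pvalue": np.nan,
            "issue": "none",
        })

    def test_hand_example(self):
        out = adjust_bh(self._frame([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(out["adj.pvalue"], [0.03, 0.03, 0.03])

    def test_single_pvalue(self):
        out = adjust_bh(self._frame([0.04]))
        assert out["adj.pvalue"].iloc[0] == pytest.approx(0.04)

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            out = adjust_bh(self._frame(list(p)))
            np.testing.assert_allclose(out["adj.pvalue"], bh_oracle(list(p)),
                                       atol=1e-12)

    def test_missing_p_stays_missing(self):
        frame = self._frame([0.01, 0.5])
        frame.loc[1, "pvalue"] = np.nan
        frame.loc[1, "issue"] = "oneConditionMissing"
        out = adjust_bh(frame)
        assert np.isnan(out["adj.pvalue"].iloc[1])
        assert out["adj.pvalue"].iloc[0] == pytest.approx(0.01)

    def test_monotone_in_p_within_label(self):
        rng = np.random.default_rng(12)
        p = rng.random(50)
        out = adjust_bh(self._frame(list(p)))
        df = out.sort_values("pvalue")
        assert df["adj.pvalue"].is_monotonic_increasing


class TestGroupComparison:
    def test_all_pairs_labels(self, small_pipeline):
        # PAPER: C = 4 conditions give 6 pairwise comparisons
        _, pst, design_, _ = small_pipeline
        res = group_comparison(pst, design_, moderation=False)
        assert res["Label"].nunique() == 6

    def test_empty_input(self):
        res = group_comparison(pd.DataFrame(columns=["Protein", "Condition",
                                                     "Abundance"]),
                               design(1, 1))
        assert res.empty

    def test_untestable_excluded_from_bh_denominator(self):
        frames = []
        for i in range(10):
            frames.append(summaries(values={"A": 5.0, "B": 6.0}, sigma=0.1,
                                    seed=i, protein=f"P{i:02d}", B=3))
        # make P00 untestable: a single observation in condition B
        lone = frames[0]
        drop = lone[(lone["Condition"] == "B")].index[1:]
        lone = lone.drop(index=drop)
        lone = pd.concat([lone[lone["Condition"] == "A"].iloc[:1],
                          lone[lone["Condition"] == "B"]])
        frames[0] = lone
        pst = pd.concat(frames, ignore_index=True)
        res = group_comparison(pst, design(1, 1, B=3), moderation=False)
        bad = res[res["Protein"] == "P00"]
        assert (bad["issue"] != "none").all()
        ok = res[res["issue"] == "none"]
        assert ok["Protein"].nunique() == 9
        # BH with m=9: largest adjusted p = max p (rank 9 of 9)
        np.testing.assert_allclose(
            ok.sort_values("pvalue")["adj.pvalue"].to_numpy(),
            bh_oracle(list(ok.sort_values("pvalue")["pvalue"])), atol=1e-12)

    def test_balanced_design_equivalence(self):
        # full-model contrast estimate equals difference of condition means
        rng = np.random.default_rng(31)
        rows = summaries(M=3, T=2, B=2, conditions=("A", "B", "C"),
                         values={"A": 10.0, "B": 11.0, "C": 12.5}, sigma=0.4,
                         seed=5)
        fit = fit_protein(rows, choose_model(design(3, 2, conditions=("A", "B", "C"))))
        means = rows.groupby("Condition")["Abundance"].mean()
        for a, b in (("A", "B"), ("B", "C"), ("A", "C")):
            res = contrast_test(fit, moderate(fit, EBPrior.identity()),
                                {a: 1.0, b: -1.0})
            assert res["log2FC"] == pytest.approx(means[a] - means[b], abs=1e-8)
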