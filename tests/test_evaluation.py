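import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from peerspread.evaluation import (
    CONDITION_ORDER,
    STRUCTURE_MEASURES,
    evaluate,
    fit_condition_model,
    fit_moderation_model,
    helmert_scheme,
    rm_anova_sphericity,
    structure_correlations,
)

CONDS = list(CONDITION_ORDER)


def simulate_results(rng, n_classes=26, effects=None, class_sd=2.0, noise_sd=1.0):
    effects = effects or {}
    rows = []
    for i in range(n_classes):
        b = rng.normal(0, class_sd)
        for c in CONDS:
            rows.append({"class_id": f"C{i:02d}", "condition": c,
                         "success_rate": 10 + b + effects.get(c, 0.0)
                         + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


def random_structure(rng, class_ids):
    df = pd.DataFrame(
        {
            "density": rng.uniform(0.5, 0.9, len(class_ids)),
            "centralization_in_degree": rng.uniform(0.1, 0.4, len(class_ids)),
            "centralization_betweenness": rng.uniform(0.01, 0.09, len(class_ids)),
            "centralization_closeness": rng.uniform(0.1, 0.4, len(class_ids)),
        },
        index=class_ids,
    )
    df.index.name = "class_id"
    return df


class TestHelmertScheme:
    def test_rows_sum_to_zero_and_orthogonal(self):
        h = helmert_scheme().to_numpy()
        assert h.sum(axis=1) == pytest.approx(np.zeros(4), abs=1e-12)
        gram = h @ h.T
        assert gram - np.diag(np.diag(gram)) == pytest.approx(np.zeros((4, 4)),
                                                              abs=1e-12)

    def test_contrasts_equal_cell_mean_differences(self):
        """Each estimate is the plain difference of the two group means."""
        rng = np.random.default_rng(2)
        res = simulate_results(rng, n_classes=10)
        means = res.groupby("condition")["success_rate"].mean()
        fit = fit_condition_model(res)
        h = helmert_scheme()
        interventions = means[["random", "in_degree", "betweenness", "closeness"]].mean()
        centrality = means[["in_degree", "betweenness", "closeness"]].mean()
        hand = {
            "interventions_vs_control": interventions - means["control"],
            "centrality_vs_random": centrality - means["random"],
            "betw_clos_vs_indegree":
                means[["betweenness", "closeness"]].mean() - means["in_degree"],
            "closeness_vs_betweenness": means["closeness"] - means["betweenness"],
        }
        for name, value in hand.items():
            assert fit.table.loc[name, "estimate"] == pytest.approx(value)


class TestConditionModel:
    def test_null_data_gives_zero_estimates(self):
        rows = [{"class_id": f"C{i}", "condition": c, "success_rate": 5.0 + i}
                for i in range(6) for c in CONDS]
        fit = fit_condition_model(pd.DataFrame(rows))
        assert fit.table["estimate"].to_numpy() == pytest.approx(np.zeros(4),
                                                                 abs=1e-8)

    def test_planted_intervention_effect_detected(self):
        rng = np.random.default_rng(3)
        res = simulate_results(rng, effects={c: 1.0 for c in CONDS if c != "control"})
        fit = fit_condition_model(res)
        row = fit.table.loc["interventions_vs_control"]
        assert row["estimate"] > 0
        assert row["p"] < 0.01

    def test_balanced_satterthwaite_df(self):
        """Within-class contrasts in a balanced design carry (g-1)(n-1) df."""
        rng = np.random.default_rng(4)
        fit = fit_condition_model(simulate_results(rng, n_classes=26))
        assert fit.table["df"].to_numpy() == pytest.approx([100.0] * 4, rel=1e-3)

    def test_missing_condition_rejected(self):
        rng = np.random.default_rng(5)
        res = simulate_results(rng, n_classes=4)
        with pytest.raises(ValueError):
            fit_condition_model(res[res.condition != "random"])

    def test_matches_lmer_satterthwaite_oracle(self, tmp_path):
        """Cross-check estimate, SE, df and p against lmerTest on an
        unbalanced table (REML + Satterthwaite reference implementation)."""
        rng = np.random.default_rng(8)
        res = simulate_results(rng, n_classes=8).drop(index=[3, 17]).reset_index(drop=True)
        fit = fit_condition_model(res)
        csv = tmp_path / "res.csv"
        res.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$condition <- factor(d$condition,
                levels=c("control","random","in_degree","betweenness","closeness"))
            m <- lmer(success_rate ~ condition + (1|class_id), data=d, REML=TRUE)
            L <- c(0, 1/4, 1/4, 1/4, 1/4)  # interventions vs control
            ct <- lmerTest::contest1D(m, L)
            cat(jsonlite::toJSON(as.list(ct), digits=12))
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        ref = {k: v[0] for k, v in json.loads(out.stdout).items()}
        row = fit.table.loc["interventions_vs_control"]
        assert row["estimate"] == pytest.approx(ref["Estimate"], rel=1e-4)
        assert row["se"] == pytest.approx(ref["Std. Error"], rel=1e-3)
        assert row["df"] == pytest.approx(ref["df"], rel=0.02)
        assert row["p"] == pytest.approx(ref["Pr(>|t|)"], rel=0.02)


class TestRmAnova:
    def test_epsilon_in_unit_interval(self):
        rng = np.random.default_rng(6)
        out = rm_anova_sphericity(simulate_results(rng))
        assert 0.0 < out["epsilon_hf"] <= 1.0

    def test_mauchly_type_one_error_near_nominal(self):
        """Compound-symmetric data satisfy sphericity: Mauchly should reject
        at roughly the nominal 5% rate."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            res = simulate_results(rng, n_classes=40, class_sd=1.0, noise_sd=1.0)
            out = rm_anova_sphericity(res)
            rejections += out["mauchly_p"] < 0.05
        rate = rejections / n_sims
        assert 0.02 <= rate <= 0.09

    def test_power_for_planted_condition_effect(self):
        """A condition effect of one residual SD is detected with power > .8."""
        rng = np.random.default_rng(8)
        detected = 0
        n_sims = 100
        effects = {"closeness": 1.0, "in_degree": 0.5}
        for _ in range(n_sims):
            res = simulate_results(rng, effects=effects, noise_sd=1.0)
            detected += rm_anova_sphericity(res)["p"] < 0.05
        assert detected / n_sims > 0.8

    def test_too_few_conditions_rejected(self):
        rng = np.random.default_rng(9)
        res = simulate_results(rng, n_classes=6)
        res = res[res.condition.isin(["control", "random"])]
        with pytest.raises(ValueError):
            rm_anova_sphericity(res)


class TestModeration:
    def test_null_moderator_interactions_near_zero(self):
        rng = np.random.default_rng(10)
        ests = []
        for _ in range(40):
            res = simulate_results(rng)
            struct = random_structure(rng, sorted(res.class_id.unique()))
            fit = fit_moderation_model(res, "density", struct)
            ests.append(fit.table.loc["density:centrality_vs_random", "estimate"])
        assert abs(np.mean(ests)) < 0.15

    def test_moderator_main_effect_recovery(self):
        """success = baseline + c * standardized moderator recovers c."""
        rng = np.random.default_rng(11)
        c_true = 3.0
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            res = simulate_results(rng, class_sd=1.0, noise_sd=0.5)
            struct = random_structure(rng, sorted(res.class_id.unique()))
            z = (struct["density"] - struct["density"].mean()) / struct["density"].std()
            res = res.assign(success_rate=res.success_rate
                             + c_true * res.class_id.map(z).to_numpy())
            fit = fit_moderation_model(res, "density", struct)
            row = fit.table.loc["density"]
            ci = 1.96 * row["se"]
            hits += abs(row["estimate"] - c_true) <= ci
        assert hits / n_sims >= 0.9

    def test_zero_variance_moderator_rejected(self):
        rng = np.random.default_rng(12)
        res = simulate_results(rng, n_classes=6)
        struct = random_structure(rng, sorted(res.class_id.unique()))
        struct["density"] = 0.7
        with pytest.raises(ValueError):
            fit_moderation_model(res, "density", struct)


class TestStructureCorrelations:
    def test_success_equal_to_density_gives_unit_r(self):
        rng = np.random.default_rng(13)
        res = simulate_results(rng, n_classes=12)
        struct = random_structure(rng, sorted(res.class_id.unique()))
        res["success_rate"] = res.class_id.map(struct["density"]).to_numpy()
        r, _ = structure_correlations(res, struct)
        assert r.loc["density"].to_numpy() == pytest.approx(np.ones(4))

    def test_matrix_shape(self):
        rng = np.random.default_rng(14)
        res = simulate_results(rng, n_classes=8)
        struct = random_structure(rng, sorted(res.class_id.unique()))
        r, p = structure_correlations(res, struct)
        assert r.shape == p.shape == (4, 4)
        assert list(r.index) == list(STRUCTURE_MEASURES)

    def test_independent_columns_rarely_flagged(self):
        rng = np.random.default_rng(15)
        flags, cells = 0, 0
        for _ in range(30):
            res = simulate_results(rng)
            struct = random_structure(rng, sorted(res.class_id.unique()))
            _, p = structure_correlations(res, struct)
            flags += (p.to_numpy() < 0.05).sum()
            cells += p.size
        assert flags / cells < 0.12


def test_evaluate_report_is_json_serialisable():
    rng = np.random.default_rng(16)
    res = simulate_results(rng, n_classes=8)
    struct = random_structure(rng, sorted(res.class_id.unique()))
    report = evaluate(res, struct)
    dumped = json.dumps(report)
    assert "planned_contrasts" in dumped
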