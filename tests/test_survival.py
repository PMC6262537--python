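"""Risk score, median split, KM/log-rank/Cox, and external application."""

import numpy as np
import pandas as pd
import pytest

from cnasig import SimConfig, generate_cohort
from cnasig.association import test_blocks as run_block_tests
from cnasig.blocks import aggregate, build_blocks
from cnasig.enrichment import enrich_by_chromosome
from cnasig.signature import Signature, derive_signature, map_blocks_to_genes
from cnasig.survival import (
    HIGH,
    LOW,
    CoxConvergenceError,
    _logrank_chi2,
    apply_signature_external,
    cox_fit,
    dichotomize,
    km_estimate,
    logrank_test,
    risk_score,
    stratify,
)


def make_signature(gene_blocks):
    rows = [
        (sym, "chr1", i * 1000, i * 1000 + 500, "loss", tuple(blocks))
        for i, (sym, blocks) in enumerate(gene_blocks.items())
    ]
    return Signature(
        genes=pd.DataFrame(
            rows,
            columns=["symbol", "chromosome", "start", "end", "direction", "supporting_blocks"],
        ),
        funnel={},
    )


class TestRiskScore:
    def test_mean_over_three_genes(self):
        bm = pd.DataFrame(
            {"P1": [0.1, -0.2, 0.4]}, index=["b1", "b2", "b3"]
        )
        sig = make_signature({"G1": ["b1"], "G2": ["b2"], "G3": ["b3"]})
        assert risk_score(bm, sig)["P1"] == pytest.approx(0.1 / 3 - 0.2 / 3 + 0.4 / 3)

    def test_all_zero_scores(self):
        bm = pd.DataFrame({"P1": [0.0, 0.0]}, index=["b1", "b2"])
        sig = make_signature({"G1": ["b1"], "G2": ["b2"]})
        assert risk_score(bm, sig)["P1"] == 0.0

    def test_single_gene_reduces_to_identity(self):
        bm = pd.DataFrame({"P1": [0.37]}, index=["b1"])
        sig = make_signature({"G1": ["b1"]})
        assert risk_score(bm, sig)["P1"] == pytest.approx(0.37)

    def test_empty_signature_rejected(self):
        bm = pd.DataFrame({"P1": [0.0]}, index=["b1"])
        with pytest.raises(ValueError, match="empty"):
            risk_score(bm, make_signature({}))

    def test_gene_without_blocks_dropped_with_warning(self):
        bm = pd.DataFrame({"P1": [1.0, 2.0]}, index=["b1", "b2"])
        sig = make_signature({"G1": ["b1"], "G2": ["b2"], "G3": ["missing"]})
        with pytest.warns(UserWarning, match="G3"):
            s = risk_score(bm, sig)
        assert s["P1"] == pytest.approx(1.5)

    def test_too_few_matchable_genes_rejected(self):
        bm = pd.DataFrame({"P1": [1.0]}, index=["b1"])
        sig = make_signature({"G1": ["b1"], "G2": ["missing"]})
        with pytest.raises(ValueError, match="too few"):
            risk_score(bm, sig)


class TestDichotomize:
    def test_median_goes_high(self):
        groups, med = dichotomize(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert med == 2.0
        assert groups.tolist() == [HIGH, HIGH, LOW]

    def test_even_n_median_between(self):
        groups, med = dichotomize(pd.Series([1.0, 1.0, 2.0, 2.0], index=list("abcd")))
        assert med == 1.5
        assert groups.tolist() == [HIGH, HIGH, LOW, LOW]

    def test_tie_policy_low(self):
        groups, _ = dichotomize(pd.Series([1.0, 2.0, 3.0], index=list("abc")), tie_policy="low")
        assert groups.tolist() == [HIGH, LOW, LOW]

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize(pd.Series([5.0, 5.0, 5.0]))


class TestKaplanMeier:
    def test_two_events_by_hand(self):
        km = km_estimate([1.0, 2.0], [True, True], ["g", "g"])["g"].set_index("time")
        assert km.loc[1.0, "survival"] == pytest.approx(0.5)
        assert km.loc[2.0, "survival"] == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        km = km_estimate([5.0, 7.0, 9.0], [False] * 3, ["g"] * 3)["g"]
        assert (km["survival"] == 1.0).all()

    def test_single_patient_event(self):
        km = km_estimate([4.0], [True], ["g"])["g"].set_index("time")
        assert km.loc[4.0, "survival"] == 0.0

    def test_curves_nonincreasing_start_at_one(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 50)
        e = rng.random(50) < 0.7
        km = km_estimate(t, e, ["g"] * 50)["g"]
        s = km["survival"].to_numpy()
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()
        assert km["survival"].iloc[0] == 1.0 or km["time"].iloc[0] > 0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.exponential(10, 40).round(1))
        km = km_estimate(t, [True] * 40, ["g"] * 40)["g"].set_index("time")
        for time in np.unique(t):
            emp = (t > time).mean()
            assert km.loc[time, "survival"] == pytest.approx(emp)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [True] * 6
        g = ["a"] * 3 + ["b"] * 3
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariant(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 30)
        e = rng.random(30) < 0.8
        g = np.array(["a"] * 15 + ["b"] * 15)
        chi2_a, p_a = logrank_test(t, e, g)
        chi2_b, p_b = logrank_test(t, e, np.where(g == "a", "b", "a"))
        assert chi2_a == pytest.approx(chi2_b, rel=1e-9)
        assert p_a == pytest.approx(p_b, rel=1e-9)

    # fixed n=8 fixture: clear but not overwhelming group separation
    FIX_T = np.array([3.0, 6.0, 9.0, 12.0, 5.0, 10.0, 15.0, 20.0])
    FIX_E = np.array([1, 1, 1, 1, 1, 1, 1, 0], dtype=bool)
    FIX_G = np.array(["A"] * 4 + ["B"] * 4)

    def test_exact_permutation_p_matches_mc_oracle(self):
        """Enumerated permutation p within Monte-Carlo error of a 1e5-draw null."""
        chi2, p_exact = logrank_test(self.FIX_T, self.FIX_E, self.FIX_G, p_method="permutation")
        rng = np.random.default_rng(12345)
        obs = _logrank_chi2(self.FIX_T, self.FIX_E, self.FIX_G == "A")
        hits = 0
        n_mc = 100_000
        for _ in range(n_mc):
            mask = np.zeros(8, dtype=bool)
            mask[rng.choice(8, 4, replace=False)] = True
            hits += _logrank_chi2(self.FIX_T, self.FIX_E, mask) >= obs - 1e-12
        p_mc = hits / n_mc
        mc_tol = 4 * np.sqrt(p_mc * (1 - p_mc) / n_mc) + 1 / 70
        assert abs(p_exact - p_mc) < mc_tol

    def test_asymptotic_p_near_exact_at_small_n(self):
        """Chi-square p tracks the exact permutation p within 0.05 at n=8."""
        chi2_a, p_asym = logrank_test(self.FIX_T, self.FIX_E, self.FIX_G)
        chi2_e, p_exact = logrank_test(self.FIX_T, self.FIX_E, self.FIX_G, p_method="permutation")
        assert chi2_a == pytest.approx(chi2_e, rel=1e-9)
        assert abs(p_asym - p_exact) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [True, True], ["a", "a"])

    def test_type_one_error_calibrated(self):
        """Null (HR=1) rejection rate at alpha=0.05 stays in [0.03, 0.07]."""
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 400
        for _ in range(reps):
            t = rng.exponential(20, 200)
            c = rng.uniform(5, 60, 200)
            times = np.minimum(t, c)
            events = t <= c
            g = np.array(["a"] * 100 + ["b"] * 100)
            _, p = logrank_test(times, events, g)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestCox:
    def test_null_covariate_hr_near_one(self):
        """Independent covariate, n=500: mean HR over replicates in [0.85, 1.18]."""
        loghrs = []
        for rep in range(5):
            rng = np.random.default_rng(50 + rep)
            x = (rng.random(500) < 0.5).astype(int)
            t = rng.exponential(20, 500)
            c = rng.uniform(5, 60, 500)
            fit = cox_fit(pd.DataFrame({"x": x}), np.minimum(t, c), t <= c)
            loghrs.append(np.log(fit.loc["x", "hazard_ratio"]))
        assert 0.85 <= float(np.exp(np.mean(loghrs))) <= 1.18

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(60)
        loghrs = []
        for _ in range(5):
            x = (rng.random(400) < 0.5).astype(int)
            t = rng.exponential(1.0 / (0.05 * 3.0**x))
            c = rng.uniform(10, 80, 400)
            fit = cox_fit(pd.DataFrame({"x": x}), np.minimum(t, c), t <= c)
            loghrs.append(np.log(fit.loc["x", "hazard_ratio"]))
        assert float(np.exp(np.mean(loghrs))) == pytest.approx(3.0, rel=0.15)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(61)
        x = (rng.random(100) < 0.5).astype(int)
        t = rng.exponential(1.0 / (0.05 * 2.0**x))
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(100, bool))
        row = fit.loc["x"]
        assert row["ci95_low"] <= row["hazard_ratio"] <= row["ci95_high"]
        assert row["hazard_ratio"] > 0

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1, 1, 1]}), [1.0, 2.0, 3.0], [True, True, True])

    def test_perfect_separation_is_explicit_failure(self):
        # every event in one covariate level: monotone partial likelihood
        x = np.array([1] * 10 + [0] * 10)
        t = np.concatenate([np.linspace(1, 5, 10), np.linspace(50, 60, 10)])
        e = np.array([True] * 10 + [False] * 10)
        with pytest.raises((CoxConvergenceError, ValueError)):
            fit = cox_fit(pd.DataFrame({"x": x}), t, e)
            # if the optimizer technically converged, the CI must betray it
            if not np.isfinite(fit.loc["x", "ci95_high"]):
                raise CoxConvergenceError("monotone likelihood")

    def test_score_test_equals_logrank_without_ties(self):
        """Cox score statistic at beta=0 equals the log-rank chi-square."""
        rng = np.random.default_rng(70)
        x = (rng.random(60) < 0.5).astype(float)
        t = rng.exponential(1.0 / (0.04 * 2.0**x))
        assert len(np.unique(t)) == 60  # no ties
        e = np.ones(60, dtype=bool)
        # test-local score-statistic oracle
        order = np.argsort(t)
        ts, xs = t[order], x[order]
        u = i0 = 0.0
        for j in range(60):
            at_risk = xs[j:]
            xbar = at_risk.mean()
            u += xs[j] - xbar
            i0 += at_risk.var()
        score_stat = u**2 / i0
        chi2, _ = logrank_test(t, e, np.where(x == 1, "a", "b"))
        assert chi2 == pytest.approx(score_stat, abs=1e-6)


@pytest.fixture(scope="module")
def discovered():
    cfg = SimConfig(seed=7)
    matrix, probes, clinical, genes, truth = generate_cohort(cfg)
    blocks = build_blocks(probes, k=10)
    bm = aggregate(matrix, blocks)
    labels = clinical.set_index("patient_id")
    rec = run_block_tests(bm, labels["relapse"], "relapse").table
    syn = run_block_tests(bm, labels["synchronous"], "synchronous").table
    enrich = enrich_by_chromosome(rec, blocks)
    hotspots = list(enrich.loc[enrich["hotspot"], "chromosome"])
    gene_map = map_blocks_to_genes(blocks, genes)
    sig = derive_signature(rec, syn, hotspots, gene_map, blocks, genes)
    return matrix, probes, clinical, bm, sig, truth


class TestStratify:
    def test_groups_partition_and_curves_valid(self, discovered):
        matrix, probes, clinical, bm, sig, truth = discovered
        res = stratify(bm, sig, clinical)
        assert set(res.groups.unique()) == {HIGH, LOW}
        assert len(res.groups) == 21
        for df in res.km.values():
            s = df["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()
        assert 0 <= res.logrank_p <= 1

    def test_carriers_are_high_risk(self, discovered):
        matrix, probes, clinical, bm, sig, truth = discovered
        res = stratify(bm, sig, clinical)
        carrier_groups = res.groups.loc[truth.affected_patients]
        assert (carrier_groups == HIGH).all()

    def test_multivariate_model_reports_signature(self, discovered):
        matrix, probes, clinical, bm, sig, truth = discovered
        res = stratify(bm, sig, clinical)
        if res.cox_multivariate is not None:
            assert "low_risk_signature" in res.cox_multivariate.index
            row = res.cox_multivariate.loc["low_risk_signature"]
            assert row["ci95_low"] <= row["hazard_ratio"] <= row["ci95_high"]

    def test_low_risk_group_outlives_high_risk(self):
        """Across seeds, median RFS of the discovered low-risk group is longer."""
        wins = total = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed)
            matrix, probes, clinical, genes, truth = generate_cohort(cfg)
            blocks = build_blocks(probes, k=10)
            bm = aggregate(matrix, blocks)
            labels = clinical.set_index("patient_id")
            rec = run_block_tests(bm, labels["relapse"], "relapse").table
            syn = run_block_tests(bm, labels["synchronous"], "synchronous").table
            enrich = enrich_by_chromosome(rec, blocks)
            hotspots = list(enrich.loc[enrich["hotspot"], "chromosome"])
            sig = derive_signature(rec, syn, hotspots, map_blocks_to_genes(blocks, genes), blocks, genes)
            if len(sig.genes) < 1:
                continue
            res = stratify(bm, sig, clinical, with_cox=False)
            cl = clinical.set_index("patient_id")
            med_low = cl.loc[res.groups[res.groups == LOW].index, "rfs_time"].median()
            med_high = cl.loc[res.groups[res.groups == HIGH].index, "rfs_time"].median()
            wins += med_low > med_high
            total += 1
        assert total >= 8 and wins / total >= 0.9


class TestApplySignatureExternal:
    def test_identity_on_discovery_cohort(self, discovered):
        matrix, probes, clinical, bm, sig, truth = discovered
        direct = stratify(bm, sig, clinical, with_cox=False)
        external = apply_signature_external(bm, sig, clinical)
        pd.testing.assert_series_equal(direct.scores, external.scores)
        pd.testing.assert_series_equal(direct.groups, external.groups)
        assert direct.logrank_p == pytest.approx(external.logrank_p)

    def test_probe_level_matrix_with_interval_fallback(self, discovered):
        matrix, probes, clinical, bm, sig, truth = discovered
        res = apply_signature_external(matrix, sig, clinical, probes=probes)
        assert len(res.scores) == 21
        carrier_groups = res.groups.loc[truth.affected_patients]
        assert (carrier_groups == HIGH).all()

    def test_external_cohort_stratifies_survival(self, discovered):
        """Fresh synthetic cohorts: low-risk RFS advantage in >= 80% of seeds."""
        matrix, probes, clinical, bm, sig, truth = discovered
        hits = 0
        seeds = range(100, 110)
        for seed in seeds:
            cfg = SimConfig(n_patients=45, n_relapse=28, n_synchronous=28, seed=seed)
            m, pr, cl, g, t = generate_cohort(cfg)
            res = apply_signature_external(m, sig, cl, probes=pr)
            hits += res.logrank_p < 0.05
        assert hits / len(seeds) >= 0.8

    def test_gene_level_matrix_by_symbol(self, discovered):
        matrix, probes, clinical, bm, sig, truth = discovered
        gene_matrix = pd.DataFrame(
            {p: {row.symbol: bm.loc[list(row.supporting_blocks), p].mean() for row in sig.genes.itertuples()}
             for p in bm.columns}
        )
        res = apply_signature_external(gene_matrix, sig, clinical)
        direct = stratify(bm, sig, clinical, with_cox=False)
        pd.testing.assert_series_equal(res.scores, direct.scores, check_names=False)

    def test_matrix_without_signature_genes_rejected(self, discovered):
        matrix, probes, clinical, bm, sig, truth = discovered
        empty = pd.DataFrame({"P1": [0.0]}, index=["UNRELATED"])
        with pytest.raises(ValueError, match="matchable"):
            apply_signature_external(empty, sig, clinical)
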