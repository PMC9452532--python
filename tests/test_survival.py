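"""Cox solver, KM/log-rank, panel construction, the mutational score."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from esccmut import simulate as sim
from esccmut import survival as sv


def _sim_clin(n, seed=0, panel=None, probs=None, censoring=0.3):
    probs = probs or {"g0": 0.15, "g1": 0.10, "g2": 0.20}
    return sim.simulate_survival_cohort(probs, n, panel or {}, seed=seed,
                                        censoring_rate=censoring)


class TestCoxSolver:
    def test_matches_lifelines_estimates(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(1)
        n = 300
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(0, 1, n)])
        t = rng.exponential(1 / (0.05 * np.exp(0.7 * X[:, 0])))
        e = (rng.random(n) < 0.8).astype(int)
        fit = sv.cox_ph(X, t, e)
        df = pd.DataFrame(X, columns=["a", "b"]).assign(T=t, E=e)
        ll = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.beta, ll.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, ll.standard_errors_.values, atol=1e-5)

    def test_matches_lifelines_with_heavy_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(2)
        n = 200
        X = rng.integers(0, 2, (n, 1)).astype(float)
        t = rng.integers(1, 15, n).astype(float)   # many tied event times
        e = (rng.random(n) < 0.7).astype(int)
        fit = sv.cox_ph(X, t, e)
        df = pd.DataFrame(X, columns=["a"]).assign(T=t, E=e)
        ll = CoxPHFitter().fit(df, "T", "E")       # lifelines uses Efron ties
        np.testing.assert_allclose(fit.beta, ll.params_.values, atol=1e-5)

    def test_matches_brute_force_partial_likelihood(self):
        # generic numerical maximization of the Efron partial likelihood
        rng = np.random.default_rng(3)
        n = 150
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(0, 1, n)])
        t = np.round(rng.exponential(20, n), 0) + 1
        e = (rng.random(n) < 0.6).astype(int)

        def neg_ll(beta):
            order = np.argsort(t, kind="stable")
            ts, ds, Xs = t[order], e[order].astype(bool), X[order]
            eta = Xs @ beta
            w = np.exp(eta)
            ll = 0.0
            for ut in np.unique(ts[ds]):
                ev = ds & (ts == ut)
                risk = ts >= ut
                m = ev.sum()
                d0 = w[ev].sum()
                s0 = w[risk].sum()
                ll += eta[ev].sum()
                for l in range(m):
                    ll -= np.log(s0 - (l / m) * d0)
            return -ll

        brute = minimize(neg_ll, np.zeros(2), method="Nelder-Mead",
                         options={"xatol": 1e-8, "fatol": 1e-10})
        fit = sv.cox_ph(X, t, e)
        np.testing.assert_allclose(fit.beta, brute.x, atol=1e-4)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="events"):
            sv.cox_ph(np.ones((5, 1)), np.arange(1., 6.), np.zeros(5))


class TestAdjustedCox:
    def test_planted_hazard_ratio_recovered(self):
        hrs = []
        for rep in range(5):
            gm, clin = _sim_clin(3000, seed=rep, panel={"g0": float(np.log(2))})
            row = sv.adjusted_cox(gm, clin, "g0")
            hrs.append(row.hr)
        assert 1.6 <= np.median(hrs) <= 2.5

    def test_all_censored_reports_no_events(self):
        gm, clin = _sim_clin(200, seed=1, censoring=1.0)
        row = sv.adjusted_cox(gm, clin, "g0")
        assert not row.ok and row.reason == "no events"

    def test_constant_indicator_reports_reason(self):
        gm, clin = _sim_clin(200, seed=2)
        gm["g0"] = 0
        row = sv.adjusted_cox(gm, clin, "g0")
        assert row.reason == "constant mutation indicator"

    def test_ci_contains_point_estimate(self):
        gm, clin = _sim_clin(800, seed=3, panel={"g0": 0.5})
        row = sv.adjusted_cox(gm, clin, "g0")
        assert row.ci_low < row.hr < row.ci_high


class TestKMLogrank:
    def test_identical_groups_not_significant(self):
        gm, clin = _sim_clin(300, seed=4)
        doubled = pd.concat([clin, clin.assign(sample_id=clin["sample_id"] + "b")])
        groups = pd.Series(["a"] * 300 + ["b"] * 300,
                           index=doubled["sample_id"])
        out = sv.km_logrank(groups, doubled)
        assert out["p"] > 0.9

    def test_planted_group_difference_detected(self):
        gm, clin = _sim_clin(1000, seed=5, panel={"g0": float(np.log(2))},
                             probs={"g0": 0.5}, censoring=0.3)
        groups = gm["g0"].map({0: "wt", 1: "mut"})
        groups.index = gm.index
        out = sv.km_logrank(groups, clin)
        assert out["p"] < 0.001

    def test_single_group_is_error(self):
        gm, clin = _sim_clin(100, seed=6)
        with pytest.raises(ValueError):
            sv.km_logrank(pd.Series("only", index=gm.index), clin)


class TestMutationalScore:
    panel = ["A", "B", "C"]

    def test_score_counts_mutated_panel_genes(self):
        gm = pd.DataFrame({"A": [1, 0], "B": [1, 0], "C": [0, 0], "D": [1, 1]},
                          index=["p1", "p2"])
        score = sv.mutational_score(gm, self.panel)
        assert score["p1"] == 2 and score["p2"] == 0

    def test_multiple_hits_in_one_gene_count_once(self):
        # multiplicity enters as a count matrix; the score uses the indicator
        gm = pd.DataFrame({"A": [3], "B": [0], "C": [0]}, index=["p1"])
        assert sv.mutational_score(gm, self.panel)["p1"] == 1

    def test_empty_panel_is_error(self):
        gm = pd.DataFrame({"A": [1]})
        with pytest.raises(ValueError):
            sv.mutational_score(gm, [])

    def test_score_monotone_and_order_invariant(self):
        rng = np.random.default_rng(0)
        gm = pd.DataFrame(rng.integers(0, 2, (50, 3)), columns=self.panel)
        base = sv.mutational_score(gm, self.panel)
        rev = sv.mutational_score(gm, self.panel[::-1])
        assert (base == rev).all()
        gm2 = gm.copy()
        gm2.iloc[0, 0] = 1
        assert sv.mutational_score(gm2, self.panel).iloc[0] >= base.iloc[0]

    def test_bands(self):
        s = pd.Series([0, 1, 2, 5])
        assert list(sv.score_bands(s)) == ["0", "1", "2+", "2+"]


class TestBuildScorePanel:
    def test_subgroup_sign_flip_excluded(self):
        # a gene protective in early stage must fail criterion (b) even with
        # a harmful overall effect
        rng = np.random.default_rng(7)
        n = 4000
        gm = pd.DataFrame({"flip": rng.integers(0, 2, n),
                           "good": rng.integers(0, 2, n)})
        gm.index = pd.Index([f"p{i}" for i in range(n)], name="sample_id")
        clin = sim._draw_clinical(rng, list(gm.index), ["d"] * n,
                                  ["WGS"] * n, ["WGS"] * n).reset_index()
        from esccmut.ingest import stage_group
        clin["stage_group"] = stage_group(clin["stage"])
        early = clin["stage_group"].eq("early").to_numpy()
        lp = np.where(early, -0.8 * gm["flip"], 1.2 * gm["flip"]) \
            + 0.7 * gm["good"].to_numpy()
        rng2 = np.random.default_rng(8)
        tev = rng2.exponential(1 / (0.02 * np.exp(lp)))
        tc = rng2.exponential(1 / 0.01, n)
        clin["os_time"] = np.minimum(tev, tc)
        clin["os_event"] = (tev <= tc).astype(int)
        panel = sv.build_score_panel(gm, clin, n=2)
        audit = panel.audit.set_index("gene")
        assert "good" in panel.genes
        assert "flip" not in panel.genes
        assert not audit.loc["flip", "pass_subgroups"]

    def test_capture_exclusions_removed_from_candidates(self):
        gm, clin = _sim_clin(1500, seed=9, panel={"g0": 0.8, "g1": 0.8})
        panel = sv.build_score_panel(gm, clin, n=2, exclusions={"g0"})
        assert "g0" not in panel.genes

    def test_frequency_tie_broken_alphabetically(self):
        rng = np.random.default_rng(10)
        n = 2000
        flip = rng.integers(0, 2, n)
        _, clin = sim.simulate_survival_cohort({"x": 0.0}, n, {}, seed=11)
        gm = pd.DataFrame({"B_gene": flip, "A_gene": flip},  # identical columns
                          index=pd.Index(clin["sample_id"], name="sample_id"))
        lp = 0.9 * flip
        rng2 = np.random.default_rng(12)
        tev = rng2.exponential(1 / (0.02 * np.exp(lp)))
        clin["os_time"] = tev
        clin["os_event"] = 1
        panel = sv.build_score_panel(gm, clin, n=1)
        assert panel.genes == ["A_gene"]

    def test_fewer_candidates_than_requested_warns_never_pads(self):
        gm, clin = _sim_clin(500, seed=13)
        with pytest.warns(UserWarning, match="candidate"):
            panel = sv.build_score_panel(gm, clin, n=8)
        assert len(panel.genes) <= 8


class TestValidatePanel:
    def test_all_zero_scores_not_evaluable(self):
        gm, clin = _sim_clin(300, seed=14)
        gm[:] = 0
        res = sv.validate_panel(["g0"], gm, clin)
        assert not res.evaluable

    def test_planted_panel_validates_per_dataset(self):
        probs = {f"pg{i}": 0.10 for i in range(4)}
        probs.update({f"ng{i}": 0.05 for i in range(5)})
        truth = {f"pg{i}": float(np.log(1.8)) for i in range(4)}
        gm, clin = sim.simulate_survival_cohort(probs, 1200, truth, seed=15,
                                                n_datasets=6, censoring_rate=0.35)
        res = sv.validate_panel(list(truth), gm, clin)
        assert res.evaluable
        per_ds = res.per_dataset.dropna(subset=["hr"])
        assert (per_ds["hr"] > 1).mean() >= 0.8
        for grp in ("early", "late"):
            assert res.strata[grp]["logrank_p"] < 0.05

    def test_dose_response_on_held_out_cohort(self):
        probs = {f"pg{i}": 0.12 for i in range(4)}
        truth = {f"pg{i}": float(np.log(2.0)) for i in range(4)}
        gm, clin = sim.simulate_survival_cohort(probs, 2000, truth, seed=16,
                                                censoring_rate=0.3)
        res = sv.validate_panel(list(truth), gm, clin)
        for grp in ("early", "late"):
            hrs = res.strata[grp]["hr_band"]
            assert hrs["2+"]["hr"] > hrs["1"]["hr"] > 1


class TestRegionSurvival:
    def _records(self, positions, n_wt=50):
        rows = [{"sample_id": f"m{i}", "dataset_id": "d", "gene": "EP300",
                 "chrom": "EP300", "pos": p, "ref": "C", "alt": "T",
                 "variant_class": "Missense_Mutation"}
                for i, p in enumerate(positions)]
        recs = pd.DataFrame(rows)
        ids = [f"m{i}" for i in range(len(positions))] + [f"w{i}" for i in range(n_wt)]
        return recs, ids

    def test_region_outside_cds_is_error(self):
        recs, ids = self._records([10, 20])
        clin = pd.DataFrame({"sample_id": ids, "stage": "II",
                             "os_time": 1.0, "os_event": 1})
        with pytest.raises(ValueError, match="CDS"):
            sv.region_survival(recs, clin, "EP300", region=(500, 900), cds=(1, 400))

    def test_planted_region_effect_separates(self):
        rng = np.random.default_rng(17)
        n_in, n_out, n_wt = 150, 150, 1200
        positions = list(rng.integers(100, 200, n_in)) \
            + list(rng.integers(300, 400, n_out))
        recs, ids = self._records(positions, n_wt=n_wt)
        in_region = np.r_[np.ones(n_in), np.zeros(n_out + n_wt)]
        lp = 0.9 * in_region
        tev = rng.exponential(1 / (0.02 * np.exp(lp)))
        tc = rng.exponential(1 / 0.008, len(ids))
        clin = pd.DataFrame({
            "sample_id": ids,
            "stage": rng.choice(["I", "II", "III", "IV"], len(ids)),
            "os_time": np.minimum(tev, tc), "os_event": (tev <= tc).astype(int)})
        out = sv.region_survival(recs, clin, "EP300", region=(100, 250),
                                 cds=(1, 500))
        assert (out["strata"] == "in_region").sum() == n_in
        ps = [out[g]["p"] for g in ("early", "late") if out[g]]
        assert min(ps) < 0.01

    def test_all_mutations_in_region_two_strata_handled(self):
        recs, ids = self._records([100, 120, 140])
        rng = np.random.default_rng(18)
        clin = pd.DataFrame({"sample_id": ids, "stage": "II",
                             "os_time": rng.exponential(10, len(ids)),
                             "os_event": 1})
        out = sv.region_survival(recs, clin, "EP300", region=(50, 200))
        assert set(out["strata"].unique()) == {"in_region", "WT"}
        assert out["early"] is not None
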