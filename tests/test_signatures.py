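"""SBS96 construction, NMF extraction, rank survey, refitting, matching."""

import numpy as np
import pandas as pd
import pytest

from esccmut import simulate as sim
from esccmut import signatures as sg


class TestChannelConventions:
    def test_pyrimidine_reference_kept_as_is(self):
        assert sg.channel_of("C", "A", "A", "A") == "A[C>A]A"

    def test_purine_reference_reverse_complemented(self):
        # G>T in 5'-TGT-3' context is A[C>A]A on the pyrimidine strand
        assert sg.channel_of("G", "T", "T", "T") == "A[C>A]A"

    def test_ambiguous_base_is_none(self):
        assert sg.channel_of("C", "A", "N", "A") is None

    def test_channel_order_is_class_major(self):
        assert sg.CHANNELS96[0] == "A[C>A]A"
        assert sg.CHANNELS96[16] == "A[C>G]A"
        assert sg.CHANNELS96[95] == "T[T>G]T"
        assert len(set(sg.CHANNELS96)) == 96


class TestBuildSBS96:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt"])

    def test_single_snv_lands_in_expected_channel(self):
        genome = {"c": "AACAA"}
        m, rep = sg.build_sbs96(self._records([("s", "c", 3, "C", "A")]), genome)
        assert m.loc["s", "A[C>A]A"] == 1
        assert rep["n_used"] == 1

    def test_column_sums_match_brute_force_tally(self, toy_cohort):
        recs = toy_cohort.records.rename(columns={
            "Tumor_Sample_Barcode": "sample_id", "Chromosome": "chrom",
            "Start_Position": "pos", "Reference_Allele": "ref",
            "Tumor_Seq_Allele2": "alt"})
        m, rep = sg.build_sbs96(recs, toy_cohort.genome)
        # brute force: count channels directly
        tally = {}
        for row in recs.itertuples(index=False):
            if len(str(row.ref)) != 1 or len(str(row.alt)) != 1 \
                    or "-" in (row.ref, row.alt):
                continue
            seq = toy_cohort.genome[row.chrom]
            ch = sg.channel_of(row.ref, row.alt, seq[row.pos - 2], seq[row.pos])
            if ch:
                tally[ch] = tally.get(ch, 0) + 1
        for ch in sg.CHANNELS96:
            assert m[ch].sum() == tally.get(ch, 0)

    def test_generator_sbs_truth_reconstructed_exactly(self, toy_cohort):
        recs = toy_cohort.records.rename(columns={
            "Tumor_Sample_Barcode": "sample_id", "Chromosome": "chrom",
            "Start_Position": "pos", "Reference_Allele": "ref",
            "Tumor_Seq_Allele2": "alt"})
        sbs_recs = recs[recs["chrom"] == "sbs_source"]
        m, _ = sg.build_sbs96(sbs_recs, toy_cohort.genome)
        truth = toy_cohort.truth.sbs96_truth
        got = m.reindex(index=truth.index, fill_value=0)
        pd.testing.assert_frame_equal(got, truth, check_dtype=False)

    def test_invariant_under_genome_reverse_complement(self):
        genome = {"c": "ATGCATTCGA"}
        recs = self._records([("s", "c", 4, "C", "T"), ("s", "c", 7, "T", "G")])
        m1, _ = sg.build_sbs96(recs, genome)
        rc = sg.revcomp(genome["c"])
        L = len(genome["c"])
        flipped = self._records([
            ("s", "c", L - 4 + 1, sg.revcomp("C"), sg.revcomp("T")),
            ("s", "c", L - 7 + 1, sg.revcomp("T"), sg.revcomp("G"))])
        m2, _ = sg.build_sbs96(flipped, {"c": rc})
        pd.testing.assert_frame_equal(m1, m2)

    def test_non_snv_and_edge_records_reported(self):
        genome = {"c": "AACAA"}
        m, rep = sg.build_sbs96(self._records([
            ("s", "c", 3, "CA", "C"),    # deletion
            ("s", "c", 1, "A", "T"),     # no 5' context
        ]), genome)
        assert rep["n_non_snv"] == 1 and rep["n_off_contig"] == 1
        assert rep["n_used"] == 0


class TestNMF:
    def _exact_matrix(self, seed=0, n=40, k=3, identifiable=False):
        rng = np.random.default_rng(seed)
        if identifiable:
            # near-disjoint supports plus pure samples make the planted
            # factorization the unique exact one (up to permutation/scale)
            sigs = sim.random_signatures(k, seed=seed, sparsity=0.92)
            mix = rng.dirichlet(np.full(k, 0.3), size=n - 2 * k)
            expo = np.vstack([np.eye(k) * 1500, np.eye(k) * 800,
                              mix * rng.uniform(100, 2000, (n - 2 * k, 1))])
        else:
            sigs = sim.random_signatures(k, seed=seed)
            expo = rng.uniform(50, 2000, size=(n, k))
        V = expo @ sigs
        return (pd.DataFrame(V, columns=list(sg.CHANNELS96)),
                sigs, expo)

    def test_exact_factorization_recovered(self):
        M, sigs, _ = self._exact_matrix(identifiable=True)
        res = sg.nmf_factorize(M, 3, seed=1, max_iter=20000, tol=1e-16)
        rel_rss = res.rss / (M.to_numpy() ** 2).sum()
        assert rel_rss < 1e-6
        ref = pd.DataFrame(sigs, index=["a", "b", "c"], columns=M.columns)
        _, best = sg.cosine_match(res.signatures, ref)
        assert (best["similarity"] >= 0.999).all()
        assert set(best["best_match"]) == {"a", "b", "c"}  # a perfect matching

    def test_rank_one_closed_form(self):
        M, _, _ = self._exact_matrix(k=1)
        res = sg.nmf_factorize(M, 1, seed=0)
        profile = M.sum(axis=0) / M.to_numpy().sum()
        np.testing.assert_allclose(res.signatures.iloc[0], profile, atol=1e-4)

    def test_fixed_seed_is_deterministic(self):
        M, _, _ = self._exact_matrix(seed=3)
        a = sg.nmf_factorize(M, 3, seed=9)
        b = sg.nmf_factorize(M, 3, seed=9)
        pd.testing.assert_frame_equal(a.signatures, b.signatures)
        pd.testing.assert_frame_equal(a.exposures, b.exposures)

    def test_objective_non_increasing(self):
        M, _, _ = self._exact_matrix(seed=5)
        res = sg.nmf_factorize(M, 3, seed=2)
        h = res.objective_history
        assert np.all(np.diff(h) <= 1e-9 * h[0])

    def test_signature_rows_stochastic_and_ordered_by_contribution(self):
        M, _, _ = self._exact_matrix(seed=6)
        res = sg.nmf_factorize(M, 3, seed=0)
        np.testing.assert_allclose(res.signatures.sum(axis=1), 1.0, atol=1e-9)
        totals = res.exposures.sum(axis=0).to_numpy()
        assert np.all(np.diff(totals) <= 1e-9)

    def test_zero_rows_removed_with_warning(self):
        M, _, _ = self._exact_matrix(seed=7, n=20)
        M.iloc[0] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            res = sg.nmf_factorize(M, 2, seed=0)
        assert len(res.exposures) == 19

    def test_agrees_with_sklearn_reconstruction_error(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        M, _, _ = self._exact_matrix(seed=8, n=30)
        noisy = M + np.random.default_rng(0).poisson(2, size=M.shape)
        res = sg.nmf_factorize(noisy, 3, seed=0, max_iter=3000, tol=1e-10)
        skl = sklearn.NMF(3, solver="mu", beta_loss="frobenius", init="random",
                          random_state=0, max_iter=3000, tol=1e-10)
        W = skl.fit_transform(noisy.to_numpy(float))
        rss_skl = np.linalg.norm(noisy.to_numpy(float) - W @ skl.components_) ** 2
        assert res.rss <= rss_skl * 1.05


class TestRankSurveyAndSelection:
    def test_select_rank_worked_example(self):
        survey = sg.RankSurvey(ks=[2, 3, 4, 5, 6],
                               cophenetic={2: .99, 3: .98, 4: .97, 5: .80, 6: .79},
                               rss={k: 0 for k in range(2, 7)}, n_restarts=10)
        assert sg.select_rank(survey) == 4

    def test_flat_cophenetic_picks_smallest_with_warning(self):
        survey = sg.RankSurvey(ks=[2, 3, 4],
                               cophenetic={2: .9, 3: .9, 4: .9},
                               rss={2: 3, 3: 2, 4: 1}, n_restarts=10)
        with pytest.warns(UserWarning):
            assert sg.select_rank(survey) == 2

    def test_too_few_candidate_ranks_error(self):
        survey = sg.RankSurvey(ks=[2, 3], cophenetic={2: 1, 3: 1},
                               rss={2: 1, 3: 1}, n_restarts=5)
        with pytest.raises(ValueError):
            sg.select_rank(survey)

    def test_single_restart_warns_degenerate(self):
        M = pd.DataFrame(np.random.default_rng(0).poisson(5, (15, 96)),
                         columns=list(sg.CHANNELS96))
        with pytest.warns(UserWarning, match="restarts"):
            survey = sg.rank_survey(M, [2, 3, 4], n_restarts=1, seed=0, max_iter=50)
        assert all(survey.cophenetic[k] == 1.0 for k in survey.ks)

    def test_recovery_on_separated_signatures(self):
        sigs = sim.random_signatures(4, seed=1, sparsity=0.85)
        expo = sim.mixture_exposures(4, 150, seed=2)
        M = sim.simulate_sbs96(sigs, expo, [5000] * 150, seed=3)
        survey = sg.rank_survey(M, range(2, 7), n_restarts=12, seed=0,
                                max_iter=150, tol=1e-4)
        assert survey.cophenetic[4] > 0.99
        assert survey.rss[4] < survey.rss[2]
        assert survey.selected_k == 4


class TestRefitExposures:
    def test_exact_mixture_recovered(self):
        sigs = sim.random_signatures(2, seed=0)
        ref = pd.DataFrame(sigs, index=["A", "B"], columns=list(sg.CHANNELS96))
        v = 0.7 * sigs[0] + 0.3 * sigs[1]
        M = pd.DataFrame([v * 1000], columns=list(sg.CHANNELS96))
        expo = sg.refit_exposures(M, ref)
        frac = expo.div(expo.sum(axis=1), axis=0)
        np.testing.assert_allclose(frac.iloc[0], [0.7, 0.3], atol=1e-9)

    def test_single_support_sample(self):
        sigs = np.zeros((2, 96))
        sigs[0, :10] = 0.1
        sigs[1, 90:] = 1 / 6
        ref = pd.DataFrame(sigs, index=["A", "B"], columns=list(sg.CHANNELS96))
        M = pd.DataFrame([sigs[0] * 500], columns=list(sg.CHANNELS96))
        expo = sg.refit_exposures(M, ref)
        assert expo.iloc[0, 0] > 0 and expo.iloc[0, 1] == 0

    def test_zero_count_sample_gets_zero_exposures(self):
        sigs = sim.random_signatures(2, seed=1)
        ref = pd.DataFrame(sigs, index=["A", "B"], columns=list(sg.CHANNELS96))
        M = pd.DataFrame(np.zeros((1, 96)), columns=list(sg.CHANNELS96))
        expo = sg.refit_exposures(M, ref)
        assert (expo.to_numpy() == 0).all()

    def test_refit_error_not_worse_than_training_error(self):
        rng = np.random.default_rng(4)
        sigs = sim.random_signatures(3, seed=4)
        expo = rng.uniform(100, 1000, (30, 3))
        M = pd.DataFrame(rng.poisson(expo @ sigs), columns=list(sg.CHANNELS96))
        res = sg.nmf_factorize(M, 3, seed=0, max_iter=3000, tol=1e-10)
        refit = sg.refit_exposures(M, res.signatures)
        rss_refit = np.linalg.norm(
            M.to_numpy(float) - refit.to_numpy() @ res.signatures.to_numpy()) ** 2
        assert rss_refit <= res.rss * (1 + 1e-9)


class TestCosineAndClusters:
    def test_identical_and_orthogonal_vectors(self):
        a = np.zeros((1, 96)); a[0, :4] = 0.25
        b = np.zeros((1, 96)); b[0, 4:8] = 0.25
        sigs = pd.DataFrame(np.vstack([a, b]), index=["s1", "s2"],
                            columns=list(sg.CHANNELS96))
        simm, best = sg.cosine_match(sigs, sigs)
        assert simm.loc["s1", "s1"] == pytest.approx(1.0)
        assert simm.loc["s1", "s2"] == pytest.approx(0.0)

    def test_catalog_parsing_both_dialects(self, tmp_path):
        sigs = sim.random_signatures(2, seed=0)
        # dialect 1: row labels
        p1 = tmp_path / "cat1.tsv"
        pd.DataFrame({"Type": list(sg.CHANNELS96), "S1": sigs[0], "S2": sigs[1]}
                     ).to_csv(p1, sep="\t", index=False)
        c1 = sg.read_catalog(p1)
        # dialect 2: COSMIC Type/SubType columns
        p2 = tmp_path / "cat2.tsv"
        pd.DataFrame({"Type": [c[2:5] for c in sg.CHANNELS96],
                      "SubType": [c[0] + c[2] + c[6] for c in sg.CHANNELS96],
                      "S1": sigs[0], "S2": sigs[1]}).to_csv(p2, sep="\t", index=False)
        c2 = sg.read_catalog(p2)
        pd.testing.assert_frame_equal(c1, c2)
        assert list(c1.columns) == list(sg.CHANNELS96)

    def test_dominant_cluster_assignment_and_tiebreak(self):
        expo = pd.DataFrame([[0.6, 0.4], [0.5, 0.5], [0.1, 0.9]],
                            columns=["sig1", "sig2"], index=["a", "b", "c"])
        labels, table = sg.dominant_cluster(expo)
        assert labels["a"] == "sig1"
        assert labels["b"] == "sig1"   # exact tie -> lower index
        assert labels["c"] == "sig2"
        assert table.loc["sig1", "n"] == 2

    def test_cluster_sizes_track_planted_groups(self):
        sigs = sim.random_signatures(3, seed=2, sparsity=0.85)
        expo_truth = np.repeat(np.eye(3), [60, 30, 10], axis=0)
        M = sim.simulate_sbs96(sigs, expo_truth, [2000] * 100, seed=5)
        ref = pd.DataFrame(sigs, index=["sig1", "sig2", "sig3"],
                           columns=list(sg.CHANNELS96))
        expo = sg.refit_exposures(M, ref)
        _, table = sg.dominant_cluster(expo)
        for name, planted in zip(["sig1", "sig2", "sig3"], [60, 30, 10]):
            sd = np.sqrt(planted * (1 - planted / 100))
            assert abs(table.loc[name, "n"] - planted) <= max(3 * sd, 3)
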