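import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from cpgrank.core_io import BetaMatrix, ValidationError
from cpgrank.signature_cluster import (
    Signature,
    apply_signature,
    cluster_purity,
    cut_clusters,
    global_methylation_change,
    hierarchical_cluster,
    pca_embed,
    zscore_rows,
)
from cpgrank.synthetic import SimulationConfig, samples_from_profile, simulate_cohort
from conftest import random_beta_matrix


class TestZscore:
    def test_two_value_row(self):
        m = BetaMatrix(pd.DataFrame([[0.0, 1.0]], index=["cg1"], columns=["a", "b"]))
        z = zscore_rows(m)
        np.testing.assert_allclose(z.loc["cg1"], [-0.7071, 0.7071], atol=1e-4)

    def test_constant_row_zeroed_with_warning(self):
        m = BetaMatrix(
            pd.DataFrame([[0.4, 0.4, 0.4]], index=["cg1"], columns=["a", "b", "c"])
        )
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_rows(m)
        np.testing.assert_array_equal(z.loc["cg1"], [0, 0, 0])

    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        z = zscore_rows(random_beta_matrix(rng, n_probes=40, n_samples=10))
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        m = random_beta_matrix(rng, n_probes=20, n_samples=6)
        scaled = BetaMatrix((m.values * 0.5 + 0.2).clip(0, 1))
        np.testing.assert_allclose(
            zscore_rows(m), zscore_rows(scaled), atol=1e-9
        )

    def test_short_rows_excluded_with_warning(self):
        vals = pd.DataFrame(
            [[0.1, 0.2, 0.3], [0.4, np.nan, np.nan]],
            index=["ok", "short"], columns=["a", "b", "c"],
        )
        with pytest.warns(UserWarning, match="<2 values"):
            z = zscore_rows(BetaMatrix(vals))
        assert list(z.index) == ["ok"]


class TestHierarchicalClustering:
    def test_two_samples_merge_at_euclidean_distance(self):
        df = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0]}, index=["p1", "p2"])
        tree = hierarchical_cluster(df)
        assert tree.merges.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(5.0)

    def test_distances_match_brute_force(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 20)))
        df.columns = [f"s{i}" for i in range(20)]
        d_oracle = np.array(
            [
                np.sqrt(((df[a] - df[b]) ** 2).sum())
                for i, a in enumerate(df.columns)
                for b in df.columns[i + 1:]
            ]
        )
        np.testing.assert_allclose(pdist(df.to_numpy().T), d_oracle, atol=1e-10)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(25, 12)),
                          columns=[f"s{i}" for i in range(12)])
        tree = hierarchical_cluster(df)
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 10)),
                          columns=[f"s{i}" for i in range(10)])
        t1 = hierarchical_cluster(df)
        t2 = hierarchical_cluster(df.sample(frac=1, random_state=7))
        l1 = cut_clusters(t1, 3)
        l2 = cut_clusters(t2, 3)
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_separated_groups_recovered_exactly(self):
        """Two well-separated synthetic groups: k=2 cut has ARI 1.0."""
        rng_ids = [f"cg{i}" for i in range(300)]
        mu_a = np.full(300, 0.3)
        mu_b = mu_a.copy()
        mu_b[:200] += 0.4  # signature probes strongly shifted
        a = samples_from_profile(mu_a, rng_ids, 10, 100, seed=11, prefix="a")
        b = samples_from_profile(mu_b, rng_ids, 10, 100, seed=12, prefix="b")
        joint = BetaMatrix(pd.concat([a.values, b.values], axis=1))
        z = zscore_rows(joint)
        labels = cut_clusters(hierarchical_cluster(z), 2)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(labels, truth) == 1.0

    def test_cut_extremes(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(10, 5)),
                          columns=[f"s{i}" for i in range(5)])
        tree = hierarchical_cluster(df)
        assert cut_clusters(tree, 1).nunique() == 1
        assert cut_clusters(tree, 5).nunique() == 5
        with pytest.raises(ValidationError):
            cut_clusters(tree, 6)

    def test_single_sample_rejected(self):
        df = pd.DataFrame({"only": [0.1, 0.2]})
        with pytest.raises(ValidationError):
            hierarchical_cluster(df)


class TestClusterPurity:
    def test_pure_cluster(self):
        labels = pd.Series([1] * 5, index=[f"s{i}" for i in range(5)])
        classes = pd.Series(["responder"] * 5, index=labels.index)
        rep = cluster_purity(labels, classes)
        assert rep.loc[1, "pure"]

    def test_mixed_cluster_composition(self):
        labels = pd.Series([1] * 5, index=[f"s{i}" for i in range(5)])
        classes = pd.Series(
            ["responder"] * 3 + ["nonresponder"] * 2, index=labels.index
        )
        rep = cluster_purity(labels, classes)
        assert not rep.loc[1, "pure"]
        assert rep.loc[1, "composition"] == {"responder": 3, "nonresponder": 2}

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(7)
        idx = [f"s{i}" for i in range(40)]
        labels = pd.Series(rng.integers(1, 4, 40), index=idx)
        classes = pd.Series(rng.choice(["x", "y"], 40), index=idx)
        rep = cluster_purity(labels, classes)
        for cl in rep.index:
            members = [s for s in idx if labels[s] == cl]
            tally = {}
            for s in members:
                tally[classes[s]] = tally.get(classes[s], 0) + 1
            assert rep.loc[cl, "composition"] == tally
            assert rep.loc[cl, "size"] == len(members)


class TestApplySignature:
    def _training(self):
        ids = [f"cg{i}" for i in range(100)]
        mu1 = np.full(100, 0.7)
        mu2 = np.full(100, 0.3)
        a = samples_from_profile(mu1, ids, 8, 100, seed=21, prefix="r")
        b = samples_from_profile(mu2, ids, 8, 100, seed=22, prefix="n")
        m = BetaMatrix(pd.concat([a.values, b.values], axis=1))
        table = pd.DataFrame(
            {
                "direction": 1,
                "mean_group1": mu1,
                "mean_group2": mu2,
                "combined_rank": np.arange(1, 101),
            },
            index=pd.Index(ids, name="probe_id"),
        )
        sig = Signature(table, group_names=("responder", "nonresponder"))
        return sig, m

    def test_reference_sample_assigned_to_own_group(self):
        sig, m = self._training()
        _, _, assignment = apply_signature(sig, m)
        for s in m.sample_ids:
            expected = "responder" if s.startswith("r") else "nonresponder"
            assert assignment.loc[s, "predicted"] == expected

    def test_self_application_reproduces_training_clustering(self):
        sig, m = self._training()
        z_train = zscore_rows(m.subset_probes(sig.probe_ids))
        t_train = hierarchical_cluster(z_train)
        z_apply, t_apply, _ = apply_signature(sig, m)
        l1 = cut_clusters(t_train, 2)
        l2 = cut_clusters(t_apply, 2)
        assert adjusted_rand_score(l1.reindex(l2.index), l2) == 1.0
        np.testing.assert_allclose(z_apply.loc[z_train.index], z_train, atol=1e-12)

    def test_followup_from_responder_profile_classified_responder(self):
        sig, m = self._training()
        new = samples_from_profile(
            sig.table["mean_group1"].to_numpy(), list(sig.probe_ids), 5, 100,
            seed=23, prefix="fu",
        )
        _, _, assignment = apply_signature(sig, new, m_reference=m)
        assert (assignment["predicted"] == "responder").all()

    def test_third_profile_has_low_margin(self):
        sig, m = self._training()
        mid = (sig.table["mean_group1"] + sig.table["mean_group2"]) / 2
        prog = samples_from_profile(mid.to_numpy(), list(sig.probe_ids), 6, 100,
                                    seed=24, prefix="prog")
        held = samples_from_profile(sig.table["mean_group1"].to_numpy(),
                                    list(sig.probe_ids), 6, 100, seed=25, prefix="h")
        _, _, a_prog = apply_signature(sig, prog, m_reference=m)
        _, _, a_held = apply_signature(sig, held, m_reference=m)
        assert a_prog["margin"].mean() < a_held["margin"].mean() / 3

    def test_low_coverage_errors(self):
        sig, m = self._training()
        small = m.subset_probes(list(sig.probe_ids[:30]))
        with pytest.raises(ValidationError, match="signature probes present"):
            apply_signature(sig, small)

    def test_signature_tsv_round_trip(self, tmp_path):
        sig, _ = self._training()
        p = tmp_path / "sig.tsv"
        sig.to_tsv(p)
        back = Signature.from_tsv(p)
        assert back.group_names == sig.group_names
        pd.testing.assert_frame_equal(
            back.table, sig.table, check_dtype=False
        )


class TestPCA:
    def test_rank_one_data_explained_by_pc1(self):
        t = np.linspace(0, 1, 6)
        base = np.linspace(0.2, 0.8, 30)
        vals = pd.DataFrame(
            {f"s{i}": np.clip(base * ti + 0.1, 0, 1) for i, ti in enumerate(t)},
            index=[f"cg{i}" for i in range(30)],
        )
        coords, evr = pca_embed(BetaMatrix(vals))
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_fractions_valid(self):
        rng = np.random.default_rng(8)
        m = random_beta_matrix(rng, n_probes=50, n_samples=10)
        _, evr = pca_embed(m, n_components=5)
        assert evr.sum() <= 1 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()

    def test_controls_tighter_than_patients(self):
        """Tight (high-precision) controls disperse less in PC space than
        heterogeneous (low-precision) patients."""
        ids = [f"cg{i}" for i in range(400)]
        mu = np.clip(np.random.default_rng(9).uniform(0.1, 0.9, 400), 0.05, 0.95)
        controls = samples_from_profile(mu, ids, 8, 200, seed=31, prefix="c")
        patients = samples_from_profile(mu, ids, 8, 20, seed=32, prefix="p")
        joint = BetaMatrix(pd.concat([controls.values, patients.values], axis=1))
        coords, _ = pca_embed(joint)
        def dispersion(prefix):
            sub = coords.loc[[s for s in coords.index if s.startswith(prefix)]]
            c = sub.mean()
            return np.sqrt(((sub - c) ** 2).sum(axis=1)).mean()
        assert dispersion("c") < dispersion("p")

    def test_degenerate_matrix_errors(self):
        m = BetaMatrix(
            pd.DataFrame(0.5, index=[f"cg{i}" for i in range(5)],
                         columns=["a", "b", "c"])
        )
        with pytest.raises(ValidationError):
            pca_embed(m)


class TestGlobalMethylationChange:
    def _paired(self, shift):
        from cpgrank.core_io import SampleSheet, SAMPLE_SHEET_COLUMNS

        rng = np.random.default_rng(10)
        dx = rng.uniform(0.2, 0.8, 500)
        vals = pd.DataFrame(
            {"s1_dx": dx, "s1_fu": np.clip(dx + shift, 0, 1)},
            index=[f"cg{i}" for i in range(500)],
        )
        rows = [
            dict(sample_id="s1_dx", subject_id="s1", timepoint="diagnosis",
                 disease="MDS", treatment="AZA", response="responder",
                 os_months=10, os_event=1, pfs_months=8, pfs_event=1,
                 reference_replicate_group=np.nan),
            dict(sample_id="s1_fu", subject_id="s1", timepoint="followup",
                 disease="MDS", treatment="AZA", response="responder",
                 os_months=10, os_event=1, pfs_months=8, pfs_event=1,
                 reference_replicate_group=np.nan),
        ]
        sheet = SampleSheet(pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS))
        return BetaMatrix(vals), sheet

    def test_identical_timepoints_give_zero(self):
        m, sheet = self._paired(0.0)
        out = global_methylation_change(m, sheet)
        assert out.loc[0, "mean_change"] == pytest.approx(0.0)

    def test_uniform_decrease_recovered(self):
        m, sheet = self._paired(-0.1)
        out = global_methylation_change(m, sheet)
        assert out.loc[0, "mean_change"] == pytest.approx(-0.1, abs=1e-9)

    def test_treated_decrease_exceeds_untreated(self):
        from cpgrank.synthetic import simulate_followup

        cfg = SimulationConfig(
            n_probes=2000, planted_sites=0,
            n_per_group={"MDS": 8}, followup_demethylation=0.08,
            followup_noise_sd=0.02, seed=33,
        )
        beta, sheet, _, _ = simulate_cohort(cfg)
        # untreat half the subjects
        t = sheet.table.copy()
        subjects = t.loc[t["disease"] == "MDS", "subject_id"].tolist()
        from cpgrank.core_io import SampleSheet

        t.loc[t["subject_id"].isin(subjects[:4]), "treatment"] = "none"
        sheet = SampleSheet(t)
        b2, s2 = simulate_followup(beta, sheet, cfg)
        out = global_methylation_change(b2, s2)
        by_arm = out.groupby(out["treatment"] == "none")["mean_change"].mean()
        assert by_arm[False] < by_arm[True]  # treated change more negative
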