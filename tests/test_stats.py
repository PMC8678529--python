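import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from swayclust.cluster import pam_cluster
from swayclust.dtw import dtw_distance_matrix
from swayclust.features import featurize
from swayclust.preprocess import preprocess_cohort
from swayclust.stats import (
    benjamini_hochberg,
    build_significance_table,
    build_transition_table,
    cluster_characteristics,
    gate_test_choice,
    pairwise_tukey,
    pairwise_wilcoxon_bh,
)
from swayclust.synthetic import (
    CohortSpec,
    SubjectSpec,
    generate_cohort,
    planted_onset_drift,
)


class TestGate:
    def test_normal_homogeneous_groups_mostly_take_tukey(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(0, 1, 50) for _ in range(4)]
            hits += gate_test_choice(groups) == "tukey"
        # five gate tests at alpha=0.05 each: expect ~(0.95)^5 ~ 77% tukey
        assert hits >= 12

    def test_lognormal_group_forces_wilcoxon(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            groups = [rng.normal(0, 1, 50) for _ in range(3)]
            groups.append(np.exp(rng.normal(0, 1.5, 50)))
            hits += gate_test_choice(groups) == "wilcoxon"
        assert hits >= 9

    def test_constant_groups_fall_back_to_wilcoxon(self):
        groups = [np.full(10, 1.0), np.full(10, 1.0)]
        assert gate_test_choice(groups) == "wilcoxon"

    def test_small_groups_excluded_with_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="excluded"):
            gate_test_choice([rng.normal(size=50), rng.normal(size=50), np.zeros(2)])
        with pytest.raises(ValueError, match="two groups"):
            gate_test_choice([np.zeros(2), np.ones(50)])


class TestBH:
    def test_hand_computed_step_up_example(self):
        raw = np.array([0.01, 0.02, 0.04, 0.30])
        adj = benjamini_hochberg(raw)
        assert adj == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.30])

    def test_monotone_and_not_below_raw(self):
        rng = np.random.default_rng(2)
        raw = rng.uniform(size=25)
        adj = benjamini_hochberg(raw)
        assert (adj >= raw - 1e-12).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestPairwise:
    def test_overwhelming_shift_is_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(10, 1, 30)
        sig, adj = pairwise_wilcoxon_bh([a, b])
        assert sig == {(0, 1)}
        assert adj[(0, 1)] < 1e-6

    def test_identical_groups_not_significant(self):
        a = np.arange(20.0)
        sig, adj = pairwise_wilcoxon_bh([a, a.copy(), a.copy()])
        assert sig == set()
        assert all(p > 0.9 for p in adj.values())

    def test_identical_constant_groups_p_one(self):
        sig, adj = pairwise_wilcoxon_bh([np.full(10, 2.0), np.full(10, 2.0)])
        assert adj[(0, 1)] == 1.0

    def test_family_is_all_pairs(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 20) for _ in range(4)]
        _, adj = pairwise_wilcoxon_bh(groups)
        assert len(adj) == 6

    def test_tukey_branch_detects_mean_shift(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 40), rng.normal(0, 1, 40), rng.normal(5, 1, 40)]
        sig, _ = pairwise_tukey(groups)
        assert sig == {(0, 2), (1, 2)}


def amplitude_only_cohort(seed=0):
    """Two planted sway regimes differing only in amplitude."""
    roster = tuple(
        SubjectSpec(f"S{i}", "CH" if i < 3 else "CI", 60 + i, (100 * i + 60, 100 * i + 70), "left")
        for i in range(6)
    )
    spec = CohortSpec(
        roster=roster,
        k_true=2,
        cluster_frequencies=(1.0, 1.0),
        cluster_amplitude=(1.0, 6.0),
        duration=15.0,
        seed=seed,
    )
    return generate_cohort(spec)


class TestSignificanceTable:
    @pytest.fixture(scope="class")
    def table(self):
        recs, truth = amplitude_only_cohort()
        slots = preprocess_cohort(recs, 5.0)
        sol = pam_cluster(dtw_distance_matrix(slots), 2, restarts=5, seed=0)
        feats = featurize(slots, sol)
        return build_significance_table(feats)

    def test_has_33_rows_with_pair_sets(self, table):
        assert len(table) == 33
        assert list(table["index"]) == list(range(1, 34))
        assert set(table["amplitude_branch"]) <= {"tukey", "wilcoxon"}

    def test_amplitude_and_sd_dominate_over_frequency(self, table):
        amp_hits = (table["amplitude_pairs"] != "None").sum()
        sd_hits = (table["sd_pairs"] != "None").sum()
        freq_hits = (table["frequency_pairs"] != "None").sum()
        assert amp_hits >= 30
        assert sd_hits >= 30
        assert freq_hits < amp_hits
        assert freq_hits < sd_hits

    def test_single_cluster_rejected(self):
        recs, _ = amplitude_only_cohort()
        slots = preprocess_cohort(recs, 5.0)
        feats = featurize(slots, None)  # cluster column all 0
        with pytest.raises(ValueError):
            build_significance_table(feats)

    def test_null_false_positive_rate_bounded_over_simulated_families(self):
        # 100 all-null families of 4 groups: the fraction of families with
        # any BH-significant pair must stay within 3x the nominal level
        rng = np.random.default_rng(7)
        positives = 0
        for _ in range(100):
            groups = [rng.normal(0, 1, 30) for _ in range(4)]
            sig, _ = pairwise_wilcoxon_bh(groups, alpha=0.05)
            positives += bool(sig)
        assert positives / 100 <= 3 * 0.05

    def test_shuffled_pipeline_labels_rarely_significant(self):
        # destroy the cluster/value link in a real feature frame by
        # shuffling labels across slots; positives should be rare
        recs, _ = amplitude_only_cohort()
        slots = preprocess_cohort(recs, 5.0)
        sol = pam_cluster(dtw_distance_matrix(slots), 2, restarts=5, seed=0)
        feats = featurize(slots, sol)
        rng = np.random.default_rng(7)
        positives = families = 0
        for _ in range(10):
            perm = feats.copy()
            slot_ids = perm["slot_id"].unique()
            shuffled = dict(
                zip(slot_ids, rng.permutation([1, 2] * (len(slot_ids) // 2)))
            )
            perm["cluster"] = perm["slot_id"].map(shuffled)
            table = build_significance_table(perm)
            for param in ("amplitude", "sd", "frequency"):
                families += 33
                positives += (table[f"{param}_pairs"] != "None").sum()
        assert positives / families <= 3 * 0.05


class TestTransitionTable:
    def test_majority_label_and_sorting(self, small_cohort):
        recs, truth = small_cohort
        slots = preprocess_cohort(recs, 5.0)
        sol = pam_cluster(dtw_distance_matrix(slots), 2, restarts=5, seed=0)
        table = build_transition_table(slots, sol)
        assert len(table) == len(recs)
        assert (
            table.sort_values(["subject_id", "days_after_onset"]).index
            == table.index
        ).all()
        for _, row in table.iterrows():
            labels = [int(v) for v in row["slot_labels"].split()]
            counts = pd.Series(labels).value_counts()
            top = counts[counts == counts.max()].index
            assert row["majority"] == min(top)
            assert row["tie"] == (len(top) > 1)

    def test_planted_majority_sequence_recovered(self):
        spec = planted_onset_drift(CohortSpec(duration=15.0, seed=2))
        recs, truth = generate_cohort(spec)
        slots = preprocess_cohort(recs, 5.0)
        sol = pam_cluster(dtw_distance_matrix(slots), 4, restarts=10, seed=0)
        table = build_transition_table(slots, sol)
        truth_by_key = dict(zip(truth.session_keys, truth.recording_labels))
        # majority labels must reproduce the planted partition exactly
        # (up to cluster renaming)
        mapping = {}
        for _, row in table.iterrows():
            t = truth_by_key[(row["subject_id"], row["days_after_onset"])]
            mapping.setdefault(row["majority"], set()).add(t)
        assert all(len(v) == 1 for v in mapping.values())
        assert len(mapping) == 4

    def test_ch_monotone_drift_ci_flat(self):
        spec = planted_onset_drift(CohortSpec(duration=15.0, seed=2))
        recs, truth = generate_cohort(spec)
        slots = preprocess_cohort(recs, 5.0)
        sol = pam_cluster(dtw_distance_matrix(slots), 4, restarts=10, seed=0)
        table = build_transition_table(slots, sol)
        truth_by_key = dict(zip(truth.session_keys, truth.recording_labels))
        table["truth"] = [
            truth_by_key[(r["subject_id"], r["days_after_onset"])]
            for _, r in table.iterrows()
        ]
        ch = table[table["disease"] == "CH"]
        rho = sps.spearmanr(ch["days_after_onset"], ch["truth"]).statistic
        assert rho < -0.9  # planted drift: later onset -> lower cluster id
        for _, sub in table[table["disease"] == "CI"].groupby("subject_id"):
            assert sub["truth"].nunique() == 1

    def test_missing_metadata_flagged(self, small_cohort):
        recs, _ = small_cohort
        slots = preprocess_cohort(recs, 5.0)
        for s in slots[:3]:
            s.metadata = dict(s.metadata, days_after_onset=-1)
        sol = pam_cluster(dtw_distance_matrix(slots), 2, restarts=3, seed=0)
        table = build_transition_table(slots, sol)
        assert table["metadata_missing"].sum() == 1


class TestOnsetOrdering:
    def test_relabel_orders_by_median_onset_and_preserves_partition(self):
        spec = planted_onset_drift(CohortSpec(duration=15.0, seed=2))
        recs, _ = generate_cohort(spec)
        slots = preprocess_cohort(recs, 5.0)
        dm = dtw_distance_matrix(slots)
        sol = pam_cluster(dm, 4, restarts=10, seed=0)
        from swayclust.stats import order_clusters_by_onset

        ordered = order_clusters_by_onset(slots, sol)
        # same partition, relabelled
        for k in range(4):
            members = ordered.members(k)
            assert len(set(sol.labels[members])) == 1
        chars = cluster_characteristics(slots, ordered)
        onset = chars.sort_values("cluster")["days_after_onset"].to_numpy()
        assert (np.diff(onset) <= 0).all()
        # validity indices are label-permutation invariant
        from swayclust.validity import davies_bouldin

        assert davies_bouldin(ordered) == pytest.approx(davies_bouldin(sol))
        assert ordered.total_cost == pytest.approx(sol.total_cost)


class TestClusterCharacteristics:
    def test_medians_and_disease_mix(self, small_cohort):
        recs, _ = small_cohort
        slots = preprocess_cohort(recs, 5.0)
        sol = pam_cluster(dtw_distance_matrix(slots), 2, restarts=5, seed=0)
        table = cluster_characteristics(slots, sol)
        assert set(table["cluster"]) == {1, 2}
        assert np.allclose(table["frac_CH"] + table["frac_CI"], 1.0)
        assert (table["days_after_onset"] > 0).all()
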