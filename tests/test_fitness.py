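"""Fitness inference: pre-processing rules, recovery, classification, concordance."""

import numpy as np
import pandas as pd
import pytest

from popfit import (
    CompetitionDesign,
    ModelConfig,
    aggregate,
    classify,
    fit_hierarchical,
    naive_frequencies,
    propagate_frequencies,
    remove_outlier_barcodes,
    replicate_concordance,
    simulate_competition,
)
from popfit.fitness import FitnessPosterior


def _counts(rows):
    return pd.DataFrame(rows, columns=["barcode_id", "edit_id", "replicate", "condition", "timepoint", "reads"])


class TestOutlierRemoval:
    def test_highest_total_removed(self):
        rows = [(f"b{i}", "e1", 1, "c", 0, r) for i, r in enumerate([100, 90, 80])]
        out = remove_outlier_barcodes(_counts(rows))
        assert sorted(out.barcode_id) == ["b1", "b2"]

    def test_single_barcode_untouched(self):
        out = remove_outlier_barcodes(_counts([("b0", "e1", 1, "c", 0, 100)]))
        assert len(out) == 1

    def test_neutral_anchor_untouched(self):
        rows = [("b0", "z1", 1, "c", 0, 100), ("b1", "z1", 1, "c", 0, 50)]
        out = remove_outlier_barcodes(_counts(rows), neutral_ids={"z1"})
        assert len(out) == 2

    def test_tie_broken_lexicographically(self):
        rows = [("bB", "e1", 1, "c", 0, 100), ("bA", "e1", 1, "c", 0, 100), ("bC", "e1", 1, "c", 0, 50)]
        out, log = remove_outlier_barcodes(_counts(rows), return_log=True)
        assert log.barcode_id.tolist() == ["bA"]
        assert sorted(out.barcode_id) == ["bB", "bC"]

    def test_per_stream_vs_global(self):
        rows = [
            ("b0", "e1", 1, "c", 0, 100), ("b1", "e1", 1, "c", 0, 10),
            ("b0", "e1", 2, "c", 0, 10), ("b1", "e1", 2, "c", 0, 100),
        ]
        per = remove_outlier_barcodes(_counts(rows))
        assert len(per) == 2  # a different barcode removed in each replicate
        glob = remove_outlier_barcodes(_counts(rows), per_stream=False)
        assert set(glob.barcode_id) == {"b1"} or set(glob.barcode_id) == {"b0"}


class TestAggregation:
    def test_sums_barcodes(self):
        rows = [("b0", "e1", 1, "c", 0, 5), ("b1", "e1", 1, "c", 0, 7)]
        agg = aggregate(_counts(rows))
        assert agg.loc[agg.edit_id == "e1", "reads"].iloc[0] == 12

    def test_matches_brute_force_group_sum(self):
        rng = np.random.default_rng(0)
        rows = []
        for b in range(30):
            edit = f"e{b % 7}"
            for rep in (1, 2):
                for t in range(3):
                    rows.append((f"b{b}", edit, rep, "c", t, int(rng.integers(0, 100))))
        table = _counts(rows)
        agg = aggregate(table)
        for _, row in agg.iterrows():
            expect = table[
                (table.edit_id == row.edit_id)
                & (table.replicate == row.replicate)
                & (table.timepoint == row.timepoint)
            ].reads.sum()
            assert row.reads == expect

    def test_missing_edit_kept_with_zeros(self):
        rows = [("b0", "e1", 1, "c", 0, 5), ("b0", "e1", 1, "c", 1, 6),
                ("b1", "e2", 1, "c", 0, 3)]
        agg = aggregate(_counts(rows))
        assert agg[(agg.edit_id == "e2") & (agg.timepoint == 1)].reads.iloc[0] == 0


class TestNaiveFrequencies:
    def test_plain_proportions(self):
        agg = pd.DataFrame(
            {"edit_id": ["a", "b"], "replicate": 1, "condition": "c", "timepoint": 0, "reads": [10, 30]}
        )
        f = naive_frequencies(agg, pseudocount=0.0)
        assert np.allclose(sorted(f.frequency), [0.25, 0.75])

    def test_single_edit_is_one(self):
        agg = pd.DataFrame(
            {"edit_id": ["a"] * 3, "replicate": 1, "condition": "c", "timepoint": [0, 1, 2], "reads": [5, 9, 2]}
        )
        assert np.allclose(naive_frequencies(agg, 0.0).frequency, 1.0)

    def test_pseudocount_hand_computed(self):
        agg = pd.DataFrame(
            {"edit_id": ["a", "b", "c"], "replicate": 1, "condition": "x", "timepoint": 0, "reads": [0, 0, 9]}
        )
        f = naive_frequencies(agg, pseudocount=0.5).frequency.to_numpy()
        assert np.allclose(sorted(f), np.array([0.5, 0.5, 9.5]) / 10.5)

    def test_all_zero_timepoint_named(self):
        agg = pd.DataFrame(
            {"edit_id": ["a", "b"], "replicate": 2, "condition": "x", "timepoint": 1, "reads": [0, 0]}
        )
        with pytest.raises(ValueError, match="replicate=2.*t=1"):
            naive_frequencies(agg, pseudocount=0.5)


def _near_noiseless_agg(s_map, neutral, n_timepoints=6, tau=1.0, depth=10**9):
    """Aggregated counts from the deterministic dynamics at huge depth."""
    edits = list(s_map)
    f0 = np.ones(len(edits)) / len(edits)
    traj = propagate_frequencies(f0, np.array([s_map[e] for e in edits]), tau, n_timepoints - 1)
    rows = []
    for rep in (1, 2):
        for t in range(n_timepoints):
            for i, e in enumerate(edits):
                rows.append((e, rep, "c", t, int(round(traj[t, i] * depth))))
    return pd.DataFrame(rows, columns=["edit_id", "replicate", "condition", "timepoint", "reads"])


class TestHierarchicalFit:
    def test_noiseless_two_edit_recovery(self):
        agg = _near_noiseless_agg({"e1": 0.1, "e2": 0.0, "z": 0.0}, {"z"})
        post, _, diags = fit_hierarchical(agg, {"z"}, ModelConfig(), tau=1.0)
        post = classify(post)
        s = post.summary.set_index("edit_id")
        assert abs(s.loc["e1", "phi_mean"] - 0.1) < 0.005
        assert s.loc["e2", "ci_lower"] <= 0 <= s.loc["e2", "ci_upper"]
        assert all(d["converged"] for d in diags.values())

    def test_recovery_on_simulated_data(self, small_design, small_competition, small_fit):
        _, truth = small_competition
        post, mean_fit, _, _ = small_fit
        cond = small_design.conditions[0]
        s_true = truth.s_vector(cond, small_design.edit_ids)
        est = post.summary.set_index("edit_id").loc[small_design.edit_ids, "phi_mean"].to_numpy()
        assert np.corrcoef(s_true, est)[0, 1] > 0.99
        assert np.sqrt(np.mean((s_true - est) ** 2)) < 0.01
        m = mean_fit.merge(truth.true_mean_fitness, on=["replicate", "condition", "timepoint"])
        assert np.corrcoef(m.mean_fitness_x, m.mean_fitness_y)[0, 1] > 0.9

    def test_anchoring_shift_invariance(self, small_design):
        # adding a constant to the true fitness of every lineage (anchors
        # included) only shifts the mean-fitness nuisance series, so the
        # inferred relative fitness is unchanged within posterior uncertainty
        from popfit.simulate import _simulate_counts

        neutral = set(small_design.neutral_ids)
        cond = small_design.conditions[0]
        base = {e: {cond: 0.1 * np.sin(i)} for i, e in enumerate(small_design.edit_ids)}
        base.update({z: {cond: 0.0} for z in neutral})
        results = []
        for c in (0.0, 0.05):
            s_map = {e: {cond: v[cond] + c} for e, v in base.items()}
            table, _ = _simulate_counts(small_design, s_map, set(), 0.0, small_design.seed)
            agg = aggregate(remove_outlier_barcodes(table, neutral_ids=neutral))
            post, _, _ = fit_hierarchical(agg, neutral, ModelConfig(), tau=small_design.tau)
            ss = post.summary.set_index("edit_id")
            results.append(
                (ss.loc[small_design.edit_ids, "phi_mean"].to_numpy(),
                 ss.loc[small_design.edit_ids, "phi_sd"].to_numpy())
            )
        (m0, sd0), (m1, sd1) = results
        z = np.abs(m0 - m1) / np.sqrt(sd0**2 + sd1**2)
        assert np.median(z) < 1.5 and np.quantile(z, 0.95) < 4.0

    def test_determinism(self, small_design, small_competition):
        table, _ = small_competition
        neutral = set(small_design.neutral_ids)
        agg = aggregate(remove_outlier_barcodes(table, neutral_ids=neutral))
        p1, m1, _ = fit_hierarchical(agg, neutral, ModelConfig(seed=1), tau=small_design.tau)
        p2, m2, _ = fit_hierarchical(agg, neutral, ModelConfig(seed=1), tau=small_design.tau)
        pd.testing.assert_frame_equal(p1.summary, p2.summary)
        pd.testing.assert_frame_equal(m1, m2)

    def test_missing_timepoint_transitions_dropped(self, small_design, small_competition):
        table, _ = small_competition
        neutral = set(small_design.neutral_ids)
        drop = (table.replicate == 1) & (table.timepoint == 2)
        agg = aggregate(table[~drop])
        post, _, diags = fit_hierarchical(agg, neutral, ModelConfig(), tau=small_design.tau)
        assert np.isfinite(post.summary.phi_mean).all()

    def test_requires_neutral_anchor(self):
        agg = pd.DataFrame(
            {"edit_id": ["a"], "replicate": 1, "condition": "c", "timepoint": 0, "reads": [5]}
        )
        with pytest.raises(ValueError, match="neutral"):
            fit_hierarchical(agg, set(), ModelConfig())

    def test_mcmc_engine_agrees_and_is_deterministic(self):
        agg = _near_noiseless_agg(
            {"e1": 0.08, "e2": -0.05, "e3": 0.0, "z": 0.0}, {"z"}, depth=10**7
        )
        cfg = ModelConfig(engine="mcmc", mcmc_steps=250, mcmc_burn=100, seed=3)
        post, _, diags = fit_hierarchical(agg, {"z"}, cfg, tau=1.0)
        s = post.summary.set_index("edit_id")
        assert abs(s.loc["e1", "phi_mean"] - 0.08) < 0.01
        assert abs(s.loc["e2", "phi_mean"] + 0.05) < 0.01
        post2, _, _ = fit_hierarchical(agg, {"z"}, cfg, tau=1.0)
        pd.testing.assert_frame_equal(post.summary, post2.summary)


class TestClassification:
    def _post(self, rows):
        summary = pd.DataFrame(rows, columns=["edit_id", "condition", "phi_mean", "phi_sd", "is_neutral_anchor"])
        return FitnessPosterior(summary=summary, rep_fitness=pd.DataFrame(
            columns=["edit_id", "condition", "replicate", "s_mean", "s_sd"]))

    def test_interval_rules(self):
        z = 1.959963984540054
        rows = [
            ("a", "1D", 0.005, 0.01 / z, False),   # interval [-0.005, 0.015] -> neutral
            ("b", "1D", 0.025, 0.0075 / z, False),  # [0.0175, 0.0325] -> beneficial
            ("c", "1D", -0.03, 0.01 / z, False),   # [-0.04, -0.02] -> deleterious
        ]
        out = classify(self._post(rows), 0.95).summary.set_index("edit_id")
        assert out.loc["a", "classification"] == "neutral"
        assert out.loc["b", "classification"] == "beneficial"
        assert out.loc["c", "classification"] == "deleterious"

    def test_condition_count_flags(self):
        z = 1.959963984540054
        rows = [
            ("a", "1D", 0.05, 0.005 / z, False),
            ("a", "2D", 0.00, 0.010 / z, False),
            ("a", "3D", 0.06, 0.005 / z, False),
            ("b", "1D", 0.00, 0.010 / z, False),
            ("b", "2D", 0.00, 0.010 / z, False),
            ("b", "3D", 0.00, 0.010 / z, False),
        ]
        post = classify(self._post(rows), 0.95)
        flags = post.edit_flags.set_index("edit_id")
        assert flags.loc["a", "n_conditions_non_neutral"] == 2
        assert bool(flags.loc["a", "non_neutral_ge2"])
        assert flags.loc["b", "n_conditions_non_neutral"] == 0
        assert not bool(flags.loc["b", "non_neutral_ge1"])
        assert bool(flags.loc["a", "beneficial_ge1"])

    def test_anchors_always_neutral(self):
        rows = [("z", "1D", 0.0, 0.0, True)]
        out = classify(self._post(rows), 0.95).summary
        assert (out.classification == "neutral").all()


class TestReplicateConcordance:
    def _post_with_reps(self, estimates):
        z = 1.959963984540054
        edits = list(estimates)
        summary = pd.DataFrame(
            [(e, "1D", 0.1, 0.001 / z, False) for e in edits],
            columns=["edit_id", "condition", "phi_mean", "phi_sd", "is_neutral_anchor"],
        )
        rep_rows = []
        for e, vals in estimates.items():
            for n, v in enumerate(vals, start=1):
                rep_rows.append((e, "1D", n, v, 0.001))
        post = FitnessPosterior(
            summary=summary,
            rep_fitness=pd.DataFrame(rep_rows, columns=["edit_id", "condition", "replicate", "s_mean", "s_sd"]),
        )
        return classify(post, 0.95)

    def test_identical_replicates_rho_one(self):
        post = self._post_with_reps({f"e{i}": (i * 0.01, i * 0.01) for i in range(1, 6)})
        out = replicate_concordance(post)
        assert np.allclose(out.spearman_rho, 1.0)

    def test_reversed_ranks_rho_minus_one(self):
        post = self._post_with_reps({f"e{i}": (i * 0.01, -i * 0.01) for i in range(1, 6)})
        out = replicate_concordance(post)
        assert np.allclose(out.spearman_rho, -1.0)

    def test_too_few_non_neutral_flagged(self):
        post = self._post_with_reps({"e1": (0.1, 0.1), "e2": (0.2, 0.2)})
        out = replicate_concordance(post)
        assert out.undefined.all()

    def test_simulated_replicates_concordant(self, small_fit):
        post, _, _, _ = small_fit
        out = replicate_concordance(post)
        assert out.spearman_rho.mean() > 0.8
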