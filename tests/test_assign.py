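"""Correlation-based assignment, overlap scoring and concept transfer."""

import numpy as np
import pandas as pd
import pytest

from ctprofiler import (
    CTPModel,
    DiscretizationParams,
    ExpressionMatrix,
    assign_cohort,
    assign_sample,
    labels_to_dict,
    overlap,
    reverse_transfer,
)
from ctprofiler.simulate import (
    PlantedCohortConfig,
    generate_noise_cohort,
    generate_planted_cohort,
)

TOY_MODEL = CTPModel(
    labels=("A", "B", "C"),
    probe_ids=("p1", "p2", "p3"),
    centroids=np.array([[1, 0, -1], [-1, 0, 1], [0, 1, -1]], dtype=float),
)


def _profile(values, probes=("p1", "p2", "p3"), name="s"):
    return pd.Series(np.asarray(values, dtype=float), index=list(probes), name=name)


class TestAssignSample:
    def test_perfect_match_wins_with_unit_correlation(self):
        res = assign_sample(_profile([1, 0, -1]), TOY_MODEL, min_common_probes=3)
        assert res.label == "A"
        assert res.correlations["A"] == pytest.approx(1.0)
        assert res.margin == pytest.approx(
            1.0 - max(res.correlations["B"], res.correlations["C"])
        )

    def test_anticorrelated_profile(self):
        res = assign_sample(_profile([1, 0, -1]), TOY_MODEL, min_common_probes=3)
        assert res.correlations["B"] == pytest.approx(-1.0)
        assert res.label != "B"

    def test_correlations_match_covariance_formula_oracle(self):
        rng = np.random.default_rng(21)
        probes = tuple(f"p{i}" for i in range(200))
        model = CTPModel(
            labels=("A", "B", "C"),
            probe_ids=probes,
            centroids=rng.uniform(-1, 1, size=(3, 200)),
        )
        v = rng.integers(-1, 2, size=200).astype(float)
        res = assign_sample(pd.Series(v, index=list(probes)), model)
        n = 200
        for i, lab in enumerate(model.labels):
            c = model.centroids[i]
            cov = (v * c).sum() - n * v.mean() * c.mean()
            r = cov / np.sqrt(
                ((v**2).sum() - n * v.mean() ** 2) * ((c**2).sum() - n * c.mean() ** 2)
            )
            assert res.correlations[lab] == pytest.approx(r, abs=1e-12)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            assign_sample(_profile([1, 1, 1]), TOY_MODEL, min_common_probes=3)

    def test_constant_centroid_named_in_error(self):
        model = CTPModel(
            labels=("A", "B", "C"),
            probe_ids=("p1", "p2", "p3"),
            centroids=np.array([[0.5, 0.5, 0.5], [-1, 0, 1], [0, 1, -1]], dtype=float),
        )
        with pytest.raises(ValueError, match="'A'"):
            assign_sample(_profile([1, 0, -1]), model, min_common_probes=3)

    def test_insufficient_probe_overlap_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            assign_sample(_profile([1, -1], probes=("p1", "p2")), TOY_MODEL)

    def test_exact_tie_flagged_and_broken_by_label_order(self):
        model = CTPModel(
            labels=("A", "B", "C"),
            probe_ids=("p1", "p2", "p3", "p4"),
            centroids=np.array(
                [[1, -1, 1, -1], [1, -1, 1, -1], [-1, 1, -1, 1]], dtype=float
            ),
        )
        res = assign_sample(_profile([1, -1, 1, -1], probes=model.probe_ids), model, 4)
        assert res.tie and res.label == "A" and res.margin == 0.0


class TestAssignCohort:
    def test_self_assignment_recovers_training_groups(self, planted, planted_model):
        x, truth, gold = planted
        calls = labels_to_dict(assign_cohort(x, planted_model))
        agree = np.mean([calls[s] == gold[s] for s in x.sample_ids])
        assert agree >= 0.90

    def test_noise_cohort_has_weak_correlations(self):
        cfg = PlantedCohortConfig(n_samples=90, n_probes=10_000, seed=2)
        xp, truth = generate_planted_cohort(cfg)
        gold = {s: "ABC"[g] for s, g in zip(xp.sample_ids, truth)}
        from ctprofiler import build_model

        model = build_model(xp, predefined_groups=gold)
        noise = generate_noise_cohort(50, 10_000, seed=3)
        res = assign_cohort(noise, model)
        mean_win = np.mean([a.winning_correlation for a in res])
        assert mean_win < 0.1
        assert len({a.label for a in res}) > 1  # spread over labels

    def test_probe_row_permutation_leaves_assignments_unchanged(self, planted, planted_model):
        x, _, _ = planted
        rng = np.random.default_rng(8)
        perm = rng.permutation(x.n_probes)
        xp = ExpressionMatrix(
            tuple(x.probe_ids[i] for i in perm), x.sample_ids, x.values[perm, :]
        )
        a = assign_cohort(x, planted_model)
        b = assign_cohort(xp, planted_model)
        for ra, rb in zip(a, b):
            assert ra.label == rb.label
            assert ra.correlations == pytest.approx(rb.correlations)

    def test_per_probe_shift_leaves_assignments_unchanged(self, planted, planted_model):
        x, _, _ = planted
        rng = np.random.default_rng(9)
        shifted = ExpressionMatrix(
            x.probe_ids, x.sample_ids, x.values + rng.normal(0, 10, size=(x.n_probes, 1))
        )
        a = assign_cohort(x, planted_model)
        b = assign_cohort(shifted, planted_model)
        assert [r.label for r in a] == [r.label for r in b]


class TestOverlap:
    def test_identical_labelings_score_one(self):
        gold = {"s1": "A", "s2": "B", "s3": "C"}
        rep = overlap(gold, gold)
        assert rep.agreement_fraction == 1.0
        assert rep.permutation == {"A": "A", "B": "B", "C": "C"}

    def test_label_swap_still_scores_one(self):
        gold = {"s1": "A", "s2": "A", "s3": "B", "s4": "C"}
        swapped = {"s1": "B", "s2": "B", "s3": "A", "s4": "C"}
        rep = overlap(gold, swapped)
        assert rep.agreement_fraction == 1.0
        assert rep.permutation["B"] == "A" and rep.permutation["A"] == "B"

    def test_five_of_six_example_against_exhaustive_search(self):
        from itertools import permutations

        samples = [f"s{i}" for i in range(6)]
        gold = dict(zip(samples, "AABBCC"))
        test = dict(zip(samples, "AABBCA"))
        rep = overlap(gold, test)
        best = max(
            np.mean([{ "A": p[0], "B": p[1], "C": p[2]}[test[s]] == gold[s] for s in samples])
            for p in permutations("ABC")
        )
        assert rep.agreement_fraction == pytest.approx(best) == pytest.approx(5 / 6)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(30)]
        a = {s: "ABC"[rng.integers(3)] for s in samples}
        b = {s: "ABC"[rng.integers(3)] for s in samples}
        assert overlap(a, b).agreement_fraction == overlap(b, a).agreement_fraction

    def test_sample_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="s2"):
            overlap({"s1": "A", "s2": "B"}, {"s1": "A", "s3": "B"})


class TestReverseTransfer:
    def test_self_transfer_recovers_gold(self, planted):
        x, _, gold = planted
        rep = reverse_transfer(x, x, gold, seed=0)
        assert rep.agreement_fraction >= 0.95

    def test_noise_source_gives_weak_transfer(self):
        cfg = PlantedCohortConfig(n_samples=60, n_probes=500, seed=1)
        target, truth = generate_planted_cohort(cfg)
        gold = {s: "ABC"[g] for s, g in zip(target.sample_ids, truth)}
        fracs = []
        for seed in range(20):
            noise = generate_noise_cohort(60, 500, seed=1000 + seed)
            rep = reverse_transfer(noise, target, gold, seed=seed)
            fracs.append(rep.agreement_fraction)
        assert np.mean(fracs) < 0.6  # near chance (1/3) plus matching slack

    def test_deterministic_given_seed(self, planted):
        x, _, gold = planted
        a = reverse_transfer(x, x, gold, seed=3)
        b = reverse_transfer(x, x, gold, seed=3)
        assert a.agreement_fraction == b.agreement_fraction
        assert dict(a.permutation) == dict(b.permutation)


def test_agreement_monotone_in_signal_fraction():
    """Median planted-label agreement does not decrease with signal fraction."""
    from ctprofiler import build_model

    medians = []
    for frac in (0.05, 0.15, 0.3):
        vals = []
        for seed in range(10):
            cfg = PlantedCohortConfig(
                n_samples=90, n_probes=500, signal_fraction=frac, effect_size=2.0, seed=seed
            )
            x, truth = generate_planted_cohort(cfg)
            gold = {s: "ABC"[g] for s, g in zip(x.sample_ids, truth)}
            model = build_model(x, seed=seed)
            calls = labels_to_dict(assign_cohort(x, model))
            vals.append(overlap(gold, calls).agreement_fraction)
        medians.append(np.median(vals))
    assert medians == sorted(medians)
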