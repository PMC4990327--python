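"""Cluster diameters, their comparison, and gene-subset robustness."""

import numpy as np
import pytest
from scipy import stats as sps

from ctprofiler import (
    AssignmentResult,
    CTPModel,
    GeneSubset,
    assign_cohort,
    build_model,
    cluster_diameter,
    compare_diameters,
    subset_robustness,
)
from ctprofiler.simulate import (
    PlantedCohortConfig,
    generate_noise_cohort,
    generate_planted_cohort,
)


def _toy_model():
    return CTPModel(
        labels=("A", "B", "C"),
        probe_ids=("p1", "p2", "p3"),
        centroids=np.array([[1, 0, -1], [-1, 0, 1], [0, 1, -1]], dtype=float),
    )


def _res(sid, label, r):
    corrs = {"A": -0.5, "B": -0.5, "C": -0.5}
    corrs[label] = r
    return AssignmentResult(sid, label, corrs, r + 0.5)


class TestClusterDiameter:
    def test_means_winning_correlations_per_label(self):
        rep = cluster_diameter(
            [_res("s1", "A", 0.4), _res("s2", "A", 0.5), _res("s3", "B", 0.3)], _toy_model()
        )
        assert rep.mean_correlation["A"] == pytest.approx(0.45)
        assert rep.mean_correlation["B"] == pytest.approx(0.3)
        assert rep.member_count == {"A": 2, "B": 1, "C": 0}

    def test_empty_label_reported_as_undefined(self):
        rep = cluster_diameter([_res("s1", "A", 0.4)], _toy_model())
        assert rep.mean_correlation["C"] is None

    def test_single_member_label_is_its_own_mean(self):
        rep = cluster_diameter([_res("s1", "B", 0.7)], _toy_model())
        assert rep.mean_correlation["B"] == pytest.approx(0.7)

    def test_exact_centroid_copies_have_unit_diameter(self, prototype_expression):
        x, truth, _ = prototype_expression
        gold = {s: "ABC"[g] for s, g in zip(x.sample_ids, truth)}
        model = build_model(x, predefined_groups=gold)
        rep = cluster_diameter(assign_cohort(x, model), model)
        for lab in "ABC":
            assert rep.mean_correlation[lab] == pytest.approx(1.0)

    def test_planted_diameter_exceeds_noise_diameter(self):
        """Structured cohorts are tighter than noise under the same model."""
        for seed in range(5):
            xp, truth = generate_planted_cohort(PlantedCohortConfig(n_samples=60, seed=seed))
            gold = {s: "ABC"[g] for s, g in zip(xp.sample_ids, truth)}
            model = build_model(xp, predefined_groups=gold)
            noise = generate_noise_cohort(60, xp.n_probes, seed=900 + seed)
            dp = cluster_diameter(assign_cohort(xp, model), model)
            dn = cluster_diameter(assign_cohort(noise, model), model)
            for lab in "ABC":
                if dp.mean_correlation[lab] is None or dn.mean_correlation[lab] is None:
                    continue
                assert dp.mean_correlation[lab] > dn.mean_correlation[lab]


class TestCompareDiameters:
    def test_identical_groups_give_null_result(self):
        g = [0.1, 0.2, 0.3, 0.4]
        res = compare_diameters(g, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue > 0.99

    def test_separated_groups_match_closed_form_welch(self):
        rng = np.random.default_rng(30)
        a = rng.normal(0.10, 0.02, size=8)
        b = rng.normal(0.45, 0.02, size=8)
        res = compare_diameters(a, b)
        assert res.pvalue < 1e-6
        # closed-form Welch t as independent oracle
        va, vb = a.var(ddof=1) / 8, b.var(ddof=1) / 8
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 7 + vb**2 / 7)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.pvalue == pytest.approx(2 * sps.t.sf(abs(t), df), rel=1e-9)

    def test_swapping_groups_flips_sign_only(self):
        a, b = [0.1, 0.12, 0.15], [0.4, 0.45, 0.42]
        r1, r2 = compare_diameters(a, b), compare_diameters(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_ranksum_alternative(self):
        res = compare_diameters([0.1, 0.11, 0.12], [0.4, 0.41, 0.42], test="ranksum")
        assert res.test == "ranksum" and res.pvalue < 0.1

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_diameters([0.2, 0.2], [0.2, 0.2])


class TestSubsetRobustness:
    def test_identity_subset_is_fully_similar(self, planted, planted_model):
        x, _, gold = planted
        rep = subset_robustness(
            x, planted_model, subset=GeneSubset(frozenset(x.probe_ids), "all"), grouping=gold
        )
        assert rep.similarity == 100.0

    def test_random_700_probe_subsets_stay_similar(self, planted, planted_model):
        x, _, _ = planted
        rep = subset_robustness(x, planted_model, size=700, n_replicates=20, seed=7)
        assert rep.similarity >= 80.0
        assert rep.similarity_sd is not None
        assert len(rep.replicate_similarities) == 20

    def test_disjoint_subsets_agree_within_15_points(self, planted, planted_model):
        x, _, _ = planted
        rng = np.random.default_rng(42)
        perm = rng.permutation(x.n_probes)
        s1 = GeneSubset(frozenset(x.probe_ids[i] for i in perm[:700]), "first")
        s2 = GeneSubset(frozenset(x.probe_ids[i] for i in perm[700:1400]), "second")
        r1 = subset_robustness(x, planted_model, subset=s1)
        r2 = subset_robustness(x, planted_model, subset=s2)
        assert abs(r1.similarity - r2.similarity) <= 15.0

    def test_similarity_non_decreasing_in_subset_size(self):
        """Median similarity grows (weakly) with subset size on planted data."""
        sizes = (50, 100, 400, 1000)
        medians = []
        for size in sizes:
            sims = []
            for seed in range(10):
                cfg = PlantedCohortConfig(n_samples=90, n_probes=1000, seed=seed)
                x, truth = generate_planted_cohort(cfg)
                gold = {s: "ABC"[g] for s, g in zip(x.sample_ids, truth)}
                model = build_model(x, predefined_groups=gold)
                rep = subset_robustness(x, model, size=size, n_replicates=1, seed=100 + seed)
                sims.append(rep.similarity)
            medians.append(np.median(sims))
        assert medians == sorted(medians)

    def test_unknown_ids_warned_and_intersected(self, planted, planted_model, caplog):
        x, _, _ = planted
        ids = set(list(x.probe_ids)[:50]) | {"not_a_probe"}
        with caplog.at_level("WARNING"):
            rep = subset_robustness(x, planted_model, subset=GeneSubset(frozenset(ids), "mixed"))
        assert rep.subset_size == 50
        assert any("absent" in rec.message for rec in caplog.records)

    def test_empty_intersection_rejected(self, planted, planted_model):
        x, _, _ = planted
        with pytest.raises(ValueError, match="no probes"):
            subset_robustness(x, planted_model, subset=GeneSubset(frozenset({"zz"}), "alien"))
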