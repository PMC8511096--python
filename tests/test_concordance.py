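import numpy as np
import pandas as pd
import pytest
from scipy import stats

from setkit import (
    classify_division,
    division_mode_test,
    pair_types,
    project_clusters,
)


def labels_of(counts_by_cluster):
    out = {}
    i = 0
    for name, n in counts_by_cluster.items():
        for _ in range(n):
            out[f"c{i}"] = name
            i += 1
    return pd.Series(out)


class TestProjectClusters:
    def test_identical_balanced_labels_closed_form(self):
        """3 identical balanced clusters of 30: per-cluster statistic is 60
        (closed form: (30-10)^2/10 + 2*(0-10)^2/10) with df 2."""
        labels = labels_of({"Proxi": 30, "Dista": 30, "Mix": 30})
        t = project_clusters(labels, labels)
        assert np.allclose(np.diag(t.contingency), 30)
        for row in t.per_cluster_chi2.itertuples():
            assert row.statistic == pytest.approx(60.0)
            assert row.df == 2
            assert row.p_value < 0.001

    def test_single_epi_cluster_matches_marginal_exactly(self):
        expr = labels_of({"Proxi": 20, "Dista": 30, "Mix": 50})
        epi = pd.Series("only", index=expr.index)
        t = project_clusters(epi, expr)
        assert t.per_cluster_chi2["statistic"].iloc[0] == pytest.approx(0.0)
        assert t.per_cluster_chi2["p_value"].iloc[0] == pytest.approx(1.0)

    def test_null_p_values_centered(self):
        """Epi labels drawn independently with the expression marginals give
        roughly uniform per-cluster p-values."""
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            expr = pd.Series(
                rng.choice(["A", "B", "C"], size=300, p=[0.5, 0.3, 0.2]),
                index=[f"c{i}" for i in range(300)],
            )
            epi = pd.Series(
                rng.choice(["A", "B", "C"], size=300, p=[0.5, 0.3, 0.2]),
                index=expr.index,
            )
            t = project_clusters(epi, expr)
            pvals.extend(t.per_cluster_chi2["p_value"])
        assert 0.3 < np.mean(pvals) < 0.7

    def test_disjoint_cells_rejected(self):
        a = pd.Series({"c1": "A"})
        b = pd.Series({"c2": "A"})
        with pytest.raises(ValueError, match="shared"):
            project_clusters(a, b)

    def test_counts_conserved(self, rng):
        cells = [f"c{i}" for i in range(200)]
        epi = pd.Series(rng.choice(["A", "B"], 200), index=cells)
        expr = pd.Series(rng.choice(["X", "Y", "Z"], 200), index=cells)
        t = project_clusters(epi, expr)
        assert t.contingency.to_numpy().sum() == 200
        assert (t.contingency.sum(axis=1) == epi.value_counts().sort_index()).all()


PAIRS = pd.DataFrame(
    {
        "pair_id": [f"p{i}" for i in range(10)],
        "proximal_cell": [f"prox{i}" for i in range(10)],
        "distal_cell": [f"dist{i}" for i in range(10)],
    }
)


class TestPairTypes:
    def labels_for(self, assignments):
        out = {}
        for i, (lp, ld) in enumerate(assignments):
            out[f"prox{i}"] = lp
            out[f"dist{i}"] = ld
        return pd.Series(out)

    def test_canonical_examples(self):
        labels = self.labels_for(
            [("Proxi", "Dista"), ("Dista", "Mix"), ("Mix", "Mix")]
        )
        res = pair_types(PAIRS.head(3), labels)
        assert res.records["pair_type"].tolist() == [
            "Proxi-Dista", "toMix", "withinCluster",
        ]

    def test_ten_pair_fixture_matches_hand_count(self):
        assignments = [
            ("Proxi", "Dista"), ("Proxi", "Dista"), ("Dista", "Proxi"),
            ("Mix", "Mix"), ("Mix", "Mix"), ("Mix", "Mix"),
            ("Proxi", "Mix"), ("Mix", "Dista"),
            ("Proxi", "Proxi"), ("Dista", "Dista"),
        ]
        res = pair_types(PAIRS, self.labels_for(assignments))
        assert res.fractions["Proxi-Dista"] == pytest.approx(0.3)
        assert res.fractions["toMix"] == pytest.approx(0.2)
        assert res.fractions["withinCluster"] == pytest.approx(0.5)
        # 6 of the 8 Mix cells sit in Mix-Mix pairs
        assert res.mix_paired_of_mix_cells == pytest.approx(6 / 8)
        assert res.mix_paired_of_all_cells == pytest.approx(6 / 20)

    def test_fractions_sum_to_one_and_partition(self):
        assignments = [("Proxi", "Dista")] * 4 + [("Mix", "Mix")] * 6
        res = pair_types(PAIRS, self.labels_for(assignments))
        assert res.fractions.sum() == pytest.approx(1.0)
        assert res.n_pairs_classified == 10

    def test_unlabelled_daughter_excluded_and_counted(self):
        labels = self.labels_for([("Proxi", "Dista")])  # only pair 0 labelled
        res = pair_types(PAIRS.head(3), labels)
        assert res.n_pairs_classified == 1
        assert res.n_pairs_excluded == 2


class TestClassifyDivision:
    def make_pairs(self, intensities):
        return pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(len(intensities))],
                "proximal_intensity": [a for a, _ in intensities],
                "distal_intensity": [b for _, b in intensities],
            }
        )

    def test_rule_examples(self):
        res = classify_division(
            self.make_pairs([(4.0, 1.0), (2.0, 2.0), (1.0, 1.3), (1.0, 4.0)])
        )
        assert res.modes.tolist() == [
            "asymmetric",  # |log2 4| = 2 > 0.5
            "symmetric",  # identical intensities
            "symmetric",  # |log2(1/1.3)| = 0.379 <= 0.5
            "reverse",
        ]

    def test_identity_is_symmetric_for_any_tau(self):
        for tau in (0.0, 0.5, 2.0):
            res = classify_division(self.make_pairs([(3.0, 3.0)]), tau=tau)
            assert res.modes.iloc[0] == "symmetric"

    def test_nonpositive_intensity_excluded(self):
        res = classify_division(self.make_pairs([(4.0, 1.0), (0.0, 2.0)]))
        assert res.n_excluded == 1
        assert res.counts.sum() == 1

    def test_percentages_sum_to_100(self):
        res = classify_division(
            self.make_pairs([(4, 1), (1, 1), (1, 4), (5, 1)])
        )
        assert res.percentages.sum() == pytest.approx(100.0)


class TestDivisionModeTest:
    def test_identical_distributions(self):
        counts = {"asymmetric": 50, "symmetric": 30, "reverse": 20}
        stat, df, p = division_mode_test(counts, counts)
        assert stat == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        a = {"asymmetric": 50, "symmetric": 25, "reverse": 25}
        b = {"asymmetric": 25, "symmetric": 50, "reverse": 25}
        stat, df, p = division_mode_test(a, b)
        assert stat == pytest.approx(50.0 / 3.0)
        assert df == 2
        assert p < 0.001

    def test_null_p_roughly_uniform(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.multinomial(150, [0.6, 0.25, 0.15])
            b = rng.multinomial(150, [0.6, 0.25, 0.15])
            stat, df, p = division_mode_test(
                dict(zip(("asymmetric", "symmetric", "reverse"), a)),
                dict(zip(("asymmetric", "symmetric", "reverse"), b)),
            )
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            division_mode_test({"asymmetric": 5}, {})
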