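"""Hub-gene clustering, TMB counting and differential mutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import memoryscreen as ms
from memoryscreen.subtype import SubgroupAssignment


def _blob_expression(rng, centers, per_cluster=20, n_hubs=5, sd=0.05):
    """Well-separated sample blobs in hub-gene space; returns (expr, labels)."""
    columns = []
    labels = []
    for ci, center in enumerate(centers):
        for _ in range(per_cluster):
            columns.append(center + rng.normal(0.0, sd, size=n_hubs))
            labels.append(ci)
    values = np.column_stack(columns)
    values = np.maximum(values, 0.0)
    expr = ms.ExpressionMatrix(
        gene_ids=[f"HUB{i}" for i in range(n_hubs)],
        sample_ids=[f"S{i:03d}" for i in range(values.shape[1])],
        values=values,
    )
    return expr, np.asarray(labels)


class TestLogTransform:
    def test_closed_form_values(self):
        expr = ms.ExpressionMatrix(
            gene_ids=["A"], sample_ids=["S1", "S2", "S3"], values=[[0.0, 1.0, 3.0]]
        )
        out = ms.log_transform_expression(expr)
        np.testing.assert_array_equal(out.values, [[0.0, 1.0, 2.0]])

    def test_preserves_identifiers(self, tiny_expression):
        out = ms.log_transform_expression(tiny_expression)
        assert list(out.gene_ids) == list(tiny_expression.gene_ids)


class TestClustering:
    def test_recovers_separated_blobs_exactly(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        expr, truth = _blob_expression(
            rng, centers=[np.full(5, 1.0), np.full(5, 5.0), np.full(5, 9.0)]
        )
        assignment = ms.cluster_by_hub_genes(expr, k=3)
        ari = sklearn_metrics.adjusted_rand_score(truth, assignment.labels)
        assert ari == 1.0

    def test_labels_ordered_by_mean_expression(self):
        rng = np.random.default_rng(1)
        expr, truth = _blob_expression(
            rng, centers=[np.full(5, 9.0), np.full(5, 1.0), np.full(5, 5.0)]
        )
        assignment = ms.cluster_by_hub_genes(expr, k=3)
        means = {
            label: expr.values[:, assignment.labels == label].mean()
            for label in (1, 2, 3)
        }
        assert means[1] < means[2] < means[3]

    def test_deterministic_across_reruns(self):
        rng = np.random.default_rng(2)
        expr, _ = _blob_expression(rng, centers=[np.full(5, 1.0), np.full(5, 6.0), np.full(5, 12.0)])
        a1 = ms.cluster_by_hub_genes(expr, k=3)
        a2 = ms.cluster_by_hub_genes(expr, k=3)
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_permuting_samples_permutes_labels(self):
        rng = np.random.default_rng(3)
        expr, _ = _blob_expression(rng, centers=[np.full(5, 1.0), np.full(5, 6.0), np.full(5, 12.0)])
        perm = rng.permutation(expr.values.shape[1])
        permuted = expr.subset_samples(list(expr.sample_ids[perm]))
        a_orig = ms.cluster_by_hub_genes(expr, k=3)
        a_perm = ms.cluster_by_hub_genes(permuted, k=3)
        np.testing.assert_array_equal(a_orig.labels[perm], a_perm.labels)

    def test_k_equal_to_samples_gives_singletons(self):
        expr = ms.ExpressionMatrix(
            gene_ids=["H"], sample_ids=["S1", "S2", "S3"], values=[[1.0, 5.0, 9.0]]
        )
        assignment = ms.cluster_by_hub_genes(expr, k=3)
        assert sorted(assignment.labels) == [1, 2, 3]

    def test_fewer_samples_than_k_rejected(self):
        expr = ms.ExpressionMatrix(
            gene_ids=["H"], sample_ids=["S1", "S2"], values=[[1.0, 5.0]]
        )
        with pytest.raises(ValueError):
            ms.cluster_by_hub_genes(expr, k=3)


class TestTmb:
    def test_hand_tally_with_nonsilent_filter(self, toy_maf):
        report = ms.compute_tmb(toy_maf, ["S1", "S2", "S3", "S4", "S5"])
        counts = dict(zip(report.counts["sample_id"], report.counts["tmb_count"]))
        # S1: 3 missense (1 silent dropped); S3: 3 non-silent (2 silent dropped)
        assert counts == {"S1": 3, "S2": 2, "S3": 3, "S4": 9, "S5": 0}

    def test_per_megabase_rate(self, toy_maf):
        report = ms.compute_tmb(toy_maf, ["S4"], capture_size_mb=38.0)
        assert report.counts.loc[0, "tmb_per_mb"] == pytest.approx(9 / 38)

    def test_additive_over_partitions(self, toy_maf):
        samples = ["S1", "S2", "S3", "S4"]
        whole = ms.compute_tmb(toy_maf, samples).counts["tmb_count"].sum()
        part1 = ms.MutationTable(records=toy_maf.records.iloc[:10])
        part2 = ms.MutationTable(records=toy_maf.records.iloc[10:])
        split = (
            ms.compute_tmb(part1, samples).counts["tmb_count"].sum()
            + ms.compute_tmb(part2, samples).counts["tmb_count"].sum()
        )
        assert whole == split


def _assignment(sizes):
    labels = np.concatenate([[i + 1] * n for i, n in enumerate(sizes)])
    samples = np.asarray([f"S{i:03d}" for i in range(labels.size)], dtype=object)
    return SubgroupAssignment(sample_ids=samples, labels=labels, k=len(sizes))


def _mutations(carriers):
    rows = [
        {"gene": gene, "sample": sample, "variant_class": "Missense_Mutation"}
        for gene, samples in carriers.items()
        for sample in samples
    ]
    return ms.MutationTable(records=pd.DataFrame(rows, columns=["gene", "sample", "variant_class"]))


def two_sided_fisher_by_enumeration(n11, n12, n21, n22):
    """Sum of hypergeometric point probabilities <= that of the observed table."""
    row1 = n11 + n12
    col1 = n11 + n21
    total = n11 + n12 + n21 + n22
    observed = stats.hypergeom.pmf(n11, total, row1, col1)
    p = 0.0
    for x in range(max(0, col1 - (total - row1)), min(row1, col1) + 1):
        prob = stats.hypergeom.pmf(x, total, row1, col1)
        if prob <= observed * (1 + 1e-9):
            p += prob
    return min(p, 1.0)


class TestDifferentialMutation:
    def test_enumeration_oracle(self):
        groups = _assignment([10, 10])
        cluster1 = groups.members(1)
        cluster2 = groups.members(2)
        mut = _mutations({"TP53": cluster1[:8] + cluster2[:1]})
        report = ms.differential_mutation(mut, groups, (1, 2))
        row = report.table.iloc[0]
        expected = two_sided_fisher_by_enumeration(8, 2, 1, 9)
        assert row["p_value"] == pytest.approx(expected, rel=1e-10)

    def test_identical_proportions_give_p_one(self):
        groups = _assignment([10, 10])
        mut = _mutations({"KRAS": groups.members(1)[:3] + groups.members(2)[:3]})
        report = ms.differential_mutation(mut, groups, (1, 2))
        assert report.table.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_gene_absent_from_both_clusters_skipped(self):
        groups = _assignment([5, 5, 5])
        mut = _mutations({"EGFR": groups.members(3)[:2]})
        report = ms.differential_mutation(mut, groups, (1, 2))
        assert report.skipped_genes == ["EGFR"]
        assert len(report.table) == 0

    def test_swapping_clusters_preserves_p(self):
        groups = _assignment([12, 8])
        mut = _mutations({"BRAF": groups.members(1)[:5] + groups.members(2)[:1]})
        p_ab = ms.differential_mutation(mut, groups, (1, 2)).table.iloc[0]["p_value"]
        p_ba = ms.differential_mutation(mut, groups, (2, 1)).table.iloc[0]["p_value"]
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_empty_cluster_rejected(self):
        groups = _assignment([5, 5])
        mut = _mutations({"A": groups.members(1)[:1]})
        with pytest.raises(ValueError):
            ms.differential_mutation(mut, groups, (1, 3))

    def test_bh_adjustment_is_monotone(self):
        groups = _assignment([15, 15])
        c1, c2 = groups.members(1), groups.members(2)
        mut = _mutations(
            {"G1": c1[:12] + c2[:1], "G2": c1[:6] + c2[:4], "G3": c1[:5] + c2[:5]}
        )
        table = ms.differential_mutation(mut, groups, (1, 2)).table
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()
        assert table["q_value"].is_monotonic_increasing
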