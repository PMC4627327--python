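"""Expression integration: variability cut, clustering, BHI, permutations, DE."""

import numpy as np
import pandas as pd
import pytest

from pclexome.expression import (
    bhi,
    differential_expression,
    group_association,
    hcluster,
    replication_probability,
    select_variable_genes,
)
from pclexome.model import ExpressionMatrix
from pclexome.simulate import simulate_expression_matrix


def em(values, genes=None, samples=None, labels=None):
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), labels or {})


def test_variable_gene_threshold():
    base = np.full((3, 10), 8.0)
    base[1, 0] += 1.2  # exceeds log2(2) = 1 deviation from its mean
    m = em(base)
    got = select_variable_genes(m, fold=2)
    assert got == ["G1"]
    with pytest.raises(ValueError):
        select_variable_genes(m, fold=1.0)


def test_variable_genes_match_brute_force(rng):
    values = rng.normal(8, 1, size=(200, 15))
    m = em(values)
    got = set(select_variable_genes(m, fold=2))
    expected = set()
    for i, g in enumerate(m.genes):
        dev = np.abs(values[i] - values[i].mean()).max()
        if dev >= 1.0:
            expected.add(g)
    assert got == expected


def _planted_matrix(rng, n_groups=3, per_group=8, n_genes=30, effect=3.0, noise=0.5):
    samples, groups = [], {}
    for g in range(n_groups):
        for i in range(per_group):
            sid = f"S{g}_{i}"
            samples.append(sid)
            groups[sid] = f"grp{g}"
    values = rng.normal(8, noise, size=(n_genes, len(samples)))
    offsets = rng.normal(0, effect, size=(n_genes, n_groups))
    for j, sid in enumerate(samples):
        g = int(sid[1])
        values[:, j] += offsets[:, g]
    labels = {s: {"translocation_group": groups[s]} for s in samples}
    return em(values, samples=samples, labels=labels), groups


def test_identical_samples_merge_first():
    values = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 1.0], [3.0, 3.0, 9.0]])
    res = hcluster(em(values), [f"G{i}" for i in range(3)], k=2)
    assert res.linkage[0, 2] == pytest.approx(0.0)  # first merge at distance 0
    assert res.labels["S0"] == res.labels["S1"] != res.labels["S2"]


def test_hcluster_recovers_planted_groups(rng):
    matrix, groups = _planted_matrix(rng)
    res = hcluster(matrix, matrix.genes, k=3)
    # adjusted Rand index of 1: the partition matches the planted groups
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(
        [groups[s] for s in matrix.samples], [res.labels[s] for s in matrix.samples]
    )
    assert ari == 1.0


def test_hcluster_gene_order_invariance(rng):
    matrix, _ = _planted_matrix(rng)
    a = hcluster(matrix, matrix.genes, k=3)
    b = hcluster(matrix, matrix.genes[::-1], k=3)
    assert a.labels == b.labels


def test_hcluster_zero_variance_sample_errors():
    values = np.ones((4, 3))
    values[:, 2] = [1, 2, 3, 4]
    with pytest.raises(ValueError, match="S0"):
        hcluster(em(values), [f"G{i}" for i in range(4)], k=2)


def test_group_association_single_cluster_p_one(rng):
    labels = {f"S{i}": 1 for i in range(12)}
    groups = {f"S{i}": "g1" if i < 6 else "g2" for i in range(12)}
    p = group_association(labels, groups, B=200, seed=0)
    assert p["g1"] == 1.0 and p["g2"] == 1.0


def test_group_association_detects_pure_cluster(rng):
    matrix, groups = _planted_matrix(rng, n_groups=3, per_group=10)
    res = hcluster(matrix, matrix.genes, k=3)
    p = group_association(res.labels, groups, B=10_000, seed=0)
    assert all(v <= 1e-3 for v in p.values())


def test_group_association_small_group_null():
    labels = {f"S{i}": i % 2 for i in range(10)}
    groups = {f"S{i}": None for i in range(10)}
    groups["S0"] = "tiny"
    assert group_association(labels, groups, B=50, seed=0)["tiny"] is None


def test_bhi_trivial_cases():
    # class-pure clusters
    labels = {"a": 1, "b": 1, "c": 2, "d": 2}
    classes = {"a": "x", "b": "x", "c": "y", "d": "y"}
    assert bhi(labels, classes) == 1.0
    # a two-member mixed cluster contributes zero
    classes = {"a": "x", "b": "y", "c": "y", "d": "y"}
    assert bhi(labels, classes) == 0.5
    with pytest.raises(ValueError):
        bhi({"a": 1}, {"a": "x"})


def test_bhi_matches_pair_enumeration(rng):
    for _ in range(30):
        n = int(rng.integers(5, 50))
        labels = {f"i{j}": int(rng.integers(1, 5)) for j in range(n)}
        classes = {f"i{j}": f"c{int(rng.integers(3))}" for j in range(n)}
        got = bhi(labels, classes)
        # brute-force pair enumeration
        scores = []
        for cl in set(labels.values()):
            items = [i for i in labels if labels[i] == cl]
            if len(items) < 2:
                continue
            pairs = [
                (x, y) for x in items for y in items if x != y
            ]
            scores.append(np.mean([classes[x] == classes[y] for x, y in pairs]))
        assert got == pytest.approx(np.mean(scores))


def test_replication_probability_bounds_and_errors(rng):
    matrix, groups = _planted_matrix(rng, n_genes=20)
    p = replication_probability(matrix, matrix.genes, matrix.genes[:5], k=3, B=1, seed=0)
    assert p in (0.5, 1.0)
    with pytest.raises(ValueError, match="smaller"):
        replication_probability(matrix, matrix.genes[:3], matrix.genes[:5], k=3)
    with pytest.raises(ValueError, match="subset"):
        replication_probability(matrix, matrix.genes[:5], ["nope"], k=3)


def test_replication_probability_detects_planted_signal(rng):
    # focal genes carry group structure, the rest of the pool is noise
    matrix, groups = _planted_matrix(rng, n_genes=12, effect=3.0, noise=0.5)
    noise = rng.normal(8, 1.5, size=(500, len(matrix.samples)))
    noise_df = pd.DataFrame(
        noise, index=[f"N{i}" for i in range(500)], columns=matrix.samples
    )
    full = ExpressionMatrix(
        pd.concat([matrix.values, noise_df]), matrix.sample_labels
    )
    pool = list(full.genes)
    p = replication_probability(full, pool, matrix.genes, k=3, B=1000, seed=2)
    assert p <= 0.01


def test_differential_expression_recovers_planted(rng):
    matrix, truth = simulate_expression_matrix(
        n_genes=1500, n_a=21, n_b=55, n_de=50, effect=1.5, seed=42
    )
    a = [s for s in matrix.samples if s.startswith("A")]
    b = [s for s in matrix.samples if s.startswith("B")]
    deg = differential_expression(matrix, a, b, q_cut=0.05)
    called = set(deg[deg.significant].index)
    planted = set(truth.gene)
    sensitivity = len(called & planted) / len(planted)
    fdr = len(called - planted) / max(1, len(called))
    assert sensitivity >= 0.9
    assert fdr <= 0.1
    # directions match the planted signs
    for _, row in truth.iterrows():
        if row.gene in called:
            assert deg.loc[row.gene, "direction"] == row.direction


def test_differential_expression_label_swap_symmetry(rng):
    matrix, _ = simulate_expression_matrix(200, 5, 6, 10, seed=3)
    a = [s for s in matrix.samples if s.startswith("A")]
    b = [s for s in matrix.samples if s.startswith("B")]
    ab = differential_expression(matrix, a, b)
    ba = differential_expression(matrix, b, a)
    assert np.allclose(ab.p, ba.p)
    assert np.allclose(ab.mean_diff, -ba.mean_diff)
    flipped = ab.direction.map({"up": "down", "down": "up"})
    swap_ok = (ba.direction == flipped) | (ba.mean_diff == 0)
    assert swap_ok.all()


def test_differential_expression_null_rate(rng):
    matrix, _ = simulate_expression_matrix(500, 10, 10, 0, seed=9)
    a = [s for s in matrix.samples if s.startswith("A")]
    b = [s for s in matrix.samples if s.startswith("B")]
    deg = differential_expression(matrix, a, b)
    assert deg.significant.sum() <= 2  # ~0 expected at q < 0.05 under the null


def test_differential_expression_degenerate_gene():
    values = np.ones((2, 8))
    values[1] = np.r_[np.zeros(4), np.ones(4)]
    matrix = em(values)
    deg = differential_expression(matrix, matrix.samples[:4], matrix.samples[4:])
    assert deg.loc["G0", "p"] == 1.0 and bool(deg.loc["G0", "degenerate"])
    with pytest.raises(ValueError, match=">= 3"):
        differential_expression(matrix, matrix.samples[:2], matrix.samples[2:])
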