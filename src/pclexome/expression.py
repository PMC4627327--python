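"""Expression-side analyses of mutated genes.

Variable-gene selection keeps genes with at least a ``fold``-fold
deviation from their cross-sample average on the log2 scale.  Samples are
clustered hierarchically (1 - Pearson correlation, average linkage) on a
gene subset; cluster/translocation-group association and the probability
of replicating the clustering with random gene draws are assessed by
seeded permutation tests; cluster quality against functional classes uses
the biological homogeneity index (BHI); two-class differential expression
is a Welch t-test with BH FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import ttest_ind

from .model import ExpressionMatrix
from .enrichment import bh_adjust


@dataclass
class ClusteringResult:
    samples: list[str]
    linkage: np.ndarray  # scipy linkage matrix (merge order + heights)
    labels: dict[str, int]  # sample -> cluster id for the chosen cut
    k: int


def select_variable_genes(matrix: ExpressionMatrix, fold: float = 2.0) -> list[str]:
    """Genes whose max |deviation from the gene's mean| >= log2(fold)."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    values = matrix.values
    dev = values.sub(values.mean(axis=1), axis=0).abs().max(axis=1)
    return values.index[dev >= np.log2(fold)].tolist()


def hcluster(matrix: ExpressionMatrix, genes: list[str], k: int) -> ClusteringResult:
    """Average-linkage clustering of samples on 1 - Pearson distances."""
    missing = set(genes) - set(matrix.genes)
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)[:5]}")
    n = len(matrix.samples)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    sub = matrix.values.loc[sorted(genes)]
    sds = sub.std(axis=0, ddof=0)
    flat = sds[sds == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance sample profile: {flat}")
    corr = np.corrcoef(sub.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = average(squareform(dist, checks=False))
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusteringResult(list(matrix.samples), Z, dict(zip(matrix.samples, labels.tolist())), k)


def group_association(
    labels: dict[str, int],
    groups: dict[str, str | None],
    B: int = 10_000,
    seed: int = 0,
) -> dict[str, float | None]:
    """Permutation p per group for concentration in a single cluster.

    Statistic: the max over clusters of the number of the group's samples
    falling in one cluster; null: B random permutations of the cluster
    labels across samples.  Groups with <2 samples get p = None.
    """
    samples = sorted(labels)
    lab = np.array([labels[s] for s in samples])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(lab) for _ in range(B)])
    out: dict[str, float | None] = {}
    for group in sorted({g for g in groups.values() if g is not None}):
        members = np.array([groups.get(s) == group for s in samples])
        if members.sum() < 2:
            out[group] = None
            continue
        obs = _max_in_one_cluster(lab, members)
        null = np.array([_max_in_one_cluster(perms[b], members) for b in range(B)])
        out[group] = float((1 + int((null >= obs).sum())) / (B + 1))
    return out


def _max_in_one_cluster(lab: np.ndarray, members: np.ndarray) -> int:
    vals, counts = np.unique(lab[members], return_counts=True)
    return int(counts.max())


def bhi(labels: dict[str, int], classes: dict[str, str | None]) -> float:
    """Biological homogeneity index: mean over clusters (with >=2 annotated
    members) of the fraction of annotated within-cluster pairs sharing a
    functional class."""
    by_cluster: dict[int, list[str]] = {}
    for item, cl in labels.items():
        if classes.get(item) is not None:
            by_cluster.setdefault(cl, []).append(item)
    scores = []
    for items in by_cluster.values():
        nj = len(items)
        if nj < 2:
            continue
        same = sum(
            1
            for i in range(nj)
            for j in range(nj)
            if i != j and classes[items[i]] == classes[items[j]]
        )
        scores.append(same / (nj * (nj - 1)))
    if not scores:
        raise ValueError("no cluster with >=2 annotated members")
    return float(np.mean(scores))


def replication_probability(
    matrix: ExpressionMatrix,
    variable_genes: list[str],
    focal_genes: list[str],
    k: int,
    B: int = 1000,
    seed: int = 0,
    groups: dict[str, str | None] | None = None,
) -> float:
    """Probability that |focal_genes| genes drawn at random from the
    variable-gene list cluster the samples at least as coherently (by BHI
    against translocation groups) as the focal genes do."""
    if len(variable_genes) < len(focal_genes):
        raise ValueError("variable_genes smaller than focal_genes")
    if not set(focal_genes) <= set(variable_genes):
        raise ValueError("focal_genes must be a subset of variable_genes")
    if groups is None:
        groups = {
            s: (matrix.sample_labels.get(s) or {}).get("translocation_group")
            for s in matrix.samples
        }
    obs = bhi(hcluster(matrix, focal_genes, k).labels, groups)
    rng = np.random.default_rng(seed)
    pool = sorted(variable_genes)
    count = 0
    for _ in range(B):
        draw = [pool[i] for i in rng.choice(len(pool), size=len(focal_genes), replace=False)]
        stat = bhi(hcluster(matrix, draw, k).labels, groups)
        if stat >= obs:
            count += 1
    return float((1 + count) / (B + 1))


def differential_expression(
    matrix: ExpressionMatrix,
    class_a: list[str],
    class_b: list[str],
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test (class A vs class B, log2 values) with BH FDR.

    Direction "up" means higher mean in class A.  Genes with zero variance
    in both classes get p = 1 and a flag.
    """
    if len(class_a) < 3 or len(class_b) < 3:
        raise ValueError("both classes need >= 3 samples")
    A = matrix.values[class_a].to_numpy()
    Bv = matrix.values[class_b].to_numpy()
    diff = A.mean(axis=1) - Bv.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = ttest_ind(A, Bv, axis=1, equal_var=False)
    degenerate = (A.std(axis=1) == 0) & (Bv.std(axis=1) == 0)
    p = np.where(np.isnan(p) | degenerate, 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    q = np.array(bh_adjust(p.tolist()))
    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "mean_diff": diff,
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(diff >= 0, "up", "down"),
            "significant": q < q_cut,
            "degenerate": degenerate,
        }
    ).set_index("gene")
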