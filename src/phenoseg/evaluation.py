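"""Clustering quality against reference organ labels: F-measure and entropy.

Both measures are computed from the label-by-cluster contingency table
``n_ij`` (number of items with label i in cluster j):

* **F-measure** — for each label the best cluster by the harmonic mean of
  precision ``P(i,j) = n_ij / n_j`` and recall ``R(i,j) = n_ij / n_i``,
  weighted by label frequency: ``F = sum_i (n_i / n) max_j F(i,j)``.
  Higher is better; 1 means every label has a cluster capturing it exactly.

* **Entropy** — cluster-size-weighted Shannon entropy (natural log) of the
  label distribution within each cluster:
  ``entropy = sum_j (n_j / n) * ( -sum_i (n_ij/n_j) ln(n_ij/n_j) )``.
  Lower is better; 0 iff every cluster is label-pure.

`sweep_k` runs repeated, independently seeded clusterings over a grid of
methods and cluster counts and reports mean and standard deviation of both
measures, mirroring how stochastic k-means results are usually summarized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from phenoseg.clustering import ClusterConfig, cluster_histograms
from phenoseg.features import HistogramSet

__all__ = [
    "ContingencyTable",
    "EvaluationReport",
    "contingency",
    "f_measure",
    "entropy",
    "evaluate",
    "sweep_k",
]


@dataclass
class ContingencyTable:
    """Label-by-cluster count matrix with its marginals."""

    counts: NDArray[np.int64]          # (labels, clusters)
    label_values: NDArray[np.int64]
    cluster_values: NDArray[np.int64]

    @property
    def label_totals(self) -> NDArray[np.int64]:
        return self.counts.sum(axis=1)

    @property
    def cluster_totals(self) -> NDArray[np.int64]:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """F-measure, entropy and per-label best clusters for one clustering."""

    f_measure: float
    entropy: float
    table: ContingencyTable
    per_class_best: dict[int, tuple[int, float]]  # label -> (cluster, F(i,j))

    def to_dict(self) -> dict:
        return {
            "f_measure": self.f_measure,
            "entropy": self.entropy,
            "n": self.table.n,
            "labels": self.table.label_values.tolist(),
            "clusters": self.table.cluster_values.tolist(),
            "contingency": self.table.counts.tolist(),
            "per_class_best": {
                str(lab): {"cluster": int(c), "f": f}
                for lab, (c, f) in self.per_class_best.items()
            },
        }


def contingency(labels: Sequence[int], assignments: Sequence[int]) -> ContingencyTable:
    """Exact label-by-cluster counts for paired label/cluster sequences."""
    labels = np.asarray(labels)
    assignments = np.asarray(assignments)
    if labels.shape != assignments.shape or labels.ndim != 1:
        raise ValueError("labels and assignments must be equal-length 1D sequences")
    if len(labels) == 0:
        raise ValueError("empty input")
    lab_vals, lab_idx = np.unique(labels, return_inverse=True)
    clu_vals, clu_idx = np.unique(assignments, return_inverse=True)
    counts = np.zeros((len(lab_vals), len(clu_vals)), dtype=np.int64)
    np.add.at(counts, (lab_idx, clu_idx), 1)
    return ContingencyTable(
        counts=counts,
        label_values=lab_vals.astype(np.int64),
        cluster_values=clu_vals.astype(np.int64),
    )


def _pairwise_f(table: ContingencyTable) -> NDArray[np.float64]:
    """F(i,j) matrix; 0 where precision + recall is 0."""
    counts = table.counts.astype(float)
    n_i = table.label_totals.astype(float)[:, None]
    n_j = table.cluster_totals.astype(float)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n_j > 0, counts / n_j, 0.0)
        R = np.where(n_i > 0, counts / n_i, 0.0)
        F = np.where(P + R > 0, 2.0 * P * R / np.where(P + R > 0, P + R, 1.0), 0.0)
    return F


def f_measure(table: ContingencyTable) -> float:
    """Label-frequency-weighted maximum over clusters of F(i,j)."""
    F = _pairwise_f(table)
    weights = table.label_totals / table.n
    return float(np.sum(weights * F.max(axis=1)))


def entropy(table: ContingencyTable) -> float:
    """Cluster-size-weighted Shannon entropy (natural log) of label mixtures.

    Zero-count cells contribute 0 (the x ln x -> 0 limit convention).
    """
    counts = table.counts.astype(float)
    n_j = table.cluster_totals.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_j[None, :] > 0, counts / np.where(n_j > 0, n_j, 1.0)[None, :], 0.0)
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    per_cluster = terms.sum(axis=0)
    return float(np.sum((n_j / table.n) * per_cluster))


def evaluate(labels: Sequence[int], assignments: Sequence[int]) -> EvaluationReport:
    """Full report (F-measure, entropy, table, per-label best cluster)."""
    table = contingency(labels, assignments)
    F = _pairwise_f(table)
    best = {
        int(lab): (int(table.cluster_values[int(np.argmax(F[i]))]), float(F[i].max()))
        for i, lab in enumerate(table.label_values)
    }
    return EvaluationReport(
        f_measure=f_measure(table),
        entropy=entropy(table),
        table=table,
        per_class_best=best,
    )


def sweep_k(
    H: HistogramSet,
    labels: Sequence[int],
    methods: Iterable[str] = ("km", "hc1", "hc2"),
    k_range: Iterable[int] = range(2, 9),
    repeats: int = 5,
    seed: int = 0,
    epsilon: float | None = None,
    n_restarts: int = 1,
) -> pd.DataFrame:
    """Mean and sd of F-measure and entropy per (method, k) over seeded repeats.

    ``labels`` must cover the clustered rows: either one label per histogram
    row, or one per source point (then ``H.point_index_map`` selects them).
    Each repeat uses a fresh seed derived from the master ``seed``; results
    are deterministic given the master seed.
    """
    labels = np.asarray(labels)
    if len(labels) == len(H):
        row_labels = labels
    elif len(labels) >= H.point_index_map.max() + 1:
        row_labels = labels[H.point_index_map]
    else:
        raise ValueError(
            f"labels (len {len(labels)}) cover neither histogram rows nor source points"
        )
    methods = list(methods)
    k_list = list(k_range)
    repeat_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    rows = []
    for method in methods:
        for k in k_list:
            fs, es = [], []
            for rep_seed in repeat_seeds:
                cfg = ClusterConfig(
                    k=k, method=method, seed=int(rep_seed),
                    epsilon=epsilon, n_restarts=n_restarts,
                )
                model = cluster_histograms(H, cfg)
                rep = evaluate(row_labels, model.assignments)
                fs.append(rep.f_measure)
                es.append(rep.entropy)
            rows.append(
                {
                    "method": method,
                    "k": k,
                    "f_mean": float(np.mean(fs)),
                    "f_std": float(np.std(fs)),
                    "entropy_mean": float(np.mean(es)),
                    "entropy_std": float(np.std(es)),
                    "repeats": repeats,
                }
            )
    return pd.DataFrame(rows)
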