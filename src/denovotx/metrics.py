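"""External clustering metrics against truth labels.

Implemented directly from their definitions (a library implementation is
used only as a cross-check in the test suite): the adjusted Rand index
(pair-counting agreement corrected for chance), entropy-based homogeneity
(each cluster holds one class) and completeness (each class lies in one
cluster), and the V-measure, their harmonic mean.
"""

from __future__ import annotations

from typing import Hashable, Mapping, Sequence

import numpy as np


def contingency_table(truth: Sequence[Hashable], predicted: Sequence[Hashable]) -> np.ndarray:
    """Counts n_ij of items with truth class i assigned to cluster j."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"label sets differ in size: {len(truth)} vs {len(predicted)}"
        )
    classes = {c: i for i, c in enumerate(dict.fromkeys(truth))}
    clusters = {k: j for j, k in enumerate(dict.fromkeys(predicted))}
    table = np.zeros((len(classes), len(clusters)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        table[classes[t], clusters[p]] += 1
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(truth: Sequence, predicted: Sequence) -> float:
    table = contingency_table(truth, predicted)
    n = table.sum()
    sum_cells = _comb2(table).sum()
    sum_rows = _comb2(table.sum(axis=1)).sum()
    sum_cols = _comb2(table.sum(axis=0)).sum()
    expected = sum_rows * sum_cols / _comb2(np.array(n))
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def homogeneity_completeness_v(truth: Sequence, predicted: Sequence) -> tuple[float, float, float]:
    table = contingency_table(truth, predicted).astype(float)
    n = table.sum()
    class_counts = table.sum(axis=1)
    cluster_counts = table.sum(axis=0)
    h_class = _entropy(class_counts)
    h_cluster = _entropy(cluster_counts)
    # conditional entropy of classes given clusters
    p = table / n
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.where(table > 0, np.log(table / cluster_counts[None, :]), 0.0)
    h_class_given_cluster = float(-(p * log_term).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term_t = np.where(table > 0, np.log(table / class_counts[:, None]), 0.0)
    h_cluster_given_class = float(-(p * log_term_t).sum())

    homogeneity = 1.0 if h_class == 0 else 1.0 - h_class_given_cluster / h_class
    completeness = 1.0 if h_cluster == 0 else 1.0 - h_cluster_given_class / h_cluster
    if homogeneity + completeness == 0:
        v = 0.0
    else:
        v = 2 * homogeneity * completeness / (homogeneity + completeness)
    return homogeneity, completeness, v


def clustering_metrics(
    truth: Sequence | Mapping[str, Hashable],
    predicted: Sequence | Mapping[str, Hashable],
) -> dict[str, float]:
    """ARI, homogeneity, completeness, and V-measure of a predicted
    partition against the truth.  Mappings (read_id -> label) are aligned
    on their shared keys, which must coincide."""
    if isinstance(truth, Mapping) or isinstance(predicted, Mapping):
        if not (isinstance(truth, Mapping) and isinstance(predicted, Mapping)):
            raise TypeError("pass either two mappings or two sequences")
        if set(truth) != set(predicted):
            raise ValueError("truth and predicted label different read sets")
        keys = sorted(truth)
        truth = [truth[k] for k in keys]
        predicted = [predicted[k] for k in keys]
    h, c, v = homogeneity_completeness_v(truth, predicted)
    return {
        "ari": adjusted_rand_index(truth, predicted),
        "homogeneity": h,
        "completeness": c,
        "v_measure": v,
    }
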