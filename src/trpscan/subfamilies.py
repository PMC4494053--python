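"""Subfamily detection by agglomerative encoding-cost clustering, major
subfamily selection, and per-subfamily model building.

The encoding cost of a partition is, per cluster,

    cost(C) = sum over match columns of -ln L(residues | pseudocounted
              column profile of C)
            + penalty_scale * (20-1) * L_match * (1/2) * ln(|C|)

in nats.  Merging starts from singletons, always takes the cheapest merge
(smallest change in total cost, ties broken on the lexicographically smallest
label pair), and the returned partition is the trajectory state with the
minimum total cost.  The pseudocounted likelihood term carries the signal:
merging near-identical sequences sharpens the profile and lowers the cost,
merging across subfamilies dilutes it and raises the cost.  The BIC-style
per-cluster penalty is kept at a small default weight where it only breaks
near-ties; at full weight the log(1) = 0 cost of singleton clusters makes the
all-singleton partition globally optimal, which defeats the purpose of the
trajectory minimum.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Alignment
from .profiles import (
    N_AA,
    ProfileModel,
    build_profile,
    calibrate,
    match_columns,
)

log = logging.getLogger("trpscan")


class ClusteringError(ValueError):
    pass


@dataclasses.dataclass
class SubfamilyPartition:
    cluster_of: dict[str, str]
    cluster_sizes: dict[str, int]
    total_cost: float  # nats
    trajectory: list[tuple[int, str, str, float]] = dataclasses.field(default_factory=list)

    def members(self, label: str) -> list[str]:
        return [s for s, c in self.cluster_of.items() if c == label]


def _counts_matrix(alignment: Alignment) -> np.ndarray:
    """(n_seqs, L_match, 20) one-hot residue indicators over match columns."""
    mat = alignment.to_indices()
    cols = match_columns(alignment)
    sub = mat[:, cols]
    n, L = sub.shape
    onehot = np.zeros((n, L, N_AA))
    rows, colpos = np.nonzero(sub < N_AA)
    onehot[rows, colpos, sub[rows, colpos]] = 1.0
    return onehot


def partition_cost(
    counts: np.ndarray,
    members_per_cluster: Sequence[Sequence[int]],
    pseudocount_weight: float = 2.0,
    penalty_scale: float = 0.05,
) -> float:
    """Total encoding cost (nats) of a partition given one-hot counts."""
    return sum(
        _cluster_cost(
            counts[list(m)].sum(axis=0), len(m), pseudocount_weight, penalty_scale
        )
        for m in members_per_cluster
    )


def _cluster_cost(
    col_counts: np.ndarray, size: int, w: float, penalty_scale: float
) -> float:
    """col_counts: (L, 20) residue counts of one cluster."""
    L = col_counts.shape[0]
    n_res = col_counts.sum(axis=1, keepdims=True)
    p = (col_counts + w / N_AA) / (n_res + w)
    nll = float(-(col_counts * np.log(p)).sum())
    penalty = penalty_scale * (N_AA - 1) * L * 0.5 * np.log(size)
    return nll + penalty


def detect_subfamilies(
    alignment: Alignment,
    pseudocount_weight: float = 2.0,
    penalty_scale: float = 0.05,
) -> SubfamilyPartition:
    """Agglomerative merging from singletons; returns the trajectory state of
    minimum total encoding cost."""
    if alignment.n_seqs < 2:
        raise ClusteringError("need at least 2 sequences")
    counts = _counts_matrix(alignment)
    n = alignment.n_seqs
    w, ps = pseudocount_weight, penalty_scale

    width = len(str(n))
    labels = [f"c{i:0{width}d}" for i in range(n)]
    # live clusters: label -> (member indices, summed counts, cost)
    clusters: dict[str, tuple[list[int], np.ndarray, float]] = {}
    for i, lab in enumerate(labels):
        c = counts[i]
        clusters[lab] = ([i], c, _cluster_cost(c, 1, w, ps))
    total = sum(v[2] for v in clusters.values())

    # pairwise merge deltas
    def merge_delta(a: str, b: str) -> float:
        ma, ca, costa = clusters[a]
        mb, cb, costb = clusters[b]
        merged_cost = _cluster_cost(ca + cb, len(ma) + len(mb), w, ps)
        return merged_cost - costa - costb

    deltas: dict[tuple[str, str], float] = {}
    live = sorted(clusters)
    for i, a in enumerate(live):
        for b in live[i + 1 :]:
            deltas[(a, b)] = merge_delta(a, b)

    best_total = total
    best_step = 0
    merges: list[tuple[str, str]] = []
    trajectory: list[tuple[int, str, str, float]] = [(0, "", "", total)]
    step = 0
    while len(clusters) > 1:
        # cheapest merge; ties -> lexicographically smallest (a, b)
        min_delta = min(deltas.values())
        pair = min(p for p, d in deltas.items() if d <= min_delta + 1e-12)
        a, b = pair
        ma, ca, costa = clusters[a]
        mb, cb, costb = clusters[b]
        merged_counts = ca + cb
        merged_cost = _cluster_cost(merged_counts, len(ma) + len(mb), w, ps)
        total += merged_cost - costa - costb
        del clusters[b]
        clusters[a] = (ma + mb, merged_counts, merged_cost)
        deltas = {p: d for p, d in deltas.items() if a not in p and b not in p}
        for other in clusters:
            if other == a:
                continue
            key = (a, other) if a < other else (other, a)
            deltas[key] = merge_delta(*key)
        step += 1
        merges.append((a, b))
        trajectory.append((step, a, b, total))
        if total < best_total - 1e-12:
            best_total = total
            best_step = step

    # replay merges up to the best step to recover that partition
    parent = {lab: lab for lab in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in merges[:best_step]:
        parent[find(b)] = find(a)
    cluster_of = {alignment.ids[i]: find(labels[i]) for i in range(n)}
    sizes: dict[str, int] = {}
    for lab in cluster_of.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    return SubfamilyPartition(
        cluster_of=cluster_of,
        cluster_sizes=sizes,
        total_cost=best_total,
        trajectory=trajectory,
    )


def select_major_subfamilies(
    partition: SubfamilyPartition, min_fraction: float = 0.05
) -> tuple[list[str], float]:
    """Clusters holding at least min_fraction of all sequences, largest first,
    plus the fraction of sequences they jointly cover."""
    if not 0.0 < min_fraction <= 1.0:
        raise ClusteringError("min_fraction must be in (0, 1]")
    total = sum(partition.cluster_sizes.values())
    selected = sorted(
        (lab for lab, sz in partition.cluster_sizes.items() if sz >= min_fraction * total),
        key=lambda lab: (-partition.cluster_sizes[lab], lab),
    )
    coverage = sum(partition.cluster_sizes[lab] for lab in selected) / total if total else 0.0
    return selected, coverage


def build_subfamily_models(
    alignment: Alignment,
    partition: SubfamilyPartition,
    selected: Sequence[str],
    pseudocount_weight: float = 2.0,
    calibration_samples: int = 200,
    rng_seed: int = 0,
    unspecific_name: str = "unspecific",
) -> tuple[list[ProfileModel], ProfileModel]:
    """One calibrated profile per selected cluster plus one pooled
    "unspecific" model built from all rows (the analogue of a generic
    ion-transport model that matches every subfamily)."""
    models: list[ProfileModel] = []
    index = {name: k for k, name in enumerate(alignment.ids)}
    for j, label in enumerate(selected):
        members = partition.members(label)
        if not members:
            raise ClusteringError(f"selected cluster {label!r} not in partition")
        if len(members) < 2:
            log.warning("cluster %s has <2 sequences; model built anyway", label)
        sub = alignment.subset([index[m] for m in members])
        model = build_profile(sub, pseudocount_weight, name=label)
        calibrate(model, n_samples=calibration_samples, rng_seed=rng_seed + j)
        models.append(model)
    unspecific = build_profile(alignment, pseudocount_weight, name=unspecific_name)
    calibrate(unspecific, n_samples=calibration_samples, rng_seed=rng_seed + len(selected))
    return models, unspecific


def partition_to_tsv(partition: SubfamilyPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tcluster_label\n")
        for sid in sorted(partition.cluster_of):
            fh.write(f"{sid}\t{partition.cluster_of[sid]}\n")


def trajectory_to_tsv(partition: SubfamilyPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tmerged_pair\ttotal_cost\n")
        for step, a, b, cost in partition.trajectory:
            fh.write(f"{step}\t{a}+{b}\t{cost:.6f}\n")
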