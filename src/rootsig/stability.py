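"""Clusterwise bootstrap stability of a Jaccard-distance bioset clustering.

Nonparametric bootstrap scheme for clusterwise stability: draw n biosets
with replacement, recluster the resample with the same linkage and the same
number of clusters k as the original partition, and score each original
cluster by the maximum Jaccard set-similarity between it and any cluster of
the resampled tree, computed on original bioset indices (duplicates drawn by
the bootstrap collapse to their original identity). The mean of these
per-run similarities is the cluster's stability index; clusters above the
robustness threshold (default 0.6) are *robust*, those at or below the
dissolution threshold (default 0.5) are *dissolved*, anything between is
*indeterminate*.

Similarity bookkeeping per run: the original cluster is first restricted to
the indices actually present in the resample; if none of its members were
drawn the run carries no information about the cluster and is, by default,
excluded from its mean (the count of such runs is reported). Set
``skip_empty_draws=False`` to instead count those runs as similarity 0 in a
strict all-B mean.

Distances between resampled biosets are looked up in the precomputed
original distance matrix (a resampled bioset is an exact copy of its
original), so B runs cost B reclusterings and no matrix rebuilds.

Reproducibility: randomness comes from ``numpy.random.default_rng`` seeded
from the config; per-run generators are derived with
``numpy.random.SeedSequence(seed).spawn(B)``, so run b is reproducible in
isolation and the full report is bit-identical across platforms for a fixed
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Bioset
from .clustering import (
    ClusterPartition,
    build_matrix,
    cut_tree,
    hierarchical_cluster,
    jaccard_distance_matrix,
)

logger = logging.getLogger(__name__)

ROBUST_THRESHOLD = 0.6
DISSOLVED_THRESHOLD = 0.5


@dataclass(frozen=True)
class StabilityConfig:
    B: int = 1000
    k: int = 14
    linkage: str = "average"
    seed: int = 0
    robust_threshold: float = ROBUST_THRESHOLD
    dissolved_threshold: float = DISSOLVED_THRESHOLD
    skip_empty_draws: bool = True

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 <= self.dissolved_threshold <= self.robust_threshold <= 1.0:
            raise ValueError(
                "need 0 <= dissolved_threshold <= robust_threshold <= 1"
            )


@dataclass
class ClusterStability:
    cluster_id: int
    members: list[str]
    per_run: list[float | None]  # length B; None where no member was drawn
    mean: float
    verdict: str  # robust / indeterminate / dissolved
    n_empty_draws: int


@dataclass
class StabilityReport:
    clusters: list[ClusterStability]
    config: StabilityConfig
    n_biosets: int
    n_degenerate_runs: int  # resamples with < 2 distinct biosets

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": [c.cluster_id for c in self.clusters],
                "n_members": [len(c.members) for c in self.clusters],
                "members": [",".join(c.members) for c in self.clusters],
                "mean_stability": [c.mean for c in self.clusters],
                "verdict": [c.verdict for c in self.clusters],
                "n_empty_draws": [c.n_empty_draws for c in self.clusters],
            }
        )

    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "config": asdict(self.config),
            "n_biosets": self.n_biosets,
            "n_degenerate_runs": self.n_degenerate_runs,
            "clusters": [asdict(c) for c in self.clusters],
        }
        return json.dumps(payload, indent=indent)


def bootstrap_resample(
    corpus: Sequence[Bioset], rng: np.random.Generator
) -> tuple[list[Bioset], np.ndarray]:
    """Draw n biosets with replacement; returns (resample, original indices)."""
    n = len(corpus)
    if n < 2:
        raise ValueError("need at least 2 biosets to resample")
    idx = rng.integers(0, n, size=n)
    return [corpus[i] for i in idx], idx


def match_similarity(
    original_cluster: set[int],
    bootstrap_labels: Sequence[int],
    provenance: Sequence[int],
) -> float:
    """Best Jaccard match of an original cluster among bootstrap clusters.

    ``bootstrap_labels[p]`` is the cluster label of resample position p and
    ``provenance[p]`` the original index drawn there. The original cluster is
    restricted to indices present in the resample; each bootstrap cluster is
    mapped to its set of distinct original indices; the maximum Jaccard
    coefficient over bootstrap clusters is returned, or 0.0 if no member of
    the original cluster was drawn.
    """
    if not original_cluster:
        raise ValueError("original cluster must be nonempty")
    drawn = set(provenance)
    restricted = original_cluster & drawn
    if not restricted:
        return 0.0
    by_label: dict[int, set[int]] = {}
    for lab, orig in zip(bootstrap_labels, provenance):
        by_label.setdefault(lab, set()).add(int(orig))
    best = 0.0
    for members in by_label.values():
        j = len(restricted & members) / len(restricted | members)
        best = max(best, j)
    return best


def assess_stability(
    corpus: Sequence[Bioset],
    config: StabilityConfig,
    partition: ClusterPartition | None = None,
) -> StabilityReport:
    """Run the full bootstrap stability assessment on a corpus.

    The original partition is computed at ``config.k`` with ``config.linkage``
    unless one is passed in; every bootstrap reclustering reuses the same k.
    """
    n = len(corpus)
    if not 1 <= config.k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    matrix = build_matrix(corpus)
    dist = jaccard_distance_matrix(matrix)
    d = dist.to_numpy()
    if partition is None:
        tree = hierarchical_cluster(dist, linkage=config.linkage)
        partition = cut_tree(tree, config.k)

    id_to_idx = {b.bioset_id: i for i, b in enumerate(corpus)}
    original_clusters: dict[int, set[int]] = {
        lab: {id_to_idx[m] for m in members}
        for lab, members in partition.clusters().items()
        if members
    }

    children = np.random.SeedSequence(config.seed).spawn(config.B)
    per_run: dict[int, list[float | None]] = {lab: [] for lab in original_clusters}
    empty_draws = {lab: 0 for lab in original_clusters}
    n_degenerate = 0
    positions = [str(p) for p in range(n)]
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) < 2:
            n_degenerate += 1
            logger.info("bootstrap run drew < 2 distinct biosets")
        d_boot = d[np.ix_(idx, idx)]
        np.fill_diagonal(d_boot, 0.0)
        tree_b = hierarchical_cluster(d_boot, linkage=config.linkage,
                                      leaf_names=positions)
        part_b = cut_tree(tree_b, config.k)
        labels = [part_b.assignment[p] for p in positions]
        drawn = set(int(i) for i in idx)
        for lab, members in original_clusters.items():
            if not members & drawn:
                empty_draws[lab] += 1
                per_run[lab].append(None if config.skip_empty_draws else 0.0)
            else:
                per_run[lab].append(match_similarity(members, labels, idx))

    idx_to_id = {i: b.bioset_id for i, b in enumerate(corpus)}
    clusters = []
    for lab in sorted(original_clusters):
        runs = per_run[lab]
        vals = [v for v in runs if v is not None]
        mean = float(np.mean(vals)) if vals else 0.0
        if mean > config.robust_threshold:
            verdict = "robust"
        elif mean <= config.dissolved_threshold:
            verdict = "dissolved"
        else:
            verdict = "indeterminate"
        clusters.append(
            ClusterStability(
                cluster_id=lab,
                members=sorted(idx_to_id[i] for i in original_clusters[lab]),
                per_run=runs,
                mean=mean,
                verdict=verdict,
                n_empty_draws=empty_draws[lab],
            )
        )
    return StabilityReport(
        clusters=clusters,
        config=config,
        n_biosets=n,
        n_degenerate_runs=n_degenerate,
    )
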