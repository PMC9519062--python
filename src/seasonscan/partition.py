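"""k-means partitioning of samples in Hellinger space and the optimal-k scan.

The seasonal partition is not chosen by a geometric criterion: samples are
clustered for every k in a range, the IndVal permutation test is run at each
k, and the partition maximising the summed IndVal of the significant taxa is
selected.  Clustering Hellinger-transformed profiles with the Euclidean
metric is equivalent to clustering the raw profiles under the Hellinger
distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .otu_io import OtuTable
from .transform import HellingerMatrix, hellinger_transform

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    """A k-cluster assignment of samples."""

    k: int
    labels: np.ndarray  # per-sample cluster index in 0..k-1
    sizes: np.ndarray  # per-cluster sample counts
    inertia: float  # within-cluster sum of squares
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if (self.sizes == 0).any():
            raise ValueError("every cluster must be non-empty")
        if self.sizes.sum() != self.labels.size:
            raise ValueError("cluster sizes must sum to the sample count")


@dataclass
class PartitionScan:
    """Result of the successive-k scan: per-k cumulative significant IndVal
    and the arg-max partition (ties broken toward smaller k)."""

    k_values: list[int]
    cum_indval: np.ndarray
    n_significant: np.ndarray
    best_k: int
    best_partition: Partition
    partitions: dict[int, Partition] = field(default_factory=dict)
    indval_tables: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "n_significant": self.n_significant,
                "cum_indval": self.cum_indval,
            }
        )


def _fix_empty_clusters(labels: np.ndarray, k: int) -> np.ndarray:
    """Move samples out of the largest clusters into any empty ones.

    Only reachable for degenerate inputs (e.g. fewer distinct profiles than
    k); keeps the partition valid so downstream statistics stay defined.
    """
    labels = labels.copy()
    sizes = np.bincount(labels, minlength=k)
    for empty in np.flatnonzero(sizes == 0):
        donor = int(np.argmax(sizes))
        move = int(np.flatnonzero(labels == donor)[-1])
        labels[move] = empty
        sizes = np.bincount(labels, minlength=k)
    return labels


def kmeans_partition(
    H: HellingerMatrix,
    k: int,
    restarts: int = 25,
    seed: int = 0,
    max_iter: int = 300,
) -> Partition:
    """Lloyd's k-means on Hellinger rows, best of ``restarts`` k-means++ runs.

    Deterministic given ``seed``.  Raises if k is outside [2, n_samples - 1].
    """
    n = H.values.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} outside the valid range [2, {n - 1}]")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=max_iter,
        random_state=seed % (2**32),
        algorithm="lloyd",
    )
    labels = km.fit_predict(H.values)
    if (np.bincount(labels, minlength=k) == 0).any():
        logger.warning("kmeans left an empty cluster at k=%d; reassigning", k)
        labels = _fix_empty_clusters(labels, k)
    sizes = np.bincount(labels, minlength=k)
    inertia = float(
        sum(
            ((H.values[labels == c] - H.values[labels == c].mean(axis=0)) ** 2).sum()
            for c in range(k)
        )
    )
    return Partition(k=k, labels=labels, sizes=sizes, inertia=inertia,
                     sample_ids=list(H.sample_ids))


def scan_partitions(
    table: OtuTable,
    k_min: int = 2,
    k_max: int | None = None,
    n_perm: int = 999,
    fdr_alpha: float = 0.05,
    restarts: int = 25,
    seed: int = 0,
    variant: str = "group_equalized",
) -> PartitionScan:
    """Scan k = k_min..k_max, keeping the partition with the highest
    cumulative IndVal of permutation-significant taxa.

    At every k the full testing machinery is rerun: k-means clustering,
    max-IndVal permutation test (``n_perm`` reallocations) and BH FDR at
    ``fdr_alpha``; the per-k score is the sum of significant taxa's IndVal.
    """
    from .indval import indval_test  # deferred to avoid an import cycle

    n = table.n_samples
    if k_max is None:
        k_max = min(12, n - 1)
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"need 2 <= k_min <= k_max <= {n - 1}")
    H = hellinger_transform(table)
    ks = list(range(k_min, k_max + 1))
    children = np.random.SeedSequence(seed).spawn(len(ks))
    cum = np.zeros(len(ks))
    nsig = np.zeros(len(ks), dtype=int)
    partitions: dict[int, Partition] = {}
    tables: dict[int, object] = {}
    for i, k in enumerate(ks):
        km_seed, perm_seed = (int(s) for s in children[i].generate_state(2) % (2**31))
        part = kmeans_partition(H, k, restarts=restarts, seed=km_seed)
        res = indval_test(
            table, part, n_perm=n_perm, fdr_alpha=fdr_alpha,
            seed=perm_seed, variant=variant,
        )
        cum[i] = float(res.stat[res.significant].sum())
        nsig[i] = int(res.significant.sum())
        partitions[k] = part
        tables[k] = res
        logger.info("scan k=%d: %d significant taxa, cum IndVal %.3f", k, nsig[i], cum[i])
    best_i = int(np.argmax(cum))  # argmax takes the first maximum -> smaller k on ties
    best_k = ks[best_i]
    return PartitionScan(
        k_values=ks,
        cum_indval=cum,
        n_significant=nsig,
        best_k=best_k,
        best_partition=partitions[best_k],
        partitions=partitions,
        indval_tables=tables,
    )
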