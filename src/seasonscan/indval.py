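"""Indicator value (IndVal) analysis with max-statistic permutation testing.

For a taxon *t* and a cluster *c* of a sample partition:

* specificity ``A(t, c)`` — the taxon's mean abundance in *c* divided by the
  sum of its mean abundances over all clusters (using cluster means already
  equalises unequal cluster sizes);
* fidelity ``B(t, c)`` — the fraction of samples in *c* where the taxon is
  present (count > 0).

The per-cluster statistic is ``sqrt(A * B)`` for the group-equalised variant
(the default, as in the *indicspecies* convention) or ``A * B`` for the
classic Dufrene–Legendre product.  Only the per-taxon maximum over clusters
is tested for significance: the null distribution is generated by randomly
reallocating samples among clusters (one shared label permutation per
iteration, preserving taxon–taxon correlation), and p-values are corrected
across taxa by Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .otu_io import OtuTable
from .partition import Partition

VARIANTS = ("classic", "group_equalized")


@dataclass
class IndValTable:
    """Per-taxon IndVal components and significance.

    ``A``, ``B`` and ``indval`` are (n_taxa, k) arrays; ``stat`` is the
    per-taxon maximum IndVal, tested against its permutation null and
    BH-adjusted into ``q_value``.
    """

    taxon_ids: list[str]
    A: np.ndarray
    B: np.ndarray
    indval: np.ndarray
    best_cluster: np.ndarray
    stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    significant: np.ndarray
    all_zero: np.ndarray
    variant: str
    n_perm: int
    fdr_alpha: float

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(len(self.taxon_ids))
        return pd.DataFrame(
            {
                "taxon_id": self.taxon_ids,
                "best_cluster": self.best_cluster,
                "A_best": self.A[idx, self.best_cluster],
                "B_best": self.B[idx, self.best_cluster],
                "indval": self.stat,
                "p_value": self.p_value,
                "q_value": self.q_value,
                "significant": self.significant,
            }
        )


def _membership(labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    member = np.zeros((labels.size, k))
    member[np.arange(labels.size), labels] = 1.0
    sizes = member.sum(axis=0)
    if (sizes == 0).any():
        raise ValueError("every cluster must be non-empty")
    return member, sizes


def _indval_arrays(
    counts: np.ndarray, member: np.ndarray, sizes: np.ndarray, variant: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised A, B, indval for counts (taxa x samples) and one-hot member."""
    means = (counts @ member) / sizes
    denom = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / np.where(denom > 0, denom, 1.0), 0.0)
    B = ((counts > 0).astype(float) @ member) / sizes
    iv = A * B
    if variant == "group_equalized":
        iv = np.sqrt(iv)
    return A, B, iv


def _check(table: OtuTable, labels: np.ndarray, variant: str) -> tuple[np.ndarray, int]:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    labels = np.asarray(labels)
    if labels.size != table.n_samples:
        raise ValueError("labels must cover every sample")
    k = int(labels.max()) + 1
    return labels, k


def indval_components(
    table: OtuTable, labels: Partition | np.ndarray, variant: str = "group_equalized"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Specificity A, fidelity B and the per-cluster IndVal statistic.

    Returns ``(A, B, indval)`` arrays of shape (n_taxa, k).  Taxa with zero
    total abundance have undefined specificity; their rows are set to 0.
    """
    if isinstance(labels, Partition):
        labels = labels.labels
    labels, k = _check(table, labels, variant)
    member, sizes = _membership(labels, k)
    return _indval_arrays(table.counts.astype(float), member, sizes, variant)


def permutation_test(
    table: OtuTable,
    labels: Partition | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    variant: str = "group_equalized",
    reallocation: str = "shared",
) -> np.ndarray:
    """Permutation p-values for each taxon's maximum IndVal.

    The observed statistic is the max-over-clusters IndVal.  Each of the
    ``n_perm`` null draws permutes the sample-to-cluster assignment (one
    shared permutation applied to all taxa, or an independent permutation per
    taxon with ``reallocation="per_taxon"``) and recomputes the max statistic;
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if reallocation not in ("shared", "per_taxon"):
        raise ValueError("reallocation must be 'shared' or 'per_taxon'")
    if isinstance(labels, Partition):
        labels = labels.labels
    labels, k = _check(table, labels, variant)
    counts = table.counts.astype(float)
    member, sizes = _membership(labels, k)
    _, _, iv = _indval_arrays(counts, member, sizes, variant)
    observed = iv.max(axis=1)

    rng = np.random.default_rng(seed)
    n = labels.size
    exceed = np.zeros(table.n_taxa, dtype=np.int64)
    for _ in range(n_perm):
        if reallocation == "shared":
            perm_counts = counts[:, rng.permutation(n)]
        else:
            # independent reallocation of each taxon's abundances among samples
            order = np.argsort(rng.random((table.n_taxa, n)), axis=1)
            perm_counts = np.take_along_axis(counts, order, axis=1)
        _, _, iv_null = _indval_arrays(perm_counts, member, sizes, variant)
        exceed += iv_null.max(axis=1) >= observed
    return (1.0 + exceed) / (1.0 + n_perm)


def adjust_fdr_bh(
    p_values: np.ndarray, fdr_alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns ``(q_values, significant)`` where ``q`` is the BH-adjusted
    p-value and ``significant = q <= fdr_alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=fdr_alpha, method="fdr_bh")
    return q, reject


def indval_test(
    table: OtuTable,
    partition: Partition,
    n_perm: int = 999,
    fdr_alpha: float = 0.05,
    seed: int = 0,
    variant: str = "group_equalized",
    reallocation: str = "shared",
) -> IndValTable:
    """Full IndVal analysis for one partition: components, max-stat
    permutation test, and BH FDR across taxa."""
    A, B, iv = indval_components(table, partition, variant)
    # ties between clusters broken toward the lower cluster index (argmax rule)
    best = iv.argmax(axis=1)
    stat = iv.max(axis=1)
    all_zero = table.taxon_totals() == 0
    p = permutation_test(
        table, partition, n_perm=n_perm, seed=seed, variant=variant,
        reallocation=reallocation,
    )
    q, sig = adjust_fdr_bh(p, fdr_alpha)
    sig = sig & ~all_zero
    return IndValTable(
        taxon_ids=list(table.taxon_ids),
        A=A,
        B=B,
        indval=iv,
        best_cluster=best,
        stat=stat,
        p_value=p,
        q_value=q,
        significant=sig,
        all_zero=all_zero,
        variant=variant,
        n_perm=n_perm,
        fdr_alpha=fdr_alpha,
    )
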