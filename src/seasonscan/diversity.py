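"""Per-sample diversity (exponential Shannon entropy) and cluster comparison.

D = exp(H) with H the Shannon entropy in nats is the Hill number of order 1,
the effective number of equally abundant taxa; it is scale-invariant and
bounded by the number of taxa present.  Clusters are compared by one-way
ANOVA with Tukey HSD post-hoc pairwise tests (Tukey–Kramer for unequal
group sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .indval import IndValTable
from .otu_io import OtuTable
from .partition import Partition

SUBSETS = ("all", "indicators_only", "background_only")


@dataclass
class TukeyResult:
    """One-way ANOVA F and p plus the Tukey HSD pairwise table."""

    F: float
    p: float
    pairwise: pd.DataFrame  # cluster_i, cluster_j, diff, q, p_adj
    groups: list[int]


def exp_shannon(sample_counts: np.ndarray) -> float:
    """Exponential Shannon entropy of one sample's counts (Hill number q=1)."""
    c = np.asarray(sample_counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("sample has no counts; diversity undefined")
    p = c[c > 0] / total
    return float(np.exp(-(p * np.log(p)).sum()))


def diversity_per_sample(
    table: OtuTable,
    partition: Partition | None = None,
    indval: IndValTable | None = None,
    subsets: tuple[str, ...] = ("all",),
) -> pd.DataFrame:
    """D for each sample, optionally restricted to indicator or background taxa.

    ``indicators_only`` keeps permutation-significant taxa, ``background_only``
    the rest (requires an IndVal table).  Samples with no reads in a subset
    get NaN.
    """
    rows = []
    for subset in subsets:
        if subset not in SUBSETS:
            raise ValueError(f"unknown subset {subset!r}")
        if subset == "all":
            mask = np.ones(table.n_taxa, dtype=bool)
        else:
            if indval is None:
                raise ValueError(f"subset {subset!r} needs an IndVal table")
            mask = indval.significant if subset == "indicators_only" else ~indval.significant
        sub = table.counts[mask]
        for j, sample in enumerate(table.sample_ids):
            col = sub[:, j]
            D = exp_shannon(col) if col.sum() > 0 else np.nan
            rows.append(
                {
                    "sample_id": sample,
                    "cluster": int(partition.labels[j]) if partition is not None else -1,
                    "subset": subset,
                    "D": D,
                }
            )
    return pd.DataFrame(rows)


def anova_tukey(
    D: np.ndarray, clusters: np.ndarray, alpha: float = 0.05
) -> TukeyResult:
    """One-way fixed-effects ANOVA of D across clusters plus Tukey HSD.

    Clusters with fewer than 2 (non-NaN) values are excluded with a warning.
    The pairwise table reports the mean difference, the studentized-range
    statistic q (Tukey–Kramer standard error for unequal sizes) and the
    adjusted p-value.
    """
    D = np.asarray(D, dtype=float)
    clusters = np.asarray(clusters)
    ok = ~np.isnan(D)
    D, clusters = D[ok], clusters[ok]
    groups: list[int] = []
    values: list[np.ndarray] = []
    for c in np.unique(clusters):
        v = D[clusters == c]
        if v.size < 2:
            warnings.warn(f"cluster {c} has < 2 samples; excluded from ANOVA",
                          stacklevel=2)
            continue
        groups.append(int(c))
        values.append(v)
    if len(groups) < 2:
        raise ValueError("need at least two clusters with >= 2 samples")

    F, p = stats.f_oneway(*values)
    if np.isnan(F):  # zero variance everywhere
        F, p = 0.0, 1.0

    # pooled within-group mean square for the studentized-range statistic
    ns = np.array([v.size for v in values])
    df_w = int(ns.sum() - len(values))
    msw = sum(((v - v.mean()) ** 2).sum() for v in values) / df_w if df_w else 0.0

    hsd = stats.tukey_hsd(*values)
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            diff = float(values[a].mean() - values[b].mean())
            se = np.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se if se > 0 else 0.0
            rows.append(
                {
                    "cluster_i": groups[a],
                    "cluster_j": groups[b],
                    "diff": diff,
                    "q": q,
                    "p_adj": float(np.clip(hsd.pvalue[a, b], 0.0, 1.0)),
                }
            )
    return TukeyResult(F=float(F), p=float(p), pairwise=pd.DataFrame(rows), groups=groups)
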