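"""Taxon typology: seasonal indicators vs the stable core vs sporadic taxa.

Permutation-significant taxa are seasonal indicators of their best cluster.
Non-significant taxa that occur in most samples form the stable (resistant)
core; non-significant taxa seen in only a few samples are sporadic
background.  The mean:max abundance ratio summarises profile flatness —
close to 1 for a stable taxon, close to 1/n for a single bloom or spike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .indval import IndValTable
from .otu_io import OtuTable

COMPONENTS = ("seasonal_indicator", "stable_core", "sporadic")


def mean_max_ratio(table: OtuTable) -> np.ndarray:
    """Per-taxon arithmetic mean over all samples divided by the maximum.

    Zero-count samples are included in the mean (flatness is judged against
    the whole series).  All-zero taxa have an undefined ratio and get NaN.
    """
    counts = table.counts.astype(float)
    mx = counts.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = counts.mean(axis=1) / mx
    ratio[mx == 0] = np.nan
    return ratio


def occurrence(table: OtuTable) -> np.ndarray:
    """Per-taxon fraction of samples with a nonzero count."""
    return (table.counts > 0).mean(axis=1)


def classify_taxa(
    indval: IndValTable,
    occ: np.ndarray,
    ratio: np.ndarray,
    occ_threshold: float = 0.80,
    sporadic_occ: float = 0.10,
) -> pd.DataFrame:
    """Assign every taxon exactly one component label.

    Precedence: a significant taxon is a ``seasonal_indicator`` of its best
    cluster regardless of occurrence.  Among the rest, occurrence >=
    ``occ_threshold`` -> ``stable_core``; occurrence < ``sporadic_occ`` ->
    ``sporadic``; anything in between is kept in the stable core with a
    low-confidence flag.
    """
    n = len(indval.taxon_ids)
    occ = np.asarray(occ, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if occ.size != n or ratio.size != n:
        raise ValueError("occurrence/ratio not aligned with the IndVal table")
    if not 0 <= sporadic_occ <= occ_threshold <= 1:
        raise ValueError("need 0 <= sporadic_occ <= occ_threshold <= 1")

    component = np.empty(n, dtype=object)
    low_confidence = np.zeros(n, dtype=bool)
    sig = indval.significant
    component[sig] = "seasonal_indicator"
    rest = ~sig
    component[rest & (occ >= occ_threshold)] = "stable_core"
    component[rest & (occ < sporadic_occ)] = "sporadic"
    mid = rest & (occ < occ_threshold) & (occ >= sporadic_occ)
    component[mid] = "stable_core"
    low_confidence[mid] = True

    cluster = np.where(sig, indval.best_cluster, -1)
    return pd.DataFrame(
        {
            "taxon_id": indval.taxon_ids,
            "component": component,
            "indicator_cluster": cluster,
            "occurrence": occ,
            "mean_max_ratio": ratio,
            "low_confidence": low_confidence,
        }
    )


def classify_table(
    table: OtuTable,
    indval: IndValTable,
    occ_threshold: float = 0.80,
    sporadic_occ: float = 0.10,
) -> pd.DataFrame:
    """Convenience wrapper computing occurrence and mean:max ratio from the
    count table before classifying."""
    if list(table.taxon_ids) != list(indval.taxon_ids):
        raise ValueError("count table and IndVal table taxa are misaligned")
    return classify_taxa(
        indval,
        occurrence(table),
        mean_max_ratio(table),
        occ_threshold=occ_threshold,
        sporadic_occ=sporadic_occ,
    )
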