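"""Hellinger transformation and transformation-based PCA.

The Hellinger transform maps a count profile to the square root of its
relative abundances; Euclidean distance between transformed profiles equals
the Hellinger distance between the raw ones, which makes Euclidean methods
(k-means, PCA) appropriate for compositional count data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .otu_io import OtuTable


@dataclass
class HellingerMatrix:
    """Hellinger-transformed abundances, samples as rows.

    Every row has unit Euclidean norm and all entries lie in [0, 1].
    """

    values: np.ndarray  # (n_samples, n_taxa)
    sample_ids: list[str]
    taxon_ids: list[str]


@dataclass
class Ordination:
    """PCA of the Hellinger matrix: per-sample scores, per-taxon loadings,
    and the fraction of variance captured by each axis."""

    scores: np.ndarray  # (n_samples, n_axes)
    loadings: np.ndarray  # (n_taxa, n_axes)
    explained_variance: np.ndarray  # fractions, non-increasing
    sample_ids: list[str]
    taxon_ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def hellinger_transform(table: OtuTable) -> HellingerMatrix:
    """Transform counts to sqrt(relative abundance), samples as rows.

    Raises if any sample has zero total reads (its profile is undefined).
    """
    totals = table.sample_totals().astype(float)
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValueError(f"samples with zero total counts: {bad}")
    values = np.sqrt(table.counts.T / totals[:, None])
    return HellingerMatrix(
        values=values,
        sample_ids=list(table.sample_ids),
        taxon_ids=list(table.taxon_ids),
    )


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    # determinism: flip each axis so its largest-magnitude loading is positive
    for a in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[i, a] < 0:
            loadings[:, a] *= -1.0
            scores[:, a] *= -1.0


def pca_hellinger(table: OtuTable, n_axes: int = 2) -> Ordination:
    """Principal components of the column-centered Hellinger matrix.

    This is transformation-based PCA: ordinary (unscaled) PCA run on
    Hellinger-transformed counts, so sample distances in the full score space
    are Hellinger distances.  Axis signs are fixed by making each axis's
    largest-magnitude taxon loading positive.
    """
    H = hellinger_transform(table)
    n_samples, n_taxa = H.values.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_axes = min(n_samples - 1, n_taxa)
    if n_axes > max_axes:
        warnings.warn(
            f"n_axes={n_axes} clipped to {max_axes} (min(samples-1, taxa))",
            stacklevel=2,
        )
        n_axes = max_axes
    pca = PCA(n_components=n_axes, svd_solver="full")
    scores = pca.fit_transform(H.values)
    loadings = pca.components_.T.copy()
    # Hellinger entries are O(1); variance below 1e-15 is numerically zero
    total_var = H.values.var(axis=0, ddof=1).sum()
    if total_var <= 1e-15:
        explained = np.zeros(n_axes)
    else:
        explained = pca.explained_variance_ / total_var
    _fix_signs(scores, loadings)
    return Ordination(
        scores=scores,
        loadings=loadings,
        explained_variance=explained,
        sample_ids=list(H.sample_ids),
        taxon_ids=list(H.taxon_ids),
    )
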