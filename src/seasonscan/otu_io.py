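"""Reading, writing, filtering and rarefying OTU count tables.

An OTU table holds non-negative integer read counts with taxa (OTUs) as rows
and samples as columns, plus optional semicolon-delimited taxonomy strings.
Sample metadata (date, depth, ice-cover flag) travels in a separate
tab-separated table keyed by ``sample_id``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OTU_HEADER = "#OTU_ID"
TAXONOMY_COL = "taxonomy"

METADATA_COLUMNS = ["sample_id", "date", "depth_m", "ice_cover"]


class OtuTableError(ValueError):
    """Raised for malformed or inconsistent OTU tables."""


@dataclass
class OtuTable:
    """Integer count matrix (taxa x samples) with ids and taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer array of shape ``(n_taxa, n_samples)``.
    taxon_ids
        Unique taxon (OTU) identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    taxonomy
        Optional per-taxon rank strings (may be empty strings).
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise OtuTableError("counts must be a 2-D matrix (taxa x samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise OtuTableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise OtuTableError("counts must be non-negative")
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n_taxa, n_samples = self.counts.shape
        if len(self.taxon_ids) != n_taxa:
            raise OtuTableError(
                f"{len(self.taxon_ids)} taxon ids for {n_taxa} count rows"
            )
        if len(self.sample_ids) != n_samples:
            raise OtuTableError(
                f"{len(self.sample_ids)} sample ids for {n_samples} count columns"
            )
        if len(set(self.taxon_ids)) != n_taxa:
            raise OtuTableError("duplicate taxon ids")
        if len(set(self.sample_ids)) != n_samples:
            raise OtuTableError("duplicate sample ids")
        if self.taxonomy is not None and len(self.taxonomy) != n_taxa:
            raise OtuTableError("taxonomy length does not match taxon count")

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def taxon_totals(self) -> np.ndarray:
        """Total reads per taxon (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by taxon id."""
        df = pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)
        df.index.name = OTU_HEADER
        return df

    def select_taxa(self, mask: np.ndarray) -> "OtuTable":
        """Subset taxa by a boolean mask or integer index array."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return OtuTable(
            counts=self.counts[idx],
            taxon_ids=[self.taxon_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            taxonomy=None if self.taxonomy is None else [self.taxonomy[i] for i in idx],
        )

    def select_samples(self, mask: np.ndarray) -> "OtuTable":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            counts=self.counts[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            taxonomy=None if self.taxonomy is None else list(self.taxonomy),
        )


def read_otu_table(path: str | Path, dialect: str = "tsv") -> OtuTable:
    """Read a tab-separated OTU table.

    The first non-comment row is the header ``#OTU_ID<TAB>sample ids...``
    with an optional trailing ``taxonomy`` column.  ``dialect="biom-tsv"``
    additionally tolerates the classic-biom preamble line and ``#OTU ID``
    spelling.
    """
    path = Path(path)
    if dialect not in ("tsv", "biom-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with path.open() as fh:
        lines = fh.read().splitlines()
    # skip biom-style comment preamble ("# Constructed from ...")
    start = 0
    while start < len(lines) and lines[start].startswith("# "):
        start += 1
    if start >= len(lines):
        raise OtuTableError(f"{path}: no header row found")
    header = lines[start].rstrip("\n").split("\t")
    first = header[0].strip()
    if first not in (OTU_HEADER, "#OTU ID", "OTU_ID"):
        raise OtuTableError(f"{path}: header must start with {OTU_HEADER!r}, got {first!r}")
    columns = header[1:]
    has_taxonomy = bool(columns) and columns[-1].strip().lower() == TAXONOMY_COL
    sample_ids = columns[:-1] if has_taxonomy else columns
    if len(set(sample_ids)) != len(sample_ids):
        raise OtuTableError(f"{path}: duplicated sample ids in header")

    taxon_ids: list[str] = []
    taxonomy: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        expected = 1 + len(sample_ids) + (1 if has_taxonomy else 0)
        if len(parts) != expected:
            raise OtuTableError(
                f"{path}:{lineno}: expected {expected} fields, got {len(parts)}"
            )
        taxon_ids.append(parts[0])
        cells = parts[1 : 1 + len(sample_ids)]
        row = []
        for col, cell in zip(sample_ids, cells):
            try:
                value = float(cell)
            except ValueError as exc:
                raise OtuTableError(
                    f"{path}:{lineno}: malformed count {cell!r} in column {col!r}"
                ) from exc
            if value != int(value):
                raise OtuTableError(
                    f"{path}:{lineno}: non-integer count {cell!r} in column {col!r}"
                )
            row.append(int(value))
        rows.append(row)
        if has_taxonomy:
            taxonomy.append(parts[-1])
    counts = np.asarray(rows, dtype=np.int64).reshape(len(taxon_ids), len(sample_ids))
    return OtuTable(
        counts=counts,
        taxon_ids=taxon_ids,
        sample_ids=list(sample_ids),
        taxonomy=taxonomy if has_taxonomy else None,
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the table in the tab-separated layout read by :func:`read_otu_table`."""
    path = Path(path)
    with path.open("w") as fh:
        header = [OTU_HEADER, *table.sample_ids]
        if table.taxonomy is not None:
            header.append(TAXONOMY_COL)
        fh.write("\t".join(header) + "\n")
        for i, taxon in enumerate(table.taxon_ids):
            row = [taxon, *(str(int(c)) for c in table.counts[i])]
            if table.taxonomy is not None:
                row.append(table.taxonomy[i])
            fh.write("\t".join(row) + "\n")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, ISO date, depth_m, ice_cover, optional truth_label)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise OtuTableError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        raise OtuTableError(f"{path}: duplicated sample_id in metadata")
    df["date"] = pd.to_datetime(df["date"])
    df["depth_m"] = df["depth_m"].astype(float)
    if (df["depth_m"] <= 0).any():
        raise OtuTableError(f"{path}: depth_m must be positive")
    df["ice_cover"] = df["ice_cover"].astype(int).astype(bool)
    return df


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out["ice_cover"] = out["ice_cover"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def filter_min_count(table: OtuTable, min_reads: int) -> OtuTable:
    """Drop taxa whose total read count over all samples is below ``min_reads``.

    With ``min_reads=5`` this is the standard low-abundance cluster filter for
    amplicon OTU tables.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.taxon_totals() >= min_reads
    if not keep.any():
        warnings.warn("filter_min_count removed every taxon", stacklevel=2)
    return table.select_taxa(keep)


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Rarefy each sample to a common depth by subsampling reads without replacement.

    Each retained sample's column is drawn from the multivariate hypergeometric
    distribution (reads are subsampled without replacement), so rarefied column
    sums equal ``depth`` exactly.  Samples with fewer than ``depth`` total reads
    are dropped and logged.

    Parameters
    ----------
    depth
        Target reads per sample.  ``None`` uses the minimum sample total.
    seed
        Seed for the subsampling RNG; the result is deterministic given it.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    sub = table.select_samples(keep)
    out = np.empty_like(sub.counts)
    for j in range(sub.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(sub.counts[:, j], depth)
    return replace(sub, counts=out)
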