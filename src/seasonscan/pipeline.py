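"""The end-to-end analysis: rarefy -> ordinate -> scan -> classify -> compare.

One seed governs every stochastic stage; each stage draws from a named
substream so stages stay reproducible when rerun from saved intermediates.
All artifacts are plain TSV/JSON so they can be inspected or re-plotted
with any tool.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import components as components_mod
from . import diversity as diversity_mod
from . import env as env_mod
from .otu_io import (OtuTable, filter_min_count, rarefy, read_otu_table,
                     read_sample_metadata, write_otu_table)
from .partition import PartitionScan, scan_partitions
from .transform import pca_hellinger

logger = logging.getLogger(__name__)

STAGE_NAMES = ("rarefy", "ordinate", "scan", "classify", "diversity", "env_lda")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    otu_path: str | None = None
    metadata_path: str | None = None
    env_path: str | None = None
    out_dir: str = "seasonscan_out"
    min_reads: int = 5
    rarefaction_depth: int | None = None  # None -> minimum sample total
    k_min: int = 2
    k_max: int | None = None
    n_perm: int = 999
    fdr_alpha: float = 0.05
    variant: str = "group_equalized"
    restarts: int = 25
    occ_threshold: float = 0.80
    sporadic_occ: float = 0.10
    n_pca_axes: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max is not None and self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if not 0 <= self.sporadic_occ <= self.occ_threshold <= 1:
            raise ValueError("need 0 <= sporadic_occ <= occ_threshold <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit codes."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGE_NAMES, children)
    }


def run_pipeline(
    config: RunConfig,
    table: OtuTable | None = None,
    metadata: pd.DataFrame | None = None,
    env_frame: pd.DataFrame | None = None,
) -> dict:
    """Execute the full analysis chain and write artifacts to ``out_dir``.

    Inputs may be passed in memory or read from the configured paths.
    Returns the JSON-ready summary dict.  On stage failure a FAILED marker
    naming the stage is written and :class:`StageError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed}
    stage = "read"
    try:
        if table is None:
            if config.otu_path is None:
                raise ValueError("no OTU table given (otu_path unset)")
            table = read_otu_table(config.otu_path)
        if metadata is None and config.metadata_path:
            metadata = read_sample_metadata(config.metadata_path)
        if env_frame is None and config.env_path:
            env_frame = pd.read_csv(config.env_path, sep="\t")

        stage = "rarefy"
        table = filter_min_count(table, config.min_reads)
        table = rarefy(table, depth=config.rarefaction_depth, seed=seeds["rarefy"])
        depth = int(table.sample_totals()[0]) if table.n_samples else 0
        summary["rarefaction_depth"] = depth
        summary["n_taxa"] = table.n_taxa
        summary["n_samples"] = table.n_samples
        write_otu_table(table, out / "otu_rarefied.tsv")

        stage = "ordinate"
        ordination = pca_hellinger(table, n_axes=config.n_pca_axes)
        ordination.scores_frame().to_csv(out / "ordination.tsv", sep="\t",
                                         index=False, float_format="%.6g")
        summary["pca_explained_variance"] = [
            round(float(v), 6) for v in ordination.explained_variance
        ]

        stage = "scan"
        scan: PartitionScan = scan_partitions(
            table,
            k_min=config.k_min,
            k_max=config.k_max,
            n_perm=config.n_perm,
            fdr_alpha=config.fdr_alpha,
            restarts=config.restarts,
            seed=seeds["scan"],
            variant=config.variant,
        )
        scan.to_frame().to_csv(out / "scan.tsv", sep="\t", index=False,
                               float_format="%.6g")
        best = scan.best_partition
        pd.DataFrame({"sample_id": table.sample_ids, "cluster": best.labels}).to_csv(
            out / "labels.tsv", sep="\t", index=False
        )
        indval_table = scan.indval_tables[scan.best_k]
        indval_table.to_frame().to_csv(out / "indval.tsv", sep="\t", index=False,
                                       float_format="%.6g")
        summary["best_k"] = scan.best_k
        summary["cum_indval"] = round(float(scan.cum_indval[scan.k_values.index(scan.best_k)]), 6)
        summary["n_significant"] = int(indval_table.significant.sum())
        summary["cluster_sizes"] = [int(s) for s in best.sizes]
        sig_share = (
            table.counts[indval_table.significant].sum(axis=0) / table.sample_totals()
        )
        summary["indicator_abundance_fraction"] = round(float(sig_share.mean()), 6)

        stage = "classify"
        typology = components_mod.classify_table(
            table, indval_table,
            occ_threshold=config.occ_threshold, sporadic_occ=config.sporadic_occ,
        )
        typology.to_csv(out / "typology.tsv", sep="\t", index=False,
                        float_format="%.6g")
        counts = typology["component"].value_counts()
        summary["component_counts"] = {
            c: int(counts.get(c, 0)) for c in components_mod.COMPONENTS
        }

        stage = "diversity"
        div = diversity_mod.diversity_per_sample(
            table, best, indval_table, subsets=diversity_mod.SUBSETS
        )
        div.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.6g")
        all_D = div[div["subset"] == "all"]
        tukey = diversity_mod.anova_tukey(
            all_D["D"].to_numpy(), all_D["cluster"].to_numpy(), alpha=config.fdr_alpha
        )
        tukey.pairwise.to_csv(out / "tukey.tsv", sep="\t", index=False,
                              float_format="%.6g")
        summary["anova_F"] = round(tukey.F, 6)
        summary["anova_p"] = float(f"{tukey.p:.3e}")
        summary["median_D"] = {
            subset: round(float(div[div["subset"] == subset]["D"].median()), 4)
            for subset in diversity_mod.SUBSETS
        }

        stage = "env_lda"
        if env_frame is None:
            logger.warning("no environmental table supplied; skipping the LDA stage")
            summary["lda"] = None
        else:
            env_df = env_mod.derive_env(env_frame)
            env_df.to_csv(out / "env_derived.tsv", sep="\t", index=False,
                          float_format="%.6g")
            if list(env_df["sample_id"]) != list(table.sample_ids):
                env_df = (
                    env_df.set_index("sample_id").loc[table.sample_ids].reset_index()
                )
            lda = env_mod.lda_clusters(env_df, best.labels)
            pd.DataFrame(
                lda.sample_scores,
                columns=[f"axis{i + 1}" for i in range(lda.sample_scores.shape[1])],
            ).assign(sample_id=table.sample_ids, cluster=best.labels).to_csv(
                out / "lda_scores.tsv", sep="\t", index=False, float_format="%.6g"
            )
            pd.DataFrame(
                lda.axes,
                index=lda.variables,
                columns=[f"axis{i + 1}" for i in range(lda.axes.shape[1])],
            ).rename_axis("variable").reset_index().assign(
                significant=lda.var_significant
            ).to_csv(out / "lda_weights.tsv", sep="\t", index=False,
                     float_format="%.6g")
            summary["lda"] = {
                "n_axes": int(lda.axes.shape[1]),
                "significant_variables": int(lda.var_significant.sum()),
                "loo_accuracy": round(
                    env_mod.loo_accuracy(env_df, best.labels), 6
                ),
            }
    except Exception as exc:  # noqa: BLE001 - stage-named abort contract
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise StageError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: best_k=%s, %s significant taxa",
                summary["best_k"], summary["n_significant"])
    return summary
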