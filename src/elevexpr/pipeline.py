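"""Pipeline orchestration: normalize -> DE (3 contrasts) -> enrichment ->
clustering, with TSV/Newick outputs and a parameter-audit run log."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .de import NegativeBinomialDE, PAIRWISE_CONTRASTS
from .enrichment import run_enrichment
from .clustering import consensus_cluster, heatmap_order, linkage_to_newick
from .normalization import estimate_size_factors, normalize, variance_stabilize

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Paths and settings for a full run; collects the analysis defaults."""

    counts: str = "counts.tsv"
    metadata: str = "metadata.tsv"
    candidates: str = "candidates.txt"
    background: str = "background.txt"
    outdir: str = "results"
    fdr_threshold: float = 0.05
    n_bins: int = 10
    bin_min_genes: int = 3
    bin_high_count_threshold: float = 3000.0
    consensus_k: int = 18
    consensus_iterations: int = 1000
    consensus_subsample_frac: float = 0.8
    nested_table: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise PipelineError("config", "fdr_threshold must be in (0, 1)")
        if self.n_bins < 2:
            raise PipelineError("config", "n_bins must be >= 2")
        if self.consensus_iterations < 1:
            raise PipelineError("config", "consensus_iterations must be >= 1")
        if not 0 < self.consensus_subsample_frac <= 1:
            raise PipelineError("config", "subsample fraction must be in (0, 1]")


def contrast_name(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}-{contrast[1]}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of in-memory results.

    Writes per-stage outputs (size factors, three DE tables, the
    Table-2-shaped enrichment summary, consensus matrix/dendrogram/labels,
    scaled heat-map matrices) plus ``run_log.txt`` under ``config.outdir``.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- load -----------------------------------------------------------
    try:
        cm = eio.read_counts(config.counts)
        sample_ids, samples = eio.read_metadata(config.metadata)
        cm = eio.attach_metadata(cm, sample_ids, samples)
        candidates = eio.read_gene_list(config.candidates, name="candidates")
        background = eio.read_gene_list(config.background, name="background")
    except (OSError, eio.DataError) as exc:
        raise PipelineError("load", str(exc)) from exc

    # --- normalize ------------------------------------------------------
    try:
        sf = estimate_size_factors(cm)
        norm = pd.DataFrame(
            normalize(cm, sf), index=cm.gene_ids, columns=cm.sample_ids
        )
        pd.DataFrame({"sample_id": cm.sample_ids, "factor": sf}).to_csv(
            out / "size_factors.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc

    # --- differential expression ---------------------------------------
    try:
        model = NegativeBinomialDE(fdr_threshold=config.fdr_threshold)
        model.fit(
            cm.counts.T,
            zones=cm.zones(),
            blocks=cm.blocks(),
            size_factors=sf,
            gene_ids=cm.gene_ids,
        )
        de_tables: dict[str, pd.DataFrame] = {}
        de_sets: dict[str, set[str]] = {}
        for contrast in PAIRWISE_CONTRASTS:
            name = contrast_name(contrast)
            table = model.results(contrast)
            de_tables[name] = table
            de_sets[name] = set(table.index[table["called"]])
            eio.write_de_table(table, out / f"de_{name}.tsv", contrast)
    except Exception as exc:
        raise PipelineError("differential_expression", str(exc)) from exc

    # --- enrichment -----------------------------------------------------
    try:
        report, details = run_enrichment(
            norm,
            candidates,
            background,
            de_sets,
            n_bins=config.n_bins,
            min_genes=config.bin_min_genes,
            high_count_threshold=config.bin_high_count_threshold,
            alpha=0.05,
            nested=config.nested_table,
            seed=config.seed,
        )
        report.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        for name, matched in details["matched"].items():
            with open(out / f"matched_background_{name}.txt", "w") as fh:
                fh.writelines(g + "\n" for g in matched.gene_ids)
    except Exception as exc:
        raise PipelineError("enrichment", str(exc)) from exc

    # --- clustering -----------------------------------------------------
    try:
        cand_in_matrix = [g for g in cm.gene_ids if g in candidates]
        expressed = norm.loc[cand_in_matrix]
        expressed = expressed[expressed.sum(axis=1) > 0]
        vst = variance_stabilize(expressed.to_numpy())
        cc = consensus_cluster(
            vst,
            k=min(config.consensus_k, cm.n_samples),
            iterations=config.consensus_iterations,
            subsample_frac=config.consensus_subsample_frac,
            seed=config.seed,
        )
        pd.DataFrame(
            cc.consensus_matrix_, index=cm.sample_ids, columns=cm.sample_ids
        ).to_csv(out / "consensus_matrix.tsv", sep="\t")
        pd.DataFrame(
            {"sample_id": cm.sample_ids, "cluster": cc.labels_}
        ).to_csv(out / "consensus_labels.tsv", sep="\t", index=False)
        with open(out / "consensus_dendrogram.nwk", "w") as fh:
            fh.write(linkage_to_newick(cc.linkage_, cm.sample_ids))

        heatmaps = {}
        landraces = cm.landraces()
        for name, de_set in de_sets.items():
            de_in = [g for g in cm.gene_ids if g in de_set and g in candidates]
            if len(de_in) < 3:
                continue
            by_lr = (
                norm.loc[de_in]
                .T.groupby(landraces)
                .mean()
                .T
            )
            order, scaled = heatmap_order(by_lr, gene_method="pearson")
            scaled.to_csv(out / f"heatmap_{name}.tsv", sep="\t")
            heatmaps[name] = scaled
    except Exception as exc:
        raise PipelineError("clustering", str(exc)) from exc

    _write_run_log(out / "run_log.txt", config, cm, de_sets, report)
    return {
        "size_factors": sf,
        "normalized": norm,
        "de_tables": de_tables,
        "de_sets": de_sets,
        "enrichment": report,
        "enrichment_details": details,
        "consensus": cc,
        "heatmaps": heatmaps,
    }


def _write_run_log(path, config, cm, de_sets, report) -> None:
    import elevexpr

    lines = [
        f"elevexpr version: {elevexpr.__version__}",
        f"samples: {cm.n_samples}  genes: {cm.n_genes}",
        "parameters:",
    ]
    for k, v in asdict(config).items():
        lines.append(f"  {k} = {v}")
    for name, s in de_sets.items():
        lines.append(f"DE genes ({name}): {len(s)}")
    lines.append("enrichment summary:")
    lines.append(report.to_string(index=False))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# reporting utilities


def fill_fraction(log2fc: float, full_scale: float = 2.11):
    """Pathway-diagram circle fill for one gene's log2 fold change.

    A fully filled circle corresponds to ``|log2fc| >= full_scale``
    (default 2.11, i.e. 2**2.11 ~ 4.32-fold); the sign gives the direction.
    Returns (fraction in [0, 1], direction, legend fold change).
    """
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    fraction = min(abs(log2fc) / full_scale, 1.0)
    if log2fc > 0:
        direction = "up_first_zone"
    elif log2fc < 0:
        direction = "up_second_zone"
    else:
        direction = "none"
    return fraction, direction, 2.0**full_scale


def summarize(
    de_sets: dict[str, set[str]], enrichment: pd.DataFrame
) -> pd.DataFrame:
    """Summary table column-compatible with the published enrichment table."""
    rows = []
    for _, r in enrichment.iterrows():
        name = r["comparison"]
        rows.append(
            {
                "comparison": name,
                "n_de": len(de_sets.get(name, set())),
                "chi2": r["chi2"],
                "p": r["p"],
                "background_ratio": r["background_ratio"],
                "de_ratio": r["de_ratio"],
                "enriched": r["enriched"],
            }
        )
    return pd.DataFrame(rows)
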