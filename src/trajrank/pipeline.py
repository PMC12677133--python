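"""End-to-end orchestration: QC -> embedding -> pseudotime -> binning ->
count forms -> RMSE ranking -> filtering -> annotation.

All tunables live in :class:`PipelineConfig`; every run logs the full
effective configuration and stamps output tables with the tool version
and a configuration hash so a run can be reproduced exactly from its
logs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    CountForm,
    CountMatrix,
    DEFAULT_MITO_PREFIXES,
    DEFAULT_NOISE_PATTERNS,
    DEFAULT_OR_PATTERNS,
    compute_qc,
    exclude_genes,
    filter_cells,
    log_transform,
    normalize_depth,
    select_hvg,
)
from .ranking import filter_panneuronal, rank_genes
from .timing_enrichment import onset_category, trajectory_auc
from .trajectory import (
    TrajectorySet,
    assign_bins,
    bin_trajectories,
    compute_dpt,
    diffusion_map,
    knn_graph,
    pca_embed,
    select_root,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every knob of the discovery pipeline, with its default."""

    reference_gene: str = "Rtp1"
    target_depth: float = 1e4
    max_mito: float = 0.2
    min_counts: int = 500
    mito_patterns: tuple[str, ...] = DEFAULT_MITO_PREFIXES
    noise_patterns: tuple[str, ...] = DEFAULT_NOISE_PATTERNS
    or_patterns: tuple[str, ...] = DEFAULT_OR_PATTERNS
    or_whitelist: tuple[str, ...] = ()
    n_hvg: int = 1000
    n_pcs: int = 40
    k_neighbors: int = 10
    n_comps: int = 15
    n_bins: int = 50
    min_cells_per_bin: int = 3
    top_k: int = 50
    root_cluster: str = "GBC"
    root_markers: tuple[str, ...] = ()
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                if isinstance(value, (tuple, list)):
                    value = ",".join(map(str, value))
                fh.write(f"{key}={value}\n")

    @classmethod
    def read(cls, path) -> "PipelineConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            hint = fields[key].type
            raw = raw.strip()
            if "tuple" in str(hint):
                kwargs[key] = tuple(v for v in raw.split(",") if v)
            elif fields[key].default.__class__ in (int,) and "float" not in str(hint):
                kwargs[key] = int(raw)
            elif isinstance(fields[key].default, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    config: PipelineConfig
    counts: CountMatrix
    meta: pd.DataFrame
    trajectories: TrajectorySet
    rank_table: pd.DataFrame
    onset: pd.DataFrame
    root_barcode: str


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(
    cfg: PipelineConfig,
    counts: CountMatrix,
    cell_meta: pd.DataFrame,
    panneuronal: set[str] | None = None,
) -> PipelineResult:
    """Run the full discovery pipeline on a count matrix.

    ``cell_meta`` must carry a ``cluster`` column (consumed, not
    recomputed).  ``panneuronal`` optionally supplies an exclusion list
    applied to the final ordering.  Deterministic given config + inputs.
    """
    logger.info("config %s: %s", cfg.config_hash(), cfg.to_dict())
    if cfg.reference_gene not in counts.genes:
        raise ValueError(
            f"reference gene {cfg.reference_gene!r} absent from the matrix"
        )

    t0 = _stage("qc")
    qc = compute_qc(counts, cfg.mito_patterns)
    meta = qc.join(cell_meta.reindex(qc.index))
    counts, meta = filter_cells(counts, meta, cfg.max_mito, cfg.min_counts)
    # noise genes (mitochondrial, Malat) removed globally
    counts = exclude_genes(counts, cfg.noise_patterns, purpose="global")
    logger.info("qc done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("normalize")
    norm = normalize_depth(counts, cfg.target_depth)
    logx = log_transform(norm)

    t0 = _stage("embed")
    # odorant-receptor genes masked out of the embedding only
    emb_keep = exclude_genes(
        counts, cfg.or_patterns, purpose="embedding-only",
        whitelist=cfg.or_whitelist,
    )
    hvg = select_hvg(
        norm[:, emb_keep],
        [g for g, k in zip(counts.genes, emb_keep) if k],
        n_top=min(cfg.n_hvg, int(emb_keep.sum())),
    )
    emb_matrix = logx[:, emb_keep][:, hvg]
    embedding = pca_embed(emb_matrix, n_pcs=min(cfg.n_pcs, min(emb_matrix.shape) - 1))
    logger.info("embed done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("dpt")
    graph = knn_graph(embedding, cfg.k_neighbors)
    dspace = diffusion_map(graph, cfg.n_comps)
    root = select_root(
        norm, counts.genes, meta,
        root_cluster=cfg.root_cluster,
        root_markers=list(cfg.root_markers) or None,
        dspace=dspace,
    )
    dspace.root = root
    pseudotime = compute_dpt(dspace, root)
    meta = meta.copy()
    meta["pseudotime"] = pseudotime
    logger.info("dpt done in %.1fs (root=%s)", time.perf_counter() - t0,
                meta.index[root])

    t0 = _stage("bin")
    bins, edges, sparse = assign_bins(
        pseudotime, cfg.n_bins, cfg.min_cells_per_bin
    )
    meta["bin"] = bins
    ts = bin_trajectories(
        norm, logx, counts.genes, bins, cfg.n_bins, edges, sparse
    )
    logger.info("bin done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("rank")
    rt = rank_genes(ts, cfg.reference_gene, k=cfg.top_k)
    if panneuronal:
        rt = filter_panneuronal(rt, panneuronal)
    logger.info("rank done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("onset")
    auc = trajectory_auc(ts, CountForm.LOG_MAX)
    onset = pd.DataFrame({"auc": auc, "onset_class": onset_category(auc)})
    logger.info("onset done in %.1fs", time.perf_counter() - t0)

    return PipelineResult(
        config=cfg, counts=counts, meta=meta, trajectories=ts,
        rank_table=rt, onset=onset, root_barcode=str(meta.index[root]),
    )


def _header(cfg: PipelineConfig) -> str:
    return f"# trajrank {__version__} config_hash={cfg.config_hash()}\n"


def write_outputs(result: PipelineResult, out_dir) -> Path:
    """Serialize a run: candidate table, trajectories, onset, metadata,
    and the effective config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(result.config)
    for name, df, index in (
        ("candidates.tsv", result.rank_table, True),
        ("trajectories.tsv", result.trajectories.to_long_df(), False),
        ("onset.tsv", result.onset, True),
        ("cell_meta.tsv", result.meta, True),
    ):
        with open(out / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index)
    result.config.write(out / "config.txt")
    return out


def export_geline(
    t: TrajectorySet,
    rt: pd.DataFrame,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict, list[str]]:
    """Long-format trajectory export backing an interactive browser.

    One record per (gene, count form, pseudotime bin) with the bin
    midpoint, value, interpolation flag and the gene's rank metadata.
    Returns (table, JSON-ready dict mirroring the table, skipped genes).
    """
    long = t.to_long_df()
    skipped: list[str] = []
    if genes is not None:
        known = [g for g in genes if g in set(long["gene"])]
        skipped = [g for g in genes if g not in set(long["gene"])]
        long = long[long["gene"].isin(known)]
        long["gene"] = pd.Categorical(long["gene"], categories=known, ordered=True)
        long = long.sort_values(["gene", "form", "bin"], kind="stable")
        long["gene"] = long["gene"].astype(str)
    rank_meta = rt.reindex(long["gene"].unique())[
        [c for c in ("mean_rank", "topk_hits", "final_rank") if c in rt.columns]
    ]
    long = long.merge(rank_meta, left_on="gene", right_index=True, how="left")
    records = long.to_dict(orient="records")  # str(float) round-trips exactly
    payload = {
        "records": json.loads(json.dumps(records, default=str)),
        "skipped_genes": skipped,
    }
    return long.reset_index(drop=True), payload, skipped
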