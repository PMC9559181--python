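"""End-to-end orchestration: tracks in, per-period clusterings and reports out.

``run_pipeline`` executes the full analysis from a single :class:`RunConfig`:
read (or simulate) tracks → detect divisions → unify the lineage → segment
into periods → normalize → trajectory distance matrices → 2-D embedding →
silhouette-optimized k-means per period → positional overlay and
lineage–cluster table → optional noise-robustness protocol.  Every
stochastic stage derives its seed from the single master seed, so reruns
with the same config are identical.  All results are CSV; plots are an
optional extra, never a data product.

Cluster indices are arbitrary within each period (there is no matching of
clusters across periods — any visual alignment of colors over time is a
presentation choice, not a computed correspondence).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .clustering_selection import (
    PeriodClustering,
    cluster_all_periods,
    write_msc_curves,
)
from .embedding import EmbeddingParams, embed_all, write_embeddings
from .errors import IntegrityError, ParameterError
from .lineage_division import LineageSet, detect_divisions, unify_lineage, write_lineage
from .robustness import run_robustness
from .synthetic_data import ColonyConfig, generate_colony
from .tracking_io import Phenotype, TrackTable, read_tracks, write_assignments, write_tracks
from .trajectory_distance import distance_matrices
from .trajectory_prep import PeriodSet, segment_periods

__all__ = [
    "RunConfig",
    "RunResult",
    "run_pipeline",
    "overlay_clusters",
    "lineage_cluster_table",
    "plot_overlay",
]

log = logging.getLogger("migpattern")


@dataclass
class RunConfig:
    """Single source of truth for one pipeline run."""

    input: Optional[str] = None  # tracks CSV; None -> simulate a colony
    dialect: str = "simple_csv"
    output_dir: str = "migpattern_run"
    seed: int = 0

    # lineage
    jump_threshold: float = 10.0
    proximity_threshold: float = 6.0

    # window
    window_slices: int = 12
    drop_partial_window: bool = True

    # embedding
    method: str = "umap"
    n_neighbors: int = 15
    min_dist: float = 0.1
    perplexity: float = 10.0

    # k-means / K selection
    k_min: int = 2
    k_max: int = 10
    n_init: int = 50
    silhouette_space: str = "embedding"

    # robustness (optional stage)
    robustness_enabled: bool = False
    sigma_grid: tuple[float, ...] = (1.0, 2.0)
    h: int = 20
    fixed_k: Optional[int] = None  # None -> max selected K of the main run
    sigma_is_std: bool = True

    # synthetic input (used when input is None)
    synthetic: Optional[dict] = None

    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, value in data.items():
            if isinstance(value, dict) and key != "synthetic":
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        if "sigma_grid" in flat and flat["sigma_grid"] is not None:
            flat["sigma_grid"] = tuple(float(s) for s in flat["sigma_grid"])
        return cls(**flat)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["sigma_grid"] = list(self.sigma_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def embedding_params(self) -> EmbeddingParams:
        return EmbeddingParams(
            n_neighbors=self.n_neighbors,
            min_dist=self.min_dist,
            perplexity=self.perplexity,
        )


@dataclass
class RunResult:
    """In-memory handle on everything a run produced."""

    config: RunConfig
    output_dir: Path
    table: TrackTable
    lineage: LineageSet
    periods: PeriodSet
    clusterings: dict[int, PeriodClustering]
    overlay: pd.DataFrame
    lineage_clusters: pd.DataFrame
    robustness: Optional[object] = None

    def assignments(self) -> dict[int, dict[int, int]]:
        return {p: c.assignment() for p, c in self.clusterings.items()}


def _load_input(config: RunConfig) -> TrackTable:
    if config.input is not None:
        return read_tracks(config.input, config.dialect)
    raw_cfg = dict(config.synthetic or {})
    if raw_cfg.get("division_schedule") is not None:
        raw_cfg["division_schedule"] = tuple(
            (int(c), int(s)) for c, s in raw_cfg["division_schedule"]
        )
    colony_cfg = ColonyConfig(**raw_cfg)
    table, _ = generate_colony(colony_cfg, seed=derive_seed(config.seed, "simulate"))
    return table


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis; writes all artifacts under the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "resolved_config.yaml")
        import sklearn, umap  # noqa: F401  (versions for the log)

        log.info(
            "versions: numpy=%s sklearn=%s umap=%s",
            np.__version__, sklearn.__version__, umap.__version__,
        )
        log.info("master seed: %d", config.seed)

        table = _load_input(config)
        write_tracks(table, out / "tracks.csv")
        log.info("stage read: %d cells, %d slices", len(table.cell_ids), table.n_slices)

        events = detect_divisions(table, config.jump_threshold, config.proximity_threshold)
        lineage = unify_lineage(table, events)
        write_lineage(lineage, out / "lineage.csv")
        log.info("stage lineage: %d divisions, %d leaf cells", len(events), lineage.n_cells)

        periods = segment_periods(lineage, config.window_slices)
        log.info("stage segment: %d periods of %d slices", periods.n_periods, periods.n)

        mats = distance_matrices(periods)
        params = config.embedding_params().clipped(periods.n_cells)
        embeddings = embed_all(mats, config.method, params, master_seed=config.seed)
        write_embeddings(embeddings, out / "embeddings.csv")
        log.info("stage embed: method=%s params=%s", config.method, params)

        if config.silhouette_space == "embedding":
            clusterings = cluster_all_periods(
                embeddings, config.k_min, config.k_max, config.n_init,
                seed=derive_seed(config.seed, "cluster"),
            )
        else:
            from .clustering_selection import select_k

            clusterings = {}
            for p in sorted(embeddings):
                e = embeddings[p]
                kmax = min(config.k_max, e.points.shape[0] - 1)
                clusterings[p] = select_k(
                    e, config.k_min, kmax, config.n_init,
                    seed=derive_seed(config.seed, "cluster", p),
                    silhouette_on="trajectory", d=mats[p],
                )
        write_msc_curves(clusterings, out / "msc_curves.csv")
        write_assignments(
            {p: c.assignment() for p, c in clusterings.items()},
            out / "assignments.csv",
            phenotypes=periods.phenotypes,
        )
        log.info("stage cluster: selected K per period: %s",
                 {p: c.K for p, c in sorted(clusterings.items())})

        overlay = overlay_clusters(periods, clusterings)
        overlay.to_csv(out / "overlay.csv", index=False)
        lct = lineage_cluster_table(lineage, clusterings)
        lct.to_csv(out / "lineage_clusters.csv", index=False)

        if config.plots:
            plot_overlay(overlay, out / "overlay.png")

        rob = None
        if config.robustness_enabled:
            rob = run_robustness(
                lineage,
                sigma_grid=config.sigma_grid,
                h=config.h,
                fixed_k=config.fixed_k,
                window=config.window_slices,
                method=config.method,
                params=params,
                n_init=min(config.n_init, 10),
                seed=derive_seed(config.seed, "robustness"),
                sigma_is_std=config.sigma_is_std,
                original=clusterings,
            )
            rob.to_csv(out / "robustness.csv")
            rob.summary().to_csv(out / "robustness_summary.csv", index=False)
            log.info("stage robustness: fixed K=%d, h=%d", rob.fixed_k, rob.h)

        return RunResult(
            config=config,
            output_dir=out,
            table=table,
            lineage=lineage,
            periods=periods,
            clusterings=clusterings,
            overlay=overlay,
            lineage_clusters=lct,
            robustness=rob,
        )
    finally:
        log.removeHandler(handler)
        handler.close()


def overlay_clusters(
    periods: PeriodSet, clusterings: Mapping[int, PeriodClustering]
) -> pd.DataFrame:
    """Join cluster labels back onto the pre-normalization coordinates.

    One row per (period, cell, slice) with the *raw* position — the cluster
    labels were computed from origin-anchored trajectories, so spatial
    coherence of clusters in this table is a finding, not a tautology.
    """
    if set(periods.periods) != set(clusterings):
        raise IntegrityError("periods of clusterings do not match the period set")
    rows = []
    for p in periods.periods:
        c = clusterings[p]
        if c.cell_order != periods.cell_ids:
            raise IntegrityError(f"cell order mismatch in period {p}")
        raw = periods.raw[p]
        for i, cid in enumerate(periods.cell_ids):
            ph = periods.phenotypes.get(cid, Phenotype.UNKNOWN).value
            for l in range(periods.n):
                rows.append((p, cid, (p - 1) * periods.n + l, raw[i, l, 0], raw[i, l, 1], int(c.labels[i]), ph))
    return pd.DataFrame(rows, columns=["period", "cell_id", "slice", "x", "y", "cluster", "phenotype"])


def lineage_cluster_table(
    lineage: LineageSet, clusterings: Mapping[int, PeriodClustering]
) -> pd.DataFrame:
    """Per leaf cell: mother, division slice, and cluster index in each period."""
    by_daughter = {}
    for ev in lineage.events:
        for d in ev.daughter_ids:
            by_daughter[d] = ev
    rows = []
    for cid in lineage.cell_ids:
        ev = by_daughter.get(cid)
        row: dict = {
            "cell_id": cid,
            "mother_id": lineage.parent.get(cid),
            "division_slice": ev.division_slice if ev is not None else None,
            "phenotype": lineage.phenotypes.get(cid, Phenotype.UNKNOWN).value,
        }
        for p in sorted(clusterings):
            row[f"cluster_p{p}"] = clusterings[p].assignment()[cid]
        rows.append(row)
    df = pd.DataFrame(rows)
    df["mother_id"] = df["mother_id"].astype("Int64")
    df["division_slice"] = df["division_slice"].astype("Int64")
    return df


def plot_overlay(overlay: pd.DataFrame, path: str | Path) -> None:
    """Per-period trajectories colored by cluster; phenotype-distinct markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    periods = sorted(overlay["period"].unique())
    ncol = min(4, len(periods))
    nrow = -(-len(periods) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 4 * nrow), squeeze=False)
    cmap = plt.get_cmap("tab10")
    for ax, p in zip(axes.flat, periods):
        sub = overlay[overlay["period"] == p]
        for cid, track in sub.groupby("cell_id"):
            color = cmap(int(track["cluster"].iloc[0]) % 10)
            marker = "s" if track["phenotype"].iloc[0] == Phenotype.TGF_PLUS.value else "o"
            ax.plot(track["x"], track["y"], "-", color=color, lw=0.8, alpha=0.7)
            ax.plot(track["x"].iloc[-1], track["y"].iloc[-1], marker, color=color, ms=3)
        ax.set_title(f"period {p}")
        ax.set_aspect("equal")
    for ax in axes.flat[len(periods):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
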