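"""End-to-end orchestration: manifest + config -> tables, rankings,
embeddings, projections, summaries, and plots.

All numerical results are CSV-first; plots are artifacts rendered from the
same tables. Every output CSV carries a header comment with the config hash
and the seed so a run is fully identifiable, and ``run.log`` records the
configuration and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, features, kinematics, ml, occupancy
from .features import FeatureTable
from .session_io import SessionRecord, load_manifest, read_arena_toml

__all__ = [
    "RunConfig",
    "run_exp1_analysis",
    "run_exp2_analysis",
    "analyze",
    "summarize",
]

logger = logging.getLogger("behavdyn")


@dataclass(frozen=True)
class RunConfig:
    """Settings of one analysis run."""

    manifest: str
    arena: str
    out_dir: str
    design: str = "exp1"  # exp1 | exp2
    grid_divisions: int | None = None  # None -> arena default
    smoothing_window: int = 200  # frames
    radius: float | None = None  # cm; None -> arena entry_radius
    availability: float | None = None  # s; None -> arena default
    bins: int = 4  # discretization for variable ranking
    perplexity: float | None = None
    seed: int = 0
    k: int = 2
    restarts: int = 10
    make_plots: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def summarize(table: FeatureTable) -> pd.DataFrame:
    """Per condition x feature: mean, median, sd, Q1, Q3 over non-missing
    values — the five statistics drawn in the summary box plots."""
    rows = []
    for condition, group in table.data.groupby(table.target, sort=True):
        for name in table.feature_names:
            vals = group[name].dropna().astype(float)
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "condition": condition,
                    "feature": name,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "median": vals.median(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    "q1": vals.quantile(0.25),
                    "q3": vals.quantile(0.75),
                }
            )
    return pd.DataFrame(rows)


def _ranking_frame(ranking: ml.RankingResult) -> pd.DataFrame:
    rows = []
    for method in ranking.scores.columns:
        for rank, feature in enumerate(ranking.order[method], start=1):
            rows.append(
                {
                    "feature": feature,
                    "method": method,
                    "score": ranking.scores.loc[feature, method],
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)


def analyze(
    sessions: list[SessionRecord],
    out_dir,
    design: str = "exp1",
    config: RunConfig | None = None,
) -> Path:
    """Run the full multilevel analysis on an in-memory corpus.

    Writes ``features.csv``, ``summary_stats.csv`` and, when both conditions
    are present, ``rankings.csv``, ``embedding.csv``, ``projection.csv``;
    optionally a ``plots/`` directory. Returns the output directory.
    """
    if not sessions:
        raise ValueError("empty session corpus")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = RunConfig(manifest="<memory>", arena="<memory>", out_dir=str(out), design=design)
    chash = config.config_hash()
    stamp = f"config={chash} seed={config.seed} behavdyn={__version__}"

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("behavdyn %s design=%s sessions=%d", __version__, design, len(sessions))
        logger.info("config: %s", json.dumps(dataclasses.asdict(config), default=str))
        logger.info(
            "libraries: numpy=%s pandas=%s", np.__version__, pd.__version__
        )

        if design == "exp1":
            table = features.assemble_exp1(
                sessions, radius=config.radius, window=config.availability
            )
        elif design == "exp2":
            table = features.assemble_exp2(sessions, window=config.availability)
        else:
            raise ValueError(f"unknown design {design!r}")
        _write_csv(table.data, out / "features.csv", stamp)
        _write_csv(summarize(table), out / "summary_stats.csv", stamp)

        conditions = table.y.unique()
        if len(conditions) < 2:
            warnings.warn(
                "single experimental condition: ranking/embedding/projection skipped",
                stacklevel=2,
            )
            logger.warning("single condition %s; ML stage skipped", conditions)
        else:
            std = features.standardize(table)
            ranking = ml.rank_variables(table, bins=config.bins)
            _write_csv(_ranking_frame(ranking), out / "rankings.csv", stamp)

            embedding = ml.tsne_embed(std, perplexity=config.perplexity, seed=config.seed)
            clusters = ml.kmeans_cluster(
                embedding.coords,
                k=config.k,
                seed=config.seed,
                restarts=config.restarts,
                reference=embedding.row_index[table.target].to_numpy(),
            )
            emb_df = embedding.row_index.copy()
            emb_df["dim1"] = embedding.coords[:, 0]
            emb_df["dim2"] = embedding.coords[:, 1]
            emb_df["cluster"] = clusters.labels
            _write_csv(emb_df, out / "embedding.csv", stamp)
            logger.info(
                "t-SNE perplexity=%.2f seed=%d; k-means k=%d purity=%.3f ari=%.3f",
                embedding.perplexity,
                embedding.seed,
                clusters.k,
                clusters.purity,
                clusters.adjusted_rand,
            )

            projection = ml.pca_projection(table)
            proj_df = projection.row_index.copy()
            proj_df["pc1"] = projection.scores[:, 0]
            proj_df["pc2"] = projection.scores[:, 1]
            _write_csv(proj_df, out / "projection.csv", stamp)
            loadings = projection.loadings.reset_index(names="feature")
            loadings["variance_ratio_pc1"] = projection.explained_variance_ratio[0]
            loadings["variance_ratio_pc2"] = projection.explained_variance_ratio[1]
            _write_csv(loadings, out / "projection_axes.csv", stamp)

        if config.make_plots:
            _render_plots(sessions, table, out, design, config)
        logger.info("analysis complete: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def run_exp1_analysis(config: RunConfig) -> Path:
    """Load the manifest named by the config and run the FT/VT analysis."""
    arena = read_arena_toml(config.arena)
    sessions = load_manifest(config.manifest, arena)
    return analyze(sessions, config.out_dir, design="exp1", config=config)


def run_exp2_analysis(config: RunConfig) -> Path:
    """Load the manifest named by the config and run the FD/WD analysis."""
    arena = read_arena_toml(config.arena)
    sessions = load_manifest(config.manifest, arena)
    return analyze(sessions, config.out_dir, design="exp2", config=config)


# ---------------------------------------------------------------------------
# plots (artifacts only; nothing downstream parses them)

def _representative_sessions(sessions) -> list[SessionRecord]:
    """First, middle, and last session of one subject per condition."""
    chosen: list[SessionRecord] = []
    by_cond: dict[str, list[SessionRecord]] = {}
    for s in sessions:
        by_cond.setdefault(s.condition, []).append(s)
    for cond, recs in sorted(by_cond.items()):
        subject = min(r.subject for r in recs)
        mine = sorted(
            (r for r in recs if r.subject == subject), key=lambda r: r.session_number
        )
        picks = {0, len(mine) // 2, len(mine) - 1}
        chosen.extend(mine[i] for i in sorted(picks))
    return chosen


def _render_plots(sessions, table: FeatureTable, out: Path, design: str, config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    reps = _representative_sessions(sessions)
    landmark = "dispenser" if design == "exp1" else "food"

    for rec in reps:
        stem = f"{rec.condition}_{rec.subject}_s{rec.session_number:02d}"
        arena = rec.arena
        # routes + locations at delivery
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(rec.trajectory.x, rec.trajectory.y, color="0.6", lw=0.3)
        for disp in arena.landmarks:
            lwd = kinematics.locations_at_events(rec.trajectory, rec.events, "delivery", disp)
            if lwd:
                pts = np.asarray(lwd)
                ax.plot(pts[:, 0], pts[:, 1], "k.", ms=4)
            ax.plot(*arena.landmark(disp), "r^", ms=8)
        ax.set(xlim=(0, arena.width), ylim=(0, arena.height), title=stem, aspect="equal")
        fig.savefig(plots / f"route_{stem}.png", dpi=100)
        plt.close(fig)

        # raw + smoothed relative distance trace
        series = kinematics.distance_series(rec.trajectory, arena, landmark, mode="relative")
        smooth = kinematics.moving_average(series, window=config.smoothing_window)
        fig, ax = plt.subplots(figsize=(6, 2.5))
        ax.plot(rec.trajectory.t, series.values, ".", color="0.7", ms=1)
        ax.plot(rec.trajectory.t, smooth.values, "r-", lw=1)
        ax.set(xlabel="time (s)", ylabel=f"relative distance to {landmark}", ylim=(0, 1), title=stem)
        fig.savefig(plots / f"distance_{stem}.png", dpi=100)
        plt.close(fig)

        # recurrence plot, downsampled for rendering only
        grid = occupancy.ZoneGrid(arena, config.grid_divisions)
        zones = occupancy.zone_series(rec.trajectory, grid)
        stride = max(1, len(zones) // 1500)
        z = zones[::stride]
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(z[:, None] == z[None, :], cmap="gray_r", origin="lower", interpolation="nearest")
        ax.set(title=f"recurrence {stem}", xlabel="frame", ylabel="frame")
        fig.savefig(plots / f"recurrence_{stem}.png", dpi=100)
        plt.close(fig)

    # per-feature summary boxes
    stats = summarize(table)
    for name in table.feature_names:
        sub = stats[stats.feature == name]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(4, 2 + 0.5 * len(sub)))
        for j, row in enumerate(sub.itertuples()):
            ax.barh(j, row.q3 - row.q1, left=row.q1, height=0.5, color="#9ecae1")
            ax.plot([row.mean], [j], "|", color="darkblue", ms=20)
            ax.plot([row.median], [j], "|", color="gold", ms=20)
            ax.plot([row.mean - row.sd, row.mean + row.sd], [j, j], "-", color="steelblue", lw=1)
        ax.set_yticks(range(len(sub)), sub.condition)
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(plots / f"summary_{name}.png", dpi=100)
        plt.close(fig)

    emb_path = out / "embedding.csv"
    if emb_path.exists():
        emb = pd.read_csv(emb_path, comment="#")
        fig, ax = plt.subplots(figsize=(4, 4))
        for cond, group in emb.groupby("condition"):
            ax.scatter(group.dim1, group.dim2, label=str(cond), s=18)
        if "sequence_label" in emb.columns:
            seq2 = emb[emb.sequence_label.astype(str) == "2"]
            ax.scatter(seq2.dim1, seq2.dim2, marker="x", color="k", s=12, label="sequence 2")
        ax.legend()
        ax.set(title="t-SNE embedding", xlabel="dim 1", ylabel="dim 2")
        fig.savefig(plots / "tsne.png", dpi=100)
        plt.close(fig)

    proj_path = out / "projection.csv"
    if proj_path.exists():
        proj = pd.read_csv(proj_path, comment="#")
        axes = pd.read_csv(out / "projection_axes.csv", comment="#")
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        for cond, group in proj.groupby("condition"):
            ax.scatter(group.pc1, group.pc2, label=str(cond), s=14)
        scale = 0.9 * max(proj.pc1.abs().max(), proj.pc2.abs().max())
        for row in axes.itertuples():
            ax.annotate(
                "", xy=(row.PC1 * scale, row.PC2 * scale), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="0.3"),
            )
            ax.text(row.PC1 * scale, row.PC2 * scale, row.feature, fontsize=7)
        ax.legend()
        ax.set(title="linear projection (PCA)", xlabel="PC1", ylabel="PC2")
        fig.savefig(plots / "projection.png", dpi=100)
        plt.close(fig)
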