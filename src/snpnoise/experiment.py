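"""Experiment orchestration: the noise ladder, SNP-subset runs, reporting.

A run sweeps every (classifier family, mislabel proportion) cell of the
ladder for a configured number of replicates, with deterministic child seeds
per (family, noise level, replicate) so cells are independent and re-runs
are byte-identical. The subset experiment repeats the ladder for the two
local methods (KNN, RF) on the most informative marker subsets, ranked once
on clean labels by single-marker variance explained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import seed_for
from .cv import aggregate, records_to_frame, run_replicate
from .data import ConfigError, GenotypeMatrix
from .noise import NoiseLadder
from .qc import run_qc
from .syndata import SynConfig, simulate

__all__ = [
    "ExperimentConfig",
    "rank_snps_by_variance_explained",
    "run_noise_ladder",
    "run_snp_subset_experiment",
    "render_report",
]

_FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed for a reproducible ladder run."""

    syn: SynConfig = field(default_factory=SynConfig)
    ladder: NoiseLadder = field(default_factory=NoiseLadder)
    families: tuple = ("knn", "lr", "rf", "svm-lin", "svm-rbf")
    replicates: int = 20
    master_seed: int = 0
    grids: dict | None = None          # family -> grid override (thinned grids etc.)
    subset_sizes: tuple = (None, 50, 30)  # None = full panel
    subset_families: tuple = ("knn", "rf")
    callrate_max: float = 0.85
    maf_max: float = 0.025
    impute_k: int = 5
    outdir: str | None = None

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


def rank_snps_by_variance_explained(G_qc: GenotypeMatrix, labels) -> pd.DataFrame:
    """Rank markers by R^2 of the single-marker regression of label on dosage.

    R^2 is the squared point-biserial correlation between dosage and the 0/1
    label; zero-variance markers score 0 and ties break toward the lower
    marker index. Returns a DataFrame (marker, chromosome, r2) in rank order.
    """
    y = np.asarray(labels, dtype=float)
    X = G_qc.dosage.astype(float)
    if G_qc.missing_mask.any():
        raise ValueError("rank markers on QC'd (complete) genotypes")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = (xc**2).sum(axis=0)
    sy = (yc**2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((sx > 0) & (sy > 0), (xc.T @ yc) ** 2 / (sx * sy), 0.0)
    order = np.lexsort((np.arange(len(r2)), -r2))
    return pd.DataFrame(
        {
            "marker": G_qc.markers.ids[order],
            "chromosome": G_qc.markers.chromosomes[order],
            "r2": r2[order],
        }
    )


def _prepare_data(config: ExperimentConfig):
    G, pheno = simulate(config.syn, seed=seed_for(config.master_seed, "syndata"))
    G_qc, report = run_qc(
        G, callrate_max=config.callrate_max, maf_max=config.maf_max, impute_k=config.impute_k
    )
    return G_qc, pheno, report


def _cell_records(X, y, family, p, p_idx, config, grid):
    records = []
    for rep in range(config.replicates):
        seed = seed_for(config.master_seed, "ladder", family, p_idx, rep)
        records.extend(
            run_replicate(
                X, y, family, p, seed, grid=grid, replicate_id=rep,
            )
        )
    return records


def run_noise_ladder(config: ExperimentConfig, data=None):
    """Sweep families x ladder; returns (per-fold records, aggregated summary).

    ``data`` may supply a pre-built ``(GenotypeMatrix, labels)`` pair
    (QC'd, complete); otherwise the synthetic fixture is generated and QC'd
    from the master seed. With ``config.outdir`` set, tidy and aggregated
    TSVs are written deterministically.
    """
    if data is None:
        G_qc, pheno, _ = _prepare_data(config)
        X, y = G_qc.dosage.astype(float), pheno.label
    else:
        G_or_X, y = data
        X = G_or_X.dosage.astype(float) if isinstance(G_or_X, GenotypeMatrix) else np.asarray(G_or_X, float)
        y = np.asarray(y)
    records = []
    for family in config.families:
        grid = (config.grids or {}).get(family)
        for p_idx, p in enumerate(config.ladder):
            records.extend(_cell_records(X, y, family, p, p_idx, config, grid))
    df = records_to_frame(records)
    summary = aggregate(df)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "records.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return df, summary


def run_snp_subset_experiment(config: ExperimentConfig, data=None):
    """Ladder runs for KNN/RF on the full panel and top-k marker subsets.

    Ranking is computed once on the clean labels before any noise injection.
    Child seeds depend only on (family, noise level, replicate), so the
    full-panel subset reproduces the main ladder's records exactly and the
    subset comparisons are paired across subset sizes.
    """
    if data is None:
        G_qc, pheno, _ = _prepare_data(config)
        y = pheno.label
    else:
        G_qc, y = data
        y = np.asarray(y)
    ranking = rank_snps_by_variance_explained(G_qc, y)
    frames = []
    for size in config.subset_sizes:
        if size is None:
            G_sub = G_qc
        else:
            if size > G_qc.n_markers:
                raise ConfigError(f"subset size {size} exceeds panel size {G_qc.n_markers}")
            top = ranking["marker"].to_numpy()[:size]
            keep = np.flatnonzero(np.isin(G_qc.markers.ids, top))
            G_sub = G_qc.subset_markers(keep)
        X = G_sub.dosage.astype(float)
        records = []
        for family in config.subset_families:
            grid = (config.grids or {}).get(family)
            for p_idx, p in enumerate(config.ladder):
                records.extend(_cell_records(X, y, family, p, p_idx, config, grid))
        df = records_to_frame(records)
        df["subset"] = "all" if size is None else str(size)
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    summary = aggregate(df, by=("family", "subset", "p"))
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "subset_records.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        summary.to_csv(out / "subset_summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return df, summary, ranking


def _summary_table_text(summary: pd.DataFrame) -> str:
    """Wide text table: one block per noise level, rows TER/FNR/FPR/AUC per family."""
    lines = ["misLabels\tminFreq\terrType\t" + "\t".join(sorted(summary["family"].unique()))]
    fams = sorted(summary["family"].unique())
    for p in sorted(summary["p"].unique()):
        sub = summary[summary["p"] == p].set_index("family")
        min_freq = sub["minority_freq"].mean()
        for metric in ("ter", "fnr", "fpr", "auc"):
            vals = "\t".join(
                f"{sub.loc[f, metric + '_mean']:.4f}" if f in sub.index else "NA"
                for f in fams
            )
            lines.append(f"{100 * p:g}\t{min_freq:.4f}\t{metric.upper()}\t{vals}")
    return "\n".join(lines) + "\n"


def render_report(
    outdir,
    summary: pd.DataFrame,
    records: pd.DataFrame | None = None,
    subset_summary: pd.DataFrame | None = None,
    force: bool = False,
) -> list:
    """Write the figures and a text summary table into ``outdir``.

    Produces an AUC-versus-noise line plot per family, TPR/TNR boxplots per
    family and noise level (when per-fold records are given), a subset
    comparison plot (when a subset summary is given), and a wide text table.
    Existing files are only overwritten with ``force``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if summary is None or summary.empty:
        warnings.warn("empty summary; nothing to render")
        return []
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _target(name):
        path = out / name
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists (use force=True to overwrite)")
        written.append(path)
        return path

    # Table block
    _target("summary_table.txt").write_text(_summary_table_text(summary))

    # AUC vs noise
    fig, ax = plt.subplots(figsize=(6, 4))
    for fam, sub in summary.groupby("family"):
        sub = sub.sort_values("p")
        ax.plot(100 * sub["p"], sub["auc_mean"], marker="o", label=fam)
    ax.set_xlabel("mislabeled observations (%)")
    ax.set_ylabel("mean AUC")
    ax.axhline(0.5, color="grey", lw=0.5, ls="--")
    ax.legend()
    fig.tight_layout()
    fig.savefig(_target("auc_vs_noise.png"), dpi=120)
    plt.close(fig)

    # TPR / TNR distributions
    if records is not None and not records.empty:
        fams = sorted(records["family"].unique())
        fig, axes = plt.subplots(len(fams), 1, figsize=(7, 2.2 * len(fams)), squeeze=False)
        for ax, fam in zip(axes[:, 0], fams):
            sub = records[records["family"] == fam]
            ps = sorted(sub["p"].unique())
            tpr = [sub.loc[sub["p"] == p, "tpr"].dropna() for p in ps]
            tnr = [sub.loc[sub["p"] == p, "tnr"].dropna() for p in ps]
            pos = np.arange(len(ps))
            ax.boxplot(tpr, positions=pos - 0.18, widths=0.3,
                       boxprops=dict(color="tab:red"), medianprops=dict(color="tab:red"))
            ax.boxplot(tnr, positions=pos + 0.18, widths=0.3,
                       boxprops=dict(color="tab:blue"), medianprops=dict(color="tab:blue"))
            ax.set_xticks(pos, [f"{100 * p:g}" for p in ps])
            ax.set_title(f"{fam}: TPR (red) / TNR (blue)")
            ax.set_ylim(-0.05, 1.05)
        axes[-1, 0].set_xlabel("mislabeled observations (%)")
        fig.tight_layout()
        fig.savefig(_target("tpr_tnr_distributions.png"), dpi=120)
        plt.close(fig)

    # subset comparison
    if subset_summary is not None and not subset_summary.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        styles = {"all": "-", "50": "--", "30": ":"}
        for (fam, subset), sub in subset_summary.groupby(["family", "subset"]):
            sub = sub.sort_values("p")
            ax.plot(
                100 * sub["p"], sub["auc_mean"],
                linestyle=styles.get(str(subset), "-"),
                marker=".", label=f"{fam} ({subset})",
            )
        ax.set_xlabel("mislabeled observations (%)")
        ax.set_ylabel("mean AUC")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(_target("subset_comparison.png"), dpi=120)
        plt.close(fig)

    return written
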