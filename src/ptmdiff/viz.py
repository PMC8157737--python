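"""Static plot exports with plot-data CSV sidecars.

Every plot function splits into a pure ``prepare_*`` step returning the
plot-ready table and a thin matplotlib rendering step, so the plot
semantics are testable from the CSV sidecar without pixel comparison.
Identical inputs produce byte-identical sidecars.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from ptmdiff.io_tables import PTMTable, SampleMetadata
from ptmdiff.normalization import BetaConfig

logger = logging.getLogger(__name__)

VOLCANO_HOVER_FIELDS = ["uniprot_id", "gene_id", "description", "log2fc", "p"]


def _save(fig: plt.Figure, path: Path) -> None:
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# preliminary diagnostics: histogram, boxplots, PCA, MDS
# ---------------------------------------------------------------------------

def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS by double-centering the squared distances."""
    d2 = np.asarray(dist, float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def prepare_pca(log2_matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first two PCs of the complete-case features.

    Samples are the observations, features the variables; returns the
    score table and the fraction of variance per component.
    """
    complete = log2_matrix.dropna(axis=0)
    if len(complete) < 3:
        raise ValueError(
            f"PCA needs >= 3 complete features, have {len(complete)}"
        )
    x = complete.to_numpy(float).T  # samples x features
    pca = PCA(n_components=2)
    scores = pca.fit_transform(x)
    out = pd.DataFrame(
        {"sample": complete.columns, "pc1": scores[:, 0], "pc2": scores[:, 1]}
    )
    return out, pca.explained_variance_ratio_


def prepare_mds(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Classical MDS of Euclidean distances between samples."""
    complete = log2_matrix.dropna(axis=0)
    x = complete.to_numpy(float).T
    n = x.shape[0]
    dist = np.zeros((n, n))
    dist[np.triu_indices(n, 1)] = pdist(x)
    dist += dist.T
    coords = classical_mds(dist)
    return pd.DataFrame(
        {"sample": complete.columns, "dim1": coords[:, 0], "dim2": coords[:, 1]}
    )


def preliminary_plots(
    log2_matrix: pd.DataFrame, meta: SampleMetadata, out_dir: str | Path
) -> dict[str, Path]:
    """Histogram, per-sample boxplots, PCA and MDS of a bound log2 matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if log2_matrix.shape[1] < 2:
        raise ValueError("preliminary plots need >= 2 samples")
    arm = meta.table.set_index("custom_id")["experimental_group"]
    paths: dict[str, Path] = {}

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(log2_matrix.to_numpy(float).ravel(), bins=50, color="steelblue")
    ax.set_xlabel("log2 intensity")
    ax.set_ylabel("count")
    ax.set_title("Distribution of log2 intensities")
    paths["histogram"] = out_dir / "histogram.png"
    _save(fig, paths["histogram"])

    fig, ax = plt.subplots(figsize=(1 + 0.8 * log2_matrix.shape[1], 4))
    data = [log2_matrix[c].dropna().to_numpy() for c in log2_matrix.columns]
    ax.boxplot(data, tick_labels=list(log2_matrix.columns))
    ax.set_ylabel("log2 intensity")
    ax.tick_params(axis="x", rotation=45)
    paths["boxplot"] = out_dir / "boxplot.png"
    _save(fig, paths["boxplot"])

    pca_df, var_ratio = prepare_pca(log2_matrix)
    pca_df["experimental_group"] = pca_df["sample"].map(arm).to_numpy()
    fig, ax = plt.subplots(figsize=(5, 5))
    for level, sub in pca_df.groupby("experimental_group"):
        ax.scatter(sub["pc1"], sub["pc2"], label=str(level))
    for _, row in pca_df.iterrows():
        ax.annotate(row["sample"], (row["pc1"], row["pc2"]), fontsize=8)
    ax.set_xlabel(f"PC1 ({100 * var_ratio[0]:.1f}% variance)")
    ax.set_ylabel(f"PC2 ({100 * var_ratio[1]:.1f}% variance)")
    ax.legend()
    paths["pca"] = out_dir / "pca.png"
    _save(fig, paths["pca"])
    pca_df.to_csv(out_dir / "pca_data.csv", index=False)
    paths["pca_data"] = out_dir / "pca_data.csv"

    mds_df = prepare_mds(log2_matrix)
    mds_df["experimental_group"] = mds_df["sample"].map(arm).to_numpy()
    fig, ax = plt.subplots(figsize=(5, 5))
    for level, sub in mds_df.groupby("experimental_group"):
        ax.scatter(sub["dim1"], sub["dim2"], label=str(level))
    ax.set_xlabel("MDS dimension 1")
    ax.set_ylabel("MDS dimension 2")
    ax.legend()
    paths["mds"] = out_dir / "mds.png"
    _save(fig, paths["mds"])
    mds_df.to_csv(out_dir / "mds_data.csv", index=False)
    paths["mds_data"] = out_dir / "mds_data.csv"
    return paths


# ---------------------------------------------------------------------------
# volcano
# ---------------------------------------------------------------------------

def prepare_volcano(
    results: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    y_mode: str = "adjusted-p",
) -> pd.DataFrame:
    """Category table behind the volcano plot.

    Rows are partitioned into ``significant`` (passes both gates),
    ``modifier`` (writer/eraser/reader match, not significant) and
    ``other``. y = -log10 of the chosen p column; infinite values from
    p = 0 are clipped to the maximum finite y plus one unit.
    """
    if y_mode not in ("raw-p", "adjusted-p"):
        raise ValueError("y_mode must be 'raw-p' or 'adjusted-p'")
    pcol = "p" if y_mode == "raw-p" else "p_adj"
    out = results.copy()
    with np.errstate(divide="ignore"):
        y = -np.log10(out[pcol].to_numpy(float))
    finite = y[np.isfinite(y)]
    ceiling = (finite.max() if finite.size else 0.0) + 1.0
    out["neg_log10_p"] = np.where(np.isinf(y), ceiling, y)
    sig = out["significant"].to_numpy(bool) if "significant" in out else (
        (out["p_adj"] < alpha) & (np.abs(out["log2fc"]) > np.log2(fc_threshold))
    )
    modifier = (
        out["modifier_match"].to_numpy(bool)
        if "modifier_match" in out
        else np.zeros(len(out), bool)
    )
    out["category"] = np.select(
        [sig, modifier & ~sig], ["significant", "modifier"], default="other"
    )
    return out


def volcano(
    results: pd.DataFrame,
    out_dir: str | Path,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    y_mode: str = "adjusted-p",
    modifiers_only: bool = False,
) -> dict[str, Path]:
    """Volcano plot export: log2fc vs -log10 p with threshold lines.

    ``modifiers_only`` renders the variant restricted to writer/eraser/
    reader matches. The sidecar CSV carries the hover fields (uniprot id,
    gene id, description, log2fc, p) plus category and coordinates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = prepare_volcano(results, alpha, fc_threshold, y_mode)
    if modifiers_only:
        mm = (
            table["modifier_match"].astype(bool)
            if "modifier_match" in table.columns
            else pd.Series(False, index=table.index)
        )
        plot_table = table[mm]
    else:
        plot_table = table
    colors = {"significant": "crimson", "modifier": "royalblue", "other": "0.6"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for cat in ("other", "modifier", "significant"):
        sub = plot_table[plot_table["category"] == cat]
        if len(sub):
            ax.scatter(
                sub["log2fc"], sub["neg_log10_p"], s=12, c=colors[cat], label=cat
            )
    lfc = np.log2(fc_threshold)
    ax.axvline(lfc, ls="--", c="k", lw=0.8)
    ax.axvline(-lfc, ls="--", c="k", lw=0.8)
    ax.axhline(-np.log10(alpha), ls="--", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change (treatment - control)")
    ylabel = "-log10 p" if y_mode == "raw-p" else "-log10 FDR-adjusted p"
    ax.set_ylabel(ylabel)
    ax.legend()
    stem = "volcano_modifiers" if modifiers_only else "volcano"
    paths = {"plot": out_dir / f"{stem}.png", "data": out_dir / f"{stem}_data.csv"}
    _save(fig, paths["plot"])
    keep = [c for c in VOLCANO_HOVER_FIELDS if c in table.columns]
    sidecar = plot_table[keep + ["p_adj", "neg_log10_p", "category"]]
    sidecar.to_csv(paths["data"], index=False)
    return paths


# ---------------------------------------------------------------------------
# heatmaps
# ---------------------------------------------------------------------------

def prepare_heatmap(
    values: pd.DataFrame, meta: SampleMetadata, method: str = "complete"
) -> pd.DataFrame:
    """Row-clustered matrix with columns in metadata order.

    Hierarchical clustering of rows: Euclidean distance, complete linkage
    by default. A single row is returned unclustered.
    """
    cols = [c for c in meta.custom_ids if c in values.columns]
    x = values[cols]
    if len(x) > 1:
        arr = x.to_numpy(float).copy()
        if np.isnan(arr).any():  # impute row means so distances stay defined
            row_means = np.nanmean(arr, axis=1)
            nan_idx = np.where(np.isnan(arr))
            arr[nan_idx] = np.take(row_means, nan_idx[0])
        link = hierarchy.linkage(arr, method=method, metric="euclidean")
        order = hierarchy.leaves_list(link)
        x = x.iloc[order]
    return x


def _render_heatmap(
    data: pd.DataFrame, labels: pd.Series, title: str, cbar_label: str, path: Path
) -> None:
    fig, ax = plt.subplots(
        figsize=(1.5 + 0.6 * data.shape[1], 1.0 + 0.25 * data.shape[0])
    )
    im = ax.imshow(data.to_numpy(float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=45, ha="right")
    ax.set_yticks(range(data.shape[0]), labels.loc[data.index])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=cbar_label)
    _save(fig, path)


def heatmap(
    z_matrix: pd.DataFrame,
    meta: SampleMetadata,
    out_dir: str | Path,
    gene_labels: pd.Series | None = None,
    linkage_method: str = "complete",
    title: str = "Significant proteins (row z-scores)",
    cbar_label: str = "z-score of log2 intensity",
    stem: str = "heatmap",
) -> dict[str, Path] | None:
    """Clustered heatmap of z-scored log2 intensities for significant rows.

    Returns None (with a message) when given zero rows; the sidecar CSV
    carries the clustered matrix with gene labels so cell values are
    testable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(z_matrix) == 0:
        logger.info("no significant features; heatmap skipped")
        return None
    data = prepare_heatmap(z_matrix, meta, method=linkage_method)
    labels = (
        gene_labels
        if gene_labels is not None
        else pd.Series(data.index, index=data.index)
    )
    paths = {"plot": out_dir / f"{stem}.png", "data": out_dir / f"{stem}_data.csv"}
    _render_heatmap(data, labels, title, cbar_label, paths["plot"])
    sidecar = data.copy()
    sidecar.insert(0, "label", labels.loc[data.index].to_numpy())
    sidecar.to_csv(paths["data"], index_label="feature")
    return paths


def ptm_heatmap(
    m_values: pd.DataFrame,
    meta: SampleMetadata,
    out_dir: str | Path,
    labels: pd.Series | None = None,
    zscore: bool = False,
    linkage_method: str = "complete",
) -> dict[str, Path] | None:
    """Heatmap of significant histone PTMs; cells are M-values per sample.

    ``zscore=True`` additionally standardises each row (off by default:
    the M-value scale is already comparable across marks).
    """
    data = m_values
    cbar = "M-value"
    if zscore:
        from ptmdiff.normalization import zscore_rows

        data = zscore_rows(m_values)
        cbar = "z-score of M-value"
    return heatmap(
        data,
        meta,
        out_dir,
        gene_labels=labels,
        linkage_method=linkage_method,
        title="Significant histone PTMs",
        cbar_label=cbar,
        stem="ptm_heatmap",
    )


# ---------------------------------------------------------------------------
# stacked beta bars
# ---------------------------------------------------------------------------

def prepare_stacked_bars(
    ptm: PTMTable,
    meta: SampleMetadata,
    histone: str | None = None,
    positions: list[str] | None = None,
    mode: str = "group-mean",
) -> pd.DataFrame:
    """Long-format table behind the stacked beta bar chart.

    One bar per amino-acid position (and per group, or per replicate in
    ``per-replicate`` mode); segments are modification states with heights
    equal to (mean) beta values. Because each family's betas sum to less
    than one, every bar total is <= 1.
    """
    if ptm.beta is None:
        raise ValueError("betas not computed; run compute_beta first")
    if mode not in ("group-mean", "per-replicate"):
        raise ValueError("mode must be 'group-mean' or 'per-replicate'")
    ann = ptm.annotations
    mask = np.ones(len(ann), dtype=bool)
    if histone is not None:
        mask &= (ann["histone_protein"].astype(str) == histone).to_numpy()
    if positions is not None:
        mask &= ann["site"].astype(str).isin(positions).to_numpy()
    if not mask.any():
        raise ValueError(
            "no PTMs left after filtering; available histones: "
            f"{sorted(ann['histone_protein'].astype(str).unique())}, sites: "
            f"{sorted(ann['site'].astype(str).unique())}"
        )
    sel_ann = ann[mask]
    sel_beta = ptm.beta[mask] if isinstance(mask, np.ndarray) else ptm.beta.loc[mask]
    rows = []
    mt = meta.table
    for i in range(len(sel_ann)):
        a = sel_ann.iloc[i]
        for _, s in mt.iterrows():
            rows.append(
                {
                    "histone_protein": a["histone_protein"],
                    "site": a["site"],
                    "modification": a["modification"],
                    "sample": s["custom_id"],
                    "experimental_group": s["experimental_group"],
                    "replicate": s["replicate"],
                    "beta": sel_beta.iloc[i][s["custom_id"]],
                }
            )
    long = pd.DataFrame(rows)
    if mode == "group-mean":
        out = (
            long.groupby(
                ["histone_protein", "site", "modification", "experimental_group"],
                sort=False,
                as_index=False,
            )["beta"].mean()
        )
        out["bar"] = (
            out["histone_protein"].astype(str)
            + out["site"].astype(str)
            + " | "
            + out["experimental_group"].astype(str)
        )
    else:
        out = long
        out["bar"] = (
            out["histone_protein"].astype(str)
            + out["site"].astype(str)
            + " | "
            + out["sample"].astype(str)
        )
    return out


def stacked_bars(
    ptm: PTMTable,
    meta: SampleMetadata,
    out_dir: str | Path,
    histone: str | None = None,
    positions: list[str] | None = None,
    mode: str = "group-mean",
) -> dict[str, Path]:
    """Stacked bar export of beta values per site and modification."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = prepare_stacked_bars(ptm, meta, histone, positions, mode)
    bars = table["bar"].unique()
    mods = table["modification"].unique()
    cmap = plt.get_cmap("tab20")
    fig, ax = plt.subplots(figsize=(1.5 + 0.7 * len(bars), 4.5))
    bottoms = np.zeros(len(bars))
    pos = {b: i for i, b in enumerate(bars)}
    for j, mod in enumerate(mods):
        sub = table[table["modification"] == mod]
        heights = np.zeros(len(bars))
        for _, row in sub.iterrows():
            heights[pos[row["bar"]]] += row["beta"]
        ax.bar(
            range(len(bars)), heights, bottom=bottoms,
            label=str(mod), color=cmap(j % 20),
        )
        bottoms += heights
    ax.set_xticks(range(len(bars)), bars, rotation=45, ha="right")
    ax.set_ylabel("beta value")
    ax.set_ylim(0, 1.05)
    ax.legend(title="modification", bbox_to_anchor=(1.02, 1), loc="upper left")
    paths = {
        "plot": out_dir / "stacked_bars.png",
        "data": out_dir / "stacked_bars_data.csv",
    }
    _save(fig, paths["plot"])
    table.to_csv(paths["data"], index=False)
    return paths
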