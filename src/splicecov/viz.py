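"""Visualization of differential-splicing results from a unified TSV.

All results funnel through one TSV layout (one row per intron of a tested
feature, with per-sample raw and adjusted value columns) from which PCA
maps, clustered heatmaps and Venn diagrams are rendered. Every plotting
operation also writes its numeric backing table (PC coordinates, dendrogram
leaf orders, region sizes) so downstream checks never parse images.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy.cluster import hierarchy  # noqa: E402
from scipy.spatial.distance import pdist  # noqa: E402
from sklearn.decomposition import PCA  # noqa: E402

_META_COLS = ["feature_id", "group_id", "chrom", "start", "end", "strand",
              "value_kind", "p_value", "q_value", "dpsi"]

_LINKAGES = {"single", "complete", "average", "weighted", "centroid", "median", "ward"}


def to_unified_tsv(path, dsr_records=None, dsa_records=None, samples=None,
                   adjusted: dict | None = None, matrix=None) -> pd.DataFrame:
    """Serialize test records into the unified per-feature TSV.

    DSR rows carry per-sample raw PSI (and adjusted PSI when provided);
    DSA rows carry raw counts (and adjusted counts). Mixing is allowed —
    the ``value_kind`` column disambiguates.
    """
    adjusted = adjusted or {}
    rows = []
    if dsr_records:
        for r in dsr_records:
            raw = r.raw_psi
            adj = adjusted.get(r.bunch_id)
            for m, key in enumerate(r.intron_keys):
                chrom, start, end, strand = key
                row = {
                    "feature_id": f"{chrom}:{start}-{end}({strand})",
                    "group_id": r.bunch_id, "chrom": chrom, "start": start,
                    "end": end, "strand": strand, "value_kind": "psi",
                    "p_value": r.p_value, "q_value": r.q_value, "dpsi": r.dpsi,
                }
                for i, sid in enumerate(samples):
                    row[sid] = float(raw[i, m]) if raw is not None else np.nan
                    if adj is not None:
                        row[f"{sid}.adjusted"] = float(adj.values[i, m])
                rows.append(row)
    if dsa_records:
        for r in dsa_records:
            chrom, start, end, strand = r.intron_key
            row = {
                "feature_id": f"{chrom}:{start}-{end}({strand})",
                "group_id": f"{chrom}:{start}-{end}({strand})",
                "chrom": chrom, "start": start, "end": end, "strand": strand,
                "value_kind": "count", "p_value": r.p_value,
                "q_value": r.q_value, "dpsi": np.nan,
            }
            y = matrix.counts_for(r.intron_key) if matrix is not None else None
            adj = adjusted.get(r.intron_key)
            for i, sid in enumerate(samples):
                row[sid] = float(y[i]) if y is not None else np.nan
                if adj is not None:
                    row[f"{sid}.adjusted"] = float(adj.values[i])
            rows.append(row)
    if not rows:
        df = pd.DataFrame(columns=_META_COLS + list(samples or []))
    else:
        sample_cols = [c for c in rows[0] if c not in _META_COLS]
        df = pd.DataFrame(rows, columns=_META_COLS + sample_cols)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_unified_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})


def _value_matrix(df: pd.DataFrame, adjusted: bool, max_na_frac: float = 0.2):
    """Feature x sample value matrix; NA imputed by feature mean."""
    sample_cols = [
        c for c in df.columns
        if c not in _META_COLS and c.endswith(".adjusted") == adjusted
    ]
    mat = df[sample_cols].to_numpy(dtype=float)
    keep = np.isnan(mat).mean(axis=1) <= max_na_frac
    mat = mat[keep]
    means = np.nanmean(np.where(np.isnan(mat), np.nan, mat), axis=1)
    inds = np.where(np.isnan(mat))
    mat[inds] = np.take(means, inds[0])
    samples = [c[: -len(".adjusted")] if adjusted else c for c in sample_cols]
    return mat, samples, df.index[keep]


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # sample, PC1, PC2, explained variance in attrs
    figure_path: str | None


def pca_plot(
    tsv, out_prefix=None, value_kind: str = "psi", adjusted: bool = False,
    q_cutoff: float | None = None, p_cutoff: float | None = None,
    metadata: pd.DataFrame | None = None, color: str | None = None,
    shape: str | None = None, label: str | None = None,
    scale: bool = False, max_na_frac: float = 0.2,
) -> PcaResult:
    """Project samples on the first two PCs of the (centered) value matrix.

    Rows can be filtered by significance before projection; sample
    aesthetics (color / shape / label) come from metadata columns.
    """
    df = read_unified_tsv(tsv) if not isinstance(tsv, pd.DataFrame) else tsv.copy()
    df = df[df["value_kind"] == value_kind]
    if q_cutoff is not None:
        df = df[df["q_value"] <= q_cutoff]
    if p_cutoff is not None:
        df = df[df["p_value"] <= p_cutoff]
    mat, samples, _ = _value_matrix(df, adjusted, max_na_frac)
    if mat.shape[0] < 2 or len(samples) < 2:
        raise ValueError(
            f"need >= 2 features and >= 2 samples after filtering "
            f"(q<={q_cutoff}, p<={p_cutoff}); got {mat.shape[0]} features"
        )
    X = mat.T  # samples x features
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    table = pd.DataFrame({"sample": samples, "PC1": coords[:, 0], "PC2": coords[:, 1]})
    table.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()

    fig_path = None
    if out_prefix is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        meta = (metadata.set_index("sample_id", drop=False)
                if metadata is not None else None)
        colors = shapes = None
        if meta is not None and color:
            levels = sorted(meta[color].astype(str).unique())
            cmap = dict(zip(levels, plt.cm.tab10.colors))
            colors = [cmap[str(meta.loc[s, color])] for s in samples]
        if meta is not None and shape:
            levels = sorted(meta[shape].astype(str).unique())
            smap = dict(zip(levels, ["o", "v", "s", "^", "D", "P"]))
            shapes = [smap[str(meta.loc[s, shape])] for s in samples]
        for i, s in enumerate(samples):
            ax.scatter(
                coords[i, 0], coords[i, 1],
                c=[colors[i]] if colors else "C0",
                marker=shapes[i] if shapes else "o",
            )
            if meta is not None and label:
                ax.annotate(str(meta.loc[s, label]), coords[i], fontsize=6)
        evr = pca.explained_variance_ratio_
        ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
        fig.tight_layout()
        fig_path = f"{out_prefix}.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        table.to_csv(f"{out_prefix}.pca.tsv", sep="\t", index=False)
    return PcaResult(coordinates=table, figure_path=fig_path)


@dataclass
class HeatmapResult:
    row_order: list
    col_order: list
    figure_path: str | None


def heatmap(
    tsv, out_prefix=None, value_kind: str = "psi", adjusted: bool = False,
    linkage: str = "weighted", metric: str = "cityblock",
    cluster_rows: bool = True, cluster_cols: bool = True,
    q_cutoff: float | None = None, max_na_frac: float = 0.2,
) -> HeatmapResult:
    """Hierarchically clustered heatmap; returns the dendrogram leaf orders."""
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; supported: {sorted(_LINKAGES)}")
    try:
        pdist(np.zeros((2, 2)), metric=metric)
    except ValueError as exc:
        raise ValueError(f"unknown metric {metric!r}: {exc}") from exc
    df = read_unified_tsv(tsv) if not isinstance(tsv, pd.DataFrame) else tsv.copy()
    df = df[df["value_kind"] == value_kind]
    if q_cutoff is not None:
        df = df[df["q_value"] <= q_cutoff]
    mat, samples, kept = _value_matrix(df, adjusted, max_na_frac)
    if not np.isfinite(mat).all():
        raise ValueError("non-finite values remain after imputation")
    feature_ids = list(df.loc[kept, "feature_id"])

    row_order = list(range(mat.shape[0]))
    col_order = list(range(mat.shape[1]))
    if cluster_rows and mat.shape[0] > 1:
        Z = hierarchy.linkage(mat, method=linkage, metric=metric)
        row_order = list(hierarchy.leaves_list(Z))
    if cluster_cols and mat.shape[1] > 1:
        Z = hierarchy.linkage(mat.T, method=linkage, metric=metric)
        col_order = list(hierarchy.leaves_list(Z))

    fig_path = None
    if out_prefix is not None:
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mat[np.ix_(row_order, col_order)], aspect="auto",
                       cmap="viridis", interpolation="nearest")
        ax.set_xticks(range(len(col_order)))
        ax.set_xticklabels([samples[j] for j in col_order], rotation=90, fontsize=5)
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, label=value_kind)
        fig.tight_layout()
        fig_path = f"{out_prefix}.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        pd.DataFrame({
            "axis": ["row"] * len(row_order) + ["col"] * len(col_order),
            "position": list(range(len(row_order))) + list(range(len(col_order))),
            "name": [feature_ids[i] for i in row_order] + [samples[j] for j in col_order],
        }).to_csv(f"{out_prefix}.order.tsv", sep="\t", index=False)
    return HeatmapResult(
        row_order=[feature_ids[i] for i in row_order],
        col_order=[samples[j] for j in col_order],
        figure_path=fig_path,
    )


@dataclass
class VennResult:
    regions: dict  # frozenset of set names -> exclusive region size
    figure_path: str | None


def venn(gene_sets: dict, out_prefix=None) -> VennResult:
    """Exclusive region cardinalities for 2-4 named sets, plus a simple figure."""
    names = list(gene_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn supports 2 to 4 sets")
    sets = {n: set(s) for n, s in gene_sets.items()}
    regions = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    fig_path = None
    if out_prefix is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        centers = {
            2: [(-0.5, 0), (0.5, 0)],
            3: [(-0.5, -0.3), (0.5, -0.3), (0, 0.55)],
            4: [(-0.6, 0), (-0.2, 0.2), (0.2, 0.2), (0.6, 0)],
        }[len(names)]
        for (x, y), name in zip(centers, names):
            ax.add_patch(plt.Circle((x, y), 0.9, alpha=0.3, label=name))
            ax.annotate(f"{name} ({len(sets[name])})", (x, y + 0.95),
                        ha="center", fontsize=8)
        ax.set_xlim(-2, 2)
        ax.set_ylim(-1.8, 1.8)
        ax.set_aspect("equal")
        ax.axis("off")
        fig_path = f"{out_prefix}.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        pd.DataFrame(
            [{"sets": "&".join(sorted(k)), "size": v} for k, v in regions.items()]
        ).to_csv(f"{out_prefix}.regions.tsv", sep="\t", index=False)
    return VennResult(regions=regions, figure_path=fig_path)
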