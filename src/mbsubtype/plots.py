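"""Graphical renderings of prediction results.

Every plot writes PNG + SVG and a machine-readable TSV twin holding exactly
the numbers drawn, so plot/data consistency is testable without touching
pixels. PCA here is visualization only: it projects test samples into the
principal-component space of the reference rank matrix but never feeds
classification, which operates in the full rank space.
"""

from __future__ import annotations

import os
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .classify import PredictionResult, summarize_by_subtype
from .io import predictions_frame
from .reference import TrainingReference
from .types import SUBTYPES, MBSubtypeError


def _save(fig: plt.Figure, path: str | os.PathLike) -> list[Path]:
    base = Path(path).with_suffix("")
    out = []
    for ext in (".png", ".svg"):
        fig.savefig(base.with_suffix(ext), bbox_inches="tight")
        out.append(base.with_suffix(ext))
    plt.close(fig)
    return out


def _twin(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> Path:
    twin = Path(path).with_suffix(".tsv")
    df.to_csv(twin, sep="\t", index=index, float_format="%.17g")
    return twin


def render_predictions_heatmap(
    results: list[PredictionResult], path: str | os.PathLike
) -> pd.DataFrame:
    """Samples x subtypes grid of vote percentages; darker = more confident."""
    if not results:
        raise MBSubtypeError("no prediction results to plot")
    grid = render_heatmap_frame(results)
    fig, ax = plt.subplots(
        figsize=(4.5, max(2.0, 0.25 * len(grid) + 1.0))
    )
    im = ax.imshow(grid.to_numpy(), cmap="Blues", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(len(SUBTYPES)), SUBTYPES, rotation=45, ha="right")
    ax.set_yticks(range(len(grid)), grid.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="vote percent")
    ax.set_title("Subtype vote percentages per sample")
    _save(fig, path)
    twin = grid.reset_index()
    _twin(twin, path)
    return grid


def render_pca(
    test_rank_matrix: np.ndarray,
    test_sample_ids: list[str],
    ref: TrainingReference,
    path: str | os.PathLike,
    n_components: int = 3,
    plot_components: int = 2,
) -> pd.DataFrame:
    """Project test samples into the reference rank matrix's PCA space.

    The PCA is fit on the centered reference rank matrix; test rank vectors
    (over the same harmonized genesets) are projected into it. The caption
    reports the variance explained by the retained components.
    """
    test_rank_matrix = np.atleast_2d(np.asarray(test_rank_matrix, dtype=float))
    if test_rank_matrix.shape[1] != len(ref.geneset_names):
        raise MBSubtypeError(
            "test rank matrix columns must match the reference genesets"
        )
    if plot_components not in (2, 3):
        raise MBSubtypeError("plot_components must be 2 or 3")
    n_components = min(n_components, ref.n_samples - 1, len(ref.geneset_names))
    pca = PCA(n_components=n_components)
    ref_scores = pca.fit_transform(ref.rank_matrix)
    test_scores = pca.transform(test_rank_matrix)
    var = pca.explained_variance_ratio_

    rows = []
    for sid, label, score in zip(ref.sample_ids, ref.labels, ref_scores):
        rows.append({"sample_id": sid, "role": "reference", "label": label,
                     **{f"PC{i + 1}": score[i] for i in range(n_components)}})
    for sid, score in zip(test_sample_ids, test_scores):
        rows.append({"sample_id": sid, "role": "test", "label": "",
                     **{f"PC{i + 1}": score[i] for i in range(n_components)}})
    df = pd.DataFrame(rows)

    fig = plt.figure(figsize=(5.5, 4.5))
    if plot_components == 3 and n_components >= 3:
        ax = fig.add_subplot(projection="3d")
    else:
        plot_components = 2
        ax = fig.add_subplot()
    cmap = dict(zip(SUBTYPES, ("tab:blue", "tab:red", "tab:orange", "tab:green",
                               "tab:gray")))
    for label in SUBTYPES:
        mask = (df["role"] == "reference") & (df["label"] == label)
        if not mask.any():
            continue
        coords = [df.loc[mask, f"PC{i + 1}"] for i in range(plot_components)]
        ax.scatter(*coords, s=12, color=cmap[label], label=label, alpha=0.7)
    mask = df["role"] == "test"
    coords = [df.loc[mask, f"PC{i + 1}"] for i in range(plot_components)]
    ax.scatter(*coords, s=40, color="purple", marker="*", label="test")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if plot_components == 3:
        ax.set_zlabel("PC3")
    ax.legend(fontsize=7)
    ax.set_title(
        "Reference rank space PCA\n"
        f"variance explained: {', '.join('%.1f%%' % (100 * v) for v in var)}"
    )
    _save(fig, path)
    _twin(df, path)
    return df


def render_distribution_pie(
    results: list[PredictionResult], path: str | os.PathLike
) -> pd.DataFrame:
    """Pie of predicted-subtype fractions across all samples tested."""
    counts, _ = summarize_by_subtype(results)
    frac = counts / counts.sum()
    df = pd.DataFrame(
        {"subtype": counts.index, "n_samples": counts.values, "fraction": frac.values}
    )
    nonzero = df[df["n_samples"] > 0]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.pie(nonzero["n_samples"], labels=nonzero["subtype"], autopct="%1.0f%%")
    ax.set_title("Predicted subtypes across samples")
    _save(fig, path)
    _twin(df, path)
    return df


def render_distribution_boxplot(
    results: list[PredictionResult], path: str | os.PathLike
) -> pd.DataFrame:
    """Boxplots of prediction confidences per predicted subtype."""
    _, confidences = summarize_by_subtype(results)
    rows = [
        {"subtype": s, "confidence_percent": c}
        for s in SUBTYPES
        for c in confidences[s]
    ]
    df = pd.DataFrame(rows, columns=["subtype", "confidence_percent"])
    present = [s for s in SUBTYPES if confidences[s]]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.boxplot(
        [confidences[s] for s in present], tick_labels=present, showmeans=False
    )
    ax.set_ylabel("confidence (% of votes)")
    ax.set_ylim(0, 105)
    ax.axhline(80, color="red", ls="--", lw=0.8)
    ax.set_title("Prediction strength per subtype")
    _save(fig, path)
    _twin(df, path)
    return df


def render_barplot(
    results: list[PredictionResult], path: str | os.PathLike
) -> pd.DataFrame:
    """Stacked per-sample vote-percentage bars (sample-centric view)."""
    if not results:
        raise MBSubtypeError("no prediction results to plot")
    grid = render_heatmap_frame(results)
    fig, ax = plt.subplots(figsize=(max(3.5, 0.3 * len(grid) + 1), 3.5))
    bottom = np.zeros(len(grid))
    colors = ("tab:blue", "tab:red", "tab:orange", "tab:green", "tab:gray")
    for s, color in zip(SUBTYPES, colors):
        ax.bar(grid.index, grid[s], bottom=bottom, label=s, color=color)
        bottom += grid[s].to_numpy()
    ax.set_ylabel("vote percent")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    ax.legend(fontsize=7)
    ax.set_title("Vote composition per sample")
    _save(fig, path)
    _twin(grid.reset_index(), path)
    return grid


def render_heatmap_frame(results: list[PredictionResult]) -> pd.DataFrame:
    """The samples x subtypes vote-percent frame shared by heatmap and barplot."""
    df = predictions_frame(results)
    k = sum(results[0].votes.values())
    grid = pd.DataFrame(
        {s: (100.0 * df[f"vote_{s}"] / k).to_numpy() for s in SUBTYPES},
        index=pd.Index(df["sample_id"].to_numpy(), name="sample_id"),
    )
    return grid
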