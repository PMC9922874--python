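"""Summary arithmetic and export helpers.

All rounding is half-away-from-zero (the convention behind printed figures
like "78.4%" and "96%"); the number of decimals is always an explicit
argument, never inferred. Every percentage string is recomputed from its
counts at call time — nothing caches formatted text.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dge import DEResult
from .errors import GeneLookupError, UndefinedPercentageError


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1) at ``decimals``."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum,
                                                  rounding=ROUND_HALF_UP))


def percent_value(numerator: int, denominator: int, decimals: int = 0) -> float:
    if denominator <= 0:
        raise UndefinedPercentageError(
            f"percentage of {numerator} over denominator {denominator} "
            "is undefined")
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    return round_half_away(100.0 * numerator / denominator, decimals)


def percent(numerator: int, denominator: int, decimals: int = 0) -> str:
    """Format ``numerator/denominator`` as a percentage string, e.g.
    ``percent(280, 357, 1) == "78.4%"``."""
    value = percent_value(numerator, denominator, decimals)
    return f"{value:.{decimals}f}%"


def threshold_fc(log2_threshold: float) -> float:
    """Fold-change equivalent of a log2 threshold, 2 decimals
    (0.7 -> 1.62; 1.0 -> 2.00)."""
    if log2_threshold < 0:
        raise ValueError("log2 threshold must be >= 0")
    return round_half_away(2.0 ** log2_threshold, 2)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def category_breakdown(genes, annotation: pd.Series,
                       decimals: int = 0) -> pd.DataFrame:
    """Count and percentage per functional category among the *annotated*
    genes of a set (unannotated genes are excluded from the denominator).

    Rows are sorted by descending count, ties broken lexicographically.
    """
    annotated = [g for g in genes if g in annotation.index]
    if not annotated:
        raise UndefinedPercentageError(
            "category breakdown is undefined: no annotated genes in the set")
    counts = annotation.reindex(annotated).value_counts()
    total = int(counts.sum())
    df = counts.rename("count").rename_axis("category").reset_index()
    df = df.sort_values(["count", "category"],
                        ascending=[False, True], ignore_index=True)
    df["percent"] = [percent(int(c), total, decimals) for c in df["count"]]
    df["denominator"] = total
    return df


@dataclass(frozen=True)
class SubsetSummary:
    n_up: int
    n_down: int
    mean_fold_change_up: float | None  # arithmetic mean of 2**log2FC, 1 dp


def subset_summary(gene_list: Sequence[str], de: DEResult) -> SubsetSummary:
    """Direction split of a named gene list by the sign of log2FC (no
    threshold), plus the mean fold change of the upregulated part."""
    missing = [g for g in gene_list if g not in de.table.index]
    if missing:
        raise GeneLookupError(
            f"gene(s) absent from the DE result: {missing[:5]}")
    lfc = de.table.loc[list(gene_list), "log2fc"]
    n_up = int((lfc > 0).sum())
    n_down = int((lfc < 0).sum())
    if n_up:
        mean_fc = round_half_away(float(np.exp2(lfc[lfc > 0]).mean()), 1)
    else:
        mean_fc = None
    return SubsetSummary(n_up=n_up, n_down=n_down, mean_fold_change_up=mean_fc)


def lfc_table(de_results: Mapping[str, DEResult],
              genes: Sequence[str]) -> pd.DataFrame:
    """Genes x contrasts log2FC matrix; errors on any missing value."""
    cols = {}
    for label, de in de_results.items():
        lfc = de.table["log2fc"].reindex(genes)
        if lfc.isna().any():
            bad = lfc.index[lfc.isna()][0]
            raise GeneLookupError(
                f"gene {bad!r} has no log2FC in contrast {label!r}")
        cols[label] = lfc
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


def heatmap_matrix(classes: pd.Series, de_results: Mapping[str, DEResult],
                   *, sort_contrast: str | None = None,
                   class_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Class-ordered genes x contrasts log2FC matrix, ready for heatmap CSV.

    Rows are grouped by class (``class_order`` or sorted class names), then
    sorted by descending log2FC in ``sort_contrast`` (default: the first
    contrast), with gene_id as the final deterministic tie-break.
    """
    genes = list(classes.index)
    values = lfc_table(de_results, genes)
    if sort_contrast is None:
        sort_contrast = values.columns[0]
    if class_order is None:
        class_order = sorted(classes.unique())
    rank = {c: i for i, c in enumerate(class_order)}
    order = sorted(
        genes,
        key=lambda g: (rank.get(classes[g], len(rank)),
                       -values.at[g, sort_contrast], g))
    out = values.reindex(order)
    out.insert(0, "class", classes.reindex(order))
    return out


def write_heatmap_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, float_format="%.6g")


def write_heatmap_png(matrix: pd.DataFrame, path: str | Path) -> None:
    """Cosmetic heatmap rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.drop(columns=["class"], errors="ignore")
    fig, ax = plt.subplots(
        figsize=(2 + 0.4 * data.shape[1], 2 + 0.02 * data.shape[0]))
    vmax = float(np.nanmax(np.abs(data.to_numpy()))) or 1.0
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2FC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
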