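"""Notochord-specificity scoring of genes from a labeled UMI count matrix.

A marker gene for driving notochord-restricted expression must be both
highly expressed in the notochord and depleted elsewhere.  With
``Expr_N`` the mean depth-normalized UMIs of a gene across notochord cells
and ``Expr_NN`` the analogous mean across all other cells, the score is

    score = Expr_N^2 / (Expr_NN + pseudocount)
          = Expression x Enrichment,   Enrichment = Expr_N / (Expr_NN + pc)

Counts are normalized to UMIs per million per cell before averaging.  The
ranked table reports the score with a 10^-3 display scaling, matching the
units of the bundled reference marker ranking for the zebrafish notochord
at 18 hpf.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "normalize_cpm",
    "group_means",
    "specificity_score",
    "rank_table",
    "rank_from_printed",
    "load_reference_markers",
]

logger = logging.getLogger(__name__)

CPM_SCALE = 1e6
DISPLAY_SCALE = 1e-3
DEFAULT_PSEUDOCOUNT = 1.0


def _counts_to_array(counts) -> tuple[np.ndarray, list, list]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index), list(counts.columns)
    arr = np.asarray(counts, dtype=float)
    return arr, list(range(arr.shape[0])), [f"g{j}" for j in range(arr.shape[1])]


def normalize_cpm(counts):
    """Scale each cell (row) to one million total counts.

    Cells with zero total are excluded, with their ids logged.  Accepts and
    returns a DataFrame (cells x genes) or a plain array.
    """
    arr, cells, genes = _counts_to_array(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    totals = arr.sum(axis=1)
    keep = totals > 0
    if not np.all(keep):
        dropped = [cells[i] for i in np.flatnonzero(~keep)]
        logger.warning("excluding %d zero-total cells: %s", len(dropped), dropped[:10])
    out = arr[keep] * (CPM_SCALE / totals[keep, None])
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=[c for c, k in zip(cells, keep) if k], columns=genes)
    return out


def group_means(normalized, group) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene arithmetic means within and outside the cell group.

    ``group`` is a per-cell boolean (True = in-group / notochord-like).
    Returns ``(expr_n, expr_nn)``.
    """
    arr, _, _ = _counts_to_array(normalized)
    g = np.asarray(group, dtype=bool)
    if g.shape[0] != arr.shape[0]:
        raise ValueError("group length does not match number of cells")
    if not g.any() or g.all():
        raise ValueError("both groups must be nonempty")
    return arr[g].mean(axis=0), arr[~g].mean(axis=0)


def specificity_score(expr_n, expr_nn, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """score = expr_n^2 / (expr_nn + pseudocount).

    The pseudocount bounds the enrichment of genes absent outside the group
    without affecting the ranking of well-expressed genes.
    """
    expr_n = np.asarray(expr_n, dtype=float)
    expr_nn = np.asarray(expr_nn, dtype=float)
    if np.any(expr_n < 0) or np.any(expr_nn < 0):
        raise ValueError("mean expressions must be nonnegative")
    return expr_n**2 / (expr_nn + pseudocount)


def rank_table(
    expr_n,
    expr_nn,
    gene_ids=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    display_scale: float = DISPLAY_SCALE,
) -> pd.DataFrame:
    """Ranked gene table with columns (gene, expression, enrichment, score).

    Sorted descending by score; ties broken by expression then gene id.
    The score column carries the 10^-3 display scaling.
    """
    expr_n = np.asarray(expr_n, dtype=float)
    expr_nn = np.asarray(expr_nn, dtype=float)
    if expr_n.size < 1:
        raise ValueError("need at least one gene")
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(expr_n.size)]
    enrichment = expr_n / (expr_nn + pseudocount)
    score = specificity_score(expr_n, expr_nn, pseudocount) * display_scale
    df = pd.DataFrame(
        {
            "gene": list(gene_ids),
            "expression": expr_n,
            "enrichment": enrichment,
            "score": score,
        }
    )
    df = df.sort_values(
        ["score", "expression", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def rank_from_printed(table: pd.DataFrame, display_scale: float = DISPLAY_SCALE) -> pd.DataFrame:
    """Recompute scores from already-averaged expression and enrichment
    columns (as printed in a marker table) and re-rank.

    ``score = expression * enrichment * display_scale`` — the enrichment
    column already encodes the out-group denominator.
    """
    req = {"gene", "expression", "enrichment"}
    if not req <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    df = table.copy()
    df["score"] = df["expression"] * df["enrichment"] * display_scale
    return df.sort_values(
        ["score", "expression", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)


def score_counts(
    counts,
    group,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gene_ids=None,
) -> pd.DataFrame:
    """CPM-normalize, average per group, score and rank in one call."""
    norm = normalize_cpm(counts)
    arr, _, genes = _counts_to_array(norm)
    if isinstance(counts, pd.DataFrame):
        kept = list(norm.index)
        group = pd.Series(np.asarray(group), index=_counts_to_array(counts)[1]).loc[kept].to_numpy()
        gene_ids = gene_ids if gene_ids is not None else genes
    else:
        totals = np.asarray(counts, dtype=float).sum(axis=1)
        group = np.asarray(group, dtype=bool)[totals > 0]
    expr_n, expr_nn = group_means(arr, group)
    return rank_table(expr_n, expr_nn, gene_ids=gene_ids, pseudocount=pseudocount)


def load_reference_markers() -> pd.DataFrame:
    """Bundled reference ranking of notochord-enriched genes (18 hpf).

    Columns: gene, expression (mean normalized UMIs per million in
    notochord cells), enrichment (notochord over rest-of-embryo mean), and
    the printed score (expression x enrichment x 10^-3).
    """
    with resources.files("notopattern.data").joinpath("notochord_markers_18hpf.csv").open() as fh:
        return pd.read_csv(fh)
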