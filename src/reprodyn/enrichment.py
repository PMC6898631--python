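"""Hypergeometric over-representation analysis against a GMT collection.

Each gene set is intersected with the declared universe before
testing; the reported gene_ratio is overlap / query size, matching the
convention of dot-plot pathway figures.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import GeneSetCollection

__all__ = ["ora", "top_pathways", "plot_dotplot"]

MIN_SET_SIZE = 5


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    min_set_size: int = MIN_SET_SIZE,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    Sets smaller than ``min_set_size`` after universe intersection are
    skipped.  Returns a DataFrame sorted by (q, p, set_id) with columns
    set_id, description, k, n, K, N, gene_ratio, p, q, significant.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query")
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query contains genes outside the universe")
    N, n = len(universe), len(query)
    rows = []
    for sid, (desc, members) in collection:
        m = members & universe
        K = len(m)
        if K < min_set_size:
            continue
        k = len(query & m)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_id": sid,
                "description": desc,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "gene_ratio": k / n,
                "p": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "description", "k", "n", "K", "N", "gene_ratio", "p", "q", "significant"]
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out.sort_values(["q", "p", "set_id"]).reset_index(drop=True)


def top_pathways(results: pd.DataFrame, top_n: int = 15) -> pd.DataFrame:
    """Top-n rows of an ORA table for dot-plot/heatmap rendering."""
    if top_n > len(results):
        warnings.warn(
            f"requested top {top_n} of {len(results)} tested sets; truncating",
            stacklevel=2,
        )
        top_n = len(results)
    ordered = results.sort_values(["q", "p", "set_id"]).reset_index(drop=True)
    return ordered.head(top_n)[["set_id", "description", "gene_ratio", "q"]]


def plot_dotplot(results: pd.DataFrame, path, top_n: int = 15) -> None:
    """Render a pathway dot plot (size = gene_ratio, color = q)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = top_pathways(results, top_n)[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(top) + 1.5))
    sc = ax.scatter(
        top["gene_ratio"],
        range(len(top)),
        s=400 * top["gene_ratio"] + 20,
        c=top["q"],
        cmap="viridis_r",
    )
    ax.set_yticks(range(len(top)), top["set_id"])
    ax.set_xlabel("gene ratio")
    fig.colorbar(sc, ax=ax, label="B-H q")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
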