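"""Chromatin-accessibility dynamics: per-time differential peaks,
closed-to-open / open-to-closed classification, and TSS assignment.

A peak significantly more accessible at time t than at 0 h (q < alpha,
log2fc > 0) is "CO" (closed to open); significantly less accessible is
"OC" (open to closed); everything else is "NC".  Peaks are linked to
genes through the nearest TSS within a 2 kb window centered on the
peak midpoint (|center - TSS| <= 1 kb), which satisfies both the
peak-centric and the TSS-centric reading of the window rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import SizeFactors, test_differential
from .io import CountMatrix, PeakSet, SampleSheet, TssTable

__all__ = [
    "test_peak_differential",
    "classify_peaks",
    "count_dynamics",
    "assign_peaks_to_tss",
    "dynamic_region_genes",
]

DEFAULT_WINDOW = 2000  # bp, centered on the peak midpoint


def test_peak_differential(
    cm: CountMatrix,
    sheet: SampleSheet,
    sf: SizeFactors,
    condition: str,
    time_h: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-peak NB Wald test of occupancy at time t vs 0 h.

    Shares the statistical core with the expression analysis; the
    feature_id column is renamed to peak_id.
    """
    out = test_differential(cm, sheet, sf, condition, time_h, alpha)
    return out.rename(columns={"feature_id": "peak_id"})


def classify_peaks(diff: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach the CO/OC/NC class to a differential-peak table."""
    sig = diff["q"] < alpha
    lfc = diff["log2fc"]
    cls = np.where(sig & (lfc > 0), "CO", np.where(sig & (lfc < 0), "OC", "NC"))
    out = diff.copy()
    out["class"] = cls
    return out


def count_dynamics(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-time counts of CO and OC regions and their ratio."""
    rows = []
    for t, grp in classified.groupby("time_h"):
        n_co = int((grp["class"] == "CO").sum())
        n_oc = int((grp["class"] == "OC").sum())
        ratio = n_co / n_oc if n_oc else np.inf if n_co else np.nan
        rows.append({"time_h": t, "n_CO": n_co, "n_OC": n_oc, "co_oc_ratio": ratio})
    return pd.DataFrame(rows).sort_values("time_h").reset_index(drop=True)


def assign_peaks_to_tss(
    peaks: PeakSet, tss: TssTable, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Assign each peak to the closest TSS within ``window``/2 bp of its
    midpoint; distance ties break toward the lexicographically smaller
    gene id.

    Returns a DataFrame with peak_id, gene_id (NaN when unassigned) and
    the signed, strand-oriented distance (peak center minus TSS, with
    the sign flipped for minus-strand genes).
    """
    half = window // 2
    centers = peaks.centers().to_numpy()
    chroms = peaks.table["chrom"].to_numpy()
    out_gene: list[object] = [None] * len(centers)
    out_dist: list[float] = [np.nan] * len(centers)

    tdf = tss.table.sort_values(["chrom", "tss", "gene_id"])
    for chrom, sub in tdf.groupby("chrom"):
        pos = sub["tss"].to_numpy()
        genes = sub["gene_id"].to_numpy()
        strands = sub["strand"].to_numpy()
        mask = np.nonzero(chroms == chrom)[0]
        if mask.size == 0:
            continue
        c = centers[mask]
        right = np.searchsorted(pos, c)
        for i, (center, r) in enumerate(zip(c, right)):
            best = None  # (|d|, gene_id, tss, strand)
            for j in (r - 1, r):
                if 0 <= j < pos.size:
                    cand = (abs(int(center) - int(pos[j])), genes[j], int(pos[j]), strands[j])
                    if best is None or cand[:2] < best[:2]:
                        best = cand
            if best is not None and best[0] <= half:
                k = mask[i]
                signed = int(center) - best[2]
                if best[3] == "-":
                    signed = -signed
                out_gene[k] = best[1]
                out_dist[k] = signed
    return pd.DataFrame(
        {"peak_id": peaks.peak_ids, "gene_id": out_gene, "distance": out_dist}
    )


def dynamic_region_genes(
    classified: pd.DataFrame, assignments: pd.DataFrame
) -> dict[tuple[float, str], list[str]]:
    """Unique genes whose assigned peaks are CO (or OC) at each time."""
    if set(classified["peak_id"]) - set(assignments["peak_id"]):
        raise ValueError("classified peaks missing from the assignment table")
    gene_of = assignments.set_index("peak_id")["gene_id"]
    out: dict[tuple[float, str], list[str]] = {}
    sig = classified[classified["class"].isin(["CO", "OC"])]
    for (t, cls), grp in sig.groupby(["time_h", "class"]):
        genes = gene_of.loc[grp["peak_id"]].dropna().unique()
        out[(float(t), str(cls))] = sorted(genes)
    return out
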