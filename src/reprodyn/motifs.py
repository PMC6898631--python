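"""PWM scanning, exact score p-values, and motif enrichment over time.

Scores are log2-odds against the background model, in bits.  Score
p-values are exact tail probabilities of the background score
distribution, computed by dynamic programming on a discretized score
lattice; for short motifs the DP agrees with full enumeration over all
4^L words.  Presence of a motif in a sequence is called through an
exact-p-value threshold so that calls are comparable across motifs of
different length and information content.

Two higher-level summaries drive the biology: "direct-effect" genes —
differentially expressed genes whose promoter carries a reprogramming-
factor motif (Oct4, Sox2, Klf4, cMyc, or the composite Oct4-Sox2) —
and a fluctuation ranking that nominates dynamically acting factors by
the standard deviation of their per-time enrichment p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PWM, MotifLibrary

__all__ = [
    "MotifHit",
    "EnrichmentSeries",
    "FluctuationScore",
    "scan_pwm",
    "score_pvalue",
    "score_threshold",
    "promoter_motif_presence",
    "direct_effect_genes",
    "motif_enrichment",
    "fluctuation_rank",
    "OSKM_MOTIFS",
]

OSKM_MOTIFS = ("Oct4", "Sox2", "Klf4", "cMyc", "Oct4-Sox2")

P_FLOOR = 1e-300
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_SCORE_BIN = 1e-3  # bits


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif_id: str
    offset: int  # 0-based start in the forward sequence
    strand: str  # '+' or '-'
    score: float  # bits


@dataclass
class EnrichmentSeries:
    """Per-time enrichment p-values for one motif."""

    motif_id: str
    times: list[float]
    pvalues: list[float]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.pvalues):
            raise ValueError("one p-value per time point required")


@dataclass(frozen=True)
class FluctuationScore:
    motif_id: str
    score: float
    rank: int
    top: bool = False


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGTN string to integer codes (N = 4)."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid sequence character {exc.args[0]!r}") from None


def _log_odds(pwm: PWM) -> np.ndarray:
    """(L, 5) log2-odds score matrix; column 4 (N) is -inf."""
    s = np.log2(pwm.matrix / pwm.background[None, :])
    return np.hstack([s, np.full((s.shape[0], 1), -np.inf)])


def _reverse_matrix(score: np.ndarray) -> np.ndarray:
    """Score matrix that scores the reverse complement of each window."""
    rc = score[::-1, [3, 2, 1, 0, 4]]
    return rc


def _window_scores(enc: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Scores of all windows of length L; windows containing N are -inf."""
    L = score.shape[0]
    n = enc.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    return score[np.arange(L)[None, :], windows].sum(axis=1)


def scan_pwm(
    sequence: str | np.ndarray,
    pwm: PWM,
    score_threshold: float,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """All hits with log2-odds score >= threshold on both strands.

    Minus-strand hits score the reverse complement of the window; the
    reported offset is the window start on the forward sequence.
    Windows containing N are skipped.  Hits are sorted by offset, with
    '+' before '-' at the same offset.
    """
    enc = encode_sequence(sequence) if isinstance(sequence, str) else sequence
    fwd = _log_odds(pwm)
    hits: list[MotifHit] = []
    for strand, mat in (("+", fwd), ("-", _reverse_matrix(fwd))):
        scores = _window_scores(enc, mat)
        for off in np.nonzero(scores >= score_threshold)[0]:
            hits.append(MotifHit(sequence_id, pwm.motif_id, int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def _score_distribution(pwm: PWM, bin_width: float = _SCORE_BIN) -> tuple[np.ndarray, int]:
    """Exact background distribution of the forward-strand score.

    Returns (probabilities, origin) where probabilities[i] is the mass
    on score bin (i + origin), in units of ``bin_width`` bits.
    """
    s = np.log2(pwm.matrix / pwm.background[None, :])
    k = np.rint(s / bin_width).astype(np.int64)  # (L, 4) integer scores
    dist = np.array([1.0])
    origin = 0
    bg = pwm.background
    for col in range(k.shape[0]):
        lo, hi = k[col].min(), k[col].max()
        new = np.zeros(dist.size + (hi - lo))
        for b in range(4):
            off = k[col, b] - lo
            new[off : off + dist.size] += bg[b] * dist
        dist = new
        origin += lo
    return dist, origin


def score_pvalue(pwm: PWM, score: float, bin_width: float = _SCORE_BIN) -> float:
    """P(background word of length L scores >= ``score``), exact DP.

    Scores above the maximum achievable return the minimal achievable
    tail (bounded below by the single best word's probability, itself
    >= 1/4^L only when that word has positive background mass).
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    dist, origin = _score_distribution(pwm, bin_width)
    # half-bin tolerance so achievable scores are counted inclusively
    target = int(np.ceil(score / bin_width - 0.5)) - origin
    if target <= 0:
        return 1.0
    if target >= dist.size:
        target = dist.size - 1  # minimal nonzero tail: the best word(s)
    p = float(dist[target:].sum())
    return min(max(p, 0.0), 1.0)


def score_threshold(pwm: PWM, presence_p: float, bin_width: float = _SCORE_BIN) -> float:
    """Smallest score whose exact p-value is <= presence_p.

    Used to calibrate presence calls; capped at the best achievable
    score when no bin reaches ``presence_p``.
    """
    if not 0 < presence_p < 1:
        raise ValueError("presence_p must be in (0, 1)")
    dist, origin = _score_distribution(pwm, bin_width)
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.nonzero(tail <= presence_p)[0]
    idx = int(ok[0]) if ok.size else dist.size - 1
    return (idx + origin) * bin_width


def _has_hit(enc: np.ndarray, pwm: PWM, threshold: float) -> bool:
    fwd = _log_odds(pwm)
    for mat in (fwd, _reverse_matrix(fwd)):
        scores = _window_scores(enc, mat)
        if scores.size and scores.max() >= threshold:
            return True
    return False


def _batch_has_hit(encs: np.ndarray, pwm: PWM, threshold: float) -> np.ndarray:
    """Presence calls for a stack of equal-length sequences (n, seq_len)."""
    fwd = _log_odds(pwm)
    L = fwd.shape[0]
    n = encs.shape[0]
    if encs.shape[1] < L:
        return np.zeros(n, dtype=bool)
    out = np.zeros(n, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(encs, L, axis=1)
    pos = np.arange(L)[None, None, :]
    # chunk to bound the (chunk, n_windows, L) gather temporary
    chunk = max(1, int(4e6 // (windows.shape[1] * L)))
    for mat in (fwd, _reverse_matrix(fwd)):
        for i in range(0, n, chunk):
            s = mat[pos, windows[i : i + chunk]].sum(axis=-1)
            out[i : i + chunk] |= (s >= threshold).any(axis=1)
    return out


def promoter_motif_presence(
    promoters: Mapping[str, str],
    library: MotifLibrary,
    presence_p: float = 1e-4,
) -> pd.DataFrame:
    """Boolean gene x motif table: does the promoter contain the motif?

    A gene has a motif iff at least one window (either strand) scores at
    or above the exact-p-value threshold ``presence_p``.
    """
    if not promoters:
        raise ValueError("empty promoter set")
    ids = list(promoters)
    encoded = [encode_sequence(promoters[g]) for g in ids]
    lengths = {e.size for e in encoded}
    stacked = np.vstack(encoded) if len(lengths) == 1 else None
    data = {}
    for pwm in library:
        thr = score_threshold(pwm, presence_p)
        if stacked is not None:
            data[pwm.motif_id] = _batch_has_hit(stacked, pwm, thr)
        else:
            data[pwm.motif_id] = [_has_hit(e, pwm, thr) for e in encoded]
    return pd.DataFrame(data, index=ids)


def direct_effect_genes(
    de_genes: Mapping[float, Sequence[str]],
    presence: pd.DataFrame,
    motif_ids: Sequence[str] = OSKM_MOTIFS,
) -> dict[float, list[str]]:
    """Per time point, the DE genes whose promoter carries >= 1 of the
    named reprogramming-factor motifs."""
    missing = [m for m in motif_ids if m not in presence.columns]
    if missing:
        raise KeyError(f"unknown motif id(s): {missing}")
    has_any = presence[list(motif_ids)].any(axis=1)
    carriers = set(presence.index[has_any])
    out = {}
    for t, genes in de_genes.items():
        unknown = [g for g in genes if g not in presence.index]
        if unknown:
            raise ValueError(f"no promoter for gene(s): {unknown[:5]}")
        out[t] = sorted(set(genes) & carriers)
    return out


def motif_enrichment(
    targets: Mapping[str, str],
    background: Mapping[str, str],
    pwm: PWM,
    presence_p: float = 1e-4,
) -> float:
    """One-sided hypergeometric enrichment of motif presence in targets.

    The universe is targets plus background; presence is called per
    sequence at the exact-p-value threshold.  Returns the upper-tail
    p-value P(X >= observed overlap).
    """
    if not targets or not background:
        raise ValueError("both target and background sets must be non-empty")
    thr = score_threshold(pwm, presence_p)
    t_hits = sum(_has_hit(encode_sequence(s), pwm, thr) for s in targets.values())
    b_hits = sum(_has_hit(encode_sequence(s), pwm, thr) for s in background.values())
    N = len(targets) + len(background)
    K = t_hits + b_hits
    n = len(targets)
    return float(stats.hypergeom.sf(t_hits - 1, N, K, n))


def presence_matrix(
    sequences: Mapping[str, str],
    library: MotifLibrary,
    presence_p: float = 1e-4,
) -> pd.DataFrame:
    """Sequence x motif presence calls at an exact-p-value threshold."""
    return promoter_motif_presence(sequences, library, presence_p)


def enrichment_series(
    presence: pd.DataFrame,
    targets_per_time: Mapping[float, Sequence[str]],
) -> list[EnrichmentSeries]:
    """Per-motif enrichment p-value series from a presence matrix.

    At each time the targets are tested against the rest of the
    sequences in the matrix (hypergeometric upper tail).
    """
    times = sorted(targets_per_time)
    N = len(presence.index)
    out = []
    for m in presence.columns:
        K = int(presence[m].sum())
        ps = []
        for t in times:
            tgt = list(targets_per_time[t])
            missing = set(tgt) - set(presence.index)
            if missing:
                raise ValueError(f"targets absent from presence matrix: {sorted(missing)[:5]}")
            k = int(presence.loc[tgt, m].sum())
            ps.append(min(float(stats.hypergeom.sf(k - 1, N, K, len(tgt))), 1.0))
        out.append(EnrichmentSeries(m, [float(t) for t in times], ps))
    return out


def fluctuation_rank(
    series: Sequence[EnrichmentSeries],
    transform: str = "neglog10",
    top_k: int = 20,
) -> list[FluctuationScore]:
    """Rank motifs by the spread of their enrichment p-values over time.

    The score is the sample standard deviation of transform(p) across
    time points (default -log10 with p floored at 1e-300; ``raw`` uses
    p itself).  Motifs are sorted by descending score with lexicographic
    motif_id tie-breaking; the top_k are marked.
    """
    if transform not in ("neglog10", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    if not series:
        return []
    grids = {tuple(s.times) for s in series}
    if len(grids) != 1:
        raise ValueError("all series must share the same time grid")
    if len(series[0].times) < 2:
        raise ValueError("need >= 2 time points")
    if top_k > len(series):
        raise ValueError("top_k exceeds the number of motifs")
    scored = []
    for s in series:
        p = np.maximum(np.asarray(s.pvalues, dtype=float), P_FLOOR)
        vals = -np.log10(p) if transform == "neglog10" else p
        scored.append((s.motif_id, float(np.std(vals, ddof=1))))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        FluctuationScore(mid, sc, rank=i + 1, top=i < top_k)
        for i, (mid, sc) in enumerate(scored)
    ]
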