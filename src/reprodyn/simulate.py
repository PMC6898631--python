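"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the structure of an induction time course in
two cell populations with different response kinetics:

* ``aml-like`` — transcriptome and chromatin respond from 3 h after
  induction, chromatin changes dominated by closed-to-open (CO)
  regions, open-to-closed (OC) regions appearing only from 12 h;
* ``hspc-like`` — no response at 3 h or 6 h, modest OC-dominated
  changes from 12 h, with ~25-fold fewer changed regions overall.

Counts are negative-binomial around log-normal base means with
per-sample library-size multipliers.  A log-normal culture-drift term
is shared between the induced (dox) and uninduced (control) arms so
that drift genes are differentially expressed against 0 h but have a
dox/control fold-change ratio near 1 — exactly the nuisance signal the
ratio-CI filter exists to remove.

Everything is reproducible: one integer seed, fanned out per stage
through a stable hash, yields byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneSetCollection,
    MotifLibrary,
    PWM,
    PeakSet,
    SampleSheet,
    TssTable,
)
from .lda import DoseGroup, simulate_lda

__all__ = [
    "SimConfig",
    "TruthLabels",
    "stage_seed",
    "generate_timecourse_counts",
    "generate_peak_experiment",
    "generate_motif_library",
    "generate_promoters",
    "generate_gene_sets",
]

PROFILES = ("aml-like", "hspc-like")

# cumulative fraction of peaks planted as changed, per time point
AML_CO_FRAC = {3.0: 0.10, 6.0: 0.12, 12.0: 0.14, 24.0: 0.16}
AML_OC_FRAC = {3.0: 0.0, 6.0: 0.0, 12.0: 0.01, 24.0: 0.02}
HSPC_CO_FRAC = {3.0: 0.0, 6.0: 0.0, 12.0: 0.004, 24.0: 0.004}
HSPC_OC_FRAC = {3.0: 0.0, 6.0: 0.0, 12.0: 0.006, 24.0: 0.008}


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment (defaults are the study
    conditions: 0/3/6/12/24 h, two replicates, 4-fold expression
    effects, dispersion 0.05, CO-dominated chromatin dynamics)."""

    seed: int = 0
    n_genes: int = 2000
    n_peaks: int = 1000
    times: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 24.0)
    replicates: int = 2
    libsize_range: tuple[float, float] = (0.7, 1.3)
    dispersion: float = 0.05
    base_mean_log: float = 4.0
    base_mean_sigma: float = 1.0
    # expression effects
    frac_affected: float = 0.05
    effect_size: float = 4.0
    frac_drift: float = 0.10
    drift_sigma: float = 0.5  # natural-log sd of the shared culture drift
    # response onset per population profile (hours)
    onset: Mapping[str, float] = field(
        default_factory=lambda: {"aml-like": 3.0, "hspc-like": 12.0}
    )
    # chromatin dynamics (cumulative planted fractions per time)
    co_frac: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {"aml-like": dict(AML_CO_FRAC), "hspc-like": dict(HSPC_CO_FRAC)}
    )
    oc_frac: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {"aml-like": dict(AML_OC_FRAC), "hspc-like": dict(HSPC_OC_FRAC)}
    )
    peak_effect: float = 6.0
    peak_width: int = 200
    genome_length: int = 1_000_000
    n_tss: int = 500
    n_death_genes: int = 30
    n_death_linked_peaks: int = 25
    # motifs and promoters
    n_decoy_motifs: int = 50
    motif_length: int = 8
    consensus_prob: float = 0.95
    promoter_length: int = 600  # -500..+100 around the TSS
    gc_content: float = 0.5
    site_fidelity: float = 1.0  # 1.0 plants the exact consensus word
    frac_direct: float = 0.4  # fraction of affected genes given a factor motif
    # gene sets
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (10, 100)
    planted_set_odds_ratio: float = 10.0
    planted_set_id: str = "positive_regulation_of_cell_death"
    # limiting dilution
    lda_doses: tuple[float, ...] = (3e2, 3e3, 3e4, 3e5)
    lda_n_per_dose: int = 6
    lda_f_control: float = 1.0 / 620.0
    lda_f_treated: float = 1.0 / 28000.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthLabels:
    """Planted ground truth, consistent with the emitted data."""

    affected_genes: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    drift_genes: set[str] = field(default_factory=set)
    direct_effect_genes: set[str] = field(default_factory=set)
    planted_motifs: dict[str, list[str]] = field(default_factory=dict)  # gene -> motifs
    peak_classes: pd.DataFrame | None = None  # peak_id x time -> CO/OC/NC
    peak_genes: dict[str, str] = field(default_factory=dict)  # death-linked peak -> gene
    death_genes: set[str] = field(default_factory=set)
    planted_set_id: str | None = None


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _stage_rng(cfg: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(cfg.seed, stage))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_timecourse_counts(
    cfg: SimConfig, profile: str = "aml-like"
) -> tuple[CountMatrix, SampleSheet, TruthLabels]:
    """Gene-level NB count time course with dox and control arms.

    Affected genes carry a multiplicative dox effect (half up, half
    down) from the profile's onset time.  Drift genes carry a shared
    per-time log-normal factor in both arms.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    rng = _stage_rng(cfg, f"counts:{profile}")
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    base = rng.lognormal(cfg.base_mean_log, cfg.base_mean_sigma, cfg.n_genes)

    n_aff = int(round(cfg.frac_affected * cfg.n_genes))
    n_drift = int(round(cfg.frac_drift * cfg.n_genes))
    special = rng.choice(cfg.n_genes, size=n_aff + n_drift, replace=False)
    aff_idx, drift_idx = special[:n_aff], special[n_aff:]
    directions = rng.choice([1, -1], size=n_aff)
    onset = cfg.onset[profile]

    times = sorted(cfg.times)
    drift = np.ones((cfg.n_genes, len(times)))
    for j, t in enumerate(times):
        if t > 0:
            drift[drift_idx, j] = rng.lognormal(0.0, cfg.drift_sigma, n_drift)

    effect = np.ones((cfg.n_genes, len(times)))
    for j, t in enumerate(times):
        if t >= onset and t > 0:
            effect[aff_idx, j] = cfg.effect_size ** directions

    sample_ids, rows, cols = [], [], []
    for cond in ("dox", "control"):
        for j, t in enumerate(times):
            for rep in range(1, cfg.replicates + 1):
                sid = f"{cond}_t{t:g}_r{rep}"
                libsize = rng.uniform(*cfg.libsize_range)
                mu = base * drift[:, j] * libsize
                if cond == "dox":
                    mu = mu * effect[:, j]
                cols.append(_nb_draw(rng, mu, cfg.dispersion))
                sample_ids.append(sid)
                rows.append({"sample_id": sid, "condition": cond, "time_h": t, "replicate": rep})
    cm = CountMatrix(genes, sample_ids, np.column_stack(cols))
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = TruthLabels(
        affected_genes={genes[i]: int(d) for i, d in zip(aff_idx, directions)},
        drift_genes={genes[i] for i in drift_idx},
    )
    return cm, sheet, truth


def generate_peak_experiment(
    cfg: SimConfig, profile: str = "aml-like"
) -> tuple[CountMatrix, SampleSheet, PeakSet, TssTable, TruthLabels]:
    """Toy-genome ATAC-like experiment with planted CO/OC dynamics.

    Changed peaks get an onset time and direction so that the planted
    per-time (n_CO, n_OC) table follows the profile's cumulative
    fractions; a subset of CO peaks is placed within 1 kb of designated
    "death-pathway" gene TSSs.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    rng = _stage_rng(cfg, f"peaks:{profile}")
    times = sorted(t for t in cfg.times if t > 0)

    tss_pos = np.sort(
        rng.choice(
            np.arange(5000, cfg.genome_length - 5000), size=cfg.n_tss, replace=False
        )
    )
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_tss)]
    strands = rng.choice(["+", "-"], size=cfg.n_tss)
    tss = TssTable(
        pd.DataFrame(
            {"gene_id": gene_ids, "chrom": "chr1", "tss": tss_pos, "strand": strands}
        )
    )

    co_frac = cfg.co_frac[profile]
    oc_frac = cfg.oc_frac[profile]

    def planted_counts(frac: Mapping[float, float]) -> dict[float, int]:
        return {t: int(round(frac.get(t, 0.0) * cfg.n_peaks)) for t in times}

    co_cum, oc_cum = planted_counts(co_frac), planted_counts(oc_frac)
    for cum in (co_cum, oc_cum):
        run = 0
        for t in times:
            if cum[t] < run:
                raise ValueError("planted fractions must be cumulative (nondecreasing)")
            run = cum[t]

    # onset assignment: peak k becomes CO (OC) at the earliest time where
    # the cumulative count first covers it
    n_co, n_oc = max(co_cum.values(), default=0), max(oc_cum.values(), default=0)
    order = rng.permutation(cfg.n_peaks)
    co_peaks = order[:n_co]
    oc_peaks = order[n_co : n_co + n_oc]
    onset_of: dict[int, tuple[str, float]] = {}
    for cum, idx, cls in ((co_cum, co_peaks, "CO"), (oc_cum, oc_peaks, "OC")):
        prev = 0
        for t in times:
            for k in idx[prev : cum[t]]:
                onset_of[int(k)] = (cls, t)
            prev = max(prev, cum[t])

    # positions: death-linked CO peaks sit within 1 kb of death-gene TSSs.
    # Death genes are drawn from TSSs with both flanking neighbours > 850 bp
    # away, so a peak planted within +/-400 bp is guaranteed to have the
    # death gene as its closest TSS (truth stays consistent with assignment).
    gaps_left = np.diff(tss_pos, prepend=-(10**9))
    gaps_right = np.diff(tss_pos, append=2 * 10**9)
    eligible = np.nonzero((gaps_left > 850) & (gaps_right > 850))[0]
    death_gene_idx = rng.choice(eligible, size=min(cfg.n_death_genes, eligible.size), replace=False)
    death_genes = {gene_ids[i] for i in death_gene_idx}
    n_linked = min(cfg.n_death_linked_peaks, n_co, cfg.n_death_genes)
    starts = rng.integers(0, cfg.genome_length - cfg.peak_width, size=cfg.n_peaks)
    peak_gene: dict[str, str] = {}
    for j in range(n_linked):
        k = int(co_peaks[j])
        g = int(death_gene_idx[j])
        offset = int(rng.integers(-400, 401))
        center = int(tss_pos[g]) + offset
        starts[k] = np.clip(center - cfg.peak_width // 2, 0, cfg.genome_length - cfg.peak_width)
        peak_gene[f"P{k:04d}"] = gene_ids[g]
    peak_ids = [f"P{k:04d}" for k in range(cfg.n_peaks)]
    peaks = PeakSet(
        pd.DataFrame(
            {
                "peak_id": peak_ids,
                "chrom": "chr1",
                "start": starts,
                "end": starts + cfg.peak_width,
            }
        )
    )

    # planted class per peak per time
    classes = pd.DataFrame("NC", index=peak_ids, columns=[f"{t:g}" for t in times])
    for k, (cls, onset) in onset_of.items():
        for t in times:
            if t >= onset:
                classes.iat[k, classes.columns.get_loc(f"{t:g}")] = cls

    base = rng.lognormal(cfg.base_mean_log, cfg.base_mean_sigma, cfg.n_peaks)
    sample_ids, rows, cols = [], [], []
    for t in [0.0] + times:
        for rep in range(1, cfg.replicates + 1):
            sid = f"dox_t{t:g}_r{rep}"
            libsize = rng.uniform(*cfg.libsize_range)
            mu = base * libsize
            if t > 0:
                fac = np.ones(cfg.n_peaks)
                for k, (cls, onset) in onset_of.items():
                    if t >= onset:
                        fac[k] = cfg.peak_effect if cls == "CO" else 1.0 / cfg.peak_effect
                mu = mu * fac
            cols.append(_nb_draw(rng, mu, cfg.dispersion))
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "condition": "dox", "time_h": t, "replicate": rep})
    cm = CountMatrix(peak_ids, sample_ids, np.column_stack(cols))
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = TruthLabels(peak_classes=classes, peak_genes=peak_gene, death_genes=death_genes)
    return cm, sheet, peaks, tss, truth


def _random_pwm(rng: np.random.Generator, motif_id: str, length: int, consensus_prob: float) -> PWM:
    consensus = rng.integers(0, 4, size=length)
    mat = np.full((length, 4), (1.0 - consensus_prob) / 3.0)
    mat[np.arange(length), consensus] = consensus_prob
    return PWM(motif_id, mat)


def generate_motif_library(cfg: SimConfig) -> MotifLibrary:
    """Named reprogramming-factor motifs plus static decoys.

    The composite Oct4-Sox2 motif is longer than the single-factor
    motifs, as composite elements are in practice.
    """
    rng = _stage_rng(cfg, "motifs")
    lengths = {"Oct4": 8, "Sox2": 7, "Klf4": 10, "cMyc": 10, "Oct4-Sox2": 15}
    motifs = [
        _random_pwm(rng, name, L, cfg.consensus_prob) for name, L in lengths.items()
    ]
    for i in range(cfg.n_decoy_motifs):
        motifs.append(_random_pwm(rng, f"decoy{i:02d}", cfg.motif_length, cfg.consensus_prob))
    return MotifLibrary(motifs)


def _consensus_word(pwm: PWM) -> str:
    return "".join("ACGT"[b] for b in pwm.matrix.argmax(axis=1))


def _sample_site(rng: np.random.Generator, pwm: PWM, fidelity: float) -> str:
    """A binding site: the consensus word, or a PWM sample at lower fidelity."""
    if fidelity >= 1.0:
        return _consensus_word(pwm)
    bases = []
    for row in pwm.matrix:
        if rng.random() < fidelity:
            bases.append("ACGT"[int(np.argmax(row))])
        else:
            bases.append("ACGT"[rng.choice(4, p=row / row.sum())])
    return "".join(bases)


def generate_promoters(
    cfg: SimConfig,
    library: MotifLibrary,
    truth: TruthLabels,
    genes: Sequence[str] | None = None,
) -> tuple[dict[str, str], TruthLabels]:
    """Background promoter sequences with sites planted into the
    promoters of designated direct-effect genes.

    Direct-effect genes are a configured fraction of the affected
    genes; each gets one site from a randomly chosen factor motif.
    Plant positions are recorded in the truth labels.
    """
    rng = _stage_rng(cfg, "promoters")
    if genes is None:
        genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    factor_ids = [m for m in ("Oct4", "Sox2", "Klf4", "cMyc", "Oct4-Sox2") if m in library.motif_ids]
    affected = sorted(truth.affected_genes)
    n_direct = int(round(cfg.frac_direct * len(affected)))
    direct = set(
        rng.choice(affected, size=n_direct, replace=False) if n_direct else []
    )

    gc = cfg.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    promoters: dict[str, str] = {}
    planted: dict[str, list[str]] = {}
    for g in genes:
        seq = "".join("ACGT"[b] for b in rng.choice(4, size=cfg.promoter_length, p=probs))
        if g in direct:
            pwm = library[factor_ids[int(rng.integers(len(factor_ids)))]]
            if cfg.promoter_length < pwm.length:
                raise ValueError("promoter shorter than motif")
            site = _sample_site(rng, pwm, cfg.site_fidelity)
            off = int(rng.integers(0, cfg.promoter_length - pwm.length + 1))
            seq = seq[:off] + site + seq[off + pwm.length :]
            planted[g] = [pwm.motif_id]
        promoters[g] = seq
    truth.direct_effect_genes = direct
    truth.planted_motifs = planted
    return promoters, truth


def generate_gene_sets(
    cfg: SimConfig, truth: TruthLabels, universe: Sequence[str] | None = None
) -> GeneSetCollection:
    """Random gene sets plus one set enriched for the affected genes at
    the configured odds ratio."""
    rng = _stage_rng(cfg, "gene_sets")
    if universe is None:
        universe = [f"G{i:04d}" for i in range(cfg.n_genes)]
    universe = list(universe)
    affected = sorted(set(truth.affected_genes) & set(universe))
    others = sorted(set(universe) - set(affected))

    lo, hi = cfg.set_size_range
    target = (lo + hi) / 2.0
    p0 = min(target / len(universe), 0.5)
    odds0 = p0 / (1 - p0)
    odds1 = cfg.planted_set_odds_ratio * odds0
    p1 = odds1 / (1 + odds1)
    members = [g for g in affected if rng.random() < p1]
    members += [g for g in others if rng.random() < p0]
    if not members:
        members = affected[:1] or universe[:1]
    sets: dict[str, tuple[str, frozenset[str]]] = {
        cfg.planted_set_id: ("planted cell-death analogue", frozenset(members))
    }
    for i in range(cfg.n_gene_sets - 1):
        size = min(int(rng.integers(lo, hi + 1)), len(universe))
        sel = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET{i:03d}"] = (f"random set {i}", frozenset(universe[j] for j in sel))
    truth.planted_set_id = cfg.planted_set_id
    return GeneSetCollection(sets)


def generate_fluctuation_experiment(
    cfg: SimConfig,
    planted_id: str = "Oct4",
    rates: Sequence[float] = (0.9, 0.05, 0.9, 0.05),
    n_pool: int = 200,
    n_with_site: int = 60,
    n_targets: int = 40,
    seq_length: int = 200,
    seed: int | None = None,
) -> tuple[dict[str, str], dict[float, list[str]], str]:
    """Sequence pool and oscillating per-time target sets for the
    motif-fluctuation ranking.

    A fraction ``rates[i]`` of the targets at the i-th nonzero time
    point carry a planted site of ``planted_id``; decoy motifs are
    never planted, so their enrichment stays static while the planted
    motif's p-value oscillates between significant and null.

    Returns (sequences, targets per time, planted motif id).
    """
    rng = np.random.default_rng(seed) if seed is not None else _stage_rng(cfg, "fluctuation")
    library = generate_motif_library(cfg)
    pwm = library[planted_id]
    gc = cfg.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: dict[str, str] = {}
    for i in range(n_pool):
        seq = "".join("ACGT"[b] for b in rng.choice(4, size=seq_length, p=probs))
        if i < n_with_site:
            site = _sample_site(rng, pwm, cfg.site_fidelity)
            off = int(rng.integers(0, seq_length - pwm.length + 1))
            seq = seq[:off] + site + seq[off + pwm.length :]
        seqs[f"S{i:03d}"] = seq
    with_ids = [f"S{i:03d}" for i in range(n_with_site)]
    without_ids = [f"S{i:03d}" for i in range(n_with_site, n_pool)]
    times = sorted(t for t in cfg.times if t > 0)[: len(rates)]
    targets: dict[float, list[str]] = {}
    for t, rate in zip(times, rates):
        n_hot = int(round(rate * n_targets))
        hot = rng.choice(with_ids, size=n_hot, replace=False)
        cold = rng.choice(without_ids, size=n_targets - n_hot, replace=False)
        targets[t] = sorted([*hot, *cold])
    return seqs, targets, planted_id


def generate_lda_tables(cfg: SimConfig) -> tuple[list[DoseGroup], list[DoseGroup]]:
    """Dose-response tables for the uninduced (control) and induced
    (treated) populations at the configured frequencies."""
    rng = _stage_rng(cfg, "lda")
    control = simulate_lda(cfg.lda_f_control, cfg.lda_doses, cfg.lda_n_per_dose, rng)
    treated = simulate_lda(cfg.lda_f_treated, cfg.lda_doses, cfg.lda_n_per_dose, rng)
    return control, treated
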