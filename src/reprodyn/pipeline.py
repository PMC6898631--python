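"""Config-driven orchestration of the analysis stages.

Each stage is an ordinary function taking a configuration mapping and
an output directory; the command-line interface in :mod:`reprodyn.cli`
is a thin wrapper around these.  Every run records a manifest with the
config hash, the seeds used, and a checksum for every file written, so
deterministic stages can be verified to reproduce byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import atac, de, enrichment, io, motifs
from .lda import compare_frequencies, fit_single_hit
from .simulate import (
    SimConfig,
    generate_gene_sets,
    generate_lda_tables,
    generate_motif_library,
    generate_peak_experiment,
    generate_promoters,
    generate_timecourse_counts,
    stage_seed,
)

__all__ = [
    "DEFAULT_CONFIG",
    "ConfigError",
    "DataError",
    "build_config",
    "cmd_simulate",
    "cmd_de",
    "cmd_motifs",
    "cmd_atac",
    "cmd_ora",
    "cmd_lda",
    "cmd_all",
]

log = logging.getLogger("reprodyn")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "alpha": 0.05,  # B-H FDR threshold
    "confidence": 0.95,  # ratio-CI filter level
    "presence_p": 1e-4,  # motif presence score p-value
    "tss_window": 2000,  # bp, centered on the peak midpoint
    "top_k_motifs": 20,
    "top_n_pathways": 15,
    "fluctuation_transform": "neglog10",
    "pairing": "index",
    "profile": "aml-like",
    "sim": {},  # SimConfig field overrides
}


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class DataError(ValueError):
    """Missing or malformed input data."""


def build_config(overrides: Mapping | None = None) -> dict:
    """Merge user overrides into the default config; unknown keys error."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if overrides:
        unknown = set(overrides) - set(cfg)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for k, v in overrides.items():
            if k == "sim":
                sim_fields = set(SimConfig.__dataclass_fields__)
                bad = set(v) - sim_fields
                if bad:
                    raise ConfigError(f"unknown sim key(s): {sorted(bad)}")
                cfg["sim"].update(v)
            else:
                cfg[k] = v
    return cfg


def _sim_config(cfg: Mapping) -> SimConfig:
    overrides = dict(cfg.get("sim", {}))
    overrides.setdefault("seed", cfg["seed"])
    overrides = {
        k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
    }
    return SimConfig(**overrides)


class Manifest:
    """Accumulates per-stage output files and checksums."""

    def __init__(self, outdir: Path, cfg: Mapping):
        self.outdir = Path(outdir)
        self.path = self.outdir / "MANIFEST.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config_hash": io.config_hash(cfg), "seed": cfg["seed"], "stages": {}}

    def record(self, stage: str, files: Sequence[Path], seed: int | None, elapsed: float) -> None:
        self.data["stages"][stage] = {
            "seed": seed,
            "elapsed_s": round(elapsed, 3),
            "files": {str(f.relative_to(self.outdir)): io.file_checksum(f) for f in files},
        }
        self.path.write_text(json.dumps(self.data, indent=2) + "\n")


def _stage(name):
    def deco(fn):
        def wrapper(cfg: Mapping, outdir) -> list[Path]:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            t0 = time.monotonic()
            seed = stage_seed(cfg["seed"], name)
            log.info("stage=%s seed=%d config=%s", name, seed, io.config_hash(cfg))
            files = fn(cfg, outdir)
            elapsed = time.monotonic() - t0
            Manifest(outdir, cfg).record(name, files, seed, elapsed)
            log.info("stage=%s done elapsed=%.2fs files=%d", name, elapsed, len(files))
            return files

        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper

    return deco


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DataError(f"{stage}: missing input {path} (run the simulate stage first?)")
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


@_stage("simulate")
def cmd_simulate(cfg: Mapping, outdir) -> list[Path]:
    """Generate the full synthetic dataset with truth labels."""
    outdir = Path(outdir)
    data = outdir / "data"
    data.mkdir(exist_ok=True)
    sim = _sim_config(cfg)
    files: list[Path] = []

    profile = cfg["profile"]
    cm, sheet, truth = generate_timecourse_counts(sim, profile)
    io.write_counts(cm, data / "rna_counts.tsv")
    io.write_sample_sheet(sheet, data / "rna_samples.tsv")
    truth_rna = pd.DataFrame(
        {
            "gene_id": cm.feature_ids,
            "affected": [g in truth.affected_genes for g in cm.feature_ids],
            "direction": [truth.affected_genes.get(g, 0) for g in cm.feature_ids],
            "drift": [g in truth.drift_genes for g in cm.feature_ids],
        }
    )
    io.write_table(truth_rna, data / "truth_rna.tsv")
    files += [data / "rna_counts.tsv", data / "rna_samples.tsv", data / "truth_rna.tsv"]

    for prof in ("aml-like", "hspc-like"):
        tag = prof.split("-")[0]
        pcm, psheet, peaks, tss, ptruth = generate_peak_experiment(sim, prof)
        io.write_counts(pcm, data / f"peaks_{tag}_counts.tsv")
        io.write_sample_sheet(psheet, data / f"peaks_{tag}_samples.tsv")
        io.write_bed(peaks, data / f"peaks_{tag}.bed")
        io.write_tss(tss, data / f"tss_{tag}.tsv")
        ptruth.peak_classes.rename_axis("peak_id").reset_index().to_csv(
            data / f"truth_peaks_{tag}.tsv", sep="\t", index=False
        )
        files += [
            data / f"peaks_{tag}_counts.tsv",
            data / f"peaks_{tag}_samples.tsv",
            data / f"peaks_{tag}.bed",
            data / f"tss_{tag}.tsv",
            data / f"truth_peaks_{tag}.tsv",
        ]

    library = generate_motif_library(sim)
    io.write_meme(library, data / "motifs.meme")
    promoters, truth = generate_promoters(sim, library, truth)
    io.write_fasta(promoters, data / "promoters.fa")
    io.write_table(
        pd.DataFrame(
            [(g, ";".join(ms)) for g, ms in sorted(truth.planted_motifs.items())],
            columns=["gene_id", "motifs"],
        ),
        data / "truth_promoters.tsv",
    )
    files += [data / "motifs.meme", data / "promoters.fa", data / "truth_promoters.tsv"]

    sets = generate_gene_sets(sim, truth)
    io.write_gmt(sets, data / "gene_sets.gmt")
    files.append(data / "gene_sets.gmt")

    control, treated = generate_lda_tables(sim)
    io.write_dose_table(control, data / "lda_control.tsv")
    io.write_dose_table(treated, data / "lda_treated.tsv")
    files += [data / "lda_control.tsv", data / "lda_treated.tsv"]
    return files


def _load_rna(outdir: Path):
    data = outdir / "data"
    cm, sheet = io.read_counts(
        _require(data / "rna_counts.tsv", "de"), _require(data / "rna_samples.tsv", "de")
    )
    return cm, sheet


@_stage("de")
def cmd_de(cfg: Mapping, outdir) -> list[Path]:
    """Differential expression vs 0 h with the ratio-CI noise filter."""
    outdir = Path(outdir)
    cm, sheet = _load_rna(outdir)
    sf = de.estimate_size_factors(cm)
    alpha, confidence = cfg["alpha"], cfg["confidence"]
    files: list[Path] = []
    for t in sheet.times:
        if t == 0:
            continue
        det = de.test_differential(cm, sheet, sf, "dox", t, alpha)
        ratios = de.ratio_ci_table(
            de.fold_change_ratios(cm, sheet, sf, t, cfg["pairing"]), confidence
        )
        affected = de.osk_affected_genes(det, ratios, alpha)
        ftag = f"{t:g}"
        io.write_table(det, outdir / f"de_t{ftag}.tsv")
        io.write_table(ratios, outdir / f"ratios_t{ftag}.tsv")
        (outdir / f"affected_t{ftag}.txt").write_text("".join(g + "\n" for g in affected))
        files += [outdir / f"de_t{ftag}.tsv", outdir / f"ratios_t{ftag}.tsv", outdir / f"affected_t{ftag}.txt"]
    return files


@_stage("motifs")
def cmd_motifs(cfg: Mapping, outdir) -> list[Path]:
    """Promoter motif presence, direct-effect genes, per-time motif
    enrichment, and the fluctuation ranking."""
    outdir = Path(outdir)
    data = outdir / "data"
    promoters = io.read_fasta(_require(data / "promoters.fa", "motifs"))
    library = io.read_motifs(_require(data / "motifs.meme", "motifs"))
    presence = motifs.promoter_motif_presence(promoters, library, cfg["presence_p"])
    presence.rename_axis("gene_id").reset_index().to_csv(
        outdir / "motif_presence.tsv", sep="\t", index=False
    )

    de_files = sorted(outdir.glob("de_t*.tsv"))
    if not de_files:
        raise DataError("motifs: no DE tables found (run the de stage first)")
    de_genes: dict[float, list[str]] = {}
    for f in de_files:
        tab = pd.read_csv(f, sep="\t")
        t = float(tab["time_h"].iloc[0])
        de_genes[t] = sorted(tab.loc[tab["significant"], "feature_id"])
    direct = motifs.direct_effect_genes(de_genes, presence)
    files = [outdir / "motif_presence.tsv"]
    for t, genes in sorted(direct.items()):
        p = outdir / f"direct_effect_t{t:g}.txt"
        p.write_text("".join(g + "\n" for g in genes))
        files.append(p)

    # per-time enrichment of each motif in DE-gene promoters vs the rest,
    # from the presence matrix (hypergeometric upper tail)
    times = sorted(de_genes)
    all_genes = list(presence.index)
    series = []
    rows = []
    for m in library.motif_ids:
        ps = []
        for t in times:
            targets = [g for g in de_genes[t] if g in presence.index]
            n, N = len(targets), len(all_genes)
            K = int(presence[m].sum())
            k = int(presence.loc[targets, m].sum()) if targets else 0
            p = float(_stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
            ps.append(min(p, 1.0))
            rows.append({"motif_id": m, "time_h": t, "p": ps[-1]})
        series.append(motifs.EnrichmentSeries(m, list(times), ps))
    io.write_table(pd.DataFrame(rows), outdir / "motif_enrichment.tsv")
    ranking = motifs.fluctuation_rank(
        series, cfg["fluctuation_transform"], min(cfg["top_k_motifs"], len(series))
    )
    io.write_table(
        pd.DataFrame([vars(r) for r in ranking]), outdir / "motif_fluctuation.tsv"
    )
    files += [outdir / "motif_enrichment.tsv", outdir / "motif_fluctuation.tsv"]
    return files


@_stage("atac")
def cmd_atac(cfg: Mapping, outdir) -> list[Path]:
    """Differential openness, CO/OC classification, TSS assignment."""
    outdir = Path(outdir)
    data = outdir / "data"
    files: list[Path] = []
    for tag in ("aml", "hspc"):
        cm, sheet = io.read_counts(
            _require(data / f"peaks_{tag}_counts.tsv", "atac"),
            _require(data / f"peaks_{tag}_samples.tsv", "atac"),
        )
        peaks = io.read_bed(_require(data / f"peaks_{tag}.bed", "atac"))
        tss = io.read_tss(_require(data / f"tss_{tag}.tsv", "atac"))
        # two-pass normalization: CO-dominated dynamics shift the plain
        # median-of-ratios factors, so re-estimate on non-differential peaks
        sf = de.reference_size_factors(cm, sheet, "dox", cfg["alpha"])
        classified = []
        for t in sheet.times:
            if t == 0:
                continue
            diff = atac.test_peak_differential(cm, sheet, sf, "dox", t, cfg["alpha"])
            classified.append(atac.classify_peaks(diff, cfg["alpha"]))
        allc = pd.concat(classified, ignore_index=True)
        dyn = atac.count_dynamics(allc)
        assignments = atac.assign_peaks_to_tss(peaks, tss, cfg["tss_window"])
        io.write_table(allc, outdir / f"peaks_{tag}_classified.tsv")
        io.write_table(dyn, outdir / f"peaks_{tag}_dynamics.tsv")
        io.write_table(assignments, outdir / f"peaks_{tag}_assignments.tsv")
        files += [
            outdir / f"peaks_{tag}_classified.tsv",
            outdir / f"peaks_{tag}_dynamics.tsv",
            outdir / f"peaks_{tag}_assignments.tsv",
        ]
        genes = atac.dynamic_region_genes(allc, assignments)
        rows = [
            {"time_h": t, "class": c, "gene_id": g}
            for (t, c), gl in sorted(genes.items())
            for g in gl
        ]
        io.write_table(
            pd.DataFrame(rows, columns=["time_h", "class", "gene_id"]),
            outdir / f"peaks_{tag}_genes.tsv",
        )
        files.append(outdir / f"peaks_{tag}_genes.tsv")
    return files


@_stage("ora")
def cmd_ora(cfg: Mapping, outdir) -> list[Path]:
    """Over-representation of the induction-affected gene lists."""
    outdir = Path(outdir)
    data = Path(outdir) / "data"
    sets = io.read_gmt(_require(data / "gene_sets.gmt", "ora"))
    cm, _ = _load_rna(outdir)
    universe = cm.feature_ids
    files: list[Path] = []
    for f in sorted(outdir.glob("affected_t*.txt")):
        genes = [g for g in f.read_text().splitlines() if g]
        tag = f.stem.replace("affected_", "")
        if not genes:
            log.warning("ora: empty gene list for %s; skipped", tag)
            continue
        res = enrichment.ora(genes, universe, sets, cfg["alpha"])
        io.write_table(res, outdir / f"ora_{tag}.tsv")
        top = enrichment.top_pathways(res, min(cfg["top_n_pathways"], len(res)))
        io.write_table(top, outdir / f"ora_{tag}_top.tsv")
        files += [outdir / f"ora_{tag}.tsv", outdir / f"ora_{tag}_top.tsv"]
    if not files:
        raise DataError("ora: no affected-gene lists found (run the de stage first)")
    return files


@_stage("lda")
def cmd_lda(cfg: Mapping, outdir) -> list[Path]:
    """Limiting-dilution frequency estimates and group comparison."""
    outdir = Path(outdir)
    data = outdir / "data"
    control = io.read_dose_table(_require(data / "lda_control.tsv", "lda"))
    treated = io.read_dose_table(_require(data / "lda_treated.tsv", "lda"))
    rows = []
    for name, groups in (("control", control), ("treated", treated)):
        est = fit_single_hit(groups, cfg["confidence"])
        rows.append(
            {
                "group": name,
                "f_hat": est.f_hat,
                "one_in": est.one_in,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "flag": est.flag or "",
            }
        )
    io.write_table(pd.DataFrame(rows), outdir / "lda_estimates.tsv")
    comp = compare_frequencies(control, treated)
    io.write_table(
        pd.DataFrame([{"lr_statistic": comp.lr_statistic, "df": comp.df, "p": comp.p}]),
        outdir / "lda_comparison.tsv",
    )
    return [outdir / "lda_estimates.tsv", outdir / "lda_comparison.tsv"]


def cmd_all(cfg: Mapping, outdir) -> list[Path]:
    """Run every stage in order and write a plain-text report."""
    outdir = Path(outdir)
    files: list[Path] = []
    for stage in (cmd_simulate, cmd_de, cmd_atac, cmd_motifs, cmd_ora, cmd_lda):
        files += stage(cfg, outdir)
    report = _report(outdir)
    (outdir / "report.txt").write_text(report)
    Manifest(outdir, cfg).record("report", [outdir / "report.txt"], None, 0.0)
    return files + [outdir / "report.txt"]


def _report(outdir: Path) -> str:
    """Headline tables of a completed run, as plain text."""
    lines = ["# reprodyn run report", ""]
    lines.append("## induction-affected genes per time point")
    for f in sorted(outdir.glob("affected_t*.txt"), key=lambda p: float(p.stem.replace("affected_t", ""))):
        n = sum(1 for g in f.read_text().splitlines() if g)
        lines.append(f"  {f.stem.replace('affected_t', '')} h: {n} genes")
    for tag in ("aml", "hspc"):
        f = outdir / f"peaks_{tag}_dynamics.tsv"
        if f.exists():
            lines += ["", f"## chromatin dynamics ({tag})", pd.read_csv(f, sep='\t').to_string(index=False)]
    f = outdir / "motif_fluctuation.tsv"
    if f.exists():
        top = pd.read_csv(f, sep="\t").head(20)
        lines += ["", "## top fluctuating motifs", top.to_string(index=False)]
    f = outdir / "lda_estimates.tsv"
    if f.exists():
        lines += ["", "## limiting-dilution estimates", pd.read_csv(f, sep='\t').to_string(index=False)]
        comp = pd.read_csv(outdir / "lda_comparison.tsv", sep="\t")
        lines += ["", "## group comparison", comp.to_string(index=False)]
    return "\n".join(lines) + "\n"
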