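"""Readers and writers for the pipeline's external formats.

All tabular formats are tab-delimited UTF-8 with a header line and a
trailing newline.  Genomic intervals follow the BED convention
(0-based, half-open).  Sequences are uppercased on read and restricted
to the ACGTN alphabet, since the downstream motif-scanning domain is
ACGT with N handled explicitly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "PeakSet",
    "TssTable",
    "GeneSetCollection",
    "PWM",
    "MotifLibrary",
    "DoseGroup",
    "read_counts",
    "read_bed",
    "read_motifs",
    "read_fasta",
    "read_tss",
    "read_gmt",
    "read_dose_table",
    "write_table",
    "write_counts",
    "write_sample_sheet",
    "write_bed",
    "write_fasta",
    "write_tss",
    "write_gmt",
    "write_meme",
    "write_dose_table",
    "load_config",
    "config_hash",
]

VALID_CONDITIONS = ("dox", "control")
_SEQ_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer counts over features (genes or peaks) x samples."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_features, n_samples), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("non-integer count")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("negative count")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SampleSheet:
    """Experimental design: one row per sample with condition, time, replicate."""

    table: pd.DataFrame  # columns: sample_id, condition, time_h, replicate

    REQUIRED = ("sample_id", "condition", "time_h", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        t = self.table
        bad = set(t["condition"]) - set(VALID_CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition(s): {sorted(bad)}")
        if (t["time_h"] < 0).any():
            raise FormatError("negative time")
        if (t["replicate"] < 1).any():
            raise FormatError("replicate indices must be >= 1")
        if t["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in sheet")
        if t.duplicated(subset=["condition", "time_h", "replicate"]).any():
            raise FormatError("duplicate (condition, time, replicate) stratum entry")
        if not (t["time_h"] == 0).any():
            raise FormatError("missing time-0 stratum")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def times(self) -> list[float]:
        return sorted(self.table["time_h"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def samples_at(self, condition: str, time_h: float) -> pd.DataFrame:
        """Rows for one (condition, time) stratum, sorted by replicate."""
        t = self.table
        sel = t[(t["condition"] == condition) & (t["time_h"] == time_h)]
        return sel.sort_values("replicate")

    def validate_against(self, cm: CountMatrix) -> None:
        sheet_ids = set(self.sample_ids)
        matrix_ids = set(cm.sample_ids)
        if sheet_ids != matrix_ids:
            unknown = matrix_ids - sheet_ids
            if unknown:
                raise FormatError(f"unknown sample(s) in count table: {sorted(unknown)}")
            raise FormatError(f"sample(s) missing from count table: {sorted(sheet_ids - matrix_ids)}")


@dataclass
class PeakSet:
    """Genomic intervals, 0-based half-open."""

    table: pd.DataFrame  # columns: peak_id, chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        for c in ("peak_id", "chrom", "start", "end"):
            if c not in t.columns:
                raise FormatError(f"peak table missing column {c}")
        if (t["start"] >= t["end"]).any():
            bad = t[t["start"] >= t["end"]].iloc[0]
            raise FormatError(f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")
        if (t["start"] < 0).any():
            raise FormatError("negative coordinate")
        if t["peak_id"].duplicated().any():
            raise FormatError("duplicate peak ids")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.table["peak_id"])

    def centers(self) -> pd.Series:
        """Peak midpoints; floor on even lengths for determinism."""
        t = self.table
        return ((t["start"] + t["end"]) // 2).astype(int)


@dataclass
class TssTable:
    """Transcription start sites, one per gene."""

    table: pd.DataFrame  # columns: gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        t = self.table
        for c in ("gene_id", "chrom", "tss", "strand"):
            if c not in t.columns:
                raise FormatError(f"TSS table missing column {c}")
        if t["gene_id"].duplicated().any():
            raise FormatError("duplicate gene ids in TSS table")
        if (t["tss"] < 0).any():
            raise FormatError("negative TSS position")
        bad = set(t["strand"]) - {"+", "-"}
        if bad:
            raise FormatError(f"invalid strand(s): {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT dialect): set_id -> (description, members)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"empty gene set {sid!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


@dataclass
class PWM:
    """Position probability matrix over ACGT with a background model.

    ``matrix`` is (L, 4) in ACGT column order; entries are strictly
    positive after pseudocounting and each row sums to 1.
    """

    motif_id: str
    matrix: np.ndarray  # (L, 4)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError(f"motif {self.motif_id}: matrix must be (L, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise FormatError(f"motif {self.motif_id}: columns do not sum to 1")
        if (self.matrix <= 0).any():
            raise FormatError(f"motif {self.motif_id}: zero probability after pseudocount")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise FormatError(f"motif {self.motif_id}: background does not sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MotifLibrary:
    """Ordered collection of PWMs sharing one background model."""

    motifs: list[PWM]

    def __post_init__(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate motif ids")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, motif_id: str) -> PWM:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(f"unknown motif id {motif_id!r}")

    @property
    def motif_ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs]


@dataclass(frozen=True)
class DoseGroup:
    """One row of a limiting-dilution dose-response table."""

    dose: float  # cells transplanted per recipient
    n_tested: int
    n_responded: int

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise FormatError("dose must be positive")
        if self.n_tested < 1:
            raise FormatError("n_tested must be >= 1")
        if not 0 <= self.n_responded <= self.n_tested:
            raise FormatError("n_responded outside [0, n_tested]")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_counts(counts_path, sheet_path) -> tuple[CountMatrix, SampleSheet]:
    """Read a feature x sample count table together with its sample sheet.

    The count table is tab-delimited with a header row of sample ids and
    feature ids in the first column.  The sheet must describe exactly the
    samples present in the table.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError("duplicate feature ids")
    try:
        values = df.to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-integer count in {counts_path}: {exc}") from None
    if not np.array_equal(values, df.to_numpy()):
        raise FormatError("non-integer count")
    cm = CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)
    sheet_df = pd.read_csv(sheet_path, sep="\t", dtype={"sample_id": str})
    sheet = SampleSheet(sheet_df)
    sheet.validate_against(cm)
    return cm, sheet


def read_bed(path) -> PeakSet:
    """Read BED3+ intervals; column 4 is the peak id when present,
    otherwise ids are auto-generated as ``chrom:start-end``."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            peak_id = parts[3] if len(parts) >= 4 and parts[3] else f"{chrom}:{start}-{end}"
            rows.append((peak_id, chrom, start, end))
    return PeakSet(pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"]))


def read_motifs(path, pseudocount: float = 1e-3) -> MotifLibrary:
    """Parse a MEME-minimal-style motif file.

    Each letter-probability column must sum to 1 within 1e-3; columns are
    then pseudocounted (``pseudocount`` added to every entry) and
    renormalized so every probability is strictly positive.  A missing
    background line means a uniform background.
    """
    background = np.full(4, 0.25)
    motifs: list[PWM] = []
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("Background letter frequencies"):
            i += 1
            freqs: dict[str, float] = {}
            while i < len(lines) and lines[i] and not lines[i].startswith("MOTIF"):
                toks = lines[i].split()
                for base, val in zip(toks[0::2], toks[1::2]):
                    freqs[base] = float(val)
                i += 1
            if set(freqs) >= set("ACGT"):
                background = np.array([freqs[b] for b in "ACGT"])
                background = background / background.sum()
            continue
        if ln.startswith("MOTIF"):
            toks = ln.split()
            if len(toks) < 2:
                raise FormatError(f"{path}: MOTIF line without an id")
            motif_id = toks[1]
            i += 1
            while i < len(lines) and not lines[i].startswith("letter-probability matrix"):
                if lines[i].startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {motif_id} has no probability matrix")
                i += 1
            if i == len(lines):
                raise FormatError(f"{path}: motif {motif_id} has no probability matrix")
            i += 1
            rows = []
            while i < len(lines) and lines[i] and not lines[i].startswith(("MOTIF", "URL")):
                vals = [float(v) for v in lines[i].split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}: motif {motif_id}: expected 4 probabilities per row")
                rows.append(vals)
                i += 1
            mat = np.array(rows, dtype=float)
            if mat.size == 0:
                raise FormatError(f"{path}: motif {motif_id}: empty matrix")
            sums = mat.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-3):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise FormatError(
                    f"{path}: motif {motif_id}: column {bad} sums to {sums[bad]:.4f}, not 1"
                )
            mat = mat + pseudocount
            mat = mat / mat.sum(axis=1, keepdims=True)
            motifs.append(PWM(motif_id, mat, background))
            continue
        i += 1
    return MotifLibrary(motifs)


def read_fasta(path) -> dict[str, str]:
    """Read FASTA sequences, uppercased; characters outside ACGTN rejected."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        extra = set(seq) - _SEQ_ALPHABET
        if extra:
            raise FormatError(f"sequence {rec.id}: invalid characters {sorted(extra)}")
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id}")
        seqs[rec.id] = seq
    return seqs


def read_tss(path) -> TssTable:
    """Read a TSS table: tab-delimited with a gene_id/chrom/tss/strand
    header, or BED6 (TSS = start on +, end-1 on -)."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        return TssTable(df[["gene_id", "chrom", "tss", "strand"]])
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED TSS needs 6 columns")
            chrom, start, end, gene_id, _, strand = parts[:6]
            start, end = int(start), int(end)
            tss = start if strand == "+" else end - 1
            rows.append((gene_id, chrom, tss, strand))
    return TssTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))


def read_gmt(path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: set_id <tab> description <tab> member genes...

    When a ``universe`` is supplied, membership outside it is an error.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs id, description, >=1 gene")
            sid, desc, genes = parts[0], parts[1], parts[2:]
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            members = frozenset(g for g in genes if g)
            if universe is not None and not members <= universe:
                raise FormatError(
                    f"{path}:{lineno}: set {sid!r} has members outside the declared universe"
                )
            sets[sid] = (desc, members)
    return GeneSetCollection(sets)


def read_dose_table(path) -> list[DoseGroup]:
    """Read a dose-response table: dose, n_tested, n_responded per row."""
    df = pd.read_csv(path, sep="\t")
    for c in ("dose", "n_tested", "n_responded"):
        if c not in df.columns:
            raise FormatError(f"dose table missing column {c}")
    return [
        DoseGroup(float(r.dose), int(r.n_tested), int(r.n_responded))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Writers — all emit tab-delimited UTF-8 with a header and trailing newline
# ---------------------------------------------------------------------------


def write_table(records, path) -> None:
    """Write a DataFrame or iterable of mappings as a TSV with header."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    records.to_csv(path, sep="\t", index=False)


def write_counts(cm: CountMatrix, path) -> None:
    df = cm.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def write_bed(peaks: PeakSet, path) -> None:
    peaks.table[["chrom", "start", "end", "peak_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tss(tss: TssTable, path) -> None:
    tss.table.to_csv(path, sep="\t", index=False)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, (desc, members) in collection:
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def write_meme(library: MotifLibrary, path) -> None:
    """Write motifs in MEME-minimal text format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if library.motifs:
            bg = library.motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{b} {v:.6f}" for b, v in zip("ACGT", bg)) + "\n\n")
        for m in library:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.length}\n")
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def write_dose_table(groups: Sequence[DoseGroup], path) -> None:
    write_table(
        pd.DataFrame(
            [(g.dose, g.n_tested, g.n_responded) for g in groups],
            columns=["dose", "n_tested", "n_responded"],
        ),
        path,
    )


# ---------------------------------------------------------------------------
# Config plumbing
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a YAML run configuration (a flat mapping of documented keys)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable content hash of a configuration mapping."""
    blob = yaml.safe_dump(dict(cfg), sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
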