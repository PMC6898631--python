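"""The whole pipeline in one call (equivalent to `reprodyn all`).

Simulates a complete dataset (counts, peaks, promoters, motifs, gene
sets, dose tables), runs every analysis stage, and prints the run
report.  Outputs and a checksummed manifest land in ./run_example.
"""

from pathlib import Path

from reprodyn.pipeline import build_config, cmd_all

outdir = Path("run_example")
cfg = build_config(
    {
        "seed": 7,
        "sim": {"n_genes": 400, "n_peaks": 300, "n_tss": 150, "n_gene_sets": 20},
    }
)
cmd_all(cfg, outdir)
print((outdir / "report.txt").read_text())
print(f"full outputs and MANIFEST.json with checksums: {outdir}/")
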