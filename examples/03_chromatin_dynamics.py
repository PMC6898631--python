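"""CO/OC chromatin dynamics and TSS assignment, AML-like vs HSPC-like.

Simulates peak-count time courses for two cell populations: the
AML-like profile opens chromatin from 3 h (CO-dominated, OC only from
12 h); the HSPC-like profile is silent until 12 h and ~25-fold less
dynamic overall.  Peaks are classified per time point against 0 h and
linked to genes through the closest TSS within a 2 kb window.
"""

import pandas as pd

from reprodyn import (
    SimConfig,
    assign_peaks_to_tss,
    classify_peaks,
    count_dynamics,
    dynamic_region_genes,
    generate_peak_experiment,
    test_peak_differential,
)
from reprodyn.de import reference_size_factors

cfg = SimConfig(seed=3)
totals = {}
for profile in ("aml-like", "hspc-like"):
    cm, sheet, peaks, tss, truth = generate_peak_experiment(cfg, profile)
    sf = reference_size_factors(cm, sheet, "dox")  # two-pass, robust to global opening
    classified = pd.concat(
        [
            classify_peaks(test_peak_differential(cm, sheet, sf, "dox", t))
            for t in (3.0, 6.0, 12.0, 24.0)
        ],
        ignore_index=True,
    )
    dyn = count_dynamics(classified)
    totals[profile] = int(dyn["n_CO"].sum() + dyn["n_OC"].sum())
    print(f"\n{profile}: CO/OC regions per time point")
    print(dyn.to_string(index=False))
    if profile == "aml-like":
        assignments = assign_peaks_to_tss(peaks, tss, window=2000)
        genes = dynamic_region_genes(classified, assignments)
        co_genes = set().union(*(g for (t, c), g in genes.items() if c == "CO"))
        linked = set(truth.peak_genes.values())
        print(f"death-pathway genes with their planted CO peak recovered: "
              f"{len(co_genes & linked)} of {len(linked)}")

print(f"\nkinetic contrast: {totals['aml-like']} vs {totals['hspc-like']} changed "
      f"region-calls = {totals['aml-like'] / totals['hspc-like']:.1f}-fold")
print("The leukemic profile responds early and mostly by opening; the")
print("normal-progenitor profile barely changes before 12 h.")
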