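"""Simulate a dye-swapped two-colour experiment and call differential expression.

Builds a small seven-contrast design with planted effects, normalises the
intensities, averages replicates to one value per gene and biological
replicate, and runs the moderated t-test with Benjamini-Hochberg control.
"""

import numpy as np

from mapktome import (
    ArrayDesign,
    average_replicates,
    call_de,
    gen_two_colour_arrays,
    moderated_test,
    normalize_table,
)

design = ArrayDesign()  # 7 contrasts, 3 biological replicates, dye swaps, 2 probes
table, truth = gen_two_colour_arrays(
    design, n_genes=500, de_fraction=0.15, effect_size=2.0,
    bias_curve=lambda a: 0.3 * np.sin(a / 2.0),  # intensity-dependent dye bias
    seed=1,
)
print(f"simulated {len(table):,} probe measurements for 500 genes")

norm = normalize_table(table, span=0.3)
matrix = average_replicates(norm, design)
result = call_de(moderated_test(matrix), alpha=0.05, fdr_method="bh")
prior = result.attrs.get("prior") or moderated_test(matrix).attrs["prior"]

counts = result[result["de_flag"]].groupby("comparison").size()
print("\ngenes called differentially expressed per contrast (adjusted p <= 0.05):")
print(counts.to_string())

truth_n = truth.de_flags.sum().sum()
called = result.merge(
    truth.de_flags.stack().rename("true_de"),
    left_on=["gene_id", "comparison"], right_index=True,
)
tp = (called["de_flag"] & called["true_de"]).sum()
print(f"\n{tp} of {truth_n} planted effects recovered "
      f"({called['de_flag'].sum()} calls in total); the moderated test shrinks "
      "gene variances towards the fitted prior before testing.")
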