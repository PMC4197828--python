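"""GO-term enrichment of a cluster and kinetic class assignment.

The kinetic classes summarise a gene's response at 1 h and 3 h after
elicitation: F-J for induced genes (transient, decreasing, sustained,
increasing, late) and A-E mirroring them for repressed genes, with a
two-fold rule separating the shapes.
"""

import pandas as pd

from mapktome import class_enrichment, classify_kinetics, hypergeom_enrichment

# --- GO enrichment -------------------------------------------------------
universe = [f"g{i}" for i in range(200)]
annotation = pd.DataFrame(
    [{"gene_id": g, "term_id": "GO:defence"} for g in universe[:30]]
    + [{"gene_id": g, "term_id": "GO:metabolism"} for g in universe[20:]]
)
cluster = universe[:25]  # heavy overlap with the defence term
res = hypergeom_enrichment(cluster, annotation, universe)
print("GO enrichment of a 25-gene cluster (hypergeometric upper tail):")
print(res.round(4).to_string(index=False))
print("ratio > 1 with small p means the term is over-represented "
      "relative to its genome frequency\n")

# --- kinetic classes -----------------------------------------------------
examples = [(10.0, 15.0), (10.0, 50.0), (10.0, 4.0), (10.0, 1.2), (1.2, 10.0), (0.1, 0.25)]
print("fold change 1h / 3h -> kinetic class:")
for fc1, fc3 in examples:
    print(f"  {fc1:>5} / {fc3:>5} -> {classify_kinetics(fc1, fc3)}")

classes = pd.Series(
    ["J"] * 40 + ["H"] * 40 + ["unclassified"] * 120,
    index=[f"g{i}" for i in range(200)],
)
late_cluster = [f"g{i}" for i in range(30)]  # all late-induced (class J)
res = class_enrichment(late_cluster, classes)
top = res.sort_values("pvalue").iloc[0]
print(f"\na cluster of late-induced genes is most enriched for class "
      f"{top['class']} (p = {top['pvalue']:.2e})")
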