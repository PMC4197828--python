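"""Detect a preferentially located motif and test cluster enrichment.

Plants a W-box-like element (TTGACC, bound by WRKY transcription factors)
in a window 200-300 bp upstream of the TSS of 400 target genes, then
recovers the window from the genome-wide scan and tests whether a gene
cluster drawn from the targets is enriched for the element.
"""

from mapktome import detect_plm, gen_promoters, scan_motif, test_cluster_enrichment

targets = [f"g{i:05d}" for i in range(400)]
promoters, truth = gen_promoters(
    2000, length=1000, planted=[("TTGACC", targets, (-300, -200), 0.6)], seed=2
)

occurrences = scan_motif(promoters, "TTGACC", strands="both")
record = detect_plm(occurrences, promoter_length=1000, bin_width=50, motif_id="wbox")
print(f"planted window: (-300, -200); detected functional window: {record.window}")
print(f"{record.genome_genes_with_hit_in_window} of {record.genome_total} promoters "
      f"carry the element inside the window (background p0 = "
      f"{record.background_proportion:.3f}); detection p = {record.pvalue:.2e}")

cluster = targets[:60]  # a co-expression cluster drawn from the targets
res = test_cluster_enrichment(record, cluster, occurrences, cluster_id="demo")
print(f"\ncluster of {res.n} genes: {res.k} carry the element in the window; "
      f"binomial p = {res.pvalue:.2e} -> "
      f"{'significantly over-represented' if res.significant else 'not significant'} "
      "(threshold p < 0.01)")
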