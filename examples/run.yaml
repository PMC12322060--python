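# Synthetic end-to-end run: `sceqtl simulate --config examples/run.yaml`
# writes the inputs, then `sceqtl run --config examples/run.yaml` maps them.
paths:
  genotypes: scratch/example/geno.vcf
  counts: scratch/example/counts.tsv
  cell_metadata: scratch/example/meta.tsv
  gene_annotation: scratch/example/annot.tsv
  outdir: scratch/example/results
analysis:
  seed: 7
  cell_types: [monocyte]
  contrasts: [LPS]
  n_permutations: 500
  qc_min_genes: 5        # the synthetic panel has few genes
  varpart_genes: 5
simulate:
  n_donors: 30
  n_variants: 200
  n_genes: 40
  cells_per_sample: 15
  n_duplicate_pairs: 1
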