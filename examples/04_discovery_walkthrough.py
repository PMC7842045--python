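"""Step through CpG-site discovery for a single gene.

Shows the intermediate objects the training pipeline produces: per-set
Spearman screening records, the rank-sum-combined candidate list, the
selected probe sets, and the per-sample MethCORR score they define.
"""

import methcorr as mc

spec = mc.SyntheticSpec(n_samples=120, n_signal_genes=5, n_null_genes=5,
                        probes_per_gene_pos=6, probes_per_gene_neg=6, seed=9)
meth, expr, truth = mc.generate(spec)

split = mc.split_samples(meth.sample_ids, seed=0)
print(f"split: {len(split.discovery1)}/{len(split.discovery2)}/"
      f"{len(split.validation)} samples (discovery1/discovery2/validation)")

rec1 = mc.spearman_screen(expr, meth, split.discovery1, 1)
rec2 = mc.spearman_screen(expr, meth, split.discovery2, 2)
print(f"significant (P < 0.01) pairs: {len(rec1)} in set 1, {len(rec2)} in set 2")

ranked = mc.combine_rank_sum(rec1, rec2)
gene = truth.signal_genes[0]
print(f"\ntop candidates for {gene} (rank-sum over both sets):")
print(ranked[ranked["gene"] == gene].head(4).to_string(index=False))

matrix = mc.select_top_cpgs(ranked, max_per_side=100)
sets = matrix.genes[gene]
truth_probes = set(truth.genes[gene].pos_probes) | set(truth.genes[gene].neg_probes)
hit = len((set(sets.pos) | set(sets.neg)) & truth_probes)
print(f"\nselected {len(sets.pos)} positive + {len(sets.neg)} negative probes; "
      f"{hit} of {len(truth_probes)} true probes recovered")

mcs = mc.compute_mcs(meth, matrix)
row = mcs.gene_ids.index(gene)
print(f"MCS for {gene}, first 5 samples: "
      + ", ".join(f"{v:.3f}" for v in mcs.mcs[row, :5]))
# The MCS tracks the gene's latent methylation signal: averaging beta over
# positive probes and (1 - beta) over negative probes cancels probe noise.
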