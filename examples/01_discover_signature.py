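"""Discover a reversal-pair signature on a fully ground-truthed cohort.

Simulates a two-group expression cohort (100 HCC-like vs 100 cirrhosis-like
samples, 200 genes, 10 planted reversal pairs), then runs the whole
discovery path: stable pairs per group -> reversal pairs -> ternary
encoding -> mRMR ranking -> IFS prefix selection -> final RBF-SVM fit.
"""

import reosig as rs

cfg = rs.SyntheticConfig(seed=7)
matrix, labels, truth = rs.generate(cfg)
print(f"cohort: {matrix.n_genes} genes x {matrix.n_samples} samples "
      f"({labels.n_pos} positive / {labels.n_neg} negative)")

result = rs.discover(matrix, labels, seed=7)

print(f"stable pairs: {len(result.stable_pos)} in the positive group, "
      f"{len(result.stable_neg)} in the negative group")
print(f"reversal pairs: {len(result.reversal)} "
      f"(planted: {len(truth.table)})")
recovered = set(zip(result.reversal.table.gene_a, result.reversal.table.gene_b))
print(f"exact ground-truth recovery: {recovered == truth.planted_pairs()}")

print(f"IFS: chose k = {result.ifs.chosen_k} of {len(result.ranked)} ranked pairs "
      f"at peak CV accuracy {result.ifs.peak_accuracy:.4f}")
print(f"signature: {result.ifs.signature}")
pct = result.train_metrics.as_percent()
print(f"training fit: sensitivity {pct['sensitivity']}%, "
      f"specificity {pct['specificity']}%, accuracy {pct['accuracy']}%")

# Stable pairs are pairs whose within-sample ordering is conserved in >= 95%
# of a group's samples; reversal pairs flip direction between groups and are
# the candidate diagnostic features. The IFS curve peaking at a small k means
# a compact signature already classifies the training cohort perfectly.
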